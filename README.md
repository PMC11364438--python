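# flyphen

Quantitative phenotyping for *Drosophila* mild-head-trauma experiments:
startle-induced climbing (Climbing Index), tracking-derived locomotor
kinematics (speed, heading, abnormal-direction fraction), vacuole
quantification in two-channel 3-D brain stacks, and survival / group
statistics — together with synthetic-data generators that produce all three
input modalities with known ground truth, so the whole pipeline is testable
without external data.

## Modules

| module | what it does |
| --- | --- |
| `flyphen.synthetic` | cohort presets; trajectory, brain-stack, and survival-table generators (seeded, bit-reproducible) |
| `flyphen.climbing` | per-second Climbing Index from positions or bin counts; accumulated & sham-normalized CI; curve permutation test |
| `flyphen.kinematics` | per-frame speed and heading (0° = vertical); abnormal-direction fractions (outside ±30°, first 3 s); speed/angular histograms |
| `flyphen.vacuoles` | brain segmentation (cortex/neuropil/exclusion); 3-D vacuole detection with size, roundness, and esophagus-exclusion filters; group stats |
| `flyphen.stats` | Kaplan–Meier with Greenwood variance; Mantel–Cox log-rank; pairwise log-rank with Bonferroni; Wilcoxon rank-sum (exact for small tie-free samples) |
| `flyphen.trajectory`, `flyphen.brain` | shared domain types and CSV/TIFF I/O |

The Climbing Index follows the standard definition: the 90 mm vial is split
into 10 equal height bins, flies counted per bin at every second of the
10 s trial (601 frames at 60 fps), and CI(t) = Σ_b b·count(t, b) / n_flies,
so CI ∈ [1, 10].

## CLI

Each pipeline stage is a console script. A typical end-to-end run:

```sh
# synthetic inputs (any of 12 presets: {male,female_mated,female_virgin} x
# {sham,D3Inj,D17Inj,D31Inj})
simulate-trajectories --preset female_mated_sham   --n-flies 15 --trials 9 --seed 1 --out sham/
simulate-trajectories --preset female_mated_D31Inj --n-flies 15 --trials 9 --seed 2 --out inj/
simulate-brain --out stack.tif --truth truth.json --mask-out mask.tif --seed 3
simulate-survival --out surv.csv --presets male_sham --presets male_D31Inj --seed 4

# analysis
ci --traj-dir sham/ --out ci_sham.csv
ci-test --group-a sham/ --group-b inj/ --n-perm 9999 --seed 5
kinematics --traj-dir inj/ --window 3 --out kin.csv --hist-out hist.json
vacuoles --stack stack.tif --mask mask.tif --out lesions.csv --summary summary.json
survival --table surv.csv --pairwise --out logrank.json
ranksum --a counts_a.csv --b counts_b.csv
```

Trajectory CSVs use the tracker-output shape (`frame, fly_id, x_mm, y_mm`);
brain stacks are multi-page TIFFs with channel-interleaved pages (nuclear,
F-actin); survival CSVs have `subject_id, group, time_days, event`.

## Notes

- All preset effect sizes are invented and documented in
  `src/flyphen/presets.json`; they encode only the qualitative group
  orderings (injured / older-at-injury / mated-female cohorts climb slower
  with more dispersed headings), not the study's measured magnitudes.
- The curve permutation test is this package's native inference for CI
  curves; it stands in for repeated-measures ANOVA, testing the same null
  (no group difference in the curve) in a self-contained, exactly
  verifiable way.
- Minimum detected lesion diameter defaults to 2 µm: at 1 µm voxel
  sampling a 1 µm lesion is a single voxel, indistinguishable from noise.
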