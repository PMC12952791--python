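# ethokit

Pose-based behavior classification, bout-level agreement analysis, and
strain-level genetic phenotyping for open-field rodent video.

`ethokit` turns per-frame keypoint tracks (12 keypoints, typically 30 fps)
into behavior ethograms and downstream genetics:

- **pose** — HDF5 pose I/O (`/poseest/points`, `/poseest/confidence`),
  coverage validation, short-gap interpolation.
- **features** — per-frame kinematics (pairwise distances, speeds, heading,
  angular velocity, joint angles) plus windowed summary statistics over
  ±*w* frames.
- **annotations** — ternary frame labels (behavior / not / unlabeled), bout
  extraction, and stitch-then-filter post-processing of predictions.
- **classify** — sparse-label tree-ensemble classifiers (random forest /
  gradient boosting / histogram gradient boosting), video-grouped
  cross-validation, portable classifier archives.
- **metrics** — confusion counts, accuracy/F1, Cohen's κ, ROC/AUROC,
  TPR at a capped FPR, Venn overlap fractions, behavior density.
- **ethograph** — bipartite bout graph between two annotators with
  interval-IoU edge weights, the bout-agreement statistic, and the
  stitch/filter hyperparameter scan.
- **phenotypes** — nine aggregate phenotypes per behavior (duration, bout
  count, mean bout length × 5/20/55-minute bins), strain z-score matrices,
  sex-effect rank tests with BH-FDR, and dataset imbalance metrics (SI/GI/AGI).
- **genetics** — genotype QC (MAF ≥ 0.10, missingness ≤ 0.05), per-SNP
  association scan, permutation-based genome-wide thresholds, GWAS power
  simulation, greedy LD-based QTL grouping, and Haseman–Elston
  heritability / genetic-correlation estimators on a GRM.
- **synth** — seeded generators for everything above: scripted pose
  sequences with ground-truth ethograms, annotator label-noise pairs, and
  strain panels with known heritability.

## CLI

```bash
ethokit simulate pose --script turn_left --frames 3000 --seed 1 -o sim.h5
ethokit validate-pose sim.h5 --min-confidence 0.3
ethokit features sim.h5 --window 5 -o features.csv
ethokit predict groomer.clf sim.h5 -o preds.csv
ethokit postprocess preds.csv --stitch 5 --filter 9 -o clean.csv
ethokit compare a.csv b.csv --bout --w-star 0.5
ethokit phenotype preds.csv --behavior groom
ethokit simulate panel --strains 60 --reps 10 --h2 0.5 -o panel
ethokit gwas-power panel_geno.csv panel_map.csv panel_pheno.csv \
    --pve 0.05 --n-causal 20 --threshold 1.9e-5 --seed 7
```

## Conventions

- Image coordinates: origin top-left, x rightward, y downward, pixel units;
  frames are 0-based.
- Velocities are reported per second (scaled by fps); derivatives are
  central differences, one-sided at sequence boundaries; windows clamp.
- Stitching merges bouts whose gap is *strictly* below the threshold;
  filtering keeps bouts of length ≥ the minimum; processing order is
  stitch → filter.
- Bout overlap is interval intersection-over-union; bout agreement counts
  bouts whose best overlap strictly exceeds w\*, averaged over both sides.
- Z-scores use the sample (n−1) standard deviation across strains; a bout
  belongs to a time bin if its onset falls inside it.
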