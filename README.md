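# geomstate

State-space geometry of working-memory task representations.

`geomstate` is for researchers who want to know not just *whether* task
variables are encoded in multichannel neural data, but whether their
population-level arrangement mirrors the task's designed structure. The
motivating paradigm crosses two binary goal dimensions (size × color) into
four goals applied to a 3 × 3 stimulus grid; if neural goal codes respect
that 2D structure, the four condition means should sit at the corners of a
square in their dominant plane.

## The statistic

For condition means **X** (n_conditions × n_channels), each channel is
z-scored across conditions and the top-2 principal components define the
condition subspace. Projected conditions are connected in the fixed design
order (goals: BR → BG → SG → SR) and scored by the circularity index

    C = 4π · Area / Perimeter²

with C = 1 for a circle, C = π/4 ≈ 0.785 for a square (the quadrilateral
maximum), and C ≈ 0 for collinear or crossed arrangements. Around this core
the package provides:

* time-resolved C in non-overlapping 80-ms windows with stratified
  resampling, and cluster-based permutation inference (within-subject label
  shuffles, max-run-length cluster statistic);
* good-vs-bad trial splits on combined behavioral error, in a shared
  whole-data subspace, with a label-swap permutation null;
* RSA: 2D (hamming 0/0.5/1) and conjunctive model RDMs, 4-fold
  cross-validated correlation-distance data RDMs, Spearman and partial
  Spearman comparison;
* theta (4–7 Hz) wPLI coherence between a frontal seed and posterior
  channels, sign-flip cluster tests, and cluster-masked coupling–geometry
  correlations;
* a volumetric searchlight (9-mm spheres over trial-wise betas) with
  bootstrap-of-permutations group cluster correction, ROI robustness
  bootstraps, and beta-series functional connectivity;
* a synthetic-data generator that plants known geometries (square, grid)
  into channels/voxels so every stage is validated by parameter recovery.

## Worked example

Simulate a session with a planted goal square active through the delays, run
the circularity time course with the scaled-down inference preset, and
summarize:

```python
from geomstate import AnalysisConfig
from geomstate.pipeline import run_pipeline

cfg = AnalysisConfig(seed=7, preset="scaled_down", out_dir="demo",
                     reps_per_cell=6, n_channels=16, noise_sd=1.0)
run_pipeline(cfg)
```

```bash
$ geomstate report --dir demo
run of geomstate 0.1.0 (preset scaled_down, seed 7)
  ...
peak circularity 0.785; 1 significant cluster(s) of 3
  cluster 420-3780 ms, size 43, p=0.0020
```

The peak of 0.785 is the square's analytic value π/4: at this SNR the
condition means recover the planted geometry almost perfectly. The
significant cluster spans 420–3780 ms — the planted activation window
(Delay 1 through Delay 2, 400–3800 ms) — with a permutation p of 0.002
against 500 within-subject label shuffles; the two sub-threshold runs
outside it are noise. The same analyses are available as library calls
(`timecourse_circularity`, `permutation_null`, `cluster_test`, ...) and as
CLI subcommands (`geomstate simulate | timecourse | split | rsa | coherence
| searchlight | fc | report`).

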