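# seqrecog

Group-level MEG source-space analysis of auditory sequence recognition,
re-built as a tested, reusable pipeline and exercised end-to-end on a
synthetic-study generator with known ground truth.

The scientific setting: participants memorize short musical pieces and then
judge five-tone excerpts (1250 ms, one tone per 250 ms) as *memorized* or
*novel* while MEG is recorded. The analysis asks (a) which brain sources are
more active when recognizing memorized than novel sequences, tone by tone,
and (b) where that memorized-minus-novel activity scales with individual
working-memory (WM) ability. Because the statistics run on ~1700 source
voxels in five time windows, multiple comparisons are corrected with a
cluster-based Monte Carlo spatial-permutation procedure.

## What the package computes

For each participant, sensor epochs are conditioned (correct-trial
selection, optional 48–52 Hz notch and 0.1–1 Hz band-pass, 100-ms baseline
correction) and projected to an 8-mm source grid with a unit-gain LCMV
beamformer: for source *i* with lead-field column *lᵢ* and sensor
covariance *C*,

    wᵢ = C⁻¹ lᵢ / (lᵢᵀ C⁻¹ lᵢ),      wᵢᵀ lᵢ = 1.

Source time courses are averaged within the five tone windows (0–250,
251–500, 501–750, 751–1000, 1001–1250 ms). Group statistics per voxel and
window:

* **contrast** — paired t across participants on memorized − novel
  (df = n − 1), binarized at two-sided α = .001;
* **WM correlation** — Pearson r between WM score and memorized − novel
  (df = n − 2), binarized at α = .05 (α = .025 for the optional
  musician/nonmusician split);
* **behavioral** — Pearson r between recognition accuracy and WM score.

Suprathreshold voxels are labelled into connected clusters (26-connectivity
by default). The observed number of significant voxels is relocated
uniformly at random over the in-brain grid 1000 times; each permutation's
maximum cluster size forms the null distribution, and an observed cluster
is significant only if its size strictly exceeds the null's 95th
percentile (nearest rank).

The synthetic-study generator plants condition effects (between-participant
Cohen's d in designated contiguous voxel clusters and tone windows) and
WM-coupled effects (per-participant amplitude = mean + β·z(WM) + residual),
projects them through seeded per-participant lead fields, and keeps the
ground truth alongside the data — so family-wise error control and cluster
recovery are measurable facts, not hopes.

## Worked example

Simulate a 70-participant study with a 30-voxel effect (d = 0.8) planted in
tone windows 3–4 on a 12×12×12 grid, run the whole pipeline, and summarize:

```python
from seqrecog import presets
from seqrecog.pipeline import RunConfig, GridConfig, run_pipeline

cfg = RunConfig(
    sim=presets.contrast_recovery_config(seed=0),
    grid=GridConfig(dims=(12, 12, 12)),
    seed=7,
)
run_pipeline(cfg, "demo_run")
```

```bash
$ seqrecog report --run-dir demo_run
participants retained: 70
behavioral WM-accuracy correlation: r = -0.109, p = 0.369
contrast clusters (significant only):
  window 1: none
  window 2: none
  window 3: pos k=30
  window 4: pos k=31
  window 5: none
correlation clusters (significant only):
  window 1: none
  window 2: none
  window 3: none
  window 4: none
  window 5: none
```

Reading the output: the planted 30-voxel effect is recovered as a
significant positive cluster of k = 30 voxels in window 3 and k = 31 in
window 4 (one leakage voxel attached), and nowhere else; no WM coupling was
planted, so the correlation maps are clean; accuracy and WM are simulated
independent, and their sample correlation (r = −0.11, p = .37) is
appropriately non-significant. Full cluster tables (per-voxel rows with
millimetre coordinates and statistics), NIfTI maps of every t/r map, and a
reproducibility manifest are written into `demo_run/`.

The same stages are available individually (`seqrecog simulate / condition
/ beamform / stats / mcs / run / report`) operating on serialized
intermediates; see `seqrecog --help`.

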