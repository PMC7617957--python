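# barrelcircuit

Quantification pipeline for relating cortical-neuron lineage to
thalamocortical input, built around five analysis stages plus a
synthetic-data generator with known ground truth:

- **synthdata** — generators for every input modality: stimulus-locked
  Poisson/Bernoulli spiking sessions with planted selectivity, laminar
  LFP synthesized from a target CSD (exact round trip), paired
  alpha-function EPSP sweeps with a planted amplitude ratio, curved
  barrel-field images with known barrel intervals / soma positions /
  dendritic splits, and pre/post plasticity spike counts with a known
  potentiation factor.  Identical parameters + seed give bit-identical
  output.
- **ephys** — zero-phase band splitting (300–6000 Hz MUA; <300 Hz LFP +
  50 Hz notch), MAD-threshold multiunit detection, current source
  density (central second spatial difference), shortest-latency-sink
  layer assignment, trough-to-peak RS/FS classification (0.5 ms
  boundary), and optotag classification (mean light latency <5 ms with
  a reliability floor).
- **tuning** — trial-by-trial spontaneous subtraction, evoked counts in
  50 ms windows, 1 ms-bin response latency (5–20 ms), and the
  selectivity index `SI = R_pw / (R_pw + R_aw)` on cumulative
  spontaneous-subtracted counts for single and 4-deflection train
  stimuli, plus population PW/AW confirmation.
- **slice_circuits** — EPSP amplitude/onset from averaged sweeps,
  monosynaptic latency gating, the paired input-bias index
  `A_ip / (A_ip + A_op)`, and intrinsic properties from current steps.
- **histomorph** — exact polyline straightening to (arc length, normal
  distance) coordinates, automatic barrel-boundary detection from the
  straightened L4 intensity profile, the soma barrel index (1 at a
  barrel center, 0 at a septal midpoint), exact per-barrel dendritic
  overlap percentages with the <5% exclusion rule, soma MPI ratios, and
  ROI expression fractions.
- **plasticity** — the pre / 8 Hz-RWS / post schedule (100 + 480 + 100
  events) and the delta spike-rate statistic `100 * post / pre` over
  250 ms windows.
- **stats_report** — one-sample/Welch/Mann-Whitney/paired tests,
  Kruskal-Wallis with Dunn's pairwise z-tests (Bonferroni), group
  summaries (mean ± SEM, type-7 IQR), and the end-to-end pipeline
  runner.

## CLI

```bash
barrelcircuit run --config config.yaml        # full pipeline
barrelcircuit ephys  --seed 1 --out out/      # single stages
barrelcircuit tuning --seed 1 --out out/
barrelcircuit slice  --seed 1 --out out/
barrelcircuit histo  --seed 1 --out out/
barrelcircuit sltp   --seed 1 --out out/
```

A config names the stages and per-stage generator parameters:

```yaml
seed: 1
stages: [ephys, tuning, laminar, slice, histo, sltp]
ephys: {n_units: 20, trials_per_whisker: 100}
slice: {n_pairs: 20, amp_ratio: 0.5}
```

Each run writes TSV result tables, the generating config copy, a
`run_log.json` (seed, versions, decisions in force) and a `summary.md`.

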