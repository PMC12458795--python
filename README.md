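# hierkit

Quantitative analytics for studies of social dominance hierarchy in small
groups of mice and its neural correlates. The package bundles, as tested and
reusable code, the bespoke procedures such a study chains together:

- **Tournament analytics** (`hierkit.tourney`) — Elo ratings over round-robin
  tube-test contests, ordinal ranks, hierarchy *stability* (fraction of
  animals keeping their rank between round robins, moving-averaged),
  pairwise *consistency* (a capped run-length counter of repeated
  same-winner outcomes, reset on reversals), *delta Elo* (per-round-robin
  rating change) with rank-dependent variance, the defensive-behavior index
  A/(A+B), and a random-outcome null ensemble for observed-vs-chance
  comparisons.
- **Calcium imaging** (`hierkit.calcium`) — fiber-photometry preprocessing
  (20 Hz block-average downsampling, Gaussian smoothing, 30 s pre-entry
  baseline), tube partition into approach/interact/retreat thirds,
  detection of the first sustained baseline deviation (five successive
  same-direction points beyond three baseline SDs), and miniscope ROI
  three-way classification (activated / inhibited / persistent at two SDs of
  the post-minus-pre difference distribution).
- **Slice electrophysiology** (`hierkit.ephys`) — FI curves and input
  resistance, two-cluster excitability typing (K-means) with Hartigan's dip
  test for bimodality, template-match detection of spontaneous postsynaptic
  currents with difference-of-exponential kinetics, per-minute cumulative
  charge transfer, paired-pulse short-term plasticity ratios, the
  antagonist-sensitive (TRPM3) fraction of the barium current, IV-curve peak
  extraction, and the alpha-filtered white-noise current stimulus generator.
- **Gene-set enrichment** (`hierkit.gsea`) — a compact permutation-FDR
  engine for single-nucleus cluster × condition comparisons: nuclei QC
  (mitochondrial / UMI-doublet / hemoglobin / immediate-early-gene filters),
  log-normalization, signal-to-noise gene ranking, weighted running-sum
  enrichment scores with leading edges, label-permutation FDR (significance
  at FDR < 0.25 and BH-adjusted p < 0.01), and intersection with external
  DEG tables.
- **Neuroanatomical tracing** (`hierkit.tracing`) — rabies convergence index
  with starter-cell normalization and anterograde relative synaptic density
  from ROI fluorescence.
- **Synthetic data** (`hierkit.synthio`) — seeded generators for every input
  class with planted ground truth (latent dominance worlds, trace onsets,
  ROI response classes, synaptic events, gene-set expression shifts and QC
  violations), so every procedure is testable end to end without recorded
  data.

## The core statistics

After each contest the winner's Elo rating rises by `k·(1 − E)` and the
loser's falls by the same amount, where `E = 1/(1 + 10^((R_loser −
R_winner)/400))` is the winner's expected score (`k = 100`, start rating
1000 by default). Stability between consecutive round robins is the
fraction of animals with unchanged ordinal rank; consistency for a pair is a
counter incremented (capped at 4 for quartets, 3 for trios) when an outcome
repeats and reset to zero on a reversal, reported as counter/cap. The
enrichment score of a gene set is the signed maximum deviation of a weighted
Kolmogorov–Smirnov running sum over the signal-to-noise-ranked gene list;
leading-edge genes are set members at or before that maximum.

## Worked example

```python
from hierkit import synthio, tourney

world = synthio.DominanceWorld(
    animal_ids=["m1", "m2", "m3", "m4"],
    latent_dominance=[1.5, 0.5, -0.5, -1.5],
    steepness=3.0, seed=11)
log = synthio.simulate_tournament(world, n_round_robins=14)   # 7 tournaments

res = tourney.HierarchyAnalysis(log).fit(null_reps=1000, seed=7)
print(res.summary().round(2))
```

```
    final_elo  final_rank  mean_delta_elo
m1    1518.58           1           37.88
m2    1164.18           2            1.86
m3     837.32           3           -9.77
m4     479.91           4          -29.97
```

The planted dominance order is recovered (m1 is rank 1 with a strongly
positive mean delta Elo; m4 the reverse). The observed mean stability
(0.942) and mean pairwise consistency (0.810) sit far above the
random-outcome null ensemble, whose 95% interval is:

```
print(res.null_quantiles().round(3))
       stability_mean  consistency_mean
0.025           0.202             0.131
0.500           0.375             0.202
0.975           0.577             0.298
```

The same analyses are available from the shell, e.g.

```bash
hierkit sim tournament --group-size 4 --seed 1 --out contests.csv
hierkit tourney --log contests.csv --null-reps 1000 --seed 7 --out stats
hierkit gsea run --counts counts_dir --gmt sets.gmt --n-perm 1000 --seed 7 --out gsea.tsv
```

Every run writes a JSON manifest (inputs, parameters, seed, versions) next
to its outputs; identical seeds reproduce outputs bit for bit.

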