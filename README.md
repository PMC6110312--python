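# mirkinet

Kinetic modeling and single-cell inference of miRNA–target response
parameters.

## The problem

A miRNA-loaded Argonaute complex (Ago–miRNA) is a shared, limited
resource: hundreds of mRNA targets compete to bind it, and a bound target
is destabilized. Which targets respond, and at what miRNA dose, is set by
two numbers per target — a Michaelis–Menten-like constant and a critical
free-complex concentration — that are essentially unmeasured *in vivo*.
Single-cell RNA-seq of a population in which miRNA expression varies
widely from cell to cell (e.g. an inducible miRNA with a co-expressed
reporter as a per-cell proxy) contains enough information to infer both
numbers for every target at once. `mirkinet` implements the model, the
inference, the supporting single-cell statistics, a stochastic simulator,
and a synthetic-data benchmark for validating the whole pipeline, aimed at
computational biologists working on post-transcriptional regulation.

## The model

For targets `i = 1..M` with transcription rate `α_i`, free-mRNA decay
`δ_i`, Ago–miRNA binding/unbinding `k_on_i`, `k_off_i` and bound-mRNA
decay `k_cat_i`, with total complexes `A` constant per cell and
`A_F = A − Σ_i Am_i` free:

    dm_i/dt  = α_i − δ_i m_i − k_on_i m_i A_F + k_off_i Am_i
    dAm_i/dt = k_on_i m_i A_F − (k_off_i + k_cat_i) Am_i

At steady state the bound fraction is `f_i = 1 / (1 + K_M_i / A_F)` with
`K_M_i = (k_off_i + k_cat_i) / k_on_i`, and the total level
`T_i = m_i + Am_i` interpolates between `T0_i = α_i/δ_i` (no miRNA) and
`T∞_i = α_i/k_cat_i` (saturating miRNA):

    T_i* = T0_i / (1 + f_i (T0_i/T∞_i − 1)) .

The target sits halfway between its plateaus at the critical concentration
`A_F^C_i = K_M_i · T∞_i / T0_i`. Across cells `j` with different free
pools `A_F^j`, the transformed matrix

    T̃_ji = (T0_i/T∞_i − 1) / (T0_i/T_ji − 1) − 1  =  K_M_i / A_F^j

is rank 1, so the best rank-1 factorization (leading SVD triplet) yields
per-cell `A_F` and per-target `K_M` simultaneously — up to one global
scale factor, which cancels in all rank orders and ratios. Heavy
smoothing along the cell axis makes `A_F` the better-determined factor;
`K_M_i` is then refined as the cell average of `A_F^j · T̃_ji`.

## Worked example

Generate the standard in-silico benchmark (300 targets, 4000 cells, total
miRNA log2-uniform on [−40, 14], calibrated log-normal measurement noise)
and recover the parameters that generated it:

```python
import numpy as np
from scipy.stats import pearsonr
from mirkinet import BenchmarkSpec, generate_benchmark, run_inference

bench = generate_benchmark(BenchmarkSpec(seed=1))
result = run_inference(bench.matrix)

idx = {p.id: i for i, p in enumerate(bench.params)}
sel = [idx[g] for g in result.gene_ids]
r_afc = pearsonr(np.log(bench.true_afc[sel]), np.log(result.a_f_c))[0]
r_km = pearsonr(np.log(bench.true_km[sel]), np.log(result.km))[0]

print(f"retained {result.cells.size} responsive cells, "
      f"{result.gene_ids.size} of {len(bench.params)} targets")
print(f"rank-1 residual of the transformed matrix: {result.residual:.3f}")
print(f"log-scale Pearson r, true vs inferred A_F^C: {r_afc:.2f}")
print(f"log-scale Pearson r, true vs inferred K_M:   {r_km:.2f}")
```

prints

```
retained 297 responsive cells, 290 of 300 targets
rank-1 residual of the transformed matrix: 0.579
log-scale Pearson r, true vs inferred A_F^C: 0.59
log-scale Pearson r, true vs inferred K_M:   0.57
```

The residual says the smoothed, transformed data are far from exactly
rank 1 — the measurement noise is large by construction (total target
levels spread about twofold among cells of similar miRNA level) — yet the
recovered critical concentrations still rank targets close to the truth
(r ≈ 0.6 on the log scale). With noise switched off the same pipeline
recovers both parameter vectors essentially exactly (r > 0.999, residual
< 1e−6). `result.scale_identified` is `False`: `A_F` and `K_M` are
reported up to the shared scale factor; `mirkinet.resolve_scale` pins it
when a ground-truth free-complex vector is available.

The same steps run from the shell:

```sh
mirkinet generate --seed 1 --out bench/
mirkinet infer --matrix bench/matrix.tsv --proxy-file bench/matrix.cells.tsv --out run/
```

Other entry points: `mirkinet simulate` (exact SSA / tau-leaping
single-cell trajectories), `mirkinet stats` (sliding-window C_V and
pairwise-correlation curves against a non-target background), and
`mirkinet cerna` (competing-RNA titration scenarios).

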