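# diurnet

Diurnal transcriptome analysis: detection of 24 h periodic genes and
inference of gene networks from short, replicated expression time
series.

Plant transcriptomes sampled through a light/dark cycle — e.g. leaves
collected every 4 h over two days with three biological replicates —
show large rhythmic programs, and the question that follows the gene
list is structural: which genes co-cycle, and which genes' expression
predicts other genes' expression a few hours later?  `diurnet`
implements that analysis end to end for researchers working with such
designs:

1. **Normalization & filtering** — read counts → RPM
   (`count / library × 10⁶`); a gene is *expressed* if all replicates
   reach RPM ≥ 1 at some sampling time.
2. **Periodicity screen** — time-averaged analytic Morlet wavelet power
   (ω₀ = 6) at the 24 h period, tested against white-noise surrogates
   (p = (1+#{null ≥ obs})/(1+1000)); a gene is *periodic* only if
   p < 0.01 in **all 30** replicate-resampled permutations of the
   series.  Peak times come from first-harmonic (cosinor) regression.
3. **Co-expression network** — Pearson correlation between periodic
   genes with a signed cutoff (r ≥ 0.7 and r ≥ 0.8 by default).
4. **Directed network** — per target gene g, a sparse ARX(p) regression

       x_g(t) = Σ_{i} Σ_{l=1..p} β_{i,l} x_i(t−l) + ε(t),   p ∈ {1,2,3}

   over *all* candidate regulators i, where each regulator's p lagged
   coefficients form one group penalized by group SCAD
   (Σ_i p_{λ,a}(‖β_i‖₂), a = 3.7), solved by group coordinate descent
   with λ chosen per target by extended BIC.  Because ~12 timepoints
   cannot support one stable fit, 30 replicate-resampled datasets yield
   30 networks; the confidence matrix B counts each directed edge's
   occurrences, and edges with B > 20 are called.  Parents, children,
   hubs (> 50 targets) and degree distributions are then summarized.

A synthetic-data module generates the full study design — sinusoidal
genes with known phases, autocorrelated background genes, sparse stable
ARX systems with known edges, and Poisson read counts — so every stage
is testable against ground truth without any external download.
See `docs/methods.md` for models, defaults and numerical details.

## Worked example

Recovering a planted regulatory network from noisy replicated series:

```python
from diurnet import (generate_arx_tensor, ensemble_infer,
                     confidence_matrix, call_edges, network_summary)

tensor, truth = generate_arx_tensor(
    n_genes=30, n_parents=6, children_per_parent=3, order=1,
    coef_magnitude=(0.4, 0.8), innovation_sd=0.1,
    grid_or_length=100, seed=7, n_reps=3, measurement_sd=0.05)

networks = ensemble_infer(tensor, order=1, M=30, base_seed=7)
called = call_edges(confidence_matrix(networks), threshold=20)

est, true = set(called.graph.edges()), truth.edge_set()
tp = len(est & true)
print(f"planted edges        : {len(true)}")
print(f"called edges (B>20)  : {len(est)}")
print(f"precision / recall   : {tp/len(est):.2f} / {tp/len(true):.2f}")
```

```
planted edges        : 18
called edges (B>20)  : 12
precision / recall   : 1.00 / 0.67
```

Every called edge is a true planted edge (the confidence filter trades
recall for precision — single trials on the same data average ~0.83
precision), and the 12 survivors span all 6 planted parents.

The full pipeline runs from a config object (or YAML file / CLI):

```python
from diurnet import PipelineConfig, simulate, run_pipeline

cfg = PipelineConfig(out_dir="demo_run", seed=42,
                     sim_n_periodic=40, sim_n_background=40, sim_n_arx=20,
                     sim_n_parents=4, sim_children_per_parent=3,
                     sim_noise_sd=0.3)
sim = simulate(cfg, out_dir="demo_sim")      # counts + truth TSVs
res = run_pipeline(cfg, counts=sim["counts"])
```

which prints stage logs and leaves TSV outputs, `summary.json` and a
checksummed `manifest.json` in `demo_run/`; for this configuration:

```
expressed genes      : 100 / 100
periodic genes       : 40 (planted: 40)
GCN at r>=0.7        : 40 nodes, 191 edges
GCN at r>=0.8        : 40 nodes, 156 edges
```

All 40 planted sinusoids (and no background or ARX gene) pass the
30-permutation wavelet screen, and the co-expression network connects
them with the expected nesting between cutoffs.  The same stages are
available as shell commands:

```bash
diurnet simulate --config config.yaml
diurnet run --config config.yaml --seed 42 --out-dir run/
diurnet periodicity counts.tsv metadata.tsv --out periodic.tsv
diurnet grn counts.tsv metadata.tsv --order 2 --out edges.tsv
```

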