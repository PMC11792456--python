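# planktonscape

Community-ecology analysis of eukaryotic plankton in a canyon reservoir,
packaged as a reusable, tested pipeline. It is aimed at freshwater
microbial ecologists who work with 18S amplicon OTU tables from spatially
replicated surveys (here: 6 sites × 3 seasons × 3 replicates = 54 samples)
and want one coherent toolchain for:

- **Diversity** — Shannon-Wiener `H = −Σ (nᵢ/N) ln(nᵢ/N)`, Margalef richness
  `M = (S−1)/ln N`, Bray-Curtis dissimilarity, NMDS (Kruskal stress-1),
  PERMANOVA, one-way ANOVA.
- **Water quality** — the trophic level index
  `TLI(Σ) = Σ Wⱼ·TLI(j)` over Chl a, TP, TN, SD and COD_Mn, with weights
  `Wⱼ = rⱼ²/Σrⱼ²` (correlations with Chl a) and the national
  oligo-/meso-/eutrophic grading, plus TLI-vs-environment and
  TLI-vs-diversity regressions.
- **Spatial structure** — haversine geographic distances, standardized
  environmental distances, distance-decay regressions with Mantel-style
  permutation p-values, and Mantel tests.
- **Constrained ordination** — a DCA gradient-length diagnostic (linear
  model when axis-1 length < 3 SD units) and Hellinger-based RDA with
  Monte-Carlo (permutation) significance, overall and per variable.
- **Co-occurrence networks** — Spearman edges (|ρ| ≥ 0.6, BH-FDR < 0.05),
  the standard topology panel (degree, density, diameter, clustering,
  modularity, path length, positive/negative split), Louvain modules, and
  Zi-Pi key-species classification (thresholds Zi = 2.5, Pi = 0.62).
- **Assembly inference** — the Sloan neutral community model, which predicts
  an OTU's occurrence frequency from its regional mean abundance p via
  `f̂ = 1 − BetaCDF(d; Nᵀm·p, Nᵀm·(1−p))` and estimates the migration rate
  m by least squares, and the modified stochasticity ratio
  `MST = D/Ē if D ≤ Ē else (1−D)/(1−Ē)` against an abundance-proportional
  null, read as stochasticity-dominated above 0.5.

Because the original sequencing data live in an external repository, the
package ships a first-class synthetic survey generator
(`planktonscape.synthetic_data`) that reproduces the survey's design with
known ground truth — a lognormal species-abundance distribution over ~2,000
OTUs, environmental gradients tied to a latent trophic axis, and switchable
neutral / niche-filtered / dispersal-limited assembly — so every method is
validated by parameter recovery rather than by eyeballing.

## Worked example

```python
from planktonscape.synthetic_data import SimulationParams, simulate_dataset
from planktonscape import assembly, tli

ds = simulate_dataset(SimulationParams(assembly_mode="neutral", seed=1))
fit = assembly.fit_ncm(assembly.occurrence_stats(ds.table))
print(f"m = {fit.m:.3f}, R2 = {fit.r2:.3f}")

nulls = assembly.null_communities(ds.table, n_iter=100, seed=1)
res = assembly.mst(ds.table, nulls)
print(f"mean MST = {res.mean:.3f} -> {res.classification}")
```

prints

```
m = 0.127, R2 = 0.972
mean MST = 0.803 -> stochastic
```

The generator's true migration rate is 0.1, so the neutral fit recovers m
within ~30% and its high R² says occurrence frequencies follow the neutral
beta prediction; the mean stochasticity ratio above 0.5 classifies assembly
as stochasticity-dominated, matching the ground truth. Running the same two
estimators on a niche-filtered survey (`assembly_mode="deterministic"`)
yields `R2 = 0.317` and `mean MST = 0.437 -> deterministic`.

The full narrative lives in the numbered drivers under `analysis/`:

```bash
python analysis/01_simulate.py --seed 1        # writes results/data/...
python analysis/02_composition_diversity.py
python analysis/03_water_quality_tli.py
python analysis/04_distance_decay_mantel.py
python analysis/05_ordination.py
python analysis/06_networks.py
python analysis/07_assembly.py
```

Each step prints what it found (for example, step 03 grades the six
synthetic sites from TLI 25.49 "Oligotrophic" to 44.88 "Mesotrophic") and
writes its tables under `results/`. The same stages are scriptable through
`planktonscape run --config config.yaml` or the per-stage subcommands
(`simulate`, `summarize`, `diversity`, `tli`).

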