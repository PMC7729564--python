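# quiescreen

Analysis pipeline for high-throughput flow-cytometry screens of cellular
quiescence in fission yeast (*Schizosaccharomyces pombe*). When a deletion
library is starved of nitrogen, each mutant's wells are sampled at days 0,
1, 7, 14, 21 and 28 and run through a plate cytometer; `quiescreen` turns
those per-well event tables into strain-level quiescence phenotypes and
pathway-level statistics:

1. **Gating** — doublet exclusion on the FSC-H/FSC-A ratio, live/dead
   classification on an amine-reactive viability dye, and DNA-content
   quadrants on (DNA-A, DNA-W) separating G0 (1C mononuclear), G2 (2C
   mononuclear) and G1/M (2C binuclear) cells. Wells with fewer than 1000
   single cells fail QC.
2. **Mortality kinetics** — for each strain, the %dead trajectory is fitted
   with seven nonlinear models (Logistic 3P, Mechanistic Growth, Gompertz
   3P, Logistic 5P, Exponential 3P, Exponential 2P, Probit 4P). The optimal
   model must (a) have the highest standardized goodness of fit across the
   candidates and (b) predict a finite day of 99% mortality within the
   extrapolation horizon. From it, T₁/₄, T₁/₂ and T₉₉ (days to 25/50/99%
   mortality) are extrapolated, with residual-bootstrap 95% confidence
   intervals.
3. **Phenotype clustering** — five features per strain (T₁/₂, T₁/₄, G2% at
   day 0, G0% at days 1 and 7) are z-scored and clustered with Ward's
   method; the number of clusters is chosen by the Cubic Clustering
   Criterion (CCC), `CCC = ln[(1−E(R²))/(1−R²)]·√(np*/2)/(0.001+E(R²))^1.2`
   with the uniform-hypercube null E(R²). Welch t-tests compare mutants to
   the wild-type control.
4. **Enrichment** — for a protein complex with K members among the N
   analyzed strains, k of which fall in a cluster of size n: fold
   enrichment `(k/n)/(K/N)` plus hypergeometric point `P(X=k)` and tail
   `P(X≥k)` probabilities, with a Benjamini–Hochberg column.

A synthetic-cytometry module simulates the whole screen — log-normal event
mixtures with planted doublets, dead cells and cell-cycle populations, and
mortality trajectories drawn from any of the seven models — so every stage
is testable end to end with no instrument data.

## Worked example

Simulate a 28-strain screen (four strains from each of seven phenotype
archetypes, 5000 events/well, 2% mortality noise) and run every stage:

```sh
quiescreen all --outdir demo --seed 11
```

with a config overriding the defaults, or from Python:

```python
from quiescreen.pipeline import RunConfig, run_pipeline
cfg = RunConfig.from_dict({
    "seed": 11,
    "simulate": {"n_per_archetype": 4, "n_events": 5000, "noise_sd": 2.0},
})
result = run_pipeline(cfg, "demo")
```

`demo/report.txt` then reads:

```
quiescreen run report (config 40f7f0994ae0, seed 11)
wells gated: 168
wells failing QC (<1000 singlets): 0
strains fitted: 28
strains clustered: 28
clustering exclusions: none
chosen number of clusters (CCC): 11
max CCC: 17.210
enrichment rows: skipped
```

168 wells (28 strains × 6 days) passed the 1000-singlet QC cutoff, every
strain yielded a converged optimal model, and the CCC picked 11 clusters
(the archetypes are jittered per strain, so the dendrogram resolves
sub-archetype structure at this noise level). The per-strain fit table
(`demo/fits.csv`) holds the selected model and threshold times, e.g.

```
             strain_id   model_id       r2       t25       t50
       control_like_01      exp3p 0.975985 30.520382 37.198894
entry_defect_strong_00      exp2p 0.996727 24.730267 27.850658
```

— the control-like strain survives well past a month (T₁/₂ ≈ 37 days)
while the entry-defect strain crosses 50% mortality around day 28. Most
simulated strains select an exponential (2P/3P) model, mirroring the
screen's behavior. `enrichment rows: skipped` appears because no category
catalog was configured; supply one with
`enrichment: {catalog: complexes.csv, background: strains.txt}` to get the
fold/hypergeometric table.

Single-number statistics are available directly:

```python
>>> from quiescreen import fold_enrichment, hypergeom_point
>>> fold_enrichment(3, 15, 9, 684)      # 3 SAGA genes in a 15-gene cluster
15.2
>>> hypergeom_point(5, 108, 10, 684)    # 5 Ino80 genes in a 108-gene cluster
0.010013...
```

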