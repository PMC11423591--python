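# planktonet

Community organization and network stability analysis for cross-kingdom
plankton microbiomes.

Marine amplicon surveys routinely ask two linked questions about prokaryotic
and eukaryotic plankton communities sampled along an environmental gradient:
*what assembles them* — deterministic selection by the environment or
stochastic dispersal and drift — and *how stable* are the co-occurrence
networks they form.  `planktonet` implements the standard analysis chain for
both questions as a reusable, tested Python library with a CLI, exercisable
end-to-end on synthetic data with known ground truth:

* **Preprocessing** — occurrence/frequency feature filters, rarefaction,
  and partitioning into abundant (>1% relative abundance in ≥10% of
  samples, or summed abundance >20%), rare (summed <0.5%) and moderate
  sub-communities.
* **Diversity & niche breadth** — richness, Shannon H, Pielou J, Faith PD;
  Bray–Curtis, geographic and environmental distance matrices with
  permutation Mantel tests; Levins niche breadth B = 1/Σ P².
* **Assembly inference** — the Sloan neutral community model (occurrence
  frequency of a taxon with mean relative abundance p predicted as
  1 − I_d(Nmp, Nm(1−p)); fitted migration m, Nm, R²); SES MNTD, βMNTD and
  βNTI against taxa-shuffle nulls; Raup–Crick on Bray–Curtis; and the
  per-pair process classification (|βNTI| > 2 → homogeneous/variable
  selection; otherwise RC ± 0.95 → dispersal limitation / homogenizing
  dispersal / drift).
* **Co-occurrence networks** — Spearman correlations of log-transformed
  relative abundances with BH-FDR control, greedy modularity, Zi/Pi node
  roles, topology summaries and a power-law degree fit.
* **Stability** — robustness to random and module-hub removal with
  secondary extinctions, efficiency-based vulnerability, and the
  betweenness-targeted fragmentation series.
* **Synthetic data** — a generator producing coalescent trees, gradient
  metadata and count tables under neutral, selection-driven and mixed
  assembly at the scale of a 38-station, ~1,900-taxon survey, with full
  ground truth for every tunable process.

See `docs/methods.md` for the models, conventions and design choices.

## Worked example

Simulate the two-kingdom fixture and contrast their assembly:

```python
import planktonet as pk
from planktonet import preprocess as pp

neutral, selection = pk.simulate_cross_kingdom_fixture(seed=1)
for name, ds in [("mostly-neutral", neutral), ("selection", selection)]:
    table = pp.filter_features(ds.table)
    labels = pp.classify_abundance_groups(table)
    fit = pk.fit_ncm(table)
    print(f"{name:>14}: {table.shape[1]} taxa retained | "
          f"abundant {int((labels=='abundant').sum())}, "
          f"rare {int((labels=='rare').sum())} | "
          f"NCM R2={fit.r2:.3f}, Nm={fit.Nm:.0f}")
```

prints

```
mostly-neutral: 1313 taxa retained | abundant 53, rare 856 | NCM R2=0.893, Nm=1211
     selection: 1266 taxa retained | abundant 54, rare 721 | NCM R2=0.534, Nm=330
```

Both kingdoms keep a rare majority and a small abundant class, as amplicon
surveys do.  The mostly-neutral kingdom's occurrence frequencies sit close
to the Sloan prediction (R² = 0.893) with a large immigration parameter; the
gradient-selected kingdom departs from neutrality (R² = 0.534) — the same
qualitative contrast that distinguishes stochastically assembled from
environmentally filtered plankton communities.  Continuing with
`pk.beta_nti`, `pk.raup_crick_bray` and `pk.classify_assembly` yields the
process fractions; `pk.build_network`, `pk.node_metrics` and
`pk.stability_analysis` produce the network and stability summaries.

The same pipeline runs from the shell:

```bash
planktonet simulate --out data/ --seed 1 --mode selection
planktonet partition --table data/table.tsv --out labels.tsv
planktonet assembly --table data/table.tsv --tree data/tree.nwk --out asm/
planktonet network --table data/table.tsv --out net/
planktonet stability --network net/network.graphml --out stab/
planktonet run --config config.yaml --out report/   # full report bundle
```

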