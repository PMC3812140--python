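# lnccompartment

Multi-compartment analysis of long noncoding RNA (lncRNA) microarray profiles
in heart failure: heart tissue, whole blood and plasma, heart-failure (HF)
versus control.

The package is aimed at transcriptomics analysts working with pooled-design
two-color/one-array-per-condition lncRNA arrays who need the whole analysis
chain as tested, scriptable code:

* **Genomic-context classification** — each lncRNA is assigned one of six
  positional classes against a coding-gene catalog (sense-overlapping,
  intronic, antisense-overlapping, non-antisense-overlapping, bidirectional
  within a 1 kb TSS-to-TSS window, intergenic), collapsed to four classes for
  reporting.
* **Expression processing** — quantile normalization, the Present/Marginal
  "2 of 2" detection-flag filter, and pure fold-change differential
  expression for the replicate-free pooled design: a probe is *up* if
  FC = HF/control ≥ 2.0 and *down* if FC ≤ 0.5 (both inclusive).
* **Integrative statistics** — Spearman rank correlation ρ (exact permutation
  p for n ≤ 9, t-approximation otherwise), class × sample length–expression
  correlation grids, Fisher's exact 2×2 test with the cross-product odds
  ratio OR = ad/bc, cross-compartment fold-change concordance, the
  triple-compartment DE intersection, classical (Torgerson) MDS on the
  correlation distance d = 1 − ρ, and average-linkage bi-clustering.
* **qPCR validation** — relative quantification by 2^(−ΔΔCt) with
  housekeeping-gene normalization and the unpaired pooled-variance t-test.
* **Synthetic-data generator** — a Gaussian-copula simulator that *plants*
  every statistic above at configured values (exact per-compartment DE
  counts; per-sample, per-class length–expression ρ; cross-compartment
  fold-change coupling; lncRNA–mRNA direction-concordance odds ratios), so
  the entire pipeline is verifiable at desk scale. The packaged
  `paper_profile.yaml` encodes the published study conditions, and a packaged
  32-row fixture transcribes the published triple-compartment overlap table.

## Worked example

```python
import lnccompartment as lc
from lnccompartment import expression_core as ec, integrative_stats as ist

cfg = lc.SimulationConfig.paper_profile()
study = lc.generate_dataset(cfg, seed=42)

classes, fractions = lc.classify_all(study.lncs, study.genes)
print("class fractions:", {k: round(v, 3) for k, v in fractions.items()})

for comp in ec.COMPARTMENTS:
    de = ec.call_de(study.lnc_expr, study.lnc_expr.pair(comp))
    up, down = ec.de_counts(de)
    print(f"{comp}: {up} up, {down} down")

de_h = ec.call_de(study.lnc_expr, study.lnc_expr.pair("heart"))
de_p = ec.call_de(study.lnc_expr, study.lnc_expr.pair("plasma"))
corr, table, fisher = ist.fold_change_concordance(de_h, de_p)
print(f"heart-plasma fold coupling: rho={corr.rho:.3f} (n={corr.n}), "
      f"direction table OR={fisher.odds_ratio:.3g}, Fisher p={fisher.p_two_sided:.2g}")

lengths = study.truth.set_index("lnc_id")["length"]
grid = ist.length_expression_grid(study.lnc_expr, lengths, classes)
print("HF-heart Total rho:", round(grid.rho.loc["Total", "heart_HF"], 3),
      " HF-plasma Total rho:", round(grid.rho.loc["Total", "plasma_HF"], 3))
```

prints

```
class fractions: {'sense_overlap': 0.2, 'antisense_overlap': 0.2, 'bidirectional': 0.1, 'intergenic': 0.5}
heart: 518 up, 908 down
whole_blood: 1139 up, 1506 down
plasma: 1619 up, 1582 down
heart-plasma fold coupling: rho=-0.239 (n=19702), direction table OR=0.00486, Fisher p=2.4e-34
HF-heart Total rho: -0.169  HF-plasma Total rho: -0.048
```

Reading: the classifier recovers the planted four-class mixture; the
fold-change caller reports exactly the planted DE counts per compartment;
lncRNAs up in the failing heart tend to be down in plasma (ρ ≈ −0.24, OR ≪ 1
for the up/down direction table); and the usual negative length–expression
correlation (ρ ≈ −0.17) collapses specifically in HF plasma (ρ ≈ −0.05) —
the headline contrast the length–expression grid is built to expose.

The same run is available end to end from the shell:

```sh
lnccompartment run -o out/            # simulate → classify → DE → stats → qPCR
lnccompartment simulate -o sim/ --seed 42
lnccompartment classify --genes sim/genes.gff3 --lncs sim/lncs.gff3 -o classes.tsv
lnccompartment de --matrix sim/expr_lnc.tsv --no-normalize -o de/
lnccompartment qpcr --ct sim/qpcr.csv -o qpcr.tsv
```

`run` writes `classes.tsv`, per-compartment DE tables, the correlation grid,
the triple-compartment overlap table, concordance odds ratios, MDS
coordinates, linkage trees, `qpcr.tsv`, a deterministic `report.json` and a
checksummed `manifest.json`.

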