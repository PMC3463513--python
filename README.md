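# resevol

Residue-level structure–evolution analysis for protein-coding genes on
small fixed phylogenies.

Buried amino acid residues evolve more slowly than exposed ones: across
many proteins, the selective constraint on a residue — measured as the
nonsynonymous/synonymous rate ratio dN/dS (ω) — rises approximately
linearly with the residue's relative solvent accessibility (RSA).
`resevol` implements the full analysis used to dissect how two
whole-protein properties shape this relationship:

* **core size** — a protein's average residue RSA; "large-core" proteins
  (low average RSA) have proportionally more buried residues;
* **expression level** — proxied by the codon adaptation index (CAI) or
  any numeric abundance measure.

The pipeline annotates residues with RSA (computed from coordinates by
Shrake–Rupley sphere sampling, normalized per residue type to its 99th
percentile, and transferred from template structures through residue
alignment maps), ranks proteins into contrast groups, pools gapless codon
columns of residues with similar RSA into concatenated alignments, and
estimates a single dN/dS per RSA bin by maximum likelihood under the
Goldman–Yang codon model on the 4-taxon *Saccharomyces* tree, with
standard errors from a codon-column bootstrap. Error-weighted straight
lines

&nbsp;&nbsp;&nbsp;&nbsp; dN/dS = b + m · RSA

are fitted per protein group; slopes and intercepts are compared between
groups with t statistics (df = n₁ + n₂ − 4) or against null values
(df = n − 2, with b = 1 the no-effect null for fold-change curves). The
per-bin **fold change** between two groups, R(RSA) = y_A/y_B, separates
structure-dependent effects (slope ≠ 0) from uniform ones (intercept ≠ 1).

A fully specified synthetic-data generator produces studies with known
ground truth — per-residue RSA, site-specific ω linear in RSA,
expression-dependent codon bias and synonymous-clock scaling — so every
stage of the pipeline is testable against the parameters that generated
its input.

## Worked example

```python
from resevol.pipeline import run_pipeline
from resevol.studies import four_cell_study_config

cfg = four_cell_study_config("out/demo", seed=1)
report = run_pipeline(cfg)

for aid, par in [("core.dnds.foldchange", "slope"),
                 ("core.dnds.foldchange", "intercept"),
                 ("expression.dnds.foldchange", "intercept"),
                 ("expression.ds.foldchange", "intercept")]:
    row = report.comparison(aid, par)
    print(f"{aid:30s} {par:9s} {row.estimate: .4f}  p={row.p:.4f}")
```

Output (seed 1):

```
core.dnds.foldchange           slope      0.0203  p=0.0121
core.dnds.foldchange           intercept  1.3017  p=0.1447
expression.dnds.foldchange     intercept  2.7780  p=0.0019
expression.ds.foldchange       intercept  1.3375  p=0.0069
```

Read: the large-core/small-core dN/dS ratio *increases* with solvent
accessibility (slope 0.020 per %RSA, p ≈ 0.01) while being statistically
indistinguishable from 1 for buried residues — core size is a
structure-dependent constraint on exposed residues. The
low/high-expression ratio is uniformly large at every RSA (intercept ≈
2.8, p ≈ 0.002), and expression also deflates the synonymous rate
uniformly (dS fold change ≈ 1.34) — expression acts on the whole coding
sequence, independent of structure.

All tables (per-bin rates, line fits, comparisons, fold-change curves)
are written as TSV under the run directory, with a checksummed
`manifest.json`.

## Command line

```bash
resevol simulate --config sim.yaml --out study/   # synthetic study
resevol sasa --pdb 1abc.pdb --chain A --out sasa.tsv
resevol rsa --sasa-tsv sasa.tsv --out-dir rsa/
resevol run --config run.yaml --seed 1            # full pipeline
```

`records`, `group`, `bin`, `rates`, `cai`, `fit` and `compare` run the
individual pipeline stages from the previous stage's files; the chained
stages and `run` produce identical output.

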