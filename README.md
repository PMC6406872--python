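# tpaquant

Absolute quantification and statistical comparison of label-free
proteomes and secretomes, built around the **Total Protein Approach
(TPA)**. The package targets the kind of study that benchmarks a
hepatic cell line (e.g. HepaRG, HepG2) against primary human
hepatocytes (PHH): it turns raw protein intensities into copies per
cell, normalizes and compares independent datasets, converts
conditioned-medium intensities into absolute secretion rates with an
albumin immunodepletion correction, screens spectral counts for
batch-to-batch differences, and runs rank-based 2D annotation
enrichment. Every stage is validated end-to-end on synthetic data
with known ground truth.

## The quantities it computes

**Copies per cell.** A protein's share of the summed MS intensity is
its share of the cell's protein mass:

```
c_i = (I_i / Σ_j I_j) · P_cell · N_A / MW_i
```

with `P_cell` the measured protein content per cell (pg), `N_A` the
Avogadro constant and `MW_i` the average molecular mass from the
sequence. Copy numbers conserve mass exactly: `Σ c_i·MW_i/N_A = P_cell`.

**Cross-system comparison.** Cyclic LOESS normalization on pairwise
MA representations of log10 copies removes depth-dependent bias
between datasets; per protein a one-way ANOVA with Tukey HSD post-hoc
contrasts and step-down Holm correction classifies each cell line vs
the reference as absent–present, obvious (fold change > 20),
significant (Holm p < 0.05) or unchanged.

**Secretion rates.** Retained secretome proteins (identified in ≥1
injection replicate of every depletion replicate) share the depleted
sample's protein mass in proportion to intensity, normalized to
ng/day/10⁶ seeded cells; albumin, removed by immunodepletion, is
quantified from the depletion loss times the bound-fraction purity.

**Spectral-count stability.** Protein-specific spectral counts are
modeled as beta-binomial (overdispersed binomial); group differences
are tested by likelihood ratio (multi-group, and a paired conditional
variant), Holm-corrected, and called differential only above a 2-fold
change.

**2D enrichment.** Per annotation term, mean-rank scores in two
log-ratio dimensions (normalized to ±1 at the extremes) with a
Hotelling T² test on the 2D ranks and Benjamini–Hochberg FDR.

## Worked example

```python
import pandas as pd
import tpaquant as tq

cfg = tq.SimulationConfig(seed=7, n_proteins=1000)
sim = tq.simulate_proteome(cfg)        # ground-truth labeled intensities

copies = pd.DataFrame({
    col: tq.tpa_copy_numbers(sim.intensity[col], sim.mw,
                             sim.profiles[sim.sample_systems[col]])
    for col in sim.intensity.columns
})
table = tq.compare_systems(copies, sim.sample_systems, reference="PHH")
print(table["category"].value_counts().to_string())
```

```
category
unchanged           709
absent_in_HepG2     126
obvious              74
significant          59
absent_in_PHH         9
absent_in_HepaRG      8
```

Of 985 proteins detected in at least two systems, 126 are never
detected in the simulated HepG2-like line, 74 differ by more than
20-fold from the reference, and 59 more are statistically significant
after family-wise correction — the planted mixture (5 % large, 5 %
moderate effects, 12 % HepG2 absences) recovered from noisy
replicates. The strongest shift:

```
largest HepG2-vs-PHH shift: P00277, log10 FC = +2.99,
Holm-adjusted Tukey p = 3.59e-12
```

The secretome stage on the same configuration:

```python
sec = tq.simulate_secretome(cfg)
rates = tq.analyze_secretome(sec.intensity, sec.depletion_rep,
                             sec.annotations, sec.experiment)
print(len(rates), tq.albumin_rate(sec.experiment))
```

retains 285 of 300 proteins (the rest fail the replicate-grid rule),
ranks them by secretion rate — the top protein secretes
~36,000 ng/day/10⁶ cells via the classical pathway — and recovers the
planted albumin rate (20,000 ng/day/10⁶ cells) exactly from the
depletion loss and band purity.

## Command line

The same stages are available as a CLI for file-based work:

```
tpaquant quantify    --protein-groups pg.txt --fasta seqs.fasta --profile profile.toml --out copies.tsv
tpaquant compare     --tables HepaRG.tsv PHH.tsv HepG2.tsv --reference PHH --out comparison.tsv
tpaquant secretome   --protein-groups sec.txt --annotations ann.tsv --meta meta.toml --out secretome.tsv
tpaquant batch-stats --counts counts.tsv --groups groups.tsv --out stability.tsv
tpaquant enrich      --values ratios.tsv --terms terms.tsv --out enrichment.tsv
tpaquant simulate    proteome --seed 7 --out-dir sim/
```

Inputs follow the MaxQuant proteinGroups TSV dialect (`Majority
protein IDs`, `Intensity <sample>`, `MS/MS count <sample>`,
`Reverse`/`Potential contaminant` flags; zero intensity = missing),
UniProt-style FASTA, and TOML metadata. Outputs are TSV with a `#`
provenance header and are byte-identical across reruns of the same
inputs and seed.

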