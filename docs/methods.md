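# Methods

`tpaquant` quantifies label-free proteomics data in absolute terms and
compares hepatic cell systems (HepaRG and HepG2 lines against primary
human hepatocytes, PHH) at the proteome and secretome level. This note
documents the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not show.

## Total Protein Approach (quant_core)

A protein's share of the summed raw MS intensity estimates its share
of the total protein mass. With a measured protein content per cell
`P_cell` (pg, from a bulk assay on a counted cell suspension) the copy
number of protein *i* is

    c_i = (I_i / Σ_j I_j) · P_cell·10⁻¹² · N_A / MW_i

with `N_A` the Avogadro constant and `MW_i` the average molecular mass
(g/mol) computed from the sequence as the sum of average residue
masses plus one water (18.01528 g/mol). Residue masses are derived
from IUPAC average atomic weights (C 12.0107, H 1.00794, N 14.0067,
O 15.9994, S 32.065, Se 78.96), so that e.g. a single glycine gives
75.0666 g/mol. Average (not monoisotopic) masses are the right choice
because the approach scales bulk mass. Selenocysteine and pyrrolysine
are recognized; the ambiguity codes B/Z/X are rejected unless
permissive mode substitutes a generic 110 g/mol (logged).

Assumptions and consequences:

* **Equal response per unit mass.** Raw intensity is taken as
  proportional to protein mass. Protein-to-protein ionization
  differences are not modeled; they cancel only in comparisons of the
  same protein across samples.
* **Mass closure.** By construction Σ c_i·MW_i/N_A = P_cell exactly
  over the quantified proteins. When low-abundance proteins go
  undetected, their (small) mass share is redistributed over the
  detected ones — an intrinsic property of the method, visible as a
  slight upward bias at shallow depth.
* **Replicate handling.** Replicates of one system are collapsed by
  the arithmetic mean of non-missing raw intensities before scaling.
  Under equal per-run depth this is equivalent to per-replicate TPA
  followed by averaging (the operation is scale-invariant); with
  unequal depth the mean-first order weights deeper runs more, which
  matches how summed intensities behave.
* **Missingness.** An intensity of 0 in input tables means *not
  quantified* and is treated as missing, never as a measured zero.
* Protein groups are quantified with the leading accession's sequence
  mass. Cell volume, where radii are available, assumes spherical
  cells: V = (4/3)πr³.

## Cross-system comparison (compare)

Copy-number tables from independently acquired datasets differ in
effective proteome depth, which appears as an abundance-dependent bias
between their log scales. `loess_normalize` removes it by cyclic
LOESS: for every column pair, the log10 ratio M is smoothed against
the mean log10 abundance A (locally weighted regression, default span
0.75, via statsmodels `lowess` with 1 %-of-range interpolation), and
half the fitted trend is transferred between the columns; cycles
repeat until the largest |median pairwise log ratio| falls below 1e-3
(at most 10 cycles). Missing values pass through. Fewer than 30
commonly detected proteins abort the fit as unreliable.

Statistics on log10 copies (log transformation stabilizes the
multiplicative noise of copy numbers):

* one-way fixed-effects ANOVA per protein across the systems with ≥2
  detected replicates;
* Tukey-Kramer HSD for the three pairwise contrasts (studentized
  range distribution, exact for unequal group sizes);
* step-down Holm adjustment across proteins — one family for the
  omnibus p, and one per system-vs-reference Tukey family. The
  pairwise Holm-adjusted Tukey p drives the per-comparison category,
  so a protein shifted only in one cell line is not flagged against
  the other.

Categories per comparison, in precedence order: **absent–present**
(detected in one side only), **obvious** (fold change above 20,
strict), **significant** (Holm-adjusted pairwise p < 0.05),
**unchanged**; proteins detected in fewer than two systems are
**not comparable**. The presence rule (detected = non-missing in ≥1
replicate, retained if detected in ≥2 of 3 systems) is applied before
any testing.

For throughput the ANOVA/Tukey machinery is evaluated in vectorized
form over all proteins; the studentized-range survival function is
computed by fixed double Gauss-Legendre quadrature of the classical
integral (64 abundance × 128 range nodes), which matches scipy's
adaptive implementation to ~1e-9 at a small fraction of the cost. The
scalar scipy-based path remains as the per-protein reference and the
two are cross-checked in the test suite. Degenerate inputs are pinned:
all values identical → p = 1; zero within-group variance with distinct
means → p = 0.

## Secretome quantification (secretome)

Conditioned-medium proteomics over a depletion × injection replicate
grid (default 3 × 3). A protein is retained iff it is identified in at
least one injection replicate of *every* depletion replicate — a
reproducibility rule that suppresses one-off identifications.
Secretion classes are assigned from precomputed annotation flags with
precedence signal peptide (classical) > predicted non-classical >
annotated extracellular/exosome localization > not secreted; predictor
internals are out of scope, their outputs are inputs here.

Rates apply the TPA to the medium: each retained protein's share of
the summed mean intensity times the protein amount of the
albumin-depleted fraction, normalized per day of secretion (default 2)
and per 10⁶ seeded cells:

    rate_i = (I_i/ΣI) · protein_after(ng) / (days · cells/10⁶)   [ng/day/10⁶ cells]

so the retained rates close exactly on the depleted-fraction mass.
The denominator uses the depleted total alone (the immunodepleted
sample is what was measured); adding back the albumin estimate is a
conceivable alternative we did not adopt, since albumin is quantified
separately. Albumin itself is estimated from the depletion loss,
corrected by the albumin purity of the bound fraction (gel
densitometry, an input scalar):

    rate_alb = (protein_before − protein_after)(ng) · purity / (days · cells/10⁶)

A leakage report summarizes the rates of cytosolic markers (default
LDHA/LDHB, GOT1, GPT) against a strict threshold (default
3 ng/day/10⁶ cells); markers at or above the threshold fail the
low-leakage verdict, absent markers pass.

## Spectral-count statistics (countstats)

Between-batch stability is tested on protein-specific spectral counts.
Proteins need ≥4 specific spectra in at least one sample; library
sizes are the column sums of the retained counts. Counts are modeled
as beta-binomial, `k_j ~ BB(t_j, π, θ)` with `α = π(1−θ)/θ`,
`β = (1−π)(1−θ)/θ`, so θ is the intra-class correlation of the
replicate-level sampling probability and θ→0 recovers the binomial
(verified numerically in the suite).

* **Multi-group test:** likelihood ratio of group-specific π_g (shared
  θ) against a common (π, θ), maximized by bounded L-BFGS-B with three
  deterministic starts from moment estimates; p from χ² with G−1 df of
  max(Λ, 0).
* **Paired test:** conditional on each pair sum s_r, k_Ar ~
  BB(s_r, π_r, θ) with logit(π_r) = logit(t_Ar/(t_Ar+t_Br)) + δ. The
  alternative maximizes (δ, θ); the null fixes δ = 0 and reuses the
  fitted θ. Re-estimating θ freely under the null would let
  overdispersion absorb a consistent paired shift (an all-or-nothing
  two-point fit as θ→1), destroying power against exactly the
  alternatives the paired design targets. With the plug-in θ the test
  is calibrated under the paired null — a shared per-pair latent
  proportion, which is what pairing means and what conditioning on s_r
  removes — and remains powerful. For unpaired data the multi-group
  test is the right tool; applying the paired test to artificially
  paired independent samples is anticonservative.

A protein is called differential when the Holm-adjusted p is below
0.05 **and** the largest pairwise fold change of group mean count
proportions exceeds 2. Zero group means are floored at half the
smallest positive group mean in the table (logged) so fold changes
stay finite; the likelihood itself uses no pseudocounts.

**Known limitation — small-sample inflation.** With 3 groups × 4
replicates and strong overdispersion, the χ²_{G−1} reference of the
multi-group profile LRT is anticonservative: under a correctly
specified beta-binomial null (π = 0.01, θ = 0.05, t = 2000) the
empirical type-I error is ≈ 0.10 at α = 0.05 (≈ 0.03 at α = 0.01; mean
Λ ≈ 2.5 against the asymptotic 2). This is a property of estimating
four parameters from twelve highly skewed counts, not an optimizer
artifact — a thorough multi-start simplex search finds identical
likelihood maxima. Fixing θ at the null estimate restores calibration
but halves power; per-group θ changes the df and the model. In the
pipeline the Holm correction absorbs the inflation: false *calls* are
essentially absent. The paired test does not share the problem
(type-I ≈ 0.04 under its null).

## 2D annotation enrichment (enrich2d)

Each dimension (e.g. the two cell-line-vs-reference log ratios) is
reduced to ranks, making results invariant under monotone transforms.
The per-dimension term score

    s = 2 (R̄_members − (n+1)/2) / (n − n_t)

is normalized so a term occupying the n_t largest values scores
exactly +1 (smallest: −1); a set and its complement score with equal
magnitude and opposite sign. Joint member-vs-rest shift is tested with
a two-sample Hotelling T² on the 2D rank vectors against a χ²₂ tail;
Wilks' Λ would be the other classical MANOVA statistic, but with one
two-group contrast in two dimensions the two coincide up to
monotone transformation, and T² is the simpler to compute. Per-term p
values are Benjamini–Hochberg adjusted; defaults: minimum term size
10, FDR threshold 0.02. A singular pooled rank covariance yields p = 1
with a warning.

## Synthetic data (synthetic)

The generators are pure functions of a frozen configuration carrying a
mandatory seed. They emulate the statistical structure the pipeline
assumes, with ground truth returned alongside:

* **Proteome.** Reference-system copies lognormal, log10 ~ N(4.5,
  1.2) (≥5 orders of magnitude across 2000 proteins); molecular masses
  log10 ~ N(4.6, 0.25) g/mol (≈40 kDa median, clipped to 5–500 kDa);
  per-system protein content per cell derived from the planted copies
  by mass closure so the TPA round-trip is exact by construction.
  Replicate structure mirrors the study design: HepaRG 5, PHH 12
  (seven donors, five in duplicate), HepG2 3. Planted effects vs PHH:
  90 % unchanged, 5 % moderate (2–10×), 5 % large (>20×), random sign;
  planted absences 12 % in HepG2 and 0.8 % in PHH (≈ the 484/3995 and
  31/3995 absence fractions of the comparison this emulates).
  Intensities are copies × mass × lognormal noise (ln-sd 0.2 ≈ 20 %
  CV); detection is Bernoulli with logistic probability in log10
  intensity (midpoint 10⁷, slope 2 — left-censoring of the low tail,
  the reason depth-aware normalization exists).
* **Counts.** 3 batches × 4 replicates, library ≈ 20 000 spectra per
  run (10 % lognormal jitter), protein weights log10 ~ N(0, 0.6)
  (spectral counts span a compressed ~3-order range), counts negative
  binomial with dispersion 0.05 (Poisson in the 0-dispersion limit);
  5 % of proteins change 4-fold in the last batch.
* **Secretome.** True rates log10 ~ N(1.5, 1.2) ng/day/10⁶ cells over
  300 proteins (sub-ng to tens of µg); the depleted-fraction protein
  amount follows from the rates by mass closure and the pre-depletion
  amount hides a planted albumin rate (default 2×10⁴ ng/day/10⁶,
  purity 0.9) behind the depletion loss. Annotation flags: 70 %
  signal peptide, 10 % non-classical, 15 % extracellular/exosome.

What passing tests show — and don't. Recovery, calibration and
round-trip results demonstrate that the implementation computes its
models correctly and that the statistics behave as designed under data
with the assumed structure. Real data violate parts of that structure
(ionization efficiency differences, correlated missingness, shared
peptides, batch effects beyond a scalar depth), so synthetic recovery
rates are upper bounds, not field performance claims. Category
recovery is evaluated without detection censoring: a protein planted
300-fold down that falls below the detection limit everywhere is
*correctly* reported absent rather than as a fold change, so censored
runs conflate the two labels by design.

## Numerical conventions

* Ties in ranks: average ranks (scipy `rankdata`), stable sorts.
* Optimizer bounds π, θ ∈ (1e-8, 1−1e-8); θ clipped inside the
  likelihood so finite-difference gradients cannot step outside.
* LRT statistics clipped at 0; p-values clipped to [0, 1].
* All randomness flows from explicit seeds through
  `numpy.random.default_rng`; outputs are byte-identical across runs
  (provenance headers carry no timestamps).
* Default thresholds: α = 0.05, fold change 2 (counts) and 20
  ("obvious"), minimum spectra 4, LOESS span 0.75.

## Problem sizes used in validation

The shipped validation runs use 500–5000 proteins per simulation,
2000-protein Monte-Carlo calibrations for the count tests, 1000-term
null calibrations for the enrichment test, and a 5000-protein
end-to-end determinism run — sizes chosen so the full suite completes
in a few minutes on one core while keeping Monte-Carlo error well
below the decision margins.
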