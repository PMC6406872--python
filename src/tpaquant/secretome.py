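"""Secretome filtering, classification and absolute secretion rates.

Conditioned-medium proteomics with albumin immunodepletion: proteins
are retained when identified reproducibly across the depletion ×
injection replicate grid, classified as secreted from precomputed
signal-peptide / non-classical-secretion / localization annotations,
and quantified as absolute secretion rates by distributing the total
protein mass of the depleted fraction over proteins in proportion to
their summed MS intensity (the Total Protein Approach applied to the
medium), normalized to seeded cells and days of secretion.

Albumin itself is removed by the depletion, so its rate is estimated
from the protein mass lost during depletion, corrected by the purity
of the albumin band in the bound fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_CLASSICAL = "classical"
CLASS_NONCLASSICAL = "nonclassical"
CLASS_ANNOTATED = "annotated_extracellular_or_exosome"
CLASS_NOT_SECRETED = "not_secreted"

#: Default cell-leakage markers (cytosolic enzymes released on lysis).
DEFAULT_LEAKAGE_MARKERS = ("LDHA", "LDHB", "GOT1", "GPT")


@dataclass
class SecretomeExperiment:
    """Design and bulk measurements of one secretome experiment.

    protein amounts are in µg; ``albumin_purity`` is the mass fraction
    of albumin in the depletion-bound fraction (gel densitometry).
    """

    seeded_cells: float
    secretion_days: float = 2.0
    protein_before_ug: float | None = None
    protein_after_ug: float | None = None
    albumin_purity: float | None = None

    def __post_init__(self) -> None:
        if self.seeded_cells <= 0:
            raise ValueError("seeded_cells must be positive")
        if self.secretion_days <= 0:
            raise ValueError("secretion_days must be positive")
        if (self.protein_before_ug is not None and self.protein_after_ug is not None
                and self.protein_after_ug > self.protein_before_ug):
            raise ValueError("protein amount after depletion exceeds amount before")
        if self.albumin_purity is not None and not (0 < self.albumin_purity <= 1):
            raise ValueError("albumin_purity must be in (0, 1]")

    @property
    def cell_days(self) -> float:
        """Denominator of all rates: days × millions of seeded cells."""
        return self.secretion_days * self.seeded_cells / 1e6


def retention_filter(
    identified: pd.DataFrame,
    depletion_rep: pd.Series,
) -> pd.Series:
    """Replicate-grid retention rule for secretome proteins.

    A protein is retained iff, for *every* depletion replicate, it was
    identified in at least one of that replicate's injection runs.
    ``identified`` is a boolean proteins × samples frame (missing cells
    count as not identified); ``depletion_rep`` maps sample name to its
    depletion replicate label.
    """
    identified = identified.fillna(False).astype(bool)
    per_depletion = identified.T.groupby(depletion_rep).any().T
    return per_depletion.all(axis=1)


def classify_secreted(annotations: pd.DataFrame, proteins=None) -> pd.Series:
    """Assign each protein a secretion class from annotation flags.

    ``annotations`` must carry boolean columns ``signal_peptide``
    (classical secretory pathway), ``nonclassical`` (predicted
    alternative secretion) and ``extracellular_or_exosome`` (annotated
    extracellular-space or exosome localization). Precedence:
    classical > nonclassical > annotated localization > not secreted.
    Proteins without an annotation row default to not secreted, with a
    warning.
    """
    index = annotations.index if proteins is None else pd.Index(proteins)
    missing = index.difference(annotations.index)
    if len(missing):
        logger.warning("no annotation for %d protein(s) (e.g. %s); "
                       "classified as not secreted", len(missing), missing[0])
    ann = annotations.reindex(index).fillna(False)
    out = pd.Series(CLASS_NOT_SECRETED, index=index, dtype=object)
    out[ann["extracellular_or_exosome"].astype(bool)] = CLASS_ANNOTATED
    out[ann["nonclassical"].astype(bool)] = CLASS_NONCLASSICAL
    out[ann["signal_peptide"].astype(bool)] = CLASS_CLASSICAL
    return out


def secretion_rates(
    mean_intensity: pd.Series,
    exp: SecretomeExperiment,
) -> pd.Series:
    """Absolute secretion rates (ng/day/10⁶ cells) for retained proteins.

    Each protein's share of the summed mean intensity times the total
    protein of the albumin-depleted fraction gives its secreted mass;
    dividing by days of secretion and millions of seeded cells gives
    the rate. Mass closure holds: summing rate × days × cells/10⁶ over
    proteins returns the depleted-fraction protein amount exactly.
    """
    if exp.protein_after_ug is None:
        raise ValueError("protein_after_ug (depleted-fraction total) is required")
    total = mean_intensity.sum(skipna=True)
    if not total > 0:
        raise ValueError("summed intensity is zero")
    share = mean_intensity / total
    total_ng = exp.protein_after_ug * 1e3
    rates = share * total_ng / exp.cell_days
    rates.name = "secretion_rate"
    return rates


def albumin_rate(exp: SecretomeExperiment) -> float:
    """Albumin secretion rate (ng/day/10⁶ cells) from depletion loss.

    The protein mass removed by immunodepletion, multiplied by the
    albumin purity of the bound fraction, estimates secreted albumin
    mass; normalized like all other rates.
    """
    if exp.protein_before_ug is None or exp.protein_after_ug is None:
        raise ValueError("protein amounts before and after depletion are required")
    if exp.albumin_purity is None or not (0 < exp.albumin_purity <= 1):
        raise ValueError("albumin_purity must be in (0, 1]")
    loss_ng = (exp.protein_before_ug - exp.protein_after_ug) * 1e3
    return loss_ng * exp.albumin_purity / exp.cell_days


def leakage_report(
    rates: pd.Series,
    markers=DEFAULT_LEAKAGE_MARKERS,
    threshold: float = 3.0,
) -> tuple[pd.DataFrame, bool]:
    """Rates of cytosolic leakage markers and a low-leakage verdict.

    The verdict passes iff every detected marker's rate is strictly
    below ``threshold`` (ng/day/10⁶ cells); markers absent from the
    secretome count as passing.
    """
    rows = []
    for m in markers:
        rate = float(rates[m]) if m in rates.index and np.isfinite(rates.get(m, np.nan)) else np.nan
        detected = np.isfinite(rate)
        rows.append({"marker": m, "rate": rate, "detected": detected,
                     "below_threshold": (rate < threshold) if detected else True})
    table = pd.DataFrame(rows).set_index("marker")
    verdict = bool(table["below_threshold"].all())
    return table, verdict


def analyze_secretome(
    intensity: pd.DataFrame,
    depletion_rep: pd.Series,
    annotations: pd.DataFrame,
    exp: SecretomeExperiment,
) -> pd.DataFrame:
    """End-to-end secretome analysis.

    Applies the retention filter to the replicate grid, averages
    non-missing intensities of retained proteins, computes secretion
    rates and classes. Returns a per-protein table with columns
    ``secretion_rate`` and ``secreted_class`` sorted by rate.
    """
    retained = retention_filter(intensity.notna(), depletion_rep)
    kept = intensity.loc[retained[retained].index]
    if kept.empty:
        return pd.DataFrame(columns=["secretion_rate", "secreted_class"])
    mean_i = kept.mean(axis=1, skipna=True)
    rates = secretion_rates(mean_i, exp)
    classes = classify_secreted(annotations, proteins=rates.index)
    out = pd.DataFrame({"secretion_rate": rates, "secreted_class": classes})
    return out.sort_values("secretion_rate", ascending=False)
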