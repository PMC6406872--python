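"""Absolute protein quantification via the Total Protein Approach (TPA).

The TPA converts each protein's share of the summed MS intensity into a
mass fraction of the cell's total protein content, then into copies per
cell using the protein's molecular mass::

    c_i = (I_i / sum_j I_j) * P_cell * N_A / MW_i

where ``P_cell`` is the measured protein mass per cell (grams), ``N_A``
the Avogadro constant and ``MW_i`` the average molecular mass in g/mol.
By construction the copy numbers conserve mass: summing ``c_i * MW_i /
N_A`` over all quantified proteins returns ``P_cell`` exactly.

Molecular masses are *average* (not monoisotopic) masses — TPA scales
bulk protein mass, so the bulk isotope distribution is the right one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

logger = logging.getLogger(__name__)

#: IUPAC average atomic masses (g/mol).
_ATOM = {"C": 12.0107, "H": 1.00794, "N": 14.0067, "O": 15.9994,
         "S": 32.065, "Se": 78.96}

#: Elemental composition of amino-acid *residues* (free amino acid minus water).
_RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "U": {"C": 3, "H": 5, "N": 1, "O": 1, "Se": 1},   # selenocysteine
    "O": {"C": 12, "H": 19, "N": 3, "O": 2},           # pyrrolysine
}

RESIDUE_MASS: dict[str, float] = {
    aa: sum(_ATOM[el] * n for el, n in formula.items())
    for aa, formula in _RESIDUE_FORMULA.items()
}

#: Mass of one water molecule, added once per chain (terminal H and OH).
WATER_MASS = 2 * _ATOM["H"] + _ATOM["O"]  # 18.01528

#: Mass substituted for ambiguous residues (B/Z/X) in permissive mode.
AMBIGUOUS_RESIDUE_MASS = 110.0


def compute_molecular_weight(sequence: str, *, permissive: bool = False) -> float:
    """Average molecular mass of a protein sequence in g/mol.

    Sum of average residue masses plus one water. The 20 standard amino
    acids plus selenocysteine (U) and pyrrolysine (O) are recognized.
    Ambiguity codes (B, Z, X) raise ``ValueError`` unless ``permissive``
    is set, in which case each contributes a generic 110.0 g/mol and a
    warning is logged.
    """
    if not sequence:
        raise ValueError("empty protein sequence")
    seq = sequence.strip().upper()
    mass = WATER_MASS
    n_ambiguous = 0
    for aa in seq:
        try:
            mass += RESIDUE_MASS[aa]
        except KeyError:
            if permissive and aa in "BZX":
                mass += AMBIGUOUS_RESIDUE_MASS
                n_ambiguous += 1
            else:
                raise ValueError(f"unrecognized residue code {aa!r}") from None
    if n_ambiguous:
        logger.warning(
            "substituted %.1f g/mol for %d ambiguous residue(s)",
            AMBIGUOUS_RESIDUE_MASS, n_ambiguous,
        )
    return mass


def cell_volume(radius: float) -> float:
    """Volume of a spherical cell (µm³) from its radius (µm)."""
    if radius <= 0:
        raise ValueError("cell radius must be positive")
    return 4.0 / 3.0 * math.pi * radius**3


def protein_per_cell(total_protein_ug: float, cell_count: float) -> float:
    """Protein content per cell in pg/cell from a bulk assay.

    ``total_protein_ug`` is the total protein measured (µg, e.g. by BCA)
    in a lysate of ``cell_count`` counted cells.
    """
    if cell_count <= 0:
        raise ValueError("cell count must be positive")
    if total_protein_ug < 0:
        raise ValueError("total protein must be non-negative")
    return total_protein_ug * 1e6 / cell_count


@dataclass
class ProteinRecord:
    """One protein group: the unit of quantification.

    ``mw`` is derived from ``sequence`` when not given explicitly. For
    shared-peptide groups the leading (first-listed) accession's
    sequence is used.
    """

    accession: str
    sequence: str | None = None
    mw: float | None = None
    is_contaminant: bool = False
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.mw is None and self.sequence:
            self.mw = compute_molecular_weight(self.sequence)
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"{self.accession}: molecular weight must be positive")


@dataclass
class CellSystemProfile:
    """Physical parameters of one cell system.

    protein_per_cell : pg/cell, from a bulk protein assay on a counted
        cell suspension.
    cell_radius : µm, average radius of cells in suspension; the volume
        assumes a spherical shape.
    seeded_cells : cells per well, used for secretome normalization.
    """

    system_name: str
    protein_per_cell: float
    cell_radius: float | None = None
    seeded_cells: float | None = None

    def __post_init__(self) -> None:
        if self.protein_per_cell <= 0:
            raise ValueError("protein_per_cell must be positive (pg/cell)")
        if self.cell_radius is not None and self.cell_radius <= 0:
            raise ValueError("cell_radius must be positive (µm)")

    @property
    def cell_volume(self) -> float | None:
        """Spherical cell volume in µm³, or None when no radius is set."""
        if self.cell_radius is None:
            return None
        return cell_volume(self.cell_radius)


@dataclass
class QuantMatrix:
    """Protein-level quantification: proteins × samples raw intensities.

    ``intensity`` uses NaN for *missing* (not identified/quantified) —
    a raw 0 in MaxQuant-style input means missing, never a measured
    zero. ``samples`` carries per-sample metadata (columns such as
    ``system``, ``batch``, ``depletion_rep``, ``injection_rep``)
    indexed by sample name.
    """

    intensity: pd.DataFrame
    samples: pd.DataFrame
    proteins: pd.DataFrame  # indexed by accession; columns incl. "mw"
    msms_count: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.intensity.index.has_duplicates:
            raise ValueError("duplicate protein accessions")
        if self.intensity.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        if (self.intensity.to_numpy() < 0).any():
            raise ValueError("negative intensities")
        if not self.samples.index.equals(self.intensity.columns):
            raise ValueError("sample metadata does not match intensity columns")
        if self.msms_count is not None:
            if (self.msms_count.to_numpy() < 0).any():
                raise ValueError("negative spectral counts")

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (non-missing intensity)."""
        return self.intensity.notna()

    def system_columns(self, system: str) -> list[str]:
        return list(self.samples.index[self.samples["system"] == system])


@dataclass
class CopyNumberTable:
    """Copies-per-cell estimates, proteins × systems."""

    copies: pd.DataFrame
    mw: pd.Series
    profiles: dict[str, CellSystemProfile] = field(default_factory=dict)
    normalized: bool = False
    loess_span: float | None = None

    def mass_per_cell(self, system: str) -> float:
        """Total protein mass per cell (pg) implied by the copy numbers."""
        c = self.copies[system].dropna()
        return float((c * self.mw.loc[c.index]).sum() / Avogadro * 1e12)


def tpa_copy_numbers(
    intensity: pd.DataFrame | pd.Series,
    mw: pd.Series,
    profile: CellSystemProfile,
) -> pd.Series:
    """Convert raw intensities of one cell system into copies per cell.

    Replicate columns are first collapsed to the arithmetic mean of
    non-missing raw intensities per protein; proteins missing in every
    replicate stay missing. The mean intensities are then scaled so
    that the summed protein mass equals ``profile.protein_per_cell``.

    Parameters
    ----------
    intensity : DataFrame (proteins × replicates) or Series
        Raw intensities with NaN for missing.
    mw : Series
        Average molecular mass (g/mol) per protein, aligned on index.
    profile : CellSystemProfile
        Supplies the total protein content per cell (pg).

    Returns
    -------
    Series of copies per cell (NaN where the protein was not detected).
    """
    if isinstance(intensity, pd.DataFrame):
        mean_i = intensity.mean(axis=1, skipna=True)
    else:
        mean_i = intensity.astype(float)
    if mean_i.isna().all():
        raise ValueError(f"{profile.system_name}: no protein detected in any replicate")
    total = mean_i.sum(skipna=True)
    if total <= 0:
        raise ValueError(f"{profile.system_name}: summed intensity is zero")
    missing_mw = mean_i.notna() & ~mean_i.index.isin(mw.index)
    if missing_mw.any():
        raise ValueError(
            f"no molecular weight for quantified protein(s): "
            f"{list(mean_i.index[missing_mw])[:5]}"
        )
    p_cell_g = profile.protein_per_cell * 1e-12
    share = mean_i / total
    copies = share * p_cell_g * Avogadro / mw.reindex(mean_i.index)
    copies.name = profile.system_name
    return copies


def copy_number_table(
    quant: QuantMatrix,
    profiles: dict[str, CellSystemProfile],
) -> CopyNumberTable:
    """TPA copy numbers for every system in ``profiles``, one column each."""
    cols = {}
    for name, prof in profiles.items():
        sample_cols = quant.system_columns(name)
        if not sample_cols:
            raise ValueError(f"no samples for system {name!r}")
        cols[name] = tpa_copy_numbers(quant.intensity[sample_cols],
                                      quant.proteins["mw"], prof)
    copies = pd.DataFrame(cols)
    return CopyNumberTable(copies=copies, mw=quant.proteins["mw"],
                           profiles=dict(profiles))
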