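"""Readers and writers for the TSV/FASTA/TOML dialects the pipeline uses.

Input quantification tables follow the MaxQuant proteinGroups dialect:
one row per protein group, a ``Majority protein IDs`` column
(semicolon-separated accessions, leading accession first), per-sample
``Intensity <sample>`` and ``MS/MS count <sample>`` columns, and
``Reverse`` / ``Potential contaminant`` flag columns where ``+`` marks
decoy and contaminant rows. A raw intensity of 0 means *not
quantified* and is read as missing, never as a measured zero.

All output tables are TSV with a ``#``-prefixed provenance header
(package version, parameters, input digests) that the readers ignore.
"""

from __future__ import annotations

import hashlib
import logging
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .quant_core import CellSystemProfile, ProteinRecord, QuantMatrix, compute_molecular_weight
from .secretome import SecretomeExperiment

logger = logging.getLogger(__name__)

MAJORITY_IDS = "Majority protein IDs"
REVERSE = "Reverse"
CONTAMINANT = "Potential contaminant"


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences into an accession -> sequence map.

    UniProt-style ``>db|ACCESSION|NAME`` headers yield the second pipe
    field as accession; plain headers use the first whitespace token.
    Duplicate accessions raise.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        if "|" in header:
            parts = header.split("|")
            accession = parts[1] if len(parts) >= 2 and parts[1] else parts[0]
        else:
            accession = header
        if accession in sequences:
            raise ValueError(f"duplicate accession in FASTA: {accession!r}")
        sequences[accession] = str(record.seq).upper().replace(" ", "")
    return sequences


def read_protein_groups(
    path,
    intensity_prefix: str = "Intensity ",
    count_prefix: str = "MS/MS count ",
    remove_flagged: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame | None, pd.DataFrame]:
    """Read a proteinGroups-dialect TSV.

    Returns ``(intensity, msms_count, protein_meta)``: intensity and
    count frames indexed by leading accession with sample names as
    columns (intensity 0 -> NaN), and per-protein metadata including
    the full ID string and flag booleans. Reverse/contaminant rows are
    dropped by default (count logged).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if MAJORITY_IDS not in df.columns:
        raise ValueError(f"missing mandatory column {MAJORITY_IDS!r}")
    intensity_cols = [c for c in df.columns if c.startswith(intensity_prefix)]
    if not intensity_cols:
        raise ValueError(f"no columns with intensity prefix {intensity_prefix!r}")
    count_cols = [c for c in df.columns if c.startswith(count_prefix)]

    is_decoy = df.get(REVERSE, pd.Series("", index=df.index)).fillna("") == "+"
    is_contaminant = df.get(CONTAMINANT, pd.Series("", index=df.index)).fillna("") == "+"
    if remove_flagged:
        flagged = is_decoy | is_contaminant
        if flagged.any():
            logger.info("removed %d flagged (reverse/contaminant) of %d rows",
                        int(flagged.sum()), len(df))
        df = df[~flagged]
        is_decoy = is_decoy[~flagged]
        is_contaminant = is_contaminant[~flagged]

    leading = df[MAJORITY_IDS].str.split(";").str[0]
    if leading.duplicated().any():
        raise ValueError("duplicate leading accessions in protein groups")
    index = pd.Index(leading, name="accession")

    intensity = (df[intensity_cols].apply(pd.to_numeric)
                 .set_axis([c[len(intensity_prefix):] for c in intensity_cols], axis=1)
                 .set_axis(index))
    intensity = intensity.where(intensity > 0)  # 0 = missing by convention
    msms = None
    if count_cols:
        msms = (df[count_cols].apply(pd.to_numeric)
                .set_axis([c[len(count_prefix):] for c in count_cols], axis=1)
                .set_axis(index).fillna(0).astype(int))
    meta = pd.DataFrame({
        "majority_ids": df[MAJORITY_IDS].to_numpy(),
        "is_decoy": is_decoy.to_numpy(),
        "is_contaminant": is_contaminant.to_numpy(),
    }, index=index)
    return intensity, msms, meta


def build_quant_matrix(
    intensity: pd.DataFrame,
    sequences: dict[str, str],
    samples: pd.DataFrame | None = None,
    msms_count: pd.DataFrame | None = None,
    permissive_mass: bool = False,
) -> QuantMatrix:
    """Assemble a :class:`QuantMatrix`, computing molecular weights.

    Shared-peptide protein groups are quantified by the leading
    accession's sequence mass; proteins without a FASTA entry raise.
    """
    missing = [acc for acc in intensity.index if acc not in sequences]
    if missing:
        raise ValueError(f"no FASTA sequence for {len(missing)} protein(s), "
                         f"e.g. {missing[:3]}")
    records = [ProteinRecord(acc, sequence=sequences[acc],
                             mw=compute_molecular_weight(sequences[acc],
                                                         permissive=permissive_mass))
               for acc in intensity.index]
    proteins = pd.DataFrame(
        {"mw": [r.mw for r in records]},
        index=pd.Index([r.accession for r in records], name="accession"),
    )
    if samples is None:
        samples = pd.DataFrame(index=intensity.columns)
    return QuantMatrix(intensity=intensity, samples=samples,
                       proteins=proteins, msms_count=msms_count)


def read_profile(path) -> CellSystemProfile:
    """Read a cell-system profile from TOML.

    Keys: ``system_name``, ``protein_per_cell_pg``; optional
    ``cell_radius_um``, ``seeded_cells``.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return CellSystemProfile(
        system_name=data["system_name"],
        protein_per_cell=float(data["protein_per_cell_pg"]),
        cell_radius=float(data["cell_radius_um"]) if "cell_radius_um" in data else None,
        seeded_cells=float(data["seeded_cells"]) if "seeded_cells" in data else None,
    )


def read_secretome_meta(path) -> SecretomeExperiment:
    """Read secretome experiment metadata from TOML.

    Keys: ``seeded_cells``, ``secretion_days``, ``protein_before_ug``,
    ``protein_after_ug``, ``albumin_purity``.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return SecretomeExperiment(
        seeded_cells=float(data["seeded_cells"]),
        secretion_days=float(data.get("secretion_days", 2.0)),
        protein_before_ug=float(data["protein_before_ug"]) if "protein_before_ug" in data else None,
        protein_after_ug=float(data["protein_after_ug"]) if "protein_after_ug" in data else None,
        albumin_purity=float(data["albumin_purity"]) if "albumin_purity" in data else None,
    )


def file_digest(path) -> str:
    """Short SHA-256 digest of a file, for provenance headers."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_table(df: pd.DataFrame, path, parameters: dict | None = None,
                inputs: dict | None = None) -> None:
    """Write a result TSV with a ``#`` provenance header.

    The header records the package version, the parameters of the run
    and digests of the input files; readers skip ``#`` lines, so the
    table round-trips losslessly. No timestamp is written — identical
    inputs yield byte-identical files.
    """
    path = Path(path)
    lines = [f"# tpaquant {__version__}"]
    for key, value in (parameters or {}).items():
        lines.append(f"# param {key} = {value}")
    for name, p in (inputs or {}).items():
        lines.append(f"# input {name} = {Path(p).name} sha256:{file_digest(p)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", na_rep="NA")


def read_table(path, index_col: int | str | None = 0) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (``#`` lines ignored)."""
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col,
                       na_values=["NA"])
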