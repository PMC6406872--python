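"""Ground-truth-labeled synthetic data for every pipeline stage.

Emulates the statistical structure of label-free proteomics data:

* lognormal copy-number distributions spanning many orders of
  magnitude, with replicate-level multiplicative intensity noise;
* intensity-dependent missingness (left censoring through a logistic
  detection curve on log10 intensity);
* system-specific planted effects — a mixture of unchanged proteins,
  moderate fold changes, large (>20x) fold changes, and proteins
  entirely absent from a system;
* overdispersed spectral counts (negative binomial) across batches,
  with planted differential proteins;
* a secretome depletion x injection replicate grid with known
  secretion rates, a known albumin rate hidden behind immunodepletion,
  and annotation flags for the secretion classifier.

All generators are pure functions of their configuration (which
carries the mandatory seed): the same config yields identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .quant_core import CellSystemProfile
from .secretome import SecretomeExperiment

REFERENCE_SYSTEM = "PHH"

_DEFAULT_REPLICATES = {"HepaRG": 5, "PHH": 12, "HepG2": 3}
_DEFAULT_ABSENT = {"HepaRG": 0.0, "PHH": 0.008, "HepG2": 0.12}
_DEFAULT_PROFILES = {
    "HepaRG": dict(protein_per_cell=300.0, cell_radius=9.5),
    "PHH": dict(protein_per_cell=400.0, cell_radius=10.5),
    "HepG2": dict(protein_per_cell=200.0, cell_radius=8.5),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-data generators.

    The defaults mirror the study conditions the pipeline targets:
    three cell systems with unbalanced replication (the reference
    primary-hepatocyte system contributes the most replicates), a 3x3
    depletion x injection secretome grid, and spectral counts from
    3 batches x 4 replicates.
    """

    seed: int
    n_proteins: int = 2000
    systems: tuple[str, ...] = tuple(_DEFAULT_REPLICATES)
    replicates: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_REPLICATES))
    fraction_absent: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_ABSENT))
    log10_copy_mean: float = 4.5
    log10_copy_sd: float = 1.2
    # planted fold-change mixture vs the reference system
    fraction_moderate_fc: float = 0.05   # 2-10x
    fraction_large_fc: float = 0.05      # > 20x
    noise_sd: float = 0.2                # lognormal (natural-log sd) intensity noise
    detect_midpoint_log10: float | None = 7.0
    detect_slope: float = 2.0
    # molecular weights: log10 normal around ~40 kDa
    log10_mw_mean: float = 4.6
    log10_mw_sd: float = 0.25
    # spectral counts: library sizes of ~2e4 spectra per run and a
    # compressed (~3 orders) dynamic range, as spectral counting shows
    count_groups: int = 3
    count_replicates: int = 4
    count_depth: float = 20000.0
    count_depth_jitter_sd: float = 0.1   # lognormal sd of per-run library size
    count_log10_sd: float = 0.6
    count_dispersion: float = 0.05
    count_effect_fraction: float = 0.05
    count_effect_fc: float = 4.0
    # secretome
    n_secretome: int = 300
    secretome_grid: tuple[int, int] = (3, 3)
    log10_rate_mean: float = 1.5
    log10_rate_sd: float = 1.2
    seeded_cells: float = 1e6
    secretion_days: float = 2.0
    albumin_rate: float = 2e4            # ng/day/1e6 cells
    albumin_purity: float = 0.9
    rate_detect_midpoint_log10: float | None = -0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, frac in self.fraction_absent.items():
            if not 0 <= frac < 1:
                raise ValueError(f"fraction_absent[{name!r}] outside [0, 1)")
        if self.fraction_moderate_fc + self.fraction_large_fc > 1:
            raise ValueError("planted fold-change fractions exceed 1")
        if self.n_proteins < 1 or self.n_secretome < 1:
            raise ValueError("need at least one protein")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ProteomeSimulation:
    """Output of :func:`simulate_proteome` with ground truth attached."""

    intensity: pd.DataFrame          # proteins x samples, NaN = not detected
    sample_systems: pd.Series        # sample -> system
    mw: pd.Series                    # g/mol per protein
    profiles: dict[str, CellSystemProfile]
    true_copies: pd.DataFrame        # proteins x systems (NaN = absent)
    true_category: pd.DataFrame      # proteins x non-reference systems
    reference: str = REFERENCE_SYSTEM


def _planted_effects(rng: np.random.Generator, cfg: SimulationConfig,
                     n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein planted log10 fold change and its class label."""
    u = rng.random(n)
    labels = np.where(
        u < cfg.fraction_large_fc, "obvious",
        np.where(u < cfg.fraction_large_fc + cfg.fraction_moderate_fc,
                 "significant", "unchanged"),
    )
    lfc = np.zeros(n)
    mod = labels == "significant"
    big = labels == "obvious"
    sign = rng.choice([-1.0, 1.0], size=n)
    lfc[mod] = sign[mod] * rng.uniform(np.log10(2), 1.0, mod.sum())
    lfc[big] = sign[big] * rng.uniform(np.log10(20), 3.0, big.sum())
    return lfc, labels


def simulate_proteome(cfg: SimulationConfig) -> ProteomeSimulation:
    """Simulate a multi-system proteome with known copy numbers.

    Reference-system copies are lognormal; each non-reference system
    applies its planted fold changes and absences. Raw intensities are
    ``copies x mw x depth x lognormal noise`` per replicate, and
    detection is Bernoulli with a logistic probability in log10
    intensity (set ``detect_midpoint_log10=None`` for full detection).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    accessions = pd.Index([f"P{i:05d}" for i in range(n)], name="accession")
    mw = pd.Series(10.0 ** rng.normal(cfg.log10_mw_mean, cfg.log10_mw_sd, n),
                   index=accessions, name="mw").clip(5e3, 5e5)
    base_log10 = rng.normal(cfg.log10_copy_mean, cfg.log10_copy_sd, n)

    true_copies = {}
    category = {}
    lfc_by_system: dict[str, np.ndarray] = {}
    for system in cfg.systems:
        if system == REFERENCE_SYSTEM:
            log10_c = base_log10.copy()
            labels = None
        else:
            lfc, labels = _planted_effects(rng, cfg, n)
            lfc_by_system[system] = lfc
            log10_c = base_log10 + lfc
        copies = 10.0 ** log10_c
        absent = rng.random(n) < cfg.fraction_absent.get(system, 0.0)
        copies[absent] = np.nan
        true_copies[system] = copies
        if labels is not None:
            lab = labels.copy().astype(object)
            lab[absent] = f"absent_in_{system}"
            category[system] = lab
    true_copies = pd.DataFrame(true_copies, index=accessions)
    # a protein absent in the reference is absent-present vs every system
    ref_absent = true_copies[REFERENCE_SYSTEM].isna().to_numpy()
    for system in category:
        category[system] = np.where(
            ref_absent & true_copies[system].notna().to_numpy(),
            f"absent_in_{REFERENCE_SYSTEM}", category[system])
    true_category = pd.DataFrame(category, index=accessions)

    # protein content per cell follows from the planted copies by mass
    # closure, so the TPA round-trip is exact by construction
    avogadro = 6.02214076e23
    profiles = {}
    for s in cfg.systems:
        p_cell_pg = float(np.nansum(true_copies[s].to_numpy() * mw.to_numpy())
                          / avogadro * 1e12)
        radius = _DEFAULT_PROFILES.get(s, {}).get("cell_radius")
        profiles[s] = CellSystemProfile(system_name=s, protein_per_cell=p_cell_pg,
                                        cell_radius=radius)

    columns = {}
    sample_systems = {}
    for system in cfg.systems:
        c = true_copies[system].to_numpy()
        for rep in range(1, cfg.replicates[system] + 1):
            name = f"{system}_r{rep}"
            eps = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
            intensity = c * mw.to_numpy() * np.exp(eps)
            if cfg.detect_midpoint_log10 is not None:
                with np.errstate(invalid="ignore", divide="ignore"):
                    p_detect = expit(cfg.detect_slope
                                     * (np.log10(intensity) - cfg.detect_midpoint_log10))
                detected = rng.random(n) < np.nan_to_num(p_detect)
                intensity = np.where(detected, intensity, np.nan)
            columns[name] = intensity
            sample_systems[name] = system
    intensity = pd.DataFrame(columns, index=accessions)
    return ProteomeSimulation(
        intensity=intensity,
        sample_systems=pd.Series(sample_systems, name="system"),
        mw=mw, profiles=profiles, true_copies=true_copies,
        true_category=true_category,
    )


@dataclass
class CountSimulation:
    """Output of :func:`simulate_counts` with ground truth attached."""

    counts: pd.DataFrame
    groups: pd.Series
    true_differential: pd.Series
    true_fc: pd.Series


def simulate_counts(cfg: SimulationConfig) -> CountSimulation:
    """Simulate an overdispersed spectral-count matrix across batches.

    Per-protein relative abundances are lognormal; a planted fraction
    of proteins changes by ``count_effect_fc`` in the last batch.
    Counts are negative binomial around ``proportion x depth`` with
    ``count_dispersion`` (variance mu + dispersion mu^2); dispersion 0
    gives Poisson counts.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_proteins
    accessions = pd.Index([f"P{i:05d}" for i in range(n)], name="accession")
    weight = 10.0 ** rng.normal(0.0, cfg.count_log10_sd, n)
    differential = rng.random(n) < cfg.count_effect_fraction
    fc = np.ones(n)
    up = rng.random(n) < 0.5
    fc[differential & up] = cfg.count_effect_fc
    fc[differential & ~up] = 1.0 / cfg.count_effect_fc

    columns = {}
    groups = {}
    for b in range(1, cfg.count_groups + 1):
        w = weight * fc if b == cfg.count_groups else weight
        prop = w / w.sum()
        for rep in range(1, cfg.count_replicates + 1):
            name = f"batch{b}_r{rep}"
            depth = cfg.count_depth * (rng.lognormal(0.0, cfg.count_depth_jitter_sd)
                                       if cfg.count_depth_jitter_sd > 0 else 1.0)
            mu = prop * depth
            if cfg.count_dispersion < 1e-9:
                k = rng.poisson(mu)
            else:
                size = 1.0 / cfg.count_dispersion
                k = rng.negative_binomial(size, size / (size + mu))
            columns[name] = k
            groups[name] = f"batch{b}"
    counts = pd.DataFrame(columns, index=accessions)
    return CountSimulation(
        counts=counts,
        groups=pd.Series(groups, name="batch"),
        true_differential=pd.Series(differential, index=accessions,
                                    name="is_differential"),
        true_fc=pd.Series(fc, index=accessions, name="true_fc"),
    )


@dataclass
class SecretomeSimulation:
    """Output of :func:`simulate_secretome` with ground truth attached."""

    intensity: pd.DataFrame          # proteins x (depletion x injection) grid
    depletion_rep: pd.Series         # sample -> depletion replicate label
    annotations: pd.DataFrame
    experiment: SecretomeExperiment
    true_rates: pd.Series            # ng/day/1e6 cells
    true_albumin_rate: float


def simulate_secretome(cfg: SimulationConfig) -> SecretomeSimulation:
    """Simulate a depleted secretome over the depletion x injection grid.

    True secretion rates are lognormal; the depleted-fraction protein
    amount is set by mass closure over the simulated proteins, and the
    pre-depletion amount hides a known albumin rate behind the
    depletion loss and band purity. Intensities are proportional to
    the true rates with lognormal noise; identification is logistic in
    log10 rate (``rate_detect_midpoint_log10=None`` for full grids).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_secretome
    accessions = pd.Index([f"S{i:04d}" for i in range(n)], name="accession")
    rates = pd.Series(10.0 ** rng.normal(cfg.log10_rate_mean, cfg.log10_rate_sd, n),
                      index=accessions, name="true_rate")

    cell_days = cfg.secretion_days * cfg.seeded_cells / 1e6
    protein_after_ug = float(rates.sum() * cell_days / 1e3)   # ng -> ug
    albumin_loss_ug = cfg.albumin_rate * cell_days / cfg.albumin_purity / 1e3
    experiment = SecretomeExperiment(
        seeded_cells=cfg.seeded_cells,
        secretion_days=cfg.secretion_days,
        protein_before_ug=protein_after_ug + albumin_loss_ug,
        protein_after_ug=protein_after_ug,
        albumin_purity=cfg.albumin_purity,
    )

    n_dep, n_inj = cfg.secretome_grid
    columns = {}
    depletion_rep = {}
    r = rates.to_numpy()
    for d in range(1, n_dep + 1):
        for i in range(1, n_inj + 1):
            name = f"dep{d}_inj{i}"
            eps = rng.normal(0.0, cfg.noise_sd, n) if cfg.noise_sd > 0 else 0.0
            intensity = r * np.exp(eps)
            if cfg.rate_detect_midpoint_log10 is not None:
                p_detect = expit(cfg.detect_slope
                                 * (np.log10(r) - cfg.rate_detect_midpoint_log10))
                detected = rng.random(n) < p_detect
                intensity = np.where(detected, intensity, np.nan)
            columns[name] = intensity
            depletion_rep[name] = f"dep{d}"
    intensity = pd.DataFrame(columns, index=accessions)

    u = rng.random(n)
    annotations = pd.DataFrame(
        {
            "signal_peptide": u < 0.70,
            "nonclassical": (u >= 0.70) & (u < 0.80),
            "extracellular_or_exosome": (u >= 0.80) & (u < 0.95),
        },
        index=accessions,
    )
    return SecretomeSimulation(
        intensity=intensity,
        depletion_rep=pd.Series(depletion_rep, name="depletion_rep"),
        annotations=annotations,
        experiment=experiment,
        true_rates=rates,
        true_albumin_rate=cfg.albumin_rate,
    )


def noiseless(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of ``cfg`` with noise and missingness switched off."""
    return replace(cfg, noise_sd=0.0, detect_midpoint_log10=None,
                   rate_detect_midpoint_log10=None,
                   fraction_absent={s: 0.0 for s in cfg.fraction_absent})
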