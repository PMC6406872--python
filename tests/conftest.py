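"""Shared fixtures: tiny on-disk input files and simulation helpers."""

import numpy as np
import pandas as pd
import pytest

from tpaquant.quant_core import tpa_copy_numbers

PG_TEXT = """\
Majority protein IDs\tIntensity s1\tIntensity s2\tMS/MS count s1\tMS/MS count s2\tReverse\tPotential contaminant
P10001;P10009\t1000000\t2000000\t5\t8\t\t
P10002\t500000\t0\t3\t0\t\t
P10003\t0\t800000\t0\t4\t\t
P10004\t250000\t300000\t2\t2\t\t
P10005\t90000\t110000\t1\t1\t\t
P10006\t4000000\t3500000\t12\t11\t\t
P10007\t60000\t70000\t1\t1\t\t
P10008\t10000\t15000\t1\t1\t\t
REV__P10010\t10000\t10000\t1\t1\t+\t
CON__P10011\t999999\t888888\t9\t9\t\t+
"""

FASTA_TEXT = """\
>sp|P10001|PROT1_HUMAN Test protein 1
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVK
ALPDAQFEVVHSLAKWKRQTLGQHDFSAGEGLYTHMKALRPDEDRLSPLHSVYVDQWDWE
>sp|P10002|PROT2_HUMAN Test protein 2
GGSSAAGG
>sp|P10003|PROT3_HUMAN
MEEPQSDPSV
>sp|P10004|PROT4_HUMAN
ACDEFGHIKLMNPQRSTVWY
>sp|P10005|PROT5_HUMAN
PEPTIDE
>sp|P10006|PROT6_HUMAN
MSTNPKPQRKTKRNTNRRPQDVKFPGG
>sp|P10007|PROT7_HUMAN
WWWWHHHH
>sp|P10008|PROT8_HUMAN
GASPVTLIMC
"""


@pytest.fixture
def protein_groups_file(tmp_path):
    path = tmp_path / "proteinGroups.txt"
    path.write_text(PG_TEXT)
    return path


@pytest.fixture
def fasta_file(tmp_path):
    path = tmp_path / "sequences.fasta"
    path.write_text(FASTA_TEXT)
    return path


@pytest.fixture
def profile_toml(tmp_path):
    path = tmp_path / "profile.toml"
    path.write_text(
        'system_name = "HepaRG"\n'
        "protein_per_cell_pg = 300.0\n"
        "cell_radius_um = 9.5\n"
    )
    return path


def replicate_copies(sim):
    """Replicate-level TPA copy numbers from a proteome simulation."""
    return pd.DataFrame({
        col: tpa_copy_numbers(sim.intensity[col], sim.mw,
                              sim.profiles[sim.sample_systems[col]])
        for col in sim.intensity.columns
    })


def betabinom_draws(rng, pi, theta, t, size):
    """Sample spectral counts from the beta-binomial null model."""
    a = pi * (1 - theta) / theta
    b = (1 - pi) * (1 - theta) / theta
    return rng.binomial(t, rng.beta(a, b, size))
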