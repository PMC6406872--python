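"""Rank-based 2D annotation enrichment.

Asks, per annotation term, whether the term's member proteins shift
jointly in two log-abundance dimensions (e.g. cell line A vs reference
and cell line B vs reference log ratios). Each dimension is reduced to
ranks, so the result is invariant under any strictly monotone
transform of the input values.

The per-dimension score is the mean member rank, centered and scaled
so that a term occupying the n_t largest values scores exactly +1 and
the n_t smallest exactly -1:

    s = 2 (R_members - (n + 1) / 2) / (n - n_t)

Joint significance uses a two-sample Hotelling T² comparing member vs
non-member 2D rank vectors, with a chi-square (2 df) tail probability,
followed by Benjamini-Hochberg adjustment across terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def term_score(values, members) -> float:
    """Rank-based enrichment score of a member set in one dimension.

    ``members`` is a boolean mask or index array into ``values``. Ties
    get average ranks. Raises on empty or all-inclusive membership.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(members)] = True
    n_t = int(mask.sum())
    if n_t == 0 or n_t == n:
        raise ValueError("membership must be a proper non-empty subset")
    ranks = stats.rankdata(v)
    r_bar = ranks[mask].mean()
    return float(2.0 * (r_bar - (n + 1) / 2.0) / (n - n_t))


def term_test_2d(x, y, members) -> float:
    """Hotelling T² p-value for a term's joint 2D rank shift.

    Both dimensions are rank-transformed; member and non-member rank
    vectors are compared with a two-sample Hotelling T² statistic and a
    chi-square (2 df) approximation. A singular pooled covariance gives
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(members)] = True
    n1 = int(mask.sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two members and two non-members")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    a = np.column_stack([rx[mask], ry[mask]])
    b = np.column_stack([rx[~mask], ry[~mask]])
    d = a.mean(axis=0) - b.mean(axis=0)
    s_pooled = ((n1 - 1) * np.cov(a, rowvar=False)
                + (n2 - 1) * np.cov(b, rowvar=False)) / (n1 + n2 - 2)
    try:
        sol = np.linalg.solve(s_pooled, d)
    except np.linalg.LinAlgError:
        logger.warning("singular pooled covariance; p set to 1")
        return 1.0
    t2 = (n1 * n2) / (n1 + n2) * float(d @ sol)
    if not np.isfinite(t2) or t2 < 0:
        logger.warning("degenerate Hotelling statistic; p set to 1")
        return 1.0
    return float(stats.chi2.sf(t2, 2))


def enrich_2d(
    x: pd.Series,
    y: pd.Series,
    memberships: dict[str, set] | pd.DataFrame,
    min_size: int = 10,
    fdr_threshold: float = 0.02,
) -> pd.DataFrame:
    """2D annotation enrichment over a collection of terms.

    Parameters
    ----------
    x, y : per-protein values of the two dimensions, aligned on a
        common protein index (proteins missing either value are
        dropped).
    memberships : term -> set of accessions, or a long-format frame
        with columns ``accession`` and ``term``.
    min_size : smallest member count (within the scored proteins) for
        a term to be tested.
    fdr_threshold : BH threshold reported in the ``enriched`` column.

    Returns a per-term table with ``score_x``, ``score_y``, ``p``,
    ``bh_fdr``, ``n_members`` and ``enriched``, sorted by p.
    """
    common = x.dropna().index.intersection(y.dropna().index)
    xv = x.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    pos = {acc: i for i, acc in enumerate(common)}
    if isinstance(memberships, pd.DataFrame):
        grouped = memberships.groupby("term")["accession"].apply(set).to_dict()
    else:
        grouped = {t: set(m) for t, m in memberships.items()}
    rows = []
    for term, accs in grouped.items():
        idx = np.array(sorted(pos[a] for a in accs if a in pos), dtype=int)
        if idx.size < min_size or idx.size >= len(common):
            continue
        rows.append({
            "term": term,
            "score_x": term_score(xv, idx),
            "score_y": term_score(yv, idx),
            "p": term_test_2d(xv, yv, idx),
            "n_members": int(idx.size),
        })
    if not rows:
        return pd.DataFrame(
            columns=["score_x", "score_y", "p", "bh_fdr", "n_members", "enriched"]
        )
    table = pd.DataFrame(rows).set_index("term")
    table["bh_fdr"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["enriched"] = table["bh_fdr"] < fdr_threshold
    return table.sort_values("p")
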