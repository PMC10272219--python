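"""Probabilistic pairwise DT co-occurrence at the leaf level.

For two damage types observed on N1 and N2 of a forest's N leaves, the number
of leaves bearing both under random, independent placement follows the
hypergeometric law

    P(j) = C(N1, j) C(N - N1, N2 - j) / C(N, N2).

The observed joint count j_obs is compared against this exact distribution —
no randomization involved.  A pair is classified *positive* when
P(J >= j_obs) < alpha, *negative* when P(J <= j_obs) < alpha, otherwise
*random*; both tails include j_obs.  Expected co-occurrence is N1*N2/N and
the reported effect size is (j_obs - expected)/N, the per-leaf excess.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .census import Census, CensusValidationError

__all__ = [
    "PairCooccurrence",
    "pair_cooccurrence",
    "cooccurrence_matrix",
    "pairing_summary",
]


@dataclass(frozen=True)
class PairCooccurrence:
    dt_a: str
    dt_b: str
    N: int
    N1: int
    N2: int
    j_obs: int
    expected: float
    p_lt: float
    p_gt: float
    effect: float
    classification: str  # positive | negative | random
    note: str = ""


def _classify(
    N: int, N1: int, N2: int, j_obs: int, alpha: float
) -> tuple[float, float, str, str]:
    if N1 == N or N2 == N:
        # a DT on every leaf admits no variation in joint count
        return 1.0, 1.0, "random", "degenerate: DT occurs on every leaf"
    dist = stats.hypergeom(N, N1, N2)
    p_gt = float(dist.sf(j_obs - 1))
    p_lt = float(dist.cdf(j_obs))
    if p_gt < alpha:
        cls = "positive"
    elif p_lt < alpha:
        cls = "negative"
    else:
        cls = "random"
    return p_lt, p_gt, cls, ""


def pair_cooccurrence(
    view: Census, dt_a: str, dt_b: str, alpha: float = 0.05
) -> PairCooccurrence:
    """Exact hypergeometric co-occurrence test for one DT pair in a view."""
    N = view.n_leaves
    if N < 2:
        raise CensusValidationError("co-occurrence needs >= 2 leaves")
    inc = view.incidents
    leaves_a = set(inc.loc[inc["dt_code"] == dt_a, "leaf_id"])
    leaves_b = set(inc.loc[inc["dt_code"] == dt_b, "leaf_id"])
    if not leaves_a or not leaves_b:
        missing = [d for d, s in ((dt_a, leaves_a), (dt_b, leaves_b)) if not s]
        raise CensusValidationError(f"DT(s) absent from view: {missing}")
    N1, N2 = len(leaves_a), len(leaves_b)
    j_obs = len(leaves_a & leaves_b)
    expected = N1 * N2 / N
    p_lt, p_gt, cls, note = _classify(N, N1, N2, j_obs, alpha)
    return PairCooccurrence(
        dt_a=dt_a, dt_b=dt_b, N=N, N1=N1, N2=N2, j_obs=j_obs,
        expected=expected, p_lt=p_lt, p_gt=p_gt,
        effect=(j_obs - expected) / N, classification=cls, note=note,
    )


def cooccurrence_matrix(
    census: Census,
    forest: str,
    *,
    alpha: float = 0.05,
    min_expected: float = 1.0,
    drop_singletons: bool = True,
) -> tuple[list[PairCooccurrence], pd.DataFrame, pd.DataFrame]:
    """All eligible unordered DT pairs within one forest.

    Singleton DTs (on exactly one leaf) are dropped when ``drop_singletons``;
    pairs with expected joint count below ``min_expected`` are excluded.
    Returns (pairs, long table incl. excluded pairs flagged, effect matrix
    with NaN for ineligible cells) — the effect matrix is the plotting analog
    of a positive/negative/random co-occurrence panel.
    """
    sub = census.leaves["forest"] == forest
    if not sub.any():
        raise CensusValidationError(f"forest {forest!r} not present in census")
    view = census.subset(census.leaves.index[sub])
    N = view.n_leaves
    occ = view.incidents.groupby("dt_code")["leaf_id"].nunique()
    dts = sorted(occ.index)
    if drop_singletons:
        dts = [d for d in dts if occ[d] > 1]
    pairs: list[PairCooccurrence] = []
    records = []
    for dt_a, dt_b in combinations(dts, 2):
        expected = occ[dt_a] * occ[dt_b] / N
        if expected < min_expected:
            records.append(
                {"dt_a": dt_a, "dt_b": dt_b, "expected": expected, "included": False}
            )
            continue
        pc = pair_cooccurrence(view, dt_a, dt_b, alpha=alpha)
        pairs.append(pc)
        rec = pc.__dict__.copy()
        rec["included"] = True
        records.append(rec)
    if len(dts) < 2:
        table = pd.DataFrame(records)
        return [], table, pd.DataFrame(index=dts, columns=dts, dtype=float)
    table = pd.DataFrame(records)
    effect = pd.DataFrame(np.nan, index=dts, columns=dts, dtype=float)
    for pc in pairs:
        effect.at[pc.dt_a, pc.dt_b] = pc.effect
        effect.at[pc.dt_b, pc.dt_a] = pc.effect
    return pairs, table, effect


def pairing_summary(pairs: list[PairCooccurrence]) -> pd.DataFrame:
    """Per-DT share of positive vs negative classifications among its
    significant pairs.

    DTs with no significant pair report n_significant = 0 and NaN percents.
    A DT positively pairing with everything it significantly meets shows
    pct_positive = 100.
    """
    dts = sorted({p.dt_a for p in pairs} | {p.dt_b for p in pairs})
    rows = []
    for dt in dts:
        sig = [
            p for p in pairs
            if dt in (p.dt_a, p.dt_b) and p.classification != "random"
        ]
        n_sig = len(sig)
        n_pos = sum(1 for p in sig if p.classification == "positive")
        rows.append(
            {
                "dt_code": dt,
                "n_significant": n_sig,
                "pct_positive": 100.0 * n_pos / n_sig if n_sig else float("nan"),
                "pct_negative": 100.0 * (n_sig - n_pos) / n_sig if n_sig else float("nan"),
            }
        )
    return pd.DataFrame(rows)
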