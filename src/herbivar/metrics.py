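"""Per-quarry herbivory and plant-community metrics.

Damage frequency is the fraction of censused leaves bearing at least one DT
matching a selector (total, generalized/specialized, or one FFG); a leaf
counts once no matter how many incidents it carries.  DT diversity is
standardized for uneven sampling by analytic sample-based rarefaction to a
common number of leaves (default 300): the expected DT richness over all
equally likely leaf subsets of that size,

    E[S] = sum_d [ 1 - C(N - m_d, n) / C(N, n) ],

with N leaves in the quarry and m_d leaves bearing DT d.  This equals the
mean of exhaustive subsampling without replacement and is deterministic; a
Monte-Carlo mode is kept as a cross-check.  Plant diversity is Shannon H (in
nats) on leaf shares per taxon, with Pielou's J = H / ln S for evenness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .census import Census, CensusValidationError

__all__ = [
    "damage_frequency",
    "rarefied_dt_diversity",
    "plant_diversity",
    "logit",
    "metrics_table",
    "HerbivoryMetrics",
]

#: metric columns emitted by :func:`metrics_table`
FREQ_SELECTORS = (
    "total",
    "specialized",
    "hole",
    "margin",
    "surface",
    "skeletonization",
    "piercing_sucking",
    "gall",
    "mine",
)
DIV_SELECTORS = ("total", "specialized", "gall", "mine")


@dataclass(frozen=True)
class HerbivoryMetrics:
    """The per-quarry metric set (9 frequencies + 4 rarefied diversities
    + plant Shannon/Pielou)."""

    quarry_key: tuple[str, str, str]
    n_leaves: int
    n_std: int
    freqs: dict[str, float]
    divs: dict[str, float]
    plant_shannon: float
    plant_pielou: float  # NaN flags the single-taxon undefined case


def _damaged_leaf_ids(view: Census, selector: str) -> set[str]:
    dts = view.catalog.resolve_selector(selector)
    inc = view.incidents
    if dts is not None:
        inc = inc[inc["dt_code"].isin(dts)]
    return set(inc["leaf_id"])


def damage_frequency(view: Census, selector: str = "total") -> float:
    """Fraction of leaves in the view bearing >= 1 DT matching ``selector``."""
    if view.n_leaves == 0:
        raise CensusValidationError("damage_frequency on empty view")
    return len(_damaged_leaf_ids(view, selector)) / view.n_leaves


def _log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(n - k + 1) - gammaln(k + 1)


def rarefied_dt_diversity(
    view: Census,
    selector: str = "total",
    n_std: int = 300,
    *,
    method: str = "analytic",
    n_draws: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Expected DT richness in a random subsample of ``n_std`` leaves.

    ``method='analytic'`` (default) evaluates the closed-form expectation;
    ``method='monte_carlo'`` subsamples leaves ``n_draws`` times without
    replacement and averages observed richness (cross-check mode).
    """
    N = view.n_leaves
    if N < n_std:
        raise CensusValidationError(
            f"view has {N} leaves < n_std={n_std}; filter quarries first "
            "(filter_quarries)"
        )
    dts = view.catalog.resolve_selector(selector)
    inc = view.incidents
    if dts is not None:
        inc = inc[inc["dt_code"].isin(dts)]
    if inc.empty:
        return 0.0
    m = inc.groupby("dt_code")["leaf_id"].nunique().to_numpy()

    if method == "analytic":
        # P(DT d absent) = C(N - m_d, n) / C(N, n); 0 when N - m_d < n.
        with np.errstate(invalid="ignore"):
            log_absent = _log_comb(N - m, n_std) - _log_comb(N, n_std)
        p_absent = np.where(N - m >= n_std, np.exp(log_absent), 0.0)
        return float(np.sum(1.0 - p_absent))

    if method == "monte_carlo":
        rng = np.random.default_rng(0) if rng is None else rng
        leaf_ids = view.leaves.index.to_numpy()
        sets = inc.groupby("dt_code")["leaf_id"].apply(set)
        richness = np.empty(n_draws)
        for i in range(n_draws):
            chosen = set(rng.choice(leaf_ids, size=n_std, replace=False))
            richness[i] = sum(1 for s in sets if s & chosen)
        return float(richness.mean())

    raise ValueError(f"unknown method {method!r}")


def plant_diversity(view: Census) -> tuple[float, float]:
    """Shannon H (nats) and Pielou J of the view's plant-taxon leaf shares.

    J is NaN when only one taxon is present (ln S = 0)."""
    if view.n_leaves == 0:
        raise CensusValidationError("plant_diversity on empty view")
    counts = view.leaves["plant_taxon"].value_counts().to_numpy(dtype=float)
    p = counts / counts.sum()
    H = float(-(p * np.log(p)).sum())
    S = len(counts)
    J = H / math.log(S) if S > 1 else float("nan")
    return H, J


def logit(p: float, n: int | None = None) -> float:
    """Natural-log logit with an empirical adjustment at the boundaries.

    p in {0, 1} is replaced by (p*(n-1) + 0.5)/n using the leaf count ``n``
    of the originating view, so boundary frequencies stay finite.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"proportion outside [0, 1]: {p}")
    if p in (0.0, 1.0):
        if n is None:
            raise ValueError("boundary proportion needs the view's leaf count n")
        p = (p * (n - 1) + 0.5) / n
    return math.log(p / (1.0 - p))


def metrics_table(census: Census, n_std: int = 300) -> pd.DataFrame:
    """All herbivory + plant metrics, one row per quarry.

    The census must already be filtered to quarries with >= ``n_std`` leaves.
    Columns: forest, env, quarry, n_leaves, freq_* (9), div_* (4, rarefied at
    n_std), plant_shannon, plant_pielou.
    """
    from .census import aggregate

    rows = []
    for key, view in aggregate(census, "quarry").items():
        H, J = plant_diversity(view)
        row = {
            "forest": key[0],
            "env": key[1],
            "quarry": key[2],
            "n_leaves": view.n_leaves,
        }
        for sel in FREQ_SELECTORS:
            row[f"freq_{sel}"] = damage_frequency(view, sel)
        for sel in DIV_SELECTORS:
            row[f"div_{sel}"] = rarefied_dt_diversity(view, sel, n_std)
        row["plant_shannon"] = H
        row["plant_pielou"] = J
        row["n_std"] = n_std
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["forest", "env", "quarry"]).reset_index(drop=True)
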