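"""Quarry-level weighted bipartite plant-DT networks and their metrics.

A quarry's incidence matrix has plant taxa as rows, damage types as columns,
and summed incident counts as weights.  Network-level metrics:

connectance
    realized links / (rows * columns) on the binary view.
nestedness (NODF)
    mean paired-overlap percentage over ordered row pairs and column pairs
    with strictly decreasing fill, scaled to [0, 100]; higher = more nested,
    i.e. more overlapping/generalized interaction structure.
partner diversity (plants)
    mean over plant rows of the Shannon entropy (nats) of each row's
    normalized interaction weights.
robustness (DTs)
    area under the secondary-extinction curve: plants are removed in random
    order and a DT survives while at least one host remains; the curve of
    surviving DT fraction vs fraction of plants removed is integrated by the
    trapezoid rule and averaged over removal orders (all P! orders enumerated
    when P <= 6).
H2'
    network-wide standardized two-dimensional Shannon specialization
    (H2max - H2) / (H2max - H2min), 0 = no specialization (interactions
    proportional to marginals) to 1 = complete specialization, where H2max /
    H2min are entropy extremes over integer matrices with the observed
    marginals (independence-rounding and greedy-concentration fills).

Bootstrap standardization resamples each quarry to a fixed number of leaves
without replacement (default 300, repeated 500 times) before building each
network, putting quarries of unequal sampling effort on a common footing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .census import Census, CensusValidationError

__all__ = [
    "IncidenceMatrix",
    "NetworkMetrics",
    "BootstrapResult",
    "build_incidence",
    "connectance",
    "nestedness_nodf",
    "partner_diversity_plants",
    "robustness_dts",
    "h2prime",
    "network_metrics",
    "bootstrap_networks",
    "degree_profile",
]

METRIC_NAMES = ("connectance", "nodf", "partner_diversity", "robustness", "h2prime")


@dataclass(frozen=True)
class IncidenceMatrix:
    """Plant x DT weighted incidence for one quarry (rows/cols lexicographic,
    all-zero marginals dropped)."""

    plants: tuple[str, ...]
    dts: tuple[str, ...]
    weights: np.ndarray  # (len(plants), len(dts)) nonnegative ints
    quarry_key: tuple[str, str, str] | None = None

    @property
    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(np.int8)


@dataclass(frozen=True)
class NetworkMetrics:
    connectance: float
    nodf: float
    partner_diversity: float
    robustness: float
    h2prime: float

    def as_dict(self) -> dict[str, float]:
        return {
            "connectance": self.connectance,
            "nodf": self.nodf,
            "partner_diversity": self.partner_diversity,
            "robustness": self.robustness,
            "h2prime": self.h2prime,
        }


def build_incidence(quarry_view: Census) -> IncidenceMatrix:
    """Sum incident counts into a plant x DT matrix for one quarry view."""
    if quarry_view.incidents.empty:
        raise CensusValidationError("no damaged leaves: cannot build a network")
    inc = quarry_view.incidents.merge(
        quarry_view.leaves[["plant_taxon"]], left_on="leaf_id", right_index=True
    )
    pivot = (
        inc.groupby(["plant_taxon", "dt_code"])["count"].sum().unstack(fill_value=0)
    )
    pivot = pivot.loc[(pivot.sum(axis=1) > 0), (pivot.sum(axis=0) > 0)]
    pivot = pivot.sort_index(axis=0).sort_index(axis=1)
    keys = quarry_view.quarry_keys
    return IncidenceMatrix(
        plants=tuple(pivot.index),
        dts=tuple(pivot.columns),
        weights=pivot.to_numpy(dtype=np.int64),
        quarry_key=keys[0] if len(keys) == 1 else None,
    )


def connectance(m: IncidenceMatrix) -> float:
    """Realized fraction of possible plant-DT links."""
    b = m.binary
    return float(b.sum() / b.size)


def _nodf_axis(b: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap percentages over ordered row pairs of ``b``."""
    fills = b.sum(axis=1)
    n = b.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j or fills[i] <= fills[j] or fills[j] == 0:
                continue  # equal (or increasing) fill contributes 0
            overlap = int(np.minimum(b[i], b[j]).sum())
            total += 100.0 * overlap / fills[j]
    return total, n * (n - 1) // 2


def nestedness_nodf(m: IncidenceMatrix) -> float:
    """Binary NODF in [0, 100]; NaN for degenerate (single-row/column) matrices."""
    b = m.binary
    if b.shape[0] < 2 or b.shape[1] < 2:
        return float("nan")
    row_sum, row_pairs = _nodf_axis(b)
    col_sum, col_pairs = _nodf_axis(b.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


def partner_diversity_plants(m: IncidenceMatrix) -> float:
    """Mean Shannon entropy (nats) of per-plant interaction weight profiles."""
    w = m.weights.astype(float)
    row_tot = w.sum(axis=1, keepdims=True)
    p = w / row_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(p > 0, -p * np.log(p), 0.0).sum(axis=1)
    return float(h.mean())


def _robustness_from_death_ranks(death: np.ndarray, P: int) -> float:
    """Trapezoid area of the survival curve given each DT's extinction step."""
    # y_k = fraction of DTs still alive after k plant removals, k = 0..P
    alive = np.array([np.mean(death > k) for k in range(P + 1)])
    return float(np.trapezoid(alive, dx=1.0 / P))


def robustness_dts(
    m: IncidenceMatrix,
    n_orders: int = 100,
    rng: np.random.Generator | None = None,
    exact_max_plants: int = 6,
) -> float:
    """Robustness of DTs to random primary removal of plants, in [0, 1].

    All P! removal orders are enumerated when P <= ``exact_max_plants``;
    otherwise ``n_orders`` random orders are averaged.
    """
    b = m.binary.astype(bool)
    P = b.shape[0]
    if P == 0:
        raise CensusValidationError("robustness needs >= 1 plant")
    host_lists = [np.nonzero(b[:, j])[0] for j in range(b.shape[1])]

    def area_for(order: np.ndarray) -> float:
        rank = np.empty(P, dtype=np.int64)
        rank[order] = np.arange(1, P + 1)  # removal step of each plant
        death = np.array([rank[h].max() for h in host_lists])
        return _robustness_from_death_ranks(death, P)

    if P <= exact_max_plants:
        areas = [area_for(np.array(o)) for o in permutations(range(P))]
    else:
        rng = np.random.default_rng(0) if rng is None else rng
        areas = [area_for(rng.permutation(P)) for _ in range(n_orders)]
    return float(np.mean(areas))


# -- H2' ----------------------------------------------------------------------


def _entropy_nats(w: np.ndarray) -> float:
    w = np.asarray(w, dtype=float).ravel()
    tot = w.sum()
    p = w[w > 0] / tot
    return float(-(p * np.log(p)).sum())


def _h2_min_fill(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Greedy maximal-concentration fill: repeatedly give min(row, col) to the
    pairing of the largest remaining row and column totals (entropy-minimal
    heuristic, ties broken by index)."""
    r = r.astype(np.int64).copy()
    c = c.astype(np.int64).copy()
    out = np.zeros((len(r), len(c)), dtype=np.int64)
    while r.sum() > 0:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        alloc = min(r[i], c[j])
        out[i, j] += alloc
        r[i] -= alloc
        c[j] -= alloc
    return out


def _h2_max_fill(r: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Entropy-maximal integer fill with the given marginals.

    Floor the independence expectation r_i c_j / m, then hand the missing
    units one at a time to the admissible cell (row and column deficits both
    positive) with the smallest current count — cell entropy is separable
    concave, so the smallest cell has the largest marginal gain — breaking
    ties by largest fractional remainder.  Exact on 2x2 matrices (verified
    against exhaustive enumeration); a heuristic beyond.
    """
    m = int(r.sum())
    e = np.outer(r, c) / m
    out = np.floor(e).astype(np.int64)
    dr = r - out.sum(axis=1)
    dc = c - out.sum(axis=0)
    frac = e - out
    while dr.sum() > 0:
        admissible = (dr[:, None] > 0) & (dc[None, :] > 0)
        # lexicographic: minimal count, then maximal remainder, then index
        score = np.where(admissible, out - frac / 2.0, np.inf)
        i, j = divmod(int(np.argmin(score)), len(c))
        out[i, j] += 1
        dr[i] -= 1
        dc[j] -= 1
    return out


def h2prime(m: IncidenceMatrix | np.ndarray) -> float:
    """Standardized two-dimensional interaction entropy H2' in [0, 1].

    H2 is the Shannon entropy of the weight matrix normalized by its total;
    H2max / H2min come from marginal-preserving integer fills (independence
    rounding / greedy concentration).  Returns NaN for degenerate matrices
    (fewer than 2 rows or columns, total weight < 2, or H2max == H2min).
    """
    w = m.weights if isinstance(m, IncidenceMatrix) else np.asarray(m, dtype=np.int64)
    if w.shape[0] < 2 or w.shape[1] < 2 or w.sum() < 2:
        return float("nan")
    r = w.sum(axis=1)
    c = w.sum(axis=0)
    h2 = _entropy_nats(w)
    h2_min = _entropy_nats(_h2_min_fill(r, c))
    h2_max = _entropy_nats(_h2_max_fill(r, c))
    if math.isclose(h2_max, h2_min, abs_tol=1e-12):
        return float("nan")
    return float(np.clip((h2_max - h2) / (h2_max - h2_min), 0.0, 1.0))


def network_metrics(
    m: IncidenceMatrix,
    *,
    n_orders: int = 100,
    rng: np.random.Generator | None = None,
    which: tuple[str, ...] = METRIC_NAMES,
) -> NetworkMetrics:
    """Compute the network-level metric set for one incidence matrix."""
    nan = float("nan")
    return NetworkMetrics(
        connectance=connectance(m) if "connectance" in which else nan,
        nodf=nestedness_nodf(m) if "nodf" in which else nan,
        partner_diversity=partner_diversity_plants(m) if "partner_diversity" in which else nan,
        robustness=robustness_dts(m, n_orders=n_orders, rng=rng) if "robustness" in which else nan,
        h2prime=h2prime(m) if "h2prime" in which else nan,
    )


# -- bootstrap ----------------------------------------------------------------


@dataclass
class BootstrapResult:
    quarry_key: tuple[str, str, str]
    sample_size: int
    n_boot: int
    seed: int
    reps: pd.DataFrame  # one row per valid rep, METRIC_NAMES columns
    n_degenerate: int

    def summary(self) -> pd.DataFrame:
        stats_ = self.reps.agg(["mean", "std", lambda s: s.quantile(0.025),
                                "median", lambda s: s.quantile(0.975)])
        stats_.index = ["mean", "sd", "q025", "median", "q975"]
        return stats_


class _QuarrySampler:
    """CSR-style incident layout for fast leaf-subset incidence matrices."""

    def __init__(self, view: Census):
        self.leaf_ids = view.leaves.index.to_numpy()
        self.n_leaves = len(self.leaf_ids)
        taxa = sorted(view.leaves["plant_taxon"].unique())
        dts = sorted(view.incidents["dt_code"].unique()) if not view.incidents.empty else []
        self.taxa = np.array(taxa)
        self.dts = np.array(dts)
        t_of_leaf = view.leaves["plant_taxon"].map({t: i for i, t in enumerate(taxa)})
        leaf_pos = {l: i for i, l in enumerate(self.leaf_ids)}
        inc = view.incidents
        li = inc["leaf_id"].map(leaf_pos).to_numpy() if not inc.empty else np.zeros(0, int)
        order = np.argsort(li, kind="stable")
        self.inc_leaf = li[order]
        self.inc_cell = (
            t_of_leaf.to_numpy()[self.inc_leaf] * max(len(dts), 1)
            + inc["dt_code"].map({d: i for i, d in enumerate(dts)}).to_numpy()[order]
        ) if len(li) else np.zeros(0, int)
        self.inc_count = inc["count"].to_numpy()[order] if len(li) else np.zeros(0, int)
        self.ptr = np.searchsorted(self.inc_leaf, np.arange(self.n_leaves + 1))

    def weights_for(self, leaf_idx: np.ndarray) -> np.ndarray:
        """Dense (taxa x dts) weight matrix for a leaf-index subset."""
        starts, ends = self.ptr[leaf_idx], self.ptr[leaf_idx + 1]
        take = np.concatenate(
            [np.arange(s, e) for s, e in zip(starts, ends)]
        ) if len(leaf_idx) else np.zeros(0, int)
        flat = np.bincount(
            self.inc_cell[take],
            weights=self.inc_count[take],
            minlength=len(self.taxa) * len(self.dts),
        )
        return flat.reshape(len(self.taxa), len(self.dts)).astype(np.int64)


def bootstrap_networks(
    quarry_view: Census,
    sample_size: int = 300,
    n_boot: int = 500,
    seed: int = 0,
    *,
    which: tuple[str, ...] = METRIC_NAMES,
    n_orders: int = 100,
) -> BootstrapResult:
    """Bootstrap-standardized network metrics for one quarry.

    Each rep draws ``sample_size`` leaves without replacement, builds the
    incidence matrix and computes the requested metrics.  Reps whose matrix
    degenerates (fewer than 2 plant rows or 2 DT columns after resampling)
    are recorded and skipped in summaries.  One seed governs both the leaf
    draws and the robustness removal orders.
    """
    N = quarry_view.n_leaves
    if N < sample_size:
        raise CensusValidationError(
            f"quarry has {N} leaves < sample_size={sample_size}"
        )
    keys = quarry_view.quarry_keys
    key = keys[0] if len(keys) == 1 else ("*", "*", "*")
    sampler = _QuarrySampler(quarry_view)
    rng = derive_rng(seed, "bootstrap", *key)
    rows = []
    n_degenerate = 0
    for _ in range(n_boot):
        leaf_idx = rng.choice(N, size=sample_size, replace=False)
        w = sampler.weights_for(leaf_idx)
        keep_r = w.sum(axis=1) > 0
        keep_c = w.sum(axis=0) > 0
        w = w[np.ix_(keep_r, keep_c)]
        if w.shape[0] < 2 or w.shape[1] < 2:
            n_degenerate += 1
            continue
        im = IncidenceMatrix(
            plants=tuple(sampler.taxa[keep_r]),
            dts=tuple(sampler.dts[keep_c]),
            weights=w,
            quarry_key=key,
        )
        rows.append(network_metrics(im, n_orders=n_orders, rng=rng, which=which).as_dict())
    reps = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    return BootstrapResult(
        quarry_key=key, sample_size=sample_size, n_boot=n_boot, seed=seed,
        reps=reps, n_degenerate=n_degenerate,
    )


def degree_profile(
    census: Census, *, drop_singletons: bool = False
) -> pd.DataFrame:
    """DT x quarry table of degrees (# host plant taxa with positive weight).

    Absent DTs get 0.  With ``drop_singletons`` DTs occurring on a single
    leaf within a quarry are zeroed for that quarry.  The first column is the
    DT's FFG annotation.
    """
    from .census import aggregate

    all_dts = sorted(set(census.incidents["dt_code"]))
    cols = {}
    for key, view in aggregate(census, "quarry").items():
        inc = view.incidents.merge(
            view.leaves[["plant_taxon"]], left_on="leaf_id", right_index=True
        )
        if drop_singletons:
            per_leaf = inc.groupby("dt_code")["leaf_id"].nunique()
            inc = inc[inc["dt_code"].map(per_leaf) > 1]
        deg = inc.groupby("dt_code")["plant_taxon"].nunique()
        cols["/".join(key)] = deg
    out = pd.DataFrame(cols, index=all_dts).fillna(0).astype(int)
    out.insert(0, "ffg", [census.catalog.ffg_of(d) for d in out.index])
    out.index.name = "dt_code"
    return out
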