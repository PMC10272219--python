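"""Dissimilarity, ordination and group-difference statistics for quarries.

Quarry compositions are either FFG profiles (fraction of leaves bearing each
functional feeding group — columns need not sum to 1, a leaf can carry
several FFGs) or plant profiles (leaf share per taxon — rows sum to 1).
Bray-Curtis dissimilarity feeds non-metric multidimensional scaling (NMDS,
Kruskal stress-1 with isotonic regression over random restarts) and ANOSIM,
the rank-based permutation test

    R = (mean between-group rank - mean within-group rank) / (N(N-1)/4),

which is exactly 1 when every between-group dissimilarity exceeds every
within-group one.  Rosner's generalized extreme Studentized deviate test
screens quarry-level metric vectors for outliers, and Tukey-Kramer
studentized-range comparisons test forest-level mean differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

from ._rng import derive_rng
from .census import FFGS, Census, CensusValidationError, aggregate

__all__ = [
    "composition_table",
    "bray_curtis",
    "nmds",
    "anosim",
    "rosner_outliers",
    "tukey_hsd",
    "OrdinationResult",
    "AnosimResult",
    "RosnerResult",
]


def composition_table(census: Census, mode: str = "ffg") -> pd.DataFrame:
    """Per-quarry composition profile.

    mode='ffg': fraction of the quarry's leaves bearing >= 1 DT of each FFG.
    mode='plant': leaf share per plant taxon (taxa absent from a quarry are 0).
    Index is 'forest/env/quarry'; metadata columns 'forest' and 'env' come
    first, value columns after.
    """
    if mode not in ("ffg", "plant"):
        raise ValueError(f"mode must be 'ffg' or 'plant', got {mode!r}")
    rows = {}
    meta = {}
    for key, view in aggregate(census, "quarry").items():
        label = "/".join(key)
        meta[label] = {"forest": key[0], "env": key[1]}
        if mode == "ffg":
            from .metrics import damage_frequency

            rows[label] = {ffg: damage_frequency(view, ffg) for ffg in FFGS}
        else:
            shares = view.leaves["plant_taxon"].value_counts(normalize=True)
            rows[label] = shares.to_dict()
    values = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0).sort_index()
    values = values[sorted(values.columns)]
    metadf = pd.DataFrame.from_dict(meta, orient="index").loc[values.index]
    return pd.concat([metadf, values], axis=1)


def _value_columns(table: pd.DataFrame) -> pd.DataFrame:
    return table.drop(columns=[c for c in ("forest", "env") if c in table.columns])


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis dissimilarity matrix between table rows.

    d(x, y) = 1 - 2 sum_c min(x_c, y_c) / sum_c (x_c + y_c).  Rows of all
    zeros yield NaN against every other row (undefined share).
    """
    values = _value_columns(table)
    if len(values) < 2:
        raise CensusValidationError("need >= 2 rows for a dissimilarity matrix")
    x = values.to_numpy(dtype=float)
    d = squareform(pdist(x, metric="braycurtis"))
    zero_rows = np.nonzero(x.sum(axis=1) == 0)[0]
    for i in zero_rows:
        d[i, :] = np.nan
        d[:, i] = np.nan
        d[i, i] = 0.0
    return pd.DataFrame(d, index=values.index, columns=values.index)


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # rows x k
    stress: float  # Kruskal stress-1
    n_restarts: int
    converged: bool
    seed: int


def nmds(
    d: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS on a precomputed dissimilarity matrix.

    Minimizes Kruskal stress-1 with monotone regression on dissimilarity
    ranks; the best of ``n_restarts`` random initializations is returned with
    centered coordinates.
    """
    index = d.index if isinstance(d, pd.DataFrame) else None
    dm = np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, equal_nan=True):
        raise CensusValidationError("NMDS needs a symmetric square dissimilarity matrix")
    if np.isnan(dm).any():
        raise CensusValidationError("dissimilarity matrix contains NaN entries")
    if dm.shape[0] < k + 1:
        raise CensusValidationError(f"need at least {k + 1} points for k={k}")
    best = None
    root = derive_rng(seed, "nmds")
    for _ in range(n_restarts):
        rs = int(root.integers(2**31 - 1))
        try:
            model = MDS(
                n_components=k,
                metric="precomputed",
                metric_mds=False,
                init="random",
                n_init=1,
                max_iter=max_iter,
                eps=tol,
                random_state=rs,
                normalized_stress=True,
            )
        except TypeError:  # sklearn < 1.9 signature
            model = MDS(
                n_components=k,
                metric=False,
                dissimilarity="precomputed",
                n_init=1,
                max_iter=max_iter,
                eps=tol,
                random_state=rs,
                normalized_stress=True,
            )
        coords = model.fit_transform(dm)
        if best is None or model.stress_ < best[0]:
            best = (float(model.stress_), coords, model.n_iter_ < max_iter)
    stress, coords, converged = best
    coords = coords - coords.mean(axis=0)
    cdf = pd.DataFrame(
        coords, index=index, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=cdf, stress=stress, n_restarts=n_restarts,
        converged=converged, seed=seed,
    )


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_perm: int
    grouping: str
    exact: bool = False


def _anosim_r(rank_pairs: np.ndarray, within: np.ndarray, denom: float) -> float:
    rb = rank_pairs[~within].mean()
    rw = rank_pairs[within].mean()
    return (rb - rw) / denom


def anosim(
    d: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    *,
    grouping: str = "groups",
    exact_limit: int = 10_000,
) -> AnosimResult:
    """Analysis of similarities on a precomputed dissimilarity matrix.

    Dissimilarities are ranked with average ranks on ties; R contrasts mean
    between- vs within-group ranks, normalized by N(N-1)/4.  The p-value is
    the fraction of label permutations with R >= observed; all distinct
    arrangements are enumerated when their number is <= ``exact_limit``,
    otherwise ``n_perm`` random permutations are used with the standard
    (1 + hits) / (1 + n_perm) estimate.
    """
    dm = np.asarray(d, dtype=float)
    labels = np.asarray(list(groups))
    N = dm.shape[0]
    if len(labels) != N:
        raise CensusValidationError("group labels must match matrix size")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise CensusValidationError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2].tolist()
        raise CensusValidationError(f"every group needs >= 2 members; too small: {small}")

    iu = np.triu_indices(N, k=1)
    dvec = dm[iu]
    if np.unique(dvec).size == 1:
        return AnosimResult(R=float("nan"), p=float("nan"), n_perm=0, grouping=grouping)
    ranks = stats.rankdata(dvec)  # average ranks on ties
    denom = N * (N - 1) / 4.0
    pairs_i, pairs_j = iu
    within_obs = labels[pairs_i] == labels[pairs_j]
    r_obs = _anosim_r(ranks, within_obs, denom)

    n_arrangements = math.factorial(N)
    for c in counts:
        n_arrangements //= math.factorial(c)
    if n_arrangements <= exact_limit:
        from sympy.utilities.iterables import multiset_permutations

        hits = total = 0
        for perm in multiset_permutations(list(labels)):
            pl = np.asarray(perm)
            w = pl[pairs_i] == pl[pairs_j]
            if _anosim_r(ranks, w, denom) >= r_obs - 1e-12:
                hits += 1
            total += 1
        return AnosimResult(
            R=float(r_obs), p=hits / total, n_perm=total, grouping=grouping, exact=True
        )

    if n_perm <= 0:
        return AnosimResult(R=float(r_obs), p=float("nan"), n_perm=0, grouping=grouping)
    rng = derive_rng(seed, "anosim", grouping)
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    w = perms[:, pairs_i] == perms[:, pairs_j]  # (n_perm, n_pairs)
    n_within = w.sum(axis=1)
    sum_within = (w * ranks).sum(axis=1)
    total_sum = ranks.sum()
    rw = sum_within / n_within
    rb = (total_sum - sum_within) / (len(ranks) - n_within)
    r_perm = (rb - rw) / denom
    hits = int(np.sum(r_perm >= r_obs - 1e-12))
    return AnosimResult(
        R=float(r_obs), p=(1 + hits) / (1 + n_perm), n_perm=n_perm, grouping=grouping
    )


@dataclass(frozen=True)
class RosnerResult:
    outliers: list[int]  # indices into the input sample
    trace: pd.DataFrame  # one row per tested candidate: R_i, lambda_i, flagged
    note: str = ""


def rosner_outliers(x, k_max: int = 3, alpha: float = 0.05) -> RosnerResult:
    """Rosner's generalized extreme Studentized deviate (GESD) test.

    Iteratively removes the value farthest from the current mean, computing
    R_i = max|x - mean| / sd against the critical value

        lambda_i = (n - i) t_{p, n-i-1} / sqrt((n-i-1+t^2)(n-i+1)),

    p = 1 - alpha / (2 (n - i + 1)).  The declared outliers are the largest
    prefix i with R_i > lambda_i.  Constant input yields no outliers with a
    diagnostic note.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < k_max + 3:
        raise CensusValidationError(f"need n >= k_max + 3 = {k_max + 3}, got {n}")
    if np.std(x, ddof=1) == 0:
        return RosnerResult(outliers=[], trace=pd.DataFrame(), note="zero variance")
    remaining = list(range(n))
    rows = []
    candidates = []
    for i in range(1, k_max + 1):
        vals = x[remaining]
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(vals - mu)
        local = int(np.argmax(dev))
        idx = remaining[local]
        R_i = dev[local] / sd
        ni = len(remaining)
        p = 1 - alpha / (2 * ni)
        t = stats.t.ppf(p, ni - 2)
        lam = (ni - 1) * t / math.sqrt((ni - 2 + t**2) * ni)
        rows.append({"i": i, "index": idx, "value": x[idx], "R": R_i,
                     "lambda": lam, "exceeds": R_i > lam})
        candidates.append(idx)
        remaining.pop(local)
    trace = pd.DataFrame(rows)
    n_out = 0
    for i in range(len(rows) - 1, -1, -1):
        if rows[i]["exceeds"]:
            n_out = i + 1
            break
    return RosnerResult(outliers=candidates[:n_out], trace=trace)


def tukey_hsd(values: dict[str, np.ndarray] | pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer studentized-range comparisons of group means.

    ``values`` maps group label -> 1-D sample (or a Series with a group
    index).  Pooled within-group variance with the unbalanced-size
    correction; returns one row per unordered pair with the mean difference,
    q statistic, adjusted p and a significance flag at ``alpha``.
    """
    if isinstance(values, pd.Series):
        values = {g: s.to_numpy() for g, s in values.groupby(level=0)}
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise CensusValidationError("Tukey needs >= 2 groups with >= 2 values each")
    k = len(groups)
    n_tot = sum(len(v) for v in groups.values())
    df = n_tot - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    if sse == 0:
        raise CensusValidationError("zero within-group variance everywhere")
    ms_within = sse / df
    rows = []
    for (ga, va), (gb, vb) in combinations(groups.items(), 2):
        diff = va.mean() - vb.mean()
        se = math.sqrt(ms_within / 2 * (1 / len(va) + 1 / len(vb)))
        q = abs(diff) / se
        p_adj = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group_a": ga, "group_b": gb, "diff": diff, "q": q,
                     "p_adj": p_adj, "significant": p_adj < alpha})
    return pd.DataFrame(rows)
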