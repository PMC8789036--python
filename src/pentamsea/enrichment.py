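"""Preranked motif set enrichment: ES, permutation null, NES, FDR, leading edge.

Given pentamers ranked by ΔPSI (descending), each motif set is scored with
the weighted Kolmogorov–Smirnov running-sum statistic: walking down the
ranking, set members ("hits") increment the sum by |metric|^p normalized by
the total hit weight, non-members decrement it by 1/(N − m).  The
enrichment score (ES) is the running-sum value of maximal absolute
deviation; a positive ES means the feature concentrates among stimulatory
(ΔPSI > 0) pentamers, a negative ES among inhibitory ones.

The null distribution is built from random member subsets of matched size
(the only permutation scheme compatible with a preranked list).  NES
divides ES by the mean |null ES| of the same sign; nominal p is the
same-sign null tail fraction with a +1/(n+1) continuity correction; the FDR
q-value follows the sign-stratified scheme of preranked GSEA (pooled
normalized null NES tail over observed NES tail, clipped to [0, 1]).
Benjamini–Hochberg is deliberately not used.

Leading-edge statistics: ``tags`` is the fraction of set members at or
before (after, for negative ES) the running-sum peak, ``list`` the fraction
of the ranking traversed to reach the peak, and
``signal = tags · (1 − list) · N/(N − m)``, clipped to [0, 1].

A set is called significant when FDR q < 0.05 and list < 50% (both strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .library import LibraryContext
from .psi import compute_delta_psi, make_ranked_list
from .sets import MotifSetCollection

DEFAULT_N_PERM = 1000
DEFAULT_SEED = 17
FDR_THRESHOLD = 0.05
LIST_THRESHOLD = 0.5


def _hit_weights(metric: np.ndarray, hit_idx: np.ndarray, p: float) -> np.ndarray:
    """|metric|^p at the hit positions; falls back to p=0 (unweighted) when
    every member's metric is zero, so the running sum stays well defined."""
    w = np.abs(metric[hit_idx]) ** p if p != 0 else np.ones(hit_idx.shape)
    if w.sum(axis=-1, keepdims=True).min() == 0:
        w = np.where(w.sum(axis=-1, keepdims=True) == 0, 1.0, w)
    return w


def _es_batch(metric: np.ndarray, hits: np.ndarray, p: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ES for a batch of same-size hit-index sets.

    ``hits``: (B, m) integer array of 0-based rank indices, sorted per row.
    Returns (es, peak_rank) with 1-based peak ranks.  The running-sum
    extremes can only occur immediately after a hit (candidate maxima) or
    immediately before one (candidate minima), so only hit positions need
    inspection.
    """
    B, m = hits.shape
    N = metric.shape[0]
    if not (1 <= m < N):
        raise ValueError(f"set size must be in [1, {N - 1}], got {m}")
    w = _hit_weights(metric, hits, p)
    cumw = np.cumsum(w, axis=1)
    nr = cumw[:, -1:]
    ranks = hits + 1                                   # 1-based hit ranks
    k = np.arange(1, m + 1)
    miss_step = 1.0 / (N - m)
    p_hit_after = cumw / nr
    p_hit_before = np.concatenate([np.zeros((B, 1)), cumw[:, :-1]], axis=1) / nr
    dev_after = p_hit_after - (ranks - k) * miss_step
    dev_before = p_hit_before - (ranks - k) * miss_step
    i_max = np.argmax(dev_after, axis=1)
    i_min = np.argmin(dev_before, axis=1)
    rows = np.arange(B)
    es_pos = dev_after[rows, i_max]
    es_neg = dev_before[rows, i_min]
    take_pos = es_pos >= -es_neg - 1e-12               # tie goes to the maximum
    es = np.where(take_pos, es_pos, es_neg)
    peak = np.where(take_pos, ranks[rows, i_max], ranks[rows, i_min] - 1)
    return es, peak


def enrichment_score(ranked: pd.Series, members, weight_exponent: float = 1.0,
                     return_running_sum: bool = False):
    """Weighted-KS enrichment score of one motif set against a ranking.

    Parameters
    ----------
    ranked : pd.Series
        Metric values indexed by pentamer, already sorted descending.
    members : iterable of str
        The motif set; must be a non-empty proper subset of the ranking.

    Returns
    -------
    (es, peak_rank) or (es, peak_rank, running_sum)
    """
    members = set(getattr(members, "members", members))
    N = len(ranked)
    if not members:
        raise ValueError("empty motif set cannot be scored")
    if len(members) >= N:
        raise ValueError("motif set must be a proper subset of the ranking")
    missing = members - set(ranked.index)
    if missing:
        raise ValueError(f"set members absent from ranking: {sorted(missing)[:5]}")
    metric = ranked.to_numpy(dtype=float)
    hit_idx = np.flatnonzero(ranked.index.isin(members))
    es, peak = _es_batch(metric, hit_idx[None, :], weight_exponent)
    es, peak = float(es[0]), int(peak[0])
    if not return_running_sum:
        return es, peak
    # explicit O(N) walk, for diagnostics/plots
    w = _hit_weights(metric, hit_idx[None, :], weight_exponent)[0]
    rs = np.empty(N)
    hit_mask = np.zeros(N, bool)
    hit_mask[hit_idx] = True
    steps = np.where(hit_mask, 0.0, -1.0 / (N - len(members)))
    steps[hit_idx] = w / w.sum()
    rs = np.cumsum(steps)
    return es, peak, rs


def sample_null(ranked: pd.Series, set_size: int, n_perm: int = DEFAULT_N_PERM,
                rng: np.random.Generator | int | None = None,
                weight_exponent: float = 1.0) -> np.ndarray:
    """Null ES sample: ES of ``n_perm`` uniformly random member subsets of
    the given size (without replacement).  Deterministic under a fixed rng."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    N = len(ranked)
    if not (1 <= set_size < N):
        raise ValueError(f"set size must be in [1, {N - 1}], got {set_size}")
    rng = np.random.default_rng(rng)
    metric = ranked.to_numpy(dtype=float)
    out = []
    for start in range(0, n_perm, 2000):
        b = min(2000, n_perm - start)
        keys = rng.random((b, N))
        hits = np.sort(np.argpartition(keys, set_size, axis=1)[:, :set_size], axis=1)
        es, _ = _es_batch(metric, hits, weight_exponent)
        out.append(es)
    return np.concatenate(out)


def leading_edge(ranked: pd.Series, members, peak_rank: int, es_sign: int
                 ) -> tuple[float, float, float]:
    """Leading-edge (tags, list, signal) for a scored set."""
    members = set(getattr(members, "members", members))
    N = len(ranked)
    m = len(members)
    ranks = np.flatnonzero(ranked.index.isin(members)) + 1
    if es_sign >= 0:
        tags = float((ranks <= peak_rank).sum()) / m
        lst = peak_rank / N
    else:
        tags = float((ranks >= peak_rank).sum()) / m
        lst = (N - peak_rank + 1) / N
    signal = min(1.0, max(0.0, tags * (1.0 - lst) * N / (N - m)))
    return tags, lst, signal


def _same_sign_stats(null: np.ndarray) -> tuple[float, float, int, int]:
    pos = null[null > 0]
    neg = null[null < 0]
    pos_mean = float(pos.mean()) if pos.size else np.nan
    neg_mean = float(np.abs(neg).mean()) if neg.size else np.nan
    return pos_mean, neg_mean, pos.size, neg.size


def normalize_and_fdr(results: pd.DataFrame, nulls: dict[int, np.ndarray]
                      ) -> pd.DataFrame:
    """Fill nes, p_nominal and fdr_q from size-matched null ES samples.

    ``results`` must carry columns ``es`` and ``size``; ``nulls`` maps set
    size to its null ES array.  Sets with no same-sign null draws get an
    undefined (NaN) NES and are excluded from significance downstream.
    """
    out = results.copy()
    nes = np.full(len(out), np.nan)
    p_nom = np.full(len(out), np.nan)
    size_stats = {s: _same_sign_stats(a) for s, a in nulls.items()}
    for i, (es, size) in enumerate(zip(out["es"], out["size"])):
        null = nulls[size]
        pos_mean, neg_mean, n_pos, n_neg = size_stats[size]
        if es > 0:
            if n_pos == 0:
                continue
            nes[i] = es / pos_mean
            p_nom[i] = (1 + (null[null > 0] >= es).sum()) / (1 + n_pos)
        elif es < 0:
            if n_neg == 0:
                continue
            nes[i] = es / neg_mean
            p_nom[i] = (1 + (null[null < 0] <= es).sum()) / (1 + n_neg)
        else:
            nes[i] = 0.0
            p_nom[i] = 1.0
    out["nes"] = nes
    out["p_nominal"] = p_nom

    # pooled normalized null NES: each scored set contributes its size's
    # null sample, normalized by that size's same-sign null means
    pooled = []
    for size in out["size"]:
        null = nulls[size]
        pos_mean, neg_mean, _, _ = size_stats[size]
        norm = np.where(null > 0,
                        null / pos_mean if np.isfinite(pos_mean) else np.nan,
                        null / neg_mean if np.isfinite(neg_mean) else np.nan)
        pooled.append(norm[np.isfinite(norm)])
    pooled = np.concatenate(pooled) if pooled else np.array([])

    obs = out["nes"].to_numpy()
    fdr = np.full(len(out), np.nan)
    n_pool = pooled.size
    for i, v in enumerate(obs):
        if not np.isfinite(v):
            continue
        if v > 0:
            null_frac = (pooled >= v).sum() / max((pooled > 0).sum(), 1)
            obs_frac = (obs[np.isfinite(obs)] >= v).sum() / max(
                (obs[np.isfinite(obs)] > 0).sum(), 1)
        elif v < 0:
            null_frac = (pooled <= v).sum() / max((pooled < 0).sum(), 1)
            obs_frac = (obs[np.isfinite(obs)] <= v).sum() / max(
                (obs[np.isfinite(obs)] < 0).sum(), 1)
        else:
            fdr[i] = 1.0
            continue
        fdr[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else 1.0
    out["fdr_q"] = fdr
    return out


class MSEA(BaseEstimator):
    """Preranked motif set enrichment analysis, sklearn-estimator style.

    Parameters
    ----------
    n_permutations : int
        Null subsets drawn per distinct set size.
    weight_exponent : float
        p of the weighted-KS statistic (1 = weighted, 0 = classical KS).
    fdr_threshold, list_threshold : float
        Significance calls require fdr_q < fdr_threshold and
        list < list_threshold (both strict).
    random_state : int
        Seed of the permutation generator; fixed seed gives byte-identical
        result tables.

    Attributes
    ----------
    results_ : pd.DataFrame
        One row per scored set, sorted by NES descending, with columns
        set_id, layer, size, es, nes, p_nominal, fdr_q, tags, list, signal,
        peak_rank, significant.
    ranking_ : pd.Series
        The ranking the sets were scored against.
    null_distributions_ : dict[int, np.ndarray]
        Null ES sample per set size.
    """

    def __init__(self, n_permutations: int = DEFAULT_N_PERM,
                 weight_exponent: float = 1.0,
                 fdr_threshold: float = FDR_THRESHOLD,
                 list_threshold: float = LIST_THRESHOLD,
                 random_state: int = DEFAULT_SEED):
        self.n_permutations = n_permutations
        self.weight_exponent = weight_exponent
        self.fdr_threshold = fdr_threshold
        self.list_threshold = list_threshold
        self.random_state = random_state

    def fit(self, ranked: pd.Series, sets: MotifSetCollection) -> "MSEA":
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rows = []
        for s in sets:
            es, peak = enrichment_score(ranked, s, self.weight_exponent)
            rows.append({"set_id": s.set_id, "layer": s.layer, "size": s.size,
                         "es": es, "peak_rank": peak})
        res = pd.DataFrame(rows)
        if res.empty:
            raise ValueError("no motif sets to score")

        ss = np.random.SeedSequence(self.random_state)
        sizes = sorted(res["size"].unique())
        children = ss.spawn(len(sizes))
        nulls = {size: sample_null(ranked, size, self.n_permutations,
                                   np.random.default_rng(child),
                                   self.weight_exponent)
                 for size, child in zip(sizes, children)}
        res = normalize_and_fdr(res, nulls)

        by_id = sets.by_id()
        led = [leading_edge(ranked, by_id[sid], pk, 1 if es >= 0 else -1)
               for sid, pk, es in zip(res["set_id"], res["peak_rank"], res["es"])]
        res[["tags", "list", "signal"]] = pd.DataFrame(led, index=res.index)
        res["significant"] = (
            np.isfinite(res["nes"])
            & (res["fdr_q"] < self.fdr_threshold)
            & (res["list"] < self.list_threshold)
        )
        res = res.sort_values(["nes", "set_id"], ascending=[False, True],
                              na_position="last", kind="mergesort")
        cols = ["set_id", "layer", "size", "es", "nes", "p_nominal", "fdr_q",
                "tags", "list", "signal", "peak_rank", "significant"]
        self.results_ = res[cols].reset_index(drop=True)
        self.ranking_ = ranked
        self.null_distributions_ = nulls
        return self

    def significant_sets(self) -> pd.DataFrame:
        return self.results_[self.results_["significant"]]


def run_msea(psi_matrix: pd.DataFrame, sets: MotifSetCollection,
             n_perm: int = DEFAULT_N_PERM, seed: int = DEFAULT_SEED,
             weight_exponent: float = 1.0,
             ctx: LibraryContext | None = None) -> pd.DataFrame:
    """End-to-end enrichment: PSI matrix → ΔPSI → ranking → scored sets."""
    delta = compute_delta_psi(psi_matrix, ctx)
    ranked = make_ranked_list(delta)
    est = MSEA(n_permutations=n_perm, random_state=seed,
               weight_exponent=weight_exponent)
    est.fit(ranked, sets)
    return est.results_


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")
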