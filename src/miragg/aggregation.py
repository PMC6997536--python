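"""Rank normalization, imputation and aggregation of prediction lists.

Each prediction source ranks a (partially overlapping) set of miRNA::mRNA
interactions.  Ranks are made comparable across sources by converting them to
*normalized relative ranks*: an item's (mid)rank within one source divided by
that source's list length, so the worst untied item in a source sits at 1.0.
An interaction a source never listed is imputed at the maximum relative rank,
1.0 — i.e. "missing" is treated as "ranked last".

The resulting items x sources matrix of values in (0, 1] is summarized per
interaction with a selectable aggregation function:

``mean`` / ``median`` / ``min`` / ``geomean``
    elementary row summaries of the normalized ranks;
``rra``
    the robust order-statistic score: under the null that a row is n
    independent Uniform(0, 1) draws, the k-th smallest entry follows
    Beta(k, n - k + 1); the score is the smallest of the n beta CDF
    p-values, Bonferroni-corrected by a factor n and capped at 1;
``stuart``
    the exact joint null probability that every order statistic of the row
    is at most its observed value, computed by an alternating recursion.

All scores are oriented lower-is-better, and the aggregated list is reranked
ascending by score with a deterministic tie-break.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "LOWER",
    "HIGHER",
    "AGGREGATION_METHODS",
    "SourceList",
    "RankMatrix",
    "build_rank_matrix",
    "aggregate",
    "beta_scores",
    "rra_rho",
    "stuart_q",
    "bates_cdf",
    "filter_by_threshold",
]

#: direction flag: small raw score = strong prediction (e.g. an energy or p-value)
LOWER = "better-is-lower"
#: direction flag: large raw score = strong prediction (e.g. a probability)
HIGHER = "better-is-higher"

_DIRECTION_ALIASES = {
    LOWER: LOWER,
    HIGHER: HIGHER,
    "lower": LOWER,
    "higher": HIGHER,
    "asc": LOWER,
    "desc": HIGHER,
}

_METHOD_ALIASES = {
    "mean": "mean",
    "median": "median",
    "min": "min",
    "geomean": "geomean",
    "geometric_mean": "geomean",
    "stuart": "stuart",
    "rra": "rra",
    "rra_default": "rra",
    "default": "rra",
}

AGGREGATION_METHODS = ("mean", "median", "min", "geomean", "stuart", "rra")

KEY_COLUMNS = ["mirna", "gene"]


@dataclass
class SourceList:
    """One predictor's scored miRNA::mRNA interactions.

    Parameters
    ----------
    name:
        Identifier of the source (used for per-source rank columns).
    entries:
        DataFrame with columns ``mirna``, ``gene``, ``score``; one row per
        interaction, no duplicates.
    direction:
        ``"better-is-lower"`` or ``"better-is-higher"``: how raw scores
        order the list.
    """

    name: str
    entries: pd.DataFrame
    direction: str = LOWER

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("source name must be non-empty")
        try:
            self.direction = _DIRECTION_ALIASES[self.direction]
        except KeyError:
            raise ValueError(f"unknown direction {self.direction!r}") from None
        missing = [c for c in KEY_COLUMNS + ["score"] if c not in self.entries.columns]
        if missing:
            raise ValueError(f"source {self.name!r} lacks columns {missing}")
        if len(self.entries) == 0:
            raise ValueError(f"source {self.name!r} is empty")
        scores = np.asarray(self.entries["score"], dtype=float)
        if not np.all(np.isfinite(scores)):
            raise ValueError(f"source {self.name!r} contains non-finite scores")
        dup = self.entries.duplicated(KEY_COLUMNS)
        if dup.any():
            first = self.entries.loc[dup, KEY_COLUMNS].iloc[0]
            raise ValueError(
                f"source {self.name!r} has duplicate interaction "
                f"({first['mirna']}, {first['gene']})"
            )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class RankMatrix:
    """Interactions x sources matrix of normalized relative ranks.

    ``r[i, j]`` is in (0, 1]; cells of interactions absent from source ``j``
    are exactly 1.0.  ``raw_rank`` holds the within-source midranks (NaN for
    absent interactions) so aggregated output can display each source's own
    rank, as in a per-database rank table.
    """

    items: pd.MultiIndex
    sources: list[str]
    r: np.ndarray
    raw_rank: np.ndarray

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.raw_rank)


def build_rank_matrix(
    sources: Sequence[SourceList],
    universe_size: int | None = None,
) -> RankMatrix:
    """Normalize every source's ranks and assemble the imputed rank matrix.

    Within each source, entries are ordered best-to-worst according to the
    source's direction, tied raw scores receive midranks, and ranks are
    divided by the source's own list length (or by ``universe_size`` when
    given, the convention where all lists share one denominator).  Items a
    source does not list are imputed at the maximum relative rank, 1.0.
    """
    if len(sources) == 0:
        raise ValueError("at least one source is required")
    names = [s.name for s in sources]
    if len(set(names)) != len(names):
        raise ValueError("source names must be unique")
    if universe_size is not None and universe_size < max(len(s) for s in sources):
        raise ValueError("universe_size smaller than a source's list length")

    frames = [s.entries[KEY_COLUMNS] for s in sources]
    universe = (
        pd.concat(frames, ignore_index=True)
        .drop_duplicates()
        .sort_values(KEY_COLUMNS, kind="mergesort")
    )
    items = pd.MultiIndex.from_frame(universe, names=KEY_COLUMNS)
    pos = pd.Series(np.arange(len(items)), index=items)

    n, k = len(items), len(sources)
    r = np.ones((n, k), dtype=float)
    raw = np.full((n, k), np.nan)
    for j, src in enumerate(sources):
        scores = np.asarray(src.entries["score"], dtype=float)
        if src.direction == HIGHER:
            scores = -scores
        midrank = stats.rankdata(scores, method="average")
        denom = float(universe_size) if universe_size is not None else float(len(src))
        idx = pos.loc[pd.MultiIndex.from_frame(src.entries[KEY_COLUMNS])].to_numpy()
        r[idx, j] = midrank / denom
        raw[idx, j] = midrank
    return RankMatrix(items=items, sources=list(names), r=r, raw_rank=raw)


def _check_row(row: np.ndarray, n: int) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    if row.ndim != 1 or len(row) != n or n < 1:
        raise ValueError("row must be a 1-d sequence of length n >= 1")
    if np.any(row <= 0) or np.any(row > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    if np.any(np.diff(row) < 0):
        raise ValueError("row must be sorted ascending")
    return row


def beta_scores(row: Sequence[float], n: int | None = None) -> np.ndarray:
    """Per-order-statistic null p-values for a sorted row of normalized ranks.

    Under the null that the ``n`` normalized ranks are independent
    Uniform(0, 1), the k-th smallest follows Beta(k, n - k + 1); the k-th
    returned value is that distribution's CDF at the observed k-th rank.
    """
    if n is None:
        n = len(row)
    row = _check_row(row, n)
    k = np.arange(1, n + 1, dtype=float)
    return special.betainc(k, n - k + 1, row)


def rra_rho(row: Sequence[float], n: int | None = None) -> float:
    """Robust rank aggregation score: Bonferroni-corrected minimum beta p-value.

    ``rho`` is the smallest of the ``n`` order-statistic p-values; the score
    is ``min(rho * n, 1)``, correcting for taking the best of n order
    statistics.  Lower = stronger consensus.
    """
    if n is None:
        n = len(row)
    rho = float(np.min(beta_scores(row, n)))
    return min(rho * n, 1.0)


def stuart_q(row: Sequence[float], n: int | None = None) -> float:
    """Joint null probability that all order statistics are <= their observed values.

    For ``n`` independent uniforms with sorted observed values r_(1) <= ... <=
    r_(n), computes ``q = P(R_(1) <= r_(1), ..., R_(n) <= r_(n))`` by the
    alternating recursion

        v_0 = 1;  v_k = sum_{i=1..k} (-1)^(i-1) v_{k-i} r_(n-k+1)^i / i!

    with ``q = n! * v_n``.  Exact floating-point arithmetic is adequate for
    the handful of sources aggregated here (n well below ~15, where n! and
    the alternating sum stay benign).
    """
    if n is None:
        n = len(row)
    row = _check_row(row, n)
    v = np.zeros(n + 1)
    v[0] = 1.0
    for k in range(1, n + 1):
        x = row[n - k]
        terms = 0.0
        p = 1.0  # running x^i / i!
        for i in range(1, k + 1):
            p *= x / i
            terms += (-1) ** (i - 1) * v[k - i] * p
        v[k] = terms
    return float(math.factorial(n) * v[n])


def _rra_rows(r_sorted: np.ndarray) -> np.ndarray:
    n = r_sorted.shape[1]
    k = np.arange(1, n + 1, dtype=float)
    p = special.betainc(k[None, :], (n - k + 1)[None, :], r_sorted)
    return np.minimum(p.min(axis=1) * n, 1.0)


def _stuart_rows(r_sorted: np.ndarray) -> np.ndarray:
    n = r_sorted.shape[1]
    v = [np.ones(r_sorted.shape[0])]
    for k in range(1, n + 1):
        x = r_sorted[:, n - k]
        acc = np.zeros(r_sorted.shape[0])
        xp = np.ones_like(x)  # running x^i / i!
        for i in range(1, k + 1):
            xp = xp * x / i
            acc += (-1) ** (i - 1) * v[k - i] * xp
        v.append(acc)
    return math.factorial(n) * v[n]


def bates_cdf(mean_rank: np.ndarray | float, n: int) -> np.ndarray | float:
    """CDF of the mean of ``n`` independent uniforms (Bates distribution).

    A monotone transform of the mean normalized rank into a null p-value:
    ranking by ``bates_cdf(mean, n)`` is identical to ranking by the mean
    itself.
    """
    x = np.asarray(mean_rank, dtype=float)
    s = np.clip(x, 0.0, 1.0) * n
    out = np.zeros_like(s)
    for k in range(0, n + 1):
        term = (-1.0) ** k * special.comb(n, k) * np.clip(s - k, 0.0, None) ** n
        out += term
    out /= math.factorial(n)
    result = np.clip(out, 0.0, 1.0)
    return float(result) if np.isscalar(mean_rank) else result


def aggregate(
    matrix: RankMatrix,
    method: str = "mean",
) -> pd.DataFrame:
    """Aggregate the rank matrix into a single reranked, scored list.

    Returns a DataFrame sorted best-to-worst with columns ``mirna``,
    ``gene``, ``score`` (lower = better), ``rank`` (1 = best),
    ``n_sources`` (sources actually listing the interaction) and one
    ``rank_<source>`` column per source holding that source's own midrank
    (NaN when absent).  Equal scores are ordered by more sources present
    first, then lexicographically by (mirna, gene), so output is
    deterministic.
    """
    try:
        method = _METHOD_ALIASES[method]
    except KeyError:
        raise ValueError(
            f"unknown aggregation method {method!r}; expected one of {AGGREGATION_METHODS}"
        ) from None

    r = matrix.r
    if method == "mean":
        score = r.mean(axis=1)
    elif method == "median":
        score = np.median(r, axis=1)
    elif method == "min":
        score = r.min(axis=1)
    elif method == "geomean":
        score = np.exp(np.log(r).mean(axis=1))
    elif method == "rra":
        score = _rra_rows(np.sort(r, axis=1))
    elif method == "stuart":
        score = _stuart_rows(np.sort(r, axis=1))

    out = matrix.items.to_frame(index=False)
    out["score"] = score
    out["n_sources"] = matrix.present_mask().sum(axis=1)
    out["_neg_n"] = -out["n_sources"]
    out = out.sort_values(
        ["score", "_neg_n", "mirna", "gene"], kind="mergesort"
    ).drop(columns="_neg_n")
    out["rank"] = np.arange(1, len(out) + 1)
    order = np.asarray(
        pd.Series(np.arange(matrix.n_items), index=matrix.items).loc[
            pd.MultiIndex.from_frame(out[KEY_COLUMNS])
        ]
    )
    for j, name in enumerate(matrix.sources):
        out[f"rank_{name}"] = matrix.raw_rank[order, j]
    cols = KEY_COLUMNS + ["score", "rank", "n_sources"] + [
        f"rank_{name}" for name in matrix.sources
    ]
    return out[cols].reset_index(drop=True)


def filter_by_threshold(results: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep interactions whose aggregated score is at most ``threshold``.

    A cutoff of 0.05 on the aggregated score is the recommended working
    threshold for shortlisting candidate targets; 1.0 keeps everything.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    return results[results["score"] <= threshold].reset_index(drop=True)
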