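"""Replicate benchmarking of competing rankings on a shared interaction set.

The protocol mirrors the standard evaluation design for comparing target
predictors: build the set of interactions *common* to every compared method,
attach validated/unvalidated labels, draw several label-stratified random
subsets ("replicates"), evaluate every method on every replicate, and test
for differences with a repeated-measures one-way ANOVA (replicates are the
subjects, methods the within-subject factor) followed by Dunnett's
many-to-one post-test against a designated control method, or a paired
Student t-test when only two methods are compared.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import DEFAULT_FRACTIONS, EvalSummary, evaluate

__all__ = [
    "BenchmarkSet",
    "ReplicateSpec",
    "PAPER_SCALE_SPEC",
    "intersect_common",
    "attach_labels",
    "subsample_replicates",
    "evaluate_all",
    "summarize_metrics",
    "rm_anova",
    "AnovaResult",
    "dunnett_posthoc",
    "paired_ttest",
    "run_benchmark",
    "run_synthetic_comparison",
    "format_mean_sd",
]


@dataclass
class BenchmarkSet:
    """Interactions common to all compared methods, with scores and labels.

    ``scores`` is indexed by (mirna, gene) with one lower-is-better score
    column per method; ``labels`` aligns 1:1 with the rows.
    """

    scores: pd.DataFrame
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.scores):
            raise ValueError("labels must align 1:1 with interactions")

    @property
    def methods(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def prevalence(self) -> float:
        return float(self.labels.mean())

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class ReplicateSpec:
    """How many stratified subsets to draw, how large, and from which seed."""

    n_replicates: int = 10
    subset_size: int = 50_000
    seed: int = 0
    prevalence_target: float | None = None  # None: inherit the parent's

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")


#: the configuration used for comparing aggregation functions on aggregated
#: data: one million interactions, 5% of them validated
PAPER_SCALE_SPEC = ReplicateSpec(n_replicates=10, subset_size=1_000_000, prevalence_target=0.05)


def intersect_common(
    scored: dict[str, pd.DataFrame],
    labels: pd.DataFrame | None = None,
) -> BenchmarkSet:
    """Keep exactly the interactions present in every scored list.

    ``scored`` maps a method name to a (mirna, gene, score) DataFrame.
    An empty intersection is reported with a warning, not an error.
    """
    if len(scored) < 2:
        raise ValueError("need at least two scored lists to intersect")
    merged: pd.DataFrame | None = None
    for name, df in scored.items():
        part = df[["mirna", "gene", "score"]].rename(columns={"score": name})
        merged = part if merged is None else merged.merge(part, on=["mirna", "gene"], how="inner")
    merged = merged.sort_values(["mirna", "gene"], kind="mergesort").reset_index(drop=True)
    if len(merged) == 0:
        warnings.warn("intersection of scored lists is empty", stacklevel=2)
    scores = merged.set_index(["mirna", "gene"])
    lab = np.zeros(len(scores), dtype=int)
    bs = BenchmarkSet(scores=scores, labels=lab, provenance={"parent": "intersection"})
    if labels is not None:
        bs = attach_labels(bs, labels)
    return bs


def attach_labels(bs: BenchmarkSet, validated: pd.DataFrame) -> BenchmarkSet:
    """Label each interaction 1 if it appears in the validated-pair table."""
    pairs = pd.MultiIndex.from_frame(validated[["mirna", "gene"]])
    lab = bs.scores.index.isin(pairs).astype(int)
    return BenchmarkSet(scores=bs.scores, labels=lab, provenance=dict(bs.provenance))


def subsample_replicates(parent: BenchmarkSet, spec: ReplicateSpec) -> list[BenchmarkSet]:
    """Draw label-stratified random subsets whose prevalence matches the parent.

    Each replicate is drawn without replacement with the number of positives
    fixed at ``round(subset_size * prevalence)`` (parent prevalence unless
    ``prevalence_target`` overrides it), so replicate prevalence matches the
    target to the nearest integer count.  Replicate ``i`` uses the
    independent seed stream ``(spec.seed, i)``; the derived seed pair is
    recorded in each replicate's provenance.
    """
    n = len(parent)
    if spec.subset_size > n:
        raise ValueError(f"subset_size {spec.subset_size} exceeds parent size {n}")
    prevalence = parent.prevalence if spec.prevalence_target is None else spec.prevalence_target
    n_pos = int(round(spec.subset_size * prevalence))
    pos_idx = np.flatnonzero(parent.labels == 1)
    neg_idx = np.flatnonzero(parent.labels == 0)
    if n_pos > len(pos_idx) or spec.subset_size - n_pos > len(neg_idx):
        raise ValueError("parent does not contain enough items of each label")
    out = []
    for i in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, i])
        take_pos = rng.choice(pos_idx, size=n_pos, replace=False)
        take_neg = rng.choice(neg_idx, size=spec.subset_size - n_pos, replace=False)
        take = np.sort(np.concatenate([take_pos, take_neg]))
        out.append(
            BenchmarkSet(
                scores=parent.scores.iloc[take],
                labels=parent.labels[take],
                provenance={
                    "parent": parent.provenance.get("parent", "parent"),
                    "replicate": i,
                    "seed": [spec.seed, i],
                },
            )
        )
    return out


def evaluate_all(
    replicates: list[BenchmarkSet],
    fractions=DEFAULT_FRACTIONS,
    spec_min: float = 0.9,
) -> pd.DataFrame:
    """Evaluate every method on every replicate.

    Returns a long DataFrame with one row per (replicate, method) carrying
    every metric of :class:`~miragg.evaluation.EvalSummary`.
    """
    if len(replicates) == 0:
        raise ValueError("need at least one replicate")
    methods = replicates[0].methods
    rows = []
    for i, rep in enumerate(replicates):
        for m in methods:
            if m not in rep.scores.columns:
                raise ValueError(f"method {m!r} missing from replicate {i}")
            summ = evaluate(
                rep.scores[m].to_numpy(), rep.labels, fractions=fractions, spec_min=spec_min
            )
            row = {"replicate": i, "method": m}
            row.update(summ.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean and SD of each metric over replicates."""
    metric_cols = [c for c in table.columns if c not in ("replicate", "method")]
    agg = table.groupby("method", sort=False)[metric_cols].agg(["mean", "std"])
    agg.columns = [f"{metric}_{stat}" for metric, stat in agg.columns]
    return agg


def format_mean_sd(mean: float, sd: float, digits: int = 4) -> str:
    return f"{mean:.{digits}f} ± {sd:.{digits}f}"


@dataclass
class AnovaResult:
    F: float
    p: float
    df_method: int
    df_error: int
    degenerate: bool = False


def rm_anova(metric_table: pd.DataFrame | np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a replicates x methods matrix.

    Replicates are the subjects; the method effect is tested against the
    method x subject interaction: ``F = MS_method / MS_error`` with
    (k - 1, (k - 1)(n - 1)) degrees of freedom.  No sphericity correction is
    applied.  A zero error variance with a non-zero method effect is
    degenerate and reported as p = 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(metric_table, dtype=float)
    if x.ndim != 2:
        raise ValueError("metric table must be 2-d (replicates x methods)")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 replicates and >= 2 methods")
    if not np.all(np.isfinite(x)):
        raise ValueError("metric table must be complete and finite")
    grand = x.mean()
    ss_subject = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_method = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_subject - ss_method
    df_method = k - 1
    df_error = (k - 1) * (n - 1)
    ms_method = ss_method / df_method
    ms_error = ss_error / df_error
    if ms_error <= 0:
        if ms_method <= 0:
            return AnovaResult(F=0.0, p=1.0, df_method=df_method, df_error=df_error, degenerate=True)
        return AnovaResult(
            F=float("inf"), p=0.0, df_method=df_method, df_error=df_error, degenerate=True
        )
    F = ms_method / ms_error
    p = float(stats.f.sf(F, df_method, df_error))
    return AnovaResult(F=float(F), p=p, df_method=df_method, df_error=df_error)


def paired_ttest(a, b) -> tuple[float, float, bool]:
    """Two-sided paired Student t-test.

    Returns ``(t, p, degenerate)``; zero-variance differences cannot be
    tested and are flagged degenerate (t = 0 and p = 1 for exact ties,
    p = 0 for a constant non-zero shift).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, True
        return math.copysign(float("inf"), d[0]), 0.0, True
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), False


def dunnett_posthoc(
    metric_table: pd.DataFrame,
    control: str,
    n_draws: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunnett-style many-to-one comparisons against a control method.

    Each non-control method is compared to the control with a paired t
    statistic on the per-replicate differences.  Family-wise adjusted
    p-values come from the null distribution of the maximum |t| over all
    contrasts, simulated by drawing multivariate normal contrast vectors
    with the correlation of the observed difference columns, scaled by a
    chi distributed standard-deviation estimate (a multivariate-t
    max-modulus null), with ``n_draws`` seeded draws.  Adjusted p-values are
    never smaller than the unadjusted paired-t p-value; with a single
    contrast they coincide with it exactly.
    """
    if not isinstance(metric_table, pd.DataFrame):
        raise TypeError("metric_table must be a DataFrame with method columns")
    if control not in metric_table.columns:
        raise ValueError(f"control method {control!r} not in table")
    others = [c for c in metric_table.columns if c != control]
    if not others:
        raise ValueError("need at least one non-control method")
    x = metric_table.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need >= 2 replicates")
    ctrl = metric_table[control].to_numpy(dtype=float)
    diffs = metric_table[others].to_numpy(dtype=float) - ctrl[:, None]

    rows = []
    tstats = np.zeros(len(others))
    raw_p = np.zeros(len(others))
    degenerate = np.zeros(len(others), dtype=bool)
    for j, name in enumerate(others):
        t, p, flag = paired_ttest(metric_table[name].to_numpy(dtype=float), ctrl)
        tstats[j], raw_p[j], degenerate[j] = t, p, flag

    if len(others) == 1:
        adj = raw_p.copy()
    else:
        sd = diffs.std(axis=0, ddof=1)
        ok = sd > 0
        corr = np.eye(len(others))
        if ok.sum() >= 2:
            sub = np.corrcoef(diffs[:, ok], rowvar=False)
            corr[np.ix_(ok, ok)] = sub
        # max-|t| null: MVN contrasts over a shared chi scale (df = n - 1)
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(others)))
        z = rng.standard_normal((n_draws, len(others))) @ L.T
        scale = np.sqrt(rng.chisquare(n - 1, size=n_draws) / (n - 1))
        max_t = np.abs(z).max(axis=1) / scale
        finite = np.isfinite(tstats)
        adj = np.ones(len(others))
        for j in range(len(others)):
            if not finite[j]:
                adj[j] = 0.0
            else:
                adj[j] = (np.sum(max_t >= abs(tstats[j])) + 1) / (n_draws + 1)
        adj = np.maximum(adj, raw_p)  # family-wise p cannot undercut the raw p
    for j, name in enumerate(others):
        rows.append(
            {
                "method": name,
                "t": tstats[j],
                "p_raw": raw_p[j],
                "p_adjusted": float(min(adj[j], 1.0)),
                "significant": bool(adj[j] < alpha),
                "degenerate": bool(degenerate[j]),
            }
        )
    return pd.DataFrame(rows).set_index("method")


def run_benchmark(
    scored: dict[str, pd.DataFrame],
    labels: pd.DataFrame,
    spec: ReplicateSpec,
    control: str,
    metric: str = "auc",
    fractions=DEFAULT_FRACTIONS,
    dunnett_seed: int = 0,
) -> dict:
    """Full comparison protocol: intersect, label, subsample, evaluate, test.

    Returns a JSON-serializable report holding the per-replicate metric
    table, per-method mean +/- SD for every metric, the repeated-measures
    ANOVA on the chosen headline ``metric`` and, with more than two methods,
    Dunnett-adjusted p-values versus ``control`` (a paired t-test when
    exactly two methods are compared).
    """
    parent = intersect_common(scored, labels=labels)
    replicates = subsample_replicates(parent, spec)
    table = evaluate_all(replicates, fractions=fractions)
    summary = summarize_metrics(table)

    wide = table.pivot(index="replicate", columns="method", values=metric)
    wide = wide[[m for m in parent.methods]]
    report: dict = {
        "config": {
            "n_replicates": spec.n_replicates,
            "subset_size": spec.subset_size,
            "seed": spec.seed,
            "control": control,
            "metric": metric,
            "parent_size": len(parent),
            "parent_prevalence": parent.prevalence,
        },
        "replicate_metrics": table.to_dict(orient="records"),
        "summary": {
            m: {c: float(summary.loc[m, c]) for c in summary.columns} for m in summary.index
        },
    }
    if len(parent.methods) > 2:
        anova = rm_anova(wide.to_numpy())
        dunnett = dunnett_posthoc(wide, control=control, seed=dunnett_seed)
        report["anova"] = {
            "F": anova.F,
            "p": anova.p,
            "df_method": anova.df_method,
            "df_error": anova.df_error,
            "degenerate": anova.degenerate,
        }
        report["comparisons"] = {
            m: {
                "t": float(dunnett.loc[m, "t"]),
                "p_raw": float(dunnett.loc[m, "p_raw"]),
                "p_adjusted": float(dunnett.loc[m, "p_adjusted"]),
                "significant": bool(dunnett.loc[m, "significant"]),
            }
            for m in dunnett.index
        }
    else:
        other = [m for m in parent.methods if m != control][0]
        t, p, flag = paired_ttest(wide[other], wide[control])
        report["comparisons"] = {
            other: {"t": t, "p_raw": p, "p_adjusted": p, "significant": bool(p < 0.05)}
        }
    return report


def run_synthetic_comparison(
    sim_config,
    spec: ReplicateSpec,
    method: str = "mean",
    aggregate_name: str = "aggregate",
    metric: str = "auc",
    fractions=DEFAULT_FRACTIONS,
    dunnett_seed: int = 0,
) -> dict:
    """Generate synthetic sources, aggregate them, and benchmark the result.

    The parameter-recovery experiment: K noisy sources with known ground
    truth are simulated, aggregated with ``method``, and the aggregate is
    compared against each individual source (its own normalized-rank
    ordering, unlisted interactions imputed last) over stratified replicate
    subsets, with the RM-ANOVA + Dunnett machinery treating the aggregate
    as the control.  Returns the same report structure as
    :func:`run_benchmark` plus a per-replicate win table for the headline
    metric.
    """
    from .aggregation import aggregate as _aggregate, build_rank_matrix
    from .simulate import simulate_sources

    sources, truth = simulate_sources(sim_config)
    matrix = build_rank_matrix(sources)
    agg = _aggregate(matrix, method=method)
    agg_scores = agg.set_index(["mirna", "gene"])["score"].reindex(matrix.items)

    score_frame = pd.DataFrame(
        {aggregate_name: agg_scores.to_numpy()}, index=matrix.items
    )
    for j, name in enumerate(matrix.sources):
        score_frame[name] = matrix.r[:, j]
    labels = (
        pd.Series(truth.labels, index=truth.items).reindex(matrix.items).to_numpy()
    )
    parent = BenchmarkSet(
        scores=score_frame, labels=labels, provenance={"parent": "synthetic"}
    )
    replicates = subsample_replicates(parent, spec)
    table = evaluate_all(replicates, fractions=fractions)
    wide = table.pivot(index="replicate", columns="method", values=metric)
    wide = wide[parent.methods]
    anova = rm_anova(wide.to_numpy())
    dunnett = dunnett_posthoc(wide, control=aggregate_name, seed=dunnett_seed)
    source_names = [m for m in parent.methods if m != aggregate_name]
    wins = (
        wide[source_names].lt(wide[aggregate_name], axis=0)
        if metric in ("auc", "pauc_90", "sens_at_90", "pr_auc", "mean_f")
        else wide[source_names].gt(wide[aggregate_name], axis=0)
    )
    return {
        "metric_table": wide,
        "summary": summarize_metrics(table),
        "anova": anova,
        "dunnett": dunnett,
        "aggregate_beats_all_sources_every_replicate": bool(wins.all().all()),
        "all_sources_significant": bool(dunnett["significant"].all()),
    }
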