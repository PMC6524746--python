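"""Evaluation machinery: performance scoring and count diagnostics.

Methods are scored as gene-level calls at nominal q-value cutoffs against a
ground-truth gene set: TPR is the recovered fraction of true genes, FDR the
fraction of calls outside the truth (0/0 counts as 0). Consensus truth sets
(union/intersection of several methods' calls) support real-data subset
experiments where no simulation truth exists. Diagnostics reproduce the two
counting-unit summaries that motivate EC testing: how many features of each
type a gene expresses, and the per-feature variance/mean ratio of
CPM-transformed counts across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "MethodResult",
    "PerformancePoint",
    "VarianceSummary",
    "tpr_fdr",
    "consensus_truth",
    "subset_experiment",
    "feature_count_summary",
    "variance_mean_summary",
    "rank_order_fp",
]

DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1)


@dataclass
class MethodResult:
    """Gene-level q-values of one method."""

    method: str
    qvalues: dict[str, float]

    def significant(self, threshold: float) -> set[str]:
        return {g for g, q in self.qvalues.items() if q < threshold}

    @classmethod
    def from_gene_results(cls, method: str, genes) -> "MethodResult":
        return cls(method=method, qvalues={g.gene_id: g.gene_q for g in genes})


@dataclass
class PerformancePoint:
    method: str
    threshold: float
    tpr: float | None  # None when the truth set is empty
    fdr: float
    n_called: int


@dataclass
class VarianceSummary:
    """log2(variance/mean) of CPM counts per feature, computed per condition."""

    values: pd.DataFrame  # feature x condition, NaN where excluded
    n_excluded: int
    mean: float


def tpr_fdr(
    result: MethodResult,
    truth: set[str],
    universe: set[str] | None = None,
    thresholds=DEFAULT_THRESHOLDS,
) -> list[PerformancePoint]:
    """TPR and observed FDR of a method's calls at each nominal cutoff.

    ``universe`` restricts scoring to a common tested-gene set (both calls
    and truth are intersected with it); by default the method's own tested
    genes. An empty truth set leaves TPR undefined (None).
    """
    if universe is None:
        universe = set(result.qvalues)
    truth_u = truth & universe
    points = []
    for t in thresholds:
        called = result.significant(t) & universe
        n_called = len(called)
        tp = len(called & truth_u)
        fp = n_called - tp
        fdr = fp / n_called if n_called else 0.0
        tpr = tp / len(truth_u) if truth_u else None
        if not truth_u:
            logger.warning("tpr_fdr: empty truth set; TPR undefined at t=%g", t)
        points.append(
            PerformancePoint(
                method=result.method, threshold=t, tpr=tpr, fdr=fdr, n_called=n_called
            )
        )
    return points


def consensus_truth(
    results: list[MethodResult], mode: str = "union", threshold: float = 0.05
) -> set[str]:
    """Union or intersection of the methods' significant gene sets."""
    if not results:
        raise ValueError("need >=1 method result")
    sets = [r.significant(threshold) for r in results]
    if mode == "union":
        return set().union(*sets)
    if mode == "intersect":
        return set.intersection(*map(set, sets))
    raise ValueError(f"unknown mode {mode!r}")


def subset_experiment(
    pipeline,
    sample_table: SampleTable,
    truth: set[str],
    n_per_group: int,
    n_iterations: int,
    threshold: float = 0.05,
    seed: int = 0,
    max_redraws: int = 100,
) -> list[PerformancePoint]:
    """Re-run a pipeline on random sample subsets and score each run.

    Per iteration, ``n_per_group`` samples are drawn without replacement
    from each condition and ``pipeline(subset_table)`` must return a
    :class:`MethodResult`, scored against the fixed full-data ``truth``.
    The whole draw is redrawn (deterministically) until every sample
    appears in at least one iteration. Fully seeded.
    """
    by_cond: dict[str, list[str]] = {}
    for sid, cond, _ in sample_table.rows:
        by_cond.setdefault(cond, []).append(sid)
    for cond, sids in by_cond.items():
        if n_per_group >= len(sids):
            raise ValueError(
                f"n_per_group={n_per_group} must be < group size {len(sids)} ({cond})"
            )
    all_samples = set(sample_table.sample_ids)
    draws = None
    for attempt in range(max_redraws):
        rng = np.random.default_rng(seed + attempt)
        candidate = [
            [
                sid
                for cond in sorted(by_cond)
                for sid in rng.choice(by_cond[cond], size=n_per_group, replace=False)
            ]
            for _ in range(n_iterations)
        ]
        used = {sid for draw in candidate for sid in draw}
        if used == all_samples:
            draws = candidate
            break
    if draws is None:
        raise RuntimeError("could not cover every sample within the redraw budget")

    cond_of = sample_table.condition_of()
    path_of = sample_table.paths()
    points = []
    for it, draw in enumerate(draws):
        subset = SampleTable(rows=[(s, cond_of[s], path_of[s]) for s in draw])
        result = pipeline(subset)
        pt = tpr_fdr(result, truth, thresholds=(threshold,))[0]
        pt = PerformancePoint(
            method=f"{result.method}#it{it}",
            threshold=threshold,
            tpr=pt.tpr,
            fdr=pt.fdr,
            n_called=pt.n_called,
        )
        points.append(pt)
    return points


def feature_count_summary(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per gene and feature type, how many features have at least one read.

    ``matrices`` maps a feature-type label (e.g. ec / transcript / exon) to
    an annotated count matrix. Returns genes x types, plus a "__total__"
    row of per-type totals.
    """
    out: dict[str, pd.Series] = {}
    for label, df in matrices.items():
        sample_cols = [c for c in df.columns if c != "gene_id"]
        expressed = df[sample_cols].sum(axis=1) >= 1
        out[label] = df.loc[expressed].groupby("gene_id").size()
    summary = pd.DataFrame(out).fillna(0).astype(int)
    summary.loc["__total__"] = summary.sum()
    return summary


def variance_mean_summary(
    matrix: pd.DataFrame, sample_table: SampleTable, cpm_threshold: float = 1.0
) -> VarianceSummary:
    """Per-feature log2(variance/mean) of CPM counts, per condition.

    Counts are CPM-transformed (count x 1e6 / column total); features where
    no sample reaches ``cpm_threshold`` are dropped (light expression
    filter), and zero-variance feature/condition cells are excluded from
    the summary with a logged count.
    """
    sample_cols = [c for c in matrix.columns if c != "gene_id"]
    counts = matrix[sample_cols].to_numpy(dtype=float)
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("sample with zero library size")
    cpm = counts * 1e6 / libs
    keep = (cpm >= cpm_threshold).any(axis=1)
    cpm = cpm[keep]
    index = matrix.index[keep]

    cond_of = sample_table.condition_of()
    conditions = sorted(set(cond_of.values()))
    cols = {}
    n_excluded = 0
    for cond in conditions:
        sel = [i for i, s in enumerate(sample_cols) if cond_of.get(s) == cond]
        if len(sel) < 2:
            raise ValueError(f"condition {cond!r} needs >=2 replicates")
        sub = cpm[:, sel]
        var = sub.var(axis=1, ddof=1)
        mean = sub.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((var > 0) & (mean > 0), var / mean, np.nan)
        n_excluded += int(np.isnan(ratio).sum())
        cols[cond] = np.log2(ratio)
    values = pd.DataFrame(cols, index=index)
    if n_excluded:
        logger.info(
            "variance_mean_summary: excluded %d zero-variance feature/condition cells",
            n_excluded,
        )
    flat = values.to_numpy().ravel()
    finite = flat[np.isfinite(flat)]
    mean = float(finite.mean()) if finite.size else float("nan")
    return VarianceSummary(values=values, n_excluded=n_excluded, mean=mean)


def rank_order_fp(result: MethodResult, truth: set[str], top_n: int = 500) -> np.ndarray:
    """Cumulative false positives among the top-ranked genes.

    Genes are sorted by q-value ascending, ties broken by gene id; entry i
    is the number of non-truth genes among the first i+1.
    """
    if not result.qvalues:
        raise ValueError("empty method result")
    ranked = sorted(result.qvalues.items(), key=lambda kv: (kv[1], kv[0]))
    fp = 0
    out = []
    for gene, _ in ranked[:top_n]:
        if gene not in truth:
            fp += 1
        out.append(fp)
    return np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_tpr_fdr(points: list[PerformancePoint], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    methods = sorted({p.method for p in points})
    for m in methods:
        pts = [p for p in points if p.method == m]
        ax.plot(
            [p.fdr for p in pts],
            [p.tpr if p.tpr is not None else np.nan for p in pts],
            "o-",
            label=m,
        )
    for t in sorted({p.threshold for p in points}):
        ax.axvline(t, ls=":", color="grey", lw=0.8)
    ax.set_xlabel("observed FDR")
    ax.set_ylabel("TPR")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rank_fp(curves: dict[str, np.ndarray], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        ax.plot(np.arange(1, len(curve) + 1), curve, label=label)
    ax.set_xlabel("rank (by q-value)")
    ax.set_ylabel("cumulative false positives")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_variance_density(summaries: dict[str, VarianceSummary], path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, summ in summaries.items():
        vals = summ.values.to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        if len(vals):
            ax.hist(vals, bins=50, density=True, histtype="step", label=label)
    ax.set_xlabel("log2(variance / mean), CPM")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
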