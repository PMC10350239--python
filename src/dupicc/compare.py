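"""Cross-study and stratified comparisons of probe reliabilities.

Covers the comparison toolkit: Spearman correlation of two reliability
vectors keyed by probe, cross-tabulation of class labels with percent
concordance, a rank-based two-group contrast (e.g. probes with vs
without an mQTL), annotation/mean-beta-stratified summaries, and the
binomial mean-variance helper p(1-p)/n that explains why probes with
extreme average methylation have low between-subject variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import DEFAULT_SCHEME, UNDEFINED_LABEL, ClassificationScheme

__all__ = [
    "CrossTab",
    "spearman_reliability",
    "crosstab_classes",
    "compare_groups",
    "GroupComparison",
    "stratified_summary",
    "binomial_variance",
]

EXACT_MAX_GROUP = 10  # exact rank-sum enumeration when both groups are this small


def _as_series(x) -> pd.Series:
    if isinstance(x, pd.Series):
        return x
    return pd.Series(dict(x))


class SpearmanResult(NamedTuple):
    rho: float
    n_shared: int


def spearman_reliability(x, y) -> SpearmanResult:
    """Spearman rank correlation of two probe -> value maps.

    Keys are intersected and probes missing in either vector dropped;
    ties receive average ranks. Requires at least 3 shared probes.
    """
    xs, ys = _as_series(x), _as_series(y)
    merged = pd.concat([xs.rename("x"), ys.rename("y")], axis=1, join="inner").dropna()
    if len(merged) < 3:
        raise ValueError(f"need at least 3 shared probes, got {len(merged)}")
    rho = stats.spearmanr(merged["x"], merged["y"]).statistic
    return SpearmanResult(rho=float(rho), n_shared=len(merged))


@dataclass(frozen=True)
class CrossTab:
    """Class-label cross-tabulation between two reliability sources.

    ``counts`` is a labels x labels matrix of shared probes, ``row_pct``
    the row-normalised percentages (1 decimal), ``concordance_pct`` the
    diagonal share of all counts as a percent (2 decimals). Probes
    classified Undefined in either source are excluded from the grid and
    reported in ``n_undefined``.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray
    n_undefined: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("cross-tabulation is empty (no shared classified probes)")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def concordance(self) -> float:
        """Fraction of shared probes with identical class labels."""
        return float(np.trace(self.counts)) / self.total

    @property
    def concordance_pct(self) -> float:
        return round(100.0 * self.concordance, 2)

    @property
    def row_pct(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / totals
        return np.round(np.where(totals > 0, pct, 0.0), 1)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels), columns=list(self.col_labels))

    def row_pct_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.row_pct, index=list(self.row_labels), columns=list(self.col_labels))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame | np.ndarray, labels=None) -> "CrossTab":
        """Build from an already-tabulated count matrix (e.g. a printed table)."""
        if isinstance(counts, pd.DataFrame):
            return cls(
                row_labels=tuple(counts.index),
                col_labels=tuple(counts.columns),
                counts=counts.to_numpy(),
            )
        if labels is None:
            raise ValueError("labels required when counts is a bare array")
        return cls(row_labels=tuple(labels), col_labels=tuple(labels), counts=np.asarray(counts))

    def __str__(self) -> str:
        cf = self.counts_frame()
        pf = self.row_pct_frame()
        out = cf.astype(str) + " (" + pf.map(lambda v: f"{v:.1f}") + "%)"
        return (
            f"{out.to_string()}\n"
            f"shared probes: {self.total}  undefined excluded: {self.n_undefined}\n"
            f"concordance: {self.concordance_pct:.2f}%"
        )


def crosstab_classes(a, b, scheme: ClassificationScheme = DEFAULT_SCHEME) -> CrossTab:
    """Cross-tabulate two probe -> class-label maps over shared probes.

    Rows come from ``a``, columns from ``b``; both must use the scheme's
    labels. Undefined (or missing) labels on either side are excluded
    from the grid and counted separately.
    """
    sa, sb = _as_series(a).astype(str), _as_series(b).astype(str)
    merged = pd.concat([sa.rename("a"), sb.rename("b")], axis=1, join="inner")
    if merged.empty:
        raise ValueError("no shared probes between the two classifications")
    defined = merged[
        (merged["a"].isin(scheme.labels)) & (merged["b"].isin(scheme.labels))
    ]
    n_undefined = len(merged) - len(defined)
    unknown = set(merged["a"]).union(merged["b"]) - set(scheme.labels) - {UNDEFINED_LABEL, "nan"}
    if unknown:
        raise ValueError(f"labels outside the classification scheme: {sorted(unknown)}")
    counts = (
        pd.crosstab(defined["a"], defined["b"])
        .reindex(index=list(scheme.labels), columns=list(scheme.labels), fill_value=0)
        .to_numpy()
    )
    return CrossTab(
        row_labels=scheme.labels,
        col_labels=scheme.labels,
        counts=counts,
        n_undefined=n_undefined,
    )


class GroupComparison(NamedTuple):
    median_in: float
    median_out: float
    p_value: float
    n_in: int
    n_out: int
    method: str


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by full enumeration.

    Enumerates every assignment of the pooled average ranks to a group of
    size len(x); the p-value is the share of assignments whose rank sum
    deviates from its null mean at least as much as the observed one.
    Handles ties through average ranks, feasible for both groups <= 10.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    d_obs = abs(w_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def compare_groups(rel, flag, stat: str = "micc") -> GroupComparison:
    """Rank-based two-group contrast of a reliability statistic.

    ``rel`` is a reliability table (DataFrame with ``probe_id`` and the
    statistic column) or a probe -> value Series; ``flag`` is a
    probe -> bool map splitting probes into the flagged group and the
    rest. Returns both group medians and a two-sided Wilcoxon rank-sum
    p-value: exact enumeration when both groups have at most 10 probes,
    otherwise the normal approximation with tie correction.
    """
    if isinstance(rel, pd.DataFrame):
        if stat not in rel.columns:
            raise ValueError(f"statistic {stat!r} not present in the reliability table")
        values = rel.set_index("probe_id")[stat] if "probe_id" in rel.columns else rel[stat]
    else:
        values = _as_series(rel)
    flags = _as_series(flag).astype(bool)
    merged = pd.concat([values.rename("v"), flags.rename("f")], axis=1, join="inner").dropna()
    x = merged.loc[merged["f"], "v"].to_numpy(dtype=float)
    y = merged.loc[~merged["f"], "v"].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty after dropping missing values")
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP:
        p = _exact_rank_sum_p(x, y)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "normal-approximation"
    return GroupComparison(
        median_in=float(np.median(x)),
        median_out=float(np.median(y)),
        p_value=p,
        n_in=len(x),
        n_out=len(y),
        method=method,
    )


def stratified_summary(
    rel: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    stratum: str | None = None,
    bins: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Reliability summaries per annotation stratum or mean-beta bin.

    Either ``stratum`` names a column of ``annotation`` (joined on
    probe_id), or ``bins`` gives mean-beta bin edges (default deciles
    [0, 0.1), ..., [0.9, 1]). Returns per-stratum probe counts and
    mean/median of ICC and mICC, skipping undefined values.
    """
    t = rel.set_index("probe_id") if "probe_id" in rel.columns else rel.copy()
    if stratum is not None:
        if annotation is None:
            raise ValueError("an annotation table is required to stratify by a field")
        ann = annotation.set_index("probe_id") if "probe_id" in annotation.columns else annotation
        if stratum not in ann.columns:
            raise ValueError(f"unknown stratum field {stratum!r}")
        groups = ann[stratum].reindex(t.index)
    else:
        edges = list(bins) if bins is not None else [round(0.1 * i, 1) for i in range(11)]
        labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-2], edges[1:-1])]
        labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
        groups = pd.cut(t["mean_beta"], bins=edges, labels=labels, right=False, include_lowest=True)
        # fold values equal to the top edge into the closed last bin
        groups[t["mean_beta"] == edges[-1]] = labels[-1]
    out = (
        t.assign(_stratum=groups.values)
        .groupby("_stratum", observed=False)
        .agg(
            n_probes=("icc", "size"),
            mean_icc=("icc", "mean"),
            median_icc=("icc", "median"),
            mean_micc=("micc", "mean"),
            median_micc=("micc", "median"),
        )
    )
    out.index.name = "stratum"
    return out


def binomial_variance(p: float, n_cells: int) -> float:
    """Variance p(1-p)/n of a proportion over ``n_cells`` cells.

    Treating a beta value as the fraction of methylated cells, the
    between-subject variance of the proportion peaks at p = 0.5 and
    vanishes at the extremes — the mean-variance relationship behind the
    low reliability of probes with extreme average methylation.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_cells < 1:
        raise ValueError("n_cells must be a positive integer")
    return p * (1.0 - p) / n_cells
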