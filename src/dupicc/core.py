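"""Per-probe reliability statistics for duplicate measurements.

This module implements the statistics for an ``n`` subjects x 2 replicates
design: the two-way ANOVA mean-square decomposition, the single-measure
absolute-agreement intraclass correlation ICC(A,1), method-of-moments
variance components, Bland-Altman 95% limits of agreement and their
half-width (HoLA), and the modified ICC

    mICC = ICC - HoLA,      HoLA = z * sigma_d   (z = 1.96 by default),

where ``sigma_d`` is the sample standard deviation of the paired
differences. The modified ICC penalises probes whose duplicate
measurements disagree in absolute terms even when the between-subject
variance is large enough to give a high ICC.

All functions operate on plain scalars/arrays and make no assumption that
the measurements are methylation beta values; any paired scalar (e.g. a
cell-type proportion) works. Range checking for beta values lives in the
I/O layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_Z",
    "UNDEFINED_LABEL",
    "InsufficientPairsError",
    "DuplicateSet",
    "AnovaSummary",
    "VarianceComponents",
    "LimitsOfAgreement",
    "ClassificationScheme",
    "DEFAULT_SCHEME",
    "anova_mean_squares",
    "icc_a1",
    "variance_components",
    "limits_of_agreement",
    "modified_icc",
    "classify",
    "reliability_statistics",
]

#: Normal quantile for 95% limits of agreement.
DEFAULT_Z = 1.96

#: Class label reported when ICC (or mICC) is undefined for a probe.
UNDEFINED_LABEL = "Undefined"


class InsufficientPairsError(ValueError):
    """Raised when fewer than two complete measurement pairs are available."""


@dataclass(frozen=True)
class DuplicateSet:
    """Paired duplicate measurements for one probe.

    Parameters
    ----------
    values : (n, 2) array_like
        One row per subject, columns are replicate 1 and replicate 2.
        All entries must be finite; incomplete pairs are dropped upstream.
    subject_ids : sequence of str, optional
        Identifiers for the rows; generated as ``s0..s{n-1}`` if omitted.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"expected an (n, 2) array, got shape {arr.shape}")
        if arr.shape[0] < 2:
            raise InsufficientPairsError(
                f"insufficient pairs: need at least 2 complete pairs, got {arr.shape[0]}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite values in duplicate set; drop incomplete pairs first")
        object.__setattr__(self, "values", arr)
        ids = tuple(str(s) for s in self.subject_ids)
        if not ids:
            ids = tuple(f"s{i}" for i in range(arr.shape[0]))
        if len(ids) != arr.shape[0]:
            raise ValueError("subject_ids length does not match number of pairs")
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return 2

    def differences(self) -> np.ndarray:
        """Replicate 1 minus replicate 2, per subject."""
        return self.values[:, 0] - self.values[:, 1]

    def swapped(self) -> "DuplicateSet":
        """The same data with replicate labels exchanged."""
        return DuplicateSet(self.values[:, ::-1], self.subject_ids)


@dataclass(frozen=True)
class AnovaSummary:
    """Mean squares of the two-way (subjects x replicates) ANOVA.

    ``msr`` is the subject (row) mean square, ``msc`` the replicate
    (column) mean square and ``mse`` the residual mean square, on
    ``n - 1``, ``k - 1`` and ``(n - 1)(k - 1)`` degrees of freedom.
    """

    msr: float
    msc: float
    mse: float
    n: int
    k: int = 2

    def __post_init__(self) -> None:
        if min(self.msr, self.msc, self.mse) < 0:
            raise ValueError("mean squares must be non-negative")
        if self.n < 2 or self.k < 2:
            raise ValueError("need n >= 2 subjects and k >= 2 replicates")


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments between/within-subject variances (truncated at 0)."""

    sigma_b2: float
    sigma_w2: float


@dataclass(frozen=True)
class LimitsOfAgreement:
    """Bland-Altman interval for paired differences and its half-width."""

    lower: float
    upper: float
    sigma_d: float
    hola: float


def anova_mean_squares(dup: DuplicateSet) -> AnovaSummary:
    """Two-way ANOVA mean squares for a duplicate set.

    Decomposes the total sum of squares into subject (row), replicate
    (column) and residual parts:

        SSR = k * sum_i (ybar_i. - ybar..)^2
        SSC = n * sum_j (ybar_.j - ybar..)^2
        SSE = sum_ij (y_ij - ybar_i. - ybar_.j + ybar..)^2

    and divides by the respective degrees of freedom. The residual sum
    of squares is accumulated directly (not by subtraction from the
    total), so exact replicate agreement yields SSE = 0 exactly.
    """
    y = dup.values
    n, k = y.shape
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    grand = float(col_means.mean())
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    resid = y - row_means[:, None] - col_means[None, :] + grand
    sse = float((resid**2).sum())
    return AnovaSummary(
        msr=ssr / (n - 1),
        msc=ssc / (k - 1),
        mse=sse / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_a1(a: AnovaSummary) -> float:
    """Single-measure, absolute-agreement, two-way random-effects ICC.

    The ANOVA estimator

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

    targets sigma_b^2 / (sigma_b^2 + sigma_w^2), the between-subject
    share of total variance, while charging systematic replicate
    (column) differences against agreement. Returns NaN when the
    denominator is zero (all measurements identical); negative estimates
    are retained, not clamped.
    """
    denom = a.msr + (a.k - 1.0) * a.mse + (a.k / a.n) * (a.msc - a.mse)
    if denom == 0.0:
        return math.nan
    return (a.msr - a.mse) / denom


def variance_components(a: AnovaSummary) -> VarianceComponents:
    """Method-of-moments variance components from the mean squares.

    sigma_w^2 = MSE and sigma_b^2 = max(0, (MSR - MSE) / k); the
    between-subject estimate is truncated at zero when MSR < MSE.
    """
    return VarianceComponents(
        sigma_b2=max(0.0, (a.msr - a.mse) / a.k),
        sigma_w2=a.mse,
    )


def limits_of_agreement(dup: DuplicateSet, z: float = DEFAULT_Z) -> LimitsOfAgreement:
    """Bland-Altman 95% limits of agreement for the paired differences.

    ``sigma_d`` is the sample standard deviation (n-1 denominator) of
    d = replicate1 - replicate2; the limits are mean(d) -/+ z*sigma_d and
    HoLA, the half-width of that interval, is z*sigma_d.
    """
    if z < 0:
        raise ValueError("z multiplier must be non-negative")
    d = dup.differences()
    mean_d = float(d.mean())
    sigma_d = float(d.std(ddof=1))
    hola = z * sigma_d
    return LimitsOfAgreement(lower=mean_d - hola, upper=mean_d + hola, sigma_d=sigma_d, hola=hola)


def modified_icc(icc: float, hola: float) -> float:
    """The modified ICC: ICC minus the half-width of the limits of agreement.

    Penalises the ICC by the absolute disagreement between duplicates, so
    that probes with a large between-subject variance but wide limits of
    agreement no longer score as highly reliable. NaN propagates from an
    undefined ICC.
    """
    if not math.isfinite(hola) or hola < 0:
        raise ValueError(f"hola must be a non-negative finite number, got {hola!r}")
    if icc is None or math.isnan(icc):
        return math.nan
    return icc - hola


@dataclass(frozen=True)
class ClassificationScheme:
    """Ordered reliability bands with an explicit boundary convention.

    ``boundary_rule[i]`` says which band a value exactly equal to
    ``cutpoints[i]`` falls into: ``"upper"`` assigns it to the band above
    the cutpoint, ``"lower"`` to the band below. The default encodes
    Poor < 0.4, Fair [0.4, 0.6), Good [0.6, 0.75], Excellent > 0.75.
    """

    cutpoints: tuple[float, ...] = (0.4, 0.6, 0.75)
    labels: tuple[str, ...] = ("Poor", "Fair", "Good", "Excellent")
    boundary_rule: tuple[str, ...] = ("upper", "upper", "lower")

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        if any(lo >= hi for lo, hi in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be strictly increasing")
        if len(self.labels) != len(cp) + 1:
            raise ValueError("need exactly one more label than cutpoints")
        if len(self.boundary_rule) != len(cp):
            raise ValueError("need one boundary rule per cutpoint")
        if any(r not in ("upper", "lower") for r in self.boundary_rule):
            raise ValueError("boundary rules must be 'upper' or 'lower'")
        object.__setattr__(self, "cutpoints", cp)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "boundary_rule", tuple(self.boundary_rule))

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Band labels plus the Undefined category."""
        return self.labels + (UNDEFINED_LABEL,)


DEFAULT_SCHEME = ClassificationScheme()


def classify(value: float, scheme: ClassificationScheme = DEFAULT_SCHEME) -> str:
    """Map a reliability value to its band label; NaN maps to Undefined."""
    if value is None:
        return UNDEFINED_LABEL
    v = float(value)
    if math.isnan(v):
        return UNDEFINED_LABEL
    for i, cut in enumerate(scheme.cutpoints):
        if v < cut:
            return scheme.labels[i]
        if v == cut:
            return scheme.labels[i + 1] if scheme.boundary_rule[i] == "upper" else scheme.labels[i]
    return scheme.labels[-1]


def reliability_statistics(
    dup: DuplicateSet,
    scheme: ClassificationScheme = DEFAULT_SCHEME,
    z: float = DEFAULT_Z,
) -> dict:
    """All per-probe statistics for one duplicate set, as a flat dict.

    Runs the full chain anova_mean_squares -> icc_a1 ->
    variance_components -> limits_of_agreement -> modified_icc ->
    classify, returning the keys used in the reliability table
    (``n_pairs``, ``icc``, ``sigma_b2``, ``sigma_w2``, ``sd_diff``,
    ``hola``, ``micc``, ``class_icc``, ``class_micc``).
    """
    a = anova_mean_squares(dup)
    icc = icc_a1(a)
    vc = variance_components(a)
    loa = limits_of_agreement(dup, z=z)
    micc = modified_icc(icc, loa.hola)
    return {
        "n_pairs": dup.n,
        "icc": icc,
        "sigma_b2": vc.sigma_b2,
        "sigma_w2": vc.sigma_w2,
        "sd_diff": loa.sigma_d,
        "hola": loa.hola,
        "micc": micc,
        "class_icc": classify(icc, scheme),
        "class_micc": classify(micc, scheme),
    }
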