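"""Probe-level reliability analysis of a beta matrix with duplicate samples.

The workhorse is :func:`reliability_scan`, which turns a probes x samples
beta matrix plus a subject -> (replicate 1, replicate 2) pair map into a
per-probe reliability table (ICC, variance components, limits of
agreement, modified ICC, class labels, mean/SD of beta). The
:class:`ProbeReliabilityModel` / :class:`ProbeReliabilityResults` pair
wraps the same computation in a fit-and-summarise interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .config import RunConfig

__all__ = [
    "DataError",
    "BetaMatrix",
    "PairMap",
    "build_pair_map",
    "filter_probes_by_missingness",
    "probe_mean_sd",
    "reliability_scan",
    "ProbeReliabilityModel",
    "ProbeReliabilityResults",
    "RELIABILITY_COLUMNS",
]

#: Fixed column contract of the reliability table.
RELIABILITY_COLUMNS = (
    "probe_id",
    "n_pairs",
    "icc",
    "sigma_b2",
    "sigma_w2",
    "sd_diff",
    "hola",
    "micc",
    "class_icc",
    "class_micc",
    "mean_beta",
    "sd_beta",
)

REQUIRED_SHEET_COLUMNS = ("sample_id", "subject_id", "replicate")


class DataError(ValueError):
    """User-facing problem with the input data (bad IDs, shapes, ranges)."""


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    Rows are probes (Illumina convention), columns are samples; entries
    are floats in [0, 1] or NaN for missing. Wraps a pandas DataFrame
    with uniqueness checks on both axes.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe IDs: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dups[:5]}")
        self.data = df.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-probe fraction of missing entries."""
        return self.data.isna().mean(axis=1)


@dataclass(frozen=True)
class PairMap:
    """Subject -> (sample id of replicate 1, sample id of replicate 2).

    ``plates`` optionally maps sample IDs to plate labels; ``excluded``
    records (subject_id, reason) for subjects dropped while pairing.
    """

    pairs: dict[str, tuple[str, str]]
    plates: dict[str, str] = field(default_factory=dict)
    excluded: tuple[tuple[str, str], ...] = ()

    @property
    def subjects(self) -> list[str]:
        return list(self.pairs)

    @property
    def n_subjects(self) -> int:
        return len(self.pairs)

    def replicate_columns(self) -> tuple[list[str], list[str]]:
        """Sample IDs of replicate 1 and replicate 2, in subject order."""
        rep1 = [p[0] for p in self.pairs.values()]
        rep2 = [p[1] for p in self.pairs.values()]
        return rep1, rep2

    @property
    def sample_ids(self) -> list[str]:
        r1, r2 = self.replicate_columns()
        return r1 + r2


def build_pair_map(
    sample_sheet: pd.DataFrame,
    require_cross_plate: bool = False,
    strict: bool = False,
) -> PairMap:
    """Pair duplicate samples by subject from a sample sheet.

    The sheet needs columns ``sample_id``, ``subject_id``, ``replicate``
    (labels ordering the two replicates) and optionally ``plate``.
    Subjects without exactly two replicates are excluded with a warning
    (an error in strict mode). With ``require_cross_plate`` set, subjects
    whose two replicates sit on the same plate are excluded too, matching
    the design choice of analysing only cross-plate duplicates so plate
    effects are not confounded with subjects.
    """
    missing = [c for c in REQUIRED_SHEET_COLUMNS if c not in sample_sheet.columns]
    if missing:
        raise DataError(f"sample sheet is missing required columns: {missing}")
    sheet = sample_sheet.copy()
    sheet["sample_id"] = sheet["sample_id"].astype(str)
    sheet["subject_id"] = sheet["subject_id"].astype(str)
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataError(f"duplicate sample IDs in sample sheet: {dups[:5]}")
    has_plate = "plate" in sheet.columns
    if require_cross_plate and not has_plate:
        raise DataError("require_cross_plate is set but the sheet has no 'plate' column")

    pairs: dict[str, tuple[str, str]] = {}
    plates: dict[str, str] = {}
    excluded: list[tuple[str, str]] = []
    for subject, grp in sheet.groupby("subject_id", sort=False):
        grp = grp.sort_values("replicate", kind="stable")
        if len(grp) != 2:
            reason = f"{len(grp)} replicates (need exactly 2)"
            if strict:
                raise DataError(f"subject {subject!r}: {reason}")
            warnings.warn(f"excluding subject {subject!r}: {reason}", stacklevel=2)
            excluded.append((subject, reason))
            continue
        s1, s2 = grp["sample_id"].tolist()
        if has_plate:
            p1, p2 = grp["plate"].astype(str).tolist()
            plates[s1], plates[s2] = p1, p2
            if require_cross_plate and p1 == p2:
                reason = f"both replicates on plate {p1!r}"
                warnings.warn(f"excluding subject {subject!r}: {reason}", stacklevel=2)
                excluded.append((subject, reason))
                continue
        pairs[subject] = (s1, s2)
    return PairMap(pairs=pairs, plates=plates, excluded=tuple(excluded))


def filter_probes_by_missingness(
    m: BetaMatrix, max_missing_frac: float = 0.05
) -> tuple[BetaMatrix, int]:
    """Drop probes missing in more than ``max_missing_frac`` of samples.

    Returns the filtered matrix and the number of probes removed. The
    threshold is inclusive: a probe is removed only when its missing
    fraction strictly exceeds it.
    """
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must lie in [0, 1]")
    frac = m.missing_fraction()
    keep = frac <= max_missing_frac
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        warnings.warn("missingness filter removed every probe", stacklevel=2)
    return BetaMatrix(m.data.loc[keep]), n_removed


def _check_pairs_resolve(m: BetaMatrix, pairs: PairMap) -> None:
    absent = [s for s in pairs.sample_ids if s not in m.data.columns]
    if absent:
        raise DataError(f"pair map references samples absent from the matrix: {absent[:5]}")
    if pairs.n_subjects == 0:
        raise DataError("pair map contains no subject pairs")


def probe_mean_sd(
    m: BetaMatrix, pairs: PairMap, seed: int = 0
) -> tuple[pd.Series, pd.Series]:
    """Per-probe mean and SD of beta values.

    The mean uses all paired samples (both replicates). The SD is taken
    after selecting, once per subject, one of the two replicates
    uniformly at random under ``seed`` (n-1 denominator), so duplicate
    samples do not artificially deflate the spread estimate. The
    selection depends only on the seed and the subject order, making it
    reproducible.
    """
    _check_pairs_resolve(m, pairs)
    rep1, rep2 = pairs.replicate_columns()
    mean_beta = m.data[rep1 + rep2].mean(axis=1)
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, size=pairs.n_subjects)
    chosen = [r2 if p else r1 for r1, r2, p in zip(rep1, rep2, pick)]
    sd_beta = m.data[chosen].std(axis=1, ddof=1)
    return mean_beta, sd_beta


def reliability_scan(
    m: BetaMatrix,
    pairs: PairMap,
    scheme: core.ClassificationScheme = core.DEFAULT_SCHEME,
    z: float = core.DEFAULT_Z,
    min_pairs: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-probe reliability table for every probe in the matrix.

    For each probe the complete duplicate pairs are assembled (subjects
    with either replicate missing are dropped, pairwise-complete), and
    the full chain of statistics is computed: ANOVA mean squares ->
    ICC(A,1) -> variance components -> limits of agreement -> modified
    ICC -> classification of both statistics. Probes with fewer than
    ``min_pairs`` complete pairs, or with zero total variance, get
    missing statistics and class "Undefined".

    Returns a DataFrame with the fixed column order
    ``RELIABILITY_COLUMNS``, one row per probe.
    """
    _check_pairs_resolve(m, pairs)
    rep1, rep2 = pairs.replicate_columns()
    a = m.data[rep1].to_numpy(dtype=float)
    b = m.data[rep2].to_numpy(dtype=float)
    subjects = np.asarray(pairs.subjects)
    mean_beta, sd_beta = probe_mean_sd(m, pairs, seed=seed)

    na_stats = {
        "icc": np.nan,
        "sigma_b2": np.nan,
        "sigma_w2": np.nan,
        "sd_diff": np.nan,
        "hola": np.nan,
        "micc": np.nan,
        "class_icc": core.UNDEFINED_LABEL,
        "class_micc": core.UNDEFINED_LABEL,
    }
    records = []
    for i, probe in enumerate(m.probe_ids):
        complete = np.isfinite(a[i]) & np.isfinite(b[i])
        n_complete = int(complete.sum())
        if n_complete < max(min_pairs, 2):
            stats = {"n_pairs": n_complete, **na_stats}
        else:
            dup = core.DuplicateSet(
                np.column_stack([a[i, complete], b[i, complete]]),
                subject_ids=tuple(subjects[complete]),
            )
            stats = core.reliability_statistics(dup, scheme=scheme, z=z)
        records.append(
            {
                "probe_id": probe,
                **stats,
                "mean_beta": mean_beta.iloc[i],
                "sd_beta": sd_beta.iloc[i],
            }
        )
    table = pd.DataFrame.from_records(records, columns=list(RELIABILITY_COLUMNS))
    return table


class ProbeReliabilityModel:
    """Reliability of duplicate measurements across probes.

    Parameters
    ----------
    beta : BetaMatrix
        Probes x samples beta-value matrix.
    pairs : PairMap
        Subject -> replicate-pair mapping into the matrix columns.
    config : RunConfig, optional
        Analysis constants (z multiplier, class bands, filters, seed).

    Examples
    --------
    >>> model = ProbeReliabilityModel.from_frames(beta_df, sheet_df)
    >>> res = model.fit()
    >>> res.table.head()
    >>> print(res.summary())
    """

    def __init__(self, beta: BetaMatrix, pairs: PairMap, config: RunConfig | None = None):
        if not isinstance(beta, BetaMatrix):
            beta = BetaMatrix(beta)
        _check_pairs_resolve(beta, pairs)
        self.beta = beta
        self.pairs = pairs
        self.config = config or RunConfig()

    @classmethod
    def from_frames(
        cls,
        beta: pd.DataFrame,
        sample_sheet: pd.DataFrame,
        config: RunConfig | None = None,
        **overrides,
    ) -> "ProbeReliabilityModel":
        """Build the model from a beta DataFrame and a sample-sheet DataFrame.

        Keyword overrides update individual :class:`RunConfig` fields,
        e.g. ``from_frames(beta, sheet, min_pairs=5, seed=7)``.
        """
        cfg = (config or RunConfig()).replace(**overrides)
        pairs = build_pair_map(sample_sheet, require_cross_plate=cfg.require_cross_plate)
        return cls(BetaMatrix(beta), pairs, cfg)

    def fit(self) -> "ProbeReliabilityResults":
        """Filter probes by missingness and run the reliability scan."""
        cfg = self.config
        filtered, n_removed = filter_probes_by_missingness(self.beta, cfg.max_missing_frac)
        table = reliability_scan(
            filtered,
            self.pairs,
            scheme=cfg.scheme,
            z=cfg.z,
            min_pairs=cfg.min_pairs,
            seed=cfg.seed,
        )
        return ProbeReliabilityResults(model=self, table=table, n_probes_filtered=n_removed)


class ProbeReliabilityResults:
    """Fitted per-probe reliability estimates plus run metadata."""

    def __init__(self, model: ProbeReliabilityModel, table: pd.DataFrame, n_probes_filtered: int):
        self.model = model
        self.table = table
        self.n_probes_filtered = n_probes_filtered
        self.config = model.config
        self.scheme = model.config.scheme

    @property
    def n_probes(self) -> int:
        return len(self.table)

    def class_counts(self, stat: str = "icc") -> pd.Series:
        """Probe counts per reliability band for ``stat`` (icc or micc)."""
        col = {"icc": "class_icc", "micc": "class_micc"}[stat]
        labels = self.scheme.all_labels
        counts = self.table[col].value_counts()
        return counts.reindex(labels, fill_value=0).astype(int)

    def summary(self) -> str:
        """Human-readable run summary: sizes, distribution, class counts."""
        t = self.table
        lines = [
            "Probe reliability of duplicate measurements",
            "=" * 45,
            f"probes analysed:        {self.n_probes}",
            f"probes filtered (miss): {self.n_probes_filtered}",
            f"subject pairs:          {self.model.pairs.n_subjects}",
            f"z multiplier:           {self.config.z}",
            f"seed:                   {self.config.seed}",
            "",
            f"{'stat':<6}{'mean':>10}{'median':>10}{'min':>10}{'max':>10}",
        ]
        for name in ("icc", "micc"):
            v = t[name].dropna()
            if len(v):
                lines.append(
                    f"{name:<6}{v.mean():>10.4f}{v.median():>10.4f}{v.min():>10.4f}{v.max():>10.4f}"
                )
            else:
                lines.append(f"{name:<6}{'NA':>10}{'NA':>10}{'NA':>10}{'NA':>10}")
        lines.append("")
        lines.append(f"{'class':<12}{'by ICC':>10}{'by mICC':>10}")
        ci, cm = self.class_counts("icc"), self.class_counts("micc")
        for label in self.scheme.all_labels:
            lines.append(f"{label:<12}{ci[label]:>10}{cm[label]:>10}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Write the reliability table in the fixed TSV column contract."""
        from .io import write_reliability_table

        write_reliability_table(self.table, path)
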