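"""Run configuration: the tunable constants of a reliability analysis.

Defaults follow the duplicate-sample EPIC-array study design: z = 1.96
for 95% limits of agreement, class cutpoints 0.4 / 0.6 / 0.75, a 5%
probe-missingness filter, and a minimum of 3 complete pairs per probe.
Configs serialize to a flat ``key = value`` text file so that every run
is reproducible from its logged config plus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

from .core import DEFAULT_Z, ClassificationScheme

__all__ = ["RunConfig", "DEFAULT_BETA_BINS"]

#: Mean-beta bin edges for stratified summaries: [0,0.1), ..., [0.9,1].
DEFAULT_BETA_BINS = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class RunConfig:
    """Constants controlling a reliability run.

    Attributes
    ----------
    z : normal quantile for the limits of agreement (HoLA = z * sigma_d).
    cutpoints, labels, boundary_rule : the reliability classification
        bands (see :class:`~dupicc.core.ClassificationScheme`).
    max_missing_frac : probes missing in more than this fraction of
        samples are removed before analysis.
    min_pairs : minimum complete duplicate pairs for a probe to receive
        statistics (below it the probe is reported with missing values).
    seed : seed for the one random step (replicate selection for the
        per-probe SD) and for simulation.
    require_cross_plate : drop subjects whose two replicates share a
        methylation plate (avoids confounding plate effects).
    beta_bins : mean-beta bin edges for stratified summaries.
    """

    z: float = DEFAULT_Z
    cutpoints: tuple[float, ...] = (0.4, 0.6, 0.75)
    labels: tuple[str, ...] = ("Poor", "Fair", "Good", "Excellent")
    boundary_rule: tuple[str, ...] = ("upper", "upper", "lower")
    max_missing_frac: float = 0.05
    min_pairs: int = 3
    seed: int = 0
    require_cross_plate: bool = False
    beta_bins: tuple[float, ...] = DEFAULT_BETA_BINS

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_frac <= 1.0:
            raise ValueError("max_missing_frac must lie in [0, 1]")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be at least 2")
        # validates cutpoints/labels/boundary_rule consistency
        self.scheme  # noqa: B018

    @property
    def scheme(self) -> ClassificationScheme:
        return ClassificationScheme(
            cutpoints=self.cutpoints,
            labels=self.labels,
            boundary_rule=self.boundary_rule,
        )

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    # -- flat key = value serialization ------------------------------------

    def to_file(self, path) -> None:
        lines = []
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {line!r}")
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            val = raw.pop(f.name)
            if f.name in ("cutpoints", "beta_bins"):
                kwargs[f.name] = tuple(float(x) for x in val.split(","))
            elif f.name in ("labels", "boundary_rule"):
                kwargs[f.name] = tuple(x.strip() for x in val.split(","))
            elif f.name == "z" or f.name == "max_missing_frac":
                kwargs[f.name] = float(val)
            elif f.name in ("min_pairs", "seed"):
                kwargs[f.name] = int(val)
            elif f.name == "require_cross_plate":
                kwargs[f.name] = val.lower() in ("1", "true", "yes", "on")
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)
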