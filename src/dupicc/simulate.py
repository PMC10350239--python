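"""Synthetic duplicate beta matrices with known variance components.

Generates paired measurements from the additive model behind the ICC:

    y_pij = clip(mu_p + b_pi + shift_p * 1[j = 2] + e_pij,  eps, 1 - eps)

with subject effects b ~ N(0, sigma_b^2) shared by both replicates and
noise e ~ N(0, sigma_w^2) independent per replicate. The implied true
reliability is sigma_b^2 / (sigma_b^2 + sigma_w^2), so recovered ICCs can
be checked against a closed form. ``shift`` is an additive plate offset
applied to replicate 2 only — the simplest mechanism that reproduces the
empirical observation that cross-plate duplicates are less reliable than
same-plate ones. Clipping to (eps, 1 - eps) keeps values on the beta
scale but biases the statistics for probes near 0 or 1; the generator
warns when more than half the values clip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import DEFAULT_Z
from .model import BetaMatrix, PairMap, build_pair_map

__all__ = ["SyntheticTruth", "SimulatedData", "simulate_duplicates", "expected_hola"]

CLIP_EPS = 1e-6


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-probe generating parameters plus global design constants."""

    mu: np.ndarray
    sigma_b2: np.ndarray
    sigma_w2: np.ndarray
    plate_shift: np.ndarray
    n_subjects: int
    seed: int
    probe_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = None
        for name in ("mu", "sigma_b2", "sigma_w2", "plate_shift"):
            arr = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            object.__setattr__(self, name, arr)
            n = len(arr) if n is None else n
            if len(arr) != n:
                raise ValueError("per-probe parameter arrays must share a length")
        if np.any((self.mu <= 0) | (self.mu >= 1)):
            raise ValueError("probe means must lie strictly inside (0, 1)")
        if np.any(self.sigma_b2 < 0) or np.any(self.sigma_w2 < 0):
            raise ValueError("variances must be non-negative")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        ids = tuple(self.probe_ids) or tuple(f"cg{i:08d}" for i in range(n))
        if len(ids) != n:
            raise ValueError("probe_ids length does not match parameters")
        object.__setattr__(self, "probe_ids", ids)

    @property
    def n_probes(self) -> int:
        return len(self.mu)

    @property
    def true_icc(self) -> np.ndarray:
        """sigma_b^2 / (sigma_b^2 + sigma_w^2); NaN where both are zero."""
        total = self.sigma_b2 + self.sigma_w2
        with np.errstate(invalid="ignore"):
            return np.where(total > 0, self.sigma_b2 / np.where(total > 0, total, 1.0), np.nan)

    @classmethod
    def constant(
        cls,
        n_probes: int,
        n_subjects: int = 69,
        mu: float = 0.5,
        sigma_b2: float = 0.04,
        sigma_w2: float = 0.01,
        plate_shift: float = 0.0,
        seed: int = 0,
    ) -> "SyntheticTruth":
        """All probes share one parameter set.

        Defaults mirror the duplicate study design (69 subject pairs) and
        a mid-range probe with true reliability 0.04 / 0.05 = 0.8.
        """
        ones = np.ones(n_probes)
        return cls(
            mu=mu * ones,
            sigma_b2=sigma_b2 * ones,
            sigma_w2=sigma_w2 * ones,
            plate_shift=plate_shift * ones,
            n_subjects=n_subjects,
            seed=seed,
        )

    def to_frame(self) -> pd.DataFrame:
        """Truth table, one row per probe (for audit / golden files)."""
        return pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "mu": self.mu,
                "sigma_b2": self.sigma_b2,
                "sigma_w2": self.sigma_w2,
                "plate_shift": self.plate_shift,
                "true_icc": self.true_icc,
            }
        )


class SimulatedData(NamedTuple):
    beta: BetaMatrix
    sample_sheet: pd.DataFrame
    pairs: PairMap
    truth: SyntheticTruth


def simulate_duplicates(truth: SyntheticTruth) -> SimulatedData:
    """Draw a duplicate beta matrix and matched sample sheet from ``truth``.

    Deterministic under ``truth.seed``. Replicate 1 samples go on plate
    "P1" and replicate 2 on "P2", so the emitted sheet is cross-plate by
    construction and the plate shift coincides with a replicate-2 offset.
    """
    rng = np.random.default_rng(truth.seed)
    P, N = truth.n_probes, truth.n_subjects
    b = rng.normal(0.0, np.sqrt(truth.sigma_b2)[:, None], size=(P, N))
    e = rng.normal(0.0, np.sqrt(truth.sigma_w2)[:, None, None], size=(P, N, 2))
    y = truth.mu[:, None, None] + b[:, :, None] + e
    y[:, :, 1] += truth.plate_shift[:, None]
    clipped = (y < CLIP_EPS) | (y > 1 - CLIP_EPS)
    frac_clipped = float(clipped.mean())
    if frac_clipped > 0.5:
        warnings.warn(
            f"{frac_clipped:.0%} of simulated values were clipped to [eps, 1-eps]; "
            "generating parameters no longer hold near the boundaries",
            stacklevel=2,
        )
    y = np.clip(y, CLIP_EPS, 1 - CLIP_EPS)

    subjects = [f"subj{i:04d}" for i in range(N)]
    rep1_ids = [f"S{i:04d}R1" for i in range(N)]
    rep2_ids = [f"S{i:04d}R2" for i in range(N)]
    data = pd.DataFrame(
        np.concatenate([y[:, :, 0], y[:, :, 1]], axis=1),
        index=list(truth.probe_ids),
        columns=rep1_ids + rep2_ids,
    )
    sheet = pd.DataFrame(
        {
            "sample_id": rep1_ids + rep2_ids,
            "subject_id": subjects + subjects,
            "replicate": [1] * N + [2] * N,
            "plate": ["P1"] * N + ["P2"] * N,
        }
    ).sort_values(["subject_id", "replicate"], kind="stable", ignore_index=True)
    pairs = build_pair_map(sheet)
    return SimulatedData(beta=BetaMatrix(data), sample_sheet=sheet, pairs=pairs, truth=truth)


def expected_hola(sigma_w2: float, z: float = DEFAULT_Z) -> float:
    """Large-n expectation of HoLA under pure within-subject noise.

    The difference of two replicates has variance 2 * sigma_w^2, so the
    half-width of the limits of agreement converges to z * sqrt(2 * sigma_w^2).
    """
    if sigma_w2 < 0:
        raise ValueError("sigma_w2 must be non-negative")
    return z * float(np.sqrt(2.0 * sigma_w2))
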