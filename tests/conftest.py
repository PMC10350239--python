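"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately use plain-Python loops over the
raw definitions (sums of squares, ranks) so that they stay independent
of the vectorised implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import dupicc


# ---------------------------------------------------------------- oracles

def oracle_mean_squares(pairs: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Brute-force two-way ANOVA mean squares from first principles."""
    n, k = len(pairs), 2
    flat = [v for row in pairs for v in row]
    grand = sum(flat) / (n * k)
    row_means = [sum(row) / k for row in pairs]
    col_means = [sum(row[j] for row in pairs) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((v - grand) ** 2 for v in flat)
    sse = sst - ssr - ssc
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def oracle_icc_a1(pairs: list[tuple[float, float]]) -> float:
    """Absolute-agreement single-measure ICC straight from the mean squares."""
    n, k = len(pairs), 2
    msr, msc, mse = oracle_mean_squares(pairs)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        return math.nan
    return (msr - mse) / denom


def oracle_sample_sd(values: list[float]) -> float:
    """Hand-rolled sample SD with n-1 denominator."""
    n = len(values)
    mean = sum(values) / n
    return math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))


def oracle_spearman(x: list[float], y: list[float]) -> float:
    """Rank (average ties) then Pearson, both by hand."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for t in range(i, j + 1):
                r[order[t]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def random_duplicate_pairs(rng: np.random.Generator, n: int) -> list[tuple[float, float]]:
    return [tuple(row) for row in rng.uniform(0.0, 1.0, size=(n, 2))]


# ---------------------------------------------------------------- fixtures

@pytest.fixture
def toy_pairs():
    """Small hand-checkable duplicate set."""
    return [(0.1, 0.2), (0.4, 0.5), (0.9, 0.7)]


@pytest.fixture
def toy_beta_and_sheet():
    """3 subjects x 2 replicates, 4 probes, one value missing."""
    samples = ["A1", "A2", "B1", "B2", "C1", "C2"]
    data = pd.DataFrame(
        {
            "A1": [0.10, 0.50, 0.30, 0.20],
            "A2": [0.12, 0.52, 0.28, np.nan],
            "B1": [0.40, 0.60, 0.35, 0.25],
            "B2": [0.38, 0.61, 0.36, 0.27],
            "C1": [0.80, 0.70, 0.33, 0.22],
            "C2": [0.82, 0.69, 0.31, 0.21],
        },
        index=["cg01", "cg02", "cg03", "cg04"],
    )
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": ["a", "a", "b", "b", "c", "c"],
            "replicate": [1, 2, 1, 2, 1, 2],
            "plate": ["P1", "P2", "P1", "P2", "P2", "P1"],
        }
    )
    return dupicc.BetaMatrix(data), sheet


@pytest.fixture
def default_scheme():
    return dupicc.DEFAULT_SCHEME
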