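"""Cohort-level summaries and exact tests for junction repair outcomes.

Aggregates per-junction classifications into the standard CSR-junction
readouts: the per-length microhomology spectrum, the three-way partition into
short MH (0-3 nt), long MH (>= 4 nt) and insertions, and the ECS insertion
frequency and size distribution — and compares conditions with a two-tailed
Fisher's exact test (point-probability method: the p-value sums the
hypergeometric probabilities of every table with the observed margins whose
probability does not exceed that of the observed table).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortSummary",
    "ExactTestResult",
    "LabeledTest",
    "summarize",
    "fisher_two_tailed",
    "compare_conditions",
    "ecs_size_distribution",
    "t_test_two_sample",
    "SPECTRUM_BINS",
]

#: microhomology spectrum bins: per-length 0-9, then >= 10 grouped, then the
#: two insertion classes
SPECTRUM_BINS = (
    ["blunt"]
    + [f"mh_{k}" for k in range(1, 10)]
    + ["mh_ge10", "ins_small", "ins_long"]
)


class EmptySummaryError(ValueError):
    """Raised when a summary is requested for an empty cohort."""


@dataclass(frozen=True)
class CohortSummary:
    condition: str
    n_unique: int
    counts: dict[str, int]
    pct: dict[str, float]
    partition3: dict[str, tuple[int, float]]
    ecs_sizes: tuple[int, ...]

    @property
    def n_cnhej(self) -> int:
        return self.partition3["mh_0_3"][0]

    @property
    def n_aej(self) -> int:
        return self.partition3["mh_ge4"][0] + self.partition3["insertion"][0]


@dataclass(frozen=True)
class ExactTestResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_tailed: float
    odds_ratio: float


@dataclass(frozen=True)
class LabeledTest:
    label: str
    result: ExactTestResult
    bonferroni_alpha: float | None = None


def _spectrum_bin(category: str, mh_length: int) -> str:
    if category in ("ins_small", "ins_long"):
        return category
    if mh_length == 0:
        return "blunt"
    if mh_length >= 10:
        return "mh_ge10"
    return f"mh_{mh_length}"


def summarize(classifications: pd.DataFrame, condition: str) -> CohortSummary:
    """Summarise unique-junction classifications for one condition.

    Counts are exact integers over the MH spectrum bins; percentages are
    100*count/n_unique; ``partition3`` coarsens the spectrum into short MH
    (0-3 nt), long MH (>=4 nt) and insertion classes.
    """
    n = len(classifications)
    if n == 0:
        raise EmptySummaryError(f"no junctions to summarise for {condition!r}")
    counts = {b: 0 for b in SPECTRUM_BINS}
    for rec in classifications.itertuples(index=False):
        counts[_spectrum_bin(rec.category, int(rec.mh_length))] += 1
    pct = {b: 100.0 * c / n for b, c in counts.items()}
    n_short = sum(
        counts[b] for b in ["blunt", "mh_1", "mh_2", "mh_3"]
    )
    n_ins = counts["ins_small"] + counts["ins_long"]
    n_long = n - n_short - n_ins
    partition3 = {
        "mh_0_3": (n_short, 100.0 * n_short / n),
        "mh_ge4": (n_long, 100.0 * n_long / n),
        "insertion": (n_ins, 100.0 * n_ins / n),
    }
    ecs_sizes = tuple(
        int(rec.insertion_len)
        for rec in classifications.itertuples(index=False)
        if bool(rec.ecs)
    )
    return CohortSummary(condition, n, counts, pct, partition3, ecs_sizes)


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> ExactTestResult:
    """Two-tailed Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The odds ratio is the sample odds ratio ad/bc with the conventions:
    bc == 0 with ad > 0 gives inf, ad == 0 with bc > 0 gives 0, and a
    doubly degenerate table gives nan.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("all cells must be non-negative")
    n = sum(cells)
    if n == 0:
        raise ValueError("the table is empty")
    # exact integer enumeration over tables with the observed margins: the
    # two-tailed p sums P(k) for every k whose point probability does not
    # exceed the observed one.  Integer numerators make the <= comparison
    # exact (no floating tie tolerance), so p is correct to full precision.
    r1, c1 = a + b, a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    num = {k: comb(c1, k) * comb(n - c1, r1 - k) for k in range(lo, hi + 1)}
    obs = num[a]
    p = sum(v for v in num.values() if v <= obs) / comb(n, r1)
    ad, bc = a * d, b * c
    if bc == 0 and ad == 0:
        odds = float("nan")
    elif bc == 0:
        odds = float("inf")
    else:
        odds = ad / bc
    return ExactTestResult(((a, b), (c, d)), min(p, 1.0), odds)


def compare_conditions(
    summary_a: CohortSummary,
    summary_b: CohortSummary,
    contrast: str = "pathway",
) -> list[LabeledTest]:
    """Exact tests between two condition summaries.

    ``pathway``: one 2x2 test of C-NHEJ vs A-EJ counts between conditions.
    ``per-category``: each spectrum partition category against the rest,
    reporting the raw p alongside the Bonferroni-adjusted alpha.
    """
    if contrast == "pathway":
        res = fisher_two_tailed(
            summary_a.n_cnhej, summary_a.n_aej, summary_b.n_cnhej, summary_b.n_aej
        )
        label = f"{summary_a.condition} vs {summary_b.condition}: C-NHEJ vs A-EJ"
        return [LabeledTest(label, res)]
    if contrast == "per-category":
        cats = [b for b in SPECTRUM_BINS]
        m = len(cats)
        out = []
        for cat in cats:
            a = summary_a.counts[cat]
            b = summary_a.n_unique - a
            c = summary_b.counts[cat]
            d = summary_b.n_unique - c
            out.append(
                LabeledTest(cat, fisher_two_tailed(a, b, c, d), 0.05 / m)
            )
        return out
    raise ValueError(f"unknown contrast {contrast!r}")


def ecs_size_distribution(
    classified: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """ECS frequency and insert sizes per condition.

    Frequency is the fraction of unique junctions flagged as ECS; sizes are
    the insertion lengths of the flagged junctions (one row per condition).
    """
    rows = []
    for condition, df in classified.items():
        n = len(df)
        sizes = sorted(int(s) for s in df.loc[df["ecs"].astype(bool), "insertion_len"])
        rows.append(
            {
                "condition": condition,
                "n_unique": n,
                "n_ecs": len(sizes),
                "ecs_frequency_pct": 100.0 * len(sizes) / n if n else 0.0,
                "ecs_sizes": sizes,
            }
        )
    return pd.DataFrame(rows)


def t_test_two_sample(
    x, y, welch: bool = False
) -> tuple[float, float]:
    """Two-sample Student's t-test on replicate values (Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)
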