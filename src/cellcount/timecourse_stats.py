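"""Group x time statistics for counting time courses.

A stress-induction experiment yields, per treatment group, per field of
view and per time point, a total cell count and a red-fluorescent
(reporter-positive) count.  Because starting red-cell percentages differ
between wells, each field's series is baseline-subtracted (the first value
is subtracted from all subsequent ones) before groups are compared.  The
endpoint comparison takes, per field, the change in red-cell percentage
between the first and last time points and tests every pair of groups with
a two-sided Mann-Whitney rank test, Bonferroni-corrected over the number
of pairs.

The Mann-Whitney implementation uses mid-ranks for ties, reports
``U = min(U_a, U_b)``, and switches between an exact permutation null
(combined sample size <= 12) and a normal approximation with tie and
continuity corrections above that.  The switch point is a fixed documented
rule so results are deterministic across sample sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import rankdata

EXACT_LIMIT = 12  # combined n at or below which the exact null is enumerated


@dataclass(frozen=True)
class TimepointRecord:
    """One field of view at one time point."""

    group: str
    dose: float
    field_of_view: int
    time_index: int
    total_count: float
    red_count: float

    def __post_init__(self) -> None:
        if self.time_index < 0:
            raise ValueError("time_index must be >= 0")

    @property
    def red_pct(self) -> float:
        if self.total_count <= 0:
            raise ValueError("red percentage undefined for non-positive total count")
        return 100.0 * self.red_count / self.total_count


@dataclass(frozen=True)
class PairwiseTest:
    """One Mann-Whitney comparison between two groups."""

    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    p_corrected: float


def baseline_subtract(series: list[float]) -> list[float]:
    """Subtract the initial value from every element (first becomes 0)."""
    if len(series) == 0:
        raise ValueError("series must not be empty")
    first = series[0]
    return [v - first for v in series]


def _u_statistics(sample_a, sample_b) -> tuple[float, float]:
    """(U_a, U_b) from mid-rank sums; ties get averaged ranks."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    n_a, n_b = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    return u_a, n_a * n_b - u_a


def _exact_p(pooled: np.ndarray, n_a: int, u_obs: float) -> float:
    """P(min(U_a, U_b) <= u_obs) by enumerating all group assignments."""
    n = len(pooled)
    ranks = rankdata(pooled)
    total = comb(n, n_a)
    n_b = n - n_a
    hits = 0
    offset = n_a * (n_a + 1) / 2.0
    for combo in itertools.combinations(range(n), n_a):
        u_a = ranks[list(combo)].sum() - offset
        if min(u_a, n_a * n_b - u_a) <= u_obs + 1e-9:
            hits += 1
    return hits / total


def _normal_p(pooled: np.ndarray, n_a: int, n_b: int, u_obs: float) -> float:
    """Two-sided normal approximation with tie and continuity corrections."""
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1.0))
    var = n_a * n_b / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        return 1.0
    z = (u_obs - mu + 0.5) / sqrt(var)  # u_obs <= mu, shift toward the mean
    p = 2.0 * 0.5 * (1.0 + erf(z / sqrt(2.0)))
    return min(1.0, p)


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney test.

    Returns ``(U, p)`` with ``U = min(U_a, U_b)``.  The null distribution
    is enumerated exactly when the combined sample size is at most
    ``EXACT_LIMIT`` (handles ties by permuting mid-ranks); otherwise a
    normal approximation with tie and continuity corrections is used.
    """
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("both samples must be nonempty")
    u_a, u_b = _u_statistics(sample_a, sample_b)
    u = min(u_a, u_b)
    pooled = np.concatenate(
        [np.asarray(sample_a, dtype=np.float64), np.asarray(sample_b, dtype=np.float64)]
    )
    n_a, n_b = len(sample_a), len(sample_b)
    if n_a + n_b <= EXACT_LIMIT:
        p = _exact_p(pooled, n_a, u)
    else:
        p = _normal_p(pooled, n_a, n_b, u)
    return float(u), float(p)


def bonferroni(p_values: list[float], m: int | None = None) -> list[float]:
    """Multiply each p by the number of comparisons (``m`` or the list
    length), capped at 1."""
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
    m = len(p_values) if m is None else m
    return [min(1.0, m * p) for p in p_values]


def endpoint_comparison(records: list[TimepointRecord]) -> list[PairwiseTest]:
    """Pairwise endpoint tests on red-percentage change.

    Per group and field of view, the statistic is the red percentage at the
    last time index minus that at the first time index (baseline
    subtraction collapses to exactly this difference at the endpoint).
    Every pair of groups is compared with :func:`mann_whitney_u` and the
    p-values are Bonferroni-corrected over the number of pairs.
    """
    if not records:
        raise ValueError("no records given")
    groups: dict[str, dict[int, dict[int, TimepointRecord]]] = {}
    for rec in records:
        groups.setdefault(rec.group, {}).setdefault(rec.field_of_view, {})[
            rec.time_index
        ] = rec

    deltas: dict[str, list[float]] = {}
    first_t = min(r.time_index for r in records)
    last_t = max(r.time_index for r in records)
    for group, fields in groups.items():
        vals = []
        for fov, by_time in sorted(fields.items()):
            if first_t not in by_time or last_t not in by_time:
                raise ValueError(
                    f"group {group!r} field {fov} lacks time index "
                    f"{first_t} or {last_t}"
                )
            vals.append(by_time[last_t].red_pct - by_time[first_t].red_pct)
        deltas[group] = vals

    pairs = list(itertools.combinations(sorted(deltas), 2))
    raw = []
    for g1, g2 in pairs:
        u, p = mann_whitney_u(deltas[g1], deltas[g2])
        raw.append((g1, g2, u, p))
    corrected = bonferroni([p for *_, p in raw])
    return [
        PairwiseTest(group_a=g1, group_b=g2, u_statistic=u, p_value=p, p_corrected=pc)
        for (g1, g2, u, p), pc in zip(raw, corrected)
    ]


# -- tidy I/O ---------------------------------------------------------------

def assemble_records(
    counts: pd.DataFrame, sample_sheet: pd.DataFrame
) -> list[TimepointRecord]:
    """Join batch counting output with a sample sheet into tidy records.

    ``counts`` needs columns ``path, cell_count, red_count``; the sheet
    maps ``path`` to ``group, dose, field_of_view, time_index``.
    """
    merged = counts.merge(sample_sheet, on="path", how="inner")
    if merged.empty:
        raise ValueError("no overlapping paths between counts and sample sheet")
    return [
        TimepointRecord(
            group=str(row.group),
            dose=float(row.dose),
            field_of_view=int(row.field_of_view),
            time_index=int(row.time_index),
            total_count=float(row.cell_count),
            red_count=float(row.red_count),
        )
        for row in merged.itertuples()
    ]


def records_to_frame(records: list[TimepointRecord]) -> pd.DataFrame:
    """Long-format table of records, with the derived red percentage."""
    return pd.DataFrame(
        {
            "group": [r.group for r in records],
            "dose": [r.dose for r in records],
            "field_of_view": [r.field_of_view for r in records],
            "time_index": [r.time_index for r in records],
            "total_count": [r.total_count for r in records],
            "red_count": [r.red_count for r in records],
            "red_pct": [r.red_pct for r in records],
        }
    )


def tests_to_frame(tests: list[PairwiseTest]) -> pd.DataFrame:
    """Pairwise tests as a table (group pair, U, raw and corrected p)."""
    return pd.DataFrame(
        {
            "group_1": [t.group_a for t in tests],
            "group_2": [t.group_b for t in tests],
            "u_statistic": [t.u_statistic for t in tests],
            "p_value": [t.p_value for t in tests],
            "corrected_p_value": [t.p_corrected for t in tests],
        }
    )
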