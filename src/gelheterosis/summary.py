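"""Pattern tallies, spot-phenotype correlation, and report tables."""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .heterosis import PATTERN_LABELS, HeterosisCall

NONADDITIVE_LABELS = tuple(p for p in PATTERN_LABELS if p != "A")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class PatternTally:
    """Counts and shares of the six heterotic patterns.

    Shares are kept both as raw fractions and as integers rounded half-up,
    the style in which such surveys are usually reported ("about 57%").
    """

    counts: dict[str, int]
    total: int
    additive_count: int
    nonadditive_count: int
    share_of_total: dict[str, float]
    share_of_nonadditive: dict[str, float]

    def share_of_total_pct(self, label: str) -> int:
        return _round_half_up(100.0 * self.share_of_total[label])

    def share_of_nonadditive_pct(self, label: str) -> int:
        return _round_half_up(100.0 * self.share_of_nonadditive[label])

    @property
    def additive_share_pct(self) -> int:
        return _round_half_up(100.0 * self.additive_count / self.total) if self.total else 0


def tally_patterns(calls: Iterable[HeterosisCall | str]) -> PatternTally:
    """Exact integer counts of pattern labels (accepts calls or bare labels)."""
    counts = {p: 0 for p in PATTERN_LABELS}
    for c in calls:
        label = c.pattern if isinstance(c, HeterosisCall) else str(c)
        if label not in counts:
            raise DomainError(f"unknown pattern label {label!r}")
        counts[label] += 1
    total = sum(counts.values())
    additive = counts["A"]
    nonadd = total - additive
    share_total = {p: (counts[p] / total if total else 0.0) for p in PATTERN_LABELS}
    share_nonadd = {
        p: (counts[p] / nonadd if nonadd else 0.0) for p in NONADDITIVE_LABELS
    }
    return PatternTally(counts, total, additive, nonadd, share_total, share_nonadd)


def tally_to_frame(tally: PatternTally) -> pd.DataFrame:
    """Report view of a tally: one row per pattern, raw and rounded shares."""
    rows = []
    for p in PATTERN_LABELS:
        rows.append(
            {
                "pattern": p,
                "count": tally.counts[p],
                "share_of_total": tally.share_of_total[p],
                "share_of_total_pct": tally.share_of_total_pct(p),
                "share_of_nonadditive": (
                    tally.share_of_nonadditive.get(p, float("nan"))
                ),
                "share_of_nonadditive_pct": (
                    tally.share_of_nonadditive_pct(p) if p != "A" else ""
                ),
            }
        )
    return pd.DataFrame(rows)


def correlate_with_phenotype(
    spot_series: Sequence[float], phenotype_series: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between a spot's per-stage mean
    intensities and the per-stage phenotype means."""
    x = np.asarray(spot_series, dtype=float)
    y = np.asarray(phenotype_series, dtype=float)
    if x.shape != y.shape:
        raise DomainError("series must have equal length")
    if x.size < 3:
        raise DomainError("correlation needs at least three paired stages")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DomainError("zero-variance series: correlation undefined")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)
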