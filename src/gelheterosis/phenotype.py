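"""Seed-setting-rate statistics: rates, stage-course ANOVA, Fisher-LSD letters.

Seed setting rate is the fraction of spikelets in the ear mid-base region
(rounds 5-15 from the base) that carry fully grown seed after saturation
pollination; it is the phenotype through which silk viability is scored.
Rates are analyzed on the raw proportion scale (no arcsine transform), a
documented simplification.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import AnovaResult, one_way_anova
from .errors import DegenerateVarianceError, DomainError, ValidationError


@dataclasses.dataclass(frozen=True)
class LsdGrouping:
    """Compact-letter display of Fisher's LSD multiple comparison.

    ``letters[i]`` is the (sorted) letter string of group ``i`` in input
    order; groups sharing any letter do not differ by more than their LSD.
    ``lsd_value`` is the threshold for the first pair of group sizes
    (informational; unbalanced designs use per-pair thresholds internally).
    """

    means: tuple[float, ...]
    letters: tuple[str, ...]
    lsd_value: float
    alpha: float


def seed_setting_rate(filled_seeds, total_spikelets):
    """filled / total, elementwise; validates 0 <= filled <= total, total > 0."""
    filled = np.asarray(filled_seeds, dtype=float)
    total = np.asarray(total_spikelets, dtype=float)
    if (total <= 0).any():
        raise ValidationError("total_spikelets must be positive")
    if ((filled < 0) | (filled > total)).any():
        raise ValidationError("filled_seeds must lie in [0, total_spikelets]")
    rate = filled / total
    return float(rate) if rate.ndim == 0 else rate


def seedset_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Append a ``rate`` column to a validated seed-set table."""
    out = table.copy()
    out["rate"] = seed_setting_rate(out["filled_seeds"], out["total_spikelets"])
    return out


def _pooled_mse(groups: list[np.ndarray]) -> tuple[float, int]:
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_within = sum(g.size for g in groups) - len(groups)
    if ss_within == 0.0:
        raise DegenerateVarianceError("pooled within-group variance is zero")
    return ss_within / df_within, df_within


def lsd_letters(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> LsdGrouping:
    """Fisher-LSD compact letter display over ``k >= 2`` replicate samples.

    The pairwise threshold is ``t(1 - alpha/2, df_within) *
    sqrt(MSE * (1/n_i + 1/n_j))`` with MSE pooled over all groups. Letters are
    assigned by the standard descending-mean sweep: start a new letter at the
    largest still-unlettered mean and extend it to every mean within LSD of
    that leader, repeating until all groups carry a letter. Assignment is
    deterministic for a fixed input order.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise DomainError("lsd_letters requires at least two groups")
    if any(a.size < 2 for a in arrs):
        raise DomainError("every group needs >= 2 replicates")
    mse, dfw = _pooled_mse(arrs)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, dfw)
    means = np.array([a.mean() for a in arrs])
    ns = np.array([a.size for a in arrs])

    def lsd(i: int, j: int) -> float:
        return tcrit * np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))

    order = np.argsort(-means, kind="stable")  # largest mean first
    letters: list[set[str]] = [set() for _ in arrs]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    next_letter = 0
    for leader in order:
        if letters[leader]:
            continue
        letter = alphabet[next_letter]
        next_letter += 1
        for j in order:
            if abs(means[leader] - means[j]) <= lsd(leader, j):
                letters[j].add(letter)
    return LsdGrouping(
        means=tuple(float(m) for m in means),
        letters=tuple("".join(sorted(s)) for s in letters),
        lsd_value=float(lsd(0, 1)),
        alpha=alpha,
    )


def stage_course_anova(seedset: pd.DataFrame, genotype: str) -> AnovaResult:
    """One-way ANOVA of replicate seed-setting rates across stages for one
    genotype (>= 2 stages with >= 2 replicates each)."""
    sub = seedset_rates(seedset[seedset["genotype"] == genotype])
    if sub.empty:
        raise ValidationError(f"genotype {genotype!r} not present in seed-set table")
    groups = [g["rate"].to_numpy() for _, g in sub.groupby("stage", sort=False)]
    return one_way_anova(groups)
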