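"""Differential-accumulation screening of normalized spot intensities.

Two screens are implemented, mirroring the two arms of the study design:

* **inbred time-course** — within one genotype, a spot is differential when
  its replicate profiles share the same stage-to-stage trend, one-way ANOVA
  across stages is significant, and the max/min ratio of stage means exceeds
  ``fc_inbred`` (default 1.5, strictly);
* **triad** — at one stage, a spot is differential between an F1 hybrid and
  its two parents when ANOVA across the three genotypes is significant and the
  max/min ratio of genotype means exceeds ``fc_triad`` (default 2, strictly).

No multiple-testing correction is applied across spots; the screens use the
raw per-spot p-value against ``alpha``, a deliberate fidelity choice that is
documented as a statistical limitation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .config import AnalysisConfig
from .errors import DegenerateVarianceError, DomainError, ValidationError
from .heterosis import TriadDesign


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    """Classical fixed-effects one-way ANOVA summary."""

    f_stat: float
    p_value: float
    df_between: int
    df_within: int


@dataclasses.dataclass(frozen=True)
class DifferentialCall:
    """Outcome of one spot's screening test.

    ``context`` is ``"inbred"`` or ``"triad"``; ``trend_ok`` is None in the
    triad context where the same-trend rule does not apply.
    """

    spot_id: str
    context: str
    max_fold: float
    p_value: float
    trend_ok: bool | None
    passed: bool


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA over ``k >= 2`` groups of ``n >= 2`` values.

    The F statistic and p-value match :func:`scipy.stats.f_oneway`; the sums
    of squares are formed explicitly so the degrees of freedom can be reported
    and the degenerate all-zero-within-variance case diagnosed.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise DomainError("one_way_anova requires at least two groups")
    if any(a.size < 2 for a in arrs):
        raise DomainError("every group must contain at least two observations")
    n_total = sum(a.size for a in arrs)
    k = len(arrs)
    grand = np.concatenate(arrs).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs)
    df_between = k - 1
    df_within = n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            # every observation identical: no evidence of any difference
            return AnovaResult(0.0, 1.0, df_between, df_within)
        raise DegenerateVarianceError(
            "zero within-group variance in every group; F is undefined"
        )
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(float(f), p, df_between, df_within)


def max_fold_change(group_means: Sequence[float]) -> float:
    """max(means) / min(means) over >= 2 strictly positive group means."""
    means = np.asarray(group_means, dtype=float)
    if means.size < 2:
        raise DomainError("max_fold_change requires at least two group means")
    if (means <= 0).any():
        raise DomainError(f"group means must be strictly positive, got {means}")
    return float(means.max() / means.min())


def _trend_signs(profile: np.ndarray, epsilon: float) -> np.ndarray:
    """Sign (+1/0/-1) of each consecutive stage change; |delta| <= epsilon *
    mean(pair) counts as flat."""
    a, b = profile[:-1], profile[1:]
    delta = b - a
    flat = np.abs(delta) <= epsilon * (a + b) / 2.0
    return np.where(flat, 0, np.sign(delta)).astype(int)


def same_trend(replicate_profiles: Sequence[Sequence[float]], epsilon: float = 0.02) -> bool:
    """True iff every replicate shows the identical up/flat/down sign pattern
    across consecutive stages.

    ``replicate_profiles`` is a replicate-major matrix whose columns are the
    ordered stages. A change is flat when its magnitude is within ``epsilon``
    (relative, against the mean of the two stage values).
    """
    mat = np.asarray(replicate_profiles, dtype=float)
    if mat.ndim != 2:
        raise DomainError("replicate_profiles must be a replicate x stage matrix")
    if mat.shape[1] < 2:
        raise DomainError("same_trend needs at least two stages")
    signs = np.stack([_trend_signs(row, epsilon) for row in mat])
    return bool((signs == signs[0]).all())


def _spot_groups(table, spot_id, group_col, group_values, value_filter=None):
    """Replicate vectors for one spot, one per value of ``group_col``,
    ordered as ``group_values`` and sorted by replicate index within each."""
    sub = table[table["spot_id"] == spot_id]
    if value_filter is not None:
        sub = value_filter(sub)
    out = []
    for gv in group_values:
        vals = sub[sub[group_col] == gv].sort_values("replicate")["intensity"].to_numpy()
        if vals.size == 0:
            raise ValidationError(f"spot {spot_id}: no observations for {group_col}={gv}")
        out.append(vals)
    return out


def select_inbred_differential(
    table,
    genotype: str,
    stages: Sequence[str],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[DifferentialCall]:
    """Screen every spot of one inbred line across its ordered stages.

    A spot passes iff the replicate same-trend rule holds, the across-stage
    ANOVA p-value is below ``config.alpha``, and the max/min ratio of stage
    means strictly exceeds ``config.fc_inbred``.
    """
    sub = table[table["genotype"] == genotype]
    if sub.empty:
        raise ValidationError(f"genotype {genotype!r} not present in table")
    calls = []
    for spot_id, spot_df in sub.groupby("spot_id", sort=True):
        groups = []
        profiles = {}
        for stage in stages:
            g = spot_df[spot_df["stage"] == stage].sort_values("replicate")
            if g.empty:
                raise ValidationError(f"spot {spot_id}: stage {stage} missing")
            groups.append(g["intensity"].to_numpy())
            for rep, val in zip(g["replicate"], g["intensity"]):
                profiles.setdefault(rep, []).append(val)
        trend_ok = same_trend(list(profiles.values()), config.trend_epsilon)
        anova = one_way_anova(groups)
        fold = max_fold_change([g.mean() for g in groups])
        passed = trend_ok and anova.p_value < config.alpha and fold > config.fc_inbred
        calls.append(
            DifferentialCall(str(spot_id), "inbred", fold, anova.p_value, trend_ok, passed)
        )
    return calls


def select_triad_differential(
    table,
    triad: TriadDesign,
    stage: str,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[DifferentialCall]:
    """Screen every spot between an F1 and its two parents at one stage.

    A spot passes iff the three-genotype ANOVA p-value is below
    ``config.alpha`` and the max/min ratio of the three genotype means
    strictly exceeds ``config.fc_triad``. The same-trend rule does not apply
    to this screen.
    """
    genos = [triad.parent_a, triad.parent_b, triad.f1]
    sub = table[(table["genotype"].isin(genos)) & (table["stage"] == stage)]
    if sub.empty:
        raise ValidationError(f"no data for triad {genos} at stage {stage!r}")
    calls = []
    for spot_id, spot_df in sub.groupby("spot_id", sort=True):
        groups = []
        for g in genos:
            vals = spot_df[spot_df["genotype"] == g].sort_values("replicate")[
                "intensity"
            ].to_numpy()
            if vals.size == 0:
                raise ValidationError(f"spot {spot_id}: genotype {g} missing at {stage}")
            groups.append(vals)
        anova = one_way_anova(groups)
        fold = max_fold_change([g.mean() for g in groups])
        passed = anova.p_value < config.alpha and fold > config.fc_triad
        calls.append(
            DifferentialCall(str(spot_id), "triad", fold, anova.p_value, None, passed)
        )
    return calls


def calls_to_frame(calls: Sequence[DifferentialCall]):
    """Tidy DataFrame view of a list of calls (for reports)."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(c) for c in calls],
                        columns=[f.name for f in dataclasses.fields(DifferentialCall)])
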