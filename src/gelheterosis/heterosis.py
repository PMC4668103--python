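"""Six-way heterotic-pattern classification and mid-parent heterosis.

Given replicate measurements of an F1 hybrid and its two inbred parents, each
protein spot (or any quantitative trait) is assigned exactly one inheritance
pattern:

========  ==========================================================
label     meaning
========  ==========================================================
``A``     additive — F1 not significantly different from the
          mid-parent value (MP = mean of the parental means)
``+``     high-parent-like (dominant toward the larger parent)
``-``     low-parent-like (dominant toward the smaller parent)
``++``    over-dominant — significantly above the high parent
``--``    under-dominant — significantly below the low parent
``+-``    partially dominant — significantly different from MP, HP
          and LP, lying strictly between the parents
========  ==========================================================

The MP comparison is a two-sample t-test of F1 replicates against
per-replicate mid-parent pseudovalues (p1_i + p2_i)/2, which keeps a variance
estimate on both sides of the test. Welch's unequal-variance t is the default
throughout; the pooled-variance form is available via ``equal_var=True``.

Mid-parent heterosis degree is the classical percentage
``MPH = 100 * (F1 - MP) / MP``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceError, DomainError, ValidationError

PATTERN_LABELS = ("A", "+", "-", "++", "--", "+-")


@dataclasses.dataclass(frozen=True)
class TriadDesign:
    """Which genotype is the F1 and which two are its parents."""

    f1: str
    parent_a: str
    parent_b: str
    stages: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len({self.f1, self.parent_a, self.parent_b}) != 3:
            raise ValidationError(
                f"triad genotypes must be distinct: {self.f1}, {self.parent_a}, {self.parent_b}"
            )


@dataclasses.dataclass(frozen=True)
class TriadMeasurements:
    """Replicate intensity vectors for one spot in one triad at one stage."""

    p1_reps: tuple[float, ...]
    p2_reps: tuple[float, ...]
    f1_reps: tuple[float, ...]
    spot_id: str = ""
    stage: str = ""

    def __post_init__(self) -> None:
        for name in ("p1_reps", "p2_reps", "f1_reps"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.size < 2:
                raise ValidationError(f"{name} needs >= 2 replicates, got {v.size}")
            if (v < 0).any():
                raise ValidationError(f"{name} contains negative intensities")


@dataclasses.dataclass(frozen=True)
class HeterosisCall:
    """One spot's pattern together with the three underlying p-values and the
    group means that drove the decision."""

    pattern: str
    p_mp: float
    p_hp: float
    p_lp: float
    mp: float
    hp: float
    lp: float
    f1_mean: float
    spot_id: str = ""
    stage: str = ""


@dataclasses.dataclass(frozen=True)
class MphResult:
    """Mid-parent heterosis degree, in percent of the mid-parent value."""

    mph_percent: float
    f1_mean: float
    mp: float


def midparent_pseudovalues(
    p1_reps: Sequence[float], p2_reps: Sequence[float]
) -> np.ndarray:
    """Element-wise parental means, paired by replicate index.

    The mean of the output equals the mid-parent value of the parental means,
    so a two-sample test of F1 replicates against these pseudovalues is a test
    against MP that retains replicate-to-replicate variation.
    """
    a = np.asarray(p1_reps, dtype=float)
    b = np.asarray(p2_reps, dtype=float)
    if a.shape != b.shape:
        raise DomainError(
            "parental replicate vectors must have equal length; pair replicates "
            f"explicitly before calling (got {a.size} and {b.size})"
        )
    return (a + b) / 2.0


def _welch_or_pooled_t(x: np.ndarray, y: np.ndarray, equal_var: bool) -> float:
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if np.isclose(x.mean(), y.mean()):
            return 1.0  # identical constants: no evidence of difference
        raise DegenerateVarianceError(
            "both samples have zero variance but different means; t is undefined"
        )
    return float(stats.ttest_ind(x, y, equal_var=equal_var).pvalue)


def classify_pattern(
    triad: TriadMeasurements, alpha: float = 0.05, equal_var: bool = False
) -> HeterosisCall:
    """Assign one of the six heterotic patterns to a triad of measurements.

    Decision procedure (HP/LP = larger/smaller parental mean; all tests
    two-sided at ``alpha``):

    1. F1 vs mid-parent pseudovalues not significant -> ``A``;
    2. else, significantly different from the HP parent *and* above it -> ``++``;
    3. else, significantly different from the LP parent *and* below it -> ``--``;
    4. else, not significantly different from HP -> ``+``;
    5. else, not significantly different from LP -> ``-``;
    6. else -> ``+-`` (differs from MP, HP and LP; strictly between parents).

    When the parental means coincide exactly (HP = LP = MP) there is no
    "between the parents", so any significant deviation is called ``++``
    above or ``--`` below the common parental mean.
    """
    p1 = np.asarray(triad.p1_reps, dtype=float)
    p2 = np.asarray(triad.p2_reps, dtype=float)
    f1 = np.asarray(triad.f1_reps, dtype=float)
    m1, m2 = p1.mean(), p2.mean()
    if m1 >= m2:
        hp_reps, lp_reps, hp, lp = p1, p2, m1, m2
    else:
        hp_reps, lp_reps, hp, lp = p2, p1, m2, m1
    pseudo = midparent_pseudovalues(p1, p2)
    mp = float(pseudo.mean())
    f1_mean = float(f1.mean())

    p_mp = _welch_or_pooled_t(f1, pseudo, equal_var)
    p_hp = _welch_or_pooled_t(f1, hp_reps, equal_var)
    p_lp = _welch_or_pooled_t(f1, lp_reps, equal_var)

    if p_mp >= alpha:
        pattern = "A"
    elif hp == lp:
        pattern = "++" if f1_mean > hp else "--"
    elif p_hp < alpha and f1_mean > hp:
        pattern = "++"
    elif p_lp < alpha and f1_mean < lp:
        pattern = "--"
    elif p_hp >= alpha:
        pattern = "+"
    elif p_lp >= alpha:
        pattern = "-"
    else:
        pattern = "+-"

    return HeterosisCall(
        pattern=pattern, p_mp=p_mp, p_hp=p_hp, p_lp=p_lp,
        mp=mp, hp=float(hp), lp=float(lp), f1_mean=f1_mean,
        spot_id=triad.spot_id, stage=triad.stage,
    )


def mph_percent(f1_mean: float, p1_mean: float, p2_mean: float) -> MphResult:
    """Mid-parent heterosis degree 100 * (F1 - MP) / MP.

    Reported values are conventionally rounded to one decimal; the raw value
    is returned here and rounding is left to the report writer.
    """
    if p1_mean < 0 or p2_mean < 0:
        raise DomainError("parental means must be non-negative")
    mp = (p1_mean + p2_mean) / 2.0
    if mp <= 0:
        raise DomainError("mid-parent value is zero; MPH undefined")
    return MphResult(100.0 * (f1_mean - mp) / mp, float(f1_mean), float(mp))


def classify_table(
    table,
    triad: TriadDesign,
    stage: str,
    alpha: float = 0.05,
    equal_var: bool = False,
    spot_ids: Sequence[str] | None = None,
) -> list[HeterosisCall]:
    """Classify every spot (or the given subset) of a normalized long table
    for one triad at one stage."""
    sub = table[table["stage"] == stage]
    if spot_ids is None:
        spot_ids = sorted(sub["spot_id"].unique())
    calls = []
    for spot in spot_ids:
        sd = sub[sub["spot_id"] == spot]
        vecs = {}
        for g in (triad.parent_a, triad.parent_b, triad.f1):
            v = sd[sd["genotype"] == g].sort_values("replicate")["intensity"].to_numpy()
            if v.size < 2:
                raise ValidationError(f"spot {spot}: genotype {g} has <2 replicates at {stage}")
            vecs[g] = tuple(v)
        tm = TriadMeasurements(
            p1_reps=vecs[triad.parent_a], p2_reps=vecs[triad.parent_b],
            f1_reps=vecs[triad.f1], spot_id=str(spot), stage=stage,
        )
        calls.append(classify_pattern(tm, alpha=alpha, equal_var=equal_var))
    return calls
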