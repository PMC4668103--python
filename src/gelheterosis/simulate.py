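"""Synthetic replicate-level datasets with known truth labels.

The generators emulate the statistical structure the analysis assumes: triads
(two inbred parents + F1) and inbred time-courses measured with three
biological replicates, multiplicative (log-normal) replicate noise, and
spot-level inheritance architectures planted at known effect sizes. They exist
so that every pipeline stage can be exercised and its recovery measured
without any external data.

Noise model: a replicate of a spot with true mean ``m`` is drawn as
``m * exp(sigma * Z)`` with ``sigma = ln(1 + cv)``, the usual first-order
log-normal stand-in for a coefficient of variation ``cv``; densitometry is
positive and right-skewed, which a multiplicative model captures and an
additive one does not. ``cv = 0`` reproduces the true means exactly.

F1 placement per planted pattern (MP/HP/LP from the two parental means):
``A`` at MP, ``+`` at HP, ``-`` at LP, ``++`` at 1.6 x HP, ``--`` at
0.6 x LP, ``+-`` midway between MP and HP; ``null`` puts all three genotypes
at the same mean (for type-I-error measurement).

Every generated gel additionally carries an invariant high-abundance
*background*: real 2-DE gels are dominated by bulk proteome spots that do not
change between genotypes or stages, which is exactly the premise that makes
"total quantity in valid spots" normalization valid. Without this background
the planted differential spots would themselves move each gel's total and the
normalization step would systematically distort the planted effects. The
background is collapsed into ``n_background_spots`` spots sharing a fixed
``background_total`` volume (so the planted spots stay a few percent of each
gel, as on a real gel); background rows are labelled ``"background"`` in the
truth table.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .heterosis import PATTERN_LABELS, TriadDesign

TRIAD_CLASSES = PATTERN_LABELS + ("null",)


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for the synthetic triad / time-course tables.

    ``n_spots_per_class`` maps a planted class (a pattern label, ``"null"``,
    or for time-courses ``"changing"``/``"null"``) to a spot count. The
    default parental means put a 3-fold effect between the parents; replicate
    CV defaults to 5% with three biological replicates, matching the design
    the analysis is built for.
    """

    n_spots_per_class: Mapping[str, int]
    parent_low_mean: float = 100.0
    parent_high_mean: float = 300.0
    cv: float = 0.05
    n_replicates: int = 3
    stages: tuple[str, ...] = ("D8", "D10", "D12")
    seed: int = 0
    overdominance_factor: float = 1.6
    underdominance_factor: float = 0.6
    inbred_fold: float = 3.0
    n_background_spots: int = 50
    background_total: float = 5e6

    def __post_init__(self) -> None:
        if self.n_background_spots < 0 or self.background_total < 0:
            raise ValidationError("background parameters must be >= 0")
        if any(n < 0 for n in self.n_spots_per_class.values()):
            raise ValidationError("spot counts must be >= 0")
        if self.cv < 0:
            raise ValidationError("cv must be >= 0")
        if not 0 < self.parent_low_mean <= self.parent_high_mean:
            raise ValidationError("need parent_high_mean >= parent_low_mean > 0")
        if self.n_replicates < 2:
            raise ValidationError("need at least two replicates")
        if not self.stages:
            raise ValidationError("at least one stage required")
        if self.inbred_fold <= 1:
            raise ValidationError("inbred_fold must exceed 1")


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    sigma = np.log1p(cv)
    return np.exp(sigma * rng.standard_normal(size))


def _append_background(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    rows: list,
    labels: list,
    genotypes,
    start_no: int,
) -> None:
    """Invariant bulk-proteome spots shared by every gel (see module docs)."""
    if spec.n_background_spots == 0:
        return
    mean = spec.background_total / spec.n_background_spots
    for i in range(spec.n_background_spots):
        spot_id = f"bkg{start_no + i:05d}"
        labels.append(
            {"spot_id": spot_id, "planted_class": "background", "planted_fold": 1.0}
        )
        for stage in spec.stages:
            for geno in genotypes:
                noise = _noise_factors(rng, spec.cv, spec.n_replicates)
                for rep in range(1, spec.n_replicates + 1):
                    rows.append((spot_id, geno, stage, rep, mean * noise[rep - 1]))


def _f1_mean(pattern: str, lp: float, hp: float, spec: SyntheticSpec) -> float:
    mp = (lp + hp) / 2.0
    placement = {
        "A": mp,
        "+": hp,
        "-": lp,
        "++": hp * spec.overdominance_factor,
        "--": lp * spec.underdominance_factor,
        "+-": (mp + hp) / 2.0,
    }
    return placement[pattern]


def generate_triads(
    spec: SyntheticSpec, triad: TriadDesign | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long spot-intensity table for a parent/parent/F1 triad plus truth labels.

    Returns ``(table, labels)``: the table holds every (spot, genotype, stage,
    replicate) intensity; labels hold one row per spot with its planted
    pattern and the planted max/min fold across the three genotype means.
    """
    unknown = set(spec.n_spots_per_class) - set(TRIAD_CLASSES)
    if unknown:
        raise ValidationError(f"unknown triad classes: {sorted(unknown)}")
    if triad is None:
        triad = TriadDesign("F1", "P_low", "P_high", spec.stages)
    rng = np.random.default_rng(spec.seed)
    lp, hp = spec.parent_low_mean, spec.parent_high_mean

    rows, labels = [], []
    spot_no = 0
    for cls in TRIAD_CLASSES:  # fixed class order => reproducible spot ids
        for _ in range(spec.n_spots_per_class.get(cls, 0)):
            spot_no += 1
            spot_id = f"spot{spot_no:05d}"
            if cls == "null":
                means = {triad.parent_a: lp, triad.parent_b: lp, triad.f1: lp}
            else:
                means = {
                    triad.parent_a: lp,
                    triad.parent_b: hp,
                    triad.f1: _f1_mean(cls, lp, hp, spec),
                }
            planted_fold = max(means.values()) / min(means.values())
            labels.append(
                {"spot_id": spot_id, "planted_class": cls, "planted_fold": planted_fold}
            )
            for stage in spec.stages:
                for geno, m in means.items():
                    noise = _noise_factors(rng, spec.cv, spec.n_replicates)
                    for rep in range(1, spec.n_replicates + 1):
                        rows.append(
                            (spot_id, geno, stage, rep, m * noise[rep - 1])
                        )
    _append_background(
        spec, rng, rows, labels,
        (triad.parent_a, triad.parent_b, triad.f1), spot_no + 1,
    )
    table = pd.DataFrame(
        rows, columns=["spot_id", "genotype", "stage", "replicate", "intensity"]
    )
    return table, pd.DataFrame(labels)


def generate_stage_course(
    spec: SyntheticSpec, genotype: str = "L1"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long table for one inbred line's time-course plus truth labels.

    ``"changing"`` spots follow a monotone geometric trend spanning
    ``spec.inbred_fold`` across the ordered stages (alternating risers and
    fallers); ``"null"`` spots are flat. Noise as in :func:`generate_triads`.
    """
    unknown = set(spec.n_spots_per_class) - {"changing", "null"}
    if unknown:
        raise ValidationError(f"unknown time-course classes: {sorted(unknown)}")
    if len(spec.stages) < 2:
        raise ValidationError("a time-course needs at least two stages")
    rng = np.random.default_rng(spec.seed)
    base = spec.parent_low_mean
    n_stages = len(spec.stages)
    expo = np.arange(n_stages) / (n_stages - 1)

    rows, labels = [], []
    spot_no = 0
    for cls in ("changing", "null"):
        for i in range(spec.n_spots_per_class.get(cls, 0)):
            spot_no += 1
            spot_id = f"spot{spot_no:05d}"
            if cls == "null":
                means = np.full(n_stages, base)
                direction, fold = "flat", 1.0
            elif i % 2 == 0:
                means = base * spec.inbred_fold ** expo
                direction, fold = "up", spec.inbred_fold
            else:
                means = base * spec.inbred_fold ** (-expo)
                direction, fold = "down", spec.inbred_fold
            labels.append(
                {
                    "spot_id": spot_id,
                    "planted_class": cls,
                    "planted_trend": direction,
                    "planted_fold": fold,
                }
            )
            for s, stage in enumerate(spec.stages):
                noise = _noise_factors(rng, spec.cv, spec.n_replicates)
                for rep in range(1, spec.n_replicates + 1):
                    rows.append((spot_id, genotype, stage, rep, means[s] * noise[rep - 1]))
    _append_background(spec, rng, rows, labels, (genotype,), spot_no + 1)
    table = pd.DataFrame(
        rows, columns=["spot_id", "genotype", "stage", "replicate", "intensity"]
    )
    return table, pd.DataFrame(labels)


def generate_seedset(
    profiles: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    ears_per_replicate: int = 10,
    spikelets_per_ear: int = 176,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicate-level seed-set table from per-genotype per-stage true rates.

    Each replicate is a pool of ``ears_per_replicate`` ears; filled seeds are
    binomial draws per ear at the true rate, aggregated per replicate. The
    default 176 spikelets per ear reflects the scored mid-base region (rounds
    5-15, ~16 kernels per round).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for geno, stages in profiles.items():
        for stage, rate in stages.items():
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"rate for ({geno}, {stage}) outside [0, 1]: {rate}")
            for rep in range(1, n_replicates + 1):
                filled = int(
                    rng.binomial(spikelets_per_ear, rate, size=ears_per_replicate).sum()
                )
                rows.append(
                    (geno, stage, rep, filled, spikelets_per_ear * ears_per_replicate)
                )
    return pd.DataFrame(
        rows,
        columns=["genotype", "stage", "replicate", "filled_seeds", "total_spikelets"],
    )
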