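"""Analysis configuration shared by the screening and classification stages.

The thresholds mirror the study design this pipeline implements: a within-line
time-course screen at >1.5-fold and a hybrid-vs-parents screen at >2-fold, both
gated on one-way ANOVA at alpha = 0.05, with spot intensities expressed in ppm
of their gel's total.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the differential / heterosis analysis.

    Parameters
    ----------
    alpha : significance level for every test (ANOVA, t, LSD).
    fc_inbred : fold-change threshold for the inbred time-course screen
        (a spot passes only if max stage-mean fold is strictly greater).
    fc_triad : fold-change threshold for the hybrid-parent triad screen.
    trend_epsilon : relative tolerance below which a stage-to-stage change
        counts as flat in the replicate same-trend rule.
    ppm_scale : per-gel normalization constant (ppm of total spot volume).
    equal_var : if True use the pooled-variance t statistic for triad
        comparisons instead of the default Welch t.
    rng_seed : seed forwarded to synthetic-data generation.
    """

    alpha: float = 0.05
    fc_inbred: float = 1.5
    fc_triad: float = 2.0
    trend_epsilon: float = 0.02
    ppm_scale: float = 1e6
    equal_var: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_inbred < 1.0:
            raise ValidationError(f"fc_inbred must be >= 1, got {self.fc_inbred}")
        if self.fc_triad < 1.0:
            raise ValidationError(f"fc_triad must be >= 1, got {self.fc_triad}")
        if self.trend_epsilon < 0.0:
            raise ValidationError(
                f"trend_epsilon must be >= 0, got {self.trend_epsilon}"
            )
        if self.ppm_scale <= 0.0:
            raise ValidationError(f"ppm_scale must be > 0, got {self.ppm_scale}")


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a flat key-value YAML file.

    Unknown keys raise :class:`~gelheterosis.errors.ValidationError` so that a
    typo cannot silently fall back to a default.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} is not a flat mapping")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return AnalysisConfig(**raw)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write the config as a flat key-value YAML file (round-trips with
    :func:`load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
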