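"""Bundled reference datasets from the maize silk-viability heterosis survey.

Two small tables from the published survey of three maize inbred lines
(Xun928, Lx9801, Zong3) and their hybrids (Xun928xZong3, Lx9801xZong3) are
shipped with the package:

* the per-spot heterotic-pattern calls for all 215 differentially accumulated
  protein spots (two hybrids x three silk stages), used to validate the
  pattern bookkeeping;
* the stage x genotype mean seed-setting rates (percent), used to validate
  the mid-parent heterosis arithmetic.

Raw replicate-level gel intensities were never published; these summary-level
tables are the recomputable part of the survey.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

XZ = "Xun928xZong3"
LZ = "Lx9801xZong3"

#: mean seed-setting rate (percent of mid-base spikelets), three replicates
#: of ten ears each; stages are days after silk emergence.
_SEED_SET_MEANS = {
    "Xun928": {"D4": 99.3, "D6": 97.4, "D8": 95.0, "D10": 26.0, "D12": 13.5},
    "Lx9801": {"D4": 96.3, "D6": 89.3, "D8": 78.8, "D10": 16.3, "D12": 1.9},
    "Zong3": {"D4": 100.0, "D6": 100.0, "D8": 100.0, "D10": 100.0, "D12": 100.0},
    XZ: {"D4": 100.0, "D6": 100.0, "D8": 95.6, "D10": 84.6, "D12": 80.2},
    LZ: {"D4": 100.0, "D6": 99.6, "D8": 80.3, "D10": 70.4, "D12": 66.9},
}

#: which genotypes form each hybrid's triad
TRIAD_PARENTS = {XZ: ("Xun928", "Zong3"), LZ: ("Lx9801", "Zong3")}


def load_pattern_survey() -> pd.DataFrame:
    """Per-spot heterotic pattern calls of the silk proteome survey.

    Columns: ``spot_id`` (gel spot number), ``hybrid``, ``stage``,
    ``fold_change`` (printed max fold, or ``Y/N`` where only the
    presence/absence of a difference was reported), ``pattern`` (one of
    A, +, -, ++, --, +-).
    """
    ref = resources.files("gelheterosis.data") / "silk_pattern_survey.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"spot_id": str})


def load_seed_set_means() -> pd.DataFrame:
    """Tidy stage x genotype mean seed-setting rates (percent)."""
    rows = [
        {"genotype": g, "stage": s, "rate_percent": v}
        for g, stages in _SEED_SET_MEANS.items()
        for s, v in stages.items()
    ]
    return pd.DataFrame(rows)


def seed_set_mean(genotype: str, stage: str) -> float:
    """Convenience scalar lookup into :func:`load_seed_set_means`."""
    return _SEED_SET_MEANS[genotype][stage]
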