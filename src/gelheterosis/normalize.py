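"""Per-gel "total quantity in valid spots" normalization.

Each 2-DE gel (one genotype x stage x replicate) is scaled so that the sum of
its spot intensities equals ``ppm_scale`` (10^6 by default): every spot is
expressed in ppm of its gel's total spot volume. This removes gel-to-gel
loading and staining differences and is the single normalization the pipeline
applies. "Valid spots" are all spots present in the table for that gel —
upstream spot detection has already happened by the time data reaches us.
"""

from __future__ import annotations

import pandas as pd

from .errors import DegenerateGelError
from .io import GEL_KEY


def normalize_total_ppm(table: pd.DataFrame, ppm_scale: float = 1e6) -> pd.DataFrame:
    """Rescale each gel so its spot intensities sum to ``ppm_scale``.

    Parameters
    ----------
    table : validated spot-intensity table (long format).
    ppm_scale : target per-gel total, default 10^6 (ppm).

    Returns
    -------
    A new table of identical shape and row order with ``intensity`` replaced by
    ``intensity / gel_total * ppm_scale``.

    Raises
    ------
    DegenerateGelError
        if any gel's total intensity is zero (nothing to normalize against);
        the error names the offending gel.
    """
    totals = table.groupby(GEL_KEY)["intensity"].transform("sum")
    if (totals <= 0).any():
        bad = table.loc[totals <= 0, GEL_KEY].drop_duplicates()
        gels = [tuple(r) for r in bad.itertuples(index=False)]
        raise DegenerateGelError(f"gel(s) with zero total intensity: {gels}")
    out = table.copy()
    out["intensity"] = table["intensity"] / totals * ppm_scale
    return out
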