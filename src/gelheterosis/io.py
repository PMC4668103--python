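"""Reading, validating and writing the tidy tables the pipeline consumes.

Canonical layouts (long/tidy, one observation per row):

* spot-intensity table: ``spot_id, genotype, stage, replicate, intensity``
* seed-set table: ``genotype, stage, replicate, filled_seeds, total_spikelets``

The decimal separator is ``.``, encoding UTF-8, and the delimiter is sniffed
from the file extension (``.csv`` comma, anything else tab). A missing
replicate makes the affected (spot, genotype, stage) cell an error rather than
being imputed: densitometry gives no principled fill-in value.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import TableParseError, ValidationError

SPOT_COLUMNS = ["spot_id", "genotype", "stage", "replicate", "intensity"]
SEEDSET_COLUMNS = ["genotype", "stage", "replicate", "filled_seeds", "total_spikelets"]

#: gel identity = one physical 2-DE gel (a genotype x stage x replicate)
GEL_KEY = ["genotype", "stage", "replicate"]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), encoding="utf-8")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise TableParseError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing required columns {missing}")
    return df[columns].copy()


def validate_spot_table(
    df: pd.DataFrame, expected_replicates: int | None = None
) -> pd.DataFrame:
    """Validate a spot-intensity table against its invariants.

    Checks non-negative numeric intensities, integer replicate indices >= 1,
    uniqueness of (spot_id, genotype, stage, replicate), and — when
    ``expected_replicates`` is given — that every (spot, genotype, stage) cell
    carries exactly that many replicates. Offending rows/cells are listed in
    the raised :class:`~gelheterosis.errors.ValidationError`; nothing is
    dropped or mutated.
    """
    problems: list[str] = []

    intensity = pd.to_numeric(df["intensity"], errors="coerce")
    bad = df.index[intensity.isna()]
    for i in bad[:5]:
        problems.append(f"row {i}: non-numeric intensity {df.at[i, 'intensity']!r}")
    neg = df.index[intensity < 0]
    for i in neg[:5]:
        problems.append(f"row {i}: negative intensity {intensity[i]}")

    rep = pd.to_numeric(df["replicate"], errors="coerce")
    badrep = df.index[rep.isna() | (rep < 1) | (rep != rep.round())]
    for i in badrep[:5]:
        problems.append(f"row {i}: replicate index {df.at[i, 'replicate']!r} invalid")

    key = ["spot_id", "genotype", "stage", "replicate"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        for _, grp in df[dup].groupby(key, sort=False):
            k = tuple(grp.iloc[0][key])
            problems.append(f"duplicate record for (spot_id, genotype, stage, replicate)={k}")
            if len(problems) > 20:
                break

    if expected_replicates is not None and not problems:
        counts = df.groupby(["spot_id", "genotype", "stage"], sort=False).size()
        off = counts[counts != expected_replicates]
        for k, n in list(off.items())[:10]:
            problems.append(
                f"cell {k} has {n} replicates, expected {expected_replicates}"
            )

    if problems:
        raise ValidationError("spot table invalid:\n  " + "\n  ".join(problems))

    out = df.copy()
    out["intensity"] = intensity.astype(float)
    out["replicate"] = rep.astype(int)
    out["spot_id"] = out["spot_id"].astype(str)
    out["genotype"] = out["genotype"].astype(str)
    out["stage"] = out["stage"].astype(str)
    return out


def read_spot_table(
    path: str | Path, expected_replicates: int | None = 3
) -> pd.DataFrame:
    """Read and validate a replicate-level spot-intensity table."""
    return validate_spot_table(_read_table(path, SPOT_COLUMNS), expected_replicates)


def validate_seedset_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a seed-set table: counts integral, 0 <= filled <= total, total > 0."""
    problems: list[str] = []
    filled = pd.to_numeric(df["filled_seeds"], errors="coerce")
    total = pd.to_numeric(df["total_spikelets"], errors="coerce")
    for i in df.index:
        f, t = filled[i], total[i]
        if pd.isna(f) or pd.isna(t) or f != int(f) or t != int(t):
            problems.append(f"row {i}: non-integer counts ({df.at[i, 'filled_seeds']!r}, "
                            f"{df.at[i, 'total_spikelets']!r})")
        elif t <= 0:
            problems.append(f"row {i}: total_spikelets must be positive, got {int(t)}")
        elif f < 0 or f > t:
            problems.append(f"row {i}: filled_seeds {int(f)} outside [0, {int(t)}]")
        if len(problems) > 10:
            break
    if problems:
        raise ValidationError("seed-set table invalid:\n  " + "\n  ".join(problems))
    out = df.copy()
    out["filled_seeds"] = filled.astype(int)
    out["total_spikelets"] = total.astype(int)
    out["replicate"] = pd.to_numeric(out["replicate"]).astype(int)
    out["genotype"] = out["genotype"].astype(str)
    out["stage"] = out["stage"].astype(str)
    return out


def read_seedset_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a replicate-level seed-set table."""
    return validate_seedset_table(_read_table(path, SEEDSET_COLUMNS))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any tidy table as UTF-8 TSV (or CSV if the extension is .csv).

    Column order is preserved as given; floats are written at full ``repr``
    precision so that write -> read -> write is byte-identical.
    """
    if df is None:
        raise ValidationError("cannot write a null result table")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False, encoding="utf-8")


# the report writer is the same serializer; the name documents intent at call sites
write_report = write_table


def read_report(path: str | Path) -> pd.DataFrame:
    """Read back a TSV/CSV written by :func:`write_report` (no validation)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep=_sep_for(path), encoding="utf-8")
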