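"""File formats and reports.

Peak tables are comma-separated UTF-8 with a mandatory header and
lower_snake_case columns (``assignment, residue, h_ppm, n_ppm, intensity,
condition``); TSV is accepted.  Chemical-shift tables come from the same CSV
dialect or from an NMR-STAR v3 file (the ``_Atom_chem_shift`` loop, as in a
BMRB deposition).  Reports are schema-versioned JSON with floats at full
precision.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .binding_core import Unit
from .structure_dynamics import RelaxationDecay, ShiftTable
from .titration_fit import TitrationSeries
from .anisotropy_fit import AnisotropyTitration

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "read_peak_table",
    "write_peak_table",
    "titration_series_from_peaks",
    "peak_table_from_titration",
    "read_anisotropy_table",
    "read_relaxation_table",
    "read_shift_table_csv",
    "read_shift_table_nmrstar",
    "write_report",
]

REPORT_SCHEMA_VERSION = "1.0"

REQUIRED_COLUMNS = ("assignment", "intensity", "condition")
_ASSIGNMENT_RE = re.compile(r"([A-Za-z]*)(\d+)")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate a per-residue peak table (CSV/TSV).

    Residue numbers are parsed from the assignment label (e.g. ``G744``)
    when the ``residue`` column is absent.  Extra columns are preserved.
    Duplicate (assignment, condition) keys are an error naming the rows.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak table {path} is missing required columns: {missing}")
    if "residue" not in df.columns:
        def parse(a):
            m = _ASSIGNMENT_RE.fullmatch(str(a).strip())
            if not m:
                raise ValueError(f"cannot parse residue number from assignment {a!r}")
            return int(m.group(2))
        df["residue"] = df["assignment"].map(parse)
    df["residue"] = df["residue"].astype(int)
    df["intensity"] = pd.to_numeric(df["intensity"])
    if (df["intensity"] < 0).any():
        raise ValueError("peak intensities must be non-negative")
    dup = df.duplicated(subset=["assignment", "condition"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        keys = df.loc[dup, ["assignment", "condition"]].drop_duplicates()
        raise ValueError(
            "duplicate (assignment, condition) keys at rows "
            f"{rows}: {keys.to_dict(orient='records')}"
        )
    return df


def write_peak_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False)


def titration_series_from_peaks(
    df: pd.DataFrame,
    u0: float,
    unit: Unit | str = Unit.MOL_PERCENT,
    regime: str = "slow_exchange_intensity",
) -> TitrationSeries:
    """Assemble a TitrationSeries from a long-format peak table.

    The ``condition`` column must hold the titrant concentration of each
    point (numeric).  Every peak must be observed at every point.
    """
    conc = pd.to_numeric(df["condition"])
    wide = df.assign(_conc=conc).pivot(
        index="assignment", columns="_conc", values="intensity"
    )
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"peaks missing at some titration points: {missing}")
    residue_of = df.drop_duplicates("assignment").set_index("assignment")["residue"]
    peaks = tuple((int(residue_of[a]), str(a)) for a in wide.index)
    return TitrationSeries(
        peaks=peaks,
        concentrations=wide.columns.to_numpy(dtype=float),
        observables=wide.to_numpy(dtype=float),
        u0=u0,
        unit=unit,
        regime=regime,
    )


def peak_table_from_titration(series: TitrationSeries) -> pd.DataFrame:
    """Long-format peak table for a series (writer matching the reader)."""
    rows = []
    for (res, lbl), trace in zip(series.peaks, series.observables):
        for conc, value in zip(series.concentrations, trace):
            rows.append(
                {"assignment": lbl, "residue": res, "h_ppm": np.nan, "n_ppm": np.nan,
                 "intensity": value, "condition": conc}
            )
    return pd.DataFrame(rows)


def read_anisotropy_table(path) -> pd.DataFrame:
    """CSV with columns concentration, anisotropy and optional sd."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in ("concentration", "anisotropy") if c not in df.columns]
    if missing:
        raise ValueError(f"anisotropy table {path} is missing columns: {missing}")
    return df


def anisotropy_titration_from_table(
    df: pd.DataFrame, labeled_conc: float, unit: Unit | str = Unit.MOL_PERCENT
) -> AnisotropyTitration:
    return AnisotropyTitration(
        labeled_conc=labeled_conc,
        titrant_concs=df["concentration"].to_numpy(dtype=float),
        anisotropy=df["anisotropy"].to_numpy(dtype=float),
        unit=unit,
        replicate_sd=df["sd"].to_numpy(dtype=float) if "sd" in df.columns else None,
    )


def read_relaxation_table(path) -> RelaxationDecay:
    """CSV with a ``residue`` column plus one ``t_<ms>`` column per delay."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    if "residue" not in df.columns:
        raise ValueError(f"relaxation table {path} needs a 'residue' column")
    delay_cols = [c for c in df.columns if c.startswith("t_")]
    if len(delay_cols) < 3:
        raise ValueError("need >= 3 delay columns named t_<milliseconds>")
    delays = np.array([float(c[2:]) for c in delay_cols])
    return RelaxationDecay(
        residues=df["residue"].to_numpy(dtype=int),
        delays_ms=delays,
        intensities=df[delay_cols].to_numpy(dtype=float),
    )


def read_shift_table_csv(path) -> ShiftTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip().lower() for c in df.columns]
    return ShiftTable(frame=df, source="csv")


# --- minimal NMR-STAR v3 chemical-shift loop reader -----------------------
# Only the _Atom_chem_shift loop is parsed (sufficient for backbone-shift
# tables as deposited at the BMRB); values of '.' or '?' are treated as
# missing.  Quoted values and comments are handled per STAR conventions.

_STAR_ATOMS = {"CA": "ca", "CB": "cb", "C": "co", "CO": "co"}


def _star_tokens(line: str):
    line = line.strip()
    if not line or line.startswith("#"):
        return []
    tokens, i = [], 0
    while i < len(line):
        if line[i].isspace():
            i += 1
            continue
        if line[i] in "'\"":
            quote = line[i]
            j = line.index(quote, i + 1)
            tokens.append(line[i + 1:j])
            i = j + 1
        else:
            j = i
            while j < len(line) and not line[j].isspace():
                j += 1
            tokens.append(line[i:j])
            i = j
    return tokens


def read_shift_table_nmrstar(path) -> ShiftTable:
    """Backbone CA/CB/CO shifts from an NMR-STAR v3 _Atom_chem_shift loop."""
    text = Path(path).read_text(encoding="utf-8")
    lines = iter(text.splitlines())
    records: dict[int, dict[str, float]] = {}
    for line in lines:
        if line.strip() != "loop_":
            continue
        tags = []
        for line in lines:
            s = line.strip()
            if s.startswith("_"):
                tags.append(s.split()[0])
            else:
                break
        if not any(t.startswith("_Atom_chem_shift.") for t in tags):
            continue
        names = [t.split(".", 1)[1] for t in tags]
        try:
            i_seq = names.index("Seq_ID")
            i_atom = names.index("Atom_ID")
            i_val = names.index("Val")
        except ValueError as exc:
            raise ValueError("NMR-STAR chemical-shift loop missing required tags") from exc
        # `line` currently holds the first data row
        row_lines = [line]
        for line in lines:
            if line.strip() in ("stop_", "save_"):
                break
            row_lines.append(line)
        for row in row_lines:
            vals = _star_tokens(row)
            if len(vals) != len(tags):
                continue
            atom = vals[i_atom].upper()
            if atom not in _STAR_ATOMS:
                continue
            if vals[i_val] in (".", "?") or vals[i_seq] in (".", "?"):
                continue
            res = int(vals[i_seq])
            records.setdefault(res, {})[_STAR_ATOMS[atom]] = float(vals[i_val])
        break
    if not records:
        raise ValueError(f"no _Atom_chem_shift records found in {path}")
    df = pd.DataFrame(
        [{"residue": r, **shifts} for r, shifts in sorted(records.items())]
    )
    return ShiftTable(frame=df, source="nmr-star")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Unit):
        return obj.value
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj


def write_report(result, path, extra: dict | None = None) -> dict:
    """Serialize a fit/topology result to schema-versioned JSON.

    ``result`` may be any object with a ``to_dict`` method or a plain dict.
    Returns the written payload.
    """
    payload = {"schema_version": REPORT_SCHEMA_VERSION, "result": _jsonable(result)}
    if extra:
        payload.update(_jsonable(extra))
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return payload
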