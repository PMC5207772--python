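"""Chemical-shift-index secondary structure, hydrogen-exchange ratios, and
CPMG R2 relaxation fits.

The chemical-shift index (CSI) assigns each residue a ternary index per
carbon atom from the deviation of its shift from a random-coil reference:
helical structure moves CA and CO downfield (positive deviation) and CB
slightly upfield.  A consensus over the available atoms, followed by a
minimum run length of four residues, yields helix segments.  This is an
approximation of a full CSI + dihedral-prediction analysis, adequate for
locating helix boundaries from backbone carbon shifts.

R2 rates come from per-residue monoexponential fits of CPMG transverse
decay curves, I(t) = I0 * exp(-R2 * t).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ShiftTable",
    "RelaxationDecay",
    "CSI_THRESHOLDS",
    "CPMG_DELAYS_MS",
    "load_random_coil_table",
    "coil_reference_for_sequence",
    "csi_secondary_structure",
    "cleanex_ratio",
    "fit_r2",
]

# Per-atom deviation thresholds (ppm) beyond which a residue votes for
# non-coil structure; standard CSI-style values.
CSI_THRESHOLDS = {"ca": 0.7, "cb": 0.7, "co": 0.5}

# Helix moves CA/CO downfield and CB upfield: sign of the deviation that
# counts as a helix vote, per atom.
_HELIX_SIGN = {"ca": +1, "co": +1, "cb": -1}

# CPMG relaxation delays (ms) used throughout this package's examples; the
# delay list is always data — fits never assume a fixed count.
CPMG_DELAYS_MS = (17.0, 35.0, 52.0, 69.0, 86.0, 104.0, 138.0, 173.0)

_PLAUSIBLE = {"ca": (40.0, 70.0), "cb": (10.0, 75.0), "co": (165.0, 185.0)}


@dataclass(frozen=True)
class ShiftTable:
    """Backbone carbon chemical shifts per residue (ppm; NaN where missing)."""

    frame: pd.DataFrame  # columns: residue, ca, cb, co
    source: str = "csv"

    def __post_init__(self):
        df = self.frame.copy()
        if "residue" not in df.columns:
            raise ValueError("shift table needs a 'residue' column")
        for col in ("ca", "cb", "co"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if len(df) == 0:
            raise ValueError("empty shift table")
        df = df.sort_values("residue").reset_index(drop=True)
        for col, (lo, hi) in _PLAUSIBLE.items():
            bad = df[col].dropna()
            bad = bad[(bad < lo) | (bad > hi)]
            if len(bad):
                warnings.warn(
                    f"{len(bad)} {col.upper()} shifts outside the plausible "
                    f"range {lo}-{hi} ppm", stacklevel=3,
                )
        object.__setattr__(self, "frame", df)


@dataclass(frozen=True)
class RelaxationDecay:
    """Per-residue transverse decay curves sampled at a list of delays (ms)."""

    residues: np.ndarray
    delays_ms: np.ndarray
    intensities: np.ndarray  # shape (n_residues, n_delays)

    def __post_init__(self):
        res = np.asarray(self.residues, dtype=int)
        t = np.asarray(self.delays_ms, dtype=float)
        intens = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if t.size < 3:
            raise ValueError("need >= 3 relaxation delays")
        if np.any(t <= 0):
            raise ValueError("delays must be positive")
        if np.any(intens < 0):
            raise ValueError("intensities must be >= 0")
        if intens.shape != (res.size, t.size):
            raise ValueError("intensity matrix shape inconsistent with residues x delays")
        object.__setattr__(self, "residues", res)
        object.__setattr__(self, "delays_ms", t)
        object.__setattr__(self, "intensities", intens)


def load_random_coil_table() -> pd.DataFrame:
    """Packaged random-coil CA/CB/CO reference shifts, indexed by amino acid."""
    ref = importlib.resources.files("bicellefit.data") / "random_coil_shifts.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path).set_index("aa")


def coil_reference_for_sequence(residues, sequence: str) -> pd.DataFrame:
    """Per-residue coil reference built from a one-letter sequence."""
    residues = np.asarray(residues, dtype=int)
    if len(sequence) != residues.size:
        raise ValueError("sequence length must match number of residues")
    table = load_random_coil_table()
    rows = [table.loc[aa] for aa in sequence.upper()]
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.insert(0, "residue", residues)
    return out


def _atom_index(dev: float, atom: str) -> int:
    thr = CSI_THRESHOLDS[atom]
    if np.isnan(dev) or abs(dev) <= thr:
        return 0
    return 1 if dev > 0 else -1


def csi_secondary_structure(
    shifts: ShiftTable,
    reference: pd.DataFrame,
    min_helix_run: int = 4,
    min_ca_coverage: float = 0.7,
):
    """Per-residue chemical-shift indices and consensus helix segments.

    ``reference`` is a per-residue coil table (columns residue, ca, cb, co)
    covering the residues of ``shifts``; build one from a sequence with
    :func:`coil_reference_for_sequence`.

    Returns ``(frame, segments)``: a DataFrame with per-atom indices and a
    consensus state in {H, C, E}, and helix segments as inclusive residue
    intervals.  Candidate segments where fewer than ``min_ca_coverage`` of
    residues carry a CA shift are dropped (too sparse to call).
    """
    df = shifts.frame.merge(
        reference.rename(columns={c: f"{c}_coil" for c in ("ca", "cb", "co")}),
        on="residue",
        how="left",
    )
    for atom in ("ca", "cb", "co"):
        dev = df[atom] - df[f"{atom}_coil"]
        df[f"{atom}_index"] = [_atom_index(d, atom) for d in dev]
        df[f"{atom}_dev"] = dev

    def consensus(row) -> str:
        votes = []
        for atom in ("ca", "cb", "co"):
            if not np.isnan(row[f"{atom}_dev"]):
                idx = row[f"{atom}_index"]
                votes.append(idx * _HELIX_SIGN[atom])
        if not votes:
            return "C"
        score = sum(votes)
        if score > 0:
            return "H"
        if score < 0:
            return "E"
        return "C"

    df["consensus"] = df.apply(consensus, axis=1)

    segments = []
    run: list[int] = []
    rows_by_res = df.set_index("residue")
    for res, state in zip(df["residue"], df["consensus"]):
        if state == "H" and (not run or res == run[-1] + 1):
            run.append(int(res))
            continue
        if len(run) >= min_helix_run:
            segments.append((run[0], run[-1]))
        run = [int(res)] if state == "H" else []
    if len(run) >= min_helix_run:
        segments.append((run[0], run[-1]))

    kept = []
    for start, end in segments:
        span = rows_by_res.loc[start:end]
        if span["ca"].notna().mean() >= min_ca_coverage:
            kept.append((start, end))
    return df, kept


def cleanex_ratio(
    mix_intensities: pd.Series, reference_intensities: pd.Series
) -> pd.Series:
    """Per-residue I/I0 between a water-exchange mixing spectrum and control.

    Low I/I0 marks exchange-resistant amides (e.g. membrane-embedded or
    stably hydrogen-bonded); the interpretation is left to the caller — no
    thresholding is applied.
    """
    mix = pd.Series(mix_intensities, dtype=float)
    ref = pd.Series(reference_intensities, dtype=float)
    shared = mix.index.intersection(ref.index)
    if len(shared) == 0:
        raise ValueError("no matched residues between mixing and reference data")
    if (ref.loc[shared] <= 0).any():
        raise ValueError("reference intensities must be positive")
    return (mix.loc[shared] / ref.loc[shared]).sort_index()


def fit_r2(decay: RelaxationDecay) -> pd.DataFrame:
    """Per-residue monoexponential R2 fits.

    Returns a DataFrame with columns residue, r2 (s^-1), r2_stderr, i0,
    i0_stderr.  Residues whose fit fails to converge are excluded with a
    warning.  Delays are in ms; rates are reported in s^-1.
    """
    t = decay.delays_ms / 1000.0  # seconds
    rows = []
    failed = []
    for res, y in zip(decay.residues, decay.intensities):
        if np.count_nonzero(y > 0) < 3:
            failed.append(int(res))
            continue
        # log-linear initial guess on the positive intensities
        pos = y > 0
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        r2_0 = max(-slope, 0.0)
        i0_0 = float(np.exp(intercept))
        try:
            popt, pcov = curve_fit(
                lambda tt, i0, r2: i0 * np.exp(-r2 * tt),
                t, y, p0=[i0_0, r2_0],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
        except Exception:
            failed.append(int(res))
            continue
        perr = np.sqrt(np.diag(pcov))
        rows.append(
            {"residue": int(res), "r2": popt[1], "r2_stderr": perr[1],
             "i0": popt[0], "i0_stderr": perr[0]}
        )
    if failed:
        warnings.warn(f"R2 fit failed for residues {failed}; excluded", stacklevel=2)
    if not rows:
        raise ValueError("R2 fitting failed for every residue")
    return pd.DataFrame(rows)
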