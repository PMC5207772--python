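"""Paramagnetic-probe accessibility profiles and membrane-topology calls.

A water-soluble paramagnet (Gd-DTPA, Mn-EDDA) broadens the amide peaks of
solvent-exposed residues, while a lipid-partitioning nitroxide (16-DSA)
broadens membrane-embedded ones.  The per-residue intensity ratio I/I0
(probe-containing over probe-free spectrum) therefore reads out depth:
membrane-embedded residues show a plateau of high hydrophilic-probe ratios
coinciding with a trough of low lipophilic-probe ratios.  The transmembrane
span is called from that coincidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HYDROPHILIC",
    "LIPOPHILIC",
    "AccessibilityProfile",
    "TopologyCall",
    "TopologyParams",
    "ProfileComparison",
    "intensity_ratio_profile",
    "call_tm_boundaries",
    "compare_profiles",
]

HYDROPHILIC = "hydrophilic"
LIPOPHILIC = "lipophilic"

# Relative error below which the 5%-of-value floor takes over: the error on
# each ratio is max(noise-derived error, 0.05 * ratio).
RELATIVE_ERROR_FLOOR = 0.05


@dataclass(frozen=True)
class AccessibilityProfile:
    """Per-residue I/I0 ratio with uncertainty for one paramagnetic probe.

    Gaps in residue numbering are allowed (prolines, overlapped peaks).
    Residues broadened beyond detection carry ratio 0, not NaN.
    """

    residues: np.ndarray
    ratio: np.ndarray
    error: np.ndarray
    probe: str
    probe_name: str = ""

    def __post_init__(self):
        res = np.asarray(self.residues, dtype=int)
        ratio = np.asarray(self.ratio, dtype=float)
        err = np.asarray(self.error, dtype=float)
        if self.probe not in (HYDROPHILIC, LIPOPHILIC):
            raise ValueError(f"probe must be hydrophilic or lipophilic, got {self.probe!r}")
        if not (res.shape == ratio.shape == err.shape) or res.ndim != 1:
            raise ValueError("residues, ratio, error must be 1-D and the same length")
        if np.any(ratio < 0):
            raise ValueError("I/I0 ratios must be >= 0")
        if res.size != np.unique(res).size:
            raise ValueError("duplicate residue numbers in profile")
        order = np.argsort(res)
        object.__setattr__(self, "residues", res[order])
        object.__setattr__(self, "ratio", ratio[order])
        object.__setattr__(self, "error", np.maximum(err, RELATIVE_ERROR_FLOOR * ratio)[order])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": self.residues, "ratio": self.ratio, "error": self.error}
        )


@dataclass(frozen=True)
class TopologyCall:
    """Inferred membrane-embedded span plus exposed segments (1-based, inclusive)."""

    tm_start: int | None
    tm_end: int | None
    protected_segments: tuple[tuple[int, int], ...]
    exposed_segments: tuple[tuple[int, int], ...]
    evidence: dict = field(default_factory=dict)

    @property
    def has_tm(self) -> bool:
        return self.tm_start is not None

    def to_dict(self) -> dict:
        return {
            "tm_start": self.tm_start,
            "tm_end": self.tm_end,
            "protected_segments": [list(s) for s in self.protected_segments],
            "exposed_segments": [list(s) for s in self.exposed_segments],
            "evidence": self.evidence,
        }


@dataclass(frozen=True)
class TopologyParams:
    """Thresholds for reading the plateau/trough coincidence.

    ``high_threshold``: minimum hydrophilic-probe ratio inside the membrane;
    ``low_threshold``: maximum lipophilic-probe ratio inside the membrane;
    ``smooth_window``: moving-median window (residues, odd);
    ``min_run``: minimum membrane-span length (a TM helix shorter than ~12
    residues cannot span a bilayer).
    """

    high_threshold: float = 0.7
    low_threshold: float = 0.5
    smooth_window: int = 3
    min_run: int = 12


@dataclass(frozen=True)
class ProfileComparison:
    """Residue-wise difference of two same-probe profiles with a verdict."""

    residues: np.ndarray
    per_residue_delta: np.ndarray
    combined_error: np.ndarray
    n_significant: int
    allowed: int
    verdict: str  # "unchanged" | "changed"

    def to_dict(self) -> dict:
        return {
            "residues": self.residues.tolist(),
            "per_residue_delta": self.per_residue_delta.tolist(),
            "combined_error": self.combined_error.tolist(),
            "n_significant": self.n_significant,
            "allowed": self.allowed,
            "verdict": self.verdict,
        }


def intensity_ratio_profile(
    paramagnetic_peaks: pd.DataFrame,
    diamagnetic_peaks: pd.DataFrame,
    noise: float,
    probe: str = HYDROPHILIC,
    probe_name: str = "",
) -> AccessibilityProfile:
    """I_para/I_dia per residue from matched peak tables.

    Tables need ``residue`` and ``intensity`` columns (the peak-table dialect
    of :mod:`bicellefit.io`).  Residues present only in the diamagnetic table
    are treated as broadened beyond detection: ratio 0 with error noise/I_dia.
    Per-residue errors are propagated from ``noise`` (same intensity units as
    the tables) and floored at 5% of the ratio.
    """
    if noise < 0:
        raise ValueError("noise must be >= 0")
    dia = diamagnetic_peaks.set_index("residue")["intensity"].astype(float)
    para = paramagnetic_peaks.set_index("residue")["intensity"].astype(float)
    if (dia < 0).any() or (para < 0).any():
        raise ValueError("peak intensities must be non-negative")
    if (dia == 0).any():
        raise ValueError("diamagnetic reference intensities must be positive")

    residues, ratios, errors = [], [], []
    for res, i_dia in dia.items():
        if res in para.index:
            i_para = para.loc[res]
            r = i_para / i_dia
            if i_para > 0:
                noise_err = r * math.hypot(noise / i_para, noise / i_dia)
            else:
                noise_err = noise / i_dia
        else:
            r = 0.0
            noise_err = noise / i_dia
        residues.append(int(res))
        ratios.append(float(r))
        errors.append(float(noise_err))
    if not residues:
        raise ValueError("no matched residues between paramagnetic and diamagnetic tables")
    return AccessibilityProfile(
        residues=np.array(residues),
        ratio=np.array(ratios),
        error=np.array(errors),
        probe=probe,
        probe_name=probe_name,
    )


def _moving_median(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.copy()
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(values.size):
        lo, hi = max(0, i - half), min(values.size, i + half + 1)
        out[i] = np.median(values[lo:hi])
    return out


def _runs(residues: np.ndarray, mask: np.ndarray):
    """Maximal runs of consecutive residue numbers where mask holds."""
    runs = []
    start = None
    prev = None
    for res, ok in zip(residues, mask):
        if ok and start is not None and res == prev + 1:
            prev = res
            continue
        if start is not None:
            runs.append((start, prev))
            start = None
        if ok:
            start = prev = res
    if start is not None:
        runs.append((start, prev))
    return runs


def call_tm_boundaries(
    hydrophilic: AccessibilityProfile,
    lipophilic: AccessibilityProfile,
    params: TopologyParams | None = None,
) -> TopologyCall:
    """Call the transmembrane span from complementary probe profiles.

    After moving-median smoothing, the TM span is the longest run of
    consecutive residues where the hydrophilic ratio is >= high_threshold
    (protected from the aqueous probe) AND the lipophilic ratio is
    <= low_threshold (broadened by the membrane probe), of length at least
    ``min_run``.  If no run qualifies, the call is empty with a
    "no membrane-embedded span" flag in the evidence.
    """
    p = params or TopologyParams()
    if hydrophilic.probe != HYDROPHILIC or lipophilic.probe != LIPOPHILIC:
        raise ValueError("profiles passed in the wrong probe order")
    shared = np.intersect1d(hydrophilic.residues, lipophilic.residues)
    if shared.size < 10:
        raise ValueError(f"need >= 10 overlapping residues, got {shared.size}")

    h_idx = np.searchsorted(hydrophilic.residues, shared)
    l_idx = np.searchsorted(lipophilic.residues, shared)
    h_smooth = _moving_median(hydrophilic.ratio[h_idx], p.smooth_window)
    l_smooth = _moving_median(lipophilic.ratio[l_idx], p.smooth_window)

    mask = (h_smooth >= p.high_threshold) & (l_smooth <= p.low_threshold)
    candidates = [r for r in _runs(shared, mask) if r[1] - r[0] + 1 >= p.min_run]

    evidence = {
        "probes": {"hydrophilic": hydrophilic.probe_name, "lipophilic": lipophilic.probe_name},
        "params": {
            "high_threshold": p.high_threshold,
            "low_threshold": p.low_threshold,
            "smooth_window": p.smooth_window,
            "min_run": p.min_run,
        },
        "n_shared_residues": int(shared.size),
    }
    if not candidates:
        evidence["flag"] = "no membrane-embedded span"
        return TopologyCall(
            tm_start=None, tm_end=None, protected_segments=(),
            exposed_segments=((int(shared[0]), int(shared[-1])),), evidence=evidence,
        )

    tm_start, tm_end = max(candidates, key=lambda r: r[1] - r[0])
    exposed = []
    if shared[0] < tm_start:
        exposed.append((int(shared[0]), int(tm_start - 1)))
    if shared[-1] > tm_end:
        exposed.append((int(tm_end + 1), int(shared[-1])))
    return TopologyCall(
        tm_start=int(tm_start),
        tm_end=int(tm_end),
        protected_segments=((int(tm_start), int(tm_end)),),
        exposed_segments=tuple(exposed),
        evidence=evidence,
    )


def compare_profiles(
    a: AccessibilityProfile, b: AccessibilityProfile, k: float = 2.0
) -> ProfileComparison:
    """Residue-wise comparison of two profiles from the same probe class.

    Deltas a - b with errors combined in quadrature; a residue is significant
    when |delta| > k * combined error.  The verdict is ``unchanged`` when the
    significant count stays within the chance allowance ceil(0.05 * n).
    """
    if a.probe != b.probe:
        raise ValueError(f"probe class mismatch: {a.probe} vs {b.probe}")
    shared = np.intersect1d(a.residues, b.residues)
    if shared.size < 10:
        raise ValueError(f"need >= 10 shared residues, got {shared.size}")
    ia = np.searchsorted(a.residues, shared)
    ib = np.searchsorted(b.residues, shared)
    delta = a.ratio[ia] - b.ratio[ib]
    err = np.hypot(a.error[ia], b.error[ib])
    with np.errstate(divide="ignore", invalid="ignore"):
        significant = np.abs(delta) > k * err
    n_sig = int(np.count_nonzero(significant))
    allowed = math.ceil(0.05 * shared.size)
    return ProfileComparison(
        residues=shared,
        per_residue_delta=delta,
        combined_error=err,
        n_significant=n_sig,
        allowed=allowed,
        verdict="unchanged" if n_sig <= allowed else "changed",
    )
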