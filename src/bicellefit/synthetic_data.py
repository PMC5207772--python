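"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a deterministic function of (truth, design, seed) and its
zero-noise output lies exactly on the model it emulates, so simulate->fit
round trips recover the generating parameters to optimizer tolerance.  The
defaults encode the study conditions this package targets: six-point
titrations at mole ratios 0, 0.5, 1, 2, 3, 4 (slow exchange, observed
subunit at 0.17 mol%) or 0, 1.25, 2.5, 3.75, 5, 7.5 (fast exchange, 0.23
mol%), CPMG decays at the standard eight delays, and anisotropy titrations
of a 0.2 µM labeled subunit in 2% w/v q=0.3 bicelles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding_core import (
    MW_D6PC,
    BindingParameters,
    Unit,
    bicelle_lipid_molarity,
    bound_fraction_raw,
    mol_percent,
    popc_pops_mean_mw,
)
from .pre_topology import HYDROPHILIC, LIPOPHILIC, AccessibilityProfile
from .structure_dynamics import CPMG_DELAYS_MS, RelaxationDecay
from .titration_fit import FAST_EXCHANGE, SLOW_EXCHANGE, TitrationSeries
from .anisotropy_fit import AnisotropyTitration

__all__ = [
    "TopologyFixture",
    "BETA1_TMCT",
    "BETA3_TMCT",
    "SimulationDesign",
    "AnisotropyDesign",
    "SLOW_MOLE_RATIOS",
    "FAST_MOLE_RATIOS",
    "default_anisotropy_u0_mol_percent",
    "simulate_titration",
    "simulate_pre_profiles",
    "simulate_r2_decay",
    "simulate_anisotropy",
]

SLOW_MOLE_RATIOS = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0)
FAST_MOLE_RATIOS = (0.0, 1.25, 2.5, 3.75, 5.0, 7.5)


@dataclass(frozen=True)
class TopologyFixture:
    """Annotated residue range with ground-truth TM and helix spans.

    Spans are 1-based inclusive residue intervals with
    tm_span ⊆ helix_span ⊆ residue_range.  Sequences are optional — the
    topology machinery works on residue numbering alone.
    """

    name: str
    residue_range: tuple[int, int]
    tm_span: tuple[int, int]
    helix_span: tuple[int, int]
    notable_sites: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        (r0, r1), (t0, t1), (h0, h1) = self.residue_range, self.tm_span, self.helix_span
        if not (r0 <= h0 <= t0 <= t1 <= h1 <= r1):
            raise ValueError("require tm_span ⊆ helix_span ⊆ residue_range")

    @property
    def residues(self) -> np.ndarray:
        return np.arange(self.residue_range[0], self.residue_range[1] + 1)


# Integrin β1 TM/CT: construct residues 719-798, membrane-embedded span
# I732-I757, helix continuing into the cytosol to K765.
BETA1_TMCT = TopologyFixture(
    name="beta1_tmct",
    residue_range=(719, 798),
    tm_span=(732, 757),
    helix_span=(732, 765),
    notable_sites={"K752": 752, "I732": 732, "I757": 757, "D759": 759, "F763": 763},
)

# Integrin β3 TM/CT: construct residues 685-762, TM I693-I721, helix
# extending ~16 residues into the cytosol, ending at A737.
BETA3_TMCT = TopologyFixture(
    name="beta3_tmct",
    residue_range=(685, 762),
    tm_span=(693, 721),
    helix_span=(693, 737),
    notable_sites={"K716": 716, "I693": 693, "I721": 721, "D723": 723, "A737": 737},
)


@dataclass(frozen=True)
class SimulationDesign:
    """Titration design: mole ratios, fixed observed concentration, noise, seed."""

    mole_ratios: tuple[float, ...] = SLOW_MOLE_RATIOS
    u0: float = 0.17
    unit: Unit = Unit.MOL_PERCENT
    noise_sd: float = 0.05
    seed: int = 0
    regime: str = SLOW_EXCHANGE

    def __post_init__(self):
        object.__setattr__(self, "unit", Unit.coerce(self.unit))
        object.__setattr__(self, "mole_ratios", tuple(float(x) for x in self.mole_ratios))


def _amp_range_default(regime: str) -> tuple[float, float]:
    # Slow exchange: reference intensities in arbitrary units around 1;
    # fast exchange: saturation hybrid shifts of 0.02-0.12 ppm, the span seen
    # for well-shifting amide peaks.
    return (0.5, 2.0) if regime == SLOW_EXCHANGE else (0.02, 0.12)


def simulate_titration(
    truth: BindingParameters,
    design: SimulationDesign,
    n_peaks: int = 4,
    amp_range: tuple[float, float] | None = None,
    first_residue: int = 701,
) -> TitrationSeries:
    """Simulate a multi-peak titration from the 1:1 depletion model.

    Per-peak amplitudes (I0 for slow exchange, delta_max for fast exchange)
    are drawn log-uniformly over ``amp_range``, then multiplicative Gaussian
    noise of relative sd ``design.noise_sd`` is applied.  All randomness
    comes from one generator seeded by ``design.seed``.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if truth.unit is not design.unit:
        raise ValueError("truth and design concentration units differ")
    rng = np.random.default_rng(design.seed)
    lo, hi = amp_range or _amp_range_default(design.regime)
    amps = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_peaks))

    l0 = np.asarray(design.mole_ratios) * design.u0
    fb = bound_fraction_raw(truth.kd, design.u0, l0)
    if design.regime == SLOW_EXCHANGE:
        clean = amps[:, None] * (1.0 - fb)[None, :]
    elif design.regime == FAST_EXCHANGE:
        clean = amps[:, None] * fb[None, :]
    else:
        raise ValueError(f"unknown regime {design.regime!r}")

    obs = clean * (1.0 + rng.normal(0.0, design.noise_sd, size=clean.shape))
    if design.regime == SLOW_EXCHANGE:
        obs = np.maximum(obs, 0.0)
    peaks = tuple((first_residue + i, f"R{first_residue + i}") for i in range(n_peaks))
    return TitrationSeries(
        peaks=peaks,
        concentrations=l0,
        observables=obs,
        u0=design.u0,
        unit=design.unit,
        regime=design.regime,
    )


# Accessibility levels of the simulated profiles: hydrophilic-probe ratios
# plateau near H_HI inside the membrane and sit near H_LO in solvent;
# lipophilic-probe ratios dip from L_HI to L_LO at the bilayer center.
_H_LO, _H_HI = 0.20, 0.95
_L_LO, _L_HI = 0.10, 0.95
# Threshold crossings are placed half a residue outside the annotated TM
# boundaries, calibrated to the default topology-calling thresholds.
_H_CROSS, _L_CROSS = 0.7, 0.5


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_pre_profiles(
    fixture: TopologyFixture,
    noise_sd: float = 0.0,
    seed: int = 0,
    steepness: float = 1.5,
    artifact_site: int | None = None,
    artifact_depth: float = 0.8,
    artifact_width: float = 2.5,
):
    """Paired hydrophilic/lipophilic accessibility profiles for a fixture.

    The hydrophilic ratio follows a flat-topped product of logistics rising
    inside the TM span (membrane-protected from the aqueous probe); the
    lipophilic ratio is one minus a Gaussian bell with its minimum at the TM
    center.  Multiplicative Gaussian noise of sd ``noise_sd`` is applied,
    then the error rule (max of the noise-derived error and 5% of the value).

    ``artifact_site`` enables the chelate-artifact mode: hydrophilic ratios
    near a carboxylate-bearing residue are depressed, emulating transient
    association of a chelate probe with Glu/Asp side chains.
    """
    res = fixture.residues.astype(float)
    t0, t1 = fixture.tm_span
    rng = np.random.default_rng(seed)

    # Hydrophilic plateau: logistic midpoints offset so the ratio crosses
    # the calibration level exactly between the boundary residue and its
    # outside neighbour.
    offset = steepness * np.log((_H_CROSS - _H_LO) / (_H_HI - _H_CROSS))
    m_start = (t0 - 0.5) - offset
    m_end = (t1 + 0.5) + offset
    g = _logistic((res - m_start) / steepness) * _logistic((m_end - res) / steepness)
    hyd = _H_LO + (_H_HI - _H_LO) * g

    # Lipophilic trough: Gaussian bell crossing the calibration level half a
    # residue outside each TM boundary, minimum at the TM center.
    center = 0.5 * (t0 + t1)
    z_cross = np.sqrt(-2.0 * np.log((_L_HI - _L_CROSS) / (_L_HI - _L_LO)))
    width = (center - (t0 - 0.5)) / z_cross
    lip = _L_HI - (_L_HI - _L_LO) * np.exp(-0.5 * ((res - center) / width) ** 2)

    if artifact_site is not None:
        depress = artifact_depth * np.exp(-((res - artifact_site) / artifact_width) ** 2)
        hyd = hyd * (1.0 - depress)

    def finish(clean, probe, name):
        noisy = clean * (1.0 + rng.normal(0.0, noise_sd, size=clean.shape))
        noisy = np.maximum(noisy, 0.0)
        # Quoted uncertainty propagates noise from both the probe-containing
        # and the probe-free reference spectrum (sqrt(2) x the per-spectrum
        # relative noise); the simulated scatter applies the net ratio
        # perturbation as one multiplicative draw, so reported errors are
        # mildly conservative, as empirical intensity-ratio errors are.
        err = np.sqrt(2.0) * noise_sd * np.maximum(noisy, 1e-12)
        return AccessibilityProfile(
            residues=fixture.residues, ratio=noisy, error=err,
            probe=probe, probe_name=name,
        )

    return (
        finish(hyd, HYDROPHILIC, "Gd-DTPA (simulated)"),
        finish(lip, LIPOPHILIC, "16-DSA (simulated)"),
    )


def simulate_r2_decay(
    r2_truth,
    delays_ms=CPMG_DELAYS_MS,
    noise_sd: float = 0.0,
    seed: int = 0,
    i0=None,
    first_residue: int = 1,
) -> RelaxationDecay:
    """Monoexponential CPMG decays for per-residue true R2 rates (s^-1)."""
    r2 = np.atleast_1d(np.asarray(r2_truth, dtype=float))
    t = np.asarray(delays_ms, dtype=float) / 1000.0
    rng = np.random.default_rng(seed)
    if i0 is None:
        i0 = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=r2.size))
    else:
        i0 = np.broadcast_to(np.asarray(i0, dtype=float), r2.shape).copy()
    clean = i0[:, None] * np.exp(-r2[:, None] * t[None, :])
    noisy = clean * (1.0 + rng.normal(0.0, noise_sd, size=clean.shape))
    return RelaxationDecay(
        residues=np.arange(first_residue, first_residue + r2.size),
        delays_ms=np.asarray(delays_ms, dtype=float),
        intensities=np.maximum(noisy, 0.0),
    )


def default_anisotropy_u0_mol_percent(
    labeled_conc_uM: float = 0.2,
    total_wv_percent: float = 2.0,
    q: float = 0.3,
) -> float:
    """Labeled-subunit concentration in mol% for the default anisotropy setup.

    0.2 µM labeled subunit in 2% w/v q=0.3 D6PC/POPC/POPS (POPC:POPS 2:1)
    bicelles; the long-chain lipid molarity comes from the two-component
    mass balance with the mole-fraction-weighted POPC/POPS molecular weight.
    """
    lipid_molar = bicelle_lipid_molarity(
        total_wv_percent, q, popc_pops_mean_mw(), MW_D6PC
    )
    return mol_percent(labeled_conc_uM, lipid_molar * 1e6)


def _default_anisotropy_concs(max_conc: float = 3.2, n: int = 12) -> tuple[float, ...]:
    # Zero point plus log-spaced points up to the accessible ceiling.
    return (0.0, *np.geomspace(0.01, max_conc, n - 1))


@dataclass(frozen=True)
class AnisotropyDesign:
    """Anisotropy titration design: schedule, replicates, noise, seed.

    Five replicate readings per point (each with additive Gaussian noise of
    sd ``noise_sd`` on the anisotropy) are averaged; their sample SD becomes
    the per-point replicate_sd, as in a typical steady-state measurement.
    """

    titrant_concs: tuple[float, ...] = field(default_factory=_default_anisotropy_concs)
    u0: float | None = None  # None: default 0.2 µM in 2% w/v bicelles, in mol%
    unit: Unit = Unit.MOL_PERCENT
    noise_sd: float = 0.005
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "unit", Unit.coerce(self.unit))
        object.__setattr__(self, "titrant_concs", tuple(float(c) for c in self.titrant_concs))
        if self.u0 is None:
            if self.unit is not Unit.MOL_PERCENT:
                raise ValueError("default u0 is only defined in mol%")
            object.__setattr__(self, "u0", default_anisotropy_u0_mol_percent())


@dataclass(frozen=True)
class AnisotropyTruth:
    """Generating parameters for a simulated anisotropy titration."""

    kd: float
    r_free: float = 0.10
    r_bound: float = 0.20
    unit: Unit = Unit.MOL_PERCENT

    def __post_init__(self):
        object.__setattr__(self, "unit", Unit.coerce(self.unit))
        if self.kd < 0:
            raise ValueError("kd must be >= 0")


def simulate_anisotropy(
    truth: AnisotropyTruth, design: AnisotropyDesign
) -> AnisotropyTitration:
    """Simulate an anisotropy titration with replicate-averaged noise."""
    if truth.unit is not design.unit:
        raise ValueError("truth and design concentration units differ")
    rng = np.random.default_rng(design.seed)
    conc = np.asarray(design.titrant_concs, dtype=float)
    fb = bound_fraction_raw(truth.kd, design.u0, conc)
    clean = truth.r_free + (truth.r_bound - truth.r_free) * fb
    if design.noise_sd > 0 and design.n_replicates > 1:
        reps = clean[:, None] + rng.normal(
            0.0, design.noise_sd, size=(conc.size, design.n_replicates)
        )
        obs = reps.mean(axis=1)
        sd = reps.std(axis=1, ddof=1)
    elif design.noise_sd > 0:
        obs = clean + rng.normal(0.0, design.noise_sd, size=conc.size)
        sd = None
    else:
        obs, sd = clean, None
    return AnisotropyTitration(
        labeled_conc=design.u0,
        titrant_concs=conc,
        anisotropy=obs,
        unit=design.unit,
        replicate_sd=sd,
    )
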