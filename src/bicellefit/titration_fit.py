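"""Global fitting of multi-peak NMR titrations to the 1:1 depletion isotherm.

Two exchange regimes are supported, matching how binding manifests in
TROSY spectra:

* slow exchange — peaks of the free species lose intensity as the complex
  forms; the model is ``I_p(L0) = I0_p * (1 - f_b(Kd, U0, L0))`` with one
  global Kd and a per-peak reference intensity I0_p.
* fast exchange — peaks shift continuously; the model is
  ``d_p(L0) = dmax_p * f_b(Kd, U0, L0)`` on hybrid shifts measured relative
  to the zero-titrant point.

Both are fit jointly over all peaks by bounded nonlinear least squares with
a multistart over Kd (the isotherm's likelihood is nearly flat in Kd when a
titration stops far from saturation, which traps single-start optimizers).
Fits that do not approach saturation are flagged and reported as Kd lower
bounds rather than estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .binding_core import Unit, bound_fraction_raw

__all__ = [
    "SLOW_EXCHANGE",
    "FAST_EXCHANGE",
    "TitrationSeries",
    "PeakEstimate",
    "BindingFitResult",
    "SaturationOptions",
    "fit_slow_exchange_global",
    "fit_fast_exchange_global",
    "assess_saturation",
    "apply_saturation_rule",
    "refit_excluding",
]

SLOW_EXCHANGE = "slow_exchange_intensity"
FAST_EXCHANGE = "fast_exchange_shift"

QUANTIFIED = "quantified"
LOWER_BOUND = "lower_bound"


@dataclass(frozen=True)
class TitrationSeries:
    """Per-peak observable traces across titrant concentrations.

    ``observables`` has shape (n_peaks, n_points): intensities (arbitrary
    units) for slow exchange, hybrid shifts (ppm, relative to the
    zero-titrant point) for fast exchange.  Points are sorted by titrant
    concentration on construction.
    """

    peaks: tuple[tuple[int, str], ...]
    concentrations: np.ndarray
    observables: np.ndarray
    u0: float
    unit: Unit = Unit.MOL_PERCENT
    regime: str = SLOW_EXCHANGE

    def __post_init__(self):
        object.__setattr__(self, "unit", Unit.coerce(self.unit))
        peaks = tuple((int(r), str(lbl)) for r, lbl in self.peaks)
        conc = np.asarray(self.concentrations, dtype=float)
        obs = np.atleast_2d(np.asarray(self.observables, dtype=float))
        if self.regime not in (SLOW_EXCHANGE, FAST_EXCHANGE):
            raise ValueError(f"unknown exchange regime {self.regime!r}")
        if conc.ndim != 1 or conc.size < 3:
            raise ValueError("need >= 3 titration points")
        if np.any(conc < 0):
            raise ValueError("titrant concentrations must be >= 0")
        if not np.any(conc == 0):
            raise ValueError("titration must include a zero-titrant point")
        if self.u0 <= 0:
            raise ValueError("u0 must be > 0")
        if obs.shape != (len(peaks), conc.size):
            raise ValueError(
                f"observables shape {obs.shape} inconsistent with "
                f"{len(peaks)} peaks x {conc.size} points"
            )
        order = np.argsort(conc, kind="stable")
        object.__setattr__(self, "peaks", peaks)
        object.__setattr__(self, "concentrations", conc[order])
        object.__setattr__(self, "observables", obs[:, order])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for _, lbl in self.peaks)

    def subset(self, keep_labels) -> "TitrationSeries":
        keep = [i for i, lbl in enumerate(self.labels) if lbl in set(keep_labels)]
        if not keep:
            raise ValueError("subset would remove every peak")
        return TitrationSeries(
            peaks=tuple(self.peaks[i] for i in keep),
            concentrations=self.concentrations.copy(),
            observables=self.observables[keep],
            u0=self.u0,
            unit=self.unit,
            regime=self.regime,
        )


@dataclass(frozen=True)
class PeakEstimate:
    """Per-peak nuisance parameter (I0 or delta_max) with its standard error."""

    value: float
    stderr: float | None


@dataclass(frozen=True)
class BindingFitResult:
    """Globally shared Kd with per-peak nuisance parameters and diagnostics."""

    kd: float
    kd_stderr: float | None
    unit: Unit
    regime: str
    per_peak: dict[str, PeakEstimate]
    residuals: np.ndarray
    saturation_fraction: float
    bound_flag: str = QUANTIFIED
    lower_bound_value: float | None = None
    excluded_peaks: tuple[str, ...] = ()
    n_points: int = 0
    redchi: float = float("nan")

    def to_dict(self) -> dict:
        """JSON-serializable report (schema-versioned by io.write_report)."""
        return {
            "kd": self.kd,
            "kd_stderr": self.kd_stderr,
            "unit": self.unit.value,
            "regime": self.regime,
            "per_peak": {
                lbl: {"value": p.value, "stderr": p.stderr}
                for lbl, p in self.per_peak.items()
            },
            "saturation_fraction": self.saturation_fraction,
            "bound_flag": self.bound_flag,
            "lower_bound_value": self.lower_bound_value,
            "excluded_peaks": list(self.excluded_peaks),
            "n_points": self.n_points,
            "redchi": self.redchi,
            "residual_ss": float(np.sum(self.residuals**2)),
        }


@dataclass(frozen=True)
class SaturationOptions:
    """Rules deciding when a fit is reported as a Kd lower bound.

    A fit is downgraded when the bound fraction at the top titrant point is
    strictly below ``saturation_threshold``, or when the upper edge of the
    Wald confidence interval on Kd exceeds ``ci_multiple`` times the top
    titrant concentration.  ``lower_bound_value`` defaults to max(L0) itself;
    published lower bounds based on other conventions can be reproduced by
    passing a different callable.
    """

    saturation_threshold: float = 0.5
    ci_multiple: float = 3.0
    ci_z: float = 1.96
    lower_bound_value: "callable | None" = None


def _model_matrix(kd: float, amps: np.ndarray, series: TitrationSeries) -> np.ndarray:
    fb = bound_fraction_raw(kd, series.u0, series.concentrations)
    if series.regime == SLOW_EXCHANGE:
        return amps[:, None] * (1.0 - fb)[None, :]
    return amps[:, None] * fb[None, :]


# NMR peak intensities and shift perturbations carry errors roughly
# proportional to the measured value (constant coefficient of variation),
# mirroring the "5% of value" convention for intensity ratios.  Residuals are
# therefore weighted by the observed values, floored at this fraction of each
# peak's full response so near-zero points are not over-weighted.
WEIGHT_FLOOR_FRACTION = 0.1


def _weight_sigma(series: TitrationSeries) -> np.ndarray:
    scale = np.max(np.abs(series.observables), axis=1)
    scale[scale == 0] = 1.0
    return np.maximum(np.abs(series.observables),
                      WEIGHT_FLOOR_FRACTION * scale[:, None])


def _fit_once(series: TitrationSeries, kd0: float, amp0: np.ndarray,
              sigma: np.ndarray):
    params = lmfit.Parameters()
    params.add("kd", value=kd0, min=0.0)
    for i, a0 in enumerate(amp0):
        params.add(f"amp_{i}", value=a0)

    n_peaks = len(series.peaks)

    def residual(p):
        amps = np.array([p[f"amp_{i}"].value for i in range(n_peaks)])
        model = _model_matrix(p["kd"].value, amps, series)
        return ((series.observables - model) / sigma).ravel()

    return lmfit.minimize(residual, params, method="least_squares")


def _fit_global(series: TitrationSeries, options: SaturationOptions) -> BindingFitResult:
    obs = series.observables
    if series.regime == SLOW_EXCHANGE and not np.any(obs != 0):
        raise ValueError("all intensities are zero; nothing to fit")
    if series.regime == FAST_EXCHANGE and not np.any(obs != 0):
        raise ValueError("no binding signal: all shift perturbations are zero")
    if len(series.peaks) < 2:
        warnings.warn(
            "global fit with a single peak: Kd and amplitude may be poorly "
            "constrained",
            stacklevel=3,
        )

    lmax = float(series.concentrations.max())
    if lmax <= 0:
        raise ValueError("titration has no nonzero titrant point")

    if series.regime == SLOW_EXCHANGE:
        amp0 = obs[:, 0].copy()  # points sorted: column 0 is the zero point
        amp0[amp0 == 0] = np.max(np.abs(obs)) or 1.0
    else:
        amp0 = obs[:, -1].copy()
        amp0[amp0 == 0] = np.max(np.abs(obs)) or 1.0

    sigma = _weight_sigma(series)
    best = None
    for mult in (0.1, 1.0, 10.0):
        try:
            out = _fit_once(series, mult * lmax, amp0, sigma)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise RuntimeError(
            "global 1:1 fit failed to converge after multistart "
            f"(regime={series.regime}, n_peaks={len(series.peaks)})"
        )

    kd = float(best.params["kd"].value)
    kd_stderr = best.params["kd"].stderr
    per_peak = {}
    for i, lbl in enumerate(series.labels):
        p = best.params[f"amp_{i}"]
        per_peak[lbl] = PeakEstimate(float(p.value), p.stderr)

    sat = float(bound_fraction_raw(kd, series.u0, lmax))
    result = BindingFitResult(
        kd=kd,
        kd_stderr=None if kd_stderr is None else float(kd_stderr),
        unit=series.unit,
        regime=series.regime,
        per_peak=per_peak,
        residuals=np.asarray(best.residual, dtype=float),
        saturation_fraction=sat,
        n_points=int(series.concentrations.size * len(series.peaks)),
        redchi=float(best.redchi),
    )
    return assess_saturation(result, series, options)


def fit_slow_exchange_global(
    series: TitrationSeries, options: SaturationOptions | None = None
) -> BindingFitResult:
    """Fit intensity-decay titration traces jointly with one global Kd."""
    if series.regime != SLOW_EXCHANGE:
        raise ValueError(f"expected regime {SLOW_EXCHANGE!r}, got {series.regime!r}")
    return _fit_global(series, options or SaturationOptions())


def fit_fast_exchange_global(
    series: TitrationSeries,
    options: SaturationOptions | None = None,
    noise_floor: float = 0.0,
) -> BindingFitResult:
    """Fit chemical-shift-perturbation traces jointly with one global Kd.

    ``noise_floor`` (ppm) rejects series where no peak moves beyond noise.
    """
    if series.regime != FAST_EXCHANGE:
        raise ValueError(f"expected regime {FAST_EXCHANGE!r}, got {series.regime!r}")
    if noise_floor > 0 and np.all(np.abs(series.observables) <= noise_floor):
        raise ValueError("no binding signal: all shift perturbations below noise")
    return _fit_global(series, options or SaturationOptions())


def assess_saturation(
    result: BindingFitResult,
    series: TitrationSeries,
    options: SaturationOptions | None = None,
) -> BindingFitResult:
    """Flag a fit as a Kd lower bound when the titration is unsaturated.

    The saturation test is a strict inequality: a fit exactly at the
    threshold remains quantified.
    """
    return apply_saturation_rule(
        result, series.u0, float(series.concentrations.max()), options
    )


def apply_saturation_rule(
    result: BindingFitResult,
    u0: float,
    lmax: float,
    options: SaturationOptions | None = None,
) -> BindingFitResult:
    """Saturation/lower-bound logic shared by NMR and anisotropy fits."""
    opt = options or SaturationOptions()
    sat = float(bound_fraction_raw(result.kd, u0, lmax))

    unsaturated = sat < opt.saturation_threshold
    ci_blown = False
    if result.kd_stderr is not None and np.isfinite(result.kd_stderr):
        ci_blown = result.kd + opt.ci_z * result.kd_stderr > opt.ci_multiple * lmax
    elif result.kd_stderr is None:
        ci_blown = True  # no curvature information: Kd is not quantifiable

    if unsaturated or ci_blown:
        lb = opt.lower_bound_value(lmax) if opt.lower_bound_value else lmax
        return replace(
            result, saturation_fraction=sat, bound_flag=LOWER_BOUND,
            lower_bound_value=float(lb),
        )
    return replace(
        result, saturation_fraction=sat, bound_flag=QUANTIFIED, lower_bound_value=None
    )


def refit_excluding(
    series: TitrationSeries,
    exclude,
    options: SaturationOptions | None = None,
) -> BindingFitResult:
    """Repeat the global fit with the named peaks removed (outlier check)."""
    exclude = tuple(exclude)
    labels = series.labels
    unknown = [lbl for lbl in exclude if lbl not in labels]
    if unknown:
        raise ValueError(f"cannot exclude unknown peaks: {unknown}")
    if set(exclude) >= set(labels):
        raise ValueError("cannot exclude every peak")
    reduced = series.subset([lbl for lbl in labels if lbl not in set(exclude)])
    if series.regime == SLOW_EXCHANGE:
        result = fit_slow_exchange_global(reduced, options)
    else:
        result = fit_fast_exchange_global(reduced, options)
    return replace(result, excluded_peaks=exclude)
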