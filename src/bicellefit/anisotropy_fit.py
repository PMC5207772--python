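"""1:1 binding fits of steady-state fluorescence anisotropy titrations.

A fluorophore-labeled subunit at fixed concentration U0 is titrated with an
unlabeled partner; complex formation slows tumbling and raises the observed
anisotropy from r_free toward r_bound::

    r(L0) = r_free + (r_bound - r_free) * f_b(Kd, U0, L0)

For membrane-anchored species concentrations are in mol% of the long-chain
lipid, the natural unit for association within a bicelle; the labeled
species is the depletable observed species U0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import lmfit
import numpy as np

from .binding_core import Unit, bound_fraction_raw
from .titration_fit import (
    BindingFitResult,
    PeakEstimate,
    SaturationOptions,
    apply_saturation_rule,
)

__all__ = ["AnisotropyTitration", "fit_anisotropy", "ANISOTROPY_REGIME"]

ANISOTROPY_REGIME = "anisotropy"


@dataclass(frozen=True)
class AnisotropyTitration:
    """Anisotropy r observed across titrant concentrations.

    ``labeled_conc`` is the fixed labeled-species concentration (U0) in the
    same unit as ``titrant_concs``.  ``replicate_sd`` (optional, per point)
    weights the fit when provided.
    """

    labeled_conc: float
    titrant_concs: np.ndarray
    anisotropy: np.ndarray
    unit: Unit = Unit.MOL_PERCENT
    replicate_sd: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "unit", Unit.coerce(self.unit))
        conc = np.asarray(self.titrant_concs, dtype=float)
        r = np.asarray(self.anisotropy, dtype=float)
        if self.labeled_conc <= 0:
            raise ValueError("labeled_conc must be > 0")
        if conc.size < 5:
            raise ValueError("need >= 5 titration points")
        if conc.shape != r.shape:
            raise ValueError("titrant_concs and anisotropy must have equal length")
        if np.any(conc < 0):
            raise ValueError("titrant concentrations must be >= 0")
        if np.any((r < 0) | (r > 0.4)):
            warnings.warn(
                "anisotropy values outside the plausible 0-0.4 range", stacklevel=3
            )
        sd = self.replicate_sd
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != r.shape or np.any(sd < 0):
                raise ValueError("replicate_sd must be non-negative, one per point")
        order = np.argsort(conc, kind="stable")
        object.__setattr__(self, "titrant_concs", conc[order])
        object.__setattr__(self, "anisotropy", r[order])
        object.__setattr__(self, "replicate_sd", None if sd is None else sd[order])


def _model(kd, r_free, r_bound, u0, l0):
    return r_free + (r_bound - r_free) * bound_fraction_raw(kd, u0, l0)


def fit_anisotropy(
    t: AnisotropyTitration, options: SaturationOptions | None = None
) -> BindingFitResult:
    """Fit Kd, r_free, r_bound to an anisotropy titration.

    Kd is reported in the titration's unit; the per-peak slot of the result
    carries r_free and r_bound.  The shared saturation rule downgrades the
    fit to a Kd lower bound when the titration does not approach saturation.
    Titrations whose anisotropy only decreases are rejected (no binding
    signal, or the labeling scheme is inverted).
    """
    conc, r = t.titrant_concs, t.anisotropy
    lo = r[conc <= np.quantile(conc, 0.25)].mean()
    hi = r[conc >= np.quantile(conc, 0.75)].mean()
    if hi < lo and not np.isclose(hi, lo):
        raise ValueError("no binding signal or inverted labeling: anisotropy decreases")
    if np.allclose(r, r[0]):
        raise ValueError("no binding signal: anisotropy is constant")

    lmax = float(conc.max())
    if lmax <= 0:
        raise ValueError("titration has no nonzero titrant point")
    weights = None if t.replicate_sd is None else 1.0 / np.maximum(t.replicate_sd, 1e-12)

    def residual(p):
        res = r - _model(p["kd"].value, p["r_free"].value, p["r_bound"].value,
                         t.labeled_conc, conc)
        return res if weights is None else res * weights

    best = None
    for mult in (0.1, 1.0, 10.0):
        params = lmfit.Parameters()
        params.add("kd", value=mult * lmax, min=0.0)
        params.add("r_free", value=float(r[0]))
        params.add("r_bound", value=float(r[-1]))
        try:
            out = lmfit.minimize(residual, params, method="least_squares")
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None or not best.success:
        raise RuntimeError("anisotropy 1:1 fit failed to converge after multistart")

    kd = float(best.params["kd"].value)
    kd_stderr = best.params["kd"].stderr
    per_peak = {
        name: PeakEstimate(
            float(best.params[name].value),
            None if best.params[name].stderr is None else float(best.params[name].stderr),
        )
        for name in ("r_free", "r_bound")
    }
    result = BindingFitResult(
        kd=kd,
        kd_stderr=None if kd_stderr is None else float(kd_stderr),
        unit=t.unit,
        regime=ANISOTROPY_REGIME,
        per_peak=per_peak,
        residuals=np.asarray(best.residual, dtype=float),
        saturation_fraction=float(bound_fraction_raw(kd, t.labeled_conc, lmax)),
        n_points=int(conc.size),
        redchi=float(best.redchi),
    )
    return apply_saturation_rule(result, t.labeled_conc, lmax, options)
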