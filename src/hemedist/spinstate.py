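"""Heme spin-state quantitation from Soret-region absorbance spectra.

Ferric P450 heme is a mixture of a six-coordinate low-spin form (S = 1/2,
Soret maximum ~416-420 nm) and a five-coordinate high-spin form (S = 5/2,
Soret ~390-405 nm), with a broad delta band near 360 nm.  The spectrum
between 320 and 500 nm is deconvoluted into three Gaussian components on
the wavelength axis (optionally over a linear baseline); the high-spin
fraction is the high-spin band area over the summed Soret band areas,
with the delta band excluded from the ratio.

The effective electron-spin factor entering the paramagnetic distance
equation is the population-weighted

    S(S+1) = 8.75 * f_HS + 0.75 * f_LS,

i.e. 35/4 for pure S = 5/2 and 3/4 for pure S = 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit.models import ConstantModel, GaussianModel, LinearModel

from .errors import FitFailureError, InputError

__all__ = [
    "AbsorbanceSpectrum",
    "SpinComposition",
    "BAND_WINDOWS",
    "deconvolute_spectrum",
    "spin_factor",
]

#: Allowed center windows (nm) for the three Soret-region components.
BAND_WINDOWS = {
    "delta": (350.0, 372.0),
    "high_spin": (385.0, 407.0),
    "low_spin": (412.0, 424.0),
}

#: FWHM = FWHM_OVER_SIGMA * sigma for a Gaussian band.
FWHM_OVER_SIGMA = 2.3548200450309493

_DEFAULT_CENTERS = {"delta": 360.0, "high_spin": 392.0, "low_spin": 417.0}
#: Starting band widths as FWHM (nm); sigma = FWHM / 2.3548.
_DEFAULT_FWHM = {"delta": 20.0, "high_spin": 14.0, "low_spin": 12.0}
_SIGMA_BOUNDS = (1.5, 30.0)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """An absolute absorbance spectrum covering the 320-500 nm window."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "absorbance", a)
        if w.size != a.size:
            raise InputError("wavelength and absorbance lengths differ")
        if w.size < 50:
            raise InputError(f"need >= 50 spectrum points, got {w.size}")
        if np.any(np.diff(w) <= 0):
            raise InputError("wavelengths must be strictly ascending")
        if w[0] > 330.0 or w[-1] < 470.0:
            raise InputError(
                "spectrum must cover the Soret region (roughly 320-500 nm); "
                f"got {w[0]:.0f}-{w[-1]:.0f} nm"
            )


@dataclass(frozen=True)
class SpinComposition:
    """Low/high-spin fractions with the fitted band parameters."""

    f_low: float
    f_high: float
    component_params: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, f in (("f_low", self.f_low), ("f_high", self.f_high)):
            if not 0.0 <= f <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {f}")
        if abs(self.f_low + self.f_high - 1.0) > 1e-9:
            raise InputError("f_low + f_high must equal 1")


def _band_area(amplitude: float) -> float:
    # lmfit's GaussianModel amplitude parameter IS the area under the band.
    return max(float(amplitude), 0.0)


def deconvolute_spectrum(
    sp: AbsorbanceSpectrum, baseline: bool = True
) -> SpinComposition:
    """Fit three Gaussian bands (delta, high spin, low spin) to a spectrum.

    Band centers are bounded to their windows (delta 350-372 nm, high spin
    385-407 nm, low spin 412-424 nm); a linear baseline is included by
    default.  The spin fractions are area ratios of the two Soret bands
    only.  A band whose center or width lands on a bound is flagged.
    """
    w, a = sp.wavelengths, sp.absorbance
    scale = float(np.max(np.abs(a)))
    if scale == 0.0:
        raise FitFailureError("all-zero spectrum cannot be deconvoluted")

    model = None
    params = None
    for name in ("delta", "high_spin", "low_spin"):
        gm = GaussianModel(prefix=f"{name}_")
        model = gm if model is None else model + gm
    params = model.make_params()
    for name in ("delta", "high_spin", "low_spin"):
        lo, hi = BAND_WINDOWS[name]
        c0 = _DEFAULT_CENTERS[name]
        s0 = _DEFAULT_FWHM[name] / FWHM_OVER_SIGMA
        amp0 = float(np.interp(c0, w, a)) * s0 * math.sqrt(2 * math.pi)
        params[f"{name}_center"].set(value=c0, min=lo, max=hi)
        params[f"{name}_sigma"].set(value=s0, min=_SIGMA_BOUNDS[0],
                                    max=_SIGMA_BOUNDS[1])
        params[f"{name}_amplitude"].set(value=max(amp0, 1e-6 * scale), min=0.0)
    if baseline:
        base = LinearModel(prefix="base_")
        model = model + base
        params.update(base.make_params(slope=0.0, intercept=0.0))
    else:
        base = ConstantModel(prefix="base_")
        model = model + base
        params.update(base.make_params(c=0.0))
        params["base_c"].set(vary=False)

    result = model.fit(a, params, x=w)
    if not result.success:
        raise FitFailureError(f"spin-state deconvolution failed: {result.message}")

    warnings: list[str] = []
    component_params: dict[str, dict[str, float]] = {}
    areas: dict[str, float] = {}
    for name in ("delta", "high_spin", "low_spin"):
        center = float(result.params[f"{name}_center"].value)
        sigma = float(result.params[f"{name}_sigma"].value)
        area = _band_area(result.params[f"{name}_amplitude"].value)
        areas[name] = area
        component_params[name] = {
            "center_nm": center,
            "sigma_nm": sigma,
            "fwhm_nm": sigma * FWHM_OVER_SIGMA,
            "area": area,
        }
        lo, hi = BAND_WINDOWS[name]
        if center - lo < 1e-6 or hi - center < 1e-6:
            warnings.append(f"{name} band center pinned at window bound")
        if (sigma - _SIGMA_BOUNDS[0] < 1e-6
                or _SIGMA_BOUNDS[1] - sigma < 1e-6):
            warnings.append(f"{name} band width pinned at bound")

    soret_total = areas["high_spin"] + areas["low_spin"]
    if soret_total <= 0:
        raise FitFailureError("both Soret band areas fitted to zero")
    f_high = areas["high_spin"] / soret_total
    return SpinComposition(
        f_low=1.0 - f_high,
        f_high=f_high,
        component_params={
            **component_params,
            "fit": {"rss": float(np.sum(result.residual**2)),
                    "n_points": int(w.size)},
        },
        warnings=tuple(warnings),
    )


def spin_factor(comp: SpinComposition) -> float:
    """Population-weighted S(S+1): 8.75*f_high + 0.75*f_low."""
    return 8.75 * comp.f_high + 0.75 * comp.f_low
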