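"""Spectral binding: one-site isotherm fits and difference-spectrum typing.

Substrate binding in the P450 active site perturbs the Soret band; the
difference absorbance at a fixed wavelength pair follows the hyperbolic
one-site isotherm

    dA([S]) = Bmax * [S] / (Ks + [S]),

whose midpoint Ks is the spectral binding constant.  A type I difference
spectrum (peak near 390 nm, trough near 420 nm) signals displacement of
the axial water and a low-to-high spin shift; type II (peak ~425-440 nm,
trough ~390-410 nm) signals nitrogen coordination to the iron.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InputError

__all__ = [
    "BindingIsotherm",
    "BindingFit",
    "DifferenceSpectrum",
    "SpectrumClassification",
    "fit_binding_constant",
    "classify_difference_spectrum",
]

# Band windows for difference-spectrum classification (nm).  Centred on
# the canonical 390/417 nm type I pair with ~8 nm tolerance.
TYPE_I_MAX_WINDOW = (385.0, 400.0)
TYPE_I_MIN_WINDOW = (415.0, 425.0)
TYPE_II_MAX_WINDOW = (425.0, 440.0)
TYPE_II_MIN_WINDOW = (390.0, 410.0)


@dataclass(frozen=True)
class BindingIsotherm:
    """Difference-absorbance titration: dA versus substrate concentration."""

    substrate_conc: np.ndarray  # µM, strictly increasing
    delta_A: np.ndarray  # absorbance units
    enzyme_label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.substrate_conc, dtype=float)
        a = np.asarray(self.delta_A, dtype=float)
        object.__setattr__(self, "substrate_conc", s)
        object.__setattr__(self, "delta_A", a)
        if s.size != a.size:
            raise InputError("substrate_conc and delta_A lengths differ")
        if s.size < 5:
            raise InputError(f"need >= 5 titration points, got {s.size}")
        if np.any(s < 0):
            raise InputError("substrate concentrations must be >= 0")
        if np.any(np.diff(s) <= 0):
            raise InputError("substrate concentrations must strictly increase")


@dataclass(frozen=True)
class BindingFit:
    """Fitted Ks and Bmax with standard errors from the covariance."""

    ks: float  # µM
    ks_se: float
    bmax: float  # AU
    bmax_se: float
    fit_diagnostics: dict = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.ks > 0 and self.bmax > 0):
            raise InputError("ks and bmax must be positive")

    def predict(self, substrate_conc: np.ndarray) -> np.ndarray:
        s = np.asarray(substrate_conc, dtype=float)
        return self.bmax * s / (self.ks + s)


@dataclass(frozen=True)
class DifferenceSpectrum:
    wavelengths: np.ndarray  # nm, ascending, within 350-500
    delta_absorbance: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.delta_absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "delta_absorbance", a)
        if w.size != a.size:
            raise InputError("wavelength and absorbance lengths differ")
        if w.size < 20:
            raise InputError(f"need >= 20 spectrum points, got {w.size}")
        if np.any(np.diff(w) <= 0):
            raise InputError("wavelengths must be strictly ascending")
        if w[0] < 350.0 - 1e-9 or w[-1] > 500.0 + 1e-9:
            raise InputError("wavelengths must lie within 350-500 nm")


@dataclass(frozen=True)
class SpectrumClassification:
    spectrum_type: str  # "type I" | "type II" | "indeterminate"
    lambda_max: float
    lambda_min: float


def _hyperbola(s: np.ndarray, bmax: float, ks: float) -> np.ndarray:
    return bmax * s / (ks + s)


def fit_binding_constant(iso: BindingIsotherm) -> BindingFit:
    """Unweighted least-squares fit of the one-site binding isotherm.

    A fitted Ks above ten times the largest titrated concentration is
    returned but flagged: the plateau is then unconstrained by the data.
    """
    s, a = iso.substrate_conc, iso.delta_A
    bmax0 = float(np.max(np.abs(a))) or 1.0
    # Ks guess: concentration nearest half-maximal response.
    half_idx = int(np.argmin(np.abs(a - 0.5 * bmax0)))
    ks0 = float(s[half_idx]) if s[half_idx] > 0 else float(np.median(s[s > 0]))

    try:
        popt, pcov = curve_fit(
            _hyperbola, s, a, p0=[bmax0, ks0],
            bounds=([1e-15, 1e-15], [np.inf, np.inf]), maxfev=10000,
        )
    except (RuntimeError, ValueError) as err:
        raise FitFailureError(
            f"binding isotherm fit failed for {iso.enzyme_label!r}"
        ) from err
    bmax, ks = popt
    if not (np.isfinite(ks) and ks > 0 and np.isfinite(bmax) and bmax > 0):
        raise FitFailureError(
            f"binding fit returned non-positive parameters for "
            f"{iso.enzyme_label!r}: bmax={bmax}, ks={ks}"
        )
    resid = a - _hyperbola(s, *popt)
    warnings: list[str] = []
    if ks > 10.0 * float(s[-1]):
        warnings.append(
            f"fitted Ks ({ks:.3g} uM) exceeds 10x the highest titrated "
            f"concentration ({s[-1]:.3g} uM); saturation is unconstrained"
        )
    ses = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return BindingFit(
        ks=float(ks),
        ks_se=float(ses[1]),
        bmax=float(bmax),
        bmax_se=float(ses[0]),
        fit_diagnostics={"rss": float(resid @ resid), "n_points": int(s.size)},
        warnings=tuple(warnings),
    )


def classify_difference_spectrum(
    ds: DifferenceSpectrum, noise_floor: float = 1e-4
) -> SpectrumClassification:
    """Label a difference spectrum as type I, type II, or indeterminate.

    Classification uses the wavelengths of the global extremum pair; a
    spectrum whose total excursion is below ``noise_floor`` is flat and
    therefore indeterminate.
    """
    w, a = ds.wavelengths, ds.delta_absorbance
    lam_max = float(w[np.argmax(a)])
    lam_min = float(w[np.argmin(a)])
    if float(np.max(a) - np.min(a)) < noise_floor:
        return SpectrumClassification("indeterminate", lam_max, lam_min)

    def within(x: float, window: tuple[float, float]) -> bool:
        return window[0] <= x <= window[1]

    if within(lam_max, TYPE_I_MAX_WINDOW) and within(lam_min, TYPE_I_MIN_WINDOW):
        label = "type I"
    elif within(lam_max, TYPE_II_MAX_WINDOW) and within(
        lam_min, TYPE_II_MIN_WINDOW
    ):
        label = "type II"
    else:
        label = "indeterminate"
    return SpectrumClassification(label, lam_max, lam_min)
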