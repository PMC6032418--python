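"""Longitudinal relaxation time (T1) estimation from inversion-recovery data.

The inversion-recovery experiment (180° pulse, variable delay ``d2``, 90°
read pulse) produces a peak height that recovers from roughly ``-H_inf``
toward ``+H_inf`` with time constant T1.  Real 180° pulses are imperfect,
so the recovery is modelled with three parameters,

    H(d2) = H_inf * (1 - 2*B*exp(-d2 / T1)),

where ``B`` in (0.4, 1.1] is the inversion-efficiency factor (B = 1 for a
perfect inversion).  T1 and its standard error come from nonlinear least
squares on the (delay, height) series.

Per-proton T1 values measured on the paramagnetic ferric enzyme and on
the diamagnetic ferrous-CO complex are paired by proton label; the pairs
feed the paramagnetic-relaxation distance calculation downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitFailureError, InputError

__all__ = [
    "ENZYME_STATES",
    "InversionRecoverySeries",
    "T1Estimate",
    "RelaxationPair",
    "PairingResult",
    "fit_inversion_recovery",
    "pair_states",
]

ENZYME_STATES = ("ferric", "ferrous_CO", "free_ligand")

#: Bounds on the inversion-efficiency factor B.
B_MIN, B_MAX = 0.4, 1.1

#: Multipliers applied to the initial T1 guess on successive restarts.
RESTART_FACTORS = (1.0, 0.3, 0.5, 2.0, 3.0, 5.0)


@dataclass(frozen=True)
class InversionRecoverySeries:
    """One proton's inversion-recovery series in one enzyme state.

    delays are the recovery delays d2 in seconds; heights are the signal
    peak heights in arbitrary units (sign carries through zero-crossing).
    """

    proton_label: str
    delays: np.ndarray
    heights: np.ndarray
    enzyme_state: str
    temperature: float = 298.0

    def __post_init__(self) -> None:
        delays = np.asarray(self.delays, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "delays", delays)
        object.__setattr__(self, "heights", heights)
        if delays.ndim != 1 or heights.ndim != 1:
            raise InputError("delays and heights must be one-dimensional")
        if delays.size != heights.size:
            raise InputError(
                f"proton {self.proton_label!r}: {delays.size} delays but "
                f"{heights.size} heights"
            )
        if np.any(delays < 0):
            raise InputError(f"proton {self.proton_label!r}: negative delay")
        if np.unique(delays).size < 4:
            raise InputError(
                f"proton {self.proton_label!r}: need >= 4 distinct delays, "
                f"got {np.unique(delays).size}"
            )
        if self.enzyme_state not in ENZYME_STATES:
            raise InputError(
                f"unknown enzyme_state {self.enzyme_state!r}; "
                f"expected one of {ENZYME_STATES}"
            )
        if not self.temperature > 0:
            raise InputError("temperature must be positive kelvin")


@dataclass(frozen=True)
class T1Estimate:
    """A fitted T1 with its standard error and fit diagnostics."""

    proton_label: str
    t1: float
    se: float
    enzyme_state: str
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t1 > 0:
            raise InputError(f"proton {self.proton_label!r}: t1 must be > 0")
        if self.se < 0:
            raise InputError(f"proton {self.proton_label!r}: se must be >= 0")


@dataclass(frozen=True)
class RelaxationPair:
    """Per-proton T1 in the ferric and ferrous-CO states, with SEs."""

    proton_label: str
    t1_ferric: float
    se_ferric: float
    t1_ferrous_co: float
    se_ferrous_co: float

    def __post_init__(self) -> None:
        if not (self.t1_ferric > 0 and self.t1_ferrous_co > 0):
            raise InputError(
                f"proton {self.proton_label!r}: T1 values must be > 0"
            )
        if self.se_ferric < 0 or self.se_ferrous_co < 0:
            raise InputError(
                f"proton {self.proton_label!r}: standard errors must be >= 0"
            )


@dataclass(frozen=True)
class PairingResult:
    pairs: tuple[RelaxationPair, ...]
    unpaired_ferric: tuple[str, ...]
    unpaired_ferrous_co: tuple[str, ...]


def _recovery(d2: np.ndarray, h_inf: float, b: float, t1: float) -> np.ndarray:
    return h_inf * (1.0 - 2.0 * b * np.exp(-d2 / t1))


def _initial_t1(delays: np.ndarray, heights: np.ndarray) -> float:
    # Delay of the sign change maps to T1 via H(t_zero)=0 at B=1:
    # t_zero = T1 * ln 2.  Fall back to the median delay if no crossing.
    order = np.argsort(delays)
    d, h = delays[order], heights[order]
    sign_change = np.nonzero(np.diff(np.sign(h)) != 0)[0]
    if sign_change.size:
        t_zero = d[sign_change[0] + 1]
    else:
        t_zero = float(np.median(d))
    return max(t_zero / math.log(2.0), 1e-6)


def fit_inversion_recovery(series: InversionRecoverySeries) -> T1Estimate:
    """Fit H(d2) = H_inf*(1 - 2B*exp(-d2/T1)) and return T1 with its SE.

    Up to five restarts scale the initial T1 guess before the fit is
    declared failed.  The SE is the square root of the T1 diagonal entry
    of the least-squares covariance.

    Raises
    ------
    FitFailureError
        If no restart converges to a positive, finite T1.
    """
    d, h = series.delays, series.heights
    h_inf0 = float(np.max(np.abs(h)))
    if h_inf0 == 0.0:
        raise FitFailureError(
            f"proton {series.proton_label!r}: all-zero heights"
        )
    t1_0 = _initial_t1(d, h)
    lower = [1e-12, B_MIN, 1e-12]
    upper = [np.inf, B_MAX, np.inf]

    last_err: Exception | None = None
    for factor in RESTART_FACTORS:
        p0 = [h_inf0, 1.0, t1_0 * factor]
        try:
            popt, pcov = curve_fit(
                _recovery, d, h, p0=p0, bounds=(lower, upper), maxfev=10000
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
            continue
        h_inf, b, t1 = popt
        var_t1 = pcov[2, 2]
        if not (np.isfinite(t1) and t1 > 0 and np.isfinite(var_t1)):
            continue
        resid = h - _recovery(d, *popt)
        rss = float(resid @ resid)
        return T1Estimate(
            proton_label=series.proton_label,
            t1=float(t1),
            se=float(math.sqrt(max(var_t1, 0.0))),
            enzyme_state=series.enzyme_state,
            fit_diagnostics={
                "rss": rss,
                "n_points": int(d.size),
                "h_inf": float(h_inf),
                "b": float(b),
                "restart_factor": factor,
            },
        )
    raise FitFailureError(
        f"inversion-recovery fit failed for proton {series.proton_label!r} "
        f"after {len(RESTART_FACTORS)} starts"
    ) from last_err


def pair_states(
    ferric: list[T1Estimate], ferrous_co: list[T1Estimate]
) -> PairingResult:
    """Match ferric and ferrous-CO T1 estimates by proton label.

    Labels present in only one list are reported as unpaired rather than
    silently dropped; an empty intersection is an error.
    """
    by_label_f = {e.proton_label: e for e in ferric}
    by_label_co = {e.proton_label: e for e in ferrous_co}
    shared = [lab for lab in by_label_f if lab in by_label_co]
    if not shared:
        raise InputError(
            "no proton label is present in both the ferric and ferrous-CO "
            "estimate lists"
        )
    pairs = tuple(
        RelaxationPair(
            proton_label=lab,
            t1_ferric=by_label_f[lab].t1,
            se_ferric=by_label_f[lab].se,
            t1_ferrous_co=by_label_co[lab].t1,
            se_ferrous_co=by_label_co[lab].se,
        )
        for lab in shared
    )
    return PairingResult(
        pairs=pairs,
        unpaired_ferric=tuple(l for l in by_label_f if l not in by_label_co),
        unpaired_ferrous_co=tuple(
            l for l in by_label_co if l not in by_label_f
        ),
    )
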