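"""Exception hierarchy shared across the package."""


class HemedistError(Exception):
    """Base class for all package-specific errors."""


class InputError(HemedistError, ValueError):
    """Raised when input data violate a documented precondition."""


class FitFailureError(HemedistError, RuntimeError):
    """Raised when a nonlinear fit fails to converge after bounded restarts."""


class NoParamagneticEffectError(InputError):
    """Raised when the ferric T1 is not shorter than the ferrous-CO T1.

    The paramagnetic ferric enzyme must relax ligand protons faster than
    the diamagnetic ferrous-CO reference; otherwise the paramagnetic rate
    1/T1P is non-positive and no distance can be derived.
    """
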