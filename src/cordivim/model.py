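"""Biexponential intravoxel incoherent motion (IVIM) forward model.

The diffusion-weighted signal of perfused tissue is modelled as the sum of a
microvascular (pseudo-diffusion) compartment and a tissue-water compartment::

    S(b) = S0 * exp(-b * D) * [ F * exp(-b * D*) + (1 - F) ]

where ``F`` is the microvascular volume fraction (stored as a fraction in
[0, 1]; reported in percent only at output boundaries), ``D*`` the
pseudo-diffusion coefficient and ``D`` the tissue diffusion coefficient, both
in mm^2/s.  The perfusion term decays out of the signal at low b-values, so
the high-b tail is mono-exponential in ``D``.

Everything here is a pure function shared by the fitting and simulation
layers; nothing touches I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateSignalError, InvalidParameterError, InvalidSignalError

__all__ = [
    "IVIMParams",
    "BValueScheme",
    "SignalDecay",
    "DEFAULT_BVALUES",
    "DEFAULT_CUTOFF_B",
    "F_BOUNDS",
    "DSTAR_BOUNDS",
    "D_BOUNDS",
    "ivim_signal",
    "monoexp_signal",
    "forward_signal",
    "r_squared",
]

#: Acquisition scheme: 14 b-values, 0 to 650 s/mm^2 in steps of 50.
DEFAULT_BVALUES: tuple[float, ...] = tuple(float(b) for b in range(0, 700, 50))

#: High-b threshold separating the diffusion-only regime (s/mm^2).
DEFAULT_CUTOFF_B: float = 400.0

#: Physical fit bounds: F as a fraction, D* and D in mm^2/s.
F_BOUNDS: tuple[float, float] = (0.0, 0.20)
DSTAR_BOUNDS: tuple[float, float] = (0.3e-3, 50e-3)
D_BOUNDS: tuple[float, float] = (1.5e-4, 54e-4)


@dataclass(frozen=True)
class IVIMParams:
    """One voxel's (or ROI's) IVIM model state.

    Parameters
    ----------
    S0 : float
        Signal amplitude at b=0 (arbitrary units, > 0).
    F : float
        Microvascular volume fraction, stored as a fraction in [0, 1].
    Dstar : float
        Pseudo-diffusion coefficient (mm^2/s).
    D : float
        Tissue diffusion coefficient (mm^2/s).

    The blood-flow-related product ``FDstar`` is derived, never fitted.
    """

    S0: float
    F: float
    Dstar: float
    D: float

    def __post_init__(self) -> None:
        vals = (self.S0, self.F, self.Dstar, self.D)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite IVIM parameter in {vals}")
        if self.S0 <= 0:
            raise InvalidParameterError(f"S0 must be positive, got {self.S0}")
        if not 0.0 <= self.F <= 1.0:
            raise InvalidParameterError(f"F must lie in [0, 1], got {self.F}")
        if self.Dstar < 0 or self.D < 0:
            raise InvalidParameterError("diffusion coefficients must be non-negative")

    @property
    def FDstar(self) -> float:
        """Derived product F * D* (mm^2/s), proportionally related to blood flow."""
        return self.F * self.Dstar

    @property
    def F_percent(self) -> float:
        """F expressed in percent (reporting convention)."""
        return 100.0 * self.F

    def as_dict(self) -> dict[str, float]:
        return {
            "S0": self.S0,
            "F": self.F,
            "Dstar": self.Dstar,
            "D": self.D,
            "FDstar": self.FDstar,
        }


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion-weighting scheme with a high-b cut-off.

    ``bvalues`` must be strictly increasing and start at 0; at least two
    b-values must lie strictly above ``cutoff`` so the mono-exponential prior
    fit of D is well-posed.
    """

    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    cutoff: float = DEFAULT_CUTOFF_B

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float)
        object.__setattr__(self, "bvalues", tuple(b.tolist()))
        if b.size < 3:
            raise InvalidSignalError("scheme needs at least 3 b-values")
        if b[0] != 0.0:
            raise InvalidSignalError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise InvalidSignalError("b-values must be strictly increasing")
        if int(np.sum(b > self.cutoff)) < 2:
            raise InvalidSignalError(
                f"need >= 2 b-values above cutoff {self.cutoff}, scheme has "
                f"{int(np.sum(b > self.cutoff))}"
            )

    @property
    def b(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)

    @property
    def high_b_mask(self) -> np.ndarray:
        """Boolean mask of b-values strictly above the cut-off."""
        return self.b > self.cutoff

    def __len__(self) -> int:
        return len(self.bvalues)


@dataclass(frozen=True)
class SignalDecay:
    """A b-value-indexed (repetition-averaged) signal vector.

    ``weight`` optionally records the total probability mass behind the decay
    when it is a weighted ROI average.
    """

    scheme: BValueScheme
    values: tuple[float, ...]
    weight: float | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", tuple(v.tolist()))
        if v.size != len(self.scheme):
            raise InvalidSignalError(
                f"decay has {v.size} values for {len(self.scheme)} b-values"
            )
        if not np.all(np.isfinite(v)):
            raise InvalidSignalError("decay contains non-finite values")
        if np.any(v < 0):
            raise InvalidSignalError("decay contains negative values")

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def ivim_signal(
    b: Sequence[float] | np.ndarray | float,
    S0: float,
    F: float,
    Dstar: float,
    D: float,
) -> np.ndarray:
    """Evaluate the biexponential IVIM signal at arbitrary b >= 0.

    Array-valued core used by both fitting and simulation; no validation
    beyond finiteness is performed here (the optimizer enforces bounds).
    """
    b = np.asarray(b, dtype=float)
    return S0 * np.exp(-b * D) * (F * np.exp(-b * Dstar) + (1.0 - F))


def monoexp_signal(
    b: Sequence[float] | np.ndarray | float, S0: float, D: float
) -> np.ndarray:
    """Mono-exponential sub-model S0 * exp(-b D) governing the high-b tail."""
    b = np.asarray(b, dtype=float)
    return S0 * np.exp(-b * D)


def forward_signal(params: IVIMParams, scheme: BValueScheme) -> SignalDecay:
    """Evaluate the IVIM model on a scheme, returning a :class:`SignalDecay`.

    Raises
    ------
    InvalidParameterError
        If any parameter is non-finite or negative (enforced by IVIMParams).
    """
    y = ivim_signal(scheme.b, params.S0, params.F, params.Dstar, params.D)
    return SignalDecay(scheme=scheme, values=tuple(y.tolist()))


def r_squared(observed, fitted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Accepts :class:`SignalDecay` objects or plain arrays of equal length
    (>= 3 points).  SS_tot is taken about the mean of the observed signal;
    the result is <= 1 and may be negative for a fit worse than the mean.

    Raises
    ------
    DegenerateSignalError
        If the observed signal is constant (SS_tot == 0).
    """
    obs = observed.y if isinstance(observed, SignalDecay) else np.asarray(observed, float)
    fit = fitted.y if isinstance(fitted, SignalDecay) else np.asarray(fitted, float)
    if obs.shape != fit.shape:
        raise InvalidSignalError("observed and fitted signals differ in length")
    if obs.size < 3:
        raise InvalidSignalError("R^2 needs at least 3 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateSignalError("constant observed signal: R^2 undefined")
    ss_res = float(np.sum((obs - fit) ** 2))
    return 1.0 - ss_res / ss_tot
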