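"""Periodic external drives for the E-I network.

The oscillatory input from an upstream population is modelled as a
T-periodic von Mises density ``p(t) = exp(kappa*cos(2*pi*(t-mu)/T)) /
I0(kappa)`` whose temporal average over one period is exactly one for
every coherence ``kappa``; the drive applied to the voltage equations is
``g(t) = A * p(t)``.  The ``kappa -> inf`` limit is a train of delta
pulses (handled symbolically, never sampled), and brief square test
pulses model optogenetic-style kicks to the E-cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.special import i0e

__all__ = [
    "VonMisesInput",
    "PulseTrain",
    "SquarePulse",
    "ForcingSpec",
    "von_mises_eval",
    "square_pulse_eval",
    "arrange_two_inputs",
]


@dataclass(frozen=True)
class VonMisesInput:
    """One periodic volley train of amplitude ``A``, period ``T`` (ms),
    coherence ``kappa`` and peak time ``mu`` (ms)."""

    A: float
    T: float
    kappa: float = 2.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("input period T must be positive")
        if self.kappa < 0:
            raise ValueError("coherence kappa must be nonnegative")
        if self.A < 0:
            raise ValueError("amplitude A must be nonnegative")

    def profile(self, t):
        """The normalised density p(t) (period-average one).

        Evaluated in log-space with the scaled Bessel function so large
        kappa never overflows."""
        c = np.cos(2.0 * np.pi * (np.asarray(t, dtype=float) - self.mu) / self.T)
        return np.exp(self.kappa * (c - 1.0)) / i0e(self.kappa)

    def __call__(self, t):
        return self.A * self.profile(t)


@dataclass(frozen=True)
class PulseTrain:
    """Pulsatile limit (kappa -> inf): p(t) = T * sum_i delta(t - t0 - i*T).

    Symbolic only -- used by the closed-form stroboscopic map and the
    analytic Arnold-tongue boundaries, never sampled on a grid."""

    A: float
    T: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("pulse-train period T must be positive")


@dataclass(frozen=True)
class SquarePulse:
    """Square current pulse applied to the E-cell voltage equation."""

    amplitude: float = 1.5
    duration: float = 2.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.onset) & (t < self.onset + self.duration),
                        self.amplitude, 0.0)


def von_mises_eval(inp: VonMisesInput, t):
    """Drive value A * p(t) of a von Mises input."""
    return inp(t)


def square_pulse_eval(pulse: SquarePulse, t):
    """Square-pulse current at time t (E-population voltage only)."""
    return pulse(t)


@dataclass(frozen=True)
class ForcingSpec:
    """One or two periodic inputs plus an optional square pulse.

    ``drive_e`` / ``drive_i`` select which population voltages receive the
    periodic drive (the square pulse always targets only the E-cells).
    """

    inputs: Tuple[VonMisesInput, ...] = ()
    pulse: Optional[SquarePulse] = None
    drive_e: bool = True
    drive_i: bool = True

    def __post_init__(self) -> None:
        if len(self.inputs) > 2:
            raise ValueError("at most two periodic inputs are supported")

    def g(self, t):
        """Combined periodic drive g(t) = sum_k A_k p_k(t)."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for inp in self.inputs:
            out = out + inp(t)
        return out

    def g_e(self, t):
        out = self.g(t) * (1.0 if self.drive_e else 0.0)
        if self.pulse is not None:
            out = out + self.pulse(t)
        return out

    def g_i(self, t):
        return self.g(t) * (1.0 if self.drive_i else 0.0)

    def kernel_args(self):
        """Pack into the flat arrays the jitted integrators consume."""
        n = len(self.inputs)
        fA = np.array([inp.A for inp in self.inputs], dtype=float)
        fT = np.array([inp.T for inp in self.inputs], dtype=float)
        fk = np.array([inp.kappa for inp in self.inputs], dtype=float)
        fmu = np.array([inp.mu for inp in self.inputs], dtype=float)
        fi0inv = np.array([1.0 / i0e(inp.kappa) for inp in self.inputs],
                          dtype=float) if n else np.empty(0)
        if self.pulse is not None:
            pamp = float(self.pulse.amplitude)
            pon = float(self.pulse.onset)
            poff = float(self.pulse.onset + self.pulse.duration)
        else:
            pamp, pon, poff = 0.0, 0.0, 0.0
        de = 1.0 if self.drive_e else 0.0
        di = 1.0 if self.drive_i else 0.0
        return fA, fT, fk, fmu, fi0inv, de, di, pamp, pon, poff


#: forcing with no inputs at all (unperturbed network)
NO_FORCING = ForcingSpec()


def arrange_two_inputs(primary: VonMisesInput,
                       distractor: VonMisesInput) -> ForcingSpec:
    """Place a distractor relative to the primary input.

    The primary must peak at mu = 0.  The peak of the input with the
    larger period is placed midway between two consecutive peaks of the
    faster one: mu2 = T1/2 if T2 >= T1 (antiphase when the periods are
    equal), otherwise mu2 = T2/2.
    """
    if primary.mu != 0.0:
        raise ValueError("primary input must have mu = 0")
    if distractor.T >= primary.T:
        mu2 = primary.T / 2.0
    else:
        mu2 = distractor.T / 2.0
    return ForcingSpec(inputs=(primary, replace(distractor, mu=mu2)))
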