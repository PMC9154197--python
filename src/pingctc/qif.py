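"""Microscopic QIF network simulator — the spiking ground truth.

Two all-to-all coupled populations of quadratic integrate-and-fire
neurons, tau V' = V^2 + eta_j + I, with Lorentzian-distributed bias
currents eta_j, threshold/reset at +/-500 and a refractory hold of
T_ref = 2*tau/V_th after each spike.  Synaptic variables follow
tau_sb S'_ab = -S_ab + J_ab r_b(t) with the population delta-rate drive
(each presynaptic spike increments S_ab by J_ab/(N_b tau_sb) on the next
Euler step).  In the large-N limit the population averages of this
network are described exactly by the 8-D mean-field model, which is what
the simulator is used to validate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .forcing import ForcingSpec, NO_FORCING
from .meanfield import ModelParams

__all__ = [
    "QIFParams",
    "SpikeRaster",
    "RateTrace",
    "sample_lorentzian",
    "simulate_qif",
    "empirical_rate",
    "step_protocol_comparison",
]

V_TH_DEFAULT = 500.0


def sample_lorentzian(n: int, center: float, half_width: float,
                      mode: str = "deterministic",
                      seed: Optional[int] = None) -> np.ndarray:
    """Bias currents from the Lorentzian of the mean-field reduction.

    'deterministic' returns the symmetric quantiles
    eta_j = center + half_width * tan(pi/2 * (2j - n - 1)/(n + 1)),
    j = 1..n (noise-free representation of the distribution, handy in
    tests); 'random' draws by inverse CDF with the given seed.
    """
    if n < 1:
        raise ValueError("need at least one sample")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if mode == "deterministic":
        j = np.arange(1, n + 1)
        return center + half_width * np.tan(
            0.5 * np.pi * (2.0 * j - n - 1.0) / (n + 1.0))
    if mode == "random":
        rng = np.random.default_rng(seed)
        u = rng.random(n)
        return center + half_width * np.tan(np.pi * (u - 0.5))
    raise ValueError(f"unknown sampling mode {mode!r}")


@dataclass(frozen=True)
class QIFParams:
    """Sizes and single-neuron constants of the spiking network; the rest
    (time constants, coupling, drives) is shared with ModelParams."""

    model: ModelParams = field(default_factory=ModelParams)
    N_e: int = 5000
    N_i: int = 5000
    v_th: float = V_TH_DEFAULT
    v_reset: float = -V_TH_DEFAULT
    eta_mode: str = "deterministic"
    seed: Optional[int] = None

    @property
    def T_ref_e(self) -> float:
        return 2.0 * self.model.tau_e / self.v_th

    @property
    def T_ref_i(self) -> float:
        return 2.0 * self.model.tau_i / self.v_th

    def eta_samples(self) -> Tuple[np.ndarray, np.ndarray]:
        m = self.model
        se = si = None
        if self.seed is not None:
            se, si = self.seed, self.seed + 1
        eta_e = sample_lorentzian(self.N_e, m.eta_e, m.delta_e,
                                  self.eta_mode, se)
        eta_i = sample_lorentzian(self.N_i, m.eta_i, m.delta_i,
                                  self.eta_mode, si)
        return eta_e, eta_i


@dataclass
class SpikeRaster:
    """Spike times with neuron ids; ids < N_e are excitatory."""

    times: np.ndarray
    neuron_ids: np.ndarray
    N_e: int
    N_i: int
    t_end: float

    @property
    def is_excitatory(self) -> np.ndarray:
        return self.neuron_ids < self.N_e

    def population(self, which: str) -> "SpikeRaster":
        mask = self.is_excitatory if which == "e" else ~self.is_excitatory
        return SpikeRaster(self.times[mask], self.neuron_ids[mask],
                           self.N_e, self.N_i, self.t_end)

    def subsample(self, n: int, seed: int = 0) -> "SpikeRaster":
        """Raster restricted to n randomly chosen neurons (plot-style)."""
        rng = np.random.default_rng(seed)
        chosen = rng.choice(self.N_e + self.N_i, size=n, replace=False)
        mask = np.isin(self.neuron_ids, chosen)
        return SpikeRaster(self.times[mask], self.neuron_ids[mask],
                           self.N_e, self.N_i, self.t_end)

    def write(self, prefix: str) -> None:
        """Two-column whitespace text `time_ms neuron_id` plus a
        population map file."""
        path = Path(f"{prefix}_spikes.txt")
        np.savetxt(path, np.column_stack([self.times, self.neuron_ids]),
                   fmt="%.6f %d")
        pop = np.zeros(self.N_e + self.N_i, dtype=int)
        pop[self.N_e:] = 1
        np.savetxt(Path(f"{prefix}_popmap.txt"),
                   np.column_stack([np.arange(pop.size), pop]), fmt="%d %d")

    @classmethod
    def read(cls, prefix: str, t_end: float) -> "SpikeRaster":
        data = np.loadtxt(f"{prefix}_spikes.txt", ndmin=2)
        pop = np.loadtxt(f"{prefix}_popmap.txt", dtype=int, ndmin=2)
        N_e = int(np.sum(pop[:, 1] == 0))
        N_i = int(np.sum(pop[:, 1] == 1))
        times = data[:, 0] if data.size else np.empty(0)
        ids = data[:, 1].astype(int) if data.size else np.empty(0, int)
        return cls(times, ids, N_e, N_i, t_end)


@dataclass
class RateTrace:
    """Population rate per time bin, in spikes/ms per neuron."""

    t: np.ndarray
    rate: np.ndarray
    bin_width: float
    N: int

    def total_spikes(self) -> float:
        return float(np.sum(self.rate) * self.bin_width * self.N)


def simulate_qif(qif: QIFParams, forcing: ForcingSpec = NO_FORCING,
                 t_end: float = 100.0, dt: float = 1e-4,
                 Ie_step: Optional[Tuple[float, float]] = None,
                 forcing_onset: float = 0.0,
                 record_synapses: bool = False, rec_stride: int = 100,
                 ) -> Tuple[SpikeRaster, Optional[np.ndarray]]:
    """Euler simulation of the spiking network.

    ``Ie_step`` = (switch time, drive before) implements step protocols
    where the tonic E-drive jumps to its ModelParams value at the switch
    time (the classic rest -> oscillation transition); the periodic drive
    is off before ``forcing_onset``.  Returns the spike raster and,
    optionally, the synaptic traces (See, Sei, Sie, Sii) recorded every
    ``rec_stride`` steps.
    """
    if dt > 1e-3:
        raise ValueError("Euler step must satisfy dt <= 1e-3 ms")
    eta_e, eta_i = qif.eta_samples()
    fargs = forcing.kernel_args()

    n_steps = int(np.round(t_end / dt))
    # generous spike buffer: gamma rates stay well below 0.15 spikes/ms/neuron
    cap = int(0.15 * (qif.N_e + qif.N_i) * max(t_end, 1.0)) + 10000
    spike_t = np.empty(cap)
    spike_id = np.empty(cap, dtype=np.int64)

    stride = rec_stride if record_synapses else 0
    nrec = n_steps // rec_stride + 1 if record_synapses else 1
    rec_S = np.zeros((nrec, 4))

    sw_t, sw_before = (0.0, 0.0) if Ie_step is None else Ie_step

    ns = _kernels.qif_euler(eta_e, eta_i, qif.model.as_array(), *fargs,
                            t_end, dt, qif.v_th, qif.v_reset,
                            sw_t, sw_before, forcing_onset,
                            spike_t, spike_id, stride, rec_S)
    if ns < 0:
        raise RuntimeError("spike buffer overflow; raise the capacity")
    raster = SpikeRaster(times=spike_t[:ns].copy(),
                         neuron_ids=spike_id[:ns].copy(),
                         N_e=qif.N_e, N_i=qif.N_i, t_end=t_end)
    if not np.all(np.isfinite(raster.times)):
        raise FloatingPointError("non-finite spike times")
    return raster, (rec_S if record_synapses else None)


def step_protocol_comparison(model: ModelParams, N: int = 5000,
                             dt: float = 1e-4,
                             t_switch: float = 20.0, t_forcing: float = 50.0,
                             t_end: float = 80.0,
                             A: float = 0.1, kappa: float = 2.0,
                             T: Optional[float] = None,
                             eta_mode: str = "deterministic",
                             seed: Optional[int] = None,
                             bin_width: float = 0.08):
    """Rest -> oscillation -> entrainment protocol, spiking vs mean-field.

    Both models start from rest (V = -1, no synaptic activity) with zero
    tonic E-drive; the drive steps to its ModelParams value at
    ``t_switch`` and a von Mises input of amplitude ``A`` switches on at
    ``t_forcing``.  Returns a DataFrame with the binned QIF population
    rates and the mean-field rates on the same time grid — in the large-N
    limit the curves lie on top of each other.
    """
    import pandas as pd

    from .forcing import VonMisesInput
    from .meanfield import integrate

    if T is None:
        raise ValueError("forcing period T must be given")
    f = ForcingSpec(inputs=(VonMisesInput(A=A, T=T, kappa=kappa),))
    qp = QIFParams(model=model, N_e=N, N_i=N, eta_mode=eta_mode, seed=seed)
    raster, _ = simulate_qif(qp, f, t_end=t_end, dt=dt,
                             Ie_step=(t_switch, 0.0),
                             forcing_onset=t_forcing)
    rate_e = empirical_rate(raster, bin_width, "e")
    rate_i = empirical_rate(raster, bin_width, "i")

    x = np.array([0.0, -1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0])
    t_grid = rate_e.t
    mf_t, mf_y = [], []
    stages = [
        (0.0, t_switch, model.with_drives(Ie=0.0), ForcingSpec()),
        (t_switch, t_forcing, model, ForcingSpec()),
        (t_forcing, t_end, model, f),
    ]
    for a, b, params, frc in stages:
        te = t_grid[(t_grid >= a) & (t_grid < b)]
        sol = integrate(x, (a, b), params, frc,
                        t_eval=np.concatenate([te, [b]]))
        x = sol.y[:, -1]
        mf_t.append(sol.t[:-1])
        mf_y.append(sol.y[:, :-1])
    mf_t = np.concatenate(mf_t)
    mf_y = np.concatenate(mf_y, axis=1)
    n = min(len(mf_t), len(t_grid))
    return pd.DataFrame({
        "t": t_grid[:n],
        "qif_r_e": rate_e.rate[:n],
        "qif_r_i": rate_i.rate[:n],
        "mf_r_e": np.interp(t_grid[:n], mf_t, mf_y[0]),
        "mf_r_i": np.interp(t_grid[:n], mf_t, mf_y[4]),
    })


def empirical_rate(raster: SpikeRaster, bin_width: float = 0.08,
                   population: str = "e",
                   smooth: int = 0) -> RateTrace:
    """Population firing rate from the raster: spike counts per bin
    divided by (bin width * population size).  Optional moving-average
    smoothing over ``smooth`` bins (off by default)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sub = raster.population(population)
    N = raster.N_e if population == "e" else raster.N_i
    edges = np.arange(0.0, raster.t_end + bin_width, bin_width)
    counts, _ = np.histogram(sub.times, bins=edges)
    rate = counts / (bin_width * N)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        rate = np.convolve(rate, kernel, mode="same")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RateTrace(t=centers, rate=rate, bin_width=bin_width, N=N)
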