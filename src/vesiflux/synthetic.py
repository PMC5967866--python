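"""Synthetic assay data with the statistical structure the analysis expects.

Every generator draws from an explicitly seeded ``numpy`` Generator (no
global RNG) and returns the same container types the analysis stages
consume, so the whole pipeline is testable without any measured dataset.

Noise model: multiplicative Gaussian with a fixed coefficient of variation,
truncated at zero — radiometric assays show roughly constant relative
error. Poisson counting noise is available for cpm-mode time courses.

The passive-flux simulator obeys a strict thermodynamic constraint: with no
coupling term the internal concentration can never exceed the external one,
so fold accumulation is bounded by 1. The commonly observed post-peak
decline of measured uptake curves has no agreed mechanism; it is mimicked,
optionally, by a phenomenological exponentially decaying vesicle-integrity
factor, clearly a curve-shape device rather than a transport model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .accumulation import UptakeTimeCourse
from .electro import IVTable
from .kinetics import DoseResponse, RateTable


@dataclass(frozen=True)
class SimConfig:
    """Shared simulation settings.

    seed is mandatory; noise_cv is the fractional coefficient of variation
    of the multiplicative measurement noise; n_replicates is the number of
    independent repeats per condition.
    """

    seed: int
    noise_cv: float = 0.05
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


DEFAULT_TIME_GRID = np.array([2.0, 5.0, 10.0, 15.0, 30.0, 60.0, 90.0, 120.0])

MMOL_TO_NMOL = 1e6


def _noisy(mean: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative Gaussian noise of coefficient of variation cv, clipped at 0."""
    if cv == 0:
        return mean.copy()
    return np.clip(mean * (1.0 + cv * rng.standard_normal(mean.shape)), 0.0, None)


def passive_mean_concentration(
    t: np.ndarray, c_out: float, k_eq: float, leak: float
) -> np.ndarray:
    """Closed-form mean internal concentration (mM) of the passive model.

    dC_in/dt = k_eq*(c_out - C_in) - leak*C_in, C_in(0) = 0, which relaxes
    to the steady state c_out*k_eq/(k_eq+leak) with rate k_eq+leak.
    """
    t = np.asarray(t, dtype=float)
    k_tot = k_eq + leak
    if k_tot == 0:
        return np.zeros_like(t)
    c_ss = c_out * k_eq / k_tot
    return c_ss * (1.0 - np.exp(-k_tot * t))


def coupled_mean_concentration(
    t: np.ndarray, c_out: float, fold_limit: float, k: float
) -> np.ndarray:
    """Mean internal concentration (mM) of the ion-coupled model.

    C_in(t) = fold_limit * c_out * (1 - exp(-k t)): exponential relaxation
    to a steady state ``fold_limit``-fold above the external concentration,
    the thermodynamic limit set by the driving-ion electrochemical gradient.
    """
    t = np.asarray(t, dtype=float)
    return fold_limit * c_out * (1.0 - np.exp(-k * t))


def _amounts_time_course(
    times: np.ndarray,
    c_mean: np.ndarray,
    v_internal: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    integrity_decay: float,
    integrity_floor: float,
    condition: str,
) -> UptakeTimeCourse:
    amounts_nmol = c_mean * v_internal * MMOL_TO_NMOL  # mM * L -> mmol -> nmol
    if integrity_decay > 0:
        integrity = integrity_floor + (1.0 - integrity_floor) * np.exp(
            -integrity_decay * times
        )
        amounts_nmol = amounts_nmol * integrity
    all_t, all_a, all_rep = [], [], []
    for rep in range(cfg.n_replicates):
        all_t.append(times)
        all_a.append(_noisy(amounts_nmol, cfg.noise_cv, rng))
        all_rep.append(np.full(times.shape, rep))
    return UptakeTimeCourse(
        times=np.concatenate(all_t),
        amounts=np.concatenate(all_a),
        amount_unit="nmol",
        replicate_ids=np.concatenate(all_rep),
        condition=condition,
    )


def simulate_passive_uptake(
    c_out: float,
    k_eq: float,
    v_internal: float,
    cfg: SimConfig,
    leak: float = 0.0,
    time_grid: Optional[np.ndarray] = None,
    integrity_decay: float = 0.0,
    integrity_floor: float = 0.6,
) -> UptakeTimeCourse:
    """Passive (uncoupled, channel-like) uptake time course.

    First-order equilibration of the internal concentration toward the
    external one; amounts are C_in * v_internal in nmol. The mean is
    monotone; a peak-then-decline shape is available through the
    phenomenological integrity factor (``integrity_decay`` > 0).
    """
    if min(c_out, k_eq, leak, v_internal) < 0:
        raise ValueError("all passive-model parameters must be >= 0")
    times = DEFAULT_TIME_GRID if time_grid is None else np.asarray(time_grid, dtype=float)
    c_mean = passive_mean_concentration(times, c_out, k_eq, leak)
    return _amounts_time_course(
        times, c_mean, v_internal, cfg, cfg.rng(),
        integrity_decay, integrity_floor, condition="passive",
    )


def simulate_coupled_uptake(
    c_out: float,
    fold_limit: float,
    k: float,
    v_internal: float,
    cfg: SimConfig,
    time_grid: Optional[np.ndarray] = None,
) -> UptakeTimeCourse:
    """Ion-coupled concentrative uptake time course (symporter-like)."""
    if fold_limit < 1:
        raise ValueError("fold_limit must be >= 1")
    times = DEFAULT_TIME_GRID if time_grid is None else np.asarray(time_grid, dtype=float)
    c_mean = coupled_mean_concentration(times, c_out, fold_limit, k)
    return _amounts_time_course(
        times, c_mean, v_internal, cfg, cfg.rng(), 0.0, 1.0, condition="coupled",
    )


DEFAULT_MM_GRID = np.geomspace(0.5, 50.0, 8)  # mM


def simulate_mm_rates(
    km: float,
    vmax: float,
    cfg: SimConfig,
    grid: Optional[np.ndarray] = None,
) -> RateTable:
    """Michaelis-Menten initial-rate data with replicate multiplicative noise.

    Default grid: 8 log-spaced concentrations over 0.5-50 mM, bracketing a
    Km in the mM range; replicates per concentration from cfg.
    """
    grid = DEFAULT_MM_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = cfg.rng()
    conc = np.tile(grid, cfg.n_replicates)
    mean = vmax * conc / (km + conc)
    return RateTable(substrate_conc=conc, rate=_noisy(mean, cfg.noise_cv, rng))


DEFAULT_DOSE_GRID = np.geomspace(1e-5, 1.0, 10)  # M, 10 uM - 1 M


def simulate_displacement(
    x50: float,
    cfg: SimConfig,
    hill: float = 1.0,
    top: float = 10000.0,
    bottom: float = 0.0,
    background: float = 500.0,
    grid: Optional[np.ndarray] = None,
) -> DoseResponse:
    """Displacement / inhibition isotherm with a constant background channel.

    Log-logistic mean plus multiplicative noise; the recorded signal is the
    specific curve plus a non-proximity background, returned alongside so
    the fitting stage can subtract it.
    """
    grid = DEFAULT_DOSE_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = cfg.rng()
    specific = bottom + (top - bottom) / (1.0 + (grid / x50) ** hill)
    signal = _noisy(specific + background, cfg.noise_cv, rng)
    return DoseResponse(ligand_conc=grid, signal=signal, background=background)


DEFAULT_IV_VOLTAGES = np.arange(-100.0, 101.0, 25.0)  # mV


def simulate_gated_trace(
    g: float,
    voltage: float,
    cfg: SimConfig,
    v_rev: float = 0.0,
    open_prob: float = 0.8,
    n_channels: int = 1,
    k_total: float = 100.0,
    n_samples: int = 2000,
    dt: float = 1e-4,
    baseline_noise_pA: float = 0.05,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One gated single-channel current sweep at a fixed holding voltage.

    Each of ``n_channels`` independent channels follows a two-state Markov
    chain with stationary open probability ``open_prob`` and total switching
    rate ``k_total`` (s^-1); the recorded current is
    n_open * g * (V - v_rev) plus Gaussian baseline noise, so a trace from
    n channels shows up to n+1 discrete levels.

    Returns (time s, current pA, open-channel count).
    """
    if not (0 <= open_prob <= 1):
        raise ValueError("open_prob must be in [0, 1]")
    rng = cfg.rng() if rng is None else rng
    k_open = open_prob * k_total        # closed -> open
    k_close = (1 - open_prob) * k_total  # open -> closed
    p_co = min(k_open * dt, 1.0)
    p_oc = min(k_close * dt, 1.0)
    states = (rng.random(n_channels) < open_prob).astype(np.int8)
    n_open = np.empty(n_samples, dtype=np.int32)
    for i in range(n_samples):
        u = rng.random(n_channels)
        flip = np.where(states == 1, u < p_oc, u < p_co)
        states = np.where(flip, 1 - states, states)
        n_open[i] = states.sum()
    unitary = g * (voltage - v_rev) * 1e-3  # pS * mV = 1e-3 pA
    current = n_open * unitary + baseline_noise_pA * rng.standard_normal(n_samples)
    t = np.arange(n_samples) * dt
    return t, current, n_open


def simulate_iv(
    g: float,
    cfg: SimConfig,
    v_rev: float = 0.0,
    open_prob: float = 0.8,
    n_channels: int = 1,
    voltages: Optional[np.ndarray] = None,
    return_traces: bool = False,
    **trace_kwargs,
):
    """Single-channel I-V table from gated sweeps at each holding voltage.

    At each voltage one sweep is simulated and the unitary open-level
    amplitude is estimated as the mean current with exactly one channel
    open minus the closed-baseline mean (0 if the sweep never closes),
    which makes the recovered conductance independent of open probability.

    Returns an IVTable, or (IVTable, list of (t, current, n_open) traces)
    when ``return_traces`` is set.
    """
    voltages = DEFAULT_IV_VOLTAGES if voltages is None else np.asarray(voltages, dtype=float)
    rng = cfg.rng()
    currents = np.empty_like(voltages)
    traces = []
    for j, v in enumerate(voltages):
        t, cur, n_open = simulate_gated_trace(
            g, v, cfg, v_rev=v_rev, open_prob=open_prob,
            n_channels=n_channels, rng=rng, **trace_kwargs,
        )
        traces.append((t, cur, n_open))
        baseline = cur[n_open == 0].mean() if np.any(n_open == 0) else 0.0
        if np.any(n_open == 1):
            currents[j] = cur[n_open == 1].mean() - baseline
        else:  # sweep never visited the one-open level; fall back to the mean level
            mean_open = n_open.mean()
            currents[j] = (cur.mean() - baseline) / max(mean_open, 1e-12)
    iv = IVTable(voltage=voltages, current=currents)
    return (iv, traces) if return_traces else iv
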