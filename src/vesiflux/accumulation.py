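"""Uptake time courses, internal concentrations and phenotype classification.

Converts measured radiotracer uptake (moles or scintillation counts) into
intraliposomal concentrations via the assay's internal volume, forms the
fold-accumulation statistic c_in/c_out, and classifies the transport
phenotype: an uncoupled channel equilibrates (fold ~1, never far above it),
while an ion-coupled transporter concentrates its substrate far beyond the
external level (e.g. ~150-fold for a Na+-coupled symporter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import AssaySpec
from .units import DPM_PER_MCI, MOL_TO_MMOL

#: fold-accumulation expected at equilibrium for an uncharged solute with
#: no membrane potential — the null hypothesis for a channel
PASSIVE_BASELINE = 1.0

DEFAULT_CHANNEL_THRESHOLD = 10.0
DEFAULT_COUPLED_THRESHOLD = 50.0


class AccumulationError(ValueError):
    """Raised for invalid uptake data or configuration."""


@dataclass
class UptakeTimeCourse:
    """One uptake time course: substrate amount in the assay vs time.

    ``amounts`` are in nmol per assay when ``amount_unit == "nmol"`` or raw
    scintillation counts when ``amount_unit == "cpm"``. Amounts need not be
    monotone: a peak followed by a decline is a common observation.
    Multiple replicates may share time points via ``replicate_ids``.
    """

    times: np.ndarray                  # s
    amounts: np.ndarray                # nmol or cpm
    amount_unit: str = "nmol"
    replicate_ids: Optional[np.ndarray] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amounts = np.asarray(self.amounts, dtype=float)
        if self.times.shape != self.amounts.shape:
            raise AccumulationError("times and amounts must have equal length")
        if self.amount_unit not in ("nmol", "cpm"):
            raise AccumulationError(f"amount_unit must be 'nmol' or 'cpm', got {self.amount_unit!r}")
        if np.any(self.times < 0):
            raise AccumulationError("times must be >= 0")
        if np.any(self.amounts < 0):
            raise AccumulationError("amounts must be >= 0")
        if self.replicate_ids is not None:
            self.replicate_ids = np.asarray(self.replicate_ids)
            if self.replicate_ids.shape != self.times.shape:
                raise AccumulationError("replicate_ids must match times in length")
        # within each replicate, times must strictly increase
        for rep in self._replicate_labels():
            t = self.times[self._mask(rep)]
            if np.any(np.diff(t) <= 0):
                raise AccumulationError(f"times not strictly increasing in replicate {rep!r}")

    def _replicate_labels(self) -> list:
        if self.replicate_ids is None:
            return [None]
        return list(dict.fromkeys(self.replicate_ids.tolist()))

    def _mask(self, rep) -> np.ndarray:
        if rep is None:
            return np.ones_like(self.times, dtype=bool)
        return self.replicate_ids == rep

    def averaged(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Mean amount per unique time point across replicates.

        Returns (times, mean amounts, SEM per point; SEM is 0 where only
        one replicate covers a time point).
        """
        t_unique = np.unique(self.times)
        means = np.empty_like(t_unique)
        sems = np.empty_like(t_unique)
        for i, t in enumerate(t_unique):
            vals = self.amounts[self.times == t]
            means[i] = vals.mean()
            sems[i] = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        return t_unique, means, sems


@dataclass
class PhenotypeReport:
    """Internal concentrations, fold accumulations and the phenotype call."""

    c_in_peak: float                       # mM
    c_in_plateau: float                    # mM
    fold_peak: float
    fold_plateau: float
    call: str                              # channel-like | concentrative | indeterminate
    passive_baseline: float = PASSIVE_BASELINE
    coupled_baseline: Optional[float] = None
    channel_threshold: float = DEFAULT_CHANNEL_THRESHOLD
    coupled_threshold: float = DEFAULT_COUPLED_THRESHOLD
    peak_time: Optional[float] = None      # s
    peak_sem: Optional[float] = None       # nmol
    plateau_sem: Optional[float] = None    # nmol

    def as_dict(self) -> dict:
        return {
            "c_in_peak": {"value": self.c_in_peak, "unit": "mM"},
            "c_in_plateau": {"value": self.c_in_plateau, "unit": "mM"},
            "fold_peak": {"value": self.fold_peak, "unit": "dimensionless"},
            "fold_plateau": {"value": self.fold_plateau, "unit": "dimensionless"},
            "fold_peak_display": format_fold(self.fold_peak),
            "fold_plateau_display": format_fold(self.fold_plateau),
            "passive_baseline": {"value": self.passive_baseline, "unit": "dimensionless"},
            "coupled_baseline": (
                {"value": self.coupled_baseline, "unit": "dimensionless"}
                if self.coupled_baseline is not None else None
            ),
            "channel_threshold": {"value": self.channel_threshold, "unit": "dimensionless"},
            "coupled_threshold": {"value": self.coupled_threshold, "unit": "dimensionless"},
            "peak_time": ({"value": self.peak_time, "unit": "s"} if self.peak_time is not None else None),
            "call": self.call,
        }


def format_fold(fold: float) -> str:
    """Display-round a fold value: nearest integer below 10, nearest ten above."""
    if fold < 10:
        return f"~{round(fold):d}"
    return f"~{10 * round(fold / 10):d}"


def counts_to_moles(counts: float, assay: AssaySpec) -> float:
    """Convert scintillation counts (cpm, 1-min count) to moles of substrate.

    counts -> dpm via counting efficiency, dpm -> mCi (2.22e9 dpm/mCi),
    mCi -> mmol via specific activity, mmol -> mol.
    """
    if assay.specific_activity is None or assay.counting_efficiency is None:
        raise AccumulationError(
            "counts_to_moles requires specific_activity and counting_efficiency in the assay spec"
        )
    dpm = counts / assay.counting_efficiency
    mmol = dpm / DPM_PER_MCI / assay.specific_activity
    return mmol / MOL_TO_MMOL


def internal_concentration(amount_mol: float, v_internal: float) -> float:
    """Internal substrate concentration in mM from moles and internal volume (L)."""
    if v_internal <= 0:
        raise AccumulationError(f"internal volume must be > 0, got {v_internal}")
    return amount_mol / v_internal * MOL_TO_MMOL  # mol/L -> mmol/L


def fold_accumulation(c_in: float, c_out: float) -> float:
    """Ratio of internal to external substrate concentration (same units)."""
    if c_out <= 0:
        raise AccumulationError(f"external concentration must be > 0, got {c_out}")
    return c_in / c_out


def summarize_time_course(
    tc: UptakeTimeCourse, plateau_n: int = 2
) -> tuple[float, float, float, float, float]:
    """Peak and plateau amounts of an uptake time course.

    Replicates are averaged per time point first; the peak is the maximum
    averaged amount, the plateau the mean of the last ``plateau_n`` averaged
    points. Returns (peak, plateau, peak time, peak SEM, plateau SEM).
    """
    if plateau_n < 1:
        raise AccumulationError("plateau_n must be >= 1")
    t, mean, sem = tc.averaged()
    if len(t) < plateau_n + 1:
        raise AccumulationError(
            f"need at least plateau_n + 1 = {plateau_n + 1} time points, got {len(t)}"
        )
    i_peak = int(np.argmax(mean))
    plateau = float(mean[-plateau_n:].mean())
    plateau_sem = float(np.sqrt(np.sum(sem[-plateau_n:] ** 2)) / plateau_n)
    return float(mean[i_peak]), plateau, float(t[i_peak]), float(sem[i_peak]), plateau_sem


def classify_phenotype(
    c_in_peak: float,
    c_in_plateau: float,
    c_out: float,
    channel_threshold: float = DEFAULT_CHANNEL_THRESHOLD,
    coupled_threshold: float = DEFAULT_COUPLED_THRESHOLD,
    coupled_baseline: Optional[float] = None,
    peak_time: Optional[float] = None,
    peak_sem: Optional[float] = None,
    plateau_sem: Optional[float] = None,
) -> PhenotypeReport:
    """Classify a transport phenotype from internal concentrations (mM).

    The call is based on the steady-state (plateau) fold accumulation:
    ``channel-like`` at or below ``channel_threshold``, ``concentrative`` at
    or above ``coupled_threshold``, ``indeterminate`` between them.
    """
    if channel_threshold >= coupled_threshold:
        raise AccumulationError(
            f"channel_threshold ({channel_threshold}) must be below "
            f"coupled_threshold ({coupled_threshold})"
        )
    fold_peak = fold_accumulation(c_in_peak, c_out)
    fold_plateau = fold_accumulation(c_in_plateau, c_out)
    if fold_plateau <= channel_threshold:
        call = "channel-like"
    elif fold_plateau >= coupled_threshold:
        call = "concentrative"
    else:
        call = "indeterminate"
    return PhenotypeReport(
        c_in_peak=c_in_peak,
        c_in_plateau=c_in_plateau,
        fold_peak=fold_peak,
        fold_plateau=fold_plateau,
        call=call,
        coupled_baseline=coupled_baseline,
        channel_threshold=channel_threshold,
        coupled_threshold=coupled_threshold,
        peak_time=peak_time,
        peak_sem=peak_sem,
        plateau_sem=plateau_sem,
    )
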