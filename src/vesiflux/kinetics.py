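"""Transport kinetics: initial rates, Michaelis-Menten, turnover, dose-response.

Initial rates are extracted as linear slopes over a short early window of
an uptake time course and normalised per mg protein per minute. Saturation
kinetics are fitted with the Michaelis-Menten form v = Vmax*S/(Km+S);
turnover kcat converts the mass-specific Vmax into a per-molecule rate.
Isotopic-dilution (EC50) and inhibition (IC50) curves are fitted with a
four-parameter log-logistic model after background subtraction.

All nonlinear fits run in log-parameter space to enforce positivity and are
solved with scipy's Levenberg-Marquardt/trust-region least squares;
standard errors are asymptotic, from the Jacobian at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from Bio.SeqUtils import molecular_weight

from .accumulation import UptakeTimeCourse
from .geometry import AssaySpec
from .units import SECONDS_PER_MINUTE


class FitError(RuntimeError):
    """Raised when a fit cannot be performed or does not converge."""


@dataclass
class RateTable:
    """Initial transport rates vs substrate concentration (replicates allowed)."""

    substrate_conc: np.ndarray   # mM
    rate: np.ndarray             # umol mg^-1 min^-1

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_conc.shape != self.rate.shape:
            raise FitError("substrate_conc and rate must have equal length")
        if np.any(self.substrate_conc <= 0):
            raise FitError("substrate concentrations must be > 0")
        if np.any(self.rate < 0):
            raise FitError("rates must be >= 0")


@dataclass
class MMFit:
    """Michaelis-Menten fit result with asymptotic uncertainties."""

    km: float                   # mM
    vmax: float                 # umol mg^-1 min^-1
    km_se: float
    vmax_se: float
    converged: bool
    residual_ss: float
    kcat: Optional[float] = None   # s^-1, set when a protomer mass is supplied

    def predict(self, s):
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)

    def as_dict(self) -> dict:
        d = {
            "km": {"value": self.km, "unit": "mM"},
            "vmax": {"value": self.vmax, "unit": "umol/mg/min"},
            "km_se": {"value": self.km_se, "unit": "mM"},
            "vmax_se": {"value": self.vmax_se, "unit": "umol/mg/min"},
            "converged": self.converged,
            "residual_ss": {"value": self.residual_ss, "unit": "(umol/mg/min)^2"},
        }
        if self.kcat is not None:
            d["kcat"] = {"value": self.kcat, "unit": "1/s"}
        return d


@dataclass
class DoseResponse:
    """Dose-response table: ligand concentration vs signal, with background.

    ``background`` is the non-proximity (nonspecific) signal, scalar or
    per-point; it is subtracted before fitting.
    """

    ligand_conc: np.ndarray      # M
    signal: np.ndarray           # counts or normalised
    background: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.ligand_conc.shape != self.signal.shape:
            raise FitError("ligand_conc and signal must have equal length")
        if np.any(self.ligand_conc < 0):
            raise FitError("ligand concentrations must be >= 0")
        self.background = np.broadcast_to(
            np.asarray(self.background, dtype=float), self.signal.shape
        ).copy()

    def corrected_signal(self) -> np.ndarray:
        return self.signal - self.background


@dataclass
class DisplacementFit:
    """Four-parameter log-logistic fit of a displacement/inhibition curve."""

    ec50_or_ic50: float          # M
    hill: float
    top: float
    bottom: float
    x50_se: float
    hill_se: float
    top_se: float
    bottom_se: float
    mode: str                    # homologous_dilution | heterologous_inhibition
    converged: bool
    residual_ss: float

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + (conc / self.ec50_or_ic50) ** self.hill
        )

    def as_dict(self) -> dict:
        label = "ec50" if self.mode == "homologous_dilution" else "ic50"
        return {
            label: {"value": self.ec50_or_ic50, "unit": "M"},
            f"{label}_se": {"value": self.x50_se, "unit": "M"},
            "hill": {"value": self.hill, "unit": "dimensionless"},
            "top": {"value": self.top, "unit": "signal"},
            "bottom": {"value": self.bottom, "unit": "signal"},
            "mode": self.mode,
            "converged": self.converged,
            "residual_ss": {"value": self.residual_ss, "unit": "signal^2"},
        }


DEFAULT_RATE_WINDOW_S = 5.0


def initial_rate(
    tc: UptakeTimeCourse,
    assay: AssaySpec,
    window: float = DEFAULT_RATE_WINDOW_S,
) -> float:
    """Initial uptake rate in umol per mg protein per minute.

    Least-squares slope of amount (nmol) vs time over [0, window] seconds,
    forced through the measured t=0 point when one exists (the origin of
    the uptake reaction is known exactly), then normalised by the protein
    mass in the assay. Requires amounts in nmol.
    """
    if assay.protein_mass is None:
        raise FitError("initial_rate requires protein_mass in the assay spec")
    if tc.amount_unit != "nmol":
        raise FitError("initial_rate expects a time course in nmol; convert cpm first")
    t, a, _ = tc.averaged()
    sel = t <= window
    if sel.sum() < 2:
        raise FitError(f"need >= 2 points within the {window}-s window, got {int(sel.sum())}")
    t_w, a_w = t[sel], a[sel]
    if np.isclose(t_w[0], 0.0):
        # regression through the measured origin: slope = sum(t*a)/sum(t^2)
        t0, a0 = t_w[0], a_w[0]
        dt, da = t_w - t0, a_w - a0
        denom = np.sum(dt**2)
        if denom == 0:
            raise FitError("all points in the window share one time")
        slope = np.sum(dt * da) / denom
    else:
        slope = np.polyfit(t_w, a_w, 1)[0]
    # nmol/s per ug protein == umol/s per mg protein
    return slope / assay.protein_mass * SECONDS_PER_MINUTE


def fit_michaelis_menten(data: RateTable, protomer_mass: Optional[float] = None) -> MMFit:
    """Fit v = Vmax*S/(Km+S) by unweighted nonlinear least squares.

    Fitted in (log Km, log Vmax) space for positivity. Initialisation:
    Km0 = median concentration, Vmax0 = 1.2 * max rate. When
    ``protomer_mass`` (g/mol) is given, kcat is derived from Vmax.
    """
    s, v = data.substrate_conc, data.rate
    if len(np.unique(s)) < 4:
        raise FitError("Michaelis-Menten fit requires >= 4 distinct concentrations")

    def model(si, log_km, log_vmax):
        km, vmax = np.exp(log_km), np.exp(log_vmax)
        return vmax * si / (km + si)

    p0 = [np.log(np.median(s)), np.log(1.2 * v.max())]
    try:
        popt, pcov = curve_fit(model, s, v, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    km, vmax = np.exp(popt)
    # delta method: SE(x) = x * SE(log x)
    log_se = np.sqrt(np.diag(pcov))
    resid = v - model(s, *popt)
    fit = MMFit(
        km=float(km),
        vmax=float(vmax),
        km_se=float(km * log_se[0]),
        vmax_se=float(vmax * log_se[1]),
        converged=bool(np.all(np.isfinite(pcov))),
        residual_ss=float(np.sum(resid**2)),
    )
    if protomer_mass is not None:
        fit.kcat = kcat_from_vmax(fit.vmax, protomer_mass)
    return fit


def mw_from_sequence(seq: str) -> float:
    """Average molar mass (g/mol) of a protein from its one-letter sequence."""
    if not seq:
        raise FitError("empty sequence")
    try:
        return float(molecular_weight(seq.upper(), seq_type="protein"))
    except ValueError as exc:
        raise FitError(f"invalid amino-acid sequence: {exc}") from exc


def kcat_from_vmax(vmax: float, protomer_mass: float) -> float:
    """Turnover number (s^-1) from mass-specific Vmax and protomer mass.

    vmax [umol mg^-1 min^-1] * M [g/mol] gives umol substrate per umol
    protein per minute * 1e-3; dividing by 60 s/min collapses to
    kcat = vmax * M / 60000.
    """
    if vmax < 0 or protomer_mass <= 0:
        raise FitError("vmax must be >= 0 and protomer mass > 0")
    return vmax * protomer_mass / 60000.0


def fit_displacement(
    data: DoseResponse,
    mode: str = "homologous_dilution",
    fix_hill: Optional[float] = None,
) -> DisplacementFit:
    """Fit a background-subtracted displacement or inhibition curve.

    Four-parameter log-logistic:
        signal = bottom + (top - bottom) / (1 + ([L]/X50)^hill)
    X50 is the EC50 (isotopic-dilution mode) or IC50 (inhibition mode).
    X50 and hill are fitted in log space; ``fix_hill`` pins the slope
    (commonly to 1 for a single-site model).
    """
    if mode not in ("homologous_dilution", "heterologous_inhibition"):
        raise FitError(f"unknown mode {mode!r}")
    conc = data.ligand_conc
    y = data.corrected_signal()
    pos = conc > 0
    if len(np.unique(conc)) < 5:
        raise FitError("displacement fit requires >= 5 distinct concentrations")
    span = y.max() - y.min()
    if span <= 0 or span < 1e-9 * max(abs(y.max()), 1.0):
        raise FitError("flat curve: no displacement signal above background")

    x50_0 = np.exp(np.mean(np.log(conc[pos])))
    top0, bottom0 = float(y.max()), float(y.min())

    if fix_hill is None:
        def model(c, log_x50, log_hill, top, bottom):
            x50, hill = np.exp(log_x50), np.exp(log_hill)
            with np.errstate(divide="ignore"):
                ratio = np.where(c > 0, (c / x50) ** hill, 0.0)
            return bottom + (top - bottom) / (1.0 + ratio)
        p0 = [np.log(x50_0), 0.0, top0, bottom0]
    else:
        hill_fixed = float(fix_hill)

        def model(c, log_x50, top, bottom):
            x50 = np.exp(log_x50)
            with np.errstate(divide="ignore"):
                ratio = np.where(c > 0, (c / x50) ** hill_fixed, 0.0)
            return bottom + (top - bottom) / (1.0 + ratio)
        p0 = [np.log(x50_0), top0, bottom0]

    try:
        popt, pcov = curve_fit(model, conc, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"displacement fit did not converge: {exc}") from exc
    se = np.sqrt(np.diag(pcov))
    resid = y - model(conc, *popt)
    x50 = float(np.exp(popt[0]))
    if fix_hill is None:
        hill, top, bottom = float(np.exp(popt[1])), float(popt[2]), float(popt[3])
        hill_se, top_se, bottom_se = float(hill * se[1]), float(se[2]), float(se[3])
    else:
        hill, hill_se = hill_fixed, 0.0
        top, bottom = float(popt[1]), float(popt[2])
        top_se, bottom_se = float(se[1]), float(se[2])
    return DisplacementFit(
        ec50_or_ic50=x50,
        hill=hill,
        top=top,
        bottom=bottom,
        x50_se=float(x50 * se[0]),
        hill_se=hill_se,
        top_se=top_se,
        bottom_se=bottom_se,
        mode=mode,
        converged=bool(np.all(np.isfinite(pcov))),
        residual_ss=float(np.sum(resid**2)),
    )
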