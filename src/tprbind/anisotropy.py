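"""Fluorescence-anisotropy binding models: direct titration and competition.

A fluorescent tracer peptide (an LFP-motif peptide, ~0.3 uM) reports on
receptor occupancy through its anisotropy.  In the direct mode the
receptor (a KLC TPR domain) is titrated and the anisotropy follows a
slope-1 dose-response curve with dissociation constant K_d.  In the
competition mode the receptor concentration is fixed and an unlabelled
competitor displaces the tracer; the free-receptor concentration then
has the closed form

    R_free = ( [R] - [C] - K_I + sqrt((K_I + [R] + [C])^2 - 4 [R][C]) ) / 2

(trace-tracer limit), and A = A_min + (A_max - A_min) R_free/(K_LFP + R_free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "AnisotropyDataset",
    "CompetitionParams",
    "direct_binding_model",
    "competition_model",
    "fit_direct",
    "fit_ki",
    "DirectFitResult",
    "CompetitionFitResult",
]


@dataclass(frozen=True)
class AnisotropyDataset:
    """Titration points (concentration, anisotropy, replicate index).

    mode "direct": x_conc is the receptor concentration.
    mode "competition": x_conc is the competitor concentration and
    klc_conc holds the fixed receptor concentration.
    """

    points: tuple  # of (x_conc: float, anisotropy: float, replicate: int)
    mode: str = "direct"
    klc_conc: float | None = None
    tracer_conc: float = 0.3

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "competition"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for x, a, _ in self.points:
            if x < 0:
                raise ValueError("concentrations must be non-negative")
            if not np.isfinite(a):
                raise ValueError("anisotropy values must be finite")

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class CompetitionParams:
    a_min: float
    a_max: float
    k_lfp: float  # tracer dissociation constant, uM
    k_i: float  # competitor dissociation constant, uM
    klc_conc: float  # fixed receptor concentration, uM

    def __post_init__(self) -> None:
        if self.a_max <= self.a_min:
            raise ValueError("a_max must exceed a_min")
        if self.k_lfp <= 0 or self.k_i <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.klc_conc < 0:
            raise ValueError("receptor concentration must be non-negative")


def direct_binding_model(klc_conc, a_min: float, a_max: float, k_d: float):
    """Slope-1 dose-response: A = a_min + (a_max - a_min) [R]/(K_d + [R])."""
    if k_d <= 0:
        raise ValueError("k_d must be positive")
    klc_conc = np.asarray(klc_conc, dtype=float)
    return a_min + (a_max - a_min) * klc_conc / (k_d + klc_conc)


def free_receptor(klc_conc: float, cstn_conc, k_i: float):
    """Trace-tracer free-receptor concentration in presence of competitor."""
    cstn_conc = np.asarray(cstn_conc, dtype=float)
    if np.any(cstn_conc < 0) or klc_conc < 0:
        raise ValueError("concentrations must be non-negative")
    disc = (k_i + klc_conc + cstn_conc) ** 2 - 4.0 * klc_conc * cstn_conc
    return 0.5 * (klc_conc - cstn_conc - k_i + np.sqrt(disc))


def competition_model(params: CompetitionParams, cstn_conc):
    """Anisotropy at competitor concentration(s) cstn_conc (uM)."""
    r_free = free_receptor(params.klc_conc, cstn_conc, params.k_i)
    return params.a_min + (params.a_max - params.a_min) * r_free / (params.k_lfp + r_free)


@dataclass(frozen=True)
class DirectFitResult:
    a_min: float
    a_max: float
    k_d: float
    stderr: dict
    identifiable: bool


@dataclass(frozen=True)
class CompetitionFitResult:
    a_min: float
    a_max: float
    k_i: float
    stderr: dict
    identifiable: bool
    k_i_lower_bound: float | None = None


def _flat(y: np.ndarray) -> bool:
    span = float(np.ptp(y))
    scale = max(abs(float(np.mean(y))), 1e-12)
    return span < 1e-9 or span < 1e-3 * scale


def fit_direct(data: AnisotropyDataset) -> DirectFitResult:
    """Least-squares fit of the slope-1 dose-response to a direct titration.

    Fits per replicate point (unweighted).  Flat data (no concentration
    dependence) is flagged unidentifiable rather than fitted.
    """
    x, y = data.x, data.y
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if _flat(y):
        return DirectFitResult(float(np.mean(y)), float(np.mean(y)), float("nan"),
                               {}, identifiable=False)
    p0 = [float(y.min()), float(y.max()), float(np.median(x[x > 0]))]
    popt, pcov = curve_fit(
        lambda c, lo, hi, kd: direct_binding_model(c, lo, hi, kd),
        x, y, p0=p0,
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 1e9]),
        maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    stderr = {"a_min": perr[0], "a_max": perr[1], "k_d": perr[2]}
    ident = bool(np.isfinite(perr[2]) and perr[2] < 10 * popt[2])
    return DirectFitResult(popt[0], popt[1], popt[2], stderr, ident)


def fit_ki(data: AnisotropyDataset, k_lfp: float, klc_conc: float) -> CompetitionFitResult:
    """Fit the competition closed form with K_LFP held fixed.

    K_LFP comes from a prior direct fit.  A competitor with no effect
    (flat curve) is reported as unidentifiable with a lower bound on
    K_I at the highest concentration tested.
    """
    x, y = data.x, data.y
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct competitor concentrations")
    if k_lfp <= 0:
        raise ValueError("k_lfp must be positive")
    if _flat(y) or float(np.ptp(y)) < 3.0 * _replicate_sd(data):
        return CompetitionFitResult(
            float(np.mean(y)), float(np.mean(y)), float("inf"), {},
            identifiable=False, k_i_lower_bound=float(x.max()),
        )

    def model(c, lo, hi, log_ki):
        p = CompetitionParams(lo, hi, k_lfp, float(np.exp(log_ki)), klc_conc)
        return competition_model(p, c)

    p0 = [float(y.min()), float(y.max()), float(np.log(max(np.median(x[x > 0]), 1e-6)))]
    popt, pcov = curve_fit(model, x, y, p0=p0, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    k_i = float(np.exp(popt[2]))
    stderr = {"a_min": perr[0], "a_max": perr[1], "k_i": k_i * perr[2]}
    # K_I counts as determined only if its log-scale error is below one e-fold
    ident = bool(np.isfinite(perr[2]) and perr[2] < 1.0)
    return CompetitionFitResult(popt[0], popt[1], k_i, stderr, ident,
                                k_i_lower_bound=None if ident else float(x.max()))


def _replicate_sd(data: AnisotropyDataset) -> float:
    """Pooled within-concentration replicate standard deviation."""
    y, x = data.y, data.x
    sds = []
    for xv in np.unique(x):
        grp = y[x == xv]
        if len(grp) > 1:
            sds.append(np.std(grp, ddof=1))
    return float(np.mean(sds)) if sds else 0.0
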