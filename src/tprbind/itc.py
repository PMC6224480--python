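"""Sequential two-site ITC binding model and global fitting.

A dimeric ligand A (a leucine-zipper dimer) binds two copies of a receptor
domain B (a kinesin light chain TPR domain) in two macroscopic stages,

    A + B + B  -> BA + B   (K1, dH1)
    BA + B     -> BAB      (K2, dH2)

with macroscopic association constants K1, K2 (uM^-1) and per-stage molar
enthalpies dH1, dH2 (kcal/mol).  Several titrations are fitted globally:
the thermodynamic parameters and active fractions are shared, while each
experiment carries local nuisance parameters (cell/syringe concentration
correction factors and a heat-of-dilution baseline).

Units throughout: concentrations uM, volumes uL, heats ucal, enthalpies
kcal/mol, temperatures K.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np
from scipy.optimize import brentq, least_squares

R_KCAL = 1.98720425e-3  # gas constant, kcal mol^-1 K^-1
T_DEFAULT = 298.15  # 25 C

__all__ = [
    "SequentialBindingParams",
    "Injection",
    "ITCExperiment",
    "LocalNuisance",
    "GlobalFitResult",
    "free_titrant",
    "single_site_species",
    "predict_heats",
    "global_fit",
    "thermo_decompose",
    "n_app",
]


@dataclass(frozen=True)
class SequentialBindingParams:
    """Global thermodynamic parameters of the sequential model.

    k1, k2 : macroscopic association constants, uM^-1
    dh1, dh2 : stage enthalpies, kcal/mol
    active_a, active_b : fractions of A (dimer) and B competent to bind,
        scaling the nominal concentrations.
    """

    k1: float
    k2: float
    dh1: float
    dh2: float
    active_a: float = 1.0
    active_b: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("association constants must be positive")
        for frac in (self.active_a, self.active_b):
            if not (0.0 < frac <= 1.0):
                raise ValueError("active fractions must lie in (0, 1]")


@dataclass(frozen=True)
class Injection:
    volume_ul: float
    heat_ucal: float = math.nan
    heat_error_ucal: float = math.nan


@dataclass(frozen=True)
class ITCExperiment:
    """One titration: dimeric A in the cell, B titrated from the syringe."""

    cell_conc_a: float  # uM, nominal dimer concentration in the cell
    syringe_conc_b: float  # uM, nominal titrant concentration
    cell_volume_ul: float
    injections: tuple[Injection, ...]
    temperature: float = T_DEFAULT
    sacrificial_first: bool = True

    def __post_init__(self) -> None:
        if self.cell_conc_a <= 0 or self.syringe_conc_b <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume_ul <= 0:
            raise ValueError("cell volume must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if len(self.injections) < 1:
            raise ValueError("need at least one injection")
        for inj in self.injections:
            if inj.volume_ul <= 0:
                raise ValueError("injection volumes must be positive")
            if math.isinf(inj.heat_ucal):
                raise ValueError("heats must be finite or NaN")

    @property
    def heats(self) -> np.ndarray:
        return np.array([inj.heat_ucal for inj in self.injections])

    @property
    def heat_errors(self) -> np.ndarray:
        return np.array([inj.heat_error_ucal for inj in self.injections])

    @property
    def volumes(self) -> np.ndarray:
        return np.array([inj.volume_ul for inj in self.injections])

    def retained(self) -> np.ndarray:
        """Boolean mask of injections entering the fit (sacrificial excluded)."""
        mask = np.ones(len(self.injections), dtype=bool)
        if self.sacrificial_first:
            mask[0] = False
        return mask


@dataclass(frozen=True)
class LocalNuisance:
    """Per-experiment nuisance parameters.

    f_cell, f_syringe : multiplicative corrections on the nominal cell and
        syringe concentrations (the locally fitted concentration factors).
    baseline : residual heat of dilution, kcal per mole of injectant.
    """

    f_cell: float = 1.0
    f_syringe: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.f_cell <= 0 or self.f_syringe <= 0:
            raise ValueError("concentration correction factors must be positive")


@dataclass(frozen=True)
class GlobalFitResult:
    params: SequentialBindingParams
    locals: tuple[LocalNuisance, ...]
    rss: float
    n_points: int
    derived: dict
    model: str
    converged: bool = True
    n_app_value: float | None = None


def free_titrant(total_a: float, total_b: float, k1: float, k2: float):
    """Solve the two-stage mass-action equilibrium for free titrant B.

    Returns ``(free_b, conc_ba, conc_bab)`` in uM satisfying

        total_a = [A] + [BA] + [BAB]
        total_b = [B] + [BA] + 2 [BAB]
        [BA]  = k1 [A][B],   [BAB] = k1 k2 [A][B]^2

    The mass-balance function is strictly monotone in [B], so a bracketed
    root-find on [0, total_b] converges unconditionally.
    """
    if total_a < 0 or total_b < 0:
        raise ValueError("total concentrations must be non-negative")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("association constants must be positive")
    if total_b == 0.0:
        return 0.0, 0.0, 0.0
    if total_a == 0.0:
        return total_b, 0.0, 0.0

    # solve for the free fraction u = [B]/total_B in [0, 1]; normalising
    # keeps the bracket well-scaled for any concentration magnitude
    def residual(u: float) -> float:
        b = u * total_b
        poly = 1.0 + k1 * b + k1 * k2 * b * b
        return u + total_a * (k1 * u + 2.0 * k1 * k2 * b * u) / poly - 1.0

    u = brentq(residual, 0.0, 1.0, xtol=1e-16, rtol=4 * np.finfo(float).eps)
    b = u * total_b
    poly = 1.0 + k1 * b + k1 * k2 * b * b
    a_free = total_a / poly
    return b, k1 * a_free * b, k1 * k2 * a_free * b * b


def single_site_species(total_a: float, total_b: float, k: float) -> float:
    """[AB] for a 1:1 equilibrium A + B <-> AB, closed form (uM)."""
    if total_a < 0 or total_b < 0:
        raise ValueError("total concentrations must be non-negative")
    if k <= 0:
        raise ValueError("association constant must be positive")
    s = total_a + total_b + 1.0 / k
    disc = s * s - 4.0 * total_a * total_b
    return 0.5 * (s - math.sqrt(disc))


def _species(model: str, params: SequentialBindingParams, total_a: float, total_b: float):
    if model == "sequential":
        _, ba, bab = free_titrant(total_a, total_b, params.k1, params.k2)
        return ba, bab
    if model == "single_site":
        return single_site_species(total_a, total_b, params.k1), 0.0
    raise ValueError(f"unknown model {model!r}")


def predict_heats(
    params: SequentialBindingParams,
    expt: ITCExperiment,
    nuisance: LocalNuisance = LocalNuisance(),
    model: str = "sequential",
) -> np.ndarray:
    """Per-injection heats (ucal) for one titration.

    Each injection of volume dv into a constant-volume perfusion cell
    displaces a fraction dv/V0 of the pre-mixing content, so cell totals
    update as c -> c (1 - dv/V0) + c_syringe dv/V0 for the injected
    species.  The heat of injection n is referenced to the post-mixing
    cell contents, with the displaced material assumed at the
    pre-injection equilibrium:

        q_n = V0 [ dH1 ( [BA]_n - (1-dv/V0)[BA]_{n-1} )
                 + (dH1+dH2) ( [BAB]_n - (1-dv/V0)[BAB]_{n-1} ) ]
              + baseline * (moles injected)

    Effective concentrations are nominal * active fraction * local factor.
    """
    v0 = expt.cell_volume_ul
    a_tot = expt.cell_conc_a * params.active_a * nuisance.f_cell
    b_syr = expt.syringe_conc_b * params.active_b * nuisance.f_syringe
    b_tot = 0.0
    ba_prev = bab_prev = 0.0
    heats = np.empty(len(expt.injections))
    for n, inj in enumerate(expt.injections):
        dil = 1.0 - inj.volume_ul / v0
        if dil <= 0:
            raise ValueError("injection volume exceeds cell volume")
        a_tot *= dil
        b_tot = b_tot * dil + b_syr * (inj.volume_ul / v0)
        ba, bab = _species(model, params, a_tot, b_tot)
        # uL * uM = 1e-12 mol; kcal/mol * 1e-12 mol = 1e-3 ucal
        q = v0 * (
            params.dh1 * (ba - dil * ba_prev)
            + (params.dh1 + params.dh2) * (bab - dil * bab_prev)
        )
        q += nuisance.baseline * inj.volume_ul * b_syr
        heats[n] = 1e-3 * q
        ba_prev, bab_prev = ba, bab
    return heats


def thermo_decompose(k: float, dh: float, temperature: float = T_DEFAULT):
    """Decompose K (uM^-1) and dH into (dG, -TdS), kcal/mol, 1 M standard state."""
    if k <= 0:
        raise ValueError("association constant must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    dg = -R_KCAL * temperature * math.log(k * 1e6)
    return dg, dg - dh


def n_app(
    factor_pairs,
    active_cell: float,
    active_lig: float,
    reading: str = "product",
) -> float:
    """Apparent binding stoichiometry from local concentration factors.

    ``factor_pairs`` is a list of per-experiment ``(f_cell_i, f_lig_i)``
    locally fitted correction factors; ``active_cell`` / ``active_lig``
    are the globally fitted active fractions.  The default "product"
    reading is

        N_app = (A_cell * A_lig / n) * sum_i f_cell,i / f_lig,i

    which reproduces the reported behaviour (ligand factors ~1.3 with
    active fractions ~0.95 give N_app ~ 0.7).  The alternative
    "quotient" reading divides by the active fractions instead.
    """
    n = len(factor_pairs)
    if n < 1:
        raise ValueError("need at least one factor pair")
    if active_cell <= 0 or active_lig <= 0:
        raise ValueError("active fractions must be positive")
    total = 0.0
    for f_cell, f_lig in factor_pairs:
        if f_lig == 0:
            raise ValueError("ligand factor must be non-zero")
        total += f_cell / f_lig
    if reading == "product":
        return (active_cell * active_lig / n) * total
    if reading == "quotient":
        return total / (n * active_cell * active_lig)
    raise ValueError(f"unknown reading {reading!r}")


class FitConvergenceError(RuntimeError):
    """Raised when the global fit fails to converge; carries best-so-far."""

    def __init__(self, message: str, best: GlobalFitResult | None = None):
        super().__init__(message)
        self.best = best


def _pack(params, locs, model, fit_active):
    x = [math.log(params.k1), params.dh1]
    if model == "sequential":
        x += [math.log(params.k2), params.dh2]
    if fit_active:
        x += [params.active_a, params.active_b]
    for loc in locs:
        x += [math.log(loc.f_cell), math.log(loc.f_syringe), loc.baseline]
    return np.array(x)


def _unpack(x, n_expts, model, fit_active, base: SequentialBindingParams):
    i = 0
    k1 = math.exp(x[i]); dh1 = x[i + 1]; i += 2
    if model == "sequential":
        k2 = math.exp(x[i]); dh2 = x[i + 1]; i += 2
    else:
        k2, dh2 = base.k2, base.dh2
    if fit_active:
        aa, ab = x[i], x[i + 1]; i += 2
    else:
        aa, ab = base.active_a, base.active_b
    params = SequentialBindingParams(k1, k2, dh1, dh2, aa, ab)
    locs = []
    for _ in range(n_expts):
        locs.append(LocalNuisance(math.exp(x[i]), math.exp(x[i + 1]), x[i + 2]))
        i += 3
    return params, tuple(locs)


def global_fit(
    experiments,
    model: str = "sequential",
    init: SequentialBindingParams | None = None,
    fit_active_fractions: bool = False,
    n_starts: int = 8,
    seed: int = 0,
    nuisance_prior_sd: float | None = 0.1,
) -> GlobalFitResult:
    """Global weighted least-squares fit over several titrations.

    Thermodynamic parameters (and, optionally, active fractions) are
    shared across experiments; each experiment gets local concentration
    correction factors and a baseline.  Sacrificial first injections are
    excluded from the residuals but kept in the dilution bookkeeping.
    Residuals are weighted by the reported per-injection heat errors when
    present, unweighted otherwise.  Multistart over log-spaced
    perturbations of the association constants guards against the
    K1/K2 correlation of two-constant models.

    The heats are exactly invariant under rescaling every concentration
    by a common factor s with K -> K/s and dH -> dH/s, so freely fitted
    cell and syringe factors leave the absolute scale of K and dH
    undetermined.  ``nuisance_prior_sd`` breaks this flat direction with
    a lognormal prior on the local concentration factors (default 10%,
    the typical accuracy of protein quantification); pass None to fit
    them unconstrained.
    """
    experiments = list(experiments)
    if not experiments:
        raise ValueError("need at least one experiment")
    if model not in ("sequential", "single_site"):
        raise ValueError(f"unknown model {model!r}")
    if init is None:
        init = SequentialBindingParams(0.1, 0.1, -10.0, 0.0)
    n_expts = len(experiments)

    masks = [e.retained() for e in experiments]
    weights = []
    for e, m in zip(experiments, masks):
        err = e.heat_errors[m]
        w = np.where(np.isfinite(err) & (err > 0), 1.0 / np.where(err > 0, err, 1.0), 1.0)
        weights.append(w)
    n_points = int(sum(m.sum() for m in masks))

    def residuals(x):
        params, locs = _unpack(x, n_expts, model, fit_active_fractions, init)
        res = []
        for e, loc, m, w in zip(experiments, locs, masks, weights):
            pred = predict_heats(params, e, loc, model=model)
            res.append((pred[m] - e.heats[m]) * w)
        if nuisance_prior_sd is not None:
            res.append(np.array([
                math.log(loc.f_cell) / nuisance_prior_sd for loc in locs
            ] + [
                math.log(loc.f_syringe) / nuisance_prior_sd for loc in locs
            ]))
        return np.concatenate(res)

    x0 = _pack(init, [LocalNuisance()] * n_expts, model, fit_active_fractions)
    nb_thermo = 4 if model == "sequential" else 2
    lo = [-math.log(1e9), -500.0] * (nb_thermo // 2)
    hi = [math.log(1e9), 500.0] * (nb_thermo // 2)
    if fit_active_fractions:
        lo += [1e-3, 1e-3]; hi += [1.0, 1.0]
    lo += [math.log(0.5), math.log(0.5), -5.0] * n_expts
    hi += [math.log(2.0), math.log(2.0), 5.0] * n_expts
    bounds = (np.array(lo), np.array(hi))

    rng = np.random.default_rng(seed)
    # log-spaced K perturbation factors for the multistart; first start is x0
    factors = np.concatenate([[1.0], np.exp(np.linspace(-2.3, 2.3, max(n_starts - 1, 0)))])
    best = None
    for j, fac in enumerate(factors[:n_starts]):
        x_start = x0.copy()
        x_start[0] = x0[0] + math.log(fac)
        if model == "sequential":
            x_start[2] = x0[2] + math.log(fac) * (1 if j % 2 == 0 else -1)
        sol = least_squares(
            residuals, x_start, bounds=bounds, method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("global fit failed to converge")

    params, locs = _unpack(best.x, n_expts, model, fit_active_fractions, init)
    # rss over the data residuals only (prior terms excluded)
    rss = 0.0
    for e, loc, m, w in zip(experiments, locs, masks, weights):
        pred = predict_heats(params, e, loc, model=model)
        rss += float(np.sum(((pred[m] - e.heats[m]) * w) ** 2))
    temperature = experiments[0].temperature
    derived = {"stage1": {}, "stage2": {}}
    dg1, mtds1 = thermo_decompose(params.k1, params.dh1, temperature)
    derived["stage1"] = {"dG": dg1, "minus_TdS": mtds1}
    if model == "sequential":
        dg2, mtds2 = thermo_decompose(params.k2, params.dh2, temperature)
        derived["stage2"] = {"dG": dg2, "minus_TdS": mtds2}
    napp = n_app(
        [(loc.f_cell, loc.f_syringe) for loc in locs],
        params.active_a, params.active_b,
    )
    return GlobalFitResult(
        params=params,
        locals=locs,
        rss=rss,
        n_points=n_points,
        derived=derived,
        model=model,
        converged=bool(best.success),
        n_app_value=napp,
    )
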