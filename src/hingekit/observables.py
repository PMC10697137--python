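"""Observable models, synthetic experiments and fitting.

Maps the three-state kinetic model onto the readouts used to characterise
designed hinges: FRET between dye-labeled sites whose separation differs
between states, fluorescence polarization (bound fraction of a labeled
peptide), and DEER distance distributions between spin-label sites.  The
fitting layer mirrors the standard analysis chain: single-exponential fits
of association traces, a linear pseudo-first-order regression of apparent
rates versus peptide concentration (slope = k_on = k2 * F_Y), tight-binding
titration isotherms, DEER two-state mixture decomposition, and finally the
inference of the state-Y fraction F_Y from on-rate ratios between variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls

from .kinetics import (
    KineticState,
    RateConstants,
    derive_equilibrium,
    equilibrium_populations,
    simulate_kinetics,
    slow_relaxation_rate,
)


class FitError(ValueError):
    """Raised when a fit problem is malformed (not merely non-convergent)."""


@dataclass
class FretParams:
    """Forster-transfer signal model.

    ``d_state`` holds the inter-label distance per hinge state (A); the
    bound state YP reuses the state-Y distance unless given explicitly.
    The default R0 of 51 A represents a typical long-range dye pair.
    """

    r0: float = 51.0
    d_state: dict = field(default_factory=lambda: {"X": 60.0, "Y": 40.0})
    scale: float = 1.0
    background: float = 0.0


@dataclass
class KineticTrace:
    t: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class TitrationCurve:
    conc: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class DistanceDistribution:
    r: np.ndarray        # A grid
    density: np.ndarray  # 1/A, trapezoidal integral 1
    truncated: bool = False


@dataclass
class FitResult:
    params: dict
    se: dict
    residual_rms: float
    converged: bool
    n_iter: int = 0
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Signal models

def fret_efficiency(r: float, r0: float) -> float:
    """E = 1 / (1 + (r/r0)^6)."""
    if r <= 0 or r0 <= 0:
        raise ValueError("distances must be positive")
    return 1.0 / (1.0 + (r / r0) ** 6)


def fret_signal(populations: dict, params: FretParams) -> float:
    """Population-weighted FRET signal: background + scale * sum_s pop_s E_s.

    ``populations`` maps state name (X, Y, YP) to its fraction (sum 1).
    """
    pops = dict(populations)
    total = sum(pops.values())
    if any(v < -1e-12 for v in pops.values()) or abs(total - 1.0) > 1e-6:
        raise ValueError("populations must be non-negative and sum to 1")
    sig = params.background
    for state, pop in pops.items():
        key = state if state in params.d_state else ("Y" if state == "YP" else state)
        if key not in params.d_state:
            raise ValueError(f"no inter-label distance for state {state!r}")
        sig += params.scale * pop * fret_efficiency(params.d_state[key], params.r0)
    return float(sig)


def bound_fraction_quadratic(kd_app: float, h_tot: float, p_tot: float) -> float:
    """Exact single-site bound fraction of the limiting species.

    Solves the tight-binding quadratic with ligand depletion in the
    cancellation-free form, valid for kd << totals.
    """
    if min(kd_app, h_tot, p_tot) < 0:
        raise ValueError("inputs must be >= 0")
    limiting = min(h_tot, p_tot)
    if limiting == 0:
        return 0.0
    return _bound_conc(kd_app, h_tot, p_tot) / limiting


def _bound_conc(kd: float, h_tot: float, p_tot: float) -> float:
    b = h_tot + p_tot + kd
    disc = max(b * b - 4.0 * h_tot * p_tot, 0.0)
    return 2.0 * h_tot * p_tot / (b + np.sqrt(disc))


# ---------------------------------------------------------------------------
# Synthetic experiments

def _hinge_fractions(state: np.ndarray, h_tot: float) -> dict:
    x, y, yp = state[:3]
    return {"X": x / h_tot, "Y": y / h_tot, "YP": yp / h_tot}


def simulate_titration(rates: RateConstants, probe_tot: float,
                       ligand_series: np.ndarray, observable: str = "fp",
                       noise_sd: float = 0.0, seed: int = 0,
                       fret_params: FretParams | None = None) -> TitrationCurve:
    """Equilibrium titration of a labeled probe with its partner.

    ``observable="fp"``: the probe is the labeled peptide at ``probe_tot``,
    titrated with hinge; the signal is the bound fraction of the peptide.
    ``observable="fret"``: the probe is the labeled hinge, titrated with
    peptide; the signal is the population-weighted FRET signal.  Gaussian
    noise of ``noise_sd`` is added with the mandatory seed.
    """
    ligand_series = np.asarray(ligand_series, float)
    if np.any(np.diff(ligand_series) <= 0):
        raise ValueError("ligand series must be strictly increasing")
    fret_params = fret_params or FretParams()
    signals = []
    for conc in ligand_series:
        if observable == "fp":
            st = equilibrium_populations(rates, h_tot=conc, p_tot=probe_tot)
            signals.append(st.yp / probe_tot)
        elif observable == "fret":
            st = equilibrium_populations(rates, h_tot=probe_tot, p_tot=conc)
            signals.append(fret_signal(
                _hinge_fractions(st.as_array(), probe_tot), fret_params))
        else:
            raise ValueError(f"unknown observable {observable!r}")
    signals = np.asarray(signals)
    rng = np.random.default_rng(seed)
    signals = signals + rng.normal(0.0, noise_sd, size=signals.shape)
    return TitrationCurve(ligand_series, signals,
                          {"probe_tot": probe_tot, "observable": observable,
                           "noise_sd": noise_sd, "seed": seed})


def simulate_association(rates: RateConstants, probe: float,
                         ligand_series: np.ndarray,
                         observable: str = "fret",
                         t_grid: np.ndarray | None = None,
                         noise_sd: float = 0.0, seed: int = 0,
                         fret_params: FretParams | None = None,
                         n_points: int = 200) -> list[KineticTrace]:
    """Mixing experiments: hinge at ``probe`` M, peptide at each ligand conc.

    The hinge starts at its conformational equilibrium.  If no time grid is
    given, each trace spans five relaxation times of the predicted apparent
    rate.  ``observable="fret"`` maps hinge populations through the FRET
    model; ``"fp"`` reports the bound hinge fraction.  A pseudo-first-order
    warning flag is set in the trace metadata when the peptide is not in at
    least 10x excess.
    """
    ligand_series = np.asarray(ligand_series, float)
    fret_params = fret_params or FretParams()
    eq = derive_equilibrium(rates)
    rng = np.random.default_rng(seed)
    traces = []
    for conc in ligand_series:
        warn = conc < 10.0 * probe
        if t_grid is None:
            k_slow = slow_relaxation_rate(rates, conc)
            tg = np.linspace(0.0, 5.0 / max(k_slow, 1e-12), n_points)
        else:
            tg = np.asarray(t_grid, float)
        init = KineticState((1 - eq.f_y) * probe, eq.f_y * probe, 0.0, conc)
        c = simulate_kinetics(rates, init, tg)
        if observable == "fret":
            sig = np.array([fret_signal(_hinge_fractions(row, probe), fret_params)
                            for row in c])
        elif observable == "fp":
            sig = c[:, 2] / probe
        else:
            raise ValueError(f"unknown observable {observable!r}")
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
        traces.append(KineticTrace(tg, sig, {
            "ligand_conc": float(conc), "probe": probe,
            "noise_sd": noise_sd, "seed": seed,
            "pseudo_first_order_warning": bool(warn),
        }))
    return traces


# ---------------------------------------------------------------------------
# Fitters

def fit_exponential(trace: KineticTrace) -> FitResult:
    """Fit signal(t) = offset + amplitude * (1 - exp(-k_app t)).

    Initialised by a semilog regression on the plateau-subtracted signal.
    A flat trace is reported with amplitude ~ 0 and an 'unidentifiable'
    flag; non-convergence within 200 iterations sets converged = False.
    """
    t = np.asarray(trace.t, float)
    y = np.asarray(trace.signal, float)
    if len(t) < 8:
        raise FitError("need at least 8 points for an exponential fit")
    span = float(y.max() - y.min())
    scale = max(np.abs(y).max(), 1e-30)
    if span < 1e-9 * scale:
        return FitResult({"k_app": np.nan, "amplitude": 0.0,
                          "offset": float(y.mean())},
                         {}, 0.0, True, flags=["unidentifiable"])
    plateau = float(np.mean(y[-max(3, len(y) // 10):]))
    resid0 = y - plateau
    usable = np.abs(resid0) > 1e-3 * max(abs(plateau), span)
    k0 = 1.0 / (t[-1] - t[0] + 1e-30)
    if usable.sum() >= 3:
        slope, _ = np.polyfit(t[usable], np.log(np.abs(resid0[usable])), 1)
        if slope < 0:
            k0 = -slope
    amp0 = plateau - y[0]

    def model(tt, k, a, c):
        return c + a * (1.0 - np.exp(-k * tt))

    try:
        popt, pcov = curve_fit(model, t, y, p0=[k0, amp0, y[0]], maxfev=200 * 4)
    except RuntimeError:
        return FitResult({"k_app": np.nan, "amplitude": np.nan, "offset": np.nan},
                         {}, np.nan, False, n_iter=200)
    resid = y - model(t, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    flags = []
    if abs(popt[1]) < 1e-6 * scale:
        flags.append("unidentifiable")
    return FitResult(
        {"k_app": float(popt[0]), "amplitude": float(popt[1]),
         "offset": float(popt[2])},
        {"k_app": float(se[0]), "amplitude": float(se[1]), "offset": float(se[2])},
        rms, True, flags=flags)


def fit_pseudo_first_order(k_apps, concs, k_se=None) -> FitResult:
    """Weighted linear regression k_app = k_on [P] + k_off.

    Weights are inverse-variance when standard errors are supplied.  A
    fitted k_off below zero by more than 2 SE is flagged as a model
    violation.
    """
    k_apps = np.asarray(k_apps, float)
    concs = np.asarray(concs, float)
    if len(k_apps) != len(concs) or len(k_apps) < 3:
        raise FitError("need >= 3 (concentration, k_app) pairs")
    if k_se is not None:
        w = 1.0 / np.clip(np.asarray(k_se, float), 1e-30, None) ** 2
    else:
        w = np.ones_like(k_apps)
    X = np.column_stack([concs, np.ones_like(concs)])
    W = np.diag(w)
    XtW = X.T @ W
    beta = np.linalg.solve(XtW @ X, XtW @ k_apps)
    resid = k_apps - X @ beta
    dof = len(k_apps) - 2
    s2 = float(resid @ (w * resid)) / max(dof, 1)
    cov = s2 * np.linalg.inv(XtW @ X)
    se = np.sqrt(np.diag(cov))
    flags = []
    if beta[1] < -2.0 * se[1]:
        flags.append("negative_koff")
    return FitResult({"k_on": float(beta[0]), "k_off": float(beta[1])},
                     {"k_on": float(se[0]), "k_off": float(se[1])},
                     float(np.sqrt(np.mean(resid ** 2))), True, flags=flags)


def fit_isotherm(curve: TitrationCurve, model: str = "quadratic") -> FitResult:
    """Fit a titration with a tight-binding (quadratic) or hyperbolic isotherm.

    The quadratic model accounts for probe depletion exactly using the probe
    concentration recorded in the curve metadata and is the default: with
    sub-nanomolar probes and nanomolar dissociation constants the hyperbolic
    approximation biases K_D upward.  An extrapolation warning is flagged
    when the fitted K_D falls outside [min conc / 100, max conc * 100].
    """
    conc = np.asarray(curve.conc, float)
    y = np.asarray(curve.signal, float)
    if len(conc) < 6:
        raise FitError("need >= 6 concentrations")
    probe = float(curve.meta.get("probe_tot", 0.0))
    span = float(y.max() - y.min())
    if span < 1e-9 * max(np.abs(y).max(), 1e-30):
        return FitResult({"kd": np.nan, "amplitude": 0.0, "offset": float(y.mean())},
                         {}, 0.0, True, flags=["unidentifiable"])

    if model == "quadratic":
        def frac(c, kd):
            return np.array([_bound_conc(kd, ci, probe) / max(probe, 1e-30)
                             for ci in c])
    elif model == "hyperbolic":
        def frac(c, kd):
            return c / (c + kd)
    else:
        raise ValueError(f"unknown isotherm model {model!r}")

    def f(c, log_kd, amp, off):
        return off + amp * frac(c, np.exp(log_kd))

    kd0 = conc[np.argmin(np.abs(y - (y[0] + 0.5 * span)))]
    try:
        popt, pcov = curve_fit(f, conc, y,
                               p0=[np.log(max(kd0, 1e-30)), span, y[0]],
                               maxfev=2000)
    except RuntimeError:
        return FitResult({"kd": np.nan, "amplitude": np.nan, "offset": np.nan},
                         {}, np.nan, False)
    kd = float(np.exp(popt[0]))
    resid = y - f(conc, *popt)
    se_log = np.sqrt(max(pcov[0, 0], 0.0))
    flags = []
    if not (conc.min() * 1e-2 <= kd <= conc.max() * 1e2):
        flags.append("extrapolated_kd")
    return FitResult({"kd": kd, "amplitude": float(popt[1]), "offset": float(popt[2])},
                     {"kd": kd * se_log, "amplitude": float(np.sqrt(max(pcov[1, 1], 0))),
                      "offset": float(np.sqrt(max(pcov[2, 2], 0)))},
                     float(np.sqrt(np.mean(resid ** 2))), True, flags=flags)


# ---------------------------------------------------------------------------
# DEER surrogates

DEER_GRID = np.arange(10.0, 80.0 + 0.25, 0.5)
DEER_SIGMA = 3.0  # A, default spin-label broadening


def deer_distribution(weights, means, sigmas=None,
                      grid: np.ndarray = DEER_GRID) -> DistanceDistribution:
    """Gaussian-mixture surrogate distance distribution on a grid.

    State means come from CB-CB distances of the design models; the default
    3 A width stands in for spin-label rotamer spread.  The density is
    renormalized to unit trapezoidal integral; if the grid truncates more
    than 0.1% of the mass the distribution is flagged.
    """
    weights = np.asarray(weights, float)
    means = np.asarray(means, float)
    if sigmas is None:
        sigmas = np.full_like(means, DEER_SIGMA)
    sigmas = np.asarray(sigmas, float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be non-negative and sum to 1")
    if np.any(sigmas <= 0):
        raise ValueError("sigmas must be positive")
    density = np.zeros_like(grid)
    for w, m, s in zip(weights, means, sigmas):
        density += w * np.exp(-0.5 * ((grid - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    mass = np.trapezoid(density, grid)
    truncated = mass < 0.999
    if mass <= 0:
        raise ValueError("all mixture mass falls outside the grid")
    return DistanceDistribution(grid.copy(), density / mass, truncated)


def decompose_deer(observed: DistanceDistribution,
                   basis_x: DistanceDistribution,
                   basis_y: DistanceDistribution) -> FitResult:
    """Non-negative least-squares two-state decomposition of a distribution.

    Returns weights (w_x, w_y) renormalized to sum 1.  Nearly collinear
    bases (cosine similarity > 0.99) are flagged unidentifiable.
    """
    if not (np.array_equal(observed.r, basis_x.r)
            and np.array_equal(observed.r, basis_y.r)):
        raise ValueError("distributions must share a common grid")
    A = np.column_stack([basis_x.density, basis_y.density])
    cos = float(A[:, 0] @ A[:, 1]
                / (np.linalg.norm(A[:, 0]) * np.linalg.norm(A[:, 1]) + 1e-300))
    w, rnorm = nnls(A, observed.density)
    total = w.sum()
    flags = []
    if cos > 0.99:
        flags.append("unidentifiable")
    if total <= 0:
        return FitResult({"w_x": np.nan, "w_y": np.nan}, {}, float(rnorm),
                         False, flags=flags + ["empty"])
    w = w / total
    return FitResult({"w_x": float(w[0]), "w_y": float(w[1])}, {},
                     float(rnorm / np.sqrt(len(observed.r))), True, flags=flags)


def kon_from_association(rates: RateConstants, probe: float,
                         ligand_series, noise_sd: float = 0.0,
                         seed: int = 0, observable: str = "fp") -> FitResult:
    """Full pseudo-first-order analysis chain on simulated data.

    Simulates association traces at each ligand concentration, fits each
    with a single exponential, and regresses the apparent rates against
    concentration; the slope estimates k_on = k2 * F_Y and the intercept
    k_off = k_m2.
    """
    ligand_series = np.asarray(ligand_series, float)
    traces = simulate_association(rates, probe, ligand_series,
                                  observable=observable,
                                  noise_sd=noise_sd, seed=seed)
    ks, ses = [], []
    for trace in traces:
        fit = fit_exponential(trace)
        ks.append(fit.params["k_app"])
        ses.append(fit.se.get("k_app") if fit.se else None)
    weights = None if any(s is None for s in ses) or noise_sd == 0 else ses
    return fit_pseudo_first_order(ks, ligand_series, weights)


# ---------------------------------------------------------------------------
# F_Y inference

def infer_fy_from_kon_ratio(k_on_variant: float, k_on_reference: float,
                            f_y_reference: float = 1.0) -> tuple[float, list]:
    """Infer the state-Y fraction of a variant from an on-rate ratio.

    Under the fast pre-equilibrium model k_on = k2 * F_Y; assuming the
    microscopic k2 is identical between variant and reference (flagged in
    the result), F_Y(variant) = F_Y(reference) * k_on(variant)/k_on(ref).
    Values above 1 are clipped and flagged inconsistent.
    """
    if min(k_on_variant, k_on_reference) <= 0 or not (0 < f_y_reference <= 1):
        raise ValueError("rates must be positive and f_y_reference in (0, 1]")
    f_y = f_y_reference * k_on_variant / k_on_reference
    flags = ["assumes_identical_k2"]
    if f_y > 1.0:
        flags.append("inconsistent_ratio")
        f_y = 1.0
    return float(f_y), flags
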