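"""Three-state kinetic model coupling a conformational pre-equilibrium to binding.

The hinge exchanges between an effector-incompetent state X and a binding
competent state Y (rates k1: X->Y, k_m1: Y->X); only Y binds the peptide P
(association k2, dissociation k_m2):

    X  <-- k_m1 / k1 -->  Y  + P  <-- k_m2 / k2 -->  YP

When the conformational exchange is much faster than binding, X/Y can be
treated as a fast pre-equilibrium and the observed association rate becomes
k_on = k2 * F_Y with F_Y = k1/(k1 + k_m1) = [Y]/([X]+[Y]), linking the
conformational equilibrium (K_conf = k1/k_m1) to the apparent affinity
K_D,app = K_D,intrinsic / F_Y.  Mutations or staples that stabilise one
state shift K_conf by exp(ddG/RT) and therefore rescale F_Y and k_on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

R_KCAL = 1.98720425e-3  # kcal / (mol K)
T_DEFAULT = 298.15      # K


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rate constants of the three-state model."""

    k1: float    # s^-1, X -> Y
    k_m1: float  # s^-1, Y -> X
    k2: float    # M^-1 s^-1, Y + P -> YP
    k_m2: float  # s^-1, YP -> Y + P

    def __post_init__(self) -> None:
        for name in ("k1", "k_m1", "k2", "k_m2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k1 + self.k_m1 <= 0:
            raise ValueError("conformational exchange requires k1 + k_m1 > 0")


@dataclass(frozen=True)
class DerivedEquilibrium:
    k_conf: float          # k1/k_m1 (dimensionless)
    f_y: float             # fractional state-Y population of unbound hinge
    kd_intrinsic: float    # M; k_m2/k2; inf-flagged when k2 == 0
    kd_app: float          # M; kd_intrinsic / f_y
    kd_defined: bool = True


@dataclass
class KineticState:
    """Concentration vector (M) of the hinge/peptide species at one time."""

    x: float
    y: float
    yp: float
    p: float
    time: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.yp, self.p], float)


@dataclass(frozen=True)
class StabilityShift:
    """Free-energy bias of the conformational equilibrium.

    Positive ``ddg_conf`` (kcal/mol) favours state Y; it multiplies K_conf
    by exp(ddg_conf / RT).
    """

    ddg_conf: float
    temperature: float = T_DEFAULT

    @property
    def fold_change(self) -> float:
        return float(np.exp(self.ddg_conf / (R_KCAL * self.temperature)))


def derive_equilibrium(rates: RateConstants) -> DerivedEquilibrium:
    """Equilibrium quantities implied by the four rate constants."""
    k_conf = np.inf if rates.k_m1 == 0 else rates.k1 / rates.k_m1
    f_y = rates.k1 / (rates.k1 + rates.k_m1)
    if rates.k2 == 0:
        return DerivedEquilibrium(k_conf, f_y, np.inf, np.inf, kd_defined=False)
    kd_int = rates.k_m2 / rates.k2
    kd_app = np.inf if f_y == 0 else kd_int / f_y
    return DerivedEquilibrium(k_conf, f_y, kd_int, kd_app)


def pre_equilibrium_kon(rates: RateConstants, p_ref: float | None = None
                        ) -> tuple[float, bool]:
    """Observed on-rate under the fast pre-equilibrium approximation.

    Returns ``(k_on, valid)`` with k_on = k2 * F_Y.  The validity flag
    checks timescale separation at a reference peptide concentration:
    (k1 + k_m1) >= 10 * (k2 * p_ref + k_m2); it is True when no reference
    is supplied.
    """
    f_y = derive_equilibrium(rates).f_y
    k_on = rates.k2 * f_y
    valid = True
    if p_ref is not None:
        valid = (rates.k1 + rates.k_m1) >= 10.0 * (rates.k2 * p_ref + rates.k_m2)
    return float(k_on), bool(valid)


def equilibrium_populations(rates: RateConstants, h_tot: float, p_tot: float
                            ) -> KineticState:
    """Exact coupled equilibrium (conformational + binding) with depletion.

    Eliminating X through K_conf reduces the system to single-site binding
    with the apparent K_D; the bound concentration is the stable root of the
    resulting quadratic.  Agrees with the long-time limit of
    :func:`simulate_kinetics`.
    """
    if h_tot < 0 or p_tot < 0:
        raise ValueError("totals must be >= 0")
    eq = derive_equilibrium(rates)
    if not eq.kd_defined or not np.isfinite(eq.kd_app):
        # no binding possible: pure conformational split
        return KineticState((1 - eq.f_y) * h_tot, eq.f_y * h_tot, 0.0, p_tot)
    kd = eq.kd_app
    b = h_tot + p_tot + kd
    disc = b * b - 4.0 * h_tot * p_tot
    # numerically stable smaller root of yp^2 - b*yp + h*p = 0
    yp = 2.0 * h_tot * p_tot / (b + np.sqrt(max(disc, 0.0)))
    u = h_tot - yp
    return KineticState((1 - eq.f_y) * u, eq.f_y * u, yp, p_tot - yp)


def _rhs(_t, c, k1, k_m1, k2, k_m2):
    x, y, yp, p = c
    bind = k2 * y * p - k_m2 * yp
    conf = k1 * x - k_m1 * y
    return [-conf, conf - bind, bind, -bind]


def simulate_kinetics(rates: RateConstants, initial: KineticState,
                      t_grid: np.ndarray) -> np.ndarray:
    """Integrate the nonlinear three-state ODE system on ``t_grid``.

    Returns an (n, 4) array of (x, y, yp, p) in M.  Uses adaptive implicit
    stepping (LSODA) with rtol 1e-8; both conservation laws (total hinge,
    total peptide) are enforced exactly by projection after integration.
    """
    t_grid = np.asarray(t_grid, float)
    if len(t_grid) == 0 or np.any(np.diff(t_grid) < 0):
        raise ValueError("t_grid must be non-empty and increasing")
    c0 = initial.as_array()
    if np.any(c0 < 0):
        raise ValueError("negative initial concentrations")
    if len(t_grid) == 1 or t_grid[-1] == t_grid[0]:
        return np.tile(c0, (len(t_grid), 1))
    h_tot = c0[0] + c0[1] + c0[2]
    p_tot = c0[2] + c0[3]
    scale = max(h_tot, p_tot, 1e-30)
    sol = solve_ivp(_rhs, (t_grid[0], t_grid[-1]), c0, t_eval=t_grid,
                    method="LSODA", rtol=1e-8, atol=1e-14 * scale,
                    args=(rates.k1, rates.k_m1, rates.k2, rates.k_m2))
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    c = np.clip(sol.y.T, 0.0, None)
    # project onto the conservation manifold
    hinge = c[:, 0] + c[:, 1] + c[:, 2]
    np.divide(c[:, :3].T, hinge, out=c[:, :3].T, where=hinge > 0)
    c[:, :3] *= h_tot
    c[:, 3] = p_tot - c[:, 2]
    return c


def linear_solution_excess_p(rates: RateConstants, p_const: float,
                             initial: KineticState, t_grid: np.ndarray
                             ) -> tuple[np.ndarray, bool]:
    """Exact pseudo-first-order solution with the peptide held constant.

    With [P] fixed the (X, Y, YP) system is linear; it is solved by
    eigendecomposition (matrix exponential fallback for defective matrices,
    flagged in the second return value).  Serves as the independent oracle
    for :func:`simulate_kinetics` in the excess-peptide regime.  The
    returned array is (n, 4) with the constant p in the last column.
    """
    t_grid = np.asarray(t_grid, float)
    A = np.array([
        [-rates.k1, rates.k_m1, 0.0],
        [rates.k1, -(rates.k_m1 + rates.k2 * p_const), rates.k_m2],
        [0.0, rates.k2 * p_const, -rates.k_m2],
    ])
    c0 = initial.as_array()[:3]
    w, V = np.linalg.eig(A)
    try:
        cond = np.linalg.cond(V)
    except np.linalg.LinAlgError:
        cond = np.inf
    defective = not np.isfinite(cond) or cond > 1e10
    if defective:
        # (nearly) repeated eigenvalues: fall back to the matrix exponential
        out = np.array([expm(A * t) @ c0 for t in t_grid])
    else:
        alpha = np.linalg.solve(V, c0)
        out = np.real((V * alpha) @ np.exp(np.outer(w, t_grid))).T
    full = np.empty((len(t_grid), 4))
    full[:, :3] = np.real(out)
    full[:, 3] = p_const
    return full, defective


def slow_relaxation_rate(rates: RateConstants, p_const: float) -> float:
    """Smallest-magnitude relaxation eigenvalue of the linear system.

    In the pre-equilibrium limit this approaches k2 * F_Y * p + k_m2, the
    apparent rate of a pseudo-first-order association experiment.
    """
    A = np.array([
        [-rates.k1, rates.k_m1, 0.0],
        [rates.k1, -(rates.k_m1 + rates.k2 * p_const), rates.k_m2],
        [0.0, rates.k2 * p_const, -rates.k_m2],
    ])
    w = np.linalg.eigvals(A)
    w = np.real(w)
    nonzero = np.sort(np.abs(w))[1:]  # drop the conserved (zero) mode
    return float(nonzero[0])


def apply_stability_shift(rates: RateConstants, shift: StabilityShift,
                          convention: str = "scale_km1") -> RateConstants:
    """Rescale the conformational equilibrium by a mutation/staple bias.

    K_conf is multiplied by exp(ddg_conf/RT).  Under ``scale_km1`` only the
    Y->X rate changes (k_m1 divided by the factor); under ``scale_k1`` only
    the X->Y rate (k1 multiplied).  Binding rates are untouched: the
    perturbations modelled are away from the effector interface, so only
    the pre-equilibrium (and hence k_on = k2*F_Y) shifts.
    """
    f = shift.fold_change
    if convention == "scale_km1":
        return replace(rates, k_m1=rates.k_m1 / f)
    if convention == "scale_k1":
        return replace(rates, k1=rates.k1 * f)
    raise ValueError(f"unknown convention {convention!r}")


def lock_state(rates: RateConstants, state: str) -> RateConstants:
    """Model a disulfide staple: lock X zeroes k1, lock Y zeroes k_m1
    (F_Y = 1, the oxidized locked-Y species)."""
    if state == "X":
        return replace(rates, k1=0.0)
    if state == "Y":
        return replace(rates, k_m1=0.0)
    raise ValueError(f"state must be 'X' or 'Y', got {state!r}")


def simulate_competition(rates_labeled: RateConstants,
                         rates_competitor: RateConstants,
                         h_lab: float, p_tot: float, h_comp: float,
                         schedule: dict, t_grid: np.ndarray) -> np.ndarray:
    """Reversibility experiment: label hinge, add peptide, then competitor.

    A second (unlabeled) hinge sharing the free-peptide pool is described by
    species (X', Y', Y'P).  The labeled hinge starts at its conformational
    equilibrium; ``p_tot`` is injected into the free pool at
    ``schedule["t_peptide"]`` and the competitor hinge (at its own
    conformational equilibrium) at ``schedule["t_competitor"]``.  Returns an
    (n, 7) array of (x, y, yp, p, x2, y2, y2p).
    """
    t_grid = np.asarray(t_grid, float)
    t_pep = float(schedule["t_peptide"])
    t_comp = float(schedule["t_competitor"])
    if not (t_grid[0] <= t_pep <= t_grid[-1]) or not (t_grid[0] <= t_comp <= t_grid[-1]):
        raise ValueError("schedule times must lie within the time grid")

    kl, kc = rates_labeled, rates_competitor

    def rhs(_t, c):
        x, y, yp, p, x2, y2, y2p = c
        bind1 = kl.k2 * y * p - kl.k_m2 * yp
        conf1 = kl.k1 * x - kl.k_m1 * y
        bind2 = kc.k2 * y2 * p - kc.k_m2 * y2p
        conf2 = kc.k1 * x2 - kc.k_m1 * y2
        return [-conf1, conf1 - bind1, bind1,
                -bind1 - bind2,
                -conf2, conf2 - bind2, bind2]

    f_lab = derive_equilibrium(kl).f_y
    f_comp = derive_equilibrium(kc).f_y
    c = np.array([(1 - f_lab) * h_lab, f_lab * h_lab, 0.0, 0.0,
                  0.0, 0.0, 0.0])
    events = sorted({t_grid[0], t_pep, t_comp, t_grid[-1]})
    out = np.empty((len(t_grid), 7))
    filled = np.zeros(len(t_grid), bool)
    for t0, t1 in zip(events, events[1:]):
        if t0 == t_pep:
            c[3] += p_tot
        if t0 == t_comp:
            c[4] += (1 - f_comp) * h_comp
            c[5] += f_comp * h_comp
        mask = (t_grid >= t0) & (t_grid <= t1) & ~filled
        te = t_grid[mask]
        if t1 > t0:
            sol = solve_ivp(rhs, (t0, t1), c, t_eval=te if len(te) else None,
                            method="LSODA", rtol=1e-8,
                            atol=1e-14 * max(h_lab + h_comp, p_tot, 1e-30))
            if not sol.success:
                raise RuntimeError(f"ODE integration failed: {sol.message}")
            if len(te):
                out[mask] = sol.y.T
                filled[mask] = True
            c = sol.y[:, -1].copy()
    out[~filled] = c
    return np.clip(out, 0.0, None)
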