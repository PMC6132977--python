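"""Hamiltonian dynamics of the extinction path and the action integral.

The scaled jump process has Hamiltonian

    H(y, theta) = beta (sum_j lam_j y_j) (sum_i mu_i (f_i - y_i)(e^{theta_i}-1))
                  + gamma sum_i y_i (e^{-theta_i}-1),

whose zero-energy manifold carries the optimal path to extinction: a
heteroclinic connection of Hamilton's equations from the endemic point
(y*, 0) to the extinction point (0, theta*).  The action

    A = int theta . dy/dt dt = - int y . dtheta/dt dt

along that connection is the exponential growth rate of the mean persistence
time, lim (ln tau)/N.  When heterogeneity is present in both infectivity and
susceptibility no closed form is available and the connection is computed
here as a two-point boundary-value problem.

Numerical formulation: the connection is posed on a scaled interval
x in [0, 1] with the (unknown) traversal time T as a free parameter,
``dz/dx = T F(z)``.  Exact fixed points are reached only at infinite time, so
the boundary conditions are projections: the departure z(0) - (y*, 0) must
lie in the unstable subspace of the linearisation at the endemic point, the
arrival z(1) - (0, theta*) in the stable subspace at the extinction point,
and time-translation invariance is removed by pinning the departure
amplitude |z(0) - (y*, 0)| to a small delta.  The O(delta^2) action missed
in the truncated tails is negligible at the default delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_bvp
from scipy.linalg import eig, null_space, orth

from .model_core import GroupModel, StagedModel, require_supercritical, validate_model
from .equilibria import endemic_equilibrium, momentum_equilibrium
from .action_formulas import ActionResult


class ConvergenceError(RuntimeError):
    """Boundary-value solve failed; diagnostics attached as ``.diagnostics``."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class Trajectory:
    """Discretised heteroclinic path on the zero-energy manifold."""

    t: np.ndarray
    y_path: np.ndarray       # (n, k)
    theta_path: np.ndarray   # (n, k)
    action_increments: np.ndarray  # (n-1,)
    model: GroupModel
    diagnostics: dict = field(default_factory=dict)


def hamiltonian(model: GroupModel, y, theta) -> float:
    """H(y, theta); vanishes identically at theta = 0 and at y = 0."""
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    force = float(np.sum(model.lam * y))
    infection = model.beta * force * np.sum(
        model.mu * (model.f - y) * np.expm1(theta))
    recovery = model.gamma * np.sum(y * np.expm1(-theta))
    return float(infection + recovery)


def equations_of_motion(model: GroupModel, y, theta) -> tuple[np.ndarray, np.ndarray]:
    """Hamilton's equations (dy/dt, dtheta/dt) = (dH/dtheta, -dH/dy)."""
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    f, lam, mu = model.f, model.lam, model.mu
    beta, gamma = model.beta, model.gamma
    force = np.sum(lam * y)
    e_th = np.exp(theta)
    e_mth = np.exp(-theta)
    dy = beta * force * mu * (f - y) * e_th - gamma * y * e_mth
    dtheta = (-beta * lam * np.sum(mu * (f - y) * (e_th - 1.0))
              + beta * force * mu * (e_th - 1.0)
              - gamma * (e_mth - 1.0))
    return dy, dtheta


def _field(model: GroupModel, z: np.ndarray) -> np.ndarray:
    k = model.k
    dy, dth = equations_of_motion(model, z[:k], z[k:])
    return np.concatenate([dy, dth])


def _field_vec(model: GroupModel, Z: np.ndarray) -> np.ndarray:
    """Vector field on a batch of states, Z of shape (2k, n)."""
    k = model.k
    f, lam, mu = model.f[:, None], model.lam[:, None], model.mu[:, None]
    beta, gamma = model.beta, model.gamma
    Y, TH = Z[:k], Z[k:]
    force = (model.lam @ Y)[None, :]
    TH = np.clip(TH, -200.0, 200.0)   # guard wild Newton iterates
    e_th = np.exp(TH)
    e_mth = np.exp(-TH)
    dY = beta * force * mu * (f - Y) * e_th - gamma * Y * e_mth
    coupling = np.sum(mu * (f - Y) * (e_th - 1.0), axis=0)[None, :]
    dTH = (-beta * lam * coupling + beta * force * mu * (e_th - 1.0)
           - gamma * (e_mth - 1.0))
    return np.vstack([dY, dTH])


def _jacobian(model: GroupModel, z: np.ndarray, h: float = 1e-7) -> np.ndarray:
    n = z.size
    J = np.empty((n, n))
    for j in range(n):
        step = h * (1.0 + abs(z[j]))
        zp = z.copy(); zp[j] += step
        zm = z.copy(); zm[j] -= step
        J[:, j] = (_field(model, zp) - _field(model, zm)) / (2.0 * step)
    return J


def _subspace_constraints(model: GroupModel, z_fp: np.ndarray, unstable: bool):
    """Rows annihilating the chosen invariant subspace's complement.

    ``unstable=True`` returns L with L (z - z_fp) = 0 iff the deviation lies
    in the unstable right subspace of the Jacobian at ``z_fp`` (used at the
    departure end); ``unstable=False`` selects the stable subspace.
    """
    k = model.k
    J = _jacobian(model, z_fp)
    vals, vecs = eig(J)
    select = vals.real > 0 if unstable else vals.real < 0
    if int(select.sum()) != k:
        raise ConvergenceError(
            f"fixed point has {int(select.sum())} "
            f"{'unstable' if unstable else 'stable'} directions, expected {k}",
            {"eigenvalues": vals})
    cols = vecs[:, select]
    basis = orth(np.hstack([cols.real, cols.imag]))
    if basis.shape[1] != k:
        raise ConvergenceError("degenerate invariant subspace at fixed point")
    L = null_space(basis.T).T       # (k, 2k)
    rates = vals.real[select]
    # dominant direction (largest |Re|): the deviation at the truncation
    # point is asymptotically aligned with it
    dom = int(np.argmax(np.abs(rates)))
    v_dom = cols[:, dom].real
    v_dom = v_dom / np.linalg.norm(v_dom)
    return L, float(np.min(np.abs(rates))), v_dom


def _solve_fixed_T(model: GroupModel, z_e, z_x, L_e, L_x, T, guess,
                   tol, max_nodes):
    """One collocation solve on a fixed truncated interval [0, T].

    With the interval fixed, the projection conditions at the two ends give
    exactly 2k boundary conditions for the 2k first-order equations; the
    finite interval itself pins the phase of the connection.
    """
    def fun(x, z):
        return T * _field_vec(model, z)

    def bc(za, zb):
        return np.concatenate([L_e @ (za - z_e), L_x @ (zb - z_x)])

    x0, z0 = guess
    return solve_bvp(fun, bc, x0, z0, tol=tol, max_nodes=max_nodes, verbose=0)


def _initial_guess(z_e, z_x, n=101):
    x = np.linspace(0.0, 1.0, n)
    ramp = 0.5 * (1.0 - np.cos(np.pi * x))  # smooth monotone 0 -> 1
    z = z_e[:, None] + (z_x - z_e)[:, None] * ramp[None, :]
    return x, z


def _solution_metrics(model, sol, z_e, z_x, n_check=501):
    xs = np.linspace(0.0, 1.0, n_check)
    zs = sol.sol(xs)
    k = model.k
    max_H = max(abs(hamiltonian(model, zs[:k, i], zs[k:, i]))
                for i in range(n_check))
    return (float(max_H), float(np.linalg.norm(zs[:, 0] - z_e)),
            float(np.linalg.norm(zs[:, -1] - z_x)))


def solve_heteroclinic(model: GroupModel, *, endpoint_tol: float = 1e-4,
                       tol: float = 1e-8, max_nodes: int = 30000,
                       hamiltonian_tol: float = 1e-6,
                       n_dense: int = 2001, T0: float | None = None,
                       max_T_steps: int = 10,
                       continuation_steps: int = 4) -> Trajectory:
    """Heteroclinic connection from (y*, 0) to (0, theta*).

    ``endpoint_tol`` is relative to the distance between the two fixed
    points.  The interval length T is grown geometrically (warm-starting
    each solve from the previous solution) until the endpoint deviations
    fall below the tolerance; if the first solve fails outright, a homotopy
    from the homogeneous model (where the straight-line path is nearly
    exact) supplies a usable starting profile.  Raises
    :class:`ConvergenceError` when no trajectory on the zero-energy
    manifold is found.
    """
    require_supercritical(model)
    k = model.k

    def endpoints(m):
        z_e = np.concatenate([endemic_equilibrium(m), np.zeros(k)])
        z_x = np.concatenate([np.zeros(k), momentum_equilibrium(m)])
        return z_e, z_x

    def prepared(m):
        z_e, z_x = endpoints(m)
        L_e, rate_e, _ = _subspace_constraints(m, z_e, unstable=True)
        L_x, rate_x, _ = _subspace_constraints(m, z_x, unstable=False)
        return z_e, z_x, L_e, L_x, rate_e, rate_x

    z_e, z_x, L_e, L_x, rate_e, rate_x = prepared(model)
    scale = np.linalg.norm(z_x - z_e)
    T = T0 if T0 is not None else (6.0 / rate_e + 6.0 / rate_x
                                   + 10.0 / model.gamma)

    def attempt(m, prep, T, guess):
        ze, zx, Le, Lx = prep
        sol = _solve_fixed_T(m, ze, zx, Le, Lx, T, guess, tol, max_nodes)
        max_H, de, dx = _solution_metrics(m, sol, ze, zx)
        on_manifold = max_H <= hamiltonian_tol and de < 0.5 * scale
        return sol, max_H, de, dx, on_manifold

    prep = (z_e, z_x, L_e, L_x)
    guess = _initial_guess(z_e, z_x)
    sol, max_H, de, dx, ok = attempt(model, prep, T, guess)

    if not ok:
        # homotopy in (lam, mu) from the homogeneous model, bisecting steps
        def homotopy_model(s):
            lam = 1.0 + s * (model.lam - 1.0)
            mu = 1.0 + s * (model.mu - 1.0)
            return validate_model(model.f, lam, mu, model.beta, model.gamma,
                                  normalise=True)

        s_done, step, attempts = 0.0, 1.0 / continuation_steps, 0
        guess_h = None
        while s_done < 1.0 and attempts < 60:
            s_next = min(1.0, s_done + step)
            m_h = homotopy_model(s_next)
            prep_h = prepared(m_h)[:4]
            g = guess_h if guess_h is not None else _initial_guess(*prep_h[:2])
            sol_h, mH, de_h, dx_h, ok_h = attempt(m_h, prep_h, T, g)
            attempts += 1
            if ok_h:
                s_done = s_next
                guess_h = (sol_h.x, sol_h.y)
                step = min(2.0 * step, max(1.0 - s_done, step))
            else:
                step *= 0.5
                if step < 1e-3:
                    raise ConvergenceError(
                        "homotopy step collapsed before reaching the target",
                        {"s_reached": s_done, "max_abs_H": mH})
        sol, max_H, de, dx, ok = attempt(model, prep, T, guess_h)
        if not ok:
            raise ConvergenceError(
                "no zero-energy trajectory found for the target model",
                {"max_abs_H": max_H})

    # grow T until the truncated endpoints are close enough to the fixed
    # points, warm-starting from the previous profile
    steps = 0
    while max(de, dx) > endpoint_tol * scale and steps < max_T_steps:
        T_new = 1.7 * T
        sol_new, mH, de_n, dx_n, ok_n = attempt(model, prep, T_new,
                                                (sol.x, sol.y))
        steps += 1
        if not ok_n or max(de_n, dx_n) > max(de, dx):
            break               # keep the best converged interval
        sol, max_H, de, dx, T = sol_new, mH, de_n, dx_n, T_new
    if max(de, dx) > 100.0 * endpoint_tol * scale:
        raise ConvergenceError(
            "endpoint deviations failed to shrink under interval growth",
            {"endpoint_distance_start": de, "endpoint_distance_end": dx,
             "T": T})

    x = np.linspace(0.0, 1.0, n_dense)
    z = sol.sol(x)
    dz = sol.sol(x, 1)          # derivative w.r.t. x; dz/dt = dz/dx / T
    y_path = z[:k].T
    theta_path = z[k:].T
    t = x * T

    H_vals = np.array([hamiltonian(model, z[:k, i], z[k:, i])
                       for i in range(x.size)])
    max_H = float(np.max(np.abs(H_vals)))

    # action increments by trapezoidal quadrature of theta . dy/dt, plus
    # analytic corrections for the truncated tails: approaching the
    # extinction point theta is already ~theta*, so the remaining integral
    # contributes -theta* . y(T) at first order; the correction at the
    # endemic end, theta(0) . (y(0) - y*), is second order but kept for
    # symmetry
    y_star = z_e[:k]
    theta_star = z_x[k:]
    integrand = np.einsum("ni,ni->n", theta_path, dz[:k].T / T)
    increments = 0.5 * (integrand[1:] + integrand[:-1]) * np.diff(t)
    tail_e = float(theta_path[0] @ (y_path[0] - y_star))
    tail_x = float(-theta_star @ y_path[-1])
    integrand_alt = -np.einsum("ni,ni->n", y_path, dz[k:].T / T)
    A_alt = float(np.trapezoid(integrand_alt, t)
                  - y_star @ theta_path[0]
                  - y_path[-1] @ (theta_star - theta_path[-1]))

    diag = {
        "T": T,
        "max_abs_H": max_H,
        "endpoint_distance_start": de,
        "endpoint_distance_end": dx,
        "endpoint_tol_abs": endpoint_tol * scale,
        "bvp_nodes": int(sol.x.size),
        "bvp_status": int(sol.status),
        "action_alt_form": A_alt,
        "tail_corrections": (tail_e, tail_x),
    }
    if max_H > hamiltonian_tol:
        raise ConvergenceError(
            f"zero-energy violation: max |H| = {max_H:.3e} exceeds "
            f"{hamiltonian_tol:.1e}", diag)
    increments = np.concatenate([[tail_e], increments, [tail_x]])
    return Trajectory(t=t, y_path=y_path, theta_path=theta_path,
                      action_increments=increments, model=model,
                      diagnostics=diag)


def action_from_trajectory(traj: Trajectory,
                           hamiltonian_tol: float = 1e-6,
                           form_agreement_tol: float = 1e-6) -> ActionResult:
    """Action A = int theta . dy/dt dt accumulated along the trajectory.

    Cross-checked against the integration-by-parts form - int y . dtheta/dt dt
    (the boundary terms vanish because theta = 0 at the endemic end and y = 0
    at the extinction end); refuses trajectories violating the zero-energy
    tolerance.
    """
    max_H = traj.diagnostics.get("max_abs_H")
    if max_H is not None and max_H > hamiltonian_tol:
        raise ValueError(
            f"trajectory violates the zero-energy manifold (max |H| = {max_H:.3e})")
    A = float(np.sum(traj.action_increments))
    A_alt = traj.diagnostics.get("action_alt_form")
    diag = dict(traj.diagnostics)
    if A_alt is not None:
        diag["form_difference"] = A - A_alt
        if abs(A - A_alt) > max(form_agreement_tol, 1e-8 * max(abs(A), 1.0)):
            diag["form_agreement_warning"] = True
    return ActionResult(A=A, method="bvp", diagnostics=diag)


def staged_hamiltonian(staged: StagedModel, y_stages, theta_stages) -> float:
    """Hamiltonian of the k-group, s-stage process (k x s arguments):

    infection creates stage-1 infectives, stage advance shifts one infective
    from stage v to v+1 at rate s*gamma per head, recovery removes stage-s
    infectives at rate s*gamma per head.  Vanishes at (y*_stages, 0) and at
    (0, theta*_stages); collapses to :func:`hamiltonian` at s = 1.
    """
    model = staged.base
    s = staged.s
    y = np.asarray(y_stages, dtype=float).reshape(model.k, s)
    th = np.asarray(theta_stages, dtype=float).reshape(model.k, s)
    f, lam, mu = model.f, model.lam, model.mu
    beta, gamma = model.beta, model.gamma
    group_tot = y.sum(axis=1)
    force = float(np.sum(lam * group_tot))
    H = beta * force * np.sum(mu * (f - group_tot) * np.expm1(th[:, 0]))
    if s > 1:
        H += s * gamma * np.sum(y[:, :-1] * np.expm1(-th[:, :-1] + th[:, 1:]))
    H += s * gamma * np.sum(y[:, -1] * np.expm1(-th[:, -1]))
    return float(H)
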