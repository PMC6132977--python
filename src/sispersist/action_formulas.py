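"""Closed-form action expressions for the persistence time exponent.

The action ``A = lim_{N->inf} (ln tau)/N`` governs how the mean time to
extinction from quasi-stationarity grows with population size.  When
heterogeneity is confined to one of infectivity or susceptibility there is
an explicit formula

    A = sum_i f_i ln(1 + c_i D(1, c)) - (gamma/beta) D(1, c),

with ``c`` the heterogeneous vector (the two cases give the same value by
network duality).  The homogeneous model has A0 = 1/R0 - 1 + ln R0 and
prefactor C = R0 sqrt(2 pi)/(R0-1)^2.  With both heterogeneities present,
a straight-line approximation of the extinction path gives the near-threshold
estimate ``A~`` (tilde), accurate for R0 only slightly above 1.

The module also evaluates the exact Hamilton-Jacobi potentials V(y) and
U(theta) for the susceptibility-heterogeneous case, both exponential and
Erlang: the action is the potential difference V(0) - V(y*) = U(0) - U(theta*)
and is independent of the stage count (so Erlang infectious periods leave
the leading-order persistence time unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import (
    GroupModel,
    StagedModel,
    basic_reproduction_number,
    require_supercritical,
)
from .equilibria import solve_D, _bracketed_root

#: R0 above which the straight-line (tilde) approximation is flagged
TILDE_WARN_R0 = 1.2


class UnsupportedConfigurationError(ValueError):
    """Raised when no closed-form action exists for the given model."""


@dataclass(frozen=True)
class ActionResult:
    A: float
    method: str
    diagnostics: dict = field(default_factory=dict)


def _xlogx(x: np.ndarray | float) -> np.ndarray | float:
    """x*ln(x) with the boundary convention 0*ln(0) = 0 (explicit branch)."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out if out.ndim else float(out)


def action_homogeneous(R0: float) -> float:
    """A0 = 1/R0 - 1 + ln(R0), the homogeneous SIS action (R0 > 1)."""
    if R0 <= 1.0:
        raise ValueError(f"homogeneous action requires R0 > 1, got {R0}")
    return 1.0 / R0 - 1.0 + np.log(R0)


def prefactor_homogeneous(R0: float) -> float:
    """C = R0 sqrt(2 pi) / (R0 - 1)^2 in tau ~ (C/sqrt(N)) exp(A N).

    Valid for the homogeneous model with time scaled so the mean infectious
    period is one; no analogue is available for heterogeneous models.
    """
    if R0 <= 1.0:
        raise ValueError(f"homogeneous prefactor requires R0 > 1, got {R0}")
    return R0 * np.sqrt(2.0 * np.pi) / (R0 - 1.0) ** 2


def action_explicit(model: GroupModel, tol: float = 1e-10) -> ActionResult:
    """Explicit action for single-type heterogeneity.

    Requires mu = 1 (heterogeneous infectivity) or lam = 1 (heterogeneous
    susceptibility); with both heterogeneities present no explicit formula
    exists and callers are directed to the boundary-value route
    (:func:`sispersist.hamiltonian_numerics.solve_heteroclinic`).
    """
    require_supercritical(model)
    mu_flat = model.is_homogeneous_in("mu", tol)
    lam_flat = model.is_homogeneous_in("lam", tol)
    if mu_flat:
        c = model.lam
        method = "explicit_infectivity"
        D = solve_D(model, "mu,lam")      # D(1, lam) since mu = 1
    elif lam_flat:
        c = model.mu
        method = "explicit_susceptibility"
        D = solve_D(model, "lam,mu")      # D(1, mu) since lam = 1
    else:
        raise UnsupportedConfigurationError(
            "no explicit action with heterogeneity in both infectivity and "
            "susceptibility; use the heteroclinic boundary-value solver")
    A = float(np.sum(model.f * np.log1p(c * D)) - model.gamma / model.beta * D)
    return ActionResult(A=A, method=method, diagnostics={"D": D})


def action_tilde(model: GroupModel) -> ActionResult:
    """Near-threshold straight-line approximation

        A~ = (D(lam,mu)/2) sum_i mu_i f_i ln(1 + lam_i D(mu,lam)) / (1 + mu_i D(lam,mu)),

    valid for R0 only slightly above 1.  Unlike the true action, the formula
    is not symmetric under interchanging lam and mu; the value for the
    role-swapped model and the difference are reported in the diagnostics,
    along with a warning flag when R0 exceeds the near-threshold regime.
    """
    r0 = require_supercritical(model)

    def tilde(m: GroupModel) -> float:
        D_lm = solve_D(m, "lam,mu")
        D_ml = solve_D(m, "mu,lam")
        terms = m.mu * m.f * np.log1p(m.lam * D_ml) / (1.0 + m.mu * D_lm)
        return float(0.5 * D_lm * np.sum(terms))

    A = tilde(model)
    A_swapped = tilde(model.swap_roles())
    diag = {
        "A_swapped": A_swapped,
        "swap_asymmetry": A - A_swapped,
        "R0": r0,
        "near_threshold_warning": bool(r0 > TILDE_WARN_R0),
    }
    return ActionResult(A=A, method="tilde_approx", diagnostics=diag)


# ---------------------------------------------------------------------------
# Hamilton-Jacobi potentials, susceptibility heterogeneity (lam = 1)
# ---------------------------------------------------------------------------

def _require_susceptibility_case(model: GroupModel):
    if not model.is_homogeneous_in("lam"):
        raise UnsupportedConfigurationError(
            "potentials are available only for heterogeneity in "
            "susceptibility (lam = 1)")


def potential_V_susceptible(model: GroupModel, y) -> float:
    """V(y) solving H(y, dV/dy) = 0 for the lam = 1 model:

        V(y) = sum_i y_i (1 + ln y_i - ln((beta/gamma) mu_i))
               - (sum_i y_i) ln(sum_i y_i)
               + sum_i (f_i - y_i) ln(f_i - y_i),

    with the 0*ln(0) = 0 convention on the boundary of the box [0, f].
    The action is the potential drop V(0) - V(y*).
    """
    _require_susceptibility_case(model)
    y = np.asarray(y, dtype=float)
    if np.any(y < -1e-15) or np.any(y > model.f + 1e-15):
        raise ValueError("y must lie in the box [0, f]")
    y = np.clip(y, 0.0, model.f)
    r = model.beta / model.gamma
    total = float(y.sum())
    out = float(np.sum(y) + np.sum(_xlogx(y)) - np.sum(y * np.log(r * model.mu)))
    out -= float(_xlogx(total))
    out += float(np.sum(_xlogx(model.f - y)))
    return out


def potential_U_susceptible(model: GroupModel, theta) -> float:
    """U(theta) for the lam = 1 model, via the internal root Q(mu, theta) of

        (beta/gamma) sum_j mu_j f_j / (exp(-theta_j) + mu_j Q) = 1 :

        U(theta) = sum_i f_i ln(1 + mu_i e^{theta_i} Q) - (gamma/beta) Q.

    Q(mu, 0) = D(1, mu) and Q(mu, theta*) = 0; hence U(0) - U(theta*)
    reproduces the explicit action.  Raises a domain error when no
    nonnegative root exists (theta outside the admissible region).
    """
    _require_susceptibility_case(model)
    theta = np.asarray(theta, dtype=float)
    f, mu = model.f, model.mu
    r = model.beta / model.gamma
    e = np.exp(theta)

    def lhs(q):
        return r * np.sum(mu * f / (np.exp(-theta) + mu * q))

    at_zero = lhs(0.0)
    if at_zero < 1.0 - 1e-12:
        raise ValueError("theta outside admissible region: no nonnegative root Q")
    if at_zero <= 1.0 + 1e-12:
        Q = 0.0
    else:
        Q = _bracketed_root(lhs, "Q(mu,theta)")
    return float(np.sum(f * np.log1p(mu * e * Q)) - Q / r)


# ---------------------------------------------------------------------------
# Erlang (method-of-stages) potentials, susceptibility heterogeneity
# ---------------------------------------------------------------------------

def staged_potential_V(staged: StagedModel, y_stages) -> float:
    """Stage-resolved V for Erlang periods and lam = 1 (k x s argument):

        V(y) = sum_{iv} y_iv (1 + ln y_iv - ln((beta/(s gamma)) mu_i))
               - (sum y_iv) ln(sum y_iv) + sum_i (f_i - sum_v y_iv) ln(...),

    reducing to :func:`potential_V_susceptible` at s = 1.  The potential
    drop V(0) - V(y*_stages) is independent of s.
    """
    model = staged.base
    _require_susceptibility_case(model)
    s = staged.s
    y = np.asarray(y_stages, dtype=float).reshape(model.k, s)
    group_tot = y.sum(axis=1)
    if np.any(y < -1e-15) or np.any(group_tot > model.f + 1e-14):
        raise ValueError("stage occupancies must be nonnegative with group sums <= f")
    y = np.clip(y, 0.0, None)
    r = model.beta / (s * model.gamma)
    total = float(y.sum())
    out = float(total + np.sum(_xlogx(y)) - np.sum(y * np.log(r * model.mu)[:, None]))
    out -= float(_xlogx(np.array(total)))
    out += float(np.sum(_xlogx(model.f - group_tot)))
    return out


def staged_potential_U(staged: StagedModel, theta_stages) -> float:
    """Stage-resolved U for Erlang periods and lam = 1:

        U(theta) = sum_i f_i ln(1 + mu_i (sum_v e^{theta_iv}) Q_s) - (s gamma/beta) Q_s,

    with Q_s the root of
        (beta/(s gamma)) sum_j mu_j f_j E_j / (1 + mu_j E_j Q_s) = 1,
    where E_j = sum_v exp(theta_jv).  Reduces to
    :func:`potential_U_susceptible` at s = 1.
    """
    model = staged.base
    _require_susceptibility_case(model)
    s = staged.s
    theta = np.asarray(theta_stages, dtype=float).reshape(model.k, s)
    f, mu = model.f, model.mu
    r = model.beta / (s * model.gamma)
    E = np.exp(theta).sum(axis=1)

    def lhs(q):
        return r * np.sum(mu * f * E / (1.0 + mu * E * q))

    at_zero = lhs(0.0)
    if at_zero < 1.0 - 1e-12:
        raise ValueError("theta outside admissible region: no nonnegative root Q_s")
    if at_zero <= 1.0 + 1e-12:
        Q = 0.0
    else:
        Q = _bracketed_root(lhs, "Q_s(mu,theta)")
    return float(np.sum(f * np.log1p(mu * E * Q)) - Q / r)
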