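"""Fixed points of the deterministic flow and of the Hamiltonian system.

For a super-critical model (R0 > 1) the deterministic mean-field ODE

    dy_i/dt = beta * (sum_j lam_j y_j) * mu_i (f_i - y_i) - gamma * y_i

has a unique globally stable endemic equilibrium ``y*`` parameterised by the
scalar ``D(lam, mu)``, the unique positive root of

    (beta/gamma) * sum_j  mu_j f_j lam_j / (1 + mu_j D)  =  1.

The momentum fixed point of the extinction path, ``theta*``, is obtained from
the role-swapped root: theta*_i = -ln(1 + lam_i D(mu, lam)).  The Erlang
(method-of-stages) variants generalise both, with the stage-resolved state
``y*_{iv} = y*_i / s`` and momenta growing linearly in the number of stages
still to traverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import (
    GroupModel,
    StagedModel,
    basic_reproduction_number,
    require_supercritical,
)

_ROOT_TOL = 1e-14


@dataclass(frozen=True)
class EquilibriumSummary:
    R0: float
    D_lam_mu: float
    D_mu_lam: float
    y_star: np.ndarray
    theta_star: np.ndarray

    def to_dict(self) -> dict:
        return {
            "R0": self.R0,
            "D_lam_mu": self.D_lam_mu,
            "D_mu_lam": self.D_mu_lam,
            "y_star": self.y_star.tolist(),
            "theta_star": self.theta_star.tolist(),
        }


@dataclass(frozen=True)
class StagedEquilibrium:
    D_s: float
    y_star_stages: np.ndarray     # (k, s)
    theta_star_stages: np.ndarray  # (k, s)


def _resolve_orientation(model: GroupModel, orientation) -> tuple[np.ndarray, np.ndarray]:
    """Return (outer, denom) vectors for D(first, second).

    The second argument's vector sits inside the denominator ``1 + denom_j D``;
    so D(lam, mu) has mu there and D(mu, lam) has lam there.
    """
    if isinstance(orientation, str):
        key = orientation.replace("(", "").replace(")", "").replace(" ", "")
        table = {
            "lam,mu": (model.lam, model.mu),
            "lambda,mu": (model.lam, model.mu),
            "mu,lam": (model.mu, model.lam),
            "mu,lambda": (model.mu, model.lam),
        }
        if key not in table:
            raise ValueError(f"unknown orientation {orientation!r}; use 'lam,mu' or 'mu,lam'")
        return table[key]
    first, second = orientation
    return np.asarray(first, dtype=float), np.asarray(second, dtype=float)


def _bracketed_root(lhs, name: str) -> float:
    """Root of the strictly decreasing ``lhs`` (with lhs(0) > 1) minus one.

    Grows the upper bracket geometrically from 1 until the left side drops
    below 1, then applies Brent's method.
    """
    hi = 1.0
    for _ in range(200):
        if lhs(hi) < 1.0:
            break
        hi *= 2.0
    else:  # pragma: no cover - unreachable for valid super-critical input
        raise RuntimeError(f"failed to bracket the root of {name}")
    return float(brentq(lambda d: lhs(d) - 1.0, 0.0, hi, xtol=_ROOT_TOL, rtol=8.9e-16))


def solve_D(model: GroupModel, orientation="lam,mu") -> float:
    """Unique positive root D(first, second) of the endemic scalar equation.

    ``orientation`` is ``"lam,mu"`` for D(lam, mu) (mu in the denominator,
    parameterising the endemic state y*) or ``"mu,lam"`` for the role-swapped
    root entering theta*.  Requires R0 > 1; the left side is strictly
    decreasing in D, starting from R0 at D=0, so a positive root exists and
    is unique exactly in the super-critical case.
    """
    require_supercritical(model)
    outer, denom = _resolve_orientation(model, orientation)
    f, r = model.f, model.beta / model.gamma

    def lhs(d):
        return r * np.sum(outer * f * denom / (1.0 + denom * d))

    # note lhs(0) = R0 > 1 regardless of orientation
    return _bracketed_root(lhs, f"D({orientation})")


def endemic_equilibrium(model: GroupModel) -> np.ndarray:
    """Endemic fixed point y*_i = mu_i f_i D(lam,mu) / (1 + mu_i D(lam,mu))."""
    D = solve_D(model, "lam,mu")
    return model.mu * model.f * D / (1.0 + model.mu * D)


def momentum_equilibrium(model: GroupModel) -> np.ndarray:
    """Momentum fixed point theta*_i = -ln(1 + lam_i D(mu,lam))."""
    D = solve_D(model, "mu,lam")
    return -np.log1p(model.lam * D)


def equilibrium_summary(model: GroupModel) -> EquilibriumSummary:
    return EquilibriumSummary(
        R0=basic_reproduction_number(model),
        D_lam_mu=solve_D(model, "lam,mu"),
        D_mu_lam=solve_D(model, "mu,lam"),
        y_star=endemic_equilibrium(model),
        theta_star=momentum_equilibrium(model),
    )


def solve_D_erlang(staged: StagedModel) -> float:
    """Root D_s(mu, lam) of the staged scalar equation

        (beta/(s*gamma)) sum_j mu_j f_j lam_j sum_{v=1}^s (1+lam_j D)^{-v} = 1.

    For s = 1 this is D(mu, lam) of the exponential-period model.
    """
    model = staged.base
    require_supercritical(model)
    s = staged.s
    f, lam, mu = model.f, model.lam, model.mu
    r = model.beta / (s * model.gamma)
    v = np.arange(1, s + 1)

    def lhs(d):
        powers = (1.0 + lam * d)[:, None] ** (-v[None, :])
        return r * np.sum(mu * f * lam * powers.sum(axis=1))

    return _bracketed_root(lhs, "D_s(mu,lam)")


def staged_equilibrium(staged: StagedModel) -> StagedEquilibrium:
    """Stage-resolved fixed points: uniform stage occupancy for y*, and
    theta*_{iv} = -(s+1-v) ln(1 + lam_i D_s(mu,lam))."""
    model = staged.base
    s = staged.s
    y = endemic_equilibrium(model)
    D_s = solve_D_erlang(staged)
    v = np.arange(1, s + 1)
    y_stages = np.repeat(y[:, None] / s, s, axis=1)
    theta_stages = -(s + 1 - v)[None, :] * np.log1p(model.lam * D_s)[:, None]
    return StagedEquilibrium(D_s=D_s, y_star_stages=y_stages,
                             theta_star_stages=theta_stages)
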