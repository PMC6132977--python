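"""Parameterisation of the k-group SIS model with separable mixing.

A closed population of ``N`` individuals is divided into ``k`` groups, group
``i`` holding a fraction ``f_i`` of the population.  An infective of group
``i`` contacts each member of group ``j`` at rate ``beta * lam_i * mu_j / N``
(separable mixing): ``lam_i`` is the relative infectivity of group ``i`` and
``mu_j`` the relative susceptibility of group ``j``.  Infectious periods are
exponential with mean ``1/gamma`` (or Erlang with ``s`` stages for the staged
variant).  Without loss of generality the group-level vectors are scaled so
that their f-weighted means are one::

    sum_i f_i = 1,    sum_i f_i * lam_i = 1,    sum_i f_i * mu_i = 1,

the overall scale being carried by ``beta``.  All closed-form results in the
package assume this scaling, so it is enforced at validation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: tolerance on the exact normalisation constraints
NORM_TOL = 1e-10


class ValidationError(ValueError):
    """Raised when raw parameters violate the model's invariants."""


class SubcriticalModelError(ValueError):
    """Raised when an operation requiring R0 > 1 receives a subcritical model."""


@dataclass(frozen=True)
class GroupModel:
    """k-group SIS parameterisation (f, lam, mu, beta, gamma).

    Instances are normally produced through :func:`validate_model`, which
    checks positivity and the f-weighted scaling of ``lam`` and ``mu``.
    """

    f: np.ndarray
    lam: np.ndarray
    mu: np.ndarray
    beta: float
    gamma: float

    @property
    def k(self) -> int:
        return self.f.shape[0]

    def swap_roles(self) -> "GroupModel":
        """Model with infectivities and susceptibilities interchanged."""
        return GroupModel(f=self.f, lam=self.mu.copy(), mu=self.lam.copy(),
                          beta=self.beta, gamma=self.gamma)

    def is_homogeneous_in(self, which: str, tol: float = NORM_TOL) -> bool:
        vec = {"lam": self.lam, "mu": self.mu}[which]
        return bool(np.all(np.abs(vec - 1.0) <= max(tol, 1e-10)))


@dataclass(frozen=True)
class StagedModel:
    """Group model with an Erlang infectious period of ``s`` stages.

    Each stage is exponential with rate ``s * gamma`` so the mean infectious
    period remains ``1/gamma``; ``s = 1`` recovers the exponential model.
    """

    base: GroupModel
    s: int

    def __post_init__(self):
        if not (isinstance(self.s, (int, np.integer)) and self.s >= 1):
            raise ValidationError(f"stage count s must be a positive integer, got {self.s!r}")


@dataclass(frozen=True)
class FiniteModel:
    """Finite-population model: integer group sizes defining the Markov chain."""

    staged: StagedModel
    N: int
    N_groups: np.ndarray

    def __post_init__(self):
        f = self.staged.base.f
        if self.N_groups.shape != f.shape:
            raise ValidationError("N_groups must have one entry per group")
        if np.any(self.N_groups < 1):
            raise ValidationError("every group must contain at least one individual")
        if int(self.N_groups.sum()) != self.N:
            raise ValidationError("group sizes must sum to N")
        # largest-remainder rounding guarantees |N_i - N f_i| < 1
        if np.any(np.abs(self.N_groups - f * self.N) >= 1.0 - 1e-9):
            raise ValidationError("N_groups must match N*f to within one individual")

    @property
    def model(self) -> GroupModel:
        return self.staged.base


def _as_positive_vector(x, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise ValidationError(f"{name} must be a 1-d vector")
    if not np.all(np.isfinite(v)):
        raise ValidationError(f"{name} contains non-finite entries")
    if np.any(v <= 0):
        raise ValidationError(f"{name} must be strictly positive")
    return v


def validate_model(f, lam, mu, beta, gamma, *, normalise: bool = False,
                   tol: float = NORM_TOL) -> GroupModel:
    """Validate raw parameters, optionally rescaling to the canonical form.

    With ``normalise=True`` the vectors ``lam`` and ``mu`` are rescaled to
    unit f-weighted mean and the rescaling factors absorbed into ``beta``, so
    that every transition rate ``beta*lam_i*mu_j/N`` is unchanged.  Without
    the flag, violations of the scaling constraints raise
    :class:`ValidationError` (silent rescaling would hide typos in published
    parameter sets).
    """
    f = _as_positive_vector(f, "f")
    lam = _as_positive_vector(lam, "lam")
    mu = _as_positive_vector(mu, "mu")
    if not (lam.shape == f.shape == mu.shape):
        raise ValidationError("f, lam, mu must all have the same length k")
    beta = float(beta)
    gamma = float(gamma)
    if not (np.isfinite(beta) and beta > 0):
        raise ValidationError("beta must be a positive finite number")
    if not (np.isfinite(gamma) and gamma > 0):
        raise ValidationError("gamma must be a positive finite number")

    if abs(f.sum() - 1.0) > tol:
        if normalise:
            f = f / f.sum()
        else:
            raise ValidationError(
                f"group fractions must sum to 1 (got {f.sum()!r}); "
                "pass normalise=True to rescale")

    mean_lam = float(f @ lam)
    mean_mu = float(f @ mu)
    if abs(mean_lam - 1.0) > tol or abs(mean_mu - 1.0) > tol:
        if normalise:
            lam = lam / mean_lam
            mu = mu / mean_mu
            beta = beta * mean_lam * mean_mu
        else:
            raise ValidationError(
                "lam and mu must have f-weighted mean 1 "
                f"(got {mean_lam!r}, {mean_mu!r}); pass normalise=True to rescale")

    m = GroupModel(f=f.copy(), lam=lam.copy(), mu=mu.copy(), beta=beta, gamma=gamma)
    m.f.setflags(write=False)
    m.lam.setflags(write=False)
    m.mu.setflags(write=False)
    return m


def basic_reproduction_number(model: GroupModel) -> float:
    """R0 = (beta/gamma) * sum_i lam_i mu_i f_i (dominant eigenvalue of the
    next-generation matrix under separable mixing)."""
    return float(model.beta / model.gamma * np.sum(model.lam * model.mu * model.f))


def require_supercritical(model: GroupModel) -> float:
    r0 = basic_reproduction_number(model)
    if r0 <= 1.0:
        raise SubcriticalModelError(
            f"R0 = {r0:.6g} <= 1: endemic persistence requires a super-critical model")
    return r0


def random_model(k: int, R0_target: float, mode: str = "both",
                 seed: int | None = 0, gamma: float = 1.0,
                 spread: float = 0.5) -> GroupModel:
    """Seeded random fixture model with a prescribed basic reproduction number.

    Group fractions are Dirichlet; heterogeneous vectors are log-normal draws
    rescaled to unit f-weighted mean (``mode`` selects which of ``lam``/``mu``
    is heterogeneous); ``beta`` is then chosen so that R0 equals
    ``R0_target`` exactly, mirroring the convention of fixing R0 and letting
    the overall infection rate float.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if R0_target <= 0:
        raise ValidationError("R0_target must be positive")
    if mode not in ("infectivity", "susceptibility", "both"):
        raise ValidationError(f"unknown heterogeneity mode {mode!r}")
    rng = np.random.default_rng(seed)
    if k == 1:
        f = np.array([1.0])
        lam = np.array([1.0])
        mu = np.array([1.0])
    else:
        f = rng.dirichlet(np.full(k, 5.0))

        def draw():
            v = np.exp(rng.normal(0.0, spread, size=k))
            return v / (f @ v)

        lam = draw() if mode in ("infectivity", "both") else np.ones(k)
        mu = draw() if mode in ("susceptibility", "both") else np.ones(k)
    beta = R0_target * gamma / float(np.sum(lam * mu * f))
    return validate_model(f, lam, mu, beta, gamma, normalise=True)


def finite_model(model: GroupModel, N: int, s: int = 1) -> FiniteModel:
    """Integer group sizes by largest-remainder rounding of ``N * f``.

    Raises :class:`ValidationError` if any group would round to zero
    individuals (the finite chain then has fewer effective groups than the
    model declares).
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    target = model.f * N
    base = np.floor(target).astype(int)
    short = int(N - base.sum())
    if short > 0:
        order = np.argsort(-(target - base), kind="stable")
        base[order[:short]] += 1
    if np.any(base < 1):
        raise ValidationError(
            f"N = {N} is too small: some group rounds to zero individuals")
    return FiniteModel(staged=StagedModel(base=model, s=int(s)), N=int(N),
                       N_groups=base)
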