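"""Annealed directed configuration networks as k-group SIS models.

Individuals carry a joint (in-degree, out-degree) drawn from a finite
distribution; infection passes along each directed link at rate kappa.
Under the annealed (uncorrelated, mean-field) approximation the network
model maps onto the k-group model via

    beta  = kappa * E[d_out],        f_j   = p(d_in(j), d_out(j)),
    mu_j  = d_in(j) / E[d_in],       lam_j = d_out(j) / E[d_out],

one group per degree pair.  Partially directed networks (with undirected
edges counted by d_un) collapse onto the purely directed description by
replacing (d_in, d_out) with (d_in + d_un, d_out + d_un).

When every individual shares the same in-degree (resp. out-degree) the
persistence-time action has the explicit degree-space form A_out (resp.
A_in); these agree exactly with the explicit group-model action evaluated on
the mapped model — exact for the group-model rates, approximate for the
underlying network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import GroupModel, validate_model
from .action_formulas import action_explicit, UnsupportedConfigurationError
from .equilibria import _bracketed_root

MEAN_TOL = 1e-10


@dataclass(frozen=True)
class DegreeDistribution:
    """Finite joint (d_in, d_out) degree distribution with link rate kappa.

    The support is stored in the canonical lexicographic order in
    (d_in, d_out), making group indices stable across calls.
    """

    support: np.ndarray   # (k, 2) int: columns d_in, d_out
    probs: np.ndarray
    kappa: float
    gamma: float

    def __post_init__(self):
        support = np.asarray(self.support, dtype=np.int64).reshape(-1, 2)
        probs = np.asarray(self.probs, dtype=float)
        if support.shape[0] != probs.shape[0]:
            raise ValueError("support and probs must have matching lengths")
        if np.any(support < 0):
            raise ValueError("degrees must be nonnegative")
        if np.any(probs <= 0):
            raise ValueError("probabilities must be strictly positive")
        if abs(probs.sum() - 1.0) > MEAN_TOL:
            raise ValueError(f"probabilities must sum to 1 (got {probs.sum()!r})")
        if len({tuple(r) for r in support}) != support.shape[0]:
            raise ValueError("duplicate degree pairs in support")
        order = np.lexsort((support[:, 1], support[:, 0]))
        object.__setattr__(self, "support", support[order])
        object.__setattr__(self, "probs", probs[order])
        if abs(self.mean_in - self.mean_out) > MEAN_TOL:
            raise ValueError(
                f"stub-matching requires E[d_in] = E[d_out] "
                f"(got {self.mean_in!r} vs {self.mean_out!r})")
        if not (self.kappa > 0 and self.gamma > 0):
            raise ValueError("kappa and gamma must be positive")

    @property
    def k(self) -> int:
        return self.support.shape[0]

    @property
    def d_in(self) -> np.ndarray:
        return self.support[:, 0]

    @property
    def d_out(self) -> np.ndarray:
        return self.support[:, 1]

    @property
    def mean_in(self) -> float:
        return float(self.probs @ self.support[:, 0])

    @property
    def mean_out(self) -> float:
        return float(self.probs @ self.support[:, 1])

    def marginal(self, which: str) -> dict[int, float]:
        col = {"in": 0, "out": 1}[which]
        out: dict[int, float] = {}
        for (row, p) in zip(self.support, self.probs):
            out[int(row[col])] = out.get(int(row[col]), 0.0) + float(p)
        return out


def groups_from_degrees(dd: DegreeDistribution) -> GroupModel:
    """Map an annealed degree distribution to the k-group model.

    Groups follow the distribution's canonical (lexicographic) ordering.
    All degrees on the support must be strictly positive: a zero in- or
    out-degree would give a vanishing susceptibility or infectivity, which
    the group model excludes.
    """
    if np.any(dd.support == 0):
        raise UnsupportedConfigurationError(
            "zero in- or out-degree on the support is not representable "
            "as a group model (lam, mu must be positive)")
    beta = dd.kappa * dd.mean_out
    mu = dd.d_in / dd.mean_in
    lam = dd.d_out / dd.mean_out
    return validate_model(dd.probs, lam, mu, beta, dd.gamma)


def collapse_partially_directed(triples, probs, kappa: float, gamma: float
                                ) -> DegreeDistribution:
    """Collapse (d_in, d_out, d_un) onto (d_in + d_un, d_out + d_un),
    aggregating probabilities over triples that coincide after collapse."""
    triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    probs = np.asarray(probs, dtype=float)
    agg: dict[tuple[int, int], float] = {}
    for (din, dout, dun), p in zip(triples, probs):
        key = (int(din + dun), int(dout + dun))
        agg[key] = agg.get(key, 0.0) + float(p)
    support = np.array(sorted(agg), dtype=np.int64)
    return DegreeDistribution(support=support,
                              probs=np.array([agg[tuple(s)] for s in support]),
                              kappa=kappa, gamma=gamma)


def _degree_action(marginal: dict[int, float], kappa: float, gamma: float
                   ) -> float:
    """A = sum_i P(d=i) ln(1 + i D) - (gamma/kappa) D with D solving
    (kappa/gamma) sum_j j P(d=j) / (1 + j D) = 1."""
    degrees = np.array(sorted(marginal), dtype=float)
    p = np.array([marginal[int(d)] for d in degrees])
    r = kappa / gamma
    if r * float(degrees @ p) <= 1.0:
        raise ValueError(
            "subcritical network: kappa/gamma * E[d] must exceed 1")
    D = _bracketed_root(lambda d: r * np.sum(degrees * p / (1.0 + degrees * d)),
                        "D_degree")
    return float(np.sum(p * np.log1p(degrees * D)) - D / r)


def _require_constant(marginal: dict[int, float], name: str):
    if len(marginal) != 1:
        raise UnsupportedConfigurationError(
            f"this formula requires a constant {name}-degree "
            f"(got support {sorted(marginal)})")


def action_out(dd: DegreeDistribution) -> float:
    """Persistence-time action for constant in-degree (heterogeneous
    out-degree; exponential infectious periods)."""
    _require_constant(dd.marginal("in"), "in")
    return _degree_action(dd.marginal("out"), dd.kappa, dd.gamma)


def action_in(dd: DegreeDistribution) -> float:
    """Persistence-time action for constant out-degree (heterogeneous
    in-degree; valid for exponential or Erlang infectious periods)."""
    _require_constant(dd.marginal("out"), "out")
    return _degree_action(dd.marginal("in"), dd.kappa, dd.gamma)
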