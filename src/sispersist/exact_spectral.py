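"""Exact mean persistence time via the quasi-stationary eigenvalue problem.

The finite-population process is a continuous-time Markov chain on counts of
infectives per group (and per Erlang stage).  The disease-free state is
absorbing and the remaining states form a single transient communicating
class C; restricting the generator to C gives Q_C, and the quasi-stationary
distribution q is the left Perron-type eigenvector

    q Q_C = -(1/tau) q,   sum q = 1,

where -(1/tau) is the eigenvalue of largest real part and tau is the mean
time to extinction starting from quasi-stationarity (the extinction time is
then exactly exponential with mean tau).

State indexing is mixed-radix: each group (with its stages) is enumerated
locally, the global index is the little-endian mixed-radix composition of
per-group local indices, and the absorbing all-zero state (global index 0)
is dropped, so transient state i corresponds to full-product index i + 1.
The indexing is stable and documented so serialised q vectors can be decoded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import eig

from .model_core import FiniteModel

#: refuse to build state spaces larger than this (override per call)
DEFAULT_STATE_CAP = 2_000_000

#: dense eigensolve below this size, sparse shift-invert above
DENSE_LIMIT = 2000


class StateSpaceTooLargeError(ValueError):
    def __init__(self, n_states: int, cap: int):
        super().__init__(
            f"transient class has {n_states} states, exceeding the cap {cap}")
        self.n_states = n_states


@dataclass(frozen=True)
class ExactResult:
    tau: float
    q: np.ndarray
    N: int
    log_tau_over_N: float
    diagnostics: dict


@dataclass(frozen=True)
class StateSpace:
    """Enumeration of the transient class C.

    ``local_states[j]`` lists group j's stage-count tuples (sum <= N_j), the
    all-susceptible tuple first; ``radix[j]`` is the mixed-radix place value
    of group j's local index in the full product space.  ``n_states`` counts
    transient states (product of local sizes minus the absorbing state).
    """

    fm: FiniteModel
    local_states: list[np.ndarray]      # per group: (n_j, s) int arrays
    sizes: np.ndarray
    radix: np.ndarray
    n_states: int

    def decode(self, idx: np.ndarray) -> np.ndarray:
        """Transient indices -> (len(idx), k, s) stage-count arrays."""
        idx = np.atleast_1d(np.asarray(idx, dtype=np.int64)) + 1
        k = self.fm.model.k
        s = self.fm.staged.s
        out = np.empty((idx.size, k, s), dtype=np.int64)
        for j in range(k):
            lid = (idx // self.radix[j]) % self.sizes[j]
            out[:, j, :] = self.local_states[j][lid]
        return out

    def encode(self, counts) -> np.ndarray:
        """(n, k, s) stage-count arrays -> transient indices (absorbing -> -1)."""
        counts = np.asarray(counts, dtype=np.int64)
        single = counts.ndim == 2
        if single:
            counts = counts[None]
        k = self.fm.model.k
        full = np.zeros(counts.shape[0], dtype=np.int64)
        for j in range(k):
            lut = {tuple(row): i for i, row in enumerate(self.local_states[j])}
            lids = np.array([lut[tuple(c)] for c in counts[:, j, :]], dtype=np.int64)
            full += lids * self.radix[j]
        out = full - 1
        return out[0] if single else out


def _local_states(N_j: int, s: int) -> np.ndarray:
    """All stage-count tuples (I_1..I_s) with sum <= N_j, all-zero first."""
    if s == 1:
        return np.arange(N_j + 1, dtype=np.int64)[:, None]
    states = [t for t in product(range(N_j + 1), repeat=s) if sum(t) <= N_j]
    states.sort(key=lambda t: (sum(t), t))
    return np.asarray(states, dtype=np.int64)


def enumerate_states(fm: FiniteModel, cap: int = DEFAULT_STATE_CAP) -> StateSpace:
    """Bijection between transient states and indices 0..|C|-1."""
    k = fm.model.k
    s = fm.staged.s
    local = [_local_states(int(nj), s) for nj in fm.N_groups]
    sizes = np.array([len(ls) for ls in local], dtype=np.int64)
    n_full = int(np.prod(sizes))
    n_states = n_full - 1
    if n_states > cap:
        raise StateSpaceTooLargeError(n_states, cap)
    radix = np.ones(k, dtype=np.int64)
    for j in range(1, k):
        radix[j] = radix[j - 1] * sizes[j - 1]
    return StateSpace(fm=fm, local_states=local, sizes=sizes, radix=radix,
                      n_states=n_states)


def build_rate_matrix(space: StateSpace) -> sp.csr_matrix:
    """Generator Q_C restricted to the transient class (CSR, row = from-state).

    Off-diagonals are the infection, stage-advance and recovery rates; the
    diagonal carries minus the total outflow including flow into the
    absorbing state, so row sums are <= 0 with strict inequality for states
    one recovery away from extinction.
    """
    fm = space.fm
    model = fm.model
    k, s = model.k, fm.staged.s
    beta, gamma = model.beta, model.gamma
    lam, mu = model.lam, model.mu
    N = fm.N
    Ng = fm.N_groups

    n = space.n_states
    full_idx = np.arange(1, n + 1, dtype=np.int64)

    # per-group local ids and local lookups
    lids = [(full_idx // space.radix[j]) % space.sizes[j] for j in range(k)]
    lut = []
    for j in range(k):
        d = {tuple(row): i for i, row in enumerate(space.local_states[j])}
        lut.append(d)

    def local_shift(j, delta):
        """Local transition table for group j: lid -> new lid (or -1)."""
        table = np.full(space.sizes[j], -1, dtype=np.int64)
        for i, row in enumerate(space.local_states[j]):
            new = row + delta
            if new.min() >= 0 and new.sum() <= Ng[j]:
                table[i] = lut[j][tuple(new)]
        return table

    # per-group totals of infectives and stage-s counts, per local state
    tot = [space.local_states[j].sum(axis=1) for j in range(k)]
    last = [space.local_states[j][:, -1] for j in range(k)]

    force = np.zeros(n)          # sum_m lam_m I_m
    for j in range(k):
        force += lam[j] * tot[j][lids[j]]

    rows, cols, vals = [], [], []
    out_total = np.zeros(n)

    def push(rates, targets_full):
        mask = rates > 0
        keep = mask & (targets_full > 0)        # drop flow into absorbing state
        rows.append(np.nonzero(keep)[0])
        cols.append(targets_full[keep] - 1)
        vals.append(rates[keep])
        out_total[mask] += rates[mask]

    for j in range(k):
        lid_j = lids[j]
        # infection in group j: I_{j1} += 1
        delta = np.zeros(s, dtype=np.int64); delta[0] = 1
        tgt = local_shift(j, delta)[lid_j]
        susc = Ng[j] - tot[j][lid_j]
        rates = np.where(tgt >= 0, beta / N * force * mu[j] * susc, 0.0)
        push(rates, full_idx + (tgt - lid_j) * space.radix[j])
        # stage advance v-1 -> v
        for v in range(1, s):
            delta = np.zeros(s, dtype=np.int64); delta[v - 1] = -1; delta[v] = 1
            tgt = local_shift(j, delta)[lid_j]
            rates = np.where(tgt >= 0,
                             s * gamma * space.local_states[j][lid_j, v - 1], 0.0)
            push(rates, full_idx + (tgt - lid_j) * space.radix[j])
        # recovery from the final stage
        delta = np.zeros(s, dtype=np.int64); delta[-1] = -1
        tgt = local_shift(j, delta)[lid_j]
        rates = np.where(tgt >= 0, s * gamma * last[j][lid_j], 0.0)
        push(rates, full_idx + (tgt - lid_j) * space.radix[j])

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    diag = np.arange(n, dtype=np.int64)
    Q = sp.coo_matrix(
        (np.concatenate([vals, -out_total]),
         (np.concatenate([rows, diag]), np.concatenate([cols, diag]))),
        shape=(n, n)).tocsr()
    return Q


def _leading_left_eigenpair(Q: sp.csr_matrix) -> tuple[float, np.ndarray]:
    """Eigenvalue of Q with largest real part and its left eigenvector."""
    n = Q.shape[0]
    if n <= DENSE_LIMIT:
        vals, vecs = eig(Q.toarray().T)
        i = int(np.argmax(vals.real))
        return float(vals[i].real), vecs[:, i].real
    # the sought eigenvalue -(1/tau) is the closest to zero: shift-invert at 0
    try:
        vals, vecs = spla.eigs(Q.T.tocsc(), k=1, sigma=0.0, which="LM")
    except Exception:
        vals, vecs = spla.eigs(Q.T.tocsc(), k=1, sigma=-1e-8, which="LM")
    return float(vals[0].real), vecs[:, 0].real


def mean_persistence_time(fm: FiniteModel, cap: int = DEFAULT_STATE_CAP,
                          residual_tol: float = 1e-8) -> ExactResult:
    """Exact tau and quasi-stationary distribution for a finite model."""
    space = enumerate_states(fm, cap=cap)
    Q = build_rate_matrix(space)
    val, q = _leading_left_eigenpair(Q)
    if val >= 0:
        raise RuntimeError("leading eigenvalue is nonnegative; generator is invalid")
    q = q / q.sum()                     # Perron vector: sign-fix then normalise
    if np.any(q < 0):
        if np.min(q) < -1e-10:
            raise RuntimeError("quasi-stationary eigenvector changes sign")
        q = np.clip(q, 0.0, None)
        q = q / q.sum()
    tau = -1.0 / val
    residual = float(np.max(np.abs(q @ Q - val * q)))
    return ExactResult(
        tau=tau, q=q, N=fm.N, log_tau_over_N=float(np.log(tau) / fm.N),
        diagnostics={"eigenvalue": val, "residual_max": residual,
                     "n_states": space.n_states,
                     "residual_ok": residual <= residual_tol})


def finite_size_action_estimate(tau_1: float, N_1: int,
                                tau_2: float, N_2: int) -> float:
    """Two-point action estimate under tau ~ (C/sqrt(N)) e^{A N}:

        A ~ (ln(tau_2 sqrt(N_2)) - ln(tau_1 sqrt(N_1))) / (N_2 - N_1).
    """
    if N_2 == N_1:
        raise ValueError("the two population sizes must differ")
    if tau_1 <= 0 or tau_2 <= 0:
        raise ValueError("persistence times must be positive")
    return float((np.log(tau_2 * np.sqrt(N_2)) - np.log(tau_1 * np.sqrt(N_1)))
                 / (N_2 - N_1))
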