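"""Sequence-to-structure alignment through a hidden Markov model.

Each predicted C-alpha atom becomes a hidden state.  Transition
probabilities between states derive from their Euclidean distance through a
Gaussian density centered on the adjacent C-alpha spacing (mean mu =
3.8047 A, sigma = 0.036 A) widened by a scale factor Lambda (default 10):

    f(x) = 1 / (Lambda sigma sqrt(2 pi)) * exp(-(x - mu)^2 / (2 (Lambda sigma)^2))

rows are normalized over all other states (no self transitions).  Emission
probabilities over the 20 amino-acid symbols are the per-state normalized
geometric mean sqrt(a * b) of the predicted amino-acid probabilities ``a``
and background frequencies ``b``.  The initial distribution is built per
chain from the emission column of the chain's first residue.

Chains are decoded one at a time by a customized Viterbi algorithm in which
a hidden state may occur at most once: after each observation column the
column argmax is committed and excluded from the rest of the decode, and
the returned path follows the committed sequence, which guarantees a simple
(repeat-free) path.  States used by a chain are removed from the model
before the next chain is aligned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .ca_extraction import CaAtomSet
from .constants import (AA_INDEX, CA_CA_MEAN, CA_CA_SIGMA, LAMBDA_SCALE,
                        background_frequencies)
from .io_formats import ChainSequenceSet, Residue, StructureModel

log = logging.getLogger(__name__)

NEG_INF = -np.inf


class InfeasibleAlignmentError(RuntimeError):
    """Fewer available states than residues to place."""


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def pairwise_distance(p, q) -> float:
    """Euclidean distance between two points in Angstrom."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sqrt(((p - q) ** 2).sum()))


def gaussian_transition_density(x, mu: float = CA_CA_MEAN,
                                sigma: float = CA_CA_SIGMA,
                                lambda_scale: float = LAMBDA_SCALE):
    """Scaled Gaussian PDF with effective standard deviation Lambda*sigma."""
    if sigma <= 0 or lambda_scale <= 0:
        raise ValueError("sigma and lambda_scale must be positive")
    s = lambda_scale * sigma
    x = np.asarray(x, dtype=float)
    out = np.exp(-((x - mu) ** 2) / (2.0 * s * s)) / (s * np.sqrt(2 * np.pi))
    return float(out) if out.ndim == 0 else out


def _log_gaussian(x: np.ndarray, mu: float, sigma: float,
                  lambda_scale: float) -> np.ndarray:
    s = lambda_scale * sigma
    return -((x - mu) ** 2) / (2.0 * s * s) - np.log(s * np.sqrt(2 * np.pi))


@dataclass
class HmmParameters:
    """lambda = (gamma, delta, Pi) over K states and 20 symbols.

    Matrices are kept in natural-log space (``log_gamma``, ``log_delta``);
    the linear-space stochastic matrices are recoverable via properties.
    ``Pi`` is built per chain (see :func:`build_initial`) and not stored.
    """

    coords: np.ndarray  # (K, 3) state coordinates, Angstrom
    log_gamma: np.ndarray  # (K, K), diagonal -inf
    log_delta: np.ndarray  # (K, 20)
    ca_probs: np.ndarray  # (K,) classifier C-alpha probability per state
    mu: float = CA_CA_MEAN
    sigma: float = CA_CA_SIGMA
    lambda_scale: float = LAMBDA_SCALE
    background: np.ndarray = field(default_factory=background_frequencies)

    @property
    def n_states(self) -> int:
        return self.coords.shape[0]

    @property
    def gamma(self) -> np.ndarray:
        g = np.exp(self.log_gamma)
        g[np.isneginf(self.log_gamma)] = 0.0
        return g

    @property
    def delta(self) -> np.ndarray:
        return np.exp(self.log_delta)

    def to_json(self, path) -> None:
        """Debug dump for small K."""
        with open(path, "w") as fh:
            json.dump({"coords": self.coords.tolist(),
                       "gamma": self.gamma.tolist(),
                       "delta": self.delta.tolist(),
                       "mu": self.mu, "sigma": self.sigma,
                       "lambda_scale": self.lambda_scale,
                       "background": self.background.tolist()}, fh)


def build_transition(coords: np.ndarray, mu: float = CA_CA_MEAN,
                     sigma: float = CA_CA_SIGMA,
                     lambda_scale: float = LAMBDA_SCALE) -> np.ndarray:
    """Log transition matrix: rows are distance densities, normalized.

    Computed and normalized entirely in log space so that rows whose
    densities underflow in linear space still normalize to finite values.
    """
    if sigma <= 0 or lambda_scale <= 0:
        raise ValueError("sigma and lambda_scale must be positive")
    coords = np.asarray(coords, dtype=float)
    k = coords.shape[0]
    if k < 2:
        return np.full((k, k), NEG_INF)
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    logf = _log_gaussian(d, mu, sigma, lambda_scale)
    np.fill_diagonal(logf, NEG_INF)  # no self transitions
    return logf - logsumexp(logf, axis=1, keepdims=True)


def build_emission(aa_probs: np.ndarray,
                   background: np.ndarray | None = None) -> np.ndarray:
    """Log emission matrix: normalized geometric mean sqrt(a*b) per state."""
    a = np.asarray(aa_probs, dtype=float)
    b = background_frequencies() if background is None else \
        np.asarray(background, dtype=float)
    if a.shape[1] != 20 or b.shape != (20,):
        raise ValueError("need 20 amino-acid probabilities per state")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("negative probabilities")
    if not np.isclose(b.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    g = np.sqrt(a * b[None, :])
    sums = g.sum(axis=1, keepdims=True)
    dead = sums[:, 0] == 0
    if dead.any():
        log.warning("%d state(s) with all-zero emission; using uniform",
                    int(dead.sum()))
        g[dead] = 1.0 / 20.0
        sums = g.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        return np.log(g / sums)


def build_initial(log_delta: np.ndarray, first_symbol: str,
                  available: np.ndarray | None = None) -> np.ndarray:
    """Log initial distribution from the emission column of ``first_symbol``.

    Restricted and renormalized over ``available`` state indices when given.
    """
    col = log_delta[:, AA_INDEX[first_symbol]].copy()
    if available is not None:
        mask = np.full(col.shape, True)
        mask[available] = False
        col[mask] = NEG_INF
    z = logsumexp(col)
    if np.isneginf(z):
        log.warning("all-zero emission column for %r; uniform initial "
                    "distribution", first_symbol)
        col = np.full(len(col), NEG_INF)
        idx = np.arange(len(col)) if available is None else available
        col[idx] = 0.0
        z = logsumexp(col)
    return col - z


def build_hmm(atoms: CaAtomSet, mu: float = CA_CA_MEAN,
              sigma: float = CA_CA_SIGMA,
              lambda_scale: float = LAMBDA_SCALE,
              background: np.ndarray | None = None) -> HmmParameters:
    """Assemble HMM parameters from clustered C-alpha atoms."""
    if len(atoms) == 0:
        raise ValueError("no predicted C-alpha atoms to build an HMM from")
    b = background_frequencies() if background is None else \
        np.asarray(background, dtype=float)
    coords = atoms.coordinates()
    return HmmParameters(
        coords=coords,
        log_gamma=build_transition(coords, mu, sigma, lambda_scale),
        log_delta=build_emission(atoms.aa_prob_matrix(), b),
        ca_probs=atoms.ca_probs(),
        mu=mu, sigma=sigma, lambda_scale=lambda_scale, background=b)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _argmax_unblocked(values: np.ndarray, blocked: np.ndarray) -> int:
    """Argmax restricted to unblocked indices (ties -> lowest index)."""
    idx = np.flatnonzero(~blocked)
    return int(idx[np.argmax(values[idx])])


@dataclass
class AlignmentResult:
    """One chain's decoded path through the HMM."""

    chain_id: str
    sequence: str
    path: np.ndarray  # (T,) global state indices, all distinct
    emission_probs: np.ndarray  # (T,) linear-space delta at each position
    log_prob: float  # joint log probability of the decoded path
    t1: np.ndarray | None = None  # (K_avail, T) score table
    t2: np.ndarray | None = None  # (K_avail, T) backpointer table
    visited_states: np.ndarray | None = None  # committed column argmaxes


def modified_viterbi(params: HmmParameters, sequence: str,
                     available: np.ndarray | None = None,
                     chain_id: str = "A",
                     keep_tables: bool = False) -> AlignmentResult:
    """Decode one chain with the no-repeat (greedy-commit) Viterbi variant.

    Forward pass: at each observation column the update runs over states
    not yet committed; after the column, its argmax is committed and
    excluded from all later columns.  Traceback follows the backpointer
    table from the final column's argmax; whenever a backpointer would
    revisit a state already on the path, the best not-yet-used predecessor
    is substituted, which makes the no-repeat property structural.
    Transition rows and the initial distribution are renormalized over
    ``available`` states.
    """
    t_len = len(sequence)
    k_all = params.n_states
    if available is None:
        available = np.arange(k_all)
    else:
        available = np.asarray(available, dtype=int)
    k = len(available)
    if k < t_len:
        raise InfeasibleAlignmentError(
            f"chain {chain_id!r}: {t_len} residues but only {k} available "
            "C-alpha states; lower the C-alpha probability threshold to "
            "obtain more candidate atoms")
    obs = np.array([AA_INDEX[c] for c in sequence])

    # restrict + renormalize over the available subset (log space)
    log_delta = params.log_delta[available]  # (k, 20)
    if k > 1:
        lg = params.log_gamma[np.ix_(available, available)]
        lg = lg - logsumexp(lg, axis=1, keepdims=True)
    else:
        lg = np.full((1, 1), NEG_INF)
    log_pi = build_initial(params.log_delta, sequence[0], available)[available]

    t1 = np.full((k, t_len), NEG_INF)
    t2 = np.zeros((k, t_len), dtype=int)
    t1[:, 0] = log_pi + log_delta[:, obs[0]]
    committed: list[int] = []
    blocked = np.zeros(k, dtype=bool)
    for j in range(1, t_len):
        scores = t1[:, j - 1][:, None] + lg  # (k_from, k_to)
        best_from = np.argmax(scores, axis=0)
        t1[:, j] = scores[best_from, np.arange(k)] + log_delta[:, obs[j]]
        t2[:, j] = best_from
        t1[blocked, j] = NEG_INF
        z = _argmax_unblocked(t1[:, j], blocked)
        committed.append(z)
        blocked[z] = True

    path_rev = [int(np.argmax(t1[:, t_len - 1]))]
    used = np.zeros(k, dtype=bool)
    used[path_rev[0]] = True
    for j in range(t_len - 1, 0, -1):
        prev = int(t2[path_rev[-1], j])
        if used[prev]:
            # backpointer collides with a state already on the path;
            # take the best unused predecessor of the current state
            cand = t1[:, j - 1] + lg[:, path_rev[-1]]
            prev = _argmax_unblocked(cand, used)
        used[prev] = True
        path_rev.append(prev)
    path_local = np.asarray(path_rev[::-1])
    if len(set(path_local.tolist())) != t_len:
        raise AssertionError("decoded path repeats a state")
    # joint log probability of the returned path
    lp = log_pi[path_local[0]] + log_delta[path_local[0], obs[0]]
    for j in range(1, t_len):
        lp += lg[path_local[j - 1], path_local[j]] + \
            log_delta[path_local[j], obs[j]]
    emission = np.exp(log_delta[path_local, obs])
    return AlignmentResult(
        chain_id=chain_id, sequence=sequence,
        path=available[path_local],
        emission_probs=emission,
        log_prob=float(lp),
        t1=t1 if keep_tables else None,
        t2=t2 if keep_tables else None,
        visited_states=available[np.asarray(committed, dtype=int)]
        if keep_tables else None)


def align_all_chains(params: HmmParameters,
                     chains: ChainSequenceSet) -> list[AlignmentResult]:
    """Align every chain, longest first, removing used states in between.

    Results are returned in the original chain input order.  A state can
    appear in at most one chain's path.
    """
    if chains.total_residues > params.n_states:
        raise InfeasibleAlignmentError(
            f"{chains.total_residues} total residues exceed "
            f"{params.n_states} C-alpha states; lower the C-alpha "
            "probability threshold")
    order = sorted(range(len(chains.chains)),
                   key=lambda i: (-len(chains.chains[i][1]), i))
    available = np.arange(params.n_states)
    results: dict[int, AlignmentResult] = {}
    for i in order:
        cid, seq = chains.chains[i]
        res = modified_viterbi(params, seq, available=available,
                               chain_id=cid)
        results[i] = res
        available = available[~np.isin(available, res.path)]
    all_states = np.concatenate([results[i].path
                                 for i in range(len(results))])
    assert len(np.unique(all_states)) == len(all_states), \
        "state reused across chains"
    return [results[i] for i in range(len(chains.chains))]


def paths_to_structure(results: list[AlignmentResult], atoms: CaAtomSet,
                       chains: ChainSequenceSet) -> StructureModel:
    """Materialize decoded paths into a C-alpha structure model.

    Until logistic confidence models are applied, ``ca_confidence`` holds
    the source atom's classifier probability and ``aa_confidence`` the HMM
    emission probability used at the position.
    """
    model = StructureModel()
    by_id = {r.chain_id: r for r in results}
    for cid, seq in chains.chains:
        res = by_id[cid]
        residues = []
        for pos, (state, aa) in enumerate(zip(res.path, seq)):
            atom = atoms.atoms[state]
            residues.append(Residue(
                coord=atom.coord.copy(), aa=aa,
                ca_confidence=float(atom.ca_prob),
                aa_confidence=float(res.emission_probs[pos]),
                ca_prob=float(atom.ca_prob),
                emission_prob=float(res.emission_probs[pos])))
        model.chains.append((cid, residues))
    return model
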