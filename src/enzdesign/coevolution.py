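"""Potts-model co-evolution inference by regularized pseudolikelihood.

The model is a pairwise Markov random field over alignment columns with the
gap treated as an ordinary state.  Fitting minimizes the sequence-weighted
negative log-pseudolikelihood plus L2 penalties; the objective is convex, so
the deterministic quasi-Newton fit from zero initialization is reproducible.
Coupling strengths are summarized as Frobenius norms of the non-gap coupling
blocks after a zero-sum gauge change, followed by the average product
correction (APC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from enzdesign.alphabet import AA21, GAP
from enzdesign.conservation import Alignment, SequenceWeights, compute_weights
from enzdesign.errors import InputError, ParameterError

logger = logging.getLogger(__name__)


@dataclass
class PottsModel:
    """Fields and pairwise couplings over alignment columns.

    ``h`` is (L, q); ``J`` is the full (L, L, q, q) tensor with
    ``J[i, j] == J[j, i].T`` and zero diagonal blocks.  ``alphabet`` maps
    state indices to characters (gap last when present).
    """

    alphabet: str
    h: np.ndarray
    J: np.ndarray
    lambda_h: float
    lambda_J: float
    converged: bool = True
    grad_norm: float = 0.0

    @property
    def L(self) -> int:
        return int(self.h.shape[0])

    @property
    def q(self) -> int:
        return int(self.h.shape[1])

    def coupling(self, i: int, j: int) -> np.ndarray:
        """The (q, q) coupling block for ordered positions (i, j), 0-based."""
        return self.J[i, j]


@dataclass
class CouplingScores:
    """Raw (``S``) and APC-corrected (``S_apc``) coupling strength matrices."""

    S: np.ndarray
    S_apc: np.ndarray

    def __post_init__(self) -> None:
        for m in (self.S, self.S_apc):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise InputError("score matrices must be square")
        if (self.S < -1e-12).any():
            raise InputError("raw scores must be non-negative")


class PairScore(NamedTuple):
    i: int  # 1-based
    j: int  # 1-based, i < j
    score: float


class CoevolvedSubstitution(NamedTuple):
    position: int  # 1-based
    from_residue: str
    to_residue: str
    partner_position: int  # 1-based
    coupling_gain: float


def _one_hot(enc: np.ndarray, q: int) -> np.ndarray:
    N, L = enc.shape
    X = np.zeros((N, L * q))
    X[np.arange(N)[:, None], np.arange(L) * q + enc] = 1.0
    return X


def _diag_block_mask(L: int, q: int) -> np.ndarray:
    mask = np.zeros((L * q, L * q), dtype=bool)
    for i in range(L):
        mask[i * q : (i + 1) * q, i * q : (i + 1) * q] = True
    return mask


def fit_potts(
    aln: Alignment,
    w: SequenceWeights | None = None,
    lambda_h: float = 0.01,
    lambda_J: float | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
    alphabet: str | None = None,
) -> PottsModel:
    """Fit fields and couplings by weighted, L2-regularized pseudolikelihood.

    The objective (averaged over effective sequences) is::

        f = [ sum_s w_s sum_i -log P(x_i^s | x_-i^s)
              + lambda_h ||h||^2 + lambda_J ||J||^2 ] / neff

    with ``lambda_J`` defaulting to ``0.2 * (L - 1)``.  ``alphabet`` defaults
    to the 21-state amino-acid alphabet; a reduced alphabet may be supplied
    for projected test models.
    """
    if aln.L < 2:
        raise InputError("need at least 2 columns to fit couplings")
    if alphabet is None:
        alphabet = AA21
    if w is None:
        w = compute_weights(aln)
    if w.neff <= 0:
        raise InputError("neff must be positive")
    if lambda_J is None:
        lambda_J = 0.2 * (aln.L - 1)
    if lambda_h < 0 or lambda_J < 0:
        raise ParameterError("regularization strengths must be non-negative")

    enc = aln.encoded(alphabet)
    L, q = aln.L, len(alphabet)
    N = aln.N
    Lq = L * q
    X = _one_hot(enc, q)
    weights = np.asarray(w.weights, dtype=float)
    neff = w.neff
    diag_mask = _diag_block_mask(L, q)
    row_idx = np.arange(N)[:, None]
    col_idx = np.arange(L) * q

    def unpack(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = theta[:Lq].reshape(L, q)
        Jm = theta[Lq:].reshape(Lq, Lq)
        Jm = 0.5 * (Jm + Jm.T)
        Jm[diag_mask] = 0.0
        return h, Jm

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        h, Jm = unpack(theta)
        logits = (X @ Jm).reshape(N, L, q) + h[None]
        lse = logsumexp(logits, axis=2)
        picked = logits[row_idx, np.arange(L)[None, :], enc]
        nll = float((weights * (lse - picked).sum(axis=1)).sum())
        f = (nll + lambda_h * (h**2).sum() + lambda_J * (Jm**2).sum()) / neff

        P = softmax(logits, axis=2)
        D = (P - (X.reshape(N, L, q))) * weights[:, None, None]
        grad_h = (D.sum(axis=0) + 2.0 * lambda_h * h) / neff
        Dflat = D.reshape(N, Lq)
        # J[(j,b),(i,a)] feeds site i's conditional and its transpose feeds
        # site j's; the symmetric projection below accounts for both.
        G = X.T @ Dflat
        G = 0.5 * (G + G.T) + 2.0 * lambda_J * Jm
        G[diag_mask] = 0.0
        G /= neff
        return f, np.concatenate([grad_h.ravel(), G.ravel()])

    theta0 = np.zeros(Lq + Lq * Lq)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol, "ftol": 1e-12, "maxcor": 20},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    converged = bool(grad_norm < tol or res.success)
    if not converged:
        logger.warning(
            "pseudolikelihood fit stopped before convergence: max|grad|=%.3e after %d iters",
            grad_norm,
            res.nit,
        )
    h, Jm = unpack(res.x)
    J = Jm.reshape(L, q, L, q).transpose(0, 2, 1, 3)
    return PottsModel(
        alphabet=alphabet,
        h=h,
        J=J,
        lambda_h=float(lambda_h),
        lambda_J=float(lambda_J),
        converged=converged,
        grad_norm=grad_norm,
    )


def _zero_sum_gauge(block: np.ndarray) -> np.ndarray:
    rm = block.mean(axis=1, keepdims=True)
    cm = block.mean(axis=0, keepdims=True)
    return block - rm - cm + block.mean()


def apply_apc(S: np.ndarray) -> np.ndarray:
    """Average product correction of a symmetric zero-diagonal score matrix."""
    L = S.shape[0]
    if L < 2:
        return np.zeros_like(S)
    row_mean = S.sum(axis=1) / (L - 1)
    total_mean = S.sum() / (L * (L - 1))
    apc = S - np.outer(row_mean, row_mean) / total_mean if total_mean != 0 else S.copy()
    np.fill_diagonal(apc, 0.0)
    return apc


def coupling_scores(model: PottsModel) -> CouplingScores:
    """Frobenius norms of gauge-fixed non-gap coupling blocks, plus APC.

    The zero-sum gauge is applied to each pair's non-gap sub-block before
    taking the norm; the APC subtracts ``mean_i * mean_j / mean`` computed
    over off-diagonal entries.
    """
    L, q = model.L, model.q
    if GAP in model.alphabet:
        keep = [k for k, ch in enumerate(model.alphabet) if ch != GAP]
    else:
        keep = list(range(q))
    keep = np.asarray(keep)
    S = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            block = model.J[i, j][np.ix_(keep, keep)]
            S[i, j] = S[j, i] = float(np.linalg.norm(_zero_sum_gauge(block)))
    return CouplingScores(S=S, S_apc=apply_apc(S))


def top_pairs(scores: CouplingScores, k: int) -> list[PairScore]:
    """The k highest APC-corrected pairs (1-based, i < j), descending.

    Ties are broken by (i, j) lexicographic order.  Asking for more pairs
    than exist returns all of them with a warning.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    L = scores.S_apc.shape[0]
    pairs = [
        PairScore(i + 1, j + 1, float(scores.S_apc[i, j]))
        for i in range(L)
        for j in range(i + 1, L)
    ]
    n_pairs = len(pairs)
    if k > n_pairs:
        logger.warning("requested %d pairs but only %d exist; returning all", k, n_pairs)
        k = n_pairs
    pairs.sort(key=lambda p: (-p.score, p.i, p.j))
    return pairs[:k]


def coevolved_substitutions(
    model: PottsModel,
    scores: CouplingScores,
    target: str,
    k_pairs: int | None = None,
) -> list[CoevolvedSubstitution]:
    """Beneficial single substitutions implied by the top co-evolving pairs.

    For each top pair (i, j) the residue ``a`` maximizing
    ``J_ij(a, target[j]) + h_i(a)`` is proposed at i when it differs from the
    target residue and the objective gain over the target residue is
    positive.  Output is sorted by descending gain, ties by (position,
    residue).  ``k_pairs`` defaults to ``1.5 * L`` rounded.
    """
    if len(target) != model.L:
        raise InputError(f"target length {len(target)} != model length {model.L}")
    if k_pairs is None:
        k_pairs = max(1, round(1.5 * model.L))
    alpha = model.alphabet
    non_gap = [k for k, ch in enumerate(alpha) if ch != GAP]
    try:
        t_idx = [alpha.index(ch) for ch in target]
    except ValueError as exc:
        raise InputError(f"target residue outside model alphabet {alpha!r}") from exc

    out: list[CoevolvedSubstitution] = []
    seen: set[tuple[int, str]] = set()
    for pair in top_pairs(scores, k_pairs):
        i, j = pair.i - 1, pair.j - 1
        ti, tj = t_idx[i], t_idx[j]
        vals = model.J[i, j][:, tj] + model.h[i]
        best = max(non_gap, key=lambda a: (vals[a], -a))
        gain = float(vals[best] - vals[ti])
        if best != ti and gain > 0 and (i, alpha[best]) not in seen:
            seen.add((i, alpha[best]))
            out.append(
                CoevolvedSubstitution(i + 1, target[i], alpha[best], j + 1, gain)
            )
    out.sort(key=lambda r: (-r.coupling_gain, r.position, r.to_residue))
    return out


def write_couplings_tsv(scores: CouplingScores, path: str) -> None:
    """TSV of all pairs: i, j (1-based, i < j), raw and APC scores."""
    L = scores.S.shape[0]
    with open(path, "w") as fh:
        fh.write("i\tj\traw\tapc\n")
        for i in range(L):
            for j in range(i + 1, L):
                fh.write(f"{i + 1}\t{j + 1}\t{scores.S[i, j]:.6f}\t{scores.S_apc[i, j]:.6f}\n")
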