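"""Per-element rate-of-evolution estimation on a neutral phylogeny.

The neutral model is a rooted tree with branch lengths in expected
substitutions/site plus a time-reversible 4x4 substitution generator and
its equilibrium base frequencies.  An element's rate of evolution is the
single constant ``rho`` multiplying every branch length that maximises the
likelihood of the element's alignment under the model (Felsenstein pruning
with transition matrices ``expm(rho * t * Q)``).  ``rho < 1`` indicates
constraint relative to the neutral rate.

Gap and unknown characters are treated as fully ambiguous (marginalised),
not as a fifth state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize_scalar

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

RHO_BOUNDS = (0.0, 4.0)
RHO_XTOL = 1e-6


def _base_likelihood(char: str) -> np.ndarray:
    """Partial likelihood vector for one observed character."""
    i = _BASE_INDEX.get(char.upper())
    if i is None:  # gap / N / anything else: fully ambiguous
        return np.ones(4)
    v = np.zeros(4)
    v[i] = 1.0
    return v


def build_gtr_rate_matrix(
    exchangeabilities: Sequence[float], eq_freqs: Sequence[float]
) -> np.ndarray:
    """Time-reversible generator from 6 exchangeabilities (AC, AG, AT, CG,
    CT, GT order) and equilibrium frequencies, scaled to one expected
    substitution per unit branch length."""
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(eq_freqs, dtype=float)
    if s.shape != (6,) or np.any(s <= 0):
        raise ValueError("need 6 positive exchangeabilities")
    if pi.shape != (4,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("equilibrium frequencies must be positive and sum to 1")
    Q = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for rate, (i, j) in zip(s, pairs):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.dot(pi, np.diag(Q))  # expected rate
    return Q / mu


@dataclass
class PhyloModel:
    """Neutral phylogeny plus time-reversible substitution model."""

    tree: dendropy.Tree
    rate_matrix: np.ndarray
    eq_freqs: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.rate_matrix, dtype=float)
        pi = np.asarray(self.eq_freqs, dtype=float)
        if not np.allclose(Q.sum(axis=1), 0, atol=1e-8):
            raise ValueError("generator rows must sum to 0")
        balance = pi[:, None] * Q
        if not np.allclose(balance, balance.T, atol=1e-8):
            raise ValueError("generator violates detailed balance")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")
        self.rate_matrix = Q
        self.eq_freqs = pi

    @classmethod
    def from_newick(
        cls,
        newick: str,
        exchangeabilities: Sequence[float] | None = None,
        eq_freqs: Sequence[float] | None = None,
    ) -> "PhyloModel":
        """Build from a newick string; Jukes-Cantor when no model given."""
        tree = dendropy.Tree.get(data=newick, schema="newick")
        if exchangeabilities is None:
            exchangeabilities = [1.0] * 6
        if eq_freqs is None:
            eq_freqs = [0.25] * 4
        Q = build_gtr_rate_matrix(exchangeabilities, eq_freqs)
        return cls(tree=tree, rate_matrix=Q, eq_freqs=np.asarray(eq_freqs, float))

    @classmethod
    def jukes_cantor(cls, newick: str) -> "PhyloModel":
        return cls.from_newick(newick)

    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def scaled(self, c: float) -> "PhyloModel":
        """A copy with all branch lengths multiplied by ``c``."""
        tree = self.tree.clone(depth=1)
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * c
        return PhyloModel(tree=tree, rate_matrix=self.rate_matrix.copy(), eq_freqs=self.eq_freqs.copy())


@dataclass(frozen=True)
class RateScale:
    """Fitted rate scale for one element."""

    rho: float
    loglik: float
    n_columns: int

    def __post_init__(self) -> None:
        if self.rho < 0 or not np.isfinite(self.loglik):
            raise ValueError("invalid rate-scale result")


def _columns_from_alignment(alignment: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Per-leaf partial likelihood arrays of shape (n_cols, 4)."""
    lengths = {len(seq) for seq in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    return {
        name: np.array([_base_likelihood(c) for c in seq])
        for name, seq in alignment.items()
    }


def column_log_likelihood(
    alignment: Mapping[str, str], model: PhyloModel, rho: float
) -> float:
    """Summed log-likelihood of alignment columns under the model with all
    branch lengths scaled by ``rho`` (Felsenstein pruning, vectorised over
    columns).  Rows must map onto tree leaves; an all-ambiguous column
    contributes log 1 = 0."""
    leaves = set(model.leaf_labels())
    missing = set(alignment) - leaves
    if missing:
        raise ValueError(f"alignment rows not in tree: {sorted(missing)}")
    partials = _columns_from_alignment(alignment)
    n_cols = next(iter(partials.values())).shape[0]
    Q = model.rate_matrix
    ones = np.ones((n_cols, 4))

    def prune(node) -> np.ndarray:
        if node.is_leaf():
            return partials.get(node.taxon.label, ones)
        out = np.ones((n_cols, 4))
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            P = expm(rho * t * Q)
            out = out * (prune(child) @ P.T)
        return out

    root_partial = prune(model.tree.seed_node)
    site_lik = root_partial @ model.eq_freqs
    if np.any(site_lik <= 0):
        raise ValueError("zero column likelihood")
    return float(np.log(site_lik).sum())


def fit_scale(alignment: Mapping[str, str], model: PhyloModel) -> RateScale:
    """Maximise the column log-likelihood over the single scale constant.

    Bounded 1-D optimisation on [0, 4] with tolerance 1e-6 on rho; the
    optimum is the element's rate as a fraction of the neutral rate.
    """
    cols = list(zip(*alignment.values()))
    if not cols:
        raise ValueError("empty alignment")
    informative = any(
        any(c.upper() in _BASE_INDEX for c in col) for col in cols
    )
    if not informative:
        raise ValueError("degenerate alignment: all characters ambiguous")
    res = minimize_scalar(
        lambda r: -column_log_likelihood(alignment, model, r),
        bounds=RHO_BOUNDS,
        method="bounded",
        options={"xatol": RHO_XTOL},
    )
    return RateScale(rho=float(res.x), loglik=float(-res.fun), n_columns=len(cols))
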