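"""Factorized conditional probability tensor.

The conditional law p(y_t | z_t) of a categorical response given q
categorical predictors is a (q+1)-order tensor. It always admits a
higher-order SVD style nonnegative factorization

    p(y_t = c | z_t) = sum_{s_1..s_q} lambda_{s_1..s_q}(c)
                       * prod_j omega^{(j)}[z_{j,t}, s_j]

with mode-j soft-clustering weights omega^{(j)} (a C_j x k_j row-stochastic
matrix, 1 <= k_j <= C_j) and a reduced core over latent strings
(s_1, .., s_q). To keep the core parsimonious, its columns are clustered
nonparametrically: a map phi assigns each latent string to one of L mixture
atoms, and lambda holds the L atom distributions over response categories
(rows on the simplex) with stick-breaking weights pi.

Latent strings are stored by mixed-radix encoding with radices (k_1..k_q),
row-major (s_1 most significant), so ``phi`` is a flat integer array of
length prod_j k_j.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .errors import CatfusionError

__all__ = ["FactorModel", "conditional_probability", "conditional_table", "string_strides"]

_SIMPLEX_TOL = 1e-10
_TINY = 1e-300


def string_strides(k):
    """Mixed-radix strides for latent strings: code = sum_j s_j * strides[j]."""
    k = np.asarray(k, dtype=np.int64)
    strides = np.ones_like(k)
    if k.size > 1:
        strides[:-1] = np.cumprod(k[::-1])[::-1][1:]
    return strides


@dataclass
class FactorModel:
    """One complete set of factorization parameters.

    Attributes
    ----------
    k : (q,) int array
        Mixture dimensions, ``1 <= k[j] <= C[j]``.
    omega : list of (C_j, k_j) arrays
        Row-stochastic soft-clustering matrices.
    phi : flat int array, length prod(k)
        Latent-string -> atom assignment, values in ``[0, L)``.
    lam : (L, C0) array
        Atom distributions over response categories; rows on the simplex.
    pi : (L,) array
        Stick-breaking weights (sums to 1).
    V : (L,) array
        Stick fractions generating ``pi`` (``V[L-1] == 1``).
    """

    k: np.ndarray
    omega: list
    phi: np.ndarray
    lam: np.ndarray
    pi: np.ndarray
    V: np.ndarray = None

    def __post_init__(self):
        self.k = np.asarray(self.k, dtype=np.int64)
        self.phi = np.asarray(self.phi, dtype=np.int64)
        self.lam = np.asarray(self.lam, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)

    @property
    def q(self):
        return self.k.size

    @property
    def C0(self):
        return self.lam.shape[1]

    @property
    def L(self):
        return self.lam.shape[0]

    @property
    def n_strings(self):
        return int(np.prod(self.k))

    @property
    def C(self):
        return np.array([w.shape[0] for w in self.omega], dtype=np.int64)

    def validate(self, atol=_SIMPLEX_TOL):
        """Assert all normalization/shape invariants; raise on violation."""
        if np.any(self.k < 1) or np.any(self.k > self.C):
            raise CatfusionError("k out of [1, C]")
        for j, w in enumerate(self.omega):
            if w.shape[1] != self.k[j]:
                raise CatfusionError(f"omega[{j}] has {w.shape[1]} columns, expected {self.k[j]}")
            if np.any(w < 0) or np.max(np.abs(w.sum(axis=1) - 1.0)) > atol:
                raise CatfusionError(f"omega[{j}] rows must lie on the simplex")
        if self.phi.size != self.n_strings:
            raise CatfusionError("phi length must equal prod(k)")
        if self.phi.min() < 0 or self.phi.max() >= self.L:
            raise CatfusionError("phi values out of [0, L)")
        if np.any(self.lam < 0) or np.max(np.abs(self.lam.sum(axis=1) - 1.0)) > atol:
            raise CatfusionError("lambda rows must lie on the simplex")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > atol:
            raise CatfusionError("pi must lie on the simplex")
        if self.V is not None and abs(self.V[-1] - 1.0) > atol:
            raise CatfusionError("last stick fraction must be 1")

    def copy(self):
        return FactorModel(
            k=self.k.copy(),
            omega=[w.copy() for w in self.omega],
            phi=self.phi.copy(),
            lam=self.lam.copy(),
            pi=self.pi.copy(),
            V=None if self.V is None else self.V.copy(),
        )


def _string_weights(model, z_row):
    """prod_j omega^(j)[z_j, s_j] over all latent strings, row-major order."""
    w = np.ones(1)
    for j in range(model.q):
        w = np.multiply.outer(w, model.omega[j][z_row[j], :]).ravel()
    return w


def conditional_probability(model, z_row):
    """Evaluate p(y = . | z) under the factorized tensor.

    Sums the core atom distributions over all latent strings, weighted by
    the product of mode weights. Output is a length-C0 probability vector
    (sums to 1 up to floating point, guaranteed by the factorization's
    normalization constraints).
    """
    z_row = np.asarray(z_row, dtype=np.int64)
    if z_row.shape != (model.q,):
        raise CatfusionError(f"z_row must have length q={model.q}")
    C = model.C
    if np.any(z_row < 0) or np.any(z_row >= C):
        raise CatfusionError("z_row codes out of range")
    w = _string_weights(model, z_row)
    return w @ model.lam[model.phi]


def conditional_table(model):
    """The full conditional tensor as an array of shape (C_1, .., C_q, C0).

    Contracts the core with every mode in a single einsum; feasible whenever
    prod_j C_j is moderate (the sampler and classifier cap this).
    """
    q = model.q
    letters = string.ascii_letters
    if 2 * q + 1 > len(letters):
        raise CatfusionError("too many predictors for a dense table")
    s_idx = letters[:q]
    c_idx = letters[q]
    z_idx = letters[q + 1 : 2 * q + 1]
    core = model.lam[model.phi].reshape(*model.k, model.C0)
    operands = [core] + list(model.omega)
    subs = s_idx + c_idx
    for j in range(q):
        subs += f",{z_idx[j]}{s_idx[j]}"
    subs += "->" + z_idx + c_idx
    return np.einsum(subs, *operands, optimize=True)


def relabel_mode(model, j, perm):
    """Apply a permutation of latent labels of mode j consistently.

    Returns a new model with omega^(j) columns permuted and phi's domain
    reindexed; the represented conditional tensor is unchanged (used to
    check label-invariance).
    """
    perm = np.asarray(perm, dtype=np.int64)
    kj = model.k[j]
    if sorted(perm.tolist()) != list(range(kj)):
        raise CatfusionError("perm must be a permutation of range(k_j)")
    out = model.copy()
    # column s of the new omega holds old column perm[s]
    out.omega[j] = model.omega[j][:, perm]
    strides = string_strides(model.k)
    codes = np.arange(model.n_strings)
    s_j = (codes // strides[j]) % kj
    new_codes = codes + (perm[s_j] - s_j) * strides[j]
    out.phi = model.phi[new_codes]
    return out
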