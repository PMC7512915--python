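"""Partially collapsed Gibbs sampler for the tensor-factorization model.

Priors
------
* Atom distributions lambda_l ~ Dirichlet(alpha, .., alpha), l = 1..L.
* Stick fractions V_l ~ Beta(1-b, a+l*b) (Pitman-Yor; a=1, b=0 gives a
  Dirichlet process), truncated at L components with V_L = 1.
* Atom assignments phi_{s_1..s_q} ~ Mult(pi).
* Mode rows omega^{(j)}(c) ~ Dirichlet(beta_j, .., beta_j) (k_j-dimensional).
* Mixture dimensions p(k_j = k) proportional to exp(-mu_j * k) on {1..C_j}.

One sweep resamples, in order: phi | rest, the sticks (pi), lambda, omega,
the latent allocations x, and finally each k_j with omega^{(j)} integrated
out (the "partially collapsed" step, which avoids trans-dimensional moves).
The collapsed full conditional is the exact Dirichlet-multinomial marginal

    p(k_j = k | x_j, z_j) proportional to
        exp(-mu_j k) * prod_c Gamma(k beta_j) / Gamma(k beta_j + n_{j,c})

on the support {max_t x_{j,t} + 1, .., C_j}. A newly sampled k_j takes
effect at the start of the next sweep (phi is reallocated there; omega is
redrawn at its own step), so every post-sweep state is a fully consistent
:class:`~catfusion.factor.FactorModel`.

All categorical sampling is done in log space; one `numpy.random.Generator`
drives every draw in a fixed documented order, so runs are reproducible
from the seed alone.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import CatfusionError
from .factor import FactorModel, conditional_table, string_strides, _TINY

__all__ = ["Hyperparams", "LatentState", "PosteriorEnsemble", "init_state",
           "gibbs_sweep", "run_gibbs"]

logger = logging.getLogger(__name__)

_TABLE_CAP = 10 ** 6  # dense-table evaluation cap on prod(C) * C0


@dataclass(frozen=True)
class Hyperparams:
    """Prior and run settings for the Gibbs sampler.

    Parameters
    ----------
    a, b : float
        Pitman-Yor parameters, ``0 <= b < 1`` and ``a > -b``. Defaults
        (1, 0) give a Dirichlet process.
    alpha : float
        Dirichlet concentration for the atom distributions (pseudo-count).
    beta : float or (q,) array or None
        Per-mode Dirichlet concentration beta_j; None means 1/C_j.
    mu : float or (q,) array
        Exponential penalty rate on each k_j; larger values favour smaller
        dimensions (mu_j = 0 is a uniform prior on {1..C_j}).
    L : int or None
        Stick-breaking truncation level; None means min(32, prod_j C_j).
    n_iter, burn_in, thin : int
        Total sweeps, discarded prefix, and retention stride. The retained
        ensemble has floor((n_iter - burn_in)/thin) samples.
    seed : int or None
        Seed for the single RNG stream.
    """

    a: float = 1.0
    b: float = 0.0
    alpha: float = 1.0
    beta: object = None
    mu: object = 1.0
    L: int = None
    n_iter: int = 30_000
    burn_in: int = 20_000
    thin: int = 5
    seed: int = None

    def __post_init__(self):
        if not (0.0 <= self.b < 1.0):
            raise CatfusionError("need 0 <= b < 1")
        if not (self.a > -self.b):
            raise CatfusionError("need a > -b")
        if self.alpha <= 0:
            raise CatfusionError("alpha must be positive")
        if self.thin < 1 or self.n_iter < 1 or self.burn_in < 0:
            raise CatfusionError("invalid iteration schedule")
        if self.burn_in >= self.n_iter:
            raise CatfusionError("burn_in must be smaller than n_iter")
        if self.L is not None and self.L < 1:
            raise CatfusionError("L must be >= 1")

    def beta_vector(self, C):
        C = np.asarray(C)
        if self.beta is None:
            return 1.0 / C.astype(float)
        beta = np.broadcast_to(np.asarray(self.beta, dtype=float), C.shape).copy()
        if np.any(beta <= 0):
            raise CatfusionError("beta_j must be positive")
        return beta

    def mu_vector(self, q):
        mu = np.broadcast_to(np.asarray(self.mu, dtype=float), (q,)).copy()
        if np.any(mu < 0):
            raise CatfusionError("mu_j must be >= 0")
        return mu

    def truncation(self, C):
        if self.L is not None:
            return int(self.L)
        return int(min(32, np.prod(np.asarray(C, dtype=np.int64))))

    def n_retained(self):
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class LatentState:
    """Current sampler state: allocations x plus the factor model.

    ``k_pending`` holds the most recent draw of the dimension vector; it is
    applied to the model at the start of the next sweep.
    """

    x: np.ndarray          # (T, q) latent allocations, x[t, j] < model.k[j]
    model: FactorModel
    k_pending: np.ndarray

    def string_codes(self):
        """Mixed-radix encoding of each row of x (radices model.k)."""
        return self.x @ string_strides(self.model.k)

    def string_response_counts(self, dataset):
        """n_{s_1..s_q}(c): counts of (latent string, response) pairs.

        Recomputed from scratch by bincount; O(T) and cheap at the problem
        sizes this sampler targets.
        """
        S = self.model.n_strings
        C0 = self.model.C0
        flat = self.string_codes() * C0 + dataset.y
        return np.bincount(flat, minlength=S * C0).reshape(S, C0)

    def mode_level_counts(self, dataset, j):
        """n_{j,c}(s) = #{t : z[t,j]=c, x[t,j]=s}, shape (C_j, k_j)."""
        kj = int(self.model.k[j])
        Cj = int(dataset.C[j])
        flat = dataset.z[:, j] * kj + self.x[:, j]
        return np.bincount(flat, minlength=Cj * kj).reshape(Cj, kj)

    def ktilde(self):
        """Occupied-cluster counts per mode: distinct labels in each x column."""
        return np.array(
            [np.unique(self.x[:, j]).size for j in range(self.x.shape[1])],
            dtype=np.int64,
        )


def _sample_rows_log(logw, rng):
    """One categorical draw per row of a log-weight matrix (Gumbel-max)."""
    g = rng.gumbel(size=logw.shape)
    return np.argmax(logw + g, axis=1)


def _sample_rows(w, rng):
    """One categorical draw per row of a nonnegative weight matrix."""
    c = np.cumsum(w, axis=1)
    u = rng.random((w.shape[0], 1)) * c[:, -1:]
    return (c < u).sum(axis=1)


def _dirichlet_rows(shape_matrix, rng):
    """Row-wise Dirichlet draws via normalized gammas, floored away from 0."""
    g = rng.gamma(shape_matrix)
    g = np.clip(g, _TINY, None)
    return g / g.sum(axis=1, keepdims=True)


def _stick_break(V):
    pi = V.copy()
    pi[1:] *= np.cumprod(1.0 - V[:-1])
    return pi


def init_state(dataset, hyperparams, rng):
    """Draw the initial state: k_j = C_j, x uniform, parameters from priors."""
    q, T = dataset.q, dataset.T
    C = dataset.C
    L = hyperparams.truncation(C)
    beta = hyperparams.beta_vector(C)
    k = C.copy()
    x = np.empty((T, q), dtype=np.int64)
    for j in range(q):
        x[:, j] = rng.integers(0, k[j], size=T)
    S = int(np.prod(k))
    phi = rng.integers(0, L, size=S)
    V = np.empty(L)
    if L > 1:
        ls = np.arange(1, L)
        V[:-1] = rng.beta(1.0 - hyperparams.b, hyperparams.a + ls * hyperparams.b)
    V[-1] = 1.0
    pi = _stick_break(V)
    lam = _dirichlet_rows(np.full((L, dataset.C0), hyperparams.alpha), rng)
    omega = [
        _dirichlet_rows(np.full((C[j], k[j]), beta[j]), rng) for j in range(q)
    ]
    model = FactorModel(k=k, omega=omega, phi=phi, lam=lam, pi=pi, V=V)
    return LatentState(x=x, model=model, k_pending=k.copy())


# --- individual Gibbs steps -------------------------------------------------

def phi_log_weights(state, dataset):
    """Unnormalized log full-conditional for every (string, atom) pair."""
    n = state.string_response_counts(dataset)          # (S, C0)
    loglam = np.log(np.clip(state.model.lam, _TINY, None))
    logpi = np.log(np.clip(state.model.pi, _TINY, None))
    return logpi[None, :] + n @ loglam.T               # (S, L)


def step_phi(state, dataset, hyperparams, rng):
    """Resample every string's atom assignment from its multinomial full
    conditional, proportional to pi_l * prod_c lambda_l(c)^{n_s(c)}."""
    state.model.phi = _sample_rows_log(phi_log_weights(state, dataset), rng)
    return state


def step_pi(state, hyperparams, rng):
    """Resample the truncated sticks from their Beta full conditionals."""
    model = state.model
    L = model.L
    nl = np.bincount(model.phi, minlength=L).astype(float)
    tail = np.concatenate([np.cumsum(nl[::-1])[::-1][1:], [0.0]])  # sum_{m>l} n_m
    V = np.empty(L)
    if L > 1:
        ls = np.arange(1, L)  # 1-based stick index
        V[:-1] = rng.beta(
            1.0 - hyperparams.b + nl[:-1],
            hyperparams.a + ls * hyperparams.b + tail[:-1],
        )
    V[-1] = 1.0
    model.V = V
    model.pi = _stick_break(V)
    return state


def step_lambda(state, dataset, hyperparams, rng):
    """Resample the atom distributions from Dirichlet full conditionals."""
    model = state.model
    n = state.string_response_counts(dataset)
    nlc = np.zeros((model.L, model.C0))
    np.add.at(nlc, model.phi, n)
    model.lam = _dirichlet_rows(hyperparams.alpha + nlc, rng)
    return state


def step_omega(state, dataset, hyperparams, rng):
    """Resample every mode matrix row from its Dirichlet full conditional.

    The matrix is rebuilt at the current k_j, so this is also where a
    pending dimension change materializes in omega.
    """
    model = state.model
    beta = hyperparams.beta_vector(dataset.C)
    for j in range(model.q):
        counts = state.mode_level_counts(dataset, j)   # (C_j, k_j)
        model.omega[j] = _dirichlet_rows(beta[j] + counts, rng)
    return state


def x_weights(state, dataset, j):
    """Unnormalized full-conditional weights for column j of x, shape (T, k_j).

    w[t, s] = omega^(j)[z_{j,t}, s] * lambda_{phi(s_1..s..s_q)}(y_t) with the
    other coordinates of x_t held fixed.
    """
    model = state.model
    kj = int(model.k[j])
    strides = string_strides(model.k)
    codes = state.string_codes()
    base = codes - state.x[:, j] * strides[j]
    idx = base[:, None] + np.arange(kj)[None, :] * strides[j]
    lamphi = np.clip(model.lam, _TINY, None)[model.phi[idx], dataset.y[:, None]]
    return np.clip(model.omega[j][dataset.z[:, j], :], _TINY, None) * lamphi


def step_x(state, dataset, hyperparams, rng):
    """Resample latent allocations column by column.

    Given the parameters, the entries of column j are conditionally
    independent across t, so each column is drawn as one vectorized block.
    """
    for j in range(state.model.q):
        if state.model.k[j] == 1:
            state.x[:, j] = 0
            continue
        state.x[:, j] = _sample_rows(x_weights(state, dataset, j), rng)
    return state


def k_log_weights(state, dataset, hyperparams, j):
    """Collapsed log full-conditional for k_j over its support.

    Returns ``(support, logw)`` where support = {max_t x[t,j]+1, .., C_j}
    and logw is the exact Dirichlet-multinomial marginal with omega^{(j)}
    integrated out (plus the exponential prior), up to a constant.
    """
    Cj = int(dataset.C[j])
    beta = hyperparams.beta_vector(dataset.C)[j]
    mu = hyperparams.mu_vector(dataset.q)[j]
    lo = int(state.x[:, j].max()) + 1
    support = np.arange(lo, Cj + 1)
    njc = np.bincount(dataset.z[:, j], minlength=Cj).astype(float)
    kb = support[:, None] * beta
    logw = -mu * support + (gammaln(kb) - gammaln(kb + njc[None, :])).sum(axis=1)
    return support, logw


def step_k(state, dataset, hyperparams, rng):
    """Sample each dimension k_j from its collapsed full conditional.

    The draw is recorded in ``k_pending``; omega and phi keep their current
    shapes until the next sweep.
    """
    for j in range(state.model.q):
        support, logw = k_log_weights(state, dataset, hyperparams, j)
        if support.size == 1:
            state.k_pending[j] = support[0]
            continue
        i = _sample_rows_log(logw[None, :], rng)[0]
        state.k_pending[j] = support[i]
    return state


def _apply_pending_k(state, rng):
    """Materialize a pending dimension change in k and phi.

    phi is reallocated over the new radices; strings that existed under the
    old radices keep their assignment, newly created strings draw from the
    current pi. (They are resampled at the imminent phi step regardless.)
    omega is rebuilt later, at its own Dirichlet step.
    """
    model = state.model
    if np.array_equal(model.k, state.k_pending):
        return state
    new_k = state.k_pending.copy()
    S_new = int(np.prod(new_k))
    new_strides = string_strides(new_k)
    codes = np.arange(S_new)
    digits = (codes[:, None] // new_strides[None, :]) % new_k[None, :]
    keep = np.all(digits < model.k[None, :], axis=1)
    new_phi = np.empty(S_new, dtype=np.int64)
    if keep.any():
        old_codes = digits[keep] @ string_strides(model.k)
        new_phi[keep] = model.phi[old_codes]
    n_new = int((~keep).sum())
    if n_new:
        pi = np.clip(model.pi, 0, None)
        new_phi[~keep] = rng.choice(model.L, size=n_new, p=pi / pi.sum())
    model.phi = new_phi
    model.k = new_k
    state.k_pending = new_k.copy()
    return state


def _dataset_zcodes(dataset):
    """Mixed-radix code of each z row with radices C (for table lookups)."""
    return dataset.z @ string_strides(dataset.C)


def data_loglik(model, dataset, zcodes=None):
    """Sum_t log p(y_t | z_t) under one factor model."""
    n_conf = int(np.prod(dataset.C))
    if n_conf * dataset.C0 <= _TABLE_CAP and model.q <= 25:
        table = conditional_table(model).reshape(n_conf, model.C0)
        if zcodes is None:
            zcodes = _dataset_zcodes(dataset)
        p = table[zcodes, dataset.y]
    else:
        from .factor import conditional_probability

        uniq, inv = np.unique(dataset.z, axis=0, return_inverse=True)
        pu = np.stack([conditional_probability(model, row) for row in uniq])
        p = pu[inv, dataset.y]
    return float(np.log(np.clip(p, _TINY, None)).sum())


def gibbs_sweep(state, dataset, hyperparams, rng, zcodes=None):
    """One full sweep (phi, pi, lambda, omega, x, k); returns the post-sweep
    data log-likelihood."""
    _apply_pending_k(state, rng)
    step_phi(state, dataset, hyperparams, rng)
    step_pi(state, hyperparams, rng)
    step_lambda(state, dataset, hyperparams, rng)
    step_omega(state, dataset, hyperparams, rng)
    step_x(state, dataset, hyperparams, rng)
    step_k(state, dataset, hyperparams, rng)
    return data_loglik(state.model, dataset, zcodes)


@dataclass
class PosteriorSample:
    """One retained snapshot: the factor model plus occupied-cluster counts."""

    model: FactorModel
    ktilde: np.ndarray


@dataclass
class PosteriorEnsemble:
    """Retained, thinned posterior samples plus run metadata."""

    samples: list
    loglik_trace: np.ndarray
    hyperparams: Hyperparams
    C0: int
    C: np.ndarray
    T: int
    predictor_level_counts: list      # n_{j,c} of the training data
    predictor_names: tuple = None
    dataset_fingerprint: str = ""

    def __len__(self):
        return len(self.samples)

    @property
    def ktilde_matrix(self):
        """(N, q) matrix of occupied-cluster counts across retained samples."""
        return np.stack([s.ktilde for s in self.samples])

    @property
    def k_matrix(self):
        return np.stack([s.model.k for s in self.samples])


def dataset_fingerprint(dataset):
    h = hashlib.sha1()
    h.update(dataset.y.tobytes())
    h.update(dataset.z.tobytes())
    h.update(np.asarray([dataset.C0], dtype=np.int64).tobytes())
    h.update(dataset.C.tobytes())
    return h.hexdigest()[:16]


def run_gibbs(dataset, hyperparams, log_every=0, callback=None):
    """Run the full sampler and collect the retained ensemble.

    Parameters
    ----------
    dataset : RegressionDataset
    hyperparams : Hyperparams
    log_every : int
        If positive, log the iteration number and current data
        log-likelihood every ``log_every`` sweeps.
    callback : callable, optional
        Called as ``callback(iteration, loglik)`` after every sweep.

    Returns
    -------
    PosteriorEnsemble
    """
    hp = hyperparams
    rng = np.random.default_rng(hp.seed)
    state = init_state(dataset, hp, rng)
    zcodes = None
    if int(np.prod(dataset.C)) * dataset.C0 <= _TABLE_CAP:
        zcodes = _dataset_zcodes(dataset)
    loglik = np.empty(hp.n_iter)
    samples = []
    for n in range(1, hp.n_iter + 1):
        loglik[n - 1] = gibbs_sweep(state, dataset, hp, rng, zcodes)
        if n > hp.burn_in and (n - hp.burn_in) % hp.thin == 0:
            samples.append(
                PosteriorSample(model=state.model.copy(), ktilde=state.ktilde())
            )
        if log_every and n % log_every == 0:
            logger.info("sweep %d/%d loglik=%.2f", n, hp.n_iter, loglik[n - 1])
        if callback is not None:
            callback(n, loglik[n - 1])
    return PosteriorEnsemble(
        samples=samples,
        loglik_trace=loglik,
        hyperparams=hp,
        C0=dataset.C0,
        C=dataset.C.copy(),
        T=dataset.T,
        predictor_level_counts=dataset.predictor_level_counts(),
        predictor_names=dataset.names(),
        dataset_fingerprint=dataset_fingerprint(dataset),
    )
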