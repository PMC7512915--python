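"""Bayes-factor tests of predictor relevance and Granger causality.

A predictor z_j matters only through the number of clusters ktilde_j its
latent allocations actually occupy: with a single occupied cluster the
conditional tensor is constant in z_j. For a predictor set Lambda the
hypotheses are

    H0: ktilde_j = 1 for every j in Lambda   (none of them matter)
    H1: ktilde_j > 1 for some j in Lambda

and the Bayes factor is the posterior-to-prior odds ratio

    BF10 = [p(H1|data)/p(H1)] / [p(H0|data)/p(H0)].

Posterior probabilities are the fractions of retained Gibbs samples
conforming to each hypothesis; the prior probability of H0 has the closed
form (independent across j)

    p(ktilde_j = 1) = sum_{k=1}^{C_j} p(k_j=k) * k
                      * prod_c (beta_j)^(n_{j,c}) / (k beta_j)^(n_{j,c})

where a^(n) = Gamma(a+n)/Gamma(a) is the rising factorial and n_{j,c} the
level counts of predictor j in the training data.

To test whether a source Granger-causes the response, Lambda is the set of
all that source's lag columns. BF10 > 20 is conventionally strong evidence,
> 150 very strong.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import CatfusionError

__all__ = [
    "GrangerTestResult",
    "effective_cluster_count",
    "prior_prob_single_cluster",
    "bayes_factor",
    "granger_test",
    "predictor_inclusion",
]

DEFAULT_BF_THRESHOLD = 20.0


@dataclass
class GrangerTestResult:
    """Outcome of one Bayes-factor relevance test.

    ``bf10`` may be ``math.inf`` when no retained sample conforms to H0.
    Raw sample fractions and the ensemble size are kept so users can judge
    the Monte-Carlo error behind the Bayes factor.
    """

    Lambda: tuple                 # 0-based predictor column indices
    predictor_names: tuple
    prior_H0: float
    prior_H1: float
    post_H0: float
    post_H1: float
    bf10: float
    n_samples: int
    threshold: float = DEFAULT_BF_THRESHOLD
    cause: str = None
    response: str = None

    @property
    def decision(self):
        """True iff the evidence for H1 clears the threshold."""
        return self.bf10 > self.threshold

    def __str__(self):
        bf = "Infinity" if math.isinf(self.bf10) else f"{self.bf10:.4g}"
        names = ", ".join(self.predictor_names)
        lines = [
            f"H1: some predictor of {{{names}}} is relevant (ktilde_j > 1)",
            f"prior   P(H0)={self.prior_H0:.4f}  P(H1)={self.prior_H1:.4f}",
            f"posterior P(H0)={self.post_H0:.4f}  P(H1)={self.post_H1:.4f}"
            f"  ({self.n_samples} samples)",
            f"BF10 = {bf}   ({'H1 accepted' if self.decision else 'H0 retained'}"
            f" at threshold {self.threshold:g})",
        ]
        return "\n".join(lines)


def effective_cluster_count(x_column):
    """Number of clusters actually occupied by one column of allocations."""
    x_column = np.asarray(x_column)
    if x_column.size == 0:
        raise CatfusionError("empty allocation column")
    return int(np.unique(x_column).size)


def _prior_log_pk(Cj, mu):
    """log p(k_j = k) for k = 1..C_j under the exponential penalty prior."""
    ks = np.arange(1, Cj + 1)
    logw = -mu * ks
    return logw - logsumexp(logw)


def prior_prob_single_cluster(level_counts, beta, mu):
    """Prior probability that a predictor's allocations form one cluster.

    Parameters
    ----------
    level_counts : (C_j,) array
        n_{j,c}: occurrences of each level of the predictor in the data.
    beta : float
        Dirichlet concentration beta_j of the mode rows.
    mu : float
        Exponential penalty rate on k_j.

    Returns
    -------
    float in (0, 1].
    """
    n = np.asarray(level_counts, dtype=float)
    if n.sum() < 1:
        raise CatfusionError("prior_prob_single_cluster needs at least one observation")
    Cj = n.size
    logpk = _prior_log_pk(Cj, mu)
    ks = np.arange(1, Cj + 1, dtype=float)
    # log prod_c (beta)^(n_c) / (k beta)^(n_c), rising factorials via loggamma
    rise_beta = (gammaln(beta + n) - gammaln(beta)).sum()
    kb = ks[:, None] * beta
    rise_kbeta = (gammaln(kb + n[None, :]) - gammaln(kb)).sum(axis=1)
    log_terms = logpk + np.log(ks) + rise_beta - rise_kbeta
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def _prior_H0(ensemble, Lambda):
    hp = ensemble.hyperparams
    beta = hp.beta_vector(ensemble.C)
    mu = hp.mu_vector(len(ensemble.C))
    p = 1.0
    for j in Lambda:
        p *= prior_prob_single_cluster(
            ensemble.predictor_level_counts[j], beta[j], mu[j]
        )
    return p


def bayes_factor(ensemble, Lambda, threshold=DEFAULT_BF_THRESHOLD,
                 cause=None, response=None):
    """Bayes factor for H1 ("some predictor in Lambda matters") against H0.

    Parameters
    ----------
    ensemble : PosteriorEnsemble
        Retained Gibbs samples (with their training-data level counts).
    Lambda : iterable of int
        0-based predictor column indices; must be non-empty.

    Returns
    -------
    GrangerTestResult
    """
    Lambda = tuple(sorted(set(int(j) for j in Lambda)))
    q = len(ensemble.C)
    if len(Lambda) == 0:
        raise CatfusionError("Lambda must be a non-empty set of predictor indices")
    if min(Lambda) < 0 or max(Lambda) >= q:
        raise CatfusionError(f"Lambda indices must lie in [0, {q})")
    if len(ensemble) == 0:
        raise CatfusionError("empty posterior ensemble")

    kt = ensemble.ktilde_matrix[:, Lambda]
    post_H0 = float(np.mean(np.all(kt == 1, axis=1)))
    post_H1 = 1.0 - post_H0
    prior_H0 = _prior_H0(ensemble, Lambda)
    prior_H1 = 1.0 - prior_H0

    if post_H0 == 0.0:
        bf10 = math.inf if post_H1 > 0 else math.nan
    elif post_H1 == 0.0:
        bf10 = 0.0
    else:
        bf10 = (post_H1 / prior_H1) / (post_H0 / prior_H0)

    names = ensemble.predictor_names or tuple(f"z{j + 1}" for j in range(q))
    return GrangerTestResult(
        Lambda=Lambda,
        predictor_names=tuple(names[j] for j in Lambda),
        prior_H0=prior_H0,
        prior_H1=prior_H1,
        post_H0=post_H0,
        post_H1=post_H1,
        bf10=bf10,
        n_samples=len(ensemble),
        threshold=threshold,
        cause=cause,
        response=response,
    )


def granger_test(ensemble, lag_spec, cause_source,
                 threshold=DEFAULT_BF_THRESHOLD):
    """Test whether ``cause_source`` Granger-causes the response.

    Lambda is the set of all lag columns contributed by ``cause_source``;
    choosing the response's own source screens for self-dependence instead.
    """
    Lambda = lag_spec.indices_for(cause_source)
    return bayes_factor(
        ensemble,
        Lambda,
        threshold=threshold,
        cause=cause_source,
        response=lag_spec.response,
    )


def predictor_inclusion(ensemble):
    """Fraction of retained samples in which each predictor is relevant
    (ktilde_j > 1); a length-q vector."""
    if len(ensemble) == 0:
        raise CatfusionError("empty posterior ensemble")
    return np.mean(ensemble.ktilde_matrix > 1, axis=0)
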