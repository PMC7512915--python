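"""Posterior-predictive sequential classification and ROC analysis.

Given M fitted class models (one posterior ensemble per dynamical regime),
a categorical test sequence is scored by its posterior-predictive
likelihood under each class,

    p(D_T | class i) = prod_t p(y_t | z_t; class i),
    p(y_t | z_t; class i) ~= (1/N) sum_n p_n(y_t | z_t),

the average running over the retained Gibbs samples (in probability space).
Class posteriors follow by Bayes' rule with user-chosen priors, updated
step by step — the classifier is sequential. For two classes the same
machinery yields a likelihood-ratio test whose threshold sweeps out an
ROC curve (probability of detection pD versus false alarm pF).

Per-sample conditional probabilities are precomputed into a dense lookup
table over all predictor configurations whenever that table is small
enough; otherwise evaluation falls back to on-demand averaging.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .errors import CatfusionError
from .factor import _TINY, conditional_probability, conditional_table, string_strides

__all__ = [
    "posterior_predictive",
    "precompute_predictive_table",
    "sequence_loglik",
    "SequentialClassifier",
    "ClassificationTrace",
    "likelihood_ratio_test",
    "roc_curve",
    "roc_auc",
]

logger = logging.getLogger(__name__)

TABLE_CAP = 10 ** 6


def posterior_predictive(ensemble, z_row):
    """Ensemble-averaged conditional probability p(y = . | z); length C0."""
    if len(ensemble) == 0:
        raise CatfusionError("empty posterior ensemble")
    acc = np.zeros(ensemble.C0)
    for s in ensemble.samples:
        acc += conditional_probability(s.model, z_row)
    return acc / len(ensemble)


def precompute_predictive_table(ensemble, cap=TABLE_CAP):
    """Average the per-sample conditional tables over the ensemble.

    Returns an array of shape (C_1, .., C_q, C0), or None when the table
    would exceed ``cap`` entries (callers then evaluate on demand).
    """
    n_entries = int(np.prod(ensemble.C)) * ensemble.C0
    if n_entries > cap:
        logger.warning(
            "predictive table with %d entries exceeds cap %d; "
            "falling back to on-demand evaluation", n_entries, cap,
        )
        return None
    acc = np.zeros((*ensemble.C, ensemble.C0))
    for s in ensemble.samples:
        acc += conditional_table(s.model)
    return acc / len(ensemble)


def _check_compatible(ensemble, dataset):
    if dataset.C0 != ensemble.C0 or not np.array_equal(dataset.C, ensemble.C):
        raise CatfusionError(
            "test data cardinalities do not match the fitted model"
        )


def sequence_loglik(ensemble, test, table=None):
    """Cumulative log posterior-predictive likelihood of a test sequence.

    Element t is ``sum_{u<=t} log p(y_u | z_u)``; the vector has length T
    and is nonincreasing.
    """
    _check_compatible(ensemble, test)
    if table is None:
        table = precompute_predictive_table(ensemble)
    if table is not None:
        flat = table.reshape(-1, test.C0)
        codes = test.z @ string_strides(test.C)
        p = flat[codes, test.y]
    else:
        p = np.array(
            [posterior_predictive(ensemble, test.z[t])[test.y[t]] for t in range(test.T)]
        )
    return np.cumsum(np.log(np.clip(p, _TINY, None)))


@dataclass
class ClassificationTrace:
    """Per-timestep cumulative log-likelihoods and class posteriors."""

    class_labels: tuple
    cum_loglik: np.ndarray      # (T, M)
    posterior: np.ndarray       # (T, M), rows sum to 1
    label: object               # final decision
    label_index: int

    @property
    def T(self):
        return self.cum_loglik.shape[0]

    def plot(self, ax=None):
        """Plot the class-posterior trajectories against test length."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(1, self.T + 1)
        for i, lab in enumerate(self.class_labels):
            ax.plot(t, self.posterior[:, i], label=str(lab))
        ax.set_xlabel("test sequence length")
        ax.set_ylabel("posterior class probability")
        ax.legend()
        return ax


class SequentialClassifier:
    """M-class sequential classifier over fitted posterior ensembles.

    Parameters
    ----------
    classes : sequence of (label, PosteriorEnsemble)
        All ensembles must share the response and predictor cardinalities.
    priors : array-like, optional
        Class prior probabilities; uniform by default.
    cap : int
        Predictive-table size cap (entries); larger tables are evaluated
        on demand.
    """

    def __init__(self, classes, priors=None, cap=TABLE_CAP):
        if len(classes) < 2:
            raise CatfusionError("need at least two classes")
        self.labels = tuple(lab for lab, _ in classes)
        self.ensembles = [ens for _, ens in classes]
        ref = self.ensembles[0]
        for ens in self.ensembles[1:]:
            if ens.C0 != ref.C0 or not np.array_equal(ens.C, ref.C):
                raise CatfusionError("class models have mismatched cardinalities")
        if priors is None:
            priors = np.full(len(classes), 1.0 / len(classes))
        priors = np.asarray(priors, dtype=float)
        if priors.shape != (len(classes),) or np.any(priors < 0) or abs(priors.sum() - 1.0) > 1e-10:
            raise CatfusionError("class priors must be a probability vector over the classes")
        self.priors = priors
        self.tables = [precompute_predictive_table(e, cap=cap) for e in self.ensembles]

    def loglik_matrix(self, test):
        """(T, M) cumulative log-likelihoods of the test data per class."""
        cols = [
            sequence_loglik(ens, test, table=tab)
            for ens, tab in zip(self.ensembles, self.tables)
        ]
        return np.column_stack(cols)

    def classify(self, test):
        """Sequentially classify a test dataset; returns a ClassificationTrace.

        The step-t posterior is proportional to
        exp(cumulative loglik_i(t)) * prior_i, normalized in log space;
        the final label maximizes the step-T posterior (ties to the lowest
        class index).
        """
        ll = self.loglik_matrix(test)
        logpost = ll + np.log(np.clip(self.priors, _TINY, None))[None, :]
        logpost = logpost - logsumexp(logpost, axis=1, keepdims=True)
        post = np.exp(logpost)
        idx = int(np.argmax(post[-1]))  # argmax takes the first (lowest) on ties
        return ClassificationTrace(
            class_labels=self.labels,
            cum_loglik=ll,
            posterior=post,
            label=self.labels[idx],
            label_index=idx,
        )


def classify_sequential(classifier, test):
    """Functional alias for :meth:`SequentialClassifier.classify`."""
    return classifier.classify(test)


def likelihood_ratio_test(ensemble1, ensemble0, test, theta=1.0,
                          table1=None, table0=None):
    """Binary likelihood-ratio test between two fitted class models.

    The statistic is p(D_T | class 1) / p(D_T | class 0) evaluated through
    the posterior predictive; the decision is class 1 iff the statistic is
    >= theta (the boundary goes to class 1).

    Returns
    -------
    (statistic, decision) : (float, int)
    """
    if theta < 0:
        raise CatfusionError("theta must be nonnegative")
    ll1 = sequence_loglik(ensemble1, test, table=table1)[-1]
    ll0 = sequence_loglik(ensemble0, test, table=table0)[-1]
    stat = math.exp(min(ll1 - ll0, 700.0)) if ll1 - ll0 < 700 else math.inf
    decision = 1 if stat >= theta else 0
    return stat, decision


def roc_curve(stat_positive, stat_negative):
    """ROC points swept over the decision threshold.

    The rule "decide positive iff statistic >= theta" is evaluated at every
    pooled unique statistic plus the extremes, giving
    pD = fraction of positives >= theta and pF = fraction of negatives
    >= theta. Points are returned ordered with pF nondecreasing, and always
    include (0, 0) and (1, 1).

    Returns
    -------
    ndarray of shape (n_points, 2), columns (pF, pD).
    """
    pos = np.asarray(stat_positive, dtype=float)
    neg = np.asarray(stat_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise CatfusionError("both statistic samples must be non-empty")
    thresholds = np.unique(np.concatenate([pos, neg]))
    pts = [(0.0, 0.0)]
    for theta in thresholds[::-1]:
        pD = float(np.mean(pos >= theta))
        pF = float(np.mean(neg >= theta))
        pts.append((pF, pD))
    pts.append((1.0, 1.0))
    pts = np.array(sorted(set(pts)))
    return pts


def roc_auc(points):
    """Trapezoidal area under an ROC point set (columns pF, pD)."""
    points = np.asarray(points, dtype=float)
    return float(np.trapezoid(points[:, 1], points[:, 0]))
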