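import numpy as np
import pytest

from catfusion.factor import FactorModel
from catfusion.sampler import (Hyperparams, PosteriorEnsemble,
                               PosteriorSample)
from catfusion.series import RegressionDataset


def random_factor_model(rng, q=3, k=None, C=None, L=4, C0=2):
    """A valid random FactorModel for oracle tests."""
    k = np.asarray(k if k is not None else [2] * q, dtype=np.int64)
    C = np.asarray(C if C is not None else [2] * q, dtype=np.int64)
    q = k.size
    omega = []
    for j in range(q):
        g = rng.gamma(1.0, size=(C[j], k[j]))
        omega.append(g / g.sum(axis=1, keepdims=True))
    S = int(np.prod(k))
    phi = rng.integers(0, L, size=S)
    lam = rng.gamma(1.0, size=(L, C0))
    lam /= lam.sum(axis=1, keepdims=True)
    g = rng.gamma(1.0, size=L)
    pi = g / g.sum()
    return FactorModel(k=k, omega=omega, phi=phi, lam=lam, pi=pi)


def random_dataset(rng, T=40, q=2, C0=2, C=None):
    C = np.asarray(C if C is not None else [2] * q, dtype=np.int64)
    z = np.column_stack([rng.integers(0, C[j], size=T) for j in range(len(C))])
    y = rng.integers(0, C0, size=T)
    return RegressionDataset(y=y, z=z, C0=C0, C=C)


def make_ensemble(models, ktilde=None, C0=2, C=None, T=10,
                  level_counts=None, hyperparams=None, names=None):
    """Assemble a PosteriorEnsemble by hand (for oracle/counting tests)."""
    C = np.asarray(C if C is not None else models[0].C, dtype=np.int64)
    if ktilde is None:
        ktilde = [m.k for m in models]
    samples = [PosteriorSample(model=m, ktilde=np.asarray(kt, dtype=np.int64))
               for m, kt in zip(models, ktilde)]
    if level_counts is None:
        level_counts = [np.full(Cj, T // Cj) for Cj in C]
    hp = hyperparams or Hyperparams(n_iter=2, burn_in=0, thin=1)
    return PosteriorEnsemble(
        samples=samples,
        loglik_trace=np.zeros(hp.n_iter),
        hyperparams=hp,
        C0=C0, C=C, T=T,
        predictor_level_counts=level_counts,
        predictor_names=names or tuple(f"z{j+1}" for j in range(len(C))),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
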