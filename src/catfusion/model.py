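"""Model/Results interface over the tensor-factorization machinery.

`ConditionalTensorModel` holds a lag-embedded categorical regression
dataset plus the prior settings; `fit()` runs the partially collapsed
Gibbs sampler and returns a `ConditionalTensorResults` carrying the
retained posterior ensemble, the log-likelihood trace, inclusion
proportions, Granger tests and posterior-predictive evaluation, with a
`summary()` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

import io
import json

import numpy as np
import pandas as pd

from . import causality as _causality
from .classify import posterior_predictive, precompute_predictive_table
from .errors import CatfusionError
from .factor import FactorModel, conditional_probability
from .sampler import (Hyperparams, PosteriorEnsemble, PosteriorSample,
                      run_gibbs)
from .series import (CategoricalSeries, LagSpec, RegressionDataset,
                     build_lagged_dataset)

__all__ = ["ConditionalTensorModel", "ConditionalTensorResults",
           "save_results", "load_results"]


class ConditionalTensorModel:
    """Bayesian nonparametric regression of a categorical response on
    lagged categorical predictors.

    Parameters
    ----------
    dataset : RegressionDataset
        Lag-embedded response/predictor pairs (see
        :func:`~catfusion.series.build_lagged_dataset`).
    **prior_kwargs
        Prior settings forwarded to :class:`~catfusion.sampler.Hyperparams`
        (a, b, alpha, beta, mu, L).
    """

    def __init__(self, dataset, **prior_kwargs):
        self.dataset = dataset
        self._prior_kwargs = dict(prior_kwargs)

    @classmethod
    def from_series(cls, series, response, max_lag=None, lag_spec=None,
                    **prior_kwargs):
        """Build from aligned CategoricalSeries.

        Either give an explicit ``lag_spec`` or a uniform ``max_lag`` (own
        lags first, then the other sources in input order).
        """
        if lag_spec is None:
            if max_lag is None:
                raise CatfusionError("give either max_lag or lag_spec")
            lag_spec = LagSpec.own_first(response, [s.name for s in series], max_lag)
        dataset = build_lagged_dataset(series, lag_spec)
        return cls(dataset, **prior_kwargs)

    @classmethod
    def from_dataframe(cls, df, response, max_lag=None, lag_spec=None,
                       categories=None, **prior_kwargs):
        """Build from a DataFrame with one categorical series per column."""
        categories = categories or {}
        series = [
            CategoricalSeries.from_labels(df[col], name=str(col),
                                          categories=categories.get(col))
            for col in df.columns
        ]
        return cls.from_series(series, response, max_lag=max_lag,
                               lag_spec=lag_spec, **prior_kwargs)

    def hyperparams(self, **run_kwargs):
        return Hyperparams(**{**self._prior_kwargs, **run_kwargs})

    def fit(self, n_iter=30_000, burn_in=20_000, thin=5, seed=None,
            log_every=0, callback=None, **prior_overrides):
        """Run the Gibbs sampler; returns a :class:`ConditionalTensorResults`.

        The default schedule retains ``(n_iter - burn_in)/thin`` samples.
        ``seed`` makes the whole run reproducible.
        """
        hp = self.hyperparams(n_iter=n_iter, burn_in=burn_in, thin=thin,
                              seed=seed, **prior_overrides)
        ensemble = run_gibbs(self.dataset, hp, log_every=log_every,
                             callback=callback)
        return ConditionalTensorResults(self, ensemble)


class ConditionalTensorResults:
    """Posterior inference results for a fitted conditional tensor model."""

    def __init__(self, model, ensemble):
        self.model = model
        self.ensemble = ensemble

    # --- basic posterior summaries -------------------------------------

    @property
    def loglik_trace(self):
        return self.ensemble.loglik_trace

    @property
    def n_samples(self):
        return len(self.ensemble)

    @property
    def ktilde(self):
        return self.ensemble.ktilde_matrix

    def inclusion_proportions(self):
        """Per-predictor fraction of samples with ktilde_j > 1."""
        return _causality.predictor_inclusion(self.ensemble)

    # --- causality ------------------------------------------------------

    def bayes_factor(self, Lambda, threshold=_causality.DEFAULT_BF_THRESHOLD):
        """Bayes factor for the relevance of a 0-based predictor index set."""
        return _causality.bayes_factor(self.ensemble, Lambda, threshold=threshold)

    def granger_test(self, cause, threshold=_causality.DEFAULT_BF_THRESHOLD):
        """Test whether source ``cause`` Granger-causes the response."""
        lag_spec = self.model.dataset.lag_spec
        if lag_spec is None:
            raise CatfusionError("dataset has no lag spec; use bayes_factor with indices")
        return _causality.granger_test(self.ensemble, lag_spec, cause,
                                       threshold=threshold)

    # --- posterior prediction --------------------------------------------

    def posterior_predictive(self, z_row):
        """Ensemble-averaged p(y = . | z)."""
        return posterior_predictive(self.ensemble, z_row)

    def predictive_table(self, cap=10 ** 6):
        return precompute_predictive_table(self.ensemble, cap=cap)

    def transition_draws(self, z_row, response_category=None):
        """Per-sample posterior draws of p(y = c | z); the raw Monte-Carlo
        trace behind transition-probability estimates and quantile bands."""
        z_row = np.asarray(z_row, dtype=np.int64)
        draws = np.stack([
            conditional_probability(s.model, z_row) for s in self.ensemble.samples
        ])
        if response_category is None:
            return draws
        return draws[:, response_category]

    # --- presentation ----------------------------------------------------

    def summary_frame(self):
        """Per-predictor posterior summary as a DataFrame."""
        ens = self.ensemble
        incl = self.inclusion_proportions()
        kt = ens.ktilde_matrix
        km = ens.k_matrix
        rows = []
        for j, name in enumerate(ens.predictor_names):
            bf = _causality.bayes_factor(ens, (j,)).bf10
            rows.append({
                "predictor": name,
                "C_j": int(ens.C[j]),
                "mean_k": km[:, j].mean(),
                "mean_ktilde": kt[:, j].mean(),
                "P(ktilde>1)": incl[j],
                "BF10": bf,
            })
        return pd.DataFrame(rows)

    def summary(self, threshold=_causality.DEFAULT_BF_THRESHOLD):
        """Readable text summary of the fit."""
        ens = self.ensemble
        hp = ens.hyperparams
        buf = io.StringIO()
        resp = (self.model.dataset.lag_spec.response
                if self.model.dataset.lag_spec else "y")
        buf.write("Conditional tensor factorization regression\n")
        buf.write("===========================================\n")
        buf.write(f"response: {resp} (C0={ens.C0})   T={ens.T}   q={len(ens.C)}\n")
        buf.write(
            f"sampler: {hp.n_iter} sweeps, burn-in {hp.burn_in}, thin {hp.thin}"
            f" -> {len(ens)} retained; L={hp.truncation(ens.C)}, a={hp.a}, b={hp.b},"
            f" alpha={hp.alpha}\n"
        )
        ll = ens.loglik_trace
        buf.write(f"final data log-likelihood: {ll[-1]:.2f}\n\n")
        frame = self.summary_frame()
        with pd.option_context("display.float_format", lambda v: f"{v:.3f}"):
            buf.write(frame.to_string(index=False))
        buf.write(
            f"\n\nBF10 > {threshold:g}: strong evidence the predictor matters"
            " (Infinity when no retained sample has ktilde_j = 1).\n"
        )
        return buf.getvalue()

    # --- plotting ---------------------------------------------------------

    def plot_loglik(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loglik_trace)
        ax.set_xlabel("sweep")
        ax.set_ylabel("data log-likelihood")
        return ax

    def plot_inclusion(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        incl = self.inclusion_proportions()
        names = self.ensemble.predictor_names
        ax.bar(range(1, len(incl) + 1), incl)
        ax.set_xticks(range(1, len(incl) + 1), names, rotation=45)
        ax.set_ylabel("P(ktilde_j > 1)")
        ax.set_ylim(0, 1.05)
        return ax

    # --- persistence ------------------------------------------------------

    def save(self, path):
        save_results(path, self)


def _hp_to_dict(hp):
    d = {k: getattr(hp, k) for k in
         ("a", "b", "alpha", "n_iter", "burn_in", "thin", "seed", "L")}
    d["beta"] = None if hp.beta is None else np.asarray(hp.beta).tolist()
    d["mu"] = np.asarray(hp.mu).tolist()
    return d


def save_results(path, results):
    """Serialize a fitted results object (dataset + ensemble) to .npz.

    Ragged per-sample arrays (phi, omega) are stored flat with offsets, so
    the container is a plain numeric npz (version tag included).
    """
    ens = results.ensemble
    ds = results.model.dataset
    q = len(ens.C)
    N = len(ens)
    kmat = ens.k_matrix
    phis = [s.model.phi for s in ens.samples]
    phi_flat = np.concatenate(phis) if N else np.empty(0, dtype=np.int64)
    phi_off = np.concatenate([[0], np.cumsum([p.size for p in phis])]).astype(np.int64)
    om_flat = np.concatenate(
        [s.model.omega[j].ravel() for s in ens.samples for j in range(q)]
    ) if N else np.empty(0)
    om_off = np.concatenate([[0], np.cumsum(
        [s.model.omega[j].size for s in ens.samples for j in range(q)]
    )]).astype(np.int64)
    meta = {
        "format_version": 1,
        "hyperparams": _hp_to_dict(ens.hyperparams),
        "predictor_names": list(ens.predictor_names or []),
        "dataset_fingerprint": ens.dataset_fingerprint,
        "lag_spec": None if ds.lag_spec is None else {
            "response": ds.lag_spec.response,
            "blocks": [[s, int(d)] for s, d in ds.lag_spec.blocks],
        },
    }
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        y=ds.y, z=ds.z, C0=np.int64(ds.C0), C=ds.C,
        loglik=ens.loglik_trace,
        k=kmat,
        ktilde=ens.ktilde_matrix,
        pi=np.stack([s.model.pi for s in ens.samples]) if N else np.empty((0, 0)),
        lam=np.stack([s.model.lam for s in ens.samples]) if N else np.empty((0, 0, 0)),
        phi_flat=phi_flat, phi_off=phi_off,
        omega_flat=om_flat, omega_off=om_off,
    )


def load_results(path):
    """Load a results object written by :func:`save_results`."""
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        if meta.get("format_version") != 1:
            raise CatfusionError("unknown results container version")
        hpd = meta["hyperparams"]
        hp = Hyperparams(
            a=hpd["a"], b=hpd["b"], alpha=hpd["alpha"],
            beta=None if hpd["beta"] is None else np.asarray(hpd["beta"]),
            mu=np.asarray(hpd["mu"]), L=hpd["L"],
            n_iter=hpd["n_iter"], burn_in=hpd["burn_in"], thin=hpd["thin"],
            seed=hpd["seed"],
        )
        lag_spec = None
        if meta["lag_spec"] is not None:
            lag_spec = LagSpec(meta["lag_spec"]["response"],
                               tuple((s, d) for s, d in meta["lag_spec"]["blocks"]))
        ds = RegressionDataset(y=f["y"], z=f["z"], C0=int(f["C0"]), C=f["C"],
                               lag_spec=lag_spec)
        q = len(ds.C)
        kmat = f["k"]
        N = kmat.shape[0]
        phi_flat, phi_off = f["phi_flat"], f["phi_off"]
        om_flat, om_off = f["omega_flat"], f["omega_off"]
        samples = []
        for i in range(N):
            k = kmat[i]
            phi = phi_flat[phi_off[i]:phi_off[i + 1]]
            omega = []
            for j in range(q):
                o = i * q + j
                omega.append(
                    om_flat[om_off[o]:om_off[o + 1]].reshape(ds.C[j], k[j])
                )
            samples.append(PosteriorSample(
                model=FactorModel(k=k.copy(), omega=omega, phi=phi.copy(),
                                  lam=f["lam"][i], pi=f["pi"][i]),
                ktilde=f["ktilde"][i],
            ))
        ens = PosteriorEnsemble(
            samples=samples,
            loglik_trace=f["loglik"],
            hyperparams=hp,
            C0=ds.C0, C=ds.C.copy(), T=ds.T,
            predictor_level_counts=ds.predictor_level_counts(),
            predictor_names=tuple(meta["predictor_names"]) or ds.names(),
            dataset_fingerprint=meta["dataset_fingerprint"],
        )
    return ConditionalTensorResults(ConditionalTensorModel(ds), ens)
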