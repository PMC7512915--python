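"""Synthetic categorical processes with known ground truth.

Two kinds of generators:

* :func:`simulate_coupled_example` — a pair of coupled binary Markov
  processes with fixed conditional tables: y evolves on its own lags
  (t-1, t-3, t-4) and theta on (y_{t-1}, y_{t-3}, theta_{t-1},
  theta_{t-2}). By construction y Granger-causes theta but
  not conversely, which makes the pair a complete test bed for structure
  recovery and causality testing.

* :func:`simulate_generic` — arbitrary sparse-lag categorical networks
  with random conditional tables, returned together with their ground
  truth for structure-recovery experiments.

Initialization draws the first max-lag symbols iid uniform and discards a
burn-in prefix (default 100) so the emitted samples are effectively
stationary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CatfusionError
from .series import CategoricalSeries

__all__ = [
    "COUPLED_Y_TABLE",
    "COUPLED_THETA_TABLE",
    "GroundTruthGenerator",
    "simulate_coupled_example",
    "simulate_table_markov",
    "simulate_generic",
]

DEFAULT_BURN_IN = 100

# p(y_t = 1 | y_{t-1}, y_{t-3}, y_{t-4}), indexed [y1][y3][y4]
COUPLED_Y_TABLE = np.zeros((2, 2, 2))
COUPLED_Y_TABLE[0, 0, 0] = 0.20
COUPLED_Y_TABLE[1, 0, 0] = 0.75
COUPLED_Y_TABLE[0, 1, 0] = 0.70
COUPLED_Y_TABLE[1, 1, 0] = 0.35
COUPLED_Y_TABLE[0, 0, 1] = 0.40
COUPLED_Y_TABLE[1, 0, 1] = 0.38
COUPLED_Y_TABLE[0, 1, 1] = 0.33
COUPLED_Y_TABLE[1, 1, 1] = 0.71

# p(theta_t = 1 | y_{t-1}, y_{t-3}, theta_{t-1}, theta_{t-2}),
# indexed [y1][y3][th1][th2]
COUPLED_THETA_TABLE = np.zeros((2, 2, 2, 2))
COUPLED_THETA_TABLE[0, 0, 0, 0] = 0.40
COUPLED_THETA_TABLE[1, 0, 0, 0] = 0.65
COUPLED_THETA_TABLE[0, 1, 0, 0] = 0.70
COUPLED_THETA_TABLE[1, 1, 0, 0] = 0.40
COUPLED_THETA_TABLE[0, 0, 1, 0] = 0.50
COUPLED_THETA_TABLE[1, 0, 1, 0] = 0.47
COUPLED_THETA_TABLE[0, 1, 1, 0] = 0.33
COUPLED_THETA_TABLE[1, 1, 1, 0] = 0.69
COUPLED_THETA_TABLE[0, 0, 0, 1] = 0.45
COUPLED_THETA_TABLE[1, 0, 0, 1] = 0.75
COUPLED_THETA_TABLE[0, 1, 0, 1] = 0.30
COUPLED_THETA_TABLE[1, 1, 0, 1] = 0.50
COUPLED_THETA_TABLE[0, 0, 1, 1] = 0.75
COUPLED_THETA_TABLE[1, 0, 1, 1] = 0.66
COUPLED_THETA_TABLE[0, 1, 1, 1] = 0.65
COUPLED_THETA_TABLE[1, 1, 1, 1] = 0.20


@dataclass
class GroundTruthGenerator:
    """Ground truth behind a simulated network of categorical series.

    ``tables[name]`` maps the joint configuration of that source's parent
    lags (in ``parents[name]`` order) to a distribution over its symbols;
    ``parents[name]`` is a tuple of (source, lag) pairs.
    """

    names: tuple
    cardinalities: dict
    parents: dict        # name -> tuple of (source, lag)
    tables: dict         # name -> array (..parent configs.., C)
    burn_in: int
    seed: object = None

    def __post_init__(self):
        for name, tab in self.tables.items():
            tab = np.asarray(tab, dtype=float)
            if np.any(tab < 0) or np.max(np.abs(tab.sum(axis=-1) - 1.0)) > 1e-10:
                raise CatfusionError(f"table rows for {name!r} must be probability vectors")
            self.tables[name] = tab

    @property
    def max_lag(self):
        lags = [lag for ps in self.parents.values() for _, lag in ps]
        return max(lags) if lags else 1

    def to_dict(self):
        return {
            "names": list(self.names),
            "cardinalities": {k: int(v) for k, v in self.cardinalities.items()},
            "parents": {k: [[s, int(l)] for s, l in v] for k, v in self.parents.items()},
            "tables": {k: v.tolist() for k, v in self.tables.items()},
            "burn_in": int(self.burn_in),
            "seed": self.seed,
        }


def _simulate_network(gen, T, rng):
    """Drive a GroundTruthGenerator forward; returns dict name -> codes."""
    D = gen.max_lag
    total = D + gen.burn_in + T
    hist = {name: np.empty(total, dtype=np.int64) for name in gen.names}
    for name in gen.names:
        hist[name][:D] = rng.integers(0, gen.cardinalities[name], size=D)
    u = {name: rng.random(total) for name in gen.names}
    tables = {name: gen.tables[name] for name in gen.names}
    cumtab = {name: np.cumsum(tables[name], axis=-1) for name in gen.names}
    for t in range(D, total):
        for name in gen.names:
            idx = tuple(hist[src][t - lag] for src, lag in gen.parents[name])
            row = cumtab[name][idx]
            hist[name][t] = int(np.searchsorted(row, u[name][t], side="right"))
    start = D + gen.burn_in
    return {name: hist[name][start:] for name in gen.names}


def simulate_coupled_example(T, seed=None, burn_in=DEFAULT_BURN_IN):
    """Simulate the coupled binary pair (y, theta) of length T.

    Returns
    -------
    (CategoricalSeries, CategoricalSeries)
        y and theta, seed-reproducible; the first max-lag symbols are drawn
        uniformly and a burn-in prefix is discarded.
    """
    if T < 1:
        raise CatfusionError("T must be >= 1")
    gen = GroundTruthGenerator(
        names=("y", "theta"),
        cardinalities={"y": 2, "theta": 2},
        parents={
            "y": (("y", 1), ("y", 3), ("y", 4)),
            "theta": (("y", 1), ("y", 3), ("theta", 1), ("theta", 2)),
        },
        # rows are (p0, p1): code 1 is drawn with the tabulated probability
        tables={
            "y": np.stack([1.0 - COUPLED_Y_TABLE, COUPLED_Y_TABLE], axis=-1),
            "theta": np.stack([1.0 - COUPLED_THETA_TABLE, COUPLED_THETA_TABLE], axis=-1),
        },
        burn_in=burn_in,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    out = _simulate_network(gen, T, rng)
    return (
        CategoricalSeries(out["y"], 2, name="y"),
        CategoricalSeries(out["theta"], 2, name="theta"),
    )


def simulate_table_markov(table, lags, T, seed=None, burn_in=DEFAULT_BURN_IN,
                          name="y"):
    """Simulate one categorical series from an explicit conditional table.

    ``table`` has shape (C, .., C, C) — one axis per entry of ``lags`` (the
    relevant own-lags, e.g. (1, 3, 4)) plus the final axis holding the
    distribution over the next symbol.
    """
    table = np.asarray(table, dtype=float)
    C = table.shape[-1]
    gen = GroundTruthGenerator(
        names=(name,),
        cardinalities={name: C},
        parents={name: tuple((name, int(l)) for l in lags)},
        tables={name: table},
        burn_in=burn_in,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    out = _simulate_network(gen, T, rng)
    return CategoricalSeries(out[name], C, name=name)


def simulate_generic(lag_structure, cardinalities, T, seed=None,
                     burn_in=DEFAULT_BURN_IN, concentration=1.0):
    """Simulate a network of categorical series with random ground truth.

    Parameters
    ----------
    lag_structure : dict
        name -> iterable of (parent_name, lag) pairs; an empty set makes
        the series iid with a random marginal.
    cardinalities : dict
        name -> number of categories.
    T : int
        Emitted length per series.
    concentration : float
        Dirichlet concentration of the random table rows.

    Returns
    -------
    (list of CategoricalSeries, GroundTruthGenerator)
    """
    if T < 1:
        raise CatfusionError("T must be >= 1")
    names = tuple(lag_structure.keys())
    rng = np.random.default_rng(seed)
    tables = {}
    parents = {}
    for name in names:
        ps = tuple((str(s), int(l)) for s, l in lag_structure[name])
        for s, l in ps:
            if s not in cardinalities:
                raise CatfusionError(f"unknown parent source {s!r}")
            if l < 1:
                raise CatfusionError("lags must be >= 1")
        parents[name] = ps
        shape = tuple(cardinalities[s] for s, _ in ps) + (cardinalities[name],)
        g = rng.gamma(concentration, size=shape)
        tables[name] = g / g.sum(axis=-1, keepdims=True)
    gen = GroundTruthGenerator(
        names=names,
        cardinalities=dict(cardinalities),
        parents=parents,
        tables=tables,
        burn_in=burn_in,
        seed=seed,
    )
    out = _simulate_network(gen, T, rng)
    series = [
        CategoricalSeries(out[name], cardinalities[name], name=name) for name in names
    ]
    return series, gen
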