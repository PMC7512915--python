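"""Categorical time series and lag embedding.

A categorical (symbol) time series is a sequence of integer category codes.
Granger-style questions about several such series are posed through a lagged
regression: the response at time t is modelled conditionally on a fixed
window of its own past and the past of the other series,

    p(y_t | y_{t-1}, ..., y_{t-Dy}, theta_{t-1}, ..., theta_{t-Dtheta}).

The lagged predictors are collected into a single vector z_t of length
q = sum of the block depths, and the aligned pairs {(y_t, z_t)} form a
:class:`RegressionDataset` — the input to every model in this package.

Internally codes are 0-based and half-open in [0, C); CSV I/O maps arbitrary
symbol labels to codes and keeps the dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, CatfusionError, InsufficientDataError

__all__ = [
    "CategoricalSeries",
    "LagSpec",
    "RegressionDataset",
    "build_lagged_dataset",
    "read_series_csv",
    "write_series_csv",
]


@dataclass
class CategoricalSeries:
    """An integer-coded categorical series.

    Parameters
    ----------
    codes : array-like of int
        Category codes in ``[0, n_categories)``, one per time step.
    n_categories : int
        Number of categories C (alphabet size).
    name : str
        Label used to refer to this series in lag specifications.
    labels : sequence, optional
        Original symbol labels, ``labels[code]`` being the symbol the code
        stands for. Defaults to the codes themselves.
    """

    codes: np.ndarray
    n_categories: int
    name: str = "y"
    labels: tuple = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 1 or self.codes.size < 1:
            raise CatfusionError(f"series {self.name!r} must be a non-empty 1-d sequence")
        if not np.issubdtype(self.codes.dtype, np.integer):
            if not np.all(self.codes == np.floor(self.codes)):
                raise CatfusionError(f"series {self.name!r} has non-integer codes")
            self.codes = self.codes.astype(np.int64)
        if self.n_categories < 1:
            raise CatfusionError("n_categories must be >= 1")
        if self.codes.min() < 0 or self.codes.max() >= self.n_categories:
            raise CatfusionError(
                f"series {self.name!r}: codes must lie in [0, {self.n_categories})"
            )
        if self.labels is None:
            self.labels = tuple(range(self.n_categories))
        else:
            self.labels = tuple(self.labels)
            if len(self.labels) != self.n_categories:
                raise CatfusionError("labels must have length n_categories")

    def __len__(self):
        return self.codes.size

    @classmethod
    def from_labels(cls, values, name="y", categories=None):
        """Build from arbitrary symbol labels; codes follow sorted label order
        (or the explicit ``categories`` order)."""
        values = pd.Series(list(values))
        if values.isna().any():
            raise CatfusionError(f"series {name!r} contains missing values")
        if categories is None:
            categories = sorted(pd.unique(values))
        cat = pd.Categorical(values, categories=categories)
        if (cat.codes < 0).any():
            raise CatfusionError(f"series {name!r} has values outside the declared categories")
        return cls(cat.codes.astype(np.int64), len(categories), name=name, labels=categories)


@dataclass(frozen=True)
class LagSpec:
    """Which lags of which series predict the response.

    ``blocks`` is an ordered list of ``(source_name, max_lag)`` pairs; block
    ``(s, D)`` contributes predictors ``s[t-1], ..., s[t-D]`` in that order.
    The total number of predictors is ``q = sum of the D's``.
    """

    response: str
    blocks: tuple

    def __post_init__(self):
        blocks = tuple((str(s), int(d)) for s, d in self.blocks)
        object.__setattr__(self, "blocks", blocks)
        if len(blocks) == 0:
            raise CatfusionError("LagSpec needs at least one block")
        names = [s for s, _ in blocks]
        if len(set(names)) != len(names):
            raise CatfusionError("duplicate source in LagSpec blocks")
        for s, d in blocks:
            if d < 1:
                raise CatfusionError(f"max lag for source {s!r} must be >= 1 (got {d})")

    @classmethod
    def own_first(cls, response, sources, max_lag):
        """Uniform depth for every source, response's own lags first."""
        order = [response] + [s for s in sources if s != response]
        return cls(response, tuple((s, max_lag) for s in order))

    @property
    def q(self):
        return sum(d for _, d in self.blocks)

    @property
    def max_lag(self):
        return max(d for _, d in self.blocks)

    @property
    def index_map(self):
        """j -> (source, lag), 0-based j, following block order."""
        out = []
        for s, d in self.blocks:
            out.extend((s, lag) for lag in range(1, d + 1))
        return tuple(out)

    def predictor_names(self):
        return tuple(f"{s}(t-{lag})" for s, lag in self.index_map)

    def indices_for(self, source):
        """0-based predictor indices contributed by ``source``."""
        idx = tuple(j for j, (s, _) in enumerate(self.index_map) if s == source)
        if not idx:
            raise CatfusionError(f"source {source!r} not present in lag spec")
        return idx


@dataclass
class RegressionDataset:
    """Aligned response/predictor pairs for the tensor regression.

    ``y`` has length T with codes in ``[0, C0)``; ``z`` is T x q with column
    j in ``[0, C[j])``.
    """

    y: np.ndarray
    z: np.ndarray
    C0: int
    C: np.ndarray
    lag_spec: LagSpec = None
    response_labels: tuple = None
    predictor_labels: tuple = None  # per-column label tuples

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.int64)
        self.z = np.asarray(self.z, dtype=np.int64)
        self.C = np.asarray(self.C, dtype=np.int64)
        if self.z.ndim != 2 or self.y.ndim != 1 or self.z.shape[0] != self.y.size:
            raise CatfusionError("y and z must be aligned (T,) and (T, q) arrays")
        if self.C.size != self.z.shape[1]:
            raise CatfusionError("C must give one cardinality per predictor column")
        if self.y.size == 0:
            raise InsufficientDataError("empty dataset")
        if self.y.min() < 0 or self.y.max() >= self.C0:
            raise CatfusionError("response codes out of [0, C0)")
        for j in range(self.q):
            col = self.z[:, j]
            if col.min() < 0 or col.max() >= self.C[j]:
                raise CatfusionError(f"predictor column {j} out of [0, {self.C[j]})")

    @property
    def T(self):
        return self.y.size

    @property
    def q(self):
        return self.z.shape[1]

    def predictor_level_counts(self):
        """n_{j,c} = #{t : z_{j,t} = c}, returned as a list of arrays."""
        return [np.bincount(self.z[:, j], minlength=self.C[j]) for j in range(self.q)]

    def names(self):
        if self.lag_spec is not None:
            return self.lag_spec.predictor_names()
        return tuple(f"z{j + 1}" for j in range(self.q))


def build_lagged_dataset(series, lag_spec):
    """Embed aligned categorical series into regression form.

    Parameters
    ----------
    series : sequence of CategoricalSeries
        Must contain the response and every source named in ``lag_spec``,
        all of equal length.
    lag_spec : LagSpec

    Returns
    -------
    RegressionDataset
        With ``T = raw length - max lag`` rows; row t holds the response at
        aligned time t and ``z[t, j]`` the (source, lag) value per the index
        map.
    """
    by_name = {s.name: s for s in series}
    if lag_spec.response not in by_name:
        raise CatfusionError(f"response series {lag_spec.response!r} not supplied")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise AlignmentError(f"series lengths differ: { {s.name: len(s) for s in series} }")
    (T_raw,) = lengths
    D = lag_spec.max_lag
    if T_raw <= D:
        raise InsufficientDataError(
            f"need length > max lag ({D}); got {T_raw}"
        )
    for name, _ in lag_spec.blocks:
        if name not in by_name:
            raise CatfusionError(f"source series {name!r} not supplied")

    T = T_raw - D
    q = lag_spec.q
    z = np.empty((T, q), dtype=np.int64)
    C = np.empty(q, dtype=np.int64)
    plabels = []
    for j, (name, lag) in enumerate(lag_spec.index_map):
        src = by_name[name]
        z[:, j] = src.codes[D - lag : T_raw - lag]
        C[j] = src.n_categories
        plabels.append(src.labels)
    resp = by_name[lag_spec.response]
    return RegressionDataset(
        y=resp.codes[D:],
        z=z,
        C0=resp.n_categories,
        C=C,
        lag_spec=lag_spec,
        response_labels=resp.labels,
        predictor_labels=tuple(plabels),
    )


def read_series_csv(path, categories=None):
    """Read one categorical series per column; header row gives names.

    Missing values are rejected. ``categories`` optionally maps a column
    name to an explicit label order.
    """
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise CatfusionError(f"{path}: missing values are not allowed")
    categories = categories or {}
    return [
        CategoricalSeries.from_labels(df[col], name=str(col), categories=categories.get(col))
        for col in df.columns
    ]


def write_series_csv(path, series):
    """Write series as one labelled column each."""
    data = {}
    for s in series:
        labels = np.asarray(s.labels, dtype=object)
        data[s.name] = labels[s.codes]
    pd.DataFrame(data).to_csv(path, index=False)
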