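"""Country-level drivers of irrigation-technique transitions.

Countries upgrade from flood towards sprinkler/drip irrigation at a speed
set by their socio-institutional capacity and hydro-climatic conditions.
This module turns country trajectories of four socioeconomic indicators
(GDP per capita, governance strength, urbanisation, gender-inequality
index) and a 20-year-mean precipitation normal into an annual flood-share
reduction rate, in four steps:

1. correlation screening (Spearman) of candidate driver variables,
2. a PCA of the four socioeconomic indicators, fitted once on the
   historical (2010) cross-country baseline and frozen for projections,
3. min-max normalisation of the PC1 score and of precipitation against
   their historical baselines,
4. a bin-lookup of adjusting factors (s, h) and the annual rate
   r = default − h + s (percentage points of flood share per year),
   floored at zero, valid for the following 5-year window.

The sign conventions: a larger socio factor *s* speeds the transition up;
a wetter climate (larger h) slows it down, since abundant water weakens
the incentive to save it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InputError,
    InsufficientDataError,
)

SOCIO_VARS = ("gdp", "gov", "urb", "gii")


def spearman_rho(x, y) -> float:
    """Spearman rank correlation between two country-level samples.

    Pairs with a missing value in either argument are dropped; at least
    three complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 complete pairs for a rank correlation, got {x.size}"
        )
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


class SocioEconomicIndex:
    """First-principal-component index of socioeconomic capacity.

    A scikit-learn-style estimator: ``fit`` standardises the four
    indicator columns (GDP, GOV, URB, GII) over the fitting countries and
    extracts principal components; ``transform`` projects (possibly
    future) country-years onto the first component with the frozen model.

    The PC1 sign is fixed so that the score correlates positively with
    GDP, i.e. richer/better-governed/more-urban countries score high.

    Attributes (after ``fit``)
    --------------------------
    mean_, scale_ : per-variable standardisation constants
    components_ : (4, 4) loading matrix, rows orthonormal
    explained_variance_ratio_ : non-increasing, sums to 1
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def get_params(self, deep: bool = True) -> dict:
        return {"n_components": self.n_components}

    def set_params(self, **params) -> "SocioEconomicIndex":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [v for v in SOCIO_VARS if v not in X.columns]
            if missing:
                raise InputError(f"missing driver variables: {missing}")
            X = X.loc[:, list(SOCIO_VARS)].to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("expected a 2-D (countries x variables) matrix")
        if np.isnan(X).any():
            raise InputError("driver matrix contains missing values")
        return X

    def fit(self, X, y=None) -> "SocioEconomicIndex":
        X = self._as_matrix(X)
        if X.shape[0] < 5:
            raise InsufficientDataError(
                f"need >= 5 countries to fit the PCA, got {X.shape[0]}"
            )
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=0)
        if np.any(self.scale_ == 0):
            bad = np.flatnonzero(self.scale_ == 0).tolist()
            raise DegenerateInputError(f"constant driver column(s): {bad}")
        Z = (X - self.mean_) / self.scale_
        pca = PCA(n_components=self.n_components)
        pca.fit(Z)
        self.components_ = pca.components_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        # sign convention: PC1 increases with GDP (column 0)
        if self.components_[0, 0] < 0:
            self.components_[0] *= -1.0
        return self

    def transform(self, X) -> np.ndarray:
        """Project rows onto PC1; returns a 1-D score array."""
        if not hasattr(self, "components_"):
            raise ConfigurationError("estimator is not fitted")
        X = self._as_matrix(X)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_[0]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def fit_pca(matrix) -> SocioEconomicIndex:
    """Fit the socioeconomic PCA on a countries x 4 baseline matrix."""
    return SocioEconomicIndex().fit(matrix)


def project_pc1(model: SocioEconomicIndex, drivers) -> np.ndarray:
    """PC1 scores for country-years under a frozen baseline model."""
    return model.transform(drivers)


def normalize(value, baseline) -> np.ndarray | float:
    """Min-max scale ``value`` against a historical baseline sample.

    The baseline minimum maps to 0 and the maximum to 1; values outside
    the baseline range map outside [0, 1] (projections may legitimately
    exceed the historical envelope).
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.size == 0:
        raise DegenerateInputError("empty normalisation baseline")
    lo, hi = float(baseline.min()), float(baseline.max())
    if not hi > lo:
        raise DegenerateInputError("degenerate baseline: min == max")
    out = (np.asarray(value, dtype=float) - lo) / (hi - lo)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FactorTable:
    """Bin lookup from normalised drivers to adjusting factors.

    ``socio_edges``/``hydro_edges`` are interior bin edges on the
    normalised scores (bins are left-closed/right-open and cover the real
    line); ``socio_factors``/``hydro_factors`` give the factor for each
    bin and must be non-decreasing, with one more entry than edges. The
    annual flood-share reduction rate is
    ``default_rate − h + s`` (percentage points per year), floored at 0.

    The shipped default spans a wider factor range on the socio axis than
    on the hydro axis, reflecting the stronger observed association of
    socioeconomic capacity with technique shares; both axes have a zero
    (neutral) bottom bin so that an average country keeps the default
    1 % yr⁻¹ rate.
    """

    socio_edges: tuple = (0.25, 0.50, 0.75, 1.00)
    socio_factors: tuple = (0.0, 0.2, 0.4, 0.6, 0.8)
    hydro_edges: tuple = (0.25, 0.50, 0.75)
    hydro_factors: tuple = (0.0, 0.1, 0.15, 0.2)
    default_rate: float = 1.0
    _validated: bool = field(default=False, compare=False)

    def validate(self) -> "FactorTable":
        for edges, factors, name in (
            (self.socio_edges, self.socio_factors, "socio"),
            (self.hydro_edges, self.hydro_factors, "hydro"),
        ):
            if len(factors) != len(edges) + 1:
                raise ConfigurationError(
                    f"{name}: need len(factors) == len(edges)+1"
                )
            if list(edges) != sorted(edges):
                raise ConfigurationError(f"{name}: edges must be sorted")
            if list(factors) != sorted(factors):
                raise ConfigurationError(
                    f"{name}: factors must be non-decreasing"
                )
        object.__setattr__(self, "_validated", True)
        return self

    @classmethod
    def default(cls) -> "FactorTable":
        return cls().validate()


def _lookup(value, edges, factors) -> np.ndarray:
    idx = np.searchsorted(np.asarray(edges), np.asarray(value, dtype=float),
                          side="right")
    return np.asarray(factors, dtype=float)[idx]


def classify_factors(socio_norm, hydro_norm, table: FactorTable):
    """Adjusting factors (s, h) for normalised driver values.

    Bin-edge ties resolve left-closed/right-open: a value exactly on an
    edge belongs to the upper bin.
    """
    if not table._validated:
        raise ConfigurationError("FactorTable must be validated before use")
    s = _lookup(socio_norm, table.socio_edges, table.socio_factors)
    h = _lookup(hydro_norm, table.hydro_edges, table.hydro_factors)
    if s.ndim == 0:
        return float(s), float(h)
    return s, h


def annual_rate(s, h, table: FactorTable):
    """Annual flood-share reduction rate, percentage points per year.

    ``r = default_rate − h + s``, floored at zero: techniques never
    regress towards flood irrigation.
    """
    r = np.maximum(table.default_rate - np.asarray(h, dtype=float)
                   + np.asarray(s, dtype=float), 0.0)
    return float(r) if r.ndim == 0 else r


def rates_for_countries(
    drivers: pd.DataFrame,
    model: SocioEconomicIndex,
    socio_baseline,
    hydro_baseline,
    table: FactorTable,
) -> pd.DataFrame:
    """Per-country annual rates from a driver table.

    ``drivers`` needs columns country, year, the four socio variables and
    ``precip20`` (20-year-mean precipitation, mm yr⁻¹). Each row yields
    the rate valid for the 5-year window starting at ``year``.
    """
    pc1 = project_pc1(model, drivers)
    socio_norm = normalize(pc1, socio_baseline)
    hydro_norm = normalize(drivers["precip20"].to_numpy(), hydro_baseline)
    s, h = classify_factors(socio_norm, hydro_norm, table)
    out = drivers.loc[:, ["country", "year"]].copy()
    out["pc1"] = pc1
    out["socio_norm"] = socio_norm
    out["hydro_norm"] = hydro_norm
    out["s"] = s
    out["h"] = h
    out["rate"] = annual_rate(s, h, table)
    return out
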