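"""Reactivity-ratio estimation from excess-monomer kinetics.

When one monomer ("ex") is in large excess, essentially every growing chain
end carries an ex-terminal unit, so the consumption of each minor monomer j
obeys ``d[M_ex]/d[M_j] = r_{ex,j} [M_ex]/[M_j]``.  Integrating gives the
zero-intercept log-log law

    ln([M_ex]_0 / [M_ex]_t) = r_{ex,j} * ln([M_j]_0 / [M_j]_t),

so one quaternary experiment yields a full row of the reactivity matrix from
through-origin regressions of the excess-monomer log consumption on each
minor monomer's log consumption.  Four experiments (each monomer in excess in
turn) assemble the complete matrix.  The approach is approximate at finite
excess ratio because a small fraction of chain ends are not ex-terminal;
:func:`jaacks_bias` quantifies that approximation error by simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chemistry import MonomerRegistry, ReactivityMatrix, validate_reactivity_matrix
from .simulate import FeedState

__all__ = ["KineticsDataset", "JaacksModel", "JaacksResults", "jaacks_fit",
           "assemble_matrix", "jaacks_bias"]

#: Minor-monomer residual fraction below which timepoints are dropped
#: (the log transform amplifies noise without bound as residuals -> 0).
MIN_RESIDUAL = 0.05


@dataclass(frozen=True)
class KineticsDataset:
    """Residual-monomer kinetics for one excess-monomer experiment.

    ``residuals`` is a timepoint x monomer table of fractions
    ``[M_k](t)/[M_k](0)`` with a first row of exact ones; ``codes`` orders the
    columns; ``excess_index`` marks the monomer run in excess.
    """

    residuals: np.ndarray
    codes: tuple[str, ...]
    excess_index: int
    feed0: FeedState
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        res = np.asarray(self.residuals, dtype=float)
        if res.ndim != 2 or res.shape[1] != len(self.codes):
            raise ValueError("residuals must be a timepoints x monomers table")
        if np.any(res <= 0) or np.any(res > 1 + 1e-9):
            raise ValueError("residual fractions must lie in (0, 1]")
        if not np.allclose(res[0], 1.0):
            raise ValueError("first row of residuals must be exactly 1.0")
        if not 0 <= self.excess_index < len(self.codes):
            raise ValueError("excess_index outside the monomer set")
        object.__setattr__(self, "residuals", res)

    @property
    def excess_code(self) -> str:
        return self.codes[self.excess_index]

    def to_frame(self) -> pd.DataFrame:
        t = self.time if self.time is not None else np.arange(len(self.residuals))
        df = pd.DataFrame(self.residuals, columns=list(self.codes))
        df.insert(0, "time", t)
        return df


class JaacksModel:
    """Through-origin log-log regression model for one excess experiment.

    Follows the model/results idiom: construct from a
    :class:`KineticsDataset`, call :meth:`fit` to obtain a
    :class:`JaacksResults`.
    """

    def __init__(self, dataset: KineticsDataset, min_residual: float = MIN_RESIDUAL):
        self.dataset = dataset
        self.min_residual = min_residual
        res = dataset.residuals
        ex = dataset.excess_index
        if res.shape[0] < 3:
            raise ValueError("need at least 2 timepoints beyond t=0")
        if res[-1, ex] >= 1.0 - 1e-12:
            raise ValueError("no measurable consumption of the excess monomer")
        drops = np.diff(res, axis=0)
        if np.any(drops > 0.05):
            warnings.warn("non-monotone residual fractions beyond noise tolerance",
                          stacklevel=2)

    def fit(self, se_method: str = "ols", n_boot: int = 200, seed: int = 0) -> "JaacksResults":
        """Estimate r_{ex,j} for every minor monomer j.

        ``se_method`` is ``"ols"`` (analytic through-origin OLS standard
        error) or ``"bootstrap"`` (pairs bootstrap over timepoints, which is
        more honest for serially correlated cumulative-conversion data).
        """
        ds = self.dataset
        res = ds.residuals
        ex = ds.excess_index
        y_all = np.log(1.0 / res[1:, ex])
        estimates: dict[str, float] = {}
        ses: dict[str, float] = {}
        npts: dict[str, int] = {}
        rng = np.random.default_rng(seed)
        for j, code in enumerate(ds.codes):
            if j == ex:
                continue
            keep = res[1:, j] >= self.min_residual
            x = np.log(1.0 / res[1:, j][keep])
            y = y_all[keep]
            if len(x) < 1 or np.all(x == 0):
                raise ValueError(f"zero consumption of monomer {code}; slope undefined")
            ols = sm.OLS(y, x[:, None]).fit()
            slope = float(ols.params[0])
            if slope <= 0:
                raise ValueError(f"non-positive slope estimate for monomer {code}")
            if se_method == "bootstrap":
                idx = rng.integers(0, len(x), size=(n_boot, len(x)))
                bx, by = x[idx], y[idx]
                denom = (bx * bx).sum(axis=1)
                ok = denom > 0
                slopes = (bx * by).sum(axis=1)[ok] / denom[ok]
                se = float(np.std(slopes, ddof=1)) if ok.sum() > 1 else np.nan
            elif se_method == "ols":
                se = float(ols.bse[0]) if len(x) > 1 else 0.0
            else:
                raise ValueError(f"unknown se_method {se_method!r}")
            estimates[code] = slope
            ses[code] = se
            npts[code] = int(len(x))
        return JaacksResults(model=self, r_estimates=estimates,
                             standard_errors=ses, n_points=npts)


@dataclass
class JaacksResults:
    """Fitted reactivity ratios r_{excess, j} for one experiment."""

    model: JaacksModel
    r_estimates: dict[str, float]
    standard_errors: dict[str, float]
    n_points: dict[str, int]

    @property
    def excess_code(self) -> str:
        return self.model.dataset.excess_code

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.r_estimates, name=f"r_{self.excess_code}/j")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.standard_errors, name="SE")

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "r_estimate": self.params,
            "SE": self.bse,
            "n_points": pd.Series(self.n_points),
        })
        df.index.name = f"added monomer (terminal={self.excess_code})"
        return df


def jaacks_fit(dataset: KineticsDataset, se_method: str = "ols") -> JaacksResults:
    """Functional wrapper: fit one excess-monomer experiment."""
    return JaacksModel(dataset).fit(se_method=se_method)


def assemble_matrix(fits, registry: MonomerRegistry) -> ReactivityMatrix:
    """Combine one fit per monomer-in-excess into the full reactivity matrix.

    Raises when a row is missing or two fits claim the same excess monomer.
    """
    by_excess: dict[str, JaacksResults] = {}
    for fit in fits:
        code = fit.excess_code
        if code in by_excess:
            raise ValueError(f"conflicting duplicate fits for excess monomer {code}")
        by_excess[code] = fit
    missing = [c for c in registry.codes if c not in by_excess]
    if missing:
        raise ValueError(f"missing excess experiments for monomers: {missing}")
    m = len(registry)
    values = np.eye(m)
    for i, code_i in enumerate(registry.codes):
        fit = by_excess[code_i]
        for j, code_j in enumerate(registry.codes):
            if i == j:
                continue
            if code_j not in fit.r_estimates:
                raise ValueError(f"fit for excess {code_i} lacks entry toward {code_j}")
            values[i, j] = fit.r_estimates[code_j]
    return validate_reactivity_matrix(values, registry)


def jaacks_bias(true_ratios: ReactivityMatrix, excess_ratio: float,
                conversion_cap: float, reps: int, seed: int,
                registry: MonomerRegistry | None = None,
                n_chains: int = 4000, n_timepoints: int = 8,
                mean_dp_target: float = 50.0) -> pd.DataFrame:
    """Relative bias (r_hat - r)/r of the estimator at a finite excess ratio.

    Simulates noiseless kinetics (the only stochasticity is the Monte Carlo
    polymerization itself) for each monomer in excess at the given
    ``excess_ratio``, fits, and averages the per-entry relative bias over
    ``reps`` independent replicates.
    """
    from .chemistry import build_monomer_registry
    from .synthetic import NoiseSpec, gen_kinetics

    if excess_ratio <= 1:
        raise ValueError("excess_ratio must exceed 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if registry is None:
        registry = build_monomer_registry()
    m = len(registry)
    bias = np.zeros((m, m))
    rng = np.random.default_rng(seed)
    for rep in range(reps):
        fits = []
        for ex in range(m):
            ratio = np.ones(m)
            ratio[ex] = excess_ratio
            ds = gen_kinetics(
                true_ratios, FeedState.from_ratio(ratio),
                n_timepoints=n_timepoints, stop_conversion=conversion_cap,
                noise=NoiseSpec(multiplicative_sd=0.0, seed=int(rng.integers(2**31))),
                excess_index=ex, n_chains=n_chains, mean_dp_target=mean_dp_target,
                registry=registry,
            )
            fits.append(jaacks_fit(ds))
        est = assemble_matrix(fits, registry)
        bias += (est.values - true_ratios.values) / true_ratios.values
    bias /= reps
    np.fill_diagonal(bias, 0.0)
    return pd.DataFrame(bias, index=registry.codes, columns=registry.codes)
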