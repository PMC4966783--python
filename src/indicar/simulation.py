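"""Synthetic-data generator, standardization comparison method and benchmark.

The generator emulates a disease-mapping study on a square lattice of
regions.  Per region: the number of subjects is uniform on a configurable
range, the per-region prevalence of a binary covariate (sex) is uniform on
(0.45, 0.55), and one standard-normal group covariate is drawn.  Per
subject: a 6-category covariate (age band) with fixed class probabilities,
reference-coded, and a continuous covariate uniform on (0.2, 1).  The
spatial effect ``b`` is multivariate normal with the Leroux covariance and
the outcome is Poisson with log-mean ``X beta + Z U gamma + Z b``.

Defaults follow the benchmark design: a 20 x 20 lattice (400 regions),
``sigma = 0.4`` and spatial dependence ``lambda`` in {0, 0.25, 0.50, 0.75,
0.99}, with regression coefficients

``beta = (-0.2, -2.5, 0.7, -2.0, -1.5, 0.2, 0.5, 0.8)`` (intercept, binary,
continuous, five category contrasts) and ``gamma = 0.2``.

The comparison ("standardization-only") method mirrors traditional areal
practice: individual covariates enter only through an indirect age–sex
standardization offset ``log E_j``, and a group-level CAR model is fitted to
the aggregated counts with the group covariate (plus intercept).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.linalg import cholesky, solve_triangular

from .backfit import FitOptions, fit_indicar
from .car_pql import GroupModelFit, fit_group_car
from .data_model import IndividualTable, RegionTable, aggregate_counts
from .errors import DataError
from .spatial import (AdjacencyStructure, LerouxParams, lattice_adjacency,
                      leroux_precision, build_structure_matrix)

#: Default 6-category age-band probabilities (youngest to oldest); a
#: six-level collapse resembling the age mix of an adult cancer cohort.
DEFAULT_AGE_PROBS = (0.02, 0.04, 0.10, 0.19, 0.26, 0.39)

DEFAULT_BETA = (-0.2, -2.5, 0.7, -2.0, -1.5, 0.2, 0.5, 0.8)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one simulation scenario (a single true ``lambda``)."""

    rows: int = 20
    cols: int = 20
    n_subjects_range: tuple = (10, 1000)
    beta_true: tuple = DEFAULT_BETA
    gamma_true: float = 0.2
    sigma_true: float = 0.4
    lambda_true: float = 0.5
    n_replicates: int = 1000
    seed: int = 20160729
    age_probs: tuple = DEFAULT_AGE_PROBS
    sex_prob_range: tuple = (0.45, 0.55)

    def __post_init__(self):
        if abs(sum(self.age_probs) - 1.0) > 1e-9 or min(self.age_probs) <= 0:
            raise ValueError("age_probs must be positive and sum to 1")
        lo, hi = self.n_subjects_range
        if lo < 1 or hi < lo:
            raise ValueError("n_subjects_range must be a positive interval")
        if not (0 <= self.lambda_true < 1):
            raise ValueError("lambda_true must lie in [0, 1); use 0.99 for "
                             "near-intrinsic dependence")
        if len(self.beta_true) != 3 + len(self.age_probs) - 1:
            raise ValueError("beta_true must have intercept + binary + "
                             "continuous + (n_categories - 1) entries")

    @property
    def theta_true(self) -> LerouxParams:
        return LerouxParams(sigma2=self.sigma_true ** 2, lam=self.lambda_true)


def simulate_dataset(config: SimulationConfig, replicate_seed: int | None = None):
    """Draw one synthetic dataset.

    Returns ``(data, regions, adj, truth)`` where ``truth`` records every
    generating value (coefficients, theta, the drawn ``b``, region sizes and
    the seed actually used).
    """
    seed = config.seed if replicate_seed is None else replicate_seed
    rng = np.random.default_rng(seed)
    adj = lattice_adjacency(config.rows, config.cols)
    M = adj.n_regions
    R = build_structure_matrix(adj)

    lo, hi = config.n_subjects_range
    n_j = rng.integers(lo, hi + 1, size=M)
    n = int(n_j.sum())
    g = np.repeat(np.arange(M), n_j)

    sex_p = rng.uniform(*config.sex_prob_range, size=M)
    sex = rng.binomial(1, sex_p[g]).astype(float)
    n_cat = len(config.age_probs)
    age = rng.choice(n_cat, size=n, p=np.asarray(config.age_probs)) + 1
    cont = rng.uniform(0.2, 1.0, size=n)
    u = rng.standard_normal(M)

    # b ~ N(0, D) sampled through the precision Cholesky: P = L L' gives
    # b = L'^{-1} z with cov(b) = P^{-1} = D, avoiding the explicit inverse.
    P = leroux_precision(config.theta_true, R)
    L = cholesky(P, lower=True)
    b = solve_triangular(L.T, rng.standard_normal(M), lower=False)

    dummies = np.column_stack([(age == k).astype(float)
                               for k in range(2, n_cat + 1)])
    X = np.column_stack([np.ones(n), sex, cont, dummies])
    x_names = (["intercept", "sex", "cont"]
               + [f"age_group[{k}]" for k in range(2, n_cat + 1)])
    beta = np.asarray(config.beta_true, dtype=float)
    eta = X @ beta + (u * config.gamma_true + b)[g]
    y = rng.poisson(np.exp(eta))

    frame = pd.DataFrame({
        "region": [adj.region_labels[j] for j in g],
        "sex": sex.astype(int), "age_group": age, "cont": cont,
    })
    data = IndividualTable(y=y, X=X, region_index=g, n_regions=M,
                           x_names=x_names,
                           frame=frame[["sex", "age_group", "cont"]],
                           region_labels=list(adj.region_labels))
    regions = RegionTable(U=u[:, None], region_labels=adj.region_labels,
                          u_names=["u"])
    truth = {
        "beta": beta, "gamma": config.gamma_true,
        "sigma": config.sigma_true, "lambda": config.lambda_true,
        "b": b, "n_j": n_j, "seed": seed,
    }
    return data, regions, adj, truth


def schema_for_simulated() -> dict:
    """Covariate schema matching the columns written by the simulator."""
    return {
        "region_column": "region",
        "outcome_column": "y",
        "covariates": [
            {"name": "sex", "type": "numeric"},
            {"name": "cont", "type": "numeric"},
            {"name": "age_group", "type": "categorical",
             "levels": [1, 2, 3, 4, 5, 6]},
        ],
    }


def standardization_offset(data: IndividualTable,
                           strata_columns=("sex", "age_group")):
    """Indirect standardization over the given strata.

    Pooled stratum rates ``r_s = (events in s) / (subjects in s)`` yield
    per-region expected counts ``E_j = sum_s n_js r_s``; the total expected
    count equals the total observed count by construction.

    Returns ``(offset, expected)``: a per-subject offset ``log r_s(i)`` and
    the per-region expected counts.  A stratum with no events falls back to
    the pooled overall rate with a warning (its own rate would make the log
    offset undefined).
    """
    if data.frame is None:
        raise DataError("individual table has no raw covariate frame; "
                        "stratified standardization needs the original columns")
    for col in strata_columns:
        if col not in data.frame.columns:
            raise DataError(f"stratum column {col!r} not in covariate frame")
    key = data.frame[list(strata_columns)].astype(str).agg("|".join, axis=1)
    codes, _ = pd.factorize(key)
    y = np.asarray(data.y, dtype=float)
    n_s = np.bincount(codes)
    y_s = np.bincount(codes, weights=y)
    rates = y_s / n_s
    if np.any(rates <= 0):
        pooled = y.sum() / len(y)
        bad = int((rates <= 0).sum())
        warnings.warn(f"{bad} stratum/strata with no events: using the "
                      f"pooled rate {pooled:.4g}", stacklevel=2)
        rates = np.where(rates > 0, rates, pooled)
    r_i = rates[codes]
    expected = np.bincount(data.region_index, weights=r_i,
                           minlength=data.n_regions)
    return np.log(r_i), expected


def compute_sir(observed, expected) -> np.ndarray:
    """Standardized incidence ratios ``SIR_j = O_j / E_j``."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same length")
    if np.any(expected <= 0):
        raise DataError("expected counts must be strictly positive")
    return observed / expected


def fit_leroux_standardized(data: IndividualTable, regions: RegionTable,
                            adj: AdjacencyStructure,
                            strata_columns=("sex", "age_group"),
                            theta_init=None, **fit_kwargs) -> GroupModelFit:
    """Comparison method: group-level CAR fit after indirect standardization.

    Individual covariates enter only through the age–sex expected counts
    ``E_j``; the model is ``Y_c,j ~ Poisson{exp(log E_j + gamma_0 +
    u_j gamma + b_j)}`` with a Leroux CAR effect.  The intercept absorbs
    residual calibration of the standardization.
    """
    _, expected = standardization_offset(data, strata_columns)
    y_c = aggregate_counts(data)
    U_comp = np.column_stack([np.ones(regions.M), regions.U])
    R = build_structure_matrix(adj)
    return fit_group_car(y_c, U_comp, np.log(expected), R,
                         theta_init=theta_init, **fit_kwargs)


_PARAM_NAMES = ("beta0", "beta1", "beta2", "beta32", "beta33", "beta34",
                "beta35", "beta36", "gamma", "sigma", "lambda")


def run_simulation_study(config: SimulationConfig,
                         methods=("indicar", "leroux_standardized"),
                         fit_options: FitOptions | None = None) -> pd.DataFrame:
    """Run the replicate study for one scenario and summarize it.

    For each replicate ``r`` (seeded ``config.seed + r``): simulate a
    dataset, fit the full individual-covariate model and/or the
    standardization-only comparison, and record parameter estimates and
    model-based standard errors.  The summary has one row per (method,
    parameter): mean estimate, empirical SE (SD across replicates; NaN for a
    single replicate) and mean model-based SE (NaN where no model SE is
    defined, i.e. for sigma and lambda).

    Replicate-level fit failures are excluded and counted in the
    ``n_failed`` column.  Deterministic given ``config.seed``.
    """
    rows = {m: [] for m in methods}
    ses = {m: [] for m in methods}
    failures = {m: 0 for m in methods}
    truths = {
        "beta0": config.beta_true[0], "beta1": config.beta_true[1],
        "beta2": config.beta_true[2], "beta32": config.beta_true[3],
        "beta33": config.beta_true[4], "beta34": config.beta_true[5],
        "beta35": config.beta_true[6], "beta36": config.beta_true[7],
        "gamma": config.gamma_true, "sigma": config.sigma_true,
        "lambda": config.lambda_true,
    }
    for r in range(config.n_replicates):
        data, regions, adj, _ = simulate_dataset(config, config.seed + r)
        if "indicar" in methods:
            try:
                fit = fit_indicar(data, regions, adj, fit_options)
                est = np.concatenate([fit.beta, fit.gamma,
                                      [fit.theta.sigma, fit.theta.lam]])
                se = np.concatenate([fit.se_beta, fit.se_gamma,
                                     [np.nan, np.nan]])
                rows["indicar"].append(est)
                ses["indicar"].append(se)
            except Exception:
                failures["indicar"] += 1
        if "leroux_standardized" in methods:
            try:
                gfit = fit_leroux_standardized(data, regions, adj)
                est = np.array([gfit.gamma[1], gfit.theta.sigma,
                                gfit.theta.lam])
                se = np.array([np.sqrt(gfit.cov_gamma_naive[1, 1]),
                               np.nan, np.nan])
                rows["leroux_standardized"].append(est)
                ses["leroux_standardized"].append(se)
            except Exception:
                failures["leroux_standardized"] += 1

    names = {"indicar": list(_PARAM_NAMES),
             "leroux_standardized": ["gamma", "sigma", "lambda"]}
    out = []
    for method in methods:
        if not rows[method]:
            continue
        est = np.vstack(rows[method])
        se = np.vstack(ses[method])
        emp = (np.std(est, axis=0, ddof=1) if est.shape[0] > 1
               else np.full(est.shape[1], np.nan))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN SE cols
            mean_se = np.nanmean(se, axis=0)
        for k, name in enumerate(names[method]):
            out.append({
                "method": method, "parameter": name,
                "true_value": truths[name],
                "mean_estimate": est[:, k].mean(),
                "empirical_se": emp[k], "mean_model_se": mean_se[k],
                "n_replicates": est.shape[0], "n_failed": failures[method],
            })
    return pd.DataFrame(out)


def study_over_lambdas(config: SimulationConfig, lambdas,
                       **kwargs) -> pd.DataFrame:
    """Run :func:`run_simulation_study` for several spatial-dependence values."""
    frames = []
    for lam in lambdas:
        df = run_simulation_study(replace(config, lambda_true=float(lam)),
                                  **kwargs)
        df.insert(0, "lambda_true", float(lam))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
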