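"""Fractional-polynomial regression of logit(DFPS) on contraceptive prevalence.

The outcome is logit(DFPS) for one indicator; the primary predictor is the
corresponding CPR, transformed by fractional-polynomial powers from the
Royston-Altman set {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (power 0 means ln x; a
repeated power (p, p) contributes x**p and x**p * ln x).  Candidate extra
covariates enter linearly.  Models are fitted by ordinary least squares with
standard errors clustered on country, because subnational regions of one
country are not independent.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .predictor import MIN_CPR, PredictorCoefficients, logit

__all__ = [
    "FP_POWERS",
    "FPModelSpec",
    "FittedModel",
    "LinearFPComparison",
    "SingularDesignError",
    "fp_transform",
    "build_design",
    "fit_ols",
    "fit_model",
    "apply_exclusion",
    "fp_search",
    "compare_linear_fp",
    "outcome_column",
    "predictor_column",
]

logger = logging.getLogger(__name__)

#: Standard fractional-polynomial candidate powers (0 denotes the natural log).
FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

_OUTCOME_COLS = {"DFPSany": "dfps_any", "DFPSm": "dfps_m"}
_PREDICTOR_COLS = {"CPRany": "cpr_any", "CPRm": "cpr_m"}


def outcome_column(outcome: str) -> str:
    try:
        return _OUTCOME_COLS[outcome]
    except KeyError:
        raise ValueError(f"outcome must be one of {tuple(_OUTCOME_COLS)}, got {outcome!r}")


def predictor_column(primary_predictor: str) -> str:
    try:
        return _PREDICTOR_COLS[primary_predictor]
    except KeyError:
        raise ValueError(
            f"primary_predictor must be one of {tuple(_PREDICTOR_COLS)}, got {primary_predictor!r}"
        )


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the collinear columns."""


@dataclass(frozen=True)
class FPModelSpec:
    """A fractional-polynomial design: outcome, primary predictor, powers, extras."""

    outcome: str = "DFPSany"
    primary_predictor: str | None = None
    powers: tuple = (0.0, 2.0)
    extra_covariates: tuple = ("cpdiff",)
    cluster_variable: str = "country_id"

    def __post_init__(self) -> None:
        outcome_column(self.outcome)
        pp = self.primary_predictor
        if pp is None:
            pp = "CPRany" if self.outcome == "DFPSany" else "CPRm"
            object.__setattr__(self, "primary_predictor", pp)
        predictor_column(pp)
        powers = tuple(sorted(float(p) for p in self.powers))
        if not 1 <= len(powers) <= 2:
            raise ValueError("powers must contain one or two entries")
        if any(p not in FP_POWERS for p in powers):
            raise ValueError(f"powers must come from {FP_POWERS}")
        object.__setattr__(self, "powers", powers)
        object.__setattr__(self, "extra_covariates", tuple(self.extra_covariates))

    @property
    def column_names(self) -> list[str]:
        base = predictor_column(self.primary_predictor)
        names = ["intercept"]
        prev = None
        for p in self.powers:
            name = f"log({base})" if p == 0 else f"{base}^{p:g}"
            if prev is not None and p == prev:
                name = f"{base}^{p:g}*log({base})" if p != 0 else f"log({base})^2"
            names.append(name)
            prev = p
        names.extend(self.extra_covariates)
        return names


@dataclass(frozen=True)
class FittedModel:
    """OLS estimates for one FP specification with country-clustered SEs."""

    spec: FPModelSpec
    coefficients: tuple
    robust_se: tuple
    rss: float
    r_squared: float
    n_obs: int
    n_clusters: int

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    @property
    def column_names(self) -> list[str]:
        return self.spec.column_names

    def coefficient(self, name: str) -> float:
        return self.coefficients[self.column_names.index(name)]

    def to_predictor_coefficients(self) -> PredictorCoefficients:
        """Convert a (log, square) + cpdiff fit to a pluggable predictor set."""
        if self.spec.powers != (0.0, 2.0) or self.spec.extra_covariates != ("cpdiff",):
            raise ValueError(
                "only the (log, square) + cpdiff specification maps onto the "
                "published predictor form"
            )
        b0, b_log, b_sq, b_cd = self.coefficients
        return PredictorCoefficients(b0, b_log, b_sq, b_cd, self.spec.outcome)


def fp_transform(x: Sequence[float], powers: Sequence[float]) -> np.ndarray:
    """FP design columns for a positive vector: one column per power, in order.

    Power 0 gives ln x; a repeated power (p, p) gives x**p then x**p * ln x
    (for p = 0: ln x then (ln x)**2).
    """
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x) | (x <= 0)):
        bad = np.flatnonzero(~np.isfinite(x) | (x <= 0))
        raise ValueError(
            f"fractional polynomial requires strictly positive values; "
            f"offending row(s): {bad[:10].tolist()}"
        )
    powers = [float(p) for p in powers]
    cols = []
    prev = None
    for p in powers:
        col = np.log(x) if p == 0 else x**p
        if prev is not None and p == prev:
            col = cols[-1] * np.log(x)
        cols.append(col)
        prev = p
    return np.column_stack(cols)


def build_design(data: pd.DataFrame, spec: FPModelSpec):
    """(X, y, clusters) for a spec: intercept, FP columns, extra covariates."""
    base = predictor_column(spec.primary_predictor)
    x = data[base].to_numpy(dtype=float)
    X = [np.ones(len(data)), *fp_transform(x, spec.powers).T]
    for extra in spec.extra_covariates:
        X.append(data[extra].to_numpy(dtype=float))
    y = logit(data[outcome_column(spec.outcome)].to_numpy(dtype=float))
    clusters = data[spec.cluster_variable].to_numpy()
    return np.column_stack(X), np.asarray(y, dtype=float), clusters


def fit_ols(
    design: np.ndarray,
    outcome_logit: np.ndarray,
    cluster_ids: np.ndarray,
    spec: FPModelSpec | None = None,
    column_names: Sequence[str] | None = None,
) -> FittedModel:
    """Least-squares fit with cluster-robust (sandwich) standard errors.

    The sandwich uses the Stata-style small-sample factor
    G/(G-1) * (N-1)/(N-k).  With every row its own cluster this reduces to the
    heteroskedasticity-robust (HC1) estimator.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome_logit, dtype=float)
    groups = pd.factorize(np.asarray(cluster_ids))[0]
    n, k = X.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows to fit {k} parameters, got {n}")
    n_clusters = int(groups.max()) + 1
    if n_clusters < 2:
        raise ValueError("cluster-robust errors require at least 2 clusters")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise SingularDesignError(
            "rank-deficient design; collinear column(s): "
            f"{_collinear_columns(X, spec, column_names)}"
        )
    res = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": groups, "use_correction": True}
    )
    rss = float(res.ssr)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return FittedModel(
        spec=spec if spec is not None else FPModelSpec(),
        coefficients=tuple(float(c) for c in res.params),
        robust_se=tuple(float(s) for s in res.bse),
        rss=rss,
        r_squared=r2,
        n_obs=n,
        n_clusters=n_clusters,
    )


def _collinear_columns(X, spec, column_names) -> list[str]:
    names = list(column_names) if column_names else (
        spec.column_names if spec else [f"x{i}" for i in range(X.shape[1])]
    )
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X)
    return [names[i] for i in sorted(piv[rank:])]


def fit_model(data: pd.DataFrame, spec: FPModelSpec) -> FittedModel:
    """Convenience wrapper: build the design from an estimation table and fit."""
    X, y, clusters = build_design(data, spec)
    return fit_ols(X, y, clusters, spec=spec)


def apply_exclusion(
    data: pd.DataFrame,
    columns: Sequence[str] = ("cpr_any", "cpr_m"),
    threshold: float = MIN_CPR,
):
    """Drop rows whose prevalence falls below ``threshold``; log each removal.

    Returns (filtered frame, exclusion log).  The default 1% floor guards the
    log transform against instability near zero; a 15% floor reproduces the
    high-prevalence sensitivity restriction.
    """
    data = data.reset_index(drop=True)
    mask = np.zeros(len(data), dtype=bool)
    entries = []
    for col in columns:
        vals = data[col].to_numpy(dtype=float)
        below = vals < threshold
        for i in np.flatnonzero(below & ~mask):
            entries.append({"row": int(i), "column": col, "value": float(vals[i]),
                            "threshold": threshold})
        mask |= below
    log = pd.DataFrame(entries, columns=["row", "column", "value", "threshold"])
    if len(log):
        logger.info("excluded %d row(s) below threshold %g", mask.sum(), threshold)
    return data[~mask].reset_index(drop=True), log


def _power_multisets() -> list[tuple]:
    singles = [(p,) for p in FP_POWERS]
    pairs = [tuple(sorted(c)) for c in itertools.combinations_with_replacement(FP_POWERS, 2)]
    return singles + pairs


def fp_search(
    data: pd.DataFrame,
    outcome: str = "DFPSany",
    primary_predictor: str | None = None,
    candidate_extras: Sequence[str] = ("cpdiff",),
    cluster_variable: str = "country_id",
) -> list[FittedModel]:
    """Exhaustive FP search: every power multiset of size 1-2 crossed with every
    subset of the candidate extra covariates, ranked best first.

    Ranking is by residual sum of squares (equivalent to Gaussian deviance),
    ties broken toward fewer parameters, then lower-degree powers.  The input
    is expected to have passed :func:`apply_exclusion` already.
    """
    fits: list[FittedModel] = []
    failures: list[str] = []
    extra_sets = [
        tuple(c)
        for r in range(len(tuple(candidate_extras)) + 1)
        for c in itertools.combinations(candidate_extras, r)
    ]
    for powers in _power_multisets():
        for extras in extra_sets:
            spec = FPModelSpec(
                outcome=outcome,
                primary_predictor=primary_predictor,
                powers=powers,
                extra_covariates=extras,
                cluster_variable=cluster_variable,
            )
            try:
                fits.append(fit_model(data, spec))
            except (SingularDesignError, ValueError) as exc:
                failures.append(f"{powers}+{extras}: {exc}")
    if not fits:
        raise SingularDesignError(
            "no candidate specification could be fitted: " + "; ".join(failures[:5])
        )
    fits.sort(key=lambda m: (m.rss, m.n_params, m.spec.powers))
    return fits


@dataclass(frozen=True)
class LinearFPComparison:
    """Straight-line versus best fractional-polynomial fit on the same rows."""

    linear: FittedModel
    best_fp: FittedModel
    f_statistic: float
    p_value: float
    n_obs: int

    @property
    def fp_improves(self) -> bool:
        return self.best_fp.rss < self.linear.rss


def compare_linear_fp(
    data: pd.DataFrame,
    outcome: str = "DFPSany",
    threshold: float = 0.15,
    candidate_extras: Sequence[str] = ("cpdiff",),
) -> LinearFPComparison:
    """Test whether FP terms improve on a straight line at higher prevalence.

    Rows below ``threshold`` prevalence are removed first (default 15%), the
    linear-in-CPR model and the best FP model (both with the same extra
    covariates) are fitted, and an F-type statistic compares the FP fit
    against the linear one on the extra degrees of freedom.
    """
    from scipy import stats

    pp = "CPRany" if outcome == "DFPSany" else "CPRm"
    col = predictor_column(pp)
    filtered, _ = apply_exclusion(data, columns=(col,), threshold=threshold)
    linear_spec = FPModelSpec(
        outcome=outcome, primary_predictor=pp, powers=(1.0,),
        extra_covariates=tuple(candidate_extras),
    )
    linear = fit_model(filtered, linear_spec)
    ranked = fp_search(
        filtered, outcome=outcome, primary_predictor=pp,
        candidate_extras=candidate_extras,
    )
    best_fp = ranked[0]
    n = linear.n_obs
    # Each selected FP power counts 2 degrees of freedom (coefficient + power
    # choice), the Royston-Altman convention that accounts for searching over
    # the power set: best-FP2 vs straight line is a 3-df comparison.
    df_extra = 2 * len(best_fp.spec.powers) - 1
    if best_fp.spec.powers == (1.0,):
        df_extra = 0
    df_resid = n - best_fp.n_params
    if df_extra <= 0 or best_fp.rss <= 0:
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat = ((linear.rss - best_fp.rss) / df_extra) / (best_fp.rss / df_resid)
        f_stat = max(f_stat, 0.0)
        p_value = float(stats.f.sf(f_stat, df_extra, df_resid))
    return LinearFPComparison(linear, best_fp, float(f_stat), p_value, n)
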