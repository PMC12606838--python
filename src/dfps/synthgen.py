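"""Synthetic survey data with the statistical structure the DFPS models assume.

Two generators make every stage of the pipeline testable without access to
the real multi-country survey archive:

* :func:`gen_region_rows` -- region-level estimation tables: contraceptive
  prevalence drawn from distributions matched to the observed multi-country
  marginals, and DFPS generated from the published logit-scale equations plus
  a shared country-level intercept perturbation and row-level Gaussian noise.
* :func:`gen_microdata` -- woman-level records whose category mix is solved
  from a target indicator quadruple, so running the indicators module on the
  output recovers the targets up to binomial sampling error.

The defaults emulate the observed study structure: 103 countries with about
11 subnational regions each (~1,100 rows), CPRany spanning 1.5%-84.8% and the
any-minus-modern gap (cpdiff) reaching 63.9 percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indicators import MODERN_METHODS, TRADITIONAL_METHODS
from .predictor import (
    DFPS_ANY_COEFFS,
    DFPS_M_COEFFS,
    PredictorCoefficients,
    inv_logit,
)

__all__ = [
    "GeneratorConfig",
    "TargetQuadruple",
    "InfeasibleTargetsError",
    "gen_region_rows",
    "gen_microdata",
    "random_consistent_targets",
]

# Scaled-Beta parameters matched (moments + 10th/50th/90th percentiles) to the
# observed multi-country marginals of CPRany and of cpdiff as a fraction of
# its admissible range.
_CPR_ANY_BOUNDS = (0.015, 0.848)
_CPR_ANY_BETA = (1.45, 1.54)
_CPDIFF_MAX = 0.639
_CPDIFF_FRAC_BETA = (0.72, 3.84)


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the region-level generator.

    ``regions_per_country`` is either an exact integer or an inclusive
    ``(low, high)`` range sampled uniformly per country.  Noise standard
    deviations are on the logit scale.  The truth coefficients default to the
    published equations.
    """

    n_countries: int = 103
    regions_per_country: int | tuple = (8, 14)
    cpr_any_bounds: tuple = _CPR_ANY_BOUNDS
    cpr_any_beta: tuple = _CPR_ANY_BETA
    cpdiff_max: float = _CPDIFF_MAX
    cpdiff_frac_beta: tuple = _CPDIFF_FRAC_BETA
    logit_noise_sd: float = 0.05
    country_effect_sd: float = 0.05
    truth_any: PredictorCoefficients = DFPS_ANY_COEFFS
    truth_m: PredictorCoefficients = DFPS_M_COEFFS
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cpr_any_bounds
        if not (0 < lo < hi < 1):
            raise ValueError(f"infeasible cpr_any_bounds {self.cpr_any_bounds}")
        if not 0 < self.cpdiff_max < 1:
            raise ValueError(f"infeasible cpdiff_max {self.cpdiff_max}")
        if self.logit_noise_sd < 0 or self.country_effect_sd < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        if self.n_countries < 1:
            raise ValueError("need at least one country")


def _region_counts(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    rpc = config.regions_per_country
    if isinstance(rpc, int):
        return np.full(config.n_countries, rpc)
    lo, hi = rpc
    return rng.integers(lo, hi + 1, size=config.n_countries)


def gen_region_rows(config: GeneratorConfig | None = None):
    """Generate an estimation table plus its noise-free truth table.

    Per region, CPRany is a scaled Beta draw and cpdiff is a Beta fraction of
    ``min(CPRany, cpdiff_max)`` -- truncation at CPRany guarantees
    CPRm = CPRany - cpdiff >= 0.  Both DFPS outcomes follow their truth
    equation plus one shared country intercept perturbation per outcome and
    independent row-level noise, all on the logit scale.  Reproducible from
    ``config.seed``; returns ``(rows, truth)``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    counts = _region_counts(config, rng)
    n = int(counts.sum())
    country_idx = np.repeat(np.arange(config.n_countries), counts)
    region_seq = np.concatenate([np.arange(c) for c in counts])

    lo, hi = config.cpr_any_bounds
    a, b = config.cpr_any_beta
    cpr_any = lo + (hi - lo) * rng.beta(a, b, n)
    af, bf = config.cpdiff_frac_beta
    cpdiff = np.minimum(cpr_any, config.cpdiff_max) * rng.beta(af, bf, n)
    cpr_m = cpr_any - cpdiff

    eta_any_true = config.truth_any.linear_predictor(cpr_any, cpdiff)
    # the modern equation is undefined at CPRm = 0; floor far below the 1%
    # exclusion threshold so such rows are generated, then excluded downstream
    eta_m_true = config.truth_m.linear_predictor(np.maximum(cpr_m, 1e-6), cpdiff)

    ce_any = rng.normal(0.0, config.country_effect_sd, config.n_countries)
    ce_m = rng.normal(0.0, config.country_effect_sd, config.n_countries)
    eta_any = eta_any_true + ce_any[country_idx] + rng.normal(0, config.logit_noise_sd, n)
    eta_m = eta_m_true + ce_m[country_idx] + rng.normal(0, config.logit_noise_sd, n)

    country = np.array([f"C{i:03d}" for i in range(config.n_countries)])[country_idx]
    region = np.array([f"{c}.R{r:02d}" for c, r in zip(country, region_seq)])
    rows = pd.DataFrame(
        {
            "country_id": country,
            "region_id": region,
            "cpr_any": cpr_any,
            "cpr_m": cpr_m,
            "cpdiff": cpdiff,
            "dfps_any": inv_logit(eta_any),
            "dfps_m": inv_logit(eta_m),
        }
    )
    truth = rows[["country_id", "region_id", "cpr_any", "cpr_m", "cpdiff"]].copy()
    truth["dfps_any"] = inv_logit(eta_any_true)
    truth["dfps_m"] = inv_logit(eta_m_true)
    return rows, truth


class InfeasibleTargetsError(ValueError):
    """Target indicator quadruple violates a structural inequality."""


@dataclass(frozen=True)
class TargetQuadruple:
    """Consistent target values for the four indicators in one stratum.

    The four indicators are mutually constrained: the share of women in need
    equals CPRany/DFPSany and also CPRm/DFPSm, so the quadruple has three free
    dimensions.  Construction validates every required inequality.
    """

    cpr_any: float
    cpr_m: float
    dfps_any: float
    dfps_m: float

    def __post_init__(self) -> None:
        checks = [
            (self.cpr_any >= self.cpr_m, "CPRany >= CPRm"),
            (self.dfps_any >= self.dfps_m, "DFPSany >= DFPSm"),
            (self.dfps_any >= self.cpr_any, "DFPSany >= CPRany"),
            (self.dfps_m >= self.cpr_m, "DFPSm >= CPRm"),
            (all(0 <= v <= 1 for v in self._tuple()), "all values in [0, 1]"),
        ]
        for ok, name in checks:
            if not ok:
                raise InfeasibleTargetsError(f"targets violate {name}: {self._tuple()}")
        # shared need share: CPRany/DFPSany must equal CPRm/DFPSm
        if abs(self.cpr_any * self.dfps_m - self.cpr_m * self.dfps_any) > 1e-9:
            raise InfeasibleTargetsError(
                "targets violate CPRany*DFPSm == CPRm*DFPSany (both ratios are "
                f"the share of women in need): {self._tuple()}"
            )
        if self.cpr_any > 0 and self.dfps_any == 0:
            raise InfeasibleTargetsError("users exist but DFPSany is zero")

    def _tuple(self):
        return (self.cpr_any, self.cpr_m, self.dfps_any, self.dfps_m)

    @property
    def need_share(self) -> float:
        """Proportion of women in need of contraception."""
        if self.dfps_any > 0:
            return self.cpr_any / self.dfps_any
        return 0.0


def random_consistent_targets(
    rng: np.random.Generator, min_need: float = 0.2
) -> TargetQuadruple:
    """Draw a random internally consistent target quadruple.

    Sampling (need share, DFPSany, DFPSm <= DFPSany) and deriving the CPRs
    guarantees consistency by construction.
    """
    need = rng.uniform(min_need, 0.95)
    dfps_any = rng.uniform(0.05, 0.98)
    dfps_m = dfps_any * rng.uniform(0.3, 1.0)
    return TargetQuadruple(need * dfps_any, need * dfps_m, dfps_any, dfps_m)


# Non-need category mix (pregnant/amenorrheic with wanted pregnancy, infecund,
# fecund but wanting a child soon) -- arbitrary realistic split.
_NOT_NEED_SPLIT = {"pregnant_wanted": 0.25, "infecund": 0.35, "wants_child": 0.40}

_CATEGORY_ORDER = (
    "modern_user",
    "traditional_user",
    "nonuser_in_need",
    "pregnant_wanted",
    "infecund",
    "wants_child",
)


def _category_probabilities(t: TargetQuadruple) -> np.ndarray:
    need = t.need_share
    p = {
        "modern_user": t.cpr_m,
        "traditional_user": t.cpr_any - t.cpr_m,
        "nonuser_in_need": max(need - t.cpr_any, 0.0),
    }
    rest = max(1.0 - need, 0.0)
    for name, share in _NOT_NEED_SPLIT.items():
        p[name] = rest * share
    probs = np.array([p[c] for c in _CATEGORY_ORDER])
    return probs / probs.sum()


def gen_microdata(
    targets: TargetQuadruple,
    n_women: int,
    seed: int = 0,
    country_id: str = "C000",
    region_id: str = "C000.R00",
    n_clusters: int = 25,
) -> pd.DataFrame:
    """Generate woman-level records matching a target indicator quadruple.

    Women are sampled into six categories (modern user, traditional user,
    non-user in need, and three not-in-need types) with probabilities solved
    from the targets; each category's survey answers are filled so the
    classification rules place the woman in exactly that category.  Weights
    are Gamma-distributed with mean one and independent of category, so the
    weighted indicator estimates are consistent for the targets.
    """
    rng = np.random.default_rng(seed)
    probs = _category_probabilities(targets)
    cats = rng.choice(len(_CATEGORY_ORDER), size=n_women, p=probs)
    modern_list = sorted(MODERN_METHODS)
    trad_list = sorted(TRADITIONAL_METHODS)

    df = pd.DataFrame(
        {
            "age": rng.integers(15, 50, n_women),
            "partnered": True,
            "method_code": "none",
            "pregnant": False,
            "postpartum_amenorrheic": False,
            "months_since_last_birth": np.nan,
            "last_pregnancy_wanted": pd.Series([None] * n_women, dtype=object),
            "wants_child_within_2y": pd.Series([None] * n_women, dtype=object),
            "never_menstruated": False,
            "menopausal": False,
            "months_since_last_period": rng.integers(0, 3, n_women).astype(float),
            "has_under5_child": rng.random(n_women) < 0.5,
            "years_married_no_birth_no_contraception_5y": False,
            "self_declared_infecund": False,
            "weight": rng.gamma(10.0, 0.1, n_women),
            "cluster_id": np.array(
                [f"{region_id}.cl{j:03d}" for j in rng.integers(0, n_clusters, n_women)]
            ),
            "country_id": country_id,
            "region_id": region_id,
            "residence": rng.choice(["urban", "rural"], n_women),
            "wealth_quintile": rng.integers(1, 6, n_women),
            "education": rng.choice(["none", "primary", "secondary+"], n_women),
        }
    )

    cat = np.array(_CATEGORY_ORDER)[cats]
    is_mod = cat == "modern_user"
    is_trad = cat == "traditional_user"
    df.loc[is_mod, "method_code"] = rng.choice(modern_list, is_mod.sum())
    df.loc[is_trad, "method_code"] = rng.choice(trad_list, is_trad.sum())

    in_need_nonuser = cat == "nonuser_in_need"
    df.loc[in_need_nonuser, "wants_child_within_2y"] = rng.choice(
        ["no", "delay_2y_plus"], in_need_nonuser.sum()
    )

    pw = cat == "pregnant_wanted"
    df.loc[pw, "pregnant"] = True
    df.loc[pw, "last_pregnancy_wanted"] = "then"
    df.loc[pw, "months_since_last_period"] = np.nan

    inf = cat == "infecund"
    trigger = rng.choice(
        ["menopausal", "never_menstruated", "self_declared_infecund",
         "years_married_no_birth_no_contraception_5y"],
        inf.sum(),
    )
    for name in np.unique(trigger):
        idx = df.index[inf][trigger == name]
        df.loc[idx, name] = True
    df.loc[inf, "wants_child_within_2y"] = "no"  # intention irrelevant once infecund

    wc = cat == "wants_child"
    df.loc[wc, "wants_child_within_2y"] = "yes"
    return df
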