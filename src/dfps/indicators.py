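"""Woman-level indicator construction: contraceptive use, need, CPR and DFPS.

The four indicators share one numerator -- partnered women 15-49 currently
using a contraceptive method (any or modern).  CPRany/CPRm divide by all
partnered women 15-49; DFPSany/DFPSm divide by the subset of those women who
are in need of contraception, so DFPS >= CPR by construction.

A woman is in need when any of these holds:

  (a) she currently uses a method (users are in need by construction, since
      the DFPS numerator must be a subset of its denominator);
  (b) she is fecund, neither pregnant nor postpartum amenorrheic, and wants no
      child within two years (or wants to delay two years or more);
  (c) she is pregnant or postpartum amenorrheic and the pregnancy was
      mistimed or unwanted.

Infecundity is any of five conditions: never menstruated; menopausal; no
under-five child with the last period more than six months ago; married five
or more years without a birth while not contracepting; self-declared unable
to conceive.  Missing answers count as condition-not-met: records are never
dropped for missing intention or fecundity fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "MODERN_METHODS",
    "TRADITIONAL_METHODS",
    "MethodTaxonomy",
    "WomanRecord",
    "IndicatorEstimate",
    "NeedConfig",
    "UnknownMethodError",
    "classify_method",
    "classify_infecund",
    "classify_need",
    "classify_frame",
    "estimate_indicator",
    "records_to_frame",
    "INDICATORS",
    "DIMENSIONS",
]

# Hubacher-Trussell modern methods: technology-based contraception.
MODERN_METHODS = frozenset(
    {
        "condom",
        "female_condom",
        "male_sterilization",
        "female_sterilization",
        "iud",
        "implant",
        "pill",
        "injectable",
        "emergency_pill",
        "patch",
        "diaphragm",
        "spermicide",
        "ring",
        "sponge",
    }
)

# Behaviour-based methods, plus LAM which is absent from the modern list.
TRADITIONAL_METHODS = frozenset(
    {"withdrawal", "rhythm", "calendar", "lam", "folk", "other_traditional"}
)

INDICATORS = ("CPRany", "CPRm", "DFPSany", "DFPSm")

#: Stratification dimensions -> grouping columns (always nested in country).
DIMENSIONS = {
    "national": ("country_id",),
    "subnational": ("country_id", "region_id"),
    "residence": ("country_id", "residence"),
    "wealth": ("country_id", "wealth_quintile"),
    "education": ("country_id", "education"),
}


class UnknownMethodError(ValueError):
    """A contraceptive method code absent from the taxonomy (and not "none")."""


@dataclass(frozen=True)
class MethodTaxonomy:
    """User-configurable split of method codes into modern and traditional."""

    modern_methods: frozenset = MODERN_METHODS
    traditional_methods: frozenset = TRADITIONAL_METHODS

    def __post_init__(self) -> None:
        object.__setattr__(self, "modern_methods", frozenset(self.modern_methods))
        object.__setattr__(
            self, "traditional_methods", frozenset(self.traditional_methods)
        )
        overlap = self.modern_methods & self.traditional_methods
        if overlap:
            raise ValueError(f"methods in both sets: {sorted(overlap)}")
        if "none" in self.modern_methods | self.traditional_methods:
            raise ValueError('"none" is reserved for non-users')


DEFAULT_TAXONOMY = MethodTaxonomy()


@dataclass
class WomanRecord:
    """One survey respondent's contraception, intention and fecundity answers.

    Optional fields default to missing/False; missing answers never drop a
    record, they simply fail to trigger the condition they inform.
    """

    age: int
    partnered: bool
    method_code: str = "none"
    pregnant: bool = False
    postpartum_amenorrheic: bool = False
    months_since_last_birth: int | None = None
    last_pregnancy_wanted: str | None = None  # then | later | not_at_all
    wants_child_within_2y: str | None = None  # yes | no | delay_2y_plus | undecided
    never_menstruated: bool = False
    menopausal: bool = False
    months_since_last_period: int | None = None
    has_under5_child: bool = False
    years_married_no_birth_no_contraception_5y: bool = False
    self_declared_infecund: bool = False
    weight: float = 1.0
    cluster_id: str = "c0"
    country_id: str = "X"
    region_id: str = "X.0"
    residence: str = "urban"
    wealth_quintile: int = 3
    education: str = "primary"

    def __post_init__(self) -> None:
        if not 15 <= self.age <= 49:
            raise ValueError(f"age {self.age} outside [15, 49]")
        if not self.weight > 0:
            raise ValueError("weight must be positive")
        if self.pregnant and self.postpartum_amenorrheic:
            raise ValueError("pregnant and postpartum_amenorrheic are exclusive")


@dataclass(frozen=True)
class IndicatorEstimate:
    """A weighted point estimate of one indicator for one population stratum."""

    indicator: str
    dimension: str
    stratum: str
    value: float | None
    numerator_weight: float
    denominator_weight: float
    n_unweighted: int
    missing: bool = False
    std_error: float | None = None


@dataclass(frozen=True)
class NeedConfig:
    """Switches for the configurable corners of the need definition."""

    amenorrhea_window_months: int = 24
    undecided_in_need: bool = False


def classify_method(method_code: str, taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY) -> str:
    """Return "modern", "traditional" or "none" for a method code.

    Unknown codes raise :class:`UnknownMethodError` -- a misspelled method must
    never silently become a non-user.
    """
    if method_code == "none":
        return "none"
    if method_code in taxonomy.modern_methods:
        return "modern"
    if method_code in taxonomy.traditional_methods:
        return "traditional"
    raise UnknownMethodError(f"unknown contraceptive method code: {method_code!r}")


def classify_infecund(w: WomanRecord) -> bool:
    """True if any of the five infecundity conditions holds (missing = not met)."""
    if w.never_menstruated or w.menopausal or w.self_declared_infecund:
        return True
    if w.years_married_no_birth_no_contraception_5y:
        return True
    mslp = w.months_since_last_period
    if not w.has_under5_child and mslp is not None and mslp > 6:
        return True
    return False


def _ppa_active(w: WomanRecord, window: int) -> bool:
    # Amenorrheic flag counts only within the postpartum window; an unknown
    # time since birth is taken at face value.
    if not w.postpartum_amenorrheic:
        return False
    mslb = w.months_since_last_birth
    return mslb is None or mslb <= window


def classify_need(
    w: WomanRecord,
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY,
    config: NeedConfig = NeedConfig(),
) -> bool:
    """True if the woman is in need of contraception (rules a-c above)."""
    if classify_method(w.method_code, taxonomy) != "none":
        return True
    if w.pregnant or _ppa_active(w, config.amenorrhea_window_months):
        return w.last_pregnancy_wanted in ("later", "not_at_all")
    if classify_infecund(w):
        return False
    wanted = ("no", "delay_2y_plus", "undecided") if config.undecided_in_need else (
        "no",
        "delay_2y_plus",
    )
    return w.wants_child_within_2y in wanted


def records_to_frame(records: Iterable[WomanRecord]) -> pd.DataFrame:
    """Materialise WomanRecords as a DataFrame (one column per field)."""
    cols = [f.name for f in dc_fields(WomanRecord)]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def classify_frame(
    df: pd.DataFrame,
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY,
    config: NeedConfig = NeedConfig(),
) -> pd.DataFrame:
    """Vectorised classification: adds user_any, user_modern, infecund, in_need.

    Operates on a WomanRecord-shaped DataFrame and validates every method code
    up front.
    """
    codes = set(df["method_code"].unique()) - {"none"}
    unknown = codes - taxonomy.modern_methods - taxonomy.traditional_methods
    if unknown:
        raise UnknownMethodError(
            f"unknown contraceptive method code(s): {sorted(unknown)}"
        )
    out = df.copy()
    modern = df["method_code"].isin(taxonomy.modern_methods).to_numpy()
    traditional = df["method_code"].isin(taxonomy.traditional_methods).to_numpy()
    out["user_modern"] = modern
    out["user_any"] = modern | traditional

    mslp = pd.to_numeric(df.get("months_since_last_period"), errors="coerce")
    infecund = (
        _bool(df, "never_menstruated")
        | _bool(df, "menopausal")
        | _bool(df, "self_declared_infecund")
        | _bool(df, "years_married_no_birth_no_contraception_5y")
        | (~_bool(df, "has_under5_child") & (mslp > 6).fillna(False).to_numpy())
    )
    out["infecund"] = infecund

    mslb = pd.to_numeric(df.get("months_since_last_birth"), errors="coerce")
    ppa = _bool(df, "postpartum_amenorrheic") & (
        mslb.isna() | (mslb <= config.amenorrhea_window_months)
    ).to_numpy()
    preg_or_ppa = _bool(df, "pregnant") | ppa
    preg_unwanted = df.get("last_pregnancy_wanted", pd.Series("", index=df.index)).isin(
        ["later", "not_at_all"]
    ).to_numpy()
    wanted_codes = ["no", "delay_2y_plus"] + (
        ["undecided"] if config.undecided_in_need else []
    )
    wants_avoid = df.get("wants_child_within_2y", pd.Series("", index=df.index)).isin(
        wanted_codes
    ).to_numpy()
    out["in_need"] = out["user_any"].to_numpy() | np.where(
        preg_or_ppa, preg_unwanted, ~infecund & wants_avoid
    )
    return out


def _bool(df: pd.DataFrame, col: str) -> np.ndarray:
    if col not in df:
        return np.zeros(len(df), dtype=bool)
    return df[col].fillna(False).astype(bool).to_numpy()


def _numerator_denominator(classified: pd.DataFrame, indicator: str):
    num = classified["user_modern" if indicator in ("CPRm", "DFPSm") else "user_any"]
    if indicator.startswith("DFPS"):
        den = classified["in_need"]
    else:
        den = pd.Series(True, index=classified.index)
    return num.to_numpy(dtype=bool), den.to_numpy(dtype=bool)


def estimate_indicator(
    records: Iterable[WomanRecord] | pd.DataFrame,
    indicator: str,
    stratify_by: str = "national",
    taxonomy: MethodTaxonomy = DEFAULT_TAXONOMY,
    config: NeedConfig = NeedConfig(),
    with_se: bool = False,
) -> list[IndicatorEstimate]:
    """Weighted indicator estimates for every stratum of one dimension.

    The analysis population is partnered women aged 15-49; other rows are
    dropped up front.  Each estimate is a ratio of weighted sums; a stratum
    whose denominator weight is zero is returned flagged missing rather than
    as 0/0.  ``with_se`` adds a Taylor-linearised standard error clustered on
    ``cluster_id``.
    """
    if indicator not in INDICATORS:
        raise ValueError(f"indicator must be one of {INDICATORS}, got {indicator!r}")
    if stratify_by not in DIMENSIONS:
        raise ValueError(
            f"stratify_by must be one of {tuple(DIMENSIONS)}, got {stratify_by!r}"
        )
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df[(df["partnered"].astype(bool)) & df["age"].between(15, 49)]
    if df.empty:
        raise ValueError("no partnered women aged 15-49 in the input")
    classified = classify_frame(df, taxonomy, config)
    num_mask, den_mask = _numerator_denominator(classified, indicator)
    w = classified["weight"].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise ValueError("sampling weights must be positive")

    work = pd.DataFrame(
        {
            "num_w": w * (num_mask & den_mask),
            "den_w": w * den_mask,
            "in_den": den_mask.astype(int),
            "cluster_id": classified["cluster_id"].to_numpy(),
        }
    )
    group_cols = list(DIMENSIONS[stratify_by])
    for c in group_cols:
        work[c] = classified[c].to_numpy()

    estimates: list[IndicatorEstimate] = []
    for key, g in work.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key)
        num_w, den_w = float(g["num_w"].sum()), float(g["den_w"].sum())
        n_unw = int(g["in_den"].sum())
        if den_w <= 0.0:
            estimates.append(
                IndicatorEstimate(
                    indicator, stratify_by, label, None, num_w, den_w,
                    n_unw, missing=True,
                )
            )
            continue
        value = num_w / den_w
        se = _ratio_cluster_se(g, value, den_w) if with_se else None
        estimates.append(
            IndicatorEstimate(
                indicator, stratify_by, label, value, num_w, den_w, n_unw,
                std_error=se,
            )
        )
    return estimates


def _ratio_cluster_se(g: pd.DataFrame, ratio: float, den_w: float) -> float | None:
    """Taylor-linearised SE of a weighted ratio, clustered on cluster_id."""
    totals = g.groupby("cluster_id")[["num_w", "den_w"]].sum()
    n_clusters = len(totals)
    if n_clusters < 2:
        return None
    z = totals["num_w"].to_numpy() - ratio * totals["den_w"].to_numpy()
    var = n_clusters / (n_clusters - 1) * float(np.sum((z - z.mean()) ** 2)) / den_w**2
    return math.sqrt(var)
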