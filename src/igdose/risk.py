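"""Lifetime attributable risk (LAR) of cancer incidence from organ dose.

Risk projection follows the BEIR VII excess-absolute-risk (EAR) models for
cancer incidence.  For an acute exposure of dose D (Sv) at age e, the LAR is
the survival-weighted sum of the excess absolute risk over attained ages::

    LAR(D, e) = sum_{a = e + L}^{100}  M(D, e, a) * 1e-4 * S(a) / S(e)

where M is the EAR in cases per 10^4 person-year-Sv, S(a) the probability of
surviving from birth to age a, and L a minimum latency (5 y for solid
cancers, 2 y for leukemia).  Solid sites (brain, lung) use::

    EAR = beta_s * D * exp(gamma * e_star) * (a / 60)**eta

and leukemia the linear-quadratic, time-since-exposure model::

    EAR = beta_s * D * (1 + theta*D)
          * exp[gamma*e_star + delta*log(t/25) + phi*e_star*log(t/25)]

with t = a - e years since exposure and e_star = (e - 30)/10 for e < 30 and
0 thereafter.  Projection is EAR-based (the LAR definition above takes M =
EAR directly); an ERR-based mode multiplying baseline incidence rates is
deliberately not implemented, as it would require a baseline-rate table.

The cumulative imaging dose of a radiotherapy course is treated as a single
acute exposure at the age of initial treatment.  No dose and dose-rate
effectiveness factor (DDREF) is applied by default (``ddref=1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dose import ExposureSummary

SITES = ("brain", "lung", "leukemia")
SOLID_SITES = ("brain", "lung")

#: Default minimum latency (years) between exposure and first attributable case.
DEFAULT_LATENCY = {"brain": 5.0, "lung": 5.0, "leukemia": 2.0}

_DATA_PACKAGE = "igdose.data"

#: Organ carrying the dose relevant to each cancer site.
SITE_ORGAN = {"brain": "brain", "lung": "lung", "leukemia": "red_bone_marrow"}
ORGAN_SITE = {v: k for k, v in SITE_ORGAN.items()}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific survivorship S(a), probability of surviving birth->age a."""

    sex: str
    survival: tuple[float, ...]  # S(a) for integer a = 0..100

    def __post_init__(self) -> None:
        s = self.survival
        if len(s) != 101:
            raise ValueError("life table must cover integer ages 0..100")
        if not math.isclose(s[0], 1.0):
            raise ValueError("S(0) must equal 1")
        if any(b > a + 1e-12 for a, b in zip(s, s[1:])):
            raise ValueError("survivorship must be non-increasing")
        if any(not 0.0 <= v <= 1.0 for v in s):
            raise ValueError("survivorship must lie in [0, 1]")

    def S(self, age: float) -> float:
        return self.survival[int(age)]


@dataclass(frozen=True)
class RiskCoefficients:
    """BEIR VII incidence-model coefficients for one (site, sex).

    ``beta`` is on the EAR scale: excess cases per 10^4 person-year-Sv.
    Solid sites carry the attained-age power ``eta``; leukemia carries the
    dose-curvature ``theta`` (per Sv) and the time-since-exposure log terms
    ``delta`` and ``phi``.
    """

    site: str
    sex: str
    beta: float
    gamma: float
    eta: float | None = None
    theta: float | None = None
    delta: float | None = None
    phi: float | None = None
    latency_years: float = 5.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.latency_years < 0:
            raise ValueError("latency must be non-negative")
        if self.site == "leukemia":
            if None in (self.theta, self.delta, self.phi):
                raise ValueError("leukemia coefficients require theta, delta, phi")
        else:
            if self.eta is None:
                raise ValueError("solid-site coefficients require eta")
            if any(v is not None for v in (self.theta, self.delta, self.phi)):
                raise ValueError("solid-site coefficients take no theta/delta/phi")


@dataclass(frozen=True)
class LARResult:
    """Lifetime attributable risk of one site for one exposed person."""

    site: str
    sex: str
    age_at_exposure: float
    dose_Sv: float
    lar_per_person: float

    @property
    def lar_per_100k(self) -> float:
        return 1e5 * self.lar_per_person


# ---------------------------------------------------------------------------
# Defaults (packaged coefficient and life-table files)
# ---------------------------------------------------------------------------


def load_risk_coefficients(path: str | Path | None = None
                           ) -> dict[tuple[str, str], RiskCoefficients]:
    """Load risk coefficients keyed by (site, sex); default: packaged file."""
    if path is None:
        src = resources.files(_DATA_PACKAGE).joinpath("risk_coefficients.csv")
        with src.open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    out: dict[tuple[str, str], RiskCoefficients] = {}
    for r in df.itertuples(index=False):
        def _opt(v):
            return None if pd.isna(v) else float(v)
        rc = RiskCoefficients(
            site=str(r.site), sex=str(r.sex), beta=float(r.beta),
            gamma=float(r.gamma), eta=_opt(r.eta), theta=_opt(r.theta),
            delta=_opt(r.delta), phi=_opt(r.phi),
            latency_years=float(r.latency_years),
        )
        out[(rc.site, rc.sex)] = rc
    return out


def default_risk_coefficients() -> dict[tuple[str, str], RiskCoefficients]:
    return load_risk_coefficients(None)


def load_life_table(path: str | Path | None = None) -> dict[str, LifeTable]:
    """Load sex-keyed life tables (CSV: age, S_male, S_female)."""
    if path is None:
        src = resources.files(_DATA_PACKAGE).joinpath("life_table_synthetic.csv")
        with src.open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    df = df.sort_values("age")
    return {
        "M": LifeTable("M", tuple(float(v) for v in df["S_male"])),
        "F": LifeTable("F", tuple(float(v) for v in df["S_female"])),
    }


def default_life_tables() -> dict[str, LifeTable]:
    return load_life_table(None)


# ---------------------------------------------------------------------------
# Excess absolute risk models
# ---------------------------------------------------------------------------


def exposure_age_transform(exposure_age: float) -> float:
    """e* = (e - 30)/10 below age 30, 0 at and above age 30."""
    return min(exposure_age - 30.0, 0.0) / 10.0


def ear_solid(coeff: RiskCoefficients, dose_Sv: float,
              exposure_age: float, attained_age: float) -> float:
    """Solid-cancer EAR (cases per 10^4 person-years) at one attained age."""
    if attained_age < exposure_age:
        raise ValueError("attained age precedes exposure age")
    if dose_Sv < 0:
        raise ValueError("dose must be non-negative")
    e_star = exposure_age_transform(exposure_age)
    return (coeff.beta * dose_Sv * math.exp(coeff.gamma * e_star)
            * (attained_age / 60.0) ** coeff.eta)


def ear_leukemia(coeff: RiskCoefficients, dose_Sv: float,
                 exposure_age: float, attained_age: float) -> float:
    """Leukemia EAR (cases per 10^4 person-years) at one attained age."""
    t = attained_age - exposure_age
    if t <= 0:
        raise ValueError("time since exposure must be positive")
    if dose_Sv < 0:
        raise ValueError("dose must be non-negative")
    e_star = exposure_age_transform(exposure_age)
    log_t = math.log(t / 25.0)
    return (coeff.beta * dose_Sv * (1.0 + coeff.theta * dose_Sv)
            * math.exp(coeff.gamma * e_star + coeff.delta * log_t
                       + coeff.phi * e_star * log_t))


def excess_absolute_risk(coeff: RiskCoefficients, dose_Sv: float,
                         exposure_age: float, attained_age: float) -> float:
    if coeff.site == "leukemia":
        return ear_leukemia(coeff, dose_Sv, exposure_age, attained_age)
    return ear_solid(coeff, dose_Sv, exposure_age, attained_age)


# ---------------------------------------------------------------------------
# Lifetime attributable risk
# ---------------------------------------------------------------------------


def lar(exposure: ExposureSummary, coeff: RiskCoefficients,
        life_table: LifeTable, ddref: float = 1.0) -> LARResult:
    """LAR of cancer incidence for one exposure (per person).

    Sums the EAR over integer attained ages from ``e + latency`` to 100,
    weighted by the conditional survival S(a)/S(e) and converted from the
    per-10^4-person-year scale.  ``ddref`` divides the solid-site linear
    dose term; the default 1 applies no dose-rate reduction.
    """
    if coeff.sex != exposure.sex:
        raise ValueError(
            f"coefficient sex {coeff.sex!r} != exposure sex {exposure.sex!r}"
        )
    if life_table.sex != exposure.sex:
        raise ValueError(
            f"life-table sex {life_table.sex!r} != exposure sex {exposure.sex!r}"
        )
    e = exposure.age_at_exposure
    if not 0 <= e <= 100:
        raise ValueError("exposure age outside life-table domain [0, 100]")
    dose = exposure.equivalent_dose_Sv
    if coeff.site != "leukemia":
        dose = dose / ddref
    s_e = life_table.S(e)
    start = int(math.ceil(e + coeff.latency_years))
    total = 0.0
    for a in range(start, 101):
        m = excess_absolute_risk(coeff, dose, e, float(a))
        total += m * 1e-4 * life_table.S(a) / s_e
    return LARResult(site=coeff.site, sex=exposure.sex, age_at_exposure=e,
                     dose_Sv=exposure.equivalent_dose_Sv, lar_per_person=total)


def lar_vs_exposure_age_curve(dose_Sv: float, sex: str, site: str,
                              coeff: RiskCoefficients, life_table: LifeTable,
                              ages: Sequence[float]) -> list[LARResult]:
    """One LAR evaluation per exposure age, for risk-vs-age curves."""
    if len(ages) == 0:
        raise ValueError("empty age list")
    results = []
    for e in ages:
        exposure = ExposureSummary(
            patient_id="curve", organ=SITE_ORGAN[site],
            cumulative_dose_cGy=dose_Sv * 100.0, equivalent_dose_Sv=dose_Sv,
            age_at_exposure=float(e), sex=sex,
        )
        results.append(lar(exposure, coeff, life_table))
    return results
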