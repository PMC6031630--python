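"""Per-procedure and cumulative organ dose from body-region circumference.

Imaging dose in image-guided radiotherapy (IGRT) depends strongly on patient
size: at fixed technique factors, a larger circumference attenuates more of
the beam before it reaches the organ, so the mean organ dose falls with
girth.  This module evaluates empirical size->dose functions for the four
imaging modalities in routine IGRT use (planning CT, kV cone-beam CT, kV and
MV planar portal imaging) and the three sentinel organs (brain for head
scans, lungs for thorax scans, red bone marrow for pelvic scans), and
accumulates per-procedure doses over a patient's image-guidance history.

Four functional families cover all (modality, organ) pairs:

* ``EXP_DECAY``:  dose = y0 * exp(-a * C)
* ``LINEAR``:     dose = y0 + a * C
* ``QUADRATIC``:  dose = y0 + a * C + b * C**2
* ``LOG_AGE``:    dose = y0 + a * ln(C) + b * age

with C the region circumference in cm and dose in cGy.  The shipped default
coefficient table covers all twelve pairs; ``load_dose_params`` /
``write_dose_params`` round-trip the same delimited format so refitted
coefficients (see :mod:`igdose.fitting`) can be deployed in place of the
defaults.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

MODALITIES = ("CT", "kVCBCT", "kVPI", "MVPI")
ORGANS = ("brain", "lung", "red_bone_marrow")
REGIONS = ("head", "thorax", "pelvis")
FORMS = ("EXP_DECAY", "LINEAR", "QUADRATIC", "LOG_AGE")

#: Organ irradiated by imaging of each body region.
REGION_ORGAN: Mapping[str, str] = {
    "head": "brain",
    "thorax": "lung",
    "pelvis": "red_bone_marrow",
}
ORGAN_REGION: Mapping[str, str] = {v: k for k, v in REGION_ORGAN.items()}

#: Observed circumference ranges (cm) per region; empirical, not physical,
#: bounds — values outside warn and extrapolate rather than fail.
CIRCUMFERENCE_RANGES: Mapping[str, tuple[float, float]] = {
    "head": (39.0, 66.0),
    "thorax": (42.0, 160.0),
    "pelvis": (37.0, 168.0),
}

#: 1 cGy absorbed dose = 0.01 Sv equivalent dose for photons (w_R = 1).
CGY_TO_SV = 0.01


class ConfigurationError(KeyError):
    """A required parameter-table entry is missing or inconsistent."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseFunctionParams:
    """One empirical size->dose function for a (modality, organ) pair.

    Parameters
    ----------
    modality, organ
        Members of :data:`MODALITIES` / :data:`ORGANS`.
    form
        Functional family, one of :data:`FORMS`.
    y0, a, b
        Coefficients.  ``b`` is required for QUADRATIC (per-cm^2) and
        LOG_AGE (per-year) and must be absent otherwise.
    comment
        Free-text provenance note carried through file round-trips.
    """

    modality: str
    organ: str
    form: str
    y0: float
    a: float
    b: float | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        needs_b = self.form in ("QUADRATIC", "LOG_AGE")
        if needs_b and self.b is None:
            raise ValueError(f"form {self.form} requires coefficient b")
        if not needs_b and self.b is not None:
            raise ValueError(f"form {self.form} takes no coefficient b")


@dataclass(frozen=True)
class ProcedureHistory:
    """Image-guidance history of one patient for one exposed organ.

    A patient imaged in several body regions is represented by several
    records, one per organ; cumulative doses are reported per organ and
    never summed across organs.
    """

    patient_id: str
    region: str
    circumference_cm: float
    age_years: float
    sex: str = "M"
    organ: str = ""
    n_ct: int = 0
    n_cbct: int = 0
    n_kvpi: int = 0
    n_mvpi: int = 0

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if not self.organ:
            object.__setattr__(self, "organ", REGION_ORGAN[self.region])
        elif self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        for name in ("n_ct", "n_cbct", "n_kvpi", "n_mvpi"):
            n = getattr(self, name)
            if not isinstance(n, (int,)) or isinstance(n, bool) or n < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {n!r}")
        if not 0.0 <= self.age_years <= 100.0:
            raise ValueError(f"age {self.age_years} outside [0, 100]")
        if self.circumference_cm <= 0:
            raise ValueError("circumference must be positive")
        lo, hi = CIRCUMFERENCE_RANGES[self.region]
        if not lo <= self.circumference_cm <= hi:
            logger.warning(
                "circumference %.1f cm outside observed %s range [%g, %g]; "
                "dose functions will extrapolate",
                self.circumference_cm, self.region, lo, hi,
            )

    @property
    def counts(self) -> dict[str, int]:
        return {
            "CT": self.n_ct,
            "kVCBCT": self.n_cbct,
            "kVPI": self.n_kvpi,
            "MVPI": self.n_mvpi,
        }

    @property
    def n_procedures(self) -> int:
        return self.n_ct + self.n_cbct + self.n_kvpi + self.n_mvpi


@dataclass(frozen=True)
class ExposureSummary:
    """Cumulative organ dose of one patient, the input to risk projection."""

    patient_id: str
    organ: str
    cumulative_dose_cGy: float
    equivalent_dose_Sv: float
    age_at_exposure: float
    sex: str

    def __post_init__(self) -> None:
        if self.cumulative_dose_cGy < 0:
            raise ValueError("cumulative dose must be non-negative")


# ---------------------------------------------------------------------------
# Default coefficient table
# ---------------------------------------------------------------------------

_DATA_PACKAGE = "igdose.data"
_DOSE_PARAM_FILE = "dose_params.csv"

DoseParamTable = dict[tuple[str, str], DoseFunctionParams]

#: Expected functional family per (modality, organ) in the default set.
DEFAULT_FORMS: Mapping[tuple[str, str], str] = {
    **{("CT", o): "EXP_DECAY" for o in ORGANS},
    **{("kVPI", o): "LINEAR" for o in ORGANS},
    **{("MVPI", o): "LINEAR" for o in ORGANS},
    ("kVCBCT", "brain"): "QUADRATIC",
    ("kVCBCT", "lung"): "LINEAR",
    ("kVCBCT", "red_bone_marrow"): "LOG_AGE",
}


def load_dose_params(path: str | Path | None = None) -> DoseParamTable:
    """Load a dose-function coefficient table (default: packaged table).

    The file is header-labelled CSV with columns
    ``modality, organ, form, y0, a, b, comment`` (``b`` blank where unused).
    """
    if path is None:
        with resources.files(_DATA_PACKAGE).joinpath(_DOSE_PARAM_FILE).open() as fh:
            df = pd.read_csv(fh, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    table: DoseParamTable = {}
    for row in df.itertuples(index=False):
        b = None if pd.isna(row.b) else float(row.b)
        comment = "" if pd.isna(getattr(row, "comment", "")) else str(row.comment)
        p = DoseFunctionParams(
            modality=str(row.modality), organ=str(row.organ), form=str(row.form),
            y0=float(row.y0), a=float(row.a), b=b, comment=comment,
        )
        key = (p.modality, p.organ)
        if key in table:
            raise ConfigurationError(f"duplicate entry for {key}")
        table[key] = p
    return table


def default_dose_params() -> DoseParamTable:
    """The packaged default coefficient table (all twelve modality/organ pairs)."""
    return load_dose_params(None)


def write_dose_params(table: DoseParamTable | Iterable[DoseFunctionParams],
                      path: str | Path) -> None:
    """Write a coefficient table in the dialect :func:`load_dose_params` reads.

    Floats are written with :func:`repr` so a write/load round trip
    reproduces every coefficient bit-exactly.
    """
    entries = table.values() if isinstance(table, dict) else list(table)
    rows = [
        {
            "modality": p.modality, "organ": p.organ, "form": p.form,
            "y0": repr(p.y0), "a": repr(p.a),
            "b": "" if p.b is None else repr(p.b),
            "comment": p.comment,
        }
        for p in entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def evaluate_dose(params: DoseFunctionParams, circumference_cm: float,
                  age_years: float | None = None) -> float:
    """Per-procedure organ dose (cGy) at the given circumference (and age).

    Raw negative values (possible when a linear form is extrapolated far
    beyond the fitted range) are clamped to 0 with a logged warning.

    Raises
    ------
    ValueError
        If ``circumference_cm`` is not positive, or ``age_years`` is missing
        for a LOG_AGE form.
    """
    if circumference_cm <= 0:
        raise ValueError("circumference must be positive")
    c = float(circumference_cm)
    if params.form == "EXP_DECAY":
        dose = params.y0 * math.exp(-params.a * c)
    elif params.form == "LINEAR":
        dose = params.y0 + params.a * c
    elif params.form == "QUADRATIC":
        dose = params.y0 + params.a * c + params.b * c * c
    elif params.form == "LOG_AGE":
        if age_years is None:
            raise ValueError(
                f"{params.modality}/{params.organ} uses a LOG_AGE form; "
                "age_years is required"
            )
        dose = params.y0 + params.a * math.log(c) + params.b * float(age_years)
    else:  # pragma: no cover - guarded by DoseFunctionParams
        raise ValueError(f"unknown form {params.form!r}")
    if not math.isfinite(dose):
        raise ValueError(
            f"non-finite dose from {params.modality}/{params.organ} at C={c}"
        )
    if dose < 0:
        logger.warning(
            "negative raw dose %.4g cGy from %s/%s at C=%.1f cm; clamped to 0",
            dose, params.modality, params.organ, c,
        )
        return 0.0
    return dose


def cumulative_dose(history: ProcedureHistory,
                    param_table: DoseParamTable,
                    include_ct: bool = True) -> ExposureSummary:
    """Accumulate per-procedure doses over a history into one organ total.

    The total is a plain count-weighted sum — each procedure's dose is taken
    as independent of the others (no protocol adaptation between scans).
    ``include_ct=False`` drops the planning-CT contribution, for analyses
    restricted to image-guidance dose only.
    """
    # per-procedure contributions accumulated with fsum: the total is the
    # correctly rounded sum of the expanded multiset, so splitting a history
    # into sub-histories and summing reproduces the single-pass result
    contributions: list[float] = []
    for modality, count in history.counts.items():
        if count == 0 or (modality == "CT" and not include_ct):
            continue
        try:
            params = param_table[(modality, history.organ)]
        except KeyError:
            raise ConfigurationError(
                f"no dose-function entry for ({modality}, {history.organ})"
            ) from None
        dose = evaluate_dose(params, history.circumference_cm,
                             history.age_years)
        contributions.extend([dose] * count)
    total = math.fsum(contributions)
    return ExposureSummary(
        patient_id=history.patient_id,
        organ=history.organ,
        cumulative_dose_cGy=total,
        equivalent_dose_Sv=total * CGY_TO_SV,
        age_at_exposure=history.age_years,
        sex=history.sex,
    )


# ---------------------------------------------------------------------------
# Cohort file I/O (one record per patient-organ)
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "patient_id", "sex", "age_years", "region", "organ", "circumference_cm",
    "n_ct", "n_cbct", "n_kvpi", "n_mvpi",
]


def histories_to_frame(histories: Iterable[ProcedureHistory]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": h.patient_id, "sex": h.sex, "age_years": h.age_years,
            "region": h.region, "organ": h.organ,
            "circumference_cm": h.circumference_cm,
            "n_ct": h.n_ct, "n_cbct": h.n_cbct,
            "n_kvpi": h.n_kvpi, "n_mvpi": h.n_mvpi,
        }
        for h in histories
    ]
    return pd.DataFrame(rows, columns=_COHORT_COLUMNS)


def frame_to_histories(df: pd.DataFrame) -> list[ProcedureHistory]:
    return [
        ProcedureHistory(
            patient_id=str(r.patient_id), sex=str(r.sex),
            age_years=float(r.age_years), region=str(r.region),
            organ=str(r.organ), circumference_cm=float(r.circumference_cm),
            n_ct=int(r.n_ct), n_cbct=int(r.n_cbct),
            n_kvpi=int(r.n_kvpi), n_mvpi=int(r.n_mvpi),
        )
        for r in df.itertuples(index=False)
    ]


def read_cohort(path: str | Path) -> list[ProcedureHistory]:
    """Read a cohort file (header-labelled CSV, one record per patient-organ)."""
    return frame_to_histories(pd.read_csv(path))


def write_cohort(histories: Iterable[ProcedureHistory], path: str | Path) -> None:
    histories_to_frame(histories).to_csv(path, index=False)
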