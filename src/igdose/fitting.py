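"""Least-squares fitting of the empirical size->dose families.

Monte Carlo (or measured) per-procedure organ doses at a range of patient
circumferences are regressed onto one of the four functional families used
by :mod:`igdose.dose`, producing coefficients in the same
:class:`~igdose.dose.DoseFunctionParams` container the evaluator consumes —
a fit->deploy round trip for new protocols or machines.

LINEAR, QUADRATIC and LOG_AGE are linear in their coefficients and solved by
ordinary least squares on the design matrix.  EXP_DECAY is genuinely
nonlinear and is fitted in original (untransformed) dose space with
Levenberg-Marquardt, initialised from a log-linear pre-fit so the result
does not depend on an arbitrary starting point.  All fits are unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .dose import FORMS, DoseFunctionParams, write_dose_params

#: Number of free coefficients per functional family.
N_PARAMS = {"EXP_DECAY": 2, "LINEAR": 2, "QUADRATIC": 3, "LOG_AGE": 3}

_XTOL = 1e-10
_MAX_ITER = 10_000


class UnderdeterminedError(ValueError):
    """Fewer samples than the chosen form's coefficient count + 1."""


@dataclass(frozen=True)
class DoseSampleSet:
    """(circumference[, age], dose) samples for one (modality, organ) pair."""

    circumference_cm: tuple[float, ...]
    dose_cGy: tuple[float, ...]
    modality: str
    organ: str
    age_years: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n = len(self.circumference_cm)
        if len(self.dose_cGy) != n:
            raise ValueError("circumference and dose lengths differ")
        if self.age_years is not None and len(self.age_years) != n:
            raise ValueError("age and dose lengths differ")
        if any(c <= 0 for c in self.circumference_cm):
            raise ValueError("circumferences must be strictly positive")
        if any(d < 0 for d in self.dose_cGy):
            raise ValueError("doses must be non-negative")

    def __len__(self) -> int:
        return len(self.circumference_cm)


@dataclass(frozen=True)
class FitResult:
    """Estimated coefficients with fit diagnostics.

    ``converged=False`` marks the coefficients non-authoritative; they are
    returned for inspection, never silently.
    """

    params: DoseFunctionParams
    rss: float
    stderr: dict[str, float]
    converged: bool

    def to_file(self, path: str | Path) -> None:
        """Serialize as a one-row parameter file loadable by the dose module."""
        write_dose_params([self.params], path)


def _design_matrix(form: str, c: np.ndarray, age: np.ndarray | None) -> np.ndarray:
    if form == "LINEAR":
        return np.column_stack([np.ones_like(c), c])
    if form == "QUADRATIC":
        return np.column_stack([np.ones_like(c), c, c * c])
    if form == "LOG_AGE":
        return np.column_stack([np.ones_like(c), np.log(c), age])
    raise ValueError(form)


def fit_dose_function(samples: DoseSampleSet, form: str) -> FitResult:
    """Fit one functional family to a sample set by least squares.

    Raises
    ------
    UnderdeterminedError
        If there are fewer than ``N_PARAMS[form] + 1`` samples.
    ValueError
        For a LOG_AGE fit without ages in every sample.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    k = N_PARAMS[form]
    n = len(samples)
    if n < k + 1:
        raise UnderdeterminedError(
            f"{form} has {k} coefficients; need at least {k + 1} samples, got {n}"
        )
    c = np.asarray(samples.circumference_cm, dtype=float)
    d = np.asarray(samples.dose_cGy, dtype=float)
    age = None
    if form == "LOG_AGE":
        if samples.age_years is None:
            raise ValueError("LOG_AGE fitting requires an age for every sample")
        age = np.asarray(samples.age_years, dtype=float)

    if form == "EXP_DECAY":
        coef, stderr, rss, converged = _fit_exp_decay(c, d)
        names = ("y0", "a")
        params = DoseFunctionParams(samples.modality, samples.organ, form,
                                    y0=coef[0], a=coef[1])
    else:
        X = _design_matrix(form, c, age)
        coef, res, rank, _ = np.linalg.lstsq(X, d, rcond=None)
        fitted = X @ coef
        rss = float(np.sum((d - fitted) ** 2))
        converged = rank == X.shape[1]
        dof = max(n - k, 1)
        sigma2 = rss / dof
        xtx_inv = np.linalg.pinv(X.T @ X)
        stderr = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
        names = ("y0", "a", "b")[:k]
        b = float(coef[2]) if k == 3 else None
        params = DoseFunctionParams(samples.modality, samples.organ, form,
                                    y0=float(coef[0]), a=float(coef[1]), b=b)

    return FitResult(
        params=params,
        rss=rss,
        stderr=dict(zip(names, (float(s) for s in stderr))),
        converged=bool(converged),
    )


def _fit_exp_decay(c: np.ndarray, d: np.ndarray):
    """Levenberg-Marquardt fit of y0*exp(-a*C), log-linear initialisation."""
    # log-linear pre-fit on positive doses; fall back to crude moments
    pos = d > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(c[pos], np.log(d[pos]), 1)
        p0 = [float(np.exp(intercept)), float(-slope)]
    else:  # pragma: no cover - all-zero doses are degenerate
        p0 = [max(float(d.max()), 1e-6), 0.0]

    def model(x, y0, a):
        return y0 * np.exp(-a * x)

    try:
        popt, pcov = optimize.curve_fit(
            model, c, d, p0=p0, maxfev=_MAX_ITER, xtol=_XTOL, ftol=_XTOL,
        )
        converged = np.all(np.isfinite(popt)) and np.all(np.isfinite(pcov))
    except RuntimeError:
        popt, pcov = np.asarray(p0), np.full((2, 2), np.nan)
        converged = False
    rss = float(np.sum((d - model(c, *popt)) ** 2))
    with np.errstate(invalid="ignore"):
        stderr = np.sqrt(np.diag(pcov))
    return (float(popt[0]), float(popt[1])), stderr, rss, converged


def select_form(samples: DoseSampleSet,
                forms: Sequence[str] = FORMS) -> list[tuple[str, float, FitResult]]:
    """Rank candidate families by AIC; ties go to the smaller family.

    Returns ``(form, aic, fit)`` triples, best first.  LOG_AGE is skipped
    automatically when the sample set carries no ages.  Requires at least
    one more sample than the largest candidate family's coefficient count.
    """
    candidates = [f for f in forms
                  if not (f == "LOG_AGE" and samples.age_years is None)]
    if not candidates:
        raise ValueError("no candidate forms to rank")
    k_max = max(N_PARAMS[f] for f in candidates)
    n = len(samples)
    if n < k_max + 1:
        raise UnderdeterminedError(
            f"need at least {k_max + 1} samples to rank all forms, got {n}"
        )
    d = np.asarray(samples.dose_cGy, dtype=float)
    # RSS floor at machine-precision scale: fits that are perfect up to
    # rounding tie exactly and the tie-break (fewer parameters) decides
    rss_floor = 1e-15 * float(d @ d) + 1e-300
    ranked = []
    for f in candidates:
        fit = fit_dose_function(samples, f)
        k = N_PARAMS[f]
        # Gaussian-likelihood AIC from the residual sum of squares
        rss = max(fit.rss, rss_floor)
        aic = n * np.log(rss / n) + 2 * k
        ranked.append((f, float(aic), fit))
    ranked.sort(key=lambda t: (t[1], N_PARAMS[t[0]]))
    return ranked


def read_samples(path: str | Path) -> list[DoseSampleSet]:
    """Read sample files (CSV: circumference,age,dose,modality,organ).

    Returns one :class:`DoseSampleSet` per (modality, organ) group; the age
    column may be blank throughout a group, in which case ages are omitted.
    """
    df = pd.read_csv(path)
    out = []
    for (mod, organ), g in df.groupby(["modality", "organ"], sort=True):
        ages = None
        if "age" in g and g["age"].notna().all():
            ages = tuple(float(a) for a in g["age"])
        out.append(DoseSampleSet(
            circumference_cm=tuple(float(c) for c in g["circumference"]),
            dose_cGy=tuple(float(d) for d in g["dose"]),
            modality=str(mod), organ=str(organ), age_years=ages,
        ))
    return out
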