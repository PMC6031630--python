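"""Itemized per-patient imaging cost under a fee schedule.

Billing follows the CMS-style structure the fee defaults encode: a fixed
charge per planning-CT scan, a per-procedure charge for each image-guidance
acquisition (kV/MV portal image, kV cone-beam CT), and a one-time
image-guidance setup fee applied once per patient as soon as the patient
has at least one guidance procedure of any type.  All arithmetic is done in
integer cents; totals are exported in dollars.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .dose import ProcedureHistory

_DATA_PACKAGE = "igdose.data"

#: Default fees (USD): CT scan, kV portal image, MV portal image,
#: kV cone-beam CT, one-time image-guidance fee.
DEFAULT_FEES = {
    "ct_fee": 3828, "kvpi_fee": 76, "mvpi_fee": 76,
    "cbct_fee": 118, "igrt_onetime_fee": 440,
}


@dataclass(frozen=True)
class FeeSchedule:
    """Per-procedure and one-time charges, stored as integer cents."""

    ct_fee_cents: int
    kvpi_fee_cents: int
    mvpi_fee_cents: int
    cbct_fee_cents: int
    igrt_onetime_fee_cents: int

    def __post_init__(self) -> None:
        for name in ("ct_fee_cents", "kvpi_fee_cents", "mvpi_fee_cents",
                     "cbct_fee_cents", "igrt_onetime_fee_cents"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_dollars(cls, ct_fee: float = DEFAULT_FEES["ct_fee"],
                     kvpi_fee: float = DEFAULT_FEES["kvpi_fee"],
                     mvpi_fee: float = DEFAULT_FEES["mvpi_fee"],
                     cbct_fee: float = DEFAULT_FEES["cbct_fee"],
                     igrt_onetime_fee: float = DEFAULT_FEES["igrt_onetime_fee"],
                     ) -> "FeeSchedule":
        return cls(*(round(f * 100) for f in
                     (ct_fee, kvpi_fee, mvpi_fee, cbct_fee, igrt_onetime_fee)))


def default_fee_schedule() -> FeeSchedule:
    """The packaged default (US CMS-style) fee schedule."""
    return load_fee_schedule(None)


def load_fee_schedule(path: str | Path | None = None) -> FeeSchedule:
    """Load a fee schedule from a YAML file of dollar amounts."""
    if path is None:
        src = resources.files(_DATA_PACKAGE).joinpath("fee_schedule.yaml")
        with src.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return FeeSchedule.from_dollars(**{k: raw[k] for k in DEFAULT_FEES})


def write_fee_schedule(schedule: FeeSchedule, path: str | Path) -> None:
    data = {
        "ct_fee": schedule.ct_fee_cents / 100,
        "kvpi_fee": schedule.kvpi_fee_cents / 100,
        "mvpi_fee": schedule.mvpi_fee_cents / 100,
        "cbct_fee": schedule.cbct_fee_cents / 100,
        "igrt_onetime_fee": schedule.igrt_onetime_fee_cents / 100,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class LineItem:
    procedure: str
    count: int
    unit_fee_cents: int

    @property
    def subtotal_cents(self) -> int:
        return self.count * self.unit_fee_cents


@dataclass(frozen=True)
class CostStatement:
    """Itemized imaging bill for one patient."""

    patient_id: str
    line_items: tuple[LineItem, ...]

    @property
    def total_cents(self) -> int:
        return sum(item.subtotal_cents for item in self.line_items)

    @property
    def total_usd(self) -> float:
        return self.total_cents / 100

    def to_records(self) -> list[dict]:
        return [
            {
                "patient_id": self.patient_id, "procedure": i.procedure,
                "count": i.count, "unit_fee_usd": i.unit_fee_cents / 100,
                "subtotal_usd": i.subtotal_cents / 100,
            }
            for i in self.line_items
        ]


def _merged_counts(histories: Iterable[ProcedureHistory]) -> tuple[str, dict[str, int]]:
    counts = {"CT": 0, "kVCBCT": 0, "kVPI": 0, "MVPI": 0}
    pid = None
    for h in histories:
        if pid is None:
            pid = h.patient_id
        elif h.patient_id != pid:
            raise ValueError(
                f"histories for different patients: {pid!r} vs {h.patient_id!r}"
            )
        for modality, n in h.counts.items():
            counts[modality] += n
    if pid is None:
        raise ValueError("no histories given")
    return pid, counts


def patient_cost(histories: ProcedureHistory | Iterable[ProcedureHistory],
                 schedule: FeeSchedule,
                 apply_onetime: bool | None = None) -> CostStatement:
    """Itemized cost for one patient's merged procedure counts.

    Accepts a single history or all of a patient's per-organ histories; the
    one-time image-guidance fee is charged once per patient, by default iff
    the merged counts include at least one guidance procedure
    (``apply_onetime`` overrides either way).
    """
    if isinstance(histories, ProcedureHistory):
        histories = [histories]
    pid, counts = _merged_counts(histories)
    if apply_onetime is None:
        apply_onetime = (counts["kVCBCT"] + counts["kVPI"] + counts["MVPI"]) > 0
    items = [
        LineItem("CT", counts["CT"], schedule.ct_fee_cents),
        LineItem("kVCBCT", counts["kVCBCT"], schedule.cbct_fee_cents),
        LineItem("kVPI", counts["kVPI"], schedule.kvpi_fee_cents),
        LineItem("MVPI", counts["MVPI"], schedule.mvpi_fee_cents),
    ]
    if apply_onetime:
        items.append(LineItem("IGRT one-time", 1, schedule.igrt_onetime_fee_cents))
    return CostStatement(patient_id=pid, line_items=tuple(items))
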