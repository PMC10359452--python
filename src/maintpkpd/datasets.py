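"""Longitudinal dataset model, NONMEM-flavoured CSV IO, exclusion filtering
and cross-validation truncation.

A :class:`Dataset` holds one :class:`PatientRecord` per patient: demographics,
dose events (mg/m² of body surface area) and observations of three kinds —
erythrocyte methotrexate (E-MTX, µmol/L), erythrocyte thioguanine nucleotides
(E-TGN, µmol/L) and the absolute neutrophil count (ANC, G/L) — on a common
day-scale timeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .units import convert_ery_concentration
from .variants import FINAL_VARIANT, ModelVariant

logger = logging.getLogger(__name__)

__all__ = [
    "OBSERVATION_KINDS",
    "Observation",
    "DoseEvent",
    "PatientRecord",
    "Dataset",
    "ExclusionLog",
    "apply_exclusions",
    "crossval_truncate",
    "read_dataset",
    "write_dataset",
    "ParseError",
]

OBSERVATION_KINDS = ("E-MTX", "E-TGN", "ANC")
DRUGS = ("6MP", "MTX")

#: Rules of the exclusion filter, in order of precedence.
RULE_FEW_METABOLITE_OBS = "lt2_metabolite_obs"
RULE_NO_DOSE = "no_dose"
RULE_MISSING_COVARIATE_OR_ANC = "missing_covariate_or_anc"


class ParseError(ValueError):
    """Raised when a dataset file violates the expected dialect."""


@dataclass(frozen=True)
class Observation:
    """A single measurement: E-MTX / E-TGN in µmol/L, ANC in G/L."""

    time: float  # days since dataset start
    kind: str
    value: float

    def __post_init__(self) -> None:
        if self.kind not in OBSERVATION_KINDS:
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"observation time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.value) or self.value < 0:
            raise ValueError(f"observation value must be finite and >= 0, got {self.value}")


@dataclass(frozen=True)
class DoseEvent:
    """An oral dose event, amount in mg per m² body surface area."""

    time: float  # days
    drug: str
    dose_per_bsa: float  # mg/m²

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"dose time must be finite and >= 0, got {self.time}")
        if not np.isfinite(self.dose_per_bsa) or self.dose_per_bsa < 0:
            raise ValueError(f"dose must be finite and >= 0, got {self.dose_per_bsa}")


@dataclass
class PatientRecord:
    """One patient: demographics, doses and time-sorted observations."""

    id: str
    age: float  # years
    height: float  # cm
    weight: float  # kg
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.height is not None and not (self.height != self.height) and self.height <= 0:
            raise ValueError("height must be positive")
        if self.weight is not None and not (self.weight != self.weight) and self.weight <= 0:
            raise ValueError("weight must be positive")
        # stable sort keeps file order at equal times
        self.observations = sorted(self.observations, key=lambda o: o.time)
        self.doses = sorted(self.doses, key=lambda d: d.time)

    # -- convenience accessors -------------------------------------------
    def times(self, kind: str) -> np.ndarray:
        return np.array([o.time for o in self.observations if o.kind == kind])

    def values(self, kind: str) -> np.ndarray:
        return np.array([o.value for o in self.observations if o.kind == kind])

    def n_obs(self, kind: str) -> int:
        return sum(1 for o in self.observations if o.kind == kind)

    def first_value(self, kind: str) -> float | None:
        for o in self.observations:  # sorted
            if o.kind == kind:
                return o.value
        return None

    def has_covariates(self) -> bool:
        def ok(x):
            return x is not None and np.isfinite(x) and x > 0

        return ok(self.height) and ok(self.weight)


@dataclass
class Dataset:
    """A collection of patients plus free-form provenance metadata."""

    patients: list[PatientRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("patient ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def get(self, pid: str) -> PatientRecord:
        for p in self.patients:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def n_observations(self, kind: str | None = None) -> int:
        if kind is None:
            return sum(len(p.observations) for p in self.patients)
        return sum(p.n_obs(kind) for p in self.patients)


@dataclass
class ExclusionLog:
    """Per excluded patient: id and the single primary rule triggered."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def add(self, pid: str, rule: str) -> None:
        if pid in {e[0] for e in self.entries}:
            raise ValueError(f"patient {pid} already excluded")
        self.entries.append((pid, rule))
        logger.info("excluded patient %s (rule %s)", pid, rule)

    def rule_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, rule in self.entries:
            counts[rule] = counts.get(rule, 0) + 1
        return counts

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["id", "rule"]).to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Exclusion filtering
# ---------------------------------------------------------------------------

def _anchor_time(patient: PatientRecord, kinds: Sequence[str]) -> float:
    """Time of the first joint measurement of all required metabolite kinds."""
    firsts = []
    for kind in kinds:
        t = patient.times(kind)
        firsts.append(t[0])
    return max(firsts) if firsts else 0.0


def _shift_patient(patient: PatientRecord, t0: float) -> PatientRecord:
    """Re-anchor a patient record so that time 0 is ``t0``; earlier events drop."""
    obs = [
        Observation(o.time - t0, o.kind, o.value)
        for o in patient.observations
        if o.time >= t0
    ]
    doses = [
        DoseEvent(d.time - t0, d.drug, d.dose_per_bsa)
        for d in patient.doses
        if d.time >= t0
    ]
    return PatientRecord(patient.id, patient.age, patient.height, patient.weight, doses, obs)


def apply_exclusions(
    dataset: Dataset, model_spec: ModelVariant = FINAL_VARIANT
) -> tuple[Dataset, ExclusionLog]:
    """Filter a dataset by the three exclusion rules and re-anchor timelines.

    Rules (checked in order; the first violated rule is logged):

    i.   fewer than two observations of any metabolite kind the model needs;
    ii.  no dose of any drug the model needs;
    iii. missing height, weight, or (for PD models) ANC observation.

    Retained patients are re-anchored so that time 0 is the first joint
    measurement of the required metabolite kinds; observations and doses
    before that point are dropped.

    Returns the filtered dataset and an :class:`ExclusionLog`.  Raises
    ``ValueError`` naming the dominant rule if no patients remain.
    """
    kinds = model_spec.required_metabolites
    kept: list[PatientRecord] = []
    log = ExclusionLog()
    for patient in dataset.patients:
        if any(patient.n_obs(k) == 0 for k in kinds):
            log.add(patient.id, RULE_FEW_METABOLITE_OBS)
            continue
        anchored = _shift_patient(patient, _anchor_time(patient, kinds))
        if any(anchored.n_obs(k) < 2 for k in kinds):
            log.add(patient.id, RULE_FEW_METABOLITE_OBS)
            continue
        if any(
            not any(d.drug == drug and d.dose_per_bsa > 0 for d in anchored.doses)
            for drug in model_spec.required_drugs
        ):
            log.add(patient.id, RULE_NO_DOSE)
            continue
        if not anchored.has_covariates() or (
            model_spec.require_anc and anchored.n_obs("ANC") == 0
        ):
            log.add(patient.id, RULE_MISSING_COVARIATE_OR_ANC)
            continue
        kept.append(anchored)

    if not kept:
        counts = log.rule_counts()
        dominant = max(counts, key=counts.get) if counts else "empty input"
        raise ValueError(
            f"all patients excluded; dominant rule: {dominant} ({counts})"
        )
    out = Dataset(kept, dict(dataset.provenance))
    return out, log


# ---------------------------------------------------------------------------
# Cross-validation truncation
# ---------------------------------------------------------------------------

def crossval_truncate(
    dataset: Dataset, model_spec: ModelVariant = FINAL_VARIANT
) -> tuple[Dataset, ExclusionLog]:
    """Truncate each patient at the time point 50% of their ANC observations
    lie before, then re-apply the exclusion filter.

    The cutoff is the time of the (floor(n/2)+1)-th ANC observation (sorted
    by time); observations of all three kinds strictly before the cutoff are
    retained, so for even n exactly half of the ANC observations survive.
    """
    truncated: list[PatientRecord] = []
    for patient in dataset.patients:
        anc_times = patient.times("ANC")
        if anc_times.size == 0:
            raise ValueError(f"patient {patient.id} has no ANC observation")
        cutoff = float(np.sort(anc_times)[anc_times.size // 2])
        obs = [o for o in patient.observations if o.time < cutoff]
        truncated.append(
            PatientRecord(
                patient.id, patient.age, patient.height, patient.weight,
                list(patient.doses), obs,
            )
        )
    return apply_exclusions(Dataset(truncated, dict(dataset.provenance)), model_spec)


# ---------------------------------------------------------------------------
# NONMEM-flavoured CSV IO
# ---------------------------------------------------------------------------

_MANDATORY_COLUMNS = ["ID", "TIME", "EVID", "DVID", "DV", "AMT", "DRUG", "HT", "WT", "AGE"]
_DVID_TO_KIND = {1: "E-MTX", 2: "E-TGN", 3: "ANC"}
_KIND_TO_DVID = {v: k for k, v in _DVID_TO_KIND.items()}
_DRUG_CODE = {1: "6MP", 2: "MTX"}
_DRUG_TO_CODE = {v: k for k, v in _DRUG_CODE.items()}
_UNITS = {"umolL", "nmol_mmolHb"}


def read_dataset(path, *, unit_default: str = "umolL") -> Dataset:
    """Parse a NONMEM-flavoured event/observation CSV into a :class:`Dataset`.

    Columns: ID, TIME, EVID (0 observation / 1 dose), DVID (1=E-MTX,
    2=E-TGN, 3=ANC), DV, AMT (mg/m²), DRUG (1=6MP, 2=MTX), HT, WT, AGE and
    an optional UNIT flag ({umolL, nmol_mmolHb}) for metabolite rows.
    Unknown columns are preserved in ``dataset.provenance``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing mandatory column(s): {', '.join(missing)}")

    def numcol(name: str, required: bool) -> np.ndarray:
        raw = df[name].mask(df[name] == "")
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value in column {name}, row {row + 2}")
        if required and vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ParseError(f"missing value in column {name}, row {row + 2}")
        # exact round trip: python float parsing of the raw strings
        out = np.full(len(raw), np.nan)
        notna = raw.notna().to_numpy()
        out[notna] = [float(x) for x in raw[notna]]
        return out

    ids = df["ID"].to_numpy()
    time = numcol("TIME", required=True)
    evid = numcol("EVID", required=True).astype(int)
    dvid = numcol("DVID", required=False)
    dv = numcol("DV", required=False)
    amt = numcol("AMT", required=False)
    drug = numcol("DRUG", required=False)
    ht = numcol("HT", required=False)
    wt = numcol("WT", required=False)
    age = numcol("AGE", required=False)
    unit = df["UNIT"].to_numpy() if "UNIT" in df.columns else np.array([""] * len(df))

    patients: dict[str, dict] = {}
    order: list[str] = []
    for i in range(len(df)):
        pid = str(ids[i])
        if pid not in patients:
            patients[pid] = {"doses": [], "obs": [], "ht": np.nan, "wt": np.nan,
                             "age": np.nan, "last_t": -np.inf}
            order.append(pid)
        rec = patients[pid]
        if time[i] < rec["last_t"]:
            raise ParseError(f"unsorted TIME for patient {pid}, row {i + 2}")
        rec["last_t"] = time[i]
        for key, col in (("ht", ht), ("wt", wt), ("age", age)):
            if np.isnan(rec[key]) and not np.isnan(col[i]):
                rec[key] = float(col[i])
        if evid[i] == 1:
            code = int(drug[i]) if not np.isnan(drug[i]) else -1
            if code not in _DRUG_CODE:
                raise ParseError(f"dose row with unknown DRUG code, row {i + 2}")
            rec["doses"].append(DoseEvent(float(time[i]), _DRUG_CODE[code], float(amt[i])))
        elif evid[i] == 0:
            code = int(dvid[i]) if not np.isnan(dvid[i]) else -1
            if code not in _DVID_TO_KIND:
                raise ParseError(f"observation row with DVID outside {{1,2,3}}, row {i + 2}")
            kind = _DVID_TO_KIND[code]
            value = float(dv[i])
            u = str(unit[i]).strip() or unit_default
            if u not in _UNITS:
                raise ParseError(f"unknown UNIT flag {u!r}, row {i + 2}")
            if kind in ("E-MTX", "E-TGN") and u == "nmol_mmolHb":
                value = convert_ery_concentration(value)
            rec["obs"].append(Observation(float(time[i]), kind, value))
        else:
            raise ParseError(f"EVID must be 0 or 1, row {i + 2}")

    extra = {
        c: df[c].tolist() for c in df.columns
        if c not in _MANDATORY_COLUMNS + ["UNIT"]
    }
    prov: dict = {"source": str(path)}
    if extra:
        prov["extra_columns"] = extra
    return Dataset(
        [
            PatientRecord(pid, rec["age"], rec["ht"], rec["wt"], rec["doses"], rec["obs"])
            for pid, rec in ((p, patients[p]) for p in order)
        ],
        prov,
    )


def write_dataset(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` to canonical NONMEM-flavoured CSV.

    Rows are ordered per patient by (time, doses-after-observations at ties);
    metabolite values are written in µmol/L with UNIT=umolL.
    """
    rows = []
    for p in dataset.patients:
        merged: list[tuple] = [(o.time, 0, o) for o in p.observations]
        merged += [(d.time, 1, d) for d in p.doses]
        merged.sort(key=lambda t: (t[0], t[1]))
        for t, evid, ev in merged:
            row = {
                "ID": p.id, "TIME": repr(float(t)), "EVID": evid,
                "DVID": "", "DV": "", "AMT": "", "DRUG": "",
                "HT": repr(float(p.height)), "WT": repr(float(p.weight)),
                "AGE": repr(float(p.age)), "UNIT": "",
            }
            if evid == 0:
                row["DVID"] = _KIND_TO_DVID[ev.kind]
                row["DV"] = repr(float(ev.value))
                if ev.kind in ("E-MTX", "E-TGN"):
                    row["UNIT"] = "umolL"
            else:
                row["DRUG"] = _DRUG_TO_CODE[ev.drug]
                row["AMT"] = repr(float(ev.dose_per_bsa))
            rows.append(row)
    df = pd.DataFrame(rows, columns=_MANDATORY_COLUMNS + ["UNIT"])
    df.to_csv(path, index=False)
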