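"""Patient-level domain types, derived hemodynamics, cohort CSV I/O and splitting.

A cohort is an ordered collection of :class:`PatientRecord`. Each record holds
the admission physiology (SBP, DBP, HR), the two cardiac biomarkers
(hs-cTnT and NT-proBNP, both ng/L), atrial-fibrillation status, vasoactive
drug doses, the five non-cardiovascular SOFA sub-scores and the 30-day
mortality outcome. The cardiovascular SOFA sub-score is never stored: it is
recomputed from MAP and vasoactive therapy so it can never disagree with the
blood-pressure fields (see :mod:`cesofa.scoring`).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AF_LEVELS",
    "PatientRecord",
    "HemodynamicDerived",
    "Cohort",
    "CohortSchemaError",
    "CohortValidationError",
    "derive_hemodynamics",
    "read_cohort",
    "write_cohort",
    "split_cohort",
    "CTNT_FLOOR",
    "BNP_FLOOR",
]

#: Assay lower limits used as detection floors; keep log transforms finite.
CTNT_FLOOR = 3.0   # ng/L
BNP_FLOOR = 5.0    # ng/L

AF_LEVELS = ("none", "pre_existing", "new_onset")
SEX_LEVELS = ("female", "male")

SOFA_COMPONENTS = ("sofa_neuro", "sofa_resp", "sofa_renal", "sofa_hepatic", "sofa_coag")


class CohortSchemaError(ValueError):
    """A cohort CSV is missing a mandatory column or has an unreadable header."""


class CohortValidationError(ValueError):
    """A field value violates a record invariant; the message cites the row."""


@dataclass(frozen=True)
class HemodynamicDerived:
    """Pressure/rate quantities derived from SBP, DBP and HR.

    map : mean arterial pressure, DBP + (SBP - DBP)/3, mmHg
    pp  : pulse pressure, SBP - DBP, mmHg
    rpp : rate pressure product, HR x SBP, mmHg * beats/min
    ppp : proportional pulse pressure, PP/SBP, dimensionless in [0, 1]
    """

    map: float
    pp: float
    rpp: float
    ppp: float


def derive_hemodynamics(sbp: float, dbp: float, hr: float) -> HemodynamicDerived:
    """Compute MAP, PP, RPP and PPP from admission vitals.

    Raises
    ------
    CohortValidationError
        If ``dbp > sbp``, ``sbp <= 0`` (PPP undefined) or ``hr <= 0``.
    """
    if sbp <= 0:
        raise CohortValidationError(f"sbp must be positive for PPP; got {sbp}")
    if dbp > sbp:
        raise CohortValidationError(f"dbp ({dbp}) exceeds sbp ({sbp})")
    if dbp <= 0:
        raise CohortValidationError(f"dbp must be positive; got {dbp}")
    if hr <= 0:
        raise CohortValidationError(f"hr must be positive; got {hr}")
    pp = sbp - dbp
    return HemodynamicDerived(
        map=dbp + pp / 3.0,
        pp=pp,
        rpp=hr * sbp,
        ppp=pp / sbp,
    )


@dataclass
class PatientRecord:
    """One patient: physiology, biomarkers, SOFA sub-scores, AF status, outcome."""

    id: str
    age: float
    sex: str
    sbp: float
    dbp: float
    hr: float
    hs_ctnt: float
    nt_probnp: float
    af_status: str
    norepinephrine_dose: float
    dopamine_dose: float
    other_vasoactive: bool
    sofa_neuro: int
    sofa_resp: int
    sofa_renal: int
    sofa_hepatic: int
    sofa_coag: int
    died_30d: bool

    def validate(self) -> None:
        if self.sex not in SEX_LEVELS:
            raise CohortValidationError(f"sex must be one of {SEX_LEVELS}; got {self.sex!r}")
        if self.af_status not in AF_LEVELS:
            raise CohortValidationError(
                f"af_status must be one of {AF_LEVELS}; got {self.af_status!r}"
            )
        derive_hemodynamics(self.sbp, self.dbp, self.hr)  # BP/HR invariants
        if self.hs_ctnt < CTNT_FLOOR:
            raise CohortValidationError(
                f"hs_ctnt below detection floor {CTNT_FLOOR} ng/L: {self.hs_ctnt}"
            )
        if self.nt_probnp < BNP_FLOOR:
            raise CohortValidationError(
                f"nt_probnp below detection floor {BNP_FLOOR} ng/L: {self.nt_probnp}"
            )
        if self.norepinephrine_dose < 0 or self.dopamine_dose < 0:
            raise CohortValidationError("vasoactive doses must be non-negative")
        for name in SOFA_COMPONENTS:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise CohortValidationError(f"{name} must be an integer in [0, 4]; got {v!r}")

    @property
    def has_af(self) -> bool:
        """Pre-existing and new-onset AF collapse into one binary predictor."""
        return self.af_status != "none"

    @property
    def hemodynamics(self) -> HemodynamicDerived:
        return derive_hemodynamics(self.sbp, self.dbp, self.hr)


@dataclass
class Cohort:
    """Ordered collection of unique-id patient records."""

    records: list[PatientRecord]
    label: str = "cohort"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def field(self, name: str) -> np.ndarray:
        """Vector of one raw field (or derived hemodynamic quantity) per record.

        Accepts record field names plus the derived names ``map``, ``pp``,
        ``rpp``, ``ppp`` and the collapsed binary ``af``.
        """
        if name in ("map", "pp", "rpp", "ppp"):
            return np.array([getattr(r.hemodynamics, name) for r in self.records], dtype=float)
        if name == "af":
            return np.array([r.has_af for r in self.records], dtype=float)
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    @property
    def outcome(self) -> np.ndarray:
        return np.array([r.died_30d for r in self.records], dtype=int)

    @property
    def mortality(self) -> float:
        return float(self.outcome.mean())

    def validate(self) -> None:
        for idx, rec in enumerate(self.records):
            try:
                rec.validate()
            except CohortValidationError as exc:
                raise CohortValidationError(f"record {idx} (id={rec.id}): {exc}") from exc


# ---------------------------------------------------------------------------
# CSV I/O

CSV_COLUMNS = [f.name for f in dc_fields(PatientRecord)]

_FLOAT_FIELDS = {
    "age", "sbp", "dbp", "hr", "hs_ctnt", "nt_probnp",
    "norepinephrine_dose", "dopamine_dose",
}
_INT_FIELDS = set(SOFA_COMPONENTS)
_BOOL_FIELDS = {"other_vasoactive", "died_30d"}


def _parse_cell(name: str, raw: str, row_no: int):
    raw = raw.strip()
    try:
        if name in _FLOAT_FIELDS:
            return float(raw)
        if name in _INT_FIELDS:
            return int(raw)
        if name in _BOOL_FIELDS:
            if raw not in ("0", "1"):
                raise ValueError(f"expected 0 or 1, got {raw!r}")
            return raw == "1"
        return raw
    except ValueError as exc:
        raise CohortValidationError(f"row {row_no}: column {name!r}: {exc}") from exc


def read_cohort(path, label: str | None = None) -> Cohort:
    """Read a cohort CSV (one row per patient, mandatory header).

    Errors cite the offending column (schema) or 1-based data row (values).
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortSchemaError(f"{path}: empty file, no header")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise CohortSchemaError(f"{path}: missing mandatory column(s): {missing}")
        records = []
        for row_no, row in enumerate(reader, start=1):
            kwargs = {name: _parse_cell(name, row[name], row_no) for name in CSV_COLUMNS}
            rec = PatientRecord(**kwargs)
            try:
                rec.validate()
            except CohortValidationError as exc:
                raise CohortValidationError(f"row {row_no}: {exc}") from exc
            records.append(rec)
    return Cohort(records, label=label or str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV with the documented column schema (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in cohort:
            row = []
            for name in CSV_COLUMNS:
                v = getattr(rec, name)
                if name in _BOOL_FIELDS:
                    row.append(int(v))
                elif name in _FLOAT_FIELDS:
                    row.append(repr(float(v)))
                else:
                    row.append(v)
            writer.writerow(row)


def split_cohort(cohort: Cohort, n_train: int, seed: int) -> tuple[Cohort, Cohort]:
    """Random train/test split; reproducible for a given seed.

    The records are partitioned: train gets exactly ``n_train``, test the
    remainder, and their id multisets union to the input's.
    """
    n = len(cohort)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}); got {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = Cohort([cohort[i] for i in train_idx], label=f"{cohort.label}/train")
    test = Cohort([cohort[i] for i in test_idx], label=f"{cohort.label}/test")
    return train, test
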