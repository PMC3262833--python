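"""Patient-level cohort containers and delimited-text I/O.

A cohort is an ordered collection of :class:`PatientRecord` objects, one per
subject, carrying demographics, the admission NIHSS, coded imaging findings
(CTA occlusion sites and NCCT hypodensity regions), treatment flags and the
6-month modified Rankin scale (mRS).  Records travel as comma-separated UTF-8
text with a mandatory header; list-valued cells (occlusion sites, hypodense
regions) use ``;`` as the inner separator and missing values are empty
strings, so a valid table round-trips through :func:`read_cohort` /
:func:`write_cohort` byte-identically.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence, TextIO, Union

import pandas as pd

__all__ = [
    "Sex",
    "OcclusionSite",
    "QUALIFYING_SITES",
    "ASPECTS_REGIONS",
    "ImagingFindings",
    "PatientRecord",
    "CohortTable",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "exclude_unanalyzable",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class OcclusionSite(str, Enum):
    """Coded CTA occlusion locations.

    ``DISTAL_ICA``, ``MCA_M1``, ``MCA_M2`` and ``BASILAR`` are the proximal
    cerebral arterial segments whose occlusion qualifies a stroke as
    BASIS-major; ``OTHER`` collects every non-qualifying occlusion (ACA, PCA,
    distal MCA branches, extracranial-only disease).
    """

    DISTAL_ICA = "DISTAL_ICA"
    MCA_M1 = "MCA_M1"
    MCA_M2 = "MCA_M2"
    BASILAR = "BASILAR"
    OTHER = "OTHER"


#: Arterial occlusion sites that satisfy the BASIS vascular criterion.
QUALIFYING_SITES = frozenset(
    {OcclusionSite.DISTAL_ICA, OcclusionSite.MCA_M1, OcclusionSite.MCA_M2, OcclusionSite.BASILAR}
)

#: The ten ASPECTS anterior-circulation regions, in canonical output order:
#: caudate, lentiform nucleus, internal capsule, insula, and the six MCA
#: cortical territories (suffixed "c" to avoid confusion with the MCA M1/M2
#: arterial segments).
ASPECTS_REGIONS = ("C", "L", "IC", "I", "M1c", "M2c", "M3c", "M4c", "M5c", "M6c")

_REGION_SET = frozenset(ASPECTS_REGIONS)
_SITE_ORDER = tuple(OcclusionSite)


class CohortValidationError(ValueError):
    """A record or table violates a cohort invariant."""


@dataclass(frozen=True)
class ImagingFindings:
    """Coded CTA occlusion sites plus NCCT hypodensity findings."""

    occlusion_sites: frozenset = frozenset()
    anterior_hypodense_regions: frozenset = frozenset()
    bilateral_pons_hypodensity: bool = False
    bilateral_thalamus_hypodensity: bool = False

    def validate(self) -> None:
        for s in self.occlusion_sites:
            if not isinstance(s, OcclusionSite):
                raise CohortValidationError(f"unknown occlusion site {s!r}")
        bad = set(self.anterior_hypodense_regions) - _REGION_SET
        if bad:
            raise CohortValidationError(f"unknown ASPECTS region(s) {sorted(bad)}")
        if len(self.anterior_hypodense_regions) > 10:
            raise CohortValidationError("more than 10 hypodense regions")


@dataclass(frozen=True)
class PatientRecord:
    """One subject of the cohort.

    ``nihss_admission`` and ``mrs_6mo`` may be ``None`` (not reliably
    obtained); such records are removed by :func:`exclude_unanalyzable`
    before any analysis.
    """

    patient_id: str
    age: float
    sex: Sex
    nihss_admission: Optional[int]
    diabetes: bool = False
    cad: bool = False
    atrial_fibrillation: bool = False
    smoking: bool = False
    hyperlipidemia: bool = False
    hypertension: bool = False
    iv_tpa: bool = False
    ia_therapy: bool = False
    findings: ImagingFindings = field(default_factory=ImagingFindings)
    mrs_6mo: Optional[int] = None

    def validate(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("empty patient_id")
        if not self.age > 0:
            raise CohortValidationError(f"{self.patient_id}: age must be > 0, got {self.age}")
        if not isinstance(self.sex, Sex):
            raise CohortValidationError(f"{self.patient_id}: invalid sex {self.sex!r}")
        if self.nihss_admission is not None and not 0 <= self.nihss_admission <= 42:
            raise CohortValidationError(
                f"{self.patient_id}: NIHSS {self.nihss_admission} outside 0..42"
            )
        if self.mrs_6mo is not None and not 0 <= self.mrs_6mo <= 6:
            raise CohortValidationError(f"{self.patient_id}: mRS {self.mrs_6mo} outside 0..6")
        self.findings.validate()


class CohortTable:
    """Ordered collection of :class:`PatientRecord` with unique ids."""

    def __init__(self, records: Sequence[PatientRecord] = (), provenance: str = ""):
        self.records = list(records)
        self.provenance = provenance
        seen = set()
        for r in self.records:
            if r.patient_id in seen:
                raise CohortValidationError(f"duplicate patient_id {r.patient_id!r}")
            seen.add(r.patient_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, CohortTable) and self.records == other.records

    def validate(self) -> None:
        for r in self.records:
            r.validate()

    def to_frame(self) -> pd.DataFrame:
        """Flat pandas view (sets kept as frozensets in object columns)."""
        rows = []
        for r in self:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "age": r.age,
                    "sex": r.sex.value,
                    "nihss_admission": r.nihss_admission,
                    "diabetes": r.diabetes,
                    "cad": r.cad,
                    "atrial_fibrillation": r.atrial_fibrillation,
                    "smoking": r.smoking,
                    "hyperlipidemia": r.hyperlipidemia,
                    "hypertension": r.hypertension,
                    "iv_tpa": r.iv_tpa,
                    "ia_therapy": r.ia_therapy,
                    "occlusion_sites": r.findings.occlusion_sites,
                    "anterior_hypodense_regions": r.findings.anterior_hypodense_regions,
                    "bilateral_pons_hypodensity": r.findings.bilateral_pons_hypodensity,
                    "bilateral_thalamus_hypodensity": r.findings.bilateral_thalamus_hypodensity,
                    "mrs_6mo": r.mrs_6mo,
                }
            )
        return pd.DataFrame(rows, columns=COLUMNS)


COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "nihss_admission",
    "diabetes",
    "cad",
    "atrial_fibrillation",
    "smoking",
    "hyperlipidemia",
    "hypertension",
    "iv_tpa",
    "ia_therapy",
    "occlusion_sites",
    "anterior_hypodense_regions",
    "bilateral_pons_hypodensity",
    "bilateral_thalamus_hypodensity",
    "mrs_6mo",
]

_BOOL_COLUMNS = (
    "diabetes",
    "cad",
    "atrial_fibrillation",
    "smoking",
    "hyperlipidemia",
    "hypertension",
    "iv_tpa",
    "ia_therapy",
    "bilateral_pons_hypodensity",
    "bilateral_thalamus_hypodensity",
)


def _fmt_float(x: float) -> str:
    # repr gives the shortest exact decimal, so read(write(x)) is lossless
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def _parse_bool(token: str, column: str) -> bool:
    if token == "1":
        return True
    if token == "0":
        return False
    raise CohortValidationError(f"column {column}: expected 0/1, got {token!r}")


def _parse_sites(cell: str) -> frozenset:
    if not cell:
        return frozenset()
    out = set()
    for tok in cell.split(";"):
        try:
            out.add(OcclusionSite(tok))
        except ValueError:
            raise CohortValidationError(f"unknown occlusion site {tok!r}") from None
    return frozenset(out)


def _parse_regions(cell: str) -> frozenset:
    if not cell:
        return frozenset()
    toks = cell.split(";")
    if len(set(toks)) != len(toks):
        raise CohortValidationError(f"duplicate hypodense region in {cell!r}")
    bad = set(toks) - _REGION_SET
    if bad:
        raise CohortValidationError(f"unknown ASPECTS region(s) {sorted(bad)}")
    return frozenset(toks)


def _record_from_row(row: dict) -> PatientRecord:
    try:
        sex = Sex(row["sex"])
    except ValueError:
        raise CohortValidationError(f"unknown sex token {row['sex']!r}") from None
    nihss = row["nihss_admission"]
    mrs = row["mrs_6mo"]
    rec = PatientRecord(
        patient_id=row["patient_id"],
        age=float(row["age"]),
        sex=sex,
        nihss_admission=int(nihss) if nihss != "" else None,
        findings=ImagingFindings(
            occlusion_sites=_parse_sites(row["occlusion_sites"]),
            anterior_hypodense_regions=_parse_regions(row["anterior_hypodense_regions"]),
            bilateral_pons_hypodensity=_parse_bool(
                row["bilateral_pons_hypodensity"], "bilateral_pons_hypodensity"
            ),
            bilateral_thalamus_hypodensity=_parse_bool(
                row["bilateral_thalamus_hypodensity"], "bilateral_thalamus_hypodensity"
            ),
        ),
        mrs_6mo=int(mrs) if mrs != "" else None,
        **{c: _parse_bool(row[c], c) for c in _BOOL_COLUMNS[:8]},
    )
    rec.validate()
    return rec


def _row_from_record(r: PatientRecord) -> list:
    sites = ";".join(s.value for s in _SITE_ORDER if s in r.findings.occlusion_sites)
    regions = ";".join(t for t in ASPECTS_REGIONS if t in r.findings.anterior_hypodense_regions)
    return [
        r.patient_id,
        _fmt_float(r.age),
        r.sex.value,
        "" if r.nihss_admission is None else str(r.nihss_admission),
        *(("1" if getattr(r, c) else "0") for c in _BOOL_COLUMNS[:8]),
        sites,
        regions,
        "1" if r.findings.bilateral_pons_hypodensity else "0",
        "1" if r.findings.bilateral_thalamus_hypodensity else "0",
        "" if r.mrs_6mo is None else str(r.mrs_6mo),
    ]


def read_cohort(source: Union[str, Path, TextIO], strict: bool = True) -> CohortTable:
    """Read a cohort CSV.

    With ``strict=True`` any malformed row aborts with
    :class:`CohortValidationError`; with ``strict=False`` offending rows are
    dropped and the drop count recorded in the table's provenance note.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return _read(fh, strict, provenance=str(source))
    return _read(source, strict, provenance=getattr(source, "name", "<stream>"))


def _read(fh: TextIO, strict: bool, provenance: str) -> CohortTable:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise CohortValidationError("empty source: missing header row") from None
    missing = [c for c in COLUMNS if c not in header]
    if missing:
        raise CohortValidationError(f"missing required column(s): {missing}")
    idx = {c: header.index(c) for c in COLUMNS}
    records, dropped = [], 0
    for lineno, raw in enumerate(reader, start=2):
        try:
            row = {c: raw[idx[c]] for c in COLUMNS}
            records.append(_record_from_row(row))
        except (CohortValidationError, ValueError, IndexError) as exc:
            if strict:
                raise CohortValidationError(f"line {lineno}: {exc}") from exc
            dropped += 1
    note = provenance if dropped == 0 else f"{provenance} ({dropped} malformed row(s) dropped)"
    table = CohortTable(records, provenance=note)
    table.dropped_rows = dropped
    return table


def write_cohort(cohort: CohortTable, sink: Union[str, Path, TextIO]) -> None:
    """Write ``cohort`` in the exact dialect :func:`read_cohort` accepts."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as fh:
            _write(cohort, fh)
    else:
        _write(cohort, sink)


def _write(cohort: CohortTable, fh: TextIO) -> None:
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(COLUMNS)
    for r in cohort:
        writer.writerow(_row_from_record(r))


def cohort_to_csv_text(cohort: CohortTable) -> str:
    buf = io.StringIO()
    _write(cohort, buf)
    return buf.getvalue()


def exclude_unanalyzable(cohort: CohortTable) -> tuple:
    """Drop records lacking a 6-month mRS or an admission NIHSS.

    Returns ``(retained_table, counts)`` where ``counts`` has keys
    ``missing_mrs`` and ``missing_nihss`` (a record missing both is counted
    under ``missing_mrs``).  Idempotent: a second application is the identity.
    """
    kept, counts = [], {"missing_mrs": 0, "missing_nihss": 0}
    for r in cohort:
        if r.mrs_6mo is None:
            counts["missing_mrs"] += 1
        elif r.nihss_admission is None:
            counts["missing_nihss"] += 1
        else:
            kept.append(r)
    excluded = counts["missing_mrs"] + counts["missing_nihss"]
    note = cohort.provenance
    if excluded:
        note = f"{note} [{excluded} excluded: {counts['missing_mrs']} missing mRS, " \
               f"{counts['missing_nihss']} missing NIHSS]"
    return CohortTable(kept, provenance=note), counts
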