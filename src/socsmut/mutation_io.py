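"""Parsing and validation of mutation catalogs and clinical tables.

The mutation dialect is a small HGVS-like ``c.`` subset covering the four
event kinds observed in coding-region screens of this sort: substitutions,
deletions, tandem duplications and insertions.  Complex delins are
deliberately unsupported (an error, never a silent coercion).

Clinical tables carry demographics, staging, treatment, response, survival
and the four expression-signature labels as plain categorical columns.
Missing data are encoded as ``.`` or empty cells and propagate as missing;
the single exception is the IPI score, where a missing factor scores 0
("pessimistic" rule), so an IPI is always computable.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd

from .gene_model import GeneModel

__all__ = [
    "MutationRecord",
    "ClinicalRecord",
    "MutationParseError",
    "ReferenceMismatchError",
    "parse_c_notation",
    "format_c_notation",
    "read_mutation_table",
    "write_mutation_table",
    "read_clinical_table",
    "write_clinical_table",
    "clinical_frame",
    "compute_ipi",
    "encode_covariates",
]

log = logging.getLogger(__name__)

KINDS = ("substitution", "deletion", "duplication", "insertion")


class MutationParseError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class MutationRecord:
    """One coding-region event in 1-based CDS coordinates.

    Insertions are anchored between ``c_start`` and ``c_start + 1`` with
    ``c_end == c_start`` by convention; duplications are tandem (the
    ``[c_start, c_end]`` slice repeated immediately after ``c_end``).
    """

    case_id: str
    kind: str
    c_start: int
    c_end: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise MutationParseError(f"unknown mutation kind {self.kind!r}")
        if not 1 <= self.c_start <= self.c_end:
            raise MutationParseError(
                f"invalid interval c.{self.c_start}_{self.c_end}"
            )

    @property
    def net_length_change(self) -> int:
        if self.kind == "substitution":
            return 0
        if self.kind == "deletion":
            return -(self.c_end - self.c_start + 1)
        if self.kind == "duplication":
            return self.c_end - self.c_start + 1
        return len(self.alt)  # insertion

    @property
    def frame_disrupting(self) -> bool:
        return self.net_length_change % 3 != 0

    def validate(self, model: GeneModel) -> "MutationRecord":
        if self.c_end > model.cds_length:
            raise MutationParseError(
                f"{self.case_id}: c.{self.c_start}_{self.c_end} outside "
                f"CDS [1, {model.cds_length}]"
            )
        if self.kind == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt:
                raise MutationParseError(
                    f"{self.case_id}: malformed substitution {self.ref}>{self.alt}"
                )
            expected = model.ref_base(self.c_start)
            if self.ref != expected:
                raise ReferenceMismatchError(
                    f"reference mismatch at c.{self.c_start}: "
                    f"expected {expected}, got {self.ref}"
                )
        elif self.kind in ("deletion", "duplication"):
            expected = model.ref_slice(self.c_start, self.c_end)
            if self.ref != expected:
                raise ReferenceMismatchError(
                    f"reference mismatch at c.{self.c_start}_{self.c_end}: "
                    f"expected {expected}, got {self.ref}"
                )
        elif self.kind == "insertion":
            if not self.alt or self.c_end != self.c_start:
                raise MutationParseError(
                    f"{self.case_id}: insertion needs bases and c_end == c_start"
                )
        return self


# ---------------------------------------------------------------------------
# c. notation


_SUB_RE = re.compile(r"^c\.(\d+)([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?del([ACGT]*)$")
_DUP_RE = re.compile(r"^c\.(\d+)(?:_(\d+))?dup([ACGT]*)$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def parse_c_notation(text: str, model: GeneModel, case_id: str = "") -> MutationRecord:
    """Parse one ``c.`` descriptor and validate it against the reference.

    Supported forms: ``c.76A>G``, ``c.100_102delTTC`` (stated bases
    optional), ``c.55_57dup``, ``c.10_11insACG``.  A stated allele that
    disagrees with the reference CDS raises :class:`ReferenceMismatchError`.
    """
    text = text.strip()
    if m := _SUB_RE.match(text):
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        rec = MutationRecord(case_id, "substitution", pos, pos, ref, alt)
    elif m := _DEL_RE.match(text):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        stated = m.group(3)
        ref = stated if stated else _safe_slice(model, start, end, text)
        rec = MutationRecord(case_id, "deletion", start, end, ref, "")
    elif m := _DUP_RE.match(text):
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        stated = m.group(3)
        ref = stated if stated else _safe_slice(model, start, end, text)
        rec = MutationRecord(case_id, "duplication", start, end, ref, ref)
    elif m := _INS_RE.match(text):
        start, end, bases = int(m.group(1)), int(m.group(2)), m.group(3)
        if end != start + 1:
            raise MutationParseError(
                f"insertion anchor must be adjacent positions, got {text!r}"
            )
        rec = MutationRecord(case_id, "insertion", start, start, "", bases)
    else:
        raise MutationParseError(f"unsupported mutation descriptor {text!r}")
    return rec.validate(model)


def _safe_slice(model: GeneModel, start: int, end: int, text: str) -> str:
    if not 1 <= start <= end <= model.cds_length:
        raise MutationParseError(
            f"{text!r}: c.{start}_{end} outside CDS [1, {model.cds_length}]"
        )
    return model.ref_slice(start, end)


def format_c_notation(rec: MutationRecord) -> str:
    """Inverse of :func:`parse_c_notation` (round-trips on all four kinds)."""
    if rec.kind == "substitution":
        return f"c.{rec.c_start}{rec.ref}>{rec.alt}"
    span = (
        f"{rec.c_start}" if rec.c_start == rec.c_end
        else f"{rec.c_start}_{rec.c_end}"
    )
    if rec.kind == "deletion":
        return f"c.{span}del{rec.ref}"
    if rec.kind == "duplication":
        return f"c.{span}dup"
    return f"c.{rec.c_start}_{rec.c_start + 1}ins{rec.alt}"


# ---------------------------------------------------------------------------
# mutation tables


def read_mutation_table(path: str | Path, model: GeneModel) -> dict[str, list[MutationRecord]]:
    """Read a per-case mutation TSV into case-grouped records.

    Two column dialects: ``case_id, mutation`` (c. notation) or the explicit
    ``case_id, kind, c_start, c_end, ref, alt``.  File order is preserved
    within each case; exact duplicate rows are kept but logged.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = set(df.columns)
    if {"case_id", "mutation"} <= cols:
        dialect = "cnotation"
    elif {"case_id", "kind", "c_start", "c_end", "ref", "alt"} <= cols:
        dialect = "explicit"
    else:
        raise MutationParseError(
            f"unknown mutation-table column set: {sorted(cols)}"
        )

    groups: dict[str, list[MutationRecord]] = {}
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            if dialect == "cnotation":
                rec = parse_c_notation(row.mutation, model, case_id=row.case_id)
            else:
                rec = MutationRecord(
                    case_id=row.case_id,
                    kind=row.kind,
                    c_start=int(row.c_start),
                    c_end=int(row.c_end),
                    ref=row.ref,
                    alt=row.alt,
                ).validate(model)
        except (ValueError, TypeError) as exc:
            raise MutationParseError(f"{path}, line {i}: {exc}") from exc
        key = tuple(row)
        if key in seen:
            log.warning("%s, line %d: exact duplicate row %s", path, i, key)
        seen.add(key)
        groups.setdefault(rec.case_id, []).append(rec)
    return groups


def write_mutation_table(groups: dict[str, list[MutationRecord]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("case_id\tmutation\n")
        for case_id, recs in groups.items():
            for rec in recs:
                fh.write(f"{case_id}\t{format_c_notation(rec)}\n")


# ---------------------------------------------------------------------------
# clinical records


_YESNO = {"yes": True, "no": False}

COO_LEVELS = ("GCB", "ABC", "unclassified")
MBL_LEVELS = ("mBL", "non-mBL", "intermediate")
PAP_LEVELS = ("BL-PAP", "PAP-1", "PAP-2", "PAP-3", "PAP-4", "mind-L")
CC_LEVELS = ("BCR", "HR", "OxPhos")
AAS_LEVELS = ("I", "II", "III", "IV")
CHEMO_LEVELS = ("ALL-like", "CHOP-like", "other", "none")
RESPONSE_LEVELS = ("CR", "CRu", "nC/SD", "PR", "PD")


@dataclass
class ClinicalRecord:
    """Per-case clinical, treatment, survival and signature-label data.

    Any field may be missing (``None``); survival is overall survival in
    months with ``os_event`` 1 = died, 0 = censored.
    """

    case_id: str
    age: Optional[float] = None
    sex: Optional[str] = None
    aas: Optional[str] = None
    b_symptoms: Optional[bool] = None
    ldh_gt_uln: Optional[bool] = None
    ecog_gt1: Optional[bool] = None
    en_gt1: Optional[bool] = None
    morphology: Optional[str] = None
    chemo_class: Optional[str] = None
    radiotherapy: Optional[bool] = None
    response: Optional[str] = None
    relapse: Optional[bool] = None
    os_time: Optional[float] = None
    os_event: Optional[int] = None
    coo: Optional[str] = None
    mbl: Optional[str] = None
    pap: Optional[str] = None
    cc: Optional[str] = None

    _VOCAB = {
        "sex": ("M", "F"),
        "aas": AAS_LEVELS,
        "chemo_class": CHEMO_LEVELS,
        "response": RESPONSE_LEVELS,
        "coo": COO_LEVELS,
        "mbl": MBL_LEVELS,
        "pap": PAP_LEVELS,
        "cc": CC_LEVELS,
    }

    def __post_init__(self) -> None:
        for name, levels in self._VOCAB.items():
            val = getattr(self, name)
            if val is not None and val not in levels:
                raise ValueError(
                    f"{self.case_id}: {name}={val!r} not in {levels}"
                )
        if self.os_time is not None and self.os_time < 0:
            raise ValueError(f"{self.case_id}: os_time < 0")
        if self.os_event is not None and self.os_event not in (0, 1):
            raise ValueError(f"{self.case_id}: os_event must be 0/1")


_BOOL_FIELDS = ("b_symptoms", "ldh_gt_uln", "ecog_gt1", "en_gt1",
                "radiotherapy", "relapse")
_FLOAT_FIELDS = ("age", "os_time")
_INT_FIELDS = ("os_event",)


def _parse_cell(name: str, raw: str):
    raw = raw.strip()
    if raw in ("", "."):
        return None
    if name in _BOOL_FIELDS:
        try:
            return _YESNO[raw.lower()]
        except KeyError:
            raise ValueError(f"{name}: expected yes/no, got {raw!r}") from None
    if name in _FLOAT_FIELDS:
        return float(raw)
    if name in _INT_FIELDS:
        return int(raw)
    return raw


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical TSV ('.' or empty cell = missing) into records."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "case_id" not in df.columns:
        raise ValueError(f"{path}: missing case_id column")
    known = {f.name for f in fields(ClinicalRecord)}
    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        kwargs = {}
        for name, raw in row.items():
            if name not in known:
                continue
            try:
                kwargs[name] = _parse_cell(name, raw) if name != "case_id" else raw
            except ValueError as exc:
                raise ValueError(f"{path}, line {i}: {exc}") from exc
        records.append(ClinicalRecord(**kwargs))
    return records


def write_clinical_table(records: list[ClinicalRecord], path: str | Path) -> None:
    names = [f.name for f in fields(ClinicalRecord) if not f.name.startswith("_")]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for rec in records:
            cells = []
            for name in names:
                val = getattr(rec, name)
                if val is None:
                    cells.append(".")
                elif isinstance(val, bool):
                    cells.append("yes" if val else "no")
                elif isinstance(val, float):
                    cells.append(repr(val))
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Records as a DataFrame (missing -> NaN/None), indexed by case_id."""
    rows = []
    for rec in records:
        rows.append({f.name: getattr(rec, f.name) for f in fields(rec)
                     if not f.name.startswith("_")})
    return pd.DataFrame(rows).set_index("case_id", drop=False)


# ---------------------------------------------------------------------------
# derived covariates


def compute_ipi(
    age_ge60: Optional[bool],
    ldh_gt_uln: Optional[bool],
    ecog_gt1: Optional[bool],
    aas_34: Optional[bool],
    en_gt1: Optional[bool],
) -> int:
    """IPI score 0-5: sum of the five adverse factors, missing scored 0.

    The missing->absent ("pessimistic") convention means a case with
    unknown factors may be under-scored; it is the only place missingness
    is converted to a value.
    """
    return sum(bool(f) for f in (age_ge60, ldh_gt_uln, ecog_gt1, aas_34, en_gt1))


def _flag(condition: Optional[bool]) -> Optional[int]:
    return None if condition is None else int(condition)


def encode_covariates(rec: ClinicalRecord, subtype_call=None) -> dict[str, Optional[int]]:
    """0/1 covariate encodings for survival modelling.

    Keys follow the regression conventions: age60 (age >= 60), ldh (> ULN),
    ecog (> 1), aas34 (stage III/IV), en (> 1 extranodal site), bsym, ib
    (immunoblastic morphology), non_gcb, non_mbl, non_pap1, non_bcr, ipi2
    (IPI >= 2), and mutation status socs1_mut / socs1_major / socs1_minor.
    A covariate is None when its source field is missing — except ipi2,
    which inherits the IPI missing->0 rule.
    """
    age60 = None if rec.age is None else rec.age >= 60
    aas34 = None if rec.aas is None else rec.aas in ("III", "IV")
    cov: dict[str, Optional[int]] = {
        "age60": _flag(age60),
        "ldh": _flag(rec.ldh_gt_uln),
        "ecog": _flag(rec.ecog_gt1),
        "aas34": _flag(aas34),
        "en": _flag(rec.en_gt1),
        "bsym": _flag(rec.b_symptoms),
        "ib": _flag(None if rec.morphology is None else rec.morphology == "IB"),
        "non_gcb": _flag(None if rec.coo is None else rec.coo != "GCB"),
        "non_mbl": _flag(None if rec.mbl is None else rec.mbl != "mBL"),
        "non_pap1": _flag(None if rec.pap is None else rec.pap != "PAP-1"),
        "non_bcr": _flag(None if rec.cc is None else rec.cc != "BCR"),
        "ipi2": int(
            compute_ipi(age60, rec.ldh_gt_uln, rec.ecog_gt1, aas34, rec.en_gt1) >= 2
        ),
    }
    if subtype_call is None:
        cov.update(socs1_mut=None, socs1_major=None, socs1_minor=None)
    else:
        call = getattr(subtype_call, "call", subtype_call)
        cov["socs1_mut"] = int(call != "wild_type")
        cov["socs1_major"] = int(call == "major")
        cov["socs1_minor"] = int(call == "minor")
    return cov
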