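"""Gene reference frame: coding sequence, protein domains, coordinate arithmetic.

Everything downstream (consequence calling, severity subtyping, motif
scanning, frequency maps) is expressed in 1-based, fully-closed CDS
coordinates (the HGVS-like ``c.`` convention).  A :class:`GeneModel` bundles
the coding sequence, an ordered list of protein-domain intervals, the set of
domain names treated as *C-terminal* for severity calling, optional flanking
context sequence for motif scanning across the CDS edges, and the transcript
position of the translation start so transcript coordinates can be mapped
onto the CDS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "DomainAnnotation",
    "GeneModel",
    "GeneModelError",
    "CdsPosition",
    "Amplicon",
    "load_gene_model",
    "socs1_model",
    "transcript_to_cds_position",
    "find_amplicon",
    "revcomp",
]

_VALID_BASES = frozenset("ACGT")
_STOPS = frozenset({"TAA", "TAG", "TGA"})


class GeneModelError(ValueError):
    """Raised for schema or validation failures in a gene model."""


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T string."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class DomainAnnotation:
    """A named protein-domain interval, 1-based inclusive amino-acid coords.

    Domains may overlap or nest (e.g. KIR and SH2 lie within the JAK
    region); they are never merged.  The derived nucleotide interval on the
    CDS is ``[3*(aa_start-1)+1, 3*aa_end]``.
    """

    name: str
    aa_start: int
    aa_end: int
    is_cterminal: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.aa_start <= self.aa_end):
            raise GeneModelError(
                f"domain {self.name!r}: invalid interval "
                f"[{self.aa_start}, {self.aa_end}]"
            )

    @property
    def nt_start(self) -> int:
        return 3 * (self.aa_start - 1) + 1

    @property
    def nt_end(self) -> int:
        return 3 * self.aa_end


@dataclass
class GeneModel:
    gene_symbol: str
    cds: str
    domains: list[DomainAnnotation] = field(default_factory=list)
    cterm_names: frozenset[str] = frozenset()
    upstream_context: str = ""
    downstream_context: str = ""
    cds_offset_in_exon2: Optional[int] = None

    def __post_init__(self) -> None:
        self.cds = _normalize_seq(self.cds)
        self.upstream_context = _normalize_seq(self.upstream_context)
        self.downstream_context = _normalize_seq(self.downstream_context)
        self.cterm_names = frozenset(self.cterm_names)

    # -- derived quantities -------------------------------------------------

    @property
    def cds_length(self) -> int:
        return len(self.cds)

    @property
    def protein_length(self) -> int:
        """Protein length in aa, stop codon included in the CDS but not here."""
        return self.cds_length // 3 - 1

    @property
    def protein(self) -> str:
        """Translation of the CDS without the terminal stop."""
        return str(Seq(self.cds).translate()).rstrip("*")

    def domain(self, name: str) -> DomainAnnotation:
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(name)

    def cterm_domains(self) -> list[DomainAnnotation]:
        return [d for d in self.domains if d.name in self.cterm_names]

    def ref_base(self, c_pos: int) -> str:
        if not 1 <= c_pos <= self.cds_length:
            raise GeneModelError(f"c.{c_pos} outside CDS [1, {self.cds_length}]")
        return self.cds[c_pos - 1]

    def ref_slice(self, c_start: int, c_end: int) -> str:
        if not 1 <= c_start <= c_end <= self.cds_length:
            raise GeneModelError(
                f"c.{c_start}_{c_end} outside CDS [1, {self.cds_length}]"
            )
        return self.cds[c_start - 1 : c_end]

    # -- validation ---------------------------------------------------------

    def validate(self, strict: bool = True) -> list[str]:
        """Check all model invariants.

        ``strict`` raises on CDS irregularities (packaged/simulated
        references must be clean); with ``strict=False`` those become
        warnings instead, so a user-supplied reference with, say, a
        non-canonical start is usable.  Domain/coordinate violations always
        raise.  Returns the list of warning messages issued.
        """
        issued: list[str] = []

        def _cds_issue(msg: str) -> None:
            if strict:
                raise GeneModelError(msg)
            issued.append(msg)
            warnings.warn(msg, stacklevel=3)

        bad = set(self.cds) - _VALID_BASES
        if bad:
            raise GeneModelError(f"CDS contains non-ACGT characters: {sorted(bad)}")
        if len(self.cds) % 3 != 0:
            raise GeneModelError(
                f"CDS length {len(self.cds)} not divisible by 3"
            )
        if not self.cds.startswith("ATG"):
            raise GeneModelError("CDS does not start with ATG")
        if self.cds[-3:] not in _STOPS:
            _cds_issue(f"CDS does not end with a stop codon (got {self.cds[-3:]})")
        internal = [
            i // 3 + 1
            for i in range(0, len(self.cds) - 3, 3)
            if self.cds[i : i + 3] in _STOPS
        ]
        if internal:
            _cds_issue(f"CDS has internal in-frame stop at codon(s) {internal}")

        plen = self.cds_length // 3  # codons incl. stop
        for d in self.domains:
            if d.nt_end > self.cds_length or d.aa_end > plen:
                raise GeneModelError(
                    f"domain {d.name!r} [{d.aa_start},{d.aa_end}] extends "
                    f"beyond the {plen}-codon CDS"
                )
        names = {d.name for d in self.domains}
        unknown = self.cterm_names - names
        if unknown:
            raise GeneModelError(
                f"cterm_names not among domains: {sorted(unknown)}"
            )
        return issued


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# loading


_REQUIRED_FIELDS = ("gene_symbol", "cds", "domains")


def load_gene_model(model_path: str | Path, strict: bool = True) -> GeneModel:
    """Load and validate a gene model from its JSON descriptor.

    Schema::

        {
          "gene_symbol": str,
          "cds": str | {"fasta": "relative/path.fa"},
          "cds_offset_in_exon2": int | null,
          "domains": [{"name", "aa_start", "aa_end", "is_cterminal"}, ...],
          "upstream_context": str, "downstream_context": str
        }

    A FASTA reference is resolved relative to the JSON file; only the first
    record is read, uppercased, with U normalized to T.
    """
    model_path = Path(model_path)
    if not model_path.exists():
        raise GeneModelError(f"gene model file not found: {model_path}")
    with open(model_path) as fh:
        raw = json.load(fh)
    for key in _REQUIRED_FIELDS:
        if key not in raw:
            raise GeneModelError(f"gene model JSON missing required field {key!r}")

    cds = raw["cds"]
    if isinstance(cds, dict):
        if "fasta" not in cds:
            raise GeneModelError("cds object must carry a 'fasta' path")
        fasta = model_path.parent / cds["fasta"]
        if not fasta.exists():
            raise GeneModelError(f"CDS FASTA not found: {fasta}")
        record = next(SeqIO.parse(str(fasta), "fasta"))
        cds = str(record.seq)

    domains = []
    for i, d in enumerate(raw["domains"]):
        for key in ("name", "aa_start", "aa_end"):
            if key not in d:
                raise GeneModelError(f"domains[{i}] missing required field {key!r}")
        domains.append(
            DomainAnnotation(
                name=d["name"],
                aa_start=int(d["aa_start"]),
                aa_end=int(d["aa_end"]),
                is_cterminal=bool(d.get("is_cterminal", False)),
            )
        )

    model = GeneModel(
        gene_symbol=raw["gene_symbol"],
        cds=cds,
        domains=domains,
        cterm_names=frozenset(d.name for d in domains if d.is_cterminal),
        upstream_context=raw.get("upstream_context", "") or "",
        downstream_context=raw.get("downstream_context", "") or "",
        cds_offset_in_exon2=raw.get("cds_offset_in_exon2"),
    )
    model.validate(strict=strict)
    return model


def socs1_model() -> GeneModel:
    """The packaged SOCS1-like default gene model (636-bp CDS).

    Domain boundaries are literature-style stand-ins recorded in the
    editable JSON fixture; the domain identities (SH3, KIR, SH2, JAK, NLS,
    SOCS box) and the C-terminal set {NLS, SOCS box} are the analysis
    defaults.
    """
    here = Path(__file__).parent / "data" / "socs1_model.json"
    return load_gene_model(here)


# ---------------------------------------------------------------------------
# coordinate arithmetic


@dataclass(frozen=True)
class CdsPosition:
    """Result of a transcript->CDS projection.

    ``region`` is ``"cds"``, ``"utr5"`` or ``"utr3"``; ``c`` is the 1-based
    CDS coordinate when inside, else ``None``; ``distance`` is the gap to
    the nearest CDS edge for UTR hits.
    """

    region: str
    c: Optional[int] = None
    distance: int = 0

    @property
    def in_cds(self) -> bool:
        return self.region == "cds"


def transcript_to_cds_position(pos: int, model: GeneModel) -> CdsPosition:
    """Map a transcript/exon-2 position onto the CDS frame.

    With the packaged SOCS1 offsets, transcript position 705 (the
    translation start) maps to c.1 and position 1340 (the stop codon end)
    to c.636.
    """
    if model.cds_offset_in_exon2 is None:
        raise GeneModelError("model has no cds_offset_in_exon2")
    if pos < 1:
        raise GeneModelError(f"transcript position must be >= 1, got {pos}")
    c = pos - model.cds_offset_in_exon2 + 1
    if c < 1:
        return CdsPosition("utr5", None, 1 - c)
    if c > model.cds_length:
        return CdsPosition("utr3", None, c - model.cds_length)
    return CdsPosition("cds", c)


def cds_to_transcript_position(c: int, model: GeneModel) -> int:
    """Inverse of :func:`transcript_to_cds_position` on [1, L_c]."""
    if model.cds_offset_in_exon2 is None:
        raise GeneModelError("model has no cds_offset_in_exon2")
    if not 1 <= c <= model.cds_length:
        raise GeneModelError(f"c.{c} outside CDS [1, {model.cds_length}]")
    return c + model.cds_offset_in_exon2 - 1


# ---------------------------------------------------------------------------
# primer / amplicon arithmetic


class PrimerError(ValueError):
    """Primer not found, or no amplifiable product."""


@dataclass(frozen=True)
class Amplicon:
    start: int  # 1-based, first base of forward-primer match
    end: int    # 1-based, last base of the reverse-primer's revcomp match
    multiple_placements: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def find_amplicon(template: str, fwd_primer: str, rev_primer: str) -> Amplicon:
    """Locate the PCR product of an exact-match primer pair on a template.

    The forward primer is matched on the given strand, the reverse primer as
    its reverse complement.  Returns the 1-based inclusive interval from the
    first base of the forward match to the last base of the reverse match;
    with multiple placements the leftmost forward match is paired with the
    nearest downstream reverse match and the result is flagged.
    """
    if not fwd_primer or not rev_primer:
        raise PrimerError("primers must be non-empty")
    template = _normalize_seq(template)
    fwd = _normalize_seq(fwd_primer)
    rev_rc = revcomp(_normalize_seq(rev_primer))

    fwd_hits = _all_occurrences(template, fwd)
    if not fwd_hits:
        raise PrimerError("primer absent: forward")
    rev_hits = _all_occurrences(template, rev_rc)
    if not rev_hits:
        raise PrimerError("primer absent: reverse")

    f0 = fwd_hits[0]
    downstream = [r for r in rev_hits if r + len(rev_rc) > f0 + len(fwd)]
    if not downstream:
        raise PrimerError("no product: reverse match upstream of forward match")
    r0 = downstream[0]
    multiple = len(fwd_hits) > 1 or len(downstream) > 1
    if multiple:
        warnings.warn(
            "multiple primer placements; returning leftmost forward with "
            "nearest downstream reverse",
            stacklevel=2,
        )
    return Amplicon(start=f0 + 1, end=r0 + len(rev_rc), multiple_placements=multiple)
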