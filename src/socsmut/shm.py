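"""Somatic-hypermutation hotspot motif scanning and targeting statistics.

AID-driven somatic hypermutation preferentially mutates the G:C pair of
RGYW/WRCY and DGYW/WRCH motifs and the A:T pair of WA/TW motifs, on both
DNA strands.  Each family's reverse complement partner is in the set
(RGYW<->WRCY, DGYW<->WRCH, WA<->TW), so scanning the forward strand for all
six patterns is mathematically identical to scanning both strands — and
avoids coordinate-mirroring bugs.  "At a motif" always means at the
*mutable* position of a hit, not merely anywhere inside the motif.
Overlapping and nested hits are all reported and never deduplicated
(every RGYW occurrence is also a DGYW occurrence); the family union drives
the targeted/untargeted dichotomy while per-family counts stay available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gene_model import GeneModel
from .mutation_io import MutationRecord

__all__ = [
    "MotifSpec",
    "MotifHit",
    "MOTIF_SPECS",
    "scan_motifs",
    "mutable_positions",
    "is_shm_targeted",
    "deletion_flank_shm",
    "summarize_shm",
    "shm_enrichment_test",
    "ShmTargeting",
    "ShmSummary",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG",
    "D": "AGT", "H": "ACT",
}


@dataclass(frozen=True)
class MotifSpec:
    family: str
    pattern: str          # IUPAC string
    mutable_offset: int   # 0-based index of the mutable base
    partner: str          # reverse-complement family

    def regex(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all found
        body = "".join(f"[{IUPAC[ch]}]" for ch in self.pattern)
        return re.compile(f"(?=({body}))")


MOTIF_SPECS: tuple[MotifSpec, ...] = (
    MotifSpec("RGYW", "RGYW", 1, "WRCY"),
    MotifSpec("WRCY", "WRCY", 2, "RGYW"),
    MotifSpec("DGYW", "DGYW", 1, "WRCH"),
    MotifSpec("WRCH", "WRCH", 2, "DGYW"),
    MotifSpec("WA", "WA", 1, "TW"),
    MotifSpec("TW", "TW", 0, "WA"),
)

_SPEC_BY_FAMILY = {s.family: s for s in MOTIF_SPECS}

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class MotifHit:
    family: str
    start: int  # 1-based position of the first motif base in the scanned seq

    @property
    def length(self) -> int:
        return len(_SPEC_BY_FAMILY[self.family].pattern)

    @property
    def end(self) -> int:
        return self.start + self.length - 1

    @property
    def mutable_position(self) -> int:
        return self.start + _SPEC_BY_FAMILY[self.family].mutable_offset


def scan_motifs(seq: str) -> list[MotifHit]:
    """All hotspot-motif occurrences in ``seq``, every family, every offset."""
    for i, ch in enumerate(seq):
        if ch not in _VALID:
            raise ValueError(f"non-ACGT character {ch!r} at position {i + 1}")
    hits: list[MotifHit] = []
    for spec in MOTIF_SPECS:
        for m in spec.regex().finditer(seq):
            hits.append(MotifHit(spec.family, m.start() + 1))
    hits.sort(key=lambda h: (h.start, h.family))
    return hits


def _scanned(model: GeneModel) -> tuple[str, int]:
    """Context-padded sequence and the offset of c.1 within it (0-based)."""
    return (
        model.upstream_context + model.cds + model.downstream_context,
        len(model.upstream_context),
    )


def mutable_positions(model: GeneModel) -> frozenset[int]:
    """CDS positions (c. coordinates) that are the mutable base of >=1 hit."""
    seq, off = _scanned(model)
    out = set()
    for h in scan_motifs(seq):
        c = h.mutable_position - off
        if 1 <= c <= model.cds_length:
            out.add(c)
    return frozenset(out)


@dataclass(frozen=True)
class ShmTargeting:
    targeted: bool
    families: tuple[str, ...]
    boundary_uncertain: bool


def is_shm_targeted(m: MutationRecord, model: GeneModel) -> ShmTargeting:
    """Whether a substitution sits on the mutable base of a hotspot motif.

    Scanning uses the model's flanking context so motifs straddling the CDS
    edge are seen; without context, positions within 3 nt of an edge carry
    a ``boundary_uncertain`` flag.
    """
    if m.kind != "substitution":
        raise ValueError(
            "is_shm_targeted applies to substitutions only; "
            "use deletion_flank_shm for deletions"
        )
    seq, off = _scanned(model)
    pos = m.c_start + off
    families = tuple(sorted({
        h.family for h in scan_motifs(seq) if h.mutable_position == pos
    }))
    uncertain = (
        (m.c_start <= 3 and not model.upstream_context)
        or (m.c_start > model.cds_length - 3 and not model.downstream_context)
    )
    return ShmTargeting(bool(families), families, uncertain)


def deletion_flank_shm(
    m: MutationRecord, model: GeneModel, window: int = 4
) -> dict[str, bool]:
    """Whether either flank of a deletion abuts a hotspot motif.

    A flank is positive when some motif occurrence intersects the
    ``window`` nt immediately outside that breakpoint (default 4 nt, one
    motif length).  ``window=0`` is always negative.
    """
    if m.kind != "deletion":
        raise ValueError("deletion_flank_shm applies to deletions only")
    if window < 0:
        raise ValueError("window must be >= 0")
    seq, off = _scanned(model)
    hits = scan_motifs(seq) if window else []
    left_lo, left_hi = m.c_start - window + off, m.c_start - 1 + off
    right_lo, right_hi = m.c_end + 1 + off, m.c_end + window + off

    def overlaps(lo: int, hi: int) -> bool:
        return any(h.start <= hi and h.end >= lo for h in hits)

    return {
        "left": window > 0 and overlaps(left_lo, left_hi),
        "right": window > 0 and overlaps(right_lo, right_hi),
    }


@dataclass
class ShmSummary:
    n_point: int
    n_at_motif: int
    fraction: Optional[float]
    n_gc: int
    n_at: int
    n_gc_at_motif: int
    n_at_at_motif: int
    family_counts: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "n_point_mutations": self.n_point,
            "n_at_motif": self.n_at_motif,
            "fraction_at_motif": self.fraction,
            "n_gc": self.n_gc,
            "n_at": self.n_at,
            "n_gc_at_motif": self.n_gc_at_motif,
            "n_at_at_motif": self.n_at_at_motif,
            "family_counts": dict(self.family_counts),
        }


def summarize_shm(
    cohort: dict[str, Sequence[MutationRecord]], model: GeneModel
) -> ShmSummary:
    """Cohort-level motif-targeting tallies over all point mutations.

    Splits by reference base class (G/C vs A/T) and reports per-family hit
    counts; the at-motif fraction is None for an empty cohort.
    """
    n_point = n_at_motif = n_gc = n_at = n_gc_m = n_at_m = 0
    fam_counts: dict[str, int] = {s.family: 0 for s in MOTIF_SPECS}
    for recs in cohort.values():
        for m in recs:
            if m.kind != "substitution":
                continue
            n_point += 1
            t = is_shm_targeted(m, model)
            gc = m.ref in "GC"
            n_gc += gc
            n_at += not gc
            if t.targeted:
                n_at_motif += 1
                n_gc_m += gc
                n_at_m += not gc
                for fam in t.families:
                    fam_counts[fam] += 1
    return ShmSummary(
        n_point=n_point,
        n_at_motif=n_at_motif,
        fraction=(n_at_motif / n_point) if n_point else None,
        n_gc=n_gc,
        n_at=n_at,
        n_gc_at_motif=n_gc_m,
        n_at_at_motif=n_at_m,
        family_counts=fam_counts,
    )


def shm_enrichment_test(
    cohort: dict[str, Sequence[MutationRecord]],
    model: GeneModel,
    B: int = 2000,
    seed: int | None = None,
) -> float:
    """Permutation test for motif targeting of the cohort's substitutions.

    Null: the observed number of substitutions lands uniformly on the CDS.
    ``p = (r + 1) / (B + 1)`` where r counts replicates whose at-motif tally
    reaches the observed one (add-one correction keeps p in (0, 1]).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    subs = [m for recs in cohort.values() for m in recs
            if m.kind == "substitution"]
    if not subs:
        raise ValueError("no substitutions to test")
    mut_pos = mutable_positions(model)
    observed = sum(m.c_start in mut_pos for m in subs)
    rng = np.random.default_rng(seed)
    is_mut = np.zeros(model.cds_length, dtype=bool)
    is_mut[[p - 1 for p in mut_pos]] = True
    draws = rng.integers(0, model.cds_length, size=(B, len(subs)))
    counts = is_mut[draws].sum(axis=1)
    r = int((counts >= observed).sum())
    return (r + 1) / (B + 1)
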