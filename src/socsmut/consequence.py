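"""Protein-level consequences of coding mutations, per event and per case.

The central severity quantity is the *intact coding length*: the number of
5' reference nucleotides still encoded in frame ahead of the first
truncating event.  It is defined at the nucleotide level by a min-rule over
all events of a case:

* a frame-disrupting indel (net inserted−deleted length mod 3 != 0)
  bounds the intact length at ``c_start − 1``;
* a stop-gain substitution creating a stop at codon *s* bounds it at
  ``3·(s − 1)``;
* a premature in-frame stop introduced inside in-frame inserted or
  duplicated material bounds it at codon granularity just before the last
  preserved reference base;
* with no such event the intact length is the full CDS length.

Silent and missense substitutions, and purely in-frame indels that create
no stop, never shorten it.  Domain impact is then read off under two
weightings: *conservative* (a downstream domain counts as lost only when
its entire coding interval lies beyond the intact length, or a deletion
removes it wholly) and *aggressive* (any partial loss, or any position
shift caused by an upstream net-length change, also counts).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .gene_model import GeneModel
from .mutation_io import MutationRecord

__all__ = [
    "MutationConsequence",
    "CaseConsequence",
    "ConflictingEventsError",
    "WEIGHTING_SCHEMES",
    "classify_mutation",
    "apply_case_mutations",
    "domain_impact",
]

log = logging.getLogger(__name__)

WEIGHTING_SCHEMES = ("conservative", "aggressive")

EFFECTS = (
    "silent",
    "missense",
    "nonsense",
    "frameshift",
    "inframe_deletion",
    "inframe_duplication",
    "inframe_insertion",
)

_STOPS = frozenset({"TAA", "TAG", "TGA"})


class ConflictingEventsError(ValueError):
    """Overlapping deletion intervals within one case."""


@dataclass(frozen=True)
class MutationConsequence:
    effect: str
    first_affected_codon: int
    premature_stop_at: Optional[int] = None  # protein codon number


@dataclass
class CaseConsequence:
    case_id: str
    mutations: list[MutationRecord]
    consequences: list[MutationConsequence]
    mutant_cds: str
    intact_cds_length: int
    truncating: bool
    affected_direct: frozenset[str] = frozenset()
    affected_conservative: frozenset[str] = frozenset()
    affected_aggressive: frozenset[str] = frozenset()


def classify_mutation(m: MutationRecord, model: GeneModel) -> MutationConsequence:
    """Effect class of a single event in the reference reading frame."""
    first_codon = math.ceil(m.c_start / 3)
    if m.kind == "substitution":
        codon_start = 3 * (first_codon - 1)  # 0-based
        ref_codon = model.cds[codon_start : codon_start + 3]
        offset = (m.c_start - 1) - codon_start
        alt_codon = ref_codon[:offset] + m.alt + ref_codon[offset + 1 :]
        if alt_codon in _STOPS:
            return MutationConsequence("nonsense", first_codon, premature_stop_at=first_codon)
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        effect = "silent" if ref_aa == alt_aa else "missense"
        return MutationConsequence(effect, first_codon)
    if m.frame_disrupting:
        return MutationConsequence("frameshift", first_codon)
    effect = {
        "deletion": "inframe_deletion",
        "duplication": "inframe_duplication",
        "insertion": "inframe_insertion",
    }[m.kind]
    return MutationConsequence(effect, first_codon)


# ---------------------------------------------------------------------------
# per-case merge


def _check_deletion_overlap(mutations: Sequence[MutationRecord]) -> None:
    dels = sorted(
        ((m.c_start, m.c_end) for m in mutations if m.kind == "deletion")
    )
    for (s1, e1), (s2, e2) in zip(dels, dels[1:]):
        if s2 <= e1:
            raise ConflictingEventsError(
                f"conflicting events: deletions [{s1},{e1}] and [{s2},{e2}] overlap"
            )


def _build_mutant(mutations: Sequence[MutationRecord], model: GeneModel):
    """Apply events 3'->5' to the reference CDS.

    Returns (mutant_cds, tags) where ``tags[i]`` is the reference position
    of mutant base i, or None for newly inserted/duplicated material.
    Applying in descending c_start order keeps every stored coordinate
    reference-valid, so no re-mapping is needed.  Repeated substitutions at
    one position are applied in file order — last wins — with a warning.
    """
    tagged: list[tuple[Optional[int], str]] = [
        (i + 1, b) for i, b in enumerate(model.cds)
    ]
    # stable descending sort: ties keep file order, so for repeated
    # substitutions at one position the later row overwrites (last wins)
    order = sorted(
        range(len(mutations)), key=lambda i: mutations[i].c_start, reverse=True
    )
    seen_sub_pos: set[int] = set()
    for idx in order:
        m = mutations[idx]
        i0 = m.c_start - 1
        if m.kind == "substitution":
            if m.c_start in seen_sub_pos:
                log.warning(
                    "%s: repeated substitution at c.%d; later row wins",
                    m.case_id, m.c_start,
                )
            seen_sub_pos.add(m.c_start)
            tagged[i0] = (m.c_start, m.alt)
        elif m.kind == "deletion":
            del tagged[i0 : m.c_end]
        elif m.kind == "duplication":
            tagged[m.c_end : m.c_end] = [(None, b) for b in m.alt]
        elif m.kind == "insertion":
            tagged[m.c_start : m.c_start] = [(None, b) for b in m.alt]
    mutant = "".join(b for _, b in tagged)
    tags = [t for t, _ in tagged]
    return mutant, tags


def _inserted_stop_bound(mutant: str, tags: list[Optional[int]]) -> Optional[int]:
    """Reference-frame bound from a premature stop inside inserted material.

    Scans mutant codons; on the first stop whose bases include newly
    inserted (untagged) material, returns 3·floor(anchor/3) where anchor is
    the last reference base preserved before that codon — whole reference
    codons ahead of the new stop, mirroring the 3·(s−1) stop-gain rule.
    """
    for i in range(0, len(mutant) - len(mutant) % 3, 3):
        codon = mutant[i : i + 3]
        if codon in _STOPS:
            codon_tags = tags[i : i + 3]
            if any(t is None for t in codon_tags):
                prior = [t for t in tags[:i] if t is not None]
                anchor = max(prior, default=0)
                return 3 * (anchor // 3)
            return None  # first in-frame stop is reference material
    return None


def apply_case_mutations(
    mutations: Sequence[MutationRecord], model: GeneModel, case_id: Optional[str] = None
) -> CaseConsequence:
    """Merge all events of one case into a mutant CDS and severity summary."""
    mutations = list(mutations)
    if case_id is None:
        case_id = mutations[0].case_id if mutations else ""
    if any(m.case_id != case_id for m in mutations if m.case_id):
        raise ValueError("all mutations must belong to one case")
    for m in mutations:
        m.validate(model)
    _check_deletion_overlap(mutations)

    consequences = [classify_mutation(m, model) for m in mutations]
    mutant, tags = _build_mutant(mutations, model)

    bounds = [model.cds_length]
    for m, cq in zip(mutations, consequences):
        if m.kind != "substitution" and m.frame_disrupting:
            bounds.append(m.c_start - 1)
        if cq.effect == "nonsense":
            bounds.append(3 * (cq.premature_stop_at - 1))
    ins_bound = _inserted_stop_bound(mutant, tags)
    if ins_bound is not None:
        bounds.append(ins_bound)
    intact = min(bounds)

    cc = CaseConsequence(
        case_id=case_id,
        mutations=mutations,
        consequences=consequences,
        mutant_cds=mutant,
        intact_cds_length=intact,
        truncating=intact < model.cds_length,
    )
    cc.affected_direct = domain_impact(cc, model, "direct")
    cc.affected_conservative = domain_impact(cc, model, "conservative")
    cc.affected_aggressive = domain_impact(cc, model, "aggressive")
    return cc


# ---------------------------------------------------------------------------
# domain impact


def _direct_hit(m: MutationRecord, nt_start: int, nt_end: int) -> bool:
    if m.kind == "insertion":
        # the anchor gap (between c_start and c_start+1) lies inside the domain
        return nt_start <= m.c_start < nt_end
    return m.c_start <= nt_end and m.c_end >= nt_start


def domain_impact(cc: CaseConsequence, model: GeneModel, scheme: str) -> frozenset[str]:
    """Domain names affected by a case under a weighting scheme.

    ``"direct"`` — an event footprint intersects the domain interval.
    ``"conservative"`` — additionally, domains wholly beyond the intact
    coding length or wholly deleted.  ``"aggressive"`` — additionally,
    domains partially beyond the intact length, partially deleted, or
    shifted by any upstream net-length-changing event.
    """
    if scheme not in ("direct",) + WEIGHTING_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    hit: set[str] = set()
    for d in model.domains:
        ns, ne = d.nt_start, d.nt_end
        if any(_direct_hit(m, ns, ne) for m in cc.mutations):
            hit.add(d.name)
            continue
        if scheme == "direct":
            continue
        if scheme == "conservative":
            if ns > cc.intact_cds_length:
                hit.add(d.name)
            elif any(
                m.kind == "deletion" and m.c_start <= ns and m.c_end >= ne
                for m in cc.mutations
            ):
                hit.add(d.name)
        else:  # aggressive
            if ne > cc.intact_cds_length:
                hit.add(d.name)
            elif any(
                m.net_length_change != 0 and m.c_start < ns
                for m in cc.mutations
            ):
                hit.add(d.name)
    return frozenset(hit)
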