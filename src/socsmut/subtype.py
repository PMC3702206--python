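"""Case-level severity subtyping: wild-type / *minor* / *major*.

A mutated case is *major* when it carries at least one foreshortening
event — stop-gain, frameshift, deletion, or frame-disrupting
duplication/insertion — whose aggressive-weighting impact reaches a
C-terminal domain (the aggressive scheme is the operational reading of
"affects presence or position" of those domains).  A case whose events are
all non-foreshortening point substitutions is *minor*.  The remaining edge
cases — foreshortening events that never reach a C-terminal domain, or
cases of in-frame indels only — default to *major* with an ``ambiguous``
flag: they are deleterious but local, and they are not point mutations, so
*minor* would be textually wrong.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .consequence import CaseConsequence, apply_case_mutations, classify_mutation
from .gene_model import GeneModel
from .mutation_io import MutationRecord, format_c_notation

__all__ = ["SubtypeCall", "classify_case", "severity_sort"]

CALLS = ("wild_type", "minor", "major")


@dataclass(frozen=True)
class SubtypeCall:
    case_id: str
    call: str
    basis: tuple[str, ...] = ()
    ambiguous: bool = False


def _is_foreshortening(m: MutationRecord, effect: str) -> bool:
    if effect == "nonsense":
        return True
    if m.kind == "deletion":
        return True
    return m.kind in ("duplication", "insertion") and m.frame_disrupting


def classify_case(
    mutations: Sequence[MutationRecord],
    model: GeneModel,
    case_id: str | None = None,
) -> SubtypeCall:
    """Call the severity subtype of one case.

    The call is invariant to mutation row order and to exact duplicate
    rows; every case receives exactly one call.
    """
    mutations = list(mutations)
    if case_id is None:
        case_id = mutations[0].case_id if mutations else ""
    if not mutations:
        return SubtypeCall(case_id, "wild_type")

    effects = [classify_mutation(m, model).effect for m in mutations]
    basis: list[str] = []
    for m, eff in zip(mutations, effects):
        if not _is_foreshortening(m, eff):
            continue
        solo = apply_case_mutations([m], model, case_id=m.case_id or case_id)
        if solo.affected_aggressive & model.cterm_names:
            basis.append(format_c_notation(m))
    if basis:
        return SubtypeCall(case_id, "major", basis=tuple(dict.fromkeys(basis)))

    if all(m.kind == "substitution" and eff != "nonsense"
           for m, eff in zip(mutations, effects)):
        return SubtypeCall(
            case_id, "minor",
            basis=tuple(dict.fromkeys(format_c_notation(m) for m in mutations)),
        )

    # foreshortening events with no C-terminal reach, or in-frame indels only:
    # severity-conservative default
    odd = tuple(dict.fromkeys(
        format_c_notation(m) for m, eff in zip(mutations, effects)
        if m.kind != "substitution" or eff == "nonsense"
    ))
    return SubtypeCall(case_id, "major", basis=odd, ambiguous=True)


def severity_sort(
    annotated: Sequence[tuple[SubtypeCall, CaseConsequence]]
) -> list[tuple[SubtypeCall, CaseConsequence]]:
    """Severity ordering of cases for mutation-map plotting.

    Ascending intact coding length (most foreshortened first), then
    descending mutation count, then case_id — a stable total order.
    """
    return sorted(
        annotated,
        key=lambda pair: (
            pair[1].intact_cds_length,
            -len(pair[1].mutations),
            pair[0].case_id,
        ),
    )
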