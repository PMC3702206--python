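"""Synthetic gene models and cohorts with planted ground truth.

The generator emulates the statistical structure of a single-gene mutation
screen in an aggressive B-cell lymphoma cohort: ~16% of cases mutated, a
50/50 split of mutated cases into truncating (*major*) and point-mutation
(*minor*) subtypes, 1-18 point mutations per mutated case with a
right-skewed (truncated-geometric) count distribution, hotspot-motif bias
of substitution positions, expression-signature labels drawn conditionally
on subtype, and exponential survival under proportional hazards with
independent uniform censoring.  Every draw flows from one seed, and the
planted truth (true subtype, true events, true motif-targeting flags) is
returned alongside the emitted tables so recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .gene_model import DomainAnnotation, GeneModel
from .mutation_io import (
    ClinicalRecord,
    MutationRecord,
    format_c_notation,
    write_clinical_table,
    write_mutation_table,
)
from .shm import mutable_positions

__all__ = [
    "SimulationParams",
    "PlantedTruth",
    "SyntheticCohort",
    "generate_reference",
    "generate_cohort",
    "socs1_domain_layout",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}

# Signature-label conditionals per subtype, proportional to the published
# screening-cohort tallies (wild-type n=130, major n=12, minor n=12); any
# of them can be overridden through SimulationParams.signature_conditionals.
_DEFAULT_SIGNATURES: dict[str, dict[str, dict[str, float]]] = {
    "coo": {
        "wild_type": {"GCB": 51, "ABC": 47, "unclassified": 32},
        "major": {"GCB": 12, "ABC": 0, "unclassified": 0},
        "minor": {"GCB": 7, "ABC": 2, "unclassified": 3},
    },
    "mbl": {
        "wild_type": {"mBL": 9, "non-mBL": 90, "intermediate": 31},
        "major": {"mBL": 1, "non-mBL": 9, "intermediate": 2},
        "minor": {"mBL": 0, "non-mBL": 10, "intermediate": 2},
    },
    "cc": {
        "wild_type": {"BCR": 66, "HR": 38, "OxPhos": 16},
        "major": {"BCR": 5, "HR": 4, "OxPhos": 0},
        "minor": {"BCR": 5, "HR": 4, "OxPhos": 2},
    },
    "pap": {
        "wild_type": {"BL-PAP": 10, "mind-L": 38, "PAP-1": 25,
                      "PAP-2": 27, "PAP-3": 21, "PAP-4": 9},
        "major": {"BL-PAP": 0, "mind-L": 4, "PAP-1": 7,
                  "PAP-2": 0, "PAP-3": 0, "PAP-4": 1},
        "minor": {"BL-PAP": 0, "mind-L": 3, "PAP-1": 5,
                  "PAP-2": 1, "PAP-3": 3, "PAP-4": 0},
    },
}


@dataclass
class SimulationParams:
    """Study-condition knobs for cohort generation.

    Defaults are the screened-cohort conditions: 154 cases, 16% mutant
    prevalence, an even major/minor split, 1-18 substitutions per mutated
    case (truncated geometric, mean ~4), substitutions landing on a hotspot
    mutable position with probability ``shm_target_prob``.  Survival is
    exponential with ``baseline_hazard`` per month, subtype log hazard
    ratios ``log_hr_major``/``log_hr_minor`` (free simulation parameters,
    not literature estimates), and ~``censoring_rate`` of subjects censored
    by an independent uniform censoring time.
    """

    n_cases: int = 154
    mutant_prevalence: float = 0.16
    p_major_given_mutant: float = 0.5
    point_mut_min: int = 1
    point_mut_max: int = 18
    point_mut_geom_p: float = 0.25
    shm_target_prob: float = 0.41
    signature_conditionals: dict = field(
        default_factory=lambda: json.loads(json.dumps(_DEFAULT_SIGNATURES))
    )
    baseline_hazard: float = 0.02           # events per month
    log_hr_major: float = -1.2
    log_hr_minor: float = 1.0
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutant_prevalence", "p_major_given_mutant",
                     "shm_target_prob", "censoring_rate", "point_mut_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 1 <= self.point_mut_min <= self.point_mut_max:
            raise ValueError("invalid point-mutation count range")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class PlantedTruth:
    subtype: dict[str, str]
    mutations: dict[str, list[str]]          # c. descriptors per case
    shm_targeted: dict[str, list[bool]]      # per substitution, draw origin
    params: SimulationParams

    def as_dict(self) -> dict:
        return {
            "subtype": self.subtype,
            "mutations": self.mutations,
            "shm_targeted": self.shm_targeted,
            "params": dataclasses.asdict(self.params),
        }


@dataclass
class SyntheticCohort:
    mutations: dict[str, list[MutationRecord]]
    clinical: list[ClinicalRecord]
    truth: PlantedTruth


# ---------------------------------------------------------------------------
# reference generation


def socs1_domain_layout() -> list[DomainAnnotation]:
    """The default SOCS1-like domain layout (for a 636-bp CDS)."""
    return [
        DomainAnnotation("SH3", 10, 40),
        DomainAnnotation("KIR", 56, 67),
        DomainAnnotation("SH2", 79, 155),
        DomainAnnotation("JAK", 56, 155),
        DomainAnnotation("NLS", 158, 173, is_cterminal=True),
        DomainAnnotation("SOCS box", 174, 210, is_cterminal=True),
    ]


def generate_reference(
    length: int = 636,
    domain_layout: Optional[Sequence[DomainAnnotation]] = None,
    seed: int = 0,
    context_length: int = 24,
    gene_symbol: str = "SYN1",
) -> GeneModel:
    """A random valid gene model: ATG start, clean ORF, terminal stop.

    Codons are rejection-sampled so no internal in-frame stop appears;
    flanking context of ``context_length`` nt is generated for motif
    scanning across CDS edges.  Deterministic under ``seed``.
    """
    if length % 3 != 0 or length < 9:
        raise ValueError("length must be a multiple of 3 and >= 9")
    if domain_layout is None:
        domain_layout = socs1_domain_layout() if length == 636 else []
    max_aa = max((d.aa_end for d in domain_layout), default=0)
    if length < 3 * (max_aa + 1):
        raise ValueError(
            f"length {length} cannot hold a domain ending at aa {max_aa}"
        )
    rng = np.random.default_rng(seed)

    def rand_codon():
        while True:
            c = "".join(rng.choice(_BASES, 3))
            if c not in _STOPS:
                return c

    n_sense = length // 3 - 2
    cds = "ATG" + "".join(rand_codon() for _ in range(n_sense))
    cds += ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    model = GeneModel(
        gene_symbol=gene_symbol,
        cds=cds,
        domains=list(domain_layout),
        cterm_names=frozenset(d.name for d in domain_layout if d.is_cterminal),
        upstream_context="".join(rng.choice(_BASES, context_length)),
        downstream_context="".join(rng.choice(_BASES, context_length)),
    )
    model.validate(strict=True)
    return model


# ---------------------------------------------------------------------------
# cohort generation


def _truncated_geometric(rng, p, lo, hi) -> int:
    while True:
        k = rng.geometric(p)
        if lo <= k <= hi:
            return int(k)


def _draw_substitution(
    rng, model, case_id, mut_pos, non_mut_pos, theta, used, allow_stop_gain
):
    """One substitution: motif-mutable position w.p. theta, else non-mutable.

    Returns (record, from_motif).  Positions are drawn without replacement
    within a case; stop-gain alleles are resampled away when disallowed.
    """
    from .consequence import classify_mutation

    for _ in range(1000):
        from_motif = bool(rng.random() < theta)
        pool = mut_pos if from_motif else non_mut_pos
        pool = [p for p in pool if p not in used]
        if not pool:
            from_motif = not from_motif
            pool = [p for p in (non_mut_pos if from_motif is False else mut_pos)
                    if p not in used]
            if not pool:
                raise RuntimeError("reference exhausted of substitution sites")
        pos = int(pool[rng.integers(0, len(pool))])
        ref = model.ref_base(pos)
        alts = [b for b in "ACGT" if b != ref]
        rng.shuffle(alts)
        for alt in alts:
            rec = MutationRecord(case_id, "substitution", pos, pos, ref, alt)
            if allow_stop_gain or classify_mutation(rec, model).effect != "nonsense":
                used.add(pos)
                return rec, from_motif
    raise RuntimeError("could not draw a valid substitution")


def _draw_truncating_event(rng, model, case_id) -> MutationRecord:
    """A frame-disrupting or stop-gain event 5' of the C-terminal domains.

    By construction its aggressive impact reaches the C-terminal set, so a
    generated major case is classifiable as major from the catalog alone.
    """
    from .consequence import classify_mutation

    ct_start = min(d.nt_start for d in model.cterm_domains())
    kind = rng.choice(["nonsense", "del1", "del2", "ins1", "dup1"])
    if kind == "nonsense":
        for _ in range(1000):
            pos = int(rng.integers(1, ct_start))
            ref = model.ref_base(pos)
            for alt in "ACGT":
                if alt == ref:
                    continue
                rec = MutationRecord(case_id, "substitution", pos, pos, ref, alt)
                if classify_mutation(rec, model).effect == "nonsense":
                    return rec
        kind = "del1"  # fall through if no stop-gain site found
    if kind in ("del1", "del2"):
        width = 1 if kind == "del1" else 2
        start = int(rng.integers(1, ct_start - width))
        ref = model.ref_slice(start, start + width - 1)
        return MutationRecord(
            case_id, "deletion", start, start + width - 1, ref, ""
        )
    if kind == "ins1":
        start = int(rng.integers(1, ct_start - 1))
        return MutationRecord(
            case_id, "insertion", start, start,
            "", str(rng.choice(_BASES)),
        )
    start = int(rng.integers(1, ct_start - 1))  # 1-nt duplication
    ref = model.ref_base(start)
    return MutationRecord(case_id, "duplication", start, start, ref, ref)


def _censoring_horizon(lams: np.ndarray, target: float) -> float:
    """Uniform(0, u) horizon giving the target expected censoring fraction."""
    if target <= 0:
        return float("inf")

    def frac(u):  # P(T > C) averaged over subjects, C ~ U(0, u)
        return float(np.mean((1 - np.exp(-lams * u)) / (lams * u)) - target)

    return brentq(frac, 1e-6, 1e6)


def generate_cohort(
    params: SimulationParams,
    model: GeneModel,
    out_dir: Optional[str | Path] = None,
) -> SyntheticCohort:
    """Draw a full synthetic cohort; optionally write the three artifacts.

    Writes ``mutations.tsv``, ``clinical.tsv`` and ``truth.json`` into
    ``out_dir`` when given — byte-identical across reruns with one seed.
    """
    rng = np.random.default_rng(params.seed)
    mut_pos = sorted(mutable_positions(model))
    non_mut_pos = sorted(set(range(1, model.cds_length + 1)) - set(mut_pos))
    if params.shm_target_prob > 0 and not mut_pos:
        raise ValueError("shm_target_prob > 0 but reference has no motif positions")
    if params.shm_target_prob < 1 and not non_mut_pos:
        raise ValueError("reference has no non-motif positions")

    mutations: dict[str, list[MutationRecord]] = {}
    truth_subtype: dict[str, str] = {}
    truth_flags: dict[str, list[bool]] = {}
    subtypes: list[str] = []
    case_ids = [f"SIM-{i + 1:04d}" for i in range(params.n_cases)]

    for case_id in case_ids:
        if rng.random() >= params.mutant_prevalence:
            subtype = "wild_type"
            recs: list[MutationRecord] = []
            flags: list[bool] = []
        else:
            subtype = (
                "major" if rng.random() < params.p_major_given_mutant else "minor"
            )
            n_pts = _truncated_geometric(
                rng, params.point_mut_geom_p,
                params.point_mut_min, params.point_mut_max,
            )
            recs, flags, used = [], [], set()
            if subtype == "major":
                recs.append(_draw_truncating_event(rng, model, case_id))
                n_pts -= 1
            for _ in range(max(0, n_pts)):
                rec, from_motif = _draw_substitution(
                    rng, model, case_id, mut_pos, non_mut_pos,
                    params.shm_target_prob, used,
                    allow_stop_gain=False,
                )
                recs.append(rec)
                flags.append(from_motif)
        mutations[case_id] = recs
        truth_subtype[case_id] = subtype
        truth_flags[case_id] = flags
        subtypes.append(subtype)

    # survival under proportional hazards with uniform censoring
    log_hr = {"wild_type": 0.0, "major": params.log_hr_major,
              "minor": params.log_hr_minor}
    lams = np.array(
        [params.baseline_hazard * math.exp(log_hr[s]) for s in subtypes]
    )
    T = rng.exponential(1.0 / lams)
    horizon = _censoring_horizon(lams, params.censoring_rate)
    C = (rng.uniform(0, horizon, size=len(T)) if np.isfinite(horizon)
         else np.full(len(T), np.inf))
    os_time = np.minimum(T, C)
    os_event = (T <= C).astype(int)

    clinical: list[ClinicalRecord] = []
    aas_levels = ("I", "II", "III", "IV")
    for i, case_id in enumerate(case_ids):
        sig = {}
        for key in ("coo", "mbl", "pap", "cc"):
            cond = params.signature_conditionals[key][subtypes[i]]
            labels = list(cond)
            weights = np.array([cond[l] for l in labels], dtype=float)
            weights = weights / weights.sum()
            sig[key] = str(labels[rng.choice(len(labels), p=weights)])
        clinical.append(ClinicalRecord(
            case_id=case_id,
            age=float(np.clip(round(rng.normal(62, 15)), 18, 95)),
            sex=("M", "F")[rng.integers(0, 2)],
            aas=aas_levels[rng.integers(0, 4)],
            b_symptoms=bool(rng.random() < 0.4),
            ldh_gt_uln=bool(rng.random() < 0.45),
            ecog_gt1=bool(rng.random() < 0.2),
            en_gt1=bool(rng.random() < 0.25),
            morphology=("CB", "IB", "ANA", "NOS")[rng.integers(0, 4)],
            os_time=float(round(os_time[i], 3)),
            os_event=int(os_event[i]),
            **sig,
        ))

    truth = PlantedTruth(
        subtype=truth_subtype,
        mutations={
            cid: [format_c_notation(m) for m in recs]
            for cid, recs in mutations.items()
        },
        shm_targeted=truth_flags,
        params=params,
    )
    cohort = SyntheticCohort(
        mutations={cid: recs for cid, recs in mutations.items() if recs},
        clinical=clinical,
        truth=truth,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mutation_table(cohort.mutations, out / "mutations.tsv")
        write_clinical_table(cohort.clinical, out / "clinical.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return cohort
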