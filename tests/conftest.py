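import json
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from socsmut.gene_model import DomainAnnotation, GeneModel, socs1_model
from socsmut.mutation_io import MutationRecord


@pytest.fixture(scope="session")
def socs1():
    return socs1_model()


@pytest.fixture()
def tiny_model():
    """Smallest useful model: 9-nt CDS ATG GCT TGA, one 1-aa domain."""
    m = GeneModel(
        gene_symbol="TINY",
        cds="ATGGCTTGA",
        domains=[DomainAnnotation("D", 2, 2, is_cterminal=True)],
        cterm_names=frozenset({"D"}),
    )
    m.validate()
    return m


@pytest.fixture()
def codon10_model():
    """36-nt CDS whose 10th codon (TAC) is one substitution from a stop."""
    cds = "ATG" + "GCT" * 8 + "TAC" + "GCT" + "TGA"
    m = GeneModel(
        gene_symbol="C10",
        cds=cds,
        domains=[
            DomainAnnotation("N", 2, 5),
            DomainAnnotation("C", 10, 11, is_cterminal=True),
        ],
        cterm_names=frozenset({"C"}),
    )
    m.validate()
    return m


@pytest.fixture()
def tmp_model_json(tmp_path):
    def make(payload: dict) -> Path:
        path = tmp_path / "model.json"
        path.write_text(json.dumps(payload))
        return path
    return make


def sub(model, pos, alt, case_id="X"):
    """Convenience: a validated substitution record at a CDS position."""
    ref = model.ref_base(pos)
    assert ref != alt, "pick a different alt"
    return MutationRecord(case_id, "substitution", pos, pos, ref, alt).validate(model)
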