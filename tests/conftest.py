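import numpy as np
import pytest

from orthoprep.og_model import (
    GeneSequence,
    Orthogroup,
    OrthogroupSet,
    SpeciesRoster,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=length))


def make_og(og_id: str, roster: SpeciesRoster, seqs: dict[str, list[str]]):
    """Build an orthogroup from {species: [residue strings]}."""
    members = {
        sp: [
            GeneSequence(f"{sp}_{og_id}_g{i}", sp, s)
            for i, s in enumerate(seqs.get(sp, []))
        ]
        for sp in roster
    }
    return Orthogroup(og_id, members)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def roster3():
    return SpeciesRoster(("A", "B", "C"))


@pytest.fixture
def tiny_set(roster3):
    """Three orthogroups: complete single-copy, one absent species, one
    two-copy species."""
    ogs = [
        make_og("OG1", roster3, {"A": ["MKVLD"], "B": ["MKVLD"], "C": ["MKVLE"]}),
        make_og("OG2", roster3, {"A": ["MKVLD"], "B": ["MKVLD"]}),
        make_og("OG3", roster3, {"A": ["MKVLD", "MKVLD"], "B": ["MKVLD"],
                                 "C": ["MKVLD"]}),
    ]
    return OrthogroupSet(roster3, ogs)
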