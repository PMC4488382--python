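import importlib.resources as ir
from pathlib import Path

import numpy as np
import pytest

from luciscreen.seqio import SequenceRecord


def data_path(name: str) -> str:
    return str(ir.files("luciscreen") / "data" / name)


@pytest.fixture(scope="session")
def table5_path() -> str:
    return data_path("table5_fyy.tsv")


@pytest.fixture(scope="session")
def table6_path() -> str:
    return data_path("table6_2ogfe1.tsv")


@pytest.fixture(scope="session")
def table7_path() -> str:
    return data_path("table7_2ogfe2.tsv")


@pytest.fixture(scope="session")
def table2_protein_path() -> str:
    return data_path("table2_protein.tsv")


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int, rec_id: str = "p") -> SequenceRecord:
    seq = "".join(rng.choice(list(AA20)) for _ in range(length))
    return SequenceRecord(id=rec_id, seq=seq, moltype="protein")


@pytest.fixture(scope="session")
def small_study(tmp_path_factory) -> tuple[Path, object]:
    """A compact synthetic study shared by structure-level tests."""
    from luciscreen.simulate import StudyConfig, generate_study

    out = tmp_path_factory.mktemp("small_study")
    cfg = StudyConfig(
        n_luminous=8,
        n_nonluminous=2,
        n_codons=150,
        n_decoys=2,
        decoy_codons=100,
        anchors={40: ("Y", "acv_tyr"), 60: ("H", "iron_his1"), 62: ("D", "iron_asp"),
                 90: ("H", "iron_his2"), 100: ("R", "rxs_arg"), 102: ("S", "rxs_ser")},
    )
    truth = generate_study(cfg, seed=11, out_dir=out)
    return out, truth
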