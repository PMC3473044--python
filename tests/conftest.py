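import numpy as np
import pytest

from seedshift.classify import classify_all
from seedshift.io import MirnaRecord, UtrRecord
from seedshift.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def let7a() -> MirnaRecord:
    """Canonical public mature sequence of hsa-let-7a."""
    return MirnaRecord("hsa-let-7a", "UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture(scope="session")
def toy_utr(let7a) -> UtrRecord:
    """Plus-strand 14 nt UTR carrying one let-7a m8 site at offset 3."""
    return UtrRecord("TOY", "TX_TOY", "chr1", 101, 114, "+", "AAACTACCTCAAAA")


@pytest.fixture(scope="session")
def small_dataset():
    """A quick planted dataset (18 events) for unit-level end-to-end checks."""
    return generate_dataset(SimConfig(
        rng_seed=7, n_mirnas=8, utr_length_range=(150, 400),
        planted_counts={"created": 6, "disrupted": 6, "modified": 6}))


@pytest.fixture(scope="session")
def planted_dataset():
    """The standard study-condition dataset: 150 planted events."""
    return generate_dataset(SimConfig(rng_seed=42))


@pytest.fixture(scope="session")
def planted_result(planted_dataset):
    return classify_all(planted_dataset.mutations, planted_dataset.utrs,
                        planted_dataset.mirnas)


def events_by_key(events) -> dict:
    """Group events by (hgvs, miRNA) for comparison against truth records."""
    out: dict = {}
    for ev in events:
        out.setdefault((ev.mutation.hgvs_g, ev.mirna_name), []).append(ev)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2012)
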