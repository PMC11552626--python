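import numpy as np
import pytest

from ptmtok.alphabet import (
    EncodedWindow,
    LabelChannel,
    ModAlphabet,
    build_alphabet,
    vectorize,
)
from ptmtok.datasets import SiteRecord, split_dataset
from ptmtok.model import ModelConfig, build_model, train
from ptmtok.simulate import SimulationSpec, simulate_proteome


@pytest.fixture(scope="session")
def phospho_channel():
    return LabelChannel("phospho-ST", frozenset("ST"), {})


@pytest.fixture(scope="session")
def phospho_alphabet(phospho_channel):
    """24-token alphabet: pad + 20 AAs + U + '@' (pS) + '&' (pT)."""
    return build_alphabet([phospho_channel])


@pytest.fixture(scope="session")
def plain_alphabet():
    return build_alphabet([])


def make_window(tokens: str, alphabet, origin=("p", 1)) -> EncodedWindow:
    k = len(tokens)
    return EncodedWindow(tokens, vectorize(tokens, alphabet), (k + 1) // 2, origin)


def toy_records(alphabet, n=400, k=9, seed=2):
    """Planted rule: positive iff '@' at offset -2 from the center 'S'."""
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    records = []
    for i in range(n):
        label = i % 2
        s = "".join(rng.choice(aas, size=k))
        mid = (k - 1) // 2
        s = s[:mid] + "S" + s[mid + 1 :]
        if label:
            s = s[: mid - 2] + "@" + s[mid - 1 :]
        win = make_window(s, alphabet, origin=(f"p{i}", mid + 1))
        records.append(SiteRecord(f"p{i}", mid + 1, "S", label, win))
    return records


@pytest.fixture(scope="session")
def toy_split(phospho_alphabet):
    return split_dataset(toy_records(phospho_alphabet), seed=0)


@pytest.fixture(scope="session")
def small_config(phospho_alphabet):
    return ModelConfig(
        k=9,
        vocab_size=phospho_alphabet.vocab_size,
        embedding_dim=21,
        conv_filters=8,
        conv_kernel=(3, 21),
        pool=2,
        dense_units=(16, 1),
        max_epochs=20,
        patience=10,
    )


@pytest.fixture(scope="session")
def toy_model(small_config, phospho_alphabet, toy_split):
    """CNN trained to convergence on the planted '@'-at-minus-2 rule."""
    model = build_model(small_config, phospho_alphabet, seed=0)
    return train(model, toy_split, seed=0)


@pytest.fixture(scope="session")
def small_simulation():
    spec = SimulationSpec(
        n_proteins=60, length_range=(80, 160), ptm_dependence=0.7,
        label_noise=0.2, base_rate=0.15, seed=5,
    )
    return spec, simulate_proteome(spec)
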