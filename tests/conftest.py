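import numpy as np
import pytest

from epmlr import PairKey, SyntheticConfig, generate_dataset, get_scale
from epmlr.features import PairCatalog


@pytest.fixture(scope="session")
def hydro():
    return get_scale("parker")


@pytest.fixture(scope="session")
def mass():
    return get_scale("side_chain_mass")


@pytest.fixture(scope="session")
def small_planted_dataset():
    """60+60 20-mers with two strong planted pairs (seed-fixed)."""
    cfg = SyntheticConfig(
        n_pos=60,
        n_neg=60,
        planted_pairs=[
            (PairKey(2, 8, "D", "K"), 0.9, 0.05),
            (PairKey(5, 16, "W", "A"), 0.9, 0.05),
        ],
        seed=0,
    )
    dataset, truth = generate_dataset(cfg)
    return dataset, truth


def random_model(n: int, top_k: int, seed: int):
    """A small MLR model with random coefficients and a random catalog."""
    from epmlr.alphabet import AMINO_ACIDS
    from epmlr.model import MLRModel

    rng = np.random.default_rng(seed)
    seen, pairs = set(), []
    while len(pairs) < top_k:
        j = int(rng.integers(1, n))
        k = int(rng.integers(j + 1, n + 1))
        key = PairKey(j, k, AMINO_ACIDS[rng.integers(20)], AMINO_ACIDS[rng.integers(20)])
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    n_pp = n * (n - 1) // 2
    return MLRModel(
        window_size=n,
        alpha=rng.normal(size=19),
        beta=rng.normal(size=n_pp),
        gamma=rng.normal(size=n_pp),
        delta=rng.normal(size=top_k),
        intercept=float(rng.normal()),
        hydro_scale=get_scale("parker"),
        mass_scale=get_scale("side_chain_mass"),
        catalog=PairCatalog.from_selected(n, pairs),
    )


def random_peptides(count: int, length: int, seed: int):
    from epmlr.alphabet import decode_codes
    from epmlr.datasets import PeptideDataset, PeptideRecord

    rng = np.random.default_rng(seed)
    return PeptideDataset(
        [
            PeptideRecord(f"r{i}", decode_codes(rng.integers(0, 20, size=length)), int(i % 2))
            for i in range(count)
        ]
    )
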