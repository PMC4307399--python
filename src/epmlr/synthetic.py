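"""Synthetic labeled peptide datasets with known, controllable class signal.

The generator emulates the structure of experimentally derived linear
B-cell epitope benchmarks: fixed-length peptides (default 20-mers), an
unbalanced positive/negative split, and — crucially — *noisy negatives*:
with probability ``negative_flip_rate`` a record labeled non-epitope is
secretly drawn from the positive sequence model, mimicking experimental
non-epitopes that are in truth epitopes.  Class signal is planted two ways:

* **position-specific residue pairs** — each planted (j, k, a, b) is
  imposed (positions j and k overwritten) with probability
  ``enrichment_pos`` in positives and ``enrichment_neg`` in negatives;
* **composition bias** — an optional residue-weight map for the positive
  background distribution.

Every planted placement and label flip is recorded in a truth dict, so
selection and model tests can check recovery against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, decode_codes
from .datasets import PeptideDataset, PeptideRecord
from .features import PairCatalog, PairKey

__all__ = ["SyntheticConfig", "generate_dataset", "make_linear_fixture"]


@dataclass
class SyntheticConfig:
    """Generation parameters; see module docstring for semantics."""

    n_pos: int = 100
    n_neg: int = 200
    peptide_length: int = 20
    planted_pairs: list[tuple[PairKey, float, float]] = field(default_factory=list)
    composition_bias: dict[str, float] | None = None
    negative_flip_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("n_pos and n_neg must be >= 1")
        if self.peptide_length < 2:
            raise ValueError("peptide_length must be >= 2")
        if not 0.0 <= self.negative_flip_rate <= 1.0:
            raise ValueError("negative_flip_rate must be in [0, 1]")
        for key, ep, en in self.planted_pairs:
            if not (1 <= key.j < key.k <= self.peptide_length):
                raise ValueError(f"planted pair {key} positions out of range")
            if key.a not in AA_INDEX or key.b not in AA_INDEX:
                raise ValueError(f"planted pair {key} has non-canonical residues")
            if not (0.0 <= ep <= 1.0 and 0.0 <= en <= 1.0):
                raise ValueError(f"planted pair {key}: enrichments must be probabilities")
        if self.composition_bias is not None:
            if any(w < 0 for w in self.composition_bias.values()):
                raise ValueError("composition_bias weights must be nonnegative")


def _background_probs(bias: dict[str, float] | None) -> np.ndarray:
    if bias is None:
        return np.full(20, 1 / 20)
    w = np.array([bias.get(aa, 1.0) for aa in AMINO_ACIDS], dtype=np.float64)
    if w.sum() == 0:
        raise ValueError("composition_bias weights sum to zero")
    return w / w.sum()


def generate_dataset(config: SyntheticConfig) -> tuple[PeptideDataset, dict]:
    """Draw a labeled dataset per the config; deterministic per seed.

    Returns (dataset, truth).  truth records, per record id, which planted
    pairs were imposed and whether a negative was generated from the
    positive model ("flipped").  Overlapping planted pairs are applied in
    list order, so a later pair overwrites a shared position.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p_pos = _background_probs(config.composition_bias)
    p_neg = np.full(20, 1 / 20)

    records, truth_records = [], {}

    def draw(label: int, rid: str, as_positive: bool) -> None:
        probs = p_pos if as_positive else p_neg
        codes = rng.choice(20, size=config.peptide_length, p=probs).astype(np.uint8)
        planted = []
        for key, ep, en in config.planted_pairs:
            rate = ep if as_positive else en
            if rng.random() < rate:
                codes[key.j - 1] = AA_INDEX[key.a]
                codes[key.k - 1] = AA_INDEX[key.b]
                planted.append(list(key))
        records.append(PeptideRecord(rid, decode_codes(codes), label))
        truth_records[rid] = {"planted": planted, "flipped": as_positive and label == 0}

    for i in range(config.n_pos):
        draw(1, f"pos_{i:05d}", as_positive=True)
    for i in range(config.n_neg):
        flipped = rng.random() < config.negative_flip_rate
        draw(0, f"neg_{i:05d}", as_positive=flipped)

    truth = {
        "config": {
            "n_pos": config.n_pos,
            "n_neg": config.n_neg,
            "peptide_length": config.peptide_length,
            "planted_pairs": [[list(key), ep, en] for key, ep, en in config.planted_pairs],
            "negative_flip_rate": config.negative_flip_rate,
            "seed": config.seed,
        },
        "records": truth_records,
    }
    return PeptideDataset(records), truth


def make_linear_fixture(
    n_samples: int, n_features_active: int, seed: int, window_size: int = 10
) -> tuple[PeptideDataset, dict]:
    """Peptides whose labels are an exact linear function of the encoding.

    Peptide length equals the window size, so each peptide is a single
    window.  ``n_features_active`` disjoint position pairs are chosen;
    positives carry all of them, negatives none, so with delta = 1/d on
    each active indicator, zero elsewhere and intercept 0, the model score
    reproduces every label exactly.  Returns (dataset, description) where
    description carries the catalog, coefficient vector and intercept.
    """
    if n_features_active < 1:
        raise ValueError("need at least one active feature")
    if 2 * n_features_active > window_size:
        raise ValueError(
            f"cannot place {n_features_active} disjoint pairs in a {window_size}-mer"
        )
    rng = np.random.default_rng(seed)
    active = [
        PairKey(2 * i + 1, 2 * i + 2,
                AMINO_ACIDS[rng.integers(20)], AMINO_ACIDS[rng.integers(20)])
        for i in range(n_features_active)
    ]
    catalog = PairCatalog.from_selected(window_size, active)

    records = []
    for i in range(n_samples):
        label = int(i % 2 == 0)
        codes = rng.integers(0, 20, size=window_size).astype(np.uint8)
        for key in active:
            if label:
                codes[key.j - 1] = AA_INDEX[key.a]
                codes[key.k - 1] = AA_INDEX[key.b]
            elif codes[key.j - 1] == AA_INDEX[key.a] and codes[key.k - 1] == AA_INDEX[key.b]:
                codes[key.k - 1] = (codes[key.k - 1] + 1) % 20  # break the pair
        records.append(PeptideRecord(f"fix_{i:04d}", decode_codes(codes), label))

    n_pp = window_size * (window_size - 1) // 2
    delta = np.full(n_features_active, 1.0 / n_features_active)
    description = {
        "window_size": window_size,
        "catalog": catalog,
        "alpha": np.zeros(19),
        "beta": np.zeros(n_pp),
        "gamma": np.zeros(n_pp),
        "delta": delta,
        "intercept": 0.0,
    }
    return PeptideDataset(records), description
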