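import math
import random
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epmlr.alphabet import AMINO_ACIDS, decode_codes
from epmlr.datasets import PeptideDataset, PeptideRecord
from epmlr.features import (
    PairCatalog,
    PairKey,
    count_pair_frequencies,
    encode_window,
    feature_length,
    filter_by_frequency,
    information_value,
    pair_window_images,
    select_top_pairs,
)
from epmlr.synthetic import SyntheticConfig, generate_dataset


# ---------------------------------------------------------------------------
# independent brute-force oracle for pair selection

def brute_force_ranking(dataset, n):
    """Dict-and-loop reimplementation of counting, filtering and D ranking."""
    counts = defaultdict(lambda: [0, 0])
    windows_per_class = [0, 0]
    for rec in dataset:
        for s in range(len(rec.sequence) - n + 1):
            w = rec.sequence[s : s + n]
            windows_per_class[rec.label] += 1
            for j in range(n):
                for k in range(j + 1, n):
                    counts[PairKey(j + 1, k + 1, w[j], w[k])][rec.label] += 1
    space = 400 * n * (n - 1) // 2
    mean = sum(c0 + c1 for c1, c0 in ((v[1], v[0]) for v in counts.values())) / space
    total_w = sum(windows_per_class)
    p1, p0 = windows_per_class[1] / total_w, windows_per_class[0] / total_w
    ranked = []
    for key, (c0, c1) in counts.items():
        tot = c0 + c1
        if tot < mean:
            continue
        f1, f0 = c1 / tot, c0 / tot
        ranked.append((key, information_value(f1, f0, p1, p0)))
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked


def _planted_fixture(seed=0, n_each=50, length=10):
    """Positives always carry (1,2,A,C); background avoids A and C."""
    rng = random.Random(seed)
    alphabet = [aa for aa in AMINO_ACIDS if aa not in "AC"]
    records = []
    for i in range(n_each):
        seq = "AC" + "".join(rng.choice(alphabet) for _ in range(length - 2))
        records.append(PeptideRecord(f"p{i}", seq, 1))
    for i in range(n_each):
        seq = "".join(rng.choice(alphabet) for _ in range(length))
        records.append(PeptideRecord(f"n{i}", seq, 0))
    return PeptideDataset(records)


class TestCounting:
    def test_candidate_space_size_for_n15(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        counts = count_pair_frequencies(dataset[:4], 15)
        assert len(counts) == 42_000  # 20 * 20 * 15 * 14 / 2

    def test_homopolymer_window_counts(self):
        ds = PeptideDataset([PeptideRecord("a", "A" * 15, 1)])
        counts = count_pair_frequencies(ds, 15)
        hit = {k: v for k, v in counts.items() if v != (0, 0)}
        assert len(hit) == 105
        assert all(k.a == "A" and k.b == "A" and v == (1, 0) for k, v in hit.items())

    def test_empty_dataset_all_zero(self):
        counts = count_pair_frequencies(PeptideDataset([]), 5)
        assert set(counts.values()) == {(0, 0)}

    def test_short_peptide_names_record(self):
        ds = PeptideDataset([PeptideRecord("shorty", "ACDE", 1)])
        with pytest.raises(ValueError, match="shorty"):
            count_pair_frequencies(ds, 15)

    def test_counts_match_brute_force(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        sub = dataset[:6]
        counts = count_pair_frequencies(sub, 8)
        brute = defaultdict(lambda: [0, 0])
        for rec in sub:
            for s in range(len(rec.sequence) - 8 + 1):
                w = rec.sequence[s : s + 8]
                for j in range(8):
                    for k in range(j + 1, 8):
                        brute[PairKey(j + 1, k + 1, w[j], w[k])][rec.label] += 1
        for key, (c0, c1) in brute.items():
            assert counts[key] == (c1, c0)


class TestFrequencyFilter:
    def test_below_mean_eliminated(self):
        k1, k2, k3 = (PairKey(1, 2, a, "A") for a in "ACD")
        survivors = filter_by_frequency({k1: (1, 0), k2: (0, 1), k3: (2, 2)})
        assert survivors == {k3}  # mean total = 2

    def test_uniform_totals_all_survive(self):
        keys = {PairKey(1, 2, a, "A"): (1, 1) for a in "ACDE"}
        assert filter_by_frequency(keys) == set(keys)

    def test_all_zero_degenerate_keeps_everything(self, caplog):
        keys = {PairKey(1, 2, a, "A"): (0, 0) for a in "ACDE"}
        with caplog.at_level("WARNING"):
            assert filter_by_frequency(keys) == set(keys)
        assert any("zero" in m for m in caplog.messages)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filter_by_frequency({})


class TestInformationValue:
    @pytest.mark.parametrize(
        "f1,f0,expected",
        [
            (0.5, 0.5, 0.0),
            (1.0, 0.0, math.log(2)),
            (0.8, 0.2, 0.8 * math.log(1.6) + 0.2 * math.log(0.4)),  # ~0.19274
        ],
    )
    def test_closed_forms_against_uniform_prior(self, f1, f0, expected):
        assert information_value(f1, f0, 0.5, 0.5) == pytest.approx(expected, abs=1e-12)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            information_value(-0.1, 1.1, 0.5, 0.5)
        with pytest.raises(ValueError):
            information_value(0.5, 0.5, 0.0, 1.0)

    @given(f1=st.floats(0, 1), p1=st.floats(0.01, 0.99))
    @settings(derandomize=True, max_examples=300)
    def test_nonnegative_and_zero_iff_f_equals_p(self, f1, p1):
        d = information_value(f1, 1 - f1, p1, 1 - p1)
        assert d >= 0.0
        if abs(f1 - p1) < 1e-12:
            assert d < 1e-12
        elif abs(f1 - p1) > 1e-3:
            assert d > 0.0


class TestSelection:
    def test_balanced_dataset_has_half_half_prior(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        catalog = select_top_pairs(dataset, 15, 100)
        assert catalog.class_prior == (0.5, 0.5)

    def test_planted_pure_pair_ranks_first(self):
        ds = _planted_fixture()
        catalog = select_top_pairs(ds, 10, 50)
        assert catalog.selected[0] == PairKey(1, 2, "A", "C")

    def test_ranking_matches_brute_force_oracle(self):
        ds = _planted_fixture(seed=1, n_each=20, length=8)
        catalog = select_top_pairs(ds, 8, 30)
        oracle = brute_force_ranking(ds, 8)
        assert catalog.selected == [key for key, _ in oracle[:30]]
        got_d = catalog.entries.D.to_numpy()[: len(oracle)]
        assert np.allclose(got_d, [d for _, d in oracle[: len(got_d)]], atol=1e-12)

    def test_equal_d_ties_broken_lexicographically(self):
        ds = _planted_fixture()
        entries = select_top_pairs(ds, 10, 500).entries
        d = entries.D.to_numpy()
        keys = [PairKey(int(r.j), int(r.k), r.a, r.b) for r in entries.itertuples()]
        for i in range(len(keys) - 1):
            if abs(d[i] - d[i + 1]) < 1e-15:
                assert keys[i] < keys[i + 1]

    def test_single_class_rejected(self):
        ds = PeptideDataset([PeptideRecord(f"p{i}", "ACDEFGHIKL", 1) for i in range(5)])
        with pytest.raises(ValueError, match="both classes"):
            select_top_pairs(ds, 8, 10)

    def test_record_order_invariance(self, small_planted_dataset):
        dataset, _ = small_planted_dataset
        shuffled = PeptideDataset(list(dataset))
        random.Random(5).shuffle(shuffled.records)
        a = select_top_pairs(dataset, 15, 200).selected
        b = select_top_pairs(shuffled, 15, 200).selected
        assert a == b

    def test_fewer_survivors_than_k_warns(self, caplog):
        ds = _planted_fixture(n_each=5, length=6)
        with caplog.at_level("WARNING"):
            catalog = select_top_pairs(ds, 6, 100_000)
        assert catalog.top_k < 100_000
        assert any("survive" in m for m in caplog.messages)

    def test_catalog_tsv_roundtrip(self, small_planted_dataset, tmp_path):
        dataset, _ = small_planted_dataset
        catalog = select_top_pairs(dataset, 15, 50)
        path = tmp_path / "catalog.tsv"
        catalog.to_tsv(path)
        back = PairCatalog.from_tsv(path)
        assert back.window_size == catalog.window_size
        assert back.selected == catalog.selected
        assert back.class_prior == catalog.class_prior
        assert np.allclose(back.entries.D, catalog.entries.D)

    @pytest.mark.parametrize(
        "planted",
        [
            [(PairKey(5, 16, "W", "A"), 0.9, 0.02)],
            # two pairs whose positions can never co-occur inside one
            # 15-mer window, so no composite cross-pair outranks them
            [(PairKey(1, 2, "D", "K"), 0.9, 0.02), (PairKey(17, 20, "W", "A"), 0.9, 0.02)],
        ],
        ids=["one_pair", "two_pairs"],
    )
    def test_planted_signal_recovered_in_top_2d(self, planted):
        for seed in range(5):
            cfg = SyntheticConfig(n_pos=2000, n_neg=2000, planted_pairs=planted, seed=seed)
            dataset, _ = generate_dataset(cfg)
            catalog = select_top_pairs(dataset, 15, 500)
            top = set(catalog.selected[: 2 * len(planted)])
            for key, _, _ in planted:
                assert set(pair_window_images(key, 20, 15)) & top, (seed, key)


class TestEncoding:
    def _catalog(self, n=15, keys=()):
        return PairCatalog.from_selected(n, list(keys))

    def test_feature_vector_length_for_n15_k500(self, hydro, mass, small_planted_dataset):
        dataset, _ = small_planted_dataset
        catalog = select_top_pairs(dataset, 15, 500)
        feats = encode_window(dataset[0].sequence[:15], hydro, mass, catalog)
        assert len(feats.vector) == 729 == feature_length(15, 500)
        assert len(feats.composition) == 19
        assert len(feats.hydro_pairs) == len(feats.mass_pairs) == 105

    def test_homopolymer_products_constant(self, hydro, mass):
        feats = encode_window("L" * 15, hydro, mass, self._catalog())
        assert np.allclose(feats.hydro_pairs, hydro["L"] ** 2)
        assert np.allclose(feats.mass_pairs, mass["L"] ** 2)

    def test_composition_counts_with_reference_omitted(self, hydro, mass):
        feats = encode_window("AAYYC", hydro, mass, self._catalog(5))
        # A=2, C=1 counted; Y (reference) omitted entirely
        assert feats.composition[0] == 2 and feats.composition[1] == 1
        assert feats.composition.sum() == 3

    def test_single_matching_indicator(self, hydro, mass):
        catalog = self._catalog(5, [PairKey(1, 3, "A", "D"), PairKey(2, 4, "W", "W")])
        feats = encode_window("ACDEF", hydro, mass, catalog)
        assert feats.pair_indicators.tolist() == [1, 0]

    def test_length_mismatch_rejected(self, hydro, mass):
        with pytest.raises(ValueError, match="length"):
            encode_window("ACD", hydro, mass, self._catalog(5))

    def test_unknown_residue_rejected(self, hydro, mass):
        with pytest.raises(ValueError, match="non-canonical"):
            encode_window("ACDEX", hydro, mass, self._catalog(5))

    def test_deterministic(self, hydro, mass, small_planted_dataset):
        dataset, _ = small_planted_dataset
        catalog = select_top_pairs(dataset, 15, 100)
        w = dataset[3].sequence[2:17]
        a = encode_window(w, hydro, mass, catalog).vector
        b = encode_window(w, hydro, mass, catalog).vector
        assert np.array_equal(a, b)
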