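"""Window feature encoding and information-value pair selection.

Every n-residue window is encoded as the concatenation of four blocks:

1. **composition** — 19 residue counts (the last residue, Y, is omitted as
   the reference to avoid an exact sum constraint with the intercept);
2. **hydrophilicity autocorrelation** — the n(n-1)/2 products B_j*B_k of
   normalized hydrophilicity values at positions j < k, in (j, k)
   lexicographic order;
3. **side-chain-mass autocorrelation** — the analogous products S_j*S_k;
4. **selected pair indicators** — K binary flags, one per selected
   position-specific residue pair (j, k, a, b), set to 1 when the window has
   residue a at position j and b at position k.

The K pairs are chosen by information value: for each candidate pair the
split of its occurrences between epitope (f1) and non-epitope (f0) windows
is compared against the class prior (P1, P0) with the Kullback–Leibler
divergence D = sum_t f_t * ln(f_t / P_t).  Pairs rarer than the average
candidate occurrence are eliminated first for statistical stability, and the
K survivors with the largest D are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, encode_sequence
from .datasets import PeptideDataset
from .scales import PropensityScale

logger = logging.getLogger(__name__)

__all__ = [
    "PairKey",
    "PairCatalog",
    "WindowFeatures",
    "extract_windows",
    "count_pair_frequencies",
    "filter_by_frequency",
    "information_value",
    "select_top_pairs",
    "encode_window",
    "design_matrix",
    "feature_length",
    "pair_window_images",
]


class PairKey(NamedTuple):
    """Position-specific residue pair: residue ``a`` at window position ``j``
    AND residue ``b`` at position ``k`` (1-based, j < k)."""

    j: int
    k: int
    a: str
    b: str


def position_pairs(n: int) -> list[tuple[int, int]]:
    """All (j, k) with 1 <= j < k <= n, lexicographic; length n(n-1)/2."""
    return [(j, k) for j in range(1, n) for k in range(j + 1, n + 1)]


def feature_length(n: int, top_k: int) -> int:
    """Total encoded length: 19 + n(n-1) + K."""
    return 19 + n * (n - 1) + top_k


def pair_window_images(key: PairKey, peptide_length: int, n: int) -> list[PairKey]:
    """Window-coordinate images of a peptide-coordinate residue pair.

    A pair planted at peptide positions (j, k) appears in window s (1-based
    start) at window coordinates (j - s + 1, k - s + 1); pairs spanning
    >= n residues appear in no window.  Selection operates on window
    coordinates, so recovery of planted peptide-level signal is checked
    against these images.
    """
    lo = max(1, key.k - n + 1)
    hi = min(peptide_length - n + 1, key.j)
    return [PairKey(key.j - s + 1, key.k - s + 1, key.a, key.b) for s in range(lo, hi + 1)]


# ---------------------------------------------------------------------------
# window extraction

def extract_windows(dataset: PeptideDataset, n: int) -> tuple[np.ndarray, np.ndarray]:
    """All n-windows of all peptides as a (m, n) uint8 code matrix.

    Returns (windows, labels): each window inherits its peptide's label.
    """
    if n < 2:
        raise ValueError("window size must be >= 2")
    chunks, labels = [], []
    for rec in dataset:
        if len(rec.sequence) < n:
            raise ValueError(f"record {rec.id!r}: length {len(rec.sequence)} < window size {n}")
        codes = encode_sequence(rec.sequence)
        w = np.lib.stride_tricks.sliding_window_view(codes, n)
        chunks.append(w)
        labels.append(np.full(len(w), rec.label, dtype=np.int64))
    if not chunks:
        return np.empty((0, n), dtype=np.uint8), np.empty(0, dtype=np.int64)
    return np.ascontiguousarray(np.vstack(chunks)), np.concatenate(labels)


# ---------------------------------------------------------------------------
# pair counting and selection

def _flat_pair_keys(windows: np.ndarray, n: int) -> np.ndarray:
    """(m, P) int32 matrix of flattened candidate keys.

    Key layout: pair-position index p (over the lexicographic (j,k) list)
    times 400, plus a*20 + b.
    """
    pp = position_pairs(n)
    js = np.array([j - 1 for j, _ in pp])
    ks = np.array([k - 1 for _, k in pp])
    w = windows.astype(np.int32)
    return (np.arange(len(pp), dtype=np.int32) * 400)[None, :] + w[:, js] * 20 + w[:, ks]


def _count_pairs(windows: np.ndarray, labels: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat (400 * n(n-1)/2,) occurrence counts per class."""
    size = 400 * (n * (n - 1) // 2)
    if len(windows) == 0:
        return np.zeros(size, dtype=np.int64), np.zeros(size, dtype=np.int64)
    keys = _flat_pair_keys(windows, n)
    pos = np.bincount(keys[labels == 1].ravel(), minlength=size)
    neg = np.bincount(keys[labels == 0].ravel(), minlength=size)
    return pos, neg


def _flat_to_key(flat: int, n: int) -> PairKey:
    pp = position_pairs(n)
    p, ab = divmod(flat, 400)
    a, b = divmod(ab, 20)
    j, k = pp[p]
    return PairKey(j, k, AMINO_ACIDS[a], AMINO_ACIDS[b])


def _key_to_flat(key: PairKey, n: int) -> int:
    pp = position_pairs(n)
    p = pp.index((key.j, key.k))
    return p * 400 + AA_INDEX[key.a] * 20 + AA_INDEX[key.b]


def count_pair_frequencies(dataset: PeptideDataset, n: int) -> dict[PairKey, tuple[int, int]]:
    """Occurrence counts of every candidate pair, per class.

    The returned mapping covers the complete candidate space of
    400 * n(n-1)/2 keys, zero counts included: each n-window of each peptide
    increments (count_pos, count_neg) for all of its n(n-1)/2 realized pairs.
    """
    windows, labels = extract_windows(dataset, n)
    pos, neg = _count_pairs(windows, labels, n)
    pp = position_pairs(n)
    out: dict[PairKey, tuple[int, int]] = {}
    flat = 0
    for j, k in pp:
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                out[PairKey(j, k, a, b)] = (int(pos[flat]), int(neg[flat]))
                flat += 1
    return out


def filter_by_frequency(counts: Mapping[PairKey, tuple[int, int]]) -> set[PairKey]:
    """Keys whose total occurrence is at least the mean over all given keys.

    The mean is taken over every key in ``counts`` (zeros included), so
    passing the complete candidate map from :func:`count_pair_frequencies`
    averages over the full candidate space.  Rare pairs below the mean are
    dropped for statistical stability — empirically about half survive.
    """
    if not counts:
        raise ValueError("empty counts mapping")
    totals = {key: cp + cn for key, (cp, cn) in counts.items()}
    mean = sum(totals.values()) / len(totals)
    if mean == 0.0:
        logger.warning("all pair counts are zero; keeping every key")
    return {key for key, tot in totals.items() if tot >= mean}


def information_value(f1: float, f0: float, p1: float, p0: float) -> float:
    """KL divergence D = f1*ln(f1/p1) + f0*ln(f0/p0), with 0*ln 0 := 0.

    (f1, f0) is a pair's occurrence split between epitope and non-epitope
    windows; (p1, p0) is the class prior.  D >= 0 with equality iff f == p.
    """
    for name, v in (("f1", f1), ("f0", f0), ("p1", p1), ("p0", p0)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative, got {v}")
    if p1 <= 0 or p0 <= 0:
        raise ValueError("class priors must be strictly positive")
    if abs(f1 + f0 - 1.0) > 1e-9 or abs(p1 + p0 - 1.0) > 1e-9:
        raise ValueError("f and p must each sum to 1")
    d = 0.0
    if f1 > 0:
        d += f1 * log(f1 / p1)
    if f0 > 0:
        d += f0 * log(f0 / p0)
    return max(d, 0.0)


@dataclass
class PairCatalog:
    """Ranked position-specific residue pairs with their selection statistics.

    ``entries`` holds one row per frequency-filter survivor, sorted by
    descending information value D (ties broken by ascending (j, k, a, b));
    ``selected`` is the top-K prefix actually used for encoding.
    """

    window_size: int
    entries: pd.DataFrame  # columns: j k a b count_pos count_neg f1 f0 D
    selected: list[PairKey]
    class_prior: tuple[float, float]  # (P1, P0)

    def __post_init__(self) -> None:
        self._indicator_lut: np.ndarray | None = None

    @property
    def top_k(self) -> int:
        return len(self.selected)

    def indicator_lut(self) -> np.ndarray:
        """Flat candidate key -> selected column index (or -1); cached."""
        if self._indicator_lut is None:
            n = self.window_size
            lut = np.full(400 * (n * (n - 1) // 2), -1, dtype=np.int32)
            for col, key in enumerate(self.selected):
                lut[_key_to_flat(key, n)] = col
            self._indicator_lut = lut
        return self._indicator_lut

    @classmethod
    def from_selected(cls, window_size: int, pairs: list[PairKey]) -> "PairCatalog":
        """Minimal catalog from an explicit pair list (no selection stats)."""
        df = pd.DataFrame(
            [(p.j, p.k, p.a, p.b, 0, 0, np.nan, np.nan, np.nan) for p in pairs],
            columns=["j", "k", "a", "b", "count_pos", "count_neg", "f1", "f0", "D"],
        )
        return cls(window_size, df, list(pairs), (0.5, 0.5))

    def to_tsv(self, path) -> None:
        df = self.entries.copy()
        rank = {key: i + 1 for i, key in enumerate(self.selected)}
        df["selected_rank"] = [
            rank.get(PairKey(int(r.j), int(r.k), r.a, r.b), 0) for r in df.itertuples()
        ]
        header = f"# window_size={self.window_size}\tP1={self.class_prior[0]!r}\tP0={self.class_prior[1]!r}\n"
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PairCatalog":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            meta = dict(tok.split("=") for tok in header.lstrip("# ").rstrip().split("\t"))
            df = pd.read_csv(fh, sep="\t")
        sel = df[df.selected_rank > 0].sort_values("selected_rank")
        selected = [PairKey(int(r.j), int(r.k), r.a, r.b) for r in sel.itertuples()]
        return cls(
            int(meta["window_size"]),
            df.drop(columns="selected_rank"),
            selected,
            (float(meta["P1"]), float(meta["P0"])),
        )


def select_top_pairs(dataset: PeptideDataset, n: int, top_k: int = 500) -> PairCatalog:
    """Rank candidate pairs by information value and keep the top K.

    Pipeline: count occurrences over every window -> eliminate pairs rarer
    than the candidate-space average -> per survivor compute the class split
    f_t = count_t / total and D against the prior P_t = (windows in class t)
    / (all windows) -> rank by descending D, ties by ascending (j, k, a, b).
    With a balanced dataset P1 = P0 = 0.5.  If fewer than K pairs survive the
    pre-filter, all survivors are selected (warning logged).
    """
    windows, labels = extract_windows(dataset, n)
    n_pos_w = int((labels == 1).sum())
    n_neg_w = int((labels == 0).sum())
    if n_pos_w == 0 or n_neg_w == 0:
        raise ValueError("pair selection requires both classes in the dataset")
    p1 = n_pos_w / len(labels)
    p0 = n_neg_w / len(labels)

    cpos, cneg = _count_pairs(windows, labels, n)
    totals = cpos + cneg
    mean = totals.mean()
    survivors = np.nonzero(totals >= mean)[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = cpos[survivors] / totals[survivors]
        f0 = cneg[survivors] / totals[survivors]
        d = np.where(f1 > 0, f1 * np.log(f1 / p1), 0.0) + np.where(
            f0 > 0, f0 * np.log(f0 / p0), 0.0
        )
    d = np.maximum(d, 0.0)

    # descending D, ties by ascending flat key (== ascending (j, k, a, b))
    order = np.lexsort((survivors, -d))
    survivors, f1, f0, d = survivors[order], f1[order], f0[order], d[order]

    keys = [_flat_to_key(int(s), n) for s in survivors]
    entries = pd.DataFrame(
        {
            "j": [key.j for key in keys],
            "k": [key.k for key in keys],
            "a": [key.a for key in keys],
            "b": [key.b for key in keys],
            "count_pos": cpos[survivors],
            "count_neg": cneg[survivors],
            "f1": f1,
            "f0": f0,
            "D": d,
        }
    )
    if len(keys) < top_k:
        logger.warning("only %d pairs survive the frequency filter (< K=%d)", len(keys), top_k)
    selected = keys[:top_k]
    return PairCatalog(n, entries, selected, (p1, p0))


# ---------------------------------------------------------------------------
# encoding

@dataclass(frozen=True)
class WindowFeatures:
    """Named feature blocks of one encoded window."""

    composition: np.ndarray  # (19,) int counts, residues ACDEFGHIKLMNPQRSTVW
    hydro_pairs: np.ndarray  # (n(n-1)/2,) B_j * B_k
    mass_pairs: np.ndarray  # (n(n-1)/2,) S_j * S_k
    pair_indicators: np.ndarray  # (K,) {0,1}

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate(
            [self.composition, self.hydro_pairs, self.mass_pairs, self.pair_indicators]
        )


def design_matrix(
    windows: np.ndarray,
    hydro: PropensityScale,
    mass: PropensityScale,
    catalog: PairCatalog,
) -> np.ndarray:
    """Encode a (m, n) window code matrix into the (m, 19 + n(n-1) + K)
    feature matrix, blocks ordered composition | hydro | mass | indicators."""
    m, n = windows.shape
    if n != catalog.window_size:
        raise ValueError(f"window length {n} != catalog window size {catalog.window_size}")
    n_pp = n * (n - 1) // 2
    k = catalog.top_k
    X = np.zeros((m, 19 + 2 * n_pp + k), dtype=np.float64)
    if m == 0:
        return X

    # composition counts over the first 19 residues (Y omitted)
    offsets = np.arange(m, dtype=np.intp)[:, None] * 20 + windows
    comp = np.bincount(offsets.ravel(), minlength=m * 20).reshape(m, 20)
    X[:, :19] = comp[:, :19]

    pp = position_pairs(n)
    js = np.array([j - 1 for j, _ in pp])
    ks = np.array([kk - 1 for _, kk in pp])
    b = hydro.as_array()[windows]
    s = mass.as_array()[windows]
    X[:, 19 : 19 + n_pp] = b[:, js] * b[:, ks]
    X[:, 19 + n_pp : 19 + 2 * n_pp] = s[:, js] * s[:, ks]

    if k:
        lut = catalog.indicator_lut()
        cols = lut[_flat_pair_keys(windows, n)]
        rows = np.broadcast_to(np.arange(m)[:, None], cols.shape)
        hit = cols >= 0
        X[rows[hit], 19 + 2 * n_pp + cols[hit]] = 1.0
    return X


def encode_window(
    window: str,
    hydro: PropensityScale,
    mass: PropensityScale,
    catalog: PairCatalog,
) -> WindowFeatures:
    """Encode a single n-mer into its named feature blocks."""
    if len(window) != catalog.window_size:
        raise ValueError(
            f"window length {len(window)} != catalog window size {catalog.window_size}"
        )
    codes = encode_sequence(window)[None, :]
    n_pp = catalog.window_size * (catalog.window_size - 1) // 2
    row = design_matrix(codes, hydro, mass, catalog)[0]
    return WindowFeatures(
        composition=row[:19].astype(np.int64),
        hydro_pairs=row[19 : 19 + n_pp],
        mass_pairs=row[19 + n_pp : 19 + 2 * n_pp],
        pair_indicators=row[19 + 2 * n_pp :].astype(np.int64),
    )
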