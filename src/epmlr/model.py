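"""Multiple-linear-regression epitope scoring.

Training builds the feature matrix of *every* n-window of every training
peptide (each window inherits its peptide's epitope label as the 0/1
regression target) and solves ordinary least squares for the coefficient
blocks alpha (composition), beta (hydrophilicity products), gamma
(side-chain-mass products), delta (selected-pair indicators) and the
intercept C.  The design matrix is collinear by construction (indicator
columns overlap the composition block), so the minimal-norm SVD solution
with a relative singular-value cutoff of 1e-10 is used; no regularization.

Scoring slides the window across a peptide one residue at a time; the
peptide's epitope propensity is the arithmetic mean of its L - n + 1 window
scores Q, thresholded (default 0.5) for a binary call.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import encode_sequence
from .datasets import PeptideDataset, PeptideRecord
from .features import (
    PairCatalog,
    PairKey,
    design_matrix,
    extract_windows,
)
from .scales import PropensityScale

logger = logging.getLogger(__name__)

__all__ = ["MLRModel", "PeptideScore", "fit", "score_window", "score_peptide",
           "score_dataset", "predict_fasta", "save_model", "load_model"]

SVD_RCOND = 1e-10


@dataclass
class MLRModel:
    """Fitted coefficients plus everything needed to reproduce scores."""

    window_size: int
    alpha: np.ndarray  # (19,) composition coefficients
    beta: np.ndarray  # (n(n-1)/2,) hydrophilicity-product coefficients
    gamma: np.ndarray  # (n(n-1)/2,) mass-product coefficients
    delta: np.ndarray  # (K,) selected-pair coefficients
    intercept: float
    hydro_scale: PropensityScale
    mass_scale: PropensityScale
    catalog: PairCatalog
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_pp = self.window_size * (self.window_size - 1) // 2
        if self.alpha.shape != (19,):
            raise ValueError("alpha must have length 19")
        if self.beta.shape != (n_pp,) or self.gamma.shape != (n_pp,):
            raise ValueError(f"beta/gamma must have length {n_pp}")
        if self.delta.shape != (self.catalog.top_k,):
            raise ValueError(f"delta must have length {self.catalog.top_k}")
        if self.catalog.window_size != self.window_size:
            raise ValueError("catalog window size mismatch")

    @property
    def coefficients(self) -> np.ndarray:
        """All coefficients in design-matrix column order (no intercept)."""
        return np.concatenate([self.alpha, self.beta, self.gamma, self.delta])


@dataclass(frozen=True)
class PeptideScore:
    """Window scores and their mean for one peptide."""

    id: str
    window_scores: list[float]
    peptide_score: float
    predicted_label: int


def fit(
    dataset: PeptideDataset,
    n: int,
    hydro: PropensityScale,
    mass: PropensityScale,
    catalog: PairCatalog,
    metadata: dict | None = None,
) -> MLRModel:
    """Ordinary-least-squares fit of the window-scoring model.

    Raises on an empty or single-class dataset.  With a rank-deficient
    design the minimal-norm solution is returned, so duplicated or
    linearly dependent feature columns do not perturb fitted scores.
    """
    if len(dataset) == 0:
        raise ValueError("cannot fit on an empty dataset")
    labels = dataset.labels
    if labels.min() == labels.max():
        raise ValueError("cannot fit on a single-class dataset")

    windows, y = extract_windows(dataset, n)
    X = design_matrix(windows, hydro, mass, catalog)
    Xi = np.hstack([X, np.ones((len(X), 1))])
    coef, *_ = np.linalg.lstsq(Xi, y.astype(np.float64), rcond=SVD_RCOND)

    n_pp = n * (n - 1) // 2
    meta = dict(metadata or {})
    meta.setdefault("dataset_hash", dataset.content_hash())
    meta.setdefault("n_records", len(dataset))
    model = MLRModel(
        window_size=n,
        alpha=coef[:19],
        beta=coef[19 : 19 + n_pp],
        gamma=coef[19 + n_pp : 19 + 2 * n_pp],
        delta=coef[19 + 2 * n_pp : -1],
        intercept=float(coef[-1]),
        hydro_scale=hydro,
        mass_scale=mass,
        catalog=catalog,
        metadata=meta,
    )
    logger.info("fitted MLR model: n=%d, %d windows, %d features", n, len(X), X.shape[1])
    return model


def _score_window_matrix(model: MLRModel, windows: np.ndarray) -> np.ndarray:
    X = design_matrix(windows, model.hydro_scale, model.mass_scale, model.catalog)
    return X @ model.coefficients + model.intercept


def score_window(model: MLRModel, window: str) -> float:
    """Epitope propensity Q of a single n-mer window."""
    if len(window) != model.window_size:
        raise ValueError(f"window length {len(window)} != model window size {model.window_size}")
    return float(_score_window_matrix(model, encode_sequence(window)[None, :])[0])


def score_peptide(model: MLRModel, record: PeptideRecord, threshold: float = 0.5) -> PeptideScore:
    """Score a peptide as the mean of its L - n + 1 window scores.

    A 20-mer scored with an n-mer window yields 21 - n window scores;
    predicted_label is 1 iff the mean score >= threshold.
    """
    n = model.window_size
    if len(record.sequence) < n:
        raise ValueError(
            f"record {record.id!r}: length {len(record.sequence)} < window size {n}"
        )
    codes = encode_sequence(record.sequence)
    windows = np.ascontiguousarray(np.lib.stride_tricks.sliding_window_view(codes, n))
    q = _score_window_matrix(model, windows)
    mean = float(q.mean())
    return PeptideScore(record.id, [float(v) for v in q], mean, int(mean >= threshold))


def score_dataset(
    model: MLRModel, dataset: PeptideDataset, threshold: float = 0.5
) -> pd.DataFrame:
    """Peptide-level scores for a whole dataset (one row per record)."""
    rows = []
    for rec in dataset:
        ps = score_peptide(model, rec, threshold)
        rows.append((rec.id, rec.label, ps.peptide_score, ps.predicted_label))
    return pd.DataFrame(rows, columns=["id", "label", "score", "predicted"])


def predict_fasta(
    model: MLRModel,
    fasta_path,
    peptide_length: int = 20,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Score every sliding ``peptide_length``-mer of each FASTA sequence.

    Output columns: sequence_id, start, end (1-based inclusive), peptide,
    score, label.  Sequences shorter than ``peptide_length`` are skipped
    with a warning.
    """
    n = model.window_size
    if peptide_length < n:
        raise ValueError(f"peptide_length {peptide_length} < model window size {n}")
    rows = []
    with open(fasta_path, encoding="utf-8") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if len(seq) < peptide_length:
                logger.warning(
                    "sequence %s (length %d) shorter than %d; skipped",
                    rec.id, len(seq), peptide_length,
                )
                continue
            codes = encode_sequence(seq)
            windows = np.ascontiguousarray(np.lib.stride_tricks.sliding_window_view(codes, n))
            q = _score_window_matrix(model, windows)
            w_per_pep = peptide_length - n + 1
            # mean of consecutive runs of window scores, one per peptide start
            csum = np.concatenate([[0.0], np.cumsum(q)])
            scores = (csum[w_per_pep:] - csum[:-w_per_pep]) / w_per_pep
            for s, sc in enumerate(scores[: len(seq) - peptide_length + 1], start=1):
                rows.append(
                    (rec.id, s, s + peptide_length - 1,
                     seq[s - 1 : s - 1 + peptide_length], float(sc), int(sc >= threshold))
                )
    return pd.DataFrame(
        rows, columns=["sequence_id", "start", "end", "peptide", "score", "label"]
    )


# ---------------------------------------------------------------------------
# serialization — one self-contained JSON document

_SCHEMA_VERSION = 1


def save_model(model: MLRModel, path) -> None:
    """Write the model (coefficients, scales, catalog) as versioned JSON."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "window_size": model.window_size,
        "alpha": model.alpha.tolist(),
        "beta": model.beta.tolist(),
        "gamma": model.gamma.tolist(),
        "delta": model.delta.tolist(),
        "intercept": model.intercept,
        "hydro_scale": {"name": model.hydro_scale.name, "values": model.hydro_scale.values},
        "mass_scale": {"name": model.mass_scale.name, "values": model.mass_scale.values},
        "catalog": {
            "window_size": model.catalog.window_size,
            "class_prior": list(model.catalog.class_prior),
            "entries": model.catalog.entries.to_dict(orient="list"),
            "selected": [list(key) for key in model.catalog.selected],
        },
        "metadata": model.metadata,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> MLRModel:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != _SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {doc.get('schema_version')!r}")
    cat = doc["catalog"]
    catalog = PairCatalog(
        window_size=cat["window_size"],
        entries=pd.DataFrame(cat["entries"]),
        selected=[PairKey(j, k, a, b) for j, k, a, b in cat["selected"]],
        class_prior=tuple(cat["class_prior"]),
    )
    return MLRModel(
        window_size=doc["window_size"],
        alpha=np.asarray(doc["alpha"]),
        beta=np.asarray(doc["beta"]),
        gamma=np.asarray(doc["gamma"]),
        delta=np.asarray(doc["delta"]),
        intercept=doc["intercept"],
        hydro_scale=PropensityScale(doc["hydro_scale"]["name"], doc["hydro_scale"]["values"]),
        mass_scale=PropensityScale(doc["mass_scale"]["name"], doc["mass_scale"]["values"]),
        catalog=catalog,
        metadata=doc.get("metadata", {}),
    )
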