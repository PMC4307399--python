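"""Labeled peptide datasets: reading, writing, trimming and resampling.

The core container is :class:`PeptideDataset`, an ordered list of
:class:`PeptideRecord` (id, sequence, binary epitope label).  Datasets are
read from two plain-text formats:

* TSV — ``id<TAB>sequence<TAB>label`` rows, optional header;
* FASTA — standard records whose headers carry a trailing ``|1`` / ``|0``
  label token (e.g. ``>pept_0007|1``).

Long records (e.g. 100-mers produced by symmetric extension of shorter
epitopes) are reduced to fixed-length cores with :func:`trim_to_core`, and
balanced positive/negative subsets are drawn with
:func:`sample_balanced_subset` for noisy-negative resampling experiments.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_INDEX

logger = logging.getLogger(__name__)

__all__ = [
    "PeptideRecord",
    "PeptideDataset",
    "read_peptide_table",
    "write_peptide_table",
    "trim_to_core",
    "sample_balanced_subset",
]


@dataclass(frozen=True)
class PeptideRecord:
    """One fixed-length peptide with a binary epitope label.

    label 1 = epitope, 0 = non-epitope; this is the indicator the regression
    is trained to reproduce, inherited by every window of the peptide.
    """

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def validate_alphabet(self) -> None:
        bad = sorted({c for c in self.sequence if c not in AA_INDEX})
        if bad:
            raise ValueError(f"record {self.id!r}: non-canonical residue(s) {bad}")


class PeptideDataset:
    """Ordered collection of :class:`PeptideRecord`.

    Order is significant: fold assignment and subset sampling are defined on
    record order, so datasets behave reproducibly end to end.
    """

    def __init__(self, records: Iterable[PeptideRecord]):
        self.records: list[PeptideRecord] = list(records)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return PeptideDataset(self.records[idx])
        return self.records[idx]

    # -- summaries ----------------------------------------------------------
    @property
    def n_positive(self) -> int:
        return sum(r.label for r in self.records)

    @property
    def n_negative(self) -> int:
        return len(self.records) - self.n_positive

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def peptide_length(self) -> int:
        """Common length of all records; raises if lengths are mixed."""
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"mixed peptide lengths {sorted(lengths)}; trim first")
        return lengths.pop()

    def subset(self, indices: Sequence[int]) -> "PeptideDataset":
        return PeptideDataset([self.records[i] for i in indices])

    def split_by_label(self) -> tuple["PeptideDataset", "PeptideDataset"]:
        """(positives, negatives), each preserving input order."""
        pos = [r for r in self.records if r.label == 1]
        neg = [r for r in self.records if r.label == 0]
        return PeptideDataset(pos), PeptideDataset(neg)

    def content_hash(self) -> str:
        """SHA-256 over (id, sequence, label) rows; stable provenance key."""
        h = hashlib.sha256()
        for r in self.records:
            h.update(f"{r.id}\t{r.sequence}\t{r.label}\n".encode())
        return h.hexdigest()


def _parse_fasta_label(header_id: str) -> tuple[str, int]:
    base, sep, tail = header_id.rpartition("|")
    if sep and tail in ("0", "1"):
        return base, int(tail)
    raise ValueError(f"FASTA header {header_id!r} lacks a trailing |0 / |1 label token")


def read_peptide_table(path, fmt: str = "tsv", strict: bool = True) -> PeptideDataset:
    """Read a labeled peptide dataset from TSV or labeled FASTA.

    Parameters
    ----------
    path
        Input file.
    fmt
        ``"tsv"`` (``id<TAB>sequence<TAB>label``, optional header) or
        ``"fasta"`` (headers ending in ``|0`` / ``|1``).
    strict
        If True (default), any record with a non-canonical residue aborts the
        read with an error listing the offending ids; if False such records
        are dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")

    records: list[PeptideRecord] = []
    if fmt == "tsv":
        with open(path, encoding="utf-8", newline="") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\r\n")
                if not line:
                    continue
                parts = line.split("\t")
                if lineno == 1 and [p.lower() for p in parts[:3]] == ["id", "sequence", "label"]:
                    continue
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}")
                rid, seq, lab = parts
                if lab not in ("0", "1"):
                    raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {lab!r}")
                records.append(PeptideRecord(rid, seq.upper(), int(lab)))
    elif fmt == "fasta":
        with open(path, encoding="utf-8") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                rid, lab = _parse_fasta_label(rec.id)
                records.append(PeptideRecord(rid, str(rec.seq).upper(), lab))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'tsv' or 'fasta'")

    if not records:
        raise ValueError(f"{path}: no peptide records found")

    offending = []
    kept = []
    for r in records:
        try:
            r.validate_alphabet()
        except ValueError:
            offending.append(r.id)
        else:
            kept.append(r)
    if offending:
        if strict:
            raise ValueError(
                f"{path}: non-canonical residues in {len(offending)} record(s): "
                + ", ".join(offending[:20])
            )
        logger.warning("%s: dropped %d record(s) with non-canonical residues", path, len(offending))
        records = kept
    if not records:
        raise ValueError(f"{path}: all records dropped during validation")

    ds = PeptideDataset(records)
    logger.info("read %d records (%d positive, %d negative) from %s",
                len(ds), ds.n_positive, ds.n_negative, path)
    return ds


def write_peptide_table(dataset: PeptideDataset, path, fmt: str = "tsv") -> None:
    """Write a dataset in the format :func:`read_peptide_table` reads back."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for r in dataset:
                fh.write(f"{r.id}\t{r.sequence}\t{r.label}\n")
    elif fmt == "fasta":
        seqs = [SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.label}", description="") for r in dataset]
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            SeqIO.write(seqs, fh, "fasta-2line")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def trim_to_core(record: PeptideRecord, core_length: int = 20) -> PeptideRecord:
    """Extract the centered ``core_length``-mer of a longer record.

    Records built by extending an epitope symmetrically on both flanks are
    reduced back to their central core.  When the residue surplus is odd, one
    extra residue is removed from the N-terminal side (remove ``ceil(r/2)``
    N-terminal, ``floor(r/2)`` C-terminal residues, ``r = length - core``).
    """
    if core_length < 1:
        raise ValueError("core_length must be positive")
    surplus = len(record.sequence) - core_length
    if surplus < 0:
        raise ValueError(
            f"record {record.id!r}: length {len(record.sequence)} < core_length {core_length}"
        )
    start = (surplus + 1) // 2
    return PeptideRecord(record.id, record.sequence[start : start + core_length], record.label)


def trim_dataset(dataset: PeptideDataset, core_length: int = 20) -> PeptideDataset:
    """Apply :func:`trim_to_core` to every record."""
    return PeptideDataset([trim_to_core(r, core_length) for r in dataset])


def sample_balanced_subset(
    positives: PeptideDataset, negatives: PeptideDataset, seed: int
) -> PeptideDataset:
    """All positives plus an equal-size random negative subset.

    Negatives are drawn uniformly without replacement; the result lists the
    positives first (input order) then the sampled negatives (sampled order),
    so downstream fold assignment is reproducible from the seed alone.
    """
    n_pos, n_neg = len(positives), len(negatives)
    if n_neg < n_pos:
        raise ValueError(f"need at least as many negatives as positives ({n_neg} < {n_pos})")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_neg, size=n_pos, replace=False)
    return PeptideDataset(list(positives) + [negatives[int(i)] for i in idx])
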