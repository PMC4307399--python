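"""Per-residue propensity scales (hydrophilicity, side-chain mass).

A :class:`PropensityScale` maps each of the 20 canonical residues to a
z-scored value (mean 0, population SD 1 over the 20 residues).  Two built-in
raw scales are provided:

* ``parker`` — Parker–Guo–Hodges HPLC-derived hydrophilicity (1986);
* ``side_chain_mass`` — monoisotopic side-chain masses (residue mass minus
  the constant C2H2NO backbone).  Because scales are z-scored, the constant
  backbone offset is immaterial.

Custom scales can be loaded from a two-column TSV ``residue<TAB>value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS

__all__ = [
    "PropensityScale",
    "normalize_scale",
    "read_scale_tsv",
    "get_scale",
    "PARKER_HYDROPHILICITY",
    "SIDE_CHAIN_MASS",
]

# Parker, Guo & Hodges (1986) HPLC hydrophilicity.
PARKER_HYDROPHILICITY: dict[str, float] = {
    "A": 2.1, "C": 1.4, "D": 10.0, "E": 7.8, "F": -9.2,
    "G": 5.7, "H": 2.1, "I": -8.0, "K": 5.7, "L": -9.2,
    "M": -4.2, "N": 7.0, "P": 2.1, "Q": 6.0, "R": 4.2,
    "S": 6.5, "T": 5.2, "V": -3.7, "W": -10.0, "Y": -1.9,
}

# Monoisotopic residue mass minus the 56.01364 Da C2H2NO backbone.
SIDE_CHAIN_MASS: dict[str, float] = {
    "G": 1.00782, "A": 15.02347, "S": 31.01839, "P": 41.03912,
    "V": 43.05477, "T": 45.03404, "C": 46.99555, "L": 57.07042,
    "I": 57.07042, "N": 58.02929, "D": 59.01330, "Q": 72.04494,
    "K": 72.08132, "E": 73.02895, "M": 75.02685, "H": 81.04527,
    "F": 91.05477, "R": 100.08747, "Y": 107.04969, "W": 130.06567,
}

_BUILTIN_RAW = {
    "parker": PARKER_HYDROPHILICITY,
    "side_chain_mass": SIDE_CHAIN_MASS,
}


@dataclass(frozen=True)
class PropensityScale:
    """A named, normalized residue->value map (mean 0, population SD 1)."""

    name: str
    values: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.values]
        if missing:
            raise ValueError(f"scale {self.name!r}: missing residues {missing}")

    def as_array(self) -> np.ndarray:
        """Values in canonical alphabet order."""
        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=np.float64)

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def normalize_scale(raw: dict[str, float], name: str) -> PropensityScale:
    """Z-score a raw residue scale over the 20 canonical values.

    Population statistics (ddof=0).  A scale with zero variance carries no
    signal and is rejected.
    """
    missing = [aa for aa in AMINO_ACIDS if aa not in raw]
    if missing:
        raise ValueError(f"scale {name!r}: missing residues {missing}")
    v = np.array([float(raw[aa]) for aa in AMINO_ACIDS])
    sd = v.std()
    if sd == 0.0:
        raise ValueError(f"scale {name!r}: zero variance; cannot normalize")
    z = (v - v.mean()) / sd
    return PropensityScale(name, dict(zip(AMINO_ACIDS, z.tolist())))


def read_scale_tsv(path, name: str | None = None) -> PropensityScale:
    """Load and normalize a two-column ``residue<TAB>value`` TSV."""
    path = Path(path)
    raw: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'residue<TAB>value'")
            raw[parts[0].upper()] = float(parts[1])
    return normalize_scale(raw, name or path.stem)


def get_scale(name: str) -> PropensityScale:
    """Built-in scale by name (``parker`` or ``side_chain_mass``), normalized."""
    try:
        return normalize_scale(_BUILTIN_RAW[name], name)
    except KeyError:
        raise ValueError(f"unknown scale {name!r}; built-ins: {sorted(_BUILTIN_RAW)}") from None
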