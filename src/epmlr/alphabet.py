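"""Canonical amino-acid alphabet and integer encoding helpers.

All feature machinery works on the 20 canonical residues in alphabetical
one-letter order; every sequence is converted once to a uint8 code array.
"""

from __future__ import annotations

import numpy as np

#: The 20 canonical residues, alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: residue -> integer code (0..19)
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Residue omitted from the 19-component composition block (last in order).
COMPOSITION_OMITTED: str = "Y"

_CODE_LUT = np.full(128, -1, dtype=np.int16)
for _aa, _i in AA_INDEX.items():
    _CODE_LUT[ord(_aa)] = _i


def is_canonical(sequence: str) -> bool:
    """True if every character is one of the 20 canonical residues."""
    return all(c in AA_INDEX for c in sequence)


def encode_sequence(sequence: str) -> np.ndarray:
    """Convert a residue string to a uint8 code array.

    Raises
    ------
    ValueError
        If the sequence contains a non-canonical character.
    """
    raw = np.frombuffer(sequence.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _CODE_LUT[np.minimum(raw, 127)]
    if (codes < 0).any():
        bad = sorted({sequence[i] for i in np.nonzero(codes < 0)[0]})
        raise ValueError(f"non-canonical residue(s) {bad} in sequence {sequence!r}")
    return codes.astype(np.uint8)


def decode_codes(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return "".join(AMINO_ACIDS[c] for c in codes)
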