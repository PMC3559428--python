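"""Residue alphabet constants shared across the package.

The fixed residue ordering A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y is used
for every 20-vector and 20x20 matrix in the package (composition vectors,
directed substitution matrices, scoring tables).
"""

from __future__ import annotations

import numpy as np

#: Canonical one-letter residue ordering used for all vectors and matrices.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

#: Index of each residue in :data:`AA_ORDER`.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Gap character used in aligned sequences.
GAP: str = "-"

#: Ambiguity letter accepted in lenient mode.
AMBIGUOUS: str = "X"

# Average amino-acid frequencies of a large curated proteome collection
# (UniProtKB/Swiss-Prot release statistics), renormalised to sum to 1.
# Used as the default ancestral composition of the sequence simulator.
_SWISSPROT_PERCENT = {
    "A": 8.25, "C": 1.37, "D": 5.45, "E": 6.75, "F": 3.86,
    "G": 7.07, "H": 2.27, "I": 5.96, "K": 5.84, "L": 9.66,
    "M": 2.42, "N": 4.06, "P": 4.70, "Q": 3.93, "R": 5.53,
    "S": 6.56, "T": 5.34, "V": 6.87, "W": 1.08, "Y": 2.92,
}

DEFAULT_AA_FREQS: np.ndarray = np.array(
    [_SWISSPROT_PERCENT[aa] for aa in AA_ORDER], dtype=float
)
DEFAULT_AA_FREQS /= DEFAULT_AA_FREQS.sum()

#: Uniform composition over the 20 residues.
UNIFORM_AA_FREQS: np.ndarray = np.full(20, 1.0 / 20.0)

# ASCII lookup table: ord(char) -> residue index, -1 for non-canonical.
_CHAR_TO_INDEX = np.full(128, -1, dtype=np.int8)
for _aa, _i in AA_INDEX.items():
    _CHAR_TO_INDEX[ord(_aa)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a residue string as an int array of indices into AA_ORDER.

    Non-canonical characters (gaps, X, ...) map to -1.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CHAR_TO_INDEX[raw]


def decode(indices: np.ndarray) -> str:
    """Inverse of :func:`encode` for arrays of valid residue indices."""
    lut = np.frombuffer(AA_ORDER.encode("ascii"), dtype=np.uint8)
    return lut[indices].tobytes().decode("ascii")
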