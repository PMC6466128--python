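"""Genetic-code tables and base/codon encodings shared across modules.

The standard (table 1) genetic code is taken from Biopython once at import
time; everything downstream works on small numpy lookup tables so the
permutation engine stays vectorized.
"""
from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_TO_AA = {c: str(Seq(c).translate()) for c in CODONS}
STOP_CODONS = frozenset(c for c, aa in CODON_TO_AA.items() if aa == "*")
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]

# aa character (ord) per codon id; codon id = 16*b0 + 4*b1 + b2
AA_OF_CODON_ID = np.array([ord(CODON_TO_AA[c]) for c in CODONS], dtype=np.int16)

# NONSYN_A2G[codon_id, pos] is True when the codon carries A at `pos` and
# the A->G transition there changes the encoded amino acid.
NONSYN_A2G = np.zeros((64, 3), dtype=bool)
for _cid, _codon in enumerate(CODONS):
    for _pos in range(3):
        if _codon[_pos] == "A":
            mutated = _codon[:_pos] + "G" + _codon[_pos + 1:]
            NONSYN_A2G[_cid, _pos] = CODON_TO_AA[mutated] != CODON_TO_AA[_codon]


# Allowed third-base alphabet per codon: the set of bases at position 3
# that encode the same amino acid (e.g. {A,G} for the two-fold purine
# boxes, {A,C,T} for Ile, {G} for Met/Trp, all four for four-fold boxes).
# Third positions sharing an alphabet are exchangeable: any permutation
# among them preserves the protein and, being a permutation, the global
# base multiset.
THIRD_ALPHABET = {}
for _codon in CODONS:
    if _codon in STOP_CODONS:
        continue
    _aa = CODON_TO_AA[_codon]
    THIRD_ALPHABET[_codon] = frozenset(
        b for b in BASES if CODON_TO_AA[_codon[:2] + b] == _aa)

_ALPHABET_IDS = {alpha: i for i, alpha in
                 enumerate(sorted(set(THIRD_ALPHABET.values()),
                                  key=lambda s: ("".join(sorted(s)))))}
#: exchange-class id per codon id (-1 for stop codons)
THIRD_GROUP_OF_CODON_ID = np.full(64, -1, dtype=np.int64)
for _cid, _codon in enumerate(CODONS):
    if _codon in THIRD_ALPHABET:
        THIRD_GROUP_OF_CODON_ID[_cid] = _ALPHABET_IDS[THIRD_ALPHABET[_codon]]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    return str(Seq(seq).translate())


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to int8 codes 0..3."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    if (out < 0).any():
        bad = seq[int(np.nonzero(out < 0)[0][0])]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def decode(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode("ascii"), dtype=np.uint8)
    return lut[np.asarray(codes, dtype=np.intp)].tobytes().decode("ascii")


def codon_ids(codes: np.ndarray) -> np.ndarray:
    """Codon ids (0..63) for a base-code array whose length is a multiple of 3."""
    c = codes.reshape(-1, 3).astype(np.int32)
    return c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
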