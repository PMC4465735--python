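"""Low-level sequence encodings and seeded RNG streams shared across modules.

Bases are encoded as uint8: A=0, C=1, G=2, T=3, N=4 (anything unrecognised
also maps to 4).  Gaps are handled at the alignment layer, not here.
"""

from __future__ import annotations

import zlib

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

# IUPAC code for an unordered set of bases (used for consensus ties).
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

# Fractional base content of every IUPAC nucleotide code (for ambiguity-aware GC).
IUPAC_FRACTIONS = {
    code: {b: 1.0 / len(bases) for b in bases}
    for bases, code in ((tuple(sorted(k)), v) for k, v in IUPAC.items())
}


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0..T=3, everything else 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def stream(master_seed: int, *tokens) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a master seed.

    Tokens (locus ids, stage names, integers) are hashed with crc32 so that
    adding loci or stages never perturbs the draws of existing streams.
    """
    entropy = [int(master_seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(t).encode("utf8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def stream_seed(master_seed: int, *tokens) -> int:
    """A single integer seed (< 2^31) derived like :func:`stream`."""
    h = int(master_seed) & 0x7FFFFFFF
    for t in tokens:
        h = zlib.crc32(str(t).encode("utf8"), h)
    return h & 0x7FFFFFFF
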