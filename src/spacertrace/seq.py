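"""Small DNA sequence helpers shared across the package.

Everything here operates on plain upper-case strings over {A,C,G,T,N};
coordinates are 0-based half-open throughout the package, and strand is
encoded as '+'/'-'.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# fixed byte encoding used by the vectorized scanners
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G+C bases (N ignored in the denominator)."""
    acgt = sum(seq.count(b) for b in DNA_ALPHABET)
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def random_dna(n: int, rng: np.random.Generator, gc: float = 0.33) -> str:
    """i.i.d. random DNA of length ``n`` with the given GC fraction.

    The default GC of 0.33 matches the low-GC genomes this package was
    designed around (host genomes of ~31-33% GC).
    """
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(4, size=n, p=p)
    return np.frombuffer(b"AGCT", dtype=np.uint8)[codes].tobytes().decode("ascii")


def encode(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes (A=0,C=1,G=2,T=3; anything else 255)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def translate(seq: str) -> str:
    """Translate an in-frame DNA string (trailing partial codon dropped)."""
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate())


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Number of mismatching positions between equal-length strings.

    With ``limit`` set, counting stops early once ``limit`` is exceeded
    (the returned value is then only guaranteed to be > limit).
    """
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    mm = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                mm += 1
        return mm
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm
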