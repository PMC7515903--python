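"""Low-level sequence helpers shared across modules.

Spidroin coding sequences are generated and manipulated as plain upper-case
strings; Biopython objects are used at the I/O boundary only.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"

# Codon table restricted so that no TA or TG dinucleotide can occur inside a
# codon or across a codon junction (no codon ends in T).  Any concatenation of
# these codons is therefore free of stop codons (TAA/TAG/TGA) in *every*
# reading frame, which keeps tandem arrays with non-codon-multiple unit
# lengths open.  Residues C, M, W and Y have no such codon and are excluded
# from generated gene bodies.
SAFE_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCC", "GCA", "GCG"),
    "R": ("CGC", "CGA", "CGG", "AGA", "AGG"),
    "N": ("AAC",),
    "D": ("GAC",),
    "E": ("GAA", "GAG"),
    "Q": ("CAA", "CAG"),
    "G": ("GGC", "GGA", "GGG"),
    "H": ("CAC",),
    "I": ("ATC",),
    "L": ("CTC",),
    "K": ("AAA", "AAG"),
    "F": ("TTC",),
    "P": ("CCC", "CCA", "CCG"),
    "S": ("TCC", "TCA", "TCG", "AGC"),
    "T": ("ACC", "ACA", "ACG"),
    "V": ("GTC",),
}

SAFE_RESIDUES = frozenset(SAFE_CODONS)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(nt: str) -> str:
    """Translate frame 0, discarding any trailing partial codon."""
    usable = len(nt) - len(nt) % 3
    return str(Seq(nt[:usable]).translate())


def encode_protein(aa: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform choice among stop-proof codons."""
    parts = []
    for res in aa:
        try:
            codons = SAFE_CODONS[res]
        except KeyError:
            raise ValueError(
                f"residue {res!r} cannot be encoded without risking a stop "
                f"codon in shifted frames; allowed: {''.join(sorted(SAFE_CODONS))}"
            )
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def mutate_keeping_frame_open(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at ``rate`` while never creating a TA or TG
    dinucleotide, so the stop-free guarantee of generated genes survives."""
    if rate <= 0:
        return seq
    out = list(seq)
    n = len(out)
    hits = np.flatnonzero(rng.random(n) < rate)
    for i in hits:
        left = out[i - 1] if i > 0 else ""
        right = out[i + 1] if i < n - 1 else ""
        choices = [b for b in DNA_ALPHABET if b != out[i]]
        if left == "T":
            choices = [b for b in choices if b not in "AG"]
        if right in "AG":
            choices = [b for b in choices if b != "T"]
        if not choices:
            continue
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def identity(a: str, b: str) -> float:
    """Fraction of matching positions over the shorter length (gap-free)."""
    if not a or not b:
        return 0.0
    m = min(len(a), len(b))
    x = np.frombuffer(a[:m].encode(), dtype=np.uint8)
    y = np.frombuffer(b[:m].encode(), dtype=np.uint8)
    return float((x == y).mean())


def cyclic_identity(unit_a: str, unit_b: str) -> float:
    """Identity between two tandem-repeat units, invariant to rotation and
    strand: a unit is only defined up to the phase at which extension entered
    the array.  Uses edit distance of ``unit_a`` against the doubled target."""
    import edlib

    best = 0.0
    for cand in (unit_b, revcomp(unit_b)):
        res = edlib.align(unit_a, cand + cand, mode="HW", task="distance")
        best = max(best, 1.0 - res["editDistance"] / max(len(unit_a), 1))
    return best
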