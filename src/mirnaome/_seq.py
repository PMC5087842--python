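"""Small shared sequence helpers (DNA alphabet, reverse complement)."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-safe)."""
    return seq.translate(_COMP)[::-1]


def is_dna(seq: str) -> bool:
    return all(c in "ACGTN" for c in seq)


def phred_to_qual(scores) -> str:
    """Phred scores -> Phred+33 quality string."""
    return "".join(chr(int(s) + 33) for s in scores)


def qual_to_phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]
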