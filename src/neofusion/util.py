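"""Small shared helpers."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


class NeofusionError(Exception):
    """Base class for package errors."""


class ParameterError(NeofusionError):
    """Invalid user-supplied parameter."""


class ConsistencyError(NeofusionError):
    """Inputs that contradict each other (e.g. alignment vs annotation)."""
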