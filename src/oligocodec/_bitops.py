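"""Helpers for the ASCII '0'/'1' bit-string representation.

Bit strings are plain ``str`` objects over {'0','1'}; positions are 1-based
in the coding layers (the weighted-sum arithmetic is defined that way).
"""

from __future__ import annotations

from .errors import DecodeError, InvalidInputError

_BITSET = frozenset("01")


def validate_bits(bits: str) -> str:
    if not _BITSET.issuperset(bits):
        bad = sorted(set(bits) - _BITSET)
        raise InvalidInputError(f"bit string contains non-binary symbols: {bad}")
    return bits


def bytes_to_bits(data: bytes) -> str:
    """Big-endian bit expansion: b'\\x05' -> '00000101'."""
    return "".join(f"{byte:08b}" for byte in data)


def bits_to_bytes(bits: str) -> bytes:
    """Inverse of :func:`bytes_to_bits`; requires a whole number of bytes."""
    validate_bits(bits)
    if len(bits) % 8:
        raise DecodeError(f"bit length {len(bits)} is not a multiple of 8")
    return bytes(int(bits[i : i + 8], 2) for i in range(0, len(bits), 8))
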