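"""Pluggable lossless compression front-end.

The pipeline treats compression as an interchangeable stage behind
:class:`CompressorSpec`: ``passthrough`` (identity) and ``zlib`` (DEFLATE)
are built in, and externally produced bitstreams can be injected by
encoding them with ``passthrough``.  Learned image codecs are deliberately
outside this package; the interface is the extension point.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

from ._bitops import bits_to_bytes, bytes_to_bits
from .errors import DecodeError, InvalidInputError, InvalidParameterError

__all__ = ["CompressorSpec", "compress", "decompress", "available_compressors"]


@dataclass(frozen=True)
class CompressorSpec:
    name: str = "zlib"
    parameters: dict = field(default_factory=dict)
    lossless: bool = True

    def __post_init__(self):
        if self.name not in _CODECS:
            raise InvalidParameterError(
                f"unknown compressor {self.name!r}; available: {sorted(_CODECS)}"
            )


def _zlib_compress(data: bytes, params: dict) -> bytes:
    return zlib.compress(data, level=int(params.get("level", 9)))


def _zlib_decompress(blob: bytes, params: dict) -> bytes:
    try:
        return zlib.decompress(blob)
    except zlib.error as exc:  # truncated or corrupted stream
        raise DecodeError(f"zlib stream failed to decode: {exc}") from exc


_CODECS = {
    "passthrough": (lambda data, params: data, lambda blob, params: blob),
    "zlib": (_zlib_compress, _zlib_decompress),
}


def available_compressors() -> list[str]:
    return sorted(_CODECS)


def compress(data: bytes, spec: CompressorSpec) -> str:
    """Compress bytes and expand the result to a bit string."""
    if not data:
        raise InvalidInputError("cannot compress an empty byte stream")
    encode, _ = _CODECS[spec.name]
    return bytes_to_bits(encode(bytes(data), spec.parameters))


def decompress(bits: str, spec: CompressorSpec) -> bytes:
    """Invert :func:`compress`; raises :class:`DecodeError` on corruption."""
    _, decode = _CODECS[spec.name]
    return decode(bits_to_bytes(bits), spec.parameters)
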