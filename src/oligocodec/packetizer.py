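"""Segmentation of a payload bitstream into indexed, LC-protected oligos.

Each oligo carries a fixed bit frame:

    [ block_1 | block_2 | ... | block_k | zero tail ]

where every block is an m-bit LC codeword protecting l message bits and the
zero tail fills the capacity left over when 3·L/2 (the bit capacity of an
L-nt oligo under the 3-bit→2-base mapping) is not an exact multiple of m.
The concatenated message bits of the blocks hold

    [ sequence index | payload slice | zero padding ]

so the index enjoys the same single-error protection as the payload.  A
sidecar records the payload length, geometry and a whole-payload checksum;
oligo pools are serialized as single-line FASTA with headers ``>seq_<i>``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._bitops import validate_bits
from .constrained_mapper import PAIR_CODEBOOK, bits_to_dna, dna_to_bits
from .errors import (
    IntegrityError,
    InvalidConfigError,
    InvalidInputError,
    PartialRecoveryError,
)
from .lc_codec import (
    CorrectionStatus,
    LCParams,
    codeword_length,
    extract_message,
    lc_decode,
    lc_encode,
    weighted_sum,
)

__all__ = [
    "CodecConfig",
    "Oligo",
    "Layout",
    "Sidecar",
    "ReassemblyReport",
    "build_oligos",
    "reassemble",
    "resolve_layout",
    "decode_block_nt",
    "decode_oligo_sequence",
    "write_pool_fasta",
    "read_pool_fasta",
    "write_reads_fasta",
    "read_reads_fasta",
]


@dataclass(frozen=True)
class CodecConfig:
    """User-facing codec geometry.

    oligo_length_nt : synthesized oligo length (even; 208 nt default).
    lc_message_bits : message bits l per LC block (12 default, giving m=18).
    index_bits : sequence-index width; ``None`` means the smallest width
        that can address the pool, resolved at encode time and recorded in
        the sidecar.
    """

    oligo_length_nt: int = 208
    lc_message_bits: int = 12
    index_bits: Optional[int] = None

    def __post_init__(self):
        if self.oligo_length_nt < 2 or self.oligo_length_nt % 2:
            raise InvalidConfigError(
                f"oligo_length_nt must be a positive even integer, got {self.oligo_length_nt}"
            )
        if self.lc_message_bits < 1:
            raise InvalidConfigError("lc_message_bits must be >= 1")
        if self.index_bits is not None and self.index_bits < 1:
            raise InvalidConfigError("index_bits must be >= 1 when given")


@dataclass(frozen=True)
class Oligo:
    """One synthesized sequence: its pool index plus the nucleotide string."""

    index: int
    sequence: str


@dataclass(frozen=True)
class Layout:
    """Fully resolved per-oligo bit geometry."""

    oligo_length_nt: int
    params: LCParams
    blocks: int          # LC codewords per oligo
    pad_bits: int        # zero tail bits after the last block
    index_bits: int
    payload_length_bits: int
    oligo_count: int

    @property
    def capacity_bits(self) -> int:
        return 3 * self.oligo_length_nt // 2

    @property
    def msg_bits_per_oligo(self) -> int:
        return self.blocks * self.params.l

    @property
    def payload_bits_per_oligo(self) -> int:
        return self.msg_bits_per_oligo - self.index_bits

    @property
    def block_aligned(self) -> bool:
        # pair boundaries coincide with block boundaries
        return self.params.m % 3 == 0

    @property
    def block_nt(self) -> int:
        return 2 * self.params.m // 3

    @property
    def pad_nt(self) -> int:
        return 2 * self.pad_bits // 3

    @property
    def pad_sequence(self) -> str:
        return bits_to_dna("0" * self.pad_bits) if self.pad_bits else ""


def _geometry(config: CodecConfig) -> tuple[LCParams, int, int]:
    params = codeword_length(config.lc_message_bits)
    capacity = 3 * config.oligo_length_nt // 2
    blocks = capacity // params.m
    if blocks < 1:
        raise InvalidConfigError(
            f"oligo of {config.oligo_length_nt} nt cannot hold one m={params.m} block"
        )
    return params, blocks, capacity - blocks * params.m


def resolve_layout(config: CodecConfig, payload_length_bits: int) -> Layout:
    """Fix index width and oligo count for a payload of the given bit length."""
    if payload_length_bits < 1:
        raise InvalidInputError("payload must be non-empty")
    params, blocks, pad = _geometry(config)
    msg_bits = blocks * params.l

    def count_for(width: int) -> int:
        per = msg_bits - width
        if per < 1:
            raise InvalidConfigError(
                f"index width {width} leaves no payload capacity "
                f"({msg_bits} message bits per oligo)"
            )
        return -(-payload_length_bits // per)

    if config.index_bits is not None:
        width = config.index_bits
        count = count_for(width)
        if count > (1 << width):
            raise InvalidConfigError(
                f"index_bits={width} cannot address {count} oligos"
            )
    else:
        width = 1
        while count_for(width) > (1 << width):
            width += 1
    return Layout(
        oligo_length_nt=config.oligo_length_nt,
        params=params,
        blocks=blocks,
        pad_bits=pad,
        index_bits=width,
        payload_length_bits=payload_length_bits,
        oligo_count=count_for(width),
    )


def payload_checksum(payload_bits: str) -> str:
    return hashlib.sha256(payload_bits.encode("ascii")).hexdigest()


@dataclass(frozen=True)
class Sidecar:
    """Out-of-band metadata required to invert an encoded pool."""

    layout: Layout
    checksum_sha256: str
    original_size_bytes: int = 0
    compressor: str = "passthrough"

    def to_text(self) -> str:
        lay = self.layout
        fields = {
            "format": "oligocodec/1",
            "oligo_length_nt": lay.oligo_length_nt,
            "lc_message_bits": lay.params.l,
            "index_bits": lay.index_bits,
            "oligo_count": lay.oligo_count,
            "payload_length_bits": lay.payload_length_bits,
            "original_size_bytes": self.original_size_bytes,
            "compressor": self.compressor,
            "checksum_sha256": self.checksum_sha256,
        }
        return "".join(f"{k}={v}\n" for k, v in fields.items())

    def write(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "Sidecar":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kv[key] = value
        if kv.get("format") != "oligocodec/1":
            raise InvalidInputError(f"unrecognized sidecar format: {kv.get('format')!r}")
        config = CodecConfig(
            oligo_length_nt=int(kv["oligo_length_nt"]),
            lc_message_bits=int(kv["lc_message_bits"]),
            index_bits=int(kv["index_bits"]),
        )
        layout = resolve_layout(config, int(kv["payload_length_bits"]))
        if layout.oligo_count != int(kv["oligo_count"]):
            raise InvalidInputError("sidecar oligo_count inconsistent with geometry")
        return cls(
            layout=layout,
            checksum_sha256=kv["checksum_sha256"],
            original_size_bytes=int(kv.get("original_size_bytes", 0)),
            compressor=kv.get("compressor", "passthrough"),
        )

    @classmethod
    def read(cls, path) -> "Sidecar":
        return cls.from_text(Path(path).read_text())


def build_oligos(payload: str, config: CodecConfig) -> tuple[list[Oligo], Sidecar]:
    """Encode a payload bit string into an indexed oligo pool.

    Oligo count is exactly ``ceil(payload_bits / payload_bits_per_oligo)``.
    Every emitted sequence satisfies the mapping constraints (GC 50%, runs
    <= 2, no GAATTC/GGC) by construction.
    """
    validate_bits(payload)
    layout = resolve_layout(config, len(payload))
    params = layout.params
    per = layout.payload_bits_per_oligo
    oligos = []
    for i in range(layout.oligo_count):
        chunk = payload[i * per : (i + 1) * per]
        msg = format(i, f"0{layout.index_bits}b") + chunk
        msg = msg.ljust(layout.msg_bits_per_oligo, "0")
        frame = "".join(
            lc_encode(msg[b * params.l : (b + 1) * params.l], params)
            for b in range(layout.blocks)
        )
        frame += "0" * layout.pad_bits
        seq = bits_to_dna(frame)
        assert len(seq) == layout.oligo_length_nt
        oligos.append(Oligo(index=i, sequence=seq))
    sidecar = Sidecar(layout=layout, checksum_sha256=payload_checksum(payload))
    return oligos, sidecar


# ---------------------------------------------------------------------------
# Decoding helpers (shared with the pipeline's read decoder)

def decode_block_nt(
    segment: str, params: LCParams, max_erasures: int = 2
) -> tuple[list[str], str]:
    """Decode one block-aligned nucleotide segment to LC message candidates.

    Returns ``(candidates, status)`` where candidates are distinct message
    bit strings.  With no invalid pairs this is a plain LC decode (intact or
    single-substitution correction).  Invalid pairs are treated as pair
    erasures: every assignment of valid dinucleotides to the erased slots is
    tried and the unique syndrome-0 completion (if any) is returned.
    """
    bits, erasures = dna_to_bits(segment)
    if not erasures:
        msg, report = lc_decode(bits, params)
        return ([msg] if msg is not None else []), report.status.value
    if len(erasures) > max_erasures:
        return [], "too_many_erasures"
    cands = set()
    for combo in product(PAIR_CODEBOOK.values(), repeat=len(erasures)):
        trial = list(segment)
        for pair_idx, pair in zip(erasures, combo):
            trial[2 * (pair_idx - 1) : 2 * pair_idx] = pair
        repaired_bits, _ = dna_to_bits("".join(trial))  # all pairs now valid
        if weighted_sum(repaired_bits) % params.U == 0:
            cands.add(extract_message(repaired_bits, params))
    if len(cands) == 1:
        return [cands.pop()], "erasure_corrected"
    return [], "erasure_ambiguous" if cands else "erasure_unresolved"


def decode_oligo_sequence(seq: str, layout: Layout) -> tuple[Optional[str], list[str]]:
    """Direct (length-exact) decode of one oligo to its message bits.

    Returns ``(message_bits, per_block_status)``; message is None when any
    block fails.  The zero tail is not validated — it carries no payload and
    a hit there must not discard the oligo.
    """
    if len(seq) != layout.oligo_length_nt:
        return None, ["bad_length"]
    params = layout.params
    statuses: list[str] = []
    msgs: list[str] = []
    if layout.block_aligned:
        w = layout.block_nt
        for b in range(layout.blocks):
            cands, status = decode_block_nt(seq[b * w : (b + 1) * w], params)
            statuses.append(status)
            if len(cands) != 1:
                return None, statuses
            msgs.append(cands[0])
    else:
        bits, erasures = dna_to_bits(seq)
        erased_bits = {
            k for pair in erasures for k in range(3 * (pair - 1), 3 * pair)
        }
        for b in range(layout.blocks):
            lo, hi = b * params.m, (b + 1) * params.m
            if erased_bits & set(range(lo, hi)):
                statuses.append("erasure_unresolved")
                return None, statuses
            msg, report = lc_decode(bits[lo:hi], params)
            statuses.append(report.status.value)
            if msg is None:
                return None, statuses
            msgs.append(msg)
    return "".join(msgs), statuses


@dataclass
class ReassemblyReport:
    oligo_statuses: dict[int, list[str]] = field(default_factory=dict)
    missing: list[int] = field(default_factory=list)
    conflicts: list[int] = field(default_factory=list)
    undecodable: int = 0
    checksum_ok: bool = False


def reassemble(
    oligos: Iterable[Oligo | str], sidecar: Sidecar
) -> tuple[str, ReassemblyReport]:
    """Invert :func:`build_oligos` on a possibly unordered/incomplete pool.

    Indices are recovered from sequence content (the declared ``Oligo.index``
    is ignored), each block is LC-decoded, padding is stripped and the
    payload truncated to its recorded bit length.  Missing indices raise
    :class:`PartialRecoveryError`; a checksum mismatch raises
    :class:`IntegrityError`.  Both carry the report.
    """
    layout = sidecar.layout
    report = ReassemblyReport()
    recovered: dict[int, str] = {}
    for item in oligos:
        seq = item.sequence if isinstance(item, Oligo) else str(item)
        msg, statuses = decode_oligo_sequence(seq, layout)
        if msg is None:
            report.undecodable += 1
            continue
        idx = int(msg[: layout.index_bits], 2)
        if idx >= layout.oligo_count:
            report.undecodable += 1
            continue
        report.oligo_statuses[idx] = statuses
        if idx in recovered and recovered[idx] != msg:
            report.conflicts.append(idx)
        recovered.setdefault(idx, msg)
    report.missing = sorted(set(range(layout.oligo_count)) - recovered.keys())
    if report.missing:
        raise PartialRecoveryError(report.missing, report)
    payload = "".join(
        recovered[i][layout.index_bits :] for i in range(layout.oligo_count)
    )[: layout.payload_length_bits]
    report.checksum_ok = payload_checksum(payload) == sidecar.checksum_sha256
    if not report.checksum_ok:
        raise IntegrityError(report=report)
    return payload, report


# ---------------------------------------------------------------------------
# FASTA interfaces (single-line records, uppercase ACGT)

def write_pool_fasta(oligos: Sequence[Oligo], path) -> None:
    records = [
        SeqRecord(Seq(o.sequence), id=f"seq_{o.index}", description="")
        for o in oligos
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_pool_fasta(path) -> list[Oligo]:
    oligos = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        idx = int(name.rsplit("_", 1)[1]) if "_" in name else len(oligos)
        oligos.append(Oligo(index=idx, sequence=str(rec.seq).upper()))
    return oligos


def write_reads_fasta(reads: Sequence[str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"read_{i}", description="")
        for i, seq in enumerate(reads)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def read_reads_fasta(path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")]
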