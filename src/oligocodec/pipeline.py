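"""End-to-end orchestration: file → oligo pool → (channel) → reads → file.

Encoding compresses the file, packetizes the bitstream into LC-protected,
index-carrying oligos and writes a FASTA pool plus its sidecar.  Decoding
works from raw reads whose origin is unknown: each read is independently
repaired and validated, the sequence index is recovered from the content,
and for every index one agreed candidate is selected from the valid reads
("generate many candidate decodings, keep a correct one").  A read counts
as valid only when every LC block reaches syndrome zero with all pair
erasures resolved and the read parses to exactly one message bit string.

Single-base indels shift the 3-bit/2-base framing of everything downstream,
so they are localized per LC-block span: a depth-first search assigns each
block span a length offset of −1, 0 or +1 nt, repairs offset spans by
exhaustive single-base reinsertion/deletion filtered on syndrome zero, and
requires the spans to tile the read exactly.  Reads needing more repair
than one indel per block span are discarded as invalid rather than
heuristically patched — redundant reads, not guesswork, carry the load.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Optional

from .compression import CompressorSpec, compress, decompress
from .constrained_mapper import audit, dna_to_bits
from .errors import IntegrityError, InvalidInputError, PartialRecoveryError
from .lc_codec import extract_message, weighted_sum
from .packetizer import (
    CodecConfig,
    Layout,
    Oligo,
    Sidecar,
    build_oligos,
    decode_block_nt,
    decode_oligo_sequence,
    payload_checksum,
    read_reads_fasta,
    write_pool_fasta,
)

__all__ = [
    "EncodeResult",
    "ReadOutcome",
    "DecodeReport",
    "encode_file",
    "encode_bytes",
    "decode_read",
    "decode_pool",
    "decode_file",
]

_BASES = "ACGT"
_MAX_BLOCK_CANDIDATES = 4
_MAX_SEARCH_NODES = 20_000


# ---------------------------------------------------------------------------
# Encoding

@dataclass(frozen=True)
class EncodeResult:
    oligos: tuple[Oligo, ...]
    sidecar: Sidecar
    oligo_count: int
    oligo_length_nt: int
    total_nt: int
    net_information_density: float


def encode_bytes(
    data: bytes,
    config: Optional[CodecConfig] = None,
    compressor: CompressorSpec | str = "zlib",
) -> EncodeResult:
    """Compress and packetize a byte stream into a constraint-clean pool."""
    if not data:
        raise InvalidInputError("cannot encode an empty byte stream")
    config = config or CodecConfig()
    spec = (
        compressor
        if isinstance(compressor, CompressorSpec)
        else CompressorSpec(name=compressor)
    )
    payload = compress(data, spec)
    oligos, sidecar = build_oligos(payload, config)
    for oligo in oligos:
        report = audit(oligo.sequence)
        if not report.satisfied:  # structurally impossible; fail loudly
            raise AssertionError(
                f"oligo {oligo.index} violates constraints: {report}"
            )
    sidecar = Sidecar(
        layout=sidecar.layout,
        checksum_sha256=sidecar.checksum_sha256,
        original_size_bytes=len(data),
        compressor=spec.name,
    )
    total_nt = len(oligos) * config.oligo_length_nt
    return EncodeResult(
        oligos=tuple(oligos),
        sidecar=sidecar,
        oligo_count=len(oligos),
        oligo_length_nt=config.oligo_length_nt,
        total_nt=total_nt,
        net_information_density=len(data) * 8 / total_nt,
    )


def encode_file(
    path,
    out_fasta,
    sidecar_path=None,
    config: Optional[CodecConfig] = None,
    compressor: CompressorSpec | str = "zlib",
) -> EncodeResult:
    """Encode a file on disk to a FASTA pool plus sidecar."""
    data = Path(path).read_bytes()
    result = encode_bytes(data, config=config, compressor=compressor)
    write_pool_fasta(result.oligos, out_fasta)
    sidecar_path = sidecar_path or str(out_fasta) + ".meta"
    result.sidecar.write(sidecar_path)
    return result


# ---------------------------------------------------------------------------
# Read-level decoding

def _block_repair_candidates(segment: str, layout: Layout, offset: int) -> list[str]:
    """Message candidates for a block span read with a ±1 nt length offset.

    The span is repaired by exhaustive single-base reinsertion (offset −1)
    or deletion (offset +1); a repair survives only if every pair is valid
    and the block syndrome is zero.
    """
    params = layout.params
    width = layout.block_nt
    repairs: set[str] = set()
    if offset == -1:
        for p in range(width):
            for base in _BASES:
                repairs.add(segment[:p] + base + segment[p:])
    else:
        for p in range(len(segment)):
            repairs.add(segment[:p] + segment[p + 1 :])
    cands: set[str] = set()
    for word in repairs:
        bits, erasures = dna_to_bits(word)
        if erasures or weighted_sum(bits) % params.U != 0:
            continue
        cands.add(extract_message(bits, params))
        if len(cands) > _MAX_BLOCK_CANDIDATES:
            return []
    return sorted(cands)


def _pad_repair_ok(segment: str, layout: Layout, offset: int) -> bool:
    pad = layout.pad_sequence
    if offset == -1:
        return any(
            segment[:p] + base + segment[p:] == pad
            for p in range(len(pad))
            for base in _BASES
        )
    return any(segment[:p] + segment[p + 1 :] == pad for p in range(len(segment)))


def decode_read(seq: str, layout: Layout) -> list[str]:
    """All minimum-correction message bit strings a read can parse to.

    Every tiling of the read into block spans (offsets sharing the sign of
    the net length change) is explored; each full parse is scored by the
    number of corrected spans, and only the minimum-cost parses are kept —
    under i.i.d. low-rate errors, fewer corrections is strictly more
    likely, and a spurious resynchronization must pay for every misframed
    block it patches up.  An empty list means the read is invalid; more
    than one entry means the parse is ambiguous (also treated as invalid by
    the pool decoder — an ambiguous read is never guessed at).
    """
    if not layout.block_aligned:
        msg, _ = decode_oligo_sequence(seq, layout)
        return [msg] if msg is not None else []
    segs = [layout.block_nt] * layout.blocks
    pads = [False] * layout.blocks
    if layout.pad_bits:
        segs.append(layout.pad_nt)
        pads.append(True)
    n = len(seq)
    net = n - layout.oligo_length_nt
    if abs(net) > len(segs):
        return []
    # Span offsets share the sign of the read's net length change: k deleted
    # bases are localized as k spans at −1 (symmetrically for insertions).
    # A read with compensating indels of both types parses at no framing and
    # is rejected as invalid rather than guessed at.
    offsets = (0,) if net == 0 else ((0, -1) if net < 0 else (0, 1))
    suffix = [0] * (len(segs) + 1)
    for i in range(len(segs) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + segs[i]

    results: dict[str, int] = {}
    block_cache: dict[tuple[int, int], tuple[list[str], int]] = {}
    nodes = 0
    aborted = False

    def block_options(i: int, pos: int, offset: int) -> tuple[list[str], int]:
        key = (pos, offset)
        if key not in block_cache:
            segment = seq[pos : pos + segs[i] + offset]
            if offset == 0:
                cands, status = decode_block_nt(segment, layout.params)
                cost = 0 if status == "intact" else 1
            else:
                cands = _block_repair_candidates(segment, layout, offset)
                cost = 1
            block_cache[key] = (cands, cost)
        return block_cache[key]

    def rec(i: int, pos: int, acc: str, cost: int) -> None:
        nonlocal nodes, aborted
        if aborted or len(results) > 8:
            aborted = True
            return
        nodes += 1
        if nodes > _MAX_SEARCH_NODES:
            aborted = True
            return
        if i == len(segs):
            if pos == n and (acc not in results or cost < results[acc]):
                results[acc] = cost
            return
        slack = len(segs) - i - 1
        for offset in offsets:
            take = segs[i] + offset
            end = pos + take
            if take < 0 or end > n:
                continue
            if not (suffix[i + 1] - slack <= n - end <= suffix[i + 1] + slack):
                continue
            if pads[i]:
                segment = seq[pos:end]
                if offset == 0:
                    rec(i + 1, end, acc, cost)
                elif _pad_repair_ok(segment, layout, offset):
                    rec(i + 1, end, acc, cost + 1)
                continue
            cands, step = block_options(i, pos, offset)
            for msg in cands:
                rec(i + 1, end, acc + msg, cost + step)

    rec(0, 0, "", 0)
    if aborted or not results:
        return []
    best = min(results.values())
    return sorted(msg for msg, c in results.items() if c == best)


# ---------------------------------------------------------------------------
# Pool-level decoding

@dataclass(frozen=True)
class ReadOutcome:
    valid: bool
    index: Optional[int]  # recovered sequence index (valid reads only)
    n_parses: int         # distinct full parses found (0, 1, or 2 = "many")


@dataclass
class DecodeReport:
    reads_total: int = 0
    reads_valid: int = 0
    read_outcomes: list[ReadOutcome] = field(default_factory=list)
    candidates_per_index: dict[int, int] = field(default_factory=dict)
    disagreements: list[int] = field(default_factory=list)
    missing: list[int] = field(default_factory=list)
    recovery_rate: float = 0.0
    checksum_ok: bool = False
    assemblies_tried: int = 0  # candidate payloads checked against the checksum


_MAX_ASSEMBLIES = 4096
_MAX_CANDIDATES_PER_INDEX = 3


def decode_pool(
    reads: Iterable[str], sidecar: Sidecar
) -> tuple[str, DecodeReport]:
    """Recover the payload bitstream from raw (unordered, noisy) reads.

    Raises :class:`PartialRecoveryError` when some index has no valid read
    and :class:`IntegrityError` when no assembled payload passes the
    sidecar checksum; both carry the report.  A payload is only ever
    returned with a verified checksum.

    When valid reads of one index disagree (a rare double error can alias
    a block to a wrong valid codeword), candidate payloads are assembled
    from the alternatives in vote order and the one matching the checksum
    is selected — many candidate decodings are generated and a correct one
    is kept.  The search is bounded; exhaustion raises IntegrityError.
    """
    layout = sidecar.layout
    report = DecodeReport()
    votes: dict[int, Counter] = {}
    for seq in reads:
        report.reads_total += 1
        parses = decode_read(seq, layout)
        if len(parses) != 1:
            report.read_outcomes.append(ReadOutcome(False, None, len(parses)))
            continue
        msg = parses[0]
        idx = int(msg[: layout.index_bits], 2)
        if idx >= layout.oligo_count:
            report.read_outcomes.append(ReadOutcome(False, None, 1))
            continue
        report.reads_valid += 1
        report.read_outcomes.append(ReadOutcome(True, idx, 1))
        votes.setdefault(idx, Counter())[msg] += 1

    options: dict[int, list[str]] = {}
    for idx, counter in votes.items():
        report.candidates_per_index[idx] = sum(counter.values())
        if len(counter) > 1:
            report.disagreements.append(idx)
        options[idx] = [
            msg for msg, _ in counter.most_common(_MAX_CANDIDATES_PER_INDEX)
        ]
    report.disagreements.sort()
    report.missing = sorted(set(range(layout.oligo_count)) - options.keys())
    report.recovery_rate = (
        (layout.oligo_count - len(report.missing)) / layout.oligo_count
    )
    if report.missing:
        raise PartialRecoveryError(report.missing, report)

    def assemble(choice: dict[int, str]) -> str:
        return "".join(
            choice[i][layout.index_bits :] for i in range(layout.oligo_count)
        )[: layout.payload_length_bits]

    choice = {idx: cands[0] for idx, cands in options.items()}
    contested = [idx for idx in report.disagreements if len(options[idx]) > 1]
    n_combos = 1
    for idx in contested:
        n_combos *= len(options[idx])
        if n_combos > _MAX_ASSEMBLIES:
            break
    combos: Iterable[tuple[str, ...]]
    if contested and n_combos <= _MAX_ASSEMBLIES:
        combos = product(*(options[idx] for idx in contested))
    else:
        combos = [tuple(choice[idx] for idx in contested)]
    for combo in combos:
        report.assemblies_tried += 1
        trial = dict(choice)
        trial.update(zip(contested, combo))
        payload = assemble(trial)
        if payload_checksum(payload) == sidecar.checksum_sha256:
            report.checksum_ok = True
            return payload, report
    raise IntegrityError(report=report)


def decode_file(
    reads_fasta,
    sidecar_path,
    out_path=None,
) -> tuple[bytes, DecodeReport]:
    """Decode a reads FASTA back to the original file bytes."""
    sidecar = Sidecar.read(sidecar_path)
    reads = read_reads_fasta(reads_fasta)
    payload, report = decode_pool(reads, sidecar)
    spec = CompressorSpec(name=sidecar.compressor)
    data = decompress(payload, spec)
    if sidecar.original_size_bytes and len(data) != sidecar.original_size_bytes:
        raise IntegrityError(
            f"decompressed size {len(data)} != recorded {sidecar.original_size_bytes}",
            report=report,
        )
    if out_path is not None:
        Path(out_path).write_bytes(data)
    return data, report
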