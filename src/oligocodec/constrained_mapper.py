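"""Constrained 3-bit ↔ 2-base transcoding and a sequence constraint auditor.

Each 3-bit group maps to a dinucleotide that pairs one weak base (A/T) with
one strong base (G/C), in either order:

    000→TC 001→TG 010→AC 011→AG 100→CT 101→CA 110→GT 111→GA

Because every emitted pair carries exactly one G/C, local GC content is 50%
by construction; because no valid pair repeats a base and no pair of two
identical bases is valid, homopolymer runs never exceed 2; and the motifs
GAATTC (EcoRI site) and GGC (Illumina error hotspot) cannot occur in any
concatenation of valid pairs.  The 8 dinucleotides with two weak or two
strong bases are outside the codebook; on decode they are flagged as
erasures (placeholder bits 000) so the error-correction layer above can
attempt recovery rather than aborting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._bitops import validate_bits
from .errors import AlphabetError, InvalidInputError, LengthParityError

__all__ = [
    "PAIR_CODEBOOK",
    "PAIR_INVERSE",
    "UNDESIRED_MOTIFS",
    "ConstraintReport",
    "bits_to_dna",
    "dna_to_bits",
    "audit",
]

PAIR_CODEBOOK: dict[str, str] = {
    "000": "TC",
    "001": "TG",
    "010": "AC",
    "011": "AG",
    "100": "CT",
    "101": "CA",
    "110": "GT",
    "111": "GA",
}
PAIR_INVERSE: dict[str, str] = {v: k for k, v in PAIR_CODEBOOK.items()}

#: Motifs excluded by construction and scanned for by the auditor.
UNDESIRED_MOTIFS: tuple[str, ...] = ("GAATTC", "GGC")

_ERASURE_BITS = "000"
_DNA_ALPHABET = frozenset("ACGT")


def bits_to_dna(bits: str) -> str:
    """Map a bit string (length divisible by 3) to its DNA image.

    Output length is 2/3 of the input length.  Padding to a multiple of 3
    is deliberately not done here — framing belongs to the packetizer.
    """
    validate_bits(bits)
    if len(bits) % 3:
        raise InvalidInputError(
            f"bit length {len(bits)} is not a multiple of 3"
        )
    return "".join(PAIR_CODEBOOK[bits[i : i + 3]] for i in range(0, len(bits), 3))


def dna_to_bits(dna: str) -> tuple[str, list[int]]:
    """Inverse mapping with erasure flagging.

    Returns ``(bits, erasures)`` where ``erasures`` lists the 1-based pair
    indices whose dinucleotide is outside the codebook; those pairs decode
    to placeholder bits 000.  Odd-length input raises
    :class:`LengthParityError` — the signature of an uncorrected indel,
    handled upstream.
    """
    _validate_dna(dna)
    if len(dna) % 2:
        raise LengthParityError(
            f"DNA length {len(dna)} is odd; pairs cannot be framed"
        )
    out: list[str] = []
    erasures: list[int] = []
    for i in range(0, len(dna), 2):
        pair = dna[i : i + 2]
        code = PAIR_INVERSE.get(pair)
        if code is None:
            erasures.append(i // 2 + 1)
            code = _ERASURE_BITS
        out.append(code)
    return "".join(out), erasures


@dataclass(frozen=True)
class ConstraintReport:
    """Audit of one nucleotide sequence against the synthesis constraints."""

    gc_percent: float
    max_homopolymer: int
    motif_hits: tuple[tuple[str, int], ...]  # (motif, 1-based position)
    invalid_pairs: tuple[int, ...] = field(default_factory=tuple)

    @property
    def satisfied(self) -> bool:
        return (
            self.gc_percent == 50.0
            and self.max_homopolymer <= 2
            and not self.motif_hits
        )


def _validate_dna(dna: str) -> None:
    if not _DNA_ALPHABET.issuperset(dna):
        bad = sorted(set(dna) - _DNA_ALPHABET)
        raise AlphabetError(f"non-ACGT symbols in sequence: {bad}")


def _max_run(dna: str) -> int:
    best = run = 1
    for a, b in zip(dna, dna[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def _find_motifs(dna: str, motifs=UNDESIRED_MOTIFS) -> list[tuple[str, int]]:
    hits = []
    for motif in motifs:
        start = dna.find(motif)
        while start != -1:
            hits.append((motif, start + 1))
            start = dna.find(motif, start + 1)  # overlapping occurrences
    return sorted(hits, key=lambda h: (h[1], h[0]))


def audit(dna: str, scan_reverse_complement: bool = False) -> ConstraintReport:
    """Audit GC content, homopolymer runs, undesired motifs, pair validity.

    Motif scanning is single-strand by default (encoder outputs are what is
    audited); pass ``scan_reverse_complement=True`` to scan both strands.
    Pair validity is only assessed for even-length input.
    """
    if not dna:
        raise InvalidInputError("cannot audit an empty sequence")
    _validate_dna(dna)
    gc = 100.0 * sum(1 for b in dna if b in "GC") / len(dna)
    hits = _find_motifs(dna)
    if scan_reverse_complement:
        comp = str.maketrans("ACGT", "TGCA")
        rc = dna.translate(comp)[::-1]
        hits += [(m + "(rc)", p) for m, p in _find_motifs(rc)]
    invalid: tuple[int, ...] = ()
    if len(dna) % 2 == 0:
        invalid = tuple(
            i // 2 + 1
            for i in range(0, len(dna), 2)
            if dna[i : i + 2] not in PAIR_INVERSE
        )
    return ConstraintReport(
        gc_percent=gc,
        max_homopolymer=_max_run(dna),
        motif_hits=tuple(hits),
        invalid_pairs=invalid,
    )
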