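"""Systematic Levenshtein (Varshamov–Tenengolts) single-error codec.

A length-``m`` binary word ``x`` belongs to the code L(m, r, U) when its
weighted position sum satisfies

    sum_{k=1}^{m} k * x_k  ≡  r  (mod U),

with positions counted from 1.  With ``r = 0`` and ``U = 2m`` the code
corrects any single substitution, single deletion, or single insertion per
codeword.  Encoding is systematic: message bits occupy the non-parity
positions in ascending order, and check bits placed at the power-of-two
positions plus the last position force the weighted sum to 0 mod U.

Check-bit placement follows the classic Hamming-style convention: parity
positions are {2^i : 2^i <= m} ∪ {m}.  The last position is therefore
always a check bit and the second-to-last always a message bit (for l >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from ._bitops import validate_bits
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "LCParams",
    "CorrectionStatus",
    "CorrectionReport",
    "codeword_length",
    "weighted_sum",
    "lc_encode",
    "lc_decode",
    "extract_message",
]


@dataclass(frozen=True)
class LCParams:
    """Code geometry for L(m, r, U) with systematic check-bit placement.

    Attributes
    ----------
    l : message bit count.
    m : codeword bit count (smallest m' with l = m' - ceil(log2 m') - 1).
    U : syndrome modulus, 2m by default.
    r : target residue, 0 by default.
    parity_positions : 1-based check-bit positions, ascending.
    """

    l: int
    m: int
    U: int
    r: int
    parity_positions: tuple[int, ...]

    @property
    def message_positions(self) -> tuple[int, ...]:
        return tuple(
            p for p in range(1, self.m + 1) if p not in set(self.parity_positions)
        )


def _ceil_log2(n: int) -> int:
    return (n - 1).bit_length()


def codeword_length(l: int) -> LCParams:
    """Solve the code geometry for an ``l``-bit message.

    Returns the smallest codeword length ``m`` whose check-bit overhead
    ``ceil(log2 m) + 1`` leaves exactly ``l`` message slots, together with
    the derived modulus ``U = 2m`` and the parity position set.

    >>> codeword_length(12).m
    18
    """
    if not isinstance(l, int) or l < 1:
        raise InvalidParameterError(f"message length must be an integer >= 1, got {l!r}")
    m = l + 2  # overhead is at least 2 (position 1 and the last position)
    while m - _ceil_log2(m) - 1 != l:
        m += 1
    parity = sorted({1 << i for i in range(m.bit_length()) if 1 << i <= m} | {m})
    params = LCParams(l=l, m=m, U=2 * m, r=0, parity_positions=tuple(parity))
    assert len(parity) == m - l
    return params


def weighted_sum(frame: str) -> int:
    """Σ k·x_k over the 1-based frame positions, not reduced mod U."""
    validate_bits(frame)
    return sum(k for k, bit in enumerate(frame, start=1) if bit == "1")


class CorrectionStatus(str, Enum):
    INTACT = "intact"
    SUBSTITUTION = "substitution_corrected"
    DELETION = "deletion_corrected"
    INSERTION = "insertion_corrected"
    UNCORRECTABLE = "uncorrectable"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class CorrectionReport:
    status: CorrectionStatus
    position: Optional[int]  # 1-based; set iff a *_corrected status
    syndrome: int

    def __post_init__(self):
        corrected = self.status in (
            CorrectionStatus.SUBSTITUTION,
            CorrectionStatus.DELETION,
            CorrectionStatus.INSERTION,
        )
        assert (self.position is not None) == corrected


def lc_encode(message: str, params: LCParams) -> str:
    """Encode ``l`` message bits into an ``m``-bit codeword of L(m, 0, U).

    The message bits fill the non-parity positions in ascending order; the
    needed parity contribution s = (U − weighted_sum mod U) mod U is then
    decomposed greedily, largest weight first, over the parity position
    weights {m} ∪ {powers of two ≤ m}.  The greedy decomposition is total on
    [0, U): if s ≥ m the remainder s − m ≤ m − 1 is covered by the distinct
    powers of two below m, and s < m is a plain binary expansion.
    """
    validate_bits(message)
    if len(message) != params.l:
        raise InvalidInputError(
            f"message length {len(message)} != l={params.l}"
        )
    frame = ["0"] * params.m
    for pos, bit in zip(params.message_positions, message):
        frame[pos - 1] = bit
    s = (params.U - weighted_sum("".join(frame)) % params.U) % params.U
    for w in sorted(params.parity_positions, reverse=True):
        if w <= s:
            frame[w - 1] = "1"
            s -= w
    if s != 0:
        raise AssertionError(
            f"greedy parity decomposition failed (residual {s}); "
            "violates the totality invariant"
        )
    return "".join(frame)


def extract_message(codeword: str, params: LCParams) -> str:
    """Read the message bits out of a codeword's non-parity positions."""
    if len(codeword) != params.m:
        raise InvalidInputError(f"codeword length {len(codeword)} != m={params.m}")
    return "".join(codeword[p - 1] for p in params.message_positions)


_extract_message = extract_message


def _suffix_ones(received: str) -> list[int]:
    """T[p] = number of 1-bits at 1-based positions >= p; T has len n+2."""
    n = len(received)
    T = [0] * (n + 2)
    for p in range(n, 0, -1):
        T[p] = T[p + 1] + (received[p - 1] == "1")
    return T


def lc_decode(received: str, params: LCParams):
    """Decode a received word of length m−1, m, or m+1.

    Returns ``(message, report)``; ``message`` is None when the status is
    ``uncorrectable`` or ``ambiguous``.  Substitutions are localized in
    closed form from the syndrome; single indels are found by exhaustive
    reinsertion/deletion, which at these block lengths is cheap and serves
    as its own correctness argument.  Ambiguity (zero or several distinct
    syndrome-0 candidates) is reported, never silently resolved.
    """
    validate_bits(received)
    m, U = params.m, params.U
    n = len(received)
    S = weighted_sum(received)

    if n == m:
        d = S % U
        if d == 0:
            return _extract_message(received, params), CorrectionReport(
                CorrectionStatus.INTACT, None, 0
            )
        # 0→1 flip at position p adds p to the sum (d = p ≤ m);
        # 1→0 flip at position p subtracts p (d = U − p ≥ m).
        if d <= m and received[d - 1] == "1":
            pos, new_bit = d, "0"
        elif d >= m and received[2 * m - d - 1] == "0":
            pos, new_bit = 2 * m - d, "1"
        else:
            return None, CorrectionReport(CorrectionStatus.UNCORRECTABLE, None, d)
        corrected = received[: pos - 1] + new_bit + received[pos:]
        return _extract_message(corrected, params), CorrectionReport(
            CorrectionStatus.SUBSTITUTION, pos, d
        )

    if n == m - 1:
        # Reinsert bit b at position p: positions >= p shift up by one, so
        # the new sum is S + p*b + T[p].
        T = _suffix_ones(received)
        hits = []
        for p in range(1, m + 1):
            for b in (0, 1):
                if (S + p * b + T[p]) % U == 0:
                    hits.append((p, str(b)))
        candidates = {}
        for p, b in hits:
            candidates.setdefault(received[: p - 1] + b + received[p - 1 :], (p, b))
        if len(candidates) == 1:
            (word, (p, _b)), = candidates.items()
            return _extract_message(word, params), CorrectionReport(
                CorrectionStatus.DELETION, p, S % U
            )
        return None, CorrectionReport(CorrectionStatus.AMBIGUOUS, None, S % U)

    if n == m + 1:
        # Delete position p: the removed bit drops p*x_p and positions > p
        # shift down, dropping one weight unit per 1-bit, i.e. T[p+1].
        T = _suffix_ones(received)
        candidates = {}
        for p in range(1, m + 2):
            xp = received[p - 1] == "1"
            if (S - p * xp - T[p + 1]) % U == 0:
                candidates.setdefault(received[: p - 1] + received[p:], p)
        if len(candidates) == 1:
            (word, p), = candidates.items()
            return _extract_message(word, params), CorrectionReport(
                CorrectionStatus.INSERTION, p, S % U
            )
        return None, CorrectionReport(CorrectionStatus.AMBIGUOUS, None, S % U)

    return None, CorrectionReport(CorrectionStatus.UNCORRECTABLE, None, S % U)
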