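"""Levenshtein/VT codec: geometry, weighted sums, encode/decode behavior."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from oligocodec.errors import InvalidInputError, InvalidParameterError
from oligocodec.lc_codec import (
    CorrectionStatus,
    codeword_length,
    lc_decode,
    lc_encode,
    weighted_sum,
)

WORKED_MESSAGE = "101000011110"
WORKED_CODEWORD = "101001010001111000"


def brute_force_m(l: int) -> int:
    """Independent oracle: scan m' upward for l = m' − ceil(log2 m') − 1."""
    import math

    m = 2
    while m - math.ceil(math.log2(m)) - 1 != l:
        m += 1
    return m


class TestGeometry:
    @pytest.mark.parametrize(
        "l, m, U",
        [(12, 18, 36), (1, 4, 8), (26, 32, 64)],
    )
    def test_known_geometries(self, l, m, U):
        params = codeword_length(l)
        assert (params.m, params.U, params.r) == (m, U, 0)
        assert params.m == brute_force_m(l)

    def test_parity_positions_small_code(self):
        assert codeword_length(1).parity_positions == (1, 2, 4)

    @pytest.mark.parametrize("l", range(1, 41))
    def test_parity_set_structure(self, l):
        params = codeword_length(l)
        parity = set(params.parity_positions)
        assert parity == {1 << i for i in range(params.m.bit_length()) if 1 << i <= params.m} | {params.m}
        assert len(parity) == params.m - l
        assert params.m in parity  # last position is always a check bit
        assert params.m - 1 not in parity  # second-to-last is a message bit
        assert len(params.message_positions) == l

    @pytest.mark.parametrize("l", [0, -3])
    def test_rejects_degenerate_message_length(self, l):
        with pytest.raises(InvalidParameterError):
            codeword_length(l)


class TestWeightedSum:
    def test_message_frame_sum(self):
        params = codeword_length(12)
        frame = ["0"] * params.m
        for pos, bit in zip(params.message_positions, WORKED_MESSAGE):
            frame[pos - 1] = bit
        assert weighted_sum("".join(frame)) == 63

    def test_all_zero_frame(self):
        assert weighted_sum("0" * 18) == 0

    def test_full_codeword_sum_is_zero_mod_U(self):
        assert weighted_sum(WORKED_CODEWORD) == 72
        assert 72 % 36 == 0


class TestEncode:
    def test_worked_codeword(self):
        assert lc_encode(WORKED_MESSAGE, codeword_length(12)) == WORKED_CODEWORD

    def test_zero_message_needs_zero_parity(self):
        assert lc_encode("0" * 12, codeword_length(12)) == "0" * 18

    def test_single_bit_code(self):
        assert lc_encode("1", codeword_length(1)) == "1011"

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidInputError):
            lc_encode("10", codeword_length(12))

    @given(st.integers(1, 14), st.data())
    def test_every_codeword_is_code_member(self, l, data):
        params = codeword_length(l)
        msg = data.draw(
            st.text(alphabet="01", min_size=l, max_size=l), label="message"
        )
        cw = lc_encode(msg, params)
        assert len(cw) == params.m
        assert weighted_sum(cw) % params.U == 0

    def test_greedy_decomposition_total_up_to_m_64(self):
        seen_m = set()
        for l in range(1, 58):
            params = codeword_length(l)
            if params.m in seen_m or params.m > 64:
                continue
            seen_m.add(params.m)
            weights = sorted(params.parity_positions, reverse=True)
            for s in range(params.U):
                residual = s
                for w in weights:
                    if w <= residual:
                        residual -= w
                assert residual == 0, (params.m, s)


class TestDecode:
    def test_intact_round_trip(self):
        msg, report = lc_decode(WORKED_CODEWORD, codeword_length(12))
        assert msg == WORKED_MESSAGE
        assert report.status is CorrectionStatus.INTACT
        assert report.syndrome == 0

    def test_substitution_at_position_5(self):
        corrupted = WORKED_CODEWORD[:4] + "1" + WORKED_CODEWORD[5:]
        msg, report = lc_decode(corrupted, codeword_length(12))
        assert msg == WORKED_MESSAGE
        assert report.status is CorrectionStatus.SUBSTITUTION
        assert (report.position, report.syndrome) == (5, 5)

    def test_deletion_of_position_12(self):
        corrupted = WORKED_CODEWORD[:11] + WORKED_CODEWORD[12:]
        msg, report = lc_decode(corrupted, codeword_length(12))
        assert msg == WORKED_MESSAGE
        assert report.status is CorrectionStatus.DELETION

    def test_two_deletions_out_of_scope(self):
        msg, report = lc_decode(WORKED_CODEWORD[:16], codeword_length(12))
        assert msg is None
        assert report.status is CorrectionStatus.UNCORRECTABLE

    @pytest.mark.parametrize("l", range(1, 9))
    def test_round_trip_exhaustive_small_codes(self, l):
        params = codeword_length(l)
        for value in range(1 << l):
            msg = format(value, f"0{l}b")
            out, report = lc_decode(lc_encode(msg, params), params)
            assert out == msg
            assert report.status is CorrectionStatus.INTACT

    @given(st.integers(9, 14), st.data())
    def test_round_trip_random_larger_codes(self, l, data):
        params = codeword_length(l)
        msg = data.draw(st.text(alphabet="01", min_size=l, max_size=l))
        out, report = lc_decode(lc_encode(msg, params), params)
        assert out == msg and report.status is CorrectionStatus.INTACT
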