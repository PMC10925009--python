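"""Packetizer: oligo assembly, indexing, reassembly, FASTA/sidecar round trips."""

import random

import pytest

from oligocodec.constrained_mapper import audit
from oligocodec.errors import (
    IntegrityError,
    InvalidConfigError,
    PartialRecoveryError,
)
from oligocodec.packetizer import (
    CodecConfig,
    Oligo,
    Sidecar,
    build_oligos,
    read_pool_fasta,
    reassemble,
    resolve_layout,
    write_pool_fasta,
)

SMALL = CodecConfig(oligo_length_nt=12, lc_message_bits=12, index_bits=4)


class TestConfigAndLayout:
    def test_default_geometry(self):
        layout = resolve_layout(CodecConfig(), payload_length_bits=1000)
        assert layout.capacity_bits == 312
        assert (layout.blocks, layout.pad_bits) == (17, 6)
        assert layout.msg_bits_per_oligo == 204

    def test_small_config_one_block_per_oligo(self):
        layout = resolve_layout(SMALL, payload_length_bits=64)
        assert (layout.blocks, layout.pad_bits) == (1, 0)
        assert layout.payload_bits_per_oligo == 8
        assert layout.oligo_count == 8

    def test_rejects_odd_or_tiny_oligos(self):
        with pytest.raises(InvalidConfigError):
            CodecConfig(oligo_length_nt=207)
        with pytest.raises(InvalidConfigError):
            resolve_layout(CodecConfig(oligo_length_nt=8), 100)

    def test_rejects_index_width_that_cannot_address_pool(self):
        with pytest.raises(InvalidConfigError):
            resolve_layout(CodecConfig(oligo_length_nt=12, index_bits=1), 10**4)


class TestBuildOligos:
    def test_eight_oligo_example(self, random_bits):
        oligos, sidecar = build_oligos(random_bits(64), SMALL)
        assert [o.index for o in oligos] == list(range(8))
        assert all(len(o.sequence) == 12 for o in oligos)

    def test_exact_capacity_single_oligo(self, random_bits):
        oligos, _ = build_oligos(random_bits(8), SMALL)
        assert len(oligos) == 1

    def test_count_matches_ceiling_formula(self, random_bits):
        for n_bits in (1, 7, 8, 9, 199, 3217):
            oligos, sidecar = build_oligos(random_bits(n_bits), CodecConfig())
            per = sidecar.layout.payload_bits_per_oligo
            assert len(oligos) == -(-n_bits // per)

    def test_every_oligo_satisfies_constraints(self, random_bits):
        oligos, _ = build_oligos(random_bits(2000), CodecConfig())
        for oligo in oligos:
            report = audit(oligo.sequence)
            assert report.gc_percent == 50.0
            assert report.max_homopolymer <= 2
            assert report.motif_hits == ()


class TestReassemble:
    def test_round_trip_across_lengths(self, random_bits):
        for n_bits in (1, 13, 204, 205, 4999):
            payload = random_bits(n_bits)
            oligos, sidecar = build_oligos(payload, CodecConfig())
            assert reassemble(oligos, sidecar)[0] == payload

    def test_order_invariance(self, random_bits):
        payload = random_bits(1000)
        oligos, sidecar = build_oligos(payload, CodecConfig())
        shuffled = list(oligos)
        random.Random(5).shuffle(shuffled)
        assert reassemble(shuffled, sidecar)[0] == payload

    def test_missing_oligo_names_the_gap(self, random_bits):
        oligos, sidecar = build_oligos(random_bits(1000), CodecConfig())
        with pytest.raises(PartialRecoveryError) as excinfo:
            reassemble([o for o in oligos if o.index != 3], sidecar)
        assert excinfo.value.missing == [3]

    def test_one_transversion_per_oligo_corrected(self, random_bits, rng):
        payload = random_bits(1500)
        oligos, sidecar = build_oligos(payload, CodecConfig())
        swap = {"T": "A", "A": "T", "C": "G", "G": "C"}
        mutated = []
        for o in oligos:
            i = int(rng.integers(len(o.sequence)))
            mutated.append(
                Oligo(o.index, o.sequence[:i] + swap[o.sequence[i]] + o.sequence[i + 1 :])
            )
        recovered, report = reassemble(mutated, sidecar)
        assert recovered == payload
        for statuses in report.oligo_statuses.values():
            assert any(
                s in ("substitution_corrected", "erasure_corrected") for s in statuses
            ) or all(s == "intact" for s in statuses)  # pad-region hits cost nothing

    def test_checksum_mismatch_raises_integrity_error(self, random_bits):
        oligos, sidecar = build_oligos(random_bits(500), CodecConfig())
        tampered = Sidecar(
            layout=sidecar.layout,
            checksum_sha256="0" * 64,
            original_size_bytes=sidecar.original_size_bytes,
            compressor=sidecar.compressor,
        )
        with pytest.raises(IntegrityError):
            reassemble(oligos, tampered)


class TestSerialization:
    def test_sidecar_text_round_trip(self, random_bits):
        _, sidecar = build_oligos(random_bits(777), CodecConfig())
        restored = Sidecar.from_text(sidecar.to_text())
        assert restored == sidecar

    def test_fasta_round_trip(self, random_bits, tmp_path):
        oligos, _ = build_oligos(random_bits(500), CodecConfig())
        path = tmp_path / "pool.fa"
        write_pool_fasta(oligos, path)
        text = path.read_text()
        assert text.startswith(">seq_0\n")
        assert read_pool_fasta(path) == list(oligos)
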