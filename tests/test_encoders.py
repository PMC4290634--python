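"""The six feature encodings and their invariants."""

import numpy as np
import pytest

from glycmotif.encoders import (
    ASANormalizer,
    EncoderArtifacts,
    PSIBLAST_COLUMNS,
    PSSMProfile,
    RESIDUE_ORDER,
    build_pwm,
    encode_aac,
    encode_aapc,
    encode_asa,
    encode_binary,
    encode_fragment,
    encode_pssm400,
    encode_pwm,
    fallback_profile,
    read_asa_table,
    read_pssm,
    scheme_dim,
    write_pssm,
)
from glycmotif.seqdata import AMINO_ACIDS, ProteinRecord


@pytest.mark.parametrize("scheme,dim", [
    ("binary", 220), ("aac", 20), ("aapc", 400), ("pwm", 11), ("pssm", 400), ("asa", 11),
])
def test_scheme_dimensions(scheme, dim):
    assert scheme_dim(scheme) == dim


class TestBinary:
    def test_glycine_first_alanine_second(self, frag_factory):
        frag = frag_factory("GAAAASAAAAA")
        vec = encode_binary(frag)
        assert vec[0] == 1.0 and vec[1:20].sum() == 0  # G -> slot 1 of block 0
        assert vec[21] == 1.0  # A -> slot 2 of block 1

    def test_padded_fragment_single_block(self, frag_factory):
        frag = frag_factory("-----S-----")
        vec = encode_binary(frag)
        assert vec.sum() == 1.0
        assert vec[5 * 20 + RESIDUE_ORDER.index("S")] == 1.0

    def test_one_hot_per_position(self, random_windows):
        for frag in random_windows[:20]:
            vec = encode_binary(frag).reshape(11, 20)
            assert np.all(vec.sum(axis=1) == 1)


class TestAAC:
    def test_homopolymer(self, frag_factory):
        vec = encode_aac(frag_factory("AAAAATAAAAA"))
        assert vec[RESIDUE_ORDER.index("A")] == pytest.approx(10 / 11)
        assert vec[RESIDUE_ORDER.index("T")] == pytest.approx(1 / 11)

    def test_padded_window_denominator(self, frag_factory):
        vec = encode_aac(frag_factory("-----STACK-"))
        for aa in "STACK":
            assert vec[RESIDUE_ORDER.index(aa)] == pytest.approx(0.2)

    def test_random_fragment_matches_hand_tally(self, random_windows):
        for frag in random_windows[:20]:
            vec = encode_aac(frag)
            for aa in AMINO_ACIDS:
                assert vec[RESIDUE_ORDER.index(aa)] == pytest.approx(
                    frag.window.count(aa) / 11
                )
            assert vec.sum() == pytest.approx(1.0)


class TestAAPC:
    def test_homopolymer(self, frag_factory):
        vec = encode_aapc(frag_factory("AAAAAAAAAAA".replace("A", "A")))
        a = RESIDUE_ORDER.index("A")
        assert vec[20 * a + a] == pytest.approx(1.0)

    def test_pair_count_unpadded(self, frag_factory):
        frag = frag_factory("ACDEFSTGHIK")
        # 10 adjacent ordered pairs in an unpadded 11-mer
        counts = encode_aapc(frag) * 10
        assert counts.sum() == pytest.approx(10)

    def test_pad_touching_pairs_excluded(self, frag_factory):
        vec = encode_aapc(frag_factory("-----STACK-"))
        # windows: ST TA AC CK -> 4 pairs
        s, t, a, c, k = (RESIDUE_ORDER.index(x) for x in "STACK")
        assert vec[20 * s + t] == pytest.approx(0.25)
        assert vec[20 * c + k] == pytest.approx(0.25)
        assert vec.sum() == pytest.approx(1.0)

    def test_length_400(self, random_windows):
        assert all(encode_aapc(f).shape == (400,) for f in random_windows[:5])


class TestPWM:
    def test_single_fragment_one_hot_rows(self, frag_factory):
        pwm = build_pwm([frag_factory("ACDEFSTGHIK")])
        assert np.allclose(pwm.weights.sum(axis=1), 1.0)
        assert pwm.weights[0][RESIDUE_ORDER.index("A")] == 1.0

    def test_two_fragments_half_half(self, frag_factory):
        pwm = build_pwm([frag_factory("ACDEFSTGHIK"), frag_factory("CCDEFSTGHIK")])
        assert pwm.weights[0][RESIDUE_ORDER.index("A")] == pytest.approx(0.5)
        assert pwm.weights[0][RESIDUE_ORDER.index("C")] == pytest.approx(0.5)

    def test_terminal_signal_column(self, frag_factory):
        pwm = build_pwm([frag_factory("-----STACK-")])
        assert pwm.weights[0][20] == 1.0  # pad -> terminal column

    def test_self_encoding_all_ones(self, frag_factory):
        frag = frag_factory("ACDEFSTGHIK")
        pwm = build_pwm([frag])
        assert np.allclose(encode_pwm(frag, pwm), 1.0)

    def test_unseen_symbol_zero(self, frag_factory):
        pwm = build_pwm([frag_factory("ACDEFSTGHIK")])
        vec = encode_pwm(frag_factory("WCDEFSTGHIK"), pwm)
        assert vec[0] == 0.0 and np.allclose(vec[1:], 1.0)

    def test_hand_checked_lookup(self, frag_factory):
        frags = [
            frag_factory("ACDEFSTGHIK"),
            frag_factory("AADEFSTGHIK"),
            frag_factory("CCDEFTTGHIK"),
        ]
        pwm = build_pwm(frags)
        vec = encode_pwm(frags[0], pwm)
        assert vec[0] == pytest.approx(2 / 3)   # A at offset -5
        assert vec[1] == pytest.approx(2 / 3)   # C at offset -4
        assert vec[5] == pytest.approx(2 / 3)   # S at center


class TestPSSM:
    def test_all_zero_profile_gives_half(self):
        prot = ProteinRecord("P1", "ACDEFSTGHIKA")
        profile = PSSMProfile("P1", prot.sequence, np.zeros((12, 20)))
        vec = encode_pssm400(profile, prot, 6)
        assert vec.shape == (400,)
        assert np.allclose(vec, 0.5)

    def test_outputs_strictly_between_zero_and_one(self, rng):
        seq = "ACDEFSTGHIKLMNPQRSVW"
        prot = ProteinRecord("P1", seq)
        profile = PSSMProfile("P1", seq, rng.normal(0, 5, (20, 20)))
        vec = encode_pssm400(profile, prot, 6)
        assert np.all(vec > 0) and np.all(vec < 1)

    def test_matches_naive_three_loop_reference(self, rng):
        """Vectorized transform vs an independent triple-loop recipe."""
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        seq = seq[:14] + "S" + seq[15:]
        prot = ProteinRecord("P1", seq)
        scores = rng.normal(0, 3, (30, 20))
        profile = PSSMProfile("P1", seq, scores)
        for position in (3, 15, 29):  # left edge, interior, right edge
            if prot.sequence[position - 1] not in "ST":
                continue
            got = encode_pssm400(profile, prot, position)
            ref = np.zeros((20, 20))
            for off in range(-5, 6):
                idx = position - 1 + off
                if not 0 <= idx < 30:
                    continue
                r = RESIDUE_ORDER.find(seq[idx])
                if r < 0:
                    continue
                for col_out, aa in enumerate(RESIDUE_ORDER):
                    ref[r, col_out] += scores[idx, PSIBLAST_COLUMNS.index(aa)]
            ref = 1 / (1 + np.exp(-(ref / 11)))
            assert np.allclose(got, ref.ravel(), atol=1e-12)

    def test_length_mismatch_rejected(self):
        prot = ProteinRecord("P1", "ACDEFSTGHIK")
        profile = PSSMProfile("P1", "ACDEF", np.zeros((5, 20)))
        with pytest.raises(ValueError, match="length"):
            encode_pssm400(profile, prot, 6)


class TestPSSMIO:
    def test_roundtrip(self, tmp_path, rng):
        seq = "ACDEFSTGHIK"
        profile = PSSMProfile("P1", seq, np.round(rng.normal(0, 2, (11, 20)), 2))
        path = tmp_path / "P1.pssm"
        write_pssm(profile, path)
        back = read_pssm(path, "P1")
        assert back.residues == seq
        assert np.allclose(back.scores, profile.scores)

    def test_hand_authored_fixture(self, tmp_path):
        header = "   " + " ".join(PSIBLAST_COLUMNS)
        lines = ["Last position-specific scoring matrix computed", header,
                 "  1 S " + " ".join(str(v) for v in range(20)),
                 "  2 T " + " ".join(str(-v) for v in range(20))]
        path = tmp_path / "toy.pssm"
        path.write_text("\n".join(lines) + "\n")
        profile = read_pssm(path, "toy")
        assert profile.residues == "ST"
        assert profile.scores[0, 0] == 0 and profile.scores[0, 19] == 19
        assert profile.scores[1, 5] == -5

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.pssm"
        path.write_text("   " + " ".join(PSIBLAST_COLUMNS) + "\n  1 S 1 2\n")
        with pytest.raises(ValueError, match="bad.pssm:2"):
            read_pssm(path)


class TestFallbackProfile:
    def test_zero_when_freq_equals_background(self, frag_factory):
        # every residue equally often at each offset == uniform background
        frags = [frag_factory(aa * 11) for aa in AMINO_ACIDS]
        # center is forced S/T in real fragments; use raw windows here
        scores = fallback_profile(frags, pseudocount=0.01)
        # each offset sees each residue once among 20 fragments = 1/20
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_enrichment_positive(self, frag_factory):
        frags = [frag_factory("PAAAASAAAAA")] * 10
        scores = fallback_profile(frags)
        assert scores[0, RESIDUE_ORDER.index("P")] > 1.0

    def test_hand_computed_cell(self, frag_factory):
        frags = [frag_factory("PAAAASAAAAA"), frag_factory("CAAAASAAAAA")]
        scores = fallback_profile(frags, pseudocount=0.01)
        expected = np.log2((0.5 + 0.01) / (0.05 + 0.01))
        assert scores[0, RESIDUE_ORDER.index("P")] == pytest.approx(expected)


class TestASA:
    def test_min_max_normalization(self):
        norm = ASANormalizer.fit([10.0, 20.0, 30.0])
        assert [norm.transform(v) for v in (10, 20, 30)] == [0.0, 0.5, 1.0]

    def test_constant_degenerates_to_zero(self):
        norm = ASANormalizer.fit([7.0, 7.0])
        assert norm.transform(7.0) == 0.0

    def test_window_with_pads_and_table(self, tmp_path):
        prot = ProteinRecord("P1", "STACK")
        lines = [f"P1\t{i}\t{10.0 * i}" for i in range(1, 6)]
        path = tmp_path / "asa.tsv"
        path.write_text("\n".join(lines) + "\n")
        table = read_asa_table(path)
        vec = encode_asa(table, prot, 1)
        assert vec[:5].sum() == 0.0  # pads
        assert vec[5] == pytest.approx(0.0)   # min value
        assert vec[9] == pytest.approx(1.0)   # max value

    def test_missing_positions_listed(self):
        prot = ProteinRecord("P1", "STACK")
        table = {("P1", 1): 5.0}
        with pytest.raises(ValueError, match=r"\[2, 3, 4, 5\]"):
            encode_asa(table, prot, 1)


class TestDispatcher:
    def test_all_dims(self, frag_factory, random_windows):
        frag = frag_factory("ACDEFSTGHIK")
        artifacts = EncoderArtifacts(pwm=build_pwm(random_windows[:10]))
        prot = ProteinRecord("P1", "ACDEFSTGHIK")
        artifacts.asa_table = {("P1", i): float(i) for i in range(1, 12)}
        artifacts.profiles["P1"] = PSSMProfile("P1", prot.sequence, np.zeros((11, 20)))
        for scheme in ("binary", "aac", "aapc", "pwm", "pssm", "asa"):
            vec = encode_fragment(frag, scheme, artifacts, prot)
            assert vec.shape == (scheme_dim(scheme),)

    def test_missing_artifact_named(self, frag_factory):
        with pytest.raises(ValueError, match="pssm"):
            encode_fragment(frag_factory("ACDEFSTGHIK"), "pssm", EncoderArtifacts())
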