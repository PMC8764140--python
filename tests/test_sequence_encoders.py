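"""Sequence encoders vs independent brute-force counting oracles."""

import numpy as np
import pytest

from conftest import make_segment, random_segment
from kcrsite.io_formats import AA_INDEX, AMINO_ACIDS, PSSMatrix, ProteinRecord, SiteLabel
from kcrsite.sequence_encoders import (
    EGAAC_GROUPS,
    EncodingError,
    Sample,
    build_matrix,
    encode_aac,
    encode_aapc,
    encode_binary,
    encode_cksaap,
    encode_eaac,
    encode_egaac,
    encode_pssm_window,
)
from kcrsite.windowing import extract_segment

# ---------------------------------------------------------------------------
# brute-force oracles: letter-by-letter counting, nothing shared with the
# implementation beyond the alphabet order


def oracle_aac(residues: str) -> np.ndarray:
    real = [c for c in residues if c in AA_INDEX]
    return np.array([real.count(a) for a in AMINO_ACIDS]) / len(real)


def oracle_aapc(residues: str) -> np.ndarray:
    real = [c for c in residues if c in AA_INDEX]
    out = np.zeros(400)
    for p, a in enumerate(real):
        for q, b in enumerate(real):
            if p != q:
                out[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1
    return out / (len(real) * (len(real) - 1))


def oracle_cksaap(residues: str, gaps) -> np.ndarray:
    blocks = []
    for k in sorted(set(gaps)):
        counts = np.zeros(400)
        valid = 0
        for p in range(len(residues) - (k + 1)):
            a, b = residues[p], residues[p + k + 1]
            if a in AA_INDEX and b in AA_INDEX:
                counts[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1
                valid += 1
        blocks.append(counts / valid if valid else counts)
    return np.concatenate(blocks)


def oracle_eaac(residues: str, w: int) -> np.ndarray:
    blocks = []
    for start in range(len(residues) - w + 1):
        sub = residues[start : start + w]
        real = [c for c in sub if c in AA_INDEX]
        counts = np.array([real.count(a) for a in AMINO_ACIDS], dtype=float)
        blocks.append(counts / len(real) if real else counts)
    return np.concatenate(blocks)


def oracle_egaac(residues: str, w: int) -> np.ndarray:
    blocks = []
    for start in range(len(residues) - w + 1):
        sub = residues[start : start + w]
        counts = np.zeros(5)
        real = 0
        for c in sub:
            for gi, (_, members) in enumerate(EGAAC_GROUPS):
                if c in members:
                    counts[gi] += 1
                    real += 1
        blocks.append(counts / real if real else counts)
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------


class TestAAC:
    def test_homopolymer(self):
        vec = encode_aac(make_segment("KKKKK"))
        assert vec.values[AA_INDEX["K"]] == 1.0
        assert vec.values.sum() == 1.0

    def test_pads_excluded(self):
        # two real residues among three pads: each carries weight 1/2
        vec = encode_aac(make_segment("--KA-"))
        assert vec.values[AA_INDEX["K"]] == 0.5
        assert vec.values[AA_INDEX["A"]] == 0.5

    def test_matches_hand_count_on_random_windows(self, rng):
        for _ in range(100):
            seg = random_segment(rng, 10, allow_x=True)
            np.testing.assert_allclose(
                encode_aac(seg).values, oracle_aac(seg.residues), rtol=1e-12
            )

    def test_all_pad_flanks_with_lone_k_still_encodes(self):
        vec = encode_aac(make_segment("---K---"))
        assert vec.values[AA_INDEX["K"]] == 1.0


class TestAAPC:
    def test_two_residue_cases(self):
        # "AC": ordered pairs (A,C) and (C,A), denominator 2*1
        seg = make_segment("--KAC" )  # K,A,C -> 6 ordered pairs
        np.testing.assert_allclose(
            encode_aapc(seg).values, oracle_aapc(seg.residues), rtol=1e-12
        )

    def test_sums_to_one(self, rng):
        for _ in range(20):
            seg = random_segment(rng, 7)
            assert encode_aapc(seg).values.sum() == pytest.approx(1.0)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(100):
            seg = random_segment(rng, 6, allow_x=True)
            np.testing.assert_allclose(
                encode_aapc(seg).values, oracle_aapc(seg.residues), rtol=1e-12
            )

    def test_single_residue_rejected(self):
        with pytest.raises(EncodingError):
            encode_aapc(make_segment("---K---"))


class TestBinary:
    def test_one_hot_blocks(self):
        vec = encode_binary(make_segment("-KC"))
        values = vec.values.reshape(3, 20)
        assert values[0].sum() == 0  # pad block
        assert values[1, AA_INDEX["K"]] == 1 and values[1].sum() == 1
        assert values[2, AA_INDEX["C"]] == 1 and values[2].sum() == 1

    def test_x_encodes_as_zero_block(self):
        values = encode_binary(make_segment("XKX")).values.reshape(3, 20)
        assert values[0].sum() == 0 and values[2].sum() == 0

    def test_aac_equals_mean_of_real_binary_blocks(self, rng):
        # cross-encoder invariant tying the two representations together
        for _ in range(30):
            seg = random_segment(rng, 8)
            blocks = encode_binary(seg).values.reshape(len(seg), 20)
            real = [i for i, c in enumerate(seg.residues) if c in AA_INDEX]
            np.testing.assert_allclose(
                encode_aac(seg).values, blocks[real].mean(axis=0), rtol=1e-12
            )


class TestCKSAAP:
    def test_single_gap_pair(self):
        vec = encode_cksaap(make_segment("AKA"), gaps=[1])
        assert vec.values[AA_INDEX["A"] * 20 + AA_INDEX["A"]] == 1.0
        assert vec.values.sum() == 1.0

    def test_homopolymer_any_gap(self):
        seg = make_segment("AAKAA")
        vec = encode_cksaap(seg, gaps=[1, 2, 3])
        v = vec.values.reshape(3, 400)
        for block in v:
            assert block.sum() == pytest.approx(1.0)

    def test_matches_pair_walk_oracle(self, rng):
        for _ in range(100):
            seg = random_segment(rng, 10, allow_x=True)
            np.testing.assert_allclose(
                encode_cksaap(seg, gaps=(1, 2, 3)).values,
                oracle_cksaap(seg.residues, (1, 2, 3)),
                rtol=1e-12,
            )

    def test_oversized_gap_rejected(self):
        with pytest.raises(EncodingError, match="too large"):
            encode_cksaap(make_segment("AKA"), gaps=[5])

    def test_empty_gap_set_rejected(self):
        with pytest.raises(EncodingError):
            encode_cksaap(make_segment("AKA"), gaps=[])


class TestEAACandEGAAC:
    def test_full_window_single_block(self):
        vec = encode_eaac(make_segment("KKKKK"), subwindow=5)
        assert len(vec) == 20
        assert vec.values[AA_INDEX["K"]] == 1.0

    def test_sliding_blocks(self):
        vec = encode_eaac(make_segment("AAKAA"), subwindow=3)
        blocks = vec.values.reshape(3, 20)
        for block in blocks:
            assert block[AA_INDEX["A"]] == pytest.approx(2 / 3)
            assert block[AA_INDEX["K"]] == pytest.approx(1 / 3)

    def test_egaac_group_fractions(self):
        vec = encode_egaac(make_segment("GAKDE"[:2] + "K" + "DE"), subwindow=5)
        # window GAKDE: g1={G,A}, g3={K}, g4={D,E}
        assert vec.values[0] == pytest.approx(2 / 5)
        assert vec.values[2] == pytest.approx(1 / 5)
        assert vec.values[3] == pytest.approx(2 / 5)

    def test_match_sliding_oracles(self, rng):
        for _ in range(100):
            seg = random_segment(rng, 8, allow_x=True)
            np.testing.assert_allclose(
                encode_eaac(seg, 5).values, oracle_eaac(seg.residues, 5), rtol=1e-12
            )
            np.testing.assert_allclose(
                encode_egaac(seg, 5).values, oracle_egaac(seg.residues, 5), rtol=1e-12
            )

    def test_blocks_sum_to_one_or_zero(self, rng):
        for _ in range(30):
            seg = random_segment(rng, 10, allow_x=True)
            blocks = encode_eaac(seg, 5).values.reshape(-1, 20)
            sums = blocks.sum(axis=1)
            assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))


class TestPssmWindow:
    def test_rows_match_direct_indexing(self, rng):
        protein = ProteinRecord("p", "ACDKFGHIK")
        pssm = PSSMatrix("p", rng.normal(size=(9, 20)))
        seg = extract_segment(protein, 4, n=2)
        vec = encode_pssm_window(seg, pssm).values.reshape(5, 20)
        for slot, pos in enumerate(seg.positions):
            np.testing.assert_array_equal(vec[slot], pssm.row(pos))

    def test_terminal_pads_give_zero_rows(self, rng):
        protein = ProteinRecord("p", "KAC")
        pssm = PSSMatrix("p", rng.normal(size=(3, 20)))
        vec = encode_pssm_window(extract_segment(protein, 1, n=2), pssm).values.reshape(5, 20)
        assert vec[0].sum() == 0 and vec[1].sum() == 0
        np.testing.assert_array_equal(vec[2], pssm.row(1))

    def test_protein_mismatch_rejected(self, rng):
        protein = ProteinRecord("p", "AKA")
        pssm = PSSMatrix("other", rng.normal(size=(3, 20)))
        with pytest.raises(EncodingError, match="does not match"):
            encode_pssm_window(extract_segment(protein, 2, n=1), pssm)


class TestBuildMatrix:
    def _samples(self, n=3):
        protein = ProteinRecord("p", "ACDKFGHKIWLKMNP")
        sites = [SiteLabel("p", pos, "positive" if pos == 4 else "negative")
                 for pos in (4, 8, 12)]
        return [Sample(protein=protein, site=s) for s in sites[:n]]

    def test_single_encoder_shape(self):
        matrix = build_matrix("aac", self._samples(), half_width=5)
        assert matrix.values.shape == (3, 20)
        assert matrix.labels == ("positive", "negative", "negative")

    def test_concatenation_dimensions_and_order(self):
        matrix = build_matrix(["aac", "aapc"], self._samples(), half_width=5)
        assert matrix.n_features == 420
        assert matrix.names[0].startswith("aac|")
        assert matrix.names[20].startswith("aapc|")

    def test_empty_sample_list_rejected(self):
        with pytest.raises(ValueError, match="no samples"):
            build_matrix("aac", [], half_width=5)

    def test_encoding_error_names_the_sample(self):
        samples = self._samples(1)
        with pytest.raises(EncodingError, match="p:4"):
            build_matrix("rrc", samples, half_width=5)  # no contact map attached

    def test_encoders_are_pure(self):
        a = build_matrix(["aac", "cksaap"], self._samples(), half_width=5)
        b = build_matrix(["aac", "cksaap"], self._samples(), half_width=5)
        np.testing.assert_array_equal(a.values, b.values)
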