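"""Sequence parsing, PSSM parsing, and gapped-dipeptide TFPSSM weighting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cspred.sequence_features import (
    AA_ALPHABET,
    FeatureMatrix,
    GappedDipeptide,
    PSSMProfile,
    ProteinRecord,
    average_ipp,
    build_feature_matrix,
    parse_pssm_ascii,
    position_probabilities,
    psiblast_command,
    read_fasta,
    tfpssm_vector,
    vocabulary,
    write_pssm_ascii,
)

from conftest import PSSM_IPP, PSSM_SEQUENCE, expected_log_odds_canonical


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nMKT\n")
        recs = read_fasta(p)
        assert [(r.id, r.sequence) for r in recs] == [("p1", "MKT")]

    def test_multiline_sequences_concatenated_in_order(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nMK\nTA\n>b\nGG\n")
        recs = read_fasta(p)
        assert [(r.id, r.sequence) for r in recs] == [("a", "MKTA"), ("b", "GG")]

    def test_lowercase_upper_cased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nmktg\n>b\nGG\n")
        assert read_fasta(p)[0].sequence == "MKTG"

    @pytest.mark.parametrize(
        "content,match",
        [
            (">a\n>b\nGG\n", "empty sequence"),
            (">a\nMK\n>a\nGG\n", "duplicate"),
            ("", "no FASTA records"),
        ],
    )
    def test_degenerate_inputs_rejected(self, tmp_path, content, match):
        p = tmp_path / "bad.fasta"
        p.write_text(content)
        with pytest.raises(ValueError, match=match):
            read_fasta(p)


def test_protein_record_rejects_invalid_residues():
    with pytest.raises(ValueError, match="invalid residue"):
        ProteinRecord("p", "MK1T")


# ---------------------------------------------------------------------------
# PSSM parsing
# ---------------------------------------------------------------------------

class TestParsePSSM:
    def test_blocks_extracted(self, pssm_file):
        prof = parse_pssm_ascii(pssm_file)
        assert prof.length == 3
        assert prof.sequence == PSSM_SEQUENCE
        assert prof.log_odds.shape == (3, 20)
        assert prof.percentages.shape == (3, 20)
        np.testing.assert_allclose(prof.log_odds, expected_log_odds_canonical())
        np.testing.assert_allclose(prof.percentages, 5.0)

    def test_ipp_is_second_to_last_numeric_column(self, pssm_file):
        prof = parse_pssm_ascii(pssm_file)
        np.testing.assert_allclose(prof.ipp, PSSM_IPP)
        assert prof.ipp[0] == pytest.approx(0.82)

    def test_short_row_is_error_naming_line(self, pssm_file):
        lines = pssm_file.read_text().splitlines()
        # drop one score field from the first data row
        lines[3] = " ".join(lines[3].split()[:-3])
        bad = pssm_file.parent / "trunc.pssm"
        bad.write_text("\n".join(lines))
        with pytest.raises(ValueError, match=r"trunc\.pssm:4"):
            parse_pssm_ascii(bad)

    def test_non_numeric_cell_is_error(self, pssm_file):
        text = pssm_file.read_text().replace(" 5.00", " x.00", 1)
        bad = pssm_file.parent / "alpha.pssm"
        bad.write_text(text)
        with pytest.raises(ValueError, match="non-numeric"):
            parse_pssm_ascii(bad)

    def test_empty_profile_is_error(self, tmp_path):
        p = tmp_path / "empty.pssm"
        p.write_text("Last position-specific scoring matrix\n\n")
        with pytest.raises(ValueError, match="L = 0"):
            parse_pssm_ascii(p)

    def test_round_trip_identity(self, pssm_file, tmp_path):
        prof = parse_pssm_ascii(pssm_file)
        out = tmp_path / "rt.pssm"
        write_pssm_ascii(prof, out)
        again = parse_pssm_ascii(out)
        np.testing.assert_allclose(again.log_odds, prof.log_odds)
        np.testing.assert_allclose(again.percentages, prof.percentages)
        np.testing.assert_allclose(again.ipp, prof.ipp)
        assert again.sequence == prof.sequence

    def test_average_ipp_matches_column_mean(self, pssm_file):
        prof = parse_pssm_ascii(pssm_file)
        assert average_ipp(prof) == pytest.approx(np.mean(PSSM_IPP))


@pytest.mark.parametrize(
    "ipp,expected", [([1, 1, 1], 1.0), ([0, 2], 1.0)]
)
def test_average_ipp_closed_forms(ipp, expected):
    L = len(ipp)
    prof = PSSMProfile(
        "p", "A" * L, np.zeros((L, 20)), np.full((L, 20), 5.0), np.array(ipp)
    )
    assert average_ipp(prof) == expected


# ---------------------------------------------------------------------------
# probability transforms
# ---------------------------------------------------------------------------

class TestPositionProbabilities:
    def test_sigmoid_of_zero_log_odds_is_half(self):
        prof = PSSMProfile("p", "AC", np.zeros((2, 20)), np.full((2, 20), 5.0), [0, 0])
        q = position_probabilities(prof, mode="sigmoid")
        np.testing.assert_allclose(q, 0.5)

    def test_pseudo_smoothed_one_hot(self):
        q = position_probabilities("A", mode="pseudo", smoothing=0.2)
        a = AA_ALPHABET.index("A")
        assert q[0, a] == pytest.approx(0.81)
        others = np.delete(q[0], a)
        np.testing.assert_allclose(others, 0.01)

    def test_percentage_rows_renormalized(self, pssm_file):
        prof = parse_pssm_ascii(pssm_file)
        q = position_probabilities(prof, mode="percentage")
        np.testing.assert_allclose(q.sum(axis=1), 1.0)

    def test_pseudo_ambiguity_code_uniform_with_warning(self):
        with pytest.warns(UserWarning, match="uniform"):
            q = position_probabilities("AXA", mode="pseudo", smoothing=0.2)
        np.testing.assert_allclose(q[1], 1 / 20)

    def test_sigmoid_requires_profile(self):
        with pytest.raises(TypeError):
            position_probabilities("ACD", mode="sigmoid")


# ---------------------------------------------------------------------------
# TFPSSM weights
# ---------------------------------------------------------------------------

def _tfpssm_bruteforce(q, gmax):
    """Independent double-loop summation over positions and residue pairs."""
    L = q.shape[0]
    out = {}
    for g in range(gmax + 1):
        for i1, a1 in enumerate(AA_ALPHABET):
            for i2, a2 in enumerate(AA_ALPHABET):
                w = 0.0
                for p in range(L - g - 1):
                    w += q[p, i1] * q[p + g + 1, i2]
                out[f"{a1}.g{g}.{a2}"] = w
    return out


class TestTfpssmVector:
    def test_uniform_q_closed_form(self):
        q = np.full((10, 20), 0.05)
        vec = tfpssm_vector(q, gmax=0)
        np.testing.assert_allclose(vec, 9 * 0.0025)

    def test_one_hot_pair_indicator(self):
        q = position_probabilities("AC", mode="pseudo", smoothing=0.0)
        vec = tfpssm_vector(q, gmax=0)
        vocab = vocabulary(0)
        assert vec[vocab.index("A.g0.C")] == pytest.approx(1.0)
        assert vec.sum() == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, pssm_file):
        prof = parse_pssm_ascii(pssm_file)
        q = position_probabilities(prof, mode="sigmoid")
        vec = tfpssm_vector(q, gmax=1)
        expected = _tfpssm_bruteforce(q, 1)
        vocab = vocabulary(1)
        np.testing.assert_allclose(vec, [expected[t] for t in vocab], atol=1e-12)

    def test_gaps_beyond_length_contribute_zero(self):
        q = position_probabilities("ACD", mode="pseudo", smoothing=0.1)
        vec = tfpssm_vector(q, gmax=5)
        blocks = vec.reshape(6, 400)
        assert blocks[2:].sum() == 0  # g >= 2 impossible at L = 3
        assert blocks[:2].sum() > 0

    def test_locality_in_unused_columns(self, rng):
        """Weights depend only on the two residue columns involved."""
        q = rng.random((8, 20))
        vec = tfpssm_vector(q, gmax=0)
        vocab = vocabulary(0)
        j = vocab.index("A.g0.C")
        q2 = q.copy()
        for other in set(AA_ALPHABET) - {"A", "C"}:
            q2[:, AA_ALPHABET.index(other)] = rng.random(8)
        assert tfpssm_vector(q2, gmax=0)[j] == pytest.approx(vec[j])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    L=st.integers(min_value=2, max_value=30),
    gmax=st.integers(min_value=0, max_value=6),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_tfpssm_conservation_identity(L, gmax, seed):
    """With per-position-normalized q, the gap-g block sums to L - g - 1."""
    rng = np.random.default_rng(seed)
    q = rng.random((L, 20))
    q /= q.sum(axis=1, keepdims=True)
    blocks = tfpssm_vector(q, gmax=gmax).reshape(gmax + 1, 400)
    for g in range(gmax + 1):
        np.testing.assert_allclose(blocks[g].sum(), max(L - g - 1, 0), atol=1e-9)


def test_tfpssm_nonnegative_for_unit_interval_q(rng):
    q = rng.random((12, 20))
    assert (tfpssm_vector(q, gmax=3) >= 0).all()


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

class TestFeatureMatrix:
    def test_default_vocabulary_shape(self):
        recs = [ProteinRecord(f"p{i}", "ACDEFGHIKL") for i in range(3)]
        fm = build_feature_matrix(recs, mode="pseudo")
        assert fm.shape == (3, 5600)
        assert fm.col_ids[0] == "A.g0.A"

    def test_identical_sequences_identical_rows(self):
        recs = [ProteinRecord("a", "MKTAYIAK"), ProteinRecord("b", "MKTAYIAK")]
        fm = build_feature_matrix(recs, mode="pseudo", gmax=3)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_normalized_row_sums_per_gap_block(self, rng):
        recs = [ProteinRecord("a", "MKTAYIAKQR"), ProteinRecord("b", "GGSHHLIVEA")]
        fm = build_feature_matrix(recs, mode="pseudo", gmax=4, smoothing=0.3)
        blocks = fm.values.reshape(2, 5, 400)
        for g in range(5):
            np.testing.assert_allclose(blocks[:, g, :].sum(axis=1), 10 - g - 1)

    def test_zero_vector_protein_rejected_by_name(self):
        recs = [ProteinRecord("ok", "MKTA"), ProteinRecord("tiny", "M")]
        with pytest.raises(ValueError, match="tiny"):
            build_feature_matrix(recs, mode="pseudo", gmax=3)

    def test_tsv_round_trip(self, tmp_path):
        recs = [ProteinRecord("a", "MKTAY"), ProteinRecord("b", "GGSHH")]
        fm = build_feature_matrix(recs, mode="pseudo", gmax=1)
        path = tmp_path / "f.tsv"
        fm.write_tsv(path)
        again = FeatureMatrix.read_tsv(path)
        assert again.row_ids == fm.row_ids
        assert again.col_ids == fm.col_ids
        np.testing.assert_allclose(again.values, fm.values)

    def test_single_protein_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_feature_matrix([ProteinRecord("a", "MKTA")], mode="pseudo")


def test_gapped_dipeptide_identifier_round_trip():
    gd = GappedDipeptide("A", "C", 7)
    assert gd.identifier == "A.g7.C"
    assert GappedDipeptide.from_identifier("A.g7.C") == gd


def test_vocabulary_size():
    assert len(vocabulary(13)) == 5600
    assert len(set(vocabulary(13))) == 5600


def test_psiblast_fast_preset_flags():
    cmd = psiblast_command("q.fasta", "uniref50", "out.pssm", preset="fast")
    assert "-matrix" in cmd and "BLOSUM80" in cmd
    assert cmd[cmd.index("-threshold") + 1] == "999"
    assert cmd[cmd.index("-num_iterations") + 1] == "2"
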