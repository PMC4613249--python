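"""Unit and oracle tests for the five descriptor families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afp_ensemble import (
    DEFAULT_ALPHABET,
    DEFAULT_PANEL,
    DisorderProfile,
    DomainAnnotation,
    ProteinRecord,
    PSSMProfile,
    ac_encode,
    default_property_table,
    derive_panel,
    disorder_features,
    domain_features,
    global_physchem,
    group_aac,
    group_dpc,
    pssm_group_features,
    sigmoid_scale,
)
from afp_ensemble.descriptors_physchem import PropertyTable

from .conftest import AA, random_sequence
from . import oracles

sequences = st.text(alphabet=AA, min_size=2, max_size=120)


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

class TestComposition:
    def test_alphabet_partitions_standard_residues(self):
        members = sorted(
            aa for _, grp in DEFAULT_ALPHABET.groups for aa in grp
        )
        assert members == sorted("ACDEFGHIKLMNPQRSTVWY")

    @pytest.mark.parametrize("seq,group,value", [
        ("AAAA", "non_polar", 1.0),
        ("DE", "carboxyl", 1.0),
        ("HHH", "imidazole", 1.0),
    ])
    def test_single_group_sequences(self, seq, group, value):
        vec = group_aac(ProteinRecord("p", seq))
        names = DEFAULT_ALPHABET.names
        assert vec[names.index(group)] == value
        assert vec.sum() == pytest.approx(1.0)

    def test_all_twenty_residues_hand_count(self):
        vec = group_aac(ProteinRecord("p", "ACDEFGHIKLMNPQRSTVWY"))
        expected = [0.15, 0.10, 0.05, 0.05, 0.05,
                    0.05, 0.05, 0.10, 0.10, 0.30]
        np.testing.assert_allclose(vec, expected)

    def test_dpc_single_pair(self):
        vec = group_dpc(ProteinRecord("p", "AG"))
        names = DEFAULT_ALPHABET.names
        idx = names.index("non_polar") * 10 + names.index("non_polar")
        assert vec[idx] == 1.0 and vec.sum() == 1.0

    def test_dpc_overlapping_pairs(self):
        vec = group_dpc(ProteinRecord("p", "DKD"))
        names = DEFAULT_ALPHABET.names
        ck = names.index("carboxyl") * 10 + names.index("primary_amine")
        kc = names.index("primary_amine") * 10 + names.index("carboxyl")
        assert vec[ck] == 0.5 and vec[kc] == 0.5

    def test_dpc_needs_two_residues(self):
        with pytest.raises(ValueError, match="length >= 2"):
            group_dpc(ProteinRecord("p", "A"))

    @settings(deadline=None, max_examples=40)
    @given(seq=sequences)
    def test_compositions_sum_to_one(self, seq):
        rec = ProteinRecord("p", seq)
        assert group_aac(rec).sum() == pytest.approx(1.0)
        assert group_dpc(rec).sum() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25)
    @given(seq=sequences, shuffle_seed=st.integers(0, 2**16))
    def test_aac_permutation_invariant(self, seq, shuffle_seed):
        rng = np.random.default_rng(shuffle_seed)
        shuffled = "".join(rng.permutation(list(seq)))
        np.testing.assert_allclose(
            group_aac(ProteinRecord("p", seq)),
            group_aac(ProteinRecord("p", shuffled)),
        )

    def test_dpc_is_order_sensitive(self):
        a = group_dpc(ProteinRecord("p", "DKDKDKKK"))
        b = group_dpc(ProteinRecord("p", "DDDKKKKK"))
        assert not np.allclose(a, b)

    def test_aac_invariant_under_self_concatenation(self):
        seq = "MKTWDES"
        np.testing.assert_array_equal(
            group_aac(ProteinRecord("p", seq)),
            group_aac(ProteinRecord("p", seq + seq)),
        )

    def test_matches_naive_oracle(self, rng):
        for _ in range(50):
            seq = random_sequence(rng, int(rng.integers(2, 150)))
            rec = ProteinRecord("p", seq)
            np.testing.assert_allclose(
                group_aac(rec), oracles.naive_aac(seq), rtol=1e-12
            )
            np.testing.assert_allclose(
                group_dpc(rec), oracles.naive_dpc(seq), rtol=1e-12
            )


# ---------------------------------------------------------------------------
# Physicochemistry
# ---------------------------------------------------------------------------

class TestGlobalPhyschem:
    def test_charge_counts(self):
        gp = global_physchem(ProteinRecord("p", "DDDD"))
        assert gp.n_negative == 4 and gp.n_positive == 0

    def test_poly_alanine_gravy_and_aliphatic(self):
        gp = global_physchem(ProteinRecord("p", "A" * 80))
        assert gp.gravy == pytest.approx(1.8)
        assert gp.aliphatic_index == pytest.approx(100.0)

    def test_pI_ordering_basic_vs_acidic(self):
        basic = global_physchem(ProteinRecord("p", "KKKK"))
        acidic = global_physchem(ProteinRecord("p", "DDDD"))
        assert basic.pI > acidic.pI

    def test_length_one_errors(self):
        with pytest.raises(ValueError, match="instability"):
            global_physchem(ProteinRecord("p", "A"))


def _uniform_table() -> PropertyTable:
    """A one-property table with distinct values, for closed-form checks."""
    return PropertyTable(
        names=("probe",), values=np.arange(20, dtype=float)[None, :]
    )


class TestAutoCovariance:
    def test_homopolymer_is_identically_zero(self):
        # zero up to rounding in the mean subtraction of identical floats
        rec = ProteinRecord("p", "W" * 60)
        np.testing.assert_allclose(ac_encode(rec), np.zeros(70),
                                   atol=1e-20)

    def test_two_residue_closed_form(self):
        # AC("xy", lam=1) = -((a - c)^2)/4: both deviations are +-(a-c)/2
        table = _uniform_table()
        rec = ProteinRecord("p", "AC")
        a = table.values[0, 0]   # A
        c = table.values[0, 4]   # C
        vec = ac_encode(rec, table, lambda_max=1, standardize=False)
        assert vec[0] == pytest.approx(-((a - c) ** 2) / 4)

    def test_translation_invariance(self, rng):
        seq = random_sequence(rng, 60)
        table = _uniform_table()
        shifted = PropertyTable(("probe",), table.values + 123.0)
        np.testing.assert_allclose(
            ac_encode(ProteinRecord("p", seq), table, 5, standardize=False),
            ac_encode(ProteinRecord("p", seq), shifted, 5,
                      standardize=False),
            atol=1e-9,
        )

    def test_scaling_homogeneity(self, rng):
        seq = random_sequence(rng, 60)
        table = _uniform_table()
        scaled = PropertyTable(("probe",), table.values * 3.0)
        np.testing.assert_allclose(
            9.0 * ac_encode(ProteinRecord("p", seq), table, 5,
                            standardize=False),
            ac_encode(ProteinRecord("p", seq), scaled, 5,
                      standardize=False),
            rtol=1e-10,
        )

    def test_reversal_invariance(self, rng):
        seq = random_sequence(rng, 70)
        fwd = ac_encode(ProteinRecord("p", seq))
        rev = ac_encode(ProteinRecord("p", seq[::-1]))
        np.testing.assert_allclose(fwd, rev, rtol=1e-9, atol=1e-12)

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValueError, match="too short"):
            ac_encode(ProteinRecord("shorty", "ACDEF"), lambda_max=10)

    def test_matches_bruteforce_oracle(self, rng):
        """Vectorized AC equals the naive double loop on random data."""
        table = default_property_table().standardized()
        for _ in range(100):
            seq = random_sequence(rng, int(rng.integers(50, 201)))
            rec = ProteinRecord("p", seq)
            got = ac_encode(rec, lambda_max=10)
            for j, prop in enumerate(table.names):
                prop_map = dict(zip("ARNDCQEGHILKMFPSTWYV",
                                    table.values[j]))
                expected = oracles.naive_ac(seq, prop_map, 10)
                np.testing.assert_allclose(
                    got[j * 10:(j + 1) * 10], expected,
                    rtol=1e-12, atol=1e-12,
                )


# ---------------------------------------------------------------------------
# Disorder
# ---------------------------------------------------------------------------

class TestDisorder:
    def test_all_ordered(self):
        rec = ProteinRecord("p", "MKTA")
        profile = DisorderProfile("p", np.zeros(4))
        vec = disorder_features(rec, profile)
        # mean, std, n_dis, n_ord, dis min/max, ord min/max
        np.testing.assert_array_equal(vec[:8], [0, 0, 0, 1, 0, 0, 4, 4])

    def test_hand_segmentation(self):
        rec = ProteinRecord("p", "MKTM")
        profile = DisorderProfile("p", np.array([0.9, 0.9, 0.1, 0.9]))
        vec = disorder_features(rec, profile, threshold=0.5)
        assert list(vec[2:8]) == [2, 1, 1, 2, 1, 1]
        names = "ARNDCQEGHILKMFPSTWYV"
        assert vec[8 + names.index("M")] == pytest.approx(0.9)
        assert vec[8 + names.index("K")] == pytest.approx(0.9)
        assert vec[8 + names.index("T")] == pytest.approx(0.1)
        assert vec[8 + names.index("A")] == 0.0  # absent residue sentinel

    def test_constant_scores(self):
        rec = ProteinRecord("p", "MKTAW")
        vec = disorder_features(rec, DisorderProfile("p", np.full(5, 0.7)))
        assert vec[0] == pytest.approx(0.7) and vec[1] == 0.0

    def test_boundary_score_counts_as_disordered(self):
        rec = ProteinRecord("p", "MK")
        vec = disorder_features(rec, DisorderProfile("p", np.array([0.5, 0.4])))
        assert vec[2] == 1 and vec[3] == 1

    def test_segments_partition_sequence(self, rng):
        for _ in range(20):
            length = int(rng.integers(5, 80))
            rec = ProteinRecord("p", random_sequence(rng, length))
            profile = DisorderProfile("p", rng.uniform(0, 1, length))
            vec = disorder_features(rec, profile)
            mask = profile.scores >= 0.5
            runs = 1 + int(np.sum(mask[1:] != mask[:-1]))
            assert vec[2] + vec[3] == runs

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="length"):
            disorder_features(
                ProteinRecord("p", "MKT"), DisorderProfile("p", np.zeros(4))
            )

    def test_invariant_to_non_reclassifying_threshold_change(self):
        rec = ProteinRecord("p", "MKTAW")
        profile = DisorderProfile("p", np.array([0.9, 0.8, 0.1, 0.2, 0.95]))
        np.testing.assert_array_equal(
            disorder_features(rec, profile, threshold=0.5),
            disorder_features(rec, profile, threshold=0.4),
        )


# ---------------------------------------------------------------------------
# Domains
# ---------------------------------------------------------------------------

class TestDomains:
    def test_default_panel(self):
        assert DEFAULT_PANEL.size == 15
        assert DEFAULT_PANEL.entries[0] == "IPR001304"
        assert DEFAULT_PANEL.entries[-1] == "IPR013106"

    def test_single_hit(self):
        vec = domain_features(DomainAnnotation("p", {"IPR001304"}))
        assert vec[0] == 1.0 and vec.sum() == 1.0

    def test_empty_and_off_panel(self):
        assert domain_features(DomainAnnotation("p")).sum() == 0.0
        assert domain_features(
            DomainAnnotation("p", {"IPR999999"})
        ).sum() == 0.0

    def test_missing_annotation_is_empty(self):
        assert domain_features(None).sum() == 0.0

    def test_derive_panel_count_boundary(self):
        anns = [
            DomainAnnotation(f"p{i}", {"IPR000001"} if i < 10 else
                             {"IPR000002"})
            for i in range(19)
        ]
        labels = [1] * 19
        panel = derive_panel(anns, labels, min_count=10)
        assert panel.entries == ("IPR000001",)  # 9 occurrences excluded

    def test_derive_panel_tie_order_lexicographic(self):
        anns = [
            DomainAnnotation(f"p{i}", {"IPR000002", "IPR000001"})
            for i in range(10)
        ]
        panel = derive_panel(anns, [1] * 10, min_count=10)
        assert panel.entries == ("IPR000001", "IPR000002")

    def test_derive_panel_ignores_negatives(self):
        anns = [DomainAnnotation(f"p{i}", {"IPR000001"}) for i in range(10)]
        with pytest.warns(UserWarning, match="empty"):
            panel = derive_panel(anns, [0] * 10, min_count=10)
        assert panel.entries == ()


# ---------------------------------------------------------------------------
# PSSM descriptors
# ---------------------------------------------------------------------------

class TestSigmoid:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.5),
        (2.0, 0.8807970779778823),
    ])
    def test_values(self, x, expected):
        assert sigmoid_scale(x) == pytest.approx(expected, rel=1e-14)

    @settings(deadline=None, max_examples=50)
    @given(x=st.floats(-700, 700))
    def test_symmetry_and_range(self, x):
        fx = sigmoid_scale(x)
        assert 0.0 < fx < 1.0 or abs(x) > 30
        assert fx == pytest.approx(1.0 - sigmoid_scale(-x), abs=1e-12)

    def test_monotone(self):
        xs = np.linspace(-20, 20, 201)
        assert np.all(np.diff(sigmoid_scale(xs)) > 0)


class TestPssmGroupFeatures:
    def test_all_zero_pssm_hand_values(self):
        rec = ProteinRecord("p", "DD")
        profile = PSSMProfile("p", np.zeros((2, 20)))
        vec = pssm_group_features(rec, profile).reshape(10, 10)
        names = DEFAULT_ALPHABET.names
        carboxyl = names.index("carboxyl")
        assert vec[carboxyl, carboxyl] == pytest.approx(1.0)
        assert vec[carboxyl, names.index("non_polar")] == pytest.approx(3.0)
        non_carboxyl = [i for i in range(10) if i != carboxyl]
        assert np.all(vec[non_carboxyl] == 0.0)

    def test_row_group_absent_gives_zero(self):
        rec = ProteinRecord("p", "AAA")  # non_polar only
        vec = pssm_group_features(
            rec, PSSMProfile("p", np.zeros((3, 20)))
        ).reshape(10, 10)
        assert np.all(vec[:9] == 0.0) and vec[9].sum() > 0

    def test_doubling_sequence_and_pssm_invariant(self, rng):
        seq = random_sequence(rng, 30)
        scores = rng.normal(size=(30, 20))
        one = pssm_group_features(
            ProteinRecord("p", seq), PSSMProfile("p", scores)
        )
        two = pssm_group_features(
            ProteinRecord("p", seq * 2),
            PSSMProfile("p", np.vstack([scores, scores])),
        )
        np.testing.assert_allclose(one, two, rtol=1e-12)

    def test_column_group_sums_partition(self, rng):
        seq = random_sequence(rng, 40)
        scores = rng.normal(size=(40, 20))
        vec = pssm_group_features(
            ProteinRecord("p", seq), PSSMProfile("p", scores)
        ).reshape(10, 10)
        scaled = sigmoid_scale(scores)
        groups = [oracles.group_of(aa) for aa in seq]
        for gi in range(10):
            rows = [i for i, g in enumerate(groups) if g == gi]
            expected = scaled[rows].sum() / len(seq) if rows else 0.0
            assert vec[gi].sum() == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="rows"):
            pssm_group_features(
                ProteinRecord("p", "MK"), PSSMProfile("p", np.zeros((3, 20)))
            )

    def test_matches_fourloop_oracle(self, rng):
        for _ in range(50):
            length = int(rng.integers(5, 80))
            seq = random_sequence(rng, length)
            scores = rng.normal(scale=4, size=(length, 20))
            got = pssm_group_features(
                ProteinRecord("p", seq), PSSMProfile("p", scores)
            )
            np.testing.assert_allclose(
                got, oracles.naive_pssm_group(seq, scores), rtol=1e-12
            )
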