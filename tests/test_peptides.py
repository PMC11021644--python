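"""Peptide-level feature computations against independent oracles."""

import math
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import DIWV
from hypothesis import given, settings
from hypothesis import strategies as st

from neoforest import peptides as pep
from conftest import make_record

AA20 = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA20, min_size=8, max_size=12)


class TestNonAnchorSubsequence:
    def test_positions_four_to_eight(self):
        assert pep.non_anchor_subsequence("ACDEFGHIK") == "EFGHI"
        assert pep.non_anchor_subsequence("AAAAAAAAA") == "AAAAA"

    def test_wrong_length_rejected(self):
        with pytest.raises(pep.InvalidPeptideError):
            pep.non_anchor_subsequence("ACDEFGHI")


class TestHydrophobicity:
    @pytest.mark.parametrize(
        "seq,expected", [("III", 4.5), ("RR", -4.5), ("W", -0.9)]
    )
    def test_kyte_doolittle_means(self, seq, expected):
        assert pep.hydrophobicity_mean(seq) == pytest.approx(expected)

    def test_unknown_residue_named_in_error(self):
        with pytest.raises(pep.InvalidPeptideError, match="'I'"):
            pep.hydrophobicity_mean("AIA", scale={"A": 1.0})

    @given(seqs)
    @settings(max_examples=50, deadline=None)
    def test_order_invariant(self, seq):
        shuffled = "".join(sorted(seq))
        assert pep.hydrophobicity_mean(seq) == pytest.approx(
            pep.hydrophobicity_mean(shuffled)
        )

    def test_wildcard_scores_zero(self):
        # inserted core position of an 8-mer contributes 0 to the sum
        assert pep.hydrophobicity_mean("IXI") == pytest.approx(9.0 / 3)


class TestClassProportions:
    @pytest.mark.parametrize(
        "seq,cls,expected",
        [
            ("FWY", pep.AROMATIC, 1.0),
            ("AAAA", pep.AROMATIC, 0.0),
            ("AVFWKDEST", pep.HYDRO_ARO, 3 / 9),
        ],
    )
    def test_examples(self, seq, cls, expected):
        assert pep.class_proportion(seq, cls) == pytest.approx(expected)

    @given(seqs)
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_disjoint_classes(self, seq):
        acidic = pep.class_proportion(seq, pep.ACIDIC)
        basic = pep.class_proportion(seq, pep.BASIC)
        assert 0 <= acidic <= 1 and 0 <= basic <= 1
        assert acidic + basic <= 1 + 1e-12

    def test_pure_class_extremes(self):
        assert pep.class_proportion("VIYFWLVI", pep.HYDRO_ARO) == 1.0
        assert pep.class_proportion("ADKGPSTM", pep.HYDRO_ARO) == 0.0

    def test_wildcard_excluded_from_counts(self):
        assert pep.class_proportion("FXF", pep.AROMATIC) == 1.0


def test_cys_count():
    assert pep.cys_count("CCC") == 3
    assert pep.cys_count("AAA") == 0
    assert pep.cys_count("ACDCA") == 2


class TestInstabilityIndex:
    @pytest.mark.parametrize("seq", ["GG", "WW"])
    def test_dipeptide_base_cases(self, seq):
        expected = (10 / len(seq)) * DIWV[seq[0]][seq[1]]
        assert pep.instability_index(seq) == pytest.approx(expected, abs=1e-6)

    def test_matches_dipeptide_table_oracle(self):
        rng = random.Random(0)
        for _ in range(20):
            seq = "".join(rng.choices(AA20, k=rng.randint(8, 12)))
            oracle = (10 / len(seq)) * sum(
                DIWV[a][b] for a, b in zip(seq, seq[1:])
            )
            assert pep.instability_index(seq) == pytest.approx(oracle, abs=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(pep.InvalidPeptideError):
            pep.instability_index("G")


class TestMolecularWeight:
    def test_glycine_reference_masses(self):
        assert pep.molecular_weight("G") == pytest.approx(75.07, abs=0.01)
        assert pep.molecular_weight("GG") == pytest.approx(132.12, abs=0.01)

    @given(st.text(alphabet=AA20, min_size=1, max_size=6),
           st.text(alphabet=AA20, min_size=1, max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_additivity_up_to_one_water(self, a, b):
        water = 18.0153
        assert pep.molecular_weight(a + b) == pytest.approx(
            pep.molecular_weight(a) + pep.molecular_weight(b) - water, abs=0.01
        )


class TestIsoelectricPoint:
    def test_termini_only_peptide_closed_form(self):
        # no titratable side chains: pI = mean of the two terminal pKas
        expected = 0.5 * (pep.EMBOSS_PKA["Nterm"] + pep.EMBOSS_PKA["Cterm"])
        assert pep.isoelectric_point("AAGG") == pytest.approx(expected, abs=1e-3)

    @given(seqs)
    @settings(max_examples=30, deadline=None)
    def test_charge_vanishes_at_pi(self, seq):
        pi = pep.isoelectric_point(seq)
        assert abs(pep._net_charge(seq, pi, pep.EMBOSS_PKA)) < 0.02

    def test_adding_lysine_raises_pi(self):
        assert pep.isoelectric_point("AAGGK") > pep.isoelectric_point("AAGG")


class TestDAI:
    def test_arithmetic(self):
        assert pep.dai(5.0, 0.5) == pytest.approx(4.5)
        assert pep.dai(1.3, 1.3) == 0
        assert pep.dai(0.1, 2.0) == pytest.approx(-1.9)

    def test_sign_flag_flips(self):
        assert pep.dai(5.0, 0.5, sign="mut_minus_wt") == pytest.approx(-4.5)

    def test_missing_wt_rank_gives_missing(self):
        assert pep.dai(None, 0.5) is None


class TestSelfSimilarity:
    def test_identity_is_one(self):
        assert pep.self_similarity("ALDKHGYEV", "ALDKHGYEV") == pytest.approx(
            1.0, abs=1e-12
        )

    def test_symmetric(self):
        a, b = "ALDKHGYEV", "ALDKHGYAV"
        assert pep.self_similarity(a, b) == pytest.approx(
            pep.self_similarity(b, a), abs=1e-12
        )

    def test_missing_wt_gives_missing(self):
        assert pep.self_similarity("ALDKHGYEV", None) is None

    def test_matches_exhaustive_kmer_oracle(self):
        """Brute-force enumeration of every k-mer pair, pure-python floats."""
        mat = substitution_matrices.load("BLOSUM62")

        def kernel(a, b, kmax=3):
            total = 0.0
            for k in range(1, kmax + 1):
                for i in range(len(a) - k + 1):
                    for j in range(len(b) - k + 1):
                        prod = 1.0
                        for t in range(k):
                            prod *= float(mat[a[i + t], b[j + t]])
                        total += prod
            return total

        rng = random.Random(42)
        for _ in range(50):
            a = "".join(rng.choices(AA20, k=9))
            pos = rng.randrange(9)
            b = a[:pos] + rng.choice(AA20) + a[pos + 1 :]
            expected = kernel(a, b) / math.sqrt(kernel(a, a) * kernel(b, b))
            assert pep.self_similarity(a, b) == pytest.approx(expected, abs=1e-9)


class TestMutationPosition:
    def test_core_relative_mapping(self):
        mut, wt = "ALDKHGYEV", "ALDKHGYAV"
        assert pep.mutation_position(mut, wt, 0, mut) == "P8"

    def test_outside_core(self):
        mut = "KALDKHGYEV"  # 10-mer, core starts at offset 1
        wt = "RALDKHGYEV"
        assert pep.mutation_position(mut, wt, 1, mut[1:10]) == "OC"

    def test_identical_sequences_rejected(self):
        with pytest.raises(ValueError):
            pep.mutation_position("ALDKHGYEV", "ALDKHGYEV", 0, "ALDKHGYEV")


class TestClassifyBinder:
    @pytest.mark.parametrize(
        "mut_rank,wt_rank,pos,expected",
        [
            (0.5, 0.8, "P5", "CB"),
            (0.3, 8.0, "P2", "IB"),
            (0.3, 8.0, "P5", "other"),
        ],
    )
    def test_categories(self, mut_rank, wt_rank, pos, expected):
        assert pep.classify_binder(mut_rank, wt_rank, pos) == expected


class TestComputePeptideFeatures:
    def test_complete_record_has_no_missing_slots(self):
        rec = make_record(
            rank_el_mut=0.5, rank_el_wt=1.0, rank_ba_mut=0.4, stability=2.0,
            netmhc_exp=1.0, prime=0.3, foreignness=0.1, expression=5.0,
            var_al_frac=0.4, cel_prev=0.8, prio_score=0.2,
        )
        feats = pep.compute_peptide_features(rec)
        assert all(v is not None for v in feats.values())

    def test_frameshift_lacks_wt_dependent_features(self):
        rec = make_record(wt_seq=None, rank_el_mut=0.5)
        feats = pep.compute_peptide_features(rec)
        assert feats["SelfSim"] is None and feats["DAI"] is None
        assert feats["HydroCore"] is not None

    @given(seqs)
    @settings(max_examples=30, deadline=None)
    def test_proportions_bounded_for_any_sequence(self, seq):
        start = max((len(seq) - 9) // 2, 0)
        core = seq[start : start + 9] if len(seq) >= 9 else seq[:4] + "X" + seq[4:]
        rec = pep.PeptideRecord(
            peptide_id="p", patient_id="q", mut_seq=seq, wt_seq=None,
            hla="HLA-A02:01", core9=core, core_start=start if len(seq) >= 9 else 0,
            label=0,
        )
        feats = pep.compute_peptide_features(rec)
        for name in ("PropHydroAro", "Aro", "PropAro", "PropSmall",
                     "PropAcidic", "PropBasic"):
            assert 0 <= feats[name] <= 1
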