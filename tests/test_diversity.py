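import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fae1pop import diversity, synthdata
from fae1pop.codons import standard_code
from fae1pop.errors import (
    CorrectionDomainError,
    DegenerateDataError,
    ParameterError,
)
from conftest import make_matrix
from oracles import brute_pi, brute_pi_between, brute_p_distance, oracle_pair_kaks


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "ACGA", 0.25),
            ("AC-T", "ACGT", 0.0),  # gap column excluded, 3 compared sites
            ("ACNT", "ACGA", 1 / 3),  # N excluded
        ],
    )
    def test_examples(self, a, b, expected):
        assert diversity.p_distance(a, b) == pytest.approx(expected)

    def test_no_comparable_sites(self):
        with pytest.raises(DegenerateDataError):
            diversity.p_distance("--AT", "AT--")

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        chars = np.array(list("ACGT-N"))
        for _ in range(30):
            a, b = (
                "".join(rng.choice(chars, size=40, p=[0.22, 0.22, 0.22, 0.22, 0.06, 0.06]))
                for _ in range(2)
            )
            try:
                expected = brute_p_distance(a, b)
            except ZeroDivisionError:
                continue
            assert diversity.p_distance(a, b) == pytest.approx(expected, abs=1e-12)


class TestNucleotideDiversity:
    def test_two_sequences_one_difference(self):
        m = make_matrix(["AAAAAAAAAA", "AAAAAAAAAT"])
        assert diversity.nucleotide_diversity(m).pi == pytest.approx(0.1)

    def test_three_sequence_enumeration(self):
        # pairs differ by 1, 2, 1 sites over 4: mean = 4/3/4 = 1/3
        m = make_matrix(["AAAA", "AAAT", "AATT"])
        res = diversity.nucleotide_diversity(m)
        assert res.pi == pytest.approx(1 / 3)
        assert res.n_pairs == 3 and res.n_sites_used == 4

    def test_identical_sequences_give_zero(self):
        m = make_matrix(["ACGTACGT"] * 5)
        assert diversity.nucleotide_diversity(m).pi == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        chars = np.array(list("ACGT-"))
        for _ in range(20):
            n = int(rng.integers(3, 12))
            seqs = [
                "".join(rng.choice(chars, size=60, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
                for _ in range(n)
            ]
            m = make_matrix(seqs)
            assert diversity.nucleotide_diversity(m).pi == pytest.approx(
                brute_pi(seqs), abs=1e-12
            )

    def test_subset_below_two_rejected(self, toy_matrix):
        with pytest.raises(ParameterError):
            diversity.nucleotide_diversity(toy_matrix, ["s1"])


class TestDivergence:
    def test_saturated_groups_hit_correction_domain(self):
        m = make_matrix(["AAAA", "TTTT"])
        with pytest.raises(CorrectionDomainError):
            diversity.divergence(m, ["s1"], ["s2"])

    def test_cross_pair_mean(self):
        m = make_matrix(["AAAA", "AAAT", "TTTT"])
        with pytest.raises(CorrectionDomainError):
            # pi_between = (4/4 + 3/4) / 2 = 0.875 >= 3/4
            diversity.divergence(m, ["s1", "s2"], ["s3"])
        # the uncorrected value is still well-defined; check via the oracle
        assert brute_pi_between(["AAAA", "AAAT"], ["TTTT"]) == pytest.approx(0.875)

    def test_identical_groups_have_zero_divergence(self):
        m = make_matrix(["ACGT", "ACGT"])
        res = diversity.divergence(m, ["s1"], ["s2"])
        assert res.pi_between == 0.0 and res.dxy == 0.0

    def test_symmetric_in_group_order(self, study_bundle):
        m = study_bundle.matrix
        ids = m.ids
        a, b = ids[:5], ids[5:9]
        r1 = diversity.divergence(m, a, b)
        r2 = diversity.divergence(m, b, a)
        assert r1.pi_between == r2.pi_between and r1.dxy == r2.dxy

    def test_dxy_at_least_pi_between(self, study_bundle):
        m = study_bundle.matrix
        r = diversity.divergence(m, m.ids[:6], m.ids[30:36])
        assert r.dxy >= r.pi_between >= 0


class TestJukesCantor:
    def test_zero_maps_to_zero(self):
        assert diversity.jukes_cantor(0.0) == 0.0

    @given(st.floats(min_value=0.0, max_value=0.745))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_anticonservative(self, p):
        d = diversity.jukes_cantor(p)
        assert d >= p
        assert diversity.jukes_cantor(p + 0.004) > d

    def test_domain_boundary(self):
        with pytest.raises(CorrectionDomainError):
            diversity.jukes_cantor(0.75)


class TestKaKs:
    def test_identical_sequences_undefined_ratio(self):
        m = make_matrix(["ATGGCTTGC"] * 3)
        res = diversity.ka_ks(m)
        assert res.Ka == 0.0 and res.Ks == 0.0 and res.ratio is None

    def test_glycine_pair_example(self):
        # GGA GGG GGA vs GGA GGG GGG: one fourfold third-position change
        m = make_matrix(["GGAGGGGGA", "GGAGGGGGG"])
        res = diversity.ka_ks(m)
        assert res.S_sites == pytest.approx(3.0)
        assert res.N_sites == pytest.approx(6.0)
        assert res.pS == pytest.approx(1 / 3)
        assert res.Ka == 0.0
        assert res.Ks == pytest.approx(0.4408, abs=2e-4)

    def test_site_conservation(self, study_bundle):
        m = study_bundle.matrix
        res = diversity.ka_ks(m, m.ids[:6])
        assert res.N_sites + res.S_sites == pytest.approx(3 * res.n_codons_used)

    def test_matches_path_enumeration_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        code = standard_code()
        sense = [c for c in code.sense_codons]
        for _ in range(50):
            n_codons = int(rng.integers(5, 20))
            base = [sense[int(i)] for i in rng.integers(len(sense), size=n_codons)]
            other = list(base)
            # perturb a few codons, keeping them sense
            for _ in range(int(rng.integers(1, 5))):
                k = int(rng.integers(n_codons))
                other[k] = sense[int(rng.integers(len(sense)))]
            a, b = "".join(base), "".join(other)
            ps, pn, S, N, sd, nd = oracle_pair_kaks(a, b)
            m = make_matrix([a, b])
            res = diversity.ka_ks(m)
            assert res.S_sites == pytest.approx(S, abs=1e-9)
            assert res.pS == pytest.approx(ps, abs=1e-9)
            assert res.pN == pytest.approx(pn, abs=1e-9)

    def test_stop_codon_rejected(self):
        m = make_matrix(["ATGTGAAAA", "ATGTGGAAA"])
        with pytest.raises(Exception, match="stop"):
            diversity.ka_ks(m)


class TestSlidingWindows:
    def _silent_rich_matrix(self, rng, n_records=6, n_codons=120, p_change=0.15):
        # fourfold codons only: every third position is silent by construction
        fourfold = ["GGA", "GCA", "CCA", "CGA", "CTA", "ACA", "GTA", "TCA"]
        base = [fourfold[int(i)] for i in rng.integers(len(fourfold), size=n_codons)]
        seqs = []
        for _ in range(n_records):
            codons = []
            for c in base:
                if rng.random() < p_change:
                    codons.append(c[:2] + "ACGT"[int(rng.integers(4))])
                else:
                    codons.append(c)
            seqs.append("".join(codons))
        return make_matrix(seqs)

    def test_window_placement_arithmetic(self):
        # 85 silent columns, size 25, step 10 -> starts at ordinals 1..61: 7 windows
        rng = np.random.default_rng(1)
        m = self._silent_rich_matrix(rng, n_codons=85, p_change=0.0)
        prof = diversity.sliding_window_silent(m, window_size=25, step=10)
        assert prof.n_silent_columns == 85
        assert list(prof.table["first_silent_ordinal"]) == [1, 11, 21, 31, 41, 51, 61]

    def test_identical_sequences_flat_zero(self):
        rng = np.random.default_rng(2)
        m = self._silent_rich_matrix(rng, p_change=0.0)
        prof = diversity.sliding_window_silent(m)
        assert (prof.table["pi_silent"] == 0).all()

    def test_uniform_diversity_profile_is_flat(self):
        rng = np.random.default_rng(3)
        m = self._silent_rich_matrix(rng, n_records=12, n_codons=200, p_change=0.2)
        prof = diversity.sliding_window_silent(m)
        overall = prof.table["pi_silent"].mean()
        assert prof.table["pi_silent"].std() < overall  # no systematic structure
        assert (prof.table["pi_silent"] - overall).abs().max() < 3 * overall ** 0.5 / 5

    def test_too_few_silent_columns(self):
        m = make_matrix(["ATGATG", "ATGATG"])
        with pytest.raises(DegenerateDataError):
            diversity.sliding_window_silent(m, window_size=25)

    def test_each_window_spans_exactly_window_size_silent_columns(self, study_bundle):
        prof = diversity.sliding_window_silent(study_bundle.matrix)
        from fae1pop import sites

        cls = sites.classify_sites(study_bundle.matrix)
        silent = cls.silent_columns()
        for _, row in prof.table.iterrows():
            inside = [
                c for c in silent if row["col_start"] <= c <= row["col_end"]
            ]
            assert len(inside) == prof.window_size
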