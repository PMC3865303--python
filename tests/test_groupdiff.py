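import numpy as np
import pytest

from fae1pop import diversity, groupdiff
from fae1pop.errors import MetadataError, ParameterError
from conftest import make_matrix
from oracles import brute_diagnostic, brute_fixed


def scheme_of(**groups):
    return groupdiff.GroupingScheme({k: set(v) for k, v in groups.items()})


def random_grouped_matrix(rng, n_per_group=4, n_groups=4, n_columns=40, p_gap=0.05):
    chars = np.array(list("ACGT-"))
    probs = [(1 - p_gap) / 4] * 4 + [p_gap]
    seqs, ids, groups = [], [], {}
    for g in range(n_groups):
        label = f"G{g}"
        groups[label] = set()
        for i in range(n_per_group):
            rid = f"{label}_{i}"
            seqs.append("".join(rng.choice(chars, size=n_columns, p=probs)))
            ids.append(rid)
            groups[label].add(rid)
    return make_matrix(seqs, ids=ids), groupdiff.GroupingScheme(groups)


class TestGroupingScheme:
    def test_overlapping_groups_rejected(self):
        with pytest.raises(MetadataError):
            scheme_of(a={"x", "y"}, b={"y"})

    def test_unknown_ids_caught_on_validation(self, toy_matrix):
        s = scheme_of(a={"s1"}, b={"ghost"})
        with pytest.raises(MetadataError, match="ghost"):
            s.validate_against(toy_matrix)

    def test_from_metadata_skips_unlabelled(self):
        m = make_matrix(["AAAA", "CCCC", "GGGG"], clades=["I", "II", ""])
        s = groupdiff.GroupingScheme.from_metadata(m)
        assert s.groups == {"I": {"s1"}, "II": {"s2"}}


class TestDiagnosticSites:
    def test_unique_uniform_state_is_diagnostic(self):
        m = make_matrix(["ACAA", "ACAA", "ATAA", "AGAA"])
        s = scheme_of(X={"s1", "s2"}, Y={"s3"}, Z={"s4"})
        sites_found = groupdiff.diagnostic_sites(m, s, "X")
        assert [(d.column, d.state) for d in sites_found] == [(2, "C")]

    def test_state_shared_with_nonmember_disqualifies(self):
        m = make_matrix(["ACAA", "ACAA", "ACAA", "AGAA"])
        s = scheme_of(X={"s1", "s2"}, Y={"s3"}, Z={"s4"})
        assert groupdiff.diagnostic_sites(m, s, "X") == []

    def test_gap_members_ignored_but_group_needs_one_assessable(self):
        m = make_matrix(["AC", "A-", "AT"])
        s = scheme_of(X={"s1", "s2"}, Y={"s3"})
        found = groupdiff.diagnostic_sites(m, s, "X")
        assert [(d.column, d.state) for d in found] == [(2, "C")]

    def test_matches_exhaustive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            m, s = random_grouped_matrix(rng)
            cols = {r.record_id: r.sequence for r in m.records}
            for label in s.labels:
                got = [
                    (d.column, d.state)
                    for d in groupdiff.diagnostic_sites(m, s, label)
                ]
                expected = brute_diagnostic(
                    cols, sorted(s.members(label)),
                    sorted(s.grouped_ids() - s.members(label)), m.n_columns,
                )
                assert got == expected

    def test_every_output_revalidates_against_definition(self, study_bundle):
        m = study_bundle.matrix
        s = groupdiff.GroupingScheme.from_metadata(m)
        for label in s.labels:
            for d in groupdiff.diagnostic_sites(m, s, label):
                col = d.column - 1
                member_states = {
                    m.record(i).sequence[col]
                    for i in s.members(label)
                    if m.record(i).sequence[col] not in "-N"
                }
                other_states = {
                    m.record(i).sequence[col]
                    for i in s.grouped_ids() - s.members(label)
                    if m.record(i).sequence[col] not in "-N"
                }
                assert member_states == {d.state}
                assert d.state not in other_states


class TestFixedDifferences:
    def test_clear_frequency_contrast_reported(self):
        # column 1: A fixed in group1 (1.0), 0.0 in group2
        m = make_matrix(["ATT", "ATT", "GTT", "GTT", "GTT"])
        fixed = groupdiff.fixed_differences(m, ["s1", "s2"], ["s3", "s4", "s5"])
        states = {(f.column, f.state) for f in fixed}
        assert (1, "A") in states and (1, "G") in states

    def test_boundary_frequency_is_strict(self):
        # A at exactly 0.70 in group a (7/10), 0.0 in group b -> not reported
        seqs = ["A"] * 7 + ["C"] * 3 + ["G"] * 3
        m = make_matrix([s * 2 for s in seqs])
        a = [f"s{i}" for i in range(1, 11)]
        b = [f"s{i}" for i in range(11, 14)]
        fixed = groupdiff.fixed_differences(m, a, b)
        assert all(f.state != "A" for f in fixed)

    def test_strict_thresholds_mean_exact_fixation(self):
        m = make_matrix(["AT", "AT", "GT", "AT"])
        # group a all A; group b carries one A (freq 0.5 > 0)
        fixed = groupdiff.fixed_differences(
            m, ["s1", "s2"], ["s3", "s4"], f_high=1.0, f_low=0.0
        )
        assert fixed == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        m, s = random_grouped_matrix(rng, n_per_group=6, n_groups=2, n_columns=60)
        a, b = sorted(s.members("G0")), sorted(s.members("G1"))
        loose = {
            (f.column, f.state)
            for f in groupdiff.fixed_differences(m, a, b, f_high=0.6, f_low=0.4)
        }
        tight = {
            (f.column, f.state)
            for f in groupdiff.fixed_differences(m, a, b, f_high=0.8, f_low=0.2)
        }
        assert tight <= loose

    def test_column_set_symmetric_in_group_order(self):
        rng = np.random.default_rng(29)
        m, s = random_grouped_matrix(rng, n_per_group=5, n_groups=2)
        a, b = sorted(s.members("G0")), sorted(s.members("G1"))
        ab = {(f.column, f.state) for f in groupdiff.fixed_differences(m, a, b)}
        ba = {(f.column, f.state) for f in groupdiff.fixed_differences(m, b, a)}
        assert ab == ba

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(15):
            m, s = random_grouped_matrix(rng, n_per_group=5, n_groups=2, n_columns=50)
            a, b = sorted(s.members("G0")), sorted(s.members("G1"))
            cols = {r.record_id: r.sequence for r in m.records}
            got = [(f.column, f.state) for f in groupdiff.fixed_differences(m, a, b)]
            assert got == brute_fixed(cols, a, b, 0.70, 0.30, m.n_columns)

    def test_bad_thresholds(self, toy_matrix):
        with pytest.raises(ParameterError):
            groupdiff.fixed_differences(
                toy_matrix, ["s1", "s2"], ["s3", "s4"], f_high=0.3, f_low=0.7
            )


class TestGroupReport:
    def test_shape_and_symmetry(self, study_bundle):
        m = study_bundle.matrix
        s = groupdiff.GroupingScheme.from_metadata(m)
        rep = groupdiff.group_report(m, s)
        assert (rep.pi_between.values.T == rep.pi_between.values).all() or (
            np.allclose(
                rep.pi_between.fillna(0).values,
                rep.pi_between.fillna(0).values.T,
            )
        )
        # diagonal equals a direct per-group pi computation
        for label in s.labels:
            members = sorted(s.members(label))
            if len(members) >= 2:
                direct = diversity.nucleotide_diversity(m, members).pi
                assert rep.pi_within[label] == pytest.approx(direct)

    def test_identical_groups_between_equals_pooled_pi(self):
        seqs = ["AAAA", "AAAT", "AAAA", "AAAT"]
        m = make_matrix(seqs, clades=["a", "a", "b", "b"])
        s = groupdiff.GroupingScheme.from_metadata(m)
        rep = groupdiff.group_report(m, s)
        pooled = diversity.nucleotide_diversity(m).pi
        # two identical groups: the cross-group mean (self-pairs included,
        # counting 0) equals pooled mean-pairwise pi scaled by (n-1)/n
        n = len(m)
        assert rep.pi_between.loc["a", "b"] == pytest.approx(pooled * (n - 1) / n)
        assert rep.pi_between.loc["a", "b"] == pytest.approx(0.125)

    def test_polymorphic_percentages_recomputable(self, study_bundle):
        from fae1pop import sites
        from fae1pop.seqio import AlignmentMatrix

        m = study_bundle.matrix
        s = groupdiff.GroupingScheme.from_metadata(m)
        rep = groupdiff.group_report(m, s)
        for _, row in rep.polymorphic.iterrows():
            members = sorted(s.members(row["group"]))
            if len(members) < 2:
                continue
            sub = AlignmentMatrix(m.subset(members), coding_offset=m.coding_offset)
            count = sites.classify_sites(sub).variable_count
            assert row["polymorphic_sites"] == count
            assert row["percent"] == sites.percent_of_matrix(count, m.n_columns)
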