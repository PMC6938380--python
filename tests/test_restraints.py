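import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from homodel.io_formats import JoinedAlignment, PairwiseAlignment
from homodel.restraints import (
    DistanceRestraint,
    RestraintEntry,
    RestraintSet,
    build_hddrs,
    gaussian_objective_term,
    mixture_density,
    template_weights,
)
from homodel.synthetic_data import ToySpec, build_native, generate_pair


class TestGaussianObjectiveTerm:
    def test_zero_deviation(self):
        assert gaussian_objective_term(4.0, 4.0, 1.0) == pytest.approx(
            math.log(math.sqrt(2 * math.pi)), abs=1e-9
        )

    def test_one_sigma_adds_exactly_half(self):
        base = gaussian_objective_term(4.0, 4.0, 1.0)
        assert gaussian_objective_term(5.0, 4.0, 1.0) == pytest.approx(base + 0.5, abs=1e-12)

    def test_matches_negative_log_normal_density(self):
        # Oracle: numerically evaluated normal pdf.
        expected = -math.log(norm.pdf(5.0, loc=4.0, scale=0.5))
        assert gaussian_objective_term(5.0, 4.0, 0.5) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(2.225791, abs=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_objective_term(5.0, 4.0, 0.0)

    @given(
        d_m=st.floats(0.5, 20.0),
        d_t=st.floats(0.5, 20.0),
        sigma=st.floats(0.01, 5.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_harmonic_identity(self, d_m, d_t, sigma):
        lhs = gaussian_objective_term(d_m, d_t, sigma) - gaussian_objective_term(d_t, d_t, sigma)
        assert lhs == pytest.approx((d_m - d_t) ** 2 / (2 * sigma**2), rel=1e-9, abs=1e-9)


class TestMixtureDensity:
    def test_single_component_equals_gaussian(self):
        d = mixture_density(4.7, [(1.0, 4.0, 0.8)])
        assert d == pytest.approx(norm.pdf(4.7, 4.0, 0.8), abs=1e-12)

    def test_equidistant_equal_sigma_symmetry(self):
        d = mixture_density(5.0, [(0.7, 4.0, 1.0), (0.3, 6.0, 1.0)])
        assert d == pytest.approx(norm.pdf(1.0), abs=1e-12)
        assert d == pytest.approx(0.241971, abs=1e-6)

    def test_against_direct_weighted_sum(self):
        # Oracle: direct weighted sum of two normal densities.
        expected = 0.7 * norm.pdf(4.5, 4.0, 0.5) + 0.3 * norm.pdf(4.5, 6.0, 1.0)
        d = mixture_density(4.5, [(0.7, 4.0, 0.5), (0.3, 6.0, 1.0)])
        assert d == pytest.approx(expected, abs=1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            mixture_density(4.0, [(0.0, 4.0, 1.0), (0.0, 5.0, 1.0)])

    def test_neg_log_mixture_two_sided_bounds(self):
        # Since max_u(w_u N_u) <= mixture <= max_u N_u:
        #   min_u obj_u <= -ln(mixture) <= min_u(obj_u - ln w_u),
        # with equality on both sides when one weight is 1.
        entries = [(0.6, 4.0, 0.5), (0.4, 5.5, 1.2)]
        for d_m in (3.0, 4.2, 5.0, 6.5):
            lhs = -math.log(mixture_density(d_m, entries))
            singles = [gaussian_objective_term(d_m, dt, s) for _, dt, s in entries]
            upper = min(s - math.log(w) for (w, _, _), s in zip(entries, singles))
            assert min(singles) - 1e-12 <= lhs <= upper + 1e-12

    def test_equality_when_one_weight_is_one(self):
        lhs = -math.log(mixture_density(4.6, [(1.0, 4.0, 0.5)]))
        assert lhs == pytest.approx(gaussian_objective_term(4.6, 4.0, 0.5), abs=1e-12)


class TestTemplateWeights:
    def test_only_lowest(self):
        assert template_weights("only_lowest", sigmas=[0.3, 0.7]) == [1.0, 0.0]

    def test_uniform(self):
        assert template_weights("uniform", n_templates=4) == [0.25] * 4

    def test_only_lowest_tie_breaks_to_first(self):
        assert template_weights("only_lowest", sigmas=[0.4, 0.4]) == [1.0, 0.0]

    def test_similarity_normalized_and_floored(self):
        w = template_weights("similarity", similarities=[0.9, 0.0])
        assert sum(w) == pytest.approx(1.0)
        assert w[1] == pytest.approx(0.05 / 0.95)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            template_weights("uniform", n_templates=0)


class TestBuildHddrs:
    def test_three_residue_identity_pair_count(self):
        native = build_native(10, "helix", "G" * 10, "t")
        # Restrict to the first three residues by using a 3-residue pair.
        tgt = build_native(3, "helix", "GGG", "tgt")
        pw = PairwiseAlignment("tgt", "tpl", "GGG", "GGG")
        aln = JoinedAlignment("tgt", (pw,))
        tpl = build_native(3, "helix", "GGG", "tpl")
        rset = build_hddrs(aln, [tpl], tgt, min_separation={"CA-CA": 1, "N-O": 1})
        cacas = rset.by_group("CA-CA")
        assert len(cacas) == 3  # pairs 1-2, 1-3, 2-3

    def test_coverage_logic_multi_template(self, multi_pair):
        native, templates, aln = multi_pair
        rset = build_hddrs(aln, templates, native)
        counts = {r.n_templates for r in rset}
        assert counts >= {3}  # identity-aligned regions see every template

    def test_partial_coverage_gives_fewer_entries(self):
        tgt = build_native(10, "helix", "LLLLLLLLLL", "tgt")
        t1 = build_native(6, "helix", "LLLLLL", "t1")
        t2 = build_native(6, "helix", "LLLLLL", "t2")
        pw1 = PairwiseAlignment("tgt", "t1", "LLLLLLLLLL", "LLLLLL----")
        pw2 = PairwiseAlignment("tgt", "t2", "LLLLLLLLLL", "----LLLLLL")
        aln = JoinedAlignment("tgt", (pw1, pw2))
        rset = build_hddrs(aln, [t1, t2], tgt)
        for r in rset.by_group("CA-CA"):
            i, j = r.atom_i[0], r.atom_j[0]
            if j <= 4:
                assert [e.template_index for e in r.entries] == [1]
            elif i >= 7:
                assert [e.template_index for e in r.entries] == [2]

    def test_distance_ceiling_excludes_pairs(self, helix_pair):
        native, templates, aln = helix_pair
        tight = build_hddrs(aln, templates, native, cutoffs={"CA-CA": 6.0})
        default = build_hddrs(aln, templates, native)
        assert len(tight.by_group("CA-CA")) < len(default.by_group("CA-CA"))
        for r in tight.by_group("CA-CA"):
            assert all(e.d_t <= 6.0 for e in r.entries)

    def test_template_order_invariance(self, multi_pair):
        native, templates, aln = multi_pair
        fwd = build_hddrs(aln, templates, native)
        rev_aln = JoinedAlignment(aln.target_id, tuple(reversed(aln.pairwise)))
        rev = build_hddrs(rev_aln, list(reversed(templates)), native)
        u_max = aln.n_templates + 1

        def canonical(rset, relabel):
            out = {}
            for r in rset:
                entries = sorted(
                    (relabel(e.template_index), round(e.d_t, 9), round(e.sigma, 9))
                    for e in r.entries
                )
                out[(r.group, r.atom_i, r.atom_j)] = tuple(entries)
            return out

        assert canonical(fwd, lambda u: u) == canonical(rev, lambda u: u_max - u)

    def test_no_duplicate_pairs_within_group(self, helix_restraints):
        seen = set()
        for r in helix_restraints:
            key = (r.group, frozenset((r.atom_i, r.atom_j)))
            assert key not in seen
            seen.add(key)

    def test_glycine_only_chain_has_no_scsc(self):
        tgt = build_native(10, "helix", "G" * 10, "tgt")
        tpl = build_native(10, "helix", "G" * 10, "tpl")
        pw = PairwiseAlignment("tgt", "tpl", tgt.sequence, tpl.sequence)
        rset = build_hddrs(JoinedAlignment("tgt", (pw,)), [tpl], tgt)
        assert rset.group_counts["SCSC"] == 0
        assert rset.group_counts["SCMC"] == 0


class TestRestraintSetSerialization:
    def test_tsv_round_trip(self, helix_restraints, tmp_path):
        p = tmp_path / "r.tsv"
        helix_restraints.to_tsv(p)
        back = RestraintSet.from_tsv(p)
        assert len(back) == len(helix_restraints)
        for a, b in zip(helix_restraints, back):
            assert (a.atom_i, a.atom_j, a.group) == (b.atom_i, b.atom_j, b.group)
            for ea, eb in zip(a.entries, b.entries):
                assert ea.d_t == pytest.approx(eb.d_t, abs=1e-5)
                assert ea.sigma == pytest.approx(eb.sigma, abs=1e-5)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DistanceRestraint(
                (1, "CA"), (3, "CA"), "CA-CA",
                (RestraintEntry(1, 5.0, 1.0, 0.5), RestraintEntry(2, 5.0, 1.0, 0.2)),
            )
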