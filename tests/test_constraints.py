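"""Pair enumeration, the constraint filters, and crossover statistics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import segfuse as sf
from segfuse.constraints import nearest_probes
from segfuse.model import BOTH, FIVE_PRIME, THREE_PRIME, CrossoverWindow

from conftest import make_anchor, make_breakpoint, make_gene, make_panel


@pytest.fixture()
def bounded_params():
    return sf.Parameters(min_fusion_len_bp=1_000, max_fusion_len_bp=2_000_000)


def _five_anchor(gene_id="GA", cn=3, chrom="chr1"):
    gene = make_gene(gene_id, chrom, 60_000, 99_000, "+")
    flank = 2 if cn != 2 else 1
    bp = make_breakpoint(chrom, 99_000, 101_000, cn_left=cn, cn_right=flank)
    return make_anchor(gene, FIVE_PRIME, cn, bp_right=bp)


def _three_anchor(gene_id="GB", cn=3, chrom="chr2"):
    gene = make_gene(gene_id, chrom, 201_000, 240_000, "+")
    flank = 2 if cn != 2 else 1
    bp = make_breakpoint(chrom, 199_000, 201_000, cn_left=flank, cn_right=cn)
    return make_anchor(gene, THREE_PRIME, cn, bp_left=bp)


class TestEnumeratePairs:
    def test_two_by_two_distinct_genes_give_four_pairs(self):
        anchors = [
            _five_anchor("A1"),
            _five_anchor("A2"),
            _three_anchor("B1"),
            _three_anchor("B2"),
        ]
        pairs = sf.enumerate_pairs(anchors)
        assert len(pairs) == 4
        assert {(f.gene.gene_id, t.gene.gene_id) for f, t in pairs} == {
            ("A1", "B1"), ("A1", "B2"), ("A2", "B1"), ("A2", "B2"),
        }

    def test_single_anchor_gives_no_pairs(self):
        assert sf.enumerate_pairs([_five_anchor()]) == []

    def test_both_role_acts_as_five_prime(self):
        gene = make_gene("GM", "chr1", 50_000, 150_000, "+")
        left = make_breakpoint("chr1", 49_000, 51_000, 2, 3)
        right = make_breakpoint("chr1", 149_000, 151_000, 3, 2)
        inner = make_anchor(gene, BOTH, 3, bp_left=left, bp_right=right, sub=(51_001, 149_000))
        pairs = sf.enumerate_pairs([inner, _three_anchor("GB")])
        assert [(f.gene.gene_id, t.gene.gene_id) for f, t in pairs] == [("GM", "GB")]

    def test_same_gene_at_same_breakpoint_never_self_pairs(self):
        gene = make_gene("GS", "chr1", 50_000, 150_000, "+")
        bp = make_breakpoint("chr1", 99_000, 101_000, 2, 3)
        five = make_anchor(gene, FIVE_PRIME, 2, bp_right=bp, sub=(50_000, 100_000))
        three = make_anchor(gene, THREE_PRIME, 3, bp_left=bp, sub=(100_001, 150_000))
        assert sf.enumerate_pairs([five, three]) == []

    def test_matches_permissive_enumeration_after_orientation(self):
        """Role-based enumeration equals all-pairs pruned by orientation."""
        anchors = [
            _five_anchor("A1", cn=3),
            _three_anchor("B1", cn=3),
            _three_anchor("B2", cn=4),
        ]
        strict = {(f.gene.gene_id, t.gene.gene_id) for f, t in sf.enumerate_pairs(anchors)}
        permissive = {
            (f.gene.gene_id, t.gene.gene_id)
            for f in anchors
            for t in anchors
            if f is not t and sf.filter_orientation(f, t)
        }
        assert strict == permissive


class TestOrientationRule:
    def test_all_sixteen_strand_side_combinations(self):
        """Keep exactly when each partner presents its strand-appropriate end."""
        for s5, e5, s3, e3 in itertools.product("+-", ["left", "right"], "+-", ["left", "right"]):
            expected = (e5 == ("right" if s5 == "+" else "left")) and (
                e3 == ("left" if s3 == "+" else "right")
            )
            assert sf.orientation_ok(s5, e5, s3, e3) is expected

    def test_canonical_forward_forward_kept(self):
        assert sf.orientation_ok("+", "right", "+", "left")

    def test_both_five_facing_ends_dropped(self):
        assert not sf.orientation_ok("+", "left", "+", "left")

    def test_minus_strand_five_partner_broken_left_kept(self):
        assert sf.orientation_ok("-", "left", "+", "left")


class TestScalarFilters:
    @pytest.mark.parametrize(
        "cn5,cn3,keep", [(3, 2, True), (13, 12, True), (2, 5, False), (4, 4, True)]
    )
    def test_cn_tolerance(self, cn5, cn3, keep, bounded_params):
        five = _five_anchor(cn=cn5)
        three = _three_anchor(cn=cn3)
        assert sf.filter_cn(five, three, bounded_params) is keep

    def test_length_bounds_inclusive(self):
        five, three = _five_anchor(), _three_anchor()
        total = five.sub_length + three.sub_length
        params = sf.Parameters(min_fusion_len_bp=total, max_fusion_len_bp=total)
        assert sf.filter_length(five, three, params)
        tight = sf.Parameters(min_fusion_len_bp=10, max_fusion_len_bp=total - 1)
        assert not sf.filter_length(five, three, tight)

    def test_length_bounds_from_toy_collection_match_brute_force(self):
        genes = [
            make_gene("A", "chr1", 1, 4_000),
            make_gene("B", "chr1", 1, 90_000),
            make_gene("C", "chr1", 1, 60_000),
        ]
        params = sf.Parameters().with_length_bounds_from(genes)
        assert params.min_fusion_len_bp == min(g.length for g in genes)
        assert params.max_fusion_len_bp == max(g.length for g in genes)

    def test_unset_bounds_is_configuration_error(self):
        with pytest.raises(sf.ConfigurationError, match="bounds"):
            sf.filter_length(_five_anchor(), _three_anchor(), sf.Parameters())


def _panel_for(five, three, values5=None, values3=None, n5=10, n3=10):
    """Probe panel covering both anchors with evenly spaced probes."""
    probes = []
    b5 = five.boundary_for(FIVE_PRIME).boundary_pos
    for i in range(n5):
        pos = five.sub_end - i * 1_000
        val = values5[i] if values5 is not None else 0.0
        probes.append((five.gene.chrom, pos, val))
    b3 = three.boundary_for(THREE_PRIME).boundary_pos
    for i in range(n3):
        pos = three.sub_start + i * 1_000
        val = values3[i] if values3 is not None else 0.0
        probes.append((three.gene.chrom, pos, val))
    return make_panel("S1", probes), b5, b3


class TestCrossoverWindow:
    def test_side_with_six_probes_is_ignored(self, bounded_params):
        five, three = _five_anchor(), _three_anchor()
        panel, _, _ = _panel_for(five, three, n5=6, n3=10)
        assert sf.crossover_window(five, three, panel, bounded_params) is None

    def test_full_sides_give_two_length_seven_series(self, bounded_params):
        five, three = _five_anchor(), _three_anchor()
        panel, _, _ = _panel_for(five, three)
        window = sf.crossover_window(five, three, panel, bounded_params)
        assert len(window.five_prime_intensities) == 7
        assert len(window.three_prime_intensities) == 7

    def test_selected_probes_equal_brute_force_nearest_k(self, bounded_params):
        rng = np.random.default_rng(9)
        positions = sorted(rng.choice(np.arange(60_000, 99_001), size=40, replace=False))
        probes = [("chr1", int(p), float(rng.normal())) for p in positions]
        panel = make_panel("S1", probes)
        boundary = 100_000
        got = nearest_probes(panel, "chr1", 60_000, 99_000, boundary, 7)
        brute = sorted(panel.records("chr1"), key=lambda r: (abs(r.pos - boundary), r.pos))[:7]
        assert got == brute

    def test_five_prime_series_runs_toward_the_junction(self, bounded_params):
        five, three = _five_anchor(), _three_anchor()
        values5 = list(range(10))  # value i sits i kb from the gene end
        panel, _, _ = _panel_for(five, three, values5=values5)
        window = sf.crossover_window(five, three, panel, bounded_params)
        # nearest probe (value 0) must be last in the 5' series
        assert window.five_prime_intensities == [6, 5, 4, 3, 2, 1, 0]


class TestCrossoverStatistics:
    def _smoothed(self, a, b):
        return CrossoverWindow(
            five_prime_intensities=list(a),
            three_prime_intensities=list(b),
            five_prime_smoothed=list(a),
            three_prime_smoothed=list(b),
        )

    def test_identical_series_correlate_perfectly_with_zero_rms(self):
        a = [1.0, 2.0, 1.5, 3.0, 2.5, 4.0, 3.5]
        w = self._smoothed(a, a)
        assert sf.crossover_correlation(w) == pytest.approx(1.0)
        assert sf.crossover_rms(w) == 0.0

    def test_negated_series_pass_on_absolute_value(self):
        a = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0, 3.5])
        w = self._smoothed(a, -a)
        r = sf.crossover_correlation(w)
        assert r == pytest.approx(-1.0)
        assert abs(r) > sf.Parameters().min_abs_correlation

    def test_correlation_equals_textbook_formula(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=7), rng.normal(size=7)
        w = self._smoothed(a, b)
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert sf.crossover_correlation(w) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_window_is_rejected(self):
        w = self._smoothed([1.0] * 7, np.arange(7.0))
        with pytest.raises(sf.DegenerateWindowError):
            sf.crossover_correlation(w)

    def test_rms_of_constant_offset_is_the_offset(self):
        a = np.array([1.0, 2.0, 1.5, 3.0, 2.5, 4.0, 3.5])
        w = self._smoothed(a, a + 0.75)
        assert sf.crossover_rms(w) == pytest.approx(0.75, abs=1e-12)

    def test_rms_equals_direct_sum_of_squares(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=7), rng.normal(size=7)
        w = self._smoothed(a, b)
        expected = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)) / 7)
        assert sf.crossover_rms(w) == pytest.approx(expected, abs=1e-12)

    def test_rms_invariant_under_common_shift(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=7), rng.normal(size=7)
        base = sf.crossover_rms(self._smoothed(a, b))
        shifted = sf.crossover_rms(self._smoothed(a + 5.0, b + 5.0))
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_abs_correlation_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=7), rng.normal(size=7)
        base = sf.crossover_correlation(self._smoothed(a, b))
        up = sf.crossover_correlation(self._smoothed(2.5 * a + 1.0, b))
        down = sf.crossover_correlation(self._smoothed(a, -0.5 * b + 3.0))
        assert up == pytest.approx(base, abs=1e-12)
        assert down == pytest.approx(-base, abs=1e-12)
        assert abs(up) == pytest.approx(abs(down), abs=1e-12)


class TestEvaluateCandidates:
    def test_empty_anchor_set_gives_empty_output(self, bounded_params):
        panel = make_panel("S1", [("chr1", 1_000, 0.0)])
        assert sf.evaluate_candidates([], panel, bounded_params) == []

    def test_planted_compliant_fusion_is_detected(self, study_results):
        groups, per_sample, _ = study_results
        for sid in ("S01", "S02", "S03"):
            assert [c.gene_pair for c in per_sample[sid]] == [("G5CMP", "G3CMP")]
        for sid in ("S04", "S05"):
            assert per_sample[sid] == []

    def test_cn_gap_pair_dropped_with_reason(self, bounded_params):
        five = _five_anchor(cn=2)
        three = _three_anchor(cn=5)
        panel, _, _ = _panel_for(five, three)
        log = []
        out = sf.evaluate_candidates([five, three], panel, bounded_params, drop_log=log)
        assert out == []
        assert ("S1", "GA", "GB", "cn") in {(s, a, b, st) for s, a, b, st, _ in log}

    def test_filter_order_permutation_invariance(self, bounded_params):
        """The three scalar filters are independent predicates: any order
        leaves the same surviving set."""
        anchors = [
            _five_anchor("A1", cn=3),
            _five_anchor("A2", cn=9),
            _three_anchor("B1", cn=3),
            _three_anchor("B2", cn=8),
        ]
        filters = {
            "cn": lambda f, t: sf.filter_cn(f, t, bounded_params),
            "orientation": lambda f, t: sf.filter_orientation(f, t),
            "length": lambda f, t: sf.filter_length(f, t, bounded_params),
        }
        baseline = None
        for order in itertools.permutations(filters.values()):
            survivors = {
                (f.gene.gene_id, t.gene.gene_id)
                for f in anchors
                for t in anchors
                if f is not t and all(fn(f, t) for fn in order)
            }
            baseline = survivors if baseline is None else baseline
            assert survivors == baseline
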