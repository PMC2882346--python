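import io
import math

import numpy as np
import pytest

from parablade.divergence import DivergentSite
from parablade.seqio import MultipleAlignment, read_structure
from parablade.structmap import (BladeAnnotation, blade_count_profile,
                                 clustering_test, default_blade_annotation,
                                 map_alignment_to_structure,
                                 read_blade_annotation, report_divergence_map)
from parablade.synthetic_data import make_toy_structure


def _site(column, residue=None, blade=None, disordered=False):
    return DivergentSite(column=column, residue_a="D", residue_b="K",
                         blosum_score=-1, charge_a=-1, charge_b=1,
                         significant_by=frozenset({"blosum_negative"}),
                         structure_residue=residue, blade=blade,
                         disordered=disordered)


class TestMapAlignmentToStructure:
    def test_gapless_reference(self, toy_structure):
        structure, _ = toy_structure
        msa = MultipleAlignment([("ref", "ACD")])
        colmap = map_alignment_to_structure(msa, "ref", 301, structure)
        assert [colmap.residue(c) for c in (1, 2, 3)] == [301, 302, 303]

    def test_reference_gap_column_unmapped(self, toy_structure):
        structure, _ = toy_structure
        msa = MultipleAlignment([("ref", "A-CD")])
        colmap = map_alignment_to_structure(msa, "ref", 301, structure)
        assert colmap.residue(2) is None
        assert [colmap.residue(c) for c in (1, 3, 4)] == [301, 302, 303]

    def test_disordered_flag_copied(self):
        text, _ = make_toy_structure(1, 5, 301, missing_spans=[(303, 303)])
        structure = read_structure(io.StringIO(text), "A", (301, 305))
        msa = MultipleAlignment([("ref", "ACDEF")])
        colmap = map_alignment_to_structure(msa, "ref", 301, structure)
        assert colmap.disordered(3) and not colmap.disordered(2)

    def test_mapping_outside_span_is_error(self, toy_structure):
        structure, _ = toy_structure
        msa = MultipleAlignment([("ref", "A" * 71)])
        with pytest.raises(ValueError, match="outside structure span"):
            map_alignment_to_structure(msa, "ref", 301, structure)

    def test_order_preserving_and_injective(self, toy_structure):
        structure, _ = toy_structure
        msa = MultipleAlignment([("ref", "AC-DE-FG")])
        colmap = map_alignment_to_structure(msa, "ref", 301, structure)
        mapped = [colmap.residue(c) for c in range(1, 9) if colmap.residue(c)]
        assert mapped == sorted(mapped)
        assert len(mapped) == len(set(mapped))


class TestBladeCountProfile:
    def test_all_sites_one_blade(self, toy_structure):
        _, annotation = toy_structure
        sites = [_site(i, residue=321 + i) for i in range(4)]  # blade 3: 321-330
        counts, unassigned = blade_count_profile(sites, annotation)
        assert counts == [0, 0, 4, 0, 0, 0, 0] and unassigned == 0

    def test_residue_between_blades_unassigned(self):
        annotation = BladeAnnotation([(1, "A", 1, 3), (2, "A", 7, 9)], n_blades=2)
        counts, unassigned = blade_count_profile([_site(1, residue=5)], annotation)
        assert counts == [0, 0] and unassigned == 1

    def test_empty_sites(self, toy_structure):
        _, annotation = toy_structure
        counts, unassigned = blade_count_profile([], annotation)
        assert counts == [0] * 7 and unassigned == 0

    def test_counts_sum_to_n_sites(self, toy_structure):
        _, annotation = toy_structure
        rng = np.random.default_rng(4)
        sites = [_site(i + 1, residue=int(r))
                 for i, r in enumerate(rng.integers(301, 380, size=25))]
        counts, unassigned = blade_count_profile(sites, annotation)
        assert sum(counts) + unassigned == 25


class TestClusteringTest:
    def test_exhaustive_two_blade_case(self, two_blade_structure):
        structure, annotation = two_blade_structure
        sites = [_site(1, residue=1), _site(2, residue=2)]  # both in blade 1
        result = clustering_test(sites, structure, annotation,
                                 statistic="max_blade_count")
        assert result.exhaustive
        assert result.n_permutations == 15  # C(6,2)
        assert result.p_value == pytest.approx(6 / 15)

    def test_degenerate_null_p_is_one(self, two_blade_structure):
        structure, annotation = two_blade_structure
        sites = [_site(1, residue=1), _site(2, residue=2)]
        result = clustering_test(sites, structure, annotation,
                                 statistic="max_blade_count",
                                 eligible=[1, 2, 3])  # all in blade 1
        assert result.p_value == 1.0

    def test_monte_carlo_close_to_exhaustive(self, two_blade_structure):
        """MC p-value agrees with the exact enumeration within 3 SE."""
        structure, annotation = two_blade_structure
        sites = [_site(1, residue=1), _site(2, residue=2)]
        exact = clustering_test(sites, structure, annotation,
                                statistic="max_blade_count").p_value
        import parablade.structmap as sm
        old = sm.EXHAUSTIVE_LIMIT
        sm.EXHAUSTIVE_LIMIT = 0
        try:
            n = 2000
            mc = clustering_test(sites, structure, annotation,
                                 statistic="max_blade_count",
                                 n_permutations=n, seed=5)
        finally:
            sm.EXHAUSTIVE_LIMIT = old
        se = math.sqrt(exact * (1 - exact) / n)
        assert abs(mc.p_value - exact) <= 3 * se + 1 / n

    def test_spatial_statistic_detects_planted_cluster(self, toy_structure):
        structure, annotation = toy_structure
        sites = [_site(i, residue=321 + i) for i in range(5)]  # inside blade 3
        result = clustering_test(sites, structure, annotation,
                                 statistic="mean_pairwise_ca_distance",
                                 n_permutations=500, seed=1)
        assert result.p_value <= 0.05

    def test_disordered_sites_excluded_from_spatial_statistic(self):
        text, annotation = make_toy_structure(2, 5, 1, missing_spans=[(2, 2)])
        structure = read_structure(io.StringIO(text), "A", (1, 10))
        sites = [_site(1, residue=1), _site(2, residue=2, disordered=True),
                 _site(3, residue=3)]
        result = clustering_test(sites, structure, annotation,
                                 statistic="mean_pairwise_ca_distance",
                                 n_permutations=50, seed=0)
        # only the 2 ordered sites enter; distances exist for both
        assert result.observed > 0

    def test_identical_seed_identical_result(self, toy_structure):
        structure, annotation = toy_structure
        sites = [_site(i, residue=321 + i) for i in range(5)]
        import parablade.structmap as sm
        old = sm.EXHAUSTIVE_LIMIT
        sm.EXHAUSTIVE_LIMIT = 0
        try:
            r1 = clustering_test(sites, structure, annotation,
                                 n_permutations=200, seed=42)
            r2 = clustering_test(sites, structure, annotation,
                                 n_permutations=200, seed=42)
        finally:
            sm.EXHAUSTIVE_LIMIT = old
        assert r1 == r2

    def test_too_few_sites(self, toy_structure):
        structure, annotation = toy_structure
        with pytest.raises(ValueError):
            clustering_test([_site(1, residue=301)], structure, annotation)


class TestBladeAnnotation:
    def test_default_has_seven_blades(self):
        annotation = default_blade_annotation()
        assert annotation.n_blades == 7
        assert sorted({b for b, _, _, _ in annotation.ranges}) == list(range(1, 8))

    def test_round_trip_tsv(self, tmp_path, toy_structure):
        _, annotation = toy_structure
        path = tmp_path / "blades.tsv"
        with open(path, "w") as fh:
            fh.write("blade\tstrand\tstart\tend\n")
            for row in annotation.ranges:
                fh.write("\t".join(str(x) for x in row) + "\n")
        again = read_blade_annotation(str(path))
        assert again.ranges == annotation.ranges

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            BladeAnnotation([(1, "A", 1, 5), (2, "A", 4, 8)], n_blades=2)


class TestReportDivergenceMap:
    def test_joined_row_and_files(self, tmp_path, toy_structure):
        _, annotation = toy_structure
        sites = [_site(5, residue=325, blade=3)]
        paths = report_divergence_map(sites, annotation, tmp_path)
        table = (tmp_path / "divergent_sites.tsv").read_text()
        assert "325" in table and "3" in table
        attr = (tmp_path / "divergent_sites.attr.tsv").read_text()
        assert "325\t" in attr

    def test_empty_sites_writes_headers(self, tmp_path, toy_structure):
        _, annotation = toy_structure
        report_divergence_map([], annotation, tmp_path)
        summary = (tmp_path / "blade_summary.tsv").read_text()
        assert summary.count("\t0\n") == 8  # 7 blades + unassigned

    def test_disordered_site_kept_in_table_not_attributes(self, tmp_path,
                                                          toy_structure):
        _, annotation = toy_structure
        sites = [_site(1, residue=310, disordered=True)]
        report_divergence_map(sites, annotation, tmp_path)
        table = (tmp_path / "divergent_sites.tsv").read_text()
        attr = (tmp_path / "divergent_sites.attr.tsv").read_text()
        assert "310" in table
        assert "310" not in attr
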