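import numpy as np
import pytest

import tempoblocks as tb
from tempoblocks.blocks import TemporalBlock
from tempoblocks.ebb import Bicluster


def _bc(genes, start, end):
    return Bicluster(genes=frozenset(genes), start=start, end=end,
                     reference_gene=min(genes))


class TestBoundaryScores:
    def test_gene_in_no_bicluster_never_boundary(self):
        bcs = [_bc({0, 1}, 1, 3)]
        profile = tb.boundary_scores(bcs, n_genes=4, n_times=6)
        assert (profile.R[2] == 0).all() and (profile.R[3] == 0).all()
        assert all(2 not in bg and 3 not in bg for bg in profile.BG)

    def test_two_starts_over_one_continuation_is_boundary(self):
        # at t=2: two biclusters start for gene 0, one continues through
        bcs = [_bc({0, 1}, 1, 4), _bc({0, 2}, 2, 4), _bc({0, 3}, 2, 3)]
        profile = tb.boundary_scores(bcs, 4, 6)
        assert profile.R[0, 2] == pytest.approx(2.0)  # 2 / max(1, 1)
        assert 0 in profile.BG[2]

    def test_single_start_no_continuation_is_not_boundary(self):
        # R = 1 / max(1, 0) = 1, and membership is strict (> theta)
        bcs = [_bc({0, 1}, 2, 4)]
        profile = tb.boundary_scores(bcs, 3, 6)
        assert profile.R[0, 2] == pytest.approx(1.0)
        assert 0 not in profile.BG[2]

    def test_global_first_column_scores_zero(self):
        bcs = [_bc({0, 1}, 0, 3), _bc({0, 2}, 0, 2)]
        profile = tb.boundary_scores(bcs, 3, 5)
        assert (profile.R[:, 0] == 0).all()

    def test_negative_theta_error(self):
        with pytest.raises(ValueError, match="theta"):
            tb.boundary_scores([], 2, 2, theta=-0.5)


class TestAssembleBlocks:
    def test_worked_example_two_blocks(self):
        biclusters, expected = tb.worked_example_fixture()
        profile = tb.boundary_scores(biclusters, 6, 7)
        blocks = tb.assemble_blocks(profile, biclusters, 6, 7)
        assert blocks == expected

    def test_no_boundary_genes_no_blocks(self):
        bcs = [_bc({0, 1}, 2, 4)]  # single pattern: R never exceeds 1
        profile = tb.boundary_scores(bcs, 3, 6)
        assert tb.assemble_blocks(profile, bcs, 3, 6) == []

    def test_dimension_mismatch_error(self):
        profile = tb.boundary_scores([], 3, 6)
        with pytest.raises(ValueError, match="match"):
            tb.assemble_blocks(profile, [], 4, 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_definition_conditions_on_phase_series(self, seed):
        series = tb.generate_phase_series(seed=seed)
        m = series.matrix
        bcs = tb.enumerate_biclusters(m, 0.1, 3, 2)
        profile = tb.boundary_scores(bcs, m.n_genes, m.n_times)
        blocks = tb.assemble_blocks(profile, bcs, m.n_genes, m.n_times)
        assert blocks, "fixture should produce temporal blocks"
        cells = set()
        for b in blocks:
            assert tb.validate_block(b, profile, m.n_times) == []
            for g in b.genes:
                for t in range(b.start, b.end + 1):
                    assert (g, t) not in cells, "blocks share a cell"
                    cells.add((g, t))

    def test_bicluster_starts_align_with_blocks(self, phase_series):
        """A bicluster start backed by boundary genes lands on a block start
        or inside a recorded disorder prefix."""
        m = phase_series.matrix
        bcs = tb.enumerate_biclusters(m, 0.1, 3, 2)
        profile = tb.boundary_scores(bcs, m.n_genes, m.n_times)
        blocks = tb.assemble_blocks(profile, bcs, m.n_genes, m.n_times)
        for bc in bcs:
            for g in bc.genes & profile.BG[bc.start]:
                homes = [
                    b for b in blocks
                    if g in b.genes and b.start <= bc.start <= b.end
                ]
                if not homes:  # trailing reorganization with no aftermath
                    assert bc.start >= max(b.end for b in blocks)
                    continue
                b = homes[0]
                span_end = b.disorder_span[1] if b.disorder_span else b.start
                assert b.start <= bc.start <= span_end


class TestValidateBlock:
    def _profile(self, bg_sets, n_genes=4):
        n_times = len(bg_sets)
        R = np.zeros((n_genes, n_times))
        for t, bg in enumerate(bg_sets):
            for g in bg:
                R[g, t] = 2.0
        return tb.BoundaryProfile(R=R, theta=1.0)

    def test_fully_conforming_block(self):
        profile = self._profile([set(), {0, 1}, set(), set(), {0, 1}, set()])
        block = TemporalBlock(genes=frozenset({0, 1}), start=1, end=3)
        assert tb.validate_block(block, profile, 6) == []

    def test_first_column_escape(self):
        profile = self._profile([{0, 1}, set(), set(), {0, 1}, set()])
        block = TemporalBlock(genes=frozenset({0, 1}), start=0, end=2)
        assert tb.validate_block(block, profile, 5) == []

    def test_violating_only_condition_a(self):
        profile = self._profile([set(), {0}, set(), set(), {0, 1}, set()])
        block = TemporalBlock(genes=frozenset({0, 1}), start=1, end=3)
        assert tb.validate_block(block, profile, 6) == ["a"]

    def test_all_conditions_reported(self):
        profile = self._profile([{0}, set(), {0}, {0}, {0}, set()])
        block = TemporalBlock(genes=frozenset({0}), start=1, end=4)
        assert tb.validate_block(block, profile, 6) == ["a", "b", "c", "d"]


class TestExpandBlock:
    def _matrix(self, values):
        values = np.asarray(values, float)
        return tb.ExpressionMatrix(
            gene_ids=[f"g{i}" for i in range(values.shape[0])],
            time_points=[f"t{j}" for j in range(values.shape[1])],
            values=values,
        )

    def test_uncorrelated_outsiders_not_added(self):
        rng = np.random.default_rng(3)
        base = np.sin(np.linspace(0, 3, 8))
        values = np.vstack([base, base + 1.0, rng.normal(size=(3, 8))])
        m = self._matrix(values)
        block = TemporalBlock(genes=frozenset({0, 1}), start=0, end=7)
        out = tb.expand_block(block, m, p=0.999)
        assert out.genes_expanded == block.genes

    def test_affine_copy_of_member_added(self):
        rng = np.random.default_rng(4)
        member = rng.normal(size=10)
        values = np.vstack([member, rng.normal(size=10), member + 5.0])
        m = self._matrix(values)
        block = TemporalBlock(genes=frozenset({0, 1}), start=0, end=9)
        out = tb.expand_block(block, m, p=0.8)
        assert 2 in out.genes_expanded  # Pearson is affine-invariant: C = 1

    @pytest.mark.parametrize("linkage", ["any", "all", "mean"])
    def test_matches_all_pairs_oracle(self, linkage):
        rng = np.random.default_rng(9)
        m = self._matrix(rng.normal(size=(20, 10)))
        block = TemporalBlock(genes=frozenset({0, 1, 2}), start=0, end=9)
        out = tb.expand_block(block, m, p=0.8, linkage=linkage)
        members = sorted(block.genes)
        for g in range(20):
            if g in block.genes:
                continue
            cors = [np.corrcoef(m.values[g], m.values[x])[0, 1] for x in members]
            passes = {
                "any": max(cors) >= 0.8,
                "all": min(cors) >= 0.8,
                "mean": np.mean(cors) >= 0.8,
            }[linkage]
            assert (g in out.genes_expanded) == passes

    def test_expansion_monotone_in_p(self):
        rng = np.random.default_rng(14)
        m = self._matrix(rng.normal(size=(15, 8)))
        block = TemporalBlock(genes=frozenset({0, 1}), start=0, end=7)
        sets = [tb.expand_block(block, m, p=p).genes_expanded
                for p in (0.2, 0.5, 0.8)]
        assert sets[2] <= sets[1] <= sets[0]

    def test_window_too_short_error(self):
        m = self._matrix(np.zeros((4, 6)))
        block = TemporalBlock(genes=frozenset({0}), start=1, end=2)
        with pytest.raises(ValueError, match="short"):
            tb.expand_block(block, m)

    def test_invalid_threshold_error(self):
        m = self._matrix(np.zeros((4, 6)))
        block = TemporalBlock(genes=frozenset({0}), start=0, end=5)
        with pytest.raises(ValueError, match="threshold"):
            tb.expand_block(block, m, p=0.0)


class TestBoundaryCounts:
    def test_refined_counts_sum_block_start_genes(self):
        blocks = [
            TemporalBlock(genes=frozenset({0, 1}), start=1, end=3),
            TemporalBlock(genes=frozenset({2, 3, 4}), start=1, end=4),
            TemporalBlock(genes=frozenset({5}), start=4, end=6),
        ]
        counts = tb.refined_boundary_counts(blocks, 7)
        assert counts.tolist() == [0, 5, 0, 0, 1, 0, 0]

    def test_local_peaks(self):
        assert tb.local_peak_times([0, 3, 0, 0, 2, 2, 0]) == [1, 4, 5]
        assert tb.local_peak_times([0, 0, 0]) == []
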