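"""Aggregate analysis: enrichment formula, pileups, rescaling, profiles."""

import numpy as np
import pandas as pd
import pytest

from osmoloop.apa import (
    AggregateBlock,
    apa,
    background_normalize,
    bilinear_resize,
    diagonal_profile,
    enrichment,
    scaled_domain_aggregate,
    standardize_loops,
    timecourse_enrichment,
)
from osmoloop.io import ContactMatrix, GenomeSpec, LoopSet
from conftest import make_loops


def brute_force_enrichment(block, fg_mode, bg_mode, cs=3):
    """Independent median(fg+1)/median(bg+1) implementation."""
    side = block.shape[0]
    w = side // 2
    if fg_mode == "center":
        fg = [block[w, w]]
    else:
        fg = [block[i, j] for i in range(w - 1, w + 2) for j in range(w - 1, w + 2)]
    if bg_mode == "corners":
        bg = [block[i, j] for i in range(cs) for j in range(cs)]
        bg += [block[i, j] for i in range(side - cs, side) for j in range(side - cs, side)]
    else:
        bg = [
            block[i, j]
            for i in range(side)
            for j in range(side)
            if max(abs(i - w), abs(j - w)) == w
        ]
    return (np.median(fg) + 1) / (np.median(bg) + 1)


class TestEnrichment:
    def test_uniform_block_is_one(self):
        assert enrichment(np.ones((21, 21))).value == 1.0

    def test_forced_center(self):
        block = np.ones((21, 21))
        block[10, 10] = 9
        assert enrichment(block, "center", "corners").value == 5.0

    @pytest.mark.parametrize("fg", ["center", "center3x3"])
    @pytest.mark.parametrize("bg", ["corners", "ring"])
    def test_matches_brute_force_oracle(self, rng, fg, bg):
        for _ in range(200):
            block = rng.integers(0, 50, (21, 21)).astype(float)
            got = enrichment(block, fg, bg).value
            assert got == brute_force_enrichment(block, fg, bg)

    def test_small_block_rejected(self):
        with pytest.raises(ValueError, match="corner_size"):
            enrichment(np.ones((5, 5)), corner_size=3)

    def test_monotone_in_center(self, rng):
        block = rng.integers(0, 10, (21, 21)).astype(float)
        e1 = enrichment(block).value
        block[10, 10] += 100
        assert enrichment(block).value > e1


class TestBackgroundNormalize:
    def test_uniform_goes_to_one(self):
        out = background_normalize(np.full((21, 21), 7.0))
        assert np.allclose(out, 1.0)

    def test_scale_invariant_on_uniform(self):
        a = background_normalize(np.full((21, 21), 3.0))
        b = background_normalize(np.full((21, 21), 6.0))
        np.testing.assert_allclose(a, b)

    def test_center_equals_enrichment(self, rng):
        block = rng.integers(0, 30, (21, 21)).astype(float)
        out = background_normalize(block)
        assert out[10, 10] == pytest.approx(enrichment(block).value)


class TestApa:
    def _matrix(self, dense):
        n = dense.shape[0]
        g = GenomeSpec(("c",), (n * 10_000,), 10_000)
        return {"c": ContactMatrix.from_dense(g, "c", np.triu(dense))}

    def test_single_loop_on_empty_matrix_is_error(self):
        g = GenomeSpec(("c",), (1_000_000,), 10_000)
        mats = {"c": ContactMatrix(g, "c", [], [], [])}
        loops = make_loops([("c", 200000, 210000, "c", 700000, 710000)])
        with pytest.raises(ValueError, match="low_signal"):
            apa(mats, loops)

    def test_mean_equals_oracle_mean_of_windows(self, rng):
        n = 300
        dense = rng.integers(0, 20, (n, n))
        dense = np.triu(dense) + np.triu(dense, 1).T
        mats = self._matrix(dense)
        rows = []
        centers = [(30, 80), (100, 160), (150, 260)]
        for i, j in centers:
            rows.append(("c", i * 10_000, (i + 1) * 10_000, "c", j * 10_000, (j + 1) * 10_000))
        block = apa(mats, make_loops(rows))
        expected = np.mean(
            [dense[i - 10 : i + 11, j - 10 : j + 11] for i, j in centers], axis=0
        )
        np.testing.assert_allclose(block.matrix, expected)
        assert block.n_used == 3

    def test_near_diagonal_and_out_of_bounds_excluded(self):
        n = 100
        dense = np.ones((n, n))
        mats = self._matrix(dense)
        rows = [
            ("c", 300000, 310000, "c", 400000, 410000),   # span 10 bins: near diagonal
            ("c", 50000, 60000, "c", 900000, 910000),     # window off the left edge
            ("c", 300000, 310000, "c", 800000, 810000),   # usable
        ]
        block = apa(mats, make_loops(rows))
        assert block.n_used == 1
        assert block.exclusions["near_diagonal"] == 1
        assert block.exclusions["out_of_bounds"] == 1

    def test_inter_chromosomal_excluded(self):
        n = 100
        dense = np.ones((n, n))
        mats = self._matrix(dense)
        rows = [
            ("c", 300000, 310000, "other", 800000, 810000),
            ("c", 300000, 310000, "c", 800000, 810000),
        ]
        block = apa(mats, make_loops(rows))
        assert block.exclusions["inter_chromosomal"] == 1


class TestBilinear:
    def test_two_by_two_center(self):
        out = bilinear_resize(np.array([[0.0, 1.0], [1.0, 0.0]]), 3)
        assert out[1, 1] == pytest.approx(0.5)

    def test_same_size_is_identity(self, rng):
        w = rng.random((100, 100))
        np.testing.assert_array_equal(bilinear_resize(w, 100), w)

    def test_constant_stays_constant(self):
        out = bilinear_resize(np.full((7, 7), 3.5), 100)
        np.testing.assert_allclose(out, 3.5)


class TestScaledAggregate:
    def test_constant_matrix_normalizes_to_uniform(self):
        n = 200
        dense = np.full((n, n), 4.0)
        g = GenomeSpec(("c",), (n * 10_000,), 10_000)
        mats = {"c": ContactMatrix.from_dense(g, "c", np.triu(dense))}
        loops = make_loops([("c", 500000, 510000, "c", 1_100_000, 1_110_000)])
        agg = scaled_domain_aggregate(mats, loops, min_span_bp=150_000)
        np.testing.assert_allclose(agg.matrix, 1.0 / 10_000, rtol=1e-9)
        assert agg.n_used == 1

    def test_short_loops_excluded(self):
        n = 200
        g = GenomeSpec(("c",), (n * 10_000,), 10_000)
        dense = np.full((n, n), 2.0)
        mats = {"c": ContactMatrix.from_dense(g, "c", np.triu(dense))}
        loops = make_loops([("c", 500000, 510000, "c", 600000, 610000)])
        with pytest.raises(ValueError):
            scaled_domain_aggregate(mats, loops, min_span_bp=150_000)

    def test_normalized_windows_sum_to_one(self, rng):
        n = 300
        dense = rng.integers(0, 9, (n, n)).astype(float)
        g = GenomeSpec(("c",), (n * 10_000,), 10_000)
        mats = {"c": ContactMatrix.from_dense(g, "c", np.triu(dense))}
        loops = make_loops([("c", 600000, 610000, "c", 1_500_000, 1_510_000)])
        agg = scaled_domain_aggregate(mats, loops)
        assert agg.matrix.sum() == pytest.approx(1.0, abs=1e-9)


class TestWeakDomains:
    def test_gained_loops_have_weaker_interiors(self):
        """Smaller simulated domain factor (gained class) gives a lower
        relative interior mean in the span-rescaled aggregate."""
        from osmoloop.apa import scaled_domain_aggregate as sda
        from osmoloop.io import LoopSet
        from osmoloop.simulate import (
            SimParams, _stream, inject_loops, loopspecs_to_loopset,
            make_loopspecs, simulate_background,
        )

        p = SimParams(seed=31)
        specs = make_loopspecs(p, n_gained=20, n_preexisting=20, n_static=0,
                               gained_span_bins=(24, 60))
        bg = simulate_background(p, rng=_stream(31, 70))
        mat = inject_loops(bg, specs, "treated", 1.0, p, rng=_stream(31, 71))
        loops = loopspecs_to_loopset(specs, p)
        interior = {}
        for k in ("gained", "preexisting"):
            sub = LoopSet(loops.df[loops.df.klass == k])
            agg = sda({p.chrom_name: mat}, sub, min_span_bp=150_000)
            interior[k] = agg.matrix[30:70, 30:70].mean() / agg.matrix.mean()
        assert interior["gained"] < interior["preexisting"]


class TestDiagonalProfile:
    def test_uniform_flat_one(self):
        trace = diagonal_profile(np.full((50, 50), 6.0))
        np.testing.assert_allclose(trace, 1.0)
        assert len(trace) == 50

    def test_domain_fixture_is_elevated_inside(self):
        mat = np.ones((100, 100))
        mat[20:80, 20:80] = 5.0  # domain square
        trace = diagonal_profile(mat)
        assert trace[50] > trace[5]
        assert trace[50] > trace[95]


class TestStandardize:
    def test_output_spans_equal_target(self, rng):
        rows = []
        for _ in range(100):
            s1 = int(rng.integers(0, 1000)) * 10_000
            s2 = s1 + int(rng.integers(30, 120)) * 10_000
            rows.append(("c", s1, s1 + 10_000, "c", s2, s2 + 10_000))
        loops = make_loops(rows)
        out = standardize_loops(loops, target_span=150_000)
        assert (out.spans == 150_000).all()

    def test_midpoint_preserved_within_one_bin(self, rng):
        rows = []
        for _ in range(100):
            s1 = int(rng.integers(0, 1000)) * 10_000 + int(rng.integers(0, 9999))
            s2 = s1 + int(rng.integers(30, 120)) * 10_000
            rows.append(("c", s1, s1 + 7_000, "c", s2, s2 + 9_000))
        loops = make_loops(rows)
        out = standardize_loops(loops, target_span=150_000)
        mid_in = (loops.df.start1 + loops.df.end1 + loops.df.start2 + loops.df.end2) // 4
        mid_out = (out.df.start1 + out.df.end1 + out.df.start2 + out.df.end2) // 4
        assert (np.abs(mid_in - mid_out) <= 10_000).all()


class TestTimecourse:
    def _mats(self, dense):
        n = dense.shape[0]
        g = GenomeSpec(("c",), (n * 10_000,), 10_000)
        return {"c": ContactMatrix.from_dense(g, "c", np.triu(dense))}

    def test_identical_matrices_flat_curves(self, rng):
        n = 150
        dense = rng.integers(1, 20, (n, n))
        dense = np.triu(dense) + np.triu(dense, 1).T
        mats = self._mats(dense)
        loops = {"gained": make_loops([("c", 300000, 310000, "c", 900000, 910000)])}
        curves, corr = timecourse_enrichment({0.0: mats, 1.0: mats, 3.0: mats}, loops)
        assert curves.loc["gained"].nunique() == 1
        assert corr is None  # no lost/preexisting class supplied

    def test_single_timepoint_correlation_missing(self, rng):
        n = 150
        dense = rng.integers(1, 20, (n, n))
        dense = np.triu(dense) + np.triu(dense, 1).T
        mats = self._mats(dense)
        loops = {
            "gained": make_loops([("c", 300000, 310000, "c", 900000, 910000)]),
            "lost": make_loops([("c", 400000, 410000, "c", 1_000_000, 1_010_000)]),
        }
        curves, corr = timecourse_enrichment({1.0: mats}, loops)
        assert curves.shape == (2, 1)
        assert corr is None
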