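"""Circular geometry, window series, model fits, segment and thirds analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from panoric import (
    ChromosomeFrame,
    RegionAnnotation,
    SlopeFit,
    circular_distance,
    fit_models,
    segment_analysis,
    segment_index,
    slope_population_analysis,
    thirds_region_analysis,
    window_series,
)
from panoric.positional import WindowSeries


def make_frame(scores, length=100_000, oric=0, regions=None, strain="S"):
    n = len(scores)
    mids = (np.arange(n) + 0.5) * (length / n)
    return ChromosomeFrame(
        strain=strain,
        length=length,
        oric=oric,
        gene_ids=[f"g{i}" for i in range(n)],
        midpoints=mids,
        scores=np.asarray(scores, dtype=float),
        regions=regions or [],
    )


class TestCircularDistance:
    def test_zero_at_oric(self):
        assert circular_distance(500, 500, 1000)[:2] == (0, 0.0)

    def test_wrapping_shorter_arc(self):
        d, norm, repl = circular_distance(3_000_000, 0, 4_000_000)
        assert d == 1_000_000 and norm == 0.5 and repl == "left"

    def test_wrap_around_origin(self):
        d, norm, _ = circular_distance(100, 900, 1000)
        assert d == 200 and norm == pytest.approx(0.4)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            circular_distance(0, 0, 0)

    @given(
        st.integers(0, 9999), st.integers(0, 9999)
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_reflection_symmetric(self, p, o):
        L = 10_000
        d, norm, _ = circular_distance(p, o, L)
        assert 0 <= d <= L / 2 and 0 <= norm <= 1
        # reflecting p about the oriC-terC axis preserves the distance
        reflected = (2 * o - p) % L
        assert circular_distance(reflected, o, L)[0] == d


class TestWindowSeries:
    def test_constant_scores_constant_means(self):
        ws = window_series(make_frame([7.0] * 40), window_size=20)
        assert np.allclose(ws.mean_score, 7.0)

    def test_circular_window_count(self):
        ws = window_series(make_frame(np.arange(40)), window_size=20, step=1)
        assert ws.n_windows == 40

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(11)
        frame = make_frame(rng.integers(0, 10, size=25), oric=40_000)
        ws = window_series(frame, window_size=5, step=1)
        n = 25
        for w in range(n):
            idx = [(w + j) % n for j in range(5)]
            assert ws.mean_score[w] == pytest.approx(np.mean(frame.scores[idx]))
            mid_gene = idx[2]
            off = (frame.midpoints[mid_gene] - frame.oric) % frame.length
            d = min(off, frame.length - off) / (frame.length / 2)
            assert ws.midpoint_distance[w] == pytest.approx(d)

    def test_window_means_invariant_to_index_rotation(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 12, size=30).astype(float)
        a = window_series(make_frame(scores, oric=10_000), window_size=5)
        rolled = np.roll(scores, -7)
        b = window_series(make_frame(rolled, oric=10_000), window_size=5)
        # same multiset of (distance, mean) pairs, just re-indexed
        assert sorted(np.round(a.mean_score, 9)) == sorted(np.round(b.mean_score, 9))

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="genes"):
            window_series(make_frame([1.0] * 5), window_size=20)

    def test_bad_window_size_rejected(self):
        with pytest.raises(ValueError, match="window_size"):
            window_series(make_frame([1.0] * 30), window_size=0)


class TestFitModels:
    def test_exact_line(self):
        d = np.linspace(0, 1, 50)
        series = WindowSeries(mean_score=5 - 2 * d, midpoint_distance=d, window_size=20, step=1)
        fit = fit_models(series)
        assert fit.slope == pytest.approx(-2.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.p_value < 0.05 and fit.significant
        assert not fit.quadratic_better

    def test_constant_series_not_significant(self):
        d = np.linspace(0, 1, 30)
        series = WindowSeries(mean_score=np.full(30, 4.0), midpoint_distance=d,
                              window_size=20, step=1)
        fit = fit_models(series)
        assert fit.slope == pytest.approx(0.0)
        assert not fit.significant

    def test_three_point_closed_form(self):
        # hand OLS: points (0,1), (0.5,2), (1,3) -> slope 2, intercept 1
        series = WindowSeries(
            mean_score=np.array([1.0, 2.0, 3.0]),
            midpoint_distance=np.array([0.0, 0.5, 1.0]),
            window_size=1, step=1,
        )
        fit = fit_models(series)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_quadratic_detected(self):
        d = np.linspace(0, 1, 60)
        rng = np.random.default_rng(0)
        y = 3 + 0.0 * d + 6 * (d - 0.5) ** 2 + rng.normal(0, 0.05, 60)
        series = WindowSeries(mean_score=y, midpoint_distance=d, window_size=20, step=1)
        assert fit_models(series).quadratic_better

    def test_zero_distance_variance_rejected(self):
        series = WindowSeries(
            mean_score=np.array([1.0, 2.0, 3.0]),
            midpoint_distance=np.zeros(3),
            window_size=1, step=1,
        )
        with pytest.raises(ValueError, match="variance"):
            fit_models(series)

    def test_permutation_p_used_with_gene_payload(self):
        rng = np.random.default_rng(5)
        frame = make_frame(rng.permutation(np.repeat(np.arange(10), 10)))
        fit = fit_models(window_series(frame), seed=1)
        assert 0 < fit.p_value <= 1
        # a random score arrangement should rarely be significant
        assert fit.p_value > 0.001


def _fit(slope, p=1.0):
    return SlopeFit(
        slope=slope, intercept=0.0, p_value=p, p_value_ols=p, r_squared=0.0,
        quadratic=(0, 0, 0), quadratic_better=False, significant=p < 0.05,
        alpha=0.05, n_windows=10,
    )


class TestSlopePopulation:
    def test_normal_slopes_inside_ks_band(self):
        """Normally distributed slopes stay inside the simultaneous KS band."""
        rng = np.random.default_rng(100)
        n_ok = 0
        reps = 100
        for _ in range(reps):
            fits = {f"s{i}": _fit(x) for i, x in enumerate(rng.normal(0, 1, 100))}
            _, summary = slope_population_analysis(fits)
            n_ok += summary["normal_within_ks_band"]
        assert n_ok >= 0.90 * reps

    def test_degenerate_flagged(self):
        fits = {f"s{i}": _fit(1.5) for i in range(5)}
        _, summary = slope_population_analysis(fits)
        assert summary["degenerate"]

    def test_sign_counts(self):
        fits = {f"n{i}": _fit(-5.0, p=0.001) for i in range(10)}
        fits.update({f"p{i}": _fit(5.0, p=0.001) for i in range(2)})
        _, summary = slope_population_analysis(fits)
        assert summary["n_significant_negative"] == 10
        assert summary["n_significant_positive"] == 2

    def test_single_strain_rejected(self):
        with pytest.raises(ValueError):
            slope_population_analysis({"s": _fit(1.0)})


class TestSegments:
    def test_gene_exactly_at_oric_in_segment_1(self):
        assert segment_index(5000, 5000, 80_000, 8) == 1

    def test_segment_1_centred_on_oric(self):
        L, o = 80_000, 40_000
        half = L / 16
        assert segment_index(o - half + 1, o, L, 8) == 1
        assert segment_index(o + half - 1, o, L, 8) == 1
        assert segment_index(o + half + 1, o, L, 8) == 2
        assert segment_index(o - half - 1, o, L, 8) == 8

    def test_start_convention(self):
        assert segment_index(0, 0, 80_000, 8, centered=False) == 1
        assert segment_index(9_999, 0, 80_000, 8, centered=False) == 1
        assert segment_index(10_001, 0, 80_000, 8, centered=False) == 2

    def test_partition_conserves_genes(self):
        rng = np.random.default_rng(2)
        frames = [
            make_frame(rng.integers(0, 8, 160), oric=int(rng.integers(100_000)), strain=f"S{i}")
            for i in range(4)
        ]
        table, _, _ = segment_analysis(frames)
        for s, sub in table.groupby("strain"):
            assert sub["n_genes"].sum() == 160

    def test_uniform_scores_not_significant(self):
        rng = np.random.default_rng(8)
        frames = [
            make_frame(rng.normal(5, 1, 200), oric=int(rng.integers(100_000)), strain=f"S{i}")
            for i in range(6)
        ]
        _, anova_p, _ = segment_analysis(frames)
        assert anova_p > 0.05

    def test_invalid_segment_count_rejected(self):
        with pytest.raises(ValueError):
            segment_analysis([make_frame([1.0] * 40)], n_segments=1)


class TestThirds:
    def test_region_spanning_oric_in_third_1(self):
        r = RegionAnnotation(start=49_000, end=51_000, region_type="phage",
                             source="phaster", strain="S")
        frame = make_frame([1.0] * 30, length=100_000, oric=50_000, regions=[r])
        per_strain, _ = thirds_region_analysis([frame])
        row = per_strain[(per_strain["third"] == 1) & (per_strain["source"] == "phaster")]
        assert int(row["n_regions"].iloc[0]) == 1

    def test_counts_conserved_across_thirds(self):
        rng = np.random.default_rng(4)
        frames = []
        for i in range(5):
            regions = [
                RegionAnnotation(
                    start=int(s), end=int(s) + 2000, region_type="GI",
                    source="alienhunter", strain=f"S{i}",
                )
                for s in rng.integers(0, 98_000, size=7)
            ]
            frames.append(make_frame([1.0] * 30, regions=regions, strain=f"S{i}"))
        per_strain, _ = thirds_region_analysis(frames)
        assert per_strain.groupby("strain")["n_regions"].sum().eq(7).all()

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="source"):
            RegionAnnotation(start=0, end=10, region_type="GI", source="mystery")

    def test_oversized_region_rejected(self):
        r = RegionAnnotation(start=0, end=200_000, region_type="GI", source="alienhunter",
                             strain="S")
        frame = make_frame([1.0] * 30, length=100_000, regions=[r])
        with pytest.raises(ValueError, match="invalid"):
            thirds_region_analysis([frame])


class TestTukeyAgainstPermutationOracle:
    def test_three_group_toy(self):
        """Tukey HSD adjusted p-values track a permutation studentized-range oracle.

        The oracle permutes group labels 10,000 times and, for each pair,
        reports the fraction of permutations whose maximal pairwise studentized
        range exceeds the observed pair's statistic (single-step adjustment).
        Agreement is asserted to 0.05 absolute, covering Monte-Carlo noise and
        the normal-theory vs permutation difference at this sample size.
        """
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(17)
        groups = [rng.normal(0, 1, 8), rng.normal(0.9, 1, 8), rng.normal(1.6, 1, 8)]
        values = np.concatenate(groups)
        labels = np.repeat([0, 1, 2], 8)
        tk = pairwise_tukeyhsd(values, labels, alpha=0.05)
        tukey_p = {
            (int(r[0]), int(r[1])): float(r[3]) for r in tk.summary().data[1:]
        }

        def pair_stats(vals):
            ms = [vals[labels == g].mean() for g in range(3)]
            sse = sum(((vals[labels == g] - ms[g]) ** 2).sum() for g in range(3))
            mse = sse / (len(vals) - 3)
            se = np.sqrt(mse / 8)
            return {
                (a, b): abs(ms[a] - ms[b]) / se for a in range(3) for b in range(3) if a < b
            }

        obs = pair_stats(values)
        n_perm = 10_000
        exceed = {k: 0 for k in obs}
        v = values.copy()
        for _ in range(n_perm):
            rng.shuffle(v)
            qmax = max(pair_stats(v).values())
            for k, q in obs.items():
                exceed[k] += qmax >= q
        for k in obs:
            perm_p = exceed[k] / n_perm
            assert perm_p == pytest.approx(tukey_p[k], abs=0.05), k
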