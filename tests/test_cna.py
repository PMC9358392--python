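"""Copy number: binning, bias correction, segmentation, ACN fit, drivers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xenospot.cna import (
    AcnFit,
    acn_pipeline,
    bin_fragments,
    call_driver_cna,
    correct_counts,
    cosmic_call,
    fit_absolute,
    profile_correlation,
    project_to_bins,
    relative_from_absolute,
    segment_bins,
)
from xenospot.errors import CoordinateError, CorrectionError, CoverageError, FitError
from xenospot.genome import GenomeLayout, HUMAN_TOY
from xenospot.simulate import make_cn_profile, simulate_bin_annotation, simulate_fragment_pool

ONE_CHROM = GenomeLayout("one", {"c1": 30_000_000})


def human_frags(rows):
    return pd.DataFrame(
        [
            {
                "fragment_id": f"f{i}",
                "category": "human_specific",
                "chromosome": c,
                "start": s,
                "end": e,
                "fragment_length": e - s,
            }
            for i, (c, s, e) in enumerate(rows)
        ]
    )


class TestBinning:
    def test_single_fragment(self):
        bins = bin_fragments(human_frags([("c1", 100, 250)]), 30_000, ONE_CHROM)
        assert bins.loc[0, "raw_count"] == 1
        assert bins["raw_count"].sum() == 1

    def test_boundary_midpoint_goes_right(self):
        # midpoint exactly 30000 -> bin [30000, 60000)
        bins = bin_fragments(human_frags([("c1", 29_900, 30_100)]), 30_000, ONE_CHROM)
        assert bins.loc[1, "raw_count"] == 1
        assert bins.loc[0, "raw_count"] == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(CoordinateError):
            bin_fragments(human_frags([("c1", 29_999_990, 30_000_050)]), 30_000, ONE_CHROM)

    def test_conservation_and_poisson_envelope(self):
        rng = np.random.default_rng(4)
        n = 100_000
        starts = rng.integers(0, 30_000_000 - 200, n)
        frags = pd.DataFrame(
            {
                "fragment_id": np.arange(n).astype(str),
                "category": "human_specific",
                "chromosome": "c1",
                "start": starts,
                "end": starts + 160,
                "fragment_length": 160,
            }
        )
        bins = bin_fragments(frags, 30_000, ONE_CHROM)
        assert bins["raw_count"].sum() == n
        mean = n / len(bins)
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], mean)
        inside = bins["raw_count"].between(lo, hi).mean()
        # 99.9% envelope per bin; allow a small number of excursions
        assert inside >= 0.995


class TestCorrection:
    def flat_bins(self, n=500, count=100.0):
        return pd.DataFrame(
            {
                "chromosome": "c1",
                "start": np.arange(n) * 30_000,
                "end": (np.arange(n) + 1) * 30_000,
                "raw_count": count,
                "gc": 0.45,
                "mappability": 0.95,
            }
        )

    def test_single_stratum_proportional_to_raw(self):
        bins = self.flat_bins()
        rng = np.random.default_rng(0)
        bins["raw_count"] = rng.poisson(100, len(bins)).astype(float)
        out = correct_counts(bins)
        ratio = out["corrected"] / out["raw_count"]
        assert np.allclose(ratio, ratio.iloc[0])
        assert out.loc[out["usable"], "corrected"].mean() == pytest.approx(1.0)

    def test_gc_bias_injection_halves_cv(self):
        """Multiplicative GC bias on flat copy number: correction removes it."""
        rng = np.random.default_rng(1)
        n = 2000
        gc = np.clip(rng.normal(0.45, 0.07, n), 0.25, 0.65)
        bias = 1.0 + 2.5 * (gc - 0.45) ** 2 * 20  # strong quadratic GC effect
        counts = rng.poisson(100 * bias)
        bins = pd.DataFrame(
            {
                "chromosome": "c1",
                "start": np.arange(n) * 30_000,
                "end": (np.arange(n) + 1) * 30_000,
                "raw_count": counts.astype(float),
                "gc": gc,
                "mappability": np.clip(rng.normal(0.95, 0.02, n), 0.6, 1.0),
            }
        )
        pre_cv = bins["raw_count"].std() / bins["raw_count"].mean()
        out = correct_counts(bins)
        usable = out.loc[out["usable"], "corrected"]
        post_cv = usable.std() / usable.mean()
        assert post_cv <= pre_cv / 2

    def test_unusable_bins_excluded(self):
        bins = self.flat_bins(100)
        bins.loc[:9, "mappability"] = 0.1  # below floor
        bins.loc[:9, "raw_count"] = 10_000.0  # would wreck medians if counted
        out = correct_counts(bins)
        assert out.loc[:9, "usable"].eq(False).all()
        assert out.loc[:9, "corrected"].isna().all()
        assert out.loc[out["usable"], "corrected"].mean() == pytest.approx(1.0)

    def test_all_unusable_is_error(self):
        bins = self.flat_bins(20)
        bins["mappability"] = 0.0
        with pytest.raises(CorrectionError):
            correct_counts(bins)


class TestSegmentation:
    def bins_from_values(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "chromosome": "c1",
                "start": np.arange(n) * 30_000,
                "end": (np.arange(n) + 1) * 30_000,
                "corrected": values,
                "usable": True,
            }
        )

    def test_constant_signal_one_segment(self):
        segs = segment_bins(self.bins_from_values(np.ones(200)))
        assert len(segs) == 1
        assert segs.loc[0, "n_bins"] == 200

    def test_two_steps_recovered(self):
        rng = np.random.default_rng(2)
        truth = np.concatenate([np.ones(60), np.ones(60) * 2.0, np.ones(60)])
        segs = segment_bins(self.bins_from_values(truth + rng.normal(0, 0.1, 180)))
        assert len(segs) == 3
        starts = segs["start"].to_numpy() // 30_000
        assert abs(starts[1] - 60) <= 2 and abs(starts[2] - 120) <= 2

    def test_single_step_replicates(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = np.concatenate([np.ones(50), np.ones(50) * 2.0]) + rng.normal(0, 0.1, 100)
            segs = segment_bins(self.bins_from_values(values))
            breaks = segs["start"].to_numpy()[1:] // 30_000
            hits += len(breaks) == 1 and abs(breaks[0] - 50) <= 2
        assert hits >= 19

    def test_chromosomes_segmented_independently(self):
        a = self.bins_from_values(np.ones(50))
        b = self.bins_from_values(np.ones(50) * 3.0)
        b["chromosome"] = "c2"
        segs = segment_bins(pd.concat([a, b], ignore_index=True))
        assert len(segs) == 2
        assert set(segs["chromosome"]) == {"c1", "c2"}


def synthetic_segments(copies, weights):
    return pd.DataFrame(
        {
            "chromosome": "c1",
            "start": np.arange(len(copies)) * 1_000_000,
            "end": (np.arange(len(copies)) + 1) * 1_000_000,
            "n_bins": weights,
            "relative_value": np.asarray(copies, dtype=float),
        }
    )


class TestAbsoluteFit:
    def test_diploid_identity(self):
        segs = synthetic_segments([1.0, 1.0], [50, 50])
        fit = fit_absolute(segs)
        assert (fit.ploidy, fit.cellularity) == (2.0, 1.0)
        assert fit.goodness == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.segments["absolute_value"], 2.0)

    @pytest.mark.parametrize(
        "psi, c, copies, weights",
        [
            (2.0, 1.0, [1, 2, 3], [10, 80, 10]),
            (3.4, 1.0, [3, 4], [60, 40]),
            (2.8, 0.6, [2, 3], [20, 80]),
        ],
    )
    def test_round_trip(self, psi, c, copies, weights):
        rel = relative_from_absolute(np.array(copies, dtype=float), psi, c)
        segs = synthetic_segments(rel, weights)
        grid = None if c == 1.0 else np.round(np.arange(0.1, 1.0 + 1e-9, 0.01), 10)
        fit = fit_absolute(segs, cellularity_grid=grid)
        assert abs(fit.ploidy - psi) <= 0.05 + 1e-9
        assert abs(fit.cellularity - c) <= 0.01 + 1e-9
        assert fit.goodness == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.segments["absolute_value"], copies, atol=1e-6)

    def test_guide_ploidy_constrains_search(self):
        segs = synthetic_segments([1.0, 1.0], [50, 50])
        fit = fit_absolute(segs, guide_ploidy=3.4)
        assert 2.9 <= fit.ploidy <= 3.9

    def test_flat_profile_resolves_to_diploid(self):
        """Ploidy-unidentifiable flat profiles take the lowest integer fit."""
        segs = synthetic_segments([1.0], [100])
        fit = fit_absolute(segs)
        assert fit.ploidy == 2.0

    def test_goodness_zero_iff_integer(self):
        rel = relative_from_absolute(np.array([2.0, 3.0]), 2.5, 1.0)
        segs = synthetic_segments(rel, [50, 50])
        exact = fit_absolute(segs, ploidy_grid=[2.5])
        assert exact.goodness == pytest.approx(0.0, abs=1e-12)
        off = fit_absolute(segs, ploidy_grid=[2.52])
        assert off.goodness > 0

    def test_empty_segments_rejected(self):
        with pytest.raises(FitError):
            fit_absolute(synthetic_segments([], []))


class TestDriverCalls:
    @pytest.mark.parametrize(
        "psi, tcn, expected",
        [
            (2.0, 5.0, "gain"),
            (2.7, 5.0, "gain"),
            (3.0, 8.0, "none"),
            (2.8, 9.0, "gain"),
            (2.0, 0.0, "loss"),
            (3.5, 0.7, "loss"),   # 0.7 < 3.5 - 2.7 = 0.8
            (3.5, 0.8, "none"),
        ],
    )
    def test_rule_table(self, psi, tcn, expected):
        assert cosmic_call(psi, tcn) == expected

    def test_gain_monotone_in_tcn(self):
        for psi in (2.0, 2.7, 2.71, 3.5, 5.0):
            calls = [cosmic_call(psi, t) for t in np.linspace(0.0, 15.0, 151)]
            first_gain = next((i for i, c in enumerate(calls) if c == "gain"), None)
            assert first_gain is not None
            assert all(c == "gain" for c in calls[first_gain:])

    def test_gene_level_weighted_mean(self):
        segs = synthetic_segments([1.0, 1.0], [50, 50])
        segs["absolute_value"] = [4.0, 8.0]
        fit = AcnFit(ploidy=2.0, cellularity=1.0, goodness=0.0, segments=segs)
        # gene spans 0.5 Mb of segment 1 and 1 Mb of segment 2 -> (0.5*4 + 1*8)/1.5
        genes = pd.DataFrame(
            {"chromosome": ["c1"], "start": [500_000], "end": [2_000_000], "name": ["MYC"]}
        )
        calls = call_driver_cna(fit, genes)
        assert calls.loc[0, "total_copy_number"] == pytest.approx((0.5 * 4 + 1 * 8) / 1.5)
        assert calls.loc[0, "call"] == "gain"

    def test_uncovered_region_rejected(self):
        segs = synthetic_segments([1.0], [10])
        fit = AcnFit(2.0, 1.0, 0.0, segs.assign(absolute_value=2.0))
        genes = pd.DataFrame(
            {"chromosome": ["c9"], "start": [0], "end": [1000], "name": ["GENE"]}
        )
        with pytest.raises(CoverageError):
            call_driver_cna(fit, genes)


class TestProfileCorrelation:
    def make_fit(self, values, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        segs = synthetic_segments(np.ones(len(values)), np.full(len(values), 10))
        segs["absolute_value"] = np.asarray(values, dtype=float) + rng.normal(0, noise, len(values))
        return AcnFit(2.0, 1.0, 0.0, segs)

    def test_identical_profiles(self):
        values = [2, 3, 2, 4, 1, 2, 5, 2, 3, 2]
        layout = GenomeLayout("t", {"c1": 10_000_000})
        r, p = profile_correlation(self.make_fit(values), self.make_fit(values), layout)
        assert r == pytest.approx(1.0)

    def test_flat_profile_undefined(self):
        layout = GenomeLayout("t", {"c1": 10_000_000})
        r, p = profile_correlation(self.make_fit([2] * 10), self.make_fit([2, 3] * 5), layout)
        assert np.isnan(r)

    def test_noise_attenuation_envelope(self):
        """Independent noise on a shared truth attenuates r toward
        var_t / (var_t + sigma^2); check against a simulation envelope."""
        rng = np.random.default_rng(7)
        layout = GenomeLayout("t", {"c1": 40_000_000})
        truth = rng.choice([1.0, 2.0, 3.0, 4.0], 40)
        sigma = 0.5
        expected_r = truth.var() / (truth.var() + sigma**2)
        rs = []
        for seed in range(40):
            a = self.make_fit(truth, noise=sigma, seed=2 * seed)
            b = self.make_fit(truth, noise=sigma, seed=2 * seed + 1)
            rs.append(profile_correlation(a, b, layout, bin_width=1_000_000)[0])
        assert abs(np.mean(rs) - expected_r) < 0.1


class TestPipeline:
    def test_min_fragment_guard(self):
        frags = simulate_fragment_pool(1_000, "human", seed=1)
        anno = simulate_bin_annotation(HUMAN_TOY, 30_000, seed=0)
        with pytest.raises(FitError, match="500000"):
            acn_pipeline(frags, anno, HUMAN_TOY)

    def test_end_to_end_recovers_profile(self):
        """Fragments drawn from an aberrant profile -> correct ploidy and
        segment copy numbers through the full pipeline."""
        profile = make_cn_profile(
            [("hchr1", 0, 10_000_000, 3), ("hchr2", 5_000_000, 20_000_000, 1)]
        )
        frags = simulate_fragment_pool(600_000, "human", seed=5, cn_profile=profile)
        anno = simulate_bin_annotation(HUMAN_TOY, 30_000, seed=0)
        fit = acn_pipeline(frags, anno, HUMAN_TOY, guide_ploidy=2.0)
        projected = project_to_bins(fit, HUMAN_TOY, bin_width=30_000)
        merged = projected.merge(
            profile, on=["chromosome", "start", "end"], suffixes=("", "_truth")
        )
        merged = merged.dropna(subset=["absolute_value"])
        match = (merged["absolute_value"].round() == merged["copies"]).mean()
        assert match >= 0.95
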