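"""Phenotype quantifications: worked numeric examples and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from feastfamine.phenotypes import (
    CellSizeSample,
    CodingSequence,
    PolysomeTrace,
    budding_reduction,
    cai_profile,
    large_cell_stats,
    normalize_luciferase,
    polysome_monosome_ratio,
    relative_adaptiveness,
    screen_zscore_differential,
    sphere_volume_stats,
)


class TestLargeCells:
    def test_gaussian_naive_fraction_is_upper_tail_of_one_sd(self):
        rng = np.random.default_rng(0)
        naive = CellSizeSample(rng.normal(22.0, 3.0, 200_000), "naive")
        _, fracs = large_cell_stats(naive, naive)
        assert fracs["naive"] == pytest.approx(1 - stats.norm.cdf(1), abs=5e-3)

    def test_one_sd_shift_puts_half_above_threshold(self):
        rng = np.random.default_rng(1)
        base = rng.normal(22.0, 3.0, 100_000)
        naive = CellSizeSample(base, "naive")
        sd = np.std(base, ddof=1)
        shifted = CellSizeSample(base + sd, "test")
        _, fracs = large_cell_stats(naive, shifted)
        assert fracs["test"] == pytest.approx(0.5, abs=5e-3)

    def test_fractions_invariant_under_unit_rescaling(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(3.0, 0.3, 5000)
        b = rng.lognormal(3.1, 0.3, 5000)
        _, f1 = large_cell_stats(CellSizeSample(a), CellSizeSample(b))
        _, f2 = large_cell_stats(CellSizeSample(a * 1e6), CellSizeSample(b * 1e6))
        assert f1 == f2

    def test_degenerate_naive_sample_rejected(self):
        with pytest.raises(ValueError):
            large_cell_stats(CellSizeSample([5.0, 5.0]), CellSizeSample([6.0]))
        with pytest.raises(ValueError):
            CellSizeSample([])


class TestSphereVolume:
    def test_measured_mean_areas_give_23_percent_volume_gap(self):
        ra, rb, pct = sphere_volume_stats(22.01, 25.36)
        assert ra == pytest.approx(2.65, abs=0.01)
        assert rb == pytest.approx(2.84, abs=0.01)
        assert pct == pytest.approx(23.0, abs=1.0)

    def test_equal_and_eightfold_cases(self):
        assert sphere_volume_stats(10.0, 10.0)[2] == pytest.approx(0.0, abs=1e-12)
        ra, rb, pct = sphere_volume_stats(np.pi, 4 * np.pi)
        assert (ra, rb) == (pytest.approx(1.0), pytest.approx(2.0))
        assert pct == pytest.approx(700.0, rel=1e-12)

    def test_inverse_symmetry(self):
        p_ab = sphere_volume_stats(22.01, 25.36)[2]
        p_ba = sphere_volume_stats(25.36, 22.01)[2]
        assert (1 + p_ab / 100) * (1 + p_ba / 100) == pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            sphere_volume_stats(0.0, 10.0)


class TestBuddingReduction:
    def test_measured_g1_fractions_give_quarter_reduction(self):
        assert budding_reduction(36.2, 27.2) == pytest.approx(24.86, abs=0.01)

    def test_trivial_cases(self):
        assert budding_reduction(50.0, 50.0) == 0.0
        assert budding_reduction(50.0, 25.0) == 50.0
        with pytest.raises(ValueError):
            budding_reduction(0.0, 10.0)


def _gaussian_trace(mono_area=1.0, poly_areas=(1.6, 1.0, 0.6), offset=0.0, scale=1.0):
    x = np.linspace(0, 60, 1200)
    sd = 0.9
    y = np.full_like(x, 0.05)
    centers = {"monosome": 18.0, "disome": 25.0}
    areas = {"monosome": mono_area, "disome": 0.8}
    for i, a in enumerate(poly_areas):
        centers[f"polysome_{i + 1}"] = 31.0 + 5.0 * i
        areas[f"polysome_{i + 1}"] = a
    for k, c in centers.items():
        y = y + areas[k] / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - c) / sd) ** 2)
    regions = {k: (c - 2.5 * sd, c + 2.5 * sd) for k, c in centers.items()}
    return PolysomeTrace(x, (y + offset) * scale, regions=regions)


class TestPolysomeRatio:
    def test_constructed_peak_areas_recovered(self):
        trace = _gaussian_trace()
        assert polysome_monosome_ratio(trace) == pytest.approx(3.2, abs=0.05)

    def test_zero_polysome_signal_gives_zero(self):
        trace = _gaussian_trace(poly_areas=(0.0, 0.0))
        assert polysome_monosome_ratio(trace) == pytest.approx(0.0, abs=1e-6)

    def test_flat_trace_rejected(self):
        x = np.linspace(0, 60, 600)
        trace = PolysomeTrace(
            x, np.full_like(x, 0.05),
            regions={"monosome": (15, 21), "disome": (22, 28), "polysome_1": (29, 50)},
        )
        with pytest.raises(ValueError):
            polysome_monosome_ratio(trace)

    def test_offset_and_scale_invariance(self):
        base = polysome_monosome_ratio(_gaussian_trace())
        shifted = polysome_monosome_ratio(_gaussian_trace(offset=0.7))
        scaled = polysome_monosome_ratio(_gaussian_trace(scale=12.0))
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_missing_annotation_rejected(self):
        trace = _gaussian_trace()
        broken = PolysomeTrace(
            trace.positions, trace.absorbance,
            regions={k: v for k, v in trace.regions.items() if k != "disome"},
        )
        with pytest.raises(ValueError):
            polysome_monosome_ratio(broken)


def _plate(fold=1.5, n=4):
    rows = []
    for genotype, f in (("naive", 1.0), ("prion", fold)):
        for i in range(n):
            renilla = 1e5 * (1 + 0.1 * i)
            rows.append({"genotype": genotype, "variant": "rare", "well": i,
                         "firefly": 0.2 * f * renilla, "renilla": renilla})
    return pd.DataFrame(rows)


class TestLuciferase:
    def test_exact_fold_recovered_noiselessly(self):
        out = normalize_luciferase(_plate(1.5))
        by = out.set_index("genotype")["normalized"]
        assert by["naive"] == pytest.approx(1.0, rel=1e-12)
        assert by["prion"] == pytest.approx(1.5, rel=1e-12)

    def test_identical_genotypes_both_unity(self):
        out = normalize_luciferase(_plate(1.0))
        assert np.allclose(out["normalized"], 1.0)

    def test_zero_renilla_rejected(self):
        plate = _plate()
        plate.loc[0, "renilla"] = 0.0
        with pytest.raises(ValueError):
            normalize_luciferase(plate)

    def test_missing_naive_wells_rejected(self):
        plate = _plate()
        with pytest.raises(ValueError):
            normalize_luciferase(plate[plate["genotype"] == "prion"])


def _screen_frame(values: dict[str, np.ndarray], n_rep=3):
    rows = []
    for background, matrix in values.items():
        for r in range(n_rep):
            for p in range(matrix.shape[0]):
                rows.append({"protein": f"P{p}", "background": background,
                             "replicate": f"r{r}", "value": matrix[p, r]})
    return pd.DataFrame(rows)


class TestScreen:
    def test_zscores_have_mean_zero_sd_one_per_replicate(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(5, 1, 40)
        vals = {"naive": np.outer(base, [1, 1.2, 0.9]),
                "prion": np.outer(base, [1.1, 1, 1.3])}
        out = screen_zscore_differential(_screen_frame(vals))
        # per-protein means of per-replicate Z-scores themselves average to 0
        assert out["z_naive"].mean() == pytest.approx(0.0, abs=1e-10)
        assert out["z_test"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_constructed_shift_called_up(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(5, 1, 50)
        shifted = base.copy()
        shifted[7] += 2.0 * np.std(base, ddof=1)
        vals = {"naive": np.outer(base, np.ones(3)),
                "prion": np.outer(shifted, np.ones(3))}
        out = screen_zscore_differential(_screen_frame(vals))
        assert out.loc["P7", "call"] == "up"
        assert (out["call"] == "up").sum() == 1
        assert out.loc["P7", "delta_z"] == pytest.approx(2.0, abs=0.1)

    def test_gain_invariance(self):
        rng = np.random.default_rng(5)
        base = rng.lognormal(5, 1, 30)
        vals = {"naive": np.outer(base, np.ones(3)),
                "prion": np.outer(base, np.ones(3))}
        gained = {"naive": vals["naive"] * np.array([1.0, 3.0, 0.5]),
                  "prion": vals["prion"] * np.array([2.0, 1.0, 4.0])}
        a = screen_zscore_differential(_screen_frame(vals))
        b = screen_zscore_differential(_screen_frame(gained))
        assert np.allclose(a["delta_z"], b["delta_z"], atol=1e-10)

    def test_constant_replicate_rejected(self):
        vals = {"naive": np.ones((20, 3)), "prion": np.ones((20, 3))}
        with pytest.raises(ValueError):
            screen_zscore_differential(_screen_frame(vals))


WEIGHTS = {"AAA": 1.0, "AAG": 0.25, "GGT": 0.5, "TTT": 1.0}


class TestCAI:
    def test_all_optimal_codons_give_unit_cai(self):
        seq = CodingSequence("AAA" * 20, "opt")
        profile = cai_profile([seq], WEIGHTS, window=5)
        assert np.allclose(profile["mean_cai"], 1.0)

    def test_constant_weight_profile(self):
        seq = CodingSequence("GGT" * 15, "half")
        profile = cai_profile([seq], WEIGHTS, window=7)
        assert np.allclose(profile["mean_cai"], 0.5)

    def test_two_codon_window_geometric_mean(self):
        seq = CodingSequence("AAGAAA", "pair")  # weights 0.25 then 1.0
        profile = cai_profile([seq], WEIGHTS, window=2)
        assert profile["mean_cai"].iloc[0] == pytest.approx(0.5)

    def test_profile_bounded_and_short_sequences_drop_out(self):
        seqs = [CodingSequence("AAGAAAAAG", "a"), CodingSequence("TTTAAA", "b")]
        profile = cai_profile(seqs, WEIGHTS, window=1)
        assert profile["n_sequences"].tolist() == [2, 2, 1]
        assert ((profile["mean_cai"] > 0) & (profile["mean_cai"] <= 1)).all()

    def test_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            CodingSequence("AAAA", "bad-length")
        with pytest.raises(ValueError):
            cai_profile([CodingSequence("CCC", "c")], WEIGHTS, window=1)

    def test_trailing_stop_codon_ignored(self):
        seq = CodingSequence("AAATAA", "with-stop")
        profile = cai_profile([seq], WEIGHTS, window=1)
        assert len(profile) == 1

    def test_relative_adaptiveness_sharp_li(self):
        usage = {"AAA": 60.0, "AAG": 15.0}  # lysine family
        w = relative_adaptiveness(usage)
        assert w["AAA"] == 1.0
        assert w["AAG"] == pytest.approx(0.25)
        assert all(0 < v <= 1 for v in w.values())
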