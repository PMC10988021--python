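"""MIC calling, DiSC traces, zone/competition arithmetic, t-test oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from elasuite.assays_stats import (
    AssayMatrix,
    DiscSummary,
    competition_abundance,
    classify_morphology,
    disc_summary,
    mic_call,
    mic_fold_change,
    star_class,
    ttest,
    zone_area,
)

CONC = [0.25, 0.5, 1, 2, 4, 8, 16, 32, 64, 128]


def growth_below(mic):
    return np.array([[c < mic for c in CONC]]).T


class TestMicCall:
    def test_first_clear_well(self):
        assert mic_call(CONC, growth_below(1)).value == "1"

    def test_all_growth_reports_above_max(self):
        assert mic_call(CONC, np.ones((len(CONC), 1), bool)).value == ">128"

    def test_replicate_disagreement_reports_range(self):
        two = np.column_stack([growth_below(16), growth_below(32)])
        assert mic_call(CONC, two).value == "16–32"

    def test_fold_change_of_passaged_strain(self):
        parent = mic_call(CONC, growth_below(1))
        passaged = mic_call(CONC, growth_below(8))
        fold = mic_fold_change(passaged.per_replicate[0], parent.per_replicate[0])
        assert fold == 8.0

    def test_od_matrix_thresholding(self):
        od = np.array([[0.8 if c < 4 else 0.01] for c in CONC])
        assert mic_call(CONC, od, od_threshold=0.05).value == "4"

    def test_non_monotone_flagged_at_highest_transition(self):
        col = np.array([[True], [False], [True], [False], [False]])
        result = mic_call([1, 2, 4, 8, 16], col)
        assert result.nonmonotone
        assert result.value == "8"

    def test_non_increasing_concentrations_rejected(self):
        with pytest.raises(ValueError):
            mic_call([1, 1, 2], np.ones((3, 1), bool))

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(scale=st.floats(0.1, 50.0), mic_idx=st.integers(1, 9))
    def test_scale_equivariance(self, scale, mic_idx):
        growth = np.array([[i < mic_idx for i in range(len(CONC))]]).T
        base = mic_call(CONC, growth).per_replicate[0]
        scaled = mic_call([c * scale for c in CONC], growth).per_replicate[0]
        assert scaled == pytest.approx(base * scale)


class TestDiscSummary:
    def make_trace(self, tau=0.5, step=500.0, t_add=10.0):
        t = np.arange(0, 30, 0.25)
        v = np.where(t < t_add, 100.0, 100.0 + step * (1 - np.exp(-(t - t_add) / tau)))
        return t, v

    def test_flat_trace_zero_release(self):
        t = np.arange(0, 30, 0.5)
        s = disc_summary(t, np.full_like(t, 100.0), 10.0)
        assert s.release == 0.0
        assert s.baseline_stable

    def test_exponential_step_plateau_within_two_minutes(self):
        t, v = self.make_trace()
        s = disc_summary(t, v, addition_time=10.0)
        assert s.time_to_plateau is not None
        assert s.time_to_plateau <= 2.0
        assert s.release == pytest.approx(500.0, rel=0.05)
        assert s.baseline == pytest.approx(100.0)

    def test_monotone_drift_has_no_plateau(self):
        t = np.arange(0, 30, 0.25)
        s = disc_summary(t, t * 50.0, 10.0)
        assert s.time_to_plateau is None
        assert np.isnan(s.release)

    def test_no_baseline_samples_rejected(self):
        with pytest.raises(ValueError):
            disc_summary([10.0, 11.0], [1.0, 2.0], addition_time=5.0)


class TestZoneAndCompetition:
    def test_zone_subtraction(self):
        assert zone_area(120.0, 20.0) == 100.0
        assert zone_area(20.0, 20.0) == 0.0

    def test_spot_larger_than_total_rejected(self):
        with pytest.raises(ValueError):
            zone_area(20.0, 21.0)

    def test_percent_abundance(self):
        assert competition_abundance(43, 57) == pytest.approx(43.0)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            competition_abundance(0, 0)

    @pytest.mark.parametrize("frac_cocci,tol", [(0.01, 0.5), (0.43, 2.0)])
    def test_planted_mixture_recovered_from_scene(self, frac_cocci, tol):
        """Mixed-morphology scene: cocci (aspect ~1) vs rods, classified by
        aspect ratio, recovers the planted mixing fraction."""
        from elasuite.cell_quant import segment_cells
        from elasuite.synth_images import Cell, CellScene, render_cells
        rng = np.random.default_rng(17)
        n = 200
        n_cocci = int(round(frac_cocci * n))
        cells = []
        side = 15
        for k in range(n):
            i, j = divmod(k, side)
            center = (2.5 + j * 4.4, 2.5 + i * 4.4)
            ang = rng.uniform(0, np.pi)
            if k < n_cocci:
                cells.append(Cell(center, ang, 0.95, 0.85, 100.0))
            else:
                cells.append(Cell(center, ang, rng.uniform(2.0, 2.8),
                                  rng.uniform(0.6, 0.8), 100.0))
        scene = CellScene(shape=(1380, 1380), cells=tuple(cells),
                          gaussian_noise=2.0, poisson=True, seed=18)
        img, _ = render_cells(scene)
        _, records = segment_cells(img)
        assert len(records) == n
        rods, cocci = classify_morphology(records)
        assert competition_abundance(cocci, rods) == pytest.approx(
            100.0 * frac_cocci, abs=tol)


def ttest_oracle(a, b):
    """Textbook pooled-variance formulas, independent of the implementation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


class TestTTest:
    def test_identical_groups(self):
        r = ttest([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.p == 1.0 and r.stars == "ns"

    def test_constant_equal_groups_degenerate(self):
        r = ttest([5, 5, 5], [5, 5, 5])
        assert r.p == 1.0 and r.stars == "ns"

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_closed_form_oracle_to_6_decimals(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 15))
        b = rng.normal(0.5, 1.4, rng.integers(3, 15))
        r = ttest(a, b)
        t_o, p_o = ttest_oracle(a, b)
        assert r.t == pytest.approx(t_o, abs=1e-6)
        assert r.p == pytest.approx(p_o, abs=1e-6)

    def test_welch_flag_matches_scipy(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 3, 7)
        r = ttest(a, b, welch=True)
        ref = sps.ttest_ind(a, b, equal_var=False)
        assert r.t == pytest.approx(ref.statistic, abs=1e-9)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_ci_covers_true_difference(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(200):
            a = rng.normal(1.0, 1.0, 12)
            b = rng.normal(0.0, 1.0, 12)
            r = ttest(a, b)
            hits += r.ci_low <= 1.0 <= r.ci_high
        assert 0.90 <= hits / 200 <= 0.99

    def test_null_p_uniformity_ks(self):
        rng = np.random.default_rng(11)
        ps = [ttest(rng.normal(0, 1, 20), rng.normal(0, 1, 20)).p
              for _ in range(2000)]
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ttest([1.0], [1.0, 2.0])


class TestStarBins:
    @pytest.mark.parametrize("p,stars", [
        (0.5, "ns"), (0.051, "ns"), (0.05, "ns"),
        (0.03, "*"), (0.0100001, "*"),
        (0.01, "**"), (0.002, "**"),
        (0.001, "***"), (0.0002, "***"),
        (0.0001, "****"), (1e-8, "****"), (0.0, "****"), (1.0, "ns"),
    ])
    def test_legend_mapping(self, p, stars):
        assert star_class(p) == stars

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(p=st.floats(0.0, 1.0, allow_nan=False))
    def test_total_and_monotone(self, p):
        order = ["****", "***", "**", "*", "ns"]
        s = star_class(p)
        assert s in order
        # more significant p never maps to a less significant bin
        assert order.index(star_class(p / 2)) <= order.index(s)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            star_class(1.5)


def test_assay_matrix_rejects_non_finite():
    import pandas as pd
    with pytest.raises(ValueError):
        AssayMatrix(pd.DataFrame({"w1": [1.0, np.nan]}))
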