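import numpy as np
import pandas as pd
import pytest

from qppdyn import (
    MotifSpec,
    preprocess_chain,
    build_null_ensemble,
    compare_timings,
    extract_peak_timings,
    make_phantom_atlas,
    refine_template,
    rss,
    significant_voxels,
    simulate_series,
)
from qppdyn.qpp_extract import QPP

LONG_AMPS = {"D1": -1.0, "D2": -1.0, "D3": -1.0, "L1": 1.0, "L2": 1.0, "L3": 1.0}
SIX = ["D1", "D2", "D3", "L1", "L2", "L3"]


@pytest.fixture(scope="module")
def long_fixture():
    """Long-window motif fixture, preprocessed without GSR.

    The phantom has no global nuisance signal, so regressing the mask mean
    would only re-inject the motif's lag-imbalance residual into every voxel
    and squash inter-regional lags; the timing analysis therefore runs on the
    filter + detrend + variance-normalise chain.
    """
    atlas, mask = make_phantom_atlas((20, 20, 4), 3)
    motif = MotifSpec(window=20, region_amplitudes=dict(LONG_AMPS),
                      region_lags={"L2": 2.0})
    series, gt = simulate_series(atlas, mask, [motif], 1.0,
                                 n_subjects=6, n_frames=1200, seed=19)
    series = preprocess_chain(series, steps=("filter", "qdt", "zvar"))
    qpp = refine_template(series, gt.occurrences["sub01"][0][0], 20)
    return atlas, mask, series, gt, qpp


class TestRss:
    def test_three_four_five(self):
        assert rss(np.array([[3.0, 4.0]]))[0] == pytest.approx(5.0)

    def test_zero_voxel(self):
        assert rss(np.zeros((1, 20)))[0] == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        tpl = rng.normal(size=(40, 20))
        expect = np.array([np.sqrt(sum(x * x for x in row)) for row in tpl])
        np.testing.assert_allclose(rss(tpl), expect, atol=1e-12)


class TestNullEnsemble:
    def test_constraints_and_determinism(self, long_fixture):
        _, _, series, _, qpp = long_fixture
        nulls = build_null_ensemble(series, qpp, n_null=10, seed=3)
        assert len(nulls.null_templates) == 10
        occ = set()
        for o in qpp.occurrences:
            occ.update(range(o, o + 20))
        for starts in nulls.segment_starts:
            # per-subject quota matches occurrence counts; no overlaps
            frames = set()
            for s in starts:
                seg = set(range(s, s + 20))
                assert not seg & occ, "null segment overlaps an occurrence"
                assert not seg & frames, "null segments overlap each other"
                frames |= seg
            for sid, s0, n in series.subjects:
                quota = int(np.sum((qpp.occurrences >= s0) & (qpp.occurrences < s0 + n)))
                got = int(np.sum((starts >= s0) & (starts < s0 + n)))
                assert got == quota
        again = build_null_ensemble(series, qpp, n_null=10, seed=3)
        for a, b in zip(nulls.null_templates, again.null_templates):
            np.testing.assert_array_equal(a, b)

    def test_no_occurrences_errors(self, long_fixture):
        _, _, series, _, _ = long_fixture
        empty = QPP(template=np.zeros((series.n_voxels, 20)), window=20,
                    stc=np.zeros(series.n_frames - 19),
                    occurrences=np.array([], dtype=int))
        with pytest.raises(ValueError, match="no occurrences"):
            build_null_ensemble(series, empty, seed=0)

    def test_infeasible_quota_errors(self, long_fixture):
        _, _, series, _, _ = long_fixture
        # occurrences tiling a subject leave no room for its null segments
        occ = np.arange(0, 1200 - 20, 20)
        full = QPP(template=np.zeros((series.n_voxels, 20)), window=20,
                   stc=np.zeros(series.n_frames - 19), occurrences=occ)
        with pytest.raises(RuntimeError, match="exhausted"):
            build_null_ensemble(series, full, n_null=1, seed=0)


class TestSignificantVoxels:
    def test_strict_exceedance(self, long_fixture):
        atlas, _, series, _, _ = long_fixture
        from qppdyn.peak_timing import NullEnsemble
        V = series.n_voxels
        tpl = np.full((V, 20), 0.1)
        nulls = NullEnsemble(n_null=2, null_templates=[tpl.copy(), tpl.copy()],
                             segment_starts=[], rng_seed=0)
        qpp = QPP(template=tpl.copy(), window=20,
                  stc=np.zeros(series.n_frames - 19),
                  occurrences=np.array([0], dtype=int))
        # real RSS equals every null RSS -> nothing strictly exceeds
        df = significant_voxels(qpp, nulls, atlas, SIX, series)
        assert len(df) == 0

    def test_motif_voxels_detected(self, long_fixture):
        atlas, _, series, gt, qpp = long_fixture
        nulls = build_null_ensemble(series, qpp, n_null=20, seed=5)
        df = significant_voxels(qpp, nulls, atlas, SIX, series)
        motif_vox = set(np.flatnonzero(np.abs(gt.templates[0]).sum(axis=1) > 0))
        sensitivity = len(set(df["voxel"]) & motif_vox) / len(motif_vox)
        assert sensitivity > 0.9


class TestPeakTimings:
    def test_noiseless_analytic_argmax(self, small_phantom):
        atlas, mask = small_phantom
        # fractional lags make the sampled argmax of the symmetric
        # half-sine lobe unique (otherwise frames 4 and 5 tie exactly)
        motif = MotifSpec(window=20,
                          region_amplitudes={"D1": -1.0, "L1": 1.0},
                          region_lags={"D1": 0.25, "L1": 0.25})
        series, gt = simulate_series(atlas, mask, [motif], 0.8,
                                     n_subjects=2, n_frames=600,
                                     noise_sd=1e-9, seed=23)
        qpp = refine_template(series, gt.occurrences["sub01"][0][0], 20)
        tpl = gt.templates[0]
        vox = np.flatnonzero(np.abs(tpl).sum(axis=1) > 0)
        voxels = pd.DataFrame({"voxel": vox, "region": "x"})
        out = extract_peak_timings(series, qpp, voxels)
        # analytic argmax of the half-sine lobes: frame 4 or 5 (peak at 4.5),
        # sampled maximum is frame 4 (earliest tie); second lobe at 14
        expect1 = np.array([np.argmax(np.abs(tpl[v, :10])) for v in vox])
        expect2 = np.array([10 + np.argmax(np.abs(tpl[v, 10:])) for v in vox])
        np.testing.assert_allclose(out["peak1"], expect1, atol=1e-9)
        np.testing.assert_allclose(out["peak2"], expect2, atol=1e-9)

    def test_lag_recovered(self, long_fixture):
        atlas, _, series, gt, qpp = long_fixture
        nulls = build_null_ensemble(series, qpp, n_null=20, seed=5)
        voxels = significant_voxels(qpp, nulls, atlas, SIX, series)
        out = extract_peak_timings(series, qpp, voxels)
        lagged = out.loc[out["region"] == "L2", "peak1"].mean()
        ref = out.loc[out["region"] == "L1", "peak1"].mean()
        assert lagged - ref == pytest.approx(2.0, abs=0.5)

    def test_constant_zero_tie_rule(self, long_fixture):
        _, _, series, _, _ = long_fixture
        zero = series.with_data(np.zeros_like(series.data))
        qpp = QPP(template=np.zeros((series.n_voxels, 20)), window=20,
                  stc=np.zeros(series.n_frames - 19),
                  occurrences=np.array([7], dtype=int))
        voxels = pd.DataFrame({"voxel": [0, 1], "region": "x"})
        out = extract_peak_timings(zero, qpp, voxels)
        assert (out["peak1"] == 0).all() and (out["peak2"] == 10).all()


class TestCompareTimings:
    def _timings(self, rng, shift_region=None, shift=0.0, n=40):
        rows = []
        for region in SIX:
            for _ in range(n):
                p1 = 4 + rng.normal(0, 0.3)
                p2 = 14 + rng.normal(0, 0.3)
                if region == shift_region:
                    p1 += shift
                    p2 += shift
                rows.append(dict(voxel=len(rows), region=region,
                                 peak1=p1, peak2=p2))
        return pd.DataFrame(rows)

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        t = self._timings(rng)
        res = compare_timings(t, t.copy())
        assert np.allclose(res.tier1["p_raw"], 1.0)
        assert not res.tier1["significant"].any()
        assert not res.tier3["significant"].any()

    def test_lagged_region_flagged(self):
        rng = np.random.default_rng(1)
        a = self._timings(rng)
        b = self._timings(rng, shift_region="L2", shift=2.0)
        res = compare_timings(a, b)
        sig = res.tier1[res.tier1["significant"]]
        # the shifted region is flagged for both peaks and dominates any
        # borderline stray that BH admits next to a very strong effect
        assert {"L2"} <= set(sig["region"])
        assert set(sig.sort_values("p_fdr").head(2)["region"]) == {"L2"}
        assert len(sig) <= 4
        pairs = res.tier3[res.tier3["significant"]]
        l2_pairs = pairs[(pairs["region_1"] == "L2") | (pairs["region_2"] == "L2")]
        # every pair involving the shifted region flagged (5 pairs x 2 peaks);
        # the interval construction shares the bigger region's mean-timing
        # error across voxels, so a few null pairs can ride along
        assert len(l2_pairs) == 10
        assert len(pairs) - len(l2_pairs) <= 4

    def test_tier2_orders_lags(self):
        rng = np.random.default_rng(2)
        a = self._timings(rng)
        a.loc[a["region"] == "L3", "peak1"] += 3.0  # L3 peaks later
        res = compare_timings(a, a.copy())
        row = res.tier2[(res.tier2["group"] == "A")
                        & (res.tier2["region_1"] == "L1")
                        & (res.tier2["region_2"] == "L3")
                        & (res.tier2["peak"] == "peak1")].iloc[0]
        assert row["mean_1"] < row["mean_2"] and row["significant"]

    def test_small_region_excluded(self):
        rng = np.random.default_rng(3)
        a = self._timings(rng)
        b = self._timings(rng)
        b = b[b["region"] != "D3"]  # < 2 voxels in group B
        res = compare_timings(a, b)
        assert "D3" in res.excluded_regions
        assert "D3" not in set(res.tier1["region"])
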