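import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qppdyn import (
    bh_fdr,
    cluster_extent_filter,
    compare_rates,
    fc_matrix,
    occurrence_stack,
    one_sample_tmap,
    refine_template,
    two_sample_tmap,
)


def bh_oracle(p, q=0.05):
    """Brute-force Benjamini-Hochberg rejection set."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def flood_fill_components(vol):
    """6-connected components by explicit flood fill."""
    vol = np.asarray(vol, dtype=bool)
    seen = np.zeros_like(vol)
    comps = []
    for start in np.argwhere(vol):
        start = tuple(start)
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            comp.append((x, y, z))
            for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= nb[i] < vol.shape[i] for i in range(3)) \
                        and vol[nb] and not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        comps.append(comp)
    return comps


class TestBhFdr:
    @settings(max_examples=200, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=1, max_value=40))
    def test_matches_oracle(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        reject, _ = bh_fdr(p)
        np.testing.assert_array_equal(reject, bh_oracle(p))

    def test_thousand_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 30))
            reject, _ = bh_fdr(p)
            np.testing.assert_array_equal(reject, bh_oracle(p))


class TestClusterExtent:
    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vol = rng.random((8, 8, 4)) < 0.35
            kept = cluster_extent_filter(vol, k=5)
            expect = np.zeros_like(vol)
            for comp in flood_fill_components(vol):
                if len(comp) >= 5:
                    for c in comp:
                        expect[c] = True
            np.testing.assert_array_equal(kept, expect)

    def test_small_clusters_removed(self):
        vol = np.zeros((6, 6, 2), dtype=bool)
        vol[0, 0:3, 0] = True  # size 3 < k
        vol[3:6, 0:4, 0] = True  # size 12 >= k
        kept = cluster_extent_filter(vol, k=10)
        assert not kept[0, 0, 0] and kept[3, 0, 0]


class TestFisherZ:
    def test_closed_form(self, motif_series):
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_fc_matrix_properties(self, motif_series):
        atlas, _, series, gt = motif_series
        rois = ["D1", "D2", "L1", "L2"]
        mats = fc_matrix(series, atlas, rois)
        assert len(mats) == len(series.subjects)
        for m in mats:
            np.testing.assert_allclose(m.z, m.z.T, atol=1e-12)
            off = m.z[~np.eye(4, dtype=bool)]
            assert np.all(np.isfinite(off))
        # D and L regions carry opposite motif signs -> strongly negative z
        z_cross = np.mean([m.z[0, 2] for m in mats])
        assert z_cross < -0.1

    def test_empty_roi_errors(self, motif_series):
        atlas, _, series, _ = motif_series
        import qppdyn
        atlas2 = qppdyn.Atlas(labels=atlas.labels,
                              names={**atlas.names, 99: "ghost"})
        with pytest.raises(ValueError, match="ghost"):
            fc_matrix(series, atlas2, ["ghost"])


class TestTMaps:
    def test_one_sample_closed_form(self):
        # t = mu * sqrt(n) / s on a hand vector
        x = np.array([1.0, 2.0, 3.0, 4.0])
        mu, s, n = x.mean(), x.std(ddof=1), len(x)
        from scipy import stats
        t_expect = mu * np.sqrt(n) / s
        assert stats.ttest_1samp(x, 0).statistic == pytest.approx(t_expect)

    def test_one_sample_map_on_fixture(self, prepped_series):
        # build the pattern from ground-truth occurrences so the test
        # isolates the t-map machinery from extraction noise
        from qppdyn.qpp_extract import QPP
        _, _, series, gt = prepped_series
        occ = gt.all_occurrences(0)
        tpl = np.mean([series.data[:, s : s + 6] for s in occ], axis=0)
        qpp = QPP(template=tpl, window=6, stc=np.zeros(series.n_frames - 5),
                  occurrences=occ, converged=True)
        smap = one_sample_tmap(qpp, series)
        assert smap.t.shape == (series.n_voxels, 6)
        motif_vox = np.abs(gt.templates[0]).sum(axis=1) > 0
        # motif voxels dominate the significant set (edge frames of the
        # half-sine carry little signal, so score a voxel by any frame)
        any_frame = smap.significant.any(axis=1)
        assert any_frame[motif_vox].mean() > 0.5 > any_frame[~motif_vox].mean()

    def test_two_sample_null_and_antisymmetry(self, prepped_series):
        _, _, series, gt = prepped_series
        qpp = refine_template(series, gt.occurrences["sub01"][0][0], 6)
        stack = occurrence_stack(series, qpp)
        half = len(stack) // 2
        a, b = stack[:half], stack[half : 2 * half]
        null_map = two_sample_tmap(a, a, series)
        assert not null_map.significant.any()
        m1 = two_sample_tmap(a, b, series)
        m2 = two_sample_tmap(b, a, series)
        np.testing.assert_allclose(m1.t, -m2.t, atol=1e-10)
        np.testing.assert_array_equal(m1.significant, m2.significant)

    def test_degenerate_voxel_flagged(self, prepped_series):
        _, _, series, gt = prepped_series
        qpp = refine_template(series, gt.occurrences["sub01"][0][0], 6)
        data = series.data.copy()
        data[0, :] = 1.0  # constant across every occurrence window
        smap = one_sample_tmap(qpp, series.with_data(data))
        assert smap.degenerate[0].all()
        assert np.all(np.isinf(smap.t[0]))


class TestCompareRates:
    def test_identical_vectors_p_one(self):
        r = {"qpp1": np.array([1.0, 1.2, 0.9, 1.1])}
        out = compare_rates(r, {"qpp1": r["qpp1"].copy()})
        assert out["p_raw"].iloc[0] == pytest.approx(1.0)
        assert not out["significant"].any()

    def test_closed_form_t(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        out = compare_rates({"q": a}, {"q": b})
        sp = np.sqrt(((a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4))
        t_expect = (a.mean() - b.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert out["t"].iloc[0] == pytest.approx(t_expect)

    def test_fdr_across_family(self):
        rng = np.random.default_rng(6)
        rates_a = {f"q{i}": rng.normal(1.0, 0.1, 10) for i in range(4)}
        rates_b = {k: v.copy() for k, v in rates_a.items()}
        rates_b["q0"] = rates_b["q0"] * 0.3  # one strong effect
        out = compare_rates(rates_a, rates_b)
        assert out.loc[out["pattern"] == "q0", "significant"].iloc[0]
        assert out["p_fdr"].between(0, 1).all()

    def test_family_mismatch(self):
        with pytest.raises(ValueError, match="famil"):
            compare_rates({"a": np.ones(3)}, {"b": np.ones(3)})
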