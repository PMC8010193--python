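import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from vlsmkit import (
    ContingencyTable,
    LesionCohort,
    VLSMConfig,
    bh_fdr_threshold,
    extract_clusters,
    liebermeister_p,
    p_to_z,
    run_vlsm,
    voxel_coverage_mask,
    voxel_table,
)
from conftest import make_mask, random_cohort


def liebermeister_oracle(a, b, c, d, direction="positive"):
    """Exact-rational hypergeometric tail on the cell-augmented table."""
    if direction == "positive":
        aa, bb, cc, dd = a + 1, b, c, d + 1
        lo = aa
    else:
        aa, bb, cc, dd = a, b + 1, c + 1, d
        lo = None
    N = aa + bb + cc + dd
    K = aa + cc  # column margin (label-positive)
    m = aa + bb  # row margin (lesioned)
    denom = math.comb(N, m)
    support = range(max(0, m + K - N), min(m, K) + 1)
    pmf = {x: Fraction(math.comb(K, x) * math.comb(N - K, m - x), denom) for x in support}
    if direction == "positive":
        return float(sum(p for x, p in pmf.items() if x >= lo))
    return float(sum(p for x, p in pmf.items() if x <= a))


class TestLiebermeister:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((3, 1, 1, 3), 26 / 252),
            ((5, 0, 0, 5), 1 / 924),
            ((0, 5, 5, 0), 1 - 1 / 924),
        ],
    )
    def test_worked_examples(self, cells, expected):
        assert liebermeister_p(ContingencyTable(*cells)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_negative_direction_matches_oracle(self):
        for cells in [(3, 1, 1, 3), (0, 4, 4, 0), (2, 2, 2, 2), (1, 0, 3, 2)]:
            t = ContingencyTable(*cells)
            assert liebermeister_p(t, "negative") == pytest.approx(
                liebermeister_oracle(*cells, "negative"), abs=1e-12
            )

    def test_rejects_negative_counts_and_empty_table(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)

    def test_positive_and_negative_tails_cover_the_distribution(self):
        # P(X >= a+1) + P(X <= a) = 1 on the shared augmented margins
        for cells in [(3, 1, 1, 3), (2, 5, 1, 4), (0, 3, 3, 0)]:
            t = ContingencyTable(*cells)
            total = liebermeister_p(t, "positive") + liebermeister_p(t, "negative")
            assert total == pytest.approx(1.0, abs=1e-12)


class TestPToZ:
    def test_quantile_fixtures(self):
        assert p_to_z(0.5) == pytest.approx(0.0, abs=1e-12)
        assert p_to_z(0.025, 1) == pytest.approx(1.959964, abs=1e-5)
        assert p_to_z(0.975, 1) == pytest.approx(-1.959964, abs=1e-5)

    def test_underflow_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert p_to_z(0.0) == 8.0
        with pytest.warns(UserWarning):
            assert p_to_z(1.0) == -8.0


class TestBHThreshold:
    def test_hand_enumerated_fixtures(self):
        assert bh_fdr_threshold([0.001, 0.2, 0.9], 0.05) == pytest.approx(0.001)
        assert bh_fdr_threshold([0.01, 0.02, 0.03], 0.05) == pytest.approx(0.03)
        assert bh_fdr_threshold([0.9, 0.9, 0.9], 0.05) is None
        with pytest.raises(ValueError):
            bh_fdr_threshold([], 0.05)

    def test_threshold_defines_the_step_up_rejection_set(self):
        from hypothesis import given, settings, strategies as st

        @settings(derandomize=True, max_examples=200, deadline=None)
        @given(
            st.lists(
                st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
                min_size=1,
                max_size=30,
            ),
            st.floats(min_value=0.01, max_value=0.5),
        )
        def check(pvals, q):
            thr = bh_fdr_threshold(pvals, q)
            p = np.sort(np.asarray(pvals))
            m = p.size
            qualifies = p <= np.arange(1, m + 1) * q / m
            if thr is None:
                assert not qualifies.any()
            else:
                k = np.nonzero(qualifies)[0].max()
                assert thr == p[k]
                assert np.all(p[: k + 1] <= thr)

        check()

    def test_agrees_with_statsmodels_step_up(self, rng):
        """Rejection set implied by the threshold matches an independent
        BH implementation on 1000 random p-vectors."""
        from statsmodels.stats.multitest import multipletests

        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3.0)
            p = np.clip(p, 1e-12, 1.0)
            thr = bh_fdr_threshold(p, 0.05)
            reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            if thr is None:
                assert not reject.any()
            else:
                assert np.array_equal(p <= thr, reject)


class TestCoverageAndTables:
    def test_coverage_strict_inequality(self, rng):
        """The >5% damaged filter is strict: on a random cohort the mask
        equals a direct per-voxel comparison, and fully/never lesioned
        voxels land on the right side."""
        from vlsmkit import VolumeGrid

        grid = VolumeGrid.isotropic((4, 4, 4))
        cohort = random_cohort(grid, 20, rng, p=0.25)
        mask = voxel_coverage_mask(cohort, 0.05)
        counts = cohort.stacked().sum(axis=0)
        assert np.array_equal(mask, counts / 20 > 0.05)
        assert mask[counts == 20].all() if (counts == 20).any() else True
        assert not mask[counts == 0].any()
        with pytest.raises(ValueError):
            voxel_coverage_mask(cohort, 1.5)

    def test_voxel_table_matches_naive_loop(self, grid8, rng):
        cohort = random_cohort(grid8, 30, rng)
        labels = rng.integers(0, 2, 30)
        for _ in range(5):
            v = tuple(rng.integers(0, 8, 3))
            t = voxel_table(cohort, labels, v)
            a = b = c = d = 0
            for m, lab in zip(cohort, labels):
                les = m.voxels[v] == 1
                if les and lab:
                    a += 1
                elif les:
                    b += 1
                elif lab:
                    c += 1
                else:
                    d += 1
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
            assert t.n == 30

    def test_degenerate_margins(self, grid8, rng):
        cohort = random_cohort(grid8, 6, rng)
        t = voxel_table(cohort, [1] * 6, (0, 0, 0))
        assert t.b == 0 and t.d == 0


class TestClusters:
    def test_two_disjoint_blocks(self):
        sig = np.zeros((12, 12, 12), dtype=bool)
        sig[1:4, 1:4, 1:4] = True
        sig[8:11, 8:11, 8:11] = True
        z = np.random.default_rng(0).uniform(1, 2, sig.shape)
        clusters = extract_clusters(sig, z, 26)
        assert [c.n_voxels for c in clusters] == [27, 27]
        assert extract_clusters(np.zeros_like(sig), z) == []

    def test_single_voxel(self):
        sig = np.zeros((5, 5, 5), dtype=bool)
        sig[2, 2, 2] = True
        z = np.ones(sig.shape)
        (c,) = extract_clusters(sig, z)
        assert c.n_voxels == 1 and c.peak_index == (2, 2, 2)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_random_blobs_match_flood_fill_oracle(self, rng, connectivity):
        sig = rng.uniform(size=(10, 10, 10)) < 0.2
        z = rng.normal(size=sig.shape)
        clusters = extract_clusters(sig, z, connectivity)
        oracle = sorted(_flood_fill_sizes(sig, connectivity), reverse=True)
        assert sorted((c.n_voxels for c in clusters), reverse=True) == oracle
        assert sum(c.n_voxels for c in clusters) == int(sig.sum())


def _neighbourhood(connectivity):
    offs = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                order = abs(di) + abs(dj) + abs(dk)
                if order == 0:
                    continue
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((di, dj, dk))
    return offs


def _flood_fill_sizes(sig, connectivity):
    """BFS component sizes, independent of skimage."""
    offs = _neighbourhood(connectivity)
    seen = np.zeros_like(sig, dtype=bool)
    sizes = []
    for start in zip(*np.nonzero(sig)):
        if seen[start]:
            continue
        queue, size = [start], 0
        seen[start] = True
        while queue:
            i, j, k = queue.pop()
            size += 1
            for di, dj, dk in offs:
                nb = (i + di, j + dj, k + dk)
                if all(0 <= n < s for n, s in zip(nb, sig.shape)) and sig[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        sizes.append(size)
    return sizes


class TestRunVLSM:
    def test_degenerate_labels_rejected(self, grid8, rng):
        cohort = random_cohort(grid8, 8, rng)
        with pytest.raises(ValueError, match="class"):
            run_vlsm(cohort, [1] * 8)
        with pytest.raises(ValueError, match="class"):
            run_vlsm(cohort, [1] * 7 + [0])

    def test_result_invariants(self, grid8, rng):
        cohort = random_cohort(grid8, 24, rng)
        labels = rng.integers(0, 2, 24)
        while labels.sum() < 2 or labels.sum() > 22:
            labels = rng.integers(0, 2, 24)
        res = run_vlsm(cohort, labels, VLSMConfig(fdr_q=0.5))
        sig = res.sig_mask.astype(bool)
        assert not np.any(sig & ~res.analyzed_mask)
        if res.fdr_p_threshold is not None:
            assert np.all(res.p_map[sig] <= res.fdr_p_threshold)
        assert sum(c.n_voxels for c in res.clusters) == int(sig.sum())
        assert np.isnan(res.p_map[~res.analyzed_mask]).all()

    def test_invariant_to_sample_ordering(self, grid8, rng):
        cohort = random_cohort(grid8, 20, rng)
        labels = np.array([1] * 8 + [0] * 12)
        res1 = run_vlsm(cohort, labels, VLSMConfig(fdr_q=0.3))
        perm = rng.permutation(20)
        cohort2 = LesionCohort([cohort.masks[i] for i in perm])
        res2 = run_vlsm(cohort2, labels[perm], VLSMConfig(fdr_q=0.3))
        assert np.array_equal(
            np.nan_to_num(res1.p_map), np.nan_to_num(res2.p_map)
        )
        assert np.array_equal(res1.sig_mask, res2.sig_mask)

    def test_voxelwise_p_matches_scalar_path(self, grid8, rng):
        """The vectorized map equals per-voxel liebermeister_p on tables."""
        cohort = random_cohort(grid8, 16, rng)
        labels = np.array([1] * 7 + [0] * 9)
        res = run_vlsm(cohort, labels, VLSMConfig(min_lesion_fraction=0.1))
        analyzed = np.argwhere(res.analyzed_mask)
        for v in map(tuple, analyzed[:: max(1, len(analyzed) // 20)]):
            t = voxel_table(cohort, labels, v)
            assert res.p_map[v] == pytest.approx(liebermeister_p(t), abs=1e-12)

    def test_two_sided_direction_runs(self, grid8, rng):
        cohort = random_cohort(grid8, 16, rng)
        labels = np.array([1] * 8 + [0] * 8)
        res = run_vlsm(cohort, labels, VLSMConfig(direction="two-sided"))
        ok = res.p_map[res.analyzed_mask]
        assert np.all((ok > 0) & (ok <= 1))
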