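import numpy as np
import pytest

from crossqtl import hotspot, scan, synth
from crossqtl.hotspot import JqtlPeak, TransMatrix
from crossqtl.io import ExpressionMatrix


@pytest.fixture(scope="module")
def hot_cross():
    design = synth.default_design(n_segregants=400, n_chromosomes=3,
                                  markers_per_chrom=60, seed=7)
    return synth.simulate_cross(design)


def _hotspot_expression(geno, hot_col, n_genes, effect_sd=0.35, seed=0,
                        second_col=None):
    rng = np.random.default_rng(seed)
    n = geno.n_segregants
    Y = np.empty((n, n_genes))
    for g in range(n_genes):
        y = rng.normal(0, 1, n)
        b = rng.normal(0, effect_sd)
        y += b * geno.values[:, hot_col]
        if second_col is not None and g % 2:
            y += rng.normal(0, effect_sd) * geno.values[:, second_col]
        Y[:, g] = y
    return ExpressionMatrix(Y, [f"g{i}" for i in range(n_genes)],
                            geno.segregants)


def _brute_mv_lod(L, X_design):
    """Independent dense-algebra oracle for the determinant LOD."""
    n = L.shape[0]
    X = np.column_stack([np.ones(n), X_design])
    B = np.linalg.lstsq(X, L, rcond=None)[0]
    E = L - X @ B
    RSS = E.T @ E
    E0 = L - L.mean(axis=0)
    RSS0 = E0.T @ E0
    return (n / 2) * np.log10(np.linalg.det(RSS0) / np.linalg.det(RSS))


class TestMvLod:
    def test_m1_reduces_to_univariate(self, rng):
        for _ in range(100):
            n = 60
            x = rng.choice([-1.0, 1.0], n)
            y = rng.normal(size=n) + rng.normal() * x
            uni, _ = scan.lod_scan(y, x[:, None])
            assert abs(hotspot.mv_lod(y[:, None], x) - uni[0]) < 1e-9

    def test_orthogonal_marker_zero(self, rng):
        n = 40
        L = rng.normal(size=(n, 3))
        # build x exactly orthogonal to every centered column and the intercept
        basis = np.column_stack([np.ones(n), L])
        q, _ = np.linalg.qr(basis)
        x = rng.normal(size=n)
        x -= q @ (q.T @ x)
        assert hotspot.mv_lod(L, x) < 1e-9

    def test_m2_matches_brute_force(self, rng):
        n = 50
        x = rng.choice([-1.0, 1.0], n)
        L = np.column_stack([0.7 * x + rng.normal(size=n),
                             rng.normal(size=n)])
        assert abs(hotspot.mv_lod(L, x) - _brute_mv_lod(L, x)) < 1e-9

    def test_rotation_invariance(self, rng):
        # determinant ratio is invariant to invertible recombination of L
        n = 80
        x = rng.choice([-1.0, 1.0], n)
        L = rng.normal(size=(n, 4)) + np.outer(x, rng.normal(size=4) * 0.4)
        for _ in range(10):
            Q = rng.normal(size=(4, 4))
            while abs(np.linalg.det(Q)) < 1e-3:
                Q = rng.normal(size=(4, 4))
            assert abs(hotspot.mv_lod(L, x) - hotspot.mv_lod(L @ Q, x)) < 1e-7

    def test_singular_l_raises(self, rng):
        n = 30
        col = rng.normal(size=n)
        L = np.column_stack([col, col])
        with pytest.raises(np.linalg.LinAlgError):
            hotspot.mv_lod(L, rng.choice([-1.0, 1.0], n))

    def test_too_few_rows_raises(self, rng):
        with pytest.raises(ValueError):
            hotspot.mv_lod(rng.normal(size=(4, 3)), np.array([1.0, -1, 1, -1]))


class TestSvdRank:
    def test_pure_noise_rank_zero(self, rng):
        R = rng.normal(size=(100, 50))
        Rs = hotspot._scale_columns(R)
        assert hotspot.significant_svd_rank(Rs, rng) <= 1

    def test_planted_factor_rank_one(self, rng):
        n, g = 150, 200
        f = rng.normal(size=n)
        R = np.outer(f, rng.normal(0, 1.0, g)) + rng.normal(size=(n, g))
        Rs = hotspot._scale_columns(R)
        assert hotspot.significant_svd_rank(Rs, rng) >= 1
        U, _, _ = np.linalg.svd(Rs, full_matrices=False)
        assert abs(np.corrcoef(U[:, 0], f)[0, 1]) > 0.9

    def test_k_max_cap(self, rng):
        n, g = 200, 300
        R = rng.normal(size=(n, g))
        for k in range(25):  # plant 25 strong orthogonal-ish factors
            R += np.outer(rng.normal(size=n), rng.normal(0, 2.0, g))
        Rs = hotspot._scale_columns(R)
        assert hotspot.significant_svd_rank(Rs, rng, k_max=20) == 20


class TestBuildTransMatrix:
    def test_planted_hotspot_dominant_column(self, hot_cross):
        hot = hot_cross.chrom_indices("chr02")[30]
        expr = _hotspot_expression(hot_cross, hot, 100, seed=3)
        tm = hotspot.build_trans_matrix("chr02", expr,
                                        np.ones((hot_cross.n_segregants, 1)),
                                        expr.genes, {}, hot_cross, seed=1)
        assert tm.m >= 1
        r = np.corrcoef(tm.L[:, 0], hot_cross.values[:, hot])[0, 1]
        assert abs(r) > 0.8

    def test_no_signal_empty(self, hot_cross, rng):
        Y = rng.normal(size=(hot_cross.n_segregants, 60))
        expr = ExpressionMatrix(Y, [f"g{i}" for i in range(60)],
                                hot_cross.segregants)
        tm = hotspot.build_trans_matrix("chr02", expr,
                                        np.ones((hot_cross.n_segregants, 1)),
                                        expr.genes, {}, hot_cross, seed=2)
        assert tm.m <= 1

    def test_two_hotspots_two_components(self, hot_cross):
        c = hot_cross.chrom_indices("chr02")
        expr = _hotspot_expression(hot_cross, c[10], 120, seed=5,
                                   second_col=c[50])
        tm = hotspot.build_trans_matrix("chr02", expr,
                                        np.ones((hot_cross.n_segregants, 1)),
                                        expr.genes, {}, hot_cross, seed=3)
        assert tm.m >= 2

    def test_empty_gene_list(self, hot_cross):
        empty = ExpressionMatrix(np.zeros((hot_cross.n_segregants, 0)), [],
                                 hot_cross.segregants)
        tm = hotspot.build_trans_matrix(
            "chr01", empty, np.ones((hot_cross.n_segregants, 1)), [], {},
            hot_cross)
        assert tm.m == 0


class TestJqtlScan:
    def _tm(self, geno, expr, chrom="chr02", seed=1):
        return hotspot.build_trans_matrix(
            chrom, expr, np.ones((geno.n_segregants, 1)), expr.genes, {},
            geno, seed=seed)

    def test_null_no_peaks(self, hot_cross, rng):
        Y = rng.normal(size=(hot_cross.n_segregants, 80))
        L = hotspot._scale_columns(Y[:, :3])  # pretend 3 score columns of noise
        tm = TransMatrix(L, "chr02", [f"g{i}" for i in range(3)])
        cidx = hot_cross.chrom_indices("chr02")
        peaks = hotspot.jqtl_scan(tm, hot_cross.values[:, cidx],
                                  hot_cross.marker_map["pos"].to_numpy()[cidx],
                                  n_perm=100, seed=4)
        assert len(peaks) == 0

    def test_single_hotspot_localized(self, hot_cross):
        cidx = hot_cross.chrom_indices("chr02")
        hits = 0
        for s in range(10):
            hot = cidx[15 + 3 * s]
            expr = _hotspot_expression(hot_cross, hot, 90, seed=100 + s)
            tm = self._tm(hot_cross, expr, seed=s)
            X = hot_cross.values[:, cidx]
            pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
            peaks = hotspot.jqtl_scan(tm, X, pos, n_perm=50, seed=s)
            if len(peaks) >= 1 and abs(peaks[0].position
                                       - hot_cross.marker_map["pos"].iloc[hot]) <= 25_000:
                hits += 1
        assert hits >= 9

    def test_two_separated_hotspots(self, hot_cross):
        cidx = hot_cross.chrom_indices("chr02")
        pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
        c1, c2 = cidx[8], cidx[52]  # >500 kb apart on the 750 kb chromosome
        expr = _hotspot_expression(hot_cross, c1, 120, seed=9, second_col=c2)
        tm = self._tm(hot_cross, expr, seed=9)
        X = hot_cross.values[:, cidx]
        peaks = hotspot.jqtl_scan(tm, X, pos, n_perm=50, seed=9)
        assert len(peaks) >= 2
        found = sorted(pk.position for pk in peaks[:2])
        truth = sorted([hot_cross.marker_map["pos"].iloc[c1],
                        hot_cross.marker_map["pos"].iloc[c2]])
        assert abs(found[0] - truth[0]) <= 25_000
        assert abs(found[1] - truth[1]) <= 25_000

    def test_subtraction_kills_peak(self, hot_cross):
        cidx = hot_cross.chrom_indices("chr02")
        hot = cidx[30]
        expr = _hotspot_expression(hot_cross, hot, 90, seed=11)
        tm = self._tm(hot_cross, expr, seed=11)
        X = hot_cross.values[:, cidx]
        lods = hotspot.mv_lod_scan(tm.L, X)
        j = int(np.argmax(lods))
        xc = X[:, j] - X[:, j].mean()
        b = xc @ (tm.L - tm.L.mean(axis=0)) / (xc @ xc)
        L2 = tm.L - np.outer(xc, b)
        lods2 = hotspot.mv_lod_scan(L2, X)
        assert lods2[j] < 1e-6


class TestRefineAndGhost:
    def test_single_peak_stable(self, hot_cross):
        cidx = hot_cross.chrom_indices("chr02")
        hot = cidx[30]
        expr = _hotspot_expression(hot_cross, hot, 90, seed=21)
        tm = hotspot.build_trans_matrix(
            "chr02", expr, np.ones((hot_cross.n_segregants, 1)), expr.genes,
            {}, hot_cross, seed=21)
        X = hot_cross.values[:, cidx]
        pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
        peaks = hotspot.jqtl_scan(tm, X, pos, n_perm=50, seed=21)
        refined = hotspot.refine_peaks(tm, X, pos, peaks)
        assert len(refined) == len(peaks)
        assert abs(refined[0].position - peaks[0].position) <= 25_000

    def test_ghost_gate_not_run_below_200(self, hot_cross, rng):
        L = rng.normal(size=(hot_cross.n_segregants, 2))
        tm = TransMatrix(L, "chr02", ["a", "b"])
        cidx = hot_cross.chrom_indices("chr02")
        X = hot_cross.values[:, cidx]
        pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
        replaced, out = hotspot.ghost_test(tm, X, pos,
                                           JqtlPeak(30, 150.0, pos[30]), [])
        assert not replaced and out[0].lod == 150.0

    def test_single_strong_hotspot_not_split(self, hot_cross):
        cidx = hot_cross.chrom_indices("chr02")
        hot = cidx[30]
        expr = _hotspot_expression(hot_cross, hot, 150, effect_sd=0.8, seed=31)
        tm = hotspot.build_trans_matrix(
            "chr02", expr, np.ones((hot_cross.n_segregants, 1)), expr.genes,
            {}, hot_cross, seed=31)
        X = hot_cross.values[:, cidx]
        pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
        peaks = hotspot.jqtl_scan(tm, X, pos, n_perm=50, seed=31)
        assert peaks and peaks[0].lod > 200
        replaced, _ = hotspot.ghost_test(tm, X, pos, peaks[0], peaks[1:],
                                         n_perm=30, seed=31)
        assert not replaced

    def test_two_close_hotspots_split(self):
        # two linked loci 30 markers apart driving one shared factor; a fused
        # mid-point peak (the ghost) must be replaced by the two true loci,
        # which flank the +/-10-marker exclusion window around the mid peak
        design = synth.CrossDesign(
            900, [synth.Chromosome("c1", 600_000, 0.5)],
            {"c1": np.linspace(1, 600_000, 60).round().astype(int)}, seed=3)
        hc = synth.simulate_cross(design)
        rng = np.random.default_rng(41)
        n = hc.n_segregants
        shared = hc.values[:, 14] + hc.values[:, 44]
        Y = np.empty((n, 150))
        for g in range(150):
            Y[:, g] = rng.normal(0, 1.0) * shared + rng.normal(size=n)
        expr = ExpressionMatrix(Y, [f"g{i}" for i in range(150)],
                                hc.segregants)
        tm = hotspot.build_trans_matrix(
            "c1", expr, np.ones((n, 1)), expr.genes, {}, hc, seed=41)
        X = hc.values
        pos = hc.marker_map["pos"].to_numpy()
        lods = hotspot.mv_lod_scan(tm.L, X)
        mid = JqtlPeak(29, float(lods[29]), int(pos[29]))
        assert mid.lod > 200
        replaced, out = hotspot.ghost_test(tm, X, pos, mid, [], n_perm=30,
                                           seed=41)
        assert replaced and len(out) == 2
        got = sorted(pk.index for pk in out)
        assert abs(got[0] - 14) <= 4 and abs(got[1] - 44) <= 4


class TestBootstrapCi:
    def test_b_zero_raises(self, hot_cross, rng):
        tm = TransMatrix(rng.normal(size=(hot_cross.n_segregants, 2)),
                         "chr02", ["a", "b"])
        cidx = hot_cross.chrom_indices("chr02")
        with pytest.raises(ValueError):
            hotspot.bootstrap_ci(tm, hot_cross.values[:, cidx],
                                 hot_cross.marker_map["pos"].to_numpy()[cidx],
                                 JqtlPeak(10, 50.0, 1000), [], B=0)

    def test_overwhelming_effect_degenerate_ci(self, hot_cross):
        cidx = hot_cross.chrom_indices("chr02")
        hot = cidx[30]
        n = hot_cross.n_segregants
        rng = np.random.default_rng(51)
        # near-noiseless signal: every bootstrap peak lands on the same marker
        L = (hot_cross.values[:, [hot]] * 5.0
             + rng.normal(0, 0.01, size=(n, 1)))
        tm = TransMatrix(L, "chr02", ["g0"])
        X = hot_cross.values[:, cidx]
        pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
        true_pos = hot_cross.marker_map["pos"].iloc[hot]
        lo, hi, bp = hotspot.bootstrap_ci(
            tm, X, pos, JqtlPeak(30, 500.0, true_pos), [], B=100, seed=5)
        assert lo == hi == true_pos
        assert len(np.unique(bp)) == 1

    def test_moderate_effect_coverage(self, hot_cross):
        cidx = hot_cross.chrom_indices("chr02")
        X = hot_cross.values[:, cidx]
        pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
        covered = 0
        n_outer = 20
        for s in range(n_outer):
            hot = cidx[10 + 2 * s]
            expr = _hotspot_expression(hot_cross, hot, 80, seed=200 + s)
            tm = hotspot.build_trans_matrix(
                "chr02", expr, np.ones((hot_cross.n_segregants, 1)),
                expr.genes, {}, hot_cross, seed=s)
            lods = hotspot.mv_lod_scan(tm.L, X)
            pk = JqtlPeak(int(np.argmax(lods)), float(np.max(lods)),
                          int(pos[int(np.argmax(lods))]))
            lo, hi, _ = hotspot.bootstrap_ci(tm, X, pos, pk, [], B=200, seed=s)
            true_pos = hot_cross.marker_map["pos"].iloc[hot]
            covered += int(lo <= true_pos <= hi)
        assert covered >= 0.85 * n_outer


class TestHotspotTargets:
    def test_planted_target_count(self, hot_cross):
        rng = np.random.default_rng(61)
        n = hot_cross.n_segregants
        cidx = hot_cross.chrom_indices("chr02")
        hot = int(cidx[25])
        n_genes = 200
        n_targets = 60
        Y = rng.normal(size=(n, n_genes))
        for g in range(n_targets):
            Y[:, g] += rng.choice([-1, 1]) * 0.35 * hot_cross.values[:, hot]
        expr = ExpressionMatrix(Y, [f"g{i}" for i in range(n_genes)],
                                hot_cross.segregants)
        cfg = scan.PermutationConfig(n_permutations=100, seed=6)
        table = hotspot.hotspot_targets(
            expr, np.ones((n, 1)), hot_cross, {"chr02": [hot]}, {}, cfg=cfg,
            seed=6)
        hit_genes = set(table.loc[table["marker_col"] == hot, "gene"])
        true_set = {f"g{i}" for i in range(n_targets)}
        assert len(hit_genes & true_set) >= 0.8 * n_targets
        assert len(hit_genes - true_set) <= 0.05 * n_genes + 3

    def test_null_hotspot_few_targets(self, hot_cross, rng):
        n = hot_cross.n_segregants
        Y = rng.normal(size=(n, 150))
        expr = ExpressionMatrix(Y, [f"g{i}" for i in range(150)],
                                hot_cross.segregants)
        hot = int(hot_cross.chrom_indices("chr01")[10])
        cfg = scan.PermutationConfig(n_permutations=100, seed=7)
        table = hotspot.hotspot_targets(
            expr, np.ones((n, 1)), hot_cross, {"chr01": [hot]}, {}, cfg=cfg,
            seed=7)
        assert len(table) <= 0.05 * 150 + 2


class TestSubtelomericFlag:
    def test_flagging(self, hot_cross):
        from crossqtl.hotspot import HotspotRecord
        cidx = hot_cross.chrom_indices("chr01")
        pos = hot_cross.marker_map["pos"].to_numpy()[cidx]
        edge = HotspotRecord("chr01", "m", int(pos[0]) + 1000, 50.0, 0, 0)
        mid = HotspotRecord("chr01", "m", int(pos[len(pos) // 2]), 50.0, 0, 0)
        out = hotspot.flag_subtelomeric([edge, mid], hot_cross)
        assert out[0].subtelomeric and not out[1].subtelomeric
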