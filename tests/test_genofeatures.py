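import numpy as np
import pandas as pd
import pytest

from autogs.errors import ConfigError, DegenerateInputError, UndefinedStatisticError
from autogs.genofeatures import (
    association_screen,
    colocalization_stats,
    extract_tam_flanks,
    ld_decay_halfmax,
    merge_qtl_intervals,
    pairwise_ld_r2,
    qc_filter,
    random_marker_baseline,
)
from conftest import make_genotypes


def sweep_line_merge(positions, half_width):
    """Independent interval-merge oracle: sort then sweep."""
    iv = sorted((max(1.0, p - half_width), p + half_width) for p in positions)
    out = []
    for s, e in iv:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def tam_table(marker_ids, categories, trait="t"):
    return pd.DataFrame(
        {"marker_id": marker_ids, "trait": trait, "category": categories}
    )


class TestQCFilter:
    def make_fixture(self):
        """10 markers, 3 planted violations: 40% missing, rare class, multiallelic."""
        rng = np.random.default_rng(0)
        n = 100
        X = rng.integers(0, 3, size=(n, 10)).astype(float)
        X[:40, 0] = np.nan  # marker 0: 40% missing
        X[:, 1] = 0.0
        X[0, 1] = 1.0  # marker 1: class freq 0.01 < 0.02
        multi = [False] * 10
        multi[2] = True  # marker 2: multiallelic
        # make the rest clean: balanced classes
        for j in range(3, 10):
            X[:, j] = rng.permutation(np.repeat([0, 1, 2], [30, 40, 30]))
        return make_genotypes(X, multiallelic=multi)

    def test_planted_violations_removed(self):
        g, report = qc_filter(self.make_fixture())
        assert g.n_markers == 7
        assert report.n_dropped_missing == 1
        assert report.n_dropped_multiallelic == 1
        assert report.n_dropped_class_freq == 1

    def test_idempotent(self):
        g1, _ = qc_filter(self.make_fixture())
        g2, report2 = qc_filter(g1)
        assert g2.n_markers == g1.n_markers
        assert np.array_equal(g2.dosages, g1.dosages)
        assert report2.n_imputed_calls == 0

    def test_moderate_missingness_imputed_with_modal_class(self):
        X = np.tile([0.0, 0.0, 2.0, 0.0, 0.0], (20, 1)).T  # column-constant markers
        X = np.column_stack([np.repeat([0.0, 1.0, 2.0], [8, 6, 6]) for _ in range(3)])
        X[0, 0] = np.nan
        g, report = qc_filter(make_genotypes(X))
        assert report.n_imputed_calls == 1
        assert g.dosages[0, 0] == 0.0  # modal class
        assert not np.isnan(g.dosages).any()

    def test_all_filtered_error(self):
        X = np.full((10, 2), np.nan)
        with pytest.raises(DegenerateInputError):
            qc_filter(make_genotypes(X))


class TestPairwiseLD:
    def test_identical_markers(self):
        x = np.array([0, 1, 2, 1, 0, 2], float)
        g = make_genotypes(np.column_stack([x, x]))
        assert pairwise_ld_r2(g, "m0", "m1") == pytest.approx(1.0)

    def test_complementary_markers(self):
        x = np.array([0, 1, 2, 1, 0, 2], float)
        g = make_genotypes(np.column_stack([x, 2 - x]))
        assert pairwise_ld_r2(g, "m0", "m1") == pytest.approx(1.0)

    def test_independent_markers_near_zero(self):
        rng = np.random.default_rng(1)
        g = make_genotypes(rng.binomial(2, 0.5, size=(2000, 2)).astype(float))
        assert pairwise_ld_r2(g, "m0", "m1") < 0.01

    def test_zero_variance_undefined(self):
        g = make_genotypes(np.column_stack([np.ones(6), np.arange(6) % 3]).astype(float))
        with pytest.raises(UndefinedStatisticError):
            pairwise_ld_r2(g, "m0", "m1")


class TestLDDecay:
    def test_block_structure_decay_scale(self):
        from autogs.simdata import SimConfig, simulate_genotypes

        cfg = SimConfig(
            seed=5, n_genotypes=300, n_markers=400, n_chromosomes=2,
            ld_block_len=10, marker_spacing_bp=5000,
        )
        g = simulate_genotypes(cfg)
        block_bp = 10 * 5000
        curve = ld_decay_halfmax(g, max_dist_bp=200_000, bin_width=10_000)
        assert curve["halfmax_bp"] is not None
        assert 0.2 * block_bp <= curve["halfmax_bp"] <= 1.5 * block_bp

    def test_duplicate_markers_flat_curve(self):
        x = np.array([0, 1, 2, 0, 1, 2, 1, 1], float)
        g = make_genotypes(
            np.column_stack([x] * 5), positions=[1, 100_000, 400_000, 900_000, 1_500_000]
        )
        curve = ld_decay_halfmax(g, max_dist_bp=2_000_000, bin_width=100_000)
        assert curve["halfmax_undefined"]
        assert curve["halfmax_bp"] is None

    def test_three_marker_hand_curve(self):
        rng = np.random.default_rng(2)
        X = rng.binomial(2, 0.5, size=(500, 3)).astype(float)
        g = make_genotypes(X, positions=[1000, 2000, 3000])
        curve = ld_decay_halfmax(g, max_dist_bp=10_000, bin_width=10_000)
        assert curve["n_pairs"][0] == 3  # all three pairs fall in one bin

    def test_single_marker_per_chromosome_error(self):
        g = make_genotypes(np.zeros((5, 2)), chroms=["1", "2"])
        with pytest.raises(DegenerateInputError):
            ld_decay_halfmax(g)


class TestTamFlanks:
    def make_genotypes_at(self, positions, n=30, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.binomial(2, 0.5, size=(n, len(positions))).astype(float)
        return make_genotypes(X, positions=positions)

    def test_fixed_distance_window(self):
        # TAM at 100 kb; neighbours at ±10 kb and ±50 kb
        g = self.make_genotypes_at([50_000, 90_000, 100_000, 110_000, 150_000])
        tams = tam_table(["m2"], ["Main"])
        sets = extract_tam_flanks(tams, g, mode="fixed_bp", flank_bp=37_000)
        assert sets["All-TAMs"] == ["m1", "m2", "m3"]
        assert sets["Main-TAMs"] == ["m1", "m2", "m3"]
        assert sets["E-TAMs"] == []

    def test_overlapping_flanks_deduplicated(self):
        g = self.make_genotypes_at([100_000, 120_000, 140_000])
        tams = tam_table(["m0", "m2"], ["Main", "GxE"])
        sets = extract_tam_flanks(tams, g, mode="fixed_bp", flank_bp=37_000)
        assert sets["All-TAMs"] == ["m0", "m1", "m2"]
        assert len(set(sets["All-TAMs"])) == len(sets["All-TAMs"])

    def test_ld_walk_stops_at_r2_boundary(self):
        # constructed LD profile: 6 tightly linked copies then independent noise
        rng = np.random.default_rng(3)
        base = rng.binomial(1, 0.5, size=(400, 2)).sum(axis=1).astype(float)
        cols = [base.copy()]
        for _ in range(5):  # near-duplicates: r² with TAM stays ≥ 0.5
            c = cols[-1].copy()
            flip = rng.random(400) < 0.02
            c[flip] = rng.integers(0, 3, flip.sum())
            cols.append(c)
        for _ in range(4):  # independent markers
            cols.append(rng.binomial(2, 0.5, 400).astype(float))
        g = make_genotypes(np.column_stack(cols))
        tams = tam_table(["m0"], ["PP_slope"])
        sets = extract_tam_flanks(tams, g, mode="ld_r2", min_r2=0.5)
        assert sets["E-TAMs"] == [f"m{i}" for i in range(6)]

    def test_absent_tam_named(self):
        g = self.make_genotypes_at([1000])
        with pytest.raises(KeyError, match="zzz"):
            extract_tam_flanks(tam_table(["zzz"], ["Main"]), g)

    def test_coordinate_reflection_symmetry(self):
        """Fixed-bp flank membership is symmetric under reflecting the genome axis."""
        positions = [10_000, 40_000, 70_000, 100_000, 130_000]
        g = self.make_genotypes_at(positions)
        tams = tam_table(["m1"], ["Main"])
        fwd = extract_tam_flanks(tams, g, mode="fixed_bp", flank_bp=35_000)["All-TAMs"]
        # reflect positions around 140000; marker order reverses
        refl = [140_000 - p for p in reversed(positions)]
        g2 = make_genotypes(g.dosages[:, ::-1], positions=refl)
        tams2 = tam_table(["m3"], ["Main"])  # m1 reflected is position index 3
        rev = extract_tam_flanks(tams2, g2, mode="fixed_bp", flank_bp=35_000)["All-TAMs"]
        assert sorted(int(m[1:]) for m in fwd) == sorted(4 - int(m[1:]) for m in rev)


class TestQTLIntervals:
    def make_genotypes_with_positions(self, positions, chroms=None):
        X = np.random.default_rng(0).binomial(2, 0.5, (10, len(positions))).astype(float)
        return make_genotypes(X, positions=positions, chroms=chroms)

    def test_two_overlapping_tams_merge(self):
        g = self.make_genotypes_with_positions([5_000_000, 6_000_000])
        iv = merge_qtl_intervals(tam_table(["m0", "m1"], ["Main", "Main"]), g)
        assert iv[("t", "Main")] == [("1", 4_000_000.0, 7_000_000.0)]

    def test_distant_tams_stay_separate(self):
        g = self.make_genotypes_with_positions([1_000_000, 10_000_000])
        iv = merge_qtl_intervals(tam_table(["m0", "m1"], ["Main", "Main"]), g)
        assert len(iv[("t", "Main")]) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sweep_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(rng.integers(1, 60_000_000, size=10).tolist())
        g = self.make_genotypes_with_positions(positions)
        iv = merge_qtl_intervals(
            tam_table([f"m{i}" for i in range(10)], ["GxE"] * 10), g
        )[("t", "GxE")]
        expected = sweep_line_merge(positions, 1e6)
        assert [(s, e) for _, s, e in iv] == [pytest.approx(x) for x in expected]

    def test_order_invariance_and_disjointness(self):
        rng = np.random.default_rng(9)
        positions = sorted(rng.integers(1, 30_000_000, size=8).tolist())
        g = self.make_genotypes_with_positions(positions)
        ids = [f"m{i}" for i in range(8)]
        a = merge_qtl_intervals(tam_table(ids, ["Main"] * 8), g)[("t", "Main")]
        b = merge_qtl_intervals(tam_table(ids[::-1], ["Main"] * 8), g)[("t", "Main")]
        assert a == b
        for (c1, s1, e1), (c2, s2, e2) in zip(a, a[1:]):
            assert c1 != c2 or e1 < s2


class TestColocalization:
    def test_identical_lists(self):
        iv = [("1", 10.0, 20.0), ("2", 5.0, 9.0)]
        stats = colocalization_stats(iv, list(iv))
        assert stats["n_colocalized"] == 2
        assert stats["share_a"] == stats["share_b"] == 1.0

    def test_disjoint_lists(self):
        a = [("1", 10.0, 20.0)]
        b = [("1", 30.0, 40.0)]
        assert colocalization_stats(a, b)["n_colocalized"] == 0

    def test_planted_shares(self):
        """5 of 35 PP intervals overlap 5 of 20 G×E intervals: 14.3% and 25.0%."""
        pp = [("1", float(i * 10), float(i * 10 + 4)) for i in range(35)]
        gxe = [("2", float(i * 10), float(i * 10 + 4)) for i in range(20)]
        for i in range(5):  # relocate 5 G×E intervals onto the first 5 PP intervals
            gxe[i] = ("1", float(i * 10 + 2), float(i * 10 + 6))
        stats = colocalization_stats(pp, gxe)
        assert stats["n_colocalized"] == 5
        assert stats["share_a"] * 100 == pytest.approx(14.3, abs=0.05)
        assert stats["share_b"] * 100 == pytest.approx(25.0, abs=0.05)


class TestRandomBaselines:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.g = make_genotypes(
            rng.binomial(2, 0.5, size=(50, 200)).astype(float),
            positions=(np.arange(200) * 5000 + 1).tolist(),
        )
        self.tams = tam_table(["m10", "m50", "m90"], ["Main", "GxE", "PP_slope"])

    def test_deterministic_under_seed(self):
        a = random_marker_baseline(self.g, self.tams, "Random1", seed=42)
        b = random_marker_baseline(self.g, self.tams, "Random1", seed=42)
        assert a == b
        c = random_marker_baseline(self.g, self.tams, "Random2", seed=42)
        d = random_marker_baseline(self.g, self.tams, "Random2", seed=42)
        assert c == d

    def test_random2_size_matches_all_tam_features(self):
        all_feats = extract_tam_flanks(self.tams, self.g, flank_bp=37_000)["All-TAMs"]
        r2 = random_marker_baseline(self.g, self.tams, "Random2", seed=1)
        assert len(r2) == len(all_feats)

    def test_random1_draws_one_anchor_per_tam(self):
        r1 = random_marker_baseline(self.g, self.tams, "Random1", seed=1, flank_bp=0)
        assert len(r1) == len(self.tams)

    def test_excess_request_rejected(self):
        small = make_genotypes(np.zeros((5, 2)) + 1.0)
        big_tams = tam_table([f"m{i}" for i in range(2)], ["Main"] * 2)
        with pytest.raises(ConfigError):
            random_marker_baseline(small, big_tams, "Random2", seed=0,
                                   all_tam_features=["a", "b", "c"])


class TestAssociationScreen:
    def test_planted_signal_has_max_statistic(self):
        rng = np.random.default_rng(0)
        g = make_genotypes(rng.binomial(2, 0.4, size=(120, 50)).astype(float))
        y = pd.Series(5.0 * g.dosages[:, 17], index=g.samples)
        res = association_screen(g, y, n_pcs=2)
        assert res["t"].abs().idxmax() == "m17"
        assert res.loc["m17", "bonferroni_sig"]

    def test_constant_response_rejected(self):
        g = make_genotypes(np.random.default_rng(1).binomial(2, 0.5, (20, 5)).astype(float))
        with pytest.raises(DegenerateInputError):
            association_screen(g, pd.Series(np.ones(20), index=g.samples))

    def test_null_response_rarely_significant(self):
        rng = np.random.default_rng(2)
        g = make_genotypes(rng.binomial(2, 0.5, size=(200, 1000)).astype(float))
        y = pd.Series(rng.normal(size=200), index=g.samples)
        res = association_screen(g, y, n_pcs=0)
        assert res["bonferroni_sig"].sum() <= 1
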