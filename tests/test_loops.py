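import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson, spearmanr

from nucbench.contact_core import BinTable, ContactMatrix, balance_ic, expected_by_distance
from nucbench.genome_model import (
    SimulationConfig,
    build_expected_matrix,
    generate_state_segmentation,
    sample_contacts,
)
from nucbench.loops import (
    _bh,
    apa,
    call_loops,
    count_interacting_enhancers,
    embed_and_cluster_loops,
    loops_from_bins,
    read_bedpe,
    shifted_loops,
    state_fold_enrichment,
    union_anchors,
    write_bedpe,
)


def match_recall(calls, truth_loops, slack=1):
    if not len(calls):
        return 0.0
    C = calls[["bin1", "bin2"]].to_numpy()
    T = truth_loops[["bin1", "bin2"]].to_numpy()
    D = np.max(np.abs(C[:, None, :] - T[None, :, :]), axis=2)
    return float(np.mean(D.min(axis=0) <= slack))


class TestBH:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.random(500) ** 2
        ours = _bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, ref, atol=1e-12)


class TestCallLoops:
    def test_unbalanced_matrix_rejected(self, decay_only_config):
        exp, _ = build_expected_matrix(decay_only_config)
        m = sample_contacts(exp, 100_000, seed=1)
        with pytest.raises(ValueError, match="balanced"):
            call_loops(m)

    def test_single_hot_pixel_pvalue_matches_poisson_tail(self, decay_only_config):
        """Hand-computed donut background: p equals the closed-form tail."""
        exp, _ = build_expected_matrix(decay_only_config)
        depth = 1_000_000
        i, j, p = exp.upper_triangle()
        counts = depth * p  # noise-free fractional counts = expectation
        hot = (i == 100) & (j == 110)
        counts = counts.copy()
        counts[hot] *= 40.0
        m = ContactMatrix(exp.bin_table, i, j, counts)
        m.weights = np.ones(m.n_bins)
        calls = call_loops(m, distance_range=(100_000, 1_000_000), fdr=0.05)
        assert len(calls) == 1
        row = calls.iloc[0]
        assert (row["bin1"], row["bin2"]) == (100, 110)
        # oracle: expected = per-diagonal mean times max local mean O/E over
        # the four backgrounds; away from the hot pixel O/E == inflated-diagonal
        # normalization, computed by brute force here
        exp_d = expected_by_distance(m)["chr1"]
        dense = m.dense("chr1", balanced=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = dense / exp_d[np.abs(np.subtract.outer(np.arange(400), np.arange(400)))]
        R, r = 5, 2
        y, x = np.mgrid[-R : R + 1, -R : R + 1]
        inner = (np.abs(y) <= r) & (np.abs(x) <= r)
        kernels = [
            ~inner & ~((y == 0) | (x == 0)),
            (y > 0) & (x < 0) & ~inner,
            (np.abs(y) <= 1) & ~inner,
            (np.abs(x) <= 1) & ~inner,
        ]
        best = -np.inf
        for k in kernels:
            vals = [oe[100 + dy, 110 + dx] for dy, dx in zip(*np.nonzero(k), strict=True)]
            best = max(best, np.mean(vals))
        lam = best * exp_d[10]
        obs = dense[100, 110]
        assert row["pvalue"] == pytest.approx(poisson.sf(obs - 1, lam), abs=1e-12)

    def test_null_calibration_no_false_calls(self):
        """Decay-only nulls at nominal FDR 0.05 yield (almost) no calls."""
        total = 0
        for s in range(5):
            cfg = SimulationConfig(seed=700 + s, loop_count=0, delta=0.0, gamma=1.0, block_length_mean=10**9)
            exp, _ = build_expected_matrix(cfg)
            m = balance_ic(sample_contacts(exp, 10_000_000, seed=800 + s))
            total += len(call_loops(m, distance_range=(100_000, 1_000_000), fdr=0.05))
        assert total == 0

    def test_planted_recall(self):
        recalls = []
        for s in range(3):
            cfg = SimulationConfig(seed=500 + s, beta=3.0, loop_count=30)
            exp, truth = build_expected_matrix(cfg)
            m = balance_ic(sample_contacts(exp, 10_000_000, seed=600 + s))
            calls = call_loops(m, distance_range=(100_000, 300_000), fdr=0.05)
            recalls.append(match_recall(calls, truth.loops))
        assert np.mean(recalls) >= 0.8

    def test_recall_nondecreasing_in_loop_strength(self):
        recalls = []
        for beta in (2.0, 3.0, 5.0):
            r = []
            for s in (900, 910):
                cfg = SimulationConfig(seed=s, beta=beta, loop_count=30)
                exp, truth = build_expected_matrix(cfg)
                m = balance_ic(sample_contacts(exp, 10_000_000, seed=s + 1))
                r.append(match_recall(call_loops(m, (100_000, 300_000)), truth.loops))
            recalls.append(np.mean(r))
        assert recalls[1] >= recalls[0] - 0.1 and recalls[2] >= recalls[1] - 0.1


class TestAPA:
    def _uniform_oe_matrix(self, n=120):
        bt = BinTable({"c": n * 25_000}, 25_000)
        i, j = np.triu_indices(n)
        sep = j - i
        m = ContactMatrix(bt, i, j, (400.0 / (1 + sep)))  # any distance-only profile
        m.weights = np.ones(n)
        return bt, m

    def test_uniform_oe_gives_unit_grid_and_score(self):
        bt, m = self._uniform_oe_matrix()
        loops = loops_from_bins(bt, [(20, 60), (40, 90), (15, 45)])
        grid, score, used, skipped = apa(m, loops, half_window=10)
        np.testing.assert_allclose(grid, 1.0, atol=1e-12)
        assert score == pytest.approx(1.0, abs=1e-12)
        assert used == 3 and skipped == 0

    def test_too_close_to_diagonal_or_edge_skipped(self):
        bt, m = self._uniform_oe_matrix()
        bad = loops_from_bins(bt, [(5, 40), (20, 28), (60, 115)])
        with pytest.raises(ValueError, match="no usable loops"):
            apa(m, bad, half_window=10)
        mixed = loops_from_bins(bt, [(5, 40), (20, 28), (60, 115), (30, 70)])
        _, _, used, skipped = apa(m, mixed, half_window=10)
        assert used == 1 and skipped == 3

    def test_planted_loops_enriched_center_beats_shift_null(self):
        cfg = SimulationConfig(seed=42, beta=3.0, loop_count=30, loop_distance_range=(400_000, 1_000_000))
        exp, truth = build_expected_matrix(cfg)
        m = balance_ic(sample_contacts(exp, 10_000_000, seed=43))
        lt = loops_from_bins(truth.bin_table, truth.loops[["bin1", "bin2"]].to_numpy())
        grid, score, used, _ = apa(m, lt, half_window=10)
        _, null_score, _, _ = apa(m, shifted_loops(lt, truth.bin_table, 30), half_window=10)
        assert grid[10, 10] >= 2.0
        assert score > null_score
        assert abs(null_score - 1.0) < 0.25


class TestUnionAnchors:
    def _mk(self, bt, pairs, source):
        df = loops_from_bins(bt, pairs, source)
        return df

    def test_identical_lists_full_intersection(self):
        bt = BinTable({"c": 100 * 25_000}, 25_000)
        pairs = [(10, 30), (50, 70)]
        anchors, upset = union_anchors(
            {"x": self._mk(bt, pairs, "x"), "y": self._mk(bt, pairs, "y")}, bt
        )
        assert len(anchors) == 4
        assert upset == {("x", "y"): 4}

    def test_disjoint_chromosomes_never_merge(self):
        bt = BinTable({"a": 50 * 25_000, "b": 50 * 25_000}, 25_000)
        la = self._mk(bt, [(10, 20)], "x")
        lb = self._mk(bt, [(60, 70)], "y")
        anchors, upset = union_anchors({"x": la, "y": lb}, bt)
        assert upset == {("x",): 2, ("y",): 2}
        assert not (anchors.get("x") & anchors.get("y")).any()

    def test_hand_enumerated_three_way_overlap(self):
        bt = BinTable({"c": 200 * 25_000}, 25_000)
        # anchors in bins: x: {10,40}, {100,140}; y: {11,41}...; z distinct
        lx = self._mk(bt, [(10, 40), (100, 140)], "x")
        ly = self._mk(bt, [(11, 41), (100, 170)], "y")
        lz = self._mk(bt, [(60, 80)], "z")
        anchors, upset = union_anchors({"x": lx, "y": ly, "z": lz}, bt, merge_slack_bins=1)
        assert upset == {("x", "y"): 3, ("y",): 1, ("z",): 2, ("x",): 1}

    def test_merged_anchors_are_separated_beyond_slack(self):
        """Idempotence: a merged set cannot merge further."""
        bt = BinTable({"c": 300 * 25_000}, 25_000)
        rng = np.random.default_rng(2)
        pairs = [(int(a), int(a) + 20) for a in rng.integers(0, 250, 40)]
        anchors, _ = union_anchors({"x": self._mk(bt, pairs, "x")}, bt, merge_slack_bins=1)
        slack = 25_000
        for chrom, grp in anchors.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] - g["end"].to_numpy()[:-1] > slack).all()


class TestStateEnrichment:
    def test_constructed_tenfold_enrichment(self):
        seg = pd.DataFrame(
            {
                "chrom": ["c"] * 10,
                "start": np.arange(10) * 1000,
                "end": (np.arange(10) + 1) * 1000,
                "state": ["k"] + ["bg"] * 9,
            }
        )
        anchors = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000]})
        table = state_fold_enrichment({"cat": anchors}, seg)
        assert table.loc["cat", "k"] == pytest.approx(10.0)
        assert table.loc["cat", "bg"] == pytest.approx(0.0)

    def test_whole_genome_category_all_ones(self):
        seg = pd.DataFrame(
            {"chrom": ["c"] * 4, "start": [0, 500, 1000, 1500], "end": [500, 1000, 1500, 2000],
             "state": ["a", "b", "a", "c"]}
        )
        cat = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [2000]})
        table = state_fold_enrichment({"all": cat}, seg)
        np.testing.assert_allclose(table.loc["all"].to_numpy(), 1.0)

    def test_uniform_random_anchors_near_unit_enrichment(self):
        rng = np.random.default_rng(5)
        n_seg = 1000
        seg = pd.DataFrame(
            {"chrom": "c", "start": np.arange(n_seg) * 1000, "end": (np.arange(n_seg) + 1) * 1000,
             "state": rng.choice(["s1", "s2", "s3"], n_seg, p=[0.5, 0.3, 0.2])}
        )
        starts = rng.integers(0, n_seg, 400) * 1000
        cat = pd.DataFrame({"chrom": "c", "start": starts, "end": starts + 1000})
        table = state_fold_enrichment({"rand": cat}, seg)
        assert ((table.loc["rand"] > 0.75) & (table.loc["rand"] < 1.3)).all()

    def test_complement_category_balances_to_unity(self):
        """bp-weighted mean of enrichment over a category and its complement is 1."""
        rng = np.random.default_rng(6)
        n_seg = 200
        seg = pd.DataFrame(
            {"chrom": "c", "start": np.arange(n_seg) * 1000, "end": (np.arange(n_seg) + 1) * 1000,
             "state": rng.choice(["s1", "s2"], n_seg)}
        )
        in_cat = rng.random(n_seg) < 0.3
        cat = seg[in_cat][["chrom", "start", "end"]]
        comp = seg[~in_cat][["chrom", "start", "end"]]
        table = state_fold_enrichment({"cat": cat, "comp": comp}, seg)
        w_cat, w_comp = in_cat.mean(), 1 - in_cat.mean()
        for s in ("s1", "s2"):
            mix = w_cat * table.loc["cat", s] + w_comp * table.loc["comp", s]
            assert mix == pytest.approx(1.0, rel=1e-9)

    def test_absent_state_undefined_not_infinite(self):
        seg = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [1000], "state": ["a"]})
        cat = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [500]})
        table = state_fold_enrichment({"cat": cat}, seg.assign(state="a"))
        assert "b" not in table.columns


@pytest.fixture(scope="module")
def planted():
    cfg = SimulationConfig(seed=63, loop_count=40, anchor_state_prob=0.5)
    exp, truth = build_expected_matrix(cfg)
    cfg.anchor_state_prob = 1.0  # deterministic anchor states
    seg = generate_state_segmentation(truth, cfg)
    lt = loops_from_bins(truth.bin_table, truth.loops[["bin1", "bin2"]].to_numpy())
    return truth, seg, lt


class TestEmbedding:
    def test_two_populations_recovered(self, planted):
        from sklearn.metrics import adjusted_rand_score

        truth, seg, lt = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = embed_and_cluster_loops(lt, seg, truth.bin_table, n_clusters=2, seed=0)
        ari = adjusted_rand_score((truth.loops["kind"] == "ep").astype(int), emb.cluster)
        assert ari >= 0.9

    def test_seed_reproducible_coordinates(self, planted):
        truth, seg, lt = planted
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e1 = embed_and_cluster_loops(lt, seg, truth.bin_table, n_clusters=2, seed=3)
            e2 = embed_and_cluster_loops(lt, seg, truth.bin_table, n_clusters=2, seed=3)
        np.testing.assert_array_equal(e1.coords, e2.coords)
        np.testing.assert_array_equal(e1.cluster, e2.cluster)

    def test_identical_compositions_flagged_degenerate(self, planted):
        truth, seg, lt = planted
        seg2 = seg.copy()
        seg2["state"] = "only"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            emb = embed_and_cluster_loops(lt, seg2, truth.bin_table, n_clusters=3, seed=0)
        assert emb.degenerate
        assert len(np.unique(emb.cluster)) == 1

    def test_fewer_loops_than_clusters_rejected(self, planted):
        truth, seg, lt = planted
        with pytest.raises(ValueError, match="fewer loops"):
            embed_and_cluster_loops(lt.iloc[:3], seg, truth.bin_table, n_clusters=6)


class TestEnhancerCounting:
    def _bed(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_no_loops_all_zero(self):
        proms = self._bed([("c", 0, 100, "g1"), ("c", 500, 600, "g2")])
        enhs = self._bed([("c", 900, 1000, "e1")])
        loops = pd.DataFrame(columns=["chrom", "start1", "end1", "start2", "end2"])
        counts = count_interacting_enhancers(loops, proms, enhs)
        assert counts.tolist() == [0, 0]

    def test_hand_wired_fixture(self):
        """3 genes, 5 enhancers, 6 loops with known wiring."""
        proms = self._bed([("c", 0, 100, "g1"), ("c", 1000, 1100, "g2"), ("c", 2000, 2100, "g3")])
        enhs = self._bed(
            [("c", 5000, 5100, "e1"), ("c", 6000, 6100, "e2"), ("c", 7000, 7100, "e3"),
             ("c", 8000, 8100, "e4"), ("c", 9000, 9100, "e5")]
        )
        loops = pd.DataFrame(
            [
                ("c", 0, 100, 5000, 5100),      # g1 - e1
                ("c", 0, 100, 6000, 6100),      # g1 - e2
                ("c", 5000, 5100, 0, 100),      # anchors swapped: still g1 - e1 (duplicate)
                ("c", 1000, 1100, 8000, 8100),  # g2 - e4
                ("c", 2000, 2100, 3000, 3100),  # g3 - no enhancer at distal anchor
                ("c", 0, 100, 50, 150),         # both anchors on g1's promoter: excluded
            ],
            columns=["chrom", "start1", "end1", "start2", "end2"],
        )
        counts = count_interacting_enhancers(loops, proms, enhs)
        assert counts["g1"] == 2 and counts["g2"] == 1 and counts["g3"] == 0

    def test_planted_link_recovery(self):
        for seed in (60, 61):
            cfg = SimulationConfig(seed=seed, loop_count=40, anchor_state_prob=0.8)
            exp, truth = build_expected_matrix(cfg)
            generate_state_segmentation(truth, cfg)
            lt = loops_from_bins(truth.bin_table, truth.loops[["bin1", "bin2"]].to_numpy())
            counts = count_interacting_enhancers(lt, truth.promoters, truth.enhancers)
            planted = truth.planted_enhancer_counts()
            cmp = pd.DataFrame({"planted": planted, "rec": counts}).fillna(0)
            rho = spearmanr(cmp["planted"], cmp["rec"]).statistic
            assert rho >= 0.9


class TestBedpeIO:
    def test_roundtrip(self, tmp_path):
        bt = BinTable({"c": 100 * 25_000}, 25_000)
        loops = loops_from_bins(bt, [(10, 30), (50, 70)], source="s1")
        path = tmp_path / "l.bedpe"
        write_bedpe(loops, path)
        back = read_bedpe(path, bt)
        assert back[["chrom", "start1", "end1", "start2", "end2"]].equals(
            loops[["chrom", "start1", "end1", "start2", "end2"]]
        )
        assert back["bin1"].tolist() == [10, 50]
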