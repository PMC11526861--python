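import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp, pearsonr

from nucbench.genome_model import (
    GroundTruth,
    SimulationConfig,
    build_expected_matrix,
    expectation_from_truth,
    generate_clusters,
    generate_state_segmentation,
    generate_tracks,
    sample_contacts,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.0},
            {"gamma": 0.0},
            {"gamma": 1.5},
            {"beta": 0.5},
            {"delta": -0.1},
            {"trans_rate": 1.0},
            {"loop_distance_range": (10_000, 500_000)},  # below 2 bins
            {"state_count": 2},
            {"chrom_sizes": {"tiny": 100_000}},  # < 10 bins
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs).validate()

    def test_too_many_loops_rejected(self):
        cfg = SimulationConfig(loop_count=10_000, loop_distance_range=(100_000, 150_000))
        with pytest.raises(ValueError):
            build_expected_matrix(cfg)


class TestExpectationModel:
    def test_normalized_and_symmetric(self):
        exp, _ = build_expected_matrix(SimulationConfig(seed=3))
        i, j, p = exp.upper_triangle()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_array_equal(exp.probs, exp.probs.T)
        assert np.all(np.diag(exp.probs) == 0)

    def test_pure_power_law_depends_only_on_distance(self, decay_only_config):
        exp, _ = build_expected_matrix(decay_only_config)
        for sep in (1, 5, 40):
            diag = np.diagonal(exp.probs, sep)
            assert np.ptp(diag) == 0.0

    def test_plaid_ratio_is_one_plus_delta(self, equal_blocks_truth):
        cfg, truth = equal_blocks_truth
        exp = expectation_from_truth(cfg, truth)
        # same separation, same vs different label, away from boundaries
        same = exp.probs[10, 20]       # A-A at separation 10
        diff = exp.probs[90, 100 + 0]  # A-B at separation 10 across the change
        assert same / diff == pytest.approx(1.0 + cfg.delta, rel=1e-12)

    def test_boundary_attenuation_matches_formula(self):
        """20-bin chromosome, one boundary, gamma=0.5: crossing pairs halved."""
        cfg = SimulationConfig(
            chrom_sizes={"c": 20 * 25_000}, seed=1, loop_count=0, delta=0.0, gamma=0.5
        )
        bt = cfg.bin_table
        truth = GroundTruth(
            bt,
            np.array(["A"] * 20),
            np.array([10]),
            pd.DataFrame(columns=["bin1", "bin2", "beta", "kind"]),
            pd.DataFrame(columns=["gene", "promoter_bin", "enhancer_bin"]),
        )
        exp = expectation_from_truth(cfg, truth)
        # brute-force oracle: direct evaluation of the multiplicative model
        def model(i, j):
            s = abs(j - i) ** -cfg.alpha
            crossings = sum(1 for b in [10] if min(i, j) < b < max(i, j))
            return s * cfg.gamma ** min(crossings, 3)

        i1, j1 = 5, 15   # crosses the boundary
        i2, j2 = 0, 10   # same distance, does not cross (10 is the boundary bin)
        assert exp.probs[i1, j1] / exp.probs[i2, j2] == pytest.approx(0.5, rel=1e-12)
        tot = sum(model(a, b) for a in range(20) for b in range(a + 1, 20))
        for (a, b) in [(5, 15), (0, 10), (2, 17), (11, 19)]:
            assert exp.probs[a, b] == pytest.approx(model(a, b) / tot, rel=1e-12)

    def test_loop_pixels_respect_distance_range(self):
        cfg = SimulationConfig(seed=9, loop_count=25)
        _, truth = build_expected_matrix(cfg)
        sep = (truth.loops["bin2"] - truth.loops["bin1"]) * cfg.bin_size
        lo, hi = cfg.loop_distance_range
        assert ((sep >= lo - cfg.bin_size) & (sep <= hi)).all()
        assert truth.loops[["bin1", "bin2"]].duplicated().sum() == 0

    def test_loop_factor_and_shoulder(self):
        cfg = SimulationConfig(seed=9, loop_count=5, delta=0.0, gamma=1.0, block_length_mean=10**9)
        exp, truth = build_expected_matrix(cfg)
        cfg0 = SimulationConfig(seed=9, loop_count=0, delta=0.0, gamma=1.0, block_length_mean=10**9)
        exp0, _ = build_expected_matrix(cfg0)
        scale = exp0.probs[0, 1] / (1.0 ** -cfg.alpha)  # normalization differs slightly
        b1, b2 = truth.loops.iloc[0][["bin1", "bin2"]]
        s = float(b2 - b1)
        ratio_center = exp.probs[b1, b2] / (s ** -cfg.alpha)
        ratio_shoulder = exp.probs[b1 + 1, b2] / ((s - 1) ** -cfg.alpha)
        ratio_far = exp.probs[b1 + 20, b2 + 40] / (20.0 ** -cfg.alpha) if b2 + 40 < 400 else None
        assert ratio_center / ratio_shoulder == pytest.approx(
            cfg.beta / ((1 + cfg.beta) / 2), rel=1e-9
        )


class TestSampling:
    def test_seeded_determinism(self, decay_only_config):
        exp, _ = build_expected_matrix(decay_only_config)
        m1 = sample_contacts(exp, 100_000, seed=7)
        m2 = sample_contacts(exp, 100_000, seed=7)
        np.testing.assert_array_equal(m1.bin1, m2.bin1)
        np.testing.assert_array_equal(m1.count, m2.count)

    def test_zero_depth_gives_empty_matrix(self, decay_only_config):
        exp, _ = build_expected_matrix(decay_only_config)
        assert sample_contacts(exp, 0, seed=1).total() == 0.0

    def test_negative_depth_rejected(self, decay_only_config):
        exp, _ = build_expected_matrix(decay_only_config)
        with pytest.raises(ValueError):
            sample_contacts(exp, -5, seed=1)

    def test_per_diagonal_means_match_analytic_expectation(self, decay_only_config):
        """Multinomial sampling: per-diagonal totals within 5 SE of depth*E."""
        exp, _ = build_expected_matrix(decay_only_config)
        depth = 1_000_000
        m = sample_contacts(exp, depth, seed=8)
        dense = m.dense("chr1")
        for sep in (1, 4, 16, 64):
            expected_total = depth * np.diagonal(exp.probs, sep).sum()
            got = np.diagonal(dense, sep).sum()
            se = np.sqrt(expected_total)  # Poisson approximation
            assert abs(got - expected_total) < 5 * se


class TestTracks:
    def test_noise_free_tracks_are_label_step_functions(self, plaid_sim):
        cfg, _, truth, _ = plaid_sim
        cfg2 = SimulationConfig(**{**cfg.__dict__, "track_noise_sd": 0.0})
        tracks = generate_tracks(truth, cfg2)
        z = truth.label_zscore()
        np.testing.assert_allclose(tracks["son"].values, z)
        assert len(np.unique(tracks["son"].values)) == 2
        r = pearsonr(tracks["son"].values, tracks["laminb"].values).statistic
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_noise_attenuates_correlation_as_closed_form(self):
        """coeff=1, sd=1: corr with label z-score -> 1/sqrt(2)."""
        cfg = SimulationConfig(
            chrom_sizes={"c": 10_000 * 25_000}, seed=13, loop_count=0, track_noise_sd=1.0
        )
        rng = np.random.default_rng(14)
        truth = GroundTruth(
            cfg.bin_table,
            rng.choice(np.array(["A", "B"]), size=10_000),
            np.array([], dtype=int),
            pd.DataFrame(columns=["bin1", "bin2", "beta", "kind"]),
            pd.DataFrame(columns=["gene", "promoter_bin", "enhancer_bin"]),
        )
        tracks = generate_tracks(truth, cfg)
        z = truth.label_zscore()
        r = pearsonr(tracks["son"].values, z).statistic
        n = z.size
        se = (1 - 0.5) / np.sqrt(n)
        assert abs(r - 1 / np.sqrt(2)) < 5 * se


class TestClusters:
    def test_forced_size_two(self, decay_only_config):
        cfg = SimulationConfig(
            **{**decay_only_config.__dict__, "cluster_count": 50,
               "cluster_size_log_range": (np.log10(2.0), np.log10(2.0))}
        )
        exp, _ = build_expected_matrix(cfg)
        cs = generate_clusters(exp, cfg)
        assert (cs.sizes() == 2).all()

    def test_seeded_determinism(self, decay_only_config):
        cfg = SimulationConfig(**{**decay_only_config.__dict__, "cluster_count": 30})
        exp, _ = build_expected_matrix(cfg)
        c1 = generate_clusters(exp, cfg, seed=5)
        c2 = generate_clusters(exp, cfg, seed=5)
        assert all(np.array_equal(a, b) for a, b in zip(c1.members, c2.members))

    def test_pair_distance_distribution_matches_resampling_oracle(self, decay_only_config):
        """Star-model pairs vs brute-force redraws from the anchor profile."""
        cfg = SimulationConfig(
            **{**decay_only_config.__dict__, "cluster_count": 1500,
               "cluster_size_log_range": (np.log10(2.0), 1.0)}
        )
        exp, _ = build_expected_matrix(cfg)
        cs = generate_clusters(exp, cfg, seed=30)
        dists = []
        for m in cs.members:
            i, j = np.triu_indices(m.size, k=1)
            dists.extend(np.abs(m[j] - m[i]))
        # oracle: same star process, independent implementation
        rng = np.random.default_rng(31)
        marg = exp.marginal()
        p_anchor = marg / marg.sum()
        odists = []
        n = exp.bin_table.n_bins
        while len(odists) < len(dists):
            size = int(round(10 ** rng.uniform(np.log10(2.0), 1.0)))
            anchor = rng.choice(n, p=p_anchor)
            row = exp.probs[anchor]
            mem = np.unique(np.append(rng.choice(n, size=max(size - 1, 1), p=row / row.sum()), anchor))
            if mem.size < 2:
                continue
            i, j = np.triu_indices(mem.size, k=1)
            odists.extend(np.abs(mem[j] - mem[i]))
        stat = ks_2samp(np.array(dists), np.array(odists)).statistic
        assert stat < 0.05

    def test_degenerate_expectation_rejected(self, decay_only_config):
        exp, _ = build_expected_matrix(decay_only_config)
        exp.probs = np.zeros_like(exp.probs)
        with pytest.raises(ValueError):
            generate_clusters(exp, decay_only_config)


class TestSegmentation:
    def test_anchor_states_deterministic_when_prob_one(self):
        cfg = SimulationConfig(seed=41, loop_count=30, anchor_state_prob=0.5)
        exp, truth = build_expected_matrix(cfg)
        cfg.anchor_state_prob = 1.0
        seg = generate_state_segmentation(truth, cfg)
        names = truth.state_names
        state = truth.state_map
        for _, row in truth.loops.iterrows():
            s1, s2 = names[state[row["bin1"]]], names[state[row["bin2"]]]
            if row["kind"] == "ep":
                assert {s1, s2} == {"promoter", "enhancer"}
            else:
                assert s1 == s2 == "insulator"

    def test_no_loops_means_no_anchor_states(self):
        cfg = SimulationConfig(seed=42, loop_count=0)
        _, truth = build_expected_matrix(cfg)
        seg = generate_state_segmentation(truth, cfg)
        assert set(seg["state"]) <= {"background_A", "background_B"}

    def test_background_states_follow_labels(self):
        cfg = SimulationConfig(seed=43, loop_count=0)
        _, truth = build_expected_matrix(cfg)
        seg = generate_state_segmentation(truth, cfg)
        is_a = truth.labels == "A"
        assert (seg["state"].to_numpy()[is_a] == "background_A").all()
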