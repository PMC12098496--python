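"""Sliding-window connectivity, state decomposition, and dynamics metrics."""
import numpy as np
import pytest

from gradstates.dfc_states import (
    StateModel,
    dfc_variability,
    fit_states,
    mean_dfc,
    n_windows,
    run_lengths,
    select_k,
    sliding_window_fc,
    state_dynamics,
    statewise_connectivity,
    window_majority_labels,
)
from gradstates.signal_prep import SubjectTimeSeries
from gradstates.synthetic_cohort import CohortSpec, generate_state_model, simulate_subject


def _ts(data, sid="s0"):
    return SubjectTimeSeries(sid, "control", np.asarray(data, float), 2.0)


def _stack_from_z(z, sid="s0", L=50, s=1, P=None):
    from gradstates.dfc_states import WindowedFCStack
    z = np.atleast_2d(np.asarray(z, float))
    P = P or int((1 + np.sqrt(1 + 8 * z.shape[1])) / 2)
    return WindowedFCStack(sid, "control", z, L, s, P, np.arange(z.shape[0]))


class TestSlidingWindow:
    def test_window_count_formula(self):
        assert n_windows(200, 50, 1) == 151
        rng = np.random.default_rng(0)
        st = sliding_window_fc(_ts(rng.standard_normal((200, 5))), 50, 1)
        assert st.n_windows == 151
        assert st.window_starts[-1] == 150

    def test_identical_columns_hit_clip_boundary(self, rng):
        x = rng.standard_normal(80)
        st = sliding_window_fc(_ts(np.column_stack([x, x, rng.standard_normal(80)])),
                               20, 1)
        z_max = np.arctanh(1 - 1e-7)
        assert np.allclose(st.z[:, 0], z_max)

    def test_known_correlation_fisher_z(self):
        # correlation exactly 0.5 -> z = atanh(0.5) = 0.5493 (4 d.p.)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        L = np.linalg.cholesky(cov)
        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 2)) @ L.T
        # orthogonalize empirically then remix to get an exact sample r of 0.5
        u = x[:, 0] - x[:, 0].mean()
        v = x[:, 1] - x[:, 1].mean()
        v = v - u * (u @ v) / (u @ u)
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        y = 0.5 * u + np.sqrt(1 - 0.25) * v
        st = sliding_window_fc(_ts(np.column_stack([u, y])), 30, 1)
        assert st.z[0, 0] == pytest.approx(0.5493, abs=5e-5)

    def test_constant_region_zeroed_with_warning(self, caplog):
        data = np.column_stack([np.ones(60), np.random.default_rng(0).standard_normal((60, 2)).T.reshape(60, 2)])
        with caplog.at_level("WARNING", logger="gradstates.dfc_states"):
            st = sliding_window_fc(_ts(data), 30, 1)
        assert np.allclose(st.z[:, :2], 0.0)  # edges touching the constant region
        assert "constant" in caplog.text


class TestVariability:
    def test_constant_z_gives_zero_sd(self):
        st = _stack_from_z(np.tile([0.3, -0.1, 0.2], (10, 1)), P=3)
        assert np.allclose(dfc_variability(st), 0.0)

    def test_alternating_closed_form(self):
        a, W = 0.4, 8
        z = np.tile([a, -a], W // 2)[:, None] * np.ones((1, 3))
        st = _stack_from_z(z, P=3)
        expected = a * np.sqrt(W / (W - 1))
        assert np.allclose(dfc_variability(st), expected)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            dfc_variability(_stack_from_z(np.zeros((1, 3)), P=3))

    def test_switching_increases_variability_over_static(self):
        spec_sw = CohortSpec(n_patients=2, n_controls=2, P=10, T=200,
                             stickiness=0.9, effect_edges=(), seed=4)
        model = generate_state_model(spec_sw)
        static_model = (np.eye(spec_sw.n_states), model[1])  # never switches
        sd_sw, sd_st = [], []
        for i in range(6):
            ts, _ = simulate_subject(spec_sw, "control", model, seed=50 + i)
            sd_sw.append(np.median(dfc_variability(sliding_window_fc(ts, 50, 1))))
            ts, _ = simulate_subject(spec_sw, "control", static_model, seed=50 + i)
            sd_st.append(np.median(dfc_variability(sliding_window_fc(ts, 50, 1))))
        assert np.median(sd_sw) > np.median(sd_st)


class TestFitStates:
    def test_separable_two_point_clustering(self):
        a = np.tile([1.0, 1.0, 1.0], (20, 1))
        b = np.tile([-1.0, -1.0, -1.0], (20, 1))
        stacks = [_stack_from_z(np.vstack([a, b]), sid="s0", P=3),
                  _stack_from_z(np.vstack([b, a]), sid="s1", P=3)]
        model = fit_states(stacks, k=2, seed=0)
        assert model.sse == pytest.approx(0.0, abs=1e-9)
        lab = model.labels["s0"]
        assert len(set(lab[:20])) == 1 and len(set(lab[20:])) == 1
        assert lab[0] != lab[20]

    def test_k1_centroid_is_pooled_mean(self, small_stacks):
        model = fit_states(small_stacks, k=1, seed=0)
        pooled = np.vstack([st.z for st in small_stacks])
        assert np.allclose(model.centroids[0], pooled.mean(axis=0), atol=1e-4)

    def test_planted_state_recovery_when_dwell_dominates_window(self):
        # dwell ~50 volumes (stickiness .98) >> window 20: sliding-window
        # k-means is consistent here and must recover the planted labels
        spec = CohortSpec(n_patients=20, n_controls=20, P=30, T=200,
                          stickiness=0.98, effect_edges=(), seed=17)
        model_true = generate_state_model(spec)
        stacks, true_lab = [], []
        for i in range(spec.n_subjects):
            ts, states = simulate_subject(spec, "control", model_true, seed=700 + i)
            ts = SubjectTimeSeries(f"s{i}", "control", ts.data, ts.tr, ts.region_ids)
            stacks.append(sliding_window_fc(ts, 20, 1))
            true_lab.append(window_majority_labels(states, 20, 1))
        model = fit_states(stacks, k=4, seed=0)
        from sklearn.metrics import adjusted_rand_score
        rec = np.concatenate([model.labels[f"s{i}"] for i in range(spec.n_subjects)])
        ari = adjusted_rand_score(np.concatenate(true_lab), rec)
        assert ari >= 0.8


class TestSelectK:
    def test_separable_case_silhouette_and_choice(self):
        rng = np.random.default_rng(0)
        a = np.tile([2.0, 2.0, 2.0], (30, 1))
        b = np.tile([-2.0, -2.0, -2.0], (30, 1))
        z = np.vstack([a, b]) + 0.01 * rng.standard_normal((60, 3))
        sel = select_k([_stack_from_z(z, P=3)], k_range=range(2, 5), seed=0)
        row = sel.table.set_index("k").loc[2]
        assert row["silhouette"] > 0.99
        assert sel.silhouette_k == 2

    def test_linear_sse_falls_back_to_silhouette(self, monkeypatch):
        import gradstates.dfc_states as mod
        assert mod._elbow(np.array([2.0, 3, 4, 5]), np.array([8.0, 6, 4, 2])) is None


class TestDynamics:
    def test_hand_enumerated_example(self):
        model = StateModel(2, np.zeros((2, 1)),
                           {"s": np.array([0, 0, 1, 1, 1, 0])}, 0.0, 0)
        d = state_dynamics(model).iloc[0]
        assert d["n_transitions"] == 2
        assert d["occupancy_state1"] == pytest.approx(0.5)
        assert d["occupancy_state2"] == pytest.approx(0.5)
        assert d["dwell_state1"] == pytest.approx(1.5)
        assert d["dwell_state2"] == pytest.approx(3.0)
        assert d["transition_frequency"] == pytest.approx(2 / 5)

    def test_constant_and_alternating_sequences(self):
        model = StateModel(2, np.zeros((2, 1)), {
            "const": np.zeros(10, int),
            "alt": np.array([0, 1] * 5),
        }, 0.0, 0)
        d = state_dynamics(model).set_index("subject_id")
        assert d.loc["const", "n_transitions"] == 0
        assert d.loc["const", "dwell_state1"] == 10
        assert np.isnan(d.loc["const", "dwell_state2"])
        assert d.loc["alt", "transition_frequency"] == 1.0

    def test_run_length_encoder_oracle(self, rng):
        """dwell/occupancy/transitions agree with a brute-force RLE on 1000
        random label sequences."""
        for _ in range(1000):
            k = int(rng.integers(2, 5))
            W = int(rng.integers(2, 40))
            lab = rng.integers(0, k, W)
            model = StateModel(k, np.zeros((k, 1)), {"s": lab}, 0.0, 0)
            d = state_dynamics(model).iloc[0]
            # brute force
            runs = []
            cur, length = lab[0], 1
            for v in lab[1:]:
                if v == cur:
                    length += 1
                else:
                    runs.append((cur, length))
                    cur, length = v, 1
            runs.append((cur, length))
            assert d["n_transitions"] == len(runs) - 1
            occ = [d[f"occupancy_state{j+1}"] for j in range(k)]
            assert np.isclose(sum(occ), 1.0)
            for j in range(k):
                lens = [l for s, l in runs if s == j]
                if lens:
                    assert d[f"dwell_state{j+1}"] == pytest.approx(np.mean(lens))
                else:
                    assert np.isnan(d[f"dwell_state{j+1}"])
            assert np.isclose(occ[0], (lab == 0).mean())

    def test_iid_states_transition_frequency(self, rng):
        # stickiness -> 1/k (i.i.d.): expected frequency (k-1)/k
        k = 4
        freqs = []
        for i in range(100):
            lab = rng.integers(0, k, 150)
            model = StateModel(k, np.zeros((k, 1)), {"s": lab}, 0.0, 0)
            freqs.append(state_dynamics(model).iloc[0]["transition_frequency"])
        assert np.mean(freqs) == pytest.approx((k - 1) / k, abs=0.02)

    def test_subject_order_invariance(self, small_stacks):
        m1 = fit_states(small_stacks, k=3, seed=5)
        m2 = fit_states(small_stacks[::-1], k=3, seed=5)
        d1 = state_dynamics(m1).set_index("subject_id")["n_transitions"]
        d2 = state_dynamics(m2).set_index("subject_id")["n_transitions"]
        # metrics per subject identical up to state relabeling
        assert (d1.sort_index() == d2.sort_index()).all()


class TestStatewise:
    def test_single_state_subject_mean_equals_overall(self):
        z = np.random.default_rng(0).standard_normal((12, 3))
        st = _stack_from_z(z, sid="s0", P=3)
        model = StateModel(3, np.zeros((3, 3)),
                           {"s0": np.zeros(12, int)}, 0.0, 0)
        sw = statewise_connectivity(model, [st])
        assert np.allclose(sw["s0"][0], z.mean(axis=0))
        assert set(sw["s0"]) == {0}

    def test_two_window_mean(self):
        z = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0], [10.0, 10.0, 10.0]])
        st = _stack_from_z(z, sid="s0", P=3)
        model = StateModel(2, np.zeros((2, 3)),
                           {"s0": np.array([0, 0, 1])}, 0.0, 0)
        sw = statewise_connectivity(model, [st])
        assert np.allclose(sw["s0"][0], [2.0, 2.0, 2.0])
        assert np.allclose(sw["s0"][1], [10.0, 10.0, 10.0])

    def test_window_accounting_invariant(self, small_stacks):
        model = fit_states(small_stacks, k=3, seed=1)
        d = state_dynamics(model)
        occ = d[[f"occupancy_state{j+1}" for j in range(3)]].to_numpy()
        W = small_stacks[0].n_windows
        assert np.allclose(occ.sum(axis=1) * W, W)
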