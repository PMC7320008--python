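import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from fuscon.dynamic import (
    _kmedians_once,
    hilbert_phase,
    kmeans_states,
    match_states,
    occurrence_group_stats,
    phase_locking,
    pool_features,
    unvectorize_matrix,
    vectorize_matrix,
)
from fuscon.preprocess import preprocess
from fuscon.simulate import (
    CohortConfig,
    StateSpec,
    build_transition_matrix,
    simulate_roi_signals,
    simulate_state_sequence,
)
from fuscon.static_fc import correlation_matrix

from conftest import sinusoid_set

FP = 0.4


class TestHilbertPhase:
    def test_retained_length_and_duration(self):
        s = sinusoid_set([0.1], n_t=1500)
        ph = hilbert_phase(s)
        assert ph.phases.shape == (1, 1300)
        assert ph.phases.shape[1] * FP == pytest.approx(520.0)

    def test_phase_advances_at_carrier_rate(self):
        s = sinusoid_set([0.1], n_t=1500)
        ph = np.unwrap(hilbert_phase(s).phases[0])
        slope = np.polyfit(np.arange(ph.size) * FP, ph, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 0.1, rel=0.01)

    def test_sign_flip_shifts_phase_by_pi(self):
        s = sinusoid_set([0.1, 0.1], phases=[0.0, np.pi], n_t=1500)
        ph = hilbert_phase(s).phases
        diff = np.angle(np.exp(1j * (ph[0] - ph[1])))
        np.testing.assert_allclose(np.abs(diff), np.pi, atol=1e-6)

    def test_short_series_rejected(self):
        s = sinusoid_set([0.1], n_t=200)
        with pytest.raises(ValueError):
            hilbert_phase(s)

    def test_requires_preprocessed_flag(self):
        s = sinusoid_set([0.1], n_t=1500, normalized=False)
        with pytest.raises(ValueError, match="band-passed"):
            hilbert_phase(s)


class TestPhaseLocking:
    def test_unit_diagonal_symmetry_range(self):
        s = sinusoid_set([0.1, 0.08, 0.12], n_t=1500)
        mpl = phase_locking(hilbert_phase(s)).mpl
        np.testing.assert_allclose(mpl[0, 0], 1.0)
        np.testing.assert_allclose(mpl, mpl.transpose(1, 0, 2), atol=1e-12)
        assert (np.abs(mpl) <= 1.0 + 1e-12).all()

    def test_antiphase_gives_minus_one(self):
        s = sinusoid_set([0.1, 0.1], phases=[0.0, np.pi], n_t=1500)
        mpl = phase_locking(hilbert_phase(s)).mpl
        np.testing.assert_allclose(mpl[0, 1], -1.0, atol=0.02)

    def test_quarter_cycle_shift_averages_to_zero(self):
        s = sinusoid_set([0.1, 0.1], phases=[0.0, np.pi / 2], n_t=1500)
        mpl = phase_locking(hilbert_phase(s)).mpl
        assert abs(mpl[0, 1].mean()) < 0.02

    def test_time_average_approximates_static_pearson(self, rng):
        # narrow-band signals: <cos(dphi)> tracks the static correlation
        cfg = CohortConfig(noise_sd=0.05)
        t = cfg.transition_matrix("control")
        seq = simulate_state_sequence(t, 1500, rng)
        series = preprocess(simulate_roi_signals(cfg, seq, "control", rng))
        mpl = phase_locking(hilbert_phase(series)).mpl
        r = correlation_matrix(series).r
        assert np.abs(mpl.mean(axis=2) - r).max() < 0.1


class TestPoolFeatures:
    def _tensor(self, n_t, animal="a"):
        s = sinusoid_set(np.full(10, 0.1), phases=np.linspace(0, 3, 10), n_t=n_t)
        s.animal_id = animal
        return phase_locking(hilbert_phase(s))

    def test_shapes(self):
        t1 = self._tensor(1500, "a")
        t2 = self._tensor(1500, "b")
        x, idx = pool_features([t1, t2])
        assert x.shape == (2 * 1300, 45)
        assert list(idx.columns) == ["animal_id", "group", "frame"]
        assert (idx["animal_id"] == "a").sum() == 1300

    def test_vectorize_roundtrip(self, rng):
        m = rng.normal(size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        np.testing.assert_array_equal(unvectorize_matrix(vectorize_matrix(m), 6), m)

    def test_roi_mismatch_rejected(self):
        t1 = self._tensor(1500)
        t2 = self._tensor(1500)
        t2.roi_labels = list(t2.roi_labels)
        t2.roi_labels[0] = "other"
        with pytest.raises(ValueError, match="ROI"):
            pool_features([t1, t2])


def _planted_clusters(rng, k=3, n_per=120, d=45, spread=0.05):
    centers = rng.choice([-1.0, 1.0], size=(k, d))
    while np.unique(centers, axis=0).shape[0] < k:
        centers = rng.choice([-1.0, 1.0], size=(k, d))
    x = np.vstack([c + rng.normal(0, spread, size=(n_per, d)) for c in centers])
    truth = np.repeat(np.arange(k), n_per)
    index = pd.DataFrame(
        {"animal_id": "a", "group": "control", "frame": np.arange(x.shape[0])}
    )
    return x, truth, index


class TestKMeansStates:
    def test_recovers_planted_partition(self, rng):
        x, truth, index = _planted_clusters(rng)
        labels = [f"r{i}" for i in range(10)]
        model = kmeans_states(x, index, labels, k=3, n_replicates=10, rng=0)
        pred = model.labels["state"].to_numpy()
        conf = np.zeros((3, 3))
        for t, p in zip(truth, pred):
            conf[t, p] += 1
        rows, cols = linear_sum_assignment(-conf)
        assert conf[rows, cols].sum() == truth.size

    def test_k_one_centroid_is_global_median(self, rng):
        x, _, index = _planted_clusters(rng, k=2, n_per=50)
        model = kmeans_states(x, index, [f"r{i}" for i in range(10)], k=1,
                              n_replicates=2, rng=0)
        np.testing.assert_allclose(
            vectorize_matrix(model.centroids[0]), np.median(x, axis=0), atol=1e-12
        )

    def test_objective_matches_recomputation_and_replicate_minimum(self, rng):
        x, _, index = _planted_clusters(rng, spread=0.4)
        model = kmeans_states(x, index, [f"r{i}" for i in range(10)], k=3,
                              n_replicates=8, rng=1)
        feats = model.centroid_features()
        from scipy.spatial.distance import cdist

        d = cdist(x, feats, metric="cityblock")
        assert model.objective == pytest.approx(d.min(axis=1).sum(), rel=1e-9)
        assert model.objective == pytest.approx(min(model.replicate_objectives))

    def test_objective_non_increasing_within_run(self, rng):
        x, _, _ = _planted_clusters(rng, spread=0.5)
        _, _, _, history = _kmedians_once(x, 3, np.random.default_rng(5), 300)
        assert all(b <= a + 1e-9 for a, b in zip(history, history[1:]))

    def test_seeded_model_is_bit_identical(self, rng):
        x, _, index = _planted_clusters(rng, spread=0.3)
        labels = [f"r{i}" for i in range(10)]
        m1 = kmeans_states(x, index, labels, k=3, n_replicates=5, rng=9)
        m2 = kmeans_states(x, index, labels, k=3, n_replicates=5, rng=9)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)
        assert (m1.labels["state"] == m2.labels["state"]).all()

    def test_more_clusters_than_distinct_rows_rejected(self):
        x = np.tile([[1.0, 2.0]], (10, 1))
        index = pd.DataFrame(
            {"animal_id": "a", "group": "g", "frame": np.arange(10)}
        )
        with pytest.raises(ValueError, match="distinct"):
            kmeans_states(x, index, ["a", "b"], k=2, n_replicates=2, rng=0)

    def test_occurrence_rows_sum_to_one(self, rng):
        x, _, index = _planted_clusters(rng)
        index = index.copy()
        index.loc[index.index >= 180, "animal_id"] = "b"
        model = kmeans_states(x, index, [f"r{i}" for i in range(10)], k=3,
                              n_replicates=5, rng=0)
        np.testing.assert_allclose(model.occurrence.sum(axis=1), 1.0, atol=1e-9)


class TestMatchStates:
    def test_self_match_identity(self, rng):
        x, _, index = _planted_clusters(rng)
        model = kmeans_states(x, index, [f"r{i}" for i in range(10)], k=3,
                              n_replicates=5, rng=0)
        m = match_states(model, model)
        assert (m["state_a"] == m["state_b"]).all()
        np.testing.assert_allclose(m["l1_distance"], 0.0, atol=1e-12)

    def test_surplus_state_left_unmatched(self, rng):
        x, _, index = _planted_clusters(rng, k=4, n_per=80)
        labels = [f"r{i}" for i in range(10)]
        m3 = kmeans_states(x, index, labels, k=3, n_replicates=6, rng=0)
        m4 = kmeans_states(x, index, labels, k=4, n_replicates=6, rng=0)
        m = match_states(m3, m4)
        assert len(m) == 3
        assert set(m["state_b"]) < set(range(4))


class TestEndToEndIdentifiability:
    def test_noise_free_constant_states_recovered_exactly(self, rng):
        """Animals frozen in distinct planted states, no noise: clustering
        must label every frame correctly up to permutation."""
        cfg = CohortConfig(noise_sd=0.0, n_frames=700)
        tensors = []
        truth = []
        for s, animal in zip(range(3), "abc"):
            seq = np.full(700, s, dtype=int)
            series = preprocess(simulate_roi_signals(cfg, seq, "control", rng,
                                                     animal_id=animal))
            tensors.append(phase_locking(hilbert_phase(series)))
            truth.append(np.full(500, s))
        x, index = pool_features(tensors)
        model = kmeans_states(x, index, cfg.roi_labels, k=3, n_replicates=10, rng=0)
        truth = np.concatenate(truth)
        pred = model.labels["state"].to_numpy()
        conf = np.zeros((3, 3))
        for t, p in zip(truth, pred):
            conf[t, p] += 1
        rows, cols = linear_sum_assignment(-conf)
        assert conf[rows, cols].sum() == truth.size

    def test_accuracy_degrades_gracefully_with_noise(self, rng):
        accs = []
        for noise in (0.05, 1.0):
            cfg = CohortConfig(noise_sd=noise, n_frames=700, dwell_scale=100.0)
            t = cfg.transition_matrix("control")
            tensors, truths = [], []
            for animal in "ab":
                seq = simulate_state_sequence(t, 700, rng)
                series = preprocess(
                    simulate_roi_signals(cfg, seq, "control", rng, animal_id=animal)
                )
                tensors.append(phase_locking(hilbert_phase(series)))
                truths.append(seq[100:-100])
            x, index = pool_features(tensors)
            model = kmeans_states(x, index, cfg.roi_labels, k=5,
                                  n_replicates=10, rng=0)
            truth = np.concatenate(truths)
            pred = model.labels["state"].to_numpy()
            conf = np.zeros((5, 5))
            for tt, p in zip(truth, pred):
                conf[tt, p] += 1
            rows, cols = linear_sum_assignment(-conf)
            accs.append(conf[rows, cols].sum() / truth.size)
        assert accs[0] > accs[1]


class TestOccurrenceStats:
    # occupancy-estimation error is governed by the dwell/duration ratio;
    # a 10 s dwell (25 frames) gives each animal enough independent state
    # visits for its occurrence rate to be well estimated
    @staticmethod
    def _occupancies(rng, occ_control, occ_arthritic, n_frames=1300, n_per_group=9):
        rows, groups = {}, {}
        for g, occ, prefix in (
            ("control", occ_control, "C"),
            ("arthritic", occ_arthritic, "A"),
        ):
            t = build_transition_matrix(np.asarray(occ), 25.0)
            for i in range(n_per_group):
                seq = simulate_state_sequence(t, n_frames, rng)
                counts = np.bincount(seq, minlength=len(occ)) / n_frames
                aid = f"{prefix}{i}"
                rows[aid] = counts
                groups[aid] = g
        occ_df = pd.DataFrame.from_dict(rows, orient="index")
        occ_df.columns = [f"state_{j}" for j in range(occ_df.shape[1])]
        return occ_df, pd.Series(groups)

    def test_planted_occupancy_shift_detected(self, rng):
        hits = 0
        for _ in range(100):
            occ, groups = self._occupancies(
                rng, (0.5, 0.1, 0.1, 0.15, 0.15), (0.3, 0.2, 0.2, 0.15, 0.15)
            )
            table = occurrence_group_stats(occ, groups)
            hits += bool(table.loc[table["state"] == "state_0", "significant"].iloc[0])
        assert hits >= 80

    def test_null_occupancy_rarely_flagged(self, rng):
        flagged = 0
        n_seeds = 100
        for _ in range(n_seeds):
            occ, groups = self._occupancies(
                rng, (0.5, 0.1, 0.1, 0.15, 0.15), (0.5, 0.1, 0.1, 0.15, 0.15)
            )
            flagged += occurrence_group_stats(occ, groups)["significant"].any()
        se = np.sqrt(0.05 * 0.95 / n_seeds)
        assert flagged / n_seeds <= 0.05 + 2 * se

    def test_small_group_rejected(self, rng):
        occ, groups = self._occupancies(
            rng, (0.5, 0.5), (0.5, 0.5), n_per_group=2
        )
        with pytest.raises(ValueError, match="3 animals"):
            occurrence_group_stats(occ, groups)
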