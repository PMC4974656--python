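import numpy as np
import pytest

from saltpepper.preprocess import kurtosis, neuropil_correct
from saltpepper.stimulus import FourierGrid, ScreenGeometry
from saltpepper.synthetic_data import (
    GroundTruthCell,
    ResponseConfig,
    SheetConfig,
    default_temporal_kernel,
    generate_dataset,
    generate_preference_maps,
    generate_running,
    ground_truth_kernel,
    place_cells,
    simulate_interneurons,
    simulate_spikes,
    spikes_to_fluorescence,
)

GRID = FourierGrid(ScreenGeometry())


def _nearest_neighbour_ori_diffs(field_um, map_length_um, seed, n=3000):
    ori, _ = generate_preference_maps(field_um, map_length_um, grid_step_um=2.0,
                                      seed=seed)
    rng = np.random.default_rng(seed + 1)
    n_grid = ori.shape[0]
    # pairs of adjacent grid nodes ~ few um apart
    r = rng.integers(1, n_grid - 1, n)
    c = rng.integers(1, n_grid - 1, n)
    d = np.abs(ori[r, c] - ori[r, c + 1]) % 180
    return np.minimum(d, 180 - d)


class TestPreferenceMaps:
    def test_salt_and_pepper_orientation_diffs_uniform(self):
        """map_length 0: neighbour orientation differences ~ U[0, 90)."""
        diffs = []
        for seed in range(4):
            ori, _ = generate_preference_maps(200.0, 0.0, 2.0, seed=seed)
            rng = np.random.default_rng(seed)
            a = ori[rng.integers(0, 100, 2500), rng.integers(0, 100, 2500)]
            b = ori[rng.integers(0, 100, 2500), rng.integers(0, 100, 2500)]
            d = np.abs(a - b) % 180
            diffs.append(np.minimum(d, 180 - d))
        diffs = np.concatenate(diffs)
        assert diffs.mean() == pytest.approx(45.0, abs=2.0)
        assert diffs.max() <= 90.0

    def test_smoothed_map_nearby_points_similar(self):
        """200-um map: pairs < 20 um apart have median |dori| < 15 deg."""
        diffs = np.concatenate(
            [_nearest_neighbour_ori_diffs(400.0, 200.0, seed) for seed in range(3)]
        )
        assert np.median(diffs) < 15.0

    def test_seed_determinism(self):
        a = generate_preference_maps(100.0, 30.0, 2.0, seed=9)
        b = generate_preference_maps(100.0, 30.0, 2.0, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_log_sf_scaling(self):
        _, lsf = generate_preference_maps(300.0, 0.0, 2.0, seed=2,
                                          sf_log_mean=-3.2, sf_log_sd=0.45)
        assert lsf.mean() == pytest.approx(-3.2, abs=0.02)
        assert lsf.std() == pytest.approx(0.45, abs=0.02)


class TestPlaceCells:
    def test_min_soma_separation(self):
        cells = place_cells(SheetConfig(n_cells=50, field_um=250.0, seed=0))
        pos = np.array([[c.x_um, c.y_um] for c in cells])
        d = np.linalg.norm(pos[None] - pos[:, None], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0

    def test_impossible_density_errors(self):
        with pytest.raises(RuntimeError):
            place_cells(SheetConfig(n_cells=100, field_um=20.0, seed=0))

    def test_columnar_maps_shared_across_planes(self):
        """decorrelation 0: preferences at matching locations in different
        planes come from one shared map."""
        cfg = SheetConfig(n_cells=40, field_um=200.0, map_length_um=40.0,
                          plane_depths_um=(0.0, 40.0, 80.0, 120.0),
                          column_decorrelation=0.0, seed=3)
        cells = place_cells(cfg)
        by_plane = {}
        for c in cells:
            by_plane.setdefault(c.depth_um, []).append(c)
        # nearest cross-plane neighbours should have similar orientation
        a = by_plane[0.0]
        b = by_plane[120.0]
        diffs = []
        for ca in a:
            d = [np.hypot(ca.x_um - cb.x_um, ca.y_um - cb.y_um) for cb in b]
            cb = b[int(np.argmin(d))]
            if min(d) < 15.0:
                dd = abs(ca.pref_orientation_deg - cb.pref_orientation_deg) % 180
                diffs.append(min(dd, 180 - dd))
        assert len(diffs) >= 3
        assert np.median(diffs) < 20.0

    def test_full_decorrelation_kills_cross_plane_similarity(self):
        diffs = []
        for seed in range(5):
            cfg = SheetConfig(n_cells=40, field_um=200.0, map_length_um=40.0,
                              plane_depths_um=(0.0, 40.0),
                              column_decorrelation=1.0, seed=seed)
            cells = place_cells(cfg)
            a = [c for c in cells if c.depth_um == 0.0]
            b = [c for c in cells if c.depth_um == 40.0]
            for ca in a:
                d = [np.hypot(ca.x_um - cb.x_um, ca.y_um - cb.y_um) for cb in b]
                cb = b[int(np.argmin(d))]
                if min(d) < 15.0:
                    dd = abs(ca.pref_orientation_deg - cb.pref_orientation_deg) % 180
                    diffs.append(min(dd, 180 - dd))
        assert np.mean(diffs) > 30.0  # ~45 under independence


class TestGroundTruthKernel:
    def test_peak_at_preference_without_bias(self):
        w = ground_truth_kernel(45.0, 0.05, 20.0, 0.7, 0.0, GRID)
        i = int(np.argmax(w))
        assert abs(GRID.orientation_deg[i] - 45.0) < 10.0
        assert np.log2(GRID.sf_cpd[i] / 0.05) == pytest.approx(0.0, abs=0.5)
        assert w.max() == pytest.approx(1.0)

    def test_identical_preferences_give_similarity_one(self):
        w1 = ground_truth_kernel(30.0, 0.04, 20.0, 0.7, 0.35, GRID)
        w2 = ground_truth_kernel(30.0, 0.04, 20.0, 0.7, 0.35, GRID)
        assert np.corrcoef(w1, w2)[0, 1] == pytest.approx(1.0)

    def test_low_sf_bias_gives_positive_similarity_for_orthogonal_prefs(self):
        """The shared low-SF template keeps even orthogonally tuned cells
        positively correlated (the non-zero similarity asymptote)."""
        w1 = ground_truth_kernel(0.0, 0.03, 20.0, 0.7, 1.0, GRID)
        w2 = ground_truth_kernel(90.0, 0.12, 20.0, 0.7, 1.0, GRID)
        assert np.corrcoef(w1, w2)[0, 1] > 0.0
        w1n = ground_truth_kernel(0.0, 0.03, 20.0, 0.7, 0.0, GRID)
        w2n = ground_truth_kernel(90.0, 0.12, 20.0, 0.7, 0.0, GRID)
        assert np.corrcoef(w1, w2)[0, 1] > np.corrcoef(w1n, w2n)[0, 1]

    def test_out_of_grid_preference_errors(self):
        with pytest.raises(ValueError):
            ground_truth_kernel(45.0, 0.5, 20.0, 0.7, 0.0, GRID)


def _make_cell(w=None, gain=1.0, baseline=0.5, inter=False):
    return GroundTruthCell(
        x_um=0, y_um=0, depth_um=0, roi_area_um2=100.0,
        pref_orientation_deg=45.0, pref_sf_cpd=0.05,
        gain=gain, baseline_rate_hz=baseline, is_interneuron=inter, w_true=w,
    )


class TestSimulateSpikes:
    def test_gain_zero_is_poisson_baseline(self, short_design):
        cell = _make_cell(w=np.zeros(GRID.n_cells), gain=0.0, baseline=2.0)
        running = np.zeros(short_design.n_frames)
        counts = simulate_spikes([cell], short_design, default_temporal_kernel(),
                                 running, ResponseConfig(run_gain_hz=0.0), seed=0)
        mean = counts.mean() * short_design.imaging_rate_hz
        var = counts.var()
        assert mean == pytest.approx(2.0, rel=0.1)
        # Poisson: variance of counts equals their mean
        assert var == pytest.approx(counts.mean(), rel=0.1)

    def test_gain_doubles_modulation(self, short_design):
        w = ground_truth_kernel(45.0, 0.05, 20.0, 0.7, 0.35, GRID)
        running = np.zeros(short_design.n_frames)
        resp = ResponseConfig(run_gain_hz=0.0, baseline_rate_hz=10.0,
                              drive_threshold_frac=0.0)
        rates = []
        for gain in (1.0, 2.0):
            c = _make_cell(w=w, gain=gain, baseline=10.0)
            counts = simulate_spikes([c], short_design, default_temporal_kernel(),
                                     running, resp, seed=1)
            rates.append(counts.mean() * short_design.imaging_rate_hz - 10.0)
        assert rates[1] == pytest.approx(2 * rates[0], rel=0.15)

    def test_condition_triggered_mean_recovers_kernel(self, full_design):
        """The empirical condition-triggered rate correlates with w_true."""
        w = ground_truth_kernel(60.0, 0.05, 20.0, 0.7, 0.35, GRID)
        cell = _make_cell(w=w, gain=2.0, baseline=0.1)
        running = np.zeros(full_design.n_frames)
        counts = simulate_spikes([cell], full_design, default_temporal_kernel(),
                                 running, ResponseConfig(run_gain_hz=0.0), seed=2)[0]
        lag = 2  # peak of the temporal kernel
        cond = full_design.lagged_condition(lag)
        means = np.array([counts[cond == j].mean() for j in range(GRID.n_cells)])
        assert np.corrcoef(means, w)[0, 1] > 0.9


class TestSpikesToFluorescence:
    def test_single_spike_ar1_decay(self):
        s = np.zeros(100)
        s[10] = 1.0
        raw, _ = spikes_to_fluorescence(s, noise_sigma=0.0, drift_amp=0.0,
                                        neuropil_weight=0.0, seed=0,
                                        spike_amplitude=1.0, population_weight=0.0)
        gamma = 2.0 ** (-(1000 / 15.5) / 135.0)
        expected = np.zeros(100)
        expected[10:] = gamma ** np.arange(90)
        assert np.allclose(raw[0], expected)
        # the trace halves every tau_half: ~2.09 frames
        assert raw[0, 10] / raw[0, 12] == pytest.approx(2.0, rel=0.05)

    def test_seed_determinism_bitwise(self):
        rng = np.random.default_rng(0)
        s = rng.poisson(0.1, (3, 500)).astype(float)
        a = spikes_to_fluorescence(s, seed=42)
        b = spikes_to_fluorescence(s, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


@pytest.fixture(scope="module")
def dataset():
    return generate_dataset(
        SheetConfig(n_cells=30, seed=11, interneuron_fraction=0.2), seed=11
    )


class TestInterneurons:
    def test_interneuron_traces_have_low_kurtosis(self, dataset):
        ks = []
        for i, c in enumerate(dataset.cells):
            if c.is_interneuron:
                corr, _, _ = neuropil_correct(dataset.raw_traces[i],
                                              dataset.neuropil_traces[i])
                ks.append(kurtosis(corr))
        assert len(ks) >= 3
        assert np.mean(np.array(ks) < 7) > 0.9

    def test_pyramidal_traces_have_high_kurtosis(self, dataset):
        ks = []
        for i, c in enumerate(dataset.cells):
            if not c.is_interneuron:
                corr, _, _ = neuropil_correct(dataset.raw_traces[i],
                                              dataset.neuropil_traces[i])
                ks.append(kurtosis(corr))
        assert np.mean(np.array(ks) > 15) > 0.9

    def test_single_neighbour_pooling_correlates(self, short_design):
        """k=1, zero tonic baseline: the interneuron rate tracks its
        neighbour's smoothed rate, so their calcium correlates."""
        import scipy.signal

        rng = np.random.default_rng(3)
        w = ground_truth_kernel(10.0, 0.04, 20.0, 0.7, 0.35, GRID)
        pyr = _make_cell(w=w, gain=20.0, baseline=1.0)
        pyr.x_um = 10.0
        inter = _make_cell(inter=True, baseline=0.0)
        cells = [pyr, inter]
        running = np.zeros(short_design.n_frames)
        resp = ResponseConfig(k_neighbours=1, interneuron_baseline_hz=0.0,
                              run_gain_hz=0.0, drive_threshold_frac=0.0)
        counts = simulate_spikes(cells, short_design, default_temporal_kernel(),
                                 running, resp, seed=4)
        counts = simulate_interneurons(cells, counts, running,
                                       short_design.imaging_rate_hz, resp, seed=5)
        gamma = 2.0 ** (-(1000 / 15.5) / 135.0)
        ca = scipy.signal.lfilter([1.0], [1.0, -gamma], counts, axis=1)
        assert np.corrcoef(ca[0], ca[1])[0, 1] > 0.5

    def test_too_few_pyramidal_errors(self, short_design):
        cells = [_make_cell(inter=True)]
        with pytest.raises(ValueError):
            simulate_interneurons(cells, np.zeros((1, 100)), np.zeros(100),
                                  15.5, ResponseConfig(k_neighbours=1), seed=0)


class TestDatasetDeterminism:
    def test_same_seed_bitwise_identical(self):
        a = generate_dataset(SheetConfig(n_cells=8, seed=5), duration_s=60.0, seed=5)
        b = generate_dataset(SheetConfig(n_cells=8, seed=5), duration_s=60.0, seed=5)
        assert np.array_equal(a.raw_traces, b.raw_traces)
        assert np.array_equal(a.spike_counts, b.spike_counts)
        assert np.array_equal(a.stimulus.kx, b.stimulus.kx)

    def test_running_indicator_binary_with_bouts(self):
        r = generate_running(10_000, 15.5, np.random.default_rng(0))
        assert set(np.unique(r)) <= {0.0, 1.0}
        assert 0.02 < r.mean() < 0.6
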