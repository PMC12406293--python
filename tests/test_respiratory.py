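"""Respiratory gating: ROI matrix, spectral embedding, orientation, selection."""

import numpy as np
import pytest

import cinesync as cs
from cinesync import respiratory as rsp
from cinesync.errors import (
    DisconnectedGraphError,
    NoPeakError,
    OrientationError,
    RoiBoundsError,
    SelectionTooShortError,
)


def _edge_series(n_frames=60, rows=40, cols=30, shift_per_frame=0.5, noise=0.0, seed=0):
    """Bright edge translating downward: displacement known by construction."""
    rng = np.random.default_rng(seed)
    y = np.arange(rows)[None, :, None]
    disp = shift_per_frame * np.arange(n_frames)
    series = 1.0 / (1.0 + np.exp(-(y - 15.0 - disp[:, None, None])))
    series = np.broadcast_to(series, (n_frames, rows, cols)).copy()
    if noise:
        series += rng.normal(0, noise, series.shape)
    return series, disp


class TestRoiMatrix:
    def test_shape_contract(self):
        series = np.zeros((10, 20, 20))
        series += np.random.default_rng(1).normal(size=series.shape)
        roi = cs.RoiSpec(0, (2, 6), (3, 8))
        assert cs.extract_roi_matrix(series, roi).shape == (10, 20)

    def test_out_of_bounds_roi(self):
        with pytest.raises(RoiBoundsError):
            cs.extract_roi_matrix(np.zeros((5, 10, 10)), cs.RoiSpec(0, (0, 12), (0, 4)))

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            cs.RoiSpec(0, (4, 4), (0, 2))

    def test_identical_frames_rows_equal_with_warning(self):
        series = np.ones((6, 8, 8))
        with pytest.warns(UserWarning, match="constant"):
            mat = cs.extract_roi_matrix(series, cs.RoiSpec(0, (0, 4), (0, 4)))
        assert np.allclose(mat, mat[0])

    def test_moving_edge_rows_diverge_monotonically(self):
        series, _ = _edge_series(n_frames=8, shift_per_frame=1.0)
        mat = cs.extract_roi_matrix(series, cs.RoiSpec(0, (5, 35), (0, 30)))
        dists = np.linalg.norm(mat - mat[0], axis=1)
        assert np.all(np.diff(dists) > 0)


class TestEmbedding:
    def test_tracks_1d_translation(self):
        series, disp = _edge_series(n_frames=80, shift_per_frame=0.25, noise=0.01)
        mat = cs.extract_roi_matrix(series, cs.RoiSpec(0, (5, 35), (0, 30)))
        sig = cs.embed_respiratory_1d(mat, k_neighbors=10)
        assert rsp.spearman_vs_reference(sig, disp) >= 0.95

    def test_identical_frames_get_identical_coordinates(self):
        series, _ = _edge_series(n_frames=30, shift_per_frame=0.5)
        series[17] = series[3]  # duplicate frame
        mat = cs.extract_roi_matrix(series, cs.RoiSpec(0, (5, 35), (0, 30)))
        sig = cs.embed_respiratory_1d(mat, k_neighbors=6)
        assert sig.values[17] == pytest.approx(sig.values[3], abs=1e-9)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            cs.embed_respiratory_1d(np.random.default_rng(0).normal(size=(5, 9)),
                                    k_neighbors=10)

    def test_disconnected_graph_reports_component(self):
        # two well-separated frame clusters, k too small to bridge them
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.01, size=(12, 6))
        b = rng.normal(100, 0.01, size=(8, 6))
        with pytest.raises(DisconnectedGraphError) as err:
            cs.embed_respiratory_1d(np.vstack([a, b]), k_neighbors=3)
        assert err.value.largest_component == 12

    def test_structureless_frames_warn_low_autocorrelation(self):
        mat = np.random.default_rng(3).normal(size=(60, 25))
        with pytest.warns(UserWarning, match="autocorrelation"):
            cs.embed_respiratory_1d(mat, k_neighbors=10)


class TestOrientation:
    @pytest.fixture()
    def phantom_slice(self, noisy_phantom):
        params, stack, truth = noisy_phantom
        roi = cs.RoiSpec(0, *cs.default_diaphragm_roi(params))
        frames = stack.slices[0]
        mat = cs.extract_roi_matrix(frames, roi)
        sig = cs.embed_respiratory_1d(mat, dt_ms=params.dt_ms)
        return params, frames, roi, sig, truth

    def test_peaks_at_end_expiration(self, phantom_slice):
        params, frames, roi, sig, truth = phantom_slice
        oriented = cs.orient_for_expiration(sig, frames, roi)
        oriented = cs.find_peaks(oriented)
        # ground-truth displacement is 0 at end expiration
        disp = truth.resp_displacement[0][oriented.peaks]
        assert np.all(disp <= 0.1 * params.resp_amp_px)

    def test_sign_invariance_of_heuristic(self, phantom_slice):
        _, frames, roi, sig, _ = phantom_slice
        flipped = rsp.RespiratorySignal(values=-sig.values, dt_ms=sig.dt_ms)
        a = cs.orient_for_expiration(sig, frames, roi)
        b = cs.orient_for_expiration(flipped, frames, roi)
        np.testing.assert_allclose(a.values, b.values)

    def test_override_wins(self, phantom_slice):
        _, frames, roi, sig, _ = phantom_slice
        forced = cs.orient_for_expiration(sig, frames, roi, override_sign=-1)
        np.testing.assert_allclose(forced.values, -sig.values)

    def test_uninformative_roi_requires_override(self):
        rng = np.random.default_rng(4)
        frames = rng.normal(size=(40, 20, 20))
        roi = cs.RoiSpec(0, (0, 20), (0, 20))
        sig = rsp.RespiratorySignal(values=rng.normal(size=40), dt_ms=36.0)
        with pytest.raises(OrientationError):
            cs.orient_for_expiration(sig, frames, roi)


class TestSelection:
    def _signal(self, values, dt_ms=36.0):
        sig = rsp.RespiratorySignal(values=np.asarray(values, float),
                                    dt_ms=dt_ms, oriented=True)
        # raw values as-is: no smoothing, no separation prior
        return rsp.find_peaks(sig, smooth_window=1, min_separation_s=0.0)

    def test_worked_toy_selection(self):
        # two peaks; band 1.0 below each peak; the first run is longer
        sig = self._signal([0, 1, 2, 3, 2, 1, 0, 1, 2, 3.1, 3.0, 2, 0])
        sel = rsp.select_end_expiratory_frames(sig, tolerance_frac=1.0 / 3.1, min_run=0)
        assert sel.peak == 3
        assert sel.frames == (2, 5)
        assert sel.n_frames == 3

    def test_monotone_signal_has_no_peak(self):
        sig = self._signal(np.arange(30.0))
        with pytest.raises(NoPeakError):
            rsp.select_end_expiratory_frames(sig, min_run=0)

    def test_short_selection_rejected(self):
        sig = self._signal([0, 1, 0, 1, 5, 1, 0])
        with pytest.raises(SelectionTooShortError, match="tolerance"):
            rsp.select_end_expiratory_frames(sig, tolerance_frac=0.1, min_run=20)

    def test_selection_grows_with_tolerance(self):
        rng = np.random.default_rng(5)
        t = np.arange(300)
        sig = self._signal(np.sin(2 * np.pi * t / 60) + 0.05 * rng.normal(size=300))
        lengths = [
            rsp.select_end_expiratory_frames(sig, tolerance_frac=f, min_run=0).n_frames
            for f in (0.05, 0.1, 0.2, 0.3, 0.5)
        ]
        assert all(b >= a for a, b in zip(lengths, lengths[1:]))

    def test_phantom_run_length_tens_of_frames(self, noisy_phantom):
        # breathing dwell at end expiration yields selections of a few tens of
        # frames at the default tolerance, the scale needed to hold an R-R
        params, stack, truth = noisy_phantom
        roi = cs.RoiSpec(0, *cs.default_diaphragm_roi(params))
        lengths = []
        for s in range(params.n_slices):
            frames = stack.slices[s]
            mat = cs.extract_roi_matrix(frames, roi)
            sig = cs.embed_respiratory_1d(mat, dt_ms=params.dt_ms)
            sig = cs.find_peaks(cs.orient_for_expiration(sig, frames, roi))
            lengths.append(cs.select_end_expiratory_frames(sig).n_frames)
        assert 20 <= np.mean(lengths) <= 80

    def test_selection_invariant_under_embedding_sign_flip(self, noisy_phantom):
        params, stack, _ = noisy_phantom
        roi = cs.RoiSpec(0, *cs.default_diaphragm_roi(params))
        frames = stack.slices[1]
        mat = cs.extract_roi_matrix(frames, roi)
        sig = cs.embed_respiratory_1d(mat, dt_ms=params.dt_ms)
        flipped = rsp.RespiratorySignal(values=-sig.values, dt_ms=sig.dt_ms)
        sels = []
        for raw in (sig, flipped):
            oriented = cs.find_peaks(cs.orient_for_expiration(raw, frames, roi))
            sels.append(cs.select_end_expiratory_frames(oriented))
        assert sels[0].frames == sels[1].frames
        assert sels[0].peak == sels[1].peak
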