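import numpy as np
import pytest
from skimage import draw, morphology

from mitopulse.segment import (
    MitoMeasurement,
    SegmentationConfig,
    detect_artifact_frames,
    link_tracks,
    segment_frame,
    segment_movie,
    smooth,
    subtract_background,
)
from mitopulse.simulate import simulate_movie
from mitopulse.traces import form_factor

from conftest import single_mito_params


class TestSubtractBackground:
    def test_constant_image_goes_to_zero(self):
        img = np.full((64, 64), 37.0)
        np.testing.assert_allclose(subtract_background(img, 10), 0.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.random((80, 80)) * 50
        a = subtract_background(img, 8)
        b = subtract_background(img + 123.0, 8)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_spot_preserved_against_opening_oracle(self):
        # independent oracle: direct morphological opening with the same disk
        img = np.zeros((160, 160))
        img[80:83, 80:83] = 500.0
        out = subtract_background(img, 50, approximate=False)
        oracle = img - morphology.opening(img, morphology.disk(50))
        np.testing.assert_allclose(out, np.maximum(oracle, 0.0))
        assert out[80:83, 80:83].sum() == pytest.approx(img.sum(), rel=0.01)

    def test_fast_path_matches_exact_on_smooth_background(self):
        yy, xx = np.mgrid[0:256, 0:256]
        img = 40 + 10 * np.sin(xx / 90.0) + 8 * np.cos(yy / 70.0)
        img[100:110, 100:130] += 300.0
        fast = subtract_background(img, 50, approximate=True)
        exact = np.maximum(img - morphology.opening(img, morphology.disk(50)), 0.0)
        obj = np.zeros(img.shape, bool)
        obj[98:112, 98:132] = True
        assert fast[obj].sum() == pytest.approx(exact[obj].sum(), rel=0.02)

    def test_radius_too_large(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((32, 32)), 50)

    def test_output_nonnegative(self):
        rng = np.random.default_rng(2)
        img = rng.random((64, 64)) * 100
        assert subtract_background(img, 5).min() >= 0.0


class TestSmooth:
    def test_impulse_response_is_gaussian_kernel(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = smooth(img, 2.0)
        # oracle: analytic 2-D Gaussian (discrete sampling, interior impulse)
        yy, xx = np.mgrid[0:41, 0:41] - 20.0
        analytic = np.exp(-(xx**2 + yy**2) / (2 * 4.0)) / (2 * np.pi * 4.0)
        np.testing.assert_allclose(out, analytic, atol=2e-4)

    def test_constant_unchanged(self):
        img = np.full((32, 32), 5.5)
        np.testing.assert_allclose(smooth(img, 2.0), 5.5, rtol=1e-12)

    def test_mass_conservation_interior_object(self):
        img = np.zeros((128, 128))
        img[60:70, 58:72] = 9.0
        out = smooth(img, 2.0)
        assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            smooth(np.zeros((8, 8)), 0.0)


class TestSegmentFrame:
    def test_blank_frame_empty(self):
        labels, meas = segment_frame(np.zeros((64, 64)), pixel_size=0.1)
        assert labels.max() == 0
        assert meas == []

    def test_two_capsules_against_simulator_oracle(self, small_sim):
        params, movie, gt = small_sim
        per_frame = segment_movie(movie, SegmentationConfig())
        rec0 = gt.records[gt.records["frame"] == 0]
        assert len(per_frame[0]) == len(rec0)
        for a, b in zip(
            sorted(m.area for m in per_frame[0]), sorted(rec0["area_um2"])
        ):
            assert a == pytest.approx(b, rel=0.05)

    def test_digitized_disk_form_factor(self):
        img = np.zeros((96, 96))
        rr, cc = draw.disk((48, 48), 20)
        img[rr, cc] = 100.0
        _, meas = segment_frame(img, pixel_size=1.0)
        assert len(meas) == 1
        ff = form_factor(meas[0].perimeter, meas[0].area)
        assert ff == pytest.approx(1.0, abs=0.05)

    def test_min_area_filter(self):
        img = np.zeros((64, 64))
        img[10, 10] = 100.0  # single-pixel speck
        img[30:40, 30:40] = 100.0
        _, meas = segment_frame(
            img, pixel_size=1.0, config=SegmentationConfig(min_area_um2=4.0)
        )
        assert len(meas) == 1
        assert meas[0].area == pytest.approx(100.0, rel=0.05)

    def test_measurement_invariants(self, small_sim):
        _, movie, _ = small_sim
        per_frame = segment_movie(movie, SegmentationConfig())
        for meas in per_frame:
            for m in meas:
                assert m.area > 0 and m.perimeter > 0
                assert m.major_axis >= m.minor_axis


def _meas(frame, x, y, label=1, area=1.0):
    return MitoMeasurement(
        frame=frame, label=label, sum_intensity={}, area=area, perimeter=4.0,
        major_axis=1.5, minor_axis=1.0, centroid=(x, y),
    )


class TestLinkTracks:
    def test_stationary_objects_full_tracks(self):
        frames = [[_meas(f, 1.0, 1.0), _meas(f, 8.0, 8.0)] for f in range(10)]
        tracks = link_tracks(frames)
        assert len(tracks) == 2
        assert all(len(t) == 10 for t in tracks)

    def test_every_measurement_in_exactly_one_track(self):
        rng = np.random.default_rng(3)
        frames = []
        pos = rng.random((6, 2)) * 20
        for f in range(8):
            pos = pos + rng.normal(0, 0.05, pos.shape)
            frames.append([_meas(f, x, y) for x, y in pos])
        tracks = link_tracks(frames)
        total = sum(len(t) for t in tracks)
        assert total == 6 * 8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        pos = rng.random((5, 2)) * 15
        frames, shuffled = [], []
        for f in range(6):
            pos = pos + rng.normal(0, 0.05, pos.shape)
            ms = [_meas(f, x, y) for x, y in pos]
            frames.append(ms)
            perm = list(ms)
            rng.shuffle(perm)
            shuffled.append(perm)

        def membership(tracks):
            return {
                frozenset((m.frame, m.centroid) for m in t.measurements) for t in tracks
            }

        assert membership(link_tracks(frames)) == membership(link_tracks(shuffled))

    def test_gating_prevents_long_jumps(self):
        # two objects teleport-swap much farther than max_disp: tracks must
        # terminate and restart rather than swap identities
        a0, b0 = (0.0, 0.0), (10.0, 10.0)
        frames = [
            [_meas(0, *a0), _meas(0, *b0)],
            [_meas(1, 20.0, 20.0), _meas(1, 30.0, 30.0)],
        ]
        tracks = link_tracks(frames, max_disp=2.0, max_gap=0)
        assert len(tracks) == 4
        assert all(len(t) == 1 for t in tracks)

    def test_gap_bridging(self):
        frames = [[_meas(0, 5.0, 5.0)], [], [_meas(2, 5.1, 5.0)]]
        tracks = link_tracks(frames, max_disp=2.0, max_gap=2)
        assert len(tracks) == 1
        assert tracks[0].gap_frames == [1]

    def test_gap_expiry(self):
        frames = [[_meas(0, 5.0, 5.0)], [], [], [], [_meas(4, 5.0, 5.0)]]
        tracks = link_tracks(frames, max_disp=2.0, max_gap=1)
        assert len(tracks) == 2

    def test_simulator_identity_accuracy(self):
        params = single_mito_params(
            n_mitos=5, image_shape=(256, 256), n_frames=15,
            mito_length_range=(0.7, 1.4), mito_width_range=(0.4, 0.5),
            motion_sigma=0.03, rng_seed=5,
        )
        movie, gt = simulate_movie(params)
        per_frame = segment_movie(movie, SegmentationConfig())
        tracks = link_tracks(per_frame)
        assert len(tracks) == 5
        correct = total = 0
        for tr in tracks:
            ids = []
            for m in tr.measurements:
                sub = gt.records[gt.records["frame"] == m.frame]
                d = np.hypot(sub["x_um"] - m.centroid[0], sub["y_um"] - m.centroid[1])
                ids.append(sub["true_id"].iloc[int(np.argmin(d.to_numpy()))])
            ids = np.asarray(ids)
            correct += int(np.sum(ids[1:] == ids[:-1]))
            total += len(ids) - 1
        assert correct / total >= 0.95


class TestArtifactFrames:
    def test_clean_movie_none(self):
        rng = np.random.default_rng(6)
        frames = rng.normal(100, 1.0, size=(20, 32, 32))
        assert detect_artifact_frames(frames) == []

    def test_single_jump_flagged(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(100, 1.0, size=(20, 32, 32))
        frames[13] += 500.0
        assert detect_artifact_frames(frames) == [13]

    def test_at_most_one_frame(self):
        rng = np.random.default_rng(8)
        frames = rng.normal(100, 1.0, size=(20, 32, 32))
        frames[4] += 400.0
        frames[15] += 900.0
        flagged = detect_artifact_frames(frames)
        assert flagged == [15]
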