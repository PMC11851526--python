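"""Forward-simulator properties: templates, deformation basis,
activation timecourses, rendering, and full-dataset structure."""

import hashlib

import numpy as np
import pytest

import painmesh as pm
from painmesh.exceptions import InvalidInputError
from painmesh.simulate import _mirror_field


class TestTemplate:
    @pytest.mark.parametrize("topo,n", [("mesh478", 478), ("bp4d83", 83)])
    def test_point_count(self, topo, n):
        assert pm.make_template(topo, seed=0).n_points == n

    def test_mirror_symmetry(self, template83, mirror83):
        perm = mirror83.permutation()
        flipped = template83.coords[perm].copy()
        flipped[:, 0] = -flipped[:, 0]
        assert np.allclose(flipped, template83.coords, atol=1e-9)

    def test_deterministic(self):
        a = pm.make_template("mesh478", seed=4)
        b = pm.make_template("mesh478", seed=4)
        assert np.array_equal(a.coords, b.coords)

    def test_feature_regions_denser_than_background(self, template83):
        """More landmarks near the eye than in an equal-size cheek-bottom
        area, mimicking real face-mesh layouts."""
        xy = template83.coords[:, :2]
        near_eye = np.sum(np.linalg.norm(xy - [-0.42, -0.35], axis=1) < 0.2)
        near_edge = np.sum(np.linalg.norm(xy - [-0.55, 0.95], axis=1) < 0.2)
        assert near_eye > near_edge

    def test_mirror_map_matches_nearest_neighbour_oracle(self, template83,
                                                         mirror83):
        """The built-in pairing equals nearest-neighbour matching of each
        point to the x-negated template."""
        neg = template83.coords * [-1, 1, 1]
        d = np.linalg.norm(template83.coords[:, None] - neg[None, :], axis=-1)
        nn = d.argmin(axis=1)
        assert np.array_equal(nn, mirror83.permutation())


class TestBasis:
    def test_one_field_per_requested_au(self, template83):
        b = pm.make_basis(template83, pm.DETECTION_AU_IDS, seed=0)
        assert set(b.fields) == set(pm.DETECTION_AU_IDS)

    def test_unknown_au_rejected(self, template83):
        with pytest.raises(InvalidInputError):
            pm.make_basis(template83, [3], seed=0)  # FACS defines no AU 3

    def test_fields_mirror_symmetric(self, basis83, mirror83):
        for au, f in basis83.fields.items():
            assert np.allclose(_mirror_field(f, mirror83), f, atol=1e-6), au

    def test_fields_zero_outside_mask_support(self, basis83):
        for au, f in basis83.fields.items():
            outside = basis83.region_masks[au] == 0
            if outside.any():
                assert np.all(f[outside] == 0.0), au

    def test_identifiability_max_cosine(self, basis83):
        flat = np.stack([basis83.fields[a].reshape(-1) for a in pm.AU_ALL_IDS])
        n = np.linalg.norm(flat, axis=1)
        cos = flat @ flat.T / np.outer(n, n)
        np.fill_diagonal(cos, 0.0)
        assert np.abs(cos).max() < 0.3


class TestTimecourse:
    def test_pain_activates_only_pain_and_background_aus(self):
        tc = pm.simulate_timecourse("pain", 8.0, 25.0, seed=0,
                                    distractor_rate=0.0, common_au_rate=0.0)
        active = {au for j, au in enumerate(tc.au_ids)
                  if tc.intensities[:, j].max() > 0}
        assert active <= set(pm.CLASS_AU_SETS["pain"])
        assert len(active) > 0

    def test_short_duration_rejected(self):
        with pytest.raises(InvalidInputError):
            pm.simulate_timecourse("pain", 1.0, 25.0)

    def test_unknown_class_rejected(self):
        with pytest.raises(InvalidInputError):
            pm.simulate_timecourse("surprise", 8.0, 25.0)

    def test_smoothness_bound_over_seeded_segments(self):
        """Frame-to-frame intensity change <= 1.0 over 100 seeded segments."""
        max_delta = 0.0
        classes = list(pm.CLASS_AU_SETS)
        for seed in range(100):
            tc = pm.simulate_timecourse(classes[seed % 4], 6.0, 25.0, seed=seed)
            if tc.intensities.size:
                max_delta = max(max_delta,
                                np.abs(np.diff(tc.intensities, axis=0)).max())
        assert max_delta <= 1.0

    def test_intensity_range(self):
        tc = pm.simulate_timecourse("happiness", 10.0, 25.0, seed=3)
        assert tc.intensities.min() >= 0.0 and tc.intensities.max() <= 5.0


class TestRender:
    def test_null_timecourse_reproduces_subject_template(self, template83, basis83):
        tc = pm.ActivationTimecourse(np.zeros((5, 8)),
                                     list(pm.DETECTION_AU_IDS), "pain")
        shape = np.full(template83.coords.shape, 0.01)
        seg = pm.render_sequence(template83, basis83, tc, subject_shape=shape,
                                 pose_jitter_deg=0.0, pose_trans_sd=0.0,
                                 noise_sd=0.0, seed=0)
        expected = template83.coords + shape
        assert np.allclose(seg.sequence.frames, expected[None], atol=1e-12)

    def test_displacement_linear_in_intensity(self, template83, basis83):
        """Intensity-5 frame differs from intensity-0 frame by exactly
        gain x field; doubling intensity doubles the displacement."""
        au = 6
        ids = [au]
        for hi, lo in [(5.0, 0.0), (2.0, 1.0)]:
            I = np.array([[lo], [hi]])
            tc = pm.ActivationTimecourse(I, ids, "pain")
            seg = pm.render_sequence(template83, basis83, tc,
                                     pose_jitter_deg=0.0, pose_trans_sd=0.0,
                                     noise_sd=0.0, seed=0)
            diff = seg.sequence.frames[1] - seg.sequence.frames[0]
            expected = (hi - lo) / 5.0 * basis83.gain * basis83.fields[au]
            assert np.allclose(diff, expected, atol=1e-12)

    def test_presence_labels_follow_intensity_threshold(self, template83, basis83):
        I = np.array([[0.5], [1.0], [3.0]])
        tc = pm.ActivationTimecourse(I, [6], "pain")
        seg = pm.render_sequence(template83, basis83, tc, noise_sd=0.0, seed=0)
        j = pm.DETECTION_AU_IDS.index(6)
        assert list(seg.au_presence[:, j]) == [0, 1, 1]
        ji = pm.INTENSITY_AU_IDS.index(6)
        assert np.allclose(seg.au_intensity[:, ji], [0.5, 1.0, 3.0])


class TestDataset:
    def test_structure_one_pain_three_other_per_subject(self, tiny_dataset):
        by_subject = {}
        for seg in tiny_dataset:
            by_subject.setdefault(seg.sequence.subject_id, []).append(
                seg.sequence.segment_class)
        assert len(by_subject) == 6
        for classes in by_subject.values():
            assert sorted(classes) == ["other", "other", "other", "pain"]

    def test_frame_budget_matches_config_arithmetic(self, tiny_dataset):
        """~ n_subjects x 4 x 4 s x 25 fps frames, within duration jitter."""
        total = sum(s.sequence.n_frames for s in tiny_dataset)
        expected = 6 * 4 * 4.0 * 25.0
        assert abs(total - expected) / expected < 0.5
        pain = sum(s.sequence.n_frames for s in tiny_dataset
                   if s.sequence.segment_class == "pain")
        ratio = pain / (total - pain)
        assert 0.2 < ratio < 0.55  # ~1:3 with jitter

    def test_same_seed_gives_byte_identical_container(self, tmp_path):
        cfg = pm.SimulationConfig(n_subjects=2, segment_seconds=3.0,
                                  topology_id="bp4d83", seed=7)
        hashes = []
        for run in range(2):
            segs = pm.simulate_dataset(cfg)
            blob = b"".join(s.sequence.frames.tobytes() + s.au_presence.tobytes()
                            for s in segs)
            hashes.append(hashlib.sha256(blob).hexdigest())
        assert hashes[0] == hashes[1]

    def test_pain_aus_hotter_in_pain_segments(self, tiny_dataset):
        """Class-conditional statistics: mean ground-truth activation of
        pain-set AUs is strictly higher in pain segments."""
        pain_idx = [pm.AU_ALL_IDS.index(a) for a in pm.CLASS_AU_SETS["pain"]]
        pain_mean = np.mean([seg.au_full[:, pain_idx].mean()
                             for seg in tiny_dataset
                             if seg.sequence.segment_class == "pain"])
        other_mean = np.mean([seg.au_full[:, pain_idx].mean()
                              for seg in tiny_dataset
                              if seg.sequence.segment_class == "other"])
        assert pain_mean > other_mean
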