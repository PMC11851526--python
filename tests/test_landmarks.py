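"""Geometry, domain types and container I/O."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import painmesh as pm
from painmesh.exceptions import (
    CapabilityError,
    DegenerateGeometryError,
    FormatError,
    InvalidInputError,
)


def random_rigid(rng, scale_range=(0.5, 2.0)):
    R = Rotation.random(rng=rng).as_matrix()
    s = rng.uniform(*scale_range)
    t = rng.uniform(-5, 5, 3)
    return R, s, t


class TestNormalizeFrame:
    def test_template_is_fixed_point(self, template83):
        out = pm.normalize_frame(template83, template83)
        # template is already centred and self-scaled; rotation is identity
        centred = template83.coords - template83.coords.mean(axis=0)
        assert np.allclose(out.coords, centred, atol=1e-9)

    def test_similarity_transform_invariance(self, template83, rng):
        base = pm.normalize_frame(template83, template83)
        for _ in range(10):
            R, s, t = random_rigid(rng)
            moved = pm.LandmarkFrame(s * template83.coords @ R.T + t, "bp4d83")
            out = pm.normalize_frame(moved, template83)
            assert np.allclose(out.coords, base.coords, atol=1e-6)

    def test_rotation_matches_svd_procrustes_oracle(self, rng):
        """5-point toy: recovered rotation equals the closed-form
        orthogonal-Procrustes solution computed independently."""
        A = rng.standard_normal((5, 3))
        template = pm.LandmarkFrame(A, "custom")
        R_true = Rotation.random(rng=rng).as_matrix()
        frame = pm.LandmarkFrame(A @ R_true.T, "custom")
        out = pm.normalize_frame(frame, template)
        # independent oracle: orthogonal Procrustes via scipy on the
        # centred/scaled configurations
        X = frame.coords - frame.coords.mean(0)
        B = template.coords - template.coords.mean(0)
        X = X * (np.mean(np.linalg.norm(B, axis=1))
                 / np.mean(np.linalg.norm(X, axis=1)))
        from scipy.linalg import orthogonal_procrustes
        R_opt, _ = orthogonal_procrustes(X, B)
        assert np.allclose(out.coords, X @ R_opt, atol=1e-8)
        assert np.allclose(out.coords, B, atol=1e-8)

    def test_idempotent(self, template83, rng):
        moved = pm.LandmarkFrame(
            1.7 * template83.coords @ Rotation.random(rng=rng).as_matrix().T + 3.0,
            "bp4d83")
        once = pm.normalize_frame(moved, template83)
        twice = pm.normalize_frame(once, template83)
        assert np.allclose(once.coords, twice.coords, atol=1e-9)

    def test_errors(self, template83):
        other = pm.LandmarkFrame(np.zeros((5, 3)) + np.arange(15).reshape(5, 3),
                                 "custom")
        with pytest.raises(InvalidInputError):
            pm.normalize_frame(other, template83)
        degenerate = pm.LandmarkFrame(np.ones((83, 3)), "bp4d83")
        with pytest.raises(DegenerateGeometryError):
            pm.normalize_frame(degenerate, template83)


class TestFlatten:
    @pytest.mark.parametrize("topo,expected", [("mesh478", 1434), ("bp4d83", 249)])
    def test_flat_length_is_three_ns(self, topo, expected):
        frame = pm.make_template(topo, seed=0)
        assert pm.flatten_frame(frame).shape == (expected,)

    def test_ordering_and_roundtrip(self, rng):
        coords = rng.standard_normal((4, 3))
        frame = pm.LandmarkFrame(coords, "custom")
        flat = pm.flatten_frame(frame)
        # documented ordering: (x0, y0, z0, x1, y1, z1, ...)
        assert np.array_equal(flat[:3], coords[0])
        assert np.array_equal(flat[3:6], coords[1])
        back = pm.unflatten_frame(flat, "custom")
        assert np.array_equal(back.coords, coords)


class TestTypes:
    def test_frame_invariants(self):
        with pytest.raises(InvalidInputError):
            pm.LandmarkFrame(np.full((83, 3), np.nan), "bp4d83")
        with pytest.raises(InvalidInputError):
            pm.LandmarkFrame(np.zeros((80, 3)), "bp4d83")

    def test_sequence_invariants(self):
        with pytest.raises(InvalidInputError):
            pm.LandmarkSequence(np.zeros((0, 83, 3)), "bp4d83")
        with pytest.raises(InvalidInputError):
            pm.LandmarkSequence(np.zeros((2, 83, 3)), "bp4d83", frame_rate=0)

    def test_mirror_map_involution_and_coverage(self, mirror83):
        perm = mirror83.permutation()
        assert np.array_equal(perm[perm], np.arange(83))
        with pytest.raises(InvalidInputError):
            pm.MirrorMap(pairs=[(0, 1), (1, 2)], midline=[3])

    def test_labels_invariants(self):
        with pytest.raises(InvalidInputError):
            pm.AUFrameLabels(presence=np.array([2] + [0] * 7),
                             intensity=np.zeros(5))
        with pytest.raises(InvalidInputError):
            pm.AUFrameLabels(presence=np.zeros(8, dtype=int),
                             intensity=np.array([6.0, 0, 0, 0, 0]))


class TestContainer:
    def test_roundtrip_bit_exact(self, tiny_dataset, tmp_path):
        path = tmp_path / "ds.h5"
        manifest = pm.write_dataset(tiny_dataset[:4], path)
        segs, manifest2 = pm.read_dataset(path)
        assert len(segs) == 4
        for a, b in zip(tiny_dataset[:4], segs):
            assert np.array_equal(a.sequence.frames, b.sequence.frames)
            assert np.array_equal(a.au_presence, b.au_presence)
            assert np.array_equal(a.au_intensity, b.au_intensity)
            assert np.array_equal(a.au_full, b.au_full)
            assert a.sequence.subject_id == b.sequence.subject_id
            assert a.sequence.segment_class == b.sequence.segment_class
        assert manifest.to_json() == manifest2.to_json()

    def test_missing_intensity_reads_as_unlabeled(self, tiny_dataset, tmp_path):
        import h5py
        path = tmp_path / "ds.h5"
        pm.write_dataset(tiny_dataset[:2], path)
        with h5py.File(path, "a") as f:
            for name in f:
                del f[name]["au_intensity"]
        segs, _ = pm.read_dataset(path)
        assert all(s.au_intensity is None for s in segs)
        assert not segs[0].intensity_labeled
        assert not segs[0].frame_labels(0).intensity_labeled

    def test_malformed_container_names_group(self, tiny_dataset, tmp_path):
        import h5py
        path = tmp_path / "ds.h5"
        pm.write_dataset(tiny_dataset[:2], path)
        with h5py.File(path, "a") as f:
            del f["segment_00001"]["landmarks"]
        with pytest.raises(FormatError, match="segment_00001"):
            pm.read_dataset(path)

    def test_study_shaped_manifest_bookkeeping(self, tmp_path):
        """A study-shaped manifest: 140 subjects, 1 pain + 3 other segments
        each (segments built tiny to keep this a metadata test)."""
        segments = []
        frames = np.zeros((2, 83, 3))
        frames[:, :, 0] = np.linspace(0, 1, 83)  # non-degenerate
        for s in range(140):
            for g, cls in enumerate(["pain", "other", "other", "other"]):
                seq = pm.LandmarkSequence(frames, "bp4d83", 25.0,
                                          f"subj_{s:04d}", f"s{s}_g{g}", cls)
                segments.append(pm.Segment(seq, np.zeros((2, 8), dtype=np.int8),
                                           np.zeros((2, 5))))
        manifest = pm.write_dataset(segments, tmp_path / "big.h5")
        subjects = manifest.subject_ids()
        assert len(subjects) == 140
        per_subject = [sum(1 for e in manifest.segments
                           if e["subject_id"] == sid) for sid in subjects]
        assert per_subject == [4] * 140
        pain = sum(1 for e in manifest.segments if e["segment_class"] == "pain")
        assert pain == 140

    def test_csv_export(self, tiny_dataset, tmp_path):
        import pandas as pd
        path = tmp_path / "seg.csv"
        pm.export_segment_csv(tiny_dataset[0], path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["frame", "point", "x", "y", "z"]
        seq = tiny_dataset[0].sequence
        assert len(df) == seq.n_frames * seq.n_points
        row = df[(df.frame == 1) & (df.point == 5)].iloc[0]
        assert np.allclose([row.x, row.y, row.z], seq.frames[1, 5])


class TestExtractorAdapter:
    def make_stub(self, template, plan):
        """plan: list of 'ok'/'fail' per frame."""
        def extractor(_path):
            for p in plan:
                yield template.coords.copy() if p == "ok" else None
        return extractor

    def test_constant_stub(self, template83):
        seqs = pm.extract_landmarks_adapter(
            "x.mp4", self.make_stub(template83, ["ok"] * 10), "bp4d83")
        assert len(seqs) == 1 and seqs[0].n_frames == 10

    def test_single_gap_interpolated_at_midpoint(self, template83):
        plan = ["ok"] * 10
        plan[3] = "fail"
        stub_frames = []

        def extractor(_path):
            for i, p in enumerate(plan):
                if p == "fail":
                    yield None
                else:
                    fr = template83.coords + float(i)
                    stub_frames.append(fr)
                    yield fr
        seqs = pm.extract_landmarks_adapter("x.mp4", extractor, "bp4d83")
        assert len(seqs) == 1 and seqs[0].n_frames == 10
        expected = 0.5 * (template83.coords + 2.0) + 0.5 * (template83.coords + 4.0)
        assert np.allclose(seqs[0].frames[3], expected)

    def test_long_gap_splits_segment(self, template83):
        plan = ["ok"] * 5 + ["fail"] * 8 + ["ok"] * 5
        seqs = pm.extract_landmarks_adapter(
            "x.mp4", self.make_stub(template83, plan), "bp4d83")
        assert len(seqs) == 2
        assert [s.n_frames for s in seqs] == [5, 5]

    def test_no_extractor_is_capability_error(self):
        with pytest.raises(CapabilityError, match="video input"):
            pm.extract_landmarks_adapter("x.mp4", None)


from hypothesis import given, settings, strategies as st


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.5, 2.0), angle=st.floats(-np.pi, np.pi),
       tx=st.floats(-10, 10))
def test_normalization_invariance_property(scale, angle, tx):
    """Property: normalize_frame output is unchanged under any uniform
    scaling + rotation + translation of the input."""
    template = pm.make_template("bp4d83", seed=0)
    R = Rotation.from_euler("xyz", [angle, angle / 2, -angle]).as_matrix()
    moved = pm.LandmarkFrame(scale * template.coords @ R.T + [tx, 1.0, -2.0],
                             "bp4d83")
    out = pm.normalize_frame(moved, template)
    ref = pm.normalize_frame(template, template)
    assert np.allclose(out.coords, ref.coords, atol=1e-6)
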