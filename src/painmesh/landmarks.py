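"""Domain types and I/O for 3D face-landmark sequences.

The privacy-preserving unit of exchange is a sequence of fixed-topology 3D
landmark frames (478 points in the dense face-mesh topology, 83 in the
sparser expert-annotated one) with per-frame action-unit (AU) labels.
Coordinate convention throughout the package: x points to the subject's
image-right, y downward, z toward the camera; a horizontal flip therefore
negates x.

The on-disk container is HDF5 with one group per segment holding
``landmarks`` [T, Ns, 3], ``au_presence`` [T, 8] and optionally
``au_intensity`` [T, 5], plus subject/class/frame-rate attributes. A JSON
manifest sits next to the container.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import h5py
import numpy as np

from .exceptions import (
    CapabilityError,
    DegenerateGeometryError,
    FormatError,
    InvalidInputError,
)

#: Declared point counts per known topology. ``custom`` accepts any count.
TOPOLOGY_POINTS = {"mesh478": 478, "bp4d83": 83}

#: The eight detectable AUs, in label order (FACS ids).
DETECTION_AU_IDS = (5, 6, 8, 9, 10, 12, 14, 18)

#: The five intensity-labelled AUs, in label order (FACS ids).
INTENSITY_AU_IDS = (6, 10, 12, 14, 17)

SEGMENT_CLASSES = ("pain", "other", "unlabeled")


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InvalidInputError(f"coords must be (Ns, 3), got {coords.shape}")
    if not np.all(np.isfinite(coords)):
        raise InvalidInputError("coords contain non-finite values")
    return coords


@dataclass
class LandmarkFrame:
    """A single frame of Ns 3D landmarks in a named topology."""

    coords: np.ndarray
    topology_id: str = "custom"

    def __post_init__(self):
        self.coords = _check_coords(self.coords)
        expected = TOPOLOGY_POINTS.get(self.topology_id)
        if expected is not None and self.coords.shape[0] != expected:
            raise InvalidInputError(
                f"topology {self.topology_id!r} declares {expected} points, "
                f"got {self.coords.shape[0]}")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]


@dataclass
class LandmarkSequence:
    """A subject's segment: T frames of landmarks plus identity metadata."""

    frames: np.ndarray  # (T, Ns, 3)
    topology_id: str = "custom"
    frame_rate: float = 25.0
    subject_id: str = ""
    segment_id: str = ""
    segment_class: str = "unlabeled"

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InvalidInputError(
                f"frames must be (T, Ns, 3), got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise InvalidInputError("sequence needs at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidInputError("frames contain non-finite values")
        if self.frame_rate <= 0:
            raise InvalidInputError("frame_rate must be positive")
        if self.segment_class not in SEGMENT_CLASSES:
            raise InvalidInputError(
                f"segment_class must be one of {SEGMENT_CLASSES}")
        expected = TOPOLOGY_POINTS.get(self.topology_id)
        if expected is not None and self.frames.shape[1] != expected:
            raise InvalidInputError(
                f"topology {self.topology_id!r} declares {expected} points, "
                f"got {self.frames.shape[1]}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_points(self) -> int:
        return self.frames.shape[1]

    def frame(self, t: int) -> LandmarkFrame:
        return LandmarkFrame(self.frames[t], self.topology_id)


@dataclass
class MirrorMap:
    """Left/right landmark index pairing used to realise a horizontal flip.

    ``pairs`` swap under a flip; ``midline`` indices map to themselves. The
    induced index permutation is an involution.
    """

    pairs: list[tuple[int, int]]
    midline: list[int]

    def __post_init__(self):
        seen: set[int] = set()
        for left, right in self.pairs:
            for idx in (left, right):
                if idx in seen:
                    raise InvalidInputError(f"index {idx} appears twice in mirror map")
                seen.add(idx)
        for idx in self.midline:
            if idx in seen:
                raise InvalidInputError(f"index {idx} appears twice in mirror map")
            seen.add(idx)
        self._n = len(seen)
        if seen != set(range(self._n)):
            raise InvalidInputError("mirror map must cover indices 0..Ns-1 exactly once")

    @property
    def n_points(self) -> int:
        return self._n

    def permutation(self) -> np.ndarray:
        perm = np.arange(self._n)
        for left, right in self.pairs:
            perm[left] = right
            perm[right] = left
        return perm


@dataclass
class AUFrameLabels:
    """Per-frame AU labels: 8 binary presences and 5 intensities in [0, 5]."""

    presence: np.ndarray  # (8,) in {0, 1}
    intensity: np.ndarray  # (5,) in [0, 5]
    intensity_labeled: bool = True

    def __post_init__(self):
        self.presence = np.asarray(self.presence)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.presence.shape != (len(DETECTION_AU_IDS),):
            raise InvalidInputError("presence must have 8 entries")
        if not np.all(np.isin(self.presence, (0, 1))):
            raise InvalidInputError("presence values must be 0 or 1")
        if self.intensity.shape != (len(INTENSITY_AU_IDS),):
            raise InvalidInputError("intensity must have 5 entries")
        if np.any((self.intensity < 0) | (self.intensity > 5)):
            raise InvalidInputError("intensity values must lie in [0, 5]")


@dataclass
class Segment:
    """A landmark sequence together with its per-frame label arrays."""

    sequence: LandmarkSequence
    au_presence: np.ndarray  # (T, 8) in {0, 1}
    au_intensity: np.ndarray | None = None  # (T, 5) in [0, 5], or None

    def __post_init__(self):
        T = self.sequence.n_frames
        self.au_presence = np.asarray(self.au_presence)
        if self.au_presence.shape != (T, len(DETECTION_AU_IDS)):
            raise InvalidInputError(
                f"au_presence must be (T, 8) = ({T}, 8), got {self.au_presence.shape}")
        if self.au_intensity is not None:
            self.au_intensity = np.asarray(self.au_intensity, dtype=np.float64)
            if self.au_intensity.shape != (T, len(INTENSITY_AU_IDS)):
                raise InvalidInputError(
                    f"au_intensity must be (T, 5), got {self.au_intensity.shape}")

    @property
    def intensity_labeled(self) -> bool:
        return self.au_intensity is not None

    def frame_labels(self, t: int) -> AUFrameLabels:
        if self.au_intensity is None:
            return AUFrameLabels(self.au_presence[t],
                                 np.zeros(len(INTENSITY_AU_IDS)),
                                 intensity_labeled=False)
        return AUFrameLabels(self.au_presence[t], self.au_intensity[t])


@dataclass
class DatasetManifest:
    """Index of a dataset container: one entry per segment plus label schema."""

    segments: list[dict]  # each: {path, subject_id, segment_class}
    topology_id: str
    label_schema: dict = field(default_factory=lambda: {
        "detection": list(DETECTION_AU_IDS),
        "intensity": list(INTENSITY_AU_IDS),
    })
    split: str = "unspecified"  # train / test / unspecified

    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg["subject_id"])
        return list(seen)

    def to_json(self) -> str:
        return json.dumps({
            "segments": self.segments,
            "topology_id": self.topology_id,
            "label_schema": self.label_schema,
            "split": self.split,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        obj = json.loads(text)
        return cls(segments=obj["segments"], topology_id=obj["topology_id"],
                   label_schema=obj["label_schema"], split=obj.get("split", "unspecified"))


# ---------------------------------------------------------------------------
# Geometry


def normalize_frame(frame: LandmarkFrame, template: LandmarkFrame) -> LandmarkFrame:
    """Similarity-Procrustes alignment of ``frame`` onto ``template``.

    Translates the centroid to the origin, rescales so the mean
    point-to-centroid distance matches the template's, and applies the
    least-squares rotation (no reflection) onto the template. The result is
    invariant to any rigid transform + uniform scaling of the input.
    """
    if frame.topology_id != template.topology_id:
        raise InvalidInputError(
            f"topology mismatch: {frame.topology_id!r} vs {template.topology_id!r}")
    X = frame.coords - frame.coords.mean(axis=0)
    B = template.coords - template.coords.mean(axis=0)
    scale_x = np.mean(np.linalg.norm(X, axis=1))
    scale_b = np.mean(np.linalg.norm(B, axis=1))
    if scale_x < 1e-12:
        raise DegenerateGeometryError("all landmarks coincide; cannot normalize")
    A = X * (scale_b / scale_x)
    # rotation R minimising ||A R - B||_F, constrained to det(R) = +1
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    return LandmarkFrame(A @ R, frame.topology_id)


def normalize_sequence(seq: LandmarkSequence, template: LandmarkFrame) -> LandmarkSequence:
    """Apply :func:`normalize_frame` to every frame of a sequence."""
    out = np.stack([
        normalize_frame(seq.frame(t), template).coords for t in range(seq.n_frames)
    ])
    return LandmarkSequence(out, seq.topology_id, seq.frame_rate,
                            seq.subject_id, seq.segment_id, seq.segment_class)


def flatten_frame(frame: LandmarkFrame) -> np.ndarray:
    """Flatten to a length-3·Ns vector ordered (x0, y0, z0, x1, y1, z1, ...)."""
    return frame.coords.reshape(-1).copy()


def unflatten_frame(vec: np.ndarray, topology_id: str = "custom") -> LandmarkFrame:
    vec = np.asarray(vec, dtype=np.float64)
    if vec.ndim != 1 or vec.size % 3 != 0:
        raise InvalidInputError("flat vector length must be a multiple of 3")
    return LandmarkFrame(vec.reshape(-1, 3), topology_id)


# ---------------------------------------------------------------------------
# Container I/O


def write_dataset(segments: Sequence[Segment], path: str | Path,
                  split: str = "unspecified") -> DatasetManifest:
    """Write segments to an HDF5 container; returns (and saves) the manifest.

    Round-trips arrays bit-exactly. The JSON manifest is written next to the
    container at ``<path>.manifest.json``.
    """
    path = Path(path)
    if not segments:
        raise InvalidInputError("cannot write an empty dataset")
    topo = segments[0].sequence.topology_id
    for seg in segments:
        if seg.sequence.topology_id != topo:
            raise InvalidInputError("all segments must share one topology")
    entries = []
    with h5py.File(path, "w") as f:
        f.attrs["topology_id"] = topo
        for i, seg in enumerate(segments):
            name = f"segment_{i:05d}"
            g = f.create_group(name)
            g.create_dataset("landmarks", data=seg.sequence.frames)
            g.create_dataset("au_presence", data=np.asarray(seg.au_presence, dtype=np.int8))
            if seg.au_intensity is not None:
                g.create_dataset("au_intensity", data=seg.au_intensity)
            au_full = getattr(seg, "au_full", None)
            if au_full is not None:
                g.create_dataset("au_full", data=np.asarray(au_full, dtype=np.int8))
            emotion = getattr(seg, "emotion", None)
            if emotion is not None:
                g.attrs["emotion"] = emotion
            g.attrs["subject_id"] = seg.sequence.subject_id
            g.attrs["segment_id"] = seg.sequence.segment_id
            g.attrs["segment_class"] = seg.sequence.segment_class
            g.attrs["frame_rate"] = seg.sequence.frame_rate
            entries.append({
                "path": name,
                "subject_id": seg.sequence.subject_id,
                "segment_class": seg.sequence.segment_class,
            })
    manifest = DatasetManifest(segments=entries, topology_id=topo, split=split)
    Path(str(path) + ".manifest.json").write_text(manifest.to_json())
    return manifest


def read_dataset(path: str | Path) -> tuple[list[Segment], DatasetManifest]:
    """Read a dataset container written by :func:`write_dataset`.

    A segment group without ``au_intensity`` is returned with
    ``au_intensity=None`` (unlabeled intensity), not treated as an error.
    """
    path = Path(path)
    manifest_path = Path(str(path) + ".manifest.json")
    segments: list[Segment] = []
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise FormatError(f"cannot open container {path}: {exc}") from exc
    with f:
        topo = f.attrs.get("topology_id", "custom")
        names = sorted(f.keys())
        for name in names:
            g = f[name]
            try:
                frames = np.asarray(g["landmarks"])
                presence = np.asarray(g["au_presence"])
            except KeyError as exc:
                raise FormatError(
                    f"group {name!r} is missing required dataset: {exc}") from exc
            intensity = np.asarray(g["au_intensity"]) if "au_intensity" in g else None
            seq = LandmarkSequence(
                frames, str(topo),
                frame_rate=float(g.attrs.get("frame_rate", 25.0)),
                subject_id=str(g.attrs.get("subject_id", "")),
                segment_id=str(g.attrs.get("segment_id", name)),
                segment_class=str(g.attrs.get("segment_class", "unlabeled")))
            seg = Segment(seq, presence, intensity)
            if "au_full" in g:
                seg.au_full = np.asarray(g["au_full"])
            if "emotion" in g.attrs:
                seg.emotion = str(g.attrs["emotion"])
            segments.append(seg)
    if manifest_path.exists():
        manifest = DatasetManifest.from_json(manifest_path.read_text())
    else:
        manifest = DatasetManifest(
            segments=[{"path": n, "subject_id": s.sequence.subject_id,
                       "segment_class": s.sequence.segment_class}
                      for n, s in zip(names, segments)],
            topology_id=str(topo))
    return segments, manifest


def export_segment_csv(segment: Segment, path: str | Path) -> None:
    """Export one segment's landmarks as CSV with header frame,point,x,y,z."""
    seq = segment.sequence
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "point", "x", "y", "z"])
        for t in range(seq.n_frames):
            for p in range(seq.n_points):
                x, y, z = (float(v) for v in seq.frames[t, p])
                writer.writerow([t, p, repr(x), repr(y), repr(z)])


# ---------------------------------------------------------------------------
# External extractor adapter


def extract_landmarks_adapter(
    video_path: str | Path,
    extractor: Callable[[str | Path], Iterable[np.ndarray | None]] | None,
    topology_id: str = "mesh478",
    frame_rate: float = 25.0,
    subject_id: str = "",
    max_gap: int = 5,
) -> list[LandmarkSequence]:
    """Wrap an external per-frame face-mesh extractor into landmark sequences.

    ``extractor(video_path)`` must yield one ``Ns×3`` array per video frame,
    or ``None`` where extraction failed. Gaps of at most ``max_gap``
    consecutive failed frames are filled by linear interpolation between the
    flanking frames; longer gaps split the recording into separate
    sequences. Leading/trailing failures are trimmed.
    """
    if extractor is None:
        raise CapabilityError(
            "no landmark extractor provided; the core pipeline operates on "
            "landmark sequences directly and does not require video input")
    raw = [None if fr is None else np.asarray(fr, dtype=np.float64)
           for fr in extractor(video_path)]
    if not raw:
        raise InvalidInputError("extractor yielded no frames")

    # locate runs of valid frames separated by gaps
    sequences: list[LandmarkSequence] = []
    chunk: list[np.ndarray] = []
    gap = 0
    part = 0

    def flush():
        nonlocal chunk, part
        if chunk:
            sequences.append(LandmarkSequence(
                np.stack(chunk), topology_id, frame_rate, subject_id,
                segment_id=f"part_{part:03d}"))
            part += 1
        chunk = []

    for fr in raw:
        if fr is None:
            gap += 1
            continue
        if gap and chunk:
            if gap <= max_gap:
                prev = chunk[-1]
                for j in range(1, gap + 1):
                    w = j / (gap + 1)
                    chunk.append((1 - w) * prev + w * fr)
            else:
                flush()
        gap = 0
        chunk.append(fr)
    flush()
    if not sequences:
        raise InvalidInputError("extractor failed on every frame")
    return sequences
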