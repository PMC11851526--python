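"""Landmark-space training augmentations.

Image-domain augmentations used when oversampling rare action units
(horizontal flip, rotation, cropping, linear distortion) are mapped to
their landmark-space analogues: index-permuting x-negation, 3D rotation,
framing jitter (translation + uniform scale — the landmark-visible effect
of a crop), and a shear matrix. Because similarity-Procrustes
normalization later cancels rotation and framing jitter, shear and flip
are the main diversity sources on the normalized pathway; transforms are
nevertheless applied pre-normalization so the un-normalized pathway also
benefits.

Augmentation is a training-split-only operation; calling it on a split
tagged ``test`` is a contract violation, not a silent no-op.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import CapabilityError, ContractViolationError, InvalidInputError
from .landmarks import LandmarkSequence, MirrorMap, Segment


@dataclass
class AugmentationSpec:
    """Symmetric-about-identity transform ranges; seeded and reproducible."""

    enable_flip: bool = True
    rotation_range_deg: float = 15.0
    framing_translation: float = 0.05
    framing_scale: tuple[float, float] = (0.9, 1.1)
    shear_range: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.rotation_range_deg < 0 or self.framing_translation < 0 or self.shear_range < 0:
            raise InvalidInputError("ranges must be nonnegative")
        lo, hi = self.framing_scale
        if not (0 < lo <= 1.0 <= hi):
            raise InvalidInputError("framing_scale must bracket 1.0")


def hflip(seq: LandmarkSequence, mirror: MirrorMap) -> LandmarkSequence:
    """Horizontal flip: negate x and permute left/right landmark indices.

    AU labels are unchanged — the label schema is bilateral.
    """
    if mirror.n_points != seq.n_points:
        raise CapabilityError(
            f"mirror map covers {mirror.n_points} points but sequence has "
            f"{seq.n_points}; supply a matching MirrorMap for this topology")
    perm = mirror.permutation()
    frames = seq.frames[:, perm, :].copy()
    frames[:, :, 0] = -frames[:, :, 0]
    return LandmarkSequence(frames, seq.topology_id, seq.frame_rate,
                            seq.subject_id, seq.segment_id, seq.segment_class)


def _sample_transform(spec: AugmentationSpec, rng: np.random.Generator):
    """One (linear matrix, translation) pair: rotation · shear · scale."""
    from scipy.spatial.transform import Rotation

    ang = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg, size=3)
    R = Rotation.from_euler("xyz", np.deg2rad(ang)).as_matrix()
    S = np.eye(3)
    off = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    for i, j in off:
        S[i, j] = rng.uniform(-spec.shear_range, spec.shear_range)
    scale = rng.uniform(*spec.framing_scale)
    t = rng.uniform(-spec.framing_translation, spec.framing_translation, size=3)
    return scale * (R @ S), t


def random_similarity_and_shear(seq: LandmarkSequence, spec: AugmentationSpec,
                                rng: np.random.Generator) -> LandmarkSequence:
    """Apply one sampled rotation+shear+framing transform to all frames.

    One transform per segment (not per frame) preserves temporal coherence.
    With all ranges zero the result is the input exactly.
    """
    M, t = _sample_transform(spec, rng)
    frames = seq.frames @ M.T + t
    return LandmarkSequence(frames, seq.topology_id, seq.frame_rate,
                            seq.subject_id, seq.segment_id, seq.segment_class)


def augment_segment(seg: Segment, spec: AugmentationSpec,
                    rng: np.random.Generator,
                    mirror: MirrorMap | None = None) -> Segment:
    """One independently transformed copy of a segment, labels verbatim."""
    seq = seg.sequence
    if spec.enable_flip and mirror is not None and rng.random() < 0.5:
        seq = hflip(seq, mirror)
    seq = random_similarity_and_shear(seq, spec, rng)
    out = Segment(seq, seg.au_presence.copy(),
                  None if seg.au_intensity is None else seg.au_intensity.copy())
    if getattr(seg, "au_full", None) is not None:
        out.au_full = seg.au_full.copy()
    out.augmented_from = seg.sequence.segment_id
    return out


def oversample_rare(segments: list[Segment], split: str,
                    target_au_indices: list[int], copies_per_positive: int,
                    spec: AugmentationSpec,
                    mirror: MirrorMap | None = None) -> list[Segment]:
    """Duplicate-and-transform segments containing rare-AU positive frames.

    ``split`` must be ``"train"``; augmenting a test split is refused. Any
    segment with at least one frame positive for a target AU (indices into
    the presence label columns) is copied ``copies_per_positive`` times,
    each copy independently transformed. Copies record their provenance in
    ``augmented_from``. Fully deterministic given ``spec.seed``.
    """
    if split == "test":
        raise ContractViolationError(
            "oversample_rare must never see a test split (leakage guard)")
    if split != "train":
        raise ContractViolationError(
            f"oversample_rare requires a split tagged 'train', got {split!r}")
    if copies_per_positive < 0:
        raise InvalidInputError("copies_per_positive must be >= 0")
    out = list(segments)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA06]))
    for seg in segments:
        if not target_au_indices:
            continue
        pos_mask = seg.au_presence[:, target_au_indices].any(axis=1)
        if not pos_mask.any():
            continue
        sub_seq = LandmarkSequence(
            seg.sequence.frames[pos_mask], seg.sequence.topology_id,
            seg.sequence.frame_rate, seg.sequence.subject_id,
            seg.sequence.segment_id, seg.sequence.segment_class)
        sub = Segment(sub_seq, seg.au_presence[pos_mask],
                      None if seg.au_intensity is None else seg.au_intensity[pos_mask])
        if getattr(seg, "au_full", None) is not None:
            sub.au_full = seg.au_full[pos_mask]
        for c in range(copies_per_positive):
            aug = augment_segment(sub, spec, rng, mirror)
            aug.sequence.segment_id = f"{seg.sequence.segment_id}_aug{c}"
            out.append(aug)
    return out


def positive_frame_counts(segments: list[Segment]) -> np.ndarray:
    """Per-AU count of positive frames over a segment list."""
    return np.sum([seg.au_presence.sum(axis=0) for seg in segments], axis=0)
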