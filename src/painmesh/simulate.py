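"""Forward simulator: AU activations -> deforming 3D landmark sequences.

Every downstream stage (AU detection, intensity regression, temporal pain
classification) is trainable and testable on this simulator, which emulates
the statistical structure of an expression-elicitation study: per subject,
one pain segment and three non-pain segments (happiness, embarrassment,
fear), each ~20 s at 25 fps, with per-subject face-shape variation, rigid
head-pose jitter and additive landmark noise.

The forward model is linear in AU intensity: each AU owns a smooth,
spatially localized 3D displacement field over a bilaterally symmetric
template mesh, and a frame is

    frame_t = RigidPose_t( subject_template
                           + sum_k (intensity_{t,k} / 5) * gain * field_k )
              + Gaussian noise.

Ground-truth labels follow the FACS convention that intensity 0 means
absence: binary presence is intensity >= 1.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial.transform import Rotation

from .exceptions import InvalidInputError
from .landmarks import (
    DETECTION_AU_IDS,
    INTENSITY_AU_IDS,
    TOPOLOGY_POINTS,
    LandmarkFrame,
    LandmarkSequence,
    MirrorMap,
    Segment,
)

#: All 34 FACS action-unit ids carried by the simulator (FACS defines no AU 3).
AU_ALL_IDS = (1, 2) + tuple(range(4, 36))

#: Emotion-class -> prototypical AU set. Pain, happiness and fear follow the
#: standard FACS emotion prototypes; embarrassment (not covered by the
#: prototype table) is modelled as a controlled smile: cheek raise + lip
#: corner pull + lip press.
CLASS_AU_SETS = {
    "pain": (4, 6, 7, 9, 17, 18, 23, 24),
    "happiness": (6, 7, 12, 25, 26),
    "fear": (1, 2, 4, 5, 7, 20, 25),
    "embarrassment": (6, 12, 24),
}

OTHER_CLASSES = ("happiness", "embarrassment", "fear")

# Anatomical anchor (x, y) for each AU's displacement field on the template,
# with y pointing down the face: brows ~ -0.55, eyes ~ -0.35, nose ~ 0,
# mouth ~ 0.55, chin ~ 0.85. All fields are bilateral (mirror-symmetric).
_AU_REGIONS: dict[int, tuple[float, float, float]] = {
    # au_id: (|x| of the left/right anchors, y, sigma)
    1: (0.15, -0.58, 0.18),   # inner brow raiser
    2: (0.45, -0.60, 0.18),   # outer brow raiser
    4: (0.22, -0.52, 0.20),   # brow lowerer
    5: (0.40, -0.40, 0.16),   # upper lid raiser
    6: (0.55, -0.08, 0.22),   # cheek raiser
    7: (0.40, -0.30, 0.16),   # lid tightener
    8: (0.16, 0.55, 0.16),    # lips toward each other
    9: (0.13, -0.10, 0.18),   # nose wrinkler
    10: (0.16, 0.42, 0.16),   # upper lip raiser
    12: (0.40, 0.55, 0.18),   # lip corner puller
    14: (0.45, 0.60, 0.16),   # dimpler
    15: (0.40, 0.65, 0.16),   # lip corner depressor
    17: (0.10, 0.85, 0.20),   # chin raiser
    18: (0.10, 0.55, 0.15),   # lip pucker
    20: (0.48, 0.55, 0.18),   # lip stretcher
    23: (0.22, 0.55, 0.14),   # lip tightener
    24: (0.16, 0.58, 0.14),   # lip presser
    25: (0.16, 0.52, 0.15),   # lips part
    26: (0.20, 0.90, 0.22),   # jaw drop
}

_MIDLINE_COUNTS = {"mesh478": 28, "bp4d83": 9}

# Facial feature clusters (left-half anchors) used to densify the template
# around eyes, nose and mouth, mimicking real face-mesh layouts.
_FEATURE_CLUSTERS = [
    ((-0.42, -0.35), 0.13, 0.22),  # eye
    ((-0.25, -0.55), 0.12, 0.10),  # brow
    ((-0.10, 0.00), 0.12, 0.16),   # nose
    ((-0.22, 0.55), 0.14, 0.25),   # mouth
    ((-0.55, 0.10), 0.18, 0.07),   # cheek
]


def _dome_z(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    r2 = (x / 1.05) ** 2 + (y / 1.30) ** 2
    return 0.55 * np.sqrt(np.clip(1.0 - r2, 0.0, None))


def builtin_mirror_map(topology_id: str, n_points: int | None = None) -> MirrorMap:
    """Mirror map for simulator-generated templates, known by construction.

    Template layout: ``n_mid`` midline points first, then ``n_pairs`` left
    points, then their right-side mirrors in the same order.
    """
    if n_points is None:
        if topology_id not in TOPOLOGY_POINTS:
            raise InvalidInputError(
                f"n_points required for topology {topology_id!r}")
        n_points = TOPOLOGY_POINTS[topology_id]
    n_mid = _MIDLINE_COUNTS.get(topology_id, n_points % 2)
    n_pairs = (n_points - n_mid) // 2
    if n_mid + 2 * n_pairs != n_points:
        raise InvalidInputError("point count incompatible with mirror layout")
    pairs = [(n_mid + i, n_mid + n_pairs + i) for i in range(n_pairs)]
    return MirrorMap(pairs=pairs, midline=list(range(n_mid)))


def make_template(topology_id: str, seed: int = 0,
                  n_points: int | None = None) -> LandmarkFrame:
    """Deterministic, bilaterally symmetric face-like template mesh.

    Points are sampled more densely around the eyes, brows, nose and mouth
    than over the rest of the face oval, and lifted onto an ellipsoidal
    dome (z toward the camera). Index layout matches
    :func:`builtin_mirror_map`.
    """
    if n_points is None:
        if topology_id not in TOPOLOGY_POINTS:
            raise InvalidInputError(
                f"n_points required for topology {topology_id!r}")
        n_points = TOPOLOGY_POINTS[topology_id]
    n_mid = _MIDLINE_COUNTS.get(topology_id, n_points % 2)
    n_pairs = (n_points - n_mid) // 2
    topo_key = zlib.crc32(topology_id.encode()) % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([seed, topo_key]))

    # midline profile: forehead -> chin
    ym = np.linspace(-1.15, 1.15, n_mid) if n_mid else np.empty(0)
    mid = np.stack([np.zeros(n_mid), ym, _dome_z(np.zeros(n_mid), ym)], axis=1) \
        if n_mid else np.empty((0, 3))

    weights = np.array([c[2] for c in _FEATURE_CLUSTERS])
    weights = weights / weights.sum()
    left = np.empty((n_pairs, 2))
    n_feat = int(0.6 * n_pairs)
    comp = rng.choice(len(_FEATURE_CLUSTERS), size=n_feat, p=weights)
    for i in range(n_feat):
        (cx, cy), sig, _ = _FEATURE_CLUSTERS[comp[i]]
        left[i] = (cx + sig * rng.standard_normal(), cy + sig * rng.standard_normal())
    # background: uniform over the left half-oval via rejection-free polar draw
    n_bg = n_pairs - n_feat
    theta = rng.uniform(0.5 * np.pi, 1.5 * np.pi, n_bg)
    rad = np.sqrt(rng.uniform(0.0, 1.0, n_bg))
    left[n_feat:, 0] = 1.0 * rad * np.cos(theta)
    left[n_feat:, 1] = 1.25 * rad * np.sin(theta)
    # keep strictly on the left and inside the oval
    left[:, 0] = -np.abs(left[:, 0]) - 0.01
    left[:, 0] = np.clip(left[:, 0], -1.0, -0.01)
    left[:, 1] = np.clip(left[:, 1], -1.2, 1.2)
    zl = _dome_z(left[:, 0], left[:, 1])
    left3 = np.stack([left[:, 0], left[:, 1], zl], axis=1)
    right3 = left3 * np.array([-1.0, 1.0, 1.0])
    coords = np.concatenate([mid, left3, right3], axis=0)
    return LandmarkFrame(coords, topology_id)


@dataclass
class DeformationBasis:
    """Per-AU localized 3D displacement fields over a template mesh.

    Each field has unit RMS displacement over its region of support and is
    exactly zero outside it; bilateral AUs are mirror-symmetric. ``gain``
    converts unit fields to template-scale displacement at intensity 5.
    """

    fields: dict[int, np.ndarray]        # au_id -> (Ns, 3)
    region_masks: dict[int, np.ndarray]  # au_id -> (Ns,) weights in [0, 1]
    gain: float = 0.15

    def displacement(self, intensities: np.ndarray, au_ids: Sequence[int]) -> np.ndarray:
        """Sum the scaled fields: (T, K) intensities -> (T, Ns, 3)."""
        T = intensities.shape[0]
        ns = next(iter(self.fields.values())).shape[0]
        F = np.stack([self.fields[a].reshape(-1) for a in au_ids])  # (K, 3Ns)
        disp = (intensities / 5.0 * self.gain) @ F
        return disp.reshape(T, ns, 3)


def _mirror_field(field: np.ndarray, mirror: MirrorMap) -> np.ndarray:
    perm = mirror.permutation()
    out = field[perm].copy()
    out[:, 0] = -out[:, 0]
    return out


def make_basis(template: LandmarkFrame, au_ids: Sequence[int], seed: int = 0,
               gain: float = 0.15, max_cosine: float = 0.3,
               mirror: MirrorMap | None = None) -> DeformationBasis:
    """Smooth, localized, mirror-symmetric displacement field per AU.

    Fields are Gaussian-windowed low-frequency random displacements anchored
    at the AU's facial region. Pairwise cosine similarity between flattened
    fields is kept below ``max_cosine`` so AUs stay statistically
    identifiable; violating draws are resampled.
    """
    unknown = [a for a in au_ids if a not in AU_ALL_IDS]
    if unknown:
        raise InvalidInputError(f"unknown AU ids: {unknown}")
    if mirror is None:
        mirror = builtin_mirror_map(template.topology_id, template.n_points)
    pts = template.coords
    xy = pts[:, :2]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    raw_fields: list[np.ndarray] = []
    windows: list[np.ndarray] = []
    for au in au_ids:
        ax, ay, sig = _AU_REGIONS.get(
            au, (0.3 + 0.4 * ((au * 37) % 7) / 7.0,
                 -0.9 + 1.8 * ((au * 61) % 11) / 11.0, 0.2))
        centers = np.array([[-ax, ay], [ax, ay]])
        d2 = ((xy[:, None, :] - centers[None, :, :]) ** 2).sum(-1).min(axis=1)
        w = np.exp(-d2 / (2.0 * sig ** 2))
        w[w < 0.01] = 0.0
        # smooth random displacement, windowed to the region + symmetrized
        disp = np.zeros((template.n_points, 3))
        for _ in range(4):
            k = rng.uniform(-6.0, 6.0, size=3)
            phase = rng.uniform(0, 2 * np.pi)
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            disp += np.cos(pts @ k + phase)[:, None] * u
        disp *= w[:, None]
        disp = 0.5 * (disp + _mirror_field(disp, mirror))
        if np.linalg.norm(disp) < 1e-9:
            raise RuntimeError(f"degenerate displacement field for AU {au}")
        raw_fields.append(disp)
        windows.append(w)

    # Windowed fields of AUs sharing a facial region (the mouth hosts many)
    # can correlate strongly; orthogonalise each field against its
    # predecessors. A linear combination of smooth local symmetric fields
    # stays smooth, local and symmetric; the region mask is widened to the
    # union of the supports the field borrows from.
    fields = {}
    masks = {}
    ortho: list[np.ndarray] = []
    ortho_w: list[np.ndarray] = []
    for i, au in enumerate(au_ids):
        f = raw_fields[i].reshape(-1).astype(np.float64)
        w = windows[i].copy()
        for j, q in enumerate(ortho):
            coef = f @ q
            if abs(coef) > 1e-12:
                f = f - coef * q
                w = np.maximum(w, ortho_w[j])
        norm = np.linalg.norm(f)
        if norm < 1e-9:
            raise RuntimeError(f"AU {au} field vanished during orthogonalisation")
        ortho.append(f / norm)
        ortho_w.append(w)
        disp = f.reshape(-1, 3)
        support = w > 0
        rms = np.sqrt(np.mean(disp[support] ** 2))
        fields[au] = disp / rms
        masks[au] = w

    flat = np.stack([fields[a].reshape(-1) for a in au_ids])
    norms = np.linalg.norm(flat, axis=1)
    cos = (flat @ flat.T) / np.outer(norms, norms)
    np.fill_diagonal(cos, 0.0)
    if np.abs(cos).max() >= max_cosine:
        raise RuntimeError("could not build an identifiable deformation basis")
    return DeformationBasis(fields=fields, region_masks=masks, gain=gain)


@dataclass
class ActivationTimecourse:
    """Smooth per-frame AU intensities for one segment."""

    intensities: np.ndarray  # (T, K) in [0, 5]
    au_ids: list[int]
    segment_class: str  # pain / happiness / embarrassment / fear

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if np.any((self.intensities < 0) | (self.intensities > 5)):
            raise InvalidInputError("intensities must lie in [0, 5]")


#: Apex-intensity distribution over {1..5}, skewed low: in real FACS-coded
#: video, absence and low intensities dominate.
_APEX_P = np.array([0.35, 0.30, 0.20, 0.10, 0.05])


def _add_pulse(track: np.ndarray, fps: float, rng: np.random.Generator,
               apex: float) -> None:
    T = track.shape[0]
    onset = rng.uniform(0.6, 2.0)
    offset = rng.uniform(0.6, 2.0)
    hold = rng.uniform(0.2, 1.5)
    total = onset + hold + offset
    # shrink pulses that would not fit a short segment
    max_total = 0.9 * T / fps
    if total > max_total:
        shrink = max_total / total
        onset, offset, hold = onset * shrink, offset * shrink, hold * shrink
        total = onset + hold + offset
    # cap the apex so each ramp's per-frame change stays <= 0.45; two
    # overlapping pulses then still respect the <= 1.0 smoothness bound
    max_slope_apex = 0.40 * 2.0 * min(onset, offset) * fps / np.pi
    apex = min(apex, max_slope_apex)
    start_s = rng.uniform(-0.25 * total, T / fps - 0.75 * total)
    t = np.arange(T) / fps - start_s
    ramp_up = np.clip(t / onset, 0.0, 1.0)
    ramp_down = np.clip((onset + hold + offset - t) / offset, 0.0, 1.0)
    env = np.clip(np.minimum(ramp_up, ramp_down), 0.0, 1.0)
    # raised-cosine smoothing of the trapezoid keeps frame deltas small
    env = 0.5 - 0.5 * np.cos(np.pi * env)
    track += apex * env


def simulate_timecourse(segment_class: str, duration_s: float, frame_rate: float,
                        seed: int | np.random.Generator = 0,
                        au_ids: Sequence[int] = AU_ALL_IDS,
                        distractor_rate: float = 0.15,
                        common_au_rate: float = 0.6,
                        common_au_ids: Sequence[int] = DETECTION_AU_IDS,
                        rare_au_scale: dict[int, float] | None = None) -> ActivationTimecourse:
    """Sample smooth onset-apex-offset AU activation pulses for one segment.

    Class-associated AUs fire 1-4 pulses with apex intensity drawn from a
    low-skewed distribution over {1..5}. Of the ``common_au_ids`` (the
    top-present detectable AUs), those not associated with any emotion
    class fire 1-2 background pulses with probability ``common_au_rate``
    per segment — their overall presence in real elicitation data is high
    without being class-specific. Every other non-class AU may fire one
    low-amplitude distractor pulse with probability ``distractor_rate``;
    class-discriminative AUs (e.g. the nose wrinkler in pain) therefore
    stay rare outside their classes, which is what keeps them informative.
    ``rare_au_scale`` multiplies a given AU's firing probability, letting
    experiments make specific AUs rare.
    """
    if segment_class not in CLASS_AU_SETS:
        raise InvalidInputError(
            f"segment_class must be one of {sorted(CLASS_AU_SETS)}")
    if duration_s < 2.0:
        raise InvalidInputError("segment duration must be at least 2 s")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = int(round(duration_s * frame_rate))
    K = len(au_ids)
    intens = np.zeros((T, K))
    active = set(CLASS_AU_SETS[segment_class])
    class_associated = set().union(*CLASS_AU_SETS.values())
    neutral_common = set(common_au_ids) - class_associated
    scale = rare_au_scale or {}
    for j, au in enumerate(au_ids):
        if au in active:
            if rng.random() > scale.get(au, 1.0):
                continue
            # pulse count grows with duration: expressive segments keep
            # firing their class AUs throughout, not once per segment
            n_pulses = min(8, 1 + rng.poisson(0.15 * duration_s))
            for _ in range(n_pulses):
                apex = float(rng.choice(np.arange(1, 6), p=_APEX_P))
                _add_pulse(intens[:, j], frame_rate, rng, apex)
        elif au in neutral_common:
            if rng.random() < common_au_rate * scale.get(au, 1.0):
                n_pulses = min(6, 1 + rng.poisson(0.08 * duration_s))
                for _ in range(n_pulses):
                    apex = float(rng.choice(np.arange(1, 6), p=_APEX_P))
                    _add_pulse(intens[:, j], frame_rate, rng, apex)
        else:
            if rng.random() < distractor_rate * scale.get(au, 1.0):
                apex = float(rng.choice([1.0, 2.0], p=[0.7, 0.3]))
                _add_pulse(intens[:, j], frame_rate, rng, apex)
    np.clip(intens, 0.0, 5.0, out=intens)
    # safety: pulse overlap could in rare cases exceed the smoothness
    # bound; temporal smoothing restores it without leaving [0, 5]
    for _ in range(5):
        if np.abs(np.diff(intens, axis=0)).max(initial=0.0) <= 1.0:
            break
        intens = gaussian_filter1d(intens, sigma=1.0, axis=0, mode="nearest")
    return ActivationTimecourse(intens, list(au_ids), segment_class)


def _smooth_pose_track(T: int, sd: float, rng: np.random.Generator,
                       n_axes: int = 3) -> np.ndarray:
    walk = np.cumsum(rng.standard_normal((T, n_axes)), axis=0)
    walk = gaussian_filter1d(walk, sigma=max(2.0, T / 20.0), axis=0, mode="nearest")
    walk -= walk.mean(axis=0)
    s = walk.std(axis=0)
    s[s < 1e-12] = 1.0
    return walk / s * sd


def render_sequence(template: LandmarkFrame, basis: DeformationBasis,
                    timecourse: ActivationTimecourse,
                    subject_shape: np.ndarray | None = None,
                    pose_jitter_deg: float = 2.0, pose_trans_sd: float = 0.01,
                    noise_sd: float = 0.01,
                    seed: int | np.random.Generator = 0,
                    frame_rate: float = 25.0,
                    subject_id: str = "", segment_id: str = "") -> Segment:
    """Render a landmark sequence from an activation timecourse.

    frame_t = R_t(subject_template + deformation_t) + t_t + noise, with the
    rigid pose following a slow smoothed random walk. Ground-truth labels
    are derived from the timecourse: presence = intensity >= 1 for the 8
    detection AUs, plus continuous intensities for the 5 intensity AUs and
    the full binary activation matrix over all simulated AUs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = template.coords if subject_shape is None else template.coords + subject_shape
    I = timecourse.intensities
    T = I.shape[0]
    shaped = base[None, :, :] + basis.displacement(I, timecourse.au_ids)
    angles = _smooth_pose_track(T, np.deg2rad(pose_jitter_deg), rng)
    trans = _smooth_pose_track(T, pose_trans_sd, rng)
    R = Rotation.from_euler("xyz", angles).as_matrix()  # (T, 3, 3)
    posed = np.einsum("tij,tnj->tni", R, shaped) + trans[:, None, :]
    if noise_sd > 0:
        posed = posed + rng.normal(0.0, noise_sd, size=posed.shape)

    idx = {au: j for j, au in enumerate(timecourse.au_ids)}

    def col(au: int) -> np.ndarray:
        return I[:, idx[au]] if au in idx else np.zeros(T)

    presence = np.stack([(col(a) >= 1.0).astype(np.int8)
                         for a in DETECTION_AU_IDS], axis=1)
    intensity = np.stack([np.clip(col(a), 0.0, 5.0)
                          for a in INTENSITY_AU_IDS], axis=1)
    au_full = np.stack([(col(a) >= 1.0).astype(np.int8)
                        for a in AU_ALL_IDS], axis=1)
    seg_class = "pain" if timecourse.segment_class == "pain" else "other"
    seq = LandmarkSequence(posed, template.topology_id, frame_rate,
                           subject_id, segment_id, seg_class)
    seg = Segment(seq, presence, intensity)
    seg.au_full = au_full
    seg.emotion = timecourse.segment_class
    return seg


@dataclass
class SimulationConfig:
    """Study-shaped simulation: per subject, 1 pain + 3 non-pain segments of
    ~20 s at 25 fps, with per-subject shape variation and AU gain."""

    n_subjects: int = 140
    pain_segments: int = 1
    other_segments: int = 3
    segment_seconds: float = 20.0
    segment_seconds_jitter: float = 2.0
    frame_rate: float = 25.0
    topology_id: str = "mesh478"
    noise_sd: float = 0.01
    pose_jitter_deg: float = 2.0
    pose_trans_sd: float = 0.01
    subject_shape_sd: float = 0.02
    subject_gain_sd: float = 0.10
    gain: float = 0.15
    distractor_rate: float = 0.15
    common_au_rate: float = 0.6
    rare_au_scale: dict = dc_field(default_factory=dict)
    simulated_au_ids: tuple = AU_ALL_IDS
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1 or self.pain_segments < 0 or self.other_segments < 0:
            raise InvalidInputError("counts must be positive")


def simulate_dataset(config: SimulationConfig) -> list[Segment]:
    """Simulate the full dataset described by ``config``.

    Deterministic given ``config.seed``. Non-pain segments cycle through
    happiness, embarrassment and fear.
    """
    template = make_template(config.topology_id, seed=config.seed)
    mirror = builtin_mirror_map(config.topology_id, template.n_points)
    basis = make_basis(template, config.simulated_au_ids, seed=config.seed,
                       gain=config.gain, mirror=mirror)
    root = np.random.SeedSequence([config.seed, 0xFACE])
    segments: list[Segment] = []
    for s, sub_ss in enumerate(root.spawn(config.n_subjects)):
        rng = np.random.default_rng(sub_ss)
        subject_id = f"subj_{s:04d}"
        shape = rng.normal(0.0, config.subject_shape_sd,
                           size=template.coords.shape)
        # subject expressiveness scales the activation trace itself, so
        # ground-truth labels track what the face actually does
        expressiveness = float(np.clip(
            1.0 + config.subject_gain_sd * rng.standard_normal(), 0.75, 1.25))
        classes = (["pain"] * config.pain_segments
                   + [OTHER_CLASSES[i % len(OTHER_CLASSES)]
                      for i in range(config.other_segments)])
        for g, cls in enumerate(classes):
            dur = config.segment_seconds + rng.uniform(
                -config.segment_seconds_jitter, config.segment_seconds_jitter)
            dur = max(2.0, dur)
            tc = simulate_timecourse(
                cls, dur, config.frame_rate, seed=rng,
                au_ids=config.simulated_au_ids,
                distractor_rate=config.distractor_rate,
                common_au_rate=config.common_au_rate,
                rare_au_scale=config.rare_au_scale or None)
            tc = ActivationTimecourse(
                np.clip(tc.intensities * expressiveness, 0.0, 5.0),
                tc.au_ids, tc.segment_class)
            seg = render_sequence(
                template, basis, tc, subject_shape=shape,
                pose_jitter_deg=config.pose_jitter_deg,
                pose_trans_sd=config.pose_trans_sd,
                noise_sd=config.noise_sd, seed=rng,
                frame_rate=config.frame_rate, subject_id=subject_id,
                segment_id=f"{subject_id}_seg_{g}")
            segments.append(seg)
    return segments
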