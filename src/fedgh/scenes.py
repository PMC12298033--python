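"""Procedural single-arm pose scenes with exact keypoint labels.

Each scene shows one instrumented arm — a two-segment kinematic chain
shoulder → elbow → wrist rendered as thick anti-aliased strokes on a
textured background, partially covered by a rectangular "manipulator"
occluder, under a per-scene illumination gain.  Ground-truth keypoints
are the kinematic joint positions themselves, so labels are exact by
construction and unaffected by occlusion or photometry (occluded joints
stay annotated, as in marker-verified capture).

Four fixed viewpoints (anterior, posterior, left lateral, right lateral)
are emulated by mirroring/shearing the kinematic chain in-plane, which
preserves exact 2-D labels.  Client heterogeneity — the driver of
inter-client gradient conflict — comes from :class:`ClientProfile`:
per-client viewpoint distributions, illumination ranges and joint-angle
distributions.  A scalar ``divergence`` dial interpolates from identical
profiles (IID control) to one-hot opposed viewpoints with opposed
illumination (the conflict fixture).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .partition import PartitionPlan, allocate_counts, assign_indices, normalize_weights

__all__ = [
    "VIEWPOINTS", "SceneSpec", "PoseSample", "ClientProfile",
    "generate_scene", "sample_scene_spec", "make_profiles", "conflict_profiles",
    "iid_profiles", "FederatedDataset", "ClientData", "make_federated_dataset",
]

VIEWPOINTS = ("anterior", "posterior", "left_lateral", "right_lateral")


@dataclass(frozen=True)
class SceneSpec:
    """Full generative description of one scene."""

    viewpoint: str = "anterior"
    arm_side: str = "right"
    pose: str = "upright"  # or "arm_extended"
    shoulder_anchor: tuple[float, float] = (24.0, 20.0)
    upper_arm_length: float = 14.0
    forearm_length: float = 12.0
    shoulder_angle: float = 1.2  # radians, from +x axis, y down
    elbow_angle: float = 0.5    # relative flexion
    occlusion_fraction: float = 0.35
    illumination_gain: float = 1.0
    background_texture_seed: int = 0
    image_size: int = 64
    torso_cue: float = 0.55  # intensity of the torso stroke disambiguating the shoulder end

    def __post_init__(self) -> None:
        if self.upper_arm_length <= 0 or self.forearm_length <= 0:
            raise ValueError("limb lengths must be positive")
        if not 0.0 <= self.occlusion_fraction <= 1.0:
            raise ValueError("occlusion_fraction must lie in [0, 1]")
        if self.viewpoint not in VIEWPOINTS:
            raise ValueError(f"unknown viewpoint {self.viewpoint!r}")
        x, y = self.shoulder_anchor
        if not (0 <= x < self.image_size and 0 <= y < self.image_size):
            raise ValueError("shoulder anchor outside image")


@dataclass
class PoseSample:
    """One rendered scene with labels and PCK normalization lengths."""

    image: np.ndarray            # (H, W) float32 in [0, 1]
    keypoints: np.ndarray        # (3, 3) [x, y, visibility]
    norm_lengths: np.ndarray     # [image diagonal, upper arm, forearm]
    viewpoint: str = "anterior"


def _chain_joints(spec: SceneSpec) -> np.ndarray:
    """Forward kinematics: shoulder, elbow, wrist in image pixels."""
    sx, sy = spec.shoulder_anchor
    a1 = spec.shoulder_angle
    if spec.pose == "arm_extended":
        a1 = a1 - 0.9  # raise toward horizontal
    side = 1.0 if spec.arm_side == "right" else -1.0
    elbow = np.array([sx + side * spec.upper_arm_length * np.cos(a1),
                      sy + spec.upper_arm_length * np.sin(a1)])
    a2 = a1 + spec.elbow_angle
    wrist = elbow + np.array([side * spec.forearm_length * np.cos(a2),
                              spec.forearm_length * np.sin(a2)])
    return np.stack([np.array([sx, sy]), elbow, wrist])


def _view_transform(points: np.ndarray, viewpoint: str, size: int) -> np.ndarray:
    """In-plane mirror/shear emulating a fixed camera viewpoint."""
    cx = (size - 1) / 2.0
    p = points.copy()
    if viewpoint == "anterior":
        return p
    if viewpoint == "posterior":
        p[:, 0] = 2 * cx - p[:, 0]
        return p
    cy = (size - 1) / 2.0
    if viewpoint == "left_lateral":
        p[:, 0] = cx + 0.65 * (p[:, 0] - cx) + 0.30 * (p[:, 1] - cy)
        return p
    # right lateral: mirrored shear
    p[:, 0] = cx - 0.65 * (p[:, 0] - cx) - 0.30 * (p[:, 1] - cy)
    return p


def _stroke(img: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float,
            value: float) -> None:
    """Draw an anti-aliased thick segment by distance thresholding."""
    h, w = img.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    d = p1 - p0
    L2 = float(d @ d)
    if L2 == 0:
        dist = np.hypot(xs - p0[0], ys - p0[1])
    else:
        t = ((xs - p0[0]) * d[0] + (ys - p0[1]) * d[1]) / L2
        t = np.clip(t, 0.0, 1.0)
        dist = np.hypot(xs - (p0[0] + t * d[0]), ys - (p0[1] + t * d[1]))
    alpha = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    np.maximum(img, value * alpha, out=img)


def generate_scene(spec: SceneSpec, rng: np.random.Generator) -> PoseSample:
    """Render one scene; ground truth equals the transformed kinematic joints."""
    size = spec.image_size
    # textured background: smoothed noise at a low mean intensity
    tex_rng = np.random.default_rng(spec.background_texture_seed)
    bg = ndimage.gaussian_filter(tex_rng.random((size, size)), sigma=2.0)
    img = (0.15 + 0.2 * bg).astype(np.float64)

    joints = _view_transform(_chain_joints(spec), spec.viewpoint, size)
    shoulder, elbow, wrist = joints

    _stroke(img, shoulder, elbow, radius=2.2, value=0.85)
    _stroke(img, elbow, wrist, radius=1.8, value=0.85)
    # torso hint behind the shoulder: the appearance cue that tells the
    # shoulder end from the wrist end.  Weak or absent cues leave
    # near-symmetric scenes whose labelling depends on the (client-biased)
    # viewpoint — the source of inter-client label conflict.
    if spec.torso_cue > 0:
        torso_top = shoulder + np.array([0.0, -6.0])
        torso_bot = shoulder + np.array([0.0, 18.0])
        _stroke(img, torso_top, torso_bot, radius=3.5, value=spec.torso_cue)

    if spec.occlusion_fraction > 0:
        # manipulator: a bright rectangle covering the middle fraction of
        # the shoulder→wrist span; labels are not altered
        mid = 0.5 * (shoulder + wrist)
        span = wrist - shoulder
        half = 0.5 * spec.occlusion_fraction * np.linalg.norm(span)
        direction = span / max(np.linalg.norm(span), 1e-9)
        perp = np.array([-direction[1], direction[0]])
        ys, xs = np.mgrid[0:size, 0:size].astype(np.float64)
        rel = np.stack([xs - mid[0], ys - mid[1]], axis=-1)
        along = rel @ direction
        across = rel @ perp
        box = (np.abs(along) <= half) & (np.abs(across) <= 3.0)
        img[box] = 0.95

    img = np.clip(img * spec.illumination_gain, 0.0, 1.0)

    vis = np.array([2.0 if (0 <= x < size and 0 <= y < size) else 0.0
                    for x, y in joints])
    keypoints = np.column_stack([joints, vis])
    norms = np.array([
        np.hypot(size, size),
        np.linalg.norm(elbow - shoulder),
        np.linalg.norm(wrist - elbow),
    ])
    return PoseSample(image=img.astype(np.float32), keypoints=keypoints,
                      norm_lengths=norms, viewpoint=spec.viewpoint)


@dataclass(frozen=True)
class ClientProfile:
    """Per-client scene distribution inducing feature heterogeneity."""

    viewpoint_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    illumination_range: tuple[float, float] = (0.8, 1.2)
    shoulder_angle_mean: float = 1.2
    shoulder_angle_std: float = 0.15
    elbow_angle_mean: float = 0.5
    elbow_angle_std: float = 0.25
    extended_prob: float = 0.3   # fraction of arm-extended (near-horizontal) poses
    torso_cue: float = 0.55      # shoulder-end disambiguation strength
    weight: float = 1.0

    def __post_init__(self) -> None:
        if abs(sum(self.viewpoint_probs) - 1.0) > 1e-9:
            raise ValueError("viewpoint distribution must sum to 1")


def sample_scene_spec(profile: ClientProfile, rng: np.random.Generator,
                      image_size: int = 64) -> SceneSpec:
    """Draw one scene description from a client's profile."""
    vp = VIEWPOINTS[rng.choice(4, p=np.asarray(profile.viewpoint_probs))]
    lo, hi = profile.illumination_range
    c = (image_size - 1) / 2.0
    return SceneSpec(
        viewpoint=vp,
        arm_side="right" if rng.random() < 0.5 else "left",
        pose="arm_extended" if rng.random() < profile.extended_prob else "upright",
        shoulder_anchor=(c + rng.uniform(-4, 4), c - image_size * 0.18 + rng.uniform(-3, 3)),
        upper_arm_length=image_size * 0.22 * rng.uniform(0.9, 1.1),
        forearm_length=image_size * 0.19 * rng.uniform(0.9, 1.1),
        shoulder_angle=rng.normal(profile.shoulder_angle_mean, profile.shoulder_angle_std),
        elbow_angle=rng.normal(profile.elbow_angle_mean, profile.elbow_angle_std),
        occlusion_fraction=rng.uniform(0.2, 0.5),
        illumination_gain=rng.uniform(lo, hi),
        background_texture_seed=int(rng.integers(2**31 - 1)),
        image_size=image_size,
        torso_cue=profile.torso_cue,
    )


def make_profiles(n_clients: int, divergence: float = 1.0,
                  weights: Sequence[float] | None = None) -> list[ClientProfile]:
    """Interpolate from identical profiles (divergence 0, IID) to strongly
    opposed ones (divergence 1).

    At full divergence each client sees one viewpoint only (cycling over
    the four views — pairs of clients thus hold mirror-image viewpoints),
    illumination alternates dark/bright, pose angles shift apart, most
    poses are arm-extended (near-horizontal, end-symmetric) and the torso
    cue disambiguating the shoulder end vanishes.  Mirror-ambiguous
    scenes with opposed viewpoints then carry conflicting labels across
    clients — the mechanism that makes client gradients collide.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    lam = divergence
    base_probs = np.full(4, 0.25)
    profiles = []
    for k in range(n_clients):
        onehot = np.zeros(4)
        onehot[k % 4] = 1.0
        probs = (1 - lam) * base_probs + lam * onehot
        if k % 2 == 0:
            illum = ((1 - lam) * 0.8 + lam * 0.45, (1 - lam) * 1.2 + lam * 0.65)
        else:
            illum = ((1 - lam) * 0.8 + lam * 1.35, (1 - lam) * 1.2 + lam * 1.60)
        angle_shift = lam * (0.35 if k % 2 == 0 else -0.35)
        profiles.append(ClientProfile(
            viewpoint_probs=tuple(probs),
            illumination_range=illum,
            shoulder_angle_mean=1.2 + angle_shift,
            extended_prob=0.3 + 0.6 * lam,
            torso_cue=0.55 * (1 - lam),
            weight=weights[k] if weights is not None else 1.0,
        ))
    return profiles


def iid_profiles(n_clients: int, weights: Sequence[float] | None = None) -> list[ClientProfile]:
    return make_profiles(n_clients, divergence=0.0, weights=weights)


def conflict_profiles(n_clients: int, weights: Sequence[float] | None = None) -> list[ClientProfile]:
    """Opposed-viewpoint, opposed-illumination profiles (divergence 1)."""
    return make_profiles(n_clients, divergence=1.0, weights=weights)


@dataclass
class ClientData:
    """One client's shard, pre-split into train and validation parts."""

    client_id: int
    train: list[PoseSample]
    val: list[PoseSample]
    profile: ClientProfile

    @property
    def n_train(self) -> int:
        return len(self.train)


@dataclass
class FederatedDataset:
    clients: list[ClientData]
    test: list[PoseSample]
    plan: PartitionPlan
    image_size: int


def make_federated_dataset(
    n: int,
    client_profiles: Sequence[ClientProfile],
    seed: int = 1234,
    image_size: int = 64,
    m_min: int = 10,
    splits: tuple[float, float, float] = (0.7, 0.2, 0.1),
) -> FederatedDataset:
    """Build per-client non-IID shards plus a profile-balanced test set.

    ``n`` is the total pool size.  The test fraction is held out first and
    drawn balanced across profiles; the remainder is partitioned across
    clients by the profiles' weights (quantity skew via the partitioner),
    each client drawing its samples from its own profile (feature skew).
    Within each client the shard splits train : val in the ratio of the
    first two split fractions.
    """
    if abs(sum(splits) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    k = len(client_profiles)
    rng = np.random.default_rng(seed)
    n_test = int(round(splits[2] * n))
    n_pool = n - n_test
    ratios = normalize_weights([p.weight for p in client_profiles])
    counts = allocate_counts(ratios, n_pool, m_min=m_min)
    plan = assign_indices(counts, n_pool, seed=seed)
    plan.m_min = m_min

    val_frac = splits[1] / (splits[0] + splits[1])
    clients = []
    for cid, profile in enumerate(client_profiles):
        c = counts[cid]
        samples = [generate_scene(sample_scene_spec(profile, rng, image_size), rng)
                   for _ in range(c)]
        n_val = min(int(round(val_frac * c)), c - 1)
        clients.append(ClientData(client_id=cid, train=samples[: c - n_val],
                                  val=samples[c - n_val :], profile=profile))

    test = []
    for i in range(n_test):
        profile = client_profiles[i % k]
        test.append(generate_scene(sample_scene_spec(profile, rng, image_size), rng))
    return FederatedDataset(clients=clients, test=test, plan=plan, image_size=image_size)
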