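"""Seeded synthetic phase-contrast scenes with pixel-level ground truth.

The generator emulates what a texture-based pixel classifier actually
sees in a phase-contrast micrograph of an adherent culture: irregular
colony blobs with a fine grainy interior texture, a smoother and slightly
brighter background, a bright halo rim just outside each colony boundary,
a slowly varying illumination bias, and (optionally) fabrication
artifacts — dark scratches and dust particles.  It is a look-alike, not
an optics simulation: there is no point-spread model, no shot noise
statistics, no defocus.  What it provides is exact ground truth (colony
mask, artifact mask) so segmentation, confluency and tracking can be
scored without any real data.

Everything is a pure function of the parameter dataclasses (seeds
included).  Colony placement first draws all random ingredients (centers,
per-colony shape-noise fields, relative sizes), then bisects a single
global radius-scale factor so the achieved colony-pixel fraction lands on
the requested target confluency — deterministic, and accurate to well
under the +/-0.02 contract over the useful target range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError

#: Roughness of colony outlines: weight of the shape-noise field against
#: the normalized radial distance.
_ROUGHNESS = 0.30
#: Grain (Gaussian sigma, px) of the colony outline noise.
_SHAPE_GRAIN = 10.0


@dataclass(frozen=True)
class SceneParams:
    """Study conditions for one synthetic field of view.

    Texture tuples are (grain sigma px, contrast = intensity sd).  The
    defaults give a clearly separable two-texture scene: fine high-contrast
    colony interiors on a smooth low-contrast background, colonies ~0.10
    darker on average, a 3 px bright halo rim, and a 6% illumination bias.
    """

    shape: tuple = (256, 256)
    target_confluency: float = 0.30
    n_colonies: int = 2
    colony_texture: tuple = (1.2, 0.16)
    background_texture: tuple = (3.0, 0.05)
    colony_level: float = -0.10
    background_level: float = 0.58
    halo_width: int = 3
    halo_gain: float = 0.20
    illumination_bias_amplitude: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_confluency <= 0.95:
            raise InvalidParameterError(
                "target_confluency must be in [0, 0.95]"
            )
        if self.halo_width < 1 or self.colony_texture[0] <= 0 or self.background_texture[0] <= 0:
            raise InvalidParameterError("widths and grains must be positive")
        if self.n_colonies < 0:
            raise InvalidParameterError("n_colonies must be >= 0")


@dataclass(frozen=True)
class ArtifactParams:
    """Fabrication artifacts: dark scratches (lines) and dust (disks)."""

    n_scratches: int = 2
    scratch_width: float = 2.0
    scratch_depth: float = 0.25
    n_dust: int = 6
    dust_radius: float = 4.0
    dust_depth: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.n_scratches < 0 or self.n_dust < 0:
            raise InvalidParameterError("artifact counts must be >= 0")


@dataclass
class SynthScene:
    """A synthetic field with its ground truths.

    ``truth_mask`` marks colony pixels (the halo rim is ground-truth
    background); ``artifact_mask`` marks artifact pixels and is disjoint
    from the truth by construction.  ``placed_artifacts`` records the
    geometry of every rendered artifact for oracle checks.
    """

    image: np.ndarray
    truth_mask: np.ndarray
    artifact_mask: np.ndarray
    params: SceneParams
    artifact_params: ArtifactParams | None = None
    achieved_confluency: float = 0.0
    placed_artifacts: list = field(default_factory=list)


def _smooth_noise(rng, shape, grain) -> np.ndarray:
    """Unit-variance, zero-mean Gaussian-smoothed noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), grain, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _colony_ingredients(rng, params: SceneParams):
    """Draw all random inputs of colony placement once, up front."""
    h, w = params.shape
    n = params.n_colonies
    centers = np.column_stack(
        [
            rng.uniform(0.18 * h, 0.82 * h, size=n),
            rng.uniform(0.18 * w, 0.82 * w, size=n),
        ]
    )
    rel = rng.uniform(0.7, 1.3, size=n)
    share = rel**2 / np.sum(rel**2)
    base_r = np.sqrt(params.target_confluency * h * w * share / np.pi)
    noise = [_smooth_noise(rng, params.shape, _SHAPE_GRAIN) for _ in range(n)]
    return centers, base_r, noise


def _blob(shape, center, radius, noise) -> np.ndarray:
    """One connected, irregular colony footprint.

    Thresholded (radial distance + shape noise); outline noise can spawn
    disconnected satellites far from the center, so only the connected
    component containing the center survives — a colony is one object.
    """
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    d = np.hypot(yy - center[0], xx - center[1])
    raw = (d / max(radius, 1e-9) + _ROUGHNESS * noise) < 1.0
    labeled, n = ndimage.label(raw, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return raw
    cy = int(np.clip(round(center[0]), 0, shape[0] - 1))
    cx = int(np.clip(round(center[1]), 0, shape[1] - 1))
    lid = labeled[cy, cx]
    if lid == 0:
        lid = int(np.argmax(np.bincount(labeled.ravel())[1:])) + 1
    return labeled == lid


def _union_mask(shape, centers, radii, noises) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for c, r, nz in zip(centers, radii, noises):
        if r > 0:
            mask |= _blob(shape, c, r, nz)
    return mask


def _calibrate_scale(shape, centers, base_r, noises, target: float) -> float:
    """Bisect the global radius scale so the union hits the target fraction."""
    def achieved(scale):
        return _union_mask(shape, centers, base_r * scale, noises).mean()

    lo, hi = 1e-3, 1.0
    while achieved(hi) < target and hi < 16.0:
        hi *= 1.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        f = achieved(mid)
        if abs(f - target) <= 0.003:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _render(params: SceneParams, truth: np.ndarray, rng_textures) -> np.ndarray:
    """Compose intensities: two textures, halo rim, illumination bias."""
    h, w = params.shape
    bg_grain, bg_contrast = params.background_texture
    col_grain, col_contrast = params.colony_texture
    bg_tex, col_tex, bias_field = rng_textures
    image = np.where(
        truth,
        params.background_level + params.colony_level + col_contrast * col_tex,
        params.background_level + bg_contrast * bg_tex,
    )
    # bright halo rim just outside the colony boundary, fading outward
    if truth.any():
        dist = ndimage.distance_transform_edt(~truth)
        band = (dist > 0) & (dist <= params.halo_width)
        profile = 1.0 - dist / (params.halo_width + 1.0)
        image = np.where(band, image + params.halo_gain * profile, image)
    image = image + params.illumination_bias_amplitude * bias_field
    return np.clip(image, 0.0, 1.0)


def _draw_textures(rng, params: SceneParams):
    h, w = params.shape
    bg_tex = _smooth_noise(rng, params.shape, params.background_texture[0])
    col_tex = _smooth_noise(rng, params.shape, params.colony_texture[0])
    bias = _smooth_noise(rng, params.shape, min(h, w) / 4.0)
    return bg_tex, col_tex, bias


def generate_scene(params: SceneParams | None = None) -> SynthScene:
    """Generate one synthetic field with exact colony ground truth."""
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(params.seed)
    textures = _draw_textures(rng, params)
    if params.target_confluency <= 0 or params.n_colonies == 0:
        truth = np.zeros(params.shape, dtype=bool)
    else:
        centers, base_r, noises = _colony_ingredients(rng, params)
        scale = _calibrate_scale(
            params.shape, centers, base_r, noises, params.target_confluency
        )
        truth = _union_mask(params.shape, centers, base_r * scale, noises)
    image = _render(params, truth, textures)
    return SynthScene(
        image=image,
        truth_mask=truth.astype(np.uint8),
        artifact_mask=np.zeros(params.shape, dtype=np.uint8),
        params=params,
        achieved_confluency=float(truth.mean()),
    )


def _segment_distance(shape, p0, p1) -> np.ndarray:
    """Distance of every pixel to the segment p0-p1 (vectorized)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    v = np.array(p1, dtype=float) - np.array(p0, dtype=float)
    L2 = float(v @ v)
    wy = yy - p0[0]
    wx = xx - p0[1]
    t = np.clip((wy * v[0] + wx * v[1]) / L2 if L2 > 0 else 0.0, 0.0, 1.0)
    return np.hypot(wy - t * v[0], wx - t * v[1])


def add_artifacts(scene: SynthScene, artifacts: ArtifactParams | None = None) -> SynthScene:
    """Render scratches and dust onto a copy of a scene.

    The colony ground truth is untouched; artifact pixels are recorded in
    ``artifact_mask`` and are kept off colony pixels (dust placement
    retries away from colonies, scratch darkening is occluded by them), so
    the two ground truths stay disjoint.
    """
    if artifacts is None:
        artifacts = ArtifactParams()
    rng = np.random.default_rng(artifacts.seed)
    h, w = scene.image.shape
    image = scene.image.copy()
    truth = scene.truth_mask.astype(bool)
    amask = scene.artifact_mask.astype(bool).copy()
    placed = list(scene.placed_artifacts)
    clear = ~ndimage.binary_dilation(
        truth, structure=np.ones((3, 3)), iterations=max(1, scene.params.halo_width)
    )

    for _ in range(artifacts.n_scratches):
        p0 = (rng.uniform(0, h - 1), rng.uniform(0, w - 1))
        ang = rng.uniform(0, np.pi)
        length = rng.uniform(0.6, 1.2) * max(h, w)
        p1 = (p0[0] + length * np.sin(ang), p0[1] + length * np.cos(ang))
        d = _segment_distance((h, w), p0, p1)
        half = artifacts.scratch_width / 2.0
        soft = np.clip(1.0 - d / (half + 0.5), 0.0, 1.0)
        hit = (d <= half + 0.5) & ~truth
        image = np.where(~truth, image - artifacts.scratch_depth * soft, image)
        amask |= hit
        placed.append({"kind": "scratch", "p0": p0, "p1": p1, "width": artifacts.scratch_width})

    yy, xx = np.ogrid[:h, :w]
    for _ in range(artifacts.n_dust):
        center = None
        for _attempt in range(50):
            cand = (rng.uniform(0, h - 1), rng.uniform(0, w - 1))
            d = np.hypot(yy - cand[0], xx - cand[1])
            if clear[d <= artifacts.dust_radius + 1].all():
                center = cand
                break
        if center is None:
            continue
        d = np.hypot(yy - center[0], xx - center[1])
        hit = d <= artifacts.dust_radius
        soft = np.clip(1.0 - (d / max(artifacts.dust_radius, 1e-9)) ** 2, 0.0, 1.0)
        image = image - artifacts.dust_depth * soft * hit
        amask |= hit
        placed.append({"kind": "dust", "center": center, "radius": artifacts.dust_radius})

    amask &= ~truth
    return SynthScene(
        image=np.clip(image, 0.0, 1.0),
        truth_mask=scene.truth_mask.copy(),
        artifact_mask=amask.astype(np.uint8),
        params=scene.params,
        artifact_params=artifacts,
        achieved_confluency=scene.achieved_confluency,
        placed_artifacts=placed,
    )


def generate_timelapse(
    initial: SceneParams | None = None,
    n_frames: int = 10,
    growth_rate: float = 0.25,
    capacity: float = 0.60,
    drift: float = 1.0,
    merge_allowed: bool = True,
    washout: dict | None = None,
    centers: Sequence | None = None,
    velocities: Sequence | None = None,
    jitter: float = 0.3,
) -> list[SynthScene]:
    """Synthetic time-lapse: logistic colony growth, drift, merges, wash-out.

    Per frame, each colony's area grows by ``growth_rate * (1 - C/K)``
    (C = total colony fraction, K = ``capacity``) and its center moves by
    its per-colony velocity (random direction of magnitude ``drift``
    unless ``velocities`` is given) plus seeded jitter.  ``washout`` maps
    colony index -> first frame at which it is gone (emulating detachment
    under perfusion).  When ``merge_allowed`` is off, a colony's move is
    cancelled in frames where it would bring footprints into contact.
    ``centers`` overrides the random initial positions (row, col).
    """
    if initial is None:
        initial = SceneParams()
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    washout = washout or {}
    rng = np.random.default_rng(initial.seed)
    textures = _draw_textures(rng, initial)
    ctr, base_r, noises = _colony_ingredients(rng, initial)
    n = initial.n_colonies
    if centers is not None:
        ctr = np.asarray(centers, dtype=float).copy()
    if velocities is None:
        angles = rng.uniform(0, 2 * np.pi, size=n)
        vel = drift * np.column_stack([np.sin(angles), np.cos(angles)])
    else:
        vel = np.asarray(velocities, dtype=float)

    scale = _calibrate_scale(
        initial.shape, ctr, base_r, noises, initial.target_confluency
    )
    radii = base_r * scale
    alive = np.ones(n, dtype=bool)
    ctr0 = ctr.copy()  # shape-noise fields ride along with their colony

    scenes = []
    for t in range(n_frames):
        for idx, f0 in washout.items():
            if t >= f0:
                alive[idx] = False
        live = [i for i in range(n) if alive[i]]
        moved_noises = []
        for i in live:
            dy, dx = np.round(ctr[i] - ctr0[i]).astype(int)
            moved_noises.append(np.roll(noises[i], (dy, dx), axis=(0, 1)))
        truth = _union_mask(
            initial.shape,
            ctr[live],
            radii[live],
            moved_noises,
        )
        image = _render(initial, truth, textures)
        scenes.append(
            SynthScene(
                image=image,
                truth_mask=truth.astype(np.uint8),
                artifact_mask=np.zeros(initial.shape, dtype=np.uint8),
                params=replace(initial, seed=initial.seed),
                achieved_confluency=float(truth.mean()),
            )
        )
        # advance state for the next frame
        total = truth.mean()
        factor = 1.0 + growth_rate * max(0.0, 1.0 - total / capacity)
        radii = radii * np.sqrt(factor)
        step = vel + rng.normal(0.0, jitter, size=(n, 2))
        new_ctr = ctr + step
        if not merge_allowed:
            for i in live:
                for j in live:
                    if j <= i:
                        continue
                    gap = np.hypot(*(new_ctr[i] - new_ctr[j]))
                    if gap < 1.3 * (radii[i] + radii[j]):
                        new_ctr[j] = ctr[j]  # cancel the later colony's move
        ctr = new_ctr
    return scenes


def scripted_event_timelapse(seed: int = 0, n_frames: int = 10):
    """A 10-frame time-lapse with one scripted merge and one wash-out.

    Three colonies: two seeded on a collision course (velocities +/-6
    px/frame toward each other) that merge mid-sequence, and one that
    washes out between frames 3 and 4.  Returns ``(scenes, expected)``
    where ``expected`` records the scripted events: exactly one merge
    and a disappearance at frames (3, 4).
    """
    params = SceneParams(seed=seed, n_colonies=3, target_confluency=0.15)
    scenes = generate_timelapse(
        params,
        n_frames=n_frames,
        growth_rate=0.12,
        capacity=0.32,
        centers=[(150, 52), (150, 204), (30, 128)],
        velocities=[(0, 6), (0, -6), (0, 0)],
        washout={2: 4},
        jitter=0.2,
    )
    expected = {"n_merges": 1, "washout_frames": (3, 4)}
    return scenes, expected


def annotations_from_truth(
    truth_mask,
    halo_width: int = 3,
    fraction: float = 0.10,
    pos_margin: int = 3,
    boundary_margin: int = 2,
    seed: int = 0,
    artifact_mask=None,
) -> np.ndarray:
    """Emulate a user's sparse trinary annotation from ground truth.

    Positives are sampled from the colony interior (eroded by
    ``pos_margin`` so the user stays clearly inside); negatives from
    everything at least ``boundary_margin`` outside the colony edge —
    including the halo rim, which a user would paint "definitely not
    colony".  ``fraction`` of each region is kept (seeded), emulating
    quick partial scribbles; when an ``artifact_mask`` is given its
    pixels are added to the negative pool so artifacts are explicitly
    taught as background.  Returns a 0/1/2 mask
    (unspecified/negative/positive).
    """
    truth = np.asarray(truth_mask).astype(bool)
    rng = np.random.default_rng(seed)
    eight = np.ones((3, 3), dtype=bool)
    pos_region = ndimage.binary_erosion(truth, structure=eight, iterations=max(1, pos_margin))
    neg_region = ~ndimage.binary_dilation(
        truth, structure=eight, iterations=max(1, boundary_margin)
    )
    ann = np.zeros(truth.shape, dtype=np.uint8)
    for region, value in ((neg_region, 1), (pos_region, 2)):
        idx = np.flatnonzero(region.ravel())
        if idx.size == 0:
            continue
        keep = rng.choice(idx, size=max(1, int(fraction * idx.size)), replace=False)
        ann.ravel()[keep] = value
    if artifact_mask is not None:
        art = np.asarray(artifact_mask).astype(bool) & ~truth
        idx = np.flatnonzero(art.ravel())
        if idx.size:
            keep = rng.choice(idx, size=max(1, int(fraction * idx.size)), replace=False)
            ann.ravel()[keep] = 1
    return ann
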