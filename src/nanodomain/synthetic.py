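"""Generators for synthetic imaging and tracking data with known ground truth.

These emulate the statistical structure of TIRF fields of diffraction-limited
puncta — sub-pixel spot positions rendered as pixel-integrated Gaussians with
log-normal amplitudes over a flat background, Poisson shot noise and Gaussian
read noise, inside an elliptical cell-like mask — plus free-diffusion
trajectories sampled at a fixed frame interval. Every generator returns the
realized ground truth alongside the data so downstream analyses (detection,
colocalization, diffusivity estimation) can be scored exactly, and every
generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

__all__ = [
    "ChannelSpec",
    "ImageSpec",
    "TrackSpec",
    "ellipse_mask",
    "render_spots",
    "random_points_in_mask",
    "generate_spot_image_set",
    "generate_coloc_point_patterns",
    "generate_free_diffusion_tracks",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel: spot count, PSF width and intensity model.

    Amplitudes are log-normal with the given median and log-scale sigma,
    reflecting the broad intensity spread of real nanodomain objects.
    """

    name: str
    n_spots: int
    sigma: float = 1.1  # PSF width, px
    amp_median: float = 400.0  # AU
    amp_sigma: float = 0.5  # log-scale
    background: float = 100.0  # AU
    poisson_noise: bool = True
    read_noise_sd: float = 3.0  # AU

    def __post_init__(self):
        if self.n_spots < 0 or self.sigma <= 0 or self.amp_median <= 0:
            raise ValueError("invalid channel spec")
        if self.background < 0 or self.read_noise_sd < 0 or self.amp_sigma < 0:
            raise ValueError("invalid channel noise spec")


@dataclass(frozen=True)
class ImageSpec:
    """Multichannel spot-image specification.

    ``coloc_plan`` maps ``(channel, anchor_channel)`` to the fraction of the
    channel's spots placed within ``coloc_radius`` px of a randomly chosen
    anchor spot (uniform in the disc); the rest are uniform in the mask.
    ``condition_plan`` maps ``(channel, anchor_channel)`` entries used the
    same way but reserved for a third, "condition" channel whose spots mark
    a subset of anchor sites.
    """

    size: tuple[int, int] = (256, 256)
    channels: tuple[ChannelSpec, ...] = ()
    coloc_plan: dict = field(default_factory=dict)
    coloc_radius: float = 3.0
    mask_margin: float = 0.05  # ellipse inset as a fraction of the frame

    def __post_init__(self):
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")
        for (ch, anchor), frac in self.coloc_plan.items():
            if ch not in names or anchor not in names:
                raise ValueError(f"coloc plan references unknown channel {ch}/{anchor}")
            if not 0 <= frac <= 1:
                raise ValueError("coloc fractions must be in [0, 1]")


@dataclass(frozen=True)
class TrackSpec:
    """Free-diffusion track specification (2-D Brownian motion)."""

    D: float = 0.2  # μm²/s
    interval: float = 0.05  # s, 20 Hz framerate
    n_tracks: int = 100
    track_length: int = 250  # frames
    loc_noise_sd: float = 0.0  # μm

    def __post_init__(self):
        if self.D < 0 or self.interval <= 0 or self.n_tracks < 1 or self.track_length < 2:
            raise ValueError("invalid track spec")
        if self.loc_noise_sd < 0:
            raise ValueError("localization noise must be non-negative")


# ---------------------------------------------------------------------------
# building blocks


def ellipse_mask(size: tuple[int, int], margin: float = 0.05) -> np.ndarray:
    """Elliptical cell-like mask inscribed in the frame with a fractional inset."""
    ny, nx = size
    y, x = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    ry, rx = (1 - margin) * ny / 2, (1 - margin) * nx / 2
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def render_spots(
    size: tuple[int, int],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
    background: float = 0.0,
) -> np.ndarray:
    """Render spots as pixel-integrated Gaussians over a flat background.

    Each spot contributes ``A·∫∫ G(x−x0, y−y0; σ) dx dy`` over every pixel,
    evaluated with error functions, so the peak pixel of a centred spot has
    value ≈ A·erf(0.5/σ√2)² — faithful at σ ≈ 1 px where point sampling is
    not. Positions are (y, x) in pixel units, pixel centres at integers.
    """
    img = np.full(size, float(background))
    if len(positions) == 0:
        return img
    half = int(np.ceil(4 * sigma)) + 1
    s2 = sigma * np.sqrt(2.0)
    ny, nx = size
    for (py, px), amp in zip(np.atleast_2d(positions), amplitudes):
        y0 = max(0, int(np.floor(py)) - half)
        y1 = min(ny, int(np.ceil(py)) + half + 1)
        x0 = max(0, int(np.floor(px)) - half)
        x1 = min(nx, int(np.ceil(px)) + half + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy = np.arange(y0, y1)
        xx = np.arange(x0, x1)
        fy = 0.5 * (erf((yy + 0.5 - py) / s2) - erf((yy - 0.5 - py) / s2))
        fx = 0.5 * (erf((xx + 0.5 - px) / s2) - erf((xx - 0.5 - px) / s2))
        # normalised so amp is the peak height of the continuous Gaussian
        img[y0:y1, x0:x1] += amp * 2 * np.pi * sigma**2 * np.outer(fy, fx)
    return img


def random_points_in_mask(mask: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` points uniform over the mask's pixel area, sub-pixel jittered (y, x)."""
    inside = np.argwhere(mask)
    if len(inside) == 0:
        raise ValueError("empty mask")
    pick = inside[rng.integers(len(inside), size=n)]
    return pick + rng.uniform(-0.5, 0.5, size=(n, 2))


def _points_near_anchors(
    anchors: np.ndarray, n: int, radius: float, mask: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """``n`` points, each uniform in the disc of ``radius`` around a random anchor."""
    out = np.empty((n, 2))
    ny, nx = mask.shape
    filled = 0
    while filled < n:
        a = anchors[rng.integers(len(anchors))]
        r = radius * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        p = a + [r * np.sin(th), r * np.cos(th)]
        iy, ix = int(round(p[0])), int(round(p[1]))
        if 0 <= iy < ny and 0 <= ix < nx and mask[iy, ix]:
            out[filled] = p
            filled += 1
    return out


# ---------------------------------------------------------------------------
# generators


def generate_coloc_point_patterns(
    mask: np.ndarray,
    n_a: int,
    n_b: int,
    frac_b_near_a: float,
    radius: float = 3.0,
    n_c: int = 0,
    frac_c_at_coincidences: float = 0.0,
    seed: int = 0,
) -> dict:
    """Three point patterns with controlled pairwise and conditional structure.

    Channel A is uniform in the mask. A binomially chosen fraction
    ``frac_b_near_a`` of B points is placed uniformly within ``radius`` px
    of a random A point, the rest uniform. Of the realized A–B coincidence
    anchors, a fraction ``frac_c_at_coincidences`` of the ``n_c`` C points
    marks those anchor positions (within ``radius``); remaining C points are
    uniform. Returns a dict with the point arrays (y, x) and boolean ground
    truth labels ``b_is_coloc`` and ``c_at_coincidence``.
    """
    if not 0 <= frac_b_near_a <= 1 or not 0 <= frac_c_at_coincidences <= 1:
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a = random_points_in_mask(mask, n_a, rng)
    n_hit = rng.binomial(n_b, frac_b_near_a)
    b = np.empty((n_b, 2))
    b_lbl = np.zeros(n_b, bool)
    anchors_used = np.empty((n_hit, 2))
    for k in range(n_hit):
        ai = rng.integers(n_a)
        anchors_used[k] = a[ai]
        b[k] = _points_near_anchors(a[ai : ai + 1], 1, radius, mask, rng)[0]
        b_lbl[k] = True
    if n_b > n_hit:
        b[n_hit:] = random_points_in_mask(mask, n_b - n_hit, rng)
    c = np.empty((0, 2))
    c_lbl = np.zeros(n_c, bool)
    if n_c > 0:
        n_cond = min(rng.binomial(n_c, frac_c_at_coincidences), n_hit)
        parts = []
        if n_cond > 0:
            idx = rng.choice(n_hit, n_cond, replace=False)
            parts.append(_points_near_anchors(anchors_used[idx], n_cond, radius, mask, rng))
            c_lbl[:n_cond] = True
        if n_c - n_cond > 0:
            parts.append(random_points_in_mask(mask, n_c - n_cond, rng))
        c = np.vstack(parts)
    perm_b = rng.permutation(n_b)
    perm_c = rng.permutation(n_c)
    return {
        "A": a,
        "B": b[perm_b],
        "C": c[perm_c] if n_c else c,
        "b_is_coloc": b_lbl[perm_b],
        "c_at_coincidence": c_lbl[perm_c] if n_c else c_lbl,
        "mask": mask,
        "radius": radius,
    }


def generate_spot_image_set(spec: ImageSpec, seed: int = 0) -> dict:
    """Multichannel spot images with per-spot ground truth.

    Returns ``{"images": {name: 2-D float array}, "truth": {name: dict}, "mask": ...}``
    where each truth dict holds ``positions`` (y, x), ``amplitudes`` and — for
    channels with a colocalization plan — the boolean ``is_coloc`` labels.
    Deterministic per (spec, seed).
    """
    rng = np.random.default_rng(seed)
    mask = ellipse_mask(spec.size, spec.mask_margin)
    placed: dict[str, np.ndarray] = {}
    truth: dict[str, dict] = {}
    anchored = {ch: (anchor, frac) for (ch, anchor), frac in spec.coloc_plan.items()}
    for ch in spec.channels:
        if ch.name in anchored:
            anchor, frac = anchored[ch.name]
            if anchor not in placed:
                raise ValueError(
                    f"channel {ch.name!r} anchored to {anchor!r}, which must come first"
                )
            if len(placed[anchor]) == 0 and frac > 0:
                raise ValueError(f"coloc plan infeasible: anchor {anchor!r} has no spots")
            n_hit = rng.binomial(ch.n_spots, frac)
            pos = np.vstack(
                [
                    _points_near_anchors(placed[anchor], n_hit, spec.coloc_radius, mask, rng),
                    random_points_in_mask(mask, ch.n_spots - n_hit, rng),
                ]
            )
            lbl = np.zeros(ch.n_spots, bool)
            lbl[:n_hit] = True
            perm = rng.permutation(ch.n_spots)
            pos, lbl = pos[perm], lbl[perm]
        else:
            pos = random_points_in_mask(mask, ch.n_spots, rng)
            lbl = None
        placed[ch.name] = pos
        amps = ch.amp_median * np.exp(ch.amp_sigma * rng.standard_normal(ch.n_spots))
        truth[ch.name] = {"positions": pos, "amplitudes": amps}
        if lbl is not None:
            truth[ch.name]["is_coloc"] = lbl
    images = {}
    for ch in spec.channels:
        t = truth[ch.name]
        img = render_spots(spec.size, t["positions"], t["amplitudes"], ch.sigma, ch.background)
        if ch.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if ch.read_noise_sd > 0:
            img = img + rng.normal(0, ch.read_noise_sd, spec.size)
        images[ch.name] = img
    return {"images": images, "truth": truth, "mask": mask}


def generate_free_diffusion_tracks(spec: TrackSpec, seed: int = 0) -> np.ndarray:
    """Brownian tracks, shape ``(n_tracks, track_length, 2)`` in μm.

    Per-axis displacement variance per frame is ``2·D·interval``; independent
    Gaussian localization noise of SD ``loc_noise_sd`` is added to every
    stored position.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(
        0.0,
        np.sqrt(2 * spec.D * spec.interval),
        size=(spec.n_tracks, spec.track_length - 1, 2),
    )
    tracks = np.concatenate(
        [np.zeros((spec.n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
    )
    if spec.loc_noise_sd > 0:
        tracks = tracks + rng.normal(0, spec.loc_noise_sd, tracks.shape)
    return tracks
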