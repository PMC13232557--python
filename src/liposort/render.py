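"""Render ground-truth populations into calibrated confocal-like images.

Geometry follows the imaging setup the pipeline emulates: 512 x 512 px at
0.25 um/px (one 128 x 128 um FOV), 16-bit counts, 5 frames at 12-s
intervals for time-lapse runs.  Three channels are modelled:

* ``membrane``  -- membrane dye: an annulus of width 0.3 um at each vesicle
  radius, total signal proportional to circumference;
* ``protein``   -- the expressed fluorescent reporter: intensity split
  between the membrane annulus (weight m(t) x angular profile) and a
  uniform lumen disk (weight 1 - m(t)), zero for non-expressing vesicles;
* ``pamcherry`` -- the photoactivatable tag: a lumen disk at basal level,
  x20 once activated.

The ideal image is blurred with a Gaussian PSF (sigma 0.3 um), Poisson
photon noise is applied, Gaussian read noise and a constant camera offset
are added, and the result is clipped and quantized to 16 bits.  Per-vesicle
kernels are normalized to unit sum before scaling, so the total ideal
signal of a liposome is exactly independent of how it is split between
membrane and lumen (photon conservation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InputError
from .population import LiposomeState, brownian_step, membrane_fraction

__all__ = ["ImagingConfig", "FrameStack", "render_frame", "render_ideal", "render_video",
           "save_stack", "load_stack", "save_preview_png"]

CHANNELS = ("membrane", "protein", "pamcherry")

#: Activated-over-basal intensity contrast of the photoactivatable tag.
ACTIVATION_CONTRAST = 20.0


@dataclass
class ImagingConfig:
    """Physical calibration of the synthetic microscope."""

    fov_um: float = 128.0
    image_px: int = 512
    px_um: float = 0.25
    psf_sigma_um: float = 0.3
    channel_gains: dict = field(
        default_factory=lambda: {"membrane": 5000.0, "protein": 5000.0, "pamcherry": 200.0}
    )
    background_offset: float = 100.0
    read_noise_sd: float = 20.0
    frame_times_s: tuple = (0.0, 12.0, 24.0, 36.0, 48.0)
    bit_depth: int = 16
    annulus_width_um: float = 0.3

    def __post_init__(self):
        if abs(self.image_px * self.px_um - self.fov_um) > 1e-6:
            raise ConfigurationError("image_px * px_um must equal fov_um")
        if any(t2 <= t1 for t1, t2 in zip(self.frame_times_s, self.frame_times_s[1:])):
            raise ConfigurationError("frame_times must be strictly increasing")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1

    def to_dict(self) -> dict:
        return {
            "fov_um": self.fov_um,
            "image_px": self.image_px,
            "px_um": self.px_um,
            "psf_sigma_um": self.psf_sigma_um,
            "channel_gains": dict(self.channel_gains),
            "background_offset": self.background_offset,
            "read_noise_sd": self.read_noise_sd,
            "frame_times_s": list(self.frame_times_s),
            "bit_depth": self.bit_depth,
            "annulus_width_um": self.annulus_width_um,
        }


@dataclass
class FrameStack:
    """Per-FOV, per-channel, per-time image stack with its calibration.

    ``channels`` maps channel name to a (T, H, W) uint array.  ``truth``
    optionally keeps the per-frame ground-truth populations used to render
    each frame (handy for evaluating detection and tracking).
    """

    fov_id: int
    channels: dict
    calibration: ImagingConfig
    truth: list | None = None


def _pixel_grid(config, x0_px, x1_px, y0_px, y1_px):
    """Physical coordinates (um) of pixel centers for a patch, origin top-left.

    Pixel (row, col) has its center at ((col + 0.5) * px, (row + 0.5) * px).
    """
    px = config.px_um
    xs = (np.arange(x0_px, x1_px) + 0.5) * px
    ys = (np.arange(y0_px, y1_px) + 0.5) * px
    return np.meshgrid(xs, ys)


def _vesicle_kernels(lp: LiposomeState, config: ImagingConfig, profile=None):
    """Unit-sum lumen-disk and membrane-ring kernels on a local patch.

    Returns (y0, x0, disk, ring) where disk/ring are float arrays whose
    elements each sum to one; ring is weighted by the angular profile and
    by a Gaussian radial band of width ``annulus_width_um`` at the vesicle
    radius.  Normalization happens on the full (unclipped) kernel so that
    scaling by a total intensity conserves photons exactly.
    """
    px = config.px_um
    r = lp.radius_um
    cx, cy = lp.center_um
    pad = r + 3.0 * config.psf_sigma_um + 2 * px
    x0 = max(0, int((cx - pad) / px))
    x1 = min(config.image_px, int(math.ceil((cx + pad) / px)))
    y0 = max(0, int((cy - pad) / px))
    y1 = min(config.image_px, int(math.ceil((cy + pad) / px)))
    X, Y = _pixel_grid(config, x0, x1, y0, y1)
    dx, dy = X - cx, Y - cy
    rho = np.hypot(dx, dy)

    # lumen disk with a one-pixel anti-aliasing ramp at the rim
    disk = np.clip((r - rho) / px + 0.5, 0.0, 1.0)
    s = disk.sum()
    if s <= 0:
        disk = np.zeros_like(rho)
    else:
        disk = disk / s

    sigma_r = config.annulus_width_um / 2.0
    ring = np.exp(-0.5 * ((rho - r) / sigma_r) ** 2)
    if profile is not None:
        theta = np.arctan2(dy, dx) % (2.0 * math.pi)
        ring = ring * profile(theta)
    s = ring.sum()
    ring = ring / s if s > 0 else np.zeros_like(rho)
    return y0, x0, disk, ring


def render_ideal(
    population: Sequence[LiposomeState],
    config: ImagingConfig,
    channel: str,
    t: float = 0.0,
) -> np.ndarray:
    """Noise-free, PSF-free ideal photon image (float64, no offset)."""
    if channel not in CHANNELS:
        raise InputError(f"unknown channel {channel!r}")
    gain = float(config.channel_gains[channel])
    img = np.zeros((config.image_px, config.image_px))
    for lp in population:
        r = lp.radius_um
        if channel == "membrane":
            total = gain * (2.0 * math.pi * r)
            y0, x0, _disk, ring = _vesicle_kernels(lp, config, profile=None)
            patch = total * ring
        elif channel == "protein":
            # dark unless the vesicle expresses a fluorescent product
            if not lp.expressing or lp.genotype.phenotype == "none":
                continue
            m, profile = membrane_fraction(lp.osc, t)
            total = gain * (math.pi * r**2)
            y0, x0, disk, ring = _vesicle_kernels(lp, config, profile=profile)
            patch = total * ((1.0 - m) * disk + m * ring)
        else:  # pamcherry
            level = lp.pamcherry_basal * (ACTIVATION_CONTRAST if lp.activated else 1.0)
            total = gain * level * (math.pi * r**2)
            y0, x0, disk, _ring = _vesicle_kernels(lp, config, profile=None)
            patch = total * disk
        img[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]] += patch
    return img


def render_frame(
    population: Sequence[LiposomeState],
    config: ImagingConfig,
    channel: str,
    t: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one channel at time ``t`` to a 16-bit image.

    With ``rng=None`` the render is noiseless (PSF and offset only), which
    is the reference image used throughout the test oracles.
    """
    ideal = render_ideal(population, config, channel, t)
    blurred = gaussian_filter(ideal, sigma=config.psf_sigma_um / config.px_um, mode="constant")
    if rng is not None:
        signal = np.zeros_like(blurred)
        lit = blurred > 1e-3  # Poisson draws only where photons land
        signal[lit] = rng.poisson(blurred[lit])
        signal += rng.normal(0.0, config.read_noise_sd, size=signal.shape)
    else:
        signal = blurred
    out = signal + config.background_offset
    return np.clip(np.round(out), 0, config.max_count).astype(np.uint16)


def render_video(
    population: Sequence[LiposomeState],
    config: ImagingConfig,
    rng: np.random.Generator | None = None,
    channels: Sequence[str] = ("membrane", "protein"),
    fov_id: int = 0,
) -> FrameStack:
    """Render a multi-channel time-lapse (default 5 frames, 12-s spacing).

    Between frames, vesicle centers advance by Brownian steps and the
    oscillation phases advance with elapsed time (time enters
    ``membrane_fraction`` directly).  The per-frame ground-truth snapshots
    are stored on the returned stack.
    """
    times = config.frame_times_s
    snapshots: list[list[LiposomeState]] = []
    current = [
        LiposomeState(
            id=lp.id, genotype=lp.genotype, center_um=lp.center_um,
            diameter_um=lp.diameter_um, expressing=lp.expressing, osc=lp.osc,
            fov=lp.fov, pamcherry_basal=lp.pamcherry_basal, activated=lp.activated,
            diffusion_scale=lp.diffusion_scale,
        )
        for lp in population
    ]
    stacks = {ch: [] for ch in channels}
    prev_t = times[0]
    for k, t in enumerate(times):
        if k > 0:
            dt = t - prev_t
            for lp in current:
                if rng is not None and lp.diffusion_scale > 0:
                    lp.center_um = brownian_step(
                        lp.center_um, dt, lp.diffusion_scale, rng, fov_um=config.fov_um
                    )
        prev_t = t
        snapshots.append([
            LiposomeState(
                id=lp.id, genotype=lp.genotype, center_um=lp.center_um,
                diameter_um=lp.diameter_um, expressing=lp.expressing, osc=lp.osc,
                fov=lp.fov, pamcherry_basal=lp.pamcherry_basal, activated=lp.activated,
                diffusion_scale=lp.diffusion_scale,
            )
            for lp in current
        ])
        for ch in channels:
            stacks[ch].append(render_frame(current, config, ch, t, rng))
    return FrameStack(
        fov_id=fov_id,
        channels={ch: np.stack(stacks[ch]) for ch in channels},
        calibration=config,
        truth=snapshots,
    )


def save_stack(stack: FrameStack, tiff_path, sidecar_json=None) -> None:
    """Write a FrameStack as a multi-page TIFF (channel-major page order).

    Pages are ordered channel-major: all frames of the first channel, then
    all frames of the next, matching the ``channels`` key order recorded in
    the sidecar JSON alongside the calibration.
    """
    names = list(stack.channels.keys())
    pages = np.concatenate([stack.channels[ch] for ch in names], axis=0)
    tifffile.imwrite(tiff_path, pages, metadata={"axes": "QYX"})
    meta = {
        "fov_id": stack.fov_id,
        "channel_order": names,
        "frames_per_channel": int(next(iter(stack.channels.values())).shape[0]),
        "calibration": stack.calibration.to_dict(),
    }
    if sidecar_json is None:
        sidecar_json = str(tiff_path) + ".json"
    with open(sidecar_json, "w") as fh:
        json.dump(meta, fh, indent=2)


def load_stack(tiff_path, sidecar_json=None) -> FrameStack:
    """Read a FrameStack written by :func:`save_stack`."""
    if sidecar_json is None:
        sidecar_json = str(tiff_path) + ".json"
    with open(sidecar_json) as fh:
        meta = json.load(fh)
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    n = meta["frames_per_channel"]
    channels = {}
    for i, ch in enumerate(meta["channel_order"]):
        channels[ch] = pages[i * n : (i + 1) * n]
    cal = meta["calibration"]
    cal["frame_times_s"] = tuple(cal["frame_times_s"])
    config = ImagingConfig(**cal)
    return FrameStack(fov_id=meta["fov_id"], channels=channels, calibration=config)


def save_preview_png(image: np.ndarray, path, cmap: str = "magma") -> None:
    """Write a contrast-stretched preview PNG of one frame (docs helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = np.percentile(image, [1, 99.8])
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    ax.imshow(image, cmap=cmap, vmin=lo, vmax=max(hi, lo + 1))
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(path)
    plt.close(fig)
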