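"""Pseudo-experimental datasets and the spot signal-to-noise utility.

``generate_pseudo_experiment`` produces trajectory ensembles with the
statistical structure of a real single-molecule acquisition: a battery of
frame rates, photobleach-limited track durations (geometric frame survival,
truncated at the 10-frame acceptance floor), ~50 nm localization noise, and
optionally a mixture of diffusive populations.  Tracks carry their true
component label so recovery can be scored.

``render_spot`` / ``spot_snr`` implement the diffraction-limited spot model
and the box-sum SNR statistic, SNR = (I_s − I_b)/sqrt(σ_s² + σ_b²), with the
sums and variances taken over 9×9-pixel boxes on and beside the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .geometry import CellGeometry, Mode
from .simulate import (
    DEFAULT_FRAME_RATES,
    SimulationConfig,
    Trajectory,
    simulate_frames,
)

BOX = 9  # pixels per side of the SNR box


@dataclass(frozen=True)
class PopulationComponent:
    """One diffusive sub-population of a pseudo-experiment."""

    weight: float
    D: float  # μm²/s
    R_conf: float | None  # μm
    mode: Mode = Mode.CYLINDER_ONLY

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("component weight must lie in [0, 1]")
        object.__setattr__(self, "mode", Mode(self.mode))


@dataclass(frozen=True)
class PseudoExperimentConfig:
    population: tuple[PopulationComponent, ...]
    n_tracks_per_rate: int = 70
    frame_rates: tuple[float, ...] = DEFAULT_FRAME_RATES
    localization_sigma: float = 0.05  # μm per axis (~50 nm precision)
    bleach_mean_frames: float = 30.0  # geometric survival mean
    min_frames: int = 10
    seed: int = 0
    geometry: CellGeometry = field(default_factory=CellGeometry)
    internal_dt: float = 5e-4

    def __post_init__(self) -> None:
        object.__setattr__(self, "population", tuple(self.population))
        w = sum(c.weight for c in self.population)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {w}")
        if self.n_tracks_per_rate < 1:
            raise ValueError("n_tracks_per_rate must be at least 1")
        if self.bleach_mean_frames <= 0:
            raise ValueError("bleach_mean_frames must be positive")


def _truncated_geometric(
    mean: float, floor: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Geometric frame counts (support 1, 2, …) resampled until >= floor."""
    p = min(1.0, 1.0 / mean)
    out = rng.geometric(p, size=size)
    short = out < floor
    while short.any():
        out[short] = rng.geometric(p, size=int(short.sum()))
        short = out < floor
    return out


def generate_pseudo_experiment(
    config: PseudoExperimentConfig,
) -> dict[float, list[Trajectory]]:
    """Emulated observation: map frame rate → list of labeled trajectories."""
    weights = np.array([c.weight for c in config.population])
    root = np.random.SeedSequence(config.seed)
    out: dict[float, list[Trajectory]] = {}
    for rate, child in zip(config.frame_rates, root.spawn(len(config.frame_rates))):
        rng = np.random.default_rng(child)
        comp_idx = rng.choice(len(weights), size=config.n_tracks_per_rate, p=weights)
        lengths = _truncated_geometric(
            config.bleach_mean_frames, config.min_frames,
            config.n_tracks_per_rate, rng,
        )
        tracks: list[Trajectory] = [None] * config.n_tracks_per_rate  # type: ignore
        for ci, comp in enumerate(config.population):
            members = np.flatnonzero(comp_idx == ci)
            if members.size == 0:
                continue
            sim = SimulationConfig(
                D=comp.D,
                R_conf=comp.R_conf,
                internal_dt=config.internal_dt,
                frame_rates=(rate,),
                frames_per_track=max(config.min_frames, int(lengths[members].max())),
                n_traj=members.size,
                mode=comp.mode,
                geometry=config.geometry,
                localization_sigma=config.localization_sigma,
            )
            frames = simulate_frames(sim, rate, rng)
            for k, idx in enumerate(members):
                n = int(lengths[idx])
                tracks[idx] = Trajectory(
                    id=f"pseudo_r{rate:g}_t{idx}",
                    frame_rate=rate,
                    times=np.arange(n) / rate,
                    positions=frames[k, :n],
                    condition_label=f"component{ci}",
                    true_component=ci,
                )
        out[rate] = list(tracks)
    return out


# ---------------------------------------------------------------------------
# spot rendering and SNR


@dataclass
class SpotImage:
    """Pixelated fluorescent spot; intensities in counts."""

    pixels: np.ndarray  # (ny, nx), >= 9x9
    pixel_size: float = 0.05  # μm per pixel (~50 nm)
    center: tuple[float, float] = (0.0, 0.0)  # (row, col) of the spot

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < BOX:
            raise ValueError(f"image must be a 2-D grid of at least {BOX}x{BOX} pixels")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")


def render_spot(
    photons: float,
    psf_sigma: float,
    background_mean: float,
    background_noise: str = "poisson",
    rng: np.random.Generator | None = None,
    *,
    pixel_size: float = 0.05,
    shape: tuple[int, int] = (15, 15),
    center: tuple[float, float] | None = None,
) -> SpotImage:
    """Integrated-Gaussian spot plus background, with photon noise.

    ``photons`` is the expected total signal count, ``psf_sigma`` the Gaussian
    point-spread width in μm, ``background_mean`` the expected background per
    pixel.  Noise is Poisson (or Gaussian with matching variance).
    """
    if photons < 0:
        raise ValueError("photons must be non-negative")
    if background_noise not in ("poisson", "gaussian"):
        raise ValueError("background_noise must be 'poisson' or 'gaussian'")
    if rng is None:
        rng = np.random.default_rng()
    ny, nx = shape
    if center is None:
        center = ((ny - 1) / 2.0, (nx - 1) / 2.0)
    s = psf_sigma / pixel_size  # PSF width in pixels
    rows = np.arange(ny)
    cols = np.arange(nx)

    def pix_integral(coords: np.ndarray, c0: float) -> np.ndarray:
        lo = (coords - 0.5 - c0) / (math.sqrt(2.0) * s)
        hi = (coords + 0.5 - c0) / (math.sqrt(2.0) * s)
        return 0.5 * (erf(hi) - erf(lo))

    expected = photons * np.outer(pix_integral(rows, center[0]),
                                  pix_integral(cols, center[1]))
    expected = expected + background_mean
    if background_noise == "poisson":
        img = rng.poisson(expected).astype(float)
    else:
        img = expected + rng.normal(0.0, np.sqrt(np.maximum(expected, 0.0)))
        img = np.maximum(img, 0.0)
    return SpotImage(pixels=img, pixel_size=pixel_size, center=center)


def _box_slice(center: tuple[int, int], shape: tuple[int, int]) -> tuple[slice, slice]:
    h = BOX // 2
    r, c = center
    if r - h < 0 or c - h < 0 or r + h >= shape[0] or c + h >= shape[1]:
        raise ValueError(f"{BOX}x{BOX} box at {center} exceeds image bounds {shape}")
    return slice(r - h, r + h + 1), slice(c - h, c + h + 1)


def snr_from_sums(I_s: float, I_b: float, var_s: float, var_b: float) -> float:
    """SNR = (I_s − I_b) / sqrt(σ_s² + σ_b²)."""
    denom = var_s + var_b
    if denom <= 0:
        raise ValueError("zero total variance; SNR undefined")
    return (I_s - I_b) / math.sqrt(denom)


def spot_snr(
    image: SpotImage | list[SpotImage] | np.ndarray,
    signal_box_center: tuple[int, int],
    background_box_center: tuple[int, int],
) -> float:
    """Box-sum SNR of a spot against a neighboring background region.

    ``image`` may be a single :class:`SpotImage` (box-sum variances are then
    propagated from per-pixel shot noise, var = sum of counts) or a stack of
    frames (list of images or a 3-D array), in which case the variances of the
    box sums are estimated empirically across frames.  The two 9×9 boxes must
    lie inside the image and must not overlap.
    """
    if isinstance(image, SpotImage):
        stack = image.pixels[None, :, :]
        empirical = False
    else:
        if isinstance(image, np.ndarray):
            stack = np.asarray(image, dtype=float)
            if stack.ndim != 3:
                raise ValueError("array input must be a (frames, ny, nx) stack")
        else:
            stack = np.stack([im.pixels for im in image])
        empirical = stack.shape[0] > 1

    shape = stack.shape[1:]
    rs, cs = _box_slice(signal_box_center, shape)
    rb, cb = _box_slice(background_box_center, shape)
    dr = abs(signal_box_center[0] - background_box_center[0])
    dc = abs(signal_box_center[1] - background_box_center[1])
    if dr < BOX and dc < BOX and (dr, dc) != (0, 0):
        raise ValueError("signal and background boxes overlap")

    sums_s = stack[:, rs, cs].sum(axis=(1, 2))
    sums_b = stack[:, rb, cb].sum(axis=(1, 2))
    if empirical:
        var_s = float(np.var(sums_s, ddof=1))
        var_b = float(np.var(sums_b, ddof=1))
    else:  # single frame: shot-noise propagation, Var(sum) = sum of counts
        var_s = float(sums_s[0])
        var_b = float(sums_b[0])
    return snr_from_sums(float(sums_s.mean()), float(sums_b.mean()), var_s, var_b)
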