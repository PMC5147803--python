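"""Monte Carlo trajectories of confined surface diffusion through a blurring camera.

The walker's dynamics live in the tangent chart centered on its initial
position: Brownian increments with per-axis variance ``2·D·dt`` (mean-square
step ``4·D·dt``), reflected off the circular confinement boundary when one is
set, and mapped onto the curved cell surface through the origin's exponential
map.  The camera model averages the projected position over every frame period
(continuous-stream acquisition, no dead time) and then adds isotropic Gaussian
localization noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (
    CellGeometry,
    Mode,
    Region,
    SurfacePoint,
    _camera_from_cap_chart,
    _camera_from_cyl_chart,
    chart_to_surface,
)

log = logging.getLogger(__name__)

DEFAULT_FRAME_RATES = (1000.0, 400.0, 260.0, 120.0, 60.0)

STEP_MODELS = ("gaussian_components", "normal_length")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation condition: diffusion, confinement, and acquisition.

    Parameters
    ----------
    D : diffusion coefficient, μm²/s.
    R_conf : confinement radius in μm, or ``None`` for unconfined motion.
    internal_dt : internal Monte Carlo time step, s (default 0.5 ms).
    frame_rates : camera rates, Hz.
    frames_per_track : frames rendered per trajectory.
    n_traj : trajectories per frame rate.
    mode : ``cylinder_only`` restricts the walker (and its origin) to the
        cylindrical section with specular end reflections; ``whole_surface``
        samples origins over the entire cell and lets walkers cross onto caps.
    localization_sigma : per-axis Gaussian localization noise, μm (0 for
        noise-free model curves).
    step_model : ``gaussian_components`` draws independent Gaussian chart
        components (standard Brownian increments); ``normal_length`` draws a
        |half-normal| step length with uniform direction.  Both give the same
        mean-square step 4·D·dt.
    """

    D: float = 1.0
    R_conf: float | None = None
    internal_dt: float = 5e-4
    frame_rates: tuple[float, ...] = DEFAULT_FRAME_RATES
    frames_per_track: int = 30
    n_traj: int = 1000
    mode: Mode = Mode.CYLINDER_ONLY
    geometry: CellGeometry = field(default_factory=CellGeometry)
    localization_sigma: float = 0.0
    seed: int = 0
    step_model: str = "gaussian_components"

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.R_conf is not None and self.R_conf <= 0:
            raise ValueError("R_conf must be positive (or None for unconfined)")
        if self.internal_dt <= 0:
            raise ValueError("internal_dt must be positive")
        if self.n_traj < 1:
            raise ValueError("n_traj must be at least 1")
        if self.frames_per_track < 10:
            raise ValueError("frames_per_track must be >= 10 (track acceptance floor)")
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "frame_rates", tuple(float(r) for r in self.frame_rates))
        for rate in self.frame_rates:
            if 1.0 / rate < self.internal_dt:
                raise ValueError(
                    f"frame period 1/{rate} Hz is shorter than internal_dt"
                )
        if self.step_model not in STEP_MODELS:
            raise ValueError(f"step_model must be one of {STEP_MODELS}")


@dataclass
class Trajectory:
    """One molecule's camera-plane track at a single frame rate."""

    id: str
    frame_rate: float
    times: np.ndarray
    positions: np.ndarray  # (n_frames, 2) in μm
    condition_label: str = ""
    true_component: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        # the 10-consecutive-frame acceptance floor is enforced at the analysis
        # stage (msd module) and by the generators; the container just needs
        # enough frames to define a displacement
        if len(self.times) < 2:
            raise ValueError(f"track {self.id!r} has fewer than 2 frames")
        dt = np.diff(self.times)
        if not np.allclose(dt, 1.0 / self.frame_rate, rtol=1e-6, atol=1e-12):
            raise ValueError("frame spacing must be uniform at 1/frame_rate")

    @property
    def n_frames(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# chart-level dynamics


def _reflect_disc_inplace(p: np.ndarray, R: float) -> None:
    """Radial-mirror reflection of (n, 2) chart positions into |p| <= R."""
    rho = np.hypot(p[:, 0], p[:, 1])
    out = rho > R
    while out.any():
        p[out] *= ((2.0 * R - rho[out]) / rho[out])[:, None]
        rho[out] = np.abs(2.0 * R - rho[out])
        out = rho > R


def _chart_paths(
    n_traj: int,
    n_samples: int,
    dt: float,
    D: float,
    R_conf: float | None,
    rng: np.random.Generator,
    step_model: str = "gaussian_components",
) -> np.ndarray:
    """Reflected Brownian chart paths, shape (n_traj, n_samples, 2), origin at 0.

    Confinement uses the closed-form radial fold equivalent to repeated
    specular mirroring about the circle: the radius is a triangle wave of the
    unconstrained radius with period 4R (a negative fold value encodes passage
    through the center, flipping the direction).
    """
    out = np.zeros((n_traj, n_samples, 2))
    if D == 0.0 or n_samples == 1:
        return out
    if step_model == "gaussian_components":
        steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(n_samples - 1, n_traj, 2))
    else:
        length = np.abs(rng.normal(0.0, math.sqrt(4.0 * D * dt),
                                   size=(n_samples - 1, n_traj)))
        angle = rng.uniform(0.0, 2.0 * math.pi, size=(n_samples - 1, n_traj))
        steps = np.stack([length * np.cos(angle), length * np.sin(angle)], axis=-1)
    if R_conf is None:
        np.cumsum(steps, axis=0, out=steps)
        out[:, 1:] = steps.transpose(1, 0, 2)
        return out
    R = R_conf
    p = np.zeros((n_traj, 2))
    for i in range(n_samples - 1):
        p += steps[i]
        rho = np.hypot(p[:, 0], p[:, 1])
        m = rho > R
        if m.any():
            u = np.mod(rho[m] + R, 4.0 * R)
            p[m] *= ((R - np.abs(u - 2.0 * R)) / rho[m])[:, None]
        out[:, i + 1] = p
    return out


def _sample_origins(
    geometry: CellGeometry, mode: Mode, n: int, rng: np.random.Generator
) -> dict:
    """Vectorized area-uniform origin sampling; returns chart arrays."""
    if mode is Mode.CYLINDER_ONLY:
        on_cap = np.zeros(n, dtype=bool)
    else:
        p_cap = geometry.cap_area / (geometry.cap_area + geometry.cylinder_area)
        on_cap = rng.random(n) < p_cap
    x0 = np.zeros(n)
    phi0 = np.zeros(n)
    u0 = np.zeros((n, 3))
    side_right = np.zeros(n, dtype=bool)
    n_cyl = int((~on_cap).sum())
    x0[~on_cap] = rng.uniform(0.0, geometry.cylinder_length, size=n_cyl)
    phi0[~on_cap] = rng.uniform(0.0, 2.0 * math.pi, size=n_cyl)
    n_cap = int(on_cap.sum())
    if n_cap:
        u = rng.normal(size=(n_cap, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        right = rng.random(n_cap) < 0.5
        u[:, 0] = np.where(right, np.abs(u[:, 0]), -np.abs(u[:, 0]))
        u0[on_cap] = u
        side_right[on_cap] = right
    return {"on_cap": on_cap, "x0": x0, "phi0": phi0, "u0": u0, "side_right": side_right}


def _chart_to_camera_batch(
    origins: dict, UV: np.ndarray, geometry: CellGeometry, mode: Mode
) -> np.ndarray:
    """Map (n, T, 2) chart displacements about per-trajectory origins to camera."""
    n, T, _ = UV.shape
    cam = np.empty((n, T, 2))
    cyl = ~origins["on_cap"]
    if cyl.any():
        x, y = _camera_from_cyl_chart(
            origins["x0"][cyl], origins["phi0"][cyl],
            UV[cyl, :, 0], UV[cyl, :, 1], geometry, mode,
        )
        cam[cyl, :, 0], cam[cyl, :, 1] = x, y
    cap = origins["on_cap"]
    if cap.any():
        x, y = _camera_from_cap_chart(
            origins["u0"][cap], origins["side_right"][cap],
            UV[cap, :, 0], UV[cap, :, 1], geometry,
        )
        cam[cap, :, 0], cam[cap, :, 1] = x, y
    return cam


def n_substeps(frame_rate: float, internal_dt: float) -> int:
    """Samples averaged per frame: round(period/dt), with the substep rescaled
    to period/n so every frame averages an integer number of positions."""
    period = 1.0 / frame_rate
    if period < internal_dt:
        raise ValueError("frame period is shorter than the internal time step")
    return max(1, round(period / internal_dt))


def planar_origins(n: int, geometry: CellGeometry) -> dict:
    """Origins at the cylinder mid-line facing the camera (azimuth 0).

    With a very large cell radius this realizes the planar-diffusion limit in
    which orthographic projection is the identity near the origin — the setup
    for free-diffusion oracle checks, where uniform azimuths would instead
    foreshorten circumferential displacements.
    """
    return {
        "on_cap": np.zeros(n, dtype=bool),
        "x0": np.full(n, geometry.cylinder_length / 2.0),
        "phi0": np.zeros(n),
        "u0": np.zeros((n, 3)),
        "side_right": np.zeros(n, dtype=bool),
    }


def simulate_frames(
    config: SimulationConfig,
    frame_rate: float,
    rng: np.random.Generator,
    frames_per_track: np.ndarray | int | None = None,
    origins: dict | None = None,
) -> np.ndarray:
    """Vectorized engine: camera-frame positions for ``n_traj`` walkers.

    Returns an array (n_traj, n_frames, 2) where ``n_frames`` is the maximum of
    ``frames_per_track`` (tracks meant to be shorter are cropped by the caller).
    Draw order (origins, then steps, then noise) is fixed, so one seed yields
    one stream of standard normals shared by every (D, R_conf) condition.
    """
    if frames_per_track is None:
        frames_per_track = config.frames_per_track
    n_frames = int(np.max(frames_per_track))
    n_sub = n_substeps(frame_rate, config.internal_dt)
    dt_eff = (1.0 / frame_rate) / n_sub
    if origins is None:
        origins = _sample_origins(config.geometry, config.mode, config.n_traj, rng)
    chart = _chart_paths(
        config.n_traj, n_frames * n_sub, dt_eff, config.D, config.R_conf, rng,
        config.step_model,
    )
    cam = _chart_to_camera_batch(origins, chart, config.geometry, config.mode)
    frames = cam.reshape(config.n_traj, n_frames, n_sub, 2).mean(axis=2)
    if config.localization_sigma > 0:
        frames = frames + rng.normal(
            0.0, config.localization_sigma, size=frames.shape
        )
    return frames


# ---------------------------------------------------------------------------
# spec-level operations


def simulate_internal_track(
    config: SimulationConfig, rng: np.random.Generator
) -> list[SurfacePoint]:
    """One walker's surface positions at ``internal_dt`` spacing.

    The track covers the longest frame period times ``frames_per_track``.
    """
    from .geometry import sample_uniform_point

    longest = 1.0 / min(config.frame_rates)
    n_samples = max(2, math.ceil(longest * config.frames_per_track / config.internal_dt))
    origin = sample_uniform_point(config.geometry, rng, config.mode)
    chart = _chart_paths(
        1, n_samples, config.internal_dt, config.D, config.R_conf, rng,
        config.step_model,
    )[0]
    return [
        chart_to_surface(origin, uv, config.geometry, config.mode) for uv in chart
    ]


def apply_camera(
    internal_track,
    frame_rate: float,
    localization_sigma: float,
    rng: np.random.Generator,
    *,
    internal_dt: float = 5e-4,
    geometry: CellGeometry | None = None,
    track_id: str = "track0",
    condition_label: str = "",
) -> Trajectory:
    """Render an internal track through the finite-exposure camera.

    ``internal_track`` is either a sequence of :class:`SurfacePoint` (projected
    orthographically first) or an (N, 2) array of camera positions sampled at
    ``internal_dt``.  Each frame is the arithmetic mean of the
    ``round(period/internal_dt)`` positions inside its period; localization
    noise is added after averaging.
    """
    if geometry is None:
        geometry = CellGeometry()
    if isinstance(internal_track, np.ndarray):
        cam = np.asarray(internal_track, dtype=float)
    else:
        cam = np.array([p.to_xyz(geometry)[:2] for p in internal_track])
    n_sub = n_substeps(frame_rate, internal_dt)
    n_frames = len(cam) // n_sub
    if n_frames < 2:
        raise ValueError(
            f"internal track too short: {len(cam)} samples give {n_frames} frames"
        )
    frames = cam[: n_frames * n_sub].reshape(n_frames, n_sub, 2).mean(axis=1)
    if localization_sigma > 0:
        frames = frames + rng.normal(0.0, localization_sigma, size=frames.shape)
    return Trajectory(
        id=track_id,
        frame_rate=frame_rate,
        times=np.arange(n_frames) / frame_rate,
        positions=frames,
        condition_label=condition_label,
    )


def simulate_condition(config: SimulationConfig) -> dict[float, list[Trajectory]]:
    """Simulate ``n_traj`` trajectories at every configured frame rate.

    Reproducible: the seed is split into one independent stream per frame rate,
    so the same config yields identical output and two configs differing only
    in (D, R_conf) share their underlying random draws (common random numbers,
    which keeps chi-squared fitting surfaces smooth across a parameter grid).
    """
    root = np.random.SeedSequence(config.seed)
    out: dict[float, list[Trajectory]] = {}
    for rate, child in zip(config.frame_rates, root.spawn(len(config.frame_rates))):
        rng = np.random.default_rng(child)
        frames = simulate_frames(config, rate, rng)
        times = np.arange(config.frames_per_track) / rate
        out[rate] = [
            Trajectory(
                id=f"sim_r{rate:g}_t{i}",
                frame_rate=rate,
                times=times,
                positions=frames[i],
                condition_label=f"D={config.D:g},R={config.R_conf}",
            )
            for i in range(config.n_traj)
        ]
    return out


# ---------------------------------------------------------------------------
# tabular I/O

_COLUMNS = ["track_id", "frame_rate_hz", "frame", "time_s", "x_um", "y_um", "condition"]


def trajectories_to_frame(tracks_by_rate: dict[float, list[Trajectory]]) -> pd.DataFrame:
    rows = []
    for rate in sorted(tracks_by_rate, reverse=True):
        for tr in tracks_by_rate[rate]:
            n = tr.n_frames
            df = pd.DataFrame(
                {
                    "track_id": tr.id,
                    "frame_rate_hz": tr.frame_rate,
                    "frame": np.arange(n),
                    "time_s": tr.times,
                    "x_um": tr.positions[:, 0],
                    "y_um": tr.positions[:, 1],
                    "condition": tr.condition_label,
                }
            )
            if tr.true_component is not None:
                df["true_component"] = tr.true_component
            rows.append(df)
    if not rows:
        raise ValueError("no trajectories to write")
    return pd.concat(rows, ignore_index=True)


def write_trajectories(tracks_by_rate: dict[float, list[Trajectory]], path) -> None:
    """Comma-separated trajectory table with a header row (UTF-8)."""
    trajectories_to_frame(tracks_by_rate).to_csv(path, index=False)


def read_trajectories(path) -> dict[float, list[Trajectory]]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # surface the offending file and reason
        raise ValueError(f"cannot parse trajectory file {path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} lacks columns {missing}")
    out: dict[float, list[Trajectory]] = {}
    for (rate, tid), grp in df.groupby(["frame_rate_hz", "track_id"], sort=False):
        grp = grp.sort_values("frame")
        tr = Trajectory(
            id=str(tid),
            frame_rate=float(rate),
            times=grp["time_s"].to_numpy(),
            positions=grp[["x_um", "y_um"]].to_numpy(),
            condition_label=str(grp["condition"].iloc[0]),
            true_component=(
                int(grp["true_component"].iloc[0])
                if "true_component" in grp.columns
                else None
            ),
        )
        out.setdefault(float(rate), []).append(tr)
    return out
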