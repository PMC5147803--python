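"""Mean-square displacement curves: per-track, ensemble, and multi-rate stitching.

A combined MSD curve spans milliseconds to seconds by merging per-rate ensemble
curves: the fastest rate is anchored so that the ordinary-least-squares
intercept through its first few points is zero, and each slower curve is
shifted by the constant that best matches it to the already-combined curve on
overlapping delays.  Shifts only remove per-rate offsets (localization-noise
floors, blur offsets); the shape of each curve is untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trajectory

log = logging.getLogger(__name__)

MIN_TRACK_FRAMES = 10
#: rates slower than this are kept for display but excluded from fitting
MIN_FIT_RATE_HZ = 60.0


@dataclass
class MSDCurve:
    """Ensemble (or single-track) MSD vs. delay at one frame rate."""

    frame_rate: float
    delays: np.ndarray  # s, strictly increasing multiples of 1/frame_rate
    msd: np.ndarray  # μm²
    sem: np.ndarray  # μm²
    n_tracks: int = 1

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.delays) == len(self.msd) == len(self.sem)):
            raise ValueError("delays, msd and sem must have equal length")
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError("delays must be strictly increasing")
        if np.any(self.msd < 0) or np.any(self.sem < 0):
            raise ValueError("msd and sem must be non-negative")


@dataclass
class CombinedMSD:
    """Single MSD curve stitched over all frame rates."""

    delays: np.ndarray
    msd: np.ndarray
    sem: np.ndarray
    source_rate: np.ndarray  # Hz of the curve each point came from
    shifts_applied: dict[float, float] = field(default_factory=dict)  # μm² per rate

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        self.source_rate = np.asarray(self.source_rate, dtype=float)
        if np.any(np.diff(self.delays) < 0):
            raise ValueError("combined delays must be sorted")

    def points_for_rate(self, rate: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = self.source_rate == rate
        return self.delays[m], self.msd[m], self.sem[m]


@dataclass(frozen=True)
class LinearFit:
    """Short-time linear MSD model ⟨r²⟩ = 4·D·t + δ²."""

    D: float  # μm²/s
    delta_sq: float  # μm², intercept from finite localization precision
    n_points: int

    @property
    def localization_precision(self) -> float | None:
        """Per-axis precision σ = sqrt(δ²/4); defined only for δ² ≥ 0."""
        if self.delta_sq < 0:
            return None
        return float(np.sqrt(self.delta_sq / 4.0))


@dataclass(frozen=True)
class PlateauEstimate:
    """Confinement size from the long-delay MSD plateau via L² = 3·⟨r²⟩_plateau."""

    detected: bool
    plateau: float | None = None  # μm²
    L: float | None = None  # confinement diameter, μm
    R: float | None = None  # confinement radius, μm


class TrackTooShortError(ValueError):
    pass


# ---------------------------------------------------------------------------


def trajectory_msd(traj: Trajectory, max_delay_frames: int | None = None) -> MSDCurve:
    """Time-averaged MSD of one track over all start frames.

    ``msd[n-1]`` is the mean over all frame pairs ``(i, i+n)`` of the squared
    2-D displacement, for delays ``n/frame_rate``.  ``max_delay_frames``
    defaults to one third of the track length (variance control).
    """
    n_frames = traj.n_frames
    if n_frames < MIN_TRACK_FRAMES:
        raise TrackTooShortError(
            f"track {traj.id!r}: {n_frames} frames < {MIN_TRACK_FRAMES}"
        )
    if max_delay_frames is None:
        max_delay_frames = max(1, n_frames // 3)
    max_delay_frames = min(max_delay_frames, n_frames - 1)
    pos = traj.positions
    vals = np.empty(max_delay_frames)
    for n in range(1, max_delay_frames + 1):
        d = pos[n:] - pos[:-n]
        vals[n - 1] = np.mean(np.sum(d * d, axis=1))
    delays = np.arange(1, max_delay_frames + 1) / traj.frame_rate
    return MSDCurve(
        frame_rate=traj.frame_rate,
        delays=delays,
        msd=vals,
        sem=np.zeros(max_delay_frames),
        n_tracks=1,
    )


def ensemble_msd(
    tracks: list[Trajectory],
    max_delay_frames: int | None = None,
    per_track_third: bool = False,
    min_tracks_per_delay: int = 1,
) -> MSDCurve:
    """Unweighted average of per-track MSD values across an ensemble.

    All tracks must share one frame rate.  At each delay the mean runs over the
    tracks long enough to contribute; the standard error is the sample standard
    deviation across those tracks divided by sqrt(count).

    ``per_track_third`` applies the variance-control rule per track: a track
    contributes delays only up to one third of its own length (appropriate for
    bleach-limited data with heterogeneous durations).  Delays with fewer than
    ``min_tracks_per_delay`` contributing tracks are dropped.
    """
    if not tracks:
        raise ValueError("ensemble_msd needs at least one track")
    rates = {t.frame_rate for t in tracks}
    if len(rates) != 1:
        raise ValueError(f"mixed frame rates in ensemble: {sorted(rates)}")
    rate = tracks[0].frame_rate

    accepted = []
    for t in tracks:
        if t.n_frames < MIN_TRACK_FRAMES:
            log.info("rejecting track %s: %d frames < %d", t.id, t.n_frames,
                     MIN_TRACK_FRAMES)
            continue
        accepted.append(t)
    if not accepted:
        raise ValueError("no track meets the 10-frame acceptance floor")

    if max_delay_frames is None:
        max_delay_frames = max(1, max(t.n_frames for t in accepted) // 3)
    per_track = []
    for t in accepted:
        cap = max(1, t.n_frames // 3) if per_track_third else max_delay_frames
        c = trajectory_msd(t, min(cap, max_delay_frames))
        row = np.full(max_delay_frames, np.nan)
        row[: len(c.msd)] = c.msd
        per_track.append(row)
    arr = np.array(per_track)  # (n_tracks, max_delay)
    counts = np.sum(~np.isnan(arr), axis=0)
    keep = counts >= max(1, min_tracks_per_delay)
    if not keep.any():
        raise ValueError("no delay has enough contributing tracks")
    mean = np.nanmean(arr[:, keep], axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(arr[:, keep], axis=0, ddof=1)
    sd = np.where(counts[keep] > 1, sd, 0.0)
    sem = sd / np.sqrt(counts[keep])
    delays = (np.arange(1, max_delay_frames + 1) / rate)[keep]
    return MSDCurve(frame_rate=rate, delays=delays, msd=mean, sem=sem,
                    n_tracks=len(accepted))


def ensemble_msd_from_frames(
    frames: np.ndarray,
    frame_rate: float,
    max_delay_frames: int | None = None,
    lengths: np.ndarray | None = None,
) -> MSDCurve:
    """Array-path ensemble MSD, equivalent to per-track :func:`trajectory_msd`
    followed by :func:`ensemble_msd` but vectorized over an (n_traj, n_frames,
    2) position array.  ``lengths`` crops individual tracks (pairs beyond a
    track's length are excluded); tracks shorter than 10 frames are dropped.
    """
    import warnings

    frames = np.asarray(frames, dtype=float)
    n_traj, n_frames, _ = frames.shape
    if lengths is not None:
        lengths = np.asarray(lengths)
        keep = lengths >= MIN_TRACK_FRAMES
        if not keep.all():
            log.info("rejecting %d tracks below the %d-frame floor",
                     int((~keep).sum()), MIN_TRACK_FRAMES)
        frames = frames[keep].copy()
        lengths = lengths[keep]
        if frames.shape[0] == 0:
            raise ValueError("no track meets the 10-frame acceptance floor")
        mask = np.arange(n_frames)[None, :] >= lengths[:, None]
        frames[mask] = np.nan
    if n_frames < MIN_TRACK_FRAMES:
        raise ValueError(f"tracks have {n_frames} frames < {MIN_TRACK_FRAMES}")
    if max_delay_frames is None:
        max_delay_frames = max(1, n_frames // 3)
    max_delay_frames = min(max_delay_frames, n_frames - 1)

    means, sems = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for n in range(1, max_delay_frames + 1):
            d = frames[:, n:, :] - frames[:, :-n, :]
            sq = d[..., 0] ** 2 + d[..., 1] ** 2
            per_track = np.nanmean(sq, axis=1)
            ok = ~np.isnan(per_track)
            m = int(ok.sum())
            means.append(float(np.mean(per_track[ok])))
            sems.append(
                float(np.std(per_track[ok], ddof=1) / np.sqrt(m)) if m > 1 else 0.0
            )
    return MSDCurve(
        frame_rate=frame_rate,
        delays=np.arange(1, max_delay_frames + 1) / frame_rate,
        msd=np.array(means),
        sem=np.array(sems),
        n_tracks=frames.shape[0],
    )


def combine_rates(curves: list[MSDCurve], anchor_points: int = 6) -> CombinedMSD:
    """Stitch per-rate MSD curves (fastest → slowest) into one combined curve.

    The fastest curve is shifted so the OLS intercept through its first
    ``anchor_points`` points is zero; each slower curve is then shifted by the
    constant minimizing the summed squared difference to the already-combined
    curve, evaluated at the slower curve's delays that fall inside the combined
    delay range (combined values linearly interpolated there).
    """
    if not curves:
        raise ValueError("no curves to combine")
    curves = sorted(curves, key=lambda c: -c.frame_rate)
    if len({c.frame_rate for c in curves}) != len(curves):
        raise ValueError("duplicate frame rates among curves")
    first = curves[0]
    if len(first.delays) < anchor_points:
        raise ValueError(
            f"fastest curve has {len(first.delays)} points; need {anchor_points} "
            "for the anchor regression"
        )
    slope, intercept = np.polyfit(first.delays[:anchor_points],
                                  first.msd[:anchor_points], 1)
    shifts = {first.frame_rate: -float(intercept)}

    delays = list(first.delays)
    msd = list(first.msd - intercept)
    sem = list(first.sem)
    src = [first.frame_rate] * len(first.delays)

    for cur in curves[1:]:
        d = np.array(delays)
        m = np.array(msd)
        order = np.argsort(d, kind="stable")
        d, m = d[order], m[order]
        inside = (cur.delays >= d[0]) & (cur.delays <= d[-1])
        if not inside.any():
            raise ValueError(
                f"no delay overlap between the combined curve (≤ {d[-1]:g} s) "
                f"and the {cur.frame_rate:g} Hz curve (from {cur.delays[0]:g} s)"
            )
        ref = np.interp(cur.delays[inside], d, m)
        shift = float(np.mean(ref - cur.msd[inside]))
        shifts[cur.frame_rate] = shift
        delays.extend(cur.delays)
        msd.extend(cur.msd + shift)
        sem.extend(cur.sem)
        src.extend([cur.frame_rate] * len(cur.delays))

    order = np.argsort(np.array(delays), kind="stable")
    return CombinedMSD(
        delays=np.array(delays)[order],
        msd=np.array(msd)[order],
        sem=np.array(sem)[order],
        source_rate=np.array(src)[order],
        shifts_applied=shifts,
    )


def fit_linear_msd(curve: MSDCurve | CombinedMSD, n_points: int = 6) -> LinearFit:
    """OLS of the first ``n_points`` of the curve against ⟨r²⟩ = 4Dt + δ²."""
    if n_points < 2:
        raise ValueError("need at least two points for a linear fit")
    t = curve.delays[:n_points]
    y = curve.msd[:n_points]
    if np.any(t < 0):
        raise ValueError("negative delays")
    if len(t) < n_points:
        raise ValueError(f"curve has only {len(t)} points, need {n_points}")
    slope, intercept = np.polyfit(t, y, 1)
    return LinearFit(D=float(slope / 4.0), delta_sq=float(intercept),
                     n_points=n_points)


def confinement_from_plateau(
    curve: MSDCurve | CombinedMSD, rel_slope_threshold: float = 0.15
) -> PlateauEstimate:
    """Confinement size from the saturated MSD via the ⟨r²⟩ = L²/3 relation.

    The plateau level is the mean of the last quartile of points.  A plateau
    is declared when the OLS slope over that quartile, multiplied by its delay
    span, is below ``rel_slope_threshold`` of the plateau level (i.e. the curve
    rises by < 15% of its level across the final quartile).

    Note the L²/3 relation is exact for square confinement domains of side L;
    for circular domains of radius R the equilibrium plateau is R², so this
    printed rule systematically maps a disc plateau to L = √3·R (the quoted
    convention is kept here because it is the field's standard quick-look
    formula; the simulation-based grid fit does not use it).
    """
    n = len(curve.delays)
    q = max(2, n // 4)
    t = curve.delays[-q:]
    y = curve.msd[-q:]
    plateau = float(np.mean(y))
    slope = float(np.polyfit(t, y, 1)[0])
    span = float(t[-1] - t[0])
    if plateau > 0 and abs(slope) * span > rel_slope_threshold * plateau:
        log.warning("no plateau detected: relative rise %.3f over last quartile",
                    abs(slope) * span / plateau)
        return PlateauEstimate(detected=False)
    L = float(np.sqrt(3.0 * plateau))
    return PlateauEstimate(detected=True, plateau=plateau, L=L, R=L / 2.0)


# ---------------------------------------------------------------------------
# tabular I/O (tab-separated, header required)


def write_combined_msd(curve: CombinedMSD, path) -> None:
    df = pd.DataFrame(
        {
            "delay_s": curve.delays,
            "msd_um2": curve.msd,
            "sem_um2": curve.sem,
            "frame_rate_hz": curve.source_rate,
            "shift_um2": [curve.shifts_applied.get(r, 0.0) for r in curve.source_rate],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_combined_msd(path) -> CombinedMSD:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"cannot parse MSD file {path}: {exc}") from exc
    required = ["delay_s", "msd_um2", "sem_um2", "frame_rate_hz", "shift_um2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"MSD file {path} lacks columns {missing}")
    shifts = {
        float(r): float(g["shift_um2"].iloc[0])
        for r, g in df.groupby("frame_rate_hz")
    }
    return CombinedMSD(
        delays=df["delay_s"].to_numpy(),
        msd=df["msd_um2"].to_numpy(),
        sem=df["sem_um2"].to_numpy(),
        source_rate=df["frame_rate_hz"].to_numpy(),
        shifts_applied=shifts,
    )


def write_msd_curve(curve: MSDCurve, path) -> None:
    df = pd.DataFrame(
        {
            "delay_s": curve.delays,
            "msd_um2": curve.msd,
            "sem_um2": curve.sem,
            "frame_rate_hz": curve.frame_rate,
            "shift_um2": 0.0,
        }
    )
    df.to_csv(path, sep="\t", index=False)
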