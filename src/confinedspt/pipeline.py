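"""End-to-end recipes: tracks → combined MSD → grid fit / mixture fit.

These functions wire the stage modules together the way an analysis session
would: build per-rate ensemble MSD curves (rates below 60 Hz are ingested but
excluded from fitting), stitch them into a combined curve, and fit either the
confinement model on a coarse-then-refined (D, R) grid or the two-population
mixture model against standard curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .fit import FitResult, MixtureFit, grid_fit, mixture_fit, model_curves
from .geometry import CellGeometry, Mode
from .msd import MIN_FIT_RATE_HZ, CombinedMSD, combine_rates, ensemble_msd
from .simulate import DEFAULT_FRAME_RATES, SimulationConfig, Trajectory
from .synthetic_data import (
    PopulationComponent,
    PseudoExperimentConfig,
    generate_pseudo_experiment,
)

log = logging.getLogger(__name__)

#: condition-agnostic coarse search grid: ~20% multiplicative steps in D
DEFAULT_COARSE_D = tuple(np.round(1.2 ** np.arange(22), 6))  # 1.0 … 46 μm²/s
#: 0.02 μm steps in confinement radius
DEFAULT_COARSE_R = tuple(np.round(np.arange(0.10, 0.3401, 0.02), 6))

#: cap on per-rate MSD delays used in fitting; individual observed tracks
#: contribute delays only up to one third of their own length
MAX_DELAY_FRAMES = 20
#: observed ensemble delays need this many contributing tracks to be kept
MIN_TRACKS_PER_DELAY = 8
#: the mixture decomposition uses a shorter window where per-track statistics
#: are dense (every accepted track spans 10 frame delays), which keeps the
#: ensemble noise at each point well characterized; the confinement grid fit
#: benefits from the longer window's plateau-level information instead
MIXTURE_MAX_DELAY_FRAMES = 10
ANCHOR_POINTS = 6


def combined_msd_from_tracks(
    tracks_by_rate: dict[float, list[Trajectory]],
    min_fit_rate: float = MIN_FIT_RATE_HZ,
    max_delay_frames: int = MAX_DELAY_FRAMES,
    anchor_points: int = ANCHOR_POINTS,
    per_track_third: bool = True,
    min_tracks_per_delay: int = MIN_TRACKS_PER_DELAY,
) -> CombinedMSD:
    """Per-rate ensemble MSDs stitched into one combined curve.

    Rates slower than ``min_fit_rate`` are dropped (with a log line) before
    stitching, mirroring the detailed-analysis convention of using 60 Hz and
    faster only.
    """
    used, dropped = [], []
    for rate in sorted(tracks_by_rate, reverse=True):
        if rate < min_fit_rate:
            dropped.append(rate)
            continue
        used.append(ensemble_msd(tracks_by_rate[rate], max_delay_frames,
                                 per_track_third=per_track_third,
                                 min_tracks_per_delay=min_tracks_per_delay))
    if dropped:
        log.info("excluding %d rate(s) below %g Hz from fitting: %s",
                 len(dropped), min_fit_rate, dropped)
    if not used:
        raise ValueError("no frame rate at or above the fitting threshold")
    return combine_rates(used, anchor_points=anchor_points)


def refine_grid(
    D_best: float, R_best: float,
    D_factor: float = 1.2, n_D: int = 9,
    R_half_width: float = 0.02, n_R: int = 11,
) -> tuple[np.ndarray, np.ndarray]:
    """Fine grid centered on a coarse minimum: one coarse D step re-divided
    (±20% in 9 log steps) and ±0.02 μm in R."""
    D_fine = D_best * D_factor ** np.linspace(-1.0, 1.0, n_D)
    R_fine = R_best + np.linspace(-R_half_width, R_half_width, n_R)
    R_fine = R_fine[R_fine > 0.02]
    return np.round(D_fine, 9), np.round(R_fine, 9)


def fit_combined(
    observed: CombinedMSD,
    sim_template: SimulationConfig,
    D_grid=DEFAULT_COARSE_D,
    R_grid=DEFAULT_COARSE_R,
    refine: bool = True,
    model_cache: dict | None = None,
    shift_mode: str = "common",
    max_refine_stages: int = 4,
) -> FitResult:
    """Coarse grid fit refined around the minimum.

    The fine grid is re-centered and re-evaluated while its minimum keeps
    landing on the fine-grid boundary (up to ``max_refine_stages`` times), so
    the returned optimum is interior whenever the surface has an interior
    minimum within reach.
    """
    if model_cache is None:
        model_cache = {}
    result = grid_fit(observed, np.asarray(D_grid), np.asarray(R_grid),
                      sim_template, model_cache, max_delay_frames=MAX_DELAY_FRAMES,
                      shift_mode=shift_mode)
    if not refine:
        return result
    for stage in range(max_refine_stages):
        D_fine, R_fine = refine_grid(result.D_best, result.R_best)
        result = grid_fit(observed, D_fine, R_fine, sim_template, model_cache,
                          max_delay_frames=MAX_DELAY_FRAMES, shift_mode=shift_mode)
        if not result.on_boundary:
            break
        log.info("refinement stage %d ended on the grid boundary at "
                 "(D=%.3g, R=%.3g); re-centering", stage + 1, result.D_best,
                 result.R_best)
    return result


@dataclass
class RecoveryResult:
    """Outcome of a generate → analyze → fit self-consistency run."""

    D_true: float
    R_true: float
    fit: FitResult
    observed: CombinedMSD

    @property
    def D_recovered(self) -> float:
        return self.fit.D_best

    @property
    def R_recovered(self) -> float:
        return self.fit.R_best


def recover_condition(
    D: float,
    R_conf: float,
    mode: Mode | str,
    seed: int,
    n_tracks_per_rate: int = 70,
    frame_rates: tuple[float, ...] = DEFAULT_FRAME_RATES,
    localization_sigma: float = 0.05,
    geometry: CellGeometry | None = None,
    model_seed: int = 20160862,
    model_n_traj: int = 1000,
    model_cache: dict | None = None,
    refine: bool = True,
) -> RecoveryResult:
    """Full pipeline self-consistency run at one generating condition.

    A pseudo-experiment is generated at (D, R_conf), reduced to a combined MSD,
    and fitted on the default coarse-then-fine grid.  ``model_seed`` fixes the
    common-random-number stream of the model curves, independent of the
    pseudo-experiment seed.
    """
    mode = Mode(mode)
    if geometry is None:
        geometry = CellGeometry()
    pcfg = PseudoExperimentConfig(
        population=(PopulationComponent(1.0, D, R_conf, mode),),
        n_tracks_per_rate=n_tracks_per_rate,
        frame_rates=frame_rates,
        localization_sigma=localization_sigma,
        seed=seed,
        geometry=geometry,
    )
    tracks = generate_pseudo_experiment(pcfg)
    observed = combined_msd_from_tracks(tracks)
    template = SimulationConfig(
        frame_rates=frame_rates,
        n_traj=model_n_traj,
        mode=mode,
        geometry=geometry,
        seed=model_seed,
    )
    fit = fit_combined(observed, template, model_cache=model_cache, refine=refine)
    return RecoveryResult(D_true=D, R_true=R_conf, fit=fit, observed=observed)


def standard_combined_msd(
    D: float,
    R_conf: float,
    mode: Mode | str,
    seed: int = 20160862,
    n_traj: int = 1000,
    frame_rates: tuple[float, ...] = DEFAULT_FRAME_RATES,
    geometry: CellGeometry | None = None,
    max_delay_frames: int = MIXTURE_MAX_DELAY_FRAMES,
) -> CombinedMSD:
    """Noise-free combined MSD standard curve for one diffusive population."""
    if geometry is None:
        geometry = CellGeometry()
    cfg = SimulationConfig(
        D=D, R_conf=R_conf, frame_rates=frame_rates, n_traj=n_traj,
        mode=Mode(mode), geometry=geometry, seed=seed,
    )
    curves = model_curves(cfg, max_delay_frames=max_delay_frames)
    return combine_rates(
        [curves[r] for r in sorted(curves, reverse=True)], anchor_points=ANCHOR_POINTS
    )


def mixture_recovery(
    fraction_A: float,
    component_A: PopulationComponent,
    component_B: PopulationComponent,
    standard_A: CombinedMSD,
    standard_B: CombinedMSD,
    seed: int,
    n_tracks_per_rate: int = 70,
    frame_rates: tuple[float, ...] = DEFAULT_FRAME_RATES,
    localization_sigma: float = 0.05,
    geometry: CellGeometry | None = None,
) -> MixtureFit:
    """Generate a two-component pseudo-experiment and re-fit its mixture weight."""
    if geometry is None:
        geometry = CellGeometry()
    pcfg = PseudoExperimentConfig(
        population=(
            replace(component_A, weight=fraction_A),
            replace(component_B, weight=1.0 - fraction_A),
        ),
        n_tracks_per_rate=n_tracks_per_rate,
        frame_rates=frame_rates,
        localization_sigma=localization_sigma,
        seed=seed,
        geometry=geometry,
    )
    tracks = generate_pseudo_experiment(pcfg)
    observed = combined_msd_from_tracks(
        tracks, max_delay_frames=MIXTURE_MAX_DELAY_FRAMES, per_track_third=False
    )
    return mixture_fit(observed, standard_A, standard_B)


# reference parameter sets used throughout examples and recovery batteries:
# inner-membrane energizer (TonB-like, cylinder-restricted) and outer-membrane
# transporter (FepA-like, whole-surface) baseline conditions
TONB_LIKE = PopulationComponent(weight=1.0, D=5.4, R_conf=0.266,
                                mode=Mode.CYLINDER_ONLY)
FEPA_LIKE = PopulationComponent(weight=1.0, D=21.0, R_conf=0.180,
                                mode=Mode.WHOLE_SURFACE)
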