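"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one statistical feature of lineage dynamics in a
microbial range expansion at desk scale:

* transverse lineage wandering as a fractional Brownian motion with a
  tunable anomalous exponent (``simulate_lineage_trajectories``),
* neutral sector-boundary coarsening by pairwise annihilation of diffusing
  boundaries on an inflating circular front (``simulate_sector_coarsening``),
* establishment of a beneficial sector as a biased random walk of its
  half-width with an absorbing origin (``simulate_establishment``),
* timelapse fluorescence images of tracer beads (``render_bead_images``),
* multiplicative plate batch effects over a 96-well layout with wild-type
  reference wells (``apply_plate_effects``),
* strain × trait tables with a known linear response (``simulate_trait_table``).

All generators draw exclusively from a ``numpy`` Generator seeded through
their parameter object, so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .msd_pipeline import BeadTrajectory

__all__ = [
    "LineageSimParams",
    "SectorSimParams",
    "EstablishmentSimParams",
    "ImagingParams",
    "PlateEffectParams",
    "TraitSimParams",
    "simulate_lineage_trajectories",
    "simulate_sector_coarsening",
    "simulate_establishment",
    "simulate_bead_motion",
    "render_bead_images",
    "apply_plate_effects",
    "simulate_trait_table",
    "DEFAULT_TRUE_COEFFICIENTS",
    "DEFAULT_TRAIT_CORRELATIONS",
    "CELL_TRAITS",
    "COLONY_TRAITS",
]

#: Effective E. coli cell width (sqrt(length·width)), µm.
EFFECTIVE_CELL_SIZE_UM = 1.7


@dataclass
class LineageSimParams:
    """Transverse lineage wandering: Var[w(s+ℓ) − w(s)] = A·ℓ^β."""

    n_trajectories: int = 50
    total_arclength: float = 1200.0  # µm
    step: float = 2.0  # µm
    msd_exponent: float = 1.33  # β ∈ (0, 2)
    msd_amplitude: float = 0.5  # A, µm^(2−β)
    seed: int = 0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.total_arclength < 10 * self.step:
            raise ValueError("total_arclength must be at least 10·step")
        if not (0 < self.msd_exponent < 2):
            raise ValueError("msd_exponent must lie in (0, 2)")
        if self.msd_amplitude < 0:
            raise ValueError("msd_amplitude must be non-negative")
        if self.n_trajectories < 1:
            raise ValueError("need at least one trajectory")


@dataclass
class SectorSimParams:
    """Annihilating sector boundaries on an inflating circular front."""

    n_boundaries: int = 40
    initial_radius: float = 1000.0  # µm, inoculum front R0
    final_radius: float = 4000.0  # µm, Rf
    boundary_diffusion: float = 1.0  # D_b, µm (arc variance per µm growth)
    radial_step: float = 5.0  # µm
    seed: int = 0

    def __post_init__(self):
        if self.n_boundaries < 2 or self.n_boundaries % 2:
            raise ValueError("n_boundaries must be even and ≥ 2")
        if not (self.final_radius > self.initial_radius > 0):
            raise ValueError("need final_radius > initial_radius > 0")
        if self.boundary_diffusion < 0:
            raise ValueError("boundary_diffusion must be non-negative")
        if self.radial_step <= 0:
            raise ValueError("radial_step must be positive")


@dataclass
class EstablishmentSimParams:
    """Biased-walk establishment of a beneficial sector's half-width."""

    selection: float = 0.1  # s, widening drift per µm of radial growth
    boundary_diffusion: float = 1.0  # D_b, µm
    initial_halfwidth: float = EFFECTIVE_CELL_SIZE_UM  # X0, one cell width
    establish_threshold: float = 50.0  # X_est, µm
    max_radial_growth: float = 3000.0  # µm
    n_trials: int = 2000
    radial_step: float = 5.0  # µm
    seed: int = 0

    def __post_init__(self):
        if self.initial_halfwidth < 0:
            raise ValueError("initial_halfwidth must be non-negative")
        if self.establish_threshold <= self.initial_halfwidth:
            raise ValueError("establish_threshold must exceed initial_halfwidth")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        if self.boundary_diffusion < 0:
            raise ValueError("boundary_diffusion must be non-negative")


@dataclass
class ImagingParams:
    """Rendering of tracer-bead timelapse stacks.

    Defaults reproduce the experimental imaging conditions: one frame every
    10 minutes for 12 hours, roughly 250 beads per field of view.
    """

    pixel_size: float = 1.0  # µm/px
    frame_interval: float = 10.0  # minutes
    duration: float = 12.0  # hours
    spot_sigma: float = 1.5  # px
    bead_density: int = 250  # beads per field
    spot_peak: float = 1000.0  # counts above background at the spot center
    photon_noise: float = 1.0  # Gaussian shot-noise amplitude (× sqrt(signal))
    background: float = 100.0  # counts
    field_shape: tuple[int, int] = (512, 512)  # (ny, nx) px
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.frame_interval <= 0 or self.spot_sigma <= 0:
            raise ValueError("pixel_size, frame_interval and spot_sigma must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 60.0 / self.frame_interval)) + 1


@dataclass
class PlateEffectParams:
    """Multiplicative plate batch effects over a 96-well style layout."""

    strain_effects: Mapping[str, float] = field(default_factory=dict)
    plate_factor_sd: float = 0.2  # log-scale sd of the plate factor
    measurement_cv: float = 0.1  # per-colony fractional noise
    n_plates: int = 3
    wt_wells_per_plate: int = 8
    replicates_per_strain: int = 3
    wt_strain: str = "WT"
    seed: int = 0

    def __post_init__(self):
        if any(v <= 0 for v in self.strain_effects.values()):
            raise ValueError("strain effects must be positive")
        if self.wt_wells_per_plate < 1:
            raise ValueError("wt_wells_per_plate must be ≥ 1")
        if self.replicates_per_strain > self.n_plates:
            raise ValueError("replicates_per_strain cannot exceed n_plates")


COLONY_TRAITS = ("front_roughness", "growth_layer_depth", "colony_area", "colony_thickness")
CELL_TRAITS = ("aspect_ratio", "minor_axis_length", "surface_area", "volume", "major_axis_length")

#: True linear-model weights: the response is driven by colony-level traits
#: only, mirroring the finding that demographic noise is an emergent
#: population-level property.
DEFAULT_TRUE_COEFFICIENTS: dict[str, float] = {
    "front_roughness": 0.40,
    "growth_layer_depth": -0.25,
    "colony_area": 0.30,
    "colony_thickness": 0.15,
}

#: Pairwise trait correlation targets: larger colonies have thinner growth
#: layers and rougher fronts.
DEFAULT_TRAIT_CORRELATIONS: dict[tuple[str, str], float] = {
    ("colony_area", "growth_layer_depth"): -0.4,
    ("colony_area", "front_roughness"): 0.4,
}


@dataclass
class TraitSimParams:
    """Strain × trait table with a known sparse linear response."""

    n_strains: int = 200
    true_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_COEFFICIENTS)
    )
    trait_correlations: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_CORRELATIONS)
    )
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if any(abs(v) >= 1 for v in self.trait_correlations.values()):
            raise ValueError("trait correlations must have magnitude < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


# ---------------------------------------------------------------------------
# lineage wandering (fractional Brownian motion)


def _fbm_cholesky(s: np.ndarray, hurst: float) -> np.ndarray:
    """Cholesky factor of the unit-amplitude fBm covariance on grid ``s``."""
    s = s[1:]  # w(0) = 0 is excluded from the Gaussian part
    h2 = 2.0 * hurst
    cov = 0.5 * (
        s[:, None] ** h2 + s[None, :] ** h2 - np.abs(s[:, None] - s[None, :]) ** h2
    )
    # tiny jitter keeps the factorization stable for H near 1
    cov[np.diag_indices_from(cov)] *= 1.0 + 1e-12
    return np.linalg.cholesky(cov)


def simulate_lineage_trajectories(
    params: LineageSimParams,
) -> tuple[list[BeadTrajectory], dict]:
    """Sample transverse lineage wanderings with a known MSD power law.

    Each trajectory is a curve (s, w(s)) sampled every ``step`` µm of
    arclength, where ``w`` is a zero-mean fractional Brownian motion with
    Hurst index β/2, so that ``Var[w(s+ℓ) − w(s)] = A·ℓ^β`` exactly.  The
    synthesis is exact (covariance factorization), limited to ≤ 4096 samples
    per trajectory.

    Returns the trajectories and the ground truth ``{"beta": β, "amplitude": A}``.
    """
    n_pts = int(np.floor(params.total_arclength / params.step)) + 1
    if n_pts > 4096:
        raise ValueError("trajectory would exceed 4096 samples; increase step")
    s = np.arange(n_pts) * params.step
    rng = np.random.default_rng(params.seed)
    trajs: list[BeadTrajectory] = []
    t = np.arange(n_pts) * 10.0  # minutes, nominal frame interval
    if params.msd_amplitude == 0:
        w_all = np.zeros((params.n_trajectories, n_pts))
    else:
        chol = _fbm_cholesky(s, hurst=params.msd_exponent / 2.0)
        z = rng.standard_normal((params.n_trajectories, n_pts - 1))
        w_all = np.zeros((params.n_trajectories, n_pts))
        w_all[:, 1:] = np.sqrt(params.msd_amplitude) * z @ chol.T
    for i in range(params.n_trajectories):
        xy = np.column_stack([s, w_all[i]])
        trajs.append(BeadTrajectory("sim", f"bead{i:04d}", t, xy))
    truth = {"beta": params.msd_exponent, "amplitude": params.msd_amplitude}
    return trajs, truth


# ---------------------------------------------------------------------------
# sector coarsening


def simulate_sector_coarsening(params: SectorSimParams) -> dict:
    """Annihilating boundary walk on an inflating front.

    ``n_boundaries`` boundaries start evenly spaced on a circle of radius R0
    (alternating-color inoculum ring).  Per radial step dr each boundary's
    arc position receives an independent Gaussian increment of variance
    2·D_b·dr; the front inflates, which dilutes angular density but never
    crosses boundaries by itself.  Adjacent boundaries that cross annihilate
    in pairs (the sector between them is lost), resolved in ascending
    angular order.  Returns the surviving sector count of one color and the
    fraction of diversity preserved, survivors / (n_boundaries / 2).
    """
    rng = np.random.default_rng(params.seed)
    n0 = params.n_boundaries
    theta = np.arange(n0) * (2 * np.pi / n0)  # ascending, span < 2π
    r = params.initial_radius
    while r < params.final_radius and len(theta) >= 2:
        dr = min(params.radial_step, params.final_radius - r)
        r += dr
        if params.boundary_diffusion > 0:
            theta = theta + rng.normal(
                0.0, np.sqrt(2.0 * params.boundary_diffusion * dr) / r, size=len(theta)
            )
        theta = _annihilate_crossed(theta)
    survivors = len(theta) // 2
    return {
        "surviving_boundaries": int(len(theta)),
        "surviving_sectors": int(survivors),
        "fraction_preserved": survivors / (n0 / 2),
        "final_radius": float(r),
    }


def _annihilate_crossed(theta: np.ndarray) -> np.ndarray:
    """Remove boundary pairs that crossed during one diffusion step.

    ``theta`` was in ascending circular order (all gaps positive, summing to
    2π) before the step.  A crossing of an adjacent pair flips the sign of
    their gap, so pairs with a negative gap annihilate.  Pairs are resolved
    left-to-right in angular order, including the wrap pair across the 0/2π
    seam, and the scan repeats until every gap is positive again (handles
    the rare multi-crossing within one step deterministically).
    """
    while len(theta) >= 2:
        gaps = np.empty(len(theta))
        gaps[:-1] = np.diff(theta)
        gaps[-1] = theta[0] + 2 * np.pi - theta[-1]
        bad = np.flatnonzero(gaps < 0)
        if len(bad) == 0:
            break
        i = int(bad[0])
        if i < len(theta) - 1:
            theta = np.delete(theta, [i, i + 1])
        else:  # wrap pair: last and first
            theta = theta[1:-1]
    return theta


# ---------------------------------------------------------------------------
# establishment probability


def simulate_establishment(params: EstablishmentSimParams) -> dict:
    """Monte-Carlo establishment probability of a beneficial sector.

    The sector half-width X performs a biased random walk in the radial
    coordinate r: dX = s·dr + N(0, 2·D_b·dr), absorbed at X ≤ 0 (extinction)
    and established at X ≥ X_est (or by surviving ``max_radial_growth``).
    Returns p_est = established / n_trials with a Wilson 95% binomial CI.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_trials
    x = np.full(n, float(params.initial_halfwidth))
    alive = x > 0
    established = np.zeros(n, dtype=bool)
    grown = 0.0
    dr = params.radial_step
    sd = np.sqrt(2.0 * params.boundary_diffusion * dr)
    while grown < params.max_radial_growth and alive.any():
        step_dr = min(dr, params.max_radial_growth - grown)
        if step_dr != dr:
            sd = np.sqrt(2.0 * params.boundary_diffusion * step_dr)
        grown += step_dr
        idx = np.flatnonzero(alive)
        x[idx] += params.selection * step_dr + (
            rng.normal(0.0, sd, size=len(idx)) if sd > 0 else 0.0
        )
        died = x[idx] <= 0
        fixed = x[idx] >= params.establish_threshold
        established[idx[fixed & ~died]] = True
        alive[idx[died | fixed]] = False
    established[alive] = True  # survived the whole expansion
    k = int(established.sum())
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return {
        "p_est": k / n,
        "n_established": k,
        "n_trials": n,
        "ci95": (float(lo), float(hi)),
    }


# ---------------------------------------------------------------------------
# bead imaging


def simulate_bead_motion(
    n_beads: int,
    n_frames: int,
    field_um: tuple[float, float] = (512.0, 512.0),
    jitter_um: float = 0.6,
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0),
    frame_interval_min: float = 10.0,
    seed: int = 0,
    margin_um: float = 15.0,
) -> list[BeadTrajectory]:
    """Random-walk bead tracks inside a field of view (helper for rendering)."""
    rng = np.random.default_rng(seed)
    fy, fx = field_um
    x0 = rng.uniform(margin_um, fx - margin_um, size=n_beads)
    y0 = rng.uniform(margin_um, fy - margin_um, size=n_beads)
    steps = rng.normal(0.0, jitter_um, size=(n_beads, n_frames - 1, 2))
    steps += np.asarray(drift_um_per_frame, dtype=float)[None, None, :]  # (dx, dy)
    pos = np.zeros((n_beads, n_frames, 2))
    pos[:, 0, 0] = x0
    pos[:, 0, 1] = y0
    pos[:, 1:, :] = pos[:, :1, :] + np.cumsum(steps, axis=1)
    t = np.arange(n_frames) * frame_interval_min
    return [
        BeadTrajectory("field", f"bead{i:04d}", t, pos[i]) for i in range(n_beads)
    ]


def render_bead_images(
    trajectories: Sequence[BeadTrajectory], params: ImagingParams
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a timelapse stack of Gaussian bead spots with noise.

    Each frame holds one isotropic Gaussian spot of peak ``spot_peak`` and
    width ``spot_sigma`` per bead at its ground-truth subpixel position
    (µm / ``pixel_size``), on a flat ``background`` with Gaussian shot-like
    noise of standard deviation ``photon_noise·sqrt(signal)``.  Pixel centers
    sit at integer coordinates, origin top-left, x right / y down.  Beads
    outside the field are simply absent from that frame.

    Returns the (n_frames, ny, nx) float stack and a ground-truth table
    (frame, bead_id, x_px, y_px, visible).
    """
    ny, nx = params.field_shape
    n_frames = min(params.n_frames, min(len(tr) for tr in trajectories))
    stack = np.full((n_frames, ny, nx), float(params.background))
    rng = np.random.default_rng(params.seed)
    half = int(np.ceil(4 * params.spot_sigma))
    truth_rows = []
    for tr in trajectories:
        px = tr.xy_um / params.pixel_size
        for f in range(n_frames):
            x, y = px[f]
            visible = (0 <= x <= nx - 1) and (0 <= y <= ny - 1)
            truth_rows.append(
                {"frame": f, "bead_id": tr.bead_id, "x_px": x, "y_px": y, "visible": visible}
            )
            if not visible:
                continue
            xi, yi = int(round(x)), int(round(y))
            x0, x1 = max(0, xi - half), min(nx, xi + half + 1)
            y0, y1 = max(0, yi - half), min(ny, yi + half + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            stack[f, y0:y1, x0:x1] += params.spot_peak * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * params.spot_sigma**2)
            )
    if params.photon_noise > 0:
        stack += rng.normal(0.0, 1.0, size=stack.shape) * (
            params.photon_noise * np.sqrt(np.maximum(stack, 0.0))
        )
    truth = pd.DataFrame(truth_rows)
    return stack, truth


# ---------------------------------------------------------------------------
# plate effects


def apply_plate_effects(params: PlateEffectParams) -> pd.DataFrame:
    """Colony-level MSD table with multiplicative plate batch effects.

    Colony value = strain_effect × plate_factor × (1 + ε), with log-normal
    plate factors (log-sd ``plate_factor_sd``) and Gaussian measurement
    noise ε of sd ``measurement_cv``.  Every plate carries
    ``wt_wells_per_plate`` wild-type wells (strain effect 1); each mutant
    strain is replicated on ``replicates_per_strain`` distinct plates.
    Reported per-colony error is ``measurement_cv × value`` (floored at a
    tiny positive number so inverse-variance weights stay finite).
    """
    rng = np.random.default_rng(params.seed)
    plate_factors = np.exp(rng.normal(0.0, params.plate_factor_sd, size=params.n_plates))
    rows = []
    cid = 0

    def add_colony(strain: str, effect: float, plate: int):
        nonlocal cid
        noise = rng.normal(0.0, params.measurement_cv) if params.measurement_cv > 0 else 0.0
        value = effect * plate_factors[plate] * (1.0 + noise)
        err = max(params.measurement_cv * abs(value), 1e-12)
        rows.append(
            {
                "colony_id": f"c{cid:05d}",
                "strain_id": strain,
                "plate_id": f"p{plate:02d}",
                "msd50": value,
                "msd50_err": err,
                "exclusion_reason": "",
            }
        )
        cid += 1

    for plate in range(params.n_plates):
        for _ in range(params.wt_wells_per_plate):
            add_colony(params.wt_strain, 1.0, plate)
    for i, (strain, effect) in enumerate(params.strain_effects.items()):
        for r in range(params.replicates_per_strain):
            add_colony(strain, effect, (i + r) % params.n_plates)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trait tables


def _trait_covariance(params: TraitSimParams) -> tuple[list[str], np.ndarray]:
    traits = list(COLONY_TRAITS)
    cov = np.eye(len(traits))
    idx = {t: i for i, t in enumerate(traits)}
    for (a, b), rho in params.trait_correlations.items():
        cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = rho
    eig = np.linalg.eigvalsh(cov)
    if eig.min() <= 0:
        raise ValueError("requested trait correlation matrix is not positive-definite")
    return traits, cov


def simulate_trait_table(params: TraitSimParams) -> tuple[pd.DataFrame, pd.Series]:
    """Strain × trait matrix with a known sparse linear response.

    Colony-level traits are drawn from a correlated standard Gaussian with
    the configured pairwise correlations; cell-level traits are independent
    standard Gaussians.  The response (relative MSD) is the configured
    linear combination of traits plus Gaussian noise.  Returns the table
    (strain_id, traits..., relative_msd) and the true noiseless response.
    """
    traits, cov = _trait_covariance(params)
    rng = np.random.default_rng(params.seed)
    chol = np.linalg.cholesky(cov)
    colony = rng.standard_normal((params.n_strains, len(traits))) @ chol.T
    cell = rng.standard_normal((params.n_strains, len(CELL_TRAITS)))
    df = pd.DataFrame(colony, columns=traits)
    for j, t in enumerate(CELL_TRAITS):
        df[t] = cell[:, j]
    true_response = np.zeros(params.n_strains)
    for t, c in params.true_coefficients.items():
        true_response = true_response + c * df[t].to_numpy()
    noise = rng.normal(0.0, params.noise_sd, size=params.n_strains) if params.noise_sd else 0.0
    df.insert(0, "strain_id", [f"s{i:04d}" for i in range(params.n_strains)])
    df["relative_msd"] = true_response + noise
    return df, pd.Series(true_response, index=df["strain_id"], name="true_response")
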