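"""Sector-based estimators of drift strength and fitness.

In a two-color neutral range expansion, drift erases diversity by locally
fixing one label, leaving a small number of surviving sectors at the final
front.  The fraction of diversity preserved divides the surviving sector
count by half the number of cells at the inoculum front (the factor of one
half accounts for same-color neighbors).  For a beneficial (e.g. antibiotic
resistant) subpopulation at initial fraction x₀, the establishment
probability divides the established sector count by the expected number of
resistant founders at the front.  The collision assay infers the fitness
coefficient between two strains from the curvature of the circular-arc
boundary formed where their colonies meet (equal-arrival-time geometry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "EFFECTIVE_CELL_SIZE_UM",
    "SectorObservation",
    "EstablishmentObservation",
    "CollisionObservation",
    "InverseSqrtFit",
    "fraction_diversity_preserved",
    "establishment_probability",
    "fit_inverse_sqrt",
    "fit_linear",
    "predict_arc_radius",
    "collision_fitness",
]

#: Effective E. coli cell size sqrt(length·width), µm.
EFFECTIVE_CELL_SIZE_UM = 1.7


@dataclass
class SectorObservation:
    colony_id: str
    n_sectors: int
    inoculum_diameter_um: float
    effective_cell_size_um: float
    n_front_cells: float
    fraction_preserved: float


@dataclass
class EstablishmentObservation:
    colony_id: str
    n_sectors: int
    inoculum_diameter_um: float
    resistant_fraction: float
    n0: float
    p_est: float


@dataclass
class CollisionObservation:
    center_distance_mm: float
    arc_radius_mm: float  # np.inf for a straight boundary
    speed_ratio: float  # k = v_other / v_focal reference (k ≥ 1 geometry)
    fitness: float  # s, signed by orientation
    consistent: bool


@dataclass
class InverseSqrtFit:
    coefficient: float
    chi2_reduced: float
    n_points: int
    spearman_rho: float
    spearman_p: float


def _front_cells(diameter_um: float, cell_size_um: float) -> float:
    if diameter_um <= 0:
        raise ValueError("inoculum diameter must be positive")
    if cell_size_um <= 0:
        raise ValueError("effective cell size must be positive")
    return np.pi * diameter_um / cell_size_um


def fraction_diversity_preserved(
    n_sectors: int,
    inoculum_diameter_um: float,
    effective_cell_size_um: float = EFFECTIVE_CELL_SIZE_UM,
    colony_id: str = "",
) -> SectorObservation:
    """Fraction of neutral diversity preserved after a range expansion.

    f = n_sectors / (0.5 · N_front) with N_front = π·diameter/cell_size —
    the number of cells around the inoculum front.  The half accounts for
    neighboring founders sharing a color label.
    """
    if n_sectors != int(n_sectors) or n_sectors < 0:
        raise ValueError("sector count must be a non-negative integer")
    n_front = _front_cells(inoculum_diameter_um, effective_cell_size_um)
    return SectorObservation(
        colony_id=colony_id,
        n_sectors=int(n_sectors),
        inoculum_diameter_um=float(inoculum_diameter_um),
        effective_cell_size_um=float(effective_cell_size_um),
        n_front_cells=n_front,
        fraction_preserved=n_sectors / (0.5 * n_front),
    )


def establishment_probability(
    n_sectors: int,
    inoculum_diameter_um: float,
    resistant_fraction: float,
    effective_cell_size_um: float = EFFECTIVE_CELL_SIZE_UM,
    colony_id: str = "",
) -> EstablishmentObservation:
    """Establishment probability p_est = N_sectors / N₀.

    N₀ = (π·diameter/cell_size) · resistant_fraction is the expected number
    of beneficial founders at the inoculum front.  Values above 1 (possible
    through counting or inoculum-size noise) trigger a warning, not an
    error.
    """
    if not (0 < resistant_fraction <= 1):
        raise ValueError("resistant_fraction must lie in (0, 1]")
    if n_sectors != int(n_sectors) or n_sectors < 0:
        raise ValueError("sector count must be a non-negative integer")
    n0 = _front_cells(inoculum_diameter_um, effective_cell_size_um) * resistant_fraction
    p = n_sectors / n0
    if p > 1:
        warnings.warn(f"p_est = {p:.3g} exceeds 1 (estimation noise)", stacklevel=2)
    return EstablishmentObservation(
        colony_id=colony_id,
        n_sectors=int(n_sectors),
        inoculum_diameter_um=float(inoculum_diameter_um),
        resistant_fraction=float(resistant_fraction),
        n0=float(n0),
        p_est=float(p),
    )


def fit_inverse_sqrt(
    f: np.ndarray, f_err: np.ndarray, msd: np.ndarray
) -> InverseSqrtFit:
    """Weighted fit of f = c/√MSD with reduced χ² and rank correlation.

    Theory for neutral sector boundaries predicts the preserved fraction to
    fall off as the inverse square root of the lineage MSD.  With g = 1/√MSD
    the single-coefficient weighted least squares solution is
    c = Σ w f g / Σ w g², w = 1/σ², and χ²_r = Σ((f − c·g)/σ)² / (N − 1).
    Zero/absent errors fall back to an unweighted fit with a warning.
    """
    f = np.asarray(f, dtype=float)
    f_err = np.asarray(f_err, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if len(f) < 2:
        raise ValueError("need at least 2 points")
    if np.any(msd <= 0):
        raise ValueError("msd values must be positive")
    if np.any(f_err <= 0):
        warnings.warn("non-positive errors supplied; using unweighted fit", stacklevel=2)
        f_err = np.ones_like(f)
    g = 1.0 / np.sqrt(msd)
    w = 1.0 / f_err**2
    c = float(np.sum(w * f * g) / np.sum(w * g * g))
    resid = (f - c * g) / f_err
    chi2_r = float(np.sum(resid**2) / (len(f) - 1))
    rho, p = scipy.stats.spearmanr(f, msd)
    return InverseSqrtFit(c, chi2_r, len(f), float(rho), float(p))


def fit_linear(f: np.ndarray, f_err: np.ndarray, x: np.ndarray) -> float:
    """Reduced χ² of a weighted straight-line fit f = a + b·x (comparison model)."""
    f = np.asarray(f, dtype=float)
    f_err = np.asarray(f_err, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(f_err <= 0):
        f_err = np.ones_like(f)
    w = 1.0 / f_err**2
    X = np.column_stack([np.ones_like(x), x])
    WX = X * w[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ f)
    resid = (f - X @ beta) / f_err
    return float(np.sum(resid**2) / (len(f) - 2))


def predict_arc_radius(speed_ratio: float, center_distance: float) -> float:
    """Arc radius of the equal-arrival-time boundary between two colonies.

    Two point inocula a distance d apart expand at speeds v₁ and v₂
    (k = v₂/v₁).  The boundary — the locus of equal arrival time — is the
    Apollonius circle with radius R = d·k/|k² − 1|; equal speeds (k = 1)
    give a straight boundary (infinite R).
    """
    if speed_ratio <= 0 or center_distance <= 0:
        raise ValueError("speed ratio and center distance must be positive")
    if speed_ratio == 1.0:
        return np.inf
    k, d = speed_ratio, center_distance
    return d * k / abs(k * k - 1.0)


def collision_fitness(
    arc_radius: float, center_distance: float, bows_into_focal: bool = False
) -> CollisionObservation:
    """Invert the arc-curvature geometry to a fitness coefficient.

    Solving R = d·k/(k² − 1) for k > 1 gives
    k = (d + √(d² + 4R²)) / (2R); the fitness coefficient is s = k − 1,
    positive when the arc bows *into* the focal colony's partner (the focal
    strain is faster) and negative when it bows into the focal colony.
    Radii smaller than d/2 imply an implausibly large speed ratio and are
    flagged inconsistent.
    """
    if center_distance <= 0:
        raise ValueError("center distance must be positive")
    if arc_radius <= 0:
        raise ValueError("arc radius must be positive (∞ allowed)")
    d = center_distance
    if np.isinf(arc_radius):
        return CollisionObservation(d, np.inf, 1.0, 0.0, True)
    R = arc_radius
    k = (d + np.sqrt(d * d + 4.0 * R * R)) / (2.0 * R)
    s = k - 1.0
    consistent = R >= d / 2.0
    if not consistent:
        warnings.warn(
            f"arc radius {R:.3g} < d/2 = {d / 2:.3g}: geometrically inconsistent "
            "observation (speed ratio would be implausibly large)",
            stacklevel=2,
        )
    if bows_into_focal:
        s = -s
    return CollisionObservation(d, R, float(k), float(s), bool(consistent))
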