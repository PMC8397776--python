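"""Windowed, detrended mean-squared-displacement statistic for lineage tracers.

The strength of demographic noise (genetic drift) at the front of a growing
colony leaves a signature in the transverse wandering of cell lineages.  This
module quantifies that wandering from tracer-bead trajectories: each
trajectory is cut into overlapping arclength windows of length ``L``, a line
of best fit is computed inside every window, and the mean squared deviation
``Δw²`` from that line — averaged over windows and then over trajectories —
gives MSD(L).  A power law ``MSD(L) = A·L^β`` is fitted across a fixed grid
of window lengths and evaluated at a reference scale (50 µm by default) to
yield one summary number per colony, which is then normalized to wild-type
colonies on the same plate and aggregated across replicates.

Conventions
-----------
* Positions are in µm, times in minutes.
* The default detrending line is the total-least-squares (principal-axis)
  fit with *perpendicular* deviations, which makes the statistic exactly
  invariant under rigid rotations; ordinary least squares on the raw (x, y)
  coordinates with vertical deviations is available via ``mode="ols"``.
* All aggregation weights are inverse squared standard errors.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "BeadTrajectory",
    "MSDCurve",
    "PowerLawFit",
    "StrainSummary",
    "default_window_grid",
    "windowed_msd",
    "aggregate_msd",
    "fit_power_law",
    "msd_at_reference",
    "colony_msd",
    "flag_diverging_trajectories",
    "normalize_to_wildtype",
    "summarize_strain",
    "compare_distributions",
]

#: Window-length grid used throughout: 200 linearly spaced lengths, µm.
GRID_MIN_UM = 6.0
GRID_MAX_UM = 1152.0
GRID_N = 200
#: Reference window length for the per-colony summary statistic, µm.
L_REF_UM = 50.0
#: Window lengths contributed to by fewer trajectories than this are dropped.
MIN_TRAJECTORIES = 5
#: Curves with fewer rows than this cannot be fit to a power law.
MIN_WINDOW_SIZES = 5


def default_window_grid(
    grid_min: float = GRID_MIN_UM,
    grid_max: float = GRID_MAX_UM,
    n: int = GRID_N,
) -> np.ndarray:
    """Linearly spaced window-length grid in µm."""
    return np.linspace(grid_min, grid_max, n)


@dataclass
class BeadTrajectory:
    """Ordered 2-D positions of one tracer bead (a proxy for a cell lineage).

    Attributes
    ----------
    colony_id, bead_id : identifiers
    t_min : (n,) array, sample times in minutes, strictly increasing
    xy_um : (n, 2) array, positions in µm
    qc_flag : free-text quality flag ("" means clean; "crowded" marks
        trajectories containing detections that were too close together)
    """

    colony_id: str
    bead_id: str
    t_min: np.ndarray
    xy_um: np.ndarray
    qc_flag: str = ""
    _s: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.xy_um = np.asarray(self.xy_um, dtype=float)
        if self.xy_um.ndim != 2 or self.xy_um.shape[1] != 2:
            raise ValueError("xy_um must be an (n, 2) array")
        if len(self.t_min) != len(self.xy_um):
            raise ValueError("t_min and xy_um length mismatch")
        if len(self.t_min) < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not np.all(np.diff(self.t_min) > 0):
            raise ValueError("t_min must be strictly increasing")
        if not (np.all(np.isfinite(self.t_min)) and np.all(np.isfinite(self.xy_um))):
            raise ValueError("non-finite coordinates or times")

    @property
    def arclength_um(self) -> np.ndarray:
        """Cumulative arclength s (µm) along the trajectory, s[0] = 0."""
        if self._s is None:
            seg = np.linalg.norm(np.diff(self.xy_um, axis=0), axis=1)
            self._s = np.concatenate([[0.0], np.cumsum(seg)])
        return self._s

    @property
    def total_arclength_um(self) -> float:
        return float(self.arclength_um[-1])

    def __len__(self) -> int:
        return len(self.t_min)


@dataclass
class MSDCurve:
    """Combined MSD per window length, weighted over trajectories."""

    L_um: np.ndarray
    msd_um2: np.ndarray
    sem_um2: np.ndarray
    n_trajectories: np.ndarray

    def __len__(self) -> int:
        return len(self.L_um)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "L_um": self.L_um,
                "msd_um2": self.msd_um2,
                "sem_um2": self.sem_um2,
                "n_trajectories": self.n_trajectories,
            }
        )


@dataclass
class PowerLawFit:
    """Weighted log-log power-law fit MSD = A·L^β with its reference value."""

    amplitude: float  # A, µm^(2-β)
    exponent: float  # β
    amplitude_err: float  # σ_A (delta method from σ_logA)
    exponent_err: float  # σ_β
    log_amplitude: float  # fitted intercept ln A
    log_amplitude_err: float
    msd50_um2: float = np.nan
    msd50_err_um2: float = np.nan
    n_windows_used: int = 0
    qc_pass: bool = False
    failed: bool = False
    failure_reason: str = ""


@dataclass
class StrainSummary:
    strain_id: str
    relative_msd: float
    sem: float
    n_replicates: int


# ---------------------------------------------------------------------------
# windowed MSD


def _window_moments(xy: np.ndarray):
    """Extended-precision prefix sums of (1, x, y, x², y², xy)."""
    x = xy[:, 0].astype(np.longdouble)
    y = xy[:, 1].astype(np.longdouble)
    zeros = np.zeros(1, dtype=np.longdouble)
    csum = lambda a: np.concatenate([zeros, np.cumsum(a)])
    return csum(x), csum(y), csum(x * x), csum(y * y), csum(x * y)


def _window_mean_sq_dev(
    xy: np.ndarray, starts: np.ndarray, ends: np.ndarray, mode: str
) -> np.ndarray:
    """Mean squared deviation from the window's best-fit line, per window.

    For TLS the mean of the squared perpendicular deviations equals the
    smallest eigenvalue of the window's 2×2 coordinate covariance (population
    normalization); for OLS it is the residual variance of y on x.  Both are
    evaluated in closed form from prefix sums.
    """
    Sx, Sy, Sxx, Syy, Sxy = _window_moments(xy)
    n = (ends - starts).astype(np.longdouble)
    mx = (Sx[ends] - Sx[starts]) / n
    my = (Sy[ends] - Sy[starts]) / n
    cxx = (Sxx[ends] - Sxx[starts]) / n - mx * mx
    cyy = (Syy[ends] - Syy[starts]) / n - my * my
    cxy = (Sxy[ends] - Sxy[starts]) / n - mx * my
    if mode == "tls":
        tr = cxx + cyy
        disc = np.sqrt((cxx - cyy) ** 2 + 4.0 * cxy * cxy)
        val = 0.5 * (tr - disc)
    elif mode == "ols":
        with np.errstate(divide="ignore", invalid="ignore"):
            val = np.where(cxx > 0, cyy - cxy * cxy / np.where(cxx > 0, cxx, 1.0), cyy)
    else:
        raise ValueError(f"unknown detrending mode {mode!r}")
    return np.maximum(val.astype(float), 0.0)


def windowed_msd(
    trajectory: BeadTrajectory,
    L: float,
    min_points: int = 3,
    coverage: float = 0.8,
    mode: str = "tls",
) -> tuple[float, float, int]:
    """Per-trajectory MSD at window length ``L``.

    Every sample index starts a candidate window containing the samples whose
    arclength lies within ``L`` of the start.  Windows with fewer than
    ``min_points`` samples or spanning less than ``coverage·L`` are skipped.
    The window value is the mean of ``Δw²`` over its samples (the
    discretization of the windowed line-deviation integral); the trajectory
    value is the unweighted mean over windows.

    Returns
    -------
    (msd, sem, n_windows) : MSD(L) in µm², SEM over windows in µm², and the
        number of admitted windows.  ``(nan, nan, 0)`` if the trajectory has
        no valid window at this ``L``.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    s = trajectory.arclength_um
    if trajectory.total_arclength_um < L:
        return (np.nan, np.nan, 0)
    starts = np.arange(len(s))
    ends = np.searchsorted(s, s + L, side="right")
    npts = ends - starts
    span = s[ends - 1] - s[starts]
    ok = (npts >= min_points) & (span >= coverage * L)
    starts, ends = starts[ok], ends[ok]
    if len(starts) == 0:
        return (np.nan, np.nan, 0)
    vals = _window_mean_sq_dev(trajectory.xy_um, starts, ends, mode)
    msd = float(np.mean(vals))
    if len(vals) > 1:
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
    else:
        sem = np.nan
    return (msd, sem, len(vals))


def combine_weighted(
    values: np.ndarray, sems: np.ndarray, weighting: str = "random-effects"
) -> tuple[float, float]:
    """Inverse-variance combination of per-trajectory MSD values at one L.

    ``weighting="fixed"`` is the plain prescription wᵢ = 1/SEMᵢ², combined
    value Σ wᵢmᵢ/Σ wᵢ with propagated error (Σ wᵢ)^(−1/2).  Because the
    per-trajectory SEM is taken over heavily overlapping windows it
    understates the trajectory-to-trajectory scatter at window lengths
    approaching the trajectory length, and pure 1/SEM² weights then bias
    the combined value toward low-MSD trajectories.  The default
    ``"random-effects"`` therefore adds a between-trajectory variance
    component τ² (DerSimonian–Laird moment estimate) to every weight,
    wᵢ = 1/(SEMᵢ² + τ²): identical to the fixed weighting when
    trajectories agree, approaching the unweighted mean when they do not.
    """
    m = np.asarray(values, dtype=float)
    s = np.asarray(sems, dtype=float)
    pos = s > 0
    if not pos.any():  # all-degenerate (zero spread) trajectories
        return float(np.mean(m)), 0.0
    s = np.where(pos, s, s[pos].min())
    w = 1.0 / s**2
    mean_fe = float(np.sum(w * m) / np.sum(w))
    if weighting == "fixed" or len(m) < 2:
        return mean_fe, float(1.0 / np.sqrt(np.sum(w)))
    if weighting != "random-effects":
        raise ValueError(f"unknown weighting {weighting!r}")
    q = float(np.sum(w * (m - mean_fe) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (len(m) - 1)) / denom) if denom > 0 else 0.0
    wr = 1.0 / (s**2 + tau2)
    return float(np.sum(wr * m) / np.sum(wr)), float(1.0 / np.sqrt(np.sum(wr)))


def aggregate_msd(
    trajectories: Sequence[BeadTrajectory],
    window_grid: np.ndarray | None = None,
    min_trajectories: int = MIN_TRAJECTORIES,
    min_points: int = 3,
    coverage: float = 0.8,
    mode: str = "tls",
    weighting: str = "random-effects",
) -> MSDCurve:
    """Inverse-variance weighted MSD curve over a field of trajectories.

    Per window length the per-trajectory values are combined by
    :func:`combine_weighted` (inverse squared standard error of the mean,
    with a between-trajectory variance component by default — see there).
    A trajectory contributes at a length only if it admits ≥ 2 windows
    there (a single window has no SEM).  Lengths reached by fewer than
    ``min_trajectories`` trajectories are dropped.
    """
    if window_grid is None:
        window_grid = default_window_grid()
    L_out, msd_out, sem_out, n_out = [], [], [], []
    for L in np.asarray(window_grid, dtype=float):
        m_list, s_list = [], []
        for traj in trajectories:
            m, s_err, n_w = windowed_msd(traj, L, min_points, coverage, mode)
            if n_w >= 2 and np.isfinite(m):
                m_list.append(m)
                s_list.append(s_err)
        if len(m_list) < min_trajectories:
            continue
        combined, err = combine_weighted(np.array(m_list), np.array(s_list), weighting)
        L_out.append(L)
        msd_out.append(combined)
        sem_out.append(err)
        n_out.append(len(m_list))
    return MSDCurve(
        np.array(L_out), np.array(msd_out), np.array(sem_out), np.array(n_out, dtype=int)
    )


# ---------------------------------------------------------------------------
# power-law fit and reference value


def fit_power_law(curve: MSDCurve, min_windows: int = MIN_WINDOW_SIZES) -> PowerLawFit:
    """Weighted least-squares fit of MSD = A·L^β in log-log coordinates.

    Weights are delta-method log errors, σ_log = σ/MSD.  Rows with
    non-positive MSD cannot enter the log fit and are excluded with a
    warning; curves with fewer than ``min_windows`` usable rows fail with
    reason ``"too_few_windows"``.
    """
    usable = np.isfinite(curve.msd_um2) & (curve.msd_um2 > 0)
    if usable.sum() < len(curve):
        n_bad = int(len(curve) - usable.sum())
        if n_bad and usable.sum() > 0:
            warnings.warn(
                f"{n_bad} non-positive MSD rows excluded from the log-log fit",
                stacklevel=2,
            )
    L = curve.L_um[usable]
    m = curve.msd_um2[usable]
    s = curve.sem_um2[usable]
    if len(L) < min_windows:
        return PowerLawFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            n_windows_used=int(len(L)), failed=True, failure_reason="too_few_windows",
        )
    log_m = np.log(m)
    sigma_log = np.where(s > 0, s / m, np.nan)
    if np.isnan(sigma_log).all():
        w = np.ones_like(log_m)
    else:
        floor = np.nanmin(np.where(sigma_log > 0, sigma_log, np.nan))
        sigma_log = np.where(np.isfinite(sigma_log) & (sigma_log > 0), sigma_log, floor)
        w = 1.0 / sigma_log**2
    X = sm.add_constant(np.log(L))
    res = sm.WLS(log_m, X, weights=w).fit()
    log_a, beta = res.params
    se_log_a, se_beta = res.bse
    A = float(np.exp(log_a))
    return PowerLawFit(
        amplitude=A,
        exponent=float(beta),
        amplitude_err=float(A * se_log_a),
        exponent_err=float(se_beta),
        log_amplitude=float(log_a),
        log_amplitude_err=float(se_log_a),
        n_windows_used=int(len(L)),
    )


def msd_at_reference(
    fit: PowerLawFit, L_ref: float = L_REF_UM, bound_method: str = "joint"
) -> PowerLawFit:
    """Evaluate the fitted power law at the reference window length.

    The error is half the difference between the upper- and lower-bounded
    coefficient evaluations.  ``bound_method="joint"`` shifts both fitted
    log-log coefficients jointly by ±1 standard error; ``"envelope"`` takes
    half the range over the four per-coefficient sign combinations.  QC
    passes when the error is below half the value.
    """
    if fit.failed:
        return fit
    msd50 = fit.amplitude * L_ref**fit.exponent
    la, b = fit.log_amplitude, fit.exponent
    sla, sb = fit.log_amplitude_err, fit.exponent_err
    logL = np.log(L_ref)
    if bound_method == "joint":
        hi = np.exp((la + sla) + (b + sb) * logL)
        lo = np.exp((la - sla) + (b - sb) * logL)
        err = abs(hi - lo) / 2.0
    elif bound_method == "envelope":
        corners = [
            np.exp((la + i * sla) + (b + j * sb) * logL)
            for i in (-1, 1)
            for j in (-1, 1)
        ]
        err = (max(corners) - min(corners)) / 2.0
    else:
        raise ValueError(f"unknown bound_method {bound_method!r}")
    out = dataclasses.replace(fit)
    out.msd50_um2 = float(msd50)
    out.msd50_err_um2 = float(err)
    out.qc_pass = bool(err < msd50 / 2.0)
    return out


def colony_msd(
    trajectories: Sequence[BeadTrajectory],
    window_grid: np.ndarray | None = None,
    L_ref: float = L_REF_UM,
    mode: str = "tls",
    **kwargs,
) -> PowerLawFit:
    """Full per-colony chain: aggregate → power-law fit → MSD(L_ref)."""
    curve = aggregate_msd(trajectories, window_grid, mode=mode, **kwargs)
    return msd_at_reference(fit_power_law(curve), L_ref=L_ref)


# ---------------------------------------------------------------------------
# QC: beneficial-sector detection from diverging trajectories


def flag_diverging_trajectories(
    trajectories: Sequence[BeadTrajectory],
    separation_gain: float = 3.0,
    neighbor_radius_um: float = 50.0,
    rel_tol: float = 0.02,
) -> bool:
    """Flag a colony whose bead trajectories diverge like a beneficial sector.

    A bulge at the colony front (an establishing beneficial sector) pushes
    initially neighboring tracers apart monotonically.  The colony is flagged
    if any pair of trajectories starting within ``neighbor_radius_um`` of
    each other separates monotonically (up to a relative tolerance) by more
    than a factor ``separation_gain`` over the common record.
    """
    if len(trajectories) < 2:
        return False
    for i in range(len(trajectories)):
        for j in range(i + 1, len(trajectories)):
            a, b = trajectories[i], trajectories[j]
            n = min(len(a), len(b))
            if n < 2:
                continue
            sep = np.linalg.norm(a.xy_um[:n] - b.xy_um[:n], axis=1)
            if sep[0] <= 0 or sep[0] > neighbor_radius_um:
                continue
            monotone = np.all(np.diff(sep) >= -rel_tol * sep[:-1])
            if monotone and sep[-1] / sep[0] > separation_gain:
                return True
    return False


# ---------------------------------------------------------------------------
# plate normalization, replicate summary, distribution comparison


def normalize_to_wildtype(
    colonies: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    wt_strain: str = "WT",
) -> pd.DataFrame:
    """Normalize colony MSD(50 µm) to the plate's wild-type weighted mean.

    ``colonies`` must carry columns ``colony_id, strain_id, plate_id,
    msd50, msd50_err`` and optionally ``exclusion_reason`` (empty string for
    clean colonies).  Wild-type wells are identified either through
    ``layout`` (columns ``plate_id, strain_id, is_wt``) or by
    ``strain_id == wt_strain``.  Adds ``relative_msd`` and
    ``relative_msd_err`` (ratio errors combined in quadrature); colonies on
    plates without a passing wild type are excluded with reason ``"no_wt"``.
    """
    df = colonies.copy()
    if "exclusion_reason" not in df:
        df["exclusion_reason"] = ""
    df["exclusion_reason"] = df["exclusion_reason"].fillna("")
    if layout is not None:
        wt_keys = set(
            map(tuple, layout.loc[layout["is_wt"].astype(bool), ["plate_id", "strain_id"]].values)
        )
        is_wt = [
            (p, s) in wt_keys for p, s in zip(df["plate_id"], df["strain_id"])
        ]
        df["is_wt"] = np.array(is_wt, dtype=bool)
    else:
        df["is_wt"] = df["strain_id"] == wt_strain
    df["relative_msd"] = np.nan
    df["relative_msd_err"] = np.nan
    for plate, grp in df.groupby("plate_id"):
        wt = grp[grp["is_wt"] & (grp["exclusion_reason"] == "") & grp["msd50"].notna()]
        if len(wt) == 0:
            df.loc[grp.index, "exclusion_reason"] = np.where(
                grp["exclusion_reason"] == "", "no_wt", grp["exclusion_reason"]
            )
            warnings.warn(f"plate {plate!r} has no passing wild-type colony", stacklevel=2)
            continue
        w = 1.0 / wt["msd50_err"].to_numpy() ** 2
        if not np.all(np.isfinite(w)):
            w = np.ones(len(wt))
        wt_mean = float(np.sum(w * wt["msd50"].to_numpy()) / np.sum(w))
        wt_err = float(1.0 / np.sqrt(np.sum(w))) if np.all(np.isfinite(w)) else 0.0
        m = grp["msd50"].to_numpy()
        e = grp["msd50_err"].to_numpy()
        rel = m / wt_mean
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_err = np.abs(rel) * np.sqrt((e / m) ** 2 + (wt_err / wt_mean) ** 2)
        df.loc[grp.index, "relative_msd"] = rel
        df.loc[grp.index, "relative_msd_err"] = rel_err
    return df


def summarize_strain(
    colonies: pd.DataFrame, min_replicates: int = 2
) -> pd.DataFrame:
    """Inverse-variance weighted per-strain mean of the relative MSD.

    Only clean colonies (empty ``exclusion_reason``) count as replicates;
    strains with fewer than ``min_replicates`` clean replicates are dropped.
    The reported error is the standard error of the mean of the replicate
    values (a single replicate, allowed when ``min_replicates=1``, reports
    its own measurement error instead).
    """
    rows = []
    clean = colonies[
        (colonies.get("exclusion_reason", "") == "") & colonies["relative_msd"].notna()
    ]
    for strain, grp in clean.groupby("strain_id"):
        vals = grp["relative_msd"].to_numpy()
        errs = grp["relative_msd_err"].to_numpy()
        if len(vals) < min_replicates:
            continue
        w = 1.0 / errs**2
        if not np.all(np.isfinite(w) & (w > 0)):
            w = np.ones_like(vals)
        mean = float(np.sum(w * vals) / np.sum(w))
        if len(vals) > 1:
            sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
        else:
            sem = float(errs[0])
        rows.append(
            {"strain_id": strain, "relative_msd": mean, "sem": sem, "n_replicates": len(vals)}
        )
    return pd.DataFrame(rows, columns=["strain_id", "relative_msd", "sem", "n_replicates"])


def compare_distributions(
    ko_values: Iterable[float],
    wt_values: Iterable[float],
    n_bootstrap: int = 10_000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> dict:
    """Compare knockout and wild-type relative-MSD distributions.

    Returns the two-sided two-sample Kolmogorov–Smirnov statistic and p,
    group means/variances/medians, and the median shift
    ``1 − median(KO)/median(WT)`` with a seeded percentile-bootstrap CI.
    """
    ko = np.asarray(list(ko_values), dtype=float)
    wt = np.asarray(list(wt_values), dtype=float)
    if len(ko) < 2 or len(wt) < 2:
        raise ValueError("need at least 2 values per group")
    ks = scipy.stats.ks_2samp(ko, wt, alternative="two-sided")
    med_ko, med_wt = float(np.median(ko)), float(np.median(wt))
    shift = 1.0 - med_ko / med_wt
    rng = np.random.default_rng(seed)
    bs_ko = np.median(rng.choice(ko, size=(n_bootstrap, len(ko)), replace=True), axis=1)
    bs_wt = np.median(rng.choice(wt, size=(n_bootstrap, len(wt)), replace=True), axis=1)
    bs_shift = 1.0 - bs_ko / bs_wt
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(bs_shift, [alpha / 2, 1 - alpha / 2])
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "mean_ko": float(np.mean(ko)),
        "mean_wt": float(np.mean(wt)),
        "var_ko": float(np.var(ko, ddof=1)),
        "var_wt": float(np.var(wt, ddof=1)),
        "median_ko": med_ko,
        "median_wt": med_wt,
        "median_shift": float(shift),
        "median_shift_ci": (float(lo), float(hi)),
        "n_bootstrap": int(n_bootstrap),
    }
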