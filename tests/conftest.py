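import numpy as np
import pytest

from colonydrift.msd_pipeline import BeadTrajectory


def random_walk_trajectory(rng, n=100, step_sd=2.0, colony="c", bead="b"):
    xy = np.cumsum(rng.normal(0.0, step_sd, (n, 2)), axis=0)
    return BeadTrajectory(colony, bead, np.arange(n, dtype=float) * 10.0, xy)


def naive_windowed_msd(tr, L, min_points=3, coverage=0.8, mode="tls"):
    """Brute-force double-loop windowed MSD (independent oracle).

    Slices every window explicitly, centers it, and takes the smallest
    eigenvalue of the coordinate covariance (TLS) or the residual variance
    of y on x (OLS) via an explicit least-squares fit.
    """
    s = tr.arclength_um
    if s[-1] < L:
        return (np.nan, np.nan, 0)
    vals = []
    for l in range(len(s)):
        idx = [j for j in range(l, len(s)) if s[j] - s[l] <= L]
        if len(idx) < min_points or s[idx[-1]] - s[l] < coverage * L:
            continue
        P = tr.xy_um[idx]
        C = P - P.mean(axis=0)
        if mode == "tls":
            cov = C.T @ C / len(idx)
            vals.append(max(float(np.linalg.eigvalsh(cov)[0]), 0.0))
        else:
            A = np.column_stack([np.ones(len(idx)), P[:, 0]])
            coef, *_ = np.linalg.lstsq(A, P[:, 1], rcond=None)
            r = P[:, 1] - A @ coef
            vals.append(float(np.mean(r**2)))
    if not vals:
        return (np.nan, np.nan, 0)
    v = np.array(vals)
    sem = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
    return (float(v.mean()), float(sem), len(v))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
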