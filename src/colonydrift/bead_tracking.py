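"""Bead detection, coarse flow estimation, and flow-assisted linking.

Tracer beads embedded in a growing colony advect with the expanding front
(a coherent flow of up to several pixels per frame) while also jittering
with the local demographic noise.  Plain nearest-neighbor linking fails once
the coherent displacement exceeds the bead spacing, so tracking proceeds in
three stages, a simplified hybrid of particle image velocimetry and single
particle tracking:

1. ``detect_beads`` — intensity maxima refined to subpixel precision by a
   background-subtracted center of mass; detections closer than a minimum
   separation are crowd-flagged (too close for reliable tracking).
2. ``estimate_coarse_flow`` — per-patch displacement between consecutive
   frames from the cross-correlation peak with parabolic subpixel
   refinement.
3. ``link_trajectories`` — each detection is advected by the interpolated
   flow, then linked greedily shortest-link-first within ``max_disp``.

Coordinate convention: pixel centers at integer coordinates, origin at the
top-left, x rightward (columns), y downward (rows); µm = px × pixel_size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .msd_pipeline import BeadTrajectory

__all__ = [
    "DetectionSet",
    "FlowField",
    "detect_beads",
    "estimate_coarse_flow",
    "link_trajectories",
    "track_stack",
]


@dataclass
class DetectionSet:
    """Subpixel bead detections in one frame."""

    frame: int
    positions: np.ndarray  # (n, 2) as (x, y) px
    intensities: np.ndarray  # (n,)
    crowd_flags: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class FlowField:
    """Coarse displacement field between two consecutive frames."""

    centers_x: np.ndarray  # patch-center x coordinates (px), ascending
    centers_y: np.ndarray  # patch-center y coordinates (px), ascending
    vectors: np.ndarray  # (ny, nx, 2) displacements (dx, dy) px
    patch: int

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear flow at (x, y) points, clamped to the patch-grid hull."""
        pts = np.atleast_2d(points).astype(float)
        px = np.clip(pts[:, 0], self.centers_x[0], self.centers_x[-1])
        py = np.clip(pts[:, 1], self.centers_y[0], self.centers_y[-1])
        if len(self.centers_y) == 1 and len(self.centers_x) == 1:
            return np.broadcast_to(self.vectors[0, 0], (len(pts), 2)).copy()
        out = np.empty((len(pts), 2))
        for k in range(2):
            interp = RegularGridInterpolator(
                (self.centers_y, self.centers_x),
                self.vectors[..., k],
                method="linear",
                bounds_error=False,
                fill_value=None,
            )
            out[:, k] = interp(np.column_stack([py, px]))
        return out


def detect_beads(
    frame: np.ndarray,
    threshold: float,
    min_separation: float = 10.0,
    refine_radius: int = 4,
    peak_footprint: int = 5,
) -> DetectionSet:
    """Detect bead spots in one frame with subpixel refinement.

    Local maxima (within a ``peak_footprint``-sized neighborhood) above
    ``threshold`` are refined by the center of mass of the
    local-background-subtracted intensity within ``refine_radius`` pixels
    (background = median of the window border).  Detections closer than
    ``min_separation`` px are crowd-flagged but kept: a neighboring spot
    inside the refinement window contaminates the center of mass, so such
    detections are unreliable (the default separation is two refinement
    radii plus a margin).
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_beads expects a 2-D intensity image")
    local_max = scipy.ndimage.maximum_filter(img, size=peak_footprint, mode="nearest")
    peaks = (img == local_max) & (img > threshold)
    ys, xs = np.nonzero(peaks)
    positions, intensities = [], []
    r = int(refine_radius)
    ny, nx = img.shape
    for y0, x0 in zip(ys, xs):
        ylo, yhi = max(0, y0 - r), min(ny, y0 + r + 1)
        xlo, xhi = max(0, x0 - r), min(nx, x0 + r + 1)
        win = img[ylo:yhi, xlo:xhi]
        border = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
        sig = np.maximum(win - np.median(border), 0.0)
        total = sig.sum()
        if total <= 0:
            positions.append((float(x0), float(y0)))
        else:
            yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
            positions.append(
                (float((sig * xx).sum() / total), float((sig * yy).sum() / total))
            )
        intensities.append(float(img[y0, x0]))
    pos = np.array(positions).reshape(-1, 2)
    crowd = np.zeros(len(pos), dtype=bool)
    if len(pos) > 1:
        for i, j in cKDTree(pos).query_pairs(min_separation):
            crowd[i] = crowd[j] = True
    return DetectionSet(0, pos, np.asarray(intensities), crowd)


def _parabolic_offset(c_m: float, c_0: float, c_p: float) -> float:
    denom = c_m - 2.0 * c_0 + c_p
    if denom >= 0 or not np.isfinite(denom):
        return 0.0
    return float(np.clip(0.5 * (c_m - c_p) / denom, -1.0, 1.0))


def _validate_vectors(vectors: np.ndarray, tol: float = 2.0, passes: int = 2) -> np.ndarray:
    """Universal outlier replacement on a PIV vector grid.

    Sparse fields leave some tiles without trackable texture; their
    correlation peaks are noise.  Each vector deviating from the median of
    its 3×3 neighborhood by more than ``tol + 2·MAD`` px (per component) is
    replaced by that median.  A single tile passes through unchanged.
    """
    gy, gx, _ = vectors.shape
    if gy * gx < 2:
        return vectors
    out = vectors.copy()
    for _ in range(passes):
        new = out.copy()
        for iy in range(gy):
            for ix in range(gx):
                ylo, yhi = max(0, iy - 1), min(gy, iy + 2)
                xlo, xhi = max(0, ix - 1), min(gx, ix + 2)
                neigh = out[ylo:yhi, xlo:xhi].reshape(-1, 2)
                mask = np.ones(len(neigh), dtype=bool)
                mask[(iy - ylo) * (xhi - xlo) + (ix - xlo)] = False
                neigh = neigh[mask]
                if len(neigh) == 0:
                    continue
                med = np.median(neigh, axis=0)
                mad = np.median(np.abs(neigh - med), axis=0)
                bad = np.abs(out[iy, ix] - med) > tol + 2.0 * mad
                if bad.any():
                    new[iy, ix] = np.where(bad, med, out[iy, ix])
        out = new
    return out


def estimate_coarse_flow(
    frame_a: np.ndarray, frame_b: np.ndarray, patch: int = 64, validate: bool = True
) -> FlowField:
    """Per-patch displacement field from a → b by FFT cross-correlation.

    The image pair is tiled into ``patch``-sized tiles; each tile's
    displacement is the location of its circular cross-correlation peak
    (mean-subtracted tiles), refined to subpixel precision by a 1-D
    parabolic fit through the peak and its neighbors in x and y.  With
    ``validate`` (default) outlier vectors from textureless tiles are
    replaced by their neighborhood median.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have the same shape")
    ny, nx = a.shape
    if patch > min(ny, nx):
        raise ValueError("patch larger than image")
    gy = ny // patch
    gx = nx // patch
    centers_y = (np.arange(gy) + 0.5) * patch - 0.5
    centers_x = (np.arange(gx) + 0.5) * patch - 0.5
    vectors = np.zeros((gy, gx, 2))
    for iy in range(gy):
        for ix in range(gx):
            ta = a[iy * patch : (iy + 1) * patch, ix * patch : (ix + 1) * patch]
            tb = b[iy * patch : (iy + 1) * patch, ix * patch : (ix + 1) * patch]
            ta = ta - ta.mean()
            tb = tb - tb.mean()
            corr = np.real(np.fft.ifft2(np.fft.fft2(tb) * np.conj(np.fft.fft2(ta))))
            corr = np.fft.fftshift(corr)
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            cy, cx = patch // 2, patch // 2
            dy = py - cy
            dx = px - cx
            # parabolic refinement with circular neighbor indexing
            fx = _parabolic_offset(
                corr[py, (px - 1) % patch], corr[py, px], corr[py, (px + 1) % patch]
            )
            fy = _parabolic_offset(
                corr[(py - 1) % patch, px], corr[py, px], corr[(py + 1) % patch, px]
            )
            vectors[iy, ix] = (dx + fx, dy + fy)
    if validate:
        vectors = _validate_vectors(vectors)
    return FlowField(centers_x, centers_y, vectors, patch)


@dataclass
class _Track:
    bead_id: int
    frames: list = field(default_factory=list)
    positions: list = field(default_factory=list)  # px
    crowded: bool = False


def link_trajectories(
    detections: list[DetectionSet],
    flows: list[FlowField | None] | None,
    max_disp: float = 5.0,
    pixel_size: float = 1.0,
    frame_interval_min: float = 10.0,
    colony_id: str = "colony",
) -> list[BeadTrajectory]:
    """Greedy flow-assisted linking of per-frame detections into tracks.

    For every frame interval each open track's position is advected by the
    interpolated coarse flow; candidate (track, detection) pairs within
    ``max_disp`` px of the prediction are linked shortest-first (ties broken
    by coordinates, so the result is invariant to detection order).
    Unmatched tracks terminate — there is no gap closing — and unmatched
    detections open new tracks.  Tracks containing a crowd-flagged detection
    carry the ``"crowded"`` QC flag.  Positions are returned in µm.
    """
    tracks: list[_Track] = []
    open_tracks: list[_Track] = []
    next_id = 0

    def start(det: DetectionSet, idx: int, frame: int) -> None:
        nonlocal next_id
        tr = _Track(next_id, [frame], [det.positions[idx].copy()], bool(det.crowd_flags[idx]))
        next_id += 1
        tracks.append(tr)
        open_tracks.append(tr)

    if not detections:
        return []
    for idx in range(len(detections[0])):
        start(detections[0], idx, 0)
    for k in range(1, len(detections)):
        det = detections[k]
        flow = flows[k - 1] if flows is not None else None
        if flows is not None and flow is None:
            warnings.warn(
                f"no flow field for interval {k - 1}->{k}; using zero-flow prediction",
                stacklevel=2,
            )
        if open_tracks:
            last = np.array([tr.positions[-1] for tr in open_tracks])
            pred = last + (flow.interpolate(last) if flow is not None else 0.0)
        else:
            pred = np.zeros((0, 2))
        # candidate links within max_disp, globally shortest first
        cands = []
        for ti, p in enumerate(pred):
            if len(det) == 0:
                break
            d = np.linalg.norm(det.positions - p, axis=1)
            for di in np.flatnonzero(d <= max_disp):
                cands.append(
                    (
                        float(d[di]),
                        float(p[0]), float(p[1]),
                        float(det.positions[di, 0]), float(det.positions[di, 1]),
                        ti, int(di),
                    )
                )
        cands.sort(key=lambda c: c[:5])
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, *_coords, ti, di in cands:
            if ti in used_tracks or di in used_dets:
                continue
            used_tracks.add(ti)
            used_dets.add(di)
            tr = open_tracks[ti]
            tr.frames.append(k)
            tr.positions.append(det.positions[di].copy())
            tr.crowded = tr.crowded or bool(det.crowd_flags[di])
        open_tracks = [tr for ti, tr in enumerate(open_tracks) if ti in used_tracks]
        for di in range(len(det)):
            if di not in used_dets:
                start(det, di, k)
    out = []
    for tr in tracks:
        if len(tr.frames) < 2:
            continue
        xy = np.array(tr.positions) * pixel_size
        t = np.array(tr.frames, dtype=float) * frame_interval_min
        out.append(
            BeadTrajectory(
                colony_id,
                f"bead{tr.bead_id:04d}",
                t,
                xy,
                qc_flag="crowded" if tr.crowded else "",
            )
        )
    return out


def track_stack(
    stack: np.ndarray,
    threshold: float,
    pixel_size: float = 1.0,
    min_separation: float = 10.0,
    refine_radius: int = 4,
    patch: int = 64,
    max_disp: float = 5.0,
    frame_interval_min: float = 10.0,
    colony_id: str = "colony",
    use_flow: bool = True,
) -> list[BeadTrajectory]:
    """Full tracking chain on an image stack: detect → flow → link."""
    stack = np.asarray(stack, dtype=float)
    detections = []
    for f in range(stack.shape[0]):
        ds = detect_beads(stack[f], threshold, min_separation, refine_radius)
        ds.frame = f
        detections.append(ds)
    flows = None
    if use_flow:
        flows = [
            estimate_coarse_flow(stack[f], stack[f + 1], patch)
            for f in range(stack.shape[0] - 1)
        ]
    return link_trajectories(
        detections, flows, max_disp, pixel_size, frame_interval_min, colony_id
    )
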