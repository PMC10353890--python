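"""Video frames -> identity-resolved trajectories in millimetres.

Detection thresholds dark blobs against a per-pixel temporal median
background inside each circular ROI; linking assigns detections to stable
fly identities frame-to-frame with an optimal bipartite (Hungarian)
assignment, gated by the maximum plausible displacement.  Merged blobs
(two flies closer than one body length) are split by k-means on the blob's
pixels, seeded from the identities' constant-velocity predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .errors import (
    CalibrationError,
    EmptyInputError,
    GeometryError,
    InvalidParameterError,
)
from .trajectories import TrajectorySet

__all__ = [
    "ArenaConfig",
    "BlobDetection",
    "FrameDetections",
    "DetectionSet",
    "detect_flies",
    "detect_sequence",
    "link_identities",
    "calibrate_scale",
    "track_frames",
]


@dataclass
class ArenaConfig:
    """Geometry and scale of the filmed arena plate.

    Up to four circular ROIs (26-mm behavioural chambers) may appear in one
    frame; each is identified by its centre (x_px, y_px) and a common pixel
    radius.  ``mm_per_px`` converts pixel to physical coordinates and must be
    consistent with the known ROI diameter to within 5%.
    """

    roi_centres: Sequence[tuple[float, float]]
    roi_radius_px: float
    mm_per_px: float
    frame_rate: float = 15.0
    roi_diameter_mm: float = 26.0
    frame_shape: tuple[int, int] | None = None  # (height, width)

    def __post_init__(self):
        if self.mm_per_px <= 0:
            raise InvalidParameterError("mm_per_px must be positive")
        if self.roi_radius_px <= 0:
            raise InvalidParameterError("roi_radius_px must be positive")
        implied = self.roi_radius_px * self.mm_per_px
        nominal = self.roi_diameter_mm / 2
        if abs(implied - nominal) > 0.05 * nominal:
            raise InvalidParameterError(
                f"roi_radius_px * mm_per_px = {implied:.2f} mm is inconsistent "
                f"with roi_diameter_mm/2 = {nominal:.2f} mm (>5% off)"
            )
        if self.frame_shape is None:
            margin = 12
            xs = [c[0] for c in self.roi_centres]
            ys = [c[1] for c in self.roi_centres]
            w = int(math.ceil(max(xs) + self.roi_radius_px + margin))
            h = int(math.ceil(max(ys) + self.roi_radius_px + margin))
            self.frame_shape = (h, w)

    @classmethod
    def single_roi(
        cls,
        mm_per_px: float = 0.1,
        frame_rate: float = 15.0,
        roi_diameter_mm: float = 26.0,
        margin_px: int = 12,
    ) -> "ArenaConfig":
        """One centred ROI with a small margin; the usual simulation fixture."""
        radius_px = roi_diameter_mm / 2 / mm_per_px
        c = radius_px + margin_px
        side = int(math.ceil(2 * c))
        return cls(
            roi_centres=[(c, c)],
            roi_radius_px=radius_px,
            mm_per_px=mm_per_px,
            frame_rate=frame_rate,
            roi_diameter_mm=roi_diameter_mm,
            frame_shape=(side, side),
        )

    @property
    def n_rois(self) -> int:
        return len(self.roi_centres)

    def px_to_mm(self, roi_index: int, xy_px: np.ndarray) -> np.ndarray:
        """Pixel coordinates -> mm relative to ROI centre (x right, y up)."""
        cx, cy = self.roi_centres[roi_index]
        xy = np.atleast_2d(np.asarray(xy_px, dtype=float))
        out = np.empty_like(xy)
        out[:, 0] = (xy[:, 0] - cx) * self.mm_per_px
        out[:, 1] = (cy - xy[:, 1]) * self.mm_per_px
        return out


@dataclass
class BlobDetection:
    """One dark blob: centroid (x_px, y_px), pixel area, merged flag."""

    centroid: tuple[float, float]
    area: int
    merged: bool = False
    pixels: np.ndarray | None = None  # (N, 2) [x, y]; kept only for merged blobs


@dataclass
class FrameDetections:
    """Detections for one frame, one list per ROI."""

    rois: list[list[BlobDetection]]


class DetectionSet(list):
    """A list of :class:`FrameDetections`, one per frame."""


_ROI_MASK_CACHE: dict[tuple, np.ndarray] = {}


def _roi_mask(shape: tuple[int, int], centre: tuple[float, float], radius: float) -> np.ndarray:
    key = (shape, float(centre[0]), float(centre[1]), float(radius))
    mask = _ROI_MASK_CACHE.get(key)
    if mask is None:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        mask = (xx - centre[0]) ** 2 + (yy - centre[1]) ** 2 <= radius**2
        if len(_ROI_MASK_CACHE) > 32:
            _ROI_MASK_CACHE.clear()
        _ROI_MASK_CACHE[key] = mask
    return mask


def _expected_blob_area_px(arena: ArenaConfig) -> float:
    # nominal fly body ellipse 2.5 x 1.2 mm
    return math.pi * (1.25 / arena.mm_per_px) * (0.6 / arena.mm_per_px)


def detect_flies(
    frame: np.ndarray,
    arena: ArenaConfig,
    expected_n: int,
    background: np.ndarray | None = None,
    mad_factor: float = 3.0,
    min_area_frac: float = 0.25,
    noise_scale: float | None = None,
) -> FrameDetections:
    """Threshold dark blobs inside each ROI of a single grayscale frame.

    ``background`` is the per-pixel temporal-median model; without one, the
    frame's own median is used (valid because flies cover a tiny fraction of
    the arena).  Blobs darker than ``background - mad_factor * 1.4826*MAD``
    and larger than ``min_area_frac`` of the nominal fly body area are
    reported.  If fewer than ``expected_n`` blobs are found, the largest
    blobs are flagged as merge candidates and carry their pixel coordinates
    so the linker can split them.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    for cx, cy in arena.roi_centres:
        if (
            cx - arena.roi_radius_px < 0
            or cy - arena.roi_radius_px < 0
            or cx + arena.roi_radius_px > w
            or cy + arena.roi_radius_px > h
        ):
            raise GeometryError("frame does not cover the configured ROI extent")

    if background is None:
        bg = np.median(frame)
        resid_scale = 1.4826 * np.median(np.abs(frame - bg))
        thresh = bg - mad_factor * max(resid_scale, 2.0)
        dark = frame < thresh
    else:
        resid = background - frame  # positive where darker than background
        if noise_scale is None:
            noise_scale = 1.4826 * float(np.median(np.abs(frame - background)))
        dark = resid > mad_factor * max(noise_scale, 2.0)

    area_1 = _expected_blob_area_px(arena)
    min_area = max(4, int(min_area_frac * area_1))

    rois: list[list[BlobDetection]] = []
    for r in range(arena.n_rois):
        mask = _roi_mask(frame.shape, arena.roi_centres[r], arena.roi_radius_px - 1)
        lab, n_lab = ndimage.label(dark & mask)
        dets: list[BlobDetection] = []
        labels_of: list[int] = []
        if n_lab:
            ys, xs = np.nonzero(lab)
            lv = lab[ys, xs]
            areas = np.bincount(lv, minlength=n_lab + 1)
            sx = np.bincount(lv, weights=xs, minlength=n_lab + 1)
            sy = np.bincount(lv, weights=ys, minlength=n_lab + 1)
            for k in range(1, n_lab + 1):
                if areas[k] < min_area:
                    continue
                dets.append(
                    BlobDetection(
                        centroid=(sx[k] / areas[k], sy[k] / areas[k]),
                        area=int(areas[k]),
                    )
                )
                labels_of.append(k)
        deficit = expected_n - len(dets)
        if deficit > 0:
            # flag merge candidates and keep their own pixels: any clearly
            # oversized blob, plus the largest blobs up to the deficit (two
            # strongly overlapping flies can stay under the area criterion)
            slices = ndimage.find_objects(lab)
            by_area = sorted(range(len(dets)), key=lambda q: -dets[q].area)
            candidates = {q for q in by_area if dets[q].area > 1.5 * area_1}
            candidates.update(by_area[:deficit])
            for q in candidates:
                d, k = dets[q], labels_of[q]
                d.merged = True
                sl = slices[k - 1]
                ys, xs = np.nonzero(lab[sl] == k)
                d.pixels = np.column_stack(
                    (xs + sl[1].start, ys + sl[0].start)
                ).astype(float)
        dets.sort(key=lambda d: (d.centroid[1], d.centroid[0]))
        rois.append(dets)
    return FrameDetections(rois=rois)


def detect_sequence(
    frames: Iterable[np.ndarray],
    arena: ArenaConfig,
    expected_n: int,
    background_frames: int = 150,
    background_percentile: float = 90.0,
    mad_factor: float = 3.0,
) -> DetectionSet:
    """Detect flies across a frame sequence with a temporal background model.

    The background is the per-pixel ``background_percentile`` of brightness
    over the first ``background_frames`` frames (or all frames if fewer).
    Flies are dark, so a high brightness percentile recovers the fly-free
    plate even where a fly pauses for part of the window — a plain temporal
    median would absorb it and render it invisible.
    """
    frames = iter(frames)
    buffer: list[np.ndarray] = []
    for f in frames:
        buffer.append(np.asarray(f, dtype=np.uint8))
        if len(buffer) >= background_frames:
            break
    if not buffer:
        raise EmptyInputError("no frames supplied")
    background = np.percentile(np.stack(buffer), background_percentile, axis=0)
    # sensor noise is stationary: estimate its scale once, on the first frame
    noise_scale = 1.4826 * float(np.median(np.abs(buffer[0].astype(float) - background)))

    dets = DetectionSet()
    for f in buffer:
        dets.append(detect_flies(f, arena, expected_n, background=background,
                                 mad_factor=mad_factor, noise_scale=noise_scale))
    for f in frames:
        dets.append(detect_flies(f, arena, expected_n, background=background,
                                 mad_factor=mad_factor, noise_scale=noise_scale))
    return dets


# ----------------------------------------------------------------------
# identity linking
# ----------------------------------------------------------------------

def _kmeans_split(pixels: np.ndarray, init: np.ndarray, n_iter: int = 10) -> np.ndarray:
    """Plain Lloyd iterations on blob pixel coordinates; returns centroids."""
    centres = init.astype(float).copy()
    for _ in range(n_iter):
        d = np.linalg.norm(pixels[:, None, :] - centres[None, :, :], axis=2)
        assign = np.argmin(d, axis=1)
        for k in range(len(centres)):
            sel = pixels[assign == k]
            if len(sel):
                centres[k] = sel.mean(axis=0)
    return centres


def link_identities(
    dets: DetectionSet,
    arena: ArenaConfig,
    expected_n: int | None = None,
    roi_index: int = 0,
    max_speed_mm_s: float = 50.0,
    coast_frames: int = 5,
) -> TrajectorySet:
    """Assign stable identities to per-frame detections for one ROI.

    Frame-to-frame assignment minimizes total centroid displacement
    (Hungarian algorithm) with a hard gate at the displacement a fly moving
    ``max_speed_mm_s`` could produce in one frame.  Identities unmatched in a
    frame coast at their predicted position (marked invalid) with the gate
    widening for up to ``coast_frames`` frames, after which re-acquisition is
    unrestricted.  Merged blobs are split by k-means seeded from the
    identities' constant-velocity predictions.  Output positions are in mm
    relative to the ROI centre.
    """
    if len(dets) == 0:
        raise EmptyInputError("no detection frames supplied")

    first = dets[0].rois[roi_index]
    if expected_n is None:
        expected_n = len(first)
    if expected_n == 0:
        raise EmptyInputError("no flies to track in the first frame")
    n = expected_n
    T = len(dets)
    gate_px = max_speed_mm_s / arena.frame_rate / arena.mm_per_px

    # --- initial identities, sorted for determinism ---------------------
    init = _frame_centroids(dets[0].rois[roi_index], n)
    if len(init) < n:
        raise EmptyInputError(
            f"first frame has {len(init)} detections; {n} flies expected"
        )
    order = np.lexsort((init[:, 0], init[:, 1]))
    pos_px = init[order[:n]].astype(float)
    vel_px = np.zeros_like(pos_px)
    missed = np.zeros(n, dtype=int)

    out = np.empty((n, T, 2))
    valid = np.zeros((n, T), dtype=bool)
    out[:, 0] = pos_px
    valid[:, 0] = True

    for t in range(1, T):
        preds = pos_px + vel_px
        blobs = dets[t].rois[roi_index]
        gates = gate_px * (1 + np.minimum(missed, coast_frames))
        cands: list[np.ndarray] = []
        from_split: list[bool] = []
        pinned: dict[int, np.ndarray] = {}  # identity -> centroid, fixed pairing
        if blobs:
            arr = np.array([b.centroid for b in blobs])
            # which blob does each identity claim (nearest within its gate)?
            d_ib = np.linalg.norm(preds[:, None, :] - arr[None, :, :], axis=2)
            nearest_blob = np.argmin(d_ib, axis=1)
            claimed = np.where(d_ib[np.arange(n), nearest_blob] <= gates, nearest_blob, -1)
            for b, blob in enumerate(blobs):
                claimants = np.nonzero(claimed == b)[0]
                if len(claimants) >= 2 and blob.pixels is not None:
                    # split a merged blob by k-means seeded at the claimants'
                    # predicted positions (pre-merge velocity carried through)
                    centres = _kmeans_split(blob.pixels, preds[claimants], n_iter=3)
                    if len(claimants) == 2:
                        # Two flies sharing a blob.  If they move alike (a
                        # pursuit pair in tandem) keep their order along the
                        # blob axis — a chaser does not teleport past its
                        # leader.  If their motion states differ (a walker
                        # passing a paused fly), velocity prediction is the
                        # reliable cue and a genuine through-pass is allowed.
                        # The criterion is relative so that the velocity
                        # memory decaying during a long merge does not flip it.
                        va = np.linalg.norm(vel_px[claimants[0]])
                        vb = np.linalg.norm(vel_px[claimants[1]])
                        v_rel = np.linalg.norm(vel_px[claimants[0]] - vel_px[claimants[1]])
                        distinct = v_rel > 0.6 * max(va, vb, 1e-9)
                        axis = centres[1] - centres[0]
                        nrm = np.linalg.norm(axis)
                        if distinct or nrm <= 1e-9:
                            dmat = np.linalg.norm(
                                preds[claimants][:, None, :] - centres[None, :2, :], axis=2
                            )
                            if dmat[0, 0] + dmat[1, 1] <= dmat[0, 1] + dmat[1, 0]:
                                pairing = (0, 1)
                            else:
                                pairing = (1, 0)
                            for k, ci in enumerate(claimants):
                                pinned[ci] = centres[pairing[k]]
                        else:
                            axis = axis / nrm
                            oc = np.argsort(centres @ axis)
                            oi = np.argsort(pos_px[claimants] @ axis)
                            for k in range(2):
                                pinned[claimants[oi[k]]] = centres[oc[k]]
                    else:
                        # three or more flies in one blob: pin each claimant
                        # to a split centroid by minimum total displacement
                        dmat = np.linalg.norm(
                            preds[claimants][:, None, :] - centres[None, :, :], axis=2
                        )
                        rr, cc = linear_sum_assignment(dmat)
                        for r_, c_ in zip(rr, cc):
                            pinned[claimants[r_]] = centres[c_]
                else:
                    cands.append(np.asarray(blob.centroid, dtype=float))
                    from_split.append(False)
        cands = np.array(cands) if len(cands) else np.empty((0, 2))
        matched = np.full(n, -1, dtype=int)
        free_ids = np.array([i for i in range(n) if i not in pinned], dtype=int)
        if len(cands) and len(free_ids):
            cost = np.linalg.norm(preds[free_ids, None, :] - cands[None, :, :], axis=2)
            big = 1e9
            cost = np.where(cost <= gates[free_ids, None], cost, big)
            rows, cols = linear_sum_assignment(cost)
            for r, c in zip(rows, cols):
                if cost[r, c] < big:
                    matched[free_ids[r]] = c
        for i in range(n):
            if i in pinned:
                # inside a merge, split centroids are noisy: blend them with
                # the prediction and keep the pre-merge velocity, so the
                # crossing stays disambiguated and a stationary fly is not
                # dragged along by pixels bleeding in from its partner
                pos_px[i] = preds[i] + 0.4 * (pinned[i] - preds[i])
                vel_px[i] *= 0.95
                missed[i] = 0
                valid[i, t] = True
            elif matched[i] >= 0:
                new = cands[matched[i]]
                if from_split[matched[i]]:
                    vel_px[i] *= 0.95
                else:
                    vel_px[i] = 0.5 * vel_px[i] + 0.5 * (new - pos_px[i])
                pos_px[i] = new
                missed[i] = 0
                valid[i, t] = True
            else:
                pos_px[i] = preds[i]
                vel_px[i] *= 0.6
                missed[i] += 1
                valid[i, t] = False
        out[:, t] = pos_px

    positions = np.empty_like(out)
    for t in range(T):
        positions[:, t, :] = arena.px_to_mm(roi_index, out[:, t, :])
    return TrajectorySet(
        positions=positions,
        valid=valid,
        frame_rate=arena.frame_rate,
        fly_ids=np.arange(1, n + 1),
        roi_id=roi_index,
    )


def _frame_centroids(blobs: list[BlobDetection], expected_n: int) -> np.ndarray:
    """Blob centroids for a frame without identity history (the first frame).

    Merged blobs are split into as many parts as needed to reach
    ``expected_n``, seeding k-means along each blob's principal axis.
    """
    if not blobs:
        return np.empty((0, 2))
    cents = [np.asarray(b.centroid, dtype=float) for b in blobs]
    n_missing = expected_n - len(blobs)
    if n_missing > 0:
        merge_order = sorted(
            (i for i, b in enumerate(blobs) if b.merged and b.pixels is not None),
            key=lambda i: -blobs[i].area,
        )
        extra = {i: 0 for i in merge_order}
        remainder = n_missing
        while remainder > 0 and merge_order:
            for i in merge_order:
                if remainder <= 0:
                    break
                extra[i] += 1
                remainder -= 1
        for i in merge_order:
            k = 1 + extra[i]
            if k < 2:
                continue
            pix = blobs[i].pixels
            mu = pix.mean(axis=0)
            u, _, _ = np.linalg.svd((pix - mu).T @ (pix - mu))
            axis = u[:, 0]
            span = (pix - mu) @ axis
            qs = np.linspace(span.min(), span.max(), k)
            init = mu + qs[:, None] * axis
            centres = _kmeans_split(pix, init)
            cents[i] = centres[0]
            cents.extend(centres[1:])
    return np.vstack([np.atleast_2d(c) for c in cents])


def track_frames(
    frames: Iterable[np.ndarray],
    arena: ArenaConfig,
    expected_n: int,
    roi_index: int = 0,
    **kwargs,
) -> TrajectorySet:
    """Convenience: detect then link a frame sequence for one ROI."""
    dets = detect_sequence(frames, arena, expected_n)
    return link_identities(dets, arena, expected_n=expected_n, roi_index=roi_index, **kwargs)


# ----------------------------------------------------------------------
# spatial calibration
# ----------------------------------------------------------------------

def calibrate_scale(
    image: np.ndarray,
    known_diameter_mm: float = 26.0,
    radius_range_px: tuple[int, int] | None = None,
) -> float:
    """Recover mm/px from the arena wall circle visible in an image.

    A Hough circle transform on the image's edges finds the ROI wall; the
    scale is ``known_diameter_mm`` divided by the fitted diameter in pixels.
    """
    from skimage.feature import canny
    from skimage.transform import hough_circle, hough_circle_peaks

    img = np.asarray(image, dtype=float)
    img = (img - img.min()) / max(float(np.ptp(img)), 1e-9)
    edges = canny(img, sigma=2.0)
    if not edges.any():
        raise CalibrationError("no edges found; cannot locate the arena circle")
    if radius_range_px is None:
        r_max = min(img.shape) // 2
        radius_range_px = (max(int(0.4 * r_max), 5), r_max)
    radii = np.arange(radius_range_px[0], radius_range_px[1] + 1)
    acc = hough_circle(edges, radii)
    _, cx, cy, r = hough_circle_peaks(acc, radii, total_num_peaks=1)
    if len(r) == 0 or r[0] <= 0:
        raise CalibrationError("no circle found in the image")
    return known_diameter_mm / (2.0 * float(r[0]))
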