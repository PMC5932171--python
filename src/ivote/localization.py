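"""Cell-center extraction from the converged vote field, plus a
scale-normalized Laplacian-of-Gaussian baseline detector.

A site is a raw peak when its score is >= every score in the surrounding
window of physical radius ``r``; peaks closer than ``r`` to a stronger peak
are suppressed, so reported centers are pairwise separated by at least one
cell radius.  Scores are the vote-field values at the surviving peaks and
can be thresholded manually or with Otsu's method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .preprocess import BRIGHT_CELLS, DARK_CELLS, ImageGrid
from .voting import VoteField

__all__ = [
    "DetectionSet",
    "find_local_maxima",
    "threshold_detections",
    "log_detector",
    "detections_to_csv",
    "detections_from_csv",
]


@dataclass(frozen=True)
class DetectionSet:
    """Detected cell centers with scores, sorted by descending score.

    Centers are 0-based lattice indices in array order; all pairs are
    separated by at least ``radius_um`` in physical units.
    """

    centers: np.ndarray  # (K, ndim) int
    scores: np.ndarray  # (K,) float, descending
    radius_um: float
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=np.int64))
        if centers.size == 0:
            centers = centers.reshape(0, len(self.spacing))
        scores = np.asarray(self.scores, dtype=np.float64).ravel()
        if centers.shape[0] != scores.shape[0]:
            raise ValueError("centers and scores length mismatch")
        if np.any(np.diff(scores) > 0):
            raise ValueError("scores must be sorted descending")
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "scores", scores)

    @property
    def count(self) -> int:
        return int(self.scores.shape[0])

    @property
    def ndim(self) -> int:
        return len(self.spacing)

    def centers_um(self) -> np.ndarray:
        return self.centers * np.asarray(self.spacing)


def _suppress_close_peaks(coords: np.ndarray, scores: np.ndarray,
                          spacing, r_um: float):
    """Greedy minimum-separation filter by descending score, ties broken
    toward the lexicographically smallest site."""
    if coords.shape[0] == 0:
        return coords, scores
    order = np.lexsort(tuple(coords[:, i] for i in range(coords.shape[1] - 1, -1, -1))
                       + (-scores,))
    coords = coords[order]
    scores = scores[order]
    sp = np.asarray(spacing)
    kept_idx: list[int] = []
    kept_um = np.empty((0, coords.shape[1]))
    for i in range(coords.shape[0]):
        p_um = coords[i] * sp
        if kept_um.shape[0]:
            d2 = np.sum((kept_um - p_um) ** 2, axis=1)
            if np.any(d2 < r_um**2):
                continue
        kept_idx.append(i)
        kept_um = np.vstack([kept_um, p_um[None, :]])
    return coords[kept_idx], scores[kept_idx]


def _maxima_of(scores: np.ndarray, spacing, r_um: float,
               radius_um: float) -> DetectionSet:
    sp = np.asarray(spacing, dtype=float)
    window = tuple(2 * int(np.ceil(r_um / s)) + 1 for s in sp)
    footprint_max = ndimage.maximum_filter(scores, size=window, mode="constant",
                                           cval=-np.inf)
    peak_mask = (scores >= footprint_max) & (scores > 0)
    coords = np.argwhere(peak_mask)
    vals = scores[peak_mask]
    coords, vals = _suppress_close_peaks(coords, vals, sp, r_um)
    return DetectionSet(centers=coords, scores=vals, radius_um=radius_um,
                        spacing=tuple(float(s) for s in sp))


def find_local_maxima(votes: VoteField, r_um: float, spacing=None) -> DetectionSet:
    """Extract cell-center candidates from a converged vote field.

    ``r_um`` is the cell-radius scale used for both the peak window and
    the minimum separation between reported centers.
    """
    spacing = votes.spacing if spacing is None else tuple(spacing)
    return _maxima_of(np.asarray(votes.scores, dtype=float), spacing, r_um, r_um)


def threshold_detections(dets: DetectionSet, method: str = "otsu",
                         value: float | None = None) -> DetectionSet:
    """Keep detections with score >= threshold.

    ``method="manual"`` uses ``value``; ``method="otsu"`` computes the
    threshold from a 256-bin histogram of the scores; ``method="otsu_log"``
    applies Otsu to the log-scores instead.  Vote scores grow with the
    squared (2D) or cubed (3D) cell radius, so on images with mixed cell
    sizes the raw-score histogram is heavy-tailed and plain Otsu can split
    the cells themselves; the log transform makes the cell/noise
    separation scale-free and is the recommended automated choice.
    """
    if method == "manual":
        if value is None:
            raise ValueError("manual thresholding requires a value")
        thr = float(value)
    elif method in ("otsu", "otsu_log"):
        if dets.count == 0:
            raise ValueError("Otsu thresholding requires a nonempty score list")
        if np.ptp(dets.scores) == 0:
            raise ValueError(
                "Otsu thresholding is undefined for constant scores; "
                "use a manual threshold"
            )
        vals = dets.scores if method == "otsu" else np.log10(dets.scores)
        # threshold_otsu returns the center of the last background bin;
        # the class boundary is that bin's upper edge
        thr_space = float(threshold_otsu(vals, nbins=256))
        thr_space += 0.5 * np.ptp(vals) / 256
        thr = thr_space if method == "otsu" else float(10**thr_space)
        keep = vals > thr_space
        return DetectionSet(centers=dets.centers[keep],
                            scores=dets.scores[keep],
                            radius_um=dets.radius_um, spacing=dets.spacing)
    else:
        raise ValueError(f"unknown threshold method: {method!r}")
    keep = dets.scores >= thr
    return DetectionSet(centers=dets.centers[keep], scores=dets.scores[keep],
                        radius_um=dets.radius_um, spacing=dets.spacing)


def log_detector(image: ImageGrid, sigma: float = 4.0, r_um: float | None = None,
                 polarity: str = DARK_CELLS) -> DetectionSet:
    """Scale-normalized Laplacian-of-Gaussian blob detector.

    ``sigma`` is in pixels on the finest axis (scaled per axis so the
    physical scale is isotropic).  The response sign is chosen so cell
    centers are maxima for the given polarity, then the same local-maxima
    and minimum-separation machinery as the voting detector is applied.
    Serves as the classical single-scale baseline.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sp = np.asarray(image.spacing, dtype=float)
    finest = sp.min()
    sigma_px = sigma * finest / sp
    if r_um is None:
        r_um = float(sigma * finest)
    response = ndimage.gaussian_laplace(image.values, sigma=sigma_px,
                                        mode="reflect")
    response *= sigma**2  # scale normalization
    if polarity == BRIGHT_CELLS:
        response = -response
    elif polarity != DARK_CELLS:
        raise ValueError(f"unknown polarity: {polarity!r}")
    return _maxima_of(response, image.spacing, r_um, r_um)


def detections_to_csv(dets: DetectionSet, path) -> None:
    """Write detections as CSV: x, y[, z] in 0-based pixels, the same in
    micrometers, and the score.  z columns are omitted for 2D."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sp = np.asarray(dets.spacing)
    cols: dict[str, np.ndarray] = {}
    # array axis order is (y, x) in 2D and (z, y, x) in 3D
    names = ["y", "x"] if dets.ndim == 2 else ["z", "y", "x"]
    for axis, name in enumerate(names):
        cols[name] = dets.centers[:, axis]
    out_names = ["x", "y"] if dets.ndim == 2 else ["x", "y", "z"]
    frame = pd.DataFrame({n: cols[n] for n in out_names})
    for axis, name in zip(range(dets.ndim - 1, -1, -1), out_names):
        frame[f"{name}_um"] = dets.centers[:, axis] * sp[axis]
    frame["score"] = dets.scores
    frame.to_csv(path, index=False, float_format="%.9g")


def detections_from_csv(path, spacing, radius_um: float) -> DetectionSet:
    """Read a detections CSV produced by :func:`detections_to_csv`."""
    frame = pd.read_csv(path)
    if "score" not in frame.columns:
        raise ValueError(
            f"{path}: not a detections file (missing 'score' column); "
            "was a truth CSV passed by mistake?"
        )
    spacing = tuple(float(s) for s in spacing)
    ndim = 3 if "z" in frame.columns else 2
    if len(spacing) != ndim:
        raise ValueError(f"{ndim}D detections but {len(spacing)} spacing entries")
    names = ["y", "x"] if ndim == 2 else ["z", "y", "x"]
    centers = frame[names].to_numpy(dtype=np.int64) if len(frame) else \
        np.empty((0, ndim), dtype=np.int64)
    scores = frame["score"].to_numpy(dtype=float)
    order = np.argsort(-scores, kind="stable")
    return DetectionSet(centers=centers[order], scores=scores[order],
                        radius_um=radius_um, spacing=spacing)
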