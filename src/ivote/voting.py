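"""The iterative voting core.

Every lattice site with nonzero gradient magnitude is a voter.  Each
iteration scatters every voter's magnitude into its vote cone (length
``r``, aperture ``phi``), then re-orients each voter toward the maximum
accumulated score inside its own cone.  The aperture is halved between
iterations, starting at pi/2, until the cone is narrower than one pixel at
distance ``r``; the last vote field is the converged detector response
whose local maxima are candidate cell centers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .preprocess import (
    DARK_CELLS,
    GradientField,
    ImageGrid,
    compute_gradient,
    default_blur_sigma,
    gaussian_blur,
)

__all__ = [
    "VoteField",
    "IterationSchedule",
    "VoteDiagnostics",
    "cast_votes",
    "collect_votes_oracle",
    "update_directions",
    "make_schedule",
    "iterative_vote",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoteField:
    """Accumulated vote scores on the input lattice.

    ``voter_member_counts`` holds, per voter, how many sites its cone
    covered in the pass that produced this field — enough to audit the
    exact bookkeeping identity
    ``sum(scores) == sum(magnitude * voter_member_counts)``.
    """

    scores: np.ndarray
    iteration_index: int
    spacing: tuple[float, ...]
    voter_member_counts: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.scores.shape

    def total_mass(self) -> float:
        return float(self.scores.sum())


@dataclass(frozen=True)
class IterationSchedule:
    """The aperture-narrowing schedule.

    Apertures are ``phi0 * shrink_factor**i``; the run stops after the
    first pass whose aperture has dropped below the termination aperture
    ``phi_t`` (that pass still executes, so its narrow cone sharpens the
    final field).  ``phi_t = 1/r_pixels`` makes the cone arc one pixel wide
    at full length, beyond which no new information is available.
    """

    phi0: float
    phi_t: float
    shrink_factor: float = 0.5
    phis: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.shrink_factor < 1.0):
            raise ValueError("shrink_factor must lie in (0, 1)")
        if self.phi_t <= 0:
            raise ValueError("terminating aperture must be positive")
        phis = []
        phi = self.phi0
        while True:
            phis.append(phi)
            if phi < self.phi_t:
                break
            phi *= self.shrink_factor
        object.__setattr__(self, "phis", tuple(phis))

    @property
    def n_iterations(self) -> int:
        return len(self.phis)


@dataclass(frozen=True)
class VoteDiagnostics:
    """Per-iteration log of a full run: aperture, vote mass, and the
    exact expected mass sum(M * member_count)."""

    phi: tuple[float, ...]
    vote_mass: tuple[float, ...]
    expected_mass: tuple[float, ...]


def make_schedule(r_pixels: float, phi0: float = math.pi / 2,
                  shrink_factor: float = 0.5) -> IterationSchedule:
    """Build the halving schedule for a cone ``r_pixels`` long.

    ``r_pixels`` is the minimum per-axis cone length in pixels; the
    termination aperture is ``1/r_pixels`` (small-angle one-pixel arc).
    """
    if r_pixels < 1:
        raise ValueError("cone length must be at least one pixel")
    return IterationSchedule(phi0=phi0, phi_t=1.0 / r_pixels,
                             shrink_factor=shrink_factor)


def _embed_3d(field: GradientField):
    """View a 2D field as a singleton-z 3D field (geometry unchanged)."""
    mag = field.magnitude
    vec = field.vectors
    spacing = field.spacing
    if mag.ndim == 2:
        mag = mag[None, ...]
        vec3 = np.zeros(mag.shape + (3,), dtype=np.float64)
        vec3[0, ..., 1:] = vec
        return np.ascontiguousarray(mag), vec3, (1.0,) + spacing
    return (np.ascontiguousarray(mag),
            np.ascontiguousarray(vec.astype(np.float64)),
            spacing)


def _check_radius(r_um: float, spacing) -> None:
    if r_um < min(spacing):
        raise ValueError(
            f"cone length {r_um} um is smaller than one pixel "
            f"(finest spacing {min(spacing)} um)"
        )


def cast_votes(field: GradientField, r_um: float, phi: float, spacing=None) -> VoteField:
    """One voting pass: scatter every voter's magnitude into its cone.

    The vote field is zero-initialized on every call.  Accumulation order
    is fixed, so the result is bit-deterministic for fixed inputs.
    """
    spacing = field.spacing if spacing is None else tuple(spacing)
    _check_radius(r_um, spacing)
    mag, vec, sp3 = _embed_3d(field)
    votes = np.zeros_like(mag)
    counts = np.zeros(mag.shape, dtype=np.int64)
    _kernels.cast_votes_3d(mag, vec, sp3[0], sp3[1], sp3[2],
                           float(r_um), math.cos(phi / 2.0), votes, counts)
    if field.ndim == 2:
        votes = votes[0]
        counts = counts[0]
    return VoteField(scores=votes, iteration_index=0, spacing=spacing,
                     voter_member_counts=counts)


def collect_votes_oracle(field: GradientField, r_um: float, phi: float,
                         spacing=None) -> VoteField:
    """Reference vote field computed by gathering instead of scattering.

    For each site, sums the magnitudes of all voters whose cone contains
    it, by exhaustive all-pairs scan with no bounding-box pruning or
    compiled code.  Intended for small fields only (O(n^2) in sites).
    """
    spacing = field.spacing if spacing is None else tuple(spacing)
    _check_radius(r_um, spacing)
    sp = np.asarray(spacing, dtype=float)
    shape = field.shape
    sites = np.stack(np.meshgrid(*[np.arange(n) for n in shape],
                                 indexing="ij"), axis=-1).reshape(-1, field.ndim)
    mag = field.magnitude.reshape(-1)
    vec = field.vectors.reshape(-1, field.ndim)
    voters = np.nonzero(mag > 0)[0]
    cos_half = math.cos(phi / 2.0)
    scores = np.zeros(sites.shape[0])
    for t in voters:
        off = (sites - sites[t]) * sp
        dist2 = np.sum(off * off, axis=1)
        dot = off @ vec[t]
        member = (dot > 0) & (dist2 < r_um**2) & (dot * dot > cos_half**2 * dist2)
        scores[member] += mag[t]
    return VoteField(scores=scores.reshape(shape), iteration_index=0,
                     spacing=spacing)


def update_directions(field: GradientField, votes: VoteField, r_um: float,
                      phi: float, spacing=None) -> GradientField:
    """Re-orient every voter toward the argmax of the vote field in its
    cone; magnitudes are preserved exactly."""
    if votes.shape != field.shape:
        raise ValueError("vote field shape does not match gradient field")
    spacing = field.spacing if spacing is None else tuple(spacing)
    mag, vec, sp3 = _embed_3d(field)
    v = votes.scores[None, ...] if field.ndim == 2 else votes.scores
    out = np.zeros_like(vec)
    _kernels.update_directions_3d(mag, vec, np.ascontiguousarray(v),
                                  sp3[0], sp3[1], sp3[2],
                                  float(r_um), math.cos(phi / 2.0), out)
    new_vec = out[0, ..., 1:].copy() if field.ndim == 2 else out
    return GradientField(magnitude=field.magnitude, vectors=new_vec,
                         spacing=field.spacing, polarity=field.polarity)


def iterative_vote(
    image: ImageGrid,
    radius_um: float,
    polarity: str = DARK_CELLS,
    sigma_blur: float | None = 2.0,
    phi0: float = math.pi / 2,
    shrink_factor: float = 0.5,
    return_diagnostics: bool = False,
):
    """Run the full iterative voting pipeline on an image.

    Parameters
    ----------
    image
        2D or 3D intensity lattice.
    radius_um
        Maximum cell radius in micrometers — the method's single required
        tuning parameter.  Must exceed the coarsest voxel spacing.
    polarity
        ``"dark_cells"`` (nuclei darker than background, e.g. Nissl
        brightfield) or ``"bright_cells"`` (fluorescence).
    sigma_blur
        Gaussian pre-blur in pixels on the finest axis (physically
        isotropic across axes); ``None`` or 0 skips blurring.

    Returns the converged :class:`VoteField` (and a
    :class:`VoteDiagnostics` when ``return_diagnostics`` is set).
    """
    if radius_um <= max(image.spacing):
        raise ValueError(
            "radius_um must exceed the coarsest voxel spacing "
            f"({max(image.spacing)} um)"
        )
    work = image
    if sigma_blur:
        work = gaussian_blur(image, default_blur_sigma(image, sigma_blur))
    field = compute_gradient(work, polarity=polarity)

    r_pixels = min(radius_um / s for s in image.spacing)
    schedule = make_schedule(r_pixels, phi0=phi0, shrink_factor=shrink_factor)

    votes = None
    phis_log, mass_log, expected_log = [], [], []
    for i, phi in enumerate(schedule.phis):
        votes = cast_votes(field, radius_um, phi)
        votes = VoteField(scores=votes.scores, iteration_index=i,
                         spacing=votes.spacing,
                         voter_member_counts=votes.voter_member_counts)
        mass = votes.total_mass()
        expected = float(
            (field.magnitude * votes.voter_member_counts).sum()
        )
        phis_log.append(phi)
        mass_log.append(mass)
        expected_log.append(expected)
        logger.info("iteration %d: phi=%.4f rad, vote mass=%.6g", i, phi, mass)
        if i < schedule.n_iterations - 1:
            field = update_directions(field, votes, radius_um, phi)
    if votes is None:  # unreachable: schedule always has >= 1 pass
        raise RuntimeError("empty iteration schedule")
    if return_diagnostics:
        diag = VoteDiagnostics(phi=tuple(phis_log), vote_mass=tuple(mass_log),
                               expected_mass=tuple(expected_log))
        return votes, diag
    return votes
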