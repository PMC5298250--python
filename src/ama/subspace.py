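"""Rotation of a filter pair within its spanned subspace, and the geometry
of encoding uncertainty.

Because the response model attaches independent noise to each filter, two
filter pairs spanning the same 2-D subspace need not encode stimuli with
the same fidelity. To study this, a pair (f1, f2) is expressed in an
orthonormal basis E of its span (first basis vector aligned with f1, so a
zero rotation angle is the original pair). A pair is parameterized by its
rotation angle theta and angle difference delta:

    f1 = E (cos t, sin t)^T,   f2 = E (cos(t + d), sin(t + d))^T,

with cosine similarity rho = cos(delta). Rotating a pair preserves unit
norms, rho, and the spanned subspace. The expected-cost landscape over
(theta, delta) reveals which filters within a subspace encode best:
scaled additive noise makes the encoding unique up to a 180-degree
rotation (a contrast reversal of both filters), orthogonal pairs are
90-degree periodic, and with constant additive noise orthogonal pairs are
rotation invariant.

The mapping of the diagonal response-noise covariance from the filter
basis into E-coordinates (center B^-T r, covariance B^-T diag(sigma^2)
B^-1) yields the uncertainty ellipses whose alignment with the
level-conditioned stimulus distributions explains why correlated filters
with scaled additive noise can out-code orthogonal ones.

All angles at this interface are in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledStimulusSet
from .decoder import CostSpec, total_cost
from .response import FilterBank, NoiseModel

__all__ = [
    "SubspaceFrame",
    "RotationLandscape",
    "build_frame",
    "rotate_pair",
    "set_angle_difference",
    "gram_schmidt_orthogonalize",
    "matched_constant_noise",
    "rotation_cost_landscape",
    "uncertainty_ellipse",
]

_COLLINEAR_TOL = 0.999


@dataclass(frozen=True)
class SubspaceFrame:
    """Orthonormal basis E (d x 2) of a filter pair's span and the pair's
    2x2 coordinates B in that basis (E @ B reconstructs the pair)."""

    E: np.ndarray
    B: np.ndarray

    @property
    def rho(self) -> float:
        """Cosine similarity of the two filters, f1 . f2."""
        return float(self.B[:, 0] @ self.B[:, 1])

    @property
    def angle_difference_deg(self) -> float:
        return float(np.degrees(np.arccos(np.clip(self.rho, -1.0, 1.0))))

    def pair(self) -> tuple[np.ndarray, np.ndarray]:
        rec = self.E @ self.B
        return rec[:, 0], rec[:, 1]


@dataclass(frozen=True)
class RotationLandscape:
    """Expected cost over rotation angle (and optionally angle difference)."""

    theta_grid: np.ndarray  # degrees
    delta_grid: np.ndarray | None  # degrees, None for a fixed-pair sweep
    cost: np.ndarray  # (n_theta,) or (n_theta, n_delta)

    def min_cost(self) -> float:
        return float(self.cost.min())


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    t = np.radians(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s], [s, c]])


def build_frame(f1: np.ndarray, f2: np.ndarray) -> SubspaceFrame:
    """Orthonormalize (f1, f2) with the first basis vector along f1."""
    f1 = np.asarray(f1, dtype=float)
    f2 = np.asarray(f2, dtype=float)
    if abs(f1 @ f2) > _COLLINEAR_TOL:
        raise ValueError("filters are (near-)collinear; the span is not 2-D")
    e1 = f1 / np.linalg.norm(f1)
    resid = f2 - (e1 @ f2) * e1
    e2 = resid / np.linalg.norm(resid)
    E = np.column_stack([e1, e2])
    B = E.T @ np.column_stack([f1, f2])
    return SubspaceFrame(E, B)


def rotate_pair(frame: SubspaceFrame, theta_deg: float):
    """Rotate both filters by theta within the subspace; unit norms, mutual
    angle, and the spanned subspace are all preserved."""
    rotated = frame.E @ (_rotation_matrix(theta_deg) @ frame.B)
    return rotated[:, 0], rotated[:, 1]


def set_angle_difference(frame: SubspaceFrame, theta_deg: float, delta_deg: float):
    """Construct the pair at rotation angle theta and angle difference
    delta inside the frame's subspace; the pair's cosine similarity is
    cos(delta)."""
    if not 0.0 < delta_deg < 180.0:
        raise ValueError("delta must lie strictly between 0 and 180 degrees")
    t = np.radians(theta_deg)
    d = np.radians(delta_deg)
    f1 = frame.E @ np.array([np.cos(t), np.sin(t)])
    f2 = frame.E @ np.array([np.cos(t + d), np.sin(t + d)])
    return f1, f2


def gram_schmidt_orthogonalize(f1: np.ndarray, f2: np.ndarray):
    """Orthonormal pair with the same span: f1 kept, f2's component along
    f1 removed and renormalized."""
    frame = build_frame(f1, f2)
    return frame.E[:, 0].copy(), frame.E[:, 1].copy()


def matched_constant_noise(
    stimulus_set: LabeledStimulusSet,
    filters: FilterBank,
    scaled_noise: NoiseModel,
) -> NoiseModel:
    """Constant additive model with the same average noise power: its fixed
    variance is the mean of the scaled model's variances over every
    (stimulus, filter) entry of the training set."""
    if scaled_noise.fano_factor <= 0:
        raise ValueError("expected a scaled additive model (fano factor > 0)")
    means = stimulus_set.stimuli @ filters.filters
    return NoiseModel(0.0, float(scaled_noise.variances(means).mean()))


def rotation_cost_landscape(
    stimulus_set: LabeledStimulusSet,
    frame: SubspaceFrame,
    theta_grid: np.ndarray,
    noise: NoiseModel,
    cost_spec: CostSpec = CostSpec(),
    delta_grid: np.ndarray | None = None,
) -> RotationLandscape:
    """Expected cost (approx mode) over the rotation grid.

    With ``delta_grid=None`` the frame's own pair is rotated rigidly, so
    the angle difference stays at the pair's own value and theta = 0 is the
    input pair. Otherwise pairs are constructed at every (theta, delta)."""
    theta_grid = np.asarray(theta_grid, dtype=float)

    def cost_of(pair):
        return total_cost(
            stimulus_set, FilterBank.from_columns(*pair), noise, cost_spec
        )

    if delta_grid is None:
        cost = np.array([cost_of(rotate_pair(frame, t)) for t in theta_grid])
        return RotationLandscape(theta_grid, None, cost)

    delta_grid = np.asarray(delta_grid, dtype=float)
    cost = np.array(
        [
            [cost_of(set_angle_difference(frame, t, d)) for d in delta_grid]
            for t in theta_grid
        ]
    )
    return RotationLandscape(theta_grid, delta_grid, cost)


def uncertainty_ellipse(
    frame: SubspaceFrame, mean_response: np.ndarray, variances: np.ndarray
):
    """Map diagonal response noise from the filter basis to E-coordinates.

    Returns (center, covariance): center u = B^-T r and covariance
    U = B^-T diag(sigma^2) B^-1 of the stimulus-position estimate in the
    orthonormal basis, given mean responses r and noise variances sigma^2
    of the two filters."""
    if abs(frame.rho) > _COLLINEAR_TOL:
        raise np.linalg.LinAlgError(
            "filter pair too correlated to invert the basis-change matrix"
        )
    mean_response = np.asarray(mean_response, dtype=float)
    variances = np.asarray(variances, dtype=float)
    b_inv_t = np.linalg.inv(frame.B).T
    center = b_inv_t @ mean_response
    cov = b_inv_t @ np.diag(variances) @ b_inv_t.T
    return center, cov
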