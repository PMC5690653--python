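"""Minimum-area enclosing ellipse (Löwner–John ellipse) of a planar point set.

The tubule diameter estimator used throughout this package is the *minor axis*
of the smallest ellipse covering all pixel centers of a tubular cross-section.
The minor axis is the right statistic because an oblique planar cut through a
circular cylinder is an ellipse whose minor axis equals the cylinder diameter,
so the estimate is invariant to the tubule's tilt against the slicing plane.

The ellipse is computed with Khachiyan's iterative barycentric-coordinate
ascent for the minimum-volume enclosing ellipsoid, specialised to 2-D.  The
returned ellipse is rescaled so that the farthest generating point lies exactly
on its boundary, guaranteeing containment of every input point to floating
point accuracy while enlarging the area by at most a factor ``1 + O(tol)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Ellipse2D", "min_enclosing_ellipse", "minor_axis_length", "MveeError"]


class MveeError(RuntimeError):
    """Raised when the Khachiyan iteration fails to converge."""


@dataclass(frozen=True)
class Ellipse2D:
    """An ellipse ``(x - center)ᵀ A (x - center) ≤ 1``.

    Attributes
    ----------
    center : (2,) ndarray
        Ellipse center, in the units of the input points.
    semi_axes : (2,) ndarray
        Semi-axis lengths ``(a, b)`` with ``a ≥ b > 0``.
    angle_rad : float
        Orientation of the major axis, in radians, in ``(-π/2, π/2]``.
        Not meaningful when the ellipse is (near-)circular.
    shape_matrix : (2, 2) ndarray
        The symmetric positive-definite matrix ``A``; its eigenvalues are
        ``1/a²`` and ``1/b²``.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    angle_rad: float
    shape_matrix: np.ndarray

    @property
    def minor_axis(self) -> float:
        """Full minor-axis length ``2 b``."""
        return 2.0 * float(self.semi_axes[1])

    @property
    def major_axis(self) -> float:
        """Full major-axis length ``2 a``."""
        return 2.0 * float(self.semi_axes[0])

    @property
    def area(self) -> float:
        return math.pi * float(self.semi_axes[0] * self.semi_axes[1])

    def contains(self, points: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside the ellipse (within relative slack)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = pts - self.center
        q = np.einsum("ij,jk,ik->i", d, self.shape_matrix, d)
        return q <= 1.0 + rtol


def _ellipse_from_quadric(A: np.ndarray, center: np.ndarray, floor: float) -> Ellipse2D:
    """Build an Ellipse2D from the quadric matrix, flooring the axes."""
    A = 0.5 * (A + A.T)
    evals, evecs = np.linalg.eigh(A)  # ascending: evals[0] -> major axis
    evals = np.maximum(evals, 1e-300)
    axes = 1.0 / np.sqrt(evals)  # descending: axes[0] = a >= axes[1] = b
    half_floor = 0.5 * floor
    if floor > 0.0 and axes[1] < half_floor:
        axes = np.maximum(axes, half_floor)
        # rebuild A so shape_matrix stays consistent with the floored axes
        A = evecs @ np.diag(1.0 / axes**2) @ evecs.T
    major_vec = evecs[:, 0]
    angle = math.atan2(major_vec[1], major_vec[0])
    if angle <= -math.pi / 2:
        angle += math.pi
    elif angle > math.pi / 2:
        angle -= math.pi
    return Ellipse2D(
        center=np.asarray(center, dtype=float).copy(),
        semi_axes=axes.copy(),
        angle_rad=angle,
        shape_matrix=A,
    )


def _degenerate_ellipse(points: np.ndarray, floor: float) -> Ellipse2D:
    """Handle rank-deficient inputs: a single point or collinear points.

    The major axis spans the point extent along its principal direction
    (scaled by √2, the exact MVEE factor for a 1-D segment embedded in the
    plane); the minor axis is the caller-supplied floor, which for pixel-center
    inputs should be one pixel width.
    """
    c = points.mean(axis=0)
    d = points - c
    if len(points) == 1 or np.allclose(d, 0.0):
        half = max(0.5 * floor, 1e-12)
        A = np.eye(2) / half**2
        return _ellipse_from_quadric(A, c, floor)
    # collinear: principal direction from SVD
    _, s, vt = np.linalg.svd(d, full_matrices=False)
    u = vt[0]
    proj = d @ u
    half_major = max(math.sqrt(2.0) * float(np.abs(proj).max()), 1e-12)
    half_minor = max(0.5 * floor, 1e-12)
    V = np.column_stack([u, [-u[1], u[0]]])
    A = V @ np.diag([1.0 / half_major**2, 1.0 / half_minor**2]) @ V.T
    return _ellipse_from_quadric(A, c, 0.0)


def min_enclosing_ellipse(
    points: np.ndarray,
    tolerance: float = 1e-4,
    max_iter: int = 10_000,
    minor_axis_floor: float = 1.0,
) -> Ellipse2D:
    """Minimum-area ellipse enclosing a set of 2-D points.

    Parameters
    ----------
    points : (n, 2) array_like
        Point coordinates (pixel centers, in pixel or physical units).
    tolerance : float
        Khachiyan convergence tolerance on the barycentric optimality gap.
    max_iter : int
        Iteration cap; exceeding it raises :class:`MveeError`.
    minor_axis_floor : float
        Lower bound applied to the *full* minor axis, so that 1-pixel-thin
        sections report one pixel width rather than zero.  Set to ``0`` to
        disable.  Expressed in the same units as ``points``.

    Returns
    -------
    Ellipse2D
        Every input point satisfies ``(x-c)ᵀA(x-c) ≤ 1`` up to float round-off
        (the quadric is rescaled onto the farthest point after convergence).

    Raises
    ------
    ValueError
        On an empty point list or non-positive tolerance.
    MveeError
        If the iteration does not converge within ``max_iter`` steps.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.size == 0:
        raise ValueError("min_enclosing_ellipse requires at least one point")
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError(f"expected (n, 2) points, got shape {P.shape}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    P = np.unique(P, axis=0)

    if len(P) <= 2 or np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-12) < 2:
        return _degenerate_ellipse(P, minor_axis_floor)

    # only convex-hull vertices can support the ellipse; dropping interior
    # points leaves the optimum unchanged and shrinks the iteration
    if len(P) > 8:
        try:
            from scipy.spatial import ConvexHull, QhullError

            P = P[ConvexHull(P).vertices]
        except QhullError:
            return _degenerate_ellipse(P, minor_axis_floor)
    n, d = P.shape

    # Khachiyan barycentric ascent on lifted points Q = [x, y, 1], with
    # Wolfe–Atwood away steps for linear convergence
    Q = np.column_stack([P, np.ones(n)])
    u = np.full(n, 1.0 / n)
    dim = d + 1
    for _ in range(max_iter):
        X = Q.T @ (Q * u[:, None])
        try:
            Xinv = np.linalg.inv(X)
        except np.linalg.LinAlgError:
            X += 1e-12 * np.eye(dim)
            Xinv = np.linalg.inv(X)
        M = np.einsum("ij,jk,ik->i", Q, Xinv, Q)
        j_plus = int(np.argmax(M))
        eps_plus = M[j_plus] / dim - 1.0
        active = u > 1e-12
        masked = np.where(active, M, np.inf)
        j_minus = int(np.argmin(masked))
        eps_minus = 1.0 - M[j_minus] / dim
        if max(eps_plus, eps_minus) <= tolerance:
            break
        if eps_plus >= eps_minus:
            j, Mj = j_plus, M[j_plus]
            step = (Mj - dim) / (dim * (Mj - 1.0))
        else:
            j, Mj = j_minus, M[j_minus]
            drop = -u[j] / (1.0 - u[j])  # largest admissible away step
            if Mj > 1.0 + 1e-15:
                step = max((Mj - dim) / (dim * (Mj - 1.0)), drop)
            else:
                step = drop
        u *= 1.0 - step
        u[j] += step
        np.maximum(u, 0.0, out=u)
    else:
        raise MveeError(
            f"Khachiyan iteration did not converge within {max_iter} iterations "
            f"(tolerance {tolerance:g})"
        )

    c = P.T @ u
    cov = P.T @ (P * u[:, None]) - np.outer(c, c)
    A = np.linalg.inv(cov) / d

    # rescale so the farthest point sits exactly on the boundary: guarantees
    # containment and can only shrink the ellipse toward the optimum
    diff = P - c
    qmax = float(np.einsum("ij,jk,ik->i", diff, A, diff).max())
    if qmax > 0:
        A = A / qmax

    return _ellipse_from_quadric(A, c, minor_axis_floor)


def minor_axis_length(ellipse: Ellipse2D, spacing_um: float = 1.0) -> float:
    """Full minor-axis length converted to μm.

    ``spacing_um`` is the physical pixel pitch when the ellipse was fitted in
    pixel units; pass 1.0 if the points were already in μm.
    """
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    return ellipse.minor_axis * spacing_um
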