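"""Rigid transforms and dense displacement fields (world mm throughout)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial.transform import Rotation

from .grid import Grid

__all__ = ["RigidTransform", "DisplacementField", "InversionError"]


class InversionError(RuntimeError):
    """Fixed-point inversion of a displacement field failed to converge."""


@dataclass(frozen=True)
class RigidTransform:
    """Rigid map ``x -> R (x - c) + c + t`` in world mm.

    The semantic direction (which frame's points go in) is a property of the
    producing operation and is documented there; the object itself is just
    the map.
    """

    rotation: np.ndarray
    translation: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_params(
        cls,
        angles_deg: tuple[float, float, float],
        translation_mm: tuple[float, float, float],
        center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        """Extrinsic x-y-z Euler angles in degrees plus a translation."""
        R = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
        return cls(R, np.asarray(translation_mm, float), np.asarray(center_mm, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return (p - self.center) @ self.rotation.T + self.center + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            self.rotation.T, -self.rotation.T @ self.translation, self.center
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the map equivalent to ``self(other(x))`` (center 0 form)."""
        M = self.as_matrix() @ other.as_matrix()
        return RigidTransform.from_matrix(M)

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = (
            self.translation + self.center - self.rotation @ self.center
        )
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return cls(M[:3, :3], M[:3, 3], np.zeros(3))

    def angles_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler("xyz", degrees=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"matrix": self.as_matrix().tolist()}, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "RigidTransform":
        return cls.from_matrix(np.asarray(json.loads(Path(path).read_text())["matrix"]))


@dataclass
class DisplacementField:
    """Dense per-voxel 3-vector field v (mm) on a reference grid.

    With the ``"pre->post"`` direction tag, a point ``x`` on the reference
    (pre-treatment) grid maps to ``x + v(x)`` in the post-treatment world
    frame.  The field is zero outside its stated region of support.
    """

    data: np.ndarray
    grid: Grid
    direction: str = "pre->post"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"field shape {self.data.shape} != grid shape {self.grid.shape} + (3,)"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("displacement field contains non-finite values")

    def _interpolator(self) -> RegularGridInterpolator:
        # linear extrapolation beyond the grid keeps the field continuous at
        # the boundary (the stored data already decays to zero at its support
        # edge), which fixed-point inversion relies on
        return RegularGridInterpolator(
            self.grid.axes(), self.data, bounds_error=False, fill_value=None
        )

    def evaluate(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear sample of v at arbitrary world points."""
        return self._interpolator()(np.atleast_2d(np.asarray(points_mm, float)))

    def transform_points(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, float))
        return p + self.evaluate(p)

    def invert_points(
        self,
        points_mm: np.ndarray,
        max_iter: int = 50,
        tol_mm: float = 0.05,
        damping: float = 0.5,
    ) -> np.ndarray:
        """Find x such that x + v(x) = p for each target point p.

        Damped fixed-point iteration ``x <- x + damping * (p - v(x) - x)``
        (damping widens the convergence region to strongly sheared but still
        diffeomorphic fields); raises :class:`InversionError` if the residual
        has not dropped below ``tol_mm`` within ``max_iter`` sweeps.
        """
        p = np.atleast_2d(np.asarray(points_mm, float))
        interp = self._interpolator()
        x = p - interp(p)
        for _ in range(max_iter):
            resid = p - interp(x) - x
            step = np.abs(resid).max()
            x = x + damping * resid
            if step < tol_mm:
                return x
        raise InversionError(
            f"fixed-point inversion did not converge (last step {step:.3f} mm)"
        )

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + grad v) at every voxel (central differences)."""
        J = np.empty((*self.grid.shape, 3, 3))
        for comp in range(3):
            g = np.gradient(self.data[..., comp], *self.grid.spacing)
            for ax in range(3):
                J[..., comp, ax] = g[ax]
        J += np.eye(3)
        return np.linalg.det(J)

    def max_magnitude(self) -> float:
        return float(np.linalg.norm(self.data, axis=-1).max())
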