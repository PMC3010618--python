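"""Shared domain types for flexibility-signal and rigidity-image comparison.

All matrices and signals are documented 1-based (positions ``j``, ``k``,
``i`` run from 1) but stored 0-based in numpy arrays.  Error messages and
on-disk coordinates use 1-based positions; see :mod:`flexcompare.io_formats`.

Gaps are always explicit boolean masks in memory.  Off-scale sentinel values
exist only at the file-format boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "SignalKind",
    "Direction",
    "FlexibilitySignal",
    "RigidityStateEnsemble",
    "SusceptibilityImage",
    "SimilarityTransform",
    "PairDistance",
    "DTWResult",
    "validate_ensemble",
]


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


class SignalKind(enum.Enum):
    IDF = "idf"
    HYDROPHOBICITY = "hydrophobicity"
    OTHER = "other"


class Direction(enum.Enum):
    A_TO_B = "a_to_b"
    B_TO_A = "b_to_a"
    SYMMETRIZED = "symmetrized"


@dataclass
class FlexibilitySignal:
    """An ordered 1D flexibility signal over torsion-angle positions.

    For IDF-like signals there are two entries per residue (PHI and PSI), so
    ``n == 2 * residue_count``; for hydrophobicity signals one entry per
    residue.  ``gap_mask[i]`` is True where the value is undefined/off-scale.
    """

    protein_id: str
    values: np.ndarray
    kind: SignalKind = SignalKind.OTHER
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValidationError(
                f"signal {self.protein_id!r}: values must be a non-empty 1D sequence"
            )
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.size, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.values.shape:
            raise ValidationError(
                f"signal {self.protein_id!r}: gap_mask length {self.gap_mask.size} "
                f"!= values length {self.values.size}"
            )
        nongap = self.values[~self.gap_mask]
        if nongap.size and not np.all(np.isfinite(nongap)):
            raise ValidationError(
                f"signal {self.protein_id!r}: non-gap values must be finite"
            )
        if self.kind is SignalKind.IDF and nongap.size and np.any(nongap < 0):
            pos = int(np.flatnonzero(~self.gap_mask)[np.argmax(nongap < 0)])
            raise ValidationError(
                f"signal {self.protein_id!r}: IDF values must be >= 0 "
                f"(position {pos + 1})"
            )

    @property
    def n(self) -> int:
        return int(self.values.size)

    def compressed(self) -> np.ndarray:
        """Non-gap values in order (the sequence DTW actually aligns)."""
        return self.values[~self.gap_mask]


def _check_state_matrix(mat: np.ndarray, index: int, m: int | None) -> int:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError(f"realization {index + 1}: matrix is not square")
    if m is not None and mat.shape[0] != m:
        raise ValidationError(
            f"realization {index + 1}: dimension {mat.shape[0]} != {m} of realization 1"
        )
    bad = ~np.isin(mat, (-1, 0, 1))
    if bad.any():
        j, k = np.argwhere(bad)[0]
        raise ValidationError(
            f"realization {index + 1}: entry {mat[j, k]} at ({j + 1},{k + 1}) "
            "not in {-1, 0, +1}"
        )
    asym = mat != mat.T
    if asym.any():
        j, k = np.argwhere(asym)[0]
        raise ValidationError(
            f"realization {index + 1}: asymmetric at ({j + 1},{k + 1})"
        )
    if np.any(np.diag(mat) != -1):
        j = int(np.flatnonzero(np.diag(mat) != -1)[0])
        raise ValidationError(
            f"realization {index + 1}: diagonal entry at ({j + 1},{j + 1}) must be -1"
        )
    return int(mat.shape[0])


@dataclass
class RigidityStateEnsemble:
    """An ensemble of symmetric rigidity-state matrices with entries in {-1,0,+1}.

    State semantics per pair (j, k): -1 = same rigid region (rigidly
    correlated), +1 = spanned by one flexible region (flexibly correlated),
    0 = flexible but uncorrelated (dangling end).  The diagonal is fixed at
    -1: a position is trivially rigid with itself.
    """

    protein_id: str
    realizations: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.realizations:
            raise ValidationError(f"ensemble {self.protein_id!r}: no realizations")
        self.realizations = [
            np.asarray(r, dtype=np.int8) for r in self.realizations
        ]
        m = None
        for i, mat in enumerate(self.realizations):
            m = _check_state_matrix(mat, i, m) if m is None else m
            _check_state_matrix(mat, i, m)

    @property
    def m(self) -> int:
        return int(self.realizations[0].shape[0])

    @property
    def n_realizations(self) -> int:
        return len(self.realizations)


def validate_ensemble(ens: RigidityStateEnsemble) -> RigidityStateEnsemble:
    """Re-check all ensemble invariants; returns the input unchanged if valid.

    Useful after in-place mutation of the realization arrays, which the
    dataclass constructor cannot see.
    """
    if not ens.realizations:
        raise ValidationError(f"ensemble {ens.protein_id!r}: no realizations")
    m = None
    for i, mat in enumerate(ens.realizations):
        size = _check_state_matrix(np.asarray(mat), i, m)
        m = size if m is None else m
    return ens


@dataclass
class SusceptibilityImage:
    """A symmetric m x m image of rigidity-state variances chi in [0, 1].

    ``gap_mask[j, k]`` is True where the pixel is undefined.  Symmetry is an
    invariant of susceptibility matrices as computed or read from disk, but a
    registered (warped) image is generally no longer symmetric; symmetry is
    therefore checked via :meth:`check_symmetric`, which readers and the
    susceptibility computation call, rather than unconditionally on
    construction.
    """

    protein_id: str
    chi: np.ndarray
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.ndim != 2 or self.chi.shape[0] != self.chi.shape[1]:
            raise ValidationError(
                f"image {self.protein_id!r}: chi must be a square matrix"
            )
        if self.chi.shape[0] < 1:
            raise ValidationError(f"image {self.protein_id!r}: empty matrix")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.chi.shape, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.gap_mask.shape != self.chi.shape:
            raise ValidationError(
                f"image {self.protein_id!r}: gap_mask shape {self.gap_mask.shape} "
                f"!= chi shape {self.chi.shape}"
            )
        nongap = self.chi[~self.gap_mask]
        if nongap.size:
            if not np.all(np.isfinite(nongap)):
                raise ValidationError(
                    f"image {self.protein_id!r}: non-gap pixels must be finite"
                )
            if nongap.min() < -1e-12 or nongap.max() > 1 + 1e-12:
                j, k = np.argwhere(
                    ~self.gap_mask & ((self.chi < 0) | (self.chi > 1))
                )[0]
                raise ValidationError(
                    f"image {self.protein_id!r}: chi[{j + 1},{k + 1}] = "
                    f"{self.chi[j, k]} outside [0, 1]"
                )

    @property
    def m(self) -> int:
        return int(self.chi.shape[0])

    def check_symmetric(self, tol: float = 1e-9) -> None:
        """Assert chi symmetric on mutually non-gap pixels and gap_mask symmetric."""
        if np.any(self.gap_mask != self.gap_mask.T):
            j, k = np.argwhere(self.gap_mask != self.gap_mask.T)[0]
            raise ValidationError(
                f"image {self.protein_id!r}: gap_mask asymmetric at ({j + 1},{k + 1})"
            )
        both = ~self.gap_mask & ~self.gap_mask.T
        diff = np.where(both, np.abs(self.chi - self.chi.T), 0.0)
        worst = float(diff.max()) if diff.size else 0.0
        if worst > tol:
            j, k = np.unravel_index(int(np.argmax(diff)), diff.shape)
            raise ValidationError(
                f"image {self.protein_id!r}: chi asymmetric at ({j + 1},{k + 1}) "
                f"(|chi_jk - chi_kj| = {worst:.3g} > {tol:.3g})"
            )


@dataclass
class SimilarityTransform:
    """Scale + rotation + translation in (x, y) pixel coordinates.

    Maps a point p in the moving image's frame to ``s * R(theta) @ p + t`` in
    the base image's frame.  x is the column index, y the row index, origin
    at the top-left pixel, 0-based internally.  Shape-preserving: straight
    lines stay straight and parallel lines stay parallel.
    """

    scale: float = 1.0
    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.scale > 0):
            raise ValidationError(f"scale must be > 0, got {self.scale}")
        self.translation = (float(self.translation[0]), float(self.translation[1]))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on column vectors (x, y, 1)."""
        c = self.scale * math.cos(self.rotation)
        s = self.scale * math.sin(self.rotation)
        tx, ty = self.translation
        return np.array([[c, -s, tx], [s, c, ty], [0.0, 0.0, 1.0]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:2, :2].T + np.asarray(self.translation)
        return out

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        inv_rot = -self.rotation
        c = inv_scale * math.cos(inv_rot)
        s = inv_scale * math.sin(inv_rot)
        tx, ty = self.translation
        return SimilarityTransform(
            scale=inv_scale,
            rotation=inv_rot,
            translation=(-(c * tx - s * ty), -(s * tx + c * ty)),
        )

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "SimilarityTransform":
        mat = np.asarray(mat, dtype=float)
        scale = math.hypot(mat[0, 0], mat[1, 0])
        if scale <= 0:
            raise ValidationError("degenerate transform matrix (zero scale)")
        rotation = math.atan2(mat[1, 0], mat[0, 0])
        return cls(scale=scale, rotation=rotation, translation=(mat[0, 2], mat[1, 2]))


@dataclass
class PairDistance:
    """The two-component similarity record for a protein pair.

    ``euclidean`` is the sum of squared pixel differences over mutually
    defined pixels divided by m**2 (conventionally labelled "Euclidean
    distance" in output tables although no square root is taken).
    ``gap_measure`` is the union-gap pixel count divided by m**2.
    """

    id_a: str
    id_b: str
    euclidean: float
    gap_measure: float
    direction: Direction = Direction.SYMMETRIZED

    def __post_init__(self) -> None:
        self.euclidean = float(self.euclidean)
        self.gap_measure = float(self.gap_measure)
        if self.euclidean < 0:
            raise ValidationError(f"euclidean must be >= 0, got {self.euclidean}")
        if not (0.0 <= self.gap_measure <= 1.0):
            raise ValidationError(
                f"gap_measure must be in [0, 1], got {self.gap_measure}"
            )

    def canonical(self) -> "PairDistance":
        """For SYMMETRIZED records, order ids lexicographically."""
        if self.direction is Direction.SYMMETRIZED and self.id_b < self.id_a:
            return PairDistance(
                self.id_b, self.id_a, self.euclidean, self.gap_measure, self.direction
            )
        return self

    @property
    def pair_label(self) -> str:
        a, b = sorted((self.id_a, self.id_b))
        return f"{a}-{b}"


_DTW_STEPS = {(0, 1), (1, 0), (1, 1)}


@dataclass
class DTWResult:
    """Result of a dynamic-time-warping alignment.

    ``path`` is 0-based internally; documented positions are 1-based, so the
    path runs from (1, 1) to (n, m_len) in document coordinates.
    """

    distance: float
    path: list[tuple[int, int]]
    n: int
    m_len: int

    def __post_init__(self) -> None:
        self.distance = float(self.distance)
        if self.distance < 0:
            raise ValidationError(f"DTW distance must be >= 0, got {self.distance}")
        if not self.path:
            raise ValidationError("DTW path is empty")
        if self.path[0] != (0, 0):
            raise ValidationError(f"DTW path must start at (1,1), got {self.path[0]}")
        if self.path[-1] != (self.n - 1, self.m_len - 1):
            raise ValidationError(
                f"DTW path must end at ({self.n},{self.m_len}), got {self.path[-1]}"
            )
        for (i0, j0), (i1, j1) in zip(self.path, self.path[1:]):
            if (i1 - i0, j1 - j0) not in _DTW_STEPS:
                raise ValidationError(
                    f"invalid DTW step from ({i0 + 1},{j0 + 1}) to ({i1 + 1},{j1 + 1})"
                )
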