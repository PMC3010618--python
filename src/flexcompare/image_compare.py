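"""Registration-based comparison of susceptibility images.

Pipeline per ordered (base, moving) pair: fill gap pixels by iterative
neighbor averaging, resize the moving image bicubically to the base
dimensions, fit a similarity transform to control points (or start from the
identity), refine it by local search minimizing the mean-squared pixel
distance, warp, and compute two measures:

* ``image_distance`` — sum of squared pixel differences over pixels where
  both images are defined, divided by m**2 (the denominator is the full
  image size, not the defined-pixel count).
* ``gap_measure`` — count of pixels where either image has a gap, divided
  by m**2.

``compare_pair`` runs both directions (roles inverted) and averages each
measure arithmetically into one SYMMETRIZED record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import transform as sk_transform

from .core import (
    Direction,
    PairDistance,
    SimilarityTransform,
    SusceptibilityImage,
    ValidationError,
)

__all__ = [
    "interpolate_gaps",
    "resize_image",
    "fit_similarity",
    "refine_by_maximum_similarity",
    "warp_image",
    "image_distance",
    "gap_measure",
    "register_onto",
    "compare_pair",
    "RegistrationResult",
]

ControlPoints = list[tuple[tuple[float, float], tuple[float, float]]]

_NEIGHBOR_KERNEL = np.ones((3, 3))
_NEIGHBOR_KERNEL[1, 1] = 0.0


def interpolate_gaps(img: SusceptibilityImage) -> SusceptibilityImage:
    """Fill gap pixels with the arithmetic mean of their non-gap 8-connected
    neighbors, sweeping Jacobi-style (values frozen per sweep) until no gap
    pixel remains.  The returned image has fully defined ``chi`` but keeps
    the original ``gap_mask`` so the gap measure still sees original gaps.
    """
    if img.gap_mask.all():
        raise ValidationError(f"image {img.protein_id!r}: all pixels are gaps")
    if not img.gap_mask.any():
        return SusceptibilityImage(
            img.protein_id, img.chi.copy(), img.gap_mask.copy()
        )
    chi = img.chi.copy()
    undefined = img.gap_mask.copy()
    while undefined.any():
        defined = (~undefined).astype(float)
        sums = ndimage.convolve(
            np.where(undefined, 0.0, chi), _NEIGHBOR_KERNEL, mode="constant"
        )
        counts = ndimage.convolve(defined, _NEIGHBOR_KERNEL, mode="constant")
        fill = undefined & (counts > 0)
        chi[fill] = sums[fill] / counts[fill]
        undefined &= ~fill
    return SusceptibilityImage(img.protein_id, chi, img.gap_mask.copy())


def _bicubic_weights(src_len: int, dst_len: int) -> np.ndarray:
    """Row-resampling matrix W (dst_len x src_len) for cubic-convolution
    interpolation (Keys kernel, a = -0.5) with edge replication and the
    pixel-center mapping src = (dst + 0.5) * src_len/dst_len - 0.5.

    Unlike prefiltered B-spline resampling, the 4-tap kernel is local, so it
    reproduces linear ramps exactly away from the image borders.
    """
    a = -0.5
    d = np.arange(dst_len)
    src = (d + 0.5) * (src_len / dst_len) - 0.5
    base = np.floor(src).astype(int)
    frac = src - base
    W = np.zeros((dst_len, src_len))
    for off in (-1, 0, 1, 2):
        x = np.abs(frac - off)
        w = np.where(
            x <= 1,
            (a + 2) * x**3 - (a + 3) * x**2 + 1,
            np.where(x < 2, a * (x**3 - 5 * x**2 + 8 * x - 4), 0.0),
        )
        idx = np.clip(base + off, 0, src_len - 1)
        np.add.at(W, (d, idx), w)
    return W


def resize_image(img: SusceptibilityImage, target_m: int) -> SusceptibilityImage:
    """Bicubic (cubic-convolution) resample of chi to target_m x target_m;
    the gap mask is resampled nearest-neighbor.  Values are clamped to
    [0, 1] (bicubic can overshoot).  Requires a gap-interpolated chi
    (bicubic through sentinel values would be meaningless)."""
    if target_m < 2:
        raise ValidationError(f"target size must be >= 2, got {target_m}")
    if np.any(np.isnan(img.chi)):
        raise ValidationError("chi contains NaN; run interpolate_gaps first")
    if target_m == img.m:
        return SusceptibilityImage(img.protein_id, img.chi.copy(), img.gap_mask.copy())
    W = _bicubic_weights(img.m, target_m)
    chi = W @ img.chi @ W.T
    src = (np.arange(target_m) + 0.5) * (img.m / target_m) - 0.5
    nearest = np.clip(np.rint(src).astype(int), 0, img.m - 1)
    mask = img.gap_mask[np.ix_(nearest, nearest)]
    return SusceptibilityImage(img.protein_id, np.clip(chi, 0.0, 1.0), mask)


def rescale_points(
    points: np.ndarray, source_m: int, target_m: int
) -> np.ndarray:
    """Map 0-based pixel coordinates through the resize used above
    (pixel-center convention: src = (dst + 0.5) * source/target - 0.5)."""
    pts = np.asarray(points, dtype=float)
    return (pts + 0.5) * (target_m / source_m) - 0.5


def fit_similarity(points: ControlPoints) -> SimilarityTransform:
    """Least-squares similarity transform mapping moving points onto base
    points; exact when given 2 distinct noiseless pairs."""
    if len(points) < 2:
        raise ValidationError(
            f"at least 2 control points are required, got {len(points)}"
        )
    src = np.array([p[0] for p in points], dtype=float)
    dst = np.array([p[1] for p in points], dtype=float)
    if np.allclose(src, src[0]):
        raise ValidationError("degenerate control points: moving points coincide")
    if hasattr(sk_transform.SimilarityTransform, "from_estimate"):
        tf = sk_transform.SimilarityTransform.from_estimate(src, dst)
        ok = bool(tf)
    else:  # scikit-image < 0.26
        tf = sk_transform.SimilarityTransform()
        ok = tf.estimate(src, dst)
    if not ok or not np.all(np.isfinite(tf.params)):
        raise ValidationError("similarity transform estimation failed")
    return SimilarityTransform.from_matrix(tf.params)


def warp_image(
    moving: SusceptibilityImage,
    tf: SimilarityTransform,
    target_m: int | None = None,
) -> SusceptibilityImage:
    """Resample the moving image into the base frame under ``tf`` (which maps
    moving coordinates to base coordinates).  Bicubic for chi; pixels whose
    source location falls outside the moving image become gaps, and original
    gap pixels are carried along nearest-neighbor."""
    target_m = target_m or moving.m
    inv = sk_transform.SimilarityTransform(matrix=tf.inverse().matrix)
    chi = sk_transform.warp(
        moving.chi,
        inverse_map=inv,
        output_shape=(target_m, target_m),
        order=3,
        mode="edge",
        preserve_range=True,
    )
    carried = (
        sk_transform.warp(
            moving.gap_mask.astype(float),
            inverse_map=inv,
            output_shape=(target_m, target_m),
            order=0,
            mode="constant",
            cval=1.0,
            preserve_range=True,
        )
        > 0.5
    )
    # pixels sampling outside the moving extent are undefined
    xs, ys = np.meshgrid(np.arange(target_m), np.arange(target_m), indexing="xy")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = tf.inverse().apply(coords)
    outside = (
        (src[:, 0] < -0.5)
        | (src[:, 0] > moving.m - 0.5)
        | (src[:, 1] < -0.5)
        | (src[:, 1] > moving.m - 0.5)
    ).reshape(target_m, target_m)
    return SusceptibilityImage(
        moving.protein_id, np.clip(chi, 0.0, 1.0), carried | outside
    )


def image_distance(
    base: SusceptibilityImage, registered: SusceptibilityImage
) -> float:
    """Sum of squared differences over mutually defined pixels, divided by
    m**2 (full image size, as printed — gaps shrink the sum, not the
    denominator; the gap measure accounts for gap burden separately)."""
    if base.m != registered.m:
        raise ValidationError(
            f"dimension mismatch: base {base.m} vs registered {registered.m}"
        )
    both = ~base.gap_mask & ~registered.gap_mask
    diff = base.chi[both] - registered.chi[both]
    return float(np.sum(diff**2) / base.m**2)


def gap_measure(base: SusceptibilityImage, registered: SusceptibilityImage) -> float:
    """Count of pixels where either image has a gap, divided by m**2."""
    if base.m != registered.m:
        raise ValidationError(
            f"dimension mismatch: base {base.m} vs registered {registered.m}"
        )
    return float(np.sum(base.gap_mask | registered.gap_mask) / base.m**2)


def refine_by_maximum_similarity(
    moving: SusceptibilityImage,
    base: SusceptibilityImage,
    init: SimilarityTransform,
    *,
    max_evals: int = 400,
) -> SimilarityTransform:
    """Deterministic coordinate-wise local search over (scale, rotation, tx,
    ty) minimizing ``image_distance`` of the warped moving image against the
    base, starting from ``init``.  Step sizes shrink by half whenever no
    parameter move improves; never returns a transform worse than ``init``."""
    if moving.m != base.m:
        raise ValidationError(
            f"refinement requires equal sizes, got {moving.m} and {base.m}"
        )

    evals = 0

    def objective(tf: SimilarityTransform) -> float:
        nonlocal evals
        evals += 1
        return image_distance(base, warp_image(moving, tf, base.m))

    best = init
    best_val = objective(best)
    steps = np.array([0.02, 0.02, 1.0, 1.0])  # scale, rotation, tx, ty
    min_steps = np.array([1e-3, 1e-3, 0.05, 0.05])

    while evals < max_evals and np.any(steps > min_steps):
        improved = False
        for k in range(4):
            for sign in (+1.0, -1.0):
                s, r = best.scale, best.rotation
                tx, ty = best.translation
                if k == 0:
                    s = s + sign * steps[0]
                    if s <= 0:
                        continue
                elif k == 1:
                    r = r + sign * steps[1]
                elif k == 2:
                    tx = tx + sign * steps[2]
                else:
                    ty = ty + sign * steps[3]
                cand = SimilarityTransform(s, r, (tx, ty))
                val = objective(cand)
                if val < best_val - 1e-15:
                    best, best_val = cand, val
                    improved = True
                if evals >= max_evals:
                    break
            if evals >= max_evals:
                break
        if not improved:
            steps = steps / 2.0
    return best


@dataclass
class RegistrationResult:
    """Diagnostics for one directional registration."""

    base_id: str
    moving_id: str
    transform: SimilarityTransform
    initial_transform: SimilarityTransform
    euclidean: float
    gap: float
    initial_euclidean: float
    registered: SusceptibilityImage = field(repr=False, default=None)


def register_onto(
    base: SusceptibilityImage,
    moving: SusceptibilityImage,
    control_points: ControlPoints | None = None,
    *,
    refine: bool = True,
    max_evals: int = 400,
) -> RegistrationResult:
    """Full directional chain: gap interpolation, resize to base dimensions,
    landmark fit (or identity when no control points are given), optional
    refinement, warp, and both measures.

    Control-point moving coordinates refer to the moving image's original
    pixel grid and are rescaled internally after the resize.
    """
    base_f = interpolate_gaps(base) if base.gap_mask.any() else base
    moving_f = interpolate_gaps(moving) if moving.gap_mask.any() else moving
    source_m = moving_f.m
    resized = resize_image(moving_f, base.m)
    if control_points is not None:
        scaled = [
            (
                tuple(rescale_points(np.array(p_mov), source_m, base.m)),
                p_base,
            )
            for p_mov, p_base in control_points
        ]
        init = fit_similarity(scaled)
    else:
        init = SimilarityTransform()
    init_dist = image_distance(base, warp_image(resized, init, base.m))
    tf = (
        refine_by_maximum_similarity(resized, base_f, init, max_evals=max_evals)
        if refine
        else init
    )
    registered = warp_image(resized, tf, base.m)
    return RegistrationResult(
        base_id=base.protein_id,
        moving_id=moving.protein_id,
        transform=tf,
        initial_transform=init,
        euclidean=image_distance(base, registered),
        gap=gap_measure(base, registered),
        initial_euclidean=init_dist,
        registered=registered,
    )


def compare_pair(
    x: SusceptibilityImage,
    y: SusceptibilityImage,
    cp_xy: ControlPoints | None = None,
    cp_yx: ControlPoints | None = None,
    *,
    refine: bool = True,
    max_evals: int = 400,
) -> PairDistance:
    """Symmetrized comparison: register y onto base x with ``cp_xy`` (moving
    = y), invert the roles with ``cp_yx`` (moving = x), and average the two
    Euclidean distances and the two gap measures arithmetically."""
    fwd = register_onto(x, y, cp_xy, refine=refine, max_evals=max_evals)
    rev = register_onto(y, x, cp_yx, refine=refine, max_evals=max_evals)
    return PairDistance(
        id_a=x.protein_id,
        id_b=y.protein_id,
        euclidean=0.5 * (fwd.euclidean + rev.euclidean),
        gap_measure=0.5 * (fwd.gap + rev.gap),
        direction=Direction.SYMMETRIZED,
    ).canonical()
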