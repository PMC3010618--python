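"""Synthetic generator of distance-constraint-model-like inputs.

Emulates the picture in which sets of residues become rigidly or flexibly
correlated as constraints form and break across an ensemble: block-structured
state matrices with per-realization activity toggling, piecewise-varying
nonnegative 1D signals, and warped/noised image pairs with exact control
points for registration tests.

Randomness is split into two substreams so that family members share the
same realization/noise draws (a *family* stream seeded only by ``seed``)
while block-boundary mutations are member-specific (a *member* stream seeded
by ``(seed, member_index)``).  With ``mutation_rate == 0`` all members are
therefore bit-identical.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    FlexibilitySignal,
    RigidityStateEnsemble,
    SignalKind,
    SimilarityTransform,
    SusceptibilityImage,
    ValidationError,
)
from .susceptibility import compute_susceptibility

__all__ = [
    "BlockKind",
    "Block",
    "SyntheticFamilySpec",
    "generate_ensemble",
    "generate_idf_signal",
    "generate_registered_pair",
]

_FAMILY_STREAM_ENSEMBLE = 2718
_FAMILY_STREAM_SIGNAL = 1618
_FAMILY_STREAM_PAIR = 4242
_MEMBER_STREAM = 31


class BlockKind(enum.Enum):
    RIGID = "rigid"
    FLEXIBLE = "flexible"


@dataclass(frozen=True)
class Block:
    """A correlated region [start, end], 1-based inclusive."""

    start: int
    end: int
    kind: BlockKind


def _as_block(b) -> Block:
    if isinstance(b, Block):
        return b
    start, end, kind = b
    if isinstance(kind, str):
        kind = BlockKind(kind.lower())
    return Block(int(start), int(end), kind)


@dataclass(frozen=True)
class SyntheticFamilySpec:
    n_proteins: int
    m: int
    n_realizations: int
    blocks: tuple[Block, ...]
    flip_prob: float = 0.0
    mutation_rate: float = 0.0
    gap_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", tuple(_as_block(b) for b in self.blocks)
        )
        if self.n_proteins < 1 or self.m < 1 or self.n_realizations < 1:
            raise ValidationError(
                "n_proteins, m and n_realizations must all be >= 1"
            )
        for name in ("flip_prob", "mutation_rate", "gap_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        prev_end = 0
        for b in sorted(self.blocks, key=lambda b: b.start):
            if not (1 <= b.start <= b.end <= self.m):
                raise ValidationError(
                    f"block [{b.start}, {b.end}] outside [1, {self.m}]"
                )
            if b.start <= prev_end:
                raise ValidationError(
                    f"block [{b.start}, {b.end}] overlaps a previous block"
                )
            prev_end = b.end


def _member_blocks(spec: SyntheticFamilySpec, member_index: int) -> list[Block]:
    """Member-specific blocks: each block's boundaries shift with probability
    ``mutation_rate``, by a discrete offset drawn from the member stream."""
    rng = np.random.default_rng([spec.seed, _MEMBER_STREAM, member_index])
    max_shift = max(1, round(0.08 * spec.m))
    jittered = []
    for b in spec.blocks:
        mutate = rng.random() < spec.mutation_rate
        ds = int(rng.integers(-max_shift, max_shift + 1))
        de = int(rng.integers(-max_shift, max_shift + 1))
        if mutate:
            start = int(np.clip(b.start + ds, 1, spec.m))
            end = int(np.clip(b.end + de, 1, spec.m))
            if end < start:
                start, end = end, start
            jittered.append(Block(start, end, b.kind))
        else:
            jittered.append(b)
    # resolve any overlap introduced by jitter
    jittered.sort(key=lambda b: (b.start, b.end))
    resolved: list[Block] = []
    for b in jittered:
        if resolved and b.start <= resolved[-1].end:
            start = resolved[-1].end + 1
            if start > b.end:
                continue
            b = Block(start, b.end, b.kind)
        resolved.append(b)
    return resolved


def generate_ensemble(
    spec: SyntheticFamilySpec, member_index: int
) -> RigidityStateEnsemble:
    """Block-structured state matrices: per realization, each block is active
    with probability ``1 - flip_prob``; pairs inside an active RIGID block
    get -1, inside an active FLEXIBLE block +1, all other off-diagonal pairs
    0.  The diagonal is always -1.  Deterministic per (seed, member_index).
    """
    if member_index < 0 or member_index >= spec.n_proteins:
        raise ValidationError(
            f"member_index {member_index} outside [0, {spec.n_proteins - 1}]"
        )
    blocks = _member_blocks(spec, member_index)
    rng = np.random.default_rng([spec.seed, _FAMILY_STREAM_ENSEMBLE])
    active = rng.random((spec.n_realizations, len(spec.blocks))) >= spec.flip_prob
    realizations = []
    for r in range(spec.n_realizations):
        mat = np.zeros((spec.m, spec.m), dtype=np.int8)
        for b_idx, b in enumerate(blocks):
            if not active[r, b_idx]:
                continue
            val = -1 if b.kind is BlockKind.RIGID else 1
            mat[b.start - 1 : b.end, b.start - 1 : b.end] = val
        np.fill_diagonal(mat, -1)
        realizations.append(mat)
    return RigidityStateEnsemble(
        protein_id=f"member{member_index}", realizations=realizations
    )


def generate_idf_signal(
    spec: SyntheticFamilySpec, member_index: int
) -> FlexibilitySignal:
    """Nonnegative piecewise signal of length m: near-zero inside RIGID
    blocks, elevated with high-frequency variation inside FLEXIBLE blocks,
    a low baseline elsewhere.  Noise and gap positions come from the family
    stream; only block boundaries differ between members."""
    if member_index < 0 or member_index >= spec.n_proteins:
        raise ValidationError(
            f"member_index {member_index} outside [0, {spec.n_proteins - 1}]"
        )
    blocks = _member_blocks(spec, member_index)
    rng = np.random.default_rng([spec.seed, _FAMILY_STREAM_SIGNAL])
    hf_noise = rng.random(spec.m)
    values = 0.15 + 0.05 * hf_noise
    for b in blocks:
        sl = slice(b.start - 1, b.end)
        if b.kind is BlockKind.RIGID:
            values[sl] = 0.005 + 0.01 * hf_noise[sl]
        else:
            values[sl] = 0.55 + 0.4 * hf_noise[sl]
    gap_mask = rng.random(spec.m) < spec.gap_frac
    if gap_mask.all():
        gap_mask[0] = False
    return FlexibilitySignal(
        protein_id=f"member{member_index}",
        values=values,
        kind=SignalKind.IDF,
        gap_mask=gap_mask,
    )


def _symmetric_mask(rng: np.random.Generator, m: int, frac: float) -> np.ndarray:
    """Symmetric boolean mask with per-pixel marginal probability ``frac``."""
    upper = rng.random((m, m)) < frac
    mask = np.triu(upper)
    return mask | mask.T


def generate_registered_pair(
    spec: SyntheticFamilySpec,
    transform: SimilarityTransform,
    noise_sd: float = 0.0,
) -> tuple[
    SusceptibilityImage,
    SusceptibilityImage,
    list[tuple[tuple[float, float], tuple[float, float]]],
]:
    """A (base, moving, control_points) triple for registration tests.

    The base image is the (lightly smoothed) susceptibility of member 0's
    ensemble.  The moving image samples the base under the given transform
    (``moving(p) = base(transform(p))``, so ``transform`` maps moving
    coordinates into the base frame), plus optional Gaussian pixel noise and
    symmetric gap insertion at ``gap_frac`` per image.  Control points are
    exact correspondences derived from the transform.
    """
    if noise_sd < 0:
        raise ValidationError(f"noise_sd must be >= 0, got {noise_sd}")
    from .image_compare import warp_image  # local import avoids cycle

    ens = generate_ensemble(spec, 0)
    chi = compute_susceptibility(ens).chi
    # mild smoothing keeps bicubic round-trip error away from block edges
    chi = np.clip(gaussian_filter(chi, sigma=1.0), 0.0, 1.0)
    chi = 0.5 * (chi + chi.T)
    rng = np.random.default_rng([spec.seed, _FAMILY_STREAM_PAIR])
    m = spec.m

    base_mask = _symmetric_mask(rng, m, spec.gap_frac)
    if base_mask.all():
        base_mask[0, 0] = False
    base_img = SusceptibilityImage("base", chi.copy(), base_mask)

    # moving(p) = base(T(p)): warp the clean base with T^{-1} as the
    # moving->"base frame" map of warp_image
    clean = SusceptibilityImage("base", chi)
    moved = warp_image(clean, transform.inverse(), m)
    moving_chi = moved.chi
    if noise_sd > 0:
        moving_chi = np.clip(
            moving_chi + rng.normal(0.0, noise_sd, size=(m, m)), 0.0, 1.0
        )
    moving_mask = moved.gap_mask | _symmetric_mask(rng, m, spec.gap_frac)
    if moving_mask.all():
        moving_mask[0, 0] = False
    moving_img = SusceptibilityImage("moving", moving_chi, moving_mask)

    anchors = np.array(
        [
            [0.25 * (m - 1), 0.25 * (m - 1)],
            [0.70 * (m - 1), 0.30 * (m - 1)],
            [0.40 * (m - 1), 0.75 * (m - 1)],
            [0.75 * (m - 1), 0.70 * (m - 1)],
        ]
    )
    mapped = transform.apply(anchors)
    control_points = [
        (tuple(p), tuple(q)) for p, q in zip(anchors, mapped)
    ]
    return base_img, moving_img, control_points
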