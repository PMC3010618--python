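"""1D signal comparison: hydrophobicity profiles and dynamic time warping.

DTW uses the forward dynamic-programming recurrence

    DTW(i, j) = d(i, j) + min(DTW(i, j-1), DTW(i-1, j-1), DTW(i-1, j))

with local cost d(i, j) = (signal1(i) - signal2(j))**2 — a sum of squared
increments, no square root anywhere.  The warping path is continuous,
monotone, and spans both signals end to end.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DTWResult, FlexibilitySignal, SignalKind, ValidationError

__all__ = [
    "HydrophobicityScale",
    "KYTE_DOOLITTLE",
    "load_scale",
    "hydrophobicity_signal",
    "Normalize",
    "dtw_distance",
    "pairwise_signal_distances",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named mapping from the 20 standard one-letter codes to real values."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(_AA20):
            missing = sorted(set(_AA20) - keys)
            extra = sorted(keys - set(_AA20))
            raise ValidationError(
                f"scale {self.name!r}: must map exactly the 20 standard codes "
                f"(missing {missing}, unexpected {extra})"
            )

    def __getitem__(self, code: str) -> float:
        return self.values[code]


KYTE_DOOLITTLE = HydrophobicityScale(
    name="kyte-doolittle",
    values={
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)

_BUILTIN_SCALES = {"kyte-doolittle": KYTE_DOOLITTLE}


def load_scale(name_or_path: str) -> HydrophobicityScale:
    """Resolve a built-in scale by name or load one from a two-column file
    (``CODE value`` per line, '#' comments)."""
    key = name_or_path.lower()
    if key in _BUILTIN_SCALES:
        return _BUILTIN_SCALES[key]
    path = Path(name_or_path)
    if not path.exists():
        raise ValidationError(
            f"unknown scale {name_or_path!r}; built-ins: "
            f"{sorted(_BUILTIN_SCALES)}"
        )
    values: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            code, val = line.split()
            values[code.upper()] = float(val)
    return HydrophobicityScale(name=path.stem, values=values)


def hydrophobicity_signal(
    seq: str,
    scale: HydrophobicityScale = KYTE_DOOLITTLE,
    *,
    protein_id: str = "",
) -> FlexibilitySignal:
    """Assign a hydrophobicity value to each amino acid in sequence order.

    'X' positions become gaps; any other non-standard code is an error
    naming its 1-based position.
    """
    seq = seq.upper()
    if not seq:
        raise ValidationError("empty sequence")
    values = np.zeros(len(seq))
    mask = np.zeros(len(seq), dtype=bool)
    for i, ch in enumerate(seq):
        if ch == "X":
            mask[i] = True
        elif ch in scale.values:
            values[i] = scale[ch]
        else:
            raise ValidationError(
                f"unknown amino-acid code {ch!r} at position {i + 1}"
            )
    return FlexibilitySignal(
        protein_id=protein_id,
        values=values,
        kind=SignalKind.HYDROPHOBICITY,
        gap_mask=mask,
    )


class Normalize(enum.Enum):
    RAW = "raw"
    PATH_LENGTH = "path"


def dtw_distance(
    s1: FlexibilitySignal,
    s2: FlexibilitySignal,
    normalize: Normalize = Normalize.RAW,
) -> DTWResult:
    """Align two signals by forward-DP dynamic time warping.

    Gap positions are compressed out of each signal before alignment.  The
    path is recovered by backtracking; ties between predecessors prefer the
    diagonal, then the vertical (i-1, j), then the horizontal (i, j-1) move
    (affects the reported path, never the distance).  With
    ``normalize=PATH_LENGTH`` the cumulative cost is divided by the path
    length; RAW is the default.
    """
    a = s1.compressed()
    b = s2.compressed()
    if a.size == 0:
        raise ValidationError(f"signal {s1.protein_id!r} is empty after gap removal")
    if b.size == 0:
        raise ValidationError(f"signal {s2.protein_id!r} is empty after gap removal")
    n, m = a.size, b.size

    cost = (a[:, None] - b[None, :]) ** 2
    acc = np.empty((n, m))
    acc[0, 0] = cost[0, 0]
    acc[0, 1:] = cost[0, 1:].cumsum() + cost[0, 0]
    acc[1:, 0] = cost[1:, 0].cumsum() + cost[0, 0]
    for i in range(1, n):
        row_prev = acc[i - 1]
        row = acc[i]
        for j in range(1, m):
            row[j] = cost[i, j] + min(
                row_prev[j - 1], row_prev[j], row[j - 1]
            )

    # backtrack; tie-break order: diagonal, then (i-1, j), then (i, j-1)
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = (
                (acc[i - 1, j - 1], (i - 1, j - 1)),
                (acc[i - 1, j], (i - 1, j)),
                (acc[i, j - 1], (i, j - 1)),
            )
            best = min(c[0] for c in candidates)
            for val, idx in candidates:
                if val == best:
                    i, j = idx
                    break
            else:  # pragma: no cover
                raise AssertionError("unreachable")
            path.append((i, j))
            continue
        path.append((i, j))
    path.reverse()

    distance = float(acc[-1, -1])
    if normalize is Normalize.PATH_LENGTH:
        distance /= len(path)
    return DTWResult(distance=distance, path=path, n=n, m_len=m)


def pairwise_signal_distances(
    signals: list[FlexibilitySignal],
    normalize: Normalize = Normalize.RAW,
) -> pd.DataFrame:
    """All-pairs DTW distance table; symmetric, NaN on the diagonal
    (reported as '*' when written to disk)."""
    if len(signals) < 2:
        raise ValidationError("need at least 2 signals")
    kinds = {s.kind for s in signals}
    if len(kinds) > 1:
        raise ValidationError(
            f"signals must all share one kind, got {sorted(k.value for k in kinds)}"
        )
    ids = [s.protein_id for s in signals]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate protein ids in signal list")
    n = len(signals)
    table = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(signals[i], signals[j], normalize).distance
            table[i, j] = table[j, i] = d
    return pd.DataFrame(table, index=ids, columns=ids)
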