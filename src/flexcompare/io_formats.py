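"""Readers and writers for signals, matrices, ensembles, sequences,
control points, and pair-distance tables.

All on-disk formats are plain delimited text.  Reads accept any run of
whitespace or commas as delimiters and '#' comment lines; writes emit
tab-delimited canonical output.  Gaps are written as ``NaN`` and read back
either from NaN tokens (always) or, additionally, via an off-scale threshold
(``GapDialect`` in THRESHOLD mode).  Coordinates in control-point files are
1-based with x = column, y = row, origin at the top-left.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .core import (
    Direction,
    FlexibilitySignal,
    PairDistance,
    RigidityStateEnsemble,
    SignalKind,
    SusceptibilityImage,
    ValidationError,
)

__all__ = [
    "GapMode",
    "GapDialect",
    "ParseError",
    "read_signal",
    "write_signal",
    "read_matrix",
    "write_matrix",
    "read_ensemble",
    "write_ensemble",
    "read_fasta",
    "read_control_points",
    "write_control_points",
    "write_distance_table",
    "read_distance_table",
    "write_signal_table",
    "read_signal_table",
]


class ParseError(ValueError):
    """Raised on malformed input files; message carries a 1-based line number."""


class GapMode(enum.Enum):
    NAN_SENTINEL = "nan"
    THRESHOLD = "threshold"


@dataclass(frozen=True)
class GapDialect:
    """How gap pixels/values are encoded in text files.

    NaN tokens ("NaN", "nan", "NA") are always treated as gaps on read.  In
    THRESHOLD mode any value with ``abs(value) >= threshold`` is additionally
    a gap (the off-scale-sentinel convention).
    """

    mode: GapMode = GapMode.NAN_SENTINEL
    threshold: float = math.inf

    def is_gap(self, value: float) -> bool:
        if math.isnan(value):
            return True
        if self.mode is GapMode.THRESHOLD:
            return abs(value) >= self.threshold
        return False


DEFAULT_DIALECT = GapDialect()

_NAN_TOKENS = {"nan", "na"}


def _parse_float(token: str, path: Path, lineno: int) -> float:
    if token.lower() in _NAN_TOKENS:
        return math.nan
    try:
        return float(token)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: cannot parse {token!r} as a number"
        ) from None


def _data_lines(path: Path) -> list[tuple[int, str]]:
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if line:
                lines.append((lineno, line.replace(",", " ")))
    return lines


# ---------------------------------------------------------------------------
# signals


def read_signal(
    path: str | Path,
    dialect: GapDialect = DEFAULT_DIALECT,
    *,
    protein_id: str | None = None,
    kind: SignalKind = SignalKind.OTHER,
) -> FlexibilitySignal:
    """Read a 1D signal: one value per line, or two columns (index, value)."""
    path = Path(path)
    rows = _data_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty signal file")
    values, mask = [], []
    for lineno, line in rows:
        fields = line.split()
        if len(fields) == 1:
            token = fields[0]
        elif len(fields) == 2:
            token = fields[1]
        else:
            raise ParseError(
                f"{path}: line {lineno}: expected 1 or 2 columns, got {len(fields)}"
            )
        v = _parse_float(token, path, lineno)
        gap = dialect.is_gap(v)
        values.append(0.0 if gap else v)
        mask.append(gap)
    return FlexibilitySignal(
        protein_id=protein_id or path.stem,
        values=np.array(values),
        kind=kind,
        gap_mask=np.array(mask, dtype=bool),
    )


def write_signal(sig: FlexibilitySignal, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# signal {sig.protein_id} kind={sig.kind.value} n={sig.n}\n")
        for v, gap in zip(sig.values, sig.gap_mask):
            fh.write("NaN\n" if gap else f"{float(v)!r}\n")


# ---------------------------------------------------------------------------
# matrices


def _read_dense(path: Path) -> tuple[np.ndarray, list[int]]:
    rows = _data_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    data, width = [], None
    for lineno, line in rows:
        fields = line.split()
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ParseError(
                f"{path}: line {lineno}: ragged row ({len(fields)} fields, "
                f"expected {width})"
            )
        data.append([_parse_float(t, path, lineno) for t in fields])
    return np.array(data, dtype=float), [ln for ln, _ in rows]


def read_matrix(
    path: str | Path,
    dialect: GapDialect = DEFAULT_DIALECT,
    *,
    protein_id: str | None = None,
    symmetry_tol: float = 1e-9,
) -> SusceptibilityImage:
    """Read a dense m x m susceptibility matrix; validates symmetry."""
    path = Path(path)
    raw, _ = _read_dense(path)
    if raw.shape[0] != raw.shape[1]:
        raise ParseError(
            f"{path}: matrix is {raw.shape[0]}x{raw.shape[1]}, expected square"
        )
    gap = np.vectorize(dialect.is_gap)(raw)
    chi = np.where(gap, 0.0, raw)
    img = SusceptibilityImage(
        protein_id=protein_id or path.stem, chi=chi, gap_mask=gap
    )
    img.check_symmetric(symmetry_tol)
    return img


def write_matrix(img: SusceptibilityImage, path: str | Path) -> None:
    path = Path(path)
    out = np.where(img.gap_mask, np.nan, img.chi)
    with open(path, "w") as fh:
        fh.write(f"# susceptibility {img.protein_id} m={img.m}\n")
        for row in out:
            fh.write("\t".join("NaN" if np.isnan(v) else repr(float(v)) for v in row))
            fh.write("\n")


# ---------------------------------------------------------------------------
# ensembles


def _parse_state_block(
    path: Path, block: list[tuple[int, str]]
) -> np.ndarray:
    data, width = [], None
    for lineno, line in block:
        fields = line.split()
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ParseError(
                f"{path}: line {lineno}: ragged row ({len(fields)} fields, "
                f"expected {width})"
            )
        row = []
        for t in fields:
            v = _parse_float(t, path, lineno)
            if not float(v).is_integer():
                raise ParseError(
                    f"{path}: line {lineno}: non-integer state value {t!r}"
                )
            row.append(int(v))
        data.append(row)
    return np.array(data, dtype=np.int8)


def read_ensemble(
    dir_or_path: str | Path, *, protein_id: str | None = None
) -> RigidityStateEnsemble:
    """Read an ensemble from a directory of per-realization matrix files or a
    single file with realizations separated by blank lines."""
    p = Path(dir_or_path)
    mats: list[np.ndarray] = []
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.is_file())
        if not files:
            raise ParseError(f"{p}: no realizations (empty directory)")
        for f in files:
            block = _data_lines(f)
            if not block:
                raise ParseError(f"{f}: empty realization file")
            mats.append(_parse_state_block(f, block))
    else:
        block: list[tuple[int, str]] = []
        with open(p) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if line:
                    block.append((lineno, line.replace(",", " ")))
                elif block:
                    mats.append(_parse_state_block(p, block))
                    block = []
        if block:
            mats.append(_parse_state_block(p, block))
        if not mats:
            raise ParseError(f"{p}: no realizations")
    return RigidityStateEnsemble(
        protein_id=protein_id or p.stem, realizations=mats
    )


def write_ensemble(ens: RigidityStateEnsemble, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# ensemble {ens.protein_id} m={ens.m} "
            f"realizations={ens.n_realizations}\n"
        )
        for i, mat in enumerate(ens.realizations):
            if i:
                fh.write("\n")
            for row in mat:
                fh.write("\t".join(str(int(v)) for v in row))
                fh.write("\n")


# ---------------------------------------------------------------------------
# sequences

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records, uppercasing sequences.

    The 20 standard one-letter codes are accepted; 'X' is permitted (unknown
    residue, treated as a gap downstream).  Any other character is an error
    naming the record and 1-based position.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        for i, ch in enumerate(seq):
            if ch not in _AA20 and ch != "X":
                raise ParseError(
                    f"{path}: record {rec.id!r}: invalid amino-acid code "
                    f"{ch!r} at position {i + 1}"
                )
        records.append((rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return records


# ---------------------------------------------------------------------------
# control points


def read_control_points(
    path: str | Path,
) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Read control points: rows ``x_moving y_moving x_base y_base``.

    On disk coordinates are 1-based (x = column, y = row, top-left origin);
    returned points are 0-based ``((x_mov, y_mov), (x_base, y_base))`` pairs.
    """
    path = Path(path)
    rows = _data_lines(path)
    points = []
    for lineno, line in rows:
        fields = line.split()
        if len(fields) != 4:
            raise ParseError(
                f"{path}: line {lineno}: expected 4 columns "
                f"(x_moving y_moving x_base y_base), got {len(fields)}"
            )
        xm, ym, xb, yb = (_parse_float(t, path, lineno) for t in fields)
        if any(math.isnan(v) for v in (xm, ym, xb, yb)):
            raise ParseError(f"{path}: line {lineno}: NaN control point")
        points.append(((xm - 1.0, ym - 1.0), (xb - 1.0, yb - 1.0)))
    if len(points) < 2:
        raise ParseError(
            f"{path}: at least 2 control points are required, got {len(points)}"
        )
    return points


def write_control_points(
    points: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    path: str | Path,
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# x_moving y_moving x_base y_base (1-based, x=column y=row)\n")
        for (xm, ym), (xb, yb) in points:
            fh.write(
                f"{float(xm) + 1.0!r}\t{float(ym) + 1.0!r}\t"
                f"{float(xb) + 1.0!r}\t{float(yb) + 1.0!r}\n"
            )


# ---------------------------------------------------------------------------
# distance tables


def write_distance_table(
    records: Sequence[PairDistance],
    path: str | Path,
    long_path: str | Path | None = None,
) -> None:
    """Write symmetrized pair distances: one column per pair ("A-B"), rows
    "euclidean" and "gap_measure".  Optionally also a long-format file
    (pair, euclidean, gap_measure) for scatter plotting."""
    path = Path(path)
    for rec in records:
        if rec.direction is not Direction.SYMMETRIZED:
            raise ValidationError(
                f"distance table requires SYMMETRIZED records, got "
                f"{rec.direction.value} for {rec.id_a}-{rec.id_b}"
            )
    labels = [rec.pair_label for rec in records]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValidationError(f"duplicate pair {dup!r} in distance table")
    with open(path, "w") as fh:
        fh.write("\t".join(["measure"] + labels) + "\n")
        fh.write(
            "\t".join(
                ["euclidean"] + [repr(float(r.euclidean)) for r in records]
            )
            + "\n"
        )
        fh.write(
            "\t".join(
                ["gap_measure"] + [repr(float(r.gap_measure)) for r in records]
            )
            + "\n"
        )
    if long_path is not None:
        with open(Path(long_path), "w") as fh:
            fh.write("pair\teuclidean\tgap_measure\n")
            for rec in records:
                fh.write(
                    f"{rec.pair_label}\t{float(rec.euclidean)!r}\t"
                    f"{float(rec.gap_measure)!r}\n"
                )


def read_distance_table(path: str | Path) -> list[PairDistance]:
    path = Path(path)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines or not lines[0].startswith("measure"):
        raise ParseError(f"{path}: missing distance-table header")
    labels = lines[0].split("\t")[1:]
    if len(lines) == 1:
        return []
    rows = {}
    for line in lines[1:]:
        fields = line.split("\t")
        rows[fields[0]] = [float(v) for v in fields[1:]]
    records = []
    for i, label in enumerate(labels):
        a, _, b = label.partition("-")
        records.append(
            PairDistance(
                id_a=a,
                id_b=b,
                euclidean=rows["euclidean"][i],
                gap_measure=rows["gap_measure"][i],
                direction=Direction.SYMMETRIZED,
            )
        )
    return records


# ---------------------------------------------------------------------------
# square signal-distance tables (diagonal undefined, marked '*')


def write_signal_table(ids: Sequence[str], table: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    table = np.asarray(table, dtype=float)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, pid in enumerate(ids):
            cells = [
                "*" if i == j or np.isnan(table[i, j]) else repr(float(table[i, j]))
                for j in range(len(ids))
            ]
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def read_signal_table(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh if l.strip()]
    if not lines:
        raise ParseError(f"{path}: empty signal table")
    ids = lines[0].split("\t")[1:]
    n = len(ids)
    table = np.full((n, n), np.nan)
    for i, line in enumerate(lines[1:]):
        fields = line.split("\t")[1:]
        for j, tok in enumerate(fields):
            if tok != "*":
                table[i, j] = float(tok)
    return ids, table
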