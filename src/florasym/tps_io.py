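"""Landmark data containers, TPS file I/O, and outline resampling.

A *configuration* is one flower corolla digitised as an ordered set of 2D
outline points: four petal blocks of 50 points each (200 points total) in the
study design, although nothing below hard-codes those counts.  Configurations
carry the nested sampling metadata (sex / tree / flower / imaging replicate /
digitisation replicate) needed by the downstream ANOVA, plus a ``transform_id``
recording which symmetry copy of the raw digitisation they are.

The TPS landmark format is the loosely-specified text format used by the tps
software family (tpsDig, tpsRegr, ...): records start with ``LM=<count>``,
followed by whitespace-separated ``x y`` lines, optionally followed by
``IMAGE=``, ``ID=`` and ``SCALE=`` keys.  TPS files have no room for design
metadata, so that lives in a sidecar CSV keyed by object id.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Configuration",
    "Dataset",
    "read_tps",
    "write_tps",
    "read_metadata",
    "write_metadata",
    "resample_outline",
    "reverse_digitisation",
    "dataset_to_coord_frame",
]

#: canonical symmetry-copy identifiers (see :mod:`florasym.symmetry`)
TRANSFORM_IDS = ("identity", "reflectV", "reflectH", "reflectHV")

METADATA_COLUMNS = ["object_id", "flower", "tree", "sex", "imaging", "digitisation"]


class TpsParseError(ValueError):
    """Raised when a TPS file is malformed."""


@dataclass
class Configuration:
    """One corolla outline with its nested-design metadata.

    ``points`` is an ``(k, 2)`` float array of ordered outline coordinates,
    petal blocks contiguous.  ``transform_id`` is ``"identity"`` for raw data
    and one of the reflection labels for symmetry copies.
    """

    points: np.ndarray
    object_id: str
    flower_id: str = ""
    tree_id: str = ""
    sex: str = ""
    imaging_rep: int = 1
    digitisation_rep: int = 1
    transform_id: str = "identity"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(
                f"configuration {self.object_id!r}: points must be (k, 2), "
                f"got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError(
                f"configuration {self.object_id!r}: non-finite coordinates"
            )
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def copy(self, **changes) -> "Configuration":
        cfg = replace(self, **changes)
        cfg.points = np.array(cfg.points, dtype=float, copy=True)
        return cfg


@dataclass
class Dataset:
    """An ordered collection of configurations with a common landmark layout."""

    configurations: list[Configuration]
    n_petals: int = 4
    points_per_petal: int = 50

    def __post_init__(self) -> None:
        counts = {c.n_points for c in self.configurations}
        if len(counts) > 1:
            raise ValueError(f"mixed landmark counts in dataset: {sorted(counts)}")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self):
        return iter(self.configurations)

    def __getitem__(self, i: int) -> Configuration:
        return self.configurations[i]

    @property
    def n_landmarks(self) -> int:
        return self.configurations[0].n_points if self.configurations else 0

    def coords(self) -> np.ndarray:
        """Stack all configurations into an ``(n, k, 2)`` array."""
        return np.stack([c.points for c in self.configurations])

    def meta(self) -> pd.DataFrame:
        """Per-configuration metadata table (one row per configuration)."""
        return pd.DataFrame(
            {
                "object_id": [c.object_id for c in self.configurations],
                "flower": [c.flower_id for c in self.configurations],
                "tree": [c.tree_id for c in self.configurations],
                "sex": [c.sex for c in self.configurations],
                "imaging": [c.imaging_rep for c in self.configurations],
                "digitisation": [c.digitisation_rep for c in self.configurations],
                "transform": [c.transform_id for c in self.configurations],
            }
        )

    def design_summary(self) -> dict:
        m = self.meta()
        return {
            "n_configurations": len(self),
            "n_landmarks": self.n_landmarks,
            "n_sexes": int(m["sex"].nunique()) if len(self) else 0,
            "n_trees": int(m["tree"].nunique()) if len(self) else 0,
            "n_flowers": int(m["flower"].nunique()) if len(self) else 0,
            "n_imaging": int(m["imaging"].nunique()) if len(self) else 0,
            "n_digitisation": int(m["digitisation"].nunique()) if len(self) else 0,
            "transforms": sorted(m["transform"].unique().tolist()) if len(self) else [],
        }


# ---------------------------------------------------------------------------
# TPS reading / writing
# ---------------------------------------------------------------------------

_KEY_RE = re.compile(r"^\s*([A-Za-z][A-Za-z0-9]*)\s*=\s*(.*?)\s*$")


def _parse_records(lines: Iterable[str], source: str) -> list[dict]:
    records: list[dict] = []
    current: dict | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        m = _KEY_RE.match(line)
        if m:
            key, value = m.group(1).upper(), m.group(2)
            if key in ("LM", "LM3"):
                if key == "LM3":
                    raise TpsParseError(
                        f"{source}:{lineno}: 3D landmark records (LM3=) are not "
                        "supported; this reader handles planar (LM=) data only"
                    )
                if current is not None:
                    records.append(current)
                try:
                    n = int(value)
                except ValueError as exc:
                    raise TpsParseError(
                        f"{source}:{lineno}: bad LM count {value!r}"
                    ) from exc
                current = {"lm": n, "coords": [], "id": None, "image": None,
                           "scale": None, "lineno": lineno}
            elif current is None:
                raise TpsParseError(
                    f"{source}:{lineno}: key {key}= before any LM= record"
                )
            elif key == "ID":
                current["id"] = value
            elif key == "IMAGE":
                current["image"] = value
            elif key == "SCALE":
                try:
                    current["scale"] = float(value)
                except ValueError as exc:
                    raise TpsParseError(
                        f"{source}:{lineno}: bad SCALE value {value!r}"
                    ) from exc
            # other keys (CURVES=, POINTS=, ...) are ignored
        else:
            if current is None:
                raise TpsParseError(
                    f"{source}:{lineno}: coordinate line before any LM= record"
                )
            parts = line.split()
            if len(parts) != 2:
                raise TpsParseError(
                    f"{source}:{lineno}: expected 'x y' pair, got {line!r}"
                )
            try:
                current["coords"].append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise TpsParseError(
                    f"{source}:{lineno}: non-numeric coordinate in {line!r}"
                ) from exc
    if current is not None:
        records.append(current)

    for i, rec in enumerate(records):
        if len(rec["coords"]) != rec["lm"]:
            name = rec["id"] if rec["id"] is not None else f"record {i + 1}"
            raise TpsParseError(
                f"{source}: record {name!r} (starting line {rec['lineno']}) "
                f"declares LM={rec['lm']} but has {len(rec['coords'])} "
                "coordinate lines"
            )
    return records


def read_tps(
    path: str | Path,
    metadata: str | Path | pd.DataFrame | None = None,
    n_petals: int = 4,
) -> Dataset:
    """Read a TPS landmark file into a :class:`Dataset`.

    ``SCALE=`` entries multiply the record's coordinates, as in tpsDig.
    Record order is preserved; object ids come from ``ID=`` keys, falling back
    to 1-based record numbers.  If *metadata* is given (a sidecar CSV path or a
    DataFrame with columns ``object_id, flower, tree, sex, imaging,
    digitisation``), it is joined onto the records by object id.
    """
    path = Path(path)
    records = _parse_records(path.read_text().splitlines(), str(path))
    if not records:
        raise TpsParseError(f"{path}: no landmark records found")

    counts = {rec["lm"] for rec in records}
    if len(counts) > 1:
        raise TpsParseError(
            f"{path}: mixed landmark counts {sorted(counts)}; all records must "
            "have the same number of points"
        )

    meta_map: dict[str, dict] = {}
    if metadata is not None:
        table = read_metadata(metadata) if not isinstance(metadata, pd.DataFrame) \
            else metadata
        meta_map = {
            str(row["object_id"]): row for _, row in table.iterrows()
        }

    configs = []
    for i, rec in enumerate(records):
        pts = np.asarray(rec["coords"], dtype=float)
        if rec["scale"] is not None:
            pts = pts * rec["scale"]
        oid = rec["id"] if rec["id"] is not None else str(i + 1)
        kwargs = {}
        if oid in meta_map:
            row = meta_map[oid]
            kwargs = dict(
                flower_id=str(row["flower"]),
                tree_id=str(row["tree"]),
                sex=str(row["sex"]),
                imaging_rep=int(row["imaging"]),
                digitisation_rep=int(row["digitisation"]),
            )
        configs.append(Configuration(points=pts, object_id=oid, **kwargs))

    k = configs[0].n_points
    ppp = k // n_petals if k % n_petals == 0 else k
    return Dataset(configs, n_petals=n_petals if k % n_petals == 0 else 1,
                   points_per_petal=ppp)


def write_tps(dataset: Dataset | Sequence[Configuration], path: str | Path) -> None:
    """Write configurations as a TPS landmark file (one record per config)."""
    configs = list(dataset)
    lines: list[str] = []
    for cfg in configs:
        lines.append(f"LM={cfg.n_points}")
        for x, y in cfg.points:
            lines.append(f"{float(x)!r} {float(y)!r}")
        lines.append(f"ID={cfg.object_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"object_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metadata file {path}: missing columns {missing}")
    return table


def write_metadata(dataset: Dataset, path: str | Path) -> None:
    m = dataset.meta().drop(columns="transform")
    m.to_csv(path, index=False)


def dataset_to_coord_frame(dataset: Dataset) -> pd.DataFrame:
    """Flat CSV-style export: one row per configuration, x1,y1,...,xk,yk."""
    coords = dataset.coords()
    n, k, _ = coords.shape
    cols = [f"{ax}{i + 1}" for i in range(k) for ax in ("x", "y")]
    frame = pd.DataFrame(coords.reshape(n, 2 * k), columns=cols)
    frame.insert(0, "object_id", [c.object_id for c in dataset])
    return frame


# ---------------------------------------------------------------------------
# Outline resampling
# ---------------------------------------------------------------------------

def resample_outline(curve: np.ndarray, n_points: int) -> np.ndarray:
    """Resample an open polyline to *n_points* at equal arc-length spacing.

    Endpoints are preserved exactly.  Interior points are placed at arc-length
    fractions ``i / (n_points - 1)`` of the total polyline length, linearly
    interpolated within segments — the digitisation convention of placing
    "equidistant" pseudolandmarks along a traced outline.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 2:
        raise ValueError("curve must be an (m >= 2, 2) array")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")

    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0.0:
        raise ValueError("degenerate curve: zero total arc length")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, 2))
    out[:, 0] = np.interp(targets, s, curve[:, 0])
    out[:, 1] = np.interp(targets, s, curve[:, 1])
    out[0] = curve[0]
    out[-1] = curve[-1]
    return out


def reverse_digitisation(config: Configuration) -> Configuration:
    """Re-label a digitisation traced in the opposite direction.

    A full outline trace read backwards is the same trace in the opposite
    direction, so the re-labelling reverses the whole point sequence: petal
    block order is reversed and within each petal point ``i`` maps to point
    ``k_petal + 1 - i``.  The operation is an involution.
    """
    out = config.copy()
    out.points = config.points[::-1].copy()
    return out
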