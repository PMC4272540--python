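"""Landmark data input/output.

Reads and writes 2D landmark configurations in two plain-text formats:

* the TPS format produced by the tpsDIG digitising software (one record
  per specimen: an ``LM=k`` line followed by ``k`` whitespace-separated
  coordinate lines, with optional ``ID=``, ``IMAGE=``, ``SCALE=`` and
  ``COMMENT=`` lines), and
* a flat delimited table with one specimen per row
  (``specimen_id,population,sex,age_class,x1,y1,...,xk,yk``).

Datasets pair each landmark configuration with specimen metadata
(population, sex, age class) and can be filtered by predicates on that
metadata.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkConfiguration",
    "SpecimenMeta",
    "ShapeDataset",
    "FormatError",
    "read_tps",
    "write_tps",
    "read_landmark_table",
    "write_landmark_table",
    "subset",
]


class FormatError(ValueError):
    """Raised for malformed landmark files or inconsistent datasets."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """One specimen's raw landmark coordinates.

    Parameters
    ----------
    specimen_id : str
        Unique specimen identifier.
    coords : ndarray of shape (k, 2)
        Landmark coordinates in image units; landmark order must be
        identical across all specimens of a dataset.
    """

    specimen_id: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise FormatError(
                f"specimen {self.specimen_id!r}: coords must be k x 2, "
                f"got shape {coords.shape}"
            )
        if coords.shape[0] < 3:
            raise FormatError(
                f"specimen {self.specimen_id!r}: need at least 3 landmarks, "
                f"got {coords.shape[0]}"
            )
        if not np.all(np.isfinite(coords)):
            raise FormatError(
                f"specimen {self.specimen_id!r}: non-finite coordinate "
                "(missing landmarks are not supported)"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        """Number of landmarks."""
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpecimenMeta:
    """Identity metadata for one specimen."""

    specimen_id: str
    population: str = ""
    sex: str = ""
    age_class: str = ""


@dataclass(frozen=True)
class ShapeDataset:
    """A collection of landmark configurations with matched metadata."""

    configurations: tuple[LandmarkConfiguration, ...]
    meta: tuple[SpecimenMeta, ...] = field(default=())

    def __post_init__(self) -> None:
        configs = tuple(self.configurations)
        meta = tuple(self.meta)
        if not meta:
            meta = tuple(SpecimenMeta(c.specimen_id) for c in configs)
        if len(meta) != len(configs):
            raise FormatError(
                f"{len(configs)} configurations but {len(meta)} metadata rows"
            )
        ks = {c.k for c in configs}
        if len(ks) > 1:
            raise FormatError(f"inconsistent landmark counts across records: {sorted(ks)}")
        ids = [m.specimen_id for m in meta]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate specimen ids: {dup}")
        object.__setattr__(self, "configurations", configs)
        object.__setattr__(self, "meta", meta)

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[tuple[LandmarkConfiguration, SpecimenMeta]]:
        return iter(zip(self.configurations, self.meta))

    @property
    def k(self) -> int:
        if not self.configurations:
            raise FormatError("empty dataset has no landmark count")
        return self.configurations[0].k

    def coords_array(self) -> np.ndarray:
        """All coordinates stacked as an (n, k, 2) array."""
        return np.stack([c.coords for c in self.configurations])

    def flip_y(self) -> "ShapeDataset":
        """Return a copy with y -> -y applied uniformly to every specimen.

        tpsDIG uses a bottom-left image origin while raster images use a
        top-left one; applying the flip to all specimens leaves every
        Procrustes-based result unchanged.
        """
        flipped = tuple(
            replace(c, coords=c.coords * np.array([1.0, -1.0]))
            for c in self.configurations
        )
        return ShapeDataset(flipped, self.meta)


_TPS_KEY = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def read_tps(path: str | Path) -> ShapeDataset:
    """Read a TPS landmark file (tpsDIG dialect).

    Keywords ``LM``, ``ID``, ``IMAGE``, ``SCALE`` and ``COMMENT`` are
    recognised case-insensitively; unknown keywords are ignored with a
    logged warning.  If a record carries ``SCALE=s`` its coordinates are
    multiplied by ``s``.  Records lacking ``ID=`` are numbered by position.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    configs: list[LandmarkConfiguration] = []
    i = 0
    record_index = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _TPS_KEY.match(line)
        if m is None or m.group(1).upper() != "LM":
            raise FormatError(
                f"{path}: expected 'LM=' at line {i + 1}, got {line!r}"
            )
        try:
            k = int(m.group(2))
        except ValueError as exc:
            raise FormatError(f"{path}: bad LM count at line {i + 1}") from exc
        i += 1
        pts: list[tuple[float, float]] = []
        while i < len(lines) and len(pts) < k:
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if _TPS_KEY.match(row) and not _looks_numeric(row):
                break  # keyword line: fewer coordinate rows than promised
            parts = row.split()
            if len(parts) != 2:
                break
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except ValueError:
                break
            i += 1
        if len(pts) != k:
            raise FormatError(
                f"{path}: record {record_index} declares LM={k} but has "
                f"{len(pts)} coordinate lines"
            )
        specimen_id = str(record_index)
        scale = None
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            km = _TPS_KEY.match(row)
            if km is None or _looks_numeric(row):
                break
            key = km.group(1).upper()
            if key == "LM":
                break
            if key == "ID":
                specimen_id = km.group(2)
            elif key == "SCALE":
                try:
                    scale = float(km.group(2))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: record {record_index}: bad SCALE {km.group(2)!r}"
                    ) from exc
            elif key in ("IMAGE", "COMMENT"):
                pass
            else:
                logger.warning(
                    "%s: record %d: ignoring unknown TPS keyword %r",
                    path, record_index, key,
                )
            i += 1
        coords = np.asarray(pts, dtype=float)
        if scale is not None:
            coords = coords * scale
        configs.append(LandmarkConfiguration(specimen_id, coords))
        record_index += 1

    return ShapeDataset(tuple(configs))


def _looks_numeric(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(dataset: ShapeDataset, path: str | Path) -> None:
    """Write a dataset as a TPS file (coordinates at full precision)."""
    out: list[str] = []
    for config in dataset.configurations:
        out.append(f"LM={config.k}")
        for x, y in config.coords:
            out.append(f"{float(x)!r} {float(y)!r}")
        out.append(f"ID={config.specimen_id}")
    Path(path).write_text("\n".join(out) + "\n")


_META_COLS = ["specimen_id", "population", "sex", "age_class"]


def read_landmark_table(path: str | Path, sep: str = ",") -> ShapeDataset:
    """Read the flat-table exchange format.

    Header: ``specimen_id,population,sex,age_class,x1,y1,...,xk,yk``;
    row order is preserved.
    """
    df = pd.read_csv(
        path, sep=sep, dtype={c: str for c in _META_COLS}, float_precision="round_trip"
    )
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required metadata columns {missing}")
    coord_cols = [c for c in df.columns if c not in _META_COLS]
    if len(coord_cols) % 2:
        raise FormatError(
            f"{path}: odd number of coordinate columns ({len(coord_cols)})"
        )
    k = len(coord_cols) // 2
    expected = [f"{a}{i}" for i in range(1, k + 1) for a in ("x", "y")]
    if coord_cols != expected:
        raise FormatError(
            f"{path}: coordinate columns must be x1,y1,...,xk,yk; got {coord_cols}"
        )
    configs = []
    meta = []
    for _, row in df.iterrows():
        coords = row[coord_cols].to_numpy(dtype=float).reshape(k, 2)
        configs.append(LandmarkConfiguration(str(row["specimen_id"]), coords))
        meta.append(
            SpecimenMeta(
                specimen_id=str(row["specimen_id"]),
                population=str(row["population"]),
                sex=str(row["sex"]),
                age_class=str(row["age_class"]),
            )
        )
    return ShapeDataset(tuple(configs), tuple(meta))


def write_landmark_table(dataset: ShapeDataset, path: str | Path, sep: str = ",") -> None:
    """Write the flat-table exchange format (full float precision)."""
    k = dataset.k
    coord_cols = [f"{a}{i}" for i in range(1, k + 1) for a in ("x", "y")]
    meta_df = pd.DataFrame(
        [[m.specimen_id, m.population, m.sex, m.age_class] for m in dataset.meta],
        columns=_META_COLS,
    )
    coords_df = pd.DataFrame(
        dataset.coords_array().reshape(len(dataset), 2 * k), columns=coord_cols
    )
    df = pd.concat([meta_df, coords_df], axis=1)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def subset(
    dataset: ShapeDataset, predicate: Callable[[SpecimenMeta], bool]
) -> ShapeDataset:
    """Return the specimens whose metadata satisfies ``predicate``.

    Original order is preserved; an empty result is legal.
    """
    keep = [(c, m) for c, m in dataset if predicate(m)]
    if not keep:
        return ShapeDataset((), ())
    configs, meta = zip(*keep)
    return ShapeDataset(tuple(configs), tuple(meta))


def dataset_from_arrays(
    coords: np.ndarray,
    specimen_ids: Sequence[str] | None = None,
    populations: Sequence[str] | None = None,
    sexes: Sequence[str] | None = None,
    age_classes: Sequence[str] | None = None,
) -> ShapeDataset:
    """Assemble a dataset from an (n, k, 2) coordinate array plus labels."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    ids = list(specimen_ids) if specimen_ids is not None else [str(i) for i in range(n)]
    pops = list(populations) if populations is not None else [""] * n
    sx = list(sexes) if sexes is not None else [""] * n
    ages = list(age_classes) if age_classes is not None else [""] * n
    configs = tuple(LandmarkConfiguration(ids[i], coords[i]) for i in range(n))
    meta = tuple(
        SpecimenMeta(ids[i], pops[i], sx[i], ages[i]) for i in range(n)
    )
    return ShapeDataset(configs, meta)
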