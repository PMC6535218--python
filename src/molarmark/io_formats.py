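"""Readers and writers for landmark and outline data.

Two landmark interchange formats are supported:

* the TPS dialect (``LM=n`` header per specimen, n ``x y`` lines, optional
  ``ID=``, ``SCALE=``, ``IMAGE=``, ``COMMENT=`` keys and ``CURVES``/``POINTS``
  blocks carrying the outline), and
* wide CSV tables with one row per specimen, coordinate columns
  ``x1,y1,...,x29,y29`` plus metadata columns.

All coordinates are millimetres; a TPS ``SCALE=`` factor is applied at read
time.  The internal axis convention is mathematical y-up with mesial = -x and
lingual = +y; files digitized in image pixel coordinates (y growing downward)
are flipped on ingest via ``pixel_origin=True``.  Readers are insensitive to
line-ending style and trailing whitespace.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, GeometryError, ParseError, UsageError
from .geometry import GROOVE_LABELS, GroovePoints, Outline
from .landmarks import LandmarkConfiguration, N_LANDMARKS

SEXES = ("F", "M", "unknown")
SIDES = ("left", "right")


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    genus: str = ""
    species: str = ""
    subspecies: str = ""
    sex: str = "unknown"
    side: str = "left"
    wear_stage: int | None = None
    population: str = ""
    collection: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise UsageError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.side not in SIDES:
            raise UsageError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.wear_stage is not None and not 1 <= int(self.wear_stage) <= 8:
            raise UsageError("wear_stage must be in 1..8 when given")

    @property
    def taxon(self) -> str:
        return " ".join(t for t in (self.genus, self.species, self.subspecies) if t)


@dataclass(frozen=True)
class LandmarkTable:
    """Per-specimen landmark configurations with metadata; units fixed to mm."""

    records: list  # list[(SpecimenRecord, LandmarkConfiguration)]
    units: str = "mm"
    tps_metadata: dict = field(default_factory=dict)  # opaque IMAGE=/COMMENT= keys

    def __post_init__(self) -> None:
        ids = [r.specimen_id for r, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise UsageError(f"duplicate specimen ids: {dup}")
        counts = {cfg.points.shape[0] for _, cfg in self.records}
        if len(counts) > 1:
            raise DimensionError(f"mixed landmark counts in table: {sorted(counts)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r, _ in self.records]

    @property
    def configurations(self) -> list[LandmarkConfiguration]:
        return [cfg for _, cfg in self.records]

    @property
    def coords(self) -> np.ndarray:
        """(n_specimens, n_landmarks, 2) coordinate stack."""
        return np.stack([cfg.points for _, cfg in self.records])

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for rec, _ in self.records:
            rows.append(
                {
                    "specimen_id": rec.specimen_id,
                    "genus": rec.genus,
                    "species": rec.species,
                    "subspecies": rec.subspecies,
                    "sex": rec.sex,
                    "side": rec.side,
                    "wear_stage": rec.wear_stage,
                    "population": rec.population,
                    "collection": rec.collection,
                }
            )
        return pd.DataFrame(rows).set_index("specimen_id")


# ---------------------------------------------------------------------------
# TPS


def _read_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return [ln.rstrip() for ln in text.splitlines()]


_KEY_RE = re.compile(r"^([A-Za-z]+)\s*=\s*(.*)$")


def read_tps(
    path, expect_landmarks: int = N_LANDMARKS, pixel_origin: bool = False
) -> LandmarkTable:
    """Read a TPS landmark file.

    Specimens whose ``LM=`` count differs from ``expect_landmarks`` raise a
    :class:`DimensionError` naming the specimen.  ``SCALE=`` multiplies the
    coordinates; ``pixel_origin=True`` flips the y axis (image convention ->
    mathematical y-up).  ``IMAGE=``/``COMMENT=`` keys are preserved as opaque
    metadata; the first ``CURVES`` block of a specimen, when present, is
    interpreted as the perimeter outline and stored in the metadata as well.
    """
    lines = _read_lines(path)
    records = []
    meta: dict[str, dict] = {}
    i = 0
    spec_no = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        m = _KEY_RE.match(line)
        if not m or m.group(1).upper() != "LM":
            raise ParseError(f"line {i + 1}: expected 'LM=n' header, got {line!r}")
        try:
            n_lm = int(m.group(2))
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: malformed landmark count {m.group(2)!r}") from exc
        i += 1
        pts = []
        for _ in range(n_lm):
            if i >= len(lines):
                raise ParseError(f"line {i + 1}: unexpected end of file inside block")
            parts = lines[i].split()
            if len(parts) != 2:
                raise ParseError(f"line {i + 1}: expected 'x y', got {lines[i]!r}")
            try:
                pts.append([float(parts[0]), float(parts[1])])
            except ValueError as exc:
                raise ParseError(f"line {i + 1}: non-numeric coordinate") from exc
            i += 1
        spec_no += 1
        spec_id = f"specimen_{spec_no}"
        scale = None
        extras: dict = {}
        curves: list[np.ndarray] = []
        while i < len(lines):
            s = lines[i].strip()
            if not s:
                i += 1
                continue
            km = _KEY_RE.match(s)
            if not km:
                raise ParseError(f"line {i + 1}: unexpected content {s!r}")
            key = km.group(1).upper()
            if key == "LM":
                break
            if key == "ID":
                spec_id = km.group(2).strip()
                i += 1
            elif key == "SCALE":
                try:
                    scale = float(km.group(2))
                except ValueError as exc:
                    raise ParseError(f"line {i + 1}: malformed SCALE value") from exc
                i += 1
            elif key == "CURVES":
                i += 1
                n_curves = int(km.group(2))
                for _c in range(n_curves):
                    pm = _KEY_RE.match(lines[i].strip())
                    if not pm or pm.group(1).upper() != "POINTS":
                        raise ParseError(f"line {i + 1}: expected 'POINTS=' in CURVES block")
                    n_pts = int(pm.group(2))
                    i += 1
                    cpts = []
                    for _p in range(n_pts):
                        parts = lines[i].split()
                        if len(parts) != 2:
                            raise ParseError(f"line {i + 1}: expected 'x y' in curve")
                        cpts.append([float(parts[0]), float(parts[1])])
                        i += 1
                    curves.append(np.asarray(cpts))
            else:  # IMAGE, COMMENT, VARIABLES... kept verbatim
                extras[key] = km.group(2)
                i += 1

        if n_lm != expect_landmarks:
            raise DimensionError(
                f"specimen {spec_id!r}: LM={n_lm}, expected {expect_landmarks}"
            )
        arr = np.asarray(pts, dtype=float)
        if pixel_origin:
            arr[:, 1] *= -1.0
            curves = [c * np.array([1.0, -1.0]) for c in curves]
        if scale is not None:
            arr *= scale
            curves = [c * scale for c in curves]
        if curves:
            extras["CURVES"] = curves
        if extras:
            meta[spec_id] = extras
        records.append(
            (SpecimenRecord(specimen_id=spec_id), LandmarkConfiguration(arr))
        )
    if not records:
        raise ParseError("no specimens found in TPS file")
    return LandmarkTable(records=records, tps_metadata=meta)


def write_tps(table: LandmarkTable, path) -> None:
    """Write a TPS file; round-trips with :func:`read_tps` to 1e-6 mm."""
    if not len(table):
        raise UsageError("cannot write an empty landmark table")
    out = io.StringIO()
    for rec, cfg in table.records:
        out.write(f"LM={cfg.points.shape[0]}\n")
        for x, y in cfg.points:
            out.write(f"{x:.6f} {y:.6f}\n")
        out.write(f"ID={rec.specimen_id}\n")
        extras = table.tps_metadata.get(rec.specimen_id, {})
        for key, value in extras.items():
            if key == "CURVES":
                continue
            out.write(f"{key}={value}\n")
    Path(path).write_text(out.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# landmark CSV

_METADATA_COLUMNS = {
    "specimen_id": "specimen_id",
    "id": "specimen_id",
    "genus": "genus",
    "species": "species",
    "subspecies": "subspecies",
    "sex": "sex",
    "side": "side",
    "wear_stage": "wear_stage",
    "population": "population",
    "collection": "collection",
}


def read_landmark_csv(
    path, n_landmarks: int = N_LANDMARKS, column_map: dict | None = None
) -> LandmarkTable:
    """Read a wide CSV: one row per specimen, columns ``x1,y1..x29,y29``.

    Metadata columns are matched case-insensitively against the standard
    names (specimen_id/id, genus, species, subspecies, sex, side, wear_stage,
    population, collection); ``column_map`` overrides the mapping, e.g.
    ``{"Taxon": "species"}``.  A missing coordinate cell raises a
    :class:`ParseError` naming the row and column.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    coord_cols = []
    for i in range(1, n_landmarks + 1):
        for axis in ("x", "y"):
            name = f"{axis}{i}"
            if name not in lower:
                raise ParseError(f"missing coordinate column {name!r}")
            coord_cols.append(lower[name])
    mapping = dict(_METADATA_COLUMNS)
    if column_map:
        mapping.update({k.lower(): v for k, v in column_map.items()})
    records = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):  # header is line 1
        coords = row[coord_cols].to_numpy()
        bad = pd.isna(coords)
        if bad.any():
            col = coord_cols[int(np.argmax(bad))]
            raise ParseError(f"row {row_no}: missing coordinate in column {col!r}")
        pts = coords.astype(float).reshape(n_landmarks, 2)
        fields_ = {"specimen_id": f"specimen_{row_no - 1}"}
        for col in df.columns:
            if col in coord_cols:
                continue
            target = mapping.get(col.lower())
            if target is None:
                continue
            value = row[col]
            if pd.isna(value):
                continue
            if target == "wear_stage":
                fields_[target] = int(value)
            else:
                fields_[target] = str(value)
        records.append((SpecimenRecord(**fields_), LandmarkConfiguration(pts)))
    if not records:
        raise ParseError("no specimens found in CSV")
    return LandmarkTable(records=records)


def write_landmark_csv(table: LandmarkTable, path) -> None:
    if not len(table):
        raise UsageError("cannot write an empty landmark table")
    n_lm = table.coords.shape[1]
    header = ["specimen_id", "genus", "species", "subspecies", "sex", "side",
              "wear_stage", "population", "collection"]
    for i in range(1, n_lm + 1):
        header += [f"x{i}", f"y{i}"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for rec, cfg in table.records:
            row = [
                rec.specimen_id, rec.genus, rec.species, rec.subspecies,
                rec.sex, rec.side,
                "" if rec.wear_stage is None else rec.wear_stage,
                rec.population, rec.collection,
            ]
            row += [f"{v:.6f}" for v in cfg.points.ravel()]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# outline CSV


def read_outline_csv(path, pixel_origin: bool = False) -> tuple[Outline, GroovePoints]:
    """Read an outline CSV with columns ``x,y[,landmark]``.

    Vertex rows must be ordered along the perimeter; exactly five rows carry
    the groove labels g6..g10 in the ``landmark`` column.  Groove points must
    coincide with polygon vertices (they are, by construction, rows of the
    same file).
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "x" not in df.columns or "y" not in df.columns:
        raise ParseError("outline CSV needs 'x' and 'y' columns")
    pts = df[["x", "y"]].to_numpy(dtype=float)
    if pixel_origin:
        pts[:, 1] *= -1.0
    if len(pts) < 3:
        raise GeometryError("outline needs at least 3 vertices")
    labels = (
        df["landmark"].fillna("").astype(str).str.strip().str.lower()
        if "landmark" in df.columns
        else pd.Series([""] * len(df))
    )
    positions: dict[str, np.ndarray] = {}
    for lbl in GROOVE_LABELS:
        hits = np.where(labels.to_numpy() == lbl)[0]
        if len(hits) == 0:
            raise ParseError(f"groove label {lbl!r} missing from outline CSV")
        if len(hits) > 1:
            raise ParseError(f"groove label {lbl!r} appears {len(hits)} times")
        positions[lbl] = pts[hits[0]]
    outline = Outline(pts)
    groove = GroovePoints(
        np.array([positions[lbl] for lbl in GROOVE_LABELS]), outline
    )
    return outline, groove


def write_outline_csv(outline: Outline, groove: GroovePoints, path) -> None:
    labels = [""] * outline.n
    for lbl, pt in zip(GROOVE_LABELS, groove.points):
        i, d = outline.nearest_vertex(pt)
        if d > 1e-9:
            raise UsageError(f"groove point {lbl} is not an outline vertex")
        labels[i] = lbl
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y", "landmark"])
        for (x, y), lbl in zip(outline.vertices, labels):
            writer.writerow([f"{x:.9f}", f"{y:.9f}", lbl])
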