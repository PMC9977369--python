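"""Exchange data model for immunogold PSD records.

A study is a collection of postsynaptic densities (PSDs), each delineated by a
closed polygonal contour traced in a freeze-fracture replica EM image, together
with the coordinates of the colloidal-gold grains that mark receptor epitopes.
All coordinates are 2D Cartesian in nanometers with y increasing upward; the
origin is arbitrary per record (pose normalization happens downstream).

Contours are vertex lists with implicit closure: the last vertex connects back
to the first. A duplicated closing vertex is accepted on read and dropped.
Ring-like PSDs are encoded as an outer contour plus hole contours.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Polygon

LAYERS = ("L4", "L5")
TARGETS = ("shaft", "spine")
RECEPTORS = ("AMPA", "GluN1")
GOLD_SIZES = (5, 10, 15)
MORPHOLOGIES = ("macular", "perforated", "horseshoe", "ring")


class ValidationError(ValueError):
    """An input violates a data-model invariant."""


def _check_vocab(value, allowed: Sequence, name: str):
    if value not in allowed:
        raise ValidationError(
            f"{name}={value!r} not in allowed values {list(allowed)}"
        )
    return value


@dataclass(frozen=True)
class Particle:
    """One colloidal gold grain: position (nm), bead size class, receptor label."""

    x: float
    y: float
    gold_size: int
    receptor: str

    def __post_init__(self):
        object.__setattr__(self, "x", float(self.x))
        object.__setattr__(self, "y", float(self.y))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"particle coordinates not finite: ({self.x}, {self.y})")
        _check_vocab(self.gold_size, GOLD_SIZES, "gold_size")
        _check_vocab(self.receptor, RECEPTORS, "receptor")


def _as_ring(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError(f"contour must be an (n, 2) vertex list, got shape {arr.shape}")
    # drop a duplicated closing vertex
    if len(arr) > 1 and np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if not np.all(np.isfinite(arr)):
        raise ValidationError("contour contains non-finite coordinates")
    return arr


@dataclass(frozen=True)
class Region:
    """A planar region bounded by a simple outer contour, minus optional holes.

    Invariants: the outer ring has >= 3 vertices and is simple
    (non-self-intersecting); every hole lies strictly inside the outer ring;
    holes are pairwise disjoint.
    """

    outer: np.ndarray
    holes: tuple[np.ndarray, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "outer", _as_ring(self.outer))
        object.__setattr__(self, "holes", tuple(_as_ring(h) for h in self.holes))
        self.validate()

    def validate(self) -> None:
        if len(self.outer) < 3:
            raise ValidationError(f"outer contour needs >= 3 vertices, got {len(self.outer)}")
        shell = Polygon(self.outer)
        if not shell.is_valid or shell.area <= 0:
            raise ValidationError("outer contour is degenerate or self-intersecting")
        hole_polys = []
        for i, h in enumerate(self.holes):
            if len(h) < 3:
                raise ValidationError(f"hole {i} needs >= 3 vertices")
            hp = Polygon(h)
            if not hp.is_valid or hp.area <= 0:
                raise ValidationError(f"hole {i} is degenerate or self-intersecting")
            if not shell.contains_properly(hp):
                raise ValidationError(f"hole {i} does not lie strictly inside the outer contour")
            hole_polys.append(hp)
        for i in range(len(hole_polys)):
            for j in range(i + 1, len(hole_polys)):
                if hole_polys[i].intersects(hole_polys[j]):
                    raise ValidationError(f"holes {i} and {j} are not disjoint")
        poly = Polygon(self.outer, [h for h in self.holes])
        if not poly.is_valid:
            raise ValidationError("region polygon is invalid")

    def to_polygon(self) -> Polygon:
        """Shapely polygon with holes (material region)."""
        return Polygon(self.outer, [h for h in self.holes])

    def __eq__(self, other):
        if not isinstance(other, Region):
            return NotImplemented
        return (
            len(self.holes) == len(other.holes)
            and np.array_equal(self.outer, other.outer)
            and all(np.array_equal(a, b) for a, b in zip(self.holes, other.holes))
        )


@dataclass(frozen=True)
class PSDRecord:
    """One PSD: identity, grouping labels, contour region, particle list."""

    psd_id: str
    animal_id: str
    layer: str
    target: str
    region: Region
    particles: tuple[Particle, ...] = ()
    morphology: str | None = None

    def __post_init__(self):
        if not self.psd_id:
            raise ValidationError("psd_id must be non-empty")
        if not self.animal_id:
            raise ValidationError(f"animal_id must be non-empty (psd_id={self.psd_id})")
        _check_vocab(self.layer, LAYERS, "layer")
        _check_vocab(self.target, TARGETS, "target")
        if self.morphology is not None:
            _check_vocab(self.morphology, MORPHOLOGIES, "morphology")
        object.__setattr__(self, "particles", tuple(self.particles))


@dataclass
class StudyDataset:
    """A set of PSD records plus free-form metadata (units, provenance, seed)."""

    records: list[PSDRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.psd_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"psd_id values not unique: {dupes}")
        self.metadata.setdefault("units", "nm")

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# JSON I/O

def _record_to_json(rec: PSDRecord) -> dict:
    return {
        "psd_id": rec.psd_id,
        "animal_id": rec.animal_id,
        "layer": rec.layer,
        "target": rec.target,
        "morphology": rec.morphology,
        "region": {
            "outer": rec.region.outer.tolist(),
            "holes": [h.tolist() for h in rec.region.holes],
        },
        "particles": [
            {"x": p.x, "y": p.y, "gold_size": p.gold_size, "receptor": p.receptor}
            for p in rec.particles
        ],
    }


def _record_from_json(obj: Mapping) -> PSDRecord:
    psd_id = obj.get("psd_id", "<missing psd_id>")
    try:
        region = Region(
            outer=obj["region"]["outer"],
            holes=tuple(obj["region"].get("holes", ())),
        )
        particles = tuple(
            Particle(
                x=float(p["x"]), y=float(p["y"]),
                gold_size=int(p["gold_size"]), receptor=str(p["receptor"]),
            )
            for p in obj.get("particles", ())
        )
        return PSDRecord(
            psd_id=str(obj["psd_id"]),
            animal_id=str(obj["animal_id"]),
            layer=str(obj["layer"]),
            target=str(obj["target"]),
            region=region,
            particles=particles,
            morphology=obj.get("morphology"),
        )
    except KeyError as e:
        raise ValidationError(f"record {psd_id}: missing required field {e}") from e
    except ValidationError as e:
        raise ValidationError(f"record {psd_id}: {e}") from e


def read_dataset(path) -> StudyDataset:
    """Read and validate a study dataset from its JSON exchange format."""
    path = Path(path)
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValueError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
    if not isinstance(obj, dict) or "records" not in obj:
        raise ValidationError(f"{path}: top level must be an object with a 'records' list")
    records = [_record_from_json(r) for r in obj["records"]]
    return StudyDataset(records=records, metadata=dict(obj.get("metadata", {})))


def write_dataset(ds: StudyDataset, path) -> Path:
    """Write a dataset to JSON; the file round-trips through read_dataset."""
    path = Path(path)
    obj = {
        "metadata": dict(ds.metadata),
        "records": [_record_to_json(r) for r in ds.records],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Selection

def select(
    ds: StudyDataset,
    layer: str | None = None,
    target: str | None = None,
    receptor: str | None = None,
    gold_size: int | None = None,
    morphology: str | None = None,
) -> StudyDataset:
    """Filter records by grouping labels and particles by receptor/gold size.

    Records are kept when they match every given record-level filter; particle
    lists are filtered by ``receptor``/``gold_size`` when given. Idempotent.
    """
    if layer is not None:
        _check_vocab(layer, LAYERS, "layer")
    if target is not None:
        _check_vocab(target, TARGETS, "target")
    if receptor is not None:
        _check_vocab(receptor, RECEPTORS, "receptor")
    if gold_size is not None:
        _check_vocab(gold_size, GOLD_SIZES, "gold_size")
    if morphology is not None:
        _check_vocab(morphology, MORPHOLOGIES, "morphology")

    out = []
    for rec in ds.records:
        if layer is not None and rec.layer != layer:
            continue
        if target is not None and rec.target != target:
            continue
        if morphology is not None and rec.morphology != morphology:
            continue
        particles = rec.particles
        if receptor is not None:
            particles = tuple(p for p in particles if p.receptor == receptor)
        if gold_size is not None:
            particles = tuple(p for p in particles if p.gold_size == gold_size)
        out.append(replace(rec, particles=particles) if particles is not rec.particles else rec)
    return StudyDataset(records=out, metadata=dict(ds.metadata))
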