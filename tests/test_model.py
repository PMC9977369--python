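import json

import numpy as np
import pytest

from psdgold.model import (
    Particle,
    PSDRecord,
    Region,
    StudyDataset,
    ValidationError,
    read_dataset,
    select,
    write_dataset,
)

from conftest import make_record, ring_region, square_region


def _dataset():
    recs = [
        make_record(square_region(100.0), [(0, 0), (10, 20), (-30, 5)],
                    psd_id="a", layer="L4", target="shaft"),
        make_record(square_region(150.0, center=(500, 500)), [(500, 500)],
                    psd_id="b", layer="L5", target="spine"),
        make_record(ring_region(), [(70, 0)], psd_id="c", layer="L4",
                    target="spine", morphology="ring"),
    ]
    return StudyDataset(records=recs, metadata={"units": "nm"})


class TestRegionInvariants:
    def test_outer_needs_three_vertices(self):
        with pytest.raises(ValidationError):
            Region(outer=[[0, 0], [1, 0]])

    def test_self_intersecting_outer_rejected(self):
        with pytest.raises(ValidationError):
            Region(outer=[[0, 0], [10, 10], [10, 0], [0, 10]])  # bow-tie

    def test_hole_outside_outer_rejected(self):
        with pytest.raises(ValidationError):
            Region(outer=[[0, 0], [10, 0], [10, 10], [0, 10]],
                   holes=([[20, 20], [25, 20], [25, 25]],))

    def test_overlapping_holes_rejected(self):
        with pytest.raises(ValidationError):
            Region(outer=[[0, 0], [100, 0], [100, 100], [0, 100]],
                   holes=([[10, 10], [50, 10], [50, 50], [10, 50]],
                          [[40, 40], [80, 40], [80, 80], [40, 80]]))

    def test_duplicated_closing_vertex_dropped(self):
        r = Region(outer=[[0, 0], [10, 0], [10, 10], [0, 10], [0, 0]])
        assert len(r.outer) == 4


class TestParticleAndRecord:
    def test_gold_size_vocabulary(self):
        with pytest.raises(ValidationError):
            Particle(x=0, y=0, gold_size=7, receptor="AMPA")

    def test_receptor_vocabulary(self):
        with pytest.raises(ValidationError):
            Particle(x=0, y=0, gold_size=5, receptor="kainate")

    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValidationError):
            Particle(x=float("nan"), y=0, gold_size=5, receptor="AMPA")

    def test_layer_vocabulary(self):
        with pytest.raises(ValidationError):
            make_record(layer="L6")

    def test_duplicate_psd_ids_rejected(self):
        with pytest.raises(ValidationError):
            StudyDataset(records=[make_record(psd_id="x"),
                                  make_record(psd_id="x")])


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        ds = _dataset()
        path = write_dataset(ds, tmp_path / "ds.json")
        back = read_dataset(path)
        assert len(back) == len(ds)
        for r1, r2 in zip(ds.records, back.records):
            assert r1.psd_id == r2.psd_id
            assert r1.layer == r2.layer and r1.target == r2.target
            assert r1.morphology == r2.morphology
            assert r1.region == r2.region
            assert r1.particles == r2.particles
        # and a second round trip is byte-identical
        path2 = write_dataset(back, tmp_path / "ds2.json")
        assert path.read_bytes() == path2.read_bytes()

    def test_empty_dataset_round_trips(self, tmp_path):
        path = write_dataset(StudyDataset(), tmp_path / "empty.json")
        back = read_dataset(path)
        assert back.records == []

    def test_gold_size_15_preserved(self, tmp_path):
        rec = PSDRecord(
            psd_id="p", animal_id="A01", layer="L4", target="shaft",
            region=square_region(),
            particles=(Particle(x=1, y=2, gold_size=15, receptor="GluN1"),),
        )
        path = write_dataset(StudyDataset(records=[rec]), tmp_path / "d.json")
        assert read_dataset(path).records[0].particles[0].gold_size == 15

    def test_malformed_json_names_line(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"records": [\n  {broken\n]}')
        with pytest.raises(ValueError, match="line"):
            read_dataset(path)

    def test_invalid_record_error_names_psd_id(self, tmp_path):
        obj = {"metadata": {}, "records": [{
            "psd_id": "bad-one", "animal_id": "A01", "layer": "L4",
            "target": "shaft",
            "region": {"outer": [[0, 0], [100, 0], [100, 100], [0, 100]],
                       "holes": [[[200, 200], [210, 200], [210, 210]]]},
            "particles": [],
        }]}
        path = tmp_path / "inv.json"
        path.write_text(json.dumps(obj))
        with pytest.raises(ValidationError, match="bad-one"):
            read_dataset(path)


class TestSelect:
    def test_layer_filter(self):
        ds = _dataset()
        out = select(ds, layer="L4")
        assert {r.psd_id for r in out.records} == {"a", "c"}

    def test_receptor_filter_drops_other_particles(self, two_receptor_dataset):
        out = select(two_receptor_dataset, receptor="AMPA")
        assert all(p.receptor == "AMPA" for r in out.records for p in r.particles)

    def test_no_criteria_is_identity(self):
        ds = _dataset()
        out = select(ds)
        assert [r.psd_id for r in out.records] == [r.psd_id for r in ds.records]

    def test_unknown_value_lists_allowed(self):
        with pytest.raises(ValidationError, match="L4"):
            select(_dataset(), layer="L9")

    def test_select_idempotent_and_composes(self):
        ds = _dataset()
        once = select(ds, layer="L4")
        twice = select(once, layer="L4")
        assert [r.psd_id for r in once.records] == [r.psd_id for r in twice.records]
        combined = select(ds, layer="L4", target="spine")
        staged = select(select(ds, layer="L4"), target="spine")
        assert ([r.psd_id for r in combined.records]
                == [r.psd_id for r in staged.records])
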