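import numpy as np
import pytest

from psdgold.model import Particle, PSDRecord, Region, StudyDataset
from psdgold.nulls import NullSpec
from psdgold.synth import CellConfig, GeneratorConfig, generate_study


def square_region(side=100.0, center=(0.0, 0.0)):
    cx, cy = center
    h = side / 2.0
    return Region(outer=[[cx - h, cy - h], [cx + h, cy - h],
                         [cx + h, cy + h], [cx - h, cy + h]])


def disc_region(radius=60.0, center=(0.0, 0.0), n=720):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Region(outer=np.column_stack([
        center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]))


def ring_region(r_outer=100.0, r_inner=40.0, n=72):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    outer = np.column_stack([r_outer * np.cos(ang), r_outer * np.sin(ang)])
    inner = np.column_stack([r_inner * np.cos(ang), r_inner * np.sin(ang)])
    return Region(outer=outer, holes=(inner,))


def make_record(region=None, particles=(), psd_id="p1", layer="L4",
                target="shaft", animal="A01", morphology=None):
    return PSDRecord(
        psd_id=psd_id, animal_id=animal, layer=layer, target=target,
        region=region if region is not None else square_region(),
        particles=tuple(Particle(x=x, y=y, gold_size=5, receptor="AMPA")
                        for x, y in particles),
        morphology=morphology,
    )


@pytest.fixture
def square_record():
    return make_record(square_region(100.0),
                       particles=[(0.0, 0.0), (30.0, 10.0), (-20.0, -40.0)])


@pytest.fixture
def ring_record():
    return make_record(ring_region(), particles=[(70.0, 0.0), (0.0, 0.0)],
                       morphology="ring")


@pytest.fixture(scope="session")
def small_study():
    """~40 uniform-placement PSDs, one cell, ~25 grains each."""
    cell = CellConfig("L4", "shaft", "AMPA", area_mean=0.05, area_sd=0.015,
                      density=500.0, r2_target=0.6, n_psd=40)
    cfg = GeneratorConfig(cells=(cell,), seed=11,
                          placement=NullSpec(model="equal", seed=11))
    ds, truth = generate_study(cfg)
    return ds, truth


@pytest.fixture
def two_receptor_dataset():
    """Two animals, equal AMPA/GluN1 structure for ratio tests."""
    records = []
    for a, animal in enumerate(["A01", "A02"]):
        for i in range(3):
            for receptor in ("AMPA", "GluN1"):
                n_grains = 4 + i
                region = square_region(200.0)
                parts = tuple(
                    Particle(x=float(10 * j - 40), y=float(5 * j - 20),
                             gold_size=5, receptor=receptor)
                    for j in range(n_grains)
                )
                records.append(PSDRecord(
                    psd_id=f"{animal}-{receptor}-{i}", animal_id=animal,
                    layer="L4", target="spine", region=region,
                    particles=parts,
                ))
    return StudyDataset(records=records)
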