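import numpy as np
import pytest

import pdokit as pk


@pytest.fixture(scope="session")
def cohort():
    """Small synthetic cohort reused across read-only tests."""
    cfg = pk.CohortConfig(
        n_pairs=6,
        snvs_per_sample=300,
        seed=11,
        planted_effects=(pk.PlantedEffect("G010", "lapatinib", -2.0),),
    )
    return pk.generate_cohort(cfg)


@pytest.fixture
def diploid_profile():
    return pk.SegmentProfile(
        sample_id="DIP_PT",
        sample_class=pk.SampleClass.PT,
        tumor_class=pk.TumorClass.NMIBC_LG,
        purity=0.8,
        segments=[
            pk.Segment("chr1", 0, 1_000_000, 1, 1),
            pk.Segment("chr1", 1_000_000, 4_000_000, 1, 1),
            pk.Segment("chr2", 0, 2_000_000, 1, 1),
        ],
    )


@pytest.fixture
def triploid_profile():
    return pk.SegmentProfile(
        sample_id="TRI_PT",
        sample_class=pk.SampleClass.PT,
        tumor_class=pk.TumorClass.MIBC,
        purity=0.8,
        segments=[
            pk.Segment("chr1", 0, 3_000_000, 2, 1),
            pk.Segment("chr1", 3_000_000, 5_000_000, 2, 1),
            pk.Segment("chr2", 0, 7_000_000, 2, 1),
        ],
    )


def make_plate(sample_id="S1", vehicle=(90.0, 100.0, 110.0), **drugs):
    """Plate with DMSO vehicle wells plus the given drug replicate readouts."""
    wells = [
        pk.Well(condition="DMSO", vehicle_class=pk.VehicleClass.DMSO, readout=v)
        for v in vehicle
    ]
    for drug, readouts in drugs.items():
        wells += [
            pk.Well(condition=drug, vehicle_class=pk.VehicleClass.DMSO, readout=r)
            for r in readouts
        ]
    return pk.PlateData(sample_id=sample_id, wells=wells)
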