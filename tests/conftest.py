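import pytest

from quadassay.assay_data import ArenaRecord, ExperimentSet
from quadassay.synthetic_worms import SimulationConfig


def make_record(
    plate_id="P1",
    assay_type="chemotaxis",
    orientation="A",
    odorant="butanone 10%",
    vehicle="ethanol",
    cohort="d1",
    counts=(5, 15, 35, 45),
    **extra,
):
    if assay_type == "dispersal":
        odorant = "none"
    return ArenaRecord(
        plate_id=plate_id,
        assay_type=assay_type,
        orientation=orientation,
        odorant=odorant,
        vehicle=vehicle,
        cohort=cohort,
        physical_counts=tuple(counts),
        extra=dict(extra),
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def attraction_experiment():
    """Hand-built interpretable attraction experiment (n>100 everywhere)."""
    arenas = []
    for i, cohort in enumerate(("d1", "d2"), start=1):
        arenas.append(
            make_record(
                plate_id=f"D{i}",
                assay_type="dispersal",
                cohort=cohort,
                counts=(37, 38, 37, 38),
            )
        )
        arenas.append(
            make_record(plate_id=f"C{i}A", orientation="A", cohort=cohort, counts=(5, 15, 35, 95))
        )
        arenas.append(
            make_record(plate_id=f"C{i}B", orientation="B", cohort=cohort, counts=(96, 30, 16, 8))
        )
    return ExperimentSet(odorant="butanone 10%", arenas=arenas)


@pytest.fixture
def fast_config():
    """Short simulation for structural tests; not calibrated for regimes."""

    def build(**kw):
        kw.setdefault("duration", 300.0)
        kw.setdefault("dt", 2.0)
        kw.setdefault("n_worms", 120)
        return SimulationConfig(**kw)

    return build
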