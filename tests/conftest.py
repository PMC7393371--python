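import numpy as np
import pytest

from macromate.events import CopulationEvent, DropRecord, PairRecord, SuckEvent


@pytest.fixture
def simple_pair() -> PairRecord:
    """Two copulations at (100,160) and (300,350), one suck after each."""
    cops = [
        CopulationEvent("p1", "a", "b", 100, 160),
        CopulationEvent("p1", "a", "b", 300, 350),
    ]
    sucks = [
        SuckEvent("p1", 170, 180, preceding_copulation_index=0),
        SuckEvent("p1", 360, 375, preceding_copulation_index=1),
    ]
    return PairRecord(
        pair_id="p1", pairing_type="lignano", copulations=cops, sucks=sucks
    )


@pytest.fixture
def typed_drop() -> DropRecord:
    cops = [
        CopulationEvent("d1", "L1", "L2", 50, 80, "LL"),
        CopulationEvent("d1", "L1", "J1", 200, 300, "LJ"),
        CopulationEvent("d1", "L1", "L2", 500, 540, "LL"),
    ]
    return DropRecord(drop_id="d1", copulations=cops)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
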