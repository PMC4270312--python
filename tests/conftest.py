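import numpy as np
import pytest

from calscreen.core import PlateLayout, WellRole, WellSpec, default_schedule


@pytest.fixture
def schedule():
    return default_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_layout(
    n_compounds: int = 4,
    n_replicates: int = 4,
    n_vehicle: int = 4,
    controls: tuple[str, ...] = (),
    plate_id: str = "plate1",
) -> PlateLayout:
    """Compact helper: compounds in replicate wells + vehicle + controls."""
    rows = "ABCDEFGHIJKLMNOP"
    wells = []
    idx = 0

    def next_addr():
        nonlocal idx
        addr = f"{rows[idx % 16]}{idx // 16 + 1}"
        idx += 1
        return addr

    for i in range(n_compounds):
        cid = f"c{i + 1:02d}"
        for _ in range(n_replicates):
            wells.append(
                WellSpec(next_addr(), WellRole.TEST, cid, 10e-6, replicate_group=cid)
            )
    for _ in range(n_vehicle):
        wells.append(WellSpec(next_addr(), WellRole.VEHICLE, replicate_group="veh"))
    for ctrl in controls:
        wells.append(
            WellSpec(next_addr(), WellRole.POSITIVE_CONTROL, ctrl, 1e-6, replicate_group=ctrl)
        )
    return PlateLayout(plate_id, 384, tuple(wells))


@pytest.fixture
def small_layout():
    return make_layout(n_compounds=2, n_replicates=2, n_vehicle=2, controls=("TP",))
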