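import numpy as np
import pandas as pd
import pytest

from platetrace import AssayTable, PlateLayout, WellSpec


@pytest.fixture
def small_table() -> AssayTable:
    """4 time points, 2 wells, plain numbers."""
    return AssayTable(
        time=np.array([0.0, 1.0, 2.0, 3.0]),
        data=pd.DataFrame({"A": [1.0, 2.0, 3.0, 4.0], "B": [10.0, 20.0, 30.0, 40.0]}),
        time_unit="h",
        value_unit="% a.s.",
    )


@pytest.fixture
def ref_layout() -> PlateLayout:
    """Layout for a 4-column table: 2 references + 2 samples with doses."""
    return PlateLayout(
        wells={
            "R1": WellSpec(label="medium", group="medium", role="medium_control"),
            "R2": WellSpec(label="medium", group="medium", role="medium_control"),
            "S1": WellSpec(label="drug 10", group="drug 10", role="sample", dose=10.0),
            "S2": WellSpec(label="drug 20", group="drug 20", role="sample", dose=20.0),
        }
    )


def make_table(time, columns, **kw) -> AssayTable:
    return AssayTable(time=np.asarray(time, float), data=pd.DataFrame(columns), **kw)
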