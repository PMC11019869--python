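import numpy as np
import pandas as pd
import pytest

from riveremf.data_model import (
    AbundanceMatrix,
    FunctionCategory,
    FunctionSchema,
    FunctionTable,
)


@pytest.fixture
def tiny_schema() -> FunctionSchema:
    return FunctionSchema(
        categories={
            "f1": FunctionCategory.NITROGEN_CYCLING,
            "f2": FunctionCategory.NITROGEN_CYCLING,
            "f3": FunctionCategory.WATER_QUALITY,
        },
        directions={"f1": 1, "f2": 1, "f3": -1},
    )


def make_table(values: np.ndarray, schema: FunctionSchema, latitudes=None) -> FunctionTable:
    n = values.shape[0]
    idx = pd.MultiIndex.from_arrays(
        [[f"S{i}" for i in range(n)], ["rhizosphere"] * n], names=["site_id", "habitat"]
    )
    lats = latitudes if latitudes is not None else np.linspace(22.0, 45.0, n)
    meta = pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(n)],
            "habitat": "rhizosphere",
            "latitude": lats,
            "longitude": 110.0,
            "elevation": 10.0,
            "lat_group": np.where(np.asarray(lats) < 33.0, "low", "high"),
        },
        index=idx,
    )
    vals = pd.DataFrame(values, index=idx, columns=schema.functions)
    return FunctionTable(values=vals, metadata=meta, schema=schema)


@pytest.fixture
def tiny_table(tiny_schema) -> FunctionTable:
    return make_table(np.array([[2.0, 0.2, 3.0], [4.0, 0.4, 5.0], [6.0, 0.9, 4.0]]), tiny_schema)


@pytest.fixture
def counts_matrix() -> AbundanceMatrix:
    data = pd.DataFrame(
        [[5.0, 5.0, 5.0, 5.0, 0.0], [10.0, 0.0, 0.0, 2.0, 1.0], [1.0, 2.0, 3.0, 4.0, 5.0]],
        index=pd.Index(["a", "b", "c"], name="sample"),
        columns=["t1", "t2", "t3", "t4", "t5"],
    )
    return AbundanceMatrix(data=data)
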