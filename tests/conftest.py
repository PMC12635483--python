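import numpy as np
import pandas as pd
import pytest

from somnidyn.io_atlas import AtlasMap, Hypnogram, RoiTimeSeries


@pytest.fixture(scope="session")
def bundled_atlas():
    from somnidyn import load_atlas

    return load_atlas("bundled")


def _tiny_atlas_frame() -> pd.DataFrame:
    """18-ROI atlas: all 5 thalamic subnetworks (2/2/4/2/2) + 3 small
    cortical networks (one sensory)."""
    rows = []
    for net, n in [("DMN", 2), ("VIS", 2), ("CON", 2)]:
        rows += [(f"{net}_{i}", net, "cortical") for i in range(1, n + 1)]
    k = 0
    for net, n in [("THAL_DMN", 2), ("THAL_VIS", 2), ("THAL_CON", 4),
                   ("THAL_lSMN", 2), ("THAL_dSMN", 2)]:
        for _ in range(n):
            k += 1
            rows.append((f"THAL_{k}", net, "thalamic"))
    df = pd.DataFrame(rows, columns=["roi_label", "network", "role"])
    df.index = pd.RangeIndex(len(df), name="roi_id")
    return df


@pytest.fixture(scope="session")
def tiny_atlas():
    return AtlasMap(_tiny_atlas_frame())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ts(data, **kw) -> RoiTimeSeries:
    data = np.asarray(data, dtype=float)
    kw.setdefault("roi_labels", [f"roi{i}" for i in range(data.shape[1])])
    return RoiTimeSeries(data=data, **kw)


@pytest.fixture
def hypnogram_simple():
    return Hypnogram(("Wake", "Wake", "Wake", "N1", "N1", "REM", "REM",
                      "REM", "REM"))
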