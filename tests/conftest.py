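import numpy as np
import pandas as pd
import pytest

from coexistevo import DFEParams, SimParams
from coexistevo.marker_dynamics import MarkerTrajectory
from coexistevo.variant_analysis import VariantTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def neutral_params():
    """Small neutral population: two lineages at 0.5 each."""
    return SimParams(
        n_total=100,
        generations=50,
        u=0.0,
        dfe=DFEParams(kind="fixed", mean_s=0.01),
        initial_fractions=(0.5, 0.5, 0.0, 0.0),
        seed=0,
        record_every=1,
    )


def make_variant_rows(rows):
    """Build a VariantTable from abbreviated row dicts."""
    defaults = {
        "strain": "B1",
        "mouse": 1,
        "day": 88,
        "contig": "chr",
        "position": 0,
        "target": "gene",
        "var_class": "SNP_NS",
        "frequency": 0.5,
        "supporting_reads": 20,
        "region_start": np.nan,
        "region_end": np.nan,
    }
    full = []
    for i, r in enumerate(rows):
        row = {**defaults, "position": i * 100, **r}
        if row["var_class"] in ("large_deletion", "HGT") and np.isnan(
            row["region_start"]
        ):
            row["region_start"] = row["position"]
            row["region_end"] = row["position"] + 10_000
        full.append(row)
    return VariantTable(pd.DataFrame(full))


@pytest.fixture
def variant_factory():
    return make_variant_rows


def make_trajectory(records, lod=300.0):
    return MarkerTrajectory(
        data=pd.DataFrame(records, columns=["mouse_id", "day", "marker", "cfu_per_g"]),
        detection_limit=lod,
    )


@pytest.fixture
def trajectory_factory():
    return make_trajectory
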