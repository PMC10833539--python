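import pandas as pd
import pytest

from signet.genomic_links import RegionClosest, TFInclusion
from signet.graph import RegulatoryGraph, build_graph


@pytest.fixture
def toy_graph() -> RegulatoryGraph:
    """2 TFs x 2 regions x 2 genes; TF2 has no site in Region2 and Region1
    is beyond the distance cutoff from G2, so the join yields 4 triples."""
    gene_patterns = {"G1": "1124", "G2": "4441", "TF1": "4441", "TF2": "1114"}
    tf_patterns = {"TF1": "4441", "TF2": "1114"}
    region_patterns = {"R1": "1124", "R2": "4441"}
    neighbors = [
        RegionClosest("R1", "G1", 1_000),
        RegionClosest("R2", "G1", 20_000),
        RegionClosest("R2", "G2", 0),
    ]
    inclusions = [
        TFInclusion("TF1", "R1"),
        TFInclusion("TF2", "R1"),
        TFInclusion("TF1", "R2"),
    ]
    return build_graph(gene_patterns, tf_patterns, region_patterns,
                       neighbors, inclusions)


@pytest.fixture
def expression_table() -> tuple[pd.DataFrame, dict[str, str]]:
    table = pd.DataFrame(
        {
            "a1": [10.0, 0.0, 100.0],
            "a2": [10.0, 0.0, 100.0],
            "b1": [1000.0, 0.0, 100.0],
            "b2": [1000.0, 0.0, 100.0],
        },
        index=["g_var", "g_silent", "g_const"],
    )
    sample_map = {"a1": "popA", "a2": "popA", "b1": "popB", "b2": "popB"}
    return table, sample_map
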