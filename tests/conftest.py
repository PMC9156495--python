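from __future__ import annotations

import pytest

from lta.dataset_io import AbundanceTable, TrafficNetwork, table_from_records


@pytest.fixture
def tri_network() -> TrafficNetwork:
    """Liver--serum--brain path, the smallest interesting traffic network."""
    return TrafficNetwork(
        compartments=("liver", "serum", "brain"),
        axes=(("serum", "liver"), ("serum", "brain")),
    )


@pytest.fixture
def mono_network() -> TrafficNetwork:
    return TrafficNetwork(compartments=("serum",), axes=())


def make_table(records, network) -> AbundanceTable:
    """Build a validated AbundanceTable from (sample, pheno, comp, lipid, signal) tuples."""
    return table_from_records(
        [
            {
                "sample_id": s,
                "phenotype": p,
                "compartment": c,
                "lipid": l,
                "signal": v,
            }
            for s, p, c, l, v in records
        ],
        network,
    )


@pytest.fixture
def toy_table(tri_network) -> AbundanceTable:
    """Two phenotypes x three compartments x two samples, two lipids.

    TG(50:1) is detected everywhere; PI(38:6) is detected only for 'case'
    in liver and serum.
    """
    rows = []
    for comp in tri_network.compartments:
        for pheno in ("ctrl", "case"):
            for i in (1, 2):
                sid = f"{pheno}{i}"
                rows.append((sid, pheno, comp, "TG(50:1)", 10.0 + i))
                if pheno == "case" and comp in ("liver", "serum"):
                    rows.append((sid, pheno, comp, "PI(38:6)", 5.0))
    return make_table(rows, tri_network)
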