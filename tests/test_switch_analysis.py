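import itertools

import pytest

from lta.dataset_io import TrafficNetwork
from lta.jaccard_stats import JaccardParams
from lta.presence import call_presence
from lta.switch_analysis import (
    classify_axis,
    classify_node,
    find_ubiquitous,
    run_switch,
)
from tests.conftest import make_table


def table_from_presence(pattern, network, phenotypes=("case", "ctrl"), n=1):
    """Build a table realising a given (lipid, comp, pheno) -> bool pattern."""
    rows = []
    lipids = sorted({l for l, _, _ in pattern})
    for comp in network.compartments:
        for pheno in phenotypes:
            for i in range(n):
                sid = f"{pheno}{i}"
                for lipid in lipids:
                    val = 1.0 if pattern.get((lipid, comp, pheno), False) else 0.0
                    rows.append((sid, pheno, comp, lipid, val))
    return make_table(rows, network)


class TestClassifyNode:
    def test_a_b_and_omitted(self, tri_network):
        pattern = {
            ("TG(50:1)", "liver", "ctrl"): True,
            ("TG(50:1)", "liver", "case"): True,   # A
            ("TG(44:0)", "liver", "ctrl"): True,   # B ctrl
            ("PI(38:6)", "liver", "case"): True,   # B case
            # PE(40:7) present nowhere -> omitted
            ("PE(40:7)", "serum", "ctrl"): False,
        }
        pm = call_presence(table_from_presence(pattern, tri_network))
        sc = classify_node(pm, "liver")
        assert sc.a_types == ("TG(50:1)",)
        assert sc.b_types == {"TG(44:0)": "ctrl", "PI(38:6)": "case"}

    def test_unknown_compartment(self, tri_network):
        pattern = {("TG(50:1)", "liver", "ctrl"): True}
        pm = call_presence(table_from_presence(pattern, tri_network))
        with pytest.raises(ValueError, match="unknown compartment"):
            classify_node(pm, "pancreas")

    def test_partition_invariant_exhaustive(self, tri_network):
        # brute force: every presence combination of one lipid at one node
        for in_ctrl, in_case in itertools.product([True, False], repeat=2):
            pattern = {
                ("TG(50:1)", "liver", "ctrl"): in_ctrl,
                ("TG(50:1)", "liver", "case"): in_case,
            }
            pm = call_presence(table_from_presence(pattern, tri_network))
            sc = classify_node(pm, "liver")
            n_present = int(in_ctrl or in_case)
            assert len(sc.a_types) + len(sc.b_types) == n_present


class TestClassifyAxis:
    def test_axis_b_type_case_only(self, tri_network):
        pattern = {
            ("PI(38:6)", "serum", "case"): True,
            ("PI(38:6)", "brain", "case"): True,
        }
        pm = call_presence(table_from_presence(pattern, tri_network))
        sc = classify_axis(pm, ("serum", "brain"))
        assert sc.b_types == {"PI(38:6)": "case"}

    def test_axis_a_type(self, tri_network):
        pattern = {
            ("TG(50:1)", "serum", p): True for p in ("ctrl", "case")
        } | {("TG(50:1)", "liver", p): True for p in ("ctrl", "case")}
        pm = call_presence(table_from_presence(pattern, tri_network))
        sc = classify_axis(pm, ("serum", "liver"))
        assert sc.a_types == ("TG(50:1)",)

    def test_planted_control_only_lipid_exhaustive(self, tri_network):
        # plant one ctrl-only lipid on serum--liver; enumerate background
        # presence combinations of a second lipid and check the B-list is
        # exactly the planted one every time
        endpoints = [("liver", "ctrl"), ("liver", "case"),
                     ("serum", "ctrl"), ("serum", "case")]
        for combo in itertools.product([True, False], repeat=4):
            pattern = {
                ("TG(44:0)", "liver", "ctrl"): True,
                ("TG(44:0)", "serum", "ctrl"): True,
            }
            for (comp, pheno), present in zip(endpoints, combo):
                pattern[("TG(50:1)", comp, pheno)] = present
            pm = call_presence(table_from_presence(pattern, tri_network))
            sc = classify_axis(pm, ("serum", "liver"))
            ctrl_b = {l for l, p in sc.b_types.items() if p == "ctrl"}
            on_ctrl = combo[0] and combo[2]
            on_case = combo[1] and combo[3]
            expected = {"TG(44:0)"} | ({"TG(50:1)"} if on_ctrl and not on_case else set())
            assert ctrl_b == expected


class TestUbiquitous:
    def test_both_phenotypes(self, tri_network):
        pattern = {
            ("TG(50:1)", c, p): True
            for c in tri_network.compartments
            for p in ("ctrl", "case")
        }
        pm = call_presence(table_from_presence(pattern, tri_network))
        assert find_ubiquitous(pm, tri_network) == {"TG(50:1)": ("case", "ctrl")}

    def test_one_phenotype_only(self, tri_network):
        pattern = {
            ("TG(50:1)", c, "ctrl"): True for c in tri_network.compartments
        }
        pattern[("TG(50:1)", "liver", "case")] = True  # misses serum + brain
        pm = call_presence(table_from_presence(pattern, tri_network))
        assert find_ubiquitous(pm, tri_network) == {"TG(50:1)": ("ctrl",)}

    def test_empty_u_list(self, tri_network):
        pattern = {
            ("TG(50:1)", "liver", "ctrl"): True,
            ("TG(50:1)", "liver", "case"): True,
            ("TG(44:0)", "serum", "ctrl"): True,
        }
        pm = call_presence(table_from_presence(pattern, tri_network))
        assert find_ubiquitous(pm, tri_network) == {}


class TestRunSwitch:
    def test_identical_phenotypes_all_a_and_j1(self, tri_network):
        pattern = {}
        for lipid in ("TG(50:1)", "PI(38:6)"):
            for c in tri_network.compartments:
                for p in ("ctrl", "case"):
                    pattern[(lipid, c, p)] = True
        pm = call_presence(table_from_presence(pattern, tri_network))
        report = run_switch(pm, tri_network, JaccardParams(B_permutations=200, seed=1))
        for sc in list(report.nodes.values()) + list(report.axes.values()):
            assert len(sc.b_types) == 0
            assert len(sc.a_types) == 2
        for res in report.jaccard.values():
            assert res.J == 1.0

    def test_single_compartment_no_axes(self, mono_network):
        rows = [
            ("c1", "ctrl", "serum", "TG(50:1)", 1.0),
            ("x1", "case", "serum", "TG(50:1)", 1.0),
        ]
        pm = call_presence(make_table(rows, mono_network))
        report = run_switch(pm, mono_network, JaccardParams(B_permutations=200, seed=1))
        assert report.axes == {}
        assert report.nodes["serum"].a_types == ("TG(50:1)",)

    def test_relabelling_swaps_b_attributions(self, tri_network):
        pattern = {
            ("TG(44:0)", "liver", "ctrl"): True,
            ("PI(38:6)", "liver", "case"): True,
            ("TG(50:1)", "liver", "ctrl"): True,
            ("TG(50:1)", "liver", "case"): True,
        }
        pm1 = call_presence(table_from_presence(pattern, tri_network))
        swapped = {(l, c, {"ctrl": "case", "case": "ctrl"}[p]): v
                   for (l, c, p), v in pattern.items()}
        pm2 = call_presence(table_from_presence(swapped, tri_network))
        r1 = run_switch(pm1, tri_network, JaccardParams(B_permutations=200, seed=1))
        r2 = run_switch(pm2, tri_network, JaccardParams(B_permutations=200, seed=1))
        assert r1.nodes["liver"].a_types == r2.nodes["liver"].a_types
        assert r1.nodes["liver"].b_types == {"TG(44:0)": "ctrl", "PI(38:6)": "case"}
        assert r2.nodes["liver"].b_types == {"TG(44:0)": "case", "PI(38:6)": "ctrl"}
        for scope in r1.jaccard:
            assert r1.jaccard[scope].J == r2.jaccard[scope].J

    def test_axis_lists_bounded_by_endpoints(self, tri_network):
        pattern = {
            ("TG(44:0)", "liver", "ctrl"): True,
            ("TG(44:0)", "serum", "ctrl"): True,
            ("PI(38:6)", "serum", "case"): True,
            ("TG(50:1)", "liver", "ctrl"): True,
            ("TG(50:1)", "liver", "case"): True,
            ("TG(50:1)", "serum", "ctrl"): True,
            ("TG(50:1)", "serum", "case"): True,
        }
        pm = call_presence(table_from_presence(pattern, tri_network))
        axis_sc = classify_axis(pm, ("serum", "liver"))
        for comp in ("serum", "liver"):
            node_sc = classify_node(pm, comp)
            node_all = set(node_sc.a_types) | set(node_sc.b_types)
            assert set(axis_sc.a_types) | set(axis_sc.b_types) <= node_all

    def test_types_frame_shape(self, tri_network):
        pattern = {
            ("TG(50:1)", c, p): True
            for c in tri_network.compartments
            for p in ("ctrl", "case")
        }
        pm = call_presence(table_from_presence(pattern, tri_network))
        report = run_switch(pm, tri_network, JaccardParams(B_permutations=200, seed=1))
        frame = report.types_frame()
        assert list(frame.columns) == [
            "scope", "scope_kind", "lipid", "type", "attributed_phenotype"
        ]
        assert set(frame["type"]) == {"A", "U"}
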