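"""Network assembly, ceRNA detection, and summaries."""

import numpy as np
import pytest

from regnet.io import GeneSetCollection
from regnet.network import (
    CeRNATriple,
    RegulatoryNetwork,
    assemble,
    find_cernas,
    summarize,
)
from regnet.targets import SupportedEdge


def mm_edge(m, g, cond="DN", support=None, sign="negative", stability=0.97):
    return SupportedEdge(m, "miRNA", g, "mRNA", cond,
                         support or {"catalog", "pcc"},
                         stability=stability, sign=sign)


def lm_edge(l, m, cond="DN"):
    return SupportedEdge(l, "lncRNA", m, "miRNA", cond, {"catalog"})


class TestAssemble:
    def test_empty_inputs(self):
        net = assemble([[]])
        assert net.nodes == {} and net.edges == []

    def test_one_edge_of_each_kind(self):
        net = assemble([
            [mm_edge("m1", "g1")],
            [lm_edge("l1", "m1")],
            [SupportedEdge("l1", "lncRNA", "g1", "mRNA", "DN", {"catalog"})],
        ], tf_targets={"g1": {"TF1"}}, allowed_tf_targets={"g1"})
        kinds = sorted(e.edge_kind for e in net.edges)
        assert kinds == ["TF->mRNA", "lncRNA->mRNA", "lncRNA->miRNA", "miRNA->mRNA"]
        assert net.nodes == {"m1": "miRNA", "g1": "mRNA", "l1": "lncRNA",
                             "TF1": "TF"}

    def test_duplicate_edges_merge_evidence(self):
        e1 = mm_edge("m", "g", "EDN", {"catalog", "pcc"}, stability=0.96)
        e2 = mm_edge("m", "g", "DN", {"catalog", "pcc"}, stability=0.99)
        net = assemble([[e1], [e2]])
        (e,) = net.edges
        assert e.condition_tag == "both"
        assert e.stability == 0.99

    def test_single_support_mirna_edges_excluded(self):
        """Only dual-support (catalog AND negative pcc) miRNA->mRNA edges
        enter the assembled network."""
        net = assemble([[
            mm_edge("m1", "g1", support={"catalog"}),
            mm_edge("m2", "g2", support={"pcc"}),
            mm_edge("m3", "g3", support={"catalog", "pcc"}),
        ]])
        assert [e.source_id for e in net.edges] == ["m3"]

    def test_function_tags_attached(self):
        sets = GeneSetCollection({"apoptosis": ("d", frozenset({"g1"}))})
        net = assemble([[mm_edge("m", "g1")]], function_sets=sets)
        assert net.function_tags["g1"] == {"apoptosis"}

    def test_tf_targets_limited_to_allowed(self):
        net = assemble([], tf_targets={"g1": {"TF1"}, "g2": {"TF1"}},
                       allowed_tf_targets={"g1"})
        assert [(e.source_id, e.target_id) for e in net.edges] == [("TF1", "g1")]


class TestFindCernas:
    def test_shared_pool_with_common_lncrnas(self):
        """A gene repressed by two miRNAs that are both sponged by three
        lncRNAs yields one triple carrying the intersection."""
        mm = [mm_edge("miR-30a", "JUN"), mm_edge("miR-29c", "JUN")]
        lm = [lm_edge(l, m) for l in ("MALAT1", "NEAT1", "TUG1")
              for m in ("miR-30a", "miR-29c")] + [lm_edge("MIAT", "miR-29c")]
        (t,) = find_cernas(mm, lm)
        assert t.mrna_id == "JUN"
        assert t.shared_mirnas == {"miR-30a", "miR-29c"}
        assert t.lncrnas == {"MALAT1", "NEAT1", "TUG1"}  # MIAT misses miR-30a

    def test_union_mode_includes_partial_sponges(self):
        mm = [mm_edge("m1", "g"), mm_edge("m2", "g")]
        lm = [lm_edge("l1", "m1"), lm_edge("l2", "m2")]
        assert find_cernas(mm, lm) == []  # intersection empty
        (t,) = find_cernas(mm, lm, mode="union")
        assert t.lncrnas == {"l1", "l2"}

    def test_single_regulator_below_min_shared(self):
        mm = [mm_edge("m1", "g")]
        lm = [lm_edge("l1", "m1")]
        assert find_cernas(mm, lm) == []

    def test_requires_dual_support_and_negative_sign(self):
        mm = [mm_edge("m1", "g", support={"pcc"}),
              mm_edge("m2", "g", sign="positive"),
              mm_edge("m3", "g"), mm_edge("m4", "g")]
        lm = [lm_edge("l", m) for m in ("m1", "m2", "m3", "m4")]
        (t,) = find_cernas(mm, lm)
        assert t.shared_mirnas == {"m3", "m4"}

    def test_input_order_invariance(self):
        rng = np.random.default_rng(0)
        mm = [mm_edge(f"m{rng.integers(5)}", f"g{rng.integers(6)}")
              for _ in range(15)]
        # dedup keys to keep edges unique
        mm = list({e.key: e for e in mm}.values())
        lm = [lm_edge(f"l{rng.integers(4)}", f"m{i}") for i in range(5)]
        fwd = find_cernas(mm, lm)
        rev = find_cernas(mm[::-1], lm[::-1])
        assert fwd == rev

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_g, n_m, n_l = rng.integers(2, 20), rng.integers(2, 8), rng.integers(1, 5)
        mm, lm = [], []
        reg, sponge = {}, {}
        for g in range(n_g):
            for m in range(n_m):
                if rng.random() < 0.25:
                    mm.append(mm_edge(f"m{m}", f"g{g}"))
                    reg.setdefault(f"g{g}", set()).add(f"m{m}")
        for l in range(n_l):
            for m in range(n_m):
                if rng.random() < 0.4:
                    lm.append(lm_edge(f"l{l}", f"m{m}"))
                    sponge.setdefault(f"m{m}", set()).add(f"l{l}")
        got = {(t.mrna_id, t.shared_mirnas, t.lncrnas)
               for t in find_cernas(mm, lm)}
        brute = set()
        for g, mirnas in reg.items():
            if len(mirnas) < 2:
                continue
            lncs = set.intersection(*(sponge.get(m, set()) for m in mirnas))
            if lncs:
                brute.add((g, frozenset(mirnas), frozenset(lncs)))
        assert got == brute

    def test_triple_validation(self):
        with pytest.raises(ValueError, match=">= 2 shared"):
            CeRNATriple("g", frozenset({"m1"}), frozenset({"l"}))


class TestSummarize:
    def test_counts_conserve_edges(self):
        net = assemble([
            [mm_edge("m1", "g1"), mm_edge("m2", "g2", "EDN")],
            [lm_edge("l1", "m1")],
        ])
        summary = summarize(net)
        assert summary["edge_counts"]["n_edges"].sum() == len(net.edges) == 3
        deg = summary["degrees"].set_index("node")
        assert deg.loc["m1", "out_degree"] == 1
        assert deg.loc["m1", "in_degree"] == 1

    def test_empty_network_all_zero(self):
        summary = summarize(RegulatoryNetwork())
        assert summary["edge_counts"].empty
        assert summary["degrees"].empty
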