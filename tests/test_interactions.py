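import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.spatial.distance import cdist

from glomscape.exceptions import ParameterError
from glomscape.interactions import (
    CommunicationNetwork,
    InteractionConfig,
    apply_slide_offsets,
    communication_probability,
    differential_network,
    incoming_signals,
    pair_proximity,
    permutation_significance,
    truncated_mean,
)
from glomscape.io import SpatialCellTable


def _typed_table(xy, types, counts, genes, slides=None):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    slide_arr = (np.asarray(slides, dtype=object) if slides is not None
                 else np.full(n, "slide1", dtype=object))
    cells = pd.DataFrame({
        "x_um": xy[:, 0], "y_um": xy[:, 1],
        "slide_id": slide_arr,
        "sample_id": np.char.add("s_", slide_arr.astype(str)),
        "condition": "control",
        "cell_type": np.asarray(types, dtype=object),
    }, index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))
    return SpatialCellTable(cells, sp.csr_matrix(counts), genes)


def _planted_tables(n=40, signal=True, seed=0):
    """S cells express ligand L, T cells receptor R, mixed in one field."""
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, 200, size=(2 * n, 2))
    types = np.array(["S"] * n + ["T"] * n, dtype=object)
    counts = rng.poisson(0.05, size=(2 * n, 4))
    if signal:
        counts[:n, 0] += rng.poisson(8, size=n)       # ligand in S
        counts[n:, 1] += rng.poisson(8, size=n)       # receptor in T
    counts[:, 3] += 1  # housekeeping so no cell is empty
    return _typed_table(xy, types, counts, ["L", "R", "X", "H"])


LR = pd.DataFrame({
    "interaction_id": ["L_R"], "ligand_genes": [["L"]],
    "receptor_genes": [["R"]], "pathway": ["P"], "category": ["secreted"],
})


class TestSlideOffsets:
    def test_two_slides_separated_by_ten_ranges(self):
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 500, size=(40, 2))
        slides = np.array(["slide1"] * 20 + ["slide2"] * 20)
        table = _typed_table(xy, ["A"] * 40, np.ones((40, 2), dtype=int),
                             ["G0", "G1"], slides)
        shifted = apply_slide_offsets(table, interaction_range_um=250)
        a = shifted.xy[:20]
        b = shifted.xy[20:]
        assert cdist(a, b).min() >= 10 * 250

    def test_within_slide_distances_preserved(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 500, size=(30, 2))
        slides = np.array(["slide1"] * 15 + ["slide2"] * 15)
        table = _typed_table(xy, ["A"] * 30, np.ones((30, 2), dtype=int),
                             ["G0", "G1"], slides)
        shifted = apply_slide_offsets(table)
        for rows in (slice(0, 15), slice(15, 30)):
            np.testing.assert_allclose(cdist(shifted.xy[rows], shifted.xy[rows]),
                                       cdist(xy[rows], xy[rows]), atol=1e-9)

    def test_single_slide_unchanged(self):
        xy = np.random.default_rng(2).uniform(0, 100, size=(10, 2))
        table = _typed_table(xy, ["A"] * 10, np.ones((10, 2), dtype=int),
                             ["G0", "G1"])
        shifted = apply_slide_offsets(table)
        np.testing.assert_array_equal(shifted.xy, xy)


class TestTruncatedMean:
    def test_hand_rule_drops_one_from_each_tail(self):
        vals = [0, 1, 2, 3, 4, 5, 6, 7, 8, 100]
        assert truncated_mean(vals, trim=0.1) == 4.5

    def test_zero_trim_is_plain_mean(self):
        vals = np.array([1.0, 2.0, 4.0])
        assert truncated_mean(vals, trim=0.0) == pytest.approx(vals.mean())

    def test_constant_vector_for_any_trim(self):
        for trim in (0.0, 0.1, 0.3, 0.49):
            assert truncated_mean([7.0] * 9, trim) == 7.0

    def test_empty_and_bad_trim_rejected(self):
        with pytest.raises(ParameterError):
            truncated_mean([])
        with pytest.raises(ParameterError):
            truncated_mean([1.0], trim=0.5)


class TestCommunicationProbability:
    def test_zero_ligand_means_zero_probability(self):
        table = _planted_tables(signal=False)
        cfg = InteractionConfig()
        net = communication_probability(table, LR, cfg)
        st = net.edges[(net.edges["source"] == "S") & (net.edges["target"] == "T")]
        assert st.empty or (st["prob"] == 0).all()

    def test_cross_slide_pairs_never_interact(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 100, size=(40, 2))
        slides = np.array(["slide1"] * 20 + ["slide2"] * 20)
        counts = np.zeros((40, 4), dtype=int)
        counts[:20, 0] = 5   # ligand only on slide1 (all S)
        counts[20:, 1] = 5   # receptor only on slide2 (all T)
        counts[:, 3] = 1
        types = np.array(["S"] * 20 + ["T"] * 20, dtype=object)
        table = _typed_table(xy, types, counts, ["L", "R", "X", "H"], slides)
        table = apply_slide_offsets(table)
        net = communication_probability(table, LR, InteractionConfig())
        st = net.edges[(net.edges["source"] == "S") & (net.edges["target"] == "T")]
        assert (st["prob"] == 0).all()

    def test_proximity_matches_pair_count_oracle(self):
        rng = np.random.default_rng(4)
        xy = rng.uniform(0, 400, size=(40, 2))
        types = np.array(["S"] * 20 + ["T"] * 20, dtype=object)
        for radius in (50.0, 150.0, 400.0):
            pi = pair_proximity(xy, types, "S", "T", radius)
            d = cdist(xy[:20], xy[20:])
            assert pi == pytest.approx((d <= radius).mean())

    def test_same_type_proximity_excludes_self_pairs(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [100.0, 0.0]])
        types = np.array(["S", "S", "S"], dtype=object)
        pi = pair_proximity(xy, types, "S", "S", 10.0)
        assert pi == pytest.approx(2 / 6)  # ordered pairs (0,1) and (1,0)

    def test_probability_monotone_in_proximity(self):
        # identical expression, shrinking layout -> pi grows -> prob grows
        rng = np.random.default_rng(5)
        base = rng.uniform(0, 1000, size=(60, 2))
        types = np.array(["S", "T"] * 30, dtype=object)
        counts = np.zeros((60, 4), dtype=int)
        counts[types == "S", 0] = 5
        counts[types == "T", 1] = 5
        counts[:, 3] = 1
        probs = []
        for scale in (1.0, 0.5, 0.1):
            table = _typed_table(base * scale, types, counts, ["L", "R", "X", "H"])
            net = communication_probability(table, LR, InteractionConfig())
            e = net.edges
            probs.append(float(e[(e["source"] == "S") & (e["target"] == "T")]["prob"]))
        assert probs[0] <= probs[1] <= probs[2]

    def test_small_types_are_skipped(self):
        table = _planted_tables(n=5)
        net = communication_probability(table, LR, InteractionConfig())
        assert net.edges.empty

    def test_absent_gene_skips_interaction_with_warning(self):
        table = _planted_tables()
        lr = LR.copy()
        lr.loc[0, "ligand_genes"] = [["MISSING"]][0]
        with pytest.warns(UserWarning, match="skipped"):
            net = communication_probability(table, lr, InteractionConfig())
        assert net.edges.empty


class TestPermutationSignificance:
    def test_planted_signal_reaches_minimum_p(self):
        table = _planted_tables(n=40)
        cfg = InteractionConfig(n_permutations=40, seed=0)
        net = communication_probability(table, LR, cfg)
        net = permutation_significance(table, LR, net, cfg)
        e = net.edges.set_index(["source", "target"])
        assert e.loc[("S", "T"), "pvalue"] == pytest.approx(1 / 41)

    def test_pvalues_in_unit_interval(self):
        table = _planted_tables(n=20, signal=False, seed=2)
        cfg = InteractionConfig(n_permutations=20, seed=0)
        net = communication_probability(table, LR, cfg)
        net = permutation_significance(table, LR, net, cfg)
        assert ((net.edges["pvalue"] > 0) & (net.edges["pvalue"] <= 1)).all()

    def test_too_few_permutations_rejected(self):
        table = _planted_tables()
        cfg = InteractionConfig(n_permutations=40, seed=0)
        net = communication_probability(table, LR, cfg)
        bad = InteractionConfig(n_permutations=5)
        with pytest.raises(ParameterError):
            permutation_significance(table, LR, net, bad)


class TestNetworkComparisons:
    def _net(self, rows, types):
        return CommunicationNetwork(
            edges=pd.DataFrame(rows, columns=["source", "target",
                                              "interaction_id", "pathway",
                                              "category", "prob", "pvalue"]),
            cell_types=types)

    def test_identical_networks_difference_is_zero(self):
        rows = [("A", "B", "i1", "P", "secreted", 0.4, 0.01)]
        d = differential_network(self._net(rows, ["A", "B"]),
                                 self._net(rows, ["A", "B"]))
        assert (d.to_numpy() == 0).all()

    def test_difference_antisymmetry(self):
        r1 = [("A", "B", "i1", "P", "secreted", 0.5, 0.01)]
        r2 = [("B", "A", "i1", "P", "secreted", 0.2, 0.01)]
        n1, n2 = self._net(r1, ["A", "B"]), self._net(r2, ["A", "B"])
        d12 = differential_network(n1, n2)
        d21 = differential_network(n2, n1)
        np.testing.assert_allclose(d12.to_numpy(), -d21.to_numpy())

    def test_missing_types_padded_with_zero(self):
        r1 = [("A", "B", "i1", "P", "secreted", 0.5, 0.01)]
        r2 = [("C", "B", "i1", "P", "secreted", 0.3, 0.01)]
        d = differential_network(self._net(r1, ["A", "B"]),
                                 self._net(r2, ["B", "C"]))
        assert list(d.index) == ["A", "B", "C"]
        assert d.loc["A", "B"] == 0.5 and d.loc["C", "B"] == -0.3

    def test_incoming_signals_sorted_and_significant_only(self):
        rows = [("A", "PEC", "i1", "PDGF", "secreted", 0.2, 0.01),
                ("B", "PEC", "i2", "TGFb", "secreted", 0.6, 0.01),
                ("C", "PEC", "i3", "VEGF", "secreted", 0.9, 0.5),
                ("A", "B", "i1", "PDGF", "secreted", 0.8, 0.01)]
        out = incoming_signals({"disease": self._net(rows, ["A", "B", "C", "PEC"])},
                               "PEC")
        assert list(out["source"]) == ["B", "A"]  # i3 insignificant, A->B wrong target
        assert out["prob"].is_monotonic_decreasing

    def test_planted_disease_ligand_tops_incoming_to_pec(self):
        # EC/MC produce the ligand, PECs the receptor, only in "disease"
        rng = np.random.default_rng(7)
        n = 30
        xy = rng.uniform(0, 200, size=(3 * n, 2))
        types = np.array(["EC"] * n + ["MC"] * n + ["PEC"] * n, dtype=object)
        genes = ["PDGFB", "PDGFRB", "OTHER", "H"]
        lr = pd.DataFrame({
            "interaction_id": ["PDGFB_PDGFRB", "OTHER_PDGFRB"],
            "ligand_genes": [["PDGFB"], ["OTHER"]],
            "receptor_genes": [["PDGFRB"], ["PDGFRB"]],
            "pathway": ["PDGF", "X"], "category": ["secreted", "secreted"],
        })
        def build(with_signal):
            counts = rng.poisson(0.02, size=(3 * n, 4))
            counts[:, 3] += 1
            if with_signal:
                counts[:2 * n, 0] += rng.poisson(6, size=2 * n)
                counts[2 * n:, 1] += rng.poisson(6, size=n)
            return _typed_table(xy, types, counts, genes)
        cfg = InteractionConfig(n_permutations=30, seed=0)
        nets = {}
        for cond, sig in (("control", False), ("disease", True)):
            t = build(sig)
            net = communication_probability(t, lr, cfg, condition=cond)
            nets[cond] = permutation_significance(t, lr, net, cfg)
        inc = incoming_signals(nets, "PEC")
        top = inc.iloc[:2]
        assert set(top["source"]) <= {"EC", "MC"}
        assert (top["pathway"] == "PDGF").all()
        diff = differential_network(nets["disease"], nets["control"])
        assert diff.loc["EC", "PEC"] > 0 and diff.loc["MC", "PEC"] > 0
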