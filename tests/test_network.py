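"""PPI merging, the ID statistic, cutoff sweeps, projection and banding."""

import numpy as np
import pandas as pd
import pytest

from dupdiverge import network
from dupdiverge.network import compute_id, merge_networks


def _edges(*pairs):
    return pd.DataFrame(pairs, columns=["protein_a", "protein_b"])


def _star(center, partners):
    return _edges(*[(center, p) for p in partners])


class TestMergeNetworks:
    def test_dedup_and_self_loop_removal(self):
        g = merge_networks([_edges(("a", "b")), _edges(("b", "a"), ("a", "a"))])
        assert g.number_of_edges() == 1
        assert g.number_of_nodes() == 2
        assert g.graph["n_self_dropped"] == 1
        assert g.graph["n_duplicates_collapsed"] == 1

    def test_empty_input(self):
        g = merge_networks([_edges()])
        assert g.number_of_nodes() == 0

    def test_disjoint_union_adds_edge_counts(self):
        lists = [
            _edges(("a1", "a2"), ("a1", "a3")),
            _edges(("b1", "b2")),
            _edges(("c1", "c2"), ("c2", "c3")),
        ]
        g = merge_networks(lists)
        assert g.number_of_edges() == sum(len(df) for df in lists)

    def test_malformed_row_reported_with_line(self):
        df = pd.DataFrame({"protein_a": ["a", None], "protein_b": ["b", "c"]})
        with pytest.raises(ValueError, match="line 3"):
            merge_networks([df])

    def test_case_normalization_collision_warns(self):
        with pytest.warns(UserWarning, match="collide"):
            g = merge_networks([_edges(("abc", "x"), ("ABC", "y"))])
        assert g.number_of_nodes() == 3  # abc/ABC merged


class TestComputeId:
    def test_stated_example(self):
        g = merge_networks([_star("a", "wxyz"), _star("b", "yz")])
        rec = compute_id("a", "b", g)
        assert (rec.i1, rec.i2, rec.i12) == (4, 2, 2)
        assert rec.id_value == pytest.approx(1 - 2 * 2 / 6)
        assert rec.eligible

    def test_identical_partner_sets_zero(self):
        g = merge_networks([_star("a", "wxyz"), _star("b", "wxyz")])
        assert compute_id("a", "b", g).id_value == 0.0

    def test_disjoint_partner_sets_one(self):
        g = merge_networks([_star("a", "wxyz"), _star("b", "mnop")])
        assert compute_id("a", "b", g).id_value == 1.0

    def test_missing_gene_ineligible(self):
        g = merge_networks([_star("a", "wxyz")])
        rec = compute_id("a", "zz", g)
        assert not rec.eligible and np.isnan(rec.id_value)

    def test_heterodimer_partner_excluded_by_default(self):
        # a and b interact with each other only: without the exclusion they
        # would each have one partner and an automatic ID of 1.
        g = merge_networks([_edges(("a", "b"))])
        rec = compute_id("a", "b", g)
        assert (rec.i1, rec.i2) == (0, 0) and np.isnan(rec.id_value)
        rec2 = compute_id("a", "b", g, exclude_partner_gene=False)
        assert (rec2.i1, rec2.i2, rec2.i12) == (1, 1, 0)

    def test_eligibility_thresholds(self):
        g = merge_networks([_star("a", "wxy"), _star("b", "xy")])
        assert not compute_id("a", "b", g).eligible          # max deg 3 < 4
        assert compute_id("a", "b", g, min_deg_high=3).eligible

    def test_id_equals_one_minus_dice_random_sets(self):
        rng = np.random.default_rng(17)
        universe = [f"p{i}" for i in range(30)]
        for _ in range(200):
            pa = set(rng.choice(universe, rng.integers(1, 12), replace=False))
            pb = set(rng.choice(universe, rng.integers(1, 12), replace=False))
            g = merge_networks([_star("a", pa), _star("b", pb)])
            rec = compute_id("a", "b", g)
            dice = 2 * len(pa & pb) / (len(pa) + len(pb))
            assert rec.id_value == pytest.approx(1 - dice, abs=1e-12)
            swapped = compute_id("b", "a", g)
            assert swapped.id_value == rec.id_value
            assert 0.0 <= rec.id_value <= 1.0


class TestSweep:
    @pytest.fixture
    def setup(self):
        rng = np.random.default_rng(5)
        frames, pairs = [], []
        for i in range(40):
            da, db = rng.integers(0, 10), rng.integers(0, 10)
            frames.append(_star(f"a{i}", [f"q{i}_{j}" for j in range(da)]))
            frames.append(_star(f"b{i}", [f"r{i}_{j}" for j in range(db)]))
            pairs.append(dict(gene_a=f"a{i}", gene_b=f"b{i}"))
        g = merge_networks([f for f in frames if len(f)])
        return pd.DataFrame(pairs), g

    def test_monotone_and_matches_brute_force(self, setup):
        pairs, g = setup
        sweep = network.sweep_id_cutoffs(pairs, g, cutoffs=range(1, 15))
        counts = sweep["n_eligible"].to_list()
        assert counts == sorted(counts, reverse=True)
        # brute-force recount straight from partner sets
        for k, expected in zip(sweep["cutoff"], counts):
            n = 0
            for _, row in pairs.iterrows():
                da = g.degree(row["gene_a"].upper()) if row["gene_a"].upper() in g else 0
                db = g.degree(row["gene_b"].upper()) if row["gene_b"].upper() in g else 0
                n += max(da, db) >= k and min(da, db) >= 1
            assert n == expected

    def test_cutoff_above_max_degree_empty(self, setup):
        pairs, g = setup
        sweep = network.sweep_id_cutoffs(pairs, g, cutoffs=[99])
        assert sweep["n_eligible"].iloc[0] == 0


class TestProjection:
    @pytest.fixture
    def families(self):
        return pd.DataFrame(
            [
                ("f1", "ref", "A1"), ("f1", "tgt", "T1"), ("f1", "tgt", "T2"),
                ("f2", "ref", "A2"), ("f2", "tgt", "T3"),
            ],
            columns=["family_id", "species", "gene_id"],
        )

    def test_family_with_interacting_reference_gene_projects(self, families):
        g = merge_networks([_star("A1", ["x", "y", "z"])])
        status = network.project_ppi_status(families, g, "ref")
        s = status.set_index("gene_id")["with_ppi"]
        assert s["T1"] and s["T2"] and s["A1"]
        assert not s["T3"] and not s["A2"]

    def test_empty_network_projects_nothing(self, families):
        import networkx as nx

        status = network.project_ppi_status(families, nx.Graph(), "ref")
        assert not status["with_ppi"].any()

    def test_pair_status_or_rule_and_missing_gene_warns(self, families):
        g = merge_networks([_star("A1", ["x"])])
        status = network.project_ppi_status(families, g, "ref")
        pairs = pd.DataFrame(
            {"gene_a": ["T1", "T3", "ZZ"], "gene_b": ["T3", "T3b", "ZZ2"]}
        )
        with pytest.warns(UserWarning, match="not covered"):
            flags = network.pair_ppi_status(pairs, status)
        assert list(flags) == [True, False, False]


class TestBanding:
    def _records(self, rows):
        df = pd.DataFrame(rows, columns=["mode", "i1", "i2", "i12"])
        df["eligible"] = True
        df["gene_a"] = "a"
        df["gene_b"] = "b"
        return df

    def test_all_zero_shared_gives_band_fraction_one(self):
        rec = self._records([("tandem", 4, 2, 0)] * 5 + [("block", 5, 5, 0)] * 5)
        res = network.shared_partner_banding(rec)
        assert (res.fractions["frac_zero_shared"] == 1.0).all()

    def test_retention_exactly_half_not_in_high_band(self):
        rec = self._records([("tandem", 4, 4, 2)])  # retention exactly 0.5
        res = network.shared_partner_banding(rec)
        assert res.fractions["frac_high_retention"].iloc[0] == 0.0

    def test_low_id_partition_has_more_high_retention(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(60):  # latent ID 0.2 -> retention 0.8
            n = int(rng.integers(4, 10))
            s = int(round(0.8 * n))
            rows.append(("block", n, n, s))
        for _ in range(60):  # latent ID 0.8 -> retention 0.2
            n = int(rng.integers(4, 10))
            s = int(round(0.2 * n))
            rows.append(("tandem", n, n, s))
        res = network.shared_partner_banding(self._records(rows))
        f = res.fractions.set_index("partition")["frac_high_retention"]
        assert f["block"] > f["tandem"]
        assert res.p_high_retention < 0.05
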