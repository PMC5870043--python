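"""Cis/trans partitioning, susceptibility and Venn overlaps."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import aneuexpr as ax
from aneuexpr.cistrans import (
    altered_chromosomes,
    chromosome_susceptibility,
    overlap_degs,
    partition_degs,
)
from aneuexpr.models import Karyotype
from aneuexpr.simulate import default_karyotypes


def _karyos():
    return {g: Karyotype(g, c) for g, c in default_karyotypes().items()}


class TestAlteredChromosomes:
    def test_addition_line(self):
        k = _karyos()
        assert altered_chromosomes(k["addition"], k["euploid"]) == {"C01"}

    def test_substitution_line(self):
        k = _karyos()
        assert altered_chromosomes(k["substitution"], k["euploid"]) == {"A01", "C01"}

    def test_identical_karyotypes(self):
        k = _karyos()
        assert altered_chromosomes(k["euploid"], k["euploid"]) == set()

    def test_mismatched_universe(self):
        a = Karyotype("a", {"A01": 2})
        b = Karyotype("b", {"A01": 2, "A02": 2})
        with pytest.raises(ValueError):
            altered_chromosomes(a, b)


def _deg_table(genes, ids, directions=None):
    directions = directions or ["up"] * len(ids)
    return pd.DataFrame(
        {
            "log2fc": [1.5 if d == "up" else -1.5 for d in directions],
            "p": 0.001,
            "q": 0.001,
            "direction": directions,
            "is_deg": True,
        },
        index=pd.Index(ids, name="gene_id"),
    )


class TestPartitionDegs:
    def test_all_cis_degenerate(self, tiny_genes):
        degs = _deg_table(tiny_genes, ["g1", "g2"])
        part = partition_degs(degs, tiny_genes, altered={"A01"})
        assert len(part.trans) == 0
        assert part.pct_trans == 0.0

    def test_published_pct_trans(self):
        """2706 trans of 3331 located DEGs -> 81.24% trans."""
        genes = pd.DataFrame(
            {
                "chromosome": ["C01"] * 625 + ["A02"] * 2706,
                "start": 1, "end": 1000, "exonic_length": 500,
                "subgenome": ["C"] * 625 + ["A"] * 2706,
            },
            index=pd.Index([f"g{i}" for i in range(3331)], name="gene_id"),
        )
        degs = _deg_table(genes, genes.index.tolist())
        part = partition_degs(degs, genes, altered={"C01"})
        assert len(part.cis) == 625
        assert part.pct_trans == 81.24

    def test_published_trans_bias(self, tiny_genes):
        """Trans up/down (2586, 2852) gives the published bias p."""
        n_up, n_down = 2586, 2852
        genes = pd.DataFrame(
            {"chromosome": "A02", "start": 1, "end": 10, "exonic_length": 5,
             "subgenome": "A"},
            index=pd.Index([f"g{i}" for i in range(n_up + n_down)], name="gene_id"),
        )
        degs = _deg_table(genes, genes.index.tolist(),
                          ["up"] * n_up + ["down"] * n_down)
        part = partition_degs(degs, genes, altered=set())
        assert float(f"{part.trans_bias.p:.2e}") == pytest.approx(3.10e-4, rel=0.02)

    def test_dosage_opposing_count(self, tiny_genes):
        degs = _deg_table(tiny_genes, ["g1", "g2", "g3"], ["up", "down", "up"])
        part = partition_degs(degs, tiny_genes, altered={"A01"}, reduced={"A01"})
        assert part.cis_up_count == 1  # g1 up on reduced A01

    def test_unlocated_genes_warned_and_counted(self, tiny_genes):
        degs = _deg_table(tiny_genes, ["g1", "ghost"])
        with pytest.warns(UserWarning):
            part = partition_degs(degs, tiny_genes, altered={"A01"})
        assert part.n_unlocated == 1
        assert len(part.cis) + len(part.trans) == 1

    def test_partition_invariant_to_order(self, tiny_genes):
        degs = _deg_table(tiny_genes, ["g1", "g2", "g3", "g4"])
        p1 = partition_degs(degs, tiny_genes, altered={"A01"})
        p2 = partition_degs(degs.iloc[::-1], tiny_genes, altered={"A01"})
        assert set(p1.cis.index) == set(p2.cis.index)
        assert set(p1.trans.index) == set(p2.trans.index)

    def test_simulated_trans_degs_all_partition_trans(self, small_experiment):
        """Planted trans DEGs sit on disomic chromosomes by
        construction, so the partition labels every one of them trans."""
        d = small_experiment
        truth = d["truth"]
        degs = ax.call_degs(d["expr"], d["samples"], "substitution", "euploid")
        altered = altered_chromosomes(
            truth.karyotypes["substitution"], truth.karyotypes["euploid"]
        )
        part = partition_degs(degs, d["genes"], altered)
        called_true_trans = degs.index[degs["is_deg"]].intersection(
            truth.is_trans.index[truth.is_trans["substitution"]]
        )
        assert len(called_true_trans) > 0
        assert called_true_trans.isin(part.trans.index).all()


class TestChromosomeSusceptibility:
    def _genes(self, per_chrom=100, chroms=("A01", "A02", "A03")):
        rows = []
        for c in chroms:
            for i in range(per_chrom):
                rows.append({"chromosome": c, "start": 1, "end": 10,
                             "exonic_length": 5, "subgenome": "A"})
        return pd.DataFrame(
            rows, index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id")
        )

    def test_proportional_distribution_not_significant(self):
        genes = self._genes()
        # 10 DEGs per 100 expressed on every chromosome
        ids = [g for i, g in enumerate(genes.index) if i % 10 == 0]
        degs = _deg_table(genes, ids)
        table = chromosome_susceptibility(degs, genes.index, genes, altered=set())
        assert (table["q"] >= 0.05).all()

    def test_enriched_chromosome_has_smallest_q(self):
        genes = self._genes()
        a01 = genes.index[genes.chromosome == "A01"]
        others = genes.index[genes.chromosome != "A01"]
        ids = list(a01[:30]) + [g for i, g in enumerate(others) if i % 10 == 0]
        degs = _deg_table(genes, ids)
        table = chromosome_susceptibility(degs, genes.index, genes, altered=set())
        table = table.set_index("chromosome")
        assert table["q"].idxmin() == "A01"
        # oracle: the 2x2 chi-square by the hand formula for A01
        tab = np.array([[30, 70], [20, 180]], dtype=float)
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.sum()
        stat = (((tab - expected) ** 2) / expected).sum()
        assert table.loc["A01", "chi2"] == pytest.approx(stat, rel=1e-9)

    def test_empty_deg_list(self):
        genes = self._genes()
        degs = _deg_table(genes, [])
        table = chromosome_susceptibility(degs, genes.index, genes, altered=set())
        assert (table["n_deg"] == 0).all()
        assert (table["p"] == 1.0).all()

    def test_altered_chromosomes_excluded(self):
        genes = self._genes()
        degs = _deg_table(genes, [genes.index[0]])
        table = chromosome_susceptibility(degs, genes.index, genes, altered={"A01"})
        assert "A01" not in set(table["chromosome"])


class TestOverlapDegs:
    def _t(self, ids, directions=None):
        directions = directions or ["up"] * len(ids)
        return pd.DataFrame(
            {"log2fc": 1.0, "p": 0.01, "q": 0.01,
             "direction": directions, "is_deg": True},
            index=pd.Index(ids, name="gene_id"),
        )

    def test_disjoint_lists(self):
        r = overlap_degs({"A": self._t(["g1", "g2"]), "B": self._t(["g3"])})
        assert r == {"A": 2, "B": 1, "A&B": 0}

    def test_identical_lists(self):
        r = overlap_degs({"A": self._t(["g1", "g2"]), "B": self._t(["g1", "g2"])})
        assert r == {"A": 0, "B": 0, "A&B": 2}

    def test_direction_aware_splits_discordant_genes(self):
        r = overlap_degs(
            {"A": self._t(["g1", "g2"], ["up", "up"]),
             "B": self._t(["g1", "g2"], ["up", "down"])},
            direction_aware=True,
        )
        assert r["A&B"] == 1  # only g1 shares direction
        assert r["A"] == 1 and r["B"] == 1

    def test_duplicate_within_list_rejected(self):
        dup = pd.DataFrame(
            {"log2fc": 1.0, "p": 0.01, "q": 0.01, "direction": "up", "is_deg": True},
            index=pd.Index(["g1", "g1"], name="gene_id"),
        )
        with pytest.raises(ValueError):
            overlap_degs({"A": dup, "B": self._t(["g2"])})

    def test_matches_brute_force_three_sets(self, rng):
        pool = [f"g{i}" for i in range(40)]
        sets = {
            name: sorted(rng.choice(pool, size=rng.integers(5, 25), replace=False))
            for name in ("A", "B", "C")
        }
        r = overlap_degs({k: self._t(v) for k, v in sets.items()})
        s = {k: set(v) for k, v in sets.items()}
        for combo in itertools.chain.from_iterable(
            itertools.combinations("ABC", k) for k in (1, 2, 3)
        ):
            inside = set.intersection(*(s[c] for c in combo))
            outside = set().union(*(s[c] for c in "ABC" if c not in combo))
            assert r["&".join(combo)] == len(inside - outside)

    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    def test_region_sum_equals_union(self, a, b, c):
        tables = {
            name: self._t([f"g{i}" for i in ids])
            for name, ids in (("A", a), ("B", b), ("C", c))
        }
        r = overlap_degs(tables)
        assert sum(r.values()) == len(a | b | c)

    def test_requires_two_or_three_lists(self):
        with pytest.raises(ValueError):
            overlap_degs({"A": self._t(["g1"])})
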