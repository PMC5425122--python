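"""Screen overlap, candidate cascade, MTI filtering and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agetrend import (
    GeneSetCollection,
    MTITable,
    PriorAgingSet,
    ValidationError,
    candidate_filter,
    enrich,
    filter_mti,
    hypergeom_overlap,
    load_alias_table,
    load_fixture,
    load_prior_aging_set,
    normalize_mirna_name,
    set_overlap,
)
from agetrend.integration import short_name

probeset_names = st.lists(
    st.sampled_from(
        [f"hsa-miR-{i}_st" for i in range(20)] + [f"U{i}_st" for i in range(20)]
    ),
    max_size=25,
)


class TestNameNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("hsa-miR-93-star_st", "hsa-miR-93*"),
            ("hsa-let-7g_st", "hsa-let-7g"),
            ("U38B_x_st", "U38B"),
            ("U91_s_st", "U91"),
            ("hsa-miR-1281_st", "hsa-miR-1281"),
            ("already-plain", "already-plain"),
        ],
    )
    def test_suffix_stripping(self, raw, expected):
        assert normalize_mirna_name(raw) == expected

    def test_alias_applied_after_stripping(self):
        aliases = load_alias_table()
        assert normalize_mirna_name("hsa-miR-93-star_st", aliases) == "hsa-miR-93-3p"
        assert normalize_mirna_name("hsa-miR-77-star_st", aliases) == "hsa-miR-77*"

    def test_short_name_drops_species_prefix(self):
        assert short_name("hsa-miR-15a_st") == "miR-15a"
        assert short_name("U43_x_st") == "U43"


class TestSetOverlap:
    def test_disjoint_lists(self):
        report = set_overlap(["hsa-miR-1_st", "U1_st"], ["hsa-miR-2_st", "U2_st"])
        for cls in ("miRNA", "snoRNA"):
            row = report.row(cls)
            assert row["intersection"] == 0
            assert row["union"] == row["n_a"] + row["n_b"]

    def test_fixture_screens_overlap(self):
        t1 = load_fixture("table1")
        t2 = load_fixture("table2")
        report = set_overlap(t1["probeset"], t2["probeset"])
        mi = report.row("miRNA")
        assert (mi["n_a"], mi["n_b"]) == (56, 40)
        assert (mi["intersection"], mi["union"]) == (25, 71)
        assert mi["pct_overlap_of_union"] == pytest.approx(100 * 25 / 71, abs=0.05)
        sno = report.row("snoRNA")
        assert (sno["intersection"], sno["union"]) == (6, 24)

    @given(probeset_names, probeset_names)
    def test_union_identity(self, a, b):
        report = set_overlap(a, b)
        for _, row in report.table.iterrows():
            assert row["union"] == row["n_a"] + row["n_b"] - row["intersection"]
            if row["union"]:
                assert 0 <= row["pct_overlap_of_union"] <= 100


class TestCandidateFilter:
    def test_fixture_cascade_reproduces_candidates(self):
        t1 = load_fixture("table1")
        stage1, stage2 = candidate_filter(t1, load_prior_aging_set(), fc_cut=2.0)
        assert len(stage1) == 15
        assert sorted(short_name(p) for p in stage2) == [
            "let-7g", "let-7i", "miR-1281", "miR-15a", "miR-30b",
        ]

    def test_borderline_fold_changes(self):
        """FC 1.998 stays outside a cut of 2; FC 0.498 passes the lower cut."""
        t1 = load_fixture("table1")
        stage1, _ = candidate_filter(t1, load_prior_aging_set(), fc_cut=2.0)
        assert "hsa-miR-423-5p_st" not in stage1  # FC 1.998
        assert "hsa-let-7i_st" in stage1  # FC 0.498
        fcs = t1.set_index("probeset").loc[stage1, "fc_last_first"]
        assert ((fcs >= 2.0) | (fcs <= 0.5)).all()

    def test_empty_prior_empties_stage_two(self):
        t1 = load_fixture("table1")
        empty = PriorAgingSet(
            pd.DataFrame(columns=["name", "direction", "tissue", "source"])
        )
        stage1, stage2 = candidate_filter(t1, empty)
        assert stage1 and not stage2

    def test_fc_cut_must_exceed_one(self):
        with pytest.raises(ValidationError):
            candidate_filter(load_fixture("table1"), load_prior_aging_set(), fc_cut=1.0)


class TestFilterMti:
    def _mti(self, records):
        return MTITable(pd.DataFrame(records, columns=["mirna", "target_gene", "evidence"]))

    def test_weak_evidence_dropped(self):
        mti = self._mti(
            [("hsa-miR-1", g, "strong") for g in ("A", "B", "C")]
            + [("hsa-miR-1", g, "weak") for g in ("D", "E")]
        )
        out = filter_mti(mti, {"hsa-miR-1": "decreasing"})
        assert out["decreasing"] == {"A", "B", "C"}

    def test_shared_targets_deduplicated(self):
        mti = self._mti(
            [("hsa-miR-1", "A", "strong"), ("hsa-miR-2", "A", "strong"),
             ("hsa-miR-2", "B", "strong")]
        )
        out = filter_mti(mti, {"hsa-miR-1": "increasing", "hsa-miR-2": "increasing"})
        assert out["increasing"] == {"A", "B"}

    def test_absent_mirna_yields_empty_set(self):
        mti = self._mti([("hsa-miR-1", "A", "strong")])
        out = filter_mti(mti, {"hsa-miR-404": "increasing"})
        assert out["increasing"] == frozenset()

    def test_counts_match_bruteforce_scan(self, rng):
        mirnas = [f"hsa-miR-{i}" for i in range(6)]
        genes = [f"G{i}" for i in range(30)]
        records = [
            (rng.choice(mirnas), rng.choice(genes), rng.choice(["strong", "weak"]))
            for _ in range(150)
        ]
        records = list(dict.fromkeys(records))
        mti = self._mti(records)
        query = {m: ("increasing" if i % 2 else "decreasing") for i, m in enumerate(mirnas[:4])}
        out = filter_mti(mti, query)
        for direction in ("increasing", "decreasing"):
            expected = {
                g for (m, g, e) in records
                if e == "strong" and query.get(m) == direction
            }
            assert out[direction] == expected

    def test_probeset_names_normalized_before_lookup(self):
        mti = self._mti([("hsa-let-7g", "A", "strong")])
        out = filter_mti(mti, {"hsa-let-7g_st": "decreasing"})
        assert out["decreasing"] == {"A"}


class TestHypergeomOverlap:
    def test_zero_overlap_certain(self):
        assert hypergeom_overlap(0, 5, 5, 100) == 1.0

    def test_complete_overlap_enumeration(self):
        assert hypergeom_overlap(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_tail_sum(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(8, 31))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        tail = sum(
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
            for i in range(k, min(K, n) + 1)
            if n - i <= N - K
        )
        assert hypergeom_overlap(k, K, n, N) == pytest.approx(tail, rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_overlap(6, 5, 5, 10)


class TestEnrich:
    def _gmt(self):
        genes = [f"G{i}" for i in range(40)]
        return GeneSetCollection(
            {
                "TARGET_SET": frozenset(genes[:8]),
                "HALF_SET": frozenset(genes[4:12]),
                "OTHER_A": frozenset(genes[12:22]),
                "OTHER_B": frozenset(genes[22:32]),
                "OTHER_C": frozenset(genes[30:40]),
            }
        )

    def test_query_equal_to_set_ranks_first(self):
        gmt = self._gmt()
        result = enrich(gmt.sets["TARGET_SET"], gmt)
        assert result["set_name"].iloc[0] == "TARGET_SET"
        assert result["k"].iloc[0] == 8

    def test_disjoint_query_empty_result(self):
        gmt = self._gmt()
        result = enrich({"G35", "G36"}, gmt, fdr=0.01)
        assert "OTHER_C" not in result.loc[result["k"] == 0, "set_name"].tolist()

    def test_pvalues_match_direct_hypergeometric(self):
        gmt = self._gmt()
        query = set(list(gmt.sets["TARGET_SET"])[:5]) | {"G20", "G21"}
        result = enrich(query, gmt, fdr=1.0).set_index("set_name")
        N = len(gmt.universe())
        for name, genes in gmt.sets.items():
            k = len(query & genes)
            if name in result.index:
                assert result.loc[name, "p_hyper"] == pytest.approx(
                    hypergeom_overlap(k, len(genes), len(query), N), rel=1e-12
                )

    def test_genes_outside_universe_dropped(self):
        gmt = self._gmt()
        with_extra = set(gmt.sets["TARGET_SET"]) | {"NOT_A_GENE"}
        result = enrich(with_extra, gmt)
        assert result["n"].iloc[0] == 8

    def test_empty_query_rejected(self):
        with pytest.raises(ValidationError):
            enrich([], self._gmt())

    def test_top_k_truncation(self):
        gmt = self._gmt()
        result = enrich(gmt.sets["TARGET_SET"] | gmt.sets["HALF_SET"], gmt,
                        fdr=1.0, top_k=2)
        assert len(result) <= 2
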