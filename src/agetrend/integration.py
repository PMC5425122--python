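"""Screen comparison, candidate selection and target-set enrichment.

Three concerns live here:

* set algebra between the correlation screen and the differential-
  expression screen, reported separately for miRNA and snoRNA probes;
* the two-stage candidate cascade — an effect-size cut on the screen's
  last/first fold change followed by membership in a prior set of
  literature-reported age-associated sncRNAs; and
* hypergeometric overlap enrichment of miRNA target genes against a GMT
  gene-set collection, with BH control across sets.

Probeset names are compared verbatim between screens; for matching
against literature names, array suffixes are stripped and a static
miRBase alias table applied (:func:`normalize_mirna_name`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .model import GeneSetCollection, MTITable, PriorAgingSet, ValidationError

logger = logging.getLogger(__name__)


def normalize_mirna_name(name: str, alias_table: dict[str, str] | None = None) -> str:
    """Canonicalize an array probeset name to a plain sncRNA name.

    Strips the Affymetrix suffixes (``_st``, ``_x_st``, ``_s_st``),
    rewrites the ``-star`` suffix to the ``*`` convention, and finally
    applies the (miRBase version) alias table if one is given.  Names
    without an alias pass through unchanged.
    """
    out = name
    if out.endswith("_st"):
        out = out[: -len("_st")]
        for tag in ("_x", "_s"):
            if out.endswith(tag):
                out = out[: -len(tag)]
    if out.endswith("-star"):
        out = out[: -len("-star")] + "*"
    out = out.replace("-star_", "*_")  # internal star markers, defensive
    if alias_table and out in alias_table:
        out = alias_table[out]
    return out


def short_name(name: str, alias_table: dict[str, str] | None = None) -> str:
    """Canonical name with the species prefix dropped (``hsa-miR-15a`` -> ``miR-15a``)."""
    out = normalize_mirna_name(name, alias_table)
    if out.startswith("hsa-"):
        out = out[len("hsa-") :]
    return out


def _default_classify(probeset: str) -> str:
    # fixture convention: miRNA probesets carry the "hsa-" species prefix
    return "miRNA" if probeset.startswith("hsa-") else "snoRNA"


@dataclass
class OverlapReport:
    """Per-class set algebra between two screens' probeset lists."""

    table: pd.DataFrame  # one row per class: n_a, n_b, intersection, union, pct

    def row(self, cls: str) -> pd.Series:
        return self.table.set_index("class").loc[cls]


def set_overlap(list_a, list_b, classify=None) -> OverlapReport:
    """Exact string-match overlap of two probeset lists, per sncRNA class.

    ``classify`` maps a probeset to ``"miRNA"`` or ``"snoRNA"``; the
    default uses the ``hsa-`` prefix convention.  The report gives, per
    class, |A|, |B|, |A∩B|, |A∪B| and 100·|A∩B|/|A∪B|.
    """
    if classify is None:
        classify = _default_classify
    a, b = set(list_a), set(list_b)
    rows = []
    for cls in ("miRNA", "snoRNA"):
        ac = {x for x in a if classify(x) == cls}
        bc = {x for x in b if classify(x) == cls}
        inter, union = ac & bc, ac | bc
        pct = 100.0 * len(inter) / len(union) if union else float("nan")
        rows.append(
            {
                "class": cls,
                "n_a": len(ac),
                "n_b": len(bc),
                "intersection": len(inter),
                "union": len(union),
                "pct_overlap_of_union": pct,
            }
        )
    return OverlapReport(pd.DataFrame(rows))


def candidate_filter(
    trend_table: pd.DataFrame,
    prior: PriorAgingSet,
    fc_cut: float = 2.0,
    alias_table: dict[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Two-stage candidate selection from the screen's trend table.

    Stage 1 keeps screened probes (trend not ``none``) whose last/first
    fold change satisfies ``FC >= fc_cut`` or ``FC <= 1/fc_cut`` — the
    unrounded values are compared, so a probe at FC 1.998 does not pass a
    cut of 2.  Stage 2 keeps those whose canonical short name appears in
    the prior age-association set.  Both lists are returned in the trend
    table's order.
    """
    if fc_cut <= 1:
        raise ValidationError("fc_cut must be > 1")
    screened = trend_table[trend_table["trend"] != "none"]
    fc = screened["fc_last_first"].astype(float)
    stage1 = screened.loc[
        (fc >= fc_cut) | (fc <= 1.0 / fc_cut), "probeset"
    ].tolist()
    prior_names = prior.names
    stage2 = [
        p for p in stage1 if short_name(p, alias_table) in prior_names
    ]
    return stage1, stage2


def filter_mti(
    mti: MTITable,
    mirnas: dict[str, str],
    evidence: str = "strong",
    alias_table: dict[str, str] | None = None,
) -> dict[str, frozenset[str]]:
    """Unique target genes of the given miRNAs at an evidence level.

    ``mirnas`` maps each miRNA name (probeset or canonical) to its trend
    direction; the result maps each direction to the deduplicated set of
    target genes.  miRNAs absent from the interaction table contribute an
    empty set and are logged.
    """
    table = mti.table
    table_names = table["mirna"].map(
        lambda n: normalize_mirna_name(n, alias_table)
    )
    by_direction: dict[str, set[str]] = {}
    for name, direction in mirnas.items():
        canon = normalize_mirna_name(name, alias_table)
        hits = table[
            (table_names == canon) & (table["evidence"] == evidence)
        ]
        if hits.empty:
            logger.info("miRNA %s: no %s-evidence interactions", canon, evidence)
        by_direction.setdefault(direction, set()).update(hits["target_gene"])
    return {d: frozenset(g) for d, g in by_direction.items()}


def hypergeom_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric overlap p-value, P(X >= k).

    ``N`` genes in the universe, ``K`` in the gene set, ``n`` in the
    query, ``k`` in the overlap.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query_genes,
    gmt: GeneSetCollection,
    universe_n: int | None = None,
    fdr: float = 0.05,
    top_k: int = 20,
) -> pd.DataFrame:
    """Hypergeometric overlap enrichment of a gene list against a GMT.

    One row per gene set with (K, k, n, N, p, BH q); rows significant at
    ``q < fdr`` are returned sorted by ascending p (ties by name) and
    truncated to ``top_k``.  Query genes outside the universe are dropped
    with a log line.  The default universe is the union of all GMT genes.
    """
    query = set(query_genes)
    if not query:
        raise ValidationError("empty query gene list")
    universe = gmt.universe()
    dropped = query - universe
    if dropped:
        logger.info(
            "%d query gene(s) outside the gene-set universe dropped", len(dropped)
        )
    query &= universe
    if not query:
        return _empty_enrichment()
    N = universe_n if universe_n is not None else len(universe)
    n = len(query)
    rows = []
    for name, genes in gmt.sets.items():
        members = genes & universe
        K = len(members)
        k = len(query & members)
        p = hypergeom_overlap(k, K, n, N)
        rows.append(
            {
                "set_name": name,
                "K": K,
                "k": k,
                "n": n,
                "N": N,
                "k_over_K": k / K if K else np.nan,
                "p_hyper": p,
            }
        )
    out = pd.DataFrame(rows)
    from .diffexp import bh_adjust

    out["q"] = bh_adjust(out["p_hyper"].to_numpy())
    out = out[out["q"] < fdr].sort_values(
        ["p_hyper", "set_name"], kind="stable"
    )
    return out.head(top_k).reset_index(drop=True)


def _empty_enrichment() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["set_name", "K", "k", "n", "N", "k_over_K", "p_hyper", "q"]
    )
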