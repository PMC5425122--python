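"""Packaged transcriptions of the study's printed result tables.

Four small TSVs ship with the package:

* ``table1`` — the 69 sncRNAs retained by the sliding-window correlation
  screen (probeset, type, Pearson R, last/first fold change, trend).
* ``table2`` — the 57 differentially expressed sncRNAs from the two-group
  (young vs elder, age cut-off 50) comparison.
* ``table3`` — sncRNAs previously reported as age-associated (one row per
  literature report; names recur across sources).
* ``table5`` — qPCR validation results for the five candidate miRNAs.

Probeset strings are kept verbatim (``hsa-miR-93-star_st``, ``U38B_x_st``)
because the screen-comparison stage matches the two screens' lists by
exact string identity.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .model import PriorAgingSet, ValidationError

FIXTURE_TABLES = ("table1", "table2", "table3", "table5")

_NUMERIC = {
    "table1": ["pearson_r", "fc_last_first"],
    "table2": ["adj_p", "fc_elder_young"],
    "table3": [],
    "table5": [
        "r_sw",
        "fc_last_first",
        "fc_elder_young",
        "adj_p",
        "rq_discovery",
        "p_discovery",
        "rq_validation",
        "p_validation",
    ],
}


def _data_path(filename: str):
    return resources.files("agetrend").joinpath("data", filename)


def load_fixture(table_id: str) -> pd.DataFrame:
    """Load one of the packaged printed-table transcriptions.

    Parameters
    ----------
    table_id
        One of ``"table1"``, ``"table2"``, ``"table3"``, ``"table5"``.
    """
    if table_id not in FIXTURE_TABLES:
        raise ValidationError(
            f"unknown fixture {table_id!r}; expected one of {FIXTURE_TABLES}"
        )
    with resources.as_file(_data_path(f"{table_id}.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"])
    for col in _NUMERIC[table_id]:
        df[col] = pd.to_numeric(df[col])
    return df


def load_prior_aging_set() -> PriorAgingSet:
    """The previously-reported age-associated sncRNA set (from ``table3``).

    The printed table lists one row per report, so the same sncRNA can
    appear several times; membership tests use the deduplicated name set.
    """
    t3 = load_fixture("table3")
    records = pd.DataFrame(
        {
            "name": t3["name"],
            "direction": t3["direction"],
            "tissue": t3["tissue"],
            "source": t3["reference"],
        }
    )
    return PriorAgingSet(records)


def load_alias_table() -> dict[str, str]:
    """Static miRBase v11 → v20 rename table (old name → current name)."""
    with resources.as_file(_data_path("mirbase_aliases.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["old_name"], df["new_name"]))
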