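"""Core in-memory containers for the age-trend analysis.

The central object is a probe-by-sample expression matrix of log2
microarray intensities, accompanied by per-sample ages and a per-probe
small-non-coding-RNA class annotation.  Containers are thin, validated
wrappers around :class:`pandas.DataFrame` so that every downstream stage
can rely on aligned, duplicate-free, finite data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SNCRNA_CLASSES = ("miRNA", "CDBox", "HAcaBox", "scaRna", "snoRNA", "other")
COHORTS = ("discovery", "validation", "synthetic")

#: Maximum plausible human age in years; ages outside [0, MAX_AGE] are rejected.
MAX_AGE = 130.0


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(values, kind: str) -> None:
    seen = pd.Index(values)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {kind} id(s): {dups}")


@dataclass
class ExpressionMatrix:
    """Probes-in-rows, samples-in-columns expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample id.
    scale
        ``"log2"`` (default, microarray convention) or ``"linear"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = self.values.columns[
                [not np.issubdtype(d, np.number) for d in self.values.dtypes]
            ].tolist()
            raise ValidationError(f"non-numeric cells in column(s): {bad}")
        if not np.all(np.isfinite(arr)):
            rows, cols = np.where(~np.isfinite(arr))
            probe = self.values.index[rows[0]]
            sample = self.values.columns[cols[0]]
            raise ValidationError(
                f"non-finite value at probe {probe!r}, sample {sample!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SampleMetadata:
    """Per-sample age (years) and cohort label.

    ``table`` is indexed by sample id with columns ``age`` and ``cohort``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"age", "cohort"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing column(s): {sorted(missing)}")
        _check_unique(self.table.index, "sample")
        ages = self.table["age"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ages)) or np.any(ages < 0) or np.any(ages > MAX_AGE):
            bad = self.table.index[
                ~np.isfinite(ages) | (ages < 0) | (ages > MAX_AGE)
            ].tolist()
            raise ValidationError(f"invalid age for sample(s): {bad}")
        bad_cohort = set(self.table["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ValidationError(f"unknown cohort label(s): {sorted(bad_cohort)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def ages(self) -> pd.Series:
        return self.table["age"].astype(float)

    def order_by_age(self) -> list[str]:
        """Sample ids sorted by age; ties keep input order (stable sort)."""
        return list(self.table["age"].sort_values(kind="stable").index)

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.table.index]
        if missing:
            raise ValidationError(f"sample(s) missing from metadata: {missing}")


@dataclass
class ProbeAnnotation:
    """Per-probe sncRNA class and species tag.

    ``table`` is indexed by probe id with columns ``sncRNA_class`` and
    ``species_tag``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sncRNA_class", "species_tag"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation missing column(s): {sorted(missing)}")
        _check_unique(self.table.index, "probe")
        bad = set(self.table["sncRNA_class"]) - set(SNCRNA_CLASSES)
        if bad:
            raise ValidationError(f"unknown sncRNA class(es): {sorted(bad)}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def require_probes(self, probe_ids) -> None:
        missing = [p for p in probe_ids if p not in self.table.index]
        if missing:
            raise ValidationError(f"probe(s) missing from annotation: {missing}")


@dataclass
class GeneSetCollection:
    """Named gene sets (MSigDB-style), with optional per-set descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def universe(self) -> frozenset[str]:
        """Union of all member genes — the default enrichment universe."""
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class MTITable:
    """miRNA-target interaction records: (mirna, target_gene, evidence)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"mirna", "target_gene", "evidence"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"MTI table missing column(s): {sorted(missing)}")
        bad = set(self.table["evidence"]) - {"strong", "weak"}
        if bad:
            raise ValidationError(f"unknown evidence class(es): {sorted(bad)}")
        if self.table.duplicated(["mirna", "target_gene", "evidence"]).any():
            raise ValidationError("duplicate MTI records")


@dataclass
class CqTable:
    """qPCR quantification-cycle records: (sample_id, assay, cq).

    Cq values are amplification cycle numbers; the usual instrument range
    is (0, 45) and anything outside is rejected as a transcription error.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"sample_id", "assay", "cq"} - set(self.table.columns)
        if missing:
            raise ValidationError(f"Cq table missing column(s): {sorted(missing)}")
        cq = self.table["cq"].to_numpy(dtype=float)
        if np.any(~np.isfinite(cq)) or np.any(cq <= 0) or np.any(cq >= 45):
            raise ValidationError("Cq values must lie in (0, 45)")
        if self.table.duplicated(["sample_id", "assay"]).any():
            dup = self.table[self.table.duplicated(["sample_id", "assay"])]
            raise ValidationError(
                f"duplicate (sample, assay) pair(s): "
                f"{dup[['sample_id', 'assay']].values.tolist()}"
            )

    def assays(self) -> list[str]:
        return sorted(self.table["assay"].unique())


@dataclass
class PriorAgingSet:
    """Small non-coding RNAs previously reported as age-associated.

    ``records`` keeps one row per literature report (a name may recur across
    sources/tissues); ``names`` is the deduplicated canonical-name set used
    for membership tests.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"name", "direction", "tissue", "source"} - set(
            self.records.columns
        )
        if missing:
            raise ValidationError(
                f"prior-aging table missing column(s): {sorted(missing)}"
            )

    @property
    def names(self) -> frozenset[str]:
        return frozenset(self.records["name"])

    def __contains__(self, name: str) -> bool:
        return name in self.names
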