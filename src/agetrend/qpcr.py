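"""Relative quantification of qPCR data by the 2^-ddCq (Livak) method.

Per sample, each target assay's quantification cycle is referenced to a
housekeeping assay (dCq = Cq_target - Cq_reference; lower dCq means more
template).  Groups are then compared on mean dCq: ddCq = mean dCq(elder)
- mean dCq(young), and the relative quantification RQ = 2^-ddCq is the
fold expression of the elder group relative to the young group.
Group differences are tested with the Wilcoxon rank-sum test — exact
for small untied samples, normal approximation with tie and continuity
corrections otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from .model import CqTable, SampleMetadata, ValidationError

AGE_BINS_DEFAULT = ((24, 40), (41, 60), (61, 70), (71, 80), (81, 90))


def delta_cq(cq: CqTable, reference_assay: str = "miR-191") -> pd.DataFrame:
    """Per-sample dCq for every non-reference assay.

    Returns a samples x targets DataFrame of ``Cq_target - Cq_reference``.
    Every sample must have a reference-assay measurement.
    """
    table = cq.table
    wide = table.pivot(index="sample_id", columns="assay", values="cq")
    if reference_assay not in wide.columns:
        raise ValidationError(f"reference assay {reference_assay!r} not in Cq table")
    ref = wide[reference_assay]
    missing = ref.index[ref.isna()].tolist()
    if missing:
        raise ValidationError(
            f"sample(s) missing reference-assay Cq: {missing}"
        )
    targets = [c for c in wide.columns if c != reference_assay]
    out = wide[targets].sub(ref, axis=0)
    out.columns.name = "assay"
    return out


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact permutation distribution when the combined sample has
    at most 20 untied observations, and the normal approximation with tie
    and continuity corrections otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if len(combined) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def relative_quantification(
    dcq: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Group-level 2^-ddCq relative quantification per target assay.

    ``dcq`` is the samples x targets dCq frame; ``groups`` labels each
    sample ``young`` or ``elder``.  Returns one row per target with the
    group mean dCq values, ddCq (elder - young), RQ and the rank-sum p.
    """
    groups = groups.loc[dcq.index]
    for grp in ("young", "elder"):
        if (groups == grp).sum() == 0:
            raise ValidationError(f"group {grp!r} is empty")
    rows = []
    for target in dcq.columns:
        vals = dcq[target].dropna()
        g = groups.loc[vals.index]
        young = vals[g == "young"].to_numpy()
        elder = vals[g == "elder"].to_numpy()
        if len(young) == 0 or len(elder) == 0:
            raise ValidationError(f"target {target!r}: a group has no dCq values")
        ddcq = elder.mean() - young.mean()
        rows.append(
            {
                "target": target,
                "n_young": len(young),
                "n_elder": len(elder),
                "dcq_young": young.mean(),
                "dcq_elder": elder.mean(),
                "ddcq": ddcq,
                "rq": 2.0 ** (-ddcq),
                "p_value": rank_sum_test(elder, young),
            }
        )
    return pd.DataFrame(rows)


def bin_by_age(metadata: SampleMetadata, bins=AGE_BINS_DEFAULT) -> pd.Series:
    """Assign each sample to the closed age interval containing its age.

    Bins must not overlap.  Samples whose age falls in no bin get a
    missing label (callers may flag or drop them).
    """
    bins = [tuple(b) for b in bins]
    for (lo1, hi1) in bins:
        if lo1 > hi1:
            raise ValidationError(f"bin ({lo1}, {hi1}) has lo > hi")
    for i, (lo1, hi1) in enumerate(bins):
        for lo2, hi2 in bins[i + 1 :]:
            if lo1 <= hi2 and lo2 <= hi1:
                raise ValidationError(
                    f"bins ({lo1}, {hi1}) and ({lo2}, {hi2}) overlap"
                )
    ages = metadata.ages()
    labels = pd.Series(pd.NA, index=ages.index, dtype=object, name="age_bin")
    for lo, hi in bins:
        inside = (ages >= lo) & (ages <= hi)
        labels[inside] = f"{lo}-{hi}"
    return labels


def bin_summaries(dcq: pd.DataFrame, bin_labels: pd.Series) -> pd.DataFrame:
    """Mean dCq per age bin and target (rows: bin, columns: target)."""
    labels = bin_labels.loc[dcq.index]
    grouped = dcq.groupby(labels, observed=True).mean()
    counts = labels.value_counts()
    grouped.insert(0, "n", counts.loc[grouped.index].to_numpy())
    return grouped


class RelativeQuantification(BaseEstimator):
    """2^-ddCq relative quantification as a fit-shaped estimator.

    Parameters
    ----------
    reference_assay : str
        Housekeeping assay name used for per-sample dCq referencing.
    cutoff : float
        Age cut for young (<= cutoff) vs elder (> cutoff) when ``fit``
        receives sample metadata rather than explicit group labels.
    bins : sequence of (lo, hi)
        Closed age intervals for the per-bin dCq summary (needs metadata).

    Attributes
    ----------
    dcq_ : samples x targets dCq frame
    groups_ : young/elder labels
    results_ : per-target RQ table (see :func:`relative_quantification`)
    bin_summary_ : per-age-bin mean dCq (when ages are available)
    """

    def __init__(
        self,
        reference_assay: str = "miR-191",
        cutoff: float = 50.0,
        bins=AGE_BINS_DEFAULT,
    ):
        self.reference_assay = reference_assay
        self.cutoff = cutoff
        self.bins = bins

    def fit(self, X: CqTable, y):
        """Quantify a Cq table against group labels or sample metadata.

        ``y`` may be a Series of ``young``/``elder`` labels or a
        :class:`SampleMetadata` (grouped at ``cutoff``; also enables the
        per-age-bin summary).
        """
        self.dcq_ = delta_cq(X, reference_assay=self.reference_assay)
        self.bin_summary_ = None
        if isinstance(y, SampleMetadata):
            from .diffexp import split_groups

            self.groups_ = split_groups(y, cutoff=self.cutoff).loc[self.dcq_.index]
            if self.bins is not None:
                self.bin_summary_ = bin_summaries(self.dcq_, bin_by_age(y, self.bins))
        else:
            self.groups_ = pd.Series(y).loc[self.dcq_.index]
        self.results_ = relative_quantification(self.dcq_, self.groups_)
        return self
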