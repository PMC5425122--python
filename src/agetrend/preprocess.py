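"""Quantile normalization and probe filtering ahead of the screens.

Quantile normalization forces every sample column to share one reference
distribution — the across-sample means of the sorted columns — so that
between-array intensity differences cannot masquerade as age trends.
Ties within a column receive the mean of the reference values at the
tied positions (average-of-tied-ranks convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import ExpressionMatrix, ProbeAnnotation, ValidationError


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ExpressionMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


class QuantileNormalizer(BaseEstimator, TransformerMixin):
    """Map every sample column onto a common reference distribution.

    The input is a probes-in-rows, samples-in-columns matrix (the
    orientation used throughout this package).  ``fit`` computes the
    reference distribution — the mean over samples of each sorted
    column — and ``transform`` replaces each column's order statistics
    with it, averaging reference values over ties.

    The operation is idempotent: transforming an already-normalized
    matrix returns it unchanged (to numerical precision).

    Attributes
    ----------
    reference_distribution_ : ndarray of shape (n_probes,)
        Sorted reference values (ascending rank means).
    """

    def fit(self, X, y=None):
        values = _as_frame(X)
        if values.shape[1] < 2:
            raise ValidationError("quantile normalization needs >= 2 samples")
        arr = values.to_numpy(dtype=float)
        self.reference_distribution_ = np.sort(arr, axis=0).mean(axis=1)
        self.n_probes_ = arr.shape[0]
        return self

    def transform(self, X):
        values = _as_frame(X)
        if values.shape[0] != self.n_probes_:
            raise ValidationError(
                f"matrix has {values.shape[0]} probes; normalizer was fit on "
                f"{self.n_probes_}"
            )
        ref = self.reference_distribution_
        out = np.empty_like(values.to_numpy(dtype=float))
        for j, col in enumerate(values.columns):
            x = values[col].to_numpy(dtype=float)
            order = np.argsort(x, kind="stable")
            assigned = np.empty_like(ref)
            assigned[order] = ref
            # ties: average the reference values the tied group spans
            assigned = (
                pd.Series(assigned).groupby(x, sort=False).transform("mean").to_numpy()
            )
            out[:, j] = assigned
        result = pd.DataFrame(out, index=values.index, columns=values.columns)
        if isinstance(X, ExpressionMatrix):
            return ExpressionMatrix(result, scale=X.scale)
        return result


def quantile_normalize(matrix):
    """Quantile-normalize a probes x samples matrix (fit and transform in one)."""
    return QuantileNormalizer().fit_transform(matrix)


def filter_probes(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    keep_species: str = "human",
    keep_probes=None,
) -> ExpressionMatrix:
    """Retain probes matching a species tag (and an optional keep-list).

    ``keep_probes`` accepts a pre-made detection keep-list (e.g. from a
    vendor background-detection step run elsewhere); probes absent from it
    are dropped after the species filter.  Probe order is preserved.
    """
    annotation.require_probes(matrix.probe_ids)
    tags = annotation.table.loc[matrix.probe_ids, "species_tag"]
    keep = tags == keep_species
    if keep_probes is not None:
        keep &= pd.Index(matrix.probe_ids).isin(list(keep_probes))
    kept = matrix.values.loc[keep.to_numpy()]
    if kept.shape[0] == 0:
        raise ValidationError(
            f"no probes left after filtering to species {keep_species!r}; "
            "the filter is too strict for this annotation"
        )
    return ExpressionMatrix(kept, scale=matrix.scale)
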