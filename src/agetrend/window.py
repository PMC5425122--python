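"""The sliding-window age-trend screen.

Samples are ordered by age; overlapping windows of ``w`` consecutive
samples are averaged per probe; each probe's window-mean series is
z-scored across windows; and the Pearson correlation between that
z-series and the windows' mean ages, together with the last/first-window
fold change, classifies the probe as increasing, decreasing or flat with
age.

The screen's retention rule: a probe is *increasing* when r >= 0.75 and
its last/first fold change (rounded to 2 decimals) is >= 1.5, and
*decreasing* when r <= -0.75 and the rounded fold change is <= 1/1.5.
Rounding before comparison is deliberate: printed fold changes such as
1.497 ("increasing") belong inside the threshold once rounded, so a
strict unrounded cut would misclassify borderline probes relative to the
reference results this screen reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator

from .model import ExpressionMatrix, SampleMetadata, ValidationError


@dataclass
class WindowSeries:
    """Ordered sliding windows over the age-sorted cohort."""

    windows: list[list[str]]
    mean_ages: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def build_windows(
    metadata: SampleMetadata,
    w: int = 10,
    step: int = 1,
    n_windows: int | None = None,
    drop_last: bool = False,
) -> WindowSeries:
    """Build age-ordered sliding windows of ``w`` samples each.

    Window k holds the samples ranked ``k*step`` .. ``k*step + w - 1`` by
    age (stable sort: equal ages keep input order), so with step 1 there
    are ``n - w + 1`` windows.  ``n_windows`` truncates the series and
    ``drop_last`` removes the final window; both exist because reported
    window counts in the field sometimes drop the last partial slide.
    """
    ordered = metadata.order_by_age()
    n = len(ordered)
    if n < w:
        raise ValidationError(f"need at least w={w} samples, got {n}")
    if w < 1 or step < 1:
        raise ValidationError("window size and step must be >= 1")
    total = (n - w) // step + 1
    windows = [ordered[k * step : k * step + w] for k in range(total)]
    if drop_last:
        windows = windows[:-1]
    if n_windows is not None:
        if not 1 <= n_windows <= len(windows):
            raise ValidationError(
                f"n_windows={n_windows} outside [1, {len(windows)}]"
            )
        windows = windows[:n_windows]
    if not windows:
        raise ValidationError("no windows left after truncation")
    ages = metadata.ages()
    mean_ages = np.array([ages.loc[win].mean() for win in windows])
    return WindowSeries(windows, mean_ages)


def window_means(
    matrix: ExpressionMatrix, series: WindowSeries
) -> pd.DataFrame:
    """Per-probe arithmetic mean within each window, on the stored scale.

    Returns a probes x windows DataFrame whose columns are window indices.
    """
    missing = {s for win in series.windows for s in win} - set(matrix.sample_ids)
    if missing:
        raise ValidationError(f"window member(s) missing from matrix: {sorted(missing)}")
    cols = {
        k: matrix.values[win].mean(axis=1) for k, win in enumerate(series.windows)
    }
    return pd.DataFrame(cols)


def zscore_rows(window_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Standardize each probe's window-mean series (population sd).

    Constant rows cannot be standardized; they become all-zero and are
    flagged in the returned boolean Series.
    """
    if window_means.shape[1] < 2:
        raise ValidationError("need >= 2 windows to z-score")
    arr = window_means.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (arr - mean) / safe_sd
    z[constant, :] = 0.0
    return (
        pd.DataFrame(z, index=window_means.index, columns=window_means.columns),
        pd.Series(constant, index=window_means.index, name="constant"),
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-d series")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("correlation undefined for constant input")
    return float(scipy.stats.pearsonr(x, y).statistic)


def fold_change_last_first(window_means: pd.DataFrame, scale: str = "log2") -> pd.Series:
    """Last-window over first-window expression ratio, on the linear scale.

    With log2 data the ratio is ``2**(m_last - m_first)``; with linear
    data it is ``m_last / m_first`` (requires a positive first-window mean).
    """
    if window_means.shape[1] < 2:
        raise ValidationError("need >= 2 windows for a last/first fold change")
    first = window_means.iloc[:, 0].astype(float)
    last = window_means.iloc[:, -1].astype(float)
    if scale == "log2":
        fc = np.power(2.0, last - first)
    elif scale == "linear":
        if (first <= 0).any():
            bad = first.index[first <= 0].tolist()
            raise ValidationError(
                f"nonpositive first-window mean for probe(s) {bad}; "
                "linear-scale fold change undefined"
            )
        fc = last / first
    else:
        raise ValidationError(f"unknown scale {scale!r}")
    return pd.Series(fc, index=window_means.index, name="fc_last_first")


def screen_trends(
    zscores: pd.DataFrame,
    mean_ages: np.ndarray,
    window_means: pd.DataFrame,
    r_threshold: float = 0.75,
    fc_threshold: float = 1.5,
    scale: str = "log2",
    rounding: int = 2,
) -> pd.DataFrame:
    """Classify every probe's age trend from its z-scored window means.

    Returns a DataFrame with columns ``probeset``, ``pearson_r``,
    ``fc_last_first`` and ``trend``.  Probes with a constant window-mean
    series have undefined correlation (``NaN``) and trend ``none``.
    """
    if not 0 < r_threshold <= 1:
        raise ValidationError("r_threshold must lie in (0, 1]")
    if fc_threshold <= 1:
        raise ValidationError("fc_threshold must be > 1")
    mean_ages = np.asarray(mean_ages, dtype=float)
    if zscores.shape[1] != len(mean_ages):
        raise ValidationError("zscores and mean_ages disagree on window count")

    z = zscores.to_numpy(dtype=float)
    constant = z.std(axis=1, ddof=0) == 0
    age_z = (mean_ages - mean_ages.mean()) / mean_ages.std(ddof=0)
    # rows of z are already standardized, so r is just the mean product
    with np.errstate(invalid="ignore"):
        r = (z * age_z[None, :]).mean(axis=1)
    r[constant] = np.nan

    fc = fold_change_last_first(window_means, scale=scale)
    fc_rounded = fc.round(rounding)
    lo_cut = round(1.0 / fc_threshold, rounding)

    trend = np.full(len(zscores), "none", dtype=object)
    inc = (~constant) & (r >= r_threshold) & (fc_rounded.to_numpy() >= fc_threshold)
    dec = (~constant) & (r <= -r_threshold) & (fc_rounded.to_numpy() <= lo_cut)
    trend[inc] = "increasing"
    trend[dec] = "decreasing"
    return pd.DataFrame(
        {
            "probeset": zscores.index,
            "pearson_r": r,
            "fc_last_first": fc.to_numpy(),
            "trend": trend,
        }
    )


class SlidingWindowScreen(BaseEstimator):
    """Sliding-window correlation screen as a fit-shaped estimator.

    ``fit`` takes the probes x samples matrix and the per-sample ages,
    builds the age-ordered windows, and leaves the full screen state in
    fitted attributes.

    Parameters
    ----------
    window_size, step
        Window width (samples) and slide increment.
    r_threshold, fc_threshold
        Retention cuts on the age correlation and the last/first fold
        change (the fold-change cut is applied to values rounded to
        ``rounding`` decimals; the decreasing cut is ``1/fc_threshold``).
    scale
        ``"log2"`` (fold change via ``2**delta``) or ``"linear"``.
    n_windows, drop_last
        Optional truncation of the window series.

    Attributes
    ----------
    windows_ : WindowSeries
    window_means_ : DataFrame, probes x windows
    zscores_ : DataFrame, probes x windows
    constant_probes_ : boolean Series (z-score undefined)
    trend_table_ : DataFrame (probeset, pearson_r, fc_last_first, trend)
    """

    def __init__(
        self,
        window_size: int = 10,
        step: int = 1,
        r_threshold: float = 0.75,
        fc_threshold: float = 1.5,
        scale: str = "log2",
        rounding: int = 2,
        n_windows: int | None = None,
        drop_last: bool = False,
    ):
        self.window_size = window_size
        self.step = step
        self.r_threshold = r_threshold
        self.fc_threshold = fc_threshold
        self.scale = scale
        self.rounding = rounding
        self.n_windows = n_windows
        self.drop_last = drop_last

    def fit(self, X, y):
        """Run the screen.

        Parameters
        ----------
        X
            ExpressionMatrix or probes x samples DataFrame.
        y
            SampleMetadata, or a sequence of ages aligned with X's columns.
        """
        if isinstance(X, ExpressionMatrix):
            matrix = X
        else:
            matrix = ExpressionMatrix(pd.DataFrame(X), scale=self.scale)
        if isinstance(y, SampleMetadata):
            metadata = y
        else:
            metadata = SampleMetadata(
                pd.DataFrame(
                    {"age": np.asarray(y, dtype=float), "cohort": "discovery"},
                    index=pd.Index(matrix.sample_ids),
                )
            )
        metadata.require_samples(matrix.sample_ids)

        self.windows_ = build_windows(
            metadata,
            w=self.window_size,
            step=self.step,
            n_windows=self.n_windows,
            drop_last=self.drop_last,
        )
        self.window_means_ = window_means(matrix, self.windows_)
        self.zscores_, self.constant_probes_ = zscore_rows(self.window_means_)
        self.trend_table_ = screen_trends(
            self.zscores_,
            self.windows_.mean_ages,
            self.window_means_,
            r_threshold=self.r_threshold,
            fc_threshold=self.fc_threshold,
            scale=matrix.scale,
            rounding=self.rounding,
        )
        return self

    def predict(self, X=None):
        """Per-probe trend labels from the fitted screen."""
        return self.trend_table_.set_index("probeset")["trend"]
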