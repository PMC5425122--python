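"""Two-group differential expression with an empirical-Bayes moderated t.

The cohort is split at an age cut-off (young: age <= cutoff, elder:
age > cutoff) and each probe is tested with an equal-variance two-sample
t whose per-probe variance is shrunk toward a common prior:

    s2_mod = (d0 * s0^2 + d * s^2) / (d0 + d)

where ``d`` is the residual degrees of freedom and the hyperparameters
``(d0, s0^2)`` are fitted by matching moments of the log residual
variances to a scaled F / log-chi-square model (the standard
empirical-Bayes treatment for microarray linear models).  The moderated
t has ``d0 + d`` degrees of freedom; with shrinkage off it reduces
exactly to the classical pooled t.  Multiple testing uses the
Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, SampleMetadata, ValidationError


def split_groups(metadata: SampleMetadata, cutoff: float = 50.0) -> pd.Series:
    """Label each sample ``young`` (age <= cutoff) or ``elder`` (age > cutoff)."""
    ages = metadata.ages()
    labels = pd.Series(
        np.where(ages.to_numpy() <= cutoff, "young", "elder"),
        index=ages.index,
        name="group",
    )
    counts = labels.value_counts()
    for grp in ("young", "elder"):
        if counts.get(grp, 0) < 2:
            raise ValidationError(
                f"group {grp!r} has {counts.get(grp, 0)} sample(s); "
                f"need >= 2 on each side of cutoff {cutoff}"
            )
    return labels


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = scipy.special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / scipy.special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-fit the prior degrees of freedom d0 and prior variance s0^2.

    Works on the log variances: for s^2 ~ s0^2 * F(df, d0), log(s^2) has
    known digamma/trigamma moments, so matching the sample mean and
    variance of ``log(s^2)`` identifies (d0, s0^2).  An excess-variance
    estimate <= 0 means the observed variances are no more dispersed than
    sampling alone explains, giving an infinite d0 (complete shrinkage).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValidationError("need >= 2 positive residual variances to fit a prior")
    z = np.log(s2[ok])
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = len(e)
    evar = ((e - emean) ** 2).sum() / (n - 1)
    excess = evar - scipy.special.polygamma(1, df / 2.0)
    if excess <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = np.exp(
        emean + scipy.special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    )
    return float(d0), float(s0_sq)


def moderated_t(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    prior_df_mode: str = "eb",
) -> pd.DataFrame:
    """Per-probe two-group t with optional empirical-Bayes shrinkage.

    ``prior_df_mode="eb"`` shrinks each probe's pooled variance toward the
    moment-fitted prior; ``"none"`` gives the ordinary pooled-variance t.
    The statistic's sign follows elder minus young.

    Returns a DataFrame with columns ``mean_young``, ``mean_elder``,
    ``t_statistic``, ``p_raw``, ``df_total`` indexed by probe.
    """
    if prior_df_mode not in ("eb", "none"):
        raise ValidationError(f"unknown prior_df_mode {prior_df_mode!r}")
    labels = labels.loc[matrix.sample_ids]
    young = matrix.values.loc[:, (labels == "young").to_numpy()]
    elder = matrix.values.loc[:, (labels == "elder").to_numpy()]
    n1, n2 = young.shape[1], elder.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 samples per group")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValidationError("zero residual degrees of freedom")

    m1 = young.mean(axis=1).to_numpy()
    m2 = elder.mean(axis=1).to_numpy()
    ss1 = ((young.to_numpy() - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((elder.to_numpy() - m2[:, None]) ** 2).sum(axis=1)
    s2 = (ss1 + ss2) / df

    if prior_df_mode == "eb":
        d0, s0_sq = fit_variance_prior(s2, df)
        if np.isinf(d0):
            s2_mod = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
            df_total = d0 + df
    else:
        s2_mod = s2
        df_total = float(df)

    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / se
    t[(se == 0) & (m1 == m2)] = 0.0
    if np.isinf(df_total):
        p = 2.0 * scipy.stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=df_total)
    return pd.DataFrame(
        {
            "mean_young": m1,
            "mean_elder": m2,
            "t_statistic": t,
            "p_raw": p,
            "df_total": df_total,
        },
        index=matrix.values.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_table(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    prior_df_mode: str = "eb",
) -> pd.DataFrame:
    """Full differential-expression table with BH-adjusted calls.

    ``fc_elder_young`` is the linear-scale ratio ``2**(mean_elder -
    mean_young)`` (log2 input assumed); direction is ``UP``/``DOWN`` for
    probes significant at the BH-adjusted ``alpha``, else ``none``.
    """
    stats = moderated_t(matrix, labels, prior_df_mode=prior_df_mode)
    p_adj = bh_adjust(stats["p_raw"].to_numpy())
    fc = np.power(2.0, stats["mean_elder"] - stats["mean_young"])
    direction = np.full(len(stats), "none", dtype=object)
    direction[(p_adj < alpha) & (fc > 1)] = "UP"
    direction[(p_adj < alpha) & (fc < 1)] = "DOWN"
    out = stats.copy()
    out["fc_elder_young"] = fc
    out["p_adj"] = p_adj
    out["direction"] = direction
    out.insert(0, "probeset", out.index)
    return out.reset_index(drop=True)


class DifferentialExpression(BaseEstimator):
    """Young-vs-elder moderated-t differential expression as an estimator.

    Parameters
    ----------
    cutoff : float
        Age cut between young (<= cutoff) and elder (> cutoff).
    alpha : float
        BH-adjusted significance level for the UP/DOWN calls.
    prior_df_mode : {"eb", "none"}
        Variance shrinkage on (empirical Bayes) or off (classical pooled t).

    Attributes
    ----------
    labels_ : Series of group labels per sample
    de_table_ : result DataFrame (see :func:`de_table`)
    prior_df_, prior_var_ : fitted hyperparameters (eb mode)
    """

    def __init__(
        self, cutoff: float = 50.0, alpha: float = 0.05, prior_df_mode: str = "eb"
    ):
        self.cutoff = cutoff
        self.alpha = alpha
        self.prior_df_mode = prior_df_mode

    def fit(self, X, y):
        if isinstance(X, ExpressionMatrix):
            matrix = X
        else:
            matrix = ExpressionMatrix(pd.DataFrame(X), scale="log2")
        if isinstance(y, SampleMetadata):
            metadata = y
        else:
            metadata = SampleMetadata(
                pd.DataFrame(
                    {"age": np.asarray(y, dtype=float), "cohort": "discovery"},
                    index=pd.Index(matrix.sample_ids),
                )
            )
        self.labels_ = split_groups(metadata, cutoff=self.cutoff)
        self.de_table_ = de_table(
            matrix, self.labels_, alpha=self.alpha, prior_df_mode=self.prior_df_mode
        )
        if self.prior_df_mode == "eb":
            n1 = int((self.labels_ == "young").sum())
            n2 = int((self.labels_ == "elder").sum())
            young = matrix.values.loc[:, (self.labels_.loc[matrix.sample_ids] == "young").to_numpy()]
            elder = matrix.values.loc[:, (self.labels_.loc[matrix.sample_ids] == "elder").to_numpy()]
            s2 = (
                ((young.to_numpy() - young.mean(axis=1).to_numpy()[:, None]) ** 2).sum(axis=1)
                + ((elder.to_numpy() - elder.mean(axis=1).to_numpy()[:, None]) ** 2).sum(axis=1)
            ) / (n1 + n2 - 2)
            self.prior_df_, self.prior_var_ = fit_variance_prior(s2, n1 + n2 - 2)
        return self

    def predict(self, X=None):
        """Per-probe UP/DOWN/none calls from the fitted comparison."""
        return self.de_table_.set_index("probeset")["direction"]
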