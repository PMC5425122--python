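"""Synthetic cohorts with known age trends, and synthetic qPCR Cq tables.

The generator emulates the statistical structure the screening pipeline
assumes: a cohort of adults whose probe-level log2 expression follows a
logistic (sigmoidal) trajectory of age,

    m_i(age) = b_i +/- A_i * L((age - a0) / tau),   L(u) = 1 / (1 + e^-u)

with inflection age ``a0`` (where the change accelerates), width ``tau``,
amplitude ``A`` in log2 units (A = 1 gives an expected last/first fold
change near 2), and i.i.d. Gaussian noise on the log2 scale.  Null probes
have A = 0.  Ground-truth labels accompany every probe so that screen
sensitivity and specificity are measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import CqTable, ExpressionMatrix, SampleMetadata, ValidationError


@dataclass
class TrendSimConfig:
    """Parameters of the synthetic expression cohort.

    Defaults mirror the study conditions: 38 donors aged 24-79, logistic
    inflection at 50 years with width 4 years, unit log2 amplitude and
    0.3 log2 units of measurement noise.
    """

    n_samples: int = 38
    age_range: tuple[float, float] = (24.0, 79.0)
    n_probes: int = 500
    frac_increasing: float = 0.10
    frac_decreasing: float = 0.05
    inflection_age: float = 50.0
    logistic_scale: float = 4.0
    amplitude: float = 1.0
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (6.0, 10.0)
    ages: list[float] | None = field(default=None)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("need at least 2 samples")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValidationError("degenerate age_range")
        if self.frac_increasing + self.frac_decreasing > 1.0:
            raise ValidationError("trend fractions must sum to <= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.logistic_scale <= 0:
            raise ValidationError("logistic_scale must be > 0")
        if not lo <= self.inflection_age <= hi:
            raise ValidationError("inflection_age must lie inside age_range")
        if self.ages is not None and len(self.ages) != self.n_samples:
            raise ValidationError("explicit age list length must equal n_samples")


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def generate_cohort(
    config: TrendSimConfig,
) -> tuple[ExpressionMatrix, SampleMetadata, pd.DataFrame]:
    """Simulate an expression cohort with ground-truth trend labels.

    Returns
    -------
    matrix, metadata, truth
        ``truth`` has one row per probe with columns ``true_class``
        (``increasing`` / ``decreasing`` / ``null``) and ``true_amplitude``.

    Ages are drawn uniformly over ``age_range`` unless ``config.ages``
    supplies an explicit list (e.g. to match a real cohort's histogram).
    Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=float)
    else:
        ages = rng.uniform(lo, hi, size=config.n_samples)

    n_inc = int(round(config.frac_increasing * config.n_probes))
    n_dec = int(round(config.frac_decreasing * config.n_probes))
    classes = np.array(
        ["increasing"] * n_inc
        + ["decreasing"] * n_dec
        + ["null"] * (config.n_probes - n_inc - n_dec)
    )

    sign = np.where(
        classes == "increasing", 1.0, np.where(classes == "decreasing", -1.0, 0.0)
    )
    amplitude = np.abs(sign) * config.amplitude
    baseline = rng.uniform(*config.baseline_range, size=config.n_probes)

    traj = _logistic((ages[None, :] - config.inflection_age) / config.logistic_scale)
    means = baseline[:, None] + (sign * amplitude)[:, None] * traj
    noise = rng.normal(0.0, config.noise_sd, size=means.shape) if config.noise_sd else 0.0
    values = means + noise

    probe_ids = [f"probe_{i:04d}" for i in range(config.n_probes)]
    sample_ids = [f"S{j:03d}" for j in range(config.n_samples)]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=probe_ids, columns=sample_ids), scale="log2"
    )
    metadata = SampleMetadata(
        pd.DataFrame(
            {"age": ages, "cohort": "synthetic"}, index=pd.Index(sample_ids)
        )
    )
    truth = pd.DataFrame(
        {"probe_id": probe_ids, "true_class": classes, "true_amplitude": amplitude}
    )
    return matrix, metadata, truth


def generate_cq(
    n_young: int,
    n_old: int,
    ddcq_true: float,
    sd: float = 0.3,
    seed: int = 0,
    target_assay: str = "target",
    reference_assay: str = "miR-191",
    baseline_dcq: float = 4.0,
    reference_mean: float = 20.0,
) -> tuple[CqTable, pd.Series]:
    """Simulate per-sample Cq values for one target and one reference assay.

    The reference Cq is Normal(``reference_mean``, sd^2); the target Cq is
    reference Cq + ``baseline_dcq`` + ``ddcq_true`` (elder group only) +
    noise, so the expected relative quantification of elder vs young is
    ``2**-ddcq_true``.

    Returns the Cq table and a Series of group labels ("young"/"elder")
    indexed by sample id.
    """
    if n_young <= 0 or n_old <= 0:
        raise ValidationError("group sizes must be positive")
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    rng = np.random.default_rng(seed)
    sample_ids = [f"V{j:03d}" for j in range(n_young + n_old)]
    groups = pd.Series(
        ["young"] * n_young + ["elder"] * n_old, index=sample_ids, name="group"
    )
    ref_cq = rng.normal(reference_mean, sd, size=n_young + n_old)
    shift = np.where(groups.to_numpy() == "elder", ddcq_true, 0.0)
    tgt_cq = ref_cq + baseline_dcq + shift + rng.normal(0.0, sd, size=len(shift))
    records = pd.DataFrame(
        {
            "sample_id": sample_ids * 2,
            "assay": [reference_assay] * len(sample_ids)
            + [target_assay] * len(sample_ids),
            "cq": np.concatenate([ref_cq, tgt_cq]),
        }
    )
    return CqTable(records), groups
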