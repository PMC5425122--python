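"""Moderated t, BH adjustment and the two-group DE table.

The empirical-Bayes moderated t is cross-checked against the Bioconductor
reference implementation (via Rscript) on a small random matrix, and
against the classical pooled t when shrinkage is off.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from agetrend import (
    DifferentialExpression,
    ExpressionMatrix,
    SampleMetadata,
    TrendSimConfig,
    ValidationError,
    bh_adjust,
    de_table,
    generate_cohort,
    moderated_t,
    split_groups,
)


def _metadata(ages):
    ids = [f"s{i}" for i in range(len(ages))]
    return SampleMetadata(
        pd.DataFrame({"age": ages, "cohort": "discovery"}, index=pd.Index(ids))
    )


def _matrix(arr):
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=[f"p{i}" for i in range(arr.shape[0])],
            columns=[f"s{i}" for i in range(arr.shape[1])],
        )
    )


def _labels(n_young, n_elder):
    ids = [f"s{i}" for i in range(n_young + n_elder)]
    return pd.Series(["young"] * n_young + ["elder"] * n_elder, index=ids)


class TestSplitGroups:
    def test_boundary_inclusive_on_young(self):
        labels = split_groups(_metadata([24, 50, 51, 79]), cutoff=50)
        assert labels.tolist() == ["young", "young", "elder", "elder"]

    def test_all_young_rejected(self):
        with pytest.raises(ValidationError, match="elder"):
            split_groups(_metadata([24, 30, 40, 45]), cutoff=50)

    def test_synthetic_cohort_partitions(self, default_cohort):
        _, metadata, _ = default_cohort
        labels = split_groups(metadata)
        assert len(labels) == 38
        assert set(labels) == {"young", "elder"}


class TestModeratedT:
    def test_identical_groups_give_null_statistic(self, rng):
        half = rng.normal(size=(20, 5))
        arr = np.hstack([half, half])
        stats = moderated_t(_matrix(arr), _labels(5, 5))
        np.testing.assert_allclose(stats["t_statistic"], 0.0, atol=1e-12)
        np.testing.assert_allclose(stats["p_raw"], 1.0, atol=1e-12)

    def test_pooled_t_hand_case(self):
        # young (-1,0,1), elder (0,1,2): pooled s2 = 1, t = 1/sqrt(2/3)
        arr = np.array([[-1.0, 0.0, 1.0, 0.0, 1.0, 2.0]])
        stats = moderated_t(_matrix(arr), _labels(3, 3), prior_df_mode="none")
        assert stats["t_statistic"].iloc[0] == pytest.approx(1.0 / np.sqrt(2 / 3))
        assert stats["df_total"].iloc[0] == 4

    def test_no_shrinkage_equals_classical_pooled_t(self, rng):
        arr = rng.normal(size=(100, 14))
        stats = moderated_t(_matrix(arr), _labels(7, 7), prior_df_mode="none")
        ref = scipy.stats.ttest_ind(arr[:, 7:], arr[:, :7], axis=1, equal_var=True)
        np.testing.assert_allclose(stats["t_statistic"], ref.statistic, atol=1e-9)
        np.testing.assert_allclose(stats["p_raw"], ref.pvalue, atol=1e-9)

    def test_shrinkage_pulls_variances_together(self, rng):
        arr = rng.normal(size=(300, 10)) * rng.uniform(0.5, 2.0, size=(300, 1))
        plain = moderated_t(_matrix(arr), _labels(5, 5), prior_df_mode="none")
        shrunk = moderated_t(_matrix(arr), _labels(5, 5), prior_df_mode="eb")
        assert shrunk["df_total"].iloc[0] > plain["df_total"].iloc[0]

    def test_null_matrix_type_one_error_near_nominal(self):
        rng = np.random.default_rng(100)
        fracs = []
        for _ in range(5):
            arr = rng.normal(size=(1000, 38))
            stats = moderated_t(_matrix(arr), _labels(21, 17))
            fracs.append((stats["p_raw"] < 0.05).mean())
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.01)

    def test_matches_bioconductor_reference(self, tmp_path):
        """Moderated t, p, prior df and prior variance agree with the
        Bioconductor linear-model implementation on a random matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(7)
        arr = rng.normal(size=(150, 12)) * rng.uniform(0.3, 3.0, size=(150, 1))
        matrix = _matrix(arr)
        mpath = tmp_path / "m.tsv"
        out = matrix.values.copy()
        out.index.name = "probe_id"
        out.to_csv(mpath, sep="\t")
        script = tmp_path / "ref.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            "args <- commandArgs(trailingOnly=TRUE)\n"
            "x <- as.matrix(read.delim(args[1], row.names=1, check.names=FALSE))\n"
            'group <- factor(rep(c("young", "elder"), each=6), levels=c("young", "elder"))\n'
            "design <- model.matrix(~group)\n"
            "fit <- eBayes(lmFit(x, design))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n"
            "                  d0=fit$df.prior, s02=fit$s2.prior)\n"
            'write.table(out, args[2], sep="\\t", quote=FALSE)\n'
        )
        rpath = tmp_path / "ref.tsv"
        subprocess.run(
            ["Rscript", str(script), str(mpath), str(rpath)],
            check=True,
            capture_output=True,
        )
        ref = pd.read_csv(rpath, sep="\t")
        stats = moderated_t(matrix, _labels(6, 6), prior_df_mode="eb")
        np.testing.assert_allclose(stats["t_statistic"], ref["t"], rtol=1e-6)
        np.testing.assert_allclose(stats["p_raw"], ref["p"], rtol=1e-6)
        assert stats["df_total"].iloc[0] - 10 == pytest.approx(
            ref["d0"].iloc[0], rel=1e-4
        )


class TestBhAdjust:
    def test_stepup_hand_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_stepup_definition(self, rng):
        p = rng.uniform(size=200)
        m = len(p)
        order = np.argsort(p)
        oracle = np.empty(m)
        running_min = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running_min = min(running_min, m * p[idx] / rank)
            oracle[idx] = running_min
        np.testing.assert_allclose(bh_adjust(p), oracle, atol=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_permutation_equivariant_and_dominates_raw(self, p):
        p = np.asarray(p)
        adjusted = bh_adjust(p)
        assert (adjusted >= p - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[perm]), adjusted[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestDeTable:
    def test_direction_calls_respect_alpha_and_fc(self, rng):
        arr = rng.normal(size=(50, 38))
        arr[:10, 21:] += 2.0  # strong elder shift up
        table = de_table(_matrix(arr), _labels(21, 17))
        up = table["direction"] == "UP"
        assert ((table.loc[up, "p_adj"] < 0.05) & (table.loc[up, "fc_elder_young"] > 1)).all()
        assert up.sum() >= 9

    def test_null_matrix_nearly_no_discoveries(self, rng):
        arr = rng.normal(size=(1000, 38))
        table = de_table(_matrix(arr), _labels(21, 17))
        assert (table["direction"] != "none").sum() <= 2

    def test_power_on_shifted_probes(self):
        detected = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            matrix, metadata, _ = generate_cohort(
                TrendSimConfig(seed=seed, n_probes=200, frac_increasing=0.0,
                               frac_decreasing=0.0, noise_sd=0.3)
            )
            arr = matrix.values.to_numpy().copy()
            labels = split_groups(metadata)
            elder_cols = (labels.loc[matrix.sample_ids] == "elder").to_numpy()
            arr[:20, elder_cols] += 1.0
            table = de_table(_matrix_like(matrix, arr), labels)
            detected.append((table["direction"].iloc[:20] != "none").sum())
        assert np.median(detected) >= 18

    def test_estimator_wraps_table(self, default_cohort):
        matrix, metadata, _ = default_cohort
        model = DifferentialExpression().fit(matrix, metadata)
        assert model.prior_df_ > 0
        assert len(model.de_table_) == matrix.n_probes
        calls = model.predict()
        assert set(calls.unique()) <= {"UP", "DOWN", "none"}


def _matrix_like(matrix, arr):
    return ExpressionMatrix(
        pd.DataFrame(arr, index=matrix.values.index, columns=matrix.values.columns)
    )
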