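"""Moderated-t statistics, threshold calls and their calibration."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import make_summary
from exonscreen.diffexpr import (GroupDesign, call_differential,
                                 estimate_prior, moderated_t_table,
                                 signed_fold, stats_table)
from exonscreen.preprocess import GENE, preprocess_pipeline
from exonscreen.synthetic import (SimulationDesign, group_design,
                                  simulate_experiment)


def pooled_t_oracle(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook pooled-variance two-sample t, coded independently."""
    n1, n2 = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    return (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))


def random_summary(rng, n_features=50, n1=4, n2=4, kind=GENE):
    vals = {f"f{i}": list(rng.normal(7, 1, size=n1 + n2))
            for i in range(n_features)}
    return make_summary(vals, kinds={f: kind for f in vals})


def two_group_design(n1=4, n2=4):
    groups = {f"S{i+1}": ("CTRL" if i < n1 else "KO") for i in range(n1 + n2)}
    return GroupDesign(groups)


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self, rng):
        s = random_summary(rng)
        recs = moderated_t_table(s, two_group_design(), prior_df=0.0)
        for i, r in enumerate(recs):
            row = s.values.iloc[i].to_numpy()
            expected = pooled_t_oracle(row[:4], row[4:])
            assert abs(r.t_moderated - expected) < 1e-10

    def test_identical_group_means_give_null_stat(self):
        s = make_summary({"f": [5.0, 6.0, 5.0, 6.0, 5.0, 6.0, 5.0, 6.0],
                          "g": [4.0, 5.0, 6.0, 7.0, 7.0, 6.0, 5.0, 4.0]},
                         kinds={"f": GENE, "g": GENE})
        recs = moderated_t_table(s, two_group_design())
        for r in recs:
            assert r.t_moderated == pytest.approx(0.0, abs=1e-12)
            assert r.p_value == pytest.approx(1.0)

    def test_equal_variances_are_shrinkage_fixed_point(self, rng):
        # all features share s_g^2 => s~^2 = s_g^2 whatever d0, so the
        # moderated t equals the ordinary pooled t
        # identical within-group residuals across features => shared s_g^2
        resid = np.array([0.1, -0.1, 0.2, -0.2, 0.15, -0.15, 0.05, -0.05])
        vals = {f"f{i}": list(resid + i * 0.3 * np.where(np.arange(8) < 4, 0, 1))
                for i in range(10)}
        s = make_summary(vals, kinds={f: GENE for f in vals})
        for d0 in (0.0, 3.0, 50.0):
            recs = moderated_t_table(s, two_group_design(), prior_df=d0)
            for i, r in enumerate(recs):
                row = s.values.iloc[i].to_numpy()
                assert r.t_moderated == pytest.approx(
                    pooled_t_oracle(row[:4], row[4:]), abs=1e-9)

    def test_zero_variance_feature_is_moderated(self, rng):
        vals = {f"f{i}": list(rng.normal(7, 1, size=8)) for i in range(20)}
        vals["flat"] = [5.0] * 4 + [6.0] * 4  # zero residual variance
        s = make_summary(vals, kinds={f: GENE for f in vals})
        recs = moderated_t_table(s, two_group_design())
        flat = next(r for r in recs if r.feature_id == "flat")
        assert np.isfinite(flat.t_moderated) and flat.p_value < 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            GroupDesign({"S1": "CTRL", "S2": "KO", "S3": "KO"})

    def test_null_type_one_error_calibrated(self, rng):
        s = random_summary(rng, n_features=2000)
        recs = moderated_t_table(s, two_group_design())
        rate = np.mean([r.p_value <= 0.05 for r in recs])
        assert 0.03 <= rate <= 0.07

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Independent oracle: limma's eBayes on the same matrix.

        Per-feature noise scales are heterogeneous so the prior df
        estimate is finite and the shrinkage path is exercised.
        """
        vals = {f"f{i}": list(rng.normal(7, rng.lognormal(0, 0.6), size=8))
                for i in range(60)}
        s = make_summary(vals, kinds={f: GENE for f in vals})
        s.values.to_csv(tmp_path / "x.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.delim('{tmp_path}/x.tsv', row.names=1))\n"
            "group <- factor(c(rep('CTRL',4), rep('KO',4)), levels=c('CTRL','KO'))\n"
            "fit <- eBayes(lmFit(x, model.matrix(~group)))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],\n"
            "                  d0=fit$df.prior, s0=fit$s2.prior)\n"
            f"write.table(out, '{tmp_path}/out.tsv', sep='\\t', quote=FALSE)\n")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        recs = moderated_t_table(s, two_group_design())
        prior = estimate_prior(
            np.array([np.var(np.concatenate([
                s.values.iloc[i, :4] - s.values.iloc[i, :4].mean(),
                s.values.iloc[i, 4:] - s.values.iloc[i, 4:].mean()])) * 8 / 6
                for i in range(60)]), 6)
        assert prior.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert prior.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose([r.t_moderated for r in recs],
                                   ref["t"].to_numpy(), rtol=1e-5)
        np.testing.assert_allclose([r.p_value for r in recs],
                                   ref["p"].to_numpy(), rtol=1e-5)


class TestCallDifferential:
    def _mk(self, fid, fold, p):
        from exonscreen.diffexpr import GeneStatsRecord
        lfc = np.log2(abs(fold)) * (1 if fold > 0 else -1)
        return GeneStatsRecord(fid, lfc, fold, 0.0, p, 6.0)

    def test_threshold_examples(self):
        recs = [self._mk("below_fold", 1.4, 0.001),
                self._mk("down_hit", -1.6, 0.04)]
        called = call_differential(recs)
        assert called == ["down_hit"]

    def test_toy_table_matches_brute_force(self):
        folds = [1.2, -1.5, 2.0, -3.0, 1.5, -1.1]
        ps = [0.01, 0.04, 0.2, 0.05, 0.051, 0.001]
        recs = [self._mk(f"f{i}", f, p) for i, (f, p) in enumerate(zip(folds, ps))]
        called = set(call_differential(recs))
        brute = {f"f{i}" for i, (f, p) in enumerate(zip(folds, ps))
                 if abs(f) >= 1.5 and p <= 0.05}
        assert called == brute == {"f1", "f3"}

    def test_relaxing_thresholds_never_shrinks_set(self, rng):
        recs = [self._mk(f"f{i}", float(signed_fold(rng.normal(0, 1))),
                         float(rng.uniform(0, 1))) for i in range(100)]
        strict = set(call_differential(recs, fold_cut=2.0, p_cut=0.01))
        loose_fold = set(call_differential(recs, fold_cut=1.2, p_cut=0.01))
        loose_p = set(call_differential(recs, fold_cut=2.0, p_cut=0.2))
        assert strict <= loose_fold and strict <= loose_p

    def test_sorted_by_p(self):
        recs = [self._mk("a", 2.0, 0.04), self._mk("b", 2.0, 0.01)]
        assert call_differential(recs) == ["b", "a"]


class TestSignedFold:
    def test_sign_convention(self):
        assert signed_fold(1.0) == pytest.approx(2.0)
        assert signed_fold(-1.0) == pytest.approx(-2.0)
        assert signed_fold(0.0) == pytest.approx(1.0)


class TestRecovery:
    def test_planted_two_fold_changes_recovered(self):
        """>= 90% of planted 2-fold transcripts called at 4v4, noise 0.25."""
        design = SimulationDesign(frac_de=0.2, de_fold_range=(2.0, 2.0),
                                  frac_as=0.0, noise_sd=0.25, seed=21)
        models, truth, matrix = simulate_experiment(100, design)
        summary, _ = preprocess_pipeline(matrix)
        gd = GroupDesign(group_design(matrix))
        recs = moderated_t_table(summary.subset(GENE), gd)
        called = set(call_differential(recs))
        planted = set(truth.de_transcripts)
        assert len(planted & called) / len(planted) >= 0.9


def test_stats_table_has_dataset_dialect_columns(rng):
    s = random_summary(rng, n_features=5)
    df = stats_table(moderated_t_table(s, two_group_design()))
    assert list(df.columns[:3]) == ["TRANSCRIPT_ID", "p-value", "F_C[KOvsCTRL]"]
    assert "fdr_bh" in df.columns
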