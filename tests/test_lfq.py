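"""Label-free quantification: normalization, linear model, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evquant import lfq
from evquant.simulate import COND_CD63, COND_CD9, ProteomeSimConfig, gen_peptide_table

from conftest import make_table, peptide_rows


class TestNormalization:
    def test_homogeneous_table_is_fixed_point(self):
        # every sample carries the same multiset of intensities, so pooled
        # median/MAD equal each sample's and the transform is the identity
        vals = [100.0, 200.0, 400.0, 800.0]
        rows = []
        for cond in ("A", "B"):
            for rep in (1, 2):
                for j, v in enumerate(vals):
                    rows.append(("P1", f"pep{j}", cond, rep, v))
        table = make_table(rows)
        out, report = lfq.normalize_total_signal(table)
        np.testing.assert_allclose(out["xic"], table["xic"], rtol=1e-12)
        np.testing.assert_allclose(report["scale"], 1.0)

    def test_scaled_replicate_median_realigned(self):
        vals = np.array([100.0, 200.0, 400.0, 800.0])
        rows = []
        for rep in (1, 2, 3):
            factor = 4.0 if rep == 3 else 1.0  # one replicate off by 4x raw
            for j, v in enumerate(vals * factor):
                rows.append(("P1", f"pep{j}", "A", rep, v))
        out, _ = lfq.normalize_total_signal(make_table(rows))
        log2 = np.log2(out["xic"])
        medians = out.assign(l=log2).groupby("replicate")["l"].median()
        np.testing.assert_allclose(medians, medians.iloc[0], rtol=1e-12)

    def test_single_sample_table_unchanged(self):
        table = make_table(peptide_rows("P1", "pep1", {"A": [100.0, None, None]}))
        table = pd.concat(
            [table, make_table(peptide_rows("P1", "pep2", {"A": [300.0, None, None]}))]
        ).reset_index(drop=True)
        out, report = lfq.normalize_total_signal(table)
        np.testing.assert_allclose(out["xic"], table["xic"], rtol=1e-12)

    def test_report_inverts_transform(self):
        rng = np.random.default_rng(0)
        rows = []
        for cond in ("A", "B"):
            for rep in (1, 2, 3):
                for j in range(6):
                    rows.append(
                        ("P1", f"pep{j}", cond, rep, float(2 ** rng.uniform(18, 25)))
                    )
        table = make_table(rows)
        out, report = lfq.normalize_total_signal(table)
        back = lfq.denormalize(out, report)
        np.testing.assert_allclose(back["xic"], table["xic"], rtol=1e-9)

    def test_undersized_sample_left_unscaled(self, caplog):
        rows = peptide_rows("P1", "pep1", {"A": [100.0, 555.0]})
        for j in range(5):
            rows += peptide_rows("P1", f"pep{j + 2}", {"B": [100.0 * (j + 1), None]})
        table = make_table(rows)
        # replicate 2 of A has a single observation
        with caplog.at_level("WARNING"):
            out, report = lfq.normalize_total_signal(table)
        rec = report.set_index(["condition", "replicate"]).loc[("A", 2)]
        assert rec["scale"] == 1.0 and rec["shift"] == 0.0
        kept = float(out.loc[(out.condition == "A") & (out.replicate == 2), "xic"].iloc[0])
        assert kept == pytest.approx(555.0, rel=1e-12)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            lfq.normalize_total_signal(make_table([]))


class TestProteinDifferential:
    def test_null_data_gives_zero_fc_unit_p(self, constant_table):
        diff = lfq.protein_differential(constant_table, "A", "B")
        np.testing.assert_allclose(diff["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(diff["p_value"], 1.0)

    def test_noiseless_fourfold_ratio_exact(self, fourfold_table):
        diff = lfq.protein_differential(fourfold_table, "A", "B")
        assert len(diff) == 1
        np.testing.assert_allclose(diff["log2fc"].iloc[0], 2.0, atol=1e-9)

    def test_one_condition_only_gets_infinity_sentinel(self):
        rows = peptide_rows("P1", "pep1", {"A": [100.0, 200.0, 150.0]})
        rows += peptide_rows("P1", "pep2", {"A": [300.0, 310.0, 290.0]})
        rows += peptide_rows("P2", "pep1", {"A": [1.0, 2.0], "B": [1.0, 2.0]})
        diff = lfq.protein_differential(make_table(rows), "A", "B")
        rec = diff.set_index("protein_id").loc["P1"]
        assert rec["log2fc"] == np.inf and np.isnan(rec["p_value"])
        assert rec["n_peptides_b"] == 0

    def test_condition_swap_negates_fc_keeps_p(self):
        cfg = ProteomeSimConfig(n_proteins=30, seed=11)
        pep, *_ = gen_peptide_table(cfg)
        d1 = lfq.protein_differential(pep, COND_CD63, COND_CD9, adjust=False)
        d2 = lfq.protein_differential(pep, COND_CD9, COND_CD63, adjust=False)
        m = d1.merge(d2, on="protein_id", suffixes=("_1", "_2"))
        np.testing.assert_allclose(m["log2fc_1"], -m["log2fc_2"], rtol=1e-9)
        np.testing.assert_allclose(m["p_value_1"], m["p_value_2"], rtol=1e-9, atol=1e-12)

    def test_scale_invariance_after_normalization(self):
        cfg = ProteomeSimConfig(n_proteins=25, seed=5, missing_rate=0.0)
        pep, *_ = gen_peptide_table(cfg)
        scaled = pep.copy()
        sel = (scaled.condition == COND_CD63) & (scaled.replicate == 2)
        scaled.loc[sel, "xic"] *= 7.3
        d1 = lfq.protein_differential(lfq.normalize_total_signal(pep)[0],
                                      COND_CD63, COND_CD9, adjust=False)
        d2 = lfq.protein_differential(lfq.normalize_total_signal(scaled)[0],
                                      COND_CD63, COND_CD9, adjust=False)
        finite = np.isfinite(d1["log2fc"])
        np.testing.assert_allclose(
            d1.loc[finite, "log2fc"], d2.loc[finite, "log2fc"], rtol=1e-6, atol=1e-8
        )

    def test_balanced_complete_fc_equals_mean_peptide_ratio(self):
        # closed-form oracle: for complete balanced data the condition
        # contrast is the mean over peptides of (mean_A - mean_B) log2 XIC
        rng = np.random.default_rng(3)
        rows = []
        expected = []
        for j in range(4):
            a = 2 ** rng.uniform(18, 25, size=3)
            b = 2 ** rng.uniform(18, 25, size=3)
            rows += peptide_rows("P1", f"pep{j}", {"A": list(a), "B": list(b)})
            expected.append(np.log2(a).mean() - np.log2(b).mean())
        diff = lfq.protein_differential(make_table(rows), "A", "B")
        np.testing.assert_allclose(diff["log2fc"].iloc[0], np.mean(expected), atol=1e-9)

    def test_matches_statsmodels_ols(self):
        # independent route: same model fitted by statsmodels formula OLS
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        rows = []
        for j in range(3):
            for rep in (1, 2, 3, 4):
                rows.append(("P1", f"pep{j}", "A", rep, float(2 ** rng.uniform(18, 22))))
                rows.append(("P1", f"pep{j}", "B", rep, float(2 ** rng.uniform(18, 22))))
        table = make_table(rows)
        diff = lfq.protein_differential(table, "A", "B")
        df = table.assign(y=np.log2(table.xic), is_a=(table.condition == "A").astype(int))
        fit = smf.ols("y ~ is_a + C(peptide_id) + C(replicate)", data=df).fit()
        np.testing.assert_allclose(diff["log2fc"].iloc[0], fit.params["is_a"], rtol=1e-9)
        np.testing.assert_allclose(diff["p_value"].iloc[0], fit.pvalues["is_a"], rtol=1e-9)

    def test_missing_condition_rejected(self, constant_table):
        with pytest.raises(ValueError, match="condition"):
            lfq.protein_differential(constant_table, "A", "C")

    def test_null_simulation_p_uniform_and_fdr_controlled(self):
        # every protein common => the A-vs-B contrast is null; the exact
        # t-test must produce uniform p-values and BH must control FDR
        cfg = ProteomeSimConfig(
            n_proteins=600,
            frac_enriched_a=0, frac_enriched_b=0, frac_common=1.0,
            frac_unique_a=0, frac_unique_b=0, frac_contaminant=0,
            frac_nonspecific=0, replicate_shift_sd=0.0, seed=19,
        )
        pep, *_ = gen_peptide_table(cfg)
        diff = lfq.protein_differential(pep, COND_CD63, COND_CD9)
        p = diff["p_value"].dropna().to_numpy()
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05
        frac_rej = float((diff["p_adj"].dropna() < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / len(p))
        assert frac_rej <= 0.05 + 2 * se


class TestAdjustBH:
    def test_step_up_hand_example(self):
        # hand step-up: sorted p * m/rank then monotone from the top
        np.testing.assert_allclose(
            lfq.adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_bounds(self):
        np.testing.assert_allclose(lfq.adjust_bh([1.0]), [1.0])
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        q = lfq.adjust_bh(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0 + 1e-12)

    def test_nan_passthrough_and_order_preserved(self):
        q = lfq.adjust_bh([0.04, np.nan, 0.01])
        assert np.isnan(q[1])
        np.testing.assert_allclose([q[0], q[2]], [0.04, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lfq.adjust_bh([0.5, 1.5])
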