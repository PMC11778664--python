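import numpy as np
import pandas as pd
import pytest

from hetloop import genotype_io as gio
from hetloop import prs
from hetloop import synthetic_data as sd

from oracles import threshold_model_auc


def make_dataset(calls, statuses, chrom=None, pos=None, subtypes=None):
    n, s = calls.shape
    subjects = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "status": statuses,
            "subtype": subtypes if subtypes is not None else ["unknown"] * n,
            "arm_id": "a",
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{j}" for j in range(s)],
            "chrom": chrom if chrom is not None else ["1"] * s,
            "pos_bp": pos if pos is not None else (np.arange(s) + 1) * 1000,
            "allele_major": "A",
            "allele_minor": "B",
            "maf": 0.0,
        }
    )
    ds = gio.GenotypeDataset(subjects=subjects, snps=snps, calls=np.asarray(calls, float))
    ds.snps["maf"] = ds.computed_maf()
    return ds


class TestGwas:
    def _sim(self, seed, n=600, s=8, beta=0.0, cov_effect=0.0):
        rng = np.random.default_rng(seed)
        from scipy.special import expit

        cov = rng.standard_normal((n, 2))
        g = rng.binomial(2, 0.35, size=(n, s)).astype(float)
        eta = -0.1 + beta * g[:, 0] + cov_effect * cov[:, 0]
        y = rng.random(n) < expit(eta)
        statuses = np.where(y, "case", "control")
        return make_dataset(g, statuses), pd.DataFrame(cov, index=[f"s{i}" for i in range(n)]), y

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        ds, cov, y = self._sim(0, n=300, s=4, beta=0.6, cov_effect=0.5)
        out = prs.gwas(ds, None, cov.to_numpy(), [0])
        for j in range(4):
            X = np.column_stack(
                [np.ones(300), ds.calls[:, j], cov.to_numpy()[:, 0]]
            )
            fit = sm.Logit(y.astype(float), X).fit(disp=0)
            assert out["beta"].iloc[j] == pytest.approx(fit.params[1], abs=1e-6)
            assert out["se"].iloc[j] == pytest.approx(fit.bse[1], rel=1e-5)
            assert out["p"].iloc[j] == pytest.approx(fit.pvalues[1], rel=1e-4)

    def test_null_p_uniform_and_signal_detected(self):
        pvals = []
        for seed in range(30):
            ds, cov, _ = self._sim(100 + seed, n=400, s=2)
            out = prs.gwas(ds)
            pvals.extend(out["p"])
        pvals = np.asarray(pvals)
        assert 0.25 < pvals.mean() < 0.75
        assert (pvals < 0.05).mean() < 0.2
        ds, cov, _ = self._sim(7, n=1500, s=3, beta=0.8)
        out = prs.gwas(ds)
        assert out["beta"].iloc[0] > 0
        assert out["p"].iloc[0] < 1e-6

    def test_case_subset_all_equals_wide(self):
        ds, cov, _ = self._sim(1, n=300, s=4, beta=0.4)
        wide = prs.gwas(ds, None, cov.to_numpy(), [0, 1])
        all_cases = set(ds.subject_ids[ds.case_mask()])
        bicl = prs.gwas(ds, all_cases, cov.to_numpy(), [0, 1])
        pd.testing.assert_frame_equal(wide, bicl)

    def test_zero_variance_flagged(self):
        calls = np.column_stack([np.ones(40), np.random.default_rng(0).integers(0, 3, 40)])
        statuses = ["case"] * 20 + ["control"] * 20
        ds = make_dataset(calls, statuses)
        out = prs.gwas(ds)
        assert out["flag"].iloc[0] == "zero_variance"
        assert out["p"].iloc[0] == 1.0
        assert out["beta"].iloc[0] == 0.0

    def test_empty_case_subset_rejected(self):
        ds, *_ = self._sim(2, n=100, s=2)
        with pytest.raises(ValueError, match="no cases"):
            prs.gwas(ds, {"nobody"})


class TestClump:
    def test_independent_snps_all_survive(self):
        rng = np.random.default_rng(3)
        calls = rng.binomial(2, 0.4, (200, 5)).astype(float)
        ds = make_dataset(calls, ["case"] * 100 + ["control"] * 100)
        stats_tbl = prs.gwas(ds)
        surv = prs.clump(stats_tbl, ds, maf_threshold=0.05)
        assert set(surv) == set(ds.snp_ids)

    def test_duplicate_column_within_window_collapses(self):
        rng = np.random.default_rng(4)
        base = rng.binomial(2, 0.4, 200).astype(float)
        other = rng.binomial(2, 0.4, 200).astype(float)
        calls = np.column_stack([base, base, other])
        ds = make_dataset(calls, ["case"] * 100 + ["control"] * 100,
                          pos=[1000, 2000, 900_000])
        stats_tbl = prs.gwas(ds)
        surv = prs.clump(stats_tbl, ds)
        assert len([s for s in surv if s in ("rs0", "rs1")]) == 1
        kept = stats_tbl.set_index("snp_id").loc[surv]
        dup = kept.loc[kept.index.isin(["rs0", "rs1"])]
        assert dup["p"].iloc[0] == min(stats_tbl["p"].iloc[:2])

    def test_duplicate_column_outside_window_survives(self):
        rng = np.random.default_rng(5)
        base = rng.binomial(2, 0.4, 200).astype(float)
        calls = np.column_stack([base, base])
        ds = make_dataset(calls, ["case"] * 100 + ["control"] * 100,
                          pos=[1000, 600_000 + 1000])
        stats_tbl = prs.gwas(ds)
        surv = prs.clump(stats_tbl, ds)
        assert set(surv) == {"rs0", "rs1"}

    def test_maf_filter_applied(self):
        rng = np.random.default_rng(6)
        rare = rng.binomial(2, 0.01, 200).astype(float)
        common = rng.binomial(2, 0.4, 200).astype(float)
        ds = make_dataset(np.column_stack([rare, common]),
                          ["case"] * 100 + ["control"] * 100)
        stats_tbl = prs.gwas(ds)
        surv = prs.clump(stats_tbl, ds, maf_threshold=0.05)
        assert surv == ["rs1"]


class TestScore:
    def test_single_snp_and_linearity(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, (30, 3)).astype(float)
        ds = make_dataset(calls, ["case"] * 15 + ["control"] * 15)
        model = prs.PrsModel(
            snps=pd.DataFrame({"snp_id": ["rs1"], "beta": [1.0], "p": [0.01]}),
            p_threshold=0.05,
        )
        np.testing.assert_allclose(prs.score(ds, model), calls[:, 1])
        model3 = prs.PrsModel(
            snps=pd.DataFrame(
                {"snp_id": ["rs0", "rs1", "rs2"], "beta": [0.5, -1.0, 2.0],
                 "p": [0.01, 0.02, 0.03]}
            ),
            p_threshold=0.05,
        )
        expected = calls @ np.array([0.5, -1.0, 2.0])
        np.testing.assert_allclose(prs.score(ds, model3), expected)
        doubled = prs.PrsModel(
            snps=model3.snps.assign(beta=model3.snps["beta"] * 2),
            p_threshold=0.05,
        )
        np.testing.assert_allclose(prs.score(ds, doubled), 2 * expected)

    def test_empty_after_threshold_rejected(self):
        ds = make_dataset(np.zeros((4, 1)), ["case", "case", "control", "control"])
        model = prs.PrsModel(
            snps=pd.DataFrame({"snp_id": ["rs0"], "beta": [1.0], "p": [0.5]}),
            p_threshold=1e-9,
        )
        with pytest.raises(ValueError, match="empty"):
            prs.score(ds, model)

    def test_missing_calls_use_arm_mean(self):
        calls = np.array([[2.0], [0.0], [np.nan], [0.0]])
        ds = make_dataset(calls, ["case", "case", "control", "control"])
        model = prs.PrsModel(
            snps=pd.DataFrame({"snp_id": ["rs0"], "beta": [1.0], "p": [0.01]}),
            p_threshold=0.05,
        )
        s = prs.score(ds, model)
        assert s[2] == pytest.approx(2 / 3)


class TestLiabilityR2:
    def test_basic_invariants(self):
        assert prs.liability_r2(0.5, 0.02) == 0.0
        aucs = np.linspace(0.501, 0.95, 120)
        vals = np.array([prs.liability_r2(a, 0.02) for a in aucs])
        assert (np.diff(vals) > 0).all()
        assert prs.liability_r2(0.3, 0.01) == pytest.approx(
            prs.liability_r2(0.7, 0.01), abs=1e-9
        )
        with pytest.raises(ValueError):
            prs.liability_r2(0.6, 0.0)

    @pytest.mark.parametrize("prevalence", [0.01, 0.02])
    @pytest.mark.parametrize("true_r2", [0.02, 0.1, 0.25])
    def test_integration_oracle_round_trip(self, prevalence, true_r2):
        auc = threshold_model_auc(np.sqrt(true_r2), prevalence)
        est = prs.liability_r2(auc, prevalence)
        assert est == pytest.approx(true_r2, rel=0.05)


class TestEvaluateAndSweep:
    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal(400)
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(400)],
                "status": rng.permutation(["case"] * 200 + ["control"] * 200),
                "subtype": "unknown",
                "arm_id": "a",
            }
        )
        subjects.loc[subjects["status"] == "control", "subtype"] = "unknown"
        auc, r2 = prs.evaluate(scores, subjects, prevalence=0.02)
        assert auc == pytest.approx(0.5, abs=0.08)
        assert r2 < 0.02

    def test_subtype_restriction_and_errors(self):
        rng = np.random.default_rng(9)
        n = 60
        subjects = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(n)],
                "status": ["case"] * 30 + ["control"] * 30,
                "subtype": ["BDI"] * 20 + ["BDII"] * 10 + ["unknown"] * 30,
                "arm_id": "a",
            }
        )
        scores = np.concatenate([np.full(20, 2.0), np.zeros(10), np.zeros(30)])
        auc_bdi, _ = prs.evaluate(scores, subjects, subtype_filter="BDI", prevalence=0.01)
        assert auc_bdi == 1.0
        auc_bdii, _ = prs.evaluate(scores, subjects, subtype_filter="BDII", prevalence=0.01)
        assert auc_bdii == 0.5
        subjects2 = subjects.copy()
        subjects2.loc[subjects2["subtype"] == "BDII", "subtype"] = "BDI"
        with pytest.raises(ValueError, match="BDII"):
            prs.evaluate(scores, subjects2, subtype_filter="BDII")

    def test_sweep_snp_counts_monotone(self):
        rng = np.random.default_rng(10)
        calls = rng.binomial(2, 0.4, (300, 12)).astype(float)
        y = ["case"] * 150 + ["control"] * 150
        ds = make_dataset(calls, y)
        stats_tbl = prs.gwas(ds)
        surv = prs.clump(stats_tbl, ds)
        ev = prs.threshold_sweep(
            {"wide": stats_tbl}, {"wide": surv}, ds, [1e-4, 0.05, 0.5, 1.0]
        )
        counts = ev.curve["n_snps"].to_numpy()
        assert (np.diff(counts) >= 0).all()
        assert counts[-1] == len(surv)
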