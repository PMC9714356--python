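"""The SNP x CpG regression scan: single-pair OLS, the vectorized path,
per-SNP Benjamini-Hochberg screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meqtlscan.containers import (
    DataError, GenotypeMatrix, MethylationMatrix, SampleTable,
)
from meqtlscan.scan import (
    STATUS_COLLINEAR, STATUS_CONSTANT_DOSAGE, STATUS_LOW_N, STATUS_OK,
    STATUS_ZERO_VARIANCE, attempted_pairs, fit_pair, per_snp_fdr, scan,
)
from _oracles import ols_normal_equations_oracle


class TestFitPair:
    def test_exact_linear_relationship(self):
        res = fit_pair(
            [0.10, 0.10, 0.20, 0.20, 0.30, 0.30],
            [0, 0, 1, 1, 2, 2],
            [40, 50, 40, 50, 40, 50],
        )
        assert res["beta_hat"] == pytest.approx(0.1, abs=1e-12)
        assert res["se"] == pytest.approx(0.0, abs=1e-7)
        assert res["status"] == STATUS_OK

    def test_constant_methylation_is_flagged_degenerate(self):
        res = fit_pair([0.5] * 8, [0, 1, 2, 0, 1, 2, 0, 1],
                       [40, 45, 50, 55, 60, 65, 70, 75])
        assert res["beta_hat"] == 0.0
        assert res["p_value"] == 1.0
        assert res["status"] == STATUS_ZERO_VARIANCE

    def test_low_n_after_pairwise_dropping(self):
        res = fit_pair([0.1, 0.2, np.nan, np.nan, np.nan],
                       [0, 1, 2, np.nan, 1], [40, 50, 60, 70, 80])
        assert res["status"] == STATUS_LOW_N
        assert res["n_used"] == 2

    def test_constant_dosage_is_flagged(self):
        res = fit_pair([0.1, 0.2, 0.3, 0.4, 0.5], [1, 1, 1, 1, 1],
                       [40, 45, 50, 55, 60])
        assert res["status"] == STATUS_CONSTANT_DOSAGE

    def test_dosage_collinear_with_age_is_flagged(self):
        res = fit_pair([0.1, 0.2, 0.3, 0.4], [0, 1, 2, 0],
                       [10, 20, 30, 10])  # age = 10 * (dosage + 1)
        assert res["status"] == STATUS_COLLINEAR

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        g = rng.integers(0, 3, n).astype(float)
        if np.ptp(g) == 0:
            g[0] = (g[0] + 1) % 3
        a = rng.uniform(20, 80, n)
        y = rng.uniform(0, 1, n)
        res = fit_pair(y, g, a)
        beta, se, t, p = ols_normal_equations_oracle(y, g, a)
        assert res["beta_hat"] == pytest.approx(beta, abs=1e-10)
        assert res["se"] == pytest.approx(se, abs=1e-10)
        assert res["t_stat"] == pytest.approx(t, abs=1e-8)
        assert res["p_value"] == pytest.approx(p, abs=1e-10)


def _build_inputs(rng, n_snps=5, n_cpgs=20, n=60, meth_missing=0.05):
    samples = pd.Index([f"S{i}" for i in range(n)])
    g = rng.integers(0, 3, (n_snps, n)).astype(float)
    g[rng.random((n_snps, n)) < 0.05] = np.nan
    m = rng.uniform(0, 1, (n_cpgs, n))
    m[rng.random((n_cpgs, n)) < meth_missing] = np.nan
    geno = GenotypeMatrix(
        codes=pd.DataFrame(g, index=[f"snp{i}" for i in range(n_snps)],
                           columns=samples)
    )
    meth = MethylationMatrix(
        values=pd.DataFrame(m, index=[f"cg{i}" for i in range(n_cpgs)],
                            columns=samples)
    )
    table = SampleTable(pd.DataFrame(
        {"group": np.where(rng.random(n) < 0.5, "case", "control"),
         "age": rng.uniform(20, 80, n)}, index=samples))
    return meth, geno, table


class TestScan:
    def test_record_count_is_the_pair_product(self):
        rng = np.random.default_rng(0)
        meth, geno, table = _build_inputs(rng, n_snps=2, n_cpgs=3)
        rec = scan(meth, geno, table)
        assert len(rec) == 6
        assert attempted_pairs(62, 485_512) == 30_101_744

    def test_vectorized_scan_equals_per_pair_fits(self):
        """The vectorized normal-equations path must reproduce the
        statsmodels per-pair fit to 1e-10, missing data included."""
        rng = np.random.default_rng(1)
        meth, geno, table = _build_inputs(rng, n_snps=5, n_cpgs=20)
        rec = scan(meth, geno, table).set_index(["snp_id", "cpg_id"])
        age = table.table["age"]
        for snp_id in geno.snp_ids:
            for cpg_id in meth.cpg_ids:
                ref = fit_pair(meth.values.loc[cpg_id], geno.codes.loc[snp_id],
                               age)
                got = rec.loc[(snp_id, cpg_id)]
                assert got["status"] == ref["status"]
                if ref["status"] == STATUS_OK:
                    assert got["beta_hat"] == pytest.approx(ref["beta_hat"],
                                                            abs=1e-10)
                    assert got["se"] == pytest.approx(ref["se"], abs=1e-10)
                    assert got["p_value"] == pytest.approx(ref["p_value"],
                                                           abs=1e-10)
                    assert got["n_used"] == ref["n_used"]

    def test_sample_permutation_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(2)
        meth, geno, table = _build_inputs(rng, meth_missing=0.0)
        rec = scan(meth, geno, table)
        perm = rng.permutation(meth.sample_ids)
        meth2 = MethylationMatrix(values=meth.values[perm])
        geno2 = GenotypeMatrix(codes=geno.codes[perm])
        table2 = SampleTable(table.table.loc[perm])
        rec2 = scan(meth2, geno2, table2)
        pd.testing.assert_frame_equal(rec, rec2)

    def test_no_shared_samples_is_an_alignment_error(self):
        rng = np.random.default_rng(3)
        meth, geno, table = _build_inputs(rng)
        meth_renamed = MethylationMatrix(
            values=meth.values.rename(columns=lambda c: c + "_other"))
        with pytest.raises(DataError, match="shared"):
            scan(meth_renamed, geno, table)

    def test_stratum_restricts_n_used(self):
        rng = np.random.default_rng(4)
        meth, geno, table = _build_inputs(rng, meth_missing=0.0)
        rec = scan(meth, geno, table, stratum="case")
        n_case = (table.table["group"] == "case").sum()
        assert (rec["n_used"] <= n_case).all()
        assert (rec["stratum"] == "case").all()


class TestPerSnpFdr:
    @staticmethod
    def _records(pvals, snp="snp1"):
        return pd.DataFrame({
            "snp_id": snp, "cpg_id": [f"cg{i}" for i in range(len(pvals))],
            "stratum": "all", "beta_hat": 0.1, "se": 0.1, "t_stat": 1.0,
            "p_value": pvals, "q_value": np.nan, "n_used": 10,
            "status": STATUS_OK,
        })

    def test_single_test_bh_is_identity(self):
        out = per_snp_fdr(self._records([0.03]), alpha=0.05)
        assert out["q_value"].iloc[0] == pytest.approx(0.03)
        assert out["significant"].iloc[0]

    def test_step_up_with_monotonization(self):
        # BH by definition: q_i = min over j >= i of m * p_(j) / j
        out = per_snp_fdr(self._records([0.001, 0.01, 0.02, 0.8]))
        np.testing.assert_allclose(
            out["q_value"], [0.004, 0.02, 0.08 / 3, 0.8], atol=1e-12
        )

    def test_all_p_one_yields_no_discoveries(self):
        out = per_snp_fdr(self._records([1.0] * 5))
        assert not out["significant"].any()

    def test_families_are_per_snp(self):
        a = self._records([0.001] + [1.0] * 9, snp="snpA")
        b = self._records([0.04] + [0.5] * 9, snp="snpB")
        out = per_snp_fdr(pd.concat([a, b], ignore_index=True))
        qa = out.loc[out["snp_id"] == "snpA", "q_value"].iloc[0]
        assert qa == pytest.approx(0.01)  # m=10 within snpA only
        qb = out.loc[out["snp_id"] == "snpB", "q_value"].iloc[0]
        assert qb == pytest.approx(0.4)

    def test_global_scope_pools_families(self):
        a = self._records([0.001] + [1.0] * 9, snp="snpA")
        b = self._records([0.04] + [0.5] * 9, snp="snpB")
        out = per_snp_fdr(pd.concat([a, b], ignore_index=True), scope="global")
        qa = out.loc[out["snp_id"] == "snpA", "q_value"].iloc[0]
        assert qa == pytest.approx(0.02)  # m=20 pooled

    def test_flagged_records_are_excluded_from_the_family(self):
        rec = self._records([0.01, 0.02, 0.03])
        rec.loc[2, "status"] = STATUS_CONSTANT_DOSAGE
        rec.loc[2, "p_value"] = np.nan
        out = per_snp_fdr(rec)
        assert np.isnan(out.loc[2, "q_value"])
        assert out.loc[0, "q_value"] == pytest.approx(0.02)  # m=2, not 3

    def test_adjusted_values_monotone_in_sorted_p(self):
        rng = np.random.default_rng(5)
        out = per_snp_fdr(self._records(rng.uniform(0, 1, 50)))
        ordered = out.sort_values("p_value")["q_value"].to_numpy()
        assert (np.diff(ordered) >= -1e-15).all()
        assert ((out["q_value"] >= out["p_value"]) | out["q_value"].isna()).all()
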