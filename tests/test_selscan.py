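from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lownsel import (
    SimConfig,
    favorable_alleles,
    nfa_lnae_association,
    nfa_scores,
    outlier_scan,
    simulate_genotypes,
    theta_wc,
    wc_fst,
)
from lownsel.genio import MISSING
from lownsel.selscan import SelscanError


def theta_reference(n1, n2, p1, p2):
    """Step-by-step two-population haploid theta, written independently
    of the vectorized estimator."""
    r = 2
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    t1 = s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1)
    t2 = pbar * (1 - pbar) * (nc - 1) / (nbar - 1) + (
        1 + (r - 1) * (nbar - nc) / (nbar - 1)
    ) * s2 / r
    return t1 / t2


class TestThetaEstimator:
    def test_published_contrast_values(self):
        """The 29-vs-35-line contrast at the two strongest reported
        frequency pairs rounds to the published theta values."""
        assert round(theta_wc([29, 35], [0.43, 0.03]), 2) == 0.37
        assert round(theta_wc([29, 35], [0.33, 0.03]), 2) == 0.26

    def test_matches_independent_formula_on_random_inputs(self):
        rng = np.random.default_rng(37)
        for _ in range(100):
            n1, n2 = rng.integers(2, 200, size=2)
            p1, p2 = rng.random(2)
            got = theta_wc([n1, n2], [p1, p2])
            expect = theta_reference(n1, n2, p1, p2)
            assert got == pytest.approx(expect, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        n1=st.integers(2, 500), n2=st.integers(2, 500),
        k1=st.integers(0, 256), k2=st.integers(0, 256),
    )
    def test_invariant_to_allele_relabelling(self, n1, n2, k1, k2):
        # dyadic frequencies so that 1-p is exact in floating point
        p1, p2 = k1 / 256, k2 / 256
        a = theta_wc([n1, n2], [p1, p2])
        b = theta_wc([n1, n2], [1 - p1, 1 - p2])
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-12)

    def test_no_differentiation_is_nonpositive(self):
        for p in (0.1, 0.3, 0.5):
            assert theta_wc([40, 40], [p, p]) <= 0

    def test_complete_fixation_approaches_one(self):
        assert theta_wc([5000, 5000], [1.0, 0.0]) == pytest.approx(1.0, abs=1e-3)

    def test_monomorphic_undefined(self):
        assert np.isnan(theta_wc([30, 30], [0.0, 0.0]))
        assert np.isnan(theta_wc([30, 30], [1.0, 1.0]))

    def test_input_validation(self):
        with pytest.raises(SelscanError):
            theta_wc([29], [0.4])
        with pytest.raises(SelscanError):
            theta_wc([29, 35], [1.2, 0.3])
        with pytest.raises(SelscanError):
            theta_wc([1, 35], [0.4, 0.3])


@pytest.fixture(scope="module")
def scanned_panel():
    cfg = SimConfig(n_snps=400, n_selected_loci=4, missing_rate=0.03, seed=101)
    geno, truth = simulate_genotypes(cfg)
    fst = wc_fst(geno, truth.group_labels, high="H")
    return geno, truth, fst


class TestWcFst:
    def test_matches_per_marker_reference(self, scanned_panel):
        geno, truth, fst = scanned_panel
        hi = truth.group_labels == "H"
        rng = np.random.default_rng(0)
        for j in rng.choice(geno.n_markers, 40, replace=False):
            col = geno.calls[:, j]
            row = fst.iloc[j]
            n1 = int(((col != MISSING) & hi.to_numpy()).sum())
            n2 = int(((col != MISSING) & ~hi.to_numpy()).sum())
            p1 = (col[hi.to_numpy()] == 2).sum() / n1
            p2 = (col[~hi.to_numpy()] == 2).sum() / n2
            expect = theta_reference(n1, n2, p1, p2)
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            if pbar in (0.0, 1.0):
                assert np.isnan(row["fst"])
            else:
                assert row["fst"] == pytest.approx(expect, abs=1e-12)
            assert (row["n_high"], row["n_low"]) == (n1, n2)

    def test_more_than_two_groups_rejected(self, scanned_panel):
        geno, truth, _ = scanned_panel
        labels = truth.group_labels.copy()
        labels.iloc[0] = "M"
        with pytest.raises(SelscanError, match="two groups"):
            wc_fst(geno, labels, high="H")

    def test_insufficient_group_flagged(self, make_geno):
        calls = np.array([[2, MISSING], [0, MISSING], [0, 2], [2, 0], [0, 0], [2, 2]])
        labels = pd.Series(["H", "H", "L", "L", "L", "L"],
                           index=[f"L{i + 1}" for i in range(6)])
        fst = wc_fst(make_geno(calls), labels, high="H")
        assert fst.loc[1, "flag"] == "insufficient"
        assert np.isnan(fst.loc[1, "fst"])

    def test_clamp_negative_option(self, scanned_panel):
        geno, truth, fst = scanned_panel
        clamped = wc_fst(geno, truth.group_labels, high="H", clamp_negative=True)
        ok = clamped["fst"].notna()
        assert (clamped.loc[ok, "fst"] >= 0).all()
        assert (fst["fst"].dropna() < 0).any()  # raw estimates do go negative


class TestOutlierScan:
    def test_strict_threshold_boundary(self):
        fst = pd.DataFrame(
            {"marker": ["a", "b", "c"], "chrom": ["1"] * 3, "pos": [1, 2, 3],
             "fst": [0.19, 0.20, 0.21]}
        )
        out, _ = outlier_scan(fst, threshold=0.2)
        assert out["marker"].tolist() == ["c"]

    def test_sorted_by_position_and_mean_reported(self, scanned_panel):
        _, _, fst = scanned_panel
        out, mean_fst = outlier_scan(fst, 0.2)
        assert mean_fst == pytest.approx(fst["fst"].dropna().mean())
        key = list(zip(out["chrom"], out["pos"]))
        assert key == sorted(key)

    def test_all_undefined_warns_empty(self):
        fst = pd.DataFrame({"marker": ["a"], "chrom": ["1"], "pos": [1],
                            "fst": [np.nan]})
        with pytest.warns(UserWarning, match="defined"):
            out, mean_fst = outlier_scan(fst)
        assert out.empty and np.isnan(mean_fst)


class TestFavorableAlleles:
    def test_planted_loci_report_planted_allele(self, scanned_panel):
        geno, truth, fst = scanned_panel
        out, _ = outlier_scan(fst, 0.2)
        fav = favorable_alleles(geno, truth.group_labels, out, high="H")
        planted = truth.selected.set_index("marker")
        for _, row in fav.iterrows():
            if row["marker"] in planted.index:
                assert row["favorable_allele"] == planted.loc[row["marker"], "favorable_allele"]
                assert row["ffa_high"] > row["ffa_low"]

    def test_fixed_contrast(self, make_geno):
        calls = np.array([[2], [2], [0], [0]])
        labels = pd.Series(["H", "H", "L", "L"], index=[f"L{i + 1}" for i in range(4)])
        g = make_geno(calls)
        fst = wc_fst(g, labels, high="H")
        fav = favorable_alleles(g, labels, fst, high="H")
        assert fav.loc[0, "favorable_allele"] == "G"
        assert (fav.loc[0, "ffa_high"], fav.loc[0, "ffa_low"]) == (1.0, 0.0)

    def test_matches_brute_force_recount(self, scanned_panel):
        geno, truth, fst = scanned_panel
        out, _ = outlier_scan(fst, 0.2)
        fav = favorable_alleles(geno, truth.group_labels, out, high="H")
        hi = (truth.group_labels == "H").to_numpy()
        for _, row in fav.iterrows():
            j = geno.marker_ids.index(row["marker"])
            col = geno.calls[:, j]
            is_alt = row["favorable_allele"] == geno.marker_map.iloc[j]["alt"]
            want = 2 if is_alt else 0
            for rows_mask, key in ((hi, "ffa_high"), (~hi, "ffa_low")):
                called = (col != MISSING) & rows_mask
                assert row[key] == pytest.approx((col[called] == want).mean())

    def test_exact_tie_excluded_with_warning(self, make_geno):
        calls = np.array([[2], [0], [2], [0]])
        labels = pd.Series(["H", "H", "L", "L"], index=[f"L{i + 1}" for i in range(4)])
        g = make_geno(calls)
        fst = wc_fst(g, labels, high="H")
        with pytest.warns(UserWarning, match="tied"):
            fav = favorable_alleles(g, labels, fst, high="H")
        assert fav.empty


class TestNfaScores:
    def test_full_carrier_counts_all(self, make_geno):
        calls = np.array([[2, 2, 2], [0, 0, 0], [2, 0, 2], [0, 0, 2]])
        labels = pd.Series(["H", "H", "L", "L"], index=[f"L{i + 1}" for i in range(4)])
        g = make_geno(calls)
        fav = pd.DataFrame(
            {"marker": ["M1", "M2", "M3"], "favorable_allele": ["G", "G", "G"]}
        )
        nfa = nfa_scores(g, fav).set_index("line")["nfa"]
        assert nfa.tolist() == [3, 0, 2, 1]

    def test_missing_counts_zero_by_default(self, make_geno):
        g = make_geno([[MISSING, MISSING], [2, 2]])
        fav = pd.DataFrame({"marker": ["M1", "M2"], "favorable_allele": ["G", "G"]})
        nfa = nfa_scores(g, fav)
        assert nfa["nfa"].tolist() == [0, 2]
        scaled = nfa_scores(g, fav, missing_policy="scale")
        assert scaled["nfa"].tolist() == [0.0, 2.0]

    def test_scale_policy_rescales_by_completeness(self, make_geno):
        g = make_geno([[2, MISSING], [2, 0]])
        fav = pd.DataFrame({"marker": ["M1", "M2"], "favorable_allele": ["G", "G"]})
        scaled = nfa_scores(g, fav, missing_policy="scale")
        assert scaled["nfa"].tolist() == [2.0, 1.0]

    def test_matches_planted_truth_without_missingness(self, clean_panel):
        geno, truth, _ = clean_panel
        fav = truth.selected.rename(columns={"favorable_allele": "favorable_allele"})
        nfa = nfa_scores(geno, fav[["marker", "favorable_allele"]])
        assert np.array_equal(
            nfa.set_index("line")["nfa"].loc[truth.true_nfa.index].to_numpy(),
            truth.true_nfa.to_numpy(),
        )


class TestAssociation:
    def test_exact_linear_relation(self):
        nfa = pd.DataFrame({"line": list("abcde"), "nfa": [0, 1, 2, 3, 4]})
        lnae = pd.Series([100.0, 150.0, 200.0, 250.0, 300.0], index=list("abcde"))
        a = nfa_lnae_association(nfa, lnae)
        assert a.pearson_r == pytest.approx(1.0)
        assert a.r_squared == pytest.approx(1.0)
        assert a.slope == pytest.approx(50.0)
        assert a.intercept == pytest.approx(100.0)

    def test_r_squared_identity(self):
        rng = np.random.default_rng(41)
        nfa = pd.DataFrame({"line": [f"L{i}" for i in range(30)],
                            "nfa": rng.integers(0, 10, 30)})
        lnae = pd.Series(rng.normal(2000, 400, 30), index=nfa["line"])
        a = nfa_lnae_association(nfa, lnae)
        assert a.r_squared == pytest.approx(a.pearson_r**2, abs=1e-12)

    def test_constant_nfa_rejected(self):
        nfa = pd.DataFrame({"line": list("abc"), "nfa": [2, 2, 2]})
        lnae = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(SelscanError, match="zero variance"):
            nfa_lnae_association(nfa, lnae)

    def test_too_few_lines_rejected(self):
        nfa = pd.DataFrame({"line": ["a", "b"], "nfa": [1, 2]})
        lnae = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(SelscanError, match=">= 3"):
            nfa_lnae_association(nfa, lnae)
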