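"""Candidate ladder, correlation pruning, conditional scan, classification."""

import numpy as np
import pandas as pd
import pytest

from admixscan import (
    AdmixtureMixedModel,
    LadderSpec,
    candidate_ladder,
    classify_explained,
    conditional_scan,
    group_eaf,
    prune_by_correlation,
    scan_ancestry,
)
from admixscan.simulate import GenotypeMatrix

from conftest import two_ancestry_cohort


def make_gm(dosages: dict) -> GenotypeMatrix:
    names = list(dosages)
    D = np.column_stack([dosages[n] for n in names])
    variants = pd.DataFrame(
        {"name": names, "chrom": "1", "position": np.arange(len(names)) * 1000,
         "a1": "A", "a2": "G", "typed": True, "info": 1.0}
    )
    return GenotypeMatrix(dosages=D, variants=variants, sample_ids=[f"s{i}" for i in range(D.shape[0])])


def assoc_frame(rows):
    return pd.DataFrame(rows, columns=["variant", "position", "p_overall"])


def eaf_frame(d):
    return pd.DataFrame(d, index=["eaf"]).T.rename(columns={"eaf": "high"}).assign(
        low=lambda df: df["high"] * 0  # overwritten below where needed
    )


class TestGroupEaf:
    def test_homozygous_group_gives_one(self):
        gm = make_gm({"v": np.array([2.0, 2.0, 0.0])})
        out = group_eaf(gm, ["A", "A", "B"])
        assert out.loc["v", "A"] == 1.0
        assert out.loc["v", "B"] == 0.0

    def test_group_eaf_difference(self):
        # High-ancestry group EAF 0.57, low 0.35: difference 0.22.
        rng = np.random.default_rng(0)
        g_mex = rng.binomial(2, 0.57, 5000).astype(float)
        g_cub = rng.binomial(2, 0.35, 5000).astype(float)
        gm = make_gm({"v": np.concatenate([g_mex, g_cub])})
        out = group_eaf(gm, ["Mexican"] * 5000 + ["Cuban"] * 5000)
        delta = out.loc["v", "Mexican"] - out.loc["v", "Cuban"]
        assert delta == pytest.approx(0.22, abs=0.03)

    def test_delta_invariant_under_allele_flip_up_to_sign(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 200).astype(float)
        labels = ["A"] * 100 + ["B"] * 100
        d1 = group_eaf(make_gm({"v": g}), labels)
        d2 = group_eaf(make_gm({"v": 2.0 - g}), labels)
        delta1 = d1.loc["v", "A"] - d1.loc["v", "B"]
        delta2 = d2.loc["v", "A"] - d2.loc["v", "B"]
        assert delta2 == pytest.approx(-delta1, abs=1e-12)


class TestLadder:
    def _eafs(self, entries):
        return pd.DataFrame(entries, index=["Mexican", "Cuban"]).T

    def test_low_p_admitted_regardless_of_eaf(self):
        assoc = assoc_frame([("v1", 100, 5e-7)])
        eafs = self._eafs({"v1": (0.5, 0.5)})
        out = candidate_ladder(assoc, None, eafs)
        assert list(out["variant"]) == ["v1"]
        assert out["rung"].iloc[0] == 1e-6

    def test_lenient_rung_requires_eaf_difference(self):
        assoc = assoc_frame([("big_delta", 100, 2e-3), ("small_delta", 200, 2e-3)])
        eafs = self._eafs({"big_delta": (0.57, 0.35), "small_delta": (0.40, 0.35)})
        out = candidate_ladder(assoc, None, eafs)
        assert list(out["variant"]) == ["big_delta"]
        assert out["min_delta_eaf"].iloc[0] == pytest.approx(0.2)

    def test_no_qualifying_variant_gives_empty(self):
        # Even the most lenient rule (p < 1e-2, delta >= 0.05) admits nothing.
        assoc = assoc_frame([("v1", 100, 0.5), ("v2", 200, 5e-3)])
        eafs = self._eafs({"v1": (0.5, 0.2), "v2": (0.50, 0.48)})
        out = candidate_ladder(assoc, None, eafs)
        assert len(out) == 0

    def test_stops_at_first_non_empty_step(self):
        assoc = assoc_frame([("early", 100, 5e-6), ("late", 200, 5e-3)])
        eafs = self._eafs({"early": (0.5, 0.5), "late": (0.9, 0.1)})
        out = candidate_ladder(assoc, None, eafs)
        assert list(out["variant"]) == ["early"]
        both = candidate_ladder(assoc, None, eafs, accumulate=True)
        assert set(both["variant"]) == {"early", "late"}

    def test_region_restriction(self):
        assoc = assoc_frame([("inside", 100, 5e-7), ("outside", 10_000, 1e-8)])
        eafs = self._eafs({"inside": (0.5, 0.5), "outside": (0.5, 0.5)})
        out = candidate_ladder(assoc, (0, 1000), eafs)
        assert list(out["variant"]) == ["inside"]

    def test_empty_region_warns(self):
        assoc = assoc_frame([("v", 100, 1e-8)])
        eafs = self._eafs({"v": (0.5, 0.5)})
        with pytest.warns(UserWarning):
            out = candidate_ladder(assoc, (5000, 6000), eafs)
        assert len(out) == 0

    def test_any_of_three_analyses_qualifies(self):
        assoc = pd.DataFrame(
            {"variant": ["v"], "position": [100], "p_overall": [0.28], "p_mainland": [3.84e-5], "p_caribbean": [0.6]}
        )
        eafs = self._eafs({"v": (0.98, 0.96)})
        out = candidate_ladder(assoc, None, eafs)
        assert list(out["variant"]) == ["v"]
        assert out["admitting_analysis"].iloc[0] == "mainland"

    def test_monotonicity_tightening_never_adds(self):
        rng = np.random.default_rng(2)
        assoc = assoc_frame([(f"v{i}", i * 10, float(10 ** rng.uniform(-7, -1))) for i in range(30)])
        eafs = self._eafs({f"v{i}": (rng.uniform(0, 1), rng.uniform(0, 1)) for i in range(30)})
        loose = LadderSpec()
        tight = LadderSpec(p_rungs=(1e-7, 1e-6, 1e-5, 1e-4, 1e-3), eaf_relaxation=(0.3, 0.25, 0.2, 0.15))
        got_loose = set(candidate_ladder(assoc, None, eafs, loose, accumulate=True)["variant"])
        got_tight = set(candidate_ladder(assoc, None, eafs, tight, accumulate=True)["variant"])
        assert got_tight <= got_loose

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            LadderSpec(p_rungs=(1e-2, 1e-6))
        with pytest.raises(ValueError):
            LadderSpec(eaf_relaxation=(0.05, 0.2))


class TestPruning:
    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, 500).astype(float)
        gm = make_gm({"a": g, "b": g})
        cands = pd.DataFrame({"variant": ["a", "b"], "position": [0, 1000], "p_min": [1e-5, 1e-4]})
        out = prune_by_correlation(cands, gm)
        assert out.loc[out["lead"], "variant"].tolist() == ["a"]

    def test_uncorrelated_pair_both_lead(self):
        rng = np.random.default_rng(4)
        gm = make_gm({"a": rng.integers(0, 3, 500).astype(float), "b": rng.integers(0, 3, 500).astype(float)})
        cands = pd.DataFrame({"variant": ["a", "b"], "position": [0, 1000], "p_min": [1e-5, 1e-4]})
        out = prune_by_correlation(cands, gm)
        assert out["lead"].all()

    def test_chain_forms_single_component(self):
        # |r(A,B)| and |r(B,C)| > 0.4 but |r(A,C)| small: single-linkage
        # gives one component and one lead.
        rng = np.random.default_rng(5)
        n = 2000
        b = rng.standard_normal(n)
        a = 0.7 * b + np.sqrt(1 - 0.49) * rng.standard_normal(n)
        c = 0.7 * b + np.sqrt(1 - 0.49) * rng.standard_normal(n) - 0.49 * a * 0
        # orthogonalize c against a to push |r(A,C)| low
        c = c - np.polyfit(a, c, 1)[0] * a * 0.9
        gm = make_gm({"A": a, "B": b, "C": c})
        R = np.corrcoef(np.column_stack([a, b, c]), rowvar=False)
        assert abs(R[0, 1]) > 0.4 and abs(R[1, 2]) > 0.4 and abs(R[0, 2]) < 0.4
        cands = pd.DataFrame({"variant": ["A", "B", "C"], "position": [0, 1, 2], "p_min": [1e-4, 1e-5, 1e-3]})
        out = prune_by_correlation(cands, gm)
        assert out["component"].nunique() == 1
        assert out.loc[out["lead"], "variant"].tolist() == ["B"]

    def test_zero_variance_dosage_unlinked(self):
        rng = np.random.default_rng(6)
        gm = make_gm({"flat": np.zeros(100), "var": rng.integers(0, 3, 100).astype(float)})
        cands = pd.DataFrame({"variant": ["flat", "var"], "position": [0, 1], "p_min": [1e-3, 1e-4]})
        out = prune_by_correlation(cands, gm)
        assert out["lead"].all()

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, 300).astype(float)
        h = rng.integers(0, 3, 300).astype(float)
        gm = make_gm({"a": g, "b": g, "c": h})
        cands = pd.DataFrame({"variant": ["a", "b", "c"], "position": [0, 1, 2], "p_min": [1e-4, 1e-5, 1e-3]})
        lead1 = set(prune_by_correlation(cands, gm).query("lead")["variant"])
        lead2 = set(prune_by_correlation(cands.iloc[::-1], gm).query("lead")["variant"])
        assert lead1 == lead2


@pytest.fixture(scope="module")
def cohort_and_null():
    cohort = two_ancestry_cohort(n=1500, beta=6.0, p1=0.5, p2=0.1, sigma2=25.0, seed=8)
    model = AdmixtureMixedModel.from_dataframe(
        cohort.phenotypes, "sbp_mean", ["age", "sex"], kinship=None, household=None, block=None
    )
    return cohort, model.fit()


class TestConditionalScan:
    def test_conditioning_on_causal_attenuates_signal(self, cohort_and_null):
        cohort, null = cohort_and_null
        j = cohort.la.interval_of(cohort.truth["causal"][0]["position"])
        d = cohort.genotypes.dosage("rs1")
        out = conditional_scan(cohort.la, "Anc1", d, null)
        assert out.iloc[j]["p_conditional"] > out.iloc[j]["p_primary"]
        assert out.iloc[j]["p_conditional"] > 0.01

    def test_conditioning_on_null_variant_is_noop_on_average(self, cohort_and_null):
        cohort, null = cohort_and_null
        d = cohort.genotypes.dosage(cohort.genotypes.variants["name"].iloc[1])
        out = conditional_scan(cohort.la, "Anc1", d, null)
        shift = (np.log10(out["p_conditional"]) - np.log10(out["p_primary"])).abs()
        assert shift.median() < 0.5

    def test_all_zero_dosage_gives_identical_scan(self, cohort_and_null):
        cohort, null = cohort_and_null
        with pytest.warns(UserWarning, match="collinear"):
            out = conditional_scan(cohort.la, "Anc1", np.zeros(null.nobs), null)
        assert np.allclose(out["p_primary"], out["p_conditional"], rtol=1e-10, equal_nan=True)
        assert out.attrs["dropped"] == ["cond0"]

    def test_row_alignment(self, cohort_and_null):
        cohort, null = cohort_and_null
        d = cohort.genotypes.dosage("rs1")
        out = conditional_scan(cohort.la, "Anc1", d, null)
        assert len(out) == cohort.la.n_intervals
        assert (out["start"] == cohort.la.intervals["start"]).all()


class TestClassification:
    @pytest.mark.parametrize(
        "p_primary,p_conditional,expected",
        [
            (2.29e-5, 0.003, "partial"),
            (4.67e-5, 0.002, "partial"),
            (1e-6, 0.5, "full"),
            (1e-6, 1e-6, "none"),
        ],
    )
    def test_examples(self, p_primary, p_conditional, expected):
        assert classify_explained(p_primary, p_conditional) == expected

    def test_requires_significant_primary(self):
        with pytest.raises(ValueError):
            classify_explained(1e-3, 0.5)
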