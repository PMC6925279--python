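"""Statistical layer: chi-square oracle, Hardy-Weinberg ploidy math,
stepwise model selection, subsampled content, burst test."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_hyp

from polyte import popstats
from polyte.popstats import (burst_family_test, build_content_table,
                             chi2_2x2, fit_stepwise_mlm, hw_convert,
                             subsampled_content)


def chi2_closed_form(a, b, c, d):
    """Independent oracle: N(ad-bc)^2 / (r1*r2*c1*c2)."""
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestChi2:
    def test_identical_proportions_give_zero(self):
        stat, p = chi2_2x2(10, 90, 10, 90)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_known_table(self):
        stat, _p = chi2_2x2(10, 90, 20, 80)
        assert stat == pytest.approx(chi2_closed_form(10, 90, 20, 80))
        assert stat == pytest.approx(3.9216, abs=1e-3)

    def test_extreme_table(self):
        stat, p = chi2_2x2(0, 100, 100, 0)
        assert stat == pytest.approx(200.0)
        assert p < 1e-40

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat, _ = chi2_2x2(int(a), int(b), int(c), int(d))
            assert abs(stat - chi2_closed_form(a, b, c, d)) < 1e-10

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi2_2x2(0, 0, 10, 20)


class TestHardyWeinberg:
    def test_published_diploid_conversion(self):
        # carrier frequency 12.2% in diploids -> allele frequency 6.3%
        res = hw_convert(f=0.122, ploidy=2)
        assert res.p == pytest.approx(0.063, abs=5e-4)

    def test_tetraploid_conversion(self):
        res = hw_convert(f=0.122, ploidy=4)
        assert res.p == pytest.approx(1 - 0.878 ** 0.25, abs=1e-12)
        assert res.p == pytest.approx(0.0320, abs=5e-4)

    def test_equal_carrier_fraction_across_ploidies(self):
        # p=0.063 at ploidy 2 and p=0.032 at ploidy 4 both give f ~ 0.122
        assert popstats.allele_to_carrier(0.063, 2) == \
            pytest.approx(0.122, abs=1e-3)
        assert popstats.allele_to_carrier(0.032, 4) == \
            pytest.approx(0.122, abs=2e-3)

    def test_zero_frequency(self):
        res = hw_convert(f=0.0, ploidy=4)
        assert res.p == 0.0
        assert res.dosage_probs[0] == pytest.approx(1.0)

    def test_dosage1_fraction_matches_enumeration(self):
        p = 0.063
        res = hw_convert(p=p, ploidy=2)
        # enumeration over genotype classes
        probs = [math.comb(2, d) * p ** d * (1 - p) ** (2 - d)
                 for d in range(3)]
        expected = probs[1] / (1 - probs[0])
        assert res.dosage1_carrier_fraction == pytest.approx(expected,
                                                             abs=1e-12)
        assert expected == pytest.approx(0.968, abs=1e-3)

    @given(f=st_hyp.floats(min_value=0.0, max_value=0.99),
           ploidy=st_hyp.sampled_from([2, 4]))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, f, ploidy):
        res = hw_convert(f=f, ploidy=ploidy)
        back = popstats.allele_to_carrier(res.p, ploidy)
        assert abs(back - f) < 1e-12
        assert abs(res.dosage_probs.sum() - 1) < 1e-9

    def test_dosage1_fraction_monotone_decreasing_in_p(self):
        for ploidy in (2, 4):
            ps = np.linspace(1e-4, 0.95, 60)
            fracs = [hw_convert(p=float(p), ploidy=ploidy)
                     .dosage1_carrier_fraction for p in ps]
            assert fracs[0] > 0.999
            assert all(x > y for x, y in zip(fracs, fracs[1:]))

    def test_monomorphic_and_invalid_inputs(self):
        assert hw_convert(f=1.0, ploidy=2).monomorphic
        with pytest.raises(ValueError):
            hw_convert(f=0.5, p=0.5, ploidy=2)
        with pytest.raises(ValueError):
            hw_convert(f=1.5, ploidy=2)
        with pytest.raises(ValueError):
            hw_convert(f=0.5, ploidy=3)


def _content_table(rng, n=200, beta_cov=5.0, interaction=0.0, noise=1.0):
    """Synthetic content table with known generating coefficients."""
    rows = []
    for i in range(n):
        ploidy = 2 if i % 2 == 0 else 4
        hc = float(rng.uniform(1, 9))
        for cat in ("non-genic", "introns+UTRs", "exonic"):
            y = 10 + beta_cov * hc + float(rng.normal(0, noise))
            if interaction and ploidy == 4 and cat == "exonic":
                y += interaction
            rows.append((f"i{i}", ploidy, hc, cat, "LF", y))
    return pd.DataFrame(rows, columns=["id", "ploidy", "haplo_coverage",
                                       "category_group", "freq_class",
                                       "count"])


class TestStepwiseMLM:
    def test_full_model_recovered_when_alphas_off(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(1)
        table = _content_table(rng, n=60)
        fit = fit_stepwise_mlm(table, alpha_in=1.0, alpha_out=1.0,
                               max_order=2,
                               factors=("haplo_coverage", "ploidy",
                                        "category_group"))
        full = smf.ols(
            "count ~ haplo_coverage + C(ploidy) + C(category_group)"
            " + haplo_coverage:C(ploidy) + haplo_coverage:C(category_group)"
            " + C(ploidy):C(category_group)", data=table).fit()
        assert fit.ssr == pytest.approx(full.ssr, rel=1e-8)
        ours = fit.coefficients.set_index("term")["coef"]
        for term, coef in full.params.items():
            assert ours[term] == pytest.approx(coef, abs=1e-8)

    def test_true_effect_selected(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            table = _content_table(rng, n=200)
            fit = fit_stepwise_mlm(table)
            if ("haplo_coverage",) in fit.terms:
                hits += 1
        assert hits >= 19

    def test_planted_ploidy_by_exonic_interaction_recovered(self):
        rng = np.random.default_rng(7)
        table = _content_table(rng, n=300, interaction=4.0)
        fit = fit_stepwise_mlm(table, max_order=2)
        assert ("ploidy", "category_group") in fit.terms
        # the fitted interaction: extra 4x content specific to exonic strata
        grid = pd.DataFrame([
            (2, 5.0, "exonic"), (4, 5.0, "exonic"),
            (2, 5.0, "non-genic"), (4, 5.0, "non-genic")],
            columns=["ploidy", "haplo_coverage", "category_group"])
        grid["freq_class"] = "LF"
        pred = fit.result.predict(grid)
        interaction = (pred[1] - pred[0]) - (pred[3] - pred[2])
        assert interaction == pytest.approx(4.0, abs=0.5)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_stepwise_mlm(_content_table(np.random.default_rng(0), n=2))


SAMPLES_40 = pd.DataFrame({
    "id": [f"d{i}" for i in range(20)] + [f"t{i}" for i in range(20)],
    "population": "p", "clade": ["c2"] * 20 + ["c4"] * 20,
    "ploidy": [2] * 20 + [4] * 20, "coverage": 8.0})


def _null_sites_states(rng, n_sites=300, hf_rate=0.3):
    rows, st_rows = [], []
    ids = SAMPLES_40["id"].tolist()
    for k in range(n_sites):
        cls = "HF" if rng.random() < hf_rate else "mid"
        rows.append((f"s{k}", "famX", "intergenic", cls, cls, cls))
        carriers = rng.choice(40, size=4, replace=False)
        st_rows.append(["C" if i in carriers else "N" for i in range(40)])
    sites = pd.DataFrame(rows, columns=["site_id", "family", "category",
                                        "freq_class", "class_2x", "class_4x"])
    states = pd.DataFrame(st_rows, columns=ids, index=sites["site_id"])
    return sites, states


class TestSubsampledContent:
    def test_identical_cohorts_mostly_nonsignificant(self):
        rng = np.random.default_rng(0)
        sites, states = _null_sites_states(rng)
        out = subsampled_content(states, sites, SAMPLES_40, n_per_group=10,
                                 reps=60, seed=1)
        valid = out.dropna(subset=["p"])
        valid = valid[(valid["mean_2x"] > 0) | (valid["mean_4x"] > 0)]
        assert (valid["p"] > 0.05).mean() >= 0.5  # no systematic excess

    def test_single_rep_rejected(self):
        rng = np.random.default_rng(0)
        sites, states = _null_sites_states(rng, n_sites=20)
        with pytest.raises(ValueError, match="repetitions"):
            subsampled_content(states, sites, SAMPLES_40, n_per_group=10,
                               reps=1)

    def test_means_converge_to_full_cohort_presence(self):
        rng = np.random.default_rng(2)
        sites, states = _null_sites_states(rng, n_sites=100)
        out = subsampled_content(states, sites, SAMPLES_40, n_per_group=20,
                                 reps=10, seed=0)
        # subsample = the whole ploidy group: counts equal cohort presence
        carried = states.to_numpy() == "C"
        cols2 = [states.columns.get_loc(i) for i in SAMPLES_40["id"][:20]]
        hf = sites["class_2x"] == "HF"
        expected = int((carried[:, cols2].any(axis=1)
                        & hf.to_numpy()).sum())
        row = out[(out["category_group"] == "non-genic")
                  & (out["freq_class"] == "HF")].iloc[0]
        assert row["mean_2x"] == pytest.approx(expected)
        assert row["sd_2x"] == 0.0


class TestBurstFamilyTest:
    def test_small_family_excluded(self):
        rng = np.random.default_rng(0)
        sites, states = _null_sites_states(rng, n_sites=9)
        out = burst_family_test(sites, states, SAMPLES_40, min_copies=10)
        assert out.empty

    def test_planted_excess_flagged_with_direction(self):
        rng = np.random.default_rng(1)
        ids = SAMPLES_40["id"].tolist()
        rows, st_rows = [], []
        for k in range(50):
            hf4 = rng.random() < 0.5
            hf2 = rng.random() < 0.1
            rows.append((f"s{k}", "famY", "intergenic", "mid",
                         "HF" if hf2 else "mid", "HF" if hf4 else "mid"))
            st_rows.append(["C"] * 40)
        sites = pd.DataFrame(rows, columns=["site_id", "family", "category",
                                            "freq_class", "class_2x",
                                            "class_4x"])
        states = pd.DataFrame(st_rows, columns=ids, index=sites["site_id"])
        out = burst_family_test(sites, states, SAMPLES_40)
        assert len(out) == 1
        assert bool(out.iloc[0]["flagged"])
        assert bool(out.iloc[0]["excess_in_4x"])

    def test_chi2_matches_oracle(self):
        rng = np.random.default_rng(1)
        ids = SAMPLES_40["id"].tolist()
        rows, st_rows = [], []
        for k in range(40):
            rows.append((f"s{k}", "famZ", "intergenic", "mid",
                         "HF" if k < 8 else "mid",
                         "HF" if k < 20 else "mid"))
            st_rows.append(["C"] * 40)
        sites = pd.DataFrame(rows, columns=["site_id", "family", "category",
                                            "freq_class", "class_2x",
                                            "class_4x"])
        states = pd.DataFrame(st_rows, columns=ids, index=sites["site_id"])
        out = burst_family_test(sites, states, SAMPLES_40)
        assert out.iloc[0]["chi2"] == pytest.approx(
            chi2_closed_form(8, 32, 20, 20))


class TestContentTable:
    def test_counts_partition_carried_insertions(self, pop_bundle):
        from polyte import landscape
        sites = landscape.annotate_sites(
            pop_bundle["sites"], pop_bundle["states"],
            pop_bundle["truth"].samples, pop_bundle["catmap"],
            arm_threshold=300_000)
        table = build_content_table(pop_bundle["states"], sites,
                                    pop_bundle["truth"].samples)
        # per individual, stratum counts sum to total carried insertions
        carried = (pop_bundle["states"] == "C").sum(axis=0)
        per_ind = table.groupby("id")["count"].sum()
        for ind, total in carried.items():
            assert per_ind[ind] == total
        assert (table["haplo_coverage"] > 0).all()
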