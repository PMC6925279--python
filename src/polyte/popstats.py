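"""Population-genetic statistics for cross-ploidy TE-content comparisons.

Covers the Hardy–Weinberg carrier/allele-frequency conversions under
polysomy, the 2x2 chi-square proportion tests, stepwise multiple linear
models of per-individual TE content, ploidy-subsampled content
comparisons, and the family-level transposition-burst test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

from .config import GENIC_NEAR

# ---------------------------------------------------------------------------
# Hardy–Weinberg ploidy math


@dataclass
class HWResult:
    """Allele/carrier frequency pair with genotype-class probabilities.

    Under Hardy–Weinberg equilibrium with tetrasomic (or disomic) random
    segregation, the non-carrier fraction is (1-p)^ploidy, so
    f = 1 - (1-p)^ploidy and p = 1 - (1-f)^(1/ploidy).
    ``dosage_probs[d]`` is the probability of carrying d copies;
    ``dosage1_carrier_fraction`` is the fraction of carriers that are
    minimal-dosage (heterozygotes in diploids, simplex heterozygotes in
    tetraploids).
    """

    ploidy: int
    f: float
    p: float
    dosage_probs: np.ndarray
    dosage1_carrier_fraction: float
    monomorphic: bool = False


def carrier_to_allele(f: float, ploidy: int) -> float:
    """Invert (1-p)^ploidy = 1-f."""
    return 1.0 - (1.0 - f) ** (1.0 / ploidy)


def allele_to_carrier(p: float, ploidy: int) -> float:
    return 1.0 - (1.0 - p) ** ploidy


def hw_convert(f: float | None = None, p: float | None = None, *,
               ploidy: int) -> HWResult:
    """Convert between carrier frequency f and allele frequency p.

    Exactly one of ``f``/``p`` must be given; both must lie in [0, 1].
    """
    if ploidy not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    if (f is None) == (p is None):
        raise ValueError("give exactly one of f or p")
    monomorphic = False
    if f is not None:
        if not 0 <= f <= 1:
            raise ValueError("f must be in [0, 1]")
        if f == 1.0:
            monomorphic = True
            p = 1.0
        else:
            p = carrier_to_allele(f, ploidy)
    else:
        if not 0 <= p <= 1:
            raise ValueError("p must be in [0, 1]")
        monomorphic = p == 1.0
        f = allele_to_carrier(p, ploidy)
    probs = st.binom.pmf(np.arange(ploidy + 1), ploidy, p)
    if probs[0] < 1.0:
        dos1 = float(probs[1] / (1.0 - probs[0]))
    else:
        dos1 = float("nan")
    return HWResult(ploidy=ploidy, f=float(f), p=float(p), dosage_probs=probs,
                    dosage1_carrier_fraction=dos1, monomorphic=monomorphic)


# ---------------------------------------------------------------------------
# 2x2 chi-square


def chi2_2x2(a: int, b: int, c: int, d: int, *,
             continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table [[a, b], [c, d]], 1 df.

    No continuity correction by default.  Raises on a zero margin.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has a zero margin")
    stat, p, _dof, _exp = st.chi2_contingency(table, correction=continuity)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Content table


def build_content_table(states: pd.DataFrame, sites: pd.DataFrame,
                        samples: pd.DataFrame) -> pd.DataFrame:
    """Per-individual carried-insertion counts by category group x freq class.

    ``states`` is the site x individual C/N/NA matrix, ``sites`` the
    annotated site table (needs ``category`` and ``freq_class`` columns),
    ``samples`` the sample sheet.  Haplo-coverage is mean coverage divided
    by ploidy.  Returns a long table with one row per individual x
    category group x frequency class.
    """
    for col in ("category", "freq_class"):
        if col not in sites.columns:
            raise ValueError(f"sites table needs a {col!r} column")
    groups = sites["category"].map(category_group)
    carried = states.to_numpy() == "C"
    rows = []
    for _, ind in samples.iterrows():
        col = states.columns.get_loc(ind["id"])
        mask = carried[:, col]
        fclass = _freq_class_column(sites, int(ind["ploidy"]))
        for cg in ("non-genic", "introns+UTRs", "exonic"):
            for fc in ("LF", "mid", "HF"):
                n = int((mask & (groups == cg).to_numpy()
                         & (fclass == fc)).sum())
                rows.append((ind["id"], int(ind["ploidy"]),
                             float(ind["coverage"]) / int(ind["ploidy"]),
                             cg, fc, n))
    return pd.DataFrame(rows, columns=["id", "ploidy", "haplo_coverage",
                                       "category_group", "freq_class", "count"])


def category_group(category: str) -> str:
    """Collapse the 8 site categories into the 3 content-model groups."""
    if category == "exon":
        return "exonic"
    if category in ("intron", "utr5", "utr3"):
        return "introns+UTRs"
    return "non-genic"


def _freq_class_column(sites: pd.DataFrame, ploidy: int) -> np.ndarray:
    """Ploidy-cohort frequency class if annotated, else the overall one."""
    col = f"class_{ploidy}x"
    if col in sites.columns:
        return sites[col].to_numpy()
    return sites["freq_class"].to_numpy()


# ---------------------------------------------------------------------------
# Stepwise multiple linear model


@dataclass
class ModelFit:
    """OLS fit selected by bidirectional stepwise F-tests."""

    terms: list[tuple[str, ...]]
    coefficients: pd.DataFrame  # term, coef, ci_low, ci_high, t, p
    ssr: float
    trace: list[str] = field(default_factory=list)
    result: object = None


def _term_token(term: tuple[str, ...], categorical: set[str]) -> str:
    return ":".join(f"C({t})" if t in categorical else t for t in term)


def _formula(response: str, terms: list[tuple[str, ...]],
             categorical: set[str]) -> str:
    if not terms:
        return f"{response} ~ 1"
    return f"{response} ~ " + " + ".join(_term_token(t, categorical)
                                         for t in terms)


def _expand_terms(factors: list[str], max_order: int) -> list[tuple[str, ...]]:
    terms = []
    for k in range(1, max_order + 1):
        terms.extend(itertools.combinations(factors, k))
    return terms


def fit_stepwise_mlm(table: pd.DataFrame, response: str = "count",
                     factors: tuple[str, ...] = ("haplo_coverage", "ploidy",
                                                 "category_group"),
                     max_order: int | None = None,
                     alpha_in: float = 0.05, alpha_out: float = 0.10,
                     max_iter: int = 50) -> ModelFit:
    """Bidirectional stepwise OLS of TE content.

    Candidate terms are the main effects of ``factors`` plus all
    interactions up to ``max_order`` (default: all orders).  At each
    round the candidate whose addition gives the smallest F-test p-value
    for the change in residual sum of squares is added if p < ``alpha_in``;
    then the included term with the largest such p-value is removed if
    p > ``alpha_out``.  Model hierarchy is respected throughout:
    an interaction can only enter once all its margins are in, and a term
    cannot leave while a superset interaction remains.
    """
    if len(table) < 10:
        raise ValueError("need >= 10 rows to fit the content model")
    categorical = {f for f in factors
                   if not pd.api.types.is_numeric_dtype(table[f])
                   or table[f].nunique() <= 4 and f != "haplo_coverage"}
    if max_order is None:
        max_order = len(factors)
    candidates = _expand_terms(list(factors), max_order)
    included: list[tuple[str, ...]] = []
    trace: list[str] = []

    def fit(terms):
        return smf.ols(_formula(response, terms, categorical), data=table).fit()

    def f_test(small, big):
        """p-value of the F-test for the extra terms of the bigger model."""
        if big.df_resid <= 0 or big.df_resid >= small.df_resid:
            return None
        num = (small.ssr - big.ssr) / (small.df_resid - big.df_resid)
        den = big.ssr / big.df_resid
        if den <= 0:
            return 0.0
        return float(st.f.sf(num / den, small.df_resid - big.df_resid,
                             big.df_resid))

    current = fit(included)
    for _ in range(max_iter):
        changed = False
        # forward: best addable candidate
        best_p, best_term, best_fit = None, None, None
        for term in candidates:
            if term in included:
                continue
            if any(tuple(sub) not in included
                   for k in range(1, len(term))
                   for sub in itertools.combinations(term, k)):
                continue  # hierarchy
            trial = fit(included + [term])
            p = f_test(current, trial)
            if p is None:
                trace.append(f"skip {term}: rank-deficient or no residual df")
                continue
            if best_p is None or p < best_p:
                best_p, best_term, best_fit = p, term, trial
        if best_term is not None and (best_p < alpha_in or alpha_in >= 1.0):
            included.append(best_term)
            current = best_fit
            trace.append(f"add {best_term} (p={best_p:.3g})")
            changed = True
        # backward: worst removable included term
        worst_p, worst_term = None, None
        for term in included:
            if any(set(term) < set(other) for other in included):
                continue  # a superset interaction depends on it
            reduced = fit([t for t in included if t != term])
            p = f_test(reduced, current)
            if p is None:
                continue
            if worst_p is None or p > worst_p:
                worst_p, worst_term = p, term
        if worst_term is not None and worst_p > alpha_out:
            included.remove(worst_term)
            current = fit(included)
            trace.append(f"drop {worst_term} (p={worst_p:.3g})")
            changed = True
        if not changed:
            break

    ci = current.conf_int(alpha=0.05)
    coeffs = pd.DataFrame({
        "term": current.params.index,
        "coef": current.params.to_numpy(),
        "ci_low": ci[0].to_numpy(),
        "ci_high": ci[1].to_numpy(),
        "t": current.tvalues.to_numpy(),
        "p": current.pvalues.to_numpy(),
    })
    return ModelFit(terms=list(included), coefficients=coeffs,
                    ssr=float(current.ssr), trace=trace, result=current)


# ---------------------------------------------------------------------------
# Subsampled content comparison


def subsampled_content(states: pd.DataFrame, sites: pd.DataFrame,
                       samples: pd.DataFrame, *, n_per_group: int = 100,
                       reps: int = 100, seed: int = 0,
                       welch: bool = True) -> pd.DataFrame:
    """Average TE content per ploidy from repeated subsampling.

    For each of ``reps`` repetitions, ``n_per_group`` individuals are
    drawn per ploidy without replacement; the number of distinct
    insertions carried by at least one drawn individual is counted per
    stratum (category group x frequency class).  Means and SDs across
    repetitions are reported together with a two-sided t-test between
    ploidies per stratum.
    """
    if reps < 2:
        raise ValueError("need >= 2 repetitions to estimate an SD")
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    groups = sites["category"].map(category_group).to_numpy()
    fclass_by_ploidy = {pl: _freq_class_column(sites, pl) for pl in (2, 4)}
    carried = states.to_numpy() == "C"
    id_by_ploidy = {
        pl: samples.loc[samples["ploidy"] == pl, "id"].tolist()
        for pl in (2, 4)
    }
    n_eff = {}
    for pl, ids in id_by_ploidy.items():
        n_eff[pl] = min(n_per_group, len(ids))
        if n_eff[pl] < n_per_group:
            import warnings
            warnings.warn(
                f"only {len(ids)} individuals at ploidy {pl}; subsampling "
                f"{n_eff[pl]} instead of {n_per_group}")
    strata = [(cg, fc) for cg in ("non-genic", "introns+UTRs", "exonic")
              for fc in ("LF", "mid", "HF")]
    counts = {(pl, s): np.zeros(reps) for pl in (2, 4) for s in strata}
    col_of = {c: i for i, c in enumerate(states.columns)}
    for r in range(reps):
        for pl, ids in id_by_ploidy.items():
            take = rng.choice(len(ids), size=n_eff[pl], replace=False)
            cols = [col_of[ids[i]] for i in take]
            present = carried[:, cols].any(axis=1)
            fclass = fclass_by_ploidy[pl]
            for s in strata:
                cg, fc = s
                counts[(pl, s)][r] = (present & (groups == cg)
                                      & (fclass == fc)).sum()
    rows = []
    for s in strata:
        a, b = counts[(2, s)], counts[(4, s)]
        if np.std(a) == 0 and np.std(b) == 0:
            t, p = (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
        else:
            t, p = st.ttest_ind(b, a, equal_var=not welch)
        rows.append((*s, a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1),
                     float(t), float(p)))
    return pd.DataFrame(rows, columns=["category_group", "freq_class",
                                       "mean_2x", "sd_2x", "mean_4x", "sd_4x",
                                       "t", "p"])


# ---------------------------------------------------------------------------
# Family-level burst test


def burst_family_test(sites: pd.DataFrame, states: pd.DataFrame,
                      samples: pd.DataFrame, *, min_copies: int = 10,
                      alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Test each TE family for an excess of high-frequency non-genic
    insertions in tetraploids.

    Families are eligible when they have strictly more than ``min_copies``
    non-reference insertions present (>=1 carrier) in *each* ploidy group.
    Per family a 2x2 chi-square of (HF vs non-HF) x (2x vs 4x) is computed
    among non-genic insertions; raw p-values are reported (an optional
    Benjamini-Hochberg column can be added with ``bh=True``).
    """
    need = {"family", "category", "freq_class"}
    if not need <= set(sites.columns):
        raise ValueError(f"sites table needs columns {sorted(need)}")
    carried = states.to_numpy() == "C"
    cols2 = [states.columns.get_loc(i)
             for i in samples.loc[samples["ploidy"] == 2, "id"]]
    cols4 = [states.columns.get_loc(i)
             for i in samples.loc[samples["ploidy"] == 4, "id"]]
    in2 = carried[:, cols2].any(axis=1)
    in4 = carried[:, cols4].any(axis=1)
    nongenic = ~sites["category"].isin(GENIC_NEAR).to_numpy()
    hf_by_ploidy = {pl: _freq_class_column(sites, pl) == "HF"
                    for pl in (2, 4)}
    rows = []
    for family, idx in sites.groupby("family").indices.items():
        idx = np.asarray(idx)
        if in2[idx].sum() <= min_copies or in4[idx].sum() <= min_copies:
            continue
        ng2 = idx[in2[idx] & nongenic[idx]]
        ng4 = idx[in4[idx] & nongenic[idx]]
        hf2 = int(hf_by_ploidy[2][ng2].sum())
        hf4 = int(hf_by_ploidy[4][ng4].sum())
        n2, n4 = len(ng2), len(ng4)
        try:
            stat, p = chi2_2x2(hf2, n2 - hf2, hf4, n4 - hf4)
        except ValueError:
            stat, p = float("nan"), float("nan")
        frac2 = hf2 / n2 if n2 else float("nan")
        frac4 = hf4 / n4 if n4 else float("nan")
        rows.append((family, n2, n4, hf2, hf4, frac2, frac4, stat, p,
                     bool(p < alpha) if not math.isnan(p) else False,
                     frac4 > frac2))
    out = pd.DataFrame(rows, columns=["family", "nongenic_2x", "nongenic_4x",
                                      "hf_2x", "hf_4x", "hf_frac_2x",
                                      "hf_frac_4x", "chi2", "p", "flagged",
                                      "excess_in_4x"])
    if out.empty:
        import warnings
        warnings.warn("no family has enough non-reference copies in both "
                      "ploidy groups")
    elif bh:
        from statsmodels.stats.multitest import multipletests
        ok = out["p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["q_bh"] = q
    return out
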