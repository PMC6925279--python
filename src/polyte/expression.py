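"""Carrier/non-carrier (C/NC) expression-ratio analysis.

For each gene, mean expression across populations in which the gene's
nearest TE insertion was detected (carrier populations) is compared to
populations where it was not.  Ratios of near-genic insertions are
tested against both a random population-relabeling null and the
intergenic-tier ratio distribution with two-sample Kolmogorov-Smirnov
tests.  Expression input is assumed already normalized; ratios are
analyzed in log2 internally and reported both ways.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .config import GENIC_NEAR

TIERS = ("genic_near", "intergenic")


def _tier_of(category: str, distance: float) -> str | None:
    if category in GENIC_NEAR:
        return "genic_near"
    if distance >= 2000:
        return "intergenic"
    return None  # 250 bp .. 2 kb: in neither tier


def cnc_ratios(expression: pd.DataFrame, sites: pd.DataFrame,
               states: pd.DataFrame, samples: pd.DataFrame,
               tier: str = "genic_near") -> pd.DataFrame:
    """Per-gene C/NC expression ratio for the requested distance tier.

    A population is "carrier" when >=1 of its members carries the gene's
    nearest insertion (NA members ignored).  Genes whose nearest
    insertion leaves no carrier or no non-carrier population are
    excluded; the count of exclusions is recorded in
    ``result.attrs['n_excluded']``.
    """
    if tier not in TIERS:
        raise ValueError(f"tier must be one of {TIERS}")
    pops = samples.groupby("population")["id"].apply(list)
    for pop, members in pops.items():
        if not any(m in expression.columns for m in members):
            raise ValueError(f"population {pop!r} has no expression columns")
    need = {"site_id", "nearest_gene", "category", "gene_distance"}
    if not need <= set(sites.columns):
        raise ValueError(f"sites table needs columns {sorted(need)}")

    # nearest insertion per gene = the one with the smallest gene distance
    cand = sites[sites["nearest_gene"].notna()].copy()
    cand["tier"] = [_tier_of(c, d) for c, d in
                    zip(cand["category"], cand["gene_distance"])]
    cand = cand.dropna(subset=["tier"])
    nearest = cand.sort_values("gene_distance").drop_duplicates("nearest_gene")
    nearest = nearest[nearest["tier"] == tier]

    rows = []
    n_excluded = 0
    for site in nearest.itertuples():
        gene = site.nearest_gene
        if gene not in expression.index:
            continue
        site_states = states.loc[site.site_id]
        c_means, nc_means = [], []
        for _pop, members in pops.items():
            cols = [m for m in members if m in expression.columns]
            if not cols:
                continue
            member_states = site_states[members]
            if (member_states == "C").any():
                c_means.append(expression.loc[gene, cols].mean())
            elif (member_states == "N").any():
                nc_means.append(expression.loc[gene, cols].mean())
        if not c_means or not nc_means:
            n_excluded += 1
            continue
        c = float(np.mean(c_means))
        nc = float(np.mean(nc_means))
        if nc <= 0:
            n_excluded += 1
            continue
        rows.append((gene, site.site_id, tier, site.gene_distance, c, nc,
                     c / nc, np.log2(c / nc)))
    out = pd.DataFrame(rows, columns=["gene_id", "site_id", "tier",
                                      "gene_distance", "c_mean", "nc_mean",
                                      "ratio", "log2_ratio"])
    out.attrs["n_excluded"] = n_excluded
    return out


def _random_null_ratios(expression: pd.DataFrame, genes: list[str],
                        pops: pd.Series, n_carrier: int, n_null: int,
                        rng) -> np.ndarray:
    """C/NC ratios from random carrier/non-carrier population labelings."""
    ratios = []
    pop_names = list(pops.index)
    per_gene = max(1, n_null // max(1, len(genes)))
    for gene in genes:
        means = {}
        for pop in pop_names:
            cols = [m for m in pops[pop] if m in expression.columns]
            means[pop] = float(expression.loc[gene, cols].mean())
        vals = np.array([means[p] for p in pop_names])
        for _ in range(per_gene):
            k = min(max(1, n_carrier), len(pop_names) - 1)
            idx = rng.permutation(len(pop_names))
            c = vals[idx[:k]].mean()
            nc = vals[idx[k:]].mean()
            if nc > 0:
                ratios.append(c / nc)
    return np.asarray(ratios)


def cnc_tests(genic: pd.DataFrame, intergenic: pd.DataFrame,
              expression: pd.DataFrame, samples: pd.DataFrame,
              n_null: int = 1000, min_records: int = 20,
              seed: int = 0) -> dict:
    """KS tests of near-genic C/NC ratios against the two nulls.

    Compares the near-genic ratio distribution to (a) ratios from random
    carrier/non-carrier population relabelings (skipped when
    ``n_null`` = 0) and (b) the intergenic-tier ratios.
    """
    if len(genic) < min_records or len(intergenic) < min_records:
        raise ValueError(
            f"need >= {min_records} records per tier "
            f"(got {len(genic)} genic, {len(intergenic)} intergenic)")
    out = {}
    g = genic["log2_ratio"].to_numpy()
    i = intergenic["log2_ratio"].to_numpy()
    stat, p = st.ks_2samp(g, i)
    out["vs_intergenic"] = {"ks": float(stat), "p": float(p)}
    if n_null > 0:
        rng = np.random.default_rng(seed)
        pops = samples.groupby("population")["id"].apply(list)
        genes = [g for g in genic["gene_id"] if g in expression.index]
        if not genes:  # relabeling null drawn over the measured genes
            genes = list(expression.index[:200])
        null = _random_null_ratios(expression, genes,
                                   pops, n_carrier=1, n_null=n_null, rng=rng)
        stat, p = st.ks_2samp(g, np.log2(null[null > 0]))
        out["vs_random"] = {"ks": float(stat), "p": float(p)}
    out["median_ratio_genic"] = float(genic["ratio"].median())
    out["median_ratio_intergenic"] = float(intergenic["ratio"].median())
    return out
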