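"""Clade-level insertion classes and local positive-selection contrasts.

An insertion is clade-specific when all of its carriers belong to one
clade: "private" with exactly one carrier, "shared" with two or more.
Clade-specific insertions shared by three or more individuals of their
clade are at locally high frequency (HF3) — candidates for local
positive selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

from .config import GENIC_NEAR
from .popstats import chi2_2x2


def classify_by_clade(states: pd.DataFrame, samples: pd.DataFrame,
                      hf3_threshold: int = 3) -> pd.DataFrame:
    """Clade occurrence / private / shared / HF3 for every site.

    NA individuals are excluded from carrier counts.  Every individual
    must have a clade label.
    """
    if samples["clade"].isna().any():
        bad = samples.loc[samples["clade"].isna(), "id"].tolist()
        raise ValueError(f"individuals without clade label: {bad}")
    clade_of = dict(zip(samples["id"], samples["clade"]))
    missing = [c for c in states.columns if c not in clade_of]
    if missing:
        raise ValueError(f"individuals without clade label: {missing}")
    rows = []
    arr = states.to_numpy()
    clades = np.array([clade_of[c] for c in states.columns])
    for i, site_id in enumerate(states.index):
        carriers = arr[i] == "C"
        n = int(carriers.sum())
        occ = sorted(set(clades[carriers]))
        if n == 0:
            cls, local = "no-carrier", 0
        elif len(occ) > 1:
            cls = "multi-clade"
            local = int(max(np.sum(carriers & (clades == c)) for c in occ))
        elif n == 1:
            cls, local = "clade-specific-private", 1
        else:
            cls, local = "clade-specific-shared", n
        hf3 = len(occ) == 1 and n >= hf3_threshold
        rows.append((site_id, ",".join(occ), cls, local, hf3))
    return pd.DataFrame(rows, columns=["site_id", "clades", "clade_class",
                                       "local_carriers", "hf3"])


def local_selection_contrast(clade_classes: pd.DataFrame,
                             sites: pd.DataFrame, samples: pd.DataFrame,
                             states: pd.DataFrame,
                             gene_class: set[str] | None = None,
                             superfamily: str | None = None,
                             min_expected: float = 1.0) -> pd.DataFrame:
    """Fraction of clade-specific insertions at local high frequency,
    per ploidy and genomic compartment, with a chi-square contrast.

    Compartments: intergenic; within-or-near (<250 bp) genes; and,
    when ``gene_class`` (a set of gene ids) is given, within-or-near
    members of that designated gene class.  ``superfamily`` restricts
    the analysis (e.g. to Copia).  The chi-square is skipped (p = NaN)
    when an expected cell count falls below ``min_expected``.
    """
    merged = sites.merge(clade_classes, on="site_id")
    if superfamily is not None:
        merged = merged[merged["superfamily"] == superfamily]
    cs = merged[merged["clade_class"].str.startswith("clade-specific")]
    ploidy_of_clade = {}
    for _, r in samples.iterrows():
        ploidy_of_clade[r["clade"]] = int(r["ploidy"])
    rows = []
    compartments = [
        ("intergenic", ~cs["category"].isin(GENIC_NEAR)),
        ("genic_near", cs["category"].isin(GENIC_NEAR)),
    ]
    if gene_class is not None:
        compartments.append(
            ("gene_class", cs["category"].isin(GENIC_NEAR)
             & cs["nearest_gene"].isin(gene_class)))
    for name, mask in compartments:
        sub = cs[mask]
        if sub.empty:
            import warnings
            warnings.warn(f"compartment {name!r} is empty")
            rows.append((name, 0, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        ploidy = sub["clades"].map(ploidy_of_clade)
        cells = {}
        for pl in (2, 4):
            s = sub[ploidy == pl]
            cells[pl] = (int(s["hf3"].sum()), len(s))
        (h2, n2), (h4, n4) = cells[2], cells[4]
        f2 = h2 / n2 if n2 else np.nan
        f4 = h4 / n4 if n4 else np.nan
        p = chi2 = np.nan
        if n2 and n4:
            table = np.array([[h2, n2 - h2], [h4, n4 - h4]], dtype=float)
            colsum, rowsum = table.sum(axis=0), table.sum(axis=1)
            if (colsum > 0).all() and (rowsum > 0).all():
                expected = np.outer(rowsum, colsum) / table.sum()
                if expected.min() >= min_expected:
                    chi2, p = chi2_2x2(h2, n2 - h2, h4, n4 - h4)
        rows.append((name, n2, n4, f2, f4, chi2, p))
    return pd.DataFrame(rows, columns=["compartment", "n_2x", "n_4x",
                                       "hf3_frac_2x", "hf3_frac_4x", "chi2",
                                       "p"])


def gene_class_enrichment(target_genes: set[str],
                          gene_classes: pd.DataFrame,
                          universe: set[str]) -> pd.DataFrame:
    """Hypergeometric enrichment of gene classes among target genes.

    ``gene_classes`` maps genes to class labels (columns gene_id,
    class_id).  Upper-tail p-values (P[X >= k]), fold enrichment, and
    Benjamini-Hochberg q-values are reported; classes with no member in
    the universe are skipped.
    """
    offenders = sorted(target_genes - universe)
    if offenders:
        raise ValueError(f"target genes outside the universe: {offenders}")
    M, n = len(universe), len(target_genes)
    rows = []
    for class_id, grp in gene_classes.groupby("class_id"):
        members = set(grp["gene_id"]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & target_genes)
        p = float(st.hypergeom.sf(k - 1, M, K, n))
        expected = n * K / M
        fold = k / expected if expected > 0 else np.nan
        rows.append((class_id, K, k, expected, fold, p))
    out = pd.DataFrame(rows, columns=["class_id", "class_size", "overlap",
                                      "expected", "fold", "p"])
    if len(out):
        from statsmodels.stats.multitest import multipletests
        out["q_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def length_matched_enrichment_null(target_genes: set[str],
                                   gene_lengths: pd.Series,
                                   class_members: set[str],
                                   universe: set[str],
                                   n_draws: int = 10_000,
                                   seed: int = 0) -> float:
    """Resampling p-value for class overlap, controlling for gene length.

    Draws ``n_draws`` random gene sets matching the target's
    length-decile composition and returns the fraction with at least the
    observed class overlap.
    """
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    lengths = gene_lengths.loc[uni]
    deciles = pd.qcut(lengths, 10, labels=False, duplicates="drop")
    by_dec = {d: np.array([g for g in uni if deciles[g] == d])
              for d in deciles.unique()}
    target_dec = deciles.loc[sorted(target_genes)]
    counts = target_dec.value_counts()
    observed = len(target_genes & class_members)
    hits = 0
    for _ in range(n_draws):
        draw = []
        for d, c in counts.items():
            pool = by_dec[d]
            draw.extend(pool[rng.choice(len(pool), size=min(c, len(pool)),
                                        replace=False)])
        if len(set(draw) & class_members) >= observed:
            hits += 1
    return (hits + 1) / (n_draws + 1)
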