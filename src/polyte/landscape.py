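"""Carrier-frequency landscapes and genomic-compartment statistics.

Carrier frequency is computed over non-NA individuals.  LF/HF classes
are the 10th/90th percentiles of the diploid frequency spectrum, applied
unchanged to tetraploids.  Site categories follow the priority order
3'UTR > 5'UTR > exon > intron > upstream<250 > downstream<250, with the
closest gene deciding orientation for flanking insertions; the
arm/pericentromere partition uses distance from the centromere
(5 Mb on a full-size genome, scaled for the synthetic one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.nonparametric.smoothers_lowess import lowess

from .annotation import CategoryMap

ARM_THRESHOLD_BP = 5_000_000


# ---------------------------------------------------------------------------
# Carrier frequency


def carrier_frequencies(states: pd.DataFrame,
                        individuals: list[str] | None = None) -> pd.Series:
    """Per-site fraction of carriers among non-NA individuals.

    ``individuals`` optionally restricts to a cohort (e.g. one ploidy).
    All-NA sites yield NaN with a warning.
    """
    sub = states[individuals] if individuals is not None else states
    arr = sub.to_numpy()
    c = (arr == "C").sum(axis=1)
    n = (arr == "N").sum(axis=1)
    denom = c + n
    if (denom == 0).any():
        import warnings
        warnings.warn(f"{int((denom == 0).sum())} all-NA site(s): frequency "
                      "undefined")
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, c / np.maximum(denom, 1), np.nan)
    return pd.Series(freq, index=states.index)


# ---------------------------------------------------------------------------
# LF / HF classes


@dataclass
class FrequencyClasses:
    """LF/HF thresholds from the diploid spectrum (linear-interpolation
    percentiles)."""

    lf_threshold: float
    hf_threshold: float

    def classify(self, freqs) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        out = np.full(freqs.shape, "mid", dtype=object)
        out[freqs <= self.lf_threshold] = "LF"
        out[freqs >= self.hf_threshold] = "HF"
        out[np.isnan(freqs)] = "mid"
        return out


def lf_hf_classes(diploid_freqs, lo_pct: float = 10.0,
                  hi_pct: float = 90.0) -> FrequencyClasses:
    """Thresholds = 10th/90th percentiles of the diploid site frequencies."""
    freqs = np.asarray(diploid_freqs, dtype=float)
    freqs = freqs[~np.isnan(freqs)]
    if len(freqs) < 10:
        raise ValueError("need >= 10 diploid site frequencies")
    lf, hf = np.percentile(freqs, [lo_pct, hi_pct])
    if not lf < hf:
        raise ValueError("degenerate frequency spectrum: identical "
                         "percentile thresholds")
    return FrequencyClasses(lf_threshold=float(lf), hf_threshold=float(hf))


# ---------------------------------------------------------------------------
# Site categorization


def classify_site(chrom: str, pos: int, category_map: CategoryMap) -> dict:
    """Category, nearest gene and gene distance of one breakpoint."""
    category = category_map.category_at(chrom, pos)
    return {
        "category": category,
        "nearest_gene": category_map.gene_at(chrom, pos),
        "gene_distance": category_map.distance_at(chrom, pos),
    }


def annotate_sites(sites: pd.DataFrame, states: pd.DataFrame,
                   samples: pd.DataFrame, category_map: CategoryMap,
                   arm_threshold: int = ARM_THRESHOLD_BP) -> pd.DataFrame:
    """Add category, gene distance, arm flag and frequency classes.

    Per-ploidy carrier frequencies (freq_2x/freq_4x) are classified with
    the diploid-derived thresholds into class_2x/class_4x; freq_class is
    the class of the overall carrier frequency.
    """
    out = sites.copy().reset_index(drop=True)
    pos_col = "pos" if "pos" in out.columns else "start"
    cats, genes, dists, arm = [], [], [], []
    centromeres = category_map.annotation.centromeres
    for site in out.itertuples():
        pos = int(getattr(site, pos_col))
        info = classify_site(site.chrom, pos, category_map)
        cats.append(info["category"])
        genes.append(info["nearest_gene"])
        dists.append(info["gene_distance"])
        cen = centromeres.get(site.chrom)
        arm.append(bool(cen is not None and abs(pos - cen) > arm_threshold))
    out["category"] = cats
    out["nearest_gene"] = genes
    out["gene_distance"] = dists
    out["arm"] = arm

    st_aligned = states.loc[out["site_id"]] if "site_id" in out.columns \
        else states
    ids2 = samples.loc[samples["ploidy"] == 2, "id"].tolist()
    ids4 = samples.loc[samples["ploidy"] == 4, "id"].tolist()
    out["carrier_freq"] = carrier_frequencies(st_aligned).to_numpy()
    out["freq_2x"] = carrier_frequencies(st_aligned, ids2).to_numpy()
    out["freq_4x"] = carrier_frequencies(st_aligned, ids4).to_numpy()
    spectrum = out.loc[out["freq_2x"] > 0, "freq_2x"]
    classes = lf_hf_classes(spectrum)
    out["class_2x"] = classes.classify(out["freq_2x"])
    out["class_4x"] = classes.classify(out["freq_4x"])
    out["freq_class"] = classes.classify(out["carrier_freq"])
    out.attrs["lf_threshold"] = classes.lf_threshold
    out.attrs["hf_threshold"] = classes.hf_threshold
    return out


# ---------------------------------------------------------------------------
# Arm fraction


def arm_fraction(sites: pd.DataFrame, centromeres: dict[str, int],
                 threshold: int = ARM_THRESHOLD_BP) -> float:
    """Fraction of sites >threshold bp from their chromosome's centromere.

    Uses the site midpoint (indistinguishable from the breakpoint at
    100-kb landscape scale).
    """
    if sites.empty:
        raise ValueError("no sites")
    if "pos" in sites.columns:
        mid = sites["pos"].to_numpy()
    else:
        mid = ((sites["start"] + sites["end"]) // 2).to_numpy()
    cen = sites["chrom"].map(centromeres).to_numpy()
    return float(np.mean(np.abs(mid - cen) > threshold))


# ---------------------------------------------------------------------------
# Density profiles


def density_profile(positions: pd.DataFrame, chrom_lengths: dict[str, int],
                    window: int = 100_000,
                    lowess_frac: float = 0.1) -> pd.DataFrame:
    """Counts per non-overlapping window plus a LOWESS smooth.

    The smooth (tricube weights, 1 robustness iteration) is for plotting
    only; downstream statistics always use the raw counts.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        n_win = max(1, -(-length // window))
        counts = np.zeros(n_win, dtype=int)
        sub = positions[positions["chrom"] == chrom]
        if len(sub):
            pos_col = "pos" if "pos" in sub.columns else "start"
            idx = np.clip(sub[pos_col].to_numpy() // window, 0, n_win - 1)
            counts = np.bincount(idx, minlength=n_win)
        centers = np.arange(n_win) * window + window // 2
        if n_win >= 5:
            smooth = lowess(counts, centers, frac=lowess_frac, it=1,
                            return_sorted=False)
        else:
            smooth = counts.astype(float)
        for i in range(n_win):
            rows.append((chrom, i * window, min((i + 1) * window, length),
                         int(counts[i]), float(smooth[i])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count",
                                       "smooth"])


# ---------------------------------------------------------------------------
# Reference-category footprint


def reference_category_footprint(
        category_map: CategoryMap,
        coverage_weights: dict[str, np.ndarray] | None = None,
        window: int = 10_000) -> pd.Series:
    """Expected category proportions of the reference genome ("WG" bar).

    Optionally weighted by relative mappable coverage per window from a
    deep control alignment.
    """
    return category_map.footprint(coverage_weights, window)


# ---------------------------------------------------------------------------
# Gene-distance bootstrap


def gene_distance_bootstrap(dist_a, dist_b, n_boot: int = 1000,
                            stat: str = "median",
                            seed: int = 0) -> dict:
    """Bootstrap the median (or mean) nearest-gene distance per cohort.

    Resamples each cohort with replacement ``n_boot`` times and compares
    the two bootstrap distributions with a two-sided t-test.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs >= 2 sites")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    fn = np.median if stat == "median" else np.mean
    rng = np.random.default_rng(seed)
    boot_a = np.array([fn(rng.choice(a, size=len(a))) for _ in range(n_boot)])
    boot_b = np.array([fn(rng.choice(b, size=len(b))) for _ in range(n_boot)])
    t, p = st.ttest_ind(boot_a, boot_b)
    return {"boot_a": boot_a, "boot_b": boot_b,
            "stat_a": float(fn(a)), "stat_b": float(fn(b)),
            "delta": float(fn(b) - fn(a)), "t": float(t), "p": float(p)}
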