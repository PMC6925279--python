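"""Genomic-compartment classification.

Every base of the genome is assigned exactly one insertion-site category
with the priority order 3'UTR > 5'UTR > exon > intron > upstream(<250 bp)
> downstream(<250 bp) > near-gene(<2 kb) > intergenic.  For positions
outside genes the orientation (upstream/downstream) is decided by the
*closest* gene, strand-aware; at exact distance ties the upstream reading
wins, mirroring the priority order and keeping classification invariant
under coordinate mirroring plus strand flip.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CATEGORIES
from .io import GenomeAnnotation

CAT_CODE = {
    "intergenic": 0,
    "near2k": 1,
    "downstream250": 2,
    "upstream250": 3,
    "intron": 4,
    "exon": 5,
    "utr5": 6,
    "utr3": 7,
}
CODE_CAT = {v: k for k, v in CAT_CODE.items()}
_FEATURE_CODE = {
    "intron": CAT_CODE["intron"],
    "exon": CAT_CODE["exon"],
    "five_prime_UTR": CAT_CODE["utr5"],
    "three_prime_UTR": CAT_CODE["utr3"],
}


class CategoryMap:
    """Per-bp category, nearest gene, and gene distance for a whole genome.

    Distance is 0 inside genes; the first base up- or downstream of a gene
    is at distance 1.
    """

    def __init__(self, annotation: GenomeAnnotation, near: int = 250,
                 far: int = 2000):
        self.annotation = annotation
        self.near = near
        self.far = far
        self._code: dict[str, np.ndarray] = {}
        self._dist: dict[str, np.ndarray] = {}
        self._gene: dict[str, np.ndarray] = {}
        self._gene_ids = annotation.genes["gene_id"].to_numpy()
        for chrom, length in annotation.chrom_lengths.items():
            self._build_chrom(chrom, int(length))

    # -- construction -----------------------------------------------------
    def _build_chrom(self, chrom: str, length: int) -> None:
        genes = self.annotation.genes
        sub = genes[genes["chrom"] == chrom].sort_values("start")
        code = np.zeros(length, dtype=np.uint8)
        dist = np.full(length, np.iinfo(np.int32).max, dtype=np.int32)
        gene_idx = np.full(length, -1, dtype=np.int32)

        if len(sub):
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            plus = (sub["strand"] == "+").to_numpy()
            orig_idx = sub.index.to_numpy(np.int64)
            pos = np.arange(length, dtype=np.int64)

            nxt = np.searchsorted(starts, pos, side="right")
            prv = np.searchsorted(ends, pos, side="right") - 1
            inside = (nxt - 1 >= 0) & (pos < ends[np.clip(nxt - 1, 0, None)])

            big = np.int64(1) << 40
            d_next = np.where(nxt < len(starts),
                              starts[np.clip(nxt, 0, len(starts) - 1)] - pos, big)
            d_prev = np.where(prv >= 0,
                              pos - ends[np.clip(prv, 0, None)] + 1, big)
            # upstream? looking at the next gene: yes iff it is on '+';
            # looking at the previous gene: yes iff it is on '-'
            up_next = np.where(nxt < len(starts),
                               plus[np.clip(nxt, 0, len(plus) - 1)], False)
            up_prev = np.where(prv >= 0, ~plus[np.clip(prv, 0, None)], False)

            use_next = d_next < d_prev
            tie = d_next == d_prev
            upstream = np.where(use_next, up_next, up_prev)
            upstream[tie] = (up_next | up_prev)[tie]
            near_gene = np.where(use_next, np.clip(nxt, 0, len(starts) - 1),
                                 np.clip(prv, 0, None))
            # at a tie, follow whichever gene yields the upstream reading
            take_next_on_tie = tie & up_next & ~up_prev
            near_gene[take_next_on_tie] = np.clip(nxt, 0, len(starts) - 1)[take_next_on_tie]
            d = np.minimum(d_next, d_prev)

            d[inside] = 0
            near_gene[inside] = (nxt - 1)[inside]

            mask = d < big
            dist[:] = np.where(mask, d, dist).astype(np.int32)
            gene_idx[:] = np.where(mask, orig_idx[near_gene], -1).astype(np.int32)

            outside = ~inside
            code[outside & (d < self.far)] = CAT_CODE["near2k"]
            lt_near = outside & (d < self.near)
            code[lt_near & upstream] = CAT_CODE["upstream250"]
            code[lt_near & ~upstream] = CAT_CODE["downstream250"]
            # genic: whole gene body defaults to intron, then explicit
            # sub-features painted in increasing priority
            for s, e in zip(starts, ends):
                code[s:e] = CAT_CODE["intron"]

        feats = self.annotation.features
        fsub = feats[feats["chrom"] == chrom]
        for ftype in ("intron", "exon", "five_prime_UTR", "three_prime_UTR"):
            for f in fsub[fsub["type"] == ftype].itertuples():
                code[f.start:f.end] = _FEATURE_CODE[ftype]

        self._code[chrom] = code
        self._dist[chrom] = dist
        self._gene[chrom] = gene_idx

    # -- queries ----------------------------------------------------------
    def category_at(self, chrom: str, pos) -> str | np.ndarray:
        self._check(chrom)
        if np.isscalar(pos):
            return CODE_CAT[int(self._code[chrom][pos])]
        codes = self._code[chrom][np.asarray(pos)]
        return np.array([CODE_CAT[c] for c in codes])

    def distance_at(self, chrom: str, pos):
        self._check(chrom)
        d = self._dist[chrom][pos]
        return int(d) if np.isscalar(pos) else d

    def gene_at(self, chrom: str, pos):
        """Nearest gene id (or None when no gene is on the chromosome)."""
        self._check(chrom)
        idx = self._gene[chrom][pos]
        if np.isscalar(pos):
            return None if idx < 0 else self._gene_ids_by_index(int(idx))
        return np.array([None if i < 0 else self._gene_ids_by_index(int(i))
                         for i in idx], dtype=object)

    def _gene_ids_by_index(self, idx: int) -> str:
        return str(self.annotation.genes.loc[idx, "gene_id"])

    def positions_of(self, chrom: str, category: str) -> np.ndarray:
        self._check(chrom)
        return np.flatnonzero(self._code[chrom] == CAT_CODE[category])

    def footprint(self, coverage_weights: dict[str, np.ndarray] | None = None,
                  window: int = 10_000) -> pd.Series:
        """Genomic footprint proportion per category.

        ``coverage_weights`` optionally gives per-chromosome arrays of
        relative mappable coverage in ``window``-bp windows; each base is
        weighted by its window's coverage before normalization (emulating
        normalization by mappability from a deep control alignment).
        """
        totals = np.zeros(len(CATEGORIES))
        for chrom, code in self._code.items():
            if coverage_weights is not None and chrom in coverage_weights:
                w_win = np.asarray(coverage_weights[chrom], dtype=float)
                w = w_win[np.arange(len(code)) // window]
                counts = np.bincount(code, weights=w, minlength=8)
            else:
                counts = np.bincount(code, minlength=8).astype(float)
            for cat in CATEGORIES:
                totals[CATEGORIES.index(cat)] += counts[CAT_CODE[cat]]
        if totals.sum() == 0:
            raise ValueError("empty genome")
        return pd.Series(totals / totals.sum(), index=list(CATEGORIES))

    def _check(self, chrom: str) -> None:
        if chrom not in self._code:
            raise KeyError(f"chromosome {chrom!r} absent from annotation")
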