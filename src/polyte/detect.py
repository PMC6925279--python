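"""Non-reference TE insertion calling from split and discordant reads.

Stages: extract soft-clipped / discordant candidates per individual,
assign the clipped portion (or unmapped mate) to a TE family against the
library, cluster anchors into per-individual candidate sites, intersect
across individuals with the minimum-support rule (>=3 reads in at least
one individual, including >=1 upstream and >=1 downstream junction
read), then score every individual at every retained site as carrier /
non-carrier / NA from support and negative coverage.

Zygosity is never inferred: a carrier may hold 1..ploidy copies.
"""

from __future__ import annotations

import math

import edlib
import numpy as np
import pandas as pd
import pysam

from .config import TYPE_A, DetectParams

_REVCOMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _rc(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


def selection_type(superfamily: str) -> str:
    """'A' for the genic-preference superfamilies, else 'B'."""
    return "A" if superfamily in TYPE_A else "B"


# ---------------------------------------------------------------------------
# Candidate extraction


def extract_candidates(bam_path, min_clip: int = 20) -> pd.DataFrame:
    """Split (soft-clip >= min_clip) and discordant (unmapped-mate) reads.

    Requires a coordinate-sorted, indexed BAM.  Returns one row per
    candidate with its genomic anchor: ``side`` is 'up' when the clip is
    at the 3' end of the alignment (read ran into the element from
    upstream), 'down' when at the 5' end, 'disc' for the unmapped mate
    of a mapped read.
    """
    bam = pysam.AlignmentFile(str(bam_path))
    so = bam.header.get("HD", {}).get("SO")
    if so != "coordinate":
        raise ValueError(f"{bam_path}: alignment not coordinate-sorted "
                         f"(SO={so!r})")
    if not bam.has_index():
        raise ValueError(f"{bam_path}: missing BAM index")
    rows = []
    for read in bam.fetch(until_eof=True):
        if read.is_secondary or read.is_supplementary:
            continue
        if read.is_unmapped:
            if not read.mate_is_unmapped and read.query_sequence:
                rows.append((read.reference_name,
                             read.next_reference_start, "disc",
                             read.query_sequence, read.query_name))
            continue
        cig = read.cigartuples
        if not cig:
            continue
        op0, len0 = cig[0]
        opn, lenn = cig[-1]
        seq = read.query_sequence
        if opn == 4 and lenn >= min_clip:  # 3' soft clip: upstream junction
            rows.append((read.reference_name, read.reference_end, "up",
                         seq[-lenn:], read.query_name))
        if op0 == 4 and len0 >= min_clip:  # 5' soft clip: downstream junction
            rows.append((read.reference_name, read.reference_start, "down",
                         seq[:len0], read.query_name))
    bam.close()
    return pd.DataFrame(rows, columns=["chrom", "anchor", "side", "seq",
                                       "read"])


# ---------------------------------------------------------------------------
# TE-family assignment


def assign_te(candidates: pd.DataFrame,
              te_library: list[tuple[str, str, str]],
              min_identity: float = 0.9,
              min_match: int = 15) -> pd.DataFrame:
    """Match candidate sequences against the TE library.

    A candidate is kept when its best hit reaches ``min_identity`` over
    its full (clipped or mate) sequence of length >= ``min_match``;
    equal-best hits go to the first library entry and are flagged
    ambiguous.
    """
    if not te_library:
        raise ValueError("TE library is empty")
    fams = [fam for fam, _sf, _seq in te_library]
    sf_of = {fam: sf for fam, sf, _seq in te_library}
    seqs = [seq for _fam, _sf, seq in te_library]
    out_rows = []
    for cand in candidates.itertuples():
        q = cand.seq
        if q is None or len(q) < min_match:
            continue
        qr = _rc(q)
        best_idx, best_dist = [], None
        # fast path: exact substring (error-free or conserved termini)
        for i, target in enumerate(seqs):
            if q in target or qr in target:
                best_idx.append(i)
        if best_idx:
            best_dist = 0
        else:
            max_dist = int(len(q) * (1 - min_identity))
            for i, target in enumerate(seqs):
                for query in (q, qr):
                    d = edlib.align(query, target, mode="HW",
                                    task="distance", k=max_dist)["editDistance"]
                    if d < 0:
                        continue
                    if best_dist is None or d < best_dist:
                        best_dist, best_idx = d, [i]
                    elif d == best_dist and i not in best_idx:
                        best_idx.append(i)
        if best_dist is None:
            continue
        identity = 1.0 - best_dist / len(q)
        if identity < min_identity:
            continue
        fam = fams[best_idx[0]]
        out_rows.append((cand.chrom, cand.anchor, cand.side, cand.read, fam,
                         sf_of[fam], identity, len(best_idx) > 1))
    return pd.DataFrame(out_rows, columns=["chrom", "anchor", "side", "read",
                                           "family", "superfamily",
                                           "identity", "ambiguous"])


# ---------------------------------------------------------------------------
# Site definition (per individual)


def define_sites(assigned: pd.DataFrame, cluster_window: int = 100,
                 discordant_window: int = 500) -> pd.DataFrame:
    """Cluster junction anchors of one individual into candidate sites.

    Split anchors of the same family within ``cluster_window`` bp merge
    into one site spanning [min anchor, max anchor + 1).  Discordant
    candidates are then attributed to the nearest same-family site
    within ``discordant_window``; discordant-only clusters are dropped
    (they can never satisfy the up+down support requirement).
    """
    cols = ["chrom", "family", "superfamily", "start", "end", "split_up",
            "split_down", "discordant"]
    if assigned.empty:
        return pd.DataFrame(columns=cols)
    rows = []
    splits = assigned[assigned["side"].isin(("up", "down"))]
    discs = assigned[assigned["side"] == "disc"]
    for (chrom, family), grp in splits.groupby(["chrom", "family"],
                                               sort=True):
        grp = grp.sort_values("anchor")
        anchors = grp["anchor"].to_numpy()
        sides = grp["side"].to_numpy()
        sf = grp["superfamily"].iloc[0]
        brk = np.flatnonzero(np.diff(anchors) > cluster_window) + 1
        for seg in np.split(np.arange(len(anchors)), brk):
            a = anchors[seg]
            s = sides[seg]
            rows.append((chrom, family, sf, int(a.min()), int(a.max()) + 1,
                         int((s == "up").sum()), int((s == "down").sum()), 0))
    sites = pd.DataFrame(rows, columns=cols)
    if not discs.empty and not sites.empty:
        for (chrom, family), grp in discs.groupby(["chrom", "family"]):
            cand = sites[(sites["chrom"] == chrom)
                         & (sites["family"] == family)]
            if cand.empty:
                continue
            mid = ((cand["start"] + cand["end"]) // 2).to_numpy()
            for anchor in grp["anchor"].to_numpy():
                d = np.abs(mid - anchor)
                j = int(np.argmin(d))
                if d[j] <= discordant_window:
                    sites.loc[cand.index[j], "discordant"] += 1
    return sites.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cross-individual intersection


def support_ok(up: int, down: int, disc: int, min_support: int = 3) -> bool:
    """The minimum-support rule: >=3 reads total with >=1 up and >=1 down."""
    return up + down + disc >= min_support and up >= 1 and down >= 1


def intersect_sites(per_individual: pd.DataFrame,
                    params: DetectParams | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-individual candidate sites and apply the support filter.

    ``per_individual`` concatenates the outputs of :func:`define_sites`
    with an added ``individual`` column.  Same-family sites whose
    intervals overlap (within the clustering window) merge across
    individuals.  A merged site is retained iff at least one individual
    satisfies :func:`support_ok`.  Returns (site table, long evidence
    table with one row per retained site x contributing individual).
    """
    params = params or DetectParams()
    site_cols = ["site_id", "chrom", "start", "end", "family", "superfamily",
                 "selection_type"]
    ev_cols = ["site_id", "individual", "split_up", "split_down", "discordant"]
    if per_individual.empty:
        return (pd.DataFrame(columns=site_cols), pd.DataFrame(columns=ev_cols))
    sites_rows, ev_rows = [], []
    k = 0
    for (chrom, family), grp in per_individual.groupby(["chrom", "family"],
                                                       sort=True):
        grp = grp.sort_values("start")
        cur = None  # [start, end, members]
        clusters = []
        for row in grp.itertuples():
            if cur is not None and row.start <= cur[1] + params.cluster_window:
                cur[1] = max(cur[1], row.end)
                cur[2].append(row)
            else:
                cur = [row.start, row.end, [row]]
                clusters.append(cur)
        for start, end, members in clusters:
            per_ind: dict[str, list[int]] = {}
            for m in members:
                acc = per_ind.setdefault(m.individual, [0, 0, 0])
                acc[0] += m.split_up
                acc[1] += m.split_down
                acc[2] += m.discordant
            if not any(support_ok(u, d, c, params.min_support)
                       for u, d, c in per_ind.values()):
                continue
            site_id = f"site{k:05d}"
            k += 1
            sites_rows.append((site_id, chrom, int(start), int(end), family,
                               members[0].superfamily,
                               selection_type(members[0].superfamily)))
            for ind, (u, d, c) in sorted(per_ind.items()):
                ev_rows.append((site_id, ind, u, d, c))
    sites = pd.DataFrame(sites_rows, columns=site_cols)
    sites = sites.sort_values(["chrom", "start"]).reset_index(drop=True)
    return sites, pd.DataFrame(ev_rows, columns=ev_cols)


# ---------------------------------------------------------------------------
# Negative coverage


def negative_coverage(bam_path, sites: pd.DataFrame) -> pd.Series:
    """Minimum read depth over the two boundary bases of each site."""
    out = np.zeros(len(sites), dtype=int)
    with pysam.AlignmentFile(str(bam_path)) as bam:
        lengths = dict(zip(bam.references, bam.lengths))
        for i, site in enumerate(sites.itertuples()):
            L = lengths[site.chrom]
            depths = []
            for pos in (site.start, max(site.start, site.end - 1)):
                pos = min(max(pos, 0), L - 1)
                cov = bam.count_coverage(site.chrom, pos, pos + 1,
                                         quality_threshold=0)
                depths.append(int(sum(c[0] for c in cov)))
            out[i] = min(depths)
    return pd.Series(out, index=sites["site_id"].to_numpy())


# ---------------------------------------------------------------------------
# State assignment


def _na_limits(samples: pd.DataFrame, params: DetectParams) -> tuple[int, int]:
    n2 = int((samples["ploidy"] == 2).sum())
    n4 = int((samples["ploidy"] == 4).sum())
    na2 = params.na_max_2x if params.na_max_2x is not None \
        else math.ceil(0.1 * n2)
    na4 = params.na_max_4x if params.na_max_4x is not None \
        else math.ceil(0.1 * n4)
    return na2, na4


def assign_states(sites: pd.DataFrame, evidence: pd.DataFrame,
                  samples: pd.DataFrame,
                  params: DetectParams | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Carrier / non-carrier / NA state for every individual at every site.

    ``evidence`` must hold, per retained site and individual, the
    support counts and the negative coverage (columns split_up,
    split_down, discordant, neg_cov); individuals without an evidence
    row for a site are an error.  An individual is a carrier iff it
    meets the support rule; otherwise a non-carrier iff
    neg_cov_min <= neg_cov <= neg_cov_max; otherwise NA.  Sites whose NA
    counts exceed the per-ploidy limits (both groups under the default
    'and' reading) are removed as non-informative.  Returns the filtered
    site table (with carrier_freq) and the site x individual state
    matrix.
    """
    params = params or DetectParams()
    params.validate()
    if "neg_cov" not in evidence.columns:
        raise ValueError("evidence table needs a neg_cov column")
    na2_max, na4_max = _na_limits(samples, params)
    inds = samples["id"].tolist()
    ploidy_of = dict(zip(samples["id"], samples["ploidy"]))
    ev = {(r.site_id, r.individual): r for r in evidence.itertuples()}
    state_rows = {}
    keep_rows = []
    freq = {}
    for site in sites.itertuples():
        states = {}
        na2 = na4 = 0
        for ind in inds:
            r = ev.get((site.site_id, ind))
            if r is None:
                raise KeyError(
                    f"no evidence for individual {ind!r} at site "
                    f"{site.site_id!r}")
            if support_ok(r.split_up, r.split_down, r.discordant,
                          params.min_support):
                states[ind] = "C"
            elif params.neg_cov_min <= r.neg_cov <= params.neg_cov_max:
                states[ind] = "N"
            else:
                states[ind] = "NA"
                if ploidy_of[ind] == 2:
                    na2 += 1
                else:
                    na4 += 1
        over2, over4 = na2 > na2_max, na4 > na4_max
        uninformative = (over2 and over4) if params.na_rule == "and" \
            else (over2 or over4)
        if uninformative:
            continue
        n_c = sum(1 for s in states.values() if s == "C")
        n_n = sum(1 for s in states.values() if s == "N")
        if n_c + n_n == 0:
            import warnings
            warnings.warn(f"site {site.site_id} is all-NA; excluded")
            continue
        keep_rows.append(site.Index)
        freq[site.site_id] = n_c / (n_c + n_n)
        state_rows[site.site_id] = states
    out_sites = sites.loc[keep_rows].copy()
    out_sites["carrier_freq"] = out_sites["site_id"].map(freq)
    states = pd.DataFrame.from_dict(state_rows, orient="index")
    states = states.reindex(columns=inds)
    states.index.name = "site_id"
    return out_sites.reset_index(drop=True), states


# ---------------------------------------------------------------------------
# Naming


def name_sites(sites: pd.DataFrame,
               known: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assign common names, '<superfamily>_new-<k>' when unannotated.

    ``known`` optionally holds annotated TE copies (columns chrom,
    start, end, name); a site overlapping one inherits its name.  Sites
    sharing a common name are suffixed '.1', '.2', ... in coordinate
    order.
    """
    sites = sites.copy()
    names = []
    for i, site in enumerate(sites.itertuples()):
        name = None
        if known is not None and len(known):
            hit = known[(known["chrom"] == site.chrom)
                        & (known["start"] < site.end)
                        & (site.start < known["end"])]
            if len(hit):
                name = str(hit.iloc[0]["name"])
        names.append(name if name else f"{site.superfamily}_new-{i + 1}")
    sites["name"] = names
    dup = sites.groupby("name")["name"].transform("size") > 1
    if dup.any():
        ordered = sites.sort_values(["chrom", "start"]).index
        counters: dict[str, int] = {}
        new = sites["name"].copy()
        for idx in ordered:
            if dup[idx]:
                base = sites.at[idx, "name"]
                counters[base] = counters.get(base, 0) + 1
                new.at[idx] = f"{base}.{counters[base]}"
        sites["name"] = new
    return sites


# ---------------------------------------------------------------------------
# End-to-end per-cohort driver


def detect_pipeline(bam_paths: dict[str, str],
                    te_library: list[tuple[str, str, str]],
                    samples: pd.DataFrame,
                    params: DetectParams | None = None,
                    known_names: pd.DataFrame | None = None,
                    ) -> dict[str, pd.DataFrame]:
    """Run the full caller over one cohort of BAMs.

    Returns {'sites', 'states', 'evidence', 'sites_support'}: the named,
    state-assigned informative site table, the C/N/NA matrix, the long
    evidence table, and the support-filtered site list before the
    NA-informativeness QC (detection sensitivity is a property of this
    last table; the QC removes sites for cross-individual missingness,
    not for lack of evidence).
    """
    params = params or DetectParams()
    per_ind = []
    for ind_id in samples["id"]:
        if ind_id not in bam_paths:
            raise KeyError(f"no alignment provided for individual {ind_id!r}")
        cands = extract_candidates(bam_paths[ind_id], params.min_clip)
        assigned = assign_te(cands, te_library, params.min_identity,
                             params.min_match)
        psites = define_sites(assigned, params.cluster_window,
                              params.discordant_window)
        psites["individual"] = ind_id
        per_ind.append(psites)
    merged = pd.concat(per_ind, ignore_index=True) if per_ind else \
        pd.DataFrame()
    sites, evidence = intersect_sites(merged, params)
    if sites.empty:
        return {"sites": sites, "states": pd.DataFrame(),
                "evidence": evidence, "sites_support": sites.copy()}
    # complete the evidence table: every individual needs counts + neg_cov
    ev = evidence.set_index(["site_id", "individual"])
    full_rows = []
    for ind_id in samples["id"]:
        neg = negative_coverage(bam_paths[ind_id], sites)
        for site_id in sites["site_id"]:
            if (site_id, ind_id) in ev.index:
                r = ev.loc[(site_id, ind_id)]
                u, d, c = int(r["split_up"]), int(r["split_down"]), \
                    int(r["discordant"])
            else:
                u = d = c = 0
            full_rows.append((site_id, ind_id, u, d, c, int(neg[site_id])))
    evidence = pd.DataFrame(full_rows, columns=["site_id", "individual",
                                                "split_up", "split_down",
                                                "discordant", "neg_cov"])
    sites_support = sites.copy()
    sites, states = assign_states(sites, evidence, samples, params)
    sites = name_sites(sites, known_names)
    states = states.loc[sites["site_id"]]
    evidence = evidence[evidence["site_id"].isin(set(sites["site_id"]))]
    return {"sites": sites, "states": states, "evidence": evidence,
            "sites_support": sites_support}


# ---------------------------------------------------------------------------
# Truth-aware evaluation helpers (validation only)


def match_to_truth(sites: pd.DataFrame, truth_insertions: pd.DataFrame,
                   window: int = 100) -> pd.DataFrame:
    """Match called sites to planted insertions within ``window`` bp.

    Adds a ``truth_id`` column (None for unmatched calls).  Dosage
    information is used for validation only, never by detection.
    """
    sites = sites.copy()
    matches = []
    by_chrom = {c: df.sort_values("pos") for c, df in
                truth_insertions.groupby("chrom")}
    for site in sites.itertuples():
        best = None
        sub = by_chrom.get(site.chrom)
        if sub is not None:
            mid = (site.start + site.end) // 2
            d = np.abs(sub["pos"].to_numpy() - mid)
            j = int(np.argmin(d))
            if d[j] <= window:
                best = sub.iloc[j]["site_id"]
        matches.append(best)
    sites["truth_id"] = matches
    return sites
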