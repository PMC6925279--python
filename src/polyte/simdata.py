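"""Synthetic diploid/autotetraploid cohort generator.

Produces, from a single seeded configuration: a multi-chromosome genome
with gene-dense arms and TE-dense pericentromeres; a TE library; planted
non-reference insertions with per-ploidy carrier-frequency spectra and
Hardy-Weinberg dosages; per-individual paired-end alignments carrying
junction-spanning soft-clipped reads, discordant mates and target-site
duplications; and an expression matrix with cis effects of genic
insertions.  All randomness derives from one master seed through named
sub-streams, so identical seed + config reproduce identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from .annotation import CategoryMap
from .config import GENIC_NEAR, SimConfig
from .io import GenomeAnnotation
from .popstats import carrier_to_allele

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# sub-stream identifiers under the master seed
_S_GENOME, _S_LIBRARY, _S_POP, _S_READS, _S_EXPR = 1, 3, 5, 10, 20


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, *stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort."""

    #: columns: site_id, chrom, pos, family, superfamily, tsd_len,
    #: category, nearest_gene, gene_distance, f_2x, f_4x
    insertions: pd.DataFrame
    #: allele dosages, insertions (index site_id) x individuals
    dosages: pd.DataFrame
    samples: pd.DataFrame
    te_library: list[tuple[str, str, str]]
    #: per-gene baseline expression means (filled by simulate_expression)
    gene_baseline: pd.Series | None = None
    config: SimConfig | None = None

    def carrier_frequency(self) -> pd.Series:
        """True carrier fraction per site (all individuals, no missingness)."""
        return (self.dosages >= 1).mean(axis=1)


# ---------------------------------------------------------------------------
# Genome


def _region_split(config: SimConfig):
    """(arm_segments, peri_segments) as (chrom, start, end) lists."""
    arms, peris = [], []
    hw = config.pericentromere_halfwidth
    for chrom, cen in zip(config.chrom_names, config.centromere_pos):
        L = config.chrom_length
        lo, hi = max(0, cen - hw), min(L, cen + hw)
        if lo > 0:
            arms.append((chrom, 0, lo))
        if hi < L:
            arms.append((chrom, hi, L))
        peris.append((chrom, lo, hi))
    return arms, peris


def _place_intervals(rng, segments, lengths, placed, margin=50, max_try=200):
    """Place non-overlapping intervals of given lengths within segments.

    ``placed`` maps chrom -> list of (start, end) already taken; updated
    in place.  Returns list of (chrom, start, end).
    """
    seg_weights = np.array([e - s for _c, s, e in segments], dtype=float)
    if seg_weights.sum() == 0:
        raise ValueError("no genomic segment available for placement")
    seg_weights /= seg_weights.sum()
    out = []
    for length in lengths:
        ok = False
        for _ in range(max_try):
            ci = rng.choice(len(segments), p=seg_weights)
            chrom, s0, e0 = segments[ci]
            if e0 - s0 <= length:
                continue
            start = int(rng.integers(s0, e0 - length))
            end = start + length
            conflict = any(start - margin < pe and ps < end + margin
                           for ps, pe in placed.setdefault(chrom, []))
            if not conflict:
                placed[chrom].append((start, end))
                out.append((chrom, start, end))
                ok = True
                break
        if not ok:
            raise ValueError("could not place feature; genome too crowded")
    return out


def _gene_structure(rng, config: SimConfig):
    """Transcription-ordered segments [(type, length), ...] of one gene."""
    n_exons = int(rng.integers(1, 6))
    utr5 = int(max(60, rng.normal(200, 50)))
    utr3 = int(max(60, rng.normal(150, 40)))
    segs = [("five_prime_UTR", utr5)]
    for i in range(n_exons):
        segs.append(("exon", int(max(80, rng.normal(300, 80)))))
        if i < n_exons - 1:
            segs.append(("intron", int(max(60, rng.normal(160, 40)))))
    segs.append(("three_prime_UTR", utr3))
    return segs


def make_te_library(config: SimConfig) -> list[tuple[str, str, str]]:
    """Deterministic per-family TE consensus sequences."""
    rng = _rng(config, _S_LIBRARY)
    records = []
    for sf_name, sf in sorted(config.te_superfamilies.items()):
        lo, hi = sf.te_length_range
        for k in range(sf.n_families):
            length = int(rng.integers(lo, hi + 1))
            records.append((f"{sf_name}F{k + 1}", sf_name,
                            _random_seq(rng, length)))
    return records


def simulate_genome(config: SimConfig) -> tuple[dict[str, str], GenomeAnnotation]:
    """Reference sequences plus gene/TE/centromere annotation.

    Genes concentrate on chromosome arms and reference TEs within the
    pericentromere, each at its configured arm/pericentromere density
    ratio.
    """
    config.validate()
    rng = _rng(config, _S_GENOME)
    sequences = {c: _random_seq(rng, config.chrom_length)
                 for c in config.chrom_names}
    arms, peris = _region_split(config)
    arm_len = sum(e - s for _c, s, e in arms)
    peri_len = sum(e - s for _c, s, e in peris)

    def split_counts(n, ratio):
        # ratio = density_arm / density_peri
        w_arm, w_peri = ratio * arm_len, peri_len
        n_arm = int(round(n * w_arm / (w_arm + w_peri))) if (w_arm + w_peri) else 0
        return n_arm, n - n_arm

    placed: dict[str, list] = {}
    genes_rows, feat_rows = [], []
    n_arm, n_peri = split_counts(config.n_genes, config.gene_arm_peri_density_ratio)
    gene_id = 0
    for segs_pool, n in ((arms, n_arm), (peris, n_peri)):
        if n == 0:
            continue
        structures = [_gene_structure(rng, config) for _ in range(n)]
        lengths = [sum(l for _t, l in s) for s in structures]
        spots = _place_intervals(rng, segs_pool, lengths, placed, margin=100)
        for (chrom, start, end), segs in zip(spots, structures):
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{gene_id:05d}"
            gene_id += 1
            genes_rows.append((gid, chrom, start, end, strand))
            layout = segs if strand == "+" else segs[::-1]
            cursor = start
            for ftype, flen in layout:
                feat_rows.append((chrom, cursor, cursor + flen, ftype, gid,
                                  strand))
                cursor += flen

    te_rows = []
    if config.n_reference_tes:
        lib = make_te_library(config)
        n_arm_te, n_peri_te = split_counts(config.n_reference_tes,
                                           config.te_arm_peri_density_ratio)
        for segs_pool, n in ((arms, n_arm_te), (peris, n_peri_te)):
            if n == 0:
                continue
            lengths = [int(rng.integers(300, 3000)) for _ in range(n)]
            spots = _place_intervals(rng, segs_pool, lengths, placed, margin=10)
            for chrom, start, end in spots:
                fam, sf, _seq = lib[int(rng.integers(0, len(lib)))]
                te_rows.append((chrom, start, end, fam, sf))

    annotation = GenomeAnnotation(
        chrom_lengths={c: config.chrom_length for c in config.chrom_names},
        genes=pd.DataFrame(genes_rows, columns=["gene_id", "chrom", "start",
                                                "end", "strand"]),
        features=pd.DataFrame(feat_rows, columns=["chrom", "start", "end",
                                                  "type", "gene_id", "strand"]),
        te_features=pd.DataFrame(te_rows, columns=["chrom", "start", "end",
                                                   "family", "superfamily"]),
        centromeres=dict(zip(config.chrom_names, config.centromere_pos)),
    )
    annotation.validate()
    return sequences, annotation


# ---------------------------------------------------------------------------
# Population


def _make_samples(config: SimConfig, rng) -> pd.DataFrame:
    rows = []
    lo, hi = config.coverage_range
    a, b = config.coverage_beta
    for clade in config.clades:
        for k in range(clade.size):
            pop = f"{clade.label}_p{k % clade.n_populations + 1}"
            cov = float(lo + (hi - lo) * rng.beta(a, b))
            rows.append((f"{clade.label}_{k:02d}", pop, clade.label,
                         clade.ploidy, round(cov, 2)))
    return pd.DataFrame(rows, columns=["id", "population", "clade", "ploidy",
                                       "coverage"])


def _selected_frequencies(rng, config: SimConfig, base_f: float,
                          category: str, family: str) -> tuple[float, float]:
    """Per-ploidy carrier frequencies after applying the selection mode."""
    f2 = f4 = base_f
    genic = category in GENIC_NEAR
    young = base_f < config.purge_freq_max
    purge_p = (config.exon_purge_prob if category == "exon"
               else config.genic_purge_prob)

    def purged(f):
        if rng.random() < purge_p:
            return 0.0
        return f * config.genic_freq_factor

    if genic and young:
        if config.selection_mode == "purifying":
            f2 = f4 = purged(base_f)
        elif config.selection_mode == "relaxed_in_4x":
            f2 = purged(base_f)  # tetraploids shelter what diploids purge
    if config.burst_family is not None and family == config.burst_family \
            and not genic:
        lo, hi = config.burst_freq_range
        f4 = float(rng.uniform(lo, hi))
    return f2, f4


def simulate_population(config: SimConfig, annotation: GenomeAnnotation,
                        category_map: CategoryMap | None = None) -> TruthSet:
    """Plant insertions and draw Hardy-Weinberg dosages for the cohort.

    Insertion positions are sampled per superfamily from its
    category-preference weights over the actual annotated compartments,
    so the generator's category labels agree with the classifier by
    construction.  Per-individual dosage ~ Binomial(ploidy, p) with
    p = 1 - (1-f)^(1/ploidy) from the ploidy-specific carrier frequency.
    """
    config.validate()
    rng = _rng(config, _S_POP)
    if category_map is None:
        category_map = CategoryMap(annotation)
    samples = _make_samples(config, rng)
    library = make_te_library(config)
    fam_by_sf: dict[str, list[str]] = {}
    for fam, sf, _seq in library:
        fam_by_sf.setdefault(sf, []).append(fam)

    margin = config.insert_size_mean + 2 * config.read_length
    pos_cache: dict[tuple[str, str], np.ndarray] = {}

    def positions(chrom, category):
        key = (chrom, category)
        if key not in pos_cache:
            p = category_map.positions_of(chrom, category)
            p = p[(p >= margin) & (p < config.chrom_length - margin)]
            pos_cache[key] = p
        return pos_cache[key]

    chosen: dict[str, list[int]] = {c: [] for c in config.chrom_names}
    rows = []
    site_idx = 0
    for sf_name, sf in sorted(config.te_superfamilies.items()):
        families = fam_by_sf[sf_name]
        cats = list(sf.category_weights)
        weights = np.array([sf.category_weights[c] for c in cats])
        for j in range(sf.n_insertions):
            family = families[j % len(families)]
            placed_ok = False
            for _ in range(200):
                cat = cats[int(rng.choice(len(cats), p=weights / weights.sum()))]
                avail = [(c, len(positions(c, cat)))
                         for c in config.chrom_names]
                total = sum(n for _c, n in avail)
                if total == 0:
                    continue
                r = int(rng.integers(0, total))
                for chrom, n in avail:
                    if r < n:
                        pos = int(positions(chrom, cat)[r])
                        break
                    r -= n
                if any(abs(pos - q) < config.min_insertion_spacing
                       for q in chosen[chrom]):
                    continue
                chosen[chrom].append(pos)
                placed_ok = True
                break
            if not placed_ok:
                raise ValueError("could not place insertion; reduce counts or "
                                 "spacing")
            base_f = float(np.clip(rng.beta(*config.af_beta), 0.004, 0.95))
            f2, f4 = _selected_frequencies(rng, config, base_f, cat, family)
            rows.append((f"ins{site_idx:04d}", chrom, pos, family, sf_name,
                         sf.tsd_length, cat,
                         category_map.gene_at(chrom, pos),
                         category_map.distance_at(chrom, pos),
                         f2, f4))
            site_idx += 1

    insertions = pd.DataFrame(rows, columns=[
        "site_id", "chrom", "pos", "family", "superfamily", "tsd_len",
        "category", "nearest_gene", "gene_distance", "f_2x", "f_4x"])
    insertions = insertions.sort_values(["chrom", "pos"]).reset_index(drop=True)

    ploidies = samples["ploidy"].to_numpy()
    dosage = np.zeros((len(insertions), len(samples)), dtype=np.int8)
    for i, ins in enumerate(insertions.itertuples()):
        for ploidy, f in ((2, ins.f_2x), (4, ins.f_4x)):
            cols = np.flatnonzero(ploidies == ploidy)
            if not len(cols) or f <= 0:
                continue
            p = carrier_to_allele(f, ploidy)
            dosage[i, cols] = rng.binomial(ploidy, p, size=len(cols))
    dosages = pd.DataFrame(dosage, index=insertions["site_id"],
                           columns=samples["id"])
    return TruthSet(insertions=insertions, dosages=dosages, samples=samples,
                    te_library=library, config=config)


def truth_states(truth: TruthSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site table + C/N state matrix straight from true dosages.

    Restricted to insertions with at least one carrier (sites nobody
    carries are undetectable by definition).  Used to exercise the
    population-level statistics without read simulation.
    """
    from .detect import selection_type

    carriers = (truth.dosages >= 1)
    keep = carriers.any(axis=1)
    sites = truth.insertions.loc[keep.to_numpy()].copy()
    sites["selection_type"] = sites["superfamily"].map(selection_type)
    states = pd.DataFrame(np.where(carriers.loc[keep], "C", "N"),
                          index=carriers.index[keep], columns=carriers.columns)
    sites["carrier_freq"] = carriers.loc[keep].mean(axis=1).to_numpy()
    return sites.reset_index(drop=True), states


# ---------------------------------------------------------------------------
# Reads


def _merge_windows(wins: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(wins):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(w) for w in out]


def simulate_reads(truth: TruthSet, sequences: dict[str, str],
                   config: SimConfig, out_dir,
                   individuals: list[str] | None = None,
                   ) -> tuple[dict[str, str], pd.DataFrame]:
    """Write one coordinate-sorted, indexed BAM per individual.

    Carried insertions produce junction reads soft-clipped at the
    breakpoint (clipped portion = TE terminus), discordant pairs whose
    TE-internal mate is emitted unmapped, and a duplicated target site;
    non-carrier haplotypes give uninterrupted coverage.  In the default
    ``focused`` read mode, pairs are only generated within ``focus_pad``
    of planted insertion positions (identical evidence, far less I/O);
    ``genome`` mode covers whole chromosomes.

    Returns (paths by individual, junction log with the per-site,
    per-individual counts of emitted up/down/discordant evidence reads).
    """
    if config.read_length >= config.insert_size_mean - 2 * config.insert_size_sd:
        raise ValueError("read length too close to fragment length")
    os.makedirs(out_dir, exist_ok=True)
    lib_seq = {fam: seq for fam, _sf, seq in truth.te_library}
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(sequences[c])} for c in sequences],
    })
    tid = {c: i for i, c in enumerate(sequences)}
    samples = truth.samples
    if individuals is None:
        individuals = samples["id"].tolist()
    ins_by_chrom = {
        c: df.sort_values("pos").reset_index(drop=True)
        for c, df in truth.insertions.groupby("chrom")
    }
    paths: dict[str, str] = {}
    jlog: dict[tuple[str, str, str], int] = {}

    for ind_i, ind_id in enumerate(individuals):
        row = samples.loc[samples["id"] == ind_id].iloc[0]
        ploidy, cov = int(row["ploidy"]), float(row["coverage"])
        rng = _rng(config, _S_READS, ind_i)
        path = os.path.join(out_dir, f"{ind_id}.bam")
        records: list[tuple[int, int, pysam.AlignedSegment]] = []
        read_no = 0
        for chrom, seq in sequences.items():
            ins = ins_by_chrom.get(chrom)
            ins_pos = (ins["pos"].to_numpy() if ins is not None
                       else np.array([], dtype=int))
            if config.read_mode == "focused":
                if not len(ins_pos):
                    continue
                wins = _merge_windows([
                    (max(0, p - config.focus_pad),
                     min(len(seq), p + config.focus_pad))
                    for p in ins_pos])
            else:
                wins = [(0, len(seq))]
            for w0, w1 in wins:
                read_no = _emit_window(
                    records, jlog, rng, config, truth, ind_id, ploidy, cov,
                    chrom, tid[chrom], seq, ins, ins_pos, w0, w1, lib_seq,
                    header, read_no)
        records.sort(key=lambda t: (t[0], t[1]))
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for _t, _p, rec in records:
                bam.write(rec)
        pysam.index(path)
        paths[ind_id] = path

    log = pd.DataFrame(
        [(s, i, k, n) for (s, i, k), n in sorted(jlog.items())],
        columns=["site_id", "individual", "kind", "count"])
    return paths, log


def _emit_window(records, jlog, rng, config, truth, ind_id, ploidy, cov,
                 chrom, tid, seq, ins, ins_pos, w0, w1, lib_seq, header,
                 read_no) -> int:
    rl = config.read_length
    ins_mean = config.insert_size_mean
    dosage = truth.dosages
    # partition the window at midpoints between insertions; spacing >=
    # min_insertion_spacing guarantees a fragment touches at most one
    cuts = [w0]
    if len(ins_pos) > 1:
        mids = (ins_pos[:-1] + ins_pos[1:]) // 2
        cuts += [int(m) for m in mids if w0 < m < w1]
    cuts.append(w1)
    sub_ins = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        if len(ins_pos):
            k = int(np.argmin(np.abs(ins_pos - (a + b) // 2)))
            sub_ins.append((a, b, ins.iloc[k]))
        else:
            sub_ins.append((a, b, None))

    for a, b, site in sub_ins:
        d = int(dosage.at[site["site_id"], ind_id]) if site is not None else 0
        hap_frac = d / ploidy
        lots = []
        lr = (b - a) + ins_mean
        n_ref = rng.poisson(cov * (1 - hap_frac) * lr / (2.0 * rl))
        lots.append(("ref", n_ref, a - ins_mean, b))
        if d > 0:
            te = lib_seq[site["family"]]
            tsd = int(site["tsd_len"])
            lh = lr + tsd + len(te)
            n_hap = rng.poisson(cov * hap_frac * lh / (2.0 * rl))
            lots.append(("hap", n_hap, a - ins_mean, b + tsd + len(te)))
        for hap_kind, n, lo, hi in lots:
            if n <= 0 or hi <= lo:
                continue
            starts = rng.integers(lo, hi, size=n)
            frag_lens = np.clip(
                rng.normal(ins_mean, config.insert_size_sd,
                           size=n).round().astype(int), rl + 10, None)
            for fs, flen in zip(starts, frag_lens):
                fs, flen = int(fs), int(flen)
                if hap_kind == "hap":
                    reads = _hap_pair(fs, flen, rl, int(site["pos"]),
                                      int(site["tsd_len"]),
                                      lib_seq[site["family"]], seq)
                else:
                    reads = _ref_pair(fs, flen, rl, seq)
                if reads is None:
                    continue
                (s1, cig1, seq1, kind1), (s2, cig2, seq2, kind2) = reads
                if kind1 == "te" and kind2 == "te":
                    continue
                read_no += 1
                recs = _pair_records(f"r{ind_id}_{read_no}", tid,
                                     s1, cig1, seq1, kind1,
                                     s2, cig2, seq2, kind2, rl, header)
                if recs is None:
                    continue
                if config.sequencing_error_rate > 0:
                    for rec in recs:
                        rec.query_sequence = _mutate(
                            rng, rec.query_sequence,
                            config.sequencing_error_rate)
                        rec.query_qualities = \
                            pysam.qualitystring_to_array("I" * rl)
                for rec in recs:
                    records.append((rec.reference_id, rec.reference_start,
                                    rec))
                if site is not None:
                    _log_junctions(jlog, site["site_id"], ind_id, rl,
                                   ((cig1, kind1), (cig2, kind2)))
    return read_no


def _log_junctions(jlog, site_id, ind_id, rl, read_kinds) -> None:
    """Book-keep evidence reads usable by the caller (clip >= 20 bp)."""
    for cig, kind in read_kinds:
        if kind in ("up", "down"):
            clip = min(int(x) for x in
                       cig.replace("M", " ").replace("S", " ").split())
            if clip >= 20:
                key = (site_id, ind_id, kind)
                jlog[key] = jlog.get(key, 0) + 1
        elif kind == "te":
            key = (site_id, ind_id, "disc")
            jlog[key] = jlog.get(key, 0) + 1


def _ref_pair(fs, flen, rl, seq):
    fe = fs + flen
    if fs < 0 or fe > len(seq):
        return None
    return ((fs, f"{rl}M", seq[fs:fs + rl], "M"),
            (fe - rl, f"{rl}M", seq[fe - rl:fe], "M"))


def _hap_pair(hs, flen, rl, pos, tsd, te, seq):
    """Fragment on the insertion haplotype; coordinates are haplotype-space.

    Haplotype = ref[:pos+tsd] + TE + ref[pos:], duplicating the
    target-site sequence ref[pos:pos+tsd] on both sides of the element.
    """
    j1, j2 = pos + tsd, pos + tsd + len(te)
    hap_len = len(seq) + tsd + len(te)
    he = hs + flen
    if hs < 0 or he > hap_len:
        return None

    def hap_slice(a, b):
        parts = []
        if a < j1:
            parts.append(seq[a:min(b, j1)])
        if b > j1 and a < j2:
            parts.append(te[max(a, j1) - j1:min(b, j2) - j1])
        if b > j2:
            parts.append(seq[pos + max(a, j2) - j2:pos + b - j2])
        return "".join(parts)

    def align(a, b):
        if b <= j1:
            return a, f"{rl}M", "M"
        if a >= j2:
            return a - tsd - len(te), f"{rl}M", "M"
        if a < j1:  # crosses the upstream junction
            matched, clip = j1 - a, b - j1
            if matched >= 20 and clip <= len(te):
                return a, f"{matched}M{clip}S", "up"
            return None, None, "te"
        if b > j2:  # crosses the downstream junction
            clip, matched = j2 - a, b - j2
            if matched >= 20:
                return pos, f"{clip}S{matched}M", "down"
            return None, None, "te"
        return None, None, "te"  # fully inside the element

    out = []
    for a, b in ((hs, hs + rl), (he - rl, he)):
        start, cig, kind = align(a, b)
        out.append((start, cig, hap_slice(a, b), kind))
    return tuple(out)


def _pair_records(name, tid, s1, cig1, seq1, kind1, s2, cig2, seq2, kind2,
                  rl, header):
    a = pysam.AlignedSegment(header)
    b = pysam.AlignedSegment(header)
    for rec, (start, cig, seq, kind), is_r2, mate in (
            (a, (s1, cig1, seq1, kind1), False, (s2, kind2)),
            (b, (s2, cig2, seq2, kind2), True, (s1, kind1))):
        rec.query_name = name
        rec.query_sequence = seq
        rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        rec.reference_id = tid
        rec.is_paired = True
        rec.is_read2 = is_r2
        rec.is_read1 = not is_r2
        rec.is_reverse = is_r2
        rec.mate_is_reverse = not is_r2
        mate_start, mate_kind = mate
        if kind == "te":
            rec.is_unmapped = True
            rec.reference_start = mate_start if mate_kind != "te" else 0
            rec.cigarstring = None
        else:
            rec.reference_start = start
            rec.cigarstring = cig
            rec.mapping_quality = 60
        if mate_kind == "te":
            rec.mate_is_unmapped = True
            rec.next_reference_id = tid
            rec.next_reference_start = start if kind != "te" else 0
        else:
            rec.next_reference_id = tid
            rec.next_reference_start = mate_start
    if a.is_unmapped and b.is_unmapped:
        return None
    if not a.is_unmapped and not b.is_unmapped:
        tlen = max(a.reference_start + rl, b.reference_start + rl) - \
            min(a.reference_start, b.reference_start)
        a.template_length = tlen if a.reference_start <= b.reference_start \
            else -tlen
        b.template_length = -a.template_length
        if kind1 == "M" and kind2 == "M":
            a.is_proper_pair = True
            b.is_proper_pair = True
    return a, b


def _mutate(rng, seq, rate):
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hits):
        arr[hits] = _BASES[rng.integers(0, 4, size=len(hits))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(truth: TruthSet, annotation: GenomeAnnotation,
                        config: SimConfig) -> pd.DataFrame:
    """Genes x individuals expression with cis insertion effects.

    Each gene gets a log-normal baseline; individuals carrying an
    insertion within the gene or <250 bp from it have that gene's
    expression multiplied by ``expression_effect``.  Insertions >=2 kb
    away have no effect.
    """
    rng = _rng(config, _S_EXPR)
    genes = annotation.genes["gene_id"].tolist()
    baseline = pd.Series(
        rng.lognormal(mean=np.log(100.0), sigma=0.6, size=len(genes)),
        index=genes)
    truth.gene_baseline = baseline
    ins = truth.insertions
    affected = ins[(ins["category"].isin(GENIC_NEAR))
                   & (ins["nearest_gene"].notna())]
    carrier = (truth.dosages >= 1)
    n_ind = len(truth.samples)
    expr = baseline.to_numpy()[:, None] * np.exp(
        rng.normal(0.0, config.expression_noise_sd, size=(len(genes), n_ind)))
    gene_row = {g: i for i, g in enumerate(genes)}
    for site in affected.itertuples():
        gi = gene_row.get(site.nearest_gene)
        if gi is None:
            continue
        mask = carrier.loc[site.site_id].to_numpy()
        expr[gi, mask] *= config.expression_effect
    return pd.DataFrame(expr, index=genes, columns=truth.samples["id"])
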