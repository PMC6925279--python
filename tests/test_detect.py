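"""Insertion caller: candidate extraction, TE assignment, clustering,
support filter, state semantics, naming."""

import numpy as np
import pandas as pd
import pysam
import pytest

from polyte import detect
from polyte.config import DetectParams

from conftest import detectable_sites


def _write_bam(path, reads, sorted_header=True, index=True, ref_len=10_000):
    header = {"HD": {"VN": "1.6",
                     "SO": "coordinate" if sorted_header else "unsorted"},
              "SQ": [{"SN": "chr1", "LN": ref_len}]}
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for name, flag, pos, cigar, seq in sorted(reads, key=lambda r: r[2]):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.mapping_quality = 60
            bam.write(a)
    if index:
        pysam.index(str(path))
    return path


class TestExtractCandidates:
    def test_soft_clip_definitions(self, tmp_path):
        reads = [
            ("r1", 0, 1000, "80M20S", "A" * 100),   # up candidate
            ("r2", 0, 1100, "25S75M", "C" * 100),   # down candidate
            ("r3", 0, 1200, "100M", "G" * 100),     # plain match: excluded
            ("r4", 0, 1300, "85M15S", "T" * 100),   # clip below threshold
        ]
        bam = _write_bam(tmp_path / "x.bam", reads)
        cands = detect.extract_candidates(bam, min_clip=20)
        assert set(cands["side"]) == {"up", "down"}
        up = cands[cands["side"] == "up"].iloc[0]
        assert up["anchor"] == 1080  # reference end of the 80M segment
        down = cands[cands["side"] == "down"].iloc[0]
        assert down["anchor"] == 1100

    def test_unsorted_or_unindexed_input_rejected(self, tmp_path):
        reads = [("r1", 0, 100, "100M", "A" * 100)]
        bam1 = _write_bam(tmp_path / "u.bam", reads, sorted_header=False)
        with pytest.raises(ValueError, match="sorted"):
            detect.extract_candidates(bam1)
        bam2 = _write_bam(tmp_path / "n.bam", reads, index=False)
        with pytest.raises(ValueError, match="index"):
            detect.extract_candidates(bam2)

    def test_empty_file_gives_empty_set(self, tmp_path):
        bam = _write_bam(tmp_path / "e.bam", [])
        assert detect.extract_candidates(bam).empty


class TestAssignTe:
    LIB = [("famA", "Copia", "ACGTACGTGGCCAATTCCGGAAGGTTCCAACCGGTTAAGGCCTT"
            "ACGTTGCA" * 3),
           ("famB", "LINE", "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAATTTTGGGGCCCC"
            "GGCCTTAA" * 3)]

    def test_exact_terminus_hit(self):
        clip = self.LIB[0][2][:25]
        cands = pd.DataFrame([("chr1", 500, "up", clip, "r1")],
                             columns=["chrom", "anchor", "side", "seq",
                                      "read"])
        out = detect.assign_te(cands, self.LIB)
        assert len(out) == 1
        assert out.iloc[0]["family"] == "famA"
        assert out.iloc[0]["identity"] == 1.0
        assert not out.iloc[0]["ambiguous"]

    def test_high_identity_single_hit_assigned(self):
        clip = list(self.LIB[1][2][10:50])
        clip[5] = "A" if clip[5] != "A" else "C"  # one mismatch: 97.5%
        cands = pd.DataFrame([("chr1", 500, "down", "".join(clip), "r1")],
                             columns=["chrom", "anchor", "side", "seq",
                                      "read"])
        out = detect.assign_te(cands, self.LIB)
        assert out.iloc[0]["family"] == "famB"
        assert out.iloc[0]["identity"] >= 0.9

    def test_no_hit_dropped(self):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 40))
        cands = pd.DataFrame([("chr1", 500, "up", junk, "r1")],
                             columns=["chrom", "anchor", "side", "seq",
                                      "read"])
        assert detect.assign_te(cands, self.LIB).empty

    def test_equal_best_flagged_ambiguous(self):
        lib = [("fam1", "Copia", self.LIB[0][2]),
               ("fam2", "Gypsy", self.LIB[0][2])]
        cands = pd.DataFrame([("chr1", 500, "up", self.LIB[0][2][:30], "r1")],
                             columns=["chrom", "anchor", "side", "seq",
                                      "read"])
        out = detect.assign_te(cands, lib)
        assert out.iloc[0]["family"] == "fam1"  # first in library order
        assert out.iloc[0]["ambiguous"]

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            detect.assign_te(pd.DataFrame(), [])


class TestDefineSites:
    def _assigned(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "anchor", "side", "read",
                                           "family", "superfamily",
                                           "identity", "ambiguous"])

    def test_same_family_anchors_cluster(self):
        a = self._assigned([
            ("chr1", 1000, "up", "r1", "famA", "Copia", 1.0, False),
            ("chr1", 1000, "up", "r2", "famA", "Copia", 1.0, False),
            ("chr1", 1005, "down", "r3", "famA", "Copia", 1.0, False)])
        sites = detect.define_sites(a)
        assert len(sites) == 1
        s = sites.iloc[0]
        assert (s["split_up"], s["split_down"]) == (2, 1)
        assert (s["start"], s["end"]) == (1000, 1006)

    def test_different_families_stay_separate(self):
        a = self._assigned([
            ("chr1", 1000, "up", "r1", "famA", "Copia", 1.0, False),
            ("chr1", 1005, "down", "r2", "famB", "LINE", 1.0, False)])
        assert len(detect.define_sites(a)) == 2

    def test_anchors_beyond_window_split(self):
        a = self._assigned([
            ("chr1", 1000, "up", "r1", "famA", "Copia", 1.0, False),
            ("chr1", 1150, "down", "r2", "famA", "Copia", 1.0, False)])
        assert len(detect.define_sites(a, cluster_window=100)) == 2

    def test_discordant_attached_to_nearest_site(self):
        a = self._assigned([
            ("chr1", 1000, "up", "r1", "famA", "Copia", 1.0, False),
            ("chr1", 1005, "down", "r2", "famA", "Copia", 1.0, False),
            ("chr1", 1200, "disc", "r3", "famA", "Copia", 1.0, False),
            ("chr1", 9000, "disc", "r4", "famA", "Copia", 1.0, False)])
        sites = detect.define_sites(a, discordant_window=500)
        assert len(sites) == 1
        assert sites.iloc[0]["discordant"] == 1  # far one unattached


class TestSupportAndStates:
    SAMPLES = pd.DataFrame({
        "id": ["d1", "d2", "d3", "t1", "t2", "t3"],
        "population": ["p"] * 6,
        "clade": ["c2"] * 3 + ["c4"] * 3,
        "ploidy": [2, 2, 2, 4, 4, 4],
        "coverage": [8.0] * 6,
    })

    def _per_individual(self):
        """Micro-cohort: 4 candidate sites, hand-written evidence."""
        rows = []

        def site(ind, start, fam, up, down, disc):
            rows.append(("chr1", fam, "Copia", start, start + 6, up, down,
                         disc, ind))

        site("d1", 1000, "famA", 2, 1, 0)   # meets the rule (2up+1down)
        site("d2", 2000, "famA", 3, 0, 0)   # 3 reads but no downstream
        site("d3", 3000, "famA", 1, 1, 0)   # only 2 reads
        site("t1", 4000, "famA", 2, 1, 1)   # meets the rule with discordant
        return pd.DataFrame(rows, columns=["chrom", "family", "superfamily",
                                           "start", "end", "split_up",
                                           "split_down", "discordant",
                                           "individual"])

    def test_support_rule_boundaries(self):
        assert detect.support_ok(2, 1, 0)
        assert not detect.support_ok(3, 0, 0)
        assert not detect.support_ok(1, 1, 0)
        assert detect.support_ok(1, 1, 1)

    def test_micro_fixture_exact_state_matrix(self):
        """Hand-built evidence yields the exact expected C/N/NA matrix,
        exercising the negative-coverage boundaries 4/5/100/101."""
        sites, evidence = detect.intersect_sites(self._per_individual())
        # only the two supported sites survive
        assert len(sites) == 2
        assert sorted(sites["start"]) == [1000, 4000]
        s1 = sites.loc[sites["start"] == 1000, "site_id"].iloc[0]
        s2 = sites.loc[sites["start"] == 4000, "site_id"].iloc[0]
        neg = {
            # site 1: boundary negative coverages around both cut-offs
            (s1, "d1"): 50, (s1, "d2"): 4, (s1, "d3"): 5,
            (s1, "t1"): 100, (s1, "t2"): 101, (s1, "t3"): 50,
            # site 2: everyone well-covered
            (s2, "d1"): 10, (s2, "d2"): 10, (s2, "d3"): 10,
            (s2, "t1"): 10, (s2, "t2"): 10, (s2, "t3"): 10,
        }
        ev = evidence.set_index(["site_id", "individual"])
        full = []
        for (sid, ind), nc in neg.items():
            if (sid, ind) in ev.index:
                r = ev.loc[(sid, ind)]
                u, d, c = int(r["split_up"]), int(r["split_down"]), \
                    int(r["discordant"])
            else:
                u = d = c = 0
            full.append((sid, ind, u, d, c, nc))
        evidence = pd.DataFrame(full, columns=["site_id", "individual",
                                               "split_up", "split_down",
                                               "discordant", "neg_cov"])
        out_sites, states = detect.assign_states(sites, evidence,
                                                 self.SAMPLES)
        expected = pd.DataFrame(
            [["C", "NA", "N", "N", "NA", "N"],
             ["N", "N", "N", "C", "N", "N"]],
            index=[s1, s2], columns=["d1", "d2", "d3", "t1", "t2", "t3"])
        pd.testing.assert_frame_equal(
            states.sort_index(), expected.sort_index(), check_names=False)
        freq = out_sites.set_index("site_id")["carrier_freq"]
        assert freq[s1] == pytest.approx(1 / 4)   # 1 C over 4 non-NA
        assert freq[s2] == pytest.approx(1 / 6)

    def test_missing_individual_is_an_error(self):
        sites, evidence = detect.intersect_sites(self._per_individual())
        evidence["neg_cov"] = 10
        with pytest.raises(KeyError, match="d2"):
            detect.assign_states(sites, evidence, self.SAMPLES)

    def test_na_rule_conjunctive_vs_disjunctive(self):
        sites, evidence = detect.intersect_sites(self._per_individual())
        # everyone NA except the carriers: 2 NA diploids + 3 NA tetraploids
        # at site 1 (limit at this cohort size is ceil(0.1*3) = 1)
        full = []
        for sid in sites["site_id"]:
            for ind in self.SAMPLES["id"]:
                hit = evidence[(evidence["site_id"] == sid)
                               & (evidence["individual"] == ind)]
                u, d, c = (int(hit.iloc[0]["split_up"]),
                           int(hit.iloc[0]["split_down"]),
                           int(hit.iloc[0]["discordant"])) if len(hit) \
                    else (0, 0, 0)
                nc = 10 if sid == sites["site_id"].iloc[1] else 2
                full.append((sid, ind, u, d, c, nc))
        ev = pd.DataFrame(full, columns=["site_id", "individual", "split_up",
                                         "split_down", "discordant",
                                         "neg_cov"])
        out_and, _ = detect.assign_states(sites, ev, self.SAMPLES,
                                          DetectParams(na_rule="and"))
        assert len(out_and) == 1  # the all-NA-ish site removed
        # disjunctive reading removes it too (both groups exceed);
        # a site failing only one group differs between readings
        ev2 = ev.copy()
        d_ids = {"d1", "d2", "d3"}
        ev2.loc[(ev2["site_id"] == sites["site_id"].iloc[0])
                & (ev2["individual"].isin(d_ids)), "neg_cov"] = 10
        out_and2, _ = detect.assign_states(sites, ev2, self.SAMPLES,
                                           DetectParams(na_rule="and"))
        out_or2, _ = detect.assign_states(sites, ev2, self.SAMPLES,
                                          DetectParams(na_rule="or"))
        assert len(out_and2) == 2 and len(out_or2) == 1

    def test_states_partition_cohort(self, small_bundle):
        res = detect.detect_pipeline(small_bundle["bam_paths"],
                                     small_bundle["truth"].te_library,
                                     small_bundle["truth"].samples)
        states = res["states"]
        n = len(small_bundle["truth"].samples)
        assert (states.isin(["C", "N", "NA"]).all(axis=None))
        assert (states.notna().sum(axis=1) == n).all()
        # every retained site has >= 1 carrier
        assert ((states == "C").sum(axis=1) >= 1).all()


class TestNaming:
    def _sites(self):
        return pd.DataFrame({
            "site_id": ["s1", "s2", "s3"],
            "chrom": ["chr1"] * 3,
            "start": [100, 500, 900],
            "end": [110, 510, 910],
            "family": ["famA", "famA", "famB"],
            "superfamily": ["Mariner", "Mariner", "LINE"],
            "selection_type": ["B", "B", "B"],
        })

    def test_synthetic_names_without_annotation(self):
        named = detect.name_sites(self._sites())
        assert named["name"].tolist() == ["Mariner_new-1", "Mariner_new-2",
                                          "LINE_new-3"]

    def test_known_names_and_duplicate_suffixes(self):
        known = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [90, 490],
            "end": [120, 520], "name": ["ALLINE1_2", "ALLINE1_2"]})
        named = detect.name_sites(self._sites(), known)
        assert named["name"].tolist() == ["ALLINE1_2.1", "ALLINE1_2.2",
                                          "LINE_new-3"]


class TestEndToEnd:
    def test_recall_and_fdr_on_synthetic_cohort(self, small_bundle):
        truth = small_bundle["truth"]
        res = detect.detect_pipeline(small_bundle["bam_paths"],
                                     truth.te_library, truth.samples)
        detectable = detectable_sites(small_bundle["jlog"])
        m_support = detect.match_to_truth(res["sites_support"],
                                          truth.insertions)
        found = set(m_support["truth_id"].dropna())
        assert len(found & detectable) / len(detectable) >= 0.9
        m_final = detect.match_to_truth(res["sites"], truth.insertions)
        assert m_final["truth_id"].isna().mean() <= 0.05

    def test_no_false_carrier_states(self, small_bundle):
        """A called carrier always truly has dosage >= 1 (error-free reads)."""
        truth = small_bundle["truth"]
        res = detect.detect_pipeline(small_bundle["bam_paths"],
                                     truth.te_library, truth.samples)
        m = detect.match_to_truth(res["sites"], truth.insertions)
        states = res["states"]
        for r in m.dropna(subset=["truth_id"]).itertuples():
            dosage = truth.dosages.loc[r.truth_id]
            for ind, state in states.loc[r.site_id].items():
                if state == "C":
                    assert dosage[ind] >= 1
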