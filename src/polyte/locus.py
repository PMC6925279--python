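"""Targeted presence/absence genotyping of one known insertion allele.

Reads are compared against two references — with and without the
insertion.  A read *bridging* an insertion extremity (aligned
contiguously across it with >= 20 bp on both sides) proves presence;
with no bridging read, >= 4 reads spanning the target-site duplication
(TSD) on the insertion-free reference prove absence; anything else is NA.
This mirrors targeted re-genotyping of a locus (such as a retroelement
inserted in an exon) where whole-genome calling is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

_REVCOMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _rc(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass
class AlleleRefs:
    """The two allele references of one insertion locus.

    ``insertion_interval`` is the inserted sequence on ``with_seq``
    (0-based half-open); ``tsd_interval`` the target-site duplication on
    ``without_seq``.  Removing the insertion from ``with_seq`` must give
    back ``without_seq`` up to the TSD duplication, i.e.
    with = without[:tsd_end] + TE + without[tsd_start:].
    """

    with_seq: str
    without_seq: str
    insertion_interval: tuple[int, int]
    tsd_interval: tuple[int, int]

    def validate(self) -> None:
        a, b = self.insertion_interval
        ts, te = self.tsd_interval
        if not (0 <= a < b <= len(self.with_seq)):
            raise ValueError("insertion interval outside the WITH reference")
        if not (0 <= ts <= te <= len(self.without_seq)):
            raise ValueError("TSD interval outside the WITHOUT reference")
        if self.with_seq[:a] != self.without_seq[:te] or \
                self.with_seq[b:] != self.without_seq[ts:]:
            raise ValueError(
                "WITH reference minus the insertion does not equal the "
                "WITHOUT reference up to the TSD duplication")

    @classmethod
    def build(cls, without_seq: str, te_seq: str, tsd_start: int,
              tsd_len: int) -> "AlleleRefs":
        """Construct the WITH reference by inserting te_seq after the TSD."""
        te_end = tsd_start + tsd_len
        with_seq = (without_seq[:te_end] + te_seq + without_seq[tsd_start:])
        refs = cls(with_seq=with_seq, without_seq=without_seq,
                   insertion_interval=(te_end, te_end + len(te_seq)),
                   tsd_interval=(tsd_start, te_end))
        refs.validate()
        return refs


@dataclass
class LocusCall:
    call: str  # carrier | non-carrier | NA
    bridge_count: int
    tsd_count: int


def _spans(read: str, ref: str, point: int, flank: int,
           max_dist: int) -> bool:
    """Does the read align contiguously across ref[point] with >= flank
    bases on each side?"""
    window = ref[max(0, point - len(read) - 5):point + len(read) + 5]
    offset = max(0, point - len(read) - 5)
    for query in (read, _rc(read)):
        res = edlib.align(query, window, mode="HW", task="locations",
                          k=max_dist)
        if res["editDistance"] < 0:
            continue
        for start, end in res["locations"]:
            s, e = offset + start, offset + end + 1
            if s <= point - flank and e >= point + flank:
                return True
    return False


def call_locus(reads: list[str], refs: AlleleRefs, min_flank: int = 20,
               min_tsd_reads: int = 4,
               max_mismatch_frac: float = 0.05) -> LocusCall:
    """Carrier / non-carrier / NA call for one individual at one locus.

    carrier iff >= 1 read bridges either insertion extremity by
    >= ``min_flank`` bp on both sides; else non-carrier iff
    >= ``min_tsd_reads`` reads bridge the full TSD (plus >= 1 base each
    side) on the WITHOUT reference; else NA.  Strand- and
    read-order-invariant.
    """
    refs.validate()
    a, b = refs.insertion_interval
    ts, te = refs.tsd_interval
    bridge = 0
    tsd = 0
    for read in reads:
        max_dist = int(len(read) * max_mismatch_frac)
        if _spans(read, refs.with_seq, a, min_flank, max_dist) or \
                _spans(read, refs.with_seq, b, min_flank, max_dist):
            bridge += 1
        # TSD bridging: contiguous over the whole TSD plus one base per side
        window = refs.without_seq[max(0, ts - len(read) - 5):
                                  te + len(read) + 5]
        offset = max(0, ts - len(read) - 5)
        for query in (read, _rc(read)):
            res = edlib.align(query, window, mode="HW", task="locations",
                              k=max_dist)
            if res["editDistance"] < 0:
                continue
            if any(offset + s <= ts - 1 and offset + e + 1 >= te + 1
                   for s, e in res["locations"]):
                tsd += 1
                break
    if bridge >= 1:
        return LocusCall("carrier", bridge, tsd)
    if tsd >= min_tsd_reads:
        return LocusCall("non-carrier", bridge, tsd)
    return LocusCall("NA", bridge, tsd)


def simulate_locus_reads(refs: AlleleRefs, carrier: bool, coverage: float,
                         read_length: int = 100, seed: int = 0) -> list[str]:
    """Uniform error-free reads from one homozygous haplotype (validation
    helper)."""
    rng = np.random.default_rng(seed)
    ref = refs.with_seq if carrier else refs.without_seq
    n = int(round(coverage * len(ref) / read_length))
    reads = []
    for _ in range(n):
        s = int(rng.integers(0, max(1, len(ref) - read_length)))
        read = ref[s:s + read_length]
        if rng.random() < 0.5:
            read = _rc(read)
        reads.append(read)
    return reads
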