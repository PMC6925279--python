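"""Readers/writers for the formats the pipeline exchanges.

Coordinate conventions: everything in memory is 0-based half-open.
GFF3 is emitted/parsed 1-based inclusive, BED 0-based half-open, SAM/BAM
via pysam (which already presents 0-based coordinates).

TSV dialect used throughout: tab-separated, UTF-8, '.' decimal, header
line prefixed with '#'.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from pyfaidx import Fasta


@dataclass
class GenomeAnnotation:
    """Gene models, reference-TE annotation and centromeres for one genome."""

    chrom_lengths: dict[str, int]
    #: columns: gene_id, chrom, start, end, strand
    genes: pd.DataFrame
    #: columns: chrom, start, end, type, gene_id, strand; type in
    #: {exon, intron, five_prime_UTR, three_prime_UTR}
    features: pd.DataFrame
    #: columns: chrom, start, end, family, superfamily
    te_features: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["chrom", "start", "end", "family", "superfamily"]))
    #: chromosome -> centromere midpoint (bp)
    centromeres: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for df, cols in (
            (self.genes, ["gene_id", "chrom", "start", "end", "strand"]),
            (self.features, ["chrom", "start", "end", "type", "gene_id", "strand"]),
        ):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"annotation table missing columns {sorted(missing)}")
        for chrom in set(self.genes["chrom"]):
            if chrom not in self.chrom_lengths:
                raise ValueError(f"gene on unknown chromosome {chrom!r}")


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    fa = Fasta(str(path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_te_library(path, records: list[tuple[str, str, str]]) -> None:
    """Write a TE library FASTA; records are (family, superfamily, sequence)."""
    with open(path, "w") as fh:
        for family, superfamily, seq in records:
            fh.write(f">{family} superfamily={superfamily}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_te_library(path) -> list[tuple[str, str, str]]:
    """Read a TE library FASTA into (family, superfamily, sequence) tuples.

    The superfamily is taken from a ``superfamily=`` tag in the description
    line; absent that, from a ``family#superfamily`` naming convention;
    otherwise it defaults to the family name itself.
    """
    records: list[tuple[str, str, str]] = []
    name = None
    desc = ""
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append((name, _superfamily_of(name, desc), "".join(chunks)))
                parts = line[1:].split(None, 1)
                name = parts[0]
                desc = parts[1] if len(parts) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line.strip())
    if name is not None:
        records.append((name, _superfamily_of(name, desc), "".join(chunks)))
    return records


def _superfamily_of(name: str, desc: str) -> str:
    for token in desc.split():
        if token.startswith("superfamily="):
            return token.split("=", 1)[1]
    if "#" in name:
        return name.split("#", 1)[1]
    return name


# ---------------------------------------------------------------------------
# GFF3

_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_gff3(path, annotation: GenomeAnnotation) -> None:
    """Emit genes, their sub-features and reference TEs as GFF3 (1-based)."""
    rows = []
    for g in annotation.genes.itertuples():
        rows.append((g.chrom, "polyte", "gene", g.start + 1, g.end, ".", g.strand,
                     ".", f"ID={g.gene_id}"))
    for i, f in enumerate(annotation.features.itertuples()):
        rows.append((f.chrom, "polyte", f.type, f.start + 1, f.end, ".", f.strand,
                     ".", f"ID={f.gene_id}.{f.type}.{i};Parent={f.gene_id}"))
    for i, t in enumerate(annotation.te_features.itertuples()):
        rows.append((t.chrom, "polyte", "transposable_element", t.start + 1, t.end,
                     ".", "+", ".",
                     f"ID=te{i};Name={t.family};superfamily={t.superfamily}"))
    rows.sort(key=lambda r: (r[0], r[3], r[4]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in annotation.chrom_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_gff3(path, chrom_lengths: dict[str, int] | None = None,
              centromeres: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse a GFF3 file into a :class:`GenomeAnnotation`.

    Recognized feature types: ``gene``, ``exon``, ``intron``,
    ``five_prime_UTR``, ``three_prime_UTR``, ``transposable_element``.
    """
    seq_lengths: dict[str, int] = {}
    genes, feats, tes = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, chrom, _start, end = line.split()[:4]
                seq_lengths[chrom] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            tags = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                genes.append((tags.get("ID", f"gene{lineno}"), chrom, start_i,
                              end_i, strand))
            elif ftype in ("exon", "intron", "five_prime_UTR", "three_prime_UTR"):
                feats.append((chrom, start_i, end_i, ftype,
                              tags.get("Parent", "").split(",")[0], strand))
            elif ftype == "transposable_element":
                tes.append((chrom, start_i, end_i, tags.get("Name", "TE"),
                            tags.get("superfamily", "unknown")))
    ann = GenomeAnnotation(
        chrom_lengths=chrom_lengths or seq_lengths,
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                           "strand"]),
        features=pd.DataFrame(feats, columns=["chrom", "start", "end", "type",
                                              "gene_id", "strand"]),
        te_features=pd.DataFrame(tes, columns=["chrom", "start", "end", "family",
                                               "superfamily"]),
        centromeres=centromeres or {},
    )
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# BED

def write_bed(path, intervals: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_centromere_bed(path, centromeres: dict[str, int]) -> None:
    write_bed(path, [(c, p, p + 1, "centromere") for c, p in centromeres.items()])


def read_centromere_bed(path) -> dict[str, int]:
    return {chrom: start for chrom, start, _end, _name in read_bed(path)}


# ---------------------------------------------------------------------------
# TSV dialect

def write_tsv(path, df: pd.DataFrame) -> None:
    """Write a DataFrame in the house TSV dialect ('#'-prefixed header)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise ValueError(f"{path}:1: expected '#'-prefixed header line")
        names = header[1:].split("\t")
        return pd.read_csv(fh, sep="\t", names=names, **kwargs)


def write_sample_sheet(path, samples: pd.DataFrame) -> None:
    cols = ["id", "population", "clade", "ploidy", "coverage"]
    write_tsv(path, samples[cols])


def read_sample_sheet(path) -> pd.DataFrame:
    df = read_tsv(path)
    need = {"id", "population", "clade", "ploidy", "coverage"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    df["ploidy"] = df["ploidy"].astype(int)
    return df


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
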