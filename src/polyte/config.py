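"""Configuration objects for the synthetic cohort and the pipeline.

The synthetic dataset emulates a diploid/autotetraploid plant cohort
resequenced at low-to-moderate depth and aligned to a close-relative
reference: gene-dense chromosome arms, TE-dense pericentromeres, and
non-reference TE insertions from eight superfamilies segregating with
ploidy-dependent carrier-frequency spectra.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import yaml

#: Superfamilies with an apparent genic insertion preference ("type A").
TYPE_A = ("Copia", "Gypsy", "CACTA", "hAT")
#: Superfamilies depleted from exons at all frequencies ("type B").
TYPE_B = ("LINE", "Mariner", "MuDR", "Harbinger")
SUPERFAMILIES = TYPE_A + TYPE_B

#: Insertion-site categories, listed in decreasing annotation priority.
CATEGORIES = (
    "utr3",
    "utr5",
    "exon",
    "intron",
    "upstream250",
    "downstream250",
    "near2k",
    "intergenic",
)

#: Categories counted as "within or near (<250 bp) a gene".
GENIC_NEAR = ("utr3", "utr5", "exon", "intron", "upstream250", "downstream250")

_TYPE_A_WEIGHTS = {
    "exon": 0.25,
    "intron": 0.15,
    "utr5": 0.05,
    "utr3": 0.05,
    "upstream250": 0.08,
    "downstream250": 0.07,
    "near2k": 0.10,
    "intergenic": 0.25,
}
_TYPE_B_WEIGHTS = {
    "exon": 0.02,
    "intron": 0.12,
    "utr5": 0.04,
    "utr3": 0.04,
    "upstream250": 0.07,
    "downstream250": 0.06,
    "near2k": 0.15,
    "intergenic": 0.50,
}
_DEFAULT_COUNTS = {
    "Copia": 40,
    "Gypsy": 30,
    "CACTA": 20,
    "hAT": 15,
    "LINE": 30,
    "Mariner": 25,
    "MuDR": 20,
    "Harbinger": 20,
}


@dataclass
class SuperfamilyConfig:
    """Per-superfamily insertion plan.

    ``category_weights`` is the insertion-preference distribution over
    :data:`CATEGORIES` (must sum to 1); ``tsd_length`` the target-site
    duplication in bp.
    """

    name: str
    n_insertions: int
    category_weights: dict[str, float]
    n_families: int = 2
    tsd_length: int = 5
    te_length_range: tuple[int, int] = (600, 1500)

    def validate(self) -> None:
        if self.n_insertions < 0:
            raise ValueError(f"{self.name}: n_insertions must be >= 0")
        if self.n_families < 1:
            raise ValueError(f"{self.name}: n_families must be >= 1")
        total = sum(self.category_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(
                f"{self.name}: category weights sum to {total:.4f}, expected 1"
            )
        unknown = set(self.category_weights) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"{self.name}: unknown categories {sorted(unknown)}")
        if self.tsd_length < 0:
            raise ValueError(f"{self.name}: tsd_length must be >= 0")


@dataclass
class CladeConfig:
    label: str
    ploidy: int
    size: int
    n_populations: int = 2


def default_superfamilies() -> dict[str, SuperfamilyConfig]:
    out = {}
    for name in SUPERFAMILIES:
        weights = dict(_TYPE_A_WEIGHTS if name in TYPE_A else _TYPE_B_WEIGHTS)
        out[name] = SuperfamilyConfig(
            name=name, n_insertions=_DEFAULT_COUNTS[name], category_weights=weights
        )
    return out


@dataclass
class SimConfig:
    """Full specification of one synthetic cohort.

    Identical ``seed`` + config reproduce byte-identical outputs.
    """

    seed: int = 1

    # genome
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    centromere_pos: tuple[int, ...] | None = None  # default: midpoint
    pericentromere_halfwidth: int = 1_000_000
    n_genes: int = 400
    gene_arm_peri_density_ratio: float = 10.0
    n_reference_tes: int = 300
    te_arm_peri_density_ratio: float = 0.1  # reference TEs denser near centromeres

    # cohort
    n_individuals_2x: int = 20
    n_individuals_4x: int = 20
    clades: list[CladeConfig] | None = None
    coverage_range: tuple[float, float] = (2.8, 18.1)
    coverage_beta: tuple[float, float] = (2.0, 3.5)  # mean depth ~8.4X

    # sequencing
    read_length: int = 100
    insert_size_mean: int = 300
    insert_size_sd: int = 30
    sequencing_error_rate: float = 0.0
    read_mode: str = "focused"  # "focused" | "genome"
    focus_pad: int = 1000

    # insertions
    te_superfamilies: dict[str, SuperfamilyConfig] = field(
        default_factory=default_superfamilies
    )
    af_beta: tuple[float, float] = (0.4, 8.0)  # carrier-frequency spectrum shape
    min_insertion_spacing: int = 800
    selection_mode: str = "relaxed_in_4x"  # neutral | purifying | relaxed_in_4x
    exon_purge_prob: float = 0.35
    genic_purge_prob: float = 0.15
    genic_freq_factor: float = 0.7
    # selection only prunes young (low-frequency) insertions: variants above
    # this carrier frequency are treated as predating the ploidy split
    purge_freq_max: float = 0.1
    burst_family: str | None = None
    burst_freq_range: tuple[float, float] = (0.25, 0.6)

    # expression
    expression_effect: float = 0.5
    expression_noise_sd: float = 0.3
    near_gene_bp: int = 250

    def __post_init__(self) -> None:
        if self.centromere_pos is None:
            self.centromere_pos = tuple(
                self.chrom_length // 2 for _ in range(self.n_chromosomes)
            )
        else:
            self.centromere_pos = tuple(self.centromere_pos)
        if self.clades is None:
            self.clades = _default_clades(self.n_individuals_2x, self.n_individuals_4x)

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need >=1 chromosome of positive length")
        if len(self.centromere_pos) != self.n_chromosomes:
            raise ValueError("one centromere position per chromosome required")
        for pos in self.centromere_pos:
            if not 0 < pos < self.chrom_length:
                raise ValueError(f"centromere at {pos} outside chromosome")
        if self.selection_mode not in ("neutral", "purifying", "relaxed_in_4x"):
            raise ValueError(f"unknown selection_mode {self.selection_mode!r}")
        if self.read_mode not in ("focused", "genome"):
            raise ValueError(f"unknown read_mode {self.read_mode!r}")
        if self.read_length >= self.insert_size_mean:
            raise ValueError("read length must be shorter than the mean fragment")
        for sf in self.te_superfamilies.values():
            sf.validate()
        # rough footprint check: mean gene ~3 kb incl. flanks
        if self.n_genes * 3000 > 0.8 * self.n_chromosomes * self.chrom_length:
            raise ValueError("gene footprint exceeds chromosome capacity")
        n2 = sum(c.size for c in self.clades if c.ploidy == 2)
        n4 = sum(c.size for c in self.clades if c.ploidy == 4)
        if n2 != self.n_individuals_2x or n4 != self.n_individuals_4x:
            raise ValueError("clade sizes do not add up to the per-ploidy counts")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["te_superfamilies"] = {
            k: dataclasses.asdict(v) for k, v in self.te_superfamilies.items()
        }
        d["clades"] = [dataclasses.asdict(c) for c in self.clades]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "te_superfamilies" in d:
            d["te_superfamilies"] = {
                k: SuperfamilyConfig(**v) for k, v in d["te_superfamilies"].items()
            }
        if d.get("clades") is not None:
            d["clades"] = [CladeConfig(**c) for c in d["clades"]]
        for key in ("centromere_pos",):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        for key in (
            "coverage_range",
            "coverage_beta",
            "af_beta",
            "burst_freq_range",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(self.to_dict()), fh, sort_keys=False)


def _plain(obj):
    """Recursively convert tuples to lists for YAML round-tripping."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _default_clades(n2: int, n4: int) -> list[CladeConfig]:
    clades = []
    for ploidy, n, labels in ((2, n2, ("din", "wcarp")), (4, n4, ("rw", "salb"))):
        half = n // 2
        sizes = (half, n - half)
        for label, size in zip(labels, sizes):
            if size > 0:
                clades.append(CladeConfig(label=f"{label}{ploidy}x", ploidy=ploidy, size=size))
    return clades


@dataclass
class DetectParams:
    """Thresholds of the insertion caller."""

    min_clip: int = 20
    min_identity: float = 0.9
    min_match: int = 15
    cluster_window: int = 100
    discordant_window: int = 500
    min_support: int = 3
    neg_cov_min: int = 5
    neg_cov_max: int = 100
    na_max_2x: int | None = None  # default: ceil(0.1 * group size)
    na_max_4x: int | None = None
    na_rule: str = "and"  # "and" | "or" — how the two ploidy NA counts combine

    def validate(self) -> None:
        if self.na_rule not in ("and", "or"):
            raise ValueError("na_rule must be 'and' or 'or'")
        if self.neg_cov_min > self.neg_cov_max:
            raise ValueError("neg_cov_min must be <= neg_cov_max")
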