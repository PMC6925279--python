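"""Shared synthetic fixtures.

Everything is generated at test time from seeded configurations; the
small cohort (2 x 1 Mb genome, 10+10 individuals) backs the read-level
tests, the large population (100+100 individuals, no reads) backs the
statistics-level tests.
"""

from __future__ import annotations

import pandas as pd
import pytest

from polyte import simdata
from polyte.annotation import CategoryMap
from polyte.config import SimConfig, default_superfamilies


def small_config(seed: int = 1, **overrides) -> SimConfig:
    sfs = default_superfamilies()
    for sf in sfs.values():
        sf.n_insertions = max(4, sf.n_insertions // 4)
    kwargs = dict(
        seed=seed, n_chromosomes=2, chrom_length=1_000_000,
        pericentromere_halfwidth=150_000, n_genes=80, n_reference_tes=60,
        n_individuals_2x=10, n_individuals_4x=10, coverage_range=(8.0, 8.0),
        te_superfamilies=sfs,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def population_config(seed: int = 7, **overrides) -> SimConfig:
    """Larger cohort, truth-dosage level only (no reads)."""
    sfs = default_superfamilies()
    for sf in sfs.values():
        sf.n_insertions *= 3
        sf.n_families = 1
    kwargs = dict(
        seed=seed, n_chromosomes=2, chrom_length=2_000_000,
        pericentromere_halfwidth=300_000, n_genes=160, n_reference_tes=100,
        n_individuals_2x=100, n_individuals_4x=100, te_superfamilies=sfs,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def stats_config(seed: int = 7, **overrides) -> SimConfig:
    """Cross-ploidy statistics scale: many insertions, 100+100 individuals,
    truth-dosage level (no reads)."""
    sfs = default_superfamilies()
    for sf in sfs.values():
        sf.n_insertions *= 7
        sf.n_families = 1
    kwargs = dict(
        seed=seed, n_chromosomes=2, chrom_length=5_000_000,
        pericentromere_halfwidth=750_000, n_genes=400, n_reference_tes=200,
        n_individuals_2x=100, n_individuals_4x=100, te_superfamilies=sfs,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """Genome + truth + per-individual BAMs for the small cohort."""
    cfg = small_config()
    sequences, annotation = simdata.simulate_genome(cfg)
    catmap = CategoryMap(annotation)
    truth = simdata.simulate_population(cfg, annotation, catmap)
    bam_dir = tmp_path_factory.mktemp("bams")
    paths, jlog = simdata.simulate_reads(truth, sequences, cfg, bam_dir)
    return {
        "config": cfg, "sequences": sequences, "annotation": annotation,
        "catmap": catmap, "truth": truth, "bam_paths": paths, "jlog": jlog,
    }


@pytest.fixture(scope="session")
def pop_bundle():
    """Population-scale truth (relaxed selection in tetraploids)."""
    cfg = population_config()
    sequences, annotation = simdata.simulate_genome(cfg)
    catmap = CategoryMap(annotation)
    truth = simdata.simulate_population(cfg, annotation, catmap)
    sites, states = simdata.truth_states(truth)
    return {
        "config": cfg, "annotation": annotation, "catmap": catmap,
        "truth": truth, "sites": sites, "states": states,
    }


def detectable_sites(jlog: pd.DataFrame) -> set[str]:
    """Truth sites with >=3 caller-usable evidence reads (>=1 up, >=1 down)
    in at least one individual."""
    j = jlog.pivot_table(index=["site_id", "individual"], columns="kind",
                         values="count", fill_value=0,
                         aggfunc="sum").reset_index()
    for k in ("up", "down", "disc"):
        if k not in j:
            j[k] = 0
    ok = j[(j["up"] >= 1) & (j["down"] >= 1)
           & (j["up"] + j["down"] + j["disc"] >= 3)]
    return set(ok["site_id"].unique())
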