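from __future__ import annotations

from pathlib import Path

import pytest

from isoprimer.cli import RunConfig
from isoprimer.fixtures import Fixture, LocusSpec, make_locus


@pytest.fixture(scope="session")
def shared_locus() -> Fixture:
    """Three isoforms, one junction common to all (seed 42)."""
    return make_locus(LocusSpec(seed=42))


@pytest.fixture(scope="session")
def noshared_locus() -> Fixture:
    """Three isoforms with no junction common to all (seed 7)."""
    return make_locus(LocusSpec(seed=7, shared_junction=False, n_isoforms=3))


@pytest.fixture(scope="session")
def decoy_locus() -> Fixture:
    """Shared-junction locus plus a ~92%-identical paralog decoy."""
    return make_locus(LocusSpec(seed=42, decoy_paralog=True))


def write_config(fixture: Fixture, tmpdir: Path, **overrides) -> RunConfig:
    """Materialize a fixture and build a RunConfig pointing at it."""
    paths = fixture.write(tmpdir / "fixture")
    cfg = RunConfig(
        genome=str(paths["genome"]),
        gtf=str(paths["gtf"]),
        transcriptome=str(paths["transcriptome"]),
        quant_table=str(paths["quant"]),
        gene_list=str(paths["genes"]),
        outdir=str(tmpdir / "out"),
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def merge_fixtures(a: Fixture, b: Fixture, tmpdir: Path, gene_order: list[str]) -> RunConfig:
    """Concatenate two loci (distinct chromosomes/gene IDs) into one input set."""
    d = tmpdir / "merged"
    d.mkdir(parents=True, exist_ok=True)
    from isoprimer.fixtures import _fasta

    genome = {**a.genome, **b.genome}
    transcriptome = {**a.transcriptome, **b.transcriptome}
    (d / "genome.fa").write_text(_fasta(genome))
    (d / "transcriptome.fa").write_text(_fasta(transcriptome))
    (d / "annotation.gtf").write_text(a.gtf_text + b.gtf_text)
    b_body = b.quant_text.split("\n", 1)[1]
    (d / "kalcounts.tsv").write_text(a.quant_text + b_body)
    (d / "genes.txt").write_text("\n".join(gene_order) + "\n")
    return RunConfig(
        genome=str(d / "genome.fa"),
        gtf=str(d / "annotation.gtf"),
        transcriptome=str(d / "transcriptome.fa"),
        quant_table=str(d / "kalcounts.tsv"),
        gene_list=str(d / "genes.txt"),
        outdir=str(tmpdir / "out"),
    )
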