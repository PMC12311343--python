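"""Seeded synthetic loci: genome, GTF, transcriptome and quantification table.

Generates toy multi-isoform genes with controlled splicing structure so
every pipeline stage is testable offline. All four artifacts are mutually
consistent: each transcriptome record equals the sequence spliced from
the genome under the GTF. Generation is a pure function of the spec
(seed included): the same spec yields byte-identical files.

Structure control:

* ``shared_junction=True`` — every isoform contains the junction between
  the first two exons of the pool, so one junction-spanning pair can
  amplify all isoforms.
* ``shared_junction=False`` — isoform ``i`` skips pool exon ``i+1``, so
  no junction is present in every isoform and a multi-pair cover is
  required.
* ``decoy_paralog=True`` — a second gene on another chromosome whose
  exons are ~92% identical, which mismatch-tolerant in-silico PCR will
  hit, planting a guaranteed non-specific discard.

Default intron lengths start above 3200 nt so that a junction-spanning
pair's would-be genomic product always exceeds the default 3500-bp
amplicon cap, exercising the empty genomic-mismatch path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import GeneModel, TranscriptModel, to_gtf
from .thermo import revcomp

__all__ = ["LocusSpec", "Fixture", "make_locus", "corrupt"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SpecError(ValueError):
    """The locus spec cannot be realized."""


@dataclass(frozen=True)
class LocusSpec:
    gene_id: str = "GSYN1"
    n_isoforms: int = 3
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (3600, 5000)
    shared_junction: bool = True
    decoy_paralog: bool = False
    expression_profile: tuple[float, ...] | None = None
    tsl_values: tuple[int | None, ...] | None = None
    strand: str = "+"
    seed: int = 42
    chrom: str = "chr1"
    decoy_chrom: str = "chr2"
    decoy_identity: float = 0.92
    flank: int = 200
    n_samples: int = 2


@dataclass
class Fixture:
    spec: LocusSpec
    genome: dict[str, str]
    gtf_text: str
    transcriptome: dict[str, str]
    quant_text: str
    gene_ids: list[str]
    genes: list[GeneModel] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all artifacts as plain text files; returns the path map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "transcriptome": outdir / "transcriptome.fa",
            "quant": outdir / "kalcounts.tsv",
            "genes": outdir / "genes.txt",
        }
        paths["genome"].write_text(_fasta(self.genome))
        paths["gtf"].write_text(self.gtf_text)
        paths["transcriptome"].write_text(_fasta(self.transcriptome))
        paths["quant"].write_text(self.quant_text)
        paths["genes"].write_text("\n".join(self.gene_ids) + "\n")
        return paths


def _fasta(records: dict[str, str], width: int = 70) -> str:
    out: list[str] = []
    for name, seq in records.items():
        out.append(f">{name}")
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + "\n"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _isoform_structures(spec: LocusSpec) -> tuple[int, list[list[int]]]:
    """(exon pool size, exon-index list per isoform)."""
    n = spec.n_isoforms
    if n < 1:
        raise SpecError("n_isoforms must be >= 1")
    if spec.shared_junction:
        pool = max(3, n + 2)
        if pool < 2:
            raise SpecError("shared junction requires at least 2 exons")
        structures = [list(range(pool))]
        for i in range(1, n):
            structures.append([0, 1] + [e for e in range(2, pool) if e != i + 1])
    else:
        if n < 2:
            raise SpecError("a no-shared-junction locus needs at least 2 isoforms")
        pool = n + 1
        structures = [[e for e in range(pool) if e != i + 1] for i in range(n)]
    return pool, structures


def _default_profile(n: int) -> tuple[float, ...]:
    return tuple(round(100.0 / (i + 1), 2) for i in range(n))


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    flip = rng.random(arr.size) > identity
    for i in np.nonzero(flip)[0]:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii")


def _assemble_chromosome(
    rng: np.random.Generator, exon_seqs: list[str], spec: LocusSpec
) -> tuple[str, list[tuple[int, int]]]:
    """Lay exons on a chromosome with random introns; returns (seq, intervals)."""
    parts = [_random_seq(rng, spec.flank)]
    pos = spec.flank
    intervals: list[tuple[int, int]] = []
    for i, exon in enumerate(exon_seqs):
        if i > 0:
            intron_len = int(rng.integers(spec.intron_len_range[0], spec.intron_len_range[1] + 1))
            parts.append(_random_seq(rng, intron_len))
            pos += intron_len
        intervals.append((pos, pos + len(exon)))
        parts.append(exon)
        pos += len(exon)
    parts.append(_random_seq(rng, spec.flank))
    return "".join(parts), intervals


def _build_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    intervals: list[tuple[int, int]],
    chrom_seq: str,
    structures: list[list[int]],
    tsl_values: tuple[int | None, ...] | None,
) -> GeneModel:
    transcripts: list[TranscriptModel] = []
    for i, structure in enumerate(structures):
        exons = [intervals[e] for e in structure]
        seq = "".join(chrom_seq[s:e] for s, e in exons)
        if strand == "-":
            seq = revcomp(seq)
            exons = list(reversed(exons))
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{gene_id}_T{i + 1}",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=exons,
                spliced_seq=seq,
                tsl=tsl_values[i] if tsl_values else None,
            )
        )
    return GeneModel(gene_id=gene_id, transcripts=transcripts)


def make_locus(spec: LocusSpec = LocusSpec()) -> Fixture:
    """Generate a complete, mutually consistent synthetic locus."""
    if spec.tsl_values is not None and len(spec.tsl_values) != spec.n_isoforms:
        raise SpecError("tsl_values length must equal n_isoforms")
    profile = spec.expression_profile or _default_profile(spec.n_isoforms)
    if len(profile) != spec.n_isoforms:
        raise SpecError("expression_profile length must equal n_isoforms")
    rng = np.random.default_rng(spec.seed)
    pool, structures = _isoform_structures(spec)
    exon_seqs = [
        _random_seq(rng, int(rng.integers(spec.exon_len_range[0], spec.exon_len_range[1] + 1)))
        for _ in range(pool)
    ]
    chrom_seq, intervals = _assemble_chromosome(rng, exon_seqs, spec)
    gene = _build_gene(
        spec.gene_id, spec.chrom, spec.strand, intervals, chrom_seq, structures, spec.tsl_values
    )

    genome = {spec.chrom: chrom_seq}
    genes = [gene]
    transcriptome = {t.transcript_id: t.spliced_seq for t in gene.transcripts}
    quant_rows = [(t.transcript_id, profile[i]) for i, t in enumerate(gene.transcripts)]

    if spec.decoy_paralog:
        decoy_exons = [_mutate(rng, s, spec.decoy_identity) for s in exon_seqs]
        decoy_seq, decoy_intervals = _assemble_chromosome(rng, decoy_exons, spec)
        decoy = _build_gene(
            f"{spec.gene_id}_DEC", spec.decoy_chrom, "+", decoy_intervals, decoy_seq,
            [list(range(pool))], None,
        )
        genome[spec.decoy_chrom] = decoy_seq
        genes.append(decoy)
        for t in decoy.transcripts:
            transcriptome[t.transcript_id] = t.spliced_seq
            quant_rows.append((t.transcript_id, 1.0))

    header = "target_id\t" + "\t".join(f"sample{i + 1}" for i in range(spec.n_samples))
    lines = [header]
    for tid, tpm in quant_rows:
        lines.append(tid + "\t" + "\t".join(f"{tpm:g}" for _ in range(spec.n_samples)))
    quant_text = "\n".join(lines) + "\n"

    return Fixture(
        spec=spec,
        genome=genome,
        gtf_text=to_gtf(genes),
        transcriptome=transcriptome,
        quant_text=quant_text,
        gene_ids=[spec.gene_id],
        genes=genes,
    )


def corrupt(fixture: Fixture, mode: str, n_subs: int = 5) -> Fixture:
    """Plant a known defect for negative-path tests.

    Modes: ``mismatch_primer_site`` embeds a substituted copy of a 20-nt
    site from the first transcript in a decoy template;
    ``nonspecific_decoy`` regenerates the locus with a near-identical
    paralog; ``zero_expression`` zeroes the target gene's abundances.
    """
    if mode == "nonspecific_decoy":
        return make_locus(replace(fixture.spec, decoy_paralog=True))
    if mode == "zero_expression":
        lines = fixture.quant_text.rstrip("\n").split("\n")
        target_tids = {t.transcript_id for g in fixture.genes for t in g.transcripts
                       if g.gene_id == fixture.spec.gene_id}
        out = [lines[0]]
        for line in lines[1:]:
            tid = line.split("\t", 1)[0]
            if tid in target_tids:
                n_cols = len(line.split("\t")) - 1
                line = tid + "\t" + "\t".join("0" for _ in range(n_cols))
            out.append(line)
        return replace_fixture(fixture, quant_text="\n".join(out) + "\n")
    if mode == "mismatch_primer_site":
        rng = np.random.default_rng(fixture.spec.seed + 1)
        first = fixture.genes[0].transcripts[0]
        site = first.spliced_seq[50:70]
        arr = list(site)
        positions = rng.choice(len(site), size=min(n_subs, len(site)), replace=False)
        for p in sorted(int(x) for x in positions):
            arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
        mutated = "".join(arr)
        decoy_template = _random_seq(rng, 240) + mutated + _random_seq(rng, 240)
        transcriptome = dict(fixture.transcriptome)
        transcriptome["MUT_SITE_T1"] = decoy_template
        new = replace_fixture(fixture, transcriptome=transcriptome)
        new.meta = dict(fixture.meta, site=site, mutated_site=mutated,
                        mutated_template_id="MUT_SITE_T1", n_subs=n_subs)
        return new
    raise ValueError(f"unknown corruption mode {mode!r}")


def replace_fixture(fixture: Fixture, **kwargs) -> Fixture:
    fields_ = dict(
        spec=fixture.spec,
        genome=dict(fixture.genome),
        gtf_text=fixture.gtf_text,
        transcriptome=dict(fixture.transcriptome),
        quant_text=fixture.quant_text,
        gene_ids=list(fixture.gene_ids),
        genes=list(fixture.genes),
        meta=dict(fixture.meta),
    )
    fields_.update(kwargs)
    return Fixture(**fields_)
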