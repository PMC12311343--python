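"""Transcript models from GTF + genome FASTA.

Parses exon features into per-gene transcript models, splices transcript
sequences from the genome, filters templates by transcript support level
(TSL), enumerates splice junctions, extracts 10-nt junction probes and
ranks junctions by prevalence across a gene's isoforms.

Coordinate conventions: GTF records are 1-based inclusive; every internal
interval is 0-based half-open; transcript-local positions are 0-based.
Exons are stored in transcript 5'->3' order, so a minus-strand transcript
lists its genomic-rightmost exon first.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .thermo import revcomp

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "SpliceJunction",
    "GeneModel",
    "strip_version",
    "parse_gtf",
    "to_gtf",
    "splice_sequence",
    "filter_by_tsl",
    "enumerate_junctions",
    "junction_probe",
    "rank_junctions",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

PROBE_FLANK = 5


def strip_version(identifier: str) -> str:
    """Drop a trailing Ensembl-style ``.N`` version suffix, if any."""
    return re.sub(r"\.\d+$", "", identifier)


@dataclass
class TranscriptModel:
    """One transcript: ordered exon blocks plus spliced sequence."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # 0-based half-open, 5'->3' transcript order
    spliced_seq: str = ""
    tsl: int | None = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def exon_lengths(self) -> list[int]:
        return [e - s for s, e in self.exons]


@dataclass
class SpliceJunction:
    """A splice junction shared by one or more isoforms of a gene.

    ``pos`` is the transcript-local 0-based index of the first base of the
    downstream exon on the representative transcript. ``donor`` and
    ``acceptor`` are genomic coordinates (0-based) of the transcript-order
    last base of the upstream exon and first base of the downstream exon.
    """

    transcript_id: str
    pos: int
    donor: int
    acceptor: int
    probe: str | None = None
    prevalence: int = 1
    transcript_positions: dict[str, int] = field(default_factory=dict)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]
    junctions: list[SpliceJunction] = field(default_factory=list)
    excluded_transcripts: list[TranscriptModel] = field(default_factory=list)

    def all_transcripts(self) -> list[TranscriptModel]:
        """Templates plus TSL-excluded isoforms (the in-silico PCR universe)."""
        return self.transcripts + self.excluded_transcripts


def _parse_tsl(raw: str | None) -> int | None:
    if raw is None:
        return None
    token = raw.strip().split()[0] if raw.strip() else ""
    if not token or token.upper() in {"NA", "NONE"}:
        return None
    try:
        return int(token)
    except ValueError:
        return None


def parse_gtf(
    gtf_text: str | Iterable[str],
    target_gene_ids: set[str] | Iterable[str],
) -> list[GeneModel]:
    """Parse exon features of a GTF into one :class:`GeneModel` per target gene.

    Target IDs are matched with Ensembl version suffixes stripped. Genes
    absent from the annotation are logged as warnings, not fatal errors.
    """
    targets = {strip_version(g) for g in target_gene_ids}
    if not targets:
        raise ValueError("no target gene IDs supplied")
    if isinstance(gtf_text, str):
        lines: Iterable[str] = gtf_text.splitlines()
    else:
        lines = gtf_text

    # (gene, transcript) -> accumulated state
    tx: dict[tuple[str, str], TranscriptModel] = {}
    seen_exons: dict[tuple[str, str], set[tuple[int, int]]] = {}
    gene_order: list[str] = []

    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GTF line {lineno}: expected 9 fields, got {len(fields)}")
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start_1 = int(start_s)
            end_1 = int(end_s)
        except ValueError as exc:
            raise ValueError(f"malformed GTF line {lineno}: non-integer coordinates") from exc
        attr = dict(_ATTR_RE.findall(attrs))
        gene_id = attr.get("gene_id")
        transcript_id = attr.get("transcript_id")
        if not gene_id or not transcript_id:
            raise ValueError(f"malformed GTF line {lineno}: missing gene_id/transcript_id")
        if strip_version(gene_id) not in targets:
            continue
        interval = (start_1 - 1, end_1)  # 1-based inclusive -> 0-based half-open
        key = (gene_id, transcript_id)
        if key not in tx:
            tx[key] = TranscriptModel(
                transcript_id=transcript_id,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                exons=[],
                tsl=_parse_tsl(attr.get("transcript_support_level")),
            )
            if gene_id not in gene_order:
                gene_order.append(gene_id)
            seen_exons[key] = set()
        if interval in seen_exons[key]:
            raise ValueError(
                f"duplicate exon {start_1}-{end_1} for transcript {transcript_id} (line {lineno})"
            )
        seen_exons[key].add(interval)
        tx[key].exons.append(interval)
        if tx[key].tsl is None:
            tx[key].tsl = _parse_tsl(attr.get("transcript_support_level"))

    genes: dict[str, GeneModel] = {}
    for (gene_id, _tid), model in tx.items():
        model.exons.sort()
        if model.strand == "-":
            model.exons.reverse()
        genes.setdefault(gene_id, GeneModel(gene_id=gene_id, transcripts=[])).transcripts.append(model)

    found = {strip_version(g) for g in genes}
    missing = sorted(targets - found)
    if missing:
        logger.warning("target genes not found in annotation: %s", ", ".join(missing))
    return [genes[g] for g in gene_order]


def to_gtf(genes: Iterable[GeneModel], source: str = "isoprimer") -> str:
    """Serialize gene models back to GTF (exon features only)."""
    out: list[str] = []
    for gene in genes:
        for t in gene.all_transcripts():
            exons = sorted(t.exons)
            for start0, end0 in exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                if t.tsl is not None:
                    attrs += f' transcript_support_level "{t.tsl}";'
                out.append(
                    "\t".join(
                        [t.chrom, source, "exon", str(start0 + 1), str(end0), ".", t.strand, ".", attrs]
                    )
                )
    return "\n".join(out) + "\n"


def splice_sequence(
    transcript: TranscriptModel,
    genome: Mapping[str, str],
    transcriptome: Mapping[str, str] | None = None,
) -> str:
    """Spliced transcript sequence from genome exon blocks.

    Exon sequences are concatenated in genomic order and reverse
    complemented for minus-strand transcripts. When a transcriptome FASTA
    record exists for the transcript and disagrees, a warning is emitted
    and the FASTA record wins.
    """
    chrom_seq = genome.get(transcript.chrom)
    if chrom_seq is None:
        raise KeyError(f"chromosome {transcript.chrom!r} not in genome")
    parts: list[str] = []
    for start, end in sorted(transcript.exons):
        if start < 0 or end > len(chrom_seq):
            raise ValueError(
                f"exon [{start},{end}) of {transcript.transcript_id} outside "
                f"chromosome {transcript.chrom} (length {len(chrom_seq)})"
            )
        parts.append(chrom_seq[start:end])
    seq = "".join(parts)
    if transcript.strand == "-":
        seq = revcomp(seq)
    if transcriptome is not None:
        record = transcriptome.get(transcript.transcript_id)
        if record is None:
            record = transcriptome.get(strip_version(transcript.transcript_id))
        if record is not None and record.upper() != seq:
            logger.warning(
                "spliced sequence of %s disagrees with transcriptome FASTA; using FASTA record",
                transcript.transcript_id,
            )
            seq = record.upper()
    return seq


def filter_by_tsl(gene: GeneModel, max_tsl: int = 3) -> GeneModel:
    """Restrict design templates to transcripts with TSL <= ``max_tsl``.

    Transcripts with missing TSL pass the filter. Removed isoforms are
    kept on ``excluded_transcripts`` so the in-silico PCR template set
    still sees them. A gene with no surviving template is returned with an
    empty template list and a warning; callers skip it downstream.
    """
    keep = [t for t in gene.transcripts if t.tsl is None or t.tsl <= max_tsl]
    drop = [t for t in gene.transcripts if not (t.tsl is None or t.tsl <= max_tsl)]
    if not keep:
        logger.warning("gene %s: no eligible template after TSL filter", gene.gene_id)
    return replace(
        gene,
        transcripts=keep,
        excluded_transcripts=gene.excluded_transcripts + drop,
        junctions=list(gene.junctions),
    )


def junction_probe(spliced_seq: str, pos: int, flank: int = PROBE_FLANK) -> str | None:
    """The ``2*flank``-nt sequence spanning a junction, or None near an end.

    Returns ``spliced_seq[pos-flank : pos+flank]`` when both flanks fit;
    None when the junction is closer than ``flank`` to a transcript end.
    """
    if not 0 < pos < len(spliced_seq):
        raise ValueError(f"junction position {pos} outside sequence of length {len(spliced_seq)}")
    if pos < flank or pos > len(spliced_seq) - flank:
        return None
    return spliced_seq[pos - flank : pos + flank]


def enumerate_junctions(gene: GeneModel) -> list[SpliceJunction]:
    """Gene-level splice junctions, deduplicated by genomic (donor, acceptor).

    Each transcript with ``e`` exons contributes ``e - 1`` junctions at
    its cumulative exon-length boundaries. Junctions sharing a genomic
    (donor, acceptor) across isoforms collapse into one record carrying
    every transcript-local position.
    """
    by_site: dict[tuple[int, int], SpliceJunction] = {}
    for t in gene.transcripts:
        cumulative = 0
        for i in range(len(t.exons) - 1):
            up_start, up_end = t.exons[i]
            down_start, down_end = t.exons[i + 1]
            cumulative += up_end - up_start
            if t.strand == "+":
                donor, acceptor = up_end - 1, down_start
            else:
                donor, acceptor = up_start, down_end - 1
            key = (donor, acceptor)
            probe = junction_probe(t.spliced_seq, cumulative) if t.spliced_seq else None
            if key not in by_site:
                by_site[key] = SpliceJunction(
                    transcript_id=t.transcript_id,
                    pos=cumulative,
                    donor=donor,
                    acceptor=acceptor,
                    probe=probe,
                    transcript_positions={t.transcript_id: cumulative},
                )
            else:
                j = by_site[key]
                j.transcript_positions[t.transcript_id] = cumulative
                if j.probe is None and probe is not None:
                    j.probe = probe
                    j.transcript_id = t.transcript_id
                    j.pos = cumulative
    return sorted(by_site.values(), key=lambda j: (j.donor, j.acceptor))


def rank_junctions(gene: GeneModel) -> list[SpliceJunction]:
    """Rank a gene's probed junctions by prevalence across its isoforms.

    Prevalence counts the distinct transcripts whose spliced sequence
    contains the junction probe as an exact substring (presence/absence;
    multiple occurrences in one transcript count once). Junctions without
    a probe are excluded from the ranking. Order: prevalence descending,
    then donor coordinate ascending, then probe lexicographic.
    """
    ranked: list[SpliceJunction] = []
    for j in gene.junctions:
        if j.probe is None:
            continue
        j.prevalence = sum(1 for t in gene.transcripts if j.probe in t.spliced_seq)
        ranked.append(j)
    ranked.sort(key=lambda j: (-j.prevalence, j.donor, j.probe))
    return ranked
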