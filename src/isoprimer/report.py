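"""Result tables and per-gene text reports.

Three tables are written with bit-stable formatting (fixed column order,
fixed row order, floats with two decimals):

* ``validation_candidates`` — selected pairs that satisfy all quality
  criteria, one row per pair;
* ``primers_order`` — two rows per selected pair in ready-for-order
  format (``<gene>_pairN_F`` / ``_R`` plus the 5'->3' sequence);
* ``primer_omnibus`` — every designed pair for every target gene,
  including discarded ones with their discard reason.

The default serialization is TSV; an optional workbook writer emits the
same three row models as sheets of one xlsx file. Per-gene non-tabular
reports land in an ``outputs`` folder; primer hybridization is shown by
coordinate-annotated template windows rather than a multiple alignment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .prioritize import GeneDesignResult, ScoredPair

__all__ = [
    "CANDIDATE_COLUMNS",
    "candidate_rows",
    "order_rows",
    "omnibus_rows",
    "to_tsv",
    "write_tables",
    "write_workbook",
    "write_gene_report",
]

CANDIDATE_COLUMNS = [
    "gene_id",
    "isoprimer_score",
    "template_transcript_id",
    "fwd_seq",
    "rev_seq",
    "expressed_amplified",
    "coverage_percent",
    "amplicons",
]

OMNIBUS_COLUMNS = CANDIDATE_COLUMNS + ["discard_reason"]

ORDER_COLUMNS = ["name", "sequence"]


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _amplicon_tokens(sp: ScoredPair) -> str:
    tokens = sorted(f"{h.template_id}-{h.length}" for h in sp.hits)
    return ";".join(tokens)


def _row(gene_id: str, sp: ScoredPair, n_expressed: int) -> list[str]:
    return [
        gene_id,
        _fmt(sp.score),
        sp.pair.template_transcript_id,
        sp.pair.fwd_seq,
        sp.pair.rev_seq,
        f"{len(sp.amplified_expressed_ids)}/{n_expressed}",
        _fmt(sp.coverage_percent),
        _amplicon_tokens(sp),
    ]


def candidate_rows(results: Iterable[GeneDesignResult]) -> list[list[str]]:
    """validation_candidates rows: genes in input order, selection order within."""
    rows = []
    for res in results:
        n_expr = len(res.covered_expressed | res.uncovered_expressed)
        for sp in res.selected:
            rows.append(_row(res.gene_id, sp, n_expr))
    return rows


def order_rows(results: Iterable[GeneDesignResult]) -> list[list[str]]:
    rows = []
    for res in results:
        for i, sp in enumerate(res.selected, start=1):
            rows.append([f"{res.gene_id}_pair{i}_F", sp.pair.fwd_seq])
            rows.append([f"{res.gene_id}_pair{i}_R", sp.pair.rev_seq])
    return rows


def omnibus_rows(results: Iterable[GeneDesignResult]) -> list[list[str]]:
    rows = []
    for res in results:
        n_expr = len(res.covered_expressed | res.uncovered_expressed)
        for sp in res.all_scored:
            rows.append(_row(res.gene_id, sp, n_expr) + [sp.discarded_reason.value])
    return rows


def to_tsv(columns: list[str], rows: list[list[str]]) -> str:
    return "\n".join(["\t".join(columns)] + ["\t".join(r) for r in rows]) + "\n"


def write_tables(results: list[GeneDesignResult], outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "validation_candidates": outdir / "primers.tsv",
        "primers_order": outdir / "primers_order.tsv",
        "primer_omnibus": outdir / "primer_omnibus.tsv",
    }
    paths["validation_candidates"].write_text(to_tsv(CANDIDATE_COLUMNS, candidate_rows(results)))
    paths["primers_order"].write_text(to_tsv(ORDER_COLUMNS, order_rows(results)))
    paths["primer_omnibus"].write_text(to_tsv(OMNIBUS_COLUMNS, omnibus_rows(results)))
    return paths


def write_workbook(results: list[GeneDesignResult], path: str | Path) -> Path:
    """Optional xlsx writer: the same three row models as named sheets."""
    from openpyxl import Workbook

    wb = Workbook()
    sheets = [
        ("validation_candidates", CANDIDATE_COLUMNS, candidate_rows(results)),
        ("primers_order", ORDER_COLUMNS, order_rows(results)),
        ("primer_omnibus", OMNIBUS_COLUMNS, omnibus_rows(results)),
    ]
    wb.remove(wb.active)
    for name, columns, rows in sheets:
        ws = wb.create_sheet(title=name)
        ws.append(columns)
        for row in rows:
            ws.append(row)
    path = Path(path)
    wb.save(path)
    return path


def _hybridization_block(sp: ScoredPair, template_id: str, template: str) -> list[str]:
    """Template window with primer annealing spans marked by coordinates."""
    lines = [f"  {template_id} ({len(template)} nt)"]
    for hit in sp.hits:
        if hit.template_id != template_id:
            continue
        f5 = hit.fwd_site.five_prime_pos
        r5 = hit.rev_site.five_prime_pos
        fwd_span = (f5, f5 + hit.fwd_site.primer_len)
        rev_span = (r5 - hit.rev_site.primer_len + 1, r5 + 1)
        lo = max(0, fwd_span[0] - 10)
        hi = min(len(template), rev_span[1] + 10)
        window = template[lo:hi]
        marks = [" "] * len(window)
        for a, b, ch in (fwd_span + (">",), rev_span + ("<",)):
            for p in range(max(a, lo), min(b, hi)):
                marks[p - lo] = ch
        lines.append(f"    product {hit.length} bp, fwd 5' at {f5} (+), rev 5' at {r5} (-)")
        for i in range(0, len(window), 70):
            lines.append(f"    {lo + i:>8} {window[i:i + 70]}")
            lines.append(f"    {'':>8} {''.join(marks[i:i + 70])}")
    return lines


def write_gene_report(
    result: GeneDesignResult,
    expression: dict[str, float],
    quantile_cutoff: float,
    expressed_ids: set[str],
    templates: dict[str, str],
    outdir: str | Path,
) -> Path:
    """Per-gene detailed text report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{result.gene_id}.txt"
    lines: list[str] = [f"Gene: {result.gene_id}", f"Selection mode: {result.mode.value}", ""]

    lines.append("## Isoform quantification")
    lines.append(f"quantile cutoff: {quantile_cutoff:.4f}")
    for tid in sorted(expression):
        flag = "expressed" if tid in expressed_ids else "below threshold"
        lines.append(f"  {tid}\t{expression[tid]:.4f}\t{flag}")
    lines.append("")

    lines.append("## Isoforms and junctions used for design")
    for sp in result.selected:
        j = sp.pair.junction
        jdesc = f"junction {j.donor}-{j.acceptor} (probe {j.probe})" if j else "no junction (free design)"
        lines.append(f"  {sp.pair.pair_id}: template {sp.pair.template_transcript_id}, {jdesc}")
    lines.append("")

    lines.append("## Primer sequences")
    for i, sp in enumerate(result.selected, start=1):
        lines.append(f"  {result.gene_id}_pair{i}_F: {sp.pair.fwd_seq}")
        lines.append(f"  {result.gene_id}_pair{i}_R: {sp.pair.rev_seq}")
    lines.append("")

    lines.append("## Hybridization of primers with matched isoforms")
    for sp in result.selected:
        for tid in sorted({h.template_id for h in sp.hits}):
            if tid in templates:
                lines.extend(_hybridization_block(sp, tid, templates[tid]))
    lines.append("")

    lines.append("## FASTA of matched isoforms")
    matched = sorted({h.template_id for sp in result.selected for h in sp.hits})
    for tid in matched:
        if tid in templates:
            lines.append(f">{tid}")
            seq = templates[tid]
            lines.extend(seq[i : i + 70] for i in range(0, len(seq), 70))
    lines.append("")

    lines.append("## Design diagnostics")
    for sp in result.selected:
        for label, stats in (("F", sp.pair.fwd_stats), ("R", sp.pair.rev_stats)):
            lines.append(
                f"  {sp.pair.pair_id}_{label}: Tm={stats.tm_celsius:.2f}C GC={stats.gc_percent:.1f}% "
                f"max_run={stats.max_run} self_comp={stats.self_comp_score} "
                f"self_end_run={stats.self_end_run} hairpin={stats.hairpin}"
            )
        lines.append(
            f"  {sp.pair.pair_id}: score={sp.score:.2f} coverage={sp.coverage_percent:.2f}% "
            f"penalty={sp.pair.penalty:.3f} discard={sp.discarded_reason.value}"
        )
    if result.discard_tally:
        lines.append("  discard tally: " + ", ".join(f"{k}={v}" for k, v in sorted(result.discard_tally.items())))
    if result.uncovered_expressed:
        lines.append("  uncovered expressed isoforms: " + ", ".join(sorted(result.uncovered_expressed)))
    path.write_text("\n".join(lines) + "\n")
    return path
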