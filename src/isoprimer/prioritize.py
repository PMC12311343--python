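"""Scoring, filtering and selection of designed primer pairs.

A pair is discarded outright when its transcriptome in-silico PCR
predicts any product on a template outside the target gene
(non-specific), when its specific products differ by more than 25 nt in
length, or when it amplifies no expressed isoform. Surviving pairs are
scored:

    score = coverage% + 10 * (# amplified expressed isoforms) + length_component

where coverage% is the share of the gene's expressed abundance amplified
by the pair and the length component is a tent function peaking (value
10) at 200-bp products and reaching 0 at +/-100 bp. Selection prefers a
single pair amplifying every expressed isoform; otherwise a greedy set
cover adds the best-scoring pair covering an uncovered expressed isoform
until no progress remains.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from enum import Enum

from .annotation import strip_version
from .design import PrimerPair
from .ispcr import AmpliconHit

__all__ = [
    "DiscardReason",
    "SelectionMode",
    "ScoredPair",
    "GeneDesignResult",
    "specificity_filter",
    "length_spread_filter",
    "length_component",
    "score_pair",
    "select_pairs",
]

MAX_LENGTH_SPREAD = 25
LENGTH_OPTIMUM = 200
LENGTH_COMPONENT_MAX = 10.0
EXPRESSED_BONUS = 10.0


class DiscardReason(str, Enum):
    NONE = "none"
    NONSPECIFIC = "nonspecific"
    LENGTH_SPREAD = "length_spread"
    NO_EXPRESSED_TARGET = "no_expressed_target"


class SelectionMode(str, Enum):
    SHARED_JUNCTION = "shared_junction"
    MULTI_PAIR_COVER = "multi_pair_cover"
    SINGLE_ISOFORM = "single_isoform"
    FAILED = "failed"


@dataclass
class ScoredPair:
    pair: PrimerPair
    hits: list[AmpliconHit] = field(default_factory=list)
    specific: bool = False
    amplified_isoform_ids: set[str] = field(default_factory=set)
    amplified_expressed_ids: set[str] = field(default_factory=set)
    coverage_percent: float = 0.0
    length_component: float = 0.0
    score: float = 0.0
    discarded_reason: DiscardReason = DiscardReason.NONE

    @property
    def surviving(self) -> bool:
        return self.discarded_reason is DiscardReason.NONE

    def specific_lengths(self) -> list[int]:
        return [h.length for h in self.hits]

    def median_length(self) -> float:
        lengths = self.specific_lengths()
        return statistics.median(lengths) if lengths else 0.0


@dataclass
class GeneDesignResult:
    gene_id: str
    selected: list[ScoredPair] = field(default_factory=list)
    covered_expressed: set[str] = field(default_factory=set)
    uncovered_expressed: set[str] = field(default_factory=set)
    mode: SelectionMode = SelectionMode.FAILED
    all_scored: list[ScoredPair] = field(default_factory=list)
    discard_tally: dict[str, int] = field(default_factory=dict)


def specificity_filter(
    pair: PrimerPair,
    transcriptome_hits: list[AmpliconHit],
    gene_transcript_ids: set[str],
) -> ScoredPair:
    """Classify a pair's transcriptome hits as specific or not.

    Any hit on a template outside the gene's own transcripts discards the
    pair as non-specific. Hits on the gene's non-expressed isoforms are
    allowed (still the right gene) and recorded; they do not count toward
    coverage. A pair with no hits at all amplifies nothing and is
    discarded too.
    """
    gene_keys = {strip_version(t) for t in gene_transcript_ids}
    scored = ScoredPair(pair=pair)
    foreign = [h for h in transcriptome_hits if strip_version(h.template_id) not in gene_keys]
    own = [h for h in transcriptome_hits if strip_version(h.template_id) in gene_keys]
    scored.hits = own
    scored.amplified_isoform_ids = {strip_version(h.template_id) for h in own}
    if foreign:
        scored.specific = False
        scored.discarded_reason = DiscardReason.NONSPECIFIC
    elif not own:
        scored.specific = False
        scored.discarded_reason = DiscardReason.NO_EXPRESSED_TARGET
    else:
        scored.specific = True
    return scored


def length_spread_filter(amplicon_lengths: list[int], max_spread: int = MAX_LENGTH_SPREAD) -> bool:
    """True (pass) iff max - min of the specific product lengths <= max_spread."""
    if not amplicon_lengths:
        raise ValueError("no amplicon lengths supplied")
    return max(amplicon_lengths) - min(amplicon_lengths) <= max_spread


def length_component(amplicon_lengths: list[int]) -> float:
    """Tent-shaped preference for ~200-bp products.

    ``max(0, 10 - |median(lengths) - 200| / 10)``: equals 10 exactly at
    200 bp and decreases symmetrically, reaching 0 at 100/300 bp.
    """
    if not amplicon_lengths:
        raise ValueError("no amplicon lengths supplied")
    med = statistics.median(amplicon_lengths)
    return max(0.0, LENGTH_COMPONENT_MAX - abs(med - LENGTH_OPTIMUM) / 10.0)


def score_pair(scored: ScoredPair, expression: dict[str, float], expressed_ids: set[str]) -> float:
    """Expression-weighted score of a surviving pair (higher is better).

    ``expression`` maps transcript id -> mean abundance; ``expressed_ids``
    is the gene's expressed-isoform set. Coverage is the amplified share
    of the gene's total expressed abundance, in percent.
    """
    expressed_keys = {strip_version(t) for t in expressed_ids}
    expr = {strip_version(t): v for t, v in expression.items()}
    scored.amplified_expressed_ids = scored.amplified_isoform_ids & expressed_keys
    total = sum(expr.get(t, 0.0) for t in expressed_keys)
    amplified = sum(expr.get(t, 0.0) for t in scored.amplified_expressed_ids)
    scored.coverage_percent = 100.0 * amplified / total if total > 0 else 0.0
    scored.length_component = length_component(scored.specific_lengths())
    scored.score = (
        scored.coverage_percent
        + EXPRESSED_BONUS * len(scored.amplified_expressed_ids)
        + scored.length_component
    )
    return scored.score


def _apply_filters(
    pairs_with_hits: list[tuple[PrimerPair, list[AmpliconHit]]],
    gene_transcript_ids: set[str],
    expression: dict[str, float],
    expressed_ids: set[str],
    max_spread: int = MAX_LENGTH_SPREAD,
) -> list[ScoredPair]:
    out: list[ScoredPair] = []
    expressed_keys = {strip_version(t) for t in expressed_ids}
    for pair, hits in pairs_with_hits:
        scored = specificity_filter(pair, hits, gene_transcript_ids)
        if scored.surviving:
            if not length_spread_filter(scored.specific_lengths(), max_spread):
                scored.discarded_reason = DiscardReason.LENGTH_SPREAD
            elif not (scored.amplified_isoform_ids & expressed_keys):
                scored.discarded_reason = DiscardReason.NO_EXPRESSED_TARGET
        if scored.surviving:
            score_pair(scored, expression, expressed_ids)
        else:
            scored.amplified_expressed_ids = scored.amplified_isoform_ids & expressed_keys
        out.append(scored)
    return out


def _selection_key(sp: ScoredPair) -> tuple:
    # higher score first; ties by product length closest to the optimum,
    # then lexicographic forward sequence
    return (-sp.score, abs(sp.median_length() - LENGTH_OPTIMUM), sp.pair.fwd_seq)


def select_pairs(
    gene_id: str,
    pairs_with_hits: list[tuple[PrimerPair, list[AmpliconHit]]],
    gene_transcript_ids: set[str],
    expression: dict[str, float],
    expressed_ids: set[str],
    single_isoform: bool = False,
    max_spread: int = MAX_LENGTH_SPREAD,
) -> GeneDesignResult:
    """Filter, score and select the pair set covering the expressed isoforms."""
    scored = _apply_filters(pairs_with_hits, gene_transcript_ids, expression, expressed_ids, max_spread)
    expressed_keys = {strip_version(t) for t in expressed_ids}
    result = GeneDesignResult(gene_id=gene_id, all_scored=scored)
    result.uncovered_expressed = set(expressed_keys)
    tally: dict[str, int] = {}
    for sp in scored:
        if not sp.surviving:
            tally[sp.discarded_reason.value] = tally.get(sp.discarded_reason.value, 0) + 1
    result.discard_tally = tally

    survivors = sorted((sp for sp in scored if sp.surviving), key=_selection_key)
    if not survivors:
        result.mode = SelectionMode.FAILED
        return result

    full = [sp for sp in survivors if sp.amplified_expressed_ids >= expressed_keys]
    if full:
        best = full[0]
        result.selected = [best]
        result.covered_expressed = set(expressed_keys)
        result.uncovered_expressed = set()
        result.mode = SelectionMode.SINGLE_ISOFORM if single_isoform else SelectionMode.SHARED_JUNCTION
        return result

    covered: set[str] = set()
    selected: list[ScoredPair] = []
    remaining = list(survivors)
    while covered != expressed_keys and remaining:
        progress = [sp for sp in remaining if sp.amplified_expressed_ids - covered]
        if not progress:
            break
        best = min(progress, key=_selection_key)
        selected.append(best)
        covered |= best.amplified_expressed_ids
        remaining.remove(best)
    result.selected = selected
    result.covered_expressed = covered
    result.uncovered_expressed = expressed_keys - covered
    result.mode = (
        SelectionMode.SINGLE_ISOFORM
        if single_isoform
        else SelectionMode.MULTI_PAIR_COVER
        if selected
        else SelectionMode.FAILED
    )
    return result
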