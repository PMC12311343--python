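"""Junction-overlapping primer pair design.

Enumerates every primer window on a spliced transcript template that
satisfies the hard constraints (length 20-25 nt, GC 30-60%, Tm 55-75 C,
poly-N run <= 4, self-complementarity and hairpin screens), requires one
primer of each pair to overlap the target splice junction with at least 7
bases on its 5' side and 4 bases on its 3' side of the boundary, and
ranks feasible pairs by a deterministic penalty:

    penalty = sum over both primers of
                  1.0*|Tm - 60| + 0.5*|len - 22| + 0.2*|GC - 50|
              + 1.0*|Tm_fwd - Tm_rev|

Lower is better; optima (60 C, 22 nt, 50% GC) and all weights are
config-exposed. Pair-level checks (pair complementarity, Tm difference)
are applied as filters and never influence the ranking, so they are
evaluated lazily in penalty order. Output is deterministic: ties break by
(fwd_start, rev_start, fwd_seq).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .annotation import SpliceJunction
from .thermo import OligoStats, complementarity, oligo_stats, revcomp

__all__ = [
    "DesignConstraints",
    "PrimerCandidate",
    "PrimerPair",
    "check_primer",
    "enumerate_junction_primers",
    "pair_penalty",
    "design_pairs",
    "design_free_pairs",
]


@dataclass(frozen=True)
class DesignConstraints:
    """Hard constraints and ranking knobs for primer design."""

    primer_len: tuple[int, int] = (20, 25)
    gc: tuple[float, float] = (30.0, 60.0)
    tm: tuple[float, float] = (55.0, 75.0)
    product_len: tuple[int, int] = (100, 300)
    max_poly_run: int = 4
    max_self_comp: int = 7
    max_end_comp: int = 3
    max_pair_tm_diff: float = 5.0
    n_return: int = 5
    junction_overlap_5p: int = 7
    junction_overlap_3p: int = 4
    hairpin_min_stem: int = 4
    hairpin_min_loop: int = 3
    oligo_conc: float = 50e-9
    monovalent_salt: float = 50e-3
    # penalty weights / optima
    wt_tm: float = 1.0
    wt_len: float = 0.5
    wt_gc: float = 0.2
    wt_pair_tm: float = 1.0
    opt_tm: float = 60.0
    opt_len: int = 22
    opt_gc: float = 50.0


@dataclass(frozen=True)
class PrimerCandidate:
    """One oriented primer window on a template.

    ``start`` is the template window start (0-based); ``seq`` is the
    synthesized oligo 5'->3' (reverse complement of the window for
    reverse orientation). ``five_prime_pos`` is the transcript-local
    position of the oligo's 5' base.
    """

    orientation: str  # 'fwd' or 'rev'
    start: int
    length: int
    seq: str
    stats: OligoStats

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.orientation == "fwd" else self.end - 1


@dataclass
class PrimerPair:
    pair_id: str
    template_transcript_id: str
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_start: int  # transcript-local 5' position of the reverse oligo
    product_len: int
    fwd_stats: OligoStats
    rev_stats: OligoStats
    penalty: float
    junction: SpliceJunction | None = None
    junction_primer: str | None = None  # 'fwd' or 'rev'
    amplicons: list = field(default_factory=list)


class _StatsCache:
    """Per-template memoized window statistics + hard-constraint verdicts."""

    def __init__(self, template: str, constraints: DesignConstraints):
        self.template = template
        self.c = constraints
        self._cache: dict[tuple[str, int, int], PrimerCandidate | None] = {}

    def get(self, orientation: str, start: int, length: int) -> PrimerCandidate | None:
        key = (orientation, start, length)
        if key not in self._cache:
            self._cache[key] = self._build(orientation, start, length)
        return self._cache[key]

    def _build(self, orientation: str, start: int, length: int) -> PrimerCandidate | None:
        window = self.template[start : start + length]
        if set(window) - set("ACGT"):
            return None
        seq = window if orientation == "fwd" else revcomp(window)
        stats = check_primer(seq, self.c)
        if stats is None:
            return None
        return PrimerCandidate(orientation, start, length, seq, stats)


def check_primer(seq: str, constraints: DesignConstraints = DesignConstraints()) -> OligoStats | None:
    """Evaluate one candidate oligo against every per-primer hard constraint.

    Returns its :class:`OligoStats` when acceptable, None otherwise.
    Length is NOT checked here (window enumeration owns it); everything
    else — GC, Tm, homopolymer runs, self-complementarity, 3' end runs
    and hairpins — is.
    """
    c = constraints
    try:
        stats = oligo_stats(
            seq,
            oligo_conc=c.oligo_conc,
            monovalent_salt=c.monovalent_salt,
            hairpin_min_stem=c.hairpin_min_stem,
            hairpin_min_loop=c.hairpin_min_loop,
        )
    except ValueError:
        return None
    if not (c.gc[0] <= stats.gc_percent <= c.gc[1]):
        return None
    if not (c.tm[0] <= stats.tm_celsius <= c.tm[1]):
        return None
    if stats.max_run > c.max_poly_run:
        return None
    if stats.self_comp_score > c.max_self_comp:
        return None
    if stats.self_end_run > c.max_end_comp:
        return None
    if stats.hairpin:
        return None
    return stats


def _junction_windows(
    template_len: int, pos: int, c: DesignConstraints, orientation: str
) -> Iterator[tuple[int, int]]:
    """(start, length) windows overlapping the junction per the 5'/4-base rule."""
    o5, o3 = c.junction_overlap_5p, c.junction_overlap_3p
    for length in range(c.primer_len[0], c.primer_len[1] + 1):
        if orientation == "fwd":
            lo, hi = pos + o3 - length, pos - o5
        else:
            lo, hi = pos + o5 - length, pos - o3
        for start in range(max(lo, 0), min(hi, template_len - length) + 1):
            yield start, length


def enumerate_junction_primers(
    template: str,
    junction_pos: int,
    constraints: DesignConstraints = DesignConstraints(),
    cache: _StatsCache | None = None,
) -> list[PrimerCandidate]:
    """All junction-overlapping candidates (both orientations) passing hard constraints."""
    if not 0 < junction_pos < len(template):
        raise ValueError(f"junction position {junction_pos} invalid for template of length {len(template)}")
    cache = cache or _StatsCache(template, constraints)
    out: list[PrimerCandidate] = []
    for orientation in ("fwd", "rev"):
        for start, length in _junction_windows(len(template), junction_pos, constraints, orientation):
            cand = cache.get(orientation, start, length)
            if cand is not None:
                out.append(cand)
    out.sort(key=lambda p: (p.orientation, p.start, p.length))
    return out


def pair_penalty(pair: PrimerPair, constraints: DesignConstraints = DesignConstraints()) -> float:
    """Deterministic ranking penalty of a feasible pair (lower is better)."""
    return _penalty(pair.fwd_stats, pair.rev_stats, constraints)


def _penalty(f: OligoStats, r: OligoStats, c: DesignConstraints) -> float:
    total = 0.0
    for s in (f, r):
        total += (
            c.wt_tm * abs(s.tm_celsius - c.opt_tm)
            + c.wt_len * abs(len(s.seq) - c.opt_len)
            + c.wt_gc * abs(s.gc_percent - c.opt_gc)
        )
    total += c.wt_pair_tm * abs(f.tm_celsius - r.tm_celsius)
    return total


def _free_windows_in(
    lo: int, hi: int, template_len: int, c: DesignConstraints
) -> Iterator[tuple[int, int]]:
    for length in range(c.primer_len[0], c.primer_len[1] + 1):
        for start in range(max(lo, 0), min(hi - length, template_len - length) + 1):
            yield start, length


def _spans_junction(start: int, end: int, pos: int | None) -> bool:
    return pos is not None and start < pos < end


def _rank_and_verify(
    raw: list[tuple[float, int, int, str, PrimerCandidate, PrimerCandidate]],
    c: DesignConstraints,
    n: int,
) -> list[tuple[PrimerCandidate, PrimerCandidate, float]]:
    """Sort feasible combos by penalty, lazily apply pair-complementarity checks."""
    raw.sort(key=lambda t: t[:4])
    chosen: list[tuple[PrimerCandidate, PrimerCandidate, float]] = []
    seen: set[tuple[str, str]] = set()
    for penalty, _fs, _rs, _fseq, fwd, rev in raw:
        if len(chosen) >= n:
            break
        key = (fwd.seq, rev.seq)
        if key in seen:
            continue
        seen.add(key)
        score, end_run = complementarity(fwd.seq, rev.seq)
        if score > c.max_self_comp or end_run > c.max_end_comp:
            continue
        chosen.append((fwd, rev, penalty))
    return chosen


def _combine(
    cache: _StatsCache,
    anchors: list[PrimerCandidate],
    junction_pos: int | None,
    c: DesignConstraints,
) -> list[tuple[float, int, int, str, PrimerCandidate, PrimerCandidate]]:
    """Feasible (anchor, mate) combos; the mate never spans the junction."""
    template_len = len(cache.template)
    combos: list[tuple[float, int, int, str, PrimerCandidate, PrimerCandidate]] = []
    pmin, pmax = c.product_len
    for anchor in anchors:
        if anchor.orientation == "fwd":
            # mate is a reverse primer; product = rev 5' - fwd 5' + 1
            lo = anchor.start + pmin  # window end >= fwd_start + pmin
            hi = anchor.start + pmax
            for start, length in _free_windows_in(lo - length_hint(c), hi, template_len, c):
                rev5 = start + length - 1
                product = rev5 - anchor.start + 1
                if not pmin <= product <= pmax:
                    continue
                if _spans_junction(start, start + length, junction_pos):
                    continue
                mate = cache.get("rev", start, length)
                if mate is None:
                    continue
                if abs(anchor.stats.tm_celsius - mate.stats.tm_celsius) > c.max_pair_tm_diff:
                    continue
                penalty = _penalty(anchor.stats, mate.stats, c)
                combos.append((penalty, anchor.start, rev5, anchor.seq, anchor, mate))
        else:
            rev5 = anchor.end - 1
            lo = rev5 - pmax + 1
            hi = rev5 - pmin + 1  # fwd_start <= rev5 - pmin + 1
            for start, length in _free_windows_in(lo, hi + length_hint(c), template_len, c):
                product = rev5 - start + 1
                if not pmin <= product <= pmax:
                    continue
                if _spans_junction(start, start + length, junction_pos):
                    continue
                mate = cache.get("fwd", start, length)
                if mate is None:
                    continue
                if abs(anchor.stats.tm_celsius - mate.stats.tm_celsius) > c.max_pair_tm_diff:
                    continue
                penalty = _penalty(mate.stats, anchor.stats, c)
                combos.append((penalty, start, rev5, mate.seq, mate, anchor))
    return combos


def length_hint(c: DesignConstraints) -> int:
    return c.primer_len[1]


def _build_pair(
    fwd: PrimerCandidate,
    rev: PrimerCandidate,
    penalty: float,
    template_id: str,
    index: int,
    junction: SpliceJunction | None,
    junction_primer: str | None,
) -> PrimerPair:
    rev5 = rev.end - 1
    return PrimerPair(
        pair_id=f"{template_id}_pair{index}",
        template_transcript_id=template_id,
        fwd_seq=fwd.seq,
        rev_seq=rev.seq,
        fwd_start=fwd.start,
        rev_start=rev5,
        product_len=rev5 - fwd.start + 1,
        fwd_stats=fwd.stats,
        rev_stats=rev.stats,
        penalty=penalty,
        junction=junction,
        junction_primer=junction_primer,
    )


def design_pairs(
    template: str,
    junction: SpliceJunction,
    constraints: DesignConstraints = DesignConstraints(),
    n: int | None = None,
    template_id: str = "",
    junction_pos: int | None = None,
) -> list[PrimerPair]:
    """Up to ``n`` ranked primer pairs with exactly one junction-spanning primer.

    ``junction_pos`` overrides the junction's transcript-local position
    when designing on a transcript other than the junction's
    representative.
    """
    n = constraints.n_return if n is None else n
    pos = junction.pos if junction_pos is None else junction_pos
    cache = _StatsCache(template, constraints)
    anchors = enumerate_junction_primers(template, pos, constraints, cache)
    combos = _combine(cache, anchors, pos, constraints)
    chosen = _rank_and_verify(combos, constraints, n)
    return [
        _build_pair(
            fwd,
            rev,
            penalty,
            template_id or junction.transcript_id,
            i + 1,
            junction,
            "fwd" if _spans_junction(fwd.start, fwd.end, pos) else "rev",
        )
        for i, (fwd, rev, penalty) in enumerate(chosen)
    ]


def design_free_pairs(
    template: str,
    constraints: DesignConstraints = DesignConstraints(),
    n: int | None = None,
    template_id: str = "",
) -> list[PrimerPair]:
    """Ranked pairs with no junction requirement (single-isoform mode)."""
    n = constraints.n_return if n is None else n
    cache = _StatsCache(template, constraints)
    anchors: list[PrimerCandidate] = []
    for start, length in _free_windows_in(0, len(template), len(template), constraints):
        cand = cache.get("fwd", start, length)
        if cand is not None:
            anchors.append(cand)
    combos = _combine(cache, anchors, None, constraints)
    chosen = _rank_and_verify(combos, constraints, n)
    return [
        _build_pair(fwd, rev, penalty, template_id, i + 1, None, None)
        for i, (fwd, rev, penalty) in enumerate(chosen)
    ]
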