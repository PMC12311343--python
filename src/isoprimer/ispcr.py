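"""Mismatch-tolerant in-silico PCR.

Primer annealing sites are located by ungapped (Hamming) scanning of both
template strands; each primer tolerates ``floor(len * pct / 100)``
mismatches. IUPAC ambiguity codes in the primer match any base of their
set; an N (or any non-ACGT character) in the template never matches,
even against a primer wildcard. There is no 3'-anchoring by default; an
optional ``anchor_3p`` requires that many exact bases at the primer 3'
end. Amplicons combine a plus-strand site with a downstream minus-strand
site; either oligo of a pair may prime either strand, but single-primer
amplicons (both sites from the same oligo) are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .thermo import revcomp

if TYPE_CHECKING:  # pragma: no cover
    from .design import PrimerPair

__all__ = [
    "PrimerSite",
    "AmpliconHit",
    "allowed_mismatches",
    "find_sites",
    "predict_amplicons",
    "genome_check",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class PrimerSite:
    """One primer annealing site on the + strand coordinate system."""

    template_id: str
    strand: str  # '+' or '-'
    five_prime_pos: int  # 0-based position of the primer's 5' base
    mismatches: int
    primer_len: int

    @property
    def three_prime_pos(self) -> int:
        if self.strand == "+":
            return self.five_prime_pos + self.primer_len - 1
        return self.five_prime_pos - self.primer_len + 1


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product: fwd + site paired with rev - site."""

    template_id: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    length: int


def allowed_mismatches(primer_len: int, pct: float = 20.0) -> int:
    """Mismatch budget for one primer: ``floor(len * pct / 100)``."""
    if not 0 <= pct <= 100:
        raise ValueError(f"mismatch percentage {pct} outside [0,100]")
    return int(primer_len * pct // 100)


def _allowed_matrix(primer: str) -> np.ndarray:
    """(len, 5) bool: which template base code matches each primer position.

    Column 4 (template N / unknown) is always False.
    """
    m = np.zeros((len(primer), 5), dtype=bool)
    for i, base in enumerate(primer.upper()):
        try:
            allowed = IUPAC[base]
        except KeyError:
            raise ValueError(f"invalid primer base {base!r}") from None
        for b in allowed:
            m[i, "ACGT".index(b)] = True
    return m


def _scan(primer: str, template_codes: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(window start, mismatches) for every window within the budget."""
    m = len(primer)
    n = template_codes.size
    if m == 0 or n < m:
        return []
    allowed = _allowed_matrix(primer)
    windows = np.lib.stride_tricks.sliding_window_view(template_codes, m)
    match = allowed[np.arange(m)[None, :], windows]
    mismatches = m - match.sum(axis=1)
    starts = np.nonzero(mismatches <= max_mm)[0]
    return [(int(s), int(mismatches[s])) for s in starts]


def find_sites(
    primer: str,
    template: str,
    pct: float = 20.0,
    template_id: str = "",
    anchor_3p: int = 0,
) -> list[PrimerSite]:
    """All annealing sites of a primer on both strands of a template.

    The primer as written is matched against the + strand; its reverse
    complement against the + strand locates - strand sites, whose
    ``five_prime_pos`` is the rightmost base of the matched window.
    """
    max_mm = allowed_mismatches(len(primer), pct)
    codes = _BASE_CODE[np.frombuffer(template.encode("ascii"), dtype=np.uint8)]
    sites: list[PrimerSite] = []
    for start, mm in _scan(primer, codes, max_mm):
        if anchor_3p and _mm_in_window(primer, template, start, -anchor_3p):
            continue
        sites.append(PrimerSite(template_id, "+", start, mm, len(primer)))
    rc = revcomp(primer.upper())
    for start, mm in _scan(rc, codes, max_mm):
        if anchor_3p and _mm_in_window(rc, template, start, anchor_3p):
            continue
        sites.append(PrimerSite(template_id, "-", start + len(primer) - 1, mm, len(primer)))
    return sites


def _mm_in_window(oriented: str, template: str, start: int, anchor: int) -> bool:
    """Any mismatch within the primer's 3'-anchor window (signed: -k suffix, +k prefix)."""
    if anchor < 0:
        span = range(len(oriented) + anchor, len(oriented))
    else:
        span = range(anchor)
    for i in span:
        t = template[start + i].upper()
        if t not in IUPAC.get(oriented[i].upper(), ""):
            return True
    return False


def predict_amplicons(
    pair: "PrimerPair",
    templates: Mapping[str, str],
    pct: float = 20.0,
    max_amplicon: int = 3500,
    anchor_3p: int = 0,
) -> list[AmpliconHit]:
    """Every predicted product of a primer pair on a set of templates.

    For each template, each (+ site of one oligo, - site of the other
    oligo) combination in productive orientation and within the length
    cap yields one hit. Length is ``rev 5' - fwd 5' + 1``. Hits are
    sorted by (template_id, fwd 5' position, length).
    """
    hits: list[AmpliconHit] = []
    for template_id in sorted(templates):
        template = templates[template_id]
        fwd_sites = find_sites(pair.fwd_seq, template, pct, template_id, anchor_3p)
        rev_sites = find_sites(pair.rev_seq, template, pct, template_id, anchor_3p)
        for plus_pool, minus_pool in ((fwd_sites, rev_sites), (rev_sites, fwd_sites)):
            for f in plus_pool:
                if f.strand != "+":
                    continue
                for r in minus_pool:
                    if r.strand != "-":
                        continue
                    # the - primer's 3' end must lie strictly downstream of
                    # the + primer's 3' end
                    if r.three_prime_pos <= f.three_prime_pos:
                        continue
                    length = r.five_prime_pos - f.five_prime_pos + 1
                    if 0 < length <= max_amplicon:
                        hits.append(AmpliconHit(template_id, f, r, length))
    hits.sort(key=lambda h: (h.template_id, h.fwd_site.five_prime_pos, h.length))
    return hits


def genome_check(
    pairs: list[tuple[str, str, "PrimerPair"]],
    genome: Mapping[str, str],
    pct: float = 20.0,
    max_amplicon: int = 3500,
) -> list[str]:
    """Genomic cross-check report lines for finalized pairs.

    ``pairs`` holds (gene_id, pair_id, pair). One tab-separated line per
    predicted genomic amplicon: gene_id, pair_id, chromosome, start, end,
    length, with 1-based inclusive genomic coordinates. Empty when no
    genomic amplification is predicted.
    """
    lines: list[str] = []
    for gene_id, pair_id, pair in pairs:
        for hit in predict_amplicons(pair, genome, pct, max_amplicon):
            start = hit.fwd_site.five_prime_pos + 1
            end = hit.rev_site.five_prime_pos + 1
            lines.append(
                "\t".join([gene_id, pair_id, hit.template_id, str(start), str(end), str(hit.length)])
            )
    return lines
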