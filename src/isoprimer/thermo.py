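"""Sequence-level primer physics.

GC content, nearest-neighbor melting temperature, homopolymer runs,
self/pair complementarity and hairpin screening. Every function here is
pure: identical inputs give bit-identical outputs.

The melting temperature uses the unified nearest-neighbor dinucleotide
parameter set (dimer enthalpies/entropies plus terminal initiation terms)
with a monovalent-salt correction applied to the entropy:

    Tm = 1000 * dH / (dS + 0.368 * (N - 1) * ln[Na+] + R * ln(C/4)) - 273.15

with dH in kcal/mol, dS in cal/(mol*K), C the total oligo concentration
(default 50 nM) and [Na+] the monovalent cation concentration (default
50 mM). The parameter table is pinned below so results are reproducible
to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "OligoStats",
    "revcomp",
    "gc_percent",
    "melting_temperature",
    "max_homopolymer_run",
    "complementarity",
    "hairpin_flag",
    "oligo_stats",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: Unified NN parameters: 5'->3' dimer -> (dH kcal/mol, dS cal/(mol*K)).
NN_PARAMS: dict[str, tuple[float, float]] = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}

#: Duplex initiation terms per terminal base pair.
INIT_GC = (0.1, -2.8)
INIT_AT = (2.3, 4.1)

#: Gas constant, cal/(mol*K).
R_GAS = 1.987


def _require_acgt(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    """Percentage of G+C bases, 0-100."""
    _require_acgt(seq)
    gc = sum(1 for b in seq if b in "GC")
    return 100.0 * gc / len(seq)


def melting_temperature(
    seq: str,
    oligo_conc: float = 50e-9,
    monovalent_salt: float = 50e-3,
) -> float:
    """Nearest-neighbor duplex melting temperature in Celsius.

    Parameters
    ----------
    seq
        Primer sequence, ACGT only, at least 8 nt.
    oligo_conc
        Total oligonucleotide strand concentration in mol/L.
    monovalent_salt
        Monovalent cation concentration in mol/L (entropy correction).
    """
    _require_acgt(seq)
    if len(seq) < 8:
        raise ValueError(f"sequence too short for NN model: {len(seq)} < 8")
    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        ih, is_ = INIT_GC if terminal in "GC" else INIT_AT
        dh += ih
        ds += is_
    for i in range(len(seq) - 1):
        nh, ns = NN_PARAMS[seq[i : i + 2]]
        dh += nh
        ds += ns
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_salt)
    return 1000.0 * dh / (ds + R_GAS * math.log(oligo_conc / 4.0)) - 273.15


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest single-base run."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for prev, cur in zip(seq, seq[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def complementarity(a: str, b: str) -> tuple[int, int]:
    """Ungapped complementarity between two oligos.

    Slides ``b`` antiparallel against ``a`` at every offset and measures
    contiguous Watson-Crick complementary runs. Returns
    ``(score, end_run)`` where ``score`` is the longest run found at any
    offset and ``end_run`` the longest run anchored at the 3' terminus of
    either oligo. ``complementarity(a, a)`` is the self-complementarity.

    An antiparallel complementary run between ``a`` and ``b`` is exactly a
    common substring of ``a`` and ``revcomp(b)``, which is how both
    quantities are computed.
    """
    _require_acgt(a)
    _require_acgt(b)
    score = _longest_common_substring(a, revcomp(b))
    end_a = _longest_suffix_in(a, revcomp(b))
    end_b = _longest_suffix_in(b, revcomp(a))
    return score, max(end_a, end_b)


def _longest_common_substring(x: str, y: str) -> int:
    best = 0
    prev = [0] * (len(y) + 1)
    for cx in x:
        cur = [0] * (len(y) + 1)
        for j, cy in enumerate(y, start=1):
            if cx == cy:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def _longest_suffix_in(x: str, y: str) -> int:
    # longest suffix of x occurring anywhere in y
    for k in range(min(len(x), len(y)), 0, -1):
        if x[-k:] in y:
            return k
    return 0


def hairpin_flag(seq: str, min_stem: int = 4, min_loop: int = 3) -> bool:
    """True iff the oligo can fold back on itself.

    Detects two in-sequence segments of length >= ``min_stem``, separated
    by >= ``min_loop`` bases, that are exact reverse complements. A pair
    of longer complementary segments always contains a ``min_stem``-long
    complementary pair at the same or larger separation, so checking
    stems of exactly ``min_stem`` is sufficient.
    """
    _require_acgt(seq)
    n = len(seq)
    if n < 2 * min_stem + min_loop:
        return False
    for i in range(n - 2 * min_stem - min_loop + 1):
        stem = seq[i : i + min_stem]
        target = revcomp(stem)
        j0 = i + min_stem + min_loop
        if target in seq[j0:]:
            return True
    return False


@dataclass(frozen=True)
class OligoStats:
    """Physical summary of one primer candidate."""

    seq: str
    gc_percent: float
    tm_celsius: float
    max_run: int
    self_comp_score: int
    self_end_run: int
    hairpin: bool


def oligo_stats(
    seq: str,
    oligo_conc: float = 50e-9,
    monovalent_salt: float = 50e-3,
    hairpin_min_stem: int = 4,
    hairpin_min_loop: int = 3,
) -> OligoStats:
    """Compute all per-oligo statistics in one pass."""
    score, end_run = complementarity(seq, seq)
    return OligoStats(
        seq=seq,
        gc_percent=gc_percent(seq),
        tm_celsius=melting_temperature(seq, oligo_conc, monovalent_salt),
        max_run=max_homopolymer_run(seq),
        self_comp_score=score,
        self_end_run=end_run,
        hairpin=hairpin_flag(seq, hairpin_min_stem, hairpin_min_loop),
    )
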