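import random

import pytest

from isoprimer.design import DesignConstraints, design_free_pairs, design_pairs
from isoprimer.fixtures import LocusSpec, make_locus
from isoprimer.ispcr import (
    AmpliconHit,
    PrimerSite,
    allowed_mismatches,
    find_sites,
    genome_check,
    predict_amplicons,
)
from isoprimer.thermo import revcomp

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def rand_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def oracle_sites(primer, template, pct):
    """Position-by-position Hamming scan on both strands (no numpy)."""
    k = len(primer) * pct // 100
    out = []
    m = len(primer)
    for oriented, strand in ((primer, "+"), (revcomp(primer), "-")):
        for start in range(len(template) - m + 1):
            mm = 0
            for i in range(m):
                t = template[start + i]
                if t not in "ACGT" or t != oriented[i]:
                    mm += 1
            if mm <= k:
                five = start if strand == "+" else start + m - 1
                out.append((strand, five, mm))
    return sorted(out)


def substitute(seq, positions):
    flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = flip[out[p]]
    return "".join(out)


class DummyPair:
    def __init__(self, fwd, rev):
        self.fwd_seq = fwd
        self.rev_seq = rev


class TestAllowedMismatches:
    @pytest.mark.parametrize("n,pct,expected", [(20, 20, 4), (22, 20, 4), (20, 0, 0), (25, 20, 5)])
    def test_floor_rule(self, n, pct, expected):
        assert allowed_mismatches(n, pct) == expected

    def test_pct_out_of_range(self):
        with pytest.raises(ValueError):
            allowed_mismatches(20, 101)


class TestFindSites:
    def test_planted_exact_match(self):
        rng = random.Random(0)
        primer = rand_seq(rng, 20)
        template = rand_seq(rng, 100) + primer + rand_seq(rng, 100)
        sites = [s for s in find_sites(primer, template, 20) if s.mismatches == 0]
        assert any(s.strand == "+" and s.five_prime_pos == 100 for s in sites)

    def test_twenty_percent_boundary(self):
        rng = random.Random(1)
        primer = rand_seq(rng, 20)
        for k, expect in [(4, True), (5, False)]:
            mutated = substitute(primer, list(range(k)))
            template = rand_seq(rng, 50) + mutated + rand_seq(rng, 50)
            found = any(
                s.five_prime_pos == 50 and s.strand == "+"
                for s in find_sites(primer, template, 20)
            )
            assert found is expect, k

    def test_minus_strand_five_prime_coordinate(self):
        rng = random.Random(2)
        primer = rand_seq(rng, 20)
        template = rand_seq(rng, 60) + revcomp(primer) + rand_seq(rng, 60)
        sites = [s for s in find_sites(primer, template, 0) if s.strand == "-"]
        assert [s.five_prime_pos for s in sites] == [79]

    def test_agrees_with_brute_force_oracle(self):
        rng = random.Random(3)
        template = rand_seq(rng, 2000)
        for _ in range(5):
            primer = rand_seq(rng, 18)
            got = sorted((s.strand, s.five_prime_pos, s.mismatches) for s in find_sites(primer, template, 20))
            assert got == oracle_sites(primer, template, 20)

    def test_pct_zero_equals_exact_substring_search(self):
        rng = random.Random(4)
        primer = rand_seq(rng, 15)
        template = rand_seq(rng, 300) + primer + rand_seq(rng, 20) + revcomp(primer)
        plus = {s.five_prime_pos for s in find_sites(primer, template, 0) if s.strand == "+"}
        expected = set()
        start = template.find(primer)
        while start != -1:
            expected.add(start)
            start = template.find(primer, start + 1)
        assert plus == expected

    def test_monotone_in_tolerance(self):
        rng = random.Random(5)
        template = rand_seq(rng, 1500)
        primer = rand_seq(rng, 18)
        def key(sites):
            return {(s.strand, s.five_prime_pos) for s in sites}
        s0 = key(find_sites(primer, template, 0))
        s10 = key(find_sites(primer, template, 10))
        s20 = key(find_sites(primer, template, 20))
        assert s0 <= s10 <= s20

    def test_iupac_primer_and_template_n(self):
        assert find_sites("ACGR", "ACGA", 0, "t")  # R matches A
        assert find_sites("ACGR", "ACGG", 0, "t")
        assert not find_sites("ACGR", "ACGC", 0, "t")
        assert not find_sites("ACGN", "ACGN", 0, "t")  # template N never matches


class TestPredictAmplicons:
    def test_planted_pair_length(self):
        rng = random.Random(6)
        fwd = rand_seq(rng, 20)
        rev = rand_seq(rng, 20)
        template = rand_seq(rng, 100) + fwd + rand_seq(rng, 160) + revcomp(rev) + rand_seq(rng, 50)
        # fwd 5' at 100; rev 5' at 100+20+160+20-1 = 299
        hits = predict_amplicons(DummyPair(fwd, rev), {"T1": template}, 0)
        assert len(hits) == 1
        assert hits[0].length == 200
        assert hits[0].fwd_site.five_prime_pos == 100
        assert hits[0].rev_site.five_prime_pos == 299

    def test_decoy_cross_match_gives_second_hit(self):
        rng = random.Random(7)
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
        t1 = rand_seq(rng, 50) + fwd + rand_seq(rng, 150) + revcomp(rev) + rand_seq(rng, 50)
        decoy = rand_seq(rng, 30) + substitute(fwd, [0, 5]) + rand_seq(rng, 120) + revcomp(substitute(rev, [3])) + rand_seq(rng, 30)
        hits = predict_amplicons(DummyPair(fwd, rev), {"T1": t1, "DEC": decoy}, 20)
        assert {h.template_id for h in hits} == {"T1", "DEC"}

    def test_symmetric_under_role_swap(self):
        rng = random.Random(8)
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
        template = rand_seq(rng, 40) + fwd + rand_seq(rng, 120) + revcomp(rev) + rand_seq(rng, 40)
        templates = {"T1": template}
        a = predict_amplicons(DummyPair(fwd, rev), templates, 20)
        b = predict_amplicons(DummyPair(rev, fwd), templates, 20)
        assert {(h.template_id, h.fwd_site.five_prime_pos, h.length) for h in a} == {
            (h.template_id, h.fwd_site.five_prime_pos, h.length) for h in b
        }

    def test_max_amplicon_cap(self):
        rng = random.Random(9)
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 20)
        template = fwd + rand_seq(rng, 4000) + revcomp(rev)
        assert predict_amplicons(DummyPair(fwd, rev), {"T": template}, 0, max_amplicon=3500) == []
        assert predict_amplicons(DummyPair(fwd, rev), {"T": template}, 0, max_amplicon=5000)

    def test_oracle_equivalence_on_fixture_transcriptome(self):
        """Hit set equals a brute-force oracle over all site combinations."""
        rng = random.Random(10)
        templates = {f"X{i}": rand_seq(rng, rng.randint(300, 900)) for i in range(30)}
        fwd, rev = rand_seq(rng, 20), rand_seq(rng, 21)
        # plant a proper pair in a few templates
        for name in ("X3", "X11"):
            t = templates[name]
            templates[name] = t[:50] + fwd + t[50:250] + revcomp(rev) + t[250:]
        pair = DummyPair(fwd, rev)
        got = {
            (h.template_id, h.fwd_site.five_prime_pos, h.rev_site.five_prime_pos, h.length)
            for h in predict_amplicons(pair, templates, 20)
        }
        expected = set()
        for name, template in templates.items():
            sf = oracle_sites(fwd, template, 20)
            sr = oracle_sites(rev, template, 20)
            for plus_pool, minus_pool, mf, mr in ((sf, sr, len(fwd), len(rev)), (sr, sf, len(rev), len(fwd))):
                for strand_f, f5, _ in plus_pool:
                    if strand_f != "+":
                        continue
                    for strand_r, r5, _ in minus_pool:
                        if strand_r != "-":
                            continue
                        # oriented: minus primer 3' end strictly downstream of plus primer 3' end
                        plus_len = mf if plus_pool is sf else mr
                        minus_len = mr if plus_pool is sf else mf
                        if r5 - minus_len + 1 <= f5 + plus_len - 1:
                            continue
                        length = r5 - f5 + 1
                        if 0 < length <= 3500:
                            expected.add((name, f5, r5, length))
        assert got == expected


def _longest_exon_seq(t):
    off = 0
    best = ""
    for length in t.exon_lengths():
        seq = t.spliced_seq[off : off + length]
        if len(seq) > len(best):
            best = seq
        off += length
    return best


class TestGenomeCheck:
    def test_junction_pair_cannot_amplify_genome(self, shared_locus):
        gene = shared_locus.genes[0]
        gene.junctions = []
        from isoprimer.annotation import enumerate_junctions, rank_junctions

        gene.junctions = enumerate_junctions(gene)
        junction = rank_junctions(gene)[0]
        t = next(tr for tr in gene.transcripts if tr.transcript_id == junction.transcript_id)
        pairs = design_pairs(t.spliced_seq, junction, template_id=t.transcript_id)
        assert pairs
        lines = genome_check(
            [(gene.gene_id, p.pair_id, p) for p in pairs], shared_locus.genome, 20
        )
        assert lines == []  # intron pushes genomic product over the cap

    def test_intra_exon_pair_reports_genomic_line(self, shared_locus):
        gene = shared_locus.genes[0]
        t = gene.transcripts[0]
        exon_seq = _longest_exon_seq(t)
        pairs = design_free_pairs(exon_seq, template_id=t.transcript_id, n=1)
        assert pairs
        pair = pairs[0]
        lines = genome_check([(gene.gene_id, "p1", pair)], shared_locus.genome, 20)
        assert len(lines) >= 1
        parts = lines[0].split("\t")
        assert parts[0] == gene.gene_id and parts[1] == "p1"
        assert int(parts[5]) == pair.product_len

    def test_line_count_matches_oracle(self, shared_locus):
        gene = shared_locus.genes[0]
        t = gene.transcripts[0]
        exon_seq = _longest_exon_seq(t)
        pairs = design_free_pairs(exon_seq, template_id=t.transcript_id, n=2)
        triples = [(gene.gene_id, f"p{i}", p) for i, p in enumerate(pairs)]
        lines = genome_check(triples, shared_locus.genome, 20)
        expected = sum(
            len(predict_amplicons(p, shared_locus.genome, 20)) for _, _, p in triples
        )
        assert len(lines) == expected
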