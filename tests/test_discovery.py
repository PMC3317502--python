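"""Six-frame ORF finding and PSSM domain scanning."""

import math

import numpy as np
import pytest
from Bio.Seq import Seq

from igreceptor import build_pssm, filter_ig_candidates, find_orfs, scan_domains
from igreceptor.discovery import AA_ALPHABET, STOP_CODONS
from igreceptor.synthetic import back_translate

PAD = "C" * 60  # poly-C: no start or stop codons


def brute_force_orfs(seq: str, min_aa: int):
    """Independent six-frame scanner: all ATG->stop spans, longest per stop."""
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    found = {}
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            codons = [s[p : p + 3] for p in range(frame, len(s) - 2, 3)]
            for ci, codon in enumerate(codons):
                if codon != "ATG":
                    continue
                for cj in range(ci, len(codons)):
                    if codons[cj] in STOP_CODONS:
                        if cj - ci >= min_aa:
                            o_start = frame + 3 * ci
                            o_end = frame + 3 * cj + 3
                            if strand == "+":
                                key = (o_start, o_end, strand)
                            else:
                                key = (L - o_end, L - o_start, strand)
                            stop_key = (key[1] if strand == "+" else key[0], strand)
                            prev = found.get(stop_key)
                            if prev is None or key[1] - key[0] > prev[1] - prev[0]:
                                cds = s[o_start : o_end - 3]
                                found[stop_key] = (
                                    key[0],
                                    key[1],
                                    strand,
                                    str(Seq(cds).translate()),
                                )
                        break
    return {(a, b, st): prot for a, b, st, prot in found.values()}


def test_single_forward_orf_is_found_exactly():
    rng = np.random.default_rng(0)
    protein = "M" + "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 120))
    insert = back_translate(protein) + "TAA"
    contig = PAD + insert + PAD
    orfs = find_orfs("c", contig, 100)
    assert len(orfs) == 1
    (o,) = orfs
    assert (o.start, o.end, o.strand) == (len(PAD), len(PAD) + len(insert), "+")
    assert o.protein == protein


def test_reverse_complement_insert_reports_same_protein_on_minus_strand():
    rng = np.random.default_rng(1)
    protein = "M" + "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 110))
    insert = str(Seq(back_translate(protein) + "TAA").reverse_complement())
    contig = PAD + insert + PAD
    orfs = find_orfs("c", contig, 100)
    assert len(orfs) == 1
    assert orfs[0].strand == "-"
    assert orfs[0].protein == protein
    assert (orfs[0].start, orfs[0].end) == (len(PAD), len(PAD) + len(insert))


def test_poly_c_contig_has_no_orfs():
    assert find_orfs("c", "C" * 500, 1) == []


def test_invalid_characters_rejected_but_n_tolerated():
    with pytest.raises(ValueError):
        find_orfs("c", "ACGTRYACGT", 1)
    # N inside a codon translates to X and is never a start/stop
    contig = PAD + "ATG" + "AAN" + "GCT" * 30 + "TAA" + PAD
    orfs = find_orfs("c", contig, 10)
    assert len(orfs) == 1
    assert orfs[0].protein[0] == "M"
    assert orfs[0].protein[1] == "X"


def test_nested_orfs_report_only_longest_per_stop():
    inner = "ATG" + "GCT" * 50 + "TAA"
    outer = "ATG" + "GGT" * 10 + inner[:-3] + "TAA"
    contig = PAD + outer + PAD
    orfs = find_orfs("c", contig, 10)
    assert len(orfs) == 1
    assert orfs[0].end - orfs[0].start == len(outer)


def test_find_orfs_agrees_with_brute_force_on_random_contigs():
    rng = np.random.default_rng(42)
    for _ in range(200):
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        got = {
            (o.start, o.end, o.strand): o.protein
            for o in find_orfs("c", contig, 25)
        }
        assert got == brute_force_orfs(contig, 25)


# ---------------------------------------------------------------------------
# PSSM


def test_pssm_matches_hand_computed_log_odds():
    examples = ["ACD", "ACD", "AYD"]
    prof = build_pssm("f", examples, pseudocount=0.5)
    idx = {a: i for i, a in enumerate(AA_ALPHABET)}

    def expected(count):
        return math.log((count + 0.5 / 20) / (3 + 0.5)) - math.log(1 / 20)

    assert prof.matrix[0, idx["A"]] == pytest.approx(expected(3))
    assert prof.matrix[1, idx["C"]] == pytest.approx(expected(2))
    assert prof.matrix[1, idx["Y"]] == pytest.approx(expected(1))
    assert prof.matrix[2, idx["A"]] == pytest.approx(expected(0))


def test_pssm_limits():
    # prior-dominated: huge pseudocount drives every entry to 0
    prof = build_pssm("f", ["AC"], pseudocount=1e9)
    assert np.allclose(prof.matrix, 0.0, atol=1e-6)
    # pure column with vanishing pseudocount approaches ln 20
    prof = build_pssm("f", ["CC"], pseudocount=1e-9)
    idx_c = AA_ALPHABET.index("C")
    assert prof.matrix[0, idx_c] == pytest.approx(math.log(20), abs=1e-6)
    with pytest.raises(ValueError):
        build_pssm("f", ["AC", "A"], 1.0)
    with pytest.raises(ValueError):
        build_pssm("f", ["AC"], 0.0)


def test_scan_finds_own_consensus_with_self_score(profiles3):
    pssms = profiles3.profiles()
    famA = pssms[0]
    hits = scan_domains("p", famA.consensus, pssms)
    assert len(hits) == 1
    assert hits[0].best_family == "famA"
    assert hits[0].score == pytest.approx(famA.self_score)
    assert hits[0].aa_interval == (0, famA.length)


def test_scan_separates_two_families_with_linker(profiles3):
    pssms = profiles3.profiles()
    protein = pssms[0].consensus + "GGGGGGGG" + pssms[1].consensus
    hits = scan_domains("p", protein, pssms)
    assert [h.best_family for h in hits] == ["famA", "famB"]
    assert hits[0].start == 0
    assert hits[1].start == len(pssms[0].consensus) + 8


def test_shuffled_consensus_rarely_hits(profiles3):
    pssms = profiles3.profiles()
    rng = np.random.default_rng(5)
    cons = list(pssms[0].consensus)
    n_hit = 0
    for _ in range(100):
        rng.shuffle(cons)
        if scan_domains("p", "".join(cons), pssms):
            n_hit += 1
    assert n_hit <= 5


def test_self_match_dominates_single_substitutions(profiles3):
    pssms = profiles3.profiles()
    famA = pssms[0]
    base = scan_domains("p", famA.consensus, pssms)[0].score
    rng = np.random.default_rng(9)
    for _ in range(50):
        pos = int(rng.integers(0, famA.length))
        aa = AA_ALPHABET[int(rng.integers(0, 20))]
        variant = famA.consensus[:pos] + aa + famA.consensus[pos + 1 :]
        hits = scan_domains("p", variant, pssms)
        assert not hits or hits[0].score <= base + 1e-9


def test_funnel_filter_preserves_order_and_counts(profiles3):
    pssms = profiles3.profiles()
    orfs = find_orfs("c", PAD + "ATG" + back_translate(pssms[0].consensus) + "TAA" + PAD, 50)
    hits = {o.orf_id: scan_domains(o.orf_id, o.protein, pssms) for o in orfs}
    kept, counts = filter_ig_candidates(orfs, hits)
    assert kept == orfs
    assert counts == {"n_input_orfs": 1, "n_ig_candidates": 1}
    kept, counts = filter_ig_candidates(orfs, {})
    assert kept == []
    assert counts["n_ig_candidates"] == 0
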