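"""Novel-vs-redundant adjudication for candidate receptor transcripts.

A candidate is compared to each previously annotated sequence on three
pieces of evidence: global percent identity of the proteins, chromosomal
interval overlap, and whether the candidate's Ig domains are identical
(p-distance zero) to domains of the subject.  The verdict rule:

* ``duplicate``                  — identity >= threshold (default 95%) AND the
                                   loci overlap;
* ``alt_transcript_candidate``   — the loci overlap, identity is below the
                                   threshold, but every candidate domain is
                                   identical to some subject domain (two
                                   transcripts of one gene differing in
                                   exon usage look exactly like this);
* ``novel``                      — everything else, including high identity at
                                   non-overlapping loci (paralogous copies at
                                   different positions are distinct genes).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import needleman_wunsch
from .phylo import p_distance

DEFAULT_IDENTITY_THRESHOLD = 95.0


@dataclass(frozen=True)
class RedundancyVerdict:
    query_id: str
    subject_id: str
    percent_identity: float
    overlap_bp: int
    identical_domain_count: int
    n_query_domains: int
    verdict: str  # duplicate | alt_transcript_candidate | novel


def percent_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment percent identity.

    100 x (identical aligned pairs) / (columns where both rows are residues).
    """
    a, b, _ = needleman_wunsch(seq_a, seq_b)
    pairs = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    ident = sum(1 for x, y in zip(a, b) if x != "-" and x == y)
    if pairs == 0:
        return 0.0
    return 100.0 * ident / pairs


def interval_overlap(
    a: tuple[str, int, int], b: tuple[str, int, int]
) -> int:
    """Overlap in bp of two 0-based half-open contig intervals (0 if different contigs)."""
    ca, sa, ea = a
    cb, sb, eb = b
    if ea < sa or eb < sb:
        raise ValueError("interval end precedes start")
    if ca != cb:
        return 0
    return max(0, min(ea, eb) - max(sa, sb))


def identical_domain_pairs(
    query_domains: list[str], subject_domains: list[str]
) -> int:
    """Count query domains identical (p-distance 0, >0 compared sites) to any subject domain."""
    count = 0
    for q in query_domains:
        for s in subject_domains:
            if len(q) != len(s):
                continue
            d, sites = p_distance(q, s)
            if sites > 0 and d == 0.0:
                count += 1
                break
    return count


def novelty_verdict(
    query_id: str,
    subject_id: str,
    identity: float,
    overlap_bp: int,
    n_query_domains: int,
    identical_domains: int,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> RedundancyVerdict:
    """Total three-way decision from precomputed evidence."""
    if overlap_bp > 0 and identity >= identity_threshold:
        verdict = "duplicate"
    elif (
        overlap_bp > 0
        and identity < identity_threshold
        and n_query_domains > 0
        and identical_domains == n_query_domains
    ):
        verdict = "alt_transcript_candidate"
    else:
        verdict = "novel"
    return RedundancyVerdict(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=identity,
        overlap_bp=overlap_bp,
        identical_domain_count=identical_domains,
        n_query_domains=n_query_domains,
        verdict=verdict,
    )


def adjudicate(
    query_id: str,
    query_protein: str,
    query_interval: tuple[str, int, int],
    query_domains: list[str],
    subject_id: str,
    subject_protein: str,
    subject_interval: tuple[str, int, int],
    subject_domains: list[str],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> RedundancyVerdict:
    """Compute all three pieces of evidence for one query/subject pair and decide."""
    ident = percent_identity(query_protein, subject_protein)
    ov = interval_overlap(query_interval, subject_interval)
    same = identical_domain_pairs(query_domains, subject_domains)
    return novelty_verdict(
        query_id,
        subject_id,
        ident,
        ov,
        len(query_domains),
        same,
        identity_threshold,
    )


def summarise(verdicts: list[RedundancyVerdict]) -> str:
    """Worst-case summary over a candidate's verdicts vs all subjects.

    duplicate beats alt_transcript_candidate beats novel; an empty list
    (no annotated subjects) is novel.
    """
    order = {"duplicate": 0, "alt_transcript_candidate": 1, "novel": 2}
    if not verdicts:
        return "novel"
    return min((v.verdict for v in verdicts), key=order.__getitem__)
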