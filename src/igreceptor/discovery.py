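"""Candidate ORF discovery and Ig-domain profile scanning.

The discovery funnel has two stages: a plain six-frame ORF finder over
genomic contigs, and a windowed position-specific scoring matrix (PSSM)
scan of each ORF's protein product against one profile per receptor
family.  ORFs with at least one profile hit are retained as Ig-receptor
candidates; the input/retained counts form the funnel record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
STOP_CODONS = {"TAA", "TAG", "TGA"}
NT_VALID = set("ACGTN")


@dataclass(frozen=True)
class CandidateORF:
    """An ATG-to-stop span in one of six frames, in contig coordinates."""

    orf_id: str
    contig_id: str
    start: int  # 0-based half-open, contig forward coordinates
    end: int
    strand: str  # '+' or '-'
    frame: int  # start offset mod 3 in the reading strand
    protein: str

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class DomainProfile:
    """Per-family log-odds matrix over amino acids (natural log, vs uniform)."""

    family: str
    matrix: np.ndarray  # (length, 20)
    consensus: str

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def self_score(self) -> float:
        """Score of the per-column best residue (consensus self-match)."""
        return float(self.matrix.max(axis=1).sum())


@dataclass(frozen=True)
class IgDomainHit:
    protein_id: str
    start: int  # 0-based aa offset, half-open interval [start, start+length)
    end: int
    score: float
    best_family: str
    per_family_scores: dict[str, float] = field(default_factory=dict)

    @property
    def aa_interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _translate(cds: str) -> str:
    """Translate a stop-stripped CDS; codons containing N become 'X'."""
    return str(Seq(cds).translate())


def find_orfs(contig_id: str, sequence: str, min_aa_length: int) -> list[CandidateORF]:
    """Find all ATG->stop ORFs of at least ``min_aa_length`` codons, six frames.

    Nested ORFs sharing a stop codon (internal ATGs) report only the longest.
    Results are ordered by contig position (leftmost first), then strand
    ('+' before '-') at equal position.  The interval includes the stop codon.

    ``N`` is tolerated: a codon containing N is never a start or stop and
    translates to ``X``.  Any other non-nucleotide character is an error.
    """
    if min_aa_length < 1:
        raise ValueError("min_aa_length must be >= 1")
    seq = sequence.upper()
    bad = set(seq) - NT_VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in {contig_id}: {sorted(bad)}")
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    found: list[CandidateORF] = []
    counter = 0
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            # walk codons; for each stop, keep earliest ATG since previous stop
            start_of_block: int | None = None  # earliest ATG in current open block
            pos = frame
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start_of_block is not None:
                        aa_len = (pos - start_of_block) // 3
                        if aa_len >= min_aa_length:
                            o_start, o_end = start_of_block, pos + 3
                            cds = s[o_start : o_end - 3]
                            if strand == "+":
                                c_start, c_end = o_start, o_end
                            else:
                                c_start, c_end = L - o_end, L - o_start
                            counter += 1
                            found.append(
                                CandidateORF(
                                    orf_id=f"{contig_id}_orf{counter}",
                                    contig_id=contig_id,
                                    start=c_start,
                                    end=c_end,
                                    strand=strand,
                                    frame=frame,
                                    protein=_translate(cds),
                                )
                            )
                    start_of_block = None
                elif codon == "ATG" and start_of_block is None:
                    start_of_block = pos
                pos += 3
    found.sort(key=lambda o: (o.start, 0 if o.strand == "+" else 1, o.end))
    # renumber in report order so ids are stable
    return [
        CandidateORF(
            orf_id=f"{contig_id}_orf{i + 1}",
            contig_id=o.contig_id,
            start=o.start,
            end=o.end,
            strand=o.strand,
            frame=o.frame,
            protein=o.protein,
        )
        for i, o in enumerate(found)
    ]


def build_pssm(
    family: str, aligned_examples: list[str], pseudocount: float = 1.0
) -> DomainProfile:
    """Build a log-odds PSSM from equal-length ungapped example sequences.

    entry(i, a) = ln[(count(i,a) + pseudocount/20) / (n + pseudocount)] - ln(1/20)
    """
    if not aligned_examples:
        raise ValueError("at least one example sequence required")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    length = len(aligned_examples[0])
    if any(len(s) != length for s in aligned_examples):
        raise ValueError("example sequences must all have equal length")
    n = len(aligned_examples)
    counts = np.zeros((length, 20), dtype=float)
    for s in aligned_examples:
        for i, a in enumerate(s):
            counts[i, AA_INDEX[a]] += 1.0
    freq = (counts + pseudocount / 20.0) / (n + pseudocount)
    matrix = np.log(freq) - np.log(1.0 / 20.0)
    consensus = "".join(AA_ALPHABET[j] for j in counts.argmax(axis=1))
    return DomainProfile(family=family, matrix=matrix, consensus=consensus)


def default_threshold(profiles: list[DomainProfile]) -> float:
    """Hit threshold: half the mean profile self-score."""
    return 0.5 * float(np.mean([p.self_score for p in profiles]))


def _encode_protein(protein: str) -> np.ndarray:
    idx = np.full(len(protein), 20, dtype=np.int64)  # 20 = unknown/X slot
    for i, a in enumerate(protein):
        idx[i] = AA_INDEX.get(a, 20)
    return idx


def scan_domains(
    protein_id: str,
    protein: str,
    profiles: list[DomainProfile],
    score_threshold: float | None = None,
) -> list[IgDomainHit]:
    """Scan every window of a protein against every family profile.

    Windows whose best per-family score reaches the threshold are kept, then
    overlaps are resolved greedily by descending score (ties to the leftmost
    start).  ``X``/unknown residues score as the per-column matrix mean.
    Returns hits in left-to-right order.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    if not protein:
        raise ValueError("empty protein")
    L = profiles[0].length
    if any(p.length != L for p in profiles):
        raise ValueError("profiles must share one length")
    if score_threshold is None:
        score_threshold = default_threshold(profiles)
    if len(protein) < L:
        return []
    idx = _encode_protein(protein)
    n_win = len(protein) - L + 1
    rows = np.arange(L)
    per_family = np.empty((len(profiles), n_win), dtype=float)
    for k, prof in enumerate(profiles):
        # extend matrix with a 21st column holding per-row means for X
        ext = np.hstack([prof.matrix, prof.matrix.mean(axis=1, keepdims=True)])
        per_family[k] = [float(ext[rows, idx[o : o + L]].sum()) for o in range(n_win)]
    best_k = per_family.argmax(axis=0)
    best_score = per_family.max(axis=0)
    candidates = [o for o in range(n_win) if best_score[o] >= score_threshold]
    candidates.sort(key=lambda o: (-best_score[o], o))
    chosen: list[int] = []
    for o in candidates:
        if all(o + L <= c or o >= c + L for c in chosen):
            chosen.append(o)
    chosen.sort()
    hits = []
    for o in chosen:
        k = int(best_k[o])
        hits.append(
            IgDomainHit(
                protein_id=protein_id,
                start=o,
                end=o + L,
                score=float(best_score[o]),
                best_family=profiles[k].family,
                per_family_scores={
                    p.family: float(per_family[j, o]) for j, p in enumerate(profiles)
                },
            )
        )
    return hits


def filter_ig_candidates(
    orfs: list[CandidateORF], hits_by_protein: dict[str, list[IgDomainHit]]
) -> tuple[list[CandidateORF], dict[str, int]]:
    """Keep ORFs with at least one Ig-domain hit; report funnel counts."""
    kept = [o for o in orfs if hits_by_protein.get(o.orf_id)]
    counts = {"n_input_orfs": len(orfs), "n_ig_candidates": len(kept)}
    return kept, counts
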