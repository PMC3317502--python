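"""Synthetic Ig-receptor fixtures with known truth.

Every downstream stage of the pipeline is exercised on generated data in
which family membership, domain architecture, signalling class, locus and
expression status are known by construction.  The generator emulates a
multi-family immunoglobulin-like receptor locus:

* one ~90-aa C2-set Ig domain consensus per family, with controlled
  inter-family divergence;
* receptor genes built as signal peptide + 2/4/6 mutated domain copies +
  stalk + (21-residue hydrophobic transmembrane block, unless soluble) +
  cytoplasmic tail, with an ITIM (``[VLSN]xYxx[LV]``) in inhibitory tails
  and a transmembrane arginine in activating receptors;
* decoy ORFs with no Ig-domain content, mimicking the non-receptor open
  reading frames a genomic search sweeps up;
* contigs assembled from these ORFs on both strands with stop-codon
  guards in the intergenic spacers, so the ORF census of a contig is
  exactly the placed truth set;
* fixed-length (default 36 nt) substitution-error reads drawn uniformly
  from expressed transcripts on both strands.

Class truth is enforced on the *final* mutated protein by the generator's
own motif/hydropathy checks (resampling until they hold), never by calling
the classifier module — which keeps the generator/classifier agreement a
genuine cross-implementation test.

Determinism: a parameter record including the seed reproduces every
fixture byte-identically.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from . import discovery
from .discovery import AA_ALPHABET, DomainProfile, build_pssm, default_threshold

# one fixed codon per amino acid; L and S chosen so that frame-aligned
# reverse-strand reading of coding sequence is stop-rich (TTA->TAA,
# TCA->TGA), which suppresses spurious reverse-strand ORFs
CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCA", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
STOP = "TAA"

HYDROPHOBIC = "LIVFAM"
POLAR = "DEGHKNQRT"  # tail/stalk background; no Y, so no accidental ITIMs
ITIM_RE = re.compile(r"(?=([VLSN].Y..[LV]))")
# Kyte-Doolittle values for the generator's own TM self-check (kept local
# on purpose: the classifier module must remain an independent observer)
_KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# stop codons in all three frames, forward ("P") and reverse ("M") strand
GUARD_P = "TAAATAAATAA"
GUARD_M = "TTATTTATTTA"

SIGNAL_LENGTH = 15
# inter-domain linker: its fixed codons (TTAACTAATCAT) place a stop codon
# in every non-coding frame on both strands, so spurious off-frame ORFs
# can never span a domain junction on the assembled contig
DOMAIN_LINKER = "LTNH"
STALK_LENGTH = 12
TM_LENGTH = 21
TAIL_LENGTH = 30
CLASSES = ("inhibitory", "activating", "soluble")


@dataclass(frozen=True)
class FamilyProfileSet:
    family_labels: tuple[str, ...]
    domain_consensus: dict[str, str]
    generation_seed: int
    inter_family_divergence: float
    domain_length: int

    def profiles(self, pseudocount: float = 1.0) -> list[DomainProfile]:
        return [
            build_pssm(f, [self.domain_consensus[f]], pseudocount)
            for f in self.family_labels
        ]


@dataclass(frozen=True)
class SyntheticGene:
    gene_id: str
    family: str
    n_ig_domains: int
    class_label: str
    cds: str  # ATG.. without the stop codon
    protein: str
    contig_id: str = ""
    start: int = 0  # 0-based half-open ORF interval incl. stop codon
    end: int = 0
    strand: str = "+"
    domain_truth: tuple[tuple[int, int], ...] = ()
    expressed: bool = True
    annotated: bool = False

    @property
    def transcript(self) -> str:
        return self.cds + STOP

    @property
    def placement(self) -> tuple[str, int, int]:
        return (self.contig_id, self.start, self.end)


@dataclass(frozen=True)
class DecoyORF:
    orf_id: str
    protein: str
    cds: str
    contig_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"


@dataclass(frozen=True)
class GeneSpec:
    family: str
    n_domains: int
    class_label: str
    expressed: bool = True
    annotated: bool = False


@dataclass
class FixtureBundle:
    profiles: FamilyProfileSet
    contigs: dict[str, str]
    genes: list[SyntheticGene]
    decoys: list[DecoyORF]
    reads: list[tuple[str, str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def truth_table(self) -> list[dict]:
        return [
            {
                "gene_id": g.gene_id,
                "family": g.family,
                "class": g.class_label,
                "n_domains": g.n_ig_domains,
                "expressed": g.expressed,
                "annotated": g.annotated,
            }
            for g in self.genes
        ]

    def truth_features(self) -> list[tuple]:
        """GFF-style feature tuples (seqid, type, start, end, strand, attrs)."""
        feats = []
        for g in self.genes:
            feats.append(
                (
                    g.contig_id,
                    "gene",
                    g.start,
                    g.end,
                    g.strand,
                    {
                        "ID": g.gene_id,
                        "family": g.family,
                        "class": g.class_label,
                        "ig_domain": "true",
                        "n_domains": str(g.n_ig_domains),
                        "expressed": str(g.expressed).lower(),
                    },
                )
            )
        for d in self.decoys:
            feats.append(
                (
                    d.contig_id,
                    "gene",
                    d.start,
                    d.end,
                    d.strand,
                    {"ID": d.orf_id, "ig_domain": "false"},
                )
            )
        return sorted(feats, key=lambda f: (f[0], f[2], f[3]))


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# profiles


def build_profiles(
    seed: int,
    family_labels: list[str],
    domain_length: int = 90,
    inter_family_divergence: float = 0.4,
) -> FamilyProfileSet:
    """One Ig-domain consensus per family at a controlled divergence.

    Each family consensus is the shared ancestral sequence mutated at a
    ``inter_family_divergence`` fraction of positions; the set is
    regenerated until every pair differs at >= divergence/2 of sites.
    """
    if len(family_labels) < 2:
        raise ValueError("need at least two families")
    if len(set(family_labels)) != len(family_labels):
        raise ValueError("family labels must be unique")
    if not 0.0 < inter_family_divergence < 1.0:
        raise ValueError("inter_family_divergence must be in (0, 1)")
    if domain_length < 30:
        raise ValueError("domain_length must be >= 30")
    n_mut = int(round(inter_family_divergence * domain_length))
    for attempt in range(200):
        rng = np.random.default_rng([int(seed), attempt, 101])
        ancestor = _random_protein(rng, domain_length)
        consensus = {}
        for fam in family_labels:
            consensus[fam] = _mutate(rng, ancestor, n_mut)
        # Ig C2 domains are extracellular: reject consensus sets carrying a
        # near-TM hydrophobic stretch, which would make soluble receptors
        # built from them carry a spurious membrane anchor
        if any(_max_window_hydropathy(c) >= 1.3 for c in consensus.values()):
            continue
        if _min_pair_divergence(consensus) >= inter_family_divergence * 0.5:
            return FamilyProfileSet(
                family_labels=tuple(family_labels),
                domain_consensus=consensus,
                generation_seed=int(seed),
                inter_family_divergence=inter_family_divergence,
                domain_length=domain_length,
            )
    raise GenerationError("could not satisfy inter-family divergence")


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = AA_ALPHABET) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def _mutate(rng: np.random.Generator, seq: str, n_positions: int) -> str:
    pos = rng.choice(len(seq), size=min(n_positions, len(seq)), replace=False)
    out = list(seq)
    for p in pos:
        choices = [a for a in AA_ALPHABET if a != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _max_window_hydropathy(seq: str, window: int = 19) -> float:
    vals = [_KD.get(a, 0.0) for a in seq]
    if len(vals) < window:
        return float("-inf")
    best = total = sum(vals[:window])
    for i in range(1, len(vals) - window + 1):
        total += vals[i + window - 1] - vals[i - 1]
        best = max(best, total)
    return best / window


def _min_pair_divergence(consensus: dict[str, str]) -> float:
    fams = list(consensus)
    best = 1.0
    for i in range(len(fams)):
        for j in range(i + 1, len(fams)):
            a, b = consensus[fams[i]], consensus[fams[j]]
            frac = sum(x != y for x, y in zip(a, b)) / len(a)
            best = min(best, frac)
    return best


def build_reference_domains(
    profiles: FamilyProfileSet,
    per_family: int = 3,
    divergence: float = 0.1,
    seed: int = 0,
) -> dict[str, tuple[str, str]]:
    """Reference domain sequences per family (id -> (family, sequence))."""
    rng = np.random.default_rng([int(seed), 202])
    n_mut = int(round(divergence * profiles.domain_length))
    refs = {}
    for fam in profiles.family_labels:
        for k in range(per_family):
            refs[f"{fam}_ref{k + 1}"] = (
                fam,
                _mutate(rng, profiles.domain_consensus[fam], n_mut),
            )
    return refs


# ---------------------------------------------------------------------------
# genes


def back_translate(protein: str) -> str:
    return "".join(CODON[a] for a in protein)


def _best_tm_span(
    protein: str, window: int = 19, threshold: float = 1.6
) -> tuple[int, int] | None:
    """Generator's own TM detector: best run of passing hydropathy windows.

    Same published definition the classifier implements (sliding-window
    Kyte-Doolittle mean, highest-peak run, C-terminal ties), coded
    independently here so the generator can verify class truth on the
    final protein without consulting the classifier module.
    """
    vals = [_KD.get(a, 0.0) for a in protein]
    n = len(vals)
    if n < window:
        return None
    means = []
    total = sum(vals[:window])
    means.append(total / window)
    for i in range(1, n - window + 1):
        total += vals[i + window - 1] - vals[i - 1]
        means.append(total / window)
    best = None  # (peak, run_start, run_end)
    run_start = None
    for i, m in enumerate(means + [float("-inf")]):
        if m >= threshold:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            peak = max(means[run_start:i])
            if best is None or peak > best[0] or (peak == best[0] and run_start > best[1]):
                best = (peak, run_start, i - 1)
            run_start = None
    if best is None:
        return None
    return best[1], best[2] + window


def _self_check_class(protein: str, expect_tm: bool) -> str:
    """Generator's own class derivation from the final protein."""
    span = _best_tm_span(protein)
    if span is None:
        return "soluble"
    if not expect_tm:
        return "INVALID"  # a soluble product must not contain a detectable TM
    start, end = span
    tail = protein[end:]
    if ITIM_RE.search(tail):
        return "inhibitory"
    if "R" in protein[start:end]:
        return "activating"
    return "unclassified"


def synthesize_gene(
    profiles: FamilyProfileSet,
    gene_id: str,
    family: str,
    n_domains: int,
    class_label: str,
    within_divergence: float = 0.1,
    rng: np.random.Generator | None = None,
    expressed: bool = True,
    annotated: bool = False,
    max_attempts: int = 200,
) -> SyntheticGene:
    """One receptor gene with verified class truth.

    The protein is signal peptide + ``n_domains`` mutated consensus copies +
    stalk + (TM block unless soluble) + cytoplasmic tail; mutations are
    resampled until the class derived from the final protein matches
    ``class_label``.
    """
    if family not in profiles.family_labels:
        raise ValueError(f"unknown family {family!r}")
    if n_domains not in (2, 4, 6):
        raise ValueError("n_domains must be 2, 4 or 6")
    if class_label not in CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    if within_divergence >= profiles.inter_family_divergence / 2:
        raise ValueError("within_divergence must be < inter_family_divergence/2")
    if rng is None:
        rng = np.random.default_rng(0)
    L = profiles.domain_length
    n_mut = int(round(within_divergence * L))
    consensus = profiles.domain_consensus[family]
    for _ in range(max_attempts):
        signal = "M" + _random_protein(rng, SIGNAL_LENGTH - 1, POLAR)
        domains = [_mutate(rng, consensus, n_mut) for _ in range(n_domains)]
        stalk = _random_protein(rng, STALK_LENGTH, POLAR)
        tail_bg = _random_protein(rng, TAIL_LENGTH, POLAR)
        if class_label == "soluble":
            tm_block = ""
        else:
            tm_block = _random_protein(rng, TM_LENGTH, HYDROPHOBIC)
            if class_label == "activating":
                mid = TM_LENGTH // 2
                tm_block = tm_block[:mid] + "R" + tm_block[mid + 1 :]
        if class_label == "inhibitory":
            motif = "VTY" + _random_protein(rng, 2, POLAR) + ("L", "V")[rng.integers(0, 2)]
            off = int(rng.integers(4, TAIL_LENGTH - 6))
            tail = tail_bg[:off] + motif + tail_bg[off + 6 :]
        else:
            tail = tail_bg
        ecto = signal + "".join(d + DOMAIN_LINKER for d in domains) + stalk
        protein = ecto + tm_block + tail
        if _self_check_class(protein, expect_tm=class_label != "soluble") != class_label:
            continue
        step = L + len(DOMAIN_LINKER)
        dom_truth = tuple(
            (SIGNAL_LENGTH + i * step, SIGNAL_LENGTH + i * step + L)
            for i in range(n_domains)
        )
        return SyntheticGene(
            gene_id=gene_id,
            family=family,
            n_ig_domains=n_domains,
            class_label=class_label,
            cds=back_translate(protein),
            protein=protein,
            domain_truth=dom_truth,
            expressed=expressed,
            annotated=annotated,
        )
    raise GenerationError(f"class {class_label!r} unreachable for gene {gene_id}")


# ---------------------------------------------------------------------------
# fixture assembly


def default_gene_specs() -> list[GeneSpec]:
    """The default 26-receptor repertoire.

    16 unannotated ("novel") genes split 7 inhibitory / 4 activating /
    5 soluble, including two six-domain (PIR-like) receptors, plus 10
    previously-annotated genes; all expressed.
    """
    novel = (
        [GeneSpec("famA", 4, "inhibitory")] * 4
        + [GeneSpec("famB", 2, "inhibitory")] * 2
        + [GeneSpec("famC", 6, "inhibitory")]
        + [GeneSpec("famA", 4, "activating")] * 2
        + [GeneSpec("famB", 2, "activating")]
        + [GeneSpec("famC", 6, "activating")]
        + [GeneSpec("famA", 4, "soluble")] * 3
        + [GeneSpec("famB", 2, "soluble")] * 2
    )
    annotated = (
        [GeneSpec("famA", 4, "inhibitory", annotated=True)] * 2
        + [GeneSpec("famA", 4, "activating", annotated=True)]
        + [GeneSpec("famA", 4, "soluble", annotated=True)]
        + [GeneSpec("famB", 2, "inhibitory", annotated=True)]
        + [GeneSpec("famB", 2, "activating", annotated=True)]
        + [GeneSpec("famB", 2, "soluble", annotated=True)]
        + [GeneSpec("famC", 6, "inhibitory", annotated=True)]
        + [GeneSpec("famC", 6, "activating", annotated=True)]
        + [GeneSpec("famC", 6, "soluble", annotated=True)]
    )
    return novel + annotated


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def build_fixture(
    gene_specs: list[GeneSpec] | None = None,
    decoy_orf_count: int = 51,
    intergenic_length: int = 120,
    seed: int = 0,
    n_contigs: int = 3,
    family_labels: tuple[str, ...] = ("famA", "famB", "famC"),
    domain_length: int = 90,
    inter_family_divergence: float = 0.4,
    within_divergence: float = 0.1,
    min_aa_length: int = 150,
    pseudocount: float = 1.0,
    max_attempts: int = 30,
) -> FixtureBundle:
    """Assemble contigs whose ORF census exactly equals the placed truth set.

    After assembly the contigs are re-scanned with the discovery module's
    ORF finder and PSSM scanner; any spurious ORF, missing ORF, or domain
    hit disagreeing with truth triggers a full deterministic regeneration
    from a derived sub-seed.  Decoy ORFs are valid ORFs whose products
    carry no Ig-domain profile material.
    """
    if gene_specs is None:
        gene_specs = default_gene_specs()
    if not gene_specs:
        raise ValueError("need at least one gene")
    if decoy_orf_count < 0:
        raise ValueError("decoy_orf_count must be >= 0")
    profiles = build_profiles(
        seed, list(family_labels), domain_length, inter_family_divergence
    )
    pssms = profiles.profiles(pseudocount)
    threshold = default_threshold(pssms)
    last_err = "no attempts made"
    for attempt in range(max_attempts):
        rng = np.random.default_rng([int(seed), attempt, 303])
        genes = [
            synthesize_gene(
                profiles,
                f"G{i + 1:02d}",
                sp.family,
                sp.n_domains,
                sp.class_label,
                within_divergence,
                rng,
                expressed=sp.expressed,
                annotated=sp.annotated,
            )
            for i, sp in enumerate(gene_specs)
        ]
        decoys = []
        for i in range(decoy_orf_count):
            plen = int(rng.integers(max(min_aa_length, 160), max(min_aa_length, 160) + 70))
            prot = "M" + _random_protein(rng, plen - 1)
            decoys.append(
                DecoyORF(orf_id=f"D{i + 1:02d}", protein=prot, cds=back_translate(prot))
            )
        placed_genes, placed_decoys, contigs = _assemble_contigs(
            rng, genes, decoys, n_contigs, intergenic_length
        )
        ok, last_err = _validate_fixture(
            contigs, placed_genes, placed_decoys, pssms, threshold, min_aa_length
        )
        if ok:
            params = {
                "seed": int(seed),
                "attempt": attempt,
                "n_genes": len(genes),
                "decoy_orf_count": decoy_orf_count,
                "intergenic_length": intergenic_length,
                "n_contigs": n_contigs,
                "family_labels": list(family_labels),
                "domain_length": domain_length,
                "inter_family_divergence": inter_family_divergence,
                "within_divergence": within_divergence,
                "min_aa_length": min_aa_length,
                "pseudocount": pseudocount,
            }
            return FixtureBundle(
                profiles=profiles,
                contigs=contigs,
                genes=placed_genes,
                decoys=placed_decoys,
                params=params,
            )
    raise GenerationError(f"fixture assembly failed after {max_attempts} attempts: {last_err}")


def _assemble_contigs(rng, genes, decoys, n_contigs, intergenic_length):
    items: list[tuple[str, object]] = [("gene", g) for g in genes] + [
        ("decoy", d) for d in decoys
    ]
    order = rng.permutation(len(items))
    contig_ids = [f"contig{c + 1}" for c in range(n_contigs)]
    parts = {c: [] for c in contig_ids}
    cursor = {c: 0 for c in contig_ids}
    placed_genes: list[SyntheticGene] = []
    placed_decoys: list[DecoyORF] = []

    def spacer() -> str:
        return GUARD_P + GUARD_M + _random_dna(rng, intergenic_length) + GUARD_P + GUARD_M

    for c in contig_ids:
        s = spacer()
        parts[c].append(s)
        cursor[c] += len(s)
    for rank, k in enumerate(order):
        kind, obj = items[k]
        c = contig_ids[rank % n_contigs]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        orf_nt = obj.cds + STOP
        insert = orf_nt if strand == "+" else str(Seq(orf_nt).reverse_complement())
        start = cursor[c]
        end = start + len(insert)
        parts[c].append(insert)
        cursor[c] = end
        s = spacer()
        parts[c].append(s)
        cursor[c] += len(s)
        if kind == "gene":
            g: SyntheticGene = obj
            placed_genes.append(
                SyntheticGene(
                    gene_id=g.gene_id,
                    family=g.family,
                    n_ig_domains=g.n_ig_domains,
                    class_label=g.class_label,
                    cds=g.cds,
                    protein=g.protein,
                    contig_id=c,
                    start=start,
                    end=end,
                    strand=strand,
                    domain_truth=g.domain_truth,
                    expressed=g.expressed,
                    annotated=g.annotated,
                )
            )
        else:
            d: DecoyORF = obj
            placed_decoys.append(
                DecoyORF(
                    orf_id=d.orf_id,
                    protein=d.protein,
                    cds=d.cds,
                    contig_id=c,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
    placed_genes.sort(key=lambda g: g.gene_id)
    placed_decoys.sort(key=lambda d: d.orf_id)
    contigs = {c: "".join(parts[c]) for c in contig_ids}
    return placed_genes, placed_decoys, contigs


def _validate_fixture(contigs, genes, decoys, pssms, threshold, min_aa_length):
    truth = {}
    for g in genes:
        truth[(g.contig_id, g.start, g.end, g.strand)] = ("gene", g)
    for d in decoys:
        truth[(d.contig_id, d.start, d.end, d.strand)] = ("decoy", d)
    found = {}
    for cid, seq in contigs.items():
        for orf in discovery.find_orfs(cid, seq, min_aa_length):
            found[(orf.contig_id, orf.start, orf.end, orf.strand)] = orf
    if set(found) != set(truth):
        extra = set(found) - set(truth)
        missing = set(truth) - set(found)
        return False, f"ORF census mismatch (extra={len(extra)}, missing={len(missing)})"
    for key, orf in found.items():
        kind, obj = truth[key]
        hits = discovery.scan_domains(orf.orf_id, orf.protein, pssms, threshold)
        if kind == "decoy":
            if hits:
                return False, f"decoy {obj.orf_id} has Ig hits"
        else:
            if len(hits) != obj.n_ig_domains:
                return False, f"gene {obj.gene_id}: {len(hits)} hits != {obj.n_ig_domains}"
            if any(h.best_family != obj.family for h in hits):
                return False, f"gene {obj.gene_id}: family mismatch in hits"
            if tuple((h.start, h.end) for h in hits) != obj.domain_truth:
                return False, f"gene {obj.gene_id}: hit intervals differ from truth"
    return True, ""


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    bundle: FixtureBundle,
    depth: float = 20.0,
    read_length: int = 36,
    error_rate: float = 0.005,
    seed: int = 0,
    utr_length: int = 50,
) -> list[tuple[str, str, str]]:
    """Uniform fixed-length reads from expressed transcripts, both strands.

    Each expressed gene's mRNA is its coding span plus ``utr_length`` of
    flanking genomic sequence on each side (untranslated regions), so
    reads straddle the coding-sequence boundaries the way real
    transcript reads do.  Expected read count per transcript is
    depth x mRNA length / read_length; substitution errors are placed
    independently per base at ``error_rate``.  Returns (read_id,
    sequence, quality) triples with a constant Q30 placeholder quality;
    read ids carry the source transcript id.
    """
    if not 0.0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    expressed = [g for g in bundle.genes if g.expressed]
    if not expressed:
        warnings.warn("no expressed transcripts; emitting no reads")
        return []

    def mrna(g: SyntheticGene) -> str:
        contig = bundle.contigs[g.contig_id]
        lo = max(0, g.start - utr_length)
        hi = min(len(contig), g.end + utr_length)
        span = contig[lo:hi]
        return span if g.strand == "+" else str(Seq(span).reverse_complement())

    shortest = min(len(mrna(g)) for g in expressed)
    if read_length > shortest:
        raise ValueError("read_length exceeds shortest expressed transcript")
    rng = np.random.default_rng([int(seed), 404])
    reads = []
    for g in expressed:
        t = mrna(g)
        n_reads = int(round(depth * len(t) / read_length))
        if n_reads == 0:
            continue
        positions = rng.integers(0, len(t) - read_length + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for i in range(n_reads):
            frag = t[positions[i] : positions[i] + read_length]
            if strands[i] == 1:
                frag = str(Seq(frag).reverse_complement())
            if error_rate > 0.0:
                mask = rng.random(read_length) < error_rate
                if mask.any():
                    chars = list(frag)
                    for j in np.nonzero(mask)[0]:
                        alt = [b for b in "ACGT" if b != chars[j]]
                        chars[j] = alt[rng.integers(0, 3)]
                    frag = "".join(chars)
            strand_tag = "+" if strands[i] == 0 else "-"
            reads.append(
                (f"{g.gene_id}:{i:05d}:{strand_tag}", frag, "?" * read_length)
            )
    bundle.reads = reads
    return reads
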