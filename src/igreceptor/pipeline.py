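"""End-to-end orchestration: fixture -> discovery -> phylogeny -> redundancy
-> structure -> expression, with one seed and one config.

The run directory receives diff-able text reports only (FASTA/FASTQ/GFF3/
TSV/JSON/newick); re-running with an identical config is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import coverage as cov
from . import discovery, io_utils, redundancy, structure, synthetic
from .phylo import (
    DomainAlignment,
    assign_family,
    bootstrap_supports,
    distance_matrix,
)


@dataclass
class PipelineConfig:
    """All stage parameters with study defaults.

    Published-protocol values are the defaults where the protocol states
    one: 1000 bootstrap replicates, 95% identity threshold, 36 nt reads,
    mismatch costs 2 then 1, strict >99% expression coverage.
    """

    seed: int = 0
    # fixture; repertoire None means the default 26-gene set
    repertoire: list[list] | None = None  # [family, n_domains, class, expressed, annotated]
    decoy_orf_count: int = 51
    intergenic_length: int = 120
    n_contigs: int = 3
    family_labels: tuple[str, ...] = ("famA", "famB", "famC")
    domain_length: int = 90
    inter_family_divergence: float = 0.4
    within_divergence: float = 0.1
    # discovery
    min_aa_length: int = 150
    pseudocount: float = 1.0
    domain_threshold: float | None = None  # None = auto (half mean self-score)
    # phylogeny
    bootstrap_replicates: int = 1000
    ambiguity_margin: float = 0.05
    refs_per_family: int = 3
    run_bootstrap: bool = True
    # redundancy
    identity_threshold: float = 95.0
    # structure
    tm_window: int = 19
    tm_threshold: float = 1.6
    # expression
    read_length: int = 36
    read_depth: float = 20.0
    read_error_rate: float = 0.005
    mismatch_cost: int = 2
    remap_cost: int = 1
    expression_threshold: float = 99.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["family_labels"] = list(self.family_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "family_labels" in d:
            d["family_labels"] = tuple(d["family_labels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class CandidateDossier:
    candidate_id: str
    n_ig_domains: int
    family_call: str
    chimeric: bool
    redundancy_verdict: str
    class_call: str
    percent_mapped: float
    expressed: bool
    truth_gene_id: str = ""


@dataclass
class PipelineResult:
    funnel: dict
    dossiers: list[CandidateDossier]
    bundle: synthetic.FixtureBundle
    out_dir: Path
    checksums: dict[str, str] = field(default_factory=dict)


def summarize_repertoire(dossiers: list[CandidateDossier]) -> dict:
    """Counts by class, family and expression; totals conserved."""
    if not dossiers:
        raise ValueError("no dossiers to summarise")
    by_class: dict[str, int] = {}
    by_family: dict[str, int] = {}
    n_expressed = 0
    for d in dossiers:
        by_class[d.class_call] = by_class.get(d.class_call, 0) + 1
        by_family[d.family_call] = by_family.get(d.family_call, 0) + 1
        n_expressed += int(d.expressed)
    return {
        "n": len(dossiers),
        "by_class": dict(sorted(by_class.items())),
        "by_family": dict(sorted(by_family.items())),
        "n_expressed": n_expressed,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gene_specs = (
        [synthetic.GeneSpec(f, int(n), c, bool(e), bool(a))
         for f, n, c, e, a in config.repertoire]
        if config.repertoire is not None
        else None
    )

    # --- stage 0: fixture -------------------------------------------------
    bundle = synthetic.build_fixture(
        gene_specs=gene_specs,
        decoy_orf_count=config.decoy_orf_count,
        intergenic_length=config.intergenic_length,
        seed=config.seed,
        n_contigs=config.n_contigs,
        family_labels=config.family_labels,
        domain_length=config.domain_length,
        inter_family_divergence=config.inter_family_divergence,
        within_divergence=config.within_divergence,
        min_aa_length=config.min_aa_length,
        pseudocount=config.pseudocount,
    )
    synthetic.simulate_reads(
        bundle,
        depth=config.read_depth,
        read_length=config.read_length,
        error_rate=config.read_error_rate,
        seed=config.seed,
    )
    io_utils.write_fasta(bundle.contigs, out / "contigs.fasta")
    io_utils.write_gff3(bundle.truth_features(), out / "truth.gff3")
    io_utils.write_tsv(
        bundle.truth_table(),
        out / "truth_table.tsv",
        ["gene_id", "family", "class", "n_domains", "expressed", "annotated"],
    )
    io_utils.write_fastq(bundle.reads, out / "reads.fastq")
    io_utils.write_json(bundle.params, out / "params.json")

    # --- stage 1: discovery ----------------------------------------------
    pssms = bundle.profiles.profiles(config.pseudocount)
    threshold = (
        config.domain_threshold
        if config.domain_threshold is not None
        else discovery.default_threshold(pssms)
    )
    orfs: list[discovery.CandidateORF] = []
    for cid in sorted(bundle.contigs):
        orfs.extend(
            discovery.find_orfs(cid, bundle.contigs[cid], config.min_aa_length)
        )
    hits_by_protein = {
        o.orf_id: discovery.scan_domains(o.orf_id, o.protein, pssms, threshold)
        for o in orfs
    }
    candidates, funnel_counts = discovery.filter_ig_candidates(orfs, hits_by_protein)
    io_utils.write_fasta({o.orf_id: o.protein for o in candidates},
                         out / "candidate_proteins.fasta")
    io_utils.write_gff3(
        [
            (o.contig_id, "ORF", o.start, o.end, o.strand,
             {"ID": o.orf_id, "ig_domain": "true" if hits_by_protein[o.orf_id] else "false"})
            for o in orfs
        ],
        out / "orfs.gff3",
    )
    io_utils.write_tsv(
        [
            {"protein_id": h.protein_id, "start": h.start, "end": h.end,
             "best_family": h.best_family, "score": h.score}
            for o in candidates for h in hits_by_protein[o.orf_id]
        ],
        out / "domain_hits.tsv",
        ["protein_id", "start", "end", "best_family", "score"],
    )

    # map candidates back to truth genes by placement (for reporting only)
    truth_by_key = {
        (g.contig_id, g.start, g.end, g.strand): g for g in bundle.genes
    }
    truth_of = {
        o.orf_id: truth_by_key.get((o.contig_id, o.start, o.end, o.strand))
        for o in candidates
    }

    # --- stage 2: phylogeny / family assignment ---------------------------
    query_rows: dict[str, str] = {}
    receptor_of: dict[str, str] = {}
    for o in candidates:
        for k, h in enumerate(hits_by_protein[o.orf_id]):
            did = f"{o.orf_id}|d{k + 1}"
            query_rows[did] = o.protein[h.start : h.end]
            receptor_of[did] = o.orf_id
    refs = synthetic.build_reference_domains(
        bundle.profiles,
        per_family=config.refs_per_family,
        divergence=config.within_divergence,
        seed=config.seed,
    )
    assignment = assign_family(
        query_rows,
        refs,
        receptor_of,
        ambiguity_margin=config.ambiguity_margin,
    )
    family_of = {r.receptor_id: r for r in assignment.receptors}
    all_rows = dict(query_rows)
    all_rows.update({rid: row for rid, (_, row) in refs.items()})
    aln = DomainAlignment(tuple(all_rows), tuple(all_rows.values()))
    dm = distance_matrix(aln)
    _write_phylip(dm, out / "distances.tsv")
    if config.run_bootstrap:
        tree, _ = bootstrap_supports(aln, config.bootstrap_replicates, config.seed)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
    io_utils.write_tsv(
        [
            {"domain_id": dc.domain_id, "best_family": dc.best_family,
             "margin": dc.margin,
             "receptor_call": family_of[receptor_of[dc.domain_id]].family,
             "chimeric": family_of[receptor_of[dc.domain_id]].chimeric}
            for dc in assignment.domains
        ],
        out / "assignments.tsv",
        ["domain_id", "best_family", "margin", "receptor_call", "chimeric"],
    )

    # --- stage 3: redundancy vs annotated set -----------------------------
    subjects = [g for g in bundle.genes if g.annotated]
    verdict_rows = []
    verdicts_by_candidate: dict[str, list[redundancy.RedundancyVerdict]] = {}
    for o in candidates:
        q_domains = [query_rows[d] for d, r in receptor_of.items() if r == o.orf_id]
        q_interval = (o.contig_id, o.start, o.end)
        vs = []
        for g in subjects:
            ov = redundancy.interval_overlap(q_interval, g.placement)
            if ov > 0:
                v = redundancy.adjudicate(
                    o.orf_id, o.protein, q_interval, q_domains,
                    g.gene_id, g.protein, g.placement,
                    [g.protein[a:b] for a, b in g.domain_truth],
                    config.identity_threshold,
                )
            else:
                # non-overlapping loci are distinct genes whatever the
                # identity; skip the costly alignment
                v = redundancy.novelty_verdict(
                    o.orf_id, g.gene_id, 0.0, 0, len(q_domains), 0,
                    config.identity_threshold,
                )
            vs.append(v)
            verdict_rows.append(
                {"query": v.query_id, "subject": v.subject_id,
                 "identity": v.percent_identity, "overlap_bp": v.overlap_bp,
                 "identical_domains": v.identical_domain_count,
                 "verdict": v.verdict}
            )
        verdicts_by_candidate[o.orf_id] = vs
    io_utils.write_tsv(
        verdict_rows, out / "verdicts.tsv",
        ["query", "subject", "identity", "overlap_bp", "identical_domains", "verdict"],
    )

    # --- stage 4: structure ------------------------------------------------
    classifications = {
        o.orf_id: structure.classify_receptor(
            o.orf_id, o.protein, config.tm_window, config.tm_threshold
        )
        for o in candidates
    }
    io_utils.write_tsv(
        [
            {
                "protein_id": c.protein_id,
                "tm_start": c.tm.start if c.tm else "",
                "tm_end": c.tm.end if c.tm else "",
                "n_itims": len(c.itims),
                "itim_variants": ",".join(s.variant for s in c.itims),
                "tm_arginine": c.tm_arginine,
                "class": c.class_call,
            }
            for c in classifications.values()
        ],
        out / "classifications.tsv",
        ["protein_id", "tm_start", "tm_end", "n_itims", "itim_variants",
         "tm_arginine", "class"],
    )

    # --- stage 5: expression ------------------------------------------------
    # reads are mapped onto the contigs themselves and coverage is
    # evaluated over each predicted gene region, the same shape as
    # mapping transcript reads back to the chromosomal segments
    regions = [(o.orf_id, o.contig_id, o.start, o.end) for o in candidates]
    reads = {rid: seq for rid, seq, _ in bundle.reads}
    first_pass, final_pass, placements = cov.two_pass_region_coverage(
        reads, bundle.contigs, regions, config.read_length,
        config.mismatch_cost, config.remap_cost, config.expression_threshold,
    )
    io_utils.write_tsv(
        [
            {"reference_id": r.reference_id,
             "percent_mapped_cost%d" % config.mismatch_cost:
                 first_pass[r.reference_id].percent_mapped_int,
             "percent_mapped_cost%d" % config.remap_cost: r.percent_mapped_int,
             "expressed": r.expressed}
            for r in final_pass.values()
        ],
        out / "coverage.tsv",
        ["reference_id",
         "percent_mapped_cost%d" % config.mismatch_cost,
         "percent_mapped_cost%d" % config.remap_cost,
         "expressed"],
    )
    io_utils.write_tsv(
        [
            {"read_id": p.read_id, "ref": p.reference_id, "pos": p.position,
             "strand": p.strand, "mismatches": p.mismatches, "score": p.score}
            for p in placements
        ],
        out / "placements.tsv",
        ["read_id", "ref", "pos", "strand", "mismatches", "score"],
    )

    # --- dossiers and funnel -------------------------------------------------
    dossiers = []
    for o in candidates:
        rc = family_of[o.orf_id]
        cls = classifications[o.orf_id]
        rep = final_pass[o.orf_id]
        g = truth_of[o.orf_id]
        dossiers.append(
            CandidateDossier(
                candidate_id=o.orf_id,
                n_ig_domains=len(hits_by_protein[o.orf_id]),
                family_call=rc.family,
                chimeric=rc.chimeric,
                redundancy_verdict=redundancy.summarise(
                    verdicts_by_candidate[o.orf_id]
                ),
                class_call=cls.class_call,
                percent_mapped=rep.percent_mapped,
                expressed=rep.expressed,
                truth_gene_id=g.gene_id if g else "",
            )
        )
    novel = [d for d in dossiers if d.redundancy_verdict == "novel"]
    class_counts: dict[str, int] = {}
    for d in novel:
        class_counts[d.class_call] = class_counts.get(d.class_call, 0) + 1
    funnel = {
        "n_orfs": funnel_counts["n_input_orfs"],
        "n_ig_candidates": funnel_counts["n_ig_candidates"],
        "n_family_assigned": sum(
            1 for d in dossiers if d.family_call != "unassigned"
        ),
        "n_novel": len(novel),
        "novel_class_counts": dict(sorted(class_counts.items())),
        "n_novel_expressed": sum(1 for d in novel if d.expressed),
    }
    io_utils.write_json(funnel, out / "funnel.json")
    io_utils.write_tsv(
        [
            {"candidate_id": d.candidate_id, "truth_gene_id": d.truth_gene_id,
             "n_ig_domains": d.n_ig_domains, "family_call": d.family_call,
             "chimeric": d.chimeric, "redundancy_verdict": d.redundancy_verdict,
             "class_call": d.class_call, "percent_mapped": d.percent_mapped,
             "expressed": d.expressed}
            for d in dossiers
        ],
        out / "dossiers.tsv",
        ["candidate_id", "truth_gene_id", "n_ig_domains", "family_call",
         "chimeric", "redundancy_verdict", "class_call", "percent_mapped",
         "expressed"],
    )
    io_utils.write_json(config.to_dict(), out / "run_config.json")

    checksums = {}
    for p in sorted(out.iterdir()):
        if p.is_file():
            checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    io_utils.write_json(checksums, out / "checksums.json")
    return PipelineResult(funnel, dossiers, bundle, out, checksums)


def _write_phylip(dm, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for i, lab in enumerate(dm.labels):
            row = "\t".join(f"{dm.d[i, j]:.6f}" for j in range(len(dm.labels)))
            fh.write(f"{lab}\t{row}\n")
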