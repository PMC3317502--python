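# igreceptor

Characterisation of immunoglobulin-like receptor gene families from
genomic sequence: candidate discovery, phylogenetic family assignment,
redundancy adjudication, signalling-class prediction and expression
calling — as one tested, reproducible pipeline.

## The problem

Innate-immune receptor families of the leukocyte receptor complex (LILR,
KIR, and the rodent PIR) are tandem arrays of highly similar genes, each
receptor built from 2–6 extracellular C2-set immunoglobulin (Ig) domains
(~90 aa), an optional single-pass transmembrane (TM) helix, and a
cytoplasmic tail. Annotating such a family in a newly sequenced genome
means answering five questions for every candidate open reading frame:

1. **Is it a receptor at all?** — does its protein product contain Ig
   domains (a 77-ORF search set typically funnels down to a few dozen)?
2. **Which family is it?** — each Ig domain is placed on a
   neighbour-joining tree against reference domains, using amino-acid
   p-distance with *pairwise deletion* (for rows `a`, `b` of one
   alignment, `d = #differing / #comparable` over columns where neither
   row has a gap or `X`), with branch confidence from bootstrap
   resampling of alignment columns;
3. **Is it novel?** — a candidate with ≥95% global-alignment identity to
   an annotated gene *at an overlapping locus* is a duplicate; identical
   Ig domains at the same locus below 95% suggest an alternative
   transcript; everything else (including high identity at a different
   position) is novel;
4. **How does it signal?** — no TM ⇒ soluble; TM plus ≥1 cytoplasmic
   ITIM (`[VLSN]xYxx[LV]`) ⇒ inhibitory; TM, no ITIM, but a charged
   arginine inside the TM ⇒ activating (ITAM-adaptor recruiting);
5. **Is it expressed?** — 36-nt transcript reads are mapped ungapped
   (score = matches − cost·mismatches, cost 2 then a permissive re-map
   at cost 1, acceptance at ≥80% of read length); a gene region covered
   at strictly more than 99% of its bases is called expressed.

Because no public per-gene dataset accompanies the analysis this package
reimplements, it ships a first-class synthetic-data module that builds
receptor loci with *known* family, architecture, class and expression
truth, so every stage is tested against ground truth and analytic
oracles (brute-force six-frame scanning, column-count p-distance,
least-squares tree search, exhaustive motif windows).

## Worked example

```bash
python examples/07_full_pipeline.py
```

prints (seed 1):

```
funnel: {'n_orfs': 77, 'n_ig_candidates': 26, 'n_family_assigned': 26,
         'n_novel': 16, 'novel_class_counts': {'activating': 4,
         'inhibitory': 7, 'soluble': 5}, 'n_novel_expressed': 16}
novel repertoire: {'n': 16, 'by_class': {'activating': 4, 'inhibitory': 7,
                   'soluble': 5}, 'by_family': {'famA': 9, 'famB': 5,
                   'famC': 2}, 'n_expressed': 16}
```

Reading: of 77 ORFs found on the three synthetic contigs, 26 contain Ig
domains; 16 of those do not duplicate the annotated set and are the novel
repertoire, classified 7 inhibitory / 4 activating / 5 soluble, with all
16 showing >99% read coverage (expressed). Each `examples/` script
demonstrates one capability the same way (fixture generation, discovery,
phylogeny, classification, redundancy, coverage).

A thin CLI wraps the same library calls:

```bash
igr run --seed 1 --out runs/demo      # full pipeline
igr fixture --seed 1 --out fix/       # just the synthetic locus
igr classify --proteins p.fa --out cls.tsv
```

## Layout

| Module | Role |
| --- | --- |
| `igreceptor.synthetic` | truth-known receptor loci, profiles, reads |
| `igreceptor.discovery` | six-frame ORF finder, PSSM domain scanner |
| `igreceptor.phylo` | p-distance, NJ, bootstrap, consensus, family calls |
| `igreceptor.redundancy` | identity / overlap / identical-domain verdicts |
| `igreceptor.structure` | TM, ITIM and arginine based classification |
| `igreceptor.coverage` | ungapped read mapping, per-base coverage calls |
| `igreceptor.pipeline` | end-to-end orchestration, reports, determinism |

See `docs/methods.md` for the models, parameter choices and limitations.
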