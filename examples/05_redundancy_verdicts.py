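"""Adjudicate novelty: percent identity, locus overlap and identical-
domain evidence decide duplicate vs alternative transcript vs novel."""

from igreceptor import adjudicate, build_profiles

profiles = build_profiles(1, ["famA", "famB"])
cons = profiles.domain_consensus["famA"]
query = "M" + "Q" * 39 + cons + "N" * 40 + cons + "T" * 40
alt = "M" + "E" * 39 + cons + "G" * 40 + cons + "K" * 40

cases = [
    ("same protein, same locus", query, ("chr18", 100, 700)),
    ("diverged linkers, same locus, identical domains", alt, ("chr18", 100, 700)),
    ("same protein, different locus", query, ("chr18", 9000, 9600)),
]
for label, subject, interval in cases:
    v = adjudicate(
        "BL_new", query, ("chr18", 0, 600), [cons, cons],
        "annotated", subject, interval, [cons, cons],
    )
    print(f"{label:48s} identity {v.percent_identity:5.1f}% "
          f"overlap {v.overlap_bp:4d} bp -> {v.verdict}")
# >=95% identity at an overlapping locus is a duplicate; identical Ig
# domains at the same locus below 95% suggest an alternative transcript;
# high identity at a different position is still a novel (paralogous) gene.
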