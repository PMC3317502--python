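"""Classify receptors as inhibitory / activating / soluble from their
transmembrane segment, cytoplasmic ITIMs and TM arginine."""

import numpy as np

from igreceptor import build_profiles, classify_receptor, synthesize_gene

profiles = build_profiles(1, ["famA", "famB"])
rng = np.random.default_rng(2)
for cls in ("inhibitory", "activating", "soluble"):
    g = synthesize_gene(profiles, f"demo_{cls}", "famA", 2, cls, 0.1, rng)
    c = classify_receptor(g.gene_id, g.protein)
    tm = f"{c.tm.start}-{c.tm.end}" if c.tm else "none"
    itims = ",".join(s.variant for s in c.itims) or "-"
    print(f"{g.gene_id:16s} TM {tm:9s} ITIMs {itims:8s} "
          f"R-in-TM {str(c.tm_arginine):5s} -> {c.class_call}")
# Inhibitory receptors carry a tail ITIM ([VLSN]xYxx[LV]); activating
# ones have no ITIM but a charged arginine inside the TM helix; soluble
# ones lack any membrane anchor.
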