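"""Run the five-stage pipeline end to end on the default fixture and
print the discovery funnel and per-candidate dossiers."""

import tempfile

from igreceptor import PipelineConfig, run_pipeline, summarize_repertoire

config = PipelineConfig(seed=1, bootstrap_replicates=100, read_depth=10.0)
with tempfile.TemporaryDirectory() as out:
    result = run_pipeline(config, out)

print("funnel:", result.funnel)
novel = [d for d in result.dossiers if d.redundancy_verdict == "novel"]
print("novel repertoire:", summarize_repertoire(novel))
for d in novel[:4]:
    print(f"  {d.candidate_id}: {d.n_ig_domains} domains, {d.family_call}, "
          f"{d.class_call}, {d.percent_mapped:.0f}% mapped")
# Expected: 77 ORFs -> 26 Ig candidates -> 16 novel receptors split
# 7 inhibitory / 4 activating / 5 soluble, all 16 called expressed.
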