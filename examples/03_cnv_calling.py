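"""Simulate coverage with a planted heterozygous deletion and call it.

Counts are negative-binomial around mean_depth x probe efficiency x
copy/2.  After two-step median normalization a diploid cell sits at 1.0
and a heterozygous deletion at ~0.5; a run of >= 7 consecutive probes at
<= 0.7 is auto-called, shorter runs go to the qPCR follow-up tier.
"""

from mipscreen import (CnvEvent, CoverageSimSpec, annotate_cnv,
                       build_fixture_gene_model, call_cnvs, normalize,
                       simulate_coverage, tile_panel)

model = build_fixture_gene_model(seed=1)
panel = tile_panel(model)

events = [
    CnvEvent(sample_id="S003", first_mip_index=100, n_mips=12, copy_state=1),
    CnvEvent(sample_id="S007", first_mip_index=30, n_mips=4, copy_state=1),
]
cov = simulate_coverage(panel, 40, CoverageSimSpec(cnv_events=events), seed=2)
print(f"coverage: {cov.shape[0]} samples x {cov.shape[1]} probes, "
      f"mean {cov.to_numpy().mean():.0f}x")

norm = normalize(cov)
for call in call_cnvs(norm):
    call = annotate_cnv(call, panel, model)
    print(f"{call.sample_id}: {call.type} over {call.n_mips} probes "
          f"(exons {call.exon_span}, mean ratio {call.mean_ratio:.2f}) "
          f"-> {call.status}")
# The 12-probe event is auto-called; the 4-probe event is flagged for
# orthogonal qPCR confirmation instead.
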