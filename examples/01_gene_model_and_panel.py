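"""Build the packaged gene fixture and tile a MIP panel over it.

The fixture emulates a very large recessive deafness-blindness gene:
73 exons spread over ~800 kb with a 15.6-kb coding sequence.  The panel
tiles every exon plus 20 nt of flanking intron with 112-nt probe targets
(new probe every 90 nt) and adds dedicated probes for four published
deep-intronic variant positions.
"""

from mipscreen import build_fixture_gene_model, tile_panel

model = build_fixture_gene_model(seed=1)
panel = tile_panel(model)

print(f"gene {model.gene_id}: {model.n_exons} exons, "
      f"span {model.total_span:,} nt, coding {model.coding_length:,} nt")
print(f"panel: {len(panel)} probes of 112 nt "
      f"({len(panel.deep_intronic_loci)} deep-intronic loci)")

e43 = model.exon(43)
print(f"exon 43: c.{e43.c_start}-{e43.c_end} ({e43.length} nt) -> "
      f"{len(panel.probes_within(e43.genomic_start - 20, e43.genomic_end + 20))} probes")
# A 123-nt exon spans only 2 probes: a deletion of it can never reach the
# 7-consecutive-probe auto-call threshold and must go to qPCR follow-up.
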