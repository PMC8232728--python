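"""Variant nomenclature arithmetic: parsing, reading frame, Grantham.

Parses the kinds of HGVS strings a screening report contains (intronic
offsets, unknown breakpoints, large deletion-insertions), checks whether
deletions preserve the reading frame, and scores amino-acid exchanges
with the Grantham physicochemical distance.
"""

from mipscreen import (deleted_aa_count, grantham, is_canonical_splice,
                       is_inframe, parse_c, parse_p_del)

cnv = parse_c("c.8559-?_8681+?del")  # whole-exon loss, breakpoints unknown
print(f"{cnv}: exon span {cnv.exonic_span_nt} nt, "
      f"in frame: {is_inframe(cnv.exonic_span_nt)}")

prot = parse_p_del("p.(Tyr2854_Arg2894del)")
print(f"{prot}: removes {deleted_aa_count(prot)} residues")
# 123 deleted nt = 41 codons: an in-frame single-exon loss.

leaky = parse_p_del("p.(Arg2894_Asn2906del,=)")
print(f"{leaky}: removes {deleted_aa_count(leaky)} residues "
      f"(mosaic with wildtype: {leaky.mosaic})")

for v in ("c.9258+1G>A", "c.7595-3C>G"):
    print(f"{v}: canonical splice site: {is_canonical_splice(parse_c(v))}")

print(f"Grantham Trp->Gly: {grantham('Trp', 'Gly')} (radical, >= 80)")
print(f"Grantham Tyr->Ser: {grantham('Tyr', 'Ser')}")
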