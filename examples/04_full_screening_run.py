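"""Full screening analysis on the packaged study-mirror cohort.

Simulates 29 USH2 + 11 arRP cases with planted SNV/CNV genotypes and
annotation decoys, then chains coverage normalization, run-length CNV
calling, the variant triage cascade and per-case resolution, writing a
complete report bundle.
"""

from pathlib import Path

from mipscreen import PipelineConfig, run_pipeline

out = Path("example_bundle")
bundle = run_pipeline(PipelineConfig(seed=1), out, simulate=True)
s = bundle["summary_payload"]

print(f"cases: {s['total']}  solved: {s['solved_inclusive']} "
      f"({s['percent_solved']}%)  biallelic P/LP only: {s['solved_strict']}")
for ph, pct in s["percent_by_phenotype"].items():
    print(f"  {ph}: {pct}% solved")
print(f"CNV alleles: {s['cnv_alleles']} across {s['cnv_distinct']} distinct CNVs")
print(f"WGS referrals: {s['n_wgs_referrals']} -> {', '.join(s['wgs_referrals'])}")
print(f"variant funnel: {s['funnel']}")
print(f"report bundle written to {out}/")
# 32/40 solved (80%): two qualifying alleles found; the seven cases left
# unexplained inside the gene (minus one solved elsewhere) go to WGS.
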