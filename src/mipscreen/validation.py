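"""Statistical validation studies for the CNV caller.

These drive the packaged simulator end-to-end (coverage simulation ->
normalization -> run-length calling) over many seeded cohorts and score
recovery of the planted events:

* sensitivity: fraction of planted run-length-or-longer deletion events
  recovered by an auto-called CNV of the right type;
* follow-up flagging: fraction of planted sub-run-length events that
  surface in the qPCR follow-up tier;
* false auto-call rate per sample: called CNVs overlapping no planted
  event.
"""

from __future__ import annotations

import numpy as np

from .cnv import call_cnvs, normalize
from .panel import MipPanel
from .simulate import CoverageSimSpec, plant_random_events, simulate_coverage


def cnv_recovery_study(panel: MipPanel, n_cohorts: int = 100,
                       n_samples: int = 40, seed: int = 0,
                       min_run: int = 7) -> dict:
    """Run the seeded parameter-recovery study and return its scores."""
    rng = np.random.default_rng(seed)
    n_large = n_small = n_large_hit = n_small_hit = n_false = 0
    for k in range(n_cohorts):
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
        events = plant_random_events(panel, sample_ids, rng)
        cohort_seed = int(rng.integers(0, 2**31 - 1))
        cov = simulate_coverage(panel, sample_ids,
                                CoverageSimSpec(cnv_events=events),
                                seed=cohort_seed)
        calls = call_cnvs(normalize(cov), min_run=min_run)
        by_sample: dict[str, list] = {}
        for c in calls:
            by_sample.setdefault(c.sample_id, []).append(c)
        matched_calls = set()
        for ev in events:
            hits = [c for c in by_sample.get(ev.sample_id, [])
                    if c.type == "deletion"
                    and c.overlaps(ev.first_mip_index, ev.last_mip_index)]
            matched_calls.update(id(c) for c in hits)
            if ev.n_mips >= min_run:
                n_large += 1
                n_large_hit += any(c.status == "called" for c in hits)
            else:
                n_small += 1
                n_small_hit += any(c.status == "qpcr_followup" for c in hits)
        n_false += sum(1 for c in calls
                       if c.status == "called" and id(c) not in matched_calls)
    return {
        "n_cohorts": n_cohorts,
        "n_large_events": n_large,
        "n_small_events": n_small,
        "sensitivity": n_large_hit / n_large if n_large else float("nan"),
        "small_event_flag_rate": n_small_hit / n_small if n_small else float("nan"),
        "false_calls_per_sample": n_false / (n_cohorts * n_samples),
    }
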