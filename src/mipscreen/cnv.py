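"""Coverage normalization and run-length CNV calling on a MIP panel.

Raw per-sample x per-MIP read counts are normalized in two steps — each
sample's row is scaled by its median count (depth correction), then each
MIP column is divided by its cohort median — so a diploid cell has
expectation 1.0 regardless of probe capture efficiency.  A heterozygous
deletion then shows ~0.5, a single-copy duplication ~1.5.

A deletion is called when at least ``min_run`` (default 7) consecutive
MIPs all have normalized coverage <= 0.7; a duplication when at least
``min_run`` consecutive MIPs are >= 1.3 (both thresholds inclusive, as
printed in the screening protocol this emulates).  Shorter excursions of
2 to ``min_run``-1 MIPs are reported as a qPCR-follow-up tier rather than
auto-called; singleton excursions are ignored as noise.  MIPs whose
cohort-median raw count falls below a floor are excluded from calling,
and runs are bridged across excluded MIPs so a structurally dropped-out
probe cannot split a true event.

Low-coverage regions are reported per sample in two tiers: below 10 reads
(manual inspection) and below 5 reads (PCR + Sanger follow-up).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genemodel import GeneModel
from .hgvs import is_inframe
from .panel import MipPanel

logger = logging.getLogger(__name__)

DEL_THRESHOLD = 0.7
DUP_THRESHOLD = 1.3
MIN_RUN = 7
MIN_FOLLOWUP_RUN = 2
MEDIAN_FLOOR = 20
HOMOZYGOUS_RATIO = 0.15  # mean ratio at or below this suggests biallelic loss


@dataclass
class NormalizedCoverage:
    """Normalized coverage matrix plus the MIPs excluded from calling."""

    values: pd.DataFrame  # samples x MIPs; NaN for excluded MIPs
    excluded_mips: list[str]
    sample_scale: pd.Series

    @property
    def included_mips(self) -> list[str]:
        return [m for m in self.values.columns if m not in set(self.excluded_mips)]


def normalize(raw: pd.DataFrame, median_floor: float = MEDIAN_FLOOR) -> NormalizedCoverage:
    """Two-step median normalization of a raw count matrix.

    Requires >= 3 samples (the per-MIP cohort reference is a median).
    MIPs whose cohort median raw count is below ``median_floor`` are
    excluded from CNV calling (their cells become NaN).  Raises ValueError
    naming the sample if a sample has no reads at all.
    """
    if raw.shape[0] < 3:
        raise ValueError("cohort-median normalization requires >= 3 samples")
    zero = raw.sum(axis=1) == 0
    if zero.any():
        bad = raw.index[zero][0]
        raise ValueError(f"sample {bad!r} has zero coverage on every MIP")

    mip_median_raw = raw.median(axis=0)
    excluded = [m for m in raw.columns if mip_median_raw[m] < median_floor]
    included = [m for m in raw.columns if m not in set(excluded)]
    if not included:
        raise ValueError("every MIP falls below the median floor")

    sample_scale = raw[included].median(axis=1)
    if (sample_scale == 0).any():
        bad = sample_scale.index[sample_scale == 0][0]
        raise ValueError(f"sample {bad!r} has zero median coverage")
    scaled = raw.div(sample_scale, axis=0)
    ratio = scaled[included].div(scaled[included].median(axis=0), axis=1)
    # De-bias the per-sample scale: a large CNV (tens of consecutive MIPs)
    # shifts the raw-count median of its carrier, inflating the rest of the
    # row.  The median of the per-MIP ratios is robust to aberrant runs
    # covering <50% of the panel, so one polish pass re-centers diploid
    # cells at 1.0.
    debias = ratio.median(axis=1)
    sample_scale = sample_scale * debias
    ratio = ratio.div(debias, axis=0)
    values = ratio.div(ratio.median(axis=0), axis=1)  # per-MIP median exactly 1
    values = values.reindex(columns=raw.columns)  # excluded -> NaN
    return NormalizedCoverage(values=values, excluded_mips=excluded,
                              sample_scale=sample_scale)


@dataclass
class CnvCall:
    """A run of consecutive MIPs with aberrant normalized coverage."""

    sample_id: str
    first_mip_index: int
    last_mip_index: int
    type: str  # deletion | duplication
    n_mips: int  # qualifying (included) MIPs in the run
    mean_ratio: float
    status: str  # called | qpcr_followup
    first_mip_id: str = ""
    last_mip_id: str = ""
    exon_span: str = ""
    first_exon: int | None = None
    last_exon: int | None = None
    deleted_nt: int | None = None
    in_frame: bool | None = None
    aa_count: int | None = None

    @property
    def likely_homozygous(self) -> bool:
        """Coverage-band hint only; zygosity is never asserted from depth."""
        return self.type == "deletion" and self.mean_ratio <= HOMOZYGOUS_RATIO

    def overlaps(self, first: int, last: int) -> bool:
        return self.first_mip_index <= last and self.last_mip_index >= first


def _state(x: float, del_thresh: float, dup_thresh: float) -> int:
    if x <= del_thresh:
        return -1
    if x >= dup_thresh:
        return 1
    return 0


def call_cnvs(norm: NormalizedCoverage, del_thresh: float = DEL_THRESHOLD,
              dup_thresh: float = DUP_THRESHOLD, min_run: int = MIN_RUN,
              min_followup: int = MIN_FOLLOWUP_RUN, merge_gap: int = 1,
              panel: MipPanel | None = None) -> list[CnvCall]:
    """Scan each sample for maximal runs of consecutive aberrant MIPs.

    Runs of >= ``min_run`` qualifying MIPs become status ``called``; runs
    of ``min_followup``..``min_run``-1 become ``qpcr_followup``; singletons
    are ignored (logged at debug level).  Excluded MIPs are transparent:
    a run continues across them when both flanks qualify.  Same-type runs
    separated by at most ``merge_gap`` discordant included MIPs are merged
    (a single capture fluctuation inside a long event must not split it);
    ``n_mips`` counts qualifying MIPs only, and the thresholds apply to
    that count.  ``merge_gap=0`` gives the strict maximal-run behaviour.
    """
    mip_ids = list(norm.values.columns)
    included_idx = [i for i, m in enumerate(mip_ids)
                    if m not in set(norm.excluded_mips)]
    pos_of = {mip: k for k, mip in enumerate(included_idx)}
    calls: list[CnvCall] = []
    arr = norm.values.to_numpy()
    for s_i, sample in enumerate(norm.values.index):
        row = arr[s_i]
        # maximal same-state runs over the included-MIP sequence
        runs: list[tuple[int, list[int]]] = []  # (state, member indices)
        state, members = 0, []
        for i in included_idx:
            st = _state(row[i], del_thresh, dup_thresh)
            if st != state:
                if state != 0 and members:
                    runs.append((state, members))
                state, members = st, []
            if st != 0:
                members.append(i)
        if state != 0 and members:
            runs.append((state, members))

        # merge same-type runs across small discordant gaps
        merged: list[tuple[int, list[int]]] = []
        for st, mem in runs:
            if (merged and merged[-1][0] == st
                    and pos_of[mem[0]] - pos_of[merged[-1][1][-1]] - 1 <= merge_gap):
                merged[-1][1].extend(mem)
            else:
                merged.append((st, list(mem)))

        for st, mem in merged:
            n = len(mem)
            if n < min_followup:
                logger.debug("singleton excursion ignored: %s mip %d",
                             sample, mem[0])
                continue
            first, last = mem[0], mem[-1]
            calls.append(CnvCall(
                sample_id=str(sample), first_mip_index=first,
                last_mip_index=last,
                type="deletion" if st < 0 else "duplication", n_mips=n,
                mean_ratio=float(np.mean([row[i] for i in mem])),
                status="called" if n >= min_run else "qpcr_followup",
                first_mip_id=mip_ids[first], last_mip_id=mip_ids[last]))
            if last - first + 1 != n:
                logger.info("run %s:%d-%d spans %d excluded/discordant MIP(s)",
                            sample, first, last, (last - first + 1) - n)
    return calls


def annotate_cnv(call: CnvCall, panel: MipPanel, model: GeneModel) -> CnvCall:
    """Attach exon span and reading-frame consequence to a CNV call.

    The affected exon range is derived from the genomic footprint of the
    run's probes; the frame consequence from the summed coding length of
    those exons (an exon-level approximation appropriate for events whose
    breakpoints lie in introns).
    """
    g_start = panel[call.first_mip_index].start
    g_end = panel[call.last_mip_index].end
    exons = model.exons_overlapping(g_start, g_end)
    if exons:
        call.first_exon, call.last_exon = exons[0].index, exons[-1].index
        call.exon_span = (str(exons[0].index) if len(exons) == 1
                          else f"{exons[0].index}-{exons[-1].index}")
        call.deleted_nt = sum(e.length for e in exons)
        call.in_frame = is_inframe(call.deleted_nt)
        call.aa_count = call.deleted_nt // 3 if call.in_frame else None
    else:
        call.exon_span = "intronic"
        call.deleted_nt = 0
        call.in_frame = None
    return call


@dataclass
class LowCoverageRegion:
    """A per-sample run of MIPs below the manual-inspection read floor."""

    sample_id: str
    first_mip_index: int
    last_mip_index: int
    min_reads: int
    manual_check: bool = True
    sanger: bool = False  # also below the Sanger-follow-up floor
    first_mip_id: str = ""
    last_mip_id: str = ""

    @property
    def tier(self) -> str:
        return "sanger" if self.sanger else "manual_check"


def low_coverage_report(raw: pd.DataFrame, manual_thresh: int = 10,
                        sanger_thresh: int = 5) -> list[LowCoverageRegion]:
    """Per-sample maximal runs of MIPs with raw reads below the floors.

    Every region below ``sanger_thresh`` is by construction also below
    ``manual_thresh``; it is reported once, carrying both tier flags.
    """
    if sanger_thresh > manual_thresh:
        raise ValueError("sanger threshold cannot exceed the manual threshold")
    mip_ids = list(raw.columns)
    out: list[LowCoverageRegion] = []
    arr = raw.to_numpy()
    for s_i, sample in enumerate(raw.index):
        row = arr[s_i]
        i = 0
        while i < len(row):
            if row[i] < manual_thresh:
                j = i
                while j + 1 < len(row) and row[j + 1] < manual_thresh:
                    j += 1
                min_reads = int(row[i:j + 1].min())
                out.append(LowCoverageRegion(
                    sample_id=str(sample), first_mip_index=i, last_mip_index=j,
                    min_reads=min_reads, sanger=min_reads < sanger_thresh,
                    first_mip_id=mip_ids[i], last_mip_id=mip_ids[j]))
                i = j + 1
            else:
                i += 1
    return out


def cnv_calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    cols = ["sample_id", "first_mip_index", "last_mip_index", "first_mip_id",
            "last_mip_id", "type", "n_mips", "mean_ratio", "status",
            "exon_span", "first_exon", "last_exon", "deleted_nt", "in_frame",
            "aa_count"]
    rows = [{c: getattr(call, c) for c in cols} for call in calls]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df["mean_ratio"] = df["mean_ratio"].round(4)
    return df
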