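"""MIP panel geometry: 112-nt capture targets tiling the exons of a gene.

Each molecular inversion probe captures a fixed-length (112 nt) target.
The panel tiles every exon plus 20 nt of flanking intron with a new probe
every 90 nt (22-nt overlap, so interior positions are covered by at least
two probes — a prerequisite for the probe-edge artifact rule used during
variant triage), and adds one dedicated probe per published deep-intronic
locus.  Probe order along the genome defines ``panel_index``, the axis on
which run-length CNV calling operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from intervaltree import IntervalTree

from .genemodel import GeneModel
from .hgvs import parse_c

PROBE_LENGTH = 112
DEFAULT_FLANK = 20
DEFAULT_STEP = 90

#: deep-intronic loci with dedicated probes in the fixture panel
DEFAULT_DEEP_INTRONIC = (
    "c.5573-843A>G",
    "c.7595-2144A>G",
    "c.8845+628C>T",
    "c.9959-4159A>G",
)


@dataclass(frozen=True)
class MipProbe:
    """One probe target: 1-based inclusive genomic interval of fixed length."""

    mip_id: str
    start: int
    end: int
    panel_index: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class MipPanel:
    """Ordered probe set over one gene."""

    def __init__(self, probes: list[MipProbe], deep_intronic_loci: tuple[str, ...] = ()):
        self.probes = sorted(probes, key=lambda p: p.panel_index)
        starts = [p.start for p in self.probes]
        if starts != sorted(starts):
            raise ValueError("panel_index ordering inconsistent with genomic order")
        self.deep_intronic_loci = tuple(deep_intronic_loci)
        self._tree = IntervalTree()
        for p in self.probes:
            self._tree.addi(p.start, p.end + 1, p)  # half-open internally
        self._by_id = {p.mip_id: p for p in self.probes}

    def __len__(self) -> int:
        return len(self.probes)

    def __getitem__(self, panel_index: int) -> MipProbe:
        return self.probes[panel_index]

    def probe(self, mip_id: str) -> MipProbe:
        return self._by_id[mip_id]

    @property
    def mip_ids(self) -> list[str]:
        return [p.mip_id for p in self.probes]

    def probes_overlapping(self, genomic_pos: int) -> list[MipProbe]:
        """All probes whose target contains the position, in panel order."""
        hits = [iv.data for iv in self._tree.at(genomic_pos)]
        return sorted(hits, key=lambda p: p.panel_index)

    def probes_within(self, genomic_start: int, genomic_end: int) -> list[MipProbe]:
        """Probes fully contained in a 1-based inclusive interval."""
        hits = [iv.data for iv in self._tree.overlap(genomic_start, genomic_end + 1)]
        return sorted((p for p in hits
                       if p.start >= genomic_start and p.end <= genomic_end),
                      key=lambda p: p.panel_index)

    def is_probe_terminal(self, genomic_pos: int) -> list[MipProbe]:
        """Probes for which the position is the last target nucleotide."""
        return [p for p in self.probes_overlapping(genomic_pos) if p.end == genomic_pos]


def _tile_interval(start: int, end: int, probe_len: int, step: int) -> list[tuple[int, int]]:
    """Cover [start, end] with fixed-length probes anchored every ``step`` nt.

    The final probe is right-anchored so the interval end is always interior
    to a probe; a target shorter than one probe gets a single left-anchored
    probe (which then overhangs the interval).
    """
    length = end - start + 1
    if length <= probe_len:
        return [(start, start + probe_len - 1)]
    anchors = list(range(start, end - probe_len + 1, step))
    last = end - probe_len + 1
    if anchors[-1] != last:
        anchors.append(last)
    return [(a, a + probe_len - 1) for a in anchors]


def tile_panel(model: GeneModel, probe_len: int = PROBE_LENGTH,
               flank: int = DEFAULT_FLANK, step: int = DEFAULT_STEP,
               deep_intronic_loci: tuple[str, ...] = DEFAULT_DEEP_INTRONIC) -> MipPanel:
    """Design a panel covering every exon ±flank plus deep-intronic loci.

    Raises ValueError for zero-length exons or a step wider than the probe
    (which would leave gaps).
    """
    if step >= probe_len:
        raise ValueError("tiling step must be smaller than the probe length")
    intervals: list[tuple[int, int]] = []
    for e in model.exons:
        if e.length < 1:
            raise ValueError(f"zero-length exon {e.index}")
        intervals.extend(_tile_interval(e.genomic_start - flank,
                                        e.genomic_end + flank, probe_len, step))
    for locus in deep_intronic_loci:
        g = model.coding_to_genomic(parse_c(locus).start)
        half = probe_len // 2
        intervals.append((g - half + 1, g - half + probe_len))
    intervals.sort()
    probes = [MipProbe(mip_id=f"MIP{i:04d}", start=s, end=t, panel_index=i)
              for i, (s, t) in enumerate(intervals)]
    return MipPanel(probes, deep_intronic_loci=deep_intronic_loci)


def validate_coverage(panel: MipPanel, model: GeneModel, flank: int = DEFAULT_FLANK) -> bool:
    """Brute-force check that every exon ±flank nucleotide is in ≥1 probe."""
    covered = IntervalTree()
    for p in panel.probes:
        covered.addi(p.start, p.end + 1)
    covered.merge_overlaps()
    for e in model.exons:
        for g in range(e.genomic_start - flank, e.genomic_end + flank + 1):
            if not covered.at(g):
                return False
    return True


# -- BED on-disk representation (0-based half-open) -------------------

def write_panel_bed(panel: MipPanel, path: str | Path, contig: str = "synthetic_gene") -> None:
    with open(path, "w") as fh:
        for p in panel.probes:
            fh.write(f"{contig}\t{p.start - 1}\t{p.end}\t{p.mip_id}\n")


def read_panel_bed(path: str | Path,
                   deep_intronic_loci: tuple[str, ...] = ()) -> MipPanel:
    probes = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {i + 1}: expected 4 BED columns")
            _, start0, end, mip_id = fields[:4]
            probes.append(MipProbe(mip_id=mip_id, start=int(start0) + 1,
                                   end=int(end), panel_index=len(probes)))
    return MipPanel(probes, deep_intronic_loci=deep_intronic_loci)
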