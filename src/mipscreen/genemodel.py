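"""Gene/transcript coordinate scaffold for a MIP screening panel.

A :class:`GeneModel` holds the ordered exon structure of one transcript in
1-based inclusive genomic coordinates together with the cumulative coding
(c.) position of every exon, so that c.-HGVS positions (including signed
intron offsets) can be projected onto the pseudo-genome that coverage and
panel geometry live on.

The packaged fixture gene emulates a very large Usher-syndrome-type-2
locus: 73 exons over a span of exactly 800,503 nt with a 15,606-nt coding
sequence.  Its exon boundaries are a fixed table chosen so that every
variant position used by the downstream worked examples (exon-deletion
spans, deep-intronic loci, canonical and non-canonical splice positions)
falls where its nomenclature implies; the random seed only varies the
lengths of unconstrained introns while preserving the total span.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hgvs import CodingPosition, parse_c

FIXTURE_SPAN = 800_503
FIXTURE_CODING_LENGTH = 15_606
FIXTURE_N_EXONS = 73

# Cumulative coding end (c. position of the last base) of each fixture exon.
_FIXTURE_C_ENDS = [
    160, 330, 510, 690, 870, 1050, 1230, 1440, 1644,
    1810, 1971, 2130, 2473, 2740, 3010, 3280, 3550, 3820, 4090, 4360, 4627,
    4747, 4867, 4987, 5182, 5377, 5572, 5727, 5882, 6037, 6192, 6347, 6502,
    6657, 6812, 6967, 7120,
    7594, 7835, 8076, 8317, 8558, 8681, 8845, 9010, 9258, 9371, 9520, 9958,
    10100,
    10260, 10420, 10580, 10740, 10900, 11047, 11250, 11389, 11600, 11800,
    12000,
    12600, 13200, 13800, 14350, 14582, 14800, 14980, 15130, 15350, 15440,
    15530, 15606,
]

# Lower bounds on intron lengths (intron i follows exon i).  Introns that
# host a deep-intronic locus or a deletion breakpoint written relative to a
# boundary must be at least twice the deepest offset, so the HGVS
# nearest-boundary convention for that position stays unambiguous.
_INTRON_FLOORS = {
    9: 20_008, 11: 24_328, 21: 50_870, 24: 1_320, 27: 1_686,
    37: 16_626, 38: 4_288, 44: 1_256, 49: 8_318, 56: 1_924,
}
_MIN_INTRON = 500


@dataclass(frozen=True)
class Exon:
    """One exon: 1-based inclusive genomic interval + coding span."""

    index: int  # 1-based ordinal along the transcript
    genomic_start: int
    genomic_end: int
    c_start: int
    c_end: int

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start + 1


class GeneModel:
    """Exon scaffold of a single transcript on a pseudo-genome contig."""

    def __init__(self, gene_id: str, strand: str, exons: list[Exon],
                 contig: str = "synthetic_gene"):
        if strand not in "+-":
            raise ValueError(f"strand must be + or -, got {strand!r}")
        self.gene_id = gene_id
        self.strand = strand
        self.exons = sorted(exons, key=lambda e: e.genomic_start)
        self.contig = contig
        self._c_starts = [e.c_start for e in self.exons]
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        prev = None
        for e in self.exons:
            if e.genomic_end < e.genomic_start:
                raise ValueError(f"exon {e.index} has negative length")
            if e.length != e.c_end - e.c_start + 1:
                raise ValueError(f"exon {e.index}: genomic and coding lengths differ")
            if prev is not None:
                if e.genomic_start <= prev.genomic_end + 1:
                    raise ValueError(
                        f"exons {prev.index}/{e.index} overlap or lack an intron")
                if e.c_start != prev.c_end + 1:
                    raise ValueError(
                        f"coding positions not contiguous at exon {e.index}")
            prev = e
        if self.exons and self.exons[0].c_start != 1:
            raise ValueError("first exon must start at c.1")

    # -- basic geometry ----------------------------------------------
    @property
    def total_span(self) -> int:
        return self.exons[-1].genomic_end - self.exons[0].genomic_start + 1

    @property
    def coding_length(self) -> int:
        return self.exons[-1].c_end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, index: int) -> Exon:
        """Exon by its 1-based transcript ordinal."""
        return self.exons[index - 1]

    # -- coordinate projection ----------------------------------------
    def exon_for_coding_base(self, base: int) -> Exon:
        if not 1 <= base <= self.coding_length:
            raise ValueError(f"c.{base} outside coding sequence")
        i = bisect_right(self._c_starts, base) - 1
        return self.exons[i]

    def coding_to_genomic(self, pos: CodingPosition | str) -> int:
        """Project a c.-position (with optional intron offset) to genomic.

        Only defined for the + strand pseudo-genome used by the fixture;
        unknown-offset positions cannot be projected.
        """
        if isinstance(pos, str):
            v = parse_c(pos if pos.startswith("c.") else f"c.{pos}1A>C")
            pos = v.start
        if pos.offset_unknown:
            raise ValueError("cannot project an unknown intronic breakpoint")
        e = self.exon_for_coding_base(pos.base)
        g = e.genomic_start + (pos.base - e.c_start)
        return g + pos.offset if self.strand == "+" else g - pos.offset

    def genomic_to_coding(self, genomic_pos: int) -> CodingPosition:
        """Project a genomic position to c.-notation (nearest-boundary rule
        for intronic positions)."""
        first, last = self.exons[0], self.exons[-1]
        if genomic_pos < first.genomic_start:
            return CodingPosition(1, genomic_pos - first.genomic_start)
        if genomic_pos > last.genomic_end:
            return CodingPosition(last.c_end, genomic_pos - last.genomic_end)
        for i, e in enumerate(self.exons):
            if e.genomic_start <= genomic_pos <= e.genomic_end:
                return CodingPosition(e.c_start + (genomic_pos - e.genomic_start))
            if genomic_pos < e.genomic_start:
                prev = self.exons[i - 1]
                d_prev = genomic_pos - prev.genomic_end
                d_next = e.genomic_start - genomic_pos
                if d_prev <= d_next:
                    return CodingPosition(prev.c_end, d_prev)
                return CodingPosition(e.c_start, -d_next)
        raise AssertionError("unreachable")

    def exons_overlapping(self, genomic_start: int, genomic_end: int) -> list[Exon]:
        """Exons intersecting a 1-based inclusive genomic interval."""
        return [e for e in self.exons
                if e.genomic_start <= genomic_end and e.genomic_end >= genomic_start]


def build_fixture_gene_model(seed: int = 1, gene_id: str = "USH2A_like") -> GeneModel:
    """Deterministically build the packaged 73-exon fixture gene.

    Exon coding boundaries are fixed; the seed shuffles spare intronic
    sequence among the introns (respecting per-intron floors) so that the
    genomic span is always exactly 800,503 nt.
    """
    c_ends = _FIXTURE_C_ENDS
    assert len(c_ends) == FIXTURE_N_EXONS and c_ends[-1] == FIXTURE_CODING_LENGTH
    exon_lengths = [c_ends[0]] + [b - a for a, b in zip(c_ends, c_ends[1:])]

    n_introns = FIXTURE_N_EXONS - 1
    floors = np.full(n_introns, _MIN_INTRON, dtype=np.int64)
    for intron_idx, floor in _INTRON_FLOORS.items():
        floors[intron_idx - 1] = floor
    slack_total = FIXTURE_SPAN - FIXTURE_CODING_LENGTH - int(floors.sum())
    if slack_total < 0:
        raise RuntimeError("fixture intron floors exceed the target span")
    rng = np.random.default_rng(seed)
    # weight spare intronic length toward a few large introns, as in real
    # multi-hundred-kb loci
    weights = rng.dirichlet(np.full(n_introns, 0.5))
    slack = rng.multinomial(slack_total, weights)
    intron_lengths = floors + slack

    exons: list[Exon] = []
    g = 5001  # upstream pad so flanking probes stay on the contig
    c = 1
    for i, length in enumerate(exon_lengths, start=1):
        exons.append(Exon(index=i, genomic_start=g, genomic_end=g + length - 1,
                          c_start=c, c_end=c + length - 1))
        c += length
        g += length
        if i <= n_introns:
            g += int(intron_lengths[i - 1])
    model = GeneModel(gene_id=gene_id, strand="+", exons=exons,
                      contig=f"{gene_id}_synthetic")
    assert model.total_span == FIXTURE_SPAN
    return model


# -- on-disk representation (4-column TSV) ----------------------------

def write_gene_model_tsv(model: GeneModel, path: str | Path) -> None:
    df = pd.DataFrame(
        {"exon_id": [e.index for e in model.exons],
         "start": [e.genomic_start for e in model.exons],
         "end": [e.genomic_end for e in model.exons],
         "c_start": [e.c_start for e in model.exons]})
    with open(path, "w") as fh:
        fh.write(f"#gene_id={model.gene_id}\tstrand={model.strand}\tcontig={model.contig}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_gene_model_tsv(path: str | Path) -> GeneModel:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing gene model header line")
        meta = dict(item.split("=", 1) for item in header[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t")
    exons = []
    c = 1
    for row in df.itertuples(index=False):
        length = int(row.end) - int(row.start) + 1
        if int(row.c_start) != c:
            raise ValueError(f"{path}: non-contiguous c_start at exon {row.exon_id}")
        exons.append(Exon(index=int(row.exon_id), genomic_start=int(row.start),
                          genomic_end=int(row.end), c_start=c, c_end=c + length - 1))
        c += length
    return GeneModel(gene_id=meta["gene_id"], strand=meta["strand"], exons=exons,
                     contig=meta.get("contig", "synthetic_gene"))
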