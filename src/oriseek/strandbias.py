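"""Replichore partitioning and leading/lagging strand-bias statistics.

Given the oriC and terminus positions of a circular chromosome, the two
replichores are the arcs oriC→ter (in increasing coordinates, mod L) and
ter→oriC. A gene is replicated on the leading strand when it is transcribed
co-directionally with the replication fork: forward-strand genes on arc 1
and reverse-strand genes on arc 2. Reported "strand lengths" are the two
replichore arc lengths — the quantity that can deviate from 50/50.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .errors import UnsupportedOperationError
from .genome_io import GeneFeature, GenomeRecord, revcomp


@dataclass
class ReplichorePartition:
    L: int
    oric_pos: int
    ter_pos: int
    arc1: tuple[int, int]  # [oriC, ter) mod L
    arc2: tuple[int, int]  # [ter, oriC) mod L
    arc1_len: int
    arc2_len: int

    @property
    def arc1_frac(self) -> float:
        return 100.0 * self.arc1_len / self.L

    @property
    def arc2_frac(self) -> float:
        return 100.0 * self.arc2_len / self.L

    def in_arc1(self, pos: int) -> bool:
        return (pos - self.oric_pos) % self.L < self.arc1_len


@dataclass
class StrandBiasReport:
    partition: ReplichorePartition
    leading_genes: int
    lagging_genes: int
    leading_base_pct: dict[str, float] = field(default_factory=dict)
    lagging_base_pct: dict[str, float] = field(default_factory=dict)

    @property
    def total_genes(self) -> int:
        return self.leading_genes + self.lagging_genes

    @property
    def leading_gene_frac(self) -> float:
        n = self.total_genes
        return 100.0 * self.leading_genes / n if n else 0.0


def partition_replichores(
    oric_pos: int, ter_pos: int, L: int, topology: str = "circular"
) -> ReplichorePartition:
    """Split a circular chromosome into its two replichore arcs."""
    if topology != "circular":
        raise UnsupportedOperationError("replichore partition requires a circular genome")
    if oric_pos % L == ter_pos % L:
        raise UnsupportedOperationError("oriC and terminus coincide; cannot partition")
    oric, ter = oric_pos % L, ter_pos % L
    arc1_len = (ter - oric) % L
    arc2_len = L - arc1_len
    return ReplichorePartition(
        L=L,
        oric_pos=oric,
        ter_pos=ter,
        arc1=(oric, ter),
        arc2=(ter, oric),
        arc1_len=arc1_len,
        arc2_len=arc2_len,
    )


def gene_strand_bias(
    features: Sequence[GeneFeature],
    partition: ReplichorePartition,
    coding_only: bool = True,
) -> tuple[int, int, float]:
    """Leading/lagging gene counts and the leading-gene percentage.

    Genes straddling the oriC/ter boundaries are classified by midpoint.
    """
    leading = lagging = 0
    for f in features:
        if coding_only and f.kind not in ("CDS", "ORF_fallback"):
            continue
        mid = f.midpoint % partition.L
        on_arc1 = partition.in_arc1(mid)
        if (on_arc1 and f.strand == "+") or (not on_arc1 and f.strand == "-"):
            leading += 1
        else:
            lagging += 1
    total = leading + lagging
    frac = 100.0 * leading / total if total else 0.0
    return leading, lagging, frac


def _arc_seq(sequence: str, arc: tuple[int, int]) -> str:
    s, e = arc
    return sequence[s:e] if e > s else sequence[s:] + sequence[:e]


def _base_pct(seq: str) -> dict[str, float]:
    counts = Counter(c for c in seq if c in "ACGT")
    total = sum(counts.values())
    return {b: (100.0 * counts[b] / total if total else 0.0) for b in "ATGC"}


def base_strand_bias(
    sequence: str, partition: ReplichorePartition
) -> tuple[dict[str, float], dict[str, float]]:
    """A/T/G/C percentages of the leading and lagging strands.

    The leading strand is the forward sequence of arc 1 concatenated with the
    reverse complement of arc 2 (each fork synthesises it continuously); the
    lagging strand is the complementary selection. N bases are excluded from
    the percentages.
    """
    arc1 = _arc_seq(sequence, partition.arc1)
    arc2 = _arc_seq(sequence, partition.arc2)
    leading = arc1 + revcomp(arc2)
    lagging = arc2 + revcomp(arc1)
    return _base_pct(leading), _base_pct(lagging)


def compute_strand_bias(
    record: GenomeRecord,
    oric_pos: int,
    ter_pos: int,
    coding_only: bool = True,
) -> StrandBiasReport:
    """Full strand-bias report for one circular record."""
    part = partition_replichores(oric_pos, ter_pos, len(record), record.topology)
    leading, lagging, _ = gene_strand_bias(record.features, part, coding_only)
    lead_pct, lag_pct = base_strand_bias(record.sequence, part)
    return StrandBiasReport(
        partition=part,
        leading_genes=leading,
        lagging_genes=lagging,
        leading_base_pct=lead_pct,
        lagging_base_pct=lag_pct,
    )
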