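"""Synthetic circular genomes with a planted oriC architecture.

Every pipeline stage can be exercised without downloads: the simulator
emits a circular chromosome with

* replichore-structured composition bias — the forward strand carries a
  G-over-C (and T-over-A) excess on the arc from the planted origin to the
  planted terminus at L/2, and the mirrored deficit on the other arc, so
  the GC-disparity minimum falls at the origin and the maximum at the
  terminus;
* a gene tiling of fixed-length placeholder genes separated by intergenic
  gaps (gene sequences are random; only their coordinates matter);
* one planted origin IGS at coordinate 0 containing exact DnaA boxes, an
  optional DnaA-trio run, and an AT-rich unwinding-element island, with a
  dnaA-named gene as its immediate flank;
* optionally, a dif site at the terminus.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .errors import ParameterError
from .genome_io import GeneFeature, GenomeRecord
from .motifs import MotifPattern, scan_iupac

# canonical E. coli dif site, used when a dif element is planted
DEFAULT_DIF = "GGTGCGCATAATGTATATTATGTTAAAT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimParams:
    """Study conditions for one simulated chromosome."""

    L: int = 200_000
    gc_skew: float = 0.04  # leading-strand G-over-C probability excess
    at_skew: float = 0.02  # leading-strand T-over-A probability excess
    n_boxes: int = 3
    include_trio: bool = True
    due_len: int = 30
    due_at_frac: float = 0.9
    gene_len: int = 900
    igs_len: int = 150
    dnaa_adjacent: bool = True
    plant_dif: bool = False
    dif_seq: str = DEFAULT_DIF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 10 * self.gene_len:
            raise ParameterError("L must be at least 10 gene lengths")
        for s in (self.gc_skew, self.at_skew):
            if not (0 <= s < 0.5):
                raise ParameterError("skew must lie in [0, 0.5)")
        if self.igs_len < 20:
            raise ParameterError("igs_len too small to hold planted elements")


@dataclass
class SimulatedGenome:
    record: GenomeRecord
    truth_oric: tuple[int, int]  # 0-based half-open
    truth_ter: int
    params: SimParams


def _draw_arc(rng: np.random.Generator, n: int, p_acgt: Sequence[float]) -> np.ndarray:
    return _BASES[rng.choice(4, size=n, p=list(p_acgt))]


def _planted_oric_seq(rng: np.random.Generator, p: SimParams, box: str) -> str:
    """Construct the origin IGS: boxes, optional trio run, AT island, filler.

    Redraws the random filler until the IGS carries exactly n_boxes exact
    box matches (both strands), so planted evidence is unambiguous.
    """
    parts = []
    for i in range(p.n_boxes):
        if i:
            parts.append("CCC")
        parts.append(box)
    if p.include_trio:
        parts.append("CCCCC" + "GAT" * 3)
    core_prefix = "".join(parts)
    due = ""
    if p.due_len:
        at = rng.random(p.due_len) < p.due_at_frac
        pick = rng.choice(2, size=p.due_len)
        due = "".join(
            ("AT"[k] if is_at else "GC"[k]) for is_at, k in zip(at, pick)
        )
        core_prefix += "CCCCC" + due
    fill = p.igs_len - len(core_prefix)
    if fill < 0:
        raise ParameterError(
            f"planted elements need {len(core_prefix)} bp but igs_len is {p.igs_len}"
        )
    pat = MotifPattern("DnaA_box", box)
    for _ in range(50):
        filler = _draw_arc(rng, fill, [0.25] * 4).tobytes().decode()
        seq = core_prefix + filler
        if len(scan_iupac(seq, pat, 0, "both")) == p.n_boxes:
            return seq
    raise ParameterError("could not place filler without spurious DnaA boxes")


def simulate_genome(params: SimParams, dnaa_box: str = "TTATCCACA") -> SimulatedGenome:
    """Generate one circular chromosome with known origin and terminus."""
    p = params
    rng = np.random.default_rng(p.seed)
    L, ter = p.L, p.L // 2

    g, c, a, t = p.gc_skew / 2, p.gc_skew / 2, p.at_skew / 2, p.at_skew / 2
    # order A, C, G, T
    p_arc1 = (0.25 - a, 0.25 - c, 0.25 + g, 0.25 + t)  # leading strand forward
    p_arc2 = (0.25 + t, 0.25 + g, 0.25 - c, 0.25 - a)  # mirrored on the other arc
    seq_arr = np.concatenate(
        [_draw_arc(rng, ter, p_arc1), _draw_arc(rng, L - ter, p_arc2)]
    )

    oric_seq = _planted_oric_seq(rng, p, dnaa_box)
    seq_arr[0 : p.igs_len] = np.frombuffer(oric_seq.encode(), dtype=np.uint8)

    if p.plant_dif:
        dif = p.dif_seq.upper()
        seq_arr[ter : ter + len(dif)] = np.frombuffer(dif.encode(), dtype=np.uint8)

    # gene tiling: gene_len genes separated by igs_len gaps, last gene extended
    # to close the circle so the planted IGS [0, igs_len) is exact
    starts = []
    cursor = p.igs_len
    while cursor + p.gene_len <= L:
        starts.append(cursor)
        cursor += p.gene_len + p.igs_len
    features = []
    for i, s in enumerate(starts):
        e = s + p.gene_len if i < len(starts) - 1 else L
        strand = "+" if rng.random() < 0.5 else "-"
        name, product = "", ""
        if i == 0 and p.dnaa_adjacent:
            strand, name = "+", "dnaA"
            product = "chromosomal replication initiator protein DnaA"
        features.append(
            GeneFeature(
                locus_tag=f"g{i + 1:04d}",
                start=s,
                end=e,
                strand=strand,
                kind="CDS",
                gene_name=name,
                product=product,
            )
        )

    record = GenomeRecord(
        id=f"sim{p.seed}",
        description=f"simulated circular chromosome L={L} seed={p.seed}",
        sequence=seq_arr.tobytes().decode(),
        topology="circular",
        features=features,
        source="simulated",
    )
    return SimulatedGenome(record, (0, p.igs_len), ter, p)


def _to_seqrecord(record: GenomeRecord) -> SeqRecord:
    rec = SeqRecord(Seq(record.sequence), id=record.id, description=record.description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = record.topology
    for f in record.features:
        quals = {"locus_tag": [f.locus_tag]}
        if f.gene_name:
            quals["gene"] = [f.gene_name]
        if f.product:
            quals["product"] = [f.product]
        rec.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type="CDS",
                qualifiers=quals,
            )
        )
    return rec


def write_fixture_set(genomes: Sequence[SimulatedGenome], out_dir: str) -> list[Path]:
    """Write FASTA + GenBank + truth TSV per genome; reproducible from seeds."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for g in genomes:
        base = out / g.record.id
        fasta, gbk, truth = (
            base.with_suffix(".fasta"),
            base.with_suffix(".gbk"),
            Path(f"{base}_truth.tsv"),
        )
        SeqIO.write([_to_seqrecord(g.record)], str(fasta), "fasta")
        SeqIO.write([_to_seqrecord(g.record)], str(gbk), "genbank")
        with open(truth, "w") as fh:
            fh.write("record_id\toric_start\toric_end\tter_pos\tseed\n")
            s, e = g.truth_oric
            # user-facing 1-based inclusive
            fh.write(f"{g.record.id}\t{s + 1}\t{e}\t{g.truth_ter + 1}\t{g.params.seed}\n")
        paths += [fasta, gbk, truth]
    return paths


def split_genome(
    record: GenomeRecord,
    n_contigs: int = 3,
    avoid: Optional[tuple[int, int]] = None,
) -> list[tuple[GenomeRecord, int]]:
    """Cut a circular record into linear contigs at intergenic positions.

    Cut points are the feature-gap midpoints nearest to evenly spaced target
    fractions, skipping any gap overlapping ``avoid`` (e.g. the planted
    origin). Returns (contig, genome offset of contig start) pairs so contig
    coordinates can be mapped back.
    """
    L = len(record)
    ivs = sorted((f.start, f.end) for f in record.features)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gap_mids = []
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        if s2 > e1:
            gap_mids.append((e1 + s2) // 2)
    wrap_len = (merged[0][0] - merged[-1][1]) % L
    if wrap_len:
        gap_mids.append((merged[-1][1] + wrap_len // 2) % L)
    if avoid is not None:
        a0, a1 = avoid
        gap_mids = [m for m in gap_mids if not (a0 <= m < a1)]
    if len(gap_mids) < n_contigs:
        raise ParameterError("not enough intergenic gaps to place the cuts")

    targets = [round((i + 0.5) * L / n_contigs) for i in range(n_contigs)]
    cuts = []
    for t in targets:
        m = min(gap_mids, key=lambda g: min(abs(g - t), L - abs(g - t)))
        if m not in cuts:
            cuts.append(m)
    cuts.sort()
    if len(cuts) < n_contigs:
        raise ParameterError("cut points collided; choose fewer contigs")

    contigs = []
    for i, c in enumerate(cuts):
        nxt = cuts[(i + 1) % len(cuts)]
        length = (nxt - c) % L
        seq = record.sequence[c:nxt] if nxt > c else record.sequence[c:] + record.sequence[:nxt]
        feats = []
        for f in record.features:
            off = (f.start - c) % L
            if off + (f.end - f.start) <= length:
                feats.append(replace(f, start=off, end=off + (f.end - f.start)))
        feats.sort(key=lambda f: f.start)
        contigs.append(
            (
                GenomeRecord(
                    id=f"{record.id}_c{i + 1}",
                    description=f"contig {i + 1} of {record.id} (offset {c})",
                    sequence=seq,
                    topology="linear",
                    features=feats,
                    source=record.source,
                ),
                c,
            )
        )
    return contigs
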