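"""Genome input and intergenic-sequence extraction.

Reads FASTA and GenBank flat files into a uniform :class:`GenomeRecord`,
provides a six-frame ORF fallback for unannotated sequences, and extracts
the maximal intergenic sequences (IGSs) that the origin predictor scores.

Coordinates are 0-based half-open internally; user-facing reports convert
to 1-based inclusive (GenBank convention) at the reporting layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import InputError

# Degenerate IUPAC codes are legal in input but the internal alphabet is
# {A,C,G,T,N}; ambiguity codes collapse to N on read.
_IUPAC = set("ACGTUNRYSWKMBDHV")
_CANON = set("ACGTN")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class GeneFeature:
    """One gene/CDS interval in 0-based half-open coordinates."""

    locus_tag: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"  # CDS | gene | ORF_fallback
    gene_name: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"feature {self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"feature {self.locus_tag}: strand must be + or -")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class GenomeRecord:
    """One replicon or contig: sequence, topology and gene features."""

    id: str
    sequence: str
    description: str = ""
    topology: str = "linear"  # circular | linear
    features: list[GeneFeature] = field(default_factory=list)
    source: str = "fasta"  # genbank | fasta | simulated

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise InputError(f"record {self.id}: empty sequence")
        bad = set(self.sequence) - _CANON
        if bad:
            raise InputError(
                f"record {self.id}: non-canonical characters {sorted(bad)} in sequence"
            )
        if self.topology not in ("circular", "linear"):
            raise InputError(f"record {self.id}: topology must be circular or linear")
        for f in self.features:
            if f.end > len(self.sequence):
                raise InputError(
                    f"record {self.id}: feature {f.locus_tag} exceeds sequence length"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class IGS:
    """A maximal annotation-free interval.

    ``end < start`` is allowed only for the wrap-around gap of a circular
    record and is interpreted modulo the record length.
    """

    record_id: str
    start: int
    end: int
    length: int
    sequence: str
    left_gene: Optional[GeneFeature] = None
    right_gene: Optional[GeneFeature] = None

    def midpoint(self, L: int) -> int:
        """Midpoint in forward genome coordinates (mod L for wrap gaps)."""
        return (self.start + self.length // 2) % L

    def at_fraction(self) -> float:
        n = sum(1 for c in self.sequence if c in "AT")
        denom = sum(1 for c in self.sequence if c != "N")
        return n / denom if denom else 0.0


def _normalise(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    out = []
    for c in s:
        if c in _CANON:
            out.append(c)
        elif c in _IUPAC:
            out.append("N")
        else:
            raise InputError(f"record {record_id}: non-IUPAC character {c!r}")
    return "".join(out)


def _find_bad_line(path: str, bad_char: str) -> int:
    """Locate the first line of a FASTA file containing an offending character."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if bad_char in line.upper():
                return i
    return -1


def read_fasta(path: str, topology: str = "linear") -> list[GenomeRecord]:
    """Read a (multi-record, wrapped, case-insensitive) FASTA file.

    Topology defaults to linear; GenBank input carries its own topology.
    """
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        raw = str(rec.seq)
        try:
            seq = _normalise(raw, rec.id)
        except InputError as exc:
            bad = str(exc).split("'")[-2]
            line = _find_bad_line(path, bad)
            raise InputError(
                f"record {rec.id}: non-IUPAC character {bad!r} (line {line})"
            ) from None
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=seq,
                topology=topology,
                source="fasta",
            )
        )
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records


def _feature_from_location(loc, ftype: str, quals: dict, length: int, idx: int):
    """Yield one GeneFeature per simple part, splitting wrap-around joins."""
    strand = "-" if loc.strand == -1 else "+"
    locus = quals.get("locus_tag", [f"{ftype.lower()}_{idx}"])[0]
    gene = quals.get("gene", [""])[0]
    product = quals.get("product", [""])[0]
    for part in getattr(loc, "parts", [loc]):
        start, end = int(part.start), int(part.end)
        if end > length or start >= end:
            warnings.warn(
                f"feature {locus}: coordinates [{start}, {end}) exceed sequence "
                f"length {length}; feature dropped"
            )
            continue
        yield GeneFeature(
            locus_tag=locus,
            start=start,
            end=end,
            strand=strand,
            kind=ftype,
            gene_name=gene,
            product=product,
        )


def read_genbank(path: str) -> list[GenomeRecord]:
    """Read a GenBank flat file, extracting CDS/gene features.

    GenBank 1-based inclusive locations become 0-based half-open (Biopython's
    native convention); ``complement()`` gives strand "-"; ``join()`` parts are
    split into separate sub-features, which also handles origin-spanning
    features on circular records.
    """
    records = []
    for rec in SeqIO.parse(path, "genbank"):
        if len(rec.seq) == 0:
            raise InputError(f"record {rec.id}: GenBank record has no ORIGIN sequence")
        seq = _normalise(str(rec.seq), rec.id)
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("circular", "linear"):
            topology = "linear"
        feats: list[GeneFeature] = []
        for i, f in enumerate(rec.features):
            if f.type not in ("CDS", "gene"):
                continue
            feats.extend(
                _feature_from_location(f.location, f.type, f.qualifiers, len(rec.seq), i)
            )
        feats.sort(key=lambda g: (g.start, g.end))
        records.append(
            GenomeRecord(
                id=rec.id,
                description=rec.description,
                sequence=seq,
                topology=topology,
                features=feats,
                source="genbank",
            )
        )
    if not records:
        raise InputError(f"{path}: no GenBank records found")
    return records


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def find_orfs_fallback(record: GenomeRecord, min_len: int = 300) -> list[GeneFeature]:
    """Crude six-frame ORF finder used when no annotation is available.

    Scans both strands for ATG/GTG/TTG → in-frame stop open reading frames of
    at least ``min_len`` nt (stop codon included), keeping the longest ORF per
    stop. It exists only to delimit intergenic sequences; it makes no attempt
    at real gene calling.
    """
    if min_len < 60:
        raise InputError("ORF fallback min_len must be >= 60")
    L = len(record.sequence)
    orfs: list[tuple[int, int, str]] = []
    for strand, seq in (("+", record.sequence), ("-", revcomp(record.sequence))):
        for frame in range(3):
            first_start: Optional[int] = None
            for pos in range(frame, L - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in STOP_CODONS:
                    if first_start is not None and pos + 3 - first_start >= min_len:
                        s, e = first_start, pos + 3
                        if strand == "-":
                            s, e = L - e, L - s
                        orfs.append((s, e, strand))
                    first_start = None
                elif first_start is None and codon in START_CODONS:
                    first_start = pos
    feats = [
        GeneFeature(
            locus_tag=f"orf_{i + 1:04d}",
            start=s,
            end=e,
            strand=st,
            kind="ORF_fallback",
        )
        for i, (s, e, st) in enumerate(sorted(orfs))
    ]
    return feats


def _merged_intervals(features: list[GeneFeature]) -> list[tuple[int, int]]:
    ivs = sorted((f.start, f.end) for f in features)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _flank_left(features: list[GeneFeature], pos: int) -> Optional[GeneFeature]:
    """Feature whose end coincides with the gap start (rightmost such)."""
    cands = [f for f in features if f.end == pos]
    return max(cands, key=lambda f: f.start) if cands else None


def _flank_right(features: list[GeneFeature], pos: int) -> Optional[GeneFeature]:
    cands = [f for f in features if f.start == pos]
    return min(cands, key=lambda f: f.end) if cands else None


def extract_igs(record: GenomeRecord, min_len: int = 80) -> list[IGS]:
    """Extract maximal feature-free intervals of length >= ``min_len``.

    On circular records the gap spanning the coordinate origin is returned as
    a single wrap-around IGS. A featureless record yields one IGS covering the
    whole sequence.
    """
    if min_len < 1:
        raise InputError("IGS min_len must be >= 1")
    L = len(record)
    seq = record.sequence
    if not record.features:
        return [IGS(record.id, 0, L, L, seq, None, None)]

    merged = _merged_intervals(record.features)
    gaps: list[IGS] = []

    def make(start: int, end: int) -> Optional[IGS]:
        length = end - start
        if length < min_len:
            return None
        return IGS(
            record.id,
            start,
            end,
            length,
            seq[start:end],
            _flank_left(record.features, start),
            _flank_right(record.features, end),
        )

    # interior gaps
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        g = make(e1, s2)
        if g:
            gaps.append(g)

    first_start = merged[0][0]
    last_end = merged[-1][1]
    if record.topology == "circular":
        # single gap from the last feature end around the origin to the first
        # feature start; collapses to a plain interval when it does not wrap
        start = last_end % L
        end = first_start
        length = (end - start) % L
        if length >= min_len:
            s = seq[start:end] if end >= start else seq[start:] + seq[:end]
            gaps.append(
                IGS(
                    record.id,
                    start,
                    end,
                    length,
                    s,
                    _flank_left(record.features, last_end),
                    _flank_right(record.features, first_start),
                )
            )
    else:
        if first_start > 0:
            g = make(0, first_start)
            if g:
                g.left_gene = None
                gaps.append(g)
        if last_end < L:
            g = make(last_end, L)
            if g:
                g.right_gene = None
                gaps.append(g)

    gaps.sort(key=lambda g: g.start)
    return gaps
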