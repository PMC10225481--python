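"""Degenerate IUPAC motif scanning and oriC functional-element finders.

Covers every element class used in bacterial origin annotation: DnaA boxes
(default E. coli consensus TTATCCACA, species-specific alternatives
selectable), DnaA-trio tandem repeats, ATP-DnaA boxes (AGATCT), Dam
methylation sites (GATC), CtrA binding motifs (TTAA-N7-TTAA), the dif
chromosome-dimer-resolution site, user-supplied motifs, and a sliding-window
AT-richness profile used as a proxy for the DNA unwinding element (DUE).

Matching rule: an IUPAC pattern symbol matches a sequence base when the
base's possibility set is a subset of the pattern symbol's set. Hence N in
the pattern matches anything at zero cost, while N in the sequence mismatches
every pattern symbol except N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, InputError
from .genome_io import revcomp

# 4-bit encoding: A=1, C=2, G=4, T=8; degenerate codes are unions
IUPAC_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7, "N": 15,
}
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}

_BYTE_BITS = np.zeros(256, dtype=np.uint8)
for sym, bits in IUPAC_BITS.items():
    _BYTE_BITS[ord(sym)] = bits


@dataclass(frozen=True)
class MotifPattern:
    """A named degenerate motif over the IUPAC nucleotide alphabet."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "iupac", self.iupac.upper())
        bad = set(self.iupac) - set(IUPAC_BITS)
        if bad:
            raise ConfigError(f"motif {self.name}: invalid IUPAC symbol(s) {sorted(bad)}")
        if not self.iupac:
            raise ConfigError(f"motif {self.name}: empty pattern")

    def __len__(self) -> int:
        return len(self.iupac)

    def reverse_complement(self) -> "MotifPattern":
        rc = "".join(IUPAC_COMPLEMENT[c] for c in reversed(self.iupac))
        return MotifPattern(self.name, rc)


@dataclass(frozen=True)
class MotifHit:
    """One motif match, in forward coordinates of the scanned sequence."""

    pattern_name: str
    start: int
    strand: str
    mismatches: int
    matched_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_seq)


@dataclass
class TrioArray:
    """A maximal tandem run of DnaA-trio trinucleotide units."""

    start: int
    strand: str
    n_units: int
    unit: str = "GAT"
    linked_box: Optional[MotifHit] = None

    @property
    def end(self) -> int:
        return self.start + 3 * self.n_units


# Named motifs the field recognises. Only three DnaA-box consensi are broadly
# published (E. coli, Cyanobacteria, T. maritima); anything else is user-supplied.
BUILTIN_DNAA_BOXES = {
    "ecoli": MotifPattern("DnaA_box", "TTATCCACA"),
    "cyanobacteria": MotifPattern("DnaA_box", "TTTTCCACA"),
    "tmaritima": MotifPattern("DnaA_box", "AAACCTACCACC"),
}


@dataclass
class MotifConfig:
    """All motif definitions and mismatch budgets used by the pipeline."""

    dnaa_box: MotifPattern = field(default_factory=lambda: BUILTIN_DNAA_BOXES["ecoli"])
    dnaa_box_max_mm: int = 1
    atp_dnaa_box: MotifPattern = field(default_factory=lambda: MotifPattern("ATP_DnaA_box", "AGATCT"))
    gatc: MotifPattern = field(default_factory=lambda: MotifPattern("GATC", "GATC"))
    ctra: MotifPattern = field(default_factory=lambda: MotifPattern("CtrA", "TTAANNNNNNNTTAA"))
    ctra_max_mm: int = 1
    trio_unit: str = "GAT"
    trio_min_units: int = 3
    trio_max_gap_to_box: int = 50
    loose_box_max_mm: int = 4  # display-only boxes adjacent to DnaA-trios
    dif: Optional[MotifPattern] = None
    dif_max_mm: int = 2
    user_motifs: list[tuple[MotifPattern, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trio_unit) != 3 or set(self.trio_unit) - set("ACGT"):
            raise ConfigError("trio_unit must be a 3-mer over ACGT")
        if self.trio_min_units < 1:
            raise ConfigError("trio_min_units must be >= 1")


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    bits = _BYTE_BITS[codes]
    if len(seq) and not bits.all():
        bad = seq[int(np.argmin(bits != 0))]
        raise InputError(f"sequence contains non-IUPAC character {bad!r}")
    return bits


def _scan_one_strand(seq_bits: np.ndarray, pattern: MotifPattern, max_mm: int) -> tuple[np.ndarray, np.ndarray]:
    plen = len(pattern)
    if plen > len(seq_bits):
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    pat_bits = np.array([IUPAC_BITS[c] for c in pattern.iupac], dtype=np.uint8)
    windows = sliding_window_view(seq_bits, plen)
    # subset test: sequence symbol set must lie within the pattern symbol set
    mismatch = (windows & pat_bits) != windows
    mm = mismatch.sum(axis=1)
    keep = np.nonzero(mm <= max_mm)[0]
    return keep, mm[keep]


def scan_iupac(
    sequence: str,
    pattern: MotifPattern,
    max_mm: int = 0,
    strands: str = "both",
) -> list[MotifHit]:
    """Find all windows within ``max_mm`` IUPAC-aware mismatches of a motif.

    Minus-strand hits are reported in forward coordinates with strand "-" and
    ``matched_seq`` in reading (biological) orientation. Results are sorted by
    start, then strand ("+" before "-").
    """
    if strands not in ("+", "both"):
        raise ConfigError("strands must be '+' or 'both'")
    seq_bits = _encode(sequence)
    plen = len(pattern)
    hits: list[MotifHit] = []
    starts, mms = _scan_one_strand(seq_bits, pattern, max_mm)
    for s, m in zip(starts, mms):
        hits.append(MotifHit(pattern.name, int(s), "+", int(m), sequence[s : s + plen]))
    if strands == "both":
        rc = pattern.reverse_complement()
        starts, mms = _scan_one_strand(seq_bits, rc, max_mm)
        for s, m in zip(starts, mms):
            hits.append(
                MotifHit(pattern.name, int(s), "-", int(m), revcomp(sequence[s : s + plen]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def find_dnaa_boxes(sequence: str, config: MotifConfig) -> list[MotifHit]:
    """DnaA boxes on both strands within the configured mismatch budget."""
    return scan_iupac(sequence, config.dnaa_box, config.dnaa_box_max_mm, "both")


def _tandem_runs(sequence: str, unit: str) -> list[tuple[int, int]]:
    """Maximal tandem runs of an exact 3-mer unit: (start, n_units)."""
    L = len(sequence)
    positions = {i for i in range(L - 2) if sequence[i : i + 3] == unit}
    runs = []
    for p in sorted(positions):
        if p - 3 in positions:
            continue  # interior of a run already counted
        n = 1
        while p + 3 * n in positions:
            n += 1
        runs.append((p, n))
    return runs


def find_dnaa_trios(
    sequence: str, boxes: list[MotifHit], config: MotifConfig
) -> list[TrioArray]:
    """Maximal DnaA-trio tandem arrays on both strands, linked to DnaA boxes.

    A trio array is linked to the nearest same-strand box whose 3' end lies at
    most ``trio_max_gap_to_box`` bp upstream (in the reading orientation of
    the run) of the array start.
    """
    unit = config.trio_unit
    arrays: list[TrioArray] = []
    for strand, u in (("+", unit), ("-", revcomp(unit))):
        for start, n in _tandem_runs(sequence, u):
            if n < config.trio_min_units:
                continue
            arrays.append(TrioArray(start=start, strand=strand, n_units=n, unit=unit))
    for arr in arrays:
        best = None
        for box in boxes:
            if box.strand != arr.strand:
                continue
            if arr.strand == "+":
                gap = arr.start - box.end
            else:  # upstream in reading orientation lies 3'-ward in forward coords
                gap = box.start - arr.end
            if 0 <= gap <= config.trio_max_gap_to_box:
                if best is None or gap < best[0]:
                    best = (gap, box)
        if best is not None:
            arr.linked_box = best[1]
    arrays.sort(key=lambda a: (a.start, a.strand))
    return arrays


def find_loose_boxes_near_trios(
    sequence: str, trios: list[TrioArray], config: MotifConfig
) -> list[MotifHit]:
    """Weakly conserved DnaA boxes (<= loose_box_max_mm) adjacent to trio runs.

    These are labeled in annotation output only; they never enter scoring,
    which is restricted to the stricter ``dnaa_box_max_mm`` budget.
    """
    if not trios:
        return []
    loose = scan_iupac(sequence, config.dnaa_box, config.loose_box_max_mm, "both")
    out = []
    for h in loose:
        if h.mismatches <= config.dnaa_box_max_mm:
            continue  # already reported by the scoring scan
        for t in trios:
            gap = t.start - h.end if h.strand == "+" else h.start - t.end
            if h.strand == t.strand and 0 <= gap <= config.trio_max_gap_to_box:
                out.append(
                    MotifHit("DnaA_box_loose", h.start, h.strand, h.mismatches, h.matched_seq)
                )
                break
    return out


def _dedupe_palindromic(hits: list[MotifHit]) -> list[MotifHit]:
    """Collapse +/- hits of a palindromic motif to one hit per forward start."""
    seen: dict[tuple[str, int], MotifHit] = {}
    for h in sorted(hits, key=lambda h: (h.start, h.strand)):
        seen.setdefault((h.pattern_name, h.start), h)
    return list(seen.values())


def find_fixed_elements(sequence: str, config: MotifConfig) -> list[MotifHit]:
    """All non-DnaA-box functional elements: GATC, ATP-DnaA box, CtrA, user motifs."""
    hits: list[MotifHit] = []
    hits += _dedupe_palindromic(scan_iupac(sequence, config.gatc, 0, "both"))
    hits += _dedupe_palindromic(scan_iupac(sequence, config.atp_dnaa_box, 0, "both"))
    hits += scan_iupac(sequence, config.ctra, config.ctra_max_mm, "both")
    for pat, mm in config.user_motifs:
        hits += scan_iupac(sequence, pat, mm, "both")
    hits.sort(key=lambda h: (h.start, h.strand, h.pattern_name))
    return hits


def at_richness_profile(sequence: str, window: int = 30) -> np.ndarray:
    """Sliding-window A+T fraction, step 1, one value per window start.

    Serves as a proxy profile for locating the AT-rich DNA unwinding element:
    the argmax window is annotated as the putative DUE.
    """
    if window < 10:
        raise InputError("AT-richness window must be >= 10")
    if window > len(sequence):
        raise InputError(
            f"AT-richness window {window} exceeds sequence length {len(sequence)}"
        )
    codes = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_at = ((codes == ord("A")) | (codes == ord("T"))).astype(float)
    return np.convolve(is_at, np.ones(window), mode="valid") / window


def due_window(sequence: str, window: int = 30) -> tuple[int, int]:
    """Interval of the most AT-rich window (ties: leftmost)."""
    if len(sequence) < 10:
        return (0, len(sequence))
    w = max(10, min(window, len(sequence)))
    profile = at_richness_profile(sequence, w)
    start = int(np.argmax(profile))
    return (start, start + w)


def write_bed(hits: list, path: str, chrom: str, offset: int = 0, L: Optional[int] = None) -> None:
    """BED6 export of element hits; score column carries the mismatch count."""
    with open(path, "w") as fh:
        for h in hits:
            if isinstance(h, TrioArray):
                name, start, end, score, strand = (
                    "DnaA_trio", h.start, h.end, h.n_units, h.strand,
                )
            else:
                name, start, end, score, strand = (
                    h.pattern_name, h.start, h.end, h.mismatches, h.strand,
                )
            s, e = start + offset, end + offset
            if L is not None:
                s, e = s % L, ((e - 1) % L) + 1
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\t{score}\t{strand}\n")
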