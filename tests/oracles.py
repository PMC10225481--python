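"""Independent brute-force oracles used to cross-check the implementation.

Deliberately naive: plain Python, character-by-character, no shared code
with the package internals.
"""

from __future__ import annotations

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


def window_mismatches(window: str, pattern: str) -> int:
    """Mismatch count under the subset rule: sequence base-set within
    pattern symbol-set (sequence N only matches pattern N)."""
    mm = 0
    for s, p in zip(window, pattern):
        s_set = IUPAC_SETS["N"] if s == "N" else IUPAC_SETS[s]
        if s == "N" and p != "N":
            mm += 1
        elif not s_set <= IUPAC_SETS[p]:
            mm += 1
    return mm


def brute_force_scan(seq: str, pattern: str, max_mm: int, strands: str = "both"):
    """All (start, strand, mismatches) whose window matches the motif."""
    hits = []
    plen = len(pattern)
    for i in range(len(seq) - plen + 1):
        w = seq[i : i + plen]
        mm = window_mismatches(w, pattern)
        if mm <= max_mm:
            hits.append((i, "+", mm))
        if strands == "both":
            mm = window_mismatches(rc(w), pattern)
            if mm <= max_mm:
                hits.append((i, "-", mm))
    return sorted(hits)


def count_substring_both_strands(seq: str, motif: str) -> int:
    """Overlapping occurrence count on both strands, palindromes deduplicated."""
    fwd = {i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif}
    rcm = rc(motif)
    rev = {i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == rcm}
    return len(fwd | rev) if rcm == motif else len(fwd) + len(rev)


STARTS = {"ATG", "GTG", "TTG"}
STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(seq: str, min_len: int):
    """Six-frame ORFs (longest per stop) as (start, end, strand) triples.

    Enumerates every start codon, extends to the first in-frame stop, and
    keeps the longest ORF per stop.
    """
    L = len(seq)
    per_stop: dict[tuple[str, int], int] = {}
    for strand, s in (("+", seq), ("-", rc(seq))):
        for i in range(L - 2):
            if s[i : i + 3] not in STARTS:
                continue
            j = i + 3
            while j + 3 <= L:
                if s[j : j + 3] in STOPS:
                    key = (strand, j)
                    if key not in per_stop or i < per_stop[key]:
                        per_stop[key] = i
                    break
                j += 3
    out = []
    for (strand, stop), start in per_stop.items():
        end = stop + 3
        if end - start < min_len:
            continue
        if strand == "-":
            start, end = L - end, L - start
        out.append((start, end, strand))
    return sorted(out)


def prefix_base_counts(seq: str, n: int) -> dict[str, int]:
    prefix = seq[:n]
    return {b: prefix.count(b) for b in "ACGT"}
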