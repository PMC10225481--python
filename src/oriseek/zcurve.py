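"""Z-curve disparity curves and GC-disparity extrema.

The Z-curve decomposition of a DNA sequence yields four cumulative
"disparity" components, reported here per prefix of length n:

* AT disparity — cumulative excess of A over T,
* GC disparity — cumulative excess of G over C,
* RY disparity — purines (A,G) minus pyrimidines (C,T),
* MK disparity — amino bases (A,C) minus keto bases (G,T).

By construction RY = AT + GC and MK = AT − GC at every prefix. On most
circular bacterial chromosomes the GC-disparity minimum marks the oriC
vicinity and its maximum the terminus vicinity, because the leading strand
is G-enriched on each replichore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError

# per-base increments, indexed by ASCII byte
_AT_INC = np.zeros(256, dtype=np.int64)
_GC_INC = np.zeros(256, dtype=np.int64)
for b, at, gc in ((ord("A"), 1, 0), (ord("T"), -1, 0), (ord("G"), 0, 1), (ord("C"), 0, -1)):
    _AT_INC[b] = at
    _GC_INC[b] = gc


@dataclass
class DisparitySet:
    """Prefix-cumulative disparity curves; index 0 is always 0."""

    length: int
    AT: np.ndarray
    GC: np.ndarray
    RY: np.ndarray
    MK: np.ndarray


def disparity_curves(sequence: str) -> DisparitySet:
    """Compute the four cumulative disparity curves of a sequence.

    N contributes 0 to all four curves. Arrays have length L+1 with entry n
    holding the cumulative disparity of the first n bases.
    """
    if not sequence:
        raise InputError("disparity_curves: empty sequence")
    codes = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    at = np.concatenate(([0], np.cumsum(_AT_INC[codes])))
    gc = np.concatenate(([0], np.cumsum(_GC_INC[codes])))
    return DisparitySet(length=len(sequence), AT=at, GC=gc, RY=at + gc, MK=at - gc)


def gc_extrema(curves: DisparitySet, topology: str = "circular") -> tuple[int, int]:
    """Global minimum and maximum positions (0..L) of the GC disparity.

    Ties are broken by the smallest index. Extrema are taken on the given
    linearization regardless of topology; rotation of a circular record is a
    display transform only.
    """
    return int(np.argmin(curves.GC)), int(np.argmax(curves.GC))


def circular_distance(a: int, b: int, L: int, topology: str = "circular") -> int:
    """Shortest separation of two coordinates, around the circle if circular."""
    d = abs(a - b)
    if topology == "circular":
        return min(d, L - d)
    return d


def smooth(curve: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average for plotting only, never for extremum-finding."""
    if window <= 1:
        return curve.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(curve.astype(float), pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: len(curve)]


def write_curves_tsv(curves: DisparitySet, path: str, step: int = 1) -> None:
    """Export (position, AT, GC, RY, MK) rows for plotting."""
    idx = np.arange(0, curves.length + 1, step)
    data = np.column_stack(
        [idx, curves.AT[idx], curves.GC[idx], curves.RY[idx], curves.MK[idx]]
    )
    header = "position\tAT\tGC\tRY\tMK"
    np.savetxt(path, data, fmt="%d", delimiter="\t", header=header, comments="")
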