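"""Windowed sequence statistics shared across pipeline stages."""

from __future__ import annotations

import numpy as np

from .model import Contig, WindowTrack

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("N")] = 4


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as codes A=0, C=1, G=2, T=3, N=4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_percent(seq: str) -> float:
    """GC% over non-N bases (NaN if no informative base)."""
    codes = encode(seq)
    n_acgt = int(np.sum(codes < 4))
    if n_acgt == 0:
        return float("nan")
    gc = int(np.sum((codes == 1) | (codes == 2)))
    return 100.0 * gc / n_acgt


def gc_profile(contig: Contig | str, window: int = 200, step: int = 200) -> WindowTrack:
    """Per-window GC% along a contig.

    One value per window: 100*(G+C)/(A+C+G+T in window); windows with more
    than 50% N are masked (NaN).  A contig shorter than the window yields an
    empty track.
    """
    if window < 50:
        raise ValueError("window must be >= 50 bp")
    if step > window:
        raise ValueError("step must be <= window")
    seq = contig.seq if isinstance(contig, Contig) else contig
    cid = contig.id if isinstance(contig, Contig) else ""
    n = len(seq)
    if n < window:
        return WindowTrack(cid, window, step, np.empty(0))
    codes = encode(seq)
    is_gc = np.concatenate([[0], np.cumsum((codes == 1) | (codes == 2))])
    is_n = np.concatenate([[0], np.cumsum(codes == 4)])
    starts = np.arange(0, n - window + 1, step)
    gc = is_gc[starts + window] - is_gc[starts]
    nn = is_n[starts + window] - is_n[starts]
    informative = window - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 100.0 * gc / informative
    vals[nn > window // 2] = np.nan
    vals[informative == 0] = np.nan
    return WindowTrack(cid, window, step, vals)
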