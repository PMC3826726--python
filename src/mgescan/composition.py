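"""Compositional statistics used as evidence of foreign DNA.

Horizontally acquired regions usually differ from the host backbone in
base composition.  This module computes G+C content and GC skew
((G-C)/(G+C)) globally and in sliding windows, and the signed G+C
deviation of a candidate element from the remainder of its replicon.
Composition is reported as evidence alongside element calls; it does not
gate them — elements are defined by their repeat/integrase geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import GenomeRecord

#: flag thresholds: absolute deviation in percentage points, or z-score
#: against the window distribution.
ANOMALY_DELTA_PP = 2.0
ANOMALY_Z = 2.0


def _counts(sequence: str) -> tuple[int, int, int]:
    """(G, C, non-N total) counts."""
    g = sequence.count("G")
    c = sequence.count("C")
    acgt = g + c + sequence.count("A") + sequence.count("T")
    return g, c, acgt


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T); N bases are excluded from both sides."""
    if not sequence:
        raise ValueError("empty sequence")
    g, c, acgt = _counts(sequence.upper())
    if acgt == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    return (g + c) / acgt


def gc_skew(sequence: str) -> float:
    """(G-C)/(G+C); defined as 0 when the sequence has no G or C."""
    if not sequence:
        raise ValueError("empty sequence")
    g, c, _ = _counts(sequence.upper())
    return 0.0 if g + c == 0 else (g - c) / (g + c)


@dataclass
class CompositionProfile:
    """Sliding-window G+C and GC-skew track for one replicon."""

    replicon_id: str
    window: int
    step: int
    starts: np.ndarray        # window start positions
    ends: np.ndarray
    gc: np.ndarray            # per-window G+C fraction
    skew: np.ndarray          # per-window (G-C)/(G+C)
    replicon_mean_gc: float

    def to_rows(self):
        """Iterate (replicon, start, end, gc, skew) report rows."""
        for s, e, g, k in zip(self.starts, self.ends, self.gc, self.skew):
            yield self.replicon_id, int(s), int(e), float(g), float(k)


def profile(record: GenomeRecord, window: int = 1000, step: int = 500) -> CompositionProfile:
    """Tile ``[0, len)`` with half-open windows of ``window`` bp every
    ``step`` bp.  A trailing partial window is kept when it spans at least
    ``window / 2`` bases."""
    n = len(record)
    if window < 50:
        raise ValueError("window must be >= 50 bp")
    if window > n:
        raise ValueError("window exceeds replicon length")
    if step < 1:
        raise ValueError("step must be >= 1")
    seq = record.sequence
    # vectorized base counts via cumulative sums
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    is_n = np.concatenate([[0], np.cumsum(arr == ord("N"))])
    starts = list(range(0, max(n - window, 0) + 1, step))
    last_end = starts[-1] + window
    if n - last_end >= window / 2:
        starts.append(last_end)
    starts = np.array(starts, dtype=int)
    ends = np.minimum(starts + window, n)
    g = is_g[ends] - is_g[starts]
    c = is_c[ends] - is_c[starts]
    nn = is_n[ends] - is_n[starts]
    acgt = (ends - starts) - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(acgt > 0, (g + c) / np.maximum(acgt, 1), np.nan)
        skew = np.where(g + c > 0, (g - c) / np.maximum(g + c, 1), 0.0)
    return CompositionProfile(
        replicon_id=record.replicon_id,
        window=window,
        step=step,
        starts=starts,
        ends=ends,
        gc=gc,
        skew=skew,
        replicon_mean_gc=gc_content(seq),
    )


def element_gc_deviation(record: GenomeRecord, start: int, end: int) -> float:
    """Signed percentage-point difference between an element's G+C and the
    G+C of the rest of its replicon (the element itself excluded)."""
    n = len(record)
    if not (0 <= start < end <= n):
        raise ValueError(f"element [{start}, {end}) outside replicon of length {n}")
    rest = record.sequence[:start] + record.sequence[end:]
    if not rest:
        raise ValueError("element covers the entire replicon")
    return 100.0 * (gc_content(record.sequence[start:end]) - gc_content(rest))


def is_anomalous(record: GenomeRecord, start: int, end: int,
                 window: int = 1000, step: int = 500) -> dict:
    """Evaluate both anomaly flags for an interval.

    Returns a dict with the signed deviation (percentage points), the
    z-score of the interval's G+C against the window distribution, and the
    two boolean flags.  Reported as evidence only.
    """
    dev = element_gc_deviation(record, start, end)
    prof = profile(record, window=min(window, len(record)), step=step)
    sd = float(np.nanstd(prof.gc))
    z = 0.0 if sd == 0 else (gc_content(record.sequence[start:end]) - float(np.nanmean(prof.gc))) / sd
    return {
        "deviation_pp": dev,
        "z": z,
        "flag_delta": abs(dev) >= ANOMALY_DELTA_PP,
        "flag_z": abs(z) >= ANOMALY_Z,
    }
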