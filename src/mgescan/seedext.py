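"""Seed-and-extend detection of same-orientation sequence matches.

Exact k-mer seeds are grouped by diagonal and extended ungapped under a
mismatch penalty chosen so that every reported segment meets the identity
floor (match +1, mismatch -p with p = id/(1-id)).  This is the primitive
behind direct-repeat (att site) detection and cross-element shared-backbone
detection.  Being ungapped, it reports the longest high-identity common
core of two repeat copies; indels split matches into separate segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class Match:
    """An ungapped local match: ``a[a_start:a_end]`` vs ``b[b_start:b_end]``."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    n_matches: int

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    @property
    def identity(self) -> float:
        return self.n_matches / self.length if self.length else 0.0


def _max_segments(prefix: np.ndarray, lo: int, hi: int, min_sum: float,
                  out: list) -> None:
    """Collect disjoint maximal-sum segments of the scored window
    ``[lo, hi)`` scoring at least ``min_sum`` (best segment first, then
    the flanks).  ``prefix`` holds prefix sums: segment (s, e) scores
    ``prefix[e] - prefix[s]``."""
    while hi - lo > 0:
        seg_pre = prefix[lo:hi + 1]
        cmin = np.minimum.accumulate(seg_pre[:-1])
        gains = seg_pre[1:] - cmin
        e_rel = int(np.argmax(gains))
        if gains[e_rel] < min_sum:
            return
        s_rel = int(np.argmin(seg_pre[:e_rel + 1]))
        out.append((lo + s_rel, lo + e_rel + 1))
        _max_segments(prefix, lo, lo + s_rel, min_sum, out)
        lo = lo + e_rel + 1  # continue on the right flank


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each k-mer (-1 where the window contains a non-ACGT
    base); empty when the sequence is shorter than k."""
    codes = _CODE[arr]
    n = arr.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        win = codes[j:j + n]
        out = out * 4 + np.where(win < 0, 0, win)
        bad |= win < 0
    out[bad] = -1
    return out


def maximal_matches(a: str, b: str, k: int = 10, min_len: int = 14,
                    min_identity: float = 0.9, pad: int = 80,
                    ) -> list[Match]:
    """All maximal ungapped matches between ``a`` and ``b`` of length
    >= ``min_len`` at identity >= ``min_identity``, same orientation.

    Matches whose interior contains no exact ``k``-mer are invisible to the
    seeding step; with the default k=10 this only affects repeats whose
    mismatches are spaced closer than k apart.  Reported segments must
    additionally score at least ``ceil(min_len*min_identity) -
    penalty*floor(min_len*(1-min_identity))`` under the +1/-penalty
    scheme, which discards only marginal near-threshold segments barely
    longer than ``min_len``.
    """
    if min_identity >= 1.0:
        penalty = float(min_len + len(a) + len(b))  # larger than any gain
    else:
        penalty = min_identity / (1.0 - min_identity)
    min_sum = max(1.0, np.ceil(min_len * min_identity)
                  - penalty * np.floor(min_len * (1.0 - min_identity)))
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    codes_a = _kmer_codes(arr_a, k)
    codes_b = _kmer_codes(arr_b, k)
    if codes_a.size == 0 or codes_b.size == 0:
        return []
    seeds: dict[int, list[int]] = {}
    for i, c in enumerate(codes_a.tolist()):
        if c >= 0:
            seeds.setdefault(c, []).append(i)
    # restrict the scan of b to positions whose k-mer occurs in a at all
    cand = np.nonzero(np.isin(codes_b, codes_a))[0]
    diagonals: dict[int, list[int]] = {}
    codes_b_list = codes_b[cand].tolist()
    for j, c in zip(cand.tolist(), codes_b_list):
        hits = seeds.get(c)
        if hits:
            for i in hits:
                diagonals.setdefault(j - i, []).append(i)
    matches: list[Match] = []
    for d, i_list in diagonals.items():
        w0 = max(0, min(i_list) - pad, -d)
        w1 = min(len(a), max(i_list) + k + pad, len(b) - d)
        if w1 - w0 < min_len:
            continue
        eq = arr_a[w0:w1] == arr_b[w0 + d:w1 + d]
        # N counts as a mismatch everywhere
        is_n = (arr_a[w0:w1] == ord("N")) | (arr_b[w0 + d:w1 + d] == ord("N"))
        eq = eq & ~is_n
        score = np.where(eq, 1.0, -penalty)
        prefix = np.concatenate([[0.0], np.cumsum(score)])
        segments: list[tuple[int, int]] = []
        _max_segments(prefix, 0, w1 - w0, min_sum, segments)
        for s0, s1 in segments:
            # trim to matching ends
            while s0 < s1 and not eq[s0]:
                s0 += 1
            while s1 > s0 and not eq[s1 - 1]:
                s1 -= 1
            length = s1 - s0
            if length < min_len:
                continue
            n_match = int(eq[s0:s1].sum())
            if n_match / length < min_identity:
                continue
            matches.append(Match(w0 + s0, w0 + s1, w0 + s0 + d, w0 + s1 + d, n_match))
    # dedupe (several seed windows can rediscover the same segment)
    uniq = {(m.a_start, m.a_end, m.b_start, m.b_end): m for m in matches}
    return sorted(uniq.values(), key=lambda m: (-m.n_matches, m.a_start, m.b_start))
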