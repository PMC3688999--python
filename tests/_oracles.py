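"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive search / dynamic
programming, sharing no code with the implementations they check.
"""

from __future__ import annotations

import numpy as np

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def brute_ssrs(s: str, circular: bool = True,
               thresholds: dict[int, int] | None = None) -> set[tuple[int, str, int]]:
    """Exhaustive (start, period) tandem-repeat search: for every start and
    unit length, extend maximally and apply primitivity, left-maximality
    and threshold rules. Returns {(start, motif, n_repeats)}."""
    thresholds = thresholds or {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}
    n = len(s)
    text = s + s if circular else s
    out: set[tuple[int, str, int]] = set()
    for p, min_rep in thresholds.items():
        if p > n:
            continue
        for start in range(n if circular else max(0, len(text) - p)):
            if start + p > len(text):
                break
            motif = text[start:start + p]
            if motif in (motif + motif)[1:-1]:
                continue  # non-primitive
            if start > 0 and text[start - 1] == text[start - 1 + p]:
                continue  # not left-maximal
            if circular and start == 0 and s[n - 1] == s[(p - 1) % n]:
                continue  # wraps leftward; counted at its true start
            length = p
            while (start + length < len(text)
                   and text[start + length] == text[start + length - p]
                   and length < n):
                length += 1
            n_rep = length // p
            if n_rep >= min_rep and n_rep * p <= n:
                out.add((start % n, motif, n_rep))
    return out


def brute_ir(s: str, min_len: int):
    """O(n^2) longest-common-substring DP between the sequence and its
    reverse complement, keeping the longest disjoint interval pair.
    Intervals are non-wrapping. Returns (length, ivA, ivB) or None."""
    n = len(s)
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    r = np.frombuffer(rc(s).encode(), dtype=np.uint8)
    best = None
    prev = np.zeros(n, dtype=np.int32)
    for i in range(n):
        eq = a[i] == r
        cur = np.where(eq, 1, 0).astype(np.int32)
        cur[1:] += np.where(eq[1:], prev[:-1], 0)
        for j in np.flatnonzero(cur >= min_len):
            m = int(cur[j])
            s1, e1 = i - m + 1, i + 1                  # in s
            s2, e2 = n - 1 - j, n - 1 - j + m          # rc image in s
            if e1 <= s2 or e2 <= s1:
                if best is None or m > best[0]:
                    best = (m, (s1, e1), (s2, e2))
        prev = cur
    return best


def walk_feature_length(parts, n: int) -> int:
    """Coordinate walker: count bases of a (possibly origin-wrapping)
    multi-part location by stepping base-by-base around the circle."""
    total = 0
    for s, e in parts:
        pos = s
        while pos != e:
            total += 1
            pos += 1
    return total


def kimura2p(P: float, Q: float) -> float:
    """Independent closed form for the equal-frequency transition/
    transversion distance (what F84 reduces to at equal base frequencies)."""
    import math
    return -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
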