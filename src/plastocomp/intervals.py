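"""Circular-coordinate interval arithmetic.

All genome coordinates in this package are 0-based half-open. On a circular
molecule of length ``n`` an interval is a pair ``(start, end)`` with
``0 <= start < n`` and ``start < end <= start + n``; an interval with
``end > n`` wraps the origin. Every piece of length/overlap/gap math in the
package goes through this module so there is exactly one place where the
wrap conventions live.
"""

from __future__ import annotations

Interval = tuple[int, int]


def length(iv: Interval) -> int:
    return iv[1] - iv[0]


def normalize(iv: Interval, n: int) -> Interval:
    """Canonical form: start in [0, n), 0 < length <= n."""
    s, e = iv
    if e - s > n:
        raise ValueError(f"interval {iv} longer than genome ({n})")
    if e <= s:
        raise ValueError(f"empty or inverted interval {iv}")
    s_ = s % n
    return (s_, s_ + (e - s))


def split_wrap(iv: Interval, n: int) -> list[Interval]:
    """Split a (possibly wrapping) interval into linear pieces within [0, n)."""
    s, e = normalize(iv, n)
    if e <= n:
        return [(s, e)]
    return [(s, n), (0, e - n)]


def contains(iv: Interval, pos: int, n: int) -> bool:
    s, e = normalize(iv, n)
    p = pos % n
    if p >= s:
        return p < e
    return p + n < e


def overlaps(a: Interval, b: Interval, n: int) -> bool:
    for s1, e1 in split_wrap(a, n):
        for s2, e2 in split_wrap(b, n):
            if s1 < e2 and s2 < e1:
                return True
    return False


def gap_forward(from_end: int, to_start: int, n: int) -> int:
    """Bases strictly between coordinate ``from_end`` (exclusive) and
    ``to_start`` walking forward around the circle."""
    return (to_start - from_end) % n


def fetch(residues: str, iv: Interval, n: int | None = None) -> str:
    """Extract the sequence of an interval, wrapping the origin if needed."""
    n = len(residues) if n is None else n
    return "".join(residues[s:e] for s, e in split_wrap(iv, n))
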