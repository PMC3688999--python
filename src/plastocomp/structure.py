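"""Quadripartite plastome architecture.

Detects the inverted-repeat pair (IRa/IRb), partitions the circle into
LSC / IRb / SSC / IRa, and characterises the four single-copy/IR junctions
(JLB, JSB, JSA, JLA) against the annotation.

IR detection is exact (no mismatches): it finds the longest pair of
disjoint, maximal intervals whose sequences are reverse complements of each
other, by seeding word matches between the genome and its reverse
complement and extending along diagonals.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass

from .genome_model import AnnotatedGenome, Sequence, reverse_complement
from .intervals import Interval, gap_forward, length, normalize, overlaps


@dataclass(frozen=True)
class IRPair:
    interval_b: Interval  # first copy in circle order from the origin
    interval_a: Interval
    length: int


@dataclass(frozen=True)
class Quadripartite:
    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int

    @property
    def lengths(self) -> dict[str, int]:
        return {"LSC": length(self.lsc), "IRb": length(self.irb),
                "SSC": length(self.ssc), "IRa": length(self.ira)}

    def junction_positions(self) -> dict[str, int]:
        """Junction coordinate = first base of the downstream region."""
        n = self.genome_length
        return {"JLB": self.irb[0] % n, "JSB": self.ssc[0] % n,
                "JSA": self.ira[0] % n, "JLA": self.lsc[0] % n}


@dataclass(frozen=True)
class JunctionContext:
    junction: str                      # JLB / JSB / JSA / JLA
    position: int
    within: str | None = None          # gene containing the junction
    offset: int | None = None          # bases into that gene's span
    spacer: tuple[str, str] | None = None   # flanking genes when intergenic
    distances: tuple[int, int] | None = None

    def describe(self) -> str:
        if self.within is not None:
            return f"{self.junction}@{self.position}: within {self.within} (+{self.offset})"
        if self.spacer is not None:
            g1, g2 = self.spacer
            d1, d2 = self.distances
            return f"{self.junction}@{self.position}: in spacer {g1}-{g2} ({d1}/{d2} bp)"
        return f"{self.junction}@{self.position}: unbounded"


class DegenerateStructureError(ValueError):
    pass


class UnknownGeneError(KeyError):
    pass


def _maximal_ir_matches(s: str, min_len: int, seed_len: int):
    """Maximal exact matches between the circle and its reverse complement,
    as (intervalA, intervalB, length) with intervals on the circle."""
    n = len(s)
    w = min(seed_len, min_len, n)
    s2 = s + s
    r2 = reverse_complement(s2)  # == rc(s) + rc(s)
    seed_pos: dict[str, list[int]] = {}
    for j in range(n):  # seeds from one rc copy suffice
        seed_pos.setdefault(r2[j:j + w], []).append(j)
    covered: dict[int, int] = {}   # diagonal (i - j) -> rightmost covered i
    out = []
    for i in range(n):
        hits = seed_pos.get(s2[i:i + w])
        if not hits:
            continue
        for j in hits:
            d = i - j
            if covered.get(d, -1) > i:
                continue
            # extend left
            li, lj = i, j
            while li > 0 and lj > 0 and s2[li - 1] == r2[lj - 1]:
                li -= 1
                lj -= 1
            # extend right
            ri, rj = i + w, j + w
            while ri < 2 * n and rj < 2 * n and s2[ri] == r2[rj]:
                ri += 1
                rj += 1
            covered[d] = ri
            m = min(ri - li, n)
            if m < min_len:
                continue
            a = normalize((li, li + m), n)
            # r2[lj : lj+m] is the rc of the circle interval starting 2n-lj-m
            b = normalize(((2 * n - lj - m) % n, (2 * n - lj - m) % n + m), n)
            out.append((a, b, m))
    return out


def find_ir(seq: Sequence, min_ir_len: int = 1000, seed_len: int = 21
            ) -> IRPair | None:
    """Longest pair of disjoint maximal exact inverted repeats, or None.

    Maximality: extending either interval one base in either direction
    breaks the reverse-complement identity.
    """
    s = seq.residues
    n = len(s)
    best = None
    seen = set()
    for a, b, m in _maximal_ir_matches(s, min_ir_len, seed_len):
        key = tuple(sorted([a, b]))
        if key in seen:
            continue
        seen.add(key)
        if not overlaps(a, b, n) and (best is None or m > best[2]):
            best = (a, b, m)
    if best is None:
        return None
    a, b, m = best
    first, second = sorted([a, b], key=lambda iv: iv[0])
    return IRPair(first, second, m)


def partition_quadripartite(seq: Sequence, ir: IRPair) -> Quadripartite:
    """Partition the circle into LSC/IRb/SSC/IRa given the IR pair.

    The larger single-copy interval is LSC (tie: the one first encountered
    from the origin); IRb is the IR copy immediately downstream of LSC.
    """
    n = len(seq)
    i1, i2 = ir.interval_b, ir.interval_a
    g12 = gap_forward(i1[1] % n, i2[0] % n, n)   # SC between copy1 and copy2
    g21 = gap_forward(i2[1] % n, i1[0] % n, n)
    if g12 == 0 or g21 == 0:
        raise DegenerateStructureError("IR copies are adjacent; no single-copy region")
    sc12 = normalize((i1[1] % n, i1[1] % n + g12), n)
    sc21 = normalize((i2[1] % n, i2[1] % n + g21), n)
    if g12 > g21 or (g12 == g21 and sc12[0] <= sc21[0]):
        lsc, ssc, irb, ira = sc12, sc21, i2, i1
    else:
        lsc, ssc, irb, ira = sc21, sc12, i1, i2
    quad = Quadripartite(lsc, irb, ssc, ira, n)
    assert sum(quad.lengths.values()) == n
    return quad


def _span_contains(genome: AnnotatedGenome, feat, pos: int) -> bool:
    n = len(genome)
    s, e = feat.span
    if e - s > n:
        return True
    return ((pos - s) % n) < (e - s)


def classify_junctions(quad: Quadripartite, genome: AnnotatedGenome
                       ) -> list[JunctionContext]:
    """Locate each junction inside a gene or in a named spacer."""
    n = len(genome)
    genes = [f for f in genome.features if f.kind != "intron"]
    out = []
    for name, pos in quad.junction_positions().items():
        hit = None
        for f in genes:
            if _span_contains(genome, f, pos):
                hit = f
                break
        if hit is not None:
            offset = (pos - hit.span[0]) % n
            out.append(JunctionContext(name, pos, within=hit.gene_name, offset=offset))
            continue
        if not genes:
            out.append(JunctionContext(name, pos))
            continue
        up = min(genes, key=lambda f: (pos - f.span[1]) % n)
        down = min(genes, key=lambda f: (f.span[0] - pos) % n)
        d1 = (pos - up.span[1]) % n
        d2 = (down.span[0] - pos) % n
        out.append(JunctionContext(name, pos, spacer=(up.gene_name, down.gene_name),
                                   distances=(d1, d2)))
    return out


_BOUNDARY_NAMES = ("JLB", "JSB", "JSA", "JLA")


def spacer_length(genome: AnnotatedGenome, g1: str, g2: str,
                  quad: Quadripartite | None = None) -> int:
    """Bases strictly between two feature spans (0 when they overlap or
    abut). Either name may be a junction (JLB/JSB/JSA/JLA, requires
    ``quad``) to measure from a quadripartite boundary."""
    n = len(genome)

    def resolve(name: str) -> Interval:
        if name in _BOUNDARY_NAMES:
            if quad is None:
                raise ValueError(f"{name} requires a Quadripartite")
            p = quad.junction_positions()[name]
            return (p, p)  # zero-width boundary marker
        feats = genome.find_features(name)
        if not feats:
            known = sorted({f.gene_name for f in genome.features})
            near = difflib.get_close_matches(name, known, n=3)
            raise UnknownGeneError(f"gene {name!r} not annotated; near matches: {near}")
        return feats[0].span

    s1, s2 = resolve(g1), resolve(g2)
    if s1[0] != s1[1] and s2[0] != s2[1] and overlaps(s1, s2, n):
        return 0
    d_fwd = (s2[0] - s1[1]) % n
    d_rev = (s1[0] - s2[1]) % n
    return min(d_fwd, d_rev)
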