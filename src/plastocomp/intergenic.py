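"""Intergenic-spacer extraction, pairwise divergence and marker selection.

Spacers are the maximal intergenic intervals of the region map, named
``g1-g2`` after their flanking genes in genome order; IR-duplicated spacers
collapse to one representative. Divergence between homologous spacers is
measured on a global pairwise alignment with gap columns excluded
(complete deletion within the pair), under three substitution models of
increasing complexity:

* p   — raw proportion of differing sites,
* JC  — Jukes-Cantor, d = -3/4 ln(1 - 4p/3),
* F84 — Felsenstein 1984 closed form with empirical base frequencies and
        the observed transition/transversion split; reduces to Kimura
        2-parameter when frequencies are equal.

Candidate markers are spacers ranking in the top K (default 25) of every
pairwise comparison whose focal-genome copy is at least ``min_len``
(default 500 bp) long.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import align
from .genome_model import (AnnotatedGenome, RegionMap, build_region_map,
                           reverse_complement)
from .intervals import Interval, fetch
from .structure import Quadripartite

_PURINES = {"A", "G"}
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class Spacer:
    name: str               # "g1-g2", flanking genes in genome order
    interval: Interval
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpacerDivergence:
    spacer: str
    pair: tuple[str, str]         # genome ids
    aligned_length: int           # gap-free columns
    p_distance: float | None
    distance: float | None        # distance under the requested model
    model: str
    defined: bool = True
    rank: int | None = None


@dataclass(frozen=True)
class MarkerCandidate:
    spacer: str
    length_focal: int
    ranks: dict[str, int] = field(hash=False, default_factory=dict)


def extract_unique_spacers(genome: AnnotatedGenome,
                           region_map: RegionMap | None = None,
                           quad: Quadripartite | None = None,
                           ) -> list[Spacer]:
    """One spacer per maximal intergenic interval; zero-length gaps are
    skipped. When ``quad`` is given, spacers fully inside IRa are dropped
    (IR duplicates collapse to the IRb copy); otherwise duplicates are
    collapsed when an identical or reverse-complement sequence with the
    same flank pair recurs."""
    region_map = region_map if region_map is not None else build_region_map(genome)
    n = len(genome)
    genes = [f for f in genome.features if f.kind != "intron"]
    out: list[Spacer] = []
    seen: set[tuple[frozenset, str]] = set()
    for s, e in region_map.intergenic_intervals():
        seq = fetch(genome.seq.residues, (s, e), n)
        if quad is not None:
            a0, a1 = quad.ira
            if (s - a0) % n < (a1 - a0) and (e - 1 - a0) % n < (a1 - a0):
                continue
        if genes:
            up = min(genes, key=lambda f: (s - f.span[1]) % n)
            down = min(genes, key=lambda f: (f.span[0] - e) % n)
            name = f"{up.gene_name}-{down.gene_name}"
        else:
            name = f"spacer@{s}"
        key = (frozenset(name.split("-", 1) if genes else [name]),
               min(seq, reverse_complement(seq)))
        if quad is None and key in seen:
            continue
        seen.add(key)
        out.append(Spacer(name, (s, e), seq))
    return out


def apply_exclusions(spacers: list[Spacer], excluded_genes: list[str],
                     known_genes: set[str] | None = None,
                     ) -> tuple[list[Spacer], list[str]]:
    """Drop spacers flanking any excluded (pseudogenized/absent) gene.

    Returns the filtered list and warnings for excluded genes that are not
    in the annotation (no-ops)."""
    warnings = []
    if known_genes is not None:
        for g in excluded_genes:
            if g not in known_genes:
                warnings.append(f"excluded gene {g!r} not annotated; ignored")
    excl = set(excluded_genes)
    kept = [sp for sp in spacers
            if not excl & set(sp.name.split("-", 1))]
    return kept, warnings


class SpacerNameConflict(ValueError):
    pass


def pair_spacers(spacers_a: list[Spacer], spacers_b: list[Spacer]
                 ) -> tuple[list[tuple[Spacer, Spacer]], list[Spacer], list[Spacer]]:
    """Match homologous spacers by their unordered flanking-gene pair."""
    def index(spacers, label):
        idx = {}
        for sp in spacers:
            key = frozenset(sp.name.split("-", 1))
            if key in idx:
                raise SpacerNameConflict(
                    f"duplicate spacer {sp.name} in genome {label} after IR collapse")
            idx[key] = sp
        return idx

    ia, ib = index(spacers_a, "A"), index(spacers_b, "B")
    pairs = [(ia[k], ib[k]) for k in ia if k in ib]
    pairs.sort(key=lambda t: t[0].interval[0])
    un_a = [sp for k, sp in ia.items() if k not in ib]
    un_b = [sp for k, sp in ib.items() if k not in ia]
    return pairs, un_a, un_b


def _f84_distance(cols: list[tuple[str, str]]) -> float | None:
    """Closed-form F84 distance from gap-free columns."""
    L = len(cols)
    P = sum(1 for x, y in cols if x != y and frozenset((x, y)) in _TRANSITIONS) / L
    Q = sum(1 for x, y in cols if x != y and frozenset((x, y)) not in _TRANSITIONS) / L
    freqs = {b: 0 for b in "ACGT"}
    for x, y in cols:
        freqs[x] += 1
        freqs[y] += 1
    tot = 2 * L
    pi = {b: c / tot for b, c in freqs.items()}
    pr = pi["A"] + pi["G"]
    py = pi["C"] + pi["T"]
    if pr == 0 or py == 0:
        return None
    A = pi["C"] * pi["T"] / py + pi["A"] * pi["G"] / pr
    B = pi["C"] * pi["T"] + pi["A"] * pi["G"]
    C = pr * py
    if A == 0 or C == 0:
        return None
    x1 = 1 - P / (2 * A) - (A - B) * Q / (2 * A * C)
    x2 = 1 - Q / (2 * C)
    if x1 <= 0 or x2 <= 0:
        return None
    return -2 * A * math.log(x1) + 2 * (A - B - C) * math.log(x2)


def divergence(spacer_a: Spacer, spacer_b: Spacer,
               pair: tuple[str, str] = ("A", "B"), model: str = "F84",
               aligner=None) -> SpacerDivergence:
    """Aligned pairwise distance for one homologous spacer pair."""
    if model not in ("p", "JC", "F84"):
        raise ValueError(f"unknown model {model!r}")
    if not spacer_a.sequence or not spacer_b.sequence:
        raise ValueError("empty spacer sequence")
    ga, gb = align.global_align(spacer_a.sequence, spacer_b.sequence, aligner)
    cols = [(x, y) for x, y in zip(ga, gb)
            if x not in "-N" and y not in "-N"]
    name = spacer_a.name
    if not cols:
        return SpacerDivergence(name, pair, 0, None, None, model, defined=False)
    L = len(cols)
    p = sum(1 for x, y in cols if x != y) / L
    if model == "p":
        d = p
    elif model == "JC":
        arg = 1 - 4 * p / 3
        d = -0.75 * math.log(arg) if arg > 0 else None
    else:
        d = _f84_distance(cols)
    return SpacerDivergence(name, pair, L, p, d, model, defined=d is not None)


def summarize_comparison(divergences: list[SpacerDivergence]
                         ) -> tuple[float, float, list[SpacerDivergence]]:
    """Mean and sample SD over defined distances plus the ranked table
    (descending distance; ties broken by longer aligned length, then name).
    A single defined distance gives SD 0."""
    defined = [d for d in divergences if d.defined]
    if not defined:
        raise ValueError("no defined distances to summarize")
    vals = [d.distance for d in defined]
    mean = sum(vals) / len(vals)
    if len(vals) > 1:
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    else:
        sd = 0.0
    ranked = sorted(defined, key=lambda d: (-d.distance, -d.aligned_length, d.spacer))
    from dataclasses import replace
    ranked = [replace(d, rank=i + 1) for i, d in enumerate(ranked)]
    return mean, sd, ranked


def select_markers(comparisons: dict[str, list[SpacerDivergence]],
                   focal_spacers: list[Spacer],
                   k: int = 25, min_len: int = 500) -> list[MarkerCandidate]:
    """Spacers in the top-``k`` of every comparison with focal length >=
    ``min_len``. ``comparisons`` maps comparator id -> ranked table (from
    :func:`summarize_comparison`)."""
    if len(comparisons) < 1:
        raise ValueError("need at least one comparison")
    lengths = {sp.name: len(sp) for sp in focal_spacers}
    top_sets = []
    rank_maps = {}
    for comp_id, ranked in comparisons.items():
        kk = min(k, len(ranked))
        rank_maps[comp_id] = {d.spacer: d.rank for d in ranked}
        top_sets.append({d.spacer for d in ranked if d.rank <= kk})
    shared = set.intersection(*top_sets)
    out = []
    for name in sorted(shared):
        if lengths.get(name, 0) >= min_len:
            out.append(MarkerCandidate(
                name, lengths[name],
                {c: rank_maps[c][name] for c in comparisons}))
    out.sort(key=lambda m: (sum(m.ranks.values()), m.spacer))
    return out


def comparison_table(divergences: list[SpacerDivergence],
                     len_a: dict[str, int] | None = None,
                     len_b: dict[str, int] | None = None) -> pd.DataFrame:
    rows = []
    for d in divergences:
        rows.append({"spacer": d.spacer,
                     "length_a": (len_a or {}).get(d.spacer),
                     "length_b": (len_b or {}).get(d.spacer),
                     "aligned_length": d.aligned_length,
                     "p_distance": d.p_distance,
                     "distance": d.distance, "model": d.model,
                     "rank": d.rank, "defined": d.defined})
    return pd.DataFrame(rows)
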