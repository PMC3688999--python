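"""Perfect microsatellite (SSR) detection and cross-genome comparison.

An SSR is a maximal perfect tandem repeat of a primitive 1-6 bp motif that
reaches a per-unit-length minimum repeat count (defaults 10, 5, 4, 3, 3, 3
for mono- through hexanucleotides). A locus is reported once, at its
smallest period: a run of twelve A's is one mononucleotide SSR, never an
(AA)x6 dinucleotide. Scanning handles the circular origin.

Cross-genome comparison classifies each SSR as conserved or
lineage-specific: conserved means same motif, same genomic region class
(coding / intron / intergenic) and flanking sequences that align between
the two plastomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from . import align
from .genome_model import AnnotatedGenome, RegionMap, Sequence
from .intervals import Interval, fetch, split_wrap

DEFAULT_MIN_REPEATS = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRThresholds:
    min_repeats: dict[int, int]

    def __post_init__(self):
        if any(v < 1 for v in self.min_repeats.values()):
            raise ValueError("thresholds must be >= 1")

    @classmethod
    def default(cls) -> "SSRThresholds":
        return cls(dict(DEFAULT_MIN_REPEATS))


@dataclass(frozen=True)
class SSR:
    motif: str
    n_repeats: int
    interval: Interval
    region: str | None = None       # coding / intron / intergenic
    context: str | None = None      # nearest gene(s)

    @property
    def unit_length(self) -> int:
        return len(self.motif)

    @property
    def length(self) -> int:
        return self.unit_length * self.n_repeats

    def key(self):
        return (self.interval[0], self.interval[1], self.motif)


@dataclass
class SSRComparison:
    conserved: list[tuple[SSR, SSR, float]]   # (A, B, flank identity)
    unique_a: list[SSR]
    unique_b: list[SSR]
    unassessable_a: list[SSR]
    unassessable_b: list[SSR]


def _primitive(motif: str) -> bool:
    """True when the motif is not a power of a shorter string."""
    return motif not in (motif + motif)[1:-1]


def scan_ssrs(seq: Sequence, thresholds: SSRThresholds | None = None
              ) -> list[SSR]:
    """All maximal perfect tandem repeats meeting their unit-length
    threshold, reported at the smallest qualifying period."""
    thresholds = thresholds or SSRThresholds.default()
    s = seq.residues
    n = len(s)
    text = s + s if seq.circular else s
    found: dict[tuple[int, int, str], SSR] = {}
    for p, min_rep in sorted(thresholds.min_repeats.items()):
        if p > n:
            continue
        limit = len(text) - p
        i = 0
        while i < limit:
            if text[i] != text[i + p]:
                i += 1
                continue
            # maximal run of period-p matches starting at i
            j = i
            while j < limit and text[j] == text[j + p]:
                j += 1
            if seq.circular and i == 0 and s[n - 1] == s[(p - 1) % n]:
                # run continues leftward across the origin; its maximal form
                # is found again at a start near the end of the first copy
                i = j + 1
                continue
            span = (j - i) + p                 # periodic span length
            n_rep = span // p
            if n_rep >= min_rep:
                start = i
                motif = text[start:start + p]
                if _primitive(motif) and n_rep * p <= n:
                    if seq.circular:
                        key = (start % n, p, motif)
                    else:
                        key = (start, p, motif)
                    if key not in found and (not seq.circular or start < n):
                        found[key] = SSR(motif, n_rep,
                                         (key[0], key[0] + n_rep * p))
            i = j + 1
    return sorted(found.values(), key=lambda r: (r.interval[0], r.unit_length))


def classify_ssrs(ssrs: list[SSR], region_map: RegionMap,
                  genome: AnnotatedGenome | None = None) -> list[SSR]:
    """Attach a region label (majority base; ties -> first base) and, when a
    genome is given, the nearest-gene context."""
    out = []
    for r in ssrs:
        region = region_map.majority_label(r.interval)
        context = None
        if genome is not None:
            context = _context(genome, r.interval)
        out.append(replace(r, region=region, context=context))
    return out


def _context(genome: AnnotatedGenome, iv: Interval) -> str | None:
    n = len(genome)
    genes = [f for f in genome.features if f.kind != "intron"]
    if not genes:
        return None
    mid = (iv[0] + (iv[1] - iv[0]) // 2) % n
    inside = [f for f in genes
              if ((mid - f.span[0]) % n) < (f.span[1] - f.span[0])]
    if inside:
        return inside[0].gene_name
    up = min(genes, key=lambda f: (mid - f.span[1]) % n)
    down = min(genes, key=lambda f: (f.span[0] - mid) % n)
    return f"{up.gene_name}-{down.gene_name}"


def _flanks(seq: Sequence, iv: Interval, flank_len: int) -> tuple[str, str]:
    n = len(seq)
    s, e = iv
    left = fetch(seq.residues, (((s - flank_len) % n), ((s - flank_len) % n) + flank_len), n)
    right = fetch(seq.residues, (e % n, e % n + flank_len), n)
    return left, right


def match_conserved_ssrs(genome_a: AnnotatedGenome, ssrs_a: list[SSR],
                         genome_b: AnnotatedGenome, ssrs_b: list[SSR],
                         flank_len: int = 100,
                         min_flank_identity: float = 0.6) -> SSRComparison:
    """Greedy one-to-one pairing of conserved SSRs between two plastomes.

    A pair is a candidate when motif and region label agree; it is accepted
    when both flank windows align with identity >= ``min_flank_identity``.
    Candidates are consumed in order of descending mean flank identity.
    SSRs whose flanks contain unresolved runs of N are reported separately.
    """
    def assessable(g, r):
        fl = _flanks(g.seq, r.interval, flank_len)
        return "NNNNN" not in fl[0] and "NNNNN" not in fl[1]

    ok_a = [r for r in ssrs_a if assessable(genome_a, r)]
    ok_b = [r for r in ssrs_b if assessable(genome_b, r)]
    candidates = []
    for ia, ra in enumerate(ok_a):
        la, ra_fl = _flanks(genome_a.seq, ra.interval, flank_len)
        for ib, rb in enumerate(ok_b):
            if ra.motif != rb.motif or ra.region != rb.region:
                continue
            lb, rb_fl = _flanks(genome_b.seq, rb.interval, flank_len)
            id_l = align.identity(la, lb)
            id_r = align.identity(ra_fl, rb_fl)
            if id_l >= min_flank_identity and id_r >= min_flank_identity:
                candidates.append(((id_l + id_r) / 2, ia, ib))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    conserved = []
    for ident, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        conserved.append((ok_a[ia], ok_b[ib], ident))
    return SSRComparison(
        conserved=conserved,
        unique_a=[r for i, r in enumerate(ok_a) if i not in used_a],
        unique_b=[r for i, r in enumerate(ok_b) if i not in used_b],
        unassessable_a=[r for r in ssrs_a if not assessable(genome_a, r)],
        unassessable_b=[r for r in ssrs_b if not assessable(genome_b, r)],
    )


def summarize_ssrs(comparison: SSRComparison) -> pd.DataFrame:
    """Cross-tab of {conserved, unique_a, unique_b} x unit length x region,
    with per-category fractions."""
    rows = []
    for r, _, _ in ((c[0], None, None) for c in comparison.conserved):
        rows.append(("conserved", r.unit_length, r.region))
    for r in comparison.unique_a:
        rows.append(("unique_a", r.unit_length, r.region))
    for r in comparison.unique_b:
        rows.append(("unique_b", r.unit_length, r.region))
    df = pd.DataFrame(rows, columns=["category", "unit_length", "region"])
    if df.empty:
        return pd.DataFrame(0, index=pd.Index([], name="category"), columns=[])
    tab = (df.groupby(["category", "unit_length", "region"])
             .size().rename("count").reset_index())
    totals = tab.groupby("category")["count"].transform("sum")
    tab["fraction"] = tab["count"] / totals
    return tab


def find_compound_regions(ssrs: list[SSR], max_gap: int = 50
                          ) -> list[list[SSR]]:
    """Maximal clusters of adjacent SSRs (gap <= max_gap) that involve at
    least two distinct motifs."""
    srt = sorted(ssrs, key=lambda r: r.interval[0])
    clusters: list[list[SSR]] = []
    cur: list[SSR] = []
    for r in srt:
        if cur and r.interval[0] - cur[-1].interval[1] <= max_gap:
            cur.append(r)
        else:
            if len(cur) >= 2:
                clusters.append(cur)
            cur = [r]
    if len(cur) >= 2:
        clusters.append(cur)
    return [c for c in clusters if len({r.motif for r in c}) >= 2]


def ssr_table(ssrs: list[SSR]) -> pd.DataFrame:
    """Tabular report (motif, repeats, start, end, region, context)."""
    return pd.DataFrame(
        [{"motif": r.motif, "repeats": r.n_repeats,
          "start": r.interval[0], "end": r.interval[1],
          "region": r.region, "context": r.context} for r in ssrs])
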