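"""Desk-scale reference-assisted plastome assembly.

Pipeline: (1) recruit putative plastome reads by shared k-mers with
reference plastomes; (2) de novo assembly of the recruited reads with a
minimal de Bruijn (k-mer graph) assembler producing unitig contigs;
(3) iterative improvement — resolve the repeat structure into a single
circular sequence using unitig adjacency, coverage-derived copy numbers and
mate-pair concordance, falling back to mate-pair scaffolding plus
consensus margin extension when the graph is broken by coverage gaps; and
(4) read-pair mapping for per-base depth and abnormal-insert-size anomaly
flagging.

The assembler is double-stranded throughout: k-mers are counted in
canonical (strand-min) form and every contig is reported once, in an
arbitrary but deterministic orientation.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np

from .genome_model import reverse_complement


@dataclass(frozen=True)
class Read:
    id: str
    residues: str


@dataclass(frozen=True)
class ReadPair:
    r1: Read
    r2: Read
    library: str = "paired_end"      # paired_end | mate_pair
    insert_mean: float = 250.0
    insert_sd: float = 30.0


@dataclass
class ReadLibrary:
    pairs: list[ReadPair]
    insert_mean: float
    insert_sd: float
    name: str = "paired_end"

    def reads(self) -> list[Read]:
        out = []
        for p in self.pairs:
            out.append(p.r1)
            out.append(p.r2)
        return out


@dataclass
class Contig:
    residues: str
    support: np.ndarray            # per-k-mer counts along the contig
    circular: bool = False

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(self.support)) if len(self.support) else 0.0


@dataclass
class Assembly:
    contigs: list[Contig]

    @property
    def circularized(self) -> bool:
        return len(self.contigs) == 1 and self.contigs[0].circular


@dataclass
class AssemblyReport:
    n_input_contigs: int
    n_scaffolds: int
    circularized: bool
    anomalies: list[tuple[int, int]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class AssemblyConfig:
    k: int = 31
    min_links: int = 3
    n_sd: float = 4.0
    min_overlap: int = 200
    max_iterations: int = 10
    max_walks: int = 64


def pair_reads(reads1, reads2, library="paired_end",
               insert_mean=250.0, insert_sd=30.0) -> list[ReadPair]:
    """Zip two FASTQ-style (id, seq, qual) lists into ReadPairs."""
    if len(reads1) != len(reads2):
        raise ValueError("mate files differ in read count")
    return [ReadPair(Read(a[0], a[1]), Read(b[0], b[1]), library,
                     insert_mean, insert_sd)
            for a, b in zip(reads1, reads2)]


# ---------------------------------------------------------------------------
# read recruitment

def recruit_reads(reads: list[Read], references: list[str],
                  k: int = 31, t: int = 2) -> list[Read]:
    """Keep reads sharing >= t k-mers (either strand) with any reference."""
    if not references:
        raise ValueError("empty reference set")
    ref_kmers: set[str] = set()
    for ref in references:
        for s in (ref, reverse_complement(ref)):
            ref_kmers.update(s[i:i + k] for i in range(len(s) - k + 1))
    out = []
    for r in reads:
        hits = sum(r.residues[i:i + k] in ref_kmers
                   for i in range(len(r.residues) - k + 1))
        if hits >= t:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# de Bruijn assembly

def _count_kmers(seqs, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for s in seqs:
        if len(s) < k or "N" in s:
            continue
        rc = reverse_complement(s)
        L = len(s)
        for i in range(L - k + 1):
            fwd = s[i:i + k]
            rev = rc[L - i - k:L - i]
            key = fwd if fwd <= rev else rev
            counts[key] = counts.get(key, 0) + 1
    return counts


class _Graph:
    """Helper around a canonical k-mer count table."""

    def __init__(self, counts: dict[str, int], k: int, min_count: int = 1):
        self.k = k
        self.counts = {km: c for km, c in counts.items() if c >= min_count}

    def count(self, km: str) -> int:
        rc = reverse_complement(km)
        return self.counts.get(km if km <= rc else rc, 0)

    def has(self, km: str) -> bool:
        return self.count(km) > 0

    def succs(self, km: str) -> list[str]:
        return [km[1:] + c for c in "ACGT" if self.has(km[1:] + c)]

    def preds(self, km: str) -> list[str]:
        return [c + km[:-1] for c in "ACGT" if self.has(c + km[:-1])]


def initial_assemble(reads: list[Read], k: int = 31, min_contig_len: int = 500,
                     min_count: int = 1) -> list[Contig]:
    """Unitigs of the double-stranded de Bruijn graph.

    Contigs are maximal non-branching paths after discarding k-mers seen
    fewer than ``min_count`` times; an isolated simple cycle (e.g. a clean
    single-copy circular genome) is emitted as one circular contig.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError("k must be odd and >= 3")
    if not reads:
        return []
    g = _Graph(_count_kmers((r.residues for r in reads), k), k, min_count)

    def canon(km):
        rc = reverse_complement(km)
        return km if km <= rc else rc

    visited: set[str] = set()
    contigs: list[Contig] = []

    def walk_from(start: str):
        """Extend a unitig rightward from ``start``; returns kmer chain."""
        chain = [start]
        cur = start
        while True:
            nxt = g.succs(cur)
            if len(nxt) != 1:
                break
            nx = nxt[0]
            if len(g.preds(nx)) != 1 or canon(nx) in visited or nx == reverse_complement(nx):
                break
            chain.append(nx)
            visited.add(canon(nx))
            cur = nx
        return chain

    def emit(chain, circular=False):
        seq = chain[0] + "".join(km[-1] for km in chain[1:])
        support = np.array([g.count(km) for km in chain])
        if circular:
            seq = seq[:-(k - 1)] if len(chain) > 1 else seq
        contigs.append(Contig(seq, support, circular))

    # unitig starts: kmers whose left context is not a simple continuation
    all_kmers = sorted(g.counts)  # canonical forms, deterministic order
    oriented = []
    for km in all_kmers:
        oriented.append(km)
        oriented.append(reverse_complement(km))
    for km in oriented:
        if canon(km) in visited:
            continue
        preds = g.preds(km)
        is_start = (len(preds) != 1
                    or len(g.succs(preds[0])) != 1
                    or preds[0] == reverse_complement(preds[0]))
        if not is_start:
            continue
        visited.add(canon(km))
        emit(walk_from(km))
    # leftover simple cycles
    for km in all_kmers:
        if km in visited:
            continue
        visited.add(km)
        chain = walk_from(km)
        emit(chain, circular=len(chain) > 1 and chain[-1][1:] + chain[0][-1] == chain[0])
    return [c for c in contigs if len(c) >= min_contig_len or c.circular]


# ---------------------------------------------------------------------------
# read mapping

class _Mapper:
    """Exact-seed + bounded-mismatch placement onto one sequence."""

    def __init__(self, seq: str, circular: bool, seed_len: int = 31,
                 max_mismatch: int = 2):
        self.n = len(seq)
        self.circular = circular
        self.seed_len = min(seed_len, self.n)
        self.max_mismatch = max_mismatch
        self.text = seq + seq[:200 + seed_len] if circular else seq
        self.index: dict[str, list[int]] = {}
        w = self.seed_len
        for i in range(self.n):
            if i + w > len(self.text):
                break
            self.index.setdefault(self.text[i:i + w], []).append(i)

    def _verify(self, read: str, pos: int) -> int | None:
        if pos + len(read) > len(self.text):
            if not self.circular:
                return None
            ext = self.text + self.text  # long reads on short circles
            window = ext[pos:pos + len(read)]
        else:
            window = self.text[pos:pos + len(read)]
        mm = sum(a != b for a, b in zip(read, window))
        return mm if mm <= self.max_mismatch else None

    def place(self, read: str) -> list[tuple[int, str, int]]:
        """All best placements as (start, strand, mismatches)."""
        best: list[tuple[int, str, int]] = []
        best_mm = self.max_mismatch + 1
        for strand, r in (("+", read), ("-", reverse_complement(read))):
            for off in (0, self.seed_len):
                if off + self.seed_len > len(r):
                    break
                for pos in self.index.get(r[off:off + self.seed_len], []):
                    start = pos - off
                    if start < 0 or (not self.circular and start + len(r) > self.n):
                        continue
                    mm = self._verify(r, start)
                    if mm is None:
                        continue
                    hit = (start % self.n, strand, mm)
                    if mm < best_mm:
                        best, best_mm = [hit], mm
                    elif mm == best_mm and hit not in best:
                        best.append(hit)
                if best_mm == 0 and off == 0:
                    break
        return best


def map_and_coverage(assembly: Assembly, reads: list[Read],
                     seed_len: int = 31, max_mismatch: int = 2
                     ) -> tuple[list[np.ndarray], int]:
    """Per-base depth per contig; multi-placed reads contribute
    fractionally to every best placement. Returns (tracks, n_unplaced)."""
    if not assembly.contigs:
        raise ValueError("empty assembly")
    mappers = [_Mapper(c.residues, c.circular, seed_len, max_mismatch)
               for c in assembly.contigs]
    tracks = [np.zeros(len(c), dtype=float) for c in assembly.contigs]
    unplaced = 0
    for r in reads:
        hits = []
        for ci, m in enumerate(mappers):
            for start, strand, mm in m.place(r.residues):
                hits.append((mm, ci, start))
        if not hits:
            unplaced += 1
            continue
        best_mm = min(h[0] for h in hits)
        hits = [h for h in hits if h[0] == best_mm]
        w = 1.0 / len(hits)
        for _, ci, start in hits:
            n = len(assembly.contigs[ci])
            end = start + len(r.residues)
            if end <= n:
                tracks[ci][start:end] += w
            else:
                tracks[ci][start:] += w
                tracks[ci][:end - n] += w
    return tracks, unplaced


# ---------------------------------------------------------------------------
# iterative improvement

def _weighted_median_coverage(contigs: list[Contig]) -> float:
    vals = []
    for c in contigs:
        vals.extend([c.mean_coverage] * max(1, len(c) // 500))
    return statistics.median(vals)


def _candidate_walks(contigs: list[Contig], k: int, max_walks: int):
    """Circular superwalks using each contig exactly its copy number of
    times (copy number from relative coverage)."""
    single = _weighted_median_coverage(contigs)
    copy_n = [max(1, round(c.mean_coverage / single)) for c in contigs]
    seqs = {}
    for i, c in enumerate(contigs):
        seqs[(i, "+")] = c.residues
        seqs[(i, "-")] = reverse_complement(c.residues)
    nodes = list(seqs)
    edges = {u: [] for u in nodes}
    for u in nodes:
        for v in nodes:
            if seqs[u][-(k - 1):] == seqs[v][:k - 1]:
                edges[u].append(v)
    # start from the longest single-copy contig, fixed orientation
    start_idx = max(range(len(contigs)),
                    key=lambda i: (copy_n[i] == 1, len(contigs[i])))
    start = (start_idx, "+")
    walks = []

    def dfs(cur, remaining, path):
        if len(walks) >= max_walks:
            return
        for nxt in edges[cur]:
            i = nxt[0]
            if nxt == start and all(r == 0 for r in remaining):
                walks.append(list(path))
                continue
            if remaining[i] == 0:
                continue
            remaining[i] -= 1
            path.append(nxt)
            dfs(nxt, remaining, path)
            path.pop()
            remaining[i] += 1

    remaining = list(copy_n)
    remaining[start_idx] -= 1
    dfs(start, remaining, [start])
    out = []
    for w in walks:
        seq = seqs[w[0]]
        for u in w[1:]:
            seq += seqs[u][k - 1:]
        out.append(seq[:-(k - 1)])
    return out, copy_n


def circular_equivalent(a: str, b: str) -> bool:
    """True when two circular sequences match up to rotation and strand."""
    if len(a) != len(b):
        return False
    return b in a + a or reverse_complement(b) in a + a


def _dedupe_circular(seqs: list[str]) -> list[str]:
    out: list[str] = []
    for s in seqs:
        if not any(circular_equivalent(s, t) for t in out):
            out.append(s)
    return out


def _concordance_vector(seq: str, lib: ReadLibrary, n_sd: float,
                        mapper: "_Mapper | None" = None) -> list[bool]:
    """Per-pair flags: does the pair map in the expected orientation with an
    insert within n_sd standard deviations of the library mean?"""
    n = len(seq)
    mapper = mapper or _Mapper(seq, circular=True)
    lo = lib.insert_mean - n_sd * lib.insert_sd
    hi = lib.insert_mean + n_sd * lib.insert_sd
    flags = []
    for p in lib.pairs:
        h1 = mapper.place(p.r1.residues)
        h2 = mapper.place(p.r2.residues)
        ok = False
        for s1, st1, _ in h1:
            for s2, st2, _ in h2:
                if st1 == st2:
                    continue
                if st1 == "+":
                    ins = (s2 + len(p.r2.residues) - s1) % n
                else:
                    ins = (s1 + len(p.r1.residues) - s2) % n
                if lo <= ins <= hi:
                    ok = True
                    break
            if ok:
                break
        flags.append(ok)
    return flags


def _try_self_circularize(c: Contig, min_overlap: int) -> Contig | None:
    s = c.residues
    if c.circular:
        return c
    max_ov = min(len(s) // 2, 20_000)
    for ov in range(max_ov, min_overlap - 1, -1):
        if s[:ov] == s[-ov:]:
            return Contig(s[:-ov], c.support, circular=True)
    return None


def _extend_margins(contigs: list[Contig], reads: list[Read],
                    cfg: AssemblyConfig, max_ext: int = 2000) -> list[Contig]:
    """Consensus extension of contig margins by overhanging reads."""
    out = []
    for c in contigs:
        if c.circular:
            out.append(c)
            continue
        seq = c.residues
        for side in ("right", "left"):
            work = seq if side == "right" else reverse_complement(seq)
            anchor_len = min(200, len(work))
            for _ in range(max_ext):
                anchor = work[-anchor_len:]
                votes: dict[str, int] = {}
                for r in reads:
                    for rr in (r.residues, reverse_complement(r.residues)):
                        idx = rr.find(anchor[-40:])
                        if idx == -1:
                            continue
                        a_start = idx - (anchor_len - 40)
                        if a_start < 0:
                            continue
                        if rr[a_start:idx + 40] != anchor:
                            continue
                        nxt_i = idx + 40
                        if nxt_i < len(rr):
                            votes[rr[nxt_i]] = votes.get(rr[nxt_i], 0) + 1
                if not votes or sum(votes.values()) < cfg.min_links:
                    break
                ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
                if len(ranked) > 1 and ranked[0][1] < 2 * ranked[1][1]:
                    break  # ambiguous branch (e.g. exiting a repeat): stop
                work += ranked[0][0]
            seq = work if side == "right" else reverse_complement(work)
        out.append(Contig(seq, c.support, False))
    return out


def _merge_overlapping(contigs: list[Contig], min_overlap: int) -> list[Contig]:
    """Merge contigs whose extended ends share an exact >= min_overlap
    suffix/prefix; greedy, deterministic."""
    work = list(contigs)
    merged = True
    while merged and len(work) > 1:
        merged = False
        for i in range(len(work)):
            for j in range(len(work)):
                if i == j or work[i].circular or work[j].circular:
                    continue
                a, b = work[i].residues, work[j].residues
                for bseq in (b, reverse_complement(b)):
                    ov = _longest_suffix_prefix(a, bseq, min_overlap)
                    if ov:
                        new = Contig(a + bseq[ov:],
                                     np.concatenate([work[i].support,
                                                     work[j].support]))
                        work = [c for idx, c in enumerate(work)
                                if idx not in (i, j)] + [new]
                        merged = True
                        break
                if merged:
                    break
            if merged:
                break
    return work


def _longest_suffix_prefix(a: str, b: str, min_overlap: int) -> int:
    max_ov = min(len(a), len(b))
    for ov in range(max_ov, min_overlap - 1, -1):
        if a[-ov:] == b[:ov]:
            return ov
    return 0


def detect_anomalies(seq: str, circular: bool, libraries: list[ReadLibrary],
                     n_sd: float = 4.0, window: int = 500, step: int = 250,
                     min_span: int = 3) -> list[tuple[int, int]]:
    """Windows whose spanning-pair median insert deviates by more than
    n_sd standard deviations from the library mean, or which are covered by
    reads but spanned by fewer than ``min_span`` concordant pairs (a
    misjoin leaves no — or only spuriously placed — spanning pairs)."""
    n = len(seq)
    mapper = _Mapper(seq, circular)
    centers = list(range(window // 2, n, step))
    spanning: list[list[float]] = [[] for _ in centers]
    covered = np.zeros(n)
    for lib in libraries:
        lo = lib.insert_mean - n_sd * lib.insert_sd
        hi = lib.insert_mean + n_sd * lib.insert_sd
        for p in lib.pairs:
            h1 = mapper.place(p.r1.residues)
            h2 = mapper.place(p.r2.residues)
            for s, _, _ in h1 + h2:
                covered[s % n] += 1
            placed = None
            for s1, st1, _ in h1:
                for s2, st2, _ in h2:
                    if st1 == st2:
                        continue
                    if st1 == "+":
                        start, ins = s1, (s2 + len(p.r2.residues) - s1) % n
                    else:
                        start, ins = s2, (s1 + len(p.r1.residues) - s2) % n
                    if lo <= ins <= hi and (placed is None or abs(ins - lib.insert_mean) < abs(placed[1] - lib.insert_mean)):
                        placed = (start, ins)
            if placed is None:
                continue
            start, ins = placed
            z = (ins - lib.insert_mean) / lib.insert_sd
            for wi, ctr in enumerate(centers):
                if (ctr - start) % n < ins:
                    spanning[wi].append(z)
    flagged = []
    for wi, ctr in enumerate(centers):
        s, e = max(0, ctr - window // 2), min(n, ctr + window // 2)
        if len(spanning[wi]) >= min_span:
            if abs(statistics.median(spanning[wi])) > n_sd:
                flagged.append((s, e))
        elif covered[s:e].sum() > 0:
            flagged.append((s, e))
    # merge adjacent flagged windows
    merged: list[tuple[int, int]] = []
    for s, e in sorted(flagged):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def iterate_improve(contigs: list[Contig], libraries: list[ReadLibrary],
                    cfg: AssemblyConfig | None = None
                    ) -> tuple[Assembly, AssemblyReport]:
    """Iteratively merge, extend and circularize the initial contigs.

    The repeat structure (collapsed IR) is resolved by enumerating circular
    superwalks of the unitig graph consistent with coverage-derived copy
    numbers and choosing the walk best supported by concordant read pairs
    (requiring >= 2:1 support over the runner-up); when the graph admits no
    such walk the fallback is mate-pair scaffolding with consensus margin
    extension and overlap merging.
    """
    cfg = cfg or AssemblyConfig()
    notes: list[str] = []
    if not contigs:
        return Assembly([]), AssemblyReport(0, 0, False, notes=["no input contigs"])
    all_reads = [r for lib in libraries for r in lib.reads()]

    final: list[Contig] = []
    if len(contigs) == 1:
        c = _try_self_circularize(contigs[0], cfg.min_overlap)
        if c is not None:
            final = [c]
            notes.append("single contig circularized (converged in one iteration)")
    if not final and len(contigs) >= 1:
        walks, copy_n = _candidate_walks(contigs, cfg.k, cfg.max_walks)
        candidates = _dedupe_circular(walks)
        if len(candidates) == 1:
            final = [Contig(candidates[0], np.concatenate(
                [c.support for c in contigs]), circular=True)]
            notes.append(f"unique circular superwalk (copy numbers {copy_n})")
        elif len(candidates) > 1:
            # score candidates only on pairs whose concordance differs
            # between candidates (e.g. repeat-spanning mate-pairs that
            # distinguish the SSC flip-flop isomers)
            vectors = []
            for s in candidates:
                mp = _Mapper(s, circular=True)
                v: list[bool] = []
                for lib in libraries:
                    v.extend(_concordance_vector(s, lib, cfg.n_sd, mp))
                vectors.append(v)
            informative = [i for i in range(len(vectors[0]))
                           if len({v[i] for v in vectors}) > 1]
            scores = [sum(v[i] for i in informative) for v in vectors]
            order = sorted(range(len(scores)), key=lambda i: -scores[i])
            best, second = scores[order[0]], scores[order[1]]
            if best >= cfg.min_links and (second == 0 or best >= 2 * second):
                final = [Contig(candidates[order[0]], np.concatenate(
                    [c.support for c in contigs]), circular=True)]
                notes.append(f"best superwalk chosen by pair support {best}:{second}")
            else:
                notes.append(f"ambiguous superwalks (support {best}:{second}); left unmerged")
    if not final:
        # fallback: consensus extension + overlap merging, to fixpoint
        work = list(contigs)
        for _ in range(cfg.max_iterations):
            before = (len(work), sum(len(c) for c in work))
            work = _extend_margins(work, all_reads, cfg)
            work = _merge_overlapping(work, cfg.min_overlap)
            if len(work) == 1:
                c = _try_self_circularize(work[0], cfg.min_overlap)
                if c is not None:
                    work = [c]
                    break
            if (len(work), sum(len(c) for c in work)) == before:
                break
        final = work
        notes.append(f"extension fallback finished with {len(work)} scaffold(s)")

    anomalies: list[tuple[int, int]] = []
    if len(final) == 1:
        anomalies = detect_anomalies(final[0].residues, final[0].circular,
                                     libraries, cfg.n_sd)
    asm = Assembly(final)
    report = AssemblyReport(len(contigs), len(final), asm.circularized,
                            anomalies, notes)
    return asm, report
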