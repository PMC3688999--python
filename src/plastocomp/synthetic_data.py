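"""Ground-truthed synthetic plastomes, genome pairs and read libraries.

The generator emulates the quadripartite plastome architecture: a circle of
LSC + IRb + SSC + IRa with IRa the exact reverse complement of IRb, GC
content around 38%, genes (CDS/tRNA/rRNA, some with introns) placed without
overlap, and — for pairs — per-spacer planted substitution rates and
planted shared/unique SSRs. Background sequence is scrubbed of accidental
threshold-passing SSRs so that planted SSR counts are exact ground truth.

Everything is reproducible from (spec, seed): one NumPy Generator per call,
no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import (AnnotatedGenome, Feature, RegionMap, Sequence,
                           reverse_complement)
from .intervals import Interval
from .ssr import SSR, SSRThresholds, scan_ssrs

_BASES = np.array(list("ACGT"))


class SizingError(ValueError):
    pass


class PlacementError(ValueError):
    pass


@dataclass(frozen=True)
class PlastomeSpec:
    """Architecture of one synthetic plastome. Defaults approximate a
    typical asterid plastome (LSC ~86 kb, SSC ~18 kb, IR ~25 kb, GC 38%)."""

    lsc_len: int = 86_000
    ssc_len: int = 18_000
    ir_len: int = 25_000
    gc: float = 0.38
    n_genes: int = 80
    intron_genes: int = 8
    seed: int = 0
    n_trna: int = 20
    n_rrna: int = 0
    ir_genes: int = 2          # rRNA genes duplicated between IRb and IRa
    junction_gene: bool = False  # plant a gene straddling JLB
    min_gap: int = 40

    def __post_init__(self):
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0,1)")
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")

    @property
    def total(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class PlantedSSRSpec:
    motif: str
    repeats: int
    region_label: str = "intergenic"
    shared: bool = True

    def __post_init__(self):
        if not (1 <= len(self.motif) <= 6):
            raise ValueError("motif unit length must be 1-6")


@dataclass(frozen=True)
class DivergenceSpec:
    """Per-spacer substitution probabilities for make_genome_pair."""

    default_rate: float = 0.02
    spacer_rates: dict[str, float] = field(default_factory=dict, hash=False)
    indel_rate: float = 0.0

    def __post_init__(self):
        for r in [self.default_rate, *self.spacer_rates.values()]:
            if not (0 <= r < 0.75):
                raise ValueError("substitution probabilities must be in [0, 0.75)")

    def rate_for(self, spacer_name: str) -> float:
        return self.spacer_rates.get(spacer_name, self.default_rate)


@dataclass(frozen=True)
class ReadLibSpec:
    read_len: int = 100
    insert_mean: int = 223
    insert_sd: int = 20
    coverage: float = 30.0
    error_rate: float = 0.0
    contaminant_fraction: float = 0.0
    mate_pair: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.insert_mean < self.read_len:
            raise ValueError("insert_mean must be >= read_len")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")


@dataclass
class PlastomeTruth:
    spec: PlastomeSpec
    regions: dict[str, Interval]          # LSC/IRb/SSC/IRa intervals
    region_map: RegionMap                 # constructed label array
    features: tuple[Feature, ...]


@dataclass
class PairTruth:
    planted_shared: list[dict]
    planted_unique: list[dict]            # unique to genome A
    spacer_true_p: dict[str, float]       # exact per-spacer p (no-indel case)
    spacer_intervals_a: dict[str, Interval]


@dataclass
class ReadTruth:
    n_pairs: int
    origins: dict[str, tuple[int, str, int, bool]]  # id -> (start, strand, insert, contaminant)


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _other_base(b: str, avoid: set[str], rng: np.random.Generator) -> str:
    choices = [x for x in "ACGT" if x != b and x not in avoid]
    return choices[int(rng.integers(len(choices)))]


def _scrub(arr: np.ndarray, rng: np.random.Generator,
           protected: list[Interval] | None = None,
           mirror_ir: tuple[Interval, Interval] | None = None,
           circular: bool = True, max_rounds: int = 20) -> None:
    """Break every threshold-passing SSR outside protected intervals by a
    single substitution (mirrored into the other IR copy when inside one)."""
    protected = protected or []
    n = len(arr)
    for _ in range(max_rounds):
        hits = scan_ssrs(Sequence("".join(arr), circular))
        dirty = False
        for h in hits:
            if any(h.interval[0] < e and s < h.interval[1] for s, e in protected):
                continue
            dirty = True
            mid = (h.interval[0] + h.length // 2) % n
            old = arr[mid]
            arr[mid] = _other_base(old, set(), rng)
            if mirror_ir is not None:
                (b0, b1), (a0, a1) = mirror_ir
                if b0 <= mid < b1:
                    arr[a0 + (b1 - 1 - mid)] = reverse_complement(arr[mid])
                elif a0 <= mid < a1:
                    arr[b0 + (a1 - 1 - mid)] = reverse_complement(arr[mid])
        if not dirty:
            return
    raise RuntimeError("could not scrub background SSRs")


_TRNA_ANTICODONS = ["UGC", "GCA", "GUC", "UUC", "GAA", "GCC", "GUG", "AUU",
                    "CAU", "UAG", "CAA", "UAA", "UUU", "CAU", "GGA", "UGA",
                    "GCU", "UGU", "GUA", "UAC", "GAC", "ACG", "GUU", "CCA"]


def _gene_names(n_cds: int, n_trna: int, n_rrna: int) -> list[tuple[str, str]]:
    names = [(f"gcp{i + 1:03d}", "CDS") for i in range(n_cds)]
    letters = "ACDEFGHIKLMNPQRSTVWY"
    names += [(f"trn{letters[i % len(letters)]}-{_TRNA_ANTICODONS[i % len(_TRNA_ANTICODONS)]}"
               + ("" if i < len(letters) else str(i)), "tRNA")
              for i in range(n_trna)]
    names += [(f"rrn{i + 1}", "rRNA") for i in range(n_rrna)]
    return names


def _place_in_region(rng, region_start, region_len, gene_specs, min_gap):
    """Lay out genes left-to-right with random gaps >= min_gap on each side."""
    total_gene = sum(l for _, _, l in gene_specs)
    k = len(gene_specs)
    slack = region_len - total_gene - (k + 1) * min_gap
    if slack < 0:
        raise SizingError(
            f"genes ({total_gene} bp + gaps) do not fit in region of {region_len} bp")
    extra = rng.multinomial(slack, np.ones(k + 1) / (k + 1)) if slack else np.zeros(k + 1, int)
    pos = region_start
    placed = []
    for i, (name, kind, length) in enumerate(gene_specs):
        pos += min_gap + int(extra[i])
        placed.append((name, kind, pos, pos + length))
        pos += length
    return placed


def make_plastome(spec: PlastomeSpec) -> tuple[AnnotatedGenome, PlastomeTruth]:
    """Build a circular quadripartite genome with ground truth.

    Layout: LSC [0,L) + IRb [L,L+I) + SSC + IRa, IRa == rc(IRb) exactly.
    """
    rng = np.random.default_rng(spec.seed)
    L, S, I = spec.lsc_len, spec.ssc_len, spec.ir_len
    n = spec.total

    lsc = _random_seq(L, spec.gc, rng)
    irb = _random_seq(I, spec.gc, rng)
    ssc = _random_seq(S, spec.gc, rng)
    for a in (lsc, irb, ssc):
        _scrub(a, rng, circular=False)

    arr = np.concatenate([lsc, irb, ssc,
                          np.array(list(reverse_complement("".join(irb))))])
    regions = {"LSC": (0, L), "IRb": (L, L + I),
               "SSC": (L + I, L + I + S), "IRa": (L + I + S, n)}

    # --- gene layout -------------------------------------------------------
    n_cds = spec.n_genes - spec.n_trna - spec.n_rrna
    if n_cds < 0:
        raise SizingError("n_trna + n_rrna exceeds n_genes")
    pool = _gene_names(n_cds, spec.n_trna, spec.n_rrna)
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]

    def draw_len(kind):
        return {"CDS": int(rng.integers(300, 1500)),
                "tRNA": int(rng.integers(70, 90)),
                "rRNA": int(rng.integers(1500, 2900))}[kind]

    specs = [(nm, kd, draw_len(kd)) for nm, kd in pool]
    # fill the SSC up to ~70% occupancy (length-aware), remainder in LSC
    ssc_specs, lsc_specs, ssc_used = [], [], 0
    target = S * len(specs) / (L + S)
    for sp in specs:
        if (len(ssc_specs) < target
                and ssc_used + sp[2] + (len(ssc_specs) + 2) * spec.min_gap < 0.7 * S):
            ssc_specs.append(sp)
            ssc_used += sp[2]
        else:
            lsc_specs.append(sp)
    lsc_end_reserved = 600 if spec.junction_gene else 0
    placed = _place_in_region(rng, 0, L - lsc_end_reserved, lsc_specs, spec.min_gap)
    placed += _place_in_region(rng, L + I, S, ssc_specs, spec.min_gap)

    features: list[Feature] = []
    intron_budget = spec.intron_genes
    for i, (name, kind, s, e) in enumerate(placed):
        strand = "+" if i % 2 == 0 else "-"
        if kind == "CDS" and intron_budget > 0 and e - s >= 600:
            third = (e - s) // 3
            parts = ((s, s + third), (e - third, e))
            intron_budget -= 1
        else:
            parts = ((s, e),)
        features.append(Feature(name, kind, strand, parts))

    # IR-duplicated genes (rRNA), mirrored exactly between the copies
    for g in range(spec.ir_genes):
        # one disjoint slot per IR gene
        slot = (I - 400) // spec.ir_genes
        hi = min(2400, slot - 100)
        if hi < 300:
            raise SizingError("IR too short for the requested ir_genes")
        glen = int(rng.integers(min(1200, hi - 1), hi))
        off = 200 + g * slot + int(rng.integers(slot - glen - 100))
        name = f"rrnIR{g + 1}"
        b0, b1 = L + off, L + off + glen
        a0, a1 = (L + I + S) + (I - (off + glen)), (L + I + S) + (I - off)
        features.append(Feature(name, "rRNA", "+", ((b0, b1),)))
        features.append(Feature(name, "rRNA", "-", ((a0, a1),)))

    if spec.junction_gene:
        features.append(Feature("jlbgene", "CDS", "+", ((L - 200, L + 300),)))

    # --- truth region map, painted straight from the placement ------------
    codes = np.zeros(n, dtype=np.uint8)
    for f in features:
        ps = sorted(f.parts)
        for k in range(len(ps) - 1):
            codes[ps[k][1]:ps[k + 1][0]] = np.maximum(codes[ps[k][1]:ps[k + 1][0]], 1)
        for s, e in ps:
            codes[s:e] = 2

    # guard bases so the planted IR is exactly maximal: neither end of the
    # repeat pair may extend by one base under the rc identity
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if arr[L - 1] == comp[arr[0]]:            # outward extension (JLB/JLA)
        arr[L - 1] = _other_base(comp[arr[0]], set(), rng)
    if arr[L + I + S - 1] == comp[arr[L + I]]:  # inward extension (JSB/JSA)
        arr[L + I + S - 1] = _other_base(comp[arr[L + I]], set(), rng)

    _scrub(arr, rng, circular=True,
           mirror_ir=(regions["IRb"], regions["IRa"]))

    genome = AnnotatedGenome(f"synth{spec.seed}", Sequence("".join(arr), True),
                             tuple(features))
    truth = PlastomeTruth(spec, regions, RegionMap(codes), tuple(features))
    return genome, truth


# ---------------------------------------------------------------------------
# genome pairs

def plant_ssr(arr: np.ndarray, start: int, motif: str, repeats: int,
              rng: np.random.Generator) -> Interval:
    """Write a maximal perfect tandem repeat at ``start`` (guard bases on
    both sides prevent accidental extension)."""
    unit = list(motif)
    seq = unit * repeats
    end = start + len(seq)
    arr[start:end] = seq
    if arr[start - 1] == motif[-1]:
        arr[start - 1] = _other_base(motif[-1], set(), rng)
    if arr[end % len(arr)] == motif[0]:
        arr[end % len(arr)] = _other_base(motif[0], set(), rng)
    return (start, end)


def make_genome_pair(genome_a: AnnotatedGenome, truth_a: PlastomeTruth,
                     div: DivergenceSpec,
                     ssrs: list[PlantedSSRSpec] = (),
                     seed: int = 0, genome_b_id: str | None = None,
                     ) -> tuple[AnnotatedGenome, AnnotatedGenome, PairTruth]:
    """Derive a diverged second genome from ``genome_a``.

    Substitutions are applied per single-copy intergenic spacer at the
    planted rate (the IR is left untouched so IRa==rc(IRb) holds in both).
    Shared SSRs are written into both genomes at homologous positions;
    unique SSRs into genome A only. Returns (genome_a', genome_b, truth):
    genome A is returned as well because planted SSRs modify it.

    With ``indel_rate`` 0 (the default) coordinates are identical between
    the genomes and per-spacer true p-distances are exact by construction.
    """
    rng = np.random.default_rng(seed)
    n = len(genome_a)
    arr_a = np.array(list(genome_a.seq.residues))
    arr_b = arr_a.copy()
    codes = truth_a.region_map.codes
    ir_ivs = [truth_a.regions["IRb"], truth_a.regions["IRa"]]

    def in_ir(s, e):
        return any(s < b and a < e for a, b in ir_ivs)

    # spacer intervals (single-copy, nonzero), named by flanking genes;
    # the run wrapping the origin is one spacer with end > n
    genes = [f for f in truth_a.features if f.kind != "intron"]
    spacer_ivs: dict[str, Interval] = {}
    runs = RegionMap(codes).intergenic_intervals(circular=True)
    for s, e in runs:
        if in_ir(s % n, min(e, n)) or (e > n and in_ir(0, e - n)):
            continue
        up = min(genes, key=lambda f: (s - f.span[1]) % n)
        down = min(genes, key=lambda f: (f.span[0] - e) % n)
        spacer_ivs[f"{up.gene_name}-{down.gene_name}"] = (s, e)

    # --- substitutions (and optional indels) in genome B ------------------
    for name, (s, e) in sorted(spacer_ivs.items(), key=lambda kv: kv[1][0]):
        rate = div.rate_for(name)
        if rate > 0:
            mask = rng.random(e - s) < rate
            for off in np.flatnonzero(mask):
                pos = (s + int(off)) % n
                arr_b[pos] = _other_base(arr_b[pos], set(), rng)

    if div.indel_rate > 0:
        # small indels implemented as segment edits on a string copy;
        # robustness-test only, coordinates downstream of each indel shift
        chars = list(arr_b)
        for name, (s, e) in sorted(spacer_ivs.items(), key=lambda kv: -kv[1][0]):
            k = rng.poisson(div.indel_rate * (e - s))
            for _ in range(int(k)):
                pos = int(rng.integers(s + 1, e - 1))
                size = int(rng.integers(1, 6))
                if rng.random() < 0.5:
                    del chars[pos:pos + size]
                else:
                    ins = _random_seq(size, truth_a.spec.gc, rng)
                    chars[pos:pos] = list(ins)
        arr_b = np.array(chars)

    # --- planted SSRs ------------------------------------------------------
    label_code = {"intergenic": 0, "intron": 1, "coding": 2}
    host_runs = {lab: [] for lab in label_code}
    pos0 = 0
    c = codes
    breaks = np.flatnonzero(np.diff(c)) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(c)]])
    for s, e in zip(starts, ends):
        lab = {0: "intergenic", 1: "intron", 2: "coding"}[int(c[s])]
        if not in_ir(int(s), int(e)):
            host_runs[lab].append((int(s), int(e)))

    planted_shared, planted_unique = [], []
    used: list[Interval] = []

    def free_segments(run: Interval, need: int) -> list[Interval]:
        segs = [run]
        for u_s, u_e in used:
            nxt = []
            for s, e in segs:
                if u_e + 30 <= s or e <= u_s - 30:
                    nxt.append((s, e))
                else:
                    if u_s - 30 - s >= need:
                        nxt.append((s, u_s - 30))
                    if e - (u_e + 30) >= need:
                        nxt.append((u_e + 30, e))
            segs = nxt
        return [seg for seg in segs if seg[1] - seg[0] >= need]

    for ps in ssrs:
        ssr_len = len(ps.motif) * ps.repeats
        need = ssr_len + 60
        options = [seg for run in host_runs[ps.region_label]
                   for seg in free_segments(run, need)]
        if not options:
            raise PlacementError(
                f"no room to plant {ps.motif}x{ps.repeats} in {ps.region_label}")
        hs, he = options[int(rng.integers(len(options)))]
        start = int(rng.integers(hs + 30, he - ssr_len - 30 + 1))
        if ps.shared:
            plant_ssr(arr_a, start, ps.motif, ps.repeats, rng)
            if div.indel_rate == 0:
                plant_ssr(arr_b, start, ps.motif, ps.repeats, rng)
            rec = {"motif": ps.motif, "repeats": ps.repeats,
                   "region": ps.region_label, "interval": (start, start + ssr_len)}
            planted_shared.append(rec)
        else:
            plant_ssr(arr_a, start, ps.motif, ps.repeats, rng)
            planted_unique.append({"motif": ps.motif, "repeats": ps.repeats,
                                   "region": ps.region_label,
                                   "interval": (start, start + ssr_len)})
        used.append((start, start + ssr_len))

    # --- scrub accidental SSRs created by mutation/planting ----------------
    protect = [r["interval"] for r in planted_shared + planted_unique]
    _scrub(arr_a, rng, protected=protect, mirror_ir=tuple(ir_ivs))
    if div.indel_rate == 0:
        _scrub(arr_b, rng, protected=protect, mirror_ir=tuple(ir_ivs))

    # --- exact per-spacer divergence truth ---------------------------------
    spacer_true_p: dict[str, float] = {}
    if div.indel_rate == 0:
        for name, (s, e) in spacer_ivs.items():
            diffs = int(np.sum(arr_a[s:e] != arr_b[s:e]))
            spacer_true_p[name] = diffs / (e - s)

    genome_a2 = AnnotatedGenome(genome_a.id, Sequence("".join(arr_a), True),
                                genome_a.features)
    features_b = genome_a.features if div.indel_rate == 0 else ()
    genome_b = AnnotatedGenome(genome_b_id or f"{genome_a.id}_pair{seed}",
                               Sequence("".join(arr_b), True), features_b)
    truth = PairTruth(planted_shared, planted_unique, spacer_true_p, spacer_ivs)
    return genome_a2, genome_b, truth


# ---------------------------------------------------------------------------
# read simulation

def simulate_reads(genome: AnnotatedGenome, lib: ReadLibSpec,
                   id_prefix: str = "sim"
                   ) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], ReadTruth]:
    """Sample read pairs uniformly over the circle (FR orientation).

    Returns (reads1, reads2, truth) where readsN are FASTQ-style
    (id, residues, quality) triples. Contaminant pairs are drawn from an
    independently generated AT-rich random sequence (phytoplasma-like).
    """
    rng = np.random.default_rng(lib.seed)
    g = genome.seq.residues
    n = len(g)
    rl = lib.read_len
    if n <= lib.insert_mean:
        raise ValueError("genome shorter than insert size")
    n_pairs = int(round(lib.coverage * n / (2 * rl)))
    contam = None
    if lib.contaminant_fraction > 0:
        contam = "".join(_random_seq(max(2 * lib.insert_mean, 20_000), 0.25,
                                     np.random.default_rng(lib.seed + 104729)))
    reads1, reads2 = [], []
    origins = {}
    qual = "I" * rl
    g2 = g + g
    for i in range(n_pairs):
        is_contam = bool(lib.contaminant_fraction > 0
                         and rng.random() < lib.contaminant_fraction)
        src = contam if is_contam else g2
        src_n = len(contam) if is_contam else n
        insert = max(2 * rl, int(round(rng.normal(lib.insert_mean, lib.insert_sd))))
        insert = min(insert, src_n - 1)
        start = int(rng.integers(src_n - insert)) if is_contam else int(rng.integers(n))
        frag = src[start:start + insert]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = reverse_complement(frag)
        r1, r2 = frag[:rl], reverse_complement(frag[-rl:])
        if lib.error_rate > 0:
            r1 = _mutate_read(r1, lib.error_rate, rng)
            r2 = _mutate_read(r2, lib.error_rate, rng)
        rid = f"{id_prefix}_{i:07d}"
        reads1.append((rid + "/1", r1, qual))
        reads2.append((rid + "/2", r2, qual))
        origins[rid] = (start, strand, insert, is_contam)
    return reads1, reads2, ReadTruth(n_pairs, origins)


def _mutate_read(r: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(r))
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        arr[i] = _other_base(arr[i], set(), rng)
    return "".join(arr)


def rotate_genome(genome: AnnotatedGenome, shift: int) -> AnnotatedGenome:
    """Rotate the circular coordinate origin by ``shift`` bases (utility for
    rotation-invariance checks)."""
    n = len(genome)
    shift %= n
    res = genome.seq.residues
    new_res = res[shift:] + res[:shift]
    feats = []
    for f in genome.features:
        parts = []
        for s, e in f.parts:
            ns = (s - shift) % n
            parts.append((ns, ns + (e - s)))
        feats.append(replace(f, parts=tuple(parts),
                             wraps=any(e > n for _, e in parts)))
    return AnnotatedGenome(genome.id, Sequence(new_res, True), tuple(feats))
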