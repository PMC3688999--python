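"""Multi-genome gene presence/absence and concatenated supermatrix export.

Ortholog grouping is name-based: plastome gene names are standardized, so
genes are grouped by normalized name through a synonym table, with a
shared-k-mer screen flagging dubious assignments instead of auto-correcting
them. Per-gene alignments are concatenated in alphabetical gene order with
absent taxa padded by ``?``; exports are relaxed PHYLIP, NEXUS (with a sets
block of gene partitions) and FASTA, the input formats of standard tree
software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import align
from .genome_model import AnnotatedGenome, reverse_complement

# genes commonly absent/pseudogenized across asterid plastomes, excluded
# from concatenation by default
DEFAULT_EXCLUDED_GENES = ("infA", "ycf15")

DEFAULT_SYNONYMS = {"pbf1": "psbN", "ycf9": "psbZ", "psb30": "ycf12"}

MISSING = "?"


@dataclass
class OrthologGroup:
    gene: str
    members: dict[str, str]            # genome id -> nucleotide sequence
    conflicts: list[str] = field(default_factory=list)

    def presence(self, genome_ids: list[str]) -> list[int]:
        return [int(g in self.members) for g in genome_ids]


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]               # taxon -> concatenated characters
    partitions: dict[str, tuple[int, int]]  # gene -> (start, end) 0-based

    @property
    def n_char(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def variable_sites(self) -> int:
        cols = zip(*(self.rows[t] for t in self.taxa))
        return sum(1 for col in cols
                   if len({c for c in col if c not in (MISSING, "-")}) > 1)


def _normalize(name: str, synonyms: dict[str, str]) -> str:
    base = name.strip()
    return synonyms.get(base, synonyms.get(base.lower(), base))


def _kmer_similarity(a: str, b: str, k: int = 12) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i:i + k] for i in range(len(a) - k + 1)}
    kb = {b[i:i + k] for i in range(len(b) - k + 1)}
    kb |= {reverse_complement(s) for s in kb}
    return len(ka & kb) / len(ka)


def group_genes(genomes: list[AnnotatedGenome],
                synonyms: dict[str, str] | None = None,
                kinds: tuple[str, ...] = ("CDS", "rRNA"),
                similarity_screen: float = 0.0,
                ) -> tuple[list[OrthologGroup], pd.DataFrame]:
    """Group genes across genomes by normalized name.

    IR duplicates collapse to one copy (the longer). Two same-named loci in
    one genome whose sequences are neither identical nor reverse
    complements are recorded as a conflict on the group. Returns the groups
    (alphabetical) and a presence/absence DataFrame (genes x genomes).
    """
    synonyms = dict(DEFAULT_SYNONYMS if synonyms is None else synonyms)
    groups: dict[str, OrthologGroup] = {}
    for genome in genomes:
        for f in genome.features:
            if f.kind not in kinds:
                continue
            name = _normalize(f.gene_name, synonyms)
            seq = genome.feature_sequence(f)
            grp = groups.setdefault(name, OrthologGroup(name, {}))
            prev = grp.members.get(genome.id)
            if prev is None:
                grp.members[genome.id] = seq
            else:
                if prev != seq and prev != reverse_complement(seq):
                    grp.conflicts.append(
                        f"{genome.id}: two distinct {name} loci")
                if len(seq) > len(prev):
                    grp.members[genome.id] = seq
    if similarity_screen > 0:
        for grp in groups.values():
            seqs = list(grp.members.items())
            ref_id, ref = max(seqs, key=lambda kv: len(kv[1]))
            for gid, s in seqs:
                if gid != ref_id and _kmer_similarity(s, ref) < similarity_screen:
                    grp.conflicts.append(
                        f"{gid}: low k-mer similarity to {ref_id} for {grp.gene}")
    ordered = [groups[g] for g in sorted(groups)]
    ids = [g.id for g in genomes]
    table = pd.DataFrame([[g.gene] + g.presence(ids) for g in ordered],
                         columns=["gene"] + ids).set_index("gene")
    return ordered, table


def _center_star(seqs: dict[str, str]) -> dict[str, str]:
    """Center-star multiple alignment around the longest member.

    Each sequence is aligned pairwise to the ungapped center; gap columns
    are merged under the 'once a gap, always a gap' rule, so every row ends
    up the same length. Equal-length inputs (the no-indel case) pass
    through unchanged.
    """
    if len({len(s) for s in seqs.values()}) == 1:
        return dict(seqs)
    center_id = max(seqs, key=lambda k: (len(seqs[k]), k))
    center = seqs[center_id]
    master = center                      # center with accumulated gaps
    rows: dict[str, str] = {}            # others, in master coordinates
    for sid in sorted(seqs):
        if sid == center_id:
            continue
        ga_c, ga_s = align.global_align(center, seqs[sid])
        new_master, new_row = [], []
        patched: dict[str, list[str]] = {t: [] for t in rows}
        i = j = 0
        while i < len(master) or j < len(ga_c):
            mi = master[i] if i < len(master) else None
            cj = ga_c[j] if j < len(ga_c) else None
            if mi == "-" and cj != "-" or (cj is None and mi == "-"):
                # old gap column not present in the new pairwise alignment
                new_master.append("-")
                new_row.append("-")
                for t in rows:
                    patched[t].append(rows[t][i])
                i += 1
            elif cj == "-" and (mi != "-" or mi is None):
                # new gap column introduced by this sequence
                new_master.append("-")
                new_row.append(ga_s[j])
                for t in rows:
                    patched[t].append("-")
                j += 1
            else:                        # both are the same center residue
                new_master.append(mi)
                new_row.append(ga_s[j])
                for t in rows:
                    patched[t].append(rows[t][i])
                i += 1
                j += 1
        master = "".join(new_master)
        rows = {t: "".join(v) for t, v in patched.items()}
        rows[sid] = "".join(new_row)
    out = dict(rows)
    out[center_id] = master
    return out


def build_supermatrix(groups: list[OrthologGroup], taxa: list[str] | None = None,
                      aligner=None, min_members: int = 4,
                      max_length_ratio: float = 10.0,
                      ) -> tuple[Supermatrix, list[str]]:
    """Align each retained group, concatenate alphabetically, pad absences.

    ``aligner`` is a hook taking ``{id: seq}`` and returning aligned
    ``{id: seq}`` (e.g. :func:`plastocomp.align.mafft_align`); the default
    is the built-in center-star aligner (a no-op stack when members are
    already equal-length). Groups with fewer than ``min_members`` members
    or member length ratio above ``max_length_ratio`` are dropped with a
    warning.
    """
    aligner = aligner or _center_star
    if taxa is None:
        taxa = sorted({t for g in groups for t in g.members})
    warnings = []
    rows = {t: [] for t in taxa}
    partitions = {}
    pos = 0
    for grp in sorted(groups, key=lambda g: g.gene):
        members = {t: s for t, s in grp.members.items() if t in taxa}
        if len(members) < min_members:
            warnings.append(f"{grp.gene}: only {len(members)} members; dropped")
            continue
        lens = [len(s) for s in members.values()]
        if max(lens) / min(lens) > max_length_ratio:
            warnings.append(f"{grp.gene}: length ratio > {max_length_ratio}; dropped")
            continue
        aligned = aligner(members)
        width = len(next(iter(aligned.values())))
        if any(len(s) != width for s in aligned.values()):
            raise ValueError(f"aligner returned ragged rows for {grp.gene}")
        for t in taxa:
            rows[t].append(aligned.get(t, MISSING * width))
        partitions[grp.gene] = (pos, pos + width)
        pos += width
    matrix = Supermatrix(list(taxa), {t: "".join(v) for t, v in rows.items()},
                         partitions)
    assert matrix.n_char == sum(e - s for s, e in partitions.values())
    return matrix, warnings


# ---------------------------------------------------------------------------
# export

def _sanitize(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._" else "_" for c in name)


def export(matrix: Supermatrix, fmt: str, path: str | Path
           ) -> dict[str, str]:
    """Write the matrix as relaxed PHYLIP, NEXUS (with sets block) or
    FASTA. Returns the taxon-name sanitization mapping."""
    mapping = {t: _sanitize(t) for t in matrix.taxa}
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("taxon names collide after sanitization")
    path = Path(path)
    if fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(matrix.taxa)} {matrix.n_char}\n")
            for t in matrix.taxa:
                fh.write(f"{mapping[t]}  {matrix.rows[t]}\n")
    elif fmt == "fasta":
        with open(path, "w") as fh:
            for t in matrix.taxa:
                fh.write(f">{mapping[t]}\n{matrix.rows[t]}\n")
    elif fmt == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={matrix.n_char};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
            for t in matrix.taxa:
                fh.write(f"    {mapping[t]}  {matrix.rows[t]}\n")
            fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
            for gene, (s, e) in matrix.partitions.items():
                fh.write(f"  CHARSET {_sanitize(gene)} = {s + 1}-{e};\n")
            fh.write("END;\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return mapping


def read_fasta_matrix(path: str | Path) -> Supermatrix:
    """Round-trip reader for FASTA exports (no partition table)."""
    taxa, rows = [], {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:]
                taxa.append(name)
                rows[name] = ""
            elif name:
                rows[name] += line
    return Supermatrix(taxa, rows, {})
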