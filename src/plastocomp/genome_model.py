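"""Genome and annotation data model plus readers/writers.

The plastome is represented as a circular :class:`Sequence` with a flat list
of :class:`Feature` records (CDS, tRNA, rRNA, intron, pseudogene). Internally
everything is 0-based half-open; the GenBank 1-based inclusive convention
exists only at the I/O boundary. Origin-wrapping features keep ``end >
len(genome)`` on their last part (see :mod:`plastocomp.intervals`).

Standard-format parsing is delegated to Biopython (``Bio.SeqIO``); this
module only adapts records to/from the internal model.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .intervals import Interval, fetch, split_wrap

_ALPHABET = set("ACGTN")
_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "intron", "pseudogene")

# region labels, ordered by priority when they overlap
CODING, INTRON, INTERGENIC = "coding", "intron", "intergenic"
_LABEL_CODE = {INTERGENIC: 0, INTRON: 1, CODING: 2}
_CODE_LABEL = {v: k for k, v in _LABEL_CODE.items()}


class GenomeFormatError(ValueError):
    """Raised on malformed GenBank/FASTA/FASTQ input."""


def reverse_complement(s: str) -> str:
    return s.translate(_RC)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A nucleotide sequence over {A,C,G,T,N}, optionally circular."""

    residues: str
    circular: bool = True

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty sequence")
        bad = set(self.residues.upper()) - _ALPHABET
        if bad:
            raise ValueError(f"non-ACGTN residues: {sorted(bad)}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "Sequence":
        return Sequence(reverse_complement(self.residues), self.circular)

    def fetch(self, iv: Interval) -> str:
        if not self.circular and iv[1] > len(self):
            raise ValueError(f"interval {iv} wraps a linear sequence")
        return fetch(self.residues, iv)


@dataclass(frozen=True)
class Feature:
    """One annotated feature; ``parts`` are ordered 0-based half-open
    intervals in genome coordinates (last part may wrap: end > genome length
    with ``wraps`` set)."""

    gene_name: str
    kind: str
    strand: str
    parts: tuple[Interval, ...]
    wraps: bool = False

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.parts:
            raise ValueError("feature with no location parts")
        for s, e in self.parts:
            if e <= s:
                raise ValueError(f"empty part ({s},{e}) in {self.gene_name}")

    @property
    def span(self) -> Interval:
        return (min(p[0] for p in self.parts), max(p[1] for p in self.parts))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def intron_intervals(self) -> list[Interval]:
        """Gaps between consecutive parts (the annotated introns)."""
        ps = sorted(self.parts)
        return [(ps[i][1], ps[i + 1][0]) for i in range(len(ps) - 1)
                if ps[i + 1][0] > ps[i][1]]


@dataclass(frozen=True)
class AnnotatedGenome:
    id: str
    seq: Sequence
    features: tuple[Feature, ...] = ()

    def __post_init__(self):
        n = len(self.seq)
        for f in self.features:
            for s, e in f.parts:
                if s < 0 or s >= n or e > 2 * n:
                    raise ValueError(
                        f"feature {f.gene_name} part ({s},{e}) outside genome "
                        f"of length {n}")

    def __len__(self) -> int:
        return len(self.seq)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def find_features(self, gene_name: str) -> list[Feature]:
        return [f for f in self.features if f.gene_name == gene_name]

    def feature_sequence(self, f: Feature) -> str:
        s = "".join(self.seq.fetch(p) for p in sorted(f.parts))
        return reverse_complement(s) if f.strand == "-" else s


@dataclass(frozen=True)
class RegionMap:
    """Partition of [0, n) into coding / intron / intergenic labels.

    Stored densely as a uint8 array; overlap priority coding > intron >
    intergenic is applied at construction.
    """

    codes: np.ndarray  # uint8, one entry per base

    def __post_init__(self):
        if self.codes.ndim != 1 or len(self.codes) == 0:
            raise ValueError("region map must be a non-empty 1-d array")

    def __len__(self) -> int:
        return len(self.codes)

    def label_at(self, pos: int) -> str:
        return _CODE_LABEL[int(self.codes[pos % len(self.codes)])]

    def intervals(self) -> list[tuple[int, int, str]]:
        """Maximal runs of one label, in genome order (no wrap merging)."""
        c = self.codes
        breaks = np.flatnonzero(np.diff(c)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [len(c)]])
        return [(int(s), int(e), _CODE_LABEL[int(c[s])])
                for s, e in zip(starts, ends)]

    def majority_label(self, iv: Interval) -> str:
        """Label covering most of the interval; ties -> label of first base."""
        n = len(self.codes)
        counts = {}
        for s, e in split_wrap(iv, n):
            vals, cnts = np.unique(self.codes[s:e], return_counts=True)
            for v, c in zip(vals, cnts):
                counts[int(v)] = counts.get(int(v), 0) + int(c)
        best = max(counts.values())
        tied = [v for v, c in counts.items() if c == best]
        if len(tied) == 1:
            return _CODE_LABEL[tied[0]]
        return self.label_at(iv[0])

    def intergenic_intervals(self, circular: bool = True) -> list[Interval]:
        """Maximal intergenic runs; on a circular map the first and last
        runs merge across the origin into one wrapping interval."""
        runs = [(s, e) for s, e, lab in self.intervals() if lab == INTERGENIC]
        n = len(self.codes)
        if (circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == n
                and runs[0] != runs[-1]):
            first, last = runs[0], runs.pop()
            runs[0] = (last[0], n + first[1])
        return runs


@dataclass(frozen=True)
class GeneContentSummary:
    n_protein_coding: int
    n_rRNA: int
    n_tRNA: int


# ---------------------------------------------------------------------------
# Region map / gene content

def build_region_map(genome: AnnotatedGenome) -> RegionMap:
    """Label every base coding / intron / intergenic.

    Exon parts of CDS/tRNA/rRNA are coding; gaps between a feature's parts
    and explicit intron features are intron; everything else (including
    pseudogenes) is intergenic. Overlaps resolve coding > intron.
    """
    n = len(genome)
    codes = np.zeros(n, dtype=np.uint8)

    def paint(iv: Interval, code: int):
        for s, e in split_wrap(iv, n):
            np.maximum(codes[s:e], code, out=codes[s:e])

    for f in genome.features:
        if f.kind == "intron":
            for p in f.parts:
                paint(p, _LABEL_CODE[INTRON])
        elif f.kind in ("CDS", "tRNA", "rRNA"):
            for iv in f.intron_intervals():
                paint(iv, _LABEL_CODE[INTRON])
            for p in f.parts:
                paint(p, _LABEL_CODE[CODING])
    return RegionMap(codes)


def summarize_gene_content(genome: AnnotatedGenome,
                           count_ir_duplicates: bool = True,
                           ) -> GeneContentSummary:
    """Count genes by kind. With ``count_ir_duplicates`` every annotated copy
    counts (IR-duplicated genes twice); otherwise gene names are unique-ed.
    Pseudogenes and intron features never count."""
    counts = {"CDS": 0, "rRNA": 0, "tRNA": 0}
    seen: set[tuple[str, str]] = set()
    for f in genome.features:
        if f.kind not in counts:
            continue
        if not count_ir_duplicates:
            key = (f.kind, f.gene_name)
            if key in seen:
                continue
            seen.add(key)
        counts[f.kind] += 1
    return GeneContentSummary(counts["CDS"], counts["rRNA"], counts["tRNA"])


# ---------------------------------------------------------------------------
# GenBank I/O

_KIND_TO_GB = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "intron": "intron", "pseudogene": "gene"}


def _location_to_parts(loc, n: int) -> tuple[tuple[Interval, ...], bool]:
    parts = [(int(p.start), int(p.end)) for p in loc.parts]
    # Biopython keeps compound parts in transcription order; re-order to
    # genome order and detect an origin wrap (…,n) followed by (0,…).
    fwd = sorted(parts)
    wraps = False
    if len(fwd) >= 2 and fwd[-1][1] == n and fwd[0][0] == 0:
        # treat as wrap only when the pieces are adjacent across the origin
        # in the original join order
        joined = {(parts[i][1] % n, parts[i + 1][0]) for i in range(len(parts) - 1)}
        if (0, 0) in joined or (parts[-1][1] % n, parts[0][0]) == (0, 0):
            wraps = True
            last = fwd.pop()           # the (…, n) piece
            first = fwd.pop(0)         # the (0, …) piece
            fwd.append((last[0], n + first[1]))
    return tuple(fwd), wraps


def _parts_to_location(parts: tuple[Interval, ...], strand: str, n: int):
    locs = []
    st = 1 if strand == "+" else -1
    for s, e in parts:
        if e > n:  # wrapping part -> two GenBank pieces
            locs.append(SimpleLocation(s, n, strand=st))
            locs.append(SimpleLocation(0, e - n, strand=st))
        else:
            locs.append(SimpleLocation(s, e, strand=st))
    if strand == "-":
        locs = locs[::-1]
    return locs[0] if len(locs) == 1 else CompoundLocation(locs)


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`."""
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise GenomeFormatError(f"{path}: malformed GenBank record: {exc}") from exc
    if len(record.seq) == 0:
        raise GenomeFormatError(f"{path}: record has no ORIGIN sequence")
    n = len(record.seq)
    circular = record.annotations.get("topology", "circular") == "circular"
    feats: list[Feature] = []
    for f in record.features:
        pseudo = "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers
        if f.type in ("CDS", "tRNA", "rRNA", "intron"):
            kind = "pseudogene" if pseudo else f.type
        elif f.type == "gene" and pseudo:
            kind = "pseudogene"
        else:
            continue
        name = (f.qualifiers.get("gene") or f.qualifiers.get("product")
                or f.qualifiers.get("note") or ["?"])[0]
        strand = "-" if f.location.strand == -1 else "+"
        parts, wraps = _location_to_parts(f.location, n)
        feats.append(Feature(name, kind, strand, parts, wraps))
    return AnnotatedGenome(record.id or record.name,
                           Sequence(str(record.seq), circular),
                           tuple(feats))


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    n = len(genome)
    record = SeqRecord(Seq(genome.seq.residues), id=genome.id, name=genome.id[:16],
                       description="", annotations={
                           "molecule_type": "DNA",
                           "topology": "circular" if genome.seq.circular else "linear"})
    for f in genome.features:
        loc = _parts_to_location(f.parts, f.strand, n)
        qualifiers = {"gene": [f.gene_name]}
        gb_type = _KIND_TO_GB[f.kind]
        if f.kind == "pseudogene":
            qualifiers["pseudo"] = [""]
        record.features.append(SeqFeature(loc, type=gb_type, qualifiers=qualifiers))
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ``[(id, residues), ...]``."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if len(rec.seq) == 0:
            raise GenomeFormatError(f"{path}: empty sequence in record {i} ({rec.id})")
        out.append((rec.id, str(rec.seq).upper()))
    return out


def write_fasta(entries, path: str | Path, width: int = 70) -> None:
    """Write ``[(id, residues), ...]`` as 70-column-wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ as ``[(id, residues, quality), ...]``."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append((rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise GenomeFormatError(
            f"{path}: truncated/malformed FASTQ near record {len(out)}: {exc}"
        ) from exc
    return out


def write_fastq(entries, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in entries:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3 (FASTA+GFF3 alternative to GenBank)

_GFF_KIND = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
             "intron": "intron", "pseudogene": "pseudogene"}
_GFF_KIND_REV = {v: k for k, v in _GFF_KIND.items()}


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    n = len(genome)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {n}\n")
        for i, f in enumerate(genome.features):
            attrs = f"ID=f{i};gene_name={f.gene_name};wraps={int(f.wraps)}"
            for s, e in f.parts:
                # wrapping parts emitted with end > n, flagged via the wraps attr
                fh.write("\t".join([genome.id, "plastocomp", _GFF_KIND[f.kind],
                                    str(s + 1), str(e), ".", f.strand, ".",
                                    attrs]) + "\n")


def read_gff3(gff_path: str | Path, fasta_path: str | Path) -> AnnotatedGenome:
    entries = read_fasta(fasta_path)
    if len(entries) != 1:
        raise GenomeFormatError("expected exactly one FASTA sequence")
    seq_id, residues = entries[0]
    grouped: dict[str, list] = {}
    order: list[str] = []
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"{gff_path}: bad GFF3 line: {line!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            fid = attrs.get("ID", cols[8])
            if fid not in grouped:
                grouped[fid] = []
                order.append(fid)
            grouped[fid].append((cols, attrs))
    feats = []
    for fid in order:
        rows = grouped[fid]
        cols0, attrs0 = rows[0]
        parts = tuple(sorted((int(c[3]) - 1, int(c[4])) for c, _ in rows))
        feats.append(Feature(attrs0.get("gene_name", fid),
                             _GFF_KIND_REV[cols0[2]], cols0[6], parts,
                             wraps=attrs0.get("wraps") == "1"))
    return AnnotatedGenome(seq_id, Sequence(residues), tuple(feats))
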