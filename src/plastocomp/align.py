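"""Global pairwise alignment used for flank matching and spacer divergence.

Thin wrapper over ``Bio.Align.PairwiseAligner`` (Needleman-Wunsch with
affine gaps). Default scores: match +1, mismatch -1, gap open -5, gap
extend -1. An external-aligner hook (MAFFT) is available for callers that
want to reproduce published, aligner-sensitive numbers.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from Bio import Align


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_DEFAULT = make_aligner()


def global_align(a: str, b: str, aligner: Align.PairwiseAligner | None = None
                 ) -> tuple[str, str]:
    """Return one optimal global alignment as two gapped strings."""
    aligner = aligner or _DEFAULT
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of identical columns over all alignment columns."""
    ga, gb = global_align(a, b, aligner)
    matches = sum(x == y and x != "-" for x, y in zip(ga, gb))
    return matches / len(ga) if ga else 0.0


def mafft_align(seqs: dict[str, str]) -> dict[str, str]:
    """External-aligner hook: run MAFFT on named sequences.

    Raises ``RuntimeError`` when mafft is not on PATH.
    """
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        inp = Path(td) / "in.fasta"
        with open(inp, "w") as fh:
            for name, s in seqs.items():
                fh.write(f">{name}\n{s}\n")
        res = subprocess.run(["mafft", "--auto", "--quiet", str(inp)],
                             capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    name = None
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line.strip().upper()
    return out
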