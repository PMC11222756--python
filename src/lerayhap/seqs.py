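"""Low-level sequence utilities shared across the pipeline.

Translation goes through Biopython's NCBI codon tables (id 2 = vertebrate
mitochondrial, id 5 = invertebrate mitochondrial — the two codes relevant for
the fish and shrimp references this pipeline was built around). Pairwise
alignment is delegated to edlib (unit-cost distances, identity) and to
Biopython's PairwiseAligner (affine gaps, where indel placement matters);
everything on top of the alignments lives here.
"""

from __future__ import annotations

import re
from functools import lru_cache

import edlib
import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

DNA = "ACGT"

IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "S": set("CG"), "W": set("AT"),
    "K": set("GT"), "M": set("AC"), "B": set("CGT"), "D": set("AGT"),
    "H": set("ACT"), "V": set("ACG"), "N": set("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def codon_table(code_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


@lru_cache(maxsize=None)
def stop_codons(code_id: int) -> tuple[str, ...]:
    return tuple(codon_table(code_id).stop_codons)


def translate(seq: str, code_id: int) -> str:
    """Translate frame 0; trailing partial codon dropped; stops rendered '*'."""
    n = len(seq) - len(seq) % 3
    if n == 0:
        return ""
    return str(Seq(seq[:n].upper()).translate(table=code_id))


def internal_stop_positions(seq: str, code_id: int) -> list[int]:
    """Codon indices (0-based) of stop codons before the final codon."""
    aa = translate(seq, code_id)
    return [i for i, a in enumerate(aa[:-1]) if a == "*"]


def has_internal_stop(seq: str, code_id: int) -> bool:
    return bool(internal_stop_positions(seq, code_id))


def iupac_mismatches(pattern: str, text: str) -> int:
    """Mismatches of ``text`` against an IUPAC-degenerate ``pattern``.

    Compared position-by-position over len(pattern); text must be at least as
    long as pattern.
    """
    return sum(
        1 for p, t in zip(pattern.upper(), text.upper()) if t not in IUPAC.get(p, set())
    )


def edit_distance(a: str, b: str, k: int = -1) -> int:
    """Global (NW) edit distance; -1 if it exceeds k (when k >= 0)."""
    return edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def global_alignment(query: str, target: str) -> tuple[str, str]:
    """End-to-end alignment of query vs target as two gapped strings."""
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    return nice["query_aligned"], nice["target_aligned"]


@lru_cache(maxsize=1)
def affine_aligner():
    """Global affine-gap aligner (Biopython PairwiseAligner).

    A gap pair always costs more than the run of mismatches it could
    replace, so pure substitution variants never acquire spurious indels.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -2
    return aligner


def alignment_identity(a: str, b: str) -> float:
    """Fraction of identical columns over all global-alignment columns.

    Terminal gaps count as columns: this is the permissive end-to-end measure
    used for the 0.6 reference-classification threshold.
    """
    qa, ta = global_alignment(a, b)
    matches = sum(1 for x, y in zip(qa, ta) if x == y)
    return matches / len(qa)


def p_distance(a: str, b: str) -> float:
    """Uncorrected p-distance with pairwise deletion.

    Equal-length inputs are compared column-by-column; unequal lengths are
    globally aligned first with affine gaps, on a canonically ordered pair
    so the result is symmetric. Columns where either sequence has a gap or
    an ambiguous base are excluded from numerator and denominator.
    """
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        x, y = sorted((a, b))
        aln = affine_aligner().align(x, y)[0]
        a, b = str(aln[0]), str(aln[1])
    diff = comp = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in DNA and y in DNA:
            comp += 1
            if x != y:
                diff += 1
    if comp == 0:
        raise ValueError("no comparable (unambiguous, ungapped) sites")
    return diff / comp


def encode(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences to a (n, L) uint8 matrix; non-ACGT -> 255."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, base in enumerate(DNA):
        lut[ord(base)] = i
        lut[ord(base.lower())] = i
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return lut[arr].reshape(len(seqs), -1)


def random_coding_sequence(n_codons: int, code_id: int, rng: np.random.Generator) -> str:
    """Random in-frame sequence with no internal stops under ``code_id``."""
    stops = set(stop_codons(code_id))
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list(DNA), size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons)


def synonymous_third_position_options(seq: str, code_id: int) -> list[tuple[int, str]]:
    """(position, alt_base) pairs at third codon positions that are synonymous.

    Only full codons of ``seq`` (frame 0) are considered.
    """
    out = []
    for c in range(len(seq) // 3):
        codon = seq[3 * c : 3 * c + 3].upper()
        aa = translate(codon, code_id)
        for alt in DNA:
            if alt == codon[2]:
                continue
            mutant = codon[:2] + alt
            if translate(mutant, code_id) == aa and aa != "*":
                out.append((3 * c + 2, alt))
    return out


def nonstop_substitution_options(seq: str, code_id: int) -> list[tuple[int, str]]:
    """All (position, alt_base) substitutions that do not create a stop codon."""
    stops = set(stop_codons(code_id))
    out = []
    for pos in range(len(seq)):
        c = pos // 3
        codon = seq[3 * c : 3 * c + 3].upper()
        for alt in DNA:
            if alt == seq[pos].upper():
                continue
            if len(codon) == 3:
                mutant = list(codon)
                mutant[pos % 3] = alt
                if "".join(mutant) in stops:
                    continue
            out.append((pos, alt))
    return out
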