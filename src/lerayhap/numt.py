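"""Pseudogene (NUMT) screening of classified ASVs.

An authentic mitochondrial haplotype of the Leray COI window translates
cleanly in the reference frame; a nuclear copy evolves free of selection and
betrays itself through frameshifting indels, internal stop codons, or deep
divergence coupled with non-synonymous change. This module produces per-ASV
translation reports against the species reference, uncorrected p-distance
matrices, midpoint-rooted NJ trees with column-resampling bootstrap, and the
authentic / putative-NUMT / artifact / unresolved decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .seqs import affine_aligner, encode, p_distance, translate


@dataclass
class IndelEvent:
    ref_position: int
    length: int
    kind: str  # "insertion" | "deletion"

    @property
    def net_frame_effect(self) -> int:
        return (self.length if self.kind == "insertion" else -self.length) % 3


@dataclass
class TranslationReport:
    asv_id: str
    aligned_length: int
    indel_events: list[IndelEvent]
    frameshift: bool
    internal_stops: int
    stop_positions: list[int]  # codon indices in the ASV's own frame
    nonsynonymous_substitutions: int
    code_id: int


def align_translate(asv: str, ref: str, code_id: int, asv_id: str = "") -> TranslationReport:
    """Global alignment of an ASV to its in-frame reference plus translation QC.

    The frameshift flag is set as soon as any alignment prefix carries a net
    indel length not divisible by three — a downstream compensating indel
    does not rescue the frame. Stops are counted on the ASV's frame-0
    translation (amplicons share the reference's frame); non-synonymous
    substitutions are counted over codons whose three columns align gap-free
    while the cumulative frame offset is zero.
    """
    if not asv or not ref:
        raise ValueError("empty sequence")
    asv, ref = asv.upper(), ref.upper()
    aln = affine_aligner().align(ref, asv)[0]
    idx = aln.indices  # (2, cols): row 0 = ref positions, row 1 = asv positions; -1 = gap
    ref_idx, asv_idx = idx[0], idx[1]
    cols = idx.shape[1]

    events: list[IndelEvent] = []
    frameshift = False
    net = 0
    codon_cols: dict[int, list[int]] = {}
    c = 0
    while c < cols:
        if ref_idx[c] >= 0 and asv_idx[c] >= 0:
            codon_cols.setdefault(int(ref_idx[c]) // 3, []).append(int(asv_idx[c]))
            c += 1
        elif ref_idx[c] < 0:  # insertion in the ASV
            start = c
            while c < cols and ref_idx[c] < 0:
                c += 1
            length = c - start
            ref_pos = int(ref_idx[c]) if c < cols else len(ref)
            events.append(IndelEvent(ref_pos, length, "insertion"))
            net += length
            if net % 3:
                frameshift = True
        else:  # deletion in the ASV
            start = c
            while c < cols and asv_idx[c] < 0:
                c += 1
            length = c - start
            events.append(IndelEvent(int(ref_idx[start]), length, "deletion"))
            net -= length
            if net % 3:
                frameshift = True

    stop_positions = [
        i for i, aa in enumerate(translate(asv, code_id)[:-1]) if aa == "*"
    ]

    nonsyn = 0
    for cdn in range(len(ref) // 3):
        positions = codon_cols.get(cdn, [])
        # comparable codon: three gap-free columns, contiguous and in frame
        if len(positions) != 3:
            continue
        if positions != list(range(positions[0], positions[0] + 3)) or positions[0] % 3:
            continue
        ref_aa = translate(ref[3 * cdn : 3 * cdn + 3], code_id)
        asv_aa = translate(asv[positions[0] : positions[0] + 3], code_id)
        if asv_aa and ref_aa and asv_aa != ref_aa and asv_aa != "*":
            nonsyn += 1

    return TranslationReport(
        asv_id=asv_id,
        aligned_length=cols,
        indel_events=events,
        frameshift=frameshift,
        internal_stops=len(stop_positions),
        stop_positions=stop_positions,
        nonsynonymous_substitutions=nonsyn,
        code_id=code_id,
    )


def amino_acid_alignment(
    seqs: list[tuple[str, str]], ref_label: str, code_id: int, width: int = 60
) -> str:
    """Interleaved amino-acid alignment text against a reference row.

    Translates each sequence in frame 0 under ``code_id``; positions
    matching the reference are shown as '.', stops as '*', so lesions stand
    out at a glance. Sequences must share the reference's length (indel
    carriers are rendered from their own frame and will visibly diverge
    downstream of the lesion).
    """
    by_label = dict(seqs)
    if ref_label not in by_label:
        raise KeyError(f"reference {ref_label!r} not among sequences")
    ref_aa = translate(by_label[ref_label], code_id)
    rows = [(ref_label, ref_aa)]
    for label, seq in seqs:
        if label == ref_label:
            continue
        aa = translate(seq, code_id)
        shown = "".join(
            a if (i >= len(ref_aa) or a != ref_aa[i]) else "." for i, a in enumerate(aa)
        )
        rows.append((label, shown))
    name_w = max(len(label) for label, _ in rows) + 2
    blocks = []
    length = max(len(aa) for _, aa in rows)
    for start in range(0, length, width):
        blocks.append(
            "\n".join(
                f"{label:<{name_w}}{aa[start:start + width]}" for label, aa in rows
            )
        )
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# p-distance matrices and NJ trees


def p_distance_matrix(seqs: list[tuple[str, str]]) -> DistanceMatrix:
    """Uncorrected pairwise p-distances (pairwise deletion) as a DistanceMatrix.

    Equal-length sequences are compared column-wise (vectorized); mixed
    lengths fall back to per-pair global alignment. Values are exact;
    rounding to the 3 decimals of the report tables happens only at output.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = [name for name, _ in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    seq_strs = [s.upper() for _, s in seqs]
    n = len(seq_strs)
    mat = np.zeros((n, n))
    if len({len(s) for s in seq_strs}) == 1:
        X = encode(seq_strs)
        valid = X != 255
        for i in range(n):
            for j in range(i + 1, n):
                both = valid[i] & valid[j]
                comp = int(both.sum())
                if comp == 0:
                    raise ValueError(f"no comparable sites between {labels[i]} and {labels[j]}")
                mat[i, j] = mat[j, i] = int(((X[i] != X[j]) & both).sum()) / comp
    else:
        for i in range(n):
            for j in range(i + 1, n):
                mat[i, j] = mat[j, i] = p_distance(seq_strs[i], seq_strs[j])
    return DistanceMatrix(mat, ids=labels)


def distance_table(dm: DistanceMatrix, decimals: int = 3):
    """Lower-triangle report layout, rounded to ``decimals``."""
    import pandas as pd

    df = pd.DataFrame(np.round(dm.data, decimals), index=dm.ids, columns=dm.ids)
    return df.where(np.tril(np.ones(df.shape, dtype=bool), k=-1))


def nj_tree(dm: DistanceMatrix, midpoint: bool = True):
    """Neighbor-joining tree (negative branch lengths clamped to zero)."""
    if len(dm.ids) < 3:
        raise ValueError("need at least three taxa")
    if not np.isfinite(dm.data).all():
        raise ValueError("non-finite distances")
    tree = nj(dm, neg_as_zero=True)
    if midpoint:
        tree = tree.root_at_midpoint()
    return tree


def _bipartitions(tree) -> set[frozenset]:
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            parts.add(min(side, leaves - side, key=sorted))
    return parts


def bootstrap_support(
    seqs: list[tuple[str, str]], n_replicates: int = 1000, seed: int = 0
) -> tuple[object, dict[frozenset, float]]:
    """Column-resampling bootstrap over an aligned nucleotide matrix.

    Returns the NJ tree on the full matrix (midpoint-rooted) and percent
    support for each internal bipartition of that tree.
    """
    if len({len(s) for _, s in seqs}) != 1:
        raise ValueError("bootstrap requires an aligned (equal-length) matrix")
    rng = np.random.default_rng(seed)
    labels = [name for name, _ in seqs]
    L = len(seqs[0][1])
    base_tree = nj_tree(p_distance_matrix(seqs), midpoint=True)
    target = _bipartitions(base_tree)
    hits = {part: 0 for part in target}
    mats = [s.upper() for _, s in seqs]
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        resampled = [
            (name, "".join(seq[c] for c in cols)) for name, seq in zip(labels, mats)
        ]
        try:
            rep_parts = _bipartitions(nj_tree(p_distance_matrix(resampled), midpoint=False))
        except ValueError:
            continue
        for part in target & rep_parts:
            hits[part] += 1
    support = {part: 100.0 * k / n_replicates for part, k in hits.items()}
    return base_tree, support


# ---------------------------------------------------------------------------
# the decision rule


@dataclass
class NumtRule:
    divergence_threshold: float = 0.026
    authentic_band: float = 0.01
    artifact_read_floor: int = 5

    def __post_init__(self) -> None:
        if self.authentic_band >= self.divergence_threshold:
            raise ValueError("authentic_band must be below divergence_threshold")


@dataclass
class StatusDecision:
    asv_id: str
    status: str  # authentic | putative_numt | artifact | unresolved
    evidence: list[str] = field(default_factory=list)


def classify_status(
    report: TranslationReport,
    min_ref_distance: float,
    total_reads: int,
    within_d1_of_more_abundant: bool,
    rule: NumtRule | None = None,
) -> StatusDecision:
    """Authentic / putative-NUMT / artifact / unresolved decision for one ASV.

    Lesions (frameshift or internal stop) are decisive NUMT evidence; clean
    sequences inside the authentic band are authentic; deep divergence with
    non-synonymous change is NUMT evidence; tiny read support adjacent to an
    abundant sequence is an artifact; anything else stays unresolved —
    a lesion-free ASV between the bands is never silently authentic.
    """
    rule = rule or NumtRule()
    evidence: list[str] = []
    if report.frameshift:
        evidence.append("frameshifting indel")
    if report.internal_stops:
        evidence.append(f"{report.internal_stops} internal stop codon(s)")
    if evidence:
        return StatusDecision(report.asv_id, "putative_numt", evidence)
    if (
        min_ref_distance >= rule.divergence_threshold
        and report.nonsynonymous_substitutions >= 1
    ):
        return StatusDecision(
            report.asv_id,
            "putative_numt",
            [
                f"p-distance {min_ref_distance:.3f} >= {rule.divergence_threshold}",
                f"{report.nonsynonymous_substitutions} non-synonymous substitution(s)",
            ],
        )
    if min_ref_distance <= rule.authentic_band:
        return StatusDecision(
            report.asv_id,
            "authentic",
            [f"p-distance {min_ref_distance:.3f} within authentic band", "frame intact"],
        )
    if total_reads < rule.artifact_read_floor and within_d1_of_more_abundant:
        return StatusDecision(
            report.asv_id,
            "artifact",
            [f"{total_reads} reads < floor", "within d=1 of a more abundant sequence"],
        )
    return StatusDecision(
        report.asv_id,
        "unresolved",
        [f"p-distance {min_ref_distance:.3f} between bands, no lesion"],
    )


def screen_asvs(
    asvs,  # list[AsvRecord]
    assignments,  # list[Assignment]
    library,  # ReferenceLibrary
    rule: NumtRule | None = None,
) -> dict[str, StatusDecision]:
    """Run the full screen over classified ASVs.

    Each ASV is aligned/translated against its species' nearest reference
    (smallest p-distance); the artifact test uses edit distance 1 against
    more abundant ASVs and references.
    """
    from .seqs import edit_distance

    rule = rule or NumtRule()
    by_id = {a.asv_id: a for a in asvs}
    ranked = sorted(asvs, key=lambda a: -a.total_reads)
    decisions: dict[str, StatusDecision] = {}
    for assign in assignments:
        asv = by_id[assign.asv_id]
        refs = library.species_entries(assign.species_id)
        if not refs:
            raise ValueError(f"no references for species {assign.species_id}")
        dists = [(p_distance(asv.sequence, e.sequence), e) for e in refs]
        min_dist, nearest = min(dists, key=lambda t: t[0])
        report = align_translate(
            asv.sequence, nearest.sequence, nearest.genetic_code_id, asv_id=asv.asv_id
        )
        bigger = [
            r.sequence for r in ranked if r.total_reads > asv.total_reads
        ] + [e.sequence for e in library.entries]
        near_big = any(edit_distance(asv.sequence, s, k=1) >= 0 for s in bigger)
        decisions[asv.asv_id] = classify_status(
            report, min_dist, asv.total_reads, near_big, rule
        )
    return decisions
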