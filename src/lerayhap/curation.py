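"""Post-clustering curation in the LULU style.

A low-abundance "daughter" row that is highly similar to a more abundant
"parent", occurs (almost) only where the parent occurs, and is consistently
rarer than it, is treated as the parent's error shadow and merged into it.
Read totals are conserved: merged daughter counts are added to the parent's
cells.
"""

from __future__ import annotations

from dataclasses import dataclass

from .classify import AsvTable
from .seqs import p_distance


@dataclass
class CurationParams:
    minimum_match: float = 84.0            # percent similarity
    minimum_relative_cooccurrence: float = 0.95
    minimum_ratio: float = 1.0
    ratio_type: str = "min"                # "min" | "avg"

    def __post_init__(self) -> None:
        if not 0 < self.minimum_match <= 100:
            raise ValueError("minimum_match must be in (0, 100]")
        if not 0 < self.minimum_relative_cooccurrence <= 1:
            raise ValueError("cooccurrence must be in (0, 1]")
        if self.ratio_type not in ("min", "avg"):
            raise ValueError("ratio_type must be 'min' or 'avg'")


def build_match_list(
    seqs: dict[str, str], min_match: float = 84.0
) -> list[tuple[str, str, float]]:
    """All pairs at percent similarity = 100 x (1 - p-distance) >= min_match."""
    labels = sorted(seqs)
    out = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            sim = 100.0 * (1.0 - p_distance(seqs[a], seqs[b]))
            if sim >= min_match:
                out.append((a, b, sim))
    return out


@dataclass
class MergeDecision:
    daughter: str
    parent: str  # final parent after resolving chains
    similarity: float
    cooccurrence: float
    ratio: float


def curate(
    table: AsvTable,
    matches: list[tuple[str, str, float]],
    params: CurationParams | None = None,
) -> tuple[AsvTable, dict[str, MergeDecision]]:
    """Merge daughters into co-occurring, similar, more abundant parents.

    Rows are visited in decreasing total abundance (ties by label); for each
    candidate daughter the accepted parent is the more abundant matching row
    maximizing the per-sample abundance ratio, subject to relative
    co-occurrence >= threshold and min/avg parent:daughter ratio >=
    minimum_ratio. Chains resolve to the final parent; the curated grand
    total equals the input grand total.
    """
    params = params or CurationParams()
    df = table.counts.copy()
    species = table.df[table.species_col]
    sim: dict[frozenset, float] = {}
    for a, b, s in matches:
        if s >= params.minimum_match:
            sim[frozenset((a, b))] = s

    totals = df.sum(axis=1)
    order = sorted(df.index, key=lambda r: (-totals[r], r))
    rank = {r: i for i, r in enumerate(order)}
    parent_of: dict[str, MergeDecision] = {}

    for daughter in order:
        d_counts = df.loc[daughter]
        d_samples = d_counts[d_counts > 0].index
        if len(d_samples) == 0:
            continue
        best: MergeDecision | None = None
        for parent in order:
            if rank[parent] >= rank[daughter] or totals[parent] <= totals[daughter]:
                continue
            s = sim.get(frozenset((daughter, parent)))
            if s is None:
                continue
            p_counts = df.loc[parent]
            shared = [smp for smp in d_samples if p_counts[smp] > 0]
            cooc = len(shared) / len(d_samples)
            if cooc < params.minimum_relative_cooccurrence:
                continue
            ratios = [p_counts[smp] / d_counts[smp] for smp in shared]
            ratio = min(ratios) if params.ratio_type == "min" else sum(ratios) / len(ratios)
            if ratio < params.minimum_ratio:
                continue
            if best is None or ratio > best.ratio:
                best = MergeDecision(daughter, parent, s, cooc, ratio)
        if best is not None:
            parent_of[daughter] = best

    def final_parent(label: str) -> str:
        seen = set()
        while label in parent_of and label not in seen:
            seen.add(label)
            label = parent_of[label].parent
        return label

    curated = df.copy()
    merge_map: dict[str, MergeDecision] = {}
    for daughter, dec in parent_of.items():
        fp = final_parent(daughter)
        merge_map[daughter] = MergeDecision(
            daughter, fp, dec.similarity, dec.cooccurrence, dec.ratio
        )
    for daughter, dec in sorted(merge_map.items()):
        curated.loc[dec.parent] += curated.loc[daughter]
        curated = curated.drop(index=daughter)

    out = curated.copy()
    out.insert(0, table.species_col, [species[r] for r in out.index])
    return AsvTable(out), merge_map
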