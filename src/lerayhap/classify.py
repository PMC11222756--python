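"""Reference classification, closed-reference d-chaining, and count tables.

ASVs are assigned to the species of their best globally-aligned reference
haplotype at a permissive identity threshold (default 0.6, computed over all
alignment columns including terminal gaps), then every ASV is chained onto
the reference/assigned seeds by single-linkage within edit distance d
(Swarm-style closed-reference clustering, default d = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .denoise import AsvRecord
from .seqs import alignment_identity, edit_distance, p_distance


@dataclass
class RefEntry:
    species_id: str
    haplotype_id: str
    sequence: str
    genetic_code_id: int


@dataclass
class ReferenceLibrary:
    entries: list[RefEntry]
    similarity_threshold: float = 0.6
    max_ref_p_distance: float = 0.25  # automated stand-in for manual NJ-tree exclusion

    def __post_init__(self) -> None:
        ids = [e.haplotype_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("haplotype_ids must be unique")

    def species_entries(self, species_id: str) -> list[RefEntry]:
        return [e for e in self.entries if e.species_id == species_id]


@dataclass
class Assignment:
    asv_id: str
    species_id: str
    best_reference: str
    identity: float
    ref_p_distance: float


def classify_asvs(
    asvs: list[AsvRecord], library: ReferenceLibrary
) -> tuple[list[Assignment], list[tuple[str, str]]]:
    """Best-reference assignment at the identity threshold.

    Ties in identity go to the first reference in library order. ASVs whose
    nearest reference exceeds ``max_ref_p_distance`` are dropped as
    non-target (the reproducible surrogate for manual tree inspection).
    Returns assignments and an (asv_id, reason) unassigned list.
    """
    if not library.entries:
        raise ValueError("empty reference library")
    assignments, unassigned = [], []
    for asv in asvs:
        best: tuple[float, RefEntry] | None = None
        for entry in library.entries:
            ident = alignment_identity(asv.sequence, entry.sequence)
            if best is None or ident > best[0]:
                best = (ident, entry)
        ident, entry = best
        if ident < library.similarity_threshold:
            unassigned.append((asv.asv_id, f"best identity {ident:.3f} < threshold"))
            continue
        ref_p = min(
            p_distance(asv.sequence, e.sequence)
            for e in library.species_entries(entry.species_id)
        )
        if ref_p > library.max_ref_p_distance:
            unassigned.append((asv.asv_id, f"nearest-reference p-distance {ref_p:.3f} too high"))
            continue
        assignments.append(Assignment(asv.asv_id, entry.species_id, entry.haplotype_id, ident, ref_p))
    return assignments, unassigned


@dataclass
class ClusterParams:
    d: int = 1

    def __post_init__(self) -> None:
        if self.d < 0 or int(self.d) != self.d:
            raise ValueError("d must be a non-negative integer")


def closed_ref_cluster(
    asvs: list[AsvRecord],
    seeds: list[tuple[str, str]],
    params: ClusterParams | None = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Single-linkage chaining of ASVs onto fixed seeds within edit distance d.

    ASVs are processed in decreasing abundance (ties by sequence); passes are
    repeated to a fixpoint so membership equals the brute-force
    single-linkage closure over {seed} ∪ {joined members}. An ASV within d of
    several clusters joins the one with the smallest distance, ties to the
    earliest seed. Returns {seed_label: [asv_id, ...]} and unclustered ids.
    """
    params = params or ClusterParams()
    if not seeds:
        raise ValueError("seeds must be nonempty")
    order = sorted(asvs, key=lambda a: (-a.total_reads, a.sequence))
    clusters: dict[str, list[str]] = {label: [] for label, _ in seeds}
    member_seqs: dict[str, list[str]] = {label: [seq] for label, seq in seeds}
    pending = list(order)
    changed = True
    while changed and pending:
        changed = False
        still = []
        for asv in pending:
            best: tuple[int, int] | None = None  # (distance, seed_index)
            for idx, (label, _) in enumerate(seeds):
                for seq in member_seqs[label]:
                    dist = edit_distance(asv.sequence, seq, k=params.d)
                    if dist >= 0 and (best is None or (dist, idx) < best):
                        best = (dist, idx)
            if best is None:
                still.append(asv)
            else:
                label = seeds[best[1]][0]
                clusters[label].append(asv.asv_id)
                member_seqs[label].append(asv.sequence)
                changed = True
        pending = still
    return clusters, [a.asv_id for a in pending]


@dataclass
class AsvTable:
    """Wide ASV/haplotype x sample count table with species row labels."""

    df: pd.DataFrame  # index: row label; columns: "species" + sample columns
    species_col: str = "species"

    @property
    def samples(self) -> list[str]:
        return [c for c in self.df.columns if c != self.species_col]

    @property
    def counts(self) -> pd.DataFrame:
        return self.df[self.samples]

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def species_subtotals(self) -> pd.Series:
        return self.counts.sum(axis=1).groupby(self.df[self.species_col]).sum()


def build_table(
    memberships: dict[str, list[str]],
    counts: dict[str, dict[str, int]],
    species_of: dict[str, str],
    sample_order: list[str] | None = None,
) -> AsvTable:
    """Aggregate member-ASV counts under their cluster seeds.

    ``memberships`` maps seed label -> member asv ids (the seed's own counts,
    if any, are looked up under its label); ``counts`` maps asv id -> per-
    sample counts. Rows are sorted by species then decreasing abundance.
    """
    known = set(counts)
    for seed, members in memberships.items():
        for m in members:
            if m not in known:
                raise KeyError(f"membership references uncounted ASV {m!r}")
    samples = sample_order or sorted({s for c in counts.values() for s in c})
    rows = {}
    for seed, members in memberships.items():
        acc = {s: 0 for s in samples}
        # a seed that is itself a counted ASV appears once, not twice
        for m in dict.fromkeys(list(members) + [seed]):
            for s, n in counts.get(m, {}).items():
                acc[s] = acc.get(s, 0) + n
        rows[seed] = acc
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    df = df.reindex(columns=samples, fill_value=0)
    df.insert(0, "species", [species_of.get(r, "unassigned") for r in df.index])
    df["_tot"] = df[samples].sum(axis=1)
    df = df.sort_values(["species", "_tot"], ascending=[True, False]).drop(columns="_tot")
    return AsvTable(df)


def summarize_species(table: AsvTable) -> pd.DataFrame:
    """Per-species read totals, row counts, and shares of the grand total."""
    counts = table.counts.sum(axis=1)
    grouped = counts.groupby(table.df[table.species_col])
    out = pd.DataFrame(
        {
            "reads": grouped.sum().astype(int),
            "n_asvs": grouped.size(),
        }
    )
    share = 100 * out["reads"] / table.grand_total
    out["share_pct"] = share.round(1)
    out["share_pct_int"] = share.round(0).astype(int)
    return out.sort_values("reads", ascending=False)
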