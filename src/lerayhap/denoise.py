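"""Dereplication and Begum-style replicate-consistency filtering.

PCR/sequencing artifacts rarely recur across independent PCR replicates of
the same sample, so an ASV's counts in a sample are kept only when the ASV
shows up in enough replicates at sufficient copy number. No error model is
involved: replicate consistency is the entire mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ConfigError(ValueError):
    pass


@dataclass
class AsvRecord:
    asv_id: str
    sequence: str
    counts: dict[tuple[str, int], int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    def per_sample(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (sample, _rep), n in self.counts.items():
            out[sample] = out.get(sample, 0) + n
        return out


@dataclass
class FilterParams:
    min_copies_per_replicate: int = 2
    min_replicates_present: int = 2
    length_range: tuple[int, int] = (300, 320)
    discard_ambiguous: bool = True


def dereplicate(merged: dict[tuple[str, int], list[str]]) -> list[AsvRecord]:
    """Collapse identical sequences across all (sample, replicate) units.

    Output order is input-order independent: records are sorted by decreasing
    total count, ties broken by sequence; ids are assigned in that order.
    """
    by_seq: dict[str, dict[tuple[str, int], int]] = {}
    for unit, seqs in merged.items():
        for seq in seqs:
            cell = by_seq.setdefault(seq.upper(), {})
            cell[unit] = cell.get(unit, 0) + 1
    ranked = sorted(by_seq.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return [
        AsvRecord(f"asv{i + 1}", seq, counts) for i, (seq, counts) in enumerate(ranked)
    ]


def replicate_filter(
    asvs: list[AsvRecord], params: FilterParams | None = None
) -> tuple[list[AsvRecord], list[tuple[str, str]]]:
    """Apply replicate-consistency, length, and ambiguity filters.

    Within each sample an ASV survives iff it reaches
    ``min_copies_per_replicate`` in at least ``min_replicates_present``
    replicates; surviving samples keep all their replicate counts. Returns
    the surviving records (re-sorted) and a (asv_id, reason) removal log.
    No sequence or count is ever created or increased.
    """
    params = params or FilterParams()
    lo, hi = params.length_range
    kept: list[AsvRecord] = []
    log: list[tuple[str, str]] = []
    for asv in asvs:
        if not lo <= len(asv.sequence) <= hi:
            log.append((asv.asv_id, f"length {len(asv.sequence)} outside [{lo}, {hi}]"))
            continue
        if params.discard_ambiguous and set(asv.sequence) - set("ACGT"):
            log.append((asv.asv_id, "ambiguous bases"))
            continue
        samples = {s for s, _ in asv.counts}
        surviving: dict[tuple[str, int], int] = {}
        for sample in samples:
            reps_ok = sum(
                1
                for (s, _r), n in asv.counts.items()
                if s == sample and n >= params.min_copies_per_replicate
            )
            if reps_ok >= params.min_replicates_present:
                surviving.update(
                    {k: n for k, n in asv.counts.items() if k[0] == sample}
                )
        if surviving:
            kept.append(AsvRecord(asv.asv_id, asv.sequence, surviving))
        else:
            log.append((asv.asv_id, "failed replicate-consistency in every sample"))
    kept.sort(key=lambda a: (-a.total_reads, a.sequence))
    return kept, log
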