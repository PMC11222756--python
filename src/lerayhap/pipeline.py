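"""End-to-end orchestration: mock-community branch and popset branch.

Stage outputs are pure functions of (inputs, config, seed); every run
directory carries the config hash and a summary JSON so reruns with the same
config and seed reproduce identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger("lerayhap")

from . import classify, curation, demux, denoise, numt, popgen, simulate
from .io import write_fasta

_KNOWN_KEYS = {
    "seed", "out_dir", "mock", "popset", "log_level",
}


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "lerayhap_run"
    mock: dict = field(default_factory=dict)
    popset: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "seed": self.seed,
                "out_dir": self.out_dir,
                "mock": self.mock,
                "popset": self.popset,
                "log_level": self.log_level,
            },
            sort_keys=True,
        )

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out (kept below 2^31)."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class MockBranchResult:
    """In-memory products of the mock branch, stage by stage."""

    community: simulate.MockCommunity
    demux_result: demux.DemuxResult
    merged: dict[tuple[str, int], list[str]]
    n_merge_rejected: int
    raw_asvs: list[denoise.AsvRecord]
    kept_asvs: list[denoise.AsvRecord]
    removal_log: list[tuple[str, str]]
    library: classify.ReferenceLibrary
    assignments: list[classify.Assignment]
    unassigned: list[tuple[str, str]]
    memberships: dict[str, list[str]]
    unclustered: list[str]
    table: classify.AsvTable
    decisions: dict[str, numt.StatusDecision]
    curated: classify.AsvTable
    merge_map: dict

    def status_by_template(self) -> dict[str, str]:
        """Screen status per ground-truth template surviving the filters."""
        seq2label = {v: k for k, v in self.community.templates.items()}
        out = {}
        for asv in self.kept_asvs:
            label = seq2label.get(asv.sequence)
            if label is not None:
                dec = self.decisions.get(asv.asv_id)
                out[label] = dec.status if dec else "unclassified"
        return out


def run_mock_stages(community: simulate.MockCommunity) -> MockBranchResult:
    """demux -> merge -> denoise -> classify -> cluster -> screen -> curate."""
    scheme = demux.TagScheme.from_plans(community.plans)
    dres = demux.demultiplex(community.reads, scheme)
    assert dres.n_assigned + len(dres.jump) + len(dres.unassigned) == len(community.reads)
    log.info(
        "demux: %d pairs in = %d assigned + %d tag-jump + %d unassigned",
        len(community.reads), dres.n_assigned, len(dres.jump), len(dres.unassigned),
    )

    merged_by_unit: dict[tuple[str, int], list[str]] = {}
    n_rejected = 0
    for unit, pairs in dres.assigned.items():
        merged, rej = demux.merge_pairs(pairs)
        n_rejected += rej
        merged_by_unit[demux.split_unit(unit)] = [seq for _, seq, _ in merged]
    n_merged = sum(len(v) for v in merged_by_unit.values())
    assert n_merged + n_rejected == dres.n_assigned
    log.info("merge: %d assigned = %d merged + %d rejected", dres.n_assigned, n_merged, n_rejected)

    raw = denoise.dereplicate(merged_by_unit)
    kept, removal_log = denoise.replicate_filter(raw)
    log.info(
        "denoise: %d merged reads -> %d ASVs -> %d after replicate filter (%d reads kept)",
        n_merged, len(raw), len(kept), sum(a.total_reads for a in kept),
    )

    library = classify.ReferenceLibrary(
        entries=[classify.RefEntry(*e) for e in community.reference_entries]
    )
    assignments, unassigned = classify.classify_asvs(kept, library)
    by_id = {a.asv_id: a for a in kept}
    ref_seqs = {e.sequence for e in library.entries}
    seeds = [(e.haplotype_id, e.sequence) for e in library.entries] + [
        (a.asv_id, by_id[a.asv_id].sequence)
        for a in assignments
        if by_id[a.asv_id].sequence not in ref_seqs
    ]
    memberships, unclustered = classify.closed_ref_cluster(kept, seeds)

    counts = {a.asv_id: a.per_sample() for a in kept}
    species_of = {e.haplotype_id: e.species_id for e in library.entries}
    species_of.update({a.asv_id: a.species_id for a in assignments})
    sample_order = [p.sample_id for p in community.plans]
    table = classify.build_table(memberships, counts, species_of, sample_order)

    log.info(
        "classify: %d ASVs -> %d assigned, %d unassigned; table total %d reads",
        len(kept), len(assignments), len(unassigned), table.grand_total,
    )
    decisions = numt.screen_asvs(kept, assignments, library)

    matches = curation.build_match_list(dict(seeds))
    curated, merge_map = curation.curate(table, matches)
    assert curated.grand_total == table.grand_total
    log.info(
        "curate: %d rows -> %d OTUs, grand total conserved at %d",
        len(table.df), len(curated.df), curated.grand_total,
    )

    return MockBranchResult(
        community=community,
        demux_result=dres,
        merged=merged_by_unit,
        n_merge_rejected=n_rejected,
        raw_asvs=raw,
        kept_asvs=kept,
        removal_log=removal_log,
        library=library,
        assignments=assignments,
        unassigned=unassigned,
        memberships=memberships,
        unclustered=unclustered,
        table=table,
        decisions=decisions,
        curated=curated,
        merge_map=merge_map,
    )


def run_mock_branch(config: RunConfig, out: Path) -> dict:
    """Mock branch with file outputs and a stage-boundary count summary."""
    mock_cfg = dict(config.mock)
    community = simulate.default_mock_community(
        seed=stage_seed(config.seed, "simulate"),
        depth=int(mock_cfg.get("depth", 1500)),
        per_base_error_rate=float(mock_cfg.get("per_base_error_rate", 0.001)),
        tag_jump_rate=float(mock_cfg.get("tag_jump_rate", 0.01)),
        chimera_rate=float(mock_cfg.get("chimera_rate", 0.005)),
    )
    simulate.write_paired_fastq(community.reads, out / "reads_R1.fastq", out / "reads_R2.fastq")
    community.manifest.to_json(out / "truth_manifest.json")
    write_fasta(
        out / "references.fasta",
        [(f"{sp}|{hid}", seq) for sp, hid, seq, _ in community.reference_entries],
    )

    res = run_mock_stages(community)
    res.demux_result.report().to_csv(out / "demux_report.tsv", sep="\t", index=False)
    res.table.df.to_csv(out / "asv_table.tsv", sep="\t")
    classify.summarize_species(res.table).to_csv(out / "species_summary.tsv", sep="\t")
    with open(out / "numt_status.tsv", "w") as fh:
        fh.write("asv_id\tstatus\tevidence\n")
        for d in res.decisions.values():
            fh.write(f"{d.asv_id}\t{d.status}\t{'; '.join(d.evidence)}\n")
    res.curated.df.to_csv(out / "curated_table.tsv", sep="\t")

    return {
        "n_read_pairs": len(community.reads),
        "n_assigned": res.demux_result.n_assigned,
        "n_tag_jump": len(res.demux_result.jump),
        "n_unassigned": len(res.demux_result.unassigned),
        "n_merge_rejected": res.n_merge_rejected,
        "n_asvs_raw": len(res.raw_asvs),
        "n_asvs_filtered": len(res.kept_asvs),
        "n_assigned_asvs": len(res.assignments),
        "n_unclustered": len(res.unclustered),
        "grand_total": res.table.grand_total,
        "curated_rows": int(len(res.curated.df)),
        "statuses": {
            s: sum(1 for d in res.decisions.values() if d.status == s)
            for s in ("authentic", "putative_numt", "artifact", "unresolved")
        },
    }


def run_popset_branch(config: RunConfig, out: Path) -> dict:
    """simulate popsets -> trim -> haplotypes -> SNPs -> clusters -> compare."""
    cfg = dict(config.popset)
    n_datasets = int(cfg.get("n_datasets", 8))
    n_pops = int(cfg.get("n_pops", 2))
    n_per_pop = int(cfg.get("n_per_pop", 20))
    n_fixed = int(cfg.get("n_fixed_diffs", 10))
    seq_len = int(cfg.get("seq_len", 650))
    gens = int(cfg.get("n_generations", 100_000))
    burn = int(cfg.get("burn_in", 200))

    pairs, n_seqs, lengths = [], [], []
    rows = []
    for d in range(n_datasets):
        placement = "outside" if d % 2 else "inside"
        data = simulate.generate_popset(
            n_pops, n_per_pop, n_fixed, seq_len,
            seed=stage_seed(config.seed, f"popset{d}"),
            fixed_placement=placement,
        )
        window = popgen.LerayWindow()
        trimmed, _ = popgen.locate_and_trim(data.sequences, data.gene, data.code_id, window)
        ks = {}
        for name, seqs in (("original", data.sequences), ("trimmed", trimmed)):
            snps = popgen.extract_snp_sites(seqs)
            post = popgen.estimate_clusters(
                snps,
                popgen.ClusterRunParams(
                    n_generations=gens, burn_in=burn,
                    seed=stage_seed(config.seed, f"mcmc{d}{name}"),
                ),
            )
            ks[name] = post
        pairs.append((f"set{d}", ks["original"].modal_k, ks["trimmed"].modal_k))
        n_seqs.append(len(data.sequences))
        lengths.append(seq_len)
        rows.append(
            {
                "dataset": f"set{d}", "placement": placement,
                "true_k": data.true_k, "true_k_trimmed": data.true_k_trimmed,
                "k_original": ks["original"].modal_k,
                "k_trimmed": ks["trimmed"].modal_k,
                "density_original": round(ks["original"].modal_density, 3),
                "density_trimmed": round(ks["trimmed"].modal_density, 3),
                "haps_original": popgen.count_haplotypes(data.sequences).n_haplotypes,
                "haps_trimmed": popgen.count_haplotypes(trimmed).n_haplotypes,
            }
        )
    report = popgen.compare_fragments(pairs, n_sequences=n_seqs, lengths=lengths)
    import pandas as pd

    pd.DataFrame(rows).to_csv(out / "popset_clusters.tsv", sep="\t", index=False)
    return {
        "n_datasets": n_datasets,
        "mean_k_original": report.mean_original,
        "mean_k_trimmed": report.mean_trimmed,
        "wilcoxon_w": report.w_statistic,
        "wilcoxon_p": report.p_value,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run both branches and write a summary JSON into the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.setLevel(config.log_level.upper())
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        log.removeHandler(h)
        h.close()
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    (out / "config.yaml").write_text(config.to_yaml())
    summary = {"config_hash": config.config_hash, "seed": config.seed}
    if config.mock.get("enabled", True):
        summary["mock"] = run_mock_branch(config, out)
    if config.popset.get("enabled", False):
        summary["popset"] = run_popset_branch(config, out)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
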