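"""Synthetic mock-community and population-dataset generator.

Everything downstream of wet lab is testable against this module: it emits
twin-tagged paired-end reads over 313-nt COI Leray amplicons (with PCR
replicates, tag jumps, chimeras and a negative control), NUMT-like templates
carrying engineered substitutions, deletions and stop codons, and
multi-population Folmer-length COI datasets for the fragment-trimming
comparison — each with a machine-readable truth manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .seqs import (
    DNA,
    has_internal_stop,
    nonstop_substitution_options,
    random_coding_sequence,
    revcomp,
    stop_codons,
    synonymous_third_position_options,
    translate,
)

LERAY_LEN = 313

# Degenerate Leray primer pair (mlCOIintF / jgHCO2198; inosines rendered as N).
PRIMER_F = "GGWACWGGWTGAACWGTWTAYCCYCC"
PRIMER_R = "TANACYTCNGGRTGNCCRAARAAYCA"

# Default nt coordinates of the Leray window inside a full-length COI gene:
# amino-acid position 130 (1-based) -> nt offset (130-1)*3 = 387, 313 nt long.
GENE_WINDOW = (387, 700)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class SpeciesConfig:
    species_id: str
    reference_seq: str
    genetic_code_id: int
    n_haplotypes: int
    n_variable_sites: int
    leray_offset: int = 0

    def __post_init__(self) -> None:
        self.reference_seq = self.reference_seq.upper()
        if len(self.reference_seq) < self.leray_offset + LERAY_LEN:
            raise ConfigError("reference shorter than leray_offset + 313")
        if self.leray_offset % 3:
            raise ConfigError("leray_offset must be codon-aligned (multiple of 3)")
        if has_internal_stop(self.reference_seq, self.genetic_code_id):
            raise ConfigError("reference translates with an internal stop")
        if self.n_variable_sites < self.n_haplotypes - 1:
            raise ConfigError(
                f"{self.n_haplotypes} haplotypes need >= {self.n_haplotypes - 1} variable sites"
            )

    @property
    def leray_window(self) -> str:
        return self.reference_seq[self.leray_offset : self.leray_offset + LERAY_LEN]


@dataclass
class NumtSpec:
    source_haplotype: str
    target_divergence: float
    deletion_lengths: list[int] = field(default_factory=list)
    force_stop_codon: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.target_divergence <= 0.5:
            raise ConfigError("target_divergence must be in [0, 0.5]")
        if sum(self.deletion_lengths) >= LERAY_LEN:
            raise ConfigError("deletions longer than the amplicon")


@dataclass
class SamplePlan:
    """One sample: a twin 7-nt tag per PCR replicate and a template mixture."""

    sample_id: str
    tags: tuple[str, ...]
    members: dict[str, float]
    total_read_pairs: int
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if any(len(t) != 7 for t in self.tags):
            raise ConfigError("tags must be 7 nt")
        if not self.is_negative_control:
            total = sum(self.members.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"abundances of {self.sample_id} sum to {total}, not 1")

    @property
    def n_pcr_replicates(self) -> int:
        return len(self.tags)

    # twin-tag scheme: the same tag sits on both primers of a replicate
    @property
    def forward_tag(self) -> str:
        return self.tags[0]

    reverse_tag = forward_tag


@dataclass
class ReadSimParams:
    read_length: int = 250
    per_base_error_rate: float = 0.001
    tag_jump_rate: float = 0.0
    chimera_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.per_base_error_rate, self.tag_jump_rate, self.chimera_rate):
            if not 0 <= r < 1:
                raise ConfigError("rates must be in [0, 1)")
        if self.read_length < 160:
            raise ConfigError("reads shorter than 160 nt cannot overlap on a 313-nt amplicon")


# ---------------------------------------------------------------------------
# truth manifest


@dataclass
class ReadTruth:
    sample_id: str
    replicate: int
    template: str
    tag_jump: bool = False
    chimera: bool = False


@dataclass
class TemplateTruth:
    species_id: str
    klass: str  # "haplotype" | "numt"
    lesions: dict = field(default_factory=dict)


@dataclass
class TruthManifest:
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    templates: dict[str, TemplateTruth] = field(default_factory=dict)
    sample_expected: dict[str, dict[str, float]] = field(default_factory=dict)
    popset: dict = field(default_factory=dict)

    def template_counts(self) -> dict[tuple[str, int], dict[str, int]]:
        """Non-chimeric, non-jumped template counts per (sample, replicate)."""
        out: dict[tuple[str, int], dict[str, int]] = {}
        for truth in self.reads.values():
            if truth.chimera or truth.tag_jump:
                continue
            cell = out.setdefault((truth.sample_id, truth.replicate), {})
            cell[truth.template] = cell.get(truth.template, 0) + 1
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        raw = json.loads(Path(path).read_text())
        return cls(
            reads={k: ReadTruth(**v) for k, v in raw["reads"].items()},
            templates={k: TemplateTruth(**v) for k, v in raw["templates"].items()},
            sample_expected=raw["sample_expected"],
            popset=raw["popset"],
        )


@dataclass
class ReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str


# ---------------------------------------------------------------------------
# haplotype and NUMT generation


def generate_haplotype_set(cfg: SpeciesConfig, seed: int) -> list[tuple[str, str]]:
    """Distinct Leray-window haplotypes segregating at exactly the planned sites.

    Substitutions are placed preferentially at synonymous third codon
    positions so that every haplotype stays in frame with no internal stops;
    haplotype 1 is the reference window itself.
    """
    rng = np.random.default_rng(seed)
    window = cfg.leray_window
    labels = [f"{cfg.species_id}_hap{i + 1}" for i in range(cfg.n_haplotypes)]
    if cfg.n_haplotypes == 1 and cfg.n_variable_sites == 0:
        return [(labels[0], window)]

    options = synonymous_third_position_options(window, cfg.genetic_code_id)
    rng.shuffle(options)
    # one option per position, synonymous first, then any frame-safe fallback
    chosen: dict[int, str] = {}
    for pos, alt in options:
        chosen.setdefault(pos, alt)
    if len(chosen) < cfg.n_variable_sites:
        fallback = nonstop_substitution_options(window, cfg.genetic_code_id)
        rng.shuffle(fallback)
        for pos, alt in fallback:
            chosen.setdefault(pos, alt)
    if len(chosen) < cfg.n_variable_sites:
        raise ConfigError("not enough frame-safe substitution sites")

    sites = sorted(rng.choice(sorted(chosen), size=cfg.n_variable_sites, replace=False))
    haps = [window]
    # partition sites round-robin across the non-reference haplotypes: every
    # site segregates and every haplotype differs from all others
    for h in range(1, cfg.n_haplotypes):
        seq = list(window)
        for s in sites[h - 1 :: cfg.n_haplotypes - 1]:
            seq[s] = chosen[s]
        haps.append("".join(seq))
    for h in haps:
        assert not has_internal_stop(h, cfg.genetic_code_id)
    return list(zip(labels, haps))


@dataclass
class NumtRecord:
    label: str
    sequence: str
    substitution_positions: list[int]
    deletions: list[tuple[int, int]]  # (position, length) on the substituted sequence
    forced_stop: bool


def generate_numt(source: str, spec: NumtSpec, code_id: int, seed: int) -> NumtRecord:
    """Engineer a NUMT-like copy: exact substitution load, then deletions.

    The substitution component realizes a p-distance of exactly
    round(d * 313) / 313 against the source; substitutions fall uniformly (a
    NUMT evolves free of coding constraint). ``force_stop_codon`` spends part
    of the substitution budget converting one internal codon to a stop.
    """
    source = source.upper()
    if len(source) != LERAY_LEN:
        raise ConfigError("NUMT source must be a 313-nt Leray window")
    rng = np.random.default_rng(seed)
    n_sub = round(spec.target_divergence * LERAY_LEN)
    seq = list(source)
    sub_positions: list[int] = []

    if spec.force_stop_codon:
        stops = stop_codons(code_id)
        best: tuple[int, int, str] | None = None  # (n_changes, codon_index, stop)
        for c in range(1, LERAY_LEN // 3 - 1):
            codon = source[3 * c : 3 * c + 3]
            for stop in stops:
                k = sum(1 for a, b in zip(codon, stop) if a != b)
                if 0 < k <= n_sub and (best is None or k < best[0]):
                    best = (k, c, stop)
        if best is None:
            raise ConfigError("substitution budget too small to force a stop codon")
        _, c, stop = best
        for j in range(3):
            if source[3 * c + j] != stop[j]:
                seq[3 * c + j] = stop[j]
                sub_positions.append(3 * c + j)
        protected = {3 * c, 3 * c + 1, 3 * c + 2}
    else:
        protected = set()

    free = [p for p in range(LERAY_LEN) if p not in protected and p not in set(sub_positions)]
    extra = rng.choice(free, size=n_sub - len(sub_positions), replace=False)
    for p in sorted(int(x) for x in extra):
        seq[p] = rng.choice([b for b in DNA if b != seq[p]])
        sub_positions.append(p)
    sub_positions.sort()

    deletions: list[tuple[int, int]] = []
    for length in spec.deletion_lengths:
        if length >= len(seq):
            raise ConfigError("deletion longer than remaining sequence")
        pos = int(rng.integers(3, len(seq) - length - 3))
        del seq[pos : pos + length]
        deletions.append((pos, length))

    out = "".join(seq)
    if spec.force_stop_codon and not has_internal_stop(out, code_id):
        raise ConfigError("deletions disrupted the forced stop codon; place stops without deletions")
    return NumtRecord(
        label=spec.label or f"numt_{spec.source_haplotype}",
        sequence=out,
        substitution_positions=sub_positions,
        deletions=deletions,
        forced_stop=spec.force_stop_codon,
    )


# ---------------------------------------------------------------------------
# read simulation


def _resolve_primer(primer: str, rng: np.random.Generator) -> str:
    from .seqs import IUPAC

    return "".join(b if b in DNA else rng.choice(sorted(IUPAC[b])) for b in primer)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, str]:
    """Apply per-base substitution errors; errored bases get quality Q10."""
    qual = ["I"] * len(seq)
    if rate > 0:
        hits = np.flatnonzero(rng.random(len(seq)) < rate)
        seq_l = list(seq)
        for p in hits:
            seq_l[p] = rng.choice([b for b in DNA if b != seq_l[p]])
            qual[p] = "+"
        seq = "".join(seq_l)
    return seq, "".join(qual)


def simulate_reads(
    plans: list[SamplePlan],
    templates: dict[str, str],
    params: ReadSimParams,
) -> tuple[list[ReadPair], TruthManifest]:
    """Emit twin-tagged paired-end reads for every plan plus a truth manifest.

    Read layout: R1 = tag + forward primer + amplicon (5'->3'), R2 = tag +
    reverse primer + reverse-complemented amplicon, both clipped to
    ``read_length``. Tag jumps replace one tag of a pair with another
    sample's tag; chimeras join two templates at a single breakpoint.
    """
    all_tags = [t for plan in plans for t in plan.tags]
    if len(set(all_tags)) != len(all_tags):
        raise ConfigError("tags must be unique across samples and replicates")
    for plan in plans:
        for label in plan.members:
            if label not in templates:
                raise ConfigError(f"unknown template {label!r} in plan {plan.sample_id}")

    rng = np.random.default_rng(params.rng_seed)
    labels = sorted(templates)
    reads: list[ReadPair] = []
    manifest = TruthManifest(
        templates={},
        sample_expected={p.sample_id: dict(p.members) for p in plans},
    )
    counter = 0
    for plan in plans:
        member_labels = sorted(plan.members) if plan.members else labels
        probs = (
            np.array([plan.members[m] for m in member_labels])
            if plan.members
            else np.full(len(labels), 1 / len(labels))
        )
        per_rep = np.full(plan.n_pcr_replicates, plan.total_read_pairs // plan.n_pcr_replicates)
        per_rep[: plan.total_read_pairs % plan.n_pcr_replicates] += 1
        for rep, n_pairs in enumerate(per_rep, start=1):
            tag = plan.tags[rep - 1]
            for _ in range(int(n_pairs)):
                label = member_labels[rng.choice(len(member_labels), p=probs)]
                amplicon = templates[label]
                chimera = params.chimera_rate > 0 and rng.random() < params.chimera_rate
                if chimera:
                    other = labels[rng.integers(len(labels))]
                    bp = int(rng.integers(50, LERAY_LEN - 50))
                    amplicon = amplicon[:bp] + templates[other][bp:]
                    truth_label = f"chimera:{label}+{other}"
                else:
                    truth_label = label

                tag1 = tag2 = tag
                jumped = params.tag_jump_rate > 0 and rng.random() < params.tag_jump_rate
                if jumped:
                    foreign = [t for t in all_tags if t != tag]
                    stray = foreign[rng.integers(len(foreign))]
                    if rng.random() < 0.5:
                        tag1 = stray
                    else:
                        tag2 = stray

                fwd = tag1 + _resolve_primer(PRIMER_F, rng) + amplicon
                rev = tag2 + _resolve_primer(PRIMER_R, rng) + revcomp(amplicon)
                r1, q1 = _mutate(fwd[: params.read_length], params.per_base_error_rate, rng)
                r2, q2 = _mutate(rev[: params.read_length], params.per_base_error_rate, rng)
                read_id = f"r{counter:07d}"
                counter += 1
                reads.append(ReadPair(read_id, r1, q1, r2, q2))
                manifest.reads[read_id] = ReadTruth(
                    sample_id=plan.sample_id,
                    replicate=rep,
                    template=truth_label,
                    tag_jump=jumped,
                    chimera=chimera,
                )
    return reads, manifest


def write_paired_fastq(reads: list[ReadPair], r1_path, r2_path) -> None:
    from .io import write_fastq

    write_fastq(r1_path, ((r.read_id, r.r1_seq, r.r1_qual) for r in reads))
    write_fastq(r2_path, ((r.read_id, r.r2_seq, r.r2_qual) for r in reads))


def generate_tags(n: int, seed: int) -> list[str]:
    """Distinct 7-nt sample tags (mutual Hamming distance >= 2)."""
    rng = np.random.default_rng(seed)
    tags: list[str] = []
    while len(tags) < n:
        t = "".join(rng.choice(list(DNA), size=7))
        if all(sum(a != b for a, b in zip(t, u)) >= 2 for u in tags):
            tags.append(t)
    return tags


# ---------------------------------------------------------------------------
# multi-population COI datasets (fragment-trimming comparison)


@dataclass
class PopsetData:
    sequences: list[tuple[str, str]]
    pop_of: dict[str, int]
    true_k: int
    true_k_trimmed: int
    gene: str
    code_id: int
    window: tuple[int, int]
    fixed_positions: dict[int, tuple[int, str]]  # gene pos -> (pop, alt base)


def generate_popset(
    n_pops: int,
    n_per_pop: int,
    n_fixed_diffs: int,
    seq_len: int,
    seed: int,
    *,
    code_id: int = 5,
    fixed_placement: str = "any",  # "any" | "inside" | "outside" the Leray window
    private_rate: float = 0.5,
    window: tuple[int, int] = GENE_WINDOW,
) -> PopsetData:
    """Populations separated by fixed synonymous differences plus private singletons.

    ``fixed_placement='outside'`` puts every fixed difference outside the
    Leray window, so the trimmed dataset carries no population structure
    (true trimmed K = 1) — the construction behind the fragment-reduction
    comparison.
    """
    if seq_len < LERAY_LEN:
        raise ConfigError("seq_len must cover the 313-nt Leray window")
    if n_fixed_diffs > seq_len:
        raise ConfigError("more fixed differences than sites")
    if n_pops > 1 and n_fixed_diffs < n_pops - 1:
        raise ConfigError("need at least one fixed difference per non-reference population")

    rng = np.random.default_rng(seed)
    gene = random_coding_sequence(516, code_id, rng)
    w0, w1 = window
    start = min(w0, max(0, w0 - (seq_len - LERAY_LEN) // 2))
    if start + seq_len < w1:
        start = w1 - seq_len
    start -= start % 3
    if start < 0 or start + seq_len > len(gene):
        raise ConfigError("seq_len does not fit in the reference gene")

    options = [
        (p, alt)
        for p, alt in synonymous_third_position_options(gene, code_id)
        if start <= p < start + seq_len
    ]
    if fixed_placement == "inside":
        options = [(p, a) for p, a in options if w0 <= p < w1]
    elif fixed_placement == "outside":
        options = [(p, a) for p, a in options if not w0 <= p < w1]
    by_pos: dict[int, str] = {}
    order = rng.permutation(len(options))
    for idx in order:
        p, a = options[idx]
        by_pos.setdefault(p, a)
    positions = sorted(by_pos)
    if n_pops > 1 and len(positions) < n_fixed_diffs:
        raise ConfigError("not enough synonymous sites for the requested fixed differences")

    fixed: dict[int, tuple[int, str]] = {}
    if n_pops > 1:
        sel = sorted(int(p) for p in rng.choice(positions, size=n_fixed_diffs, replace=False))
        for i, p in enumerate(sel):
            fixed[p] = (1 + i % (n_pops - 1), by_pos[p])

    private_pool = [p for p in positions if p not in fixed]
    sequences: list[tuple[str, str]] = []
    pop_of: dict[str, int] = {}
    for pop in range(n_pops):
        for ind in range(n_per_pop):
            seq = list(gene[start : start + seq_len])
            for p, (owner, alt) in fixed.items():
                if owner == pop:
                    seq[p - start] = alt
            for _ in range(rng.poisson(private_rate)):
                p = private_pool[rng.integers(len(private_pool))]
                seq[p - start] = by_pos[p]
            sid = f"pop{pop + 1}_ind{ind + 1}"
            sequences.append((sid, "".join(seq)))
            pop_of[sid] = pop + 1

    inside = [p for p in fixed if w0 <= p < w1]
    pops_inside = {fixed[p][0] for p in inside}
    true_k_trimmed = 1 + len(pops_inside) if n_pops > 1 else 1
    return PopsetData(
        sequences=sequences,
        pop_of=pop_of,
        true_k=n_pops,
        true_k_trimmed=min(true_k_trimmed, n_pops),
        gene=gene,
        code_id=code_id,
        window=window,
        fixed_positions=fixed,
    )


# ---------------------------------------------------------------------------
# the default mock-community scenario


@dataclass
class MockCommunity:
    species: list[SpeciesConfig]
    haplotypes: dict[str, str]
    numts: dict[str, NumtRecord]
    plans: list[SamplePlan]
    templates: dict[str, str]
    reads: list[ReadPair]
    manifest: TruthManifest
    params: ReadSimParams

    @property
    def reference_entries(self) -> list[tuple[str, str, str, int]]:
        """(species_id, haplotype_id, sequence, code_id) for the local library."""
        out = []
        for cfg in self.species:
            for label, seq in self.haplotypes.items():
                if label.startswith(cfg.species_id + "_hap"):
                    out.append((cfg.species_id, label, seq, cfg.genetic_code_id))
        return out


def default_mock_community(
    seed: int,
    depth: int = 1500,
    per_base_error_rate: float = 0.001,
    tag_jump_rate: float = 0.01,
    chimera_rate: float = 0.005,
) -> MockCommunity:
    """The study-like scenario: two fish and one shrimp in two mock tanks.

    Three species (vertebrate-mito fish with 3 and 2 haplotypes, an
    invertebrate-mito shrimp with 2 haplotypes), per-haplotype individual
    samples, two community tanks, a negative control receiving ~0.1% of the
    mean sample depth, and six NUMT templates: three with 1-nt deletions (one
    with an additional 2-nt frameshifting deletion), two with internal stop
    codons, and one lesion-free divergent copy.
    """
    rng = np.random.default_rng(seed)
    mk = lambda: random_coding_sequence(105, 2, rng)  # noqa: E731
    species = [
        SpeciesConfig("Hoct", mk(), 2, 3, 3),
        SpeciesConfig("Pdyb", mk(), 2, 2, 1),
        SpeciesConfig("Plat", random_coding_sequence(105, 5, rng), 5, 2, 1),
    ]
    haplotypes: dict[str, str] = {}
    for i, cfg in enumerate(species):
        haplotypes.update(generate_haplotype_set(cfg, seed + 11 * (i + 1)))

    numt_specs = [
        ("Hoct_hap1", NumtSpec("Hoct_hap1", 0.100, [1], False, "numtHO1"), 2),
        ("Hoct_hap2", NumtSpec("Hoct_hap2", 0.106, [1, 2], False, "numtHO2"), 2),
        ("Hoct_hap1", NumtSpec("Hoct_hap1", 0.113, [1], False, "numtHO3"), 2),
        ("Plat_hap1", NumtSpec("Plat_hap1", 0.042, [], True, "numtPL1"), 5),
        ("Plat_hap2", NumtSpec("Plat_hap2", 0.058, [], True, "numtPL2"), 5),
        ("Plat_hap1", NumtSpec("Plat_hap1", 0.121, [], False, "numtPL3"), 5),
    ]
    numts = {
        spec.label: generate_numt(haplotypes[src], spec, code, seed + 101 + i)
        for i, (src, spec, code) in enumerate(numt_specs)
    }
    templates = dict(haplotypes)
    templates.update({k: v.sequence for k, v in numts.items()})

    def mix(main: str, extras: dict[str, float]) -> dict[str, float]:
        rest = 1.0 - sum(extras.values())
        return {main: rest, **extras}

    sample_members = {
        "HO-1": mix("Hoct_hap1", {"numtHO1": 0.015, "numtHO3": 0.012}),
        "HO-2": mix("Hoct_hap2", {"numtHO2": 0.012}),
        "HO-3": {"Hoct_hap3": 1.0},
        "PD-1": {"Pdyb_hap1": 1.0},
        "PD-2": {"Pdyb_hap2": 1.0},
        "PL-1": mix("Plat_hap1", {"numtPL1": 0.012, "numtPL3": 0.012}),
        "PL-2": mix("Plat_hap2", {"numtPL2": 0.012}),
        "mockA": {
            "Hoct_hap1": 0.30, "Hoct_hap2": 0.25, "Pdyb_hap1": 0.20,
            "Plat_hap1": 0.10, "Plat_hap2": 0.08, "numtHO1": 0.03,
            "numtPL1": 0.02, "numtPL3": 0.02,
        },
        "mockB": {"Hoct_hap3": 0.45, "Pdyb_hap2": 0.35, "Plat_hap1": 0.20},
    }
    n_units = (len(sample_members) + 1) * 3
    tags = generate_tags(n_units, seed + 7)
    plans = []
    for i, (sid, members) in enumerate(sample_members.items()):
        plans.append(SamplePlan(sid, tuple(tags[3 * i : 3 * i + 3]), members, depth))
    plans.append(
        SamplePlan(
            "NEG", tuple(tags[-3:]), {}, max(2, round(0.001 * depth)),
            is_negative_control=True,
        )
    )

    params = ReadSimParams(
        per_base_error_rate=per_base_error_rate,
        tag_jump_rate=tag_jump_rate,
        chimera_rate=chimera_rate,
        rng_seed=seed + 1,
    )
    reads, manifest = simulate_reads(plans, templates, params)
    for cfg in species:
        for label in haplotypes:
            if label.startswith(cfg.species_id + "_hap"):
                manifest.templates[label] = TemplateTruth(cfg.species_id, "haplotype")
    for src, spec, code in numt_specs:
        rec = numts[spec.label]
        manifest.templates[spec.label] = TemplateTruth(
            src.split("_")[0],
            "numt",
            lesions={
                "deletions": [list(d) for d in rec.deletions],  # JSON-stable form
                "forced_stop": rec.forced_stop,
                "n_substitutions": len(rec.substitution_positions),
            },
        )
    return MockCommunity(
        species=species,
        haplotypes=haplotypes,
        numts=numts,
        plans=plans,
        templates=templates,
        reads=reads,
        manifest=manifest,
        params=params,
    )
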