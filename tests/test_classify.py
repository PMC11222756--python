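"""Reference classification, d=1 chaining, and count-table arithmetic."""

import numpy as np
import pytest

from lerayhap import examples
from lerayhap.classify import (
    AsvTable,
    ClusterParams,
    RefEntry,
    ReferenceLibrary,
    build_table,
    classify_asvs,
    closed_ref_cluster,
    summarize_species,
)
from lerayhap.denoise import AsvRecord
from lerayhap.seqs import edit_distance, random_coding_sequence


@pytest.fixture(scope="module")
def library():
    rng = np.random.default_rng(10)
    ref_a = random_coding_sequence(105, 2, rng)[:313]
    ref_b = random_coding_sequence(105, 5, rng)[:313]
    return ReferenceLibrary(
        entries=[RefEntry("fish", "fish_hap1", ref_a, 2), RefEntry("shrimp", "shrimp_hap1", ref_b, 5)]
    )


def _record(seq, n=10, asv_id="q1"):
    return AsvRecord(asv_id, seq, {("s", 1): n})


class TestClassify:
    def test_exact_match_full_identity(self, library):
        ref = library.entries[0].sequence
        assigns, unassigned = classify_asvs([_record(ref)], library)
        assert not unassigned
        assert assigns[0].species_id == "fish"
        assert assigns[0].identity == 1.0

    def test_divergent_but_homologous_assigned(self, library):
        ref = library.entries[0].sequence
        rng = np.random.default_rng(1)
        positions = rng.choice(313, size=38, replace=False)  # p ~ 0.121
        seq = list(ref)
        for p in positions:
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        assigns, _ = classify_asvs([_record("".join(seq))], library)
        assert assigns and assigns[0].species_id == "fish"
        # the optimal global alignment can only improve on positional identity
        assert 1 - 38 / 313 <= assigns[0].identity < 1.0
        assert assigns[0].identity >= 0.6

    def test_random_sequence_unassigned(self, library):
        rng = np.random.default_rng(2)
        junk = "".join(rng.choice(list("ACGT"), size=313))
        assigns, unassigned = classify_asvs([_record(junk)], library)
        assert not assigns and len(unassigned) == 1

    def test_input_order_invariance(self, library):
        ref = library.entries[0].sequence
        variants = [
            _record(ref[:i] + ("A" if ref[i] != "A" else "C") + ref[i + 1 :], asv_id=f"q{i}")
            for i in (5, 50, 200)
        ]
        fwd, _ = classify_asvs(variants, library)
        rev, _ = classify_asvs(variants[::-1], library)
        assert {a.asv_id: a.species_id for a in fwd} == {a.asv_id: a.species_id for a in rev}


class TestClosedRefCluster:
    def test_exact_match_joins_at_distance_zero(self):
        seed = "ACGT" * 78 + "A"
        clusters, rest = closed_ref_cluster([_record(seed)], [("seed", seed)])
        assert clusters["seed"] == ["q1"] and rest == []

    def test_beyond_d_unclustered(self):
        seed = "ACGT" * 78 + "A"
        far = "TT" + seed[2:]
        clusters, rest = closed_ref_cluster([_record(far)], [("seed", seed)], ClusterParams(d=1))
        assert rest == ["q1"]

    def test_chain_through_intermediate(self):
        seed = "ACGT" * 78 + "A"
        a = "T" + seed[1:]                 # 1 from seed
        b = "TG" + seed[2:]                # 1 from a, 2 from seed
        recs = [_record(a, n=100, asv_id="a"), _record(b, n=10, asv_id="b")]
        clusters, rest = closed_ref_cluster(recs, [("seed", seed)])
        assert clusters["seed"] == ["a", "b"] and rest == []

    def test_chain_independent_of_abundance_order(self):
        seed = "ACGT" * 78 + "A"
        a = "T" + seed[1:]
        b = "TG" + seed[2:]
        recs = [_record(a, n=10, asv_id="a"), _record(b, n=100, asv_id="b")]
        clusters, rest = closed_ref_cluster(recs, [("seed", seed)])
        assert set(clusters["seed"]) == {"a", "b"} and rest == []

    def test_d_zero_is_exact_matching(self):
        seed = "ACGT" * 78 + "A"
        near = "T" + seed[1:]
        clusters, rest = closed_ref_cluster(
            [_record(seed, asv_id="x"), _record(near, asv_id="y")],
            [("seed", seed)],
            ClusterParams(d=0),
        )
        assert clusters["seed"] == ["x"] and rest == ["y"]

    def test_matches_brute_force_single_linkage_closure(self):
        rng = np.random.default_rng(3)
        base = random_coding_sequence(105, 2, rng)[:313]
        seqs = []
        for i in range(50):
            s = list(base)
            for p in rng.choice(313, size=int(rng.integers(0, 4)), replace=False):
                s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
            seqs.append("".join(s))
        recs = [_record(s, n=int(rng.integers(1, 500)), asv_id=f"q{i}") for i, s in enumerate(seqs)]
        seeds = [("seed", base)]
        clusters, rest = closed_ref_cluster(recs, seeds, ClusterParams(d=1))
        # oracle: transitive closure from the seed over the d<=1 graph
        nodes = {"seed": base, **{r.asv_id: r.sequence for r in recs}}
        reached = {"seed"}
        frontier = ["seed"]
        while frontier:
            cur = frontier.pop()
            for nid, nseq in nodes.items():
                if nid not in reached and edit_distance(nodes[cur], nseq, k=1) >= 0:
                    reached.add(nid)
                    frontier.append(nid)
        assert set(clusters["seed"]) == reached - {"seed"}
        assert set(rest) == set(nodes) - reached


class TestTables:
    def test_worked_example_row_and_grand_totals(self):
        table = examples.example_asv_table()
        assert table.row_totals()["PD20-1 Hap-1"] == 23_139
        assert table.grand_total == 160_796
        subtotals = table.species_subtotals()
        assert int(subtotals.sum()) == table.grand_total

    def test_empty_membership_empty_table(self):
        table = build_table({}, {}, {})
        assert table.grand_total == 0 and len(table.df) == 0

    def test_synthetic_counts_match_manifest(self, clean_mock_run):
        """Error-free run: table cells equal the manifest's surviving counts."""
        run = clean_mock_run
        seeds = [(e.haplotype_id, e.sequence) for e in run.library.entries]
        seq_of = {a.asv_id: a.sequence for a in run.kept_asvs}
        extra = [
            (a.asv_id, seq_of[a.asv_id])
            for a in run.assignments
            if seq_of[a.asv_id] not in {s for _, s in seeds}
        ]
        memberships, _ = closed_ref_cluster(run.kept_asvs, seeds + extra)
        counts = {a.asv_id: a.per_sample() for a in run.kept_asvs}
        species_of = {e.haplotype_id: e.species_id for e in run.library.entries}
        species_of.update({a.asv_id: a.species_id for a in run.assignments})
        table = build_table(memberships, counts, species_of)
        total_kept = sum(a.total_reads for a in run.kept_asvs)
        assert table.grand_total == total_kept
        # oracle: per-template counts recomputed from the manifest with the
        # replicate-consistency rule applied by hand
        truth_cells = run.community.manifest.template_counts()
        expected: dict[str, dict[str, int]] = {}
        for (sample, rep), cell in truth_cells.items():
            for tmpl, cnt in cell.items():
                expected.setdefault(tmpl, {}).setdefault(sample, {})[rep] = cnt
        kept_by_seq = {a.sequence: a for a in run.kept_asvs}
        for lbl, seq in run.community.templates.items():
            asv = kept_by_seq.get(seq)
            per_sample_truth = {}
            for sample, reps in expected.get(lbl, {}).items():
                if sum(1 for c in reps.values() if c >= 2) >= 2:
                    per_sample_truth[sample] = sum(reps.values())
            if asv is None:
                assert per_sample_truth == {}
            else:
                assert asv.per_sample() == per_sample_truth

    def test_summary_reproduces_species_shares(self):
        summary = summarize_species(examples.example_asv_table())
        ho = summary.loc["H. octogrammus"]
        assert ho["reads"] == 110_628 and ho["n_asvs"] == 8 and ho["share_pct_int"] == 69
        pl = summary.loc["P. latirostris"]
        assert pl["reads"] == 6_845 and pl["n_asvs"] == 9 and pl["share_pct"] == 4.3
        assert summary.loc["P. dybowskii", "share_pct_int"] == 27

    def test_single_species_share_is_hundred(self):
        import pandas as pd

        df = pd.DataFrame({"species": ["x", "x"], "s1": [10, 5]}, index=["a", "b"])
        summary = summarize_species(AsvTable(df))
        assert summary.loc["x", "share_pct"] == 100.0
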