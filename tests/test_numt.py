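"""Translation reports, p-distance matrices, NJ trees, and the NUMT rule."""

import numpy as np
import pytest
from skbio import DistanceMatrix

from lerayhap.numt import (
    NumtRule,
    align_translate,
    bootstrap_support,
    classify_status,
    distance_table,
    nj_tree,
    p_distance_matrix,
)
from lerayhap.seqs import random_coding_sequence


@pytest.fixture(scope="module")
def ref():
    return random_coding_sequence(105, 5, np.random.default_rng(0))[:313]


class TestAlignTranslate:
    def test_identical_sequences_clean_report(self, ref):
        rep = align_translate(ref, ref, 5)
        assert not rep.frameshift
        assert rep.internal_stops == 0
        assert rep.nonsynonymous_substitutions == 0
        assert rep.indel_events == []

    def test_two_nt_deletion_is_frameshift(self, ref):
        rep = align_translate(ref[:100] + ref[102:], ref, 5)
        assert rep.frameshift
        assert rep.indel_events[0].length == 2

    def test_in_frame_deletion_is_not_frameshift(self, ref):
        rep = align_translate(ref[:99] + ref[102:], ref, 5)
        assert not rep.frameshift
        assert rep.indel_events[0].kind == "deletion"

    def test_engineered_internal_stop_detected(self, ref):
        mutant = ref[:150] + "TAG" + ref[153:]
        rep = align_translate(mutant, ref, 5)
        assert rep.internal_stops >= 1
        assert 50 in rep.stop_positions
        assert not rep.frameshift  # pure substitutions must not read as indels

    def test_nonsynonymous_substitution_counted(self, ref):
        # force a first-codon-position change: almost always non-synonymous
        pos = 150
        mutant = ref[:pos] + ("A" if ref[pos] != "A" else "G") + ref[pos + 1 :]
        rep = align_translate(mutant, ref, 5)
        from lerayhap.seqs import translate

        expected = int(translate(mutant, 5)[50] != translate(ref, 5)[50])
        assert rep.nonsynonymous_substitutions == expected

    def test_empty_sequence_rejected(self, ref):
        with pytest.raises(ValueError):
            align_translate("", ref, 5)


class TestPDistanceMatrix:
    def test_single_site_difference_rounds_to_0_003(self, ref):
        other = ref[:10] + ("A" if ref[10] != "A" else "G") + ref[11:]
        dm = p_distance_matrix([("hap1", ref), ("hap2", other)])
        assert round(dm[0, 1], 3) == 0.003

    def test_identical_sequences_zero(self, ref):
        dm = p_distance_matrix([("a", ref), ("b", ref)])
        assert dm[0, 1] == 0.0

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            L = int(rng.integers(50, 400))
            a = "".join(rng.choice(list("ACGT"), size=L))
            b = "".join(rng.choice(list("ACGT"), size=L))
            dm = p_distance_matrix([("a", a), ("b", b)])
            brute = sum(x != y for x, y in zip(a, b)) / L
            assert dm[0, 1] == pytest.approx(brute)

    def test_ambiguous_columns_pairwise_deleted(self):
        a = "ACGTN" * 20
        b = "ACGAA" * 20
        dm = p_distance_matrix([("a", a), ("b", b)])
        assert dm[0, 1] == pytest.approx(20 / 80)  # N columns excluded

    def test_fewer_than_two_sequences_rejected(self, ref):
        with pytest.raises(ValueError):
            p_distance_matrix([("a", ref)])

    def test_report_layout_rounds_to_three_decimals(self, ref):
        other = ref[:10] + ("A" if ref[10] != "A" else "G") + ref[11:]
        df = distance_table(p_distance_matrix([("a", ref), ("b", other)]))
        assert df.loc["b", "a"] == 0.003
        assert np.isnan(df.loc["a", "b"])


class TestNJTree:
    def test_three_taxon_branch_lengths_closed_form(self):
        dm = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]], ["a", "b", "c"])
        tree = nj_tree(dm, midpoint=False)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_recovers_additive_six_taxon_topology(self):
        # generating tree: ((a:1,b:2):3,(c:1,d:1):2,(e:2,f:1):1)
        paths = {
            "a": {"ab": 1}, "b": {"ab": 2},
            "c": {"cd": 1}, "d": {"cd": 1},
            "e": {"ef": 2}, "f": {"ef": 1},
        }
        stem = {"ab": 3, "cd": 2, "ef": 1}
        taxa = list("abcdef")

        def dist(x, y):
            (gx, lx), (gy, ly) = next(iter(paths[x].items())), next(iter(paths[y].items()))
            if gx == gy:
                return lx + ly
            return lx + stem[gx] + stem[gy] + ly

        mat = [[0 if i == j else dist(x, y) for j, y in enumerate(taxa)] for i, x in enumerate(taxa)]
        tree = nj_tree(DistanceMatrix(mat, taxa), midpoint=False)
        clades = {
            frozenset(t.name for t in node.tips())
            for node in tree.non_tips(include_self=False)
        }
        for pair in ({"a", "b"}, {"c", "d"}, {"e", "f"}):
            assert any(c == pair or c == set(taxa) - pair for c in map(set, clades))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))

    def test_bootstrap_supports_clear_split(self, ref):
        rng = np.random.default_rng(1)
        seq2 = list(ref)
        for p in rng.choice(313, size=40, replace=False):
            seq2[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq2[p]]
        far = "".join(seq2)

        # light noise so tips are distinct
        def jiggle(s, k):
            s = list(s)
            s[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[k]]
            return "".join(s)

        seqs = [
            ("g1_0", ref), ("g1_1", jiggle(ref, 5)),
            ("g2_0", far), ("g2_1", jiggle(far, 7)),
        ]
        _, support = bootstrap_support(seqs, n_replicates=200, seed=4)
        split = [v for k, v in support.items() if set(k) in ({"g1_0", "g1_1"}, {"g2_0", "g2_1"})]
        assert split and min(split) >= 95.0


class TestAminoAcidAlignment:
    def test_stops_and_changes_visible_against_reference(self, ref):
        from lerayhap.numt import amino_acid_alignment

        mutant = ref[:150] + "TAG" + ref[153:]
        text = amino_acid_alignment(
            [("consensus", ref), ("asv1", mutant)], "consensus", 5
        )
        asv_lines = "".join(
            line.split(None, 1)[1]
            for line in text.splitlines()
            if line.startswith("asv1")
        )
        assert asv_lines.count("*") == 1          # the engineered stop
        assert set(asv_lines) - {"*"} == {"."}    # everything else matches


class TestStatusRule:
    def _report(self, ref, asv):
        return align_translate(asv, ref, 5, asv_id="q")

    def test_frameshift_is_putative_numt(self, ref):
        rep = self._report(ref, ref[:100] + ref[102:])
        dec = classify_status(rep, 0.05, 100, False)
        assert dec.status == "putative_numt"

    def test_internal_stop_is_putative_numt(self, ref):
        rep = self._report(ref, ref[:150] + "TAG" + ref[153:])
        dec = classify_status(rep, 0.003, 100, False)
        assert dec.status == "putative_numt"

    def test_reference_identical_is_authentic(self, ref):
        dec = classify_status(self._report(ref, ref), 0.0, 100, False)
        assert dec.status == "authentic"

    def test_lesion_free_between_bands_is_unresolved(self, ref):
        # ~0.019 divergence, synonymous-ish but no lesion: ambiguous zone
        dec = classify_status(self._report(ref, ref), 0.019, 100, False)
        assert dec.status == "unresolved"

    def test_low_support_neighbor_is_artifact(self, ref):
        dec = classify_status(self._report(ref, ref), 0.019, 3, True)
        assert dec.status == "artifact"

    def test_monotone_in_divergence(self, ref):
        rng = np.random.default_rng(5)
        seq = list(ref)
        for p in rng.choice(104, size=12, replace=False):
            pos = int(p) * 3
            seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        rep = self._report(ref, "".join(seq))
        ranks = {"authentic": 0, "unresolved": 1, "artifact": 1, "putative_numt": 2}
        statuses = [
            classify_status(rep, d, 100, False).status
            for d in (0.0, 0.005, 0.01, 0.02, 0.026, 0.05, 0.2)
        ]
        assert [ranks[s] for s in statuses] == sorted(ranks[s] for s in statuses)

    def test_band_ordering_enforced(self):
        with pytest.raises(ValueError):
            NumtRule(divergence_threshold=0.01, authentic_band=0.02)
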