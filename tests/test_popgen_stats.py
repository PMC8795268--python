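"""Alignment statistics: site classes, diagnostic sites, Nei diversity, coding effects, NJ.

The diversity statistics and the tree/assignment machinery are each checked
against independent brute-force oracles (pair enumeration, exhaustive codon
mutation, topology enumeration) rather than against the formulas they
implement.
"""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from skbio import TreeNode

from callihyb.errors import ConfigurationError, ValidationError
from callihyb.io_formats import SequenceRecord
from callihyb.popgen_stats import (
    DistanceMatrix,
    coding_effect,
    diagnostic_sites,
    haplotype_diversity,
    nj_tree,
    nucleotide_diversity,
    p_distance_matrix,
    site_classes,
)

BASES = "ACGT"


def _records(seqs, species=None):
    return [
        SequenceRecord(
            id=f"s{i}", sequence=s, species_label=None if species is None else species[i]
        )
        for i, s in enumerate(seqs)
    ]


def hd_oracle(counts):
    """Probability that two draws without replacement differ (pair enumeration)."""
    labels = [lab for lab, c in counts.items() for _ in range(c)]
    pairs = list(itertools.combinations(range(len(labels)), 2))
    return sum(labels[i] != labels[j] for i, j in pairs) / len(pairs)


def pi_oracle(seqs):
    """Mean per-site pairwise difference over all unordered sequence pairs."""
    pairs = list(itertools.combinations(seqs, 2))
    total = 0.0
    for a, b in pairs:
        total += sum(x != y for x, y in zip(a, b)) / len(a)
    return total / len(pairs)


class TestSiteClasses:
    def test_identical_sequences_have_no_polymorphism(self):
        anns = site_classes(_records(["ACGT", "ACGT"]))
        assert all(a.site_class == "monomorphic" for a in anns)

    def test_transition_vs_transversion(self):
        anns = site_classes(_records(["AAC", "GCC"]))
        assert anns[0].change_type == "transition"  # {A,G}
        assert anns[1].change_type == "transversion"  # {A,C}
        assert anns[2].site_class == "monomorphic"

    def test_multiallelic_flagged(self):
        anns = site_classes(_records(["A", "C", "G"]))
        assert anns[0].change_type == "multiallelic"

    def test_n_ignored_as_state(self):
        anns = site_classes(_records(["AN", "AN", "AA"]))
        assert [a.site_class for a in anns] == ["monomorphic", "monomorphic"]

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValidationError, match="ragged"):
            site_classes(_records(["ACG", "AC"]))


class TestDiagnosticSites:
    def test_brute_force_on_random_alignments(self):
        """Definition check: diagnostic iff fixed within the species and absent outside."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            n, length = 6, 30
            species = rng.choice(["x", "y", "z"], size=n).tolist()
            if len(set(species)) < 2:
                continue
            seqs = ["".join(rng.choice(list(BASES), size=length)) for _ in range(n)]
            recs = _records(seqs, species)
            got = diagnostic_sites(recs, {r.id: sp for r, sp in zip(recs, species)})
            for sp in set(species):
                expected = 0
                for col in range(length):
                    own = {s[col] for s, q in zip(seqs, species) if q == sp}
                    other = {s[col] for s, q in zip(seqs, species) if q != sp}
                    if len(own) == 1 and not (own & other):
                        expected += 1
                assert got.get(sp, 0) == expected

    def test_two_species_fixed_difference_counts_for_both(self):
        recs = _records(["AAAA", "AAAT"], species=["x", "y"])
        assert diagnostic_sites(recs, {"s0": "x", "s1": "y"}) == {"x": 1, "y": 1}

    def test_within_species_disagreement_not_diagnostic(self):
        recs = _records(["AAAA", "AAAT", "AAAC"], species=["x", "x", "y"])
        got = diagnostic_sites(recs, {"s0": "x", "s1": "x", "s2": "y"})
        assert got["x"] == 0

    def test_single_species_rejected(self):
        recs = _records(["AAAA", "AAAT"], species=["x", "x"])
        with pytest.raises(ValidationError):
            diagnostic_sites(recs, {"s0": "x", "s1": "x"})


class TestHaplotypeDiversity:
    def test_single_haplotype_is_zero(self):
        hd, se = haplotype_diversity({"h": 10})
        assert hd == 0.0

    def test_two_singletons_give_one(self):
        hd, _ = haplotype_diversity({"a": 1, "b": 1})
        assert hd == pytest.approx(1.0)

    def test_study_cohort_composition(self):
        """Hd for haplotype counts {8, 10, 11, 4} (n = 33)."""
        hd, se = haplotype_diversity({"HCa": 8, "HCj": 10, "HCp": 11, "HCp2": 4})
        assert hd == pytest.approx(0.7462, abs=1e-4)
        assert se > 0

    def test_oracle_on_random_compositions(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = rng.integers(1, 6)
            counts = {f"h{i}": int(rng.integers(1, 8)) for i in range(k)}
            if sum(counts.values()) < 2:
                continue
            hd, _ = haplotype_diversity(counts)
            assert hd == pytest.approx(hd_oracle(counts), abs=1e-12)

    def test_permutation_invariance_and_singleton_monotonicity(self):
        counts = {"a": 5, "b": 3, "c": 2}
        hd1, _ = haplotype_diversity(counts)
        hd2, _ = haplotype_diversity(dict(reversed(list(counts.items()))))
        assert hd1 == pytest.approx(hd2, abs=1e-15)
        hd3, _ = haplotype_diversity({**counts, "new": 1})
        assert hd3 > hd1


class TestNucleotideDiversity:
    def test_identical_sequences_give_zero(self):
        pi, _ = nucleotide_diversity(_records(["ACGT" * 5] * 3))
        assert pi == 0.0

    def test_hand_case_two_sequences(self):
        a = "A" * 100
        b = "C" + "A" * 99
        pi, _ = nucleotide_diversity(_records([a, b]))
        assert pi == pytest.approx(0.01, abs=1e-15)

    def test_oracle_on_random_datasets(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            length = int(rng.integers(5, 40))
            seqs = ["".join(rng.choice(list(BASES), size=length)) for _ in range(n)]
            pi, _ = nucleotide_diversity(_records(seqs))
            assert pi == pytest.approx(pi_oracle(seqs), abs=1e-12)

    def test_weighted_types_equal_expanded_instances(self):
        """π over (type, count) input equals π over the expanded sample."""
        a, b = "AACCGGTT", "AACCGGAA"
        recs = _records([a, b])
        pi_w, _ = nucleotide_diversity(recs, counts={"s0": 3, "s1": 2})
        expanded = _records([a, a, a, b, b])
        pi_e, _ = nucleotide_diversity(expanded)
        assert pi_w == pytest.approx(pi_e, abs=1e-12)


class TestCodingEffect:
    @pytest.mark.parametrize(
        "codon_a,codon_b,effect,aa",
        [
            ("CTA", "CCA", "nonsynonymous", "L1P"),
            ("GCC", "GCT", "synonymous", None),
            ("GTG", "ATG", "nonsynonymous", "V1M"),
        ],
    )
    def test_known_codon_changes(self, codon_a, codon_b, effect, aa):
        anns = coding_effect(_records([codon_a, codon_b]), reading_frame_offset=0)
        hits = [a for a in anns if a.coding_effect is not None]
        assert len(hits) == 1
        assert hits[0].coding_effect == effect
        assert hits[0].aa_change == aa

    def test_stop_codon_annotated_not_fatal(self):
        # TGG -> AGG: under the vertebrate mito code AGG is a stop
        anns = coding_effect(_records(["TGG", "AGG"]), reading_frame_offset=0)
        hit = next(a for a in anns if a.coding_effect is not None)
        assert hit.coding_effect == "nonsynonymous"
        assert "*" in hit.aa_change

    def test_exhaustive_single_base_mutations_against_translation_oracle(self):
        """All 9 single-base mutants of 20 random codons, vs direct translation."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            codon = "".join(rng.choice(list(BASES), size=3))
            for pos in range(3):
                for base in BASES:
                    if base == codon[pos]:
                        continue
                    mutant = codon[:pos] + base + codon[pos + 1 :]
                    anns = coding_effect(_records([codon, mutant]), reading_frame_offset=0)
                    hit = next(a for a in anns if a.coding_effect is not None)
                    aa1 = str(Seq(codon).translate(table=2))
                    aa2 = str(Seq(mutant).translate(table=2))
                    expected = "synonymous" if aa1 == aa2 else "nonsynonymous"
                    assert hit.coding_effect == expected, (codon, mutant)

    def test_frame_offset_respected(self):
        # same substitution lands in different codons depending on the frame
        recs = _records(["AATTGG", "AATTAG"])
        f0 = coding_effect(recs, reading_frame_offset=0)
        hit = next(a for a in f0 if a.coding_effect is not None)
        assert hit.position == 5

    def test_bad_frame_rejected(self):
        with pytest.raises(ConfigurationError):
            coding_effect(_records(["AAA", "AAT"]), reading_frame_offset=3)


class TestDistancesAndNj:
    def test_p_distance_matrix_properties(self, default_panel):
        dm = p_distance_matrix(list(default_panel.haplotypes))
        d = dm.distances
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0)
        assert (d[~np.eye(len(dm.labels), dtype=bool)] > 0).all()

    def test_three_taxa_closed_form_branch_lengths(self):
        dm = DistanceMatrix(
            labels=("A", "B", "C"),
            distances=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]),
        )
        tree = TreeNode.read([nj_tree(dm)])
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_nj_recovers_topology_on_random_additive_matrices(self):
        """Seeded battery of 4-taxon additive matrices with topology AB|CD."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            a, b, c, d, e = rng.uniform(0.01, 0.2, size=5)
            dm = DistanceMatrix(
                labels=("A", "B", "C", "D"),
                distances=np.array(
                    [
                        [0, a + b, a + e + c, a + e + d],
                        [a + b, 0, b + e + c, b + e + d],
                        [a + e + c, b + e + c, 0, c + d],
                        [a + e + d, b + e + d, c + d, 0],
                    ]
                ),
            )
            tree = TreeNode.read([nj_tree(dm)])
            splits = {
                frozenset(t.name for t in node.tips())
                for node in tree.non_tips()
            }
            assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_nj_on_ultrametric_matrix_matches_upgma_grouping(self):
        # closest pair (A,B) must be a cherry, as UPGMA would make it
        dm = DistanceMatrix(
            labels=("A", "B", "C", "D"),
            distances=np.array(
                [[0, 0.1, 0.4, 0.4], [0.1, 0, 0.4, 0.4], [0.4, 0.4, 0, 0.2], [0.4, 0.4, 0.2, 0]]
            ),
        )
        tree = TreeNode.read([nj_tree(dm)])
        splits = {frozenset(t.name for t in n.tips()) for n in tree.non_tips()}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_panel_penicillata_haplotypes_on_distinct_branches(self, default_panel):
        newick = nj_tree(p_distance_matrix(list(default_panel.haplotypes)))
        tree = TreeNode.read([newick])
        names = {t.name for t in tree.tips()}
        assert {"HCp", "HCp2", "HCp1"} <= names
        assert tree.find("HCp") is not tree.find("HCp2")

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(labels=("A", "B"), distances=np.array([[0, 0.1], [0.1, 0]]))
        with pytest.raises(ValidationError):
            nj_tree(dm)
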