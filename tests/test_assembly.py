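"""Placement, pairwise overlap rules, merging, and greedy LPV assembly."""

import numpy as np
import pytest

from helpers_oracle import Pep, naive_assemble, random_instance
from peptilap.assembly import (
    PlacedPeptide,
    assemble_lpvs,
    assert_fixpoint,
    merge_pair,
    overlap_length,
    place_observations,
    place_peptide,
)
from peptilap.model import ModKind, ModificationEvent, PeptideObservation, PrecursorProtein
from peptilap.ortho import OrthoGroup

PRECURSOR = "MKSIYFVAGLFVMLVQGDKRHSQGTFTSDYSKYLDSRRAQDFVQWLMNTKRNNAQDFVE"


def protein(accession="GCG", seq=PRECURSOR):
    return PrecursorProtein(accession=accession, sequence=seq)


def placed(start, end, acc="GCG", seq=PRECURSOR, n_block=False, c_block=False, support=(0,)):
    return PlacedPeptide(
        sequence=seq[start - 1 : end],
        accession=acc,
        start=start,
        end=end,
        n_term_blocked=n_block,
        c_term_blocked=c_block,
        support=frozenset(support),
    )


class TestPlacement:
    def test_glucagon_span(self, glucagon_like_precursor, toy_group):
        obs = PeptideObservation("HSQGTFTSDYSKYLDS", accessions=["GCG"])
        p = place_peptide(obs, toy_group, {"GCG": glucagon_like_precursor})
        assert p is not None
        assert (p.start, p.end) == (21, 36)
        assert glucagon_like_precursor.sequence[p.start - 1 : p.end] == obs.sequence

    def test_leftmost_occurrence_on_repeat(self):
        prot = protein(seq="AAQDFVEXXQDFVEYY")
        group = OrthoGroup("g", members=["GCG"])
        p = place_peptide(PeptideObservation("QDFVE"), group, {"GCG": prot})
        assert (p.start, p.end) == (3, 7)

    def test_absent_peptide_excluded_and_reported(self, toy_group, glucagon_like_precursor):
        obs = [PeptideObservation("WWWWWW", accessions=["GCG"])]
        placed_set, unplaced = place_observations(
            obs, [0], toy_group, {"GCG": glucagon_like_precursor}
        )
        assert placed_set == [] and unplaced == [0]

    def test_dedup_unions_support_and_modifications(self, toy_group, glucagon_like_precursor):
        obs = [
            PeptideObservation("HSQGTFTSDYSKYLDS", accessions=["GCG"], sample_id="a"),
            PeptideObservation(
                "HSQGTFTSDYSKYLDS",
                [ModificationEvent(ModKind.PHOSPHO, 7)],
                accessions=["GCG"],
                sample_id="b",
            ),
        ]
        placed_set, _ = place_observations(obs, [0, 1], toy_group,
                                           {"GCG": glucagon_like_precursor})
        (p,) = placed_set
        assert p.support == frozenset({0, 1})
        assert ("phospho", p.start + 6, True) in p.modifications


class TestOverlap:
    def test_partial_overlap_counts_shared_residues(self):
        assert overlap_length(placed(10, 15), placed(13, 17)) == 3

    def test_containment_counts_as_overlap(self):
        a, b = placed(10, 12), placed(8, 20)
        brute = len(set(range(10, 13)) & set(range(8, 21)))
        assert overlap_length(a, b) == brute == 3

    def test_amidated_cterm_blocks_extension(self):
        a = placed(10, 15, c_block=True)
        b = placed(13, 18)
        assert overlap_length(a, b) is None

    def test_single_residue_overlap_disallowed(self):
        assert overlap_length(placed(10, 15), placed(15, 20)) is None

    def test_different_members_disallowed(self):
        assert overlap_length(placed(10, 15), placed(10, 15, acc="OTHER")) is None

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            s1, s2 = rng.integers(1, 40, size=2)
            a = placed(int(s1), int(s1) + int(rng.integers(2, 15)),
                       n_block=bool(rng.random() < 0.3), c_block=bool(rng.random() < 0.3))
            b = placed(int(s2), int(s2) + int(rng.integers(2, 15)),
                       n_block=bool(rng.random() < 0.3), c_block=bool(rng.random() < 0.3))
            assert overlap_length(a, b) == overlap_length(b, a)


class TestMerge:
    def test_union_interval(self):
        m = merge_pair(placed(10, 15), placed(13, 17), {"GCG": protein()})
        assert (m.start, m.end) == (10, 17)
        assert m.sequence == PRECURSOR[9:17]

    def test_containment_merge_unions_support(self):
        m = merge_pair(placed(10, 12, support=(1,)), placed(8, 20, support=(2,)),
                       {"GCG": protein()})
        assert (m.start, m.end) == (8, 20)
        assert m.support == frozenset({1, 2})

    def test_shared_amidated_terminus_is_preserved(self):
        a = placed(8, 15, c_block=True)
        b = placed(10, 15, c_block=True)
        m = merge_pair(a, b, {"GCG": protein()})
        assert (m.start, m.end) == (8, 15)
        assert m.c_term_blocked

    def test_block_comes_from_the_terminus_provider(self):
        a = placed(10, 15, n_block=True)  # provides the N-terminus
        b = placed(12, 20, c_block=True)  # provides the C-terminus
        m = merge_pair(a, b, {"GCG": protein()})
        assert m.n_term_blocked and m.c_term_blocked


class TestAssembly:
    def test_ladder_collapses_to_single_lpv(self):
        prot = protein()
        ladder = [placed(20, 36, support=(i,)) for i in range(1)]
        ladder += [placed(20 + k, 36, support=(k,)) for k in range(1, 4)]
        lpvs = assemble_lpvs(ladder, {"GCG": prot})
        assert len(lpvs) == 1
        assert (lpvs[0].start, lpvs[0].end) == (20, 36)
        assert lpvs[0].support == frozenset({0, 1, 2, 3})

    def test_disjoint_members_stay_separate(self):
        prots = {"A": protein("A"), "B": protein("B")}
        lpvs = assemble_lpvs([placed(10, 20, acc="A"), placed(10, 20, acc="B")], prots)
        assert len(lpvs) == 2

    def test_fixpoint_and_support_conservation_random(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        prot = protein("T", seq)
        for _ in range(50):
            inst = random_instance(rng, 45, int(rng.integers(2, 13)))
            peps = [
                placed(p.start, p.end, acc="T", seq=seq, n_block=p.n_block,
                       c_block=p.c_block, support=tuple(p.support))
                for p in inst
            ]
            lpvs = assemble_lpvs(peps, {"T": prot})
            assert_fixpoint(lpvs)
            # support multiset conserved and partitioned
            all_support = sorted(i for l in lpvs for i in l.support)
            assert all_support == sorted(i for p in peps for i in p.support)
            # every input peptide is contained in its supporting LPV
            by_support = {i: l for l in lpvs for i in l.support}
            for p in peps:
                for i in p.support:
                    l = by_support[i]
                    assert l.start <= p.start and p.end <= l.end

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        prot = protein("T", seq)
        inst = random_instance(rng, 45, 10)
        peps = [
            placed(p.start, p.end, acc="T", seq=seq, n_block=p.n_block,
                   c_block=p.c_block, support=tuple(p.support))
            for p in inst
        ]
        ref = assemble_lpvs(peps, {"T": prot})
        for _ in range(5):
            order = rng.permutation(len(peps))
            again = assemble_lpvs([peps[i] for i in order], {"T": prot})
            assert again == ref

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        prot = protein("T", seq)
        for _ in range(100):
            inst = random_instance(rng, 45, int(rng.integers(2, 13)))
            peps = [
                placed(p.start, p.end, acc="T", seq=seq, n_block=p.n_block,
                       c_block=p.c_block, support=tuple(p.support))
                for p in inst
            ]
            mine = {
                (l.start, l.end, l.n_term_blocked, l.c_term_blocked, l.support)
                for l in assemble_lpvs(peps, {"T": prot})
            }
            assert mine == naive_assemble(inst)
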