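"""TE-library realignment and the support / match-length filters."""

from __future__ import annotations

import shutil

import numpy as np
import pytest

from retrofind.classify import (
    TEMatch,
    align_to_te_library,
    collect_candidate_sequences,
    filter_and_assign,
    load_te_library,
    reverse_complement,
)
from retrofind.cluster import CandidateCluster
from retrofind.evidence import EvidenceKind, InsertionEvidence
from retrofind.params import Parameters

HAS_MINIMAP2 = shutil.which("minimap2") is not None
ENGINES = ["edlib"] + (["minimap2"] if HAS_MINIMAP2 else [])


def ev(read_id="r1", position=100, seq="ACGT", kind=EvidenceKind.INSERTION_OP, hp=None):
    return InsertionEvidence(
        read_id=read_id,
        contig="chr1",
        position=position,
        kind=kind,
        sequence=seq,
        haplotype=hp,
    )


def match(read_id, te_name="Alu", aligned_len=300, query_len=300):
    return TEMatch(
        read_id=read_id,
        te_name=te_name,
        aligned_len=aligned_len,
        strand="+",
        query_len=query_len,
    )


class TestCollectCandidates:
    def test_one_candidate_per_member(self):
        cluster = CandidateCluster(
            "chr1", [ev("a", seq="AAAA"), ev("b", seq="CCCC"), ev("c", seq="GGGG")]
        )
        cands = collect_candidate_sequences(cluster)
        assert [(c.id, c.sequence) for c in cands] == [
            ("a", "AAAA"),
            ("b", "CCCC"),
            ("c", "GGGG"),
        ]

    def test_sequences_verbatim(self):
        seq = "ACGTN" * 10
        cluster = CandidateCluster("chr1", [ev("x", seq=seq)])
        assert collect_candidate_sequences(cluster)[0].sequence == seq

    def test_duplicate_read_ids_disambiguated(self):
        cluster = CandidateCluster(
            "chr1",
            [ev("dup", position=100, seq="AAAA"), ev("dup", position=105, seq="TTTT")],
        )
        cands = collect_candidate_sequences(cluster)
        assert [c.id for c in cands] == ["dup", "dup#2"]
        assert all(c.read_id == "dup" for c in cands)


class TestAlignToLibrary:
    @pytest.mark.parametrize("engine", ENGINES)
    def test_exact_copy_matches_its_entry(self, te_library_fasta, engine):
        library = load_te_library(te_library_fasta)
        hits = align_to_te_library(
            [("q1", library["Alu"])], te_library_fasta, engine=engine
        )
        assert len(hits) == 1
        assert hits[0].te_name == "Alu"
        assert hits[0].strand == "+"
        assert hits[0].aligned_len >= 0.9 * len(library["Alu"])

    @pytest.mark.parametrize("engine", ENGINES)
    def test_reverse_complement_matches_minus_strand(self, te_library_fasta, engine):
        library = load_te_library(te_library_fasta)
        hits = align_to_te_library(
            [("q1", reverse_complement(library["SVA"]))], te_library_fasta, engine=engine
        )
        assert len(hits) == 1
        assert (hits[0].te_name, hits[0].strand) == ("SVA", "-")

    def test_random_sequence_has_no_hit(self, te_library_fasta):
        rng = np.random.default_rng(42)
        decoy = "".join(rng.choice(list("ACGT"), 300))
        assert align_to_te_library([("q1", decoy)], te_library_fasta, engine="edlib") == []

    def test_empty_te_fasta_fatal(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            align_to_te_library([("q1", "ACGT" * 100)], str(empty))

    def test_empty_candidates(self, te_library_fasta):
        assert align_to_te_library([], te_library_fasta) == []

    @pytest.mark.skipif(not HAS_MINIMAP2, reason="minimap2 not on PATH")
    def test_batching_invariance(self, te_library_fasta):
        """Batched alignment equals per-candidate alignment."""
        library = load_te_library(te_library_fasta)
        cands = [(f"q{i}", library[name]) for i, name in enumerate(library)]
        together = align_to_te_library(cands, te_library_fasta, engine="minimap2")
        separate = [
            hit
            for cand in cands
            for hit in align_to_te_library([cand], te_library_fasta, engine="minimap2")
        ]
        assert sorted((m.read_id, m.te_name) for m in together) == sorted(
            (m.read_id, m.te_name) for m in separate
        )


class TestFilterAndAssign:
    def cluster(self, n=4):
        return CandidateCluster("chr1", [ev(f"r{i}") for i in range(n)])

    def test_four_valid_alu_passes(self):
        matches = [match(f"r{i}") for i in range(4)]
        params = Parameters(min_supporting_reads=3)
        family, supporting = filter_and_assign(self.cluster(), matches, params)
        assert family == "Alu"
        assert len(supporting) == 4

    def test_ten_percent_rule_invalidates_short_match(self):
        # 25 aligned of a 300 bp candidate: below the 10% floor of 30
        matches = [match(f"r{i}", aligned_len=25, query_len=300) for i in range(4)]
        params = Parameters(min_supporting_reads=3, match_fraction=0.10)
        assert filter_and_assign(self.cluster(), matches, params) is None

    def test_exactly_ten_percent_is_valid(self):
        matches = [match(f"r{i}", aligned_len=30, query_len=300) for i in range(3)]
        params = Parameters(min_supporting_reads=3, match_fraction=0.10)
        assert filter_and_assign(self.cluster(), matches, params) is not None

    def test_split_family_support_fails(self):
        matches = [match("r0"), match("r1")] + [
            match("r2", te_name="L1"),
            match("r3", te_name="L1"),
        ]
        params = Parameters(min_supporting_reads=3)
        assert filter_and_assign(self.cluster(), matches, params) is None

    def test_family_map_merges_subfamilies(self):
        matches = [
            match("r0", te_name="AluYa5"),
            match("r1", te_name="AluYb8"),
            match("r2", te_name="AluY"),
        ]
        params = Parameters(min_supporting_reads=3)
        fam_map = {"AluYa5": "Alu", "AluYb8": "Alu", "AluY": "Alu"}
        family, supporting = filter_and_assign(
            self.cluster(), matches, params, family_map=fam_map
        )
        assert family == "Alu"
        assert len(supporting) == 3

    def test_match_order_invariance(self):
        matches = [match(f"r{i}") for i in range(3)] + [match("r3", te_name="L1")]
        params = Parameters(min_supporting_reads=3)
        a = filter_and_assign(self.cluster(), matches, params)
        b = filter_and_assign(self.cluster(), list(reversed(matches)), params)
        assert a == b

    def test_limit_behaviour_everything_passes(self):
        """match_fraction -> 0 and support 1: any aligned candidate passes."""
        matches = [match("r0", aligned_len=1, query_len=10_000)]
        params = Parameters(min_supporting_reads=1, match_fraction=1e-9)
        assert filter_and_assign(self.cluster(1), matches, params) is not None

    @pytest.mark.parametrize("knob", ["support", "fraction"])
    def test_monotone_filtering(self, knob):
        """Raising min support or match fraction never adds passing clusters."""
        rng = np.random.default_rng(0)
        scenarios = []
        for _ in range(50):
            n = int(rng.integers(1, 8))
            scenarios.append(
                [
                    match(
                        f"r{i}",
                        te_name=str(rng.choice(["Alu", "L1"])),
                        aligned_len=int(rng.integers(1, 301)),
                        query_len=300,
                    )
                    for i in range(n)
                ]
            )
        if knob == "support":
            settings = [Parameters(min_supporting_reads=k) for k in (1, 2, 3, 5)]
        else:
            settings = [
                Parameters(min_supporting_reads=1, match_fraction=f)
                for f in (0.05, 0.1, 0.5, 1.0)
            ]
        counts = []
        for params in settings:
            passing = sum(
                filter_and_assign(self.cluster(8), matches, params) is not None
                for matches in scenarios
            )
            counts.append(passing)
        assert counts == sorted(counts, reverse=True)
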