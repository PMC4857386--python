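"""Domain invariants, modification grammar, and table/FASTA round trips."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from peptilap.assembly import LPV
from peptilap.io import (
    EvidenceFormatError,
    ModificationParseError,
    RejectedRow,
    format_modifications,
    lpv_table,
    lpvs_from_table,
    parse_modifications,
    parse_modified_sequence,
    read_evidence,
    read_fasta,
    write_evidence,
    write_fasta,
)
from peptilap.model import (
    InvariantError,
    ModKind,
    ModificationEvent,
    PeptideObservation,
    PrecursorProtein,
    count_unique,
)


class TestModificationInvariants:
    def test_terminal_kinds_must_sit_on_termini(self):
        ModificationEvent(ModKind.ACETYL_NTERM, 1).validate("SYSMEH")
        ModificationEvent(ModKind.AMIDE_CTERM, 6).validate("SYSMEH")
        with pytest.raises(InvariantError):
            ModificationEvent(ModKind.ACETYL_NTERM, 2).validate("SYSMEH")
        with pytest.raises(InvariantError):
            ModificationEvent(ModKind.AMIDE_CTERM, 3).validate("SYSMEH")

    def test_phospho_requires_sty(self):
        ModificationEvent(ModKind.PHOSPHO, 3).validate("SYSMEH")
        with pytest.raises(InvariantError):
            ModificationEvent(ModKind.PHOSPHO, 4).validate("SYSMEH")

    def test_short_and_dirty_sequences_rejected(self):
        with pytest.raises(InvariantError):
            PeptideObservation(sequence="SYSME").validate()
        with pytest.raises(InvariantError):
            PeptideObservation(sequence="SYSMEHX1").validate()


class TestModificationGrammar:
    def test_parse_canonical_tokens(self):
        mods = parse_modifications("phospho@3;amide_cterm@13")
        assert mods == [
            ModificationEvent(ModKind.PHOSPHO, 3),
            ModificationEvent(ModKind.AMIDE_CTERM, 13),
        ]

    def test_unlocalized_phospho_marker(self):
        (mod,) = parse_modifications("phospho@3?")
        assert mod.localized is False

    def test_unknown_token_is_an_error(self):
        with pytest.raises(ModificationParseError):
            parse_modifications("methyl@3")

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from([ModKind.PHOSPHO, ModKind.OXIDATION]),
                st.integers(1, 50),
                st.booleans(),
            ),
            max_size=6,
        )
    )
    def test_format_parse_round_trip(self, raw):
        mods = [
            ModificationEvent(kind, pos, localized if kind is ModKind.PHOSPHO else True)
            for kind, pos, localized in raw
        ]
        assert sorted(parse_modifications(format_modifications(mods))) == sorted(mods)

    def test_maxquant_modified_sequence(self):
        seq, mods = parse_modified_sequence("_(ac)SYS(ph)MEHFRWGKPV(am)_")
        assert seq == "SYSMEHFRWGKPV"
        assert ModificationEvent(ModKind.ACETYL_NTERM, 1) in mods
        assert ModificationEvent(ModKind.PHOSPHO, 3) in mods
        assert ModificationEvent(ModKind.AMIDE_CTERM, 13) in mods


class TestEvidenceReader:
    HEADER = "sequence\tmodifications\taccessions\tsample\tmsms_count\n"

    def test_phospho_amide_row(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        path.write_text(self.HEADER + "SYSMEHFRWGKPV\tphospho@3;amide_cterm@13\tPOMC\ts01\t4\n")
        (obs,) = read_evidence(path)
        assert obs.sequence == "SYSMEHFRWGKPV"
        assert len(obs.modifications) == 2
        assert obs.spectral_count == 4
        assert obs.is_phospho and obs.is_amidated

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        path.write_text(self.HEADER)
        assert read_evidence(path) == []

    def test_one_row_per_sample(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        rows = "".join(f"HSQGTFTSDYS\t\tGCG\ts{i}\t1\n" for i in range(3))
        path.write_text(self.HEADER + rows)
        obs = read_evidence(path)
        assert len(obs) == 3
        assert {o.sample_id for o in obs} == {"s0", "s1", "s2"}
        assert len({o.sequence for o in obs}) == 1

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        path.write_text("sequence\tmodifications\tsample\nAAAAAA\t\ts0\n")
        with pytest.raises(EvidenceFormatError, match="accessions"):
            read_evidence(path)

    def test_bad_modification_reports_row_number(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        path.write_text(self.HEADER + "HSQGTFTSDYS\tweird@2\tGCG\ts0\t1\n")
        with pytest.raises(ModificationParseError, match="row 2"):
            read_evidence(path)

    def test_short_rows_collected_not_dropped_silently(self, tmp_path):
        path = tmp_path / "evidence.tsv"
        path.write_text(self.HEADER + "HSQGT\t\tGCG\ts0\t1\nHSQGTFTSDYS\t\tGCG\ts0\t2\n")
        rejects: list[RejectedRow] = []
        obs = read_evidence(path, rejects=rejects)
        assert len(obs) == 1
        assert len(rejects) == 1 and rejects[0].sequence == "HSQGT"

    def test_order_independence(self, tmp_path):
        lines = [f"PEPTIDE{c}\t\tP1\ts{i % 2}\t{i + 1}\n" for i, c in enumerate("ACDEFG")]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.write_text(self.HEADER + "".join(lines))
        shuffled = lines[:]
        random.Random(0).shuffle(shuffled)
        b.write_text(self.HEADER + "".join(shuffled))
        key = lambda o: (o.sequence, o.sample_id, o.spectral_count)
        assert sorted(read_evidence(a), key=key) == sorted(read_evidence(b), key=key)

    def test_maxquant_dialect(self, tmp_path):
        path = tmp_path / "evidence.txt"
        path.write_text(
            "Sequence\tModified sequence\tProteins\tExperiment\tMS/MS Count\n"
            "SYSMEHFRWGKPV\t_SYS(ph)MEHFRWGKPV(am)_\tPOMC\ts01\t4\n"
            "HSQGTFTSDYS\t_HSQGTFTSDYS_\tGCG;GCG2\ts02\t2\n"
        )
        first, second = read_evidence(path, dialect="maxquant_evidence")
        assert first.is_phospho and first.is_amidated and first.spectral_count == 4
        assert second.accessions == ["GCG", "GCG2"] and second.sample_id == "s02"

    def test_evidence_round_trip(self, tmp_path):
        obs = [
            PeptideObservation("SYSMEHFRWGKPV",
                               [ModificationEvent(ModKind.PHOSPHO, 3, localized=False)],
                               ["POMC"], "s01", 4),
            PeptideObservation("HSQGTFTSDYS", [], ["GCG", "GCG2"], "s02", 2, intensity=1e6),
        ]
        path = tmp_path / "round.tsv"
        write_evidence(obs, path)
        back = read_evidence(path)
        assert [(o.sequence, o.mod_key, tuple(o.accessions), o.sample_id, o.spectral_count)
                for o in back] == \
               [(o.sequence, o.mod_key, tuple(o.accessions), o.sample_id, o.spectral_count)
                for o in obs]


class TestCountUnique:
    def test_mod_specific_variants_vs_sequences(self):
        obs = [
            PeptideObservation("SAAAAA"),
            PeptideObservation("SAAAAA", [ModificationEvent(ModKind.PHOSPHO, 1)]),
            PeptideObservation("SAAAAA", [ModificationEvent(ModKind.PHOSPHO, 1)], sample_id="s2"),
        ]
        assert count_unique(obs) == (2, 1)

    def test_empty(self):
        assert count_unique([]) == (0, 0)


class TestFasta:
    def test_round_trip_uppercase_and_stop_strip(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P01 GN=Gcg OS=Rat\nhsqgtftsdys*\n>P02\nMKSIY\n")
        prots = read_fasta(path)
        assert [p.accession for p in prots] == ["P01", "P02"]
        assert prots[0].sequence == "HSQGTFTSDYS"
        assert prots[0].gene == "Gcg"
        out = tmp_path / "out.fasta"
        write_fasta(prots, out)
        assert [(p.accession, p.sequence) for p in read_fasta(out)] == \
               [(p.accession, p.sequence) for p in prots]

    def test_duplicate_accession_is_an_error(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P01\nAAA\n>P01\nCCC\n")
        with pytest.raises(ValueError, match="P01"):
            read_fasta(path)

    def test_empty_fasta(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text("")
        assert read_fasta(path) == []


class TestLpvTable:
    def test_round_trip(self, tmp_path):
        lpvs = [
            LPV("HSQGTFTSDYS", "GCG", 21, 31, False, True,
                support=frozenset({1, 2}), modifications=frozenset({("phospho", 23, True)}),
                group_id="g1"),
            LPV("QDFVQWLMNT", "GCG", 40, 49, True, False,
                support=frozenset({3}), modifications=frozenset(), group_id="g1"),
        ]
        df = lpv_table(lpvs)
        path = tmp_path / "lpvs.tsv"
        df.to_csv(path, sep="\t", index=False)
        import pandas as pd

        back = lpvs_from_table(pd.read_csv(path, sep="\t", keep_default_na=False))
        assert back == lpvs

    def test_empty_list_gives_header_only(self, tmp_path):
        df = lpv_table([])
        assert len(df) == 0 and "sequence" in df.columns
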