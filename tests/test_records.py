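"""Structure grammar, label derivation, validation and dataset I/O."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoshift.records import (
    TASKS,
    TASK_NAMES,
    DatasetFormatError,
    DomainError,
    Linkage,
    OligoStructure,
    Residue,
    SpectrumRecord,
    StructureParseError,
    TaskLabels,
    canonicalize,
    format_structure,
    labels_frame,
    labels_from_structure,
    parse_structure,
    read_dataset,
    write_dataset,
)
from glycoshift.simulate import random_structure


class TestGrammar:
    def test_linear_disaccharide_round_trip(self):
        text = "b-D-Galp-(1->3)-a-D-Glcp"
        s = parse_structure(text)
        assert s.is_disaccharide
        assert s.reducing_anomer == "alpha"
        assert s.residues[0].monomer == "Glc"
        assert s.residues[1].monomer == "Gal"
        assert s.linkage_from(1).position == 3
        assert s.linkage_from(1).anomer == "beta"
        assert format_structure(s) == text

    def test_linear_trisaccharide_round_trip(self):
        text = "a-D-Glcp-(1->3)-b-D-Galp-(1->4)-b-D-Manp"
        s = parse_structure(text)
        assert not s.is_disaccharide
        assert s.chain == "linear"
        assert [r.monomer for r in s.residues] == ["Man", "Gal", "Glc"]
        assert s.linkage_from(2).position == 3  # first linkage (terminal donor)
        assert s.linkage_from(1).position == 4  # second linkage (to reducing end)
        assert format_structure(s) == text

    def test_branched_trisaccharide_round_trip(self):
        text = "a-D-Glcp-(1->2)-[a-D-Manp-(1->6)]-b-D-Glcp"
        s = parse_structure(text)
        assert s.chain == "branched"
        assert s.residues[1].monomer == "Man"  # bracketed = middle
        assert s.residues[2].monomer == "Glc"  # unbracketed = first
        assert s.linkage_from(2).position == 2
        assert s.linkage_from(1).position == 6
        assert format_structure(s) == text

    def test_substituent_tokens_round_trip(self):
        text = "b-D-GlcpNAc-(1->4)-a-D-Glcp-OMe"
        s = parse_structure(text)
        assert s.residues[1].n_acetylated
        assert s.residues[0].o_methyl_positions == frozenset({1})
        assert s.n_carbons == 6 + 1 + 6 + 2  # ring + OMe + ring + NAc
        assert format_structure(s) == text

    def test_ring_o_methyl_token(self):
        s = parse_structure("a-D-Glcp-(1->2)-b-D-Galp-3Me")
        assert s.residues[0].o_methyl_positions == frozenset({3})

    @pytest.mark.parametrize(
        "text",
        [
            "x-D-Glcp-(1->4)-a-D-Glcp",          # bad anomer letter
            "a-D-Xylp-(1->4)-a-D-Glcp",          # unknown monomer
            "a-D-Glcp-(1->5)-a-D-Glcp",          # invalid position
            "a-D-Glcp(1->4)-a-D-Glcp",           # missing hyphen
            "a-D-Glcp-(1->2)-[a-D-Manp-(1->6)-b-D-Glcp",  # unbalanced bracket
        ],
    )
    def test_malformed_strings_raise_parse_error(self, text):
        with pytest.raises(StructureParseError):
            parse_structure(text)

    @pytest.mark.parametrize(
        "text",
        [
            "a-L-Glcp-(1->4)-a-D-Glcp",          # wrong enantiomer series
            "a-L-Rhap-(1->6)-a-L-Fucp",          # (1->6) into a 6-deoxy sugar
            "a-D-Glcp-(1->3)-a-D-Glcp-3Me",      # linkage into O-methylated position
            "a-D-Glcp-(1->2)-a-D-GlcpNAc",       # (1->2) into the NAc position
            "a-D-Glcp-(1->2)-a-D-Glcp-(1->3)-a-D-Glcp-(1->4)-a-D-Glcp",  # 4 residues
        ],
    )
    def test_out_of_scope_structures_raise_domain_error(self, text):
        with pytest.raises(DomainError):
            parse_structure(text)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10**6), kind=st.sampled_from(["di", "tri"]))
    def test_format_parse_round_trip_over_random_structures(self, seed, kind):
        rng = np.random.default_rng(seed)
        s = random_structure(rng, kind)
        # generated structures may list linkages in either order; the
        # round trip must agree up to canonical form
        assert canonicalize(parse_structure(format_structure(s))) == canonicalize(s)


class TestDomainValidation:
    def test_residue_rules(self):
        with pytest.raises(DomainError):
            Residue("Rha", n_acetylated=True)
        with pytest.raises(DomainError):
            Residue("Glc", n_acetylated=True, o_methyl_positions=frozenset({2}))
        with pytest.raises(DomainError):
            Residue("Fuc", o_methyl_positions=frozenset({6}))
        with pytest.raises(DomainError):
            Residue("Glc", o_methyl_positions=frozenset({5}))

    def test_structure_rules(self):
        red = Residue("Glc")
        don = Residue("Gal")
        with pytest.raises(DomainError):  # self-glycosylation
            Linkage(0, 0, 4, "alpha")
        with pytest.raises(DomainError):  # branched at the same carbon
            OligoStructure(
                (red, don, don),
                (Linkage(1, 0, 4, "alpha"), Linkage(2, 0, 4, "beta")),
                "alpha",
            )
        with pytest.raises(DomainError):  # non-reducing anomeric OMe
            OligoStructure(
                (red, Residue("Gal", o_methyl_positions=frozenset({1}))),
                (Linkage(1, 0, 4, "alpha"),),
                "alpha",
            )

    def test_task_labels_alphabet_check(self):
        with pytest.raises(DomainError):
            TaskLabels(
                ano_f="Z", ano_s="X", ano_r="A", f_link="X", s_link="A",
                red_end="A", m_residue="X", f_residue="A", chain_type="X",
            )


class TestLabels:
    def test_disaccharide_labels(self):
        labels = labels_from_structure(parse_structure("b-D-Galp-(1->3)-a-D-Glcp"))
        assert labels.as_dict() == {
            "ano_f": "B", "ano_s": "X", "ano_r": "A", "f_link": "X",
            "s_link": "B", "red_end": "A", "m_residue": "X",
            "f_residue": "B", "chain_type": "X",
        }

    def test_branched_trisaccharide_labels(self):
        labels = labels_from_structure(
            parse_structure("a-D-Glcp-(1->2)-[a-D-Manp-(1->6)]-b-D-Glcp")
        )
        assert labels.as_dict() == {
            "ano_f": "A", "ano_s": "A", "ano_r": "B", "f_link": "A",
            "s_link": "D", "red_end": "A", "m_residue": "C",
            "f_residue": "A", "chain_type": "B",
        }

    def test_disaccharide_na_pattern_is_exact(self, default_records):
        na_tasks = {"ano_s", "f_link", "m_residue", "chain_type"}
        for rec in default_records:
            labels = rec.labels.as_dict()
            expected_x = na_tasks if rec.structure.is_disaccharide else set()
            assert {t for t, v in labels.items() if v == "X"} == expected_x

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10**6), kind=st.sampled_from(["di", "tri"]))
    def test_labels_lie_in_task_alphabets(self, seed, kind):
        rng = np.random.default_rng(seed)
        labels = labels_from_structure(random_structure(rng, kind)).as_dict()
        for task in TASK_NAMES:
            assert labels[task] in TASKS[task]


class TestCanonicalize:
    def test_branch_order_is_normalised(self):
        raw = OligoStructure(
            (Residue("Glc"), Residue("Glc"), Residue("Man")),
            (Linkage(1, 0, 2, "alpha"), Linkage(2, 0, 6, "beta")),
            "alpha",
        )
        canon = canonicalize(raw)
        assert canon.linkage_from(2).position == 2  # first residue at the lower position
        assert canon.residues[2].monomer == "Glc"
        assert canon.residues[1].monomer == "Man"
        assert parse_structure(format_structure(canon)) == canon

    def test_linear_and_canonical_structures_unchanged(self):
        s = parse_structure("a-D-Glcp-(1->2)-[a-D-Manp-(1->6)]-b-D-Glcp")
        assert canonicalize(s) == s


class TestSpectrumRecord:
    def test_labels_derived_from_structure(self):
        s = parse_structure("b-D-Galp-(1->3)-a-D-Glcp")
        rec = SpectrumRecord(id="r1", shifts_ppm=[60.0] * 12, structure=s)
        assert rec.labels == labels_from_structure(s)

    @pytest.mark.parametrize(
        "shifts",
        [[], [50.0] * 24, [50.0, -1.0], [50.0, 231.0]],
    )
    def test_shift_validation(self, shifts):
        with pytest.raises(DatasetFormatError):
            SpectrumRecord(id="bad", shifts_ppm=shifts)


class TestDatasetIO:
    @pytest.mark.parametrize("name", ["data.tsv", "data.csv"])
    def test_round_trip(self, tmp_path, name, default_records):
        subset = default_records[:25]
        path = tmp_path / name
        write_dataset(subset, path)
        back = read_dataset(path)
        assert [r.id for r in back] == [r.id for r in subset]
        for a, b in zip(back, subset):
            assert a.structure == b.structure
            assert a.labels == b.labels
            assert np.allclose(a.shifts_ppm, b.shifts_ppm, atol=1e-6)

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tstructure\nr1\t\n")
        with pytest.raises(DatasetFormatError, match="missing required column"):
            read_dataset(path)

    def test_unparsable_shifts_raise(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tstructure\tshifts\nr1\t\t60.0;sixty\n")
        with pytest.raises(DatasetFormatError, match="unparsable shift list"):
            read_dataset(path)

    def test_label_disagreement_raises(self, tmp_path, default_records):
        path = tmp_path / "data.tsv"
        write_dataset(default_records[:3], path)
        lines = path.read_text().splitlines()
        header = lines[0].split("\t")
        row = lines[1].split("\t")
        col = header.index("ano_r")
        row[col] = "B" if row[col] == "A" else "A"
        lines[1] = "\t".join(row)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DatasetFormatError, match="disagree"):
            read_dataset(path)

    def test_records_without_structure_read_back_unlabelled(self, tmp_path):
        rec = SpectrumRecord(id="anon", shifts_ppm=[55.0, 90.0])
        path = tmp_path / "data.tsv"
        write_dataset([rec], path)
        back = read_dataset(path)
        assert back[0].structure is None and back[0].labels is None

    def test_labels_frame_alignment_and_missing_labels(self, default_records):
        frame = labels_frame(default_records[:10])
        assert list(frame.columns) == list(TASK_NAMES)
        assert list(frame.index) == [r.id for r in default_records[:10]]
        with pytest.raises(DatasetFormatError, match="without labels"):
            labels_frame([SpectrumRecord(id="anon", shifts_ppm=[60.0])])
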