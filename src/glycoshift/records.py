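"""Domain model for pyranosyl di- and trisaccharides and their 13C spectra.

Structures are chains of 2 or 3 pyranose residues (index 0 is always the
reducing end) joined by (1->2), (1->3), (1->4) or (1->6) glycosidic
linkages of alpha or beta configuration.  Each structure determines nine
categorical labels: the anomeric configuration of the first unit, second
unit and reducing end; the first and second linkage types; the reducing,
middle and first residue identities; and the chain type (linear vs
branched).  For disaccharides the four tasks that refer to a third
residue (second-unit anomer, first linkage, middle residue, chain type)
take the "not applicable" class ``X``.

A small textual notation, e.g. ``b-D-Glcp-(1->4)-a-D-Glcp`` or the
branched ``a-D-Glcp-(1->2)-[a-D-Glcp-(1->6)]-a-D-Glcp``, serves for I/O;
it is modelled on the conventional condensed nomenclature for glycans.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

MONOMERS = ("Glc", "Gal", "Man", "Rha", "Fuc")
#: 6-deoxy sugars: C6 is a methyl group (no hydroxyl), hence cannot accept
#: a (1->6) linkage and resonates below 20 ppm.
DEOXY_MONOMERS = frozenset({"Rha", "Fuc"})
#: Absolute configuration used in the notation (D for the hexoses,
#: L for the 6-deoxy sugars considered here).
MONOMER_SERIES = {"Glc": "D", "Gal": "D", "Man": "D", "Rha": "L", "Fuc": "L"}

LINKAGE_POSITIONS = (2, 3, 4, 6)
ANOMERS = ("alpha", "beta")

ANOMER_CODE = {"alpha": "A", "beta": "B"}
LINKAGE_CODE = {2: "A", 3: "B", 4: "C", 6: "D"}
MONOMER_CODE = {"Glc": "A", "Gal": "B", "Man": "C", "Rha": "D", "Fuc": "E"}

#: Task name -> class alphabet, in the fixed task order used throughout.
TASKS: dict[str, tuple[str, ...]] = {
    "ano_f": ("A", "B"),
    "ano_s": ("A", "B", "X"),
    "ano_r": ("A", "B"),
    "f_link": ("A", "B", "C", "D", "X"),
    "s_link": ("A", "B", "C", "D"),
    "red_end": ("A", "B", "C", "D", "E"),
    "m_residue": ("A", "B", "C", "D", "E", "X"),
    "f_residue": ("A", "B", "C", "D", "E"),
    "chain_type": ("A", "B", "X"),
}
TASK_NAMES = tuple(TASKS)

MAX_SHIFTS = 23
PPM_LOW, PPM_HIGH = 0.0, 230.0


class StructureParseError(ValueError):
    """Raised when a structure string does not match the grammar."""


class DomainError(ValueError):
    """Raised for grammatically valid but chemically out-of-scope input."""


class DatasetFormatError(ValueError):
    """Raised for malformed dataset files."""


@dataclass(frozen=True)
class Residue:
    """One pyranose unit, optionally N-acetylated and/or O-methylated."""

    monomer: str
    n_acetylated: bool = False
    o_methyl_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.monomer not in MONOMERS:
            raise DomainError(f"unknown monomer {self.monomer!r}; expected one of {MONOMERS}")
        positions = frozenset(self.o_methyl_positions)
        object.__setattr__(self, "o_methyl_positions", positions)
        if not positions <= {1, 2, 3, 4, 6}:
            raise DomainError(f"O-methyl positions {sorted(positions)} outside {{1,2,3,4,6}}")
        if self.n_acetylated and 2 in positions:
            raise DomainError("position 2 carries the N-acetyl group; it cannot also be O-methylated")
        if self.n_acetylated and self.monomer in DEOXY_MONOMERS:
            raise DomainError(f"2-acetamido {self.monomer} is outside the modelled space")
        if 6 in positions and self.monomer in DEOXY_MONOMERS:
            raise DomainError(f"{self.monomer} is 6-deoxy; no O-methyl at C6")

    @property
    def n_carbons(self) -> int:
        """Ring carbons plus two per N-acetyl (carbonyl + methyl) and one per O-methyl."""
        return 6 + (2 if self.n_acetylated else 0) + len(self.o_methyl_positions)


@dataclass(frozen=True)
class Linkage:
    """A glycosidic bond: donor C1 -> acceptor carbon ``position``."""

    donor_index: int
    acceptor_index: int
    position: int
    anomer: str

    def __post_init__(self) -> None:
        if self.donor_index == self.acceptor_index:
            raise DomainError("a residue cannot glycosylate itself")
        if self.position not in LINKAGE_POSITIONS:
            raise DomainError(f"linkage position {self.position} not in {LINKAGE_POSITIONS}")
        if self.anomer not in ANOMERS:
            raise DomainError(f"anomer must be one of {ANOMERS}, got {self.anomer!r}")


@dataclass(frozen=True)
class OligoStructure:
    """A di- or trisaccharide.

    Residue index 0 is the reducing end.  For trisaccharides, index 1 is
    the middle residue (donor of the second linkage) and index 2 the
    first residue (the one most remote from, or second attached to, the
    reducing end; donor of the first linkage).  Linear chains link
    2 -> 1 -> 0; branched chains link both 1 -> 0 and 2 -> 0.
    """

    residues: tuple[Residue, ...]
    linkages: tuple[Linkage, ...]
    reducing_anomer: str

    def __post_init__(self) -> None:
        residues = tuple(self.residues)
        linkages = tuple(self.linkages)
        object.__setattr__(self, "residues", residues)
        object.__setattr__(self, "linkages", linkages)
        n = len(residues)
        if n not in (2, 3):
            raise DomainError(f"only di- and trisaccharides are modelled (got {n} residues)")
        if self.reducing_anomer not in ANOMERS:
            raise DomainError(f"reducing anomer must be one of {ANOMERS}")
        pairs = sorted((l.donor_index, l.acceptor_index) for l in linkages)
        if n == 2:
            if pairs != [(1, 0)]:
                raise DomainError("a disaccharide has exactly one linkage, donor 1 -> acceptor 0")
        else:
            if pairs not in ([(1, 0), (2, 0)], [(1, 0), (2, 1)]):
                raise DomainError(
                    "a trisaccharide is either linear (2->1, 1->0) or branched (1->0, 2->0)"
                )
            if pairs == [(1, 0), (2, 0)]:
                by_donor = {l.donor_index: l for l in linkages}
                if by_donor[1].position == by_donor[2].position:
                    raise DomainError("branched linkages must attach at distinct acceptor positions")
        for l in linkages:
            acceptor = residues[l.acceptor_index]
            if l.position == 6 and acceptor.monomer in DEOXY_MONOMERS:
                raise DomainError(f"(1->6) linkage into 6-deoxy {acceptor.monomer}")
            if l.position in acceptor.o_methyl_positions:
                raise DomainError(f"acceptor position {l.position} is O-methylated")
            if l.position == 2 and acceptor.n_acetylated:
                raise DomainError("(1->2) linkage into an N-acetylated position")
        occupied: dict[int, list[int]] = {}
        for l in linkages:
            occupied.setdefault(l.acceptor_index, []).append(l.position)
        for idx, pos in occupied.items():
            if len(pos) != len(set(pos)):
                raise DomainError(f"residue {idx} accepts two linkages at the same carbon")
        for i, res in enumerate(residues):
            if 1 in res.o_methyl_positions and i != 0:
                raise DomainError("anomeric O-methylation is only possible at the reducing end")

    @property
    def is_disaccharide(self) -> bool:
        return len(self.residues) == 2

    @property
    def chain(self) -> str:
        """``linear`` / ``branched`` for trisaccharides, else ``not_applicable``."""
        if self.is_disaccharide:
            return "not_applicable"
        donors = {l.donor_index: l.acceptor_index for l in self.linkages}
        return "branched" if donors == {1: 0, 2: 0} else "linear"

    def linkage_from(self, donor_index: int) -> Linkage:
        for l in self.linkages:
            if l.donor_index == donor_index:
                return l
        raise KeyError(donor_index)

    @property
    def n_carbons(self) -> int:
        return sum(r.n_carbons for r in self.residues)

    def anomer_of(self, index: int) -> str:
        """Anomeric configuration of residue ``index`` (glycosidic or reducing)."""
        if index == 0:
            return self.reducing_anomer
        return self.linkage_from(index).anomer


@dataclass(frozen=True)
class TaskLabels:
    """Single-letter class codes for the nine classification tasks."""

    ano_f: str
    ano_s: str
    ano_r: str
    f_link: str
    s_link: str
    red_end: str
    m_residue: str
    f_residue: str
    chain_type: str

    def __post_init__(self) -> None:
        for task, alphabet in TASKS.items():
            value = getattr(self, task)
            if value not in alphabet:
                raise DomainError(f"label {value!r} not in alphabet {alphabet} for task {task}")

    def as_dict(self) -> dict[str, str]:
        return {task: getattr(self, task) for task in TASK_NAMES}


def labels_from_structure(structure: OligoStructure) -> TaskLabels:
    """Derive the nine task labels from a validated structure.

    Disaccharides have no third residue, so the tasks that refer to one
    (second-unit anomer, first linkage, middle residue, chain type) are
    labelled ``X``; their single glycosidic anomer maps to the first-unit
    anomer task, their linkage to the second-linkage task (the linkage
    adjacent to the reducing end) and their non-reducing residue to the
    first-residue task.  For branched trisaccharides residue 2 plays the
    "first" role and residue 1 the "middle" role, exactly as for linear
    chains.
    """
    reducing = structure.residues[0]
    ano_r = ANOMER_CODE[structure.reducing_anomer]
    red_end = MONOMER_CODE[reducing.monomer]
    if structure.is_disaccharide:
        link = structure.linkage_from(1)
        return TaskLabels(
            ano_f=ANOMER_CODE[link.anomer],
            ano_s="X",
            ano_r=ano_r,
            f_link="X",
            s_link=LINKAGE_CODE[link.position],
            red_end=red_end,
            m_residue="X",
            f_residue=MONOMER_CODE[structure.residues[1].monomer],
            chain_type="X",
        )
    first_link = structure.linkage_from(2)
    second_link = structure.linkage_from(1)
    return TaskLabels(
        ano_f=ANOMER_CODE[first_link.anomer],
        ano_s=ANOMER_CODE[second_link.anomer],
        ano_r=ano_r,
        f_link=LINKAGE_CODE[first_link.position],
        s_link=LINKAGE_CODE[second_link.position],
        red_end=red_end,
        m_residue=MONOMER_CODE[structure.residues[1].monomer],
        f_residue=MONOMER_CODE[structure.residues[2].monomer],
        chain_type="A" if structure.chain == "linear" else "B",
    )


@dataclass
class SpectrumRecord:
    """One compound: identifier, raw shift list and optional structure/labels."""

    id: str
    shifts_ppm: list[float]
    structure: OligoStructure | None = None
    labels: TaskLabels | None = None

    def __post_init__(self) -> None:
        shifts = [float(v) for v in self.shifts_ppm]
        if len(shifts) > MAX_SHIFTS:
            raise DatasetFormatError(f"record {self.id}: {len(shifts)} shifts exceed the {MAX_SHIFTS}-slot descriptor")
        if not shifts:
            raise DatasetFormatError(f"record {self.id}: empty shift list")
        bad = [v for v in shifts if not (PPM_LOW < v < PPM_HIGH)]
        if bad:
            raise DatasetFormatError(f"record {self.id}: shifts outside ({PPM_LOW}, {PPM_HIGH}) ppm: {bad}")
        self.shifts_ppm = shifts
        if self.labels is None and self.structure is not None:
            self.labels = labels_from_structure(self.structure)


# ---------------------------------------------------------------------------
# Structure notation
# ---------------------------------------------------------------------------

_RESIDUE_RE = re.compile(
    r"(?P<anomer>[ab])-(?P<series>[DL])-(?P<monomer>Glc|Gal|Man|Rha|Fuc)p"
    r"(?P<nac>NAc)?(?P<ome>(?:-(?:OMe|[2346]Me))*)"
)
_LINK_RE = re.compile(r"\(1->(?P<pos>[2346])\)")


def _parse_residue(token: str, offset: int) -> tuple[str, Residue]:
    m = _RESIDUE_RE.fullmatch(token)
    if m is None:
        raise StructureParseError(f"malformed residue token {token!r} at position {offset}")
    monomer = m.group("monomer")
    if m.group("series") != MONOMER_SERIES[monomer]:
        raise DomainError(f"{monomer} is used as its {MONOMER_SERIES[monomer]} enantiomer here")
    positions = set()
    for part in filter(None, m.group("ome").split("-")):
        if part == "OMe":
            positions.add(1)
        else:
            positions.add(int(part[0]))
    anomer = "alpha" if m.group("anomer") == "a" else "beta"
    return anomer, Residue(monomer, n_acetylated=bool(m.group("nac")), o_methyl_positions=frozenset(positions))


def _split_chain(text: str) -> list[str]:
    """Split ``residue-(1->n)-residue...`` on linkage tokens, keeping both."""
    parts: list[str] = []
    pattern = re.compile(r"-\(1->([2346])\)-")
    last = 0
    for m in pattern.finditer(text):
        parts.append(text[last : m.start()])
        parts.append(m.group(1))
        last = m.end()
    parts.append(text[last:])
    return parts


def parse_structure(text: str) -> OligoStructure:
    """Parse the condensed notation into a validated :class:`OligoStructure`.

    Grammar (one optional bracketed branch, attached to the reducing end)::

        chain  := residue ( "-(1->n)-" residue ){1,2}
        branch := residue "-(1->n)-" "[" residue "-(1->n)-" "]" residue

    In a branched string the unbracketed (leftmost) residue is the
    "first" residue (index 2) and the bracketed one the "middle"
    residue (index 1).
    """
    text = text.strip()
    branch_m = re.search(r"\[(?P<inner>[^\]]*)\]-", text)
    if "[" in text or "]" in text:
        if branch_m is None:
            raise StructureParseError(f"unbalanced brackets in {text!r}")
        inner = branch_m.group("inner")
        outer = text[: branch_m.start()] + text[branch_m.end() :]
        outer_parts = _split_chain(outer)
        inner_m = re.fullmatch(r"(?P<res>.+)-\(1->(?P<pos>[2346])\)", inner)
        if len(outer_parts) != 3 or inner_m is None:
            raise StructureParseError(f"branched structure must be A-(1->x)-[B-(1->y)]-C, got {text!r}")
        f_anomer, f_res = _parse_residue(outer_parts[0], 0)
        m_anomer, m_res = _parse_residue(inner_m.group("res"), branch_m.start() + 1)
        r_anomer, r_res = _parse_residue(outer_parts[2], branch_m.end())
        return OligoStructure(
            residues=(r_res, m_res, f_res),
            linkages=(
                Linkage(1, 0, int(inner_m.group("pos")), m_anomer),
                Linkage(2, 0, int(outer_parts[1]), f_anomer),
            ),
            reducing_anomer=r_anomer,
        )
    parts = _split_chain(text)
    if len(parts) not in (3, 5) or len(parts) % 2 == 0:
        n_res = (len(parts) + 1) // 2
        if n_res > 3:
            raise DomainError(f"{n_res} residues exceed the di/trisaccharide scope")
        raise StructureParseError(f"could not parse chain {text!r}")
    tokens = parts[0::2]
    positions = [int(p) for p in parts[1::2]]
    parsed = [_parse_residue(tok, text.find(tok)) for tok in tokens]
    # The leftmost residue is the terminal (non-reducing) one; the rightmost
    # the reducing end, which gets index 0.
    residues = tuple(res for _, res in reversed(parsed))
    reducing_anomer = parsed[-1][0]
    linkages = []
    n = len(residues)
    for i, pos in enumerate(positions):
        donor = n - 1 - i
        linkages.append(Linkage(donor, donor - 1, pos, parsed[i][0]))
    return OligoStructure(residues=residues, linkages=tuple(linkages), reducing_anomer=reducing_anomer)


def _format_residue(res: Residue, anomer: str) -> str:
    token = f"{'a' if anomer == 'alpha' else 'b'}-{MONOMER_SERIES[res.monomer]}-{res.monomer}p"
    if res.n_acetylated:
        token += "NAc"
    for pos in sorted(res.o_methyl_positions):
        token += "-OMe" if pos == 1 else f"-{pos}Me"
    return token


def format_structure(structure: OligoStructure) -> str:
    """Render the canonical notation string (inverse of :func:`parse_structure`).

    For branched trisaccharides the branch of residue 2 (the "first"
    residue) is written unbracketed; canonical structures have residue 2
    attached at the lower-numbered position.
    """
    res = structure.residues
    if structure.is_disaccharide:
        link = structure.linkage_from(1)
        return (
            f"{_format_residue(res[1], link.anomer)}-(1->{link.position})-"
            f"{_format_residue(res[0], structure.reducing_anomer)}"
        )
    first = structure.linkage_from(2)
    second = structure.linkage_from(1)
    if structure.chain == "linear":
        return (
            f"{_format_residue(res[2], first.anomer)}-(1->{first.position})-"
            f"{_format_residue(res[1], second.anomer)}-(1->{second.position})-"
            f"{_format_residue(res[0], structure.reducing_anomer)}"
        )
    return (
        f"{_format_residue(res[2], first.anomer)}-(1->{first.position})-"
        f"[{_format_residue(res[1], second.anomer)}-(1->{second.position})]-"
        f"{_format_residue(res[0], structure.reducing_anomer)}"
    )


def canonicalize(structure: OligoStructure) -> OligoStructure:
    """Return the canonical form: linkages ordered by donor index, and
    branched structures get their branches ordered so that the first
    residue (index 2) attaches at the lower-numbered position."""
    if structure.chain != "branched":
        ordered = tuple(sorted(structure.linkages, key=lambda l: l.donor_index))
        if ordered == structure.linkages:
            return structure
        return OligoStructure(
            residues=structure.residues,
            linkages=ordered,
            reducing_anomer=structure.reducing_anomer,
        )
    l1 = structure.linkage_from(1)
    l2 = structure.linkage_from(2)
    if l2.position < l1.position:
        ordered = tuple(sorted(structure.linkages, key=lambda l: l.donor_index))
        if ordered == structure.linkages:
            return structure
        return OligoStructure(
            residues=structure.residues,
            linkages=ordered,
            reducing_anomer=structure.reducing_anomer,
        )
    return OligoStructure(
        residues=(structure.residues[0], structure.residues[2], structure.residues[1]),
        linkages=(
            Linkage(1, 0, l2.position, l2.anomer),
            Linkage(2, 0, l1.position, l1.anomer),
        ),
        reducing_anomer=structure.reducing_anomer,
    )


# ---------------------------------------------------------------------------
# Dataset I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("id", "structure", "shifts")


def write_dataset(records: Iterable[SpectrumRecord], path: str | Path, fmt: str | None = None) -> None:
    """Write records to TSV (default) or CSV with 6-decimal shift formatting."""
    path = Path(path)
    sep = _separator(path, fmt)
    rows = []
    for rec in records:
        row: dict[str, str] = {
            "id": rec.id,
            "structure": format_structure(rec.structure) if rec.structure is not None else "",
            "shifts": ";".join(f"{v:.6f}" for v in rec.shifts_ppm),
        }
        if rec.labels is not None:
            row.update(rec.labels.as_dict())
        rows.append(row)
    columns = list(_REQUIRED_COLUMNS) + [t for t in TASK_NAMES if any(t in r for r in rows)]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep=sep, index=False)


def read_dataset(path: str | Path, fmt: str | None = None) -> list[SpectrumRecord]:
    """Read a spectrum dataset; labels are derived from the structure when absent.

    When both a structure and label columns are present the stored labels
    must agree with the ones derived from the structure.
    """
    path = Path(path)
    sep = _separator(path, fmt)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required column(s) {missing}")
    has_labels = all(t in frame.columns for t in TASK_NAMES)
    records: list[SpectrumRecord] = []
    for _, row in frame.iterrows():
        structure = parse_structure(row["structure"]) if row["structure"] else None
        try:
            shifts = [float(v) for v in row["shifts"].split(";") if v]
        except ValueError as exc:
            raise DatasetFormatError(f"record {row['id']}: unparsable shift list") from exc
        labels = None
        if has_labels and row[TASK_NAMES[0]]:
            labels = TaskLabels(**{t: row[t] for t in TASK_NAMES})
        rec = SpectrumRecord(id=row["id"], shifts_ppm=shifts, structure=structure, labels=labels)
        if structure is not None and labels is not None:
            derived = labels_from_structure(structure)
            if derived != labels:
                raise DatasetFormatError(
                    f"record {rec.id}: stored labels {labels.as_dict()} disagree with "
                    f"structure-derived labels {derived.as_dict()}"
                )
        records.append(rec)
    return records


def labels_frame(records: Sequence[SpectrumRecord]) -> pd.DataFrame:
    """Nine-task label table (rows aligned with ``records``), indexed by id."""
    missing = [r.id for r in records if r.labels is None]
    if missing:
        raise DatasetFormatError(f"records without labels: {missing}")
    return pd.DataFrame([r.labels.as_dict() for r in records], index=[r.id for r in records])


def _separator(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise DatasetFormatError(f"unknown dataset format {fmt!r}")
    return "\t" if fmt == "tsv" else ","
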