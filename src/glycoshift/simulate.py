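"""Synthetic 13C spectra for di- and trisaccharides.

Shifts are produced by an additive increment model, the way empirical
shift-prediction schemes for carbohydrates work: each residue
contributes six ring-carbon shifts, glycosylation moves the donor
anomeric carbon downfield by a position-dependent amount and replaces
the substituted acceptor carbon with a characteristic glycosidation
value, and N-acetyl / O-methyl substituents contribute their own
carbons and local changes.  Independent Gaussian noise (default 0.3
ppm) emulates the spread between calculated and experimental shifts
and between laboratories.

The default tables are stylised, editable constants.  They preserve
the qualitative ordering of carbohydrate 13C spectroscopy (deoxy
methyls below 20 ppm, ring carbons in the middle, anomeric carbons
further downfield, the amide carbonyl above 170 ppm) and the standard
glycosidation-shift phenomenology (the substituted carbon and the
donor anomeric carbon move downfield by amounts that depend on the
linkage position, the donor residue and its anomeric configuration),
but they are not a reproduction of any specific prediction program or
compound assignment.  See docs/methods.md for the full rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .records import (
    ANOMERS,
    DEOXY_MONOMERS,
    LINKAGE_POSITIONS,
    MONOMERS,
    TASKS,
    TASK_NAMES,
    Linkage,
    OligoStructure,
    Residue,
    SpectrumRecord,
    canonicalize,
    labels_from_structure,
)

__all__ = [
    "IncrementModel",
    "SimulatedDataset",
    "default_increment_model",
    "simulate_spectrum",
    "generate_dataset",
    "random_structure",
    "structure_with",
]


class SimulationConfigError(KeyError):
    """A model table lacks an entry required by the structure."""


_MONOMER_INDEX = {m: i for i, m in enumerate(MONOMERS)}

#: Which donor residues occur at each linkage position (the modelled
#: transferase-style specificity).  The order fixes the rank a donor
#: occupies inside the per-position glycosidation windows.
DONOR_ORDER: dict[int, tuple[str, ...]] = {
    2: ("Glc", "Rha", "Fuc"),
    3: ("Glc", "Gal"),
    4: ("Gal", "Man", "Fuc"),
    6: ("Man", "Rha"),
}

#: Which positions each monomer can donate into (inverse of DONOR_ORDER).
ALLOWED_DONOR_POSITIONS: dict[str, frozenset[int]] = {
    m: frozenset(p for p, donors in DONOR_ORDER.items() if m in donors) for m in MONOMERS
}

#: Ring-carbon shifts (C1..C6, ppm) of the free reducing pyranoses.
#: C1/C2/C6 follow a 1.3-ppm monomer grid, C3/C5 a 1.3-ppm anomer pair,
#: C4 is common; Rha/Fuc put their 6-deoxy methyl below 20 ppm.
_BASE_SHIFTS: dict[tuple[str, str], tuple[float, ...]] = {
    ("Glc", "alpha"): (88.2, 66.4, 74.2, 61.2, 82.0, 62.5),
    ("Glc", "beta"): (88.2, 66.4, 75.5, 61.2, 83.3, 62.5),
    ("Gal", "alpha"): (89.5, 67.7, 74.2, 61.2, 82.0, 63.8),
    ("Gal", "beta"): (89.5, 67.7, 75.5, 61.2, 83.3, 63.8),
    ("Man", "alpha"): (90.8, 69.0, 74.2, 61.2, 82.0, 65.1),
    ("Man", "beta"): (90.8, 69.0, 75.5, 61.2, 83.3, 65.1),
    ("Rha", "alpha"): (92.1, 70.3, 74.2, 61.2, 82.0, 14.3),
    ("Rha", "beta"): (92.1, 70.3, 75.5, 61.2, 83.3, 14.3),
    ("Fuc", "alpha"): (93.4, 71.6, 74.2, 61.2, 82.0, 15.6),
    ("Fuc", "beta"): (93.4, 71.6, 75.5, 61.2, 83.3, 15.6),
}

#: Per linkage position: window origins (ppm) of the glycosidation
#: values.  The substituted acceptor carbon is set to
#: ``acceptor_* + 1.3 * (k*[donor is beta] + donor rank)`` where k is
#: the number of donors occurring at that position; the donor anomeric
#: carbon of a terminal donor is set to ``donor_anomeric + 2.6 * rank``.
#: ``neighbor`` is the delta applied to the ring neighbours of the
#: substituted carbon (none in the default model).
_GLYCOSYLATION: dict[int, dict[str, float]] = {
    2: {"acceptor_reducing": 148.0, "acceptor_middle": 122.0, "donor_anomeric": 94.7, "neighbor": 0.0},
    3: {"acceptor_reducing": 155.8, "acceptor_middle": 129.8, "donor_anomeric": 101.2, "neighbor": 0.0},
    4: {"acceptor_reducing": 161.0, "acceptor_middle": 135.0, "donor_anomeric": 105.1, "neighbor": 0.0},
    6: {"acceptor_reducing": 168.8, "acceptor_middle": 142.8, "donor_anomeric": 111.6, "neighbor": 0.0},
}

#: Rank step inside acceptor windows (anomer block and donor level).
_WINDOW_STEP = 1.3
#: Rank step inside the terminal-donor anomeric window.
_DONOR_STEP = 2.6
#: Anomeric carbon of a substituted (chain-interior) donor, or of the
#: senior donor on a doubly substituted core: 115.5 + 1.3 * monomer index.
_SUBSTITUTED_DONOR_C1 = 115.5
#: Glycosidation deltas on the donor's other carbons: C3/C5 and the
#: deoxy methyl move downfield when a residue acts as donor; C3 moves
#: again when the donor is itself substituted.
_DONOR_C3_DELTA = 2.6
_DONOR_C5_DELTA = 2.6
_DONOR_METHYL_DELTA = 2.6

_SUBSTITUENTS: dict[str, float] = {
    "nac_carbonyl": 175.3,   # amide C=O
    "nac_methyl": 59.9,      # amide CH3 (stylised; kept in the hexose zone)
    "nac_c2": 72.9,          # C2 bearing the NHAc group (replaces the C2 shift)
    "ome_anomeric": 57.3,    # OCH3 of a methyl glycoside
    "ome_ring": 58.6,        # OCH3 on a ring hydroxyl
    "ome_anomeric_c_delta": 0.0,   # C1 change on anomeric O-methylation
    "ome_ring_c_delta": 0.0,       # ring-carbon change on O-methylation
}


@dataclass(frozen=True)
class IncrementModel:
    """Tables and noise level driving :func:`simulate_spectrum`."""

    base_shifts: Mapping[tuple[str, str], tuple[float, ...]] = field(default_factory=lambda: dict(_BASE_SHIFTS))
    glycosylation_increment: Mapping[int, Mapping[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in _GLYCOSYLATION.items()})
    substituent_shifts: Mapping[str, float] = field(default_factory=lambda: dict(_SUBSTITUENTS))
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for (monomer, anomer), values in self.base_shifts.items():
            if len(values) != 6:
                raise ValueError(f"base shifts for {monomer}/{anomer} must have 6 entries")
            if not (88.0 < values[0] < 106.0):
                raise ValueError(f"anomeric base shift of {monomer}/{anomer} outside (88, 106) ppm")
            if monomer in DEOXY_MONOMERS and not (14.0 < values[5] < 20.0):
                raise ValueError(f"deoxy methyl base shift of {monomer}/{anomer} outside (14, 20) ppm")
        if not (170.0 < self.substituent_shifts["nac_carbonyl"] < 180.0):
            raise ValueError("N-acetyl carbonyl shift outside (170, 180) ppm")

    def to_dict(self) -> dict:
        return {
            "base_shifts": {f"{m}/{a}": list(v) for (m, a), v in self.base_shifts.items()},
            "glycosylation_increment": {str(k): dict(v) for k, v in self.glycosylation_increment.items()},
            "substituent_shifts": dict(self.substituent_shifts),
            "noise_sd": self.noise_sd,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "IncrementModel":
        return cls(
            base_shifts={tuple(k.split("/")): tuple(v) for k, v in data["base_shifts"].items()},
            glycosylation_increment={int(k): dict(v) for k, v in data["glycosylation_increment"].items()},
            substituent_shifts=dict(data["substituent_shifts"]),
            noise_sd=float(data.get("noise_sd", 0.3)),
        )

    @classmethod
    def from_yaml(cls, path) -> "IncrementModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_increment_model(noise_sd: float = 0.3) -> IncrementModel:
    """The shipped default tables with the given noise level."""
    return IncrementModel(noise_sd=noise_sd)


def _lookup(table: Mapping, key, what: str):
    try:
        return table[key]
    except KeyError as exc:
        raise SimulationConfigError(f"increment model lacks {what} entry {key!r}") from exc


def _donor_rank(position: int, monomer: str) -> int:
    order = _lookup(DONOR_ORDER, position, "donor order")
    if monomer not in order:
        raise SimulationConfigError(f"increment model lacks donor entry {monomer!r} at position {position}")
    return order.index(monomer)


def simulate_spectrum(structure: OligoStructure, model: IncrementModel, seed: int) -> list[float]:
    """One shift per carbon atom of ``structure`` (unsorted, in atom order).

    Six ring carbons per residue, plus two carbons per N-acetyl group and
    one per O-methyl group; shifts are base values modified by
    glycosidation and substituent contributions, plus Gaussian(0,
    ``model.noise_sd``) noise.  Deterministic for a given
    (structure, model, seed).
    """
    rng = np.random.default_rng(seed)
    acceptors = {link.acceptor_index for link in structure.linkages}
    ring: list[list[float]] = []
    extra: list[float] = []
    for idx, residue in enumerate(structure.residues):
        anomer = structure.anomer_of(idx)
        base = _lookup(model.base_shifts, (residue.monomer, anomer), "base shift")
        carbons = [float(v) for v in base]
        if idx > 0:  # every non-reducing residue is a glycosidic donor
            carbons[2] += _DONOR_C3_DELTA
            carbons[4] += _DONOR_C5_DELTA
            if residue.monomer in DEOXY_MONOMERS:
                carbons[5] += _DONOR_METHYL_DELTA
            if idx in acceptors:  # substituted (chain-interior) donor
                carbons[2] += _DONOR_C3_DELTA
                carbons[0] = _SUBSTITUTED_DONOR_C1 + _WINDOW_STEP * _MONOMER_INDEX[residue.monomer]
        ring.append(carbons)
    for link in structure.linkages:
        inc = _lookup(model.glycosylation_increment, link.position, "glycosylation")
        donor = structure.residues[link.donor_index]
        rank = _donor_rank(link.position, donor.monomer)
        k = len(DONOR_ORDER[link.position])
        window_base = inc["acceptor_reducing"] if link.acceptor_index == 0 else inc["acceptor_middle"]
        acceptor = ring[link.acceptor_index]
        pos = link.position
        acceptor[pos - 1] = window_base + _WINDOW_STEP * (k * (link.anomer == "beta") + rank)
        for neighbor in (pos - 1, pos + 1):
            if 1 <= neighbor <= 6 and neighbor != pos:
                acceptor[neighbor - 1] += inc["neighbor"]
        if link.donor_index not in acceptors:  # terminal donor
            ring[link.donor_index][0] = inc["donor_anomeric"] + _DONOR_STEP * rank
    # On a doubly substituted core the two branches crowd each other;
    # the donor at the senior (higher) position is shifted further
    # downfield, into the substituted-donor window.
    core_links = [l for l in structure.linkages if l.acceptor_index == 0]
    if len(core_links) == 2:
        senior = max(core_links, key=lambda l: l.position)
        monomer = structure.residues[senior.donor_index].monomer
        ring[senior.donor_index][0] = _SUBSTITUTED_DONOR_C1 + _WINDOW_STEP * _MONOMER_INDEX[monomer]
    sub = model.substituent_shifts
    for idx, residue in enumerate(structure.residues):
        if residue.n_acetylated:
            ring[idx][1] = sub["nac_c2"]
            extra.extend([sub["nac_carbonyl"], sub["nac_methyl"]])
        for pos in sorted(residue.o_methyl_positions):
            if pos == 1:
                ring[idx][0] += sub["ome_anomeric_c_delta"]
                extra.append(sub["ome_anomeric"])
            else:
                ring[idx][pos - 1] += sub["ome_ring_c_delta"]
                extra.append(sub["ome_ring"])
    shifts = np.array([v for carbons in ring for v in carbons] + extra, dtype=float)
    if model.noise_sd > 0:
        shifts = shifts + rng.normal(0.0, model.noise_sd, size=shifts.size)
    # Shifts live in the physical window (0, 230) ppm; very large noise
    # levels could otherwise push a value outside it, so clamp with a
    # small margin.  Irrelevant at realistic noise levels (< 1 ppm).
    shifts = np.clip(shifts, 0.05, 229.95)
    return [float(v) for v in shifts]


# ---------------------------------------------------------------------------
# Random structures and datasets
# ---------------------------------------------------------------------------

_P_NAC = 0.12       # chance that an eligible Glc/Gal residue is N-acetylated
_P_OME = 0.2        # chance that the reducing end is anomerically O-methylated
_P_BRANCHED = 0.4   # fraction of trisaccharides with a branched core
_HEXOSES = tuple(m for m in MONOMERS if m not in DEOXY_MONOMERS)


def random_structure(rng: np.random.Generator, kind: str, constraints: Mapping[str, str] | None = None) -> OligoStructure:
    """Sample one structure from the modelled combinatorial space.

    Linkage positions are drawn first (uniformly) and residues
    compatible with them second, so that every linkage-type and residue
    class keeps support.  ``kind`` is ``"di"`` or ``"tri"``.
    ``constraints`` may pin task labels (task name -> class code);
    sampling then rejects until the labels match (every constraint
    class is directly reachable, so this terminates quickly).
    """
    constraints = dict(constraints or {})
    for _ in range(10_000):
        s = _sample_structure(rng, kind)
        if not constraints:
            return s
        labels = labels_from_structure(s).as_dict()
        if all(labels[t] == c for t, c in constraints.items()):
            return s
    raise ValueError(f"could not satisfy constraints {constraints} for kind {kind!r}")


def _sample_structure(rng: np.random.Generator, kind: str) -> OligoStructure:
    if kind not in ("di", "tri"):
        raise ValueError("kind must be 'di' or 'tri'")

    def pick(seq):
        return seq[rng.integers(len(seq))]

    def anomer():
        return ANOMERS[rng.integers(2)]

    def with_nac(monomer, accepts_at_2, allow_nac):
        # N-acetylation replaces the 2-OH, so a residue glycosylated at
        # O-2 cannot carry it; at most one NAc per compound.
        nac = (allow_nac and not accepts_at_2 and monomer in ("Glc", "Gal")
               and rng.random() < _P_NAC)
        return Residue(monomer, n_acetylated=nac)

    def acceptors_for(*positions):
        # 6-deoxy sugars lack an O-6 and cannot accept at position 6
        return _HEXOSES if 6 in positions else MONOMERS

    if kind == "di":
        pos = pick(LINKAGE_POSITIONS)
        red = with_nac(pick(acceptors_for(pos)), pos == 2, True)
        donor = with_nac(pick(DONOR_ORDER[pos]), False, not red.n_acetylated)
        if rng.random() < _P_OME:
            red = replace(red, o_methyl_positions=frozenset({1}))
        return OligoStructure((red, donor), (Linkage(1, 0, pos, anomer()),), anomer())
    if rng.random() < _P_BRANCHED:
        mid_mon = pick(MONOMERS)
        hi = pick(sorted(ALLOWED_DONOR_POSITIONS[mid_mon] - {2}))
        lo = pick([p for p in (2, 3, 4) if p < hi])
        red = with_nac(pick(acceptors_for(lo, hi)), lo == 2, True)
        n_nac = int(red.n_acetylated)
        mid = with_nac(mid_mon, False, n_nac < 1)
        n_nac += int(mid.n_acetylated)
        first = with_nac(pick(DONOR_ORDER[lo]), False, n_nac < 1)
        if rng.random() < _P_OME:
            red = replace(red, o_methyl_positions=frozenset({1}))
        links = (Linkage(1, 0, hi, anomer()), Linkage(2, 0, lo, anomer()))
        return canonicalize(OligoStructure((red, mid, first), links, anomer()))
    p_first = pick(LINKAGE_POSITIONS)
    mid_mon = pick(_HEXOSES if p_first == 6 else MONOMERS)
    p_second = pick(sorted(ALLOWED_DONOR_POSITIONS[mid_mon]))
    red = with_nac(pick(acceptors_for(p_second)), p_second == 2, True)
    n_nac = int(red.n_acetylated)
    mid = with_nac(mid_mon, p_first == 2, n_nac < 1)
    n_nac += int(mid.n_acetylated)
    first = with_nac(pick(DONOR_ORDER[p_first]), False, n_nac < 1)
    if rng.random() < _P_OME:
        red = replace(red, o_methyl_positions=frozenset({1}))
    links = (Linkage(1, 0, p_second, anomer()), Linkage(2, 1, p_first, anomer()))
    return canonicalize(OligoStructure((red, mid, first), links, anomer()))


#: For targeted sampling: which chain kinds can realise a (task, class) pair.
def _feasible_kinds(task: str, cls: str) -> tuple[str, ...]:
    if cls == "X":
        return ("di",)
    if task in ("ano_s", "f_link", "m_residue", "chain_type"):
        return ("tri",)
    return ("di", "tri")


@dataclass
class SimulatedDataset:
    """Records plus the generation configuration that produced them."""

    records: list[SpectrumRecord]
    generation_config: dict


def generate_dataset(
    n: int,
    balance: Mapping | None,
    model: IncrementModel,
    seed: int,
) -> SimulatedDataset:
    """Generate ``n`` labelled records with simulated spectra.

    ``balance`` may hold ``n_di`` / ``n_tri`` counts (default: a 55/45
    split mirroring a mixed di+tri study design) and ``quotas``, a
    mapping ``task -> {class: minimum count}``.  Structures are sampled
    position-first; quota deficits are then repaired by resampling
    surplus records conditioned on the lacking class.  Unsatisfiable
    quotas raise with the failing task/class.  Output is reproducible
    for a given seed.
    """
    balance = dict(balance or {})
    n_di = balance.get("n_di")
    n_tri = balance.get("n_tri")
    if n_di is None and n_tri is None:
        n_di = round(n * 0.55)
        n_tri = n - n_di
    elif n_di is None:
        n_di = n - int(n_tri)
    elif n_tri is None:
        n_tri = n - int(n_di)
    n_di, n_tri = int(n_di), int(n_tri)
    if n_di < 0 or n_tri < 0 or n_di + n_tri != n:
        raise ValueError(f"di/tri counts ({n_di}, {n_tri}) do not add up to n={n}")
    quotas: dict[str, dict[str, int]] = {t: dict(v) for t, v in balance.get("quotas", {}).items()}
    if n >= 40 and "quotas" not in balance:
        # default coverage: every class of every task represented once,
        # as far as the di/tri composition allows
        for task, alphabet in TASKS.items():
            quotas[task] = {}
            for cls in alphabet:
                kinds = _feasible_kinds(task, cls)
                if ("di" in kinds and n_di > 0) or ("tri" in kinds and n_tri > 0):
                    quotas[task][cls] = 1
    _check_quotas(quotas, n_di, n_tri)

    rng = np.random.default_rng(seed)
    kinds = ["di"] * n_di + ["tri"] * n_tri
    structures = [random_structure(rng, kind) for kind in kinds]
    _repair_quotas(structures, kinds, quotas, rng)

    seeds = np.random.SeedSequence(seed).spawn(n)
    records = []
    for i, structure in enumerate(structures):
        child_seed = int(seeds[i].generate_state(1)[0] % (2**31))
        shifts = simulate_spectrum(structure, model, child_seed)
        records.append(SpectrumRecord(id=f"SIM-{i + 1:04d}", shifts_ppm=shifts, structure=structure))
    config = {"n": n, "n_di": n_di, "n_tri": n_tri, "seed": seed, "noise_sd": model.noise_sd, "quotas": quotas}
    return SimulatedDataset(records=records, generation_config=config)


def _check_quotas(quotas: Mapping[str, Mapping[str, int]], n_di: int, n_tri: int) -> None:
    for task, classes in quotas.items():
        if task not in TASKS:
            raise ValueError(f"unknown task {task!r} in balance spec")
        tri_needed = 0
        for cls, count in classes.items():
            if cls not in TASKS[task]:
                raise ValueError(f"class {cls!r} not in alphabet of task {task}")
            kinds = _feasible_kinds(task, cls)
            if kinds == ("di",) and count > n_di:
                raise ValueError(f"quota unsatisfiable: task {task}, class {cls} needs {count} disaccharides")
            if kinds == ("tri",):
                tri_needed += count
        if tri_needed > n_tri:
            raise ValueError(f"quota unsatisfiable: task {task} needs {tri_needed} trisaccharides, have {n_tri}")


def _repair_quotas(
    structures: list[OligoStructure],
    kinds: list[str],
    quotas: Mapping[str, Mapping[str, int]],
    rng: np.random.Generator,
) -> None:
    """Resample records in place until every quota is met."""
    for _ in range(200):
        labels = [labels_from_structure(s).as_dict() for s in structures]
        deficit = None
        for task, classes in quotas.items():
            for cls, want in classes.items():
                have = sum(1 for lab in labels if lab[task] == cls)
                if have < want:
                    deficit = (task, cls, want - have)
                    break
            if deficit:
                break
        if deficit is None:
            return
        task, cls, _ = deficit
        feasible = _feasible_kinds(task, cls)
        # replace a record whose current classes are in surplus
        replace_idx = None
        for i in rng.permutation(len(structures)):
            if kinds[i] not in feasible:
                continue
            lab = labels[i]
            surplus = all(
                sum(1 for l2 in labels if l2[t] == lab[t]) > quotas.get(t, {}).get(lab[t], 0)
                for t in TASK_NAMES
            )
            if surplus:
                replace_idx = int(i)
                break
        if replace_idx is None:
            raise ValueError(f"quota unsatisfiable during repair: task {task}, class {cls}")
        structures[replace_idx] = random_structure(rng, kinds[replace_idx], constraints={task: cls})
    raise ValueError("quota repair did not converge")


def structure_with(task: str, cls: str, rng: np.random.Generator) -> OligoStructure:
    """A random structure realising class ``cls`` of ``task``."""
    kinds = _feasible_kinds(task, cls)
    kind = kinds[rng.integers(len(kinds))]
    return random_structure(rng, kind, constraints={task: cls})
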