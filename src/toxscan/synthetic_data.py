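"""Seeded generators for every input the pipeline consumes.

Three generators, each emitting a truth table alongside its data so every
downstream stage can be scored without re-deriving anything:

* sequence families with residues planted at ten anchored positions,
  spec'd indels between anchors and uniform background mutations;
* coordinate fixtures (PDB text) with partner atoms planted at exact
  distances from named catalytic-chain atoms;
* ordinal states evolved root-to-tip along a rooted tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .catalog import (
    AcceptanceClass,
    SiteCatalog,
    SiteDefinition,
    default_catalog,
    load_reference_panel,
)
from .io_formats import GAP, RootedTree, SequenceRecord
from .ancestral_states import StateModel, default_state_model

_AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubtypeSpec:
    name: str
    site_residues: tuple[str, ...]            # length 10, '-' for deletion
    indels: tuple[tuple[int, int], ...] = ()  # (interval 1-9, insert length)
    expected_class: str | None = None

    def __post_init__(self) -> None:
        if len(self.site_residues) != 10:
            raise ValueError("subtype needs exactly 10 site residues")
        for interval, length in self.indels:
            if not 1 <= interval <= 9:
                raise ValueError(f"insert interval {interval} outside 1..9")
            if length < 1:
                raise ValueError("insert length must be >= 1")


@dataclass(frozen=True)
class FamilySpec:
    scaffold_length: int = 100
    anchors: tuple[int, ...] = (10, 25, 29, 45, 52, 66, 78, 79, 81, 82)
    reference_profile: tuple[str, ...] = tuple("RIYWRVYCEF")
    subtypes: tuple[SubtypeSpec, ...] = ()
    background_prob: float = 0.0
    n_per_subtype: int = 1
    seed: int = 0
    reference_id: str = "REF"

    def __post_init__(self) -> None:
        if len(self.anchors) != 10:
            raise ValueError("exactly 10 anchors required")
        if list(self.anchors) != sorted(set(self.anchors)):
            raise ValueError("anchors must be strictly increasing")
        if self.anchors[0] < 1 or self.anchors[-1] > self.scaffold_length:
            raise ValueError("anchors must lie within the scaffold")
        if not 0.0 <= self.background_prob <= 1.0:
            raise ValueError("background probability must be in [0,1]")
        for subtype in self.subtypes:
            for interval, _ in subtype.indels:
                # an insertion goes immediately before anchor interval+1; it
                # must not displace the anchors that bound its interval
                if self.anchors[interval] - self.anchors[interval - 1] < 1:
                    raise ValueError(
                        f"indel in interval {interval} collides with anchors"
                    )


@dataclass
class FamilySample:
    reference: SequenceRecord
    catalog: SiteCatalog
    sequences: list[SequenceRecord]      # ungapped
    alignment: list[SequenceRecord]      # true MSA; reference row first
    truth: list[dict]


def _scaffold_catalog(spec: FamilySpec, base: SiteCatalog) -> SiteCatalog:
    """Catalog anchored to the synthetic scaffold, reusing the default
    acceptance classes and decision table."""
    lo = spec.anchors[9] - 12
    if lo < 1 or lo > spec.anchors[6]:
        raise ValueError(
            "anchors 7-10 must fit inside a 13-residue loop window"
        )
    sites = tuple(
        SiteDefinition(
            index=i + 1,
            position=spec.anchors[i],
            residue=spec.reference_profile[i],
            acceptance_class=base.sites[i].acceptance_class,
        )
        for i in range(10)
    )
    return SiteCatalog(
        sites=sites,
        reference_id=spec.reference_id,
        classes=base.classes,
        loop_region=(lo, lo + 12),
        consensus_sites=base.consensus_sites,
        decision=base.decision,
    )


def simulate_family(spec: FamilySpec) -> FamilySample:
    """Generate a sequence family with planted site residues and indels.

    Background mutations never touch the anchor positions, so the truth
    table remains exact.  A fixed seed yields byte-identical output.
    """
    if not spec.subtypes:
        raise ValueError("family spec has no subtypes")
    rng = np.random.default_rng(spec.seed)
    base = default_catalog()

    scaffold = list(rng.choice(list(_AA), size=spec.scaffold_length))
    anchor_idx = [a - 1 for a in spec.anchors]
    for i, idx in enumerate(anchor_idx):
        scaffold[idx] = spec.reference_profile[i]
    reference = SequenceRecord(
        id=spec.reference_id, residues="".join(scaffold)
    )
    catalog = _scaffold_catalog(spec, base)

    # column layout of the true MSA: before the anchor of site k+1, reserve
    # max-insert-length columns for interval k (inserts are right-aligned,
    # i.e. placed immediately before the downstream anchor)
    max_insert: dict[int, int] = {}
    for subtype in spec.subtypes:
        per_interval: dict[int, int] = {}
        for interval, length in subtype.indels:
            per_interval[interval] = per_interval.get(interval, 0) + length
        for interval, total in per_interval.items():
            pos = anchor_idx[interval]
            max_insert[pos] = max(max_insert.get(pos, 0), total)

    ref_aligned: list[str] = []
    for pos in range(spec.scaffold_length):
        ref_aligned.append(GAP * max_insert.get(pos, 0))
        ref_aligned.append(scaffold[pos])
    width = sum(len(p) for p in ref_aligned)

    sequences: list[SequenceRecord] = []
    aligned_rows: list[SequenceRecord] = [
        SequenceRecord(
            id=spec.reference_id, residues="".join(ref_aligned), aligned=True
        )
    ]
    truth: list[dict] = []
    anchor_set = set(anchor_idx)
    for subtype in spec.subtypes:
        insert_at: dict[int, int] = {}
        for interval, length in subtype.indels:
            pos = anchor_idx[interval]
            insert_at[pos] = insert_at.get(pos, 0) + length
        deleted = {
            anchor_idx[i]
            for i in range(10)
            if subtype.site_residues[i] == GAP
        }
        insert_lengths = [0] * 9
        for interval, length in subtype.indels:
            insert_lengths[interval - 1] += length

        for rep in range(spec.n_per_subtype):
            chars = list(scaffold)
            for pos in range(spec.scaffold_length):
                if pos in anchor_set:
                    continue
                if rng.random() < spec.background_prob:
                    alternatives = [a for a in _AA if a != chars[pos]]
                    chars[pos] = alternatives[rng.integers(len(alternatives))]
            for i, idx in enumerate(anchor_idx):
                chars[idx] = subtype.site_residues[i]

            plain: list[str] = []
            gapped: list[str] = []
            for pos in range(spec.scaffold_length):
                slot = max_insert.get(pos, 0)
                if slot:
                    length = insert_at.get(pos, 0)
                    insert = "".join(rng.choice(list(_AA), size=length))
                    plain.append(insert)
                    gapped.append(GAP * (slot - length) + insert)
                if pos in deleted:
                    gapped.append(GAP)
                else:
                    plain.append(chars[pos])
                    gapped.append(chars[pos])

            seq_id = f"{subtype.name}_{rep:03d}"
            sequences.append(
                SequenceRecord(id=seq_id, residues="".join(plain))
            )
            aligned_rows.append(
                SequenceRecord(
                    id=seq_id, residues="".join(gapped), aligned=True
                )
            )
            assert len(aligned_rows[-1].residues) == width
            truth.append(
                {
                    "sequence_id": seq_id,
                    "subtype": subtype.name,
                    "site_residues": subtype.site_residues,
                    "insertion_lengths": tuple(insert_lengths),
                    "expected_class": subtype.expected_class,
                }
            )
    return FamilySample(
        reference=reference,
        catalog=catalog,
        sequences=sequences,
        alignment=aligned_rows,
        truth=truth,
    )


def panel_subtypes() -> tuple[SubtypeSpec, ...]:
    """The eight literature phosphatase rows as planted subtypes."""
    subtypes = []
    for row in load_reference_panel():
        residues = tuple(row[f"site{i}"] for i in range(1, 11))
        indels = []
        if row.get("inserts"):
            for item in row["inserts"].split(","):
                interval, length = item.split(":")
                indels.append((int(interval), int(length)))
        subtypes.append(
            SubtypeSpec(
                name=row["phosphatase"].replace("-", "_"),
                site_residues=residues,
                indels=tuple(indels),
                expected_class=row["reported_class"],
            )
        )
    return tuple(subtypes)


# ---------------------------------------------------------------------------
# coordinate fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedAtom:
    target_residue: int
    distance: float            # to the named target atom, exact
    element: str = "C"
    target_atom: str = "CA"    # "CA" (carbon) or "O" (carbonyl oxygen)

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("planted distance must be positive")


@dataclass(frozen=True)
class StructureFixtureSpec:
    residue_numbers: tuple[int, ...]
    planted: tuple[PlantedAtom, ...] = ()
    partner_is_ligand: bool = False
    ligand_id: str = "LIG"
    spacing: float = 8.0
    seed: int = 0


def _pdb_line(serial: int, name: str, resname: str, chain: str, resnum: int,
              x: float, y: float, z: float, element: str,
              het: bool = False) -> str:
    record = "HETATM" if het else "ATOM  "
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:>5d} {pad_name:<4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}{'':1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}"
        f"{0.0:>6.2f}          {element:>2s}"
    )


def simulate_structure_fixture(spec: StructureFixtureSpec) -> tuple[str, list[dict]]:
    """PDB text with partner atoms at exact planted distances, plus truth.

    Catalytic chain A holds one residue per entry of ``residue_numbers``
    (a CA carbon and a carbonyl O, 1.23 A apart, spaced ``spacing`` A along
    x).  Each planted partner atom sits exactly ``distance`` A from its
    named target atom, along -z, so the planted pair is always the
    minimum-distance pair for that residue.
    """
    positions: dict[tuple[int, str], tuple[float, float, float]] = {}
    lines: list[str] = []
    serial = 1
    for k, resnum in enumerate(spec.residue_numbers):
        x = round(spec.spacing * k, 3)
        positions[(resnum, "CA")] = (x, 0.0, 0.0)
        positions[(resnum, "O")] = (x, 1.23, 0.0)
        lines.append(_pdb_line(serial, "CA", "ALA", "A", resnum, x, 0.0, 0.0, "C"))
        serial += 1
        lines.append(_pdb_line(serial, "O", "ALA", "A", resnum, x, 1.23, 0.0, "O"))
        serial += 1

    truth: list[dict] = []
    het = spec.partner_is_ligand
    partner_chain = "B"
    resname = spec.ligand_id if het else "GLY"
    for i, planted in enumerate(spec.planted):
        if planted.target_residue not in spec.residue_numbers:
            raise ValueError(
                f"planted atom targets unknown residue {planted.target_residue}"
            )
        tx, ty, tz = positions[(planted.target_residue, planted.target_atom)]
        coords = (tx, ty, round(tz - planted.distance, 3))
        name = f"{planted.element}{i + 1}"
        resnum = 1 if het else i + 1
        lines.append(
            _pdb_line(serial, name, resname, partner_chain, resnum,
                      *coords, planted.element, het=het)
        )
        serial += 1
        truth.append(
            {
                "residue_number": planted.target_residue,
                "target_atom": planted.target_atom,
                "distance": planted.distance,
                "partner_element": planted.element,
                "partner_atom": name,
            }
        )
    lines.append("END")
    return "\n".join(lines) + "\n", truth


def write_structure_fixture(spec: StructureFixtureSpec,
                            path: str | Path) -> list[dict]:
    text, truth = simulate_structure_fixture(spec)
    Path(path).write_text(text, encoding="utf-8")
    return truth


# ---------------------------------------------------------------------------
# states on trees
# ---------------------------------------------------------------------------

def simulate_states_on_tree(tree: RootedTree, change_prob: float,
                            root_state: str,
                            model: StateModel | None = None,
                            seed: int = 0) -> tuple[dict[int, str], dict[str, str]]:
    """Evolve ordinal states root-to-tip with single +-1 rank steps.

    Returns (true state per node index, tip label -> state).
    """
    if not 0.0 <= change_prob < 1.0:
        raise ValueError("change probability must be in [0,1)")
    model = model or default_state_model()
    rng = np.random.default_rng(seed)
    states: dict[int, str] = {}
    states[tree.root.index] = root_state
    model.rank(root_state)  # validates

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_rank = model.rank(states[node.parent.index])
        rank = parent_rank
        if rng.random() < change_prob:
            if rank == 0:
                rank += 1
            elif rank == model.n - 1:
                rank -= 1
            else:
                rank += 1 if rng.random() < 0.5 else -1
        states[node.index] = model.states[rank]

    tip_states = {t.label: states[t.index] for t in tree.tips()}
    return states, tip_states


def random_tree(n_tips: int, seed: int = 0,
                branch_length: float = 1.0) -> RootedTree:
    """Random rooted binary tree grown by sequential tip attachment."""
    from .io_formats import TreeNode

    if n_tips < 1:
        raise ValueError("need at least one tip")
    rng = np.random.default_rng(seed)
    root = TreeNode(label="T0" if n_tips == 1 else None, length=None)
    tips = [root]
    for i in range(1, n_tips):
        target = tips[int(rng.integers(len(tips)))]
        left = TreeNode(label=target.label, length=branch_length, parent=target)
        right = TreeNode(label=f"T{i}", length=branch_length, parent=target)
        target.label = None
        target.children = [left, right]
        tips.remove(target)
        tips.extend([left, right])
    if n_tips == 1:
        root.label = "T0"
    else:
        for tip in tips:
            if tip.label is None:
                tip.label = "T0"
    return RootedTree(root)
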