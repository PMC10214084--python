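"""Readers and writers for the standard formats the pipeline touches.

Every other module consumes only the in-memory types defined here:
:class:`SequenceRecord` for (aligned) FASTA, :class:`CoordinateModel` for
PDB/mmCIF coordinate files and :class:`RootedTree` for Newick trees.
Report tables are plain TSV with ``-`` for missing cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
from Bio import SeqIO
from Bio.PDB import MMCIFParser, PDBParser

logger = logging.getLogger(__name__)

GAP = "-"
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: letters outside the 20-letter alphabet that are normalised to 'X'
_AMBIGUOUS = {"U": "X", "O": "X", "B": "X", "Z": "X", "J": "X"}
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence, optionally gapped when part of an alignment."""

    id: str
    residues: str
    description: str = ""
    aligned: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.aligned and GAP in self.residues:
            raise ValueError(
                f"unaligned record {self.id!r} contains gap characters"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


def _normalise_residues(raw: str, record_id: str) -> str:
    seq = raw.upper().replace(".", GAP).rstrip("*")
    out = []
    for ch in seq:
        if ch in AMINO_ACIDS or ch in (GAP, "X"):
            out.append(ch)
        elif ch in _AMBIGUOUS:
            logger.warning(
                "record %s: residue %r mapped to X", record_id, ch
            )
            out.append("X")
        else:
            raise ValueError(
                f"record {record_id!r}: invalid residue character {ch!r}"
            )
    return "".join(out)


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    With ``aligned=True`` all records must have equal length; gap characters
    ('-' or '.') are permitted and normalised to '-'.  Duplicate ids and
    ragged aligned input are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _normalise_residues(str(rec.seq), rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                description=rec.description,
                aligned=aligned,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if aligned:
        length = len(records[0])
        for rec in records:
            if len(rec) != length:
                raise ValueError(
                    f"ragged alignment: record {rec.id!r} has length "
                    f"{len(rec)}, expected {length}"
                )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def is_heavy(self) -> bool:
        return self.element not in ("H", "D")


@dataclass
class ResidueCoords:
    number: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)


@dataclass
class LigandGroup:
    chain_id: str
    component_id: str
    number: int
    icode: str
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class ChainCoords:
    id: str
    residues: list[ResidueCoords] = field(default_factory=list)

    def residue(self, number: int, icode: str = " ") -> ResidueCoords | None:
        for res in self.residues:
            if res.number == number and res.icode == icode:
                return res
        return None


@dataclass
class CoordinateModel:
    """First model of a coordinate file: polymer chains plus het groups."""

    chains: dict[str, ChainCoords] = field(default_factory=dict)
    ligands: list[LigandGroup] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        n = sum(len(r.atoms) for c in self.chains.values() for r in c.residues)
        return n + sum(len(l.atoms) for l in self.ligands)

    def ligand_components(self) -> list[str]:
        return sorted({l.component_id for l in self.ligands})


def _pick_atoms(bio_residue) -> list[Atom]:
    """Resolve altlocs to the highest-occupancy conformer (ties: first seen)."""
    atoms = []
    for atom in bio_residue:
        if atom.is_disordered():
            children = list(atom.disordered_get_list())
            best = max(
                range(len(children)),
                key=lambda i: (children[i].get_occupancy() or 0.0, -i),
            )
            atom = children[best]
        coord = atom.get_coord()
        if not all(math.isfinite(float(v)) for v in coord):
            raise ValueError(f"non-finite coordinate on atom {atom.get_name()}")
        element = (atom.element or "").strip().upper()
        atoms.append(
            Atom(
                name=atom.get_name(),
                element=element,
                x=float(coord[0]),
                y=float(coord[1]),
                z=float(coord[2]),
            )
        )
    return atoms


def _looks_like_mmcif(path: Path) -> bool:
    if path.suffix.lower() in (".cif", ".mmcif"):
        return True
    if path.suffix.lower() in (".pdb", ".ent"):
        return False
    with open(path, "r", errors="replace") as fh:
        head = fh.read(4096)
    return head.lstrip().startswith("data_") or "_atom_site." in head


def read_structure(path: str | Path, include_waters: bool = False) -> CoordinateModel:
    """Parse a PDB or mmCIF file (auto-detected) into a :class:`CoordinateModel`.

    Only the first model of multi-model files is returned; alternate
    locations are resolved to the highest-occupancy conformer; waters are
    excluded unless ``include_waters`` is set.
    """
    path = Path(path)
    parser = MMCIFParser(QUIET=True) if _looks_like_mmcif(path) else PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ValueError(f"cannot parse coordinate file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise ValueError(f"no models in coordinate file {path}")
    model = models[0]

    out = CoordinateModel()
    for chain in model:
        chain_out = ChainCoords(id=chain.id)
        for residue in chain:
            hetflag, resnum, icode = residue.get_id()
            name = residue.get_resname().strip()
            if hetflag == "W" or name in _WATER_NAMES:
                if not include_waters:
                    continue
            atoms = _pick_atoms(residue)
            if hetflag.startswith("H_"):
                out.ligands.append(
                    LigandGroup(
                        chain_id=chain.id,
                        component_id=name,
                        number=int(resnum),
                        icode=icode,
                        atoms=atoms,
                    )
                )
            else:
                chain_out.residues.append(
                    ResidueCoords(
                        number=int(resnum), icode=icode, name=name, atoms=atoms
                    )
                )
        if chain_out.residues:
            seen_keys = set()
            for res in chain_out.residues:
                if res.key in seen_keys:
                    raise ValueError(
                        f"duplicate residue {res.key} in chain {chain.id}"
                    )
                seen_keys.add(res.key)
            out.chains[chain_out.id] = chain_out
    if out.n_atoms == 0:
        raise ValueError(f"empty model in coordinate file {path}")
    return out


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class TreeNode:
    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None
    index: int = -1

    @property
    def is_tip(self) -> bool:
        return not self.children


class RootedTree:
    """Rooted tree with parent pointers and unique tip labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._reindex()
        labels = [t.label for t in self.tips()]
        if any(lbl is None for lbl in labels):
            raise ValueError("every tip must carry a label")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        for node in self.preorder():
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length")

    def _reindex(self) -> None:
        for i, node in enumerate(self.preorder()):
            node.index = i

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = list(self.preorder())
        return reversed(out)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_tip]

    def n_nodes(self) -> int:
        return sum(1 for _ in self.preorder())


def _check_parentheses(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(
                    f"unbalanced parenthesis in Newick at position {pos}"
                )
    if depth != 0:
        raise ValueError(
            f"unbalanced parentheses in Newick: {depth} unclosed at end of string"
        )


def _convert_dendropy(dnode, parent: TreeNode | None) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = TreeNode(label=label, length=dnode.edge.length, parent=parent)
    for child in dnode.child_nodes():
        node.children.append(_convert_dendropy(child, node))
    return node


def read_newick(path: str | Path) -> RootedTree:
    """Read a single rooted Newick tree; basal polytomies are allowed."""
    text = Path(path).read_text(encoding="utf-8").strip()
    if not text.endswith(";"):
        raise ValueError("Newick string must end with ';'")
    _check_parentheses(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse Newick in {path}: {exc}") from exc
    root = _convert_dendropy(dtree.seed_node, None)
    return RootedTree(root)


def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string (convenience wrapper around :func:`read_newick`)."""
    import tempfile

    with tempfile.NamedTemporaryFile(
        "w", suffix=".nwk", delete=False, encoding="utf-8"
    ) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_newick(name)
    finally:
        Path(name).unlink(missing_ok=True)


def _newick_node(node: TreeNode, comments: Mapping[int, str] | None) -> str:
    if node.children:
        inner = ",".join(_newick_node(c, comments) for c in node.children)
        text = f"({inner})"
        if node.label:
            text += node.label
    else:
        text = node.label or ""
    if comments and node.index in comments:
        text += f"[&{comments[node.index]}]"
    if node.length is not None:
        text += f":{node.length:g}"
    return text


def write_newick(tree: RootedTree, path: str | Path,
                 comments: Mapping[int, str] | None = None) -> None:
    """Write a tree to Newick; ``comments`` maps node index -> comment body."""
    Path(path).write_text(
        _newick_node(tree.root, comments) + ";\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

MISSING = "-"


def write_report_table(rows: Sequence[Mapping[str, object]],
                       columns: Sequence[str], path: str | Path,
                       header_comment: str | None = None) -> None:
    """Write rows as a TSV with a stable column order and '-' for missing."""
    columns = list(columns)
    colset = set(columns)
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        for i, row in enumerate(rows):
            extra = set(row) - colset
            if extra:
                raise ValueError(
                    f"row {i} has keys not in column spec: {sorted(extra)}"
                )
            cells = []
            for col in columns:
                value = row.get(col)
                cells.append(MISSING if value is None else str(value))
            fh.write("\t".join(cells) + "\n")


def read_report_table(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    """Read a TSV produced by :func:`write_report_table`."""
    lines = [
        line.rstrip("\n")
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if not line.startswith("#")
    ]
    if not lines:
        raise ValueError(f"empty report table {path}")
    columns = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(columns):
            raise ValueError(f"row width mismatch in {path}: {line!r}")
        rows.append(dict(zip(columns, cells)))
    return columns, rows
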