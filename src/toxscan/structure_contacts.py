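"""Census of catalytic-subunit residues contacting a regulator chain or ligand.

Contact criterion: any heavy-atom pair within a cutoff (default 4.0 A).
A contact is POLAR when the minimum-distance pair involves N/O/S on both
sides, or when any N/O--N/O pair falls inside the hydrogen-bond cutoff
(default 3.5 A); angle criteria are not applied because crystal structures
carry no hydrogens.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .catalog import SiteCatalog
from .io_formats import Atom, CoordinateModel, LigandGroup, ResidueCoords

logger = logging.getLogger(__name__)

DEFAULT_CONTACT_CUTOFF = 4.0
DEFAULT_HBOND_CUTOFF = 3.5
_POLAR_ELEMENTS = frozenset({"N", "O", "S"})
_HBOND_ELEMENTS = frozenset({"N", "O"})


class PartnerKind(enum.Enum):
    LIGAND = "LIGAND"
    CHAIN = "CHAIN"


class ContactType(enum.Enum):
    POLAR = "POLAR"
    NONPOLAR = "NONPOLAR"


@dataclass(frozen=True)
class ContactRecord:
    catalytic_chain: str
    residue_number: int
    residue_name: str
    partner_kind: PartnerKind
    partner_id: str               # chain id, or ligand component id
    partner_detail: str           # closest partner residue/atom
    min_distance: float
    contact_type: ContactType
    hbond: bool = False
    site_index: int | None = None
    loop_member: bool = False

    def __post_init__(self) -> None:
        if self.site_index is not None and not 1 <= self.site_index <= 10:
            raise ValueError("site index out of range")
        if self.hbond and self.contact_type is not ContactType.POLAR:
            raise ValueError("hydrogen bond implies a polar contact")


def _heavy(atoms: Iterable[Atom]) -> list[Atom]:
    return [a for a in atoms if a.is_heavy]


def _coords(atoms: list[Atom]) -> np.ndarray:
    return np.array([a.coord for a in atoms], dtype=float)


def _classify_pair(res_atoms: list[Atom], partner_atoms: list[Atom],
                   dist: np.ndarray, hbond_cutoff: float) -> ContactType:
    i, j = np.unravel_index(int(np.argmin(dist)), dist.shape)
    a, b = res_atoms[i], partner_atoms[j]
    if a.element in _POLAR_ELEMENTS and b.element in _POLAR_ELEMENTS:
        return ContactType.POLAR
    no_rows = [k for k, at in enumerate(res_atoms) if at.element in _HBOND_ELEMENTS]
    no_cols = [k for k, at in enumerate(partner_atoms) if at.element in _HBOND_ELEMENTS]
    if no_rows and no_cols and dist[np.ix_(no_rows, no_cols)].min() <= hbond_cutoff:
        return ContactType.POLAR
    return ContactType.NONPOLAR


def _contacts_against(model: CoordinateModel, cat_chain: str,
                      residue_set: Iterable[int],
                      partner_atoms: list[Atom],
                      partner_kind: PartnerKind, partner_id: str,
                      partner_labels: list[str],
                      cutoff: float, hbond_cutoff: float,
                      roi: Mapping[int, int | None] | None,
                      loop_positions: frozenset[int]) -> list[ContactRecord]:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cat_chain not in model.chains:
        raise KeyError(f"chain {cat_chain!r} not in model")
    partner_heavy = _heavy(partner_atoms)
    if not partner_heavy:
        raise ValueError("partner has no heavy atoms")
    partner_xyz = _coords(partner_heavy)
    heavy_labels = [
        lbl for lbl, a in zip(partner_labels, partner_atoms) if a.is_heavy
    ]

    chain = model.chains[cat_chain]
    records: list[ContactRecord] = []
    for number in sorted(set(residue_set)):
        residue = chain.residue(number)
        if residue is None:
            logger.warning(
                "residue %d absent from chain %s; skipped", number, cat_chain
            )
            continue
        res_heavy = _heavy(residue.atoms)
        if not res_heavy:
            continue
        dist = cdist(_coords(res_heavy), partner_xyz)
        dmin = float(dist.min())
        if dmin > cutoff:
            continue
        j = int(np.argmin(dist.min(axis=0)))
        records.append(
            ContactRecord(
                catalytic_chain=cat_chain,
                residue_number=number,
                residue_name=residue.name,
                partner_kind=partner_kind,
                partner_id=partner_id,
                partner_detail=heavy_labels[j],
                min_distance=dmin,
                contact_type=_classify_pair(
                    res_heavy, partner_heavy, dist, hbond_cutoff
                ),
                site_index=roi.get(number) if roi else None,
                loop_member=number in loop_positions,
            )
        )
    return records


def residue_contacts(model: CoordinateModel, cat_chain: str,
                     residue_set: Iterable[int], partner_chain: str,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
                     roi: Mapping[int, int | None] | None = None,
                     loop_positions: Iterable[int] = ()) -> list[ContactRecord]:
    """Contacts between catalytic-chain residues and a partner chain.

    One record per residue of ``residue_set`` (author numbering) with at
    least one heavy-atom pair within ``cutoff`` of any partner-chain heavy
    atom.  ``roi`` optionally maps author numbers to catalog site indices.
    """
    if partner_chain not in model.chains:
        raise KeyError(f"partner chain {partner_chain!r} not in model")
    partner_atoms: list[Atom] = []
    labels: list[str] = []
    for res in model.chains[partner_chain].residues:
        for atom in res.atoms:
            partner_atoms.append(atom)
            labels.append(f"{res.name}{res.number}:{atom.name}")
    return _contacts_against(
        model, cat_chain, residue_set, partner_atoms, PartnerKind.CHAIN,
        partner_chain, labels, cutoff, hbond_cutoff, roi,
        frozenset(loop_positions),
    )


def ligand_contacts(model: CoordinateModel, cat_chain: str,
                    residue_set: Iterable[int], ligand_component_id: str,
                    cutoff: float = DEFAULT_CONTACT_CUTOFF,
                    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
                    roi: Mapping[int, int | None] | None = None,
                    loop_positions: Iterable[int] = ()) -> list[ContactRecord]:
    """Contacts between catalytic-chain residues and a het-group ligand."""
    groups = [
        l for l in model.ligands if l.component_id == ligand_component_id
    ]
    if not groups:
        raise KeyError(
            f"ligand {ligand_component_id!r} absent; present het groups: "
            f"{model.ligand_components()}"
        )
    atoms: list[Atom] = []
    labels: list[str] = []
    for group in groups:
        for atom in group.atoms:
            atoms.append(atom)
            labels.append(f"{group.component_id}:{atom.name}")
    return _contacts_against(
        model, cat_chain, residue_set, atoms, PartnerKind.LIGAND,
        ligand_component_id, labels, cutoff, hbond_cutoff, roi,
        frozenset(loop_positions),
    )


def detect_hbonds(records: list[ContactRecord], model: CoordinateModel,
                  donor_acceptor_cutoff: float = DEFAULT_HBOND_CUTOFF
                  ) -> list[ContactRecord]:
    """Annotate records whose residue has an N/O atom within the donor-acceptor
    cutoff of a partner N/O atom; such contacts are promoted to POLAR."""
    out: list[ContactRecord] = []
    for rec in records:
        chain = model.chains[rec.catalytic_chain]
        residue = chain.residue(rec.residue_number)
        res_no = [
            a for a in residue.atoms
            if a.is_heavy and a.element in _HBOND_ELEMENTS
        ]
        partner_no: list[Atom] = []
        if rec.partner_kind is PartnerKind.LIGAND:
            for group in model.ligands:
                if group.component_id == rec.partner_id:
                    partner_no.extend(
                        a for a in group.atoms
                        if a.is_heavy and a.element in _HBOND_ELEMENTS
                    )
        else:
            for res in model.chains[rec.partner_id].residues:
                partner_no.extend(
                    a for a in res.atoms
                    if a.is_heavy and a.element in _HBOND_ELEMENTS
                )
        hbond = False
        if res_no and partner_no:
            dist = cdist(_coords(res_no), _coords(partner_no))
            hbond = bool(dist.min() <= donor_acceptor_cutoff)
        if hbond:
            out.append(
                replace(rec, hbond=True, contact_type=ContactType.POLAR)
            )
        else:
            out.append(replace(rec, hbond=False))
    return out


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionSummary:
    per_regulator: dict[str, int]      # distinct residues-of-interest in contact
    site_usage: dict[int, int]         # site index -> number of regulators
    loop_usage: dict[int, int]         # loop reference position -> regulators
    n_sites_used: int
    n_loop_used: int


def catalog_roi(catalog: SiteCatalog, offset: int = 0) -> dict[int, int | None]:
    """Residues of interest in author numbering: site positions (mapped to
    their site index) plus loop positions (mapped to None), shifted by a
    per-structure numbering offset."""
    roi: dict[int, int | None] = {
        pos + offset: None for pos in catalog.loop_positions()
    }
    for site in catalog.sites:
        roi[site.position + offset] = site.index
    return roi


def interaction_summary(census: Mapping[str, list[ContactRecord]],
                        catalog: SiteCatalog,
                        offsets: Mapping[str, int] | None = None
                        ) -> InteractionSummary:
    """Aggregate per-regulator contact records into usage counts.

    ``census`` maps a regulator name to its contact records; ``offsets``
    optionally gives the author-numbering offset used for that structure so
    loop positions can be reported in reference coordinates.
    """
    per_regulator: dict[str, int] = {}
    site_users: dict[int, set[str]] = {s.index: set() for s in catalog.sites}
    loop_users: dict[int, set[str]] = {p: set() for p in catalog.loop_positions()}

    for regulator, records in census.items():
        offset = (offsets or {}).get(regulator, 0)
        residues = set()
        for rec in records:
            if rec.site_index is None and not rec.loop_member:
                continue
            residues.add(rec.residue_number)
            if rec.site_index is not None:
                site_users[rec.site_index].add(regulator)
            if rec.loop_member:
                loop_users.setdefault(rec.residue_number - offset, set()).add(regulator)
        per_regulator[regulator] = len(residues)

    site_usage = {idx: len(users) for idx, users in site_users.items()}
    loop_usage = {pos: len(users) for pos, users in loop_users.items()}
    return InteractionSummary(
        per_regulator=per_regulator,
        site_usage=site_usage,
        loop_usage=loop_usage,
        n_sites_used=sum(1 for v in site_usage.values() if v > 0),
        n_loop_used=sum(1 for v in loop_usage.values() if v > 0),
    )
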