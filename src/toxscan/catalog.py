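"""Binding-site catalog: ten anchored sites, acceptance classes, decision table.

The default catalog anchors the ten okadaic-acid binding sites to human PP1
numbering (R96, I130, Y134, W206, R221, V250, Y272, C273, E275, F276) and
carries the per-site residue acceptance classes plus the four-level
sensitivity decision table.  Everything is editable through a YAML config so
alternative rule sets never require code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .io_formats import AMINO_ACIDS

N_SITES = 10
LOOP_LENGTH = 13


@dataclass(frozen=True)
class AcceptanceClass:
    """A named set of residues accepted at a site."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        bad = self.members - AMINO_ACIDS
        if bad:
            raise ValueError(
                f"acceptance class {self.name!r} has non-residue members {sorted(bad)}"
            )

    def __contains__(self, residue: str) -> bool:
        return residue in self.members


@dataclass(frozen=True)
class SiteDefinition:
    index: int
    position: int          # 1-based position in the ungapped reference
    residue: str           # expected reference residue (numbering guard)
    acceptance_class: str  # class name looked up in the catalog

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_SITES:
            raise ValueError(f"site index {self.index} outside 1..{N_SITES}")
        if self.position < 1:
            raise ValueError("reference position must be >= 1")


@dataclass(frozen=True)
class DecisionTable:
    """Parameters of the four-level sensitivity decision."""

    gross_min_violations: int = 3
    gross_insert_min_length: int = 6
    gross_insert_intervals: frozenset[int] = frozenset({5, 6, 7})
    insensitive_sites: frozenset[int] = frozenset({8, 10})
    insensitive_residues: frozenset[str] = frozenset("FWYDEKRH")


@dataclass(frozen=True)
class SiteCatalog:
    sites: tuple[SiteDefinition, ...]
    reference_id: str
    classes: dict[str, AcceptanceClass]
    loop_region: tuple[int, int] = (268, 280)
    consensus_sites: frozenset[int] = frozenset({6, 8, 9, 10})
    decision: DecisionTable = field(default_factory=DecisionTable)

    def __post_init__(self) -> None:
        if len(self.sites) != N_SITES:
            raise ValueError(f"catalog must define exactly {N_SITES} sites")
        positions = [s.position for s in self.sites]
        if positions != sorted(set(positions)):
            raise ValueError("site positions must be strictly increasing")
        if [s.index for s in self.sites] != list(range(1, N_SITES + 1)):
            raise ValueError("site indices must be 1..10 in order")
        lo, hi = self.loop_region
        if hi - lo + 1 != LOOP_LENGTH:
            raise ValueError(
                f"loop region must span {LOOP_LENGTH} residues, got {hi - lo + 1}"
            )
        for site in self.sites[6:]:  # sites 7-10 sit inside the loop
            if not lo <= site.position <= hi:
                raise ValueError(
                    f"site {site.index} at {site.position} outside loop region"
                )
        for site in self.sites:
            if site.acceptance_class not in self.classes:
                raise ValueError(
                    f"site {site.index} references unknown class "
                    f"{site.acceptance_class!r}"
                )

    def site(self, index: int) -> SiteDefinition:
        if not 1 <= index <= N_SITES:
            raise ValueError(f"invalid site index {index}")
        return self.sites[index - 1]

    def acceptance(self, index: int) -> AcceptanceClass:
        return self.classes[self.site(index).acceptance_class]

    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.sites)

    def loop_positions(self) -> tuple[int, ...]:
        lo, hi = self.loop_region
        return tuple(range(lo, hi + 1))

    def with_reference(self, reference_id: str) -> "SiteCatalog":
        return replace(self, reference_id=reference_id)


def _parse_decision(raw: dict) -> DecisionTable:
    return DecisionTable(
        gross_min_violations=int(raw.get("gross_min_violations", 3)),
        gross_insert_min_length=int(raw.get("gross_insert_min_length", 6)),
        gross_insert_intervals=frozenset(
            int(i) for i in raw.get("gross_insert_intervals", (5, 6, 7))
        ),
        insensitive_sites=frozenset(
            int(i) for i in raw.get("insensitive_sites", (8, 10))
        ),
        insensitive_residues=frozenset(raw.get("insensitive_residues", "FWYDEKRH")),
    )


def catalog_from_dict(raw: dict) -> SiteCatalog:
    classes = {
        name: AcceptanceClass(name=name, members=frozenset(str(members)))
        for name, members in raw["classes"].items()
    }
    sites = tuple(
        SiteDefinition(
            index=int(s["index"]),
            position=int(s["position"]),
            residue=str(s["residue"]),
            acceptance_class=str(s["class"]),
        )
        for s in sorted(raw["sites"], key=lambda s: int(s["index"]))
    )
    loop = tuple(int(v) for v in raw.get("loop_region", (268, 280)))
    return SiteCatalog(
        sites=sites,
        reference_id=str(raw["reference_id"]),
        classes=classes,
        loop_region=(loop[0], loop[1]),
        consensus_sites=frozenset(
            int(i) for i in raw.get("consensus_sites", (6, 8, 9, 10))
        ),
        decision=_parse_decision(raw.get("decision", {})),
    )


def catalog_to_dict(catalog: SiteCatalog) -> dict:
    return {
        "reference_id": catalog.reference_id,
        "loop_region": list(catalog.loop_region),
        "sites": [
            {
                "index": s.index,
                "position": s.position,
                "residue": s.residue,
                "class": s.acceptance_class,
            }
            for s in catalog.sites
        ],
        "classes": {
            name: "".join(sorted(cls.members))
            for name, cls in catalog.classes.items()
        },
        "consensus_sites": sorted(catalog.consensus_sites),
        "decision": {
            "gross_min_violations": catalog.decision.gross_min_violations,
            "gross_insert_min_length": catalog.decision.gross_insert_min_length,
            "gross_insert_intervals": sorted(
                catalog.decision.gross_insert_intervals
            ),
            "insensitive_sites": sorted(catalog.decision.insensitive_sites),
            "insensitive_residues": "".join(
                sorted(catalog.decision.insensitive_residues)
            ),
        },
    }


def save_catalog(catalog: SiteCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(catalog_to_dict(catalog), fh, sort_keys=False)


def load_catalog(path: str | Path) -> SiteCatalog:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return catalog_from_dict(raw)


def default_catalog() -> SiteCatalog:
    text = (
        resources.files("toxscan.data")
        .joinpath("default_catalog.yaml")
        .read_text(encoding="utf-8")
    )
    return catalog_from_dict(yaml.safe_load(text))


def load_reference_panel() -> list[dict[str, str]]:
    """Literature panel: residues at the ten sites, IC50 and reported class.

    Returns one dict per phosphatase with keys ``phosphatase``, ``accession``,
    ``oa_ic50`` (nM, possibly qualified with '>', '~' or a range 'a-b'),
    ``reported_class``, ``site1`` .. ``site10`` and ``inserts``
    (semi-colon free ``interval:length`` pairs, comma separated).
    """
    text = (
        resources.files("toxscan.data")
        .joinpath("reference_panel.tsv")
        .read_text(encoding="utf-8")
    )
    lines = [l for l in text.splitlines() if l.strip()]
    columns = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        cells = line.split("\t")
        cells += [""] * (len(columns) - len(cells))
        rows.append(dict(zip(columns, cells)))
    return rows


def ic50_lower_bound_nM(text: str) -> float:
    """Lower bound in nM of a qualified IC50 string ('15-50', '>1000', '~1')."""
    text = text.strip().lstrip(">~").replace("–", "-")
    if "-" in text:
        text = text.split("-")[0]
    return float(text)
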