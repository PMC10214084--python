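"""Consensus acceptance rules and the four-level okadaic-acid sensitivity call.

The per-site acceptance classes and the decision table both live in the
catalog config; this module is a pure rule engine over
:class:`~toxscan.site_mapping.SiteProfile` objects.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .catalog import N_SITES, SiteCatalog
from .io_formats import GAP
from .site_mapping import SiteProfile


class SiteStatus(enum.Enum):
    CONFORMS = "CONFORMS"
    VIOLATES = "VIOLATES"
    GAP = "GAP"


class SensitivityClass(enum.IntEnum):
    """Ordinal sensitivity classes, worst (lowest) to best (highest)."""

    GROSSLY_INSENSITIVE = 0
    INSENSITIVE = 1
    MODERATELY_SENSITIVE = 2
    SENSITIVE = 3

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "SensitivityClass":
        for value, name in _LABELS.items():
            if name == label:
                return value
        raise ValueError(f"unknown sensitivity class {label!r}")


_LABELS = {
    SensitivityClass.GROSSLY_INSENSITIVE: "GrosslyInsensitive",
    SensitivityClass.INSENSITIVE: "Insensitive",
    SensitivityClass.MODERATELY_SENSITIVE: "ModeratelySensitive",
    SensitivityClass.SENSITIVE: "Sensitive",
}


@dataclass(frozen=True)
class ViolationProfile:
    sequence_id: str
    statuses: tuple[SiteStatus, ...]           # one per site 1-10
    violating_sites: frozenset[int]            # subset of the consensus sites
    deletions: frozenset[int]                  # sites with a GAP
    insertions: tuple[tuple[int, int], ...]    # (interval index 1-9, length)
    site_residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.statuses) != N_SITES:
            raise ValueError("need exactly 10 site statuses")


@dataclass(frozen=True)
class SensitivityCall:
    sensitivity: SensitivityClass
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("rationale must not be empty")


def evaluate_site(site_index: int, residue_or_gap: str,
                  catalog: SiteCatalog) -> SiteStatus:
    """Judge one residue (or gap) against its site's acceptance class."""
    acceptance = catalog.acceptance(site_index)  # validates the index
    if residue_or_gap == GAP:
        return SiteStatus.GAP
    if residue_or_gap in acceptance:
        return SiteStatus.CONFORMS
    return SiteStatus.VIOLATES


def violation_profile(profile: SiteProfile,
                      catalog: SiteCatalog) -> ViolationProfile:
    statuses = tuple(
        evaluate_site(i + 1, profile.site_residues[i], catalog)
        for i in range(N_SITES)
    )
    violating = frozenset(
        i + 1
        for i in range(N_SITES)
        if (i + 1) in catalog.consensus_sites
        and statuses[i] is not SiteStatus.CONFORMS
    )
    deletions = frozenset(
        i + 1 for i in range(N_SITES) if statuses[i] is SiteStatus.GAP
    )
    insertions = tuple(
        (k + 1, length)
        for k, length in enumerate(profile.insertion_lengths)
        if length > 0
    )
    return ViolationProfile(
        sequence_id=profile.sequence_id,
        statuses=statuses,
        violating_sites=violating,
        deletions=deletions,
        insertions=insertions,
        site_residues=profile.site_residues,
    )


def classify_sensitivity(vp: ViolationProfile,
                         catalog: SiteCatalog) -> SensitivityCall:
    """Map a violation profile to one of the four ordinal sensitivity classes.

    Decision table (explicit post-hoc codification, editable in config):

    * no consensus-site violations -> Sensitive;
    * >= ``gross_min_violations`` violations plus an insertion of at least
      ``gross_insert_min_length`` residues in one of the configured
      inter-site intervals -> GrosslyInsensitive;
    * otherwise a *violating* aromatic/charged residue at site 8 or 10 ->
      Insensitive (restricting to violating residues keeps the call
      monotone: degrading a conforming residue can never raise the class);
    * everything else -> ModeratelySensitive.
    """
    table = catalog.decision
    rationale: list[str] = []
    if not vp.violating_sites:
        rationale.append("no violations at consensus sites")
        return SensitivityCall(SensitivityClass.SENSITIVE, tuple(rationale))

    rationale.append(
        "violations at sites {%s}" % ",".join(map(str, sorted(vp.violating_sites)))
    )
    long_inserts = [
        (k, length)
        for k, length in vp.insertions
        if k in table.gross_insert_intervals
        and length >= table.gross_insert_min_length
    ]
    if len(vp.violating_sites) >= table.gross_min_violations and long_inserts:
        for k, length in long_inserts:
            rationale.append(f"insert of {length} residues in interval {k}->{k + 1}")
        return SensitivityCall(
            SensitivityClass.GROSSLY_INSENSITIVE, tuple(rationale)
        )

    for site_index in sorted(table.insensitive_sites):
        residue = vp.site_residues[site_index - 1]
        if site_index in vp.violating_sites and residue in table.insensitive_residues:
            rationale.append(
                f"aromatic/charged residue {residue} at site {site_index}"
            )
            return SensitivityCall(
                SensitivityClass.INSENSITIVE, tuple(rationale)
            )

    rationale.append("violations tolerated at moderate level")
    return SensitivityCall(
        SensitivityClass.MODERATELY_SENSITIVE, tuple(rationale)
    )


def classify_profile(profile: SiteProfile,
                     catalog: SiteCatalog) -> SensitivityCall:
    """Convenience composition of the two steps above."""
    return classify_sensitivity(violation_profile(profile, catalog), catalog)


CHECK = "✓"


def conservation_matrix(profiles: list[SiteProfile],
                        catalog: SiteCatalog) -> list[dict[str, str]]:
    """Presence/absence matrix: one row per sequence, '✓'/'-' per site."""
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for profile in profiles:
        row: dict[str, str] = {"sequence": profile.sequence_id}
        for i in range(N_SITES):
            status = evaluate_site(i + 1, profile.site_residues[i], catalog)
            row[f"site{i + 1}"] = CHECK if status is SiteStatus.CONFORMS else "-"
        rows.append(row)
    return rows
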