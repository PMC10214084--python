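"""End-to-end orchestration: run every stage and emit the report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ancestral_states import annotate_changes, default_state_model, sankoff
from .catalog import SiteCatalog, default_catalog, load_catalog
from .conservation import column_conservation, scan_invariant_windows
from .io_formats import (
    read_fasta,
    read_newick,
    read_structure,
    write_newick,
    write_report_table,
)
from .sensitivity_rules import (
    classify_sensitivity,
    conservation_matrix,
    violation_profile,
)
from .site_mapping import extract_site_profile, locate_reference_columns
from .structure_contacts import (
    catalog_roi,
    detect_hbonds,
    interaction_summary,
    residue_contacts,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class RunConfig:
    catalog_path: str | None = None
    contact_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    min_majority: float = 0.95
    window_length: int = 13
    root_state: str = "ModeratelySensitive"
    out_dir: str = "toxscan_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def catalog(self) -> SiteCatalog:
        if self.catalog_path:
            return load_catalog(self.catalog_path)
        return default_catalog()

    def digest(self) -> str:
        # the output location is not part of the analysis configuration
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        return hashlib.sha256(
            yaml.safe_dump(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def profiles_from_alignment(alignment_path: str | Path, reference_id: str,
                            catalog: SiteCatalog):
    alignment = read_fasta(alignment_path, aligned=True)
    columns = locate_reference_columns(alignment, reference_id, catalog)
    return [
        extract_site_profile(alignment, rec.id, columns, reference_id)
        for rec in alignment
    ], alignment


def run_pipeline(config: RunConfig, alignment_path: str | Path,
                 reference_id: str | None = None,
                 tree_path: str | Path | None = None,
                 tip_states_path: str | Path | None = None,
                 manifest_path: str | Path | None = None) -> dict[str, Path]:
    """Run all stages for which inputs are present; missing optional stages
    are logged as SKIP.  Returns the mapping of report name to written path."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = config.catalog()
    reference_id = reference_id or catalog.reference_id
    header = (
        f"toxscan {__version__} | config {config.digest()} | seed {config.seed}"
    )
    outputs: dict[str, Path] = {}

    # --- site mapping + classification -----------------------------------
    try:
        profiles, alignment = profiles_from_alignment(
            alignment_path, reference_id, catalog
        )
    except Exception as exc:
        raise StageError("map-sites", str(exc)) from exc

    try:
        matrix_rows = conservation_matrix(profiles, catalog)
        path = out_dir / "site_matrix.tsv"
        write_report_table(
            matrix_rows,
            ["sequence"] + [f"site{i}" for i in range(1, 11)],
            path,
            header_comment=header,
        )
        outputs["site_matrix"] = path

        class_rows = []
        for profile in profiles:
            vp = violation_profile(profile, catalog)
            call = classify_sensitivity(vp, catalog)
            row = {"sequence": profile.sequence_id}
            for i in range(10):
                row[f"site{i + 1}"] = profile.site_residues[i]
            row["violations"] = ",".join(map(str, sorted(vp.violating_sites))) or None
            row["inserts"] = ",".join(
                f"{k}:{n}" for k, n in vp.insertions
            ) or None
            row["class"] = call.sensitivity.label
            row["rationale"] = "; ".join(call.rationale)
            class_rows.append(row)
        path = out_dir / "classification.tsv"
        write_report_table(
            class_rows,
            ["sequence"] + [f"site{i}" for i in range(1, 11)]
            + ["violations", "inserts", "class", "rationale"],
            path,
            header_comment=header,
        )
        outputs["classification"] = path
    except StageError:
        raise
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc

    # --- conservation ----------------------------------------------------
    try:
        scores = column_conservation(alignment)
        reference = next(r for r in alignment if r.id == reference_id)
        windows = scan_invariant_windows(
            scores, reference, config.min_majority, config.window_length
        )
        rows = [
            {
                "column": sc.column,
                "majority": sc.majority_residue,
                "fraction": f"{sc.majority_fraction:.4f}",
                "entropy_bits": f"{sc.entropy_bits:.4f}",
                "gap_fraction": f"{sc.gap_fraction:.4f}",
                "unreliable": "yes" if sc.unreliable else "no",
            }
            for sc in scores
        ]
        path = out_dir / "conservation.tsv"
        write_report_table(
            rows,
            ["column", "majority", "fraction", "entropy_bits",
             "gap_fraction", "unreliable"],
            path,
            header_comment=header
            + " | windows: "
            + (";".join(f"{a}-{b}" for a, b in windows) or "none"),
        )
        outputs["conservation"] = path
    except Exception as exc:
        raise StageError("conserve", str(exc)) from exc

    # --- structure census (optional) -------------------------------------
    if manifest_path is not None:
        try:
            census = {}
            offsets = {}
            for entry in _read_manifest(manifest_path):
                model = read_structure(entry["structure"])
                offset = int(entry.get("offset") or 0)
                roi = catalog_roi(catalog, offset)
                records = residue_contacts(
                    model,
                    entry["cat_chain"],
                    roi.keys(),
                    entry["partner_chain"],
                    cutoff=config.contact_cutoff,
                    hbond_cutoff=config.hbond_cutoff,
                    roi=roi,
                    loop_positions=[
                        p + offset for p in catalog.loop_positions()
                    ],
                )
                records = detect_hbonds(records, model, config.hbond_cutoff)
                census[entry["regulator"]] = records
                offsets[entry["regulator"]] = offset
            summary = interaction_summary(census, catalog, offsets)
            rows = [
                {"regulator": reg, "n_residues_of_interest": n}
                for reg, n in summary.per_regulator.items()
            ]
            path = out_dir / "census.tsv"
            write_report_table(
                rows, ["regulator", "n_residues_of_interest"], path,
                header_comment=header
                + f" | sites_used {summary.n_sites_used}/10"
                + f" | loop_used {summary.n_loop_used}/13",
            )
            outputs["census"] = path
        except Exception as exc:
            raise StageError("census", str(exc)) from exc
    else:
        logger.info("SKIP census: no structure manifest")

    # --- ancestral states (optional) -------------------------------------
    if tree_path is not None and tip_states_path is not None:
        try:
            tree = read_newick(tree_path)
            tip_states = _read_tip_states(tip_states_path)
            annotated = sankoff(
                tree, tip_states, default_state_model(), config.root_state
            )
            changes = annotate_changes(annotated)
            rows = [
                {
                    "child": ch.child_label or f"node{ch.child_index}",
                    "parent_state": ch.parent_state,
                    "child_state": ch.child_state,
                    "direction": ch.direction.value,
                }
                for ch in changes
            ]
            path = out_dir / "branch_changes.tsv"
            write_report_table(
                rows, ["child", "parent_state", "child_state", "direction"],
                path,
                header_comment=header + f" | parsimony_cost {annotated.total_cost:g}",
            )
            outputs["branch_changes"] = path
            path = out_dir / "annotated_tree.nwk"
            write_newick(
                tree, path,
                comments={
                    idx: f"state={state}"
                    for idx, state in annotated.states.items()
                },
            )
            outputs["annotated_tree"] = path
        except Exception as exc:
            raise StageError("ancestral", str(exc)) from exc
    else:
        logger.info("SKIP ancestral: tree or tip states missing")

    log_path = out_dir / "run_log.json"
    log_path.write_text(
        json.dumps(
            {
                "tool": "toxscan",
                "version": __version__,
                "config_hash": config.digest(),
                "outputs": {k: str(v) for k, v in outputs.items()},
            },
            indent=2,
            sort_keys=True,
        ),
        encoding="utf-8",
    )
    outputs["run_log"] = log_path
    return outputs


def _read_manifest(path: str | Path) -> list[dict[str, str]]:
    from .io_formats import read_report_table

    columns, rows = read_report_table(path)
    required = {"structure", "cat_chain", "partner_chain", "regulator"}
    missing = required - set(columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return rows


def _read_tip_states(path: str | Path) -> dict[str, str]:
    from .io_formats import read_report_table

    columns, rows = read_report_table(path)
    if "tip" not in columns or "state" not in columns:
        raise ValueError("tip state table needs 'tip' and 'state' columns")
    return {row["tip"]: row["state"] for row in rows}
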