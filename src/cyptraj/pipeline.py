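"""End-to-end orchestration: manifest of complexes -> species report bundle.

For every complex in the manifest: distance series, summary statistics and
substrate call; across complexes: one-way ANOVA with Bonferroni post-hoc;
per complex: gromos clustering, representative pose and interaction
profile. Outputs are deterministic functions of (manifest, config, input
files): reruns produce byte-identical files. Failing complexes are
reported and skipped, never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import contacts as _contacts
from .classify import ClassificationResult, classify, species_report
from .config import merge_config
from .geometry import distance_series, summarize
from .io import AtomSelector, Trajectory, read_frame_table, read_multimodel_pdb, write_pdb
from .stats import bonferroni_pairwise, one_way_anova

log = logging.getLogger("cyptraj")

MANIFEST_COLUMNS = [
    "complex_id",
    "molecule",
    "species",
    "cyp",
    "trajectory",
    "atoms",
    "reactive",
    "fe",
    "ligand",
]

__all__ = ["ComplexManifestEntry", "PipelineResult", "read_manifest", "run_pipeline"]


@dataclass(frozen=True)
class ComplexManifestEntry:
    complex_id: str
    molecule: str
    species: str
    cyp: str
    trajectory: str  # multi-model PDB, or frame-table TSV (then atoms required)
    reactive: str  # selector string for the atom undergoing the reaction
    fe: str  # selector string for the heme iron
    atoms: str = ""  # atom-metadata sidecar for frame tables
    ligand: str = ""  # ligand selection; derived from `reactive` if empty
    notes: str = ""

    def ligand_selector(self) -> str:
        if self.ligand:
            return self.ligand
        sel = AtomSelector.from_string(self.reactive)
        if sel.res_name:
            return f"resname={sel.res_name}"
        raise ValueError(
            f"{self.complex_id}: no ligand selector and the reactive selector "
            "names no residue to derive one from"
        )


@dataclass
class PipelineResult:
    per_complex: dict = field(default_factory=dict)
    anova: dict | None = None
    pairwise: list = field(default_factory=list)
    report: pd.DataFrame | None = None
    errors: dict = field(default_factory=dict)  # complex_id -> message

    @property
    def n_failed(self) -> int:
        return len(self.errors)


def read_manifest(path) -> list[ComplexManifestEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["complex_id", "molecule", "species", "cyp", "trajectory", "reactive", "fe"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: manifest is empty")
    entries = [
        ComplexManifestEntry(
            complex_id=row["complex_id"],
            molecule=row["molecule"],
            species=row["species"],
            cyp=row["cyp"],
            trajectory=row["trajectory"],
            reactive=row["reactive"],
            fe=row["fe"],
            atoms=row.get("atoms", ""),
            ligand=row.get("ligand", ""),
            notes=row.get("notes", ""),
        )
        for row in df.to_dict("records")
    ]
    keys = [(e.molecule, e.species, e.cyp) for e in entries]
    if len(set(keys)) != len(keys):
        raise ValueError(f"{path}: duplicate (molecule, species, cyp) entries")
    return entries


def _load_trajectory(entry: ComplexManifestEntry, base: Path) -> Trajectory:
    traj_path = base / entry.trajectory
    if traj_path.suffix.lower() == ".pdb":
        return read_multimodel_pdb(traj_path)
    if not entry.atoms:
        raise ValueError(f"{entry.complex_id}: frame-table trajectory needs an 'atoms' sidecar")
    return read_frame_table(traj_path, base / entry.atoms)


def _cluster_frames(n_frames: int, max_frames: int) -> np.ndarray | None:
    """Even stride restriction for the O(n^2) RMSD matrix; None = all frames."""
    if n_frames <= max_frames:
        return None
    stride = int(np.ceil(n_frames / max_frames))
    return np.arange(0, n_frames, stride)


def run_pipeline(
    manifest: list[ComplexManifestEntry],
    config: dict | None = None,
    outdir: str | Path | None = None,
    base_dir: str | Path = ".",
) -> PipelineResult:
    """Run the full analysis over a manifest of complexes.

    When ``outdir`` is given, per-complex TSVs (distance series, cluster
    membership, contacts), representative-pose PDBs, the species report
    (TSV) and a consolidated machine-readable ``report.json`` are written
    there. Every number in the human-readable report is also present in
    the JSON.
    """
    if not manifest:
        raise ValueError("manifest is empty")
    cfg = merge_config(config)
    base = Path(base_dir)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", json.dumps(cfg, sort_keys=True))

    result = PipelineResult()
    series_by_id: dict[str, np.ndarray] = {}
    calls: list[ClassificationResult] = []

    for entry in manifest:
        try:
            traj = _load_trajectory(entry, base)
            series = distance_series(
                traj,
                entry.reactive,
                entry.fe,
                pbc_mode=cfg["pbc_mode"],
                complex_id=entry.complex_id,
            )
            summary = summarize(series)
            call = classify(
                series,
                threshold=cfg["threshold_nm"],
                complex_id=entry.complex_id,
                molecule=entry.molecule,
                species=entry.species,
                cyp=entry.cyp,
            )
            frames_subset = _cluster_frames(traj.n_frames, int(cfg["max_cluster_frames"]))
            rmsd = _cluster.pairwise_rmsd(
                traj,
                cfg["cluster_rmsd_selection"],
                fit_selection=cfg["cluster_fit_selection"],
                frame_indices=frames_subset,
            )
            clusters = _cluster.gromos_cluster(rmsd, cutoff=cfg["cluster_cutoff_nm"])
            pose = _cluster.representative_pose(traj, clusters)
            profile = _contacts.build_interaction_report(
                entry.complex_id,
                pose,
                entry.ligand_selector(),
                hbond_d_max=cfg["hbond_d_max_nm"],
                hbond_angle_min=cfg["hbond_angle_min_deg"],
                hydrophobic_d_max=cfg["hydrophobic_d_max_nm"],
            )
        except Exception as exc:
            log.error("complex %s failed: %s", entry.complex_id, exc)
            result.errors[entry.complex_id] = str(exc)
            continue

        series_by_id[entry.complex_id] = series.values
        calls.append(call)
        result.per_complex[entry.complex_id] = {
            "molecule": entry.molecule,
            "species": entry.species,
            "cyp": entry.cyp,
            "n_frames": summary.n_frames,
            "mean_nm": summary.mean,
            "sd_nm": summary.sd,
            "min_nm": summary.min,
            "max_nm": summary.max,
            "call": call.call,
            "threshold_nm": call.threshold,
            "fraction_below_threshold": call.fraction_below_threshold,
            "n_clusters": clusters.n_clusters,
            "cluster_sizes": clusters.sizes,
            "cluster_centers": clusters.centers,
            "predominant_interaction": profile.predominant_kind,
            "n_hbonds": sum(1 for c in profile.contacts if c.kind == "hbond"),
            "n_hydrophobic": sum(1 for c in profile.contacts if c.kind == "hydrophobic"),
        }

        if out is not None:
            pd.DataFrame(
                {"frame": np.arange(series.n_frames), "distance_nm": series.values}
            ).to_csv(out / f"{entry.complex_id}_distances.tsv", sep="\t", index=False,
                     float_format="%.6f")
            membership = clusters.membership()
            pd.DataFrame(
                {
                    "frame": sorted(membership),
                    "cluster_id": [membership[f] for f in sorted(membership)],
                    "is_center": [f in clusters.centers for f in sorted(membership)],
                }
            ).to_csv(out / f"{entry.complex_id}_clusters.tsv", sep="\t", index=False)
            write_pdb(out / f"{entry.complex_id}_representative.pdb", pose)
            pd.DataFrame(
                [
                    {
                        "kind": c.kind,
                        "protein_residue": c.protein_residue,
                        "protein_atom": c.protein_atom,
                        "ligand_atom": c.ligand_atom,
                        "distance_nm": round(c.distance, 4),
                        "angle_deg": None if c.angle is None else round(c.angle, 1),
                    }
                    for c in profile.contacts
                ]
            ).to_csv(out / f"{entry.complex_id}_contacts.tsv", sep="\t", index=False)

    if len(series_by_id) >= 2:
        ids = sorted(series_by_id)
        groups = [series_by_id[i] for i in ids]
        anova = one_way_anova(groups)
        pairwise = bonferroni_pairwise(groups, alpha=cfg["alpha"])
        result.anova = {
            "group_ids": ids,
            "F": anova.F,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p": anova.p,
        }
        result.pairwise = [
            {
                "a": ids[c.group_a],
                "b": ids[c.group_b],
                "mean_difference_nm": c.mean_difference,
                "p_raw": c.p_raw,
                "p_adjusted": c.p_adjusted,
                "significant": c.significant,
            }
            for c in pairwise
        ]

    if calls:
        result.report = species_report(calls)

    if out is not None:
        if result.report is not None:
            result.report.to_csv(out / "species_report.tsv", sep="\t", index=False)
        if result.pairwise:
            pd.DataFrame(result.pairwise).to_csv(
                out / "pairwise_comparisons.tsv", sep="\t", index=False
            )
        bundle = {
            "config": cfg,
            "per_complex": result.per_complex,
            "anova": result.anova,
            "pairwise": result.pairwise,
            "errors": result.errors,
        }
        (out / "report.json").write_text(json.dumps(bundle, indent=2, sort_keys=True) + "\n")

    if result.errors:
        log.warning("%d complex(es) failed: %s", len(result.errors), sorted(result.errors))
    return result
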