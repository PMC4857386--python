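"""End-to-end pipeline: read -> annotate -> place -> collapse -> motifs ->
hotlist -> occupancy -> map, with a JSON run manifest.

The pipeline is a thin orchestration of the library modules; all stage
outputs are plain text (TSV/JSON) with stable ordering, so a rerun with
identical inputs produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import assembly, candidates, io, motifs, occupancy as occupancy_mod, ortho, pepmap
from .model import DEFAULT_MIN_LENGTH, count_unique
from .ortho import OrthoGroup

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Inputs and parameters of a pipeline run; the numeric defaults are
    the framework's standard parameterization (minimum peptide length 6,
    minimum merge overlap 2, occupancy threshold of 3 observations, 3-residue
    flanks)."""

    evidence: str = ""
    fasta: str = ""
    mapping: str = ""
    features: Optional[str] = None
    genes: Optional[str] = None
    known_peptides: Optional[str] = None
    out_dir: str = "peptilap_run"
    dialect: str = "generic_tsv"
    min_peptide_length: int = DEFAULT_MIN_LENGTH
    min_obs: int = 3
    flank_width: int = 3
    phospho_window: int = 5
    restrict_prohormone: bool = True
    write_xlsx: bool = False


def _merged_group(index: ortho.GroupIndex, gids: tuple[str, ...]) -> OrthoGroup:
    if len(gids) == 1:
        return index.groups[gids[0]]
    members = sorted({m for g in gids for m in index.groups[g].members})
    refs = [r for g in gids for r in index.groups[g].reference_peptides]
    return OrthoGroup(
        group_id="+".join(gids),
        members=members,
        is_prohormone=any(index.groups[g].is_prohormone for g in gids),
        reference_peptides=refs,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the outputs plus ``manifest.json`` into
    ``config.out_dir``.  Returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    # ---- read ------------------------------------------------------------
    name = stage("read")
    try:
        rejects: list[io.RejectedRow] = []
        observations = io.read_evidence(
            config.evidence, dialect=config.dialect,
            min_length=config.min_peptide_length, rejects=rejects,
        )
        proteins = io.read_fasta(config.fasta)
        mapping = ortho.read_mapping_table(config.mapping)
        annotations = io.read_annotation_tables(
            config.features, config.genes, config.known_peptides
        )
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    n_variants, n_sequences = count_unique(observations)
    manifest["stages"][name] = {
        "n_rows": len(observations) + len(rejects),
        "n_observations": len(observations),
        "n_rejected": len(rejects),
        "n_modspecific_variants": n_variants,
        "n_unique_sequences": n_sequences,
        "n_proteins": len(proteins),
    }
    if rejects:
        pd.DataFrame([vars(r) for r in rejects]).to_csv(
            out / "rejected_rows.tsv", sep="\t", index=False
        )

    # ---- annotate --------------------------------------------------------
    name = stage("annotate")
    try:
        index = ortho.build_group_index(mapping, proteins)
        ortho.flag_prohormone_groups(index, annotations)
        assignment = ortho.assign_observations(observations, index)
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    mapped_gids = {a.assigned_group_ids for a in assignment.assignments}
    flat_gids = sorted({g for gids in mapped_gids for g in gids})
    manifest["stages"][name] = {
        "n_groups_total": len(index.groups),
        "n_prohormone_groups_total": index.n_prohormone,
        "n_groups_with_peptides": len(flat_gids),
        "n_prohormone_groups_with_peptides": sum(
            index.groups[g].is_prohormone for g in flat_gids
        ),
        "n_unmapped_observations": len(assignment.unmapped_observation_ids),
    }

    # ---- place + collapse ------------------------------------------------
    name = stage("collapse")
    proteins_by_acc = {p.accession: p for p in proteins}
    all_lpvs: list[assembly.LPV] = []
    placed_by_group: dict[str, list[assembly.PlacedPeptide]] = {}
    groups_used: dict[str, OrthoGroup] = {}
    n_unplaced = 0
    try:
        for a in assignment.assignments:
            group = _merged_group(index, a.assigned_group_ids)
            obs = [observations[i] for i in a.observation_ids]
            placed, unplaced = assembly.place_observations(
                obs, a.observation_ids, group, proteins_by_acc
            )
            n_unplaced += len(unplaced)
            if not placed:
                continue
            placed_by_group[group.group_id] = placed
            groups_used[group.group_id] = group
            all_lpvs.extend(assembly.assemble_lpvs(placed, proteins_by_acc, group.group_id))
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    lpv_df = io.lpv_table(sorted(all_lpvs, key=lambda l: (l.group_id, l.anchor)))
    lpv_df.to_csv(out / "lpvs.tsv", sep="\t", index=False)
    prohormone_gids = {gid for gid, g in groups_used.items() if g.is_prohormone}
    manifest["stages"][name] = {
        "n_placed_unique_peptides": sum(len(v) for v in placed_by_group.values()),
        "n_unplaced_observations": n_unplaced,
        "n_lpvs": len(all_lpvs),
        "n_prohormone_lpvs": sum(l.group_id in prohormone_gids for l in all_lpvs),
    }

    # ---- motifs ----------------------------------------------------------
    name = stage("motifs")
    try:
        motif_frames = []
        for label, selector in (
            ("lpv_prohormone", [l for l in all_lpvs if l.group_id in prohormone_gids]),
            ("lpv_other", [l for l in all_lpvs if l.group_id not in prohormone_gids]),
            ("lpv_amidated", [l for l in all_lpvs if l.is_amidated]),
        ):
            if not selector:
                continue
            flanks = [
                motifs.extract_flanks(l, proteins_by_acc[l.accession], k=config.flank_width)
                for l in selector
            ]
            n_mat, c_mat = motifs.terminal_motif_matrices(flanks, k=config.flank_width)
            for side, mat in (("N", n_mat), ("C", c_mat)):
                frame = motifs.matrix_to_frame(mat)
                frame.insert(0, "set", label)
                frame.insert(1, "side", side)
                motif_frames.append(frame)
        if motif_frames:
            pd.concat(motif_frames, ignore_index=True).to_csv(
                out / "motif_matrices.tsv", sep="\t", index=False, float_format="%.6g"
            )
        manifest["stages"][name] = {"n_matrix_rows": sum(len(f) for f in motif_frames)}
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc

    # ---- hotlist ---------------------------------------------------------
    name = stage("hotlist")
    try:
        # the restriction must see merged multi-group ids as well
        for gid, g in groups_used.items():
            index.groups.setdefault(gid, g)
        records = candidates.build_hotlist(
            all_lpvs,
            proteins_by_acc,
            group_index=index if config.restrict_prohormone else None,
            restrict_prohormone=config.restrict_prohormone,
            flank_width=config.flank_width,
        )
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    candidates.hotlist_frame(records).to_csv(out / "hotlist.tsv", sep="\t", index=False)
    manifest["stages"][name] = {"n_candidates": len(records)}

    # ---- occupancy -------------------------------------------------------
    name = stage("occupancy")
    try:
        sites = []
        gene_names = {p.accession: p.gene or "" for p in proteins}
        for p in proteins:
            relevant = [o for o in observations if p.accession in o.accessions]
            if not relevant:
                continue
            anchored, _ = occupancy_mod.anchor_observations(relevant, p)
            cov = occupancy_mod.residue_coverage(anchored, p)
            sites.extend(occupancy_mod.compute_occupancy(cov, p, min_obs=config.min_obs))
        occ_df = occupancy_mod.occupancy_frame(sites, gene_names)
        occ_df.to_csv(out / "occupancy.tsv", sep="\t", index=False, float_format="%.6g")
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    manifest["stages"][name] = {"n_sites": len(sites)}

    # ---- map -------------------------------------------------------------
    name = stage("map")
    try:
        group_maps = []
        for gid in sorted(prohormone_gids):
            group = groups_used[gid]
            placed = placed_by_group.get(gid, [])
            lpvs = [l for l in all_lpvs if l.group_id == gid]
            if len(set(group.members) & set(proteins_by_acc)) > 1:
                continue  # multi-member groups need an external alignment
            group_maps.append(
                pepmap.build_group_map(group, proteins_by_acc, placed, lpvs)
            )
        pepmap.maps_to_json(group_maps, out / "peptide_map.json")
        if config.write_xlsx and group_maps:
            pepmap.maps_to_xlsx(group_maps, out / "peptide_map.xlsx")
    except Exception as exc:
        raise PipelineError(f"stage {name}: {exc}") from exc
    manifest["stages"][name] = {"n_group_maps": len(group_maps)}

    # ---- manifest --------------------------------------------------------
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
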