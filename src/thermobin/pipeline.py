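"""End-to-end orchestration of the binning / profiling / energetics stages.

``run_pipeline`` chains the stages on one configuration: simulate a mock
community, run the two homology tracks and their consensus, seed
phylum-level bins, recruit unassigned sequences by tetranucleotide
correlation, propagate mate pairs, evaluate against the simulation
truth, compute bin statistics and diversity indices, cluster planted
protein families and transfer EC numbers, call EC presence, and rank
reaction energetics.  Everything is deterministic given the config seed,
and a manifest records parameters and stage warnings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import datasets, families, profiles, tetra
from .energetics import affinity_table, rank_reactions
from .homology import (
    LcaParams,
    TaxonAssignment,
    besthit_assign,
    consensus_assign,
    lca_assign,
)
from .io import RANKS, Lineage, SequenceRecord
from .otu import diversity_indices
from .synthetic import TruthTable, default_scenario, plant_protein_families

ANALYTIC_STAGES = (
    "simulate",
    "homology",
    "tetra",
    "mates",
    "families",
    "profiles",
    "energetics",
)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's quoted values."""

    seed: int = 0
    # synthetic community
    n_reads: int = 1800
    hit_free_fraction: float = 0.3
    # homology binning
    lca_min_score: float = 35.0
    lca_top_percent: float = 10.0
    lca_min_support: int = 5
    besthit_min_bit: float = 300.0
    # tetranucleotide binning
    tetra_min_length: int = 900
    tetra_min_bin_size: int = 50
    # protein families
    mcl_inflation: float = 1.2
    mcl_e_cutoff: float = 1e-40
    ec_min_frac: float = 0.01
    n_planted_families: int = 20
    planted_family_size: int = 10
    # metabolic profile
    ec_presence_cutoff: float = 0.25
    small_bin_pct: float = 0.2
    # OTU stage
    otu_threshold: float = 0.03
    # stage toggles
    run_tetra: bool = True
    run_families: bool = True
    run_profiles: bool = True
    run_energetics: bool = True


def phylum_bins(
    assignments: Mapping[str, TaxonAssignment],
) -> tuple[dict[str, list[str]], dict[str, Lineage]]:
    """Group phylum-resolved assignments into bins keyed by phylum name."""
    bins: dict[str, list[str]] = {}
    lineages: dict[str, Lineage] = {}
    for qid in sorted(assignments):
        a = assignments[qid]
        if a.lineage.depth >= 2:
            phylum = a.lineage.name_at("phylum")
            bins.setdefault(phylum, []).append(qid)
            lineages.setdefault(phylum, a.lineage.truncate(2))
    return bins, lineages


def evaluate_against_truth(
    assignments: Mapping[str, TaxonAssignment],
    truth: TruthTable,
    taxon_lineages: Mapping[str, Lineage],
) -> pd.DataFrame:
    """Per-rank precision/recall of assignments against simulation truth.

    Precision counts correct calls among sequences assigned at (or
    below) a rank; recall counts them among all sequences.  Undefined
    precision (nothing assigned at the rank) is reported as NaN.
    """
    missing = [qid for qid in assignments if qid not in truth]
    if missing:
        raise ValueError(f"assignments for ids missing from truth: {missing[:5]}")
    rows = []
    total = len(assignments)
    for depth, rank in enumerate(RANKS, start=1):
        assigned = correct = 0
        for qid, a in assignments.items():
            if a.lineage.depth >= depth:
                assigned += 1
                true_lin = taxon_lineages[truth.taxon_of(qid)]
                if a.lineage.ranks[:depth] == true_lin.ranks[:depth]:
                    correct += 1
        rows.append(
            {
                "rank": rank,
                "n_total": total,
                "n_assigned": assigned,
                "n_correct": correct,
                "precision": correct / assigned if assigned else float("nan"),
                "recall": correct / total if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run every enabled stage and return the collected results.

    The returned dict holds the scenario (reads, truth, hit tables),
    per-stage outputs, recruitment statistics, the evaluation table and
    a manifest.  With ``outdir`` the main tables are also written as CSV
    plus a JSON manifest; reruns with the same seed are byte-identical.
    """
    caught: list[str] = []
    manifest: dict = {"parameters": asdict(config), "stages": [], "warnings": caught}
    result: dict = {"config": config, "manifest": manifest}

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        # --- simulate -----------------------------------------------------
        scenario = default_scenario(
            seed=config.seed,
            n_reads=config.n_reads,
            hit_free_fraction=config.hit_free_fraction,
        )
        result["scenario"] = scenario
        reads: list[SequenceRecord] = scenario["reads"]
        truth: TruthTable = scenario["truth"]
        taxonomy = scenario["references"]
        taxon_lineages = {m.taxon_id: m.lineage for m in scenario["community"]}
        manifest["stages"].append("simulate")

        # --- homology binning ----------------------------------------------
        lca = lca_assign(
            scenario["protein_hits"],
            taxonomy,
            LcaParams(
                min_score=config.lca_min_score,
                top_percent=config.lca_top_percent,
                min_support=config.lca_min_support,
            ),
        )
        besthit = besthit_assign(
            scenario["nucleotide_hits"], taxonomy, min_bit=config.besthit_min_bit
        )
        consensus = consensus_assign(lca, besthit)
        homology: dict[str, TaxonAssignment] = {}
        for rec in reads:
            homology[rec.id] = consensus.get(rec.id, TaxonAssignment(sequence_id=rec.id))
        result["lca"] = lca
        result["besthit"] = besthit
        result["homology"] = homology
        manifest["stages"].append("homology")

        final = dict(homology)

        # --- tetranucleotide recruitment ------------------------------------
        if config.run_tetra:
            bins, bin_lineages = phylum_bins(homology)
            freqs = tetra.profile_matrix(reads)
            scores = tetra.fit_pca(freqs)
            scores_by_id = {rec.id: scores[i] for i, rec in enumerate(reads)}
            bin_stats = tetra.bin_internal_stats(
                bins, scores_by_id, min_bin_size=config.tetra_min_bin_size
            )
            candidates = [r for r in reads if homology[r.id].lineage.depth < 2]
            recruited = tetra.recruit_unassigned(
                candidates,
                bin_stats,
                scores_by_id,
                bin_lineages,
                min_length=config.tetra_min_length,
            )
            for qid, a in recruited.items():
                if a.assigned:
                    final[qid] = a
            result["bin_stats"] = bin_stats
            result["pc_scores"] = scores_by_id
            manifest["stages"].append("tetra")

            final, conflicts = tetra.propagate_mates(final, reads)
            manifest["mate_conflicts"] = [list(c) for c in conflicts]
            manifest["stages"].append("mates")

        result["assignments"] = final

        # --- recruitment / assignment statistics ----------------------------
        by_id = {r.id: r for r in reads}
        hit_free = scenario["hit_free_ids"]
        eligible = [
            rid
            for rid in hit_free
            if by_id[rid].length > config.tetra_min_length
        ]
        # the tetranucleotide stage = correlation recruitment + mate propagation
        stage_ids = [
            qid for qid, a in final.items() if a.method in ("tetra", "mate")
        ]
        n_corr_eligible = sum(1 for rid in eligible if final[rid].method == "tetra")
        n_stage_eligible = sum(
            1 for rid in eligible if final[rid].method in ("tetra", "mate")
        )
        correct_phylum = sum(
            1
            for rid in stage_ids
            if final[rid].lineage.name_at("phylum")
            == taxon_lineages[truth.taxon_of(rid)].name_at("phylum")
        )
        result["recruitment"] = {
            "n_eligible_hit_free": len(eligible),
            "n_recruited_eligible": n_stage_eligible,
            "eligible_recruited_frac": (
                n_stage_eligible / len(eligible) if eligible else float("nan")
            ),
            "eligible_correlation_frac": (
                n_corr_eligible / len(eligible) if eligible else float("nan")
            ),
            "n_recruited": len(stage_ids),
            "recruited_phylum_accuracy": (
                correct_phylum / len(stage_ids) if stage_ids else float("nan")
            ),
        }
        result["assigned_fraction"] = sum(
            1 for a in final.values() if a.lineage.depth >= 2
        ) / len(final)

        result["evaluation"] = evaluate_against_truth(final, truth, taxon_lineages)

        # --- bin statistics and diversity ----------------------------------
        if config.run_profiles:
            final_bins, _ = phylum_bins(final)
            site_total_nt = sum(r.length for r in reads)
            genome_mb = {
                m.lineage.name_at("phylum"): m.genome_length / 1e6
                for m in scenario["community"]
            }
            reports = []
            for phylum in sorted(final_bins):
                members = final_bins[phylum]
                reports.append(
                    profiles.bin_report(
                        bin_id=phylum,
                        site="site1",
                        assigned_lengths_nt=[by_id[m].length for m in members],
                        est_genome_mb=genome_mb.get(phylum, 2.0),
                        site_total_nt=site_total_nt,
                        small_bin_pct=config.small_bin_pct,
                    )
                )
            result["bin_reports"] = profiles.bin_report_table(reports)
            result["diversity"] = diversity_indices(
                [len(final_bins[p]) for p in sorted(final_bins)]
            )
            manifest["stages"].append("profiles")

        # --- protein families and EC transfer -------------------------------
        if config.run_families:
            fam_seed = int(
                np.random.SeedSequence((config.seed, 0xFA111E5)).generate_state(1)[0]
                % 2**31
            )
            edges, ec_labels, fam_truth = plant_protein_families(
                config.n_planted_families,
                config.planted_family_size,
                seed=fam_seed,
            )
            graph = families.build_graph(edges, e_value_cutoff=config.mcl_e_cutoff)
            clusters = families.mcl_cluster(
                graph, inflation=config.mcl_inflation, ec_labels=ec_labels
            )
            transferred = families.transfer_all(
                clusters, ec_labels, min_frac=config.ec_min_frac
            )
            result["clusters"] = clusters
            result["ec_labels"] = ec_labels
            result["family_truth"] = fam_truth
            result["transferred_ecs"] = transferred

            ec_counts: dict[str, int] = {}
            for labels in ec_labels.values():
                for ec in labels:
                    ec_counts[ec] = ec_counts.get(ec, 0) + 1
            for ecs in transferred.values():
                for ec in ecs:
                    ec_counts[ec] = ec_counts.get(ec, 0) + 1
            result["ec_profile"] = profiles.ec_presence(
                ec_counts, scope="site1", cutoff=config.ec_presence_cutoff
            )
            manifest["stages"].append("families")

        # --- energetics ------------------------------------------------------
        if config.run_energetics:
            reactions = datasets.load_synthetic_reactions()
            sites = datasets.load_synthetic_site_conditions()
            aff = affinity_table(reactions, sites)
            result["energetics"] = rank_reactions(aff)
            manifest["stages"].append("energetics")

        caught.extend(str(w.message) for w in wlist)

    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def assignments_frame(assignments: Mapping[str, TaxonAssignment]) -> pd.DataFrame:
    rows = []
    for qid in sorted(assignments):
        a = assignments[qid]
        row = {"sequence_id": qid}
        row.update({rank: name for rank, name in zip(RANKS, a.lineage.ranks)})
        row.update(
            {"assigned_rank": a.assigned_rank, "method": a.method, "rule": a.rule}
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _write_artifacts(result: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    assignments_frame(result["assignments"]).to_csv(
        outdir / "assignments.csv", index=False
    )
    result["evaluation"].to_csv(outdir / "evaluation.csv", index=False)
    if "bin_reports" in result:
        result["bin_reports"].to_csv(outdir / "bin_reports.csv", index=False)
    if "clusters" in result:
        pd.DataFrame(
            [
                {"cluster_id": c.cluster_id, "member": m}
                for c in result["clusters"]
                for m in c.members
            ]
        ).to_csv(outdir / "clusters.csv", index=False)
        pd.DataFrame(
            [
                {"protein": p, "ec": ec}
                for p in sorted(result["transferred_ecs"])
                for ec in sorted(result["transferred_ecs"][p])
            ]
        ).to_csv(outdir / "transferred_ecs.csv", index=False)
    if "energetics" in result:
        result["energetics"]["ranked"].to_csv(outdir / "affinities.csv", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=2, sort_keys=True)
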