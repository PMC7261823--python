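"""Top-level driver chaining every stage of the adaptation analysis.

With ``simulate=True`` the pipeline generates all of its inputs from
the synthetic module (seeded by the config), then runs: isobaric
quantification and set bridging -> protein and mRNA differential
expression -> drug-screen scoring and hit calling -> ChIP-consensus
candidate derivation -> over-representation analysis.  Every output
table is stamped with the config hash; all randomness flows from the
single config seed, so a run is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dea, enrich, integrate, io, quant, screen, synthetic
from .config import PipelineConfig

logger = logging.getLogger(__name__)

PROTEIN_CONDITIONS = ("untreated", "gef24", "gef48")
MRNA_TIMEPOINTS = ("gef2", "gef6", "gef24")


@dataclass
class PipelineResult:
    """Bundle of all stage outputs plus summary counts."""

    protein_matrix: quant.ProteinRatioMatrix
    protein_dea: dict[str, pd.DataFrame]
    mrna_dea: dict[str, pd.DataFrame]
    picked_fdr: pd.DataFrame
    screen_table: pd.DataFrame
    synergy_calls: list[screen.SynergyCall]
    hit_table: pd.DataFrame
    consensus: set[str]
    candidates: integrate.CandidateSet
    hit_target_table: pd.DataFrame
    ora_tables: dict[str, pd.DataFrame]
    summary: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)


def _planted_effects(cfg: PipelineConfig, rng: np.random.Generator) -> tuple[dict, dict]:
    """Choose differential genes and their condition-wise log2 fold changes.

    The same gene symbols carry effects at both layers: at protein level
    in the silenced arm (time-increasing response), at mRNA level across
    the treatment time course.
    """
    sim = cfg.simulation
    genes = [f"G{i:05d}" for i in range(min(sim.n_genes_protein, sim.n_genes_mrna))]
    chosen = sorted(rng.choice(genes, size=min(sim.n_de_genes, len(genes)), replace=False).tolist())
    protein_fx: dict[str, dict[str, float]] = {}
    mrna_fx: dict[str, dict[str, float]] = {}
    for i, g in enumerate(chosen):
        sign = 1.0 if i % 2 == 0 else -1.0
        delta = sign * sim.de_log2fc
        # silencing response grows with treatment duration
        protein_fx[g] = {"siKD_untreated": 0.5 * delta, "siKD_gef24": 0.75 * delta,
                         "siKD_gef48": delta}
        mrna_fx[g] = {"gef2": 0.25 * delta, "gef6": 0.5 * delta, "gef24": delta}
    return protein_fx, mrna_fx


def simulate_inputs(cfg: PipelineConfig) -> dict:
    """Generate every pipeline input table from the config seed."""
    sim = cfg.simulation
    rng = np.random.default_rng(cfg.seed)
    protein_fx, mrna_fx = _planted_effects(cfg, rng)
    psm_tables, psm_truth = synthetic.generate_psm_tables(
        n_genes=sim.n_genes_protein, psm_per_gene=sim.psm_per_gene,
        effects=protein_fx, noise_sd=sim.psm_noise_sd, seed=cfg.seed + 1)
    counts, count_truth = synthetic.generate_count_matrix(
        n_genes=sim.n_genes_mrna, dispersion=sim.count_dispersion,
        lfc_spec=mrna_fx, seed=cfg.seed + 2)
    wells, screen_truth = synthetic.generate_screen_plates(
        n_compounds=sim.n_compounds, n_synergists=sim.n_synergists,
        synergy_shift=sim.synergy_shift, noise_sd=sim.screen_noise_sd,
        seed=cfg.seed + 3)
    protein_genes = [f"G{i:05d}" for i in range(sim.n_genes_protein)]
    up_genes = sorted(g for g, fx in protein_fx.items() if max(fx.values()) > 0)
    n_planted = min(len(up_genes), sim.n_consensus_genes // 2)
    consensus = set(rng.choice(up_genes, size=n_planted, replace=False).tolist()) if n_planted else set()
    others = sorted(set(protein_genes) - consensus)
    consensus |= set(rng.choice(others, size=max(sim.n_consensus_genes - n_planted, 0),
                                replace=False).tolist())
    chip, chip_truth = synthetic.generate_chip_experiments(
        universe=protein_genes, consensus_genes=consensus,
        n_experiments=sim.n_chip_experiments, min_experiments=cfg.min_chip_experiments,
        background_rate=sim.chip_background_rate, seed=cfg.seed + 4)
    decoys, _ = synthetic.generate_decoy_scores(n_genes=sim.n_genes_protein, seed=cfg.seed + 5)
    gene_sets = synthetic.generate_gene_sets(
        universe=protein_genes, enriched_genes=set(up_genes),
        n_sets=sim.n_gene_sets, seed=cfg.seed + 6)
    # drug -> target annotation: synergists preferentially target regulated genes
    ann_rows = []
    compounds = sorted(wells.loc[wells["control"] == "none", "compound"].unique())
    regulated_pool = up_genes or protein_genes
    for comp in compounds:
        n_t = int(rng.integers(1, 4))
        pool = regulated_pool if comp in screen_truth.synergist_compounds else protein_genes
        targets = rng.choice(pool, size=min(n_t, len(pool)), replace=False)
        for t in sorted(targets.tolist()):
            ann_rows.append({"compound": comp, "target": t, "source": "sim"})
    annotation = pd.DataFrame(ann_rows, columns=["compound", "target", "source"])
    return {
        "psm_tables": psm_tables, "counts": counts, "wells": wells, "chip": chip,
        "decoys": decoys, "gene_sets": gene_sets, "annotation": annotation,
        "truth": {
            "protein_effects": protein_fx, "mrna_effects": mrna_fx,
            "synergists": screen_truth.synergist_compounds,
            "consensus_genes": chip_truth.consensus_genes,
            "screen_extras": screen_truth.extras,
        },
    }


def _bridged_matrix(psm_tables: dict[str, pd.DataFrame]) -> quant.ProteinRatioMatrix:
    """Quantify each 10-plex set and bridge them through the pooled reference."""
    designs = {d.set_id: d for d in synthetic.default_psm_designs()}
    matrices = {}
    for set_id, table in psm_tables.items():
        mat = quant.quantify(table)
        mat.values.columns = [designs[set_id].channels[c] for c in mat.values.columns]
        matrices[set_id] = mat
    return quant.bridge_sets(matrices["set1"], matrices["set2"], reference_label="ref")


def _sample_groups(matrix: quant.ProteinRatioMatrix) -> dict[str, str]:
    """Map bridged column labels 'setX:cond:rep' to their condition."""
    return {c: c.split(":")[1] for c in matrix.samples}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None,
                 inputs: dict | None = None) -> PipelineResult:
    """Execute all stages; write result tables to ``out_dir`` if given."""
    chash = cfg.config_hash()
    if inputs is None:
        logger.info("stage=simulate seed=%d", cfg.seed)
        inputs = simulate_inputs(cfg)
    truth = inputs.get("truth", {})

    # --- quantification ---------------------------------------------------
    matrix = _bridged_matrix(inputs["psm_tables"])
    logger.info("stage=quant genes=%d samples=%d", len(matrix.genes), len(matrix.samples))
    picked = quant.picked_protein_fdr(inputs["decoys"], fdr_cutoff=cfg.fdr_protein)
    logger.info("stage=picked_fdr passed=%d", int(picked["passed"].sum()))

    # --- differential expression -----------------------------------------
    groups = _sample_groups(matrix)
    protein_dea: dict[str, pd.DataFrame] = {}
    for cond in PROTEIN_CONDITIONS:
        res = dea.moderated_protein_dea(matrix, groups, (f"siKD_{cond}", f"siCtrl_{cond}"))
        protein_dea[cond] = res
        _, ud = dea.call_significant(res, "protein")
        logger.info("stage=protein_dea cond=%s genes=%d up=%d down=%d",
                    cond, len(res), ud["up"], ud["down"])
    counts = inputs["counts"]
    count_groups = {s: s.rsplit("_", 1)[0] for s in counts.columns}
    mrna_dea: dict[str, pd.DataFrame] = {}
    for tp in MRNA_TIMEPOINTS:
        res = dea.nb_count_dea(counts, count_groups, (tp, "ctrl"))
        mrna_dea[tp] = res
        _, ud = dea.call_significant(res, "mrna")
        logger.info("stage=mrna_dea tp=%s genes=%d up=%d down=%d",
                    tp, len(res), ud["up"], ud["down"])

    # --- drug screen ------------------------------------------------------
    screen_table, calls = screen.score_screen(
        inputs["wells"], t=cfg.activity_threshold, hit_cutoff=cfg.sdss_cutoff,
        se_cutoff=cfg.se_cutoff)
    hit_table = screen.screen_summary(calls, inputs["annotation"])
    logger.info("stage=screen compounds=%d hits=%d", len(calls), len(hit_table))

    # --- integration ------------------------------------------------------
    joint, overlap = integrate.merge_omics(mrna_dea["gef24"], protein_dea["gef24"])
    consensus = integrate.consensus_chip_targets(inputs["chip"], cfg.min_chip_experiments)
    candidates = integrate.candidate_targets(consensus, protein_dea, direction="up")
    hit_targets = integrate.map_hit_targets(hit_table, inputs["annotation"],
                                            mrna_dea["gef24"], protein_dea["gef24"])
    logger.info("stage=integrate overlap_both=%d consensus=%d candidates=%d",
                overlap["both"], len(consensus), len(candidates.genes))

    # --- enrichment -------------------------------------------------------
    background = {str(g) for g in matrix.genes}
    ora_tables: dict[str, pd.DataFrame] = {}
    for cond, res in protein_dea.items():
        regulated = set(res.loc[res["significant"], "gene"]) & background
        ora_tables[cond] = enrich.ora(regulated, inputs["gene_sets"], background,
                                      fdr_cutoff=cfg.ora_fdr)
        logger.info("stage=ora cond=%s query=%d enriched=%d",
                    cond, len(regulated), int(ora_tables[cond]["enriched"].sum()))

    summary = {
        "n_proteins_quantified": int(len(matrix.genes)),
        "n_proteins_fdr_pass": int(picked["passed"].sum()),
        "n_mrnas_quantified": int(len(mrna_dea["gef24"])),
        "overlap_both_layers": overlap["both"],
        "n_screen_hits": int(len(hit_table)),
        "n_consensus_targets": int(len(consensus)),
        "n_candidates": int(len(candidates.genes)),
        "protein_up_down": {c: dea.call_significant(t, "protein")[1] for c, t in protein_dea.items()},
        "mrna_up_down": {c: dea.call_significant(t, "mrna")[1] for c, t in mrna_dea.items()},
        "config_hash": chash,
    }

    result = PipelineResult(
        protein_matrix=matrix, protein_dea=protein_dea, mrna_dea=mrna_dea,
        picked_fdr=picked, screen_table=screen_table, synergy_calls=calls,
        hit_table=hit_table, consensus=consensus, candidates=candidates,
        hit_target_table=hit_targets, ora_tables=ora_tables,
        summary=summary, truth=truth)

    if out_dir is not None:
        _write_outputs(result, cfg, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    io.write_ratio_matrix(result.protein_matrix, out_dir / "protein_matrix.tsv", chash)
    io.write_table(result.picked_fdr, out_dir / "picked_fdr.tsv", chash)
    for cond, res in result.protein_dea.items():
        io.write_dea(res, out_dir / f"dea_protein_{cond}.tsv", chash)
    for tp, res in result.mrna_dea.items():
        io.write_dea(res, out_dir / f"dea_mrna_{tp}.tsv", chash)
    io.write_table(result.screen_table, out_dir / "screen_curves.tsv", chash)
    io.write_table(result.hit_table, out_dir / "screen_hits.tsv", chash)
    io.write_gene_list(result.consensus, out_dir / "chip_consensus.txt")
    io.write_gene_list(result.candidates.genes, out_dir / "candidates.txt")
    io.write_table(result.hit_target_table, out_dir / "hit_targets.tsv", chash)
    for cond, tab in result.ora_tables.items():
        io.write_table(tab, out_dir / f"ora_{cond}.tsv", chash)
    with open(out_dir / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
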