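"""Cross-layer set logic: omics overlap, annotation, ChIP consensus, candidates.

These operations combine the differential-expression layers with
external evidence tables: Venn-style overlaps of the mRNA and protein
layers, per-category counts against regulator annotations (TFs,
kinases, ...), consensus filtering of transcription-factor ChIP target
lists across experiments, intersection of the consensus targets with
up-regulated proteins to derive regulated-candidate sets, and the
regulation status of drug-screen hit targets.  Gene identity is the
upper-cased symbol string throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    genes: set[str]
    provenance: str


def _norm(gene: str) -> str:
    return str(gene).strip().upper()


def merge_omics(mrna: pd.DataFrame, protein: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full outer join of the two DEA layers with overlap counts.

    Returns the joint table (suffixes ``_mrna`` / ``_protein``) and the
    counts: genes quantified only at mRNA level, only at protein level,
    at both, and significantly regulated at both.
    """
    for name, df in (("mrna", mrna), ("protein", protein)):
        dup = df["gene"][df["gene"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene rows in {name} table: {sorted(set(dup))[:5]}")
    joint = mrna.merge(protein, on="gene", how="outer", suffixes=("_mrna", "_protein"), sort=True)
    in_m = joint["log2fc_mrna"].notna()
    in_p = joint["log2fc_protein"].notna()
    sig_m = joint["significant_mrna"].eq(True)
    sig_p = joint["significant_protein"].eq(True)
    counts = {
        "mrna_only": int((in_m & ~in_p).sum()),
        "protein_only": int((in_p & ~in_m).sum()),
        "both": int((in_m & in_p).sum()),
        "regulated_both": int((sig_m & sig_p).sum()),
    }
    return joint, counts


def annotate_genes(subset: set[str], category_tables: pd.DataFrame) -> dict[str, int]:
    """Count members of ``subset`` in each annotation category.

    ``category_tables`` has columns gene, category (multi-label allowed);
    a gene may be counted in several categories.
    """
    subset = {_norm(g) for g in subset}
    counts: dict[str, int] = {}
    for category, grp in category_tables.groupby("category", sort=True):
        members = {_norm(g) for g in grp["gene"]}
        counts[str(category)] = len(members & subset)
    return counts


def consensus_chip_targets(evidence: pd.DataFrame, min_experiments: int = 4) -> set[str]:
    """Genes supported by at least ``min_experiments`` ChIP experiments.

    ``evidence`` has columns gene, experiment_id; duplicate
    (gene, experiment) pairs count once.
    """
    n_exp = evidence["experiment_id"].nunique()
    if not 1 <= min_experiments <= max(n_exp, 1):
        raise ValueError(f"min_experiments={min_experiments} outside [1, {n_exp}]")
    per_gene = evidence.drop_duplicates(["gene", "experiment_id"]).groupby("gene")["experiment_id"].nunique()
    return {_norm(g) for g in per_gene[per_gene >= min_experiments].index}


def candidate_targets(
    consensus: set[str],
    dea_by_condition: dict[str, pd.DataFrame],
    direction: str = "up",
) -> CandidateSet:
    """Consensus ChIP targets that are significantly regulated in >=1 condition.

    ``direction='up'`` keeps genes significantly up-regulated (log2fc > 0)
    in at least one of the supplied DEA tables; ``'down'`` is symmetric.
    """
    if direction not in {"up", "down"}:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    regulated: set[str] = set()
    for cond, dea in dea_by_condition.items():
        sig = dea["significant"].astype(bool)
        if direction == "up":
            sel = sig & (dea["log2fc"] > 0)
        else:
            sel = sig & (dea["log2fc"] < 0)
        regulated |= {_norm(g) for g in dea.loc[sel, "gene"]}
    genes = {_norm(g) for g in consensus} & regulated
    prov = f"chip>=consensus ∩ {direction}-in->=1-of-{len(dea_by_condition)}-conditions"
    return CandidateSet(genes=genes, provenance=prov)


def map_hit_targets(
    hits: pd.DataFrame,
    annotation: pd.DataFrame,
    mrna: pd.DataFrame | None,
    protein: pd.DataFrame | None,
) -> pd.DataFrame:
    """Regulation status of every target of every screen hit.

    ``hits`` is the screen hit table (column ``compound``); ``annotation``
    maps compound -> target (union over sources).  Each target in the
    union is flagged for significant up-regulation at mRNA and protein
    level when those DEA tables are given.
    """
    hit_compounds = set(hits["compound"]) if len(hits) else set()
    targets = sorted({
        _norm(t) for c, t in zip(annotation["compound"], annotation["target"])
        if c in hit_compounds
    })

    def up_set(dea: pd.DataFrame | None) -> set[str]:
        if dea is None or dea.empty:
            return set()
        sel = dea["significant"].astype(bool) & (dea["log2fc"] > 0)
        return {_norm(g) for g in dea.loc[sel, "gene"]}

    up_m, up_p = up_set(mrna), up_set(protein)
    return pd.DataFrame({
        "target": targets,
        "up_mrna": [t in up_m for t in targets],
        "up_protein": [t in up_p for t in targets],
    })
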