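"""Isobaric (TMT 10-plex) protein quantification.

Turns PSM-level reporter-ion intensities into a gene x sample matrix of
log2 relative abundances using median sweeping: each PSM's log2
intensities are centred on their row median, per-gene ratios are the
per-channel median over the PSMs unique to that gene, and the resulting
matrix is column-median centred.  Two multiplex sets that share a pooled
internal-reference channel can be bridged onto a common scale.  Protein
identification confidence is controlled with a picked target/decoy FDR
computed on gene symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical TMT 10-plex reporter channel labels
TMT_CHANNELS = [
    "tmt_126", "tmt_127N", "tmt_127C", "tmt_128N", "tmt_128C",
    "tmt_129N", "tmt_129C", "tmt_130N", "tmt_130C", "tmt_131",
]


@dataclass
class ProteinRatioMatrix:
    """Gene x sample log2 relative abundances plus per-gene PSM counts.

    ``values`` rows are indexed by gene symbol, columns by sample label.
    ``n_psms`` is the number of unique PSMs that contributed to each row.
    """

    values: pd.DataFrame
    n_psms: pd.Series

    def __post_init__(self) -> None:
        self.n_psms = self.n_psms.reindex(self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def sweep_psm_ratios(psm: pd.DataFrame, channels: list[str] | None = None) -> pd.DataFrame:
    """Row-centre PSM reporter intensities on the log2 scale.

    Each PSM's channel intensities are log2-transformed and the row
    median is subtracted, making every PSM a vector of within-spectrum
    relative abundances (row median exactly 0).  Missing channels are
    ignored by the median.  PSMs with fewer than two quantified channels
    carry no relative information and are dropped with a warning.

    Parameters
    ----------
    psm:
        PSM table with metadata columns (``psm_id``, ``gene``, ``unique``,
        ``set_id``) and positive reporter intensities in ``channels``.
    channels:
        Reporter column names; defaults to the TMT 10-plex labels.
    """
    channels = list(channels or TMT_CHANNELS)
    missing = [c for c in channels if c not in psm.columns]
    if missing:
        raise ValueError(f"PSM table lacks reporter columns: {missing}")
    inten = psm[channels].to_numpy(dtype=float)
    if np.any(inten[np.isfinite(inten)] <= 0):
        raise ValueError("reporter intensities must be strictly positive")
    n_obs = np.isfinite(inten).sum(axis=1)
    keep = n_obs >= 2
    if not keep.all():
        logger.warning("dropping %d PSM(s) with <2 quantified channels", int((~keep).sum()))
    with np.errstate(invalid="ignore"):
        log2 = np.log2(inten[keep])
    ratios = log2 - np.nanmedian(log2, axis=1, keepdims=True)
    out = psm.loc[keep, [c for c in psm.columns if c not in channels]].copy()
    out[channels] = ratios
    return out


def aggregate_protein_ratios(
    psm_ratios: pd.DataFrame,
    channels: list[str] | None = None,
    min_psms: int = 1,
) -> ProteinRatioMatrix:
    """Collapse row-centred PSM ratios to per-gene medians.

    Only PSMs flagged unique to a single gene are used; for each gene the
    per-channel median over its unique PSMs is taken.  Genes with fewer
    than ``min_psms`` unique PSMs are excluded.
    """
    channels = list(channels or TMT_CHANNELS)
    uniq = psm_ratios[psm_ratios["unique"].astype(bool)]
    dropped = psm_ratios.loc[~psm_ratios["unique"].astype(bool), "gene"].unique()
    grouped = uniq.groupby("gene", sort=True)
    values = grouped[channels].median()
    n_psms = grouped.size().rename("n_psms")
    lost = set(dropped) - set(values.index)
    if lost:
        logger.warning("excluding %d gene(s) with no unique PSMs", len(lost))
    keep = n_psms >= min_psms
    return ProteinRatioMatrix(values=values.loc[keep], n_psms=n_psms.loc[keep])


def center_columns(matrix: ProteinRatioMatrix) -> ProteinRatioMatrix:
    """Median-centre each sample column (idempotent)."""
    if matrix.values.empty:
        raise ValueError("cannot centre an empty matrix")
    centred = matrix.values - matrix.values.median(axis=0, skipna=True)
    return ProteinRatioMatrix(values=centred, n_psms=matrix.n_psms.copy())


def quantify(psm: pd.DataFrame, channels: list[str] | None = None, min_psms: int = 1) -> ProteinRatioMatrix:
    """sweep -> aggregate -> centre, the full per-set quantification."""
    return center_columns(aggregate_protein_ratios(sweep_psm_ratios(psm, channels), channels, min_psms))


def bridge_sets(
    set1: ProteinRatioMatrix,
    set2: ProteinRatioMatrix,
    reference_label: str = "ref",
    set_prefixes: tuple[str, str] = ("set1", "set2"),
) -> ProteinRatioMatrix:
    """Combine two multiplex sets through their pooled-reference channel.

    Within each set every sample column is expressed relative to that
    set's internal-reference column (log2 ratio-to-reference); the
    reference columns are then dropped and the sets joined on the genes
    quantified in both.  Any set-level additive offset cancels, so the
    combined matrix is comparable across sets.
    """
    frames = []
    n_psms = []
    for mat, prefix in zip((set1, set2), set_prefixes):
        ref_cols = [c for c in mat.samples if c == reference_label or c.endswith(f":{reference_label}")]
        if len(ref_cols) != 1:
            raise ValueError(
                f"set {prefix!r} must contain exactly one reference column "
                f"{reference_label!r}; found {ref_cols}"
            )
        rel = mat.values.sub(mat.values[ref_cols[0]], axis=0).drop(columns=ref_cols)
        rel.columns = [f"{prefix}:{c}" for c in rel.columns]
        frames.append(rel)
        n_psms.append(mat.n_psms)
    shared = frames[0].index.intersection(frames[1].index)
    logger.info(
        "bridging: %d + %d genes, overlap %d", len(frames[0]), len(frames[1]), len(shared)
    )
    combined = pd.concat([frames[0].loc[shared], frames[1].loc[shared]], axis=1)
    total_psms = n_psms[0].loc[shared] + n_psms[1].loc[shared]
    return ProteinRatioMatrix(values=combined, n_psms=total_psms)


def picked_protein_fdr(scored: pd.DataFrame, fdr_cutoff: float = 0.01) -> pd.DataFrame:
    """Picked target/decoy protein FDR on gene symbols.

    For every gene symbol only the higher-scoring of its target/decoy
    entries competes (score ties keep the target).  Picked entries are
    ranked by decreasing score; the FDR at rank k is
    ``#decoys(<=k) / #targets(<=k)`` (0/0 -> 0, capped at 1) and the
    q-value is the running minimum of FDR from the bottom of the list.

    Parameters
    ----------
    scored:
        Columns ``gene``, ``is_decoy`` (bool), ``score``.
    fdr_cutoff:
        q-value threshold for the ``passed`` flag (default 1% FDR).

    Returns
    -------
    DataFrame with columns gene, is_decoy, score, q_value, passed —
    exactly one picked row per gene symbol, sorted by decreasing score.
    """
    if not np.isfinite(scored["score"]).all():
        raise ValueError("scores must be finite")
    df = scored.copy()
    df["is_decoy"] = df["is_decoy"].astype(bool)
    # stable pick: highest score wins, target wins ties
    df = df.sort_values(["gene", "score", "is_decoy"], ascending=[True, False, True])
    picked = df.groupby("gene", sort=True).head(1)
    picked = picked.sort_values(["score", "gene"], ascending=[False, True]).reset_index(drop=True)
    n_decoy = picked["is_decoy"].cumsum().to_numpy(dtype=float)
    n_target = (~picked["is_decoy"]).cumsum().to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_target > 0, n_decoy / np.maximum(n_target, 1), np.where(n_decoy > 0, 1.0, 0.0))
    fdr = np.minimum(fdr, 1.0)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    picked["q_value"] = q
    picked["passed"] = (~picked["is_decoy"]) & (picked["q_value"] <= fdr_cutoff)
    return picked
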