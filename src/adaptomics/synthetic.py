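"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one input class of the analysis at desk scale
and records the planted truth (differential genes, synergistic
compounds, consensus ChIP targets) so downstream stages have an exact
recovery target:

* two TMT 10-plex PSM tables with triplicate conditions and a pooled
  internal-reference channel (channel 10),
* negative-binomial mRNA count matrices with planted time-dependent
  log2 fold changes,
* mono/combination drug-screen plates with log-logistic dose responses
  on a five-dose, 10-fold dilution ladder plus DMSO / benzethonium
  control wells,
* seven transcription-factor ChIP experiments with planted consensus
  targets, and
* target/decoy protein score tables for picked-FDR testing.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import TMT_CHANNELS

REFERENCE_CHANNEL = TMT_CHANNELS[-1]  # channel 10 carries the pooled reference


@dataclass
class SetDesign:
    """Channel layout of one 10-plex set: channel -> sample label.

    Sample labels are ``condition:replicate``; the reference channel is
    labelled ``ref``.
    """

    set_id: str
    channels: dict[str, str]

    @property
    def reference_channel(self) -> str:
        for ch, label in self.channels.items():
            if label == "ref":
                return ch
        raise ValueError(f"set {self.set_id!r} has no reference channel")

    def condition_of(self, channel: str) -> str:
        label = self.channels[channel]
        return label if label == "ref" else label.split(":", 1)[0]


@dataclass
class SimTruth:
    """Planted ground truth of a simulation run."""

    seed: int
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    synergist_compounds: set[str] = field(default_factory=set)
    consensus_genes: set[str] = field(default_factory=set)
    extras: dict = field(default_factory=dict)


def default_psm_designs() -> list[SetDesign]:
    """Two 10-plex sets: triplicate control-silencing and target-silencing
    arms over untreated / 24 h / 48 h drug treatment, pooled reference in
    channel 10 of each set."""
    designs = []
    for set_id, arm in (("set1", "siCtrl"), ("set2", "siKD")):
        channels: dict[str, str] = {}
        i = 0
        for cond in ("untreated", "gef24", "gef48"):
            for rep in (1, 2, 3):
                channels[TMT_CHANNELS[i]] = f"{arm}_{cond}:{rep}"
                i += 1
        channels[REFERENCE_CHANNEL] = "ref"
        designs.append(SetDesign(set_id=set_id, channels=channels))
    return designs


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def generate_psm_tables(
    n_genes: int = 2000,
    psm_per_gene: float = 3.0,
    designs: list[SetDesign] | None = None,
    effects: dict[str, dict[str, float]] | None = None,
    noise_sd: float = 0.2,
    shared_rate: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], SimTruth]:
    """Simulate PSM-level reporter intensity tables for each 10-plex set.

    The log2 intensity of a PSM in a sample channel is
    gene baseline + per-PSM offset + planted condition effect + noise.
    The reference channel carries the pooled internal-reference sample —
    a physical pool of ALL sample channels across ALL sets — so its
    expected intensity is the mean intensity over every sample condition
    in the experiment and it cancels exactly when sets are bridged.
    A ``shared_rate`` fraction of extra PSMs are flagged non-unique and
    must be ignored by quantification.

    Parameters
    ----------
    psm_per_gene:
        Mean PSM count per gene; actual counts are 1 + Poisson(mean - 1).
    effects:
        gene -> {condition: log2 fold change vs baseline}.
    noise_sd:
        Channel noise in log2 units (>= 0; 0 gives exact recovery).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    designs = designs if designs is not None else default_psm_designs()
    if not designs:
        raise ValueError("need at least one set design")
    effects = effects or {}
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    baseline = rng.normal(16.0, 1.5, size=n_genes)
    n_psms = 1 + rng.poisson(max(psm_per_gene - 1.0, 0.0), size=n_genes)
    # the pooled reference mixes every sample condition of every set
    pool_conditions = [d.condition_of(ch) for d in designs
                       for ch in d.channels if d.channels[ch] != "ref"]
    pool_factor = {
        g: float(np.mean([2.0 ** effects.get(g, {}).get(c, 0.0) for c in pool_conditions]))
        for g in effects
    }
    tables: dict[str, pd.DataFrame] = {}
    for design in designs:
        ref_ch = design.reference_channel
        sample_chs = [ch for ch in TMT_CHANNELS if ch != ref_ch]
        rows = []
        psm_counter = 0
        for gi, gene in enumerate(genes):
            gene_fx = effects.get(gene, {})
            for _ in range(n_psms[gi]):
                offset = rng.normal(0.0, 1.0)
                row: dict[str, object] = {
                    "psm_id": f"{design.set_id}_psm{psm_counter:07d}",
                    "gene": gene, "unique": True, "set_id": design.set_id,
                }
                for ch in sample_chs:
                    cond = design.condition_of(ch)
                    lv = baseline[gi] + offset + gene_fx.get(cond, 0.0)
                    if noise_sd > 0:
                        lv += rng.normal(0.0, noise_sd)
                    row[ch] = 2.0 ** lv
                ref_lv = baseline[gi] + offset + np.log2(pool_factor.get(gene, 1.0))
                if noise_sd > 0:
                    ref_lv += rng.normal(0.0, noise_sd)
                row[ref_ch] = 2.0 ** ref_lv
                rows.append(row)
                psm_counter += 1
        # non-unique PSMs: quantified but flagged shared
        n_shared = rng.binomial(len(rows), shared_rate)
        for j in range(n_shared):
            gi = int(rng.integers(n_genes))
            offset = rng.normal(0.0, 1.0)
            row = {
                "psm_id": f"{design.set_id}_shared{j:05d}",
                "gene": genes[gi], "unique": False, "set_id": design.set_id,
            }
            log2_vals = []
            for ch in sample_chs:
                lv = baseline[gi] + offset + rng.normal(0.0, max(noise_sd, 0.0) or 0.0)
                log2_vals.append(lv)
                row[ch] = 2.0 ** lv
            row[ref_ch] = float(np.mean(2.0 ** np.asarray(log2_vals)))
            rows.append(row)
        cols = ["psm_id", "gene", "unique", "set_id"] + TMT_CHANNELS
        tables[design.set_id] = pd.DataFrame(rows)[cols]
    truth = SimTruth(seed=seed, de_genes={g: dict(fx) for g, fx in effects.items()})
    return tables, truth


def default_count_design() -> dict[str, str]:
    """Triplicate RNA samples: untreated control and 2/6/24 h drug treatment."""
    design = {}
    for cond in ("ctrl", "gef2", "gef6", "gef24"):
        for rep in (1, 2, 3):
            design[f"{cond}_{rep}"] = cond
    return design


def generate_count_matrix(
    n_genes: int = 5000,
    design: dict[str, str] | None = None,
    dispersion: float = 0.05,
    lfc_spec: dict[str, dict[str, float]] | None = None,
    lib_sizes: dict[str, float] | None = None,
    mean_expression: float = 250.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate an RNA count matrix with planted fold changes.

    Counts are negative-binomial with mean
    ``lib_size * baseline * 2^lfc(gene, condition)`` and gene-wise
    dispersion ``alpha`` (``alpha = 0`` degenerates to Poisson).
    Baselines are log-normal around ``mean_expression``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    design = design if design is not None else default_count_design()
    lfc_spec = lfc_spec or {}
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    baseline = mean_expression * rng.lognormal(0.0, 1.0, size=n_genes)
    samples = list(design)
    lib = np.array([float((lib_sizes or {}).get(s, 1.0)) for s in samples])
    if np.any(lib <= 0):
        raise ValueError("library size factors must be positive")
    mat = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        cond = design[sample]
        lfc = np.array([lfc_spec.get(g, {}).get(cond, 0.0) for g in genes])
        mean = lib[j] * baseline * 2.0**lfc
        if np.any(mean < 0):
            raise ValueError("negative NB mean")
        if dispersion == 0:
            mat[:, j] = rng.poisson(mean)
        else:
            lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
            mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    truth = SimTruth(seed=seed, de_genes={g: dict(v) for g, v in lfc_spec.items()})
    return counts, truth


def generate_screen_plates(
    n_compounds: int = 528,
    n_synergists: int = 17,
    n_doses: int = 5,
    dilution: float = 10.0,
    dose_min: float = 1e-9,
    synergy_shift: float = -1.5,
    efficacy_shift: float = 0.0,
    noise_sd: float = 0.0,
    compounds_per_plate: int = 40,
    neg_signal: float = 100000.0,
    pos_signal: float = 2000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate mono + combination screen plates with planted synergists.

    Every compound gets a random 4PL inhibition curve (top U[0,100],
    bottom 0, slope U[0.5,3], inflection uniform over the tested log10
    window).  Planted synergists are drawn with potency headroom (top
    U[60,100], slope U[1,3], inflection in the upper half of the
    window) and have their combination-arm curve shifted left by
    ``synergy_shift`` log10 units (a potency gain) and optionally up by
    ``efficacy_shift`` % (efficacy gain); all other compounds respond
    identically in both arms, so their expected synergy score is zero.  Well signals interpolate linearly between
    the DMSO (negative) and benzethonium-chloride (positive) control
    levels, with Gaussian noise of ``noise_sd`` % inhibition units.

    The truth records the planted synergist ids and, under ``extras``,
    the generating curve parameters per compound and arm.
    """
    if n_doses < 2:
        raise ValueError("need at least 2 doses")
    if dilution <= 1:
        raise ValueError("dilution must be > 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    doses = dose_min * dilution ** np.arange(n_doses)
    x = np.log10(doses)
    compounds = [f"C{i:04d}" for i in range(n_compounds)]
    synergists = set(rng.choice(compounds, size=min(n_synergists, n_compounds), replace=False).tolist())
    curves: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    rows = []
    plate_of = {c: f"plate{(i // compounds_per_plate) + 1:02d}" for i, c in enumerate(compounds)}
    x_mid = 0.5 * (x.min() + x.max())
    for comp in compounds:
        if comp in synergists:
            top = float(rng.uniform(60.0, 100.0))
            slope = float(rng.uniform(1.0, 3.0))
            infl = float(rng.uniform(x_mid, x.max()))
        else:
            top = float(rng.uniform(0.0, 100.0))
            slope = float(rng.uniform(0.5, 3.0))
            infl = float(rng.uniform(x.min(), x.max()))
        for arm in ("mono", "combo"):
            a, c = top, infl
            if arm == "combo" and comp in synergists:
                c = infl + synergy_shift
                a = top + efficacy_shift
                if not -1.0 <= a <= 101.0:
                    raise ValueError(
                        f"efficacy_shift drives top response to {a:.1f}%, outside [0, 100]"
                    )
                a = float(np.clip(a, 0.0, 100.0))
            curves[(comp, arm)] = (a, 0.0, slope, c)
            inhib = a / (1.0 + 10.0 ** (slope * (c - x)))
            if noise_sd > 0:
                inhib = inhib + rng.normal(0.0, noise_sd, size=n_doses)
            via = 100.0 - inhib
            signal = pos_signal + (neg_signal - pos_signal) * via / 100.0
            for k in range(n_doses):
                rows.append({
                    "plate_id": plate_of[comp], "well": f"{comp}_{arm}_d{k + 1}",
                    "compound": comp, "arm": arm, "conc_molar": doses[k],
                    "signal": signal[k], "control": "none",
                })
    # control wells per plate
    for plate_id in sorted(set(plate_of.values())):
        for i in range(16):
            v = 100.0 + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"plate_id": plate_id, "well": f"neg{i + 1}", "compound": "DMSO",
                         "arm": "ctrl", "conc_molar": 0.0,
                         "signal": pos_signal + (neg_signal - pos_signal) * v / 100.0,
                         "control": "neg"})
        for i in range(8):
            v = (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"plate_id": plate_id, "well": f"pos{i + 1}", "compound": "BzCl",
                         "arm": "ctrl", "conc_molar": 0.0,
                         "signal": pos_signal + (neg_signal - pos_signal) * v / 100.0,
                         "control": "pos"})
    wells = pd.DataFrame(rows, columns=["plate_id", "well", "compound", "arm",
                                        "conc_molar", "signal", "control"])
    truth = SimTruth(seed=seed, synergist_compounds=synergists,
                     extras={"curves": curves, "x_window": (float(x.min()), float(x.max()))})
    return wells, truth


def generate_chip_experiments(
    universe: list[str],
    consensus_genes: set[str],
    n_experiments: int = 7,
    min_experiments: int = 4,
    background_rate: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate TF ChIP target lists across experiments.

    Every consensus gene is planted into at least ``min_experiments``
    experiments (uniformly between that floor and all of them); every
    universe gene additionally enters each experiment independently with
    probability ``background_rate``.
    """
    if not 0.0 <= background_rate <= 1.0:
        raise ValueError("background_rate must lie in [0, 1]")
    consensus_genes = set(consensus_genes)
    if not consensus_genes <= set(universe):
        raise ValueError("consensus genes must be drawn from the universe")
    rng = np.random.default_rng(seed)
    exp_ids = [f"chip{i + 1}" for i in range(n_experiments)]
    membership: dict[str, set[str]] = {g: set() for g in universe}
    for gene in sorted(consensus_genes):
        k = int(rng.integers(min_experiments, n_experiments + 1))
        chosen = rng.choice(exp_ids, size=k, replace=False)
        membership[gene].update(chosen.tolist())
    if background_rate > 0:
        hits = rng.random((len(universe), n_experiments)) < background_rate
        for gi, gene in enumerate(universe):
            membership[gene].update(e for e, h in zip(exp_ids, hits[gi]) if h)
    rows = [{"gene": g, "experiment_id": e}
            for g in universe for e in sorted(membership[g])]
    evidence = pd.DataFrame(rows, columns=["gene", "experiment_id"])
    truth = SimTruth(seed=seed, consensus_genes=consensus_genes)
    return evidence, truth


def generate_decoy_scores(
    n_genes: int = 1000,
    target_shift: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimTruth]:
    """One target and one decoy score per gene symbol.

    Decoy scores are standard normal; target scores are shifted up by
    ``target_shift`` (0 makes targets and decoys exchangeable, the null
    for FDR calibration).
    """
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    rows = []
    for gi, gene in enumerate(genes):
        rows.append({"gene": gene, "is_decoy": False,
                     "score": float(rng.normal(target_shift, 1.0))})
        rows.append({"gene": gene, "is_decoy": True,
                     "score": float(rng.normal(0.0, 1.0))})
    truth = SimTruth(seed=seed)
    return pd.DataFrame(rows), truth


def generate_gene_sets(
    universe: list[str],
    enriched_genes: set[str] | None = None,
    n_sets: int = 20,
    set_size: int = 50,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Random gene-set collection; the first set over-samples
    ``enriched_genes`` so one planted enrichment signal exists."""
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    uni = np.asarray(universe)
    for i in range(n_sets):
        name = f"SET_{i:03d}"
        if i == 0 and enriched_genes:
            planted = sorted(enriched_genes)[: set_size // 2]
            rest = rng.choice(uni, size=max(set_size - len(planted), 0), replace=False)
            sets[name] = set(planted) | set(rest.tolist())
        else:
            sets[name] = set(rng.choice(uni, size=min(set_size, len(uni)), replace=False).tolist())
    return sets
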