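"""Dose-response screen scoring: plate normalisation, 4PL fits, DSS and sDSS.

The screen format is a multi-dose single-agent plate assay: each
compound is tested at five concentrations on a 10-fold dilution ladder
(a 10,000-fold range), alone (mono arm) and together with a fixed
concentration of an anchor drug (combo arm).  Plates carry negative
(DMSO) and positive (benzethonium chloride) viability controls used for
per-plate normalisation to percent inhibition.  Each arm is fitted with
a four-parameter log-logistic curve

    y(x) = d + (a - d) / (1 + 10^(b (c - x))),    x = log10 dose,

and summarised by the drug sensitivity score (DSS): the area between
the curve and an activity threshold t over the tested log-concentration
window, normalised so a curve pinned at 100% inhibition scores 100.
Synergy is the difference sDSS = DSS_combo - DSS_mono; compounds with
sDSS above a cutoff (default 5) and acceptable fit quality in both arms
are called combination hits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


@dataclass
class DoseResponseSeries:
    compound: str
    arm: str                 # "mono" or "combo"
    doses: np.ndarray        # molar concentrations, strictly increasing
    responses: np.ndarray    # % inhibition
    plate_id: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError(f"{self.compound}/{self.arm}: doses must be strictly increasing")


@dataclass
class FittedCurve:
    top: float               # a, max asymptote (% inhibition)
    bottom: float            # d (%)
    slope: float             # b > 0
    inflection: float        # c, log10 molar
    converged: bool
    residual_se: float       # % units

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        """% inhibition at log10 dose x."""
        return self.bottom + (self.top - self.bottom) / (
            1.0 + 10.0 ** (self.slope * (self.inflection - np.asarray(x, dtype=float)))
        )


@dataclass
class DssResult:
    compound: str
    arm: str
    dss: float
    variant: str = "DSS1"
    excluded: bool = False
    activity_threshold: float = 10.0


@dataclass
class SynergyCall:
    compound: str
    sdss: float
    is_hit: bool


def normalize_plate(wells: pd.DataFrame,
                    clip_range: tuple[float, float] | None = (0.0, 100.0)) -> list[DoseResponseSeries]:
    """Convert raw well signals to % inhibition series, per plate.

    ``wells`` columns: plate_id, well, compound, arm, conc_molar, signal,
    control in {none, neg, pos}.  Viability is linear between the mean
    negative (DMSO, 100% viable) and positive (toxic, 0% viable) control
    signals; inhibition = 100 - viability.  Normalised responses are then
    clamped to ``clip_range`` (the assay's physical domain) so that
    reader noise outside [0, 100] does not masquerade as lack of fit;
    pass ``clip_range=None`` to keep raw normalised values.
    """
    series: list[DoseResponseSeries] = []
    for plate_id, plate in wells.groupby("plate_id", sort=True):
        neg = plate.loc[plate["control"] == "neg", "signal"]
        pos = plate.loc[plate["control"] == "pos", "signal"]
        if len(neg) < 2 or len(pos) < 2:
            raise ValueError(f"plate {plate_id!r}: need >=2 wells per control")
        mean_neg, mean_pos = neg.mean(), pos.mean()
        if mean_neg <= mean_pos:
            raise ValueError(
                f"plate {plate_id!r}: negative-control signal ({mean_neg:.3g}) must exceed "
                f"positive-control signal ({mean_pos:.3g})"
            )
        drugged = plate[plate["control"] == "none"]
        for (compound, arm), grp in drugged.groupby(["compound", "arm"], sort=True):
            grp = grp.sort_values("conc_molar")
            viability = 100.0 * (grp["signal"].to_numpy() - mean_pos) / (mean_neg - mean_pos)
            inhibition = 100.0 - viability
            if clip_range is not None:
                inhibition = np.clip(inhibition, *clip_range)
            series.append(DoseResponseSeries(
                compound=str(compound), arm=str(arm),
                doses=grp["conc_molar"].to_numpy(),
                responses=inhibition,
                plate_id=str(plate_id),
            ))
    return series


def fit_4pl(series: DoseResponseSeries, max_top: float = 100.0) -> FittedCurve:
    """Bounded least-squares fit of the 4PL curve to one dose series.

    Bounds: top in [0, 100], bottom in [0, top], slope in (0, 10],
    inflection within +/-2 log10 units of the tested dose window.  On
    optimizer failure a flat curve at the mean response is returned with
    ``converged=False``.
    """
    x = np.log10(series.doses)
    y = series.responses
    if np.unique(x).size < 4:
        raise ValueError(f"{series.compound}/{series.arm}: need >=4 distinct doses")

    def resid(p: np.ndarray) -> np.ndarray:
        a, d_frac, b, c = p
        d = d_frac * a
        return d + (a - d) / (1.0 + 10.0 ** (b * (c - x))) - y

    # parameterise bottom as a fraction of top so 0 <= d <= a holds in-box
    y_span = max(y.max() - max(y.min(), 0.0), 1.0)
    p0 = np.array([
        np.clip(y.max(), 1.0, max_top),
        np.clip(max(y.min(), 0.0) / max(y.max(), 1.0), 0.0, 1.0),
        1.0,
        x[np.argmin(np.abs(y - (max(y.min(), 0.0) + y_span / 2.0)))],
    ])
    lb = np.array([0.0, 0.0, 1e-3, x.min() - 2.0])
    ub = np.array([max_top, 1.0, 10.0, x.max() + 2.0])
    p0 = np.clip(p0, lb, ub)
    try:
        cost0 = 0.5 * float(np.sum(resid(p0) ** 2))
        sol = least_squares(resid, p0, bounds=(lb, ub), method="trf", max_nfev=2000)
        # status 0 (iteration cap) still counts when the fit improved on p0
        ok = np.isfinite(sol.x).all() and (sol.success or sol.cost <= cost0)
    except Exception:
        ok = False
    n = y.size
    dof = max(n - 4, 1)
    if not ok:
        flat = float(np.clip(y.mean(), 0.0, max_top))
        se = float(np.sqrt(np.sum((y - flat) ** 2) / dof))
        logger.warning("%s/%s: 4PL fit failed, flat fallback", series.compound, series.arm)
        return FittedCurve(top=flat, bottom=flat, slope=1.0, inflection=float(x.mean()),
                           converged=False, residual_se=se)
    a, d_frac, b, c = sol.x
    se = float(np.sqrt(np.sum(sol.fun**2) / dof))
    return FittedCurve(top=float(a), bottom=float(d_frac * a), slope=float(b),
                       inflection=float(c), converged=True, residual_se=se)


def _area_above(curve: FittedCurve, t: float, x_lo: float, x_hi: float) -> float:
    """Closed-form integral of (y(x) - t) from x_lo to x_hi.

    Uses the antiderivative of the log-logistic,
    F(x) = d x + (a - d) ln(1 + 10^(b (x - c))) / (b ln 10).
    """
    a, d, b, c = curve.top, curve.bottom, curve.slope, curve.inflection

    def F(x: float) -> float:
        return d * x + (a - d) * np.log1p(10.0 ** (b * (x - c))) / (b * LOG10)

    return F(x_hi) - F(x_lo) - t * (x_hi - x_lo)


def compute_dss(
    curve: FittedCurve,
    x_min: float,
    x_max: float,
    t: float = 10.0,
    variant: str = "DSS1",
    compound: str = "",
    arm: str = "",
    extra_norm: float = 1.0,
) -> DssResult:
    """Drug sensitivity score over the log10 dose window [x_min, x_max].

    The score integrates the fitted inhibition above the activity
    threshold ``t`` from x1 (where the curve crosses t, clipped to the
    window) to x_max and normalises by the full window area
    (100 - t)(x_max - x_min), so DSS1 in [0, 100].  A curve whose top
    asymptote never exceeds ``t`` scores 0.  Variants DSS2/DSS3 divide
    the DSS1 area term by a configurable extra normalisation factor.
    """
    if not x_min < x_max:
        raise ValueError("x_min must be < x_max")
    if variant not in {"DSS1", "DSS2", "DSS3"}:
        raise ValueError(f"unknown DSS variant {variant!r}")
    a, d, b, c = curve.top, curve.bottom, curve.slope, curve.inflection
    if a <= t:
        dss = 0.0
    else:
        if d >= t:
            x1 = x_min  # curve sits above threshold across the whole window
        else:
            x1 = c - np.log10((a - t) / (t - d)) / b
            x1 = float(np.clip(x1, x_min, x_max))
        area = max(_area_above(curve, t, x1, x_max), 0.0)
        dss = 100.0 * area / ((100.0 - t) * (x_max - x_min)) / extra_norm
    return DssResult(compound=compound, arm=arm, dss=float(dss), variant=variant,
                     activity_threshold=t)


def qc_filter(dss: DssResult, curve: FittedCurve, se_cutoff: float = 19.0) -> DssResult:
    """Flag scores whose curve fit standard error exceeds the cutoff.

    The exclusion is strict (> cutoff); a fit with residual SE exactly at
    the cutoff is retained.
    """
    dss.excluded = bool(curve.residual_se > se_cutoff)
    return dss


def compute_sdss(mono: DssResult, combo: DssResult, hit_cutoff: float = 5.0) -> SynergyCall:
    """Synergy score sdss = DSS_combo - DSS_mono with QC-aware hit call."""
    if mono.compound != combo.compound:
        raise ValueError(f"arm mismatch: {mono.compound!r} vs {combo.compound!r}")
    if mono.variant != combo.variant:
        raise ValueError(f"DSS variant mismatch: {mono.variant} vs {combo.variant}")
    sdss = combo.dss - mono.dss
    is_hit = (sdss > hit_cutoff) and not (mono.excluded or combo.excluded)
    return SynergyCall(compound=mono.compound, sdss=float(sdss), is_hit=bool(is_hit))


def score_screen(
    wells: pd.DataFrame,
    t: float = 10.0,
    hit_cutoff: float = 5.0,
    se_cutoff: float = 19.0,
    variant: str = "DSS1",
) -> tuple[pd.DataFrame, list[SynergyCall]]:
    """Normalise, fit and score every compound with mono + combo arms.

    Returns the per-compound-arm table (curve parameters, residual SE,
    DSS, exclusion flag) and the synergy calls.  Non-converged fits are
    retained in the table but excluded from hit calling.
    """
    series = normalize_plate(wells)
    by_compound: dict[str, dict[str, DoseResponseSeries]] = {}
    for s in series:
        by_compound.setdefault(s.compound, {})[s.arm] = s
    rows = []
    calls: list[SynergyCall] = []
    for compound in sorted(by_compound):
        arms = by_compound[compound]
        results: dict[str, DssResult] = {}
        for arm in ("mono", "combo"):
            if arm not in arms:
                continue
            s = arms[arm]
            curve = fit_4pl(s)
            x = np.log10(s.doses)
            res = compute_dss(curve, x.min(), x.max(), t=t, variant=variant,
                              compound=compound, arm=arm)
            res = qc_filter(res, curve, se_cutoff)
            if not curve.converged:
                res.excluded = True
            results[arm] = res
            rows.append({
                "compound": compound, "arm": arm, "dss": res.dss,
                "top": curve.top, "bottom": curve.bottom, "slope": curve.slope,
                "inflection": curve.inflection, "residual_se": curve.residual_se,
                "converged": curve.converged, "excluded": res.excluded,
            })
        if "mono" in results and "combo" in results:
            calls.append(compute_sdss(results["mono"], results["combo"], hit_cutoff))
    return pd.DataFrame(rows), calls


def screen_summary(calls: list[SynergyCall], target_annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hit table sorted by decreasing sDSS with per-hit target lists.

    ``target_annotation`` has columns compound, target (and optionally
    source); targets are the deduplicated union across sources.
    """
    hits = sorted((c for c in calls if c.is_hit), key=lambda c: (-c.sdss, c.compound))
    target_map: dict[str, list[str]] = {}
    if target_annotation is not None and len(target_annotation):
        target_map = (
            target_annotation.groupby("compound")["target"]
            .apply(lambda s: sorted(set(s)))
            .to_dict()
        )
    rows = []
    for call in hits:
        targets = target_map.get(call.compound, [])
        if not targets and target_map:
            logger.info("hit %s has no target annotation", call.compound)
        rows.append({
            "compound": call.compound,
            "sdss": call.sdss,
            "targets": ";".join(targets),
            "n_targets": len(targets),
        })
    return pd.DataFrame(rows, columns=["compound", "sdss", "targets", "n_targets"])
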