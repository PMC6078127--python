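"""Viability-plate analytics and Chou-Talalay synergy calculus.

The plate readout is a resorufin fluorescence proportional to living
cells; the fraction of dead cells (fraction affected, FA) is

    FA = (control - treated) / control

and may be negative when a treatment stimulates growth relative to the
untreated control.  Two dose-effect summaries are provided:

* a linear sensitivity fit of percent dead cells on dose in nM, whose
  slope (% dead cells per nM) implies EC50 = 50 / |slope| nM; and
* the median-effect model fa/(1 - fa) = (D / Dm)^m, fitted by ordinary
  least squares of log10(fa/(1-fa)) on log10(D).

For an n-component mixture dosed at fixed ratio, the combination index
at effect level fa is

    CI = sum_i (f_i * D_combo(fa)) / D_i(fa)

where D_combo(fa) is the total mixture dose reaching fa and D_i(fa) the
single-agent dose doing the same.  CI < 1 signals synergy, CI > 1
antagonism, and CI near 1 additivity; because an exact-1 call is vacuous
under floating point, the additive call spans a band (default
[0.9, 1.1], which matches published tables calling 1.10 additive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PlateRecord",
    "DoseResponseSeries",
    "LinearFit",
    "MedianEffectFit",
    "InteractionResult",
    "fraction_dead",
    "summarize_plate",
    "linear_sensitivity",
    "ec50_from_slope",
    "median_effect_fit",
    "dose_for_effect",
    "combination_index",
    "classify_interaction",
    "interaction_matrix",
]

CONTROL_LABELS = frozenset({"vehicle", "untreated", "control"})
SCRAMBLE_LABEL = "scramble"
ADDITIVE_BAND = (0.9, 1.1)


@dataclass(frozen=True)
class PlateRecord:
    """One well: treatment, total-agent dose in µM, raw fluorescence."""

    well: str
    treatment: str
    dose_uM: float
    fluorescence: float

    def __post_init__(self) -> None:
        if self.dose_uM < 0:
            raise ValueError("dose must be non-negative")
        if self.fluorescence < 0:
            raise ValueError("fluorescence must be non-negative")


@dataclass
class DoseResponseSeries:
    """Mean fraction-affected per dose for one treatment."""

    treatment: str
    doses_uM: np.ndarray
    fa_mean: np.ndarray
    fa_sd: np.ndarray
    n_replicates: np.ndarray
    timepoint: str = "24h"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.doses_uM = np.asarray(self.doses_uM, dtype=float)
        self.fa_mean = np.asarray(self.fa_mean, dtype=float)
        if np.any(np.diff(self.doses_uM) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(self.fa_mean > 1):
            raise ValueError("fraction affected cannot exceed 1")


@dataclass
class LinearFit:
    """OLS of % dead cells on dose in nM, with the slope-implied EC50."""

    treatment: str
    slope: float  # % dead cells per nM
    intercept: float  # %
    r_squared: float
    ec50_uM: float
    cytotoxic: bool = True  # False flags a non-positive slope


@dataclass
class MedianEffectFit:
    """Median-effect line fit: fa/(1-fa) = (D/Dm)^m."""

    treatment: str
    m: float
    Dm_uM: float
    r_squared: float
    n_points: int
    n_excluded: int = 0


@dataclass
class InteractionResult:
    """Combination index of a fixed-ratio mixture at one effect level."""

    components: tuple[str, ...]
    fractions: tuple[float, ...]
    fa: float
    ci: float
    label: str


def fraction_dead(resorufin_control: float, resorufin_treated: float) -> float:
    """(control - treated) / control; negative when treated outgrows control."""
    if resorufin_control <= 0:
        raise ValueError("control signal must be positive")
    if resorufin_treated < 0:
        raise ValueError("treated signal must be non-negative")
    return (resorufin_control - resorufin_treated) / resorufin_control


def summarize_plate(
    records: Sequence[PlateRecord],
    adjust_to_scramble: bool = False,
    timepoint: str = "24h",
) -> list[DoseResponseSeries]:
    """Collapse wells to per-treatment dose-response series.

    FA is computed per well against the mean untreated-control signal.
    With ``adjust_to_scramble``, the plate's mean scramble FA is
    subtracted from every treatment FA (off-target toxicity correction;
    adjusted values may go negative).
    """
    controls = [r.fluorescence for r in records if r.treatment in CONTROL_LABELS]
    if not controls:
        raise ValueError("plate has no untreated-control wells")
    control_mean = float(np.mean(controls))
    scramble_fa = 0.0
    if adjust_to_scramble:
        sc = [
            fraction_dead(control_mean, r.fluorescence)
            for r in records
            if r.treatment == SCRAMBLE_LABEL
        ]
        if not sc:
            raise ValueError("scramble adjustment requested but no scramble wells")
        scramble_fa = float(np.mean(sc))
    series: list[DoseResponseSeries] = []
    grouped: dict[str, dict[float, list[float]]] = {}
    for r in records:
        if r.treatment in CONTROL_LABELS or r.treatment == SCRAMBLE_LABEL:
            continue
        fa = fraction_dead(control_mean, r.fluorescence) - scramble_fa
        grouped.setdefault(r.treatment, {}).setdefault(r.dose_uM, []).append(fa)
    for treatment, per_dose in grouped.items():
        doses = np.array(sorted(per_dose))
        means = np.array([np.mean(per_dose[d]) for d in doses])
        sds = np.array([np.std(per_dose[d], ddof=1) if len(per_dose[d]) > 1 else 0.0 for d in doses])
        ns = np.array([len(per_dose[d]) for d in doses])
        warns = []
        if np.any(ns < 2):
            warns.append(f"{treatment}: fewer than 2 replicates at some doses")
        series.append(
            DoseResponseSeries(
                treatment=treatment,
                doses_uM=doses,
                fa_mean=np.minimum(means, 1.0),
                fa_sd=sds,
                n_replicates=ns,
                timepoint=timepoint,
                warnings=warns,
            )
        )
    return series


def ec50_from_slope(slope_pct_per_nM: float) -> float:
    """Dose (µM) at which the linear % dead model reaches 50%: 50/|slope| nM."""
    if slope_pct_per_nM == 0:
        return float("inf")
    return 50.0 / abs(slope_pct_per_nM) / 1000.0


def linear_sensitivity(series: DoseResponseSeries) -> LinearFit:
    """OLS of FA*100 (%) on dose in nM; EC50 derived from the slope.

    A non-positive slope marks the treatment as non-cytotoxic (EC50 is
    still reported from |slope|, matching how such rows are tabulated).
    """
    if series.doses_uM.size < 3:
        raise ValueError("need at least 3 dose points")
    x_nM = series.doses_uM * 1000.0
    if np.ptp(x_nM) == 0:
        raise ValueError("zero dose variance")
    y_pct = series.fa_mean * 100.0
    res = stats.linregress(x_nM, y_pct)
    slope = float(res.slope)
    cytotoxic = slope > 0
    if not cytotoxic:
        warnings.warn(
            f"{series.treatment}: non-positive slope; treatment is non-cytotoxic",
            stacklevel=2,
        )
    return LinearFit(
        treatment=series.treatment,
        slope=slope,
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ec50_uM=ec50_from_slope(slope),
        cytotoxic=cytotoxic,
    )


def median_effect_fit(series: DoseResponseSeries) -> MedianEffectFit:
    """Fit log10(fa/(1-fa)) = m*log10(D) - m*log10(Dm) by OLS.

    Points with FA outside the open interval (0, 1) have an undefined
    logit and are excluded; the exclusion count is reported.
    """
    fa = series.fa_mean
    dose = series.doses_uM
    usable = (fa > 0) & (fa < 1) & (dose > 0)
    n_excl = int((~usable).sum())
    fa, dose = fa[usable], dose[usable]
    if fa.size < 2:
        raise ValueError("need at least 2 points with FA strictly in (0, 1)")
    if np.ptp(dose) == 0:
        raise ValueError("all usable doses equal")
    x = np.log10(dose)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError("median-effect slope m must be positive (no dose response)")
    Dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(
        treatment=series.treatment,
        m=m,
        Dm_uM=Dm,
        r_squared=float(res.rvalue**2),
        n_points=int(fa.size),
        n_excluded=n_excl,
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx = Dm * (fa/(1-fa))^(1/m), the dose producing effect level fa."""
    if not 0 < fa < 1:
        raise ValueError("fa must be strictly between 0 and 1")
    return fit.Dm_uM * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def classify_interaction(
    ci: float, additive_band: tuple[float, float] = ADDITIVE_BAND
) -> str:
    """synergy below the band, additive within it, antagonism above."""
    if ci <= 0:
        raise ValueError("combination index must be positive")
    lo, hi = additive_band
    if ci < lo:
        return "synergy"
    if ci > hi:
        return "antagonism"
    return "additive"


def combination_index(
    component_fits: Sequence[MedianEffectFit],
    fractions: Sequence[float],
    combo_fit: MedianEffectFit,
    fa: float = 0.5,
    additive_band: tuple[float, float] = ADDITIVE_BAND,
) -> InteractionResult:
    """Fixed-ratio combination index at effect level ``fa``.

    The mixture is dosed by total concentration with component i at a
    constant fraction f_i (sum 1); CI sums each component's share of the
    effective combination dose against its single-agent iso-effective
    dose.  Supports any number of components >= 2.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(component_fits) != len(fractions):
        raise ValueError("one mixing fraction per component required")
    if len(component_fits) < 2:
        raise ValueError("a combination needs at least 2 components")
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions sum to {sum(fractions)}, expected 1")
    D_combo = dose_for_effect(combo_fit, fa)
    ci = sum(
        f * D_combo / dose_for_effect(fit, fa)
        for f, fit in zip(fractions, component_fits)
    )
    return InteractionResult(
        components=tuple(f.treatment for f in component_fits),
        fractions=fractions,
        fa=fa,
        ci=float(ci),
        label=classify_interaction(float(ci), additive_band),
    )


def interaction_matrix(
    results: Mapping[str, Sequence[InteractionResult]],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Pairwise interaction-label matrices per cell line, plus a consensus.

    ``results`` maps cell line -> pairwise InteractionResults (each with
    exactly 2 components, keyed by unordered pair).  The consensus cell is
    the shared label where every cell line agrees and "discordant"
    otherwise; pairs absent from a line are ignored for consensus.
    """
    per_line: dict[str, dict[frozenset[str], str]] = {}
    agents: list[str] = []
    for line, rs in results.items():
        seen: dict[frozenset[str], str] = {}
        for r in rs:
            if len(r.components) != 2:
                raise ValueError("interaction matrices are pairwise")
            key = frozenset(r.components)
            if key in seen:
                raise ValueError(
                    f"duplicate pair {sorted(key)} in cell line {line!r}"
                )
            seen[key] = r.label
            for a in r.components:
                if a not in agents:
                    agents.append(a)
        per_line[line] = seen

    def as_frame(labels: Mapping[frozenset[str], str]) -> pd.DataFrame:
        df = pd.DataFrame("", index=agents, columns=agents, dtype=object)
        for pair, lab in labels.items():
            a, b = sorted(pair)
            df.loc[a, b] = lab
            df.loc[b, a] = lab
        return df

    matrices = {line: as_frame(labs) for line, labs in per_line.items()}
    consensus = pd.DataFrame("", index=agents, columns=agents, dtype=object)
    all_pairs = set().union(*per_line.values()) if per_line else set()
    for pair in all_pairs:
        labs = {labs[pair] for labs in per_line.values() if pair in labs}
        lab = labs.pop() if len(labs) == 1 else "discordant"
        a, b = sorted(pair)
        consensus.loc[a, b] = lab
        consensus.loc[b, a] = lab
    return matrices, consensus
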