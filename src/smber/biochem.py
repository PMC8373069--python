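"""Bulk biochemistry: gel-lane quantification, equilibrium binding and
pre-steady-state burst kinetics.

EMSA lanes are quantified as background-corrected band fractions.
Equilibrium titrations are fit with the exact single-site
ligand-depletion ("quadratic") solution, required because DNA and
protein concentrations in a gel-shift assay sit near the dissociation
constant, where the hyperbolic approximation fails. Glycosylase
excision time courses follow the standard pre-steady-state burst form

    product(t) = A0 * (1 - exp(-k_burst * t)) + A0 * k_ss * t

whose amplitude ``A0`` counts active enzyme (first rapid turnover) and
whose linear tail measures the slow product-release-limited steady
state; stimulation of turnover by a second factor shows up as an
increase in ``k_ss`` and in late-time product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "ExcisionTimeCourse",
    "BurstFit",
    "BindingIsotherm",
    "KdFit",
    "LaneQuantification",
    "FoldStimulation",
    "fraction_bound_quadratic",
    "quantify_lane",
    "fit_quadratic_kd",
    "fit_burst_kinetics",
    "stimulation_fold",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExcisionTimeCourse:
    """Product formation over time, as percent of substrate cleaved."""

    times: np.ndarray           # s, ascending
    product_percent: np.ndarray # % of substrate
    enzyme_total: float         # nM
    substrate_total: float      # nM
    burst_exceeds_substrate: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.product_percent, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "product_percent", p)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any((p < 0) | (p > 100)):
            raise ValueError("product_percent must lie in [0, 100]")

    @property
    def product_nm(self) -> np.ndarray:
        return self.product_percent / 100.0 * self.substrate_total


@dataclass(frozen=True)
class BurstFit:
    amplitude: float            # nM active enzyme
    k_burst: float              # 1/s
    k_ss: float                 # 1/s per-enzyme steady-state turnover
    r_squared: float
    amplitude_se: float = math.nan
    k_burst_se: float = math.nan
    k_ss_se: float = math.nan

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.k_burst < 0 or self.k_ss < 0:
            raise ValueError("burst parameters must be non-negative")


@dataclass(frozen=True)
class BindingIsotherm:
    titrant: np.ndarray         # nM
    fraction_bound: np.ndarray  # [0, 1]
    dna_total: float            # nM

    def __post_init__(self) -> None:
        e = np.asarray(self.titrant, dtype=float)
        fb = np.asarray(self.fraction_bound, dtype=float)
        object.__setattr__(self, "titrant", e)
        object.__setattr__(self, "fraction_bound", fb)
        if np.any((fb < 0) | (fb > 1)):
            raise ValueError("fraction_bound must lie in [0, 1]")
        if self.dna_total <= 0:
            raise ValueError("dna_total must be positive")


@dataclass(frozen=True)
class KdFit:
    kd: float                   # nM
    standard_error: float       # nM
    model: str = "quadratic_depletion"

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")


@dataclass(frozen=True)
class LaneQuantification:
    """Background-corrected band percentages of one gel lane."""

    band_percent: dict          # band -> % of corrected lane total
    group_percent: dict         # group -> % (bands partition the lane)
    corrected_total: float

    def __post_init__(self) -> None:
        for name, v in {**self.band_percent, **self.group_percent}.items():
            if not 0 <= v <= 100 + 1e-9:
                raise ValueError(f"percent for {name!r} outside [0, 100]: {v}")


@dataclass(frozen=True)
class FoldStimulation:
    product_fold: float         # product ratio at t_eval
    k_ss_fold: float            # ratio of fitted turnover rates (nan if 0/0)
    t_eval: float


# ---------------------------------------------------------------------------
# EMSA quantification
# ---------------------------------------------------------------------------

def quantify_lane(
    intensities: dict[str, float],
    background: float,
    groups: dict[str, list[str]] | None = None,
) -> LaneQuantification:
    """Percent of lane signal in each band and band group.

    ``background`` is the per-band blank-region signal subtracted from
    every band before normalizing by the corrected lane total; corrected
    band signals are clipped at zero. Default grouping puts every band
    except one named ``"free"`` into a ``"bound"`` group.
    """
    corrected = {b: max(0.0, v - background) for b, v in intensities.items()}
    total = sum(corrected.values())
    if total <= 0:
        raise ValueError("background-corrected lane total must be positive")
    band_percent = {b: 100.0 * v / total for b, v in corrected.items()}
    if groups is None:
        groups = {"bound": [b for b in intensities if b != "free"]}
        if "free" in intensities:
            groups["free"] = ["free"]
    group_percent = {}
    for g, bands in groups.items():
        missing = [b for b in bands if b not in corrected]
        if missing:
            raise ValueError(f"group {g!r} references unknown bands {missing}")
        group_percent[g] = sum(band_percent[b] for b in bands)
    return LaneQuantification(band_percent, group_percent, total)


# ---------------------------------------------------------------------------
# equilibrium binding
# ---------------------------------------------------------------------------

def fraction_bound_quadratic(
    e_total: float | np.ndarray, s_total: float, kd: float
) -> float | np.ndarray:
    """Exact single-site fraction bound under ligand depletion.

    Solves ``(E-b)(S-b) = Kd*b`` for bound DNA ``b`` and returns
    ``b/S``:

        b = [(E + S + Kd) - sqrt((E + S + Kd)^2 - 4*E*S)] / 2
    """
    e = np.asarray(e_total, dtype=float)
    if s_total <= 0 or kd <= 0:
        raise ValueError("s_total and kd must be positive")
    b = e + s_total + kd
    disc = b * b - 4.0 * e * s_total
    bound = (b - np.sqrt(np.maximum(disc, 0.0))) / 2.0
    fb = bound / s_total
    return float(fb) if np.isscalar(e_total) else fb


def fit_quadratic_kd(isotherm: BindingIsotherm) -> KdFit:
    """Nonlinear LS fit of the ligand-depletion model to a titration.

    Needs at least 4 points and a visible transition (the isotherm must
    move by >= 0.2 in fraction bound); otherwise the dissociation
    constant is not identifiable and a ValueError names the problem.
    """
    e = isotherm.titrant
    fb = isotherm.fraction_bound
    if e.size < 4:
        raise ValueError("need >= 4 titration points")
    if float(fb.max() - fb.min()) < 0.2:
        raise ValueError(
            "flat isotherm: no binding transition in the titration range, "
            "Kd is not identifiable"
        )
    s = isotherm.dna_total

    def model(ee: np.ndarray, kd: float) -> np.ndarray:
        return fraction_bound_quadratic(ee, s, kd)

    # half-saturation titrant as scale guess
    p0 = max(float(np.interp(0.5, fb, e)), 1e-6) if fb.max() >= 0.5 else float(e.max())
    popt, pcov = curve_fit(model, e, fb, p0=[p0], bounds=(1e-12, np.inf), maxfev=10000)
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    return KdFit(kd=float(popt[0]), standard_error=se)


# ---------------------------------------------------------------------------
# burst kinetics
# ---------------------------------------------------------------------------

def _burst_model(t: np.ndarray, a0: float, k_burst: float, k_ss: float) -> np.ndarray:
    return a0 * (1.0 - np.exp(-k_burst * t)) + a0 * k_ss * t


def fit_burst_kinetics(tc: ExcisionTimeCourse) -> BurstFit:
    """Fit the burst-plus-linear model to a product time course (in nM).

    Parameters are bounded non-negative and the amplitude cannot exceed
    total enzyme. Needs >= 5 time points including early times that
    resolve the burst.
    """
    t = tc.times
    p = tc.product_nm
    if t.size < 5:
        raise ValueError("need >= 5 time points for a burst fit")
    a_max = tc.enzyme_total if tc.enzyme_total > 0 else np.inf
    a0_guess = min(float(np.max(p)), a_max * 0.999) or 1e-3
    nonzero = t[t > 0]
    kb_guess = 1.0 / float(nonzero[min(2, nonzero.size - 1)])
    p0 = [max(a0_guess, 1e-6), kb_guess, 1e-5]
    try:
        popt, pcov = curve_fit(
            _burst_model, t, p, p0=p0,
            bounds=([0.0, 0.0, 0.0], [a_max, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = p - _burst_model(t, *p0)
        raise RuntimeError(
            f"burst fit did not converge (residual RMS at start "
            f"{float(np.sqrt(np.mean(resid**2))):.3g} nM)"
        ) from err
    pred = _burst_model(t, *popt)
    ss_res = float(np.sum((p - pred) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [math.nan] * 3
    return BurstFit(
        amplitude=float(popt[0]), k_burst=float(popt[1]), k_ss=float(popt[2]),
        r_squared=r2,
        amplitude_se=float(ses[0]), k_burst_se=float(ses[1]), k_ss_se=float(ses[2]),
    )


def stimulation_fold(
    tc_minus: ExcisionTimeCourse,
    tc_plus: ExcisionTimeCourse,
    t_eval: float,
) -> FoldStimulation:
    """Fold stimulation of excision between two time courses.

    Reports both the interpolated product ratio at ``t_eval`` (what an
    end-point gel comparison shows) and the ratio of fitted steady-state
    turnover rates; the two need not coincide when substrate nears
    exhaustion.
    """
    for tc in (tc_minus, tc_plus):
        if not (tc.times[0] <= t_eval <= tc.times[-1]):
            raise ValueError(f"t_eval={t_eval} outside time course coverage")
    p_minus = float(np.interp(t_eval, tc_minus.times, tc_minus.product_nm))
    p_plus = float(np.interp(t_eval, tc_plus.times, tc_plus.product_nm))
    if p_minus <= 0:
        raise ValueError("reference product at t_eval is non-positive")
    fit_minus = fit_burst_kinetics(tc_minus)
    fit_plus = fit_burst_kinetics(tc_plus)
    if fit_minus.k_ss > 1e-12:
        k_fold = fit_plus.k_ss / fit_minus.k_ss
    else:
        k_fold = math.inf if fit_plus.k_ss > 1e-12 else math.nan
    return FoldStimulation(product_fold=p_plus / p_minus, k_ss_fold=k_fold,
                           t_eval=t_eval)
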