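"""AFM volumetrics: particle volumes, volume-to-molecular-weight
calibration, and Gaussian deconvolution of species populations.

The volume of a deposited particle is ``(<H> - B) * A`` (mean height
above image background times thresholded area). For protein-DNA
complexes the flanking-DNA contribution is removed by subtracting the
mean of two unbound DNA stretches of matching length,
``V_protein = V_complex - (V_DNA1 + V_DNA2)/2``. Protein volume is
proportional to molecular weight, so an OLS standard curve built from
proteins of known mass converts volumes to kDa, and a 1-D Gaussian
mixture fit over the converted masses resolves monomer/dimer/co-complex
populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ParticleMeasurement",
    "ComplexMeasurement",
    "StandardCurve",
    "SpeciesModel",
    "particle_volume",
    "protein_volume_from_complex",
    "fit_standard_curve",
    "fit_species_gaussians",
]

_REL_TOL = 1e-9


def particle_volume(mean_height: float, background: float, area: float) -> float:
    """``(<H> - B) * A`` in nm^3; negative results are physically
    suspect (sub-background particle) but returned, not clipped."""
    if not area > 0:
        raise ValueError(f"area must be positive, got {area}")
    return (mean_height - background) * area


def protein_volume_from_complex(v_complex: float, v_dna1: float, v_dna2: float) -> float:
    """Subtract the mean flanking-DNA volume from a complex volume."""
    for name, v in (("v_complex", v_complex), ("v_dna1", v_dna1), ("v_dna2", v_dna2)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    return v_complex - (v_dna1 + v_dna2) / 2.0


@dataclass(frozen=True)
class ParticleMeasurement:
    """Height/area record of one free particle; volume is derived."""

    mean_height: float          # nm
    background: float           # nm
    area: float                 # nm^2
    volume: float = None        # nm^3, computed if omitted

    def __post_init__(self) -> None:
        v = particle_volume(self.mean_height, self.background, self.area)
        if self.volume is None:
            object.__setattr__(self, "volume", v)
        elif abs(self.volume - v) > _REL_TOL * max(1.0, abs(v)):
            raise ValueError("stored volume inconsistent with (<H>-B)*A")

    @property
    def sub_background(self) -> bool:
        return self.volume < 0


@dataclass(frozen=True)
class ComplexMeasurement:
    """Protein-DNA complex volume with flanking-DNA correction."""

    v_complex: float            # nm^3
    v_dna1: float               # nm^3
    v_dna2: float               # nm^3
    v_protein: float = None     # nm^3, computed if omitted
    mw: float = math.nan        # kDa, set after calibration

    def __post_init__(self) -> None:
        v = protein_volume_from_complex(self.v_complex, self.v_dna1, self.v_dna2)
        if self.v_protein is None:
            object.__setattr__(self, "v_protein", v)
        elif abs(self.v_protein - v) > _REL_TOL * max(1.0, abs(v)):
            raise ValueError("stored v_protein inconsistent with DNA subtraction")

    def with_mw(self, curve: "StandardCurve") -> "ComplexMeasurement":
        return ComplexMeasurement(self.v_complex, self.v_dna1, self.v_dna2,
                                  self.v_protein, curve.mw(self.v_protein))


@dataclass(frozen=True)
class StandardCurve:
    """Linear volume-vs-molecular-weight calibration.

    ``volume = slope * mw + intercept``; the inverse map
    ``mw = (volume - intercept) / slope`` assigns masses to unknowns.
    """

    slope: float                # nm^3 / kDa
    intercept: float            # nm^3
    r_squared: float
    points: tuple = ()          # (label, mw_kda, volume_nm3)

    def volume(self, mw: float | np.ndarray) -> float | np.ndarray:
        return self.slope * np.asarray(mw, dtype=float) + self.intercept

    def mw(self, volume: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(volume, dtype=float) - self.intercept) / self.slope


def fit_standard_curve(points: list[tuple[str, float, float]]) -> StandardCurve:
    """OLS of mean volume on known molecular weight.

    ``points`` are ``(label, mw_kda, mean_volume_nm3)`` triples for the
    calibration proteins; at least two distinct masses are required.
    """
    if len(points) < 2:
        raise ValueError("calibration needs >= 2 points")
    mws = np.array([p[1] for p in points], dtype=float)
    vols = np.array([p[2] for p in points], dtype=float)
    if np.ptp(mws) == 0:
        raise ValueError("calibration molecular weights are degenerate")
    slope, intercept = np.polyfit(mws, vols, 1)
    pred = slope * mws + intercept
    ss_res = float(np.sum((vols - pred) ** 2))
    ss_tot = float(np.sum((vols - vols.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(float(slope), float(intercept), r2, tuple(points))


# ---------------------------------------------------------------------------
# Gaussian mixture deconvolution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesModel:
    """k-component 1-D Gaussian mixture over molecular weights.

    Components are canonicalized in ascending mean order; ``ll_history``
    records the log-likelihood at every EM iteration of the winning
    restart (non-decreasing by construction of EM).
    """

    means: np.ndarray           # kDa
    sds: np.ndarray             # kDa
    weights: np.ndarray
    assignments: np.ndarray     # max-posterior component per particle
    log_likelihood: float
    bic: float
    ll_history: np.ndarray
    converged: bool

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("component sds must be positive")


def _em_once(x: np.ndarray, k: int, means0: np.ndarray,
             max_iter: int, tol: float) -> tuple:
    n = x.size
    means = means0.copy()
    sds = np.full(k, max(np.std(x) / k, 1e-6))
    weights = np.full(k, 1.0 / k)
    sd_floor = max(1e-8 * max(np.ptp(x), 1.0), 1e-12)
    ll_prev = -np.inf
    history = []
    converged = False
    for _ in range(max_iter):
        # E step in log space
        log_pdf = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :]) - 0.5 * math.log(2 * math.pi)
            + np.log(weights[None, :])
        )
        m = log_pdf.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.sum(np.exp(log_pdf - m), axis=1))
        ll = float(np.sum(log_norm))
        history.append(ll)
        resp = np.exp(log_pdf - log_norm[:, None])
        if ll - ll_prev < tol and np.isfinite(ll_prev):
            converged = True
            break
        ll_prev = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, sd_floor ** 2))
    return means, sds, weights, history, converged


def fit_species_gaussians(
    mws: list[float] | np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> SpeciesModel:
    """EM fit of a k-component Gaussian mixture to molecular weights.

    k-means initialization, ``n_restarts`` restarts keeping the best
    log-likelihood; every particle is assigned its maximum-posterior
    component. Non-convergence within ``max_iter`` returns the best
    model so far with ``converged=False``. BIC is reported for
    information only; ``k`` is caller-specified.
    """
    x = np.asarray(mws, dtype=float)
    if x.ndim != 1:
        raise ValueError("mws must be 1-D")
    if x.size < 5 * k:
        raise ValueError(f"need >= {5 * k} observations for k={k}, got {x.size}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        km = KMeans(n_clusters=k, n_init=1,
                    random_state=int(rng.integers(2**31))).fit(x.reshape(-1, 1))
        means0 = np.sort(km.cluster_centers_.ravel())
        means, sds, weights, history, converged = _em_once(x, k, means0, max_iter, tol)
        if best is None or history[-1] > best[3][-1]:
            best = (means, sds, weights, history, converged)
    means, sds, weights, history, converged = best

    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    log_pdf = (
        -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        - np.log(sds[None, :]) + np.log(weights[None, :])
    )
    assignments = np.argmax(log_pdf, axis=1)
    ll = history[-1]
    n_params = 3 * k - 1
    bic = -2.0 * ll + n_params * math.log(x.size)
    return SpeciesModel(
        means=means, sds=sds, weights=weights / weights.sum(),
        assignments=assignments, log_likelihood=ll, bic=bic,
        ll_history=np.asarray(history), converged=converged,
    )
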