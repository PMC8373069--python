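"""Synthetic observables with known ground truth.

Every input the analysis stages consume can be generated here: tightrope
position series (a stationary/motile mixture with exponential bound
lifetimes and right-censoring at the observation window), two-channel
co-binding fields, AFM volume populations, burst-plus-linear excision
time courses and quadratic-binding (ligand-depletion) isotherms.

Motion model: motile particles follow fractional Brownian motion with
Hurst exponent ``H = alpha/2`` so that the ensemble MSD scales as
``2*D*t**alpha`` by construction; ``alpha = 1`` is the pure Brownian
case. Stationary particles are localization noise about a fixed binding
site. Bound lifetimes are exponential with mean ``half_life/ln 2``,
drawn independently of the motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
from scipy.linalg import cholesky, toeplitz

from .afm import ComplexMeasurement, StandardCurve
from .biochem import BindingIsotherm, ExcisionTimeCourse, fraction_bound_quadratic
from .survival import DwellRecord
from .trajectory import Trajectory

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "fractional_gaussian_noise",
    "simulate_tightrope_particles",
    "simulate_dwell_records",
    "simulate_afm_field",
    "simulate_excision_timecourse",
    "simulate_binding_isotherm",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the tightrope simulation.

    Defaults mirror the imaging conditions the pipeline targets: 12.5
    frames/s over a 300 s observation window on substrates carrying one
    abasic site every 2 kb (0.34 um/kb for B-form DNA), with 0.03 um
    localization noise typical of a quantum-dot label.
    """

    frame_rate: float = 12.5        # frames / s
    window: float = 300.0           # s
    n_particles: int = 100
    motile_fraction: float = 0.10
    D_true: float = 3.75e-3         # um^2/s
    alpha_true: float = 1.0
    loc_noise_sd: float = 0.03      # um
    half_life_true: float = 8900.0  # s
    coloc_fraction: float = 0.0
    site_spacing: float = 2.0       # kb between damage sites
    bp_to_um: float = 0.34          # um per kb
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("frame_rate", self.frame_rate > 0),
            ("window", self.window > 0),
            ("n_particles", self.n_particles >= 0),
            ("motile_fraction", 0 <= self.motile_fraction <= 1),
            ("coloc_fraction", 0 <= self.coloc_fraction <= 1),
            ("D_true", self.D_true >= 0),
            ("alpha_true", 0 < self.alpha_true < 2),
            ("loc_noise_sd", self.loc_noise_sd >= 0),
            ("half_life_true", self.half_life_true > 0),
            ("site_spacing", self.site_spacing > 0),
            ("bp_to_um", self.bp_to_um > 0),
        ]
        for name, ok in checks:
            value = getattr(self, name)
            if not np.isfinite(value) or not ok:
                raise ValueError(f"invalid SimulationConfig.{name}: {value!r}")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    @property
    def site_spacing_um(self) -> float:
        return self.site_spacing * self.bp_to_um

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TruthRecord:
    """Per-particle ground truth retained for parameter-recovery tests."""

    particle_id: int
    is_motile: bool
    is_cobound: bool
    true_lifetime: float            # s, uncensored draw
    censored: bool
    generator_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _fgn_cholesky(n: int, hurst: float) -> np.ndarray:
    """Lower Cholesky factor of the unit-step fGn covariance (Toeplitz)."""
    k = np.arange(n, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * (np.abs(k - 1) ** h2 - 2.0 * k ** h2 + (k + 1) ** h2)
    cov = toeplitz(gamma)
    # tiny jitter guards against round-off loss of positive definiteness
    cov[np.diag_indices_from(cov)] += 1e-12
    return cholesky(cov, lower=True)


def fractional_gaussian_noise(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """``n`` correlated unit-variance increments of fBm at unit time step.

    Exact sampling through the Cholesky factor of the fGn covariance;
    ``hurst = 0.5`` short-circuits to i.i.d. normals.
    """
    if not 0 < hurst < 1:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    if n < 1:
        raise ValueError("n must be >= 1")
    z = rng.standard_normal(n)
    if abs(hurst - 0.5) < 1e-12:
        return z
    return _fgn_cholesky(n, round(hurst, 12)) @ z


def _fbm_positions(n_steps: int, dt: float, d: float, alpha: float,
                   rng: np.random.Generator) -> np.ndarray:
    """fBm path with increment variance ``2*D*dt**alpha`` (n_steps+1 points)."""
    hurst = alpha / 2.0
    inc = fractional_gaussian_noise(n_steps, hurst, rng)
    scale = math.sqrt(2.0 * d) * dt ** hurst
    x = np.empty(n_steps + 1)
    x[0] = 0.0
    np.cumsum(inc * scale, out=x[1:])
    return x


# ---------------------------------------------------------------------------
# tightrope particles
# ---------------------------------------------------------------------------

def _draw_lifetime(rng: np.random.Generator, half_life: float) -> float:
    return float(rng.exponential(half_life / LN2))


def _n_observed_frames(lifetime: float, config: SimulationConfig) -> tuple[int, bool]:
    n_window = int(round(config.window * config.frame_rate))
    censored = lifetime >= config.window
    duration = config.window if censored else lifetime
    n = min(n_window, max(2, int(duration * config.frame_rate)))
    return n, censored


def simulate_tightrope_particles(
    config: SimulationConfig,
) -> tuple[list[Trajectory], list[TruthRecord]]:
    """Simulate a field of labelled particles bound to damage sites.

    Single-channel mode (``coloc_fraction = 0``) emits one trajectory per
    particle on channel "605". Two-channel mode treats ``n_particles`` as
    the union of distinct entities: ``round(coloc_fraction * n)`` of them
    are co-bound pairs sharing a site (one trajectory in each channel,
    sharing the underlying path with independent localization noise and a
    <=0.05 um registration offset); the remainder are split between the
    channels as singles on their own sites.

    Returns the trajectories plus one :class:`TruthRecord` per entity.
    """
    rng = np.random.default_rng(config.seed)
    if config.coloc_fraction > 0:
        return _simulate_two_channel(config, rng)

    trajectories: list[Trajectory] = []
    truths: list[TruthRecord] = []
    for pid in range(config.n_particles):
        is_motile = bool(rng.random() < config.motile_fraction)
        lifetime = _draw_lifetime(rng, config.half_life_true)
        n_obs, censored = _n_observed_frames(lifetime, config)
        site = pid * config.site_spacing_um
        times = np.arange(n_obs) * config.dt
        if is_motile and config.D_true > 0:
            base = site + _fbm_positions(n_obs - 1, config.dt, config.D_true,
                                         config.alpha_true, rng)
        else:
            base = np.full(n_obs, site)
        positions = base + rng.normal(0.0, config.loc_noise_sd, size=n_obs)
        trajectories.append(
            Trajectory(pid, "605", times, positions, censored=censored)
        )
        truths.append(
            TruthRecord(pid, is_motile, False, lifetime, censored,
                        {"site_um": site})
        )
    return trajectories, truths


def _simulate_two_channel(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[Trajectory], list[TruthRecord]]:
    n = config.n_particles
    n_pairs = int(round(config.coloc_fraction * n))
    n_singles = n - n_pairs
    n_single_a = n_singles // 2 + n_singles % 2
    roles = ["pair"] * n_pairs + ["a"] * n_single_a + ["b"] * (n_singles - n_single_a)
    rng.shuffle(roles)

    trajectories: list[Trajectory] = []
    truths: list[TruthRecord] = []
    next_id = 0
    for entity, role in enumerate(roles):
        is_motile = bool(rng.random() < config.motile_fraction)
        lifetime = _draw_lifetime(rng, config.half_life_true)
        n_obs, censored = _n_observed_frames(lifetime, config)
        site = entity * config.site_spacing_um
        times = np.arange(n_obs) * config.dt
        if is_motile and config.D_true > 0:
            base = site + _fbm_positions(n_obs - 1, config.dt, config.D_true,
                                         config.alpha_true, rng)
        else:
            base = np.full(n_obs, site)

        def _emit(channel: str, offset: float) -> None:
            nonlocal next_id
            positions = base + offset + rng.normal(0.0, config.loc_noise_sd, size=n_obs)
            trajectories.append(
                Trajectory(next_id, channel, times, positions, censored=censored)
            )
            next_id += 1

        if role == "pair":
            _emit("605", 0.0)
            _emit("705", float(rng.uniform(-0.05, 0.05)))
        elif role == "a":
            _emit("605", 0.0)
        else:
            _emit("705", 0.0)
        truths.append(
            TruthRecord(entity, is_motile, role == "pair", lifetime, censored,
                        {"site_um": site, "role": role})
        )
    return trajectories, truths


def simulate_dwell_records(
    n: int,
    half_life: float,
    window: float | None = None,
    seed: int = 0,
) -> list[DwellRecord]:
    """Exponential bound lifetimes, right-censored at ``window`` if given."""
    if n <= 0:
        raise ValueError("n must be positive")
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    rng = np.random.default_rng(seed)
    lifetimes = rng.exponential(half_life / LN2, size=n)
    records = []
    for pid, t in enumerate(lifetimes):
        if window is not None and t >= window:
            records.append(DwellRecord(pid, float(window), observed=False))
        else:
            records.append(DwellRecord(pid, float(t), observed=True))
    return records


# ---------------------------------------------------------------------------
# AFM fields
# ---------------------------------------------------------------------------

def simulate_afm_field(
    species_means: list[float],
    species_weights: list[float],
    curve: StandardCurve,
    n: int,
    noise_sd: float,
    seed: int = 0,
    dna_volume_mean: float = 20.0,
    dna_volume_sd: float = 2.0,
) -> tuple[list[ComplexMeasurement], list[int]]:
    """Protein-DNA complexes drawn from a mixture of species.

    Species are drawn by weight, molecular weights (kDa) converted to
    protein volume through the calibration ``curve``, Gaussian volume
    noise (``noise_sd`` nm^3) added, and flanking-DNA volumes attached so
    the DNA-subtraction step downstream is exercised. Returns the
    measurements and the ground-truth species label per particle.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    weights = np.asarray(species_weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("species weights must sum to 1")
    if curve.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    means = np.asarray(species_means, dtype=float)
    if means.size != weights.size:
        raise ValueError("species_means and species_weights length mismatch")

    rng = np.random.default_rng(seed)
    labels = rng.choice(means.size, size=n, p=weights)
    measurements = []
    for lab in labels:
        v_protein_true = curve.volume(means[lab])
        v_dna1 = float(rng.normal(dna_volume_mean, dna_volume_sd))
        v_dna2 = float(rng.normal(dna_volume_mean, dna_volume_sd))
        v_complex = v_protein_true + (v_dna1 + v_dna2) / 2.0 + float(rng.normal(0.0, noise_sd))
        measurements.append(ComplexMeasurement(v_complex, v_dna1, v_dna2))
    return measurements, [int(l) for l in labels]


# ---------------------------------------------------------------------------
# bulk biochemistry
# ---------------------------------------------------------------------------

def simulate_excision_timecourse(
    amplitude: float,
    k_burst: float,
    k_ss: float,
    substrate_cap: float,
    times: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    enzyme_total: float | None = None,
) -> ExcisionTimeCourse:
    """Burst-plus-linear product formation for a glycosylase time course.

    ``product(t) = min(cap, A*(1 - exp(-k_burst*t)) + A*k_ss*t) + noise``
    in nM; the burst amplitude ``A`` is the active-enzyme concentration
    and ``k_ss`` the slow per-enzyme steady-state turnover. ``noise_sd``
    is in percent of substrate. An amplitude exceeding the substrate cap
    is allowed but flagged via ``burst_exceeds_substrate``.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly ascending")
    if amplitude < 0 or k_burst < 0 or k_ss < 0:
        raise ValueError("amplitude and rates must be non-negative")
    if substrate_cap <= 0:
        raise ValueError("substrate_cap must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    product = amplitude * (1.0 - np.exp(-k_burst * t)) + amplitude * k_ss * t
    product = np.minimum(product, substrate_cap)
    percent = 100.0 * product / substrate_cap
    percent = percent + rng.normal(0.0, noise_sd, size=t.size)
    percent = np.clip(percent, 0.0, 100.0)
    return ExcisionTimeCourse(
        times=t,
        product_percent=percent,
        enzyme_total=amplitude if enzyme_total is None else enzyme_total,
        substrate_total=substrate_cap,
        burst_exceeds_substrate=amplitude > substrate_cap,
    )


def simulate_binding_isotherm(
    kd: float,
    dna_total: float,
    titrant: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingIsotherm:
    """Noisy fraction-bound readout of a single-site titration.

    Fraction bound comes from the exact ligand-depletion quadratic
    (valid when DNA concentration is near ``kd``); Gaussian noise is
    added and the readout clipped to [0, 1] as a gel quantification
    would be.
    """
    if kd <= 0 or dna_total <= 0:
        raise ValueError("kd and dna_total must be positive")
    e = np.asarray(titrant, dtype=float)
    if np.any(e < 0):
        raise ValueError("titrant concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    fb = fraction_bound_quadratic(e, dna_total, kd)
    fb = np.clip(fb + rng.normal(0.0, noise_sd, size=e.size), 0.0, 1.0)
    return BindingIsotherm(titrant=e, fraction_bound=fb, dna_total=dna_total)
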