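"""Synthetic multi-environment trials with a known reaction-norm architecture.

The generator emulates the structure of a hybrid-maize multi-environment
trial: several hundred genotypes scored in a handful of environments whose
seasons differ in temperature level, seasonal phase and day-to-day noise.
Phenotypes follow the reaction-norm model the pipeline assumes,

    y_ge = μ + Σ_m β_m x_gm + (s̄ + Σ_q γ_q x_gq) · z_e + u_e + ε_ge,

where x are 0/1/2 dosages, β are environment-stable main-QTL effects, γ are
slope-QTL effects, z_e is the standardized mean of a chosen EP over a
chosen developmental-stage window (computed through the real envparams /
envirotyping code path), s̄ is the population-average environmental
sensitivity, u_e an environment main effect and ε residual noise.  Every
component is stored so phenotypes are exactly reconstructable and every
downstream estimate has ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .envirotyping import (
    RDEPMatrix,
    StageThresholdTable,
    maize_stage_table,
    rdep_profiles,
    stack_windowed_eps,
)
from .envparams import EPTable, build_ep_series
from .errors import ConfigError
from .genofeatures import GenotypeMatrix
from .plasticity import TraitTable

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for one synthetic trial.

    Defaults describe a mid-size temperate maize trial: 500 hybrids × 2000
    SNPs in 10-marker LD blocks over 10 chromosomes, 8 environments with
    site-to-site temperature offsets (SD 6 °F), planting-phase shifts
    (± 15 d) and day-to-day weather noise (SD 6 °F); 10 main QTL and 10
    slope QTL of unit effect SD, population-average sensitivity 3, a
    non-EP-mediated environment main effect of SD 0.3 and residual SD 0.25
    (trait units) — a regime where the trait's environmental response is
    predominantly mediated by the target thermal window, as for
    photothermally driven traits.
    """

    n_genotypes: int = 500
    n_markers: int = 2000
    n_envs: int = 8
    n_chromosomes: int = 10
    maf_range: tuple = (0.1, 0.5)
    ld_block_len: int = 10
    ld_flip_prob: float = 0.05
    marker_spacing_bp: int = 5000
    n_main_qtl: int = 10
    n_slope_qtl: int = 10
    main_effect_sd: float = 1.0
    slope_effect_sd: float = 1.0
    mean_slope: float = 3.0
    target_ep: str = "PTT"
    target_window: tuple = (3, 6)  # stage indices A..B (V3..V6)
    env_effect_sd: float = 0.3
    residual_sd: float = 0.25
    trait_mean: float = 100.0
    trait: str = "trait1"
    # weather template
    season_days: int = 200
    base_temp_mean: float = 72.0  # °F mid-season mean of (tmax+tmin)/2
    seasonal_amplitude: float = 8.0
    env_offset_sd: float = 6.0
    env_amplitude_sd: float = 2.0
    env_phase_range_days: float = 15.0
    daily_temp_noise_sd: float = 6.0
    diurnal_range_mean: float = 20.0
    diurnal_range_sd: float = 3.0
    base_day_length: float = 13.0
    day_length_amplitude: float = 1.5
    env_day_length_sd: float = 0.3
    rain_rate_mm: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genotypes, self.n_markers, self.n_envs) < 1:
            raise ConfigError("counts must be positive")
        if self.n_main_qtl + self.n_slope_qtl > self.n_markers:
            raise ConfigError("QTL counts exceed n_markers")
        a, b = self.target_window
        if a > b:
            raise ConfigError("target window must have A ≤ B")


@dataclass
class SimTruth:
    """Ground truth of one simulated trial."""

    main_qtl: list
    main_effects: np.ndarray
    slope_qtl: list
    slope_effects: np.ndarray
    genotype_main: np.ndarray  # Σ β x per genotype
    genotype_slope: np.ndarray  # s̄ + Σ γ x per genotype
    env_ep_raw: pd.Series  # raw target-window EP mean per env
    env_ep_z: pd.Series  # standardized version used in the model
    env_effects: pd.Series
    residuals: pd.DataFrame  # genotype × env
    trait_mean: float

    def reconstruct(self) -> pd.DataFrame:
        """Phenotypes rebuilt from stored components (exact up to float error)."""
        z = self.env_ep_z.to_numpy()
        y = (
            self.trait_mean
            + self.genotype_main[:, None]
            + np.outer(self.genotype_slope, z)
            + self.env_effects.to_numpy()[None, :]
            + self.residuals.to_numpy()
        )
        return pd.DataFrame(y, index=self.residuals.index, columns=self.residuals.columns)


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """SNP dosages in LD blocks with a physical map.

    Haplotypes are simulated per block: the block's first marker draws
    alleles at a MAF uniform in ``maf_range``; each subsequent marker copies
    the previous marker's haplotype allele, flipping with probability
    ``ld_flip_prob``, so within-block r² decays geometrically with marker
    distance.  ``ld_block_len = 1`` gives fully independent markers.
    """
    rng = np.random.default_rng([config.seed, 1])
    n, m = config.n_genotypes, config.n_markers
    hap = np.empty((2 * n, m), dtype=np.int8)
    lo, hi = config.maf_range
    j = 0
    while j < m:
        block_end = min(j + config.ld_block_len, m)
        p = rng.uniform(lo, hi)
        hap[:, j] = rng.random(2 * n) < p
        for k in range(j + 1, block_end):
            flip = rng.random(2 * n) < config.ld_flip_prob
            hap[:, k] = np.where(flip, 1 - hap[:, k - 1], hap[:, k - 1])
        j = block_end
    dosages = (hap[0::2] + hap[1::2]).astype(float)

    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms = [f"chr{i // per_chrom + 1}" for i in range(m)]
    pos = [(i % per_chrom + 1) * config.marker_spacing_bp for i in range(m)]
    marker_map = pd.DataFrame(
        {"chrom": chroms, "pos": pos}, index=[f"m{i}" for i in range(m)]
    )
    samples = [f"g{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, dosages=dosages, marker_map=marker_map)


def simulate_weather(config: SimConfig) -> pd.DataFrame:
    """Daily weather tables for all environments (long format).

    Each environment gets a sinusoidal season with its own temperature
    offset, amplitude jitter and phase shift, plus day-to-day noise — so
    window means of thermal EPs genuinely differ between developmental
    windows across environments.  Day length follows a latitude-like curve
    with a small per-site offset; humidity, rainfall and radiation are
    weakly weather-coupled noise.
    """
    rng = np.random.default_rng([config.seed, 2])
    days = np.arange(config.season_days)
    frames = []
    for e in range(config.n_envs):
        env_id = f"env{e + 1}"
        offset = rng.normal(0.0, config.env_offset_sd)
        amp = config.seasonal_amplitude + rng.normal(0.0, config.env_amplitude_sd)
        phase = rng.uniform(-config.env_phase_range_days, config.env_phase_range_days)
        tmean = (
            config.base_temp_mean
            + offset
            + amp * np.sin(np.pi * (days + phase) / config.season_days)
            + rng.normal(0.0, config.daily_temp_noise_sd, size=len(days))
        )
        dtr = np.clip(
            rng.normal(config.diurnal_range_mean, config.diurnal_range_sd, len(days)),
            2.0, None,
        )
        tmax = tmean + dtr / 2
        tmin = tmean - dtr / 2
        dl_off = rng.normal(0.0, config.env_day_length_sd)
        dl = np.clip(
            config.base_day_length + dl_off
            + config.day_length_amplitude * np.sin(np.pi * (days + phase) / config.season_days)
            + rng.normal(0.0, 0.05, len(days)),
            0.1, 24.0,
        )
        rh = np.clip(rng.normal(65.0, 10.0, len(days)), 5.0, 100.0)
        pre = rng.exponential(config.rain_rate_mm, len(days)) * (rng.random(len(days)) < 0.4)
        par = np.clip(1.6 * dl + rng.normal(0.0, 2.0, len(days)), 0.5, None)
        frames.append(
            pd.DataFrame(
                {
                    "env_id": env_id,
                    "date": pd.date_range("2020-05-01", periods=len(days), freq="D"),
                    "tmax": tmax,
                    "tmin": tmin,
                    "day_length": dl,
                    "rh": rh,
                    "pre": pre,
                    "par": par,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _target_window_z(
    rdeps: dict[str, RDEPMatrix], config: SimConfig
) -> tuple[pd.Series, pd.Series]:
    a, b = config.target_window
    windowed = stack_windowed_eps(rdeps)
    raw = windowed[(config.target_ep, a, b)]
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ConfigError("target-window EP constant across environments")
    return raw, (raw - raw.mean()) / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    weather: pd.DataFrame,
    config: SimConfig,
    thresholds: StageThresholdTable | None = None,
) -> tuple[TraitTable, SimTruth, dict[str, EPTable], dict[str, RDEPMatrix]]:
    """Reaction-norm phenotypes on top of simulated genotypes and weather.

    The slope QTL act through the standardized mean of ``config.target_ep``
    over stage window A..B, computed with the real envirotyping code path.
    Returns the trait table, the ground truth and the intermediate EP /
    RD_EP products.
    """
    thresholds = thresholds or maize_stage_table()
    rng = np.random.default_rng([config.seed, 3])
    ep_tables = {
        env: build_ep_series(sub, pd.to_datetime(sub["date"]).min())
        for env, sub in weather.groupby("env_id", sort=True)
    }
    rdeps = rdep_profiles(ep_tables, thresholds)
    unreached = [e for e, r in rdeps.items() if np.isnan(r.matrix.to_numpy()).any()]
    if unreached:
        logger.warning(
            "season too cool/short to reach all stages in: %s", ", ".join(unreached)
        )
    raw, z = _target_window_z(rdeps, config)
    envs = list(z.index)

    m_ids = np.array(genotypes.marker_ids)
    qtl = rng.choice(len(m_ids), size=config.n_main_qtl + config.n_slope_qtl, replace=False)
    main_qtl = m_ids[qtl[: config.n_main_qtl]]
    slope_qtl = m_ids[qtl[config.n_main_qtl:]]
    beta = rng.normal(0.0, config.main_effect_sd, config.n_main_qtl)
    gamma = rng.normal(0.0, config.slope_effect_sd, config.n_slope_qtl)

    # centered dosages so the population means of the genetic values are
    # exactly 0 and mean_slope regardless of the effect draw
    Xm = genotypes.to_frame()[main_qtl].to_numpy()
    Xs = genotypes.to_frame()[slope_qtl].to_numpy()
    g_main = (Xm - Xm.mean(axis=0)) @ beta
    g_slope = config.mean_slope + (Xs - Xs.mean(axis=0)) @ gamma

    u = pd.Series(rng.normal(0.0, config.env_effect_sd, len(envs)), index=envs)
    eps = pd.DataFrame(
        rng.normal(0.0, config.residual_sd, (len(genotypes.samples), len(envs))),
        index=genotypes.samples, columns=envs,
    )
    truth = SimTruth(
        main_qtl=list(main_qtl), main_effects=beta,
        slope_qtl=list(slope_qtl), slope_effects=gamma,
        genotype_main=g_main, genotype_slope=g_slope,
        env_ep_raw=raw, env_ep_z=z, env_effects=u, residuals=eps,
        trait_mean=config.trait_mean,
    )
    trait_table = TraitTable(values=truth.reconstruct(), trait=config.trait)
    return trait_table, truth, ep_tables, rdeps


@dataclass
class SimulatedTrial:
    config: SimConfig
    genotypes: GenotypeMatrix
    weather: pd.DataFrame
    ep_tables: dict
    rdeps: dict
    trait_table: TraitTable
    truth: SimTruth
    stage_table: StageThresholdTable = field(default_factory=maize_stage_table)


def simulate_trial(config: SimConfig | None = None, **overrides) -> SimulatedTrial:
    """One-call generator: genotypes + weather + EPs + phenotypes + truth."""
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        raise ConfigError("pass either a config or keyword overrides, not both")
    genotypes = simulate_genotypes(config)
    weather = simulate_weather(config)
    trait_table, truth, ep_tables, rdeps = simulate_phenotypes(genotypes, weather, config)
    return SimulatedTrial(
        config=config, genotypes=genotypes, weather=weather,
        ep_tables=ep_tables, rdeps=rdeps, trait_table=trait_table, truth=truth,
    )


def true_tam_table(truth: SimTruth, trait: str) -> pd.DataFrame:
    """TAM table built from the planted QTL (oracle GWAS), for feature tests."""
    rows = [
        {"marker_id": m, "trait": trait, "category": "Main", "effect": b}
        for m, b in zip(truth.main_qtl, truth.main_effects)
    ] + [
        {"marker_id": m, "trait": trait, "category": "GxE", "effect": g}
        for m, g in zip(truth.slope_qtl, truth.slope_effects)
    ]
    return pd.DataFrame(rows)
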