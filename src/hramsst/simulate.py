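"""Synthetic LC-MS runs and longitudinal SST histories with known truth.

Two levels of simulation support testing of the whole pipeline without
any instrument data:

* :func:`generate_run` emulates one centroided MS1 injection of the
  reference panel: each compound elutes as a Gaussian chromatographic
  peak and every centroid m/z is displaced by a configurable true bias
  plus Gaussian ppm noise, so the bias recovered by EIC apex measurement
  has a known target.  Decoy centroids and a noise baseline are added to
  exercise window extraction.

* :func:`generate_history` emulates months of replicate SST records.
  Signed replicate errors are Gaussian around per-compound true means
  (default spreads 0.7 ppm positive / 0.5 ppm negative mode, the
  magnitudes typical of a well-behaved Orbitrap); a drift slope adds
  ``slope x batch injections`` to post-batch errors; calibration effects
  (CalMix-only penalty, poor-quality penalty, days-since-calibration
  slopes) inflate the error magnitude additively, leaving the sign
  untouched, so the absolute-error calibration model recovers them as
  linear coefficients.

All randomness flows from :class:`numpy.random.default_rng` (PCG64), so a
fixed seed reproduces output bit for bit across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .chem import CompoundPanel, default_panel
from .history import HISTORY_COLUMNS, History
from .spectra import Run, Spectrum
from .sst import InjectionResult

__all__ = [
    "SyntheticRunConfig",
    "RunGroundTruth",
    "generate_run",
    "generate_injections",
    "SyntheticHistoryConfig",
    "HistoryGroundTruth",
    "generate_history",
]


@dataclass
class SyntheticRunConfig:
    """Parameters of one synthetic centroided MS1 run."""

    panel: CompoundPanel = field(default_factory=default_panel)
    polarity: str = "POS"
    true_bias_ppm: float = 0.0
    per_compound_bias_ppm: dict[str, float] = field(default_factory=dict)
    mass_noise_sd_ppm: float = 0.0
    run_minutes: float = 7.0
    rt_assignments: dict[str, float] = field(default_factory=dict)
    peak_sigma_minutes: float = 0.06
    peak_height: float = 1e6
    baseline_height: float = 1e3
    n_baseline_peaks: int = 20
    decoy_offset_ppm: float = 80.0  # >= 50 ppm keeps default 10 ppm windows clean
    decoy_height: float = 1e4
    scan_interval_seconds: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_noise_sd_ppm < 0:
            raise ValueError("mass_noise_sd_ppm must be non-negative")
        if self.peak_sigma_minutes <= 0:
            raise ValueError("peak_sigma_minutes must be positive")


@dataclass(frozen=True)
class RunGroundTruth:
    """True per-compound bias and elution time injected into a run."""

    polarity: str
    bias_ppm: dict[str, float]
    rt_minutes: dict[str, float]
    mass_noise_sd_ppm: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "polarity": self.polarity,
            "bias_ppm": self.bias_ppm,
            "rt_minutes": self.rt_minutes,
            "mass_noise_sd_ppm": self.mass_noise_sd_ppm,
            "seed": self.seed,
        }


def _default_rt_spread(names: list[str], run_minutes: float) -> dict[str, float]:
    # spread peaks over the middle of the gradient, away from the void and re-equilibration
    lo, hi = 0.15 * run_minutes, 0.85 * run_minutes
    if len(names) == 1:
        return {names[0]: (lo + hi) / 2.0}
    centers = np.linspace(lo, hi, len(names))
    return dict(zip(names, centers))


def generate_run(config: SyntheticRunConfig) -> tuple[Run, RunGroundTruth]:
    """Generate a centroided run containing the matching-polarity panel
    compounds as Gaussian peaks with a known mass bias."""
    rng = np.random.default_rng(config.seed)
    compounds = list(config.panel.by_polarity(config.polarity))
    names = [c.name for c in compounds]
    rt_centers = dict(_default_rt_spread(names, config.run_minutes))
    rt_centers.update({k: v for k, v in config.rt_assignments.items() if k in set(names)})
    bias = {
        name: config.per_compound_bias_ppm.get(name, config.true_bias_ppm) for name in names
    }

    n_scans = int(np.floor(config.run_minutes * 60.0 / config.scan_interval_seconds)) + 1
    times = np.arange(n_scans) * config.scan_interval_seconds / 60.0

    # static baseline centroids, kept away from every target window
    targets = np.array([c.expected_mz for c in compounds]) if compounds else np.empty(0)
    baseline_mz = []
    while len(baseline_mz) < config.n_baseline_peaks:
        candidate = rng.uniform(100.0, 1000.0)
        if targets.size == 0 or np.min(np.abs(candidate - targets) / targets) * 1e6 > 2 * config.decoy_offset_ppm:
            baseline_mz.append(candidate)
    baseline_mz = np.array(sorted(baseline_mz))

    spectra: list[Spectrum] = []
    for scan_index, rt in enumerate(times):
        mz_list: list[float] = []
        int_list: list[float] = []
        for compound in compounds:
            center = rt_centers[compound.name]
            height = config.peak_height * float(
                np.exp(-0.5 * ((rt - center) / config.peak_sigma_minutes) ** 2)
            )
            if height < 1.0:
                continue
            ppm_shift = bias[compound.name]
            if config.mass_noise_sd_ppm > 0:
                ppm_shift += rng.normal(0.0, config.mass_noise_sd_ppm)
            mz_list.append(compound.expected_mz * (1.0 + ppm_shift * 1e-6))
            int_list.append(height)
            # decoy centroid well outside the extraction window
            mz_list.append(compound.expected_mz * (1.0 + config.decoy_offset_ppm * 1e-6))
            int_list.append(config.decoy_height * float(rng.uniform(0.5, 1.5)))
        mz_list.extend(baseline_mz)
        int_list.extend(config.baseline_height * rng.uniform(0.2, 1.0, size=baseline_mz.size))

        order = np.argsort(mz_list)
        mz_arr = np.asarray(mz_list)[order]
        int_arr = np.asarray(int_list)[order]
        keep = np.concatenate(([True], np.diff(mz_arr) > 0))  # drop exact duplicates
        spectra.append(
            Spectrum(
                scan_index=scan_index,
                rt_minutes=float(rt),
                mz=mz_arr[keep],
                intensity=int_arr[keep],
                polarity=config.polarity,
            )
        )
    run = Run(spectra=spectra, source_id=f"synthetic-seed{config.seed}", polarity=config.polarity)
    truth = RunGroundTruth(
        polarity=config.polarity,
        bias_ppm=bias,
        rt_minutes={k: float(v) for k, v in rt_centers.items()},
        mass_noise_sd_ppm=config.mass_noise_sd_ppm,
        seed=config.seed,
    )
    return run, truth


def generate_injections(
    panel: CompoundPanel,
    polarity: str,
    n_replicates: int = 5,
    phase: str = "PRE",
    compound_means_ppm: dict[str, float] | float = 0.0,
    replicate_sd_ppm: float = 0.5,
    seed: int = 0,
) -> list[InjectionResult]:
    """Directly simulate replicate injection error vectors (bypassing the
    spectral layer) for verdict-level studies."""
    rng = np.random.default_rng(seed)
    names = [c.name for c in panel.by_polarity(polarity)]
    if isinstance(compound_means_ppm, dict):
        means = {n: compound_means_ppm.get(n, 0.0) for n in names}
    else:
        means = {n: float(compound_means_ppm) for n in names}
    results = []
    for rep in range(1, n_replicates + 1):
        errors = {n: float(means[n] + rng.normal(0.0, replicate_sd_ppm)) for n in names}
        results.append(
            InjectionResult(
                injection_id=f"sim-{phase}-{polarity}-{rep}",
                polarity=polarity,
                phase=phase,
                errors=errors,
            )
        )
    return results


@dataclass
class SyntheticHistoryConfig:
    """Parameters of a synthetic longitudinal SST history.

    Error mechanism per replicate row of compound c in a batch with n
    real-sample injections:

    ``base ~ Normal(mu_c + drift_slope * n * 1[POST], sd_polarity)``
    ``error = sign(base) * (|base| + poor_penalty * 1[POOR]
    + calmix_penalty * 1[CALMIX] + days_effect * days
    + poor_days_effect * days * 1[POOR])``

    Magnitude effects enter additively on |error| so the calibration
    model's coefficients equal the configured penalties in expectation.
    """

    panel: CompoundPanel = field(default_factory=default_panel)
    n_batches: int = 50
    injections_per_batch: int | tuple[int, int] = (5, 120)
    replicates_per_phase: int = 5
    compound_true_means_ppm: dict[str, float] = field(default_factory=dict)
    replicate_sd_pos: float = 0.7
    replicate_sd_neg: float = 0.5
    drift_slope_ppm_per_injection: float = 0.0
    cal_quality_mix: float = 0.2  # fraction of batches with POOR calibration
    poor_cal_penalty_ppm: float = 0.0
    calmix_fraction: float = 0.3  # fraction calibrated with CalMix only
    calmix_penalty_ppm: float = 0.0
    days_since_cal_max: float = 14.0
    days_effect_ppm_per_day: float = 0.0
    poor_days_effect_ppm_per_day: float = 0.0
    start_date: date = date(2024, 1, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cal_quality_mix <= 1 or not 0 <= self.calmix_fraction <= 1:
            raise ValueError("mix fractions must lie in [0, 1]")
        if min(self.replicate_sd_pos, self.replicate_sd_neg) < 0:
            raise ValueError("replicate sds must be non-negative")


@dataclass(frozen=True)
class HistoryGroundTruth:
    compound_true_means_ppm: dict[str, float]
    drift_slope_ppm_per_injection: float
    poor_cal_penalty_ppm: float
    calmix_penalty_ppm: float
    days_effect_ppm_per_day: float
    poor_days_effect_ppm_per_day: float
    replicate_sd_pos: float
    replicate_sd_neg: float
    seed: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def generate_history(config: SyntheticHistoryConfig) -> tuple[History, HistoryGroundTruth]:
    """Simulate a longitudinal history of PRE/POST SST replicates for both
    polarities with fully known generating parameters."""
    rng = np.random.default_rng(config.seed)
    compounds = list(config.panel)
    mu = {c.name: config.compound_true_means_ppm.get(c.name, 0.0) for c in compounds}
    sd_by_pol = {"POS": config.replicate_sd_pos, "NEG": config.replicate_sd_neg}

    n_b, n_c, n_r = config.n_batches, len(compounds), config.replicates_per_phase

    # batch-level covariates
    if isinstance(config.injections_per_batch, tuple):
        lo, hi = config.injections_per_batch
        n_inj = rng.integers(lo, hi + 1, size=n_b)
    else:
        n_inj = np.full(n_b, int(config.injections_per_batch))
    calmix = rng.random(n_b) < config.calmix_fraction
    poor = rng.random(n_b) < config.cal_quality_mix
    cal_rms = np.where(poor, rng.uniform(0.32, 0.8, n_b), rng.uniform(0.05, 0.30, n_b))
    days = np.round(rng.uniform(0.0, config.days_since_cal_max, n_b), 2)
    penalty = (
        config.poor_cal_penalty_ppm * poor
        + config.calmix_penalty_ppm * calmix
        + config.days_effect_ppm_per_day * days
        + config.poor_days_effect_ppm_per_day * days * poor
    )

    # row layout: batch -> phase (PRE, POST) -> compound -> replicate
    per_batch = 2 * n_c * n_r
    ib = np.repeat(np.arange(n_b), per_batch)
    is_post = np.tile(np.repeat(np.array([0, 1]), n_c * n_r), n_b)
    ic = np.tile(np.repeat(np.arange(n_c), n_r), n_b * 2)
    rep = np.tile(np.arange(1, n_r + 1), n_b * 2 * n_c)

    mu_arr = np.array([mu[c.name] for c in compounds])
    sd_arr = np.array([sd_by_pol[c.polarity] for c in compounds])
    loc = mu_arr[ic] + config.drift_slope_ppm_per_injection * n_inj[ib] * is_post
    base = rng.normal(loc, sd_arr[ic])
    error = np.sign(base) * (np.abs(base) + penalty[ib])

    names = np.array([c.name for c in compounds])
    polarities = np.array([c.polarity for c in compounds])
    dates = np.array([(config.start_date + timedelta(days=3 * b)).isoformat() for b in range(n_b)])
    batch_ids = np.array([f"B{b:03d}" for b in range(n_b)])
    df = pd.DataFrame(
        {
            "batch_id": batch_ids[ib],
            "date": dates[ib],
            "polarity": polarities[ic],
            "phase": np.where(is_post == 1, "POST", "PRE"),
            "replicate": rep,
            "n_batch_injections": n_inj[ib],
            "cal_type": np.where(calmix[ib], "CALMIX", "CALMIX_FLEXMIX"),
            "cal_rms_ppm": cal_rms[ib],
            "days_since_cal": days[ib],
            "compound": names[ic],
            "error_ppm": error,
        }
    )[HISTORY_COLUMNS]
    truth = HistoryGroundTruth(
        compound_true_means_ppm=mu,
        drift_slope_ppm_per_injection=config.drift_slope_ppm_per_injection,
        poor_cal_penalty_ppm=config.poor_cal_penalty_ppm,
        calmix_penalty_ppm=config.calmix_penalty_ppm,
        days_effect_ppm_per_day=config.days_effect_ppm_per_day,
        poor_days_effect_ppm_per_day=config.poor_days_effect_ppm_per_day,
        replicate_sd_pos=config.replicate_sd_pos,
        replicate_sd_neg=config.replicate_sd_neg,
        seed=config.seed,
    )
    return History(df), truth
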