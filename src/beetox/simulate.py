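"""Synthetic study generator: counts, ground truth, survival, and food intake.

Emulates the statistical structure of an acute-vs-chronic pesticide exposure
RNA-seq experiment so that every downstream stage of the pipeline is testable
without sequencing data:

* negative-binomial gene counts with a mean-dispersion trend, per-colony
  log2-scale effects, and scheme-dependent replicate variance;
* a shared-acute DE gene set (mostly upregulated, large amplitudes), a
  partially shared chronic set with a few strongly downregulated immune-like
  genes, and compound-specific sets — acute amplitudes are rescaled so the
  mean |log2FC| of the shared-acute set is exactly
  ``amplitude_ratio_acute_over_chronic`` times that of the shared-chronic set;
* exponential survival with treatment-specific hazards (acute arms are only
  at elevated hazard during the final two days of the 14-day experiment);
* linear per-bee food-intake trends with a treatment-by-day interaction.

All outputs are deterministic functions of ``SynthConfig`` (including its
seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CONTROL, SynthConfig, treatment_label

EXPERIMENT_DAYS = 14
ACUTE_WINDOW_DAYS = 2
INTAKE_MEASUREMENT_DAYS = tuple(range(2, EXPERIMENT_DAYS + 1, 2))

#: Generator defaults for treatment-specific hazard ratios, chosen so the
#: clothianidin arms emulate mortality in the mid-50s percent (acute, over its
#: two-day window) and high-20s percent (chronic, over 14 days) against a
#: baseline hazard of 0.008/day, with mild effects for the other compounds.
DEFAULT_HAZARD_RATIOS: dict[str, float] = {
    "control": 1.0,
    "acetamiprid_chronic": 1.3,
    "acetamiprid_acute": 3.0,
    "clothianidin_chronic": 3.06,
    "clothianidin_acute": 42.5,
    "sulfoxaflor_chronic": 1.2,
    "sulfoxaflor_acute": 2.5,
}

#: Generator defaults for intake slopes (mL per bee per day of exposure,
#: relative to control); only chronic and acute clothianidin depress intake.
DEFAULT_INTAKE_SLOPES: dict[str, float] = {
    "clothianidin_chronic": -0.063,
    "clothianidin_acute": -0.51,
}

CATEGORY_NULL = "null"
CATEGORY_SHARED_ACUTE = "shared_acute"
CATEGORY_SHARED_CHRONIC = "shared_chronic"


def _round_half_up(x: float) -> int:
    """Round-half-up used to turn a fraction of a set size into a count."""
    return int(np.floor(x + 0.5))


@dataclass
class GroundTruth:
    """True per-gene effects behind a synthetic count matrix.

    Attributes
    ----------
    lfc : DataFrame, genes x treatments
        True log2 fold change of each treatment relative to control.
    category : Series
        One of ``null``, ``shared_acute``, ``acute_specific:<compound>``,
        ``shared_chronic``, ``chronic_specific:<compound>`` per gene.
    """

    lfc: pd.DataFrame
    category: pd.Series

    @property
    def is_null(self) -> pd.Series:
        return self.category == CATEGORY_NULL

    @property
    def is_de(self) -> pd.Series:
        return ~self.is_null

    @property
    def shared_acute(self) -> pd.Series:
        return self.category == CATEGORY_SHARED_ACUTE

    @property
    def shared_chronic(self) -> pd.Series:
        return self.category == CATEGORY_SHARED_CHRONIC

    def de_in_treatment(self, treatment: str) -> pd.Series:
        return self.lfc[treatment] != 0.0

    def de_in_scheme(self, scheme: str) -> pd.Series:
        cols = [c for c in self.lfc.columns if c.endswith("_" + scheme)]
        return (self.lfc[cols] != 0.0).any(axis=1)


def _sample_table(config: SynthConfig) -> pd.DataFrame:
    rows = []
    for treatment in config.treatments:
        if treatment == CONTROL:
            compound = scheme = "none"
        else:
            compound, scheme = treatment.rsplit("_", 1)
        for rep in range(config.replicates_for(treatment)):
            rows.append(
                {
                    "sample_id": f"{treatment}_r{rep + 1}",
                    "treatment": treatment,
                    "compound": compound,
                    "scheme": scheme,
                    "colony": rep % config.colonies + 1,
                }
            )
    return pd.DataFrame(rows)


def _signed_magnitudes(
    rng: np.random.Generator, size: int, up_fraction: float, magnitudes: np.ndarray
) -> np.ndarray:
    """Attach signs to magnitudes with an exact (round-half-up) up count."""
    n_up = min(_round_half_up(up_fraction * size), size)
    signs = np.full(size, -1.0)
    signs[rng.permutation(size)[:n_up]] = 1.0
    return signs * magnitudes


def _assign_truth(config: SynthConfig, rng: np.random.Generator) -> GroundTruth:
    n = config.n_genes
    gene_ids = pd.Index([f"g{i + 1:05d}" for i in range(n)], name="gene_id")
    category = pd.Series(CATEGORY_NULL, index=gene_ids, dtype=object)
    lfc = pd.DataFrame(0.0, index=gene_ids, columns=config.treatments[1:])

    order = rng.permutation(n)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        idx = order[cursor : cursor + k]
        cursor += k
        return idx

    lo, hi = config.lfc_magnitude_range
    draw = lambda k: rng.uniform(lo, hi, size=k)  # noqa: E731

    # chronic shared set first: its mean |LFC| anchors the amplitude ratio
    shared_chronic_idx = take(config.shared_chronic_set_size)
    n_strong = min(config.chronic_n_strong_down, len(shared_chronic_idx))
    chronic_shared_lfc = np.empty(len(shared_chronic_idx))
    if len(shared_chronic_idx):
        chronic_shared_lfc[:n_strong] = config.chronic_strong_down_lfc
        rest = len(shared_chronic_idx) - n_strong
        chronic_shared_lfc[n_strong:] = _signed_magnitudes(
            rng, rest, 1.0 - config.chronic_down_fraction, draw(rest)
        )

    # acute shared set: raw magnitudes rescaled to hit the amplitude ratio
    shared_acute_idx = take(config.shared_acute_set_size)
    acute_raw = draw(len(shared_acute_idx))
    if len(shared_acute_idx) and len(shared_chronic_idx):
        target = (
            config.amplitude_ratio_acute_over_chronic
            * np.mean(np.abs(chronic_shared_lfc))
        )
        acute_scale = target / np.mean(acute_raw)
    elif len(shared_acute_idx):
        acute_scale = config.amplitude_ratio_acute_over_chronic
    else:
        acute_scale = 1.0
    acute_shared_lfc = _signed_magnitudes(
        rng, len(shared_acute_idx), config.acute_up_fraction, acute_scale * acute_raw
    )

    category.iloc[shared_chronic_idx] = CATEGORY_SHARED_CHRONIC
    category.iloc[shared_acute_idx] = CATEGORY_SHARED_ACUTE
    for compound in config.compounds:
        lfc.iloc[shared_chronic_idx, lfc.columns.get_loc(treatment_label(compound, "chronic"))] = chronic_shared_lfc
        lfc.iloc[shared_acute_idx, lfc.columns.get_loc(treatment_label(compound, "acute"))] = acute_shared_lfc

    # compound-specific sets share the scheme-level amplitude scales
    for compound in config.compounds:
        k = config.specific_acute_set_sizes.get(compound, 0)
        idx = take(k)
        category.iloc[idx] = f"acute_specific:{compound}"
        vals = _signed_magnitudes(rng, k, config.acute_up_fraction, acute_scale * draw(k))
        lfc.iloc[idx, lfc.columns.get_loc(treatment_label(compound, "acute"))] = vals
    for compound in config.compounds:
        k = config.specific_chronic_set_sizes.get(compound, 0)
        idx = take(k)
        category.iloc[idx] = f"chronic_specific:{compound}"
        vals = _signed_magnitudes(rng, k, 1.0 - config.chronic_down_fraction, draw(k))
        lfc.iloc[idx, lfc.columns.get_loc(treatment_label(compound, "chronic"))] = vals

    return GroundTruth(lfc=lfc, category=category)


def generate_counts(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a synthetic gene x sample count matrix with metadata and truth.

    Returns
    -------
    counts : DataFrame (genes x samples, non-negative integers)
    samples : DataFrame with columns sample_id, treatment, compound, scheme, colony
    truth : GroundTruth
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    samples = _sample_table(config)
    truth = _assign_truth(config, rng)
    n = config.n_genes

    baseline = rng.normal(*config.baseline_log2_mean, size=n)
    de_mask_baseline = truth.is_de.to_numpy()
    baseline[de_mask_baseline] = rng.normal(
        *config.de_baseline_log2_mean, size=int(de_mask_baseline.sum())
    )
    colony_eff = (
        rng.normal(0.0, config.colony_effect_sd, size=(n, config.colonies))
        if config.colony_effect_sd > 0
        else np.zeros((n, config.colonies))
    )
    lo, hi = config.library_size_range
    libsizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    de_mask = truth.is_de.to_numpy()
    n_de = int(de_mask.sum())
    alpha0, alpha1 = config.dispersion_trend

    counts = np.zeros((n, len(samples)), dtype=np.int64)
    for j, row in enumerate(samples.itertuples(index=False)):
        log2mean = baseline + colony_eff[:, row.colony - 1]
        if row.treatment != CONTROL:
            log2mean = log2mean + truth.lfc[row.treatment].to_numpy()
        if n_de and config.replicate_noise_sd > 0:
            sd = config.replicate_noise_sd
            if row.scheme == "acute":
                sd *= config.acute_extra_sd_factor
            noise = np.zeros(n)
            noise[de_mask] = rng.normal(0.0, sd, size=n_de)
            log2mean = log2mean + noise
        weights = np.exp2(log2mean - log2mean.max())
        mu = libsizes[j] * weights / weights.sum()
        mu = np.maximum(mu, 1e-8)
        alpha = alpha0 + alpha1 / mu
        poisson_like = alpha < 1e-8
        col = np.empty(n, dtype=np.int64)
        if poisson_like.any():
            col[poisson_like] = rng.poisson(mu[poisson_like])
        if (~poisson_like).any():
            a = alpha[~poisson_like]
            m = mu[~poisson_like]
            col[~poisson_like] = rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * m))
        counts[:, j] = col

    counts = pd.DataFrame(counts, index=truth.lfc.index, columns=samples["sample_id"].to_list())
    counts.columns.name = "sample_id"
    return counts, samples, truth


def generate_survival(
    config: SynthConfig,
    hazard_ratios: dict[str, float] | None = None,
    horizon_days: int = EXPERIMENT_DAYS,
    baseline_hazard: float = 0.008,
    bees_per_microcolony: int = 6,
) -> pd.DataFrame:
    """Simulate per-bee exponential survival records, censored at the horizon.

    Chronic and control individuals are at constant hazard
    ``baseline_hazard * HR`` over the whole experiment.  Acute individuals are
    at baseline hazard until the exposure window opens (the final two days)
    and at elevated hazard only inside the window.
    """
    config.validate()
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    hr = dict(DEFAULT_HAZARD_RATIOS if hazard_ratios is None else hazard_ratios)
    for t, v in hr.items():
        if v <= 0:
            raise ValueError(f"hazard ratio for {t!r} must be positive")
    rng = np.random.default_rng([int(config.seed), 1])
    rows = []
    for treatment in config.treatments:
        ratio = hr.get(treatment, 1.0)
        n = config.replicates_for(treatment) * bees_per_microcolony
        acute = treatment.endswith("_acute")
        window_start = max(horizon_days - ACUTE_WINDOW_DAYS, 0) if acute else 0
        if acute:
            t_pre = rng.exponential(1.0 / baseline_hazard, size=n)
            t_win = rng.exponential(1.0 / (baseline_hazard * ratio), size=n)
            time = np.where(t_pre < window_start, t_pre, window_start + t_win)
        else:
            time = rng.exponential(1.0 / (baseline_hazard * ratio), size=n)
        event = (time < horizon_days).astype(int)
        time = np.minimum(time, float(horizon_days))
        for i in range(n):
            rows.append(
                {
                    "individual": f"{treatment}_b{i + 1}",
                    "treatment": treatment,
                    "time_days": float(time[i]),
                    "event": int(event[i]),
                    "window_start": window_start,
                }
            )
    return pd.DataFrame(rows)


def generate_intake(
    config: SynthConfig,
    slopes: dict[str, float] | None = None,
    baseline: float = 1.5,
    colony_offset_sd: float = 0.05,
    noise_sd: float = 0.08,
    common_day_slope: float = 0.0,
) -> pd.DataFrame:
    """Simulate per-microcolony average daily food intake per bee (mL).

    Intake is measured every other day over the 14-day experiment.  For
    chronic and control treatments the treatment slope acts per day of the
    experiment; for acute treatments it acts per day after the exposure
    window opens (day 12), so the last two measurements carry the effect.
    """
    config.validate()
    if noise_sd < 0 or colony_offset_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    slope_map = dict(DEFAULT_INTAKE_SLOPES if slopes is None else slopes)
    rng = np.random.default_rng([int(config.seed), 2])
    colony_offsets = (
        rng.normal(0.0, colony_offset_sd, size=config.colonies)
        if colony_offset_sd > 0
        else np.zeros(config.colonies)
    )
    rows = []
    for treatment in config.treatments:
        slope = slope_map.get(treatment, 0.0)
        acute = treatment.endswith("_acute")
        for rep in range(config.replicates_for(treatment)):
            colony = rep % config.colonies + 1
            for day in INTAKE_MEASUREMENT_DAYS:
                exposure_days = max(day - (EXPERIMENT_DAYS - ACUTE_WINDOW_DAYS), 0) if acute else day
                value = (
                    baseline
                    + colony_offsets[colony - 1]
                    + common_day_slope * day
                    + slope * exposure_days
                )
                if noise_sd > 0:
                    value += rng.normal(0.0, noise_sd)
                rows.append(
                    {
                        "microcolony": f"{treatment}_m{rep + 1}",
                        "colony": colony,
                        "treatment": treatment,
                        "day": day,
                        "intake_ml_per_bee": value,
                    }
                )
    return pd.DataFrame(rows)
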