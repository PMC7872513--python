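"""Synthetic cohort and multi-omics layer generator with planted ground truth.

The generator emulates the structure of a five-layer blood-omics aging study:
a phenotype table of demographic/lifestyle/somatic/mental-health determinants,
one marker matrix per omics layer whose markers encode a latent *biological
age*, and 6-year follow-up outcomes.  Every planted parameter is recorded in
:class:`SimulationTruth` so downstream stages can be validated against a known
answer.

Latent model (one deviation per subject i and layer l)::

    d_il = sum_k gamma_kl * x~_ik  +  s_l * u_i  +  eps_il

with standardized determinants ``x~``, a shared standard-normal factor ``u``
and independent noise scaled so Var(d_il) = 1.  The layer's biological age is
``b_il = age_i + sigma_l * d_il`` and informative markers are noisy affine
readouts of ``b_il``.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (
    CohortConfig,
    ConfigurationError,
    DETERMINANTS,
    DISEASE_CATEGORIES,
    FollowupConfig,
    InputError,
    LAYERS,
    LayerSimConfig,
    TelomereConfig,
)

__all__ = [
    "OmicsLayer",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_omics_layer",
    "simulate_telomere",
    "simulate_followup",
    "telomere_noise_for_target",
]


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Generator keyed on (seed, stage tag).

    Folding the tag in guarantees that passing the same integer seed to
    different generator stages (cohort, each layer, follow-up) never replays
    the same random stream — overlapping streams would silently correlate
    supposedly independent noise.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


@dataclass
class OmicsLayer:
    """One marker matrix with technical covariates and missingness metadata.

    ``values`` is subjects x markers (index = subject_id); missing entries are
    NaN and flagged in ``mask``.  ``upper_mask`` marks the subset of missing
    entries censored at the *upper* detection limit (the rest are lower-limit
    or plain missing).
    """

    name: str
    values: pd.DataFrame
    batch: pd.Series
    lab: pd.Series | None = None
    mask: pd.DataFrame | None = None
    upper_mask: pd.DataFrame | None = None
    lower_limits: pd.Series | None = None
    upper_limits: pd.Series | None = None

    def __post_init__(self):
        if self.values.shape[1] < 1:
            raise InputError(f"layer {self.name!r} has no markers")
        if self.name == "telomere" and self.values.shape[1] != 1:
            raise InputError("telomere layer must have exactly one marker")
        if self.mask is None:
            self.mask = self.values.isna()
        if not self.batch.index.equals(self.values.index):
            raise InputError("batch covariate misaligned with marker matrix rows")

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def n_missing(self) -> int:
        return int(self.mask.to_numpy().sum())

    def copy(self) -> "OmicsLayer":
        return OmicsLayer(
            name=self.name,
            values=self.values.copy(),
            batch=self.batch.copy(),
            lab=None if self.lab is None else self.lab.copy(),
            mask=self.mask.copy(),
            upper_mask=None if self.upper_mask is None else self.upper_mask.copy(),
            lower_limits=None if self.lower_limits is None else self.lower_limits.copy(),
            upper_limits=None if self.upper_limits is None else self.upper_limits.copy(),
        )


@dataclass
class SimulationTruth:
    """Record of every planted generator parameter (artifact bookkeeping for
    the unobservable aging process; regenerating with the same seed reproduces
    identical outputs)."""

    seed: int
    deviations: pd.DataFrame  # subjects x layers, unit-variance latents
    shared_factor: pd.Series
    shared_loadings: dict[str, float]
    determinant_effects: dict[str, dict[str, float]]
    layer_r2: dict[str, float] = field(default_factory=dict)
    layer_sigma: dict[str, float] = field(default_factory=dict)
    marker_loadings: dict[str, np.ndarray] = field(default_factory=dict)
    informative_markers: dict[str, list[str]] = field(default_factory=dict)
    batch_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    lab_offsets: dict[str, np.ndarray] = field(default_factory=dict)
    telomere_slope: float | None = None
    telomere_noise_sd: float | None = None
    followup_params: dict | None = None

    def biological_age(self, cohort: pd.DataFrame, layer: str) -> pd.Series:
        """Latent biological age of a layer: age + sigma_l * deviation."""
        sigma = self.layer_sigma.get(layer)
        if sigma is None:
            raise InputError(f"layer {layer!r} has not been simulated")
        return cohort["age"] + sigma * self.deviations[layer]

    def to_json(self, path: str | Path) -> None:
        def conv(obj):
            if isinstance(obj, pd.DataFrame):
                return {c: obj[c].tolist() for c in obj.columns}
            if isinstance(obj, pd.Series):
                return obj.tolist()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            raise TypeError(type(obj))

        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), default=conv, indent=1)
        )


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

def _draw_determinants(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the phenotype marginals of a middle-aged epidemiological cohort.

    Determinants are drawn independently except where noted (n_chronic is the
    sum of the disease flags; depression severity is shifted upward in current
    MDD cases).
    """
    n = cfg.n
    t = pd.DataFrame(index=pd.Index([f"S{i:05d}" for i in range(n)], name="subject_id"))
    t["age"] = rng.uniform(cfg.age_min, cfg.age_max, n)
    t["sex"] = rng.binomial(1, cfg.p_female, n)  # female=1, male=0
    t["education"] = np.clip(rng.normal(12.1, 3.2, n), 6, 22)
    t["alcohol"] = rng.gamma(1.2, 5.2, n)
    smoker = rng.binomial(1, 0.5, n)
    t["smoking"] = smoker * rng.gamma(1.5, 14.7, n)  # pack-years, mean ~11
    t["physical_activity"] = rng.gamma(2.5, 1470.0, n)  # MET-min/week
    t["bmi"] = np.clip(rng.normal(25.6, 4.1, n), 16, 50)
    t["disability"] = rng.gamma(2.0, 12.5, n)
    t["lung_capacity"] = rng.normal(478.0, 110.0, n)
    t["grip_strength"] = np.clip(rng.normal(37.1, 9.0, n), 5, None)
    rates = dict(
        cardiometabolic=0.18, respiratory=0.09, musculoskeletal=0.10,
        digestive=0.09, neurological=0.03, endocrine=0.03, cancer=0.07,
    )
    for cat in DISEASE_CATEGORIES:
        t[cat] = rng.binomial(1, rates[cat], n)
    t["metsyn_components"] = rng.binomial(5, 0.272, n)
    t["n_chronic"] = t[list(DISEASE_CATEGORIES)].sum(axis=1)
    t["mdd_current"] = rng.binomial(1, 0.27, n)
    t["depression_severity"] = rng.gamma(3.24, 5.55, n) + 12.0 * t["mdd_current"]
    t["childhood_trauma"] = rng.choice(
        5, size=n, p=[0.55, 0.18, 0.12, 0.09, 0.06]
    )
    return t


def simulate_cohort(
    config: CohortConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Generate a phenotype table and the planted per-layer aging deviations.

    Returns ``(cohort, truth)`` where ``truth.deviations`` holds the
    unit-variance latent deviation of every subject for each of the five
    layers, with planted determinant effects and cross-layer correlations.
    """
    cfg = config or CohortConfig()
    if cfg.n < 10:
        raise InputError(f"cohort size must be >= 10, got {cfg.n}")
    for name in cfg.determinant_effects:
        if name not in DETERMINANTS:
            raise ConfigurationError(f"unknown determinant in effect map: {name!r}")
    for layer_map in cfg.determinant_effects.values():
        for layer in layer_map:
            if layer not in LAYERS:
                raise ConfigurationError(f"unknown layer in effect map: {layer!r}")
    for layer in cfg.shared_loadings:
        if layer not in LAYERS:
            raise ConfigurationError(f"unknown layer in shared loadings: {layer!r}")

    rng = _rng(seed, "cohort")
    cohort = _draw_determinants(cfg, rng)
    n = cfg.n

    u = rng.standard_normal(n)
    deviations = pd.DataFrame(index=cohort.index, columns=list(LAYERS), dtype=float)
    for layer in LAYERS:
        s = float(cfg.shared_loadings.get(layer, 0.0))
        gammas = {
            det: eff[layer]
            for det, eff in cfg.determinant_effects.items()
            if layer in eff
        }
        planted = np.zeros(n)
        for det, gamma in gammas.items():
            x = cohort[det].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ConfigurationError(f"determinant {det!r} is constant; cannot standardize")
            planted += gamma * (x - x.mean()) / sd
        var_planted = planted.var(ddof=1) if gammas else 0.0
        eps_var = 1.0 - var_planted - s * s
        if eps_var < 0:
            raise ConfigurationError(
                f"layer {layer!r}: planted effect + shared-factor variance exceeds 1"
            )
        deviations[layer] = planted + s * u + np.sqrt(eps_var) * rng.standard_normal(n)

    truth = SimulationTruth(
        seed=int(seed),
        deviations=deviations,
        shared_factor=pd.Series(u, index=cohort.index, name="shared_factor"),
        shared_loadings={k: float(v) for k, v in cfg.shared_loadings.items()},
        determinant_effects={
            det: {layer: float(g) for layer, g in eff.items()}
            for det, eff in cfg.determinant_effects.items()
        },
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# omics layers
# ---------------------------------------------------------------------------

def _subset_subjects(
    index: pd.Index, coverage: float, rng: np.random.Generator
) -> pd.Index:
    if not 0 < coverage <= 1:
        raise ConfigurationError(f"coverage must be in (0, 1], got {coverage}")
    if coverage == 1.0:
        return index
    k = max(2, int(round(coverage * len(index))))
    keep = np.sort(rng.choice(len(index), size=k, replace=False))
    return index[keep]


def simulate_omics_layer(
    cohort: pd.DataFrame,
    truth: SimulationTruth,
    layer_config: LayerSimConfig,
    seed: int = 0,
) -> OmicsLayer:
    """Simulate one marker panel as noisy readouts of latent biological age.

    Informative markers are ``a_j * b_i`` plus homoscedastic Gaussian noise of
    SD ``c``, with log-normal loadings ``|a_j|`` so that per-marker
    information is heavy-tailed (as in real age-associated panels) and ``c``
    chosen in closed form so the GLS-optimal combination of the informative
    panel attains ``target_r2`` against biological age ``b``; the remaining
    markers are pure noise.  Batch and lab offsets are added per (level,
    marker); optional detection-limit censoring masks the extreme tails of
    each marker.
    """
    cfg = layer_config
    if cfg.n_informative > cfg.n_markers:
        raise InputError(
            f"n_informative ({cfg.n_informative}) > n_markers ({cfg.n_markers})"
        )
    if not 0 <= cfg.target_r2 < 1:
        raise InputError(f"target_r2 must be in [0, 1), got {cfg.target_r2}")
    if cfg.n_batches < 1:
        raise InputError("n_batches must be >= 1")

    rng = _rng(seed, f"layer:{cfg.name}")
    subjects = _subset_subjects(cohort.index, cfg.coverage, rng)
    n = len(subjects)
    p, q = cfg.n_markers, cfg.n_informative

    d = truth.deviations.loc[subjects, cfg.name].to_numpy()
    age = cohort.loc[subjects, "age"].to_numpy()
    b = age + cfg.sigma_years * d  # latent biological age of this layer

    marker_names = [f"{cfg.name[:3]}_m{j:05d}" for j in range(p)]
    values = rng.standard_normal((n, p))  # noise markers ~ N(0, 1)
    loadings = np.zeros(p)
    if q > 0 and cfg.target_r2 > 0:
        a = np.exp(rng.normal(0.0, cfg.loading_sigma, q)) * rng.choice([-1.0, 1.0], q)
        var_b = b.var(ddof=1)
        if cfg.noise_sd is not None:
            tau = float(cfg.noise_sd)
        else:
            # panel information sum(a_j^2)/c^2 solves R2 = var_b/(var_b + c^2/sum(a^2))
            tau = np.sqrt((a**2).sum() * var_b * (1.0 - cfg.target_r2) / cfg.target_r2)
        values[:, :q] = a * b[:, None] + tau * rng.standard_normal((n, q))
        loadings[:q] = a
    elif q > 0 and cfg.noise_sd == 0:
        # degenerate: exact affine readout
        a = np.exp(rng.normal(0.0, cfg.loading_sigma, q)) * rng.choice([-1.0, 1.0], q)
        values[:, :q] = a * b[:, None]
        loadings[:q] = a

    batch = rng.integers(cfg.n_batches, size=n)
    batch_offsets = rng.normal(0.0, cfg.batch_sd, (cfg.n_batches, p))
    values += batch_offsets[batch]
    lab = None
    lab_offsets = np.zeros((0, p))
    if cfg.n_labs > 1:
        lab_idx = rng.integers(cfg.n_labs, size=n)
        lab_offsets = rng.normal(0.0, cfg.lab_sd, (cfg.n_labs, p))
        values += lab_offsets[lab_idx]
        lab = pd.Series(
            [f"L{k}" for k in lab_idx], index=subjects, name="lab", dtype=object
        )

    df = pd.DataFrame(values, index=subjects, columns=marker_names)
    mask = pd.DataFrame(False, index=subjects, columns=marker_names)
    upper_mask = None
    lower_limits = upper_limits = None
    if cfg.censor_mode not in ("none", "missing", "limit"):
        raise ConfigurationError(f"unknown censor_mode {cfg.censor_mode!r}")
    if cfg.censor_mode != "none" and (cfg.censor_frac > 0 or cfg.censor_frac_upper > 0):
        lo = df.quantile(cfg.censor_frac) if cfg.censor_frac > 0 else None
        hi = (
            df.quantile(1.0 - cfg.censor_frac_upper)
            if cfg.censor_frac_upper > 0
            else None
        )
        if lo is not None:
            below = df.lt(lo, axis=1)
            mask |= below
        if hi is not None:
            above = df.gt(hi, axis=1)
            mask |= above
            upper_mask = above
        df = df.mask(mask)
        if cfg.censor_mode == "limit":
            lower_limits = lo.rename("lower_limit") if lo is not None else None
            upper_limits = hi.rename("upper_limit") if hi is not None else None

    truth.layer_r2[cfg.name] = float(cfg.target_r2)
    truth.layer_sigma[cfg.name] = float(cfg.sigma_years)
    truth.marker_loadings[cfg.name] = loadings
    truth.informative_markers[cfg.name] = marker_names[:q]
    truth.batch_offsets[cfg.name] = batch_offsets
    truth.lab_offsets[cfg.name] = lab_offsets

    return OmicsLayer(
        name=cfg.name,
        values=df,
        batch=pd.Series([f"B{k}" for k in batch], index=subjects, name="batch", dtype=object),
        lab=lab,
        mask=mask,
        upper_mask=upper_mask,
        lower_limits=lower_limits,
        upper_limits=upper_limits,
    )


# ---------------------------------------------------------------------------
# telomere layer
# ---------------------------------------------------------------------------

def telomere_noise_for_target(
    target_r: float, age_slope: float, deviation_loading: float, age_var: float
) -> float:
    """Residual noise SD so that cor(-T/S, age) = target_r analytically.

    From r^2 = slope^2 var(age) / (slope^2 var(age) + loading^2 + sigma^2).
    """
    signal = age_slope**2 * age_var
    total_noise = signal * (1.0 - target_r**2) / target_r**2
    sigma2 = total_noise - deviation_loading**2
    if sigma2 < 0:
        raise ConfigurationError(
            "deviation loading alone exceeds the noise budget for the "
            f"target age correlation {target_r}"
        )
    return float(np.sqrt(sigma2))


def simulate_telomere(
    cohort: pd.DataFrame,
    truth: SimulationTruth,
    params: TelomereConfig | None = None,
    seed: int = 0,
) -> OmicsLayer:
    """Simulate a single T/S-ratio-like marker declining with age."""
    cfg = params or TelomereConfig()
    if cfg.age_slope >= 0:
        raise ConfigurationError(
            f"telomere age slope must be negative, got {cfg.age_slope}"
        )
    rng = _rng(seed, "telomere")
    subjects = _subset_subjects(cohort.index, cfg.coverage, rng)
    age = cohort.loc[subjects, "age"].to_numpy()
    d = truth.deviations.loc[subjects, "telomere"].to_numpy()

    noise_sd = cfg.noise_sd
    if noise_sd is None:
        noise_sd = telomere_noise_for_target(
            cfg.target_age_correlation,
            cfg.age_slope,
            cfg.deviation_loading,
            age.var(ddof=1),
        )
    ts = (
        cfg.mean_ts
        + cfg.age_slope * (age - age.mean())
        - cfg.deviation_loading * d  # larger deviation = biologically older = shorter
        + noise_sd * rng.standard_normal(len(subjects))
    )
    truth.telomere_slope = float(cfg.age_slope)
    truth.telomere_noise_sd = float(noise_sd)
    truth.layer_sigma["telomere"] = 0.0

    df = pd.DataFrame({"TS_ratio": ts}, index=subjects)
    return OmicsLayer(
        name="telomere",
        values=df,
        batch=pd.Series("B0", index=subjects, name="batch", dtype=object),
    )


# ---------------------------------------------------------------------------
# follow-up outcomes
# ---------------------------------------------------------------------------

def _outcome_probability(
    rate: float, logodds: np.ndarray
) -> np.ndarray:
    if not 0 <= rate <= 1:
        raise InputError(f"outcome rate must be in [0, 1], got {rate}")
    if rate in (0.0, 1.0):
        return np.full(logodds.shape, rate)
    return expit(logit(rate) + logodds)


def simulate_followup(
    cohort: pd.DataFrame,
    truth: SimulationTruth,
    params: FollowupConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Add 6-year mortality and per-category disease-onset flags.

    Onset is only defined for subjects without the disease at baseline (the
    flag stays 0 for baseline cases); probabilities follow a logistic model in
    standardized age and the planted layer deviations.
    """
    cfg = params or FollowupConfig()
    rng = _rng(seed, "followup")
    out = cohort.copy()
    n = len(out)
    z_age = (out["age"] - out["age"].mean()).to_numpy() / out["age"].std(ddof=1)
    dev_term = np.zeros(n)
    for layer, eff in cfg.deviation_logodds.items():
        if layer not in LAYERS:
            raise ConfigurationError(f"unknown layer in followup effects: {layer!r}")
        dev_term += eff * truth.deviations[layer].to_numpy()

    p_mort = _outcome_probability(cfg.mortality_rate, cfg.age_logodds * z_age + dev_term)
    out["mortality_6y"] = rng.binomial(1, p_mort)

    for cat in DISEASE_CATEGORIES:
        rate = cfg.onset_rates.get(cat, 0.0)
        p_onset = _outcome_probability(rate, cfg.onset_age_logodds * z_age + dev_term)
        draw = rng.binomial(1, p_onset)
        eligible = out[cat].to_numpy() == 0
        out[f"onset_{cat}_6y"] = np.where(eligible, draw, 0)

    truth.followup_params = dataclasses.asdict(cfg)
    return out


def validate_cohort(cohort: pd.DataFrame, require_followup: bool = False) -> None:
    """Check the CohortTable invariants; raise :class:`InputError` on violation."""
    if cohort.index.hasnans or cohort.index.duplicated().any():
        raise InputError("subject ids must be present and unique")
    binary = ["sex", "mdd_current", *DISEASE_CATEGORIES]
    if require_followup:
        binary += ["mortality_6y"] + [f"onset_{c}_6y" for c in DISEASE_CATEGORIES]
    for col in binary:
        if col in cohort and not cohort[col].isin([0, 1]).all():
            raise InputError(f"column {col!r} must be binary 0/1")
    if "metsyn_components" in cohort and not cohort["metsyn_components"].isin(range(6)).all():
        raise InputError("metsyn_components must be integers 0..5")
    if require_followup:
        for cat in DISEASE_CATEGORIES:
            col = f"onset_{cat}_6y"
            if col in cohort and (cohort.loc[cohort[cat] == 1, col] != 0).any():
                raise InputError(f"{col} must be 0 for baseline cases")
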