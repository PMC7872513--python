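"""Run configuration for the multi-omics aging pipeline.

Every tunable of the pipeline lives in one :class:`PipelineConfig` tree that
round-trips through YAML/JSON unchanged, so that a run is fully described by
``(config, seed)``.  Layer dimensions default to a scaled-down but
shape-faithful version of a five-layer blood-omics study: a single telomere
T/S marker, a large CpG-methylation panel, a gene-expression panel, and
targeted protein/metabolite panels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """A configuration value is inconsistent or refers to an unknown name."""


class InputError(ValueError):
    """Input data violates an operation's preconditions."""


#: Canonical layer order used throughout the package.
LAYERS = ("telomere", "epigenetic", "transcriptomic", "proteomic", "metabolomic")

#: The four panel-based layers that go through clock training (telomere is a
#: single direct measurement and is handled separately).
OMICS_LAYERS = LAYERS[1:]

DISEASE_CATEGORIES = (
    "cardiometabolic",
    "respiratory",
    "musculoskeletal",
    "digestive",
    "neurological",
    "endocrine",
    "cancer",
)

#: Determinant panel, in the row order of the association table
#: (demographic, lifestyle, somatic health, mental health).
DETERMINANTS = (
    "sex",
    "education",
    "alcohol",
    "smoking",
    "physical_activity",
    "bmi",
    "disability",
    "lung_capacity",
    "grip_strength",
    *DISEASE_CATEGORIES,
    "metsyn_components",
    "n_chronic",
    "mdd_current",
    "depression_severity",
    "childhood_trauma",
)

#: Indicator column order for association tables.
INDICATORS = (*LAYERS, "composite_sum", "composite_pc1")

#: Literal step lists used by the original methylation / gene-expression
#: clock-building procedure, available as presets for full-scale panels.
CPG_STEP_PRESET = (0, 100, 1000, 10_000, 80_000, 100_000)
GENE_STEP_PRESET = (100, 500, 1000, 1200, 1400)


@dataclass
class CohortConfig:
    """Marginals of the simulated phenotype table and the planted latent model.

    ``determinant_effects`` maps determinant name -> {layer: gamma}, the
    standardized effect of that determinant on the layer's latent aging
    deviation.  ``shared_loadings`` maps layer -> loading on a single shared
    factor; the planted cross-layer deviation correlation of layers l, m is
    the product of their loadings.
    """

    n: int = 800
    age_min: float = 18.0
    age_max: float = 65.0
    p_female: float = 0.66
    shared_loadings: dict[str, float] = field(
        default_factory=lambda: {
            # total cross-layer deviation correlation = loading product plus
            # the shared determinant-effect covariance; these keep every pair
            # below 0.2, highest for proteomic-metabolomic (~0.18)
            "telomere": 0.10,
            "epigenetic": 0.25,
            "transcriptomic": 0.35,
            "proteomic": 0.40,
            "metabolomic": 0.30,
        }
    )
    determinant_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # planted standardized effects on the latent deviations, mirroring
            # the association pattern of a five-clock cohort study: male sex,
            # BMI, smoking and metabolic syndrome on most layers, depression
            # measures on epigenetic/transcriptomic/proteomic aging
            # (female=1 is "biologically younger", hence negative sex effects)
            "sex": {
                "telomere": -0.06, "epigenetic": -0.10, "transcriptomic": -0.15,
                "proteomic": -0.03, "metabolomic": -0.08,
            },
            "alcohol": {"proteomic": 0.07},
            "smoking": {
                "telomere": 0.06, "transcriptomic": 0.05,
                "proteomic": 0.10, "metabolomic": 0.05,
            },
            "bmi": {
                "telomere": 0.04, "epigenetic": 0.09, "transcriptomic": 0.14,
                "proteomic": 0.12, "metabolomic": 0.23,
            },
            "disability": {"epigenetic": 0.11},
            "digestive": {"transcriptomic": 0.06, "proteomic": 0.06},
            "endocrine": {"proteomic": 0.06},
            "cardiometabolic": {"metabolomic": 0.05},
            "metsyn_components": {
                "telomere": 0.06, "transcriptomic": 0.13,
                "proteomic": 0.13, "metabolomic": 0.21,
            },
            "n_chronic": {"proteomic": 0.09},
            "mdd_current": {"epigenetic": 0.09, "transcriptomic": 0.07, "proteomic": 0.08},
            "depression_severity": {"epigenetic": 0.12, "proteomic": 0.07},
            "childhood_trauma": {"epigenetic": 0.12},
        }
    )


@dataclass
class LayerSimConfig:
    """Settings for one simulated marker panel.

    ``target_r2`` is the oracle R² that the best linear predictor built from
    the informative markers attains against the layer's latent biological age
    (chronological age + sigma_years * deviation).  ``loading_sigma`` is the
    log-normal spread of per-marker information, emulating the heavy-tailed
    age-association spectrum of real omics panels (a few strong markers, many
    weak ones).  ``noise_sd`` overrides the R²-derived marker noise when set
    (used for degenerate/diagnostic panels).  ``coverage`` is the fraction of
    cohort subjects measured on this layer.
    """

    name: str = "layer"
    n_markers: int = 100
    n_informative: int = 20
    target_r2: float = 0.5
    sigma_years: float = 5.0
    loading_sigma: float = 1.5
    noise_sd: float | None = None
    n_batches: int = 3
    batch_sd: float = 0.5
    n_labs: int = 2
    lab_sd: float = 0.3
    censor_mode: str = "none"  # none | missing | limit
    censor_frac: float = 0.0
    censor_frac_upper: float = 0.0
    coverage: float = 1.0


@dataclass
class TelomereConfig:
    """Single-marker telomere (T/S ratio analogue) layer.

    The T/S ratio declines with age; ``noise_sd=None`` calibrates the residual
    noise analytically so that cor(-T/S, age) hits ``target_age_correlation``.
    """

    mean_ts: float = 1.2
    age_slope: float = -0.004  # T/S units per year; must be negative
    deviation_loading: float = 0.01
    noise_sd: float | None = None
    target_age_correlation: float = 0.30
    coverage: float = 1.0


@dataclass
class FollowupConfig:
    """6-year follow-up outcome model (mortality and per-category onset)."""

    mortality_rate: float = 0.02
    onset_rates: dict[str, float] = field(
        default_factory=lambda: {
            "cardiometabolic": 0.05,
            "respiratory": 0.03,
            "musculoskeletal": 0.04,
            "digestive": 0.03,
            "neurological": 0.01,
            "endocrine": 0.02,
            "cancer": 0.03,
        }
    )
    age_logodds: float = 0.5  # per SD of age, mortality
    onset_age_logodds: float = 0.3  # per SD of age, disease onset
    deviation_logodds: dict[str, float] = field(
        default_factory=lambda: {layer: 0.10 for layer in LAYERS}
    )


@dataclass
class PreprocessConfig:
    """Per-layer missingness thresholds (absolute counts for metabolites,
    a fraction for proteins, matching the platform conventions)."""

    metabolomic_max_missing_per_subject: int = 25
    metabolomic_max_missing_per_marker: int = 250
    protein_max_missing_fraction: float = 0.30


@dataclass
class ClockConfig:
    """Cross-validated ridge clock settings.

    ``candidates`` maps layer name to the stepped marker-count list; ``None``
    means "use all markers" (the convention for the small targeted panels).
    """

    n_folds: int = 10
    plateau_tol: float = 0.01
    n_inner_folds: int = 5
    n_lambdas: int = 8
    candidates: dict[str, list[int] | None] = field(
        default_factory=lambda: {
            "epigenetic": [0, 100, 500, 2000, 10_000, 20_000],
            "transcriptomic": [100, 500, 1000, 2000, 5000],
            "proteomic": None,
            "metabolomic": None,
        }
    )


@dataclass
class FDRConfig:
    n_permutations: int = 1000
    target_fdr: float = 0.05


def default_layer_configs() -> dict[str, LayerSimConfig]:
    """Scaled-down but shape-faithful default panels for the four omics layers."""
    return {
        "epigenetic": LayerSimConfig(
            name="epigenetic", n_markers=20_000, n_informative=500, target_r2=0.90
        ),
        "transcriptomic": LayerSimConfig(
            name="transcriptomic", n_markers=5000, n_informative=200, target_r2=0.55
        ),
        "proteomic": LayerSimConfig(
            name="proteomic",
            n_markers=171,
            n_informative=40,
            target_r2=0.80,
            censor_mode="limit",
            censor_frac=0.02,
        ),
        "metabolomic": LayerSimConfig(
            name="metabolomic",
            n_markers=231,
            n_informative=60,
            target_r2=0.52,
            censor_mode="missing",
            censor_frac=0.02,
        ),
    }


@dataclass
class PipelineConfig:
    """Full configuration of a simulate -> clocks -> associations -> FDR run."""

    seed: int = 0
    outdir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    layers: dict[str, LayerSimConfig] = field(default_factory=default_layer_configs)
    telomere: TelomereConfig = field(default_factory=TelomereConfig)
    followup: FollowupConfig = field(default_factory=FollowupConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    clocks: ClockConfig = field(default_factory=ClockConfig)
    determinants: list[str] = field(default_factory=lambda: list(DETERMINANTS))
    fdr: FDRConfig = field(default_factory=FDRConfig)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        for key in ("seed", "outdir", "determinants"):
            if key in d:
                kwargs[key] = d[key]
        for key, sub in (
            ("cohort", CohortConfig),
            ("telomere", TelomereConfig),
            ("followup", FollowupConfig),
            ("preprocess", PreprocessConfig),
            ("clocks", ClockConfig),
            ("fdr", FDRConfig),
        ):
            if key in d:
                kwargs[key] = sub(**d[key])
        if "layers" in d:
            kwargs["layers"] = {
                name: LayerSimConfig(**cfg) for name, cfg in d["layers"].items()
            }
        unknown = set(d) - set(kwargs)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        """Stable short hash identifying the configuration (excluding outdir)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_determinants(names, known=DETERMINANTS) -> None:
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ConfigurationError(f"unknown determinant name(s): {unknown}")
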