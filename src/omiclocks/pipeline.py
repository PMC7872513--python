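"""End-to-end orchestration: simulate -> preprocess -> clocks -> indicators ->
composites -> associations -> permutation FDR -> report artifacts.

Every stochastic stage receives a seed derived deterministically from the
root seed, so the whole run — and any stage re-run in isolation — is
reproducible from ``(config, seed)``.
"""

from __future__ import annotations

import logging
import platform
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .associations import associate_all, partial_spearman_matrix
from .cohort import (
    OmicsLayer,
    SimulationTruth,
    simulate_cohort,
    simulate_followup,
    simulate_omics_layer,
    simulate_telomere,
)
from .clocks import ClockFit, crossval_predict_age
from .composite import (
    AgingIndicatorSet,
    CompositeIndex,
    composite_pc1,
    composite_sum,
    residualize_on_age,
    telomere_indicator,
)
from .config import (
    InputError,
    LAYERS,
    OMICS_LAYERS,
    PipelineConfig,
)
from .permfdr import PermutationFDRTable, compute_fdr
from .preprocess import PreprocessReport, preprocess_layer

log = logging.getLogger("omiclocks")

__all__ = ["PipelineResult", "run_pipeline", "load_cohort", "stage_seed",
           "build_indicators"]


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed and stage name."""
    ss = np.random.SeedSequence([int(root_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: pd.DataFrame
    truth: SimulationTruth
    layers: dict[str, OmicsLayer]
    processed: dict[str, OmicsLayer]
    reports: dict[str, PreprocessReport]
    clock_fits: dict[str, ClockFit]
    indicators: AgingIndicatorSet
    composites: dict[str, CompositeIndex]
    associations: pd.DataFrame
    fdr: PermutationFDRTable
    correlations: pd.DataFrame
    correlation_p: pd.DataFrame
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def indicator_table(self) -> pd.DataFrame:
        """Indicators plus composite columns, aligned on the cohort index."""
        table = self.indicators.indicators.copy()
        for name, comp in self.composites.items():
            table[f"composite_{comp.variant}"] = comp.values.reindex(table.index)
        return table


def build_indicators(
    cohort: pd.DataFrame,
    clock_fits: dict[str, ClockFit],
    telomere_layer: OmicsLayer,
) -> AgingIndicatorSet:
    """Turn out-of-fold predicted ages into the five aging indicators.

    The four clock layers are age-regressed within their covered subjects;
    the telomere layer is the standardized negated T/S ratio.
    """
    table = pd.DataFrame(index=cohort.index, columns=list(LAYERS), dtype=float)
    ts = telomere_layer.values.iloc[:, 0]
    table.loc[ts.index, "telomere"] = telomere_indicator(ts.to_numpy())
    for layer, fit in clock_fits.items():
        pred = fit.oof_predictions
        age = cohort.loc[pred.index, "age"].to_numpy()
        table.loc[pred.index, layer] = residualize_on_age(pred.to_numpy(), age)
    return AgingIndicatorSet(indicators=table)


def _wide_association_table(assoc: pd.DataFrame, threshold: float | None) -> pd.DataFrame:
    """Determinant-rows x indicator (beta, p, fdr-significant) column pairs."""
    wide = {}
    for ind in assoc["indicator"].unique():
        sub = assoc[assoc["indicator"] == ind].set_index("determinant")
        wide[(ind, "beta")] = sub["beta"]
        wide[(ind, "p")] = sub["p"]
        wide[(ind, "fdr_sig")] = (
            (sub["p"] <= threshold).astype(int) if threshold is not None else 0
        )
    out = pd.DataFrame(wide)
    out.columns = [f"{ind}.{stat}" for ind, stat in out.columns]
    out.index.name = "determinant"
    return out


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis described by ``config``; write artifacts to
    ``config.outdir`` when set."""
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}
    stage = "configure"
    try:
        # --- simulate ---------------------------------------------------
        stage = "simulate"
        t0 = time.perf_counter()
        cohort, truth = simulate_cohort(cfg.cohort, stage_seed(cfg.seed, "cohort"))
        layers: dict[str, OmicsLayer] = {}
        layers["telomere"] = simulate_telomere(
            cohort, truth, cfg.telomere, stage_seed(cfg.seed, "telomere")
        )
        for name, layer_cfg in cfg.layers.items():
            layers[name] = simulate_omics_layer(
                cohort, truth, layer_cfg, stage_seed(cfg.seed, f"layer:{name}")
            )
        cohort = simulate_followup(
            cohort, truth, cfg.followup, stage_seed(cfg.seed, "followup")
        )
        timings[stage] = time.perf_counter() - t0
        log.info("simulated cohort n=%d with %d layers", len(cohort), len(layers))

        # --- preprocess -------------------------------------------------
        stage = "preprocess"
        t0 = time.perf_counter()
        processed: dict[str, OmicsLayer] = {}
        reports: dict[str, PreprocessReport] = {}
        for name, layer in layers.items():
            processed[name], reports[name] = preprocess_layer(layer, cfg.preprocess)
        timings[stage] = time.perf_counter() - t0

        # --- clocks -----------------------------------------------------
        stage = "clocks"
        t0 = time.perf_counter()
        clock_fits: dict[str, ClockFit] = {}
        for name in cfg.layers:
            layer = processed[name]
            age = cohort.loc[layer.subjects, "age"]
            clock_fits[name] = crossval_predict_age(
                layer,
                age,
                K=cfg.clocks.n_folds,
                candidates=cfg.clocks.candidates.get(name),
                plateau_tol=cfg.clocks.plateau_tol,
                n_inner=cfg.clocks.n_inner_folds,
                n_lambdas=cfg.clocks.n_lambdas,
                seed=stage_seed(cfg.seed, f"clock:{name}"),
            )
            log.info(
                "clock %s: k*=%d, oof cor(pred, age)=%.3f",
                name,
                clock_fits[name].k_star,
                max(clock_fits[name].validation_curve),
            )
        timings[stage] = time.perf_counter() - t0

        # --- indicators & composites -------------------------------------
        stage = "indicators"
        t0 = time.perf_counter()
        indicators = build_indicators(cohort, clock_fits, processed["telomere"])
        composites = {
            "sum": composite_sum(indicators),
            "pc1": composite_pc1(indicators),
        }
        timings[stage] = time.perf_counter() - t0
        log.info("composite overlap subjects: %d", len(indicators.overlap_ids))

        # --- associations -------------------------------------------------
        stage = "associations"
        t0 = time.perf_counter()
        ind_table = indicators.indicators.copy()
        ind_table["composite_sum"] = composites["sum"].values.reindex(ind_table.index)
        ind_table["composite_pc1"] = composites["pc1"].values.reindex(ind_table.index)
        assoc = associate_all(ind_table, cohort, cfg.determinants)
        corr, corr_p = partial_spearman_matrix(
            indicators.indicators, cohort["sex"]
        )
        timings[stage] = time.perf_counter() - t0

        # --- permutation FDR ----------------------------------------------
        stage = "fdr"
        t0 = time.perf_counter()
        fdr = compute_fdr(
            ind_table,
            cohort,
            assoc["p"].to_numpy(),
            B=cfg.fdr.n_permutations,
            seed=stage_seed(cfg.seed, "fdr"),
            target_fdr=cfg.fdr.target_fdr,
            determinants=cfg.determinants,
        )
        assoc = assoc.assign(
            fdr=fdr.fdr,
            fdr_significant=(
                (assoc["p"] <= fdr.threshold).astype(int)
                if fdr.threshold is not None
                else 0
            ),
        )
        timings[stage] = time.perf_counter() - t0
        log.info(
            "FDR threshold at %.0f%%: %s",
            100 * cfg.fdr.target_fdr,
            "none" if fdr.threshold is None else f"{fdr.threshold:.3g}",
        )
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    result = PipelineResult(
        config=cfg,
        cohort=cohort,
        truth=truth,
        layers=layers,
        processed=processed,
        reports=reports,
        clock_fits=clock_fits,
        indicators=indicators,
        composites=composites,
        associations=assoc,
        fdr=fdr,
        correlations=corr,
        correlation_p=corr_p,
        timings=timings,
    )
    if cfg.outdir:
        write_artifacts(result, Path(cfg.outdir))
    return result


def write_artifacts(result: PipelineResult, outdir: Path) -> None:
    cfg = result.config
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = f"omiclocks seed={cfg.seed} config={cfg.config_hash()}"
    cfg.to_yaml(outdir / "config.yaml")
    io.write_cohort(result.cohort, outdir / "cohort.tsv", header_comment=stamp)
    result.truth.to_json(outdir / "truth.json")
    for name, layer in result.layers.items():
        io.write_layer(layer, outdir / f"layer_{name}.tsv", header_comment=stamp)
    for name, report in result.reports.items():
        report.to_json(outdir / f"preprocess_{name}.json")
    preds = pd.concat(
        [
            pd.DataFrame(
                {
                    "subject_id": fit.oof_predictions.index,
                    "layer": name,
                    "predicted_age": fit.oof_predictions.to_numpy(),
                }
            )
            for name, fit in result.clock_fits.items()
        ]
    )
    io.write_table(preds, outdir / "predicted_ages.tsv", header_comment=stamp, index=False)
    for name, fit in result.clock_fits.items():
        fit.to_json(outdir / f"clockfit_{name}.json")
    io.write_table(result.indicator_table, outdir / "indicators.tsv", header_comment=stamp)
    result.composites["pc1"].to_json(outdir / "pc1_loadings.json")
    io.write_table(
        result.associations, outdir / "associations.tsv", header_comment=stamp, index=False
    )
    io.write_table(
        _wide_association_table(result.associations, result.fdr.threshold),
        outdir / "associations_wide.tsv",
        header_comment=stamp,
    )
    io.write_table(result.correlations, outdir / "correlations.tsv", header_comment=stamp)
    result.fdr.to_json(outdir / "fdr.json")
    io.write_json(
        {
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "config": cfg.to_dict(),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "stage_seconds": result.timings,
            "n_overlap": len(result.indicators.overlap_ids),
            "fdr_threshold": result.fdr.threshold,
        },
        outdir / "run_log.json",
    )


def load_cohort(
    phenotype_path: str | Path, layer_paths: dict[str, str | Path]
) -> tuple[pd.DataFrame, dict[str, OmicsLayer]]:
    """Read a cohort table and layer TSVs, aligning all by subject_id.

    Layers may cover only a subset of subjects (per-layer sample sizes can
    differ); layer subjects absent from the phenotype table are an error.
    """
    cohort = io.read_cohort(phenotype_path)
    layers: dict[str, OmicsLayer] = {}
    for name, path in layer_paths.items():
        layer = io.read_layer(path, name)
        overlap = layer.subjects.intersection(cohort.index)
        if len(overlap) == 0:
            raise InputError(f"layer {name!r} shares no subject ids with the cohort")
        extra = layer.subjects.difference(cohort.index)
        if len(extra):
            log.warning(
                "layer %s: %d subjects not in the phenotype table dropped",
                name,
                len(extra),
            )
        order = cohort.index[cohort.index.isin(layer.subjects)]
        layer.values = layer.values.loc[order]
        layer.mask = layer.mask.loc[order]
        layer.batch = layer.batch.loc[order]
        if layer.lab is not None:
            layer.lab = layer.lab.loc[order]
        if layer.upper_mask is not None:
            layer.upper_mask = layer.upper_mask.loc[order]
        layers[name] = layer
    return cohort, layers
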