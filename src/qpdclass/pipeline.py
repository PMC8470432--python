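"""Run configuration, seed management, logging, and the end-to-end pipeline.

A single :class:`RunConfig` (validated with pydantic, unknown keys
rejected, units spelled out in the field names) describes the whole study:
particle roster, medium, trap stiffness table, detector, acquisition grid,
segmentation, feature extraction and cross-validation settings.  One CLI
``--seed`` deterministically derives every stage seed through numpy's
SeedSequence spawn keys, so a run is reproducible from the config file and
one integer.  ``run_pipeline`` executes simulate → segment → featurize →
benchmark (both channel modes) and emits a manifest with checksums of every
output file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import io as qio
from .classify import ClassifierSpec, compare_channel_modes, default_classifier_specs
from .features import features_to_frame, fit_channel_pca, project_features, segment_trace, spectral_transform
from .trap_sim import (
    DetectorModel,
    MediumSpec,
    ParticleClass,
    QPDTrace,
    SimConfig,
    generate_dataset,
)

__all__ = [
    "RunConfig",
    "RunManifest",
    "default_config",
    "load_config",
    "stage_seed",
    "run_pipeline",
    "traces_to_spectra",
    "logger",
]

logger = logging.getLogger("qpdclass")

_STAGES = {"simulate": 0, "featurize": 1, "benchmark": 2, "permute": 3}


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a stage seed from the run seed: SeedSequence spawn keys keyed
    by a fixed per-stage index.  Pure and documented; always < 2^31."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(_STAGES[stage],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Configuration schema (units in field names; unknown keys rejected)
# ---------------------------------------------------------------------------


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ClassConfig(_Strict):
    label: str
    material: str
    diameter_um: float
    refractive_index: float


class MediumConfig(_Strict):
    temperature_K: float = 298.0
    viscosity_Pa_s: float = 8.9e-4
    refractive_index: float = 1.3270


class DetectorConfig(_Strict):
    xy_responsivity_V_per_m: float = 1.0e7
    sum_baseline_V: float = 5.0
    sum_responsivity_V_per_m: float = 2.0e6
    noise_sd_V: float = 0.01


class SimGridConfig(_Strict):
    sampling_rate_hz: float = 10_000.0
    duration_s: float = 120.0
    integrator_substeps: int = 1
    burn_in_s: float = 1.0
    integrator: Literal["euler", "exact"] = "euler"


class FeatureConfig(_Strict):
    segment_duration_s: float = 0.5
    n_components: int = 2
    pca_scope: Literal["train_only", "global"] = "train_only"


class CVConfig(_Strict):
    n_folds: int = 6
    inner_folds: int = 5
    families: list[str] = Field(
        default_factory=lambda: ["random_forest", "svm", "knn", "mlp"]
    )


class OutputConfig(_Strict):
    store_traces: bool = True


class RunConfig(_Strict):
    classes: list[ClassConfig]
    stiffness_table_N_per_m: dict[str, list[float]]
    signals_per_class: int = 6
    medium: MediumConfig = Field(default_factory=MediumConfig)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    sim: SimGridConfig = Field(default_factory=SimGridConfig)
    features: FeatureConfig = Field(default_factory=FeatureConfig)
    cv: CVConfig = Field(default_factory=CVConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    # -- conversions to domain objects -------------------------------------

    def particle_classes(self) -> list[ParticleClass]:
        return [
            ParticleClass(
                label=c.label,
                material=c.material,
                radius=0.5 * c.diameter_um * 1e-6,
                refractive_index=c.refractive_index,
            )
            for c in self.classes
        ]

    def medium_spec(self) -> MediumSpec:
        return MediumSpec(
            temperature=self.medium.temperature_K,
            viscosity=self.medium.viscosity_Pa_s,
            refractive_index=self.medium.refractive_index,
        )

    def detector_model(self) -> DetectorModel:
        return DetectorModel(
            xy_responsivity=self.detector.xy_responsivity_V_per_m,
            sum_baseline=self.detector.sum_baseline_V,
            sum_responsivity=self.detector.sum_responsivity_V_per_m,
            noise_sd=self.detector.noise_sd_V,
        )

    def sim_config(self, seed: int = 0) -> SimConfig:
        return SimConfig(
            sampling_rate=self.sim.sampling_rate_hz,
            duration=self.sim.duration_s,
            integrator_substeps=self.sim.integrator_substeps,
            burn_in=self.sim.burn_in_s,
            seed=seed,
            integrator=self.sim.integrator,
        )

    def stiffness_table(self) -> dict[str, tuple[float, float, float]]:
        return {
            label: tuple(vals)  # type: ignore[misc]
            for label, vals in self.stiffness_table_N_per_m.items()
        }

    def classifier_specs(self, seed: int = 0) -> list[ClassifierSpec]:
        specs = default_classifier_specs(seed)
        return [s for s in specs if s.family in self.cv.families]


_DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default.yaml"


def default_config() -> RunConfig:
    """The committed default: 6 classes, 6 signals x 120 s at 10 kHz."""
    return load_config(_DEFAULT_CONFIG_PATH)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------


def traces_to_spectra(traces: list[QPDTrace], segment_duration_s: float = 0.5):
    """Segment every trace and FFT every segment (the featurize stage up to,
    but not including, PCA — which is fold-scoped)."""
    spectra = []
    for trace in traces:
        for seg in segment_trace(trace, segment_duration_s):
            spectra.append(spectral_transform(seg))
    return spectra


class RunManifest(BaseModel):
    model_config = ConfigDict(extra="forbid")
    artifact_version: str
    seed: int
    stage_seeds: dict[str, int]
    config: dict
    outputs: dict[str, str]  # relative path -> sha256


def run_pipeline(config: RunConfig, out_dir: str | Path, seed: int = 0) -> RunManifest:
    """Execute the end-to-end study and write all stage outputs.

    Stages: simulate the labelled dataset; (optionally) store the traces;
    segment + FFT; write an exploratory feature table (PCA over the full
    dataset — fold-scoped PCA is refit inside the benchmark); run the paired
    3-channel vs SUM-only benchmark; write reports and a manifest.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {stage: stage_seed(seed, stage) for stage in _STAGES}
    outputs: dict[str, str] = {}

    def register(path: Path) -> None:
        outputs[str(path.relative_to(out_dir))] = qio.sha256_file(path)

    logger.info("simulate: %d classes x %d signals, seed %d",
                len(config.classes), config.signals_per_class, seeds["simulate"])
    traces = generate_dataset(
        config.particle_classes(),
        config.signals_per_class,
        config.stiffness_table(),
        config.detector_model(),
        config.medium_spec(),
        config.sim_config(),
        base_seed=seeds["simulate"],
    )
    if config.output.store_traces:
        manifest_path = qio.write_dataset(traces, out_dir / "traces")
        for entry in json.loads(manifest_path.read_text())["traces"]:
            register(out_dir / "traces" / entry["file"])
        register(manifest_path)

    logger.info("featurize: %g s segments", config.features.segment_duration_s)
    spectra = traces_to_spectra(traces, config.features.segment_duration_s)
    pca = fit_channel_pca(spectra, config.features.n_components)
    feats = features_to_frame(project_features(s, pca, "all") for s in spectra)
    feat_path = qio.write_features(feats, out_dir / "features.csv")
    register(feat_path)
    pca_path = out_dir / "pca_model.json"
    pca_path.write_text(json.dumps(qio.pca_model_to_dict(pca)))
    register(pca_path)

    logger.info("benchmark: families %s", config.cv.families)
    comparison = compare_channel_modes(
        spectra,
        config.classifier_specs(seeds["benchmark"]),
        seed=seeds["benchmark"],
        n_folds=config.cv.n_folds,
        pca_scope=config.features.pca_scope,
        inner_folds=config.cv.inner_folds,
    )
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(qio.comparison_to_dict(comparison), indent=2))
    register(report_path)
    for mode, rep in (("all", comparison.all_channels), ("sum_only", comparison.sum_only)):
        for fam, fam_rep in rep.families.items():
            p = out_dir / f"confusion_{mode}_{fam}.csv"
            pd.DataFrame(
                fam_rep.confusion_normalized,
                index=rep.class_labels,
                columns=rep.class_labels,
            ).to_csv(p)
            register(p)

    manifest = RunManifest(
        artifact_version=__version__,
        seed=seed,
        stage_seeds=seeds,
        config=config.model_dump(),
        outputs=outputs,
    )
    (out_dir / "run_manifest.json").write_text(manifest.model_dump_json(indent=2))
    logger.info("pipeline complete: %d output files", len(outputs))
    return manifest
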