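"""End-to-end orchestration: ensemble statistics, DEER simulation or
measurement, inversion, and model-experiment comparison.

The headline question the pipeline answers: is the distance
distribution recovered from a DEER trace consistent with the
intra-dimer Cu-Cu distance law of a given (synthetic or supplied)
tetramer ensemble?  Consistency is quantified by the difference of
distribution modes and by the overlap coefficient
integral min(p_ensemble, p_inverted) dr on the common 1-8 nm grid;
both are artifact metrics for what is otherwise a qualitative
comparison.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forward import DeerTrace, DistanceDistribution, read_trace
from .geometry import (
    OligomerEnsemble,
    PairClass,
    distance_distribution,
    orientation_distribution,
    pair_distances,
    read_ensemble,
    summarize_distances,
)
from .inversion import InversionResult, count_modes, invert_trace
from .stats import compare_distance_samples, select_representatives
from .surface import SasaParams, radius_of_gyration, tetramer_filter
from .synthetic import DeerAcquisitionSpec, EnsembleSpec, generate_deer_trace, generate_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "AnalysisReport",
    "ensemble_distance_model",
    "run_model_experiment_comparison",
]


class PipelineStageError(RuntimeError):
    """Failure of a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one end-to-end run (distances nm, times ns)."""

    ensemble_spec: EnsembleSpec | None = None
    pdb_path: str | None = None
    trace_path: str | None = None
    acquisition: DeerAcquisitionSpec = field(default_factory=DeerAcquisitionSpec)
    r_min: float = 1.0
    r_max: float = 8.0
    r_points: int = 201
    alpha: float | None = None  # None selects by L-curve corner
    distance_bin_width: float = 0.1
    orientation_bin_width: float = 0.05
    test_method: str = "mannwhitney"
    filter_max_configs: int = 100  # SASA filter subsample cap
    seed: int = 0

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            return str(obj)

        payload = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Per-class distance and orientation statistics, filter outcomes,
    inversion results, and the model-experiment comparison."""

    config_hash: str
    seed: int
    n_configurations: int
    stoichiometry: str
    intra_summary: tuple[float, float] | None  # mean, sd (nm)
    inter_summary: tuple[float, float] | None
    intra_curve: tuple[np.ndarray, np.ndarray] | None
    inter_curve: tuple[np.ndarray, np.ndarray] | None
    orientation_angle_sd_deg: float
    tetramer_fraction: float
    tetramer_ratios: np.ndarray
    intra_vs_inter_pvalue: float | None
    inversion: InversionResult
    ensemble_mode_nm: float
    inverted_mode_nm: float
    mode_difference_nm: float
    overlap_coefficient: float
    n_inverted_modes: int
    representative_ids: np.ndarray
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"# config_hash = {self.config_hash}",
            f"# seed = {self.seed}",
            f"n_configurations = {self.n_configurations}",
            f"stoichiometry = {self.stoichiometry}",
        ]
        if self.intra_summary:
            lines += [
                f"intra_mean_nm = {self.intra_summary[0]:.4f}",
                f"intra_sd_nm = {self.intra_summary[1]:.4f}",
            ]
        if self.inter_summary:
            lines += [
                f"inter_mean_nm = {self.inter_summary[0]:.4f}",
                f"inter_sd_nm = {self.inter_summary[1]:.4f}",
            ]
        lines += [
            f"orientation_angle_sd_deg = {self.orientation_angle_sd_deg:.3f}",
            f"tetramer_fraction = {self.tetramer_fraction:.4f}",
        ]
        if self.intra_vs_inter_pvalue is not None:
            lines.append(f"intra_vs_inter_pvalue = {self.intra_vs_inter_pvalue:.3e}")
        lines += [
            f"lambda_fit = {self.inversion.lambda_fit:.4f}",
            f"k_fit_per_ns = {self.inversion.k_fit:.4e}",
            f"alpha = {self.inversion.alpha:.4e}",
            f"ensemble_mode_nm = {self.ensemble_mode_nm:.3f}",
            f"inverted_mode_nm = {self.inverted_mode_nm:.3f}",
            f"mode_difference_nm = {self.mode_difference_nm:.3f}",
            f"overlap_coefficient = {self.overlap_coefficient:.4f}",
            f"n_inverted_modes = {self.n_inverted_modes}",
            "representative_ids = " + ",".join(map(str, self.representative_ids)),
        ]
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def ensemble_distance_model(
    ens: OligomerEnsemble,
    r_grid: np.ndarray,
    bin_width: float = 0.1,
) -> DistanceDistribution:
    """Predicted DEER distance distribution of an ensemble: the
    unit-integral histogram of intra-dimer Cu-Cu distances (inter-dimer
    for Cuh, which has no intra pairs), interpolated onto the inversion
    grid and renormalized; distances outside the grid fold to zero."""
    d = pair_distances(ens, PairClass.INTRA_DIMER)
    if d.size == 0:
        d = pair_distances(ens, PairClass.INTER_DIMER)
    centers, density = distance_distribution(d, bin_width)
    p = np.interp(r_grid, centers, density, left=0.0, right=0.0)
    if np.trapezoid(p, r_grid) <= 0:
        raise ValueError("ensemble distances fall entirely outside the grid")
    return DistanceDistribution(r_grid, p).normalized()


def _stage(name: str, timings: dict):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %-12s %.2f s", name, timings[name])
            return False

    return _Ctx()


def run_model_experiment_comparison(
    config: PipelineConfig, ensemble: OligomerEnsemble | None = None
) -> AnalysisReport:
    """Run the full chain and return an :class:`AnalysisReport`.

    The ensemble comes from the ``ensemble`` argument (e.g. a merged or
    pre-built one), from ``config.pdb_path``, or is generated from
    ``config.ensemble_spec``; the trace comes from ``config.trace_path``
    or is simulated from the ensemble's own distance model (a
    self-consistency round trip).
    """
    timings: dict[str, float] = {}
    r_grid = np.linspace(config.r_min, config.r_max, config.r_points)

    with _stage("ensemble", timings):
        if ensemble is not None:
            ens = ensemble
        elif config.pdb_path is not None:
            ens = read_ensemble(config.pdb_path)
        elif config.ensemble_spec is not None:
            ens = generate_ensemble(config.ensemble_spec)
        else:
            raise ValueError("config must supply ensemble_spec or pdb_path")
        if len(ens) == 0:
            raise ValueError("ensemble is empty")

    with _stage("geometry", timings):
        d_intra = pair_distances(ens, PairClass.INTRA_DIMER)
        d_inter = pair_distances(ens, PairClass.INTER_DIMER)
        intra_summary = (
            summarize_distances(d_intra) if d_intra.size >= 2 else None
        )
        inter_summary = (
            summarize_distances(d_inter) if d_inter.size >= 2 else None
        )
        intra_curve = (
            distance_distribution(d_intra, config.distance_bin_width)
            if d_intra.size
            else None
        )
        inter_curve = (
            distance_distribution(d_inter, config.distance_bin_width)
            if d_inter.size
            else None
        )
        cls = (
            PairClass.INTRA_DIMER if d_intra.size else PairClass.INTER_DIMER
        )
        orient = orientation_distribution(ens, cls, config.orientation_bin_width)

    with _stage("filter", timings):
        subset = ens.configurations[: config.filter_max_configs]
        flags_ratios = [tetramer_filter(c, SasaParams()) for c in subset]
        ratios = np.array([r for _, r in flags_ratios])
        tetramer_fraction = float(np.mean([f for f, _ in flags_ratios]))

    with _stage("stats", timings):
        if d_intra.size >= 10 and d_inter.size >= 10:
            pvalue = compare_distance_samples(
                d_intra, d_inter, method=config.test_method
            ).p_value
        else:
            pvalue = None

    with _stage("trace", timings):
        model_p = ensemble_distance_model(
            ens, r_grid, config.distance_bin_width
        )
        if config.trace_path is not None:
            trace: DeerTrace = read_trace(config.trace_path)
        else:
            trace, _ = generate_deer_trace(model_p, config.acquisition)

    with _stage("inversion", timings):
        inv = invert_trace(trace, r=r_grid, alpha=config.alpha)

    with _stage("comparison", timings):
        mode_ens = model_p.mode()
        mode_inv = inv.mode_r
        overlap = float(np.trapezoid(np.minimum(model_p.p, inv.p.p), r_grid))
        n_modes = count_modes(inv.p)

    with _stage("representatives", timings):
        per_conf = []
        for conf in ens:
            pc = [
                float(np.linalg.norm(s1.cu - s2.cu))
                for s1, s2 in _conf_pairs(conf)
            ]
            per_conf.append(np.mean(pc) if pc else np.nan)
        per_conf = np.asarray(per_conf)
        rg = np.array([radius_of_gyration(c) for c in ens])
        valid = ~np.isnan(per_conf)
        rep_ids = (
            select_representatives(per_conf[valid], rg[valid])
            if valid.any()
            else np.empty(0, dtype=int)
        )

    return AnalysisReport(
        config_hash=config.config_hash(),
        seed=config.seed,
        n_configurations=len(ens),
        stoichiometry=ens.stoichiometry,
        intra_summary=intra_summary,
        inter_summary=inter_summary,
        intra_curve=intra_curve,
        inter_curve=inter_curve,
        orientation_angle_sd_deg=orient.angle_sd_deg,
        tetramer_fraction=tetramer_fraction,
        tetramer_ratios=ratios,
        intra_vs_inter_pvalue=pvalue,
        inversion=inv,
        ensemble_mode_nm=mode_ens,
        inverted_mode_nm=mode_inv,
        mode_difference_nm=abs(mode_ens - mode_inv),
        overlap_coefficient=overlap,
        n_inverted_modes=n_modes,
        representative_ids=rep_ids,
        stage_seconds=timings,
    )


def _conf_pairs(conf):
    from .geometry import _class_pairs

    pairs = _class_pairs(conf, PairClass.INTRA_DIMER)
    if not pairs:
        pairs = _class_pairs(conf, PairClass.INTER_DIMER)
    return pairs
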