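"""Configuration-driven orchestration of the two experiments: PCA
detectable-signal counting and distributed source localization, both
comparing scalp-potential (EEG) against electric-field (EFEG) sensing on the
same simulated cortical sources.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd
import yaml

from . import forward_bem, inverse, metrics, signal_count
from .experiment_data import (
    FIELD_KINDS,
    PCA_STANDOFFS,
    build_data_matrix,
    build_source_space,
    calibrate_amplitude,
    dipole_gain_matrix,
    make_montage,
    patch_gain,
)
from .forward_spherical import default_head_model
from .geometry import synthetic_cortex

__all__ = ["ExperimentConfig", "run_pca_experiment", "run_localization_experiment", "report"]

log = logging.getLogger("efeg")


@dataclasses.dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    model: str = "spherical"  # "spherical" | "bem"
    cortex_subdivision: int = 5
    cortex_base_radius: float = 0.066
    fold_amplitude: float = 0.008
    fold_wavenumber: int = 12
    n_sensors: int = 128
    field_kinds: tuple = FIELD_KINDS
    pca_standoffs: tuple = PCA_STANDOFFS
    localization_standoffs: tuple = (0.0,)
    threshold_band: tuple = signal_count.DEFAULT_THRESHOLD_BAND
    n_thresholds: int = 25
    solvers: tuple = ("harmony",)
    basis_order: int = 64
    lambda_grid: tuple = tuple(float(x) for x in np.logspace(-3, 3, 7))
    n_localization_patches: int = 500
    n_tune_patches: int = 200
    mask_alpha: float = 0.05
    n_top: int = 37
    bem_level: int = 3
    seed: int = 0

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _prepare_out(config: ExperimentConfig, out_dir, force: bool) -> pathlib.Path | None:
    if out_dir is None:
        return None
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "config.yaml"
    if marker.exists():
        old = ExperimentConfig.from_yaml(marker.read_text())
        if old.content_hash() != config.content_hash() and not force:
            raise RuntimeError(
                f"output dir {out} holds artifacts for config "
                f"{old.content_hash()}, not {config.content_hash()}; "
                "pass force=True to overwrite"
            )
    marker.write_text(config.to_yaml())
    return out


def _stage(name: str, t0: float, config: ExperimentConfig) -> float:
    t1 = time.perf_counter()
    log.info("stage=%s config=%s seed=%d wall=%.2fs", name, config.content_hash(), config.seed, t1 - t0)
    return t1


def build_simulation(config: ExperimentConfig) -> dict:
    """Shared first stage: cortex, source space, head model, calibrated
    scalp-potential gain."""
    t0 = time.perf_counter()
    cortex = synthetic_cortex(
        base_radius=config.cortex_base_radius,
        fold_amplitude=config.fold_amplitude,
        wavenumber=config.fold_wavenumber,
        seed=config.seed,
        subdivision=config.cortex_subdivision,
    )
    patches = build_source_space(cortex)
    t0 = _stage("cortex+patches", t0, config)
    if config.model == "spherical":
        model = default_head_model()
    elif config.model == "bem":
        meshes = forward_bem.spherical_shell_meshes(level=config.bem_level)
        model = forward_bem.assemble_bem(meshes)
    else:
        raise ValueError(f"unknown model {config.model!r}")
    montage_v = make_montage(config.n_sensors, 0.0, ("V",), allow_any_count=True)
    gain_dip_v = dipole_gain_matrix(model, cortex, montage_v)
    gain_v = patch_gain(model, cortex, patches, montage_v, dipole_gain=gain_dip_v)
    amplitude = calibrate_amplitude(gain_v)
    _stage("potential-gain+calibration", t0, config)
    return {
        "cortex": cortex,
        "patches": patches,
        "model": model,
        "montage_v": montage_v,
        "gain_dip_v": gain_dip_v,
        "gain_v": gain_v,
        "amplitude": amplitude,
    }


def run_pca_experiment(
    config: ExperimentConfig,
    out_dir: str | pathlib.Path | None = None,
    force: bool = False,
    sim: dict | None = None,
) -> dict:
    """Data matrices -> covariances -> normalized spectra -> detectable-signal
    counts and field/potential ratios, per montage and standoff."""
    out = _prepare_out(config, out_dir, force)
    if sim is None:
        sim = build_simulation(config)
    cortex, patches, model = sim["cortex"], sim["patches"], sim["model"]
    amplitude = sim["amplitude"]
    thresholds = signal_count.threshold_grid(config.threshold_band, config.n_thresholds)

    t0 = time.perf_counter()
    dm_v = build_data_matrix(model, cortex, patches, sim["montage_v"], amplitude, gain=sim["gain_v"])
    spec_v = signal_count.eigenspectrum(signal_count.covariance(dm_v), label="V", standoff=0.0)
    spectra = {("V", 0.0): spec_v}
    ratio_frames = []
    field_kinds = tuple(config.field_kinds)
    if config.model == "bem":
        field_kinds = tuple(k for k in field_kinds if k != "E_r")
    standoffs = config.pca_standoffs if config.model == "spherical" else (0.0,)
    t0 = _stage("pca-potential", t0, config)
    for standoff in standoffs:
        montage_f = make_montage(config.n_sensors, standoff, field_kinds, allow_any_count=True)
        dm_f = build_data_matrix(model, cortex, patches, montage_f, amplitude)
        spec_f = signal_count.eigenspectrum(
            signal_count.covariance(dm_f), label="E", standoff=standoff
        )
        spectra[("E", standoff)] = spec_f
        frame = signal_count.signal_ratio_curve(spec_f, spec_v, thresholds)
        frame["standoff"] = standoff
        frame["montage"] = montage_f.montage_id
        ratio_frames.append(frame)
        t0 = _stage(f"pca-field@{standoff}", t0, config)
    ratios = pd.concat(ratio_frames, ignore_index=True)
    scalp = ratios[ratios["standoff"] == 0.0]
    max_ratio = float(np.nanmax(scalp["ratio"])) if len(scalp) else float("nan")

    if out is not None:
        ratios.to_csv(out / "signal_ratios.csv", index=False)
        rows = []
        for (label, standoff), spec in spectra.items():
            for i, v in enumerate(spec.values):
                rows.append({"montage": label, "standoff": standoff, "rank": i + 1, "eigenvalue": v})
        pd.DataFrame(rows).to_csv(out / "eigenspectra.csv", index=False)
    return {"spectra": spectra, "ratios": ratios, "max_ratio_scalp": max_ratio}


def _arm_data(config, sim, channel_type: str, standoff: float):
    """Dipole gain, patch data and noise template of one localization arm;
    potential channels are average-referenced (gain and data alike)."""
    cortex, patches, model = sim["cortex"], sim["patches"], sim["model"]
    if channel_type == "V":
        montage = sim["montage_v"]
        gain_dip = inverse.average_reference(sim["gain_dip_v"])
    else:
        kinds = tuple(config.field_kinds)
        if config.model == "bem":
            kinds = tuple(k for k in kinds if k != "E_r")
        montage = make_montage(config.n_sensors, standoff, kinds, allow_any_count=True)
        gain_dip = dipole_gain_matrix(model, cortex, montage)
    data = patch_gain(model, cortex, patches, montage, dipole_gain=gain_dip) * sim["amplitude"]
    C = signal_count.covariance(data)
    eps = inverse.DEFAULT_EPSILON_FRACTION * np.trace(C) / C.shape[0]
    template = C + eps * np.eye(C.shape[0])
    return montage, gain_dip, data, template


def run_localization_experiment(
    config: ExperimentConfig,
    out_dir: str | pathlib.Path | None = None,
    force: bool = False,
    sim: dict | None = None,
    ground_truth_injection: bool = False,
) -> dict:
    """Tune lambda per arm, solve a seeded patch subsample, probability-mask,
    score with the extent-corrected geodesic error, and compare arms."""
    out = _prepare_out(config, out_dir, force)
    if sim is None:
        sim = build_simulation(config)
    cortex, patches = sim["cortex"], sim["patches"]
    rng = np.random.default_rng(config.seed + 1)
    n_score = min(config.n_localization_patches, len(patches))
    score_idx = (
        rng.choice(len(patches), size=n_score, replace=False)
        if n_score < len(patches)
        else np.arange(len(patches))
    )
    score_patches = [patches[i] for i in score_idx]
    cache = metrics.GeodesicCache(cortex)
    extents = {p.patch_id: metrics.patch_extent(p, cortex, cache) for p in score_patches}

    basis = None
    if "harmony" in config.solvers:
        basis = inverse.laplacian_basis(cortex, config.basis_order)

    results: dict[tuple[str, str, float], list[metrics.LocalizationResult]] = {}
    arms = [("V", 0.0)] + [("E", s) for s in config.localization_standoffs]
    t0 = time.perf_counter()
    for channel_type, standoff in arms:
        montage, gain, data, template = _arm_data(config, sim, channel_type, standoff)
        t0 = _stage(f"gain-{channel_type}@{standoff}", t0, config)
        for solver in config.solvers:
            if ground_truth_injection:
                n_dipoles = 2 * len(cortex.right.vertices)
                masked = np.zeros((n_dipoles, n_score))
                for j, p in enumerate(score_patches):
                    masked[p.members, j] = 1.0
            else:
                lam, _ = inverse.tune_lambda(
                    gain,
                    template,
                    data,
                    patches,
                    cortex,
                    solver=solver,
                    lambda_grid=config.lambda_grid,
                    basis=basis if solver == "harmony" else None,
                    n_sample=config.n_tune_patches,
                    seed=config.seed + 2,
                    n_top=config.n_top,
                    source_scale=sim["amplitude"],
                )
                t0 = _stage(f"tune-{solver}-{channel_type}@{standoff} lambda={lam:g}", t0, config)
                noise = inverse.NoiseCovariance(lam * template, epsilon=0.0, lambda_scale=lam)
                op = inverse.make_inverse_operator(
                    gain, noise, solver,
                    basis=basis if solver == "harmony" else None,
                    source_scale=sim["amplitude"],
                )
                sols = op.W @ data[:, score_idx]
                std = op.dipole_std()
                masked = np.empty_like(sols)
                for j in range(n_score):
                    sol = inverse.InverseSolution(sols[:, j], solver, lam)
                    masked[:, j] = inverse.probability_mask(
                        sol, std, config.mask_alpha, n_comparisons=montage.n_channels
                    ).amplitudes
            arm_results = [
                metrics.score_patch(
                    masked[:, j], p, cortex, cache, solver, channel_type, standoff,
                    n_top=config.n_top, extent=extents[p.patch_id],
                )
                for j, p in enumerate(score_patches)
            ]
            results[(solver, channel_type, standoff)] = arm_results
            t0 = _stage(f"score-{solver}-{channel_type}@{standoff}", t0, config)

    summaries = {}
    for solver in config.solvers:
        for standoff in config.localization_standoffs:
            cmp = metrics.compare_channels(
                results[(solver, "V", 0.0)], results[(solver, "E", standoff)]
            )
            summaries[(solver, standoff)] = cmp

    if out is not None:
        frames = [metrics.results_frame(r) for r in results.values()]
        pd.concat(frames, ignore_index=True).to_csv(out / "localization_results.csv", index=False)
        rows = []
        for (solver, standoff), cmp in summaries.items():
            rows.append(
                {
                    "solver": solver,
                    "standoff": standoff,
                    "median_potential_m": cmp["median_potential"],
                    "median_field_m": cmp["median_field"],
                    "median_ratio": cmp["median_ratio"],
                    "fraction_below_diagonal": cmp["fraction_below_diagonal"],
                }
            )
        pd.DataFrame(rows).to_csv(out / "localization_summary.csv", index=False)
        for (solver, channel_type, standoff), r in results.items():
            cdf = metrics.error_cdf(r)
            cdf.to_csv(out / f"cdf_{solver}_{channel_type}_{standoff:g}.csv", index=False)
    return {"results": results, "summaries": summaries, "score_idx": score_idx}


def report(out_dirs: list[str | pathlib.Path], path: str | pathlib.Path | None = None) -> str:
    """Markdown summary of the experiment outputs found in ``out_dirs``;
    missing artifacts are listed rather than fatal.  Regeneration from the
    same outputs is idempotent."""
    lines = ["# EFEG simulation report", ""]
    for d in out_dirs:
        d = pathlib.Path(d)
        lines.append(f"## {d}")
        cfg = d / "config.yaml"
        if cfg.exists():
            h = ExperimentConfig.from_yaml(cfg.read_text()).content_hash()
            lines.append(f"- config hash: `{h}`")
        else:
            lines.append("- config.yaml: missing (not run)")
        ratios = d / "signal_ratios.csv"
        if ratios.exists():
            df = pd.read_csv(ratios)
            scalp = df[df["standoff"] == 0.0]
            if len(scalp):
                lines.append(
                    f"- max field/potential signal-count ratio on the scalp: "
                    f"{np.nanmax(scalp['ratio']):.2f}"
                )
        else:
            lines.append("- signal_ratios.csv: missing (not run)")
        summ = d / "localization_summary.csv"
        if summ.exists():
            df = pd.read_csv(summ)
            for _, row in df.iterrows():
                lines.append(
                    f"- {row['solver']} @ {row['standoff']:g} m: median error "
                    f"V={100 * row['median_potential_m']:.2f} cm, "
                    f"E={100 * row['median_field_m']:.2f} cm, "
                    f"ratio={row['median_ratio']:.2f}"
                )
        else:
            lines.append("- localization_summary.csv: missing (not run)")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        pathlib.Path(path).write_text(text)
    return text
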