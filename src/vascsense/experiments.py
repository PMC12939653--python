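"""Configuration-driven experiment drivers tying the modules together.

A single :class:`ExperimentConfig` collects every module's settings (and all
seeds); :func:`run_single` executes the configured reconstruction methods on
one seeded phantom and returns per-method quality and topology metrics;
:func:`run_benchmark` loops seeds and aggregates.  The command-line interface
wraps these functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as qm
from .acquisition import PolicyConfig, poisson_disc_mask, run_closed_loop
from .core import ImageVolume, KSpaceMeasurement
from .crossscale import MesoParams, MicroParams
from .phantom import (NoiseModel, PhantomSpec, apply_motion_perturbation,
                      generate_vascular_phantom, simulate_kspace)
from .recon import (HankelConfig, PartialFourierConfig, ReconConfig,
                    TopoRegConfig, cs_reconstruct, reconstruct_full,
                    stochastic_realizations, weighted_reconstruct)
from .sensors import (confidence_weights, generate_streams, instability_score,
                      preprocess, synchronize)
from .topology import (TopologyConfig, TopologySummary, betti_deviation,
                       branch_completeness, diagrams_from_image,
                       persistence_stability, topology_uncertainty)

__all__ = ["ExperimentConfig", "run_single", "run_benchmark",
            "sensor_line_weights", "generate_fixtures"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything a reproducible experiment needs, seeds included."""

    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec(
        grid_shape=(96, 96), n_main_branches=5, n_collateral_loops=2,
        branch_contrast=6.0))
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(
        kspace_noise_sigma=0.06))
    accel_target: float = 0.70
    center_fraction: float = 0.08
    min_radius: float = 1.2
    recon: ReconConfig = field(default_factory=lambda: ReconConfig(
        lambda_reg=1e-2, max_iterations=80))
    policy: PolicyConfig = field(default_factory=lambda: PolicyConfig(
        candidate_count=2, batch_size=128, surrogate_iterations=15,
        n_realizations_for_U=2, candidate_profiles=("spectrum",)))
    topo: TopologyConfig = field(default_factory=TopologyConfig)
    meso: MesoParams = field(default_factory=MesoParams)
    micro: MicroParams = field(default_factory=MicroParams)
    budget: int = 6
    ensemble_k: int = 3
    perturb_scale: float = 1.0
    adaptive: bool = True
    hankel: bool = True
    pf_init: bool = False
    topo_reg: bool = True
    sensors: bool = False
    seed: int = 0

    def full_recon_cfg(self) -> ReconConfig:
        return replace(
            self.recon,
            hankel=HankelConfig(enabled=self.hankel),
            pf=PartialFourierConfig(enabled=self.pf_init,
                                    phase_band_fraction=self.center_fraction),
            topo=TopoRegConfig(enabled=self.topo_reg),
        )

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _topology_row(recon: ImageVolume, truth, ensemble, cfg: ExperimentConfig):
    (d0, d1), g = diagrams_from_image(recon, cfg.topo)
    u = topology_uncertainty(ensemble, (d0, d1), cfg.topo)
    stab = persistence_stability(ensemble, (d0, d1), cfg=cfg.topo)
    dbeta = betti_deviation(g, truth)
    bc = branch_completeness(g, truth) if g.n_edges else 0.0
    summary = TopologySummary(u, dbeta, bc, stab)
    return summary


def run_single(cfg: ExperimentConfig, methods=("cs", "full")) -> pd.DataFrame:
    """Run the configured methods on one seeded phantom.

    ``cs``        static Poisson-disc mask + plain CS (sparsity only);
    ``cs_priors`` same mask, full reconstructor (priors, no adaptivity);
    ``full``      adaptive closed loop at matched final acceleration;
    ``random``    closed loop with random action selection (control).
    """
    img, truth = generate_vascular_phantom(cfg.phantom)
    ks = simulate_kspace(img, cfg.noise, seed=cfg.seed + 1)
    n_pe = ks.shape[0]
    motion_block = (int(0.25 * n_pe), int(0.50 * n_pe))  # sequential order
    if cfg.noise.motion_shift_mm > 0:
        ks = apply_motion_perturbation(ks, cfg.noise.motion_shift_mm, 0.25,
                                       seed=cfg.seed + 2,
                                       start_line=motion_block[0])
    total = int(np.prod(cfg.phantom.grid_shape))
    rows = []
    t0 = time.perf_counter()

    static_mask = poisson_disc_mask(
        cfg.phantom.grid_shape, cfg.accel_target, cfg.min_radius,
        cfg.center_fraction, seed=cfg.seed + 3)
    y_static = ks.restrict(static_mask)

    def add_row(method, recon, mask, ensemble):
        summary = _topology_row(recon, truth, ensemble, cfg)
        rows.append({
            "method": method,
            "seed": cfg.seed,
            "acceleration": mask.acceleration,
            "psnr_db": qm.psnr(img, recon),
            "ssim": qm.ssim(img, recon),
            "nmse": qm.nmse(img, recon),
            "betti_deviation": summary.betti_deviation,
            "branch_completeness": summary.branch_completeness,
            "persistence_stability": summary.persistence_stability,
            "U": summary.U,
            "U_macro": summary.U_macro,
            "wall_s": time.perf_counter() - t0,
        })

    if "cs" in methods:
        recon = cs_reconstruct(y_static, cfg.recon)
        ens = stochastic_realizations(y_static, cfg.recon, cfg.ensemble_k,
                                      cfg.perturb_scale, seed=cfg.seed + 11,
                                      reconstructor=cs_reconstruct)
        add_row("cs", recon, static_mask, ens)

    if "cs_priors" in methods:
        fcfg = cfg.full_recon_cfg()
        recon = reconstruct_full(y_static, fcfg)
        ens = stochastic_realizations(y_static, fcfg, cfg.ensemble_k,
                                      cfg.perturb_scale, seed=cfg.seed + 12)
        add_row("cs_priors", recon, static_mask, ens)

    for method, selector in (("full", "uncertainty"), ("random", "random")):
        if method not in methods:
            continue
        budgeted = cfg.budget * cfg.policy.batch_size
        a0 = cfg.accel_target + budgeted / total
        if a0 >= 0.98:
            raise ValueError("budget exceeds the k-space that is left")
        init_mask = poisson_disc_mask(
            cfg.phantom.grid_shape, a0, cfg.min_radius, cfg.center_fraction,
            seed=cfg.seed + 3)
        fcfg = cfg.full_recon_cfg()
        pol = replace(cfg.policy, seed=cfg.seed + 17)
        final_mask, recon, log = run_closed_loop(
            ks, init_mask, cfg.budget, fcfg, pol, cfg.topo, truth,
            tol_rel=None, action_selector=selector)
        y_final = ks.restrict(final_mask)
        ens = stochastic_realizations(y_final, fcfg, cfg.ensemble_k,
                                      cfg.perturb_scale, seed=cfg.seed + 13)
        add_row(method, recon, final_mask, ens)

    if cfg.sensors and cfg.noise.motion_shift_mm > 0:
        weights = sensor_line_weights(ks, seed=cfg.seed + 2)
        recon = weighted_reconstruct(y_static, weights, cfg.recon)
        ens = stochastic_realizations(
            y_static, cfg.recon, cfg.ensemble_k, cfg.perturb_scale,
            seed=cfg.seed + 14,
            reconstructor=lambda y, c: weighted_reconstruct(y, weights, c))
        add_row("cs_sensor_weighted", recon, static_mask, ens)

    return pd.DataFrame(rows)


def sensor_line_weights(ks: KSpaceMeasurement, seed: int,
                        line_time_s: float = 0.05,
                        burst=(0.25, 0.50)) -> np.ndarray:
    """Per-phase-encode-line confidence weights from simulated sensors.

    Emulates a scan in which lines are acquired sequentially at
    ``line_time_s`` per line while an instability epoch (motion burst)
    occupies the ``burst`` fraction of the scan.  Returns a full-grid weight
    array in which every sample of a readout shares its line's weight.
    """
    n_lines = ks.shape[0]
    duration = n_lines * line_time_s
    schedule = [(burst[0] * duration, burst[1] * duration)]
    streams = [preprocess(s) for s in generate_streams(
        duration, schedule, seed=seed, channels=("ecg", "resp", "gradient"))]
    readout_t = (np.arange(n_lines) + 0.5) * line_time_s
    state, _ = synchronize(streams, readout_t)
    score = instability_score(state)
    w_line = confidence_weights(score)
    w = np.ones(ks.shape)
    w *= w_line.reshape((-1,) + (1,) * (len(ks.shape) - 1))
    return w


def run_benchmark(cfg: ExperimentConfig, n_seeds: int,
                  methods=("cs", "full")) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Loop ``run_single`` across seeds; aggregate mean/SD per method.

    Partial failures are logged as rows with ``error`` set and skipped in the
    aggregate.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    frames, failures = [], []
    for s in range(n_seeds):
        c = replace(cfg, seed=cfg.seed + s,
                    phantom=replace(cfg.phantom, seed=cfg.phantom.seed + s))
        try:
            frames.append(run_single(c, methods))
        except Exception as exc:  # noqa: BLE001 - keep the benchmark running
            failures.append({"seed": c.seed, "error": repr(exc)})
    per_run = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if failures:
        per_run.attrs["failures"] = failures
    if per_run.empty:
        return per_run, per_run
    numeric = per_run.select_dtypes("number").columns.drop("seed")
    agg = per_run.groupby("method")[list(numeric)].agg(["mean", "std"])
    return per_run, agg


def generate_fixtures(cfg: ExperimentConfig, outdir):
    """Write phantom, k-space, mask and sensor fixtures plus a manifest."""
    from pathlib import Path

    from . import io as vio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    img, truth = generate_vascular_phantom(cfg.phantom)
    ks = simulate_kspace(img, cfg.noise, seed=cfg.seed + 1)
    mask = poisson_disc_mask(cfg.phantom.grid_shape, cfg.accel_target,
                             cfg.min_radius, cfg.center_fraction,
                             seed=cfg.seed + 3)
    files = {}
    vio.save_image_nifti(img, out / "phantom.nii.gz")
    files["phantom.nii.gz"] = "phantom image"
    from .crossscale import annotate_conductances
    vio.save_graph_graphml(annotate_conductances(truth),
                           out / "truth_graph.graphml")
    files["truth_graph.graphml"] = "ground-truth vascular graph"
    vio.save_kspace_h5(ks, out / "kspace.h5")
    files["kspace.h5"] = "simulated k-space"
    vio.save_mask_h5(mask, out / "mask.h5", seed=cfg.seed + 3)
    files["mask.h5"] = "static Poisson-disc mask"
    streams = generate_streams(10.0, [(3.0, 5.0)], seed=cfg.seed)
    for s in streams:
        vio.save_stream_csv(s, out / f"sensor_{s.channel}.csv")
        files[f"sensor_{s.channel}.csv"] = f"{s.channel} stream"
    manifest = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                "files": files}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
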