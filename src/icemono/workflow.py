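"""Run configuration, seeding, and the end-to-end demo pipeline.

A run is fully determined by its configuration (plain key-value YAML, all
tunables defaulted to the package's documented choices) and its seed; every
output table carries the config hash and seed in a comment header, and
re-running an identical configuration reproduces identical numeric output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import assay_stats, interface, nucleation, order_params, synthetic_data
from .synthetic_data import ThermalState


def compute_supercooling(state: ThermalState) -> float:
    """S = T_M − T (K)."""
    return state.supercooling


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults."""

    seed: int = 0
    stages: tuple = ("assay", "isotherm", "orientation", "profile")
    # neighbour graph / order parameters
    oo_cutoff: float = 3.5          # Å, first minimum of the water O–O correlation
    steinhardt_l: int = 6
    variant: str = "locally_averaged_q"
    calibration_noise: float = 0.15  # Å, thermal noise of the ice calibration fixture
    min_neighbors: int = 4           # coordination floor for ice-like molecules
    # profile
    bin_width: float = 0.5           # Å
    baseline_halfwidth: float = 5.0  # Å, central slab window
    interface_halfwidth: float = 5.0  # Å around the hydroxyl plane
    profile_frames: int = 40
    profile_waters: int = 260
    nucleus_size: int = 30
    # isotherm
    gamma_water_vacuum: float = 80.1  # mN/m
    block_count: int = 5
    ptrace_samples: int = 4000
    l_z: float = 200.0               # Å
    # assay
    n_droplets: int = 96
    t_start: float = 0.0
    t_end: float = -30.0
    cooling_rate: float = 1.0        # K/min
    assay_bin_width: float = 0.5     # K
    mc_draws: int = 1000
    percentiles: tuple = (10.0, 90.0)
    molecules_per_droplet: float = 1e15
    # monolayer
    n_chl: int = 64
    s_a_per_mol: float = 70.0
    tilt_mean: float = 30.0
    tilt_kappa: float = 60.0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        d["percentiles"] = list(d["percentiles"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "percentiles" in d:
            d["percentiles"] = tuple(d["percentiles"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _header(config: RunConfig, stage: str, extra: dict | None = None) -> str:
    meta = {"stage": stage, "config_hash": config.config_hash, "seed": config.seed}
    meta.update(extra or {})
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def calibrate_default_threshold(config: RunConfig | None = None, seed: int | None = None) -> float:
    """Calibrate the ice/liquid q̄6 threshold on generated fixtures: a noisy
    ideal-Ic lattice against a random liquid slab."""
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    ice = synthetic_data.build_ice_lattice("Ic", (2, 2, 2),
                                           noise_sigma=config.calibration_noise, seed=seed)
    g_ice = order_params.neighbor_list(ice, config.oo_cutoff, method="brute")
    q_ice = order_params.local_average_q(
        order_params.steinhardt_q(g_ice, l=config.steinhardt_l), g_ice)
    box = np.array([22.0, 22.0, 22.0])
    liq = synthetic_data.build_liquid_slab(360, box, min_dist=2.45, seed=seed + 1)
    from .trajectory_io import infer_topology

    oxy = infer_topology(liq).water_oxygens
    g_liq = order_params.neighbor_list(liq, config.oo_cutoff, method="brute", subset=oxy)
    q_liq = order_params.local_average_q(
        order_params.steinhardt_q(g_liq, l=config.steinhardt_l), g_liq)
    # calibrate on molecules that satisfy the classifier's coordination floor
    sel_i = q_ice.neighbor_counts >= config.min_neighbors
    sel_l = q_liq.neighbor_counts >= config.min_neighbors
    return order_params.calibrate_threshold(q_ice.q[sel_i], q_liq.q[sel_l])


# --------------------------------------------------------------------------- #
# stages
# --------------------------------------------------------------------------- #


def _stage_assay(config: RunConfig, outdir: Path) -> dict:
    def site_density(t):
        return 0.0 if t > -8.0 else 2e-15 * (np.exp(0.45 * (-8.0 - t)) - 1.0)

    truth = synthetic_data.AssayGroundTruth(
        site_density_fn=site_density,
        molecules_per_droplet=config.molecules_per_droplet,
        t_start=config.t_start, t_end=config.t_end,
        cooling_rate=config.cooling_rate, n_droplets=config.n_droplets,
        bin_width=config.assay_bin_width, seed=config.seed)
    assay = synthetic_data.simulate_freezing_assay(truth)
    curve = assay_stats.poisson_mc_ci(assay, config.assay_bin_width, config.mc_draws,
                                      config.percentiles, seed=config.seed + 1)
    import pandas as pd

    df = pd.DataFrame({
        "temperature_C": curve.grid,
        "fraction_frozen": curve.fraction_frozen,
        "n_mol": curve.n_mol,
        "ci_lower": curve.ci_lower,
        "ci_upper": curve.ci_upper,
        "true_n_mol": truth.true_nmol(curve.grid),
    })
    path = outdir / "assay_nmol.csv"
    with open(path, "w") as fh:
        fh.write(_header(config, "assay", {"n_droplets": config.n_droplets,
                                           "mc_draws": config.mc_draws}))
        df.to_csv(fh, index=False)
    inside = ((df.true_n_mol >= df.ci_lower) & (df.true_n_mol <= df.ci_upper))
    ok = inside[~df.n_mol.isna()]
    return {"band_coverage_of_truth": float(ok.mean()) if len(ok) else float("nan"),
            "n_frozen": int((~assay.records.censored).sum())}


def _stage_isotherm(config: RunConfig, outdir: Path) -> dict:
    rows = []
    for k, (s_a, gamma_true) in enumerate([(70.0, 38.0), (40.0, 25.0), (30.0, 5.0)]):
        p_zz = 2.0 * gamma_true / 0.01 / config.l_z
        trace, g_known = synthetic_data.generate_pressure_trace(
            0.0, 0.0, p_zz, sigma=120.0, n_samples=config.ptrace_samples,
            l_z=config.l_z, seed=config.seed + 10 + k)
        res = interface.surface_tension(trace, config.block_count,
                                        config.gamma_water_vacuum)
        rows.append((s_a, res.gamma, res.gamma_se, res.pi, res.pi_se, g_known))
    import pandas as pd

    df = pd.DataFrame(rows, columns=["s_a_per_mol", "gamma", "gamma_se", "pi",
                                     "pi_se", "gamma_true"])
    path = outdir / "isotherm.csv"
    with open(path, "w") as fh:
        fh.write(_header(config, "isotherm", {"gamma_water_vacuum": config.gamma_water_vacuum}))
        df.to_csv(fh, index=False)
    return {"max_gamma_error_se": float(np.max(np.abs(df.gamma - df.gamma_true) /
                                               np.maximum(df.gamma_se, 1e-12)))}


def _stage_orientation(config: RunConfig, outdir: Path) -> dict:
    cfg, topo, truth = synthetic_data.build_monolayer_slab(
        config.n_chl, config.s_a_per_mol, config.tilt_mean, config.tilt_kappa,
        water_params={"n_molecules": 350}, seed=config.seed + 20)
    dist, theta = interface.tilt_angles(cfg, topo)
    sel = interface.select_interfacial_water(cfg, topo)
    ddist, _ = interface.dipole_angles(cfg, topo, "water_dipole", subset=sel)
    import pandas as pd

    df = pd.DataFrame({"theta_deg": dist.bin_centers, "tilt_density": dist.density,
                       "water_dipole_density": ddist.density})
    path = outdir / "orientation.csv"
    with open(path, "w") as fh:
        fh.write(_header(config, "orientation", {"s_a_per_mol": config.s_a_per_mol}))
        df.to_csv(fh, index=False)
    return {"mean_tilt_deg": float(np.mean(theta)),
            "true_tilt_deg": float(config.tilt_mean),
            "n_interfacial_waters": int(len(sel))}


def _stage_profile(config: RunConfig, outdir: Path) -> dict:
    box = np.array([24.0, 24.0, 60.0])
    base = synthetic_data.build_liquid_slab(config.profile_waters, box, min_dist=2.5,
                                            seed=config.seed + 30,
                                            z_range=(10.0, 50.0))
    mid = 30.0

    step = 8.0  # folded distance from the midplane where the planted density jumps

    def density(z):
        return 10.0 if abs(z - mid) > step else 1.0

    traj, truths = synthetic_data.plant_nuclei_trajectory(
        base, config.nucleus_size, density, config.profile_frames,
        seed=config.seed + 31)
    thr = calibrate_default_threshold(config)
    com = nucleation.trajectory_largest_nucleus_comz(
        traj, config.oo_cutoff, config.steinhardt_l, thr, config.variant)
    zeta_max = np.nanmax(np.abs(com - mid))
    profile = nucleation.com_z_profile(
        com, config.bin_width, fold=True, midplane=mid,
        baseline_window=(0.0, config.baseline_halfwidth),
        interface_window=(step + config.bin_width / 2, zeta_max + config.bin_width))
    import pandas as pd

    df = pd.DataFrame({"z_aligned": profile.aligned_centers, "counts": profile.counts,
                       "density": profile.density})
    path = outdir / "comz_profile.csv"
    with open(path, "w") as fh:
        fh.write(_header(config, "profile", {"threshold": round(thr, 6),
                                             "frames": config.profile_frames}))
        df.to_csv(fh, index=False)
    ratio = nucleation.interfacial_enhancement(profile)
    return {"enhancement_ratio": float(ratio), "threshold": float(thr),
            "frames_detected": int(np.sum(~np.isnan(com)))}


_STAGES = {
    "assay": _stage_assay,
    "isotherm": _stage_isotherm,
    "orientation": _stage_orientation,
    "profile": _stage_profile,
}


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages in order into ``outdir``; returns a
    summary dict (also written as JSON).  A stage failure aborts the run
    with the failing stage named."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(config.to_yaml())
    summary = {"config_hash": config.config_hash, "seed": config.seed}
    for stage in config.stages:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r} (have {sorted(_STAGES)})")
        try:
            summary[stage] = _STAGES[stage](config, outdir)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
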