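"""End-to-end orchestration of the synthetic photoactivation study.

Three runnable campaigns, mirroring the experimental workflows:

``run_photoactivation_pipeline``
    generate per-excitation absorption time series -> global fit of
    (k1, k2) and EADS per replicate -> power/probe-rate correction ->
    action-spectrum assembly with bootstrap CIs -> oscillator-strength
    normalization -> recovery report of the generating yield modulation.

``run_anisotropy_pipeline``
    polarized fluorescence pairs over a temperature ramp -> Raman-masked
    anisotropy averages -> TDM angles -> logistic temperature-onset fit;
    in parallel, initial photoactivation rates over the same ramp ->
    onset fit and Arrhenius activation energy above the onset.

``run_fes_pipeline``
    three-well bicycle-pedal landscape -> well-tempered metadynamics on
    a depth-scaled copy (desk-scale sampling) -> free-energy
    reconstruction -> minima and minimax barriers, alongside the exact
    analytic analysis of the full-depth preset.

All stages draw their randomness from per-stage child seeds derived by
stable hashing from the single run seed, so reruns with the same
config and seed are byte-identical and stages can be rerun in
isolation.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from . import action as action_mod
from . import anisotropy as aniso_mod
from . import kinetics, metad, synthetic
from .spectra import Spectrum, resample, to_abs_oscillator_strength

__all__ = [
    "ConfigError",
    "DEFAULT_CONFIG",
    "load_config",
    "child_seed",
    "run_photoactivation_pipeline",
    "run_anisotropy_pipeline",
    "run_fes_pipeline",
]


class ConfigError(ValueError):
    """Raised when a run configuration is malformed."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "photoactivation": {
        "excitation_points": [19800.0, 20400.0, 21000.0, 21600.0, 22200.0, 22800.0, 23400.0],
        "n_replicates": 3,
        "noise_sd": 0.003,
        "k1_peak": 0.01,        # s^-1 at the f_abs maximum, unit yield
        "k2_peak": 0.002,
        "yield_center": 21000.0,  # sigmoidal yield modulation g(nu)
        "yield_width": 1200.0,
        "yield_floor": 0.35,
        "n_times": 36,
        "powers": [130.0, 80.0, 30.0],  # uW, cycled over excitation points
        "reference_power": 130.0,
        "probe_only_rate": 0.0002,
        "n_boot": 2000,
    },
    "anisotropy": {
        "temperatures": list(np.arange(180.0, 315.0, 5.0)),
        "t_on": 240.0,
        "onset_width": 8.0,
        "theta_lo": 15.0,
        "theta_hi": 48.0,
        "noise_sd": 0.0005,
        "excitation_wavenumber": 23250.0,
        "raman_shifts": [1517.0, 1157.0],
        "rate_prefactor": 100.0,
        "rate_ea": 8.5,
        "rate_noise_frac": 0.05,
        "arrhenius_margin": 2.0,   # exclude T < t_on + margin*onset_width
    },
    "fes": {
        "depth_scale": 0.2,
        "n_steps": 160000,
        "hill_width": 8.0,
        "h0": 0.06,
        "deposit_interval": 0.5,
        "kb_delta_t": 20.0,
        "temperature": 300.0,
        "friction": 0.02,
        "dt": 0.1,
        "grid_spacing": 2.0,
        "min_prominence": 1.0,     # kcal/mol, filters bias-ripple minima
    },
}


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2^31) derived from the run seed."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def load_config(source=None) -> dict:
    """Build a validated run config from a YAML path, dict, or defaults.

    Sections and keys are checked against the schema; an unknown key or
    a non-mapping section raises :class:`ConfigError` naming it.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = copy.deepcopy(dict(source))
    for section, value in user.items():
        if section == "seed":
            cfg["seed"] = int(value)
            continue
        if section not in cfg:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(value, dict):
            raise ConfigError(f"config section {section!r} must be a mapping")
        for key, v in value.items():
            if key not in cfg[section]:
                raise ConfigError(f"unknown key {key!r} in config section {section!r}")
            cfg[section][key] = v
    return cfg


def _require_section(config: dict, name: str) -> dict:
    if name not in config or not isinstance(config[name], dict):
        raise ConfigError(f"missing config section {name!r}")
    return config[name]


def _emission_shape(grid=None) -> Spectrum:
    """Generic canthaxanthin-like fluorescence band for the anisotropy stage."""
    if grid is None:
        grid = np.arange(14000.0, 24000.0, 10.0)
    values = np.exp(-((grid - 19800.0) ** 2) / (2 * 1300.0**2))
    return Spectrum(grid, values, kind="emission")


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    path.write_text(json.dumps(payload, indent=2, default=default, allow_nan=True))


# ---------------------------------------------------------------------------
# photoactivation campaign


def run_photoactivation_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Generate, fit, correct, assemble and normalize the action spectra.

    Returns a report with the per-excitation fitted and corrected rates,
    the two action spectra with bootstrap CIs, the yield-like ratios
    k_i/f_abs, and the RMS recovery error of the generating yield
    modulation g(nu) (both ratios share the same g by construction).
    """
    config = config if config is not None else load_config()
    cfg = _require_section(config, "photoactivation")
    seed = child_seed(config.get("seed", 0), "photoactivation")
    rng = np.random.default_rng(seed)

    grid = synthetic.default_grid()
    presets = synthetic.ocp_species_presets()
    basis = [synthetic.make_vibronic_spectrum(presets[s], grid) for s in ("OCPO", "OCPI", "OCPR")]
    f_abs = {
        "OCPO": to_abs_oscillator_strength(basis[0]),
        "OCPI": to_abs_oscillator_strength(basis[1]),
    }

    nus = np.asarray(cfg["excitation_points"], dtype=float)
    g_true = cfg["yield_floor"] + (1.0 - cfg["yield_floor"]) * expit(
        (nus - cfg["yield_center"]) / cfg["yield_width"]
    )
    fits = {1: {}, 2: {}}
    per_excitation = []
    for i, nu in enumerate(nus):
        fo = float(np.interp(nu, f_abs["OCPO"].grid, f_abs["OCPO"].values))
        fi = float(np.interp(nu, f_abs["OCPI"].grid, f_abs["OCPI"].values))
        k1_true = cfg["k1_peak"] * (fo / np.max(f_abs["OCPO"].values)) * g_true[i]
        k2_true = cfg["k2_peak"] * (fi / np.max(f_abs["OCPI"].values)) * g_true[i]
        power = cfg["powers"][i % len(cfg["powers"])]
        k_slow = min(k1_true, k2_true) * power / cfg["reference_power"]
        k_fast = max(k1_true, k2_true) * power / cfg["reference_power"]
        times = np.unique(
            np.concatenate(
                [
                    np.linspace(0.0, 3.0 / k_fast, cfg["n_times"] // 2),
                    np.linspace(0.0, 4.0 / k_slow, cfg["n_times"] // 2),
                ]
            )
        )
        protocol = synthetic.IlluminationProtocol(
            excitation_wavenumber=float(nu),
            power=power,
            reference_power=cfg["reference_power"],
            probe_only_rate=cfg["probe_only_rate"],
            sample_times=tuple(times),
            noise_sd=cfg["noise_sd"],
        )
        rep_rates = {1: [], 2: []}
        for _rep in range(cfg["n_replicates"]):
            series = synthetic.simulate_photoactivation_series(
                basis,
                k1_true + cfg["probe_only_rate"],
                k2_true + cfg["probe_only_rate"],
                protocol,
                seed=int(rng.integers(2**31 - 1)),
            )
            fit = kinetics.fit_global(series, reference_eads=basis)
            probe_scaled = cfg["probe_only_rate"] * power / cfg["reference_power"]
            for step, k_raw in ((1, fit.k1), (2, fit.k2)):
                # noise can push a fitted rate below the probe floor on the
                # red edge; those points clamp to zero (and are masked by
                # the oscillator-strength floor downstream)
                k_corr = (
                    kinetics.correct_rate(
                        k_raw, power=power,
                        reference_power=cfg["reference_power"],
                        probe_only_rate=probe_scaled,
                    )
                    if k_raw >= probe_scaled
                    else 0.0
                )
                rep_rates[step].append(k_corr)
        fits[1][float(nu)] = rep_rates[1]
        fits[2][float(nu)] = rep_rates[2]
        per_excitation.append(
            {
                "nu": float(nu),
                "power_uW": power,
                "k1_true": k1_true,
                "k2_true": k2_true,
                "k1_fit_mean": float(np.mean(rep_rates[1])),
                "k2_fit_mean": float(np.mean(rep_rates[2])),
            }
        )

    spectra_out = {}
    rms_g = {}
    for step, reactant in ((1, "OCPO"), (2, "OCPI")):
        spec = action_mod.assemble_action_spectrum(
            fits[step],
            reactant=reactant,
            n_boot=cfg["n_boot"],
            seed=child_seed(seed, f"bootstrap-k{step}"),
        )
        action_mod.normalize_by_oscillator_strength(spec, f_abs[reactant])
        mask = spec.ratio_mask
        g_ref = g_true[mask] / np.mean(g_true[mask])
        ratio = spec.ratio[mask] / np.mean(spec.ratio[mask])
        rms_g[f"k{step}"] = float(np.sqrt(np.mean((ratio - g_ref) ** 2)))
        spectra_out[f"k{step}"] = spec

    report = {
        "stage": "photoactivation",
        "seed": seed,
        "per_excitation": per_excitation,
        "yield_recovery_rms": rms_g,
        "action": {
            name: {
                "nu": spec.excitation_grid,
                "k": spec.k,
                "ci_low": spec.ci_low,
                "ci_high": spec.ci_high,
                "ratio": spec.ratio,
                "ratio_mask": spec.ratio_mask.astype(int),
            }
            for name, spec in spectra_out.items()
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        _write_json(outdir / "photoactivation_report.json", report)
        import pandas as pd

        df = pd.DataFrame(
            {
                "nu_cm-1": spectra_out["k1"].excitation_grid,
                "k1": spectra_out["k1"].k,
                "k1_lo": spectra_out["k1"].ci_low,
                "k1_hi": spectra_out["k1"].ci_high,
                "k2": spectra_out["k2"].k,
                "k2_lo": spectra_out["k2"].ci_low,
                "k2_hi": spectra_out["k2"].ci_high,
                "k1_over_f": spectra_out["k1"].ratio,
                "k2_over_f": spectra_out["k2"].ratio,
            }
        )
        df.to_csv(outdir / "action_spectrum.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# anisotropy / temperature campaign


def run_anisotropy_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Temperature ramp of TDM angles and initial rates; onsets and Ea."""
    config = config if config is not None else load_config()
    cfg = _require_section(config, "anisotropy")
    seed = child_seed(config.get("seed", 0), "anisotropy")
    rng = np.random.default_rng(seed)

    temps = np.asarray(cfg["temperatures"], dtype=float)
    if temps.size == 0:
        raise ConfigError("anisotropy.temperatures must not be empty")
    theta_true = cfg["theta_lo"] + (cfg["theta_hi"] - cfg["theta_lo"]) * expit(
        (temps - cfg["t_on"]) / cfg["onset_width"]
    )
    shape = _emission_shape()
    raman = [(s, 0.5, 40.0) for s in cfg["raman_shifts"]]
    thetas = []
    for th in theta_true:
        i_ma, i_perp = synthetic.simulate_polarized_pair(
            float(th),
            shape,
            raman_lines=raman,
            excitation_wavenumber=cfg["excitation_wavenumber"],
            noise_sd=cfg["noise_sd"],
            seed=int(rng.integers(2**31 - 1)),
        )
        pair = aniso_mod.PolarizedSpectra(i_ma, i_perp, cfg["excitation_wavenumber"])
        spec = aniso_mod.anisotropy_from_magic_angle(pair)
        keep = aniso_mod.raman_mask(spec.grid, cfg["excitation_wavenumber"], cfg["raman_shifts"])
        r_avg = aniso_mod.average_anisotropy(spec, mask=keep)
        thetas.append(aniso_mod.tdm_angle_from_anisotropy(r_avg, mode="clamp"))
    thetas = np.asarray(thetas)
    onset_theta = aniso_mod.fit_temperature_onset(temps, thetas)

    model = synthetic.RateTemperatureModel(
        prefactor=cfg["rate_prefactor"], ea=cfg["rate_ea"],
        t_on=cfg["t_on"], onset_width=cfg["onset_width"],
    )
    table = synthetic.simulate_initial_rates(
        model, temps, noise_frac=cfg["rate_noise_frac"], seed=child_seed(seed, "rates")
    )
    # joint Arrhenius x logistic fit separates the onset from the
    # activated growth above it
    onset_rate = kinetics.fit_rate_onset(temps, table["rate_per_s"].to_numpy())
    t_arr = cfg["t_on"] + cfg["arrhenius_margin"] * cfg["onset_width"]
    arr = kinetics.arrhenius_fit(table["T_K"], table["rate_per_s"], t_min=t_arr)

    report = {
        "stage": "anisotropy",
        "seed": seed,
        "temperatures": temps,
        "theta_deg": thetas,
        "t_on_theta": onset_theta.t_on,
        "t_on_rate": onset_rate.t_on,
        "t_on_delta": abs(onset_theta.t_on - onset_rate.t_on),
        "ea_kcal_mol": arr.ea,
        "ea_ci": list(arr.ea_ci),
        "onset_theta": {
            "t_on": onset_theta.t_on, "width": onset_theta.width,
            "theta_lo": onset_theta.theta_lo, "theta_hi": onset_theta.theta_hi,
            "rms": onset_theta.rms,
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        _write_json(outdir / "anisotropy_report.json", report)
        table.to_csv(outdir / "initial_rates.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# free-energy-surface campaign


def run_fes_pipeline(config: dict | None = None, outdir=None) -> dict:
    """Sample the bicycle-pedal landscape with WT-metaD and analyse it.

    The full-depth three-well preset (dark / p / q) is analysed
    analytically; the Langevin sampler runs on a depth-scaled copy so
    that barrier crossings occur within a desk-scale hill budget, and
    the reconstruction is compared against the scaled analytic surface.
    """
    config = config if config is not None else load_config()
    cfg = _require_section(config, "fes")
    seed = child_seed(config.get("seed", 0), "fes")

    preset = synthetic.three_well_preset()
    analytic = preset.grid(1.0)
    analytic_minima = metad.find_minima(analytic)
    dark, p, q = analytic_minima[0], analytic_minima[1], analytic_minima[2]
    if p[2] < q[2]:  # order: dark (0), p (~30), q (~7) by construction
        p, q = q, p
    barriers_analytic = {
        "dark_to_p": metad.barrier_between(analytic, dark[:2], p[:2]),
        "p_to_q": metad.barrier_between(analytic, p[:2], q[:2]),
    }

    scaled = preset.scaled(cfg["depth_scale"])
    params = metad.WTMetaDParams(
        hill_width=cfg["hill_width"], h0=cfg["h0"],
        deposit_interval=cfg["deposit_interval"], kb_delta_t=cfg["kb_delta_t"],
        temperature=cfg["temperature"], friction=cfg["friction"], dt=cfg["dt"],
        seed=seed,
    )
    start = (dark[0], dark[1])
    traj, bias = metad.run_wtmetad(scaled, scaled.gradient, params, int(cfg["n_steps"]), x0=start)
    fes = metad.reconstruct_fes(bias, params, spacing=cfg["grid_spacing"])
    sampled_minima = metad.prominent_minima(fes, cfg["min_prominence"])

    sampled_barriers = {}
    if len(sampled_minima) >= 2:
        for name, (ma, mb) in {
            "first_to_second": (sampled_minima[0], sampled_minima[1]),
        }.items():
            sampled_barriers[name] = metad.barrier_between(fes, ma[:2], mb[:2])
    if len(sampled_minima) >= 3:
        sampled_barriers["second_to_third"] = metad.barrier_between(
            fes, sampled_minima[1][:2], sampled_minima[2][:2]
        )

    report = {
        "stage": "fes",
        "seed": seed,
        "bias_factor": params.bias_factor,
        "n_hills": len(bias),
        "analytic_minima": analytic_minima,
        "analytic_relative_energies": {"p_minus_dark": p[2] - dark[2], "q_minus_dark": q[2] - dark[2]},
        "analytic_barriers": barriers_analytic,
        "depth_scale": cfg["depth_scale"],
        "sampled_minima": sampled_minima,
        "sampled_barriers": sampled_barriers,
        "trajectory_extent": [float(np.min(traj[:, 0])), float(np.max(traj[:, 0]))],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        metad.write_hills(outdir / "run.hills", bias, params)
        np.savetxt(
            outdir / "fes.csv",
            np.column_stack(
                [np.repeat(fes.cv1, fes.cv2.size), np.tile(fes.cv2, fes.cv1.size), fes.values.ravel()]
            ),
            delimiter=",",
            header="cv1_deg,cv2_deg,free_energy_kcal_mol",
            comments="",
        )
        _write_json(outdir / "fes_report.json", report)
    return report
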