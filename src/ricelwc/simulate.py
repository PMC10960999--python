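"""Synthetic field campaigns with the statistical structure the analysis
assumes.

The generator plants known truth so every downstream stage has a recovery
test: graded leaf-water-content (LWC) populations across irrigation
treatments (CK flooded control > mild AWD > severe AWD), canopy
reflectance built from a smooth dry-canopy base curve with
water-absorption troughs near 1450 and 1940 nm plus a tightly
LWC-coupled feature pair at the planted wavelengths, midday canopy
microclimate following a planted non-stressed baseline
Tc - Ta = A + B*VPD with a stress-heating term for drying plots, and
physiological covariates (SPAD, Fv/Fm, Fo, Y(II), LAI, biomass, yield)
drawn as linear-in-LWC Gaussians whose noise variances are solved in
closed form to hit target Pearson correlations with LWC.

The major 1450/1940 nm absorption troughs deliberately carry extra
plot-level variability (canopy-structure/saturation effects), so the
planted pair - whose depth is tightly coupled to LWC - is the most
LWC-correlated two-band normalised difference on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

import ricelwc.cwsi as cwsi_mod
from .records import (SpectraCollection, STAGES, TREATMENTS, WAVELENGTH_GRID,
                      ValidationError)

STAGE_DATES = {"booting": (7, 25), "flowering": (8, 15),
               "initial_filling": (9, 1), "middle_filling": (9, 15)}


@dataclass
class SimulationDesign:
    """Study design and planted truth for a synthetic campaign.

    Defaults emulate a two-year, four-cultivar rice experiment with three
    irrigation regimes, five replicate plots per cell (120 plots), four
    growth stages and hourly midday microclimate.
    """

    years: tuple[int, ...] = (2021, 2022)
    site: str = "S1"
    n_cultivars: int = 4
    n_replicates: int = 5
    treatments: tuple[str, ...] = TREATMENTS
    stages: tuple[str, ...] = STAGES
    # latent LWC structure: CK stage means minus treatment offsets
    stage_lwc_means: dict = field(default_factory=lambda: {
        "booting": 0.78, "flowering": 0.76,
        "initial_filling": 0.73, "middle_filling": 0.70})
    treatment_lwc_offsets: dict = field(default_factory=lambda: {
        "CK": 0.0, "MADW": -0.04, "SADW": -0.08})
    lwc_sigma: float = 0.02           # within-cell latent spread
    # reflectance model
    planted_pair: tuple[int, int] = (1287, 1673)
    reflectance_sigma: float = 0.008  # i.i.d. band noise after scan averaging
    brightness_sigma: float = 0.02    # multiplicative whole-spectrum jitter
    n_scans_averaged: int = 10
    # microclimate / planted baseline
    A_true: float = 2.0               # degC
    B_true: float = -2.0              # degC per kPa
    stress_gain: float = 2.5          # degC of extra heating at full stress
    hourly_noise_sigma: float = 0.3   # degC
    hours: tuple[int, int] = (10, 14)
    air_temp_mean: float = 30.0
    air_temp_sigma: float = 2.0
    rh_mean: float = 70.0
    rh_sigma: float = 8.0
    # covariate correlation targets with LWC (within stage, Fig-6-like ranges)
    correlation_targets: dict = field(default_factory=lambda: {
        "CWSI": -0.75, "FvFm": 0.65, "SPAD": 0.60, "Fo": -0.50,
        "YII": 0.55, "LAI": 0.50, "biomass": 0.45, "yield_t_ha": 0.50})
    covariate_noise_scale: float = 1.0
    planting_density: float = 25.06   # hills per m^2 (30.0 cm x 13.3 cm spacing)
    seed: int = 0

    def __post_init__(self):
        la, lb = self.planted_pair
        if la == lb:
            raise ValidationError("planted band pair must use two distinct bands")
        for lam in (la, lb):
            if lam not in WAVELENGTH_GRID:
                raise ValidationError(f"planted band {lam} nm not on the grid")
        for name, rho in self.correlation_targets.items():
            if not (-1.0 < rho < 1.0) or rho == 0.0:
                raise ValidationError(
                    f"correlation target for {name} must be in (-1, 1) and non-zero")
        for s in (self.lwc_sigma, self.reflectance_sigma, self.hourly_noise_sigma,
                  self.covariate_noise_scale):
            if s < 0:
                raise ValidationError("noise scales must be >= 0")

    @property
    def n_plots(self) -> int:
        return (len(self.years) * self.n_cultivars * len(self.treatments)
                * self.n_replicates)


@dataclass
class CampaignResult:
    spectra: SpectraCollection
    microclimate: pd.DataFrame
    physiology: pd.DataFrame        # raw field measurements (FW, DW, PAM levels, D)
    observations: pd.DataFrame      # derived traits incl. latent-baseline CWSI
    truth: dict


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _base_curve(wl: np.ndarray) -> np.ndarray:
    """Smooth dry-canopy reflectance: green peak, red edge, SWIR decline."""
    return (0.05
            + 0.04 * np.exp(-(wl - 550.0) ** 2 / (2 * 40.0 ** 2))
            + 0.40 * _sigmoid((wl - 715.0) / 22.0)
            - 0.18 * _sigmoid((wl - 1500.0) / 220.0)
            - 0.12 * _sigmoid((wl - 2000.0) / 150.0))


def _gauss(wl, center, width):
    return np.exp(-(wl - center) ** 2 / (2.0 * width ** 2))


def _within_stage_lwc_sd(design: SimulationDesign) -> float:
    offs = np.array([design.treatment_lwc_offsets[t] for t in design.treatments])
    return float(np.sqrt(offs.var() + design.lwc_sigma ** 2))


def simulate_campaign(design: SimulationDesign | None = None,
                      seed: int | None = None) -> CampaignResult:
    """Generate one full campaign; same seed gives bit-identical tables."""
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    wl = WAVELENGTH_GRID.astype(float)
    la, lb = design.planted_pair

    # --- plot frame -------------------------------------------------------
    plots = []
    for year in design.years:
        for c in range(design.n_cultivars):
            for trt in design.treatments:
                for rep in range(design.n_replicates):
                    plots.append({
                        "plot_id": f"Y{year}C{c + 1}{trt}R{rep + 1}",
                        "year": year, "site": design.site,
                        "cultivar": f"C{c + 1}", "treatment": trt})
    plots = pd.DataFrame(plots)
    n_plots = len(plots)

    # --- latent LWC per plot/stage ---------------------------------------
    rows = []
    for stage in design.stages:
        mu = (plots["treatment"].map(design.treatment_lwc_offsets).to_numpy()
              + design.stage_lwc_means[stage])
        lwc = mu + rng.normal(0.0, design.lwc_sigma, n_plots)
        block = plots.copy()
        block["stage"] = stage
        block["LWC_latent"] = np.clip(lwc, 0.02, 0.98)
        rows.append(block)
    latent = pd.concat(rows, ignore_index=True)

    # stage-varying ND gain/offset: quadratic in the planted stage-mean
    # stress level (1 - normalised LWC), emulating stage-dependent slope
    # and intercept of the ND-LWC relation
    lwc_floor, lwc_span = 0.60, 0.20
    stage_gain, stage_offset = {}, {}
    for stage in design.stages:
        mean_lwc = (design.stage_lwc_means[stage]
                    + np.mean(list(design.treatment_lwc_offsets.values())))
        u = 1.0 - (mean_lwc - lwc_floor) / lwc_span
        stage_gain[stage] = 0.10 + 0.15 * u - 0.10 * u ** 2
        stage_offset[stage] = 0.08 + 0.06 * u + 0.05 * u ** 2

    # --- reflectance ------------------------------------------------------
    base = _base_curve(wl)
    g1450 = _gauss(wl, 1450.0, 45.0)
    g1940 = _gauss(wl, 1940.0, 70.0)
    g_b = _gauss(wl, float(lb), 25.0)   # LWC-coupled absorption feature
    g_a = _gauss(wl, float(la), 15.0)   # reference band brightens with LWC

    w = (latent["LWC_latent"].to_numpy() - lwc_floor) / lwc_span
    n_obs = len(latent)
    eta1 = np.clip(rng.normal(0, 1, n_obs), -2, 2)
    eta2 = np.clip(rng.normal(0, 1, n_obs), -2, 2)
    gains = latent["stage"].map(stage_gain).to_numpy()
    offsets = latent["stage"].map(stage_offset).to_numpy()

    depth = (np.outer(0.35 + 0.50 * w + 0.25 * eta1, g1450)
             + np.outer(0.60 + 0.70 * w + 0.35 * eta2, g1940)
             + np.outer(offsets + gains * w, g_b)
             - np.outer(0.06 * w, g_a))
    brightness = 1.0 + rng.normal(0, design.brightness_sigma, n_obs)
    refl = base[None, :] * np.exp(-depth) * brightness[:, None]
    refl += rng.normal(0, design.reflectance_sigma, refl.shape)
    refl = np.clip(refl, 0.0, 1.0)

    meta = latent[["plot_id", "year", "site", "cultivar", "treatment", "stage"]].copy()
    meta["n_scans"] = design.n_scans_averaged
    spectra = SpectraCollection(meta, refl)

    # --- microclimate -----------------------------------------------------
    sd_lwc = _within_stage_lwc_sd(design)
    hours = np.arange(design.hours[0], design.hours[1] + 1)
    H = hours.size
    # closed-form plot-level noise so downstream CWSI hits its target
    # correlation with LWC: total noise = signal * sqrt(1/rho^2 - 1),
    # minus the part contributed by averaged hourly noise
    rho_cwsi = design.correlation_targets["CWSI"]
    norm_span = 0.16
    if design.stress_gain > 0:
        sig_stress = design.stress_gain * sd_lwc / norm_span
        need = (sig_stress * np.sqrt(1.0 / rho_cwsi ** 2 - 1.0)
                * design.covariate_noise_scale)
        hourly_part = design.hourly_noise_sigma ** 2 / H
        if design.covariate_noise_scale > 0 and need ** 2 < hourly_part:
            raise ValidationError(
                "correlation target unreachable for CWSI: hourly noise alone "
                "exceeds the allowed total noise")
        plot_stress_sd = np.sqrt(max(need ** 2 - hourly_part, 0.0))
    else:
        plot_stress_sd = 0.0

    # normalised LWC relative to the well-watered (CK) stage mean, so CK
    # plots sit on the planted baseline on average
    ck_mean = latent["stage"].map(design.stage_lwc_means).to_numpy()
    lwc_norm = 1.0 + (latent["LWC_latent"].to_numpy() - ck_mean) / norm_span
    stress = design.stress_gain * (1.0 - lwc_norm)
    stress = stress + rng.normal(0, plot_stress_sd, n_obs)

    micro_rows = []
    for i in range(n_obs):
        year = int(latent.loc[i, "year"])
        month, day = STAGE_DATES.get(latent.loc[i, "stage"], (8, 1))
        Ta = design.air_temp_mean + rng.normal(0, design.air_temp_sigma, H)
        RH = np.clip(design.rh_mean + rng.normal(0, design.rh_sigma, H), 20.0, 98.0)
        d = cwsi_mod.vpd(Ta, RH)
        dT = (design.A_true + design.B_true * d + stress[i]
              + rng.normal(0, design.hourly_noise_sigma, H))
        for h, ta, rh, dt in zip(hours, Ta, RH, dT):
            micro_rows.append({
                "plot_id": latent.loc[i, "plot_id"], "stage": latent.loc[i, "stage"],
                "treatment": latent.loc[i, "treatment"],
                "timestamp": pd.Timestamp(year, month, day, int(h)),
                "Tc": ta + dt, "Ta": ta, "RH": rh})
    microclimate = pd.DataFrame(micro_rows)

    # --- physiological covariates ----------------------------------------
    lwc = latent["LWC_latent"].to_numpy()
    obs = meta.drop(columns="n_scans").copy()
    obs["LWC"] = lwc

    def linear_covariate(name, intercept, slope):
        rho = design.correlation_targets[name]
        if np.sign(slope) != np.sign(rho):
            raise ValidationError(f"{name}: slope sign must match its target correlation")
        sig_signal = abs(slope) * sd_lwc
        noise_sd = (sig_signal * np.sqrt(1.0 / rho ** 2 - 1.0)
                    * design.covariate_noise_scale)
        return intercept + slope * lwc + rng.normal(0, noise_sd, n_obs)

    obs["SPAD"] = linear_covariate("SPAD", -4.0, 60.0)
    obs["FvFm"] = np.clip(linear_covariate("FvFm", 0.20, 0.80), 0.0, 1.0)
    obs["Fo"] = np.clip(linear_covariate("Fo", 950.0, -600.0), 50.0, None)
    obs["YII"] = np.clip(linear_covariate("YII", 0.10, 0.70), 0.0, 1.0)
    obs["LAI"] = np.clip(linear_covariate("LAI", -1.8, 8.0), 0.1, None)
    obs["biomass"] = np.clip(linear_covariate("biomass", 0.8, 10.0), 0.1, None)
    obs["yield_t_ha"] = np.clip(linear_covariate("yield_t_ha", 0.2, 12.0), 0.1, None)

    # raw field measurements from which the pipeline re-derives the traits
    phys = obs[["plot_id", "year", "site", "cultivar", "treatment", "stage"]].copy()
    FW = 4.0 * (1.0 + 0.05 * np.clip(rng.normal(0, 1, n_obs), -2, 2))
    phys["FW"] = FW
    phys["DW"] = FW * (1.0 - lwc)
    phys["Fo"] = obs["Fo"]
    phys["Fm"] = obs["Fo"] / (1.0 - np.clip(obs["FvFm"], 0.0, 0.999))
    fm_prime = 1500.0 * (1.0 + 0.05 * np.clip(rng.normal(0, 1, n_obs), -2, 2))
    phys["Fm_prime"] = fm_prime
    phys["Fs"] = fm_prime * (1.0 - obs["YII"])
    phys["SPAD"] = obs["SPAD"]
    phys["D"] = obs["LAI"] * 10000.0 / design.planting_density
    phys["rho"] = design.planting_density
    phys["biomass"] = obs["biomass"]
    phys["yield_t_ha"] = obs["yield_t_ha"]

    # reference CWSI from the planted baseline (downstream recomputes it
    # from a fitted baseline)
    baseline = cwsi_mod.CwsiBaseline(A=design.A_true, B=design.B_true,
                                     n_fit=0, r2_fit=1.0)
    ref = cwsi_mod.plot_stage_cwsi(microclimate, baseline, design.hours)
    obs = obs.merge(ref, on=["plot_id", "stage"], how="left")

    truth = {
        "seed": int(design.seed if seed is None else seed),
        "A_true": design.A_true, "B_true": design.B_true,
        "planted_pair": list(design.planted_pair),
        "stage_nd_gain": stage_gain, "stage_nd_offset": stage_offset,
        "correlation_targets": dict(design.correlation_targets),
        "stage_lwc_means": dict(design.stage_lwc_means),
        "treatment_lwc_offsets": dict(design.treatment_lwc_offsets),
        "n_plots": int(n_plots),
        "stress_gain": design.stress_gain,
    }
    return CampaignResult(spectra=spectra, microclimate=microclimate,
                          physiology=phys, observations=obs, truth=truth)


def truth_report(truth: dict) -> dict:
    """JSON-ready summary of the planted parameters for recovery checks."""
    return {
        "planted_baseline": {"A": truth["A_true"], "B": truth["B_true"]},
        "planted_pair": truth["planted_pair"],
        "stage_nd_gain": truth["stage_nd_gain"],
        "stage_nd_offset": truth["stage_nd_offset"],
        "correlation_targets": truth["correlation_targets"],
        "n_plots": truth["n_plots"],
        "seed": truth["seed"],
    }


def simulate_coupled_dataset(seed: int,
                             coefficients: tuple[float, float, float] = (1.49, -0.08, 0.57),
                             sigma: float = 0.01,
                             n_train: int = 55, n_valid: int = 36) -> pd.DataFrame:
    """Data drawn from a known coupled model LWC = b1*ND + b2*CWSI + b0 + e,
    with a two-year label matching the modelling (2022) / validation (2021)
    split sizes; used for coefficient-recovery checks."""
    rng = np.random.default_rng(seed)
    b1, b2, b0 = coefficients
    n = n_train + n_valid
    nd = rng.normal(0.20, 0.05, n)
    cw = rng.normal(0.50, 0.15, n)
    lwc = b0 + b1 * nd + b2 * cw + rng.normal(0, sigma, n)
    year = np.array([2022] * n_train + [2021] * n_valid)
    return pd.DataFrame({"year": year, "ND": nd, "CWSI": cw, "LWC": lwc})


def simulate_nonlinear_benchmark(seed: int, n: int = 240,
                                 interaction: float = 4.0,
                                 sigma: float = 0.01) -> pd.DataFrame:
    """Benchmark data with a planted ND x CWSI interaction that a linear
    model cannot express; tree ensembles can."""
    rng = np.random.default_rng(seed)
    nd = rng.normal(0.20, 0.05, n)
    cw = rng.normal(0.50, 0.15, n)
    lwc = (0.57 + 1.49 * nd - 0.08 * cw
           - interaction * (nd - 0.20) * (cw - 0.50)
           + rng.normal(0, sigma, n))
    return pd.DataFrame({"ND": nd, "CWSI": cw, "LWC": lwc})
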