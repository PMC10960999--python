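"""End-to-end orchestration: simulate or ingest, derive physiology, fit the
CWSI baseline, compute indices, run the band search, screen covariates,
fit coupled models with the year split, and benchmark the ML regressors.

Each stage writes its outputs before the next starts, so any stage can be
inspected or re-run independently; the run report collects every headline
number with a pointer back to the stage that produced it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bandsearch, bench, coupling, indices, physio, screening
import ricelwc.cwsi as cwsi_mod
from .config import RunConfig
from .records import (SpectraCollection, STAGES, ValidationError, write_spectra,
                      merge_observations, read_microclimate, read_observations,
                      read_spectra, records_to_collection, group_and_average)
from .simulate import SimulationDesign, simulate_campaign, truth_report

logger = logging.getLogger("ricelwc")

STAGE_ORDER = ["ingest", "physiology", "cwsi", "indices", "bandscan",
               "screening", "coupling", "benchmark"]


def derive_physiology(phys: pd.DataFrame) -> pd.DataFrame:
    """Compute LWC, Fv/Fm, Y(II) and LAI from the raw field measurements."""
    rows = []
    for _, r in phys.iterrows():
        row = {c: r[c] for c in ["plot_id", "year", "site", "cultivar",
                                 "treatment", "stage"]}
        row["LWC"] = physio.leaf_water_content(physio.LeafSample(r["FW"], r["DW"]))
        fl = physio.FluorescenceRecord(Fo=r["Fo"], Fm=r["Fm"], Fs=r["Fs"],
                                       Fm_prime=r["Fm_prime"])
        row["FvFm"] = physio.fv_fm(fl)
        row["YII"] = physio.y_ii(fl)
        row["LAI"] = physio.leaf_area_index(physio.CanopySample(r["D"], r["rho"]))
        row["Fo"] = r["Fo"]
        row["SPAD"] = r["SPAD"]
        row["biomass"] = r.get("biomass", np.nan)
        row["yield_t_ha"] = r.get("yield_t_ha", np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_all(config: RunConfig, until: str | None = None) -> dict:
    """Run the pipeline through ``until`` (inclusive; default: everything).

    Returns the run report as a dict; artifacts land under ``config.out_dir``.
    """
    if until is not None and until not in STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}; choose from {STAGE_ORDER}")
    stop = STAGE_ORDER.index(until) if until else len(STAGE_ORDER) - 1
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "config": {"nd_pair": config.nd_pair,
                                                    "band_step": config.band_step,
                                                    "train_year": config.train_year}}

    # -- ingest ------------------------------------------------------------
    truth = None
    if config.simulate:
        design = SimulationDesign(seed=config.seed, **config.design_overrides)
        campaign = simulate_campaign(design)
        spectra, micro, phys = campaign.spectra, campaign.microclimate, campaign.physiology
        truth = campaign.truth
        report["truth"] = truth_report(truth)
        write_spectra(spectra, out / "spectra.csv")
        micro.to_csv(out / "microclimate.csv", index=False)
        phys.to_csv(out / "physiology_raw.csv", index=False)
    else:
        records = group_and_average(read_spectra(config.spectra_path))
        spectra = records_to_collection(records)
        micro = read_microclimate(config.microclimate_path)
        phys = read_observations(config.physiology_path)
    report["n_spectra"] = len(spectra)
    if stop < 1:
        return _finish(report, out)

    # -- physiology --------------------------------------------------------
    traits = derive_physiology(phys)
    traits.to_csv(out / "physiology.csv", index=False)
    if stop < 2:
        return _finish(report, out)

    # -- CWSI --------------------------------------------------------------
    treatments = phys[["plot_id", "treatment"]].drop_duplicates()
    micro_t = micro if "treatment" in micro.columns else micro.merge(treatments, on="plot_id")
    baseline = cwsi_mod.fit_baseline(micro_t[micro_t["treatment"] == "CK"],
                                     config.baseline_window)
    stage_cwsi = cwsi_mod.plot_stage_cwsi(micro_t, baseline, config.baseline_window,
                                          config.vpg_convention)
    (out / "cwsi_baseline.json").write_text(json.dumps({
        "A": baseline.A, "B": baseline.B, "n_fit": baseline.n_fit,
        "r2_fit": baseline.r2_fit}, indent=2))
    stage_cwsi.to_csv(out / "cwsi.csv", index=False)
    report["cwsi_baseline"] = {"A": baseline.A, "B": baseline.B,
                               "n_fit": baseline.n_fit, "r2_fit": baseline.r2_fit}
    obs = merge_observations(traits, stage_cwsi)
    if config.drop_outliers:
        flags = screening.flag_outliers(obs, ["LWC", "SPAD", "FvFm", "CWSI"],
                                        config.outlier_n_sd, config.outlier_rule)
        obs = obs[~flags]
    obs.to_csv(out / "observations.csv", index=False)
    if stop < 3:
        return _finish(report, out)

    # -- band search first when no pair is configured ------------------------
    lwc_by_key = obs.set_index(["plot_id", "stage"])["LWC"]
    stages = [s for s in STAGES if s in set(spectra.meta["stage"])]
    scan_results: dict[str, bandsearch.BandSearchResult] = {}
    for stage in stages:
        mask = (spectra.meta["stage"] == stage).to_numpy()
        sub = spectra.subset(mask)
        y = lwc_by_key.loc[list(zip(sub.meta["plot_id"], sub.meta["stage"]))].to_numpy()
        scan_results[stage] = bandsearch.scan_pairs(sub, y, stage, config.band_step)
    report["band_search"] = {
        s: {"best_pair": list(r.best_pair), "best_r2": r.best_r2,
            "best_rmse": r.best_rmse, "n": r.n_samples}
        for s, r in scan_results.items()}
    pd.DataFrame([{"stage": s, "lambda1": r.best_pair[0], "lambda2": r.best_pair[1],
                   "best_r2": r.best_r2, "best_rmse": r.best_rmse}
                  for s, r in scan_results.items()]).to_csv(out / "best_pairs.csv",
                                                            index=False)

    nd_pair = config.nd_pair or _consensus_pair(scan_results)
    report["nd_pair"] = list(nd_pair)

    # -- indices -----------------------------------------------------------
    idx = indices.index_table(spectra, nd_pair=nd_pair)
    idx = idx.merge(obs, on=["plot_id", "year", "site", "cultivar", "treatment",
                             "stage"], how="inner")
    idx.to_csv(out / "indices.csv", index=False)
    if stop < 4:
        return _finish(report, out)

    comparison = bandsearch.stage_table(
        scan_results, {s: idx[idx["stage"] == s] for s in stages})
    comparison.to_csv(out / "index_comparison.csv", index=False)
    report["index_comparison"] = comparison.drop(
        columns=[c for c in comparison.columns if c.endswith("_sig")]
    ).to_dict(orient="records")
    if stop < 5:
        return _finish(report, out)

    # -- screening ---------------------------------------------------------
    pcc_all = {}
    for stage in stages:
        r, sig = screening.pcc_matrix(idx[idx["stage"] == stage])
        r.to_csv(out / f"pcc_{stage}.tsv", sep="\t")
        pcc_all[stage] = r
    ranked = screening.select_covariates(
        idx, ["CWSI", "FvFm", "SPAD", "Fo", "YII", "LAI", "biomass"], k=3)
    ranked.to_csv(out / "covariate_ranking.csv", index=False)
    desc = screening.descriptive_stats(
        idx, [v for v in screening.DEFAULT_SCREEN_VARIABLES if v in idx.columns])
    desc.to_csv(out / "descriptives.csv", index=False)
    report["covariate_ranking"] = ranked["covariate"].tolist()
    report["pcc_lwc_cwsi"] = {s: float(pcc_all[s].loc["LWC", "CWSI"]) for s in stages}
    if stop < 6:
        return _finish(report, out)

    # -- coupling ----------------------------------------------------------
    train_all, valid_all = coupling.year_split(idx, config.train_year)
    stage_models, coupled_rows, diag_rows = [], [], []
    for stage in stages:
        tr = train_all[train_all["stage"] == stage]
        va = valid_all[valid_all["stage"] == stage]
        line = coupling.fit_stage_line(tr["ND"], tr["LWC"], stage,
                                       va["ND"], va["LWC"])
        stage_models.append(line)
        coupled = []
        for cov in config.covariates:
            cm = coupling.fit_coupled(tr, va, cov, stage)
            coupled.append(cm)
            coll = screening.collinearity(tr[["ND", cov]])
            dw = screening.durbin_watson(_sorted_residuals(tr, cm, cov))
            diag_rows.append({"stage": stage, "covariate": cov,
                              "vif_ND": coll[0].vif, "vif_cov": coll[1].vif,
                              "tolerance_ND": coll[0].tolerance,
                              "durbin_watson": dw})
            coupled_rows.append({
                "stage": stage, "covariate": cov, **{
                    f"b_{k}": v for k, v in cm.coefficients.items()},
                "model_r2": cm.model_r2, "prediction_r2": cm.prediction_r2,
                "rmse": cm.rmse_pred})
        improvement = coupling.compare_models(line, coupled)
        improvement.to_csv(out / f"improvement_{stage}.csv", index=False)
    stage_cov_means = idx.groupby("stage")[list(config.covariates)].mean()
    quads = coupling.slope_intercept_analysis(stage_models, stage_cov_means)
    pd.DataFrame([vars(q) for q in quads]).to_csv(out / "slope_intercept_quadratics.csv",
                                                  index=False)
    coupled_df = pd.DataFrame(coupled_rows)
    coupled_df.to_csv(out / "coupled_models.csv", index=False)
    pd.DataFrame(diag_rows).to_csv(out / "diagnostics.csv", index=False)
    report["stage_lines"] = [{"stage": m.stage, "a": m.a, "b": m.b,
                              "r2_fit": m.r2_fit, "r2_pred": m.r2_pred}
                             for m in stage_models]
    report["coupled_models"] = coupled_df.to_dict(orient="records")
    if stop < 7:
        return _finish(report, out)

    # -- ML benchmark ------------------------------------------------------
    bench_stage = config.benchmark_stage
    data = idx[idx["stage"] == bench_stage]
    results = bench.run_benchmark(data, ["ND", "CWSI"], "LWC",
                                  config.train_fraction,
                                  config.stage_seed("benchmark"))
    table = bench.results_table(results)
    ratios = bench.compare_to_mlr(results)
    table.to_csv(out / "benchmark.csv", index=False)
    ratios.to_csv(out / "benchmark_ratios.csv", index=False)
    report["benchmark"] = table.to_dict(orient="records")
    report["benchmark_ratios"] = ratios.to_dict(orient="records")
    return _finish(report, out)


def _sorted_residuals(train: pd.DataFrame, model, cov: str) -> np.ndarray:
    ordered = train.sort_values(["year", "site", "plot_id"])
    pred = model.predict(ordered["ND"], ordered[cov])
    return ordered["LWC"].to_numpy(float) - pred


def _consensus_pair(scan_results) -> tuple[int, int]:
    """Cross-stage recommendation: the per-stage optimum whose mean R^2
    across all stages is highest (this artifact's own aggregation rule)."""
    best, best_score = None, -np.inf
    for res in scan_results.values():
        score = []
        for other in scan_results.values():
            wl = other.wavelengths
            i = np.abs(wl - res.best_pair[0]).argmin()
            j = np.abs(wl - res.best_pair[1]).argmin()
            score.append(other.r2_matrix[i, j])
        score = float(np.nanmean(score))
        if score > best_score:
            best, best_score = res.best_pair, score
    return best


def _finish(report: dict, out: Path) -> dict:
    (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
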