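"""End-to-end orchestration: tree rings -> climate -> models -> genetics.

:func:`run_pipeline` executes the full analysis from a
:class:`PipelineConfig`, writing per-stage CSVs, a JSON metrics summary
and a run log (package version, seeds, content hashes) into an output
directory.  A missing genotype input skips the genetic stages with an
explicit "skipped: missing input" status instead of failing, so the
dendro half can run alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pial import __version__, climate as climate_mod, dataio, drought, gea, growth_model, popgen, treering

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, analysis windows, and thresholds for a full run.

    Defaults are the study constants: trend window 1970-2011, drought
    2012-2015 vs pre-drought 2008-2011, normals WY1970-1999, anomaly
    reference WY1970-2015, alpha 0.05, locus presence 0.8, MAF 0.02,
    VIF cutoff 10, outlier multiplier 3 SD, 999 permutations.
    """

    rwl_path: str | None = None
    tree_meta_path: str | None = None
    climate_path: str | None = None
    climate_resolution: str = "water_year"
    genotype_path: str | None = None
    genotype_format: str = "matrix012"
    sample_sheet_path: str | None = None

    trend_window: tuple[int, int] = (1970, 2011)
    model_window: tuple[int, int] = (1971, 2011)
    drought_window: tuple[int, int] = (2012, 2015)
    predrought_window: tuple[int, int] = (2008, 2011)
    normals_span: tuple[int, int] = (1970, 1999)
    anomaly_reference: tuple[int, int] = (1970, 2015)

    alpha: float = 0.05
    min_locus_presence: float = 0.8
    min_maf: float = 0.02
    vif_cutoff: float = 10.0
    sd_mult: float = 3.0
    n_perm: int = 999
    n_boot: int = 1000
    seed: int = 7

    def __post_init__(self) -> None:
        for name in (
            "trend_window",
            "model_window",
            "drought_window",
            "predrought_window",
            "normals_span",
            "anomaly_reference",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} {lo}:{hi} not ordered")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_maf < 0.5:
            raise ValueError("min_maf must be in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, val in raw.items():
            if isinstance(val, list) and len(val) == 2 and key.endswith(("window", "span", "reference")):
                raw[key] = tuple(val)
        return cls(**raw)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, seed: int) -> str:
    dataio.write_csv(df, path, seed=seed)
    return _hash_file(path)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every available stage and return the metrics dictionary.

    Writes per-stage CSVs plus ``metrics.json`` and ``run_log.json``
    under ``outdir``.  Stage errors propagate with the stage name;
    partial outputs written before the failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics: dict = {}
    hashes: dict[str, str] = {}
    stage_status: dict[str, str] = {}
    seed = config.seed

    # ---------------- tree rings ----------------
    stage = "treering"
    try:
        series = dataio.read_rwl(config.rwl_path)
        meta = pd.read_csv(config.tree_meta_path, comment="#")
        series = dataio.attach_tree_metadata(series, meta)
        by_site: dict[str, list] = {}
        for s in series:
            by_site.setdefault(s.site_id, []).append(s)
        summary = treering.series_summary(by_site)
        hashes["site_summary.csv"] = _write(summary, outdir / "site_summary.csv", seed)

        bai_series = [
            treering.standardize_bai(treering.ring_widths_to_bai(s)) for s in series
        ]
        slopes_by_site: dict[str, list[float]] = {}
        slope_rows = []
        for b in bai_series:
            sl = treering.tree_growth_trend(b, window=config.trend_window)
            if sl is not None:
                slopes_by_site.setdefault(b.site_id, []).append(sl)
                slope_rows.append({"tree_id": b.tree_id, "site_id": b.site_id, "slope": sl})
        trends = treering.classify_site_trends(slopes_by_site, alpha=config.alpha)
        hashes["trends.csv"] = _write(trends, outdir / "trends.csv", seed)
        hashes["tree_slopes.csv"] = _write(
            pd.DataFrame(slope_rows), outdir / "tree_slopes.csv", seed
        )
        metrics["mean_ar1"] = float(summary["mean_ar1"].mean())
        metrics["trend_counts"] = trends["trend_class"].value_counts().to_dict()
        stage_status[stage] = "ok"
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # ---------------- climate ----------------
    stage = "climate"
    try:
        clim = dataio.read_climate_table(
            config.climate_path, resolution=config.climate_resolution
        )
        normals = climate_mod.climate_normals(clim, span=config.normals_span)
        hashes["normals.csv"] = _write(normals, outdir / "normals.csv", seed)
        anomalies = climate_mod.drought_anomaly_zscores(
            clim,
            drought_window=config.drought_window,
            reference=config.anomaly_reference,
        )
        hashes["anomalies.csv"] = _write(anomalies, outdir / "anomalies.csv", seed)
        stage_status[stage] = "ok"
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # ---------------- growth-climate model ----------------
    stage = "growth_model"
    try:
        panel_rows = []
        for b in bai_series:
            if b.sbai is None:
                continue
            panel_rows.append(
                pd.DataFrame({"site_id": b.site_id, "year": b.years, "sbai": b.sbai})
            )
        panel = (
            pd.concat(panel_rows, ignore_index=True)
            .groupby(["site_id", "year"], as_index=False)["sbai"]
            .mean()
        )
        design = growth_model.build_design(panel, clim, window=config.model_window)
        ranking, fits = growth_model.select_growth_model(design)
        hashes["model_ranking.csv"] = _write(ranking, outdir / "model_ranking.csv", seed)
        best_name = growth_model.best_supported_model(ranking)
        best = fits[best_name]
        metrics["best_model"] = str(best_name)
        metrics["best_model_pseudo_r2"] = round(float(best.pseudo_r2), 10)
        metrics["best_model_phi"] = round(float(best.phi), 10)
        coef = dict(zip(("intercept", *best.terms), best.beta))
        metrics["beta_tmn"] = round(float(coef.get("Tmn", np.nan)), 10)
        metrics["beta_ppt"] = round(float(coef.get("PPT", np.nan)), 10)
        stage_status[stage] = "ok"
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # ---------------- drought response ----------------
    stage = "drought"
    try:
        rd_by_site: dict[str, list[float]] = {}
        rd_rows = []
        for b in bai_series:
            rd = drought.drought_response_index(
                b, drought=config.drought_window, reference=config.predrought_window
            )
            if rd is not None:
                rd_by_site.setdefault(b.site_id, []).append(rd)
                rd_rows.append({"tree_id": b.tree_id, "site_id": b.site_id, "r_d": rd})
        response = drought.classify_site_response(rd_by_site, alpha=config.alpha)
        hashes["drought_response.csv"] = _write(
            response, outdir / "drought_response.csv", seed
        )
        rd_tree = pd.DataFrame(rd_rows)
        hashes["tree_response.csv"] = _write(rd_tree, outdir / "tree_response.csv", seed)
        metrics["response_counts"] = response["response_class"].value_counts().to_dict()

        # correlations of site mean R_d with drought climate anomalies
        anom_wide = anomalies.pivot(index="site_id", columns="variable", values="z")
        merged = response.set_index("site_id").join(anom_wide, how="inner")
        corr_rows = {}
        for var in anom_wide.columns:
            try:
                r, p = drought.correlate(
                    merged["mean"].to_numpy(), merged[var].to_numpy(), method="pearson"
                )
                corr_rows[var] = {"r": round(r, 10), "p": round(p, 10)}
            except ValueError:
                corr_rows[var] = {"r": None, "p": None}
        metrics["response_climate_correlations"] = corr_rows
        stage_status[stage] = "ok"
    except Exception as exc:
        raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    # ---------------- genetics ----------------
    if config.genotype_path is None or not Path(config.genotype_path).exists():
        stage_status["popgen"] = "skipped: missing input"
        stage_status["gea"] = "skipped: missing input"
    else:
        stage = "popgen"
        try:
            gm = dataio.read_genotype_table(
                config.genotype_path,
                format=config.genotype_format,
                sample_sheet=config.sample_sheet_path,
            )
            gm, attrition = popgen.filter_genotypes(
                gm,
                min_locus_presence=config.min_locus_presence,
                min_maf=config.min_maf,
            )
            hashes["filter_attrition.csv"] = _write(
                attrition, outdir / "filter_attrition.csv", seed
            )
            fst = popgen.weir_cockerham_fst(
                gm, n_boot=config.n_boot, seed=seed
            )
            diversity = popgen.expected_heterozygosity(gm)
            diversity = diversity.merge(
                popgen.nucleotide_diversity(gm)[["site_id", "pi", "pi_se"]], on="site_id"
            )
            hashes["diversity.csv"] = _write(diversity, outdir / "diversity.csv", seed)
            pair = fst.pairwise
            hashes["pairwise_fst.csv"] = _write(
                pair.reset_index().rename(columns={"index": "site_id"}),
                outdir / "pairwise_fst.csv",
                seed,
            )
            site_order = list(pair.index)
            sites_tab = gm.sites.set_index("site_id").loc[site_order].reset_index()
            d_geo = popgen.utm_distance_matrix(sites_tab)
            mantel_r, mantel_p = popgen.mantel_test(
                pair.to_numpy(), d_geo, n_perm=config.n_perm, seed=seed
            )
            pca = popgen.genotype_pca(gm, n_axes=4)
            metrics["n_snps_after_filter"] = int(gm.n_loci)
            metrics["global_fst"] = round(float(fst.theta_global), 10)
            metrics["global_fst_ci"] = [round(fst.ci_low, 10), round(fst.ci_high, 10)]
            metrics["mantel_r"] = round(float(mantel_r), 10)
            metrics["mantel_p"] = round(float(mantel_p), 10)
            metrics["pca_pc1_pct_variance"] = round(float(pca.percent_variance[0]), 10)
            stage_status[stage] = "ok"
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

        stage = "gea"
        try:
            normals_wide = normals.pivot(index="site_id", columns="variable", values="mean")
            site_of_ind = gm.individuals["site_id"]
            clim_ind = normals_wide.loc[site_of_ind.to_numpy()].reset_index(drop=True)
            Y, imputed_frac = gea.impute_most_common(gm)
            selection = gea.vif_forward_select(
                clim_ind,
                Y,
                vif_cutoff=config.vif_cutoff,
                p_enter=config.alpha,
                n_perm=max(99, config.n_perm // 5),
                seed=seed,
            )
            hashes["selection_trace.csv"] = _write(
                selection.trace, outdir / "selection_trace.csv", seed
            )
            if not selection.selected:
                raise RuntimeError("forward selection kept no climate predictors")
            X = clim_ind[selection.selected]
            sites_ind = gm.sites.set_index("site_id").loc[site_of_ind.to_numpy()]
            Z = sites_ind[["utm_n", "utm_e"]].reset_index(drop=True)
            rda = gea.partial_rda(
                Y, X, Z, locus_ids=gm.loci["locus_id"].to_numpy(), scale_y=True
            )
            rda = gea.rda_permutation_tests(
                Y, X, Z, n_perm=config.n_perm, seed=seed, rda=rda, scale_y=True
            )
            outliers = gea.detect_outlier_loci(
                rda, Y, clim_ind, sd_mult=config.sd_mult
            )
            hashes["outliers.csv"] = _write(outliers.table, outdir / "outliers.csv", seed)
            axis_tab = pd.DataFrame(
                {
                    "axis": [f"RDA{k + 1}" for k in range(rda.n_axes)],
                    "eigenvalue": rda.eigenvalues,
                    "p": rda.p_axes,
                }
            )
            hashes["rda_axes.csv"] = _write(axis_tab, outdir / "rda_axes.csv", seed)

            phen = rd_tree.set_index("tree_id")["r_d"]
            try:
                link = gea.link_scores_to_phenotype(
                    rda, gm.individuals["individual_id"].to_numpy(), phen
                )
                hashes["phenotype_link.csv"] = _write(
                    link, outdir / "phenotype_link.csv", seed
                )
                metrics["phenotype_rs_by_axis"] = {
                    row["axis"]: round(float(row["r_s"]), 10) for _, row in link.iterrows()
                }
            except ValueError as exc:
                logger.warning("phenotype linkage skipped: %s", exc)
                metrics["phenotype_rs_by_axis"] = {}
            metrics["selected_predictors"] = selection.selected
            metrics["rda_r2_adj"] = round(float(rda.r2_adj), 10)
            metrics["rda_p_full"] = round(float(rda.p_full), 10)
            metrics["n_significant_axes"] = len(rda.significant_axes(config.alpha))
            metrics["n_outlier_loci"] = int(outliers.table["locus_id"].nunique())
            metrics["outlier_variable_counts"] = (
                outliers.table.drop_duplicates("locus_id")["assigned_variable"]
                .value_counts()
                .to_dict()
            )
            metrics["imputed_fraction"] = round(float(imputed_frac), 10)
            stage_status[stage] = "ok"
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc

    metrics["stages"] = stage_status
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=_jsonify)
    run_log = {
        "package_version": __version__,
        "seed": seed,
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(config).items()},
        "stage_status": stage_status,
        "output_hashes": hashes,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
    return metrics


def simulate_inputs(
    outdir: str | Path,
    seed: int = 7,
    n_sites: int = 27,
    n_trees_per_site: int = 28,
    n_genetic_sites: int = 22,
    n_per_site_genotyped: int = 15,
    n_loci: int = 3000,
    n_adaptive: int = 50,
    gamma: float = 1.5,
    missing_rate: float = 0.2,
    site_slopes: dict[str, float] | float = 0.0,
    drought_boost: float = 1.0,
) -> dict[str, str]:
    """Write a complete synthetic input set (rwl, meta, climate, genotypes).

    Returns the paths, keyed the way :class:`PipelineConfig` names them.
    The genotyped sites are the first ``n_genetic_sites`` of the
    network, mirroring a study where some southern/eastern sites drop
    out of the genetic dataset.
    """
    from pial import synthetic
    from pial.climate import climate_normals

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clim, truth_c = synthetic.simulate_climate(n_sites=n_sites, seed=seed)
    dataio.write_csv(clim, outdir / "climate.csv", seed=seed)

    gp = synthetic.GrowthParams(site_slopes=site_slopes, drought_boost=drought_boost)
    series, truth_t = synthetic.simulate_ring_widths(
        clim, n_trees_per_site=n_trees_per_site, growth_params=gp, seed=seed
    )
    dataio.write_rwl(series, outdir / "rings.rwl", dialect="units_0.001mm")
    meta = pd.DataFrame(
        {
            "tree_id": [s.tree_id for s in series],
            "site_id": [s.site_id for s in series],
            "dbh_cm": [s.dbh_cm for s in series],
            "height_m": np.nan,
        }
    )
    dataio.write_csv(meta, outdir / "tree_meta.csv", seed=seed)

    sites = truth_c.site_table.iloc[:n_genetic_sites]
    normals = climate_normals(clim[clim["site_id"].isin(sites["site_id"])])
    env = normals.pivot(index="site_id", columns="variable", values="mean")
    gm, truth_g = synthetic.simulate_genotypes(
        sites,
        n_per_site=n_per_site_genotyped,
        n_loci=n_loci,
        n_adaptive=n_adaptive,
        gamma=gamma,
        missing_rate=missing_rate,
        seed=seed,
        env=env,
    )
    dataio.write_matrix012(gm, outdir / "genotypes.csv", seed=seed)
    sheet = gm.individuals.merge(gm.sites, on="site_id")
    dataio.write_csv(
        sheet[["individual_id", "site_id", "utm_e", "utm_n", "latitude"]],
        outdir / "sample_sheet.csv",
        seed=seed,
    )
    truth = truth_c.merge(truth_t).merge(truth_g)
    truth_json = {
        "phi_sim": truth.phi_sim,
        "b_tmn": truth.b_tmn,
        "b_ppt": truth.b_ppt,
        "adaptive_loci": truth.adaptive_loci.to_dict(orient="records")
        if truth.adaptive_loci is not None
        else [],
        "stepping_stone_range_m": truth.stepping_stone_range_m,
        "seed": seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)

    return {
        "rwl_path": str(outdir / "rings.rwl"),
        "tree_meta_path": str(outdir / "tree_meta.csv"),
        "climate_path": str(outdir / "climate.csv"),
        "genotype_path": str(outdir / "genotypes.csv"),
        "sample_sheet_path": str(outdir / "sample_sheet.csv"),
    }
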