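"""End-to-end monitoring-network design pipeline.

Stages, each writing CSV artifacts into the output directory and an entry
into ``manifest.json``:

1. ``simulate``  — synthetic city (locations, sources, covariates, truth);
2. ``qc``        — hourly series per current site, completeness QC, annual means;
3. ``features``  — proximity recoding, low-variability exclusion, z-scaling;
4. ``lur``       — forward-selected land-use regression, predictions everywhere;
5. ``cluster``   — DiD curve over k, k choice, best k-means solution, profiles;
6. ``allocate``  — greedy placement of the new sites with pick log;
7. ``stability`` — subsample adjusted-Rand robustness check.

The manifest echoes every parameter and records a SHA-256 hash of each
artifact, so a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster_engine, geo_features, lur_model, site_allocator, stability
from .monitoring_records import annual_summaries, daily_averages
from .synthetic_city import CityConfig, generate_city, generate_hourly_series

__all__ = ["PipelineConfig", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    seed: int = 0
    year: int = 2010
    city: dict = field(default_factory=dict)          # CityConfig overrides
    qc: dict = field(default_factory=dict)            # completeness thresholds
    features: dict = field(default_factory=lambda: {
        "unique_frac": 0.10, "land_use_frac": 0.10})
    lur: dict = field(default_factory=dict)           # SelectionConfig fields
    cluster: dict = field(default_factory=lambda: {
        "k": None, "k_max": 15, "n_restarts": 50,
        "marginal_gain_threshold": 1.0, "lookahead": 3})
    allocate: dict = field(default_factory=lambda: {
        "n_new": 20, "tie_rule": "lowest_index"})
    stability: dict = field(default_factory=lambda: {
        "n_reps": 20, "keep_frac": 0.90, "n_restarts": 10})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}

    def record(stage: str, files: dict[str, Path], **info) -> None:
        manifest["stages"][stage] = {
            "artifacts": {k: {"path": p.name, "sha256": _sha256(p)}
                          for k, p in files.items()},
            **info}

    try:
        # -- simulate ----------------------------------------------------
        city_cfg = CityConfig(seed=config.seed, **config.city)
        locations, sources, covariates, concentration = generate_city(city_cfg)
        loc_path = out / "locations.csv"
        _write(locations, loc_path)
        cov_path = out / "covariates_raw.csv"
        covariates.to_csv(cov_path)
        conc_path = out / "concentration_true.csv"
        concentration.rename_axis("location_id").to_csv(conc_path)
        record("simulate", {"locations": loc_path, "covariates": cov_path,
                            "concentration": conc_path},
               n_locations=len(locations))

        # -- qc ----------------------------------------------------------
        current_ids = locations.loc[locations["role"] == "current", "id"]
        seeds = np.random.SeedSequence(config.seed).generate_state(
            len(current_ids)) % (2 ** 31)
        hourly = pd.concat([
            generate_hourly_series(int(s), year=config.year, site_id=sid,
                                   mean=float(concentration[sid]))
            for sid, s in zip(current_ids, seeds)], ignore_index=True)
        daily = daily_averages(hourly)
        summaries = annual_summaries(daily, year=config.year, **config.qc)
        qc_path = out / "annual_summaries.csv"
        _write(summaries, qc_path)
        record("qc", {"annual_summaries": qc_path},
               n_sites=len(summaries),
               n_eligible=int(summaries["eligible"].sum()))

        # -- features ----------------------------------------------------
        recoded = geo_features.recode_matrix(covariates)
        filtered, excl_report = geo_features.exclude_low_variability(
            recoded, **config.features)
        scaled, stats = geo_features.zscale(filtered)
        feat_path = out / "covariates_recoded.csv"
        filtered.to_csv(feat_path)
        scaled_path = out / "covariates_scaled.csv"
        scaled.to_csv(scaled_path)
        stats_path = out / "scaling_stats.csv"
        _write(stats, stats_path, index=True)
        excl_path = out / "excluded_variables.csv"
        _write(excl_report, excl_path)
        record("features", {"recoded": feat_path, "scaled": scaled_path,
                            "scaling_stats": stats_path,
                            "exclusions": excl_path},
               n_excluded=len(excl_report), n_kept=len(filtered.variables))

        # -- lur ---------------------------------------------------------
        eligible = summaries.loc[summaries["eligible"], "site_id"]
        y = summaries.set_index("site_id").loc[eligible, "annual_mean"]
        X_fit = filtered.values.loc[eligible]
        sel_cfg = lur_model.SelectionConfig(**config.lur)
        model = lur_model.forward_select(X_fit, y, sel_cfg)
        predictions = lur_model.predict(model, filtered.values)
        model_path = out / "lur_model.json"
        model.to_json(model_path)
        pred_path = out / "predictions.csv"
        predictions.rename_axis("location_id").to_csv(pred_path)
        record("lur", {"model": model_path, "predictions": pred_path},
               variables=model.variables, loocv_r2=model.loocv_r2)

        # -- cluster -----------------------------------------------------
        ccfg = config.cluster
        X_sel = scaled.values[model.variables] if model.variables \
            else scaled.values
        curve = cluster_engine.did_curve(
            X_sel, predictions, k_max=ccfg.get("k_max", 15),
            n_restarts=ccfg.get("n_restarts", 50), seed=config.seed)
        k = ccfg.get("k") or cluster_engine.suggest_k(
            curve, ccfg.get("marginal_gain_threshold", 1.0),
            ccfg.get("lookahead", 3))
        solution = cluster_engine.kmeans_best(
            X_sel, k, n_restarts=ccfg.get("n_restarts", 50), seed=config.seed)
        profiles = cluster_engine.cluster_profiles(solution.assignment, X_sel)
        curve_path = out / "did_curve.csv"
        _write(curve.to_frame(), curve_path)
        assign_path = out / "assignment.csv"
        _write(pd.DataFrame({"location_id": locations["id"],
                             "cluster": solution.assignment + 1}), assign_path)
        prof_path = out / "cluster_profiles.csv"
        _write(profiles, prof_path, index=True)
        record("cluster", {"did_curve": curve_path, "assignment": assign_path,
                           "profiles": prof_path},
               k=int(k), total_ssw=solution.total_ssw)

        # -- allocate ----------------------------------------------------
        counts = site_allocator.ClusterCounts.from_assignment(
            locations, solution.assignment + 1)
        pools = {
            c + 1: grp.tolist() for c, grp in
            locations.loc[locations["role"] == "candidate", "id"]
            .groupby(solution.assignment[
                (locations["role"] == "candidate").to_numpy()])}
        acfg = config.allocate
        result = site_allocator.allocate(
            counts, n_new=acfg.get("n_new", 20),
            tie_rule=acfg.get("tie_rule", "lowest_index"),
            seed=config.seed, candidate_pools=pools)
        counts_path = out / "cluster_counts.csv"
        _write(counts.counts, counts_path)
        new_path = out / "new_sites.csv"
        _write(pd.DataFrame({"cluster": list(result.new_sites),
                             "n_new": list(result.new_sites.values())}),
               new_path)
        picks_path = out / "picks.csv"
        _write(result.picks, picks_path)
        chosen_path = out / "chosen_candidates.csv"
        _write(pd.DataFrame({"location_id": result.chosen_ids}), chosen_path)
        record("allocate", {"cluster_counts": counts_path,
                            "new_sites": new_path, "picks": picks_path,
                            "chosen": chosen_path},
               n_new=result.n_placed)

        # -- stability ---------------------------------------------------
        scfg = config.stability
        rep = stability.subsample_stability(
            X_sel, k, solution.assignment,
            n_reps=scfg.get("n_reps", 20),
            keep_frac=scfg.get("keep_frac", 0.90),
            n_restarts=scfg.get("n_restarts", 10), seed=config.seed)
        stab_path = out / "stability.csv"
        _write(rep.to_frame(), stab_path)
        record("stability", {"ari": stab_path},
               mean_ari=rep.mean, frac_excellent=rep.frac_excellent,
               frac_below_moderate=rep.frac_below_moderate)
    except Exception as err:
        stage = _next_stage(manifest)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


_STAGE_ORDER = ["simulate", "qc", "features", "lur", "cluster", "allocate",
                "stability"]


def _next_stage(manifest: dict) -> str:
    done = set(manifest["stages"])
    for s in _STAGE_ORDER:
        if s not in done:
            return s
    return "finalize"


def report(out_dir) -> str:
    """Human-readable design summary from a completed run directory."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    lines: list[str] = []

    lur_info = manifest["stages"]["lur"]
    model = lur_model.LurModel.from_json(out / "lur_model.json")
    lines.append("Land use regression (annual average)")
    if model.variables:
        lines.append(f"{'variable':<28}{'std. coef':>12}{'p value':>10}")
        for v in model.variables:
            lines.append(f"{v:<28}{model.standardized[v]:>12.2f}"
                         f"{model.pvalues[v]:>10.3g}")
        lines.append(f"LOOCV R2 = {lur_info['loocv_r2']:.2f}")
    else:
        lines.append("no variables selected (null model)")

    cl = manifest["stages"]["cluster"]
    lines.append("")
    lines.append(f"Clusters: k = {cl['k']} (total SSW {cl['total_ssw']:.1f})")

    counts = pd.read_csv(out / "cluster_counts.csv")
    new = pd.read_csv(out / "new_sites.csv").set_index("cluster")["n_new"]
    lines.append("")
    lines.append(f"{'cluster':>8}{'current':>9}{'subject':>9}"
                 f"{'candidate':>10}{'cur/sub x1e4':>14}{'new sites':>10}")
    for _, row in counts.iterrows():
        ratio = (site_allocator.current_subject_ratio(
            row["n_current"], row["n_subject"])
            if row["n_subject"] > 0 else float("nan"))
        lines.append(f"{row['cluster']:>8}{row['n_current']:>9}"
                     f"{row['n_subject']:>9}{row['n_candidate']:>10}"
                     f"{ratio:>14.1f}{new.get(row['cluster'], 0):>10}")

    st = manifest["stages"]["stability"]
    lines.append("")
    lines.append(f"Stability: mean ARI {st['mean_ari']:.3f}; "
                 f"{100 * st['frac_excellent']:.0f}% of replicates excellent "
                 f"(>=0.90), {100 * st['frac_below_moderate']:.0f}% below "
                 f"moderate (<0.65)")
    return "\n".join(lines)
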