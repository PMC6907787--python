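"""End-to-end orchestration of the analysis sequence.

``run_all`` executes the stages in dependency order: simulate (or load) ->
mock-derived count filter -> timepoint harmonization -> alpha diversity with
Bayesian trend selection per index -> CSS normalization -> Bray-Curtis ->
NMDS (aggregate k=3 and per-treatment k=2) -> phylum aggregation and
prevalence -> random-forest tuning/fit/importance (fecal and cecal subsets
separately) -> ELISA quantification and IgA trend selection -> Spearman
association screen.  Every stage writes tab-separated outputs with a header
recording stage name, seed and parameters, and the manifest records a
SHA-256 checksum per output file.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance, bayes, diversity, forest, immuno, io, simulate
from .errors import ConfigError

__all__ = ["PipelineConfig", "RunManifest", "run_all"]

_PROFILES = {
    "full": bayes.ChainConfig.full_profile,
    "test": bayes.ChainConfig.test_profile,
    "smoke": bayes.ChainConfig.smoke_profile,
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (single master seed)."""

    outdir: str = "vaxbiome_out"
    seed: int = 0
    simulate: bool = True
    sim_overrides: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)  # counts/metadata/taxonomy when simulate off
    stages: dict = field(default_factory=lambda: {
        "filter": True, "alpha_trend": True, "beta": True,
        "taxa": True, "forest": True, "iga": True, "screen": True,
    })
    css_quantile: float = 0.5
    nmds_k_aggregate: int = 3
    nmds_k_treatment: int = 2
    nmds_starts: int = 2
    nmds_max_iter: int = 200
    chain_profile: str = "smoke"
    alpha_responses: tuple = ("observed", "chao1", "shannon", "inv_simpson")
    forest_trees: int = 200
    tune_M: int = 10
    tune_reps: int = 5
    tune_trees: int = 50
    screen_top_k: int = 30
    screen_alpha: float = 0.1
    min_prevalence: float = 0.01

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        bad = set(doc) - known
        if bad:
            raise ConfigError(f"unknown configuration keys: {sorted(bad)}")
        cfg = cls(**doc)
        if cfg.chain_profile not in _PROFILES:
            raise ConfigError(f"unknown chain profile {cfg.chain_profile!r}")
        return cfg


@dataclass
class RunManifest:
    seed: int
    stages: list = field(default_factory=list)

    def record(self, name: str, params: dict, outputs: dict, wall_clock: float):
        self.stages.append({
            "stage": name, "params": params, "outputs": outputs,
            "wall_clock": wall_clock,
        })

    def output_checksums(self) -> dict:
        out = {}
        for st in self.stages:
            out.update(st["outputs"])
        return out

    def write(self, path):
        Path(path).write_text(json.dumps({"seed": self.seed, "stages": self.stages}, indent=1))


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class _Stage:
    """Context helper: collects outputs and records a manifest entry."""

    def __init__(self, manifest: RunManifest, outdir: Path, name: str, params: dict):
        self.manifest = manifest
        self.outdir = outdir
        self.name = name
        self.params = params
        self.outputs = {}
        self.t0 = time.time()

    def meta(self) -> dict:
        return {"stage": self.name, "seed": self.manifest.seed,
                "params": json.dumps(self.params, sort_keys=True)}

    def path(self, fname: str) -> Path:
        return self.outdir / fname

    def register(self, fname: str):
        self.outputs[fname] = _sha256(self.outdir / fname)

    def done(self):
        self.manifest.record(self.name, self.params, self.outputs,
                             round(time.time() - self.t0, 3))


def _fit_trend_table(data: pd.DataFrame, chains: bayes.ChainConfig,
                     weeks) -> tuple[pd.DataFrame, pd.DataFrame, bayes.FitSummary]:
    """Fit the 30-model grid, select by DIC, summarize CIs per treatment/week."""
    fits = []
    for spec in bayes.enumerate_models():
        draws = bayes.gibbs_fit(data, spec, chains=chains)
        fits.append(bayes.fit_summary(draws))
    best = bayes.select_model(fits)
    sel = pd.DataFrame(
        [
            {
                "model": f.model.label(),
                "degree": f.model.degree,
                "intercept": f.model.intercept,
                "trend": f.model.trend,
                "Dbar": f.dbar,
                "pD": f.p_d,
                "DIC": f.dic,
                "max_rhat": f.rhat.dropna().max(),
                "converged": f.converged,
                "selected": f is best,
            }
            for f in fits
        ]
    )
    ci_rows = []
    for t in best.draws.treatments:
        for w in weeks:
            lo, med, hi = bayes.expected_response_ci(best.draws, t, w)
            ci_rows.append((t, w, lo, med, hi))
    ci = pd.DataFrame(ci_rows, columns=["treatment", "week", "lower", "median", "upper"])
    return sel, ci, best


def run_all(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed)
    chains = _PROFILES[config.chain_profile](seed=config.seed)

    try:
        # ---- stage: inputs --------------------------------------------
        st = _Stage(manifest, outdir, "inputs", {"simulate": config.simulate})
        if config.simulate:
            sim_cfg = simulate.SimConfig(seed=config.seed, **config.sim_overrides)
            counts, samples, taxonomy, truth = simulate.simulate_study(sim_cfg)
            mock, members = simulate.simulate_mock_samples(sim_cfg, truth)
            iga = simulate.simulate_iga(sim_cfg, truth) if config.stages.get("iga") else None
            plate = simulate.simulate_elisa_plate(sim_cfg) if config.stages.get("iga") else None
            io.write_count_table(counts, st.path("counts.tsv"), meta=st.meta())
            io.write_table(samples, st.path("samples.tsv"), meta=st.meta())
            io.write_table(taxonomy, st.path("taxonomy.tsv"), meta=st.meta())
            io.write_count_table(mock, st.path("mock.tsv"), meta=st.meta())
            truth.to_json(st.path("ground_truth.json"))
            for f in ("counts.tsv", "samples.tsv", "taxonomy.tsv", "mock.tsv",
                      "ground_truth.json"):
                st.register(f)
            if iga is not None:
                io.write_table(iga, st.path("iga.tsv"), meta=st.meta())
                st.register("iga.tsv")
        else:
            counts = io.read_count_table(config.paths["counts"])
            samples = io.read_table(config.paths["metadata"])
            taxonomy = io.read_table(config.paths["taxonomy"])
            mock = io.read_count_table(config.paths["mock"]) if "mock" in config.paths else None
            members = (
                Path(config.paths["mock_members"]).read_text().split()
                if "mock_members" in config.paths else []
            )
            iga = io.read_table(config.paths["iga"]) if "iga" in config.paths else None
            plate = None
        st.done()

        # ---- stage: mock-based filter ---------------------------------
        if config.stages.get("filter") and mock is not None:
            st = _Stage(manifest, outdir, "filter", {})
            threshold = abundance.mock_based_cutoff(mock, members)
            counts = abundance.apply_count_threshold(counts, threshold)
            st.params["threshold"] = threshold
            io.write_count_table(counts, st.path("counts_filtered.tsv"), meta=st.meta())
            st.register("counts_filtered.tsv")
            st.done()

        fecal = samples[samples["sample_type"] == "fecal"]
        cecal = samples[samples["sample_type"] == "cecal"]
        weeks_shared = sorted(
            set(fecal.loc[fecal["treatment"] != "RB", "week"].unique())
        )

        # ---- stage: alpha diversity + trend selection -----------------
        if config.stages.get("alpha_trend"):
            st = _Stage(manifest, outdir, "alpha_trend",
                        {"profile": config.chain_profile})
            harmonized, dropped = abundance.harmonize_timepoints(fecal)
            st.params["dropped_rb_rows"] = dropped
            alpha = diversity.alpha_table(counts.loc[harmonized.index])
            io.write_table(alpha, st.path("alpha.tsv"), meta=st.meta())
            st.register("alpha.tsv")
            for response in config.alpha_responses:
                data = harmonized.assign(value=alpha[response])[
                    ["value", "treatment", "mouse", "week"]
                ]
                sel, ci, _ = _fit_trend_table(data, chains, weeks_shared)
                io.write_table(sel, st.path(f"trend_{response}_models.tsv"),
                               meta=st.meta(), index=False)
                io.write_table(ci, st.path(f"trend_{response}_ci.tsv"),
                               meta=st.meta(), index=False)
                st.register(f"trend_{response}_models.tsv")
                st.register(f"trend_{response}_ci.tsv")
            st.done()

        # ---- stage: beta diversity ------------------------------------
        norm = None
        if config.stages.get("beta"):
            st = _Stage(manifest, outdir, "beta",
                        {"css_quantile": config.css_quantile,
                         "k_aggregate": config.nmds_k_aggregate,
                         "k_treatment": config.nmds_k_treatment})
            active = counts.loc[fecal.index]
            active = active.loc[active.sum(axis=1) > 0]
            norm = abundance.css_normalize(active, config.css_quantile)
            dist = diversity.bray_curtis(norm.data)
            ord_all = diversity.nmds(
                dist, k=config.nmds_k_aggregate, n_starts=config.nmds_starts,
                max_iter=config.nmds_max_iter, seed=config.seed,
            )
            coords = pd.DataFrame(
                ord_all.coordinates, index=ord_all.sample_ids,
                columns=[f"axis{i + 1}" for i in range(config.nmds_k_aggregate)],
            )
            coords["stress"] = ord_all.stress
            io.write_table(coords, st.path("nmds_aggregate.tsv"), meta=st.meta())
            st.register("nmds_aggregate.tsv")
            for t, group in fecal.loc[fecal.index.isin(norm.data.index)].groupby("treatment"):
                sub = norm.data.loc[group.index]
                ord_t = diversity.nmds(
                    diversity.bray_curtis(sub), k=config.nmds_k_treatment,
                    n_starts=config.nmds_starts, max_iter=config.nmds_max_iter,
                    seed=config.seed,
                )
                ct = pd.DataFrame(
                    ord_t.coordinates, index=ord_t.sample_ids,
                    columns=[f"axis{i + 1}" for i in range(config.nmds_k_treatment)],
                )
                ct["stress"] = ord_t.stress
                io.write_table(ct, st.path(f"nmds_{t}.tsv"), meta=st.meta())
                st.register(f"nmds_{t}.tsv")
            st.done()

        # ---- stage: taxonomic aggregation -----------------------------
        if config.stages.get("taxa"):
            st = _Stage(manifest, outdir, "taxa",
                        {"min_prevalence": config.min_prevalence})
            active = counts.loc[fecal.index]
            active = active.loc[active.sum(axis=1) > 0]
            phyla = abundance.aggregate_taxa(active, taxonomy, "phylum")
            rel = abundance.relative_abundance(phyla)
            keep = abundance.prevalent_taxa(rel, config.min_prevalence)
            bars = (
                rel[keep]
                .join(fecal[["treatment", "week"]])
                .groupby(["treatment", "week"])
                .mean()
            )
            io.write_table(bars, st.path("phylum_bars.tsv"), meta=st.meta())
            st.register("phylum_bars.tsv")
            st.done()

        # ---- stage: random forest -------------------------------------
        top_features = None
        if config.stages.get("forest"):
            st = _Stage(manifest, outdir, "forest",
                        {"n_trees": config.forest_trees, "tune_M": config.tune_M,
                         "tune_reps": config.tune_reps})
            if norm is None:
                active = counts.loc[fecal.index]
                active = active.loc[active.sum(axis=1) > 0]
                norm = abundance.css_normalize(active, config.css_quantile)
            for label, subset in (("fecal", fecal), ("cecal", cecal)):
                idx = subset.index.intersection(
                    norm.data.index if label == "fecal" else counts.index
                )
                if label == "fecal":
                    feats = norm.data.loc[idx].copy()
                else:
                    sub_counts = counts.loc[idx]
                    sub_counts = sub_counts.loc[sub_counts.sum(axis=1) > 0]
                    idx = sub_counts.index
                    feats = abundance.css_normalize(
                        sub_counts, config.css_quantile
                    ).data
                labels = subset.loc[idx, "treatment"].to_numpy()
                if len(np.unique(labels)) < 2 or len(idx) < 10:
                    continue
                feats["week"] = subset.loc[idx, "week"].to_numpy(dtype=float)
                X = feats.to_numpy(dtype=float)
                tune = forest.tune_feature_count(
                    X, labels, M=min(config.tune_M, X.shape[1]),
                    reps=config.tune_reps, n_trees=config.tune_trees,
                    seed=config.seed,
                )
                fit = forest.fit_forest(
                    X, labels, n_trees=config.forest_trees,
                    mtry=tune.chosen_m, seed=config.seed,
                )
                oob = forest.oob_summary(fit, labels)
                imp = forest.gini_importance(fit, feature_names=list(feats.columns))
                top = imp.head(config.screen_top_k)
                imp_table = top.rename("gini").to_frame()
                lineage = taxonomy.reindex(top.index)
                imp_table = imp_table.join(lineage)
                tune_table = pd.DataFrame(
                    {"median_oob": tune.medians, "mean_oob": tune.means}
                )
                tune_table["chosen"] = tune_table.index == tune.chosen_m
                io.write_table(tune_table, st.path(f"rf_{label}_tune.tsv"), meta=st.meta())
                io.write_table(oob.confusion, st.path(f"rf_{label}_confusion.tsv"),
                               meta=st.meta())
                io.write_table(imp_table, st.path(f"rf_{label}_importance.tsv"),
                               meta=st.meta())
                st.params[f"{label}_chosen_m"] = tune.chosen_m
                st.params[f"{label}_oob_error"] = round(float(oob.error), 4)
                for f in (f"rf_{label}_tune.tsv", f"rf_{label}_confusion.tsv",
                          f"rf_{label}_importance.tsv"):
                    st.register(f)
                if label == "fecal":
                    top_features = [f for f in top.index if f != "week"]
            st.done()

        # ---- stage: ELISA / IgA trends --------------------------------
        if config.stages.get("iga") and iga is not None:
            st = _Stage(manifest, outdir, "iga", {"profile": config.chain_profile})
            if plate is not None:
                titers = immuno.titer_table(plate)
                io.write_table(titers, st.path("elisa_titers.tsv"), meta=st.meta())
                st.register("elisa_titers.tsv")
            total = iga.dropna(subset=["total_iga"]).assign(value=lambda d: d["total_iga"])
            sel, ci, _ = _fit_trend_table(
                total[["value", "treatment", "mouse", "week"]], chains, weeks_shared
            )
            io.write_table(sel, st.path("trend_total_iga_models.tsv"),
                           meta=st.meta(), index=False)
            io.write_table(ci, st.path("trend_total_iga_ci.tsv"),
                           meta=st.meta(), index=False)
            spec_data = iga.dropna(subset=["mper_iga"]).copy()
            spec_data["value"] = immuno.log_transform_specific(spec_data["mper_iga"])
            sel2, ci2, _ = _fit_trend_table(
                spec_data[["value", "treatment", "mouse", "week"]], chains, weeks_shared
            )
            io.write_table(sel2, st.path("trend_mper_iga_models.tsv"),
                           meta=st.meta(), index=False)
            io.write_table(ci2, st.path("trend_mper_iga_ci.tsv"),
                           meta=st.meta(), index=False)
            for f in ("trend_total_iga_models.tsv", "trend_total_iga_ci.tsv",
                      "trend_mper_iga_models.tsv", "trend_mper_iga_ci.tsv"):
                st.register(f)
            st.done()

        # ---- stage: association screen --------------------------------
        if config.stages.get("screen") and config.stages.get("iga") and iga is not None:
            st = _Stage(manifest, outdir, "screen",
                        {"alpha": config.screen_alpha, "top_k": config.screen_top_k})
            if norm is None:
                active = counts.loc[fecal.index]
                active = active.loc[active.sum(axis=1) > 0]
                norm = abundance.css_normalize(active, config.css_quantile)
            feats = norm.data
            if top_features:
                feats = feats[[c for c in top_features if c in feats.columns]]
            alpha_f = diversity.alpha_table(counts.loc[feats.index])
            feats = feats.join(alpha_f)
            iga_vars = iga[["total_iga", "mper_iga"]]
            screen = immuno.correlation_screen(
                feats, iga_vars, samples.loc[feats.index],
                alpha_level=config.screen_alpha,
            )
            io.write_table(screen, st.path("spearman_screen.tsv"),
                           meta=st.meta(), index=False)
            st.register("spearman_screen.tsv")
            st.done()
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest
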