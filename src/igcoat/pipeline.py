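"""End-to-end orchestration: simulate/load -> preprocess -> flow model ->
taxa model -> diversity, driven by a single validated config with
deterministic per-stage seeds and a run manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

import igcoat
from igcoat import diversity as div
from igcoat import preprocess as pp
from igcoat import synthetic_data as syn
from igcoat import taxa_model as tm
from igcoat.feature_table import FeatureTable, validate_metadata, write_metadata
from igcoat.flow_model import (
    build_design,
    fit_flow_model,
    flow_summary_table,
    glmm_r2,
    predict_proportions,
    validate_flow_counts,
)

log = logging.getLogger("igcoat")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    table: str | None = None
    metadata: str | None = None
    flow: str | None = None
    taxonomy: str | None = None
    out_dir: str = "igcoat_run"


class PreprocessConfig(_Strict):
    min_reads: int = 500
    min_total: int = 10
    drop_singletons: bool = True
    decontam_threshold: float = 0.5
    batch_key: str | None = "run"
    rarefaction_depth: int = 1000


class McmcConfig(_Strict):
    chains: int = 4
    warmup: int = 500
    draws: int = 500


class FlowConfig(_Strict):
    mcmc: McmcConfig = Field(default_factory=McmcConfig)
    interval: float = 0.90
    beta_prior_sd: float | None = None


class TaxaConfig(_Strict):
    mcmc: McmcConfig = Field(default_factory=McmcConfig)
    top_k: int = 11
    baseline: str = "presort"       # or "ig_neg"
    mode: str = "population"
    prior_sd: float = 5.0
    per_ig_class: bool = True


class DiversityConfig(_Strict):
    distance: str = "aitchison"     # or "braycurtis"
    permutations: int = 999
    permanova_groups: str = "cohort"


class SimulateConfig(_Strict):
    n_healthy: int = 11
    n_dre: int = 11
    n_are: int = 8
    n_ire: int = 3
    n_incomplete: int = 1
    replicates_per_sample: int = 2
    n_negative_controls: int = 4
    beta_flow: dict[str, float] = Field(default_factory=dict)
    sigma_dog_flow: float = 0.5
    sigma_ig_dog: float = 0.3
    flow_trials: int = 10_000
    taxa: list[str] = Field(
        default_factory=lambda: ["taxon1", "taxon2", "taxon3"]
    )
    beta_taxa: dict[str, dict[str, float]] = Field(default_factory=dict)
    sigma_dog_taxa: float = 0.3
    depth_mean: float = 14_000.0
    contaminant_taxa: list[str] = Field(
        default_factory=lambda: ["contamA", "contamB"]
    )
    contaminant_load: float = 1e-4


class PipelineConfig(_Strict):
    seed: int = 0
    paths: PathsConfig = Field(default_factory=PathsConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    flow: FlowConfig = Field(default_factory=FlowConfig)
    taxa: TaxaConfig = Field(default_factory=TaxaConfig)
    diversity: DiversityConfig = Field(default_factory=DiversityConfig)
    simulate: SimulateConfig | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)


class StageError(RuntimeError):
    """Pipeline failure carrying the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    order = ["simulate", "rarefy", "flow", "taxa", "permanova", "predict"]
    children = np.random.SeedSequence(master).spawn(len(order))
    return int(children[order.index(stage)].generate_state(1)[0])


def validate_inputs(
    table: FeatureTable, metadata: pd.DataFrame, flow: pd.DataFrame | None
) -> dict:
    """Cross-reference and domain checks; returns itemized findings."""
    findings: list[str] = []
    try:
        validate_metadata(metadata)
    except ValueError as exc:
        findings.append(str(exc))
        return {"passed": False, "findings": findings}

    md_ids = set(metadata["sample_id"])
    for sid in table.sample_ids:
        if sid not in md_ids:
            findings.append(f"table sample {sid!r} missing from metadata")
    for sid in md_ids - set(table.sample_ids):
        findings.append(f"metadata sample {sid!r} missing from table")
    if (table.counts < 0).any():
        findings.append("negative counts in feature table")
    if not np.issubdtype(table.counts.dtype, np.integer):
        if not np.allclose(table.counts, np.round(table.counts)):
            findings.append("non-integer counts in feature table")
    real = metadata[~metadata["is_control"].astype(bool)]
    for col, domain in (
        ("cohort", set(syn.COHORTS)),
        ("stage", set(syn.STAGES)),
        ("ig_class", set(syn.IG_CLASSES)),
        ("fraction", set(syn.FRACTIONS)),
    ):
        bad = set(real[col].astype(str)) - domain
        if bad:
            findings.append(f"unknown {col} level(s): {sorted(bad)}")
    if flow is not None:
        try:
            validate_flow_counts(flow)
        except ValueError as exc:
            findings.append(str(exc))
        else:
            dogs_md = set(real["dog_id"].astype(str))
            for d in set(flow["dog_id"].astype(str)) - dogs_md:
                findings.append(f"flow dog {d!r} missing from metadata")
    return {"passed": not findings, "findings": findings}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write reports into the output directory.

    Returns the run manifest (also written as ``manifest.json``).
    Idempotent for a fixed config: numeric outputs are byte-identical
    across reruns.
    """
    out = Path(config.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": igcoat.__version__, "seed": config.seed,
                      "stages": {}}

    # ------------------------------------------------------------- inputs
    if config.simulate is not None:
        sim = config.simulate
        design, metadata = syn.simulate_cohort(
            sim.n_healthy, sim.n_dre, sim.n_are, sim.n_ire,
            seed=_stage_seed(config.seed, "simulate"),
            n_incomplete=sim.n_incomplete,
            replicates_per_sample=sim.replicates_per_sample,
            n_negative_controls=sim.n_negative_controls,
        )
        params = syn.GeneratorParams(
            beta_flow=sim.beta_flow,
            sigma_dog_flow=sim.sigma_dog_flow,
            sigma_ig_dog=sim.sigma_ig_dog,
            flow_trials=sim.flow_trials,
            taxa=list(sim.taxa),
            beta_taxa=sim.beta_taxa,
            sigma_dog_taxa=sim.sigma_dog_taxa,
            depth_mean=sim.depth_mean,
            contaminant_taxa=list(sim.contaminant_taxa),
            contaminant_load=sim.contaminant_load,
            seed=_stage_seed(config.seed, "simulate"),
        )
        flow = syn.simulate_flow_counts(design, params)
        table, truth = syn.simulate_fraction_counts(design, params)
        table, contam_truth = syn.spike_contaminants(table, metadata, params)
        truth["contaminants"] = contam_truth
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        table.write_tsv(out / "simulated_table.tsv")
        write_metadata(metadata, out / "simulated_metadata.tsv")
        flow.to_csv(out / "simulated_flow.tsv", sep="\t", index=False)
        manifest["stages"]["simulate"] = {
            "dogs": len(design.dogs),
            "samples": table.n_samples,
            "features": table.n_features,
        }
        taxonomy = {f: f for f in table.feature_ids}
    else:
        p = config.paths
        if not (p.table and p.metadata):
            raise StageError("inputs", "missing_input",
                            "need table+metadata paths or a simulation block")
        table = FeatureTable.read_tsv(p.table)
        metadata = pd.read_csv(p.metadata, sep="\t",
                               dtype={"sample_id": str, "dog_id": str})
        metadata["is_control"] = metadata["is_control"].astype(bool)
        flow = pd.read_csv(p.flow, sep="\t") if p.flow else None
        if p.taxonomy:
            taxdf = pd.read_csv(p.taxonomy, sep="\t")
            taxonomy = dict(zip(taxdf.iloc[:, 0].astype(str),
                                taxdf.iloc[:, 1].astype(str)))
        else:
            taxonomy = {f: f for f in table.feature_ids}

    report = validate_inputs(table, metadata, flow)
    manifest["stages"]["validate"] = report
    if not report["passed"]:
        raise StageError("validate", "invalid_input",
                         "; ".join(report["findings"][:5]))

    # --------------------------------------------------------- preprocess
    cfg = config.preprocess
    counts_log = {"input": {"features": table.n_features,
                            "samples": table.n_samples}}
    try:
        t = pp.filter_low_depth(table, cfg.min_reads)
        counts_log["depth_filter"] = {"features": t.n_features,
                                      "samples": t.n_samples}
        t = pp.filter_rare_features(t, cfg.min_total)
        counts_log["abundance_filter"] = {"features": t.n_features,
                                          "samples": t.n_samples}
        md_t = metadata[metadata["sample_id"].isin(t.sample_ids)]
        results, t = pp.prevalence_decontam(
            t, md_t, cfg.decontam_threshold, cfg.batch_key
        )
        pp.contam_report(results).to_csv(out / "decontam.tsv", sep="\t",
                                         index=False)
        counts_log["decontam"] = {"features": t.n_features,
                                  "samples": t.n_samples}
        real_ids = set(
            metadata.loc[~metadata["is_control"].astype(bool), "sample_id"]
        )
        t = t.select_samples([s for s in t.sample_ids if s in real_ids])
        t = pp.merge_replicates(t, metadata)
        counts_log["merge"] = {"features": t.n_features,
                               "samples": t.n_samples}
        t = pp.filter_rare_features(t, 0, drop_singletons=cfg.drop_singletons)
        counts_log["singleton_prune"] = {"features": t.n_features,
                                         "samples": t.n_samples}
    except pp.EmptyTableError as exc:
        raise StageError("preprocess", "empty_table", str(exc)) from exc
    merged_meta = _merged_metadata(metadata)
    rarefied = pp.rarefy(t, cfg.rarefaction_depth,
                         seed=_stage_seed(config.seed, "rarefy"))
    counts_log["rarefy"] = {"features": rarefied.n_features,
                            "samples": rarefied.n_samples}
    manifest["stages"]["preprocess"] = counts_log
    t.write_tsv(out / "table_processed.tsv")
    rarefied.write_tsv(out / "table_rarefied.tsv")

    # --------------------------------------------------------- flow model
    if flow is not None:
        fdesign = build_design(flow, factors=["ig_class", "cohort", "stage"])
        fdraws = fit_flow_model(
            flow, fdesign,
            n_chains=config.flow.mcmc.chains,
            n_warmup=config.flow.mcmc.warmup,
            n_draws=config.flow.mcmc.draws,
            seed=_stage_seed(config.seed, "flow"),
            beta_prior_sd=config.flow.beta_prior_sd,
        )
        flow_summary_table(fdraws, fdesign, config.flow.interval).to_csv(
            out / "flow_summary.tsv", sep="\t", index=False
        )
        from igcoat.design import reference_grid

        predict_proportions(
            fdraws, fdesign, reference_grid(fdesign), config.flow.interval
        ).to_csv(out / "flow_predictions.tsv", sep="\t", index=False)
        marg, cond = glmm_r2(fdraws, fdesign)
        manifest["stages"]["flow_model"] = {
            "r2_marginal": marg,
            "r2_conditional": cond,
            "converged": fdraws.sampler_meta.get("converged"),
        }

    # --------------------------------------------------------- taxa model
    agg = pp.aggregate_top_taxa(t, taxonomy, k=config.taxa.top_k)
    spec = tm.TaxaModelSpec(
        taxa=agg.feature_ids[:-1], prior_sd=config.taxa.prior_sd
    )
    enrich_frames = []
    ig_groups = (
        sorted(merged_meta.loc[~merged_meta["is_control"], "ig_class"]
               .astype(str).unique())
        if config.taxa.per_ig_class
        else [None]
    )
    for ig in ig_groups:
        sub = merged_meta if ig is None else merged_meta[
            merged_meta["is_control"] | (merged_meta["ig_class"] == ig)
        ]
        sub_table = agg.select_samples(
            [s for s in agg.sample_ids if s in set(sub["sample_id"])]
        )
        tdraws, tdesign = tm.fit_taxa_model(
            sub_table, sub, spec,
            n_chains=config.taxa.mcmc.chains,
            n_warmup=config.taxa.mcmc.warmup,
            n_draws=config.taxa.mcmc.draws,
            seed=_stage_seed(config.seed, "taxa"),
        )
        frame = tm.enrichment_summary(
            tdraws, tdesign, spec,
            baseline_fraction=config.taxa.baseline,
            ig_class=ig,
            mode=config.taxa.mode,
        )
        enrich_frames.append(frame)
    enrichment = pd.concat(enrich_frames, ignore_index=True)
    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    tm.raw_palm_index(
        agg, merged_meta, baseline_fraction=config.taxa.baseline,
        group_keys=["cohort", "stage", "ig_class"],
    ).to_csv(out / "raw_palm_index.tsv", sep="\t", index=False)
    manifest["stages"]["taxa_model"] = {
        "taxa": spec.taxa, "ig_groups": [g or "joint" for g in ig_groups]
    }

    # ---------------------------------------------------------- diversity
    h = div.shannon_per_sample(rarefied)
    h = h.merge(merged_meta, on="sample_id", how="left")
    h.to_csv(out / "shannon.tsv", sep="\t", index=False)
    div_stage: dict = {}
    try:
        lmm = div.fit_shannon_lmm(h)
        mm = div.marginal_means(lmm, ["cohort", "stage"])
        mm.to_csv(out / "shannon_marginal_means.tsv", sep="\t", index=False)
        marg, cond = div.lmm_r2(lmm)
        div_stage["shannon_r2"] = {"marginal": marg, "conditional": cond}
    except ValueError as exc:
        div_stage["shannon_lmm"] = f"skipped: {exc}"

    samples_x_features = rarefied.counts.T
    if config.diversity.distance == "braycurtis":
        dist = div.bray_curtis(samples_x_features, rarefied.sample_ids)
    else:
        dist = div.aitchison_distance(samples_x_features, rarefied.sample_ids)
    dist.write_tsv(out / "distance.tsv")
    dmeta = merged_meta.set_index("sample_id").loc[rarefied.sample_ids]
    groups = dmeta[config.diversity.permanova_groups].astype(str)
    if groups.nunique() >= 2:
        res = div.permanova(
            dist, groups, n_perm=config.diversity.permutations,
            seed=_stage_seed(config.seed, "permanova"),
        )
        div_stage["permanova"] = res
    bc = div.bray_curtis(samples_x_features, rarefied.sample_ids)
    tree = div.upgma(bc)
    (out / "upgma.nwk").write_text(tree.to_newick() + "\n")
    manifest["stages"]["diversity"] = div_stage

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _merged_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Metadata for merged (run/replicate-collapsed) sample IDs."""
    real = metadata[~metadata["is_control"].astype(bool)].copy()
    real["sample_id"] = (
        real[["dog_id", "stage", "ig_class", "fraction"]]
        .astype(str).agg(".".join, axis=1)
    )
    merged = real.drop_duplicates("sample_id").copy()
    merged["run"] = "merged"
    merged["replicate"] = 1
    return merged.reset_index(drop=True)
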