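"""Ground-truth-known generators for Ig-sort experiments.

Emulates the study layout — healthy plus DRE/ARE/IRE cohorts, before/after
stages, IgA/IgG classes, pre-sort / Ig+ / Ig- fractions, two sequencing
runs with duplicates and per-run negative controls — with binomial coating
counts under dog-level logit random effects and multinomial taxon counts
under dog-level random intercepts. Every generated quantity a recovery
test could need (true coating probabilities, true condition proportions,
true enrichment ratios, planted contaminants) is returned in a truth
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from igcoat.design import build_design
from igcoat.feature_table import (
    COHORTS,
    FRACTIONS,
    IG_CLASSES,
    STAGES,
    FeatureTable,
)

_FLOW_STREAM, _FRACTION_STREAM, _CONTAM_STREAM = 0, 1, 2


def _substream(seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible child stream of the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[index])


@dataclass
class CohortDesign:
    """Cohort layout: which dogs exist, and which cells they occupy."""

    dogs: list[tuple[str, str]]                # (dog_id, cohort)
    dog_stages: dict[str, list[str]]           # per-dog stages (may be partial)
    stages: tuple[str, ...] = STAGES
    ig_classes: tuple[str, ...] = IG_CLASSES
    fractions: tuple[str, ...] = FRACTIONS
    runs: tuple[str, ...] = ("run1", "run2")
    replicates_per_sample: int = 2
    n_negative_controls: int = 4

    def __post_init__(self) -> None:
        if not self.dogs:
            raise ValueError("design must contain at least one dog")
        for dog_id, cohort in self.dogs:
            if cohort not in COHORTS:
                raise ValueError(f"unknown cohort {cohort!r} for dog {dog_id!r}")
        for dog_id, _ in self.dogs:
            if not self.dog_stages.get(dog_id):
                raise ValueError(f"dog {dog_id!r} appears in no stage")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.n_negative_controls < 0:
            raise ValueError("n_negative_controls must be >= 0")

    @property
    def dog_ids(self) -> list[str]:
        return [d for d, _ in self.dogs]

    def cohort_of(self, dog_id: str) -> str:
        for d, c in self.dogs:
            if d == dog_id:
                return c
        raise KeyError(dog_id)


@dataclass
class GeneratorParams:
    """Data-generating counterparts of the model parameters."""

    beta_flow: dict[str, float] = field(default_factory=dict)
    sigma_dog_flow: float = 0.5
    sigma_ig_dog: float = 0.3
    flow_trials: int = 10_000
    taxa: list[str] = field(default_factory=lambda: ["taxon1", "taxon2", "taxon3"])
    beta_taxa: dict[str, dict[str, float]] = field(default_factory=dict)
    sigma_dog_taxa: float = 0.3
    depth_mean: float = 14_000.0
    contaminant_taxa: list[str] | dict[str, list[str]] = field(
        default_factory=lambda: ["contamA", "contamB"]
    )
    # reads leaked into true samples; keep small so per-sample presence
    # stays stochastic and prevalence-based detection has signal
    contaminant_load: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_dog_flow < 0 or self.sigma_ig_dog < 0 or self.sigma_dog_taxa < 0:
            raise ValueError("random-effect SDs must be >= 0")
        if self.flow_trials < 1:
            raise ValueError("flow_trials must be >= 1")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        if not (0.0 <= self.contaminant_load < 1.0):
            raise ValueError("contaminant_load must be in [0, 1)")
        if not self.taxa:
            raise ValueError("at least one modelled taxon is required")
        unknown = set(self.beta_taxa) - set(self.taxa)
        if unknown:
            raise ValueError(f"beta_taxa given for unknown taxa: {sorted(unknown)}")

    def contaminants_for_run(self, run: str) -> list[str]:
        if isinstance(self.contaminant_taxa, dict):
            return list(self.contaminant_taxa.get(run, []))
        return list(self.contaminant_taxa)

    def all_contaminants(self) -> list[str]:
        if isinstance(self.contaminant_taxa, dict):
            seen: list[str] = []
            for taxa in self.contaminant_taxa.values():
                seen.extend(t for t in taxa if t not in seen)
            return seen
        return list(self.contaminant_taxa)


# ---------------------------------------------------------------------------
# Cohort / metadata
# ---------------------------------------------------------------------------

def design_metadata(design: CohortDesign) -> pd.DataFrame:
    """One metadata row per dog x stage x Ig x fraction x replicate, plus
    per-run negative controls. Replicates alternate between runs."""
    rows = []
    for dog_id, cohort in design.dogs:
        for stage in design.dog_stages[dog_id]:
            for ig in design.ig_classes:
                for fraction in design.fractions:
                    for rep in range(1, design.replicates_per_sample + 1):
                        run = design.runs[(rep - 1) % len(design.runs)]
                        rows.append(
                            {
                                "sample_id": f"{dog_id}.{stage}.{ig}.{fraction}.r{rep}",
                                "dog_id": dog_id,
                                "cohort": cohort,
                                "stage": stage,
                                "ig_class": ig,
                                "fraction": fraction,
                                "run": run,
                                "replicate": rep,
                                "is_control": False,
                            }
                        )
    for run in design.runs:
        for i in range(1, design.n_negative_controls + 1):
            rows.append(
                {
                    "sample_id": f"neg.{run}.{i}",
                    "dog_id": f"ctrl.{run}.{i}",
                    "cohort": "control",
                    "stage": "control",
                    "ig_class": "control",
                    "fraction": "control",
                    "run": run,
                    "replicate": 1,
                    "is_control": True,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    n_healthy: int,
    n_dre: int,
    n_are: int,
    n_ire: int,
    seed: int,
    *,
    n_incomplete: int = 0,
    replicates_per_sample: int = 2,
    n_negative_controls: int = 4,
) -> tuple[CohortDesign, pd.DataFrame]:
    """Build a cohort with the given group sizes and its sample metadata.

    `n_incomplete` dogs (chosen deterministically from the diseased dogs
    under `seed`) provide only 'before' samples, mirroring drop-out.
    """
    counts = {"healthy": n_healthy, "DRE": n_dre, "ARE": n_are, "IRE": n_ire}
    if any(v < 0 for v in counts.values()):
        raise ValueError("cohort sizes must be >= 0")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty design: at least one dog is required")

    dogs: list[tuple[str, str]] = []
    for cohort in ("healthy", "DRE", "ARE", "IRE"):
        for i in range(1, counts[cohort] + 1):
            dogs.append((f"{cohort}{i:02d}", cohort))

    rng = np.random.default_rng(seed)
    diseased = [d for d, c in dogs if c != "healthy"]
    if n_incomplete > len(diseased):
        raise ValueError("n_incomplete exceeds the number of diseased dogs")
    incomplete = set(
        rng.choice(diseased, size=n_incomplete, replace=False)
    ) if n_incomplete else set()

    dog_stages = {
        d: (["before"] if d in incomplete else list(STAGES)) for d, _ in dogs
    }
    design = CohortDesign(
        dogs=dogs,
        dog_stages=dog_stages,
        replicates_per_sample=replicates_per_sample,
        n_negative_controls=n_negative_controls,
    )
    return design, design_metadata(design)


# ---------------------------------------------------------------------------
# Flow cytometry counts
# ---------------------------------------------------------------------------

def _flow_frame(design: CohortDesign) -> pd.DataFrame:
    rows = []
    for dog_id, cohort in design.dogs:
        for stage in design.dog_stages[dog_id]:
            for ig in design.ig_classes:
                rows.append(
                    {"dog_id": dog_id, "cohort": cohort, "stage": stage, "ig_class": ig}
                )
    return pd.DataFrame(rows)


def _resolve_beta(term_names: list[str], beta: dict[str, float]) -> np.ndarray:
    unknown = set(beta) - set(term_names)
    if unknown:
        raise ValueError(
            f"coefficients given for unknown design terms: {sorted(unknown)}; "
            f"valid terms: {term_names}"
        )
    return np.array([beta.get(t, 0.0) for t in term_names])


def simulate_flow_counts(design: CohortDesign, params: GeneratorParams) -> pd.DataFrame:
    """Binomial coating counts per dog x stage x Ig class.

    p = inv-logit(x'beta + u_dog + v_dog * [Ig == IgG]) with
    u ~ N(0, sigma_dog_flow), v ~ N(0, sigma_ig_dog); positive counts are
    Binomial(flow_trials, p). The true p is stored alongside.
    """
    frame = _flow_frame(design)
    dm = build_design(frame, factors=["ig_class", "cohort", "stage"])
    beta = _resolve_beta(dm.term_names, params.beta_flow)

    rng = _substream(params.seed, _FLOW_STREAM)
    u = rng.normal(0.0, params.sigma_dog_flow, size=dm.n_dogs)
    v = rng.normal(0.0, params.sigma_ig_dog, size=dm.n_dogs)

    eta = dm.fixed @ beta + u[dm.dog_index] + v[dm.dog_index] * dm.ig_indicator
    p = 1.0 / (1.0 + np.exp(-eta))
    positive = rng.binomial(params.flow_trials, p)

    out = frame.copy()
    out["positive"] = positive
    out["total"] = params.flow_trials
    out["true_p"] = p
    return out


# ---------------------------------------------------------------------------
# Ig-sorted fraction counts
# ---------------------------------------------------------------------------

TAXA_FACTORS = ["fraction", "cohort", "stage"]


def _softmax_with_reference(eta: np.ndarray) -> np.ndarray:
    """Baseline-category softmax; reference category has linear predictor 0."""
    full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    full = full - full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    depth = rng.poisson(mean, size=size)
    while (depth == 0).any():
        zero = depth == 0
        depth[zero] = rng.poisson(mean, size=int(zero.sum()))
    return depth


def simulate_fraction_counts(
    design: CohortDesign, params: GeneratorParams
) -> tuple[FeatureTable, dict]:
    """Multinomial taxon counts for every non-control sample.

    Per sample i (dog d): eta_im = x_i' beta_m + u_{d,m} for each modelled
    taxon m (reference 'other' at 0), probabilities by softmax, counts ~
    Multinomial(depth_i, p_i) with depth ~ Poisson(depth_mean) truncated
    at 1. Control samples are emitted as all-zero columns (filled by
    :func:`spike_contaminants`).

    Returns the table and a truth record with true population-level
    proportions per condition and true Ig+/baseline enrichment ratios.
    """
    metadata = design_metadata(design)
    real = metadata[~metadata["is_control"]].reset_index(drop=True)
    if real.empty:
        raise ValueError("design yields no non-control samples")

    dm = build_design(real, factors=TAXA_FACTORS)
    taxa = list(params.taxa)
    m = len(taxa)
    beta = np.zeros((m, dm.n_terms))
    for k, taxon in enumerate(taxa):
        beta[k] = _resolve_beta(dm.term_names, params.beta_taxa.get(taxon, {}))

    rng = _substream(params.seed, _FRACTION_STREAM)
    u = rng.normal(0.0, params.sigma_dog_taxa, size=(dm.n_dogs, m))

    eta = dm.fixed @ beta.T + u[dm.dog_index]          # rows x m
    probs = _softmax_with_reference(eta)               # rows x (m + 1)
    depth = _truncated_poisson(rng, params.depth_mean, len(real))
    counts = np.empty((len(real), m + 1), dtype=np.int64)
    for i in range(len(real)):
        counts[i] = rng.multinomial(depth[i], probs[i])

    feature_ids = taxa + ["other"]
    all_ids = list(metadata["sample_id"])
    table = np.zeros((m + 1, len(all_ids)), dtype=np.int64)
    pos = {s: j for j, s in enumerate(all_ids)}
    for i, sid in enumerate(real["sample_id"]):
        table[:, pos[sid]] = counts[i]

    truth = _fraction_truth(dm, beta, feature_ids, params)
    truth["realized_depths"] = {
        sid: int(d) for sid, d in zip(real["sample_id"], depth)
    }
    return FeatureTable(table, feature_ids, all_ids), truth


def _fraction_truth(dm, beta: np.ndarray, feature_ids: list[str],
                    params: GeneratorParams) -> dict:
    from igcoat.design import reference_grid

    conditions = reference_grid(dm)
    true_props: dict[str, list[float]] = {}
    for cond in conditions:
        p = _softmax_with_reference(dm.encode(cond) @ beta.T)
        key = "|".join(f"{f}={cond[f]}" for f in dm.factors)
        true_props[key] = [float(x) for x in p]

    ratios: dict[str, dict[str, dict[str, float]]] = {}
    non_fraction = [f for f in dm.factors if f != "fraction"]
    for baseline in ("presort", "ig_neg"):
        ratios[baseline] = {}
        groups = {
            tuple(c[f] for f in non_fraction)
            for c in conditions
        }
        for group in sorted(groups):
            cond = dict(zip(non_fraction, group))
            p_bound = _softmax_with_reference(
                dm.encode({**cond, "fraction": "ig_pos"}) @ beta.T
            )
            p_base = _softmax_with_reference(
                dm.encode({**cond, "fraction": baseline}) @ beta.T
            )
            key = "|".join(f"{f}={cond[f]}" for f in non_fraction) or "all"
            ratios[baseline][key] = {
                feature_ids[k]: float(p_bound[k] / p_base[k])
                for k in range(len(feature_ids))
            }
    return {
        "taxa": feature_ids,
        "factors": list(dm.factors),
        "true_proportions": true_props,
        "true_enrichment": ratios,
        "sigma_dog_taxa": params.sigma_dog_taxa,
        "depth_mean": params.depth_mean,
    }


# ---------------------------------------------------------------------------
# Contaminants
# ---------------------------------------------------------------------------

def spike_contaminants(
    table: FeatureTable, metadata: pd.DataFrame, params: GeneratorParams
) -> tuple[FeatureTable, dict]:
    """Fill negative controls with contaminant reads and leak them into
    true samples at rate `contaminant_load`.

    Controls receive Multinomial(depth, uniform over that run's
    contaminants); each true sample receives Binomial(sample depth, load)
    contaminant reads. Returns the augmented table and a truth record of
    planted contaminant identities.
    """
    contaminants = params.all_contaminants()
    overlap = set(contaminants) & set(table.feature_ids)
    if overlap:
        raise ValueError(f"contaminant taxa already present in table: {sorted(overlap)}")
    if not (0.0 <= params.contaminant_load < 1.0):
        raise ValueError("contaminant_load must be in [0, 1)")

    md = metadata.set_index("sample_id")
    rng = _substream(params.seed, _CONTAM_STREAM)

    new_counts = np.zeros((len(contaminants), table.n_samples), dtype=np.int64)
    cont_pos = {c: i for i, c in enumerate(contaminants)}

    for j, sid in enumerate(table.sample_ids):
        row = md.loc[sid]
        run_contams = params.contaminants_for_run(str(row["run"]))
        if not run_contams:
            continue
        probs = np.full(len(run_contams), 1.0 / len(run_contams))
        if bool(row["is_control"]):
            depth = int(_truncated_poisson(rng, params.depth_mean, 1)[0])
            drawn = rng.multinomial(depth, probs)
        else:
            if params.contaminant_load == 0.0:
                continue
            sample_depth = int(table.counts[:, j].sum())
            n_cont = rng.binomial(sample_depth, params.contaminant_load)
            if n_cont == 0:
                continue
            drawn = rng.multinomial(n_cont, probs)
        for name, c in zip(run_contams, drawn):
            new_counts[cont_pos[name], j] += c

    out = FeatureTable(
        np.vstack([table.counts, new_counts]),
        table.feature_ids + contaminants,
        list(table.sample_ids),
    )
    truth = {
        "contaminant_taxa": contaminants,
        "contaminants_by_run": {
            run: params.contaminants_for_run(run)
            for run in sorted(metadata["run"].astype(str).unique())
        },
        "contaminant_load": params.contaminant_load,
    }
    return out, truth
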