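"""Feature-table hygiene: depth/abundance filters, replicate merging,
prevalence-based decontamination with a batch factor, rarefaction, and
family-level top-k aggregation.

Boundary semantics are strict: "< min_reads" and "< min_total" drop, the
boundary value survives. All filters are idempotent; merging and
aggregation conserve total counts exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from igcoat.feature_table import FeatureTable, align_to_metadata


class EmptyTableError(ValueError):
    """Raised when a filter would drop every sample (unless allowed)."""


def filter_low_depth(
    table: FeatureTable, min_reads: int = 500, *, allow_empty: bool = False
) -> FeatureTable:
    """Drop samples whose total count is strictly below `min_reads`."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = table.sample_sums() >= min_reads
    if table.n_samples and not keep.any() and not allow_empty:
        raise EmptyTableError(
            f"all {table.n_samples} samples fall below {min_reads} reads; "
            "pass allow_empty=True to accept an empty table"
        )
    return table.select_samples(keep)


def filter_rare_features(
    table: FeatureTable, min_total: int = 10, drop_singletons: bool = False
) -> FeatureTable:
    """Drop features with total abundance strictly below `min_total`;
    optionally also prune absent/singleton features (row sum <= 1)."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    sums = table.feature_sums()
    keep = sums >= min_total
    if drop_singletons:
        keep &= sums > 1
    return table.select_features(keep)


def merge_replicates(
    table: FeatureTable,
    metadata: pd.DataFrame,
    group_keys: list[str] | None = None,
) -> FeatureTable:
    """Sum counts over samples sharing all `group_keys` (runs/duplicates).

    Output sample IDs are the group labels joined with '.'.
    """
    if group_keys is None:
        group_keys = ["dog_id", "stage", "ig_class", "fraction"]
    md = align_to_metadata(table, metadata)
    for key in group_keys:
        if key not in md.columns:
            raise KeyError(f"metadata has no column {key!r}")
        if md[key].isna().any():
            raise ValueError(f"missing values in group key {key!r}")

    labels = md[group_keys].astype(str).agg(".".join, axis=1)
    order: list[str] = []
    seen: set[str] = set()
    for lab in labels:
        if lab not in seen:
            seen.add(lab)
            order.append(lab)
    merged = np.zeros((table.n_features, len(order)), dtype=table.counts.dtype)
    pos = {lab: j for j, lab in enumerate(order)}
    for col, lab in enumerate(labels):
        merged[:, pos[lab]] += table.counts[:, col]
    return FeatureTable(merged, list(table.feature_ids), order)


# ---------------------------------------------------------------------------
# Prevalence-based decontamination
# ---------------------------------------------------------------------------

@dataclass
class ContamResult:
    """Per-feature decontamination verdict."""

    feature_id: str
    score: float                       # NaN when undefined (absent feature)
    per_batch_scores: dict[str, float] = field(default_factory=dict)
    is_contaminant: bool = False


def _prevalence_score(k_ctrl: int, n_ctrl: int, k_true: int, n_true: int) -> float:
    """One-sided exact probability that the feature is at least this
    prevalent in controls under exchangeability (hypergeometric tail).

    Small values indicate contaminant-like features (more prevalent in
    negative controls than in true samples).
    """
    table = np.array([[k_ctrl, n_ctrl - k_ctrl], [k_true, n_true - k_true]])
    return float(stats.fisher_exact(table, alternative="greater")[1])


def prevalence_decontam(
    table: FeatureTable,
    metadata: pd.DataFrame,
    threshold: float = 0.5,
    batch_key: str | None = None,
) -> tuple[list[ContamResult], FeatureTable]:
    """Classify contaminants by comparing presence/absence prevalence in
    negative controls versus true samples.

    Per feature the score is the one-sided Fisher exact tail probability
    for "more prevalent in controls"; features scoring below `threshold`
    are removed. With `batch_key` (e.g. the sequencing run) scores are
    computed per batch and combined by the minimum — a feature is flagged
    if it looks contaminant-like in any batch. Features absent everywhere
    get an undefined (NaN) score and are retained.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    md = align_to_metadata(table, metadata)
    is_control = md["is_control"].astype(bool).to_numpy()

    if batch_key is None:
        batches = {"all": np.ones(len(md), dtype=bool)}
    else:
        if batch_key not in md.columns:
            raise KeyError(f"metadata has no column {batch_key!r}")
        batches = {
            str(b): (md[batch_key].astype(str) == str(b)).to_numpy()
            for b in md[batch_key].astype(str).unique()
        }
    for name, mask in batches.items():
        if not (is_control & mask).any():
            raise ValueError(f"no negative controls in batch {name!r}")
        if not (~is_control & mask).any():
            raise ValueError(f"no true samples in batch {name!r}")

    present = table.counts > 0
    results: list[ContamResult] = []
    for i, fid in enumerate(table.feature_ids):
        per_batch: dict[str, float] = {}
        for bname, mask in batches.items():
            ctrl = is_control & mask
            true = ~is_control & mask
            k_ctrl = int(present[i, ctrl].sum())
            k_true = int(present[i, true].sum())
            if k_ctrl + k_true == 0:
                per_batch[bname] = float("nan")
            else:
                per_batch[bname] = _prevalence_score(
                    k_ctrl, int(ctrl.sum()), k_true, int(true.sum())
                )
        defined = [s for s in per_batch.values() if not np.isnan(s)]
        score = min(defined) if defined else float("nan")
        is_cont = bool(defined) and score < threshold
        results.append(ContamResult(fid, score, per_batch, is_cont))

    n_absent = sum(1 for r in results if np.isnan(r.score))
    if n_absent:
        warnings.warn(
            f"{n_absent} feature(s) absent from all samples and controls: "
            "score undefined, retained",
            stacklevel=2,
        )
    keep = [r.feature_id for r in results if not r.is_contaminant]
    return results, table.select_features(keep)


def contam_report(results: list[ContamResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"feature_id": r.feature_id, "score": r.score,
               "is_contaminant": r.is_contaminant}
        for b, s in r.per_batch_scores.items():
            row[f"score_{b}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Rarefaction and aggregation
# ---------------------------------------------------------------------------

def rarefy(table: FeatureTable, depth: int = 1000, seed: int = 0) -> FeatureTable:
    """Subsample each sample without replacement to exactly `depth` reads;
    samples with fewer than `depth` reads are dropped. Deterministic for a
    fixed seed."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    cols = []
    for j in np.flatnonzero(keep):
        cols.append(rng.multivariate_hypergeometric(table.counts[:, j], depth))
    kept_ids = [table.sample_ids[j] for j in np.flatnonzero(keep)]
    counts = (
        np.column_stack(cols) if cols
        else np.zeros((table.n_features, 0), dtype=np.int64)
    )
    return FeatureTable(counts, list(table.feature_ids), kept_ids)


def aggregate_top_taxa(
    table: FeatureTable,
    taxonomy: dict[str, str],
    k: int = 11,
    other_label: str = "other",
    unassigned_label: str = "unassigned",
) -> FeatureTable:
    """Sum features into families and keep the `k` most abundant families
    (by grand total) plus an 'other' row holding the remainder. Column
    sums are conserved exactly."""
    if k < 0:
        raise ValueError("k must be >= 0")
    families = [taxonomy.get(f, unassigned_label) for f in table.feature_ids]
    fam_order: list[str] = []
    seen: set[str] = set()
    for fam in families:
        if fam not in seen:
            seen.add(fam)
            fam_order.append(fam)
    agg = np.zeros((len(fam_order), table.n_samples), dtype=table.counts.dtype)
    pos = {f: i for i, f in enumerate(fam_order)}
    for i, fam in enumerate(families):
        agg[pos[fam]] += table.counts[i]

    totals = agg.sum(axis=1)
    # stable: ties broken by first appearance; a family already named like
    # the catch-all label is routed into the remainder row
    candidates = [i for i in range(len(fam_order)) if fam_order[i] != other_label]
    top_idx = sorted(candidates, key=lambda i: (-totals[i], i))[:k]
    top_idx_sorted = sorted(top_idx)
    rest = [i for i in range(len(fam_order)) if i not in set(top_idx)]
    rows = [agg[i] for i in top_idx_sorted]
    names = [fam_order[i] for i in top_idx_sorted]
    other = (
        agg[rest].sum(axis=0) if rest
        else np.zeros(table.n_samples, dtype=table.counts.dtype)
    )
    rows.append(other)
    names.append(other_label)
    return FeatureTable(np.vstack(rows), names, list(table.sample_ids))
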