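"""Alpha/beta diversity: Shannon index with a log-scale linear mixed
model and marginal means, CLR/Aitchison and Bray-Curtis distances,
PERMANOVA, and UPGMA hierarchical clustering with Newick export.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from igcoat.design import DesignMatrix, build_design

# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon index H = -sum p_i log p_i over positive proportions.

    Natural log by default (configurable base)."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("at least one positive count is required")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


# ---------------------------------------------------------------------------
# Compositional transforms and distances
# ---------------------------------------------------------------------------

def clr_transform(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centred log-ratio per sample (columns of a features x samples
    matrix, or per row of a samples x features matrix — the transform is
    applied along `axis`).

    x -> ln((x + psi) / g) with g the geometric mean of (x + psi); each
    transformed sample sums to zero.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = np.asarray(counts, dtype=float) + pseudocount
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with sample labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("values shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = np.maximum(self.values, 0.0)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(c) for c in df.columns], df.to_numpy())


def _samples_matrix(counts: np.ndarray) -> np.ndarray:
    """Interpret input as samples x features (transpose of a FeatureTable)."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return x


def aitchison_distance(
    counts: np.ndarray, labels: list[str] | None = None, pseudocount: float = 1.0
) -> DistanceMatrix:
    """Euclidean distance between CLR-transformed samples (rows)."""
    x = _samples_matrix(counts)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    clr = clr_transform(x, pseudocount)
    diff = clr[:, None, :] - clr[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    if labels is None:
        labels = [f"s{i}" for i in range(x.shape[0])]
    return DistanceMatrix(labels, d)


def bray_curtis(counts: np.ndarray, labels: list[str] | None = None) -> DistanceMatrix:
    """BC(a, b) = sum |a_i - b_i| / sum (a_i + b_i); in [0, 1]."""
    x = _samples_matrix(counts)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=-1)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(d, 0.0)
    if labels is None:
        labels = [f"s{i}" for i in range(x.shape[0])]
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted ultrametric tree node; `height` is the merge height."""

    name: str
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_newick(self) -> str:
        return self._newick_inner(parent_height=None) + ";"

    def _newick_inner(self, parent_height: float | None) -> str:
        if self.is_leaf:
            body = self.name
        else:
            body = "(" + ",".join(
                c._newick_inner(self.height) for c in self.children
            ) + ")"
        if parent_height is None:
            return body
        return f"{body}:{parent_height - self.height:g}"


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative clustering (UPGMA).

    Merge heights are half the average inter-cluster distance, so the
    cophenetic distance between two leaves equals the average original
    distance between their clusters. Ties are broken by the
    lexicographically smallest pair of cluster labels.
    """
    if dist.n < 2:
        raise ValueError("need at least 2 leaves")
    clusters: dict[str, TreeNode] = {
        lab: TreeNode(lab, 0.0) for lab in dist.labels
    }
    sizes = {lab: 1 for lab in dist.labels}
    d = {
        frozenset((a, b)): dist.values[i, j]
        for i, a in enumerate(dist.labels)
        for j, b in enumerate(dist.labels)
        if i < j
    }
    labels = sorted(dist.labels)
    while len(labels) > 1:
        best = None
        for a, b in itertools.combinations(labels, 2):
            key = (d[frozenset((a, b))], a, b)
            if best is None or key < best:
                best = key
        dd, a, b = best
        new_label = f"({a}+{b})"
        node = TreeNode(new_label, dd / 2.0, [clusters[a], clusters[b]])
        na, nb = sizes[a], sizes[b]
        for c in labels:
            if c in (a, b):
                continue
            dac = d.pop(frozenset((a, c)))
            dbc = d.pop(frozenset((b, c)))
            d[frozenset((new_label, c))] = (na * dac + nb * dbc) / (na + nb)
        del d[frozenset((a, b))]
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[new_label] = node
        sizes[new_label] = na + nb
        labels = sorted(clusters.keys())
    return next(iter(clusters.values()))


def cophenetic_matrix(tree: TreeNode, labels: list[str]) -> np.ndarray:
    """Pairwise cophenetic distances (2 x merge height of the LCA)."""
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros((n, n))

    def visit(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.name]
        child_leaves = [visit(c) for c in node.children]
        for la, lb in itertools.combinations(range(len(child_leaves)), 2):
            for x in child_leaves[la]:
                for y in child_leaves[lb]:
                    out[pos[x], pos[y]] = out[pos[y], pos[x]] = 2.0 * node.height
        return [leaf for group in child_leaves for leaf in group]

    visit(tree)
    return out


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_ss(d2: np.ndarray, groups: np.ndarray, n: int) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances."""
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    *,
    strata=None,
) -> dict:
    """One-way PERMANOVA: pseudo-F, R-squared, and permutation p-value.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm) under free permutation of
    the sample labels (optionally restricted within `strata` blocks).
    """
    groups = np.asarray([str(g) for g in groups])
    n = dist.n
    if len(groups) != n:
        raise ValueError("groups length does not match the distance matrix")
    uniq = np.unique(groups)
    a = len(uniq)
    for g in uniq:
        if (groups == g).sum() == n:
            raise ValueError("a group equals the full sample set")
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    d2 = dist.values**2

    def f_stat(lab: np.ndarray) -> float:
        ss_total, ss_within = _permanova_ss(d2, lab, n)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    ss_total, ss_within = _permanova_ss(d2, groups, n)
    ss_among = ss_total - ss_within
    f_obs = (ss_among / (a - 1)) / (ss_within / (n - a))
    r2 = ss_among / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    if strata is not None:
        strata = np.asarray([str(s) for s in strata])
        if len(strata) != n:
            raise ValueError("strata length does not match the distance matrix")
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for s in np.unique(strata):
                idx = np.flatnonzero(strata == s)
                perm[idx] = idx[rng.permutation(len(idx))]
        if f_stat(groups[perm]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"pseudo_F": float(f_obs), "R2": float(r2), "p_value": float(p),
            "n_perm": n_perm}


# ---------------------------------------------------------------------------
# Shannon linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """REML fit of log(Shannon) ~ full factorial + (1 | dog)."""

    design: DesignMatrix
    fixed_estimates: np.ndarray
    fixed_cov: np.ndarray
    sigma_dog2: float
    sigma_resid2: float
    loglike: float
    response: np.ndarray
    n_excluded: int = 0

    def fitted(self) -> np.ndarray:
        return self.design.fixed @ self.fixed_estimates

    def residuals(self) -> np.ndarray:
        return self.response - self.fitted()


def fit_shannon_lmm(
    h_values: pd.DataFrame,
    *,
    factors: list[str] | None = None,
    response_col: str = "shannon",
    dog_key: str = "dog_id",
) -> LmmFit:
    """REML linear mixed model for natural-log Shannon diversity.

    Rows with non-positive Shannon (log undefined) are excluded with a
    warning. Fixed effects are the full factorial expansion of `factors`
    (default Ig class x cohort x stage); the dog random intercept carries
    the repeated-measures structure.
    """
    import statsmodels.api as sm

    if factors is None:
        factors = ["ig_class", "cohort", "stage"]
    df = h_values.copy()
    bad = df[response_col] <= 0
    n_excluded = int(bad.sum())
    if n_excluded:
        warnings.warn(
            f"excluding {n_excluded} sample(s) with Shannon <= 0 "
            "(log undefined)",
            stacklevel=2,
        )
        df = df.loc[~bad].reset_index(drop=True)
    if df[dog_key].nunique() < 2:
        raise ValueError("at least 2 dogs are required")

    design = build_design(df, factors=factors, dog_key=dog_key)
    y = np.log(df[response_col].to_numpy(dtype=float))

    if np.var(y) < 1e-12:
        # degenerate constant response: exact zero-variance fit
        beta = np.zeros(design.n_terms)
        beta[0] = y.mean() if len(y) else 0.0
        return LmmFit(design, beta, np.zeros((design.n_terms,) * 2), 0.0, 0.0,
                      float("nan"), y, n_excluded)

    groups = df[dog_key].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, design.fixed, groups=groups)
        try:
            res = model.fit(reml=True, method="lbfgs", maxiter=500)
        except Exception:
            res = model.fit(reml=True, maxiter=500)

    k = design.n_terms
    return LmmFit(
        design=design,
        fixed_estimates=np.asarray(res.fe_params, dtype=float),
        fixed_cov=np.asarray(res.cov_params())[:k, :k],
        sigma_dog2=float(np.asarray(res.cov_re)[0, 0]),
        sigma_resid2=float(res.scale),
        loglike=float(res.llf),
        response=y,
        n_excluded=n_excluded,
    )


def lmm_r2(fit: LmmFit) -> tuple[float, float]:
    """Nakagawa marginal/conditional R^2 for the linear mixed model."""
    var_fixed = float(np.var(fit.fitted()))
    denom = var_fixed + fit.sigma_dog2 + fit.sigma_resid2
    if denom <= 0:
        return 0.0, 0.0
    return var_fixed / denom, (var_fixed + fit.sigma_dog2) / denom


def marginal_means(
    fit: LmmFit,
    grid_factors: list[str],
    level: float = 0.95,
    *,
    exponentiate: bool = False,
) -> pd.DataFrame:
    """Estimated marginal means over a factor grid with normal-theory CIs.

    Each cell averages the fixed-effect predictions over all levels of
    the non-grid factors with equal weights (the averaging weights sum to
    1 per cell). Estimates are on the log scale unless `exponentiate`.
    """
    from scipy import stats as sps

    design = fit.design
    for f in grid_factors:
        if f not in design.factors:
            raise KeyError(f"factor {f!r} not in the fitted design")
    other = [f for f in design.factors if f not in grid_factors]
    all_levels = {
        f: [design.reference_levels[f]] + design.levels[f] for f in design.factors
    }
    z = sps.norm.ppf(0.5 + level / 2.0)

    rows = []
    for combo in itertools.product(*(all_levels[f] for f in grid_factors)):
        cell = dict(zip(grid_factors, combo))
        weights_rows = []
        for rest in itertools.product(*(all_levels[f] for f in other)):
            weights_rows.append(design.encode({**cell, **dict(zip(other, rest))}))
        c = np.mean(weights_rows, axis=0)
        est = float(c @ fit.fixed_estimates)
        se = float(np.sqrt(max(c @ fit.fixed_cov @ c, 0.0)))
        lo, hi = est - z * se, est + z * se
        if exponentiate:
            est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        rows.append({**cell, "estimate": est, "se": se, "lo": lo, "hi": hi})
    return pd.DataFrame(rows)


def shannon_per_sample(table, base: float | None = None) -> pd.DataFrame:
    """Shannon index for every sample of a FeatureTable."""
    vals = []
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        vals.append(
            {"sample_id": sid,
             "shannon": shannon(col, base) if col.sum() > 0 else float("nan")}
        )
    return pd.DataFrame(vals)
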