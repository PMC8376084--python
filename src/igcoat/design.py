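"""Treatment-coded full-interaction design matrices for the mixed models.

All three hierarchical models share the fixed-effect structure
``1 + f1 * f2 * ... * fk`` (intercept, main effects, all interactions)
with treatment contrasts against user-chosen reference levels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Conventional reference levels for the study factors.
DEFAULT_REFERENCES = {
    "ig_class": "IgA",
    "cohort": "healthy",
    "stage": "before",
    "fraction": "presort",
}


@dataclass
class DesignMatrix:
    """Fixed-effect matrix plus the grouping info the samplers need."""

    fixed: np.ndarray                 # rows x P
    term_names: list[str]
    factors: list[str]                # factor order used for expansion
    levels: dict[str, list[str]]      # observed non-reference levels per factor
    reference_levels: dict[str, str]
    dog_ids: list[str]                # unique dogs, fit order
    dog_index: np.ndarray             # per-row index into dog_ids
    ig_indicator: np.ndarray          # per-row 0/1 slope covariate (IgG vs IgA)

    @property
    def n_rows(self) -> int:
        return self.fixed.shape[0]

    @property
    def n_terms(self) -> int:
        return self.fixed.shape[1]

    @property
    def n_dogs(self) -> int:
        return len(self.dog_ids)

    def encode(self, combination: dict[str, str]) -> np.ndarray:
        """Design row for one factor combination (for prediction grids)."""
        row = np.zeros(self.n_terms)
        for j, spec in enumerate(self._term_specs):
            row[j] = 1.0
            for factor, level in spec:
                if factor not in combination:
                    raise KeyError(f"combination missing factor {factor!r}")
                if combination[factor] != level:
                    row[j] = 0.0
                    break
        for factor, value in combination.items():
            if factor not in self.factors:
                raise KeyError(f"unknown factor {factor!r}")
            known = set(self.levels[factor]) | {self.reference_levels[factor]}
            if value not in known:
                raise ValueError(f"unknown level {value!r} for factor {factor!r}")
        return row

    # populated by build_design; list of ((factor, level), ...) per column
    _term_specs: list[tuple] = field(default_factory=list, repr=False)


def _term_name(spec: tuple) -> str:
    if not spec:
        return "Intercept"
    return ":".join(f"{factor}[{level}]" for factor, level in spec)


def build_design(
    metadata: pd.DataFrame,
    factors: list[str],
    reference_levels: dict[str, str] | None = None,
    dog_key: str = "dog_id",
    ig_key: str = "ig_class",
) -> DesignMatrix:
    """Expand ``1 + f1 * f2 * ... * fk`` with treatment contrasts.

    Parameters
    ----------
    metadata:
        One row per modelled observation; must contain every factor plus
        `dog_key`.
    factors:
        Ordered factor names; the expansion is intercept, main effects in
        this order, then all higher-order interactions.
    reference_levels:
        Reference (omitted) level per factor; defaults from
        :data:`DEFAULT_REFERENCES`. Each reference must occur in the data.

    Single-level factors contribute no columns beyond the intercept. A
    2 x 4 x 2 factor space therefore expands to 16 full-rank columns.
    """
    refs = dict(DEFAULT_REFERENCES)
    if reference_levels:
        refs.update(reference_levels)

    for f in factors:
        if f not in metadata.columns:
            raise KeyError(f"metadata has no column {f!r}")
    if dog_key not in metadata.columns:
        raise KeyError(f"metadata has no column {dog_key!r}")
    if metadata[factors].isna().any().any():
        raise ValueError("missing factor values in metadata")

    levels: dict[str, list[str]] = {}
    for f in factors:
        observed = list(pd.unique(metadata[f].astype(str)))
        if f not in refs or refs[f] not in observed:
            if f in refs and len(observed) >= 1:
                # tolerate a conventional reference absent from a subset fit
                # only when the factor has a single level (it then drops out)
                if len(observed) == 1:
                    refs[f] = observed[0]
                else:
                    raise ValueError(
                        f"reference level {refs.get(f)!r} for factor {f!r} "
                        f"not present in data (observed: {observed})"
                    )
            elif f not in refs:
                raise ValueError(f"no reference level given for factor {f!r}")
        non_ref = [lv for lv in observed if lv != refs[f]]
        levels[f] = sorted(non_ref)

    term_specs: list[tuple] = [()]
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            for lvls in itertools.product(*(levels[f] for f in combo)):
                term_specs.append(tuple(zip(combo, lvls)))

    n = len(metadata)
    X = np.zeros((n, len(term_specs)))
    X[:, 0] = 1.0
    col_cache = {f: metadata[f].astype(str).to_numpy() for f in factors}
    for j, spec in enumerate(term_specs[1:], start=1):
        mask = np.ones(n, dtype=bool)
        for factor, level in spec:
            mask &= col_cache[factor] == level
        X[mask, j] = 1.0

    dog_vals = metadata[dog_key].astype(str).to_numpy()
    dog_ids = list(pd.unique(dog_vals))
    dog_pos = {d: i for i, d in enumerate(dog_ids)}
    dog_index = np.array([dog_pos[d] for d in dog_vals], dtype=int)

    if ig_key in metadata.columns and ig_key in factors and levels.get(ig_key):
        # 0/1 indicator for the (single) non-reference Ig level
        slope_level = levels[ig_key][0]
        ig_indicator = (col_cache[ig_key] == slope_level).astype(float)
    else:
        ig_indicator = np.zeros(n)

    dm = DesignMatrix(
        fixed=X,
        term_names=[_term_name(s) for s in term_specs],
        factors=list(factors),
        levels=levels,
        reference_levels={f: refs[f] for f in factors},
        dog_ids=dog_ids,
        dog_index=dog_index,
        ig_indicator=ig_indicator,
    )
    dm._term_specs = term_specs
    return dm


def reference_grid(design: DesignMatrix) -> list[dict[str, str]]:
    """All factor combinations observed levels x levels (full crossing)."""
    all_levels = {
        f: [design.reference_levels[f]] + design.levels[f] for f in design.factors
    }
    grid = []
    for combo in itertools.product(*(all_levels[f] for f in design.factors)):
        grid.append(dict(zip(design.factors, combo)))
    return grid
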