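"""RLQ cross-covariance analysis and its among/within-species partial forms.

RLQ links an environment table R (plots × environmental variables), an
occurrence table L (plots × observations, non-negative) and a trait table Q
(observations × traits).  L is converted to a relative-frequency table whose
row and column sums provide the weights under which R and Q are scaled with
the mixed-variable conventions of :mod:`traitflux.ordination_hs`.  The
doubly-centred frequency table mediates a cross matrix whose singular value
decomposition yields axes maximizing the squared cross-covariance between
linear combinations of environmental variables and traits.

The two partial analyses separate the components of trait structure: in the
*among-species* form each observation's trait row is replaced by its species
mean, in the *within-species* form by its deviation from that mean.  The two
derived Q tables sum to the raw Q for quantitative traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import Study
from .ordination_hs import MixedTable, scale_mixed_table

__all__ = [
    "RLQInput",
    "RLQResult",
    "rlq",
    "partial_rlq",
    "build_rlq_input",
    "split_trait_table",
]


@dataclass
class RLQInput:
    R: MixedTable  # plots × environment
    L: np.ndarray  # plots × observations, non-negative
    Q: MixedTable  # observations × traits

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        if np.any(L < 0):
            raise ValueError("L must be non-negative")
        if L.shape[0] != len(self.R.data):
            raise ValueError("R rows must align with L rows")
        if L.shape[1] != len(self.Q.data):
            raise ValueError("Q rows must align with L columns")
        if np.any(L.sum(axis=1) == 0):
            raise ValueError("L has empty rows (plots without observations)")
        if np.any(L.sum(axis=0) == 0):
            raise ValueError("L has empty columns (observations in no plot)")
        self.L = L


@dataclass
class RLQResult:
    eigenvalues: np.ndarray
    pct_cross_covariance: np.ndarray
    env_coefficients: pd.DataFrame  # scaled env columns × axes
    trait_coefficients: pd.DataFrame  # scaled trait columns × axes
    env_contributions: pd.DataFrame  # per variable × axes, % summing to 100
    trait_contributions: pd.DataFrame
    total_cross_covariance: float
    notes: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.env_coefficients.shape[1]


def _contributions(
    coefs: np.ndarray, columns: list[tuple[str, str | None]], axes: list[str]
) -> pd.DataFrame:
    """Per-variable contributions: squared coefficients summed over a
    variable's indicator columns, scaled to 100% per axis."""
    sq = coefs**2
    variables: list[str] = []
    for var, _lev in columns:
        if var not in variables:
            variables.append(var)
    rows = []
    for var in variables:
        idx = [j for j, (v, _l) in enumerate(columns) if v == var]
        rows.append(sq[idx, :].sum(axis=0))
    mat = np.asarray(rows)
    totals = mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(totals > 0, 100.0 * mat / totals, 0.0)
    return pd.DataFrame(mat, index=variables, columns=axes)


def rlq(inp: RLQInput, n_axes: int = 2, allow_zero_variance: bool = False) -> RLQResult:
    """Run the three-table cross-covariance decomposition.

    Eigenvalue k is the squared k-th singular value of the scaled cross
    matrix; their sum equals the squared Frobenius norm of that matrix
    (asserted on every run).  Coefficient signs are fixed by making the
    largest-magnitude environment coefficient on each axis positive.
    """
    P = inp.L / inp.L.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    R = MixedTable(inp.R.data, inp.R.kinds, row_weights=r)
    Q = MixedTable(inp.Q.data, inp.Q.kinds, row_weights=c)
    Rs = scale_mixed_table(R, allow_zero_variance=allow_zero_variance)
    Qs = scale_mixed_table(Q, allow_zero_variance=allow_zero_variance)
    P0 = P - np.outer(r, c)
    M = Rs.matrix.T @ P0 @ Qs.matrix
    total = float(np.sum(M * M))
    notes = list(
        f"zero-variance column {n!r} dropped" for n in Rs.dropped + Qs.dropped
    )
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    eigenvalues = s**2
    if not np.isclose(eigenvalues.sum(), total, rtol=1e-10, atol=1e-12):
        raise AssertionError("trace identity violated: sum of eigenvalues != ||M||_F^2")
    if total <= 0:
        warnings.warn("rank-0 cross matrix: all RLQ eigenvalues are zero")
        notes.append("rank-0 cross matrix")
    k = min(n_axes, len(s))
    axes = [f"axis{a + 1}" for a in range(k)]
    U, V = U[:, :k].copy(), Vt.T[:, :k].copy()
    for a in range(k):
        j = int(np.argmax(np.abs(U[:, a])))
        if U[j, a] < 0:
            U[:, a] = -U[:, a]
            V[:, a] = -V[:, a]
    env_idx = [f"{v}" if lev is None else f"{v}:{lev}" for v, lev in Rs.columns]
    trait_idx = [f"{v}" if lev is None else f"{v}:{lev}" for v, lev in Qs.columns]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * eigenvalues / total if total > 0 else eigenvalues * 0.0
    return RLQResult(
        eigenvalues=eigenvalues,
        pct_cross_covariance=pct,
        env_coefficients=pd.DataFrame(U, index=env_idx, columns=axes),
        trait_coefficients=pd.DataFrame(V, index=trait_idx, columns=axes),
        env_contributions=_contributions(U, Rs.columns, axes),
        trait_contributions=_contributions(V, Qs.columns, axes),
        total_cross_covariance=total,
        notes=notes,
    )


# ----------------------------------------------------------------------
# Study-level builders
# ----------------------------------------------------------------------


def split_trait_table(
    study: Study, forest_type: str, component: str
) -> tuple[pd.DataFrame, dict[str, str], list]:
    """Build the observations × traits table for one partial component.

    ``among_species``: quantitative rows are species means (over the species'
    individuals in the forest type) and categorical species attributes are
    attached per individual.  ``within_species``: quantitative deviations
    from those species means; categorical traits are excluded (no recorded
    within-species variation).  ``raw``: observed values plus categoricals.
    """
    inds = study.individuals_of(forest_type)
    if not inds:
        raise ValueError(f"no individuals in forest type {forest_type!r}")
    quant = [t.name for t in study.quantitative_traits]
    missing = [
        (i.individual_id, t)
        for i in inds
        for t in quant
        if t not in i.trait_values
    ]
    if missing:
        raise ValueError(
            f"{len(missing)} missing trait values (impute first), e.g. {missing[:3]}"
        )
    sp_means: dict[str, dict[str, float]] = {}
    for t in quant:
        acc: dict[str, list[float]] = {}
        for i in inds:
            acc.setdefault(i.species_id, []).append(i.trait_values[t])
        for s, vals in acc.items():
            sp_means.setdefault(s, {})[t] = float(np.mean(vals))

    singletons = sorted(
        {s for s in sp_means if sum(i.species_id == s for i in inds) == 1}
    )
    rows = []
    kinds: dict[str, str] = {t: "quantitative" for t in quant}
    cat_names = ["phenology", "compoundness", "pubescence", "legume"]
    for i in inds:
        row: dict[str, object] = {}
        for t in quant:
            if component == "among_species":
                row[t] = sp_means[i.species_id][t]
            elif component == "within_species":
                row[t] = i.trait_values[t] - sp_means[i.species_id][t]
            elif component == "raw":
                row[t] = i.trait_values[t]
            else:
                raise ValueError(f"unknown component {component!r}")
        if component in ("among_species", "raw"):
            sp = study.species_info(i.species_id)
            for cname in cat_names:
                row[cname] = sp.categorical_value(cname)
        rows.append(row)
    if component in ("among_species", "raw"):
        kinds.update({c: "categorical" for c in cat_names})
    df = pd.DataFrame(rows, index=[i.individual_id for i in inds])
    return df, kinds, singletons


def build_rlq_input(
    study: Study, forest_type: str, component: str = "raw"
) -> tuple[RLQInput, list[str]]:
    """Assemble R (plot environment), L (plots × individuals incidence) and
    Q (per ``component``) for one forest type."""
    plots = study.plots_of(forest_type)
    inds = study.individuals_of(forest_type)
    plot_index = {p.plot_id: i for i, p in enumerate(plots)}
    env_cols = ["successional_age"] + study.env_variables
    rdf = pd.DataFrame(
        [
            {"successional_age": p.successional_age, **p.env}
            for p in plots
        ],
        index=[p.plot_id for p in plots],
    )[env_cols]
    R = MixedTable(rdf, {c: "quantitative" for c in env_cols})
    L = np.zeros((len(plots), len(inds)))
    for j, ind in enumerate(inds):
        L[plot_index[ind.plot_id], j] = 1.0
    qdf, kinds, singletons = split_trait_table(study, forest_type, component)
    Q = MixedTable(qdf, kinds)
    notes = [
        f"species {s!r} has a single individual (zero within-species row)"
        for s in singletons
    ]
    return RLQInput(R=R, L=L, Q=Q), notes


def partial_rlq(
    study: Study, forest_type: str, component: str, n_axes: int = 2
) -> RLQResult:
    """RLQ on the among-species or within-species component of the traits.

    Species means for the split are computed per forest type, matching the
    fixed community means of the single-trait decomposition.
    """
    if component not in ("among_species", "within_species", "raw"):
        raise ValueError(f"unknown component {component!r}")
    inp, notes = build_rlq_input(study, forest_type, component)
    result = rlq(inp, n_axes=n_axes, allow_zero_variance=True)
    result.notes.extend(notes)
    return result
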