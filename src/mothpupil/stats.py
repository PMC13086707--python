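"""Hierarchical model selection and pairwise contrasts on kinetic parameters.

Per-specimen slope ``b`` and half-time ``t50`` are compared across species,
sex and temperature with Gaussian-family linear models of increasing
interaction order,

    response ~ (sex + species + temperature)^n,    n = 0..3,

where n = 0 is the intercept-only model.  Consecutive orders are compared
by sequential ANOVA F-tests; a more complex order is accepted when it is
significantly better than the last accepted model *and* has a lower AIC.
Pairwise comparisons between the levels of a chosen factor use estimated
marginal means (model predictions averaged over the other factors' level
grid) with Tukey studentized-range adjustment, summarised as a compact
letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm

__all__ = [
    "SpecimenRecord",
    "ModelHierarchy",
    "ContrastTable",
    "fit_glm_hierarchy",
    "select_model",
    "emm_pairwise",
    "pearson_correlation",
]

FACTORS = ("sex", "species", "temperature_C")

SPECIES_LEVELS = ("CP", "LB", "GM")
SEX_LEVELS = ("male", "female")


@dataclass(frozen=True)
class SpecimenRecord:
    """One specimen's metadata and fitted kinetic parameters."""

    specimen_id: str
    species: str
    sex: str
    temperature_C: float
    phase: str  # closing | opening
    b: float
    t50_s: float


def records_to_frame(records: Sequence[SpecimenRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class ModelHierarchy:
    """Nested Gaussian linear models of increasing interaction order."""

    response: str
    orders: list[int]
    formulas: list[str]
    results: list  # statsmodels RegressionResults, parallel to orders
    aic: list[float]
    loglik: list[float]
    df_resid: list[float]
    sequential_p: list[float]  # p-value comparing orders[i] vs orders[i+1]

    def summary_frame(self) -> pd.DataFrame:
        seq = [np.nan, *self.sequential_p]
        return pd.DataFrame(
            {
                "order": self.orders,
                "formula": self.formulas,
                "loglik": self.loglik,
                "aic": self.aic,
                "df_resid": self.df_resid,
                "p_vs_previous": seq,
            }
        )


def _formula(response: str, order: int) -> str:
    if order == 0:
        return f"{response} ~ 1"
    terms = " + ".join(f"C({f})" for f in FACTORS)
    if order == 1:
        return f"{response} ~ {terms}"
    return f"{response} ~ ({terms})**{order}"


def fit_glm_hierarchy(
    records: Sequence[SpecimenRecord] | pd.DataFrame,
    response: str = "b",
    max_order: int = 3,
) -> ModelHierarchy:
    """Fit the nested model hierarchy for one response.

    Gaussian-family GLMs with identity link are fitted as ordinary least
    squares (identical estimates and likelihood).  When the design for an
    order is rank-deficient (empty factor cells), the hierarchy is
    truncated at the previous order with a warning.
    """
    df = records_to_frame(records)
    if response == "t50":
        response = "t50_s"
    if response not in df.columns:
        raise ValueError(f"response {response!r} not found in records")
    cols = [response, *FACTORS]
    df = df.dropna(subset=[c for c in cols if c in df.columns])
    if not np.all(np.isfinite(df[response])):
        raise ValueError("response contains non-finite values")

    orders, formulas, results = [], [], []
    for order in range(0, max_order + 1):
        formula = _formula(response, order)
        res = smf.ols(formula, data=df).fit()
        exog = res.model.exog
        if np.linalg.matrix_rank(exog) < exog.shape[1]:
            warnings.warn(
                f"design for order {order} is rank-deficient (empty cells); "
                f"hierarchy truncated at order {order - 1}",
                stacklevel=2,
            )
            break
        orders.append(order)
        formulas.append(formula)
        results.append(res)

    seq_p = []
    for prev, curr in zip(results[:-1], results[1:]):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # anova_lm warns on 0/NaN F for equal fits
            tab = anova_lm(prev, curr)
        seq_p.append(float(tab["Pr(>F)"].iloc[-1]))
    return ModelHierarchy(
        response=response,
        orders=orders,
        formulas=formulas,
        results=results,
        aic=[float(r.aic) for r in results],
        loglik=[float(r.llf) for r in results],
        df_resid=[float(r.df_resid) for r in results],
        sequential_p=seq_p,
    )


def select_model(hierarchy: ModelHierarchy, alpha: float = 0.05) -> int:
    """Walk the hierarchy from simplest to most complex and pick an order.

    Order n is accepted iff its sequential p-value against the previous
    order is below ``alpha`` AND its AIC is below the last accepted
    model's; the last accepted order is returned (0 when no step is
    accepted).
    """
    accepted = 0
    for i in range(1, len(hierarchy.orders)):
        p = hierarchy.sequential_p[i - 1]
        if np.isfinite(p) and p < alpha and hierarchy.aic[i] < hierarchy.aic[accepted]:
            accepted = i
    return hierarchy.orders[accepted]


@dataclass
class ContrastTable:
    """Estimated marginal means, Tukey-adjusted contrasts and letters."""

    factor: str
    alpha: float
    emmeans: pd.DataFrame  # level, emmean, se, letters
    contrasts: pd.DataFrame  # level_1, level_2, estimate, se, t, p_adj
    df_resid: float


def emm_pairwise(result, factor: str, alpha: float = 0.05) -> ContrastTable:
    """All pairwise comparisons of one factor's estimated marginal means.

    The EMM of a level is the model prediction averaged over the full level
    grid of the other model factors (each grid cell weighted equally, as in
    the reference-grid convention).  Pairwise differences are tested with
    the studentized-range (Tukey) adjustment on the model's residual
    degrees of freedom; levels are summarised by a compact letter display
    in which levels sharing a letter do not differ at ``alpha``.
    """
    formula_factors = [f for f in FACTORS if f"C({f})" in result.model.formula]
    if factor not in formula_factors:
        raise ValueError(f"factor {factor!r} is not a term of the fitted model")
    data = result.model.data.frame
    levels = {f: sorted(data[f].unique().tolist()) for f in formula_factors}
    grid = pd.DataFrame(
        list(itertools.product(*[levels[f] for f in formula_factors])),
        columns=formula_factors,
    )
    (design,) = build_design_matrices([result.model.data.design_info], grid)
    design = np.asarray(design)
    beta = result.params.to_numpy()
    cov = result.cov_params().to_numpy()
    dfres = float(result.df_resid)

    fac_levels = levels[factor]
    k = len(fac_levels)
    l_rows = {}
    for lev in fac_levels:
        sel = (grid[factor] == lev).to_numpy()
        l_rows[lev] = design[sel].mean(axis=0)
    emm = {lev: float(l_rows[lev] @ beta) for lev in fac_levels}
    emm_se = {lev: float(np.sqrt(l_rows[lev] @ cov @ l_rows[lev])) for lev in fac_levels}

    rows = []
    pmat = pd.DataFrame(np.ones((k, k)), index=fac_levels, columns=fac_levels)
    for a, b in itertools.combinations(fac_levels, 2):
        L = l_rows[a] - l_rows[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        tstat = est / se
        p_adj = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(tstat), k, dfres))
        p_adj = min(1.0, p_adj)
        rows.append({"level_1": a, "level_2": b, "estimate": est, "se": se, "t": tstat, "p_adj": p_adj})
        pmat.loc[a, b] = pmat.loc[b, a] = p_adj
    contrasts = pd.DataFrame(rows)

    letters = _compact_letter_display(fac_levels, pmat, emm, alpha)
    emmeans = pd.DataFrame(
        {
            "level": fac_levels,
            "emmean": [emm[lev] for lev in fac_levels],
            "se": [emm_se[lev] for lev in fac_levels],
            "letters": [letters[lev] for lev in fac_levels],
        }
    ).sort_values("emmean", ignore_index=True)
    return ContrastTable(factor=factor, alpha=alpha, emmeans=emmeans, contrasts=contrasts, df_resid=dfres)


def _compact_letter_display(levels, pmat: pd.DataFrame, emm: dict, alpha: float) -> dict:
    """Letters via maximal cliques of the non-significance graph.

    Levels in a clique are mutually non-significant and share a letter;
    significantly different levels never share one.  Cliques (hence
    letters) are ordered by the mean of their members' EMMs.
    """
    g = nx.Graph()
    g.add_nodes_from(levels)
    for a in levels:
        for b in levels:
            if a < b and pmat.loc[a, b] >= alpha:
                g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    cliques.sort(key=lambda c: np.mean([emm[lev] for lev in c]))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lev: "" for lev in levels}
    for i, clique in enumerate(cliques):
        for lev in clique:
            letters[lev] += alphabet[i]
    return letters


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform) for paired measurements."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError(f"at least 3 pairs are required, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
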