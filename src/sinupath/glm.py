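"""General linear models of movement indices on morphological and
physiological covariates, with backward AIC selection, type-3 ANOVA and
adjusted D-squared.

The model grid regresses each movement index on location (LOC), sex (SEX),
sternite length (STER), femur length (FEMU) and the enzyme activities of
phosphoglucose isomerase (PGI) and pyruvate kinase (PYRU), plus interactions
of the covariates with sex and location.  Responses are Gaussian/identity
except the maximum expected displacement TE, modelled with a Poisson/log
family (the Poisson deviance and its gammaln-extended log-likelihood accept
the non-negative continuous response).

Categorical terms use sum-to-zero contrasts, a prerequisite for meaningful
type-3 (marginal) tests.  Fitting is delegated to statsmodels' IRLS; the
design/contrast construction, the stepwise AIC search, the per-term deletion
tests and the explained-deviance summaries are implemented here.

Notes on AIC
------------
For Gaussian models the log-likelihood is the profile (ML) form
``-n/2 * (log(2*pi*deviance/n) + 1)`` and the error variance counts as one
estimated parameter, matching the convention of R's ``AIC``/``step`` used in
this literature.  For Poisson models the likelihood uses the continuous
factorial extension ``gammaln(y + 1)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import gammaln

from .errors import AliasedTermError, ConfigError

__all__ = [
    "GLMSpec",
    "GLMFit",
    "DesignMatrix",
    "build_design",
    "fit_glm",
    "backward_select",
    "type3_anova",
    "adjusted_d2",
    "significance_band",
    "model_report",
    "DEFAULT_CATEGORICAL",
    "FULL_TERMS",
]

#: Columns treated as categorical factors unless a spec overrides them.
DEFAULT_CATEGORICAL = ("LOC", "SEX")

#: The full starting term list for the movement-index models.
FULL_TERMS = (
    "LOC", "SEX", "FEMU", "STER", "PGI", "PYRU",
    "LOC:SEX", "SEX:FEMU", "SEX:STER",
    "LOC:FEMU", "LOC:STER", "LOC:PGI", "LOC:PYRU",
)


@dataclass(frozen=True)
class GLMSpec:
    """Model specification: response, family and term list.

    ``terms`` holds main effects and ``A:B`` interactions.  Unless
    ``enforce_marginality`` is disabled, a term list containing an
    interaction must also contain its constituent main effects.
    """

    response: str
    family: str  # "gaussian" | "poisson"
    terms: tuple
    categorical: tuple = DEFAULT_CATEGORICAL
    enforce_marginality: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "poisson"):
            raise ConfigError(f"unknown family {self.family!r}")
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.enforce_marginality:
            for t in self.terms:
                for parent in t.split(":"):
                    if ":" in t and parent not in self.terms:
                        raise ConfigError(
                            f"marginality violated: {t} present without {parent}"
                        )

    def drop(self, term: str) -> "GLMSpec":
        return GLMSpec(self.response, self.family,
                       tuple(t for t in self.terms if t != term),
                       self.categorical, self.enforce_marginality)

    def droppable_terms(self) -> tuple:
        """Terms removable in one backward step.

        Interactions are always droppable; with marginality enforced, a main
        effect is droppable only when it appears in no remaining interaction.
        """
        if not self.enforce_marginality:
            return self.terms
        in_interaction = {p for t in self.terms if ":" in t for p in t.split(":")}
        return tuple(t for t in self.terms if ":" in t or t not in in_interaction)


@dataclass(frozen=True)
class DesignMatrix:
    """Encoded design: the matrix, column names and a column->term map."""

    X: np.ndarray
    columns: tuple
    term_of_column: tuple  # parallel to columns; "Intercept" for the constant

    def columns_for(self, term: str) -> np.ndarray:
        return np.array([t == term for t in self.term_of_column])

    def without(self, term: str) -> "DesignMatrix":
        keep = ~self.columns_for(term)
        return DesignMatrix(
            self.X[:, keep],
            tuple(c for c, k in zip(self.columns, keep) if k),
            tuple(t for t, k in zip(self.term_of_column, keep) if k),
        )

    @property
    def n_params(self) -> int:
        return self.X.shape[1]


def _sum_contrast(series: pd.Series, name: str):
    """Sum-to-zero encoding: one column per non-reference level (sorted
    order, last level is the reference coded -1)."""
    levels = sorted(pd.unique(series.astype(str)))
    if len(levels) < 2:
        raise ConfigError(f"factor {name} has a single level")
    ref = levels[-1]
    cols, names = [], []
    for lev in levels[:-1]:
        col = np.where(series.astype(str) == lev, 1.0,
                       np.where(series.astype(str) == ref, -1.0, 0.0))
        cols.append(col)
        names.append(f"{name}[S.{lev}]")
    return cols, names


def build_design(data: pd.DataFrame, terms, categorical=DEFAULT_CATEGORICAL,
                 check_rank: bool = True) -> DesignMatrix:
    """Encode a term list into a design matrix with an intercept.

    Continuous terms contribute one column; categorical terms contribute
    sum-to-zero contrast columns; an ``A:B`` interaction contributes the
    elementwise products of its components' columns.
    """
    n = len(data)
    columns = [np.ones(n)]
    names = ["Intercept"]
    term_of = ["Intercept"]

    def main_effect_cols(name: str):
        if name in categorical:
            return _sum_contrast(data[name], name)
        if name not in data.columns:
            raise ConfigError(f"unknown term {name!r}")
        return [np.asarray(data[name], dtype=float)], [name]

    for term in terms:
        parts = term.split(":")
        part_cols = [main_effect_cols(p) for p in parts]
        cols, labels = part_cols[0]
        for more_cols, more_labels in part_cols[1:]:
            cols = [c1 * c2 for c1 in cols for c2 in more_cols]
            labels = [f"{l1}:{l2}" for l1 in labels for l2 in more_labels]
        columns.extend(cols)
        names.extend(labels)
        term_of.extend([term] * len(cols))

    X = np.column_stack(columns)
    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name the terms whose columns are linearly dependent on the rest
            aliased = []
            for term in dict.fromkeys(term_of):
                if term == "Intercept":
                    continue
                keep = np.array([t != term for t in term_of])
                if np.linalg.matrix_rank(X[:, keep]) == rank:
                    aliased.append(term)
            raise AliasedTermError(
                f"design is rank deficient (rank {rank} < {X.shape[1]}); "
                f"aliased terms: {', '.join(aliased) or 'undetermined'}"
            )
    return DesignMatrix(X, tuple(names), tuple(term_of))


@dataclass(frozen=True)
class GLMFit:
    """A fitted model with the summaries the reporting layer needs."""

    spec: GLMSpec
    design: DesignMatrix
    params: pd.Series
    bse: pd.Series
    llf: float
    deviance: float
    null_deviance: float
    aic: float
    n: int
    p_params: int  # estimated parameters incl. intercept (and scale if gaussian)
    d2: float
    adj_d2: float
    type3_table: pd.DataFrame | None = None
    aic_trace: tuple = field(default_factory=tuple)


def _family(name: str):
    if name == "gaussian":
        return sm.families.Gaussian()
    return sm.families.Poisson()


def _loglik(family: str, y: np.ndarray, mu: np.ndarray, deviance: float) -> float:
    n = len(y)
    if family == "gaussian":
        return -0.5 * n * (math.log(2 * math.pi * deviance / n) + 1.0)
    # Poisson with the continuous factorial extension
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _fit_design(spec: GLMSpec, design: DesignMatrix, y: np.ndarray) -> GLMFit:
    fam = _family(spec.family)
    if spec.family == "poisson" and np.any(y < 0):
        raise ConfigError(f"{spec.response}: poisson response must be non-negative")
    with warnings.catch_warnings():
        # statsmodels flags non-integer Poisson responses; the continuous
        # extension is intentional here
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design.X, family=fam)
        res = model.fit(maxiter=100, tol=1e-8)
    mu = np.asarray(res.fittedvalues)
    deviance = float(res.deviance)
    llf = _loglik(spec.family, y, mu, deviance)
    p_mean = design.n_params
    p_params = p_mean + (1 if spec.family == "gaussian" else 0)
    aic = -2.0 * llf + 2.0 * p_params
    null_dev = float(res.null_deviance)
    d2 = 0.0 if null_dev == 0 else (null_dev - deviance) / null_dev
    n = len(y)
    adj = adjusted_d2_value(d2, n=n, p=p_mean)
    return GLMFit(
        spec=spec,
        design=design,
        params=pd.Series(res.params, index=design.columns),
        bse=pd.Series(res.bse, index=design.columns),
        llf=llf,
        deviance=deviance,
        null_deviance=null_dev,
        aic=aic,
        n=n,
        p_params=p_params,
        d2=float(np.clip(d2, 0.0, 1.0)),
        adj_d2=adj,
    )


def fit_glm(spec: GLMSpec, data: pd.DataFrame) -> GLMFit:
    """Fit one model by IRLS (Gaussian/identity reduces to exact OLS)."""
    sub = data.dropna(subset=[spec.response, *_data_columns(spec)])
    y = np.asarray(sub[spec.response], dtype=float)
    design = build_design(sub, spec.terms, spec.categorical)
    return _fit_design(spec, design, y)


def _data_columns(spec: GLMSpec):
    cols = []
    for t in spec.terms:
        for p in t.split(":"):
            if p not in cols:
                cols.append(p)
    return cols


def adjusted_d2_value(d2: float, n: int, p: int) -> float:
    """Adjusted explained deviance: 1 - [(n - 1)/(n - p)] * (1 - D²).

    The explained-deviance analogue of adjusted R²; ``p`` is the number of
    estimated mean parameters including the intercept.
    """
    if n <= p:
        raise ConfigError(f"adjusted D² undefined for n={n} <= p={p}")
    if d2 >= 1.0:
        return 1.0
    return 1.0 - ((n - 1) / (n - p)) * (1.0 - d2)


def adjusted_d2(fit: GLMFit) -> tuple[float, float]:
    """(D², adjusted D²) of a fitted model."""
    return fit.d2, fit.adj_d2


def backward_select(full: GLMSpec, data: pd.DataFrame,
                    tol: float = 1e-8) -> GLMFit:
    """Backward stepwise AIC selection.

    Repeatedly deletes the single droppable term whose removal most
    decreases AIC, and stops when no deletion decreases it.  With
    marginality enforced (the default) a main effect becomes droppable only
    once it appears in no remaining interaction; ``enforce_marginality=False``
    on the spec allows the freer deletions sometimes seen in published
    stepwise tables.  AIC ties (within ``tol``) keep the term — the larger
    model wins — and candidate ties are broken by term name, so the search
    is deterministic given the data.
    """
    # fix the estimation sample once so AICs stay comparable across steps
    sub = data.dropna(subset=[full.response, *_data_columns(full)])
    y = np.asarray(sub[full.response], dtype=float)

    def fit_spec(spec: GLMSpec) -> GLMFit:
        design = build_design(sub, spec.terms, spec.categorical)
        return _fit_design(spec, design, y)

    current = fit_spec(full)
    trace = [(",".join(current.spec.terms) or "1", current.aic)]
    while True:
        candidates = []
        for term in sorted(current.spec.droppable_terms()):
            reduced = fit_spec(current.spec.drop(term))
            candidates.append((reduced.aic, term, reduced))
        if not candidates:
            break
        best_aic, _, best_fit = min(candidates, key=lambda c: (c[0], c[1]))
        if best_aic < current.aic - tol:
            current = best_fit
            trace.append((",".join(current.spec.terms) or "1", current.aic))
        else:
            break
    return GLMFit(**{**current.__dict__, "aic_trace": tuple(trace)})


def type3_anova(fit: GLMFit, data: pd.DataFrame | None = None) -> pd.DataFrame:
    """Type-3 (marginal) per-term tests.

    Each term in the fitted model is tested by refitting without that term's
    design columns while keeping every other column — including interactions
    involving it — which is meaningful under the sum-to-zero contrasts used
    here.  Gaussian models use an F test on the deviance difference; Poisson
    models a likelihood-ratio chi-square.
    """
    y = None
    spec = fit.spec
    # recover the response actually used in the fit from the stored design
    if data is not None:
        sub = data.dropna(subset=[spec.response, *_data_columns(spec)])
        y = np.asarray(sub[spec.response], dtype=float)
    if y is None or len(y) != fit.n:
        raise ConfigError("type3_anova needs the data frame the model was fit on")

    rows = []
    terms = [t for t in dict.fromkeys(fit.design.term_of_column) if t != "Intercept"]
    df_resid_full = fit.n - fit.design.n_params
    for term in terms:
        reduced_design = fit.design.without(term)
        df_term = fit.design.n_params - reduced_design.n_params
        reduced = _fit_design(spec, reduced_design, y)
        dev_diff = reduced.deviance - fit.deviance
        if spec.family == "gaussian":
            statistic = (dev_diff / df_term) / (fit.deviance / df_resid_full)
            p = float(stats.f.sf(statistic, df_term, df_resid_full))
            stat_name = "F"
        else:
            statistic = dev_diff
            p = float(stats.chi2.sf(statistic, df_term))
            stat_name = "LR_chi2"
        rows.append({"term": term, "df": df_term, "stat": float(statistic),
                     "stat_name": stat_name, "p": p,
                     "band": significance_band(p)})
    return pd.DataFrame(rows)


def significance_band(p: float) -> str:
    """Symbolic significance: *** <0.001, ** <0.01, * <0.05, • <0.1."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "•"
    return ""


DEFAULT_FAMILY_MAP = {
    "length_m": "gaussian", "S2": "gaussian", "TE": "poisson",
    "TS": "gaussian", "DC_deg_s": "gaussian", "SDDC_deg_s": "gaussian",
}


def model_report(data: pd.DataFrame, responses=None, family_map=None,
                 full_terms=FULL_TERMS, enforce_marginality: bool = True,
                 categorical=DEFAULT_CATEGORICAL):
    """Fit, select and test one model per movement index.

    Returns ``(band_grid, long_table, fits)``: a terms x responses grid of
    significance bands (``—`` where a term was removed by AIC selection),
    a machine-readable long table with statistics, p-values, AIC and the
    deviance summaries, and the fitted models themselves.
    """
    family_map = dict(DEFAULT_FAMILY_MAP, **(family_map or {}))
    responses = list(responses or [r for r in family_map if r in data.columns])
    long_rows, fits = [], {}
    grid = pd.DataFrame("—", index=list(full_terms), columns=responses)
    for resp in responses:
        spec = GLMSpec(resp, family_map.get(resp, "gaussian"), full_terms,
                       categorical=categorical,
                       enforce_marginality=enforce_marginality)
        fit = backward_select(spec, data)
        table = type3_anova(fit, data)
        fit = GLMFit(**{**fit.__dict__, "type3_table": table})
        fits[resp] = fit
        for _, row in table.iterrows():
            grid.loc[row["term"], resp] = row["band"] or "n.s."
            long_rows.append({
                "response": resp, "family": spec.family, "term": row["term"],
                "df": row["df"], "stat": row["stat"],
                "stat_name": row["stat_name"], "p": row["p"],
                "band": row["band"], "aic": fit.aic, "n": fit.n,
                "D2": fit.d2, "adj_D2": fit.adj_d2,
            })
    return grid, pd.DataFrame(long_rows), fits
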