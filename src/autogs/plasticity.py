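"""Reaction norms, variance decomposition and heritability.

A genotype's phenotypic plasticity (PP) is summarized by the intercept and
slope of its reaction norm: the per-genotype ordinary-least-squares
regression of phenotype on the critical-window EP mean across environments.
Variance of the genotype × environment phenotype table is decomposed into
genotype, environment and G×E-plus-residual components, from which
broad-sense line-mean heritability H² = σ²g / (σ²g + σ²e/L) follows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .envirotyping import CriticalWindow
from .errors import DegenerateInputError, UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass
class TraitTable:
    """Genotype × environment phenotype matrix for one trait (NaN = missing)."""

    values: pd.DataFrame  # rows genotypes, columns environments
    trait: str

    def __post_init__(self):
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise DegenerateInputError(
                f"trait table needs ≥ 2 genotypes and ≥ 2 environments, "
                f"got {self.values.shape}"
            )

    @classmethod
    def from_long(cls, df: pd.DataFrame, trait: str) -> "TraitTable":
        """Build from a long table with columns genotype_id, env_id, trait, value."""
        sub = df[df["trait"] == trait] if "trait" in df.columns else df
        wide = sub.pivot_table(index="genotype_id", columns="env_id", values="value",
                               aggfunc="mean")
        return cls(values=wide, trait=trait)

    @property
    def environments(self):
        return list(self.values.columns)

    @property
    def genotypes(self):
        return list(self.values.index)


@dataclass(frozen=True)
class PPParams:
    """Per-genotype reaction-norm parameters for one (trait, critical window)."""

    genotype_id: str
    trait: str
    critical_window: CriticalWindow
    intercept: float
    slope: float
    r2_fit: float
    n_envs: int


@dataclass(frozen=True)
class VarianceComponents:
    var_g: float
    var_e: float
    var_gxe_residual: float
    shares: tuple  # (share_g, share_e, share_gxe)
    h2: float


def environment_trait_means(trait_table: TraitTable) -> pd.Series:
    """Arithmetic trait mean per environment, skipping missing values."""
    empty = trait_table.values.columns[trait_table.values.isna().all(axis=0)]
    if len(empty):
        raise DegenerateInputError(
            f"environment(s) with no observations: {list(empty)}"
        )
    return trait_table.values.mean(axis=0, skipna=True)


def fit_reaction_norms(
    trait_table: TraitTable,
    window: CriticalWindow,
    windowed_eps: pd.Series,
    min_envs: int = 3,
) -> list[PPParams]:
    """Per-genotype OLS of phenotype on the critical-window EP mean.

    ``windowed_eps`` maps env_id → the A..B EP mean for ``window``.
    Genotypes observed in fewer than ``min_envs`` environments (with both a
    phenotype and an EP value) are skipped with a log message; a genotype
    whose environments show zero EP variance is likewise skipped.  Raises
    only when no genotype can be fitted.
    """
    envs = trait_table.values.columns.intersection(windowed_eps.index)
    Y = trait_table.values[envs]
    x_full = windowed_eps.loc[envs].to_numpy(float)

    out: list[PPParams] = []
    n_skipped = n_degenerate = 0
    for g, row in Y.iterrows():
        y = row.to_numpy(float)
        ok = ~(np.isnan(y) | np.isnan(x_full))
        if ok.sum() < min_envs:
            n_skipped += 1
            continue
        x, yy = x_full[ok], y[ok]
        sx = x.std()
        if sx == 0:
            n_degenerate += 1
            continue
        slope = float(np.cov(x, yy, ddof=1)[0, 1] / np.var(x, ddof=1))
        intercept = float(yy.mean() - slope * x.mean())
        resid = yy - (intercept + slope * x)
        ssy = float(((yy - yy.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ssy if ssy > 0 else 1.0
        out.append(
            PPParams(str(g), trait_table.trait, window, intercept, slope, r2, int(ok.sum()))
        )
    if n_skipped:
        logger.info("%d genotype(s) below %d-environment minimum, skipped", n_skipped, min_envs)
    if n_degenerate:
        logger.warning("%d genotype(s) with zero EP variance, skipped", n_degenerate)
    if not out:
        raise DegenerateInputError("no genotype had enough environments / EP variance to fit")
    return out


def pp_params_frame(params: list[PPParams]) -> pd.DataFrame:
    """One row per genotype × trait × critical window, CSV-ready."""
    return pd.DataFrame(
        {
            "genotype_id": [p.genotype_id for p in params],
            "trait": [p.trait for p in params],
            "ep_name": [p.critical_window.ep_name for p in params],
            "start_stage": [p.critical_window.start_label or p.critical_window.start_stage
                            for p in params],
            "end_stage": [p.critical_window.end_label or p.critical_window.end_stage
                          for p in params],
            "intercept": [p.intercept for p in params],
            "slope": [p.slope for p in params],
            "r2_fit": [p.r2_fit for p in params],
            "n_envs": [p.n_envs for p in params],
        }
    )


def _mom_decomposition(Y: np.ndarray) -> tuple[float, float, float]:
    """Two-way method of moments on a genotype × environment table.

    With one observation per cell the expected mean squares are
    E[MS_G] = σ²res + L σ²g, E[MS_E] = σ²res + G σ²e, E[MS_res] = σ²res,
    where σ²res absorbs G×E and measurement error.  Exact on balanced data;
    missing cells are mean-imputed first (adequate for near-balanced
    tables; REML handles strong unbalance).
    """
    G, L = Y.shape
    if np.isnan(Y).any():
        row_mean = np.nanmean(Y, axis=1, keepdims=True)
        col_mean = np.nanmean(Y, axis=0, keepdims=True)
        grand = np.nanmean(Y)
        fill = row_mean + col_mean - grand
        Y = np.where(np.isnan(Y), fill, Y)
    grand = Y.mean()
    gm = Y.mean(axis=1)
    em = Y.mean(axis=0)
    ss_g = L * ((gm - grand) ** 2).sum()
    ss_e = G * ((em - grand) ** 2).sum()
    resid = Y - gm[:, None] - em[None, :] + grand
    ss_res = (resid**2).sum()
    ms_g = ss_g / (G - 1)
    ms_e = ss_e / (L - 1)
    ms_res = ss_res / ((G - 1) * (L - 1))
    var_res = ms_res
    var_g = max((ms_g - ms_res) / L, 0.0)
    var_e = max((ms_e - ms_res) / G, 0.0)
    return var_g, var_e, var_res


def _reml_decomposition(Y: np.ndarray) -> tuple[float, float, float]:
    """Crossed random-intercept REML via statsmodels variance components."""
    import statsmodels.formula.api as smf

    G, L = Y.shape
    df = pd.DataFrame(
        {
            "y": Y.ravel(),
            "geno": np.repeat([f"g{i}" for i in range(G)], L),
            "env": np.tile([f"e{j}" for j in range(L)], G),
        }
    ).dropna()
    df["one"] = 1
    model = smf.mixedlm(
        "y ~ 1", df, groups="one",
        vc_formula={"geno": "0 + C(geno)", "env": "0 + C(env)"},
    )
    fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    names = list(fit.model.exog_vc.names)
    vc = dict(zip(names, fit.vcomp))
    return (
        float(max(vc["geno"], 0.0)),
        float(max(vc["env"], 0.0)),
        float(fit.scale),
    )


def variance_decomposition(
    trait_table: TraitTable, method: str = "mom"
) -> VarianceComponents:
    """Decompose phenotypic variance into genotype / environment / G×E+residual.

    ``method='mom'`` (default) is the closed-form two-way method of moments;
    ``method='reml'`` refines with a crossed random-effects REML fit.
    Negative moment estimates are truncated to zero.  H² uses the
    line-mean formula with the residual component as error variance.
    """
    Y = trait_table.values.to_numpy(float)
    if Y.shape[1] < 2:
        raise DegenerateInputError("need ≥ 2 environments to estimate var_e")
    if method == "mom":
        var_g, var_e, var_res = _mom_decomposition(Y)
    elif method == "reml":
        var_g, var_e, var_res = _reml_decomposition(Y)
    else:
        raise ValueError(f"unknown method {method!r}")
    total = var_g + var_e + var_res
    shares = (
        (var_g / total, var_e / total, var_res / total) if total > 0 else (0.0, 0.0, 0.0)
    )
    h2 = (
        heritability(var_g, var_res, Y.shape[1])
        if var_g + var_res > 0
        else float("nan")
    )
    return VarianceComponents(var_g, var_e, var_res, shares, h2)


def heritability(var_g: float, var_e: float, n_envs: int) -> float:
    """Broad-sense line-mean heritability H² = σ²g / (σ²g + σ²e / L)."""
    if var_g < 0 or var_e < 0:
        raise ValueError("variance components must be non-negative")
    if n_envs < 1:
        raise ValueError("n_envs must be ≥ 1")
    if var_g == 0 and var_e == 0:
        raise UndefinedStatisticError("H² undefined when both variances are zero")
    return var_g / (var_g + var_e / n_envs)
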