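"""Feature assembly, stacked-ensemble regression and cross-environment evaluation.

Rows are observed (genotype, environment) phenotype records; columns are
marker dosages (a chosen feature class such as All-TAMs-plus-flanks) and,
optionally, environmental covariates — either the raw daily EP series or
the reduced 9 × W RD_EP profile of the row's environment.  A stacking
ensemble of gradient-boosted trees (XGBoost, LightGBM, sklearn histogram
GBM) and a Bayesian ridge regressor is tuned by a seeded random search and
combined by a non-negative linear meta-learner fit on out-of-fold
predictions.  Accuracy is the Pearson correlation (PCC) between observed
and predicted phenotypes, under plain fivefold CV or one of three
cross-environment/cross-genotype hold-out scenarios:

* scenario 1 — untested genotypes in tested environments
  (leave-one-half-of-genotypes-out, repeated);
* scenario 2 — tested genotypes in untested environments
  (leave-one-environment-out);
* scenario 3 — untested genotypes in untested environments (joint).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.linear_model import BayesianRidge, LinearRegression
from sklearn.model_selection import KFold

from .envirotyping import RDEPMatrix
from .errors import ConfigError, DegenerateInputError, SchemaMismatchError, UndefinedStatisticError
from .plasticity import TraitTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics

def pcc(observed, predicted) -> float:
    """Pearson correlation between observed and predicted vectors."""
    o = np.asarray(observed, float)
    p = np.asarray(predicted, float)
    if len(o) < 3:
        raise DegenerateInputError("PCC needs length ≥ 3")
    if o.std() == 0 or p.std() == 0:
        raise UndefinedStatisticError("PCC undefined for a constant vector")
    return float(np.corrcoef(o, p)[0, 1])


def percent_change(baseline_pcc: float, improved_pcc: float) -> float:
    """(improved − baseline) / baseline × 100."""
    if baseline_pcc == 0:
        raise UndefinedStatisticError("percent change undefined for zero baseline")
    return (improved_pcc - baseline_pcc) / baseline_pcc * 100.0


# ---------------------------------------------------------------------------
# feature assembly

@dataclass
class FeatureSet:
    """Design matrix over (genotype, environment) rows with column provenance."""

    X: pd.DataFrame  # MultiIndex rows (genotype_id, env_id)
    response: pd.Series
    provenance: pd.Series  # per-column tag

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ConfigError("feature matrix contains missing cells")
        if not self.provenance.index.equals(self.X.columns):
            raise ConfigError("provenance must cover every column exactly")

    @property
    def genotypes(self):
        return self.X.index.get_level_values(0)

    @property
    def environments(self):
        return self.X.index.get_level_values(1)


def assemble_features(
    genotypes,
    marker_set: list,
    rdeps: dict[str, RDEPMatrix] | None,
    trait_table: TraitTable,
    ep_mode: str = "none",
    raw_ep_tables: dict | None = None,
    marker_tags: dict | None = None,
) -> FeatureSet:
    """Build the (genotype, environment) design matrix for one trait.

    One row per observed phenotype; marker columns repeat the genotype's
    dosages across its environments, EP columns are identical for all
    genotypes within an environment.  ``ep_mode``: ``none`` (markers only),
    ``reduced`` (flattened 9 × W RD_EP cells; NaN cells from unreached
    stages are filled with that cell's cross-environment mean) or ``raw``
    (per-day EP values truncated to the shortest common season).
    """
    if ep_mode not in ("none", "raw", "reduced"):
        raise ConfigError(f"unknown ep_mode {ep_mode!r}")
    geno_frame = genotypes.to_frame()[marker_set]

    long = trait_table.values.stack()
    long = long[long.index.get_level_values(0).isin(geno_frame.index)]
    long.index.names = ["genotype_id", "env_id"]
    if long.empty:
        raise DegenerateInputError("no (genotype, environment) rows with phenotypes")
    g_idx = long.index.get_level_values(0)
    e_idx = long.index.get_level_values(1)

    X = geno_frame.loc[g_idx].set_index(long.index)
    tags = pd.Series(
        [marker_tags.get(m, "marker") if marker_tags else "marker" for m in X.columns],
        index=X.columns,
    )

    if ep_mode != "none":
        envs = sorted(set(e_idx))
        if ep_mode == "reduced":
            if rdeps is None:
                raise ConfigError("reduced ep_mode requires RD_EP profiles")
            missing = [e for e in envs if e not in rdeps]
            if missing:
                raise ConfigError(f"environment(s) lacking EP profile: {missing}")
            stacked = np.stack([rdeps[e].matrix.to_numpy().ravel() for e in envs])
            cell_mean = np.nanmean(stacked, axis=0)
            stacked = np.where(np.isnan(stacked), cell_mean, stacked)
            names = [
                f"RDEP:{ep}:{win}"
                for ep in rdeps[envs[0]].matrix.index
                for win in rdeps[envs[0]].matrix.columns
            ]
            ep_frame = pd.DataFrame(stacked, index=envs, columns=names)
            tag = "RD_EP"
        else:
            if raw_ep_tables is None:
                raise ConfigError("raw ep_mode requires daily EP tables")
            missing = [e for e in envs if e not in raw_ep_tables]
            if missing:
                raise ConfigError(f"environment(s) lacking EP profile: {missing}")
            from .envparams import EP_NAMES

            n_days = min(len(raw_ep_tables[e].daily) for e in envs)
            rows = {
                e: raw_ep_tables[e].daily[list(EP_NAMES)].to_numpy()[:n_days].ravel()
                for e in envs
            }
            names = [f"RAWEP:{ep}:d{d}" for d in range(n_days) for ep in EP_NAMES]
            ep_frame = pd.DataFrame.from_dict(rows, orient="index")
            ep_frame.columns = names
            tag = "Raw_EP"
        ep_block = ep_frame.loc[e_idx].set_index(long.index)
        X = pd.concat([X, ep_block], axis=1)
        tags = pd.concat([tags, pd.Series(tag, index=ep_block.columns)])

    return FeatureSet(X=X, response=long.rename(trait_table.trait), provenance=tags)


# ---------------------------------------------------------------------------
# cross-validation schemes

@dataclass
class CVScheme:
    scheme: str
    folds: list  # list of (train_idx ndarray, test_idx ndarray, fold_label)
    seed: int


def make_cv_scheme(
    rows: pd.MultiIndex,
    scheme: str,
    seed: int,
    n_folds: int = 5,
    n_repeats: int = 10,
) -> CVScheme:
    """Fold construction for fivefold CV and the three prediction scenarios.

    ``rows`` is the (genotype, environment) row index.  ``fivefold``
    partitions rows at random; ``scenario1`` holds out a random half of the
    genotypes (all their rows), repeated ``n_repeats`` times; ``scenario2``
    holds out each environment once; ``scenario3`` crosses each environment
    with a random genotype half, training on the other genotypes in the
    other environments only.
    """
    rng = np.random.default_rng(seed)
    genos = rows.get_level_values(0).to_numpy()
    envs = rows.get_level_values(1).to_numpy()
    uniq_g = np.unique(genos)
    uniq_e = np.unique(envs)
    all_idx = np.arange(len(rows))
    folds = []

    if scheme == "fivefold":
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for i, (tr, te) in enumerate(kf.split(all_idx)):
            folds.append((tr, te, f"fold{i + 1}"))
    elif scheme == "scenario1":
        if len(uniq_g) < 2:
            raise ConfigError("scenario1 needs ≥ 2 genotypes")
        for r in range(n_repeats):
            held = set(rng.choice(uniq_g, size=len(uniq_g) // 2, replace=False))
            te = np.nonzero(np.isin(genos, list(held)))[0]
            tr = np.setdiff1d(all_idx, te)
            folds.append((tr, te, f"rep{r + 1}"))
    elif scheme == "scenario2":
        if len(uniq_e) < 2:
            raise ConfigError("scenario2 needs ≥ 2 environments")
        for e in uniq_e:
            te = np.nonzero(envs == e)[0]
            tr = np.setdiff1d(all_idx, te)
            folds.append((tr, te, str(e)))
    elif scheme == "scenario3":
        if len(uniq_e) < 2:
            raise ConfigError("scenario3 needs ≥ 2 environments")
        if len(uniq_g) < 2:
            raise ConfigError("scenario3 needs ≥ 2 genotypes")
        for e in uniq_e:
            held = set(rng.choice(uniq_g, size=len(uniq_g) // 2, replace=False))
            te = np.nonzero((envs == e) & np.isin(genos, list(held)))[0]
            tr = np.nonzero((envs != e) & ~np.isin(genos, list(held)))[0]
            folds.append((tr, te, str(e)))
    else:
        raise ConfigError(f"unknown CV scheme {scheme!r}")
    return CVScheme(scheme=scheme, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# base learners and tuning

def fast_sample_params(name: str, rng: np.random.Generator) -> dict:
    """Reduced search space for small design matrices (≲ 1000 rows).

    Shallow trees and 40–100 boosting rounds; appropriate when rows are few
    and features moderately many, and an order of magnitude cheaper than the
    default space.
    """
    if name == "xgb":
        return {
            "n_estimators": int(rng.integers(40, 101)),
            "max_depth": int(rng.integers(2, 5)),
            "learning_rate": float(10 ** rng.uniform(-1.5, -0.5)),
            "subsample": float(rng.uniform(0.7, 1.0)),
            "reg_lambda": float(10 ** rng.uniform(-2, 1)),
        }
    if name == "lgbm":
        return {
            "n_estimators": int(rng.integers(40, 101)),
            "num_leaves": int(rng.integers(7, 32)),
            "learning_rate": float(10 ** rng.uniform(-1.5, -0.5)),
            "min_child_samples": int(rng.integers(5, 31)),
            "reg_lambda": float(10 ** rng.uniform(-2, 1)),
        }
    if name == "hgb":
        return {
            "max_iter": int(rng.integers(40, 101)),
            "max_depth": int(rng.integers(2, 5)),
            "learning_rate": float(10 ** rng.uniform(-1.5, -0.5)),
            "l2_regularization": float(10 ** rng.uniform(-2, 1)),
        }
    return _sample_params(name, rng)


def _sample_params(name: str, rng: np.random.Generator) -> dict:
    """Draw one hyperparameter configuration from the documented search space."""
    if name == "xgb":
        return {
            "n_estimators": int(rng.integers(100, 401)),
            "max_depth": int(rng.integers(3, 9)),
            "learning_rate": float(10 ** rng.uniform(-2, -0.5)),
            "subsample": float(rng.uniform(0.6, 1.0)),
            "colsample_bytree": float(rng.uniform(0.5, 1.0)),
            "reg_lambda": float(10 ** rng.uniform(-2, 1)),
        }
    if name == "lgbm":
        return {
            "n_estimators": int(rng.integers(100, 401)),
            "num_leaves": int(rng.integers(15, 128)),
            "learning_rate": float(10 ** rng.uniform(-2, -0.5)),
            "min_child_samples": int(rng.integers(5, 31)),
            "reg_lambda": float(10 ** rng.uniform(-2, 1)),
        }
    if name == "hgb":
        return {
            "max_iter": int(rng.integers(100, 401)),
            "max_depth": int(rng.integers(3, 9)),
            "learning_rate": float(10 ** rng.uniform(-2, -0.5)),
            "l2_regularization": float(10 ** rng.uniform(-2, 1)),
        }
    if name == "bayes":
        return {
            "alpha_1": float(10 ** rng.uniform(-7, -5)),
            "lambda_1": float(10 ** rng.uniform(-7, -5)),
        }
    raise ConfigError(f"unknown base learner {name!r}")


def _make_learner(name: str, params: dict, seed: int):
    if name == "xgb":
        from xgboost import XGBRegressor

        return XGBRegressor(
            random_state=seed, n_jobs=1, tree_method="hist", verbosity=0, **params
        )
    if name == "lgbm":
        from lightgbm import LGBMRegressor

        return LGBMRegressor(
            random_state=seed, n_jobs=1, deterministic=True, force_col_wise=True,
            verbose=-1, **params,
        )
    if name == "hgb":
        return HistGradientBoostingRegressor(random_state=seed, **params)
    if name == "bayes":
        return BayesianRidge(**params)
    raise ConfigError(f"unknown base learner {name!r}")


DEFAULT_BASE_LEARNERS = ("xgb", "lgbm", "hgb", "bayes")


@dataclass
class StackedModel:
    """Trained stacking ensemble: tuned base learners + non-negative meta weights."""

    base_names: list
    base_params: dict
    base_models: dict
    meta: LinearRegression
    columns: pd.Index
    seed: int
    config_hash: str
    fitted_values: np.ndarray = field(default=None, repr=False)

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "StackedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _tune_one(name, X, y, budget, inner_cv, seed, rng, sampler):
    """Random-search one learner: best mean-squared-error over inner CV."""
    best_params, best_score = None, np.inf
    kf = KFold(n_splits=inner_cv, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    for _ in range(budget):
        params = sampler(name, rng)
        errs = []
        for tr, te in splits:
            m = _make_learner(name, params, seed)
            m.fit(X[tr], y[tr])
            errs.append(float(np.mean((m.predict(X[te]) - y[te]) ** 2)))
        score = float(np.mean(errs))
        if score < best_score:
            best_params, best_score = params, score
    return best_params, best_score


def train_stacked_ensemble(
    features: FeatureSet,
    base_learners=DEFAULT_BASE_LEARNERS,
    tuning_budget: int = 50,
    seed: int = 0,
    inner_k: int = 5,
    tuning_cv: int = 3,
    search_space: str = "default",
) -> StackedModel:
    """Tune, stack and fit the ensemble on all rows of ``features``.

    Each base learner is tuned by a seeded random search (``tuning_budget``
    configurations scored by ``tuning_cv``-fold mean squared error); its
    out-of-fold predictions over an internal ``inner_k``-fold split train a
    non-negative linear meta-learner with intercept.  Tuned learners are
    refit on all rows for the final artifact.  Fully deterministic under
    ``seed``.  ``search_space`` selects the hyperparameter space:
    ``"default"`` or ``"fast"`` (see :func:`fast_sample_params`).
    """
    if tuning_budget < 1:
        raise ConfigError("tuning_budget must be ≥ 1")
    if len(base_learners) < 1:
        raise ConfigError("need at least one base learner")
    X = features.X.to_numpy(float)
    y = features.response.to_numpy(float)
    if len(y) < 50:
        raise DegenerateInputError(f"need ≥ 50 training rows, got {len(y)}")

    cfg = {
        "base_learners": list(base_learners),
        "tuning_budget": tuning_budget,
        "inner_k": inner_k,
        "tuning_cv": tuning_cv,
        "seed": seed,
        "n_columns": X.shape[1],
        "search_space": search_space,
    }
    sampler = fast_sample_params if search_space == "fast" else _sample_params
    config_hash = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:12]

    tuned: dict = {}
    kept: list = []
    for i, name in enumerate(base_learners):
        rng = np.random.default_rng([seed, i])
        try:
            params, score = _tune_one(
                name, X, y, tuning_budget, tuning_cv, seed, rng, sampler
            )
            tuned[name] = params
            kept.append(name)
            logger.info("tuned %s: inner MSE %.4g", name, score)
        except Exception as exc:  # noqa: BLE001 — a failing learner is excluded, not fatal
            logger.warning("base learner %s failed to fit (%s); excluded", name, exc)
    if not kept:
        raise ConfigError("every base learner failed to fit")

    kf = KFold(n_splits=inner_k, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    oof = np.zeros((len(y), len(kept)))
    for j, name in enumerate(kept):
        for tr, te in splits:
            m = _make_learner(name, tuned[name], seed)
            m.fit(X[tr], y[tr])
            oof[te, j] = m.predict(X[te])
    meta = LinearRegression(positive=True)
    meta.fit(oof, y)

    base_models = {}
    for name in kept:
        m = _make_learner(name, tuned[name], seed)
        m.fit(X, y)
        base_models[name] = m
    model = StackedModel(
        base_names=kept, base_params=tuned, base_models=base_models, meta=meta,
        columns=features.X.columns, seed=seed, config_hash=config_hash,
    )
    model.fitted_values = predict(model, features.X)
    return model


def predict(model: StackedModel, X_new: pd.DataFrame) -> np.ndarray:
    """Meta-combined base predictions for new rows (schema-checked, unclipped)."""
    missing = model.columns.difference(X_new.columns)
    extra = X_new.columns.difference(model.columns)
    if len(missing) or len(extra):
        raise SchemaMismatchError(missing, extra)
    X = X_new[model.columns].to_numpy(float)
    base = np.column_stack([model.base_models[n].predict(X) for n in model.base_names])
    return model.meta.predict(base)


@dataclass
class PredictionResult:
    scheme: str
    fold_labels: list
    fold_pcc: list
    observed: list
    predicted: list

    @property
    def mean_pcc(self) -> float:
        vals = [p for p in self.fold_pcc if not np.isnan(p)]
        return float(np.mean(vals)) if vals else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fold": self.fold_labels, "pcc": self.fold_pcc})


def evaluate(
    features: FeatureSet,
    cv: CVScheme,
    base_learners=DEFAULT_BASE_LEARNERS,
    tuning_budget: int = 50,
    seed: int = 0,
    inner_k: int = 5,
    tuning_cv: int = 3,
    search_space: str = "default",
) -> PredictionResult:
    """Train and score the stacked ensemble over the folds of ``cv``.

    Per-fold PCC between observed and predicted phenotypes; a fold with a
    constant vector reports NaN (missing PCC) rather than failing.
    """
    labels, pccs, obs_all, pred_all = [], [], [], []
    for tr, te, label in cv.folds:
        sub = FeatureSet(
            X=features.X.iloc[tr],
            response=features.response.iloc[tr],
            provenance=features.provenance,
        )
        model = train_stacked_ensemble(
            sub, base_learners=base_learners, tuning_budget=tuning_budget,
            seed=seed, inner_k=inner_k, tuning_cv=tuning_cv,
            search_space=search_space,
        )
        pred = predict(model, features.X.iloc[te])
        obs = features.response.iloc[te].to_numpy(float)
        try:
            r = pcc(obs, pred)
        except (DegenerateInputError, UndefinedStatisticError):
            r = float("nan")
        labels.append(label)
        pccs.append(r)
        obs_all.append(obs)
        pred_all.append(pred)
        logger.info("%s %s: PCC %.4f (n=%d)", cv.scheme, label, r, len(obs))
    return PredictionResult(cv.scheme, labels, pccs, obs_all, pred_all)


def permutation_importance(
    model: StackedModel,
    X: pd.DataFrame,
    response: pd.Series,
    n_repeats: int = 5,
    seed: int = 0,
    columns=None,
) -> pd.DataFrame:
    """Mean PCC drop when a feature column is permuted.

    For each column (or the subset ``columns``), the column is shuffled
    ``n_repeats`` times and the drop in PCC relative to the intact matrix is
    averaged; the sign of the feature's marginal effect is the sign of its
    Pearson correlation with the prediction.  Deterministic under ``seed``.
    """
    if len(response) < 30:
        raise DegenerateInputError("permutation importance needs ≥ 30 rows")
    rng = np.random.default_rng(seed)
    y = response.to_numpy(float)
    baseline = pcc(y, predict(model, X))
    cols = list(columns) if columns is not None else list(X.columns)
    base_pred = predict(model, X)
    drops, signs = [], []
    Xw = X.copy()
    for c in cols:
        orig = Xw[c].to_numpy().copy()
        vals = []
        for _ in range(n_repeats):
            Xw[c] = rng.permutation(orig)
            vals.append(baseline - pcc(y, predict(model, Xw)))
        Xw[c] = orig
        drops.append(float(np.mean(vals)))
        sd = np.std(orig)
        signs.append(float(np.sign(np.corrcoef(orig, base_pred)[0, 1])) if sd > 0 else 0.0)
    out = pd.DataFrame({"importance": drops, "effect_sign": signs}, index=cols)
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("importance", ascending=False)
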