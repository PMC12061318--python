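"""Stage segmentation, environmental dimensionality reduction and critical windows.

The season of each environment is cut into developmental-stage windows by
cumulative growing degree days (36 maize stages V0..V21, R1..R6 by
default).  Daily EPs are averaged within each stage window, giving the
reduced 9 × W ``RD_EP`` profile per environment.  A sliding-window scan over
all stage spans A..B then looks for the span in which an EP's
across-environment mean is linearly related to the across-environment trait
means (the *critical window*, |r| ≥ 0.90 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .envparams import EP_NAMES, EPTable
from .errors import ConfigError, DegenerateInputError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: 36 maize developmental stages: vegetative V0..V29 (emergence through
#: tassel), then reproductive R1..R6 (silking through maturity).
MAIZE_STAGE_LABELS = tuple(f"V{i}" for i in range(30)) + tuple(f"R{i}" for i in range(1, 7))

#: Default cumulative-GDD upper bounds (°F·day) for the 36 maize stages.
#: Vegetative stages advance roughly every 60 °F·day after a 100 °F·day
#: emergence phase; reproductive stages span wider thermal intervals.  The
#: table is ordinary configuration — any strictly increasing bound vector
#: with matching labels may be supplied instead.
MAIZE_GDD_BOUNDS = tuple(
    [100.0 + 60.0 * i for i in range(30)]  # V0..V29 -> 100..1840
    + [1980.0, 2120.0, 2260.0, 2400.0, 2520.0, 2640.0]  # R1..R6
)

#: A compact 11-stage example table (wheat-style Zadoks macro-stages, °C·day
#: scale converted to °F·day) for small-season crops.
WHEAT_STAGE_LABELS = tuple(f"Z{i}" for i in range(1, 12))
WHEAT_GDD_BOUNDS = tuple(np.linspace(180.0, 2160.0, 11))


@dataclass(frozen=True)
class StageThresholdTable:
    """Ordered stage labels and their cumulative-GDD upper bounds."""

    stage_labels: tuple
    gdd_bounds: tuple

    def __post_init__(self):
        if len(self.stage_labels) != len(self.gdd_bounds):
            raise ConfigError(
                f"{len(self.stage_labels)} labels vs {len(self.gdd_bounds)} bounds"
            )
        b = np.asarray(self.gdd_bounds, float)
        if not np.all(np.diff(b) > 0):
            raise ConfigError("stage GDD bounds must be strictly increasing")

    def __len__(self):
        return len(self.stage_labels)


def maize_stage_table() -> StageThresholdTable:
    return StageThresholdTable(MAIZE_STAGE_LABELS, MAIZE_GDD_BOUNDS)


def wheat_stage_table() -> StageThresholdTable:
    return StageThresholdTable(WHEAT_STAGE_LABELS, WHEAT_GDD_BOUNDS)


@dataclass
class StageWindows:
    """Per-stage contiguous day index ranges ``[start, stop)`` for one season.

    Stages the season never reaches carry ``(i, i)`` empty ranges and are
    listed in ``unreached``.
    """

    ranges: list
    labels: tuple
    unreached: list = field(default_factory=list)

    def day_counts(self) -> np.ndarray:
        return np.array([b - a for a, b in self.ranges], dtype=int)


@dataclass
class RDEPMatrix:
    """Reduced environmental profile: 9 EPs × W stage-windows for one env.

    ``matrix`` is a DataFrame with EP names as rows and stage labels as
    columns; empty windows hold NaN.  ``window_days`` counts the days per
    window.
    """

    env_id: str
    matrix: pd.DataFrame
    window_days: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class CriticalWindow:
    """A stage span A..B in which an EP linearly drives a trait across envs."""

    trait: str
    ep_name: str
    start_stage: int
    end_stage: int
    r: float
    start_label: str = ""
    end_label: str = ""

    @property
    def span(self) -> int:
        return self.end_stage - self.start_stage + 1


def segment_stages(cumulative_gdd, thresholds: StageThresholdTable) -> StageWindows:
    """Assign each day to its developmental stage by cumulative GDD.

    A day belongs to the first stage whose upper bound strictly exceeds its
    cumulative GDD; days beyond the last bound stay in the final stage.
    Returns contiguous, non-overlapping day ranges; unreached stages are
    flagged.
    """
    g = np.asarray(cumulative_gdd, float)
    if np.any(np.diff(g) < 0):
        raise ConfigError("cumulative GDD must be non-decreasing")
    bounds = np.asarray(thresholds.gdd_bounds, float)
    stage_of_day = np.searchsorted(bounds, g, side="right")
    stage_of_day = np.minimum(stage_of_day, len(bounds) - 1)
    ranges, unreached = [], []
    for s in range(len(bounds)):
        idx = np.nonzero(stage_of_day == s)[0]
        if idx.size:
            ranges.append((int(idx[0]), int(idx[-1]) + 1))
        else:
            prev_stop = ranges[-1][1] if ranges else 0
            ranges.append((prev_stop, prev_stop))
            unreached.append(thresholds.stage_labels[s])
    if unreached:
        logger.info("season does not reach stage(s): %s", ", ".join(map(str, unreached)))
    return StageWindows(ranges=ranges, labels=tuple(thresholds.stage_labels), unreached=unreached)


def reduce_eps(ep_table: EPTable, windows: StageWindows) -> RDEPMatrix:
    """Average each EP within each stage window (one value per EP per window)."""
    daily = ep_table.daily[list(EP_NAMES)].to_numpy()
    if daily.shape[0] < windows.ranges[-1][1]:
        raise ConfigError(
            f"{ep_table.env_id}: EP series shorter than segmented season "
            f"({daily.shape[0]} vs {windows.ranges[-1][1]} days)"
        )
    w = len(windows.ranges)
    mat = np.full((len(EP_NAMES), w), np.nan)
    for j, (a, b) in enumerate(windows.ranges):
        if b > a:
            mat[:, j] = np.nanmean(daily[a:b], axis=0)
    return RDEPMatrix(
        env_id=ep_table.env_id,
        matrix=pd.DataFrame(mat, index=list(EP_NAMES), columns=list(windows.labels)),
        window_days=windows.day_counts(),
    )


def sliding_window_means(rdep: RDEPMatrix) -> pd.DataFrame:
    """Day-weighted mean of every EP over every stage span A..B.

    Returns a DataFrame indexed by (ep_name, start, stop) — W(W+1)/2 spans
    per EP — with the A..B mean weighted by per-window day counts.  Spans
    containing only empty windows are NaN.
    """
    vals = rdep.matrix.to_numpy()  # (9, W)
    days = rdep.window_days.astype(float)  # (W,)
    w = vals.shape[1]
    weighted = np.where(np.isnan(vals), 0.0, vals) * days
    present_days = np.where(np.isnan(vals), 0.0, days)  # per-EP usable days
    cw = np.concatenate([np.zeros((len(EP_NAMES), 1)), np.cumsum(weighted, axis=1)], axis=1)
    cd = np.concatenate([np.zeros((len(EP_NAMES), 1)), np.cumsum(present_days, axis=1)], axis=1)

    index, values = [], []
    for a in range(w):
        for b in range(a, w):
            num = cw[:, b + 1] - cw[:, a]
            den = cd[:, b + 1] - cd[:, a]
            with np.errstate(invalid="ignore", divide="ignore"):
                mean = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
            for i, ep in enumerate(EP_NAMES):
                index.append((ep, a, b))
                values.append(mean[i])
    idx = pd.MultiIndex.from_tuples(index, names=["ep_name", "start", "stop"])
    return pd.DataFrame({"value": values}, index=idx)


def stack_windowed_eps(rdeps: dict[str, RDEPMatrix]) -> pd.DataFrame:
    """Environments × (ep, A, B) matrix of sliding-window means."""
    cols = {env: sliding_window_means(r)["value"] for env, r in rdeps.items()}
    return pd.DataFrame(cols).T.sort_index()


def _overlaps(w1: CriticalWindow, w2: CriticalWindow) -> bool:
    return w1.start_stage <= w2.end_stage and w2.start_stage <= w1.end_stage


def critical_window_search(
    env_trait_means: pd.Series,
    windowed_eps: pd.DataFrame,
    r_threshold: float = 0.90,
    trait: str = "",
    stage_labels: tuple | None = None,
    collapse_overlaps: bool = True,
) -> list[CriticalWindow]:
    """Find stage spans whose EP means track the environment trait means.

    For every (EP, A, B), the Pearson correlation between the
    environment-wise trait means and the environment-wise A..B EP means is
    computed (environments with a missing EP value are dropped pairwise).
    Spans with |r| ≥ ``r_threshold`` qualify; per EP, overlapping qualifying
    spans are collapsed to the single best-|r| one (ties: smaller span, then
    earlier start).  Output is sorted by |r| descending with the same
    tie-break.

    ``env_trait_means`` maps env_id → trait mean; ``windowed_eps`` is the
    output of :func:`stack_windowed_eps` (rows = environments).
    """
    envs = env_trait_means.index.intersection(windowed_eps.index)
    if len(envs) < 3:
        raise DegenerateInputError(f"need ≥ 3 environments, got {len(envs)}")
    y = env_trait_means.loc[envs].to_numpy(float)
    if np.nanstd(y) == 0:
        raise UndefinedStatisticError("trait means constant across environments")
    X = windowed_eps.loc[envs].to_numpy(float)  # (n_env, n_span*9)

    qualifying: list[CriticalWindow] = []
    n_skipped = 0
    keys = windowed_eps.columns
    for j, (ep, a, b) in enumerate(keys):
        x = X[:, j]
        ok = ~np.isnan(x)
        if ok.sum() < 3:
            n_skipped += 1
            continue
        xs, ys = x[ok], y[ok]
        if xs.std() == 0 or ys.std() == 0:
            n_skipped += 1
            continue
        r = float(np.corrcoef(xs, ys)[0, 1])
        if abs(r) >= r_threshold:
            sa = stage_labels[a] if stage_labels else str(a)
            sb = stage_labels[b] if stage_labels else str(b)
            qualifying.append(
                CriticalWindow(trait, ep, int(a), int(b), r, sa, sb)
            )
    if n_skipped:
        logger.info("skipped %d degenerate (EP, A, B) spans", n_skipped)

    order = lambda w: (-abs(w.r), w.span, w.start_stage)
    qualifying.sort(key=order)
    if not collapse_overlaps:
        return qualifying
    kept: list[CriticalWindow] = []
    for w in qualifying:
        if not any(k.ep_name == w.ep_name and _overlaps(k, w) for k in kept):
            kept.append(w)
    return kept


def cluster_environments(
    rdeps: dict[str, RDEPMatrix], k: int
) -> tuple[pd.Series, np.ndarray]:
    """Ward clustering of environments on their flattened RD_EP profiles.

    Missing cells are imputed by that (EP, window) cell's cross-environment
    mean; each EP's values are standardized before Euclidean distances.
    Returns (assignments indexed by env_id, scipy linkage matrix).
    """
    envs = sorted(rdeps)
    if len(envs) < k:
        raise ConfigError(f"{len(envs)} environments < k={k}")
    mats = np.stack([rdeps[e].matrix.to_numpy() for e in envs])  # (n, 9, W)
    n_missing = int(np.isnan(mats).sum())
    if n_missing:
        logger.warning("imputing %d missing RD_EP cell(s) by cross-environment mean", n_missing)
        cell_mean = np.nanmean(mats, axis=0)
        idx = np.where(np.isnan(mats))
        mats[idx] = cell_mean[idx[1], idx[2]]
    # per-EP standardization: zero mean / unit sd over (env, window)
    mu = mats.mean(axis=(0, 2), keepdims=True)
    sd = mats.std(axis=(0, 2), keepdims=True)
    sd[sd == 0] = 1.0
    flat = ((mats - mu) / sd).reshape(len(envs), -1)
    Z = linkage(pdist(flat, metric="euclidean"), method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=envs, name="cluster"), Z


def rdep_profiles(
    ep_tables: dict[str, EPTable], thresholds: StageThresholdTable
) -> dict[str, RDEPMatrix]:
    """Segment + reduce every environment: the standard envirotyping step."""
    out = {}
    for env_id, tbl in ep_tables.items():
        windows = segment_stages(tbl.cumulative_gdd, thresholds)
        out[env_id] = reduce_eps(tbl, windows)
    return out
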