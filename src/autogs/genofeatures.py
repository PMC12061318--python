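"""Genotype QC, linkage disequilibrium, TAM feature extraction and QTL intervals.

Markers are biallelic SNP dosages coded 0/1/2 with 1-based, closed genomic
coordinates.  Trait-associated markers (TAMs) from a GWAS are grouped into
environment-stable Main-TAMs and environment-responsive E-TAMs (G×E-TAMs
plus plasticity slope/intercept TAMs); prediction feature sets take the
TAMs together with flanking markers, by fixed ±37 kb distance or by LD
contiguity (r² ≥ 0.5 with the TAM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, UndefinedStatisticError

logger = logging.getLogger(__name__)

TAM_CATEGORIES = ("Main", "GxE", "PP_slope", "PP_intercept")
E_TAM_CATEGORIES = ("GxE", "PP_slope", "PP_intercept")


@dataclass
class GenotypeMatrix:
    """Genotype × marker dosage matrix with a physical marker map.

    ``dosages``: (n_samples, n_markers) float array, NaN for missing calls.
    ``marker_map``: DataFrame indexed by marker id with columns ``chrom``,
    ``pos`` (1-based bp) and optional boolean ``multiallelic``.
    """

    samples: list
    dosages: np.ndarray
    marker_map: pd.DataFrame

    def __post_init__(self):
        if self.dosages.shape != (len(self.samples), len(self.marker_map)):
            raise ConfigError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.samples)}, {len(self.marker_map)})"
            )
        if (self.marker_map["pos"] < 0).any():
            raise ConfigError("negative marker positions")
        for _, sub in self.marker_map.groupby("chrom", sort=False):
            if not sub["pos"].is_monotonic_increasing:
                raise ConfigError("marker positions must be sorted within chromosome")

    @property
    def marker_ids(self) -> list:
        return list(self.marker_map.index)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def subset(self, marker_ids) -> "GenotypeMatrix":
        idx = self.marker_map.index.get_indexer(list(marker_ids))
        if (idx < 0).any():
            missing = [m for m, i in zip(marker_ids, idx) if i < 0]
            raise KeyError(f"markers not in map: {missing[:5]}")
        order = np.sort(idx)
        return GenotypeMatrix(
            self.samples, self.dosages[:, order], self.marker_map.iloc[order]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.marker_map.index)


@dataclass
class QCReport:
    n_input: int
    n_dropped_missing: int
    n_dropped_multiallelic: int
    n_dropped_class_freq: int
    n_imputed_calls: int
    n_retained: int


def qc_filter(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.30,
    min_class_freq: float = 0.02,
) -> tuple[GenotypeMatrix, QCReport]:
    """Standard SNP quality control.

    Drops markers with missing rate > ``max_missing`` and multiallelic
    markers, imputes remaining missing calls with the per-marker modal
    genotype class, then drops markers where any *observed* genotype class
    (0/1/2) has frequency below ``min_class_freq``.  Idempotent.
    """
    X = genotypes.dosages.copy()
    n_input = X.shape[1]
    keep = np.ones(n_input, dtype=bool)

    miss = np.isnan(X).mean(axis=0)
    drop_missing = miss > max_missing
    keep &= ~drop_missing

    if "multiallelic" in genotypes.marker_map.columns:
        multi = genotypes.marker_map["multiallelic"].fillna(False).to_numpy(bool)
    else:
        multi = np.zeros(n_input, bool)
    n_multi_dropped = int((multi & keep).sum())
    keep &= ~multi

    n_imputed = 0
    for j in np.nonzero(keep & (miss > 0))[0]:
        col = X[:, j]
        nan = np.isnan(col)
        observed = col[~nan].astype(int)
        counts = np.bincount(observed, minlength=3)
        col[nan] = float(np.argmax(counts))
        n_imputed += int(nan.sum())
    if n_imputed:
        logger.info("imputed %d missing call(s) by per-marker modal class", n_imputed)

    drop_freq = np.zeros(n_input, bool)
    n = X.shape[0]
    for j in np.nonzero(keep)[0]:
        counts = np.bincount(X[:, j].astype(int), minlength=3)
        freqs = counts / n
        observed = counts > 0
        if np.any(freqs[observed] < min_class_freq):
            drop_freq[j] = True
    keep &= ~drop_freq

    if not keep.any():
        raise DegenerateInputError("QC removed every marker")
    out = GenotypeMatrix(
        genotypes.samples, X[:, keep], genotypes.marker_map.iloc[np.nonzero(keep)[0]]
    )
    report = QCReport(
        n_input=n_input,
        n_dropped_missing=int(drop_missing.sum()),
        n_dropped_multiallelic=n_multi_dropped,
        n_dropped_class_freq=int(drop_freq.sum()),
        n_imputed_calls=n_imputed,
        n_retained=int(keep.sum()),
    )
    return out, report


def pairwise_ld_r2(genotypes: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared Pearson correlation of two markers' dosage vectors."""
    sub = genotypes.to_frame()
    a = sub[marker_a].to_numpy(float)
    b = sub[marker_b].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero-variance marker in LD computation")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _ld_r2_matrix(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.nan
    C = (Xc.T @ Xc) / X.shape[0]
    R = C / np.outer(sd, sd)
    return R**2


def ld_decay_halfmax(
    genotypes: GenotypeMatrix,
    max_dist_bp: int = 2_000_000,
    bin_width: int = 50_000,
    r2_threshold: float = 0.2,
) -> dict:
    """Distance-binned mean r² curve with half-max and threshold decay distances.

    All intra-chromosome marker pairs within ``max_dist_bp`` contribute to
    the curve.  ``halfmax_bp`` is the first bin midpoint where mean r²
    drops to half the first bin's mean (None + flag when the curve never
    drops that far); ``threshold_bp`` is where mean r² first drops below
    ``r2_threshold``.
    """
    n_bins = int(np.ceil(max_dist_bp / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    any_pairs = False
    for _, sub in genotypes.marker_map.groupby("chrom", sort=False):
        if len(sub) < 2:
            continue
        any_pairs = True
        idx = genotypes.marker_map.index.get_indexer(sub.index)
        X = genotypes.dosages[:, idx]
        pos = sub["pos"].to_numpy(float)
        R2 = _ld_r2_matrix(X)
        iu = np.triu_indices(len(pos), k=1)
        d = np.abs(pos[iu[1]] - pos[iu[0]])
        r2 = R2[iu]
        ok = (d <= max_dist_bp) & (d > 0) & ~np.isnan(r2)
        b = np.minimum((d[ok] // bin_width).astype(int), n_bins - 1)
        np.add.at(sums, b, r2[ok])
        np.add.at(counts, b, 1)
    if not any_pairs:
        raise DegenerateInputError("fewer than 2 markers on every chromosome")
    with np.errstate(invalid="ignore"):
        curve = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mid = (np.arange(n_bins) + 0.5) * bin_width

    filled = ~np.isnan(curve)
    first = curve[filled][0] if filled.any() else np.nan
    halfmax_bp, flat = None, False
    below_half = filled & (curve <= first / 2.0)
    if below_half.any():
        halfmax_bp = float(mid[below_half][0])
    else:
        flat = True
    threshold_bp = None
    below_thr = filled & (curve < r2_threshold)
    if below_thr.any():
        threshold_bp = float(mid[below_thr][0])
    return {
        "bin_mid_bp": mid,
        "mean_r2": curve,
        "n_pairs": counts,
        "halfmax_bp": halfmax_bp,
        "halfmax_undefined": flat,
        "threshold_bp": threshold_bp,
    }


def _validate_tams(tams: pd.DataFrame, genotypes: GenotypeMatrix) -> None:
    bad_cat = set(tams["category"]) - set(TAM_CATEGORIES)
    if bad_cat:
        raise ConfigError(f"unknown TAM categories {sorted(bad_cat)}")
    absent = [m for m in tams["marker_id"] if m not in genotypes.marker_map.index]
    if absent:
        raise KeyError(f"TAM(s) absent from marker map: {absent[:5]}")


def _flank_fixed(genotypes: GenotypeMatrix, tam: str, flank_bp: int) -> list:
    row = genotypes.marker_map.loc[tam]
    sub = genotypes.marker_map[genotypes.marker_map["chrom"] == row["chrom"]]
    close = sub[(sub["pos"] >= row["pos"] - flank_bp) & (sub["pos"] <= row["pos"] + flank_bp)]
    return list(close.index)


def _flank_ld(genotypes: GenotypeMatrix, tam: str, min_r2: float) -> list:
    chrom = genotypes.marker_map.loc[tam, "chrom"]
    sub = genotypes.marker_map[genotypes.marker_map["chrom"] == chrom]
    order = list(sub.index)
    i0 = order.index(tam)
    idx = genotypes.marker_map.index.get_indexer(order)
    X = genotypes.dosages[:, idx]
    t = X[:, i0]
    if t.std() == 0:
        return [tam]
    kept = [tam]
    for step in (-1, 1):  # walk outwards while contiguous r² holds
        i = i0 + step
        while 0 <= i < len(order):
            x = X[:, i]
            if x.std() == 0:
                break
            if np.corrcoef(t, x)[0, 1] ** 2 < min_r2:
                break
            kept.append(order[i])
            i += step
    return kept


def extract_tam_flanks(
    tams: pd.DataFrame,
    genotypes: GenotypeMatrix,
    mode: str = "fixed_bp",
    flank_bp: int = 37_000,
    min_r2: float = 0.5,
    trait: str | None = None,
) -> dict[str, list]:
    """TAM-plus-flank marker sets per feature class.

    ``tams`` has columns marker_id, trait, category.  Returns marker-id
    lists for ``All-TAMs`` (Main ∪ E), ``Main-TAMs`` and ``E-TAMs``
    (G×E ∪ PP categories), de-duplicated and in map order.  ``fixed_bp``
    takes all markers within ±``flank_bp`` of each TAM; ``ld_r2`` walks
    contiguously outward while r² with the TAM stays ≥ ``min_r2``.
    """
    if trait is not None:
        tams = tams[tams["trait"] == trait]
    _validate_tams(tams, genotypes)
    if mode not in ("fixed_bp", "ld_r2"):
        raise ConfigError(f"unknown flank mode {mode!r}")

    def expand(marker_ids) -> list:
        found: set = set()
        for m in marker_ids:
            found.update(
                _flank_fixed(genotypes, m, flank_bp)
                if mode == "fixed_bp"
                else _flank_ld(genotypes, m, min_r2)
            )
        return [m for m in genotypes.marker_map.index if m in found]

    main = tams.loc[tams["category"] == "Main", "marker_id"].tolist()
    e = tams.loc[tams["category"].isin(E_TAM_CATEGORIES), "marker_id"].tolist()
    return {
        "All-TAMs": expand(main + e),
        "Main-TAMs": expand(main),
        "E-TAMs": expand(e),
    }


def merge_qtl_intervals(
    tams: pd.DataFrame,
    genotypes: GenotypeMatrix,
    half_width_bp: float = 1e6,
) -> dict[tuple, list]:
    """±``half_width_bp`` QTL intervals around TAMs, merged when overlapping.

    Returns per (trait, category) a sorted list of disjoint
    (chrom, start_bp, end_bp) closed intervals, clipped below at 1.
    """
    _validate_tams(tams, genotypes)
    out: dict[tuple, list] = {}
    for (trait, cat), sub in tams.groupby(["trait", "category"], sort=True):
        pos = genotypes.marker_map.loc[sub["marker_id"], ["chrom", "pos"]]
        raw = [
            (c, max(1.0, p - half_width_bp), p + half_width_bp)
            for c, p in zip(pos["chrom"], pos["pos"])
        ]
        merged: list = []
        for c, s, e in sorted(raw):
            if merged and merged[-1][0] == c and s <= merged[-1][2]:
                prev = merged[-1]
                merged[-1] = (c, prev[1], max(prev[2], e))
            else:
                merged.append((c, s, e))
        out[(trait, cat)] = merged
    return out


def colocalization_stats(qtls_a: list, qtls_b: list) -> dict:
    """Count intervals of each list overlapping (≥ 1 bp) any of the other.

    A pair of QTL sets co-localizes where their closed intervals intersect;
    reports the co-localized count (pairs with overlap, counted as
    overlapping A-intervals) and each set's share.
    """

    def overlaps(x, y):
        return x[0] == y[0] and x[1] <= y[2] and y[1] <= x[2]

    a_hit = [a for a in qtls_a if any(overlaps(a, b) for b in qtls_b)]
    b_hit = [b for b in qtls_b if any(overlaps(b, a) for a in qtls_a)]
    n = len(a_hit)
    return {
        "n_colocalized": n,
        "share_a": n / len(qtls_a) if qtls_a else 0.0,
        "share_b": len(b_hit) / len(qtls_b) if qtls_b else 0.0,
    }


def random_marker_baseline(
    genotypes: GenotypeMatrix,
    tams: pd.DataFrame,
    scheme: str,
    seed: int,
    mode: str = "fixed_bp",
    flank_bp: int = 37_000,
    min_r2: float = 0.5,
    all_tam_features: list | None = None,
) -> list:
    """Random-marker control feature sets.

    ``Random1`` draws as many random anchor markers as there are TAMs and
    expands each by the same flank rule; ``Random2`` draws uniformly exactly
    as many markers as the All-TAMs-plus-flanks feature set contains
    (``all_tam_features``, computed here when not supplied).  Seeded and
    reproducible.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(genotypes.marker_map.index)
    if scheme == "Random1":
        n_anchor = len(tams)
        if n_anchor > len(ids):
            raise ConfigError("more TAMs than available markers")
        anchors = rng.choice(ids, size=n_anchor, replace=False)
        found: set = set()
        for m in anchors:
            found.update(
                _flank_fixed(genotypes, m, flank_bp)
                if mode == "fixed_bp"
                else _flank_ld(genotypes, m, min_r2)
            )
        return [m for m in ids if m in found]
    if scheme == "Random2":
        if all_tam_features is None:
            all_tam_features = extract_tam_flanks(
                tams, genotypes, mode=mode, flank_bp=flank_bp, min_r2=min_r2
            )["All-TAMs"]
        k = len(all_tam_features)
        if k > len(ids):
            raise ConfigError("requested count exceeds available markers")
        chosen = set(rng.choice(ids, size=k, replace=False))
        return [m for m in ids if m in chosen]
    raise ConfigError(f"unknown baseline scheme {scheme!r}")


def association_screen(
    genotypes: GenotypeMatrix,
    response: pd.Series,
    n_pcs: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Single-marker OLS association scan with principal-component covariates.

    Regresses the response on each marker's dosage plus the top ``n_pcs``
    genotype PCs (via Frisch–Waugh residualization), returning per-marker
    effect, t statistic, p-value and a Bonferroni significance flag at
    family-wise level ``alpha``.  A lightweight screen meant to produce TAM
    tables for end-to-end synthetic runs, not a replacement for a
    mixed-model GWAS.
    """
    from scipy import stats

    common = [s for s in genotypes.samples if s in response.index]
    if len(common) < 10:
        raise DegenerateInputError(f"need ≥ 10 samples, got {len(common)}")
    y = response.loc[common].to_numpy(float)
    if y.std() == 0:
        raise DegenerateInputError("constant response")
    rows = [genotypes.samples.index(s) for s in common]
    X = genotypes.dosages[rows]
    n, p = X.shape

    Z = np.ones((n, 1))
    if n_pcs > 0:
        Xc = X - X.mean(axis=0)
        # PCs of the genotype matrix via thin SVD
        U, S, _ = np.linalg.svd(Xc, full_matrices=False)
        Z = np.hstack([Z, U[:, :n_pcs]])
    # residualize response and dosages on covariates
    Q, _ = np.linalg.qr(Z)
    y_r = y - Q @ (Q.T @ y)
    X_r = X - Q @ (Q.T @ X)

    ssx = (X_r**2).sum(axis=0)
    ssx_safe = np.where(ssx > 0, ssx, np.nan)
    beta = (X_r * y_r[:, None]).sum(axis=0) / ssx_safe
    resid = y_r[:, None] - X_r * beta
    dof = n - Z.shape[1] - 1
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(sigma2 / ssx_safe)
        tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), dof)
    bonf = pval < alpha / p
    return pd.DataFrame(
        {"effect": beta, "t": tstat, "p": pval, "bonferroni_sig": bonf},
        index=genotypes.marker_map.index,
    )
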