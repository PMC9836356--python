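"""Windowed genomic features, population LD, and CO-count models.

Per non-overlapping window (960 kb at study scale): GC fraction over
non-N bases, gene count, Gypsy-/Copia-LTR and simple-repeat counts
(features assigned by interval midpoint), and mean pairwise genotype r^2
over marker pairs within 10 kb.  CO counts are modelled on centred/scaled
features by OLS with 5-fold repeated cross-validation, and feature
enrichment between window classes uses a two-tailed Wilcoxon rank-sum
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenomeLayout, GenotypeMatrix

MODEL1_FEATURES = ["gc", "gene_count", "simple_count", "copia_count", "gypsy_count", "sex_male"]
MODEL2_FEATURES = ["gc", "gene_count", "copia_count", "gypsy_count"]


def make_windows(layout: GenomeLayout, window_bp: int) -> pd.DataFrame:
    rows = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
        for start in range(0, length, window_bp):
            rows.append((chrom, start, min(start + window_bp, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _midpoint_window_counts(
    mids: np.ndarray, chroms: np.ndarray, windows: pd.DataFrame, window_bp: int
) -> np.ndarray:
    counts = np.zeros(len(windows), dtype=int)
    wkey = {(r.chrom, r.start): i for i, r in enumerate(windows.itertuples(index=False))}
    for c, m in zip(chroms, mids):
        key = (c, int(m // window_bp) * window_bp)
        if key in wkey:
            counts[wkey[key]] += 1
    return counts


def window_features(
    fasta_path: str,
    gff3_path: str,
    repeat_bed_path: str,
    layout: GenomeLayout,
    window_bp: int = 960_000,
) -> pd.DataFrame:
    """Feature table per non-overlapping window.

    GC is computed over non-N bases; genes and repeats count toward the
    window containing their interval midpoint (half-open convention: a
    midpoint on a boundary belongs to the right window).
    """
    from pyfaidx import Fasta

    from .io import read_bed

    windows = make_windows(layout, window_bp)
    fa = Fasta(fasta_path)
    gc = np.full(len(windows), np.nan)
    for i, r in enumerate(windows.itertuples(index=False)):
        seq = str(fa[r.chrom][r.start : r.end]).upper()
        atgc = sum(seq.count(b) for b in "ATGC")
        gc[i] = (seq.count("G") + seq.count("C")) / atgc if atgc else np.nan
    windows["gc"] = gc

    genes = _read_gene_intervals(gff3_path)
    # GFF3 is 1-based inclusive; midpoint on the 0-based half-open interval
    gmid = (genes["start"].to_numpy() - 1 + genes["end"].to_numpy()) // 2
    windows["gene_count"] = _midpoint_window_counts(
        gmid, genes["chrom"].to_numpy(), windows, window_bp
    )

    rep = read_bed(repeat_bed_path)
    rmid = (rep["start0"].to_numpy() + rep["end0"].to_numpy()) // 2
    for cls, col in [("Gypsy", "gypsy_count"), ("Copia", "copia_count"), ("simple", "simple_count")]:
        mask = rep["name"] == cls
        windows[col] = _midpoint_window_counts(
            rmid[mask.to_numpy()], rep.loc[mask, "chrom"].to_numpy(), windows, window_bp
        )
    return windows


def _read_gene_intervals(gff3_path: str) -> pd.DataFrame:
    """Gene intervals via gffutils (in-memory DB); malformed lines are
    counted and skipped by the parser."""
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            gff3_path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows = [(f.seqid, f.start, f.end) for f in db.features_of_type("gene")]
    except EmptyInputError:
        rows = []
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# population LD


def geno_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete
    samples; NaN if < 2 complete pairs or either vector is constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = (a >= 0) & (b >= 0)
    if ok.sum() < 2:
        return np.nan
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def window_mean_ld(
    geno: GenotypeMatrix,
    layout: GenomeLayout,
    window_bp: int = 960_000,
    pair_max_bp: int = 10_000,
) -> pd.DataFrame:
    """Mean pairwise r^2 per window over marker pairs <= ``pair_max_bp``
    apart whose left member lies in the window (left-anchored convention)."""
    windows = make_windows(layout, window_bp)
    sums = np.zeros(len(windows))
    ns = np.zeros(len(windows), dtype=int)
    wkey = {(r.chrom, r.start): i for i, r in enumerate(windows.itertuples(index=False))}
    markers = geno.markers
    for chrom in layout.chrom_names:
        sl = geno.chrom_slice(chrom)
        pos = markers["pos"].to_numpy()[sl]
        dose = geno.dosage[:, sl]
        for j in range(len(pos)):
            hi = np.searchsorted(pos, pos[j] + pair_max_bp, side="right")
            wi = wkey.get((chrom, int((pos[j] - 1) // window_bp) * window_bp))
            if wi is None:
                continue
            for k in range(j + 1, hi):
                r2 = geno_r2(dose[:, j], dose[:, k])
                if np.isfinite(r2):
                    sums[wi] += r2
                    ns[wi] += 1
    with np.errstate(invalid="ignore"):
        windows["mean_r2"] = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    windows["n_pairs"] = ns
    return windows


# ---------------------------------------------------------------------------
# CO models


@dataclass
class CoModelResult:
    model: str
    coefficients: pd.Series
    stderr: pd.Series
    r2: float
    cv_r2: float
    cv_rmse: float
    dropped: list[str]


def fit_co_models(
    data: pd.DataFrame,
    model: str = "model1",
    cv_folds: int = 5,
    cv_repeats: int = 10,
    seed: int = 0,
    backward_aic: bool = False,
) -> CoModelResult:
    """OLS of window CO counts on centred/scaled genomic features.

    ``data`` holds one row per (window, half-sib family) with a ``count``
    column and the feature columns; model1 includes simple repeats and
    sex, model2 omits them.  Cross-validated R^2 and RMSE are averaged
    over ``cv_repeats`` seeded shuffles of ``cv_folds`` folds.  With
    ``backward_aic`` the feature set is pruned stepwise by AIC first.
    """
    import statsmodels.api as sm
    from sklearn.model_selection import RepeatedKFold

    feats = list(MODEL1_FEATURES if model == "model1" else MODEL2_FEATURES)
    feats = [f for f in feats if f in data.columns]
    y = data["count"].to_numpy(float)
    X = data[feats].to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    dropped = [f for f, s in zip(feats, sd) if s == 0]
    keep = sd > 0
    feats = [f for f, k in zip(feats, keep) if k]
    Xz = (X[:, keep] - mu[keep]) / sd[keep]

    def ols_fit(cols: list[int]):
        design = sm.add_constant(Xz[:, cols])
        return sm.OLS(y, design).fit()

    cols = list(range(len(feats)))
    if backward_aic:
        fit = ols_fit(cols)
        improved = True
        while improved and len(cols) > 1:
            improved = False
            best_aic, best_cols = fit.aic, cols
            for drop in range(len(cols)):
                trial = cols[:drop] + cols[drop + 1 :]
                f = ols_fit(trial)
                if f.aic < best_aic:
                    best_aic, best_cols, fit = f.aic, trial, f
                    improved = True
            cols = best_cols
    fit = ols_fit(cols)
    names = ["intercept"] + [feats[c] for c in cols]
    coefs = pd.Series(fit.params, index=names)
    stderr = pd.Series(fit.bse, index=names)

    Xcv = Xz[:, cols]
    rkf = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    r2s, rmses = [], []
    for train, test in rkf.split(Xcv):
        d_tr = sm.add_constant(Xcv[train], has_constant="add")
        d_te = sm.add_constant(Xcv[test], has_constant="add")
        f = sm.OLS(y[train], d_tr).fit()
        pred = d_te @ f.params
        resid = y[test] - pred
        sst = ((y[test] - y[test].mean()) ** 2).sum()
        r2s.append(1.0 - (resid**2).sum() / sst if sst > 0 else np.nan)
        rmses.append(float(np.sqrt((resid**2).mean())))
    return CoModelResult(
        model, coefs, stderr, float(fit.rsquared),
        float(np.nanmean(r2s)), float(np.nanmean(rmses)), dropped,
    )


# ---------------------------------------------------------------------------
# enrichment


def wilcoxon_rank_sum(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-sum W (Mann-Whitney U of x, the R convention) and p-value.

    Exact by enumeration when n_x + n_y <= 20 with no ties, otherwise the
    normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def feature_enrichment(
    features: pd.DataFrame,
    class_a: np.ndarray,
    class_b: np.ndarray,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Wilcoxon rank-sum between two disjoint window classes
    (boolean masks or index arrays over ``features`` rows)."""
    a_idx = np.asarray(class_a)
    b_idx = np.asarray(class_b)
    if a_idx.dtype == bool:
        a_idx = np.flatnonzero(a_idx)
    if b_idx.dtype == bool:
        b_idx = np.flatnonzero(b_idx)
    if len(a_idx) == 0:
        raise ValueError("class_a is empty")
    if len(b_idx) == 0:
        raise ValueError("class_b is empty")
    if set(a_idx) & set(b_idx):
        raise ValueError("classes must be disjoint")
    if feature_cols is None:
        feature_cols = [
            c for c in ("gc", "gene_count", "gypsy_count", "copia_count", "simple_count", "mean_r2")
            if c in features.columns
        ]
    rows = []
    for col in feature_cols:
        xa = features[col].to_numpy(float)[a_idx]
        xb = features[col].to_numpy(float)[b_idx]
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        w, p = wilcoxon_rank_sum(xa, xb)
        rows.append((col, w, p))
    return pd.DataFrame(rows, columns=["feature", "W", "p"])


def spearman_ld_vs_co(mean_ld: np.ndarray, co_counts: np.ndarray) -> tuple[float, float]:
    """Spearman correlation between window mean r^2 and cumulative CO
    counts (complete windows only)."""
    ld = np.asarray(mean_ld, float)
    co = np.asarray(co_counts, float)
    ok = np.isfinite(ld) & np.isfinite(co)
    rho, p = stats.spearmanr(ld[ok], co[ok])
    return float(rho), float(p)
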