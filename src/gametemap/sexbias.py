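"""Heterochiasmy tests at chromosome and sub-chromosome scale.

Chromosome scale: a 1-df chi-square on cumulative female vs male CO counts
per linkage group (equal gamete numbers by design) and a Poisson GLMM with
sex, chromosome, their interaction and half-sib family size as fixed
effects plus a family random intercept nested in sex.

Finer scale: a Morlet continuous wavelet transform locates the dyadic
scale at which the male-female CO count difference carries the most
variance (960 kb by default for 30-kb bins); non-overlapping windows at
that scale are then tested with an exact conditional Poisson ratio test
(binomial mid-P) and Benjamini-Hochberg FDR, after trimming putative
centromere/telomere windows and index-of-dispersion outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenomeLayout, Pedigree


# ---------------------------------------------------------------------------
# chromosome scale


def lg_chisq_test(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-LG chi-square for C_f vs C_m with E = (C_f + C_m)/2 (df=1),
    Bonferroni-adjusted over the LGs tested; zero-total LGs are skipped."""
    out = counts.copy()
    cf = out["C_f"].to_numpy(float)
    cm = out["C_m"].to_numpy(float)
    total = cf + cm
    with np.errstate(invalid="ignore", divide="ignore"):
        e = total / 2.0
        chi2 = (cf - e) ** 2 / e + (cm - e) ** 2 / e
    chi2[total == 0] = np.nan
    p = stats.chi2.sf(chi2, df=1)
    m = int(np.isfinite(chi2).sum())
    out["chisq"] = chi2
    out["p"] = p
    out["p_bonf"] = np.minimum(p * max(m, 1), 1.0)
    out["significant"] = out["p_bonf"] <= 0.05
    return out


@dataclass
class GlmmResult:
    method: str                      # "glmm_vb" or "glm"
    params: pd.Series
    sd: pd.Series
    converged: bool
    sex_coef: float
    sex_sd: float

    @property
    def exp_sex(self) -> float:
        return float(np.exp(self.sex_coef))

    def sex_wald_ci(self, z: float = 1.96) -> tuple[float, float]:
        return (
            float(np.exp(self.sex_coef - z * self.sex_sd)),
            float(np.exp(self.sex_coef + z * self.sex_sd)),
        )


def fit_poisson_glmm(
    counts: pd.DataFrame,
    method: str = "auto",
    vc_sd_floor: float = 0.1,
) -> GlmmResult:
    """Fit per-(parent, chromosome) CO totals.

    ``counts`` needs columns parent, sex ("female"/"male"), chrom, count,
    and optionally fam_size (gametes per parent; dropped if constant).

    ``method="auto"`` fits the variational-Bayes Poisson mixed model with
    a parent random intercept; when the estimated random-intercept
    standard deviation falls below ``vc_sd_floor`` — i.e. the counts show
    no family-level overdispersion and the random effect is degenerate —
    the model is reduced to the fixed-effects Poisson GLM, whose Wald
    intervals are then correctly calibrated.  ``"glmm_vb"`` and ``"glm"``
    force either route; fit failures fall back to the GLM with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = counts.copy()
    df["sex_male"] = (df["sex"] == "male").astype(float)
    terms = ["sex_male", "C(chrom)", "sex_male:C(chrom)"]
    if "fam_size" in df and df["fam_size"].nunique() > 1:
        df["fam_size_z"] = (df["fam_size"] - df["fam_size"].mean()) / df["fam_size"].std()
        terms.append("fam_size_z")
    formula = "count ~ " + " + ".join(terms)

    if method in ("auto", "glmm_vb"):
        try:
            from statsmodels.genmod.bayes_mixed_glm import PoissonBayesMixedGLM

            model = PoissonBayesMixedGLM.from_formula(
                formula, {"fam": "0 + C(parent)"}, df
            )
            fit = model.fit_vb()
            vc_sd = float(np.exp(fit.vcp_mean).max())
            if method == "glmm_vb" or vc_sd >= vc_sd_floor:
                names = list(fit.model.exog_names)
                params = pd.Series(fit.fe_mean, index=names)
                sd = pd.Series(fit.fe_sd, index=names)
                return GlmmResult(
                    "glmm_vb", params, sd, True,
                    float(params["sex_male"]), float(sd["sex_male"]),
                )
        except Exception as exc:  # pragma: no cover - fallback path
            warnings.warn(f"Poisson GLMM failed ({exc}); falling back to fixed-effects GLM")
    fit = smf.glm(formula, data=df, family=sm.families.Poisson()).fit()
    return GlmmResult(
        "glm", fit.params, fit.bse, True,
        float(fit.params["sex_male"]), float(fit.bse["sex_male"]),
    )


def per_lg_sex_counts(co_regions: pd.DataFrame, ped: Pedigree) -> pd.DataFrame:
    """Cumulative per-LG CO counts by sex and the per-(parent, LG) table
    used by the GLMM."""
    fam_sizes = {p: len(ped.offspring_of(p)) for p in ped.parents}
    per_parent = (
        co_regions.groupby(["parent", "sex", "chrom"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    # ensure zero cells are present
    full = pd.MultiIndex.from_product(
        [ped.parents, sorted(co_regions["chrom"].unique())], names=["parent", "chrom"]
    ).to_frame(index=False)
    full["sex"] = [ped.sex_of(p) for p in full["parent"]]
    per_parent = full.merge(per_parent, how="left", on=["parent", "sex", "chrom"])
    per_parent["count"] = per_parent["count"].fillna(0).astype(int)
    per_parent["fam_size"] = per_parent["parent"].map(fam_sizes)
    per_lg = (
        per_parent.pivot_table(index="chrom", columns="sex", values="count", aggfunc="sum")
        .rename(columns={"female": "C_f", "male": "C_m"})
        .reset_index()
    )
    return per_lg, per_parent


# ---------------------------------------------------------------------------
# wavelet scale selection


def _morlet_cwt(signal: np.ndarray, scales_bins: np.ndarray) -> np.ndarray:
    """|CWT|^2 of a (mean-removed) signal with a complex Morlet (omega0=6)
    at Fourier periods ``scales_bins`` (in samples).  PyWavelets backend."""
    import pywt

    fc = 6.0 / (2.0 * np.pi)  # centre frequency of the omega0=6 Morlet
    wavelet = f"cmor1.0-{fc:.6f}"
    pywt_scales = np.asarray(scales_bins, float) * fc
    x = signal - signal.mean()
    coefs, _ = pywt.cwt(x, pywt_scales, wavelet)
    return np.abs(coefs) ** 2


def wavelet_scale_analysis(
    signals: dict[str, dict[str, np.ndarray]],
    bin_bp: int = 30_000,
    scales_bins: np.ndarray | None = None,
    select_range_bins: tuple[int, int] = (16, 64),
) -> tuple[pd.DataFrame, int]:
    """Per-scale variance decomposition of male, female, and difference CO
    count signals, cone-of-influence excluded, averaged over chromosomes.

    ``signals[chrom]`` maps "male"/"female" to 30-kb bin count arrays.
    Returns the power table and the selected window scale in bins: the
    dyadic scale within ``select_range_bins`` maximising the variance
    fraction of the difference signal.
    """
    if scales_bins is None:
        scales_bins = 2 ** np.arange(1, 9)  # 2..256 bins = 60 kb..7.68 Mb
    scales_bins = np.asarray(scales_bins, int)
    acc = {k: np.zeros(len(scales_bins)) for k in ("male", "female", "difference")}
    weight = np.zeros(len(scales_bins))
    for chrom, sig in signals.items():
        male = np.asarray(sig["male"], float)
        female = np.asarray(sig["female"], float)
        n = len(male)
        series = {"male": male, "female": female, "difference": male - female}
        for name, x in series.items():
            for si, s in enumerate(scales_bins):
                if n < 2 * s:
                    continue  # signal shorter than twice the scale: skip
                power = _morlet_cwt(x, np.array([s]))[0]
                coi = int(np.ceil(np.sqrt(2.0) * s))
                kept = power[coi : n - coi] if n > 2 * coi else power[:0]
                if kept.size == 0:
                    continue
                acc[name][si] += kept.mean() * kept.size
                if name == "male":
                    weight[si] += kept.size
    rows = []
    for si, s in enumerate(scales_bins):
        mean_p = {k: (acc[k][si] / weight[si] if weight[si] > 0 else np.nan) for k in acc}
        rows.append((int(s), int(s) * bin_bp, mean_p["male"], mean_p["female"], mean_p["difference"]))
    table = pd.DataFrame(
        rows, columns=["scale_bins", "scale_bp", "power_male", "power_female", "power_difference"]
    )
    for col in ("power_male", "power_female", "power_difference"):
        total = np.nansum(table[col])
        table[col.replace("power", "varfrac")] = table[col] / total if total > 0 else np.nan
    lo, hi = select_range_bins
    cand = table[(table["scale_bins"] >= lo) & (table["scale_bins"] <= hi)]
    cand = cand.dropna(subset=["varfrac_difference"])
    selected = int(cand.loc[cand["varfrac_difference"].idxmax(), "scale_bins"]) if len(cand) else lo
    return table, selected


def binned_sex_signals(
    co_regions: pd.DataFrame, layout: GenomeLayout, bin_bp: int = 30_000
) -> dict[str, dict[str, np.ndarray]]:
    """Midpoint-assigned CO counts per sex in ``bin_bp`` bins per chromosome."""
    out = {}
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
        n_bins = int(np.ceil(length / bin_bp))
        out[chrom] = {}
        for sex in ("male", "female"):
            sub = co_regions[(co_regions["chrom"] == chrom) & (co_regions["sex"] == sex)]
            idx = np.minimum(sub["midpoint"].to_numpy() // bin_bp, n_bins - 1).astype(int)
            out[chrom][sex] = np.bincount(idx, minlength=n_bins).astype(float)
    return out


# ---------------------------------------------------------------------------
# windowed counts, exact test, FDR


def index_of_dispersion(counts: np.ndarray) -> float:
    """Unbiased variance / mean of per-parent counts (NaN when mean 0)."""
    counts = np.asarray(counts, float)
    m = counts.mean()
    if m == 0:
        return np.nan
    return float(counts.var(ddof=1) / m)


def window_co_counts(
    co_regions: pd.DataFrame,
    layout: GenomeLayout,
    ped: Pedigree,
    window_bp: int = 960_000,
    centromere_min_count: float | None = None,
    iod_percentiles: tuple[float, float] = (5.0, 95.0),
) -> pd.DataFrame:
    """Non-overlapping window CO counts per parent with filter flags.

    Windows are anchored at 0; the trailing partial window is kept and
    flagged.  ``centromere_min_count`` defaults to the 20th percentile of
    each chromosome's window totals (a proxy for the unquantified
    chromosome-wide minimum average CO count rule); IOD outliers outside
    the given global percentiles are flagged.  ``retained`` marks windows
    passing both filters.
    """
    parents = ped.parents
    rows = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
        n_win = int(np.ceil(length / window_bp))
        sub = co_regions[co_regions["chrom"] == chrom]
        idx_by_parent = {}
        for p in parents:
            mids = sub.loc[sub["parent"] == p, "midpoint"].to_numpy()
            idx_by_parent[p] = np.bincount(
                np.minimum(mids // window_bp, n_win - 1).astype(int), minlength=n_win
            )
        for w in range(n_win):
            start = w * window_bp
            end = min(start + window_bp, length)
            per_parent = np.array([idx_by_parent[p][w] for p in parents])
            cf = int(sum(c for p, c in zip(parents, per_parent) if ped.sex_of(p) == "female"))
            cm = int(sum(c for p, c in zip(parents, per_parent) if ped.sex_of(p) == "male"))
            rows.append(
                [chrom, start, end, end - start < window_bp, *per_parent, cf, cm,
                 int(per_parent.sum()), index_of_dispersion(per_parent)]
            )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "partial", *parents, "C_f", "C_m", "total", "iod"],
    )
    if centromere_min_count is None:
        thresh = table.groupby("chrom")["total"].transform(lambda t: np.percentile(t, 20))
    else:
        thresh = pd.Series(centromere_min_count, index=table.index)
    table["flag_centromere"] = table["total"] < thresh
    finite = table["iod"].dropna()
    lo, hi = np.percentile(finite, iod_percentiles) if len(finite) else (np.nan, np.nan)
    table["flag_iod"] = ~table["iod"].between(lo, hi)
    table["retained"] = ~(table["flag_centromere"] | table["flag_iod"])
    return table


def midp_poisson_ratio_test(c_f, c_m):
    """Two-sided exact Poisson ratio test via the conditional binomial.

    Under H0 (equal rates) X = C_f | n = C_f + C_m ~ Binomial(n, 1/2); the
    central mid-P doubles the smaller of the two mid-corrected tails and
    caps at 1.  n = 0 returns 1.  Accepts scalars or arrays.
    """
    x = np.asarray(c_f)
    n = x + np.asarray(c_m)
    pmf_x = stats.binom.pmf(x, np.maximum(n, 1), 0.5)
    lower = stats.binom.cdf(x - 1, np.maximum(n, 1), 0.5) + 0.5 * pmf_x
    upper = stats.binom.sf(x, np.maximum(n, 1), 0.5) + 0.5 * pmf_x
    out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    out = np.where(n == 0, 1.0, out)
    return float(out) if out.ndim == 0 else out


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as NaN."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def sex_bias_tests(window_table: pd.DataFrame, fdr_threshold: float = 0.25) -> pd.DataFrame:
    """Mid-P + BH over retained windows; adds midp, q, male_biased
    (q <= threshold and C_m > C_f) and background (f:m ratio < 1 with q in
    [0.4, 0.8]) classifications."""
    out = window_table.copy()
    midp = np.full(len(out), np.nan)
    retained = out["retained"].to_numpy()
    if retained.any():
        midp[retained] = midp_poisson_ratio_test(
            out.loc[retained, "C_f"].to_numpy(), out.loc[retained, "C_m"].to_numpy()
        )
    out["midp"] = midp
    out["q"] = bh_adjust(midp)
    out["sex_biased"] = (out["q"] <= fdr_threshold) & retained
    out["male_biased"] = out["sex_biased"] & (out["C_m"] > out["C_f"])
    ratio_lt1 = out["C_m"] > out["C_f"]  # female:male ratio < 1
    out["background"] = retained & ratio_lt1 & out["q"].between(0.4, 0.8)
    return out
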