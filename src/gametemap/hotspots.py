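"""Crossover hotspot calling in 30-kb windows against a Poisson null.

Windows are screened with structural-region, marker-sparsity and
index-of-dispersion filters, then tested with an upper-tail Poisson
p-value at a genome-wide mean rate lambda, Bonferroni-controlled over the
retained windows.  Runs of adjacent significant windows share a cluster
id.  The same machinery is applied per sex with sex-specific lambdas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenomeLayout, Pedigree
from .sexbias import window_co_counts


def hotspot_pvalue(k: int | np.ndarray, lam: float) -> float | np.ndarray:
    """Upper-tail Poisson p = P(K >= k | lambda) = 1 - F(k-1; lambda)."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    out = stats.poisson.sf(np.asarray(k) - 1, lam)
    return float(out) if out.ndim == 0 else out


def apply_hotspot_filters(
    window_table: pd.DataFrame,
    marker_positions: dict[str, np.ndarray],
    iod_band: tuple[float, float] = (10.0, 90.0),
    flank_bp: int = 60_000,
    min_flank_markers: float = 2.0,
    excluded_regions: pd.DataFrame | None = None,
    sparsity_rule: str = "flank",  # "flank" | "adjacent_window"
    iod_rule: str = "band",        # "band" | "top_only"
) -> pd.DataFrame:
    """Flag hotspot-screen windows that fail the filters.

    * ``excluded``: window overlaps a structural-artifact region
      (BED-style table chrom/start0/end0).
    * ``sparse``: mean informative-marker count within ``flank_bp`` of the
      two window borders < ``min_flank_markers`` (or, with the
      ``adjacent_window`` rule, >= 1 CO in the window but mean marker count
      of the two adjacent windows < 1).
    * ``iod_out``: IOD outside the global percentile band (or above the
      top percentile only with ``top_only``).

    Adds a boolean ``retained`` column; flagged windows are never called.
    """
    out = window_table.copy()
    n = len(out)
    excluded = np.zeros(n, dtype=bool)
    if excluded_regions is not None and len(excluded_regions):
        for r in excluded_regions.itertuples(index=False):
            hit = (
                (out["chrom"] == r.chrom)
                & (out["start"] < r.end0)
                & (out["end"] > r.start0)
            )
            excluded |= hit.to_numpy()
    out["flag_excluded"] = excluded

    sparse = np.zeros(n, dtype=bool)
    for chrom, grp in out.groupby("chrom", sort=False):
        pos = np.sort(np.asarray(marker_positions.get(chrom, np.array([]))))
        idx = grp.index.to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if sparsity_rule == "flank":
            left = np.searchsorted(pos, starts) - np.searchsorted(pos, starts - flank_bp)
            right = np.searchsorted(pos, ends + flank_bp) - np.searchsorted(pos, ends)
            sparse[idx] = (left + right) / 2.0 < min_flank_markers
        elif sparsity_rule == "adjacent_window":
            width = ends - starts
            lcnt = np.searchsorted(pos, starts) - np.searchsorted(pos, starts - width)
            rcnt = np.searchsorted(pos, ends + width) - np.searchsorted(pos, ends)
            sparse[idx] = (grp["total"].to_numpy() >= 1) & ((lcnt + rcnt) / 2.0 < 1.0)
        else:
            raise ValueError(f"unknown sparsity_rule {sparsity_rule!r}")
    out["flag_sparse"] = sparse

    finite = out["iod"].dropna()
    if len(finite):
        lo, hi = np.percentile(finite, iod_band)
    else:
        lo, hi = np.nan, np.nan
    if iod_rule == "band":
        iod_out = ~out["iod"].between(lo, hi)
    elif iod_rule == "top_only":
        iod_out = out["iod"] > hi
    else:
        raise ValueError(f"unknown iod_rule {iod_rule!r}")
    out["flag_iod"] = iod_out.to_numpy()
    out["retained"] = ~(out["flag_excluded"] | out["flag_sparse"] | out["flag_iod"])
    return out


@dataclass
class HotspotResult:
    calls: pd.DataFrame            # retained windows with k, lambda, p, is_hotspot, cluster
    lam: float
    n_retained: int
    n_candidates_prefilter: int    # significant before filtering (screening count)
    scope: str


def call_hotspots(
    window_table: pd.DataFrame,
    scope: str = "combined",
    lam: float | None = None,
    alpha: float = 0.05,
) -> HotspotResult:
    """Bonferroni-controlled Poisson upper-tail calls on retained windows.

    ``scope`` picks the count column: combined total, or the female/male
    cumulative counts; ``lam`` defaults to the mean count per retained
    window for that scope.  Maximal runs of adjacent hotspot windows share
    a cluster id.  Also reports how many windows would have been
    significant before filtering (the pre-filter candidate count).
    """
    col = {"combined": "total", "female": "C_f", "male": "C_m"}[scope]
    table = window_table.copy()
    retained = table["retained"].to_numpy()
    m = int(retained.sum())
    if m == 0:
        empty = table.iloc[:0].copy()
        return HotspotResult(empty, np.nan, 0, 0, scope)
    counts_all = table[col].to_numpy(float)
    if lam is None:
        lam = float(counts_all[retained].mean())
    if lam <= 0:
        raise ValueError("lambda must be > 0 (no COs in retained windows?)")
    p_all = hotspot_pvalue(counts_all.astype(int), lam)
    # pre-filter candidate count uses the same lambda over all windows
    n_pre = int((p_all <= alpha / max(len(table), 1)).sum())
    calls = table.loc[retained].copy()
    calls["k"] = calls[col].astype(int)
    calls["lam"] = lam
    calls["p"] = p_all[retained]
    calls["is_hotspot"] = calls["p"] <= alpha / m

    cluster = np.full(len(calls), -1, dtype=int)
    cid = -1
    prev_key = None
    width = (calls["end"] - calls["start"]).to_numpy()
    for i, r in enumerate(calls.itertuples(index=False)):
        if not calls["is_hotspot"].iloc[i]:
            prev_key = None
            continue
        key = (r.chrom, r.start)
        if prev_key is not None and r.chrom == prev_key[0] and r.start == prev_key[1] + width[i - 1]:
            pass  # extend current cluster
        else:
            cid += 1
        cluster[i] = cid
        prev_key = key
    calls["cluster"] = cluster
    return HotspotResult(calls, float(lam), m, n_pre, scope)


def hotspot_analysis(
    co_regions: pd.DataFrame,
    layout: GenomeLayout,
    ped: Pedigree,
    marker_positions: dict[str, np.ndarray],
    window_bp: int = 30_000,
    alpha: float = 0.05,
    excluded_regions: pd.DataFrame | None = None,
    lam: dict[str, float] | None = None,
) -> dict[str, HotspotResult]:
    """30-kb window counts + filters + combined and per-sex hotspot calls."""
    table = window_co_counts(
        co_regions, layout, ped, window_bp=window_bp,
        centromere_min_count=0.0,  # the hotspot screen uses its own filters
    )
    table = apply_hotspot_filters(table, marker_positions, excluded_regions=excluded_regions)
    results = {}
    for scope in ("combined", "female", "male"):
        results[scope] = call_hotspots(
            table, scope=scope, lam=None if lam is None else lam.get(scope), alpha=alpha
        )
    return results
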