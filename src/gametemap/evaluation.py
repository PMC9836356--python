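"""Truth-recovery metrics for simulated crosses.

Used by the test-suite and the acceptance script to score the pipeline
against the simulator's recorded ground truth: crossover precision/recall
with end-buffer exclusion, junction-level phase accuracy, and the
detectable fraction of injected genotype errors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ParentalHaplotypes
from .pedigree import mendelian_consistent_table
from .simcross import SimParents, SimTruth


def match_crossovers(
    co_regions: pd.DataFrame,
    truth: SimTruth,
    tol_bp: int = 50_000,
) -> pd.DataFrame:
    """Greedy one-to-one matching of called CO regions to true breakpoints.

    A call matches a true breakpoint of the same gamete/chromosome when the
    breakpoint lies within [left_pos - tol, right_pos + tol].  Returns the
    calls with ``matched`` and ``true_bp`` columns.
    """
    out = co_regions.copy()
    out["matched"] = False
    out["true_bp"] = np.nan
    for (off, par, chrom), grp in out.groupby(["offspring", "parent", "chrom"], sort=False):
        gid = f"{off}:{par}"
        true_bps = list(truth.gametes[gid].breakpoints.get(chrom, np.array([])))
        used = set()
        for idx, r in grp.iterrows():
            best, best_d = None, None
            for t_i, bp in enumerate(true_bps):
                if t_i in used:
                    continue
                if r.left_pos - tol_bp <= bp <= r.right_pos + tol_bp:
                    d = abs(bp - r.midpoint)
                    if best is None or d < best_d:
                        best, best_d = t_i, d
            if best is not None:
                used.add(best)
                out.loc[idx, "matched"] = True
                out.loc[idx, "true_bp"] = true_bps[best]
    return out


def co_precision_recall(
    co_regions: pd.DataFrame,
    truth: SimTruth,
    end_buffer_bp: int = 500_000,
    tol_bp: int = 50_000,
) -> dict[str, float]:
    """Precision/recall of CO calls restricted to the chromosome interior
    (true breakpoints and call midpoints >= ``end_buffer_bp`` from either
    end), plus the median call span."""
    layout = truth.parents.layout
    lengths = dict(zip(layout.chrom_names, layout.chrom_lengths_bp))
    matched = match_crossovers(co_regions, truth, tol_bp)

    def interior(chrom: str, x: np.ndarray) -> np.ndarray:
        L = lengths[chrom]
        return (x >= end_buffer_bp) & (x <= L - end_buffer_bp)

    call_keep = np.zeros(len(matched), dtype=bool)
    for chrom in lengths:
        m = (matched["chrom"] == chrom).to_numpy()
        call_keep[m] = interior(chrom, matched.loc[m, "midpoint"].to_numpy())
    calls_int = matched.loc[call_keep]
    tp = int(calls_int["matched"].sum())
    n_calls = len(calls_int)

    # interior true breakpoints, only for gametes the calls cover
    parents_seen = set(co_regions["parent"].unique())
    found: dict[tuple[str, str, str], set[float]] = {}
    for r in matched.loc[matched["matched"]].itertuples(index=False):
        found.setdefault((r.offspring, r.parent, r.chrom), set()).add(float(r.true_bp))
    n_true = 0
    n_true_found = 0
    for gid, g in truth.gametes.items():
        if g.parent not in parents_seen:
            continue
        off = gid.split(":")[0]
        for chrom, bps in g.breakpoints.items():
            hits = found.get((off, g.parent, chrom), set())
            L = lengths[chrom]
            for bp in bps:
                if end_buffer_bp <= bp <= L - end_buffer_bp:
                    n_true += 1
                    if float(bp) in hits:
                        n_true_found += 1
    precision = tp / n_calls if n_calls else np.nan
    recall = n_true_found / n_true if n_true else np.nan
    return {
        "precision": precision,
        "recall": recall,
        "n_calls_interior": n_calls,
        "n_true_interior": n_true,
        "median_span_bp": float(np.median(co_regions["span_bp"])) if len(co_regions) else np.nan,
    }


def phase_junction_accuracy(
    haps: ParentalHaplotypes,
    parents: SimParents,
    min_conf_rank: float | None = None,
    confident_only: bool = True,
) -> dict[str, float]:
    """Fraction of junctions whose inferred coupling/repulsion sign matches
    the founder truth, overall and over confident junctions only."""
    pos_by_chrom = {
        c: parents.markers["pos"].to_numpy()[parents.chrom_slices[c]]
        for c in parents.layout.chrom_names
    }
    hap = parents.haplotypes[haps.parent]
    agree_all, n_all, agree_conf, n_conf = 0, 0, 0, 0
    for chrom, ph in haps.chroms.items():
        sl = parents.chrom_slices[chrom]
        pos_all = pos_by_chrom[chrom]
        idx = np.searchsorted(pos_all, ph.positions)
        h0 = hap[0, sl][idx]
        true_sign = np.where(h0[1:] == h0[:-1], 1, -1)
        est_sign = ph.junction_signs()
        ok = est_sign == true_sign
        agree_all += int(ok.sum())
        n_all += len(ok)
        conf = ~ph.low_conf
        agree_conf += int(ok[conf].sum())
        n_conf += int(conf.sum())
    return {
        "accuracy_all": agree_all / n_all if n_all else np.nan,
        "accuracy_confident": agree_conf / n_conf if n_conf else np.nan,
        "n_junctions": n_all,
        "n_confident": n_conf,
    }


def expected_mendelian_violation_rate(
    gm: np.ndarray, gf: np.ndarray, true_offspring: np.ndarray, error_rate: float
) -> float:
    """Expected observed trio-violation fraction under the simulator's
    error model (substitution to a uniformly random different dosage).

    For each call, a substituted dosage is detectable iff it is Mendelian-
    inconsistent with the parental pair; the detectable fraction is
    averaged by enumeration over the two possible substitutions.
    """
    tab = mendelian_consistent_table()
    ok = (gm >= 0) & (gf >= 0) & (true_offspring >= 0)
    gm, gf, t = gm[ok], gf[ok], true_offspring[ok]
    detect = np.zeros(len(t))
    for shift in (1, 2):
        sub = (t + shift) % 3
        detect += ~tab[gm, gf, sub]
    return float(error_rate * (detect / 2.0).mean())
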