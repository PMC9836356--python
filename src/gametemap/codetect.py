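"""Gamete haplotype labelling, smoothing, and crossover demarcation.

Each offspring's transmitted alleles from the focal parent are translated
into haplotype labels (A/B) at the parent's phased markers, de-noised with
an overlapping majority-vote window run from both chromosome ends, and
segmented into haplotype blocks.  Interior blocks shorter than the minimum
block size (default 500 kb) are absorbed — removing most gene-conversion
tracts and residual genotyping error — and each boundary between surviving
blocks is reported as a crossover region bounded by its flanking markers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ParentalHaplotypes
from .phasing import FocalContribution

A, B, NA = np.int8(0), np.int8(1), np.int8(-1)


@dataclass
class GameteLabelTrack:
    """Raw and smoothed haplotype labels for one gamete on one chromosome."""

    offspring: str
    parent: str
    sex: str
    chrom: str
    positions: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None


def assign_gamete_labels(
    contrib: FocalContribution, haps: ParentalHaplotypes
) -> dict[str, np.ndarray]:
    """Raw label matrices per chromosome: 0 where the transmitted allele
    matches haplotype A, 1 for haplotype B, -1 where NA."""
    out = {}
    for chrom, sl in contrib.chrom_slices.items():
        codes = contrib.codes[:, sl]
        hap_a = haps.chroms[chrom].hap_a
        lab = np.where(codes == hap_a[None, :], A, B).astype(np.int8)
        lab[codes < 0] = NA
        out[chrom] = lab
    return out


# ---------------------------------------------------------------------------
# smoothing


def _window_majorities(lab: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Majority label of each sliding window (starts 0, step, 2*step, ...);
    trailing windows use all remaining markers.  Returns (starts, labels)."""
    m = len(lab)
    is_a = (lab == A).astype(np.int32)
    is_b = (lab == B).astype(np.int32)
    ca = np.concatenate([[0], np.cumsum(is_a)])
    cb = np.concatenate([[0], np.cumsum(is_b)])
    starts = np.arange(0, max(m - step, 1), step)
    ends = np.minimum(starts + window, m)
    na_ = ca[ends] - ca[starts]
    nb_ = cb[ends] - cb[starts]
    maj = np.where(na_ > nb_, A, np.where(nb_ > na_, B, NA)).astype(np.int8)
    return starts, maj


def _directional_pass(lab: np.ndarray, window: int, step: int) -> np.ndarray:
    """Left-to-right pass: each marker takes the majority label of the first
    (leftmost) window that covers it."""
    m = len(lab)
    if m == 0:
        return lab.copy()
    if m < window:
        # single-window fallback for short chromosomes
        na_, nb_ = int((lab == A).sum()), int((lab == B).sum())
        fill = A if na_ > nb_ else B if nb_ > na_ else NA
        return np.full(m, fill, dtype=np.int8)
    starts, maj = _window_majorities(lab, window, step)
    out = np.full(m, NA, dtype=np.int8)
    # first covering window for marker i: smallest start s with s <= i < s+window
    first_w = np.clip(np.ceil((np.arange(m) - window + 1) / step).astype(int), 0, len(starts) - 1)
    out = maj[first_w]
    return out


def _centered_majority(lab: np.ndarray, i: int, window: int) -> np.int8:
    lo = max(i - window // 2, 0)
    hi = min(lo + window, len(lab))
    seg = lab[lo:hi]
    na_, nb_ = int((seg == A).sum()), int((seg == B).sum())
    return A if na_ > nb_ else B if nb_ > na_ else NA


def smooth_labels(raw: np.ndarray, window: int = 20, step: int | None = None) -> np.ndarray:
    """Two-pass overlapping majority smoothing of one gamete's raw labels.

    Windows of ``window`` informative markers advance by ``step`` (default
    window/2) from both chromosome ends; the marker-wise consensus of the
    two passes is taken.  Disagreements fall back to the majority of a
    centred window; residual ties keep the marker's own raw label (a
    centred window ties exactly at a clean haplotype switch, where the raw
    label is already correct), else inherit the left neighbour.  The
    result contains no NA within the covered span.
    """
    if window % 2:
        raise ValueError("window must be even")
    if step is None:
        step = window // 2
    m = len(raw)
    if m == 0:
        return raw.copy()
    if m < window:
        warnings.warn(f"chromosome with {m} < {window} informative markers; single-window majority")
    fwd = _directional_pass(raw, window, step)
    bwd = _directional_pass(raw[::-1], window, step)[::-1]
    out = np.full(m, NA, dtype=np.int8)
    agree = fwd == bwd
    out[agree] = fwd[agree]
    take_other = (~agree) & ((fwd == NA) | (bwd == NA))
    out[take_other] = np.where(fwd[take_other] == NA, bwd[take_other], fwd[take_other])
    for i in np.flatnonzero(out == NA):
        lab = _centered_majority(raw, i, window)
        if lab == NA:
            # residual tie: the marker's own raw label (a tie is split
            # exactly at a clean switch, where the raw label is right),
            # else the left neighbour
            lab = raw[i] if raw[i] != NA else (out[i - 1] if i > 0 else NA)
        out[i] = lab
    if out[0] == NA:  # leading ties with nothing to the left
        nz = np.flatnonzero(out != NA)
        out[: nz[0]] = out[nz[0]] if nz.size else A
    return out


# ---------------------------------------------------------------------------
# block segmentation and CO regions


def _runs(lab: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of constant label as (label, i_first, i_last)."""
    edges = np.flatnonzero(np.diff(lab)) + 1
    bounds = np.concatenate([[0], edges, [len(lab)]])
    return [(int(lab[bounds[k]]), int(bounds[k]), int(bounds[k + 1] - 1)) for k in range(len(bounds) - 1)]


def call_blocks_and_co_regions(
    smoothed: np.ndarray,
    positions: np.ndarray,
    min_block_bp: int = 500_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment one gamete's smoothed labels into haplotype blocks and CO
    regions.

    Interior blocks spanning < ``min_block_bp`` are deleted and their span
    absorbed by the flanks (same label: merge; different labels: the longer
    flank wins), iterating until stable; terminal blocks are exempt.  One
    CO region is emitted per boundary between surviving blocks, bounded by
    the last marker of the left block and the first of the right.
    """
    if np.any(smoothed == NA):
        raise ValueError("smoothed labels must be NA-free")
    blocks = _runs(smoothed)

    def span(blk: tuple[int, int, int]) -> int:
        return int(positions[blk[2]] - positions[blk[1]])

    changed = True
    while changed and len(blocks) > 1:
        changed = False
        interior = [
            (k, span(blocks[k])) for k in range(1, len(blocks) - 1) if span(blocks[k]) < min_block_bp
        ]
        if not interior:
            break
        k = min(interior, key=lambda t: (t[1], t[0]))[0]
        left, mid, right = blocks[k - 1], blocks[k], blocks[k + 1]
        if left[0] == right[0]:
            blocks[k - 1 : k + 2] = [(left[0], left[1], right[2])]
        elif span(left) >= span(right):
            blocks[k - 1 : k + 1] = [(left[0], left[1], mid[2])]
        else:
            blocks[k : k + 2] = [(right[0], mid[1], right[2])]
        # coalesce any adjacent same-label blocks the absorption created
        merged: list[tuple[int, int, int]] = []
        for blk in blocks:
            if merged and merged[-1][0] == blk[0]:
                merged[-1] = (blk[0], merged[-1][1], blk[2])
            else:
                merged.append(blk)
        blocks = merged
        changed = True

    block_rows = [
        (int(positions[b[1]]), int(positions[b[2]]), "A" if b[0] == A else "B",
         b[2] - b[1] + 1, span(b))
        for b in blocks
    ]
    blocks_df = pd.DataFrame(
        block_rows, columns=["first_pos", "last_pos", "label", "n_markers", "span_bp"]
    )
    co_rows = []
    for k in range(len(blocks) - 1):
        left_pos = int(positions[blocks[k][2]])
        right_pos = int(positions[blocks[k + 1][1]])
        co_rows.append((left_pos, right_pos, (left_pos + right_pos) // 2, right_pos - left_pos))
    co_df = pd.DataFrame(co_rows, columns=["left_pos", "right_pos", "midpoint", "span_bp"])
    return blocks_df, co_df


def detect_crossovers(
    contrib: FocalContribution,
    haps: ParentalHaplotypes,
    sex: str,
    window: int = 20,
    min_block_bp: int = 500_000,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray]]:
    """Full detection for one focal parent's half-sib family.

    Returns (co_regions, blocks, smoothed label matrices per chromosome);
    CO regions carry offspring, parent, sex, chromosome and the flanking-
    marker interval.
    """
    raw_by_chrom = assign_gamete_labels(contrib, haps)
    co_all, blk_all = [], []
    smoothed_by_chrom: dict[str, np.ndarray] = {}
    for chrom, sl in contrib.chrom_slices.items():
        raw = raw_by_chrom[chrom]
        pos = contrib.markers["pos"].to_numpy()[sl]
        sm = np.full_like(raw, NA)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, off in enumerate(contrib.offspring):
                # only markers informative for THIS gamete demarcate its
                # blocks: windows hold 20 informative markers and CO
                # regions are bounded by unequivocally labelled markers
                inf = raw[i] >= 0
                if inf.sum() < 2:
                    continue
                sm_i = smooth_labels(raw[i][inf], window=window)
                sm[i, inf] = sm_i
                blocks_df, co_df = call_blocks_and_co_regions(sm_i, pos[inf], min_block_bp)
                for df, acc in ((blocks_df, blk_all), (co_df, co_all)):
                    df = df.copy()
                    df.insert(0, "chrom", chrom)
                    df.insert(0, "sex", sex)
                    df.insert(0, "parent", contrib.parent)
                    df.insert(0, "offspring", off)
                    acc.append(df)
        smoothed_by_chrom[chrom] = sm
    co = pd.concat(co_all, ignore_index=True) if co_all else pd.DataFrame(
        columns=["offspring", "parent", "sex", "chrom", "left_pos", "right_pos", "midpoint", "span_bp"]
    )
    blocks = pd.concat(blk_all, ignore_index=True) if blk_all else pd.DataFrame()
    return co, blocks, smoothed_by_chrom


def extract_co_sequences(
    co_regions: pd.DataFrame,
    fasta_path: str,
    max_span_bp: int = 10_000,
) -> tuple[dict[str, str], int]:
    """Export narrowly demarcated CO regions as FASTA records.

    Regions with span <= ``max_span_bp`` are extracted as the half-open
    0-based interval [left_pos - 1, right_pos) covering both flanking
    markers; records are named offspring:parent:chrom:left-right.
    """
    from pyfaidx import Fasta

    fa = Fasta(fasta_path)
    records: dict[str, str] = {}
    n_skipped = 0
    for r in co_regions.itertuples(index=False):
        if r.span_bp > max_span_bp:
            continue
        if r.chrom not in fa or r.right_pos > len(fa[r.chrom]):
            warnings.warn(f"region outside sequence bounds: {r.chrom}:{r.left_pos}-{r.right_pos}")
            n_skipped += 1
            continue
        name = f"{r.offspring}:{r.parent}:{r.chrom}:{r.left_pos}-{r.right_pos}"
        records[name] = str(fa[r.chrom][r.left_pos - 1 : r.right_pos])
    return records, len(records)


def co_regions_to_bed(co_regions: pd.DataFrame) -> pd.DataFrame:
    """BED-like view: 0-based half-open flanking-marker interval."""
    out = co_regions.copy()
    out["start0"] = out["left_pos"] - 1
    out["end0"] = out["right_pos"]
    return out[["chrom", "start0", "end0", "offspring", "parent", "sex", "span_bp", "midpoint"]]
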