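"""Genetic linkage maps over reference-ordered markers (Kosambi distances).

Per-parent maps are built from smoothed gamete label tracks: adjacent-
marker recombination fractions (switch frequency over informative gametes)
are converted to centiMorgans with the Kosambi mapping function, which
allows for partial crossover interference.  The consensus map pools all
gametes over 10-kb pseudo-markers after binning columns with redundant
segregation information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenomeLayout

RF_CLAMP = 0.499


def kosambi_cm(rf: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 * ln((1+2r)/(1-2r)) in centiMorgans."""
    r = np.asarray(rf, dtype=float)
    if np.any(r < 0):
        raise ValueError("rf must be >= 0")
    if np.any(r >= 0.5):
        raise ValueError("rf >= 0.5 maps to infinite distance")
    out = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(out) if out.ndim == 0 else out


def bin_redundant_markers(columns: np.ndarray) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Collapse identical label columns (NA matches only NA) to their first
    member.  ``columns`` is (n_gametes, n_markers); returns the indices of
    the representatives (in order) and representative -> member lists."""
    seen: dict[bytes, int] = {}
    bins: dict[int, list[int]] = {}
    reps: list[int] = []
    for j in range(columns.shape[1]):
        key = columns[:, j].tobytes()
        if key in seen:
            bins[seen[key]].append(j)
        else:
            seen[key] = j
            reps.append(j)
            bins[j] = [j]
    return np.array(reps, dtype=int), bins


@dataclass
class GeneticMap:
    """Per-chromosome cumulative map with physical anchors."""

    entries: dict[str, pd.DataFrame]      # chrom -> (id, bp, cM)
    summary: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.summary is None:
            rows = []
            for chrom, df in self.entries.items():
                cm = float(df["cM"].iloc[-1]) if len(df) else 0.0
                bp = int(df["bp"].iloc[-1] - df["bp"].iloc[0]) if len(df) else 0
                kb_per_cm = (bp / 1000.0) / cm if cm > 0 else np.nan
                rows.append((chrom, len(df), bp, cm, kb_per_cm))
            self.summary = pd.DataFrame(
                rows, columns=["chrom", "n_markers", "span_bp", "length_cM", "kb_per_cM"]
            )

    @property
    def length_cm(self) -> float:
        return float(self.summary["length_cM"].sum())

    @property
    def span_bp(self) -> int:
        return int(self.summary["span_bp"].sum())

    @property
    def kb_per_cm(self) -> float:
        return (self.span_bp / 1000.0) / self.length_cm if self.length_cm > 0 else np.nan

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for chrom, df in self.entries.items():
            d = df.copy()
            d.insert(0, "chrom", chrom)
            parts.append(d)
        return pd.concat(parts, ignore_index=True)


def _adjacent_rf(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Switch frequency between adjacent markers over pairwise-complete
    gametes; labels (n_gametes, m) with -1 NA.  Returns (rf, n_informative)."""
    A, B = labels[:, :-1], labels[:, 1:]
    ok = (A >= 0) & (B >= 0)
    n = ok.sum(axis=0).astype(float)
    sw = ((A != B) & ok).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        rf = sw / np.where(n > 0, n, np.nan)
    return np.nan_to_num(rf, nan=0.0), n


def _map_from_labels(
    positions: np.ndarray, labels: np.ndarray, id_prefix: str, do_bin: bool = True
) -> pd.DataFrame:
    if labels.shape[1] < 2:
        raise ValueError("need >= 2 informative markers per chromosome")
    if do_bin:
        reps, _ = bin_redundant_markers(labels)
        positions = positions[reps]
        labels = labels[:, reps]
    else:
        reps = np.arange(labels.shape[1])
    rf, _ = _adjacent_rf(labels)
    if np.any(rf >= 0.5):
        warnings.warn(f"{int((rf >= 0.5).sum())} junction(s) with rf >= 0.5 clamped to {RF_CLAMP}")
        rf = np.minimum(rf, RF_CLAMP)
    cm = np.concatenate([[0.0], np.cumsum(kosambi_cm(rf))])
    return pd.DataFrame(
        {"id": [f"{id_prefix}_{j}" for j in reps], "bp": positions.astype(int), "cM": cm}
    )


def build_parent_map(
    tracks: dict[str, tuple[np.ndarray, np.ndarray]],
    parent: str = "parent",
    bin_markers: bool = True,
) -> GeneticMap:
    """Framework map for one parent.

    ``tracks[chrom] = (positions, smoothed_label_matrix)`` with one row per
    gamete of this parent.  Redundant columns are binned first; adjacent
    rf >= 0.5 is clamped to 0.499 with a warning.
    """
    entries = {}
    for chrom, (pos, labels) in tracks.items():
        entries[chrom] = _map_from_labels(pos, labels, f"{parent}_{chrom}", bin_markers)
    return GeneticMap(entries)


def blocks_to_window_labels(
    blocks: pd.DataFrame,
    layout: GenomeLayout,
    window_bp: int = 10_000,
) -> dict[str, tuple[np.ndarray, np.ndarray, list[str]]]:
    """Per-gamete pseudo-marker labels: for every ``window_bp`` window, the
    label of the haplotype block covering the window centre (NA if none).

    ``blocks`` needs columns offspring, parent, chrom, first_pos, last_pos,
    label.  Returns chrom -> (window_centers, labels (n_gametes, n_windows),
    gamete_ids).
    """
    gametes = sorted(set(zip(blocks["offspring"], blocks["parent"])))
    g_idx = {g: i for i, g in enumerate(gametes)}
    out = {}
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
        centers = np.arange(window_bp // 2, length, window_bp)
        lab = np.full((len(gametes), len(centers)), -1, dtype=np.int8)
        sub = blocks.loc[blocks["chrom"] == chrom]
        for (off, par), grp in sub.groupby(["offspring", "parent"], sort=False):
            i = g_idx[(off, par)]
            grp = grp.sort_values("first_pos")
            firsts = grp["first_pos"].to_numpy()
            lasts = grp["last_pos"].to_numpy()
            codes = np.where(grp["label"].to_numpy() == "A", 0, 1).astype(np.int8)
            # blocks tile the covered span with boundaries at CO-region
            # midpoints, so the switch is visible to adjacent windows
            cuts = np.concatenate(
                [[firsts[0]], (lasts[:-1] + firsts[1:]) // 2, [lasts[-1]]]
            )
            for k in range(len(codes)):
                lo = np.searchsorted(centers, cuts[k], side="left")
                hi = np.searchsorted(centers, cuts[k + 1], side="right")
                lab[i, lo:hi] = codes[k]
        out[chrom] = (centers, lab, [f"{o}:{p}" for o, p in gametes])
    return out


def build_consensus_map(
    blocks: pd.DataFrame,
    layout: GenomeLayout,
    window_bp: int = 10_000,
) -> GeneticMap:
    """Consensus map over 10-kb pseudo-markers pooling all gametes.

    Window labels are parent-relative, so switch counts (and hence rf) are
    within-gamete quantities and pool cleanly across families.
    """
    win = blocks_to_window_labels(blocks, layout, window_bp)
    entries = {}
    for chrom, (centers, lab, _) in win.items():
        covered = np.flatnonzero((lab >= 0).any(axis=0))
        if covered.size < 2:
            entries[chrom] = pd.DataFrame({"id": [], "bp": [], "cM": []})
            continue
        entries[chrom] = _map_from_labels(
            centers[covered], lab[:, covered], f"pm_{chrom}", do_bin=True
        )
    return GeneticMap(entries)
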