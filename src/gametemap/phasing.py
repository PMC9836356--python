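"""Parental haplotype phasing from half-sib transmitted-allele patterns.

Two independent routes are combined:

1. adjacent-marker LD-sign chaining — the Pearson correlation of
   transmitted-allele indicators across offspring decides coupling
   (r > 0) or repulsion (r < 0) between neighbouring markers;
2. two-point linkage clustering — recombination fractions and LOD scores
   over a banded neighbourhood of marker pairs, single-linkage clustered
   at rf <= max_rf and LOD > min_lod, with phase propagated along the
   linkage graph.

The consensus keeps junctions where the methods agree and resolves
conflicts in favour of the higher rank-normalised confidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, ParentalHaplotypes, Pedigree, PhasedChromosome

#: contribution code of the focal (heterozygous) parent given the other
#: parent's dosage (rows, 3=missing) and the offspring dosage (cols,
#: 3=missing): 0 = transmitted ref, 1 = transmitted alt, -1 = unknown
#: (ambiguous all-het trio, Mendelian violation, or missing data).
_CONTRIB = np.array(
    [
        #  o=0  o=1  o=2  o=NA
        [0, 1, -1, -1],   # other = 0
        [0, -1, 1, -1],   # other = 1 (o=1 ambiguous)
        [-1, 0, 1, -1],   # other = 2
        [-1, -1, -1, -1], # other missing
    ],
    dtype=np.int8,
)


@dataclass
class FocalContribution:
    """offspring x informative-marker transmitted-allele codes for one
    focal parent (0=ref, 1=alt, -1=NA), with the retained marker table."""

    parent: str
    offspring: list[str]
    markers: pd.DataFrame            # chrom, pos (subset of the input, in order)
    codes: np.ndarray                # int8 (n_offspring, n_markers)
    chrom_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_slices:
            chroms = self.markers["chrom"].to_numpy()
            for c in pd.unique(chroms):
                idx = np.flatnonzero(chroms == c)
                self.chrom_slices[str(c)] = slice(int(idx[0]), int(idx[-1]) + 1)


def infer_focal_contribution(
    geno: GenotypeMatrix,
    ped: Pedigree,
    focal_parent: str,
    focal_dosage: np.ndarray | None = None,
    max_na_frac: float = 0.25,
) -> FocalContribution:
    """Deterministic allele subtraction at the focal parent's heterozygous
    markers.

    All-heterozygous trios and Mendelian violations yield NA; markers with
    more than ``max_na_frac`` NA across the half-sib family are dropped.
    """
    if focal_dosage is None:
        focal_dosage = geno.row(focal_parent)
    het = focal_dosage == 1
    offspring = ped.offspring_of(focal_parent)
    O = np.stack([geno.row(o) for o in offspring])[:, het]       # noqa: E741
    GO = np.stack(
        [geno.row(ped.other_parent(o, focal_parent)) for o in offspring]
    )[:, het]
    codes = _CONTRIB[np.where(GO < 0, 3, GO), np.where(O < 0, 3, O)]
    na_frac = (codes < 0).mean(axis=0)
    keep = na_frac <= max_na_frac
    markers = geno.markers.loc[het, ["chrom", "pos"]].iloc[keep].reset_index(drop=True)
    return FocalContribution(focal_parent, offspring, markers, codes[:, keep])


# ---------------------------------------------------------------------------
# method 1: adjacent-marker LD sign chaining


def _junction_r(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of transmitted-allele indicators for every adjacent marker
    pair, over offspring non-NA at both; returns (r, n) arrays of len m-1."""
    X = codes.astype(float)
    X[codes < 0] = np.nan
    A, B = X[:, :-1], X[:, 1:]
    ok = ~np.isnan(A) & ~np.isnan(B)
    n = ok.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sa = np.where(ok, A, 0.0).sum(axis=0)
        sb = np.where(ok, B, 0.0).sum(axis=0)
        saa = np.where(ok, A * A, 0.0).sum(axis=0)
        sbb = np.where(ok, B * B, 0.0).sum(axis=0)
        sab = np.where(ok, A * B, 0.0).sum(axis=0)
        cov = sab - sa * sb / np.where(n > 0, n, np.nan)
        va = saa - sa * sa / np.where(n > 0, n, np.nan)
        vb = sbb - sb * sb / np.where(n > 0, n, np.nan)
        r = cov / np.sqrt(va * vb)
    return r, n


def phase_by_adjacent_ld(
    contrib: FocalContribution,
    min_abs_ld: float = 0.3,
    min_informative: int = 10,
) -> ParentalHaplotypes:
    """Chain phase along physical order from LD signs.

    Haplotype A carries the ref allele at the first marker of each
    chromosome by convention.  Junctions with |r| below ``min_abs_ld`` or
    fewer than ``min_informative`` jointly observed offspring are flagged
    low-confidence; their sign is still applied (coupling when undefined).
    """
    chroms: dict[str, PhasedChromosome] = {}
    for chrom, sl in contrib.chrom_slices.items():
        codes = contrib.codes[:, sl]
        pos = contrib.markers["pos"].to_numpy()[sl]
        r, n = _junction_r(codes)
        sign = np.where(np.nan_to_num(r) < 0, -1, 1)
        low = (np.abs(np.nan_to_num(r)) < min_abs_ld) | (n < min_informative)
        hap_a = np.empty(len(pos), dtype=np.int8)
        hap_a[0] = 0
        # cumulative sign product: allele flips at repulsion junctions
        flips = np.concatenate([[1], sign]).cumprod()
        hap_a = ((1 - flips) // 2).astype(np.int8)
        chroms[chrom] = PhasedChromosome(pos, hap_a, np.abs(r), low)
    return ParentalHaplotypes(contrib.parent, chroms, method="adjacent_ld")


# ---------------------------------------------------------------------------
# method 2: two-point rf/LOD linkage clustering


def lod_score(rf: np.ndarray | float, n: np.ndarray | float) -> np.ndarray | float:
    """Two-point phase-known LOD: n*(rf*log10 rf + (1-rf)*log10(1-rf) + log10 2),
    with the rf -> 0 / 1 limits handled (x*log10 x -> 0)."""
    rf = np.asarray(rf, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = np.where(rf > 0, rf * np.log10(np.where(rf > 0, rf, 1.0)), 0.0)
        t2 = np.where(rf < 1, (1 - rf) * np.log10(np.where(rf < 1, 1 - rf, 1.0)), 0.0)
    out = n * (t1 + t2 + np.log10(2.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class TwoPointResult:
    haplotypes: ParentalHaplotypes
    pairs: pd.DataFrame            # chrom, i, j, rf, lod, phase (+1/-1)
    groups: dict[str, list[int]]   # chrom -> linkage-group sizes


def twopoint_rf_lod(
    contrib: FocalContribution,
    max_rf: float = 0.5,
    min_lod: float = 8.0,
    band: int = 30,
) -> TwoPointResult:
    """Estimate rf/LOD for marker pairs within a banded neighbourhood and
    single-linkage cluster them into phased linkage groups.

    rf is estimated under the better of the two phase assignments
    (min(d, n-d)/n); phase is propagated breadth-first along edges with
    rf <= max_rf and LOD > min_lod.  A chromosome splitting into more than
    one group triggers a warning; each group is phased independently
    (anchored ref-first).
    """
    chroms: dict[str, PhasedChromosome] = {}
    pair_rows = []
    groups: dict[str, list[int]] = {}
    for chrom, sl in contrib.chrom_slices.items():
        codes = contrib.codes[:, sl]
        pos = contrib.markers["pos"].to_numpy()[sl]
        m = codes.shape[1]
        neighbors: list[list[tuple[int, int, float]]] = [[] for _ in range(m)]
        adj_lod = np.full(max(m - 1, 0), np.nan)
        for d in range(1, min(band, m - 1) + 1):
            A, B = codes[:, :-d], codes[:, d:]
            ok = (A >= 0) & (B >= 0)
            n = ok.sum(axis=0).astype(float)
            mm = ((A != B) & ok).sum(axis=0).astype(float)
            with np.errstate(invalid="ignore"):
                rf_c = mm / np.where(n > 0, n, np.nan)
            phase = np.where(rf_c > 0.5, -1, 1)
            rf = np.where(rf_c > 0.5, 1.0 - rf_c, rf_c)
            lod = lod_score(np.nan_to_num(rf, nan=0.5), n)
            if d == 1:
                adj_lod = lod.copy()
            linked = (n > 0) & (rf <= max_rf) & (lod > min_lod)
            for i in np.flatnonzero(linked):
                j = i + d
                neighbors[i].append((j, int(phase[i]), float(lod[i])))
                neighbors[j].append((i, int(phase[i]), float(lod[i])))
                pair_rows.append((chrom, i, j, float(rf[i]), float(lod[i]), int(phase[i])))
        # BFS phase propagation per connected component
        hap_a = np.zeros(m, dtype=np.int8)
        visited = np.zeros(m, dtype=bool)
        sizes = []
        for start in range(m):
            if visited[start]:
                continue
            visited[start] = True
            hap_a[start] = 0
            queue = [start]
            size = 1
            while queue:
                u = queue.pop()
                for v, ph, _ in neighbors[u]:
                    if not visited[v]:
                        visited[v] = True
                        hap_a[v] = hap_a[u] if ph > 0 else 1 - hap_a[u]
                        queue.append(v)
                        size += 1
            sizes.append(size)
        groups[chrom] = sizes
        if len(sizes) > 1:
            warnings.warn(
                f"{contrib.parent}/{chrom}: markers split into {len(sizes)} "
                f"linkage groups (sizes {sizes})"
            )
        low = ~(adj_lod > min_lod)
        chroms[chrom] = PhasedChromosome(pos, hap_a, adj_lod, low)
    pairs = pd.DataFrame(pair_rows, columns=["chrom", "i", "j", "rf", "lod", "phase"])
    return TwoPointResult(ParentalHaplotypes(contrib.parent, chroms, "twopoint"), pairs, groups)


# ---------------------------------------------------------------------------
# consensus


def consensus_phase(
    method1: ParentalHaplotypes, method2: ParentalHaplotypes
) -> tuple[ParentalHaplotypes, pd.DataFrame]:
    """Junction-wise consensus of the two phasing routes.

    Agreeing junctions are kept; disagreements are resolved in favour of
    the method whose confidence (|r| for LD chaining, adjacent-pair LOD for
    two-point) has the higher rank among its own junctions, and logged.
    """
    chroms: dict[str, PhasedChromosome] = {}
    rows = []
    for chrom, ph1 in method1.chroms.items():
        ph2 = method2.chroms[chrom]
        if not np.array_equal(ph1.positions, ph2.positions):
            raise ValueError(f"methods disagree on marker set for {chrom}")
        s1, s2 = ph1.junction_signs(), ph2.junction_signs()
        c1 = np.nan_to_num(ph1.junction_conf)
        c2 = np.nan_to_num(ph2.junction_conf)
        rank1 = pd.Series(c1).rank(pct=True).to_numpy()
        rank2 = pd.Series(c2).rank(pct=True).to_numpy()
        sign = s1.copy()
        conflict = s1 != s2
        # a junction flagged low-confidence by one method defers to the
        # other; only both-confident (or both-low) conflicts go to ranks
        use2 = conflict & (ph1.low_conf & ~ph2.low_conf)
        tie = conflict & (ph1.low_conf == ph2.low_conf)
        use2 |= tie & (rank2 > rank1)
        sign[use2] = s2[use2]
        for j in np.flatnonzero(conflict):
            rows.append(
                (method1.parent, chrom, int(ph1.positions[j]), int(ph1.positions[j + 1]),
                 float(c1[j]), float(c2[j]), "twopoint" if use2[j] else "adjacent_ld")
            )
        flips = np.concatenate([[1], sign]).cumprod()
        hap_a = ((1 - flips) // 2).astype(np.int8)
        conf = np.maximum(rank1, rank2)
        low = ph1.low_conf & ph2.low_conf
        chroms[chrom] = PhasedChromosome(ph1.positions, hap_a, conf, low)
    conflicts = pd.DataFrame(
        rows, columns=["parent", "chrom", "pos_left", "pos_right", "conf_ld", "conf_lod", "winner"]
    )
    return ParentalHaplotypes(method1.parent, chroms, "consensus"), conflicts


def refine_phase_by_switch_rate(
    contrib: FocalContribution,
    haps: ParentalHaplotypes,
    threshold: float = 0.5,
    max_iter: int = 3,
) -> tuple[ParentalHaplotypes, int]:
    """Flip junctions where most gametes appear to switch haplotype.

    A single mis-phased junction makes *every* gamete of the family look
    recombinant at that point, whereas a real CO is private to one gamete;
    a per-junction switch rate above ``threshold`` therefore flags a phase
    error.  A gamete spanning several junctions between its informative
    markers spreads its switch indicator over all of them.  Returns the
    refined haplotypes and the number of junctions flipped.
    """
    total_flips = 0
    chroms = dict(haps.chroms)
    for _ in range(max_iter):
        flips_this_round = 0
        for chrom, sl in contrib.chrom_slices.items():
            ph = chroms[chrom]
            codes = contrib.codes[:, sl]
            lab = np.where(codes == ph.hap_a[None, :], 0, 1).astype(np.int8)
            lab[codes < 0] = -1
            m = lab.shape[1]
            switch = np.zeros(m - 1)
            span = np.zeros(m - 1)
            for g in range(lab.shape[0]):
                inf = np.flatnonzero(lab[g] >= 0)
                if inf.size < 2:
                    continue
                a, b = inf[:-1], inf[1:]
                sw = lab[g, a] != lab[g, b]
                for j1, j2, s in zip(a, b, sw):
                    span[j1:j2] += 1
                    if s:
                        switch[j1:j2] += 1
            with np.errstate(invalid="ignore"):
                rate = switch / np.where(span > 0, span, np.nan)
            bad = np.flatnonzero(rate > threshold)
            if bad.size == 0:
                continue
            sign = ph.junction_signs().astype(int)
            sign[bad] *= -1
            flips = np.concatenate([[1], sign]).cumprod()
            base = ph.hap_a[0]
            hap_a = np.where(flips > 0, base, 1 - base).astype(np.int8)
            chroms[chrom] = PhasedChromosome(
                ph.positions, hap_a, ph.junction_conf, ph.low_conf
            )
            flips_this_round += bad.size
        total_flips += flips_this_round
        if flips_this_round == 0:
            break
    return ParentalHaplotypes(haps.parent, chroms, haps.method), total_flips


def phase_parent(
    geno: GenotypeMatrix,
    ped: Pedigree,
    focal_parent: str,
    focal_dosage: np.ndarray | None = None,
    min_abs_ld: float = 0.3,
    min_lod: float = 8.0,
    band: int = 30,
) -> tuple[ParentalHaplotypes, FocalContribution, pd.DataFrame]:
    """Contribution inference + both phasing routes + consensus + switch-
    rate refinement, bundled."""
    contrib = infer_focal_contribution(geno, ped, focal_parent, focal_dosage)
    m1 = phase_by_adjacent_ld(contrib, min_abs_ld=min_abs_ld)
    m2 = twopoint_rf_lod(contrib, min_lod=min_lod, band=band)
    haps, conflicts = consensus_phase(m1, m2.haplotypes)
    haps, _ = refine_phase_by_switch_rate(contrib, haps)
    return haps, contrib, conflicts
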