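"""Synthetic full-factorial cross generator.

Emulates a 7x7 factorial mating design (14 parents, 49 full-sib families)
segregating on a multi-chromosome genome with a known, per-sex crossover
landscape.  Every downstream stage of the pipeline can therefore be tested
by parameter recovery: the generator records the true parental haplotypes
and every gamete's true crossover breakpoints.

Model
-----
* Marker allele frequencies are drawn uniformly from a MAF range and parent
  haplotype alleles are sampled independently per haplotype (founders are
  unrelated, sites are in linkage equilibrium).
* Crossovers per gamete follow, per chromosome, either a Poisson process
  with a piecewise-constant, sex-specific intensity (``interference_mode=
  "none"``) or a stationary gamma-renewal process on the cumulative
  intensity scale (``"gamma"``, default), which reproduces the positive
  crossover interference characteristic of plant meiosis.
* Genotyping error substitutes a uniformly random *different* dosage with
  probability ``error_rate``; missingness masks calls independently.

All randomness derives from one master seed through per-stream
``SeedSequence`` spawning, so outputs are independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenomeLayout, GenotypeMatrix, Pedigree
from . import io as gio

FEMALE_PARENTS = [f"F{i}" for i in range(1, 8)]
MALE_PARENTS = [f"M{i}" for i in range(1, 8)]


# ---------------------------------------------------------------------------
# recombination landscape


@dataclass
class Hotspot:
    chrom: str
    start_bp: int
    end_bp: int
    multiplier: float
    sexes: tuple[str, ...] = ("female", "male")


@dataclass
class RecombLandscape:
    """Piecewise-constant crossover intensity (COs/bp/meiosis) per sex.

    ``breaks[chrom]`` holds segment boundaries including 0 and the
    chromosome length; ``rates[sex][chrom]`` the per-bp intensity on each
    segment.  The integral over a chromosome is the expected CO count per
    gamete for that sex.
    """

    breaks: dict[str, np.ndarray]
    rates: dict[str, dict[str, np.ndarray]]
    obligate_co: bool = False
    interference_mode: str = "gamma"  # "none" | "gamma"
    interference_nu: float = 5.0

    def __post_init__(self) -> None:
        for sex in ("female", "male"):
            for chrom, r in self.rates[sex].items():
                if np.any(np.asarray(r) < 0):
                    raise ValueError("intensities must be >= 0")
                if len(r) != len(self.breaks[chrom]) - 1:
                    raise ValueError(f"rates/breaks mismatch on {chrom}")

    @classmethod
    def uniform(
        cls,
        layout: GenomeLayout,
        co_per_gamete: float = 1.2,
        male_multiplier: float = 1.2,
        male_biased_chroms: list[str] | None = None,
        hotspots: list[Hotspot] | None = None,
        obligate_co: bool = False,
        interference_mode: str = "gamma",
        interference_nu: float = 5.0,
    ) -> "RecombLandscape":
        """Flat landscape with ``co_per_gamete`` expected female COs per
        chromosome, a male rate multiplier on a subset of chromosomes
        (default: every other chromosome), and optional hotspot intervals
        whose intensity is multiplied without renormalisation."""
        if male_biased_chroms is None:
            male_biased_chroms = layout.chrom_names[::2]
        if male_multiplier <= 0:
            raise ValueError("male_multiplier must be > 0")
        breaks: dict[str, np.ndarray] = {}
        rates: dict[str, dict[str, np.ndarray]] = {"female": {}, "male": {}}
        for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
            base = co_per_gamete / length
            cuts = {0, length}
            for h in hotspots or []:
                if h.chrom == chrom:
                    cuts.update((h.start_bp, h.end_bp))
            b = np.array(sorted(cuts), dtype=float)
            breaks[chrom] = b
            for sex in ("female", "male"):
                r = np.full(len(b) - 1, base)
                if sex == "male" and chrom in male_biased_chroms:
                    r *= male_multiplier
                for h in hotspots or []:
                    if h.chrom == chrom and sex in h.sexes:
                        mid = (b[:-1] + b[1:]) / 2
                        r[(mid >= h.start_bp) & (mid < h.end_bp)] *= h.multiplier
                rates[sex][chrom] = r
        return cls(breaks, rates, obligate_co, interference_mode, interference_nu)

    @classmethod
    def piecewise(
        cls,
        layout: GenomeLayout,
        co_per_gamete: float = 1.2,
        n_segments: int = 10,
        variation: float = 0.6,
        seed: int = 0,
        male_multiplier: float = 1.2,
        male_biased_chroms: list[str] | None = None,
        obligate_co: bool = False,
        interference_mode: str = "gamma",
        interference_nu: float = 5.0,
    ) -> "RecombLandscape":
        """Spatially variable landscape: ``n_segments`` equal segments per
        chromosome with rates base*(1 + variation*u), u ~ Uniform(-1, 1),
        renormalised so the female integral equals ``co_per_gamete``."""
        if not (0 <= variation <= 1):
            raise ValueError("variation must lie in [0, 1]")
        if male_biased_chroms is None:
            male_biased_chroms = layout.chrom_names[::2]
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
        breaks: dict[str, np.ndarray] = {}
        rates: dict[str, dict[str, np.ndarray]] = {"female": {}, "male": {}}
        for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
            b = np.linspace(0, length, n_segments + 1)
            u = rng.uniform(-1.0, 1.0, size=n_segments)
            r = (co_per_gamete / length) * (1.0 + variation * u)
            r *= co_per_gamete / np.sum(np.diff(b) * r)
            breaks[chrom] = b
            rates["female"][chrom] = r
            rates["male"][chrom] = r * (male_multiplier if chrom in male_biased_chroms else 1.0)
        return cls(breaks, rates, obligate_co, interference_mode, interference_nu)

    def expected_co(self, chrom: str, sex: str) -> float:
        b = self.breaks[chrom]
        return float(np.sum(np.diff(b) * self.rates[sex][chrom]))

    def _cumulative(self, chrom: str, sex: str) -> tuple[np.ndarray, np.ndarray]:
        b = self.breaks[chrom]
        cum = np.concatenate([[0.0], np.cumsum(np.diff(b) * self.rates[sex][chrom])])
        return b, cum

    def sample_breakpoints(self, chrom: str, sex: str, rng: np.random.Generator) -> np.ndarray:
        """Draw true CO positions (bp, float) for one gamete.

        Poisson mode: N ~ Poisson(Lambda) with positions by inverse-CDF of
        the cumulative intensity (exact for piecewise-constant rates).
        Gamma mode: stationary gamma(nu) renewal process on the cumulative
        intensity scale, mapped back through the inverse cumulative
        intensity; the first arrival uses the equilibrium (length-biased)
        delay so that marginal rates match the landscape.
        """
        b, cum = self._cumulative(chrom, sex)
        total = cum[-1]
        for _ in range(1000):
            if total == 0:
                u = np.zeros(0)
            elif self.interference_mode == "none":
                n = rng.poisson(total)
                u = np.sort(rng.uniform(0.0, total, size=n))
            elif self.interference_mode == "gamma":
                nu = self.interference_nu
                pts = []
                # stationary delay: U * length-biased gamma(nu+1, 1/nu)
                t = rng.uniform() * rng.gamma(nu + 1.0, 1.0 / nu)
                while t < total:
                    pts.append(t)
                    t += rng.gamma(nu, 1.0 / nu)
                u = np.array(pts)
            else:
                raise ValueError(f"unknown interference_mode {self.interference_mode!r}")
            if len(u) > 0 or not self.obligate_co:
                break
        else:
            raise RuntimeError("obligate_co: no CO drawn in 1000 attempts (zero intensity?)")
        # invert the piecewise-linear cumulative intensity
        pos = np.interp(u, cum, b)
        pos = np.unique(pos)
        return pos[(pos > 0) & (pos < b[-1])]


# ---------------------------------------------------------------------------
# parents and markers


@dataclass
class SimParents:
    """True phased founder haplotypes over the full marker set."""

    layout: GenomeLayout
    markers: pd.DataFrame                       # chrom, pos, ref, alt
    haplotypes: dict[str, np.ndarray]           # parent -> (2, n_markers) 0/1
    chrom_slices: dict[str, slice] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_slices:
            chroms = self.markers["chrom"].to_numpy()
            for c in self.layout.chrom_names:
                idx = np.flatnonzero(chroms == c)
                self.chrom_slices[c] = slice(int(idx[0]), int(idx[-1]) + 1) if idx.size else slice(0, 0)

    @property
    def parents(self) -> list[str]:
        return list(self.haplotypes)

    def dosage_of(self, parent: str) -> np.ndarray:
        return self.haplotypes[parent].sum(axis=0).astype(np.int8)

    def het_mask(self, parent: str) -> np.ndarray:
        h = self.haplotypes[parent]
        return h[0] != h[1]


def _sample_unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n sorted, unique, 1-based positions; O(n) memory even for long chromosomes."""
    if n > length:
        raise ValueError("more markers requested than available positions")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False) if pos.size > n else pos)


def simulate_parent_haplotypes(
    layout: GenomeLayout,
    n_markers_per_chrom: int = 2000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> SimParents:
    """Draw marker positions, allele frequencies and 14 founder genomes."""
    if n_markers_per_chrom < 2:
        raise ValueError("need at least 2 markers per chromosome")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    bases = np.array(list("ACGT"))
    rows = []
    freqs = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
        pos = _sample_unique_positions(rng, length, n_markers_per_chrom)
        p = rng.uniform(lo, hi, size=n_markers_per_chrom)
        ref_i = rng.integers(0, 4, size=n_markers_per_chrom)
        alt_i = (ref_i + rng.integers(1, 4, size=n_markers_per_chrom)) % 4
        for k in range(n_markers_per_chrom):
            rows.append((chrom, int(pos[k]), bases[ref_i[k]], bases[alt_i[k]]))
        freqs.append(p)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    p_alt = np.concatenate(freqs)
    haplotypes = {}
    for parent in FEMALE_PARENTS + MALE_PARENTS:
        haplotypes[parent] = (rng.uniform(size=(2, len(markers))) < p_alt).astype(np.int8)
    return SimParents(layout, markers, haplotypes)


# ---------------------------------------------------------------------------
# meiosis


@dataclass
class Gamete:
    parent: str
    sex: str
    alleles: np.ndarray                      # 0/1 over all markers
    breakpoints: dict[str, np.ndarray]       # chrom -> float bp, increasing
    start_hap: dict[str, int]                # chrom -> 0/1


def simulate_meiosis(
    parents: SimParents,
    parent: str,
    landscape: RecombLandscape,
    sex: str,
    rng: np.random.Generator | int,
) -> Gamete:
    """Produce one gamete: CO positions per chromosome plus the transmitted
    allele at every marker (active haplotype flips at each CO)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    hap = parents.haplotypes[parent]
    alleles = np.empty(len(parents.markers), dtype=np.int8)
    breakpoints: dict[str, np.ndarray] = {}
    start_hap: dict[str, int] = {}
    positions = parents.markers["pos"].to_numpy()
    for chrom in parents.layout.chrom_names:
        if chrom not in landscape.breaks:
            raise KeyError(f"landscape does not cover chromosome {chrom!r}")
        sl = parents.chrom_slices[chrom]
        bps = landscape.sample_breakpoints(chrom, sex, rng)
        h0 = int(rng.integers(0, 2))
        pos = positions[sl]
        active = (h0 + np.searchsorted(bps, pos)) % 2
        alleles[sl] = hap[:, sl][active, np.arange(sl.stop - sl.start)]
        breakpoints[chrom] = bps
        start_hap[chrom] = h0
    return Gamete(parent, sex, alleles, breakpoints, start_hap)


# ---------------------------------------------------------------------------
# the cross


@dataclass
class SimTruth:
    """Ground truth of a simulated cross: every gamete's breakpoints and
    the founder haplotypes, plus the landscape and master seed used."""

    seed: int
    landscape: RecombLandscape
    parents: SimParents
    gametes: dict[str, Gamete]               # gamete_id -> Gamete

    def breakpoint_table(self) -> pd.DataFrame:
        rows = []
        for gid, g in sorted(self.gametes.items()):
            for chrom, bps in g.breakpoints.items():
                for bp in bps:
                    rows.append((gid, g.parent, chrom, int(round(bp))))
        return pd.DataFrame(rows, columns=["gamete_id", "parent_id", "chrom", "breakpoint_bp"])

    def co_count(self, parent: str | None = None, sex: str | None = None) -> int:
        n = 0
        for g in self.gametes.values():
            if parent is not None and g.parent != parent:
                continue
            if sex is not None and g.sex != sex:
                continue
            n += sum(len(b) for b in g.breakpoints.values())
        return n


def default_family_sizes(total: int = 829, shape: tuple[int, int] = (7, 7)) -> np.ndarray:
    """Split ``total`` progeny as evenly as possible over the factorial
    grid (default: 45 families of 17 and 4 of 16 summing to 829)."""
    n_fam = shape[0] * shape[1]
    base = total // n_fam
    sizes = np.full(n_fam, base, dtype=int)
    sizes[: total - base * n_fam] += 1
    return sizes.reshape(shape)


def simulate_factorial_cross(
    parents: SimParents,
    landscape: RecombLandscape,
    family_sizes: np.ndarray | None = None,
    error_rate: float = 0.01,
    missing_rate: float = 0.05,
    seed: int = 0,
    outdir: str | None = None,
) -> tuple[GenotypeMatrix, Pedigree, SimTruth]:
    """Mate every mother with every father and genotype the offspring.

    Each offspring is the union of one maternal and one paternal gamete;
    genotype errors substitute a random different dosage and missingness
    masks calls.  When ``outdir`` is given, VCF + pedigree TSV + truth TSV
    are written there.
    """
    if not (0 <= error_rate < 1 and 0 <= missing_rate < 1):
        raise ValueError("error_rate and missing_rate must lie in [0, 1)")
    if family_sizes is None:
        family_sizes = default_family_sizes()
    family_sizes = np.asarray(family_sizes, dtype=int)
    if family_sizes.shape != (7, 7):
        raise ValueError("family_sizes must be a 7x7 matrix")
    if (family_sizes < 0).any():
        raise ValueError("family sizes must be non-negative")

    ss = np.random.SeedSequence(seed)
    n_markers = len(parents.markers)
    off_ids, ped_rows, dosages = [], [], []
    gametes: dict[str, Gamete] = {}
    k = 0
    for i, mom in enumerate(FEMALE_PARENTS):
        for j, dad in enumerate(MALE_PARENTS):
            for _ in range(family_sizes[i, j]):
                oid = f"O{k:04d}_{mom}x{dad}"
                rng_m = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, k, 0)))
                rng_p = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, k, 1)))
                gm = simulate_meiosis(parents, mom, landscape, "female", rng_m)
                gp = simulate_meiosis(parents, dad, landscape, "male", rng_p)
                gametes[f"{oid}:{mom}"] = gm
                gametes[f"{oid}:{dad}"] = gp
                dosage = (gm.alleles.astype(np.int8) + gp.alleles.astype(np.int8))
                rng_e = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2, k)))
                if error_rate > 0:
                    err = rng_e.uniform(size=n_markers) < error_rate
                    shift = rng_e.integers(1, 3, size=n_markers).astype(np.int8)
                    dosage = np.where(err, (dosage + shift) % 3, dosage).astype(np.int8)
                if missing_rate > 0:
                    miss = rng_e.uniform(size=n_markers) < missing_rate
                    dosage = np.where(miss, np.int8(-1), dosage)
                off_ids.append(oid)
                ped_rows.append((oid, mom, dad))
                dosages.append(dosage)
                k += 1

    # parents are genotyped too (error/missing-free founder truth)
    samples = list(off_ids) + FEMALE_PARENTS + MALE_PARENTS
    for p in FEMALE_PARENTS + MALE_PARENTS:
        dosages.append(parents.dosage_of(p))
    geno = GenotypeMatrix(samples, parents.markers, np.vstack(dosages))
    ped = Pedigree(pd.DataFrame(ped_rows, columns=["offspring", "mother", "father"]))
    truth = SimTruth(seed, landscape, parents, gametes)

    if outdir is not None:
        gio.ensure_dir(outdir)
        gio.write_vcf(geno, f"{outdir}/genotypes.vcf", parents.layout)
        gio.write_pedigree(ped, f"{outdir}/pedigree.tsv")
        gio.write_truth(truth.breakpoint_table(), f"{outdir}/truth.tsv")
    return geno, ped, truth


# ---------------------------------------------------------------------------
# annotation tracks


@dataclass
class FeatureCoupling:
    """How strongly feature densities track the CO intensity landscape.

    Coupling coefficients are correlations on the unit-window scale: +1
    couples a feature deterministically and positively to intensity, 0
    decouples it.  Defaults mirror the qualitative structure reported for
    poplar (genes and simple repeats up, GC and LTRs down, in regions of
    high crossover activity).
    """

    gene: float = 0.6
    simple: float = 0.6
    gypsy: float = -0.6
    copia: float = -0.6
    gc: float = -0.5
    genes_per_10kb: float = 0.35
    repeats_per_10kb: float = 0.5
    gc_base: float = 0.34
    gc_amplitude: float = 0.06
    gc_gradient: tuple[float, float] | None = None  # (start, end) GC along chrom
    deterministic: bool = False


def simulate_feature_tracks(
    layout: GenomeLayout,
    landscape: RecombLandscape,
    coupling: FeatureCoupling | None = None,
    seed: int = 0,
    unit_bp: int = 10_000,
    outdir: str | None = None,
) -> dict[str, object]:
    """Generate genome FASTA (GC landscape), gene GFF3 and repeat BED whose
    densities are (optionally) coupled to the crossover landscape.

    Returns the sequences plus the per-unit-window truth table of feature
    counts, and writes genome.fasta / genes.gff3 / repeats.bed when
    ``outdir`` is given.
    """
    if coupling is None:
        coupling = FeatureCoupling()
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    seqs: dict[str, str] = {}
    gene_rows, repeat_rows, truth_rows = [], [], []
    gene_n = 0
    for chrom, length in zip(layout.chrom_names, layout.chrom_lengths_bp):
        starts = np.arange(0, length, unit_bp)
        ends = np.minimum(starts + unit_bp, length)
        mids = (starts + ends) / 2.0
        # female intensity as the reference landscape signal, standardised
        b, cum = landscape._cumulative(chrom, "female")
        w_int = np.interp(ends, b, cum) - np.interp(starts, b, cum)
        z = (w_int - w_int.mean()) / (w_int.std() + 1e-12)

        def expected(base: float, c: float) -> np.ndarray:
            lam = base * (1.0 + c * z)
            return np.clip(lam, 0.0, None)

        counts = {}
        for feat, c, base in [
            ("gene", coupling.gene, coupling.genes_per_10kb),
            ("simple", coupling.simple, coupling.repeats_per_10kb),
            ("gypsy", coupling.gypsy, coupling.repeats_per_10kb),
            ("copia", coupling.copia, coupling.repeats_per_10kb),
        ]:
            lam = expected(base * unit_bp / 10_000, c)
            if coupling.deterministic:
                counts[feat] = np.round(lam).astype(int)
            else:
                counts[feat] = rng.poisson(lam)

        if coupling.gc_gradient is not None:
            g0, g1 = coupling.gc_gradient
            gc_target = g0 + (g1 - g0) * mids / length
        else:
            gc_target = coupling.gc_base + coupling.gc_amplitude * coupling.gc * z
        gc_target = np.clip(gc_target, 0.2, 0.8)

        # sequence: per unit window, iid bases at the window's GC target
        chunks = []
        for wi in range(len(starts)):
            n = int(ends[wi] - starts[wi])
            gc = gc_target[wi]
            probs = [(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2]
            chunks.append(rng.choice(np.array(list("ATGC")), size=n, p=probs))
        seqs[chrom] = "".join("".join(c) for c in chunks)

        for wi in range(len(starts)):
            w0, w1 = int(starts[wi]), int(ends[wi])
            for _ in range(counts["gene"][wi]):
                s = int(rng.integers(w0, max(w1 - 500, w0 + 1)))
                e = min(s + int(rng.integers(200, 2000)), w1)
                gene_n += 1
                gene_rows.append((chrom, s + 1, e, f"gene{gene_n:06d}"))
            for cls in ("simple", "gypsy", "copia"):
                label = {"simple": "simple", "gypsy": "Gypsy", "copia": "Copia"}[cls]
                for _ in range(counts[cls][wi]):
                    s = int(rng.integers(w0, max(w1 - 100, w0 + 1)))
                    e = min(s + int(rng.integers(50, 800)), w1)
                    repeat_rows.append((chrom, s, e, label))
            truth_rows.append(
                (chrom, w0, w1, counts["gene"][wi], counts["simple"][wi],
                 counts["gypsy"][wi], counts["copia"][wi], gc_target[wi], w_int[wi])
            )

    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "feature_id"])
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start0", "end0", "name"])
    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start0", "end0", "n_genes", "n_simple", "n_gypsy",
                 "n_copia", "gc_target", "co_intensity"],
    )
    out = {"sequences": seqs, "genes": genes, "repeats": repeats, "truth": truth}
    if outdir is not None:
        gio.ensure_dir(outdir)
        gio.write_fasta(seqs, f"{outdir}/genome.fasta")
        gio.write_gff3(genes, f"{outdir}/genes.gff3")
        gio.write_bed(repeats, f"{outdir}/repeats.bed")
        out["paths"] = {
            "fasta": f"{outdir}/genome.fasta",
            "gff3": f"{outdir}/genes.gff3",
            "bed": f"{outdir}/repeats.bed",
        }
    return out
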