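"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Marker positions are 1-based (VCF style) everywhere in memory; BED output
  converts to 0-based half-open at the I/O boundary.
* Genotypes are alt-allele dosages coded as int8: 0, 1, 2, or -1 for missing.
* Haplotype alleles are coded 0 (ref) / 1 (alt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.int8(-1)


@dataclass
class GenomeLayout:
    """Chromosome names and physical lengths of the (synthetic) genome."""

    chrom_names: list[str]
    chrom_lengths_bp: list[int]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths_bp):
            raise ValueError("chrom_names and chrom_lengths_bp differ in length")
        if any(l <= 0 for l in self.chrom_lengths_bp):
            raise ValueError("all chromosome lengths must be positive")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths_bp[self.chrom_names.index(chrom)]

    @classmethod
    def test_scale(cls, n_chroms: int = 2, chrom_length_bp: int = 5_000_000) -> "GenomeLayout":
        """Desk-scale layout used throughout the test suite."""
        names = [f"Chr{i + 1:02d}" for i in range(n_chroms)]
        return cls(names, [chrom_length_bp] * n_chroms)

    @classmethod
    def full_scale(cls) -> "GenomeLayout":
        """A 19-chromosome layout of roughly poplar-like, descending sizes."""
        lengths = np.linspace(35e6, 8e6, 19).round().astype(int).tolist()
        return cls([f"Chr{i + 1:02d}" for i in range(19)], lengths)


@dataclass
class GenotypeMatrix:
    """samples x markers alt-dosage matrix with a marker index.

    ``markers`` holds columns chrom, pos, ref, alt sorted by (chrom, pos);
    ``dosage`` is int8 with -1 for missing calls.
    """

    samples: list[str]
    markers: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError("dosage shape does not match samples x markers")
        bad = ~np.isin(self.dosage, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("dosage codes restricted to {0,1,2,-1}")
        order = np.lexsort((self.markers["pos"].to_numpy(), self.markers["chrom"].to_numpy()))
        if not np.array_equal(order, np.arange(len(self.markers))):
            raise ValueError("markers must be sorted by (chrom, pos)")
        self._sample_idx = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def row(self, sample: str) -> np.ndarray:
        return self.dosage[self._sample_idx[sample]]

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset_samples(self, names: list[str]) -> "GenotypeMatrix":
        rows = [self._sample_idx[n] for n in names]
        return GenotypeMatrix(list(names), self.markers, self.dosage[rows])


@dataclass
class Pedigree:
    """offspring -> (mother, father) map for the full-factorial design."""

    table: pd.DataFrame  # columns: offspring, mother, father

    def __post_init__(self) -> None:
        mothers = set(self.table["mother"])
        fathers = set(self.table["father"])
        if mothers & fathers:
            raise ValueError("mothers and fathers must be disjoint")

    @property
    def mothers(self) -> list[str]:
        return sorted(set(self.table["mother"]))

    @property
    def fathers(self) -> list[str]:
        return sorted(set(self.table["father"]))

    @property
    def parents(self) -> list[str]:
        return self.mothers + self.fathers

    def sex_of(self, parent: str) -> str:
        if parent in set(self.table["mother"]):
            return "female"
        if parent in set(self.table["father"]):
            return "male"
        raise KeyError(f"unknown parent {parent!r}")

    def parents_of(self, offspring: str) -> tuple[str, str]:
        row = self.table.loc[self.table["offspring"] == offspring]
        if row.empty:
            raise KeyError(f"unknown offspring {offspring!r}")
        return str(row["mother"].iloc[0]), str(row["father"].iloc[0])

    def offspring_of(self, parent: str) -> list[str]:
        t = self.table
        mask = (t["mother"] == parent) | (t["father"] == parent)
        return t.loc[mask, "offspring"].tolist()

    def other_parent(self, offspring: str, focal: str) -> str:
        m, f = self.parents_of(offspring)
        if focal == m:
            return f
        if focal == f:
            return m
        raise KeyError(f"{focal!r} is not a parent of {offspring!r}")


@dataclass
class PhasedChromosome:
    """One parent's phased heterozygous markers on one chromosome."""

    positions: np.ndarray          # 1-based, strictly increasing
    hap_a: np.ndarray              # 0/1 allele carried by haplotype A
    junction_conf: np.ndarray = field(default=None)  # len n-1; |r| or LOD
    low_conf: np.ndarray = field(default=None)       # bool, len n-1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hap_a = np.asarray(self.hap_a, dtype=np.int8)
        n = len(self.positions)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.junction_conf is None:
            self.junction_conf = np.full(max(n - 1, 0), np.nan)
        if self.low_conf is None:
            self.low_conf = np.zeros(max(n - 1, 0), dtype=bool)

    @property
    def hap_b(self) -> np.ndarray:
        return (1 - self.hap_a).astype(np.int8)

    def junction_signs(self) -> np.ndarray:
        """+1 where adjacent markers are in coupling (same hap-A allele)."""
        if len(self.hap_a) < 2:
            return np.zeros(0, dtype=np.int8)
        return np.where(self.hap_a[1:] == self.hap_a[:-1], 1, -1).astype(np.int8)


@dataclass
class ParentalHaplotypes:
    """Phased haplotypes for one parent, keyed by chromosome."""

    parent: str
    chroms: dict[str, PhasedChromosome]
    method: str = "consensus"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, ph in self.chroms.items():
            conf = np.append(ph.junction_conf, np.nan)
            for i, pos in enumerate(ph.positions):
                rows.append((chrom, int(pos), int(ph.hap_a[i]), int(ph.hap_b[i]), conf[i]))
        return pd.DataFrame(rows, columns=["chrom", "pos", "hap_a", "hap_b", "junction_conf"])
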