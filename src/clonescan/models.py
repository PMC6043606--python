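"""Core domain types shared across the toolkit.

The analyses operate on three in-memory containers:

* :class:`ReferenceGenome` — the haploid, majority-rules reference the reads
  of every isolate were aligned to.
* :class:`GenotypeTable` — one isolate's genotype class (hom-ref / het /
  hom-nonref) at a set of 1-based genome positions.
* pandas DataFrames for per-position read-count tables (pileups) and derived
  per-position tracks; their column contracts live in :mod:`clonescan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

# genotype class codes used throughout
HOM_REF = 0
HET = 1
HOM_NONREF = 2

GT_LABELS = {HOM_REF: "hom-ref", HET: "het", HOM_NONREF: "hom-nonref"}


@dataclass(frozen=True)
class ReferenceGenome:
    """A haploid reference: ordered chromosomes with lengths in bp.

    An explicit base sequence is optional; all statistics here depend only on
    coordinates, so desk-scale genomes are plain length tables.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for _, l in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @classmethod
    def desk_default(cls, n_chrom: int = 4, length: int = 1_000_000) -> "ReferenceGenome":
        """Small genome for interactive use: 4 chromosomes x 1 Mb."""
        return cls(tuple((f"chr{i + 1}", length) for i in range(n_chrom)))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class PopulationModel:
    """Population-level polymorphism: where the segregating sites are and at
    what allele frequencies.

    ``snp_density`` is the expected number of polymorphic sites per bp.
    ``sfs_mode`` selects the allele-frequency law for the minor allele
    frequency q: ``"uniform"`` draws q ~ U(q_min, 0.5); ``"neutral"`` draws q
    with density proportional to 1/q on [1/(2N), 0.5]. The 2:1
    het:hom-nonref expectation under Hardy-Weinberg holds for either law.
    """

    snp_density: float
    sfs_mode: str = "uniform"
    seed: int = 0
    q_min: float = 0.05
    pop_size: int = 1000  # N for the neutral 1/q spectrum lower cutoff

    def __post_init__(self) -> None:
        if not 0 <= self.snp_density < 1:
            raise ValueError("snp_density must be in [0, 1)")
        if self.sfs_mode not in ("uniform", "neutral"):
            raise ValueError(f"unknown sfs_mode {self.sfs_mode!r}")

    def draw_frequencies(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Minor allele frequencies for ``n`` sites under the configured SFS."""
        if self.sfs_mode == "uniform":
            return rng.uniform(self.q_min, 0.5, size=n)
        # neutral: density ∝ 1/q on [q_lo, 0.5] → inverse-CDF sampling
        q_lo = 1.0 / (2 * self.pop_size)
        u = rng.uniform(size=n)
        return q_lo * (0.5 / q_lo) ** u


@dataclass(frozen=True)
class ClonalModel:
    """A clonal family: one inbred founder and mitotic descendants.

    The founder carries large homozygous (loss-of-heterozygosity) blocks;
    each descendant accumulates private heterozygous point mutations at rate
    ``mu`` per bp per mitotic division, dividing every
    ``division_interval_days`` days for ``years_since_divergence`` years.
    """

    founder_seed: int
    n_isolates: int
    years_since_divergence: tuple[float, ...]
    mu: float = 1e-9
    division_interval_days: float = 2.0
    loh_blocks: tuple[tuple[str, int, int], ...] = ()
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if len(self.years_since_divergence) != self.n_isolates:
            raise ValueError("need one divergence time per isolate")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.loh_blocks:
            if end <= start:
                raise ValueError(f"empty LoH block {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, blocks in by_chrom.items():
            blocks.sort()
            for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping LoH blocks on {chrom}")

    def divisions(self, years: float) -> float:
        return years * 365.25 / self.division_interval_days


@dataclass(frozen=True)
class SequencingModel:
    """Short-read resequencing noise model for pileup simulation.

    ``mapping_bias`` (<= 1) multiplies the sampling probability of reads from
    the non-reference haplotype before renormalisation, emulating an
    aligner's preference for reads matching the reference.
    """

    mean_coverage: float = 60.0
    error_rate: float = 0.01
    mapping_bias: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 < self.mapping_bias <= 1:
            raise ValueError("mapping_bias must be in (0, 1]")


@dataclass
class SitePanel:
    """The population's segregating sites, realised once per population so
    that all simulated isolates share the same positions, minor-allele
    frequencies and reference alleles.

    ``ref_is_major[i]`` records whether the haploid reference sequence (one
    random haplotype from the population) carries the major allele at site i.
    """

    chrom: np.ndarray  # str array
    pos: np.ndarray  # int64, 1-based
    q: np.ndarray  # minor allele frequency per site
    ref_is_major: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class GenotypeTable:
    """Genotype classes of a single isolate at a set of genome positions.

    ``gt`` holds class codes (0 hom-ref, 1 het, 2 hom-nonref). Positions are
    1-based and sorted by (chrom, pos). ``private`` marks sites created as
    isolate-private mutations by the clonal generator (truth labels for
    tests; analysis code never reads it).
    """

    name: str
    chrom: np.ndarray
    pos: np.ndarray
    gt: np.ndarray
    private: np.ndarray | None = None

    def __post_init__(self) -> None:
        order = np.lexsort((self.pos, self.chrom))
        self.chrom = np.asarray(self.chrom)[order]
        self.pos = np.asarray(self.pos, dtype=np.int64)[order]
        self.gt = np.asarray(self.gt, dtype=np.int8)[order]
        if self.private is not None:
            self.private = np.asarray(self.private, dtype=bool)[order]

    def __len__(self) -> int:
        return len(self.pos)

    # --- genotype-class views -------------------------------------------------

    def sites(self, classes: Iterable[int]) -> set[tuple[str, int]]:
        mask = np.isin(self.gt, list(classes))
        return set(zip(self.chrom[mask].tolist(), self.pos[mask].tolist()))

    @property
    def het_sites(self) -> set[tuple[str, int]]:
        """Heterozygous positions — the 'SNPs' of this isolate in the
        within-strain sense used throughout this package."""
        return self.sites([HET])

    @property
    def nonref_sites(self) -> set[tuple[str, int]]:
        return self.sites([HET, HOM_NONREF])

    def class_counts(self) -> dict[str, int]:
        return {
            GT_LABELS[c]: int((self.gt == c).sum()) for c in (HOM_REF, HET, HOM_NONREF)
        }


def positions_in_blocks(
    chrom: np.ndarray, pos: np.ndarray, blocks: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Boolean mask of (chrom, pos) pairs lying in any [start, end) block (1-based starts)."""
    mask = np.zeros(len(pos), dtype=bool)
    for bchrom, start, end in blocks:
        mask |= (chrom == bchrom) & (pos >= start) & (pos < end)
    return mask
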