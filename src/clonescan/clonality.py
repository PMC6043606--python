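"""Quantitative Hardy-Weinberg / clonality diagnostics.

Three analyses distinguish a clonal (asexual) lineage from sexually
recombining isolates in multi-isolate diploid data:

1. **Hom-nonref deficit.** Against a random-haplotype reference, HWE
   predicts one homozygous non-reference position for every two
   heterozygous ones. A clonal family descended from one founder shows a
   10-100x deficit of hom-nonref positions.
2. **Excess SNP sharing.** Under HWE the probability that a heterozygous
   site of one isolate is heterozygous in each of n independent isolates is
   at most (1/2)^n (2pq maximised at p = 1/2). Clones share nearly all
   their SNPs, which is astronomically unlikely under that bound; sampling
   one site per chromosome removes linkage between the tested sites.
3. **Crossover scarcity** (computed in :mod:`clonescan.crossovers`) —
   consumed here for the combined verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def predicted_homnonref(n_het: float) -> float:
    """Expected homozygous non-reference count under HWE given the observed
    heterozygous count: half of it (the 2:1 law)."""
    if n_het < 0:
        raise ValueError("n_het must be >= 0")
    return n_het / 2.0


def sharing_bound(n_other_isolates: int) -> float:
    """Upper bound on the per-site probability that a het site is het in all
    of ``n_other_isolates`` independent HWE isolates: (1/2)^n, since
    2pq <= 1/2 for every allele frequency p."""
    if n_other_isolates < 1:
        raise ValueError("need at least one other isolate")
    return 0.5**n_other_isolates


def unlinked_sharing_test(
    n_sites: int, n_shared: int, per_site_bound: float
) -> float:
    """Exact binomial upper tail P[X >= n_shared], X ~ Binomial(n_sites, b).

    ``n_sites`` unlinked sites (one per chromosome) are each shared with
    probability at most ``per_site_bound`` under HWE; a tiny tail
    probability at the observed sharing level rejects HWE.
    """
    if not 0 < per_site_bound <= 1:
        raise ValueError("per-site bound must be in (0, 1]")
    if n_shared > n_sites or n_shared < 0:
        raise ValueError("n_shared must be in [0, n_sites]")
    return float(stats.binom.sf(n_shared - 1, n_sites, per_site_bound))


@dataclass(frozen=True)
class HweReport:
    """Per-isolate summary of the HWE diagnostics."""

    isolate: str
    n_het: int
    n_homnonref: int
    predicted_homnonref: float
    n_sites_tested: int
    n_shared: int
    per_site_bound: float
    tail_probability: float
    verdict: str  # consistent-with-HWE | clonal-signature | indeterminate


def sample_unlinked_shared_sites(
    focal_het: set[tuple[str, int]],
    other_het: list[set[tuple[str, int]]],
    chromosomes: list[str],
    seed: int,
) -> tuple[int, int]:
    """Draw one focal het site uniformly per chromosome and count how many
    are het in *all* other isolates. Returns (n_sites, n_shared);
    chromosomes without focal het sites are skipped."""
    rng = np.random.default_rng(seed)
    n_sites = 0
    n_shared = 0
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for site in focal_het:
        by_chrom.setdefault(site[0], []).append(site)
    for chrom in chromosomes:
        sites = sorted(by_chrom.get(chrom, []))
        if not sites:
            continue
        site = sites[rng.integers(len(sites))]
        n_sites += 1
        if all(site in o for o in other_het):
            n_shared += 1
    return n_sites, n_shared


def clonality_verdict(
    n_het: int,
    n_homnonref: int,
    tail_probability: float,
    crossover_density: float | None = None,
    crossover_split: float | None = None,
    deficit_fold: float = 10.0,
    ratio_tol: float = 0.25,
    alpha: float = 1e-6,
) -> str:
    """Combined per-isolate clade label.

    ``H-like`` (sexual): hom-nonref/het ratio within ``ratio_tol`` of the
    HWE value 1/2 and, when crossover information is supplied, a crossover
    density above ``crossover_split``. ``L-like`` (clonal): at least
    ``deficit_fold`` fewer hom-nonref than predicted AND the unlinked
    sharing test rejects HWE at ``alpha``. Conflicting evidence returns
    ``indeterminate`` rather than silently picking a side.
    """
    predicted = predicted_homnonref(n_het)
    ratio_ok = (
        n_het > 0
        and n_homnonref > 0
        and abs(n_homnonref / n_het - 0.5) <= ratio_tol * 0.5
    )
    deficit = predicted > 0 and n_homnonref < predicted / deficit_fold
    sharing_rejects = tail_probability < alpha
    xo_high = crossover_density is None or (
        crossover_split is not None and crossover_density >= crossover_split
    )
    xo_low = crossover_density is None or (
        crossover_split is not None and crossover_density < crossover_split
    )
    h_like = ratio_ok and not deficit and not sharing_rejects and xo_high
    l_like = deficit and sharing_rejects and xo_low
    if h_like and not l_like:
        return "H-like"
    if l_like and not h_like:
        return "L-like"
    return "indeterminate"
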