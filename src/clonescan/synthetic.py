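"""Synthetic-data generator.

Emulates the statistical structure the downstream analyses assume:

* a sexual, randomly mating diploid population in Hardy-Weinberg equilibrium
  (HWE), sequenced against a haploid majority-rules reference that is itself
  one random haplotype from the population — which makes the expected
  het : hom-nonref count ratio exactly 2:1 at any allele-frequency spectrum
  (per site: E[het] = 2pq, E[hom-nonref] = pq);
* a clonal family descended from a single inbred founder that carries large
  homozygous blocks (loss of heterozygosity) and whose members differ only
  by private heterozygous point mutations — no meiosis is ever applied;
* per-position read-count tables with Poisson coverage, uniform sequencing
  error and a multiplicative mapping bias against the non-reference allele.

All randomness flows through explicit integer seeds; outputs are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    HET,
    HOM_NONREF,
    HOM_REF,
    ClonalModel,
    GenotypeTable,
    PopulationModel,
    ReferenceGenome,
    SequencingModel,
    SitePanel,
    positions_in_blocks,
)

BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# site panel


def realize_panel(ref: ReferenceGenome, pop: PopulationModel) -> SitePanel:
    """Draw the population's segregating sites once.

    Site count per chromosome is Binomial(length, snp_density); positions are
    uniform without replacement; minor-allele frequencies follow the model's
    SFS; the reference allele at each site is a single random haplotype draw
    (major allele with probability p = 1 - q).
    """
    rng = np.random.default_rng(pop.seed)
    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    expected = pop.snp_density * ref.total_length
    if 0 < expected < 1:
        warnings.warn(
            f"expected site count {expected:.2f} < 1; panel may be empty",
            stacklevel=2,
        )
    for name, length in ref.chromosomes:
        n = rng.binomial(length, pop.snp_density)
        p = np.sort(rng.choice(length, size=n, replace=False)) + 1  # 1-based
        chroms.append(np.full(n, name, dtype=object))
        poss.append(p.astype(np.int64))
    chrom = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos = np.concatenate(poss) if poss else np.array([], dtype=np.int64)
    q = pop.draw_frequencies(len(pos), rng)
    ref_is_major = rng.uniform(size=len(pos)) < (1.0 - q)
    return SitePanel(chrom=chrom, pos=pos, q=q, ref_is_major=ref_is_major)


# ---------------------------------------------------------------------------
# genotype simulation


def _genotype_classes(panel: SitePanel, rng: np.random.Generator) -> np.ndarray:
    """HWE genotype classes relative to the reference allele.

    The isolate's minor-allele dosage at each site is Binomial(2, q). The
    genotype class then depends on which allele the reference carries.
    """
    dosage = rng.binomial(2, panel.q)
    gt = np.empty(len(panel), dtype=np.int8)
    maj = panel.ref_is_major
    # reference carries the major allele: dosage counts non-reference copies
    gt[maj] = dosage[maj]
    # reference carries the minor allele: non-reference copies = 2 - dosage
    gt[~maj] = 2 - dosage[~maj]
    return gt


def simulate_sexual_isolate(
    ref: ReferenceGenome,
    pop: PopulationModel,
    seed: int,
    name: str = "sexual",
    panel: SitePanel | None = None,
) -> GenotypeTable:
    """One random-mating diploid isolate drawn from the population panel.

    Pass the same ``panel`` (or the same ``pop``, whose seed fixes it) to
    draw several isolates from one population.
    """
    if panel is None:
        panel = realize_panel(ref, pop)
    rng = np.random.default_rng(seed)
    gt = _genotype_classes(panel, rng)
    return GenotypeTable(
        name=name,
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        gt=gt,
        private=np.zeros(len(panel), dtype=bool),
    )


def simulate_clonal_isolates(
    ref: ReferenceGenome,
    pop: PopulationModel,
    clonal: ClonalModel,
    names: Sequence[str] | None = None,
    panel: SitePanel | None = None,
    return_founder: bool = False,
):
    """A clonal family: inbred founder plus mitotic descendants.

    The haploid majority-rules reference of such a study is assembled from
    the clonal lineage itself, so one of the founder's haplotypes *is* the
    reference haplotype: the founder is heterozygous where its second
    (random population) haplotype differs from the reference allele and
    homozygous-reference elsewhere — it carries no homozygous non-reference
    position, and descendants acquire them only by double-hit mutation
    (never simulated here). LoH blocks are then forced homozygous
    reference. Each descendant inherits the founder genotype unchanged and
    adds private heterozygous mutations, Poisson with mean
    ploidy x genome_length x mu x divisions, at uniform random positions
    (redrawn on the rare collision with an existing site).
    """
    if panel is None:
        panel = realize_panel(ref, pop)
    frng = np.random.default_rng(clonal.founder_seed)
    # second haplotype carries the minor allele with probability q; het iff
    # it differs from the reference allele
    h2_minor = frng.uniform(size=len(panel)) < panel.q
    het = h2_minor == panel.ref_is_major
    founder = GenotypeTable(
        name="founder",
        chrom=panel.chrom.copy(),
        pos=panel.pos.copy(),
        gt=np.where(het, HET, HOM_REF).astype(np.int8),
        private=np.zeros(len(panel), dtype=bool),
    )
    if clonal.loh_blocks:
        in_loh = positions_in_blocks(founder.chrom, founder.pos, clonal.loh_blocks)
        founder.gt[in_loh] = HOM_REF

    if names is None:
        names = [f"clone{i + 1}" for i in range(clonal.n_isolates)]
    rng = np.random.default_rng(clonal.founder_seed + 1)
    lengths = ref.lengths
    chrom_names = ref.names
    chrom_weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()
    existing = set(zip(founder.chrom.tolist(), founder.pos.tolist()))

    isolates = []
    for name, years in zip(names, clonal.years_since_divergence):
        mean = clonal.ploidy * ref.total_length * clonal.mu * clonal.divisions(years)
        n_mut = rng.poisson(mean)
        new_sites: set[tuple[str, int]] = set()
        while len(new_sites) < n_mut:
            c = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
            p = int(rng.integers(1, lengths[c] + 1))
            if (c, p) not in existing and (c, p) not in new_sites:
                new_sites.add((c, p))
        if new_sites:
            mchrom = np.array([c for c, _ in new_sites], dtype=object)
            mpos = np.array([p for _, p in new_sites], dtype=np.int64)
            chrom = np.concatenate([founder.chrom, mchrom])
            pos = np.concatenate([founder.pos, mpos])
            gt = np.concatenate([founder.gt, np.full(len(new_sites), HET, np.int8)])
            private = np.concatenate(
                [np.zeros(len(founder), bool), np.ones(len(new_sites), bool)]
            )
        else:
            chrom, pos, gt = founder.chrom.copy(), founder.pos.copy(), founder.gt.copy()
            private = np.zeros(len(founder), bool)
        isolates.append(GenotypeTable(name=name, chrom=chrom, pos=pos, gt=gt, private=private))

    if return_founder:
        return isolates, founder
    return isolates


# ---------------------------------------------------------------------------
# pileup simulation


def simulate_pileup(
    genotype: GenotypeTable,
    seqmodel: SequencingModel,
    ref: ReferenceGenome | None = None,
    dense: bool = False,
    hemizygous_blocks: Sequence[tuple[str, int, int]] = (),
    copy_number_blocks: Sequence[tuple[str, int, int, float]] = (),
) -> pd.DataFrame:
    """Per-position read counts for one isolate.

    Depth is Poisson(mean_coverage), halved inside hemizygous blocks and
    multiplied by the factor of any copy-number block. Each read comes from
    one of the two haplotypes with probability 1/2, the non-reference
    haplotype downweighted by ``mapping_bias`` before renormalisation (a het
    site therefore has expected non-reference read fraction
    bias / (1 + bias)). Sequencing error flips a read's base to a uniformly
    random other base with probability ``error_rate``.

    With ``dense=True`` (requires ``ref``) every genome position is emitted,
    monomorphic positions as hom-ref; otherwise only the genotype table's
    sites are emitted.

    Returns a DataFrame with columns chrom, pos, ref_base, ref_count and
    A/C/G/T non-reference counts (the reference base's own column is 0).
    """
    rng = np.random.default_rng(seqmodel.seed)
    if dense:
        if ref is None:
            raise ValueError("dense pileup requires a ReferenceGenome")
        chroms, poss, gts = [], [], []
        site_lookup = {
            (c, int(p)): g
            for c, p, g in zip(genotype.chrom, genotype.pos, genotype.gt)
        }
        for cname, length in ref.chromosomes:
            allpos = np.arange(1, length + 1, dtype=np.int64)
            g = np.zeros(length, dtype=np.int8)
            on_c = genotype.chrom == cname
            g[genotype.pos[on_c] - 1] = genotype.gt[on_c]
            chroms.append(np.full(length, cname, dtype=object))
            poss.append(allpos)
            gts.append(g)
        chrom = np.concatenate(chroms)
        pos = np.concatenate(poss)
        gt = np.concatenate(gts)
        del site_lookup
    else:
        chrom, pos, gt = genotype.chrom, genotype.pos, genotype.gt

    n = len(pos)
    depth_mean = np.full(n, float(seqmodel.mean_coverage))
    for bchrom, start, end, factor in copy_number_blocks:
        sel = (chrom == bchrom) & (pos >= start) & (pos < end)
        depth_mean[sel] *= factor
    hemi = positions_in_blocks(chrom, pos, hemizygous_blocks)
    depth_mean[hemi] *= 0.5

    depth = rng.poisson(depth_mean)

    # expected non-reference read fraction per genotype class
    b = seqmodel.mapping_bias
    p_alt = np.zeros(n)
    p_alt[gt == HET] = b / (1.0 + b)
    p_alt[gt == HOM_NONREF] = 1.0
    # a hemizygous het site keeps a single haplotype: ref or alt, coin flip
    hemi_het = hemi & (gt == HET)
    p_alt[hemi_het] = rng.integers(0, 2, size=int(hemi_het.sum())).astype(float)

    alt_reads = rng.binomial(depth, p_alt)
    ref_reads = depth - alt_reads

    # ref/alt base identities are a property of the genome position, not of
    # the sequencing run, so different isolates' pileups agree on them
    mix = (pos.astype(np.uint64) * np.uint64(2654435761)) >> np.uint64(7)
    ref_base_idx = (mix % np.uint64(4)).astype(np.int64)
    alt_base_idx = (ref_base_idx + 1 + ((mix >> np.uint64(2)) % np.uint64(3)).astype(np.int64)) % 4

    counts = np.zeros((n, 4), dtype=np.int64)  # observed reads per base
    e = seqmodel.error_rate
    for true_idx, reads in ((ref_base_idx, ref_reads), (alt_base_idx, alt_reads)):
        errs = rng.binomial(reads, e)
        keep = reads - errs
        np.add.at(counts, (np.arange(n), true_idx), keep)
        if e > 0:
            # split errors uniformly over the three other bases
            err_split = np.zeros((n, 3), dtype=np.int64)
            err_split[:, 0] = rng.binomial(errs, 1 / 3)
            err_split[:, 1] = rng.binomial(errs - err_split[:, 0], 0.5)
            err_split[:, 2] = errs - err_split[:, 0] - err_split[:, 1]
            for off in range(3):
                np.add.at(
                    counts,
                    (np.arange(n), (true_idx + 1 + off) % 4),
                    err_split[:, off],
                )

    ref_count = counts[np.arange(n), ref_base_idx].copy()
    counts[np.arange(n), ref_base_idx] = 0  # A/C/G/T columns hold non-ref counts

    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref_base": BASES[ref_base_idx],
            "ref_count": ref_count,
            "A": counts[:, 0],
            "C": counts[:, 1],
            "G": counts[:, 2],
            "T": counts[:, 3],
        }
    )
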