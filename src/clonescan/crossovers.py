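"""Pairwise crossover-density estimation from genotype concordance.

Two isolates that share recombining ancestry switch, along a chromosome,
between tracts where their genotypes agree (co-inherited haplotype
background) and tracts where they disagree. The estimator marks every
informative site (het in at least one isolate of the pair, genotyped in
both) concordant or discordant, run-length encodes the track per
chromosome, absorbs runs shorter than a minimum number of sites as noise
(isolate-private mutations, genotyping error), and counts the surviving
state transitions as crossovers. Density is crossovers per Kb of assayed
span (first to last informative site, summed over chromosomes).

Clonal pairs differ only at sparse private mutations — isolated discordant
sites that the run-length filter absorbs — and so show near-zero density;
sexually related pairs alternate in long tracts and show densities orders
of magnitude higher.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import GenotypeTable, HET


@dataclass
class ConcordanceTrack:
    """Concordance states at informative sites of one isolate pair."""

    chrom: np.ndarray
    pos: np.ndarray
    concordant: np.ndarray  # bool

    def __len__(self) -> int:
        return len(self.pos)


def build_concordance(a: GenotypeTable, b: GenotypeTable) -> ConcordanceTrack:
    """Concordance track over sites het in at least one of the pair.

    Sites absent from one table count as hom-ref there (the generator and
    the refined matrix only materialise non-reference sites); pass tables on
    the same reference coordinates.
    """
    gt_a = {(c, int(p)): g for c, p, g in zip(a.chrom, a.pos, a.gt)}
    gt_b = {(c, int(p)): g for c, p, g in zip(b.chrom, b.pos, b.gt)}
    sites = sorted(set(gt_a) | set(gt_b))
    chroms, poss, conc = [], [], []
    for site in sites:
        ga = gt_a.get(site, 0)
        gb = gt_b.get(site, 0)
        if HET not in (ga, gb):
            continue  # informative sites only
        chroms.append(site[0])
        poss.append(site[1])
        conc.append(ga == gb)
    return ConcordanceTrack(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        concordant=np.array(conc, dtype=bool),
    )


def _absorb_short_runs(states: np.ndarray, min_run: int) -> list[tuple[bool, int]]:
    """RLE with runs shorter than min_run merged into their neighbours,
    iterated to a fixpoint. Returns [(state, length), ...]."""
    runs: list[list[object]] = []
    for s in states:
        if runs and runs[-1][0] == bool(s):
            runs[-1][1] += 1
        else:
            runs.append([bool(s), 1])
    changed = True
    while changed and len(runs) > 1:
        changed = False
        # drop the shortest sub-threshold run first for stability
        short = [i for i, r in enumerate(runs) if r[1] < min_run]
        if not short:
            break
        i = min(short, key=lambda j: runs[j][1])
        dropped = runs.pop(i)
        if 0 < i < len(runs) and runs[i - 1][0] == runs[i][0]:
            runs[i - 1][1] += runs[i][1] + dropped[1]
            runs.pop(i)
        elif i > 0:
            runs[i - 1][1] += dropped[1]
        else:
            runs[0][1] += dropped[1]
        changed = True
    return [(bool(s), int(l)) for s, l in runs]


@dataclass(frozen=True)
class CrossoverEstimate:
    n_crossovers: int
    assayed_kb: float
    density_per_kb: float


def estimate_crossovers(track: ConcordanceTrack, min_run_sites: int = 10) -> CrossoverEstimate:
    """Crossover count and per-Kb density from a concordance track.

    Transitions between concordance runs of at least ``min_run_sites``
    informative sites count as crossovers; shorter runs are treated as
    noise and absorbed before counting. Raising ``min_run_sites`` can only
    lower the count.
    """
    if min_run_sites < 1:
        raise ValueError("min_run_sites must be >= 1")
    if len(track) == 0:
        warnings.warn("empty concordance track; density 0", stacklevel=2)
        return CrossoverEstimate(0, 0.0, 0.0)
    total = 0
    span_bp = 0
    for chrom in dict.fromkeys(track.chrom.tolist()):
        sel = track.chrom == chrom
        states = track.concordant[sel]
        pos = track.pos[sel]
        runs = _absorb_short_runs(states, min_run_sites)
        total += max(0, len(runs) - 1)
        if len(pos) > 1:
            span_bp += int(pos.max() - pos.min())
    kb = span_bp / 1000.0
    density = total / kb if kb > 0 else 0.0
    return CrossoverEstimate(total, kb, density)


def pairwise_densities(
    isolates: list[GenotypeTable], min_run_sites: int = 10
) -> dict[tuple[str, str], CrossoverEstimate]:
    """Crossover estimates for every unordered isolate pair."""
    out = {}
    for i, a in enumerate(isolates):
        for b in isolates[i + 1 :]:
            track = build_concordance(a, b)
            out[(a.name, b.name)] = estimate_crossovers(track, min_run_sites)
    return out
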