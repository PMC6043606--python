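"""Detection of SNP deserts — statistically significant low-heterozygosity regions.

Model: SNPs (heterozygous positions) fall independently with per-bp
probability p, the isolate-specific genome-wide SNP density. The distance
from a position to the k-th SNP downstream then follows a negative binomial
with parameters p and k; equivalently, an interval of length L contains
fewer than k SNPs with probability P[Binomial(L, p) <= k - 1]. Let L* be the
smallest interval length for which that probability drops to alpha
(defaults: k = 5, alpha = 1e-4). Every interval longer than L* containing
fewer than k SNPs is a desert; deserts that overlap or lie within a small
gap of each other (default 100 bp) are merged. Near the 3' end of a
chromosome, where only j < k SNPs remain downstream of an anchor, the
criterion uses the negative binomial with parameters p and j instead; with
j = 0 no desert can be declared.

The significance calculation is done by exact binomial tail summation, not
by a continuous approximation, so the failures/successes convention of the
negative binomial never enters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DesertModel:
    """Scan parameters: per-bp SNP probability p (1/p = mean inter-SNP
    distance), run length k, tail probability alpha, and the merge gap."""

    p: float
    k: int = 5
    alpha: float = 1e-4
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def estimate_p(n_snps: int, callable_length: int) -> float:
    """Genome-wide per-bp SNP probability: SNP count over callable length
    (reference gaps excluded via the caller's mask)."""
    if callable_length <= 0:
        raise ValueError("callable_length must be positive")
    return n_snps / callable_length


# ---------------------------------------------------------------------------
# threshold


def desert_threshold(model: DesertModel, k: int | None = None) -> int:
    """Smallest integer L with P[Binomial(L, p) <= k - 1] <= alpha.

    Monotone in L, so located by bisection on the exact binomial CDF.
    """
    k = model.k if k is None else k
    if k < 1:
        raise ValueError("k must be >= 1")

    def tail(L: int) -> float:
        return float(stats.binom.cdf(k - 1, L, model.p))

    lo = k  # smallest length that can even hold k SNPs
    if tail(lo) <= model.alpha:
        return lo
    hi = lo
    while tail(hi) > model.alpha:
        hi *= 2
        if hi > 10**12:
            raise RuntimeError("threshold search diverged; p too small?")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if tail(mid) <= model.alpha:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# scan


def _candidate_intervals(
    pos: np.ndarray, chrom_len: int, model: DesertModel, thresholds: dict[int, int]
) -> list[tuple[int, int]]:
    """Raw (pre-merge) desert intervals on one chromosome, 1-based closed.

    Interior/5' candidates: intervals strictly between SNP i and SNP i+k
    (chromosome start acting as a virtual boundary at position 0), which
    contain exactly k - 1 SNPs; deserts when their interior length exceeds
    L_k. 3' tail: for an anchor with j < k SNPs remaining (j >= 1), the
    interval to the last SNP contains j - 1 of them and is a desert when its
    interior length exceeds L_j.
    """
    m = len(pos)
    k = model.k
    out: list[tuple[int, int]] = []
    bounds = np.concatenate(([0], pos))  # virtual boundary at chromosome start
    # interior + 5' candidates: need at least k SNPs downstream of the anchor
    for i in range(0, m - k + 1):
        left = bounds[i]
        right = pos[i + k - 1]  # the k-th SNP after the anchor
        length = right - left - 1
        if length > thresholds[k]:
            out.append((int(left) + 1, int(right) - 1))
    # 3' tail: anchors with 1 <= j < k SNPs remaining; interval to the last SNP
    for j in range(1, min(k, m + 1)):
        i = m - j  # anchor index into bounds (0 = chromosome start)
        left = bounds[i]
        right = pos[m - 1]
        length = right - left - 1
        if length > thresholds[j]:
            out.append((int(left) + 1, int(right) - 1))
    return [iv for iv in out if iv[1] >= iv[0]]


def merge_intervals(
    intervals: list[tuple[int, int]], merge_gap: int
) -> list[tuple[int, int]]:
    """Merge intervals that overlap or are separated by <= merge_gap bp,
    iterated to a fixpoint (1-based closed coordinates)."""
    merged = sorted(intervals)
    while True:
        out: list[list[int]] = []
        for s, e in merged:
            if out and s - out[-1][1] - 1 <= merge_gap:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        new = [(s, e) for s, e in out]
        if new == merged:
            return new
        merged = new


def find_deserts(
    snp_positions: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    model: DesertModel,
) -> pd.DataFrame:
    """Scan every chromosome for SNP deserts.

    ``snp_positions`` maps chromosome name to sorted 1-based SNP positions.
    Returns one row per merged desert with 1-based closed start/end, length,
    SNP count n, density p = n/L and sigma = sqrt(p (1 - p) / L).
    """
    thresholds = {j: desert_threshold(model, k=j) for j in range(1, model.k + 1)}
    max_len = max(chrom_lengths.values()) if chrom_lengths else 0
    if thresholds[model.k] >= max_len:
        warnings.warn(
            "desert threshold exceeds the longest chromosome; no desert can be called",
            stacklevel=2,
        )
    rows = []
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(snp_positions.get(chrom, np.array([], dtype=np.int64)))
        if len(pos) and np.any(np.diff(pos) < 0):
            warnings.warn(f"unsorted SNP positions on {chrom}; sorting", stacklevel=2)
            pos = np.sort(pos)
        cands = _candidate_intervals(pos, length, model, thresholds)
        for start, end in merge_intervals(cands, model.merge_gap):
            n = int(((pos >= start) & (pos <= end)).sum())
            L = end - start + 1
            dens, lo, hi = desert_density(n, L)
            rows.append((chrom, start, end, L, n, dens, lo, hi))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "length", "n_snps", "density", "lo2sig", "hi2sig"],
    )


def desert_density(n: int, L: int) -> tuple[float, float, float]:
    """SNP density of a region with n SNPs in L bp, with a +-2 sigma band:
    p = n/L, sigma = sqrt(p (1 - p) / L)."""
    if L <= 0:
        raise ValueError("region length must be positive")
    if n > L:
        raise ValueError("more SNPs than base pairs")
    p = n / L
    sigma = float(np.sqrt(p * (1 - p) / L))
    return p, p - 2 * sigma, p + 2 * sigma


# ---------------------------------------------------------------------------
# cross-isolate comparisons


def shared_boundaries(
    desert_tables: dict[str, pd.DataFrame], tol_bp: int = 0
) -> pd.DataFrame:
    """Cluster desert boundaries across isolates.

    Two deserts from different isolates share a left (right) boundary when
    their starts (ends) agree within ``tol_bp``. Returns one row per
    boundary cluster: chrom, side, representative coordinate, number of
    isolates sharing it and their names.
    """
    if len(desert_tables) < 2:
        raise ValueError("need deserts from at least two isolates")
    rows = []
    for side, col in (("left", "start"), ("right", "end")):
        points: list[tuple[str, int, str]] = []  # (chrom, coord, isolate)
        for iso, table in desert_tables.items():
            for _, r in table.iterrows():
                points.append((r["chrom"], int(r[col]), iso))
        points.sort()
        cluster: list[tuple[str, int, str]] = []
        for pt in points + [("\x7f", -1, "")]:  # sentinel flush
            if cluster and (pt[0] != cluster[0][0] or pt[1] - cluster[-1][1] > tol_bp):
                isolates = sorted({iso for _, _, iso in cluster})
                rows.append(
                    (cluster[0][0], side, cluster[0][1], len(isolates), ",".join(isolates))
                )
                cluster = []
            if pt[1] >= 0:
                cluster.append(pt)
    return pd.DataFrame(rows, columns=["chrom", "side", "coord", "n_isolates", "isolates"])


def desert_age_profile(
    deserts: pd.DataFrame,
    snp_positions: dict[str, np.ndarray],
    chrom_lengths: dict[str, int],
    min_length: int = 50_000,
) -> tuple[pd.DataFrame, float, float]:
    """Relative-age profile of long deserts.

    Under uniform mutation accumulation since a SNP-free origin, older
    deserts carry proportionally more SNPs per bp; simultaneous origin
    predicts homogeneous densities. For each desert of at least
    ``min_length`` bp the function reports its SNP density with a 2-sigma
    band alongside the density of the flanking (non-desert) sequence, a
    chi-square homogeneity test across desert densities, and the
    fold-depletion of deserts relative to flanks (flank density / pooled
    desert density).
    """
    long = deserts[deserts["length"] >= min_length]
    rows = []
    flank_snps = 0
    flank_len = 0
    for chrom, length in chrom_lengths.items():
        pos = np.asarray(snp_positions.get(chrom, np.array([], dtype=np.int64)))
        in_desert = np.zeros(len(pos), dtype=bool)
        desert_span = 0
        for _, r in deserts[deserts["chrom"] == chrom].iterrows():
            in_desert |= (pos >= r["start"]) & (pos <= r["end"])
            desert_span += int(r["length"])
        flank_snps += int((~in_desert).sum())
        flank_len += length - desert_span
    for _, r in long.iterrows():
        p, lo, hi = desert_density(int(r["n_snps"]), int(r["length"]))
        rows.append((r["chrom"], int(r["start"]), int(r["end"]), int(r["length"]),
                     int(r["n_snps"]), p, lo, hi))
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length", "n_snps", "density", "lo2sig", "hi2sig"]
    )
    # chi-square homogeneity: SNP counts vs expectation under one shared rate
    if len(table) >= 2 and table["n_snps"].sum() > 0:
        rate = table["n_snps"].sum() / table["length"].sum()
        expected = rate * table["length"].to_numpy(dtype=float)
        chi2 = float(((table["n_snps"] - expected) ** 2 / expected).sum())
        p_hom = float(stats.chi2.sf(chi2, df=len(table) - 1))
    else:
        p_hom = float("nan")
    if flank_len > 0 and table["length"].sum() > 0 and table["n_snps"].sum() > 0:
        fold = (flank_snps / flank_len) / (table["n_snps"].sum() / table["length"].sum())
    else:
        fold = float("nan")
    return table, p_hom, fold


def fold_depletion(genome_snps: int, genome_length: int, region_snps: int, region_length: int) -> float:
    """Expected over observed SNPs in a region at the genome-wide density."""
    expected = genome_snps / genome_length * region_length
    if region_snps == 0:
        return float("inf")
    return expected / region_snps
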