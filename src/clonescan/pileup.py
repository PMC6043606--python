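"""Per-position R statistic and genotype-class diagnostics.

For each genome position, let ``rc`` be the number of aligned reads carrying
the reference nucleotide and ``nc`` the number carrying the most common
non-reference nucleotide. The allele-balance statistic

    R = nc / (nc + rc)

sits near 0 at homozygous-reference positions, near 0.5 at heterozygous
positions of a diploid, and near 1 at positions homozygous for a
non-reference allele. Ignoring all but the most common non-reference base
strips most technical sequencing error out of the statistic.

The module classifies positions into those three modes, tests the
Hardy-Weinberg 2:1 het : hom-nonref expectation, checks that an isolate is a
single genotype (a mixture of two genotypes splits the het mode into ~0.25
and ~0.75 components), and derives coverage-based quantities: relative copy
number of a region (e.g. rDNA arrays) and hemizygous intervals where one
homologous copy is deleted (half depth, no het calls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BASE_COLS = ["A", "C", "G", "T"]


# ---------------------------------------------------------------------------
# R computation


def compute_R(counts: pd.DataFrame, ambiguity_frac: float = 0.2) -> pd.DataFrame:
    """R track from a per-position read-count table.

    ``counts`` needs columns chrom, pos, ref_count and A/C/G/T non-reference
    counts. Returns a DataFrame with R, depth (= rc + nc), nc, rc, and an
    ``ambiguous`` flag set where the second most common non-reference base
    count exceeds max(1, ambiguity_frac x nc) — multiple non-reference
    alleles at one position most likely reflect technical error.
    Depth-0 positions get R = NaN.
    """
    nonref = counts[BASE_COLS].to_numpy(dtype=np.int64)
    if (nonref < 0).any() or (counts["ref_count"].to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    order = np.sort(nonref, axis=1)
    nc = order[:, -1]
    second = order[:, -2]
    rc = counts["ref_count"].to_numpy(dtype=np.int64)
    depth = rc + nc
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.where(depth > 0, nc / np.maximum(depth, 1), np.nan)
    ambiguous = second > np.maximum(1, ambiguity_frac * nc)
    return pd.DataFrame(
        {
            "chrom": counts["chrom"].to_numpy(),
            "pos": counts["pos"].to_numpy(),
            "rc": rc,
            "nc": nc,
            "depth": depth,
            "R": R,
            "ambiguous": ambiguous,
        }
    )


def coverage_bounds(
    track: pd.DataFrame, lo_factor: float = 0.25, hi_factor: float = 2.0
) -> tuple[float, float]:
    """Depth bounds for 'extreme read coverage' exclusion, as multiples of
    the genome-wide median depth (defaults 0.25x and 2x)."""
    med = float(track["depth"].median())
    return lo_factor * med, hi_factor * med


def classify_positions(
    track: pd.DataFrame,
    cov_lo: float,
    cov_hi: float,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> pd.DataFrame:
    """Assign each position a genotype class from its R value.

    hom-ref if R < het_band[0]; het inside the band (inclusive); hom-nonref
    above it; ``excluded`` where depth falls outside [cov_lo, cov_hi] or R is
    undefined; ``ambiguous`` flags carry through as their own class.
    Returns the track with a ``gt_class`` column.
    """
    if not cov_lo < cov_hi:
        raise ValueError("cov_lo must be < cov_hi")
    lo, hi = het_band
    R = track["R"].to_numpy()
    depth = track["depth"].to_numpy()
    cls = np.full(len(track), "hom-ref", dtype=object)
    cls[(R >= lo) & (R <= hi)] = "het"
    cls[R > hi] = "hom-nonref"
    cls[track["ambiguous"].to_numpy()] = "ambiguous"
    cls[(depth < cov_lo) | (depth > cov_hi) | np.isnan(R)] = "excluded"
    out = track.copy()
    out["gt_class"] = cls
    return out


def class_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = classified["gt_class"].value_counts().to_dict()
    for key in ("hom-ref", "het", "hom-nonref", "ambiguous", "excluded"):
        counts.setdefault(key, 0)
    return {k: int(v) for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Hardy-Weinberg 2:1 diagnostic


@dataclass(frozen=True)
class HweRatioResult:
    n_het: int
    n_homnonref: int
    ratio: float
    p_value: float


def hwe_ratio_test(n_het: int, n_homnonref: int) -> HweRatioResult:
    """Two-sided binomial test of the HWE expectation het : hom-nonref = 2 : 1.

    Under random mating against a random-haplotype reference, a site
    contributes het with probability 2pq and hom-nonref with probability pq,
    so among het + hom-nonref sites the het fraction is 2/3 regardless of
    the allele-frequency spectrum.
    """
    n = n_het + n_homnonref
    if n <= 0:
        raise ValueError("need at least one het or hom-nonref site")
    ratio = n_het / n_homnonref if n_homnonref > 0 else float("inf")
    p = stats.binomtest(n_het, n, 2 / 3, alternative="two-sided").pvalue
    return HweRatioResult(n_het, n_homnonref, ratio, float(p))


# ---------------------------------------------------------------------------
# single-genotype check


def estimate_mapping_bias(het_R: np.ndarray) -> float:
    """Mapping bias b from the centre m of the het-range R distribution via
    m = b / (1 + b); an unbiased library returns ~1.

    The median is used as the centre: at realistic depths R is a coarse
    lattice (multiples of 1/depth) and a histogram mode is unstable.
    """
    het_R = het_R[~np.isnan(het_R)]
    m = float(np.median(het_R))
    m = min(max(m, 1e-3), 1 - 1e-3)
    return m / (1.0 - m)


def correct_bias(R: np.ndarray, bias: float) -> np.ndarray:
    """Invert the mapping-bias distortion r = b f / (b f + 1 - f) of the true
    non-reference fraction f: f = r / (b + r - b r)."""
    return R / (bias + R - bias * R)


@dataclass(frozen=True)
class SingleGenotypeResult:
    verdict: str  # "single" | "mixed" | "indeterminate"
    mean_R: float
    std_R: float
    bias: float
    n_modes: int


def single_genotype_check(
    het_R: np.ndarray,
    bias_correct: bool = True,
    mean_tol: float = 0.05,
    min_sites: int = 100,
) -> SingleGenotypeResult:
    """Verdict on whether an isolate's reads come from one genotype.

    A 50:50 mixture of two genotypes turns sites het in only one of them
    into R modes near 0.25 and 0.75, and shifts the mean away from 0.5. The
    check requires the (bias-corrected) mean of het-range R values to sit
    within ``mean_tol`` of 0.5 and the het-range histogram to be unimodal.
    """
    het_R = np.asarray(het_R, dtype=float)
    het_R = het_R[~np.isnan(het_R)]
    if len(het_R) < min_sites:
        return SingleGenotypeResult("indeterminate", float("nan"), float("nan"), 1.0, 0)
    bias = estimate_mapping_bias(het_R) if bias_correct else 1.0
    corrected = correct_bias(het_R, bias)
    mean = float(corrected.mean())
    std = float(corrected.std())
    n_modes = _count_modes(corrected)
    single = abs(mean - 0.5) <= mean_tol and n_modes <= 1
    return SingleGenotypeResult("single" if single else "mixed", mean, std, bias, n_modes)


def _count_modes(values: np.ndarray, bins: int = 30, rel_height: float = 0.4) -> int:
    """Peaks in a smoothed histogram on (0.1, 0.9): local maxima above
    rel_height x global max, separated by a dip below half the lower peak."""
    hist, _ = np.histogram(values, bins=bins, range=(0.1, 0.9))
    smooth = np.convolve(hist, np.ones(3) / 3, mode="same")
    floor = rel_height * smooth.max()
    peaks = [
        i
        for i in range(1, bins - 1)
        if smooth[i] >= floor and smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
    ]
    # merge contiguous/plateau peaks, then require a genuine dip between them
    modes: list[int] = []
    for i in peaks:
        if modes and all(
            smooth[j] > 0.5 * min(smooth[i], smooth[modes[-1]])
            for j in range(modes[-1], i + 1)
        ):
            if smooth[i] > smooth[modes[-1]]:
                modes[-1] = i
            continue
        modes.append(i)
    return len(modes)


# ---------------------------------------------------------------------------
# coverage-derived quantities


def relative_copy_number(
    region_depths: np.ndarray, genome_depths: np.ndarray
) -> float:
    """Copies per haploid genome of a region: median depth in the region
    divided by the genome-wide median depth (used e.g. for 18S rDNA arrays)."""
    region_depths = np.asarray(region_depths)
    genome_depths = np.asarray(genome_depths)
    if region_depths.size == 0 or genome_depths.size == 0:
        raise ValueError("empty depth track")
    genome_med = float(np.median(genome_depths))
    if genome_med == 0:
        raise ValueError("zero genome-wide median depth")
    return float(np.median(region_depths)) / genome_med


def detect_hemizygous_regions(
    classified: pd.DataFrame,
    window: int = 5_000,
    depth_band: tuple[float, float] = (0.35, 0.65),
    max_het_per_window: int = 0,
) -> pd.DataFrame:
    """Intervals where one homologous copy is deleted.

    Scans non-overlapping windows per chromosome; a window is hemizygous when
    its median depth falls within ``depth_band`` x the genome-wide median and
    it contains no more than ``max_het_per_window`` het calls. Adjacent
    hemizygous windows merge. Returns BED-style rows (chrom, start, end;
    0-based half-open).
    """
    genome_med = float(classified["depth"].median())
    rows: list[tuple[str, int, int]] = []
    for chrom, sub in classified.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        depth = sub["depth"].to_numpy()
        het = (sub["gt_class"] == "het").to_numpy()
        if len(pos) == 0:
            continue
        last = int(pos.max())
        current: list[int] | None = None
        for start in range(1, last + 1, window):
            end = min(start + window, last + 1)
            sel = (pos >= start) & (pos < end)
            if not sel.any():
                flag = False
            else:
                med = float(np.median(depth[sel]))
                flag = (
                    depth_band[0] * genome_med <= med <= depth_band[1] * genome_med
                    and int(het[sel].sum()) <= max_het_per_window
                )
            if flag:
                if current is None:
                    current = [start, end]
                else:
                    current[1] = end
            elif current is not None:
                rows.append((chrom, current[0] - 1, current[1] - 1))
                current = None
        if current is not None:
            rows.append((chrom, current[0] - 1, current[1] - 1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
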