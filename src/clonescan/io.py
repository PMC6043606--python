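"""Readers and writers for the toolkit's on-disk formats.

Pileup count tables and tracks are TSV; genotypes travel as minimal VCF
(read back through cyvcf2); interval outputs are BED (0-based half-open).
Internally all positions are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import HET, HOM_NONREF, HOM_REF, GenotypeTable, ReferenceGenome

PILEUP_COLUMNS = ["chrom", "pos", "ref_base", "ref_count", "A", "C", "G", "T"]

_GT_FIELD = {HOM_REF: "0/0", HET: "0/1", HOM_NONREF: "1/1"}
_GT_CODE = {(0, 0): HOM_REF, (0, 1): HET, (1, 0): HET, (1, 1): HOM_NONREF}


# ---------------------------------------------------------------------------
# TSV


def write_pileup_tsv(pileup: pd.DataFrame, path: str | Path) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup table missing columns: {sorted(missing)}")
    return df


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV (chrom, length) without header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_track_tsv(track: pd.DataFrame, path: str | Path) -> None:
    track.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: pd.DataFrame, path: str | Path, one_based: bool = False) -> None:
    """Write (chrom, start, end[, ...]) intervals as BED. With
    ``one_based=True`` the input is 1-based closed and converted."""
    out = intervals.copy()
    if one_based:
        out["start"] = out["start"] - 1
    cols = ["chrom", "start", "end"] + [c for c in out.columns if c not in ("chrom", "start", "end")]
    out[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df


# ---------------------------------------------------------------------------
# VCF


def write_vcf(
    isolates: Sequence[GenotypeTable],
    ref: ReferenceGenome,
    path: str | Path,
    ref_base: str = "A",
    alt_base: str = "C",
) -> None:
    """Minimal multi-sample VCF of genotype classes.

    Genotype classes carry no base identity, so placeholder REF/ALT bases
    are written; downstream consumers in this toolkit only use coordinates
    and the GT field.
    """
    sites: dict[tuple[str, int], dict[str, int]] = {}
    for iso in isolates:
        for c, p, g in zip(iso.chrom, iso.pos, iso.gt):
            sites.setdefault((c, int(p)), {})[iso.name] = int(g)
    names = [iso.name for iso in isolates]
    chrom_order = {name: i for i, name in enumerate(ref.names)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in ref.chromosomes:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names) + "\n")
        for (chrom, pos), gts in sorted(
            sites.items(), key=lambda kv: (chrom_order.get(kv[0][0], 1 << 30), kv[0][1])
        ):
            fields = [_GT_FIELD[gts.get(n, HOM_REF)] if n in gts else "./." for n in names]
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref_base}\t{alt_base}\t.\tPASS\t.\tGT\t" + "\t".join(fields) + "\n"
            )


def read_vcf(path: str | Path) -> list[GenotypeTable]:
    """Read a VCF into per-sample genotype tables (cyvcf2 backend).

    Missing genotypes are skipped per sample; only SNP records are kept.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    per_sample: list[list[tuple[str, int, int]]] = [[] for _ in names]
    for rec in vcf:
        gts = rec.genotypes  # [allele1, allele2, phased] per sample
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            code = _GT_CODE[(1 if a > 0 else 0, 1 if b > 0 else 0)]
            per_sample[i].append((rec.CHROM, rec.POS, code))
    out = []
    for name, rows in zip(names, per_sample):
        out.append(
            GenotypeTable(
                name=name,
                chrom=np.array([r[0] for r in rows], dtype=object),
                pos=np.array([r[1] for r in rows], dtype=np.int64),
                gt=np.array([r[2] for r in rows], dtype=np.int8),
            )
        )
    return out


def raw_calls_frame(table: GenotypeTable, depth: int = 30, alt_base: str = "C") -> pd.DataFrame:
    """Convert a genotype table's non-reference sites into the raw-call
    DataFrame shape :func:`clonescan.refine.refine_snps` consumes (synthetic
    depth/alt counts implied by the genotype class)."""
    mask = table.gt != HOM_REF
    gt = table.gt[mask]
    alt = np.where(gt == HET, depth // 2, depth)
    return pd.DataFrame(
        {
            "chrom": table.chrom[mask],
            "pos": table.pos[mask],
            "alt": alt_base,
            "genotype": np.where(gt == HET, "het", "hom-nonref"),
            "depth": depth,
            "alt_count": alt,
        }
    )


# ---------------------------------------------------------------------------
# JSON / histograms


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")


def r_histogram(R: Iterable[float], bin_width: float = 0.01) -> pd.DataFrame:
    """Position counts per R bin (fixed width, [0, 1])."""
    values = np.asarray(list(R), dtype=float)
    values = values[~np.isnan(values)]
    nbins = int(round(1.0 / bin_width))
    hist, edges = np.histogram(values, bins=nbins, range=(0.0, 1.0))
    return pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:], "count": hist})
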