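"""Cross-isolate SNP refinement.

A variant caller run independently per isolate misses real heterozygous
sites that sit just under its calling threshold in one isolate while being
confidently called in another. Refinement rescues such positions: wherever a
SNP was called raw in at least one isolate, every other isolate with
sufficient coverage and a sufficient fraction of reads supporting the *same*
alternate allele at that position gains a rescued heterozygous call;
covered isolates without allele support are recorded hom-ref, uncovered
ones as missing. Refinement only ever adds calls — raw calls are never
removed — and is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: genotype-class codes used in the refined matrix
MISSING = "missing"
HOM_REF = "hom-ref"
HET = "het"
HOM_NONREF = "hom-nonref"


@dataclass
class SnpCall:
    """One isolate's call at one (chrom, pos, alt) locus."""

    genotype: str  # het | hom-nonref
    depth: int
    alt_count: int
    provenance: str = "raw"  # raw | rescued


@dataclass
class SnpMatrix:
    """Union of refined SNP loci x isolates.

    ``calls[(chrom, pos, alt)][isolate]`` is a :class:`SnpCall`, or the
    string codes ``hom-ref`` / ``missing``. Multi-allelic positions stay as
    separate (pos, alt) records and are never merged.
    """

    isolates: list[str]
    calls: dict[tuple[str, int, str], dict[str, SnpCall | str]] = field(default_factory=dict)

    def snp_sites(self, isolate: str) -> set[tuple[str, int]]:
        """Positions where the isolate carries a (raw or rescued) SNP call."""
        return {
            (chrom, pos)
            for (chrom, pos, _alt), row in self.calls.items()
            if isinstance(row.get(isolate), SnpCall)
        }

    def genotype_class(self, isolate: str, locus: tuple[str, int, str]) -> str:
        entry = self.calls[locus].get(isolate, MISSING)
        return entry.genotype if isinstance(entry, SnpCall) else entry

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, pos, alt), row in sorted(self.calls.items()):
            rec: dict[str, object] = {"chrom": chrom, "pos": pos, "alt": alt}
            for iso in self.isolates:
                rec[iso] = self.genotype_class(iso, (chrom, pos, alt))
            rows.append(rec)
        return pd.DataFrame(rows)


def _pileup_support(pileup: pd.DataFrame) -> dict[tuple[str, int], dict[str, int]]:
    """Index a pileup table: (chrom, pos) -> per-base read counts + ref count."""
    idx: dict[tuple[str, int], dict[str, int]] = {}
    if pileup is None or len(pileup) == 0:
        return idx
    cols = {c: pileup[c].to_numpy() for c in ("chrom", "pos", "ref_count", "A", "C", "G", "T")}
    for i in range(len(pileup)):
        key = (cols["chrom"][i], int(cols["pos"][i]))
        idx[key] = {
            "ref": int(cols["ref_count"][i]),
            **{b: int(cols[b][i]) for b in "ACGT"},
        }
    return idx


def refine_snps(
    raw_calls: dict[str, pd.DataFrame],
    pileups: dict[str, pd.DataFrame],
    min_depth: int = 10,
    min_alt_frac: float = 0.2,
) -> SnpMatrix:
    """Merge per-isolate raw calls into a refined cross-isolate matrix.

    ``raw_calls[iso]`` is a DataFrame with columns chrom, pos, alt, genotype
    (het/hom-nonref), depth, alt_count. ``pileups[iso]`` provides read
    support at positions the caller skipped (chrom, pos, ref_count, A/C/G/T
    non-reference counts). An uncalled isolate is rescued het at a locus
    when its depth >= min_depth and its reads for the locus's own alt allele
    reach min_alt_frac of depth; otherwise it is hom-ref if covered
    (depth >= min_depth) or missing.
    """
    isolates = list(raw_calls)
    matrix = SnpMatrix(isolates=isolates)
    support = {iso: _pileup_support(pileups[iso]) for iso in isolates if iso in pileups}

    for iso, table in raw_calls.items():
        for _, r in table.iterrows():
            locus = (r["chrom"], int(r["pos"]), str(r["alt"]))
            matrix.calls.setdefault(locus, {})[iso] = SnpCall(
                genotype=str(r["genotype"]),
                depth=int(r["depth"]),
                alt_count=int(r["alt_count"]),
                provenance="raw",
            )

    for locus, row in matrix.calls.items():
        chrom, pos, alt = locus
        for iso in isolates:
            if iso in row:
                continue  # raw call wins; refinement never removes it
            counts = support.get(iso, {}).get((chrom, pos))
            if counts is None:
                row[iso] = MISSING
                continue
            depth = counts["ref"] + counts.get(alt, 0)
            if depth < min_depth:
                row[iso] = MISSING
            elif counts.get(alt, 0) >= min_alt_frac * depth:
                row[iso] = SnpCall(
                    genotype=HET,
                    depth=depth,
                    alt_count=counts.get(alt, 0),
                    provenance="rescued",
                )
            else:
                row[iso] = HOM_REF
    return matrix


def sharing_stats(matrix: SnpMatrix, reference_isolate: str) -> pd.DataFrame:
    """Table-style per-isolate summary: total SNPs, % shared with the
    reference isolate, and private SNP count (SNPs seen in exactly one
    isolate). Loci missing in an isolate are excluded from its denominators.
    """
    if reference_isolate not in matrix.isolates:
        raise ValueError(f"unknown reference isolate {reference_isolate!r}")
    sites = {iso: matrix.snp_sites(iso) for iso in matrix.isolates}
    ref_sites = sites[reference_isolate]
    rows = []
    for iso in matrix.isolates:
        own = sites[iso]
        others = set().union(*(sites[o] for o in matrix.isolates if o != iso)) if len(matrix.isolates) > 1 else set()
        shared_pct = 100.0 * len(own & ref_sites) / len(own) if own else float("nan")
        rows.append((iso, len(own), shared_pct, len(own - others)))
    return pd.DataFrame(rows, columns=["isolate", "n_snps", "shared_with_ref_pct", "private_snps"])
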