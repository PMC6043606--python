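"""SNP-sharing cladogram and divergence-time estimation.

The tree over isolates is built top-down: at each node, every bipartition
(A, B) of the node's isolates is scored

    score(A, B) = S(A) + S(B) - X(A, B)

where S(A) is the number of SNP positions present (heterozygous) in *all*
members of A, and X(A, B) counts positions present in at least one member
of each side but not in all of either — i.e. sharing that the split fails
to explain. The maximum-scoring split is chosen (ties broken by the
lexicographically smallest partition) and recursion continues until leaves.
Internal branch lengths are the number of SNPs shared by every isolate in
the subtree below; terminal branch lengths are private SNP counts.

Divergence times follow a mitotic molecular clock: private heterozygous
SNPs accumulate at ploidy x genome_size x mu per division, one division
every ``division_interval_days`` days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations


@dataclass(frozen=True)
class ClockModel:
    """Mitotic molecular clock for private-SNP divergence dating."""

    mu: float = 1e-9  # mutations per bp per division
    division_interval_days: float = 2.0
    genome_size: float = 32e6
    ploidy: int = 2

    def __post_init__(self) -> None:
        if min(self.mu, self.division_interval_days, self.genome_size, self.ploidy) <= 0:
            raise ValueError("all clock parameters must be positive")


@dataclass
class CladeNode:
    """Node of the SNP-sharing cladogram. ``branch_length`` is the SNP count
    on the branch leading to this node (shared SNPs for internal nodes,
    private SNPs for leaves)."""

    isolates: tuple[str, ...]
    branch_length: int
    children: list["CladeNode"] = field(default_factory=list)
    tie: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf:
            return f"{self.isolates[0]}:{self.branch_length}"
        inner = ",".join(c._newick() for c in self.children)
        return f"({inner}):{self.branch_length}"

    def leaves(self) -> list["CladeNode"]:
        if self.is_leaf:
            return [self]
        return [l for c in self.children for l in c.leaves()]


def sharing_counts(
    snp_sets: dict[str, set[tuple[str, int]]], subset: tuple[str, ...]
) -> int:
    """Number of SNP positions present in every member of ``subset``."""
    if not subset:
        raise ValueError("empty subset")
    it = iter(subset)
    acc = set(snp_sets[next(it)])
    for iso in it:
        acc &= snp_sets[iso]
    return len(acc)


def _cross_sharing(
    snp_sets: dict[str, set[tuple[str, int]]], a: tuple[str, ...], b: tuple[str, ...]
) -> int:
    """X(A, B): positions in >= 1 member of each side but not in all of
    either side — the sharing a split fails to capture."""
    union_a = set().union(*(snp_sets[i] for i in a))
    union_b = set().union(*(snp_sets[i] for i in b))
    inter_a = sharing_set(snp_sets, a)
    inter_b = sharing_set(snp_sets, b)
    return len((union_a & union_b) - inter_a - inter_b)


def sharing_set(
    snp_sets: dict[str, set[tuple[str, int]]], subset: tuple[str, ...]
) -> set[tuple[str, int]]:
    it = iter(subset)
    acc = set(snp_sets[next(it)])
    for iso in it:
        acc &= snp_sets[iso]
    return acc


def _best_split(
    snp_sets: dict[str, set[tuple[str, int]]], members: tuple[str, ...]
) -> tuple[tuple[str, ...], tuple[str, ...], bool]:
    """Exhaustively score all bipartitions of ``members``; lexicographically
    smallest first side wins ties (reported via the flag)."""
    best = None
    best_score = None
    tie = False
    ordered = sorted(members)
    n = len(ordered)
    for r in range(1, n // 2 + 1):
        for combo in combinations(ordered, r):
            a = tuple(combo)
            b = tuple(x for x in ordered if x not in combo)
            if r == n - r and a > b:
                continue  # each unordered bipartition once
            # "sharing" within a side needs at least two members; a singleton
            # contributes nothing (otherwise peeling off the largest SNP set
            # always wins, regardless of structure)
            s_a = sharing_counts(snp_sets, a) if len(a) > 1 else 0
            s_b = sharing_counts(snp_sets, b) if len(b) > 1 else 0
            score = s_a + s_b - _cross_sharing(snp_sets, a, b)
            key = (a, b)
            if best_score is None or score > best_score:
                best, best_score, tie = key, score, False
            elif score == best_score:
                tie = True
                if key < best:
                    best = key
    assert best is not None
    return best[0], best[1], tie


def build_cladogram(snp_sets: dict[str, set[tuple[str, int]]]) -> CladeNode:
    """Recursive maximum-sharing cladogram over the isolates of
    ``snp_sets`` (isolate name -> set of het SNP positions)."""
    if len(snp_sets) < 2:
        raise ValueError("need at least two isolates")
    all_isolates = tuple(sorted(snp_sets))

    def private_count(iso: str) -> int:
        others = set().union(*(snp_sets[o] for o in all_isolates if o != iso))
        return len(snp_sets[iso] - others)

    def grow(members: tuple[str, ...]) -> CladeNode:
        if len(members) == 1:
            return CladeNode(members, branch_length=private_count(members[0]))
        a, b, tie = _best_split(snp_sets, members)
        node = CladeNode(
            members,
            branch_length=sharing_counts(snp_sets, members),
            children=[grow(a), grow(b)],
            tie=tie,
        )
        return node

    return grow(all_isolates)


def divergence_years(private_snps: float, clock: ClockModel) -> float:
    """Years needed to accumulate ``private_snps`` neutral heterozygous
    mutations under the mitotic clock."""
    rate_per_year = (
        clock.ploidy * clock.genome_size * clock.mu * (365.25 / clock.division_interval_days)
    )
    if rate_per_year == 0:
        raise ValueError("zero mutation rate")
    return private_snps / rate_per_year
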