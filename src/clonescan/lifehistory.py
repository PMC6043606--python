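"""Competition between obligate asexual and facultatively sexual lineages.

A minimal discrete-generation model: one generation is one mitotic division
(default every 2 days). Asexual lineages divide every generation. A
facultatively sexual group divides too, except during meiotic episodes:
every ``meiotic_interval`` generations the group pauses for ``meiotic_cost``
generations, at the end of which its members are randomly paired and
recombined at a single tracked locus (offspring genotypes are
Hardy-Weinberg draws from the group's own allele pool) and lose their
mitotic lineage identity. After growth, the population is resampled
multinomially back to the cap N, which supplies genetic drift.

Because meiosis only ever costs divisions here, an obligate asexual gains a
factor 2^d per sexual cycle of its competitors and sweeps to dominance; in
the neutral limit (zero cost, no tracked-locus advantage) lineage
frequencies reduce to Wright-Fisher drift.

The advantageous-Mendelian-recessive scenario models homozygous-recessive
(aa) fitness as a longer time between meiotic events: their interval is
``meiotic_interval x recessive_advantage``. Recombination among the other
lineages reassembles aa on new backgrounds, so the allele can fix while the
original aa lineage's unbroken mitotic descent is displaced — unless that
lineage is an obligate asexual, which keeps its identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ASEXUAL = "asexual"
FACULTATIVE = "facultative"

#: dosage of the recessive allele per genotype
DOSAGE = {"AA": 0, "Aa": 1, "aa": 2}


@dataclass(frozen=True)
class SimConfig:
    """Competition-model parameters.

    pop_cap: population size N the multinomial resampling holds.
    generations: simulated mitotic generations (2 days each by default).
    meiotic_interval: generations between sexual episodes (default 365,
        i.e. sex about every two years).
    meiotic_cost: generations of paused division per episode.
    recessive_advantage: factor (>= 1) multiplying the meiotic interval of
        homozygous-recessive (aa) facultative genotypes.
    initial_focal_freq: starting frequency of the focal lineage.
    division_interval_days: calendar length of one generation.
    """

    pop_cap: int = 10_000
    generations: int = 20_000
    meiotic_interval: int = 365
    meiotic_cost: int = 2
    recessive_advantage: float = 1.0
    initial_focal_freq: float = 0.01
    division_interval_days: float = 2.0

    def __post_init__(self) -> None:
        if self.pop_cap <= 0 or self.meiotic_interval < 1:
            raise ValueError("pop_cap must be > 0 and meiotic_interval >= 1")
        if self.meiotic_cost < 0 or self.recessive_advantage < 1:
            raise ValueError("meiotic_cost >= 0 and recessive_advantage >= 1 required")


@dataclass
class Trajectory:
    """Per-generation state of one replicate."""

    focal_freq: np.ndarray  # frequency of the focal lineage
    allele_freq: np.ndarray  # frequency of the recessive allele
    fixation_generation: int | None  # focal lineage at frequency 1
    lost_generation: int | None  # focal lineage extinct
    events: list[str] = field(default_factory=list)

    @property
    def censored(self) -> bool:
        return self.fixation_generation is None and self.lost_generation is None

    def fixation_years(self, division_interval_days: float) -> float | None:
        if self.fixation_generation is None:
            return None
        return self.fixation_generation * division_interval_days / 365.25


# ---------------------------------------------------------------------------
# engine

Class = tuple[str, str, str]  # (strategy, genotype, lineage)


def _interval(genotype: str, cfg: SimConfig) -> int:
    t = cfg.meiotic_interval
    if genotype == "aa" and cfg.recessive_advantage > 1:
        t = int(round(t * cfg.recessive_advantage))
    return max(1, t)


def _recombine_group(
    counts: dict[Class, int], genotypes: list[str], rng: np.random.Generator
) -> None:
    """Replace all facultative members of the given genotype groups with
    random-mating offspring drawn from their pooled alleles."""
    members = {
        c: n for c, n in counts.items() if c[0] == FACULTATIVE and c[1] in genotypes
    }
    total = sum(members.values())
    if total == 0:
        return
    dosage = sum(DOSAGE[c[1]] * n for c, n in members.items())
    q = dosage / (2 * total)
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    offspring = rng.multinomial(total, probs)
    for c in members:
        del counts[c]
    for gt, n in zip(("AA", "Aa", "aa"), offspring):
        if n:
            key = (FACULTATIVE, gt, "recombined")
            counts[key] = counts.get(key, 0) + int(n)


def run_competition(
    cfg: SimConfig,
    seed: int,
    focal_strategy: str = ASEXUAL,
    focal_genotype: str = "AA",
    background_genotype_freq: float = 0.0,
) -> Trajectory:
    """One replicate of the lineage-competition model.

    The focal lineage (default: an obligate asexual clone with a neutral
    genotype) starts at ``initial_focal_freq`` inside a facultatively sexual
    background whose recessive-allele frequency is
    ``background_genotype_freq``. Returns the focal lineage's frequency
    trajectory, the allele trajectory, and fixation/extinction events.
    """
    rng = np.random.default_rng(seed)
    n_focal = max(1, int(round(cfg.initial_focal_freq * cfg.pop_cap)))
    n_back = cfg.pop_cap - n_focal
    q = background_genotype_freq
    back = rng.multinomial(n_back, [(1 - q) ** 2, 2 * q * (1 - q), q**2])
    counts: dict[Class, int] = {}
    for gt, n in zip(("AA", "Aa", "aa"), back):
        if n:
            counts[(FACULTATIVE, gt, "background")] = int(n)
    counts[(focal_strategy, focal_genotype, "focal")] = n_focal

    phase: dict[str, int] = {}
    pause: dict[str, int] = {}
    focal_freq = np.empty(cfg.generations + 1)
    allele_freq = np.empty(cfg.generations + 1)
    events: list[str] = []
    fixation = lost = None

    def record(t: int) -> None:
        total = sum(counts.values())
        focal = sum(n for c, n in counts.items() if c[2] == "focal")
        dosage = sum(DOSAGE[c[1]] * n for c, n in counts.items())
        focal_freq[t] = focal / total
        allele_freq[t] = dosage / (2 * total)

    record(0)
    for t in range(1, cfg.generations + 1):
        # meiotic clocks per facultative genotype group
        active_groups = {c[1] for c in counts if c[0] == FACULTATIVE}
        paused: set[str] = set()
        for g in sorted(active_groups):
            if pause.get(g, 0) > 0:
                pause[g] -= 1
                if pause[g] == 0:
                    _recombine_group(counts, [g], rng)
                    events.append(f"gen {t}: group {g} recombined")
                else:
                    paused.add(g)
                continue
            phase[g] = phase.get(g, 0) + 1
            if phase[g] >= _interval(g, cfg):
                phase[g] = 0
                if cfg.meiotic_cost == 0:
                    _recombine_group(counts, [g], rng)
                    events.append(f"gen {t}: group {g} recombined (costless)")
                else:
                    pause[g] = cfg.meiotic_cost
                    paused.add(g)

        # division: everyone doubles except paused facultative groups
        grown = {
            c: (n if c[0] == FACULTATIVE and c[1] in paused else 2 * n)
            for c, n in counts.items()
        }
        total = sum(grown.values())
        keys = list(grown)
        probs = np.array([grown[k] for k in keys], dtype=float) / total
        sampled = rng.multinomial(cfg.pop_cap, probs)
        counts = {k: int(n) for k, n in zip(keys, sampled) if n > 0}

        record(t)
        if lost is None and focal_freq[t] == 0.0:
            lost = t
            events.append(f"gen {t}: focal lineage extinct")
        if fixation is None and focal_freq[t] == 1.0:
            fixation = t
            events.append(f"gen {t}: focal lineage fixed")
        if fixation is not None or lost is not None:
            focal_freq = focal_freq[: t + 1]
            allele_freq = allele_freq[: t + 1]
            break

    return Trajectory(focal_freq, allele_freq, fixation, lost, events)


def recessive_reassembly(cfg: SimConfig, seed: int, obligate_focal: bool = False,
                         background_allele_freq: float = 0.1) -> Trajectory:
    """Advantageous-recessive scenario.

    The focal lineage is homozygous recessive (aa); its meiotic interval is
    stretched by ``recessive_advantage`` (obligate variant: no meiosis at
    all). The background carries the allele at ``background_allele_freq``,
    so recombination among background lineages can reassemble aa on new
    backgrounds. The returned trajectory separates the allele's fate
    (``allele_freq``) from the focal lineage's (``focal_freq``).
    """
    if cfg.recessive_advantage <= 1 and not obligate_focal:
        pass  # neutral limit is allowed; focal then has no advantage
    return run_competition(
        cfg,
        seed,
        focal_strategy=ASEXUAL if obligate_focal else FACULTATIVE,
        focal_genotype="aa",
        background_genotype_freq=background_allele_freq,
    )


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class Summary:
    n_replicates: int
    n_fixed: int
    n_lost: int
    n_censored: int
    fixation_probability: float
    fixation_probability_ci: tuple[float, float]
    median_fixation_generations: float | None
    median_fixation_years: float | None
    median_fixation_ci_generations: tuple[float, float] | None


def summarize(
    trajectories: list[Trajectory],
    division_interval_days: float = 2.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> Summary:
    """Fixation probability and median fixation time with bootstrap CIs.

    Censored replicates (neither fixed nor lost within the horizon) are
    counted separately and excluded from the fixation-time median.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    rng = np.random.default_rng(seed)
    fixed = np.array([t.fixation_generation is not None for t in trajectories])
    lost = np.array([t.lost_generation is not None for t in trajectories])
    censored = ~fixed & ~lost
    times = np.array(
        [t.fixation_generation for t in trajectories if t.fixation_generation is not None],
        dtype=float,
    )
    n = len(trajectories)
    p_fix = fixed.mean()
    boot_p = rng.binomial(n, p_fix, size=n_boot) / n if n else np.array([0.0])
    p_ci = (float(np.quantile(boot_p, 0.025)), float(np.quantile(boot_p, 0.975)))
    if len(times):
        boot_med = np.median(
            times[rng.integers(0, len(times), size=(n_boot, len(times)))], axis=1
        )
        med = float(np.median(times))
        med_ci = (float(np.quantile(boot_med, 0.025)), float(np.quantile(boot_med, 0.975)))
        med_years = med * division_interval_days / 365.25
    else:
        med = med_years = med_ci = None
    return Summary(
        n_replicates=n,
        n_fixed=int(fixed.sum()),
        n_lost=int(lost.sum()),
        n_censored=int(censored.sum()),
        fixation_probability=float(p_fix),
        fixation_probability_ci=p_ci,
        median_fixation_generations=med,
        median_fixation_years=med_years,
        median_fixation_ci_generations=med_ci,
    )
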