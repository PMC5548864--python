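"""Inheritable bi-objective combinatorial GA for joint feature/hyperparameter search.

The optimizer evolves chromosomes that encode a feature subset (n binary
genes, exactly r of them set) together with three 4-bit genes for the nu-SVR
hyperparameters (gamma, C, nu). Fitness is the Pearson correlation of
10-fold CV between true and estimated survival time, with one fixed fold
partition per run so that fitness is deterministic and elitism is monotone.

The "inheritable" part: the subset-size problem C(n, r) is solved for
r = r_start .. r_end in a single run. After finishing size r, every
individual inherits its genes and flips one random 0 -> 1, seeding the
search at size r+1 with good size-r material. The final answer is the best
solution over all sizes (ties broken toward the smallest subset).

Recombination is the orthogonal-array ("intelligent") crossover: positions
where the two parents differ are grouped into a few factors, an OA
experiment evaluates a small set of candidate children, per-factor main
effects pick the predicted-best level for each factor, and the child is the
better of the predicted-best composite and the best candidate actually
evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .errors import ConfigError, SchemaError, UndefinedCorrelationError
from .oa import build_oa, main_effects
from .regression import CVResult, Hyperparams, cross_validate, kfold_indices

logger = logging.getLogger(__name__)

N_HYPER_GENES = 3
GENE_LEVELS = 16  # 4-bit genes


def decode_hyper(genes) -> Hyperparams:
    """Decode the three 4-bit genes to (gamma, C, nu).

    gamma = 2^(g1-15)  (grid 2^-15 .. 2^0)
    C     = 2^(g2-5)   (grid 2^-5 .. 2^10)
    nu    = (g3+1)/16  (grid 1/16 .. 1)
    """
    genes = tuple(int(g) for g in genes)
    if len(genes) != N_HYPER_GENES or any(not 0 <= g < GENE_LEVELS for g in genes):
        raise ConfigError(f"hyper genes must be three integers in 0..15, got {genes}")
    return Hyperparams(gamma=2.0 ** (genes[0] - 15), C=2.0 ** (genes[1] - 5),
                       nu=(genes[2] + 1) / 16.0)


@dataclass
class Chromosome:
    """GA search point: feature bit-vector plus three 4-bit hyper genes."""

    feature_bits: np.ndarray  # uint8, length n
    hyper_genes: tuple[int, int, int]

    def key(self) -> tuple[bytes, tuple[int, int, int]]:
        return (self.feature_bits.tobytes(), self.hyper_genes)

    def copy(self) -> "Chromosome":
        return Chromosome(self.feature_bits.copy(), self.hyper_genes)

    @property
    def popcount(self) -> int:
        return int(self.feature_bits.sum())


@dataclass
class GAConfig:
    """IBCGA settings.

    Defaults follow the conventional settings of the intelligent-EA lineage
    this optimizer derives from (population 50, crossover 0.8, mutation 0.05,
    60 generations, subset sweep 5..30); all are overridable and small
    configurations are routine for benchmarks.
    """

    n_pop: int = 50
    p_c: float = 0.8
    p_m: float = 0.05
    g_max: int = 60
    r_start: int = 5
    r_end: int = 30
    cv_seed: int = 0
    ga_seed: int = 0
    k_folds: int = 10
    fixed_hyper_genes: tuple[int, int, int] | None = None
    max_oa_factors: int = 7  # caps OA size at 8 fitness calls per crossover

    def __post_init__(self) -> None:
        if self.n_pop < 4 or self.n_pop % 2:
            raise ConfigError("n_pop must be an even integer >= 4")
        if not (0 <= self.p_c <= 1 and 0 <= self.p_m <= 1):
            raise ConfigError("p_c and p_m must lie in [0, 1]")
        if not (1 <= self.r_start <= self.r_end):
            raise ConfigError("need 1 <= r_start <= r_end")


@dataclass
class SignatureResult:
    """Outcome of one IBCGA run."""

    selected_features: list[str]
    hyperparams: Hyperparams
    fitness: float  # CV Pearson CC
    mae: float  # CV mean absolute error, months
    per_r_trace: dict[int, float]  # best fitness reached at each subset size
    generation_trace: dict[int, list[float]] = field(default_factory=dict)
    cv_seed: int = 0
    ga_seed: int = 0
    hyper_genes: tuple[int, int, int] = (0, 0, 0)

    @property
    def m(self) -> int:
        return len(self.selected_features)


def repair(bits: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Force popcount(bits) == r by flipping uniformly chosen excess/deficit bits."""
    if r > len(bits):
        raise ConfigError(f"target popcount {r} exceeds length {len(bits)}")
    bits = bits.copy()
    count = int(bits.sum())
    if count > r:
        ones = np.flatnonzero(bits)
        drop = rng.choice(ones, size=count - r, replace=False)
        bits[drop] = 0
    elif count < r:
        zeros = np.flatnonzero(bits == 0)
        add = rng.choice(zeros, size=r - count, replace=False)
        bits[add] = 1
    return bits


def mutate(c: Chromosome, rng: np.random.Generator,
           fixed_hyper: bool = False) -> Chromosome:
    """Popcount-preserving mutation.

    Swaps one uniformly chosen selected bit with one unselected bit and,
    with probability 0.5, re-randomizes one 4-bit hyper gene. When every bit
    is set there is no swap partner and the feature genes stay untouched.
    """
    out = c.copy()
    ones = np.flatnonzero(out.feature_bits)
    zeros = np.flatnonzero(out.feature_bits == 0)
    if len(ones) and len(zeros):
        out.feature_bits[rng.choice(ones)] = 0
        out.feature_bits[rng.choice(zeros)] = 1
    if not fixed_hyper and rng.random() < 0.5:
        genes = list(out.hyper_genes)
        genes[rng.integers(N_HYPER_GENES)] = int(rng.integers(GENE_LEVELS))
        out.hyper_genes = tuple(genes)
    return out


def _contiguous_groups(positions: np.ndarray, k: int) -> list[np.ndarray]:
    """Partition differing positions (in index order) into k contiguous groups."""
    return [g for g in np.array_split(positions, k) if len(g)]


def oa_crossover(a: Chromosome, b: Chromosome, fitness, rng: np.random.Generator,
                 target_popcount: int | None = None,
                 max_factors: int = 7) -> Chromosome:
    """Orthogonal-array (intelligent) crossover.

    Positions where the parents differ are grouped into at most
    ``max_factors`` contiguous factors (differing hyper genes form one extra
    factor). An OA experiment evaluates N <= 8 candidate children — factor at
    level 1 takes parent ``a``'s genes, level 2 takes ``b``'s — and the
    per-factor main effects predict the best level of each factor. The
    returned child is the fitter of the predicted-best composite and the
    best candidate actually evaluated, then repaired to ``target_popcount``
    bits if requested (pass ``None`` to skip repair).

    ``fitness`` is any callable Chromosome -> float (larger is better).
    """
    if len(a.feature_bits) != len(b.feature_bits):
        raise SchemaError("parents have different lengths")
    if a.popcount != b.popcount:
        raise SchemaError(f"parent popcounts differ: {a.popcount} vs {b.popcount}")

    diff = np.flatnonzero(a.feature_bits != b.feature_bits)
    hyper_differ = a.hyper_genes != b.hyper_genes
    if len(diff) == 0 and not hyper_differ:
        return a.copy()

    max_feature_factors = max_factors - (1 if hyper_differ else 0)
    groups = _contiguous_groups(diff, min(len(diff), max_feature_factors)) if len(diff) else []
    k = len(groups) + (1 if hyper_differ else 0)

    def compose(levels) -> Chromosome:
        child = a.copy()
        for g, lv in zip(groups, levels[: len(groups)]):
            if lv == 2:
                child.feature_bits[g] = b.feature_bits[g]
        if hyper_differ and levels[-1] == 2:
            child.hyper_genes = b.hyper_genes
        return child

    if k == 0:  # pragma: no cover - guarded by the early return above
        return a.copy()

    oa = build_oa(k)
    candidates = [compose(row) for row in oa.levels]
    responses = np.array([fitness(c) for c in candidates])
    finite = np.isfinite(responses)
    if not finite.any():
        return a.copy()
    # infeasible candidates (e.g. empty subsets scoring -inf) enter the
    # effect estimate as slightly-worse-than-worst so levels avoid them
    clipped = np.where(finite, responses, responses[finite].min() - 1.0)
    effects = main_effects(oa, clipped)
    best_levels = np.where(effects.level_means[:, 0] >= effects.level_means[:, 1], 1, 2)
    composite = compose(best_levels)

    best_row = int(np.argmax(responses))
    child = composite if fitness(composite) >= responses[best_row] else candidates[best_row]
    child = child.copy()
    if target_popcount is not None and child.popcount != target_popcount:
        child.feature_bits = repair(child.feature_bits, target_popcount, rng)
    return child


class _FitnessCache:
    """Memoized CV fitness over chromosomes; keyed by (feature bits, hyper genes)."""

    def __init__(self, cohort: Cohort, folds, fixed_genes=None):
        self.cohort = cohort
        self.folds = folds
        self.fixed_genes = fixed_genes
        self.cache: dict = {}
        self.evaluations = 0

    def genes_of(self, c: Chromosome):
        return self.fixed_genes if self.fixed_genes is not None else c.hyper_genes

    def cv_result(self, c: Chromosome) -> CVResult | None:
        sel = np.flatnonzero(c.feature_bits)
        if len(sel) == 0:
            return None
        h = decode_hyper(self.genes_of(c))
        return cross_validate(self.cohort.X[:, sel], self.cohort.y, h, folds=self.folds)

    def __call__(self, c: Chromosome) -> float:
        key = (c.feature_bits.tobytes(), self.genes_of(c))
        if key in self.cache:
            return self.cache[key]
        self.evaluations += 1
        try:
            res = self.cv_result(c)
            fit = -np.inf if res is None else res.cc
        except UndefinedCorrelationError:
            fit = -np.inf  # constant predictions carry no ranking information
        self.cache[key] = fit
        return fit


def _random_chromosome(n: int, r: int, rng: np.random.Generator,
                       fixed_genes=None) -> Chromosome:
    bits = np.zeros(n, dtype=np.uint8)
    bits[rng.choice(n, size=r, replace=False)] = 1
    genes = fixed_genes if fixed_genes is not None else tuple(
        int(g) for g in rng.integers(GENE_LEVELS, size=N_HYPER_GENES))
    return Chromosome(bits, genes)


def run_ibcga(cohort: Cohort, cfg: GAConfig) -> SignatureResult:
    """Run the inheritable GA sweep and return the best signature found.

    Deterministic given the cohort and ``(cfg.cv_seed, cfg.ga_seed)``.
    """
    n = cohort.n
    if cfg.r_end > n:
        raise ConfigError(f"r_end={cfg.r_end} exceeds feature count {n}")
    rng = np.random.default_rng(cfg.ga_seed)
    folds = kfold_indices(cohort.M, cfg.k_folds, cfg.cv_seed)
    fitness = _FitnessCache(cohort, folds, cfg.fixed_hyper_genes)

    pop = [_random_chromosome(n, cfg.r_start, rng, cfg.fixed_hyper_genes)
           for _ in range(cfg.n_pop)]
    best_per_r: dict[int, Chromosome] = {}
    per_r_trace: dict[int, float] = {}
    generation_trace: dict[int, list[float]] = {}

    for r in range(cfg.r_start, cfg.r_end + 1):
        gen_best: list[float] = []
        for gen in range(cfg.g_max):
            fits = np.array([fitness(c) for c in pop])
            elite_idx = int(np.argmax(fits))
            elite = pop[elite_idx].copy()
            elite_fit = fits[elite_idx]

            # tournament selection (size 2) into a mating pool
            pool = []
            for _ in range(cfg.n_pop):
                i, j = rng.integers(cfg.n_pop, size=2)
                pool.append(pop[i].copy() if fits[i] >= fits[j] else pop[j].copy())

            # OA crossover on p_c * n_pop parents, paired consecutively;
            # each pair is replaced by (child, fitter parent)
            n_parents = int(cfg.p_c * cfg.n_pop) // 2 * 2
            for i in range(0, n_parents, 2):
                pa, pb = pool[i], pool[i + 1]
                child = oa_crossover(pa, pb, fitness, rng, target_popcount=r,
                                     max_factors=cfg.max_oa_factors)
                keep = pa if fitness(pa) >= fitness(pb) else pb
                pool[i], pool[i + 1] = child, keep

            # mutation on p_m * n_pop individuals, sparing the current best
            pool_fits = [fitness(c) for c in pool]
            protected = int(np.argmax(pool_fits))
            n_mut = int(round(cfg.p_m * cfg.n_pop))
            if n_mut and cfg.n_pop > 1:
                choices = [i for i in range(cfg.n_pop) if i != protected]
                for i in rng.choice(choices, size=min(n_mut, len(choices)), replace=False):
                    pool[i] = mutate(pool[i], rng,
                                     fixed_hyper=cfg.fixed_hyper_genes is not None)

            # elitism: the previous best individual always survives
            pool_fits = [fitness(c) for c in pool]
            if max(pool_fits) < elite_fit:
                pool[int(np.argmin(pool_fits))] = elite
            pop = pool
            gen_best.append(max(elite_fit, max(fitness(c) for c in pop)))

        fits = np.array([fitness(c) for c in pop])
        best = pop[int(np.argmax(fits))].copy()
        best_per_r[r] = best
        per_r_trace[r] = float(np.max(fits))
        generation_trace[r] = gen_best
        logger.info("r=%d best CC=%.4f (%d CV evaluations so far)",
                    r, per_r_trace[r], fitness.evaluations)

        if r < cfg.r_end:
            # inheritance: every individual flips one random 0 -> 1
            for c in pop:
                zeros = np.flatnonzero(c.feature_bits == 0)
                if len(zeros):
                    c.feature_bits[rng.choice(zeros)] = 1

    # best size: maximal fitness, ties toward the smallest subset
    best_r = max(sorted(per_r_trace), key=lambda r: per_r_trace[r])
    for r in sorted(per_r_trace):
        if per_r_trace[r] == per_r_trace[best_r]:
            best_r = r
            break
    winner = best_per_r[best_r]
    genes = fitness.genes_of(winner)
    final = fitness.cv_result(winner)
    sel = np.flatnonzero(winner.feature_bits)
    return SignatureResult(
        selected_features=[cohort.feature_names[i] for i in sel],
        hyperparams=decode_hyper(genes),
        fitness=final.cc,
        mae=final.mae,
        per_r_trace=per_r_trace,
        generation_trace=generation_trace,
        cv_seed=cfg.cv_seed,
        ga_seed=cfg.ga_seed,
        hyper_genes=tuple(genes),
    )
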