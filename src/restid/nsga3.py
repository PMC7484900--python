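"""From-scratch NSGA-III for mixed binary/integer/real chromosomes.

The evolutionary loop follows the reference-point based many-objective NSGA
framework: a parent population of size N produces offspring by tournament
selection, crossover and mutation; parents and offspring are combined,
non-dominated sorted, and the next population is filled front by front.  The
partially admitted last front is resolved by niching against a Das-Dennis set
of reference points on the unit simplex: members are associated with the
nearest reference line after ideal-point translation and intercept
normalization, and slots go to the reference points with the smallest niche
counts, preferring the member closest to an empty niche's line.

Termination: every ``period`` generations the ideal and nadir points of the
first front are compared with those at the previous check; the run stops when
their maximum absolute displacement drops to ``tol`` (default 1e-4, checked
every 10th generation) or after ``max_gen`` generations (default 300).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np


# ---------------------------------------------------------------------------
# Encoding and chromosomes

@dataclass(frozen=True)
class GeneSpec:
    """One non-binary gene: integer (uniform resample) or real (SBX/polynomial)."""
    kind: str            # "int" or "real"
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("int", "real"):
            raise ValueError(f"gene kind must be 'int' or 'real', got {self.kind!r}")
        if not self.low < self.high:
            raise ValueError("gene range must satisfy low < high")


@dataclass(frozen=True)
class Encoding:
    """Chromosome layout: ``n_bits`` binary genes followed by typed genes."""
    n_bits: int = 0
    genes: tuple[GeneSpec, ...] = ()

    @property
    def n_genes(self) -> int:
        return self.n_bits + len(self.genes)


@dataclass
class Chromosome:
    bits: np.ndarray                  # uint8 vector, length encoding.n_bits
    genes: list[float] = field(default_factory=list)

    def copy(self) -> "Chromosome":
        return Chromosome(bits=self.bits.copy(), genes=list(self.genes))

    def key(self) -> tuple:
        return (tuple(int(b) for b in self.bits), tuple(self.genes))


def random_chromosome(encoding: Encoding, rng: np.random.Generator) -> Chromosome:
    bits = rng.integers(0, 2, size=encoding.n_bits).astype(np.uint8)
    genes: list[float] = []
    for g in encoding.genes:
        if g.kind == "int":
            genes.append(float(rng.integers(int(g.low), int(g.high) + 1)))
        else:
            genes.append(float(rng.uniform(g.low, g.high)))
    chrom = Chromosome(bits=bits, genes=genes)
    _repair(chrom, encoding, rng)
    return chrom


def _repair(chrom: Chromosome, encoding: Encoding, rng: np.random.Generator) -> None:
    """Clip genes into range and guarantee at least one set channel bit."""
    for i, g in enumerate(encoding.genes):
        v = min(max(chrom.genes[i], g.low), g.high)
        chrom.genes[i] = float(round(v)) if g.kind == "int" else float(v)
    if encoding.n_bits > 0 and not chrom.bits.any():
        chrom.bits[rng.integers(encoding.n_bits)] = 1


# ---------------------------------------------------------------------------
# Reference points (Das-Dennis systematic simplex lattice)

@dataclass
class ReferencePointSet:
    points: np.ndarray   # (H, M), rows on the unit simplex
    divisions: int


def generate_reference_points(n_objectives: int, divisions: int) -> ReferencePointSet:
    """All points with coordinates in {0, 1/p, ..., 1} summing to 1.

    For M objectives and p divisions this yields C(M+p-1, p) points; with
    M=3, p=1 they are exactly the simplex apexes (1,0,0), (0,1,0), (0,0,1).
    """
    if n_objectives < 2:
        raise ValueError("need at least 2 objectives")
    if divisions < 1:
        raise ValueError("need at least 1 division")
    rows = []
    # stars-and-bars: choose cut positions among p + M - 1 slots
    for cuts in combinations(range(divisions + n_objectives - 1), n_objectives - 1):
        parts = []
        prev = -1
        for c in cuts:
            parts.append(c - prev - 1)
            prev = c
        parts.append(divisions + n_objectives - 2 - prev)
        rows.append([p / divisions for p in parts])
    return ReferencePointSet(points=np.array(rows, dtype=float), divisions=divisions)


# ---------------------------------------------------------------------------
# Non-dominated sorting

def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto dominance for minimization: <= everywhere and < somewhere."""
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(objectives: Sequence[np.ndarray]) -> list[list[int]]:
    """Partition indices into fronts by domination level (front 1 first)."""
    n = len(objectives)
    if n == 0:
        return []
    objs = np.asarray(objectives, dtype=float)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dominates(objs[j], objs[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts = []
    current = [i for i in range(n) if n_dominating[i] == 0]
    while current:
        fronts.append(current)
        nxt = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


# ---------------------------------------------------------------------------
# Normalization and association

def _achievement_scalarizing(objs: np.ndarray, axis: int) -> np.ndarray:
    w = np.full(objs.shape[1], 1e-6)
    w[axis] = 1.0
    return np.max(objs / w, axis=1)


def normalize_and_associate(objectives: np.ndarray, reference_points: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalize objectives and associate each member with a reference line.

    Objectives are translated by the per-axis ideal point, then scaled by the
    intercepts of the hyperplane through the ASF-selected extreme points; when
    the hyperplane is degenerate (singular system or non-positive intercepts)
    the per-axis maximum spread is used instead, and unit scale as a last
    resort.  Each member is associated to the reference line (origin through a
    reference point) with the smallest perpendicular distance.

    Returns ``(association index per member, perpendicular distance per
    member, normalized objectives)``.
    """
    objs = np.atleast_2d(np.asarray(objectives, dtype=float))
    n, m = objs.shape
    ideal = objs.min(axis=0)
    translated = objs - ideal

    intercepts = None
    extreme_idx = [int(np.argmin(_achievement_scalarizing(translated, j)))
                   for j in range(m)]
    extremes = translated[extreme_idx]
    if np.linalg.matrix_rank(extremes) == m:
        try:
            plane = np.linalg.solve(extremes, np.ones(m))
            candidate = 1.0 / plane
            if np.all(candidate > 1e-12) and np.all(np.isfinite(candidate)):
                intercepts = candidate
        except np.linalg.LinAlgError:
            pass
    if intercepts is None:
        spread = translated.max(axis=0)
        intercepts = np.where(spread > 1e-12, spread, 1.0)
    normalized = translated / intercepts

    directions = reference_points / np.linalg.norm(reference_points, axis=1,
                                                   keepdims=True)
    # distance of each member to each reference line through the origin
    proj = normalized @ directions.T                      # (n, H)
    proj_pts = proj[:, :, None] * directions[None, :, :]  # (n, H, M)
    dists = np.linalg.norm(normalized[:, None, :] - proj_pts, axis=2)
    association = np.argmin(dists, axis=1)
    distance = dists[np.arange(n), association]
    return association, distance, normalized


# ---------------------------------------------------------------------------
# Niching (Algorithm 1 niche-preserving selection)

def niching_select(last_front: Sequence[int], associations: dict[int, int],
                   distances: dict[int, float], niche_counts: np.ndarray,
                   n_slots: int, rng: np.random.Generator) -> list[int]:
    """Fill ``n_slots`` from the last front by minimum-niche-count preference.

    ``associations``/``distances`` map member index -> reference point /
    perpendicular distance; ``niche_counts`` holds rho_j over the already
    admitted members and is updated in place.  An empty niche takes its
    closest associated last-front member; an occupied one takes a random
    associated member; a niche with no last-front member left is excluded for
    the rest of this generation.  Ties in the minimum count break uniformly
    at random.
    """
    if n_slots > len(last_front):
        raise ValueError(f"cannot select {n_slots} from a front of {len(last_front)}")
    remaining = {int(i) for i in last_front}
    excluded: set[int] = set()
    selected: list[int] = []
    while len(selected) < n_slots:
        eligible = [j for j in range(len(niche_counts)) if j not in excluded]
        min_count = min(niche_counts[j] for j in eligible)
        j_min = [j for j in eligible if niche_counts[j] == min_count]
        j_star = int(rng.choice(j_min))
        members = [i for i in remaining if associations[i] == j_star]
        if not members:
            excluded.add(j_star)
            continue
        if niche_counts[j_star] == 0:
            pick = min(members, key=lambda i: distances[i])
        else:
            pick = int(rng.choice(members))
        selected.append(pick)
        remaining.discard(pick)
        niche_counts[j_star] += 1
    return selected


def select_next_population(combined_objs: np.ndarray, population_size: int,
                           reference_points: np.ndarray,
                           rng: np.random.Generator) -> list[int]:
    """Pick the next generation's indices from a combined parent+offspring set.

    Whole fronts are admitted while they fit; the partially admitted last
    front is resolved by reference-point niching.  Any front admitted whole
    (in particular front 1 whenever it is no larger than the population)
    survives intact.
    """
    fronts = non_dominated_sort(combined_objs)
    next_idx: list[int] = []
    l = 0
    while l < len(fronts) and len(next_idx) + len(fronts[l]) <= population_size:
        next_idx.extend(fronts[l])
        l += 1
    if len(next_idx) < population_size and l < len(fronts):
        last_front = fronts[l]
        st = next_idx + last_front
        assoc, dist, _ = normalize_and_associate(combined_objs[st],
                                                 reference_points)
        assoc_map = {idx: int(a) for idx, a in zip(st, assoc)}
        dist_map = {idx: float(d) for idx, d in zip(st, dist)}
        rho = np.zeros(len(reference_points), dtype=int)
        for idx in next_idx:
            rho[assoc_map[idx]] += 1
        chosen = niching_select(last_front, assoc_map, dist_map, rho,
                                population_size - len(next_idx), rng)
        next_idx.extend(chosen)
    return next_idx


# ---------------------------------------------------------------------------
# Variation

@dataclass
class VariationRates:
    bit_crossover_prob: float = 0.9    # per offspring pair, uniform crossover
    bit_flip_prob: float | None = None  # default 1 / total genes
    int_mutation_prob: float = 0.1     # uniform resampling per integer gene
    real_crossover_prob: float = 0.9
    real_mutation_prob: float = 0.1
    sbx_eta: float = 30.0
    polynomial_eta: float = 20.0


def _tournament(pop_size: int, ranks: Sequence[int], dists: Sequence[float],
                rng: np.random.Generator) -> int:
    """Binary tournament on (front rank, then perpendicular distance)."""
    a, b = rng.integers(pop_size), rng.integers(pop_size)
    if ranks[a] != ranks[b]:
        return a if ranks[a] < ranks[b] else b
    if dists[a] != dists[b]:
        return a if dists[a] < dists[b] else b
    return a if rng.random() < 0.5 else b


def _sbx_pair(x: float, y: float, low: float, high: float, eta: float,
              rng: np.random.Generator) -> tuple[float, float]:
    if abs(x - y) < 1e-14:
        return x, y
    u = rng.random()
    beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
    c1 = 0.5 * ((1 + beta) * x + (1 - beta) * y)
    c2 = 0.5 * ((1 - beta) * x + (1 + beta) * y)
    return (min(max(c1, low), high), min(max(c2, low), high))


def _polynomial_mutate(x: float, low: float, high: float, eta: float,
                       rng: np.random.Generator) -> float:
    u = rng.random()
    span = high - low
    if u < 0.5:
        delta = (2 * u) ** (1 / (eta + 1)) - 1
    else:
        delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
    return min(max(x + delta * span, low), high)


def vary(parents: Sequence[Chromosome], ranks: Sequence[int],
         dists: Sequence[float], encoding: Encoding, rng: np.random.Generator,
         rates: VariationRates | None = None) -> list[Chromosome]:
    """Produce N offspring by tournament selection, crossover and mutation.

    Channel bits: uniform crossover then per-bit flips; integer genes are
    inherited parent-wise and mutated by uniform resampling; real genes use
    simulated binary crossover and polynomial mutation.  Offspring with an
    all-zero channel mask are repaired by setting one random bit.
    """
    rates = rates or VariationRates()
    n = len(parents)
    flip_p = rates.bit_flip_prob
    if flip_p is None:
        flip_p = 1.0 / max(encoding.n_genes, 1)
    offspring: list[Chromosome] = []
    while len(offspring) < n:
        p1 = parents[_tournament(n, ranks, dists, rng)].copy()
        p2 = parents[_tournament(n, ranks, dists, rng)].copy()
        # uniform crossover on channel bits
        if encoding.n_bits and rng.random() < rates.bit_crossover_prob:
            swap = rng.random(encoding.n_bits) < 0.5
            p1.bits[swap], p2.bits[swap] = p2.bits[swap], p1.bits[swap].copy()
        for i, g in enumerate(encoding.genes):
            if g.kind == "real" and rng.random() < rates.real_crossover_prob:
                p1.genes[i], p2.genes[i] = _sbx_pair(
                    p1.genes[i], p2.genes[i], g.low, g.high, rates.sbx_eta, rng)
        for child in (p1, p2):
            if encoding.n_bits:
                flips = rng.random(encoding.n_bits) < flip_p
                child.bits[flips] ^= 1
            for i, g in enumerate(encoding.genes):
                if g.kind == "int":
                    if rng.random() < rates.int_mutation_prob:
                        child.genes[i] = float(rng.integers(int(g.low),
                                                            int(g.high) + 1))
                else:
                    if rng.random() < rates.real_mutation_prob:
                        child.genes[i] = _polynomial_mutate(
                            child.genes[i], g.low, g.high,
                            rates.polynomial_eta, rng)
            _repair(child, encoding, rng)
            offspring.append(child)
    return offspring[:n]


# ---------------------------------------------------------------------------
# Termination

@dataclass
class TerminationRule:
    tol: float = 1e-4
    period: int = 10
    max_gen: int = 300
    _checkpoint: tuple[np.ndarray, np.ndarray] | None = field(default=None,
                                                              repr=False)

    def check(self, generation: int, front_objectives: np.ndarray) -> bool:
        """True when the run should stop at this generation.

        The objective-space criterion compares the ideal and nadir points of
        the current first front against those at the previous periodic check;
        it only fires at generations divisible by ``period``.
        """
        if generation >= self.max_gen:
            return True
        front = np.atleast_2d(front_objectives)
        ideal, nadir = front.min(axis=0), front.max(axis=0)
        if generation == 0:
            self._checkpoint = (ideal, nadir)  # baseline for the first check
            return False
        if generation % self.period != 0:
            return False
        previous, self._checkpoint = self._checkpoint, (ideal, nadir)
        if previous is None:
            return False
        shift = max(np.abs(ideal - previous[0]).max(),
                    np.abs(nadir - previous[1]).max())
        return bool(shift <= self.tol)


# ---------------------------------------------------------------------------
# Main loop

@dataclass
class EvolutionResult:
    population: list[Chromosome]
    objectives: np.ndarray              # objectives of the final population
    front: list[Chromosome]             # final first front (unique members)
    front_objectives: np.ndarray
    n_generations: int
    history: list[dict]                 # per-generation log records


def evolve(fitness_fn: Callable[[Chromosome], Sequence[float]],
           encoding: Encoding, n_objectives: int = 3, population_size: int = 20,
           rng: np.random.Generator | int | None = None,
           reference_divisions: int = 5,
           termination: TerminationRule | None = None,
           rates: VariationRates | None = None,
           log: list[dict] | None = None) -> EvolutionResult:
    """Run the NSGA-III loop and return the final population and first front.

    ``fitness_fn`` maps a chromosome to its objective vector (all objectives
    minimized).  Evaluations are memoized on the chromosome key so re-visited
    genotypes are not re-scored.  With a fixed ``rng`` seed the trajectory is
    fully reproducible.
    """
    rng = np.random.default_rng(rng)
    termination = termination or TerminationRule()
    refs = generate_reference_points(n_objectives, reference_divisions).points
    history: list[dict] = log if log is not None else []
    cache: dict[tuple, np.ndarray] = {}

    def evaluate(chrom: Chromosome) -> np.ndarray:
        key = chrom.key()
        if key not in cache:
            try:
                cache[key] = np.asarray(fitness_fn(chrom), dtype=float)
            except Exception as exc:
                raise RuntimeError(
                    f"fitness evaluation failed for chromosome bits="
                    f"{chrom.bits.tolist()} genes={chrom.genes}: {exc}") from exc
        return cache[key]

    population = [random_chromosome(encoding, rng) for _ in range(population_size)]
    pop_objs = np.array([evaluate(c) for c in population])
    fronts = non_dominated_sort(pop_objs)
    ranks, dists = _rank_and_distance(pop_objs, fronts, refs)

    generation = 0
    while True:
        first = fronts[0]
        history.append({
            "generation": generation,
            "objectives": pop_objs.tolist(),
            "front_indices": list(first),
            "chromosomes": [
                {"bits": c.bits.tolist(), "genes": list(c.genes)} for c in population
            ],
        })
        if termination.check(generation, pop_objs[first]):
            break
        offspring = vary(population, ranks, dists, encoding, rng, rates)
        off_objs = np.array([evaluate(c) for c in offspring])
        combined = population + offspring
        combined_objs = np.vstack([pop_objs, off_objs])
        next_idx = select_next_population(combined_objs, population_size, refs,
                                          rng)
        population = [combined[i] for i in next_idx]
        pop_objs = combined_objs[next_idx]
        fronts = non_dominated_sort(pop_objs)
        ranks, dists = _rank_and_distance(pop_objs, fronts, refs)
        generation += 1

    first = fronts[0]
    uniq: dict[tuple, int] = {}
    for i in first:
        uniq.setdefault(population[i].key(), i)
    front_idx = sorted(uniq.values())
    return EvolutionResult(
        population=population, objectives=pop_objs,
        front=[population[i] for i in front_idx],
        front_objectives=pop_objs[front_idx],
        n_generations=generation, history=history,
    )


def _rank_and_distance(objs: np.ndarray, fronts: list[list[int]],
                       refs: np.ndarray) -> tuple[list[int], list[float]]:
    ranks = [0] * len(objs)
    for r, front in enumerate(fronts):
        for i in front:
            ranks[i] = r
    _, dist, _ = normalize_and_associate(objs, refs)
    return ranks, [float(d) for d in dist]


# ---------------------------------------------------------------------------
# Hypervolume (exact, 3 objectives) — used as a progress diagnostic in tests

def hypervolume_3d(points: np.ndarray, reference: Sequence[float]) -> float:
    """Exact dominated hypervolume of a 3-objective minimization front.

    Sweeps the third objective and accumulates 2-D dominated area slices.
    Points not strictly better than ``reference`` in every objective are
    ignored.
    """
    ref = np.asarray(reference, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    pts = pts[np.all(pts < ref, axis=1)]
    if len(pts) == 0:
        return 0.0
    fronts = non_dominated_sort(pts)
    pts = pts[fronts[0]]
    order = np.argsort(pts[:, 2], kind="stable")
    pts = pts[order]
    zs = pts[:, 2]
    hv = 0.0
    for i in range(len(pts)):
        z_next = zs[i + 1] if i + 1 < len(pts) else ref[2]
        active = pts[: i + 1, :2]
        hv += _area_2d(active, ref[:2]) * (z_next - zs[i])
    return hv


def _area_2d(points: np.ndarray, ref: np.ndarray) -> float:
    order = np.lexsort((points[:, 1], points[:, 0]))
    area = 0.0
    best_y = ref[1]
    staircase = []
    for x, y in points[order]:
        if y < best_y:
            staircase.append((x, y))
            best_y = y
    for i, (x, y) in enumerate(staircase):
        x_next = staircase[i + 1][0] if i + 1 < len(staircase) else ref[0]
        area += (x_next - x) * (ref[1] - y)
    return area
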