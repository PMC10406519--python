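"""Genetic algorithm over pacing protocols.

The GA evolves a fixed-size population of N-pulse protocols toward
high termination ratio (TR) at low pacing cost (PC).  Per generation
it either mutates one uniformly drawn protocol (with probability
``p_mutation``) or crosses two parents drawn without replacement,
evaluates the offspring's TR through a pluggable fitness backend (PC
is analytic), and admits a candidate only if its would-be percentile
rank clears configured thresholds in BOTH metrics.  An admitted
candidate replaces the bottom entry of a lexicographic sort whose
primary metric alternates between TR and PC on every replacement —
deliberately non-elitist, so a protocol excelling in only one metric
can still be displaced.

Source selection carries no pressure (parents are uniform draws); all
pressure sits in the dual-percentile acceptance gate and the
alternating replacement sort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .episodes import EpisodeLibrary
from .pacing import PacingProtocol, pacing_cost, termination_ratio

__all__ = [
    "GAHyperparams",
    "PopulationEntry",
    "SurrogateBackend",
    "SimulationBackend",
    "mutate",
    "crossover",
    "percentile_ranks",
    "accept",
    "replace_worst",
    "init_population",
    "run_ga",
    "classify_convergence",
]


@dataclass(frozen=True)
class GAHyperparams:
    """GA configuration.

    The mutation intervals double as the admissible parameter box for
    population initialisation.  Amplitudes are a.u., intervals ms.
    """

    population_size: int = 50
    n_generations: int = 200
    p_mutation: float = 0.5
    amp_range: tuple[float, float] = (0.0, 2.0)
    interval_range: tuple[float, float] = (40.0, 260.0)
    q_pc: float = 0.5
    q_tr: float = 0.5
    n_pulses: int = 5
    pulse_len: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 4:
            raise ValueError("population_size must be at least 4")
        if not 0.0 <= self.p_mutation <= 1.0:
            raise ValueError("p_mutation must lie in [0, 1]")
        if self.amp_range[0] < 0:
            raise ValueError("amplitudes are monophasic: a_lo >= 0")
        if self.interval_range[0] <= self.pulse_len:
            raise ValueError("interval_range must start above the pulse length")


@dataclass
class PopulationEntry:
    """A protocol with its cached metrics inside a GA population."""

    protocol: PacingProtocol
    pc: float
    tr: float
    birth_gen: int = 0


class SurrogateBackend:
    """Analytic fitness landscape for desk-scale GA exercise.

    TR falls off as a Gaussian of the normalised distance to a hidden
    target protocol (coordinates scaled by their mutation-interval
    widths), giving a smooth unimodal landscape with a known optimum.
    Deterministic; one evaluation is free.
    """

    def __init__(self, target: PacingProtocol, hp: GAHyperparams, width: float = 0.35):
        self.target = target
        self.hp = hp
        self.width = float(width)
        self._tvec = target.as_vector()
        n = target.n_pulses
        self._scale = np.array(
            [hp.amp_range[1] - hp.amp_range[0]] * n
            + [hp.interval_range[1] - hp.interval_range[0]] * (n - 1)
        )

    def __call__(self, protocol: PacingProtocol) -> float:
        z = (protocol.as_vector() - self._tvec) / self._scale
        return float(math.exp(-float(z @ z) / (2.0 * self.width**2)))


class SimulationBackend:
    """Simulation-backed TR evaluation over an episode library."""

    def __init__(
        self,
        library: EpisodeLibrary,
        t_dom: float,
        n_distributions: int = 5,
        seed: int = 0,
        n_sites: int | None = None,
    ):
        self.library = library
        self.t_dom = float(t_dom)
        self.n_distributions = int(n_distributions)
        self.seed = int(seed)
        self.n_sites = n_sites

    def __call__(self, protocol: PacingProtocol) -> float:
        tr, _, _ = termination_ratio(
            protocol,
            self.library,
            self.t_dom,
            self.n_distributions,
            self.seed,
            self.n_sites,
        )
        return tr


def mutate(
    protocol: PacingProtocol, hp: GAHyperparams, rng: np.random.Generator
) -> PacingProtocol:
    """Replace exactly one uniformly chosen parameter with a uniform draw.

    Amplitude coordinates draw from ``amp_range``, interval coordinates
    from ``interval_range``; every other coordinate is untouched.
    """
    n = protocol.n_pulses
    vec = protocol.as_vector()
    k = int(rng.integers(0, protocol.n_params))
    lo, hi = hp.amp_range if k < n else hp.interval_range
    vec[k] = rng.uniform(lo, hi)
    return PacingProtocol.from_vector(vec, n, protocol.pulse_len)


def crossover(
    p1: PacingProtocol, p2: PacingProtocol, rng: np.random.Generator
) -> tuple[PacingProtocol, PacingProtocol]:
    """Single-point crossover at a random pulse, excluding the final one.

    With cut k in {1, ..., N-1}, child 1 takes pulses 1..k of the first
    parent (with the bridging interval k) and pulses k+1..N of the
    second; child 2 is the mirror image.
    """
    if p1.n_pulses != p2.n_pulses:
        raise ValueError("parents must have the same pulse count")
    n = p1.n_pulses
    k = int(rng.integers(1, n))
    c1 = PacingProtocol(
        p1.amplitudes[:k] + p2.amplitudes[k:],
        p1.intervals[:k] + p2.intervals[k:],
        p1.pulse_len,
    )
    c2 = PacingProtocol(
        p2.amplitudes[:k] + p1.amplitudes[k:],
        p2.intervals[:k] + p1.intervals[k:],
        p2.pulse_len,
    )
    return c1, c2


def percentile_ranks(
    population: list[PopulationEntry], pc: float, tr: float
) -> tuple[float, float]:
    """Would-be percentile ranks of a candidate in the current population.

    Rank is the fraction of entries the candidate beats: strictly lower
    PC / strictly higher TR count fully, ties count half.
    """
    if not population:
        raise ValueError("population is empty")
    n = len(population)
    worse_pc = sum(1.0 for e in population if e.pc > pc) + 0.5 * sum(
        1.0 for e in population if e.pc == pc
    )
    worse_tr = sum(1.0 for e in population if e.tr < tr) + 0.5 * sum(
        1.0 for e in population if e.tr == tr
    )
    return worse_pc / n, worse_tr / n


def accept(ranks: tuple[float, float], hp: GAHyperparams) -> bool:
    """Pass iff both percentile ranks clear their thresholds."""
    r_pc, r_tr = ranks
    return r_pc >= hp.q_pc and r_tr >= hp.q_tr


def replace_worst(
    population: list[PopulationEntry], entry: PopulationEntry, tr_primary: bool
) -> list[PopulationEntry]:
    """Replace the bottom entry of the alternating lexicographic sort.

    ``tr_primary=True`` sorts by TR descending with PC ascending as the
    tie-break; ``False`` sorts by PC ascending with TR descending as
    the tie-break.  The sort is stable, so among fully tied entries the
    one latest in population order is replaced.  The accepted entry is
    appended; population size is conserved.
    """
    if tr_primary:
        key = lambda e: (-e.tr, e.pc)  # noqa: E731
    else:
        key = lambda e: (e.pc, -e.tr)  # noqa: E731
    worst = sorted(population, key=key)[-1]
    out = [e for e in population if e is not worst]
    out.append(entry)
    return out


def _uniform_protocol(hp: GAHyperparams, rng: np.random.Generator) -> PacingProtocol:
    amps = rng.uniform(*hp.amp_range, size=hp.n_pulses)
    ivals = rng.uniform(*hp.interval_range, size=hp.n_pulses - 1)
    return PacingProtocol(tuple(amps), tuple(ivals), hp.pulse_len)


def init_population(
    scheme: str,
    hp: GAHyperparams,
    fitness,
    rng: np.random.Generator,
    base_protocol: PacingProtocol | None = None,
    jitter: float = 0.1,
) -> list[PopulationEntry]:
    """Build and evaluate an initial population.

    ``"uniform"`` draws every parameter uniformly from its mutation
    interval; ``"adp-jitter"`` perturbs a base (typically ADP-derived)
    protocol multiplicatively by ``1 + jitter * uniform(-1, 1)`` per
    parameter, clipped into the mutation intervals.
    """
    entries: list[PopulationEntry] = []
    if scheme == "uniform":
        protos = [_uniform_protocol(hp, rng) for _ in range(hp.population_size)]
    elif scheme == "adp-jitter":
        if base_protocol is None:
            raise ValueError("adp-jitter initialisation needs a base protocol")
        base = base_protocol.as_vector()
        n = base_protocol.n_pulses
        lo = np.array([hp.amp_range[0]] * n + [hp.interval_range[0]] * (n - 1))
        hi = np.array([hp.amp_range[1]] * n + [hp.interval_range[1]] * (n - 1))
        protos = []
        for _ in range(hp.population_size):
            vec = base * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=base.size))
            protos.append(
                PacingProtocol.from_vector(
                    np.clip(vec, lo, hi), n, base_protocol.pulse_len
                )
            )
    else:
        raise ValueError(f"unknown initialisation scheme {scheme!r}")
    for proto in protos:
        entries.append(
            PopulationEntry(proto, pacing_cost(proto), float(fitness(proto)), 0)
        )
    return entries


@dataclass
class GAHistory:
    """Per-generation population statistics and the acceptance log."""

    rows: list[dict] = field(default_factory=list)
    acceptance_log: list[dict] = field(default_factory=list)
    failures: int = 0

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _stats_row(gen: int, population: list[PopulationEntry], n_accepted: int) -> dict:
    pcs = np.array([e.pc for e in population])
    trs = np.array([e.tr for e in population])
    return {
        "generation": gen,
        "mean_pc": pcs.mean(),
        "std_pc": pcs.std(),
        "mean_tr": trs.mean(),
        "std_tr": trs.std(),
        "best_tr": trs.max(),
        "min_pc": pcs.min(),
        "n_accepted": n_accepted,
    }


def run_ga(
    population: list[PopulationEntry],
    hp: GAHyperparams,
    fitness,
    start_generation: int = 0,
    max_failures: int = 20,
) -> tuple[list[PopulationEntry], GAHistory]:
    """Run the generation loop from an evaluated population.

    Each generation draws its own random stream from the master seed,
    so runs are reproducible and resumable from any generation
    boundary.  Backend failures skip the candidate and count against a
    bounded budget.  Returns the final population and history.
    """
    if len(population) != hp.population_size:
        raise ValueError(
            f"population size {len(population)} != configured {hp.population_size}"
        )
    pop = list(population)
    hist = GAHistory()
    parity_tr_primary = True
    hist.rows.append(_stats_row(start_generation, pop, 0))
    for gen in range(start_generation, start_generation + hp.n_generations):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=hp.seed % 2**31, spawn_key=(gen,))
        )
        if rng.random() < hp.p_mutation:
            src = pop[int(rng.integers(0, len(pop)))]
            candidates = [mutate(src.protocol, hp, rng)]
        else:
            i, j = rng.choice(len(pop), size=2, replace=False)
            candidates = list(crossover(pop[i].protocol, pop[j].protocol, rng))
        n_accepted = 0
        for proto in candidates:
            try:
                tr = float(fitness(proto))
            except Exception as exc:  # noqa: BLE001 - backend failures are logged
                hist.failures += 1
                hist.acceptance_log.append(
                    {"generation": gen, "accepted": False, "error": repr(exc)}
                )
                if hist.failures > max_failures:
                    raise RuntimeError(
                        f"fitness backend failed {hist.failures} times"
                    ) from exc
                continue
            pc = pacing_cost(proto)
            ranks = percentile_ranks(pop, pc, tr)
            ok = accept(ranks, hp)
            hist.acceptance_log.append(
                {
                    "generation": gen,
                    "accepted": ok,
                    "pc": pc,
                    "tr": tr,
                    "r_pc": ranks[0],
                    "r_tr": ranks[1],
                }
            )
            if ok:
                entry = PopulationEntry(proto, pc, tr, birth_gen=gen + 1)
                pop = replace_worst(pop, entry, parity_tr_primary)
                parity_tr_primary = not parity_tr_primary
                n_accepted += 1
        hist.rows.append(_stats_row(gen + 1, pop, n_accepted))
    return pop, hist


def classify_convergence(series, smooth: int = 9) -> str:
    """Heuristic label for a metric-trajectory: one of ``asymptotic``,
    ``rebounding`` or ``quasi-linear``.

    The smoothed series is split into thirds; persistent slope-sign
    reversal marks rebounding, a final slope comparable to the initial
    one quasi-linear, and a flattening monotone trend asymptotic.
    Diagnostic only.
    """
    y = np.asarray(series, float)
    if y.size < 3 * smooth:
        raise ValueError("series too short to classify")
    kernel = np.ones(smooth) / smooth
    ys = np.convolve(y, kernel, mode="valid")
    d = np.diff(ys)
    third = len(d) // 3
    s0, s2 = d[:third].mean(), d[-third:].mean()
    main_sign = np.sign(s0) if s0 != 0 else np.sign(d.mean())
    reversal = d[third:] * main_sign < -1e-12
    if reversal.mean() > 0.25:
        return "rebounding"
    if abs(s2) >= 0.5 * abs(s0):
        return "quasi-linear"
    return "asymptotic"
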