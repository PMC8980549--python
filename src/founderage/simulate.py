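"""Forward simulation of founder haplotype descent.

Carrier chromosomes descend from a single founder haplotype for ``g``
generations.  Recombination follows a Haldane (no-interference) model:
crossovers fall as a Poisson process on the genetic map, so over g
meioses the nearest breakpoint on each side of the focal site is
Exponential(g)-distributed in Morgans.  Material beyond the nearest
breakpoint on each side is replaced by a draw from a background
haplotype pool with specified frequencies (only the breakpoint nearest
the focal site matters to the estimators, so later history on replaced
material is simply a fresh pool draw at sampling time).  Each marker
additionally mutates with probability mu per generation to one of the
other three bases uniformly; the focal site itself never mutates, since
carriers are ascertained on the mutation.

Controls are diplotypes formed from two independent pool draws (random
mating / Hardy–Weinberg), with phase discarded.

Every stochastic operation draws from a single ``numpy`` generator
seeded by the mandatory config seed, so runs are replayable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frequency import GenotypeMatrix
from .markers import ALLELES, CarrierMatrix, MarkerMap


@dataclass
class SimulationConfig:
    marker_map: MarkerMap
    founder: str  # allele string, one per marker
    pool: dict[str, float]  # background haplotype -> frequency (sums to 1)
    g: int  # generations since the founder
    n_chromosomes: int
    n_controls: int
    seed: int
    mu: float = 1e-8

    def __post_init__(self) -> None:
        if len(self.founder) != len(self.marker_map):
            raise ValueError("founder length must equal map length")
        total = sum(self.pool.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pool frequencies sum to {total}, not 1")
        for hap in self.pool:
            if len(hap) != len(self.marker_map):
                raise ValueError("pool haplotype length must equal map length")
            if any(a not in ALLELES for a in hap):
                raise ValueError("pool haplotype allele outside {A,C,G,T}")
        if self.g < 0:
            raise ValueError("g must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated carriers."""

    g: int
    seed: int
    # per chromosome, genetic position (Morgans from the focal site) of the
    # nearest breakpoint on each side; inf = no breakpoint (segment runs
    # past the map end)
    left_breakpoints: np.ndarray = field(default_factory=lambda: np.array([]))
    right_breakpoints: np.ndarray = field(default_factory=lambda: np.array([]))
    # (chromosome, marker index, generation) marker mutation events
    mutations: list[tuple[int, int, int]] = field(default_factory=list)

    def one_sided_lengths(self, map_left: float, map_right: float) -> tuple[
        np.ndarray, np.ndarray
    ]:
        """True segment lengths truncated at the map extent."""
        return (
            np.minimum(self.left_breakpoints, map_left),
            np.minimum(self.right_breakpoints, map_right),
        )


def _pool_draw(rng: np.random.Generator, haps: list[str], freqs: np.ndarray) -> str:
    return haps[rng.choice(len(haps), p=freqs)]


def simulate_carriers(config: SimulationConfig) -> tuple[CarrierMatrix, SimTruth]:
    """Simulate ``n_chromosomes`` carrier chromosomes of founder descent.

    Each chromosome keeps founder material within Exponential(g)
    distances of the focal site on both sides and pool material beyond;
    markers mutate Binomial(g, mu) times, each time moving uniformly to
    one of the other three bases.  With g = 0 every chromosome is an
    exact founder copy.
    """
    rng = np.random.default_rng(config.seed)
    mm = config.marker_map
    n_markers = len(mm)
    focal = mm.focal_index
    morgans = np.array([mm.morgans_from_focal(p) for p in mm.positions])
    haps = sorted(config.pool)
    freqs = np.array([config.pool[h] for h in haps])
    founder = np.array(list(config.founder), dtype="<U1")
    other = {
        a: [b for b in sorted(ALLELES) if b != a] for a in ALLELES
    }

    rows, labels = [], []
    lbp = np.full(config.n_chromosomes, np.inf)
    rbp = np.full(config.n_chromosomes, np.inf)
    mutations: list[tuple[int, int, int]] = []
    for k in range(config.n_chromosomes):
        hap = founder.copy()
        if config.g > 0:
            l = rng.exponential(1.0 / config.g)
            r = rng.exponential(1.0 / config.g)
            lbp[k], rbp[k] = l, r
            left_bg = np.array(list(_pool_draw(rng, haps, freqs)), dtype="<U1")
            right_bg = np.array(list(_pool_draw(rng, haps, freqs)), dtype="<U1")
            left_mask = (np.arange(n_markers) < focal) & (morgans > l)
            right_mask = (np.arange(n_markers) > focal) & (morgans > r)
            hap[left_mask] = left_bg[left_mask]
            hap[right_mask] = right_bg[right_mask]
            if config.mu > 0.0:
                n_mut = rng.binomial(config.g, config.mu, size=n_markers)
                n_mut[focal] = 0  # carriers are ascertained on the mutation
                for i in np.nonzero(n_mut)[0]:
                    for _ in range(int(n_mut[i])):
                        hap[i] = rng.choice(other[str(hap[i])])
                        mutations.append((k, int(i), config.g))
        rows.append(hap)
        labels.append(f"SIM{k:03d}-a")

    matrix = CarrierMatrix(
        chromosome_labels=labels, alleles=np.array(rows, dtype="<U1")
    )
    truth = SimTruth(
        g=config.g,
        seed=config.seed,
        left_breakpoints=lbp,
        right_breakpoints=rbp,
        mutations=mutations,
    )
    return matrix, truth


def simulate_controls(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate ``n_controls`` unphased control diplotypes by independent
    pool draws under random mating."""
    rng = np.random.default_rng(config.seed + 1)
    haps = sorted(config.pool)
    freqs = np.array([config.pool[h] for h in haps])
    n_markers = len(config.marker_map)
    a1 = np.empty((config.n_controls, n_markers), dtype="<U1")
    a2 = np.empty((config.n_controls, n_markers), dtype="<U1")
    for s in range(config.n_controls):
        h1 = _pool_draw(rng, haps, freqs)
        h2 = _pool_draw(rng, haps, freqs)
        a1[s] = list(h1)
        a2[s] = list(h2)
    return GenotypeMatrix(
        sample_ids=[f"CTRL{s:04d}" for s in range(config.n_controls)],
        marker_ids=config.marker_map.rsids,
        a1=a1,
        a2=a2,
    )
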