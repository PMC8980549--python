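"""Multilocus haplotype frequency estimation from unphased genotypes.

Two phase-free estimators are provided:

* ``em_frequencies`` — the classic expectation-maximization algorithm:
  each multi-heterozygous sample is distributed over its compatible
  phase resolutions in proportion to current haplotype-frequency
  products, and frequencies are re-estimated from expected counts until
  the fixed point.
* ``chm_frequencies`` — a composite haplotype method: a single counting
  pass in which every compatible phase resolution of an ambiguous
  sample receives equal fractional weight.  (This is a from-scratch
  definition of composite counting, not a bit-compatible
  re-implementation of any proprietary tool.)

Missing genotypes are marginalized over the alleles observed at that
marker, weighted (EM) or equally (CHM) across the compatible
haplotypes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .markers import ALLELES, MISSING, CarrierMatrix
from .haplotype import Block, FounderHaplotype, _matches

#: refuse to enumerate more phase resolutions per sample than this
MAX_RESOLUTIONS = 1 << 16


@dataclass
class GenotypeMatrix:
    """Unphased control genotypes: samples × markers, each genotype an
    unordered allele pair; ``-`` marks a missing allele."""

    sample_ids: list[str]
    marker_ids: list[str]
    a1: np.ndarray  # (n_samples, n_markers), dtype '<U1'
    a2: np.ndarray

    def __post_init__(self) -> None:
        self.a1 = np.asarray(self.a1, dtype="<U1")
        self.a2 = np.asarray(self.a2, dtype="<U1")
        if self.a1.shape != self.a2.shape:
            raise ValueError("allele arrays must have identical shape")
        valid = list(ALLELES | {MISSING})
        if (~np.isin(self.a1, valid)).any() or (~np.isin(self.a2, valid)).any():
            raise ValueError("genotype allele outside {A,C,G,T,-}")

    @property
    def n_samples(self) -> int:
        return self.a1.shape[0]

    @property
    def n_markers(self) -> int:
        return self.a1.shape[1]


@dataclass
class FrequencyEstimate:
    """Haplotype → frequency estimate on the unit simplex."""

    frequencies: dict[str, float]
    method: str
    loglik: float | None = None
    n_iter: int = 0
    converged: bool = True

    def __getitem__(self, hap: str) -> float:
        return self.frequencies.get(hap, 0.0)


def _marker_subset(
    genotypes: GenotypeMatrix, markers: list[int] | list[str] | None
) -> list[int]:
    if markers is None:
        return list(range(genotypes.n_markers))
    idx = []
    for m in markers:
        idx.append(
            genotypes.marker_ids.index(m) if isinstance(m, str) else int(m)
        )
    return idx


def _observed_alleles(genotypes: GenotypeMatrix, cols: list[int]) -> list[list[str]]:
    out = []
    for j in cols:
        seen = sorted(
            set(genotypes.a1[:, j]) | set(genotypes.a2[:, j]) - {MISSING}
        )
        seen = [a for a in seen if a != MISSING]
        if not seen:
            raise ValueError(
                f"marker {genotypes.marker_ids[j]} has no observed alleles"
            )
        out.append(seen)
    return out


def _resolutions(
    g1: np.ndarray, g2: np.ndarray, alleles: list[list[str]]
) -> list[tuple[str, str]]:
    """All compatible (hap1, hap2) phase resolutions of one sample, as
    an unordered pair (hap1 <= hap2).  Missing genotypes expand over the
    alleles observed at that marker."""
    per_site: list[list[tuple[str, str]]] = []
    count = 1
    for x, y, obs in zip(g1, g2, alleles):
        if x == MISSING and y == MISSING:
            opts = sorted({tuple(sorted((a, b))) for a in obs for b in obs})
        elif MISSING in (x, y):
            known = y if x == MISSING else x
            opts = sorted({tuple(sorted((known, a))) for a in obs})
        elif x == y:
            opts = [(x, y)]
        else:
            opts = [(x, y), (y, x)]
        per_site.append(opts)
        count *= len(opts)
        if count > MAX_RESOLUTIONS:
            raise ValueError(
                "too many phase resolutions for one sample; restrict the "
                "marker subset"
            )
    out = set()
    for combo in itertools.product(*per_site):
        h1 = "".join(c[0] for c in combo)
        h2 = "".join(c[1] for c in combo)
        out.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(out)


def _prepare(
    genotypes: GenotypeMatrix, markers
) -> tuple[list[list[tuple[str, str]]], list[str]]:
    cols = _marker_subset(genotypes, markers)
    alleles = _observed_alleles(genotypes, cols)
    per_sample = []
    complete = 0
    for s in range(genotypes.n_samples):
        g1 = genotypes.a1[s, cols]
        g2 = genotypes.a2[s, cols]
        if not ((g1 == MISSING) | (g2 == MISSING)).any():
            complete += 1
        per_sample.append(_resolutions(g1, g2, alleles))
    if complete == 0:
        raise ValueError("no sample with complete genotypes at these markers")
    hap_space = sorted({h for res in per_sample for pair in res for h in pair})
    return per_sample, hap_space


def em_frequencies(
    genotypes: GenotypeMatrix,
    markers: list[int] | list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = None,
    n_restarts: int = 0,
) -> FrequencyEstimate:
    """EM haplotype frequencies over the chosen marker subset.

    Initialization is uniform over observed-compatible haplotypes for
    determinism; ``n_restarts`` > 0 adds seeded random restarts (Dirichlet
    starts) and returns the best fixed point by log-likelihood, a cheap
    multimodality check.  Iteration stops when the largest absolute
    frequency change falls below ``tol``.
    """
    per_sample, hap_space = _prepare(genotypes, markers)
    hap_index = {h: i for i, h in enumerate(hap_space)}
    pairs = [
        [(hap_index[h1], hap_index[h2]) for h1, h2 in res]
        for res in per_sample
    ]

    starts = [np.full(len(hap_space), 1.0 / len(hap_space))]
    if n_restarts:
        rng = np.random.default_rng(seed)
        starts += [
            rng.dirichlet(np.ones(len(hap_space))) for _ in range(n_restarts)
        ]

    best: tuple[float, np.ndarray, int, bool] | None = None
    for freqs in starts:
        freqs = freqs.copy()
        converged = False
        prev_ll = -np.inf
        for it in range(1, max_iter + 1):
            counts = np.zeros_like(freqs)
            ll = 0.0
            for res in pairs:
                ws = np.array(
                    [
                        (2.0 if i != j else 1.0) * freqs[i] * freqs[j]
                        for i, j in res
                    ]
                )
                tot = ws.sum()
                if tot <= 0.0:
                    ws = np.full(len(res), 1.0 / len(res))
                    tot = 1.0
                    ll += -np.inf
                else:
                    ws = ws / tot
                    ll += np.log(tot)
                for w, (i, j) in zip(ws, res):
                    counts[i] += w
                    counts[j] += w
            new = counts / counts.sum()
            if ll < prev_ll - 1e-9:  # EM guarantee; numerical guard only
                warnings.warn("EM log-likelihood decreased", RuntimeWarning)
            prev_ll = ll
            delta = float(np.max(np.abs(new - freqs)))
            freqs = new
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"EM did not converge in {max_iter} iterations", RuntimeWarning
            )
        if best is None or prev_ll > best[0]:
            best = (prev_ll, freqs, it, converged)

    ll, freqs, n_iter, converged = best
    return FrequencyEstimate(
        frequencies={h: float(f) for h, f in zip(hap_space, freqs) if f > 0.0},
        method="EM",
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
    )


def chm_frequencies(
    genotypes: GenotypeMatrix,
    markers: list[int] | list[str] | None = None,
) -> FrequencyEstimate:
    """Composite counting: each sample's compatible phase resolutions
    receive equal fractional weight in a single pass (samples with at
    most one heterozygous marker contribute whole counts, as they have a
    unique resolution)."""
    per_sample, hap_space = _prepare(genotypes, markers)
    counts = {h: 0.0 for h in hap_space}
    for res in per_sample:
        w = 1.0 / len(res)
        for h1, h2 in res:
            counts[h1] += w
            counts[h2] += w
    total = sum(counts.values())
    return FrequencyEstimate(
        frequencies={h: c / total for h, c in counts.items() if c > 0.0},
        method="CHM",
    )


def carrier_block_probability(
    matrix: CarrierMatrix,
    founder: FounderHaplotype,
    block: Block,
    control_freqs: FrequencyEstimate | None = None,
) -> dict[str, float]:
    """Frequency of the founder block haplotype among carrier
    chromosomes, and (when control frequencies over the block's markers
    are supplied) the probability that a random non-ancestral chromosome
    carries it.

    ``carrier_frequency`` counts chromosomes conserving the founder
    haplotype from the mutation through the block's label marker — the
    P_D that feeds the age estimators; ``block_match_frequency`` counts
    chromosomes matching the founder over the block's own markers
    regardless of what happened nearer the mutation.  Missing carrier
    genotypes count as matching, mirroring the sharing rules used
    elsewhere.
    """
    span = block.member_markers
    n_local = 0
    n_conserved = 0
    lo, hi = sorted((founder.core.start, block.label_index))
    lo = min(lo, founder.core.stop - 1)
    hi = max(hi, founder.core.stop - 1)
    for k in range(matrix.n_chromosomes):
        row = matrix.alleles[k]
        if all(_matches(row[i], founder.alleles[i]) for i in span):
            n_local += 1
        if all(
            _matches(row[i], founder.alleles[i]) for i in range(lo, hi + 1)
        ):
            n_conserved += 1
    out = {
        "carrier_frequency": n_conserved / matrix.n_chromosomes,
        "block_match_frequency": n_local / matrix.n_chromosomes,
    }
    if control_freqs is not None:
        target = "".join(founder.alleles[i] for i in span)
        out["population_probability"] = control_freqs[target]
    return out
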