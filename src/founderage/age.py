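"""Mutation-age estimators in generations.

Three related estimator families date a founder mutation from the decay
of its ancestral haplotype:

* **Decay (closed form).**  With P_D the ancestral-haplotype frequency
  on carrier chromosomes, P_N its frequency in controls, and theta the
  recombination fraction from the mutation to the haplotype block, the
  linkage-disequilibrium constant is delta = (P_D − P_N)/(1 − P_N) and
  the age is g = ln(delta)/ln(1 − theta): one generation of
  recombination at rate theta multiplies the excess association by
  (1 − theta).
* **Iterative transition-matrix.**  The carrier-chromosome state vector
  (ancestral, non-ancestral), starting at (1, 0), is multiplied each
  generation by the column-stochastic matrix K = cR + muM + (1−c−mu)I,
  where R resets to the control frequencies (R11 = R12 = a,
  R21 = R22 = 1 − a) and M is a marker-mutation matrix with M11 = 0,
  M12 = 1/3, M21 = 1, M22 = 2/3 (a SNP mutation destroys the ancestral
  allele with certainty and recreates it 1 time in 3).  The age is the
  (interpolated) generation at which the ancestral-state frequency
  reaches the observed P_D; with mu = 0 this equals the closed form.
* **Gamma (segment-length).**  One-sided conserved ancestral segment
  lengths around the mutation are modelled as Exponential(g) in
  Morgans; with S the summed length of the 2n one-sided segments the
  bias-corrected MLE is g = (2n − 1)/S, with Gamma-quantile confidence
  limits.  Censored segments (no recombination observed within the map)
  contribute their observed length to S but not to the event count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .haplotype import SegmentData

GENERATION_YEARS = 25.0  # calendar years per meiotic generation


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


class NotEstimableError(ValueError):
    """The requested age is undefined for these inputs (e.g. the
    ancestral haplotype is no more frequent in carriers than in
    controls, so there is no association left to decay)."""


@dataclass
class AgeInputs:
    """Per-block inputs for the decay and iterative estimators.

    p_d: ancestral-haplotype frequency among carrier chromosomes.
    p_n: its frequency among control chromosomes (Fn).
    theta: recombination fraction from the mutation to the block.
    mu: per-generation marker mutation rate (SNP-scale default 1e-8).
    """

    p_d: float
    p_n: float
    theta: float
    mu: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("p_d", "p_n", "theta", "mu"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.theta + self.mu >= 1.0:
            raise ValueError("theta + mu must be < 1")


@dataclass
class AgeEstimate:
    generations: float
    rounded: int
    method: str
    ci_low: float | None = None
    ci_high: float | None = None

    def years(self, generation_years: float = GENERATION_YEARS) -> float:
        return self.generations * generation_years


def delta(inputs: AgeInputs) -> tuple[float, bool]:
    """Linkage-disequilibrium constant delta = (P_D − P_N)/(1 − P_N).

    Returns ``(delta, estimable)``; ``estimable`` is False when
    delta <= 0, in which case the decay formula has no solution.
    """
    if inputs.p_n >= 1.0:
        raise ValueError("p_n must be < 1")
    d = (inputs.p_d - inputs.p_n) / (1.0 - inputs.p_n)
    return d, d > 0.0


def risch_age(inputs: AgeInputs) -> AgeEstimate:
    """Closed-form decay estimate g = ln(delta)/ln(1 − theta)."""
    d, ok = delta(inputs)
    if not ok:
        raise NotEstimableError(
            f"delta={d:.5g} <= 0: not estimable by the decay formula"
        )
    if inputs.theta <= 0.0:
        raise NotEstimableError("theta = 0: no recombination clock")
    g = math.log(d) / math.log1p(-inputs.theta)
    return AgeEstimate(generations=g, rounded=round_half_up(g), method="risch")


@dataclass
class GoldsteinModel:
    """Per-generation transition model for the carrier-chromosome
    ancestral-state frequency.

    a: ancestral allele/haplotype frequency in controls;
    c: recombination rate to the block; mu: marker mutation rate.
    """

    a: float
    c: float
    mu: float = 1e-8

    @property
    def K(self) -> np.ndarray:
        a, c, mu = self.a, self.c, self.mu
        R = np.array([[a, a], [1.0 - a, 1.0 - a]])
        M = np.array([[0.0, 1.0 / 3.0], [1.0, 2.0 / 3.0]])
        I = np.eye(2)
        return c * R + mu * M + (1.0 - c - mu) * I


def goldstein_age(
    model: GoldsteinModel,
    target_p_d: float,
    max_iter: int = 100_000,
) -> AgeEstimate:
    """Iterate the state vector (1, 0) under K until the ancestral-state
    frequency falls to ``target_p_d``; interpolation between the
    bracketing generations gives a fractional age.

    On the probability simplex the deviation of the state from the fixed
    point of K shrinks by the subdominant eigenvalue each generation, so
    the interpolation is geometric in (state − fixed point); for mu = 0
    the result then equals the closed-form decay estimate exactly.
    """
    K = model.K
    if not np.allclose(K.sum(axis=0), 1.0, atol=1e-12):
        raise ValueError("K columns must sum to 1")
    if target_p_d > 1.0 or target_p_d <= 0.0:
        raise ValueError("target_p_d must be in (0, 1]")
    state = np.array([1.0, 0.0])
    if target_p_d >= state[0]:
        return AgeEstimate(generations=0.0, rounded=0, method="goldstein")
    # ancestral-state fixed point of the column-stochastic recursion
    k11, k12 = K[0, 0], K[0, 1]
    p_star = k12 / (1.0 - k11 + k12)
    if target_p_d <= p_star:
        raise NotEstimableError(
            f"target {target_p_d:.5g} at or below the asymptotic ancestral "
            f"frequency {p_star:.5g}; not reachable by iteration"
        )
    prev = state[0]
    for g in range(1, max_iter + 1):
        state = K @ state
        cur = state[0]
        if cur <= target_p_d:
            ratio = (cur - p_star) / (prev - p_star)
            if 0.0 < ratio < 1.0:
                frac = math.log((target_p_d - p_star) / (prev - p_star)) / math.log(
                    ratio
                )
            else:  # degenerate step: fall back to linear interpolation
                frac = (prev - target_p_d) / (prev - cur)
            gen = (g - 1) + frac
            return AgeEstimate(
                generations=gen, rounded=round_half_up(gen), method="goldstein"
            )
        prev = cur
    raise NotEstimableError(f"target not reached within {max_iter} generations")


def gamma_age(
    data: SegmentData,
    alpha: float = 0.05,
    genealogy: str = "independent",
    include_censored: bool = True,
) -> AgeEstimate:
    """Segment-length (Gamma) age estimate.

    Independent genealogy: with S the sum of the 2n one-sided segment
    lengths (Morgans) and m the number of uncensored segments, the point
    estimate is (m − 1)/S and the CI is
    [q_Gamma(alpha/2; m)/S, q_Gamma(1 − alpha/2; m)/S]; with no
    censoring m = 2n.  Correlated genealogy: chromosomes are collapsed
    to one lineage per family per side, and families sharing a
    recombinant ancestor on a side are collapsed further to a single
    effective lineage on that side.  ``include_censored=False`` drops
    censored segments from S entirely instead of treating them as
    censored-exponential observations.
    """
    if genealogy not in ("independent", "correlated"):
        raise ValueError("genealogy must be 'independent' or 'correlated'")

    lengths, censored = [], []
    for side, (vals, flags, groups) in enumerate(
        (
            (data.left, data.left_censored, data.left_group),
            (data.right, data.right_censored, data.right_group),
        )
    ):
        if genealogy == "independent":
            lengths.extend(vals)
            censored.extend(flags)
        else:
            seen_fam: set[str] = set()
            seen_grp: set[str] = set()
            for v, c, fam, grp in zip(vals, flags, data.families, groups):
                if grp is not None:
                    if grp in seen_grp:
                        continue
                    seen_grp.add(grp)
                elif fam in seen_fam:
                    continue
                seen_fam.add(fam)
                lengths.append(v)
                censored.append(c)

    lengths = np.asarray(lengths, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    if not include_censored:
        lengths, censored = lengths[~censored], censored[~censored]
    S = float(lengths.sum())
    m = int((~censored).sum())
    if S <= 0.0:
        raise NotEstimableError("total segment length is zero")
    if m < 2:
        raise NotEstimableError(
            "fewer than two uncensored segments; age not identifiable"
        )
    g = (m - 1) / S
    lo = stats.gamma.ppf(alpha / 2.0, a=m) / S
    hi = stats.gamma.ppf(1.0 - alpha / 2.0, a=m) / S
    return AgeEstimate(
        generations=g,
        rounded=round_half_up(g),
        method=f"gamma-{genealogy}",
        ci_low=float(lo),
        ci_high=float(hi),
    )


def bootstrap_ci(
    estimator,
    inputs: AgeInputs,
    n_chromosomes: int = 18,
    B: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
):
    """Parametric bootstrap CI for a decay-family estimator.

    Carrier-chromosome sharing is resampled as Binomial(n_chromosomes,
    P_D); the estimator is re-applied to each replicate and the
    percentile interval returned.  Deterministic under a fixed seed.
    """
    if inputs.p_d >= 1.0:
        return (0.0, 0.0)
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_chromosomes, inputs.p_d, size=B)
    estimates = []
    for k in draws:
        rep = AgeInputs(
            p_d=k / n_chromosomes,
            p_n=inputs.p_n,
            theta=inputs.theta,
            mu=inputs.mu,
        )
        try:
            estimates.append(estimator(rep).generations)
        except (NotEstimableError, ValueError):
            continue
    if len(estimates) < B / 2:
        raise NotEstimableError(
            f"estimator failed in {B - len(estimates)}/{B} bootstrap replicates"
        )
    lo, hi = np.percentile(estimates, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def age_table(
    blocks: pd.DataFrame,
    n_chromosomes: int = 18,
    mu: float = 1e-8,
    bootstrap: int = 0,
    seed: int | None = None,
    generation_years: float = GENERATION_YEARS,
) -> tuple[pd.DataFrame, dict]:
    """Per-block, per-frequency-source age table.

    ``blocks`` needs columns ``label_rsid``, ``shared_chromosomes``,
    ``fn_em``, ``fn_chm``, ``theta``; the focal block (theta == 0 or
    missing Fn) is skipped.  Returns the table (one row per block ×
    {EM, CHM}, with decay and iterative estimates, flags for
    not-estimable blocks, optional bootstrap CIs) plus a summary with
    the min/max rounded age over estimable entries and the year window.
    """
    rows = []
    for _, blk in blocks.iterrows():
        p_d = blk["shared_chromosomes"] / n_chromosomes
        for source in ("em", "chm"):
            fn = blk.get(f"fn_{source}")
            theta = blk["theta"]
            if pd.isna(fn) or theta == 0.0:
                continue
            inputs = AgeInputs(p_d=p_d, p_n=float(fn), theta=float(theta), mu=mu)
            d, ok = delta(inputs)
            row = {
                "label_rsid": blk["label_rsid"],
                "source": source.upper(),
                "p_d": p_d,
                "p_n": float(fn),
                "theta": float(theta),
                "delta": d,
                "estimable": ok,
                "risch": np.nan,
                "risch_rounded": pd.NA,
                "goldstein": np.nan,
                "goldstein_rounded": pd.NA,
                "ci_low": np.nan,
                "ci_high": np.nan,
            }
            if ok and theta > 0.0:
                r = risch_age(inputs)
                gmodel = GoldsteinModel(a=float(fn), c=float(theta), mu=mu)
                try:
                    gold = goldstein_age(gmodel, p_d)
                    row["goldstein"] = gold.generations
                    row["goldstein_rounded"] = gold.rounded
                except NotEstimableError:
                    pass
                row["risch"] = r.generations
                row["risch_rounded"] = r.rounded
                if bootstrap:
                    lo, hi = bootstrap_ci(
                        risch_age,
                        inputs,
                        n_chromosomes=n_chromosomes,
                        B=bootstrap,
                        seed=seed,
                    )
                    row["ci_low"], row["ci_high"] = lo, hi
            rows.append(row)
    table = pd.DataFrame(rows)
    estimable = table[table["estimable"] & table["risch_rounded"].notna()]
    if len(estimable):
        gmin = int(estimable["risch_rounded"].min())
        gmax = int(estimable["risch_rounded"].max())
        summary = {
            "min_generations": gmin,
            "max_generations": gmax,
            "min_years": gmin * generation_years,
            "max_years": gmax * generation_years,
        }
    else:
        summary = {
            "min_generations": None,
            "max_generations": None,
            "min_years": None,
            "max_years": None,
        }
    return table, summary
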