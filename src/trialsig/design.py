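"""Exact single-arm two-stage binomial designs and design-consistent inference.

A Simon two-stage design enrolls ``n1`` patients, stops for futility when the
stage-1 response count is at most ``r1``, otherwise enrolls to a planned total
of ``n`` and declares the regimen positive when the total response count is at
least ``r + 1``.  All probabilities here are exact binomial convolutions; no
Monte Carlo is involved.

Beyond the classic design search (optimal = minimum expected sample size under
the null; minimax = minimum total sample size) the module implements the
conditional-error machinery needed when stage 2 under- or over-enrolls: the
type-I error remaining after stage 1, ``A(s1)``, is preserved by recomputing
the final boundary against the attained second-stage size.  Inference on the
observed response count follows the stagewise ordering of Koyama and Chen:
the one-sided p-value sums over all continuing stage-1 paths, with the
second-stage tail evaluated at the attained size, and confidence limits are
obtained by inverting that p-value in the true response probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist
from scipy.stats import binom

__all__ = [
    "DesignHypotheses",
    "TwoStageDesign",
    "OperatingCharacteristics",
    "TrialResult",
    "DesignInference",
    "InfeasibleDesignError",
    "CannotRejectError",
    "exact_reject_prob",
    "operating_characteristics",
    "simon_search",
    "conditional_error",
    "recalibrate_threshold",
    "stagewise_p_value",
    "design_consistent_ci",
    "design_consistent_inference",
    "clopper_pearson",
    "tmb",
]


class InfeasibleDesignError(ValueError):
    """No two-stage design satisfies the error constraints within ``n_max``."""


class CannotRejectError(ValueError):
    """The attained second stage cannot produce enough responses to reject."""


@dataclass(frozen=True)
class DesignHypotheses:
    """Null/alternative response probabilities with one-sided error bounds."""

    p0: float
    p1: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 < self.p1 <= 1.0:
            raise ValueError(f"require 0 <= p0 < p1 <= 1, got p0={self.p0}, p1={self.p1}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0,1), got {self.beta}")


@dataclass(frozen=True)
class TwoStageDesign:
    """A (r1, n1, r, n) two-stage boundary: stop if X1 <= r1, positive if total >= r+1."""

    hypotheses: DesignHypotheses
    r1: int
    n1: int
    r: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.r1 < self.n1 < self.n):
            raise ValueError(f"require 0 <= r1 < n1 < n, got r1={self.r1}, n1={self.n1}, n={self.n}")
        if not (self.r1 <= self.r < self.n):
            raise ValueError(f"require r1 <= r < n, got r1={self.r1}, r={self.r}, n={self.n}")

    @property
    def n2(self) -> int:
        return self.n - self.n1

    def to_dict(self) -> dict:
        return {
            "r1": self.r1,
            "n1": self.n1,
            "r": self.r,
            "n": self.n,
            "p0": self.hypotheses.p0,
            "p1": self.hypotheses.p1,
            "alpha": self.hypotheses.alpha,
            "beta": self.hypotheses.beta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoStageDesign":
        hyp = DesignHypotheses(p0=d["p0"], p1=d["p1"], alpha=d["alpha"], beta=d["beta"])
        return cls(hypotheses=hyp, r1=d["r1"], n1=d["n1"], r=d["r"], n=d["n"])


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Rejection probability, early-termination probability and expected N at a given p."""

    reject_prob: float
    pet: float
    en: float


@dataclass(frozen=True)
class TrialResult:
    """Observed responses: stage-1 count, total count, and attained total enrollment."""

    s1: int
    s_total: int
    n_attained: int

    def __post_init__(self) -> None:
        if not 0 <= self.s1 <= self.s_total:
            raise ValueError(f"require 0 <= s1 <= s_total, got s1={self.s1}, s_total={self.s_total}")
        if self.s_total > self.n_attained:
            raise ValueError(f"s_total={self.s_total} exceeds n_attained={self.n_attained}")


@dataclass(frozen=True)
class DesignInference:
    """Design-consistent inference on the true response probability."""

    p_value: float
    point_estimate: float
    ci_low: float
    ci_high: float
    level: float
    threshold_recal: int | None = None


def _check_prob(p: float, name: str = "p") -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0,1], got {p}")


def exact_reject_prob(design: TwoStageDesign, p: float) -> float:
    """Probability that the design declares the regimen positive at true rate ``p``.

    Sums over continuing stage-1 paths: sum_{x1=r1+1..n1} b(x1; n1, p) *
    Pr[X2 >= r+1-x1; n2, p].
    """
    _check_prob(p)
    x1 = np.arange(design.r1 + 1, design.n1 + 1)
    # sf(k) = P[X > k] so P[X2 >= r+1-x1] = sf(r - x1); clip handles x1 > r
    tails = np.where(x1 > design.r, 1.0, binom.sf(design.r - x1, design.n2, p))
    return float(np.sum(binom.pmf(x1, design.n1, p) * tails))


def operating_characteristics(design: TwoStageDesign, p: float) -> OperatingCharacteristics:
    """PET, expected sample size, and rejection probability at true rate ``p``."""
    _check_prob(p)
    pet = float(binom.cdf(design.r1, design.n1, p))
    en = design.n1 + (1.0 - pet) * design.n2
    return OperatingCharacteristics(
        reject_prob=exact_reject_prob(design, p), pet=pet, en=en
    )


def _feasible_designs(hyp: DesignHypotheses, n_max: int):
    """Yield (en_p0, n, n1, r1, r) for every feasible design with n <= n_max."""
    p0, p1, alpha, beta = hyp.p0, hyp.p1, hyp.alpha, hyp.beta
    for n in range(2, n_max + 1):
        for n1 in range(1, n):
            n2 = n - n1
            k1 = np.arange(n1 + 1)
            pmf1_0 = binom.pmf(k1, n1, p0)
            pmf1_1 = binom.pmf(k1, n1, p1)
            cdf1_1 = np.cumsum(pmf1_1)
            pmf2_0 = binom.pmf(np.arange(n2 + 1), n2, p0)
            pmf2_1 = binom.pmf(np.arange(n2 + 1), n2, p1)
            for r1 in range(0, n1):
                # power cannot exceed the continuation probability under p1
                if cdf1_1[r1] > beta:
                    break
                cont0 = pmf1_0.copy()
                cont0[: r1 + 1] = 0.0
                cont1 = pmf1_1.copy()
                cont1[: r1 + 1] = 0.0
                tot0 = np.convolve(cont0, pmf2_0)
                tot1 = np.convolve(cont1, pmf2_1)
                tail0 = np.cumsum(tot0[::-1])[::-1]  # tail0[t] = P[continue & total >= t]
                tail1 = np.cumsum(tot1[::-1])[::-1]
                # smallest r with type-I error <= alpha; power decreases in r,
                # so only that r can satisfy both constraints
                ok = np.nonzero(tail0[1:] <= alpha)[0]
                if ok.size == 0:
                    continue
                r = int(max(ok[0], r1))
                while tail0[r + 1] > alpha:
                    r += 1
                if r >= n:
                    continue
                if tail1[r + 1] >= 1.0 - beta:
                    pet0 = float(np.sum(pmf1_0[: r1 + 1]))
                    en = n1 + (1.0 - pet0) * n2
                    yield (en, n, n1, r1, r)


def simon_search(hyp: DesignHypotheses, n_max: int = 100) -> dict[str, TwoStageDesign]:
    """Exhaustive search for the optimal and minimax two-stage designs.

    The optimal design minimizes the expected sample size under the null
    hypothesis; the minimax design minimizes the total planned sample size
    (breaking ties by expected null sample size).  Remaining ties break by
    smaller ``n`` then smaller ``n1`` for a deterministic result.
    """
    feasible = list(_feasible_designs(hyp, n_max))
    if not feasible:
        raise InfeasibleDesignError(
            f"no feasible two-stage design with n <= {n_max} for "
            f"p0={hyp.p0}, p1={hyp.p1}, alpha={hyp.alpha}, beta={hyp.beta}"
        )

    def build(rec) -> TwoStageDesign:
        _, n, n1, r1, r = rec
        return TwoStageDesign(hypotheses=hyp, r1=r1, n1=n1, r=r, n=n)

    opt = min(feasible, key=lambda f: (f[0], f[1], f[2]))
    mmx = min(feasible, key=lambda f: (f[1], f[0], f[2]))
    return {"optimal": build(opt), "minimax": build(mmx)}


def conditional_error(design: TwoStageDesign, s1: int) -> float:
    """Type-I error remaining after observing ``s1`` stage-1 responses.

    A(s1) = Pr[X2 >= r+1-s1; n2, p0] for continuing trials; 0 below the
    futility boundary, 1 once the final boundary is already crossed.
    """
    if not 0 <= s1 <= design.n1:
        raise ValueError(f"s1 must be in [0, n1={design.n1}], got {s1}")
    if s1 <= design.r1:
        return 0.0
    if s1 >= design.r + 1:
        return 1.0
    return float(binom.sf(design.r - s1, design.n2, design.hypotheses.p0))


def recalibrate_threshold(design: TwoStageDesign, s1: int, n2_attained: int) -> int:
    """Minimum total responses rejecting H0 at the attained second-stage size.

    Returns the smallest integer ``m`` with
    Pr[X2 >= m - s1; n2_attained, p0] <= A(s1), so the conditional (and hence
    unconditional) type-I error of the original design is preserved.
    """
    if s1 <= design.r1:
        raise ValueError(
            f"stage 2 never opened: s1={s1} <= r1={design.r1}; recalibration undefined"
        )
    if n2_attained < 0:
        raise ValueError(f"n2_attained must be >= 0, got {n2_attained}")
    a = conditional_error(design, s1)
    p0 = design.hypotheses.p0
    for m in range(s1, s1 + n2_attained + 1):
        # P[X2 >= m - s1] with the convention that an empty requirement is 1
        k = m - s1
        tail = 1.0 if k <= 0 else float(binom.sf(k - 1, n2_attained, p0))
        if tail <= a:
            return m
    raise CannotRejectError(
        f"no attainable total response count rejects H0: s1={s1}, "
        f"n2_attained={n2_attained}, conditional error A={a:.6g}"
    )


def stagewise_p_value(
    design: TwoStageDesign, result: TrialResult, p: float | None = None
) -> float:
    """One-sided p-value under the stagewise ordering at the attained size.

    p = sum_{m1=r1+1..n1} b(m1; n1, p0) * Pr[X2 >= s_total - m1; n2*, p0],
    where n2* = n_attained - n1 and the second-stage tail is 1 whenever the
    stage-1 count alone already reaches ``s_total``.  Passing ``p`` evaluates
    the same tail probability at an arbitrary response rate (used for
    confidence-limit inversion).
    """
    if result.n_attained < design.n1:
        raise ValueError(
            f"n_attained={result.n_attained} below stage-1 size n1={design.n1}; "
            "stage-1 enrollment deviations are not supported"
        )
    if result.s1 > design.n1:
        raise ValueError(f"s1={result.s1} exceeds n1={design.n1}")
    if result.s1 <= design.r1:
        raise ValueError(
            f"trial stopped at stage 1 (s1={result.s1} <= r1={design.r1}); "
            "stagewise inference applies to trials that opened stage 2"
        )
    prob = design.hypotheses.p0 if p is None else p
    _check_prob(prob)
    n2s = result.n_attained - design.n1
    m1 = np.arange(design.r1 + 1, design.n1 + 1)
    deficit = result.s_total - m1
    tails = np.where(deficit <= 0, 1.0, binom.sf(deficit - 1, n2s, prob))
    return float(np.sum(binom.pmf(m1, design.n1, prob) * tails))


def design_consistent_ci(
    design: TwoStageDesign, result: TrialResult, level: float = 0.95
) -> tuple[float, float]:
    """Two-sided confidence interval by inverting the stagewise p-value.

    The lower limit solves p-value(p) = (1-level)/2 and the upper limit solves
    p-value(p) = 1 - (1-level)/2; the p-value is monotone increasing in p, so
    each root is unique.  Bounds are clipped to [0, 1].
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    tail = (1.0 - level) / 2.0

    def f(p: float, target: float) -> float:
        return stagewise_p_value(design, result, p=p) - target

    eps = 1e-12
    lo = 0.0 if f(eps, tail) >= 0 else brentq(f, eps, 1 - eps, args=(tail,), xtol=1e-8)
    hi = (
        1.0
        if f(1 - eps, 1 - tail) <= 0
        else brentq(f, eps, 1 - eps, args=(1 - tail,), xtol=1e-8)
    )
    return (float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1)))


def design_consistent_inference(
    design: TwoStageDesign, result: TrialResult, level: float = 0.95
) -> DesignInference:
    """Bundle p-value, point estimate, CI and recalibrated boundary for a trial."""
    ci = design_consistent_ci(design, result, level)
    try:
        thr = recalibrate_threshold(design, result.s1, result.n_attained - design.n1)
    except CannotRejectError:
        thr = None
    return DesignInference(
        p_value=stagewise_p_value(design, result),
        point_estimate=result.s_total / result.n_attained,
        ci_low=ci[0],
        ci_high=ci[1],
        level=level,
        threshold_recal=thr,
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval from beta-distribution quantiles."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0,1), got {level}")
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(beta_dist.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1.0 - a, k + 1, n - k))
    return (lo, hi)


def tmb(n_nonsyn: float, capture_mb: float) -> float:
    """Tumor mutational burden: non-synonymous somatic mutations per captured Mb."""
    if capture_mb <= 0:
        raise ValueError(f"capture size must be positive, got {capture_mb} Mb")
    if n_nonsyn < 0:
        raise ValueError(f"mutation count must be >= 0, got {n_nonsyn}")
    return n_nonsyn / capture_mb
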