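"""Synthetic trial outcomes and expression cohorts with planted structure.

Two generators give every pipeline stage a test surface without any external
download.  ``simulate_trial`` draws two-stage binomial trial outcomes under a
true response rate, applying the conditional-error recalibrated boundary when
the attained enrollment differs from plan.  ``simulate_expression_cohort``
draws a negative-binomial gene-by-sample count matrix for two clinical-benefit
groups with named planted gene programs (log2 fold-changes applied in one
group), and progression-free survival whose hazard is log-linear in a true
per-sample signature score, right-censored at a fixed horizon.

All randomness flows from a single seed through spawned substreams, so a
cohort is a pure function of (config, seed) and components can be re-drawn
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TwoStageDesign, recalibrate_threshold
from .io import CLINICAL_COLUMNS

__all__ = [
    "TrialSimConfig",
    "PlantedSet",
    "SyntheticCohortConfig",
    "simulate_trial",
    "simulate_expression_cohort",
]


@dataclass(frozen=True)
class TrialSimConfig:
    """Replicated two-stage trial simulation settings."""

    design: TwoStageDesign
    p_true: float
    n_attained: int
    reps: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_true <= 1.0:
            raise ValueError(f"p_true must be in [0,1], got {self.p_true}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n_attained < self.design.n1:
            raise ValueError("n_attained cannot be below the stage-1 size")


@dataclass(frozen=True)
class PlantedSet:
    """A named gene program: member gene indices, log2 fold-change, favored group."""

    name: str
    gene_indices: tuple[int, ...]
    lfc: float
    up_in: str  # "CB" or "NCB"

    def __post_init__(self) -> None:
        if self.up_in not in ("CB", "NCB"):
            raise ValueError(f"up_in must be 'CB' or 'NCB', got {self.up_in!r}")
        if len(set(self.gene_indices)) != len(self.gene_indices):
            raise ValueError(f"planted set {self.name!r} has duplicate gene indices")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All knobs of the expression-cohort generator.

    Baseline log2 mean counts are uniform over ``baseline_logmean_range`` and
    per-gene dispersions uniform over ``nb_dispersion`` (variance mu + a*mu^2).
    The survival link uses the planted set named ``survival_set`` (oriented so
    that higher score means higher hazard when ``hazard_theta`` > 0):
    PFS ~ Exponential(rate = baseline_hazard * exp(theta * z(score))),
    censored at ``censor_time`` months.
    """

    n_cb: int = 15
    n_ncb: int = 15
    n_genes: int = 1000
    planted_sets: tuple[PlantedSet, ...] = ()
    nb_dispersion: tuple[float, float] = (0.05, 0.4)
    baseline_logmean_range: tuple[float, float] = (3.0, 9.0)
    hazard_theta: float = 0.8
    baseline_hazard: float = 0.2
    censor_time: float = 24.0
    platinum_resistant_frac: float = 0.7
    seed: int = 0
    arm: str = "A"
    survival_set: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_cb, self.n_ncb, self.n_genes) < 1:
            raise ValueError("n_cb, n_ncb and n_genes must be positive")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        if not 0 < self.nb_dispersion[0] <= self.nb_dispersion[1]:
            raise ValueError("dispersion range must be positive and ordered")
        for ps in self.planted_sets:
            if ps.gene_indices and max(ps.gene_indices) >= self.n_genes:
                raise ValueError(
                    f"planted set {ps.name!r} indexes gene {max(ps.gene_indices)} "
                    f"but n_genes={self.n_genes}"
                )


def simulate_trial(cfg: TrialSimConfig) -> pd.DataFrame:
    """Simulate replicated two-stage trials; returns one row per replicate.

    Columns: ``s1`` (stage-1 responses), ``continued``, ``s_total``,
    ``rejected``.  Stage 2 opens when s1 > r1; the rejection boundary is the
    original r+1 at planned enrollment and the conditional-error recalibrated
    threshold otherwise.
    """
    d = cfg.design
    rng = np.random.default_rng(cfg.seed)
    s1 = rng.binomial(d.n1, cfg.p_true, size=cfg.reps)
    cont = s1 > d.r1
    n2_att = cfg.n_attained - d.n1
    s2 = np.where(cont, rng.binomial(n2_att, cfg.p_true, size=cfg.reps), 0)
    s_total = s1 + s2
    if cfg.n_attained == d.n:
        thresholds = np.full(cfg.reps, d.r + 1)
    else:
        # recalibrated boundary depends only on s1; cache per value
        cache: dict[int, float] = {}
        thresholds = np.empty(cfg.reps)
        for v in np.unique(s1[cont]):
            try:
                cache[int(v)] = recalibrate_threshold(d, int(v), n2_att)
            except Exception:
                cache[int(v)] = np.inf  # cannot reject from this stage-1 count
        thresholds[:] = np.inf
        for v, thr in cache.items():
            thresholds[s1 == v] = thr
    rejected = cont & (s_total >= thresholds)
    return pd.DataFrame(
        {"s1": s1, "continued": cont, "s_total": s_total, "rejected": rejected}
    )


def _true_scores(cfg: SyntheticCohortConfig, group: np.ndarray) -> np.ndarray:
    """Per-sample true signature score: mean planted log2 shift of the survival set."""
    if cfg.survival_set is None:
        return np.zeros(len(group))
    chosen = [ps for ps in cfg.planted_sets if ps.name == cfg.survival_set]
    if not chosen:
        raise ValueError(f"survival_set {cfg.survival_set!r} is not a planted set")
    ps = chosen[0]
    return np.where(group == ps.up_in, ps.lfc, 0.0)


def simulate_expression_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate (counts, clinical, truth) for a two-group expression cohort.

    counts : genes x samples DataFrame of negative-binomial counts.
    clinical : one row per sample with the standard schema plus the planted
        group and the true (standardized) signature score.
    truth : planted parameters for recovery tests.
    """
    root = np.random.default_rng(cfg.seed)
    ss_expr, ss_surv, ss_misc = [np.random.default_rng(s) for s in
                                 np.random.SeedSequence(cfg.seed).spawn(3)]

    n = cfg.n_cb + cfg.n_ncb
    group = np.array(["CB"] * cfg.n_cb + ["NCB"] * cfg.n_ncb)
    samples = [f"{cfg.arm}_S{i:03d}" for i in range(n)]
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    base_log2 = root.uniform(*cfg.baseline_logmean_range, size=cfg.n_genes)
    disp = root.uniform(*cfg.nb_dispersion, size=cfg.n_genes)
    size_factor = np.exp(ss_misc.normal(0.0, 0.15, size=n))

    lfc = np.zeros((cfg.n_genes, n))
    for ps in cfg.planted_sets:
        idx = np.asarray(ps.gene_indices, int)
        lfc[np.ix_(idx, np.nonzero(group == ps.up_in)[0])] += ps.lfc
    mu = (2.0 ** (base_log2[:, None] + lfc)) * size_factor[None, :]
    # NB with variance mu + a*mu^2: shape n = 1/a, success prob p = n/(n+mu)
    shape = (1.0 / disp)[:, None]
    counts = ss_expr.negative_binomial(shape, shape / (shape + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=samples)

    raw_score = _true_scores(cfg, group)
    sd = raw_score.std()
    z = (raw_score - raw_score.mean()) / sd if sd > 0 else np.zeros(n)
    rate = cfg.baseline_hazard * np.exp(cfg.hazard_theta * z)
    t_event = ss_surv.exponential(1.0 / rate)
    event = t_event <= cfg.censor_time
    pfs = np.minimum(t_event, cfg.censor_time)

    # response categories: documented arbitrary rule sufficient to exercise
    # benefit labelling -- responders are low-risk-score samples that lasted,
    # early progressors are PD, the rest SD
    q25 = np.quantile(z, 0.25) if sd > 0 else np.inf
    response = np.where(
        (z <= q25) & (pfs >= 2.0), "PR", np.where(pfs < 2.0, "PD", "SD")
    )
    platinum = np.where(
        ss_misc.uniform(size=n) < cfg.platinum_resistant_frac, "resistant", "sensitive"
    )
    clinical = pd.DataFrame(
        {
            "sample": samples,
            "arm": cfg.arm,
            "response": response,
            "pfs_months": np.round(pfs, 3),
            "event": event.astype(int),
            "platinum_status": platinum,
            "planted_group": group,
            "true_score": np.round(z, 6),
        }
    )[CLINICAL_COLUMNS + ["planted_group", "true_score"]]

    truth = {
        "seed": cfg.seed,
        "n_cb": cfg.n_cb,
        "n_ncb": cfg.n_ncb,
        "n_genes": cfg.n_genes,
        "hazard_theta": cfg.hazard_theta,
        "baseline_hazard": cfg.baseline_hazard,
        "censor_time": cfg.censor_time,
        "planted_sets": [
            {
                "name": ps.name,
                "gene_names": [genes[i] for i in ps.gene_indices],
                "lfc": ps.lfc,
                "up_in": ps.up_in,
            }
            for ps in cfg.planted_sets
        ],
    }
    return counts_df, clinical, truth
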