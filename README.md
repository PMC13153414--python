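# trialsig

Statistical machinery for single-arm phase-II oncology trials with a
translational transcriptomic companion, built around two needs that arise
together in practice:

1. **Exact two-stage binomial design and inference.** Simon two-stage designs
   (optimal and minimax) found by exhaustive search; exact operating
   characteristics; conditional-error recalibration of the final decision
   boundary when stage 2 under- or over-enrolls; and design-consistent
   (stagewise-ordering) p-values and confidence intervals on the observed
   response rate at the attained sample size.
2. **Signature discovery and scoring from bulk RNA-seq.** Moderated-t gene
   ranking between clinical-benefit groups, preranked gene-set enrichment
   with leading-edge extraction, derivation of a cross-arm resistance
   signature by intersecting leading edges, rank-based single-sample scoring
   (and a z-mean variant for variance-stabilized external cohorts), and
   association of scores with benefit (AUC, Wilcoxon), progression-free
   survival (Spearman) and outcome (Kaplan–Meier / log-rank / hazard ratio).

A synthetic-data module generates two-stage trial outcomes under a true
response rate and negative-binomial expression cohorts with planted gene
programs and score-linked survival, so the full pipeline is testable without
any external data.

## The model in brief

A two-stage design `(r1, n1, r, n)` stops for futility when the stage-1
response count `X1 ≤ r1` and declares the regimen positive when the total
response count reaches `r + 1`. Its rejection probability at true rate `p` is
the exact convolution

```
R(p) = Σ_{x1 = r1+1}^{n1}  b(x1; n1, p) · Pr[X2 ≥ r + 1 − x1; n − n1, p].
```

The search minimizes expected null sample size `EN(p0) = n1 + (1 − PET(p0))(n − n1)`
subject to `R(p0) ≤ α` and `R(p1) ≥ 1 − β`. When the attained second-stage
size `n2*` differs from plan, the conditional error
`A(s1) = Pr[X2 ≥ r + 1 − s1; n − n1, p0]` is preserved: the new boundary is the
smallest total `m` with `Pr[X2* ≥ m − s1; n2*, p0] ≤ A(s1)`. Inference uses the
stagewise-ordering p-value with the second-stage tail evaluated at `n2*`;
confidence limits invert it at tail masses `(1−level)/2` and `1−(1−level)/2`.

On the transcriptomic side, enrichment is the weighted Kolmogorov–Smirnov
running sum over a single moderated-t-ranked gene list (hits weighted by
`|t|^w`), the leading edge is the member prefix at the running-sum extremum,
and the single-sample rank score is the mean within-sample rank of signature
genes rescaled to its theoretical bounds and centered on `[-0.5, 0.5]`.

## Worked example

```python
from trialsig import (DesignHypotheses, TrialResult, simon_search,
                      operating_characteristics, exact_reject_prob,
                      conditional_error, recalibrate_threshold,
                      design_consistent_inference)

hyp = DesignHypotheses(p0=0.20, p1=0.40, alpha=0.10, beta=0.10)
design = simon_search(hyp, n_max=60)["optimal"]
# -> r1=3, n1=17, r=10, n=37: enroll 17; continue on >= 4 responses;
#    positive on >= 11 of 37

oc = operating_characteristics(design, 0.20)
# PET(p0)=0.549  EN(p0)=26.0  alpha=0.0948  power=0.9033

conditional_error(design, 4)            # 0.0867 type-I error left after 4/17
recalibrate_threshold(design, 4, 19)    # 11: boundary at 36 attained patients

inf = design_consistent_inference(design, TrialResult(s1=4, s_total=7, n_attained=36))
# ORR=19.4%  95% CI=(9.5, 43.5)%  p=0.389
```

Read: under-enrollment (36 instead of 37 patients) does not change the
11-response positivity bar here, the observed 7 responses fall short of it,
and the design-consistent interval for the response rate runs from 9.5% to
43.5%.

The same operations are exposed on the command line:

```bash
trialsig design search --p0 0.2 --p1 0.4 --alpha 0.1 --beta 0.1
trialsig design recalibrate --design 3,17,10,37 --p0 0.2 --p1 0.4 --s1 4 --n2-attained 19
trialsig simulate cohort --config cohort.yaml --out cohort/
trialsig run pipeline --config pipeline.yaml --out results/
```

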