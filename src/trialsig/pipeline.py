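"""End-to-end orchestration: design reports and the translational pipeline.

Configuration is a plain nested dict (typically loaded from YAML by the CLI).
Both entry points are deterministic given the config: the design report is
exact arithmetic, and the translational run threads a single seed through
enrichment permutations.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .design import (
    DesignHypotheses,
    TrialResult,
    TwoStageDesign,
    design_consistent_inference,
    operating_characteristics,
    simon_search,
)
from .enrichment import (
    intersect_leading_edges,
    moderated_t_rank,
    normalize_logcpm,
    preranked_gsea,
)
from .io import GeneSet, read_clinical, read_counts, read_gmt, write_json
from .scoring import (
    auc_benefit,
    km_logrank_hr,
    label_benefit,
    median_split,
    rank_tests,
    singscore_up,
    spearman_pfs,
)

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_design_report(config: dict) -> dict:
    """Design search, operating characteristics, recalibration and inference.

    ``config['arms']`` maps arm name to a dict with ``p0, p1, alpha, beta``
    and optionally ``n_max``, ``design`` (r1,n1,r,n to use instead of the
    search result), ``observed`` ({s1, s_total, n_attained}) and ``level``.
    """
    if "arms" not in config or not config["arms"]:
        raise ValueError("config must define at least one arm under 'arms'")
    report: dict = {"version": __version__, "arms": {}}
    for arm, spec in config["arms"].items():
        for key in ("p0", "p1", "alpha", "beta"):
            if key not in spec:
                raise ValueError(f"arm {arm!r}: missing design hypothesis field {key!r}")
        hyp = DesignHypotheses(spec["p0"], spec["p1"], spec["alpha"], spec["beta"])
        found = simon_search(hyp, n_max=spec.get("n_max", 100))
        if "design" in spec:
            d = spec["design"]
            design = TwoStageDesign(hyp, r1=d["r1"], n1=d["n1"], r=d["r"], n=d["n"])
        else:
            design = found["optimal"]
        grid = spec.get("oc_grid", [round(p, 2) for p in np.arange(0.0, 1.0001, 0.05)])
        oc = {
            str(p): vars(operating_characteristics(design, float(p))) for p in grid
        }
        entry = {
            "hypotheses": vars(hyp),
            "optimal": found["optimal"].to_dict(),
            "minimax": found["minimax"].to_dict(),
            "design_used": design.to_dict(),
            "operating_characteristics": oc,
        }
        if "observed" in spec:
            obs = spec["observed"]
            result = TrialResult(obs["s1"], obs["s_total"], obs["n_attained"])
            inf = design_consistent_inference(design, result, level=spec.get("level", 0.95))
            entry["inference"] = {
                "s1": result.s1,
                "s_total": result.s_total,
                "n_attained": result.n_attained,
                "orr": inf.point_estimate,
                "p_value": inf.p_value,
                "ci_low": inf.ci_low,
                "ci_high": inf.ci_high,
                "level": inf.level,
                "threshold_recalibrated": inf.threshold_recal,
                "positive": (
                    inf.threshold_recal is not None
                    and result.s_total >= inf.threshold_recal
                ),
            }
        report["arms"][arm] = entry
    return report


def _associations(scores: pd.Series, clin: pd.DataFrame, flip_auc: bool) -> dict:
    clin = clin.set_index("sample").loc[scores.index]
    out: dict = {}
    cb = scores[clin["benefit"] == "CB"]
    ncb = scores[clin["benefit"] == "NCB"]
    if len(cb) >= 3 and len(ncb) >= 3:
        w = rank_tests(cb.to_numpy(), ncb.to_numpy())
        out["wilcoxon_cb_vs_ncb"] = {"statistic": w.statistic, "p_value": w.p_value}
        a = auc_benefit(scores.to_numpy(), (clin["benefit"] == "CB").to_numpy(), flip=flip_auc)
        out["auc"] = {"auc": a.statistic, "p_value": a.p_value, "flipped": flip_auc}
    sp = spearman_pfs(scores.to_numpy(), clin["pfs_months"].to_numpy())
    out["spearman_pfs"] = {"rho": sp.statistic, "p_value": sp.p_value}
    groups = median_split(scores)
    if clin.loc[groups == "low", "event"].sum() > 0 and clin.loc[groups == "high", "event"].sum() > 0:
        km = km_logrank_hr(clin.reset_index(), groups.to_numpy(), reference="low")
        out["km_median_split"] = {
            "hazard_ratio": km.statistic,
            "hr_ci": [km.ci_low, km.ci_high],
            "logrank_p": km.p_value,
            "median_low": km.extra["curves"]["low"]["median"],
            "median_high": km.extra["curves"]["high"]["median"],
        }
    return out


def run_translational_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Per-arm ranking, enrichment, cross-arm signature, scoring and association.

    ``config`` keys:
      arms: {name: {counts: path, clinical: path}}
      gene_sets: GMT path
      signature_pathways: pathway names whose leading edges are intersected
      gsea: {n_perm, weight, min_size, max_size, seed}
      signatures: optional {name: {pathway: set name in GMT, flip_auc: bool}}
          extra single-sample scores to compute alongside the derived one
      platinum_resistant_only: optional flag restricting AUC to that subset
    """
    gsea_cfg = config.get("gsea", {})
    seed = int(gsea_cfg.get("seed", 0))
    sets = read_gmt(config["gene_sets"])
    set_by_name = {s.name: s for s in sets}

    bundle: dict = {"version": __version__, "seed": seed, "arms": {}, "inputs": {}}
    rankings: dict[str, pd.DataFrame] = {}
    enrichments: dict[str, list] = {}
    logcpms: dict[str, pd.DataFrame] = {}
    clinicals: dict[str, pd.DataFrame] = {}

    for arm, paths in config["arms"].items():
        counts = read_counts(paths["counts"])
        clin = read_clinical(paths["clinical"])
        clin = label_benefit(clin)
        missing = set(counts.columns) - set(clin["sample"])
        if missing:
            raise ValueError(f"arm {arm}: samples without clinical rows: {sorted(missing)[:5]}")
        clin = clin[clin["sample"].isin(counts.columns)].reset_index(drop=True)
        counts = counts[clin["sample"].tolist()]
        logcpm = normalize_logcpm(counts)
        groups = clin.set_index("sample").loc[counts.columns, "benefit"].to_numpy()
        ranking = moderated_t_rank(logcpm, groups)  # statistic: NCB minus CB
        results = preranked_gsea(
            ranking,
            sets,
            weight=float(gsea_cfg.get("weight", 1.0)),
            n_perm=int(gsea_cfg.get("n_perm", 1000)),
            seed=seed,
            min_size=int(gsea_cfg.get("min_size", 5)),
            max_size=int(gsea_cfg.get("max_size", 2000)),
        )
        rankings[arm] = ranking
        enrichments[arm] = results
        logcpms[arm] = logcpm
        clinicals[arm] = clin
        bundle["inputs"][arm] = {
            "counts": str(paths["counts"]),
            "counts_sha256": _sha256(paths["counts"]),
            "clinical": str(paths["clinical"]),
            "clinical_sha256": _sha256(paths["clinical"]),
            "n_samples": int(counts.shape[1]),
            "n_genes": int(counts.shape[0]),
        }
        bundle["arms"][arm] = {
            "n_cb": int((groups == "CB").sum()),
            "n_ncb": int((groups == "NCB").sum()),
            "enrichment": [
                {
                    "set_name": r.set_name,
                    "es": r.es,
                    "nes": r.nes,
                    "p_raw": r.p_raw,
                    "p_adj": r.p_adj,
                    "n_hits": r.n_hits,
                    "n_leading_edge": len(r.leading_edge),
                    "leading_edge": list(r.leading_edge),
                }
                for r in results
            ],
        }

    signature = intersect_leading_edges(
        enrichments, list(config["signature_pathways"]), signature_name="derived_signature"
    )
    bundle["derived_signature"] = signature.sorted_members()

    score_specs: dict[str, tuple[GeneSet, bool]] = {"derived_signature": (signature, True)}
    for name, spec in config.get("signatures", {}).items():
        score_specs[name] = (set_by_name[spec["pathway"]], bool(spec.get("flip_auc", False)))

    for arm in config["arms"]:
        clin = clinicals[arm]
        if config.get("platinum_resistant_only"):
            keep = clin.loc[clin["platinum_status"] == "resistant", "sample"]
            clin = clin[clin["sample"].isin(keep)].reset_index(drop=True)
        arm_scores: dict = {}
        for name, (gs, flip) in score_specs.items():
            sc = singscore_up(logcpms[arm][clin["sample"].tolist()], gs)
            arm_scores[name] = {
                "scores": {s: float(v) for s, v in sc.items()},
                "associations": _associations(sc, clin, flip_auc=flip),
            }
        bundle["arms"][arm]["signature_scores"] = arm_scores

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for arm in config["arms"]:
            rankings[arm].to_csv(out / f"{arm}_ranking.tsv", sep="\t", index=False,
                                 lineterminator="\n")
        write_json(bundle, out / "results.json")
        logger.info("wrote pipeline bundle to %s", out)
    return bundle
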