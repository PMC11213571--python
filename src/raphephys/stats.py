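"""Group-comparison layer and the end-to-end report pipeline.

The testing workflow is the classical gated one: each group is first
checked for normality with a Kolmogorov-Smirnov test (parameters estimated
from the sample; no Lilliefors correction, a deliberate and logged choice);
if every group passes at alpha = 0.05, two groups are compared with an
unpaired t-test and three or more with one-way ANOVA, otherwise with the
Mann-Whitney U test or Kruskal-Wallis. No multiple-testing correction is
applied; every comparison is reported so users can apply their own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

ALPHA = 0.05


def normality_gate(groups: list[np.ndarray], alpha: float = ALPHA) -> bool:
    """True iff every group passes the KS normality test at *alpha*.

    KS is run against a normal with mean/SD estimated from each sample
    (the common-practice variant; conservative without the Lilliefors
    correction). Groups with fewer than 3 values fail the gate with a
    warning: normality is untestable there.
    """
    for g in groups:
        g = np.asarray(g, dtype=float)
        g = g[np.isfinite(g)]
        if len(g) < 3:
            logger.warning("normality gate: group with n=%d is insufficient", len(g))
            return False
        sd = g.std(ddof=1)
        if sd == 0:
            return False
        _, p = sps.kstest(g, "norm", args=(g.mean(), sd))
        if p < alpha:
            return False
    return True


@dataclass
class GroupComparison:
    feature: str
    groups: list[str]
    test: str                       # t | mann-whitney | anova | kruskal-wallis
    statistic: float
    p_value: float
    means: list[float]
    sems: list[float]
    ns: list[int]
    normal: bool = False

    def to_dict(self) -> dict:
        return {
            "feature": self.feature, "groups": self.groups, "test": self.test,
            "statistic": self.statistic, "p_value": self.p_value,
            "means": self.means, "sems": self.sems, "ns": self.ns,
            "normal": self.normal,
        }


def compare(
    feature: str,
    groups: dict[str, np.ndarray],
    alpha: float = ALPHA,
    mwu_method: str = "auto",
) -> GroupComparison:
    """Gated group comparison: t / Mann-Whitney for two groups, ANOVA /
    Kruskal-Wallis for three or more, reporting mean +/- SEM and n per
    group. Missing values are dropped per group."""
    names = list(groups)
    samples = []
    for name in names:
        g = np.asarray(groups[name], dtype=float)
        g = g[np.isfinite(g)]
        if len(g) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        samples.append(g)
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    normal = normality_gate(samples, alpha=alpha)
    if len(samples) == 2:
        if normal:
            stat, p = sps.ttest_ind(*samples)
            test = "t"
        else:
            res = sps.mannwhitneyu(*samples, alternative="two-sided", method=mwu_method)
            stat, p = res.statistic, res.pvalue
            test = "mann-whitney"
    else:
        if normal:
            stat, p = sps.f_oneway(*samples)
            test = "anova"
        else:
            stat, p = sps.kruskal(*samples)
            test = "kruskal-wallis"
    return GroupComparison(
        feature=feature, groups=names, test=test,
        statistic=float(stat), p_value=float(p),
        means=[float(g.mean()) for g in samples],
        sems=[float(g.std(ddof=1) / math.sqrt(len(g))) for g in samples],
        ns=[len(g) for g in samples],
        normal=normal,
    )


def percent_active(n_active: int, n_total: int) -> int:
    """Percentage of spontaneously active cells, rounded to the nearest
    integer with halves away from zero (11/30 -> 37)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_active <= n_total:
        raise ValueError("need 0 <= n_active <= n_total")
    return int(math.floor(100.0 * n_active / n_total + 0.5))


# ---------------------------------------------------------------------------
# report pipeline


DEFAULT_CONFIG = {
    "seed": 0,
    "n_per_group": 12,
    "phenotype": "serotonergic",
    "groups": {
        "Sham": {},
        "DMI+6-OHDA": {"spontaneous_fraction": 0.72, "ahp_tau_ms": {"mul": 0.85}},
    },
    "classify": {"enabled": True, "n_serotonergic": 15, "n_dopaminergic": 15},
    "morphology": {"n_cells": 10, "circularity": [0.85, 0.65]},
    "features": ["rheobase", "tau", "capacitance", "input_resistance", "ahp_duration"],
}

_REQUIRED_KEYS = ("seed", "n_per_group", "phenotype", "groups")


def _validate_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    if not isinstance(cfg["groups"], dict) or not cfg["groups"]:
        raise ValueError("config 'groups' must be a non-empty mapping")
    if cfg["n_per_group"] < 2:
        raise ValueError("n_per_group must be >= 2")
    if cfg["classify"].get("enabled"):
        total = cfg["classify"]["n_serotonergic"] + cfg["classify"]["n_dopaminergic"]
        if total < 4:
            raise ValueError("classification requires at least 4 cells")
    return cfg


def run_pipeline(config: dict | None = None, out_dir: str | Path | None = None) -> dict:
    """End-to-end demo pipeline: simulate cohorts, extract feature panels,
    classify cell types, compute morphometrics and group statistics, and
    (optionally) write TSV/JSON reports plus a log to *out_dir*.

    Deterministic for a fixed config (timestamps excepted). Returns the
    report as a dict.
    """
    from . import classify as clf
    from . import features as feats
    from . import morpho, synth

    cfg = _validate_config(config or {})
    seed = int(cfg["seed"])
    out = {"config": cfg, "seed": seed,
           "config_hash": hashlib.sha256(
               json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]}

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out_dir / "run.log")
        logging.getLogger("raphephys").addHandler(handler)
    logger.info("pipeline start: seed=%d hash=%s", seed, out["config_hash"])

    # cohort simulation + panel extraction
    cells = synth.make_cohort(
        int(cfg["n_per_group"]), cfg["groups"], seed=seed, phenotype=cfg["phenotype"]
    )
    panels = [
        feats.extract_panel(c.bundle, target_rate=c.params.target_rate_hz)
        for c in cells
    ]
    for p, c in zip(panels, cells):
        p.group = c.group
    panel_df = feats.panels_to_frame(panels)
    out["n_cells"] = len(panels)

    # spontaneous-activity proportions per group
    activity = {}
    for group in cfg["groups"]:
        sub = panel_df[panel_df["group"] == group]
        n_active = int((sub["spontaneous"] == True).sum())  # noqa: E712
        activity[group] = {
            "n_active": n_active, "n_total": len(sub),
            "percent_active": percent_active(n_active, len(sub)) if len(sub) else None,
        }
    out["spontaneous_activity"] = activity

    # group statistics on extracted features
    comparisons = []
    for feat in cfg["features"]:
        groups = {}
        for group in cfg["groups"]:
            vals = panel_df.loc[panel_df["group"] == group, feat].dropna().to_numpy()
            if len(vals) >= 2:
                groups[group] = vals
        if len(groups) >= 2:
            comparisons.append(compare(feat, groups).to_dict())
    out["comparisons"] = comparisons

    # two-type classification on a fresh typed cohort
    if cfg["classify"].get("enabled"):
        typed = synth.make_typed_cohort(
            {"serotonergic": int(cfg["classify"]["n_serotonergic"]),
             "dopaminergic": int(cfg["classify"]["n_dopaminergic"])},
            seed=seed + 1, include_zero=False,
        )
        tpanels = [
            feats.extract_panel(c.bundle, target_rate=c.params.target_rate_hz)
            for c in typed
        ]
        result = clf.classify_two_types(tpanels)
        out["classification"] = {
            "n_clustered": len(result.labels),
            "n_excluded": result.n_excluded,
            "purity": result.purity(),
            "explained_variance": result.explained_variance[:2].tolist(),
        }

    # morphometrics on generated fixtures
    morph_cfg = cfg.get("morphology", {})
    n_morph = int(morph_cfg.get("n_cells", 0))
    rows = []
    rng = np.random.default_rng(seed + 2)
    for k in range(n_morph):
        target = morph_cfg["circularity"][k % len(morph_cfg["circularity"])]
        contour = morpho.SomaContour(
            synth.make_soma_polygon(target, scale=8.0, seed=int(rng.integers(2**31)))
        )
        sm = morpho.soma_metrics(contour)
        tree = synth.make_tree(
            int(rng.integers(2, 6)), int(rng.integers(0, 7)),
            seed=int(rng.integers(2**31)),
        )
        tm = morpho.tree_metrics(tree)
        rows.append({
            "cell": f"morph_{k:02d}", "area": sm.area, "perimeter": sm.perimeter,
            "major_axis": sm.major_axis, "minor_axis": sm.minor_axis,
            "circularity": sm.circularity,
            "n_primary_dendrites": tm.n_primary_dendrites,
            "n_bifurcations": tm.n_bifurcations,
            "n_terminations": tm.n_terminations,
            "total_length": tm.total_length,
        })
    out["morphometrics"] = rows

    if out_dir is not None:
        panel_df.to_csv(out_dir / "feature_panels.tsv", sep="\t", index=False)
        if rows:
            import pandas as pd

            pd.DataFrame(rows).to_csv(out_dir / "morphometrics.tsv", sep="\t", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(out, fh, indent=1, default=str)
        logger.info("pipeline done: %d cells", out["n_cells"])
    return out
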