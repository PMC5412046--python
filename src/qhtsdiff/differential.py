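"""Differential pharmacology between two screened cell lines.

Given per-curve metrics for the same compound library in two cell lines, this
module calls

* **selectively active MOA classes** -- class-mean AUC ratio between the
  lines, flagged when the z-score of the log ratio across classes is >= 2 SD
  from the mean,
* **stringent potency hits** -- high-quality curve class in line A combined
  with a >= 10-fold potency advantage (delta-logAC50 < -1),
* **shared hits** -- near-complete cell killing in both lines
  (MAXR < 30% each),
* **target enrichment** -- per-target two-tailed Fisher's exact test of a hit
  set against the whole annotated library, Benjamini-Hochberg adjusted,
* the **expression-drug overlay** -- drug targets whose expression differs
  more than a fold-change threshold, paired with the potency/efficacy deltas
  of the compounds annotated against them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .crc import HIGH_QUALITY_CODES
from .screen_sim import CompoundAnnotation

__all__ = [
    "class_auc_differential",
    "stringent_potency_hits",
    "shared_maxr_hits",
    "fisher_target_enrichment",
    "fisher_two_tailed",
    "bh_adjust",
    "expression_drug_overlay",
]

#: Floor for the denominator of the class-mean AUC ratio (AUC units); keeps
#: the ratio finite for classes inactive in line B.
AUC_RATIO_FLOOR = 1.0


def _require_metrics(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{name} metrics lack columns: {sorted(missing)}")


def class_auc_differential(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    annotations: Sequence[CompoundAnnotation],
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Call selectively active MOA classes from class-mean AUC ratios.

    For each class: mean AUC per line over its compounds, percent ratio
    100 * mean_A / max(mean_B, floor), and a z-score of the log2 ratio across
    all classes.  ``selective_a`` iff z >= +z_threshold (more active in line
    A), ``selective_b`` iff z <= -z_threshold.  The z-score lives on the log
    scale so that swapping the two lines exactly negates it.
    """
    _require_metrics(metrics_a, ["compound_id", "auc"], "line A")
    _require_metrics(metrics_b, ["compound_id", "auc"], "line B")
    auc_a = metrics_a.set_index("compound_id")["auc"]
    auc_b = metrics_b.set_index("compound_id")["auc"]
    common = auc_a.index.intersection(auc_b.index)
    if len(common) == 0:
        raise ValueError("metric tables share no compound ids")

    by_class: dict[str, list[str]] = {}
    for ann in annotations:
        if ann.compound_id in common:
            by_class.setdefault(ann.moa_class, []).append(ann.compound_id)
    for moa in sorted({a.moa_class for a in annotations} - set(by_class)):
        warnings.warn(f"MOA class {moa!r} has no measured compounds; omitted",
                      stacklevel=2)

    rows = []
    for moa, cids in sorted(by_class.items()):
        ma = float(auc_a.loc[cids].mean())
        mb = float(auc_b.loc[cids].mean())
        ratio = 100.0 * max(ma, AUC_RATIO_FLOOR) / max(mb, AUC_RATIO_FLOOR)
        rows.append(
            {
                "moa_class": moa,
                "n_compounds": len(cids),
                "mean_auc_line_a": ma,
                "mean_auc_line_b": mb,
                "auc_ratio_pct": ratio,
                "log2_ratio": float(np.log2(ratio / 100.0)),
            }
        )
    out = pd.DataFrame(rows)
    lr = out["log2_ratio"].to_numpy()
    sd = float(np.std(lr, ddof=1)) if len(lr) > 1 else 0.0
    if sd > 0:
        out["zscore"] = (lr - lr.mean()) / sd
    else:
        out["zscore"] = 0.0
    out["call"] = "none"
    out.loc[out["zscore"] >= z_threshold, "call"] = "selective_a"
    out.loc[out["zscore"] <= -z_threshold, "call"] = "selective_b"
    return out


def _censored_logac50(
    metrics: pd.DataFrame, top_log10_molar: float
) -> tuple[pd.Series, pd.Series]:
    """logAC50 with right-censoring: unconverged/inactive compounds are
    assigned the top tested concentration (counts as less potent)."""
    lac = metrics.set_index("compound_id")["logac50"].astype(float)
    censored = ~np.isfinite(lac)
    return lac.fillna(top_log10_molar), censored


def stringent_potency_hits(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    top_log10_molar: float,
    delta_threshold: float = -1.0,
) -> set[str]:
    """Compounds with a high-quality curve class in line A and
    logAC50(A) - logAC50(B) < ``delta_threshold`` (default: >=10-fold more
    potent in line A).  Compounds without a finite logAC50 in line B are
    right-censored at the top tested concentration."""
    _require_metrics(metrics_a, ["compound_id", "crc", "logac50"], "line A")
    _require_metrics(metrics_b, ["compound_id", "logac50"], "line B")
    crc_a = metrics_a.set_index("compound_id")["crc"].astype(float)
    lac_a = metrics_a.set_index("compound_id")["logac50"].astype(float)
    lac_b, _ = _censored_logac50(metrics_b, top_log10_molar)
    hits = set()
    for cid, code in crc_a.items():
        if round(code, 1) not in {round(c, 1) for c in HIGH_QUALITY_CODES}:
            continue
        a = lac_a.loc[cid]
        if not np.isfinite(a):
            continue
        b = lac_b.loc[cid] if cid in lac_b.index else top_log10_molar
        if a - b < delta_threshold:
            hits.add(str(cid))
    return hits


def shared_maxr_hits(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    threshold_pct: float = 30.0,
) -> set[str]:
    """Compounds achieving >= (100 - threshold)% cell killing at the top dose
    in BOTH lines (MAXR < threshold in each)."""
    _require_metrics(metrics_a, ["compound_id", "maxr_pct"], "line A")
    _require_metrics(metrics_b, ["compound_id", "maxr_pct"], "line B")
    ma = metrics_a.set_index("compound_id")["maxr_pct"]
    mb = metrics_b.set_index("compound_id")["maxr_pct"]
    common = ma.index.intersection(mb.index)
    sel = (ma.loc[common] < threshold_pct) & (mb.loc[common] < threshold_pct)
    return set(map(str, common[sel]))


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio and two-tailed Fisher exact p for the 2x2 table [[a,b],[c,d]].

    Two-tailed means the sum of hypergeometric probabilities of all tables
    with the same margins that are no more likely than the observed one.
    """
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforced.

    Stable under permutation of the input (q-values permute correspondingly).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_target_enrichment(
    selected_ids: set[str],
    annotations: Sequence[CompoundAnnotation],
    q_threshold: float = 0.01,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-target two-tailed Fisher's exact enrichment of a hit set.

    Background = the full annotated library (selected set included).  Each
    target's 2x2 table is [selected & target, selected & not; unselected &
    target, unselected & not].  Multi-target compounds count once per
    annotated target.  Both BH-adjusted (q) and raw-p significance flags are
    reported.
    """
    lib_ids = {a.compound_id for a in annotations}
    stray = selected_ids - lib_ids
    if stray:
        raise ValueError(
            f"selected compounds missing from annotations: {sorted(stray)[:5]}"
        )
    target_members: dict[str, set[str]] = {}
    for ann in annotations:
        for t in ann.targets:
            target_members.setdefault(t, set()).add(ann.compound_id)

    n_total = len(lib_ids)
    n_sel = len(selected_ids)
    rows = []
    for target, members in sorted(target_members.items()):
        a = len(selected_ids & members)
        b = n_sel - a
        c = len(members) - a
        d = n_total - n_sel - c
        odds, p = fisher_two_tailed(a, b, c, d)
        rows.append(
            {"target": target, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": float(odds), "p_value": float(p)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["significant_q"] = out["q_value"] < q_threshold
        out["significant_p"] = out["p_value"] < p_threshold
        out = out.sort_values("p_value", kind="stable").reset_index(drop=True)
    return out


def expression_drug_overlay(
    de_results: pd.DataFrame,
    annotations: Sequence[CompoundAnnotation],
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    top_log10_molar: float,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Overlay differential expression of druggable targets with the
    potency/efficacy deltas of the compounds annotated against them.

    Rows: targets with |log2 FC| >= log2(fc_threshold) between the lines.
    Columns carry the target's fold-change direction and the median and
    spread of delta-logAC50 (line A - line B, right-censored at the top
    tested concentration) and delta-MAXR over that target's compounds.
    """
    if "gene" not in de_results.columns or "log2_fc" not in de_results.columns:
        raise ValueError("de_results must carry 'gene' and 'log2_fc' columns")
    fc_by_gene = de_results.set_index("gene")["log2_fc"].astype(float)

    target_members: dict[str, list[str]] = {}
    for ann in annotations:
        for t in ann.targets:
            target_members.setdefault(t, []).append(ann.compound_id)
    overlap = [t for t in target_members if t in fc_by_gene.index]
    if not overlap:
        warnings.warn("no annotated target has a DE measurement", stacklevel=2)
        return pd.DataFrame(
            columns=["target", "log2_fc", "direction", "n_compounds",
                     "median_delta_logac50", "iqr_delta_logac50",
                     "median_delta_maxr", "n_censored"]
        )

    lac_a, cen_a = _censored_logac50(metrics_a, top_log10_molar)
    lac_b, cen_b = _censored_logac50(metrics_b, top_log10_molar)
    maxr_a = metrics_a.set_index("compound_id")["maxr_pct"]
    maxr_b = metrics_b.set_index("compound_id")["maxr_pct"]

    cutoff = np.log2(fc_threshold)
    rows = []
    for target in sorted(overlap):
        fc = float(fc_by_gene.loc[target])
        if abs(fc) < cutoff:
            continue
        cids = [c for c in target_members[target]
                if c in lac_a.index and c in lac_b.index]
        if not cids:
            continue
        dl = (lac_a.loc[cids] - lac_b.loc[cids]).to_numpy()
        dm = (maxr_a.loc[cids] - maxr_b.loc[cids]).to_numpy()
        q1, q3 = np.percentile(dl, [25, 75])
        rows.append(
            {
                "target": target,
                "log2_fc": fc,
                "direction": "up" if fc > 0 else "down",
                "n_compounds": len(cids),
                "median_delta_logac50": float(np.median(dl)),
                "iqr_delta_logac50": float(q3 - q1),
                "median_delta_maxr": float(np.median(dm)),
                "n_censored": int((cen_a.loc[cids] | cen_b.loc[cids]).sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["target", "log2_fc", "direction", "n_compounds",
                 "median_delta_logac50", "iqr_delta_logac50",
                 "median_delta_maxr", "n_censored"],
    )
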