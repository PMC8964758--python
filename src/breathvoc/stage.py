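"""Stage-distance, single-marker ROC, and pre/post-treatment response
analyses.

The severity hypothesis: HCC samples lying farther from the SVM decision
boundary (signed RKHS distance, :meth:`breathvoc.classify.BreathSVC.signed_distance`)
are at more advanced BCLC stages. This module summarizes per-stage mean ±
SD distances with a Spearman trend, evaluates single VOC markers by ROC
(AUC via the Mann–Whitney concordance estimator with ties counted ½), and
classifies treatment response from pre/post abundance changes on the raw
AU scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import BreathSVC, CVMetrics
from .cohort import STAGE_ORDER
from .stats import TestResult, mann_whitney_u, paired_t

__all__ = [
    "StageDistanceSummary",
    "ROCResult",
    "DeltaRecord",
    "stage_distances",
    "roc_curve",
    "evaluate_cutoff",
    "youden_optimal_cutoff",
    "paired_deltas",
    "response_analysis",
]


@dataclass
class StageDistanceSummary:
    """Per-BCLC-stage boundary-distance summary plus a monotone-trend check."""

    table: pd.DataFrame  # index stage, columns n/mean/sd
    spearman_rho: float
    spearman_p: float
    notes: list

    @property
    def means(self) -> pd.Series:
        return self.table["mean"]


def stage_distances(model: BreathSVC, X, stages) -> StageDistanceSummary:
    """Mean ± SD signed distance per BCLC stage, in ordinal stage order.

    Stages with no samples are omitted with a note; single-sample stages
    report SD 0 with an ``n=1`` note. The Spearman correlation of stage
    rank vs distance is the auxiliary trend statistic.
    """
    stages = np.asarray(stages, dtype=str)
    d = model.signed_distance(np.asarray(X, dtype=float))
    if len(d) != len(stages):
        raise ValueError("one stage label per sample required")
    rows, notes = [], []
    for s in STAGE_ORDER:
        mask = stages == s
        n = int(mask.sum())
        if n == 0:
            notes.append(f"stage {s}: no samples, omitted")
            continue
        if n == 1:
            notes.append(f"stage {s}: single sample, SD reported as 0")
        rows.append({"stage": s, "n": n, "mean": float(d[mask].mean()),
                     "sd": float(d[mask].std(ddof=1)) if n > 1 else 0.0})
    table = pd.DataFrame(rows).set_index("stage")
    rank = np.array([STAGE_ORDER.index(s) for s in stages])
    if len(np.unique(rank)) > 1 and len(np.unique(d)) > 1:
        rho, p = sps.spearmanr(rank, d)
    else:
        rho, p = float("nan"), float("nan")
    return StageDistanceSummary(table=table, spearman_rho=float(rho),
                                spearman_p=float(p), notes=notes)


@dataclass
class ROCResult:
    """Cutoff grid with per-cutoff metrics and the Mann–Whitney AUC.

    ``direction`` is "higher" when larger marker values indicate the
    positive class, "lower" otherwise. Cutoffs are strictly increasing:
    midpoints between consecutive sorted unique marker values plus ±∞.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray
    auc: float
    direction: str
    chosen_cutoff: float | None = None

    def at_cutoff(self, cutoff: float) -> dict:
        i = int(np.argmin(np.abs(self.cutoffs - cutoff)))
        return {"cutoff": float(self.cutoffs[i]), "sensitivity": float(self.sensitivity[i]),
                "specificity": float(self.specificity[i]), "accuracy": float(self.accuracy[i])}

    def to_dict(self) -> dict:
        return {
            "cutoffs": self.cutoffs.tolist(), "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(), "accuracy": self.accuracy.tolist(),
            "auc": self.auc, "direction": self.direction, "chosen_cutoff": self.chosen_cutoff,
        }


def _check_direction(direction: str) -> None:
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")


def evaluate_cutoff(values, labels, cutoff: float, direction: str = "higher") -> CVMetrics:
    """Confusion counts at one cutoff; the boundary value counts as
    positive (marker ≥ cutoff for direction='higher', ≤ for 'lower')."""
    _check_direction(direction)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if not np.isfinite(cutoff) and not np.isinf(cutoff):
        raise ValueError("cutoff must be a number")
    pred = values >= cutoff if direction == "higher" else values <= cutoff
    return CVMetrics(
        tp=int(np.sum(pred & labels)), tn=int(np.sum(~pred & ~labels)),
        fp=int(np.sum(pred & ~labels)), fn=int(np.sum(~pred & labels)),
    )


def roc_curve(values, labels, direction: str = "higher") -> ROCResult:
    """ROC over the midpoint cutoff grid with the Mann–Whitney AUC.

    AUC = P(marker_case > marker_control) + ½ P(tie) (flipped for
    direction='lower'), identical to the normalized U statistic.
    """
    _check_direction(direction)
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.empty(0)
    cutoffs = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.empty(len(cutoffs))
    spec = np.empty(len(cutoffs))
    acc = np.empty(len(cutoffs))
    for i, c in enumerate(cutoffs):
        m = evaluate_cutoff(values, labels, c, direction)
        sens[i], spec[i], acc[i] = m.sensitivity, m.specificity, m.accuracy

    pos, neg = values[labels], values[~labels]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    auc = (gt + 0.5 * eq) / (len(pos) * len(neg))
    if direction == "lower":
        auc = 1.0 - auc
    return ROCResult(cutoffs=cutoffs, sensitivity=sens, specificity=spec,
                     accuracy=acc, auc=float(auc), direction=direction)


def youden_optimal_cutoff(roc: ROCResult) -> float:
    """Cutoff maximizing Youden's J = sensitivity + specificity − 1; exact
    J ties break toward higher specificity, then the later grid point."""
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    best = best[np.argsort(roc.specificity[best], kind="stable")]
    return float(roc.cutoffs[best[-1]])


@dataclass(frozen=True)
class DeltaRecord:
    """One patient × compound pre/post pair on the raw AU scale."""

    patient: str
    compound: str
    pre: float
    post: float
    modality: str
    responder: bool

    @property
    def delta(self) -> float:
        return self.post - self.pre


def paired_deltas(voc_raw: pd.DataFrame, meta: pd.DataFrame,
                  compounds=None) -> pd.DataFrame:
    """Build per-patient pre/post delta records from the cohort tables.

    Uses the blank-corrected (or raw) AU matrix — response deltas are
    analyzed on the AU scale, not log2. Returns one row per
    (pair_id, compound) with pre, post, delta, modality, responder.
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    paired = meta[meta["pair_id"].astype(str) != ""]
    compounds = list(voc_raw.columns) if compounds is None else list(compounds)
    rows = []
    for pid, grp in paired.groupby("pair_id"):
        tp = grp["timepoint"]
        if set(tp) != {"pre", "post"}:
            raise ValueError(f"pair {pid} lacks a pre/post sample pair")
        pre_id = grp.index[tp == "pre"][0]
        post_id = grp.index[tp == "post"][0]
        for c in compounds:
            rows.append({
                "patient": pid, "compound": c,
                "pre": float(voc_raw.loc[pre_id, c]),
                "post": float(voc_raw.loc[post_id, c]),
                "delta": float(voc_raw.loc[post_id, c] - voc_raw.loc[pre_id, c]),
                "modality": grp["modality"].iloc[0],
                "responder": grp["responder"].iloc[0] in (True, "yes", "true", "1"),
            })
    return pd.DataFrame(rows)


def _compound_report(sub: pd.DataFrame, cutoff: float | None) -> dict:
    resp = sub[sub["responder"]]
    nonresp = sub[~sub["responder"]]
    report: dict = {
        "n_responders": int(len(resp)),
        "n_nonresponders": int(len(nonresp)),
        "paired_t": paired_t(sub["pre"], sub["post"]).to_record(),
        "delta_mw": mann_whitney_u(resp["delta"], nonresp["delta"]).to_record(),
    }
    # Response-defining marker: the reduction (pre − post) when responders
    # decrease more than non-responders, otherwise the raw delta.
    decrease = resp["delta"].mean() < nonresp["delta"].mean()
    marker = (sub["pre"] - sub["post"]) if decrease else sub["delta"]
    roc = roc_curve(marker.to_numpy(), sub["responder"].to_numpy(), direction="higher")
    chosen = youden_optimal_cutoff(roc) if cutoff is None else float(cutoff)
    roc.chosen_cutoff = chosen
    m = evaluate_cutoff(marker.to_numpy(), sub["responder"].to_numpy(), chosen, "higher")
    report["marker"] = "reduction (pre - post)" if decrease else "delta (post - pre)"
    report["roc_auc"] = roc.auc
    report["cutoff"] = chosen
    report["cutoff_metrics"] = m.as_dict()
    report["responder_delta_mean"] = float(resp["delta"].mean())
    report["nonresponder_delta_mean"] = float(nonresp["delta"].mean())
    return report


def response_analysis(deltas: pd.DataFrame, by_modality: bool = True,
                      cutoff: float | None = None) -> dict:
    """Treatment-response report per compound.

    For every compound: a paired t test of pre vs post over all treated
    patients; a Mann–Whitney U test comparing deltas between responders and
    non-responders; ROC + cutoff metrics (Youden-optimal unless ``cutoff``
    is supplied) on the response-defining change. Subgroup reports per
    treatment modality (TACE / PLAT); a subgroup whose responder classes
    are not both present is skipped with a warning entry.
    """
    report: dict = {"overall": {}, "warnings": []}
    n_resp = deltas.drop_duplicates("patient")["responder"].sum()
    n_total = deltas["patient"].nunique()
    if n_resp == 0 or n_resp == n_total:
        raise ValueError("need at least one responder and one non-responder")
    report["n_patients"] = int(n_total)
    report["n_responders"] = int(n_resp)
    report["responder_share_pct"] = 100.0 * n_resp / n_total
    for c, sub in deltas.groupby("compound", sort=False):
        report["overall"][c] = _compound_report(sub, cutoff)
    if by_modality:
        report["by_modality"] = {}
        for mod, msub in deltas.groupby("modality", sort=False):
            pat = msub.drop_duplicates("patient")
            r = pat["responder"].sum()
            if r == 0 or r == len(pat):
                report["warnings"].append(
                    f"modality {mod}: only one responder class present, skipped")
                continue
            report["by_modality"][mod] = {
                "n_patients": int(len(pat)),
                "n_responders": int(r),
                "responder_share_pct": 100.0 * r / len(pat),
                "compounds": {c: _compound_report(s, cutoff)
                              for c, s in msub.groupby("compound", sort=False)},
            }
    return report
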