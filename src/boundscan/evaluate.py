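"""Evaluation machinery: coverage, threshold-swept precision/recall
with break-even, protein-level metrics, and protein-level cross-validation.

Conventions shared by all metrics:

* boundary points come from :func:`boundscan.signals.boundary_points`
  (both flanks of each inter-domain transition, chain termini excluded);
* distance tolerances are inclusive (``within 20 residues`` means <= 20);
* coverage and recall are boundary-level counts — several sites near one
  boundary count it once;
* an undefined precision (no predictions) is flagged as None, never
  reported as 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import (
    ProteinCall,
    SitePrediction,
    TwoStageBoundaryClassifier,
    call_protein,
    predict_sites,
    fit_two_stage,
    ClassifierConfig,
)
from .signals import SignalSite, boundary_points
from .types import DomainDefinition, ProteinClass, SiteLabel


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    precision: float | None  # None when no near calls were made
    recall: float
    n_predicted: int
    n_correct: int


@dataclass
class ProteinMetrics:
    accuracy: float
    single_precision: float | None
    single_recall: float
    multi_precision: float | None
    multi_recall: float


@dataclass
class EvalReport:
    coverage: float | None = None
    pr_curve: list[PRPoint] = field(default_factory=list)
    break_even: float | None = None
    protein_metrics: ProteinMetrics | None = None
    task1_accuracy: float | None = None
    task2_accuracy: float | None = None


def signal_coverage(
    sites_by_chain: dict[str, list[SignalSite]],
    defs: dict[str, DomainDefinition],
    tol: int = 20,
) -> float | None:
    """Fraction of inter-domain boundary points with a signal within ``tol``.

    Only multi-domain chains contribute; returns None when there are no
    boundary points at all.
    """
    covered = total = 0
    for chain_id, definition in defs.items():
        points = boundary_points(definition)
        positions = [s.position for s in sites_by_chain.get(chain_id, [])]
        for p in points:
            total += 1
            if any(abs(pos - p) <= tol for pos in positions):
                covered += 1
    if total == 0:
        return None
    return covered / total


def _eligible_boundaries(
    definition: DomainDefinition, terminal_margin: int
) -> set[int]:
    """Boundary points farther than ``terminal_margin`` from both termini."""
    start = definition.ranges[0][0]
    end = definition.ranges[-1][1]
    return {
        p
        for p in boundary_points(definition)
        if p - start > terminal_margin and end - p > terminal_margin
    }


def site_pr(
    predictions_by_chain: dict[str, list[SitePrediction]],
    defs: dict[str, DomainDefinition],
    threshold: float,
    tol: int = 20,
    terminal_margin: int = 40,
) -> PRPoint:
    """Precision/recall of near calls at one stage-2 decision threshold.

    Precision: over sites with stage-2 margin > threshold, the fraction
    within ``tol`` of a true boundary point.  Recall: over boundary
    points more than ``terminal_margin`` residues from both chain
    termini, the fraction with such a call within ``tol``.
    """
    n_pred = n_correct = recalled = eligible = 0
    for chain_id, preds in predictions_by_chain.items():
        definition = defs.get(chain_id)
        points = boundary_points(definition) if definition is not None else set()
        near = [
            p
            for p in preds
            if p.stage2_score is not None and p.stage2_score > threshold
        ]
        n_pred += len(near)
        n_correct += sum(
            1 for p in near if any(abs(p.position - b) <= tol for b in points)
        )
        if definition is not None:
            for b in _eligible_boundaries(definition, terminal_margin):
                eligible += 1
                if any(abs(p.position - b) <= tol for p in near):
                    recalled += 1
    precision = n_correct / n_pred if n_pred else None
    recall = recalled / eligible if eligible else 0.0
    return PRPoint(threshold, precision, recall, n_pred, n_correct)


def pr_curve(
    predictions_by_chain: dict[str, list[SitePrediction]],
    defs: dict[str, DomainDefinition],
    thresholds: np.ndarray | None = None,
    tol: int = 20,
    terminal_margin: int = 40,
) -> list[PRPoint]:
    """Sweep the decision threshold (default -1.5..1.5, step 0.05)."""
    if thresholds is None:
        thresholds = default_thresholds()
    return [
        site_pr(predictions_by_chain, defs, float(t), tol, terminal_margin)
        for t in thresholds
    ]


def default_thresholds(lo: float = -1.5, hi: float = 1.5, step: float = 0.05) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.linspace(lo, hi, n + 1)


def break_even(curve: list[PRPoint]) -> float | None:
    """Precision (= recall) where the two curves cross.

    Located at the first sign change of (precision - recall) along the
    threshold sweep, by linear interpolation between the adjacent
    points; None when the difference never changes sign (points with
    undefined precision are skipped).
    """
    pts = [p for p in curve if p.precision is not None]
    if not pts:
        return None
    for a, b in zip(pts, pts[1:]):
        da = a.precision - a.recall
        db = b.precision - b.recall
        if da == 0:
            return a.precision
        if da * db < 0:
            frac = da / (da - db)  # root of the linear interpolant
            return a.precision + frac * (b.precision - a.precision)
    if pts and pts[-1].precision == pts[-1].recall:
        return pts[-1].precision
    return None


def protein_metrics(
    calls: dict[str, ProteinCall], truth: dict[str, DomainDefinition]
) -> ProteinMetrics:
    """Accuracy and per-class precision/recall of single/multi calls."""
    missing = set(calls) - set(truth)
    if missing:
        raise KeyError(f"chains missing from truth: {sorted(missing)}")
    tp = {ProteinClass.SINGLE_DOMAIN: 0, ProteinClass.MULTI_DOMAIN: 0}
    fp = dict(tp)
    fn = dict(tp)
    correct = 0
    for chain_id, call in calls.items():
        true_cls = (
            ProteinClass.MULTI_DOMAIN
            if truth[chain_id].is_multi_domain
            else ProteinClass.SINGLE_DOMAIN
        )
        if call.call == true_cls:
            correct += 1
            tp[true_cls] += 1
        else:
            fp[call.call] += 1
            fn[true_cls] += 1

    def prec(cls):
        denom = tp[cls] + fp[cls]
        return tp[cls] / denom if denom else None

    def rec(cls):
        denom = tp[cls] + fn[cls]
        return tp[cls] / denom if denom else 0.0

    return ProteinMetrics(
        accuracy=correct / len(calls) if calls else 0.0,
        single_precision=prec(ProteinClass.SINGLE_DOMAIN),
        single_recall=rec(ProteinClass.SINGLE_DOMAIN),
        multi_precision=prec(ProteinClass.MULTI_DOMAIN),
        multi_recall=rec(ProteinClass.MULTI_DOMAIN),
    )


@dataclass
class ChainData:
    """Everything the cross-validator needs about one chain."""

    chain_id: str
    X: np.ndarray  # (n_sites, n_features)
    y: np.ndarray  # site-label codes (0 false, 1 near, 2 away)
    positions: list[int]
    sites: list[SignalSite]
    definition: DomainDefinition


def crossval(
    chains: list[ChainData],
    k: int = 10,
    seed: int = 0,
    config: ClassifierConfig = ClassifierConfig(),
    thresholds: np.ndarray | None = None,
) -> EvalReport:
    """Protein-level k-fold cross-validation of the full cascade.

    Chains (not sites) are shuffled with ``seed`` and split into k folds
    of sizes differing by at most one; k == len(chains) is leave-one-out.
    Per fold the cascade is fitted on the training chains and applied to
    the held-out chains; site predictions are pooled across folds before
    computing metrics.

    Task-1 accuracy is stage 1 against the false vs near/away truth over
    all sites; task-2 accuracy is stage 2 against near vs away over
    multi-domain-chain sites (scored directly, without the stage-1 gate,
    matching per-task evaluation).
    """
    n = len(chains)
    if k > n:
        raise ValueError(f"k={k} exceeds number of chains ({n})")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    predictions_by_chain: dict[str, list[SitePrediction]] = {}
    t1_correct = t1_total = t2_correct = t2_total = 0
    calls: dict[str, ProteinCall] = {}
    truth: dict[str, DomainDefinition] = {c.chain_id: c.definition for c in chains}

    for fold in folds:
        test_idx = set(fold.tolist())
        train = [c for i, c in enumerate(chains) if i not in test_idx]
        test = [chains[i] for i in fold]
        X_train = np.vstack([c.X for c in train if len(c.X)])
        y_train = np.concatenate([c.y for c in train if len(c.y)])
        model = fit_two_stage(X_train, y_train, config)
        clf: TwoStageBoundaryClassifier = model.classifier
        for c in test:
            if len(c.X) == 0:
                preds: list[SitePrediction] = []
            else:
                preds = predict_sites(model, c.X, c.positions)
                s1 = clf.stage1_.decision_function(c.X)
                t1_correct += int(np.sum((s1 > 0) == (c.y != 0)))
                t1_total += len(c.y)
                multi = c.y != 0
                if np.any(multi):
                    s2 = clf.stage2_.decision_function(c.X[multi])
                    t2_correct += int(np.sum((s2 > 0) == (c.y[multi] == 1)))
                    t2_total += int(multi.sum())
            predictions_by_chain[c.chain_id] = preds
            calls[c.chain_id] = call_protein(preds, c.chain_id)

    multi_defs = {cid: d for cid, d in truth.items() if d.is_multi_domain}
    curve = pr_curve(predictions_by_chain, multi_defs, thresholds)
    sites_by_chain = {c.chain_id: c.sites for c in chains}
    return EvalReport(
        coverage=signal_coverage(sites_by_chain, multi_defs),
        pr_curve=curve,
        break_even=break_even(curve),
        protein_metrics=protein_metrics(calls, truth),
        task1_accuracy=t1_correct / t1_total if t1_total else None,
        task2_accuracy=t2_correct / t2_total if t2_total else None,
    )
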