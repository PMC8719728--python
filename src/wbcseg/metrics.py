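"""Segmentation evaluation: pixel-level confusion metrics and kappa, plus
object-level partition-comparison measures (PRI, VOI, GCE).

Pixel metrics treat nonzero mask values as leukocyte.  Metrics whose
denominator vanishes are reported as ``None`` (undefined), never silently
zero, so that averages over image sets can skip them.

With a single ground truth the probabilistic Rand index reduces to the
plain Rand index — the fraction of pixel pairs on which the two
partitions agree.  VOI uses the natural logarithm by default (only a
constant factor; configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

KAPPA_BANDS = ("poor", "reasonable", "good", "very good", "excellent")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies: truth/prediction = WBC vs background."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f_score: float | None
    jaccard: float | None
    kappa: float | None
    kappa_class: str | None
    pri: float | None
    voi: float | None
    gce: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts; nonzero pixels count as leukocyte."""
    p = np.asarray(pred) != 0
    t = np.asarray(truth) != 0
    if p.shape != t.shape:
        raise ValueError(
            f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def pixel_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy, specificity, precision, sensitivity, f-score, Jaccard, kappa.

    Kappa is the chance-corrected accuracy ``(Ac - t) / (1 - t)`` where
    ``t`` is the expected agreement under independent marginals.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    n = c.total
    if n == 0:
        raise ValueError("empty confusion table")
    ac = (tp + tn) / n
    sp = _ratio(tn, tn + fp)
    pr = _ratio(tp, tp + fp)
    se = _ratio(tp, tp + fn)
    f = _ratio(2 * tp, 2 * tp + fp + fn)
    j = _ratio(tp, tp + fp + fn)
    t = ((tp + fn) * (tp + fp) + (tn + fn) * (tn + fp)) / n ** 2
    kappa = (ac - t) / (1 - t) if t < 1 else None
    return {
        "accuracy": ac, "specificity": sp, "precision": pr,
        "sensitivity": se, "f_score": f, "jaccard": j, "kappa": kappa,
    }


def kappa_class(k: float) -> str:
    """Qualitative agreement band for a kappa value.

    poor (K<=0.2), reasonable (0.2<K<=0.4), good (0.4<K<=0.6),
    very good (0.6<K<=0.8), excellent (K>0.8).
    """
    if k <= 0.2:
        return "poor"
    if k <= 0.4:
        return "reasonable"
    if k <= 0.6:
        return "good"
    if k <= 0.8:
        return "very good"
    return "excellent"


def _contingency(seg: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Contingency table n_ij between the label sets of two partitions."""
    s = np.asarray(seg).ravel()
    t = np.asarray(truth).ravel()
    if s.shape != t.shape:
        raise ValueError("partitions must share dimensions")
    _, si = np.unique(s, return_inverse=True)
    _, ti = np.unique(t, return_inverse=True)
    table = np.zeros((si.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(table, (si, ti), 1)
    return table


def pri(seg: np.ndarray, truth: np.ndarray) -> float:
    """Rand index: fraction of pixel pairs on which the partitions agree."""
    table = _contingency(seg, truth)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least two pixels to form a pair")
    def c2(x):
        return x * (x - 1) // 2
    same_both = c2(table).sum()
    same_s = c2(table.sum(axis=1)).sum()
    same_t = c2(table.sum(axis=0)).sum()
    pairs = c2(int(n))
    agreements = pairs + 2 * int(same_both) - int(same_s) - int(same_t)
    return agreements / pairs


def voi(seg: np.ndarray, truth: np.ndarray, log_base: float | None = None) -> float:
    """Variation of information: H(S) + H(I) - 2 F(S, I), >= 0.

    Zero iff the partitions are identical up to relabeling.  Natural log
    by default.
    """
    table = _contingency(seg, truth).astype(np.float64)
    n = table.sum()
    p = table / n
    ps = p.sum(axis=1)
    pt = p.sum(axis=0)

    def ent(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    nz = p > 0
    mi = np.sum(p[nz] * np.log(p[nz] / (ps[:, None] * pt[None, :])[nz]))
    v = ent(ps) + ent(pt) - 2 * mi
    if log_base is not None:
        v /= np.log(log_base)
    return max(float(v), 0.0)


def gce(seg: np.ndarray, truth: np.ndarray) -> float:
    """Global consistency error: refinement-tolerant local error in [0, 1].

    Per pixel the error is |R(S,x) \\ R(I,x)| / |R(S,x)|; GCE takes the
    direction (segmentation as refinement of truth, or vice versa) with
    the smaller total.  Zero when either partition refines the other.
    """
    table = _contingency(seg, truth).astype(np.float64)
    n = table.sum()
    a = table.sum(axis=1)    # |R(S, x)| per seg region
    b = table.sum(axis=0)    # |R(I, x)| per truth region
    with np.errstate(invalid="ignore", divide="ignore"):
        e_si = np.sum(table * (a[:, None] - table) / a[:, None], where=a[:, None] > 0)
        e_is = np.sum(table * (b[None, :] - table) / b[None, :], where=b[None, :] > 0)
    return float(min(e_si, e_is) / n)


def evaluate(pred: np.ndarray, truth: np.ndarray) -> EvaluationReport:
    """Full report: pixel metrics on the binarized masks, partition metrics
    on the labeled masks (background is one region, each object its own)."""
    pm = pixel_metrics(confusion(pred, truth))
    k = pm["kappa"]
    return EvaluationReport(
        sensitivity=pm["sensitivity"],
        specificity=pm["specificity"],
        precision=pm["precision"],
        accuracy=pm["accuracy"],
        f_score=pm["f_score"],
        jaccard=pm["jaccard"],
        kappa=k,
        kappa_class=kappa_class(k) if k is not None else None,
        pri=pri(pred, truth),
        voi=voi(pred, truth),
        gce=gce(pred, truth),
    )
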