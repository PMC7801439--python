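"""ROC / Mann-Whitney analysis of docking-score sets.

Docking scores (e.g. SMINA affinities in kcal/mol) are compared between
labeled ligand groups — known binders, random compounds, molecules
generated for the target, molecules generated for other targets.  The
area under the empirical ROC curve is computed by pair counting with half
credit for ties, which makes the identity

    AUC = U / (n1 * n2)

with the Mann-Whitney U statistic exact by construction.  More negative
docking scores mean stronger predicted binding, so with the default
``lower_is_positive`` orientation positives are ranked by -score.
Structures whose binders-vs-random AUC falls below a threshold (0.6 in
the intended workflow) are dropped by ``discriminability_filter`` as
unable to discriminate actives from random compounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ScoreSet",
    "ScoreComparison",
    "roc_auc",
    "roc_curve_points",
    "mann_whitney",
    "discriminability_filter",
    "group_report",
    "parse_smina_log",
    "DEFAULT_CONTRASTS",
]

#: the four standard contrasts, as (positive label, negative label)
DEFAULT_CONTRASTS = (
    ("known_binders", "random"),
    ("known_binders", "generated_for_others"),
    ("generated_for_target", "random"),
    ("generated_for_target", "known_binders"),
)


@dataclass
class ScoreSet:
    """One labeled sample of docking scores (lower = stronger binding)."""

    label: str
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64).ravel()
        if self.scores.size == 0:
            raise ValueError(f"score set {self.label!r} is empty")
        if not np.isfinite(self.scores).all():
            raise ValueError(f"score set {self.label!r} contains non-finite values")

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclass
class ScoreComparison:
    """Two-sample comparison: U statistic, AUC = U/(n1*n2) and p-value."""

    n1: int
    n2: int
    U: float
    auc: float
    p_value: float

    def __post_init__(self):
        assert abs(self.auc - self.U / (self.n1 * self.n2)) < 1e-12


def _u_statistic(pos: np.ndarray, neg: np.ndarray) -> float:
    """U of 'positives rank above negatives', midrank (half-tie) convention."""
    n1, n2 = pos.size, neg.size
    combined = np.concatenate([pos, neg])
    ranks = stats.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def roc_auc(
    positives: ScoreSet,
    negatives: ScoreSet,
    lower_is_positive: bool = True,
) -> tuple[ScoreComparison, np.ndarray]:
    """AUC by pair counting plus the empirical ROC curve points.

    ``lower_is_positive`` declares that smaller scores indicate the
    positive class (the docking convention); pair counting then runs on
    negated scores.  Returns (comparison, ROC points as an (m, 2) array of
    (FPR, TPR)).
    """
    sgn = -1.0 if lower_is_positive else 1.0
    pos = sgn * positives.scores
    neg = sgn * negatives.scores
    n1, n2 = pos.size, neg.size
    u = _u_statistic(pos, neg)
    auc = u / (n1 * n2)
    _, p = _mw_pvalue(pos, neg, alternative="two-sided")
    comparison = ScoreComparison(n1=n1, n2=n2, U=float(u), auc=float(auc), p_value=float(p))
    return comparison, roc_curve_points(pos, neg)


def roc_curve_points(pos_ranked: np.ndarray, neg_ranked: np.ndarray) -> np.ndarray:
    """Empirical ROC curve (FPR, TPR) sweeping the decision threshold.

    Inputs are already oriented so that larger values mean 'more positive'.
    Tied scores collapse to a single point, so the trapezoidal area equals
    the half-tie pair-counting AUC.
    """
    scores = np.concatenate([pos_ranked, neg_ranked])
    labels = np.concatenate([np.ones(pos_ranked.size), np.zeros(neg_ranked.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    tp = np.cumsum(labels)
    fp = np.cumsum(1 - labels)
    # keep only the last index of each tied-score run
    keep = np.r_[np.diff(scores) != 0, True]
    tpr = np.r_[0.0, tp[keep] / pos_ranked.size]
    fpr = np.r_[0.0, fp[keep] / neg_ranked.size]
    return np.column_stack([fpr, tpr])


def _mw_pvalue(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """U statistic (of a over b) and p-value via scipy.

    Exact enumeration when n1*n2 <= 400 and the samples are tie-free, else
    the tie-corrected normal approximation.
    """
    tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    a: ScoreSet, b: ScoreSet, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U (of ``a`` over ``b``, midranks for ties) and p-value.

    Identities: U_a + U_b = n1*n2; U_a/(n1*n2) equals the pair-counting
    AUC of ``a`` vs ``b`` on the same orientation.  When every value is
    tied across both sets the p-value is 1.
    """
    u = _u_statistic(a.scores, b.scores)
    if np.unique(np.concatenate([a.scores, b.scores])).size == 1:
        return float(u), 1.0
    _, p = _mw_pvalue(a.scores, b.scores, alternative)
    return float(u), p


def discriminability_filter(
    comparisons, threshold: float = 0.6
) -> list:
    """Keep structure ids whose binders-vs-random AUC reaches ``threshold``.

    ``comparisons`` is an iterable of (structure id, ScoreComparison);
    structures with AUC < threshold fail to discriminate actives from
    random compounds and are dropped.
    """
    if not (0.5 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0.5, 1]")
    return [sid for sid, comp in comparisons if comp.auc >= threshold]


def group_report(
    sets: dict,
    contrasts=DEFAULT_CONTRASTS,
    lower_is_positive: bool = True,
) -> list[dict]:
    """All requested pairwise contrasts as tidy rows.

    ``sets`` maps label -> ScoreSet.  Each row carries positive/negative
    labels, n1, n2, U, AUC, p-value and the ROC points.  Contrasts with a
    missing label are skipped (with a stderr warning).
    """
    import warnings

    if len(sets) < 2:
        raise ValueError("need at least two labeled score sets")
    rows = []
    for pos_label, neg_label in contrasts:
        if pos_label not in sets or neg_label not in sets:
            warnings.warn(f"contrast {pos_label} vs {neg_label} skipped: label missing")
            continue
        comp, roc = roc_auc(sets[pos_label], sets[neg_label], lower_is_positive)
        rows.append(
            {
                "positive": pos_label,
                "negative": neg_label,
                "n1": comp.n1,
                "n2": comp.n2,
                "U": comp.U,
                "auc": comp.auc,
                "p_value": comp.p_value,
                "roc_points": roc,
            }
        )
    return rows


def parse_smina_log(text: str) -> list[float]:
    """Best-mode affinities (kcal/mol) from SMINA stdout, one per docked ligand.

    Parses each results table of the form::

        mode |   affinity | dist from best mode
             | (kcal/mol) | rmsd l.b.| rmsd u.b.
        -----+------------+----------+----------
           1       -9.5      0.000      0.000

    and returns the mode-1 affinity of every table in order.
    """
    affinities: list[float] = []
    in_table = False
    for line in text.splitlines():
        if line.lstrip().startswith("-----+"):
            in_table = True
            continue
        if in_table:
            parts = line.split()
            if len(parts) >= 2 and parts[0] == "1":
                try:
                    affinities.append(float(parts[1]))
                except ValueError:
                    pass
            in_table = False
    return affinities
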