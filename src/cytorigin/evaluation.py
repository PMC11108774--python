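"""Diagnostic-performance statistics for five-category origin prediction.

Covers the full reporting family: cancer-positive probability
(P_cancer = 1 - P_benign), top-n accuracy, micro-averaged one-versus-rest
AUROC with DeLong confidence intervals, exact (Clopper-Pearson) binomial
intervals, the 0/1/2 diagnostic score eta, Fleiss' kappa with Landis-Koch
interpretation, real-world accuracy bounds under unresolvable (uncertainty)
cases, stratified evaluation, permutation tests, and perturbation-based
covariate importance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss
from statsmodels.stats.proportion import proportion_confint

from .bagio import CATEGORIES
from .errors import DataError, ParameterError
from .mil_models import ProbabilityVector

BENIGN_IDX = CATEGORIES.index("benign")


# -------------------------------------------------------------------- types
@dataclass
class PredictionSet:
    """Per-case probability vectors, true labels and optional strata tags.

    ``labels`` entries are category names, or None for uncertainty cases
    (no ground truth; excluded from every metric except accuracy bounds).
    """

    probs: np.ndarray                      # (n, 5) in CATEGORIES order
    labels: Sequence[Optional[str]]
    case_ids: Optional[Sequence[str]] = None
    strata: Dict[str, Sequence] = field(default_factory=dict)

    def __post_init__(self):
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.probs.shape[1] != len(CATEGORIES):
            raise ParameterError("probability matrix must have 5 columns")
        if len(self.labels) != len(self.probs):
            raise ParameterError("labels and probabilities differ in length")
        if self.case_ids is None:
            self.case_ids = [f"case_{i}" for i in range(len(self.probs))]

    @property
    def n(self) -> int:
        return len(self.probs)

    def labeled(self) -> "PredictionSet":
        mask = np.array([lab is not None for lab in self.labels])
        return self.subset(mask)

    def n_uncertain(self) -> int:
        return sum(lab is None for lab in self.labels)

    def subset(self, mask) -> "PredictionSet":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return PredictionSet(
            self.probs[idx],
            [self.labels[i] for i in idx],
            [self.case_ids[i] for i in idx],
            {k: np.asarray(v)[idx] for k, v in self.strata.items()},
        )

    def label_indices(self) -> np.ndarray:
        return np.array([CATEGORIES.index(lab) for lab in self.labels])


@dataclass
class MetricReport:
    n: int
    auroc: float
    auroc_ci: tuple
    per_category_auroc: Dict[str, float]
    topn: Dict[int, float]
    accuracy: float
    accuracy_ci: tuple
    sensitivity: float
    sensitivity_ci: tuple
    specificity: float
    specificity_ci: tuple
    ppv: float
    ppv_ci: tuple
    npv: float
    npv_ci: tuple


@dataclass
class ImportanceReport:
    """Perturbation-based covariate importance: Delta = (tau - tau^pert)/tau."""

    tau_acc: float
    tau_age: float
    tau_sex: float
    tau_site: float

    @property
    def delta_age(self) -> float:
        return (self.tau_acc - self.tau_age) / self.tau_acc

    @property
    def delta_sex(self) -> float:
        return (self.tau_acc - self.tau_sex) / self.tau_acc

    @property
    def delta_site(self) -> float:
        return (self.tau_acc - self.tau_site) / self.tau_acc


# ----------------------------------------------------------------- P_cancer
def cancer_probability(p) -> float:
    """Cancer-positive probability P_cancer = 1 - P_benign."""
    if isinstance(p, ProbabilityVector):
        return p.p_cancer
    p = np.asarray(p, dtype=float)
    ProbabilityVector(p)  # validation
    return float(1.0 - p[BENIGN_IDX])


# ------------------------------------------------------------------- top-n
def _top_ranks(probs: np.ndarray) -> np.ndarray:
    """Category indices by descending probability; ties keep category order."""
    return np.argsort(-probs, axis=1, kind="stable")


def topn_accuracy(preds: PredictionSet, n: int) -> float:
    """Fraction of cases whose true category is among the n most probable."""
    if n < 1 or n > len(CATEGORIES):
        raise ParameterError(f"n must be in [1, {len(CATEGORIES)}]")
    ps = preds.labeled()
    if ps.n == 0:
        raise DataError("no labeled cases")
    ranks = _top_ranks(ps.probs)[:, :n]
    truth = ps.label_indices()
    return float(np.mean([t in row for t, row in zip(truth, ranks)]))


# -------------------------------------------------------------------- AUROC
def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auroc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via the rank (Mann-Whitney) statistic, ties counted 1/2."""
    y = np.asarray(y).astype(bool)
    pos, neg = scores[y], scores[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("AUROC needs at least one positive and one negative")
    r = _midrank(scores)
    return float((r[y].sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg)))


def delong_variance(y: np.ndarray, scores: np.ndarray) -> float:
    """DeLong variance of the AUROC estimate (structural components)."""
    y = np.asarray(y).astype(bool)
    pos, neg = scores[y], scores[~y]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    v01 = (tz[:m] - tx) / n                 # components over positives
    v10 = 1.0 - (tz[m:] - ty) / m           # components over negatives
    s01 = np.var(v01, ddof=1) if m > 1 else 0.0
    s10 = np.var(v10, ddof=1) if n > 1 else 0.0
    return s01 / m + s10 / n


def delong_ci(y, scores, level: float = 0.95) -> tuple:
    auc = auroc_rank(np.asarray(y), np.asarray(scores, float))
    se = np.sqrt(delong_variance(np.asarray(y), np.asarray(scores, float)))
    z = stats.norm.ppf(0.5 + level / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def micro_ovr_auroc(preds: PredictionSet, with_ci: bool = True) -> dict:
    """Micro-averaged one-versus-rest AUROC across the five categories.

    The 5 one-hot label columns and 5 probability columns are flattened into
    a single binary problem; the AUROC comes from the rank statistic and the
    CI from DeLong's variance.  Per-category OvR AUROCs are also reported
    (categories absent from the truth set are skipped).
    """
    ps = preds.labeled()
    truth = ps.label_indices()
    if len(np.unique(truth)) < 2:
        raise DataError("degenerate labels: a single class cannot be ranked one-vs-rest")
    onehot = np.zeros_like(ps.probs, dtype=bool)
    onehot[np.arange(ps.n), truth] = True
    y_flat = onehot.ravel(order="F")
    s_flat = ps.probs.ravel(order="F")
    out = {"auroc": auroc_rank(y_flat, s_flat)}
    if with_ci:
        out["ci"] = delong_ci(y_flat, s_flat)
    per_cat = {}
    for j, cat in enumerate(CATEGORIES):
        yj = truth == j
        if 0 < yj.sum() < ps.n:
            per_cat[cat] = auroc_rank(yj, ps.probs[:, j])
    out["per_category"] = per_cat
    return out


# ------------------------------------------------------------- binomial CI
def binomial_ci(successes: int, trials: int, level: float = 0.95) -> tuple:
    """Exact Clopper-Pearson interval via beta quantiles."""
    if trials < 1:
        raise ParameterError("trials must be >= 1")
    if not (0 <= successes <= trials):
        raise ParameterError("successes must be in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="beta")
    return (float(0.0 if np.isnan(lo) else lo), float(1.0 if np.isnan(hi) else hi))


# --------------------------------------------------------- diagnostic score
def diagnostic_scores(pred_categories: Sequence[str],
                      true_categories: Sequence[str]) -> np.ndarray:
    """Per-case scores: 0 for benign/malignant confusion, 1 for malignant with
    wrong origin, 2 for a fully correct prediction."""
    if len(pred_categories) != len(true_categories):
        raise DataError("prediction/truth length mismatch")
    etas = []
    for pred, true in zip(pred_categories, true_categories):
        if pred is None or true is None:
            raise DataError("diagnostic score requires labeled cases")
        pred_malignant = pred != "benign"
        true_malignant = true != "benign"
        if pred_malignant != true_malignant:
            etas.append(0)
        elif pred == true:
            etas.append(2)
        else:
            etas.append(1)
    return np.array(etas)


def diagnostic_score_mean(etas: np.ndarray, level: float = 0.95) -> dict:
    """Mean diagnostic score with a normal-approximation CI on the mean."""
    etas = np.asarray(etas, dtype=float)
    mean = float(etas.mean())
    se = etas.std(ddof=1) / np.sqrt(len(etas)) if len(etas) > 1 else 0.0
    z = stats.norm.ppf(0.5 + level / 2)
    return {"mean": mean, "ci": (mean - z * se, mean + z * se)}


# ------------------------------------------------------------ Fleiss kappa
LANDIS_KOCH_BINS = (
    (-np.inf, 0.0, "poor"), (0.0, 0.20, "slight"), (0.20, 0.40, "fair"),
    (0.40, 0.60, "moderate"), (0.60, 0.80, "substantial"), (0.80, np.inf, "almost perfect"),
)


def landis_koch_label(kappa: float) -> str:
    for lo, hi, label in LANDIS_KOCH_BINS:
        if lo <= kappa < hi or (label == "almost perfect" and kappa >= lo):
            return label
    return "poor"


@dataclass
class FleissResult:
    kappa: float
    label: str
    z: float
    p_value: float


def fleiss_kappa(matrix: np.ndarray) -> FleissResult:
    """Fleiss' kappa = (p_o - p_e)/(1 - p_e) for a cases x categories count
    matrix, with the Landis-Koch qualitative label and a two-sided z-test
    against kappa = 0 (large-sample null variance, Fleiss 1971)."""
    M = np.asarray(matrix, dtype=float)
    row_sums = M.sum(axis=1)
    if len(np.unique(row_sums)) != 1:
        raise DataError("every case must be rated by the same number of raters")
    r = row_sums[0]
    if r < 2:
        raise DataError("at least 2 raters are required")
    n = M.shape[0]
    kappa = float(_sm_fleiss(M))
    p_j = M.sum(axis=0) / (n * r)
    p_e = float((p_j**2).sum())
    var0 = (2.0 / (n * r * (r - 1))) * (
        p_e - (2 * r - 3) * p_e**2 + 2 * (r - 2) * (p_j**3).sum()) / (1 - p_e) ** 2
    z = kappa / np.sqrt(var0) if var0 > 0 else np.inf
    p = 2 * stats.norm.sf(abs(z))
    return FleissResult(kappa=kappa, label=landis_koch_label(kappa), z=float(z),
                        p_value=float(p))


# ---------------------------------------------------------- accuracy bounds
def accuracy_bounds(acc_known: float, n_known: int, n_uncertain: int) -> tuple:
    """Top-1 accuracy bounds when uncertainty cases carry no ground truth:
    assume 0% (lower) or 100% (upper) accuracy on them."""
    if n_known < 1 or n_uncertain < 0:
        raise ParameterError("counts must satisfy n_known >= 1, n_uncertain >= 0")
    total = n_known + n_uncertain
    lower = acc_known * n_known / total
    upper = (acc_known * n_known + n_uncertain) / total
    return (lower, upper)


# ---------------------------------------------------------------- reporting
def evaluate_predictions(preds: PredictionSet) -> MetricReport:
    """Full metric suite on labeled cases.

    Multi-class metrics use argmax assignment; the binary cancer task
    thresholds P_cancer at 0.5.  Proportion CIs are Clopper-Pearson.
    """
    ps = preds.labeled()
    if ps.n == 0:
        raise DataError("no labeled cases to evaluate")
    truth = ps.label_indices()
    if len(np.unique(truth)) < 2:
        warnings.warn("degenerate stratum: a single truth class; AUROC undefined")
        auroc, ci, per_cat = np.nan, (np.nan, np.nan), {}
    else:
        res = micro_ovr_auroc(ps)
        auroc, ci, per_cat = res["auroc"], res["ci"], res["per_category"]
    pred_idx = _top_ranks(ps.probs)[:, 0]
    correct = int((pred_idx == truth).sum())
    topn = {k: topn_accuracy(ps, k) for k in (1, 2, 3)}
    # binary cancer task at threshold 0.5 on P_cancer
    p_cancer = 1.0 - ps.probs[:, BENIGN_IDX]
    pred_pos = p_cancer >= 0.5
    true_pos = truth != BENIGN_IDX
    tp = int((pred_pos & true_pos).sum())
    tn = int((~pred_pos & ~true_pos).sum())
    fp = int((pred_pos & ~true_pos).sum())
    fn = int((~pred_pos & true_pos).sum())

    def prop(num, den):
        if den == 0:
            return np.nan, (np.nan, np.nan)
        return num / den, binomial_ci(num, den)

    sens, sens_ci = prop(tp, tp + fn)
    spec, spec_ci = prop(tn, tn + fp)
    ppv, ppv_ci = prop(tp, tp + fp)
    npv, npv_ci = prop(tn, tn + fn)
    return MetricReport(
        n=ps.n, auroc=auroc, auroc_ci=ci, per_category_auroc=per_cat, topn=topn,
        accuracy=correct / ps.n, accuracy_ci=binomial_ci(correct, ps.n),
        sensitivity=sens, sensitivity_ci=sens_ci,
        specificity=spec, specificity_ci=spec_ci,
        ppv=ppv, ppv_ci=ppv_ci, npv=npv, npv_ci=npv_ci)


def stratified_eval(preds: PredictionSet, stratifier: str) -> Dict[str, MetricReport]:
    """Metric suite computed independently per stratum of the chosen tag."""
    if stratifier not in preds.strata:
        raise ParameterError(f"unknown stratifier {stratifier!r}; "
                             f"available: {sorted(preds.strata)}")
    tags = np.asarray(preds.strata[stratifier])
    out = {}
    for value in sorted(map(str, set(tags))):
        out[value] = evaluate_predictions(preds.subset(tags.astype(str) == value))
    return out


# ----------------------------------------------------------- permutation test
def permutation_test(set_a: np.ndarray, set_b: np.ndarray, reps: int = 10_000,
                     seed: int = 0, paired: Optional[bool] = None) -> float:
    """Two-sided permutation p-value for the difference in means.

    Paired samples (same cases) use sign-flips of per-case differences;
    unpaired samples use label shuffling.  The add-one estimator keeps
    p >= 1/(reps+1).
    """
    if reps < 100:
        raise ParameterError("at least 100 permutation replicates are required")
    a, b = np.asarray(set_a, float), np.asarray(set_b, float)
    rng = np.random.default_rng(seed)
    if paired is None:
        paired = len(a) == len(b)
    if paired:
        if len(a) != len(b):
            raise DataError("paired test requires equal-length score vectors")
        diff = a - b
        obs = abs(diff.mean())
        signs = rng.choice([-1.0, 1.0], size=(reps, len(diff)))
        null = np.abs((signs * diff).mean(axis=1))
    else:
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        null = np.empty(reps)
        for i in range(reps):
            perm = rng.permutation(pooled)
            null[i] = abs(perm[:len(a)].mean() - perm[len(a):].mean())
    return float((1 + (null >= obs - 1e-12).sum()) / (reps + 1))


# --------------------------------------------------- perturbation importance
def perturb_importance(predict_fn: Callable, cases: Sequence[tuple], seed: int = 0,
                       uses_clinical: bool = True) -> ImportanceReport:
    """Covariate importance by input perturbation.

    ``cases`` is a sequence of (bag, ClinicalCovariates, true class index);
    ``predict_fn(bag, cov)`` returns a ProbabilityVector.  Age is replaced by
    a uniform integer draw on [18, 90]; sex and sampling site are flipped.
    Delta^c = (tau - tau^c) / tau for each covariate c.
    """
    if not uses_clinical:
        raise ParameterError("perturbation importance is not applicable to an image-only model")
    from .bagio import ClinicalCovariates  # local import to avoid cycle noise

    rng = np.random.default_rng(seed)

    def top1(case_list):
        hits = 0
        for bag, cov, y in case_list:
            p = predict_fn(bag, cov)
            hits += int(np.argmax(p.p if isinstance(p, ProbabilityVector) else p) == y)
        return hits / len(case_list)

    tau = top1(cases)
    aged = [(b, ClinicalCovariates(int(rng.integers(18, 91)), c.sex, c.site), y)
            for b, c, y in cases]
    sexed = [(b, ClinicalCovariates(c.age, "female" if c.sex == "male" else "male", c.site), y)
             for b, c, y in cases]
    sited = [(b, ClinicalCovariates(c.age, c.sex,
                                    "ascites" if c.site == "hydrothorax" else "hydrothorax"), y)
             for b, c, y in cases]
    return ImportanceReport(tau_acc=tau, tau_age=top1(aged), tau_sex=top1(sexed),
                            tau_site=top1(sited))
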