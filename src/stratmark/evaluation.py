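"""Marker-set evaluation: classifiers, AUC with error bars, risk tables.

Three standard classifiers score samples with a probability of the
positive outcome: random forest (500 unpruned trees, sqrt(p) candidate
features per split — the conventional defaults), Gaussian naive Bayes
with class-frequency priors, and unpenalized logistic regression.

AUC is the Mann-Whitney probability that a random positive sample
outscores a random negative one (ties count half). Uncertainty comes
from either 100-repeat bootstrap resampling scored on out-of-bag
samples, or external repeated stratified cross-validation; both report
the mean and the standard error (SD of per-evaluation AUCs / sqrt(n)).

Risk stratification splits the cohort at a quantile of the score
distribution computed a priori on all samples (cutoffs 50/75/90% by
default): samples strictly above the threshold form the high-risk class
(HRC). The report carries the share of patients and of cases in the
HRC, per-class risks and odds, the diagnostic odds ratio
DOR = odds_HRC / odds_LRC and the risk ratio RR = risk_HRC / risk_LRC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB

from .dataset import ExpressionDataset

__all__ = [
    "ClassifierSpec",
    "AucEstimate",
    "RiskReport",
    "auc",
    "train_classifier",
    "score_classifier",
    "bootstrap_oob_auc",
    "external_cv_scores",
    "risk_stratify",
    "auc_vs_k",
    "auc_by_level",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS = (0.50, 0.75, 0.90)

CLASSIFIER_KINDS = ("random_forest", "naive_bayes", "logistic_regression")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family with its fixed default parameters."""

    kind: str = "random_forest"
    n_trees: int = 500  # random forest only

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")

    def build(self, seed: int = 0):
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.n_trees, max_features="sqrt",
                random_state=seed)
        if self.kind == "naive_bayes":
            return GaussianNB()
        return LogisticRegression(penalty=None, max_iter=5000)


def train_classifier(spec: ClassifierSpec, X, y, seed: int = 0):
    """Fit a classifier; both classes must be present in ``y``."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")
    model = spec.build(seed)
    model.fit(np.asarray(X, dtype=float), y)
    return model


def score_classifier(model, X) -> np.ndarray:
    """Per-sample probability of the positive class."""
    proba = model.predict_proba(np.asarray(X, dtype=float))
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return proba[:, pos_col]


@dataclass
class AucEstimate:
    """AUC mean with a resampling standard error."""

    mean: float
    standard_error: float
    n_evaluations: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0) or self.standard_error < 0:
            raise ValueError("invalid AUC estimate")


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _estimate(aucs: list[float]) -> AucEstimate:
    vals = np.asarray(aucs, dtype=float)
    se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
    return AucEstimate(float(vals.mean()), float(se), int(vals.size))


def bootstrap_oob_auc(dataset: ExpressionDataset, markers, spec: ClassifierSpec,
                      n_boot: int = 100, random_state: int = 0) -> AucEstimate:
    """Bootstrap the cohort; train on each draw, score its out-of-bag samples.

    Draws whose OOB set (or training draw) lacks one of the classes are
    redrawn. Returns the mean AUC over draws and its standard error.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    markers = list(markers)
    X = dataset.values[markers].to_numpy()
    y = dataset.y
    n = y.size
    rng = np.random.default_rng(random_state)
    aucs: list[float] = []
    attempts = 0
    while len(aucs) < n_boot:
        attempts += 1
        if attempts > 50 * n_boot:
            raise ValueError("dataset too small to yield two-class OOB draws")
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0 or len(np.unique(y[idx])) < 2 \
                or len(np.unique(y[oob])) < 2:
            continue
        seed = int(rng.integers(0, 2 ** 31 - 1))
        model = train_classifier(spec, X[idx], y[idx], seed=seed)
        aucs.append(auc(score_classifier(model, X[oob]), y[oob]))
    return _estimate(aucs)


def external_cv_scores(dataset: ExpressionDataset, markers, spec: ClassifierSpec,
                       plan=None) -> tuple[pd.Series, AucEstimate]:
    """Out-of-fold scores from external repeated stratified CV.

    Every sample is scored only by models that never saw it; the
    returned per-sample score is the mean over repeats, and the AUC
    estimate aggregates one AUC per repeat (default 10-fold x 30).
    """
    from .protocol import CvPlan, stratified_folds  # local import, avoids cycle

    plan = plan or CvPlan(n_repeats=30, n_folds=10)
    markers = list(markers)
    X = dataset.values[markers].to_numpy()
    y = dataset.y
    folds = stratified_folds(y, plan)
    seeds = np.random.SeedSequence([plan.rng_seed, 2]).spawn(plan.n_iterations)
    score_sum = np.zeros(y.size)
    per_repeat_auc: list[float] = []
    it = 0
    for r in range(plan.n_repeats):
        repeat_scores = np.empty(y.size)
        for f in range(plan.n_folds):
            test = np.flatnonzero(folds[r] == f)
            train = np.flatnonzero(folds[r] != f)
            seed = int(seeds[it].generate_state(1)[0] % (2 ** 31 - 1))
            it += 1
            model = train_classifier(spec, X[train], y[train], seed=seed)
            repeat_scores[test] = score_classifier(model, X[test])
        score_sum += repeat_scores
        per_repeat_auc.append(auc(repeat_scores, y))
    scores = pd.Series(score_sum / plan.n_repeats, index=dataset.values.index,
                       name="score")
    return scores, _estimate(per_repeat_auc)


# ---------------------------------------------------------------------------
# risk stratification
# ---------------------------------------------------------------------------

@dataclass
class RiskReport:
    """Risk-stratification summary at one cutoff.

    ``cutoff`` is the score quantile separating the low-risk class (LRC)
    from the high-risk class (HRC). Risks are outcome fractions within
    each class; odds = risk / (1 - risk); DOR = odds_hrc / odds_lrc;
    RR = risk_hrc / risk_lrc. Values are stored at full precision;
    ``rounded()`` reproduces the conventional table formatting.
    """

    cutoff: float
    share_patients_hrc: float
    share_cases_hrc: float
    risk_lrc: float
    risk_hrc: float
    odds_lrc: float = field(init=False)
    odds_hrc: float = field(init=False)
    dor: float = field(init=False)
    rr: float = field(init=False)

    def __post_init__(self) -> None:
        self.odds_lrc = _odds(self.risk_lrc)
        self.odds_hrc = _odds(self.risk_hrc)
        self.dor = self.odds_hrc / self.odds_lrc if self.odds_lrc > 0 else np.inf
        self.rr = self.risk_hrc / self.risk_lrc if self.risk_lrc > 0 else np.inf

    @classmethod
    def from_risks(cls, cutoff: float, share_patients_hrc: float,
                   share_cases_hrc: float, risk_lrc: float,
                   risk_hrc: float) -> "RiskReport":
        """Build a report from already-measured shares and per-class risks."""
        return cls(cutoff, share_patients_hrc, share_cases_hrc,
                   risk_lrc, risk_hrc)

    def rounded(self) -> dict[str, float]:
        """Printed-precision view: shares/risks to 0.1 percentage point,
        odds to 2 decimals, DOR and RR to 1 decimal (half-up rounding)."""
        return {
            "cutoff_pct": _round_half_up(100 * self.cutoff, 0),
            "share_patients_hrc_pct": _round_half_up(100 * self.share_patients_hrc, 1),
            "share_cases_hrc_pct": _round_half_up(100 * self.share_cases_hrc, 1),
            "risk_lrc_pct": _round_half_up(100 * self.risk_lrc, 1),
            "risk_hrc_pct": _round_half_up(100 * self.risk_hrc, 1),
            "odds_lrc": _round_half_up(self.odds_lrc, 2),
            "odds_hrc": _round_half_up(self.odds_hrc, 2),
            "dor": _round_half_up(self.dor, 1),
            "rr": _round_half_up(self.rr, 1),
        }


def _odds(risk: float) -> float:
    if not (0.0 <= risk < 1.0):
        raise ValueError(f"risk must be in [0, 1), got {risk}")
    return risk / (1.0 - risk)


def _round_half_up(value: float, decimals: int) -> float:
    if not np.isfinite(value):
        return float(value)
    quant = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def risk_stratify(scores, labels, cutoff_quantile: float = 0.75,
                  mode: str = "quantile") -> RiskReport:
    """Split the cohort at a score cutoff and report risk metrics.

    By default the threshold is the given quantile of the full score
    vector (established a priori on all samples); ``mode="probability"``
    treats ``cutoff_quantile`` as a raw score threshold instead. HRC
    membership is strict (score > threshold), so ties at the threshold
    stay in the LRC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("risk stratification requires both classes")
    if mode == "quantile":
        if not (0.0 < cutoff_quantile < 1.0):
            raise ValueError("cutoff_quantile must be in (0, 1)")
        threshold = float(np.quantile(scores, cutoff_quantile))
    elif mode == "probability":
        threshold = float(cutoff_quantile)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hrc = scores > threshold
    if hrc.all() or not hrc.any():
        raise ValueError("degenerate stratification: one class is empty "
                         "(are all scores identical?)")
    cases = labels == 1
    return RiskReport(
        cutoff=cutoff_quantile,
        share_patients_hrc=float(hrc.mean()),
        share_cases_hrc=float((hrc & cases).sum() / cases.sum()),
        risk_lrc=float(labels[~hrc].mean()),
        risk_hrc=float(labels[hrc].mean()),
    )


def auc_vs_k(dataset: ExpressionDataset, ranked_features, ks,
             spec: ClassifierSpec | None = None, n_boot: int = 100,
             random_state: int = 0) -> pd.DataFrame:
    """Bootstrap-OOB AUC as a function of panel size.

    For each k the model uses the first k of ``ranked_features``. The
    same seed (hence the same bootstrap draws) is used at every k, so
    adjacent panel sizes are compared on common resamples.
    """
    spec = spec or ClassifierSpec()
    ranked_features = list(ranked_features)
    rows = []
    for k in ks:
        k = int(k)
        if k > len(ranked_features):
            break
        est = bootstrap_oob_auc(dataset, ranked_features[:k], spec,
                                n_boot=n_boot, random_state=random_state)
        rows.append({"k": k, "auc_mean": est.mean, "auc_se": est.standard_error,
                     "n_evaluations": est.n_evaluations})
    return pd.DataFrame(rows)


def auc_by_level(dataset: ExpressionDataset, marker_sets: dict[int, list],
                 spec: ClassifierSpec | None = None, n_boot: int = 100,
                 random_state: int = 0) -> pd.DataFrame:
    """Bootstrap-OOB AUC per clustering level using that level's final
    marker set (common bootstrap draws across levels)."""
    spec = spec or ClassifierSpec()
    rows = []
    for k in sorted(marker_sets):
        markers = marker_sets[k]
        if not markers:
            continue
        est = bootstrap_oob_auc(dataset, markers, spec, n_boot=n_boot,
                                random_state=random_state)
        rows.append({"level": int(k), "n_markers": len(markers),
                     "auc_mean": est.mean, "auc_se": est.standard_error,
                     "n_evaluations": est.n_evaluations})
    return pd.DataFrame(rows)
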