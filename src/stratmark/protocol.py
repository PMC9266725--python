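"""The marker-selection protocols.

Base protocol (one train/test split): filter all-relevant features on
the training samples, cluster them on 1 - rho^2 (training correlations
only), pick one representative per cluster at every clustering level,
optionally fit a classifier on the representatives and score the
held-out bin.

Proposed protocol: run the base protocol inside repeated stratified
k-fold cross-validation (default 30 repeats x 5 folds = 150 iterations)
and rank features, per clustering level, by how often they were chosen
as a cluster representative. The final marker set at level k is the
top-k features of that level's frequency ranking; the count acts as a
stability-based quality metric that replaces the single-run p-value
ordering. The choice of the working level (where the AUC-vs-k curve
plateaus) is left to the user.

All randomness derives from one master seed via spawned seed sequences,
so a full 150-iteration run is exactly reproducible.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import cut_and_represent, correlation_matrix, dissimilarity, \
    hierarchical_cluster
from .dataset import ExpressionDataset
from .evaluation import ClassifierSpec, auc, train_classifier, score_classifier
from .relevance import DiscretizationScheme, RelevanceResult, scheme_with_seed, \
    select_relevant

__all__ = [
    "CvPlan",
    "FrequencyRanking",
    "BaseProtocolResult",
    "ProtocolResult",
    "stratified_folds",
    "run_base_protocol",
    "run_proposed_protocol",
    "stability_table",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = range(2, 16)


@dataclass(frozen=True)
class CvPlan:
    """Repeated stratified k-fold plan (always stratified)."""

    n_repeats: int = 30
    n_folds: int = 5
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ValueError("need n_repeats >= 1 and n_folds >= 2")
        if not self.stratified:
            raise ValueError("only stratified CV is supported")

    @property
    def n_iterations(self) -> int:
        return self.n_repeats * self.n_folds


def stratified_folds(labels, plan: CvPlan) -> np.ndarray:
    """Fold assignments, shape (n_repeats, n_samples), values in 0..n_folds-1.

    Per repeat, each class is randomly permuted and dealt round-robin
    into folds, so per-fold class counts differ from exact proportionality
    by at most one sample.
    """
    y = np.asarray(labels)
    for cls in (0, 1):
        if (y == cls).sum() < plan.n_folds:
            raise ValueError(
                f"class {cls} has fewer samples than n_folds={plan.n_folds}")
    out = np.empty((plan.n_repeats, y.size), dtype=int)
    children = np.random.SeedSequence(plan.rng_seed).spawn(plan.n_repeats)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            perm = rng.permutation(idx)
            out[r, perm] = np.arange(perm.size) % plan.n_folds
    return out


@dataclass
class BaseProtocolResult:
    """One train/test split of the base protocol."""

    relevance: RelevanceResult
    representatives: dict[int, list[str]]  # level -> chosen features
    aucs: dict[int, float] = field(default_factory=dict)  # level -> test AUC


@dataclass
class FrequencyRanking:
    """Per clustering level, how often each feature was a representative."""

    counts: dict[int, Counter]  # level -> feature -> count
    n_iterations: int

    def ordered(self, level: int, tie_p: pd.Series | None = None) -> list[tuple[str, int]]:
        """(feature, count) pairs ordered by count desc, then smaller
        full-data p-value, then lexicographic ID."""
        ctr = self.counts.get(level, Counter())

        def key(item):
            f, c = item
            p = tie_p.get(f, 1.0) if tie_p is not None else 1.0
            return (-c, p, str(f))

        return sorted(ctr.items(), key=key)


def run_base_protocol(dataset: ExpressionDataset, train_idx, test_idx,
                      levels=DEFAULT_LEVELS, linkage: str = "complete",
                      scheme: DiscretizationScheme | None = None,
                      n_permutations: int = 1000, alpha: float = 0.05,
                      classifier: ClassifierSpec | None = None,
                      model_seed: int = 0) -> BaseProtocolResult:
    """Feature selection, clustering and representative choice on the
    training split only, optionally with a held-out AUC per level.

    If no feature passes the filter the representative sets are empty
    and no model is evaluated (logged, not an error).
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test splits must be disjoint")
    train = dataset.subset_samples(train_idx)
    scheme = scheme or DiscretizationScheme()

    relevance = select_relevant(train, scheme, n_permutations=n_permutations,
                                alpha=alpha)
    relevant = relevance.relevant_features
    reps: dict[int, list[str]] = {}
    aucs: dict[int, float] = {}

    if not relevant:
        logger.info("no relevant features on this training split")
        return BaseProtocolResult(relevance, {int(k): [] for k in levels}, {})

    dendro = None
    if len(relevant) > 1:
        rho = correlation_matrix(train, relevant)
        dendro = hierarchical_cluster(dissimilarity(rho), method=linkage)

    for k in levels:
        k = int(k)
        eff_k = min(k, len(relevant))
        if dendro is None or eff_k == 1:
            ranked = relevance.ranked()
            chosen = [f for f in ranked.index if f in set(relevant)][:eff_k]
        else:
            cut = cut_and_represent(dendro, eff_k, relevance)
            chosen = cut.representative_features
        reps[k] = chosen
        if classifier is not None and chosen:
            model = train_classifier(classifier, train.values[chosen].to_numpy(),
                                     train.y, seed=model_seed)
            test = dataset.subset_samples(test_idx)
            if len(set(test.y)) == 2:
                scores = score_classifier(model, test.values[chosen].to_numpy())
                aucs[k] = auc(scores, test.y)
    return BaseProtocolResult(relevance, reps, aucs)


@dataclass
class ProtocolResult:
    """Output of the proposed (frequency-ranking) protocol."""

    ranking: FrequencyRanking
    marker_sets: dict[int, list[str]]  # level -> final top-k markers
    full_relevance: RelevanceResult
    plan: CvPlan
    level_aucs: dict[int, list[float]] = field(default_factory=dict)

    def auc_curve(self) -> pd.DataFrame:
        """Mean and standard error of the per-iteration held-out AUC by level."""
        rows = []
        for k in sorted(self.level_aucs):
            vals = np.asarray(self.level_aucs[k], dtype=float)
            if vals.size == 0:
                continue
            se = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            rows.append({"level": k, "auc_mean": vals.mean(), "auc_se": se,
                         "n_evaluations": vals.size})
        return pd.DataFrame(rows)


def run_proposed_protocol(dataset: ExpressionDataset, plan: CvPlan = CvPlan(),
                          levels=DEFAULT_LEVELS, linkage: str = "complete",
                          scheme: DiscretizationScheme | None = None,
                          n_permutations: int = 1000, alpha: float = 0.05,
                          classifier: ClassifierSpec | None = None) -> ProtocolResult:
    """Frequency ranking of cluster representatives over repeated CV.

    Runs the base protocol in every CV iteration, counts per level how
    often each feature is chosen as a representative, and forms the
    final marker set at level k as the top-k features by count (ties:
    smaller full-data p-value, then feature ID). Iterations where the
    filter finds nothing contribute no counts.
    """
    scheme = scheme or DiscretizationScheme()
    levels = [int(k) for k in levels]
    folds = stratified_folds(dataset.y, plan)

    full_relevance = select_relevant(dataset, scheme,
                                     n_permutations=n_permutations, alpha=alpha)
    full_p = full_relevance.table["p_value"]

    counts: dict[int, Counter] = {k: Counter() for k in levels}
    level_aucs: dict[int, list[float]] = {k: [] for k in levels}
    iter_seeds = np.random.SeedSequence([plan.rng_seed, 1]).spawn(plan.n_iterations)
    it = 0
    for r in range(plan.n_repeats):
        for f in range(plan.n_folds):
            test_idx = np.flatnonzero(folds[r] == f)
            train_idx = np.flatnonzero(folds[r] != f)
            seed = int(iter_seeds[it].generate_state(1)[0] % (2 ** 31 - 1))
            it += 1
            res = run_base_protocol(
                dataset, train_idx, test_idx, levels=levels, linkage=linkage,
                scheme=scheme_with_seed(scheme, seed),
                n_permutations=n_permutations, alpha=alpha,
                classifier=classifier, model_seed=seed)
            for k in levels:
                for feat in res.representatives.get(k, []):
                    counts[k][feat] += 1
                if k in res.aucs:
                    level_aucs[k].append(res.aucs[k])

    ranking = FrequencyRanking(counts, plan.n_iterations)
    marker_sets: dict[int, list[str]] = {}
    for k in levels:
        ordered = ranking.ordered(k, tie_p=full_p)
        marker_sets[k] = [f for f, _ in ordered[:k]]
    return ProtocolResult(ranking, marker_sets, full_relevance, plan,
                          {k: v for k, v in level_aucs.items() if v})


def stability_table(result: ProtocolResult, levels=None) -> pd.DataFrame:
    """Marker-by-level table of frequency ranks.

    Rows are markers in the order they first enter a final marker set as
    the level increases; columns are levels; a cell holds the feature's
    1-based rank in that level's frequency ranking (NaN if it was never
    a representative at that level). The stability of a candidate panel
    shows up as its markers occupying the top rows across levels.
    """
    levels = sorted(result.marker_sets if levels is None else [int(k) for k in levels])
    full_p = result.full_relevance.table["p_value"]
    inclusion: list[str] = []
    for k in levels:
        for f in result.marker_sets.get(k, []):
            if f not in inclusion:
                inclusion.append(f)
    table = pd.DataFrame(index=pd.Index(inclusion, name="marker"),
                         columns=levels, dtype=float)
    for k in levels:
        for rank, (f, _) in enumerate(result.ranking.ordered(k, tie_p=full_p), 1):
            if f in table.index:
                table.loc[f, k] = rank
    return table
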