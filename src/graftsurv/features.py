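"""Hybrid feature selection: information-gain filter, buffalo-herd wrapper,
and accuracy-driven one-by-one backward elimination.

The filter stage ranks every pre-operative covariate by information gain --
the reduction in label entropy achieved by partitioning the records on the
(discretized) feature values -- and rejects features whose gain does not
exceed the threshold (zero by default: an exactly uninformative feature
contributes nothing). The wrapper stage searches feature subsets with the
buffalo-herd optimizer over a continuous position vector mapped to masks by
a sigmoid transfer, scoring each candidate by the validation accuracy of a
classifier trained on it. The elimination stage then tentatively removes
each surviving feature, weakest-ranked first, and permanently drops it only
when the removal *strictly* improves validation accuracy.

All three stages see only the training partition; their internal validation
split is a stratified 80/20 split of those rows with a fixed derived seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from . import abo, ann
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "BinningConfig",
    "ClassifierConfig",
    "SelectionConfig",
    "FeatureRanking",
    "FeatureMask",
    "SelectionResult",
    "entropy",
    "information_gain",
    "rank_features",
    "ig_filter",
    "abo_wrapper_select",
    "backward_eliminate",
    "hybrid_select",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class BinningConfig:
    """Discretization of continuous features for information gain.

    A feature with at most ``n_bins`` distinct values is used as-is
    (categorical/integer-coded); otherwise it is cut into ``n_bins``
    equal-frequency bins.
    """

    n_bins: int = 10

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be at least 2")


@dataclass(frozen=True)
class ClassifierConfig:
    """Which classifier scores candidate subsets in wrapper stages.

    ``logistic`` (default) is a regularized linear model -- fast enough to
    be refit hundreds of times inside the herd search; ``tree`` is a depth-
    limited CART; ``ann`` is the buffalo-trained perceptron itself, at a
    reduced herd budget.
    """

    kind: str = "logistic"
    params: dict = field(default_factory=dict)

    def build(self, seed: int):
        if self.kind == "logistic":
            return make_pipeline(
                StandardScaler(),
                LogisticRegression(max_iter=500, **self.params),
            )
        if self.kind == "tree":
            return DecisionTreeClassifier(
                max_depth=self.params.get("max_depth", 5), random_state=seed
            )
        if self.kind == "ann":
            return ann.ANNClassifier(random_state=seed, **self.params)
        raise ConfigurationError(f"unknown classifier kind: {self.kind!r}")


@dataclass
class SelectionConfig:
    """Stage toggles and budgets for :func:`hybrid_select`."""

    ig_threshold: float = 0.0
    binning: BinningConfig = field(default_factory=BinningConfig)
    use_ig_filter: bool = True
    use_abo_wrapper: bool = True
    use_backward_elimination: bool = True
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    wrapper_abo: abo.ABOConfig = field(
        default_factory=lambda: abo.ABOConfig(
            n_buffalo=15, max_iterations=20, bounds=(-4.0, 4.0)
        )
    )
    val_fraction: float = 0.2
    seed: int = 0


# ---------------------------------------------------------------------------
# entropy / information gain


def entropy(labels) -> float:
    """Shannon entropy of a categorical vector, in bits (0*log0 := 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DataError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-np.sum(p * np.log2(p)))


def _discretize(feature, binning: BinningConfig) -> np.ndarray:
    """Integer codes per record; missing values become their own code."""
    s = pd.Series(np.asarray(feature).ravel())
    if pd.api.types.is_numeric_dtype(s) and s.nunique(dropna=True) > binning.n_bins:
        cut = pd.qcut(s, binning.n_bins, duplicates="drop")
        codes = cut.cat.codes.to_numpy().copy()  # NaN -> -1
    else:
        codes = pd.factorize(s, use_na_sentinel=True)[0].copy()
    return codes


def information_gain(feature, labels, binning: BinningConfig | None = None) -> float:
    """H(labels) - sum_v (n_v/n) H(labels | feature = v), in bits."""
    if binning is None:
        binning = BinningConfig()
    labels = np.asarray(labels)
    feature = np.asarray(feature)
    if feature.shape[0] != labels.shape[0]:
        raise DataError("feature and labels must have equal length")
    codes = _discretize(feature, binning)
    n = labels.size
    cond = 0.0
    for v in np.unique(codes):
        sub = labels[codes == v]
        cond += (sub.size / n) * entropy(sub)
    ig = entropy(labels) - cond
    # clip tiny negative rounding residue
    return max(float(ig), 0.0)


@dataclass
class FeatureRanking:
    """Per-feature gains (bits) and the descending-gain ordering."""

    feature_names: list[str]
    gains: np.ndarray
    order: np.ndarray  # indices, descending gain

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in self.order],
                "information_gain_bits": self.gains[self.order],
            }
        )


@dataclass
class FeatureMask:
    """Boolean subset of the feature columns plus its provenance stage."""

    values: np.ndarray
    provenance: str
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if not self.values.any():
            raise ConfigurationError("a feature mask must select at least one feature")

    @property
    def n_selected(self) -> int:
        return int(self.values.sum())

    def selected_names(self) -> list[str]:
        if self.feature_names is None:
            raise ConfigurationError("mask carries no feature names")
        return [n for n, keep in zip(self.feature_names, self.values) if keep]

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or [f"f{i}" for i in range(self.values.size)]
        return pd.DataFrame(
            {
                "feature": names,
                "selected": self.values.astype(int),
                "provenance": self.provenance,
            }
        )


def rank_features(
    X: pd.DataFrame, labels, binning: BinningConfig | None = None
) -> FeatureRanking:
    gains = np.array(
        [information_gain(X[c].to_numpy(), labels, binning) for c in X.columns]
    )
    order = np.argsort(-gains, kind="stable")
    return FeatureRanking(feature_names=list(X.columns), gains=gains, order=order)


def ig_filter(
    X: pd.DataFrame,
    labels,
    threshold: float = 0.0,
    binning: BinningConfig | None = None,
) -> FeatureMask:
    """Keep features whose gain strictly exceeds the threshold.

    An empty result is repaired to the single top-ranked feature.
    """
    if threshold < 0:
        raise ConfigurationError("threshold must be non-negative")
    ranking = rank_features(X, labels, binning)
    mask = ranking.gains > threshold
    if not mask.any():
        mask[int(ranking.order[0])] = True
    return FeatureMask(mask, provenance="ig_filter", feature_names=list(X.columns))


# ---------------------------------------------------------------------------
# wrapper stages


def _internal_split(X: pd.DataFrame, y: np.ndarray, val_fraction: float, seed: int):
    idx_tr, idx_val = train_test_split(
        np.arange(len(X)),
        test_size=val_fraction,
        random_state=seed,
        stratify=y,
    )
    return idx_tr, idx_val


class _SubsetScorer:
    """Validation accuracy of the configured classifier on a feature subset.

    Results are cached per mask so the herd search never refits the same
    subset twice.
    """

    def __init__(self, X, y, classifier_config, val_fraction, seed):
        self.X = X.to_numpy(dtype=float)
        self.y = np.asarray(y)
        self.config = classifier_config
        self.seed = seed
        self.idx_tr, self.idx_val = _internal_split(X, self.y, val_fraction, seed)
        self._cache: dict[tuple, float] = {}

    def accuracy(self, mask: np.ndarray) -> float:
        key = tuple(np.flatnonzero(mask).tolist())
        if key in self._cache:
            return self._cache[key]
        cols = np.flatnonzero(mask)
        try:
            clf = self.config.build(self.seed)
            clf.fit(self.X[np.ix_(self.idx_tr, cols)], self.y[self.idx_tr])
            pred = clf.predict(self.X[np.ix_(self.idx_val, cols)])
            acc = float(np.mean(pred == self.y[self.idx_val]))
        except Exception as exc:  # classifier failure -> worst-case fitness
            logger.warning("classifier failed on subset %s: %s", key, exc)
            acc = 0.0
        self._cache[key] = acc
        return acc


def abo_wrapper_select(
    X: pd.DataFrame,
    labels,
    mask_in: FeatureMask,
    classifier_config: ClassifierConfig | None = None,
    abo_config: abo.ABOConfig | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> FeatureMask:
    """Herd search over subsets of the incoming mask.

    The optimizer works on a continuous position of length equal to the
    number of incoming features, binarized by a sigmoid transfer; fitness
    is 1 minus validation accuracy. The incoming mask itself seeds the
    herd, so the returned subset never scores worse than it.
    """
    if classifier_config is None:
        classifier_config = ClassifierConfig()
    if abo_config is None:
        abo_config = abo.ABOConfig(n_buffalo=15, max_iterations=20, bounds=(-4.0, 4.0))
    abo_config = replace(abo_config, seed=seed)
    active = np.flatnonzero(mask_in.values)
    scorer = _SubsetScorer(X, labels, classifier_config, val_fraction, seed)
    if active.size == 1:
        return FeatureMask(
            mask_in.values.copy(), "abo_wrapper", feature_names=list(X.columns)
        )

    def objective(w: np.ndarray) -> float:
        sub = abo.binarize_position(w, transfer="sigmoid", cutoff=0.5)
        full = np.zeros(mask_in.values.size, dtype=bool)
        full[active[sub]] = True
        return 1.0 - scorer.accuracy(full)

    low, high = abo_config.bounds
    x0 = np.full(active.size, 0.75 * high)  # sigmoid(3) ~ 0.95: the full mask
    result = abo.minimize(objective, active.size, abo_config, x0=x0)
    best_acc = 1.0 - result.best_f
    # parsimony tie-break: among every evaluated subset achieving the best
    # validation accuracy, return the smallest (lexicographic on indices for
    # determinism); no size term enters the fitness itself
    best_key = min(
        (k for k, a in scorer._cache.items() if a >= best_acc),
        key=lambda k: (len(k), k),
    )
    full = np.zeros(mask_in.values.size, dtype=bool)
    full[list(best_key)] = True
    logger.info(
        "abo_wrapper: %d -> %d features, val accuracy %.4f",
        active.size, int(full.sum()), best_acc,
    )
    return FeatureMask(full, provenance="abo_wrapper", feature_names=list(X.columns))


def backward_eliminate(
    X: pd.DataFrame,
    labels,
    mask_in: FeatureMask,
    classifier_config: ClassifierConfig | None = None,
    val_fraction: float = 0.2,
    seed: int = 0,
    binning: BinningConfig | None = None,
) -> FeatureMask:
    """One-by-one backward elimination driven by validation accuracy.

    Features are scanned in ascending information-gain order (weakest
    candidates first); each is tentatively removed and permanently dropped
    only when validation accuracy strictly improves -- a tie keeps the
    feature. Scanning repeats until a full pass makes no removal or a
    single feature remains. The final accuracy therefore never falls below
    the initial one.
    """
    if classifier_config is None:
        classifier_config = ClassifierConfig()
    scorer = _SubsetScorer(X, labels, classifier_config, val_fraction, seed)
    mask = mask_in.values.copy()
    ranking = rank_features(X, labels, binning)
    scan_order = [int(i) for i in np.argsort(ranking.gains, kind="stable")]
    acc = scorer.accuracy(mask)
    initial_acc = acc
    removed = True
    while removed and mask.sum() > 1:
        removed = False
        for j in scan_order:
            if not mask[j] or mask.sum() <= 1:
                continue
            trial = mask.copy()
            trial[j] = False
            trial_acc = scorer.accuracy(trial)
            if trial_acc > acc:
                logger.debug(
                    "eliminate %s: %.4f -> %.4f", X.columns[j], acc, trial_acc
                )
                mask = trial
                acc = trial_acc
                removed = True
            else:
                logger.debug("keep %s (%.4f <= %.4f)", X.columns[j], trial_acc, acc)
    assert acc >= initial_acc
    logger.info(
        "backward_eliminate: %d -> %d features, val accuracy %.4f -> %.4f",
        mask_in.n_selected, int(mask.sum()), initial_acc, acc,
    )
    return FeatureMask(mask, provenance="backward_elimination",
                       feature_names=list(X.columns))


@dataclass
class SelectionResult:
    """Final mask plus the per-stage provenance trail."""

    mask: FeatureMask
    ranking: FeatureRanking
    stage_masks: dict[str, FeatureMask]


def hybrid_select(
    X: pd.DataFrame, labels, config: SelectionConfig | None = None
) -> SelectionResult:
    """Compose filter -> herd wrapper -> backward elimination.

    Each stage can be disabled in the config; with all stages off the full
    mask is returned. Later stages only ever remove features, so the final
    subset is nested in the filter's output.
    """
    if config is None:
        config = SelectionConfig()
    labels = np.asarray(labels)
    ranking = rank_features(X, labels, config.binning)
    mask = FeatureMask(
        np.ones(X.shape[1], dtype=bool), "input", feature_names=list(X.columns)
    )
    stage_masks: dict[str, FeatureMask] = {}
    if config.use_ig_filter:
        mask = ig_filter(X, labels, config.ig_threshold, config.binning)
        stage_masks["ig_filter"] = mask
    if config.use_abo_wrapper:
        mask = abo_wrapper_select(
            X, labels, mask,
            classifier_config=config.classifier,
            abo_config=config.wrapper_abo,
            val_fraction=config.val_fraction,
            seed=config.seed,
        )
        stage_masks["abo_wrapper"] = mask
    if config.use_backward_elimination:
        mask = backward_eliminate(
            X, labels, mask,
            classifier_config=config.classifier,
            val_fraction=config.val_fraction,
            seed=config.seed,
            binning=config.binning,
        )
        stage_masks["backward_elimination"] = mask
    return SelectionResult(mask=mask, ranking=ranking, stage_masks=stage_masks)
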