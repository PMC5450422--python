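"""Group statistics and classification of leaflet feature tables.

A feature table is a pandas DataFrame with one row per leaflet sample, a
``group`` label column (developmental stage L1..Ln, genotype, ...) and
named numeric parameter columns.  Because most blade and margin parameters
are not normally distributed, group comparisons report both one-way ANOVA
and Kruskal-Wallis p-values, with per-group mean +- s.e. and a pairwise
significance flag based on non-overlapping 95% confidence intervals.

Classification of four or more leaflet groups uses either k-means
clustering or a shallow feedforward neural network on three to four
z-scored parameters; the network is evaluated over repeated stratified
75/25 train/test splits.  A genetic algorithm searches the space of
feature subsets for combinations reaching a target accuracy.  All
randomness is driven by explicit integer seeds, and every result object
records the seed it was produced with.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

GROUP_COL = "group"


@dataclass
class GroupComparison:
    parameter: str
    groups: dict                 # label -> dict(mean, sem, n, dispersion)
    anova_p: float
    kruskal_p: float
    significant_pairs: dict      # (label_a, label_b) -> bool (95% CI disjoint)
    confidence: float = 0.95


@dataclass
class ClassificationResult:
    method: str
    feature_subset: tuple
    group_labels: tuple
    confusion_matrix: np.ndarray  # rows = true group, cols = assigned
    accuracy: float               # mean held-out accuracy (ann) / overall (kmeans)
    pooled_accuracy: float        # trace / total of the aggregated matrix
    n_repeats: int
    seed: int

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion_matrix,
                            index=list(self.group_labels),
                            columns=list(self.group_labels))


@dataclass
class MorphospaceEllipsoid:
    label: str
    center: np.ndarray            # 3-vector of feature means
    covariance: np.ndarray        # 3x3 sample covariance
    confidence: float = 0.95
    n: int = 0

    def semi_axes(self) -> np.ndarray:
        """Lengths of the ellipsoid semi-axes at the confidence level."""
        chi2 = stats.chi2.ppf(self.confidence, df=len(self.center))
        eigvals = np.clip(np.linalg.eigvalsh(self.covariance), 0.0, None)
        return np.sqrt(chi2 * eigvals)


def _group_arrays(table: pd.DataFrame, parameter: str,
                  groups=None) -> dict[str, np.ndarray]:
    if GROUP_COL not in table.columns:
        raise ValueError(f"feature table lacks a {GROUP_COL!r} column")
    if parameter not in table.columns:
        raise ValueError(f"unknown parameter {parameter!r}")
    labels = list(groups) if groups is not None else (
        list(pd.unique(table[GROUP_COL]))
    )
    out = {}
    for lab in labels:
        vals = table.loc[table[GROUP_COL] == lab, parameter].dropna().to_numpy()
        out[lab] = vals.astype(float)
    return out


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    groups=None,
    confidence: float = 0.95,
) -> GroupComparison:
    """One-way ANOVA and Kruskal-Wallis comparison of one parameter.

    Per group: mean, standard error, n and dispersion (sd/mean).  Pairs of
    groups are flagged significant when their t-based confidence intervals
    of the mean do not overlap.  Requires at least two groups with n >= 2.
    """
    arrays = _group_arrays(table, parameter, groups)
    arrays = {k: v for k, v in arrays.items() if len(v)}
    if len(arrays) < 2:
        raise ValueError("need at least two non-empty groups")
    if any(len(v) < 2 for v in arrays.values()):
        raise ValueError("every group needs n >= 2")
    values = list(arrays.values())
    anova_p = float(stats.f_oneway(*values).pvalue)
    kruskal_p = float(stats.kruskal(*values).pvalue)

    summary = {}
    ci = {}
    for lab, v in arrays.items():
        mean = float(np.mean(v))
        sem = float(stats.sem(v))
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, df=len(v) - 1)
        ci[lab] = (mean - tcrit * sem, mean + tcrit * sem)
        summary[lab] = {
            "mean": mean,
            "sem": sem,
            "n": len(v),
            "dispersion": float(np.std(v, ddof=1) / mean) if mean else np.nan,
        }
    sig = {}
    for a, b in itertools.combinations(arrays, 2):
        lo_a, hi_a = ci[a]
        lo_b, hi_b = ci[b]
        sig[(a, b)] = bool(hi_a < lo_b or hi_b < lo_a)
    return GroupComparison(
        parameter=parameter, groups=summary, anova_p=anova_p,
        kruskal_p=kruskal_p, significant_pairs=sig, confidence=confidence,
    )


def _design(table: pd.DataFrame, features) -> tuple[np.ndarray, np.ndarray, tuple]:
    features = tuple(features)
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    sub = table.dropna(subset=list(features))
    X = sub[list(features)].to_numpy(dtype=float)
    y = sub[GROUP_COL].to_numpy()
    return X, y, features


def kmeans_classify(
    table: pd.DataFrame,
    features,
    k: int | None = None,
    seed: int = 0,
) -> ClassificationResult:
    """k-means clustering of z-scored features, scored against true groups.

    Cluster labels are mapped to group labels by the accuracy-maximizing
    assignment (optimal bipartite matching on the contingency table).
    """
    X, y, features = _design(table, features)
    labels = tuple(pd.unique(y))
    if k is None:
        k = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError("k exceeds the number of samples")
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    assign = km.fit_predict(Xs)

    # contingency: true group x cluster
    cont = np.zeros((len(labels), k), dtype=int)
    lab_index = {lab: i for i, lab in enumerate(labels)}
    for yi, ci in zip(y, assign):
        cont[lab_index[yi], ci] += 1
    rows, cols = linear_sum_assignment(-cont)
    mapping = {c: r for r, c in zip(rows, cols)}
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    for yi, ci in zip(y, assign):
        mapped = mapping.get(ci)
        if mapped is None:  # extra cluster beyond group count
            mapped = int(np.argmax(cont[:, ci]))
        confusion[lab_index[yi], mapped] += 1
    acc = float(np.trace(confusion) / confusion.sum())
    return ClassificationResult(
        method="kmeans", feature_subset=features, group_labels=labels,
        confusion_matrix=confusion, accuracy=acc, pooled_accuracy=acc,
        n_repeats=1, seed=seed,
    )


def ann_classify(
    table: pd.DataFrame,
    features,
    hidden_units: int = 8,
    n_repeats: int = 30,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> ClassificationResult:
    """Feedforward-network classification over repeated 75/25 splits.

    Each repeat draws a stratified random split, trains a single-hidden-
    layer perceptron (*hidden_units* units, lbfgs) on standardized
    training features and scores the held-out quarter.  ``accuracy`` is
    the mean held-out accuracy over repeats; the aggregated confusion
    matrix (summed over repeats) also yields ``pooled_accuracy``.
    """
    if not (3 <= hidden_units <= 64):
        raise ValueError("hidden_units out of the supported range")
    X, y, features = _design(table, features)
    labels = tuple(pd.unique(y))
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < 4]
    if len(too_small):
        raise ValueError(
            "groups too small for a stratified 75/25 split: "
            + ", ".join(map(str, too_small.index))
        )
    lab_index = {lab: i for i, lab in enumerate(labels)}
    rng_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    accs = []
    for rs in rng_seeds:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, stratify=y, random_state=int(rs)
        )
        scaler = StandardScaler().fit(X_tr)
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden_units,), solver="lbfgs",
            max_iter=800, random_state=int(rs),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lbfgs convergence chatter
            clf.fit(scaler.transform(X_tr), y_tr)
        pred = clf.predict(scaler.transform(X_te))
        accs.append(float(np.mean(pred == y_te)))
        for yt, yp in zip(y_te, pred):
            confusion[lab_index[yt], lab_index[yp]] += 1
    return ClassificationResult(
        method="ann", feature_subset=features, group_labels=labels,
        confusion_matrix=confusion, accuracy=float(np.mean(accs)),
        pooled_accuracy=float(np.trace(confusion) / confusion.sum()),
        n_repeats=n_repeats, seed=seed,
    )


def _fitness_factory(table, classifier, seed, ann_repeats):
    cache: dict[tuple, float] = {}

    def fitness(subset: tuple) -> float:
        key = tuple(sorted(subset))
        if key not in cache:
            if classifier == "kmeans":
                res = kmeans_classify(table, key, seed=seed)
            elif classifier == "ann":
                res = ann_classify(table, key, n_repeats=ann_repeats, seed=seed)
            else:
                raise ValueError(f"unknown classifier {classifier!r}")
            cache[key] = res.accuracy
        return cache[key]

    return fitness, cache


def ga_select_features(
    table: pd.DataFrame,
    classifier: str = "kmeans",
    subset_size: int = 3,
    min_accuracy: float = 0.85,
    seed: int = 0,
    population_size: int = 40,
    generations: int = 60,
    mutation_rate: float = 0.25,
    elitism: int = 2,
    ann_repeats: int = 5,
) -> list[tuple[tuple, float]]:
    """Genetic-algorithm search for high-accuracy feature subsets.

    Individuals are feature subsets of fixed size; fitness is the
    classification accuracy of the chosen classifier on that subset.
    Tournament selection, uniform membership crossover (child drawn from
    the parents' union), single-feature swap mutation, small elitism.
    Returns every subset evaluated during the run that reaches
    *min_accuracy*, de-duplicated and ranked by accuracy (best first);
    an empty list when none qualifies.
    """
    candidates = [
        c for c in table.columns
        if c != GROUP_COL and pd.api.types.is_numeric_dtype(table[c])
        and table[c].notna().any() and table[c].std() > 0
    ]
    if len(candidates) < subset_size:
        raise ValueError("fewer candidate features than subset_size")
    rng = np.random.default_rng(seed)
    fitness, cache = _fitness_factory(table, classifier, seed, ann_repeats)

    def random_subset():
        return tuple(sorted(rng.choice(candidates, subset_size, replace=False)))

    pop = [random_subset() for _ in range(population_size)]
    for _ in range(generations):
        scored = sorted(pop, key=fitness, reverse=True)
        nxt = scored[:elitism]
        while len(nxt) < population_size:
            # tournament of 3 per parent
            def pick():
                contenders = [pop[i] for i in
                              rng.choice(len(pop), 3, replace=False)]
                return max(contenders, key=fitness)

            pa, pb = pick(), pick()
            union = sorted(set(pa) | set(pb))
            child = tuple(sorted(rng.choice(union, subset_size, replace=False)))
            if rng.random() < mutation_rate:
                outside = [c for c in candidates if c not in child]
                if outside:
                    child = list(child)
                    child[rng.integers(subset_size)] = outside[
                        rng.integers(len(outside))
                    ]
                    child = tuple(sorted(set(child)))
                    while len(child) < subset_size:
                        extra = [c for c in candidates if c not in child]
                        child = tuple(sorted(
                            child + (extra[rng.integers(len(extra))],)
                        ))
            nxt.append(child)
        pop = nxt
    for subset in pop:  # make sure the final generation is scored
        fitness(subset)
    hits = [(k, v) for k, v in cache.items() if v >= min_accuracy]
    hits.sort(key=lambda kv: (-kv[1], kv[0]))
    return hits


def morphospace_ellipsoids(
    table: pd.DataFrame,
    features,
    confidence: float = 0.95,
    min_n: int = 4,
) -> list[MorphospaceEllipsoid]:
    """Per-group 95% confidence ellipsoids in a 3-feature morphospace."""
    features = tuple(features)
    if len(features) != 3:
        raise ValueError("morphospace requires exactly 3 features")
    X, y, features = _design(table, features)
    out = []
    for lab in pd.unique(y):
        pts = X[y == lab]
        if len(pts) < min_n:
            warnings.warn(f"group {lab!r} has n < {min_n}; skipped")
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        out.append(MorphospaceEllipsoid(
            label=str(lab), center=center, covariance=cov,
            confidence=confidence, n=len(pts),
        ))
    return out
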