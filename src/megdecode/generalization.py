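"""Temporal cross-category generalization with cluster permutation inference.

A classifier trained to separate two stimulus groups at train-time T1 is
tested on a (possibly different) pair of groups at every test-time T2,
yielding a train x test accuracy matrix.  When a test group coincides with
a train group, all image combinations in which the same exemplar appears in
both the training and the testing pair are excluded, so the classifier is
never evaluated on an exemplar it was trained to separate; with fully
distinct groups the train/test independence holds automatically.  Cells on
the diagonal of a same-pair specification are replaced by cross-validated
accuracies.

Group-level inference uses a sign-flip permutation test on the maximal
4-connected cluster size: cell-wise one-sample t of (accuracy - chance),
thresholded at the cluster-definition p, clusters scored by size, and the
null built by randomly flipping the sign of each subject's whole matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from scipy import stats as sps

from .datamodel import ConfigError, ConditionDesign, PipelineConfig, SourceDataset
from .mvpa import LDA_RIDGE, cv_accuracy_timecourse, prepare_subject_region

__all__ = [
    "Group",
    "GeneralizationSpec",
    "GeneralizationMatrix",
    "ClusterResult",
    "admissible_combinations",
    "generalization_matrix",
    "cluster_permutation_2d",
]

_CONNECTIVITY_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _image_of(condition_label: str) -> str:
    return condition_label.rsplit(":", 1)[0]


@dataclass(frozen=True)
class Group:
    """A named set of conditions acting as one class (e.g. post-state faces)."""

    name: str
    conditions: tuple[str, ...]

    def __post_init__(self):
        if not self.conditions:
            raise ConfigError(f"group {self.name!r} has no conditions")


@dataclass(frozen=True)
class GeneralizationSpec:
    """Train pair (A vs B) and test pair (C vs D) with class correspondence
    A<->C, B<->D."""

    train_groups: tuple[Group, Group]
    test_groups: tuple[Group, Group]

    @property
    def all_conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in (*self.train_groups, *self.test_groups):
            for c in g.conditions:
                if c not in seen:
                    seen.append(c)
        return tuple(seen)

    @property
    def same_pair(self) -> bool:
        return (self.train_groups[0] == self.test_groups[0]
                and self.train_groups[1] == self.test_groups[1])


@dataclass
class GeneralizationMatrix:
    """Train-time x test-time accuracies per subject."""

    accuracy: np.ndarray      # (n_subjects, n_train_bins, n_test_bins)
    subjects: list[str]
    bin_times: np.ndarray
    combos_used: int


@dataclass
class ClusterResult:
    clusters: list[tuple[np.ndarray, int, float]]   # (cell mask, size, p)
    significant: list[tuple[np.ndarray, int, float]] = field(
        default_factory=list)
    t_map: np.ndarray | None = None
    max_null_sizes: np.ndarray | None = None


def admissible_combinations(spec: GeneralizationSpec
                            ) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """Enumerate ((train_a, train_b), (test_a, test_b)) condition choices.

    One condition (exemplar) is chosen per group for the training and the
    testing pair.  For every group shared between the train and test sides,
    the exemplar chosen for training must differ from the one chosen for
    testing; with no shared group all combinations are kept.
    """
    A, B = spec.train_groups
    C, D = spec.test_groups
    shared = [(tg, sg) for tg in (0, 1) for sg in (0, 1)
              if spec.train_groups[tg] == spec.test_groups[sg]]
    combos = []
    for ta, tb, ca, cb in product(A.conditions, B.conditions,
                                  C.conditions, D.conditions):
        train, test = (ta, tb), (ca, cb)
        if any(_image_of(train[tg]) == _image_of(test[sg])
               for tg, sg in shared):
            continue
        combos.append((train, test))
    if not combos:
        raise ConfigError(
            "exemplar-exclusion rules left no admissible train/test "
            "combination for this specification"
        )
    return combos


def _lda_timecourse(A: np.ndarray, B: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Full-data LDA per time bin.  A, B: (k, T, d) -> w (T, d), b (T,)."""
    At = np.asarray(A, float).transpose(1, 0, 2)
    Bt = np.asarray(B, float).transpose(1, 0, 2)
    k = At.shape[1]
    mu_a, mu_b = At.mean(axis=1), Bt.mean(axis=1)
    dev_a = At - mu_a[:, None]
    dev_b = Bt - mu_b[:, None]
    cov = (np.einsum("tkd,tke->tde", dev_a, dev_a)
           + np.einsum("tkd,tke->tde", dev_b, dev_b)) / (2 * k - 2)
    d = At.shape[2]
    ridge = (LDA_RIDGE / d) * np.trace(cov, axis1=-2, axis2=-1)
    cov = cov + ridge[:, None, None] * np.eye(d)
    w = np.linalg.solve(cov, (mu_a - mu_b)[..., None])[..., 0]
    b = np.einsum("td,td->t", w, (mu_a + mu_b) / 2.0)
    return w, b


def generalization_matrix(dataset: SourceDataset, region: str,
                          spec: GeneralizationSpec, config: PipelineConfig,
                          design: ConditionDesign | None = None,
                          ) -> GeneralizationMatrix:
    """Per-subject train-time x test-time accuracy for one specification.

    Classifiers are trained per admissible exemplar combination on all
    pseudo-trials of the training pair at T1 and tested on the test pair's
    pseudo-trials at every T2; accuracies are averaged over combinations.
    The PC basis is fit on all conditions referenced by the specification
    (or on an explicit ``design``) so train and test share a feature space.
    """
    combos = admissible_combinations(spec)
    if design is None:
        design = dataset.design
    needed = set(spec.all_conditions)
    missing = needed - set(design.labels)
    if missing:
        raise ConfigError(f"spec references unknown conditions {sorted(missing)}")
    mats = []
    bin_times = None
    for subject in dataset.subjects:
        feats = prepare_subject_region(dataset, subject, region, design, config)
        bin_times = feats.bin_times
        T = len(bin_times)
        acc = np.zeros((T, T))
        for (train_a, train_b), (test_a, test_b) in combos:
            A = feats.scores[train_a]
            B = feats.scores[train_b]
            w, b = _lda_timecourse(A, B)
            Xa = feats.scores[test_a].transpose(1, 0, 2)   # (T2, k, d)
            Xb = feats.scores[test_b].transpose(1, 0, 2)
            sa = np.einsum("ud,tkd->utk", w, Xa) - b[:, None, None]
            sb = np.einsum("ud,tkd->utk", w, Xb) - b[:, None, None]
            correct = (sa >= 0).mean(axis=2) + (sb < 0).mean(axis=2)
            combo_acc = correct / 2.0                      # (T1, T2)
            if (train_a, train_b) == (test_a, test_b):
                diag = cv_accuracy_timecourse(A, B)
                combo_acc[np.diag_indices(T)] = diag
            acc += combo_acc
        mats.append(acc / len(combos))
    return GeneralizationMatrix(
        accuracy=np.stack(mats), subjects=list(dataset.subjects),
        bin_times=bin_times, combos_used=len(combos))


def _t_map(data: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """Cell-wise one-sample t of sign-flipped (accuracy - chance) data."""
    x = data if signs is None else data * signs[:, None, None]
    n = x.shape[0]
    m = x.mean(axis=0)
    s = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (s / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def _max_cluster_size(supra: np.ndarray) -> int:
    labels, n = ndimage.label(supra, structure=_CONNECTIVITY_4)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(supra, labels, range(1, n + 1))))


def cluster_permutation_2d(matrices: np.ndarray, chance: float = 0.5,
                           config: PipelineConfig | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> ClusterResult:
    """Max-cluster-size sign-flip permutation test on accuracy matrices.

    ``matrices`` is (n_subjects, T1, T2).  Above-chance cells passing the
    two-sided cluster-definition threshold form 4-connected clusters; the
    null flips the sign of each subject's whole (matrix - chance).
    """
    cfg = config if config is not None else PipelineConfig()
    mats = np.asarray(matrices, dtype=float)
    if mats.ndim != 3 or mats.shape[0] < 2:
        raise ConfigError("need (n_subjects >= 2, T1, T2) accuracy matrices")
    n_subj = mats.shape[0]
    n_perm = cfg.n_permutations
    if n_perm < 100:
        warnings.warn(
            f"{n_perm} permutations give a very coarse null distribution",
            stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    data = mats - chance
    t_crit = float(sps.t.ppf(1.0 - cfg.cluster_definition_p / 2.0, n_subj - 1))

    t_obs = _t_map(data)
    supra = t_obs > t_crit
    labels, n_clusters = ndimage.label(supra, structure=_CONNECTIVITY_4)

    null_max = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_subj)
        null_max[i] = _max_cluster_size(
            _t_map(data, signs) > t_crit)

    clusters = []
    for c in range(1, n_clusters + 1):
        mask = labels == c
        size = int(mask.sum())
        p = float((1 + np.sum(null_max >= size)) / (n_perm + 1))
        clusters.append((mask, size, p))
    clusters.sort(key=lambda item: -item[1])
    significant = [c for c in clusters if c[2] < cfg.cluster_alpha]
    return ClusterResult(clusters=clusters, significant=significant,
                         t_map=t_obs, max_null_sizes=null_max)
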