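"""Region-based MVPA: downsampling, pseudo-trials, PC features, pairwise LDA.

The decoding unit is one subject x region.  Raw epochs are restricted to
the analysis window, averaged into 10 ms bins, reduced to ``k`` pseudo-
trials per condition (averages of disjoint random trial groups), projected
onto the region's three leading principal components (one shared basis per
subject x region, fit across all conditions and analysis-window bins so
that patterns at different times and conditions live in a common feature
space), and classified pairwise with a regularised LDA.  Accuracy is the
mean over all k^2 leave-one-per-class train/test splits (100 folds at the
default k = 10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .datamodel import (
    ConditionDesign,
    ConditionExcluded,
    ConfigError,
    PipelineConfig,
    SourceDataset,
    window_mask,
)

__all__ = [
    "PseudoTrials",
    "RegionFeatures",
    "TrainedClassifier",
    "RdmStack",
    "downsample_epochs",
    "make_pseudotrials",
    "extract_region_features",
    "train_lda",
    "cross_validated_accuracy",
    "cv_accuracy_timecourse",
    "compute_empirical_rdms",
    "prepare_subject_region",
    "analysis_bin_times",
    "pseudotrial_rng",
]

LDA_RIDGE = 1e-6


def downsample_epochs(epochs: np.ndarray, ratio: int) -> np.ndarray:
    """Average consecutive groups of ``ratio`` samples along the time axis.

    The final bin may be partial (e.g. 501 samples at ratio 10 give 50 full
    bins plus one single-sample bin, 51 in total).  ``ratio`` of 1 is the
    identity.
    """
    if ratio <= 0:
        raise ConfigError("downsample ratio must be a positive integer")
    if ratio == 1:
        return epochs
    V, T = epochs.shape[0], epochs.shape[1]
    n_bins = int(np.ceil(T / ratio))
    out_shape = (V, n_bins) + epochs.shape[2:]
    out = np.empty(out_shape, dtype=np.result_type(epochs, np.float64))
    for b in range(n_bins):
        out[:, b] = epochs[:, b * ratio:(b + 1) * ratio].mean(axis=1)
    return out


def _bin_centres(values: np.ndarray, ratio: int) -> np.ndarray:
    n_bins = int(np.ceil(len(values) / ratio))
    return np.array([values[b * ratio:(b + 1) * ratio].mean()
                     for b in range(n_bins)])


def analysis_bin_times(time_axis: np.ndarray,
                       config: PipelineConfig) -> np.ndarray:
    """Centre times (ms) of the analysis bins for a given raw time axis."""
    step = float(np.diff(time_axis).mean())
    mask = window_mask(time_axis, config.analysis_window_ms)
    return _bin_centres(np.asarray(time_axis, float)[mask],
                        config.effective_ratio(step))


@dataclass
class PseudoTrials:
    """Pseudo-trials of one condition: disjoint-group trial averages."""

    data: np.ndarray                       # (k, n_vertices, n_timebins)
    group_sizes: np.ndarray                # (k,)
    source_trial_indices: list[np.ndarray]


@dataclass
class RegionFeatures:
    """Shared PC basis and per-condition scores of one subject x region.

    ``scores`` are mean-centred (the PCA convention) and feed the
    classifiers, where the common offset is irrelevant to LDA.
    ``score_offset`` is the projection of the PCA mean onto the basis;
    adding it back gives raw response projections, which is what physical
    power measures use (RMS of a centred score would cancel exactly the
    condition-average response it is meant to quantify).
    """

    pc_basis: np.ndarray                   # (n_vertices, n_pc), orthonormal
    scores: dict[str, np.ndarray]          # condition -> (k, n_timebins, n_pc)
    explained_variance: np.ndarray         # variance ratios, non-increasing
    bin_times: np.ndarray = field(default_factory=lambda: np.zeros(0))
    score_offset: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def raw_scores(self, condition: str) -> np.ndarray:
        """Uncentred projections: scores plus the common PCA-mean offset."""
        return self.scores[condition] + self.score_offset


@dataclass(frozen=True)
class TrainedClassifier:
    """A pairwise LDA: discriminant normal ``w``, offset ``b``.

    ``w`` points toward ``class_order[0]``: samples with ``w @ x >= b`` are
    assigned to the first class (ties deterministically to the first).
    """

    w: np.ndarray
    b: float
    class_order: tuple[str, str]

    def predict_first(self, X: np.ndarray) -> np.ndarray:
        """Boolean: True where a sample is classified as class_order[0]."""
        return X @ self.w >= self.b


def make_pseudotrials(trials: np.ndarray, k: int, min_trials: int,
                      rng: np.random.Generator,
                      subject: str | None = None,
                      condition: str = "") -> PseudoTrials:
    """Partition trials into ``k`` disjoint near-equal groups and average.

    With n in [50, 80] and k = 10 every group holds five to eight trials.
    Conditions below ``min_trials`` raise :class:`ConditionExcluded`.
    """
    n = trials.shape[-1]
    if n < min_trials:
        raise ConditionExcluded(subject, condition, n, min_trials)
    if k > n:
        raise ConfigError(f"cannot form {k} pseudo-trials from {n} trials")
    perm = rng.permutation(n)
    groups = np.array_split(perm, k)
    data = np.stack([trials[..., g].mean(axis=-1) for g in groups])
    sizes = np.array([len(g) for g in groups])
    return PseudoTrials(data=data, group_sizes=sizes,
                        source_trial_indices=[np.sort(g) for g in groups])


def extract_region_features(pseudotrials: dict[str, PseudoTrials],
                            n_pc: int = 3,
                            bin_times: np.ndarray | None = None,
                            ) -> RegionFeatures:
    """PCA over the vertex dimension, shared across conditions and bins.

    The fit pools every pseudo-trial of every condition at every analysis
    bin (rows = samples, columns = vertices) so all downstream classifiers
    operate in one common ``n_pc``-dimensional space.
    """
    conds = list(pseudotrials)
    first = pseudotrials[conds[0]].data
    k, V, T = first.shape
    if V < n_pc:
        raise ConfigError(f"{V} vertices < {n_pc} requested components")
    rows = np.concatenate([
        pseudotrials[c].data.transpose(0, 2, 1).reshape(-1, V) for c in conds
    ])
    pca = PCA(n_components=n_pc, svd_solver="full")
    pca.fit(rows)
    basis = pca.components_.T                      # (V, n_pc)
    scores = {}
    for c in conds:
        flat = pseudotrials[c].data.transpose(0, 2, 1).reshape(-1, V)
        scores[c] = pca.transform(flat).reshape(k, T, n_pc)
    return RegionFeatures(
        pc_basis=basis,
        scores=scores,
        explained_variance=pca.explained_variance_ratio_,
        bin_times=bin_times if bin_times is not None else np.zeros(0),
        score_offset=pca.mean_ @ basis,
    )


def _pooled_lda(mu_a: np.ndarray, mu_b: np.ndarray,
                cov_pooled: np.ndarray) -> tuple[np.ndarray, float]:
    d = mu_a.shape[-1]
    ridge = LDA_RIDGE * np.trace(cov_pooled) / d
    sigma = cov_pooled + ridge * np.eye(d)
    try:
        w = np.linalg.solve(sigma, mu_a - mu_b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate
        raise np.linalg.LinAlgError(
            "pooled covariance singular even after ridge regularisation"
        ) from exc
    b = float(w @ (mu_a + mu_b) / 2.0)
    return w, b


def train_lda(features_a: np.ndarray, features_b: np.ndarray,
              class_order: tuple[str, str] = ("A", "B")) -> TrainedClassifier:
    """Fisher LDA with pooled covariance and a small ridge.

    ``w`` is proportional to ``pooled_cov^-1 (mu_A - mu_B)``; the decision
    boundary sits midway between the projected class means.
    """
    A = np.asarray(features_a, dtype=float)
    B = np.asarray(features_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ConfigError("class feature arrays must be 2-D with equal width")
    mu_a, mu_b = A.mean(0), B.mean(0)
    Sa = (A - mu_a).T @ (A - mu_a)
    Sb = (B - mu_b).T @ (B - mu_b)
    df = A.shape[0] + B.shape[0] - 2
    if df <= 0:
        raise ConfigError("need at least 2 samples per class")
    w, b = _pooled_lda(mu_a, mu_b, (Sa + Sb) / df)
    return TrainedClassifier(w=w, b=b, class_order=class_order)


def cv_accuracy_timecourse(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Leave-one-per-class CV accuracy, vectorised over time bins.

    ``A`` and ``B`` have shape ``(k, T, d)``; the result has shape ``(T,)``.
    All ``k^2`` held-out pairs are enumerated; training statistics for each
    fold are obtained by downdating the full-class sums.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ConfigError("both classes need equal pseudo-trial counts")
    k, T, d = A.shape
    if k < 3:
        raise ConfigError("need at least 3 pseudo-trials per class")
    At = A.transpose(1, 0, 2)      # (T, k, d)
    Bt = B.transpose(1, 0, 2)

    def loo_stats(X):
        S = X.sum(axis=1)                                   # (T, d)
        mu = (S[:, None, :] - X) / (k - 1)                  # (T, k, d)
        G = np.einsum("tkd,tke->tde", X, X)                 # (T, d, d)
        outer = np.einsum("tkd,tke->tkde", X, X)            # (T, k, d, d)
        cov = (G[:, None] - outer
               - (k - 1) * np.einsum("tkd,tke->tkde", mu, mu))
        return mu, cov

    muA, covA = loo_stats(At)
    muB, covB = loo_stats(Bt)
    df = 2 * k - 4
    sigma = (covA[:, :, None] + covB[:, None, :]) / df      # (T, k, k, d, d)
    ridge = (LDA_RIDGE / d) * np.trace(sigma, axis1=-2, axis2=-1)
    sigma = sigma + ridge[..., None, None] * np.eye(d)
    delta = muA[:, :, None, :] - muB[:, None, :, :]         # (T, k, k, d)
    w = np.linalg.solve(sigma, delta[..., None])[..., 0]
    b = np.einsum("tijd,tijd->tij", w, (muA[:, :, None, :]
                                        + muB[:, None, :, :]) / 2.0)
    score_a = np.einsum("tijd,tid->tij", w, At) - b
    score_b = np.einsum("tijd,tjd->tij", w, Bt) - b
    correct = (score_a >= 0).astype(float) + (score_b < 0)
    return correct.mean(axis=(1, 2)) / 2.0


def cross_validated_accuracy(pseudo_a: np.ndarray,
                             pseudo_b: np.ndarray) -> float:
    """CV accuracy for one time bin (``(k, d)`` arrays, k^2 folds)."""
    A = np.asarray(pseudo_a, dtype=float)[:, None, :]
    B = np.asarray(pseudo_b, dtype=float)[:, None, :]
    return float(cv_accuracy_timecourse(A, B)[0])


def pseudotrial_rng(seed: int, subject_index: int,
                    condition_index: int) -> np.random.Generator:
    """Deterministic per-(subject, condition) stream for trial grouping.

    The grouping is drawn once per run seed and shared across regions,
    mirroring the fact that a recorded trial spans all regions at once.
    """
    return np.random.default_rng(
        np.random.SeedSequence((seed, subject_index, condition_index)))


def prepare_subject_region(dataset: SourceDataset, subject: str, region: str,
                           design: ConditionDesign, config: PipelineConfig,
                           window_ms: tuple[float, float] | None = None,
                           ) -> RegionFeatures:
    """Window, downsample, pseudo-average and PCA-project one subject x region."""
    t = np.asarray(dataset.time_axis, float)
    win = window_ms if window_ms is not None else config.analysis_window_ms
    mask = window_mask(t, win)
    ratio = config.effective_ratio(dataset.sampling_step_ms)
    bin_times = _bin_centres(t[mask], ratio)
    subj_idx = dataset.subjects.index(subject)
    pseudos: dict[str, PseudoTrials] = {}
    for cond_idx, cond in enumerate(design.labels):
        epochs = dataset.get(subject, region, cond)[:, mask, :]
        binned = downsample_epochs(epochs, ratio)
        rng = pseudotrial_rng(config.rng_seed, subj_idx, cond_idx)
        pseudos[cond] = make_pseudotrials(
            binned, config.n_pseudotrials, config.min_trials, rng,
            subject=subject, condition=cond)
    return extract_region_features(pseudos, config.n_pc, bin_times)


@dataclass
class RdmStack:
    """Pairwise decoding accuracies over subject x region x pair x timebin."""

    accuracies: np.ndarray        # (n_subjects, n_regions, 28, n_timebins)
    subjects: list[str]
    regions: list[str]
    pair_labels: list             # PairLabel order (see rsa module)
    bin_times: np.ndarray
    excluded_subjects: list[str] = field(default_factory=list)

    def rdm(self, subject: str, region: str, timebin: int) -> np.ndarray:
        i = self.subjects.index(subject)
        j = self.regions.index(region)
        return self.accuracies[i, j, :, timebin]


def compute_empirical_rdms(dataset: SourceDataset, design: ConditionDesign,
                           config: PipelineConfig) -> RdmStack:
    """Pairwise CV decoding for all 28 condition pairs of one category.

    Subjects with any condition below the trial-count threshold are dropped
    from the analysis (recorded in ``excluded_subjects``).
    """
    from .rsa import enumerate_condition_pairs

    design.validate_analysis_template()
    pairs = enumerate_condition_pairs(design)
    kept_subjects: list[str] = []
    excluded: list[str] = []
    per_subject: list[np.ndarray] = []
    bin_times = analysis_bin_times(dataset.time_axis, config)
    for subject in dataset.subjects:
        try:
            region_accs = []
            for region in dataset.regions:
                feats = prepare_subject_region(
                    dataset, subject, region, design, config)
                accs = np.empty((len(pairs), len(bin_times)))
                for p_idx, pair in enumerate(pairs):
                    A = feats.scores[pair.member_a]
                    B = feats.scores[pair.member_b]
                    accs[p_idx] = cv_accuracy_timecourse(A, B)
                region_accs.append(accs)
        except ConditionExcluded:
            excluded.append(subject)
            continue
        kept_subjects.append(subject)
        per_subject.append(np.stack(region_accs))
    if not kept_subjects:
        raise ConfigError("every subject was excluded by the trial threshold")
    return RdmStack(
        accuracies=np.stack(per_subject),
        subjects=kept_subjects,
        regions=list(dataset.regions),
        pair_labels=list(pairs),
        bin_times=bin_times,
        excluded_subjects=excluded,
    )
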