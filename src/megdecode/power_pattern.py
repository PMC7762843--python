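"""Dissociating power-driven from pattern-driven recognition effects.

Two complementary measures operate in the region's 3-D PC feature space:

* **RMS power** of the PC scores (per pseudo-trial, then averaged) tracks
  the overall strength of the regional response per condition.
* **Alpha angle**: the angle between the discriminant normals of two LDA
  classifiers — (pre-state object vs nonsense) and (post-state object vs
  nonsense).  A small alpha means recognition left the activity pattern
  intact (any decoding gain must come from power); a large alpha means the
  pattern reorganised.  Alpha is kept on [0, 180] degrees (no folding), and
  is referenced to its pre-stimulus baseline, where pattern similarity is
  at chance.

A pure power effect shows a decoding gain with a positive across-subject
correlation between decoding gain and power gain and alpha at or below
baseline; a pure pattern effect shows a decoding gain with no power
correlation and alpha above baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ConditionDesign, ConfigError, PipelineConfig, SourceDataset
from .mvpa import RegionFeatures, prepare_subject_region, train_lda
from .stats import AnovaTable, TestResult, paired_t, rm_anova

__all__ = [
    "PowerTimecourse",
    "PatternAngleResult",
    "rms_power_timecourse",
    "power_anova",
    "pattern_angle",
    "angle_timecourse_vs_baseline",
    "decoding_power_association",
]

EXACT_SPEARMAN_MAX_N = 8


@dataclass
class PowerTimecourse:
    """Mean RMS of the PC scores per condition x timebin."""

    rms: np.ndarray              # (n_conditions, n_timebins)
    conditions: list[str]
    bin_times: np.ndarray

    def for_condition(self, condition: str) -> np.ndarray:
        return self.rms[self.conditions.index(condition)]


@dataclass
class PatternAngleResult:
    """Alpha-angle timecourses and their baseline comparison."""

    alpha: np.ndarray            # (n_subjects, n_timebins), degrees
    bin_times: np.ndarray
    baseline_alpha: np.ndarray   # (n_subjects,)
    window_alpha: np.ndarray     # (n_subjects,)
    test: TestResult             # paired t: window vs baseline


def rms_power_timecourse(features: RegionFeatures,
                         conditions: list[str] | None = None,
                         ) -> PowerTimecourse:
    """RMS over the PC projections, per pseudo-trial, then averaged.

    Uses raw (uncentred) projections: power quantifies the response
    amplitude itself, not its deviation from the grand-average response.
    """
    conds = conditions if conditions is not None else list(features.scores)
    rows = []
    for cond in conds:
        s = features.raw_scores(cond)                   # (k, T, n_pc)
        rms = np.sqrt(np.mean(np.square(s), axis=-1))   # (k, T)
        rows.append(rms.mean(axis=0))
    return PowerTimecourse(rms=np.stack(rows), conditions=list(conds),
                           bin_times=features.bin_times)


def power_anova(summaries: pd.DataFrame) -> AnovaTable:
    """Two-way repeated-measures ANOVA of window-averaged RMS power.

    ``summaries`` is long-format with columns ``subject``, ``session``
    (first/second), ``group`` (object/nonsense) and ``rms``.
    """
    required = {"subject", "session", "group", "rms"}
    if not required.issubset(summaries.columns):
        raise ConfigError(f"summaries must have columns {sorted(required)}")
    return rm_anova(summaries, dv="rms", subject="subject",
                    within=["session", "group"])


def pattern_angle(w_pre: np.ndarray, w_post: np.ndarray) -> float:
    """Angle (degrees, [0, 180]) between two discriminant normals.

    Orientation is preserved — both classifiers must share the class-order
    convention (object first, nonsense second) so that 180 degrees means a
    genuinely inverted pattern, not an arbitrary sign flip.
    """
    a = np.asarray(w_pre, dtype=float)
    b = np.asarray(w_post, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("discriminant normal has zero norm")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def condition_pattern_angle(features: RegionFeatures, cond_a: str,
                            cond_b: str,
                            window_ms: tuple[float, float]) -> float:
    """Angle between two conditions' mean feature patterns in a window.

    Averages raw PC projections over pseudo-trials and window bins and
    measures the angle between the two mean vectors — a direct estimate of
    how far one condition's spatial pattern rotated relative to the other,
    without reference to a third condition.
    """
    mask = ((features.bin_times >= window_ms[0])
            & (features.bin_times <= window_ms[1]))
    if not mask.any():
        raise ConfigError("window contains no analysis bins")
    a = features.raw_scores(cond_a)[:, mask].mean(axis=(0, 1))
    b = features.raw_scores(cond_b)[:, mask].mean(axis=(0, 1))
    return pattern_angle(a, b)


def _session_matched_pairs(design: ConditionDesign):
    """(pre-pair, post-pair) classifier specs per (object, nonsense) choice."""
    cat = design.analysis_category
    out = []
    for obj in design.stimuli(cat):
        for non in design.stimuli("nonsense"):
            out.append((
                (f"{obj}:pre", f"{non}:s1"),
                (f"{obj}:post", f"{non}:s2"),
            ))
    return out


def angle_timecourse_vs_baseline(dataset: SourceDataset, region: str,
                                 design: ConditionDesign,
                                 config: PipelineConfig,
                                 effect_window_ms: tuple[float, float],
                                 ) -> PatternAngleResult:
    """Alpha timecourse per subject and its window-vs-baseline paired t.

    For each admissible (object stimulus, nonsense stimulus) choice the
    pre-state classifier is trained against session-1 nonsense and the
    post-state classifier against session-2 nonsense; alpha is averaged
    over the four choices within subject before the group-level test.
    Baseline alpha comes from classifiers trained on pre-stimulus bins of
    the same condition pairs.
    """
    t0, t1 = config.baseline_window_ms
    if t1 <= t0:
        raise ConfigError("baseline window is empty")
    full_window = (t0, config.analysis_window_ms[1])
    pairs = _session_matched_pairs(design)
    alpha_rows = []
    bin_times = None
    for subject in dataset.subjects:
        feats = prepare_subject_region(
            dataset, subject, region, design, config, window_ms=full_window)
        bin_times = feats.bin_times
        T = len(bin_times)
        alphas = np.zeros((len(pairs), T))
        for p_idx, (pre_pair, post_pair) in enumerate(pairs):
            for tb in range(T):
                w_pre = train_lda(
                    feats.scores[pre_pair[0]][:, tb],
                    feats.scores[pre_pair[1]][:, tb],
                    class_order=pre_pair).w
                w_post = train_lda(
                    feats.scores[post_pair[0]][:, tb],
                    feats.scores[post_pair[1]][:, tb],
                    class_order=post_pair).w
                alphas[p_idx, tb] = pattern_angle(w_pre, w_post)
        alpha_rows.append(alphas.mean(axis=0))
    alpha = np.stack(alpha_rows)
    base_mask = (bin_times >= t0) & (bin_times < t1)
    if not base_mask.any():
        raise ConfigError("no analysis bins fall inside the baseline window")
    win_mask = ((bin_times >= effect_window_ms[0])
                & (bin_times <= effect_window_ms[1]))
    baseline_alpha = alpha[:, base_mask].mean(axis=1)
    window_alpha = alpha[:, win_mask].mean(axis=1)
    test = paired_t(window_alpha, baseline_alpha)
    return PatternAngleResult(
        alpha=alpha, bin_times=bin_times,
        baseline_alpha=baseline_alpha, window_alpha=window_alpha, test=test)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    observed = abs(rho)
    count = 0
    total = 0
    for perm in permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


def decoding_power_association(decoding_gain: np.ndarray,
                               power_delta: np.ndarray,
                               ) -> tuple[float, float]:
    """Across-subject Spearman correlation of decoding gain vs power gain.

    ``decoding_gain`` is (post-object vs nonsense accuracy) minus
    (pre-object vs nonsense accuracy), per subject; ``power_delta`` is the
    post-minus-pre RMS power difference.  Exact permutation p for n <= 8,
    t-approximation for larger groups.
    """
    x = np.asarray(decoding_gain, dtype=float)
    y = np.asarray(power_delta, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("inputs must be equal-length vectors")
    if x.size < 5:
        raise ConfigError("need at least 5 subjects for a correlation")
    res = sps.spearmanr(x, y)
    rho = float(res.statistic)
    if x.size <= EXACT_SPEARMAN_MAX_N:
        p = _spearman_exact_p(x, y, rho)
    else:
        p = float(res.pvalue)
    return rho, p
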