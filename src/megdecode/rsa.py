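"""Model RDM, Spearman RSA, the 9-component RDM profile and effect maps.

The 28 unordered pairs of the 8 per-category conditions partition into nine
profile components according to the role of the comparison:

====  =======================================================  =======
name  pairwise comparison                                      entries
====  =======================================================  =======
dU    different exemplars, naively unrecognizable (pre)              1
dR    different exemplars, induced recognition (post)                1
dN    different nonsense exemplars within a session                  2
dNa   different nonsense exemplars across sessions                   2
sNa   same nonsense exemplar across sessions                         2
UN    pre-state object vs nonsense                                   8
RN    post-state object vs nonsense                                  8
sRU   same object, pre vs post                                       2
dRU   different objects, pre vs post                                 2
====  =======================================================  =======

The binary model RDM assigns high dissimilarity (1) to every pair that
crosses the recognized/unrecognized boundary — RN, sRU and dRU (12 entries)
— and low dissimilarity (0) elsewhere, grouping pre-state objects with
nonsense.  Empirical RDMs (pairwise decoding accuracies) are compared to
the model by Spearman correlation; Fisher-transformed coefficients are
tested against zero per region x timebin with BH-FDR correction across the
whole map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import Condition, ConditionDesign, ConfigError, DesignError
from .stats import fdr_bh, fisher_z, one_sample_t

__all__ = [
    "COMPONENTS",
    "COMPONENT_WEIGHTS",
    "HIGH_COMPONENTS",
    "PROFILE_CONTRASTS",
    "PairLabel",
    "ModelRDM",
    "RsaResult",
    "RdmProfile",
    "EffectMap",
    "enumerate_condition_pairs",
    "build_model_rdm",
    "rsa_correlation",
    "compute_profile",
    "profile_contrast",
    "searchlight_effect_map",
]

COMPONENTS = ("dU", "dR", "dN", "dNa", "sNa", "UN", "RN", "sRU", "dRU")
COMPONENT_WEIGHTS = (1, 1, 2, 2, 2, 8, 8, 2, 2)
HIGH_COMPONENTS = ("RN", "sRU", "dRU")
PROFILE_CONTRASTS = ("dR-dU", "dNa-dN", "sNa", "RN-UN", "sRU-sNa")


@dataclass(frozen=True)
class PairLabel:
    component: str
    member_a: str     # condition label
    member_b: str


@dataclass(frozen=True)
class ModelRDM:
    values: np.ndarray      # binary, aligned to PairLabel order

    def __post_init__(self):
        if int(self.values.sum()) != 12:
            raise DesignError("model RDM must contain exactly 12 ones")


@dataclass(frozen=True)
class RsaResult:
    rho: float
    z: float
    degenerate: bool = False


@dataclass(frozen=True)
class RdmProfile:
    component_means: np.ndarray    # (9,)
    weights: np.ndarray            # (9,), sums to 28
    low_avg: float                 # weighted mean of components 1-6
    high_avg: float                # weighted mean of components 7-9


@dataclass
class EffectMap:
    """Region x timebin statistics of the Fisher-z RSA map."""

    table: pd.DataFrame            # region, timebin, time_ms, z_mean, t, p, significant
    window_summaries: dict[tuple[float, float], list[str]] = field(
        default_factory=dict)


def _classify_pair(a: Condition, b: Condition, category: str) -> str:
    """Assign the profile component of one unordered condition pair."""
    cats = {a.category, b.category}
    if cats == {category}:
        if a.stimulus_id == b.stimulus_id:
            return "sRU"                       # same object, pre vs post
        if a.state == b.state:
            return "dU" if a.state == "pre" else "dR"
        return "dRU"
    if cats == {"nonsense"}:
        if a.stimulus_id == b.stimulus_id:
            return "sNa"
        return "dN" if a.state == b.state else "dNa"
    # object vs nonsense
    obj = a if a.category == category else b
    return "RN" if obj.state == "post" else "UN"


def enumerate_condition_pairs(design: ConditionDesign) -> list[PairLabel]:
    """All 28 unordered pairs in canonical component-grouped order."""
    design.validate_analysis_template()
    cat = design.analysis_category
    labelled = []
    for a, b in combinations(design.conditions, 2):
        comp = _classify_pair(a, b, cat)
        labelled.append(PairLabel(comp, a.label, b.label))
    order = {c: i for i, c in enumerate(COMPONENTS)}
    labelled.sort(key=lambda p: (order[p.component], p.member_a, p.member_b))
    counts = [sum(p.component == c for p in labelled) for c in COMPONENTS]
    if tuple(counts) != COMPONENT_WEIGHTS:
        raise DesignError(
            f"pair multiplicities {counts} do not match the expected "
            f"{COMPONENT_WEIGHTS}"
        )
    return labelled


def build_model_rdm(pairs: list[PairLabel]) -> ModelRDM:
    """Binary model: 1 across the recognized/unrecognized boundary."""
    values = np.array(
        [1.0 if p.component in HIGH_COMPONENTS else 0.0 for p in pairs])
    return ModelRDM(values=values)


def rsa_correlation(empirical: np.ndarray, model: ModelRDM) -> RsaResult:
    """Spearman correlation (average ranks for ties) and its Fisher z.

    A zero-variance empirical vector has no defined correlation; the result
    is rho = 0 with ``degenerate`` set, to be excluded from group tests.
    """
    emp = np.asarray(empirical, dtype=float)
    if emp.shape != model.values.shape:
        raise ConfigError("empirical and model RDM lengths differ")
    if np.ptp(emp) == 0.0:
        return RsaResult(rho=0.0, z=0.0, degenerate=True)
    rho = float(sps.spearmanr(emp, model.values).statistic)
    return RsaResult(rho=rho, z=fisher_z(rho))


def compute_profile(empirical: np.ndarray,
                    pairs: list[PairLabel]) -> RdmProfile:
    """Average RDM entries within each of the nine components."""
    emp = np.asarray(empirical, dtype=float)
    comp_of = np.array([COMPONENTS.index(p.component) for p in pairs])
    means = np.array([emp[comp_of == i].mean() for i in range(9)])
    weights = np.asarray(COMPONENT_WEIGHTS, dtype=int)
    low = float(np.average(means[:6], weights=weights[:6]))
    high = float(np.average(means[6:], weights=weights[6:]))
    return RdmProfile(component_means=means, weights=weights,
                      low_avg=low, high_avg=high)


def profile_contrast(profiles: np.ndarray, contrast: str,
                     chance: float = 0.5):
    """Per-subject profile contrast values and their one-sample t.

    ``profiles`` is (n_subjects, 9) of component means.  Difference
    contrasts (e.g. ``RN-UN``) are tested against zero; the plain ``sNa``
    component is tested against chance-level accuracy.
    """
    prof = np.atleast_2d(np.asarray(profiles, dtype=float))
    if prof.shape[0] < 2:
        raise ConfigError("need at least 2 subjects for a contrast test")
    if contrast not in PROFILE_CONTRASTS:
        raise ConfigError(
            f"unknown contrast {contrast!r}; valid: {PROFILE_CONTRASTS}")
    idx = {c: i for i, c in enumerate(COMPONENTS)}
    if "-" in contrast:
        a, b = contrast.split("-")
        values = prof[:, idx[a]] - prof[:, idx[b]]
        test = one_sample_t(values, 0.0)
    else:
        values = prof[:, idx[contrast]]
        test = one_sample_t(values, chance)
    return values, test


def searchlight_effect_map(z: np.ndarray, regions: list[str],
                           bin_times: np.ndarray, fdr_q: float = 0.05,
                           windows: list[tuple[float, float]] | None = None,
                           valid: np.ndarray | None = None) -> EffectMap:
    """One-sample t of Fisher-z values per region x timebin, BH-FDR jointly.

    ``z`` is (n_subjects, n_regions, n_timebins).  ``valid`` optionally
    masks degenerate subject cells (excluded from the t-test).  A window
    summary flags a region when at least half of that window's bins are
    FDR-significant.
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 3 or z.shape[1] != len(regions):
        raise ConfigError("z must be (n_subjects, n_regions, n_timebins)")
    if z.shape[0] < 2:
        raise ConfigError("need at least 2 subjects for an effect map")
    n_regions, n_bins = z.shape[1], z.shape[2]
    t_stat = np.full((n_regions, n_bins), np.nan)
    p_val = np.ones((n_regions, n_bins))
    z_mean = np.full((n_regions, n_bins), np.nan)
    for r in range(n_regions):
        for b in range(n_bins):
            col = z[:, r, b]
            if valid is not None:
                col = col[valid[:, r, b]]
            if col.size < 2 or col.std(ddof=1) == 0.0:
                z_mean[r, b] = col.mean() if col.size else np.nan
                continue
            res = one_sample_t(col, 0.0)
            t_stat[r, b], p_val[r, b] = res.statistic, res.p
            z_mean[r, b] = col.mean()
    significant = fdr_bh(p_val, fdr_q)
    rows = []
    for r, region in enumerate(regions):
        for b in range(n_bins):
            rows.append({
                "region": region, "timebin": b,
                "time_ms": float(bin_times[b]),
                "z_mean": z_mean[r, b], "t": t_stat[r, b],
                "p": p_val[r, b], "significant": bool(significant[r, b]),
            })
    table = pd.DataFrame(rows)
    summaries: dict[tuple[float, float], list[str]] = {}
    for win in windows or []:
        in_win = (bin_times >= win[0]) & (bin_times <= win[1])
        flagged = [
            regions[r] for r in range(n_regions)
            if in_win.sum() and
            significant[r, in_win].sum() >= 0.5 * in_win.sum()
        ]
        summaries[tuple(win)] = flagged
    return EffectMap(table=table, window_summaries=summaries)
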