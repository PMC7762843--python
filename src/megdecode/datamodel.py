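"""Shared data model: conditions, designs, datasets and pipeline configuration.

The experimental design emulated throughout the package is a pre/post
training paradigm: object images (faces, tools) are shown before training
(*naively unrecognizable*, state ``pre``) and after a short training
procedure that induces recognition (*induced recognition*, state ``post``);
meaningless *nonsense* images are shown in two sessions (``s1``/``s2``)
bracketing the training and serve as a recognition-free control for session
drift.  One per-category analysis therefore involves eight conditions:
2 object stimuli x {pre, post} plus 2 nonsense stimuli x {s1, s2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

CATEGORIES = ("face", "tool", "nonsense")
OBJECT_STATES = ("pre", "post")
NONSENSE_SESSIONS = ("s1", "s2")


class SchemaError(Exception):
    """A stored container is missing a required group/dataset/attribute."""


class ValidationError(Exception):
    """A dataset violates a structural invariant."""


class DesignError(Exception):
    """A condition design does not match the expected template."""


class ConfigError(Exception):
    """Invalid analysis or simulation configuration."""


class ConditionExcluded(Exception):
    """Raised when a condition has too few trials to be analysed.

    Mirrors the trial-count inclusion rule: conditions with fewer than
    ``min_trials`` (default 50) usable trials are excluded, and the subject
    is dropped from the per-category analysis that needs the condition.
    """

    def __init__(self, subject: str | None, condition: str, n_trials: int,
                 min_trials: int):
        self.subject = subject
        self.condition = condition
        self.n_trials = n_trials
        self.min_trials = min_trials
        super().__init__(
            f"condition {condition!r}"
            + (f" of subject {subject!r}" if subject else "")
            + f" has {n_trials} trials < required {min_trials}"
        )


@dataclass(frozen=True)
class Condition:
    """A single experimental condition.

    ``state`` is ``pre``/``post`` for object stimuli (before/after the
    recognition-inducing training) and ``s1``/``s2`` for nonsense stimuli
    (first/second recording session).
    """

    stimulus_id: str
    category: str          # face | tool | nonsense
    state: str             # pre | post | s1 | s2

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise DesignError(f"unknown category {self.category!r}")
        allowed = NONSENSE_SESSIONS if self.category == "nonsense" else OBJECT_STATES
        if self.state not in allowed:
            raise DesignError(
                f"state {self.state!r} invalid for category {self.category!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.stimulus_id}:{self.state}"

    @classmethod
    def from_label(cls, label: str, category: str) -> "Condition":
        stim, state = label.rsplit(":", 1)
        return cls(stim, category, state)


@dataclass(frozen=True)
class ConditionDesign:
    """A labelled set of conditions for one per-category analysis.

    The canonical per-category design has exactly eight conditions:
    2 object stimuli x {pre, post} and 2 nonsense stimuli x {s1, s2}.
    A *full* design additionally carries the other object category; use
    :meth:`for_category` to slice out one analysis.
    """

    conditions: tuple[Condition, ...]
    analysis_category: str = "face"

    def __post_init__(self) -> None:
        if self.analysis_category not in ("face", "tool"):
            raise DesignError(
                f"analysis_category must be 'face' or 'tool', "
                f"got {self.analysis_category!r}"
            )
        for cat in CATEGORIES:
            ids = [c.stimulus_id for c in self.conditions if c.category == cat]
            if len(set(ids)) * self._n_states(cat) != len(ids):
                raise DesignError(
                    f"duplicate (stimulus, state) combinations in category {cat!r}"
                )

    @staticmethod
    def _n_states(category: str) -> int:
        return 2

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.conditions)

    def stimuli(self, category: str) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.conditions:
            if c.category == category and c.stimulus_id not in out:
                out.append(c.stimulus_id)
        return tuple(out)

    def conditions_of(self, category: str,
                      state: str | None = None) -> tuple[Condition, ...]:
        return tuple(
            c for c in self.conditions
            if c.category == category and (state is None or c.state == state)
        )

    def for_category(self, category: str) -> "ConditionDesign":
        """Slice the 8-condition analysis design for one object category."""
        if category not in ("face", "tool"):
            raise DesignError(f"analysis category must be face/tool, got {category!r}")
        kept = tuple(
            c for c in self.conditions if c.category in (category, "nonsense")
        )
        return ConditionDesign(kept, analysis_category=category)

    def validate_analysis_template(self) -> None:
        """Check the 2+2+2+2 template of a per-category analysis design."""
        cat = self.analysis_category
        objs = self.stimuli(cat)
        nons = self.stimuli("nonsense")
        if len(objs) != 2 or len(nons) != 2 or len(self.conditions) != 8:
            raise DesignError(
                f"analysis design must have 2 {cat} stimuli x pre/post and "
                f"2 nonsense stimuli x s1/s2 (8 conditions); got "
                f"{len(objs)} {cat} stimuli, {len(nons)} nonsense stimuli, "
                f"{len(self.conditions)} conditions"
            )
        for stim in objs:
            for state in OBJECT_STATES:
                if Condition(stim, cat, state) not in self.conditions:
                    raise DesignError(f"missing condition {stim}:{state}")
        for stim in nons:
            for sess in NONSENSE_SESSIONS:
                if Condition(stim, "nonsense", sess) not in self.conditions:
                    raise DesignError(f"missing condition {stim}:{sess}")

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "analysis_category": self.analysis_category,
            "conditions": [
                {"stimulus_id": c.stimulus_id, "category": c.category,
                 "state": c.state}
                for c in self.conditions
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConditionDesign":
        conds = tuple(
            Condition(c["stimulus_id"], c["category"], c["state"])
            for c in d["conditions"]
        )
        return cls(conds, analysis_category=d.get("analysis_category", "face"))

    @classmethod
    def default(cls, category: str = "face") -> "ConditionDesign":
        """The canonical 8-condition per-category design."""
        conds = []
        for i in (1, 2):
            for state in OBJECT_STATES:
                conds.append(Condition(f"{category}{i}", category, state))
        for i in (1, 2):
            for sess in NONSENSE_SESSIONS:
                conds.append(Condition(f"nonsense{i}", "nonsense", sess))
        return cls(tuple(conds), analysis_category=category)

    @classmethod
    def full_default(cls) -> "ConditionDesign":
        """Both object categories plus nonsense: 12 conditions."""
        conds = []
        for cat in ("face", "tool"):
            for i in (1, 2):
                for state in OBJECT_STATES:
                    conds.append(Condition(f"{cat}{i}", cat, state))
        for i in (1, 2):
            for sess in NONSENSE_SESSIONS:
                conds.append(Condition(f"nonsense{i}", "nonsense", sess))
        return cls(tuple(conds), analysis_category="face")


@dataclass
class SourceDataset:
    """Multi-subject region-resolved source epochs.

    ``epochs[(subject, region, condition_label)]`` is a real array of shape
    ``(n_vertices, n_times, n_trials)``.  All conditions of one subject
    share ``time_axis`` (milliseconds, uniform step) and the per-region
    vertex count.  The time axis includes a pre-stimulus baseline segment
    and the post-stimulus analysis window.
    """

    subjects: list[str]
    regions: list[str]
    time_axis: np.ndarray
    sampling_step_ms: float
    design: ConditionDesign
    epochs: dict[tuple[str, str, str], np.ndarray] = field(default_factory=dict)

    def get(self, subject: str, region: str, condition: str) -> np.ndarray:
        return self.epochs[(subject, region, condition)]

    @property
    def n_times(self) -> int:
        return len(self.time_axis)

    def n_vertices(self, subject: str, region: str) -> int:
        for cond in self.design.labels:
            key = (subject, region, cond)
            if key in self.epochs:
                return self.epochs[key].shape[0]
        raise KeyError(f"no epochs stored for ({subject}, {region})")

    def validate(self, min_vertices: int = 4) -> None:
        t = np.asarray(self.time_axis, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ValidationError("time_axis must be a vector of length >= 2")
        steps = np.diff(t)
        if not np.all(steps > 0):
            raise ValidationError("time_axis must be strictly increasing")
        if not np.allclose(steps, self.sampling_step_ms, rtol=1e-6, atol=1e-9):
            raise ValidationError(
                "time_axis step does not match sampling_step_ms"
            )
        bad: list[tuple[str, str, str]] = []
        for subj in self.subjects:
            for region in self.regions:
                v_count: int | None = None
                for cond in self.design.labels:
                    key = (subj, region, cond)
                    if key not in self.epochs:
                        bad.append(key)
                        continue
                    arr = self.epochs[key]
                    if arr.ndim != 3 or arr.shape[1] != len(t):
                        bad.append(key)
                        continue
                    if v_count is None:
                        v_count = arr.shape[0]
                        if v_count < min_vertices:
                            raise ValidationError(
                                f"region {region!r} of subject {subj!r} has "
                                f"{v_count} vertices < minimum {min_vertices} "
                                "(violates minimum vertex-count invariant)"
                            )
                    elif arr.shape[0] != v_count:
                        bad.append(key)
        if bad:
            raise ValidationError(
                "inconsistent epoch shapes for (subject, region, condition): "
                + ", ".join(map(str, bad[:10]))
                + ("..." if len(bad) > 10 else "")
            )


@dataclass
class PipelineConfig:
    """Analysis configuration shared by all stages.

    ``downsample_ratio`` is the decimation factor relative to a 1 kHz base
    rate; the effective number of raw samples averaged per analysis bin is
    ``downsample_ratio / sampling_step_ms`` so that the analysis time
    resolution is 10 ms regardless of the stored sampling step.
    """

    analysis_window_ms: tuple[float, float] = (0.0, 500.0)
    downsample_ratio: int = 10
    n_pseudotrials: int = 10
    min_trials: int = 50
    n_pc: int = 3
    fdr_q: float = 0.05
    n_permutations: int = 10000
    cluster_alpha: float = 0.05
    cluster_definition_p: float = 0.05
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.downsample_ratio <= 0:
            raise ConfigError("downsample_ratio must be positive")
        if self.n_pseudotrials < 2:
            raise ConfigError("n_pseudotrials must be >= 2")
        if self.n_pc < 1:
            raise ConfigError("n_pc must be >= 1")

    def effective_ratio(self, sampling_step_ms: float) -> int:
        """Samples averaged per analysis bin for data at ``sampling_step_ms``."""
        ratio = self.downsample_ratio / sampling_step_ms
        r = int(round(ratio))
        if r < 1 or not np.isclose(ratio, r):
            raise ConfigError(
                f"downsample_ratio {self.downsample_ratio} (ms per bin) is not "
                f"an integer multiple of the sampling step {sampling_step_ms} ms"
            )
        return r

    def to_dict(self) -> dict:
        return {
            "analysis_window_ms": list(self.analysis_window_ms),
            "downsample_ratio": self.downsample_ratio,
            "n_pseudotrials": self.n_pseudotrials,
            "min_trials": self.min_trials,
            "n_pc": self.n_pc,
            "fdr_q": self.fdr_q,
            "n_permutations": self.n_permutations,
            "cluster_alpha": self.cluster_alpha,
            "cluster_definition_p": self.cluster_definition_p,
            "baseline_window_ms": list(self.baseline_window_ms),
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("analysis_window_ms", "baseline_window_ms"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def window_mask(time_axis: Iterable[float],
                window_ms: tuple[float, float]) -> np.ndarray:
    """Boolean mask of time samples falling inside a closed window."""
    t = np.asarray(list(time_axis), dtype=float)
    lo, hi = window_ms
    return (t >= lo - 1e-9) & (t <= hi + 1e-9)
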