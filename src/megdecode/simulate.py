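"""Synthetic multi-subject source datasets with injectable recognition effects.

The generator emulates the pre/post-training design at the level the
analysis consumes: per (subject, region, condition), trials are an evoked
envelope riding on a condition-specific unit-norm spatial pattern plus
spatially and temporally smooth Gaussian noise,

    trial(v, t) = a_c(t) * g(t) * p_c(t)[v] + noise(v, t).

Spatial patterns are drawn independently per subject x region x stimulus
(there is no vertex correspondence across subjects, matching the analysis'
indifference to inter-subject vertex alignment).  Session 2 (post-training)
patterns of *every* stimulus are mildly perturbed relative to session 1 to
emulate between-session drift; recognition effects proper are injected on
top via :class:`EffectSpec`:

``power_gain``
    post-state amplitude becomes ``(1 + beta) * a_pre`` inside the effect
    window while the spatial pattern is untouched (a pure power effect).
``pattern_rotation``
    the post-state pattern is rotated by ``theta`` degrees within the plane
    spanned by the pre pattern and a random orthogonal direction, inside the
    effect window; amplitude is untouched (a pure pattern effect).
``delayed_shared_pattern``
    one shared category-level pattern is added to pre-state objects during
    the effect window and to post-state objects during the same window
    shifted by ``delta_t`` ms (the temporal-generalization scenario: the
    same neural component recurring later for newly recognized stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import convolve1d, gaussian_filter1d

from .datamodel import (
    Condition,
    ConditionDesign,
    ConfigError,
    SourceDataset,
    window_mask,
)

__all__ = ["EffectSpec", "SimConfig", "simulate_dataset", "null_dataset",
           "gamma_envelope"]

EFFECT_KINDS = ("power_gain", "pattern_rotation", "delayed_shared_pattern")


def gamma_envelope(t_ms: np.ndarray, peak_ms: float = 120.0,
                   shape: float = 3.0) -> np.ndarray:
    """Gamma-shaped evoked envelope, zero before stimulus onset, peak 1.

    ``g(t) = (t/peak)^shape * exp(shape * (1 - t/peak))`` for t > 0; the
    maximum sits exactly at ``peak_ms``.  Larger ``shape`` narrows the bump.
    """
    t = np.asarray(t_ms, dtype=float)
    g = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / peak_ms
    g[pos] = x ** shape * np.exp(shape * (1.0 - x))
    return g


def _raised_cosine(t_ms: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Smooth unit bump supported on ``window`` (Hann profile)."""
    t = np.asarray(t_ms, dtype=float)
    lo, hi = window
    out = np.zeros_like(t)
    inside = (t >= lo) & (t <= hi)
    if hi > lo:
        phase = (t[inside] - lo) / (hi - lo)
        out[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return out


@dataclass(frozen=True)
class EffectSpec:
    """One injectable recognition effect (see module docstring).

    ``magnitude`` is the gain factor beta for ``power_gain``, the rotation
    angle theta in degrees for ``pattern_rotation``, and the time offset
    delta-t in ms for ``delayed_shared_pattern``.  ``amplitude`` scales the
    shared component of ``delayed_shared_pattern`` relative to the per-
    stimulus evoked amplitude and is ignored by the other kinds.

    ``subject_sd`` sets realistic between-subject heterogeneity: each
    subject's realised magnitude is the nominal one times a unit-mean
    log-normal draw with this log-scale spread (0 disables it).  Without
    heterogeneity an across-subject decoding-power correlation could not
    arise even for a genuine power effect, since every subject would share
    the same true effect size.  Rotation angles are clipped to [0, 90]
    after scaling; the time offset of ``delayed_shared_pattern`` is kept
    fixed across subjects (its per-subject scaling would smear the
    generalization cluster, not its strength) and heterogeneity applies to
    the shared component's amplitude instead.
    """

    kind: str
    region: str
    window_ms: tuple[float, float]
    magnitude: float
    target_category: str = "both"  # face | tool | both
    amplitude: float = 1.0
    subject_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ConfigError(f"unknown effect kind {self.kind!r}")
        if self.target_category not in ("face", "tool", "both"):
            raise ConfigError(
                f"target_category must be face/tool/both, "
                f"got {self.target_category!r}"
            )
        if self.kind == "power_gain" and self.magnitude <= -1:
            raise ConfigError("power gain beta must exceed -1")
        if self.kind == "pattern_rotation" and not 0 <= self.magnitude <= 90:
            raise ConfigError("rotation angle must lie in [0, 90] degrees")
        if self.window_ms[1] <= self.window_ms[0]:
            raise ConfigError("effect window must have positive length")

    def targets(self, category: str) -> bool:
        return self.target_category in ("both", category)


@dataclass
class SimConfig:
    """Generator configuration.

    Defaults mirror the emulated experiment: 16 subjects, 75 trials per
    condition, 50 vertices per region, epochs spanning -200..500 ms at a
    10 ms step, and an evoked envelope peaking near 120 ms.

    Geometry of the signal model: each region expresses activity in a
    ``signal_dim``-dimensional functional subspace; stimulus patterns are
    unit vectors in it, clustered around a common evoked-response anchor
    (``pattern_spread`` sets the departure from the anchor) and evolving
    smoothly in time (``pattern_timescale_ms``).  ``latent_noise_fraction``
    of the noise variance lies in the same subspace (ongoing activity
    sharing the evoked components); the rest is spatially correlated
    across all vertices with a power-law eigenvalue spectrum
    (``noise_spectrum_exponent``).  ``snr`` is the ratio of signal RMS
    (across vertices, at the envelope peak) to noise RMS; the default is
    set so that pairwise decoding of distinct stimuli and injected
    effects lands in the 0.6-0.8 accuracy range typical of source-space
    MEG decoding.
    """

    n_subjects: int = 16
    regions: Sequence[str] = ("rIO", "rMO", "insula", "rOF", "rFG", "ctrl")
    n_vertices: int = 50
    n_trials: int = 75
    tmin_ms: float = -200.0
    tmax_ms: float = 500.0
    sampling_step_ms: float = 10.0
    envelope: Callable[[np.ndarray], np.ndarray] | None = None
    envelope_peak_ms: float = 120.0
    envelope_shape: float = 2.0
    snr: float = 0.4
    session_drift: float = 0.2
    signal_dim: int = 3
    pattern_spread: float = 0.5
    pattern_timescale_ms: float = 40.0
    noise_spectrum_exponent: float = 0.5
    latent_noise_fraction: float = 0.3
    effects: list[EffectSpec] = field(default_factory=list)
    design: ConditionDesign | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ConfigError("snr must be positive")
        if not 0.0 <= self.session_drift <= 1.0:
            raise ConfigError("session_drift must lie in [0, 1]")
        if self.n_vertices < 4:
            raise ConfigError("need at least 4 vertices per region")
        if not 2 <= self.signal_dim <= self.n_vertices:
            raise ConfigError(
                "signal_dim must lie in [2, n_vertices] (drift and "
                "rotation need at least a 2-plane)")
        if not 0.0 < self.pattern_spread <= 1.0:
            raise ConfigError("pattern_spread must lie in (0, 1]")
        if not 0.0 <= self.latent_noise_fraction < 1.0:
            raise ConfigError("latent_noise_fraction must lie in [0, 1)")
        if self.pattern_timescale_ms <= 0:
            raise ConfigError("pattern_timescale_ms must be positive")
        for eff in self.effects:
            if eff.region not in self.regions:
                raise ConfigError(
                    f"effect region {eff.region!r} not among simulated "
                    f"regions {list(self.regions)}"
                )

    @property
    def time_axis(self) -> np.ndarray:
        n = int(round((self.tmax_ms - self.tmin_ms) / self.sampling_step_ms)) + 1
        return self.tmin_ms + self.sampling_step_ms * np.arange(n)

    def envelope_values(self, t_ms: np.ndarray) -> np.ndarray:
        if self.envelope is not None:
            g = np.asarray(self.envelope(t_ms), dtype=float)
            if np.any(g < 0):
                raise ConfigError("envelope must be nonnegative")
            return g
        return gamma_envelope(t_ms, self.envelope_peak_ms, self.envelope_shape)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthogonal_unit(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.standard_normal(p.shape)
    u -= (u @ p) * p
    return _unit(u)


def _rotate(p: np.ndarray, theta_deg: float, u: np.ndarray) -> np.ndarray:
    """Givens rotation of unit vector ``p`` by theta within span(p, u)."""
    th = np.deg2rad(theta_deg)
    return np.cos(th) * p + np.sin(th) * u


def _noise_mixing(n_vertices: int, exponent: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Spatial mixing matrix with a power-law eigenvalue spectrum.

    Eigenvalues decay as ``j ** -exponent`` (normalised to unit mean
    variance across vertices): spatially smooth noise without letting a
    single ongoing-activity component swamp the evoked signal subspace.
    """
    q, _ = np.linalg.qr(rng.standard_normal((n_vertices, n_vertices)))
    lam = np.arange(1, n_vertices + 1, dtype=float) ** -exponent
    return q * np.sqrt(lam * n_vertices / lam.sum())


_TEMPORAL_KERNEL = np.array([0.25, 0.5, 0.25])


def simulate_dataset(cfg: SimConfig) -> SourceDataset:
    """Generate a full multi-subject dataset according to ``cfg``.

    Deterministic: the same config (including ``rng_seed``) always yields
    bit-identical output.
    """
    design = cfg.design if cfg.design is not None else ConditionDesign.full_default()
    t = cfg.time_axis
    g = cfg.envelope_values(t)
    subjects = [f"sub{i + 1:02d}" for i in range(cfg.n_subjects)]
    regions = list(cfg.regions)
    rng = np.random.default_rng(cfg.rng_seed)

    # noise scaled so that snr = signal RMS / noise RMS at the envelope peak
    sigma = (1.0 / np.sqrt(cfg.n_vertices)) / cfg.snr

    epochs: dict[tuple[str, str, str], np.ndarray] = {}
    for subj in subjects:
        # per-subject multiplicative effect-size heterogeneity (unit mean)
        subj_scale = {
            id(e): float(np.exp(e.subject_sd * rng.standard_normal()
                                - e.subject_sd ** 2 / 2.0))
            for e in cfg.effects
        }
        for region in regions:
            region_effects = [e for e in cfg.effects if e.region == region]
            mixing = _noise_mixing(cfg.n_vertices,
                                   cfg.noise_spectrum_exponent, rng)
            # every pattern of a region lives in a low-dimensional
            # functional subspace (orthonormal basis W), matching the
            # analysis premise that a few principal components carry the
            # region's discriminative activity
            W, _ = np.linalg.qr(
                rng.standard_normal((cfg.n_vertices, cfg.signal_dim)))
            # stimulus patterns cluster around a common evoked-response
            # anchor and evolve smoothly over time (autocorrelation set by
            # pattern_timescale_ms), so classifiers generalise across
            # nearby times only.  ``pattern_spread`` sets how far stimuli
            # depart from the anchor; a recognition-induced rotation moves
            # the post-state pattern away from the whole baseline cluster,
            # which is exactly the configuration change the model RDM
            # encodes.
            anchor = _unit(rng.standard_normal(cfg.signal_dim))
            spread = cfg.pattern_spread
            smooth = cfg.pattern_timescale_ms / cfg.sampling_step_ms
            stimuli: dict[str, dict[str, np.ndarray]] = {}
            for cat in ("face", "tool", "nonsense"):
                for stim in design.stimuli(cat):
                    raw = gaussian_filter1d(
                        rng.standard_normal((cfg.signal_dim, len(t))),
                        smooth, axis=1, mode="nearest")
                    raw -= anchor[:, None] * (anchor @ raw)[None, :]
                    norms = np.linalg.norm(raw, axis=0)
                    dev = raw / np.maximum(norms, 1e-12)
                    C1 = (np.sqrt(1.0 - spread ** 2) * anchor[:, None]
                          + spread * dev)                       # (d, T)
                    drift_dir = _unit(rng.standard_normal(cfg.signal_dim))
                    C2 = C1 + cfg.session_drift * drift_dir[:, None]
                    C2 = C2 / np.linalg.norm(C2, axis=0)
                    rot_target = _unit(rng.standard_normal(cfg.signal_dim))
                    stimuli[stim] = {"c1": C1, "c2": C2, "rot": rot_target,
                                     "category": cat}
            shared = {cat: _unit(rng.standard_normal(cfg.signal_dim))
                      for cat in ("face", "tool")}

            for cond in design.conditions:
                info = stimuli[cond.stimulus_id]
                session2 = cond.state in ("post", "s2")
                L = (info["c2"] if session2 else info["c1"]).copy()  # (d, T)
                amp = np.ones(len(t))
                for eff in region_effects:
                    if cond.category == "nonsense" or not eff.targets(cond.category):
                        continue
                    in_win = window_mask(t, eff.window_ms)
                    if eff.kind == "power_gain" and cond.state == "post":
                        amp[in_win] *= 1.0 + eff.magnitude * subj_scale[id(eff)]
                    elif eff.kind == "pattern_rotation" and cond.state == "post":
                        theta = min(90.0, eff.magnitude * subj_scale[id(eff)])
                        # per-bin Givens rotation toward a fixed target
                        # direction, orthogonalised so the angle is exact
                        C = L[:, in_win]
                        u = info["rot"][:, None] - C * (info["rot"] @ C)
                        u_norm = np.linalg.norm(u, axis=0)
                        u = u / np.maximum(u_norm, 1e-12)
                        L[:, in_win] = (np.cos(np.deg2rad(theta)) * C
                                        + np.sin(np.deg2rad(theta)) * u)
                signal_latent = amp[None, :] * g[None, :] * L    # (d, T)
                for eff in region_effects:
                    if eff.kind != "delayed_shared_pattern":
                        continue
                    if cond.category == "nonsense" or not eff.targets(cond.category):
                        continue
                    win = eff.window_ms
                    if cond.state == "post":
                        win = (win[0] + eff.magnitude, win[1] + eff.magnitude)
                    bump = _raised_cosine(t, win)
                    signal_latent = signal_latent + (
                        eff.amplitude * subj_scale[id(eff)]
                        * np.outer(shared[cond.category], bump))
                signal = W @ signal_latent                       # (V, T)

                noise = rng.standard_normal(
                    (cfg.n_vertices, len(t), cfg.n_trials))
                noise = np.einsum("vw,wtn->vtn", mixing, noise)
                # ongoing activity in the region's functional subspace:
                # a fixed fraction of noise variance lives in the latent
                # span, like real background rhythms that occupy the same
                # components as the evoked response
                f = cfg.latent_noise_fraction
                if f > 0:
                    b = np.sqrt(f / (1.0 - f) * cfg.n_vertices
                                / cfg.signal_dim)
                    latent = rng.standard_normal(
                        (cfg.signal_dim, len(t), cfg.n_trials))
                    noise = noise + b * np.einsum("vd,dtn->vtn", W, latent)
                # short temporal smoothing kernel; renormalised to sigma
                noise = convolve1d(noise, _TEMPORAL_KERNEL, axis=1,
                                   mode="nearest")
                noise *= sigma / np.sqrt(np.mean(noise ** 2))
                arr = (signal[:, :, None] + noise).astype(np.float32)
                epochs[(subj, region, cond.label)] = arr

    ds = SourceDataset(
        subjects=subjects,
        regions=regions,
        time_axis=t,
        sampling_step_ms=cfg.sampling_step_ms,
        design=design,
        epochs=epochs,
    )
    ds.validate()
    return ds


def null_dataset(cfg: SimConfig) -> SourceDataset:
    """Dataset with no injected recognition effect (session drift only)."""
    if cfg.effects:
        raise ConfigError("null_dataset requires a config with empty effects")
    return simulate_dataset(cfg)
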