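"""End-to-end orchestration: simulate -> decode -> RSA -> profile ->
power/pattern -> generalize -> report.

Each stage writes plain CSV tables into the run directory; the run manifest
records the configuration, seed and output hashes so a rerun with the same
manifest reproduces every table bit-for-bit (timestamps aside).  All
randomness derives from the two seeds in the configs: the simulation seed
drives data generation and the pipeline seed drives pseudo-trial grouping
and permutation draws.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import ConditionDesign, PipelineConfig, SourceDataset
from .generalization import (
    GeneralizationSpec,
    Group,
    cluster_permutation_2d,
    generalization_matrix,
)
from .io import save_dataset, save_results
from .mvpa import RdmStack, compute_empirical_rdms, prepare_subject_region
from .power_pattern import (
    angle_timecourse_vs_baseline,
    decoding_power_association,
    power_anova,
    rms_power_timecourse,
)
from .rsa import (
    COMPONENTS,
    PROFILE_CONTRASTS,
    build_model_rdm,
    compute_profile,
    profile_contrast,
    rsa_correlation,
    searchlight_effect_map,
)
from .simulate import EffectSpec, SimConfig, simulate_dataset

logger = logging.getLogger("megdecode")

__all__ = [
    "DemoLayout",
    "default_demo_simconfig",
    "run_pipeline",
    "rsa_z_stack",
    "window_profiles",
    "recognition_metrics",
    "report",
]


@dataclass
class DemoLayout:
    """Regions and windows of the demonstration scenario.

    One region carries a pure power gain in an early window, one a pure
    pattern rotation in an intermediate window, one a delayed shared
    category pattern, and one region is a no-effect control.
    """

    power_region: str = "rIO"
    power_window: tuple[float, float] = (90.0, 140.0)
    rotation_region: str = "insula"
    rotation_window: tuple[float, float] = (200.0, 240.0)
    delayed_region: str = "rFG"
    delayed_window: tuple[float, float] = (120.0, 200.0)
    delayed_dt: float = 100.0
    control_region: str = "ctrl"


def default_demo_simconfig(seed: int = 0, n_subjects: int = 16,
                           layout: DemoLayout | None = None,
                           snr: float = 0.4,
                           power_beta: float = 0.5,
                           rotation_deg: float = 60.0) -> SimConfig:
    """The demonstration scenario: one effect of each kind plus a control."""
    lay = layout or DemoLayout()
    regions = [lay.power_region, lay.rotation_region, lay.delayed_region,
               lay.control_region]
    effects = [
        EffectSpec("power_gain", lay.power_region, lay.power_window,
                   power_beta, target_category="both"),
        EffectSpec("pattern_rotation", lay.rotation_region,
                   lay.rotation_window, rotation_deg, target_category="both"),
        # a strong category-level component (N170m-like), recurring with a
        # delay for newly recognized stimuli; its subject variability is
        # kept moderate, as canonical evoked components are reliable
        EffectSpec("delayed_shared_pattern", lay.delayed_region,
                   lay.delayed_window, lay.delayed_dt,
                   target_category="face", amplitude=2.0, subject_sd=0.3),
    ]
    return SimConfig(n_subjects=n_subjects, regions=regions, snr=snr,
                     effects=effects, rng_seed=seed)


def rsa_z_stack(rdms: RdmStack) -> tuple[np.ndarray, np.ndarray]:
    """Fisher-z RSA correlations per subject x region x timebin.

    Returns ``(z, valid)`` where ``valid`` masks non-degenerate cells.
    """
    model = build_model_rdm(rdms.pair_labels)
    n_s, n_r, _, n_t = rdms.accuracies.shape
    z = np.zeros((n_s, n_r, n_t))
    valid = np.ones((n_s, n_r, n_t), dtype=bool)
    for i in range(n_s):
        for j in range(n_r):
            for t in range(n_t):
                res = rsa_correlation(rdms.accuracies[i, j, :, t], model)
                z[i, j, t] = res.z
                valid[i, j, t] = not res.degenerate
    return z, valid


def window_profiles(rdms: RdmStack, region: str,
                    window_ms: tuple[float, float]) -> np.ndarray:
    """(n_subjects, 9) component means of window-averaged empirical RDMs."""
    j = rdms.regions.index(region)
    mask = ((rdms.bin_times >= window_ms[0])
            & (rdms.bin_times <= window_ms[1]))
    win_rdm = rdms.accuracies[:, j][:, :, mask].mean(axis=2)
    return np.stack([
        compute_profile(win_rdm[i], rdms.pair_labels).component_means
        for i in range(win_rdm.shape[0])
    ])


def recognition_metrics(dataset: SourceDataset, design: ConditionDesign,
                        config: PipelineConfig, rdms: RdmStack, region: str,
                        window_ms: tuple[float, float]) -> pd.DataFrame:
    """Per-subject decoding gain, power delta and RMS cell means in a window.

    Decoding gain = mean RN accuracy - mean UN accuracy; power delta =
    window RMS of post-state objects minus pre-state objects.  The RMS cell
    means (session x group) feed the power ANOVA.
    """
    cat = design.analysis_category
    j = rdms.regions.index(region)
    mask = ((rdms.bin_times >= window_ms[0])
            & (rdms.bin_times <= window_ms[1]))
    comp = np.array([p.component for p in rdms.pair_labels])
    rows = []
    for i, subject in enumerate(rdms.subjects):
        acc = rdms.accuracies[i, j][:, mask].mean(axis=1)
        gain = acc[comp == "RN"].mean() - acc[comp == "UN"].mean()
        feats = prepare_subject_region(dataset, subject, region, design,
                                       config)
        fmask = ((feats.bin_times >= window_ms[0])
                 & (feats.bin_times <= window_ms[1]))
        power = rms_power_timecourse(feats)

        def wmean(labels: list[str]) -> float:
            vals = [power.for_condition(c)[fmask].mean() for c in labels]
            return float(np.mean(vals))

        pre = wmean([c.label for c in design.conditions_of(cat, "pre")])
        post = wmean([c.label for c in design.conditions_of(cat, "post")])
        non1 = wmean([c.label for c in design.conditions_of("nonsense", "s1")])
        non2 = wmean([c.label for c in design.conditions_of("nonsense", "s2")])
        rows.append({
            "subject": subject, "decoding_gain": gain,
            "power_delta": post - pre,
            "rms_object_s1": pre, "rms_object_s2": post,
            "rms_nonsense_s1": non1, "rms_nonsense_s2": non2,
        })
    return pd.DataFrame(rows)


def _power_anova_table(metrics: pd.DataFrame) -> pd.DataFrame:
    long = []
    for _, row in metrics.iterrows():
        for session in ("s1", "s2"):
            for group in ("object", "nonsense"):
                long.append({
                    "subject": row["subject"], "session": session,
                    "group": group, "rms": row[f"rms_{group}_{session}"],
                })
    table = power_anova(pd.DataFrame(long)).table.reset_index()
    return table


def cross_exemplar_specs(train_category: str, test_category: str,
                         ) -> list[GeneralizationSpec]:
    """Pre-state vs nonsense classifiers tested on post-state vs nonsense,
    always across exemplars.

    Training on one exemplar and testing on the other (both orders,
    averaged) restricts generalization to components shared across
    exemplars — stimulus-specific patterns cannot carry over — which is
    the cross-category logic of the delayed-component analysis.
    """
    specs = []
    for tr, te in (("1", "2"), ("2", "1")):
        specs.append(GeneralizationSpec(
            (Group(f"{train_category}{tr}_pre",
                   (f"{train_category}{tr}:pre",)),
             Group(f"nonsense{tr}_s1", (f"nonsense{tr}:s1",))),
            (Group(f"{test_category}{te}_post",
                   (f"{test_category}{te}:post",)),
             Group(f"nonsense{te}_s2", (f"nonsense{te}:s2",))),
        ))
    return specs


def default_generalization_specs(design: ConditionDesign,
                                 control_category: str | None = None,
                                 ) -> dict[str, list[GeneralizationSpec]]:
    """The demonstration specifications (each entry is averaged over specs).

    ``within_post`` decodes post-state objects vs nonsense with itself
    (cross-validated diagonal); ``pre_to_post`` probes a delayed recurrence
    of the pre-state shared component in the post state across exemplars;
    ``control`` applies the same probe to a category lacking the component.
    """
    cat = design.analysis_category
    post = Group(f"{cat}_post",
                 tuple(c.label for c in design.conditions_of(cat, "post")))
    non2 = Group("nonsense_s2",
                 tuple(c.label for c in design.conditions_of("nonsense", "s2")))
    specs = {
        "within_post": [GeneralizationSpec((post, non2), (post, non2))],
        "pre_to_post": cross_exemplar_specs(cat, cat),
    }
    if control_category is not None:
        specs["control"] = cross_exemplar_specs(cat, control_category)
    return specs


def run_pipeline(out_dir: str | Path,
                 sim_config: SimConfig | None = None,
                 config: PipelineConfig | None = None,
                 dataset: SourceDataset | None = None,
                 category: str = "face",
                 layout: DemoLayout | None = None,
                 save_data: bool = False) -> Path:
    """Run every stage on simulated (or provided) data; write CSV results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig(n_permutations=1000)
    lay = layout or DemoLayout()
    if dataset is None:
        sim = sim_config or default_demo_simconfig()
        logger.info("simulating dataset: %d subjects, %d regions",
                    sim.n_subjects, len(sim.regions))
        dataset = simulate_dataset(sim)
        if save_data:
            save_dataset(dataset, out / "dataset.h5")
    design = dataset.design.for_category(category)

    # --- decode ---------------------------------------------------------
    rdms = compute_empirical_rdms(dataset, design, cfg)
    if rdms.excluded_subjects:
        logger.info("excluded subjects (trial threshold): %s",
                    rdms.excluded_subjects)
    n_s, n_r, n_p, n_t = rdms.accuracies.shape
    rdm_table = pd.DataFrame({
        "subject": np.repeat(rdms.subjects, n_r * n_p * n_t),
        "region": np.tile(np.repeat(rdms.regions, n_p * n_t), n_s),
        "pair": np.tile(np.repeat(
            [f"{p.component}|{p.member_a}|{p.member_b}"
             for p in rdms.pair_labels], n_t), n_s * n_r),
        "time_ms": np.tile(rdms.bin_times, n_s * n_r * n_p),
        "accuracy": rdms.accuracies.ravel(),
    })

    # --- RSA map --------------------------------------------------------
    z, valid = rsa_z_stack(rdms)
    windows = [lay.power_window, lay.rotation_window,
               (lay.delayed_window[0] + lay.delayed_dt,
                lay.delayed_window[1] + lay.delayed_dt)]
    emap = searchlight_effect_map(z, rdms.regions, rdms.bin_times,
                                  fdr_q=cfg.fdr_q, windows=windows,
                                  valid=valid)

    # --- profiles and contrasts ----------------------------------------
    prof_rows, contrast_rows = [], []
    for region, window in ((lay.power_region, lay.power_window),
                           (lay.rotation_region, lay.rotation_window)):
        if region not in rdms.regions:
            continue
        prof = window_profiles(rdms, region, window)
        for i, subject in enumerate(rdms.subjects):
            for c_idx, comp in enumerate(COMPONENTS):
                prof_rows.append({
                    "region": region, "window": f"{window[0]}-{window[1]}",
                    "subject": subject, "component": comp,
                    "mean_accuracy": prof[i, c_idx],
                })
        for contrast in PROFILE_CONTRASTS:
            values, test = profile_contrast(prof, contrast)
            contrast_rows.append({
                "region": region, "window": f"{window[0]}-{window[1]}",
                "contrast": contrast, "mean": float(np.mean(values)),
                "t": test.statistic, "df": test.df, "p": test.p,
            })

    # --- power / pattern -----------------------------------------------
    pp_rows, anova_tables, assoc_rows = [], [], []
    for region, window, kind in (
            (lay.power_region, lay.power_window, "power_gain"),
            (lay.rotation_region, lay.rotation_window, "pattern_rotation")):
        if region not in rdms.regions:
            continue
        metrics = recognition_metrics(dataset, design, cfg, rdms, region,
                                      window)
        anova = _power_anova_table(metrics)
        anova.insert(0, "region", region)
        anova_tables.append(anova)
        rho, p = decoding_power_association(
            metrics["decoding_gain"].to_numpy(),
            metrics["power_delta"].to_numpy())
        angle = angle_timecourse_vs_baseline(dataset, region, design, cfg,
                                             window)
        assoc_rows.append({
            "region": region, "window": f"{window[0]}-{window[1]}",
            "injected": kind, "spearman_rho": rho, "spearman_p": p,
            "alpha_window_mean": float(angle.window_alpha.mean()),
            "alpha_baseline_mean": float(angle.baseline_alpha.mean()),
            "alpha_t": angle.test.statistic, "alpha_p": angle.test.p,
        })
        for i, subject in enumerate(dataset.subjects):
            for b, tms in enumerate(angle.bin_times):
                pp_rows.append({
                    "region": region, "subject": subject,
                    "time_ms": float(tms), "alpha_deg": angle.alpha[i, b],
                })

    # --- generalization -------------------------------------------------
    gen_rows, cluster_rows = [], []
    other = {"face": "tool", "tool": "face"}[category]
    has_control = bool(dataset.design.conditions_of(other))
    specs = default_generalization_specs(
        design, control_category=other if has_control else None)
    gen_region = lay.delayed_region if lay.delayed_region in rdms.regions \
        else rdms.regions[0]
    rng = np.random.default_rng(cfg.rng_seed + 1)
    for name, spec_list in specs.items():
        mats = []
        for spec in spec_list:
            gm = generalization_matrix(dataset, gen_region, spec, cfg,
                                       design=dataset.design)
            mats.append(gm.accuracy)
        gm_acc = np.mean(mats, axis=0)
        result = cluster_permutation_2d(gm_acc, 0.5, cfg, rng)
        T = len(gm.bin_times)
        mean_acc = gm_acc.mean(axis=0)
        for i in range(T):
            for jj in range(T):
                gen_rows.append({
                    "spec": name, "region": gen_region,
                    "train_ms": float(gm.bin_times[i]),
                    "test_ms": float(gm.bin_times[jj]),
                    "accuracy": mean_acc[i, jj],
                })
        for mask, size, p in result.clusters:
            ti, tj = np.nonzero(mask)
            cluster_rows.append({
                "spec": name, "region": gen_region, "size": size, "p": p,
                "significant": p < cfg.cluster_alpha,
                "train_ms_min": float(gm.bin_times[ti.min()]),
                "train_ms_max": float(gm.bin_times[ti.max()]),
                "test_ms_min": float(gm.bin_times[tj.min()]),
                "test_ms_max": float(gm.bin_times[tj.max()]),
            })

    tables = {
        "rdms": rdm_table,
        "rsa_map": emap.table,
        "profiles": pd.DataFrame(prof_rows),
        "profile_contrasts": pd.DataFrame(contrast_rows),
        "power_anova": pd.concat(anova_tables, ignore_index=True)
        if anova_tables else pd.DataFrame(),
        "alpha_timecourses": pd.DataFrame(pp_rows),
        "power_pattern_summary": pd.DataFrame(assoc_rows),
        "generalization": pd.DataFrame(gen_rows),
        "generalization_clusters": pd.DataFrame(cluster_rows),
    }
    extra = {
        "category": category,
        "excluded_subjects": rdms.excluded_subjects,
        "window_summaries": {
            f"{lo}-{hi}": regs
            for (lo, hi), regs in emap.window_summaries.items()
        },
    }
    save_results(tables, out, config=cfg, extra_manifest=extra)
    return out


def report(results_dir: str | Path, fmt: str = "png") -> list[Path]:
    """Render summary figures from the CSV tables alone."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = Path(results_dir)
    written: list[Path] = []

    def missing(name: str) -> bool:
        if not (res / f"{name}.csv").exists():
            logger.warning("report: missing %s.csv, skipped", name)
            return True
        return False

    if not missing("rsa_map"):
        emap = pd.read_csv(res / "rsa_map.csv")
        regions = emap["region"].unique()
        times = np.sort(emap["time_ms"].unique())
        grid = emap.pivot_table(index="region", columns="time_ms",
                                values="z_mean").loc[regions]
        sig = emap.pivot_table(index="region", columns="time_ms",
                               values="significant").loc[regions]
        fig, ax = plt.subplots(figsize=(8, 0.5 * len(regions) + 2))
        im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="RdBu_r",
                       extent=[times.min(), times.max(),
                               len(regions) - 0.5, -0.5])
        ys, xs = np.nonzero(sig.to_numpy() > 0.5)
        if len(ys):
            ax.scatter(times[xs], ys, s=6, c="k", marker=".")
            ax.set_title("RSA effect map (dots: FDR-significant)")
        else:
            ax.set_title("RSA effect map: no significant cells")
        ax.set_yticks(range(len(regions)), regions)
        ax.set_xlabel("time (ms)")
        fig.colorbar(im, ax=ax, label="mean Fisher z")
        target = res / f"rsa_map.{fmt}"
        fig.savefig(target, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(target)

    if not missing("profiles"):
        prof = pd.read_csv(res / "profiles.csv")
        if len(prof):
            for (region, window), sub in prof.groupby(["region", "window"]):
                means = sub.groupby("component")["mean_accuracy"].mean()
                means = means.reindex(list(COMPONENTS))
                w = np.array(
                    [1, 1, 2, 2, 2, 8, 8, 2, 2], dtype=float)
                low = np.average(means[:6], weights=w[:6])
                high = np.average(means[6:], weights=w[6:])
                fig, ax = plt.subplots(figsize=(6, 3.5))
                ax.bar(range(9), means.to_numpy(),
                       color=plt.cm.viridis(w / w.max()))
                ax.hlines(low, -0.5, 5.5, linestyles="dashed", color="k")
                ax.hlines(high, 5.5, 8.5, linestyles="dashed", color="k")
                ax.axvline(5.5, color="grey", lw=0.8)
                ax.set_xticks(range(9), COMPONENTS)
                ax.set_ylabel("decoding accuracy")
                ax.set_title(f"RDM profile: {region} {window} ms "
                             "(components 1-6 | 7-9)")
                target = res / f"profile_{region}_{window}.{fmt}"
                fig.savefig(target, dpi=120, bbox_inches="tight")
                plt.close(fig)
                written.append(target)

    if not missing("alpha_timecourses"):
        alpha = pd.read_csv(res / "alpha_timecourses.csv")
        if len(alpha):
            fig, ax = plt.subplots(figsize=(7, 3.5))
            for region, sub in alpha.groupby("region"):
                tc = sub.groupby("time_ms")["alpha_deg"].mean()
                ax.plot(tc.index, tc.to_numpy(), label=region)
            ax.axvline(0, color="grey", lw=0.8)
            ax.axhline(90, color="grey", lw=0.8, linestyle="dotted")
            ax.set_xlabel("time (ms)")
            ax.set_ylabel("alpha (degrees)")
            ax.legend()
            ax.set_title("Discriminant-normal angle (baseline: t < 0)")
            target = res / f"alpha_timecourses.{fmt}"
            fig.savefig(target, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(target)

    if not missing("generalization"):
        gen = pd.read_csv(res / "generalization.csv")
        clusters = pd.read_csv(res / "generalization_clusters.csv") \
            if (res / "generalization_clusters.csv").exists() else None
        for name, sub in gen.groupby("spec"):
            grid = sub.pivot_table(index="train_ms", columns="test_ms",
                                   values="accuracy")
            fig, ax = plt.subplots(figsize=(5, 4.2))
            im = ax.imshow(grid.to_numpy(), origin="lower", cmap="viridis",
                           extent=[grid.columns.min(), grid.columns.max(),
                                   grid.index.min(), grid.index.max()])
            title = f"generalization: {name}"
            if clusters is not None and len(clusters):
                sig = clusters[(clusters["spec"] == name)
                               & clusters["significant"]]
                for _, row in sig.iterrows():
                    ax.add_patch(plt.Rectangle(
                        (row["test_ms_min"], row["train_ms_min"]),
                        row["test_ms_max"] - row["test_ms_min"],
                        row["train_ms_max"] - row["train_ms_min"],
                        fill=False, edgecolor="red", lw=1.5))
                if len(sig) == 0:
                    title += " (no significant cluster)"
            ax.plot([grid.columns.min(), grid.columns.max()],
                    [grid.index.min(), grid.index.max()],
                    color="w", lw=0.8)
            ax.set_xlabel("test time (ms)")
            ax.set_ylabel("train time (ms)")
            ax.set_title(title)
            fig.colorbar(im, ax=ax, label="accuracy")
            target = res / f"generalization_{name}.{fmt}"
            fig.savefig(target, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(target)

    return written
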