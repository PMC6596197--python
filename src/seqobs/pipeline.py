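"""End-to-end orchestration of the two headline analyses.

``run_pipeline`` drives the stages

    simulate -> behavior -> glm -> roi -> ldc -> searchlight -> stats

on a fully synthetic study described by a :class:`~seqobs.io.StudyConfig`
and writes a deterministic artifact directory (event tables, NIfTI maps,
summary tables, and a manifest with content hashes).  The stats stage
emits the two hypothesis tests: (1) the average crossnobis dissimilarity
between the four observed sequences is above zero, and (2) the
post-training trained-vs-untrained difference, corrected for
pre-training differences via the regression intercept.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import design, glm, mvpa, roi as roi_mod, searchlight as sl, stats, synth
from .io import StudyConfig, write_manifest, write_nifti, write_table

__all__ = ["Pipeline", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ["simulate", "behavior", "glm", "roi", "ldc", "searchlight", "stats"]
DEPENDENCIES = {
    "simulate": [],
    "behavior": ["simulate"],
    "glm": ["simulate"],
    "roi": ["glm"],
    "ldc": ["roi"],
    "searchlight": ["glm"],
    "stats": ["behavior", "ldc"],
}
SESSIONS = ("pre", "post")
CONDITIONS = ("trained", "untrained")

#: spatial extent (mm) and strength of the simulated univariate training
#: effect (reduced activity for trained sequences post-training) that the
#: ROI-definition stage is meant to find
EFFECT_RADIUS_MM = 8.0
EFFECT_SIZE = 1.5
GROUP_PEAK_P = 0.005


class Pipeline:
    """Stage runner holding the in-memory state of one synthetic study."""

    def __init__(self, config: StudyConfig, outdir: str | Path):
        self.cfg = config
        self.out = Path(outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.state: dict = {}
        self.done: set[str] = set()
        if (config.n_runs, config.n_volumes, config.tr) != (
            design.N_RUNS,
            design.N_RECORDED_VOLUMES,
            design.TR,
        ):
            raise ValueError("config run structure must match the scanning design")

    # ---------------------------------------------------------------- stages
    def run(self, stages: list[str] | None = None) -> Path:
        stages = list(STAGES) if stages is None else stages
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            missing = [d for d in DEPENDENCIES[stage] if d not in self.done]
            if missing:
                raise ValueError(f"stage {stage!r} requires {missing} to run first")
            logger.info("running stage %s", stage)
            getattr(self, f"_stage_{stage}")()
            self.done.add(stage)
        write_manifest(self.out, self.cfg)
        return self.out

    def _grid_positions(self) -> np.ndarray:
        idx = np.indices(self.cfg.grid_shape).reshape(3, -1).T
        return roi_mod.voxel_to_mm(idx, self.cfg.affine)

    def _stage_simulate(self) -> None:
        cfg = self.cfg
        pool = design.sample_sequence_pool(cfg.seeds["pool"])
        pos = self._grid_positions()
        center = pos.mean(axis=0)
        effect_blob = np.linalg.norm(pos - center, axis=1) <= EFFECT_RADIUS_MM

        subjects = []
        group_mean = np.random.default_rng(cfg.seeds["patterns"]).standard_normal(
            (2, cfg.n_voxels)
        )
        for s in range(cfg.n_subjects):
            alloc = design.allocate_conditions(pool, cfg.seeds["allocation"] + s)
            params = synth.PatternParams(
                n_voxels=cfg.n_voxels,
                signal_amplitude={
                    (ses, c): cfg.signal_amplitude for ses in SESSIONS for c in CONDITIONS
                },
                noise_variance=cfg.noise_variance,
                noise_length_scale_mm=cfg.noise_length_scale_mm,
                ar1_coef=cfg.ar1_coef,
                drift_amplitude=cfg.drift_amplitude,
                voxel_positions_mm=pos,
            )
            truth = synth.simulate_patterns(params, cfg.seeds["patterns"] + 1 + s)
            # group-consistent condition means so group-level univariate
            # statistics are meaningful
            truth = replace(truth, condition_mean=group_mean + 0.3 * truth.condition_mean)
            # post-training: reduced mean response to trained sequences
            # inside a focal effect region (what the ROI stage must find)
            post_mean = truth.condition_mean.copy()
            post_mean[0] = post_mean[0] - EFFECT_SIZE * effect_blob
            truth_post = replace(truth, condition_mean=post_mean)
            sessions = {}
            for ses, tr_ses in (("pre", truth), ("post", truth_post)):
                sched = design.build_scanning_session(
                    alloc, cfg.seeds["schedule"] + 100 * s + (0 if ses == "pre" else 1)
                )
                study = synth.simulate_bold(
                    sched,
                    tr_ses,
                    session=ses,
                    seed=cfg.seeds["bold"] + 100 * s + (0 if ses == "pre" else 1),
                    noise_scale=cfg.bold_noise_scale,
                )
                sessions[ses] = study
            subjects.append({"alloc": alloc, "truth": truth, "sessions": sessions})
        self.state["subjects"] = subjects
        self.state["effect_blob"] = effect_blob
        ev = design.events_to_table(subjects[0]["sessions"]["pre"].events.blocks_or_runs[0])
        write_table(ev, self.out / "events_sub00_pre_run00.tsv")

    def _stage_behavior(self) -> None:
        cfg = self.cfg
        params = synth.BehaviorParams(
            n_subjects=cfg.n_subjects,
            delta_init=cfg.delta_init_ms,
            delta_exec=cfg.delta_exec_ms,
            error_prob=cfg.error_prob,
        )
        trials = synth.simulate_behavior(params, cfg.seeds["behavior"])
        summary = beh.summarize(trials)
        self.state["behavior_summary"] = summary
        write_table(trials, self.out / "behavior_trials.tsv")
        write_table(summary, self.out / "behavior_summary.tsv")

    def _stage_glm(self) -> None:
        cfg = self.cfg
        for subj in self.state["subjects"]:
            fits = {}
            for ses, study in subj["sessions"].items():
                run_fits = [
                    glm.fit(y, X, whiten="ar1")
                    for y, X in zip(study.bold_runs, study.designs)
                ]
                seq_betas = np.stack(
                    [
                        np.stack([f.beta(f"seq_{q}") for f in run_fits])
                        for q in range(8)
                    ]
                )  # (8, runs, P)
                residuals = [f.residuals for f in run_fits]
                fits[ses] = {"betas": seq_betas, "residuals": residuals}
            subj["glm"] = fits
            subj["noise"] = mvpa.estimate_noise_cov(
                [r for ses in SESSIONS for r in fits[ses]["residuals"]]
            )
        betas0 = self.state["subjects"][0]["glm"]["pre"]["betas"]
        write_nifti(
            betas0.reshape(8, cfg.n_runs, *cfg.grid_shape)[:, 0].transpose(1, 2, 3, 0),
            cfg.affine,
            self.out / "betas_sub00_pre_run00.nii.gz",
        )

    def _intercept_map(self, subj: dict) -> np.ndarray:
        """Voxelwise run-level regression intercept of post on pre differences."""
        diffs = {}
        for ses in SESSIONS:
            b = subj["glm"][ses]["betas"]  # (8, runs, P)
            diffs[ses] = b[:4].mean(axis=0) - b[4:].mean(axis=0)  # (runs, P)
        pre, post = diffs["pre"], diffs["post"]
        pre_c = pre - pre.mean(axis=0)
        denom = (pre_c**2).sum(axis=0)
        slope = np.where(denom > 0, (pre_c * post).sum(axis=0) / np.where(denom > 0, denom, 1), 0.0)
        return post.mean(axis=0) - slope * pre.mean(axis=0)

    def _stage_roi(self) -> None:
        cfg = self.cfg
        mask = np.ones(cfg.grid_shape, dtype=bool)
        maps = np.stack(
            [self._intercept_map(s).reshape(cfg.grid_shape) for s in self.state["subjects"]]
        )
        t_map = stats._t_map(maps)
        from scipy import stats as sps

        t_crit = sps.t.ppf(1 - GROUP_PEAK_P / 2, cfg.n_subjects - 1)
        peaks = roi_mod.group_peaks(t_map, mask, t_crit, k_min=10)
        rois = []
        rows = []
        for r, peak in enumerate(peaks):
            per_subject = []
            for s, subj in enumerate(self.state["subjects"]):
                sp = roi_mod.subject_peak(
                    self._intercept_map(subj).reshape(cfg.grid_shape),
                    peak,
                    cfg.affine,
                    mask,
                    radius_mm=cfg.group_radius_mm,
                )
                spec = roi_mod.sphere_roi(
                    sp,
                    cfg.affine,
                    mask,
                    radius_mm=cfg.subject_radius_mm,
                    subject=f"sub{s:02d}",
                    group_center=peak,
                )
                per_subject.append(spec)
                rows.append(
                    {
                        "roi": r,
                        "subject": s,
                        "group_center": str(peak),
                        "subject_center": str(sp),
                        "n_voxels": spec.size,
                    }
                )
            rois.append(per_subject)
        self.state["rois"] = rois
        self.state["group_t_map"] = t_map
        write_nifti(t_map, cfg.affine, self.out / "group_training_tmap.nii.gz")
        write_table(pd.DataFrame(rows), self.out / "roi_table.tsv")

    def _stage_ldc(self) -> None:
        cfg = self.cfg
        rows = []
        for r, per_subject in enumerate(self.state["rois"]):
            for s, spec in enumerate(per_subject):
                subj = self.state["subjects"][s]
                lin = np.ravel_multi_index(tuple(spec.member_voxels.T), cfg.grid_shape)
                noise = subj["noise"].restrict(lin)
                for ses in SESSIONS:
                    betas = subj["glm"][ses]["betas"][:, :, lin]
                    for cond, sel in (("trained", slice(0, 4)), ("untrained", slice(4, 8))):
                        ldc = mvpa.random_subspace_ldc(
                            betas[sel],
                            noise,
                            n_subsets=cfg.n_subsets,
                            subset_size=cfg.subset_size,
                            seed=cfg.seeds["subspace"] + 1000 * r + 10 * s,
                        )
                        rows.append(
                            {
                                "roi": r,
                                "subject": s,
                                "session": ses,
                                "condition": cond,
                                "ldc": ldc,
                            }
                        )
        tab = pd.DataFrame(rows)
        self.state["roi_ldc"] = tab
        write_table(tab, self.out / "roi_ldc.tsv")

    def _stage_searchlight(self) -> None:
        cfg = self.cfg
        mask = np.ones(cfg.grid_shape, dtype=bool)
        nbh = sl.build_neighborhoods(mask, cfg.affine, k=cfg.searchlight_k)
        lin = np.ravel_multi_index(tuple(nbh.voxels.T), cfg.grid_shape)
        summaries = []
        mean_maps: dict[str, np.ndarray] = {}
        for s, subj in enumerate(self.state["subjects"]):
            noise = subj["noise"].restrict(lin)
            maps = {}
            for ses in SESSIONS:
                betas = subj["glm"][ses]["betas"][:, :, lin]
                for cond, sel in (("trained", slice(0, 4)), ("untrained", slice(4, 8))):
                    m = sl.searchlight_ldc(
                        betas[sel],
                        noise,
                        nbh,
                        fwhm_mm=cfg.ldc_smoothing_fwhm_mm,
                        session=ses,
                        condition=cond,
                    )
                    key = f"{ses}_{cond}"
                    maps[key] = m
                    mean_maps.setdefault(key, np.zeros(len(nbh)))
                    mean_maps[key] += m.values / cfg.n_subjects
            summ = sl.global_summary(maps)
            summ.insert(0, "subject", s)
            summaries.append(summ)
        tab = pd.concat(summaries, ignore_index=True)
        self.state["searchlight_summary"] = tab
        self.state["neighborhoods"] = nbh
        write_table(tab, self.out / "searchlight_global_summary.tsv")
        for key, vals in mean_maps.items():
            vol = np.zeros(cfg.grid_shape)
            vol[tuple(nbh.voxels.T)] = vals
            write_nifti(vol, cfg.affine, self.out / f"searchlight_mean_{key}.nii.gz")

    def _stage_stats(self) -> None:
        rows = []
        # behavioral training effects (hypothesis: faster trained sequences)
        summary = self.state["behavior_summary"]
        for measure in ("initiation_ms", "execution_ms", "error_rate_pct"):
            pre, post = beh.condition_differences(summary, measure)
            eff = stats.intercept_effect(pre, post)
            rows.append(
                {
                    "analysis": f"behavior_{measure}",
                    "estimate": eff.b0,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "t": eff.t,
                    "df": eff.df,
                    "p": eff.p,
                    "d_z": eff.d_z,
                }
            )
        # hypothesis 1: average LDC above zero (per ROI and session)
        ldc = self.state["roi_ldc"]
        n_rois = ldc["roi"].nunique()
        for (r, ses), grp in ldc.groupby(["roi", "session"]):
            mean_ldc = grp.groupby("subject")["ldc"].mean().to_numpy()
            res = stats.one_sample_t(mean_ldc, tail="one", m_corrections=n_rois)
            rows.append(
                {
                    "analysis": f"ldc_above_zero_roi{r}_{ses}",
                    "estimate": float(mean_ldc.mean()),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "t": res.statistic,
                    "df": res.df[0],
                    "p": res.p,
                    "d_z": res.effect_size,
                }
            )
        # hypothesis 2: posttraining trained > untrained, intercept-corrected
        for r, grp in ldc.groupby("roi"):
            wide = grp.pivot_table(
                index="subject", columns=["session", "condition"], values="ldc"
            )
            pre = (wide[("pre", "trained")] - wide[("pre", "untrained")]).to_numpy()
            post = (wide[("post", "trained")] - wide[("post", "untrained")]).to_numpy()
            eff = stats.intercept_effect(pre, post)
            rows.append(
                {
                    "analysis": f"ldc_training_effect_roi{r}",
                    "estimate": eff.b0,
                    "ci_low": eff.ci_low,
                    "ci_high": eff.ci_high,
                    "t": eff.t,
                    "df": eff.df,
                    "p": eff.p,
                    "d_z": eff.d_z,
                }
            )
        tab = pd.DataFrame(rows)
        self.state["stats"] = tab
        write_table(tab, self.out / "stats_summary.tsv")

        anova_src = ldc.rename(columns={"session": "scan", "condition": "training"})
        if n_rois >= 2:
            within = ["roi", "scan", "training"]
        else:
            within = ["scan", "training"]
        anova = stats.rm_anova(anova_src, dv="ldc", within=within)
        self.state["anova"] = anova
        write_table(anova, self.out / "ldc_anova.tsv")


def run_pipeline(
    config: StudyConfig, outdir: str | Path, stages: list[str] | None = None
) -> Pipeline:
    """Run the requested stages (default: all) and write artifacts."""
    pipe = Pipeline(config, outdir)
    pipe.run(stages)
    return pipe
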