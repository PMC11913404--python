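"""End-to-end orchestration: events → routine → photometry → align → stats.

`analyze_cohort` runs the full analysis on in-memory sessions;
`run_pipeline` wraps it with file I/O, a YAML config and a reproducible
results bundle.  Activity before the rewarded magazine entry is analyzed on
tail-fixed rNP-ME blocks, activity after it on head-fixed ME-MX blocks; the
cluster-based permutation test on the stacked routine-index weights is the
headline inference.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import photometry as ph
from .align import align_blocks, peri_event_matrix
from .routine import RoutineIndexConfig, routine_index, select_transformation
from .stats import (CovariateSet, RoutineRegression, covariates_for_blocks,
                    build_long_table, lrt_model_comparison,
                    pre_post_comparison, shuffle_r2_validation)


@dataclass
class AnalysisParams:
    """Every tunable of the analysis, with the study defaults."""

    ri: RoutineIndexConfig = field(default_factory=RoutineIndexConfig)
    dff: ph.DffParams = field(default_factory=ph.DffParams)
    cycle_anchor: str = "ME"
    pre_window: float = 1.0        # tail-fixed rNP-ME window, s
    post_window: float = 1.5       # head-fixed ME-MX window, s
    alpha_forming: float = 0.05
    n_perm: int = 10_000
    n_bins: int = 10               # SE bins for behavioral curves
    n_shuffles_r2: int = 1000
    n_shuffles_snr: int = 1000
    lmm_time_bins: int = 10
    min_blocks: int = 8
    channel: str = "z"
    seed: int = 0


@dataclass
class SubjectData:
    """One subject's per-stage intermediate products."""

    subject_id: str
    stream: ev.EventStream
    trace: ph.PhotometryTrace
    blocks: list = None
    cycles: list = None
    matrices: dict = None        # "pre" (rNP-ME tail), "post" (ME-MX head), "peri_me"
    covariates: dict = None


@dataclass
class CohortAnalysis:
    """Results bundle of one cohort run."""

    params: AnalysisParams
    subjects: list                       # SubjectData, analysis-eligible
    excluded: list                       # (subject_id, reason)
    transformation_report: object
    cluster_results: dict                # interval name -> ClusterResult
    auc_results: dict                    # interval name -> list[AucTestResult]
    pre_post: object
    shuffle_r2: dict                     # measure name -> ShuffleR2Result
    snr: dict                            # subject -> SNRReport
    model_comparison: dict               # interval name -> ModelComparisonTable
    regressions: dict                    # interval name -> RoutineRegressionResults

    def summary(self) -> str:
        lines = [f"Cohort analysis: {len(self.subjects)} subjects "
                 f"({len(self.excluded)} excluded)"]
        lines.append(f"  selected RI transformation: "
                     f"{self.transformation_report.selected}")
        for name, res in self.cluster_results.items():
            sig = res.significant()
            if sig:
                for c in sig:
                    lines.append(
                        f"  {name}: significant RI cluster "
                        f"[{c.t_start:+.3f}, {c.t_end:+.3f}] s, "
                        f"mass={c.mass:.1f}, p={c.p:.4f}, sign={c.sign:+d}")
            else:
                lines.append(f"  {name}: no significant RI clusters")
        lines.append(f"  pre/post magazine-entry Wilcoxon p = {self.pre_post.p:.4f}")
        for name, res in self.shuffle_r2.items():
            lines.append(f"  shuffle-R2 ({name}): mean R2 = "
                         f"{res.r2_original.mean():.3f}, p = {res.p:.4f}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "n_subjects": len(self.subjects),
            "excluded": list(self.excluded),
            "transformation": self.transformation_report.to_json_dict(),
            "clusters": {k: v.to_json_dict()
                         for k, v in self.cluster_results.items()},
            "auc": {k: [a.to_json_dict() for a in v]
                    for k, v in self.auc_results.items()},
            "pre_post_p": self.pre_post.p,
            "shuffle_r2": {k: {"mean_r2": float(v.r2_original.mean()),
                               "p": v.p} for k, v in self.shuffle_r2.items()},
            "snr": {k: {"snr": (None if not np.isfinite(v.snr_original)
                                else float(v.snr_original)), "p": v.p}
                    for k, v in self.snr.items()},
            "model_comparison": {
                k: v.table.to_dict(orient="records")
                for k, v in self.model_comparison.items()},
        }


def _subject_stage(subj: SubjectData, params: AnalysisParams) -> str | None:
    """Segment, preprocess and align one subject; returns a reason if unusable."""
    subj.blocks = ev.segment_blocks(subj.stream)
    subj.cycles = ev.segment_cycles(subj.blocks, cycle_anchor=params.cycle_anchor)
    if len(subj.cycles) < 2:
        return "fewer than 2 cycles"
    subj.trace = ph.preprocess(subj.trace)
    subj.matrices, subj.covariates = {}, {}
    layout = {"pre": ("rNP-ME", "tail_fixed", params.pre_window),
              "post": ("ME-MX", "head_fixed", params.post_window)}
    for name, (btype, mode, window) in layout.items():
        blocks = [b for b in subj.blocks if b.block_type == btype]
        kept, X = covariates_for_blocks(blocks, subj.cycles, params.ri)
        if len(kept) < params.min_blocks:
            return f"fewer than {params.min_blocks} usable {btype} blocks"
        M = align_blocks(subj.trace, kept, mode=mode, window_override=window,
                         channel=params.channel)
        idmap = {id(b): i for i, b in enumerate(kept)}
        rows = [idmap[id(b)] for b in M.block_refs]
        if len(rows) < params.min_blocks:
            return f"fewer than {params.min_blocks} aligned {btype} blocks"
        subj.matrices[name] = M
        subj.covariates[name] = X.subset(rows)
    me_times = [b.t_end for b in subj.matrices["pre"].block_refs]
    subj.matrices["peri_me"] = peri_event_matrix(
        subj.trace, me_times, pre=0.5, post=0.5, channel=params.channel)
    return None


def _ri_curve(subj: SubjectData, params: AnalysisParams) -> pd.Series:
    """Mean routine index per SE bin for one subject."""
    edges = np.linspace(0, 1, params.n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    se = np.array([c.session_elapsed for c in subj.cycles])
    ri = np.array([routine_index(c.duration, params.ri) for c in subj.cycles])
    idx = np.clip(np.digitize(se, edges[1:-1]), 0, params.n_bins - 1)
    vals = [ri[idx == k].mean() if (idx == k).any() else np.nan
            for k in range(params.n_bins)]
    return pd.Series(vals, index=centers)


def analyze_cohort(streams, traces, params: AnalysisParams | None = None,
                   subject_ids=None) -> CohortAnalysis:
    """Run the full analysis on in-memory sessions.

    Parameters
    ----------
    streams, traces : per-subject EventStream / raw PhotometryTrace lists
    params : AnalysisParams (study defaults if omitted)
    """
    params = params or AnalysisParams()
    if subject_ids is None:
        subject_ids = [s.subject_id for s in streams]
    subjects, excluded = [], []
    for sid, stream, trace in zip(subject_ids, streams, traces):
        subj = SubjectData(subject_id=sid, stream=stream, trace=trace)
        reason = _subject_stage(subj, params)
        if reason:
            excluded.append((sid, reason))
            warnings.warn(f"subject {sid} excluded: {reason}", stacklevel=2)
        else:
            subjects.append(subj)
    if len(subjects) < 5:
        raise ValueError(f"only {len(subjects)} usable subjects")

    durations = {s.subject_id: [c.duration for c in s.cycles] for s in subjects}
    transformation = select_transformation(
        durations, L=params.ri.L, seed=params.seed)

    cluster_results, auc_results, model_comp, regressions = {}, {}, {}, {}
    for name in ("pre", "post"):
        model = RoutineRegression(
            {s.subject_id: s.matrices[name] for s in subjects},
            {s.subject_id: s.covariates[name] for s in subjects})
        res = model.fit()
        regressions[name] = res
        cres = res.cluster_test(coef="ri", alpha_forming=params.alpha_forming,
                                n_perm=params.n_perm, seed=params.seed)
        cluster_results[name] = cres
        auc_results[name] = [res.auc_test((c.t_start, c.t_end))
                             for c in cres.significant()]
        long_df = build_long_table(
            {s.subject_id: s.matrices[name] for s in subjects},
            {s.subject_id: s.covariates[name] for s in subjects},
            n_time_bins=params.lmm_time_bins)
        model_comp[name] = lrt_model_comparison(long_df)

    pre_post = pre_post_comparison(
        {s.subject_id: s.matrices["peri_me"] for s in subjects})

    ri_curves = pd.DataFrame({s.subject_id: _ri_curve(s, params)
                              for s in subjects}).T
    measures = {}
    for s in subjects:
        cp = ev.choice_proportions(s.blocks, n_bins=params.n_bins)
        bc = ev.blocks_per_cycle_curve(s.cycles, n_bins=params.n_bins)
        measures.setdefault("p_rnp_me", {})[s.subject_id] = \
            pd.Series(cp["p_rnp_me"].to_numpy(), index=cp["se_bin_center"])
        measures.setdefault("p_mx_rnp", {})[s.subject_id] = \
            pd.Series(cp["p_mx_rnp"].to_numpy(), index=cp["se_bin_center"])
        measures.setdefault("blocks_per_cycle", {})[s.subject_id] = \
            pd.Series(bc["mean_n_blocks"].to_numpy(), index=bc["se_bin_center"])
    shuffle_r2 = {}
    for mname, curves in measures.items():
        behavior = pd.DataFrame(curves).T
        try:
            shuffle_r2[mname] = shuffle_r2_validation(
                ri_curves, behavior, n_shuffles=params.n_shuffles_r2,
                seed=params.seed)
        except ValueError as exc:
            warnings.warn(f"shuffle-R2 skipped for {mname}: {exc}",
                          stacklevel=2)

    snr = {s.subject_id: ph.snr_shuffle_test(
        s.matrices["peri_me"].Y, n_shuffles=params.n_shuffles_snr,
        seed=params.seed) for s in subjects}

    return CohortAnalysis(
        params=params, subjects=subjects, excluded=excluded,
        transformation_report=transformation,
        cluster_results=cluster_results, auc_results=auc_results,
        pre_post=pre_post, shuffle_r2=shuffle_r2, snr=snr,
        model_comparison=model_comp, regressions=regressions)


# ---------------------------------------------------------------------------
# file-driven pipeline
# ---------------------------------------------------------------------------

@dataclass
class SubjectFiles:
    subject_id: str
    events_path: str
    trace_path: str


@dataclass
class PipelineConfig:
    subjects: list                      # of SubjectFiles
    outdir: str = "results"
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        subjects = [SubjectFiles(**s) for s in raw.get("subjects", [])]
        pr = raw.get("params", {})
        ri = RoutineIndexConfig(**pr.pop("ri", {}))
        dff = ph.DffParams(**pr.pop("dff", {}))
        params = AnalysisParams(ri=ri, dff=dff, **pr)
        return cls(subjects=subjects, outdir=raw.get("outdir", "results"),
                   params=params)

    def to_yaml(self, path) -> None:
        raw = {"outdir": self.outdir,
               "subjects": [asdict(s) for s in self.subjects],
               "params": asdict(self.params)}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps({"subjects": [asdict(s) for s in self.subjects],
                           "params": asdict(self.params)},
                          sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> CohortAnalysis:
    """Load files, run :func:`analyze_cohort`, write the results bundle."""
    streams, traces, ids = [], [], []
    for s in config.subjects:
        for path in (s.events_path, s.trace_path):
            if not os.path.exists(path):
                raise FileNotFoundError(
                    f"subject {s.subject_id}: missing file {path}")
        streams.append(ev.read_events(s.events_path, subject_id=s.subject_id))
        trace = ph.read_trace(s.trace_path, subject_id=s.subject_id)
        trace.params = config.params.dff
        traces.append(trace)
        ids.append(s.subject_id)
    os.makedirs(config.outdir, exist_ok=True)
    try:
        analysis = analyze_cohort(streams, traces, config.params,
                                  subject_ids=ids)
    except Exception:
        with open(os.path.join(config.outdir, "failed"), "w") as fh:
            fh.write("analysis stage failed\n")
        raise
    results = analysis.to_json_dict()
    results["run"] = {"config_hash": config.config_hash(),
                      "seed": config.params.seed,
                      "n_perm": config.params.n_perm}
    with open(os.path.join(config.outdir, "results.json"), "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    for name, res in analysis.regressions.items():
        rows = []
        for sid, series in res.beta_series.items():
            df = series.to_frame()
            df.insert(0, "subject", sid)
            rows.append(df)
        pd.concat(rows).to_csv(
            os.path.join(config.outdir, f"beta_series_{name}.csv"), index=False)
    for name, mc in analysis.model_comparison.items():
        mc.table.to_csv(
            os.path.join(config.outdir, f"model_comparison_{name}.csv"),
            index=False)
    with open(os.path.join(config.outdir, "summary.txt"), "w") as fh:
        fh.write(analysis.summary() + "\n")
    return analysis
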