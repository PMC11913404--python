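"""Regression of aligned Ca²⁺ activity on behavioral covariates, and inference.

The central model regresses each peri-event timepoint of a subject's
block × time activity matrix ``Y`` on three per-block covariates —
session elapsed (SE), block velocity (BV) and the routine index (RI):

    Y(:, t) = β₀(t) + β_SE(t)·SE + β_BV(t)·BV + β_RI(t)·RI

Per-subject coefficient series are stacked into N_S × T matrices and group
inference on β_RI uses a one-sample cluster-based permutation test
(sign-flip null, max-cluster-mass correction).  Post-hoc AUC regressions
summarize each block's activity over an identified interval and test the
subject-level weights with one-sample Wilcoxon signed-rank tests.  Nested
linear mixed models fitted by ML provide likelihood-ratio evidence that the
SE and BV nuisance terms are needed alongside RI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import AlignedMatrix, interval_auc
from .events import Block, Cycle, block_cycle_map
from .routine import DEFAULT_CONFIG, RoutineIndexConfig, routine_index

COVARIATES = ("se", "bv", "ri")


@dataclass
class CovariateSet:
    """Per-block covariate vectors paired with one AlignedMatrix."""

    se: np.ndarray
    bv: np.ndarray
    ri: np.ndarray

    def __post_init__(self) -> None:
        self.se = np.asarray(self.se, dtype=float)
        self.bv = np.asarray(self.bv, dtype=float)
        self.ri = np.asarray(self.ri, dtype=float)
        if not (self.se.shape == self.bv.shape == self.ri.shape):
            raise ValueError("covariate vectors must have equal length")
        for name in COVARIATES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"covariate {name} contains non-finite values")

    @property
    def K(self) -> int:
        return int(self.se.size)

    def design(self) -> np.ndarray:
        return np.column_stack(
            [np.ones(self.K), self.se, self.bv, self.ri])

    def subset(self, idx) -> "CovariateSet":
        return CovariateSet(self.se[idx], self.bv[idx], self.ri[idx])


def covariates_for_blocks(blocks: list[Block], cycles: list[Cycle],
                          cfg: RoutineIndexConfig = DEFAULT_CONFIG):
    """Build covariates for the given blocks; RI comes from the enclosing cycle.

    Blocks that belong to no cycle (e.g. before the first rewarded magazine
    entry) are dropped.  Returns ``(kept_blocks, CovariateSet)``.
    """
    mapping = cycles if isinstance(cycles, dict) else block_cycle_map(cycles)
    kept, se, bv, ri = [], [], [], []
    for b in blocks:
        cyc = mapping.get(id(b))
        if cyc is None:
            continue
        kept.append(b)
        se.append(b.session_elapsed)
        bv.append(b.block_velocity)
        ri.append(routine_index(cyc.duration, cfg))
    return kept, CovariateSet(np.array(se), np.array(bv), np.array(ri))


@dataclass
class BetaSeries:
    """Per-timepoint OLS coefficients for one subject."""

    beta0: np.ndarray
    beta_se: np.ndarray
    beta_bv: np.ndarray
    beta_ri: np.ndarray
    time_axis: np.ndarray
    subject_id: str = ""

    def coef(self, name: str) -> np.ndarray:
        return {"intercept": self.beta0, "se": self.beta_se,
                "bv": self.beta_bv, "ri": self.beta_ri}[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_axis, "beta0": self.beta0,
            "beta_se": self.beta_se, "beta_bv": self.beta_bv,
            "beta_ri": self.beta_ri})


def _check_design(X: CovariateSet) -> None:
    if X.K < 8:
        raise ValueError(f"need at least 8 blocks, got {X.K}")
    cols = {name: getattr(X, name) for name in COVARIATES}
    for i, a in enumerate(COVARIATES):
        for b in list(COVARIATES)[i + 1:]:
            sa, sb = cols[a].std(), cols[b].std()
            if sa == 0 or sb == 0:
                continue
            r = np.corrcoef(cols[a], cols[b])[0, 1]
            if abs(r) > 0.9999:
                raise ValueError(f"collinear covariates: {a} and {b}")
    if np.linalg.matrix_rank(X.design()) < 4:
        raise ValueError("rank-deficient design matrix")


def pointwise_regression(M: AlignedMatrix, X: CovariateSet,
                         subject_id: str = "") -> BetaSeries:
    """Independent OLS of Y(:, t) on [1, SE, BV, RI] at every timepoint."""
    if M.K != X.K:
        raise ValueError("matrix rows and covariate length differ")
    _check_design(X)
    coef, *_ = np.linalg.lstsq(X.design(), M.Y, rcond=None)
    if not np.all(np.isfinite(coef)):
        raise ValueError("non-finite regression coefficients")
    return BetaSeries(beta0=coef[0], beta_se=coef[1], beta_bv=coef[2],
                      beta_ri=coef[3], time_axis=M.time_axis.copy(),
                      subject_id=subject_id or "")


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    start: int
    end: int  # inclusive column index
    t_start: float
    t_end: float
    mass: float
    p: float
    sign: int


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    alpha_cluster_forming: float
    n_permutations: int
    seed: int | None
    t_obs: np.ndarray
    null_max_mass: np.ndarray

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_json_dict(self) -> dict:
        return {
            "alpha_cluster_forming": self.alpha_cluster_forming,
            "threshold_t": self.threshold,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "clusters": [
                {"t_start_s": c.t_start, "t_end_s": c.t_end,
                 "mass": c.mass, "p": c.p, "sign": c.sign}
                for c in self.clusters],
        }


def _row_t_stats(B: np.ndarray) -> np.ndarray:
    n = B.shape[0]
    mu = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mu / (sd / np.sqrt(n)), 0.0)
    return t


def _perm_t_stats(B: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t statistics for every sign-flip permutation in one pass.

    Sign flips leave each column's sum of squares unchanged, so only the
    permuted means need a matrix product.
    """
    n = B.shape[0]
    mean_p = signs @ B / n                       # (n_perm, T)
    ssq = (B ** 2).sum(axis=0)                   # (T,)
    var_p = (ssq[None, :] - n * mean_p ** 2) / (n - 1)
    var_p = np.maximum(var_p, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_p > 0, mean_p / np.sqrt(var_p / n), 0.0)
    return t


def _max_cluster_mass_rows(t_abs: np.ndarray, thresh: float) -> np.ndarray:
    """Max contiguous supra-threshold |t| mass per row, fully vectorized."""
    supra = t_abs > thresh
    m = np.where(supra, t_abs, 0.0)
    c = np.cumsum(m, axis=1)
    T = t_abs.shape[1]
    # index of the most recent non-supra column (or -1)
    idx = np.where(~supra, np.arange(T)[None, :], -1)
    idx = np.maximum.accumulate(idx, axis=1)
    base = np.where(idx >= 0,
                    np.take_along_axis(c, np.maximum(idx, 0), axis=1), 0.0)
    return (c - base).max(axis=1)


def _find_clusters(t: np.ndarray, thresh: float):
    supra = np.abs(t) > thresh
    clusters = []
    start = None
    for i, s in enumerate(supra):
        if s and start is None:
            start = i
        elif not s and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, len(supra) - 1))
    return clusters


def cluster_permutation(B, alpha_forming: float = 0.05,
                        n_perm: int = 10_000, seed: int | None = None,
                        time_axis=None) -> ClusterResult:
    """One-sample cluster-based permutation test on an N_S × T weight matrix.

    At each timepoint a two-sided one-sample t statistic is computed across
    subjects; timepoints with |t| above the α-forming critical value form
    contiguous clusters whose mass is Σ|t|.  The null flips the sign of
    whole subject rows and records the maximum cluster mass per permutation;
    each observed cluster's p is the add-one permutation estimate.
    """
    B = np.asarray(B, dtype=float)
    n_s, T = B.shape
    if n_s < 5:
        raise ValueError("need at least 5 subjects")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if time_axis is None:
        time_axis = np.arange(T, dtype=float)
    time_axis = np.asarray(time_axis, dtype=float)
    thresh = float(sps.t.ppf(1 - alpha_forming / 2, df=n_s - 1))
    t_obs = _row_t_stats(B)
    spans = _find_clusters(t_obs, thresh)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_s))
    t_perm = _perm_t_stats(B, signs)
    null_max = _max_cluster_mass_rows(np.abs(t_perm), thresh)
    clusters = []
    for (a, b) in spans:
        mass = float(np.abs(t_obs[a:b + 1]).sum())
        p = (1.0 + np.sum(null_max >= mass)) / (1.0 + n_perm)
        clusters.append(Cluster(
            start=a, end=b, t_start=float(time_axis[a]),
            t_end=float(time_axis[b]), mass=mass, p=float(p),
            sign=int(np.sign(t_obs[a:b + 1].mean()))))
    return ClusterResult(clusters=clusters, threshold=thresh,
                         alpha_cluster_forming=alpha_forming,
                         n_permutations=n_perm, seed=seed,
                         t_obs=t_obs, null_max_mass=null_max)


# ---------------------------------------------------------------------------
# subject-level Wilcoxon tests
# ---------------------------------------------------------------------------

def wilcoxon_across_subjects(weights, exact_max_n: int = 25) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p across subject weights.

    Exact null for small cohorts (N_S ≤ ``exact_max_n``), normal
    approximation with continuity correction above.
    """
    w = np.asarray(weights, dtype=float)
    if w.size < 5:
        raise ValueError("need at least 5 subjects")
    if np.all(w == 0):
        raise ValueError("degenerate test: all weights zero")
    method = "exact" if w.size <= exact_max_n else "approx"
    res = sps.wilcoxon(w, alternative="two-sided", method=method,
                       correction=(method == "approx"))
    return float(res.pvalue)


@dataclass
class AucTestResult:
    """Per-subject AUC regression weights and group Wilcoxon p per covariate."""

    weights: pd.DataFrame  # rows subjects, columns beta0/beta_se/beta_bv/beta_ri
    p_values: dict
    interval: tuple

    def to_json_dict(self) -> dict:
        return {"interval_s": list(self.interval),
                "p_values": {k: float(v) for k, v in self.p_values.items()},
                "weights": self.weights.reset_index().to_dict(orient="records")}


def auc_regression(M: AlignedMatrix, X: CovariateSet, interval) -> np.ndarray:
    """Per-subject OLS of interval AUC on [1, SE, BV, RI]; returns 4 betas."""
    auc = interval_auc(M, interval)
    _check_design(X)
    coef, *_ = np.linalg.lstsq(X.design(), auc, rcond=None)
    return coef


@dataclass
class PrePostResult:
    p: float
    table: pd.DataFrame  # per-subject pre/post mean activity


def pre_post_comparison(matrices_by_subject: dict,
                        pre_interval=(-0.5, 0.0),
                        post_interval=(0.0, 0.5)) -> PrePostResult:
    """Mean activity just before vs just after the anchor event.

    Per subject: blocks' mean activity in each window, averaged over blocks;
    the per-subject pre/post pairs are compared by a two-sided paired
    Wilcoxon signed-rank test.  Identical pre and post give p = 1.
    """
    rows = {}
    for subj, M in matrices_by_subject.items():
        lo, hi = M.time_axis[0], M.time_axis[-1]
        if lo > pre_interval[0] + 1e-9 or hi < post_interval[1] - 1e-9:
            raise ValueError(
                f"subject {subj}: time axis [{lo}, {hi}] does not cover the "
                f"pre/post windows")
        n_cols_pre = ((M.time_axis >= pre_interval[0] - 1e-9)
                      & (M.time_axis <= pre_interval[1] + 1e-9)).sum()
        n_cols_post = ((M.time_axis >= post_interval[0] - 1e-9)
                       & (M.time_axis <= post_interval[1] + 1e-9)).sum()
        pre = interval_auc(M, pre_interval) / n_cols_pre
        post = interval_auc(M, post_interval) / n_cols_post
        rows[subj] = {"pre": float(pre.mean()), "post": float(post.mean())}
    table = pd.DataFrame.from_dict(rows, orient="index")
    d = (table["post"] - table["pre"]).to_numpy()
    if np.all(d == 0):
        p = 1.0
    else:
        method = "exact" if d.size <= 25 else "approx"
        p = float(sps.wilcoxon(d, alternative="two-sided", method=method,
                               correction=(method == "approx")).pvalue)
    return PrePostResult(p=p, table=table)


# ---------------------------------------------------------------------------
# shuffle-R² validation of the routine index against behavioral curves
# ---------------------------------------------------------------------------

@dataclass
class ShuffleR2Result:
    r2_original: pd.Series  # per subject
    null_means: np.ndarray
    p: float
    n_shuffles: int
    seed: int | None
    dropped_subjects: list


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of y regressed on x (with intercept).

    A flat curve (zero variance on either side) carries no linear
    relationship; its R² is defined as 0.
    """
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _derangement(rng: np.random.Generator, n: int) -> np.ndarray:
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def shuffle_r2_validation(ri_curves: pd.DataFrame,
                          behavior_curves: pd.DataFrame,
                          n_shuffles: int = 1000,
                          seed: int | None = None,
                          scheme: str = "derangement") -> ShuffleR2Result:
    """R² between each subject's RI curve and a behavioral curve, vs a
    subject-shuffled null.

    Both inputs are subjects × SE-bin DataFrames on a common bin grid; bins
    where either curve is NaN are ignored per subject, and subjects with
    fewer than 3 shared occupied bins are dropped with a warning.  The null
    re-pairs behavior curves with RI curves from *other* subjects
    (derangement by default, full permutation with ``scheme="permutation"``),
    and p compares the across-subject mean R² with the null means.
    """
    if not ri_curves.index.equals(behavior_curves.index):
        behavior_curves = behavior_curves.reindex(ri_curves.index)
    subjects, dropped = [], []
    for subj in ri_curves.index:
        ok = ri_curves.loc[subj].notna() & behavior_curves.loc[subj].notna()
        if ok.sum() < 3:
            dropped.append(subj)
            warnings.warn(f"subject {subj!r} dropped: <3 occupied bins",
                          stacklevel=2)
        else:
            subjects.append(subj)
    if len(subjects) < 2:
        raise ValueError("fewer than 2 usable subjects")

    def pair_r2(b_subj, r_subj):
        ok = (ri_curves.loc[r_subj].notna()
              & behavior_curves.loc[b_subj].notna())
        if ok.sum() < 3:
            return np.nan
        return _r2(ri_curves.loc[r_subj, ok].to_numpy(),
                   behavior_curves.loc[b_subj, ok].to_numpy())

    orig = pd.Series({s: pair_r2(s, s) for s in subjects})
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_shuffles)
    n = len(subjects)
    for k in range(n_shuffles):
        perm = (_derangement(rng, n) if scheme == "derangement"
                else rng.permutation(n))
        vals = [pair_r2(subjects[i], subjects[perm[i]]) for i in range(n)]
        null_means[k] = np.nanmean(vals)
    p = (1.0 + np.sum(null_means >= orig.mean())) / (1.0 + n_shuffles)
    return ShuffleR2Result(r2_original=orig, null_means=null_means,
                           p=float(p), n_shuffles=n_shuffles, seed=seed,
                           dropped_subjects=dropped)


# ---------------------------------------------------------------------------
# nested linear mixed models / likelihood-ratio comparison
# ---------------------------------------------------------------------------

MODEL_FORMULAS = {
    "RI": "y ~ ri * time",
    "RI + SE": "y ~ ri * time + se * time",
    "RI + BV": "y ~ ri * time + bv * time",
    "Full": "y ~ ri * time + se * time + bv * time",
}


def build_long_table(matrices_by_subject: dict,
                     covariates_by_subject: dict,
                     n_time_bins: int = 10) -> pd.DataFrame:
    """Stack (subject, block, timepoint) records for mixed-model fitting.

    Each subject's aligned matrix is reduced to ``n_time_bins`` equal column
    bins (mean activity within a bin); ``time`` is the bin-center time in
    seconds, entering the models as a continuous covariate.
    """
    records = []
    for subj, M in matrices_by_subject.items():
        X = covariates_by_subject[subj]
        if M.K != X.K:
            raise ValueError(f"subject {subj}: rows/covariates mismatch")
        edges = np.linspace(0, M.T, n_time_bins + 1).astype(int)
        for b in range(n_time_bins):
            lo, hi = edges[b], edges[b + 1]
            if hi <= lo:
                continue
            act = M.Y[:, lo:hi].mean(axis=1)
            t_center = float(M.time_axis[lo:hi].mean())
            for k in range(M.K):
                records.append({"subject": subj, "block": k,
                                "time": t_center, "y": act[k],
                                "se": X.se[k], "bv": X.bv[k], "ri": X.ri[k]})
    return pd.DataFrame.from_records(records)


@dataclass
class ModelComparisonTable:
    """LRTs of restricted mixed models against the full model (Model 4)."""

    table: pd.DataFrame
    n_obs: int
    converged: dict

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def _fit_mixedlm(formula: str, df: pd.DataFrame):
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning
    model = smf.mixedlm(formula, data=df, groups=df["subject"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=500)
            if not np.isfinite(res.llf):
                raise ValueError("non-finite log-likelihood")
            return res, True
        except Exception:
            try:
                res = model.fit(reml=False, method="powell", maxiter=1000)
                return res, bool(np.isfinite(res.llf))
            except Exception:
                return None, False


def lrt_model_comparison(long_df: pd.DataFrame,
                         models: dict | None = None) -> ModelComparisonTable:
    """Fit the four nested mixed models by ML and compare each with the full.

    Fixed effects are the covariate main effects, a linear time term and
    their interactions; the random effect is a subject intercept.  ML (not
    REML) fitting is used because the likelihood-ratio tests compare
    fixed-effect structures.  Reported DF counts fixed-effect parameters
    plus the random-intercept and residual variances, matching the standard
    mixed-model parameter count.
    """
    if long_df["subject"].nunique() < 5:
        raise ValueError("need at least 5 subjects")
    models = models or MODEL_FORMULAS
    n = len(long_df)
    fits, converged = {}, {}
    for name, formula in models.items():
        res, ok = _fit_mixedlm(formula, long_df)
        fits[name] = res
        converged[name] = ok
    full = fits["Full"]
    if full is None:
        raise RuntimeError("full model failed to fit")

    def dof(res):
        return int(res.k_fe) + 1 + 1  # fixed effects + re variance + residual

    rows = []
    for name, res in fits.items():
        if res is None:
            rows.append({"Model": name, "DF": np.nan, "AIC": np.nan,
                         "BIC": np.nan, "LL": np.nan, "LR": np.nan,
                         "dDF": np.nan, "p": np.nan})
            continue
        k = dof(res)
        row = {"Model": name, "DF": k,
               "AIC": -2 * res.llf + 2 * k,
               "BIC": -2 * res.llf + k * np.log(n),
               "LL": res.llf}
        if name != "Full" and converged.get("Full"):
            lr = 2 * (full.llf - res.llf)
            ddf = dof(full) - k
            row.update(LR=lr, dDF=ddf,
                       p=float(sps.chi2.sf(lr, ddf)) if ddf > 0 else np.nan)
        else:
            row.update(LR=np.nan, dDF=np.nan, p=np.nan)
        rows.append(row)
    order = [m for m in models if m != "Full"] + ["Full"]
    table = (pd.DataFrame(rows).set_index("Model").loc[order].reset_index())
    return ModelComparisonTable(table=table, n_obs=n, converged=converged)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class RoutineRegression:
    """Cohort-level per-timepoint regression of aligned activity on SE/BV/RI.

    Parameters
    ----------
    aligned_by_subject : mapping subject -> AlignedMatrix
        One matrix per subject, all on the same time axis.
    covariates_by_subject : mapping subject -> CovariateSet
        Row-matched covariates for each matrix.
    """

    def __init__(self, aligned_by_subject: dict, covariates_by_subject: dict):
        if set(aligned_by_subject) != set(covariates_by_subject):
            raise ValueError("subject keys differ between matrices and covariates")
        if len(aligned_by_subject) < 2:
            raise ValueError("need at least 2 subjects")
        axes = [M.time_axis for M in aligned_by_subject.values()]
        for ax in axes[1:]:
            if ax.shape != axes[0].shape or not np.allclose(ax, axes[0]):
                raise ValueError("subjects must share one time axis")
        self.aligned = dict(aligned_by_subject)
        self.covariates = dict(covariates_by_subject)
        self.time_axis = axes[0]

    def fit(self) -> "RoutineRegressionResults":
        series = {
            subj: pointwise_regression(self.aligned[subj],
                                       self.covariates[subj], subject_id=str(subj))
            for subj in self.aligned
        }
        return RoutineRegressionResults(self, series)


class RoutineRegressionResults:
    """Fitted per-subject beta series with group-level inference methods."""

    def __init__(self, model: RoutineRegression, beta_series: dict):
        self.model = model
        self.beta_series = beta_series
        self.subjects = list(beta_series)
        self.time_axis = model.time_axis

    def B(self, coef: str = "ri") -> np.ndarray:
        """Stacked N_S × T matrix of one coefficient across subjects."""
        return np.vstack([self.beta_series[s].coef(coef) for s in self.subjects])

    def cluster_test(self, coef: str = "ri", alpha_forming: float = 0.05,
                     n_perm: int = 10_000, seed: int | None = None) -> ClusterResult:
        return cluster_permutation(self.B(coef), alpha_forming=alpha_forming,
                                   n_perm=n_perm, seed=seed,
                                   time_axis=self.time_axis)

    def auc_test(self, interval) -> AucTestResult:
        rows = {}
        for subj in self.subjects:
            coef = auc_regression(self.model.aligned[subj],
                                  self.model.covariates[subj], interval)
            rows[subj] = dict(zip(("beta0", "beta_se", "beta_bv", "beta_ri"),
                                  coef))
        weights = pd.DataFrame.from_dict(rows, orient="index")
        p_values = {name: wilcoxon_across_subjects(weights[f"beta_{name}"])
                    for name in COVARIATES}
        return AucTestResult(weights=weights, p_values=p_values,
                             interval=tuple(interval))

    def summary(self) -> str:
        lines = [
            "Routine-formation pointwise regression",
            f"  subjects: {len(self.subjects)}   "
            f"timepoints: {self.time_axis.size}   "
            f"window: [{self.time_axis[0]:.3f}, {self.time_axis[-1]:.3f}] s",
            "  mean beta (across subjects, averaged over time):",
        ]
        for name in ("intercept", "se", "bv", "ri"):
            key = "intercept" if name == "intercept" else name
            vals = np.vstack([self.beta_series[s].coef(key)
                              for s in self.subjects])
            lines.append(f"    beta_{name:<10} {vals.mean():+.4f}")
        return "\n".join(lines)
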