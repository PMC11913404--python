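"""Routine index: a per-cycle measure of how settled reward-seeking has become.

For a cycle ``C`` completed in ``T(C)`` seconds the routine index is
``RI(C) = f(L / T(C))`` with ``L = 60`` s/min, so the untransformed index is
the number of cycles the animal would complete per minute at its current
pace.  The transformation ``f`` normalizes the index's distribution; it is
chosen among linear, logarithmic, reciprocal and square-root candidates by
minimizing a Kolmogorov–Smirnov distance to normality across subjects, and
defaults to the square root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

TRANSFORMATIONS = {
    "linear": lambda x: x,
    "logarithmic": np.log,
    "reciprocal": lambda x: 1.0 / x,
    "square_root": np.sqrt,
}


@dataclass
class RoutineIndexConfig:
    """Configuration of the routine index.

    ``L`` is the number of seconds per minute (a constant, 60);
    ``transformation`` names the normalizing function ``f``.
    """

    L: float = 60.0
    transformation: str = "square_root"

    def __post_init__(self) -> None:
        if self.transformation not in TRANSFORMATIONS:
            raise ValueError(
                f"transformation must be one of {sorted(TRANSFORMATIONS)}")

    @property
    def f(self):
        return TRANSFORMATIONS[self.transformation]


DEFAULT_CONFIG = RoutineIndexConfig()


def routine_index(cycle_duration, cfg: RoutineIndexConfig = DEFAULT_CONFIG):
    """RI = f(L / T(C)).  Accepts a scalar or array of cycle durations (s)."""
    t = np.asarray(cycle_duration, dtype=float)
    if np.any(t <= 0):
        raise ValueError("cycle duration must be positive")
    out = cfg.f(cfg.L / t)
    return float(out) if np.isscalar(cycle_duration) else out


def ks_statistic(sample) -> float:
    """K–S distance between the standardized sample's ECDF and the standard normal.

    The sample is standardized by its own mean and (ddof=1) SD before the
    comparison, so the statistic is invariant to positive affine rescaling;
    it is used only as a relative normality score, never for inference.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    z = (x - x.mean()) / sd
    return float(sps.kstest(z, "norm").statistic)


@dataclass
class TransformationReport:
    """Per-subject K–S statistics across candidate transformations.

    ``ks_table`` is subjects × transformations; ``summary`` holds the group
    mean ± SEM per transformation plus paired-t and Dunnett-style
    max-|t|-adjusted p-values of each alternative against square_root;
    ``selected`` is the transformation with the lowest group-mean K–S.
    """

    ks_table: pd.DataFrame
    summary: pd.DataFrame
    selected: str
    dropped_subjects: list = field(default_factory=list)
    n_resamples: int = 0
    seed: int | None = None

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected,
            "summary": self.summary.reset_index().to_dict(orient="records"),
            "dropped_subjects": list(self.dropped_subjects),
            "n_resamples": self.n_resamples,
            "seed": self.seed,
        }


def _max_t_adjusted_pvalues(diffs: np.ndarray, n_resamples: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Dunnett-style adjustment: sign-flip resampling of the max |t| statistic.

    ``diffs`` is subjects × contrasts (paired differences vs the reference).
    The same subject-level sign flip is applied to every contrast, preserving
    their correlation, and each contrast's adjusted p is the fraction of
    resamples whose max-|t| meets or exceeds its observed |t|.
    """
    n, m = diffs.shape

    def tstats(d):
        mu = d.mean(axis=0)
        se = d.std(axis=0, ddof=1) / np.sqrt(n)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se > 0, mu / se, 0.0)

    t_obs = np.abs(tstats(diffs))
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, n))
    # center under the paired null before flipping; sign flips leave each
    # contrast's sum of squares unchanged, so only means need the matmul
    centered = diffs - diffs.mean(axis=0)
    mean_r = signs @ centered / n                       # (R, m)
    ssq = (centered ** 2).sum(axis=0)                   # (m,)
    var_r = np.maximum((ssq[None, :] - n * mean_r ** 2) / (n - 1), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_r = np.where(var_r > 0, np.abs(mean_r) / np.sqrt(var_r / n), 0.0)
    max_null = t_r.max(axis=1)
    return (1.0 + (max_null[:, None] >= t_obs[None, :]).sum(axis=0)) / (1.0 + n_resamples)


def select_transformation(durations_by_subject: dict,
                          L: float = 60.0,
                          candidates: tuple = ("linear", "logarithmic",
                                               "reciprocal", "square_root"),
                          reference: str = "square_root",
                          n_resamples: int = 10_000,
                          seed: int | None = 0) -> TransformationReport:
    """Score candidate transformations by per-subject K–S normality distance.

    Parameters
    ----------
    durations_by_subject : mapping subject -> array of cycle durations (s)
    L : seconds per minute
    candidates : transformation names to score
    reference : the transformation paired comparisons are made against
    n_resamples : resamples for the max-|t| (Dunnett-style) adjustment
    seed : resampling seed

    Subjects failing the :func:`ks_statistic` preconditions are dropped with
    a warning; at least two must survive.
    """
    rows = {}
    dropped = []
    for subj, durs in durations_by_subject.items():
        durs = np.asarray(durs, dtype=float)
        try:
            rows[subj] = {
                name: ks_statistic(routine_index(
                    durs, RoutineIndexConfig(L=L, transformation=name)))
                for name in candidates
            }
        except ValueError as exc:
            dropped.append(subj)
            warnings.warn(f"subject {subj!r} dropped: {exc}", stacklevel=2)
    if len(rows) < 2:
        raise ValueError("fewer than 2 subjects with valid K-S statistics")
    ks = pd.DataFrame.from_dict(rows, orient="index")[list(candidates)]
    mean = ks.mean(axis=0)
    sem = ks.sem(axis=0)
    selected = str(mean.idxmin())

    alts = [c for c in candidates if c != reference]
    diffs = ks[alts].to_numpy() - ks[[reference]].to_numpy()
    p_paired = np.array([
        sps.ttest_rel(ks[a], ks[reference]).pvalue for a in alts])
    rng = np.random.default_rng(seed)
    p_adj = _max_t_adjusted_pvalues(diffs, n_resamples, rng)
    summary = pd.DataFrame({"mean_ks": mean, "sem_ks": sem})
    summary["p_paired_t"] = pd.Series(dict(zip(alts, p_paired)))
    summary["p_max_t_adjusted"] = pd.Series(dict(zip(alts, p_adj)))
    return TransformationReport(ks_table=ks, summary=summary, selected=selected,
                                dropped_subjects=dropped,
                                n_resamples=n_resamples, seed=seed)
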