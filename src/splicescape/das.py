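"""Differential alternative splicing via a logit-PSI linear mixed model.

For each exercise group G and post-exercise timepoint T, the samples at T are
concatenated with the group's pre-exercise samples and, per event,

    logit(PSI) ~ Timepoint + Batch + BMI + calculatedAge + codedsiteid
                 + pct_umi_dup + RIN + Sex + (1 | pid)

is fit by REML.  The two-sided p value of the Timepoint coefficient is the
event's significance at (G, T); p values are FDR-adjusted within each
group × timepoint.  A non-exercise control arm corrects for circadian /
time-of-day effects: an event is called DAS in an exercise arm only if it is
not significant in the control arm at the same timepoint, or changes in the
opposite direction there.

The logit uses a linear remap away from the boundaries,
p' = a + (1 - 2a)·psi with a = 0.001, so PSI of exactly 0 or 1 stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

DEFAULT_NUMERIC_COVARIATES = ("BMI", "calculatedAge", "pct_umi_dup", "RIN")
DEFAULT_CATEGORICAL_COVARIATES = ("Batch", "codedsiteid", "Sex")


@dataclass
class DasModelSpec:
    """Model definition for per-event differential-splicing fits.

    ``df_mode`` selects the reference distribution for the Timepoint
    coefficient test: 'within' uses a t distribution with containment-style
    within-participant degrees of freedom (see :func:`_within_df`),
    'normal' the large-sample normal approximation.
    """

    numeric_covariates: tuple[str, ...] = DEFAULT_NUMERIC_COVARIATES
    categorical_covariates: tuple[str, ...] = DEFAULT_CATEGORICAL_COVARIATES
    adjust: float = 0.001
    alpha: float = 0.05
    df_mode: str = "within"

    def __post_init__(self):
        if not (0 < self.adjust < 0.5):
            raise ValueError("logit adjustment must lie in (0, 0.5)")
        if self.df_mode not in ("within", "normal"):
            raise ValueError("df_mode must be 'within' or 'normal'")


@dataclass
class FitResult:
    coef: float
    se: float
    p: float
    n_obs: int
    status: str  # 'ok' or 'unfittable'

    @classmethod
    def unfittable(cls, n_obs: int = 0) -> "FitResult":
        return cls(np.nan, np.nan, np.nan, n_obs, "unfittable")


def logit_transform(psi, adjust: float = 0.001):
    """Boundary-adjusted log-odds: log(p'/(1-p')) with p' = a + (1-2a)·psi."""
    psi = np.asarray(psi, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((psi < 0) | (psi > 1)):
            raise ValueError("PSI outside [0, 1]")
    p = adjust + (1.0 - 2.0 * adjust) * psi
    return np.log(p / (1.0 - p))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values; NaNs are excluded from
    the family and returned as NaN."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum() == 0:
        return out
    vals = p[mask]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p values outside [0, 1]")
    out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def _within_df(X: np.ndarray, groups: np.ndarray) -> int:
    """Containment-style degrees of freedom for a within-participant
    coefficient: n_obs − n_participants − (number of design columns that
    vary within participants).  Between-participant covariates do not
    consume within-participant information."""
    order = np.argsort(groups, kind="stable")
    Xs, gs = X[order], groups[order]
    starts = np.flatnonzero(np.r_[True, gs[1:] != gs[:-1]])
    bounds = np.r_[starts, len(gs)]
    p_within = 0
    for j in range(X.shape[1]):
        col = Xs[:, j]
        if any(np.ptp(col[a:b]) > 0 for a, b in zip(bounds[:-1], bounds[1:])):
            p_within += 1
    n_groups = len(starts)
    return max(1, len(gs) - n_groups - p_within)


def build_design(
    samples: pd.DataFrame, timepoint: str, spec: DasModelSpec
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Fixed-effect design for a Pre-vs-timepoint contrast within one arm.

    Categorical covariates observed at a single level are dropped (they are
    collinear with the intercept).  Returns (X, column names, groups).
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(samples))}
    cols["Timepoint"] = (samples["Timepoint"] == timepoint).to_numpy(dtype=float)
    for cov in spec.numeric_covariates:
        cols[cov] = samples[cov].to_numpy(dtype=float)
    for cov in spec.categorical_covariates:
        levels = sorted(samples[cov].astype(str).unique())
        for lev in levels[1:]:  # reference = first level
            cols[f"{cov}[{lev}]"] = (samples[cov].astype(str) == lev).to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols), samples["pid"].to_numpy()


def fit_event(
    psi: pd.Series,
    samples: pd.DataFrame,
    timepoint: str,
    spec: DasModelSpec | None = None,
) -> FitResult:
    """Fit the logit-PSI mixed model for one event within one arm.

    ``psi`` is indexed by sample id; ``samples`` holds the arm's metadata at
    {Pre, timepoint} with one row per sample.  Missing PSI observations are
    dropped pairwise.  Degenerate inputs (fewer than 2 participants observed
    at both timepoints, or zero response variance) yield an unfittable
    result rather than an exception.
    """
    spec = spec or DasModelSpec()
    meta = samples.set_index("sample_id") if "sample_id" in samples.columns else samples
    common = psi.dropna().index.intersection(meta.index)
    y_psi = psi.loc[common]
    meta = meta.loc[common]

    # need ≥2 participants with observations at both timepoints
    tp_per_pid = meta.groupby("pid")["Timepoint"].nunique()
    if (tp_per_pid >= 2).sum() < 2:
        return FitResult.unfittable(len(common))

    y = logit_transform(y_psi.to_numpy(), spec.adjust)
    if np.ptp(y) == 0:
        return FitResult.unfittable(len(common))

    X, names, groups = build_design(meta.reset_index(), timepoint, spec)
    # drop constant non-intercept columns (e.g. single-level numeric covariate)
    keep = [i for i in range(X.shape[1]) if i == 0 or np.ptp(X[:, i]) > 0]
    X = X[:, keep]
    names = [names[i] for i in keep]
    k_tp = names.index("Timepoint") if "Timepoint" in names else None
    if k_tp is None:
        return FitResult.unfittable(len(common))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = MixedLM(y, X, groups=groups)
            res = model.fit(reml=True)
            if not res.converged:
                res = model.fit(reml=True, method="powell")
            if not res.converged:
                return FitResult.unfittable(len(y))
    except (np.linalg.LinAlgError, ValueError):
        return FitResult.unfittable(len(y))

    coef = float(res.params[k_tp])
    se = float(res.bse[k_tp])
    if not np.isfinite(se) or se == 0:
        return FitResult.unfittable(len(y))
    tstat = coef / se
    if spec.df_mode == "normal":
        p = 2.0 * stats.norm.sf(abs(tstat))
    else:
        df = _within_df(X, groups)
        p = 2.0 * stats.t.sf(abs(tstat), df)
    return FitResult(coef, se, float(p), len(y), "ok")


def fit_arm_timepoint(
    psi: pd.DataFrame,
    samples: pd.DataFrame,
    arm: str,
    timepoint: str,
    spec: DasModelSpec | None = None,
    track: str = "junction",
) -> pd.DataFrame:
    """Fit every event of one PSI track for one arm × timepoint.

    Returns a frame indexed by event id with coef / p / FDR / direction /
    status columns; FDR is computed within this arm × timepoint family.
    """
    spec = spec or DasModelSpec()
    sub = samples[
        (samples["arm"] == arm) & (samples["Timepoint"].isin(["Pre", timepoint]))
    ]
    rows = {}
    for eid, row in psi.iterrows():
        fr = fit_event(row, sub, timepoint, spec)
        rows[eid] = (fr.coef, fr.p, fr.n_obs, fr.status)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["coef", "p", "n_obs", "status"]
    )
    out.index.name = "event_id"
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    out["direction"] = np.sign(out["coef"]).fillna(0).astype(int)
    out["arm"] = arm
    out["timepoint"] = timepoint
    out["track"] = track
    return out


def call_das(
    exercise: pd.DataFrame, control: pd.DataFrame | None, alpha: float = 0.05
) -> pd.DataFrame:
    """Apply the control-arm correction and emit verdicts for one exercise
    arm × timepoint (single track).

    DAS iff FDR_exercise < alpha AND (FDR_control ≥ alpha OR the control
    direction differs).  Events untested in control count as non-significant
    there.
    """
    if control is not None and len(control):
        tps = set(control["timepoint"].unique())
        if tps and tps != set(exercise["timepoint"].unique()):
            raise ValueError(f"control timepoints {tps} do not match exercise")
    out = exercise.copy()
    sig_ex = out["fdr"] < alpha
    if control is None or not len(control):
        ctl_blocks = pd.Series(False, index=out.index)
    else:
        ctl = control.reindex(out.index)
        ctl_sig = ctl["fdr"] < alpha
        same_dir = ctl["direction"] == out["direction"]
        ctl_blocks = (ctl_sig & same_dir).fillna(False)
    verdict = np.where(
        out["status"] == "unfittable",
        "unfittable",
        np.where(sig_ex & ~ctl_blocks, "DAS", "not-DAS"),
    )
    out["verdict"] = verdict
    return out


def das_pipeline(
    merged_psi,
    samples: pd.DataFrame,
    exercise_arms: tuple[str, ...] = ("EE", "RE"),
    control_arm: str = "Control",
    timepoints: tuple[str, ...] | None = None,
    spec: DasModelSpec | None = None,
) -> pd.DataFrame:
    """Run the full DAS analysis over every track × arm × timepoint.

    ``merged_psi`` is a :class:`splicescape.psi.MergedPsi`.  Returns a long
    frame, one row per event × arm × timepoint × track, with verdicts.  An
    event with provenance 'both' is DAS if either track calls it.
    """
    spec = spec or DasModelSpec()
    if timepoints is None:
        timepoints = tuple(t for t in samples["Timepoint"].unique() if t != "Pre")
    frames = []
    for track, pm in merged_psi.tracks():
        for tp in timepoints:
            ctl = (
                fit_arm_timepoint(pm.psi, samples, control_arm, tp, spec, track)
                if control_arm in set(samples["arm"])
                else None
            )
            for arm in exercise_arms:
                ex = fit_arm_timepoint(pm.psi, samples, arm, tp, spec, track)
                frames.append(call_das(ex, ctl, spec.alpha).reset_index())
    out = pd.concat(frames, ignore_index=True)
    out["provenance"] = out["event_id"].map(merged_psi.provenance)
    return out


def consolidate_verdicts(das_long: pd.DataFrame) -> pd.DataFrame:
    """Per event × arm × timepoint, combine the track-level verdicts.

    DAS if any track is DAS; the source track(s) of the call are recorded,
    and direction conflicts between significant tracks are flagged rather
    than resolved.
    """
    def _combine(g: pd.DataFrame) -> pd.Series:
        hits = g[g["verdict"] == "DAS"]
        if len(hits):
            dirs = set(hits["direction"])
            return pd.Series(
                {
                    "verdict": "DAS",
                    "source_tracks": ",".join(sorted(hits["track"])),
                    "direction": int(hits["direction"].iloc[0]) if len(dirs) == 1 else 0,
                    "direction_conflict": len(dirs) > 1,
                }
            )
        v = "unfittable" if (g["verdict"] == "unfittable").all() else "not-DAS"
        return pd.Series(
            {"verdict": v, "source_tracks": "", "direction": 0, "direction_conflict": False}
        )

    grouped = das_long.groupby(["event_id", "arm", "timepoint"], sort=True)
    return grouped.apply(_combine, include_groups=False).reset_index()


def differential_omics(
    features: pd.DataFrame,
    samples: pd.DataFrame,
    exercise_arm: str,
    timepoint: str,
    control_arm: str = "Control",
    spec: DasModelSpec | None = None,
) -> pd.DataFrame:
    """Difference-in-changes (delta-delta) contrast per feature.

    Fits, per feature, a cell-means mixed model over arm × timepoint with a
    participant random intercept and the standard covariates, and tests
    (T − Pre in the exercise arm) − (T − Pre in control).  Used for
    differential chromatin accessibility and differential phosphorylation on
    continuous normalized scales.
    """
    spec = spec or DasModelSpec()
    sub = samples[
        samples["arm"].isin([exercise_arm, control_arm])
        & samples["Timepoint"].isin(["Pre", timepoint])
    ].copy()
    meta = sub.set_index("sample_id")
    cells = meta["arm"].astype(str) + ":" + meta["Timepoint"].astype(str)
    cell_levels = sorted(cells.unique())
    required = {
        f"{exercise_arm}:Pre",
        f"{exercise_arm}:{timepoint}",
        f"{control_arm}:Pre",
        f"{control_arm}:{timepoint}",
    }
    if not required.issubset(cell_levels):
        raise ValueError(f"contrast references absent cells: {required - set(cell_levels)}")

    cols = {lev: (cells == lev).to_numpy(dtype=float) for lev in cell_levels}
    names = list(cols)
    for cov in spec.numeric_covariates:
        if cov in meta.columns:
            v = meta[cov].to_numpy(dtype=float)
            if np.ptp(v) > 0:
                cols[cov] = v
                names.append(cov)
    for cov in spec.categorical_covariates:
        if cov in meta.columns:
            levels = sorted(meta[cov].astype(str).unique())
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (meta[cov].astype(str) == lev).to_numpy(dtype=float)
                names.append(f"{cov}[{lev}]")
    X = np.column_stack([cols[n] for n in names])
    groups_all = meta["pid"].to_numpy()

    contrast = np.zeros(X.shape[1])
    contrast[names.index(f"{exercise_arm}:{timepoint}")] = 1.0
    contrast[names.index(f"{exercise_arm}:Pre")] = -1.0
    contrast[names.index(f"{control_arm}:{timepoint}")] = -1.0
    contrast[names.index(f"{control_arm}:Pre")] = 1.0

    rows = {}
    feats = features[meta.index]
    for fid, row in feats.iterrows():
        y = row.to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < X.shape[1] + 2 or np.ptp(y[ok]) == 0:
            rows[fid] = (np.nan, np.nan)
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                res = MixedLM(y[ok], X[ok], groups=groups_all[ok]).fit(reml=True)
            eff = float(contrast @ res.params[: X.shape[1]])
            var = float(contrast @ res.cov_params()[: X.shape[1], : X.shape[1]] @ contrast)
            if var <= 0 or not np.isfinite(var):
                rows[fid] = (np.nan, np.nan)
                continue
            z = eff / np.sqrt(var)
            if spec.df_mode == "normal":
                p = 2.0 * stats.norm.sf(abs(z))
            else:
                p = 2.0 * stats.t.sf(abs(z), _within_df(X[ok], groups_all[ok]))
            rows[fid] = (eff, float(p))
        except (np.linalg.LinAlgError, ValueError):
            rows[fid] = (np.nan, np.nan)

    out = pd.DataFrame.from_dict(rows, orient="index", columns=["effect", "p"])
    out.index.name = "feature_id"
    out["fdr"] = benjamini_hochberg(out["p"].to_numpy())
    out["arm"] = exercise_arm
    out["timepoint"] = timepoint
    return out


def summarize_multilevel(
    gene_list,
    deg_genes,
    das_genes,
    phospho_genes,
) -> dict[str, int]:
    """Count, over a gene list (e.g. spliceosome components), how many genes
    are regulated at each level — expression, splicing, phosphorylation —
    and at any level."""
    genes = set(gene_list)
    deg = genes & set(deg_genes)
    das = genes & set(das_genes)
    pho = genes & set(phospho_genes)
    return {
        "n_genes": len(genes),
        "DEG": len(deg),
        "DAS": len(das),
        "phospho": len(pho),
        "any": len(deg | das | pho),
    }
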