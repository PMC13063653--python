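"""Rater-reliability estimation: "true" landmark positions, intra-/inter-
rater variability of landmarks and of the derived deviation parameters,
and the CI-width sample-size formula.

The "true" position of a landmark on one subject is the fixed intercept
of a per-axis random-intercept model fitted to the 12 (raters x repeats)
placements,

    y_ij = mu + u_i + e_ij,   u_i ~ N(0, sigma_rater^2),  e_ij ~ N(0, sigma^2),

estimated by restricted maximum likelihood.  For a balanced complete
design the intercept equals the grand mean and the REML variance
components equal the one-way ANOVA estimators truncated at zero; the
general (unbalanced) case is handled by profiling the REML likelihood
over the variance ratio gamma = sigma_rater^2 / sigma^2.

Variability statistics follow a two-stage scheme: a sample SD per cell
(per rater x subject over repeats for intra-rater; per repeat x subject
over raters for inter-rater), then an intercept-only linear model over
all cells — i.e. the mean cell SD with a normal-theory 95% CI.  3D
variability is the Euclidean combination of the three per-axis SDs,
computed per cell before combining.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from dentasym.geometry import PROFILE_PARAMETERS, compute_profile
from dentasym.frame import frame_from_landmarks, to_frame
from dentasym.io import Point3, RatingRecord

__all__ = [
    "TruePositionEstimate",
    "VariabilityEstimate",
    "SampleSizeSpec",
    "fit_random_intercept",
    "estimate_true_positions",
    "true_position_records",
    "intra_rater_sds",
    "inter_rater_sds",
    "combine_sds",
    "magnitude_3d",
    "landmark_variability",
    "parameter_variability",
    "profiles_table",
    "required_sample_size",
]

AXES = ("x", "y", "z")


@dataclass(frozen=True)
class TruePositionEstimate:
    """REML fixed-intercept position of one landmark on one subject."""

    subject_id: str
    landmark: str
    position: Point3
    ci95: tuple[float, float, float]  # per-axis half-widths, mm
    rater_variance: tuple[float, float, float]  # mm^2 per axis
    residual_variance: tuple[float, float, float]  # mm^2 per axis


@dataclass(frozen=True)
class VariabilityEstimate:
    """Combined cell-SD estimate for one target x mode x axis."""

    target: str
    mode: str  # "intra" | "inter"
    axis: str  # "x" | "y" | "z" | "3D" | "scalar"
    mean_sd: float
    ci95_half_width: float
    n_cells: int


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to the CI-width sample-size formula."""

    sigma2: float  # variance, mm^2
    w: float  # target CI width, mm
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.w <= 0:
            raise ValueError("w must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class RandomInterceptFit:
    intercept: float
    intercept_se: float
    group_variance: float
    residual_variance: float


def _reml_profile_neg2ll(gamma: float, groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Profiled REML -2 log-likelihood at variance ratio *gamma*.

    Returns (-2ll up to a constant, profiled sigma^2, GLS intercept).
    """
    n_tot = sum(len(g) for g in groups)
    w = np.array([len(g) / (1.0 + gamma * len(g)) for g in groups])
    means = np.array([g.mean() for g in groups])
    mu = float(w @ means / w.sum())
    within = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    between = float(w @ (means - mu) ** 2)
    q = within + between
    sigma2 = q / (n_tot - 1)
    neg2ll = (
        (n_tot - 1) * (math.log(max(sigma2, 1e-300)) + 1.0)
        + sum(math.log1p(gamma * len(g)) for g in groups)
        + math.log(w.sum())
    )
    return neg2ll, sigma2, mu


def fit_random_intercept(groups: Iterable[Sequence[float]]) -> RandomInterceptFit:
    """REML fit of an intercept + random-group-intercept model.

    *groups* is one sequence of observations per grouping level (rater).
    Balanced designs use the closed-form ANOVA solution; unbalanced ones
    profile the likelihood over the variance ratio.  Variance estimates
    are truncated at zero.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    sizes = {len(g) for g in gs}
    n_tot = sum(len(g) for g in gs)
    r = len(gs)

    if len(sizes) == 1:
        k = sizes.pop()
        grand = float(np.concatenate(gs).mean())
        msb = k * sum((g.mean() - grand) ** 2 for g in gs) / (r - 1)
        msw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs) / (r * (k - 1))
        if msb >= msw:
            sigma2 = msw
            sigma2_u = (msb - msw) / k
            var_mu = msb / (r * k)
        else:  # boundary: gamma = 0
            sigma2 = sum(float(((g - grand) ** 2).sum()) for g in gs) / (n_tot - 1)
            sigma2_u = 0.0
            var_mu = sigma2 / (r * k)
        return RandomInterceptFit(grand, math.sqrt(var_mu), sigma2_u, sigma2)

    # Unbalanced: profile REML over log-gamma (plus the gamma=0 boundary).
    def objective(log_gamma: float) -> float:
        return _reml_profile_neg2ll(math.exp(log_gamma), gs)[0]

    res = minimize_scalar(objective, bounds=(-25.0, 25.0), method="bounded",
                          options={"xatol": 1e-12})
    best_gamma = math.exp(res.x)
    if _reml_profile_neg2ll(0.0, gs)[0] <= res.fun:
        best_gamma = 0.0
    _, sigma2, mu = _reml_profile_neg2ll(best_gamma, gs)
    w_sum = sum(len(g) / (1.0 + best_gamma * len(g)) for g in gs)
    return RandomInterceptFit(mu, math.sqrt(sigma2 / w_sum), best_gamma * sigma2, sigma2)


def estimate_true_positions(
    ratings: Sequence[RatingRecord],
) -> list[TruePositionEstimate]:
    """Per subject x landmark, estimate the true position and its 95% CI.

    Requires >= 2 raters and >= 2 repeats per rater for every
    subject x landmark cell; offending cells are reported together.
    """
    z = norm.ppf(0.975)
    by_subject: dict[str, list[RatingRecord]] = {}
    for rec in ratings:
        by_subject.setdefault(rec.subject_id, []).append(rec)

    offenders: list[str] = []
    estimates: list[TruePositionEstimate] = []
    for subject in sorted(by_subject):
        recs = by_subject[subject]
        names = sorted(set().union(*(set(r.landmarks) for r in recs)))
        for name in names:
            per_rater: dict[str, list[np.ndarray]] = {}
            for rec in recs:
                if name in rec.landmarks:
                    per_rater.setdefault(rec.rater_id, []).append(
                        rec.landmarks[name].as_array()
                    )
            if len(per_rater) < 2 or any(len(v) < 2 for v in per_rater.values()):
                offenders.append(f"{subject}/{name}")
                continue
            pos, ci, var_u, var_e = [], [], [], []
            for axis in range(3):
                groups = [
                    [obs[axis] for obs in obs_list] for obs_list in per_rater.values()
                ]
                fit = fit_random_intercept(groups)
                pos.append(fit.intercept)
                ci.append(z * fit.intercept_se)
                var_u.append(fit.group_variance)
                var_e.append(fit.residual_variance)
            estimates.append(
                TruePositionEstimate(
                    subject_id=subject,
                    landmark=name,
                    position=Point3(*pos),
                    ci95=tuple(ci),
                    rater_variance=tuple(var_u),
                    residual_variance=tuple(var_e),
                )
            )
    if offenders:
        raise ValueError(
            "insufficient replication (need >=2 raters x >=2 repeats) for: "
            + ", ".join(offenders)
        )
    return estimates


def true_position_records(
    estimates: Sequence[TruePositionEstimate], group: str = "unassigned"
) -> list[RatingRecord]:
    """Assemble one noise-free RatingRecord per subject from true positions."""
    by_subject: dict[str, dict[str, Point3]] = {}
    for est in estimates:
        by_subject.setdefault(est.subject_id, {})[est.landmark] = est.position
    return [
        RatingRecord(subject, "model", 1, group, landmarks)
        for subject, landmarks in sorted(by_subject.items())
    ]


def _cell_sds(df: pd.DataFrame, cell_cols: list[str], value_col: str) -> pd.Series:
    counts = df.groupby(cell_cols, sort=True)[value_col].count()
    skipped = int((counts < 2).sum())
    if skipped:
        warnings.warn(f"skipped {skipped} cell(s) with < 2 replicates", stacklevel=3)
    sds = df.groupby(cell_cols, sort=True)[value_col].std(ddof=1)
    return sds[counts >= 2]


def intra_rater_sds(df: pd.DataFrame, value_col: str = "value") -> pd.Series:
    """Sample SD of *value_col* per (subject, rater) cell, over repeats."""
    return _cell_sds(df, ["subject", "rater"], value_col)


def inter_rater_sds(df: pd.DataFrame, value_col: str = "value") -> pd.Series:
    """Sample SD of *value_col* per (subject, repeat) cell, over raters."""
    return _cell_sds(df, ["subject", "repeat"], value_col)


def combine_sds(
    cell_sds: Sequence[float],
    target: str = "",
    mode: str = "intra",
    axis: str = "scalar",
) -> VariabilityEstimate:
    """Intercept-only linear model over cell SDs: mean with normal 95% CI."""
    sds = np.asarray(cell_sds, dtype=float)
    if sds.size < 2:
        raise ValueError("combine_sds needs >= 2 cell SDs")
    mean = float(sds.mean())
    half = float(norm.ppf(0.975) * sds.std(ddof=1) / math.sqrt(sds.size))
    return VariabilityEstimate(target, mode, axis, mean, half, int(sds.size))


def magnitude_3d(sdx: float, sdy: float, sdz: float) -> float:
    """Euclidean 3D combination sqrt(x^2 + y^2 + z^2) of per-axis SDs."""
    if sdx < 0 or sdy < 0 or sdz < 0:
        raise ValueError("SDs must be >= 0")
    return math.hypot(sdx, sdy, sdz)


def _common_frame_coordinates(
    ratings: Sequence[RatingRecord],
    estimates: Sequence[TruePositionEstimate] | None = None,
) -> pd.DataFrame:
    """Long table of all landmark placements in each subject's common frame.

    The common frame per subject is built from the estimated true
    positions, so per-axis SDs are comparable across subjects (x is
    always transverse, etc.).
    """
    if estimates is None:
        estimates = estimate_true_positions(ratings)
    frames = {
        rec.subject_id: frame_from_landmarks(rec)
        for rec in true_position_records(estimates)
    }
    rows = []
    for rec in ratings:
        frame = frames[rec.subject_id]
        for name, p in rec.landmarks.items():
            local = to_frame(p, frame)
            rows.append(
                {
                    "subject": rec.subject_id,
                    "rater": rec.rater_id,
                    "repeat": rec.repeat_index,
                    "landmark": name,
                    "x": local.x,
                    "y": local.y,
                    "z": local.z,
                }
            )
    return pd.DataFrame(rows)


def landmark_variability(
    ratings: Sequence[RatingRecord],
    estimates: Sequence[TruePositionEstimate] | None = None,
) -> list[VariabilityEstimate]:
    """Intra- and inter-rater variability per landmark and axis (and 3D).

    Placements are expressed in each subject's common frame, per-cell
    SDs are formed under both cell schemes, the 3D SD is computed per
    cell from the three per-axis SDs, and cells are combined across all
    subjects into a mean SD with 95% CI.
    """
    table = _common_frame_coordinates(ratings, estimates)
    out: list[VariabilityEstimate] = []
    for mode, cell_cols in (("intra", ["subject", "rater"]), ("inter", ["subject", "repeat"])):
        for landmark, sub in table.groupby("landmark", sort=True):
            per_axis = {
                axis: _cell_sds(sub, cell_cols, axis) for axis in AXES
            }
            for axis in AXES:
                out.append(combine_sds(per_axis[axis].to_numpy(), landmark, mode, axis))
            aligned = pd.concat(per_axis, axis=1).dropna()
            sd3 = np.sqrt((aligned**2).sum(axis=1)).to_numpy()
            out.append(combine_sds(sd3, landmark, mode, "3D"))
    return out


def profiles_table(ratings: Sequence[RatingRecord]) -> pd.DataFrame:
    """Deviation profile of every rating, one row per (subject, rater, repeat)."""
    rows = []
    for rec in ratings:
        row = {
            "subject": rec.subject_id,
            "rater": rec.rater_id,
            "repeat": rec.repeat_index,
            "group": rec.group,
        }
        row.update(compute_profile(rec).as_dict())
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["subject", "rater", "repeat"]).reset_index(drop=True)


def parameter_variability(
    ratings: Sequence[RatingRecord],
    profiles: pd.DataFrame | None = None,
) -> list[VariabilityEstimate]:
    """Intra- and inter-rater variability of the seven deviation parameters.

    Each rating's profile is computed in its own frame (origin at its own
    LS); per-cell SDs are then combined across all subjects.
    """
    if profiles is None:
        profiles = profiles_table(ratings)
    out: list[VariabilityEstimate] = []
    for mode, fn in (("intra", intra_rater_sds), ("inter", inter_rater_sds)):
        for param in PROFILE_PARAMETERS:
            sds = fn(profiles, value_col=param)
            out.append(combine_sds(sds.to_numpy(), param, mode, "scalar"))
    return out


def required_sample_size(spec: SampleSizeSpec) -> int:
    """Observations needed so a 1-alpha CI for a normal mean has width <= w.

    N = ceil(4 z_{1-alpha/2}^2 sigma^2 / w^2), at least 1.
    """
    z = norm.ppf(1.0 - spec.alpha / 2.0)
    n = 4.0 * z * z * spec.sigma2 / (spec.w * spec.w)
    return max(1, math.ceil(n - 1e-9))
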