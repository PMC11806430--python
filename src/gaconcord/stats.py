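"""Reflectivity-by-scotoma-class statistics and repeated-measures comparisons.

Two analyses sit on top of the concordance pipeline:

* per-locus choroidal reflectivity versus scotoma class (absolute / relative /
  non-scotomatous), fitted as a cell-means linear mixed model with an
  eye-level random intercept and a structured residual covariance over
  repeated visits — AR(1), heterogeneous AR(1) (ARH(1)), or heterogeneous
  compound symmetry (CSH), selected by the lowest REML AIC when not fixed;
* the paired modality comparison of per-line Dice coefficients (OCT-defined
  versus FAF-defined atrophy), an intercept-only model on the per-line
  differences with the same random-effect layout.

The fitter is a compact block-diagonal REML implementation (one block per
eye): the marginal covariance of eye *i* is ``sigma_b^2 J + R_i`` with
``R_i`` block-diagonal over repeated-measures series (eye x locus, or
eye x axis), and the restricted log-likelihood is maximised over transformed
covariance parameters with L-BFGS-B.  Fixed effects and their covariance then
come from generalised least squares at the fitted covariance; the global test
of group equality is a Wald F with residual denominator degrees of freedom,
followed (when significant) by pairwise two-sided t-tests at 0.05.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .microperimetry import LocusClass
from .oct import ReflectanceProfile

__all__ = [
    "CovarianceStructure",
    "GroupEstimate",
    "PairwiseDifference",
    "ModelFit",
    "locus_reflectivity",
    "fit_grouped_repeated",
    "compare_modalities",
    "reflectivity_histogram",
    "simulate_locus_observations",
]

CovarianceStructure = Literal["AR1", "ARH1", "CSH"]
_STRUCTURES: tuple[str, ...] = ("AR1", "ARH1", "CSH")


# ---------------------------------------------------------------------------
# Per-locus reflectivity extraction
# ---------------------------------------------------------------------------


def locus_reflectivity(
    profile: ReflectanceProfile,
    position_um: float,
    footprint_um: float = 125.0,
) -> float:
    """Mean slab reflectivity (0-255) at a locus position.

    Averages the profile over columns within half a footprint of the locus
    centre; the default footprint is one Goldmann III stimulus diameter
    (125 um).  A zero footprint degenerates to the nearest column.  A locus
    whose centre falls within half a footprint beyond the outermost column
    (the stimulus still overlaps imaged retina) is averaged over the covered
    columns; anything further out is an error.
    """
    pos = profile.positions_um
    slack = footprint_um / 2.0
    if not pos[0] - slack <= position_um <= pos[-1] + slack:
        raise ValueError(
            f"locus position {position_um} um outside profile domain "
            f"[{pos[0]}, {pos[-1]}] um"
        )
    if footprint_um < 0:
        raise ValueError("footprint must be non-negative")
    mask = np.abs(pos - position_um) <= footprint_um / 2.0
    if not mask.any():
        idx = int(np.argmin(np.abs(pos - position_um)))
        return float(profile.mean_raw[idx])
    return float(profile.mean_raw[mask].mean())


# ---------------------------------------------------------------------------
# REML fitter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairwiseDifference:
    group_a: str
    group_b: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class ModelFit:
    """Fitted repeated-measures model: group means, tests, covariance choice."""

    group_means: dict[str, GroupEstimate]
    pairwise_differences: tuple[PairwiseDifference, ...]
    global_f: float | None
    global_df: tuple[float, float] | None
    global_p: float | None
    covariance_structure: str
    fit_criterion: float
    n_obs: int
    converged: bool
    candidate_criteria: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "group_means": {
                g: {"estimate": e.estimate, "se": e.se, "ci": [e.ci_low, e.ci_high]}
                for g, e in self.group_means.items()
            },
            "pairwise_differences": [
                {
                    "groups": [d.group_a, d.group_b],
                    "estimate": d.estimate,
                    "se": d.se,
                    "ci": [d.ci_low, d.ci_high],
                    "p_value": d.p_value,
                }
                for d in self.pairwise_differences
            ],
            "global_test": None
            if self.global_f is None
            else {
                "F": self.global_f,
                "df": list(self.global_df),
                "p_value": self.global_p,
            },
            "covariance_structure": self.covariance_structure,
            "fit_criterion_aic": self.fit_criterion,
            "candidate_criteria": self.candidate_criteria,
            "n_obs": self.n_obs,
            "converged": self.converged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


class _RemlProblem:
    """Block-diagonal (per-eye) REML problem with a structured residual."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        eye: np.ndarray,
        series: np.ndarray,
        time: np.ndarray,
        structure: str,
    ) -> None:
        self.structure = structure
        self.n, self.p = X.shape
        self.times = np.unique(time)
        self.n_times = len(self.times)
        t_idx = np.searchsorted(self.times, time)

        self.blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for e in np.unique(eye):
            m = eye == e
            self.blocks.append((y[m], X[m], series[m], t_idx[m]))

    @property
    def n_cov_params(self) -> int:
        if self.structure == "AR1":
            return 3
        return 2 + self.n_times  # log sigma_b, z_rho, log sigma_t per time

    def start(self, y: np.ndarray) -> np.ndarray:
        s = max(np.std(y), 1e-3)
        if self.structure == "AR1":
            return np.array([math.log(s / 2), math.log(s), 0.2])
        return np.concatenate(
            [[math.log(s / 2), 0.2], np.full(self.n_times, math.log(s))]
        )

    def _residual_block(self, theta: np.ndarray, s_codes: np.ndarray, t_codes: np.ndarray) -> np.ndarray:
        rho = math.tanh(theta[1]) if self.structure != "AR1" else math.tanh(theta[2])
        m = len(s_codes)
        same_series = s_codes[:, None] == s_codes[None, :]
        if self.structure == "AR1":
            sig = math.exp(theta[1])
            lag = np.abs(t_codes[:, None] - t_codes[None, :])
            R = sig**2 * rho**lag
        else:
            sig_t = np.exp(theta[2:])[t_codes]
            outer = sig_t[:, None] * sig_t[None, :]
            if self.structure == "ARH1":
                lag = np.abs(t_codes[:, None] - t_codes[None, :])
                R = outer * rho**lag
            else:  # CSH
                R = outer * rho
                np.fill_diagonal(R, sig_t**2)
        return np.where(same_series, R, 0.0)

    def _block_cov(self, theta: np.ndarray, s_codes: np.ndarray, t_codes: np.ndarray) -> np.ndarray:
        sigma_b2 = math.exp(theta[0]) ** 2
        V = self._residual_block(theta, s_codes, t_codes)
        return V + sigma_b2

    def neg2_reml(self, theta: np.ndarray) -> float:
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        ytVy = 0.0
        logdet = 0.0
        for y_i, X_i, s_i, t_i in self.blocks:
            V = self._block_cov(theta, s_i, t_i)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return 1e12
            logdet += 2.0 * np.log(np.diag(L)).sum()
            Xs = np.linalg.solve(L, X_i)
            ys = np.linalg.solve(L, y_i)
            XtVX += Xs.T @ Xs
            XtVy += Xs.T @ ys
            ytVy += ys @ ys
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - XtVy @ beta
        return (
            logdet
            + logdet_XtVX
            + quad
            + (self.n - self.p) * math.log(2 * math.pi)
        )

    def fit(self) -> tuple[np.ndarray, float, bool]:
        y_all = np.concatenate([b[0] for b in self.blocks])
        res = optimize.minimize(
            self.neg2_reml,
            self.start(y_all),
            method="L-BFGS-B",
            options={"maxiter": 200},
        )
        return res.x, float(res.fun), bool(res.success)

    def gls(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fixed effects and their covariance at the fitted covariance parameters."""
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        for y_i, X_i, s_i, t_i in self.blocks:
            V = self._block_cov(theta, s_i, t_i)
            L = np.linalg.cholesky(V)
            Xs = np.linalg.solve(L, X_i)
            ys = np.linalg.solve(L, y_i)
            XtVX += Xs.T @ Xs
            XtVy += Xs.T @ ys
        cov = np.linalg.inv(XtVX)
        beta = cov @ XtVy
        return beta, cov


def _fit_one_structure(
    y: np.ndarray,
    X: np.ndarray,
    eye: np.ndarray,
    series: np.ndarray,
    time: np.ndarray,
    structure: str,
) -> tuple[_RemlProblem, np.ndarray, float, bool]:
    prob = _RemlProblem(y, X, eye, series, time, structure)
    theta, neg2ll, ok = prob.fit()
    aic = neg2ll + 2 * prob.n_cov_params
    return prob, theta, aic, ok


def fit_grouped_repeated(
    observations: pd.DataFrame,
    covariance: CovarianceStructure | Literal["auto"] = "auto",
    value_col: str = "reflectivity",
    group_col: str = "locus_class",
    eye_col: str = "eye_id",
    series_cols: Sequence[str] = ("eye_id", "locus_id"),
    time_col: str = "visit",
    alpha: float = 0.05,
) -> ModelFit:
    """REML fit of per-group means with eye random effects and structured residuals.

    ``observations`` is a long-format table with one row per measurement.
    Group means use cell-means coding, so the fixed effects *are* the per-group
    estimates.  With ``covariance="auto"`` all three structures (AR(1),
    ARH(1), CSH) are fitted and the lowest-AIC one retained, mirroring the
    usual covariance-selection procedure for repeated measures.  The global
    Wald F-test of group equality gates the pairwise comparisons.
    """
    df = observations.dropna(subset=[value_col]).copy()
    groups = sorted(df[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if df[eye_col].nunique() < 2:
        warnings.warn(
            "single-eye data: the eye-level random effect is not identifiable; "
            "estimates degrade to a within-eye analysis",
            stacklevel=2,
        )

    y = df[value_col].to_numpy(dtype=float)
    X = np.column_stack(
        [(df[group_col].astype(str) == g).to_numpy(dtype=float) for g in groups]
    )
    eye = df[eye_col].astype(str).to_numpy()
    series = (
        df[list(series_cols)].astype(str).agg("|".join, axis=1).to_numpy()
    )
    time = df[time_col].to_numpy()

    candidates = _STRUCTURES if covariance == "auto" else (covariance,)
    fits = {}
    for s in candidates:
        try:
            fits[s] = _fit_one_structure(y, X, eye, series, time, s)
        except Exception as exc:  # singular or otherwise degenerate
            warnings.warn(f"covariance structure {s} failed to fit: {exc}", stacklevel=2)
    if not fits:
        raise RuntimeError(
            "no covariance structure could be fitted; try a simpler structure"
        )
    criteria = {s: aic for s, (_, _, aic, _) in fits.items()}
    best = min(criteria, key=criteria.get)
    prob, theta, aic, ok = fits[best]

    beta, cov = prob.gls(theta)
    se = np.sqrt(np.diag(cov))
    ddf = prob.n - prob.p
    tcrit = sps.t.ppf(1 - alpha / 2, ddf)

    group_means = {
        g: GroupEstimate(
            estimate=float(beta[i]),
            se=float(se[i]),
            ci_low=float(beta[i] - tcrit * se[i]),
            ci_high=float(beta[i] + tcrit * se[i]),
        )
        for i, g in enumerate(groups)
    }

    # global Wald F for equality of all group means
    p = len(groups)
    C = np.zeros((p - 1, p))
    C[:, 0] = 1.0
    for i in range(p - 1):
        C[i, i + 1] = -1.0
    cb = C @ beta
    cvc = C @ cov @ C.T
    F = float(cb @ np.linalg.solve(cvc, cb) / (p - 1))
    global_p = float(sps.f.sf(F, p - 1, ddf))

    pairwise: list[PairwiseDifference] = []
    if global_p < alpha:
        for i in range(p):
            for j in range(i + 1, p):
                d = beta[i] - beta[j]
                sd = math.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j])
                t = d / sd
                pairwise.append(
                    PairwiseDifference(
                        group_a=groups[i],
                        group_b=groups[j],
                        estimate=float(d),
                        se=float(sd),
                        ci_low=float(d - tcrit * sd),
                        ci_high=float(d + tcrit * sd),
                        p_value=float(2 * sps.t.sf(abs(t), ddf)),
                    )
                )

    return ModelFit(
        group_means=group_means,
        pairwise_differences=tuple(pairwise),
        global_f=F,
        global_df=(float(p - 1), float(ddf)),
        global_p=global_p,
        covariance_structure=best,
        fit_criterion=float(criteria[best]),
        n_obs=prob.n,
        converged=ok,
        candidate_criteria={k: float(v) for k, v in criteria.items()},
    )


def compare_modalities(
    paired: pd.DataFrame,
    covariance: CovarianceStructure = "AR1",
    oct_col: str = "dsc_oct",
    faf_col: str = "dsc_faf",
    eye_col: str = "eye_id",
    axis_col: str = "axis",
    time_col: str = "visit",
    alpha: float = 0.05,
) -> ModelFit:
    """Estimated mean paired DSC difference (OCT - FAF) under repeated measures.

    Each row is one line scan with both modality DSCs defined; the per-line
    differences are fitted with an intercept-only model, an eye random
    intercept, and AR(1) residuals over visits within each eye x axis series
    (the structure with the best fit for this comparison).
    """
    df = paired.dropna(subset=[oct_col, faf_col]).copy()
    if df.empty:
        raise ValueError("no paired OCT/FAF records with defined DSC")
    if df[eye_col].nunique() < 2:
        warnings.warn(
            "single-eye data: the eye-level random effect is not identifiable; "
            "the comparison degrades to a within-eye analysis",
            stacklevel=2,
        )

    y = (df[oct_col] - df[faf_col]).to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    eye = df[eye_col].astype(str).to_numpy()
    series = (df[eye_col].astype(str) + "|" + df[axis_col].astype(str)).to_numpy()
    time = df[time_col].to_numpy()

    prob, theta, aic, ok = _fit_one_structure(y, X, eye, series, time, covariance)
    beta, cov = prob.gls(theta)
    se = math.sqrt(cov[0, 0])
    ddf = prob.n - 1
    tcrit = sps.t.ppf(1 - alpha / 2, ddf)
    t = beta[0] / se
    p_value = float(2 * sps.t.sf(abs(t), ddf))

    diff = PairwiseDifference(
        group_a="OCT",
        group_b="FAF",
        estimate=float(beta[0]),
        se=float(se),
        ci_low=float(beta[0] - tcrit * se),
        ci_high=float(beta[0] + tcrit * se),
        p_value=p_value,
    )
    return ModelFit(
        group_means={
            "difference": GroupEstimate(
                estimate=diff.estimate, se=diff.se, ci_low=diff.ci_low, ci_high=diff.ci_high
            )
        },
        pairwise_differences=(diff,),
        global_f=float(t**2),
        global_df=(1.0, float(ddf)),
        global_p=p_value,
        covariance_structure=covariance,
        fit_criterion=float(aic),
        n_obs=prob.n,
        converged=ok,
    )


# ---------------------------------------------------------------------------
# Histogram and synthetic observations
# ---------------------------------------------------------------------------


def reflectivity_histogram(
    observations: pd.DataFrame,
    bins: np.ndarray | int = 26,
    value_col: str = "reflectivity",
    group_col: str = "locus_class",
    csv_path=None,
    plot_path=None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-class normalised reflectivity histograms over shared bins.

    Returns ``{class: (bin_edges, density)}``; classes with no observations
    are omitted with a warning.  Optionally writes the densities as CSV and a
    line plot of scotoma likelihood versus slab reflectance.
    """
    values = observations[value_col].to_numpy(dtype=float)
    if np.isscalar(bins) or isinstance(bins, int):
        edges = np.histogram_bin_edges(values, bins=bins, range=(0.0, 255.0))
    else:
        edges = np.asarray(bins, dtype=float)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cls in (c.value for c in LocusClass):
        sel = observations[group_col].astype(str) == cls
        if not sel.any():
            warnings.warn(f"no observations in class {cls!r}; omitted", stacklevel=2)
            continue
        dens, _ = np.histogram(values[sel], bins=edges, density=True)
        out[cls] = (edges, dens)
    if csv_path is not None:
        table = {"bin_left": edges[:-1], "bin_right": edges[1:]}
        table.update({cls: dens for cls, (_, dens) in out.items()})
        pd.DataFrame(table).to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        centers = (edges[:-1] + edges[1:]) / 2.0
        for cls, (_, dens) in out.items():
            ax.plot(centers, dens, label=cls)
        ax.set_xlabel("mean choroidal slab reflectance (grayscale)")
        ax.set_ylabel("density")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return out


def simulate_locus_observations(
    class_means: Sequence[float] = (128.0, 113.0, 104.0),
    n_eyes: int = 24,
    n_visits: int = 5,
    n_loci_per_class: int = 4,
    eye_sd: float = 10.0,
    resid_sd: float = 20.0,
    rho: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic long-format locus observations for parameter-recovery studies.

    Class means default to the absolute / relative / non-scotomatous ordering
    on the 0-255 grayscale scale; each eye contributes a random intercept
    (``eye_sd``) and each eye x locus series an AR(1) residual process over
    visits (marginal SD ``resid_sd``, lag-one correlation ``rho``).
    """
    rng = np.random.default_rng(seed)
    classes = [c.value for c in LocusClass]
    if len(class_means) != len(classes):
        raise ValueError("one mean per locus class required")
    rows = []
    for e in range(n_eyes):
        b_e = rng.normal(0.0, eye_sd)
        locus_id = 0
        for cls, mu in zip(classes, class_means):
            for _ in range(n_loci_per_class):
                eps = np.empty(n_visits)
                eps[0] = rng.normal(0.0, resid_sd)
                for t in range(1, n_visits):
                    eps[t] = rho * eps[t - 1] + rng.normal(
                        0.0, resid_sd * math.sqrt(1 - rho**2)
                    )
                for t in range(n_visits):
                    rows.append(
                        {
                            "eye_id": f"eye{e:02d}",
                            "visit": t,
                            "locus_id": locus_id,
                            "locus_class": cls,
                            "reflectivity": mu + b_e + eps[t],
                        }
                    )
                locus_id += 1
    return pd.DataFrame(rows)
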