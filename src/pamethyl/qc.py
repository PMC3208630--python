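"""Beta-value computation, detection filtering, and technical screening.

Methylation at each interrogated CpG is summarized as the beta value,
the methylated fraction of total locus intensity M/(M+U), ranging from 0
(fully unmethylated) to 1 (fully methylated).  Probes are filtered on
detection p-values (signal above background), samples are screened for
outliers with PCA on the beta matrix, and the top principal components
are regressed against technical covariates to look for confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import BetaMatrix

__all__ = [
    "QcReport",
    "compute_beta",
    "detection_filter",
    "pca_screen",
    "outlier_flag",
    "covariate_screen",
]


@dataclass
class QcReport:
    probes_tested: int
    probes_passed: int
    sample_flags: dict[str, bool] = field(default_factory=dict)
    pc_table: pd.DataFrame | None = None
    covariate_pvalues: pd.DataFrame | None = None

    @property
    def pass_rate(self) -> float:
        return self.probes_passed / self.probes_tested if self.probes_tested else 0.0


def compute_beta(
    m: np.ndarray, u: np.ndarray, offset: float = 0.0
) -> np.ndarray:
    """Beta = M / (M + U + offset), elementwise.

    Negative background-corrected intensities are clamped to zero before
    the ratio so beta stays in [0, 1].  A zero denominator yields NaN
    (missing), not an error.  ``offset`` defaults to 0 (the plain ratio);
    a stabilizing constant in the denominator can be supplied for
    low-intensity data.
    """
    m = np.clip(np.asarray(m, dtype=float), 0.0, None)
    u = np.clip(np.asarray(u, dtype=float), 0.0, None)
    denom = m + u + offset
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(denom > 0, m / np.where(denom > 0, denom, 1.0), np.nan)
    return beta


def detection_filter(
    detection_p: np.ndarray,
    p_threshold: float = 0.01,
    min_sample_fraction: float = 1.0,
) -> tuple[np.ndarray, QcReport]:
    """Keep probes detected above background in enough samples.

    A probe passes iff its detection p-value is strictly below
    ``p_threshold`` in at least ``min_sample_fraction`` of samples.
    ``detection_p`` is samples x probes.  Returns the per-probe pass mask
    and a report with the counts.
    """
    detection_p = np.asarray(detection_p, dtype=float)
    if detection_p.size == 0:
        raise ValueError("empty detection p-value matrix")
    detected = detection_p < p_threshold
    frac = detected.mean(axis=0)
    mask = frac >= min_sample_fraction
    report = QcReport(probes_tested=mask.size, probes_passed=int(mask.sum()))
    return mask, report


def _impute_probe_mean(values: np.ndarray) -> np.ndarray:
    """Replace NaNs with the per-probe (column) mean; all-NaN columns -> 0.5."""
    out = np.array(values, dtype=float, copy=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(out, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.5)
    nan_r, nan_c = np.nonzero(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out


def pca_screen(
    beta: BetaMatrix, n_components: int = 5
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of samples in probe space.

    Missing entries are imputed by the probe mean, probes are centered,
    and the components are taken from the SVD of the centered matrix.
    Scores are the sample projections (U * singular values); eigenvalues
    are the PC variances (s^2 / (n - 1)), non-increasing.  If fewer than
    ``n_components`` components exist (at most n_samples - 1 after
    centering), the result is truncated with a warning.
    """
    if beta.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = _impute_probe_mean(beta.values)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    max_rank = beta.n_samples - 1
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components but only {max_rank} exist; truncating",
            stacklevel=2,
        )
        n_components = max_rank
    r = min(n_components, len(s))
    scores = u[:, :r] * s[:r]
    eigenvalues = s[:r] ** 2 / (beta.n_samples - 1)
    score_df = pd.DataFrame(
        scores, index=beta.sample_ids, columns=[f"PC{i+1}" for i in range(r)]
    )
    return score_df, eigenvalues


def outlier_flag(pc_scores: pd.DataFrame, z_threshold: float = 3.0) -> pd.Series:
    """Flag samples beyond ``z_threshold`` standard deviations on any PC.

    Zero-variance components are skipped.  Needs at least 3 samples for
    the SD to be meaningful.
    """
    if len(pc_scores) < 3:
        raise ValueError("outlier screening needs at least 3 samples")
    flags = pd.Series(False, index=pc_scores.index)
    for col in pc_scores.columns:
        sd = pc_scores[col].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        centered = pc_scores[col] - pc_scores[col].mean()
        flags |= centered.abs() > z_threshold * sd
    return flags


def _logistic_lrt_p(y: np.ndarray, x: np.ndarray) -> tuple[float, bool]:
    """Likelihood-ratio p for a binary covariate on one PC.

    Returns (p, separated).  Perfect separation drives the LR statistic
    to its monotone limit; it is reported as p -> 0 with the flag set
    rather than raised.
    """
    # Detect quasi-complete separation: the two classes' x ranges disjoint.
    x0, x1 = x[y == 0], x[y == 1]
    separated = x0.max() < x1.min() or x1.max() < x0.min()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=200)
            null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)
        lr = 2 * (full.llf - null.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    except Exception:
        separated = True
        p = 0.0
    return p, separated


def covariate_screen(
    pc_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    continuous: list[str] | None = None,
    nominal: list[str] | None = None,
) -> pd.DataFrame:
    """Test each (PC, covariate) pair for association.

    Continuous covariates: ordinary least squares of the PC on the
    covariate, two-sided slope-test p.  Nominal covariates: logistic
    regression of the covariate on the PC, likelihood-ratio p (binary
    factors; multi-level factors are tested level-vs-rest and the
    minimum p reported).  Perfect separation is reported as p = 0 with a
    ``separated`` flag, constant covariates as missing.

    Returns a long DataFrame: pc, covariate, kind, p_value, separated.
    """
    continuous = continuous or []
    nominal = nominal or []
    rows = []
    for cov in continuous + nominal:
        kind = "continuous" if cov in continuous else "nominal"
        values = covariates[cov]
        for pc in pc_scores.columns:
            x = pc_scores[pc].to_numpy(dtype=float)
            p: float | None
            separated = False
            if values.nunique(dropna=True) < 2:
                p = None
            elif kind == "continuous":
                v = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
                ok = np.isfinite(v) & np.isfinite(x)
                if ok.sum() < 3:
                    p = None
                else:
                    res = stats.linregress(v[ok], x[ok])
                    p = float(res.pvalue)
            else:
                codes, _ = pd.factorize(values)
                levels = np.unique(codes[codes >= 0])
                ps = []
                for lev in levels if len(levels) > 2 else levels[:1]:
                    y = (codes == lev).astype(float)
                    ok = codes >= 0
                    pi, sep = _logistic_lrt_p(y[ok], x[ok])
                    separated |= sep
                    ps.append(pi)
                p = min(ps) if ps else None
            rows.append(
                {
                    "pc": pc,
                    "covariate": cov,
                    "kind": kind,
                    "p_value": p,
                    "separated": separated,
                }
            )
    return pd.DataFrame(rows)
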