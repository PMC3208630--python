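"""Internal validation: LOOCV, likelihood-ratio power, clustering.

Leave-one-out cross-validation refits the whole classification pipeline
(standardize -> SVD -> Bayesian probit) on n-1 samples and predicts the
held-out sample's class from its posterior predictive probability.  The
probe set is fixed before cross-validation begins (the selection is not
repeated inside folds), which matches the evaluated design and is mildly
optimistic; nested re-selection is available behind a flag.

Study power is computed from the generalized likelihood ratio lambda
between the intercept-only null and the fitted alternative:
-2 ln(lambda) is referred to a chi-square distribution with one degree
of freedom, and power = 1 - Pr(chi2(1) >= -2 ln lambda).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import bcsvd
from .bcsvd import SamplerSettings
from .types import BetaMatrix

__all__ = [
    "LoocvResult",
    "PowerResult",
    "loocv",
    "glr_power",
    "glr_from_fits",
    "hierarchical_cluster",
    "ClusterResult",
]

logger = logging.getLogger(__name__)


@dataclass
class LoocvResult:
    sample_ids: list[str]
    true_labels: np.ndarray
    predicted_labels: np.ndarray
    predictive_probabilities: np.ndarray
    flagged_folds: list[str] = field(default_factory=list)

    @property
    def _ok(self) -> np.ndarray:
        flagged = np.isin(self.sample_ids, self.flagged_folds)
        return ~flagged

    @property
    def sensitivity(self) -> float:
        ok = self._ok
        cases = ok & (self.true_labels == 1)
        if cases.sum() == 0:
            return float("nan")
        return float((self.predicted_labels[cases] == 1).mean())

    @property
    def specificity(self) -> float:
        ok = self._ok
        controls = ok & (self.true_labels == 0)
        if controls.sum() == 0:
            return float("nan")
        return float((self.predicted_labels[controls] == 0).mean())


@dataclass(frozen=True)
class PowerResult:
    neg_ln_lambda: float
    """-ln(lambda), the log generalized likelihood ratio (>= 0)."""

    @property
    def deviance(self) -> float:
        return 2.0 * self.neg_ln_lambda

    @property
    def power(self) -> float:
        return float(1.0 - stats.chi2.sf(self.deviance, df=1))


def loocv(
    beta: BetaMatrix,
    labels: np.ndarray,
    settings: SamplerSettings = SamplerSettings(),
    seed: int = 0,
    selector=None,
) -> LoocvResult:
    """Leave-one-out cross-validation of the probit classifier.

    ``beta`` holds the (pre-selected) significant probes only.  For each
    fold the remaining n-1 samples are standardized, decomposed and
    fitted afresh; the held-out sample is projected into the training
    score space (using training means/SDs and loadings) and called a
    case when its posterior predictive probability exceeds 0.5 (ties go
    to control).  ``selector``, if given, re-selects probes inside each
    fold from the training split (nested selection); it receives
    (training BetaMatrix, training labels) and returns probe ids.

    A fold whose training split loses one class entirely is flagged and
    excluded from the confusion counts.
    """
    labels = np.asarray(labels)
    if beta.n_probes == 0:
        raise ValueError("empty probe set")
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("need at least 2 samples per class")
    n = beta.n_samples
    preds = np.zeros(n, dtype=int)
    probs = np.zeros(n)
    flagged: list[str] = []
    for i in range(n):
        train_idx = [k for k in range(n) if k != i]
        y_tr = labels[train_idx]
        if (y_tr == 0).sum() < 1 or (y_tr == 1).sum() < 1:
            flagged.append(beta.sample_ids[i])
            logger.warning("fold %s leaves a class empty; excluded", beta.sample_ids[i])
            continue
        train = beta.subset_samples([beta.sample_ids[k] for k in train_idx])
        if selector is not None:
            probe_ids = selector(train, y_tr)
            train = train.subset_probes(probe_ids)
            held = beta.subset_samples([beta.sample_ids[i]]).subset_probes(probe_ids)
        else:
            held = beta.subset_samples([beta.sample_ids[i]])
        design = bcsvd.standardize(train, y_tr)
        decomp = bcsvd.svd_reduce(design)
        draws = bcsvd.gibbs_fit(
            decomp.scores, design.y, settings=settings, seed=seed + i
        )
        x_held = held.values[0]
        keep = [held.probe_ids.index(p) for p in design.probe_ids]
        z_held = (x_held[keep] - design.probe_means) / design.probe_sds
        score_held = z_held @ decomp.loadings
        p_case = float(bcsvd.predictive_probability(draws, score_held)[0])
        probs[i] = p_case
        preds[i] = 1 if p_case > 0.5 else 0  # ties -> control
    return LoocvResult(
        sample_ids=list(beta.sample_ids),
        true_labels=labels.astype(int),
        predicted_labels=preds,
        predictive_probabilities=probs,
        flagged_folds=flagged,
    )


def glr_power(neg_ln_lambda: float) -> PowerResult:
    """Power from -ln(lambda): 1 - Pr(chi2(1) >= -2 ln lambda)."""
    if neg_ln_lambda < 0:
        raise ValueError("-ln(lambda) must be non-negative")
    return PowerResult(neg_ln_lambda=float(neg_ln_lambda))


def glr_from_fits(loglik_null: float, loglik_alt: float) -> PowerResult:
    """Power from the two model log-likelihoods.

    lambda = L0 / L1, so -ln(lambda) = loglik_alt - loglik_null.
    """
    if loglik_alt < loglik_null:
        raise ValueError("alternative log-likelihood below the null's")
    return PowerResult(neg_ln_lambda=float(loglik_alt - loglik_null))


@dataclass
class ClusterResult:
    linkage: np.ndarray
    sample_ids: list[str]
    flat_labels: np.ndarray  # k=2 cut, values 1/2

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            return f"({rec(node.left)},{rec(node.right)}):{node.dist:.6g}"

        return rec(tree) + ";"


def hierarchical_cluster(beta: BetaMatrix, k: int = 2) -> ClusterResult:
    """Agglomerative clustering of samples at the given probes.

    Euclidean distance with average linkage (the defaults of the classic
    microarray viewers).  SciPy's linkage breaks distance ties by the
    lowest cluster index, so the result is deterministic for a fixed
    sample order.
    """
    if beta.n_samples < 2:
        raise ValueError("clustering needs at least 2 samples")
    if beta.n_samples < k:
        raise ValueError(f"cannot cut {beta.n_samples} samples into {k} clusters")
    x = np.nan_to_num(beta.values, nan=0.5)
    z = hierarchy.linkage(pdist(x, metric="euclidean"), method="average")
    flat = hierarchy.fcluster(z, t=k, criterion="maxclust")
    return ClusterResult(linkage=z, sample_ids=list(beta.sample_ids), flat_labels=flat)
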