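"""Phenotype classification, methylation-phenotype regression, enrichment.

Phenotype rules follow the evaluated primate cohort's definitions:
intermittent/anovulatory cycling is a mean cycle length above 34 days;
hyperandrogenism is basal testosterone at or above a threshold (0.32
ng/ml in the reference colony — the control mean plus one standard
deviation — or derived from the supplied controls); polycystic ovary
morphology is 10 or more ~1-3 mm follicles per greatest ovarian
diameter.

Probe-wise association between methylation and a numeric phenotype is
ordinary least-squares regression with the Pearson correlation and the
two-sided slope-test p-value, corrected for multiple testing by both
Bonferroni and Benjamini-Hochberg.  Regressions are run within a stated
sample subset (typically the cases), with the control subset analyzed
alongside as a negative comparison.

Gene-set over-representation uses the right-tailed Fisher (exact
hypergeometric) test against a caller-supplied reference list, e.g. the
full gene list of the array rather than the whole genome, so array
design bias does not masquerade as enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix

__all__ = [
    "CYCLE_LENGTH_THRESHOLD",
    "TESTOSTERONE_THRESHOLD",
    "FOLLICLE_THRESHOLD",
    "classify_phenotypes",
    "phenotype_regression",
    "bonferroni",
    "bh_fdr",
    "enrichment",
    "EnrichmentResult",
]

CYCLE_LENGTH_THRESHOLD = 34.0  # days; strictly greater => intermittent
TESTOSTERONE_THRESHOLD = 0.32  # ng/ml; inclusive (>=)
FOLLICLE_THRESHOLD = 10  # follicles per greatest ovarian diameter; inclusive


def classify_phenotypes(
    pheno: pd.DataFrame,
    testosterone_threshold: float | None = None,
) -> pd.DataFrame:
    """Per-sample clinical labels from the phenotype sheet.

    ``testosterone_threshold`` defaults to the literal 0.32 ng/ml; pass
    ``None`` explicitly through :func:`derive_testosterone_threshold` to
    recompute control mean + 1 SD from the data at hand.  Missing
    measurements yield missing labels (pandas NA), not False.
    """
    thr = (
        TESTOSTERONE_THRESHOLD
        if testosterone_threshold is None
        else testosterone_threshold
    )
    out = pd.DataFrame({"sample_id": pheno["sample_id"]})

    def col(name: str) -> pd.Series:
        if name in pheno:
            return pd.to_numeric(pheno[name], errors="coerce")
        return pd.Series(np.nan, index=pheno.index)

    cyc = col("cycle_length")
    t = col("testosterone")
    fol = col("follicle_count")
    out["cycle_status"] = pd.array(
        np.where(cyc.isna(), None, np.where(cyc > CYCLE_LENGTH_THRESHOLD,
                                            "intermittent", "normal")),
        dtype="string",
    )
    out["hyperandrogenic"] = pd.array(
        np.where(t.isna(), None, t >= thr), dtype="boolean"
    )
    out["pco"] = pd.array(
        np.where(fol.isna(), None, fol >= FOLLICLE_THRESHOLD), dtype="boolean"
    )
    return out


def derive_testosterone_threshold(pheno: pd.DataFrame) -> float:
    """Control mean + 1 SD of basal testosterone."""
    controls = pheno[pheno["group"] == "control"]
    t = pd.to_numeric(controls["testosterone"], errors="coerce").dropna()
    if t.empty:
        raise ValueError("no control testosterone values to derive a threshold")
    return float(t.mean() + t.std(ddof=1))


@dataclass(frozen=True)
class AssociationRow:
    probe_id: str
    phenotype: str
    n: int
    slope: float
    r: float
    p_raw: float


def phenotype_regression(
    beta: BetaMatrix,
    pheno: pd.DataFrame,
    phenotype: str,
    subset: pd.Series | np.ndarray,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Probe-wise OLS of methylation on a numeric phenotype.

    ``subset`` is a boolean mask over samples (e.g. cases only) and is
    mandatory: association is assessed within a group, not across the
    case-control contrast.  Probes with a zero-variance phenotype or
    fewer than ``min_pairs`` complete pairs are skipped with a reason.
    Bonferroni and BH corrections are computed over the m probes
    actually tested within the subset.

    Returns a DataFrame with columns probe_id, phenotype, n, slope, r,
    p_raw, p_bonferroni, q_bh, skipped_reason.
    """
    subset = np.asarray(subset, dtype=bool)
    if subset.shape[0] != beta.n_samples:
        raise ValueError("subset mask must have one entry per sample")
    values = pd.to_numeric(
        pheno.set_index("sample_id").loc[beta.sample_ids, phenotype],
        errors="coerce",
    ).to_numpy(dtype=float)

    rows = []
    for j, pid in enumerate(beta.probe_ids):
        y = beta.values[subset, j]
        x = values[subset]
        ok = np.isfinite(x) & np.isfinite(y)
        reason = None
        slope = r = p = np.nan
        n_ok = int(ok.sum())
        if n_ok < min_pairs:
            reason = "too_few_pairs"
        elif np.ptp(x[ok]) == 0:
            reason = "constant_phenotype"
        elif np.ptp(y[ok]) == 0:
            reason = "constant_methylation"
        else:
            res = stats.linregress(x[ok], y[ok])
            slope, r, p = float(res.slope), float(res.rvalue), float(res.pvalue)
        rows.append(
            {
                "probe_id": pid,
                "phenotype": phenotype,
                "n": n_ok,
                "slope": slope,
                "r": r,
                "p_raw": p,
                "skipped_reason": reason,
            }
        )
    df = pd.DataFrame(rows)
    tested = df["skipped_reason"].isna() & df["p_raw"].notna()
    m = int(tested.sum())
    df["p_bonferroni"] = np.nan
    df["q_bh"] = np.nan
    if m:
        df.loc[tested, "p_bonferroni"] = bonferroni(df.loc[tested, "p_raw"].to_numpy(), m)
        df.loc[tested, "q_bh"] = bh_fdr(df.loc[tested, "p_raw"].to_numpy())
    return df


def bonferroni(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """min(1, m * p), elementwise; m defaults to len(pvals)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m cannot be smaller than the number of tests")
    return np.minimum(1.0, m * p)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    k: int  # input genes hitting the set
    set_size: int  # set genes present in the reference
    list_size: int  # input genes present in the reference
    reference_size: int
    p_value: float

    @property
    def ratio(self) -> float:
        return self.k / self.set_size if self.set_size else float("nan")


def enrichment(
    input_genes: set[str] | list[str],
    gene_sets: dict[str, set[str] | list[str]],
    reference_genes: set[str] | list[str],
) -> list[EnrichmentResult]:
    """Right-tailed Fisher over-representation against a custom reference.

    Input genes outside the reference are dropped (logged via the
    returned sizes); each set is intersected with the reference.  The
    p-value is the exact hypergeometric upper tail P(X >= k) with
    population size |reference|, |set| successes and |input| draws.
    """
    reference = set(reference_genes)
    if not reference:
        raise ValueError("empty reference gene list")
    inp = set(input_genes) & reference
    results = []
    for name, genes in gene_sets.items():
        s = set(genes) & reference
        k = len(inp & s)
        # P(X >= k); sf(k-1) is the exact right tail.
        p = float(stats.hypergeom.sf(k - 1, len(reference), len(s), len(inp)))
        results.append(
            EnrichmentResult(
                set_name=name,
                k=k,
                set_size=len(s),
                list_size=len(inp),
                reference_size=len(reference),
                p_value=min(p, 1.0),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results
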