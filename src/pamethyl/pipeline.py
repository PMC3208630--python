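"""End-to-end orchestration: simulate -> QC -> test -> filter -> validate.

Each stage writes its artifacts into the run directory together with a
JSON manifest recording the seed and settings that produced them, so a
rerun with the same config reproduces every file.  A stage failure
raises with the stage name; artifacts written so far are left in place.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, bcsvd, io, qc, simulate, validation, validity
from .bcsvd import SamplerSettings
from .config import PipelineConfig
from .types import BetaMatrix

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _labels(pheno: pd.DataFrame, sample_ids: list[str]) -> np.ndarray:
    groups = pheno.set_index("sample_id").loc[sample_ids, "group"]
    return (groups == "PA").to_numpy().astype(int)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the toggled stages; returns the run directory.

    Stage order: simulate, qc, bcsvd, filter_probes (validity), validate
    (LOOCV/power/clustering), associate, enrich.  Later stages read the
    artifacts of earlier ones from the run directory, so a partial rerun
    can resume from existing files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text("")
    config.to_yaml(out / "config.yaml")
    st = config.stages
    settings = SamplerSettings(
        prior_variance=config.prior_variance,
        n_iter=config.n_iter,
        burn_in=config.burn_in,
    )
    perm_settings = SamplerSettings(
        prior_variance=config.prior_variance,
        n_iter=config.perm_n_iter,
        burn_in=config.perm_burn_in,
    )

    def manifest(stage: str, **extra) -> None:
        with open(out / f"{stage}.manifest.json", "w") as fh:
            json.dump({"stage": stage, "seed": config.seed, **extra}, fh, indent=1)

    try:
        if st.simulate:
            beta, pheno, truth = simulate.generate_dataset(config.simulation)
            io.write_beta_matrix(beta, out / "beta.tsv")
            io.write_phenotypes(pheno, out / "phenotypes.csv")
            io.write_truth_set(truth, out / "truth.json")
            genome, probes, vtruth = simulate.generate_genome_and_probes(
                config.simulation
            )
            io.write_genome_fasta(genome, out / "genome.fasta")
            io.write_genes_bed(genome.genes, out / "genes.bed")
            io.write_probe_manifest(probes, out / "manifest.csv")
            io.write_truth_set(vtruth, out / "validity_truth.json")
            manifest(
                "simulate",
                n_samples=beta.n_samples,
                n_probes=beta.n_probes,
                n_differential=len(truth.differential_probe_ids),
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e

    beta = io.read_beta_matrix(out / "beta.tsv")
    pheno = io.read_phenotypes(out / "phenotypes.csv")
    labels = _labels(pheno, beta.sample_ids)

    try:
        if st.qc:
            m, u, det_p = simulate.simulate_intensities(beta, config.simulation)
            beta_rt = qc.compute_beta(m, u)
            mask, report = qc.detection_filter(
                det_p, config.detection_p_threshold, config.min_sample_fraction
            )
            kept = [p for p, k in zip(beta.probe_ids, mask) if k]
            beta_q = BetaMatrix(beta_rt[:, mask], beta.sample_ids, kept)
            scores, eig = qc.pca_screen(beta_q, config.n_components)
            flags = qc.outlier_flag(scores, config.outlier_z)
            screen = qc.covariate_screen(
                scores,
                pheno.set_index("sample_id").loc[beta.sample_ids].reset_index(),
                continuous=["dna_amount", "od_260_280"],
                nominal=["batch"],
            )
            io.write_beta_matrix(beta_q, out / "beta_qc.tsv")
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            screen.to_csv(out / "covariate_screen.tsv", sep="\t", index=False)
            manifest(
                "qc",
                probes_tested=report.probes_tested,
                probes_passed=report.probes_passed,
                pass_rate=report.pass_rate,
                outliers=[s for s, f in flags.items() if f],
                eigenvalues=eig.tolist(),
            )
            logger.info(
                "QC: %d/%d probes passed (%.1f%%)",
                report.probes_passed,
                report.probes_tested,
                100 * report.pass_rate,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("qc", e) from e

    beta_for_test = (
        io.read_beta_matrix(out / "beta_qc.tsv")
        if (out / "beta_qc.tsv").exists()
        else beta
    )

    results = None
    try:
        if st.bcsvd:
            design = bcsvd.standardize(beta_for_test, labels)
            results = bcsvd.permutation_pvalues(
                design,
                b=config.n_permutations,
                seed=config.seed,
                settings=settings,
                permutation_settings=perm_settings,
                pooled=config.pooled_permutations,
            )
            df = pd.DataFrame(
                {
                    "probe_id": [r.probe_id for r in results],
                    "statistic": [r.statistic for r in results],
                    "direction": [r.direction for r in results],
                    "empirical_p": [r.empirical_p for r in results],
                    "significant": [r.empirical_p < config.alpha for r in results],
                }
            )
            df.to_csv(out / "bcsvd_results.tsv", sep="\t", index=False)
            manifest(
                "bcsvd",
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                n_significant=int(df["significant"].sum()),
                dropped_probes=design.dropped_probe_ids,
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("bcsvd", e) from e

    sig_ids: list[str] = []
    if (out / "bcsvd_results.tsv").exists():
        df = pd.read_csv(out / "bcsvd_results.tsv", sep="\t")
        sig_ids = df.loc[df["significant"], "probe_id"].tolist()

    try:
        if st.filter_probes and (out / "manifest.csv").exists():
            genome = io.read_genome_fasta(
                out / "genome.fasta", io.read_genes_bed(out / "genes.bed")
            )
            probes = io.read_probe_manifest(out / "manifest.csv")
            rows = []
            for p in probes:
                v = validity.validate_probe(
                    p.probe_id,
                    p.sequence,
                    genome,
                    expected_gene=p.gene_symbol,
                    max_mismatches=config.max_mismatches,
                )
                h = v.chosen_hit
                rows.append(
                    {
                        "probe_id": v.probe_id,
                        "valid": v.valid,
                        "reason": v.reason,
                        "chrom": h.chrom if h else None,
                        "start": h.start if h else None,
                        "strand": h.strand if h else None,
                        "mismatches": h.mismatch_count if h else None,
                        "identity": h.identity if h else None,
                        "mapped_gene": v.mapped_gene,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "validity.tsv", sep="\t", index=False)
            manifest(
                "filter_probes",
                n_probes=len(rows),
                n_valid=sum(r["valid"] for r in rows),
            )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("filter_probes", e) from e

    try:
        if st.validate and sig_ids:
            beta_sig = beta_for_test.subset_probes(sig_ids)
            cv = validation.loocv(beta_sig, labels, settings=settings, seed=config.seed)
            clust = validation.hierarchical_cluster(beta_sig)
            with open(out / "loocv.json", "w") as fh:
                json.dump(
                    {
                        "sensitivity": cv.sensitivity,
                        "specificity": cv.specificity,
                        "predicted": cv.predicted_labels.tolist(),
                        "probabilities": cv.predictive_probabilities.tolist(),
                        "flagged_folds": cv.flagged_folds,
                    },
                    fh,
                    indent=1,
                )
            (out / "dendrogram.nwk").write_text(clust.to_newick() + "\n")
            pd.DataFrame(
                {"sample_id": clust.sample_ids, "cluster": clust.flat_labels}
            ).to_csv(out / "clusters.tsv", sep="\t", index=False)
            manifest("validate", n_significant=len(sig_ids))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("validate", e) from e

    try:
        if st.associate and sig_ids:
            beta_sig = beta_for_test.subset_probes(sig_ids)
            for name, mask in (
                ("PA", labels == 1),
                ("control", labels == 0),
            ):
                assoc = association.phenotype_regression(
                    beta_sig, pheno, config.association_phenotype, mask
                )
                assoc.to_csv(
                    out / f"association_{name}.tsv", sep="\t", index=False
                )
            manifest("associate", phenotype=config.association_phenotype)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("associate", e) from e

    try:
        if st.enrich and (out / "manifest.csv").exists() and sig_ids:
            probes = io.read_probe_manifest(out / "manifest.csv")
            gene_of = {p.probe_id: p.gene_symbol for p in probes}
            reference = sorted({p.gene_symbol for p in probes})
            input_genes = {gene_of[p] for p in sig_ids if p in gene_of}
            # Toy sets: genes split by even/odd index as a smoke contract.
            sets = {
                "even_genes": {g for i, g in enumerate(reference) if i % 2 == 0},
                "odd_genes": {g for i, g in enumerate(reference) if i % 2 == 1},
            }
            res = association.enrichment(input_genes, sets, reference)
            pd.DataFrame(
                [
                    {
                        "set": r.set_name,
                        "k": r.k,
                        "set_size": r.set_size,
                        "list_size": r.list_size,
                        "reference_size": r.reference_size,
                        "ratio": r.ratio,
                        "p_value": r.p_value,
                    }
                    for r in res
                ]
            ).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest("enrich", n_sets=len(sets))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("enrich", e) from e

    return out
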