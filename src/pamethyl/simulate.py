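"""Synthetic data generation for the whole pipeline.

This module produces every input the downstream stages consume, with a
known ground truth: beta matrices with planted differential probes,
two-channel (methylated / unmethylated) intensities, toy genomes with
planted probe sequences covering each validity-criterion outcome, and
phenotype tables shaped like a small case-control primate study
(prenatally androgenized cases versus controls, infant and adult
cohorts).

The default configuration mirrors the infant study arm: 5 controls
versus 7 cases, with 163 differential loci out of a few thousand probes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BetaMatrix, Gene, GenomeBundle, ProbeRecord, TruthSet

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "simulate_intensities",
    "generate_genome_and_probes",
    "generate_phenotypes",
    "PROBE_CLASS_EXPECTATIONS",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults replicate the infant arm of the emulated design: 5 controls
    vs 7 prenatally androgenized cases, 163 differential loci among 2,163
    probes (a down-sampled stand-in for the 27,578-probe array), a group
    difference of 0.3 on the beta scale against within-group noise of
    0.05, and two assay batches.
    """

    n_control: int = 5
    n_case: int = 7
    n_probes: int = 2163
    n_differential: int = 163
    effect_size: float = 0.3
    within_group_sd: float = 0.05
    n_batches: int = 2
    batch_effect_sd: float = 0.01
    seed: int = 0
    intensity_scale: float = 1000.0
    failed_probe_fraction: float = 0.0
    age_class: str = "infant"

    def __post_init__(self) -> None:
        if self.n_control <= 0 or self.n_case <= 0 or self.n_probes <= 0:
            raise ValueError("sample and probe counts must be positive")
        if not 0 <= self.n_differential <= self.n_probes:
            raise ValueError("n_differential must lie in [0, n_probes]")
        if min(self.effect_size, self.within_group_sd, self.batch_effect_sd) < 0:
            raise ValueError("effect and noise scales must be non-negative")
        if self.n_batches <= 0:
            raise ValueError("need at least one batch")
        if not 0 <= self.failed_probe_fraction <= 1:
            raise ValueError("failed_probe_fraction must lie in [0, 1]")


def _truncnorm_beta(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    """Per-entry normal draws clamped to the unit interval.

    A clipped normal is used as the beta-value noise model: the marginals
    of array beta values concentrate away from the boundaries, so at the
    noise scales of interest clipping is rare and the group means stay
    where they were planted.
    """
    draws = rng.normal(mean, sd) if sd > 0 else np.array(mean, copy=True)
    return np.clip(draws, 0.0, 1.0)


def generate_dataset(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, TruthSet]:
    """Simulate a beta matrix with planted differential probes.

    Controls are drawn around per-probe baseline means; cases are shifted
    by a signed per-probe effect at the differential probes only.  Batch
    labels are assigned round-robin across samples and add a shared
    normal offset per (batch, probe).  Any group mean pushed outside
    [0, 1] by the requested effect is clamped and the probe flagged in
    the returned :class:`TruthSet`.

    Returns the beta matrix (samples x probes), the phenotype/sample
    sheet, and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_case
    sample_ids = [f"ctrl_{i+1}" for i in range(config.n_control)] + [
        f"case_{i+1}" for i in range(config.n_case)
    ]
    probe_ids = [f"probe_{j+1:05d}" for j in range(config.n_probes)]
    labels = np.r_[np.zeros(config.n_control, int), np.ones(config.n_case, int)]

    # Baseline means kept away from the boundaries so a +/-0.3 shift fits.
    baseline = rng.uniform(0.15, 0.85, size=config.n_probes)
    diff_idx = rng.choice(config.n_probes, size=config.n_differential, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_differential)

    case_mean = baseline.copy()
    case_mean[diff_idx] += signs * config.effect_size
    clamped_idx = diff_idx[(case_mean[diff_idx] < 0) | (case_mean[diff_idx] > 1)]
    case_mean = np.clip(case_mean, 0.0, 1.0)
    true_delta = np.zeros(config.n_probes)
    true_delta[diff_idx] = case_mean[diff_idx] - baseline[diff_idx]

    mean = np.where(labels[:, None] == 1, case_mean[None, :], baseline[None, :])
    batches = np.array([i % config.n_batches for i in range(n)])
    if config.batch_effect_sd > 0:
        batch_offsets = rng.normal(
            0.0, config.batch_effect_sd, size=(config.n_batches, config.n_probes)
        )
        mean = mean + batch_offsets[batches]
    values = _truncnorm_beta(rng, mean, config.within_group_sd)

    beta = BetaMatrix(values, sample_ids, probe_ids)
    pheno = generate_phenotypes(config, sample_ids, labels, batches, rng)
    truth = TruthSet(
        differential_probe_ids={probe_ids[j] for j in diff_idx},
        true_delta_beta={probe_ids[j]: float(true_delta[j]) for j in diff_idx},
        clamped={probe_ids[j] for j in clamped_idx},
    )
    return beta, pheno, truth


def generate_phenotypes(
    config: SimulationConfig,
    sample_ids: list[str],
    labels: np.ndarray,
    batches: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotype/sample sheet shaped like the emulated study tables.

    Controls get low basal testosterone (~0.07-0.27 ng/ml) and normal
    cycles; cases get elevated androgens, long/anovulatory cycles and
    polyfollicular ovaries in the adult arm.  Technical covariates (DNA
    amount, OD 260/280, batch) are independent of group so the covariate
    screen is calibrated under its null.
    """
    is_case = labels == 1
    n = len(sample_ids)
    testosterone = np.where(
        is_case,
        rng.uniform(0.20, 0.55, size=n),
        rng.uniform(0.05, 0.27, size=n),
    )
    androstenedione = np.where(
        is_case,
        rng.uniform(0.5, 4.5, size=n),
        rng.uniform(0.5, 1.2, size=n),
    )
    cycle_length = np.where(
        is_case,
        rng.integers(31, 121, size=n).astype(float),
        rng.integers(24, 35, size=n).astype(float),
    )
    follicles = np.where(
        is_case, rng.integers(8, 20, size=n), rng.integers(2, 8, size=n)
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_case, "PA", "control"),
            "age_class": config.age_class,
            "testosterone": np.round(testosterone, 2),
            "androstenedione": np.round(androstenedione, 2),
            "cycle_length": cycle_length,
            "follicle_count": follicles,
            "dna_amount": np.round(rng.uniform(500, 2000, size=n), 1),
            "od_260_280": np.round(rng.uniform(1.7, 2.0, size=n), 2),
            "batch": [f"batch_{b+1}" for b in batches],
        }
    )


def simulate_intensities(
    beta: BetaMatrix, config: SimulationConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-channel intensities whose ratio reproduces the input beta.

    Per (sample, probe): a Poisson total around ``intensity_scale`` is
    split binomially into methylated (M) and unmethylated (U) counts with
    success probability beta, so E[M/(M+U)] equals the input beta.  A
    configured fraction of probes is planted as failed detections:
    their detection p-values are drawn above any sensible threshold,
    everything else near zero.

    Returns (M, U, detection_p), each samples x probes.
    """
    rng = np.random.default_rng(config.seed + 1)
    b = np.nan_to_num(beta.values, nan=0.5)
    total = rng.poisson(config.intensity_scale, size=b.shape)
    m = rng.binomial(total, b)
    u = total - m

    detection_p = rng.uniform(0.0, 1e-4, size=b.shape)
    n_failed = int(round(config.failed_probe_fraction * beta.n_probes))
    if n_failed:
        failed = rng.choice(beta.n_probes, size=n_failed, replace=False)
        detection_p[:, failed] = rng.uniform(0.05, 1.0, size=(b.shape[0], n_failed))
    return m.astype(float), u.astype(float), detection_p


# Planted probe classes and the verdict reason the validity module must
# produce for each (see pamethyl.validity).  Class key -> reason code.
PROBE_CLASS_EXPECTATIONS = {
    "exact_match": "PASS",
    "mismatch_1_3": "PASS",
    "mismatch_4plus": "TOO_MANY_MISMATCHES",
    "anchor_broken": "ANCHOR_FAIL",
    "multi_one_perfect": "PASS",
    "multi_no_perfect": "AMBIGUOUS_NO_PERFECT_TOP",
    "outside_annotation": "ANNOTATION_FAIL",
}

_CLASS_CYCLE = list(PROBE_CLASS_EXPECTATIONS)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, positions: list[int]) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def generate_genome_and_probes(
    config: SimulationConfig,
    seed: int | None = None,
    n_probes_per_class: int = 1,
    chrom_length: int = 50_000,
    n_chromosomes: int = 2,
    n_genes: int = 20,
) -> tuple[GenomeBundle, list[ProbeRecord], TruthSet]:
    """Toy genome plus planted 50-nt probes with known validity verdicts.

    Seven probe classes are planted, one expected verdict each:

    - ``exact_match``: verbatim 50/50 copy with a matching 3'-terminal CG;
    - ``mismatch_1_3``: 1-3 internal substitutions (identity >= 94%);
    - ``mismatch_4plus``: >= 4 substitutions;
    - ``anchor_broken``: perfect body but the genomic bases under the
      probe's 3'-terminal CG dinucleotide are mutated;
    - ``multi_one_perfect``: the source locus is duplicated with 2
      mismatches elsewhere, so exactly one 100% hit exists;
    - ``multi_no_perfect``: two near-copies, neither 100%;
    - ``outside_annotation``: a perfect hit placed in intergenic space
      far from every gene's upstream window and body.

    Every planted probe is drawn from inside a gene body (except the last
    class) so annotation remapping succeeds when alignment does.  Probe
    3'-terminal bases are forced to CG at the source locus, matching the
    array design in which each probe ends on the interrogated CpG.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    total_needed = n_probes_per_class * len(_CLASS_CYCLE)
    if n_chromosomes * chrom_length < total_needed * 400 + 4000:
        raise ValueError("genome too short to host the requested probes")

    chrom_names = [f"chr{i+1}" for i in range(n_chromosomes)]
    seqs = {name: list(_random_seq(rng, chrom_length)) for name in chrom_names}

    # Lay out genes on alternating strands, evenly spaced with gaps large
    # enough that the 1.5 kb upstream windows never collide.
    genes: list[Gene] = []
    slot = chrom_length // max(1, (n_genes // n_chromosomes))
    gi = 0
    for name in chrom_names:
        per_chrom = n_genes // n_chromosomes
        for k in range(per_chrom):
            start = k * slot + 2000
            end = min(start + slot - 2500, chrom_length - 1)
            if end - start < 300:
                continue
            strand = "+" if gi % 2 == 0 else "-"
            genes.append(Gene(f"gene_{gi+1:02d}", name, strand, start, end))
            gi += 1

    body_genes = [g for g in genes]
    probes: list[ProbeRecord] = []
    truth = TruthSet()
    probe_counter = itertools.count(1)

    def host_locus(gene: Gene, offset: int) -> tuple[str, int]:
        pos = gene.start + 50 + offset
        if pos + 50 >= gene.end:
            pos = gene.start + (gene.end - gene.start) // 2
        return gene.chrom, pos

    def plant(chrom: str, pos: int) -> str:
        """Write a random 50-mer ending in CG into the genome; return it."""
        window = _random_seq(rng, 48) + "CG"
        seqs[chrom][pos : pos + 50] = list(window)
        return window

    for rep in range(n_probes_per_class):
        for ci, cls in enumerate(_CLASS_CYCLE):
            pid = f"vp_{next(probe_counter):03d}"
            gene = body_genes[(rep * len(_CLASS_CYCLE) + ci) % len(body_genes)]
            chrom, pos = host_locus(gene, 120 * rep + 60 * ci)

            if cls == "exact_match":
                probe_seq = plant(chrom, pos)
            elif cls == "mismatch_1_3":
                genomic = plant(chrom, pos)
                k = int(rng.integers(1, 4))
                positions = sorted(rng.choice(48, size=k, replace=False).tolist())
                probe_seq = _mutate(rng, genomic, positions)
            elif cls == "mismatch_4plus":
                genomic = plant(chrom, pos)
                k = int(rng.integers(4, 8))
                positions = sorted(rng.choice(48, size=k, replace=False).tolist())
                probe_seq = _mutate(rng, genomic, positions)
            elif cls == "anchor_broken":
                genomic = plant(chrom, pos)
                # Break the genomic CG under the probe's 3' anchor: the
                # probe keeps its designed CG end, the genome loses it.
                seqs[chrom][pos + 48] = "T" if genomic[48] != "T" else "A"
                seqs[chrom][pos + 49] = "T" if genomic[49] != "T" else "A"
                probe_seq = genomic
            elif cls == "multi_one_perfect":
                probe_seq = plant(chrom, pos)
                other = chrom_names[(chrom_names.index(chrom) + 1) % n_chromosomes]
                dup_pos = chrom_length - 600 - 200 * (rep * len(_CLASS_CYCLE) + ci)
                mutated = _mutate(rng, probe_seq, [10, 20])
                seqs[other][dup_pos : dup_pos + 50] = list(mutated)
            elif cls == "multi_no_perfect":
                designed = _random_seq(rng, 48) + "CG"
                near1 = _mutate(rng, designed, [5])
                near2 = _mutate(rng, designed, [30])
                seqs[chrom][pos : pos + 50] = list(near1)
                other = chrom_names[(chrom_names.index(chrom) + 1) % n_chromosomes]
                dup_pos = chrom_length - 1400 - 200 * (rep * len(_CLASS_CYCLE) + ci)
                seqs[other][dup_pos : dup_pos + 50] = list(near2)
                probe_seq = designed
            elif cls == "outside_annotation":
                # Intergenic: past the last gene end + its 1.5 kb margin.
                chrom = chrom_names[0]
                pos = chrom_length - 100 - 300 * (rep + 1)
                probe_seq = plant(chrom, pos)
            else:  # pragma: no cover
                raise AssertionError(cls)

            probes.append(
                ProbeRecord(
                    probe_id=pid,
                    sequence=probe_seq,
                    gene_symbol=gene.gene_id,
                    chrom=chrom,
                    pos=pos,
                    strand="+",
                )
            )
            truth.planted_validity[pid] = PROBE_CLASS_EXPECTATIONS[cls]

    genome = GenomeBundle({n: "".join(s) for n, s in seqs.items()}, genes)
    return genome, probes, truth
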