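"""Cross-species probe validity: alignment, criteria, gene remapping.

Array probes are 50-nt sequences designed against the human genome, each
ending on the interrogated CpG.  When the arrays are applied to another
primate, sequence divergence can silently invalidate a probe, so every
significant probe is re-aligned to the target genome and filtered by
three criteria:

1. the probe's 3'-terminal CG dinucleotide must match the genome exactly
   at the aligned locus (single-base extension requires it);
2. at most 3 of the 50 nucleotides may mismatch (identity >= 94%);
3. if the probe aligns to multiple loci, it is valid only when exactly
   one hit is a perfect (100% identity, anchored) match, and that hit is
   the one retained.

Surviving probes keep their human gene annotation only if the aligned
interval falls within 1.5 kb upstream of the annotated gene's
transcription start site or overlaps its gene body in the target genome.

Alignment is exhaustive and ungapped: every placement on both strands
with at most ``max_mismatches`` substitutions is reported.  At 50 nt the
criteria count substitutions only, so gapped alignment is unnecessary.
All coordinates are 0-based half-open on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import Gene, GenomeBundle

__all__ = [
    "AlignmentHit",
    "ValidityVerdict",
    "align_probe",
    "apply_validity_criteria",
    "map_to_annotation",
    "validate_probe",
    "UPSTREAM_WINDOW",
]

PROBE_LEN = 50
MAX_MISMATCHES_DEFAULT = 7  # alignment recall; validity itself cuts at 3
UPSTREAM_WINDOW = 1500

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped placement of a 50-nt probe.

    ``start`` is the 0-based forward-strand start; the hit spans
    [start, start + 50).  ``three_prime_anchor_ok`` records whether the
    probe's terminal CG dinucleotide matches the genome at the aligned
    3' end.
    """

    chrom: str
    start: int
    strand: str
    mismatch_count: int
    three_prime_anchor_ok: bool

    @property
    def identity(self) -> float:
        return (PROBE_LEN - self.mismatch_count) / PROBE_LEN

    @property
    def end(self) -> int:
        return self.start + PROBE_LEN


@dataclass
class ValidityVerdict:
    probe_id: str
    valid: bool
    reason: str  # PASS | ANCHOR_FAIL | TOO_MANY_MISMATCHES |
    #              AMBIGUOUS_NO_PERFECT_TOP | NO_HIT | ANNOTATION_FAIL
    chosen_hit: AlignmentHit | None = None
    mapped_gene: str | None = None

    def __post_init__(self) -> None:
        if self.valid and (self.reason != "PASS" or self.chosen_hit is None):
            raise ValueError("valid verdicts must carry reason PASS and a hit")


def _scan_strand(
    probe: np.ndarray, chrom_arr: np.ndarray, max_mismatches: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mismatch counts of the probe against every window of one strand.

    Returns (starts, mismatch_counts) for windows within the budget.
    Vectorized as a sum of shifted inequality masks: for probe position
    i, compare probe[i] against chrom[start + i] for all starts at once.
    """
    n = len(chrom_arr) - PROBE_LEN + 1
    if n <= 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    mism = np.zeros(n, dtype=np.int16)
    for i in range(PROBE_LEN):
        mism += chrom_arr[i : i + n] != probe[i]
    keep = np.nonzero(mism <= max_mismatches)[0]
    return keep, mism[keep].astype(int)


def align_probe(
    probe_seq: str,
    genome: GenomeBundle,
    max_mismatches: int = MAX_MISMATCHES_DEFAULT,
) -> list[AlignmentHit]:
    """All ungapped placements of a probe with <= max_mismatches.

    Both strands are scanned; N in the probe or genome counts as a
    mismatch.  Hits are sorted by mismatch count, then (chrom, start,
    strand) for determinism.
    """
    probe_seq = probe_seq.upper()
    if len(probe_seq) != PROBE_LEN:
        raise ValueError(f"probe length {len(probe_seq)} != {PROBE_LEN}")
    if set(probe_seq) - set("ACGTN"):
        raise ValueError("probe alphabet must be ACGTN")
    probe_fwd = np.frombuffer(probe_seq.encode(), dtype="S1")
    # A reverse-strand placement means the probe matches the reverse
    # complement of the forward window; equivalently the window matches
    # revcomp(probe) on the forward strand.
    probe_rc = np.frombuffer(_revcomp(probe_seq).encode(), dtype="S1")

    hits: list[AlignmentHit] = []
    for chrom in sorted(genome.chromosomes):
        seq = genome.chromosomes[chrom].upper()
        arr = np.frombuffer(seq.encode(), dtype="S1")
        for strand, pr in (("+", probe_fwd), ("-", probe_rc)):
            starts, mism = _scan_strand(pr, arr, max_mismatches)
            for start, mm in zip(starts.tolist(), mism.tolist()):
                window = seq[start : start + PROBE_LEN]
                aligned = window if strand == "+" else _revcomp(window)
                anchor_ok = aligned[48:50] == probe_seq[48:50]
                hits.append(
                    AlignmentHit(
                        chrom=chrom,
                        start=int(start),
                        strand=strand,
                        mismatch_count=int(mm),
                        three_prime_anchor_ok=anchor_ok,
                    )
                )
    hits.sort(key=lambda h: (h.mismatch_count, h.chrom, h.start, h.strand))
    return hits


def _is_perfect(hit: AlignmentHit) -> bool:
    # "Top match with 100% identity": we additionally require the 3'
    # anchor, since an unanchored perfect body cannot be extended.
    return hit.mismatch_count == 0 and hit.three_prime_anchor_ok


def apply_validity_criteria(
    probe_id: str, hits: list[AlignmentHit]
) -> ValidityVerdict:
    """Decide validity from the alignment hits of one probe.

    No hits -> NO_HIT.  Multiple hits invoke criterion 3: valid only
    when exactly one hit is a perfect anchored match, which becomes the
    chosen hit.  A single hit is judged on criteria 1 (3' CG anchor) and
    2 (<= 3 mismatches) alone.
    """
    if not hits:
        return ValidityVerdict(probe_id, valid=False, reason="NO_HIT")
    if len(hits) > 1:
        perfect = [h for h in hits if _is_perfect(h)]
        if len(perfect) != 1:
            return ValidityVerdict(
                probe_id,
                valid=False,
                reason="AMBIGUOUS_NO_PERFECT_TOP",
                chosen_hit=hits[0],
            )
        return ValidityVerdict(
            probe_id, valid=True, reason="PASS", chosen_hit=perfect[0]
        )
    hit = hits[0]
    if not hit.three_prime_anchor_ok:
        return ValidityVerdict(
            probe_id, valid=False, reason="ANCHOR_FAIL", chosen_hit=hit
        )
    if hit.mismatch_count > 3:
        return ValidityVerdict(
            probe_id, valid=False, reason="TOO_MANY_MISMATCHES", chosen_hit=hit
        )
    return ValidityVerdict(probe_id, valid=True, reason="PASS", chosen_hit=hit)


def _upstream_interval(gene: Gene) -> tuple[int, int]:
    """Strand-aware 1.5 kb window upstream of the TSS, half-open."""
    if gene.strand == "+":
        return max(0, gene.tss - UPSTREAM_WINDOW), gene.tss
    return gene.tss + 1, gene.tss + 1 + UPSTREAM_WINDOW


def map_to_annotation(
    verdict: ValidityVerdict,
    genes: list[Gene],
    expected_gene: str | None,
) -> ValidityVerdict:
    """Confirm the human gene annotation at the aligned locus.

    A passing probe stays valid only if its aligned interval overlaps
    the 1.5 kb upstream window or the gene body of the gene whose ID
    matches the probe's designed annotation; otherwise the reason
    becomes ANNOTATION_FAIL.  Non-passing verdicts pass through
    unchanged.
    """
    if not genes:
        raise ValueError("empty gene annotation")
    if not verdict.valid or verdict.chosen_hit is None:
        return verdict
    hit = verdict.chosen_hit
    for gene in genes:
        if expected_gene is not None and gene.gene_id != expected_gene:
            continue
        if gene.chrom != hit.chrom:
            continue
        up_start, up_end = _upstream_interval(gene)
        in_upstream = hit.start < up_end and hit.end > up_start
        in_body = hit.start < gene.end and hit.end > gene.start
        if in_upstream or in_body:
            verdict.mapped_gene = gene.gene_id
            return verdict
    return ValidityVerdict(
        verdict.probe_id,
        valid=False,
        reason="ANNOTATION_FAIL",
        chosen_hit=hit,
    )


def validate_probe(
    probe_id: str,
    probe_seq: str,
    genome: GenomeBundle,
    expected_gene: str | None = None,
    max_mismatches: int = MAX_MISMATCHES_DEFAULT,
) -> ValidityVerdict:
    """Full validity pipeline for one probe: align, criteria, remap."""
    hits = align_probe(probe_seq, genome, max_mismatches=max_mismatches)
    verdict = apply_validity_criteria(probe_id, hits)
    if verdict.valid and genome.genes:
        verdict = map_to_annotation(verdict, genome.genes, expected_gene)
    return verdict
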