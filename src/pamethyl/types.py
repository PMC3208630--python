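"""Core in-memory containers shared across the pipeline stages.

The central object is :class:`BetaMatrix`, a samples x probes matrix of
methylation fractions (beta values, M/(M+U)) with sample and probe
identifiers.  Missing values are encoded as NaN throughout; every value
that is not missing lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BetaMatrix",
    "GenomeBundle",
    "Gene",
    "ProbeRecord",
    "TruthSet",
]


@dataclass
class BetaMatrix:
    """Samples x probes matrix of methylation fractions in [0, 1].

    Parameters
    ----------
    values
        Array of shape (n_samples, n_probes).  NaN marks missing entries.
    sample_ids, probe_ids
        Unique identifiers for rows and columns respectively.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = list(self.sample_ids)
        self.probe_ids = list(self.probe_ids)
        if self.values.ndim != 2:
            raise ValueError("beta values must be a 2-D array")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.probe_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.probe_ids)} probes"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if len(set(self.probe_ids)) != p:
            raise ValueError("duplicate probe IDs")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            bad = np.argwhere((self.values < 0) | (self.values > 1))
            i, j = bad[0]
            raise ValueError(
                f"beta value out of [0,1] at probe {self.probe_ids[j]!r}, "
                f"sample {self.sample_ids[i]!r}: {self.values[i, j]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing (NaN) entries, same shape as ``values``."""
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        """Probes-in-rows DataFrame (the on-disk TSV orientation)."""
        return pd.DataFrame(
            self.values.T, index=self.probe_ids, columns=self.sample_ids
        )

    def subset_probes(self, probe_ids: list[str]) -> "BetaMatrix":
        idx = {p: j for j, p in enumerate(self.probe_ids)}
        cols = [idx[p] for p in probe_ids]
        return BetaMatrix(self.values[:, cols], self.sample_ids, list(probe_ids))

    def subset_samples(self, sample_ids: list[str]) -> "BetaMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return BetaMatrix(self.values[rows, :], list(sample_ids), self.probe_ids)


@dataclass(frozen=True)
class Gene:
    """A gene model in 0-based half-open coordinates.

    The transcription start site (TSS) is ``start`` on the + strand and
    ``end - 1`` on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class GenomeBundle:
    """A target genome plus its gene annotation.

    ``chromosomes`` maps chromosome name to nucleotide sequence (upper-case
    ACGT string); ``genes`` use 0-based half-open coordinates and must lie
    within their chromosome.
    """

    chromosomes: dict[str, str]
    genes: list[Gene]

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chromosomes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome {g.chrom}")
            if g.end > len(self.chromosomes[g.chrom]):
                raise ValueError(f"gene {g.gene_id} extends past chromosome end")


@dataclass(frozen=True)
class ProbeRecord:
    """A 50-nt array probe with its human-derived design annotation."""

    probe_id: str
    sequence: str
    gene_symbol: str
    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 50:
            raise ValueError(
                f"probe {self.probe_id} sequence length {len(self.sequence)} != 50"
            )


@dataclass
class TruthSet:
    """Ground truth attached to a synthetic dataset.

    ``true_delta_beta`` maps probe id -> signed beta-scale group difference
    (case minus control); non-differential probes are absent or zero.
    ``planted_validity`` maps probe id -> the verdict reason code the
    validity module is expected to produce.  ``clamped`` flags probes whose
    requested effect pushed a group mean outside [0, 1].
    """

    differential_probe_ids: set[str] = field(default_factory=set)
    true_delta_beta: dict[str, float] = field(default_factory=dict)
    planted_validity: dict[str, str] = field(default_factory=dict)
    clamped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        missing = self.differential_probe_ids - set(self.true_delta_beta)
        if missing:
            raise ValueError(f"differential probes without a true effect: {missing}")

    def to_dict(self) -> dict:
        return {
            "differential_probe_ids": sorted(self.differential_probe_ids),
            "true_delta_beta": dict(sorted(self.true_delta_beta.items())),
            "planted_validity": dict(sorted(self.planted_validity.items())),
            "clamped": sorted(self.clamped),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSet":
        return cls(
            differential_probe_ids=set(d.get("differential_probe_ids", ())),
            true_delta_beta=dict(d.get("true_delta_beta", {})),
            planted_validity=dict(d.get("planted_validity", {})),
            clamped=set(d.get("clamped", ())),
        )
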