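"""Readers and writers for the pipeline's on-disk formats.

Beta matrices travel as TSV with probes in rows and a sample-ID header;
genomes as FASTA; gene annotation as BED6 (0-based half-open) or GFF3
(1-based inclusive, converted on read); probe manifests and phenotype
sheets as CSV; gene sets as GMT; truth sets and run manifests as JSON;
dendrograms as Newick text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import BetaMatrix, Gene, GenomeBundle, ProbeRecord, TruthSet

__all__ = [
    "read_beta_matrix",
    "write_beta_matrix",
    "read_genome_fasta",
    "write_genome_fasta",
    "read_genes_bed",
    "write_genes_bed",
    "read_genes_gff3",
    "write_genes_gff3",
    "read_probe_manifest",
    "write_probe_manifest",
    "read_phenotypes",
    "write_phenotypes",
    "read_truth_set",
    "write_truth_set",
    "read_gmt",
    "read_gene_list",
]

MISSING_TOKEN = "NA"


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    df = beta.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.10g")


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes x samples TSV into a BetaMatrix.

    Missing cells (``NA`` or empty) become NaN.  Out-of-range or
    non-numeric values are rejected with the offending probe/sample
    named; ragged rows and duplicate IDs are errors.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_TOKEN, ""], dtype=str
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe IDs: {dupes}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate sample IDs in header")
    values = np.empty(df.shape, dtype=float)
    for jc, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric value at probe {probe!r}, sample {col!r}: "
                f"{df.loc[probe, col]!r}"
            )
        values[:, jc] = converted.to_numpy()
    out_of_range = (values < 0) | (values > 1)
    if np.any(out_of_range):
        i, j = np.argwhere(out_of_range)[0]
        raise ValueError(
            f"beta value out of [0,1] at probe {df.index[i]!r}, "
            f"sample {df.columns[j]!r}: {values[i, j]}"
        )
    return BetaMatrix(values.T, list(df.columns), list(df.index))


def write_genome_fasta(genome: GenomeBundle, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: str | Path, genes: list[Gene] | None = None) -> GenomeBundle:
    chroms = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return GenomeBundle(chromosomes=chroms, genes=genes or [])


def write_genes_bed(genes: list[Gene], path: str | Path) -> None:
    """BED6: chrom, start, end (0-based half-open), name, score, strand."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_genes_bed(path: str | Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 needs 6 columns, got {len(fields)}: {line!r}")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(Gene(name, chrom, strand, int(start), int(end)))
    return genes


def write_genes_gff3(genes: list[Gene], path: str | Path) -> None:
    """GFF3 gene features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tpamethyl\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_genes_gff3(path: str | Path) -> list[Gene]:
    """Read gene features from GFF3, converting to 0-based half-open."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"GFF3 needs 9 columns: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
            if gene_id is None:
                raise ValueError(f"GFF3 gene without ID attribute: {line!r}")
            genes.append(Gene(gene_id, chrom, strand, int(start) - 1, int(end)))
    return genes


def write_probe_manifest(probes: list[ProbeRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "probe_id": p.probe_id,
                "sequence": p.sequence,
                "gene_symbol": p.gene_symbol,
                "chrom": p.chrom,
                "pos": p.pos,
                "strand": p.strand,
            }
            for p in probes
        ]
    ).to_csv(path, index=False)


def read_probe_manifest(path: str | Path) -> list[ProbeRecord]:
    df = pd.read_csv(path, dtype={"probe_id": str, "sequence": str})
    return [
        ProbeRecord(
            probe_id=row.probe_id,
            sequence=row.sequence,
            gene_symbol=row.gene_symbol,
            chrom=row.chrom,
            pos=int(row.pos),
            strand=row.strand,
        )
        for row in df.itertuples()
    ]


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[MISSING_TOKEN])


def write_truth_set(truth: TruthSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth_set(path: str | Path) -> TruthSet:
    with open(path) as fh:
        return TruthSet.from_dict(json.load(fh))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
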