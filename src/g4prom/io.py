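"""Readers and writers for the pipeline's plain-text formats.

FASTA promoter records carry ``gene_id|strand|tss`` headers; motif
coordinates travel as BED6 (0-based half-open, strand '+' for coding and
'-' for template, relative to the gene); expression tables are TSV with
columns gene_id, tpm_wt, tpm_mut, postfc, ppde; titrations are CSV with
protein_conc_M, anisotropy and an optional sd column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genesets import TABLE_COLUMNS, _check_table
from .profiles import PromoterRecord
from .scan import CODING, TEMPLATE, G4Match

_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_promoters_fasta(records: list[PromoterRecord], path) -> None:
    seq_records = [
        SeqRecord(Seq(r.seq), id=f"{r.gene_id}|{r.gene_strand}|{r.tss}", description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_promoters_fasta(path) -> list[PromoterRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) == 3:
            gene_id, strand, tss = parts[0], parts[1], int(parts[2])
        else:
            gene_id, strand, tss = rec.id, "+", len(rec.seq) // 2
        out.append(PromoterRecord(gene_id, strand, tss, str(rec.seq).upper()))
    return out


def write_matches_bed(matches_by_gene: dict[str, list[G4Match]], path) -> None:
    """BED6 of motif matches; chrom column holds the gene id."""
    rows = []
    for gene_id, matches in matches_by_gene.items():
        for m in matches:
            rows.append(
                {
                    "chrom": gene_id,
                    "start": m.start,
                    "end": m.end,
                    "name": m.matched,
                    "score": 0,
                    "strand": "+" if m.strand_class == CODING else "-",
                }
            )
    pd.DataFrame(rows, columns=_BED_COLUMNS).to_csv(
        str(path), sep="\t", header=False, index=False
    )


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(str(path), sep="\t", header=None, names=_BED_COLUMNS)
    df["strand_class"] = df["strand"].map({"+": CODING, "-": TEMPLATE})
    return df


def write_expression_table(table: pd.DataFrame, path) -> None:
    _check_table(table)
    table.loc[:, TABLE_COLUMNS].to_csv(str(path), sep="\t", index=False)


def read_expression_table(path) -> pd.DataFrame:
    table = pd.read_csv(str(path), sep="\t")
    return _check_table(table)


def write_titration_csv(series, path, truth: dict | None = None) -> None:
    df = pd.DataFrame(
        {"protein_conc_M": series.protein_totals, "anisotropy": series.readings}
    )
    if series.replicate_sd is not None:
        df["sd"] = series.replicate_sd
    df.to_csv(str(path), index=False)


def read_titration_csv(path, l_total: float):
    from .binding import TitrationSeries

    df = pd.read_csv(str(path))
    for col in ("protein_conc_M", "anisotropy"):
        if col not in df.columns:
            raise ValueError(f"titration CSV lacks column {col!r}")
    sd = df["sd"].to_numpy() if "sd" in df.columns else None
    return TitrationSeries(
        protein_totals=df["protein_conc_M"].to_numpy(),
        readings=df["anisotropy"].to_numpy(),
        l_total=l_total,
        replicate_sd=sd,
    )


def read_gene_list(path) -> list[str]:
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]
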