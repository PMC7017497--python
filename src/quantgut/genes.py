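"""Absolute functional gene-content scaling.

Predicted per-genome gene copies (PICRUSt2-style hidden-state output, rows =
ASVs, columns = KEGG orthologs plus a 16S copy-number column) are combined
with absolute ASV abundances: dividing each ASV's absolute 16S-copy abundance
by its 16S copies per genome gives genome equivalents, and summing genome
equivalents times per-genome gene copies over ASVs gives the inferred
absolute abundance of each ortholog (e.g. bile salt hydrolase K01442,
beta-glucuronidase K01195, arylsulfatase K01130) per sample unit.
"""

from __future__ import annotations

import pandas as pd

MARKER_COLUMN = "16S_rRNA_Count"


def read_gene_copy_table(path) -> pd.DataFrame:
    """ASV x (KO ids + 16S copy number) TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if MARKER_COLUMN not in df.columns:
        raise ValueError(f"gene-copy table lacks the {MARKER_COLUMN!r} column")
    if (df[MARKER_COLUMN] < 1).any():
        raise ValueError("16S copies per genome must be >= 1")
    return df.astype(float)


def genome_equivalents(absolute: pd.DataFrame, copies16s: pd.Series) -> pd.DataFrame:
    """genomes[s, a] = absolute 16S copies[s, a] / 16S copies per genome[a]."""
    missing = [a for a in absolute.columns if a not in copies16s.index]
    if missing:
        raise KeyError(f"ASV(s) missing from the 16S copy table: {missing[:10]}")
    c = copies16s.reindex(absolute.columns).astype(float)
    if (c < 1).any():
        raise ValueError("16S copies per genome must be >= 1")
    return absolute.div(c, axis=1)


def absolute_gene_abundance(
    genomes: pd.DataFrame, gene_copies: pd.DataFrame
) -> pd.DataFrame:
    """gene[s, k] = sum_a genomes[s, a] * copies[a, k] (samples x orthologs)."""
    if set(genomes.columns) != set(gene_copies.index):
        raise ValueError("genome table and gene-copy table cover different ASV sets")
    g = gene_copies.reindex(genomes.columns)
    if (g.to_numpy() < 0).any():
        raise ValueError("gene copies per genome must be >= 0")
    return genomes @ g


def scale_gene_content(
    absolute: pd.DataFrame, gene_copy_table: pd.DataFrame
) -> pd.DataFrame:
    """One-shot: absolute ASV table + PICRUSt2-style table -> samples x KO."""
    kos = [c for c in gene_copy_table.columns if c != MARKER_COLUMN]
    genomes = genome_equivalents(absolute, gene_copy_table[MARKER_COLUMN])
    return absolute_gene_abundance(genomes, gene_copy_table[kos])
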