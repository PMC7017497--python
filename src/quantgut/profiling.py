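"""Absolute microbiome profiling: ASV counts + total loads -> absolute abundance.

The central computation of quantitative sequencing: per-sample read counts
are converted to relative abundances, contaminant taxa are identified and
removed, taxa are collapsed to a chosen rank, and relative abundances are
anchored to an independently measured total 16S load to give copies per
normalization unit, with per-cell lower-limit-of-detection flags.

Contaminants are called by two complementary rules:

* prevalence — a taxon absent from every cecum-contents sample (the
  highest-biomass compartment) but present elsewhere is a likely reagent or
  handling contaminant;
* frequency — a reagent contaminant contributes a roughly constant ambient
  mass per reaction, so its read *frequency* is inversely proportional to
  sample DNA concentration. Each taxon's log-frequency/log-concentration
  relationship is scored against a slope -1 (contaminant) vs slope 0
  (biological) model by residual sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .samples import SampleRecord

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = ""

#: lineage substrings treated as plant-origin organellar signal
ORGANELLAR_MARKERS = ("chloroplast", "mitochondria", "rickettsiales")


# ---------------------------------------------------------------------------
# taxonomy


@dataclass
class Taxonomy:
    """ASV id -> ordered lineage levels (domain..species), Silva-style."""

    lineages: dict[str, tuple[str, ...]]
    confidence: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_strings(
        cls, mapping: dict[str, str], confidence: Optional[dict[str, float]] = None
    ) -> "Taxonomy":
        parsed = {}
        for asv, lineage in mapping.items():
            levels = [lv.strip() for lv in lineage.split(";")]
            # strip Silva rank prefixes like "o__"
            levels = [lv.split("__", 1)[1] if "__" in lv else lv for lv in levels]
            levels += [UNASSIGNED] * (len(RANKS) - len(levels))
            parsed[asv] = tuple(levels[: len(RANKS)])
        return cls(parsed, confidence or {})

    def label_at(self, asv: str, level: str) -> str:
        """Collapsed group label: the lineage prefix through `level`.

        Unassigned ranks keep their (empty) placeholder so that ASVs
        unassigned below some rank group under the deepest assigned prefix —
        the same grouping the QIIME2 taxa "collapse" action produces.
        """
        k = RANKS.index(level) + 1
        return ";".join(self.lineages[asv][:k])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"asv_id": a, "lineage": ";".join(lv), "confidence": self.confidence.get(a, 1.0)}
            for a, lv in self.lineages.items()
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "Taxonomy":
        df = pd.read_csv(path, sep="\t").fillna({"lineage": ""})
        return cls.from_strings(
            dict(zip(df["asv_id"], df["lineage"])),
            dict(zip(df["asv_id"], df["confidence"])),
        )


# ---------------------------------------------------------------------------
# tables

# Count/relative/absolute tables are pandas DataFrames with samples as the
# index and taxa as columns. Absolute tables travel with a boolean flag frame
# marking below-LLOD cells and a unit string.


@dataclass
class AbsoluteAbundanceTable:
    values: pd.DataFrame
    flags: pd.DataFrame  # True where below LLOD
    unit: str = "copies/g"

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.flags.index) or not self.values.columns.equals(
            self.flags.columns
        ):
            raise ValueError("values and flags must share index and columns")


@dataclass
class ContaminantCall:
    taxon: str
    flagged_by: str  # cecum_prevalence | frequency_score | both
    score: float = float("nan")


def read_counts(path) -> pd.DataFrame:
    """Read a count table from TSV (auto-orienting) or BIOM.

    TSV tables may have taxa as rows (QIIME-style, first header cell
    ``#OTU ID`` or ``taxon``/``asv_id``) or samples as rows.
    """
    path = str(path)
    if path.endswith(".biom"):
        from skbio.table import Table

        with open(path) as fh:
            table = Table.from_tsv(fh, None, None, lambda x: x)
        df = table.to_dataframe(dense=True).T  # biom: observations x samples
        return df.astype(float)
    df = pd.read_csv(path, sep="\t", index_col=0)
    first = str(df.index.name or "").lstrip("#").strip().lower()
    if first in {"otu id", "otu_id", "asv_id", "taxon", "feature id", "feature_id"}:
        df = df.T
    return df.astype(float)


def write_counts(counts: pd.DataFrame, path, orientation: str = "taxa_as_rows") -> None:
    out = counts.T if orientation == "taxa_as_rows" else counts
    out.index.name = "asv_id" if orientation == "taxa_as_rows" else "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# operations


def to_relative(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances; all-zero samples become NaN rows."""
    if counts.empty:
        raise ValueError("count table is empty")
    totals = counts.sum(axis=1)
    rel = counts.div(totals, axis=0)
    rel[totals == 0] = np.nan
    return rel


def collapse_taxa(table: pd.DataFrame, taxonomy: Taxonomy, level: str) -> pd.DataFrame:
    """Sum columns over taxa sharing the lineage prefix through `level`."""
    if level not in RANKS:
        raise ValueError(f"unknown taxonomic level {level!r}; expected one of {RANKS}")
    missing = [c for c in table.columns if c not in taxonomy.lineages]
    if missing:
        raise KeyError(f"taxa missing from taxonomy: {missing[:5]}")
    labels = {c: taxonomy.label_at(c, level) for c in table.columns}
    return table.T.groupby(table.columns.map(labels)).sum().T


def flag_contaminants_prevalence(
    counts: pd.DataFrame, metadata: Sequence[SampleRecord]
) -> list[ContaminantCall]:
    """Flag taxa with zero counts in all cecum-contents samples but reads elsewhere."""
    cecum_ids = [
        r.sample_id
        for r in metadata
        if r.site == "CEC" and r.material == "contents" and r.sample_id in counts.index
    ]
    if not cecum_ids:
        raise ValueError("metadata contains no cecum-contents samples present in the table")
    in_cecum = counts.loc[cecum_ids].sum(axis=0) > 0
    anywhere = counts.sum(axis=0) > 0
    flagged = counts.columns[(~in_cecum) & anywhere]
    return [ContaminantCall(t, "cecum_prevalence") for t in flagged]


def score_contaminant_frequency(
    relative: pd.DataFrame,
    dna_concentration: pd.Series,
    threshold: float = 0.5,
    min_samples: int = 5,
) -> list[ContaminantCall]:
    """Score each taxon's frequency/concentration relationship.

    For samples where the taxon is present, fit log(frequency) against
    log(concentration) under the contaminant model (slope fixed at -1, free
    intercept) and the biological model (constant frequency). The score is
    SSR_contaminant / (SSR_contaminant + SSR_biological): -> 0 for a pure
    ambient contaminant, -> 1 for a concentration-independent organism.
    Taxa scoring below `threshold` are flagged.
    """
    conc = dna_concentration.reindex(relative.index)
    if conc.isna().any():
        raise ValueError("missing DNA concentration for some samples")
    if (conc <= 0).any():
        raise ValueError("DNA concentrations must be positive")
    logc = np.log(conc.to_numpy(dtype=float))
    calls: list[ContaminantCall] = []
    for taxon in relative.columns:
        freq = relative[taxon].to_numpy(dtype=float)
        mask = np.isfinite(freq) & (freq > 0)
        if mask.sum() < min_samples:
            continue
        y = np.log(freq[mask])
        x = logc[mask]
        # contaminant: y = c - x  =>  c fit by least squares
        resid_c = (y + x) - np.mean(y + x)
        ssr_contam = float(np.sum(resid_c**2))
        ssr_biol = float(np.sum((y - np.mean(y)) ** 2))
        denom = ssr_contam + ssr_biol
        score = 0.5 if denom == 0 else ssr_contam / denom
        if score < threshold:
            calls.append(ContaminantCall(taxon, "frequency_score", score))
    return calls


def remove_contaminants(
    table: pd.DataFrame,
    calls: Iterable[ContaminantCall],
    keep_organellar: bool = False,
    is_relative: bool = False,
) -> pd.DataFrame:
    """Drop flagged taxa columns (and, optionally, plant-origin organellar taxa).

    Relative tables are re-normalized to sum to 1; absolute tables are not
    rescaled — removing a contaminant subtracts its mass from the sample.
    """
    drop = {c.taxon for c in calls if c.taxon in table.columns}
    if not keep_organellar:
        for col in table.columns:
            low = str(col).lower()
            if any(m in low for m in ORGANELLAR_MARKERS):
                drop.add(col)
    out = table.drop(columns=sorted(drop))
    if is_relative:
        totals = out.sum(axis=1)
        out = out.div(totals.where(totals > 0), axis=0)
    return out


def to_absolute(
    relative: pd.DataFrame,
    loads: dict[str, "LoadEstimateLike"],
    llod_floor: Optional[float] = None,
    depths: Optional[pd.Series] = None,
) -> AbsoluteAbundanceTable:
    """Anchor relative abundances to total loads: cell = fraction x load.

    A cell is flagged below LLOD when its absolute value falls under the
    load-equivalent of a single read at that sample's sequencing depth (or a
    configured floor), or when the whole sample's load is below detection.
    """
    missing = [s for s in relative.index if s not in loads]
    if missing:
        raise KeyError(f"no load estimate for sample(s): {missing[:5]}")
    units = {getattr(loads[s], "unit", "copies/g") for s in relative.index}
    values = relative.mul(
        pd.Series({s: loads[s].value for s in relative.index}), axis=0
    )
    flags = pd.DataFrame(False, index=relative.index, columns=relative.columns)
    for s in relative.index:
        est = loads[s]
        if getattr(est, "flag", "ok") == "below_llod":
            flags.loc[s, :] = True
            continue
        if llod_floor is not None:
            cell_llod = llod_floor
        elif depths is not None and s in depths.index and depths[s] > 0:
            cell_llod = est.value / float(depths[s])
        else:
            cell_llod = 0.0
        flags.loc[s, :] = values.loc[s] < cell_llod
    unit = units.pop() if len(units) == 1 else "mixed"
    return AbsoluteAbundanceTable(values, flags, unit)


def mean_group_profile(
    absolute: AbsoluteAbundanceTable | pd.DataFrame,
    metadata: Sequence[SampleRecord],
    by: tuple[str, ...] = ("group", "site"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arithmetic mean absolute profile per group (and its re-normalized
    relative version), the quantity plotted as per-group composition bars."""
    values = absolute.values if isinstance(absolute, AbsoluteAbundanceTable) else absolute
    meta = {r.sample_id: r for r in metadata}
    keys = {}
    for s in values.index:
        r = meta.get(s)
        if r is None:
            raise KeyError(f"sample {s} missing from metadata")
        keys[s] = tuple(getattr(r, b) for b in by)
    grouped = values.groupby(values.index.map(keys)).mean()
    totals = grouped.sum(axis=1)
    rel = grouped.div(totals.where(totals > 0), axis=0)
    return grouped, rel


class LoadEstimateLike:  # typing aid only
    value: float
    unit: str
    flag: str
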