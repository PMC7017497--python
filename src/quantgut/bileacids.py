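"""Targeted bile-acid quantification from LC-MS peak areas.

Post-processing of a targeted bile-acid panel: per-species instrument drift
correction against interspersed pooled-QC injections, external calibration
(7 levels, 0.05-30 uM, three replicate series), inverse calibration with
internal-standard normalization where a matched deuterated standard exists,
back-calculation through the sample dilution chain, and pool summaries
(total bile acids, fraction unconjugated, fraction of secondary species).

The species panel — conjugation state (tauro/glyco/unconjugated), primary
vs secondary class, internal-standard mapping, and the UDCA/HDCA merge (the
two epimers co-elute and are reported as a sum) — ships as an editable TSV
registry.

Peak-area tables are long-format: one row per injection x species with
columns ``injection_index, sample_id, injection_type, standard_conc_uM,
species, area, is_id, is_area``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .samples import SampleRecord

CAL_LEVELS_UM = (0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 30.0)
LLOQ_UM = 0.05
ULOQ_UM = 30.0
IS_CONC_UM = 5.0

FLAG_OK = "ok"
FLAG_BELOW_LLOQ = "below_lloq"
FLAG_ABOVE_RANGE = "above_range"


def load_panel(path=None) -> pd.DataFrame:
    """Species registry: conjugation, class, IS mapping, merge partner."""
    if path is None:
        path = resources.files("quantgut.data") / "bileacid_panel.tsv"
    panel = pd.read_csv(path, sep="\t").fillna("")
    bad = panel[~panel["conjugation"].isin(["tauro", "glyco", "unconjugated"])]
    if len(bad):
        raise ValueError(f"unclassified conjugation for: {list(bad['species'])}")
    bad = panel[~panel["ba_class"].isin(["primary", "secondary"])]
    if len(bad):
        raise ValueError(f"unclassified primary/secondary for: {list(bad['species'])}")
    return panel.set_index("species")


@dataclass
class CalibrationFit:
    """Linear response fit for one species: response = slope*conc + intercept."""

    species: str
    slope: float
    intercept: float
    r_squared: float
    range_um: tuple[float, float] = (LLOQ_UM, ULOQ_UM)

    @property
    def is_valid(self) -> bool:
        return self.slope > 0

    def concentration_at(self, response: float) -> float:
        return (response - self.intercept) / self.slope


@dataclass
class ConcentrationTable:
    """Per-sample bile-acid concentrations.

    ``extract_um`` is in the reconstituted extract; ``values`` is
    back-calculated to the sample (nmol/g contents, or uM = nmol/mL for
    bile), with per-cell range flags.
    """

    values: pd.DataFrame
    extract_um: pd.DataFrame
    flags: pd.DataFrame
    units: pd.Series  # per sample


def correct_drift(areas: pd.DataFrame) -> pd.DataFrame:
    """Divide areas by a per-species drift factor interpolated across QCs.

    The factor at injection i is the piecewise-linear interpolation of
    (QC area / first QC area) through the QC injections; injections outside
    the QC bracket use the nearest QC's factor.
    """
    qc = areas[areas["injection_type"] == "qc"]
    n_qc = qc["injection_index"].nunique()
    if n_qc < 2:
        warnings.warn("fewer than 2 QC injections; drift correction skipped")
        return areas.copy()
    out = areas.copy()
    for col_sp, col_area in (("species", "area"), ("is_id", "is_area")):
        for sp, sub in qc.groupby(col_sp):
            sub = sub.sort_values("injection_index")
            ref = sub[col_area].iloc[0]
            if ref <= 0:
                continue
            xi = sub["injection_index"].to_numpy(dtype=float)
            fi = sub[col_area].to_numpy(dtype=float) / ref
            sel = out[col_sp] == sp
            factors = np.interp(out.loc[sel, "injection_index"].to_numpy(float), xi, fi)
            out.loc[sel, col_area] = out.loc[sel, col_area] / factors
    return out


def _response(df: pd.DataFrame) -> pd.Series:
    """IS-normalized response where an IS area exists, raw area otherwise."""
    has_is = df["is_area"].notna() & (df["is_area"] > 0)
    resp = df["area"].astype(float).copy()
    resp[has_is] = df.loc[has_is, "area"] / df.loc[has_is, "is_area"] * IS_CONC_UM
    return resp


def fit_calibration(
    areas: pd.DataFrame, weighting: Optional[str] = "1/x"
) -> dict[str, CalibrationFit]:
    """Per-species least-squares fit of (drift-corrected) response vs conc,
    pooling the replicate calibration series.

    The default 1/x weighting keeps the low end of the 600-fold calibration
    range accurate: with roughly proportional (multiplicative) detector
    noise, unweighted OLS lets the top standards dictate the intercept,
    which badly biases back-calculation near the LLOQ.
    """
    std = areas[areas["injection_type"] == "standard"]
    if std.empty:
        raise ValueError("no standard injections found")
    fits: dict[str, CalibrationFit] = {}
    for sp, sub in std.groupby("species"):
        conc = sub["standard_conc_uM"].to_numpy(dtype=float)
        if np.unique(conc).size < 2:
            raise ValueError(f"species {sp}: fewer than 2 calibration levels")
        resp = _response(sub).to_numpy(dtype=float)
        if weighting == "1/x":
            w = 1.0 / conc
        elif weighting is None:
            w = np.ones_like(conc)
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        xm = np.average(conc, weights=w)
        ym = np.average(resp, weights=w)
        sxx = float(np.sum(w * (conc - xm) ** 2))
        slope = float(np.sum(w * (conc - xm) * (resp - ym)) / sxx)
        intercept = float(ym - slope * xm)
        ssr = float(np.sum(w * (resp - intercept - slope * conc) ** 2))
        sst = float(np.sum(w * (resp - ym) ** 2))
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        fits[sp] = CalibrationFit(
            sp, slope, intercept, r2, (float(conc.min()), float(conc.max())),
        )
    return fits


def quantify(
    areas: pd.DataFrame,
    fits: dict[str, CalibrationFit],
    metadata: Sequence[SampleRecord],
    panel: Optional[pd.DataFrame] = None,
) -> ConcentrationTable:
    """Inverse calibration + dilution chain -> sample-level concentrations.

    Values below the lowest calibration level are reported as 0 and flagged;
    values above the highest level are reported but flagged out-of-range.
    Merged species pairs (UDCA/HDCA) are summed into one record.
    """
    if panel is None:
        panel = load_panel()
    meta = {r.sample_id: r for r in metadata}
    smp = areas[areas["injection_type"] == "sample"].copy()
    unknown = set(smp["species"]) - set(panel.index)
    if unknown:
        raise ValueError(f"species not in panel: {sorted(unknown)}")
    smp["response"] = _response(smp)
    extract = {}
    for (sid, sp), sub in smp.groupby(["sample_id", "species"]):
        fit = fits.get(sp)
        if fit is None or not fit.is_valid:
            raise ValueError(f"no valid calibration for species {sp}")
        extract[(sid, sp)] = fit.concentration_at(float(sub["response"].mean()))
    ex = pd.Series(extract).unstack()

    # merge co-eluting pairs into a single reported species
    merged_cols: dict[str, list[str]] = {}
    for sp in ex.columns:
        partner = panel.loc[sp, "merged_with"]
        if partner and partner in ex.columns:
            key = "/".join(sorted([sp, partner]))
        else:
            key = sp
        merged_cols.setdefault(key, []).append(sp)
    ex_merged = pd.DataFrame(
        {key: ex[cols].sum(axis=1) for key, cols in merged_cols.items()}
    )

    flags = pd.DataFrame(FLAG_OK, index=ex_merged.index, columns=ex_merged.columns)
    values = ex_merged.copy()
    units = {}
    for sid in ex_merged.index:
        rec = meta.get(sid)
        if rec is None:
            raise KeyError(f"sample {sid} missing from metadata")
        for key in ex_merged.columns:
            v = ex_merged.loc[sid, key]
            if v < LLOQ_UM:
                values.loc[sid, key] = 0.0
                ex_merged.loc[sid, key] = max(v, 0.0)
                flags.loc[sid, key] = FLAG_BELOW_LLOQ
            elif v > ULOQ_UM:
                flags.loc[sid, key] = FLAG_ABOVE_RANGE
        values.loc[sid] = values.loc[sid] * rec.dilution_factor
        units[sid] = "uM" if rec.material == "bile" else "nmol/g"
    return ConcentrationTable(values, ex_merged, flags, pd.Series(units))


@dataclass
class BileAcidProfileSummary:
    sample_id: str
    total: float
    fraction_unconjugated: float
    fraction_secondary: float
    unit: str


def summarize_profile(
    conc: ConcentrationTable, panel: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Per-sample pool summary: total, fraction unconjugated, fraction
    secondary (conjugated + unconjugated secondary species)."""
    if panel is None:
        panel = load_panel()

    def classify(key: str, axis: str) -> set[str]:
        members = key.split("/")
        missing = [m for m in members if m not in panel.index]
        if missing:
            raise ValueError(f"species not classified in panel: {missing}")
        return {panel.loc[m, axis] for m in members}

    rows = []
    for sid in conc.values.index:
        total = unconj = secondary = 0.0
        for key in conc.values.columns:
            v = float(conc.values.loc[sid, key])
            total += v
            if classify(key, "conjugation") == {"unconjugated"}:
                unconj += v
            if classify(key, "ba_class") == {"secondary"}:
                secondary += v
        rows.append(
            {
                "sample_id": sid,
                "total": total,
                "fraction_unconjugated": unconj / total if total > 0 else math.nan,
                "fraction_secondary": secondary / total if total > 0 else math.nan,
                "unit": conc.units[sid],
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def read_areas(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {
        "injection_index", "sample_id", "injection_type", "standard_conc_uM",
        "species", "area", "is_id", "is_area",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak-area table missing columns: {sorted(missing)}")
    return df
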