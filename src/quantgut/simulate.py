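"""Synthetic study generator with known ground truth.

Emulates the raw data of a four-arm mouse coprophagy-prevention study
(functional tail cup TC-F, mock tail cup TC-M, wire floor WF, standard
housing CTRL; six gastrointestinal sites; lumenal contents, mid-small-
intestine mucosa, and gallbladder bile) so the whole downstream pipeline is
testable against known truth:

* per-site, per-group log-scale total 16S loads — orders of magnitude lower
  in the upper gut of non-coprophagic (TC-F) mice;
* taxa with three behaviors: "fecal" taxa absent from the TC-F upper gut,
  "true small intestine" taxa (*Lactobacillales*-like) stable across groups,
  and taxa reduced only in the TC-F cecum;
* dietary plant-organellar signal (chloroplast / mitochondrial 16S) at a
  constant level per gram regardless of microbial load;
* reagent contaminants contributing a fixed ambient copy mass per reaction,
  so their read frequency is inversely proportional to sample DNA
  concentration;
* assay readouts: multinomial read counts, Poisson droplet partitioning
  (ddPCR), binomial serial-dilution wells (MPN), a linear Cq/log10-copies
  response with a standard series (qPCR), and bile-acid peak areas with
  internal standards, calibration series, QC injections and sensitivity
  drift.

The same seed always produces bit-identical outputs; every raw table
round-trips through the writers/readers in this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .samples import (
    COPROPHAGIC_GROUPS,
    GROUPS,
    SMALL_INTESTINE_SITES,
    UPPER_GIT_SITES,
    SampleRecord,
    read_metadata,
    write_metadata,
)
from .loads import DdpcrRun, MpnAssay, QpcrRun
from .profiling import Taxonomy, read_counts, write_counts
from .genes import MARKER_COLUMN

SITES_CONTENTS = ("STM", "SI1", "SI2", "SI3", "CEC", "COL")

# extraction bookkeeping (contents): mass extracted into a fixed elution volume
EXTRACT_MASS_G = 0.05
EXTRACT_VOLUME_UL = 100.0
SEQ_TEMPLATE_UL = 3.0
QPCR_TEMPLATE_UL = 1.5
#: fraction of 16S copies per g carried by culturable cells, and homogenate mL/g
CULTURABLE_FRACTION = 0.1
HOMOGENATE_ML_PER_G = 10.0

# bile-acid bookkeeping: extract = sample / dilution chain
BA_CHAIN_CONTENTS = 100.0   # x10 extraction, decant 10%, reconstitute at x100
BA_CHAIN_BILE = 10000.0     # x10 ethanol, x10 water predilution, then the chain
QC_POOL_UM = 2.0

BSH_KO = "K01442"
GUS_KO = "K01195"
ARYLSULF_KO = "K01130"
KO_IDS = (BSH_KO, GUS_KO, ARYLSULF_KO)


# ---------------------------------------------------------------------------
# configuration types


@dataclass
class TaxonSpec:
    """One simulated ASV and its behavior across groups and sites.

    ``site_log10_mean`` is the mean log10 relative propensity per site under
    coprophagic conditions (arbitrary units; per-sample propensities are
    closed to fractions). ``behavior`` modifies it per group:

    * ``fecal`` — true abundance exactly 0 in the TC-F upper GIT;
    * ``true_small_intestine`` — unchanged across groups;
    * ``cecum_shifted`` — mean reduced by ``tcf_cecum_drop`` in the TC-F
      cecum only;
    * ``dietary`` — plant-organellar: constant absolute copies per gram
      (``site_log10_mean`` is then log10 copies/g), independent of load.
    """

    name: str
    lineage: str
    behavior: str
    site_log10_mean: dict[str, float]
    copies_16s: float = 4.0
    gene_copies: dict[str, float] = field(default_factory=dict)
    log10_sd: float = 0.3
    tcf_cecum_drop: float = 1.0

    BEHAVIORS = ("fecal", "true_small_intestine", "cecum_shifted", "dietary")

    def __post_init__(self) -> None:
        if self.behavior not in self.BEHAVIORS:
            raise ValueError(f"taxon {self.name}: unknown behavior {self.behavior!r}")
        if self.copies_16s < 1:
            raise ValueError(f"taxon {self.name}: 16S copies per genome must be >= 1")

    def mean_log10(self, group: str, site: str) -> float:
        m = self.site_log10_mean[site]
        if self.behavior == "fecal" and group == "TC-F" and site in UPPER_GIT_SITES:
            return -math.inf
        if self.behavior == "cecum_shifted" and group == "TC-F" and site == "CEC":
            return m - self.tcf_cecum_drop
        return m


@dataclass
class ContaminantSpec:
    """A reagent contaminant: fixed ambient copies per sequencing reaction."""

    name: str
    lineage: str
    ambient_copies_per_rxn: float
    present_in_cecum: bool = False  # no true biological presence anywhere

    def __post_init__(self) -> None:
        if self.ambient_copies_per_rxn < 0:
            raise ValueError(f"contaminant {self.name}: ambient copies must be >= 0")
        if self.present_in_cecum:
            raise ValueError("contaminants have no true biological presence in cecum")


@dataclass
class AssayNoise:
    """Noise/design constants of the simulated assays (study defaults)."""

    cq_sd: float = 0.15
    qpcr_slope: float = -3.3219280948873623  # 100% efficiency
    qpcr_intercept: float = 38.0
    n_droplets: int = 20000
    droplet_volume_nl: float = 0.85
    mpn_dilutions: int = 8
    mpn_replicates: int = 8
    mpn_inoculum_ml: float = 0.01
    peak_area_cv: float = 0.05
    drift_slope: float = -0.002
    qc_every: int = 8

    def __post_init__(self) -> None:
        for name in ("cq_sd", "peak_area_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"assay_noise.{name} must be >= 0")
        if self.n_droplets < 1 or self.mpn_dilutions < 1 or self.mpn_replicates < 1:
            raise ValueError("assay design counts must be >= 1")


@dataclass
class SimulationConfig:
    n_mice_per_group: int = 6
    groups: tuple[str, ...] = GROUPS
    sites: tuple[str, ...] = SITES_CONTENTS
    seed: int = 0
    sequencing_depth: int = 10_000
    taxon_panel: list[TaxonSpec] = field(default_factory=lambda: default_taxon_panel())
    contaminant_panel: list[ContaminantSpec] = field(
        default_factory=lambda: default_contaminant_panel()
    )
    load_model: dict = field(default_factory=lambda: default_load_model())
    bileacid_model: dict = field(default_factory=lambda: default_bileacid_model())
    assay_noise: AssayNoise = field(default_factory=AssayNoise)
    count_model: str = "multinomial"  # multinomial | dirichlet_multinomial | expected
    overdispersion: float = 0.0  # Dirichlet-multinomial scale (0 = off)
    include_mucosa: bool = True
    include_bileacids: bool = True
    load_log10_sd: float = 0.4

    def validate(self) -> None:
        if self.n_mice_per_group < 1:
            raise ValueError("invalid config field n_mice_per_group: must be >= 1")
        if self.sequencing_depth < 1:
            raise ValueError("invalid config field sequencing_depth: must be >= 1")
        if self.count_model not in ("multinomial", "dirichlet_multinomial", "expected"):
            raise ValueError(f"invalid config field count_model: {self.count_model!r}")
        if self.load_log10_sd < 0:
            raise ValueError("invalid config field load_log10_sd: must be >= 0")
        if self.overdispersion < 0:
            raise ValueError("invalid config field overdispersion: must be >= 0")
        for g in self.groups:
            if g not in GROUPS:
                raise ValueError(f"invalid config field groups: unknown group {g!r}")
        for s in self.sites:
            if s not in SITES_CONTENTS:
                raise ValueError(f"invalid config field sites: unknown site {s!r}")
        for (g, s), (mu, sd) in self.load_model.items():
            if sd is not None and sd < 0:
                raise ValueError(f"invalid config field load_model: SD < 0 at {(g, s)}")
        for (g, s), (total, fu, fs) in self.bileacid_model.items():
            if not (0 <= fu <= 1 and 0 <= fs <= 1):
                raise ValueError(
                    f"invalid config field bileacid_model: fraction outside [0,1] at {(g, s)}"
                )
            if total < 0:
                raise ValueError(f"invalid config field bileacid_model: total < 0 at {(g, s)}")

    def noise_free(self) -> "SimulationConfig":
        """A copy with every noise source off (exact expected readouts)."""
        return replace(
            self,
            count_model="expected",
            load_log10_sd=0.0,
            contaminant_panel=[],
            assay_noise=replace(
                self.assay_noise, cq_sd=0.0, peak_area_cv=0.0, drift_slope=0.0
            ),
        )


# ---------------------------------------------------------------------------
# study defaults


def default_taxon_panel() -> list[TaxonSpec]:
    def lin(p, c, o, f, g):
        return f"d__Bacteria;p__{p};c__{c};o__{o};f__{f};g__{g};s__"

    flat = {s: 3.0 for s in SITES_CONTENTS}
    lacto = {"STM": 2.8, "SI1": 2.6, "SI2": 2.6, "SI3": 2.6, "CEC": 2.2, "COL": 2.2}
    beta = {"STM": 1.0, "SI1": 1.0, "SI2": 1.0, "SI3": 1.2, "CEC": 2.5, "COL": 2.5}
    panel = [
        TaxonSpec("ASV_clost1", lin("Firmicutes", "Clostridia", "Clostridiales",
                  "Lachnospiraceae", "Roseburia"), "fecal", dict(flat), 6,
                  {BSH_KO: 2, GUS_KO: 2, ARYLSULF_KO: 1}),
        TaxonSpec("ASV_clost2", lin("Firmicutes", "Clostridia", "Clostridiales",
                  "Ruminococcaceae", "Faecalibacterium"), "fecal", dict(flat), 5,
                  {BSH_KO: 2, GUS_KO: 1, ARYLSULF_KO: 1}),
        TaxonSpec("ASV_bact1", lin("Bacteroidetes", "Bacteroidia", "Bacteroidales",
                  "Bacteroidaceae", "Bacteroides"), "fecal", dict(flat), 4,
                  {BSH_KO: 2, GUS_KO: 3, ARYLSULF_KO: 1}),
        TaxonSpec("ASV_bact2", lin("Bacteroidetes", "Bacteroidia", "Bacteroidales",
                  "Muribaculaceae", "Muribaculum"), "fecal", dict(flat), 4,
                  {BSH_KO: 1, GUS_KO: 2, ARYLSULF_KO: 0}),
        TaxonSpec("ASV_erysi1", lin("Firmicutes", "Erysipelotrichia",
                  "Erysipelotrichales", "Erysipelotrichaceae", "Turicibacter"),
                  "fecal", dict(flat), 5, {BSH_KO: 1, GUS_KO: 0, ARYLSULF_KO: 0}),
        TaxonSpec("ASV_lacto1", lin("Firmicutes", "Bacilli", "Lactobacillales",
                  "Lactobacillaceae", "Lactobacillus"), "true_small_intestine",
                  dict(lacto), 5, {BSH_KO: 1, GUS_KO: 0, ARYLSULF_KO: 0}),
        TaxonSpec("ASV_lacto2", lin("Firmicutes", "Bacilli", "Lactobacillales",
                  "Lactobacillaceae", "Ligilactobacillus"), "true_small_intestine",
                  {k: v - 0.4 for k, v in lacto.items()}, 6,
                  {BSH_KO: 1, GUS_KO: 0, ARYLSULF_KO: 0}),
        TaxonSpec("ASV_beta1", lin("Proteobacteria", "Gammaproteobacteria",
                  "Betaproteobacteriales", "Burkholderiaceae", "Parasutterella"),
                  "cecum_shifted", dict(beta), 3, {BSH_KO: 0, GUS_KO: 1, ARYLSULF_KO: 0}),
        TaxonSpec("ASV_chloro", "d__Eukaryota;p__Streptophyta;c__;o__Chloroplast;f__;g__;s__",
                  "dietary", {s: 6.5 for s in SITES_CONTENTS}, 1, {}),
        TaxonSpec("ASV_mito", lin("Proteobacteria", "Alphaproteobacteria",
                  "Rickettsiales", "Mitochondria", "Mitochondria"),
                  "dietary", {s: 6.0 for s in SITES_CONTENTS}, 1, {}),
    ]
    return panel


def default_contaminant_panel() -> list[ContaminantSpec]:
    def lin(p, c, o, f, g):
        return f"d__Bacteria;p__{p};c__{c};o__{o};f__{f};g__{g};s__"

    return [
        ContaminantSpec("ASV_cont_ralstonia", lin("Proteobacteria",
                        "Gammaproteobacteria", "Betaproteobacteriales",
                        "Burkholderiaceae", "Ralstonia"), 30.0),
        ContaminantSpec("ASV_cont_sphingo", lin("Proteobacteria",
                        "Alphaproteobacteria", "Sphingomonadales",
                        "Sphingomonadaceae", "Sphingomonas"), 20.0),
        ContaminantSpec("ASV_cont_brady", lin("Proteobacteria",
                        "Alphaproteobacteria", "Rhizobiales",
                        "Xanthobacteraceae", "Bradyrhizobium"), 10.0),
    ]


def default_load_model() -> dict:
    """(group, site) -> (mean log10 16S copies/g, SD is config-level).

    Coprophagic groups carry fecal-level loads throughout; TC-F mice are
    ~3 orders of magnitude lower in the upper GIT, unchanged in the lower.
    """
    copro = {"STM": 8.3, "SI1": 8.0, "SI2": 8.5, "SI3": 9.0, "CEC": 10.5, "COL": 10.5}
    tcf = {"STM": 5.3, "SI1": 5.0, "SI2": 5.5, "SI3": 6.5, "CEC": 10.4, "COL": 10.4}
    model = {}
    for site in SITES_CONTENTS:
        for g in COPROPHAGIC_GROUPS:
            model[(g, site)] = (copro[site], None)
        model[("TC-F", site)] = (tcf[site], None)
    return model


def default_bileacid_model() -> dict:
    """(group, site) -> (total pool, fraction unconjugated, fraction secondary).

    Totals in nmol/g for lumenal contents and uM (nmol/mL) for bile; highest
    in the small intestine, ~10x lower in the large intestine. Coprophagic
    mice deconjugate progressively down the small intestine; TC-F mice keep
    nearly the whole small-intestine pool conjugated and carry a smaller
    secondary fraction everywhere.
    """
    totals = {"STM": 500.0, "SI1": 2500.0, "SI2": 2000.0, "SI3": 1500.0,
              "CEC": 200.0, "COL": 150.0, "BILE": 25000.0}
    fu_copro = {"STM": 0.30, "SI1": 0.12, "SI2": 0.28, "SI3": 0.50,
                "CEC": 0.70, "COL": 0.75, "BILE": 0.04}
    fu_tcf = {"STM": 0.04, "SI1": 0.01, "SI2": 0.012, "SI3": 0.02,
              "CEC": 0.30, "COL": 0.35, "BILE": 0.01}
    fs_copro, fs_tcf = 0.30, 0.08
    model = {}
    for site in totals:
        for g in COPROPHAGIC_GROUPS:
            model[(g, site)] = (totals[site], fu_copro[site], fs_copro)
        model[("TC-F", site)] = (totals[site], fu_tcf[site], fs_tcf)
    return model


#: within-class species weights used to split each bile-acid pool
BA_SPECIES_WEIGHTS = {
    ("tauro", "primary"): {"TCA": 0.65, "TbMCA": 0.35},
    ("tauro", "secondary"): {"TDCA": 0.6, "TwMCA": 0.4},
    ("unconjugated", "primary"): {"CA": 0.6, "bMCA": 0.4},
    ("unconjugated", "secondary"): {"DCA": 0.5, "wMCA": 0.3, "UDCA": 0.1, "HDCA": 0.1},
}

#: instrument response factors (area counts per uM), fixed study-wide
BA_RESPONSE_FACTORS = {
    "TCA": 11000.0, "TbMCA": 9000.0, "TDCA": 12000.0, "TwMCA": 8500.0,
    "CA": 10000.0, "bMCA": 9500.0, "DCA": 13000.0, "wMCA": 8000.0,
    "UDCA": 10500.0, "HDCA": 9800.0,
    "D4-TCA": 10800.0, "D4-TDCA": 11800.0, "D4-CA": 9900.0, "D4-DCA": 12700.0,
    "D4-GUDCA": 10200.0, "D4-GCA": 10000.0, "D4-GDCA": 11000.0,
    "D4-GCDCA": 10000.0, "D4-GLCA": 10000.0,
}

BA_IS_MAP = {
    "TCA": "D4-TCA", "TbMCA": "D4-TCA", "TDCA": "D4-TDCA", "TwMCA": "D4-TDCA",
    "CA": "D4-CA", "bMCA": "D4-CA", "DCA": "D4-DCA", "wMCA": "D4-DCA",
    "UDCA": "D4-GUDCA", "HDCA": "D4-GUDCA",
}

CAL_LEVELS_UM = (0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 30.0)


# ---------------------------------------------------------------------------
# assay-level generators


def gen_ddpcr_run(
    true_conc_per_ul: float,
    rng: np.random.Generator,
    n_droplets: int = 20000,
    droplet_volume_nl: float = 0.85,
    dilution: float = 1.0,
    sample_id: str = "sim",
    exact: bool = False,
) -> DdpcrRun:
    """Poisson droplet partitioning: each droplet positive with
    probability 1 - exp(-conc * droplet volume / dilution)."""
    if true_conc_per_ul < 0:
        raise ValueError("true concentration must be >= 0")
    lam = true_conc_per_ul / dilution * droplet_volume_nl * 1e-3
    p_pos = -math.expm1(-lam)
    if exact:
        k = int(round(n_droplets * p_pos))
    else:
        k = int(rng.binomial(n_droplets, p_pos))
    return DdpcrRun(sample_id, n_droplets, k, droplet_volume_nl, dilution=dilution)


def gen_mpn_plate(
    true_density_per_ml: float,
    rng: np.random.Generator,
    n_dilutions: int = 8,
    n_replicates: int = 8,
    inoculum_ml: float = 0.01,
    dilution_factor: float = 10.0,
    sample_id: str = "sim",
) -> MpnAssay:
    """Binomial wells: positive with probability 1 - exp(-density * volume),
    across consecutive serial dilutions of the sample."""
    if true_density_per_ml < 0:
        raise ValueError("true density must be >= 0")
    volumes, ns, ps = [], [], []
    for i in range(1, n_dilutions + 1):
        v = inoculum_ml * dilution_factor ** (-i)
        p_pos = -math.expm1(-true_density_per_ml * v)
        volumes.append(v)
        ns.append(n_replicates)
        ps.append(int(rng.binomial(n_replicates, p_pos)))
    return MpnAssay(sample_id, volumes, ns, ps)


def gen_qpcr_run(
    true_copies_per_rxn: float,
    rng: np.random.Generator,
    cq_sd: float = 0.15,
    slope: float = -3.3219280948873623,
    intercept: float = 38.0,
    n_replicates: int = 3,
    standard_copies: Sequence[float] = tuple(10.0**k for k in range(2, 9)),
    sample_id: str = "sim",
) -> QpcrRun:
    """Triplicate Cq ~ Normal(intercept + slope*log10(copies), cq_sd), plus a
    10-fold standard-dilution series measured with the same noise."""
    if true_copies_per_rxn <= 0:
        raise ValueError("true copies per reaction must be > 0")
    mean_cq = intercept + slope * math.log10(true_copies_per_rxn)
    cqs = mean_cq + cq_sd * rng.standard_normal(n_replicates)
    standards = []
    for c in standard_copies:
        cq = intercept + slope * math.log10(c) + cq_sd * rng.standard_normal()
        standards.append((float(c), float(cq)))
    return QpcrRun(sample_id, [float(c) for c in cqs], standards,
                   template_volume_ul=QPCR_TEMPLATE_UL)


def gen_bileacid_run(
    true_pools: pd.DataFrame,
    rng: np.random.Generator,
    drift_slope: float = -0.002,
    qc_every: int = 8,
    peak_area_cv: float = 0.05,
    dilution_factors: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Long-format peak-area table for one LC-MS run.

    ``true_pools``: rows = samples, columns = species, values = sample-level
    concentration (nmol/g or uM); ``dilution_factors`` maps sample to the
    chain factor from sample to extract. Calibration series are injected at
    the start, middle and end of the run; pooled-QC injections every
    ``qc_every`` injections; internal standards ride at 5 uM in every
    injection. Analyte area = response factor x extract concentration x
    (1 + drift_slope x injection index) x log-normal noise.
    """
    dilution_factors = dilution_factors or {}
    species = list(true_pools.columns)
    sample_ids = list(true_pools.index)

    # injection order: [std series 1] samples(1st half) [std series 2]
    # samples(2nd half) [std series 3], with QCs interleaved every qc_every
    cal_series = [("standard", c) for c in CAL_LEVELS_UM]
    half = len(sample_ids) // 2
    payload = (
        cal_series
        + [("sample", s) for s in sample_ids[:half]]
        + cal_series
        + [("sample", s) for s in sample_ids[half:]]
        + cal_series
    )
    rows = []
    idx = 0
    n_since_qc = qc_every  # force a QC at injection 0

    def emit(kind, ident, concs):
        nonlocal idx
        drift = 1.0 + drift_slope * idx
        for sp in species:
            rf = BA_RESPONSE_FACTORS[sp]
            noise = math.exp(rng.normal(0.0, peak_area_cv)) if peak_area_cv > 0 else 1.0
            area = rf * concs.get(sp, 0.0) * drift * noise
            is_id = BA_IS_MAP[sp]
            is_noise = math.exp(rng.normal(0.0, peak_area_cv)) if peak_area_cv > 0 else 1.0
            is_area = BA_RESPONSE_FACTORS[is_id] * 5.0 * drift * is_noise
            rows.append(
                {
                    "injection_index": idx,
                    "sample_id": ident,
                    "injection_type": kind,
                    "standard_conc_uM": concs.get(sp, 0.0) if kind == "standard" else np.nan,
                    "species": sp,
                    "area": area,
                    "is_id": is_id,
                    "is_area": is_area,
                }
            )
        idx += 1

    for kind, ident in payload:
        if n_since_qc >= qc_every:
            emit("qc", f"QC_{idx}", {sp: QC_POOL_UM for sp in species})
            n_since_qc = 0
        if kind == "standard":
            emit("standard", f"STD_{ident}_{idx}", {sp: float(ident) for sp in species})
        else:
            chain = dilution_factors.get(ident, BA_CHAIN_CONTENTS)
            concs = {sp: float(true_pools.loc[ident, sp]) / chain for sp in species}
            emit("sample", ident, concs)
        n_since_qc += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-study generation


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    metadata: list[SampleRecord]
    truth_absolute: pd.DataFrame  # content samples x taxa, copies/g
    truth_loads: pd.Series  # content samples: total copies/g (incl. dietary)
    truth_mucosal_loads: pd.Series  # mucosal samples: copies/100 ng DNA
    truth_culturable: pd.Series  # content samples: culturable cells/mL homogenate
    truth_bileacids: pd.DataFrame  # sample x (total, frac_unconj, frac_secondary)
    asv_counts: pd.DataFrame  # content samples x ASVs (incl. contaminants)
    taxonomy: Taxonomy
    gene_copy_table: pd.DataFrame
    qpcr_runs: list[QpcrRun]
    ddpcr_runs: list[DdpcrRun]
    mpn_plates: list[MpnAssay]
    bileacid_areas: pd.DataFrame


def _sample_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, *key])


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from the ground-truth model."""
    config.validate()
    noise = config.assay_noise
    taxa = config.taxon_panel
    contams = config.contaminant_panel
    taxon_names = [t.name for t in taxa]
    all_names = taxon_names + [c.name for c in contams]

    metadata: list[SampleRecord] = []
    truth_abs_rows, truth_loads, truth_cult = {}, {}, {}
    truth_muc = {}
    counts_rows = {}
    qpcr_runs, ddpcr_runs, mpn_plates = [], [], []
    ba_truth_rows = {}
    ba_samples, ba_dilutions = {}, {}

    mouse_index = 0
    for g_i, group in enumerate(config.groups):
        for m in range(config.n_mice_per_group):
            mouse_id = f"M{mouse_index:02d}"
            mouse_index += 1
            for s_i, site in enumerate(config.sites):
                sid = f"{mouse_id}_{site}_CNT"
                rng = _sample_rng(config.seed, 1, g_i, m, s_i)
                mu, sd = config.load_model[(group, site)]
                if sd is None:
                    sd = config.load_log10_sd
                log10_load = mu + sd * rng.standard_normal()
                microbial_load = 10.0**log10_load

                # per-taxon propensities -> true absolute abundances
                abs_per_g = {}
                weights = {}
                for t in taxa:
                    if t.behavior == "dietary":
                        continue
                    mlog = t.mean_log10(group, site)
                    if mlog == -math.inf:
                        weights[t.name] = 0.0
                    else:
                        weights[t.name] = 10.0 ** (
                            mlog + t.log10_sd * rng.standard_normal()
                        )
                wsum = sum(weights.values())
                for t in taxa:
                    if t.behavior == "dietary":
                        abs_per_g[t.name] = 10.0 ** (
                            t.site_log10_mean[site]
                            + t.log10_sd * rng.standard_normal()
                        )
                    else:
                        abs_per_g[t.name] = microbial_load * weights[t.name] / wsum
                total_per_g = sum(abs_per_g.values())

                extract_conc = total_per_g * EXTRACT_MASS_G / EXTRACT_VOLUME_UL
                dna_conc = extract_conc / 2e5  # ng/uL-equivalent, proportional
                rec = SampleRecord(
                    sid, mouse_id, group, site, "contents",
                    mass_g=EXTRACT_MASS_G, dilution_factor=EXTRACT_VOLUME_UL,
                    dna_conc_ng_ul=dna_conc,
                )
                metadata.append(rec)
                truth_abs_rows[sid] = dict(abs_per_g, **{c.name: 0.0 for c in contams})
                truth_loads[sid] = total_per_g

                # sequencing reaction composition: sample template + ambient mass
                copies_rxn = {
                    n: abs_per_g[n] * EXTRACT_MASS_G / EXTRACT_VOLUME_UL * SEQ_TEMPLATE_UL
                    for n in taxon_names
                }
                for c in contams:
                    copies_rxn[c.name] = c.ambient_copies_per_rxn
                tot = sum(copies_rxn.values())
                p = np.array([copies_rxn[n] / tot for n in all_names])
                if config.count_model == "expected":
                    counts = p * config.sequencing_depth
                elif config.count_model == "dirichlet_multinomial" and config.overdispersion > 0:
                    alpha = p / config.overdispersion
                    pd_ = rng.dirichlet(np.maximum(alpha, 1e-12))
                    counts = rng.multinomial(config.sequencing_depth, pd_).astype(float)
                else:
                    counts = rng.multinomial(config.sequencing_depth, p).astype(float)
                counts_rows[sid] = dict(zip(all_names, counts))

                # load assays
                qpcr_runs.append(
                    gen_qpcr_run(
                        extract_conc * QPCR_TEMPLATE_UL, rng, cq_sd=noise.cq_sd,
                        slope=noise.qpcr_slope, intercept=noise.qpcr_intercept,
                        sample_id=sid,
                    )
                )
                ddpcr_runs.append(
                    _autodiluted_ddpcr(extract_conc, rng, noise, sid,
                                       exact=config.count_model == "expected")
                )
                density = (
                    microbial_load * CULTURABLE_FRACTION / HOMOGENATE_ML_PER_G
                )
                truth_cult[sid] = density
                mpn_plates.append(
                    gen_mpn_plate(
                        density, rng, noise.mpn_dilutions, noise.mpn_replicates,
                        noise.mpn_inoculum_ml, sample_id=sid,
                    )
                )

                if config.include_bileacids and (group, site) in config.bileacid_model:
                    _add_bileacid_sample(
                        sid, group, site, "contents", config, rng,
                        ba_truth_rows, ba_samples, ba_dilutions,
                    )

            # mucosa (mid-small intestine) and gallbladder bile, one per mouse
            rng = _sample_rng(config.seed, 2, g_i, m)
            if config.include_mucosa and "SI2" in config.sites:
                sid = f"{mouse_id}_SI2_MUC"
                lum = truth_loads[f"{mouse_id}_SI2_CNT"]
                log10_muc = math.log10(lum) - 2.0 + 0.45 * rng.standard_normal()
                per100ng = 10.0**log10_muc
                dna_input = 250.0
                dna_conc = dna_input / EXTRACT_VOLUME_UL
                extract_conc = per100ng * dna_conc / 100.0
                rec = SampleRecord(
                    sid, mouse_id, group, "SI2", "mucosa",
                    dna_input_ng=dna_input, dilution_factor=EXTRACT_VOLUME_UL,
                    dna_conc_ng_ul=dna_conc,
                )
                metadata.append(rec)
                truth_muc[sid] = per100ng
                qpcr_runs.append(
                    gen_qpcr_run(
                        extract_conc * QPCR_TEMPLATE_UL, rng, cq_sd=noise.cq_sd,
                        slope=noise.qpcr_slope, intercept=noise.qpcr_intercept,
                        sample_id=sid,
                    )
                )
                ddpcr_runs.append(
                    _autodiluted_ddpcr(extract_conc, rng, noise, sid,
                                       exact=config.count_model == "expected")
                )
            if config.include_bileacids and (group, "BILE") in config.bileacid_model:
                sid = f"{mouse_id}_BILE"
                metadata.append(
                    SampleRecord(sid, mouse_id, group, "BILE", "bile",
                                 mass_g=None, dilution_factor=BA_CHAIN_BILE)
                )
                _add_bileacid_sample(
                    sid, group, "BILE", "bile", config, rng,
                    ba_truth_rows, ba_samples, ba_dilutions,
                )

    truth_absolute = pd.DataFrame.from_dict(truth_abs_rows, orient="index")[all_names]
    asv_counts = pd.DataFrame.from_dict(counts_rows, orient="index")[all_names]

    taxonomy = Taxonomy.from_strings(
        {**{t.name: t.lineage for t in taxa}, **{c.name: c.lineage for c in contams}}
    )
    gene_rows = {}
    for t in taxa:
        gene_rows[t.name] = {k: float(t.gene_copies.get(k, 0.0)) for k in KO_IDS}
        gene_rows[t.name][MARKER_COLUMN] = float(t.copies_16s)
    for c in contams:
        gene_rows[c.name] = {k: 0.0 for k in KO_IDS}
        gene_rows[c.name][MARKER_COLUMN] = 2.0
    gene_copy_table = pd.DataFrame.from_dict(gene_rows, orient="index")

    if ba_samples:
        pools = pd.DataFrame.from_dict(ba_samples, orient="index")
        rng = _sample_rng(config.seed, 3)
        ba_areas = gen_bileacid_run(
            pools, rng, drift_slope=noise.drift_slope, qc_every=noise.qc_every,
            peak_area_cv=noise.peak_area_cv, dilution_factors=ba_dilutions,
        )
        truth_ba = pd.DataFrame.from_dict(ba_truth_rows, orient="index")
    else:
        ba_areas = pd.DataFrame()
        truth_ba = pd.DataFrame()

    return SyntheticStudy(
        config, metadata, truth_absolute, pd.Series(truth_loads),
        pd.Series(truth_muc, dtype=float), pd.Series(truth_cult),
        truth_ba, asv_counts, taxonomy, gene_copy_table,
        qpcr_runs, ddpcr_runs, mpn_plates, ba_areas,
    )


def _autodiluted_ddpcr(extract_conc, rng, noise: AssayNoise, sid, exact=False) -> DdpcrRun:
    """Dilute the template into the quantifiable droplet range (as a bench
    scientist would), recording the dilution on the run."""
    vol_ul = noise.droplet_volume_nl * 1e-3
    lam = extract_conc * vol_ul
    dilution = 10.0 ** max(0, math.ceil(math.log10(lam / 0.35))) if lam > 0.35 else 1.0
    return gen_ddpcr_run(
        extract_conc, rng, noise.n_droplets, noise.droplet_volume_nl,
        dilution, sid, exact=exact,
    )


def _add_bileacid_sample(sid, group, site, material, config, rng,
                         truth_rows, samples, dilutions) -> None:
    total0, fu0, fs0 = config.bileacid_model[(group, site)]
    jitter = config.assay_noise.peak_area_cv > 0 or config.load_log10_sd > 0
    if jitter:
        total = total0 * math.exp(rng.normal(0.0, 0.25))
        fu = _logit_jitter(fu0, 0.25, rng)
        fs = _logit_jitter(fs0, 0.25, rng)
    else:
        total, fu, fs = total0, fu0, fs0
    pools = {
        ("tauro", "primary"): total * (1 - fu) * (1 - fs),
        ("tauro", "secondary"): total * (1 - fu) * fs,
        ("unconjugated", "primary"): total * fu * (1 - fs),
        ("unconjugated", "secondary"): total * fu * fs,
    }
    species_conc = {}
    for key, pool in pools.items():
        for sp, w in BA_SPECIES_WEIGHTS[key].items():
            species_conc[sp] = pool * w
    truth_rows[sid] = {
        "total": total, "fraction_unconjugated": fu, "fraction_secondary": fs,
    }
    samples[sid] = species_conc
    dilutions[sid] = BA_CHAIN_BILE if material == "bile" else BA_CHAIN_CONTENTS


def _logit_jitter(p: float, sd: float, rng) -> float:
    p = min(max(p, 1e-6), 1 - 1e-6)
    z = math.log(p / (1 - p)) + rng.normal(0.0, sd)
    return 1.0 / (1.0 + math.exp(-z))


# ---------------------------------------------------------------------------
# writers / readers (round-trip guaranteed)


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["metadata"] = outdir / "metadata.tsv"
    write_metadata(study.metadata, paths["metadata"])

    paths["counts"] = outdir / "asv_counts.tsv"
    write_counts(study.asv_counts, paths["counts"])

    paths["taxonomy"] = outdir / "taxonomy.tsv"
    study.taxonomy.write(paths["taxonomy"])

    paths["gene_copies"] = outdir / "gene_copies.tsv"
    gc = study.gene_copy_table.copy()
    gc.index.name = "asv_id"
    gc.to_csv(paths["gene_copies"], sep="\t")

    paths["qpcr"] = outdir / "qpcr.csv"
    write_qpcr_runs(study.qpcr_runs, paths["qpcr"])

    paths["ddpcr"] = outdir / "ddpcr.csv"
    write_ddpcr_runs(study.ddpcr_runs, paths["ddpcr"])

    paths["mpn"] = outdir / "mpn.csv"
    write_mpn_plates(study.mpn_plates, paths["mpn"])

    if len(study.bileacid_areas):
        paths["bileacid_areas"] = outdir / "bileacid_areas.csv"
        study.bileacid_areas.to_csv(paths["bileacid_areas"], index=False)

    # ground-truth bundle for tests
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    t = study.truth_absolute.copy()
    t.index.name = "sample_id"
    t.to_csv(truth_dir / "absolute.tsv", sep="\t")
    study.truth_loads.rename("total_copies_per_g").rename_axis("sample_id").to_csv(
        truth_dir / "loads.tsv", sep="\t"
    )
    study.truth_mucosal_loads.rename("copies_per_100ng").rename_axis("sample_id").to_csv(
        truth_dir / "mucosal_loads.tsv", sep="\t"
    )
    study.truth_culturable.rename("cells_per_ml").rename_axis("sample_id").to_csv(
        truth_dir / "culturable.tsv", sep="\t"
    )
    if len(study.truth_bileacids):
        tb = study.truth_bileacids.copy()
        tb.index.name = "sample_id"
        tb.to_csv(truth_dir / "bileacids.tsv", sep="\t")
    paths["truth"] = truth_dir
    return paths


def write_qpcr_runs(runs: Sequence[QpcrRun], path) -> None:
    rows = []
    for r in runs:
        for i, cq in enumerate(r.cq_values):
            rows.append({"sample_id": r.sample_id, "record": "sample",
                         "replicate": i, "copies": np.nan, "cq": cq})
        for c, cq in r.standards:
            rows.append({"sample_id": r.sample_id, "record": "standard",
                         "replicate": -1, "copies": c, "cq": cq})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_qpcr_runs(path) -> list[QpcrRun]:
    df = pd.read_csv(path)
    runs = []
    for sid, sub in df.groupby("sample_id", sort=False):
        cqs = sub[sub["record"] == "sample"].sort_values("replicate")["cq"].tolist()
        std = sub[sub["record"] == "standard"]
        standards = list(zip(std["copies"].astype(float), std["cq"].astype(float)))
        runs.append(QpcrRun(sid, cqs, standards, template_volume_ul=QPCR_TEMPLATE_UL))
    return runs


def write_ddpcr_runs(runs: Sequence[DdpcrRun], path) -> None:
    pd.DataFrame(
        [
            {"sample_id": r.sample_id, "n_droplets": r.n_droplets,
             "n_positive": r.n_positive, "droplet_volume_nl": r.droplet_volume_nl,
             "dilution": r.dilution}
            for r in runs
        ]
    ).to_csv(path, index=False)


def read_ddpcr_runs(path) -> list[DdpcrRun]:
    df = pd.read_csv(path)
    return [
        DdpcrRun(r.sample_id, int(r.n_droplets), int(r.n_positive),
                 float(r.droplet_volume_nl), dilution=float(r.dilution))
        for r in df.itertuples()
    ]


def write_mpn_plates(plates: Sequence[MpnAssay], path) -> None:
    rows = []
    for a in plates:
        for i, (v, n, p) in enumerate(zip(a.volumes_ml, a.n_wells, a.n_positive)):
            rows.append({"sample_id": a.sample_id, "dilution_index": i,
                         "volume_ml": v, "n_wells": n, "n_positive": p})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mpn_plates(path) -> list[MpnAssay]:
    df = pd.read_csv(path)
    plates = []
    for sid, sub in df.groupby("sample_id", sort=False):
        sub = sub.sort_values("dilution_index")
        plates.append(
            MpnAssay(sid, sub["volume_ml"].tolist(), sub["n_wells"].astype(int).tolist(),
                     sub["n_positive"].astype(int).tolist())
        )
    return plates
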