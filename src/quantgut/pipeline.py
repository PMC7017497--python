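"""End-to-end orchestration: simulate -> loads -> profile -> genes -> bile acids -> stats.

A run is driven by a single config mapping (YAML on disk), executes the
stages in dependency order on one input directory, and records a manifest
(config hash, seed, per-stage outputs with row counts and checksums) so that
identical config + inputs reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .samples import SampleRecord, read_metadata
from . import bileacids, genes, loads, profiling, simulate, stats


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "n_mice_per_group": 6,
    "sequencing_depth": 10000,
    "collapse_level": "order",
    "contaminant_score_threshold": 0.5,
    "keep_organellar": False,
    "load_method": "qpcr",  # which assay anchors absolute abundances
    "pca_components": 2,
}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, path: Path, n_rows: int) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.stages[stage] = {
            "path": str(path), "rows": int(n_rows), "sha256": digest,
        }

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "version": self.version,
                    "stages": self.stages,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def load_config(path=None) -> dict:
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        config.update(user)
    return config


# ---------------------------------------------------------------------------
# stages


def stage_simulate(config: dict, outdir: Path) -> dict[str, Path]:
    sim = simulate.SimulationConfig(
        seed=int(config["seed"]),
        n_mice_per_group=int(config["n_mice_per_group"]),
        sequencing_depth=int(config["sequencing_depth"]),
    )
    study = simulate.generate_study(sim)
    return simulate.write_study(study, outdir)


def stage_quantify_loads(
    qpcr_path, ddpcr_path, mpn_path, metadata_path, out_path
) -> pd.DataFrame:
    metadata = {r.sample_id: r for r in read_metadata(metadata_path)}
    estimates = []
    if qpcr_path is not None and Path(qpcr_path).exists():
        for run in simulate.read_qpcr_runs(qpcr_path):
            est = loads.quantify_qpcr(run)
            est = loads.to_extract_concentration(est, run.template_volume_ul)
            estimates.append(loads.normalize_load(est, metadata[run.sample_id]))
    if ddpcr_path is not None and Path(ddpcr_path).exists():
        for run in simulate.read_ddpcr_runs(ddpcr_path):
            est = loads.quantify_ddpcr(run)
            estimates.append(loads.normalize_load(est, metadata[run.sample_id]))
    if mpn_path is not None and Path(mpn_path).exists():
        for plate in simulate.read_mpn_plates(mpn_path):
            est = loads.estimate_mpn(plate)
            rec = metadata[plate.sample_id]
            factor = (rec.mass_g or 0.05) * simulate.HOMOGENATE_ML_PER_G
            estimates.append(loads.normalize_load(est, rec, factor=factor))
    loads.write_loads(estimates, out_path)
    return loads.loads_to_frame(estimates)


def stage_profile(
    counts_path, taxonomy_path, loads_path, metadata_path, outdir: Path,
    level: str = "order", threshold: float = 0.5, keep_organellar: bool = False,
    load_method: str = "qpcr",
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = profiling.read_counts(counts_path)
    taxonomy = profiling.Taxonomy.read(taxonomy_path)
    metadata = read_metadata(metadata_path)
    load_by_sample = {
        e.sample_id: e
        for e in loads.read_loads(loads_path)
        if e.method == load_method
    }
    missing = [s for s in counts.index if s not in load_by_sample]
    if missing:
        raise ValueError(
            f"profile stage: no {load_method} load for sample(s) {missing[:5]}"
        )
    dna_conc = pd.Series(
        {r.sample_id: r.dna_conc_ng_ul for r in metadata if r.dna_conc_ng_ul}
    )

    relative = profiling.to_relative(counts)
    prev_calls = profiling.flag_contaminants_prevalence(counts, metadata)
    kept = relative.drop(columns=[c.taxon for c in prev_calls])
    freq_calls = profiling.score_contaminant_frequency(
        kept, dna_conc.reindex(kept.index), threshold=threshold
    )
    calls = prev_calls + freq_calls

    filtered_rel = profiling.remove_contaminants(
        relative, calls, keep_organellar=keep_organellar, is_relative=True
    )
    depths = counts.sum(axis=1)
    absolute = profiling.to_absolute(filtered_rel, load_by_sample, depths=depths)
    abs_level = profiling.collapse_taxa(absolute.values, taxonomy, level)
    rel_level = profiling.collapse_taxa(filtered_rel, taxonomy, level)

    paths = {}
    for name, frame in (
        ("absolute_asv", absolute.values), ("absolute_flags", absolute.flags),
        (f"absolute_{level}", abs_level), (f"relative_{level}", rel_level),
    ):
        p = outdir / f"{name}.tsv"
        out = frame.copy()
        out.index.name = "sample_id"
        out.to_csv(p, sep="\t")
        paths[name] = p
    calls_frame = pd.DataFrame(
        [{"taxon": c.taxon, "flagged_by": c.flagged_by, "score": c.score} for c in calls]
    )
    p = outdir / "contaminant_calls.tsv"
    calls_frame.to_csv(p, sep="\t", index=False)
    paths["contaminant_calls"] = p
    return paths


def stage_genes(absolute_path, gene_copies_path, out_path) -> pd.DataFrame:
    absolute = pd.read_csv(absolute_path, sep="\t", index_col=0)
    gct = genes.read_gene_copy_table(gene_copies_path)
    gene_abs = genes.scale_gene_content(absolute, gct.reindex(absolute.columns).dropna())
    out = gene_abs.copy()
    out.index.name = "sample_id"
    out.to_csv(out_path, sep="\t")
    return gene_abs


def stage_bileacids(areas_path, metadata_path, outdir: Path, panel_path=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = bileacids.load_panel(panel_path)
    areas = bileacids.read_areas(areas_path)
    metadata = read_metadata(metadata_path)
    corrected = bileacids.correct_drift(areas)
    fits = bileacids.fit_calibration(corrected)
    conc = bileacids.quantify(corrected, fits, metadata, panel)
    summary = bileacids.summarize_profile(conc, panel)
    cpath = outdir / "bileacid_concentrations.tsv"
    v = conc.values.copy()
    v.index.name = "sample_id"
    v.to_csv(cpath, sep="\t")
    spath = outdir / "bileacid_summary.tsv"
    summary.to_csv(spath, sep="\t")
    return {"concentrations": cpath, "summary": spath}


def stage_stats(
    absolute_path, metadata_path, outdir: Path, n_components: int = 2
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    absolute = pd.read_csv(absolute_path, sep="\t", index_col=0)
    metadata = {r.sample_id: r for r in read_metadata(metadata_path)}
    z = stats.log10_standardize(absolute)
    pca = stats.run_pca(z, n_components, preprocessing="log10_standardized_absolute")
    paths = {}
    for name, frame in (("pca_scores", pca.scores), ("pca_loadings", pca.loadings)):
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t")
        paths[name] = p
    groups = pd.Series({s: metadata[s].group for s in absolute.index if s in metadata})
    sites = pd.Series({s: metadata[s].site for s in absolute.index if s in metadata})
    rows = []
    for site in sites.unique():
        sel = sites[sites == site].index
        sub = absolute.loc[sel]
        # rank tests are scale-invariant; run them on the absolute values
        for res in stats.compare_feature_table(sub, groups.reindex(sel)):
            for r in res.pairwise.itertuples():
                rows.append(
                    {"feature": res.feature, "site": site, "kw_p": res.kw_p,
                     "group_a": r.group_a, "group_b": r.group_b,
                     "p": r.p, "q": r.q}
                )
    p = outdir / "group_comparisons.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["group_comparisons"] = p
    return paths


# ---------------------------------------------------------------------------
# validation and the full run


def validate_inputs(paths: dict) -> list[str]:
    """Cross-file referential checks; returns a list of violations (empty = ok)."""
    violations: list[str] = []
    try:
        metadata = read_metadata(paths["metadata"])
    except Exception as e:  # noqa: BLE001 - report, don't raise
        return [f"metadata: {e}"]
    ids = {r.sample_id for r in metadata}
    if "counts" in paths:
        counts = profiling.read_counts(paths["counts"])
        for s in counts.index:
            if s not in ids:
                violations.append(f"counts sample {s} absent from metadata")
        if "taxonomy" in paths:
            tax = profiling.Taxonomy.read(paths["taxonomy"])
            for a in counts.columns:
                if a not in tax.lineages:
                    violations.append(f"ASV {a} absent from taxonomy")
        if "gene_copies" in paths:
            gct = genes.read_gene_copy_table(paths["gene_copies"])
            for a in counts.columns:
                if a not in gct.index:
                    violations.append(f"ASV {a} absent from gene-copy table")
    for key in ("qpcr", "ddpcr", "mpn"):
        if key in paths and Path(paths[key]).exists():
            df = pd.read_csv(paths[key])
            for s in df["sample_id"].unique():
                if s not in ids:
                    violations.append(f"{key} sample {s} absent from metadata")
    return violations


def run_pipeline(config_path=None, outdir="run", config: Optional[dict] = None) -> RunManifest:
    """Execute every stage on a fresh synthetic study; abort naming the
    failing stage; write the manifest."""
    cfg = config if config is not None else load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(_config_hash(cfg), int(cfg["seed"]), __version__)

    stage = "simulate"
    try:
        raw = stage_simulate(cfg, outdir / "raw")
        manifest.record(stage, raw["counts"], sum(1 for _ in open(raw["counts"])) - 1)

        stage = "quantify-loads"
        loads_path = outdir / "loads.tsv"
        ldf = stage_quantify_loads(
            raw["qpcr"], raw["ddpcr"], raw["mpn"], raw["metadata"], loads_path
        )
        manifest.record(stage, loads_path, len(ldf))

        stage = "profile"
        prof = stage_profile(
            raw["counts"], raw["taxonomy"], loads_path, raw["metadata"],
            outdir / "profile", level=cfg["collapse_level"],
            threshold=cfg["contaminant_score_threshold"],
            keep_organellar=cfg["keep_organellar"], load_method=cfg["load_method"],
        )
        manifest.record(stage, prof["absolute_asv"],
                        sum(1 for _ in open(prof["absolute_asv"])) - 1)

        stage = "genes"
        genes_path = outdir / "gene_abundance.tsv"
        gdf = stage_genes(prof["absolute_asv"], raw["gene_copies"], genes_path)
        manifest.record(stage, genes_path, len(gdf))

        stage = "bileacids"
        ba = stage_bileacids(raw["bileacid_areas"], raw["metadata"], outdir / "bileacids")
        manifest.record(stage, ba["summary"], sum(1 for _ in open(ba["summary"])) - 1)

        stage = "stats"
        st = stage_stats(
            prof[f"absolute_{cfg['collapse_level']}"], raw["metadata"],
            outdir / "stats", n_components=int(cfg["pca_components"]),
        )
        manifest.record(stage, st["pca_scores"],
                        sum(1 for _ in open(st["pca_scores"])) - 1)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    manifest.write(outdir / "manifest.json")
    return manifest
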