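"""Validation measurements: the pipeline run end-to-end against known truth.

Each function here re-runs part of the package on freshly simulated data and
returns a summary metric: estimator/oracle agreement, parameter recovery and
CI coverage, ground-truth recovery of the profiling stage, contaminant-filter
power, statistical calibration, and the study's qualitative direction tests.
All randomness flows from an explicit seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import bileacids, genes, loads, profiling, simulate, stats
from .samples import COPROPHAGIC_GROUPS, SMALL_INTESTINE_SITES


# ---------------------------------------------------------------------------
# shared plumbing


def qpcr_content_loads(study: simulate.SyntheticStudy) -> dict[str, loads.LoadEstimate]:
    """Per-sample total loads from the study's qPCR runs, in sample units."""
    meta = {r.sample_id: r for r in study.metadata}
    out = {}
    for run in study.qpcr_runs:
        est = loads.quantify_qpcr(run)
        est = loads.to_extract_concentration(est, run.template_volume_ul)
        out[run.sample_id] = loads.normalize_load(est, meta[run.sample_id])
    return out


def estimated_absolute_table(
    study: simulate.SyntheticStudy, filter_contaminants: bool = True
):
    """The profiling stage on one study: counts -> relative -> absolute."""
    rel = profiling.to_relative(study.asv_counts)
    if filter_contaminants:
        conc = pd.Series(
            {r.sample_id: r.dna_conc_ng_ul for r in study.metadata if r.dna_conc_ng_ul}
        ).reindex(rel.index)
        prev = profiling.flag_contaminants_prevalence(study.asv_counts, study.metadata)
        kept = rel.drop(columns=[c.taxon for c in prev])
        freq = profiling.score_contaminant_frequency(kept, conc)
        rel = profiling.remove_contaminants(
            rel, prev + freq, keep_organellar=True, is_relative=True
        )
    ld = {
        k: v for k, v in qpcr_content_loads(study).items() if k in rel.index
    }
    return profiling.to_absolute(rel, ld, depths=study.asv_counts.sum(axis=1))


# ---------------------------------------------------------------------------
# estimator oracles and recovery


def mpn_grid_oracle(assay: loads.MpnAssay) -> float:
    """Two-stage dense grid search over log10 density (independent of the
    root-finding ML path)."""
    vols = np.asarray(assay.volumes_ml)
    ns = np.asarray(assay.n_wells)
    ps = np.asarray(assay.n_positive)

    def loglik(grid):
        lam = grid[:, None]
        with np.errstate(divide="ignore"):
            logp = np.log(-np.expm1(-lam * vols))
        return np.where(ps > 0, ps * logp, 0.0).sum(axis=1) - (
            (ns - ps) * vols * lam
        ).sum(axis=1)

    coarse = np.logspace(-2, 14, 3201)
    best = coarse[int(np.argmax(loglik(coarse)))]
    fine = best * np.logspace(-0.02, 0.02, 3201)
    return float(fine[int(np.argmax(loglik(fine)))])


def mpn_oracle_agreement(n_plates: int = 1000, seed: int = 0) -> dict:
    """Max relative deviation (%) between ML and grid-search MPN over random
    simulated plates of the study's 8 x 8 serial-dilution design."""
    rng = np.random.default_rng([seed, 101])
    devs = []
    while len(devs) < n_plates:
        density = 10 ** rng.uniform(2.0, 9.0)
        plate = simulate.gen_mpn_plate(density, rng)
        if all(p == 0 for p in plate.n_positive) or all(
            p == n for p, n in zip(plate.n_positive, plate.n_wells)
        ):
            continue
        est = loads.estimate_mpn(plate)
        oracle = mpn_grid_oracle(plate)
        devs.append(abs(est.value - oracle) / oracle)
    return {"max_rel_dev_pct": 100.0 * float(np.max(devs)), "n": len(devs)}


def ddpcr_closed_form() -> dict:
    """Concentration at half-positive droplets (0.85 nL), plus monotonicity."""
    est = loads.quantify_ddpcr(loads.DdpcrRun("s", 20000, 10000, 0.85))
    values = [
        loads.quantify_ddpcr(loads.DdpcrRun("s", 20000, k)).value
        for k in range(1, 20000, 199)
    ]
    monotone = all(b > a for a, b in zip(values, values[1:]))
    return {"copies_per_ul": float(est.value), "monotone": monotone, "n": 20000}


def estimator_recovery(n_per_decade: int = 500, seed: int = 0) -> dict:
    """Median relative error and 95%-CI coverage for the qPCR, ddPCR and MPN
    estimators across 10^2..10^9 true copies (or cells)."""
    rng = np.random.default_rng([seed, 102])
    noise = simulate.AssayNoise()
    out = {}
    for method in ("qpcr", "ddpcr", "mpn"):
        errs, covered, n = [], 0, 0
        for dec in range(2, 10):
            for _ in range(n_per_decade):
                true = 10 ** (dec + rng.uniform(0.0, 1.0))
                if method == "qpcr":
                    est = loads.quantify_qpcr(simulate.gen_qpcr_run(true, rng))
                elif method == "ddpcr":
                    run = simulate._autodiluted_ddpcr(true, rng, noise, "s")
                    est = loads.quantify_ddpcr(run)
                else:
                    est = loads.estimate_mpn(simulate.gen_mpn_plate(true, rng))
                if est.flag != loads.FLAG_OK:
                    continue
                errs.append(abs(est.value - true) / true)
                covered += est.ci_low <= true <= est.ci_high
                n += 1
        out[method] = {
            "median_rel_error_pct": 100.0 * float(np.median(errs)),
            "ci_coverage_pct": 100.0 * covered / n,
            "n": n,
        }
    return out


def qpcr_ddpcr_agreement(n_samples: int = 200, seed: int = 0) -> dict:
    """Fraction of simulated samples where the two assays' 95% CIs overlap."""
    rng = np.random.default_rng([seed, 103])
    noise = simulate.AssayNoise()
    agree, n = 0, 0
    for _ in range(n_samples):
        true = 10 ** rng.uniform(2.5, 8.5)  # copies/uL extract
        q = loads.quantify_qpcr(simulate.gen_qpcr_run(true * 1.5, rng))
        q = loads.to_extract_concentration(q, 1.5)
        d = loads.quantify_ddpcr(simulate._autodiluted_ddpcr(true, rng, noise, "s"))
        if q.flag != loads.FLAG_OK or d.flag != loads.FLAG_OK:
            continue
        n += 1
        agree += max(q.ci_low, d.ci_low) <= min(q.ci_high, d.ci_high)
    return {"agreement_pct": 100.0 * agree / n, "n": n}


# ---------------------------------------------------------------------------
# profiling stage


def profile_recovery(seed: int = 0, depth: int = 10_000) -> dict:
    """Ground-truth recovery of the profiling stage.

    Noise off: the estimated absolute table must equal truth exactly.
    Default noise: Spearman correlation between estimated and true absolute
    abundances across unflagged cells.
    """
    cfg = simulate.SimulationConfig(seed=seed, sequencing_depth=depth)
    nf = simulate.generate_study(cfg.noise_free())
    table = estimated_absolute_table(nf, filter_contaminants=False)
    truth = nf.truth_absolute[table.values.columns]
    t = truth.to_numpy()
    dev = np.abs(table.values.to_numpy() - t) / np.where(t == 0, 1.0, t)
    noise_free_max = float(np.max(dev))

    study = simulate.generate_study(cfg)
    table = estimated_absolute_table(study, filter_contaminants=True)
    truth = study.truth_absolute[table.values.columns]
    est = table.values.to_numpy().ravel()
    tr = truth.to_numpy().ravel()
    fl = table.flags.to_numpy().ravel()
    mask = (~fl) & (tr > 0) & (est > 0)
    rho = sps.spearmanr(est[mask], tr[mask]).statistic
    return {
        "noise_free_max_rel_dev": noise_free_max,
        "spearman_rho": float(rho),
        "n_cells": int(mask.sum()),
    }


def contaminant_filter_power(n_replicates: int = 200, seed: int = 0) -> dict:
    """Frequency-score sensitivity on ambient-mass contaminants and false-
    positive rate on microbial taxa, across replicate studies."""
    sens, fp = [], []
    for i in range(n_replicates):
        study = simulate.generate_study(
            simulate.SimulationConfig(seed=(seed * 100003 + i) % 2**31)
        )
        rel = profiling.to_relative(study.asv_counts)
        conc = pd.Series(
            {r.sample_id: r.dna_conc_ng_ul for r in study.metadata if r.dna_conc_ng_ul}
        ).reindex(rel.index)
        flagged = {c.taxon for c in profiling.score_contaminant_frequency(rel, conc)}
        contams = {c.name for c in study.config.contaminant_panel}
        microbial = {
            t.name for t in study.config.taxon_panel if t.behavior != "dietary"
        }
        sens.append(len(flagged & contams) / len(contams))
        fp.append(len(flagged & microbial) / len(microbial))
    return {
        "sensitivity_pct": 100.0 * float(np.mean(sens)),
        "false_positive_pct": 100.0 * float(np.mean(fp)),
        "n": n_replicates,
    }


# ---------------------------------------------------------------------------
# statistics


def null_fdr_calibration(
    n_replicates: int = 1000, n_features: int = 8, seed: int = 0
) -> dict:
    """Under a global null (no group effects), fraction of features with any
    BH-adjusted pairwise rejection at q < 0.05."""
    rng = np.random.default_rng([seed, 104])
    groups = pd.Series(
        ["TC-F"] * 6 + ["TC-M"] * 6 + ["WF"] * 6 + ["CTRL"] * 6
    )
    rejected, total = 0, 0
    for _ in range(n_replicates):
        table = pd.DataFrame(10 ** rng.normal(6.0, 1.0, size=(24, n_features)))
        for res in stats.compare_feature_table(table, groups):
            total += 1
            rejected += bool((res.pairwise["q"] < 0.05).any())
    return {"feature_rejection_pct": 100.0 * rejected / total, "n": total}


def exact_mwu_separated() -> dict:
    """Exact two-sided Mann-Whitney p for fully separated 6 vs 6 groups."""
    values = pd.Series(list(range(6)) + list(range(10, 16)))
    groups = pd.Series(["lo"] * 6 + ["hi"] * 6)
    res = stats.compare_groups(values, groups)
    return {"p": float(res.pairwise["p"].iloc[0]), "n": 12}


# ---------------------------------------------------------------------------
# direction tests (the study's qualitative findings on synthetic data)


def direction_tests(n_replicates: int = 100, seed: int = 0) -> dict:
    """Replicate-level pass rates for the four qualitative patterns:

    1. TC-F upper-GIT total loads below every coprophagic group's;
    2. fecal taxa below LLOD in the TC-F small intestine while
       *Lactobacillales*-like taxa persist;
    3. BSH-ortholog absolute abundance in the TC-F small intestine at least
       two orders of magnitude below every coprophagic group's;
    4. unconjugated bile-acid fraction near zero in the TC-F small intestine
       and monotonically increasing SI1 -> SI3 in every coprophagic group.
    """
    passes = {"loads": 0, "llod_pattern": 0, "bsh": 0, "bileacids": 0}
    for i in range(n_replicates):
        study = simulate.generate_study(
            simulate.SimulationConfig(seed=(seed * 99991 + i) % 2**31)
        )
        meta = {r.sample_id: r for r in study.metadata}
        ld = qpcr_content_loads(study)

        rows = [
            {"g": meta[s].group, "site": meta[s].site,
             "v": math.log10(max(e.value, 1.0))}
            for s, e in ld.items()
            if meta[s].material == "contents"
        ]
        gm = pd.DataFrame(rows).groupby(["g", "site"])["v"].mean()
        passes["loads"] += all(
            gm[("TC-F", site)]
            < min(gm[(g, site)] for g in COPROPHAGIC_GROUPS)
            for site in ("STM", "SI1", "SI2", "SI3")
        )

        table = estimated_absolute_table(study, filter_contaminants=False)
        fecal = [t.name for t in study.config.taxon_panel if t.behavior == "fecal"]
        lacto = [
            t.name for t in study.config.taxon_panel
            if t.behavior == "true_small_intestine"
        ]
        ok = True
        for s in table.values.index:
            r = meta[s]
            if r.group == "TC-F" and r.site in SMALL_INTESTINE_SITES:
                ok = ok and bool(table.flags.loc[s, fecal].all())
                ok = ok and not bool(table.flags.loc[s, lacto].any())
        passes["llod_pattern"] += ok

        gene_abs = genes.scale_gene_content(table.values, study.gene_copy_table)
        bsh = np.log10(np.maximum(gene_abs[simulate.BSH_KO], 1.0))
        rows = [
            {"g": meta[s].group, "site": meta[s].site, "v": bsh[s]}
            for s in bsh.index
            if meta[s].site in SMALL_INTESTINE_SITES
        ]
        gm = pd.DataFrame(rows).groupby(["g", "site"])["v"].mean()
        passes["bsh"] += all(
            gm[("TC-F", site)]
            < min(gm[(g, site)] for g in COPROPHAGIC_GROUPS) - 2.0
            for site in SMALL_INTESTINE_SITES
        )

        corrected = bileacids.correct_drift(study.bileacid_areas)
        fits = bileacids.fit_calibration(corrected)
        conc = bileacids.quantify(corrected, fits, study.metadata)
        summary = bileacids.summarize_profile(conc)
        rows = [
            {"g": meta[s].group, "site": meta[s].site,
             "v": summary.loc[s, "fraction_unconjugated"]}
            for s in summary.index
        ]
        gm = pd.DataFrame(rows).groupby(["g", "site"])["v"].mean()
        ba_ok = all(gm[("TC-F", site)] < 0.05 for site in SMALL_INTESTINE_SITES)
        for g in COPROPHAGIC_GROUPS:
            ba_ok = ba_ok and gm[(g, "SI1")] < gm[(g, "SI2")] < gm[(g, "SI3")]
        passes["bileacids"] += ba_ok

    return {
        k + "_pass_pct": 100.0 * v / n_replicates for k, v in passes.items()
    } | {"n": n_replicates}
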