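"""Total microbial load estimation from raw quantification assays.

Three independent assays yield a total-load estimate per sample:

* qPCR — a run-specific standard curve (ordinary least squares of Cq on
  log10 copies) is inverted at the sample's mean triplicate Cq.
* ddPCR — the Poisson partition estimator: with ``k`` positive droplets out
  of ``n``, the mean occupancy is ``lambda = -ln((n - k)/n)`` copies per
  droplet, and concentration follows from the droplet volume and dilution.
* MPN — maximum-likelihood most-probable-number density from the
  positive/negative pattern of a replicated serial-dilution culture.

All estimators return a :class:`LoadEstimate` carrying the point value, a
95% confidence interval, the method, the unit, and a detection flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .samples import SampleRecord

FLAG_OK = "ok"
FLAG_BELOW_LLOD = "below_llod"
FLAG_ABOVE_RANGE = "above_range"

#: droplet volume (nL) used when a run does not specify one (vendor convention)
DEFAULT_DROPLET_VOLUME_NL = 0.85
#: minimum positive droplets considered distinguishable from zero
DDPCR_LLOD_POSITIVES = 3


# ---------------------------------------------------------------------------
# domain types


@dataclass
class QpcrRun:
    """One qPCR assay of one sample: triplicate Cq plus its standard series.

    ``cq_values`` may contain NaN for wells that never amplified.
    ``standards`` is a sequence of (known copies per reaction, Cq) pairs.
    """

    sample_id: str
    cq_values: Sequence[float]
    standards: Sequence[tuple[float, float]]
    reaction_volume_ul: float = 15.0
    template_volume_ul: float = 1.5

    def __post_init__(self) -> None:
        if len(self.standards) < 2:
            raise ValueError(
                f"qPCR run {self.sample_id}: need >= 2 standard points"
            )


@dataclass
class StandardCurveFit:
    """OLS fit of Cq against log10(copies): Cq = intercept + slope * log10(c).

    The residual summary (``n_points``, ``x_mean``, ``s_xx``,
    ``residual_var``) lets back-calculation propagate the curve's own
    prediction uncertainty in addition to the sample's replicate scatter.
    """

    slope: float
    intercept: float
    r_squared: float
    n_points: int = 0
    x_mean: float = 0.0
    s_xx: float = 0.0
    residual_var: float = 0.0

    def prediction_var_cq(self, cq: float) -> float:
        """Variance of the curve's predicted Cq at the back-calculated x."""
        if self.n_points < 3 or self.s_xx <= 0:
            return 0.0
        x0 = (cq - self.intercept) / self.slope
        return self.residual_var * (1.0 / self.n_points + (x0 - self.x_mean) ** 2 / self.s_xx)

    @property
    def efficiency(self) -> float:
        """Amplification efficiency as a fraction (1.0 = perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def is_valid(self) -> bool:
        return self.slope < 0

    def copies_at(self, cq: float) -> float:
        return 10.0 ** ((cq - self.intercept) / self.slope)

    def cq_at(self, copies: float) -> float:
        return self.intercept + self.slope * math.log10(copies)


@dataclass
class DdpcrRun:
    sample_id: str
    n_droplets: int
    n_positive: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    template_volume_ul: float = 2.0
    dilution: float = 1.0

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError(f"ddPCR run {self.sample_id}: n_droplets must be > 0")
        if not (0 <= self.n_positive <= self.n_droplets):
            raise ValueError(
                f"ddPCR run {self.sample_id}: n_positive outside [0, n_droplets]"
            )
        if self.droplet_volume_nl <= 0:
            raise ValueError(f"ddPCR run {self.sample_id}: droplet volume must be > 0")


@dataclass
class MpnAssay:
    """Replicated serial-dilution culture outcome for one sample.

    ``volumes_ml[i]`` is the volume of *original* sample delivered to each
    well at dilution level i; ``n_wells[i]`` replicate wells were inoculated
    of which ``n_positive[i]`` showed growth.
    """

    sample_id: str
    volumes_ml: Sequence[float]
    n_wells: Sequence[int]
    n_positive: Sequence[int]

    def __post_init__(self) -> None:
        if not (len(self.volumes_ml) == len(self.n_wells) == len(self.n_positive)):
            raise ValueError(f"MPN assay {self.sample_id}: ragged dilution arrays")
        if len(self.volumes_ml) < 1:
            raise ValueError(f"MPN assay {self.sample_id}: need >= 1 dilution level")
        for v, n, p in zip(self.volumes_ml, self.n_wells, self.n_positive):
            if v <= 0 or n <= 0 or not (0 <= p <= n):
                raise ValueError(f"MPN assay {self.sample_id}: invalid dilution row")


@dataclass
class LoadEstimate:
    sample_id: str
    value: float
    unit: str
    method: str
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    flag: str = FLAG_OK
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# qPCR


def fit_standard_curve(standards: Sequence[tuple[float, float]]) -> StandardCurveFit:
    """OLS of Cq on log10(copies) across a standard-dilution series."""
    if len(standards) < 2:
        raise ValueError("standard curve needs >= 2 points")
    copies = np.asarray([s[0] for s in standards], dtype=float)
    cq = np.asarray([s[1] for s in standards], dtype=float)
    if np.any(copies <= 0):
        raise ValueError("standard copies must be > 0")
    x = np.log10(copies)
    if np.ptp(x) == 0:
        raise ValueError("standards span a single copy level; cannot fit a curve")
    res = stats.linregress(x, cq)
    resid = cq - (res.intercept + res.slope * x)
    dof = x.size - 2
    return StandardCurveFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(x.size),
        x_mean=float(np.mean(x)),
        s_xx=float(np.sum((x - np.mean(x)) ** 2)),
        residual_var=float(np.sum(resid**2) / dof) if dof > 0 else 0.0,
    )


def quantify_qpcr(run: QpcrRun, fit: Optional[StandardCurveFit] = None) -> LoadEstimate:
    """Back-calculate copies per reaction from mean triplicate Cq.

    Wells flagged "no amplification" (NaN Cq) are dropped; if fewer than two
    of three wells amplified the sample is reported below the detection limit.
    The CI propagates the SE of the mean Cq through the standard curve.
    """
    if fit is None:
        fit = fit_standard_curve(run.standards)
    if not fit.is_valid:
        raise ValueError(f"qPCR run {run.sample_id}: standard-curve slope is not negative")
    cq = np.asarray(run.cq_values, dtype=float)
    good = cq[np.isfinite(cq)]
    n_missing = cq.size - good.size
    if good.size == 0 or (cq.size >= 3 and n_missing >= 2):
        return LoadEstimate(
            run.sample_id, 0.0, "copies/reaction", "qpcr", 0.0, float("nan"),
            flag=FLAG_BELOW_LLOD,
        )
    mean_cq = float(np.mean(good))
    value = fit.copies_at(mean_cq)
    if good.size > 1:
        # Student-t quantile: triplicates are a very small sample; the
        # calibration curve's prediction variance is added in quadrature
        tq = float(stats.t.ppf(0.975, good.size - 1))
        se = math.sqrt(
            float(np.var(good, ddof=1)) / good.size + fit.prediction_var_cq(mean_cq)
        )
        lo_cq, hi_cq = mean_cq - tq * se, mean_cq + tq * se
        # slope < 0: higher Cq -> fewer copies
        ci = sorted((fit.copies_at(lo_cq), fit.copies_at(hi_cq)))
    else:
        ci = (value, value)
    return LoadEstimate(
        run.sample_id, value, "copies/reaction", "qpcr", ci[0], ci[1],
        extra={"mean_cq": mean_cq, "efficiency": fit.efficiency},
    )


# ---------------------------------------------------------------------------
# ddPCR


def quantify_ddpcr(run: DdpcrRun) -> LoadEstimate:
    """Poisson partition estimate of template concentration (copies/uL).

    lambda = -ln(n_neg / n) copies per droplet; concentration is
    lambda / droplet volume, scaled back up by the run's dilution factor.
    The CI comes from a Wilson interval on the negative-droplet fraction
    propagated through -ln.
    """
    n, k = run.n_droplets, run.n_positive
    vol_ul = run.droplet_volume_nl * 1e-3
    if k == n:
        return LoadEstimate(
            run.sample_id, float("inf"), "copies/uL", "ddpcr",
            -math.log(1.0 / n) / vol_ul * run.dilution, float("inf"),
            flag=FLAG_ABOVE_RANGE,
        )
    lo_neg, hi_neg = _wilson_interval(n - k, n)
    # fewer negatives -> more copies: bounds swap through -ln
    ci_high = -math.log(lo_neg) / vol_ul * run.dilution if lo_neg > 0 else float("inf")
    ci_low = -math.log(hi_neg) / vol_ul * run.dilution
    if k == 0:
        return LoadEstimate(
            run.sample_id, 0.0, "copies/uL", "ddpcr", 0.0, ci_high,
            flag=FLAG_BELOW_LLOD,
        )
    lam = -math.log((n - k) / n)
    conc = lam / vol_ul * run.dilution
    flag = FLAG_BELOW_LLOD if k < DDPCR_LLOD_POSITIVES else FLAG_OK
    return LoadEstimate(
        run.sample_id, conc, "copies/uL", "ddpcr", ci_low, ci_high, flag=flag,
        extra={"lambda": lam},
    )


def _wilson_interval(successes: int, n: int, z: float = 1.959963984540054):
    p = successes / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


# ---------------------------------------------------------------------------
# MPN


def _mpn_loglik(lam: float, assay: MpnAssay) -> float:
    ll = 0.0
    for v, n, p in zip(assay.volumes_ml, assay.n_wells, assay.n_positive):
        q = -lam * v  # log P(well negative)
        if p > 0:
            ll += p * math.log(-math.expm1(q))
        ll += (n - p) * q
    return ll


def _mpn_score(lam: float, assay: MpnAssay) -> float:
    s = 0.0
    for v, n, p in zip(assay.volumes_ml, assay.n_wells, assay.n_positive):
        e = math.exp(-lam * v)
        if p > 0:
            s += p * v * e / (1.0 - e)
        s -= (n - p) * v
    return s


def estimate_mpn(assay: MpnAssay) -> LoadEstimate:
    """Maximum-likelihood MPN density (per mL of original sample).

    The ML density solves sum_i [p_i v_i e^{-lam v_i}/(1-e^{-lam v_i})
    - (n_i - p_i) v_i] = 0, found by bracketed root search on the score;
    the 95% CI uses the log-normal approximation on ln(MPN) with the
    observed Fisher information.
    """
    vols = np.asarray(assay.volumes_ml, dtype=float)
    ns = np.asarray(assay.n_wells, dtype=int)
    ps = np.asarray(assay.n_positive, dtype=int)
    total_nv = float(np.sum(ns * vols))
    if np.all(ps == 0):
        # upper bound: density at which P(all wells negative) = 5%
        return LoadEstimate(
            assay.sample_id, 0.0, "MPN/mL", "mpn", 0.0,
            math.log(20.0) / total_nv, flag=FLAG_BELOW_LLOD,
        )
    if np.all(ps == ns):
        lower = math.log(20.0) / total_nv  # density below which all-positive has P < 5%
        return LoadEstimate(
            assay.sample_id, float("inf"), "MPN/mL", "mpn", lower, float("inf"),
            flag=FLAG_ABOVE_RANGE,
        )
    # bracket the root on a log grid spanning far beyond any plausible density
    v_max, v_min = float(np.max(vols)), float(np.min(vols))
    lo, hi = 1e-6 / v_max, 1e3 / v_min
    # score is decreasing in lambda; expand bracket if needed
    while _mpn_score(lo, assay) < 0 and lo > 1e-300:
        lo /= 1e3
    while _mpn_score(hi, assay) > 0 and hi < 1e300:
        hi *= 1e3
    lam = optimize.brentq(
        _mpn_score, lo, hi, args=(assay,), xtol=1e-300, rtol=1e-12, maxiter=200
    )
    # observed Fisher information for the binomial-dilution likelihood
    info = 0.0
    for v, n in zip(vols, ns):
        e = math.exp(-lam * v)
        if e < 1.0:
            info += n * v**2 * e / (1.0 - e)
    if info > 0:
        se_ln = 1.0 / (lam * math.sqrt(info))
        ci = (lam * math.exp(-1.96 * se_ln), lam * math.exp(1.96 * se_ln))
    else:
        ci = (lam, lam)
    return LoadEstimate(assay.sample_id, lam, "MPN/mL", "mpn", ci[0], ci[1])


# ---------------------------------------------------------------------------
# normalization to sample units


def to_extract_concentration(
    est: LoadEstimate, template_volume_ul: float, dilution: float = 1.0
) -> LoadEstimate:
    """Convert a copies-per-reaction estimate to copies/uL of the extract."""
    scale = dilution / template_volume_ul
    return LoadEstimate(
        est.sample_id, est.value * scale, "copies/uL", est.method,
        est.ci_low * scale, est.ci_high * scale, est.flag, dict(est.extra),
    )


def normalize_load(
    raw: LoadEstimate, sample: SampleRecord, factor: Optional[float] = None
) -> LoadEstimate:
    """Scale a per-reaction/per-uL estimate to the sample normalization unit.

    Lumenal contents are reported per gram of total contents via the
    extraction dilution chain recorded in the metadata (``factor`` overrides
    it, e.g. the homogenate volume for MPN densities); mucosal samples per
    100 ng of input DNA; MPN densities per gram of contents.
    """
    if factor is None:
        factor = sample.dilution_factor
    if sample.material == "mucosa":
        if sample.dna_input_ng is None:
            raise ValueError(f"sample {sample.sample_id}: missing DNA input (ng)")
        scaled = raw.value * factor / (sample.dna_input_ng / 100.0)
        unit = "copies/100 ng DNA"
    else:
        if sample.mass_g is None:
            raise ValueError(f"sample {sample.sample_id}: missing sample mass (g)")
        scaled = raw.value * factor / sample.mass_g
        unit = "MPN/g" if raw.method == "mpn" else "copies/g"
    scale = scaled / raw.value if raw.value not in (0.0, float("inf")) else (
        factor / (sample.mass_g if sample.material != "mucosa" else sample.dna_input_ng / 100.0)
    )
    return LoadEstimate(
        raw.sample_id, scaled, unit, raw.method,
        raw.ci_low * scale, raw.ci_high * scale, raw.flag, dict(raw.extra),
    )


# ---------------------------------------------------------------------------
# tabular I/O


def loads_to_frame(estimates: Sequence[LoadEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "value": e.value,
                "unit": e.unit,
                "method": e.method,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "flag": e.flag,
            }
            for e in estimates
        ]
    )


def write_loads(estimates: Sequence[LoadEstimate], path) -> None:
    loads_to_frame(estimates).to_csv(path, sep="\t", index=False)


def read_loads(path) -> list[LoadEstimate]:
    df = pd.read_csv(path, sep="\t")
    return [
        LoadEstimate(
            r.sample_id, float(r.value), r.unit, r.method,
            float(r.ci_low), float(r.ci_high), r.flag,
        )
        for r in df.itertuples()
    ]
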