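"""Synthetic CLL cohort generator.

Emulates the statistical structure the analysis pipeline assumes, so every
stage can be exercised end-to-end without patient-level data:

* marginal lesion and mutation frequencies of a chemoimmunotherapy-era CLL
  trial population (del13q 47.4%, del11q 18%, tri12 12.5%, del17p 4.4%;
  SF3B1 22%, NOTCH1 15%, ATM 11%, TP53 9%, BIRC3 6%), with the known
  dependences: TP53 mutations concentrate in del17p cases, BIRC3 deletions
  ride on del11q deletions;
* a log-normal telomere-length distribution (median 3.21 kb, range about
  1.1-10 kb over ~500 patients), shorter in U-CLL;
* a per-patient CNA count = canonical lesion weights plus a negative-
  binomial "extra event" count whose latent rate is tied to TL through a
  Gaussian copula, calibrated so that Kendall's tau-b between TL and the
  curated CNA count hits a configurable target (default -0.147);
* raw segment lists carrying curation traps (split events that must
  re-merge, sub-5-Mb off-catalog fragments that must be filtered, CN-LOH
  decoys that must be excluded, biallelic 13q deletions that must count
  twice, oscillating chromothripsis clusters that must collapse to one) —
  all count-preserving by construction, so the curated count round-trips
  to the latent count;
* Weibull proportional-hazards survival with administrative censoring,
  with per-trial baselines (e.g. OS median 6 y, 17 y horizon) and a
  default hazard-ratio vector matching the multivariate overall-survival
  model of the older chlorambucil/fludarabine trial cohort; an alternative
  "group-hazard" mode draws times from per-GC-class Weibulls calibrated
  to reference 5-year survival rates for Kaplan-Meier checks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import CalibrationError, ConfigurationError, ValidationError
from .segments import MB, Segment, SegState, load_chrom_lengths

#: copula correlation between the TL normal score and the extra-CNA normal
#: score, calibrated (see :func:`calibrate_tl_cna_rho`) so the population
#: Kendall tau-b of TL vs total curated CNA count is -0.147 under the
#: default configuration. Recalibrate after changing the count or TL model.
DEFAULT_TL_CNA_RHO = -0.2596

#: default multivariate overall-survival hazard ratios (long-follow-up
#: chlorambucil/fludarabine trial cohort); age is per year, centred.
CLL4_OS_LOG_HRS = {
    "hgc": math.log(1.61),
    "tp53_aberrant": math.log(2.94),
    "tri12": math.log(1.79),
    "tl_s": math.log(1.70),
    "ucll": math.log(1.54),
    "sf3b1_mut": math.log(1.50),
    "age_c": math.log(1.05),
}

CLL4_PFS_LOG_HRS = {
    "tp53_aberrant": math.log(2.68),
    "ucll": math.log(1.94),
    "tl_s": math.log(1.52),
}

ARCADM_OS_LOG_HRS = {
    "tp53_aberrant": math.log(2.91),
    "n_cll": math.log(1.94),
    "age_c": math.log(1.05),
}

ARCADM_PFS_LOG_HRS = {
    "tp53_aberrant": math.log(3.59),
    "ucll": math.log(2.04),
    "tl_s": math.log(1.92),
}


@dataclass(frozen=True)
class EndpointModel:
    """Weibull proportional-hazards model for one survival endpoint."""

    name: str
    baseline_median_years: float
    horizon_years: float
    shape: float = 1.2
    log_hrs: Mapping[str, float] = field(default_factory=dict)
    age_center: float = 64.0

    def __post_init__(self) -> None:
        if self.baseline_median_years <= 0 or self.horizon_years <= 0 or self.shape <= 0:
            raise ConfigurationError("Weibull parameters must be positive")


def default_endpoints(trial: str = "CLL4") -> dict[str, EndpointModel]:
    if trial.upper().startswith("CLL4"):
        return {
            "OS": EndpointModel("OS", 6.0, 17.0, log_hrs=CLL4_OS_LOG_HRS),
            "PFS": EndpointModel("PFS", 2.4, 10.0, log_hrs=CLL4_PFS_LOG_HRS),
        }
    return {
        "OS": EndpointModel("OS", 6.44, 9.0, log_hrs=ARCADM_OS_LOG_HRS),
        "PFS": EndpointModel("PFS", 4.72, 9.0, log_hrs=ARCADM_PFS_LOG_HRS),
    }


#: reference 5-year overall-survival rates by GC class (the intermediate
#: class has no established rate; midpoint used)
GROUP_OS_5Y = {
    "CLL4": {"LGC": 0.61, "IGC": 0.50, "HGC": 0.42},
    "ARCADM": {"LGC": 0.51, "IGC": 0.40, "HGC": 0.29},
}


@dataclass
class SimConfig:
    """All generator frequencies, effect sizes and calibration targets."""

    n_patients: int = 495
    seed: int = 0
    trial_label: str = "CLL4"

    # -- IGHV and epitype (epitype conditional on IGHV; marginals
    #    n/i/m = 0.49/0.32/0.19 at p_ucll = 0.60)
    p_ucll: float = 0.60
    epitype_given_u: tuple[float, float, float] = (0.75, 0.20, 0.05)
    epitype_given_m: tuple[float, float, float] = (0.10, 0.50, 0.40)

    # -- canonical lesions
    p_del13q: float = 0.474
    p_biallelic_given_del13q: float = 0.21
    p_del13q_class2: float = 170 / 256
    p_del11q: float = 0.18
    p_birc3_del_given_del11q: float = 0.70
    p_tri12: float = 0.125
    p_del17p: float = 0.044

    # -- mutations over the 9-gene panel
    p_tp53_mut_given_del17p: float = 0.80
    p_tp53_mut_no_del17p: float = 0.061
    p_atm_mut_given_del11q: float = 0.20
    p_atm_mut_no_del11q: float = 0.089
    mutation_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "SF3B1": 0.22,
            "NOTCH1": 0.15,
            "BIRC3": 0.032,
            "XPO1": 0.05,
            "MYD88": 0.03,
            "SAMHD1": 0.02,
            "MED12": 0.02,
        }
    )

    # -- telomere length (log-normal, kb)
    tl_log_median: float = math.log(3.21)
    tl_log_sd: float = 0.38
    tl_ucll_log_shift: float = -0.15  # U-CLL shorter; centred so the median holds
    tl_cna_tau_target: float = -0.147
    tl_cna_rho: float = DEFAULT_TL_CNA_RHO
    emit_second_tl_platform: bool = False
    tl_platform_tau: float = 0.657

    # -- extra (non-canonical) CNA count: negative binomial, log-mean
    #    linear in TP53 aberration and U-CLL, copula-linked to TL
    extra_log_mean: float = 0.05
    extra_beta_tp53: float = math.log(1.5)
    extra_beta_ucll: float = math.log(1.8)
    extra_nb_size: float = 0.45

    # -- demographics
    p_male: float = 0.74
    binet_probs: tuple[float, float, float] = (0.20, 0.48, 0.32)
    age_mean: float = 63.5
    age_sd: float = 9.0
    age_range: tuple[float, float] = (36.0, 86.0)

    # -- missingness of optional assays
    p_missing_ighv: float = 0.113
    p_missing_epitype: float = 0.099
    p_missing_tl: float = 0.0

    # -- survival
    survival_mode: str = "ph"  # "ph" or "group_hazard"
    endpoints: Mapping[str, EndpointModel] | None = None
    group_os_5y: Mapping[str, float] | None = None
    group_shape: float = 1.2

    # -- segment-noise knobs (curation traps; all count-preserving)
    p_split_event: float = 0.15
    subthreshold_rate: float = 0.4  # Poisson mean per patient
    cnloh_rate: float = 0.3  # Poisson mean per patient
    p_chromothripsis: float = 0.02

    # -- FISH
    fish_discordance: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "p_ucll",
            "p_del13q",
            "p_biallelic_given_del13q",
            "p_del13q_class2",
            "p_del11q",
            "p_birc3_del_given_del11q",
            "p_tri12",
            "p_del17p",
            "p_male",
            "fish_discordance",
            "p_split_event",
            "p_chromothripsis",
            "p_missing_ighv",
            "p_missing_epitype",
            "p_missing_tl",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for probs in (self.epitype_given_u, self.epitype_given_m, self.binet_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"probabilities {probs} must sum to 1")
        if not -1.0 < self.tl_cna_rho < 1.0:
            raise ValidationError("copula correlation must lie in (-1, 1)")
        if self.survival_mode not in ("ph", "group_hazard"):
            raise ValidationError(f"unknown survival_mode {self.survival_mode!r}")

    def resolved_endpoints(self) -> dict[str, EndpointModel]:
        if self.endpoints is not None:
            return dict(self.endpoints)
        return default_endpoints(self.trial_label)

    def resolved_group_os_5y(self) -> dict[str, float]:
        if self.group_os_5y is not None:
            return dict(self.group_os_5y)
        key = "CLL4" if self.trial_label.upper().startswith("CLL4") else "ARCADM"
        return dict(GROUP_OS_5Y[key])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("endpoints"):
            d["endpoints"] = {
                k: dataclasses.asdict(v) for k, v in self.resolved_endpoints().items()
            }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        eps = raw.pop("endpoints", None)
        cfg = cls(**raw)
        if eps:
            cfg.endpoints = {
                name: EndpointModel(name=name, **params) for name, params in eps.items()
            }
        return cfg


# ---------------------------------------------------------------------------
# Latent draws

_EPITYPES = np.array(["n-CLL", "i-CLL", "m-CLL"])


def _draw_latent(config: SimConfig, rng: np.random.Generator, rho: float | None = None):
    """Draw the per-patient latent feature table (no segments/survival)."""
    n = config.n_patients
    rho = config.tl_cna_rho if rho is None else rho
    z1 = rng.standard_normal(n)
    w = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho * rho) * w

    ucll = rng.random(n) < config.p_ucll
    epi = np.empty(n, dtype=object)
    u_idx = np.where(ucll)[0]
    m_idx = np.where(~ucll)[0]
    epi[u_idx] = rng.choice(_EPITYPES, size=len(u_idx), p=config.epitype_given_u)
    epi[m_idx] = rng.choice(_EPITYPES, size=len(m_idx), p=config.epitype_given_m)

    tl = np.exp(
        config.tl_log_median
        + config.tl_log_sd * z1
        + config.tl_ucll_log_shift * (ucll.astype(float) - config.p_ucll)
    )

    del13q = rng.random(n) < config.p_del13q
    biallelic13q = del13q & (rng.random(n) < config.p_biallelic_given_del13q)
    del13q_class2 = rng.random(n) < config.p_del13q_class2
    del11q = rng.random(n) < config.p_del11q
    birc3_del = del11q & (rng.random(n) < config.p_birc3_del_given_del11q)
    tri12 = rng.random(n) < config.p_tri12
    del17p = rng.random(n) < config.p_del17p

    tp53_mut = np.where(
        del17p,
        rng.random(n) < config.p_tp53_mut_given_del17p,
        rng.random(n) < config.p_tp53_mut_no_del17p,
    )
    atm_mut = np.where(
        del11q,
        rng.random(n) < config.p_atm_mut_given_del11q,
        rng.random(n) < config.p_atm_mut_no_del11q,
    )
    other_muts = {
        gene: rng.random(n) < rate for gene, rate in config.mutation_rates.items()
    }
    tp53_aberrant = del17p | tp53_mut

    mean_extra = np.exp(
        config.extra_log_mean
        + config.extra_beta_tp53 * tp53_aberrant.astype(float)
        + config.extra_beta_ucll * ucll.astype(float)
    )
    r = config.extra_nb_size
    q = sps.norm.cdf(z2)
    extras = sps.nbinom.ppf(q, n=r, p=r / (r + mean_extra))
    # cap at the upper end of plausible per-patient burdens (observed cohort
    # ranges top out in the low twenties) so extreme copula quantiles stay placeable
    extras = np.minimum(extras, 25).astype(int)

    lesion_weight = (
        del13q.astype(int)
        + biallelic13q.astype(int)  # biallelic 13q counts twice
        + del11q.astype(int)
        + tri12.astype(int)
        + del17p.astype(int)
    )
    count = lesion_weight + extras
    chromo = (rng.random(n) < config.p_chromothripsis) & (extras >= 1)

    df = pd.DataFrame(
        {
            "ucll": ucll,
            "epitype": epi,
            "tl_kb": np.round(tl, 3),
            "del13q": del13q,
            "del13q_biallelic": biallelic13q,
            "del13q_class2": del13q_class2,
            "del11q": del11q,
            "birc3_del": birc3_del,
            "tri12": tri12,
            "del17p": del17p,
            "TP53_mut": tp53_mut,
            "ATM_mut": atm_mut,
            **{f"{g}_mut": v for g, v in other_muts.items()},
            "tp53_aberrant": tp53_aberrant,
            "extras": extras,
            "chromothripsis": chromo,
            "cna_count": count,
        }
    )
    df["hgc"] = df["cna_count"] >= 5
    df["gc_class"] = pd.cut(
        df["cna_count"], bins=[-0.5, 2.5, 4.5, np.inf], labels=["LGC", "IGC", "HGC"]
    ).astype(str)
    df["tl_class"] = np.where(tl < 2.92, "S", np.where(tl <= 3.57, "I", "L"))
    df["tl_s"] = df["tl_class"] == "S"
    df["n_cll"] = df["epitype"] == "n-CLL"
    df["sf3b1_mut"] = df["SF3B1_mut"]
    return df


def calibrate_tl_cna_rho(
    config: SimConfig | None = None,
    target: float | None = None,
    n: int = 60_000,
    seed: int = 20_240,
    tol: float = 1e-3,
) -> float:
    """Bisection search for the copula correlation achieving the target
    Kendall tau-b between TL and the latent CNA count.

    Uses common random numbers (one fixed latent draw re-linked at each
    candidate correlation), so the estimated tau is smooth and monotone in
    the correlation; the search stops when the bracket is narrower than
    ``tol``. Raises if the target is unattainable even at correlation -0.99
    (count dispersion bounds the achievable dependence).
    """
    config = config or SimConfig()
    target = config.tl_cna_tau_target if target is None else target
    big = dataclasses.replace(config, n_patients=n)

    def tau_at(rho: float) -> float:
        rng = np.random.default_rng(seed)
        df = _draw_latent(big, rng, rho=rho)
        return float(sps.kendalltau(df["tl_kb"], df["cna_count"], variant="b").statistic)

    lo, hi = -0.99, 0.0
    t_lo, t_hi = tau_at(lo), tau_at(hi)
    if not (t_lo <= target <= t_hi):
        raise CalibrationError(
            f"target tau {target} outside achievable range [{t_lo:.3f}, {t_hi:.3f}]"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if tau_at(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Survival

def _weibull_times(
    lp: np.ndarray, scale: float, shape: float, rng: np.random.Generator
) -> np.ndarray:
    e = rng.exponential(size=len(lp))
    return scale * (e / np.exp(lp)) ** (1.0 / shape)


def _solve_baseline_scale(
    lp: np.ndarray, median: float, shape: float
) -> float:
    """Scale of the baseline Weibull such that the cohort's marginal
    survival median equals ``median`` given the linear predictors."""

    def marginal_surv(scale: float) -> float:
        return float(np.mean(np.exp(-((median / scale) ** shape) * np.exp(lp))))

    lo, hi = 1e-3, 1e4
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        if marginal_surv(mid) < 0.5:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-10:
            break
    return math.sqrt(lo * hi)


def simulate_survival(
    features: pd.DataFrame,
    model: EndpointModel,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time_years, event) from the Weibull PH model.

    The linear predictor is the sum of log-hazard-ratios times covariate
    values (``age_c`` is age minus the model's centring age); times beyond
    the follow-up horizon are administratively censored.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    lp = np.zeros(len(features))
    for name, loghr in model.log_hrs.items():
        if name not in features.columns:
            raise ConfigurationError(f"survival covariate {name!r} missing")
        lp = lp + loghr * features[name].astype(float).to_numpy()
    scale = _solve_baseline_scale(lp, model.baseline_median_years, model.shape)
    t = _weibull_times(lp, scale, model.shape, rng)
    event = t <= model.horizon_years
    time = np.minimum(t, model.horizon_years)
    time = np.maximum(time, 1e-4)  # guard against zero durations
    return np.round(time, 4), event


def _group_hazard_survival(
    gc_class: pd.Series,
    rates_5y: Mapping[str, float],
    horizon: float,
    shape: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-GC-class Weibull calibrated so S(5) equals the reference rate."""
    scales = {
        g: 5.0 / (-math.log(s5)) ** (1.0 / shape) for g, s5 in rates_5y.items()
    }
    t = np.empty(len(gc_class))
    for g, scale in scales.items():
        idx = (gc_class == g).to_numpy()
        t[idx] = scale * rng.exponential(size=int(idx.sum())) ** (1.0 / shape)
    event = t <= horizon
    return np.round(np.minimum(t, horizon), 4), event


def simulate_survival_cohort(
    config: SimConfig, endpoint: str = "OS"
) -> pd.DataFrame:
    """Latent feature table plus one endpoint's survival columns, without
    segment rendering — the fast path for survival parameter-recovery
    studies. Columns: the latent features, ``time_years`` and ``event``."""
    rng = np.random.default_rng(config.seed)
    df = _draw_latent(config, rng)
    age = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, size=config.n_patients)),
        *config.age_range,
    )
    df["age"] = age
    model = config.resolved_endpoints()[endpoint]
    df["age_c"] = age - model.age_center
    t, e = simulate_survival(df, model, rng)
    df["time_years"] = t
    df["event"] = e
    return df


# ---------------------------------------------------------------------------
# Segment emission

#: chromosomes free of default catalog regions; fillers and noise go here
_FILLER_CHROMS = ("1", "3", "5", "7", "8", "9", "10", "15", "16", "18", "19", "20")

_MDR_START = 50_000_000  # 13q14 minimally deleted region of the default catalog
_ATM_START, _ATM_END = 108_093_211, 108_239_829
_BIRC3_START = 102_188_181
_TP53_END = 7_590_856
_CHR12_LEN = 133_851_895


class _FillerPlacer:
    """Places off-catalog events along reserved chromosomes, spaced so that
    neighbours never fall within the 5 Mb merge gap."""

    def __init__(self, chrom_lengths: Mapping[str, int], exclude: set[str]):
        self.pool = [c for c in _FILLER_CHROMS if c not in exclude]
        self.lengths = chrom_lengths
        self.cursors = {c: 10 * MB for c in self.pool}
        self.i = 0

    def place(self, span: int) -> tuple[str, int]:
        for _ in range(len(self.pool)):
            chrom = self.pool[self.i % len(self.pool)]
            self.i += 1
            start = self.cursors[chrom]
            if start + span < self.lengths[chrom] - 5 * MB:
                self.cursors[chrom] = start + span + int(6.5 * MB)
                return chrom, start
        raise CalibrationError("ran out of genome for filler events")


def emit_segments(
    sample_id: str,
    patient: Mapping,
    config: SimConfig,
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[Segment]:
    """Render one patient's latent lesion set as a raw segment list,
    injecting curation traps at the configured rates. The traps are
    count-preserving: full curation returns exactly the latent CNA count."""
    if chrom_lengths is None:
        chrom_lengths = load_chrom_lengths()
    segs: list[Segment] = []

    def add(chrom, start, end, state, flag=False):
        segs.append(
            Segment(
                sample_id=sample_id,
                chrom=chrom,
                start=int(start),
                end=int(end),
                state=state,
                platform="sim",
                chromothripsis_flag=flag,
            )
        )

    # canonical lesions at their loci
    if patient["del13q"]:
        if patient["del13q_class2"]:
            size = rng.uniform(2.5, 25.0) * MB
        else:
            size = rng.uniform(0.9, 1.9) * MB
        start = _MDR_START - rng.uniform(0.05, 0.1) * MB
        state = SegState.BIALLELIC_LOSS if patient["del13q_biallelic"] else SegState.LOSS
        add("13", start, start + size, state)
    if patient["del11q"]:
        if patient["birc3_del"]:
            start = _BIRC3_START - rng.uniform(0.5, 3.0) * MB
            end = _ATM_END + rng.uniform(0.5, 8.0) * MB
        else:
            start = _ATM_START - rng.uniform(0.5, 3.0) * MB
            end = _ATM_END + rng.uniform(0.5, 8.0) * MB
        add("11", start, end, SegState.LOSS)
    if patient["del17p"]:
        start = rng.uniform(0.0, 5.0) * MB
        end = _TP53_END + rng.uniform(0.5, 10.0) * MB
        add("17", start, end, SegState.LOSS)
    if patient["tri12"]:
        add("12", 0, _CHR12_LEN, SegState.GAIN)

    # chromothripsis cluster: one latent extra rendered as oscillation
    n_fillers = int(patient["extras"])
    exclude: set[str] = set()
    if patient["chromothripsis"]:
        n_fillers -= 1
        chrom = "9"
        exclude.add(chrom)
        pos = 20 * MB
        for _ in range(12):
            add(chrom, pos, pos + int(0.5 * MB), SegState.LOSS)
            pos += MB

    placer = _FillerPlacer(chrom_lengths, exclude)
    for _ in range(n_fillers):
        size = int(rng.uniform(5.5, 20.0) * MB)
        state = SegState.GAIN if rng.random() < 0.4 else SegState.LOSS
        if rng.random() < config.p_split_event:
            # split into two fragments <= merge-gap apart: must re-merge
            gap = int(rng.uniform(1.0, 4.5) * MB)
            chrom, start = placer.place(size + gap)
            cut = int(size * rng.uniform(0.3, 0.7))
            add(chrom, start, start + cut, state)
            add(chrom, start + cut + gap, start + size + gap, state)
        else:
            chrom, start = placer.place(size)
            add(chrom, start, start + size, state)

    # sub-threshold off-catalog fragments: must be filtered out
    for _ in range(rng.poisson(config.subthreshold_rate)):
        size = int(rng.uniform(0.5, 4.4) * MB)
        state = SegState.GAIN if rng.random() < 0.5 else SegState.LOSS
        chrom, start = placer.place(size)
        add(chrom, start, start + size, state)

    # CN-LOH decoys: must be excluded before counting
    for _ in range(rng.poisson(config.cnloh_rate)):
        size = int(rng.uniform(5.0, 15.0) * MB)
        chrom, start = placer.place(size)
        add(chrom, start, start + size, SegState.CN_LOH)

    return segs


# ---------------------------------------------------------------------------
# Bundle assembly

@dataclass
class CohortBundle:
    """The full synthetic input bundle plus the latent truth table."""

    config: SimConfig
    clinical: pd.DataFrame
    mutations: pd.DataFrame
    tl: pd.DataFrame
    epitype: pd.DataFrame
    fish: pd.DataFrame
    segments: list[Segment]
    truth: pd.DataFrame

    def seg_frame(self) -> pd.DataFrame:
        """Segments as a SEG-style table (1-based inclusive coordinates)."""
        return pd.DataFrame(
            [
                {
                    "sample": s.sample_id,
                    "chrom": s.chrom,
                    "start": s.start + 1,
                    "end": s.end,
                    "state": s.state.value.lower(),
                    "platform": s.platform,
                    "chromothripsis_flag": s.chromothripsis_flag,
                }
                for s in self.segments
            ]
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
        self.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
        self.tl.to_csv(outdir / "tl.tsv", sep="\t", index=False)
        self.epitype.to_csv(outdir / "epitype.tsv", sep="\t", index=False)
        self.fish.to_csv(outdir / "fish.tsv", sep="\t", index=False)
        self.seg_frame().to_csv(outdir / "segments.seg", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest = {"config": _jsonable(self.config.to_dict())}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def generate_cohort(config: SimConfig) -> CohortBundle:
    """Generate the full synthetic bundle; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"SYN{i:04d}" for i in range(1, n + 1)]
    truth = _draw_latent(config, rng)
    truth.insert(0, "sample_id", ids)

    age = np.clip(
        np.round(rng.normal(config.age_mean, config.age_sd, size=n)),
        *config.age_range,
    )
    truth["age"] = age
    truth["age_c"] = age - 64.0
    sex = np.where(rng.random(n) < config.p_male, "M", "F")
    binet = rng.choice(["A", "B", "C"], size=n, p=config.binet_probs)

    # survival
    surv_cols = {}
    if config.survival_mode == "ph":
        for name, model in config.resolved_endpoints().items():
            t, e = simulate_survival(truth, model, rng)
            surv_cols[f"{name.lower()}_time_years"] = t
            surv_cols[f"{name.lower()}_event"] = e
    else:
        rates = config.resolved_group_os_5y()
        horizon = config.resolved_endpoints()["OS"].horizon_years
        t, e = _group_hazard_survival(
            truth["gc_class"], rates, horizon, config.group_shape, rng
        )
        surv_cols["os_time_years"] = t
        surv_cols["os_event"] = e
    for k, v in surv_cols.items():
        truth[k] = v

    # missingness masks (truth keeps the full values)
    ighv_missing = rng.random(n) < config.p_missing_ighv
    epi_missing = rng.random(n) < config.p_missing_epitype
    tl_missing = rng.random(n) < config.p_missing_tl

    ighv_lbl = np.where(truth["ucll"], "U-CLL", "M-CLL").astype(object)
    ighv_lbl[ighv_missing] = None
    clinical = pd.DataFrame(
        {
            "sample_id": ids,
            "trial": config.trial_label,
            "age": age.astype(int),
            "sex": sex,
            "binet": binet,
            "ighv": ighv_lbl,
            **surv_cols,
        }
    )

    mut_rows = []
    gene_cols = [c for c in truth.columns if c.endswith("_mut") and c != "sf3b1_mut"]
    for i, sid in enumerate(ids):
        for col in gene_cols:
            if truth[col].iat[i]:
                mut_rows.append(
                    {
                        "sample": sid,
                        "gene": col[:-4],
                        "vaf": round(float(rng.beta(2.0, 2.0)), 3),
                    }
                )
    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "vaf"])

    tl_rows = pd.DataFrame(
        {
            "sample": ids,
            "tl_kb": truth["tl_kb"],
            "platform": "STELA",
        }
    )[~tl_missing]
    if config.emit_second_tl_platform:
        a = math.sin(math.pi * config.tl_platform_tau / 2.0)
        z1 = (np.log(truth["tl_kb"]) - config.tl_log_median) / config.tl_log_sd
        z2 = a * z1 + math.sqrt(1 - a * a) * rng.standard_normal(n)
        tl2 = np.exp(config.tl_log_median + config.tl_log_sd * z2)
        tl_rows = pd.concat(
            [
                tl_rows,
                pd.DataFrame(
                    {"sample": ids, "tl_kb": np.round(tl2, 3), "platform": "MMQPCR"}
                ),
            ],
            ignore_index=True,
        )

    epitype = pd.DataFrame({"sample": ids, "epitype": truth["epitype"]})[~epi_missing]

    flip = lambda x: x ^ (rng.random(n) < config.fish_discordance)  # noqa: E731
    fish = pd.DataFrame(
        {
            "sample": ids,
            "del17p": flip(truth["del17p"].to_numpy()),
            "del11q": flip(truth["del11q"].to_numpy()),
            "tri12": flip(truth["tri12"].to_numpy()),
            "del13q": flip(truth["del13q"].to_numpy()),
        }
    )

    chrom_lengths = load_chrom_lengths()
    segments: list[Segment] = []
    for i, sid in enumerate(ids):
        segments.extend(
            emit_segments(sid, truth.iloc[i], config, rng, chrom_lengths)
        )

    return CohortBundle(
        config=config,
        clinical=clinical,
        mutations=mutations,
        tl=tl_rows.reset_index(drop=True),
        epitype=epitype.reset_index(drop=True),
        fish=fish,
        segments=segments,
        truth=truth,
    )
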