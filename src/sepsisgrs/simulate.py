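"""Seeded synthetic cohort generator.

Emulates the statistical structure of a large prospective biobank cohort
followed for sepsis and its cardiovascular complications, so that every
downstream stage (genotype input, GRS, phenotyping, landmark survival) can
be exercised and validated without access to protected data:

* genotypes drawn under Hardy–Weinberg equilibrium at each panel SNP's risk
  allele frequency;
* covariates: recruitment age uniform on 40–69, sex, race (predominantly
  White), a log-normal 10-year baseline cardiovascular risk score standing in
  for the pooled-cohort-equation ASCVD risk, and 10 standard-normal ancestry
  principal components;
* sepsis onset as an exponential time-to-event whose log-rate is linear in
  age, sex and baseline risk, with the marginal cumulative incidence
  calibrated numerically to the target (~2.2% over 12.6 years of follow-up);
* cardiovascular event times from a piecewise-constant hazard
  ``lambda(t) = lambda0 * GRS**gamma * exp(beta'x) * m(t)`` where ``m(t)`` is
  1 before sepsis onset and switches to the short-/mid-/long-term window
  multipliers afterwards — so a subject's GRS is literally their relative
  risk, and planted window multipliers are recoverable by landmark Cox fits;
* death as an independent exponential that censors all outcomes.

Every draw flows from one ``numpy`` Generator seeded from the config, so a
given config reproduces the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotypes import GenotypeMatrix
from .grs import MISSING, compute_grs_matrix
from .panel import SNPPanel, SNPRecord
from .survival import DAYS_PER_YEAR

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_sepsis",
    "simulate_event_times",
    "simulate_cohort",
    "records_from_truth",
]

TRAITS = ("MI", "IS", "VTE")

#: Per-trait spread of log odds ratios, chosen so the synthetic GRS
#: distributions occupy the low/intermediate/high bins in roughly the
#: proportions seen for real panels of this size (VTE panels carry a few
#: large-effect variants, MI panels many small ones).
DEFAULT_OR_LOG_SD = {"MI": 0.075, "IS": 0.105, "VTE": 0.19}

DEFAULT_PANEL_SIZES = {"MI": 78, "IS": 30, "VTE": 22}

#: Baseline event hazards per person-year, matching non-sepsis cumulative
#: incidences of ~3.2% (MI), ~1.4% (IS), ~1.7% (VTE) over 12.6 years.
DEFAULT_BASELINE_HAZARDS = {"MI": 0.002565, "IS": 0.001103, "VTE": 0.001369}

#: Post-sepsis hazard multipliers for the (0-30 d], (30 d-2 y], (>2 y)
#: windows.  Mid- and long-term values are realistic point estimates for
#: this design; short-term multipliers are large finite placeholders — real
#: short-window estimates are unstable or inestimable at these event counts.
DEFAULT_SEPSIS_HR_WINDOWS = {
    "MI": (100.0, 3.70, 0.40),
    "IS": (50.0, 4.92, 0.40),
    "VTE": (80.0, 11.03, 0.63),
}

#: Log-hazard coefficients for (age-54.5 years, male, standardized log
#: baseline risk) on cardiovascular events and on sepsis onset.  Sepsis and
#: the outcomes share risk factors, so covariate adjustment is genuinely
#: load-bearing in the recovery analyses.
DEFAULT_COVARIATE_EFFECTS = {"age": 0.02, "male": 0.20, "log_ascvd": 0.25}
DEFAULT_SEPSIS_COVARIATE_EFFECTS = {"age": 0.04, "male": 0.35, "log_ascvd": 0.35}

RECRUITMENT_EPOCH = pd.Timestamp("2008-01-01")

RACE_LEVELS = ("White", "Black", "Asian", "Other")
RACE_PROBS = (0.94, 0.02, 0.02, 0.02)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the study-like conditions."""

    n_subjects: int = 10_000
    seed: int = 0
    followup_years: float = 12.6
    sepsis_rate: float = 0.022
    grs_exponent: float = 1.0
    death_rate: float = 0.0045
    prevalent_sepsis_frac: float = 0.01
    genotype_missing_rate: float = 0.0
    panel_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PANEL_SIZES))
    baseline_hazards: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_HAZARDS)
    )
    sepsis_hr_windows: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEPSIS_HR_WINDOWS)
    )
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    sepsis_covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEPSIS_COVARIATE_EFFECTS)
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        for name in ("sepsis_rate", "death_rate", "followup_years"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for t, lam in self.baseline_hazards.items():
            if lam < 0:
                raise ValueError(f"baseline hazard for {t} must be non-negative")
        for t, ws in self.sepsis_hr_windows.items():
            if any(w < 0 for w in ws):
                raise ValueError(f"window multipliers for {t} must be non-negative")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        if "sepsis_hr_windows" in d:
            d["sepsis_hr_windows"] = {k: tuple(v) for k, v in d["sepsis_hr_windows"].items()}
        return cls(**d)


@dataclass
class SyntheticCohort:
    """Full generator output: inputs for every downstream stage plus truth."""

    config: SimulationConfig
    panels: dict[str, SNPPanel]
    genotypes: dict[str, GenotypeMatrix]
    grs: pd.DataFrame | None  # subject_id + grs_/group_ columns, None if gamma=0
    registry: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame  # continuous-time ground truth, one row per subject


# ---------------------------------------------------------------------------
# panels and genotypes


def simulate_panel(
    trait: str,
    n_snps: int | None = None,
    seed: int = 0,
    or_log_sd: float | None = None,
) -> SNPPanel:
    """Synthetic risk-SNP panel with GWAS-significant, HWE-compatible rows.

    Stand-in for a published panel (the real supplementary SNP lists are not
    redistributable); sizes default to 78 (MI), 30 (IS), 22 (VTE).
    """
    if n_snps is None:
        n_snps = DEFAULT_PANEL_SIZES[trait]
    if or_log_sd is None:
        or_log_sd = DEFAULT_OR_LOG_SD[trait]
    trait_offset = {"MI": 1, "IS": 2, "VTE": 3}[trait]
    rng = np.random.default_rng([seed, trait_offset])
    log_or = np.abs(rng.normal(0.0, or_log_sd, n_snps)) + 0.01
    freq = rng.uniform(0.05, 0.95, n_snps)
    gwas_p = 10.0 ** (-rng.uniform(8.5, 30.0, n_snps))
    chrom = rng.integers(1, 23, n_snps)
    pos = rng.integers(10_000, 50_000_000, n_snps)
    # unambiguous allele pairs only (no A/T, C/G strand ambiguity)
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
    records = []
    for i in range(n_snps):
        risk, other = pairs[int(rng.integers(len(pairs)))]
        records.append(
            SNPRecord(
                rsid=f"rs{trait.lower()}{i + 1:04d}",
                chrom=str(chrom[i]),
                pos=int(pos[i]),
                risk_allele=risk,
                other_allele=other,
                odds_ratio=float(np.exp(log_or[i])),
                risk_freq=float(freq[i]),
                gwas_p=float(gwas_p[i]),
            )
        )
    return SNPPanel(trait=trait, snps=tuple(records), source_note="synthetic panel")


def simulate_genotypes(
    n: int,
    panel: SNPPanel,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
    subject_ids: tuple[str, ...] | None = None,
) -> GenotypeMatrix:
    """HWE genotypes: dosage at SNP i ~ Binomial(2, f_i), i.i.d. subjects."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.array([s.risk_freq for s in panel])
    dosage = rng.binomial(2, freqs, size=(n, len(panel))).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = MISSING
    if subject_ids is None:
        subject_ids = tuple(f"S{i + 1:06d}" for i in range(n))
    return GenotypeMatrix(subject_ids=subject_ids, rsids=panel.rsids, dosage=dosage)


# ---------------------------------------------------------------------------
# covariates and sepsis


def simulate_covariates(n: int, seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Baseline covariate table: age, sex, race, ASCVD-like risk score, PCs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:06d}" for i in range(n)],
            "age": rng.uniform(40.0, 69.0, n),
            "male": rng.binomial(1, 0.45, n),
            "race": rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS),
        }
    )
    # 10-year baseline cardiovascular risk, log-normal around a 5% median
    df["ascvd_risk"] = np.exp(rng.normal(np.log(0.05), 0.5, n))
    df["log_ascvd"] = (np.log(df["ascvd_risk"]) - np.log(0.05)) / 0.5
    pcs = rng.normal(0.0, 1.0, size=(n, 10))
    for k in range(10):
        df[f"pc{k + 1}"] = pcs[:, k]
    return df


def _linear_predictor(cov: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    """Centered log-hazard contribution of the covariates."""
    lp = np.zeros(len(cov))
    centers = {"age": 54.5, "male": 0.45, "log_ascvd": 0.0}
    for name, beta in effects.items():
        lp += beta * (cov[name].to_numpy(dtype=float) - centers.get(name, 0.0))
    return lp


def simulate_sepsis(
    covariates: pd.DataFrame,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Exponential time-to-sepsis, calibrated to the target cumulative rate.

    The per-subject rate is ``lambda0 * exp(beta'x)``; ``lambda0`` is solved
    numerically so the realized-covariate expectation of
    ``1 - exp(-rate * followup)`` equals ``config.sepsis_rate`` exactly.
    Returns columns ``sepsis`` (onset within follow-up) and ``sepsis_onset``
    (years from recruitment; NaN for non-cases).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(covariates)
    out = pd.DataFrame(index=covariates.index)
    if config.sepsis_rate == 0 or n == 0:
        out["sepsis"] = np.zeros(n, dtype=bool)
        out["sepsis_onset"] = np.nan
        return out

    rel = np.exp(_linear_predictor(covariates, config.sepsis_covariate_effects))
    T = config.followup_years

    def mean_incidence(lam0: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam0 * rel * T))) - config.sepsis_rate

    lam0 = brentq(mean_incidence, 1e-12, 10.0, xtol=1e-14)
    onset = rng.exponential(1.0 / (lam0 * rel))
    case = onset <= T
    out["sepsis"] = case
    out["sepsis_onset"] = np.where(case, onset, np.nan)
    return out


# ---------------------------------------------------------------------------
# event times


def simulate_event_times(
    base_rate: np.ndarray,
    sepsis_onset: np.ndarray,
    multipliers: tuple[float, float, float],
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Piecewise-exponential event times by inversion.

    Each subject's hazard is ``base_rate`` before sepsis onset and
    ``base_rate * w_k`` in the three post-onset windows (0-30 d], (30 d-2 y],
    (>2 y).  ``sepsis_onset`` is in years (NaN/inf = never septic).  Returns
    event times in years (possibly inf).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = np.asarray(base_rate, dtype=float)
    n = r.size
    onset = np.asarray(sepsis_onset, dtype=float).copy()
    onset[~np.isfinite(onset)] = np.inf
    w1, w2, w3 = multipliers

    # segment boundaries per subject: 0, s, s+30d, s+730d, inf
    b = np.column_stack(
        [
            np.zeros(n),
            onset,
            onset + 30.0 / DAYS_PER_YEAR,
            onset + 730.0 / DAYS_PER_YEAR,
            np.full(n, np.inf),
        ]
    )
    rates = np.column_stack([r, r * w1, r * w2, r * w3])
    with np.errstate(invalid="ignore"):
        durations = np.diff(b, axis=1)
        seg_haz = np.where(durations > 0, rates * durations, 0.0)
    seg_haz = np.where(np.isnan(seg_haz), 0.0, seg_haz)  # inf segment * 0 rate
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(seg_haz, axis=1)], axis=1)

    e = rng.exponential(1.0, n)
    t = np.full(n, np.inf)
    remaining = e.copy()
    for k in range(4):
        hits = (remaining > cum[:, k]) & (remaining <= cum[:, k + 1]) & (rates[:, k] > 0)
        t[hits] = b[hits, k] + (remaining[hits] - cum[hits, k]) / rates[hits, k]
    return t


# ---------------------------------------------------------------------------
# full cohort


def _years_to_date(years) -> pd.Series | pd.DatetimeIndex:
    days = np.round(np.atleast_1d(np.asarray(years, dtype=float)) * DAYS_PER_YEAR)
    return RECRUITMENT_EPOCH + pd.to_timedelta(days, unit="D")


def simulate_cohort(
    config: SimulationConfig,
    panels: Mapping[str, SNPPanel] | None = None,
    include_genotypes: bool | None = None,
) -> SyntheticCohort:
    """Generate the full synthetic study: genotypes, GRS, registry, events.

    ``include_genotypes=None`` simulates genotypes exactly when the GRS
    enters the hazard (``grs_exponent != 0``); at ``gamma = 0`` every
    subject's GRS factor is 1 and genotypes are skipped for speed unless
    requested.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    if include_genotypes is None:
        include_genotypes = config.grs_exponent != 0.0

    if panels is None:
        panels = {
            t: simulate_panel(t, config.panel_sizes.get(t), seed=config.seed)
            for t in TRAITS
        }

    cov = simulate_covariates(n, rng)
    sep = simulate_sepsis(cov, config, rng)

    genotypes: dict[str, GenotypeMatrix] = {}
    grs_wide: pd.DataFrame | None = None
    grs_factor = {t: np.ones(n) for t in TRAITS}
    if include_genotypes:
        grs_wide = pd.DataFrame({"subject_id": cov["subject_id"]})
        for t in TRAITS:
            gm = simulate_genotypes(
                n,
                panels[t],
                rng,
                missing_rate=config.genotype_missing_rate,
                subject_ids=tuple(cov["subject_id"]),
            )
            genotypes[t] = gm
            res = compute_grs_matrix(gm, panels[t])
            grs_wide[f"grs_{t}"] = res["grs"].to_numpy()
            grs_wide[f"group_{t}"] = res["group"].to_numpy()
            grs_factor[t] = res["grs"].to_numpy() ** config.grs_exponent

    lp = _linear_predictor(cov, config.covariate_effects)
    onset = sep["sepsis_onset"].to_numpy()

    truth = cov.copy()
    truth["sepsis_onset"] = onset
    death = (
        rng.exponential(1.0 / config.death_rate, n)
        if config.death_rate > 0
        else np.full(n, np.inf)
    )
    truth["death_time"] = death
    for t in TRAITS:
        base = config.baseline_hazards[t] * grs_factor[t] * np.exp(lp)
        truth[f"time_{t}"] = simulate_event_times(
            base, onset, tuple(config.sepsis_hr_windows[t]), rng
        )
    if grs_wide is not None:
        for t in TRAITS:
            truth[f"grs_{t}"] = grs_wide[f"grs_{t}"]

    registry, events = _assemble_tables(truth, config, rng)
    return SyntheticCohort(
        config=config,
        panels=dict(panels),
        genotypes=genotypes,
        grs=grs_wide,
        registry=registry,
        events=events,
        truth=truth,
    )


_TRAIT_CODES = {"MI": ("ICD10", "I21.9"), "IS": ("ICD10", "I63.9"), "VTE": ("ICD10", "I80.2")}


def _assemble_tables(
    truth: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dated registry and diagnosis-event tables from the continuous truth."""
    n = len(truth)
    T = config.followup_years
    death = truth["death_time"].to_numpy()
    censor = np.minimum(death, T)

    registry = truth[["subject_id", "age", "male", "race", "ascvd_risk", "log_ascvd"]].copy()
    registry["recruit_date"] = RECRUITMENT_EPOCH
    registry["followup_end"] = _years_to_date(np.full(n, T))
    registry["death_date"] = pd.NaT
    died = death < T
    registry.loc[died, "death_date"] = _years_to_date(death[died])

    subject_ids = truth["subject_id"].to_numpy()
    frames = []
    onset = truth["sepsis_onset"].to_numpy()
    sepsis_obs = np.isfinite(onset) & (onset < censor)
    frames.append(
        pd.DataFrame(
            {
                "subject_id": subject_ids[sepsis_obs],
                "system": "ICD10",
                "code": "A41.9",
                "date": _years_to_date(onset[sepsis_obs]),
            }
        )
    )
    for t in TRAITS:
        sys_, code = _TRAIT_CODES[t]
        times = truth[f"time_{t}"].to_numpy()
        observed = np.isfinite(times) & (times <= censor)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[observed],
                    "system": sys_,
                    "code": code,
                    "date": _years_to_date(times[observed]),
                }
            )
        )
    rows = []

    # a small fraction of subjects carry a pre-recruitment sepsis code and
    # must be excluded from the incident cohort downstream
    if config.prevalent_sepsis_frac > 0 and n > 0:
        k = int(round(config.prevalent_sepsis_frac * n))
        prevalent = rng.choice(n, size=k, replace=False)
        for i in prevalent:
            rows.append(
                (
                    truth["subject_id"].iat[i],
                    "ICD10",
                    "A40.0",
                    RECRUITMENT_EPOCH - pd.Timedelta(days=365),
                )
            )
    if rows:
        frames.append(pd.DataFrame(rows, columns=["subject_id", "system", "code", "date"]))
    events = pd.concat(frames, ignore_index=True)
    events = events.sort_values(["subject_id", "date"], kind="stable").reset_index(drop=True)
    return registry, events


def records_from_truth(truth: pd.DataFrame, trait: str, followup_years: float) -> pd.DataFrame:
    """Survival records (continuous time, no date rounding) from the truth table.

    Applies the study's origin convention: non-sepsis subjects are timed from
    recruitment, sepsis subjects from sepsis onset; subjects whose outcome,
    death or censoring precedes their sepsis onset revert to the appropriate
    handling (death before onset means never diagnosed; an event before onset
    removes the subject from that outcome's post-sepsis analysis).
    """
    T = followup_years
    death = truth["death_time"].to_numpy()
    censor = np.minimum(death, T)
    onset = truth["sepsis_onset"].to_numpy()
    etime = truth[f"time_{trait}"].to_numpy()

    sepsis = np.isfinite(onset) & (onset < censor)
    event_before_origin = sepsis & np.isfinite(etime) & (etime <= onset)
    keep = ~event_before_origin

    origin = np.where(sepsis, onset, 0.0)
    end = np.minimum(etime, censor)
    event = np.isfinite(etime) & (etime <= censor)
    rec = pd.DataFrame(
        {
            "subject_id": truth["subject_id"],
            "time": end - origin,
            "event": event,
            "sepsis": sepsis.astype(int),
            "age": truth["age"],
            "male": truth["male"],
            "log_ascvd": truth["log_ascvd"],
        }
    )
    if "race" in truth.columns:
        rec["race"] = truth["race"]
    rec = rec[keep & (rec["time"] > 0)]
    return rec.reset_index(drop=True)
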