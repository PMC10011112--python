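"""Population-standardized multiplicative genetic risk score (GRS).

The score for one subject and one trait is

    GRS = prod_i OR_i**g_i / W_i,
    W_i = f_i**2 * OR_i**2 + 2 f_i (1 - f_i) OR_i + (1 - f_i)**2,

where ``g_i`` is the subject's risk-allele dosage at SNP i (0, 1, or 2),
``OR_i`` the per-allele odds ratio from an external GWAS, and ``f_i`` the risk
allele frequency in the reference population.  ``W_i`` is the Hardy–Weinberg
expectation of ``OR_i**g_i``, so each factor — and hence the product — has
population mean 1, and a subject's GRS reads directly as relative risk versus
the general population (GRS 1.5 ≈ 1.5-fold the population-average risk).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .genotypes import GenotypeMatrix
    from .panel import SNPPanel

__all__ = [
    "compute_w",
    "per_snp_term",
    "compute_grs",
    "compute_grs_matrix",
    "assign_risk_group",
    "assign_combined_group",
    "GRSResult",
    "RISK_GROUPS",
    "COMBINED_GROUPS",
    "LOW_CUT",
    "HIGH_CUT",
]

#: Risk-group cut points on the GRS scale: low < 0.5 <= intermediate < 2.0 <= high.
LOW_CUT = 0.5
HIGH_CUT = 2.0

RISK_GROUPS = ("low", "intermediate", "high")
#: Cross-trait summary groups: all three GRS < 1.0 / any GRS >= 2.0 / the rest.
COMBINED_GROUPS = ("all_low", "remaining", "any_high")

MISSING = -1  # sentinel dosage, shared with genotypes module


@dataclass(frozen=True)
class GRSResult:
    """Per-subject, per-trait score with missingness bookkeeping."""

    subject_id: str
    trait: str
    grs: float
    n_snps_used: int
    n_missing: int
    group: str
    all_missing: bool = False


def compute_w(odds_ratio: float, risk_freq: float) -> float:
    """Hardy–Weinberg expectation of ``OR**g`` at risk-allele frequency ``f``.

    W = f²·OR² + 2f(1−f)·OR + (1−f)².  At OR = 1 the three terms sum to
    (f + (1−f))² = 1 for any f.
    """
    if np.any(np.asarray(odds_ratio) <= 0):
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")
    f = np.asarray(risk_freq, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError(f"risk_freq must lie in [0, 1], got {risk_freq}")
    orr = np.asarray(odds_ratio, dtype=float)
    w = f**2 * orr**2 + 2 * f * (1 - f) * orr + (1 - f) ** 2
    return float(w) if np.isscalar(odds_ratio) and np.isscalar(risk_freq) else w


def per_snp_term(dosage: int, odds_ratio: float, risk_freq: float) -> float:
    """Single-SNP factor ``OR**g / W`` of the multiplicative score.

    Under Hardy–Weinberg genotypes at frequency ``f`` this factor has
    expectation exactly 1, which is what makes the product population
    standardized.
    """
    if dosage not in (0, 1, 2):
        raise ValueError(f"dosage must be 0, 1 or 2, got {dosage}")
    return odds_ratio**dosage / compute_w(odds_ratio, risk_freq)


def compute_grs(
    dosages: Mapping[str, int],
    panel: "SNPPanel",
    subject_id: str = "",
    missing_policy: str = "expected_term",
) -> GRSResult:
    """Score one subject from a per-rsid dosage map.

    Missing SNPs (absent keys or the ``MISSING`` sentinel) contribute a factor
    of 1 — exactly the Hardy–Weinberg expectation of the factor they replace —
    so missingness shrinks the score toward the population mean rather than
    biasing it up or down.
    """
    if missing_policy != "expected_term":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if len(panel) == 0:
        raise ValueError("cannot score against an empty panel")
    unknown = set(dosages) - set(panel.rsids)
    if unknown:
        raise KeyError(f"dosage keys not in panel: {sorted(unknown)}")

    log_grs = 0.0
    n_used = 0
    for snp in panel:
        g = dosages.get(snp.rsid, MISSING)
        if g == MISSING:
            continue
        log_grs += np.log(per_snp_term(int(g), snp.odds_ratio, snp.risk_freq))
        n_used += 1
    grs = float(np.exp(log_grs))
    n_missing = len(panel) - n_used
    return GRSResult(
        subject_id=subject_id,
        trait=panel.trait,
        grs=grs,
        n_snps_used=n_used,
        n_missing=n_missing,
        group=assign_risk_group(grs),
        all_missing=(n_used == 0),
    )


def compute_grs_matrix(genotypes: "GenotypeMatrix", panel: "SNPPanel") -> pd.DataFrame:
    """Vectorized scoring of a full cohort.

    Returns a DataFrame with columns ``subject_id trait grs n_snps_used
    n_missing group``, one row per subject, in genotype-matrix subject order.
    Panel SNPs absent from the genotype matrix count as missing for every
    subject.
    """
    if len(panel) == 0:
        raise ValueError("cannot score against an empty panel")
    col = {r: j for j, r in enumerate(genotypes.rsids)}

    n = len(genotypes.subject_ids)
    log_sum = np.zeros(n)
    n_used = np.zeros(n, dtype=int)
    for snp in panel:
        j = col.get(snp.rsid)
        if j is None:
            continue
        g = genotypes.dosage[:, j]
        ok = g != MISSING
        w = compute_w(snp.odds_ratio, snp.risk_freq)
        # log-term lookup by dosage: g in {0,1,2} -> g*log(OR) - log(W)
        log_sum[ok] += g[ok] * np.log(snp.odds_ratio) - np.log(w)
        n_used += ok.astype(int)

    grs = np.exp(log_sum)
    groups = np.array(
        [assign_risk_group(v) for v in grs], dtype=object
    )
    return pd.DataFrame(
        {
            "subject_id": list(genotypes.subject_ids),
            "trait": panel.trait,
            "grs": grs,
            "n_snps_used": n_used,
            "n_missing": len(panel) - n_used,
            "group": groups,
        }
    )


def assign_risk_group(
    grs: float, low_cut: float = LOW_CUT, high_cut: float = HIGH_CUT
) -> str:
    """Bin a score: low < ``low_cut`` ≤ intermediate < ``high_cut`` ≤ high."""
    if low_cut >= high_cut:
        raise ValueError(f"low_cut {low_cut} must be below high_cut {high_cut}")
    if grs <= 0:
        raise ValueError(f"grs must be positive, got {grs}")
    if grs < low_cut:
        return "low"
    if grs >= high_cut:
        return "high"
    return "intermediate"


def assign_combined_group(grs_mi: float, grs_is: float, grs_vte: float) -> str:
    """Cross-trait summary label from the three per-trait scores.

    ``any_high`` if any score is ≥ 2.0; ``all_low`` if all three are < 1.0;
    otherwise ``remaining``.
    """
    vals = (grs_mi, grs_is, grs_vte)
    if any(v <= 0 for v in vals):
        raise ValueError(f"all GRS values must be positive, got {vals}")
    if max(vals) >= 2.0:
        return "any_high"
    if max(vals) < 1.0:
        return "all_low"
    return "remaining"
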