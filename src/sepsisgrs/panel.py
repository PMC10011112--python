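"""SNP risk panels: loading, validation, GWAS-significance filtering, LD pruning.

A panel parameterizes one trait's genetic risk score.  Each record carries the
risk allele, its per-allele odds ratio ``OR`` from an external GWAS, the risk
allele frequency ``f`` in the reference population, and the derived
standardization constant ``W`` — the Hardy–Weinberg expectation of ``OR**g``
at frequency ``f`` (see :mod:`sepsisgrs.grs`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grs import compute_w

__all__ = [
    "SNPRecord",
    "SNPPanel",
    "LDMatrix",
    "load_panel",
    "load_ld_matrix",
    "filter_gwas_significant",
    "ld_prune",
]

PANEL_COLUMNS = [
    "rsid",
    "chrom",
    "pos",
    "risk_allele",
    "other_allele",
    "odds_ratio",
    "risk_freq",
    "gwas_p",
]

TRAITS = ("MI", "IS", "VTE")


class PanelError(ValueError):
    """Malformed or invalid panel input."""


@dataclass(frozen=True)
class SNPRecord:
    """One risk-associated SNP with its score parameters."""

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    odds_ratio: float
    risk_freq: float
    gwas_p: float
    w: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise PanelError(f"{self.rsid}: odds_ratio must be > 0, got {self.odds_ratio}")
        if not (0.0 < self.risk_freq < 1.0):
            raise PanelError(f"{self.rsid}: risk_freq must be in (0, 1), got {self.risk_freq}")
        if not (0.0 < self.gwas_p <= 1.0):
            raise PanelError(f"{self.rsid}: gwas_p must be in (0, 1], got {self.gwas_p}")
        if self.risk_allele == self.other_allele:
            raise PanelError(f"{self.rsid}: risk and other allele are identical")
        if np.isnan(self.w):
            object.__setattr__(self, "w", compute_w(self.odds_ratio, self.risk_freq))

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous (A/T or C/G) SNPs."""
        pair = {self.risk_allele.upper(), self.other_allele.upper()}
        return pair in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class SNPPanel:
    """Ordered collection of SNP records for one trait."""

    trait: str
    snps: tuple[SNPRecord, ...]
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise PanelError(f"unknown trait {self.trait!r}; expected one of {TRAITS}")
        rsids = [s.rsid for s in self.snps]
        dupes = {r for r in rsids if rsids.count(r) > 1}
        if dupes:
            raise PanelError(f"duplicate rsids in panel: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    def record(self, rsid: str) -> SNPRecord:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise KeyError(rsid)

    def subset(self, rsids: Iterable[str]) -> "SNPPanel":
        """Restrict to the given rsids, preserving the panel's own order."""
        keep = set(rsids)
        return replace(self, snps=tuple(s for s in self.snps if s.rsid in keep))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {c: getattr(s, c) for c in PANEL_COLUMNS} | {"w": s.w} for s in self.snps
        ]
        return pd.DataFrame(rows, columns=PANEL_COLUMNS + ["w"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame()[PANEL_COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise r-squared between panel SNPs, keyed by rsid."""

    rsids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if r2.shape != (n, n):
            raise PanelError(f"LD matrix shape {r2.shape} does not match {n} rsids")
        if not np.allclose(r2, r2.T, atol=1e-9):
            raise PanelError("LD matrix is not symmetric")
        if np.nanmin(r2) < -1e-12 or np.nanmax(r2) > 1 + 1e-12:
            raise PanelError("LD r2 values must lie in [0, 1]")
        object.__setattr__(self, "r2", r2)

    def value(self, a: str, b: str) -> float:
        idx = {r: i for i, r in enumerate(self.rsids)}
        try:
            return float(self.r2[idx[a], idx[b]])
        except KeyError as e:
            raise PanelError(f"rsid {e.args[0]!r} missing from LD matrix") from None


def load_panel(path: str | Path, trait: str = "MI") -> SNPPanel:
    """Read a tab-separated panel file.

    Expected header: ``rsid chrom pos risk_allele other_allele odds_ratio
    risk_freq gwas_p``.  Lines starting with ``#`` are comments.  Validation
    failures name the offending line or rsid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise PanelError(f"{path}: cannot parse panel file: {e}") from e
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelError(f"{path}: missing required columns {missing}")

    records = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            rec = SNPRecord(
                rsid=str(row["rsid"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                risk_allele=str(row["risk_allele"]),
                other_allele=str(row["other_allele"]),
                odds_ratio=float(row["odds_ratio"]),
                risk_freq=float(row["risk_freq"]),
                gwas_p=float(row["gwas_p"]),
            )
        except PanelError:
            raise
        except (TypeError, ValueError) as e:
            raise PanelError(f"{path}: malformed row at line {line_no}: {e}") from e
        records.append(rec)
    return SNPPanel(trait=trait, snps=tuple(records), source_note=str(path))


def load_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square TSV whose header row and first column are rsids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise PanelError(f"{path}: LD matrix row and column rsids differ")
    return LDMatrix(rsids=tuple(df.columns), r2=df.to_numpy(dtype=float))


def filter_gwas_significant(panel: SNPPanel, alpha: float = 5e-8) -> SNPPanel:
    """Keep records with GWAS p strictly below ``alpha``; order preserved."""
    return replace(panel, snps=tuple(s for s in panel.snps if s.gwas_p < alpha))


def ld_prune(panel: SNPPanel, ld: LDMatrix, r2_max: float = 0.2) -> SNPPanel:
    """Greedy LD pruning retaining the highest-``W`` SNP among correlated ones.

    SNPs are visited in order of decreasing ``W`` (ties broken by rsid); a SNP
    is accepted iff its r² with every already-accepted SNP is strictly below
    ``r2_max``.  The retained set therefore has all pairwise r² < ``r2_max``,
    and within any correlated cluster the highest-``W`` member survives.  The
    result is returned in the original panel order and is independent of the
    input row order.
    """
    idx = {r: i for i, r in enumerate(ld.rsids)}
    for s in panel.snps:
        if s.rsid not in idx:
            raise PanelError(f"rsid {s.rsid!r} missing from LD matrix")

    order = sorted(panel.snps, key=lambda s: (-s.w, s.rsid))
    accepted: list[SNPRecord] = []
    for cand in order:
        i = idx[cand.rsid]
        if all(ld.r2[i, idx[a.rsid]] < r2_max for a in accepted):
            accepted.append(cand)
    keep = {s.rsid for s in accepted}
    return replace(panel, snps=tuple(s for s in panel.snps if s.rsid in keep))
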