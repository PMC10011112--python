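"""Genotype input: VCF and dosage-TSV readers aligned to panel risk alleles.

Everything downstream works on risk-allele *dosages* — the count of copies of
the panel's risk allele a subject carries (0, 1, 2, or missing).  A VCF stores
REF/ALT genotype calls, so each panel SNP must be oriented: if the risk allele
is the ALT allele the dosage is the ALT count, if it is the REF allele the
dosage is ``2 - ALT count``, and any other allele pairing is an error rather
than a silent guess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .grs import MISSING

if TYPE_CHECKING:  # pragma: no cover
    from .panel import SNPPanel

__all__ = [
    "GenotypeMatrix",
    "read_vcf_dosages",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "flip_orientation",
    "AlleleMismatchError",
]


class AlleleMismatchError(ValueError):
    """Panel alleles match neither REF/ALT orientation of a VCF record."""


class GenotypeParseError(ValueError):
    """Malformed genotype input."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Subjects × SNPs risk-allele dosages; ``-1`` encodes missing."""

    subject_ids: tuple[str, ...]
    rsids: tuple[str, ...]
    dosage: np.ndarray  # int8, shape (n_subjects, n_snps)

    def __post_init__(self) -> None:
        d = np.asarray(self.dosage, dtype=np.int8)
        if d.shape != (len(self.subject_ids), len(self.rsids)):
            raise GenotypeParseError(
                f"dosage shape {d.shape} inconsistent with "
                f"{len(self.subject_ids)} subjects x {len(self.rsids)} SNPs"
            )
        bad = ~np.isin(d, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeParseError(
                f"dosage entry {int(d[i, j])} at subject {self.subject_ids[i]!r}, "
                f"SNP {self.rsids[j]!r} not in {{0, 1, 2, missing}}"
            )
        object.__setattr__(self, "dosage", d)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    def subject_dosages(self, subject_id: str) -> dict[str, int]:
        """Per-rsid dosage map for one subject, omitting missing entries."""
        i = self.subject_ids.index(subject_id)
        row = self.dosage[i]
        return {r: int(g) for r, g in zip(self.rsids, row) if g != MISSING}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosage.astype(float), index=list(self.subject_ids), columns=list(self.rsids)
        )
        return df.mask(df < 0)


def flip_orientation(dosage_row: np.ndarray | Sequence[int]) -> np.ndarray:
    """Swap 0 ↔ 2 (counting the opposite allele); 1 and missing are fixed."""
    row = np.asarray(dosage_row, dtype=np.int8)
    out = row.copy()
    ok = row != MISSING
    out[ok] = 2 - row[ok]
    return out


def _warn_palindromic(panel: "SNPPanel") -> None:
    ambiguous = [s.rsid for s in panel if s.is_palindromic]
    if ambiguous:
        warnings.warn(
            f"strand-ambiguous (A/T or C/G) panel SNPs: {ambiguous}; "
            "orientation is taken at face value, verify strand upstream",
            UserWarning,
            stacklevel=3,
        )


def read_vcf_dosages(path: str | Path, panel: "SNPPanel") -> GenotypeMatrix:
    """Read hard-call GT genotypes for the panel's SNPs from a VCF.

    Records are matched by rsid first, then by (chrom, pos).  Panel SNPs
    absent from the VCF become all-missing columns; ``./.`` calls are missing.
    Only biallelic, diploid records are accepted at panel sites.
    """
    from cyvcf2 import VCF  # deferred: optional at import time

    _warn_palindromic(panel)
    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    n = len(samples)
    by_rsid = {s.rsid: k for k, s in enumerate(panel)}
    by_pos = {(s.chrom, s.pos): k for k, s in enumerate(panel)}

    dosage = np.full((n, len(panel)), MISSING, dtype=np.int8)
    seen: set[int] = set()
    for rec in vcf:
        k = by_rsid.get(rec.ID) if rec.ID else None
        if k is None:
            k = by_pos.get((str(rec.CHROM), rec.POS))
        if k is None or k in seen:
            continue
        snp = panel.snps[k]
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"multiallelic VCF record at panel site {snp.rsid} "
                f"({rec.CHROM}:{rec.POS})"
            )
        ref, alt = rec.REF, rec.ALT[0]
        if (snp.risk_allele, snp.other_allele) == (alt, ref):
            flip = False
        elif (snp.risk_allele, snp.other_allele) == (ref, alt):
            flip = True
        else:
            raise AlleleMismatchError(
                f"{snp.rsid}: panel alleles ({snp.risk_allele}, {snp.other_allele}) "
                f"match neither orientation of VCF REF/ALT ({ref}, {alt})"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        alt_count = np.select(
            [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        col = alt_count if not flip else flip_orientation(alt_count)
        ploidy = rec.ploidy
        if ploidy != 2:
            raise GenotypeParseError(
                f"{snp.rsid}: ploidy {ploidy} unsupported; diploid autosomal GT required"
            )
        dosage[:, k] = col
        seen.add(k)

    return GenotypeMatrix(subject_ids=samples, rsids=panel.rsids, dosage=dosage)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    """Read a dosage matrix TSV: header of rsids, first column subject_id,
    cells in {0, 1, 2, NA}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "subject_id":
        raise GenotypeParseError(f"{path}: first column must be 'subject_id'")
    rsids = tuple(df.columns[1:])
    subjects = tuple(df["subject_id"].astype(str))

    dosage = np.full((len(subjects), len(rsids)), MISSING, dtype=np.int8)
    for j, rsid in enumerate(rsids):
        col = df[rsid]
        for i, v in enumerate(col):
            if pd.isna(v) or v == "NA":
                continue
            if v not in ("0", "1", "2"):
                raise GenotypeParseError(
                    f"{path}: invalid dosage {v!r} at row {i + 2}, column {rsid!r}"
                )
            dosage[i, j] = int(v)
    return GenotypeMatrix(subject_ids=subjects, rsids=rsids, dosage=dosage)


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Inverse of :func:`read_dosage_tsv` (missing written as NA)."""
    df = genotypes.to_frame()
    df.index.name = "subject_id"
    out = df.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t")
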