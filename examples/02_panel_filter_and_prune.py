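"""Filter a SNP panel to GWAS-significant hits and prune it for LD.

Writes a small panel and LD matrix to a temporary directory, loads them back
through the file interfaces, then applies the two selection steps used to
build a score panel: keep SNPs with p < 5e-8, and among SNPs in linkage
disequilibrium (r^2 >= 0.2) keep the one with the highest standardization
weight W.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from sepsisgrs import filter_gwas_significant, ld_prune, load_ld_matrix, load_panel

rows = [
    # rsid chrom pos risk other OR freq p
    ("rs100", 1, 1000, "A", "G", 1.8, 0.30, 1e-12),
    ("rs101", 1, 1500, "T", "C", 1.4, 0.30, 1e-10),  # in LD with rs100
    ("rs200", 2, 5000, "A", "C", 1.3, 0.50, 1e-09),
    ("rs300", 3, 9000, "T", "G", 1.6, 0.20, 1e-06),  # not genome-wide significant
]
r2 = pd.DataFrame(np.eye(4), index=[r[0] for r in rows], columns=[r[0] for r in rows])
r2.loc["rs100", "rs101"] = r2.loc["rs101", "rs100"] = 0.65

with tempfile.TemporaryDirectory() as d:
    ppath = Path(d) / "panel.tsv"
    header = "rsid\tchrom\tpos\trisk_allele\tother_allele\todds_ratio\trisk_freq\tgwas_p\n"
    ppath.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))
    ldpath = Path(d) / "ld.tsv"
    r2.to_csv(ldpath, sep="\t")

    panel = load_panel(ppath, trait="MI")
    ld = load_ld_matrix(ldpath)

print("loaded:     ", ", ".join(f"{s.rsid} (W={s.w:.3f}, p={s.gwas_p:.0e})" for s in panel))
sig = filter_gwas_significant(panel)
print("significant:", ", ".join(s.rsid for s in sig), " (rs300 dropped: p >= 5e-8)")
pruned = ld_prune(sig, ld)
print("LD-pruned:  ", ", ".join(s.rsid for s in pruned), " (rs101 dropped: r2=0.65 with the higher-W rs100)")
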