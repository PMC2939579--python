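"""Published FOXI1 resequencing results, packaged as in-memory fixtures.

The human FOXI1 gene (chromosome 5) was resequenced over 4,007 bp in 20
Yoruba, 20 European and 20 East Asian individuals (40 chromosomes per
population), yielding 22 variants — 21 substitutions and one
insertion/deletion, coded here like any other biallelic site.  Derived
allele frequencies were printed to two decimals, so integer counts are
recovered as round(DAF x 40), which is exact for 2N = 40.  The
haplotype table lists the 15 haplotypes observed after excluding
singleton variants, with per-continent counts.  These tables drive the
desk-scale validation of every diversity and FST routine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diversity import derived_counts_from_daf

SURVEYED_BP = 4007
TWO_N = 40
POPULATIONS = ("Yoruban", "European", "Asian")

# position (NCBI build 36.3, chr5), dbSNP id, site class, anc/der alleles,
# DAF per population (Yoruban, European, Asian)
_VARIANTS = [
    (169465818, "rs2277944",  "CS",  "G", "A", 0.58, 0.20, 0.35),
    (169466184, "rs2277945",  "I",   "T", "C", 0.23, 0.28, 0.43),
    (169466367, "rs2112669",  "I",   "C", "G", 0.55, 0.23, 0.33),
    (169466686, "rs11951903", "I",   "T", "C", 0.05, 0.00, 0.25),
    (169466751, "rs4315934",  "I",   "A", "G", 0.88, 0.55, 0.78),
    (169466837, "rs4315935",  "I",   "A", "G", 0.88, 0.55, 0.78),
    (169467111, "rs2879269",  "I",   "A", "G", 0.03, 0.10, 0.00),
    (169467123, "rs7380481",  "I",   "T", "C", 0.23, 0.28, 0.43),
    (169467572, "rs77136537", "I",   "G", "A", 0.00, 0.03, 0.00),
    (169468070, "rs55685928", "CS",  "G", "A", 0.05, 0.00, 0.00),
    (169468100, "rs10063424", "CS",  "C", "T", 0.10, 0.10, 0.00),
    (169468141, "rs3828625",  "CNS", "A", "G", 0.00, 0.00, 0.03),
    (169468312, "rs6873124",  "UTR", "C", "A", 0.53, 0.20, 0.33),
    (169468336, "rs55762796", "UTR", "A", "T", 0.05, 0.08, 0.03),
    (169468524, "rs72828668", "UTR", "G", "C", 0.00, 0.00, 0.03),
    (169468633, "rs6555887",  "UTR", "A", "G", 0.15, 0.10, 0.00),
    (169468728, "rs6555888",  "UTR", "A", "G", 0.83, 0.70, 0.95),
    (169468749, "rs77823283", "UTR", "A", "G", 0.00, 0.03, 0.00),
    (169468769, "chr5:169468769", "UTR", "T", "A", 0.00, 0.03, 0.00),
    (169469034, "chr5:169469034", "UTR", "T", "A", 0.03, 0.00, 0.00),
    (169469117, "rs45466695", "UTR", "C", "T", 0.00, 0.08, 0.00),
    (169469123, "rs3839285",  "UTR", "-", "T", 0.53, 0.20, 0.33),
]

# per-continent counts of the 15 non-singleton haplotypes
_HAPLOTYPE_COUNTS = {
    "Europe": [8, 0, 0, 10, 1, 3, 7, 6, 1, 0, 0, 0, 1, 3, 0],
    "Africa": [19, 2, 1, 8, 0, 2, 1, 1, 0, 2, 1, 1, 1, 0, 1],
    "Asia":   [3, 10, 1, 16, 0, 1, 7, 2, 0, 0, 0, 0, 0, 0, 0],
}

# haplotype counts behind the published per-population K and Hd
# (Africa: 12 distinct haplotypes over 40 chromosomes)
AFRICA_HAPLOTYPE_COUNTS = (19, 2, 1, 8, 2, 1, 1, 2, 1, 1, 1, 1)


def foxi1_variant_table() -> pd.DataFrame:
    """22 variants with per-population DAFs and derived counts."""
    df = pd.DataFrame(_VARIANTS, columns=[
        "pos", "id", "site_class", "anc_allele", "der_allele",
        "daf_Yoruban", "daf_European", "daf_Asian"])
    for pop in POPULATIONS:
        df[f"count_{pop}"] = [derived_counts_from_daf(f, TWO_N)
                              for f in df[f"daf_{pop}"]]
    return df


def foxi1_derived_counts() -> dict[str, np.ndarray]:
    """Derived counts per population (including monomorphic zeros),
    plus the pooled sample of 120 chromosomes."""
    df = foxi1_variant_table()
    out = {pop: df[f"count_{pop}"].to_numpy() for pop in POPULATIONS}
    out["All"] = sum(out[p] for p in POPULATIONS)
    return out


def foxi1_haplotype_table() -> pd.DataFrame:
    """15 non-singleton haplotypes with per-continent counts."""
    return pd.DataFrame(_HAPLOTYPE_COUNTS,
                        index=[f"Ht-{i:02d}" for i in range(1, 16)])


def foxi1_expected() -> pd.DataFrame:
    """Published per-population summary statistics used as desk-scale
    validation targets."""
    rows = {
        "European": dict(two_n=40, S=17, pi=0.0012, K=12, Hd=0.874,
                         tajimas_D=0.485, fu_li_D_star=0.431, fu_li_D=0.433,
                         fu_li_F_star=0.530, fu_li_F=0.543, fu_fs=-0.421,
                         fay_wu_H=1.600),
        "Asian": dict(two_n=40, S=13, pi=0.0010, K=8, Hd=0.768,
                      tajimas_D=1.134, fu_li_D_star=0.065, fu_li_D=0.030,
                      fu_li_F_star=0.486, fu_li_F=0.485, fu_fs=1.969,
                      fay_wu_H=-1.923),
        "Yoruban": dict(two_n=40, S=16, pi=0.0011, K=12, Hd=0.741,
                        tajimas_D=0.487, fu_li_D_star=0.763, fu_li_D=0.799,
                        fu_li_F_star=0.793, fu_li_F=0.831, fu_fs=-0.664,
                        fay_wu_H=-2.928),
        "All": dict(two_n=120, S=22, pi=0.0012, K=19, Hd=0.837,
                    tajimas_D=0.360, fu_li_D_star=-0.808, fu_li_D=-0.863,
                    fu_li_F_star=-0.430, fu_li_F=-0.458, fu_fs=-1.417,
                    fay_wu_H=-0.410),
    }
    return pd.DataFrame(rows).T


def foxi1_fst_expected() -> dict[str, float]:
    """Published per-SNP AMOVA FST values among the three samples."""
    df = foxi1_variant_table()
    fst = [0.123, 0.026, 0.092, 0.162, 0.113, 0.113, 0.042, 0.026, 0.000,
           0.026, 0.028, 0.000, 0.091, -0.012, 0.000, 0.051, 0.082, 0.000,
           0.000, 0.000, 0.051, 0.091]
    return dict(zip(df["id"], fst))
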