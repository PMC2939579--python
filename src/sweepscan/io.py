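"""Readers and writers for the formats the pipeline consumes.

Phased VCF is read through cyvcf2; everything else is plain TSV/BED.
The haplotype-matrix TSV dialect is: a header row of site ids, then one
row per chromosome, first column the chromosome id (``sample_1`` /
``sample_2`` for diploids), remaining columns 0/1 alleles (``.`` for
missing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datamodel import MISSING, GeneticMap, HaplotypeMatrix, PopulationPanel, SiteTable


def read_phased_vcf(path: str, panel: PopulationPanel | None = None
                    ) -> tuple[SiteTable, HaplotypeMatrix]:
    """Read a phased, biallelic VCF into a haplotype matrix.

    Sites are polarized from the INFO/AA tag where it matches REF or
    ALT; a column whose ancestral allele is ALT is recoded so that 1
    means derived.  Sites without a usable AA are flagged unpolarized
    and keep REF=0/ALT=1 coding.

    Raises ``ValueError`` for unphased genotypes (naming the record) and
    for multiallelic records.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chrom, pos, ids, anc, der, polar = [], [], [], [], [], []
    columns = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {rec.CHROM}:{rec.POS}")
        gts = rec.genotypes  # [allele_a, allele_b, phased]
        col = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            if len(g) == 2:  # haploid call
                a, phased = g
                b = a
            else:
                a, b, phased = g[0], g[1], g[-1]
                if not phased:
                    raise ValueError(
                        f"unphased genotype for sample {samples[i]} at "
                        f"{rec.CHROM}:{rec.POS}")
            col[2 * i] = MISSING if a < 0 else a
            col[2 * i + 1] = MISSING if b < 0 else b
        aa = rec.INFO.get("AA")
        ref, alt = rec.REF, rec.ALT[0]
        if aa is not None and aa.upper() == alt.upper():
            # ancestral is ALT: flip so 1 = derived
            flip = col.copy()
            flip[col == 0] = 1
            flip[col == 1] = 0
            col = flip
            a_allele, d_allele, pol = alt, ref, True
        elif aa is not None and aa.upper() == ref.upper():
            a_allele, d_allele, pol = ref, alt, True
        else:
            a_allele, d_allele, pol = ref, alt, False
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        anc.append(a_allele)
        der.append(d_allele)
        polar.append(pol)
        columns.append(col)
    sites = SiteTable(np.array(chrom, dtype=object), np.array(pos),
                      np.array(ids, dtype=object), np.array(anc, dtype=object),
                      np.array(der, dtype=object), np.array(polar))
    alleles = (np.column_stack(columns) if columns
               else np.empty((2 * len(samples), 0), dtype=np.int8))
    cids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    return sites, HaplotypeMatrix(alleles, cids, sites)


def write_haplotypes_tsv(path: str, matrix: HaplotypeMatrix) -> None:
    with open(path, "w") as fh:
        fh.write("chromosome\t" + "\t".join(str(i) for i in matrix.sites.ids) + "\n")
        for cid, row in zip(matrix.sample_ids, matrix.alleles):
            cells = ["." if a == MISSING else str(int(a)) for a in row]
            fh.write(cid + "\t" + "\t".join(cells) + "\n")


def read_haplotypes_tsv(path: str, sites: SiteTable | None = None) -> HaplotypeMatrix:
    """Read the haplotype TSV dialect; positions default to 1..n_sites
    unless a :class:`SiteTable` is supplied."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cids = df.iloc[:, 0].tolist()
    cells = df.iloc[:, 1:].to_numpy(dtype=object)
    alleles = np.where(cells == ".", MISSING, cells).astype(np.int8)
    if sites is None:
        ids = list(df.columns[1:])
        try:  # ids that are bare integers carry the bp position
            pos = np.array([int(i) for i in ids], dtype=np.int64)
        except ValueError:
            pos = np.arange(1, len(ids) + 1)
        sites = SiteTable.simple(pos, ids=ids)
    return HaplotypeMatrix(alleles, cids, sites)


def write_sites_tsv(path: str, sites: SiteTable) -> None:
    sites.to_frame().to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str) -> SiteTable:
    df = pd.read_csv(path, sep="\t")
    return SiteTable(df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(),
                     df["id"].to_numpy(dtype=object),
                     df["anc_allele"].to_numpy(dtype=object),
                     df["der_allele"].to_numpy(dtype=object),
                     df["polarized"].to_numpy(dtype=bool))


def read_genetic_map(path: str) -> GeneticMap:
    """TSV ``pos_bp<TAB>cM`` (with or without header) or 4-column PLINK
    ``.map`` (chrom, id, cM, bp)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#", dtype=str)
    if df.shape[1] == 4:  # PLINK map
        cm = df.iloc[:, 2].astype(float).to_numpy()
        bp = df.iloc[:, 3].astype(float).to_numpy()
    else:
        # drop a header line if the first cell is not numeric
        try:
            float(df.iloc[0, 0])
        except ValueError:
            df = df.iloc[1:]
        bp = df.iloc[:, 0].astype(float).to_numpy()
        cm = df.iloc[:, 1].astype(float).to_numpy()
    order = np.argsort(bp)
    return GeneticMap(bp[order], cm[order])


def read_panel_tsv(path: str) -> PopulationPanel:
    """Panel TSV with columns sample, population, region, latitude, longitude."""
    df = pd.read_csv(path, sep="\t")
    sp = dict(zip(df["sample"].astype(str), df["population"].astype(str)))
    pops = df.drop_duplicates("population")
    pr = dict(zip(pops["population"].astype(str), pops.get("region", pops["population"]).astype(str)))
    lat = (dict(zip(pops["population"].astype(str), pops["latitude"].astype(float)))
           if "latitude" in df.columns else {})
    lon = (dict(zip(pops["population"].astype(str), pops["longitude"].astype(float)))
           if "longitude" in df.columns else {})
    two_n = df.groupby("population")["sample"].count().mul(2).to_dict()
    return PopulationPanel(sp, pr, lat, lon, {str(k): int(v) for k, v in two_n.items()})


def read_genes_bed(path: str) -> pd.DataFrame:
    """BED3+ gene spans (0-based half-open starts, per BED convention)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name=[f"gene{i}" for i in range(len(df))])
    df.columns = ["chrom", "start", "end", "name"]
    return df
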