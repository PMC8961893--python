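"""In-memory genotype panel and VCF / metadata I/O.

The central container is :class:`GenotypePanel`: a samples x variants matrix of
biallelic genotype dosages (0/1/2, ``-1`` for missing) together with the
per-genotype fields a low-coverage variant caller emits — read depth (DP),
phred genotype quality (GQ), phred-scaled normalized genotype likelihoods (PL)
and, after imputation/refinement, genotype posteriors (GP).  Sample metadata
(collection site, stage, indoor/outdoor capture location, dusk/dawn capture
window) rides along as a pandas DataFrame.

VCF 4.2 reading and writing is delegated to pysam; only biallelic SNV records
are retained on read (multi-allelic records are dropped and counted, matching
the biallelic scope of every downstream statistic).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

MISSING = -1

#: metadata columns expected by stratified analyses
METADATA_COLUMNS = ("site", "stage", "location", "window")


@dataclass
class GenotypePanel:
    """Samples x biallelic-variants genotype matrix with per-genotype fields.

    Attributes
    ----------
    sample_ids : list of str
    variants : DataFrame with columns ``chrom, pos, ref, alt`` (pos 1-based)
    calls : int8 array (n_samples, n_variants); dosage of the alt allele,
        ``-1`` when missing
    dp, gq : int32 arrays (n_samples, n_variants)
    pl : int32 array (n_samples, n_variants, 3) in VCF genotype order
        (ref-hom, het, alt-hom); normalized so each triple contains a 0
    gp : optional float64 array (n_samples, n_variants, 3); posteriors
    mask : optional bool array; True where the genotype is flagged
        low-confidence (candidate for imputation)
    metadata : optional per-sample DataFrame indexed by sample id
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    calls: np.ndarray
    dp: np.ndarray
    gq: np.ndarray
    pl: np.ndarray
    gp: np.ndarray | None = None
    mask: np.ndarray | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n_s, n_v = self.calls.shape
        if len(self.sample_ids) != n_s:
            raise ValueError("sample_ids length does not match calls rows")
        if len(self.variants) != n_v:
            raise ValueError("variants length does not match calls columns")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("variant positions must be positive (1-based)")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean matrix of missing calls."""
        return self.calls == MISSING

    def strata(self, column: str = "site") -> np.ndarray:
        """Per-sample stratum labels from the metadata table."""
        if self.metadata is None:
            raise ValueError("panel has no sample metadata")
        return self.metadata.loc[self.sample_ids, column].to_numpy()

    def alt_allele_freq(self) -> np.ndarray:
        """Alternative-allele frequency per variant over non-missing calls.

        Monomorphic-by-missingness sites (no calls at all) yield ``nan``.
        """
        missing = self.calls == MISSING
        n = (~missing).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(missing, 0, self.calls).sum(axis=0) / (2.0 * n)
        return np.where(n > 0, freq, np.nan)

    def take_variants(self, index: np.ndarray) -> "GenotypePanel":
        """Subset variants by integer or boolean index, preserving order."""
        idx = np.asarray(index)
        return replace(
            self,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            calls=self.calls[:, idx],
            dp=self.dp[:, idx],
            gq=self.gq[:, idx],
            pl=self.pl[:, idx],
            gp=None if self.gp is None else self.gp[:, idx],
            mask=None if self.mask is None else self.mask[:, idx],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(index)
        ids = [self.sample_ids[i] for i in np.arange(self.n_samples)[idx]]
        return replace(
            self,
            sample_ids=ids,
            calls=self.calls[idx],
            dp=self.dp[idx],
            gq=self.gq[idx],
            pl=self.pl[idx],
            gp=None if self.gp is None else self.gp[idx],
            mask=None if self.mask is None else self.mask[idx],
            metadata=None if self.metadata is None else self.metadata.loc[ids],
        )

    def copy(self) -> "GenotypePanel":
        return replace(
            self,
            variants=self.variants.copy(),
            calls=self.calls.copy(),
            dp=self.dp.copy(),
            gq=self.gq.copy(),
            pl=self.pl.copy(),
            gp=None if self.gp is None else self.gp.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )


def _build_header(panel: GenotypePanel, with_gp: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    lengths = panel.variants.groupby("chrom", sort=False)["pos"].max()
    for chrom, maxpos in lengths.items():
        header.add_line(f"##contig=<ID={chrom},length={int(maxpos) + 1000}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line(
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (phred)">'
    )
    header.add_line(
        '##FORMAT=<ID=PL,Number=G,Type=Integer,'
        'Description="Normalized phred-scaled genotype likelihoods">'
    )
    if with_gp:
        header.add_line(
            '##FORMAT=<ID=GP,Number=G,Type=Float,'
            'Description="Genotype posterior probabilities">'
        )
    header.add_samples(panel.sample_ids)
    return header


_GT_FROM_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF 4.2 with GT:DP:GQ:PL[:GP]."""
    with_gp = panel.gp is not None
    header = _build_header(panel, with_gp)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, var in enumerate(panel.variants.itertuples(index=False)):
            rec = vf.new_record(
                contig=var.chrom,
                start=int(var.pos) - 1,
                stop=int(var.pos),
                alleles=(var.ref, var.alt),
            )
            for i, sid in enumerate(panel.sample_ids):
                fmt = rec.samples[sid]
                fmt["GT"] = _GT_FROM_DOSAGE[int(panel.calls[i, j])]
                fmt["DP"] = int(panel.dp[i, j])
                fmt["GQ"] = int(panel.gq[i, j])
                fmt["PL"] = tuple(int(x) for x in panel.pl[i, j])
                if with_gp:
                    fmt["GP"] = tuple(round(float(x), 5) for x in panel.gp[i, j])
            vf.write(rec)


def read_vcf(
    path: str | Path, metadata: pd.DataFrame | None = None
) -> tuple[GenotypePanel, int]:
    """Read a VCF into a :class:`GenotypePanel`.

    Returns the panel and the count of dropped non-biallelic-SNV records.
    Missing PL/GQ/DP entries default to flat PL, GQ 0, DP 0.
    """
    rows, calls, dps, gqs, pls, gps = [], [], [], [], [], []
    n_dropped = 0
    any_gp = False
    with pysam.VariantFile(str(path)) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
                n_dropped += 1
                continue
            rows.append((rec.chrom, rec.pos, rec.alleles[0], rec.alleles[1]))
            row_c, row_d, row_q, row_p, row_g = [], [], [], [], []
            for sid in sample_ids:
                fmt = rec.samples[sid]
                gt = fmt.get("GT", (None, None))
                if gt is None or any(a is None for a in gt):
                    row_c.append(MISSING)
                else:
                    row_c.append(int(sum(gt)))
                row_d.append(int(fmt.get("DP") or 0))
                row_q.append(int(fmt.get("GQ") or 0))
                pl = fmt.get("PL")
                if pl is None or any(x is None for x in pl):
                    pl = (0, 0, 0)
                row_p.append(tuple(int(x) for x in pl))
                gp = fmt.get("GP")
                if gp is not None and not any(x is None for x in gp):
                    any_gp = True
                    row_g.append(tuple(float(x) for x in gp))
                else:
                    row_g.append((np.nan, np.nan, np.nan))
            calls.append(row_c)
            dps.append(row_d)
            gqs.append(row_q)
            pls.append(row_p)
            gps.append(row_g)

    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    n_v, n_s = len(variants), len(sample_ids)
    if n_v == 0:
        calls = np.zeros((0, n_s), dtype=np.int8)
        dps = gqs = np.zeros((0, n_s), dtype=np.int32)
        pls = np.zeros((0, n_s, 3), dtype=np.int32)
        any_gp = False
    panel = GenotypePanel(
        sample_ids=sample_ids,
        variants=variants,
        calls=np.array(calls, dtype=np.int8).T,
        dp=np.array(dps, dtype=np.int32).T,
        gq=np.array(gqs, dtype=np.int32).T,
        pl=np.array(pls, dtype=np.int32).transpose(1, 0, 2),
        gp=np.array(gps, dtype=float).transpose(1, 0, 2) if any_gp else None,
        metadata=metadata,
    )
    return panel, n_dropped


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV (columns: sample, site, stage, location,
    window) indexed by sample id."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ValueError("metadata TSV must have a 'sample' column")
    return meta.set_index("sample")


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample")
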