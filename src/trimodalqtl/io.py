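"""Readers and writers for the pipeline's on-disk formats.

Coordinates are BED-style 0-based half-open everywhere internally; VCF
positions (1-based) are converted at parse/write time. Count and trait
matrices are TSV with a feature_id column followed by one column per donor.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .countqtl import GenotypePosterior
from .simulate import GenotypePanel


def donor_names(n: int) -> list:
    return [f"donor{i:02d}" for i in range(n)]


def write_vcf(panel: GenotypePanel, path: str, chrom: str = "chr1", start_pos: int = 1000,
              spacing: int = 500) -> None:
    """Write a panel as uncompressed VCF with GT and GP FORMAT fields."""
    header = pysam.VariantHeader()
    header.contigs.add(chrom, length=start_pos + spacing * (len(panel.variant_ids) + 1))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GP", 3, "Float", "Genotype class probabilities (0/0, 0/1, 1/1)")
    donors = donor_names(panel.n_donors)
    for d in donors:
        header.add_sample(d)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v, vid in enumerate(panel.variant_ids):
            rec = out.new_record(
                contig=chrom, start=start_pos + v * spacing - 1, stop=start_pos + v * spacing,
                alleles=("A", "G"), id=vid,
            )
            for i, d in enumerate(donors):
                g = int(panel.hard_call[v, i])
                rec.samples[d]["GT"] = [(0, 0), (0, 1), (1, 1)][g]
                rec.samples[d]["GP"] = tuple(float(x) for x in panel.gp[v, i])
            out.write(rec)


def read_vcf_genotypes(path: str) -> dict:
    """Read GT+GP from a VCF into GenotypePosterior objects keyed by variant id.

    Donors lacking GP fall back to a one-hot encoding of the hard call.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    out = {}
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            gp = np.asarray(rec.format("GP"), dtype=float)
        except (KeyError, TypeError, ValueError):
            gp = None
        dosage = np.asarray(rec.gt_types, dtype=int)  # 0 hom-ref, 1 het, 3 hom-alt
        hard = np.where(dosage == 3, 2, dosage)
        if gp is None:
            probs = np.eye(3)[hard]
        else:
            probs = gp
            missing = ~np.isfinite(probs).all(axis=1)
            if missing.any():
                probs[missing] = np.eye(3)[hard[missing]]
            probs = probs / probs.sum(axis=1, keepdims=True)
        out[vid] = GenotypePosterior(vid, probs)
    return out


def write_count_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_count_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: pd.DataFrame, path: str, extra_cols: tuple = ()) -> None:
    cols = ["chrom", "start", "end", *extra_cols]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str, extra_cols: tuple = ("name",)) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", *extra_cols][: df.shape[1]]
    df.columns = names + [f"col{i}" for i in range(len(names), df.shape[1])]
    bad = df.index[(df["start"] < 0) | (df["start"] >= df["end"])]
    if len(bad):
        raise ValueError(f"malformed BED interval at line {int(bad[0]) + 1} of {os.path.basename(path)}")
    return df


def check_bed_sorted(df: pd.DataFrame, path: str = "") -> None:
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            line = int(grp.index[np.argmin(np.diff(starts) >= 0) + 1]) + 1
            raise ValueError(f"unsorted BED{f' {path}' if path else ''} at line {line} (chrom {chrom})")
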