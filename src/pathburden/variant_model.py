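"""Cohort variant data model: multi-sample VCF + per-variant annotations.

The in-memory layout is columnar: a :class:`pandas.DataFrame` of per-variant
fields (one row per ALT allele — multi-allelic sites are split) plus dense
``(n_variants, n_samples)`` integer matrices for genotypes and read depths.
Genotype codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  Depth -1 means the
DP field was absent.  Coordinates are 1-based, exactly as VCF.

A sample *carries* a variant iff its genotype is het or hom-alt; missing
genotypes count as non-carriers for rate computation but remain
distinguishable in the genotype matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("pathburden")

GT_MISSING, GT_HOMREF, GT_HET, GT_HOMALT = -1, 0, 1, 2
DP_MISSING = -1

#: columns a variant table always carries
VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "site_qual", "mapping_quality"]

#: annotation columns; the first three are mandatory in input files
ANNOTATION_REQUIRED = ["gene", "region", "consequence"]
ANNOTATION_MAF_COLUMNS = [
    "maf_1000g_all", "maf_esp6500", "maf_gnomad_all", "maf_gnomad_eas",
]
ANNOTATION_COLUMNS = (
    ["chrom", "pos", "ref", "alt"]
    + ANNOTATION_REQUIRED
    + ANNOTATION_MAF_COLUMNS
    + [
        "sift_call", "polyphen_call", "mutationtaster_call", "cadd_phred",
        "dbscsnv_splice_relevant", "in_repeat_region", "splice_distance_bp",
    ]
)

REGIONS = {
    "exonic", "splicing", "exonic;splicing", "intronic", "intergenic",
    "UTR", "other",
}
CONSEQUENCES = {
    "synonymous SNV", "nonsynonymous SNV", "stopgain", "stoploss",
    "frameshift indel", "nonframeshift indel", "unknown",
}


class VcfFormatError(ValueError):
    pass


class AnnotationFormatError(ValueError):
    pass


class CohortJoinError(ValueError):
    pass


def variant_key_frame(df: pd.DataFrame) -> pd.Index:
    """Index of (chrom, pos, ref, alt) tuples identifying each ALT allele."""
    return pd.MultiIndex.from_arrays(
        [df["chrom"].astype(str), df["pos"].astype(int),
         df["ref"].astype(str), df["alt"].astype(str)],
        names=["chrom", "pos", "ref", "alt"],
    )


def indel_length(ref: str, alt: str) -> int:
    """VCF allele convention: max(len(ref), len(alt)) - 1; 0 for an SNV."""
    return max(len(ref), len(alt)) - 1


@dataclass
class VariantTable:
    """Per-ALT variant records plus genotype and depth matrices."""

    records: pd.DataFrame
    genotypes: np.ndarray  # int8 (n_variants, n_samples)
    depths: np.ndarray     # int32 (n_variants, n_samples)
    samples: list[str]

    def __post_init__(self) -> None:
        n, s = len(self.records), len(self.samples)
        if self.genotypes.shape != (n, s) or self.depths.shape != (n, s):
            raise ValueError("genotype/depth matrices must be (n_variants, n_samples)")
        if (self.records["pos"] < 1).any():
            raise ValueError("positions must be 1-based (>= 1)")

    def __len__(self) -> int:
        return len(self.records)


def read_vcf(path: str | Path) -> VariantTable:
    """Read a VCF (v4.2, plain or bgzipped) into a :class:`VariantTable`.

    Multi-allelic sites are split into one record per ALT allele: a sample's
    genotype for allele *k* is the number of its chromosomes carrying that
    allele (0/1/2), missing if any called allele is ``.``.  Site-level QUAL
    and INFO/MQ are copied to every split record.
    """
    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise VcfFormatError(f"{path}: VCF has no GT FORMAT field")
    has_dp = "DP" in vf.header.formats
    if not has_dp:
        logger.warning("%s: no DP FORMAT field; depths recorded as missing", path)
    samples = list(vf.header.samples)
    rows, gts, dps = [], [], []
    for rec in vf:
        alts = rec.alts or ()
        for ai, alt in enumerate(alts, start=1):
            gt_row = np.full(len(samples), GT_MISSING, dtype=np.int8)
            dp_row = np.full(len(samples), DP_MISSING, dtype=np.int32)
            for si, sname in enumerate(samples):
                call = rec.samples[sname]
                alleles = call.get("GT")
                if alleles is not None and None not in alleles:
                    gt_row[si] = sum(1 for a in alleles if a == ai)
                if has_dp:
                    dp = call.get("DP")
                    if dp is not None:
                        dp_row[si] = int(dp)
            mq = rec.info.get("MQ") if "MQ" in rec.info else None
            rows.append(
                (rec.chrom, rec.pos, rec.ref, alt,
                 float(rec.qual) if rec.qual is not None else np.nan,
                 float(mq) if mq is not None else np.nan)
            )
            gts.append(gt_row)
            dps.append(dp_row)
    records = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    gt = (np.vstack(gts) if gts
          else np.empty((0, len(samples)), dtype=np.int8))
    dp = (np.vstack(dps) if dps
          else np.empty((0, len(samples)), dtype=np.int32))
    return VariantTable(records=records, genotypes=gt, depths=dp, samples=samples)


def write_vcf(table: VariantTable, path: str | Path) -> None:
    """Write a :class:`VariantTable` as VCF v4.2 with GT/DP and INFO/MQ."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">')
    for chrom, sub in table.records.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(sub["pos"].max()) + 10_000)
    for s in table.samples:
        header.add_sample(s)
    gt_tuples = {GT_HOMREF: (0, 0), GT_HET: (0, 1), GT_HOMALT: (1, 1),
                 GT_MISSING: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, row in enumerate(table.records.itertuples(index=False)):
            rec = out.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            if not np.isnan(row.site_qual):
                rec.qual = float(row.site_qual)
            if not np.isnan(row.mapping_quality):
                rec.info["MQ"] = float(row.mapping_quality)
            for si, s in enumerate(table.samples):
                rec.samples[s]["GT"] = gt_tuples[int(table.genotypes[i, si])]
                if table.depths[i, si] != DP_MISSING:
                    rec.samples[s]["DP"] = int(table.depths[i, si])
            out.write(rec)


_MISSING_TOKENS = {".", "", "NA", "nan"}


def _parse_float(tok, colname: str, lineno: int | None = None) -> float:
    if pd.isna(tok) or str(tok) in _MISSING_TOKENS:
        return np.nan
    try:
        return float(tok)
    except ValueError:
        logger.warning("unparseable %s value %r; recorded as missing", colname, tok)
        return np.nan


def _parse_bool(tok) -> object:
    if pd.isna(tok) or str(tok) in _MISSING_TOKENS:
        return pd.NA
    s = str(tok).strip().lower()
    if s in {"true", "1", "yes", "y", "t"}:
        return True
    if s in {"false", "0", "no", "n", "f"}:
        return False
    return pd.NA


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an ANNOVAR-multianno-style annotation TSV.

    ``.`` denotes missing throughout.  Mandatory columns: chrom, pos, ref,
    alt, gene, region, consequence.  MAFs that fail to parse become missing
    with a warning; categorical predictor calls are lower-cased.
    """
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [
        c for c in ["chrom", "pos", "ref", "alt"] + ANNOTATION_REQUIRED
        if c not in df.columns
    ]
    if missing_cols:
        raise AnnotationFormatError(
            f"{path}: missing mandatory column(s): {missing_cols}"
        )
    out = pd.DataFrame({
        "chrom": df["chrom"].astype(str),
        "pos": df["pos"].astype(int),
        "ref": df["ref"].astype(str),
        "alt": df["alt"].astype(str),
        "gene": df["gene"].astype(str).str.strip().str.upper(),
        "region": df["region"].astype(str).str.strip(),
        "consequence": df["consequence"].astype(str).str.strip(),
    })
    for col in ANNOTATION_MAF_COLUMNS + ["cadd_phred", "splice_distance_bp"]:
        if col in df.columns:
            out[col] = [_parse_float(v, col) for v in df[col]]
        else:
            out[col] = np.nan
    for col in ["sift_call", "polyphen_call", "mutationtaster_call"]:
        if col in df.columns:
            vals = df[col].astype(str).str.strip().str.lower()
            out[col] = vals.where(~vals.isin(_MISSING_TOKENS), other=pd.NA)
        else:
            out[col] = pd.NA
    out["dbscsnv_splice_relevant"] = (
        [_parse_bool(v) for v in df["dbscsnv_splice_relevant"]]
        if "dbscsnv_splice_relevant" in df.columns else pd.NA
    )
    out["in_repeat_region"] = (
        [bool(_parse_bool(v)) if _parse_bool(v) is not pd.NA else False
         for v in df["in_repeat_region"]]
        if "in_repeat_region" in df.columns else False
    )
    out["indel_length"] = [
        indel_length(r, a) for r, a in zip(out["ref"], out["alt"])
    ]
    bad_maf = out[ANNOTATION_MAF_COLUMNS].stack(future_stack=True)
    bad_maf = bad_maf[(bad_maf < 0) | (bad_maf > 1)]
    if len(bad_maf):
        raise AnnotationFormatError(f"{path}: MAF values outside [0,1]")
    return out


def read_groups(path: str | Path) -> pd.DataFrame:
    """Read the two-column ``sample_id<TAB>group`` file (case/control)."""
    df = pd.read_csv(str(path), sep="\t", header=None,
                     names=["sample_id", "group"], dtype=str, comment="#")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise CohortJoinError(f"{path}: unknown group label(s) {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise CohortJoinError(f"{path}: duplicate sample ids")
    return df


@dataclass
class CohortTable:
    """Joined variants + annotations + sample group labels.

    ``records`` carries both the variant-level and the annotation-level
    columns, one row per ALT allele; the genotype/depth matrices are aligned
    row-for-row with ``records`` and column-for-column with ``samples``.
    """

    samples: pd.DataFrame        # columns: sample_id, group
    records: pd.DataFrame
    genotypes: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        if not set(self.samples["group"]) <= {"case", "control"}:
            raise CohortJoinError("sample groups must be 'case' or 'control'")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def __len__(self) -> int:
        return len(self.records)

    def group_columns(self, group: Literal["case", "control"]) -> np.ndarray:
        mask = (self.samples["group"] == group).to_numpy()
        return np.nonzero(mask)[0]

    def n_in_group(self, group: str) -> int:
        return int((self.samples["group"] == group).sum())

    def carrier_matrix(self, min_depth_exclusive: int | None = None) -> np.ndarray:
        """Boolean (n_variants, n_samples): het or hom-alt.

        With ``min_depth_exclusive`` set, a carrier call additionally needs
        that sample's depth strictly above the threshold; samples with
        missing depth fall back to the genotype alone.
        """
        carrier = self.genotypes >= GT_HET
        if min_depth_exclusive is not None:
            ok = (self.depths > min_depth_exclusive) | (self.depths == DP_MISSING)
            carrier = carrier & ok
        return carrier

    def subset(self, row_mask: np.ndarray) -> "CohortTable":
        idx = np.asarray(row_mask)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return CohortTable(
            samples=self.samples,
            records=self.records.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            depths=self.depths[idx],
        )


def join_cohort(
    variants: VariantTable,
    annotations: pd.DataFrame,
    sample_groups: pd.DataFrame,
    unmatched: Literal["drop", "error"] = "drop",
) -> tuple[CohortTable, int]:
    """Join variants with annotations on (chrom, pos, ref, alt).

    Returns the joined table and the count of variants that had no matching
    annotation (dropped with a warning under ``unmatched='drop'``).  Every
    VCF sample must appear in ``sample_groups``.
    """
    roster = dict(zip(sample_groups["sample_id"], sample_groups["group"]))
    missing = [s for s in variants.samples if s not in roster]
    if missing:
        raise CohortJoinError(
            f"sample(s) in VCF absent from group file: {missing}"
        )
    samples = pd.DataFrame({
        "sample_id": variants.samples,
        "group": [roster[s] for s in variants.samples],
    })
    vkey = variant_key_frame(variants.records)
    akey = variant_key_frame(annotations)
    if akey.duplicated().any():
        raise CohortJoinError("duplicate (chrom,pos,ref,alt) keys in annotations")
    ann_indexed = annotations.set_index(akey)
    matched = vkey.isin(ann_indexed.index)
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        if unmatched == "error":
            raise CohortJoinError(
                f"{n_unmatched} variant(s) without annotation"
            )
        logger.warning("dropping %d unannotated variant(s)", n_unmatched)
    keep = np.nonzero(matched.to_numpy() if hasattr(matched, "to_numpy") else matched)[0]
    recs = variants.records.iloc[keep].reset_index(drop=True)
    ann_rows = ann_indexed.loc[vkey[keep]].reset_index(drop=True)
    ann_cols = [c for c in ann_rows.columns
                if c not in ("chrom", "pos", "ref", "alt")]
    joined = pd.concat([recs, ann_rows[ann_cols]], axis=1)
    table = CohortTable(
        samples=samples,
        records=joined,
        genotypes=variants.genotypes[keep],
        depths=variants.depths[keep],
    )
    return table, n_unmatched
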