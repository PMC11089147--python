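"""Seven-rule rare/deleterious variant filter cascade with per-stage accounting.

Stages, in canonical order:

1. ``quality`` — read depth > 4 in at least one sample, RMS mapping quality
   > 30, variant quality score > 20 (all strict).
2. ``rarity`` — MAF < 0.01 in every consulted population panel (1000g_all,
   esp6500siv2_all, gnomAD_ALL, gnomAD_EAS); a missing MAF counts as rare.
3. ``region`` — exonic, exonic;splicing, or splicing within 10 bp of the
   junction.
4. ``synonymous`` — synonymous SNVs discarded unless dbscSNV flags them as
   splice-relevant.
5. ``repeat_indel`` — non-frameshift indels shorter than 10 bp inside
   RepeatMasker repeats discarded.
6. ``consensus`` — kept only if more than half of the four deleteriousness
   predictors (SIFT, PolyPhen, MutationTaster, CADD >= cutoff) vote harmful,
   i.e. at least 3 of 4; missing predictors cast no vote and the bar is not
   lowered.
7. ``splice_distance`` — splicing-region sites more than 2 bp from the
   junction with no predicted splice effect discarded.

Every predicate is pure and record-local, so the surviving set is invariant
under stage permutation; only the trace's attribution of removals changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variant_model import (
    ANNOTATION_MAF_COLUMNS,
    DP_MISSING,
    CohortTable,
)


@dataclass(frozen=True)
class FilterThresholds:
    """All tunable cutoffs of the cascade (strict-inequality semantics)."""

    min_depth_exclusive: int = 4
    min_mapping_quality_exclusive: float = 30.0
    min_site_qual_exclusive: float = 20.0
    max_maf_exclusive: float = 0.01
    splice_window_bp: int = 10
    repeat_indel_max_len_exclusive: int = 10
    splice_distance_removal_bp: int = 2
    consensus_votes_required: int = 3
    cadd_deleterious_cutoff: float = 20.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"threshold {name} must be positive, got {v}")
        if not 1 <= self.consensus_votes_required <= 4:
            raise ValueError("consensus_votes_required must be in [1, 4]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterThresholds":
        return cls(**dict(d))


def _is_true(ser: pd.Series) -> np.ndarray:
    return ser.eq(True).fillna(False).to_numpy(dtype=bool)


# ---------------------------------------------------------------------------
# vectorized stage predicates: records (+ depths) -> (keep mask, reason array)

def _stage_quality(table: CohortTable, t: FilterThresholds):
    rec = table.records
    dp = table.depths
    if dp.shape[1]:
        depth_ok = (dp > t.min_depth_exclusive).any(axis=1) | (
            dp == DP_MISSING
        ).all(axis=1)
    else:
        depth_ok = np.ones(len(rec), dtype=bool)
    mq = rec["mapping_quality"].to_numpy(dtype=float)
    qual = rec["site_qual"].to_numpy(dtype=float)
    missing = np.isnan(mq) | np.isnan(qual)
    keep = depth_ok & ~missing & (mq > t.min_mapping_quality_exclusive) & (
        qual > t.min_site_qual_exclusive
    )
    reason = np.full(len(rec), "", dtype=object)
    reason[~depth_ok] = "depth"
    sel = depth_ok & missing
    reason[sel] = "missing_quality"
    sel = depth_ok & ~missing & (mq <= t.min_mapping_quality_exclusive)
    reason[sel] = "mapping_quality"
    sel = (depth_ok & ~missing & (mq > t.min_mapping_quality_exclusive)
           & (qual <= t.min_site_qual_exclusive))
    reason[sel] = "site_qual"
    return keep, reason


def _stage_rarity(table: CohortTable, t: FilterThresholds):
    rec = table.records
    common = np.zeros(len(rec), dtype=bool)
    for col in ANNOTATION_MAF_COLUMNS:
        maf = rec[col].to_numpy(dtype=float)
        common |= ~np.isnan(maf) & (maf >= t.max_maf_exclusive)
    reason = np.where(common, "maf", "").astype(object)
    return ~common, reason


def _stage_region(table: CohortTable, t: FilterThresholds):
    rec = table.records
    region = rec["region"].to_numpy(dtype=object)
    dist = rec["splice_distance_bp"].to_numpy(dtype=float)
    keep = np.isin(region, ["exonic", "exonic;splicing"]) | (
        (region == "splicing") & ~np.isnan(dist) & (dist <= t.splice_window_bp)
    )
    reason = np.where(~keep, "region", "").astype(object)
    return keep, reason


def _stage_synonymous(table: CohortTable, t: FilterThresholds):
    rec = table.records
    splice_relevant = _is_true(rec["dbscsnv_splice_relevant"])
    remove = (rec["consequence"].to_numpy(dtype=object) == "synonymous SNV") & (
        ~splice_relevant
    )
    reason = np.where(remove, "synonymous", "").astype(object)
    return ~remove, reason


def _stage_repeat_indel(table: CohortTable, t: FilterThresholds):
    rec = table.records
    remove = (
        (rec["consequence"].to_numpy(dtype=object) == "nonframeshift indel")
        & (rec["indel_length"].to_numpy(dtype=int)
           < t.repeat_indel_max_len_exclusive)
        & rec["in_repeat_region"].to_numpy(dtype=bool)
    )
    reason = np.where(remove, "repeat_indel", "").astype(object)
    return ~remove, reason


def _stage_consensus(table: CohortTable, t: FilterThresholds):
    rec = table.records
    votes = np.zeros(len(rec), dtype=int)
    for col in ("sift_call", "polyphen_call", "mutationtaster_call"):
        votes += (
            rec[col].eq("deleterious").fillna(False).to_numpy(dtype=bool)
        ).astype(int)
    cadd = rec["cadd_phred"].to_numpy(dtype=float)
    votes += (~np.isnan(cadd) & (cadd >= t.cadd_deleterious_cutoff)).astype(int)
    keep = votes >= t.consensus_votes_required
    reason = np.where(~keep, "consensus", "").astype(object)
    return keep, reason


def _stage_splice_distance(table: CohortTable, t: FilterThresholds):
    rec = table.records
    dist = rec["splice_distance_bp"].to_numpy(dtype=float)
    splice_relevant = _is_true(rec["dbscsnv_splice_relevant"])
    remove = (
        (rec["region"].to_numpy(dtype=object) == "splicing")
        & ~np.isnan(dist)
        & (dist > t.splice_distance_removal_bp)
        & ~splice_relevant
    )
    reason = np.where(remove, "splice_distance", "").astype(object)
    return ~remove, reason


STAGE_ORDER: tuple[str, ...] = (
    "quality", "rarity", "region", "synonymous", "repeat_indel",
    "consensus", "splice_distance",
)

_STAGES: dict[str, Callable] = {
    "quality": _stage_quality,
    "rarity": _stage_rarity,
    "region": _stage_region,
    "synonymous": _stage_synonymous,
    "repeat_indel": _stage_repeat_indel,
    "consensus": _stage_consensus,
    "splice_distance": _stage_splice_distance,
}


# ---------------------------------------------------------------------------
# scalar predicates (record-level API; cascade uses the vectorized versions,
# and a property test pins scalar/vectorized agreement)

def _one_row_table(record: Mapping) -> CohortTable:
    rec = dict(record)
    depths = rec.pop("depths", None)
    if depths is None and "depth" in rec:
        depths = [rec.pop("depth")]
    depths = np.asarray([depths if depths is not None else []],
                        dtype=np.int32).reshape(1, -1)
    n_samp = depths.shape[1]
    defaults = {
        "chrom": "1", "pos": 1, "ref": "A", "alt": "C",
        "site_qual": np.nan, "mapping_quality": np.nan,
        "gene": "G", "region": "exonic", "consequence": "nonsynonymous SNV",
        "sift_call": pd.NA, "polyphen_call": pd.NA,
        "mutationtaster_call": pd.NA, "cadd_phred": np.nan,
        "dbscsnv_splice_relevant": pd.NA, "in_repeat_region": False,
        "indel_length": 0, "splice_distance_bp": np.nan,
    }
    for col in ANNOTATION_MAF_COLUMNS:
        defaults[col] = np.nan
    defaults.update(rec)
    records = pd.DataFrame([defaults])
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samp)],
        "group": ["case"] * n_samp,
    })
    gt = np.full((1, n_samp), 1, dtype=np.int8)
    return CohortTable(samples=samples, records=records,
                       genotypes=gt, depths=depths)


def _scalar(stage: str, record: Mapping, t: FilterThresholds):
    keep, reason = _STAGES[stage](_one_row_table(record), t)
    return bool(keep[0]), (reason[0] or None)


def quality_filter(record: Mapping, t: FilterThresholds = FilterThresholds()):
    """Keep iff depth > 4 (any sample), MQ > 30 and QUAL > 20, all strict."""
    return _scalar("quality", record, t)


def rarity_filter(record: Mapping, t: FilterThresholds = FilterThresholds()):
    """Keep iff every present panel MAF is < 0.01; missing MAFs count rare."""
    return _scalar("rarity", record, t)


def region_filter(record: Mapping, t: FilterThresholds = FilterThresholds()):
    """Keep exonic / exonic;splicing, or splicing within the 10 bp window."""
    return _scalar("region", record, t)


def synonymous_filter(record: Mapping, t: FilterThresholds = FilterThresholds()):
    """Discard synonymous SNVs unless dbscSNV marks them splice-relevant."""
    return _scalar("synonymous", record, t)


def repeat_indel_filter(record: Mapping, t: FilterThresholds = FilterThresholds()):
    """Discard non-frameshift indels < 10 bp lying in repeat regions."""
    return _scalar("repeat_indel", record, t)


def deleteriousness_consensus(record: Mapping, t: FilterThresholds = FilterThresholds()):
    """Keep iff >= 3 of 4 predictors vote harmful; missing casts no vote."""
    return _scalar("consensus", record, t)


def splice_distance_filter(record: Mapping, t: FilterThresholds = FilterThresholds()):
    """Discard splicing sites > 2 bp from the junction with no splice effect."""
    return _scalar("splice_distance", record, t)


# ---------------------------------------------------------------------------
# trace + orchestration

@dataclass
class StageTrace:
    stage: str
    n_in: int
    n_kept: int
    reasons: dict[str, int] = field(default_factory=dict)


@dataclass
class FilterTrace:
    stages: list[StageTrace] = field(default_factory=list)

    def validate(self) -> None:
        """Conservation: in - kept = sum of reasons; stages chain up."""
        for st in self.stages:
            if st.n_in - st.n_kept != sum(st.reasons.values()):
                raise ValueError(f"trace inconsistent at stage {st.stage}")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.n_kept != b.n_in:
                raise ValueError(
                    f"kept({a.stage}) != in({b.stage}): {a.n_kept} vs {b.n_in}"
                )

    def removal_reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for st in self.stages:
            for r, c in st.reasons.items():
                out[r] = out.get(r, 0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st in self.stages:
            if st.reasons:
                for r, c in sorted(st.reasons.items()):
                    rows.append((st.stage, st.n_in, st.n_kept, r, c))
            else:
                rows.append((st.stage, st.n_in, st.n_kept, ".", 0))
        return pd.DataFrame(rows, columns=["stage", "in", "kept", "reason", "count"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def record_filter_reasons(
    table: CohortTable,
    t: FilterThresholds = FilterThresholds(),
    order: Sequence[str] = STAGE_ORDER,
) -> pd.DataFrame:
    """Per-record cascade outcome: first failing stage and its reason code.

    Because every predicate is record-local, each record's fate is fully
    determined by evaluating all stages on the unfiltered table; the *first*
    failing stage in ``order`` is the one the trace attributes the removal
    to.  Returns a frame with boolean ``kept``, ``stage`` and ``reason``
    (empty strings for survivors).
    """
    if set(order) != set(STAGE_ORDER):
        raise ValueError(f"order must be a permutation of {STAGE_ORDER}")
    n = len(table)
    stage_out = np.full(n, "", dtype=object)
    reason_out = np.full(n, "", dtype=object)
    undecided = np.ones(n, dtype=bool)
    for stage in order:
        keep, reason = _STAGES[stage](table, t)
        hit = undecided & ~keep
        stage_out[hit] = stage
        reason_out[hit] = reason[hit]
        undecided &= keep
    return pd.DataFrame({
        "kept": undecided, "stage": stage_out, "reason": reason_out,
    })


def run_cascade(
    table: CohortTable,
    t: FilterThresholds = FilterThresholds(),
    order: Sequence[str] = STAGE_ORDER,
) -> tuple[CohortTable, FilterTrace]:
    """Apply all seven predicates in ``order`` with per-stage accounting.

    Returns the surviving :class:`CohortTable` and a :class:`FilterTrace`
    whose per-stage reason counts attribute each removal to the first stage
    (in the given order) whose predicate the record fails.  An empty input
    yields an empty output with a zero-count trace.
    """
    fate = record_filter_reasons(table, t, order)
    trace = FilterTrace()
    remaining = len(table)
    for stage in order:
        hit = fate["stage"] == stage
        reasons: dict[str, int] = (
            fate.loc[hit, "reason"].value_counts().to_dict()
        )
        n_removed = int(hit.sum())
        trace.stages.append(
            StageTrace(stage=stage, n_in=remaining,
                       n_kept=remaining - n_removed, reasons=reasons)
        )
        remaining -= n_removed
    trace.validate()
    return table.subset(fate["kept"].to_numpy()), trace
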