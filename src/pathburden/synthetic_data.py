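"""Synthetic case/control exome cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes — and nothing more.  Per gene, each sample of each group is a
*qualifying carrier* with a configured probability; each carrier receives
one or more planted variants that pass all seven cascade predicates by
construction (rare MAFs, exonic consequence, >=3 harmful predictor votes,
depths/MQ/QUAL above the quality cutoffs).  Contaminant variants can be
planted that fail exactly one designated rule and pass all others, so the
cascade's removals can be checked record-for-record against the emitted
:class:`TruthManifest`.

Variant positions live on a toy contig ("1") with a fixed 100 kb window per
gene; the mapping is written into the VCF header comments.  There is no
attempt at read-level realism, linkage disequilibrium, or site-frequency
spectra — see the package docs for what passing tests do and do not show.

All randomness flows from one :class:`numpy.random.Generator` seeded by the
config, so outputs are byte-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pathway_db import (
    GeneSet,
    PathwayDatabase,
    carbohydrate_pathway_fixture,
    write_gmt,
)
from .variant_model import (
    ANNOTATION_MAF_COLUMNS,
    DP_MISSING,
    GT_HET,
    GT_HOMALT,
    GT_HOMREF,
    GT_MISSING,
    CohortTable,
    VariantTable,
    indel_length,
    write_vcf,
)

GENE_WINDOW = 100_000   # toy contig: gene i occupies [i*GENE_WINDOW+1, +50kb]
GENE_SPAN = 50_000

CONTAMINANT_RULES = (
    "depth", "mapping_quality", "site_qual", "maf", "region",
    "synonymous", "repeat_indel", "consensus", "splice_distance",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """Per-gene carrier model: one Bernoulli carrier draw per sample, then
    ``1 + Poisson(extra_variants_mean)`` qualifying variants per carrier."""

    gene: str
    case_carrier_prob: float
    control_carrier_prob: float
    extra_variants_mean: float = 0.6

    def __post_init__(self) -> None:
        for p in (self.case_carrier_prob, self.control_carrier_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"carrier prob out of [0,1] for {self.gene}")
        if self.extra_variants_mean < 0:
            raise ConfigError("extra_variants_mean must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int
    n_controls: int
    genes: tuple[GeneModel, ...]
    background_gene_count: int = 50
    background_carrier_prob: float = 0.01
    pathways: tuple[GeneSet, ...] = ()
    maf_missing_prob: float = 0.3
    rare_maf_beta: tuple[float, float] = (0.5, 400.0)
    predictor_concordance_deleterious: float = 0.95
    predictor_concordance_benign: float = 0.05
    contaminants_per_rule: tuple[tuple[str, int], ...] = ()
    site_sharing_prob: float = 0.3
    hom_alt_fraction: float = 0.05
    genotype_missing_rate: float = 0.002
    case_age_mean_sd: tuple[float, float] = (31.88, 10.25)
    control_age_mean_sd: tuple[float, float] = (33.41, 10.48)
    case_female_count: int | None = None
    control_female_count: int | None = None
    female_prob: float = 0.6
    illness_duration_mean_months: float = 6.62
    hamd_mean_sd: tuple[float, float] = (25.84, 5.28)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("need at least one case and one control")
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate gene names in config")
        for rule, count in self.contaminants_per_rule:
            if rule not in CONTAMINANT_RULES:
                raise ConfigError(
                    f"unknown contaminant rule {rule!r}; "
                    f"valid: {CONTAMINANT_RULES}"
                )
            if count < 0:
                raise ConfigError("contaminant counts must be >= 0")
        universe = set(names) | {
            f"BKG{i:04d}" for i in range(1, self.background_gene_count + 1)
        }
        for gs in self.pathways:
            missing = gs.genes - universe
            if missing:
                raise ConfigError(
                    f"pathway {gs.pathway_id} names genes the simulation "
                    f"does not generate: {sorted(missing)}"
                )

    def all_genes(self) -> list[str]:
        return [g.gene for g in self.genes] + [
            f"BKG{i:04d}" for i in range(1, self.background_gene_count + 1)
        ]


# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


class _SitePool:
    """Allocates unique positions inside each gene's window."""

    def __init__(self, gene_index: dict[str, int], rng: np.random.Generator):
        self.gene_index = gene_index
        self.rng = rng
        self.used: dict[str, set[int]] = {g: set() for g in gene_index}

    def new_pos(self, gene: str) -> int:
        base = self.gene_index[gene] * GENE_WINDOW
        used = self.used[gene]
        while True:
            pos = base + 1 + int(self.rng.integers(0, GENE_SPAN))
            if pos not in used:
                used.add(pos)
                return pos


@dataclass
class _Variant:
    gene: str
    pos: int
    ref: str
    alt: str
    site_qual: float
    mapping_quality: float
    region: str
    consequence: str
    mafs: dict[str, float]
    sift: object
    polyphen: object
    mutationtaster: object
    cadd: float
    dbscsnv: object
    in_repeat: bool
    splice_distance: float
    fail_rule: str | None          # None for qualifying variants
    carriers: list[int] = field(default_factory=list)  # sample indices
    depth_override: tuple[int, int] | None = None      # (lo, hi) for ALL dp


@dataclass
class TruthManifest:
    """Ground truth: planted variants and per-sample/gene carrier flags."""

    variants: pd.DataFrame  # chrom,pos,ref,alt,gene,fail_rule,carriers
    carriers: pd.DataFrame  # sample_id, gene, n_qualifying_variants

    def carrier_flags(self) -> pd.DataFrame:
        """Wide boolean frame sample_id x gene of true qualifying carriers."""
        if self.carriers.empty:
            return pd.DataFrame()
        return (
            self.carriers.assign(flag=True)
            .pivot_table(index="sample_id", columns="gene", values="flag",
                         aggfunc="any", fill_value=False)
        )


@dataclass
class CohortSimulation:
    """A generated cohort with every artifact the pipeline consumes."""

    config: SimulationConfig
    samples: pd.DataFrame           # sample_id, group
    variants: VariantTable
    annotations: pd.DataFrame       # same layout read_annotations produces
    metadata: pd.DataFrame
    manifest: TruthManifest

    def to_cohort_table(self) -> CohortTable:
        ann_cols = [c for c in self.annotations.columns
                    if c not in ("chrom", "pos", "ref", "alt")]
        joined = pd.concat(
            [self.variants.records.reset_index(drop=True),
             self.annotations[ann_cols].reset_index(drop=True)], axis=1
        )
        return CohortTable(
            samples=self.samples, records=joined,
            genotypes=self.variants.genotypes, depths=self.variants.depths,
        )

    def pathway_database(self) -> PathwayDatabase:
        return PathwayDatabase.from_gene_sets(
            self.config.pathways, background=self.config.all_genes()
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "annotations": outdir / "annotations.tsv",
            "groups": outdir / "groups.tsv",
            "metadata": outdir / "metadata.csv",
            "gmt": outdir / "pathways.gmt",
            "background": outdir / "background_genes.txt",
            "truth_variants": outdir / "truth_variants.tsv",
            "truth_carriers": outdir / "truth_carriers.tsv",
        }
        write_vcf(self.variants, paths["vcf"])
        _write_annotation_tsv(self.annotations, paths["annotations"])
        self.samples.to_csv(paths["groups"], sep="\t", index=False,
                            header=False)
        self.metadata.to_csv(paths["metadata"], index=False)
        if self.config.pathways:
            write_gmt(
                PathwayDatabase.from_gene_sets(self.config.pathways),
                paths["gmt"],
            )
        paths["background"].write_text(
            "\n".join(self.config.all_genes()) + "\n"
        )
        self.manifest.variants.to_csv(paths["truth_variants"], sep="\t",
                                      index=False)
        self.manifest.carriers.to_csv(paths["truth_carriers"], sep="\t",
                                      index=False)
        return paths


def _write_annotation_tsv(ann: pd.DataFrame, path: Path) -> None:
    out = ann.copy()
    for col in out.columns:
        if out[col].dtype == object or str(out[col].dtype) == "boolean":
            out[col] = out[col].map(
                lambda v: "." if pd.isna(v)
                else ("true" if v is True else "false" if v is False else v)
            )
    out = out.drop(columns=["indel_length"], errors="ignore")
    out.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# generation internals

def _draw_rare_maf(rng: np.random.Generator, a: float, b: float) -> float:
    for _ in range(50):
        v = rng.beta(a, b)
        if v < 0.01:
            return float(v)
    return float(rng.uniform(0, 0.0099))


def _qualifying_fields(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    base_maf = _draw_rare_maf(rng, *cfg.rare_maf_beta)
    mafs = {}
    for col in ANNOTATION_MAF_COLUMNS:
        if rng.random() < cfg.maf_missing_prob:
            mafs[col] = np.nan
        else:
            mafs[col] = min(base_maf * rng.uniform(0.5, 1.5), 0.0099)
    p = cfg.predictor_concordance_deleterious
    votes = list(rng.random(4) < p)
    while sum(votes) < 3:  # qualifying variants must clear the 3-vote bar
        votes[int(rng.integers(0, 4))] = True
    cat = ["deleterious" if v else "tolerated" for v in votes[:3]]
    cadd = float(rng.uniform(25, 45)) if votes[3] else float(rng.uniform(0, 15))
    return dict(
        site_qual=float(rng.uniform(50, 1500)),
        mapping_quality=float(rng.uniform(40, 70)),
        region="exonic",
        consequence="stopgain" if rng.random() < 0.1 else "nonsynonymous SNV",
        mafs=mafs,
        sift=cat[0], polyphen=cat[1], mutationtaster=cat[2], cadd=cadd,
        dbscsnv=pd.NA, in_repeat=False, splice_distance=np.nan,
    )


def _snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return str(_BASES[i]), str(_BASES[j])


def _make_contaminant(
    rule: str, gene: str, pool: _SitePool,
    cfg: SimulationConfig, rng: np.random.Generator,
) -> _Variant:
    f = _qualifying_fields(cfg, rng)
    ref, alt = _snv_alleles(rng)
    depth_override = None
    if rule == "depth":
        depth_override = (0, 4)
    elif rule == "mapping_quality":
        f["mapping_quality"] = float(rng.uniform(5, 30))
    elif rule == "site_qual":
        f["site_qual"] = float(rng.uniform(0.5, 20))
    elif rule == "maf":
        panel = ANNOTATION_MAF_COLUMNS[int(rng.integers(0, 4))]
        f["mafs"][panel] = float(rng.uniform(0.011, 0.2))
    elif rule == "region":
        f["region"] = "intronic"
        f["splice_distance"] = float(rng.integers(11, 200))
    elif rule == "synonymous":
        f["consequence"] = "synonymous SNV"
        f["dbscsnv"] = False
    elif rule == "repeat_indel":
        length = int(rng.integers(1, 10))  # < 10 bp, non-frameshift plant
        extra = "".join(rng.choice(_BASES, size=length))
        ref, alt = ref + extra, ref
        f["consequence"] = "nonframeshift indel"
        f["in_repeat"] = True
    elif rule == "consensus":
        harmful = rng.choice(4, size=2, replace=False)  # exactly 2 of 4
        cat = ["deleterious" if k in harmful else "tolerated" for k in range(3)]
        f["sift"], f["polyphen"], f["mutationtaster"] = cat
        f["cadd"] = (float(rng.uniform(25, 45)) if 3 in harmful
                     else float(rng.uniform(0, 15)))
    elif rule == "splice_distance":
        f["region"] = "splicing"
        f["consequence"] = "unknown"
        f["splice_distance"] = float(rng.integers(3, 11))
        f["dbscsnv"] = False
    else:  # pragma: no cover - guarded by config validation
        raise ConfigError(f"unknown contaminant rule {rule!r}")
    return _Variant(
        gene=gene, pos=pool.new_pos(gene), ref=ref, alt=alt,
        fail_rule=rule, depth_override=depth_override, **f,
    )


def generate_cohort(cfg: SimulationConfig) -> CohortSimulation:
    """Generate a full cohort (variants, annotations, demographics, truth).

    Deterministic given ``cfg.seed``: rerunning with the same config yields
    byte-identical emitted files.
    """
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_cases + cfg.n_controls
    sample_ids = [f"case_{i:04d}" for i in range(1, cfg.n_cases + 1)] + [
        f"control_{i:04d}" for i in range(1, cfg.n_controls + 1)
    ]
    groups = ["case"] * cfg.n_cases + ["control"] * cfg.n_controls
    samples = pd.DataFrame({"sample_id": sample_ids, "group": groups})

    all_genes = cfg.all_genes()
    gene_index = {g: i for i, g in enumerate(all_genes)}
    pool = _SitePool(gene_index, rng)

    gene_models = list(cfg.genes) + [
        GeneModel(gene=f"BKG{i:04d}",
                  case_carrier_prob=cfg.background_carrier_prob,
                  control_carrier_prob=cfg.background_carrier_prob)
        for i in range(1, cfg.background_gene_count + 1)
    ]

    variants: list[_Variant] = []
    carrier_rows: list[tuple[str, str, int]] = []
    case_idx = np.arange(cfg.n_cases)
    ctrl_idx = np.arange(cfg.n_cases, n_total)

    for gm in gene_models:
        u = rng.random(n_total)
        is_carrier = np.empty(n_total, dtype=bool)
        is_carrier[case_idx] = u[case_idx] < gm.case_carrier_prob
        is_carrier[ctrl_idx] = u[ctrl_idx] < gm.control_carrier_prob
        gene_sites: list[_Variant] = []
        for s in np.nonzero(is_carrier)[0]:
            n_var = 1 + int(rng.poisson(gm.extra_variants_mean))
            carrier_rows.append((sample_ids[s], gm.gene, n_var))
            for _ in range(n_var):
                shareable = [v for v in gene_sites if s not in v.carriers]
                if shareable and rng.random() < cfg.site_sharing_prob:
                    v = shareable[int(rng.integers(0, len(shareable)))]
                    v.carriers.append(int(s))
                else:
                    ref, alt = _snv_alleles(rng)
                    v = _Variant(
                        gene=gm.gene, pos=pool.new_pos(gm.gene),
                        ref=ref, alt=alt, fail_rule=None,
                        **_qualifying_fields(cfg, rng),
                    )
                    v.carriers.append(int(s))
                    gene_sites.append(v)
        variants.extend(gene_sites)

    for rule, count in cfg.contaminants_per_rule:
        for _ in range(count):
            gene = all_genes[int(rng.integers(0, len(all_genes)))]
            v = _make_contaminant(rule, gene, pool, cfg, rng)
            v.carriers = sorted(
                int(s) for s in rng.choice(n_total, size=int(rng.integers(1, 4)),
                                           replace=False)
            )
            variants.append(v)

    variants.sort(key=lambda v: (v.pos, v.alt))

    # genotype / depth matrices
    n_var = len(variants)
    gt = np.full((n_var, n_total), GT_HOMREF, dtype=np.int8)
    dp = np.zeros((n_var, n_total), dtype=np.int32)
    for i, v in enumerate(variants):
        lo, hi = v.depth_override if v.depth_override else (5, 250)
        dp[i] = rng.integers(lo, hi + 1, size=n_total)
        miss = rng.random(n_total) < cfg.genotype_missing_rate
        gt[i, miss] = GT_MISSING
        for s in v.carriers:
            gt[i, s] = (GT_HOMALT if rng.random() < cfg.hom_alt_fraction
                        else GT_HET)
            if not v.depth_override:
                dp[i, s] = int(rng.integers(10, 251))

    records = pd.DataFrame({
        "chrom": "1",
        "pos": [v.pos for v in variants],
        "ref": [v.ref for v in variants],
        "alt": [v.alt for v in variants],
        "site_qual": [v.site_qual for v in variants],
        "mapping_quality": [v.mapping_quality for v in variants],
    })
    vtable = VariantTable(records=records, genotypes=gt, depths=dp,
                          samples=sample_ids)

    ann = pd.DataFrame({
        "chrom": "1",
        "pos": records["pos"],
        "ref": records["ref"],
        "alt": records["alt"],
        "gene": [v.gene for v in variants],
        "region": [v.region for v in variants],
        "consequence": [v.consequence for v in variants],
    })
    for col in ANNOTATION_MAF_COLUMNS:
        ann[col] = [v.mafs[col] for v in variants]
    ann["sift_call"] = pd.array([v.sift for v in variants], dtype=object)
    ann["polyphen_call"] = pd.array([v.polyphen for v in variants],
                                    dtype=object)
    ann["mutationtaster_call"] = pd.array(
        [v.mutationtaster for v in variants], dtype=object)
    ann["cadd_phred"] = [v.cadd for v in variants]
    ann["dbscsnv_splice_relevant"] = pd.array(
        [v.dbscsnv for v in variants], dtype=object)
    ann["in_repeat_region"] = [v.in_repeat for v in variants]
    ann["splice_distance_bp"] = [v.splice_distance for v in variants]
    ann["indel_length"] = [indel_length(v.ref, v.alt) for v in variants]

    manifest = TruthManifest(
        variants=pd.DataFrame({
            "chrom": "1",
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "gene": [v.gene for v in variants],
            "fail_rule": [v.fail_rule or "." for v in variants],
            "carriers": [",".join(sample_ids[s] for s in v.carriers)
                         for v in variants],
        }),
        carriers=pd.DataFrame(
            carrier_rows, columns=["sample_id", "gene",
                                   "n_qualifying_variants"]
        ),
    )
    metadata = _generate_metadata(cfg, samples, rng)
    return CohortSimulation(
        config=cfg, samples=samples, variants=vtable, annotations=ann,
        metadata=metadata, manifest=manifest,
    )


def _generate_metadata(
    cfg: SimulationConfig, samples: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    def sexes(n: int, female_count: int | None) -> np.ndarray:
        if female_count is None:
            return np.where(rng.random(n) < cfg.female_prob,
                            "female", "male")
        out = np.array(["female"] * female_count
                       + ["male"] * (n - female_count))
        rng.shuffle(out)
        return out

    def ages(n: int, mean_sd: tuple[float, float]) -> np.ndarray:
        return np.clip(rng.normal(*mean_sd, size=n), 18, 60).round(1)

    sex = np.concatenate([
        sexes(cfg.n_cases, cfg.case_female_count),
        sexes(cfg.n_controls, cfg.control_female_count),
    ])
    age = np.concatenate([
        ages(cfg.n_cases, cfg.case_age_mean_sd),
        ages(cfg.n_controls, cfg.control_age_mean_sd),
    ])
    duration = np.full(len(samples), np.nan)
    hamd = np.full(len(samples), np.nan)
    duration[: cfg.n_cases] = np.round(
        rng.exponential(cfg.illness_duration_mean_months, cfg.n_cases), 1
    )
    hamd[: cfg.n_cases] = np.clip(
        rng.normal(*cfg.hamd_mean_sd, cfg.n_cases), 8, 52
    ).round(0)
    return pd.DataFrame({
        "sample_id": samples["sample_id"],
        "group": samples["group"],
        "age_years": age,
        "sex": sex,
        "illness_duration_months": duration,
        "hamd_score": hamd,
    })


# ---------------------------------------------------------------------------
# canned scenarios

def null_cohort(cfg: SimulationConfig) -> CohortSimulation:
    """Generate a cohort with no case/control structure.

    Validates that every gene's carrier probabilities are identical across
    groups, then delegates to :func:`generate_cohort`.
    """
    for gm in cfg.genes:
        if gm.case_carrier_prob != gm.control_carrier_prob:
            raise ConfigError(
                f"null cohort requires equal group probabilities; "
                f"gene {gm.gene} differs"
            )
    return generate_cohort(cfg)


def null_config(
    n_per_group: int = 60,
    n_genes: int = 120,
    carrier_prob: float = 0.01,
    pathway_sizes: Sequence[int] = (20, 30),
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """A no-structure config: every gene identical in both groups; pathways
    are arbitrary consecutive blocks of genes (pure chance structure)."""
    genes = tuple(
        GeneModel(gene=f"NULL{i:04d}", case_carrier_prob=carrier_prob,
                  control_carrier_prob=carrier_prob)
        for i in range(1, n_genes + 1)
    )
    pathways, start = [], 0
    for k, size in enumerate(pathway_sizes, start=1):
        block = [g.gene for g in genes[start:start + size]]
        if len(block) < size:
            raise ConfigError("pathway_sizes exceed the gene universe")
        pathways.append(GeneSet(pathway_id=f"NULLPATH{k}",
                                name=f"null block {k}",
                                genes=frozenset(block)))
        start += size
    return SimulationConfig(
        n_cases=n_per_group, n_controls=n_per_group, genes=genes,
        background_gene_count=0, pathways=tuple(pathways), seed=seed,
        **overrides,
    )


#: tiered case carrier probabilities echoing the shape of the published
#: per-gene mutation rates (amylases lower, brush-border genes saturated)
STUDYLIKE_CASE_PROBS = {
    "AMY1A": 0.76, "AMY2A": 0.77, "AMY2B": 0.82,
    "SI": 1.0, "MGAM": 1.0, "LCT": 1.0,
}


def studylike_scenario(seed: int = 0) -> SimulationConfig:
    """A SHAPE-ALIKE of the published study design, not its data.

    117 cases vs 78 controls; the six-gene carbohydrate-digestion pathway is
    embedded with tiered case carrier probabilities (high for SI/MGAM/LCT,
    lower for the amylases) and zero control carrier probability, on top of
    a 994-gene background mutated at equal low rates in both groups.  The
    background rate is set so that a few percent of background genes carry a
    post-filter mutation in each group — the regime of a pathway-annotated
    exome cohort, where the mutated-gene fraction n/N is small.  Sex counts
    are fixed at 75/42 (cases) and 46/32 (controls); ages are drawn around
    means of 31.9 and 33.4 years.
    """
    genes = tuple(
        GeneModel(gene=g, case_carrier_prob=p, control_carrier_prob=0.0,
                  extra_variants_mean=1.0)
        for g, p in STUDYLIKE_CASE_PROBS.items()
    )
    return SimulationConfig(
        n_cases=117, n_controls=78, genes=genes,
        # per-sample background rate chosen so a background gene is mutated
        # in >=1 of 117 cases with probability ~0.03 (small mutated-gene
        # fraction n/N, as in a pathway-annotated exome background)
        background_gene_count=994, background_carrier_prob=0.00026,
        pathways=(carbohydrate_pathway_fixture(),),
        contaminants_per_rule=tuple(
            (rule, 5) for rule in CONTAMINANT_RULES
        ),
        case_female_count=75, control_female_count=46,
        seed=seed,
    )


def with_seed(cfg: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(cfg, seed=seed)


# ---------------------------------------------------------------------------
# fast null-calibration harness (no per-variant simulation)

def null_mutated_gene_replicates(
    n_replicates: int,
    n_samples: int,
    gene_names: Sequence[str],
    carrier_prob: float,
    rng: np.random.Generator,
) -> Iterable[set[str]]:
    """Yield, per replicate, the set of genes mutated in >= 1 of ``n_samples``
    samples when every sample x gene is an independent Bernoulli carrier.

    This is the sample-level null model of :func:`null_cohort` restricted to
    the quantity enrichment consumes (the mutated-gene set), which makes
    thousands of replicates cheap.
    """
    gene_arr = np.asarray(gene_names)
    for _ in range(n_replicates):
        carried = (
            rng.random((n_samples, gene_arr.size)) < carrier_prob
        ).any(axis=0)
        yield set(gene_arr[carried])


#: study conditions for the type-I-error calibration experiment: a 60+60
#: cohort over 400 genes with pathways of Reactome-scale sizes; the
#: per-sample carrier probability makes each gene mutated in >=1 group
#: sample with probability 0.4, keeping the discrete tail fine-grained.
NULL_CALIBRATION = {
    "n_samples_per_group": 60,
    "n_genes": 400,
    "per_sample_carrier_prob": 1.0 - 0.6 ** (1.0 / 60.0),
    "pathway_sizes": (30, 40, 60, 80),
}


def null_enrichment_positive_rate(
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of pathways called enriched across null replicates.

    Draws ``n_replicates`` no-structure cohorts under the frozen
    :data:`NULL_CALIBRATION` conditions, runs the pathway enrichment test on
    each at level ``alpha``, and returns the enriched-call fraction — the
    Monte-Carlo estimate of the test's achieved type-I error.
    """
    from .enrichment import enrichment_from_mutated  # local: avoid heavy import at module load

    cond = NULL_CALIBRATION
    genes = [f"NULL{i:04d}" for i in range(1, cond["n_genes"] + 1)]
    pathways, start = [], 0
    for k, size in enumerate(cond["pathway_sizes"], start=1):
        pathways.append(GeneSet(
            pathway_id=f"NULLPATH{k}", name=f"null block {k}",
            genes=frozenset(genes[start:start + size]),
        ))
        start += size
    db = PathwayDatabase.from_gene_sets(pathways, background=genes)
    rng = np.random.default_rng(seed)
    calls = total = 0
    for mutated in null_mutated_gene_replicates(
        n_replicates, cond["n_samples_per_group"], genes,
        cond["per_sample_carrier_prob"], rng,
    ):
        rep = enrichment_from_mutated(mutated, db, alpha=alpha)
        calls += int(rep["enriched"].sum())
        total += len(rep)
    return calls / total
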