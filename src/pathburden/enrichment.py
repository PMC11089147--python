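"""Gene-level and pathway-level mutation-enrichment statistics.

The core statistic is the upper-tail hypergeometric probability

    p = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n) = P(X >= m)

with N the number of pathway-annotated genes in the background universe,
n the number of background genes carrying at least one surviving (post-filter)
variant in the group under study, M the number of background genes annotated
to the pathway, and m the number of mutated genes within the pathway.  A
pathway is *enrichment positive* when at least one of its genes is mutation
enriched; a gene/pathway is called enriched when p <= alpha (0.05 by default,
boundary inclusive).

The tail is computed with exact log-combinatorics (log-gamma + logsumexp),
safe against overflow for backgrounds up to ~1e5 genes.  No multiple-testing
correction is applied by the headline report; a Benjamini-Hochberg column is
emitted alongside for convenience and clearly labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .pathway_db import GeneSet, PathwayDatabase
from .variant_model import CohortTable

DEFAULT_ALPHA = 0.05

#: tolerance for the boundary-inclusive call (p <= alpha counts as enriched):
#: the log-gamma tail carries ~1e-15 relative rounding, so a p that is
#: mathematically equal to alpha must not be pushed to the wrong side
_ALPHA_EPS = 1e-9


def _is_enriched(p, alpha: float):
    return p <= alpha * (1.0 + _ALPHA_EPS)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts entering the hypergeometric tail; invariants enforced."""

    N: int  # background (pathway-annotated) genes
    M: int  # background genes in the pathway under test
    n: int  # mutated background genes in the group
    m: int  # mutated genes within the pathway

    def __post_init__(self) -> None:
        if not (0 <= self.M <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"need 0 <= M, n <= N; got {self}")
        if not 0 <= self.m <= min(self.n, self.M):
            raise ValueError(f"need 0 <= m <= min(n, M); got {self}")
        if self.N == 0:
            raise ValueError("background must be non-empty")


def _log_comb(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeometric_enrichment_p(inp: EnrichmentInput) -> float:
    """Upper tail P(X >= m) for X ~ Hypergeometric(N, M, n).

    Summed in log space over the feasible support [m, min(n, M)]; returns
    exactly 1.0 at m = 0 (empty lower sum).
    """
    N, M, n, m = inp.N, inp.M, inp.n, inp.m
    if m == 0:
        return 1.0
    i = np.arange(m, min(n, M) + 1)
    # pmf(i) = C(M,i) C(N-M,n-i) / C(N,n); infeasible i have -inf log terms
    log_terms = _log_comb(M, i) + _log_comb(N - M, n - i) - _log_comb(N, n)
    log_terms = log_terms[np.isfinite(log_terms)]
    if log_terms.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def hypergeom_tail(N: int, M: int, n: int, m: int) -> float:
    """Convenience wrapper around :func:`hypergeometric_enrichment_p`."""
    return hypergeometric_enrichment_p(EnrichmentInput(N=N, M=M, n=n, m=m))


# ---------------------------------------------------------------------------
# carrier / mutated-gene extraction from a filtered cohort

def _group_carrier_by_gene(
    filtered: CohortTable,
    group: Literal["case", "control"],
    min_depth_exclusive: int | None = 4,
) -> pd.DataFrame:
    """Boolean frame (gene x group-sample): carries >= 1 surviving variant."""
    cols = filtered.group_columns(group)
    if cols.size == 0:
        raise ValueError(f"cohort has no '{group}' samples")
    carrier = filtered.carrier_matrix(min_depth_exclusive)[:, cols]
    genes = filtered.records["gene"]
    df = pd.DataFrame(carrier, columns=np.asarray(filtered.sample_ids)[cols])
    df["gene"] = genes.to_numpy()
    return df.groupby("gene").any()


def mutated_genes(
    filtered: CohortTable,
    group: Literal["case", "control"],
    min_depth_exclusive: int | None = 4,
) -> set[str]:
    """Genes with >= 1 surviving variant carried by >= 1 sample of the group."""
    if len(filtered) == 0:
        return set()
    by_gene = _group_carrier_by_gene(filtered, group, min_depth_exclusive)
    return set(by_gene.index[by_gene.any(axis=1)])


def enrichment_from_mutated(
    mutated: Iterable[str],
    db: PathwayDatabase,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Pathway-level hypergeometric test given the set of mutated genes.

    ``n`` counts mutated genes restricted to the database background; genes
    outside the background do not enter the test.
    """
    bg = db.background_genes
    mut_bg = set(g.upper() for g in mutated) & bg
    N, n = len(bg), len(mut_bg)
    rows = []
    for gs in db:
        M = len(gs.genes)
        m = len(gs.genes & mut_bg)
        p = hypergeom_tail(N, M, n, m)
        rows.append((gs.pathway_id, N, M, n, m, p, _is_enriched(p, alpha)))
    return pd.DataFrame(
        rows, columns=["pathway_id", "N", "M", "n", "m", "p_value", "enriched"]
    ).set_index("pathway_id")


def gene_enrichment_flags(
    mutated: Iterable[str],
    db: PathwayDatabase,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, bool]:
    """Per-gene enrichment flags: the same tail applied to a singleton set.

    For a single gene (M = 1) the tail reduces to n/N when the gene is
    mutated and 1 otherwise, so a gene is enriched iff it is mutated and
    n/N <= alpha.
    """
    bg = db.background_genes
    mut_bg = set(g.upper() for g in mutated) & bg
    N, n = len(bg), len(mut_bg)
    flags = {}
    for g in bg:
        m = 1 if g in mut_bg else 0
        flags[g] = _is_enriched(hypergeom_tail(N, 1, n, m), alpha)
    return flags


def gene_enrichment_test(
    filtered: CohortTable,
    db: PathwayDatabase,
    group: Literal["case", "control"],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-pathway hypergeometric enrichment for one cohort group."""
    return enrichment_from_mutated(mutated_genes(filtered, group), db, alpha)


def pathway_positivity(
    per_gene_enriched: Mapping[str, bool], gs: GeneSet
) -> bool:
    """Positive iff at least one pathway gene is mutation enriched.

    Genes without a flag are treated as not enriched.
    """
    return any(per_gene_enriched.get(g, False) for g in gs.genes)


# ---------------------------------------------------------------------------
# mutation / carrier rates

def gene_mutation_rate(
    filtered: CohortTable,
    gene: str,
    group: Literal["case", "control"],
    min_depth_exclusive: int | None = 4,
) -> float:
    """Fraction of group samples carrying >= 1 surviving variant in ``gene``."""
    n_group = filtered.n_in_group(group)
    if n_group == 0:
        raise ValueError(f"cohort has no '{group}' samples")
    if len(filtered) == 0:
        return 0.0
    by_gene = _group_carrier_by_gene(filtered, group, min_depth_exclusive)
    gene = gene.upper()
    if gene not in by_gene.index:
        return 0.0
    return float(by_gene.loc[gene].sum()) / n_group


def pathway_carrier_rate(
    filtered: CohortTable,
    gs: GeneSet,
    group: Literal["case", "control"],
    min_depth_exclusive: int | None = 4,
) -> float:
    """Fraction of group samples carrying >= 1 surviving variant in any
    pathway gene."""
    n_group = filtered.n_in_group(group)
    if n_group == 0:
        raise ValueError(f"cohort has no '{group}' samples")
    if len(filtered) == 0:
        return 0.0
    by_gene = _group_carrier_by_gene(filtered, group, min_depth_exclusive)
    in_set = by_gene.index.isin(gs.genes)
    if not in_set.any():
        return 0.0
    return float(by_gene.loc[in_set].any(axis=0).sum()) / n_group


# ---------------------------------------------------------------------------
# headline report

@dataclass
class EnrichmentResult:
    """One pathway's case/control statistics for the headline comparison."""

    pathway_id: str
    p_case: float
    p_control: float
    positive_case: bool
    positive_control: bool
    rate_case: float
    rate_control: float
    per_gene: dict[str, tuple[float, float]] = field(default_factory=dict)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (reported, not used)."""
    k = len(p)
    order = np.argsort(p)
    adj = np.empty(k)
    prev = 1.0
    for rank in range(k, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * k / rank)
        adj[i] = prev
    return adj


def cohort_compare(
    filtered: CohortTable,
    db: PathwayDatabase,
    alpha: float = DEFAULT_ALPHA,
    min_depth_exclusive: int | None = 4,
) -> pd.DataFrame:
    """Per-pathway case/control enrichment, positivity and carrier rates.

    Report is sorted by case p-value ascending, ties broken by pathway id.
    Requires both groups to be present; single-group cohorts should use the
    group-specific operations instead.
    """
    for group in ("case", "control"):
        if filtered.n_in_group(group) == 0:
            raise ValueError(
                f"cohort has no '{group}' samples; use the group-specific "
                "operations (gene_enrichment_test, pathway_carrier_rate)"
            )
    mut = {g: mutated_genes(filtered, g, min_depth_exclusive)
           for g in ("case", "control")}
    enr = {g: enrichment_from_mutated(mut[g], db, alpha)
           for g in ("case", "control")}
    flags = {g: gene_enrichment_flags(mut[g], db, alpha)
             for g in ("case", "control")}
    rows = []
    gene_cols: dict[str, float] = {}
    for gs in db:
        row = {
            "pathway_id": gs.pathway_id,
            "p_case": enr["case"].loc[gs.pathway_id, "p_value"],
            "p_control": enr["control"].loc[gs.pathway_id, "p_value"],
            "positive_case": pathway_positivity(flags["case"], gs),
            "positive_control": pathway_positivity(flags["control"], gs),
            "rate_case": pathway_carrier_rate(
                filtered, gs, "case", min_depth_exclusive),
            "rate_control": pathway_carrier_rate(
                filtered, gs, "control", min_depth_exclusive),
        }
        for g in sorted(gs.genes):
            row[f"rate_case.{g}"] = gene_mutation_rate(
                filtered, g, "case", min_depth_exclusive)
            row[f"rate_control.{g}"] = gene_mutation_rate(
                filtered, g, "control", min_depth_exclusive)
        rows.append(row)
    report = pd.DataFrame(rows)
    report["q_case_bh"] = _bh_adjust(report["p_case"].to_numpy())
    report = report.sort_values(
        ["p_case", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    lead = ["pathway_id", "p_case", "p_control", "q_case_bh",
            "positive_case", "positive_control", "rate_case", "rate_control"]
    return report[lead + [c for c in report.columns if c not in lead]]
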