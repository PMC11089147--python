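"""Pathway gene-set definitions (GMT dialect) and the background gene universe.

A :class:`PathwayDatabase` holds named gene sets together with the background
universe of pathway-annotated genes against which enrichment is tested.  By
default the background is the union of all loaded sets; an explicit background
list (one symbol per line) can override it, since the full universe of
pathway-annotated genes is usually larger than the sets under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be parsed; message names the line."""


class PathwayValidationError(ValueError):
    """Raised when database invariants are violated (duplicate ids, etc.)."""


def _normalize_symbol(sym: str) -> str:
    sym = sym.strip().upper()
    if not sym or any(ch.isspace() for ch in sym):
        raise PathwayValidationError(f"invalid gene symbol: {sym!r}")
    return sym


@dataclass(frozen=True)
class GeneSet:
    """A named pathway: an id, a human-readable name, and its gene symbols.

    Symbols are normalized to uppercase on construction; duplicates collapse
    (they are a set), but an empty set is rejected.
    """

    pathway_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        normalized = frozenset(_normalize_symbol(g) for g in self.genes)
        if not normalized:
            raise PathwayValidationError(
                f"gene set {self.pathway_id!r} has no genes"
            )
        object.__setattr__(self, "genes", normalized)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


@dataclass
class PathwayDatabase:
    """Gene sets keyed by pathway id plus the background gene universe.

    Invariant: every set's genes are a subset of ``background_genes``.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    background_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.background_genes = frozenset(
            _normalize_symbol(g) for g in self.background_genes
        )
        for gs in self.sets.values():
            missing = gs.genes - self.background_genes
            if missing:
                raise PathwayValidationError(
                    f"pathway {gs.pathway_id!r} has genes outside the "
                    f"background: {sorted(missing)}"
                )

    @classmethod
    def from_gene_sets(
        cls,
        gene_sets: Iterable[GeneSet],
        background: Iterable[str] | None = None,
    ) -> "PathwayDatabase":
        sets: dict[str, GeneSet] = {}
        for gs in gene_sets:
            if gs.pathway_id in sets:
                raise PathwayValidationError(
                    f"duplicate pathway_id {gs.pathway_id!r}"
                )
            sets[gs.pathway_id] = gs
        if background is None:
            bg: frozenset[str] = frozenset().union(
                *(gs.genes for gs in sets.values())
            ) if sets else frozenset()
        else:
            bg = frozenset(_normalize_symbol(g) for g in background)
        return cls(sets=sets, background_genes=bg)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, pathway_id: str) -> GeneSet:
        return self.sets[pathway_id]

    def __iter__(self):
        return iter(self.sets.values())


def read_gmt(path: str | Path, background: str | Path | None = None) -> PathwayDatabase:
    """Read a Broad-dialect GMT file: ``id<TAB>description<TAB>gene...``.

    Each line needs at least three tab-separated fields (at least one gene).
    ``background`` optionally points at a plain-text gene list (one symbol per
    line) defining the background universe; otherwise the union of all sets is
    used.

    Raises
    ------
    GmtParseError
        On a malformed line (message includes the 1-based line number).
    PathwayValidationError
        On duplicate pathway ids or background/subset violations.
    """
    path = Path(path)
    gene_sets: list[GeneSet] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path.name}:{lineno}: expected at least 3 tab-separated "
                    f"fields (id, description, >=1 gene), got {len(fields)}"
                )
            pid, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise GmtParseError(
                    f"{path.name}:{lineno}: pathway {pid!r} lists no genes"
                )
            gene_sets.append(
                GeneSet(pathway_id=pid.strip(), name=desc.strip(),
                        genes=frozenset(genes))
            )
    bg = None
    if background is not None:
        bg = [
            ln.strip()
            for ln in Path(background).read_text(encoding="utf-8").splitlines()
            if ln.strip()
        ]
    return PathwayDatabase.from_gene_sets(gene_sets, background=bg)


def write_gmt(db: PathwayDatabase | Mapping[str, GeneSet], path: str | Path) -> None:
    """Write gene sets back out as GMT (genes sorted for reproducibility)."""
    sets = db.sets if isinstance(db, PathwayDatabase) else dict(db)
    with Path(path).open("w", encoding="utf-8") as fh:
        for gs in sets.values():
            fh.write("\t".join([gs.pathway_id, gs.name, *sorted(gs.genes)]) + "\n")


#: Genes of the Reactome "Digestion of dietary carbohydrate" pathway: the
#: three salivary/pancreatic amylases plus the three intestinal brush-border
#: disaccharidase loci (sucrase-isomaltase, maltase-glucoamylase, lactase).
CARBOHYDRATE_PATHWAY_GENES = frozenset(
    {"AMY1A", "AMY2A", "AMY2B", "SI", "MGAM", "LCT"}
)


def carbohydrate_pathway_fixture() -> GeneSet:
    """The six-gene carbohydrate-digestion pathway used throughout the tests."""
    return GeneSet(
        pathway_id="CARB_DIGESTION",
        name="Digestion of dietary carbohydrate",
        genes=CARBOHYDRATE_PATHWAY_GENES,
    )
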