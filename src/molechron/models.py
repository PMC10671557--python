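"""Core domain types: gene models, exon-annotated alignments, lesion records,
and category-labeled time trees.

Coordinate convention
---------------------
All coding-sequence coordinates are 1-based, closed intervals, expressed in
CDS-alignment space *including* insertion columns (columns where the
reference taxon carries a gap).  This matches the convention used in curated
inactivating-mutation tables, where e.g. ``1478-1575D (E13)`` names the
alignment columns deleted in a taxon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy

ALLOWED_SYMBOLS = set("ACGTN-")

GENE_GROUPS = (
    "cone_activation",
    "cone_recovery",
    "rod_activation",
    "rod_recovery",
    "lens_cornea",
)

#: inactivating-mutation kind codes
LESION_KINDS = (
    "I",      # frameshift insertion
    "D",      # frameshift deletion
    "S",      # premature stop codon
    "SCM",    # start codon mutation
    "TCM",    # termination codon mutation
    "Do",     # donor splice-site mutation
    "Ac",     # acceptor splice-site mutation
    "BD",     # intron-exon boundary deletion
    "STSD",   # spectral tuning site deletion
    "CBSM",   # chromophore binding-site mutation
    "SBCM",   # Schiff base counterion mutation
    "NBR",    # no BLAST results (possible gene/exon loss)
    "NMR",    # no mapped reads (possible gene/exon loss)
    "INV",    # inversion
    "AfSI",   # AfroSINE insertion
)

SPLICE_KINDS = ("Do", "Ac")

SITE_ROLES = (
    "spectral_tuning",
    "chromophore_binding",
    "schiff_base_counterion",
    "transmembrane",
)


class StructuralError(ValueError):
    """Input data violates a structural contract (lengths, symbols, labels)."""


@dataclass
class IntronSites:
    """Donor/acceptor dinucleotides observed for one intron in one taxon."""

    intron_index: int  # 1-based; intron k lies between exon k and exon k+1
    donor: str
    acceptor: str

    def __post_init__(self) -> None:
        for dinuc in (self.donor, self.acceptor):
            if len(dinuc) != 2 or not set(dinuc.upper()) <= ALLOWED_SYMBOLS:
                raise StructuralError(
                    f"bad splice dinucleotide {dinuc!r} for intron {self.intron_index}"
                )


@dataclass
class GeneModel:
    """Exon structure and per-taxon splice-site evidence for one gene."""

    gene_id: str
    exon_lengths: list[int]
    intron_sites: dict[str, list[IntronSites]] = field(default_factory=dict)
    genetic_code: int = 1
    gene_group: Optional[str] = None
    pleiotropic: bool = False

    def __post_init__(self) -> None:
        if not self.exon_lengths or any(n < 1 for n in self.exon_lengths):
            raise StructuralError(f"{self.gene_id}: exon lengths must be >= 1")
        if self.gene_group is not None and self.gene_group not in GENE_GROUPS:
            raise StructuralError(
                f"{self.gene_id}: unknown gene group {self.gene_group!r}"
            )
        n_introns = len(self.exon_lengths) - 1
        for taxon, sites in self.intron_sites.items():
            if len(sites) != n_introns:
                raise StructuralError(
                    f"{self.gene_id}/{taxon}: expected {n_introns} intron records, "
                    f"got {len(sites)}"
                )

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    def exon_of_cds_position(self, pos: int) -> int:
        """1-based exon index containing 1-based reference-CDS position."""
        if not 1 <= pos <= self.cds_length:
            raise StructuralError(f"{self.gene_id}: CDS position {pos} out of range")
        cum = 0
        for i, n in enumerate(self.exon_lengths, start=1):
            cum += n
            if pos <= cum:
                return i
        raise AssertionError("unreachable")


@dataclass
class CodingAlignment:
    """Multi-taxon CDS alignment annotated with exons and insertion columns.

    ``insertion_columns`` are exactly the columns where the reference taxon
    carries a gap; ``column_exon_map[i]`` is the 1-based exon index of
    0-based column ``i``.
    """

    gene_id: str
    rows: dict[str, str]
    reference_taxon: str
    column_exon_map: list[int]
    insertion_columns: set[int]  # 0-based column indices

    def __post_init__(self) -> None:
        if self.reference_taxon not in self.rows:
            raise StructuralError(
                f"{self.gene_id}: reference taxon {self.reference_taxon!r} missing"
            )
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise StructuralError(f"{self.gene_id}: unequal row lengths {lengths}")
        (n,) = lengths
        if len(self.column_exon_map) != n:
            raise StructuralError(f"{self.gene_id}: column_exon_map length mismatch")
        ref = self.rows[self.reference_taxon]
        ref_gaps = {i for i, ch in enumerate(ref) if ch == "-"}
        if ref_gaps != self.insertion_columns:
            raise StructuralError(
                f"{self.gene_id}: insertion_columns do not equal reference-gap columns"
            )
        for taxon, seq in self.rows.items():
            bad = set(seq.upper()) - ALLOWED_SYMBOLS
            if bad:
                raise StructuralError(f"{self.gene_id}/{taxon}: bad symbols {bad}")

    @property
    def n_columns(self) -> int:
        return len(self.column_exon_map)

    @property
    def reference_cds_length(self) -> int:
        return self.n_columns - len(self.insertion_columns)

    def non_insertion_columns(self) -> list[int]:
        ins = self.insertion_columns
        return [i for i in range(self.n_columns) if i not in ins]

    @classmethod
    def from_rows(
        cls, gene_id: str, rows: dict[str, str], reference_taxon: str,
        gene_model: GeneModel,
    ) -> "CodingAlignment":
        """Build the alignment, deriving exon map and insertion columns.

        The reference row with its gaps removed must equal the gene model's
        CDS length; insertion columns inherit the exon of the nearest
        preceding non-insertion column (or the first exon at the start).
        """
        ref = rows.get(reference_taxon)
        if ref is None:
            raise StructuralError(f"{gene_id}: reference taxon missing")
        ref_len = sum(1 for ch in ref if ch != "-")
        if ref_len != gene_model.cds_length:
            raise StructuralError(
                f"{gene_id}: reference CDS length {ref_len} != gene model "
                f"length {gene_model.cds_length}"
            )
        column_exon_map: list[int] = []
        insertion_columns: set[int] = set()
        cds_pos = 0
        for i, ch in enumerate(ref):
            if ch == "-":
                insertion_columns.add(i)
                exon = gene_model.exon_of_cds_position(max(cds_pos, 1))
            else:
                cds_pos += 1
                exon = gene_model.exon_of_cds_position(cds_pos)
            column_exon_map.append(exon)
        return cls(gene_id, dict(rows), reference_taxon, column_exon_map,
                   insertion_columns)


@dataclass
class SiteEntry:
    protein_position: int  # 1-based, reference coordinates
    role: str
    allowed_residues: frozenset[str]

    def __post_init__(self) -> None:
        if self.protein_position < 1:
            raise StructuralError("site positions are 1-based (>= 1)")
        if self.role not in SITE_ROLES:
            raise StructuralError(f"unknown site role {self.role!r}")
        if not self.allowed_residues:
            raise StructuralError("allowed_residues must be non-empty")


@dataclass
class SiteTable:
    entries: list[SiteEntry]


@dataclass(frozen=True)
class LesionRecord:
    """One inactivating mutation in one taxon (or individual) and gene."""

    taxon: str
    gene: str
    kind: str
    start: Optional[int] = None      # 1-based alignment coordinate
    end: Optional[int] = None
    intron_index: Optional[int] = None
    feature_label: str = ""          # e.g. "E5", "In4", "In1E2"
    sharing: str = "autapomorphic"   # shared | autapomorphic | individual_specific:<id>
    detail: str = ""                 # e.g. observed splice dinucleotide
    frameshift: bool = False
    possibly_tolerated: bool = False

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise StructuralError(
                f"unknown lesion kind {self.kind!r}; allowed: {', '.join(LESION_KINDS)}"
            )
        if self.kind in SPLICE_KINDS:
            if self.intron_index is None:
                raise StructuralError(f"{self.kind} records need an intron index")
        elif self.start is not None and self.end is not None and self.start > self.end:
            raise StructuralError(f"interval start {self.start} > end {self.end}")

    @property
    def location_key(self) -> tuple:
        if self.kind in SPLICE_KINDS:
            return ("intron", self.intron_index)
        return ("interval", self.start, self.end)


@dataclass
class LesionTable:
    records: list[LesionRecord]
    group_map: dict[str, str] = field(default_factory=dict)
    pleiotropic_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.gene not in self.group_map:
                raise StructuralError(f"gene {rec.gene} missing from group_map")
            key = (rec.taxon, rec.gene, rec.kind, rec.location_key,
                   rec.feature_label)
            if key in seen:
                raise StructuralError(f"duplicate lesion record {key}")
            seen.add(key)

    def eye_specific_records(self) -> list[LesionRecord]:
        return [r for r in self.records if r.gene not in self.pleiotropic_set]


BACKGROUND = "background"


def parse_category(token: str) -> str:
    """Map a branch-mark token to a category label.

    ``""`` -> background, ``T1`` -> ``transitional:1``, ``P2`` ->
    ``pseudogenic:2``.  Full-form labels pass through.
    """
    if not token:
        return BACKGROUND
    if token.startswith("T") and token[1:].isdigit():
        return f"transitional:{int(token[1:])}"
    if token.startswith("P") and token[1:].isdigit():
        return f"pseudogenic:{int(token[1:])}"
    if token == BACKGROUND or token.split(":")[0] in ("transitional", "pseudogenic"):
        return token
    raise StructuralError(f"unrecognized branch-category token {token!r}")


def category_token(category: str) -> str:
    if category == BACKGROUND:
        return ""
    regime, k = category.split(":")
    return ("T" if regime == "transitional" else "P") + k


@dataclass
class LabeledTimeTree:
    """Rooted tree with optional node ages (MY) and per-branch selection
    categories.

    The category of a branch is stored on its child node as
    ``node.category``.  Ages, when present, must strictly decrease from
    root to tips, and every ``transitional:k`` branch must subtend only
    ``pseudogenic:k`` branches.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        for node in self.tree:
            if not hasattr(node, "category"):
                node.category = BACKGROUND
            if not hasattr(node, "age_my"):
                node.age_my = None
        self.validate()

    # -- accessors ---------------------------------------------------------
    def nodes(self):
        return self.tree.preorder_node_iter()

    def branch_nodes(self):
        """Child nodes of all branches (every node except the root)."""
        root = self.tree.seed_node
        return [nd for nd in self.tree.preorder_node_iter() if nd is not root]

    def categories(self) -> list[str]:
        seen: list[str] = []
        for nd in self.branch_nodes():
            if nd.category not in seen:
                seen.append(nd.category)
        return seen

    def tip_label(self, node) -> str:
        return node.taxon.label if node.taxon else (node.label or "")

    def node_by_tips(self, tips: Iterable[str]):
        tips = set(tips)
        labels = {t.label for t in self.tree.taxon_namespace}
        missing = tips - labels
        if missing:
            raise StructuralError(f"unknown tips in age table: {sorted(missing)}")
        node = self.tree.mrca(taxa=[t for t in self.tree.taxon_namespace
                                    if t.label in tips])
        if node is None:
            raise StructuralError(f"no MRCA found for {sorted(tips)}")
        return node

    def branch_duration_my(self, node) -> float:
        """Duration of the branch above ``node`` in MY (requires ages)."""
        parent = node.parent_node
        if parent is None:
            raise StructuralError("root has no branch")
        if parent.age_my is None or node.age_my is None:
            raise StructuralError("branch endpoints lack ages")
        return parent.age_my - node.age_my

    def branches_in_category(self, category: str):
        return [nd for nd in self.branch_nodes() if nd.category == category]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for node in self.tree.preorder_node_iter():
            if node.edge.length is not None and node.edge.length < 0:
                raise StructuralError("negative branch length")
            if node.parent_node is not None:
                pa, ca = node.parent_node.age_my, node.age_my
                if pa is not None and ca is not None and not pa > ca:
                    raise StructuralError(
                        f"node ages must strictly decrease root->tip ({pa} !> {ca})"
                    )
            cat = getattr(node, "category", BACKGROUND)
            if cat.startswith("transitional:"):
                k = cat.split(":")[1]
                want = f"pseudogenic:{k}"
                for desc in node.preorder_iter():
                    if desc is node:
                        continue
                    if desc.category != want:
                        raise StructuralError(
                            f"transitional:{k} branch subtends a "
                            f"{desc.category} branch; expected {want}"
                        )
            if cat.startswith("pseudogenic:"):
                parent = node.parent_node
                pcat = getattr(parent, "category", BACKGROUND) if parent else BACKGROUND
                k = cat.split(":")[1]
                ok = pcat in (f"pseudogenic:{k}", f"transitional:{k}")
                if not ok and parent is not None and parent.parent_node is not None:
                    raise StructuralError(
                        f"pseudogenic:{k} branch under a {pcat} branch; a "
                        f"pseudogenic branch needs a transitional or pseudogenic stem"
                    )
                # branches hanging directly off the root are allowed to start
                # a pseudogenic clade only via a transitional stem; a root
                # child with pseudogenic category and background siblings is
                # the same violation
                if not ok and parent is not None and parent.parent_node is None:
                    raise StructuralError(
                        f"pseudogenic:{k} branch at the root without a "
                        f"transitional:{k} stem"
                    )

    def transitional_branch(self, k: int = 1):
        """The (unique) child node of the ``transitional:k`` branch."""
        nodes = self.branches_in_category(f"transitional:{k}")
        if len(nodes) != 1:
            raise StructuralError(
                f"expected exactly one transitional:{k} branch, found {len(nodes)}"
            )
        return nodes[0]

    def clone(self) -> "LabeledTimeTree":
        t2 = self.tree.clone(depth=1)
        for nd, nd2 in zip(self.tree, t2):
            nd2.category = nd.category
            nd2.age_my = nd.age_my
        return dataclasses.replace(self, tree=t2)
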