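"""Readers and writers for the package's plain-text formats.

Formats
-------
* aligned FASTA for CDS alignments (gap ``-``, ambiguity ``N``)
* newick with PAML-style branch marks for category-labeled trees
  (``#T1`` = transitional category 1, ``#P1`` = pseudogenic category 1;
  unmarked branches are background), with node ages in a sidecar TSV keyed
  by tip set
* TSV for gene models, splice-site dinucleotides, site tables, and
  curated lesion tables
"""

from __future__ import annotations

import csv
from typing import Optional

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    ALLOWED_SYMBOLS,
    BACKGROUND,
    CodingAlignment,
    GeneModel,
    IntronSites,
    LabeledTimeTree,
    LesionRecord,
    LesionTable,
    SiteEntry,
    SiteTable,
    StructuralError,
    category_token,
    parse_category,
)

# ---------------------------------------------------------------------------
# alignments


def read_alignment(path, gene_model: GeneModel, reference_taxon: str) -> CodingAlignment:
    """Read an aligned FASTA into a :class:`CodingAlignment`.

    The reference row minus its gaps must match the gene model's CDS
    length; every symbol must be one of ``ACGTN-``.
    """
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in ALLOWED_SYMBOLS:
                raise StructuralError(
                    f"{gene_model.gene_id}/{rec.id}: non-nucleotide symbol "
                    f"{ch!r} at column {pos}"
                )
        rows[rec.id] = seq
    return CodingAlignment.from_rows(
        gene_model.gene_id, rows, reference_taxon, gene_model
    )


def write_alignment(aln: CodingAlignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in aln.rows.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# gene models


def read_gene_model(path, splice_path=None) -> GeneModel:
    """Read a one-row gene-model TSV (gene_id, exon_lengths, gene_group,
    pleiotropic) plus an optional splice-site TSV (taxon, intron_index,
    donor, acceptor)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = [r for r in reader if r.get("gene_id")]
    if len(rows) != 1:
        raise StructuralError(f"{path}: expected exactly one gene-model row")
    row = rows[0]
    exon_lengths = [int(x) for x in row["exon_lengths"].split(",")]
    intron_sites: dict[str, list[IntronSites]] = {}
    if splice_path is not None:
        with open(splice_path, newline="") as fh:
            for r in csv.DictReader(fh, delimiter="\t"):
                intron_sites.setdefault(r["taxon"], []).append(
                    IntronSites(int(r["intron_index"]), r["donor"], r["acceptor"])
                )
        for sites in intron_sites.values():
            sites.sort(key=lambda s: s.intron_index)
    return GeneModel(
        gene_id=row["gene_id"],
        exon_lengths=exon_lengths,
        intron_sites=intron_sites,
        gene_group=row.get("gene_group") or None,
        pleiotropic=(row.get("pleiotropic", "").strip().lower() in ("1", "true", "yes")),
    )


def read_site_table(path) -> SiteTable:
    entries = []
    with open(path, newline="") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            entries.append(
                SiteEntry(
                    protein_position=int(r["protein_position"]),
                    role=r["role"],
                    allowed_residues=frozenset(r["allowed_residues"]),
                )
            )
    return SiteTable(entries)


# ---------------------------------------------------------------------------
# lesion tables


def read_gene_groups(path) -> tuple[dict[str, str], set[str]]:
    """Read a gene-group TSV (gene, group, pleiotropic) into
    (group_map, pleiotropic_set)."""
    group_map: dict[str, str] = {}
    pleiotropic: set[str] = set()
    with open(path, newline="") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            group_map[r["gene"]] = r["group"]
            if r.get("pleiotropic", "").strip().lower() in ("1", "true", "yes"):
                pleiotropic.add(r["gene"])
    return group_map, pleiotropic


def _normalize_kind(kind: str) -> str:
    # combined absence evidence ("NBR/NMR") counts as one entry
    return kind.split("/")[0].strip()


def read_lesion_table(
    path,
    group_map: dict[str, str],
    pleiotropic_set: Optional[set[str]] = None,
    pairs: Optional[dict[str, tuple[str, str]]] = None,
) -> LesionTable:
    """Read a curated lesion TSV.

    Columns: gene, taxon_scope, kind, start, end, feature, individual_tag,
    detail.  ``taxon_scope`` naming a pair in ``pairs`` with tag ``both``
    expands to one *shared* record per pair member; a tag naming one member
    yields a single individual-specific record.
    """
    pairs = pairs or {}
    records: list[LesionRecord] = []
    with open(path, newline="") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            if not r.get("gene"):
                continue
            kind = _normalize_kind(r["kind"])
            start = int(r["start"]) if r.get("start") else None
            end = int(r["end"]) if r.get("end") else start
            feature = r.get("feature", "")
            intron_index = None
            if kind in ("Do", "Ac"):
                if not feature.startswith("In"):
                    raise StructuralError(
                        f"splice lesion needs an In<k> feature, got {feature!r}"
                    )
                intron_index = int(feature[2:])
                start = end = None
            scope = r["taxon_scope"]
            tag = (r.get("individual_tag") or "").strip()
            detail = r.get("detail", "")
            frameshift = kind in ("I", "D")

            def rec(taxon: str, sharing: str) -> LesionRecord:
                return LesionRecord(
                    taxon=taxon, gene=r["gene"], kind=kind, start=start, end=end,
                    intron_index=intron_index, feature_label=feature,
                    sharing=sharing, detail=detail, frameshift=frameshift,
                )

            if scope in pairs:
                a, b = pairs[scope]
                if tag in ("both", ""):
                    records.append(rec(a, "shared"))
                    records.append(rec(b, "shared"))
                elif tag in (a, b):
                    records.append(rec(tag, f"individual_specific:{tag}"))
                else:
                    raise StructuralError(
                        f"individual_tag {tag!r} not a member of pair {scope!r}"
                    )
            else:
                records.append(rec(scope, "autapomorphic"))
    return LesionTable(records, group_map, pleiotropic_set or set())


def write_lesion_table(table: LesionTable, path) -> None:
    from .lesions import format_lesion_label

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["taxon", "gene", "kind", "start", "end", "feature", "sharing",
             "detail", "frameshift", "label"]
        )
        for rec in table.records:
            writer.writerow(
                [rec.taxon, rec.gene, rec.kind,
                 rec.start if rec.kind not in ("Do", "Ac") else rec.intron_index,
                 rec.end if rec.kind not in ("Do", "Ac") else "",
                 rec.feature_label, rec.sharing, rec.detail,
                 int(rec.frameshift), format_lesion_label(rec)]
            )


# ---------------------------------------------------------------------------
# labeled trees


def _strip_marks(tree: dendropy.Tree) -> None:
    for node in tree:
        label = node.taxon.label if node.taxon else node.label
        if label is None:
            node.category = BACKGROUND
            continue
        if "#" in label:
            name, token = label.split("#", 1)
            node.category = parse_category(token)
        else:
            name, node.category = label, BACKGROUND
        if node.taxon:
            node.taxon.label = name
        else:
            node.label = name or None


def read_labeled_tree(path_or_string, ages_path=None) -> LabeledTimeTree:
    """Read a newick tree with optional ``#T<k>``/``#P<k>`` branch marks and
    an optional node-age TSV (columns ``tips`` (comma-separated), ``age_my``).

    When an age table is supplied, tips default to age 0.
    """
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    tree.is_rooted = True
    _strip_marks(tree)
    for node in tree:
        node.age_my = None
    ltt = LabeledTimeTree(tree)
    if ages_path is not None:
        apply_node_ages(ltt, ages_path)
    return ltt


def apply_node_ages(ltt: LabeledTimeTree, ages_path) -> None:
    for node in ltt.tree.leaf_node_iter():
        node.age_my = 0.0
    with open(ages_path, newline="") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            tips = [t.strip() for t in r["tips"].split(",")]
            node = (ltt.node_by_tips(tips) if len(tips) > 1
                    else _tip_node(ltt, tips[0]))
            node.age_my = float(r["age_my"])
    ltt.validate()


def _tip_node(ltt: LabeledTimeTree, label: str):
    for node in ltt.tree.leaf_node_iter():
        if node.taxon and node.taxon.label == label:
            return node
    raise StructuralError(f"unknown tip {label!r}")


def _newick_node(ltt: LabeledTimeTree, node) -> str:
    token = category_token(node.category)
    mark = f"#{token}" if token else ""
    length = "" if node.edge.length is None else f":{node.edge.length:.10g}"
    if node.is_leaf():
        return f"{ltt.tip_label(node)}{mark}{length}"
    inner = ",".join(_newick_node(ltt, ch) for ch in node.child_nodes())
    label = node.label or ""
    return f"({inner}){label}{mark}{length}"


def write_labeled_tree(ltt: LabeledTimeTree, path, ages_path=None) -> None:
    with open(path, "w") as fh:
        fh.write(_newick_node(ltt, ltt.tree.seed_node) + ";\n")
    if ages_path is not None:
        with open(ages_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["tips", "age_my"])
            for node in ltt.tree.preorder_node_iter():
                if node.age_my is None:
                    continue
                tips = sorted(
                    ltt.tip_label(leaf) for leaf in node.leaf_iter()
                )
                writer.writerow([",".join(tips), node.age_my])


def load_bundled_lesion_table() -> LesionTable:
    """The curated inactivating-mutation tables for the marsupial mole
    (two individuals) and the two golden-mole species, bundled with the
    package."""
    from importlib.resources import files

    data = files("molechron.data")
    group_map, pleio = read_gene_groups(data / "eye_genes.tsv")
    pairs = {
        "Notoryctes_typhlops": ("Notoryctes_typhlops_NYGC",
                                "Notoryctes_typhlops_DNAZoo"),
        "Chrysochloridae": ("Chrysochloris_asiatica", "Amblysomus_hottentotus"),
    }
    return read_lesion_table(
        data / "mole_eye_lesions.tsv", group_map, pleio, pairs
    )
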