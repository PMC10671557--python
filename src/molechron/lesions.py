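"""Detection, labeling, and tallying of gene-inactivating mutations.

The scanner works on exon-annotated CDS alignments and emulates manual
pseudogene annotation: frameshift indels, premature stop codons (after
masking — frameshift insertions removed, deletions N-filled), start/stop
codon mutations, non-canonical splice-site dinucleotides, intron-exon
boundary deletions, and disrupted opsin functional sites.
"""

from __future__ import annotations

import warnings
from typing import Optional

from .genetic_code import STANDARD_CODE, GeneticCode, translate
from .models import (
    CodingAlignment,
    GeneModel,
    LesionRecord,
    LesionTable,
    SiteTable,
    StructuralError,
)

CANONICAL_DONORS = {"GT", "GC"}
CANONICAL_ACCEPTOR = "AG"


def _exon_feature(aln: CodingAlignment, start_col: int, end_col: int) -> str:
    """Exon tag for a 1-based closed column interval, e.g. ``E5`` or ``E1-E3``."""
    e1 = aln.column_exon_map[start_col - 1]
    e2 = aln.column_exon_map[end_col - 1]
    return f"E{e1}" if e1 == e2 else f"E{e1}-E{e2}"


def indel_events(aln: CodingAlignment, taxon: str) -> list[dict]:
    """All maximal indel runs for ``taxon`` (frameshifting or not).

    Deletions are runs of columns where the taxon is gapped but the
    reference is not; insertions are runs of reference-gap columns where
    the taxon has sequence.  Each event dict carries 1-based ``start``/
    ``end`` columns, ``kind`` (I/D), ``length`` in affected bases, and
    ``frameshift``.
    """
    if taxon not in aln.rows:
        raise StructuralError(f"taxon {taxon!r} not in alignment {aln.gene_id}")
    seq = aln.rows[taxon]
    ins = aln.insertion_columns
    events = []
    current: Optional[dict] = None
    for col in range(aln.n_columns):
        ch = seq[col]
        if col in ins:
            kind = "I" if ch != "-" else None
        else:
            kind = "D" if ch == "-" else None
        if kind is None:
            current = None
            continue
        if current is not None and current["kind"] == kind and current["end"] == col:
            current["end"] = col + 1
            current["length"] += 1
        else:
            current = {"kind": kind, "start": col + 1, "end": col + 1, "length": 1}
            events.append(current)
    for ev in events:
        ev["frameshift"] = ev["length"] % 3 != 0
    return events


def detect_indels(aln: CodingAlignment, taxon: str) -> list[LesionRecord]:
    """Frameshifting insertion/deletion lesions for one taxon.

    Runs whose length is a multiple of 3 are in-frame and are not lesions
    (see :func:`indel_events` for the full run list).  A row that is gapped
    at every reference column yields a single whole-gene deletion record
    and a warning.
    """
    seq = aln.rows.get(taxon)
    if seq is None:
        raise StructuralError(f"taxon {taxon!r} not in alignment {aln.gene_id}")
    non_ins = aln.non_insertion_columns()
    if non_ins and all(seq[c] == "-" for c in non_ins):
        warnings.warn(
            f"{aln.gene_id}/{taxon}: row is all-gap; emitting a whole-gene deletion"
        )
        return [
            LesionRecord(
                taxon=taxon, gene=aln.gene_id, kind="D",
                start=1, end=aln.n_columns,
                feature_label=_exon_feature(aln, 1, aln.n_columns),
                frameshift=True,
            )
        ]
    records = []
    for ev in indel_events(aln, taxon):
        if not ev["frameshift"]:
            continue
        records.append(
            LesionRecord(
                taxon=taxon, gene=aln.gene_id, kind=ev["kind"],
                start=ev["start"], end=ev["end"],
                feature_label=_exon_feature(aln, ev["start"], ev["end"]),
                frameshift=True,
            )
        )
    return records


def mask_for_stop_scan(aln: CodingAlignment, taxon: str) -> str:
    """Exon sequence of ``taxon`` in the reference frame: insertion columns
    removed, deleted positions N-filled.  Output length equals the
    reference CDS length."""
    seq = aln.rows.get(taxon)
    if seq is None:
        raise StructuralError(f"taxon {taxon!r} not in alignment {aln.gene_id}")
    out = []
    for col in aln.non_insertion_columns():
        ch = seq[col]
        out.append("N" if ch == "-" else ch)
    return "".join(out)


def _codon_columns(aln: CodingAlignment, codon_index: int) -> tuple[int, int]:
    """1-based (start, end) alignment columns of 0-based masked codon."""
    non_ins = aln.non_insertion_columns()
    return non_ins[3 * codon_index] + 1, non_ins[3 * codon_index + 2] + 1


def detect_premature_stops(
    masked: str, aln: CodingAlignment, taxon: str,
    code: GeneticCode = STANDARD_CODE,
) -> list[LesionRecord]:
    """Premature stop codons in a masked (in-frame) sequence.

    Codons containing N are never called; the final codon is the canonical
    stop position and is handled by
    :func:`detect_terminal_codon_mutations`.  A stop within two codons of
    the canonical stop is recorded but flagged possibly tolerated.
    """
    if len(masked) % 3:
        raise StructuralError(
            f"masked sequence length {len(masked)} not divisible by 3 "
            f"(mask contract broken)"
        )
    n_codons = len(masked) // 3
    records = []
    for i in range(n_codons - 1):
        codon = masked[3 * i : 3 * i + 3].upper()
        if "N" in codon:
            continue
        if code.is_stop(codon):
            start, end = _codon_columns(aln, i)
            records.append(
                LesionRecord(
                    taxon=taxon, gene=aln.gene_id, kind="S", start=start, end=end,
                    feature_label=_exon_feature(aln, start, end),
                    possibly_tolerated=(i >= n_codons - 3),
                )
            )
    return records


def detect_terminal_codon_mutations(
    masked: str, aln: CodingAlignment, taxon: str,
    code: GeneticCode = STANDARD_CODE,
) -> list[LesionRecord]:
    """Start-codon (non-ATG first codon) and termination-codon (non-stop
    final codon) mutations; N-containing codons are not called."""
    if len(masked) % 3:
        raise StructuralError("masked sequence length not divisible by 3")
    records = []
    first = masked[:3].upper()
    if "N" not in first and first != "ATG":
        start, end = _codon_columns(aln, 0)
        records.append(
            LesionRecord(taxon=taxon, gene=aln.gene_id, kind="SCM",
                         start=start, end=end,
                         feature_label=_exon_feature(aln, start, end))
        )
    last = masked[-3:].upper()
    if "N" not in last and not code.is_stop(last):
        i = len(masked) // 3 - 1
        start, end = _codon_columns(aln, i)
        records.append(
            LesionRecord(taxon=taxon, gene=aln.gene_id, kind="TCM",
                         start=start, end=end,
                         feature_label=_exon_feature(aln, start, end))
        )
    return records


def check_splice_sites(gene_model: GeneModel, taxon: str) -> list[LesionRecord]:
    """Non-canonical splice-site dinucleotides (donor not GT/GC, acceptor
    not AG).  Dinucleotides containing N or gap are skipped."""
    sites = gene_model.intron_sites.get(taxon)
    if sites is None:
        raise StructuralError(
            f"{gene_model.gene_id}: no splice dinucleotides for {taxon!r}"
        )
    records = []
    for site in sites:
        donor = site.donor.upper()
        acceptor = site.acceptor.upper()
        if not (set(donor) & set("N-")) and donor not in CANONICAL_DONORS:
            records.append(
                LesionRecord(taxon=taxon, gene=gene_model.gene_id, kind="Do",
                             intron_index=site.intron_index,
                             feature_label=f"In{site.intron_index}", detail=donor)
            )
        if not (set(acceptor) & set("N-")) and acceptor != CANONICAL_ACCEPTOR:
            records.append(
                LesionRecord(taxon=taxon, gene=gene_model.gene_id, kind="Ac",
                             intron_index=site.intron_index,
                             feature_label=f"In{site.intron_index}", detail=acceptor)
            )
    return records


def detect_boundary_deletions(
    aln: CodingAlignment, gene_model: GeneModel, taxon: str,
    intron_deletion_flags: dict[tuple[int, str], int],
) -> list[LesionRecord]:
    """Deletion runs abutting an exon edge combined with a nonzero flanking
    intronic deletion extent.

    ``intron_deletion_flags`` maps ``(intron_index, side)`` with side
    ``"donor"`` (3' end of exon k / 5' of intron k) or ``"acceptor"``
    (3' end of intron k / 5' start of exon k+1) to the number of deleted
    intronic bases.  Matching runs of any length (frameshifting or not)
    become boundary-deletion (BD) records.
    """
    exon_first_col: dict[int, int] = {}
    exon_last_col: dict[int, int] = {}
    for col, exon in enumerate(aln.column_exon_map, start=1):
        exon_first_col.setdefault(exon, col)
        exon_last_col[exon] = col
    records = []
    for ev in indel_events(aln, taxon):
        if ev["kind"] != "D":
            continue
        start, end = ev["start"], ev["end"]
        start_exon = aln.column_exon_map[start - 1]
        end_exon = aln.column_exon_map[end - 1]
        # run begins at the first column of exon k+1 -> acceptor-side BD
        if start == exon_first_col.get(start_exon) and start_exon >= 2:
            k = start_exon - 1
            bp = intron_deletion_flags.get((k, "acceptor"), 0)
            if bp > 0:
                records.append(
                    LesionRecord(
                        taxon=taxon, gene=aln.gene_id, kind="BD",
                        start=start, end=end,
                        feature_label=f"In{k}E{start_exon}",
                        detail=f"last {bp} bp of In{k} and first {end - start + 1} "
                               f"bp ({start}-{end}) of E{start_exon}",
                    )
                )
                continue
        # run ends at the last column of exon k -> donor-side BD
        if end == exon_last_col.get(end_exon) and end_exon <= len(gene_model.exon_lengths) - 1:
            k = end_exon
            bp = intron_deletion_flags.get((k, "donor"), 0)
            if bp > 0:
                records.append(
                    LesionRecord(
                        taxon=taxon, gene=aln.gene_id, kind="BD",
                        start=start, end=end,
                        feature_label=f"E{end_exon}In{k}",
                        detail=f"last {end - start + 1} bp ({start}-{end}) of "
                               f"E{end_exon} and first {bp} bp of In{k}",
                    )
                )
    return records


def check_site_table(
    masked: str, sites: SiteTable, aln: CodingAlignment, taxon: str,
    code: GeneticCode = STANDARD_CODE,
) -> list[LesionRecord]:
    """Disruptions of annotated opsin functional sites.

    Deleted (N-filled) spectral-tuning codons give STSD records; residues
    outside the allowed set at chromophore-binding or Schiff-base
    counterion positions give CBSM/SBCM records.  Transmembrane entries
    are positional annotations without a lesion code and are not called.
    """
    protein = translate(masked, code)
    kind_by_role = {"chromophore_binding": "CBSM", "schiff_base_counterion": "SBCM"}
    records = []
    for entry in sites.entries:
        pos = entry.protein_position
        if pos > len(protein):
            raise StructuralError(
                f"site position {pos} beyond protein length {len(protein)}"
            )
        residue = protein[pos - 1]
        codon = masked[3 * (pos - 1) : 3 * pos].upper()
        start, end = _codon_columns(aln, pos - 1)
        if entry.role == "spectral_tuning":
            if "N" in codon:  # deleted (N-filled) tuning site
                records.append(
                    LesionRecord(taxon=taxon, gene=aln.gene_id, kind="STSD",
                                 start=start, end=end,
                                 feature_label=_exon_feature(aln, start, end))
                )
        elif entry.role in kind_by_role:
            if residue == "X":
                continue  # ambiguous codon: no call
            if residue not in entry.allowed_residues:
                records.append(
                    LesionRecord(taxon=taxon, gene=aln.gene_id,
                                 kind=kind_by_role[entry.role],
                                 start=start, end=end,
                                 feature_label=_exon_feature(aln, start, end))
                )
    return records


def format_lesion_label(rec: LesionRecord) -> str:
    """Deterministic label in the curated-table notation,
    e.g. ``1478–1575D (E13)``, ``412–414S (E5)``, ``In6Do (AT)``."""
    if rec.kind in ("Do", "Ac"):
        base = f"In{rec.intron_index}{rec.kind}"
        return f"{base} ({rec.detail})" if rec.detail else base
    if rec.kind == "BD":
        base = f"{rec.feature_label}BD"
        return f"{base} ({rec.detail})" if rec.detail else base
    if rec.kind == "INV":
        return f"{rec.feature_label}{rec.kind}"
    if rec.start is None:
        return rec.kind
    span = (str(rec.start) if rec.start == rec.end
            else f"{rec.start}–{rec.end}")
    suffix = f" ({rec.feature_label})" if rec.feature_label else ""
    return f"{span}{rec.kind}{suffix}"


def scan_gene(
    aln: CodingAlignment,
    gene_model: GeneModel,
    taxon: str,
    site_table: Optional[SiteTable] = None,
    intron_deletion_flags: Optional[dict[tuple[int, str], int]] = None,
    code: GeneticCode = STANDARD_CODE,
) -> list[LesionRecord]:
    """Run the full scanner for one taxon and gene.

    Deletion runs upgraded to boundary deletions replace the plain D
    records with the same interval.
    """
    records = detect_indels(aln, taxon)
    if intron_deletion_flags:
        bd = detect_boundary_deletions(aln, gene_model, taxon, intron_deletion_flags)
        bd_intervals = {(r.start, r.end) for r in bd}
        records = [r for r in records
                   if not (r.kind == "D" and (r.start, r.end) in bd_intervals)]
        records.extend(bd)
    masked = mask_for_stop_scan(aln, taxon)
    records.extend(detect_premature_stops(masked, aln, taxon, code))
    records.extend(detect_terminal_codon_mutations(masked, aln, taxon, code))
    if taxon in gene_model.intron_sites:
        records.extend(check_splice_sites(gene_model, taxon))
    if site_table is not None:
        records.extend(check_site_table(masked, site_table, aln, taxon, code))
    return records


# ---------------------------------------------------------------------------
# tallies over curated lesion tables


def classify_gene_status(table: LesionTable, gene: str,
                         pair: tuple[str, str]) -> str:
    """``intact_both`` / ``lesioned_one`` / ``lesioned_both`` for a pair of
    taxa or individuals; shared records count for both members."""
    lesioned = set()
    for rec in table.eye_specific_records():
        if rec.gene == gene and rec.taxon in pair:
            lesioned.add(rec.taxon)
    if len(lesioned) == 2:
        return "lesioned_both"
    if len(lesioned) == 1:
        return "lesioned_one"
    return "intact_both"


def tally_lesions(
    table: LesionTable, taxon_or_individual: str,
    groups: Optional[set[str]] = None,
) -> tuple[int, dict[str, int]]:
    """Per-entry inactivating-mutation tally for one taxon or individual.

    Counts one per applicable record; pleiotropic genes are excluded.
    Returns the total and a per-gene breakdown.
    """
    per_gene: dict[str, int] = {}
    for rec in table.eye_specific_records():
        if rec.taxon != taxon_or_individual:
            continue
        if groups is not None and table.group_map[rec.gene] not in groups:
            continue
        per_gene[rec.gene] = per_gene.get(rec.gene, 0) + 1
    return sum(per_gene.values()), per_gene


def tally_inactivated_genes(
    table: LesionTable, taxon_or_individual: str, group: str,
) -> int:
    """Number of non-pleiotropic genes in ``group`` with at least one
    applicable record."""
    _, per_gene = tally_lesions(table, taxon_or_individual, {group})
    return len(per_gene)
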