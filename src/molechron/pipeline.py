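"""End-to-end orchestration: scan -> fit (eight combinations) -> date -> map.

The central entry point for dating is :func:`date_gene_group`, which fits
the branch-category codon model under both codon-frequency conventions and
both pseudogenic-omega modes (estimated / fixed at 1.0), then applies the
one- and two-synonymous-rate mixed-branch equations and averages the eight
resulting dates.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .codon_model import (
    CodonAlignment,
    SelectionFit,
    category_synonymous_rate,
    fit_branch_model,
)
from .dating import (
    DatingInputs,
    InactivationEstimate,
    average_combinations,
)
from .genetic_code import STANDARD_CODE
from .lesions import tally_inactivated_genes, tally_lesions
from .models import (
    BACKGROUND,
    LabeledTimeTree,
    StructuralError,
)
from .parsimony import deltran_assign


def concat_genes(alignments: list[CodonAlignment],
                 taxa: Optional[list[str]] = None
                 ) -> tuple[CodonAlignment, list[tuple[str, int, int]]]:
    """Column-wise concatenation of codon alignments in the given order.

    Taxa missing from a gene are padded with fully ambiguous codons.
    Returns the concatenation and per-gene partitions as (name, start,
    end) 1-based codon intervals.
    """
    if not alignments:
        raise StructuralError("nothing to concatenate")
    if taxa is None:
        taxa = []
        for aln in alignments:
            for t in aln.taxa:
                if t not in taxa:
                    taxa.append(t)
    partitions = []
    rows: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for i, aln in enumerate(alignments):
        n = aln.n_codons
        partitions.append((f"gene_{i + 1}", pos + 1, pos + n))
        for t in taxa:
            rows[t].extend(aln.codons.get(t, ["NNN"] * n))
        pos += n
    return CodonAlignment(rows, alignments[0].code), partitions


def codon_alignment_from_fasta(path) -> CodonAlignment:
    """Read an in-frame FASTA into a codon alignment (stops become NNN)."""
    from Bio import SeqIO

    code = STANDARD_CODE
    codons = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if len(seq) % 3:
            raise StructuralError(f"{rec.id}: length {len(seq)} not in frame")
        row = [seq[i:i + 3] for i in range(0, len(seq), 3)]
        codons[rec.id] = ["NNN" if code.is_stop(c) else c for c in row]
    return CodonAlignment(codons, code)


@dataclass
class GroupDating:
    estimate: InactivationEstimate
    fits: dict[tuple[str, str], SelectionFit]  # (freq_model, mode) -> fit

    def report(self) -> dict:
        return {
            "mean_T_i_mya": self.estimate.mean_T_i,
            "combos": [
                {
                    "freq_model": c.freq_model,
                    "omega_p_mode": c.omega_p_mode,
                    "equation": c.equation,
                    "t_p_my": c.t_p,
                    "T_i_mya": c.T_i,
                    "clamped": c.clamped,
                    "omega_f": c.inputs.omega_f,
                    "omega_t": c.inputs.omega_t,
                    "omega_p": c.inputs.omega_p,
                }
                for c in self.estimate.combos
            ],
            "fits": {
                f"{fm}_{mode}": {
                    "lnL": fit.lnL,
                    "kappa": fit.kappa_hat,
                    "omega": fit.omega_hat,
                    "converged": fit.converged,
                }
                for (fm, mode), fit in self.fits.items()
            },
        }


def date_gene_group(
    tree: LabeledTimeTree,
    aln: CodonAlignment,
    transitional_k: int = 1,
    omega_starts: tuple[float, ...] = (0.1, 0.5, 1.0),
    max_iter: int = 500,
) -> GroupDating:
    """Eight-combination inactivation dating for one gene-group alignment.

    Requires node ages on the tree (for branch durations and the
    transitional branch's age interval).
    """
    trans = tree.transitional_branch(transitional_k)
    T_upper = trans.parent_node.age_my
    T_lower = trans.age_my
    if T_upper is None or T_lower is None:
        raise StructuralError("transitional branch endpoints need ages")
    t_cat = f"transitional:{transitional_k}"
    p_cat = f"pseudogenic:{transitional_k}"
    fits: dict[tuple[str, str], SelectionFit] = {}
    per_combo = []
    for fm in ("CF1", "CF2"):
        for mode in ("estimated", "fixed"):
            fit = fit_branch_model(
                tree, aln, fm,
                fix_pseudogenic_omega=1.0 if mode == "fixed" else None,
                omega_starts=omega_starts, max_iter=max_iter,
            )
            fits[(fm, mode)] = fit
            omega_f = fit.omega_hat[BACKGROUND]
            omega_t = fit.omega_hat[t_cat]
            omega_p = fit.omega_hat[p_cat]
            s_f = category_synonymous_rate(fit, tree, BACKGROUND)
            s_p = category_synonymous_rate(fit, tree, p_cat)
            for eq in ("one_rate", "two_rate"):
                per_combo.append(
                    ((fm, mode, eq),
                     DatingInputs(T_upper=T_upper, T_lower=T_lower,
                                  omega_f=omega_f, omega_t=omega_t,
                                  omega_p=omega_p, equation=eq,
                                  s_f=s_f, s_p=s_p))
                )
    return GroupDating(estimate=average_combinations(per_combo), fits=fits)


# ---------------------------------------------------------------------------
# full pipeline run


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    lesion_table: Optional[str] = None
    gene_groups: Optional[str] = None
    pairs: Optional[dict] = None
    alignments: Optional[dict] = None  # group name -> in-frame FASTA
    tree: Optional[str] = None
    ages: Optional[str] = None
    characters: Optional[str] = None   # lesion presence/absence TSV
    tally_taxa: Optional[list] = None
    omega_starts: tuple = (0.1, 0.5, 1.0)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["omega_starts"] = tuple(raw.get("omega_starts", (0.1, 0.5, 1.0)))
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage the configuration enables and write a report bundle.

    Outputs under ``output_dir``: ``lesions.tsv`` and ``tallies.json`` when
    a lesion fixture is given, ``dating.json`` with the eight-combination
    grid per gene group when alignments and a dated tree are given,
    ``deltran_map.tsv`` when characters are given, and ``run_log.json``.
    """
    from . import __version__
    from .io import (
        read_gene_groups,
        read_labeled_tree,
        read_lesion_table,
        write_lesion_table,
    )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    if config.lesion_table:
        if not config.gene_groups:
            raise StructuralError("lesion_table requires gene_groups")
        group_map, pleio = read_gene_groups(config.gene_groups)
        pairs = {k: tuple(v) for k, v in (config.pairs or {}).items()}
        table = read_lesion_table(config.lesion_table, group_map, pleio, pairs)
        write_lesion_table(table, out / "lesions.tsv")
        taxa = config.tally_taxa or sorted({r.taxon for r in table.records})
        tallies = {}
        for taxon in taxa:
            total, per_gene = tally_lesions(table, taxon)
            tallies[taxon] = {
                "total": total,
                "per_gene": per_gene,
                "inactivated_genes_per_group": {
                    g: tally_inactivated_genes(table, taxon, g)
                    for g in sorted(set(group_map.values()))
                },
            }
        (out / "tallies.json").write_text(json.dumps(tallies, indent=1))
        report["tallies"] = tallies

    tree = None
    if config.tree:
        tree = read_labeled_tree(config.tree, config.ages)

    if config.alignments:
        if tree is None:
            raise StructuralError("dating requires a tree")
        dating = {}
        for group, fasta in sorted(config.alignments.items()):
            aln = codon_alignment_from_fasta(fasta)
            result = date_gene_group(
                tree, aln, omega_starts=config.omega_starts
            )
            dating[group] = result.report()
        (out / "dating.json").write_text(json.dumps(dating, indent=1))
        report["dating"] = dating

    if config.characters:
        if tree is None:
            raise StructuralError("character mapping requires a tree")
        import csv as _csv

        by_lesion: dict[str, dict] = {}
        with open(config.characters, newline="") as fh:
            for r in _csv.DictReader(fh, delimiter="\t"):
                by_lesion.setdefault(r["lesion"], {})[r["tip"]] = r["state"]
        with open(out / "deltran_map.tsv", "w", newline="") as fh:
            writer = _csv.writer(fh, delimiter="\t")
            writer.writerow(["lesion", "branch_tips", "from", "to"])
            for lesion, states in sorted(by_lesion.items()):
                result = deltran_assign(tree, states)
                for tips, a, b in result["changes"]:
                    writer.writerow([lesion, ",".join(sorted(tips)), a, b])
        report["characters_mapped"] = len(by_lesion)

    log = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "stages": sorted(k for k in report if k != "seed"),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return report
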