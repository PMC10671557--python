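"""Synthetic-data generation with known ground truth.

Two generators cover the pipeline's inputs:

* :func:`simulate_codon_alignment` evolves codon sequences along a dated
  tree under the GY94 model with branch-category omegas and an optional
  functional-to-neutral switch at a known date on a designated branch.
  All category generators share the *neutral* flux scaling, so the
  synonymous rate is clock-like across regimes and the switch date is
  identified by the excess nonsynonymous rate alone.

* :func:`inject_lesions` plants frameshift indels, premature stops,
  start/stop-codon mutations, splice-site changes, and boundary deletions
  at random legal positions in a gene alignment, emitting a machine-
  readable truth table in the same record format the scanner produces.

Defaults define the study conditions used throughout the package's tests:
kappa = 3, background omega = 0.15, pseudogenic omega = 1.0, 300 codons,
and a neutral rate of 0.006 substitutions/codon/MY (about 2 x 10^-3 per
site per MY, a typical mammalian neutral rate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .codon_model import CodonAlignment, CodonModelSpec, neutral_scaled_rate_matrix, _EigenP
from .genetic_code import STANDARD_CODE, GeneticCode
from .models import (
    BACKGROUND,
    CodingAlignment,
    GeneModel,
    IntronSites,
    LabeledTimeTree,
    LesionRecord,
    StructuralError,
)

#: default nucleotide composition (slightly AT-rich, mammal-like)
DEFAULT_BASE_FREQS = {"A": 0.30, "C": 0.21, "G": 0.21, "T": 0.28}

DEFAULT_KAPPA = 3.0
DEFAULT_OMEGA_BACKGROUND = 0.15
DEFAULT_OMEGA_PSEUDOGENIC = 1.0
DEFAULT_N_CODONS = 300
#: neutral substitutions per codon per MY
DEFAULT_NEUTRAL_RATE = 0.006


def f1x4_pi(base_freqs: dict[str, float],
            code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    pi = np.array(
        [
            base_freqs[c[0]] * base_freqs[c[1]] * base_freqs[c[2]]
            for c in code.sense_codons
        ]
    )
    return pi / pi.sum()


@dataclass
class SimulationConfig:
    tree: LabeledTimeTree
    seed: int
    kappa: float = DEFAULT_KAPPA
    pi: Optional[np.ndarray] = None
    omega_background: float = DEFAULT_OMEGA_BACKGROUND
    omega_pseudogenic: float = DEFAULT_OMEGA_PSEUDOGENIC
    switch_tips: Optional[frozenset] = None  # identifies the switch branch
    switch_time: Optional[float] = None      # MYA; the true T_i
    n_codons: int = DEFAULT_N_CODONS
    neutral_rate: float = DEFAULT_NEUTRAL_RATE

    def __post_init__(self) -> None:
        if self.seed is None:
            raise StructuralError("seed is mandatory")
        if self.n_codons < 1:
            raise StructuralError("n_codons must be >= 1")
        if self.pi is None:
            self.pi = f1x4_pi(DEFAULT_BASE_FREQS)


@dataclass
class SimulationTruth:
    config: dict
    per_branch_omega: list
    true_T_i: Optional[float]
    lesions: list[LesionRecord] = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            if isinstance(o, LesionRecord):
                return o.__dict__
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(
            {
                "config": self.config,
                "per_branch_omega": self.per_branch_omega,
                "true_T_i": self.true_T_i,
                "lesions": [r.__dict__ for r in self.lesions],
            },
            default=default, indent=1, sort_keys=True,
        )


def _category_omega(category: str, config: SimulationConfig) -> float:
    if category == BACKGROUND:
        return config.omega_background
    if category.startswith("pseudogenic:"):
        return config.omega_pseudogenic
    if category.startswith("transitional:"):
        # a transitional branch without an explicit switch evolves
        # functionally (the switch machinery overrides this)
        return config.omega_background
    raise StructuralError(f"unknown category {category!r}")


def _sample_children(P: np.ndarray, parents: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    rows = P[parents]
    cum = np.cumsum(rows, axis=1)
    cum /= cum[:, -1:]
    u = rng.random((len(parents), 1))
    return (cum > u).argmax(axis=1)


def simulate_codon_alignment(
    config: SimulationConfig,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment along the dated tree.

    The switch branch (identified by the tip set of its child node;
    defaults to the ``transitional:1`` branch when a switch time is given)
    evolves under the background omega from its origin down to
    ``switch_time`` MYA and neutrally (pseudogenic omega) from there to its
    child node.  Deterministic for a fixed seed.
    """
    code = STANDARD_CODE
    rng = np.random.default_rng(config.seed)
    pi = np.asarray(config.pi, dtype=float)
    spec = CodonModelSpec(pi=pi, kappa=config.kappa,
                          omega_by_category={BACKGROUND: 1.0})

    eigens: dict[float, _EigenP] = {}

    def P_of(omega: float, duration_my: float) -> np.ndarray:
        ep = eigens.get(omega)
        if ep is None:
            ep = eigens[omega] = _EigenP(
                neutral_scaled_rate_matrix(spec, omega), pi
            )
        return ep.P(config.neutral_rate * duration_my)

    tree = config.tree
    switch_node = None
    if config.switch_time is not None:
        if config.switch_tips is not None:
            switch_node = _node_by_tipset(tree, config.switch_tips)
        else:
            switch_node = tree.transitional_branch(1)
        upper = switch_node.parent_node.age_my
        lower = switch_node.age_my
        if upper is None or lower is None:
            raise StructuralError("switch branch endpoints need ages")
        if not lower <= config.switch_time <= upper:
            raise StructuralError(
                f"switch_time {config.switch_time} outside branch interval "
                f"[{lower}, {upper}]"
            )

    states: dict[int, np.ndarray] = {}
    root = tree.tree.seed_node
    states[id(root)] = rng.choice(len(pi), size=config.n_codons, p=pi)
    per_branch_omega = []
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        duration = tree.branch_duration_my(node)
        parent_states = states[id(node.parent_node)]
        if switch_node is not None and node is switch_node:
            t_functional = node.parent_node.age_my - config.switch_time
            t_pseudo = config.switch_time - node.age_my
            mid = parent_states
            if t_functional > 0:
                mid = _sample_children(
                    P_of(config.omega_background, t_functional), mid, rng
                )
            if t_pseudo > 0:
                mid = _sample_children(
                    P_of(config.omega_pseudogenic, t_pseudo), mid, rng
                )
            states[id(node)] = mid
            per_branch_omega.append(
                [sorted(_tips(node)), "switch", config.switch_time]
            )
            continue
        omega = _category_omega(node.category, config)
        if duration > 0:
            states[id(node)] = _sample_children(
                P_of(omega, duration), parent_states, rng
            )
        else:
            states[id(node)] = parent_states.copy()
        per_branch_omega.append([sorted(_tips(node)), omega, None])

    codons = {}
    for leaf in tree.tree.leaf_node_iter():
        labels = [code.sense_codons[s] for s in states[id(leaf)]]
        codons[tree.tip_label(leaf)] = labels
    truth = SimulationTruth(
        config={
            "seed": config.seed, "kappa": config.kappa,
            "omega_background": config.omega_background,
            "omega_pseudogenic": config.omega_pseudogenic,
            "n_codons": config.n_codons, "neutral_rate": config.neutral_rate,
            "switch_time": config.switch_time,
        },
        per_branch_omega=per_branch_omega,
        true_T_i=config.switch_time,
    )
    return CodonAlignment(codons, code), truth


def _tips(node) -> frozenset:
    return frozenset(
        leaf.taxon.label if leaf.taxon else leaf.label
        for leaf in node.leaf_iter()
    )


def _node_by_tipset(tree: LabeledTimeTree, tips: frozenset):
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is not None and _tips(node) == frozenset(tips):
            return node
    raise StructuralError(f"no branch with tip set {sorted(tips)}")


def default_study_tree() -> LabeledTimeTree:
    """The 10-taxon dated tree used for end-to-end recovery studies.

    A pair of 'mole' tips (M1, M2) forms a pseudogenic crown clade of age
    12.04 MY whose stem (the transitional branch) descends from a node of
    age 68.21 MY — the golden-mole / tenrec calibration pair — embedded
    among eight background outgroups.
    """
    newick = ("(G:0.0,(F:0.0,(E:0.0,((M1#P1:0.0,M2#P1:0.0)#T1:0.0,"
              "(D:0.0,(C:0.0,(B:0.0,(A:0.0,H:0.0):0.0):0.0):0.0):0.0):0.0)"
              ":0.0):0.0);")
    from .io import read_labeled_tree

    ltt = read_labeled_tree(newick)
    age_by_tips = {
        frozenset({"G", "F", "E", "D", "C", "B", "A", "H", "M1", "M2"}): 80.0,
        frozenset({"F", "E", "D", "C", "B", "A", "H", "M1", "M2"}): 76.0,
        frozenset({"E", "D", "C", "B", "A", "H", "M1", "M2"}): 72.0,
        frozenset({"D", "C", "B", "A", "H", "M1", "M2"}): 68.21,
        frozenset({"M1", "M2"}): 12.04,
        frozenset({"D", "C", "B", "A", "H"}): 60.0,
        frozenset({"C", "B", "A", "H"}): 50.0,
        frozenset({"B", "A", "H"}): 40.0,
        frozenset({"A", "H"}): 30.0,
    }
    for node in ltt.tree.preorder_node_iter():
        tips = _tips(node)
        if len(tips) == 1:
            node.age_my = 0.0
        else:
            node.age_my = age_by_tips[tips]
        node.edge.length = None
    ltt.validate()
    return ltt


DEFAULT_TRUE_T_I = 26.03


def make_case_study(
    out_dir,
    seed: int,
    true_T_i: float = DEFAULT_TRUE_T_I,
    n_codons: int = DEFAULT_N_CODONS,
    gene_groups: tuple[str, ...] = ("lens_cornea",),
):
    """Write a complete, directly consumable synthetic bundle.

    For each requested gene group the bundle contains a FASTA codon
    alignment evolved on :func:`default_study_tree` with the
    functional-to-neutral switch at ``true_T_i`` MYA on the transitional
    branch, plus the labeled newick tree, a node-age TSV, and a truth JSON.
    Byte-identical for a fixed seed.
    """
    from pathlib import Path

    from .io import write_labeled_tree

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = default_study_tree()
    truth_all = {}
    for g, group in enumerate(gene_groups):
        config = SimulationConfig(
            tree=tree, seed=seed + 7919 * g, switch_time=true_T_i,
            n_codons=n_codons,
        )
        aln, truth = simulate_codon_alignment(config)
        fasta = out / f"{group}.fasta"
        with open(fasta, "w") as fh:
            for taxon, seq in aln.to_sequences().items():
                fh.write(f">{taxon}\n{seq}\n")
        truth_all[group] = json.loads(truth.to_json())
    write_labeled_tree(tree, out / "tree.nwk", out / "node_ages.tsv")
    (out / "truth.json").write_text(
        json.dumps(truth_all, indent=1, sort_keys=True)
    )
    return out


# ---------------------------------------------------------------------------
# gene alignments with injected lesions


def simulate_gene_alignment(
    gene_model: GeneModel,
    taxa: list[str],
    seed: int,
    substitution_prob: float = 0.02,
    code: GeneticCode = STANDARD_CODE,
) -> CodingAlignment:
    """A clean (lesion-free) gene alignment for the injector.

    The reference CDS is ATG + random sense codons + a stop codon; other
    taxa differ by random sense-to-sense codon substitutions, so the
    scanner finds nothing before injection.  Canonical splice
    dinucleotides (GT/AG) are installed for every taxon.
    """
    rng = np.random.default_rng(seed)
    n_codons = gene_model.cds_length // 3
    if gene_model.cds_length % 3 or n_codons < 4:
        raise StructuralError("gene model CDS must be a multiple of 3, >= 12 bp")
    sense = [c for c in code.sense_codons]
    body = rng.choice(len(sense), size=n_codons - 2)
    stop = code.stop_codons[int(rng.integers(len(code.stop_codons)))]
    ref_codons = ["ATG"] + [sense[i] for i in body] + [stop]
    rows = {}
    for k, taxon in enumerate(taxa):
        codons = list(ref_codons)
        if k > 0 and substitution_prob > 0:
            hits = np.nonzero(rng.random(n_codons - 2) < substitution_prob)[0]
            for h in hits:
                codons[1 + h] = sense[int(rng.integers(len(sense)))]
        rows[taxon] = "".join(codons)
    n_introns = len(gene_model.exon_lengths) - 1
    gene_model.intron_sites = {
        taxon: [IntronSites(k + 1, "GT", "AG") for k in range(n_introns)]
        for taxon in taxa
    }
    return CodingAlignment.from_rows(
        gene_model.gene_id, rows, taxa[0], gene_model
    )


_NONCANONICAL_DONORS = ("AT", "CT", "GA", "TT", "AG", "GG")
_NONCANONICAL_ACCEPTORS = ("GG", "AA", "CG", "TG", "AC", "GA")
_FRAMESHIFT_LENGTHS = (1, 2, 4, 5)


def inject_lesions(
    aln: CodingAlignment,
    gene_model: GeneModel,
    taxon: str,
    lesion_spec: list[tuple[str, int]],
    seed: int,
    code: GeneticCode = STANDARD_CODE,
):
    """Inject the requested lesions at random legal positions.

    ``lesion_spec`` lists (kind, count) pairs over kinds D, I, S, SCM, TCM,
    Do, Ac, BD.  Lesions never overlap (a one-codon buffer separates
    interval lesions).  Returns ``(alignment, gene_model, truth_records,
    intron_deletion_flags)``; truth records carry the exact coordinates,
    kinds, and feature labels the scanner reports.
    """
    rng = np.random.default_rng(seed)
    if taxon not in aln.rows:
        raise StructuralError(f"taxon {taxon!r} not in alignment")
    if aln.insertion_columns:
        raise StructuralError("injector expects an insertion-free base alignment")
    if taxon == aln.reference_taxon:
        raise StructuralError(
            "cannot inject into the reference taxon (it defines the frame)"
        )
    seq = list(aln.rows[taxon])
    n_cols = aln.n_columns
    n_codons = n_cols // 3
    exon_ends = []
    cum = 0
    for L in gene_model.exon_lengths:
        cum += L
        exon_ends.append(cum)  # 1-based last column of each exon
    exon_starts = [1] + [e + 1 for e in exon_ends[:-1]]

    # codon indices (0-based) available for interval lesions: keep the
    # start codon, the final stop, and a trailing sense codon untouched
    used = np.zeros(n_codons, dtype=bool)
    used[0] = used[-1] = True
    used[max(0, n_codons - 4):] = True

    def reserve(c0: int, c1: int) -> bool:
        lo, hi = max(0, c0 - 1), min(n_codons, c1 + 2)
        if used[lo:hi].any():
            return False
        used[lo:hi] = True
        return True

    order = {"BD": 0, "D": 1, "I": 2, "S": 3, "SCM": 4, "TCM": 5, "Do": 6, "Ac": 7}
    requests = []
    for kind, count in lesion_spec:
        if kind not in order:
            raise StructuralError(f"injector does not support kind {kind!r}")
        requests.extend([kind] * count)
    requests.sort(key=order.__getitem__)

    truth: list[dict] = []
    insertions: list[tuple[int, int]] = []  # (after 1-based column, length)
    flags: dict[tuple[int, str], int] = {}
    splice_used: set[int] = set()
    n_introns = len(gene_model.exon_lengths) - 1

    for kind in requests:
        placed = False
        for _ in range(200):
            if kind == "D":
                L = int(rng.choice(_FRAMESHIFT_LENGTHS))
                c0 = int(rng.integers(1, n_codons - 1))
                start = 3 * c0 + 1 + int(rng.integers(0, 3))
                end = start + L - 1
                if end > n_cols:
                    continue
                c1 = (end - 1) // 3
                # stay inside one exon and off its edges so a plain D can
                # never masquerade as a boundary deletion
                exon = aln.column_exon_map[start - 1]
                if (aln.column_exon_map[end - 1] != exon
                        or start <= exon_starts[exon - 1]
                        or end >= exon_ends[exon - 1]):
                    continue
                if not reserve(c0, c1):
                    continue
                for col in range(start, end + 1):
                    seq[col - 1] = "-"
                truth.append({"kind": "D", "start": start, "end": end})
                placed = True
            elif kind == "I":
                L = int(rng.choice(_FRAMESHIFT_LENGTHS))
                c0 = int(rng.integers(1, n_codons - 1))
                after = 3 * c0 + 1 + int(rng.integers(0, 2))  # inside codon
                exon = aln.column_exon_map[after - 1]
                if after >= exon_ends[exon - 1]:
                    continue
                if not reserve(c0, c0):
                    continue
                insertions.append((after, L))
                truth.append({"kind": "I", "after": after, "length": L})
                placed = True
            elif kind == "S":
                c0 = int(rng.integers(1, n_codons - 1))
                if not reserve(c0, c0):
                    continue
                stop = code.stop_codons[int(rng.integers(len(code.stop_codons)))]
                seq[3 * c0 : 3 * c0 + 3] = list(stop)
                truth.append({"kind": "S", "start": 3 * c0 + 1, "end": 3 * c0 + 3})
                placed = True
            elif kind == "SCM":
                if used[0] and any(t["kind"] == "SCM" for t in truth):
                    break
                seq[0:3] = list("GTG")
                truth.append({"kind": "SCM", "start": 1, "end": 3})
                placed = True
            elif kind == "TCM":
                if any(t["kind"] == "TCM" for t in truth):
                    break
                sense = code.sense_codons
                seq[n_cols - 3 : n_cols] = list(
                    sense[int(rng.integers(len(sense)))]
                )
                truth.append({"kind": "TCM", "start": n_cols - 2, "end": n_cols})
                placed = True
            elif kind in ("Do", "Ac"):
                if n_introns == 0:
                    raise StructuralError("gene model has no introns")
                k = int(rng.integers(1, n_introns + 1))
                if k in splice_used:
                    continue
                splice_used.add(k)
                site = gene_model.intron_sites[taxon][k - 1]
                if kind == "Do":
                    site.donor = str(rng.choice(_NONCANONICAL_DONORS))
                    detail = site.donor
                else:
                    site.acceptor = str(rng.choice(_NONCANONICAL_ACCEPTORS))
                    detail = site.acceptor
                truth.append({"kind": kind, "intron_index": k, "detail": detail})
                placed = True
            elif kind == "BD":
                if n_introns == 0:
                    raise StructuralError("gene model has no introns")
                k = int(rng.integers(1, n_introns + 1))
                side = "acceptor" if rng.random() < 0.5 else "donor"
                if (k, side) in flags:
                    continue
                L = int(rng.integers(3, 9))
                if side == "acceptor":
                    start = exon_starts[k]  # first column of exon k+1
                    end = start + L - 1
                    if end >= exon_ends[k]:
                        continue
                else:
                    end = exon_ends[k - 1]  # last column of exon k
                    start = end - L + 1
                    if start <= exon_starts[k - 1]:
                        continue
                c0, c1 = (start - 1) // 3, (end - 1) // 3
                if not reserve(c0, c1):
                    continue
                bp = int(rng.integers(5, 60))
                flags[(k, side)] = bp
                for col in range(start, end + 1):
                    seq[col - 1] = "-"
                feature = (f"In{k}E{k + 1}" if side == "acceptor"
                           else f"E{k}In{k}")
                truth.append({"kind": "BD", "start": start, "end": end,
                              "feature": feature, "side": side, "intron": k})
                placed = True
            if placed:
                break
        if not placed:
            raise StructuralError(
                f"could not place a {kind} lesion (gene too small or too "
                f"many lesions requested)"
            )

    # apply insertions right-to-left, building the final rows
    rows = {t: list(s) for t, s in aln.rows.items()}
    rows[taxon] = seq
    sense = code.sense_codons
    for after, L in sorted(insertions, reverse=True):
        block = [
            "ACGT"[int(b)] for b in rng.integers(0, 4, size=L)
        ]
        for t in rows:
            filler = block if t == taxon else ["-"] * L
            rows[t] = rows[t][:after] + filler + rows[t][after:]

    def shift(col: int) -> int:
        return col + sum(L for after, L in insertions if after < col)

    final_rows = {t: "".join(s) for t, s in rows.items()}
    final_aln = CodingAlignment.from_rows(
        aln.gene_id, final_rows, aln.reference_taxon, gene_model
    )

    from .lesions import _exon_feature  # shared feature-tag formatting

    records = []
    for t in truth:
        kind = t["kind"]
        if kind in ("Do", "Ac"):
            records.append(
                LesionRecord(taxon=taxon, gene=aln.gene_id, kind=kind,
                             intron_index=t["intron_index"],
                             feature_label=f"In{t['intron_index']}",
                             detail=t["detail"])
            )
            continue
        if kind == "I":
            start = shift(t["after"]) + 1
            end = start + t["length"] - 1
        else:
            start, end = shift(t["start"]), shift(t["end"])
        feature = (t["feature"] if kind == "BD"
                   else _exon_feature(final_aln, start, end))
        records.append(
            LesionRecord(
                taxon=taxon, gene=aln.gene_id, kind=kind, start=start, end=end,
                feature_label=feature,
                frameshift=(kind in ("I", "D") and (end - start + 1) % 3 != 0),
            )
        )
    return final_aln, gene_model, records, flags
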