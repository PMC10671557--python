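"""Branch-category dN/dS estimation under a reversible 61-state codon model.

The substitution model is the Goldman-Yang-style codon model: instantaneous
rates between codons differing at a single position are

    q(i -> j) = pi_j * kappa^[transition] * omega^[nonsynonymous],

zero for multi-position changes, with the generator rescaled so branch
lengths are expected substitutions per codon.  Codon frequencies come from
observed nucleotide composition, either pooled over codon positions (CF1,
the F1X4 convention) or position-specific (CF2, F3X4).  Each branch of the
input tree carries a selection category (background / transitional /
pseudogenic) and every category has its own omega, optionally held fixed.

Likelihoods are computed by Felsenstein pruning with site-pattern
compression; codons containing N or gap are partial ambiguities (sums over
compatible states).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .genetic_code import STANDARD_CODE, GeneticCode, is_transition
from .models import BACKGROUND, CodingAlignment, LabeledTimeTree, StructuralError

# ---------------------------------------------------------------------------
# codon alignments for selection analyses


@dataclass
class CodonAlignment:
    """In-frame multi-taxon codon alignment (insertion columns removed,
    stops masked)."""

    codons: dict[str, list[str]]
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    def __post_init__(self) -> None:
        lengths = {len(c) for c in self.codons.values()}
        if len(lengths) != 1:
            raise StructuralError(f"unequal codon-sequence lengths {lengths}")

    @property
    def taxa(self) -> list[str]:
        return list(self.codons)

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.codons.values())))

    def to_sequences(self) -> dict[str, str]:
        return {t: "".join(c) for t, c in self.codons.items()}


def prepare_paml_alignment(
    aln: CodingAlignment, code: GeneticCode = STANDARD_CODE
) -> CodonAlignment:
    """Strip insertion columns from every row and replace stop codons with
    NNN, leaving an in-frame alignment in the reference reading frame."""
    keep = aln.non_insertion_columns()
    if len(keep) % 3:
        raise StructuralError(
            f"{aln.gene_id}: reference CDS length {len(keep)} not divisible by 3"
        )
    codons: dict[str, list[str]] = {}
    for taxon, seq in aln.rows.items():
        stripped = "".join(seq[c] for c in keep).upper()
        row = []
        for i in range(0, len(stripped), 3):
            codon = stripped[i : i + 3]
            row.append("NNN" if code.is_stop(codon) else codon)
        codons[taxon] = row
    return CodonAlignment(codons, code)


def estimate_frequencies(
    aln: CodonAlignment, model: str = "CF1"
) -> np.ndarray:
    """Equilibrium sense-codon frequencies from observed composition.

    CF1 pools nucleotide counts over all codon positions (F1X4); CF2 keeps
    per-position counts (F3X4).  N and gap symbols are excluded.
    """
    if model not in ("CF1", "CF2"):
        raise ValueError(f"unknown frequency model {model!r}")
    counts = np.zeros((3, 4))
    index = {n: i for i, n in enumerate("ACGT")}
    for row in aln.codons.values():
        for codon in row:
            for k, ch in enumerate(codon):
                i = index.get(ch)
                if i is not None:
                    counts[k, i] += 1
    if counts.sum() == 0:
        raise StructuralError("empty alignment: no unambiguous nucleotides")
    if model == "CF1":
        pooled = counts.sum(axis=0)
        freqs = np.tile(pooled / pooled.sum(), (3, 1))
    else:
        totals = counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise StructuralError("a codon position has no unambiguous bases")
        freqs = counts / totals
    code = aln.code
    pi = np.array(
        [
            freqs[0, index[c[0]]] * freqs[1, index[c[1]]] * freqs[2, index[c[2]]]
            for c in code.sense_codons
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise StructuralError("degenerate codon frequencies")
    return pi / total


# ---------------------------------------------------------------------------
# rate matrix


def _pair_structure(code: GeneticCode):
    """Arrays (i, j, transition?, nonsynonymous?) over single-step codon
    pairs; cached per genetic code."""
    cache = _pair_structure.__dict__.setdefault("cache", {})
    if code.table_id in cache:
        return cache[code.table_id]
    ii, jj, ts, ns = [], [], [], []
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(*diffs[0]))
            ns.append(code.amino_acid[i] != code.amino_acid[j])
    out = (np.array(ii), np.array(jj), np.array(ts), np.array(ns))
    cache[code.table_id] = out
    return out


@dataclass
class CodonModelSpec:
    """Parameter bundle for the codon substitution model."""

    pi: np.ndarray
    kappa: float
    omega_by_category: dict[str, float]
    freq_model: str = "CF1"
    fixed_categories: frozenset[str] = frozenset()
    genetic_code: int = 1

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise StructuralError("pi must sum to 1 (within 1e-12)")
        if (self.pi < 0).any():
            raise StructuralError("pi must be non-negative")
        if self.kappa < 0 or any(w < 0 for w in self.omega_by_category.values()):
            raise StructuralError("kappa and omega must be non-negative")

    @property
    def code(self) -> GeneticCode:
        return STANDARD_CODE if self.genetic_code == 1 else GeneticCode(self.genetic_code)


def _raw_rate_matrix(spec: CodonModelSpec, omega: float) -> np.ndarray:
    pi, kappa, code = spec.pi, spec.kappa, spec.code
    if (pi == 0).any():
        raise StructuralError("pi contains zero entries: chain is non-ergodic")
    n = code.n_states
    ii, jj, ts, ns = _pair_structure(code)
    rates = pi[jj] * np.where(ts, kappa, 1.0) * np.where(ns, omega, 1.0)
    Q = np.zeros((n, n))
    Q[ii, jj] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_rate_matrix(
    spec: CodonModelSpec, omega: float
) -> np.ndarray:
    """Scaled GY94 generator for one omega: rows sum to zero and the mean
    rate sum(pi_i * -q_ii) equals 1 substitution per codon per unit branch
    length."""
    Q = _raw_rate_matrix(spec, omega)
    scale = -(spec.pi * np.diag(Q)).sum()
    if scale <= 0:
        raise StructuralError("degenerate rate matrix (zero total flux)")
    return Q / scale


def neutral_scaled_rate_matrix(
    spec: CodonModelSpec, omega: float
) -> np.ndarray:
    """GY94 generator scaled by the *neutral* (omega = 1) flux, so one unit
    of branch length is one expected neutral substitution per codon.

    Under this common scaling, the synonymous rate is identical across
    omega categories — the molecular-clock-on-silent-sites assumption a
    regime-switch simulation needs.
    """
    Q = _raw_rate_matrix(spec, omega)
    Q1 = _raw_rate_matrix(spec, 1.0)
    scale = -(spec.pi * np.diag(Q1)).sum()
    if scale <= 0:
        raise StructuralError("degenerate rate matrix (zero total flux)")
    return Q / scale


def flux_fractions(spec: CodonModelSpec, omega: float) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractions of the equilibrium substitution
    flux under a scaled generator with the given omega."""
    pi, code = spec.pi, spec.code
    Q = build_rate_matrix(spec, omega)
    ii, jj, ts, ns = _pair_structure(code)
    flux = pi[ii] * Q[ii, jj]
    syn = flux[~ns].sum()
    total = flux.sum()
    return syn / total * 1.0, (total - syn) / total * 1.0


# ---------------------------------------------------------------------------
# pruning likelihood


class _EigenP:
    """Transition probabilities from the symmetrized eigendecomposition of a
    reversible generator."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = Q * d[:, None] / d[None, :]
        S = (S + S.T) / 2.0  # enforce symmetry against round-off
        w, V = np.linalg.eigh(S)
        self.w = w
        self.A = V / d[:, None]
        self.B = V.T * d[None, :]

    def P(self, t: float) -> np.ndarray:
        M = (self.A * np.exp(self.w * t)) @ self.B
        np.clip(M, 0.0, None, out=M)
        return M


class _LikelihoodEngine:
    """Reusable pruning machinery for one (tree topology, alignment) pair.

    Branch lengths, kappa, and per-category omegas vary between calls;
    the site patterns, tip masks, and postorder are fixed.
    """

    def __init__(self, ltt: LabeledTimeTree, aln: CodonAlignment,
                 pi: np.ndarray, code: Optional[GeneticCode] = None):
        self.code = code or aln.code
        self.pi = np.asarray(pi, dtype=float)
        tree = ltt.tree
        self.postorder = list(tree.postorder_node_iter())
        self.node_index = {id(nd): k for k, nd in enumerate(self.postorder)}
        self.root_index = self.node_index[id(tree.seed_node)]
        self.children = [
            [self.node_index[id(ch)] for ch in nd.child_nodes()]
            for nd in self.postorder
        ]
        self.category = [getattr(nd, "category", BACKGROUND)
                         for nd in self.postorder]
        self.is_leaf = [nd.is_leaf() for nd in self.postorder]
        tip_labels = [
            nd.taxon.label if nd.taxon else nd.label
            for nd in self.postorder
        ]
        # site-pattern compression
        taxa = [lbl for k, lbl in enumerate(tip_labels) if self.is_leaf[k]]
        missing = [t for t in taxa if t not in aln.codons]
        if missing:
            raise StructuralError(f"tree tips missing from alignment: {missing}")
        mat = np.array([aln.codons[t] for t in taxa])
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_counts = counts.astype(float)
        self.site_of_pattern_example = {
            p: int(np.nonzero(inverse == p)[0][0]) for p in range(len(counts))
        }
        self.tip_masks: dict[str, np.ndarray] = {}
        for r, taxon in enumerate(taxa):
            masks = np.stack(
                [self.code.codon_state_mask(c) for c in patterns[r]]
            ).astype(float)
            self.tip_masks[taxon] = masks
        self.tip_labels = tip_labels
        self._eigen_cache: dict[tuple, _EigenP] = {}

    def _eigen(self, kappa: float, omega: float) -> _EigenP:
        key = (kappa, omega)
        ep = self._eigen_cache.get(key)
        if ep is None:
            spec = CodonModelSpec(
                pi=self.pi, kappa=kappa,
                omega_by_category={BACKGROUND: omega},
            )
            ep = _EigenP(build_rate_matrix(spec, omega), self.pi)
            if len(self._eigen_cache) > 32:
                self._eigen_cache.clear()
            self._eigen_cache[key] = ep
        return ep

    def loglik(self, kappa: float, omega_by_category: dict[str, float],
               branch_lengths: np.ndarray) -> float:
        """Log-likelihood; ``branch_lengths`` indexed by postorder node."""
        partials: list[Optional[np.ndarray]] = [None] * len(self.postorder)
        logscale = 0.0
        for k, _ in enumerate(self.postorder):
            if self.is_leaf[k]:
                partials[k] = self.tip_masks[self.tip_labels[k]]
                continue
            L = None
            for c in self.children[k]:
                omega = omega_by_category[self.category[c]]
                P = self._eigen(kappa, omega).P(branch_lengths[c])
                msg = partials[c] @ P.T
                L = msg if L is None else L * msg
                partials[c] = None
            mx = L.max(axis=1)
            if (mx <= 0).any():
                bad = int(np.argmax(mx <= 0))
                raise StructuralError(
                    f"zero partial likelihood at site "
                    f"{self.site_of_pattern_example[bad]}"
                )
            L /= mx[:, None]
            logscale += float(self.pattern_counts @ np.log(mx))
            partials[k] = L
        site_lik = partials[self.root_index] @ self.pi
        if (site_lik <= 0).any() or not np.isfinite(site_lik).all():
            bad = int(np.argmax(~(site_lik > 0)))
            raise StructuralError(
                f"non-finite likelihood at site {self.site_of_pattern_example[bad]}"
            )
        return float(self.pattern_counts @ np.log(site_lik)) + logscale


def prune_loglik(
    tree: LabeledTimeTree, aln: CodonAlignment, spec: CodonModelSpec
) -> float:
    """Log-likelihood of the alignment on the tree (branch lengths taken
    from ``tree``; each branch's omega from its category)."""
    engine = _LikelihoodEngine(tree, aln, spec.pi)
    bl = np.zeros(len(engine.postorder))
    for k, nd in enumerate(engine.postorder):
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise StructuralError("branch lengths required for prune_loglik")
            bl[k] = nd.edge.length
    return engine.loglik(spec.kappa, spec.omega_by_category, bl)


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class BranchEstimate:
    tips: frozenset
    category: str
    length: float  # expected substitutions per codon
    duration_my: Optional[float] = None


@dataclass
class SelectionFit:
    lnL: float
    kappa_hat: float
    omega_hat: dict[str, float]
    branches: list[BranchEstimate]
    per_category: dict[str, dict]
    pi: np.ndarray
    freq_model: str
    fixed_categories: frozenset
    converged: bool
    n_eval: int
    n_codons: int

    @property
    def n_free_parameters(self) -> int:
        free_omegas = len(self.omega_hat) - len(self.fixed_categories)
        return 1 + free_omegas + len(self.branches)


def _initial_branch_lengths(engine: _LikelihoodEngine, nodes) -> np.ndarray:
    bl = np.zeros(len(nodes))
    for k, nd in enumerate(nodes):
        if nd.parent_node is None:
            continue
        if nd.edge.length:
            bl[k] = max(nd.edge.length, 1e-4)
        elif nd.age_my is not None and nd.parent_node.age_my is not None:
            bl[k] = max((nd.parent_node.age_my - nd.age_my) * 0.005, 1e-4)
        else:
            bl[k] = 0.05
    return bl


def fit_branch_model(
    tree: LabeledTimeTree,
    aln: CodonAlignment,
    freq_model: str = "CF1",
    fix_pseudogenic_omega: Optional[float] = None,
    omega_starts: tuple[float, ...] = (0.1, 0.5, 1.0),
    kappa_start: float = 2.0,
    max_iter: int = 500,
    warm_start: Optional[SelectionFit] = None,
) -> SelectionFit:
    """Jointly maximize the likelihood over kappa, per-category omegas, and
    branch lengths.

    ``fix_pseudogenic_omega`` pins every ``pseudogenic:*`` category to the
    given value (the neutral-ratio mode uses 1.0).  Multiple starts scale
    the free omegas; the best optimum is kept.
    """
    pi = estimate_frequencies(aln, freq_model)
    engine = _LikelihoodEngine(tree, aln, pi)
    nodes = engine.postorder
    categories = sorted({nd.category for nd in nodes if nd.parent_node is not None},
                        key=lambda c: (c != BACKGROUND, c))
    fixed = frozenset(
        c for c in categories if c.startswith("pseudogenic:")
    ) if fix_pseudogenic_omega is not None else frozenset()
    free_cats = [c for c in categories if c not in fixed]
    branch_idx = [k for k, nd in enumerate(nodes) if nd.parent_node is not None]

    def unpack(x: np.ndarray):
        kappa = float(np.exp(x[0]))
        omegas = {c: fix_pseudogenic_omega for c in fixed}
        for m, c in enumerate(free_cats):
            omegas[c] = float(np.exp(x[1 + m]))
        bl = np.zeros(len(nodes))
        bl[branch_idx] = np.exp(x[1 + len(free_cats):])
        return kappa, omegas, bl

    n_eval = 0

    def negloglik(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        kappa, omegas, bl = unpack(x)
        try:
            return -engine.loglik(kappa, omegas, bl)
        except (StructuralError, FloatingPointError):
            return 1e12

    if warm_start is not None:
        bl0_map = {b.tips: b.length for b in warm_start.branches}
        bl0 = np.array(
            [max(bl0_map.get(_tipset(nodes[k]), 0.05), 1e-6) for k in branch_idx]
        )
        kappa_start = warm_start.kappa_hat
    else:
        bl0 = np.array([_initial_branch_lengths(engine, nodes)[k]
                        for k in branch_idx])

    bounds = (
        [(np.log(0.01), np.log(100.0))]
        + [(np.log(1e-4), np.log(50.0))] * len(free_cats)
        + [(np.log(1e-7), np.log(20.0))] * len(branch_idx)
    )
    start_vectors = [
        np.concatenate(
            [
                [np.log(kappa_start)],
                np.log(np.full(len(free_cats), max(scale, 1e-3))),
                np.log(bl0),
            ]
        )
        for scale in omega_starts
    ]
    if warm_start is not None:
        # start exactly at the warm fit's optimum (new categories inherit
        # its background omega), so a nested warm fit can never be beaten
        # downward by optimizer noise
        fallback = warm_start.omega_hat.get(BACKGROUND, 0.5)
        w0 = [max(warm_start.omega_hat.get(c, fallback), 1e-4)
              for c in free_cats]
        start_vectors.append(
            np.concatenate(
                [[np.log(warm_start.kappa_hat)], np.log(w0), np.log(bl0)]
            )
        )
    best = None
    for x0 in start_vectors:
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-7},
        )
        f_start = negloglik(x0)
        if f_start < res.fun:  # guard against a rare line-search failure
            res.fun, res.x = f_start, x0
        if best is None or res.fun < best.fun:
            best = res
    kappa, omegas, bl = unpack(best.x)

    spec = CodonModelSpec(pi=pi, kappa=kappa, omega_by_category=omegas,
                          freq_model=freq_model, fixed_categories=fixed)
    branches = []
    per_category: dict[str, dict] = {}
    fS1, fN1 = flux_fractions(spec, 1.0)
    for k in branch_idx:
        nd = nodes[k]
        dur = None
        if nd.age_my is not None and nd.parent_node.age_my is not None:
            dur = nd.parent_node.age_my - nd.age_my
        branches.append(
            BranchEstimate(tips=_tipset(nd), category=nd.category,
                           length=float(bl[k]), duration_my=dur)
        )
    for cat in categories:
        omega = omegas[cat]
        fS, fN = flux_fractions(spec, omega)
        t_sum = sum(b.length for b in branches if b.category == cat)
        durs = [b.duration_my for b in branches if b.category == cat]
        duration = sum(durs) if all(d is not None for d in durs) else None
        e_syn = t_sum * fS * aln.n_codons
        e_nonsyn = t_sum * fN * aln.n_codons
        dS = t_sum * fS / (3.0 * fS1)
        dN = t_sum * fN / (3.0 * fN1)
        per_category[cat] = {
            "omega": omega,
            "dN": dN,
            "dS": dS,
            "dN_dS": dN / dS if dS > 0 else np.inf,
            "expected_synonymous_substitutions": e_syn,
            "expected_nonsynonymous_substitutions": e_nonsyn,
            "total_branch_length": t_sum,
            "total_duration_my": duration,
        }
    return SelectionFit(
        lnL=-float(best.fun), kappa_hat=kappa, omega_hat=omegas,
        branches=branches, per_category=per_category, pi=pi,
        freq_model=freq_model, fixed_categories=fixed,
        converged=bool(best.success), n_eval=n_eval, n_codons=aln.n_codons,
    )


def _tipset(node) -> frozenset:
    return frozenset(
        leaf.taxon.label if leaf.taxon else leaf.label
        for leaf in node.leaf_iter()
    )


def likelihood_ratio_test(fit_null: SelectionFit, fit_alt: SelectionFit,
                          df: int) -> float:
    """Upper-tail chi-square p-value for nested fits; negative statistics
    (optimizer noise) are clamped to zero."""
    stat = max(0.0, 2.0 * (fit_alt.lnL - fit_null.lnL))
    return float(chi2.sf(stat, df))


def category_synonymous_rate(fit: SelectionFit, tree: LabeledTimeTree,
                             category: str) -> float:
    """Synonymous substitutions per synonymous site per MY over the
    branches of one category (requires node ages)."""
    info = fit.per_category.get(category)
    if info is None:
        raise StructuralError(f"category {category!r} not in fit")
    duration = info["total_duration_my"]
    if duration is None:
        # recompute durations from the tree if the fit lacked ages
        duration = sum(
            tree.branch_duration_my(nd)
            for nd in tree.branches_in_category(category)
        )
    if not duration or duration <= 0:
        raise StructuralError(f"category {category!r} has zero total duration")
    return info["dS"] / duration
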