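"""Genetic-code bookkeeping for codon models and lesion scanning.

The codon substitution machinery works on the sense codons of a genetic
code (61 for the standard code); stop codons are excluded from the state
space.  Helpers here expose the codon list, codon <-> index maps, the
synonymy structure, and ambiguity expansion for codons containing N or
gap characters.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = {"A", "G"}

#: pairs of nucleotides whose interchange is a transition
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


class GeneticCode:
    """Sense-codon state space of a genetic code.

    Parameters
    ----------
    table_id:
        NCBI genetic-code table id (1 = standard).
    """

    def __init__(self, table_id: int = 1):
        self.table_id = table_id
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.stop_codons = sorted(table.stop_codons)
        self.sense_codons = sorted(
            c for c in table.forward_table if set(c) <= set(NUCLEOTIDES)
        )
        self.n_states = len(self.sense_codons)
        self.codon_index = {c: i for i, c in enumerate(self.sense_codons)}
        self.amino_acid = [table.forward_table[c] for c in self.sense_codons]
        self.start_codons = sorted(table.start_codons)

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate_codon(self, codon: str) -> str:
        """One-letter residue for ``codon``; ``X`` if ambiguous, ``*`` if stop."""
        if codon in self.codon_index:
            return self.amino_acid[self.codon_index[codon]]
        if codon in self.stop_codons:
            return "*"
        return "X"

    def codon_state_mask(self, codon: str) -> np.ndarray:
        """Boolean mask over sense-codon states compatible with ``codon``.

        ``N`` and ``-`` are wildcards.  A codon that can only be a stop maps
        to the all-false mask and must be removed upstream; a fully
        ambiguous codon maps to the all-true mask.
        """
        return self._mask(codon.upper())

    @lru_cache(maxsize=4096)
    def _mask(self, codon: str) -> np.ndarray:
        mask = np.zeros(self.n_states, dtype=bool)
        for i, sense in enumerate(self.sense_codons):
            if all(cn in ("N", "-", "?") or cn == sn for cn, sn in zip(codon, sense)):
                mask[i] = True
        mask.setflags(write=False)
        return mask


STANDARD_CODE = GeneticCode(1)


def translate(seq: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate an in-frame nucleotide sequence; N-containing codons give X."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} is not divisible by 3")
    return "".join(
        code.translate_codon(seq[i : i + 3].upper()) for i in range(0, len(seq), 3)
    )
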