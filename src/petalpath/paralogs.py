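"""Paralog substrate-specificity comparison (DFR-1 vs DFR-2 style).

Each paralog copy is summarized as a per-residue consensus amino-acid
sequence with a variability flag; the two copies are then compared residue
by residue and classified as identical, fixed difference, or variable in
one/both copies.  Difference counts inside named domains (e.g. the
26-residue substrate-specificity region) quantify divergence where it
matters for substrate choice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import (
    GENETIC_CODE,
    IUPAC_TO_ALLELES,
    STOP,
    DomainAnnotation,
    SequenceRecord,
)

__all__ = [
    "ConsensusSequence",
    "ParalogComparison",
    "build_consensus",
    "compare_paralogs",
    "region_difference_count",
    "residue_state",
]

COMPARISON_CLASSES = (
    "identical", "fixed_difference", "variable_in_A", "variable_in_B",
    "variable_in_both",
)


@dataclass(frozen=True)
class ConsensusSequence:
    """Majority amino-acid consensus with per-residue variability flags."""

    gene_id: str
    sequence: str
    variable: tuple  # booleans, one per residue

    def __len__(self) -> int:
        return len(self.sequence)


def _sample_residue_states(codon: str) -> set:
    """Amino-acid states a sample's codon can encode (IUPAC het expanded)."""
    expansions = [sorted(IUPAC_TO_ALLELES.get(ch, set())) for ch in codon]
    if any(not e or len(e) > 2 for e in expansions):
        return set()  # masked (gap, N, 3+-base code)
    states = set()
    from itertools import product
    for bases in product(*expansions):
        states.add(GENETIC_CODE["".join(bases)])
    return states


def build_consensus(records: Sequence[SequenceRecord], gene_id: str = "",
                    genetic_code: Mapping[str, str] = GENETIC_CODE) -> ConsensusSequence:
    """Per-residue majority consensus over in-frame aligned CDS records.

    Ties are broken toward the lexicographically first amino acid and the
    residue is flagged variable; a residue is variable whenever any sample
    (or within-sample ambiguity) yields a second state.  An internal stop
    in the consensus raises an error naming the residue.
    """
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("aligned sequences have unequal lengths")
    (length,) = lengths
    if length % 3:
        raise ValueError(f"aligned CDS length {length} not divisible by 3")
    n_res = length // 3

    letters = []
    variable = []
    for i in range(n_res):
        tally: Counter = Counter()
        states_here = set()
        for rec in records:
            codon = rec.sequence[3 * i:3 * i + 3]
            states = _sample_residue_states(codon)
            if not states:
                continue
            states_here |= states
            for aa in states:
                tally[aa] += 1
        if not tally:
            raise ValueError(f"residue {i + 1}: all samples masked")
        top = max(tally.values())
        winners = sorted(aa for aa, c in tally.items() if c == top)
        aa = winners[0]
        is_variable = len(states_here) > 1
        if aa == STOP and i < n_res - 1:
            raise ValueError(f"internal stop codon in consensus at residue {i + 1}")
        letters.append(aa)
        variable.append(is_variable)
    return ConsensusSequence(gene_id=gene_id, sequence="".join(letters),
                             variable=tuple(variable))


@dataclass(frozen=True)
class ParalogComparison:
    """Residue-level classification between two paralog consensuses."""

    gene_a: str
    gene_b: str
    table: pd.DataFrame  # columns: aa_pos, state_A, state_B, class

    def class_counts(self) -> dict:
        counts = dict.fromkeys(COMPARISON_CLASSES, 0)
        counts.update(self.table["class"].value_counts().to_dict())
        return counts

    @property
    def n_fixed_differences(self) -> int:
        return int((self.table["class"] == "fixed_difference").sum())


def compare_paralogs(cons_a: ConsensusSequence, cons_b: ConsensusSequence) -> ParalogComparison:
    """Classify every residue between two equal-length paralog consensuses.

    ``fixed_difference`` requires both copies invariant at the residue and
    differing states; a residue variable in one copy is classified by that
    copy regardless of the other's state.
    """
    if len(cons_a) != len(cons_b):
        raise ValueError(
            f"consensus lengths differ: {len(cons_a)} vs {len(cons_b)}")
    rows = []
    for i, (sa, sb) in enumerate(zip(cons_a.sequence, cons_b.sequence), start=1):
        va, vb = cons_a.variable[i - 1], cons_b.variable[i - 1]
        if va and vb:
            cls = "variable_in_both"
        elif va:
            cls = "variable_in_A"
        elif vb:
            cls = "variable_in_B"
        elif sa != sb:
            cls = "fixed_difference"
        else:
            cls = "identical"
        rows.append({"aa_pos": i, "state_A": sa, "state_B": sb, "class": cls})
    return ParalogComparison(gene_a=cons_a.gene_id, gene_b=cons_b.gene_id,
                             table=pd.DataFrame(rows))


def region_difference_count(comparison: ParalogComparison,
                            domain: DomainAnnotation) -> int:
    """Fixed differences inside a named domain's [start,end] interval."""
    n = len(comparison.table)
    if domain.start_aa > n or domain.end_aa > n:
        raise ValueError(
            f"domain {domain.name!r} [{domain.start_aa},{domain.end_aa}] "
            f"extends beyond sequence length {n}")
    sub = comparison.table[
        comparison.table["aa_pos"].between(domain.start_aa, domain.end_aa)]
    return int((sub["class"] == "fixed_difference").sum())


def residue_state(consensus: ConsensusSequence, aa_pos: int) -> str:
    """Consensus amino acid at a 1-based residue position."""
    if not (1 <= aa_pos <= len(consensus)):
        raise ValueError(f"residue {aa_pos} out of range 1..{len(consensus)}")
    return consensus.sequence[aa_pos - 1]
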