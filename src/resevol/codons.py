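"""Standard genetic code tables and single-nucleotide codon-neighbor bookkeeping.

Everything downstream (rate matrices, counting estimators, simulators) works
on integer indices into the 61 sense codons of the standard nuclear code.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code

NUCLEOTIDES = "TCAG"
ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3))
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_OF_CODON = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}
AA_VEC = np.array([AA_OF_CODON[c] for c in SENSE_CODONS])

# synonymous families: amino acid -> tuple of codon indices
SYN_FAMILIES: dict[str, tuple[int, ...]] = {}
for _i, _c in enumerate(SENSE_CODONS):
    SYN_FAMILIES.setdefault(AA_OF_CODON[_c], tuple())
SYN_FAMILIES = {
    aa: tuple(i for i, c in enumerate(SENSE_CODONS) if AA_OF_CODON[c] == aa)
    for aa in SYN_FAMILIES
}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(a: str, b: str) -> bool:
    return (a, b) in _TRANSITIONS


def _build_pairs():
    i_idx, j_idx, pos_idx, ts, syn = [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            i_idx.append(i)
            j_idx.append(j)
            pos_idx.append(k)
            ts.append(is_transition(ci[k], cj[k]))
            syn.append(AA_OF_CODON[ci] == AA_OF_CODON[cj])
    return (
        np.array(i_idx, dtype=np.intp),
        np.array(j_idx, dtype=np.intp),
        np.array(pos_idx, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


# arrays over all ordered single-nucleotide sense-codon pairs
PAIR_I, PAIR_J, PAIR_POS, PAIR_TS, PAIR_SYN = _build_pairs()

# per-codon neighbor lists (ragged, stored as index slices into the pair arrays)
_order = np.lexsort((PAIR_J, PAIR_I))
PAIR_I, PAIR_J, PAIR_POS, PAIR_TS, PAIR_SYN = (
    a[_order] for a in (PAIR_I, PAIR_J, PAIR_POS, PAIR_TS, PAIR_SYN)
)
NEIGHBOR_SLICES = tuple(
    slice(lo, hi)
    for lo, hi in zip(
        np.searchsorted(PAIR_I, np.arange(N_SENSE)),
        np.searchsorted(PAIR_I, np.arange(N_SENSE), side="right"),
    )
)


class CodonError(ValueError):
    """Raised for sequences that cannot be interpreted as sense codons."""


def codons_of_sequence(seq: str) -> list[str]:
    """Split an in-frame nucleotide sequence into codon strings."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise CodonError(f"sequence length {len(seq)} is not a multiple of 3")
    return [seq[k : k + 3] for k in range(0, len(seq), 3)]


def codon_to_index(codon: str, column: int | None = None) -> int:
    """Index of a sense codon; raises CodonError for stops or ambiguity."""
    codon = codon.upper().replace("U", "T")
    idx = CODON_INDEX.get(codon)
    if idx is None:
        where = "" if column is None else f" at codon column {column}"
        if codon in STOP_CODONS:
            raise CodonError(f"stop codon {codon}{where}")
        raise CodonError(f"non-sense codon {codon!r}{where}")
    return idx


def sequence_to_indices(seq: str) -> np.ndarray:
    """Integer codon indices for a gapless in-frame coding sequence."""
    return np.array(
        [codon_to_index(c, column=k) for k, c in enumerate(codons_of_sequence(seq))],
        dtype=np.intp,
    )


def indices_to_sequence(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in np.asarray(idx, dtype=np.intp))


def is_sense_codon(codon: str) -> bool:
    return codon.upper().replace("U", "T") in CODON_INDEX
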