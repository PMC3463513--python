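"""Codon adaptation index from a relative-adaptiveness table.

Relative adaptiveness follows the Sharp–Li construction: within each
synonymous family, w(codon) = count(codon) / count(most frequent synonym)
over a reference set of (typically highly expressed) coding sequences, with
a 0.5 pseudo-count for codons absent from the reference. CAI is the
geometric mean of w over the counted codons of a sequence or codon multiset.
Single-codon families (Met, Trp) and stop codons carry no usage signal and
are excluded from the geometric mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import (
    AA_OF_CODON,
    CODON_INDEX,
    SENSE_CODONS,
    SYN_FAMILIES,
    codons_of_sequence,
)

__all__ = [
    "AdaptivenessTable",
    "CAIValue",
    "relative_adaptiveness",
    "compute_cai",
    "EXCLUDED_AMINO_ACIDS",
]

EXCLUDED_AMINO_ACIDS = ("M", "W")  # single-codon families


@dataclass
class AdaptivenessTable:
    """codon -> relative adaptiveness w in (0, 1]; max w = 1 in every family."""

    w: dict[str, float]
    reference: str = "unspecified"

    def __post_init__(self):
        for codon, value in self.w.items():
            if codon not in CODON_INDEX:
                raise ValueError(f"{codon!r} is not a sense codon")
            if not (0 < value <= 1):
                raise ValueError(f"w({codon}) = {value} outside (0, 1]")
        for aa, fam in SYN_FAMILIES.items():
            fam_w = [self.w[SENSE_CODONS[i]] for i in fam if SENSE_CODONS[i] in self.w]
            if fam_w and abs(max(fam_w) - 1.0) > 1e-9:
                raise ValueError(f"family {aa} has no codon with w = 1")

    def excluded(self, codon: str) -> bool:
        return AA_OF_CODON[codon] in EXCLUDED_AMINO_ACIDS

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "codon": c,
                "amino_acid": AA_OF_CODON[c],
                "w": self.w[c],
                "excluded": self.excluded(c),
            }
            for c in SENSE_CODONS
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, reference: str | None = None) -> "AdaptivenessTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df["codon"], df["w"])), reference=reference or str(path))


@dataclass
class CAIValue:
    cai: float
    n_codons: int  # codons contributing to the geometric mean


def relative_adaptiveness(reference_sequences, reference: str = "user") -> AdaptivenessTable:
    """Build a relative-adaptiveness table from reference coding sequences."""
    seqs = list(reference_sequences)
    if not seqs:
        raise ValueError("empty reference set")
    counts: Counter[str] = Counter()
    for seq in seqs:
        for codon in codons_of_sequence(seq):
            if codon in CODON_INDEX:
                counts[codon] += 1
    w: dict[str, float] = {}
    for aa, fam in SYN_FAMILIES.items():
        fam_codons = [SENSE_CODONS[i] for i in fam]
        fam_counts = {c: counts.get(c, 0) for c in fam_codons}
        top = max(fam_counts.values())
        if top == 0:
            for c in fam_codons:  # family absent: no usage information
                w[c] = 1.0
            continue
        for c in fam_codons:
            w[c] = (fam_counts[c] if fam_counts[c] > 0 else 0.5) / top
    return AdaptivenessTable(w, reference=reference)


def compute_cai(sequence_or_codons, table: AdaptivenessTable) -> CAIValue:
    """Geometric-mean CAI of a coding sequence or codon multiset."""
    if isinstance(sequence_or_codons, str):
        codons = codons_of_sequence(sequence_or_codons)
    else:
        codons = list(sequence_or_codons)
    logs = []
    for codon in codons:
        codon = codon.upper().replace("U", "T")
        if codon not in CODON_INDEX:
            continue  # gaps / ambiguity / stops carry no usage signal
        if table.excluded(codon):
            continue
        logs.append(np.log(table.w[codon]))
    if not logs:
        raise ValueError("no countable codons (all excluded or non-sense)")
    return CAIValue(cai=float(np.exp(np.mean(logs))), n_codons=len(logs))


def bootstrap_cai_se(codons, table: AdaptivenessTable, B: int = 100, seed=None) -> float:
    """Bootstrap SE of CAI over a codon multiset (resampling codons)."""
    rng = np.random.default_rng(seed)
    counted = [
        c for c in codons if c.upper() in CODON_INDEX and not table.excluded(c.upper())
    ]
    if len(counted) < 2:
        return np.nan
    logw = np.array([np.log(table.w[c.upper()]) for c in counted])
    n = len(logw)
    idx = rng.integers(0, n, size=(B, n))
    vals = np.exp(logw[idx].mean(axis=1))
    return float(vals.std(ddof=1))
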