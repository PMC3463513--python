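"""Join RSA annotations with codon alignments, group proteins, bin residues.

The unit of analysis is the ResidueRecord: one aligned structural residue
carrying its RSA value and the gapless codon column observed across the
taxa. Proteins are ranked on whole-protein covariates (average residue RSA
for core size, an expression proxy such as CAI for expression) and the
extreme quantile fractions become the contrast groups. Gapless records are
partitioned into RSA bins with shared edges and each bin's codon columns
are concatenated into one alignment for rate estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .codons import CODON_INDEX, codons_of_sequence

__all__ = [
    "CodonAlignment",
    "ResidueRecord",
    "RSABin",
    "BinnedAlignment",
    "map_codons_to_structure",
    "assign_groups",
    "bin_residues",
    "concatenate_bin_alignment",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = tuple(float(e) for e in range(0, 101, 10))


@dataclass
class CodonAlignment:
    """An in-frame multi-taxon codon alignment for one protein."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]  # nucleotide strings, '-' gaps allowed

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.sequences = tuple(s.upper().replace("U", "T") for s in self.sequences)
        if len(self.taxa) != len(self.sequences):
            raise ValueError("one sequence per taxon required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences differ in length: {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3

    def codon_column(self, k: int) -> tuple[str, ...]:
        return tuple(s[3 * k : 3 * k + 3] for s in self.sequences)

    def column_is_sense(self, k: int) -> bool:
        """True iff every taxon shows an unambiguous sense codon at column k.

        Gaps, ambiguity characters (N, X, ...) and stop codons all disqualify
        the column.
        """
        return all(c in CODON_INDEX for c in self.codon_column(k))

    @classmethod
    def from_fasta(cls, path, taxa_order) -> "CodonAlignment":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        missing = [t for t in taxa_order if t not in records]
        if missing:
            raise ValueError(f"taxa missing from {path}: {missing}")
        return cls(tuple(taxa_order), tuple(records[t] for t in taxa_order))

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, s in zip(self.taxa, self.sequences):
                fh.write(f">{t}\n{s}\n")


@dataclass
class ResidueRecord:
    """One aligned structural residue: RSA plus its codon column."""

    protein_id: str
    residue_index: int  # 1-based target position
    rsa: float  # percent; NaN when the template alignment was gapped
    codons: tuple[str, ...]  # one codon per taxon
    gapless: bool


@dataclass
class RSABin:
    """One RSA interval with its representative x-value."""

    index: int
    lo: float
    hi: float  # [lo, hi); the last bin is closed at 100
    x: float  # representative RSA (mean of members by default)
    count: int

    @property
    def empty(self) -> bool:
        return self.count == 0


@dataclass
class BinnedAlignment:
    """Concatenated gapless codon columns of one RSA bin."""

    taxa: tuple[str, ...]
    codons: np.ndarray  # (n_taxa, n_codons) sense-codon indices
    bin: RSABin | None = None
    protein_ids: tuple[str, ...] = ()

    @property
    def n_codons(self) -> int:
        return 0 if self.codons.size == 0 else self.codons.shape[1]

    @property
    def usable(self) -> bool:
        return self.n_codons > 0


def map_codons_to_structure(
    alignment: CodonAlignment, rsa: "RSAProfile", protein_id: str
) -> list[ResidueRecord]:
    """One ResidueRecord per target position, joining codon columns with RSA.

    Columns are 1:1 with target residues, so the alignment's codon length
    must equal the RSA profile length. A record is gapless iff every taxon
    shows a sense codon and the RSA value is present.
    """
    rsa_values = rsa.values
    if alignment.n_codons != len(rsa_values):
        raise ValueError(
            f"protein {protein_id}: alignment has {alignment.n_codons} codons but "
            f"RSA profile covers {len(rsa_values)} residues"
        )
    records = []
    for k in range(alignment.n_codons):
        value = float(rsa_values[k])
        sense = alignment.column_is_sense(k)
        records.append(
            ResidueRecord(
                protein_id=protein_id,
                residue_index=k + 1,
                rsa=value,
                codons=alignment.codon_column(k),
                gapless=sense and not np.isnan(value),
            )
        )
    return records


def assign_groups(proteins: pd.DataFrame, fraction: float = 1.0 / 3.0) -> pd.DataFrame:
    """Label proteins by ranked core-size and expression quantile fractions.

    `proteins` needs columns protein_id, avg_rsa, expression. Each axis is
    ranked ascending independently; the bottom floor(fraction*N) proteins
    become large_core / low_expr, the top floor(fraction*N) small_core /
    high_expr, the remainder mid. Ties are broken by protein ID for
    determinism (tie counts trigger a warning). fraction = 0.5 leaves the
    mid class empty.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    required = {"protein_id", "avg_rsa", "expression"}
    if not required.issubset(proteins.columns):
        raise ValueError(f"proteins table needs columns {sorted(required)}")
    n = len(proteins)
    k = int(np.floor(fraction * n))
    if k < 2:
        raise ValueError(f"fewer than 2 proteins per class (N={n}, fraction={fraction})")

    out = proteins.copy().reset_index(drop=True)

    def classify(col: str, low_label: str, high_label: str) -> pd.Series:
        vals = out[col].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            raise ValueError(f"all proteins tied on {col!r}: unrankable")
        n_ties = int(len(vals) - out[col].nunique())
        if n_ties:
            warnings.warn(f"{n_ties} rank ties on {col!r} broken by protein ID", stacklevel=2)
        order = np.lexsort((out["protein_id"].to_numpy(), vals))
        labels = np.array(["mid"] * n, dtype=object)
        labels[order[:k]] = low_label
        labels[order[-k:]] = high_label
        return pd.Series(labels)

    out["core_class"] = classify("avg_rsa", "large_core", "small_core")
    out["expr_class"] = classify("expression", "low_expr", "high_expr")
    return out


def bin_residues(
    records: list[ResidueRecord],
    edges=DEFAULT_BIN_EDGES,
    *,
    x_mode: str = "mean",
) -> list[tuple[RSABin, list[ResidueRecord]]]:
    """Partition gapless records into RSA bins.

    Edges must be strictly increasing from 0 to 100. Intervals are half-open
    [lo, hi) with the last bin closed at 100. The representative x-value is
    the mean member RSA ("mean", default) or the interval midpoint
    ("midpoint"); empty bins are kept but flagged by count = 0.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2:
        raise ValueError("need at least two bin edges")
    if edges[0] != 0 or edges[-1] != 100 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must increase strictly from 0 to 100")
    if x_mode not in ("mean", "midpoint"):
        raise ValueError(f"unknown x_mode {x_mode!r}")
    members: list[list[ResidueRecord]] = [[] for _ in range(len(edges) - 1)]
    for rec in records:
        if not rec.gapless:
            raise ValueError(
                f"record {rec.protein_id}:{rec.residue_index} is not gapless; "
                "filter records before binning"
            )
        if np.isnan(rec.rsa) or rec.rsa < 0 or rec.rsa > 100:
            raise ValueError(
                f"RSA {rec.rsa} outside [0, 100] for {rec.protein_id}:{rec.residue_index}"
            )
        b = int(np.searchsorted(edges, rec.rsa, side="right")) - 1
        b = min(b, len(edges) - 2)  # RSA = 100 falls in the closed last bin
        members[b].append(rec)
    out = []
    for b in range(len(edges) - 1):
        lo, hi = float(edges[b]), float(edges[b + 1])
        if members[b]:
            x = (
                float(np.mean([r.rsa for r in members[b]]))
                if x_mode == "mean"
                else (lo + hi) / 2.0
            )
        else:
            x = (lo + hi) / 2.0
            warnings.warn(f"bin [{lo}, {hi}) is empty", stacklevel=2)
        out.append((RSABin(index=b, lo=lo, hi=hi, x=x, count=len(members[b])), members[b]))
    return out


def concatenate_bin_alignment(
    members: list[ResidueRecord], bin: RSABin | None = None, taxa=None
) -> BinnedAlignment:
    """Concatenate a bin's codon columns, sorted by protein then position."""
    if not members:
        if taxa is None:
            raise ValueError("cannot infer taxa for an empty bin; pass taxa=")
        return BinnedAlignment(
            taxa=tuple(taxa), codons=np.zeros((len(taxa), 0), dtype=np.intp), bin=bin
        )
    ordered = sorted(members, key=lambda r: (r.protein_id, r.residue_index))
    n_taxa = len(ordered[0].codons)
    if taxa is None:
        taxa = tuple(f"taxon{i+1}" for i in range(n_taxa))
    cols = np.empty((n_taxa, len(ordered)), dtype=np.intp)
    for k, rec in enumerate(ordered):
        if not rec.gapless:
            raise ValueError(
                f"gapped record {rec.protein_id}:{rec.residue_index} in bin concatenation"
            )
        for t, codon in enumerate(rec.codons):
            idx = CODON_INDEX.get(codon)
            if idx is None:
                raise ValueError(
                    f"non-sense codon {codon!r} in record flagged gapless "
                    f"({rec.protein_id}:{rec.residue_index})"
                )
            cols[t, k] = idx
    return BinnedAlignment(
        taxa=tuple(taxa),
        codons=cols,
        bin=bin,
        protein_ids=tuple(dict.fromkeys(r.protein_id for r in ordered)),
    )
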