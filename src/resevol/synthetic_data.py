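"""Synthetic study generator with known residue-level ground truth.

The generator emulates a residue-level structure-evolution study design:
proteins fall into four cells (core size x expression class); each residue
draws an RSA value from its core-class Beta distribution; the residue's
true dN/dS is linear in RSA with a cell-specific intercept and slope
(core size modulates the slope, expression rescales the whole line); codon
columns then evolve along a fixed small tree under a Goldman-Yang rate
matrix with that site's rate ratio. Expression additionally (i) enriches
the root/stationary codon distribution for preferred synonymous codons and
(ii) rescales the whole substitution clock relative to a fixed neutral
mutation scale, producing a uniform (structure-independent) deflation of dS
in highly expressed proteins.

Simulation is by exact continuous-time Markov chain (Gillespie) sampling
per site per branch, so no matrix exponentials are involved and the
realized substitution events can be counted exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .alignment_binning import CodonAlignment
from .codon_bias import AdaptivenessTable, compute_cai
from .codon_evolution import PhyloTree, neutral_flux
from .codons import (
    N_SENSE,
    NEIGHBOR_SLICES,
    PAIR_J,
    PAIR_SYN,
    PAIR_TS,
    SENSE_CODONS,
    SYN_FAMILIES,
    indices_to_sequence,
)
from .structure_rsa import RSAProfile, _profile_frame

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "CELLS",
    "generator_adaptiveness",
    "simulate_protein_set",
    "simulate_codon_alignment",
    "simulate_alignment",
    "simulate_study",
    "write_study",
]

CORE_CLASSES = ("large_core", "small_core")
EXPR_CLASSES = ("low_expr", "high_expr")
CELLS = tuple(itertools.product(CORE_CLASSES, EXPR_CLASSES))

DEFAULT_TREE = "((cerevisiae:0.15,paradoxus:0.20):0.15,mikatae:0.30,bayanus:0.38);"


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a synthetic four-cell study.

    The dN/dS line for a protein in cell (c, e) is
        omega(RSA) = max(omega_floor,
                         expression_omega_scale[e] *
                         (dnds_intercept + dnds_slope[c] * RSA))
    with RSA in percent. Core size modulates the slope only; expression
    rescales the whole line, so fold changes between expression classes are
    uniform in RSA. syn_rate_scale rescales the entire substitution clock of
    a class relative to the fixed neutral scale, deflating dS (and dN)
    uniformly; codon_bias_gamma sets the extra stationary weight of each
    family's preferred codon.
    """

    seed: int
    n_proteins_per_cell: int = 50
    residue_range: tuple[int, int] = (130, 170)
    rsa_beta: dict = field(
        default_factory=lambda: {"large_core": (1.7, 4.3), "small_core": (2.5, 3.6)}
    )
    dnds_intercept: float = 0.12
    dnds_slope: dict = field(
        default_factory=lambda: {"large_core": 0.0050, "small_core": 0.0006}
    )
    expression_omega_scale: dict = field(
        default_factory=lambda: {"low_expr": 1.0, "high_expr": 0.40}
    )
    syn_rate_scale: dict = field(
        default_factory=lambda: {"low_expr": 1.0, "high_expr": 0.70}
    )
    codon_bias_gamma: dict = field(
        default_factory=lambda: {"low_expr": 0.0, "high_expr": 4.0}
    )
    kappa: float = 2.5
    tree_newick: str = DEFAULT_TREE
    omega_floor: float = 0.01
    focal_taxon: str = "cerevisiae"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_proteins_per_cell < 1:
            raise ValueError("need at least one protein per cell")
        lo, hi = self.residue_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad residue range {self.residue_range}")
        if self.omega_floor <= 0:
            raise ValueError("omega floor must be positive")
        for c in CORE_CLASSES:
            a, b = self.rsa_beta[c]
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {c} must be positive")
            if self.dnds_slope[c] < 0:
                raise ValueError("negative ground-truth slopes are not supported")
        for e in EXPR_CLASSES:
            if self.syn_rate_scale[e] <= 0:
                raise ValueError("synonymous-rate scales must be positive")
            if self.expression_omega_scale[e] <= 0:
                raise ValueError("expression omega scales must be positive")
            if self.codon_bias_gamma[e] < 0:
                raise ValueError("codon bias strength must be non-negative")
        for rsa in (0.0, 100.0):
            for c, e in CELLS:
                if self.true_omega(rsa, (c, e)) <= 0:
                    raise ValueError("omega(RSA) must be positive on [0, 100]")
        tree = PhyloTree.from_newick(self.tree_newick)
        if self.focal_taxon not in tree.taxa:
            raise ValueError(f"focal taxon {self.focal_taxon!r} not in tree")

    def true_omega(self, rsa: float, cell: tuple[str, str]) -> float:
        core, expr = cell
        line = self.dnds_intercept + self.dnds_slope[core] * rsa
        return max(self.omega_floor, self.expression_omega_scale[expr] * line)

    def true_line(self, cell: tuple[str, str]) -> tuple[float, float]:
        """(intercept, slope) of the cell's dN/dS-versus-RSA line."""
        core, expr = cell
        e = self.expression_omega_scale[expr]
        return e * self.dnds_intercept, e * self.dnds_slope[core]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "residue_range" in raw:
            raw["residue_range"] = tuple(raw["residue_range"])
        if "rsa_beta" in raw:
            raw["rsa_beta"] = {k: tuple(v) for k, v in raw["rsa_beta"].items()}
        return cls(**raw)


def preferred_codons() -> dict[str, str]:
    """Deterministic preferred codon per synonymous family (first in order)."""
    return {aa: SENSE_CODONS[fam[0]] for aa, fam in SYN_FAMILIES.items()}


def generator_adaptiveness(gamma: float) -> AdaptivenessTable:
    """Relative-adaptiveness table implied by the high-bias stationary weights."""
    pref = set(preferred_codons().values())
    w = {}
    for c in SENSE_CODONS:
        w[c] = 1.0 if c in pref else 1.0 / (1.0 + gamma) if gamma > 0 else 1.0
    return AdaptivenessTable(w, reference=f"synthetic-generator(gamma={gamma:g})")


def stationary_distribution(gamma: float) -> np.ndarray:
    """Codon frequencies: uniform amino acids, biased within-family usage."""
    pref = set(preferred_codons().values())
    pi = np.zeros(N_SENSE)
    n_aa = len(SYN_FAMILIES)
    for fam in SYN_FAMILIES.values():
        weights = np.array(
            [1.0 + gamma if SENSE_CODONS[i] in pref else 1.0 for i in fam]
        )
        weights /= weights.sum()
        for i, wt in zip(fam, weights):
            pi[i] = wt / n_aa
    return pi


class _CellMachinery:
    """Precomputed per-expression-class rate bookkeeping for the simulator."""

    def __init__(self, kappa: float, gamma: float):
        self.pi = stationary_distribution(gamma)
        self.base = self.pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0)
        syn = np.where(PAIR_SYN, self.base, 0.0)
        non = np.where(~PAIR_SYN, self.base, 0.0)
        self.syn_out = np.array([syn[s].sum() for s in NEIGHBOR_SLICES])
        self.non_out = np.array([non[s].sum() for s in NEIGHBOR_SLICES])
        self.scale = neutral_flux(kappa, self.pi)


def _evolve_branch(states, omegas, syn_scale, t, mach: _CellMachinery, rng, counts=None):
    """Exact CTMC evolution of all sites along one branch of length t."""
    states = states.copy()
    n = len(states)
    rates = syn_scale * (mach.syn_out[states] + omegas * mach.non_out[states]) / mach.scale
    waits = rng.exponential(1.0, n) / rates
    for k in np.where(waits < t)[0]:
        elapsed = waits[k]
        state = states[k]
        while elapsed < t:
            sl = NEIGHBOR_SLICES[state]
            wts = mach.base[sl] * np.where(PAIR_SYN[sl], 1.0, omegas[k])
            total = wts.sum()
            choice = rng.choice(len(wts), p=wts / total)
            if counts is not None:
                counts["syn" if PAIR_SYN[sl][choice] else "nonsyn"] += 1
            state = PAIR_J[sl][choice]
            rate = syn_scale * (mach.syn_out[state] + omegas[k] * mach.non_out[state]) / mach.scale
            elapsed += rng.exponential(1.0) / rate
        states[k] = state
    return states


def _simulate_on_tree(root_states, omegas, syn_scale, tree: PhyloTree, mach, rng, counts=None):
    """Evolve from the root down every branch; returns tip name -> states."""
    tips: dict[str, np.ndarray] = {}

    def walk(node, states):
        for child in node.children:
            evolved = _evolve_branch(
                states, omegas, syn_scale, child.length, mach, rng, counts
            )
            if child.is_tip:
                tips[child.name] = evolved
            else:
                walk(child, evolved)

    walk(tree.root, root_states)
    return tips


def simulate_protein_set(config: SimulationConfig):
    """Draw the protein panel: IDs, cells, per-residue RSA values.

    Returns (rsa_profiles, truth) where truth is a DataFrame with columns
    protein_id, core_class_true, expr_class_true, cell.
    """
    config.validate()
    root_ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root_ss.spawn(1)[0])
    profiles: dict[str, RSAProfile] = {}
    rows = []
    counter = 0
    for core, expr in CELLS:
        a, b = config.rsa_beta[core]
        for _ in range(config.n_proteins_per_cell):
            counter += 1
            pid = f"P{counter:04d}"
            length = int(rng.integers(config.residue_range[0], config.residue_range[1] + 1))
            rsa = 100.0 * rng.beta(a, b, size=length)
            profiles[pid] = RSAProfile(
                _profile_frame(np.arange(1, length + 1), ["X"] * length, rsa),
                metadata={"source": "synthetic"},
            )
            rows.append(
                {
                    "protein_id": pid,
                    "core_class_true": core,
                    "expr_class_true": expr,
                    "cell": f"{core}.{expr}",
                }
            )
    truth = pd.DataFrame(rows)
    return profiles, truth


def simulate_codon_alignment(
    rsa_values: np.ndarray,
    cell: tuple[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
    machinery: dict | None = None,
    counts: dict | None = None,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve one protein's codon alignment given its residue RSA values.

    Returns the alignment (taxa in tree tip order) and the per-site true
    omega values.
    """
    core, expr = cell
    tree = PhyloTree.from_newick(config.tree_newick)
    if machinery is None:
        machinery = {}
    if expr not in machinery:
        machinery[expr] = _CellMachinery(config.kappa, config.codon_bias_gamma[expr])
    mach = machinery[expr]
    omegas = np.array([config.true_omega(r, cell) for r in rsa_values])
    root = rng.choice(N_SENSE, size=len(omegas), p=mach.pi)
    tips = _simulate_on_tree(
        root, omegas, config.syn_rate_scale[expr], tree, mach, rng, counts
    )
    taxa = tree.taxa
    seqs = tuple(indices_to_sequence(tips[t]) for t in taxa)
    return CodonAlignment(taxa, seqs), omegas


def simulate_alignment(
    omega: float,
    n_codons: int,
    *,
    tree_newick: str = DEFAULT_TREE,
    kappa: float = 2.5,
    gamma: float = 0.0,
    syn_scale: float = 1.0,
    seed: int | None = None,
    counts: dict | None = None,
):
    """Constant-omega alignment for estimator calibration studies.

    Returns a BinnedAlignment-compatible object (taxa + codon index matrix).
    """
    from .alignment_binning import BinnedAlignment

    rng = np.random.default_rng(seed)
    tree = PhyloTree.from_newick(tree_newick)
    mach = _CellMachinery(kappa, gamma)
    omegas = np.full(n_codons, float(omega))
    root = rng.choice(N_SENSE, size=n_codons, p=mach.pi)
    tips = _simulate_on_tree(root, omegas, syn_scale, tree, mach, rng, counts)
    taxa = tree.taxa
    return BinnedAlignment(taxa=taxa, codons=np.vstack([tips[t] for t in taxa]))


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    alignments: dict
    rsa: dict
    expression: pd.DataFrame  # protein_id, expression (focal-taxon CAI)
    truth_groups: pd.DataFrame
    ground_truth: pd.DataFrame  # protein_id, residue_index, true_rsa, true_omega, cell
    adaptiveness: AdaptivenessTable
    taxa: tuple[str, ...]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Full synthetic study: proteins, RSA, alignments, expression proxy."""
    config.validate()
    profiles, truth = simulate_protein_set(config)
    tree = PhyloTree.from_newick(config.tree_newick)
    gamma_hi = max(config.codon_bias_gamma.values())
    table = generator_adaptiveness(gamma_hi)
    machinery: dict = {}
    root_ss = np.random.SeedSequence(config.seed)
    # stream 0 is used by simulate_protein_set; proteins get streams 1..N
    streams = root_ss.spawn(1 + len(truth))
    alignments = {}
    expr_rows = []
    gt_rows = []
    for k, row in enumerate(truth.itertuples(index=False)):
        pid = row.protein_id
        cell = (row.core_class_true, row.expr_class_true)
        rng = np.random.default_rng(streams[1 + k])
        rsa_values = profiles[pid].values
        aln, omegas = simulate_codon_alignment(
            rsa_values, cell, config, rng, machinery=machinery
        )
        alignments[pid] = aln
        focal = aln.sequences[aln.taxa.index(config.focal_taxon)]
        expr_rows.append(
            {"protein_id": pid, "expression": compute_cai(focal, table).cai}
        )
        # annotate residue types from the focal-taxon translation
        from .codons import AA_OF_CODON, codons_of_sequence

        types = [AA_OF_CODON[c] for c in codons_of_sequence(focal)]
        profiles[pid].data["residue_type"] = types
        for i, (r, w) in enumerate(zip(rsa_values, omegas)):
            gt_rows.append(
                {
                    "protein_id": pid,
                    "residue_index": i + 1,
                    "true_rsa": r,
                    "true_omega": w,
                    "cell": f"{cell[0]}.{cell[1]}",
                }
            )
    return SyntheticStudy(
        config=config,
        alignments=alignments,
        rsa=profiles,
        expression=pd.DataFrame(expr_rows),
        truth_groups=truth,
        ground_truth=pd.DataFrame(gt_rows),
        adaptiveness=table,
        taxa=tree.taxa,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Emit the study in the exact file formats the pipeline ingests."""
    from pathlib import Path

    outdir = Path(outdir)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    (outdir / "rsa").mkdir(parents=True, exist_ok=True)
    for pid, aln in study.alignments.items():
        aln.to_fasta(outdir / "alignments" / f"{pid}.fasta")
    for pid, prof in study.rsa.items():
        prof.to_tsv(outdir / "rsa" / f"{pid}.tsv")
    study.expression.to_csv(
        outdir / "expression.tsv", sep="\t", index=False, float_format="%.10g"
    )
    study.truth_groups.to_csv(outdir / "groups_truth.tsv", sep="\t", index=False)
    study.ground_truth.to_csv(
        outdir / "ground_truth.tsv", sep="\t", index=False, float_format="%.10g"
    )
    study.adaptiveness.to_tsv(outdir / "adaptiveness.tsv")
    study.config.to_yaml(outdir / "config.yaml")
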