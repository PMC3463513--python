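"""Canonical simulation studies built on the pipeline.

Two study designs are packaged here so that tests, scripts and users run
exactly the same configurations:

* the four-cell joint-effects study — core size modulates the slope of the
  dN/dS-versus-RSA line only, expression rescales the whole line and the
  synonymous clock uniformly — whose expected outcome pattern is:
  (a) core-size fold change in dN/dS: slope > 0, intercept ≈ 1;
  (b) expression fold change in dN/dS: intercept > 1, slope ≈ 0;
  (c) dS fold change: intercept > 1 for expression, ≈ 1 for core size;
  (d) the large-core/low-expression cell has the steepest dN/dS slope,
      exceeding both single-change cells;

* a null calibration study — two protein groups generated from one
  identical dN/dS line — measuring the type-I error of the slope-equality
  t-test over many small replicate pipeline runs.
"""

from __future__ import annotations

import numpy as np

from .alignment_binning import (
    ResidueRecord,
    bin_residues,
    concatenate_bin_alignment,
)
from .codon_evolution import (
    PhyloTree,
    bootstrap_se,
    estimate_rates_ml,
    estimate_rates_profile,
)
from .pipeline import RunConfig, RunReport
from .regression_stats import compare_line_params, weighted_line_fit
from .synthetic_data import DEFAULT_TREE, SimulationConfig, simulate_codon_alignment

__all__ = [
    "four_cell_study_config",
    "evaluate_four_cell_report",
    "null_slope_pvalue",
    "slope_test_rejection_rate",
    "BROAD_BIN_EDGES",
]

# broad, occupancy-balanced RSA bins for fold-change analyses (RSA mass
# concentrates below ~60%)
BROAD_BIN_EDGES = (0.0, 15.0, 30.0, 45.0, 60.0, 80.0, 100.0)


def four_cell_study_config(outdir, seed: int) -> RunConfig:
    """The packaged four-cell joint-effects study configuration.

    64 proteins per cell of 200-300 residues (realistic structural-template
    lengths), broad RSA bins, per-bin maximum-likelihood rates with B = 200
    profile-bootstrap standard errors.
    """
    return RunConfig(
        outdir=str(outdir),
        seed=seed,
        simulate=SimulationConfig(
            seed=seed, n_proteins_per_cell=64, residue_range=(200, 300)
        ),
        bin_edges=BROAD_BIN_EDGES,
        bootstrap_B=200,
        bootstrap_method="profile",
        rates_mode="per_bin",
        tree_newick=DEFAULT_TREE,
    )


def evaluate_four_cell_report(report: RunReport, alpha: float = 0.05) -> dict:
    """Score the four expected qualitative patterns on one pipeline report.

    Returns {check_name: (passed, estimate, p)} where the estimate is the
    relevant slope/intercept (or None for the ordering check).
    """

    def row(aid, par):
        r = report.comparison(aid, par)
        return float(r.estimate), float(r.p)

    out = {}
    e, p = row("core.dnds.foldchange", "slope")
    out["core_fold_slope_positive"] = (p < alpha and e > 0, e, p)
    e, p = row("core.dnds.foldchange", "intercept")
    out["core_fold_intercept_near_1"] = (p > alpha, e, p)
    e, p = row("expression.dnds.foldchange", "intercept")
    out["expr_fold_intercept_above_1"] = (p < alpha and e > 1, e, p)
    e, p = row("expression.dnds.foldchange", "slope")
    out["expr_fold_slope_flat"] = (p > alpha, e, p)
    e, p = row("expression.ds.foldchange", "intercept")
    out["ds_expr_fold_intercept_above_1"] = (p < alpha and e > 1, e, p)
    e, p = row("core.ds.foldchange", "intercept")
    out["ds_core_fold_intercept_near_1"] = (p > alpha, e, p)

    fits = report.fits
    cells = fits[(fits.analysis == "dnds") & fits.group.str.startswith("cell.")]
    slopes = dict(zip(cells.group, cells.slope))
    steepest = max(slopes, key=slopes.get)
    out["steepest_cell_is_large_core_low_expr"] = (
        steepest == "cell.large_core.low_expr",
        None,
        None,
    )
    four = report.comparisons[report.comparisons.analysis_id == "four_cell.dnds.slopes"]
    for other, name in (
        ("cell.large_core.high_expr", "ll_slope_exceeds_large_high"),
        ("cell.small_core.low_expr", "ll_slope_exceeds_small_low"),
    ):
        r = four[
            (four.group_a == "cell.large_core.low_expr") & (four.group_b == other)
        ].iloc[0]
        out[name] = (bool(r.p < alpha and r.estimate > 0), float(r.estimate), float(r.p))
    return out


# ---------------------------------------------------------------------------
# null calibration of the slope-equality test
# ---------------------------------------------------------------------------


def _null_config(seed: int, n_residues: int) -> SimulationConfig:
    """Both groups share one generative line; no expression effects."""
    return SimulationConfig(
        seed=seed,
        n_proteins_per_cell=1,
        residue_range=(n_residues, n_residues),
        rsa_beta={"large_core": (1.9, 4.0), "small_core": (1.9, 4.0)},
        dnds_intercept=0.15,
        dnds_slope={"large_core": 0.0025, "small_core": 0.0025},
        expression_omega_scale={"low_expr": 1.0, "high_expr": 1.0},
        syn_rate_scale={"low_expr": 1.0, "high_expr": 1.0},
        codon_bias_gamma={"low_expr": 0.0, "high_expr": 0.0},
        tree_newick=DEFAULT_TREE,
    )


def _simulate_group_records(config, n_proteins, label, streams, offset):
    """Simulate one group's proteins and return gapless residue records."""
    tree = PhyloTree.from_newick(config.tree_newick)
    cell = ("large_core", "low_expr")  # any cell: all cells identical here
    machinery: dict = {}
    records = []
    a, b = config.rsa_beta["large_core"]
    lo, _hi = config.residue_range
    for i in range(n_proteins):
        rng = np.random.default_rng(streams[offset + i])
        rsa = 100.0 * rng.beta(a, b, size=lo)
        aln, _ = simulate_codon_alignment(rsa, cell, config, rng, machinery=machinery)
        pid = f"{label}{i:03d}"
        for k in range(aln.n_codons):
            records.append(
                ResidueRecord(
                    protein_id=pid,
                    residue_index=k + 1,
                    rsa=float(rsa[k]),
                    codons=aln.codon_column(k),
                    gapless=True,
                )
            )
    return tree, records


def _group_slope_fit(records, edges, tree, taxa, B, rng, min_codons=30):
    binned = bin_residues(records, edges)
    pooled_members = [m for _, members in binned for m in members]
    pooled = concatenate_bin_alignment(pooled_members, taxa=taxa)
    shared = estimate_rates_ml(
        pooled, tree, pi_mode="empirical", omega_starts=(0.5,)
    )
    points = []
    for rsabin, members in binned:
        if len(members) < min_codons:
            continue
        aln = concatenate_bin_alignment(members, bin=rsabin, taxa=taxa)
        est = estimate_rates_profile(
            aln,
            tree,
            kappa=shared.kappa,
            branch_lengths=shared.branch_lengths,
            pi=shared.pi,
        )
        if est.undefined:
            continue
        boot = bootstrap_se(
            aln,
            tree,
            B=B,
            seed=int(rng.integers(2**31 - 1)),
            method="profile",
            estimate=est,
        )
        if boot.unreliable or not np.isfinite(boot.se_dnds) or boot.se_dnds <= 0:
            continue
        points.append((rsabin.x, est.dnds, boot.se_dnds))
    if len(points) < 3:
        raise ValueError("fewer than 3 usable bins in null run")
    return weighted_line_fit(points)


NULL_BIN_EDGES = tuple(float(e) for e in range(0, 91, 6)) + (100.0,)


def null_slope_pvalue(
    seed: int,
    *,
    n_proteins: int = 16,
    n_residues: int = 120,
    edges=NULL_BIN_EDGES,
    B: int = 400,
) -> float:
    """One reduced-size null pipeline run; returns the slope-equality p-value.

    Two groups of proteins are simulated from the same dN/dS-versus-RSA
    line, pushed through binning, shared-tree rate estimation with profile
    bootstrap errors, and weighted line fits; the slope-difference t-test
    p-value is returned. Under the null it is uniform, so rejection at
    alpha estimates the test's type-I error.
    """
    config = _null_config(seed, n_residues)
    config.validate()
    streams = np.random.SeedSequence(seed).spawn(2 * n_proteins + 1)
    rng = np.random.default_rng(streams[-1])
    tree, rec_a = _simulate_group_records(config, n_proteins, "A", streams, 0)
    _, rec_b = _simulate_group_records(config, n_proteins, "B", streams, n_proteins)
    taxa = tree.taxa
    fit_a = _group_slope_fit(rec_a, edges, tree, taxa, B, rng)
    fit_b = _group_slope_fit(rec_b, edges, tree, taxa, B, rng)
    return compare_line_params(fit_a, fit_b, "slope").p


def slope_test_rejection_rate(
    n_runs: int, seed: int, alpha: float = 0.05, **kwargs
) -> tuple[float, int]:
    """Fraction of null runs rejecting slope equality at `alpha`."""
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31 - 1)
    n_reject = 0
    n_ok = 0
    for s in seeds:
        try:
            p = null_slope_pvalue(int(s), **kwargs)
        except ValueError:
            continue
        n_ok += 1
        if p < alpha:
            n_reject += 1
    if n_ok == 0:
        raise RuntimeError("no null runs completed")
    return n_reject / n_ok, n_ok
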