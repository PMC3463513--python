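"""Single-ratio codon-model rate estimation on small fixed trees.

The estimator implements the Goldman–Yang codon substitution model with one
nonsynonymous/synonymous rate ratio (omega) shared across all sites of a
concatenated alignment, a transition/transversion ratio kappa, and codon
frequencies pi. The likelihood is computed by Felsenstein pruning on an
unrooted tree with branch lengths measured in expected substitutions per
codon; all free parameters (omega, kappa, branch lengths) are jointly
optimized by bounded quasi-Newton search on log-transformed parameters.

dN and dS are derived from the maximum-likelihood rate matrix using
mutational-opportunity site counts (the matrix with omega set to 1 defines
the proportion of nonsynonymous/synonymous sites), so that dN/dS equals the
estimated omega exactly.

Standard errors come from a codon-column bootstrap: resampled alignments of
identical size are re-estimated and the standard deviation of the replicate
estimates is reported. A Nei–Gojobori pathway-counting estimator is provided
as an independent cross-check; it shares no code with the likelihood path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .codons import (
    AA_OF_CODON,
    CODON_INDEX,
    N_SENSE,
    NUCLEOTIDES,
    PAIR_I,
    PAIR_J,
    PAIR_SYN,
    PAIR_TS,
    SENSE_CODONS,
    STOP_CODONS,
    CodonError,
    is_transition,
)

__all__ = [
    "GY94Params",
    "MatrixInfo",
    "PhyloTree",
    "RateEstimate",
    "BootstrapResult",
    "Ng86Result",
    "build_gy94_matrix",
    "tree_log_likelihood",
    "estimate_rates_ml",
    "estimate_rates_profile",
    "bootstrap_se",
    "estimate_with_se",
    "ng86_rates",
    "ng86_counts",
    "f3x4_frequencies",
]


# ---------------------------------------------------------------------------
# model parameters and rate matrix
# ---------------------------------------------------------------------------


@dataclass
class GY94Params:
    """Parameters of the single-ratio codon model.

    omega: nonsynonymous/synonymous rate ratio (>= 0).
    kappa: transition/transversion rate ratio (>= 0).
    pi: stationary codon frequencies over the 61 sense codons (sums to 1).
    branch_lengths: expected substitutions per codon, one per tree edge
        (ordering defined by PhyloTree.edge_order); optional until a tree
        is attached.
    """

    omega: float
    kappa: float
    pi: np.ndarray
    branch_lengths: np.ndarray | None = None


@dataclass
class MatrixInfo:
    """Bookkeeping for a built rate matrix."""

    prop_syn: float  # fraction of equilibrium flux that is synonymous
    prop_nonsyn: float
    flux: float  # mean substitutions/codon/unit time before normalization
    scale: float  # divisor applied to the raw matrix


def _validate_pi(pi: np.ndarray) -> np.ndarray:
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_SENSE,):
        raise ValueError(f"pi must have shape ({N_SENSE},), got {pi.shape}")
    if np.any(pi <= 0):
        raise ValueError("pi must be strictly positive")
    if abs(pi.sum() - 1.0) > 1e-6:
        raise ValueError(f"pi must sum to 1 (got {pi.sum():.8f})")
    return pi / pi.sum()


def _raw_pair_rates(omega, kappa, pi, syn_scale=1.0):
    rates = pi[PAIR_J] * np.where(PAIR_TS, kappa, 1.0) * syn_scale
    rates = rates * np.where(PAIR_SYN, 1.0, omega)
    return rates


def neutral_flux(kappa: float, pi: np.ndarray) -> float:
    """Mean substitutions/codon/unit time of the raw matrix at omega=1, s=1."""
    pi = _validate_pi(pi)
    rates = _raw_pair_rates(1.0, kappa, pi)
    return float(np.sum(pi[PAIR_I] * rates))


def build_gy94_matrix(
    params: GY94Params,
    *,
    syn_scale: float = 1.0,
    normalize: str = "unit",
) -> tuple[np.ndarray, MatrixInfo]:
    """Build the 61x61 instantaneous rate matrix.

    Off-diagonal q(i->j) is zero unless codons differ at a single nucleotide;
    otherwise proportional to pi_j, multiplied by kappa for transitions and by
    omega for nonsynonymous changes. `syn_scale` multiplies all single-step
    rates (used by the simulator to model a uniform deflation of the
    synonymous clock relative to a fixed neutral mutation-rate scale).

    normalize:
      "unit"    — mean flux is 1 substitution per codon per unit branch length
                  (estimation convention);
      "neutral" — divide by the flux of the omega=1, syn_scale=1 matrix so
                  branch lengths keep a fixed neutral-clock meaning across
                  sites with different omega (simulation convention);
      "none"    — raw matrix.
    """
    pi = _validate_pi(params.pi)
    if params.omega < 0 or params.kappa < 0:
        raise ValueError("omega and kappa must be non-negative")
    rates = _raw_pair_rates(params.omega, params.kappa, pi, syn_scale)
    Q = np.zeros((N_SENSE, N_SENSE))
    Q[PAIR_I, PAIR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    flux = float(np.sum(pi[PAIR_I] * rates))
    if normalize == "unit":
        scale = flux
    elif normalize == "neutral":
        scale = neutral_flux(params.kappa, pi)
    elif normalize == "none":
        scale = 1.0
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    if scale <= 0:
        raise ValueError("degenerate rate matrix (zero flux)")
    Q /= scale
    syn_flux = float(np.sum(pi[PAIR_I[PAIR_SYN]] * rates[PAIR_SYN]))
    info = MatrixInfo(
        prop_syn=syn_flux / flux if flux > 0 else np.nan,
        prop_nonsyn=1.0 - syn_flux / flux if flux > 0 else np.nan,
        flux=flux,
        scale=scale,
    )
    return Q, info


def site_proportions(kappa: float, pi: np.ndarray) -> tuple[float, float]:
    """Mutational-opportunity proportions (nonsyn, syn) at omega = 1."""
    pi = _validate_pi(pi)
    rates = _raw_pair_rates(1.0, kappa, pi)
    total = np.sum(pi[PAIR_I] * rates)
    syn = np.sum(pi[PAIR_I[PAIR_SYN]] * rates[PAIR_SYN])
    return float(1.0 - syn / total), float(syn / total)


def _eigendecompose(Q: np.ndarray, pi: np.ndarray):
    """Symmetric eigendecomposition of a pi-reversible rate matrix."""
    d = np.sqrt(pi)
    B = Q * d[:, None] / d[None, :]
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    return w, U, d


def _transition_matrix(eig, t: float) -> np.ndarray:
    w, U, d = eig
    P = (U * np.exp(w * t)) @ U.T
    P = P / d[:, None] * d[None, :]
    np.clip(P, 1e-300, None, out=P)
    return P


def f3x4_frequencies(codon_matrix: np.ndarray) -> np.ndarray:
    """Codon frequencies from position-specific nucleotide frequencies (F3x4).

    `codon_matrix` holds sense-codon indices, any shape; frequencies are
    pooled over all taxa. A pseudo-count keeps every frequency positive.
    """
    idx = np.asarray(codon_matrix, dtype=np.intp).ravel()
    if idx.size == 0:
        raise ValueError("cannot estimate codon frequencies from empty data")
    counts = np.zeros((3, 4))
    nt_index = {nt: k for k, nt in enumerate(NUCLEOTIDES)}
    codon_nt = np.array(
        [[nt_index[c[p]] for p in range(3)] for c in SENSE_CODONS], dtype=np.intp
    )
    for p in range(3):
        counts[p] = np.bincount(codon_nt[idx, p], minlength=4)
    counts += 0.5
    freq = counts / counts.sum(axis=1, keepdims=True)
    pi = freq[0, codon_nt[:, 0]] * freq[1, codon_nt[:, 1]] * freq[2, codon_nt[:, 2]]
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    name: str | None
    length: float | None  # edge length to parent; None for the root
    children: list["_Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """A small fixed-topology tree for pruning likelihoods.

    Parsed from newick. A bifurcating root is collapsed (derooted) whenever
    the tree has more than two tips, so that the 4-taxon case carries the
    five identifiable branch lengths of the unrooted topology.
    """

    def __init__(self, root: _Node):
        self.root = root
        self._edges: list[_Node] = []
        self._collect_edges(root)

    def _collect_edges(self, node: _Node):
        for child in node.children:
            self._edges.append(child)
            self._collect_edges(child)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(nd) -> _Node:
            name = nd.taxon.label if nd.taxon is not None else None
            length = nd.edge.length
            out = _Node(name=name, length=length)
            out.children = [convert(c) for c in nd.child_nodes()]
            return out

        root = convert(tree.seed_node)
        root.length = None
        n_tips = sum(1 for _ in cls(root).tips())
        if len(root.children) == 2 and n_tips > 2:
            # deroot: merge the two root edges into one internal edge
            a, b = root.children
            keep, move = (a, b) if a.children else (b, a)
            move = _Node(
                name=move.name,
                length=(move.length or 0.0) + (keep.length or 0.0),
                children=move.children,
            )
            root = _Node(name=keep.name, length=None, children=keep.children + [move])
        return cls(root)

    def tips(self):
        def walk(node):
            if node.is_tip:
                yield node
            for c in node.children:
                yield from walk(c)

        yield from walk(self.root)

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tips())

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    @property
    def branch_lengths(self) -> np.ndarray:
        return np.array([e.length if e.length is not None else np.nan for e in self._edges])

    def with_branch_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        lengths = np.asarray(lengths, dtype=float)
        if lengths.shape != (self.n_edges,):
            raise ValueError(f"expected {self.n_edges} branch lengths")
        if np.any(~np.isfinite(lengths)) or np.any(lengths < 0):
            raise ValueError("branch lengths must be finite and non-negative")

        import copy

        root = copy.deepcopy(self.root)
        out = PhyloTree(root)
        for edge, t in zip(out._edges, lengths):
            edge.length = float(t)
        return out

    def validate_against(self, taxa) -> None:
        if set(self.taxa) != set(taxa):
            raise ValueError(
                f"tree tips {sorted(self.taxa)} do not match alignment taxa {sorted(taxa)}"
            )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _pattern_counts(codons: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Compress alignment columns (n_taxa x n_cols) into unique patterns."""
    cols = np.ascontiguousarray(codons.T)
    patterns, counts = np.unique(cols, axis=0, return_counts=True)
    return patterns.T, counts.astype(float)


def _pattern_log_likelihoods(patterns, tree: PhyloTree, taxon_pos, eig, lengths_by_id):
    """Log-likelihood of each codon-column pattern under the pruning recursion."""

    def partial(node: _Node) -> np.ndarray:
        P = _transition_matrix(eig, lengths_by_id[id(node)])
        if node.is_tip:
            obs = patterns[taxon_pos[node.name]]
            return P[:, obs]
        return P @ down(node)

    def down(node: _Node) -> np.ndarray:
        out = None
        for child in node.children:
            term = partial(child)
            out = term if out is None else out * term
        return out

    pi = eig[2] ** 2
    root_partial = down(tree.root)
    like = pi @ root_partial
    return np.log(like)


def tree_log_likelihood(alignment, tree: PhyloTree, params: GY94Params) -> float:
    """Log-likelihood of a gapless codon alignment under the single-ratio model.

    `alignment` is anything with `.taxa` and `.codons` (sense-codon index
    matrix of shape n_taxa x n_codons), e.g. a BinnedAlignment. The result is
    invariant to root placement (pulley principle) because the model is
    reversible.
    """
    taxa = list(alignment.taxa)
    codons = np.asarray(alignment.codons, dtype=np.intp)
    if codons.size and (codons.min() < 0 or codons.max() >= N_SENSE):
        bad = int(np.argwhere((codons < 0) | (codons >= N_SENSE))[0][1])
        raise CodonError(f"invalid codon state at column {bad}")
    tree.validate_against(taxa)
    if params.branch_lengths is None:
        lengths = tree.branch_lengths
        if np.any(~np.isfinite(lengths)):
            raise ValueError("tree has missing branch lengths and params provide none")
        work_tree = tree
    else:
        work_tree = tree.with_branch_lengths(params.branch_lengths)
    Q, _ = build_gy94_matrix(params, normalize="unit")
    eig = _eigendecompose(Q, _validate_pi(params.pi))
    patterns, counts = _pattern_counts(codons)
    taxon_pos = {t: k for k, t in enumerate(taxa)}
    lengths_by_id = {id(e): e.length for e in work_tree._edges}
    logs = _pattern_log_likelihoods(patterns, work_tree, taxon_pos, eig, lengths_by_id)
    return float(np.sum(counts * logs))


# ---------------------------------------------------------------------------
# maximum-likelihood estimation
# ---------------------------------------------------------------------------


@dataclass
class RateEstimate:
    """Point estimates (and, once bootstrapped, standard errors) for one bin."""

    dnds: float
    dn: float
    ds: float
    se_dnds: float | None = None
    se_dn: float | None = None
    se_ds: float | None = None
    n_codons: int = 0
    log_likelihood: float = np.nan
    converged: bool = False
    undefined: bool = False  # no synonymous signal: dN/dS not interpretable
    kappa: float = np.nan
    branch_lengths: np.ndarray | None = None
    pi: np.ndarray | None = None

    @property
    def omega(self) -> float:
        return self.dnds


_OMEGA_BOUNDS = (1e-4, 50.0)
_KAPPA_BOUNDS = (0.05, 100.0)
_T_BOUNDS = (1e-9, 10.0)
_DS_UNDEFINED = 1e-7


class _Objective:
    """Negative log-likelihood over log-transformed (omega, kappa, lengths)."""

    def __init__(self, patterns, counts, tree, taxa, pi):
        self.patterns = patterns
        self.counts = counts
        self.tree = tree
        self.taxon_pos = {t: k for k, t in enumerate(taxa)}
        self.pi = pi
        self.n_edges = tree.n_edges

    def unpack(self, x):
        omega = math.exp(x[0])
        kappa = math.exp(x[1])
        lengths = np.exp(x[2:])
        return omega, kappa, lengths

    def __call__(self, x):
        omega, kappa, lengths = self.unpack(x)
        Q, _ = build_gy94_matrix(
            GY94Params(omega=omega, kappa=kappa, pi=self.pi), normalize="unit"
        )
        eig = _eigendecompose(Q, self.pi)
        lengths_by_id = {id(e): t for e, t in zip(self.tree._edges, lengths)}
        logs = _pattern_log_likelihoods(
            self.patterns, self.tree, self.taxon_pos, eig, lengths_by_id
        )
        return -float(np.sum(self.counts * logs))


def _initial_branch_lengths(patterns, counts, tree, taxa) -> np.ndarray:
    """Crude starting lengths from the mean pairwise codon difference."""
    n = counts.sum()
    taxon_pos = {t: k for k, t in enumerate(taxa)}
    diffs = []
    for a, b in itertools.combinations(range(len(taxa)), 2):
        d = np.sum(counts * (patterns[a] != patterns[b])) / n
        diffs.append(d)
    mean_d = max(1e-3, float(np.mean(diffs)))
    # spread the mean path length over the edges of the tree
    per_edge = max(5e-3, mean_d / max(2, tree.n_edges - 1))
    return np.full(tree.n_edges, per_edge)


def _derive_rates(omega, kappa, pi, lengths) -> tuple[float, float]:
    """Tree-summed dN and dS per site under mutational-opportunity counts."""
    params = GY94Params(omega=omega, kappa=kappa, pi=pi)
    _, info = build_gy94_matrix(params, normalize="unit")
    rho_n1, rho_s1 = site_proportions(kappa, pi)
    T = float(np.sum(lengths))
    dn = T * info.prop_nonsyn / (3.0 * rho_n1)
    ds = T * info.prop_syn / (3.0 * rho_s1)
    return dn, ds


def _mle(
    patterns,
    counts,
    tree: PhyloTree,
    taxa,
    pi,
    *,
    omega_starts=(0.1, 0.5, 1.5),
    kappa_init=2.0,
    warm_start: np.ndarray | None = None,
    tol=1e-8,
):
    obj = _Objective(patterns, counts, tree, taxa, pi)
    bounds = (
        [tuple(np.log(_OMEGA_BOUNDS)), tuple(np.log(_KAPPA_BOUNDS))]
        + [tuple(np.log(_T_BOUNDS))] * tree.n_edges
    )
    starts = []
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    else:
        t0 = _initial_branch_lengths(patterns, counts, tree, taxa)
        for w0 in omega_starts:
            starts.append(
                np.concatenate([[math.log(w0), math.log(kappa_init)], np.log(t0)])
            )
    best = None
    for x0 in starts:
        res = minimize(
            obj,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    omega, kappa, lengths = obj.unpack(best.x)
    return omega, kappa, lengths, -best.fun, bool(best.success), best.x


def estimate_rates_ml(
    alignment,
    topology: PhyloTree,
    *,
    pi_mode: str = "F3x4",
    pi: np.ndarray | None = None,
    omega_starts=(0.1, 0.5, 1.5),
    kappa_init: float = 2.0,
    warm_start: np.ndarray | None = None,
    tol: float = 1e-8,
) -> RateEstimate:
    """Jointly estimate omega, kappa and branch lengths; derive dN and dS.

    pi_mode: "F3x4" (position-specific nucleotide frequencies, default),
    "empirical" (observed codon frequencies), or "uniform"; `pi` overrides.
    Alignments with no variation yield dN = dS = 0 with dN/dS undefined;
    alignments with no synonymous signal (dS below 1e-7) are flagged
    undefined as well.
    """
    codons = np.asarray(alignment.codons, dtype=np.intp)
    if codons.size == 0:
        raise ValueError("cannot estimate rates from an empty alignment")
    taxa = list(alignment.taxa)
    topology.validate_against(taxa)
    n_codons = codons.shape[1]
    patterns, counts = _pattern_counts(codons)

    if pi is None:
        if pi_mode == "F3x4":
            pi = f3x4_frequencies(codons)
        elif pi_mode == "empirical":
            raw = np.bincount(codons.ravel(), minlength=N_SENSE).astype(float) + 0.5
            pi = raw / raw.sum()
        elif pi_mode == "uniform":
            pi = np.full(N_SENSE, 1.0 / N_SENSE)
        else:
            raise ValueError(f"unknown pi_mode {pi_mode!r}")
    pi = _validate_pi(pi)

    invariant = all(np.all(p == p[0]) for p in patterns.T.reshape(-1, len(taxa)))
    if invariant:
        lnl = float(np.sum(counts * np.log(pi[patterns[0]])))
        return RateEstimate(
            dnds=np.nan,
            dn=0.0,
            ds=0.0,
            n_codons=n_codons,
            log_likelihood=lnl,
            converged=True,
            undefined=True,
            pi=pi,
        )

    omega, kappa, lengths, lnl, ok, xhat = _mle(
        patterns,
        counts,
        topology,
        taxa,
        pi,
        omega_starts=omega_starts,
        kappa_init=kappa_init,
        warm_start=warm_start,
        tol=tol,
    )
    dn, ds = _derive_rates(omega, kappa, pi, lengths)
    undefined = ds < _DS_UNDEFINED
    est = RateEstimate(
        dnds=np.nan if undefined else omega,
        dn=dn,
        ds=ds,
        n_codons=n_codons,
        log_likelihood=lnl,
        converged=ok,
        undefined=undefined,
        kappa=kappa,
        branch_lengths=lengths,
        pi=pi,
    )
    est._xhat = xhat  # cached optimizer solution for warm-started bootstrap
    return est


def estimate_rates_profile(
    alignment,
    topology: PhyloTree,
    *,
    kappa: float,
    branch_lengths: np.ndarray,
    pi: np.ndarray,
) -> RateEstimate:
    """Estimate omega alone, holding kappa and branch lengths fixed.

    Used when many small bins share one tree: the nuisance parameters are
    estimated once from the pooled group alignment and each bin profiles only
    the rate ratio. Substantially faster than the joint fit and appropriate
    when bins are subsets of the same concatenated data.
    """
    codons = np.asarray(alignment.codons, dtype=np.intp)
    if codons.size == 0:
        raise ValueError("cannot estimate rates from an empty alignment")
    taxa = list(alignment.taxa)
    topology.validate_against(taxa)
    pi = _validate_pi(pi)
    patterns, counts = _pattern_counts(codons)
    if all(np.all(p == p[0]) for p in patterns.T):
        lnl = float(np.sum(counts * np.log(pi[patterns[0]])))
        return RateEstimate(
            dnds=np.nan, dn=0.0, ds=0.0, n_codons=codons.shape[1],
            log_likelihood=lnl, converged=True, undefined=True,
            kappa=kappa, branch_lengths=np.asarray(branch_lengths, float), pi=pi,
        )
    taxon_pos = {t: k for k, t in enumerate(taxa)}
    lengths = np.asarray(branch_lengths, dtype=float)
    lengths_by_id = {id(e): t for e, t in zip(topology._edges, lengths)}

    def neg_ll(logw):
        Q, _ = build_gy94_matrix(
            GY94Params(omega=math.exp(logw), kappa=kappa, pi=pi), normalize="unit"
        )
        eig = _eigendecompose(Q, pi)
        logs = _pattern_log_likelihoods(patterns, topology, taxon_pos, eig, lengths_by_id)
        return -float(np.sum(counts * logs))

    res = minimize_scalar(
        neg_ll,
        bounds=(math.log(_OMEGA_BOUNDS[0]), math.log(_OMEGA_BOUNDS[1])),
        method="bounded",
        options={"xatol": 1e-7},
    )
    omega = math.exp(res.x)
    dn, ds = _derive_rates(omega, kappa, pi, lengths)
    undefined = ds < _DS_UNDEFINED
    return RateEstimate(
        dnds=np.nan if undefined else omega,
        dn=dn,
        ds=ds,
        n_codons=codons.shape[1],
        log_likelihood=-res.fun,
        converged=bool(res.success),
        undefined=undefined,
        kappa=kappa,
        branch_lengths=lengths,
        pi=pi,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    se_dnds: float
    se_dn: float
    se_ds: float
    n_replicates: int
    n_undefined: int
    unreliable: bool
    method: str


def _profile_omega_curve(patterns, tree, taxa, pi, kappa, lengths, omega_grid):
    """Per-pattern log-likelihood over a grid of omega (kappa, lengths fixed)."""
    taxon_pos = {t: k for k, t in enumerate(taxa)}
    lengths_by_id = {id(e): t for e, t in zip(tree._edges, lengths)}
    out = np.empty((len(omega_grid), patterns.shape[1]))
    for g, w in enumerate(omega_grid):
        Q, _ = build_gy94_matrix(GY94Params(omega=w, kappa=kappa, pi=pi), normalize="unit")
        eig = _eigendecompose(Q, pi)
        out[g] = _pattern_log_likelihoods(patterns, tree, taxon_pos, eig, lengths_by_id)
    return out


def _quadratic_argmax(x, y, k):
    """Refine a grid argmax by fitting a parabola through three points."""
    if k == 0 or k == len(x) - 1:
        return x[k]
    x0, x1, x2 = x[k - 1], x[k], x[k + 1]
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 * x2 * (y0 - y1) + x1 * x1 * (y2 - y0) + x0 * x0 * (y1 - y2)) / denom
    if a >= 0:
        return x1
    return float(np.clip(-b / (2 * a), x0, x2))


def bootstrap_se(
    alignment,
    topology: PhyloTree,
    B: int = 100,
    seed: int | None = None,
    *,
    method: str = "full",
    estimate: RateEstimate | None = None,
    pi_mode: str = "F3x4",
) -> BootstrapResult:
    """Codon-column bootstrap standard errors for dN/dS, dN and dS.

    Each replicate resamples the alignment's codon columns with replacement
    (keeping the column count fixed) and re-estimates the rates.

    method "full" re-optimizes all parameters per replicate, warm-started at
    the original MLE. method "profile" re-optimizes omega only, holding kappa
    and branch lengths at the full-data MLE and sharing a cached
    omega-profile across replicates; it is used for large scaled-down
    simulation studies where thousands of bootstrap fits are needed.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replicates")
    codons = np.asarray(alignment.codons, dtype=np.intp)
    if codons.size == 0:
        raise ValueError("cannot bootstrap an empty alignment")
    n = codons.shape[1]
    rng = np.random.default_rng(seed)
    if estimate is None:
        estimate = estimate_rates_ml(alignment, topology, pi_mode=pi_mode)
    if estimate.undefined or estimate.branch_lengths is None:
        return BootstrapResult(np.nan, np.nan, np.nan, B, B, True, method)

    patterns, counts = _pattern_counts(codons)
    taxa = list(alignment.taxa)
    pi = estimate.pi
    probs = counts / counts.sum()

    values = np.full((B, 3), np.nan)  # omega, dn, ds
    n_undef = 0

    if method == "full":
        xhat = getattr(estimate, "_xhat", None)
        for b in range(B):
            rep_counts = rng.multinomial(n, probs).astype(float)
            keep = rep_counts > 0
            try:
                omega, kappa, lengths, _, ok, _ = _mle(
                    patterns[:, keep],
                    rep_counts[keep],
                    topology,
                    taxa,
                    pi,
                    warm_start=xhat,
                    tol=1e-6,
                )
            except Exception:
                n_undef += 1
                continue
            dn, ds = _derive_rates(omega, kappa, pi, lengths)
            if ds < _DS_UNDEFINED:
                n_undef += 1
                continue
            values[b] = (omega, dn, ds)
    elif method == "profile":
        w_hat = estimate.dnds
        grid = np.geomspace(
            max(_OMEGA_BOUNDS[0], w_hat / 5.0), min(_OMEGA_BOUNDS[1], w_hat * 5.0), 21
        )
        curve = _profile_omega_curve(
            patterns, topology, taxa, pi, estimate.kappa, estimate.branch_lengths, grid
        )
        # second shared profile over a tree-scale factor: dN and dS track the
        # replicate's total substitution signal, not just its N/S partition
        T = estimate.branch_lengths
        scale_grid = np.geomspace(1.0 / 3.0, 3.0, 15)
        Q, _ = build_gy94_matrix(
            GY94Params(omega=w_hat, kappa=estimate.kappa, pi=pi), normalize="unit"
        )
        eig = _eigendecompose(Q, pi)
        taxon_pos = {t: k for k, t in enumerate(taxa)}
        scale_curve = np.empty((len(scale_grid), patterns.shape[1]))
        for g, c in enumerate(scale_grid):
            lengths_by_id = {id(e): c * t for e, t in zip(topology._edges, T)}
            scale_curve[g] = _pattern_log_likelihoods(
                patterns, topology, taxon_pos, eig, lengths_by_id
            )
        # closed-form dN/dS derivation: the flux split depends on omega only
        # through the scalar synonymous/nonsynonymous opportunity sums
        rates1 = _raw_pair_rates(1.0, estimate.kappa, pi)
        a_total = float(np.sum(pi[PAIR_I] * rates1))
        a_syn = float(np.sum(pi[PAIR_I[PAIR_SYN]] * rates1[PAIR_SYN]))
        a_non = a_total - a_syn
        rho_n1, rho_s1 = a_non / a_total, a_syn / a_total
        t_total = float(np.sum(T))
        for b in range(B):
            rep_counts = rng.multinomial(n, probs).astype(float)
            ll = curve @ rep_counts
            k = int(np.argmax(ll))
            omega = _quadratic_argmax(grid, ll, k)
            ll_c = scale_curve @ rep_counts
            kc = int(np.argmax(ll_c))
            c_b = _quadratic_argmax(scale_grid, ll_c, kc)
            flux_n = omega * a_non
            flux_tot = flux_n + a_syn
            dn = c_b * t_total * (flux_n / flux_tot) / (3.0 * rho_n1)
            ds = c_b * t_total * (a_syn / flux_tot) / (3.0 * rho_s1)
            if ds < _DS_UNDEFINED:
                n_undef += 1
                continue
            values[b] = (omega, dn, ds)
    else:
        raise ValueError(f"unknown bootstrap method {method!r}")

    ok = ~np.isnan(values[:, 0])
    n_ok = int(ok.sum())
    # replicates pinned at the omega search boundary carry no curvature
    # information; a majority of them makes the SE meaningless
    at_bound = np.sum(
        (values[ok, 0] <= _OMEGA_BOUNDS[0] * 1.05)
        | (values[ok, 0] >= _OMEGA_BOUNDS[1] * 0.95)
    )
    unreliable = n_undef > B / 2 or n_ok < 2 or at_bound > n_ok / 2
    if n_ok >= 2:
        sds = values[ok].std(axis=0, ddof=1)
    else:
        sds = np.full(3, np.nan)
    return BootstrapResult(
        se_dnds=float(sds[0]),
        se_dn=float(sds[1]),
        se_ds=float(sds[2]),
        n_replicates=B,
        n_undefined=n_undef,
        unreliable=unreliable,
        method=method,
    )


def estimate_with_se(
    alignment,
    topology: PhyloTree,
    B: int = 100,
    seed: int | None = None,
    *,
    method: str = "full",
    pi_mode: str = "F3x4",
    **kwargs,
) -> RateEstimate:
    """Convenience wrapper: ML point estimates plus bootstrap standard errors."""
    est = estimate_rates_ml(alignment, topology, pi_mode=pi_mode, **kwargs)
    if est.undefined:
        return est
    boot = bootstrap_se(
        alignment, topology, B=B, seed=seed, method=method, estimate=est, pi_mode=pi_mode
    )
    return replace(est, se_dnds=boot.se_dnds, se_dn=boot.se_dn, se_ds=boot.se_ds)


# ---------------------------------------------------------------------------
# Nei–Gojobori counting oracle
# ---------------------------------------------------------------------------


@dataclass
class Ng86Result:
    dn: float
    ds: float
    dnds: float
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


def _codon_syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (changes to stops excluded)."""
    aa = AA_OF_CODON[codon]
    n_syn = 0
    n_valid = 0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            n_valid += 1
            if AA_OF_CODON[alt] == aa:
                n_syn += 1
    if n_valid == 0:
        return 0.0
    return 3.0 * n_syn / n_valid


def _pair_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over shortest paths."""
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if AA_OF_CODON[cur] == AA_OF_CODON[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            paths.append((syn, nonsyn))
    if not paths:  # all paths pass through stops; fall back to counting anyway
        paths = []
        for order in itertools.permutations(diff_pos):
            cur = c1
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                a = AA_OF_CODON.get(cur)
                b = AA_OF_CODON.get(nxt)
                if a is not None and b is not None and a == b:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            paths.append((syn, nonsyn))
    syn = float(np.mean([p[0] for p in paths]))
    nonsyn = float(np.mean([p[1] for p in paths]))
    return syn, nonsyn


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(
            f"proportion of differences {p:.4f} >= 3/4: Jukes-Cantor correction undefined"
        )
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_counts(seq1, seq2) -> tuple[float, float, float, float]:
    """Pathway-enumeration site and difference counts for a sequence pair.

    Returns (syn_sites, nonsyn_sites, syn_diffs, nonsyn_diffs) before any
    distance correction, so single-codon enumeration examples are checkable
    even where the correction saturates.
    """
    from .codons import codons_of_sequence

    cod1 = codons_of_sequence(seq1) if isinstance(seq1, str) else list(seq1)
    cod2 = codons_of_sequence(seq2) if isinstance(seq2, str) else list(seq2)
    if len(cod1) != len(cod2):
        raise ValueError("sequences must have equal codon length")
    if not cod1:
        raise ValueError("empty sequences")
    for c in itertools.chain(cod1, cod2):
        if c not in CODON_INDEX:
            raise CodonError(f"non-sense codon {c!r}")
    S = sum((_codon_syn_sites(a) + _codon_syn_sites(b)) / 2 for a, b in zip(cod1, cod2))
    N = 3.0 * len(cod1) - S
    Sd = Nd = 0.0
    for a, b in zip(cod1, cod2):
        s, n = _pair_path_differences(a, b)
        Sd += s
        Nd += n
    return S, N, Sd, Nd


def ng86_rates(seq1: str, seq2: str) -> Ng86Result:
    """Nei–Gojobori (1986) dN and dS for a pair of gapless coding sequences.

    Synonymous/nonsynonymous sites are counted per codon by enumerating the
    three alternative nucleotides at each position (stop-producing changes
    excluded); observed differences are averaged over all shortest mutational
    pathways between each codon pair, and the Jukes-Cantor correction is
    applied to both proportions. Exhaustive enumeration throughout: this is
    an oracle, not a production estimator.
    """
    S, N, Sd, Nd = ng86_counts(seq1, seq2)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    ds = _jukes_cantor(ps) if Sd > 0 else 0.0
    dn = _jukes_cantor(pn) if Nd > 0 else 0.0
    dnds = dn / ds if ds > 0 else np.nan
    return Ng86Result(
        dn=dn, ds=ds, dnds=dnds, syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd
    )


# ---------------------------------------------------------------------------
# small direct oracle used in tests (matrix exponential, no pruning)
# ---------------------------------------------------------------------------


def pairwise_log_likelihood_direct(
    codons1: np.ndarray, codons2: np.ndarray, t: float, params: GY94Params
) -> float:
    """Two-sequence likelihood via a direct matrix exponential (test oracle)."""
    Q, _ = build_gy94_matrix(params, normalize="unit")
    P = expm(Q * t)
    pi = _validate_pi(params.pi)
    return float(np.sum(np.log(pi[codons1] * P[codons1, codons2])))
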