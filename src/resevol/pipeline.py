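"""End-to-end analysis pipeline: ingest/simulate -> group -> bin -> rates ->
CAI -> fits -> comparisons, with every stage reading and writing plain files.

The monolithic run is literally the chained sequence of stage functions, so
any stage can be re-run standalone from the previous stage's outputs and
the results are identical. All randomness (bootstrap resampling, synthetic
data) derives from the single run seed; reruns with the same config and
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment_binning import (
    DEFAULT_BIN_EDGES,
    CodonAlignment,
    ResidueRecord,
    assign_groups,
    bin_residues,
    concatenate_bin_alignment,
    map_codons_to_structure,
)
from .codon_bias import AdaptivenessTable, bootstrap_cai_se, compute_cai, relative_adaptiveness
from .codon_evolution import (
    PhyloTree,
    bootstrap_se,
    estimate_rates_ml,
    estimate_rates_profile,
)
from .codons import SENSE_CODONS
from .regression_stats import (
    compare_line_params,
    fold_change_curve,
    test_param_null,
    weighted_line_fit,
    LineFit,
)
from .structure_rsa import RSAProfile
from .synthetic_data import SimulationConfig, simulate_study, write_study

logger = logging.getLogger("resevol.pipeline")

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either `simulate` holds a SimulationConfig or `study_dir` points to a
    directory with the standard study layout (alignments/*.fasta, rsa/*.tsv,
    expression.tsv, optionally adaptiveness.tsv).
    """

    outdir: str
    seed: int
    simulate: SimulationConfig | None = None
    study_dir: str | None = None
    taxa: tuple[str, ...] | None = None  # defaults to estimation-tree tip order
    grouping_fraction: float = 1.0 / 3.0
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    bin_x_mode: str = "mean"
    bootstrap_B: int = 100
    bootstrap_method: str = "full"  # or "profile"
    rates_mode: str = "per_bin"  # or "shared_tree"
    pi_mode: str = "empirical"  # codon-frequency convention for estimation
    min_bin_codons: int = 10
    tree_newick: str = "((cerevisiae,paradoxus),mikatae,bayanus);"
    analyses: tuple[str, ...] = ("dnds", "dn", "ds", "cai")
    comparisons: tuple[str, ...] = ("core", "expression", "four_cell")
    cai_reference: str = "study"  # "study", "top_decile", or a TSV path
    expression_column: str = "expression"

    def validate(self) -> None:
        if self.simulate is None and self.study_dir is None:
            raise ValueError("either a simulate block or a study_dir is required")
        if not 0 < self.grouping_fraction <= 0.5:
            raise ValueError("grouping fraction must lie in (0, 0.5]")
        if self.bootstrap_B < 2:
            raise ValueError("bootstrap_B must be >= 2")
        if self.rates_mode not in ("per_bin", "shared_tree"):
            raise ValueError(f"unknown rates_mode {self.rates_mode!r}")
        if self.bootstrap_method not in ("full", "profile"):
            raise ValueError(f"unknown bootstrap_method {self.bootstrap_method!r}")
        for c in self.comparisons:
            if c not in ("core", "expression", "four_cell"):
                raise ValueError(f"unknown comparison {c!r}")
        for a in self.analyses:
            if a not in ("dnds", "dn", "ds", "cai"):
                raise ValueError(f"unknown analysis {a!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("simulate") is not None:
            raw["simulate"] = SimulationConfig(**raw["simulate"])
        for key in ("bin_edges", "analyses", "comparisons", "taxa"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    outdir: Path
    groups: pd.DataFrame
    rates: pd.DataFrame
    cai: pd.DataFrame | None
    fits: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict
    warnings: list = field(default_factory=list)

    def comparison(self, analysis_id: str, parameter: str) -> pd.Series:
        df = self.comparisons
        hit = df[(df["analysis_id"] == analysis_id) & (df["parameter"] == parameter)]
        if hit.empty:
            raise KeyError(f"no comparison {analysis_id}/{parameter}")
        return hit.iloc[0]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _stable_seed(seed: int, *tokens) -> np.random.SeedSequence:
    keys = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=tuple(keys))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _study_dir(cfg: RunConfig) -> Path:
    if cfg.simulate is not None:
        return Path(cfg.outdir) / "study"
    return Path(cfg.study_dir)


def _estimation_taxa(cfg: RunConfig) -> tuple[str, ...]:
    if cfg.taxa is not None:
        return tuple(cfg.taxa)
    return PhyloTree.from_newick(cfg.tree_newick).taxa


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(cfg: RunConfig) -> Path:
    """Materialize the synthetic study (no-op for file-based inputs)."""
    study = _study_dir(cfg)
    if cfg.simulate is not None:
        sim_cfg = cfg.simulate
        write_study(simulate_study(sim_cfg), study)
        logger.info("simulated study with %d proteins", 4 * sim_cfg.n_proteins_per_cell)
    return study


def stage_records(cfg: RunConfig) -> None:
    """Join alignments with RSA profiles into the residue-record table."""
    out = Path(cfg.outdir)
    study = _study_dir(cfg)
    taxa = _estimation_taxa(cfg)
    expression = pd.read_csv(study / "expression.tsv", sep="\t")
    expr_col = cfg.expression_column
    if expr_col not in expression.columns:
        raise ValueError(f"expression table lacks column {expr_col!r}")
    rows = []
    protein_rows = []
    n_dropped = 0
    for fasta in sorted((study / "alignments").glob("*.fasta")):
        pid = fasta.stem
        aln = CodonAlignment.from_fasta(fasta, taxa)
        rsa = RSAProfile.from_tsv(study / "rsa" / f"{pid}.tsv")
        records = map_codons_to_structure(aln, rsa, pid)
        values = [r.rsa for r in records if not np.isnan(r.rsa)]
        protein_rows.append({"protein_id": pid, "avg_rsa": float(np.mean(values))})
        for r in records:
            if not r.gapless:
                n_dropped += 1
            row = {
                "protein_id": r.protein_id,
                "residue_index": r.residue_index,
                "rsa": r.rsa,
                "gapless": r.gapless,
            }
            for t, codon in zip(taxa, r.codons):
                row[f"codon_{t}"] = codon
            rows.append(row)
    if not rows:
        raise ValueError(f"no alignments found under {study}")
    records_df = pd.DataFrame(rows)
    proteins = pd.DataFrame(protein_rows).merge(
        expression[["protein_id", expr_col]].rename(columns={expr_col: "expression"}),
        on="protein_id",
        how="inner",
    )
    logger.info(
        "records: %d residues, %d dropped as gapped/missing", len(records_df), n_dropped
    )
    _write_tsv(records_df, out / "records.tsv")
    _write_tsv(proteins, out / "proteins.tsv")


def stage_group(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    proteins = pd.read_csv(out / "proteins.tsv", sep="\t")
    groups = assign_groups(proteins, fraction=cfg.grouping_fraction)
    _write_tsv(groups, out / "groups.tsv")
    logger.info(
        "groups: %s", groups.groupby(["core_class", "expr_class"]).size().to_dict()
    )


def _group_definitions(cfg: RunConfig, groups: pd.DataFrame) -> dict[str, set]:
    defs: dict[str, set] = {}
    if "core" in cfg.comparisons:
        for label in ("large_core", "small_core"):
            defs[f"core.{label}"] = set(groups.loc[groups.core_class == label, "protein_id"])
    if "expression" in cfg.comparisons:
        for label in ("low_expr", "high_expr"):
            defs[f"expr.{label}"] = set(groups.loc[groups.expr_class == label, "protein_id"])
    if "four_cell" in cfg.comparisons:
        for c in ("large_core", "small_core"):
            for e in ("low_expr", "high_expr"):
                defs[f"cell.{c}.{e}"] = set(
                    groups.loc[
                        (groups.core_class == c) & (groups.expr_class == e), "protein_id"
                    ]
                )
    return defs


def stage_bin(cfg: RunConfig) -> None:
    """Filter each group's gapless records and bin them with shared edges."""
    out = Path(cfg.outdir)
    taxa = _estimation_taxa(cfg)
    records = pd.read_csv(out / "records.tsv", sep="\t")
    groups = pd.read_csv(out / "groups.tsv", sep="\t")
    defs = _group_definitions(cfg, groups)
    gapless = records[records.gapless].copy()
    bin_dir = out / "bins"
    bin_dir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for gname, pids in sorted(defs.items()):
        sub = gapless[gapless.protein_id.isin(pids)]
        recs = [
            ResidueRecord(
                protein_id=row.protein_id,
                residue_index=int(row.residue_index),
                rsa=float(row.rsa),
                codons=tuple(getattr(row, f"codon_{t}") for t in taxa),
                gapless=True,
            )
            for row in sub.itertuples(index=False)
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            binned = bin_residues(recs, cfg.bin_edges, x_mode=cfg.bin_x_mode)
        for rsabin, members in binned:
            if members:
                baln = concatenate_bin_alignment(members, bin=rsabin, taxa=taxa)
                seqs = ["".join(SENSE_CODONS[i] for i in baln.codons[t]) for t in range(len(taxa))]
                CodonAlignment(taxa, tuple(seqs)).to_fasta(
                    bin_dir / f"{gname}.bin{rsabin.index:02d}.fasta"
                )
            index_rows.append(
                {
                    "group": gname,
                    "bin_index": rsabin.index,
                    "lo": rsabin.lo,
                    "hi": rsabin.hi,
                    "x": rsabin.x,
                    "mid": (rsabin.lo + rsabin.hi) / 2.0,
                    "n_codons": rsabin.count,
                }
            )
    _write_tsv(pd.DataFrame(index_rows), out / "bins_index.tsv")


def _load_bin_alignment(path: Path, taxa) -> "object":
    aln = CodonAlignment.from_fasta(path, taxa)
    members_idx = np.array(
        [[aln.sequences[t][3 * k : 3 * k + 3] for k in range(aln.n_codons)] for t in range(len(taxa))]
    )
    from .codons import CODON_INDEX
    from .alignment_binning import BinnedAlignment

    codons = np.array(
        [[CODON_INDEX[c] for c in row] for row in members_idx], dtype=np.intp
    )
    return BinnedAlignment(taxa=tuple(taxa), codons=codons)


def stage_rates(cfg: RunConfig) -> None:
    """Per-bin maximum-likelihood rates with bootstrap standard errors."""
    out = Path(cfg.outdir)
    taxa = _estimation_taxa(cfg)
    topology = PhyloTree.from_newick(cfg.tree_newick)
    bins_index = pd.read_csv(out / "bins_index.tsv", sep="\t")
    rows = []
    for gname, sub in bins_index.groupby("group", sort=True):
        shared = None
        if cfg.rates_mode == "shared_tree":
            alns = []
            for row in sub.itertuples(index=False):
                path = out / "bins" / f"{gname}.bin{row.bin_index:02d}.fasta"
                if path.exists():
                    alns.append(_load_bin_alignment(path, taxa))
            if alns:
                from .alignment_binning import BinnedAlignment

                pooled = BinnedAlignment(
                    taxa=tuple(taxa),
                    codons=np.concatenate([a.codons for a in alns], axis=1),
                )
                shared = estimate_rates_ml(pooled, topology, pi_mode=cfg.pi_mode)
        for row in sub.itertuples(index=False):
            path = out / "bins" / f"{gname}.bin{row.bin_index:02d}.fasta"
            base = {
                "group": gname,
                "bin_index": int(row.bin_index),
                "x": float(row.x),
                "mid": float(row.mid),
                "n_codons": int(row.n_codons),
            }
            if not path.exists() or row.n_codons < cfg.min_bin_codons:
                logger.warning(
                    "group %s bin %d skipped (%d codons)", gname, row.bin_index, row.n_codons
                )
                rows.append(
                    {**base, "dnds": np.nan, "se_dnds": np.nan, "dn": np.nan,
                     "se_dn": np.nan, "ds": np.nan, "se_ds": np.nan,
                     "lnl": np.nan, "converged": False, "undefined": True}
                )
                continue
            aln = _load_bin_alignment(path, taxa)
            if shared is not None and not shared.undefined:
                est = estimate_rates_profile(
                    aln,
                    topology,
                    kappa=shared.kappa,
                    branch_lengths=shared.branch_lengths,
                    pi=shared.pi,
                )
            else:
                est = estimate_rates_ml(aln, topology, pi_mode=cfg.pi_mode)
            if est.undefined:
                logger.warning("group %s bin %d: dN/dS undefined", gname, row.bin_index)
                rows.append(
                    {**base, "dnds": np.nan, "se_dnds": np.nan, "dn": est.dn,
                     "se_dn": np.nan, "ds": est.ds, "se_ds": np.nan,
                     "lnl": est.log_likelihood, "converged": est.converged,
                     "undefined": True}
                )
                continue
            seed = _stable_seed(cfg.seed, "bootstrap", gname, row.bin_index)
            boot = bootstrap_se(
                aln,
                topology,
                B=cfg.bootstrap_B,
                seed=np.random.default_rng(seed).integers(2**31 - 1),
                method=cfg.bootstrap_method,
                estimate=est,
            )
            if boot.unreliable:
                logger.warning(
                    "group %s bin %d: bootstrap unreliable (%d/%d undefined)",
                    gname, row.bin_index, boot.n_undefined, boot.n_replicates,
                )
            rows.append(
                {
                    **base,
                    "dnds": est.dnds,
                    "se_dnds": boot.se_dnds if not boot.unreliable else np.nan,
                    "dn": est.dn,
                    "se_dn": boot.se_dn if not boot.unreliable else np.nan,
                    "ds": est.ds,
                    "se_ds": boot.se_ds if not boot.unreliable else np.nan,
                    "lnl": est.log_likelihood,
                    "converged": est.converged,
                    "undefined": False,
                }
            )
    _write_tsv(pd.DataFrame(rows), out / "rates.tsv")


def _load_adaptiveness(cfg: RunConfig) -> AdaptivenessTable:
    study = _study_dir(cfg)
    if cfg.cai_reference == "study":
        path = study / "adaptiveness.tsv"
        if not path.exists():
            raise ValueError("study has no adaptiveness.tsv; set cai_reference")
        return AdaptivenessTable.from_tsv(path, reference="study")
    if cfg.cai_reference == "top_decile":
        expression = pd.read_csv(study / "expression.tsv", sep="\t")
        col = cfg.expression_column
        cut = expression[col].quantile(0.9)
        top = expression.loc[expression[col] >= cut, "protein_id"]
        taxa = _estimation_taxa(cfg)
        focal = taxa[0]
        seqs = []
        for pid in top:
            aln = CodonAlignment.from_fasta(study / "alignments" / f"{pid}.fasta", taxa)
            seqs.append(aln.sequences[aln.taxa.index(focal)].replace("-", ""))
        return relative_adaptiveness(seqs, reference="top_decile")
    return AdaptivenessTable.from_tsv(cfg.cai_reference)


def stage_cai(cfg: RunConfig) -> None:
    """Per-bin CAI of the focal (first-taxon) codons, with bootstrap SEs."""
    out = Path(cfg.outdir)
    if "cai" not in cfg.analyses:
        return
    taxa = _estimation_taxa(cfg)
    focal = taxa[0]
    table = _load_adaptiveness(cfg)
    bins_index = pd.read_csv(out / "bins_index.tsv", sep="\t")
    rows = []
    for row in bins_index.itertuples(index=False):
        path = out / "bins" / f"{row.group}.bin{row.bin_index:02d}.fasta"
        base = {
            "group": row.group,
            "bin_index": int(row.bin_index),
            "x": float(row.x),
            "mid": float(row.mid),
        }
        if not path.exists() or row.n_codons < cfg.min_bin_codons:
            rows.append({**base, "cai": np.nan, "se_cai": np.nan, "n": 0})
            continue
        aln = CodonAlignment.from_fasta(path, taxa)
        codons = [aln.sequences[aln.taxa.index(focal)][3 * k : 3 * k + 3] for k in range(aln.n_codons)]
        value = compute_cai(codons, table)
        seed = _stable_seed(cfg.seed, "cai", row.group, row.bin_index)
        se = bootstrap_cai_se(
            codons, table, B=cfg.bootstrap_B,
            seed=np.random.default_rng(seed).integers(2**31 - 1),
        )
        rows.append({**base, "cai": value.cai, "se_cai": se, "n": value.n_codons})
    _write_tsv(pd.DataFrame(rows), out / "cai.tsv")


def _fit_from_rows(df, ycol, secol) -> LineFit | None:
    pts = [
        (row.x, getattr(row, ycol), getattr(row, secol))
        for row in df.itertuples(index=False)
        if np.isfinite(getattr(row, ycol))
        and np.isfinite(getattr(row, secol))
        and getattr(row, secol) > 0
    ]
    if len(pts) < 3:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return weighted_line_fit(pts)


def stage_fit(cfg: RunConfig) -> None:
    """Error-weighted dN/dS (and dN, dS) versus RSA lines per group."""
    out = Path(cfg.outdir)
    rates = pd.read_csv(out / "rates.tsv", sep="\t")
    rows = []
    for gname, sub in rates.groupby("group", sort=True):
        for analysis, ycol, secol in (
            ("dnds", "dnds", "se_dnds"),
            ("dn", "dn", "se_dn"),
            ("ds", "ds", "se_ds"),
        ):
            if analysis not in cfg.analyses and analysis != "dnds":
                continue
            fit = _fit_from_rows(sub, ycol, secol)
            if fit is None:
                logger.warning("group %s: <3 usable bins for %s fit", gname, analysis)
                continue
            slope_test = test_param_null(fit, "slope", 0.0)
            rows.append(
                {
                    "group": gname,
                    "analysis": analysis,
                    "slope": fit.slope,
                    "se_slope": fit.se_slope,
                    "intercept": fit.intercept,
                    "se_intercept": fit.se_intercept,
                    "n": fit.n,
                    "chi2": fit.chi2,
                    "p_slope_vs_0": slope_test.p,
                }
            )
    _write_tsv(pd.DataFrame(rows), out / "fits.tsv")


_COMPARISON_GROUPS = {
    "core": ("core.large_core", "core.small_core"),
    "expression": ("expr.low_expr", "expr.high_expr"),
}


def stage_compare(cfg: RunConfig) -> None:
    """Fold-change curves, their fits, and between-group parameter tests."""
    out = Path(cfg.outdir)
    rates = pd.read_csv(out / "rates.tsv", sep="\t")
    fits = pd.read_csv(out / "fits.tsv", sep="\t")
    cai = None
    if "cai" in cfg.analyses and (out / "cai.tsv").exists():
        cai = pd.read_csv(out / "cai.tsv", sep="\t")
    rows = []

    def fit_of(group, analysis="dnds") -> LineFit | None:
        hit = fits[(fits.group == group) & (fits.analysis == analysis)]
        if hit.empty:
            return None
        r = hit.iloc[0]
        return LineFit(
            slope=r.slope, intercept=r.intercept, se_slope=r.se_slope,
            se_intercept=r.se_intercept, n=int(r.n), chi2=r.chi2,
        )

    def series(group, analysis):
        # fold changes compare the same interval across groups, so the bin
        # midpoint (identical by construction) is the shared x-value
        if analysis == "cai":
            sub = cai[cai.group == group].sort_values("bin_index")
            return [(r.mid, r.cai, r.se_cai) for r in sub.itertuples(index=False)]
        sub = rates[rates.group == group].sort_values("bin_index")
        ycol, secol = analysis, f"se_{analysis}"
        return [
            (r.mid, getattr(r, ycol), getattr(r, secol))
            for r in sub.itertuples(index=False)
        ]

    def add_row(analysis_id, group_a, group_b, parameter, estimate, se, t, df_, p):
        rows.append(
            {
                "analysis_id": analysis_id,
                "group_a": group_a,
                "group_b": group_b,
                "parameter": parameter,
                "estimate": estimate,
                "se": se,
                "t": t,
                "df": df_,
                "p": p,
            }
        )

    for comparison in cfg.comparisons:
        if comparison in _COMPARISON_GROUPS:
            ga, gb = _COMPARISON_GROUPS[comparison]
            # direct comparison of the two groups' dN/dS-vs-RSA lines
            fa, fb = fit_of(ga), fit_of(gb)
            if fa is not None and fb is not None:
                for parameter in ("slope", "intercept"):
                    res = compare_line_params(fa, fb, parameter)
                    est = getattr(fa, parameter) - getattr(fb, parameter)
                    add_row(
                        f"{comparison}.dnds.lines", ga, gb, parameter, est,
                        np.sqrt(getattr(fa, f"se_{parameter}") ** 2 + getattr(fb, f"se_{parameter}") ** 2),
                        res.t, res.df, res.p,
                    )
            # fold-change curves per analysis
            for analysis in cfg.analyses:
                if analysis == "cai" and cai is None:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        curve = fold_change_curve(series(ga, analysis), series(gb, analysis))
                except ValueError as exc:
                    logger.warning("%s %s fold change: %s", comparison, analysis, exc)
                    continue
                fc = pd.DataFrame(
                    {
                        "x": [p.x for p in curve],
                        "ratio": [p.ratio for p in curve],
                        "sigma": [p.sigma for p in curve],
                    }
                )
                _write_tsv(fc, out / f"foldchange_{comparison}_{analysis}.tsv")
                if len(curve) >= 3:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fcfit = weighted_line_fit([(p.x, p.ratio, p.sigma) for p in curve])
                    slope_test = test_param_null(fcfit, "slope", 0.0)
                    icpt_test = test_param_null(fcfit, "intercept", 1.0)
                    aid = f"{comparison}.{analysis}.foldchange"
                    add_row(aid, ga, gb, "slope", fcfit.slope, fcfit.se_slope,
                            slope_test.t, slope_test.df, slope_test.p)
                    add_row(aid, ga, gb, "intercept", fcfit.intercept, fcfit.se_intercept,
                            icpt_test.t, icpt_test.df, icpt_test.p)
        elif comparison == "four_cell":
            cells = [
                f"cell.{c}.{e}"
                for c in ("large_core", "small_core")
                for e in ("low_expr", "high_expr")
            ]
            cell_fits = {g: fit_of(g) for g in cells}
            for i, ga in enumerate(cells):
                for gb in cells[i + 1 :]:
                    fa, fb = cell_fits[ga], cell_fits[gb]
                    if fa is None or fb is None:
                        continue
                    res = compare_line_params(fa, fb, "slope")
                    add_row(
                        "four_cell.dnds.slopes", ga, gb, "slope",
                        fa.slope - fb.slope,
                        np.sqrt(fa.se_slope**2 + fb.se_slope**2),
                        res.t, res.df, res.p,
                    )
    _write_tsv(pd.DataFrame(rows), out / "comparisons.tsv")


def stage_manifest(cfg: RunConfig) -> dict:
    out = Path(cfg.outdir)
    files = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.suffix in (".tsv", ".fasta", ".yaml"):
            files[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and collect the results."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    captured: list[str] = []
    handler = logging.Handler()
    handler.emit = lambda record: captured.append(record.getMessage())
    logger.addHandler(handler)
    try:
        stage_simulate(config)
        stage_records(config)
        stage_group(config)
        stage_bin(config)
        stage_rates(config)
        stage_cai(config)
        stage_fit(config)
        stage_compare(config)
        manifest = stage_manifest(config)
    finally:
        logger.removeHandler(handler)
    return RunReport(
        outdir=out,
        groups=pd.read_csv(out / "groups.tsv", sep="\t"),
        rates=pd.read_csv(out / "rates.tsv", sep="\t"),
        cai=pd.read_csv(out / "cai.tsv", sep="\t") if (out / "cai.tsv").exists() else None,
        fits=pd.read_csv(out / "fits.tsv", sep="\t"),
        comparisons=pd.read_csv(out / "comparisons.tsv", sep="\t"),
        manifest=manifest,
        warnings=captured,
    )
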