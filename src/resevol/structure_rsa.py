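"""Solvent accessibility: per-residue SASA, RSA normalization, template transfer.

Per-atom solvent-accessible surface area is computed with Shrake–Rupley
sphere sampling: a deterministic quasi-uniform point set is placed on each
atom's probe-expanded sphere and the accessible fraction is the fraction of
points outside every neighboring expanded sphere. Per-residue SASA is the
sum over the residue's atoms.

Raw SASA is converted to relative solvent accessibility (RSA, 0-100%) by
dividing by a per-residue-type normalizer — by default the 99th percentile
of raw SASA within each residue type over a reference set — with values
above the normalizer capped at 100%.

RSA computed on a template structure is transferred to a homologous target
protein through an explicit residue alignment map; unmapped (gapped) target
positions carry a missing value (NaN) and are excluded downstream. RSA = 0
is meaningful (fully buried), so missing is never encoded as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VDW_RADII",
    "VDW_TABLE_NAME",
    "AtomSet",
    "RawSASAProfile",
    "RSAProfile",
    "NormalizationTable",
    "read_pdb",
    "sphere_points",
    "compute_sasa",
    "normalize_rsa",
    "transfer_rsa",
]

# Bondi (1964) van der Waals radii, Å; the table name is recorded in outputs.
VDW_TABLE_NAME = "bondi1964"
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}


@dataclass
class AtomSet:
    """A set of heavy atoms with residue assignment, 1-based residue indices."""

    elements: np.ndarray  # str array
    residue_index: np.ndarray  # int, non-decreasing within a chain
    residue_type: np.ndarray  # 1-letter amino acid codes, per atom
    coords: np.ndarray  # (n, 3) in Å
    radii: np.ndarray | None = None  # vdW radii; looked up from VDW_RADII if None

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_type = np.asarray(self.residue_type, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.radii is None:
            radii = []
            for el in self.elements:
                key = str(el).upper()
                if key not in VDW_RADII:
                    raise ValueError(f"no van der Waals radius for element {el!r}")
                radii.append(VDW_RADII[key])
            self.radii = np.array(radii)
        else:
            self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("van der Waals radii must be positive")

    def __len__(self) -> int:
        return len(self.coords)

    def without_hydrogens(self) -> "AtomSet":
        keep = np.array([str(e).upper() != "H" for e in self.elements])
        return AtomSet(
            self.elements[keep],
            self.residue_index[keep],
            self.residue_type[keep],
            self.coords[keep],
            self.radii[keep],
        )


def _profile_frame(residue_index, residue_type, value) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_index": np.asarray(residue_index, dtype=int),
            "residue_type": np.asarray(residue_type, dtype=object),
            "value": np.asarray(value, dtype=float),
        }
    )


@dataclass
class RawSASAProfile:
    """Per-residue raw solvent-accessible surface area in Å²."""

    data: pd.DataFrame  # columns: residue_index, residue_type, value
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.data["value"].to_numpy()
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("raw SASA must be non-negative")

    def to_tsv(self, path) -> None:
        _write_profile_tsv(self.data, path)

    @classmethod
    def from_tsv(cls, path) -> "RawSASAProfile":
        return cls(_read_profile_tsv(path))


@dataclass
class RSAProfile:
    """Per-residue relative solvent accessibility in percent, NaN = missing."""

    data: pd.DataFrame  # columns: residue_index, residue_type, value
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        vals = self.data["value"].to_numpy()
        ok = vals[~np.isnan(vals)]
        if np.any((ok < 0) | (ok > 100)):
            raise ValueError("RSA must lie in [0, 100]")

    @property
    def values(self) -> np.ndarray:
        return self.data["value"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        _write_profile_tsv(self.data, path)

    @classmethod
    def from_tsv(cls, path) -> "RSAProfile":
        return cls(_read_profile_tsv(path))


def _write_profile_tsv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["value"] = out["value"].map(lambda v: "." if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, sep="\t", index=False)


def _read_profile_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"residue_index": int, "residue_type": str})
    df["value"] = pd.to_numeric(df["value"].replace(".", np.nan))
    return df


@dataclass
class NormalizationTable:
    """Per-residue-type denominators (Å²) for RSA normalization."""

    denominators: dict[str, float]
    source: str = "empirical-p99"

    def __post_init__(self):
        for aa, v in self.denominators.items():
            if not (v > 0):
                raise ValueError(f"normalizer for {aa!r} must be positive (got {v})")

    @classmethod
    def from_profiles(cls, profiles, percentile: float = 99.0) -> "NormalizationTable":
        """Empirical percentile of raw SASA within each residue type."""
        frames = [p.data for p in profiles]
        pooled = pd.concat(frames, ignore_index=True).dropna(subset=["value"])
        if pooled.empty:
            raise ValueError("no residues to build a normalization table from")
        denom = (
            pooled.groupby("residue_type")["value"]
            .quantile(percentile / 100.0)
            .to_dict()
        )
        denom = {aa: float(v) for aa, v in denom.items() if v > 0}
        return cls(denom, source=f"empirical-p{percentile:g}")


def read_pdb(path, chain: str | None = None, drop_hydrogens: bool = True) -> AtomSet:
    """Read ATOM records of one chain from a PDB file into an AtomSet."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import is_aa
    from Bio.SeqUtils import seq1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", path)
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain is None:
        selected = chains[0]
    else:
        match = [c for c in chains if c.id == chain]
        if not match:
            raise ValueError(f"chain {chain!r} not found (have {[c.id for c in chains]})")
        selected = match[0]
    elements, res_idx, res_type, coords = [], [], [], []
    for residue in selected.get_residues():
        if not is_aa(residue, standard=True):
            continue
        one = seq1(residue.get_resname())
        for atom in residue.get_atoms():
            el = (atom.element or "").strip().upper()
            if drop_hydrogens and el in ("H", "D"):
                continue
            elements.append(el)
            res_idx.append(residue.id[1])
            res_type.append(one)
            coords.append(atom.coord)
    if not coords:
        raise ValueError(f"no protein atoms found in {path}")
    return AtomSet(elements, res_idx, res_type, np.array(coords))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def compute_sasa(
    structure: AtomSet, probe_radius: float = 1.4, n_points: int = 960
) -> RawSASAProfile:
    """Shrake–Rupley solvent-accessible surface area, summed per residue.

    Deterministic for a fixed point count. Hydrogens should be excluded
    before the call (read_pdb drops them by default).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    if probe_radius <= 0:
        raise ValueError("probe radius must be positive")
    pts = sphere_points(n_points)
    coords = structure.coords
    expanded = structure.radii + probe_radius
    n = len(structure)
    areas = np.zeros(n)
    # neighbor search via simple distance matrix; inputs here are small
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    for i in range(n):
        ri = expanded[i]
        cutoff2 = (ri + expanded) ** 2
        nbrs = np.where((d2[i] < cutoff2) & (np.arange(n) != i))[0]
        test = coords[i] + ri * pts  # (n_points, 3)
        accessible = np.ones(len(test), dtype=bool)
        for j in nbrs:
            dj2 = np.sum((test - coords[j]) ** 2, axis=1)
            accessible &= dj2 >= expanded[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * ri * ri * accessible.mean()
    out = (
        pd.DataFrame(
            {
                "residue_index": structure.residue_index,
                "residue_type": structure.residue_type,
                "area": areas,
            }
        )
        .groupby(["residue_index"], sort=True)
        .agg(residue_type=("residue_type", "first"), value=("area", "sum"))
        .reset_index()
    )
    return RawSASAProfile(
        _profile_frame(out["residue_index"], out["residue_type"], out["value"]),
        metadata={
            "probe_radius": probe_radius,
            "n_points": n_points,
            "vdw_table": VDW_TABLE_NAME,
        },
    )


def normalize_rsa(raw: RawSASAProfile, norm: NormalizationTable) -> RSAProfile:
    """RSA = 100 × raw / normalizer, capped at 100%; cap events are counted."""
    df = raw.data
    values = np.empty(len(df))
    n_capped = 0
    for k, (aa, v) in enumerate(zip(df["residue_type"], df["value"])):
        if np.isnan(v):
            values[k] = np.nan
            continue
        denom = norm.denominators.get(aa)
        if denom is None:
            raise ValueError(f"no normalizer for residue type {aa!r}")
        rsa = 100.0 * v / denom
        if rsa > 100.0:
            rsa = 100.0
            n_capped += 1
        values[k] = rsa
    if n_capped:
        warnings.warn(f"capped {n_capped} residues at 100% RSA", stacklevel=2)
    meta = dict(raw.metadata)
    meta.update({"normalization": norm.source, "n_capped": n_capped})
    return RSAProfile(
        _profile_frame(df["residue_index"], df["residue_type"], values), metadata=meta
    )


def transfer_rsa(
    template_rsa: RSAProfile,
    residue_map: pd.DataFrame,
    target_length: int | None = None,
    target_types: dict[int, str] | None = None,
) -> RSAProfile:
    """Carry template RSA onto target residues through an alignment map.

    `residue_map` has columns template_index, target_index (1-based, both
    injective over mapped pairs). Target positions missing from the map are
    assigned NaN. Justified by the conservation of backbone conformation —
    and hence site-specific RSA — between close homologs.
    """
    required = {"template_index", "target_index"}
    if not required.issubset(residue_map.columns):
        raise ValueError(f"residue map needs columns {sorted(required)}")
    tmpl = residue_map["template_index"].to_numpy(dtype=int)
    targ = residue_map["target_index"].to_numpy(dtype=int)
    if len(set(tmpl)) != len(tmpl) or len(set(targ)) != len(targ):
        raise ValueError("residue map must be injective on both sides")
    lookup = dict(
        zip(template_rsa.data["residue_index"].astype(int), template_rsa.data["value"])
    )
    missing = [int(t) for t in tmpl if int(t) not in lookup]
    if missing:
        raise ValueError(f"map references template positions absent from profile: {missing[:5]}")
    if target_length is None:
        target_length = int(targ.max())
    values = np.full(target_length, np.nan)
    types = np.array(["X"] * target_length, dtype=object)
    mapped_type = dict(
        zip(template_rsa.data["residue_index"].astype(int), template_rsa.data["residue_type"])
    )
    for tp, tg in zip(tmpl, targ):
        if not (1 <= tg <= target_length):
            raise ValueError(f"target index {tg} outside 1..{target_length}")
        values[tg - 1] = lookup[int(tp)]
        types[tg - 1] = mapped_type[int(tp)]
    if target_types:
        for idx, aa in target_types.items():
            types[idx - 1] = aa
    return RSAProfile(
        _profile_frame(np.arange(1, target_length + 1), types, values),
        metadata={"source": "transfer", "n_mapped": len(tmpl)},
    )
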