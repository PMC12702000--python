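"""Weighted isomorphous difference maps and per-residue IADDAT scoring.

Pipeline: scale mutant amplitudes onto the wild-type reference, form
error-weighted difference structure factors (F_mut - F_WT), phase them
from a reference model, Fourier-synthesise the difference density, then
integrate |delta-rho| above a noise threshold near each residue's heavy
atoms (IADDAT: integration of absolute difference density above
threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from scipy.spatial import cKDTree

from .errors import (
    IncompatibleDatasetsError,
    InsufficientOverlapError,
    InvariantViolationError,
    ParameterError,
)
from .model_io import AtomicModel, ResidueKey, heavy_atom_counts, heavy_atoms
from .sfcalc import structure_factors
from .tracks import ResidueTrack, normalize_track

logger = logging.getLogger(__name__)

__all__ = [
    "ReflectionSet",
    "WeightedDifferenceSet",
    "DensityGrid",
    "scale_to_reference",
    "weighted_differences",
    "synthesize_map",
    "iaddat",
    "normalize_track",
]

MIN_COMMON_REFLECTIONS = 10


@dataclass
class ReflectionSet:
    """Merged amplitudes on a common cell.

    ``data`` columns: h, k, l (int), F, SIGF (float). Miller indices are
    unique; F and SIGF non-negative.
    """

    data: pd.DataFrame
    cell: tuple[float, float, float, float, float, float]
    spacegroup: str = "P 1"
    d_min: float | None = None

    def __post_init__(self) -> None:
        need = {"h", "k", "l", "F", "SIGF"}
        if not need.issubset(self.data.columns):
            raise InvariantViolationError(f"reflection table needs columns {sorted(need)}")
        if self.data.duplicated(subset=["h", "k", "l"]).any():
            raise InvariantViolationError("duplicate Miller indices")
        if (self.data["F"] < 0).any() or (self.data["SIGF"] < 0).any():
            raise InvariantViolationError("F and SIGF must be non-negative")

    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, cell, spacegroup: str = "P 1", d_min: float | None = None):
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        df = df.rename(columns={"f": "F", "sigf": "SIGF"})
        df[["h", "k", "l"]] = df[["h", "k", "l"]].astype(int)
        return cls(df[["h", "k", "l", "F", "SIGF"]], tuple(cell), spacegroup, d_min)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_mtz(cls, path, f_col: str = "F", sigf_col: str = "SIGF"):
        mtz = gemmi.read_mtz_file(str(path))
        arr = np.array(mtz, copy=True)
        labels = mtz.column_labels()
        idx = {lab: i for i, lab in enumerate(labels)}
        for col in ("H", "K", "L", f_col, sigf_col):
            if col not in idx:
                raise InvariantViolationError(f"{path}: MTZ lacks column {col}")
        df = pd.DataFrame(
            {
                "h": arr[:, idx["H"]].astype(int),
                "k": arr[:, idx["K"]].astype(int),
                "l": arr[:, idx["L"]].astype(int),
                "F": arr[:, idx[f_col]],
                "SIGF": arr[:, idx[sigf_col]],
            }
        ).dropna()
        c = mtz.cell
        return cls(
            df,
            (c.a, c.b, c.c, c.alpha, c.beta, c.gamma),
            mtz.spacegroup.hm if mtz.spacegroup else "P 1",
            d_min=mtz.resolution_high(),
        )

    def to_mtz(self, path) -> None:
        mtz = gemmi.Mtz(with_base=True)
        mtz.cell = self.gemmi_cell()
        mtz.spacegroup = gemmi.SpaceGroup(self.spacegroup)
        mtz.add_dataset("allonet")
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
        mtz.set_data(self.data[["h", "k", "l", "F", "SIGF"]].to_numpy(float))
        mtz.write_to_file(str(path))


def _asu_index(df: pd.DataFrame, spacegroup: str) -> pd.DataFrame:
    """Map Miller indices to the reduced reciprocal-space asymmetric unit."""
    if spacegroup.replace(" ", "") in ("P1", "P-1"):
        # P1: already unique per Friedel convention; nothing to remap
        return df
    sg = gemmi.SpaceGroup(spacegroup)
    asu = gemmi.ReciprocalAsu(sg)
    ops = sg.operations()
    mapped = [asu.to_asu((int(r.h), int(r.k), int(r.l)), ops)[0] for r in df.itertuples()]
    out = df.copy()
    out[["h", "k", "l"]] = np.array(mapped)
    return out


def _common(mut: ReflectionSet, wt: ReflectionSet) -> pd.DataFrame:
    ca, cb = np.array(mut.cell), np.array(wt.cell)
    if np.max(np.abs(ca - cb) / np.abs(cb)) > 0.01:
        raise IncompatibleDatasetsError(
            f"unit cells differ by more than 1%: {mut.cell} vs {wt.cell}"
        )
    a = _asu_index(mut.data, mut.spacegroup)
    b = _asu_index(wt.data, wt.spacegroup)
    j = a.merge(b, on=["h", "k", "l"], suffixes=("_mut", "_wt"))
    return j


def scale_to_reference(mut: ReflectionSet, wt: ReflectionSet) -> ReflectionSet:
    """Least-squares isotropic scale of mutant amplitudes onto the reference.

    Finds the scalar k minimising sum (k F_mut - F_WT)^2 over common
    reflections and returns mut with F and SIGF multiplied by k. A single
    overall scale stands in for the full refinement-program scaling model;
    difference amplitudes are insensitive to the smooth residual.
    """
    j = _common(mut, wt)
    if len(j) < MIN_COMMON_REFLECTIONS:
        raise InsufficientOverlapError(
            f"only {len(j)} common reflections (< {MIN_COMMON_REFLECTIONS})"
        )
    denom = float(np.sum(j["F_mut"] ** 2))
    if denom == 0:
        raise InvariantViolationError("all mutant amplitudes are zero")
    k = float(np.sum(j["F_mut"] * j["F_wt"]) / denom)
    out = mut.data.copy()
    out["F"] = out["F"] * k
    out["SIGF"] = out["SIGF"] * k
    scaled = replace(mut, data=out)
    scaled.scale_factor = k  # attached for reporting
    return scaled


@dataclass
class WeightedDifferenceSet:
    """Per-reflection weighted difference amplitudes with model phases.

    ``data`` columns: h, k, l, delta_f, sig_delta_f, weight, w_delta_f,
    phase_deg. ``report`` counts reflections dropped from either input.
    """

    data: pd.DataFrame
    cell: tuple
    d_min: float
    alpha: float
    report: dict = field(default_factory=dict)


def difference_weights(delta_f: np.ndarray, sig_delta_f: np.ndarray, alpha: float) -> np.ndarray:
    """w = [1 + sig^2/<sig^2> + alpha * dF^2/<dF^2>]^-1.

    The error term down-weights poorly measured differences; the alpha
    term (alpha = 0.05 by convention) suppresses outlier amplitudes.
    Degenerate all-zero means drop the corresponding term.
    """
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    delta_f = np.asarray(delta_f, float)
    sig_delta_f = np.asarray(sig_delta_f, float)
    mean_sig2 = float(np.mean(sig_delta_f**2))
    mean_df2 = float(np.mean(delta_f**2))
    term_sig = sig_delta_f**2 / mean_sig2 if mean_sig2 > 0 else 0.0
    term_df = alpha * delta_f**2 / mean_df2 if mean_df2 > 0 else 0.0
    return 1.0 / (1.0 + term_sig + term_df)


def weighted_differences(
    mut: ReflectionSet,
    wt: ReflectionSet,
    alpha: float = 0.05,
    phase_source: AtomicModel | None = None,
    b_iso: float = 15.0,
) -> WeightedDifferenceSet:
    """Form w*(F_mut - F_WT) with phases from a reference model.

    Inputs are assumed already scaled (see :func:`scale_to_reference`).
    Phases come from direct structure-factor summation over the phase
    source (normally the WT model); reflections present in only one
    dataset are dropped and counted in the report.
    """
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    j = _common(mut, wt)
    if len(j) == 0:
        raise InsufficientOverlapError("no common reflections")
    n_only_mut = len(mut.data) - len(j)
    n_only_wt = len(wt.data) - len(j)

    delta_f = (j["F_mut"] - j["F_wt"]).to_numpy(float)
    sig = np.sqrt(j["SIGF_mut"].to_numpy(float) ** 2 + j["SIGF_wt"].to_numpy(float) ** 2)
    w = difference_weights(delta_f, sig, alpha)

    hkl = j[["h", "k", "l"]].to_numpy(int)
    if phase_source is None:
        raise ParameterError("a phase_source model is required")
    src = phase_source if phase_source.cell is not None else phase_source.with_cell(wt.cell)
    fcalc = structure_factors(src, hkl, b_iso=b_iso)
    phase_deg = np.degrees(np.angle(fcalc))

    d_min = mut.d_min or wt.d_min
    if d_min is None:
        from .sfcalc import inv_d2

        d_min = float(1.0 / np.sqrt(np.max(inv_d2(hkl, gemmi.UnitCell(*wt.cell)))))

    data = pd.DataFrame(
        {
            "h": hkl[:, 0],
            "k": hkl[:, 1],
            "l": hkl[:, 2],
            "delta_f": delta_f,
            "sig_delta_f": sig,
            "weight": w,
            "w_delta_f": w * delta_f,
            "phase_deg": phase_deg,
        }
    )
    report = {"n_common": len(j), "n_only_mut": n_only_mut, "n_only_wt": n_only_wt}
    if n_only_mut or n_only_wt:
        logger.warning("dropped unmatched reflections: %s", report)
    return WeightedDifferenceSet(
        data=data, cell=tuple(wt.cell), d_min=float(d_min), alpha=alpha, report=report
    )


@dataclass
class DensityGrid:
    """Real-space map on the unit cell; grid point (0,0,0) at fractional origin."""

    values: np.ndarray  # shape (na, nb, nc), indexed by fractional position
    cell: tuple
    units: str = "e/A^3"

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise InvariantViolationError("grid must be 3-D with >= 2 points per axis")
        if not np.all(np.isfinite(self.values)):
            raise InvariantViolationError("grid contains non-finite values")

    def gemmi_cell(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(*self.cell)

    def to_ccp4(self, path) -> None:
        g = gemmi.FloatGrid(*self.values.shape)
        g.set_unit_cell(self.gemmi_cell())
        g.spacegroup = gemmi.SpaceGroup("P 1")
        np.array(g, copy=False)[...] = self.values.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = g
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))

    @classmethod
    def from_ccp4(cls, path) -> "DensityGrid":
        m = gemmi.read_ccp4_map(str(path))
        m.setup(float("nan"))
        g = m.grid
        c = g.unit_cell
        vals = np.array(g, copy=True).astype(float)
        return cls(vals, (c.a, c.b, c.c, c.alpha, c.beta, c.gamma), units="map")


def synthesize_map(diffs: WeightedDifferenceSet, grid_spacing_factor: float = 3.0) -> DensityGrid:
    """Inverse Fourier synthesis of {w*dF, phi} with Friedel completion.

    rho(x) = (1/V) * sum_h w dF_h exp(i phi_h) exp(-2 pi i h.x), evaluated
    on a grid with spacing <= d_min / grid_spacing_factor. Amplitudes in
    electrons give density in e-/A^3.
    """
    if "phase_deg" not in diffs.data.columns or diffs.data["phase_deg"].isna().any():
        raise ParameterError("phases are required for map synthesis")
    cell = gemmi.UnitCell(*diffs.cell)
    spacing = diffs.d_min / grid_spacing_factor
    hkl = diffs.data[["h", "k", "l"]].to_numpy(int)
    dims = []
    for length, max_idx in zip((cell.a, cell.b, cell.c), np.abs(hkl).max(axis=0)):
        n = max(int(np.ceil(length / spacing)), 2 * int(max_idx) + 2)
        dims.append(next_fast_len(n))
    na, nb, nc = dims

    coeffs = np.zeros((na, nb, nc), dtype=complex)
    amp = diffs.data["w_delta_f"].to_numpy(float)
    phi = np.radians(diffs.data["phase_deg"].to_numpy(float))
    Fh = amp * np.exp(1j * phi)
    for (h, k, l), f in zip(hkl, Fh):
        coeffs[h % na, k % nb, l % nc] += f
        if not (h == 0 and k == 0 and l == 0):
            coeffs[-h % na, -k % nb, -l % nc] += np.conj(f)

    rho = np.fft.fftn(coeffs).real / cell.volume
    return DensityGrid(values=rho, cell=tuple(diffs.cell))


def _check_same_cell(a: tuple, b: tuple) -> None:
    if np.max(np.abs(np.array(a) - np.array(b)) / np.array(b)) > 1e-3:
        raise IncompatibleDatasetsError(f"grid/model cells differ: {a} vs {b}")


def iaddat(
    grid: DensityGrid,
    model: AtomicModel,
    threshold: float = 0.04,
    radius: float = 1.5,
    denominator: str = "heavy_atoms",
) -> ResidueTrack:
    """Integrate |delta-rho| above threshold near each residue's heavy atoms.

    Every voxel with |value| > threshold lying within ``radius`` (periodic
    minimum-image distance) of at least one protein heavy atom is assigned
    to the residue of the nearest such atom (ties -> lower (chain, resnum)).
    Residue score = sum of assigned |values| divided by the residue's
    heavy-atom count (``denominator`` in {"heavy_atoms", "voxels", "none"}).
    Defaults follow the published protocol: threshold 0.04 e-/A^3 on an
    absolute-scale map, radius 1.5 A.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    if radius <= 0:
        raise ParameterError("radius must be > 0")
    if model.cell is None:
        raise IncompatibleDatasetsError("model has no unit cell")
    _check_same_cell(grid.cell, model.cell)

    cell = grid.gemmi_cell()
    orth = np.array(cell.orth.mat.tolist())
    ha = heavy_atoms(model)
    keys = list(ha["key"])
    apos = ha[["x", "y", "z"]].to_numpy(float)

    # replicate atoms in 27 neighbouring cells for minimum-image distances
    shifts = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)], float
    )
    cart_shifts = shifts @ orth.T
    rep = (apos[None, :, :] + cart_shifts[:, None, :]).reshape(-1, 3)
    rep_key_idx = np.tile(np.arange(len(keys)), len(cart_shifts))
    tree = cKDTree(rep)

    na, nb, nc = grid.values.shape
    mask = np.abs(grid.values) > threshold
    sums: dict[ResidueKey, float] = {k: 0.0 for k in model.residue_keys()}
    nvox: dict[ResidueKey, int] = {k: 0 for k in sums}
    if mask.any():
        idx = np.argwhere(mask)
        frac = idx / np.array([na, nb, nc], float)
        vox = frac @ orth.T
        dists, nearest = tree.query(vox, k=8, distance_upper_bound=radius)
        vals = np.abs(grid.values[mask])
        for row in range(len(vox)):
            d = dists[row]
            hit = np.isfinite(d)
            if not hit.any():
                continue
            dmin = d[hit].min()
            cand = nearest[row][hit & (d <= dmin + 1e-9)]
            key = min(keys[rep_key_idx[c]] for c in cand)
            sums[key] += float(vals[row])
            nvox[key] += 1

    counts = heavy_atom_counts(model)
    if denominator == "heavy_atoms":
        scores = {k: v / counts[k] for k, v in sums.items()}
    elif denominator == "voxels":
        scores = {k: (v / nvox[k] if nvox[k] else 0.0) for k, v in sums.items()}
    elif denominator == "none":
        scores = sums
    else:
        raise ParameterError(f"unknown denominator {denominator!r}")
    return ResidueTrack(
        scores=scores,
        modality="iaddat",
        meta={"threshold": threshold, "radius": radius, "denominator": denominator},
    )
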