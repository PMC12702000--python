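"""Direct-summation structure factors with tabulated atomic scattering factors.

F(h) = sum_j occ_j * f_j(s) * exp(-B s^2 / 4) * exp(2 pi i h.x_j)

with x_j fractional coordinates, s = 1/d, and f_j(s) the 4-Gaussian +
constant form-factor parametrisation (International Tables vol. C, via
gemmi's element tables). No bulk-solvent term: difference maps are
dominated by local ordered features, and the same approximation is used
consistently by the phase source and the synthetic generator.
"""

from __future__ import annotations

import gemmi
import numpy as np

from .model_io import AtomicModel, heavy_atoms

_CHUNK = 4096  # reflections per broadcast block; keeps memory < ~100 MB


def reciprocal_metric(cell: gemmi.UnitCell) -> np.ndarray:
    """3x3 reciprocal metric tensor G*, so that 1/d^2 = h G* h^T."""
    orth = np.array(cell.orth.mat.tolist())
    g = orth.T @ orth  # direct metric
    return np.linalg.inv(g)


def inv_d2(hkl: np.ndarray, cell: gemmi.UnitCell) -> np.ndarray:
    gstar = reciprocal_metric(cell)
    h = np.asarray(hkl, dtype=float)
    return np.einsum("ij,jk,ik->i", h, gstar, h)


def form_factors(elements: list[str], s2: np.ndarray) -> np.ndarray:
    """f(s) for each element symbol at each s^2 = 1/d^2; shape (n_el, n_hkl)."""
    out = np.empty((len(elements), len(s2)))
    stol2 = s2 / 4.0  # (sin theta / lambda)^2
    for i, el in enumerate(elements):
        it92 = gemmi.Element(el).it92
        a = np.asarray(it92.a)
        b = np.asarray(it92.b)
        out[i] = (a[:, None] * np.exp(-b[:, None] * stol2[None, :])).sum(0) + it92.c
    return out


def structure_factors(
    model: AtomicModel,
    hkl: np.ndarray,
    b_iso: float = 15.0,
    heavy_only: bool = False,
) -> np.ndarray:
    """Complex F(h) for the given Miller indices by direct summation.

    Waters are included (they scatter) unless ``heavy_only`` — the
    heavy-atom filter is an IADDAT concept, not a scattering one.
    Uniform isotropic B; occupancy-weighted; altlocs summed as modelled.
    """
    cell = model.gemmi_cell()
    atoms = heavy_atoms(model) if heavy_only else model.atoms
    frac_mat = np.linalg.inv(np.array(cell.orth.mat.tolist()))
    xyz = atoms[["x", "y", "z"]].to_numpy(float)
    frac = xyz @ frac_mat.T
    occ = atoms["occupancy"].to_numpy(float)
    elements = atoms["element"].tolist()
    uniq = sorted(set(elements))
    el_idx = np.array([uniq.index(e) for e in elements])

    hkl = np.asarray(hkl, dtype=int)
    F = np.empty(len(hkl), dtype=complex)
    for lo in range(0, len(hkl), _CHUNK):
        block = hkl[lo : lo + _CHUNK]
        s2 = inv_d2(block, cell)
        ff = form_factors(uniq, s2)  # (n_uniq, nb)
        damp = np.exp(-b_iso * s2 / 4.0)  # B s^2/4 with s = 1/d
        phase = np.exp(2j * np.pi * (block.astype(float) @ frac.T))  # (nb, natom)
        coeff = occ[None, :] * ff[el_idx, :].T  # (nb, natom)
        F[lo : lo + len(block)] = (coeff * phase).sum(axis=1) * damp
    return F


def unique_hkl_p1(cell: gemmi.UnitCell, d_min: float, include_origin: bool = True) -> np.ndarray:
    """Friedel-unique Miller indices to d_min in P1.

    One index of each Friedel pair is kept, chosen lexicographically
    (h > 0, or h = 0 and k > 0, or h = k = 0 and l >= 0).
    """
    hmax = int(np.floor(cell.a / d_min)) + 1
    kmax = int(np.floor(cell.b / d_min)) + 1
    lmax = int(np.floor(cell.c / d_min)) + 1
    h, k, l = np.meshgrid(
        np.arange(-hmax, hmax + 1),
        np.arange(-kmax, kmax + 1),
        np.arange(-lmax, lmax + 1),
        indexing="ij",
    )
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    keep = (
        (hkl[:, 0] > 0)
        | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
        | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] >= 0))
    )
    hkl = hkl[keep]
    s2 = inv_d2(hkl, cell)
    in_res = s2 <= 1.0 / d_min**2 + 1e-12
    hkl = hkl[in_res]
    if not include_origin:
        hkl = hkl[~np.all(hkl == 0, axis=1)]
    # stable order: by resolution then lexicographic
    order = np.lexsort((hkl[:, 2], hkl[:, 1], hkl[:, 0]))
    return hkl[order]
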