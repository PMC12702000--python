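"""Synthetic paired inputs with known ground truth.

Emulates a small P1 crystal of a single helical chain, a mutation-like
perturbation (side-chain deletion at the mutated site, an ordered water
appearing in its place, and sub-angstrom shifts of a distal "tendril" of
side chains), amplitude measurement noise, and an HDX-MS experiment
(pepsin-like peptide tiling, six timepoints, duplicate measurements at
30 s and 300 s) with planted residue-level exchange differences.

All randomness flows from one top-level seed through named substreams so
each stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as pyteomics_mass

from .errors import ParameterError
from .hdx import (
    DEFAULT_D2O_FRACTION,
    DEFAULT_TIMEPOINTS,
    DEUTERIUM_MASS_SHIFT,
    FD_SENTINEL,
    amide_positions,
    exchangeable_amides,
)
from .diffmap import ReflectionSet
from .model_io import ATOM_COLUMNS, AtomicModel, ResidueKey
from .network import ResidueSet
from .sfcalc import structure_factors, unique_hkl_p1

# substream tags (mixed with the user seed into a SeedSequence)
_STREAM_STRUCTURE = 11
_STREAM_EDIT = 23
_STREAM_REFL_WT = 37
_STREAM_REFL_MUT = 41
_STREAM_PEPTIDES = 53
_STREAM_HDX_NOISE = 67

#: replicate schedule of the labelling design: n=2 at 30 s and 300 s, else n=1
DEFAULT_REPLICATES = {30.0: 2, 300.0: 2}

SIDECHAIN_ATOMS = ("CB", "CG")

AA20 = "ACDEFGHIKLMNQRSTVWY"  # Pro handled separately


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    site: ResidueKey
    tendril: list[ResidueKey]
    deleted_atoms: list[tuple] = field(default_factory=list)
    shifted_atoms: list[tuple] = field(default_factory=list)
    added_waters: list[tuple] = field(default_factory=list)
    planted_dhdx: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    @property
    def perturbed(self) -> ResidueSet:
        """All planted residues: atomic edits plus HDX-difference segments."""
        chain = self.site.chain
        members = {self.site, *self.tendril} | {
            ResidueKey(chain, int(r)) for r, v in self.planted_dhdx.items() if v != 0.0
        }
        return ResidueSet(
            label="planted",
            members=frozenset(members),
            provenance="synthetic ground truth",
        )

    def to_json(self, path) -> None:
        d = {
            "site": list(self.site),
            "tendril": [list(t) for t in self.tendril],
            "deleted_atoms": self.deleted_atoms,
            "shifted_atoms": self.shifted_atoms,
            "added_waters": self.added_waters,
            "planted_dhdx": self.planted_dhdx,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(d, indent=1, default=str))


def make_toy_crystal(n_residues: int, seed: int) -> AtomicModel:
    """Single-chain helical poly-Ala-like model in a padded orthogonal P1 cell.

    Six heavy atoms per residue (N, CA, C, O plus CB/CG side-chain
    pseudo-atoms at increasing radius); a small seeded jitter makes each
    seed a distinct but equally realistic conformer. The cell encloses
    all atoms with >= 4 A margin.
    """
    if not 10 <= n_residues <= 100:
        raise ParameterError("n_residues must be in [10, 100]")
    rng = _rng(seed, _STREAM_STRUCTURE)
    rows = []
    rise, twist, r_ca = 1.5, np.radians(100.0), 2.3
    for i in range(1, n_residues + 1):
        th = i * twist
        ca = np.array([r_ca * np.cos(th), r_ca * np.sin(th), i * rise])
        radial = np.array([np.cos(th), np.sin(th), 0.0])
        tang = np.array([-np.sin(th), np.cos(th), 0.0])
        atoms = {
            "N": ca - 1.45 * tang + np.array([0, 0, -0.6]),
            "CA": ca,
            "C": ca + 1.52 * tang + np.array([0, 0, 0.4]),
            "O": ca + 1.52 * tang + 1.2 * radial + np.array([0, 0, 0.9]),
            "CB": ca + 1.53 * radial,
            "CG": ca + 2.9 * radial + 0.4 * tang,
        }
        for name, pos in atoms.items():
            pos = pos + rng.normal(0.0, 0.15, size=3)
            element = "N" if name == "N" else ("O" if name == "O" else "C")
            rows.append(("A", i, "ALA", name, "", element, *pos, 1.0))
    atoms_df = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    xyz = atoms_df[["x", "y", "z"]].to_numpy()
    pad = 4.0
    shift = pad - xyz.min(axis=0)
    atoms_df[["x", "y", "z"]] = xyz + shift
    extent = xyz.max(axis=0) - xyz.min(axis=0) + 2 * pad
    cell = (float(extent[0]), float(extent[1]), float(extent[2]), 90.0, 90.0, 90.0)
    return AtomicModel(atoms=atoms_df, cell=cell, spacegroup="P 1")


def apply_mutation_like_edit(
    model: AtomicModel,
    site: ResidueKey,
    tendril: list[ResidueKey],
    shift_A: float = 0.5,
    seed: int = 0,
) -> tuple[AtomicModel, GroundTruth]:
    """Make the 'mutant' model: delete, hydrate, and nudge.

    Side-chain atoms at ``site`` are removed and one ordered water is
    placed at their centroid; side-chain atoms of each tendril residue
    are displaced by exactly ``shift_A`` in seeded random directions.
    """
    rng = _rng(seed, _STREAM_EDIT)
    df = model.atoms.copy().reset_index(drop=True)
    truth = GroundTruth(site=site, tendril=list(tendril), seed=seed)

    def _res_mask(key: ResidueKey):
        return (df["chain"] == key.chain) & (df["resnum"] == key.resnum)

    site_sc = _res_mask(site) & df["atom"].isin(SIDECHAIN_ATOMS)
    if not _res_mask(site).any():
        raise ParameterError(f"site residue {site} not in model")
    deleted = df[site_sc]
    truth.deleted_atoms = [(site.chain, site.resnum, a) for a in deleted["atom"]]
    centroid = deleted[["x", "y", "z"]].to_numpy(float).mean(axis=0)
    df = df[~site_sc].reset_index(drop=True)

    for key in tendril:
        m = _res_mask(key) & df["atom"].isin(SIDECHAIN_ATOMS)
        if not m.any():
            raise ParameterError(f"tendril residue {key} not in model")
        idx = df.index[m]
        for i in idx:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            df.loc[i, ["x", "y", "z"]] = (
                df.loc[i, ["x", "y", "z"]].to_numpy(float) + shift_A * direction
            )
            truth.shifted_atoms.append((key.chain, key.resnum, df.loc[i, "atom"], shift_A))

    wat_num = int(df["resnum"].max()) + 10
    water = pd.DataFrame(
        [("A", wat_num, "HOH", "O", "", "O", *centroid, 1.0)], columns=ATOM_COLUMNS
    )
    truth.added_waters = [("A", wat_num, [float(v) for v in centroid])]
    df = pd.concat([df, water], ignore_index=True)
    return AtomicModel(atoms=df, cell=model.cell, spacegroup=model.spacegroup), truth


def simulate_reflections(
    model: AtomicModel,
    d_min: float = 2.0,
    noise_frac: float = 0.05,
    seed: int = 0,
    b_iso: float = 15.0,
    stream: int = _STREAM_REFL_WT,
) -> ReflectionSet:
    """Amplitudes from direct summation with proportional Gaussian noise.

    F_obs = |F_calc| + N(0, noise_frac * |F_calc|), clipped at 0;
    sigF = noise_frac * |F_calc| is reported as the uncertainty.
    """
    if d_min < 1.0:
        raise ParameterError("d_min must be >= 1.0 A")
    if noise_frac < 0:
        raise ParameterError("noise_frac must be >= 0")
    cell = model.gemmi_cell()
    hkl = unique_hkl_p1(cell, d_min, include_origin=True)
    f_true = np.abs(structure_factors(model, hkl, b_iso=b_iso))
    sig = noise_frac * f_true
    rng = _rng(seed, stream)
    f_obs = np.clip(f_true + rng.normal(0.0, 1.0, size=len(f_true)) * sig, 0.0, None)
    df = pd.DataFrame(
        {"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "F": f_obs, "SIGF": sig}
    )
    return ReflectionSet(data=df, cell=model.cell, spacegroup="P 1", d_min=float(d_min))


def random_sequence(n: int, seed: int, pro_every: int = 13) -> str:
    """Random 20-letter sequence with sparse prolines (never at position 2)."""
    rng = _rng(seed, _STREAM_PEPTIDES)
    seq = [AA20[i] for i in rng.integers(0, len(AA20), size=n)]
    for p in range(pro_every, n, pro_every):
        seq[p] = "P"
    return "".join(seq)


def _pepsin_tiling(length: int, rng: np.random.Generator, passes: int = 6) -> list[tuple[int, int]]:
    """Random overlapping 5-15-mer tilings, ~4-5x average redundancy.

    Local-HDX pepsin maps are highly redundant; several independent
    fragmentation passes emulate the overlapping charge states and
    missed cleavages of a real peptide map.
    """
    spans: set[tuple[int, int]] = set()
    for _ in range(passes):
        pos = 1
        while pos <= length:
            plen = int(rng.integers(5, 16))
            end = min(pos + plen - 1, length)
            if length - end < 5:
                end = length
            start = max(1, end - max(plen, 5) + 1) if end == length else pos
            spans.add((start, end))
            if end == length:
                break
            pos = end + 1 - int(rng.integers(0, 3))
    return sorted(spans)


def _wt_uptake(t: float, t50: np.ndarray, d_max: float = 80.0) -> np.ndarray:
    """Two-parameter logistic in log-time: %D(t) = D_max * t / (t + t50)."""
    return d_max * t / (t + t50)


def _delta_scale(t: float, tau: float = 100.0) -> float:
    """Smooth growth of the planted difference; equals 1 exactly at 300 s."""
    return (1.0 - np.exp(-t / tau)) / (1.0 - np.exp(-300.0 / tau))


def simulate_hdx_tables(
    sequence: str,
    planted_track: dict[int, float],
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    replicates: dict[float, int] | None = None,
    noise_sd: float = 1.5,
    seed: int = 0,
    d2o_fraction: float = DEFAULT_D2O_FRACTION,
    states: tuple[str, str] = ("WT", "MUT"),
    return_truth: bool = False,
):
    """Long-format peptide centroid-mass table for a WT/mutant pair.

    Residue-level WT uptake follows a logistic curve in log-time; the
    mutant adds the planted per-residue difference (its value defined at
    300 s, scaled smoothly across timepoints). Peptide %D is the mean
    over the peptide's exchange-reporting amides; Gaussian noise
    (``noise_sd`` percentage points) is added per replicate, and %D is
    converted to centroid masses as the exact inverse of the analyser's
    FD-corrected percent-deuteration formula. Undeuterated and FD control
    rows are emitted for every peptide and state.
    """
    if len(sequence) < 20:
        raise ParameterError("sequence must have >= 20 residues")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    L = len(sequence)
    rng_pep = _rng(seed, _STREAM_PEPTIDES)
    rng_noise = _rng(seed, _STREAM_HDX_NOISE)
    replicates = dict(DEFAULT_REPLICATES) if replicates is None else replicates

    spans = []
    for s, e in _pepsin_tiling(L, rng_pep):
        pep = sequence[s - 1 : e]
        try:
            exchangeable_amides(pep)
        except Exception:
            continue  # degenerate (Pro-heavy) fragment: pepsin map omits it
        spans.append((s, e, pep))

    t50 = np.exp(rng_pep.uniform(np.log(20.0), np.log(5000.0), size=L))  # per residue
    wt_state, mut_state = states

    rows = []
    truth_rows = []
    for s, e, pep in spans:
        n_ex = exchangeable_amides(pep)
        m0 = float(pyteomics_mass.calculate_mass(sequence=pep))
        m_fd = m0 + n_ex * DEUTERIUM_MASS_SHIFT * d2o_fraction
        amides = np.array(amide_positions(pep, s)) - 1  # 0-based residue indices
        for state in states:
            rows.append((state, pep, s, e, 0.0, 1, m0))
            rows.append((state, pep, s, e, FD_SENTINEL, 1, m_fd))
            for t in timepoints:
                base = _wt_uptake(t, t50[amides])
                if state == mut_state:
                    scale = _delta_scale(t)
                    base = base + np.array(
                        [planted_track.get(r + 1, 0.0) * scale for r in amides]
                    )
                pct_clean = float(base.mean())
                truth_rows.append((state, pep, s, e, float(t), pct_clean))
                for rep in range(1, replicates.get(t, 1) + 1):
                    pct = pct_clean + (rng_noise.normal(0.0, noise_sd) if noise_sd else 0.0)
                    m_t = m0 + pct / 100.0 * (m_fd - m0)
                    rows.append((state, pep, s, e, float(t), rep, m_t))
    table = pd.DataFrame(
        rows,
        columns=["state", "sequence", "start", "end", "timepoint_s", "replicate", "centroid_mass_da"],
    )
    if return_truth:
        truth = pd.DataFrame(
            truth_rows,
            columns=["state", "sequence", "start", "end", "timepoint_s", "pct_d_true"],
        )
        return table, truth
    return table


def write_peptide_table(df: pd.DataFrame, path) -> None:
    """CSV writer matching :func:`allonet.hdx.read_peptide_table` ('FD' rows)."""
    out = df.copy()
    out["timepoint_s"] = [
        "FD" if np.isinf(t) else (int(t) if float(t).is_integer() else t)
        for t in out["timepoint_s"]
    ]
    out.to_csv(path, index=False)


@dataclass
class SyntheticScenario:
    """One complete paired synthetic study with its ground truth."""

    wt_model: AtomicModel
    mut_model: AtomicModel
    wt_reflections: ReflectionSet
    mut_reflections: ReflectionSet
    hdx_table: pd.DataFrame
    sequence: str
    truth: GroundTruth
    d_min: float
    seed: int

    def write(self, outdir) -> dict:
        from .model_io import write_model

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "wt_model": outdir / "wt.pdb",
            "mut_model": outdir / "mut.pdb",
            "wt_reflections": outdir / "wt_reflections.csv",
            "mut_reflections": outdir / "mut_reflections.csv",
            "hdx": outdir / "hdx.csv",
            "truth": outdir / "truth.json",
        }
        write_model(self.wt_model, paths["wt_model"])
        write_model(self.mut_model, paths["mut_model"])
        self.wt_reflections.to_csv(paths["wt_reflections"])
        self.mut_reflections.to_csv(paths["mut_reflections"])
        write_peptide_table(self.hdx_table, paths["hdx"])
        self.truth.to_json(paths["truth"])
        return {k: str(v) for k, v in paths.items()}


def planted_sector(
    truth: GroundTruth, n_residues: int, n_extra: int = 4, seed: int = 0
) -> ResidueSet:
    """A coevolving-sector stand-in that contains the planted network.

    Mirrors a sector harbouring the allosteric tendril: all planted
    residues plus ``n_extra`` seeded random others.
    """
    rng = _rng(seed, 7717)
    chain = truth.site.chain
    core = sorted(k.resnum for k in truth.perturbed.members)
    pool = [r for r in rng.permutation(np.arange(1, n_residues + 1)) if r not in core]
    members = {ResidueKey(chain, int(r)) for r in core + [int(x) for x in pool[:n_extra]]}
    return ResidueSet("planted-sector", frozenset(members), "synthetic: contains planted network")


def random_sector(
    size: int, n_residues: int, seed: int, chain: str = "A", tag: int = 7919
) -> ResidueSet:
    """A size-matched sector with no relation to the planted perturbation."""
    rng = _rng(seed, tag)
    picks = rng.permutation(np.arange(1, n_residues + 1))[:size]
    return ResidueSet(
        "random-sector",
        frozenset(ResidueKey(chain, int(r)) for r in picks),
        "synthetic: uniform random residues",
    )


def segment_track(
    centers_amplitudes: dict[int, float], half_width: int, n_residues: int
) -> dict[int, float]:
    """Contiguous planted segments: each center spreads over +/- half_width.

    Exchange perturbations act on secondary-structure elements, not lone
    residues, so the planted track covers a short segment around each
    perturbed site (later centers overwrite earlier ones on overlap).
    """
    track: dict[int, float] = {}
    for center, amp in centers_amplitudes.items():
        for r in range(center - half_width, center + half_width + 1):
            if 1 <= r <= n_residues:
                track[r] = amp
    return track


def benchmark_scenario(
    seed: int,
    n_residues: int = 40,
    site: int = 25,
    tendril: tuple[int, ...] = (10, 12, 30),
    shift_A: float = 0.5,
    d_min: float = 2.0,
    noise_frac: float = 0.05,
    hdx_noise_sd: float = 1.5,
    planted_dhdx: dict[int, float] | None = None,
) -> SyntheticScenario:
    """The default study conditions: one mutation, a 3-residue tendril.

    40-residue chain, 2.0 A data with 5% amplitude noise, HDX noise
    1.5 percentage points, planted 300 s differences about twice the
    7-point network cutoff, spread over +/-3-residue segments around
    each perturbed site (exchange perturbations act on secondary-
    structure elements, not lone residues).
    """
    if planted_dhdx is None:
        centers = {site: 20.0}
        signs = (-1.0, -1.0, 1.0)
        for r, sgn in zip(tendril, signs):
            centers[r] = sgn * 15.0
        planted_dhdx = segment_track(centers, half_width=2, n_residues=n_residues)
    wt = make_toy_crystal(n_residues, seed)
    site_key = ResidueKey("A", site)
    tendril_keys = [ResidueKey("A", r) for r in tendril]
    mut, truth = apply_mutation_like_edit(wt, site_key, tendril_keys, shift_A=shift_A, seed=seed)
    truth.planted_dhdx = dict(planted_dhdx)
    wt_refl = simulate_reflections(wt, d_min, noise_frac, seed, stream=_STREAM_REFL_WT)
    mut_refl = simulate_reflections(mut, d_min, noise_frac, seed, stream=_STREAM_REFL_MUT)
    sequence = random_sequence(n_residues, seed)
    hdx_table = simulate_hdx_tables(
        sequence, planted_dhdx, noise_sd=hdx_noise_sd, seed=seed
    )
    return SyntheticScenario(
        wt_model=wt,
        mut_model=mut,
        wt_reflections=wt_refl,
        mut_reflections=mut_refl,
        hdx_table=hdx_table,
        sequence=sequence,
        truth=truth,
        d_min=d_min,
        seed=seed,
    )
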