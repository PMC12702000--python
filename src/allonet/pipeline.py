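"""End-to-end wiring: difference map -> IADDAT, HDX -> residue track, network.

`analyze_pair` handles one mutant/WT pair in memory; `run_pipeline`
drives it from a file-based configuration (the CLI's `run` subcommand)
and writes per-stage artifacts plus a provenance manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import hdx as hdxmod
from .diffmap import iaddat, scale_to_reference, synthesize_map, weighted_differences
from .model_io import AtomicModel, ResidueKey, read_model
from .network import (
    DHDX_CUTOFF,
    IADDAT_CUTOFF,
    OverlapResult,
    ResidueSet,
    hypergeometric_overlap,
    jaccard,
    load_sector,
    pool_sets,
    threshold_track,
)
from .tracks import ResidueTrack, normalize_track

logger = logging.getLogger(__name__)


@dataclass
class PairResult:
    """Per-mutant tracks and thresholded sets."""

    label: str
    iaddat_raw: ResidueTrack
    iaddat_norm: ResidueTrack
    hdx_track: ResidueTrack
    iaddat_set: ResidueSet
    hdx_set: ResidueSet
    diff_report: dict


@dataclass
class PipelineResult:
    """Combined network and its overlap statistics."""

    pairs: list[PairResult]
    network: ResidueSet
    population: ResidueSet
    overlaps: list[OverlapResult] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "network_size": len(self.network),
            "population_size": len(self.population),
            "per_mutant": {
                p.label: {
                    "iaddat_set": len(p.iaddat_set),
                    "hdx_set": len(p.hdx_set),
                }
                for p in self.pairs
            },
            "overlaps": [o.as_dict() for o in self.overlaps],
        }


def analyze_pair(
    label: str,
    wt_model: AtomicModel,
    wt_reflections,
    mut_reflections,
    hdx_table: pd.DataFrame,
    wt_state: str = "WT",
    mut_state: str = "MUT",
    alpha: float = 0.05,
    iaddat_threshold: float = 0.04,
    iaddat_radius: float = 1.5,
    iaddat_cutoff: float = IADDAT_CUTOFF,
    dhdx_cutoff: float = DHDX_CUTOFF,
    timepoint: float = 300.0,
    cap: float = 0.3,
    use_selected_peptides: bool = False,
    grid_spacing_factor: float = 3.0,
) -> PairResult:
    """One mutant vs WT: weighted difference map, IADDAT, delta-HDX track, sets.

    IADDAT voxels are assigned against the WT (reference/phase-source)
    model so that density at deleted-atom positions is still attributed
    to the right residue. The residue-level HDX track uses all peptides
    by default: redundant overlapping coverage is what allows residue-
    level inference, and restricting to the minimal spanning selection
    (``use_selected_peptides=True``) leaves gaps at each selected
    peptide's non-reporting first residues.
    """
    scaled_mut = scale_to_reference(mut_reflections, wt_reflections)
    diffs = weighted_differences(scaled_mut, wt_reflections, alpha=alpha, phase_source=wt_model)
    grid = synthesize_map(diffs, grid_spacing_factor=grid_spacing_factor)
    raw = iaddat(grid, wt_model, threshold=iaddat_threshold, radius=iaddat_radius)
    norm = normalize_track(raw, cap=cap)
    iset = threshold_track(norm, iaddat_cutoff, mode="greater", label=f"{label}:iaddat")

    table = hdx_table
    ex = hdxmod.exchange_table(table)
    diffres = hdxmod.difference_records(
        ex[ex["state"] == mut_state], ex[ex["state"] == wt_state]
    )
    spans = None
    if use_selected_peptides:
        spans = hdxmod.select_spanning_peptides(ex[ex["state"] == wt_state])
    track = hdxmod.residue_projection(diffres.records, timepoint=timepoint, spans=spans)
    hset = threshold_track(track, dhdx_cutoff, mode="abs_greater", label=f"{label}:dhdx")

    return PairResult(
        label=label,
        iaddat_raw=raw,
        iaddat_norm=norm,
        hdx_track=track,
        iaddat_set=iset,
        hdx_set=hset,
        diff_report={
            "reflections": diffs.report,
            "unmatched_peptides_mut": len(diffres.unmatched_mut),
            "unmatched_peptides_wt": len(diffres.unmatched_wt),
        },
    )


def measurable_population(
    wt_model: AtomicModel, hdx_table: pd.DataFrame, mode: str = "auto", chain: str = "A"
) -> ResidueSet:
    """The hypergeometric universe.

    'auto': residues both modelled in the crystal structure and covered
    by peptides shared across all states — the conservatively measurable
    set. 'model': all modelled residues.
    """
    modelled = set(wt_model.residue_keys())
    if mode == "model":
        members = modelled
    elif mode == "auto":
        states = hdx_table["state"].unique()
        per_state = [
            {(int(s), int(e)) for s, e in zip(g["start"], g["end"])}
            for _, g in hdx_table.groupby("state")
        ]
        shared = set.intersection(*per_state) if len(per_state) else set()
        covered = set()
        for s, e in shared:
            covered |= {ResidueKey(chain, r) for r in range(s, e + 1)}
        members = modelled & covered
    else:
        raise ValueError(f"unknown population mode {mode!r}")
    return ResidueSet(label=f"population:{mode}", members=frozenset(members), provenance=mode)


def combine_network(pairs: list[PairResult], label: str = "combined") -> ResidueSet:
    """Pool the per-mutant IADDAT and delta-HDX sets into the combined network."""
    sets = []
    for p in pairs:
        sets.extend([p.iaddat_set, p.hdx_set])
    return pool_sets(sets, label=label)


def compare_sectors(
    network: ResidueSet, sectors: list[ResidueSet], population: ResidueSet
) -> list[OverlapResult]:
    """Enrichment of each sector in the network, inside the population.

    Residues outside the measurable population (not modelled, or in an
    HDX coverage gap) cannot participate in the draw, so both the network
    and each sector are clipped to the population before testing.
    """
    net = ResidueSet(
        label=network.label,
        members=network.members & population.members,
        provenance=network.provenance + " (clipped to population)",
    )
    out = []
    for sec in sectors:
        clipped = ResidueSet(
            label=sec.label,
            members=sec.members & population.members,
            provenance=sec.provenance + " (clipped to population)",
        )
        out.append(hypergeometric_overlap(net, clipped, population))
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """File-driven run: one or more mutants, optional sector comparisons.

    Config keys: wt_model, pairs (list of {label, wt_reflections,
    mut_reflections}), hdx_table, states, sectors (list of paths),
    population ('auto' | 'model'), plus the numeric thresholds of
    :func:`analyze_pair`. Writes per-stage CSVs and a manifest with input
    hashes and parameters.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"inputs": {}, "parameters": {}, "outputs": {}, "status": "running"}
    try:
        wt_model = read_model(config["wt_model"])
        manifest["inputs"]["wt_model"] = _sha256(config["wt_model"])
        hdx_table = hdxmod.read_peptide_table(config["hdx_table"])
        manifest["inputs"]["hdx_table"] = _sha256(config["hdx_table"])
        params = {
            k: config[k]
            for k in (
                "alpha",
                "iaddat_threshold",
                "iaddat_radius",
                "iaddat_cutoff",
                "dhdx_cutoff",
                "timepoint",
                "cap",
            )
            if k in config
        }
        manifest["parameters"] = params

        from .diffmap import ReflectionSet

        def _load_refl(path):
            path = str(path)
            if path.endswith(".mtz"):
                return ReflectionSet.from_mtz(path)
            cell = wt_model.cell
            return ReflectionSet.from_csv(path, cell=cell)

        pairs = []
        for pc in config["pairs"]:
            pr = analyze_pair(
                pc["label"],
                wt_model,
                _load_refl(pc["wt_reflections"]),
                _load_refl(pc["mut_reflections"]),
                hdx_table,
                wt_state=config.get("wt_state", "WT"),
                mut_state=pc.get("mut_state", "MUT"),
                **params,
            )
            pairs.append(pr)
            track_csv = outdir / f"{pc['label']}_tracks.csv"
            iadd = pr.iaddat_norm.to_frame().rename(columns={"score": "iaddat_norm"})
            iadd["iaddat_raw"] = [pr.iaddat_raw.scores[k] for k in sorted(pr.iaddat_raw.scores)]
            iadd.to_csv(track_csv, index=False)
            hdx_csv = outdir / f"{pc['label']}_dhdx.csv"
            pr.hdx_track.to_frame().to_csv(hdx_csv, index=False)
            manifest["outputs"][pc["label"]] = [str(track_csv), str(hdx_csv)]

        network = combine_network(pairs)
        population = measurable_population(
            wt_model, hdx_table, mode=config.get("population", "auto")
        )
        result = PipelineResult(pairs=pairs, network=network, population=population)
        sectors = [load_sector(p) for p in config.get("sectors", [])]
        if sectors:
            result.overlaps = compare_sectors(network, sectors, population)

        summary_path = outdir / "network_summary.json"
        summary_path.write_text(json.dumps(result.summary(), indent=1))
        manifest["outputs"]["summary"] = str(summary_path)
        manifest["status"] = "ok"
        return manifest
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        raise
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
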