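"""Residue-level differential HDX-MS from peptide centroid masses.

Takes long-format peptide tables (state x peptide x timepoint x replicate
centroid masses), computes back-exchange-corrected percent deuteration,
mutant-minus-WT differences, and projects peptide differences onto single
residues by inverse-amide-count weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegeneratePeptideError, JoinError, ParameterError
from .model_io import ResidueKey
from .tracks import ResidueTrack

logger = logging.getLogger(__name__)

#: mass increment of one H -> D substitution (Da)
DEUTERIUM_MASS_SHIFT = 2.014101778 - 1.007825032
#: default D2O mole fraction of the labelling buffer
DEFAULT_D2O_FRACTION = 0.90
#: timepoint grid of the labelling experiment (seconds)
DEFAULT_TIMEPOINTS = (30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0)
#: |delta %D| below this is displayed as neutral (gray band)
NEUTRAL_BAND = 5.0
#: peptide %D outside [0,100] by more than this fails QC and is dropped
QC_EXCURSION = 5.0

FD_SENTINEL = np.inf  # timepoint value marking fully-deuterated control rows


def exchangeable_amides(sequence: str) -> int:
    """Number of backbone amides that report exchange for a peptide.

    Excluded: the N-terminal residue (no amide within the peptide), every
    proline (no amide NH), and — when position 2 is not proline — the
    second residue, whose amide back-exchanges too fast to retain label.
    """
    seq = sequence.upper()
    if len(seq) < 2:
        raise DegeneratePeptideError(f"peptide {sequence!r} shorter than 2 residues")
    n = (len(seq) - 1) - seq[1:].count("P")
    if seq[1] != "P":
        n -= 1
    if n < 1:
        raise DegeneratePeptideError(f"peptide {sequence!r} has no exchangeable amides")
    return n


def amide_positions(sequence: str, start: int) -> list[int]:
    """Residue numbers (given peptide start) whose amides carry signal.

    These are the non-proline residues from peptide position 3 onward —
    the closed-form count of :func:`exchangeable_amides` enumerated.
    """
    seq = sequence.upper()
    return [start + i for i in range(2, len(seq)) if seq[i] != "P"]


def percent_deuteration(
    m_t: float,
    m_0: float,
    m_fd: float | None,
    n_exchangeable: int,
    d2o_fraction: float = DEFAULT_D2O_FRACTION,
) -> float:
    """Back-exchange-corrected %deuteration of one peptide measurement.

    With a fully-deuterated (FD) control: %D = 100 (m_t - m_0)/(m_FD - m_0),
    which cancels back-exchange and any affine mass-axis miscalibration.
    Without FD: %D = 100 (m_t - m_0) / (n_ex * dm_HD * x_D2O), the
    theoretical-maximum normalisation at the labelling D2O fraction.
    """
    if m_fd is not None:
        if m_fd <= m_0:
            raise ParameterError(f"FD mass {m_fd} must exceed undeuterated mass {m_0}")
        return 100.0 * (m_t - m_0) / (m_fd - m_0)
    if n_exchangeable < 1:
        raise DegeneratePeptideError("n_exchangeable must be >= 1")
    return 100.0 * (m_t - m_0) / (n_exchangeable * DEUTERIUM_MASS_SHIFT * d2o_fraction)


def read_peptide_table(path) -> pd.DataFrame:
    """Read the long-format CSV: state,sequence,start,end,timepoint_s,replicate,centroid_mass_da.

    FD control rows carry timepoint_s = "FD" (mapped to an infinite
    sentinel); undeuterated rows carry timepoint_s = 0.
    """
    df = pd.read_csv(path, dtype={"state": str, "sequence": str})
    df["timepoint_s"] = [
        FD_SENTINEL if str(t).strip().upper() == "FD" else float(t) for t in df["timepoint_s"]
    ]
    df[["start", "end"]] = df[["start", "end"]].astype(int)
    bad = df["end"] - df["start"] + 1 != df["sequence"].str.len()
    if bad.any():
        raise JoinError(f"{int(bad.sum())} rows where span does not match sequence length")
    return df


def exchange_table(
    measurements: pd.DataFrame,
    d2o_fraction: float = DEFAULT_D2O_FRACTION,
    use_fd: bool = True,
    qc: bool = True,
) -> pd.DataFrame:
    """Peptide-level exchange records: %D per (state, span, timepoint).

    Replicate %D values are averaged (sample sd, n-1 denominator,
    reported). Peptides lacking an undeuterated reference — or an FD
    reference when ``use_fd`` — are skipped with a warning. QC drops
    records with %D outside [-5, 105]; smaller excursions outside [0,100]
    are retained (measurement noise) with a warning count.
    """
    rows = []
    n_warn = n_drop = 0
    for (state, start, end, seq), grp in measurements.groupby(
        ["state", "start", "end", "sequence"], sort=True
    ):
        und = grp[grp["timepoint_s"] == 0.0]
        if und.empty:
            logger.warning("no undeuterated reference for %s %s-%s; skipped", state, start, end)
            continue
        m0 = float(und["centroid_mass_da"].mean())
        m_fd = None
        if use_fd:
            fd = grp[np.isinf(grp["timepoint_s"])]
            if fd.empty:
                logger.warning("no FD control for %s %s-%s; skipped", state, start, end)
                continue
            m_fd = float(fd["centroid_mass_da"].mean())
        n_ex = exchangeable_amides(seq)
        labelled = grp[np.isfinite(grp["timepoint_s"]) & (grp["timepoint_s"] > 0)]
        for tp, tgrp in labelled.groupby("timepoint_s"):
            pct = np.array(
                [
                    percent_deuteration(m, m0, m_fd, n_ex, d2o_fraction)
                    for m in tgrp["centroid_mass_da"]
                ]
            )
            mean = float(pct.mean())
            if qc and not (-QC_EXCURSION <= mean <= 100 + QC_EXCURSION):
                n_drop += 1
                continue
            if mean < 0 or mean > 100:
                n_warn += 1
            rows.append(
                {
                    "state": state,
                    "start": start,
                    "end": end,
                    "sequence": seq,
                    "timepoint_s": float(tp),
                    "pct_d": mean,
                    "uptake_da": float(np.mean(tgrp["centroid_mass_da"] - m0)),
                    "n_exchangeable": n_ex,
                    "n_replicates": len(pct),
                    "sd": float(pct.std(ddof=1)) if len(pct) > 1 else np.nan,
                }
            )
    if n_warn:
        logger.warning("%d records slightly outside [0, 100]%% retained", n_warn)
    if n_drop:
        logger.warning("%d records failed QC (|excursion| > %s points) and were dropped",
                       n_drop, QC_EXCURSION)
    if not rows:
        raise JoinError("no peptide exchange records could be formed")
    return pd.DataFrame(rows)


@dataclass
class DifferenceResult:
    """Mutant-minus-WT peptide differences plus a coverage report."""

    records: pd.DataFrame  # start,end,sequence,timepoint_s,delta_pct_d,...
    unmatched_mut: pd.DataFrame
    unmatched_wt: pd.DataFrame

    def woods_table(self) -> pd.DataFrame:
        """Woods-plot table: span midpoint vs difference, one row per peptide."""
        df = self.records.copy()
        df["midpoint"] = (df["start"] + df["end"]) / 2.0
        return df[["midpoint", "start", "end", "timepoint_s", "delta_pct_d"]]


def difference_records(mutant: pd.DataFrame, wt: pd.DataFrame) -> DifferenceResult:
    """Inner-join mutant and WT exchange records; delta %D = mut - WT.

    Positive differences mean faster exchange in the mutant. Peptides
    observed in only one state are excluded from differences and listed
    in the coverage report.
    """
    keys = ["start", "end", "sequence", "timepoint_s"]
    j = mutant.merge(wt, on=keys, suffixes=("_mut", "_wt"))
    if j.empty:
        raise JoinError("no common peptides between mutant and WT")
    j["delta_pct_d"] = j["pct_d_mut"] - j["pct_d_wt"]
    out = j[keys + ["delta_pct_d", "n_exchangeable_mut"]].rename(
        columns={"n_exchangeable_mut": "n_exchangeable"}
    )
    tag_m = mutant.set_index(keys).index
    tag_w = wt.set_index(keys).index
    return DifferenceResult(
        records=out,
        unmatched_mut=mutant[~tag_m.isin(tag_w)],
        unmatched_wt=wt[~tag_w.isin(tag_m)],
    )


def residue_projection(
    diffs: pd.DataFrame,
    timepoint: float = 300.0,
    smoothing_window: int = 1,
    chain: str = "A",
    spans: set[tuple[int, int]] | None = None,
    coverage: str = "amides",
) -> ResidueTrack:
    """Project peptide delta %D onto residues at one timepoint.

    Each residue receives the weighted mean of delta %D over all peptides
    covering it, weighted by 1/(exchangeable amides) so short peptides —
    more local information — dominate. With ``coverage='amides'`` (default)
    a peptide covers only its exchange-reporting amide positions (non-Pro
    residues from position 3 on): the first two residues and prolines of a
    peptide carry no deuterium signal, so assigning them the peptide value
    would only smear the track. ``coverage='span'`` paints the whole span.
    Residues covered by no peptide are missing (absent), not zero.
    Optional centered moving average over ``smoothing_window`` residues;
    |value| <= 5 is flagged neutral in the display field (the gray band of
    the strip plots). ``spans`` restricts the projection to selected
    peptides.
    """
    if coverage not in ("amides", "span"):
        raise ParameterError(f"unknown coverage mode {coverage!r}")
    sel = diffs[diffs["timepoint_s"] == timepoint]
    if spans is not None:
        sel = sel[[(s, e) in spans for s, e in zip(sel["start"], sel["end"])]]
    if sel.empty:
        raise ParameterError(f"no difference records at timepoint {timepoint}")
    wsum: dict[int, float] = {}
    vsum: dict[int, float] = {}
    for rec in sel.itertuples():
        w = 1.0 / rec.n_exchangeable
        if coverage == "amides":
            positions = amide_positions(rec.sequence, rec.start)
        else:
            positions = range(rec.start, rec.end + 1)
        for r in positions:
            wsum[r] = wsum.get(r, 0.0) + w
            vsum[r] = vsum.get(r, 0.0) + w * rec.delta_pct_d
    values = {r: vsum[r] / wsum[r] for r in wsum}

    if smoothing_window > 1:
        half = smoothing_window // 2
        smoothed = {}
        for r in values:
            neigh = [values[q] for q in range(r - half, r + half + 1) if q in values]
            smoothed[r] = float(np.mean(neigh))
        values = smoothed

    scores = {ResidueKey(chain, r): v for r, v in sorted(values.items())}
    display = {k: (0.0 if abs(v) <= NEUTRAL_BAND else v) for k, v in scores.items()}
    return ResidueTrack(
        scores=scores,
        modality="delta_hdx",
        meta={
            "timepoint_s": timepoint,
            "smoothing_window": smoothing_window,
            "weighting": "inverse_exchangeable_amides",
            "neutral_band": NEUTRAL_BAND,
            "signed": True,
        },
        display=display,
    )


def select_spanning_peptides(records: pd.DataFrame) -> set[tuple[int, int]]:
    """Greedy minimal-size tiling of the sequence by short peptides.

    Weighted set cover over residues: repeatedly pick the peptide with
    the best (newly covered residues)/(length) ratio — ties broken by
    shorter peptide, then smaller start — until no peptide adds coverage.
    A final pruning pass drops any pick made redundant by later ones
    (longest first), so no selected peptide is removable without losing
    coverage. Mirrors choosing the shortest peptides that still span the
    sequence.
    """
    if records.empty:
        raise ParameterError("no peptides to select from")
    spans = sorted({(int(s), int(e)) for s, e in zip(records["start"], records["end"])})
    covered: set[int] = set()
    chosen: set[tuple[int, int]] = set()
    while True:
        best = None
        for (s, e) in spans:
            if (s, e) in chosen:
                continue
            new = len(set(range(s, e + 1)) - covered)
            if new == 0:
                continue
            length = e - s + 1
            score = (-new / length, length, s)
            if best is None or score < best[0]:
                best = (score, (s, e))
        if best is None:
            break
        chosen.add(best[1])
        s, e = best[1]
        covered |= set(range(s, e + 1))

    # prune redundant picks, longest first, until irredundant
    pruning = True
    while pruning:
        pruning = False
        for (s, e) in sorted(chosen, key=lambda se: (-(se[1] - se[0]), se[0])):
            rest: set[int] = set()
            for (s2, e2) in chosen - {(s, e)}:
                rest |= set(range(s2, e2 + 1))
            if covered <= rest:
                chosen.remove((s, e))
                pruning = True
                break
    return chosen


def coverage_fraction(measurements: pd.DataFrame, sequence_length: int) -> float:
    """Shared coverage: % of residues covered by peptides seen in every state.

    A peptide (span) counts only if it was observed in all states present
    in the table; the covered residues are the union of those spans.
    """
    if sequence_length < 1:
        raise ParameterError("sequence length must be >= 1")
    states = measurements["state"].unique()
    per_state = [
        {(int(s), int(e)) for s, e in zip(g["start"], g["end"])}
        for _, g in measurements.groupby("state")
    ]
    shared = set.intersection(*per_state) if per_state else set()
    covered: set[int] = set()
    for s, e in shared:
        covered |= set(range(s, min(e, sequence_length) + 1))
    covered = {r for r in covered if 1 <= r <= sequence_length}
    return 100.0 * len(covered) / sequence_length
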