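"""Combined allosteric-network construction and residue-set overlap statistics.

Residue sets come from thresholding per-residue tracks (IADDAT > 0.13 on
the normalized scale; |delta HDX| > 7 points at 300 s), are pooled across
variants into the combined network, and compared with externally supplied
coevolving sectors via the Jaccard ratio and a one-sided hypergeometric
enrichment test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .errors import InvariantViolationError, ParameterError, SectorParseError
from .model_io import ResidueKey
from .tracks import ResidueTrack

logger = logging.getLogger(__name__)

#: default cutoff on the normalized (0-1) IADDAT scale
IADDAT_CUTOFF = 0.13
#: default cutoff on |delta %D| at 300 s, percentage points
DHDX_CUTOFF = 7.0


@dataclass(frozen=True)
class ResidueSet:
    """A labelled set of residue addresses with its provenance string."""

    label: str
    members: frozenset[ResidueKey]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.members)


def threshold_track(
    track: ResidueTrack,
    cutoff: float,
    mode: str = "greater",
    label: str | None = None,
) -> ResidueSet:
    """Residues whose score exceeds the cutoff (strict inequality).

    ``mode='greater'`` for non-negative tracks (IADDAT), ``'abs_greater'``
    for signed tracks (delta HDX). Missing residues are never included.
    """
    if cutoff < 0:
        raise ParameterError("cutoff must be >= 0")
    if mode == "greater":
        members = {k for k, v in track.scores.items() if v > cutoff}
    elif mode == "abs_greater":
        members = {k for k, v in track.scores.items() if abs(v) > cutoff}
    else:
        raise ParameterError(f"unknown mode {mode!r}")
    return ResidueSet(
        label=label or f"{track.modality}>{cutoff}",
        members=frozenset(members),
        provenance=f"{track.modality} {mode} {cutoff} (meta={track.meta})",
    )


def pool_sets(sets: list[ResidueSet], label: str = "pooled") -> ResidueSet:
    """Union of residue sets; provenance concatenated."""
    members: frozenset[ResidueKey] = frozenset()
    for s in sets:
        members |= s.members
    return ResidueSet(
        label=label,
        members=members,
        provenance=" | ".join(s.label for s in sets),
    )


def jaccard(x: ResidueSet, y: ResidueSet) -> float:
    """J(X, Y) = |X intersect Y| / |X union Y|."""
    union = x.members | y.members
    if not union:
        raise InvariantViolationError("Jaccard undefined for two empty sets")
    return len(x.members & y.members) / len(union)


def hypergeom_sf(k: int, n_population: int, n_successes: int, n_draws: int) -> float:
    """Upper-tail P(K >= k) for K ~ Hypergeometric(N, K_successes, n_draws).

    Summed from the exact log-pmf (log-factorials via gammaln); numerically
    exact to ~1e-14 for the population sizes of interest.
    """
    if not (0 <= n_successes <= n_population and 0 <= n_draws <= n_population):
        raise ParameterError("invalid hypergeometric parameters")
    kmax = min(n_draws, n_successes)
    kmin = max(0, n_draws + n_successes - n_population)
    if k <= kmin:
        return 1.0
    if k > kmax:
        return 0.0

    def log_c(n, r):
        return gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1)

    ks = np.arange(k, kmax + 1)
    logp = (
        log_c(n_successes, ks)
        + log_c(n_population - n_successes, n_draws - ks)
        - log_c(n_population, n_draws)
    )
    return float(min(1.0, np.exp(logp).sum()))


@dataclass
class OverlapResult:
    """Jaccard + hypergeometric enrichment of two residue sets in a population."""

    x_label: str
    y_label: str
    n_x: int
    n_y: int
    n_intersection: int
    n_union: int
    jaccard: float
    p_hypergeometric: float
    n_population: int
    #: mid-p = P(K > k) + P(K = k)/2; approximately uniform under the null
    #: where the discrete upper-tail p is conservative — use for calibration
    #: diagnostics, report p_hypergeometric for inference
    midp_hypergeometric: float = 1.0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def hypergeometric_overlap(x: ResidueSet, y: ResidueSet, population: ResidueSet) -> OverlapResult:
    """Test whether X and Y share more residues than chance draws would.

    One-sided upper tail: p = P(K >= |X intersect Y|) when |X| residues
    are drawn without replacement from the population containing |Y|
    'successes'. The population should be the measurable universe
    (modelled in the crystal and covered by shared HDX peptides).
    """
    if not x.members <= population.members:
        raise ParameterError(f"set {x.label!r} not contained in population")
    if not y.members <= population.members:
        raise ParameterError(f"set {y.label!r} not contained in population")
    inter = x.members & y.members
    union = x.members | y.members
    N, nY, nX, k = len(population.members), len(y.members), len(x.members), len(inter)
    p = hypergeom_sf(k, N, nY, nX)
    midp = p - 0.5 * (p - hypergeom_sf(k + 1, N, nY, nX))
    return OverlapResult(
        x_label=x.label,
        y_label=y.label,
        n_x=len(x.members),
        n_y=len(y.members),
        n_intersection=len(inter),
        n_union=len(union),
        jaccard=len(inter) / len(union) if union else 0.0,
        p_hypergeometric=p,
        n_population=len(population.members),
        midp_hypergeometric=midp,
    )


def load_sector(path, label: str | None = None, default_chain: str = "A") -> ResidueSet:
    """Read a residue-set file: one 'chain:resnum' or bare number per line.

    Blank lines and '#' comments ignored; duplicates collapsed with a
    warning.
    """
    path = Path(path)
    members: set[ResidueKey] = set()
    n_dup = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        tok = raw.split("#")[0].strip()
        if not tok:
            continue
        try:
            if ":" in tok:
                chain, num = tok.split(":")
                key = ResidueKey(chain.strip(), int(num))
            else:
                key = ResidueKey(default_chain, int(tok))
        except ValueError as exc:
            raise SectorParseError(f"{path}:{lineno}: cannot parse {tok!r}", line=lineno) from exc
        if key in members:
            n_dup += 1
        members.add(key)
    if n_dup:
        logger.warning("%s: %d duplicate residues collapsed", path, n_dup)
    return ResidueSet(label=label or path.stem, members=frozenset(members), provenance=str(path))


def save_sector(rset: ResidueSet, path) -> None:
    lines = [f"{k.chain}:{k.resnum}" for k in sorted(rset.members)]
    Path(path).write_text("\n".join(lines) + "\n")
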