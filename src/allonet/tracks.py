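"""Per-residue scalar tracks (IADDAT, delta-%D) and their normalization."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvariantViolationError
from .model_io import ResidueKey


@dataclass
class ResidueTrack:
    """A scalar per residue over an addressed sequence range.

    ``scores`` maps ResidueKey -> value. Residues absent from ``scores``
    are *missing* (not measured), which downstream thresholding never
    includes — distinct from an explicit 0. ``display`` holds capped /
    flagged values for plotting; raw scores are never overwritten.
    """

    scores: dict[ResidueKey, float]
    modality: str = ""
    meta: dict = field(default_factory=dict)
    display: dict[ResidueKey, float] | None = None

    def max(self) -> float:
        return max(self.scores.values()) if self.scores else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": k.chain,
                "resnum": k.resnum,
                "score": v,
                **({"display": self.display[k]} if self.display else {}),
            }
            for k, v in sorted(self.scores.items())
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str = "score", **kw) -> "ResidueTrack":
        scores = {
            ResidueKey(str(r.chain), int(r.resnum)): float(getattr(r, value_col))
            for r in df.itertuples()
        }
        return cls(scores=scores, **kw)


def normalize_track(track: ResidueTrack, cap: float | None = None) -> ResidueTrack:
    """Scale scores to a 0-1 range by dividing by the maximum.

    An all-zero track is returned unchanged (degenerate guard). If ``cap``
    is given, a ``display`` field carries min(value, cap) for plotting
    while raw normalized values are preserved.
    """
    if any(v < 0 for v in track.scores.values()):
        raise InvariantViolationError("normalize_track requires non-negative scores")
    m = track.max()
    if m == 0:
        scores = dict(track.scores)
    else:
        scores = {k: v / m for k, v in track.scores.items()}
    display = None
    if cap is not None:
        display = {k: min(v, cap) for k, v in scores.items()}
    meta = dict(track.meta)
    meta.update(normalized=True, cap=cap, raw_max=m)
    return ResidueTrack(scores=scores, modality=track.modality, meta=meta, display=display)
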