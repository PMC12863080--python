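"""Ori/Ter localization from GC skew and replichore-relative positions.

On a circular bacterial chromosome the leading strand is G-rich, so the
windowed skew S = (G - C)/(G + C) switches sign at the replication
origin and terminus: the cumulative skew curve has its global minimum
near Ori and its global maximum near Ter.

Extrema are located on the mean-centered cumulative curve (the plain
cumulative sum is also reported): centering removes the linear drift a
nonzero genome-wide mean skew would add, which makes the located Ori
and Ter equivariant under rotation of the assembly start.  For balanced
replichores the two curves have the same extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from . import stats_kernel

__all__ = [
    "SkewProfile",
    "PositionalSample",
    "gc_skew_profile",
    "flag_ambiguous",
    "relative_position",
    "test_positional_bias",
]


@dataclass
class SkewProfile:
    genome_id: str
    window_bp: int
    S_w: np.ndarray            # per-window skew
    cumS: np.ndarray           # plain cumulative sum
    cum_centered: np.ndarray   # cumulative sum of (S - mean S); used for extrema
    ori_bp: int                # window midpoint at global min of cum_centered
    ter_bp: int                # window midpoint at global max
    genome_length_bp: int
    ambiguous: bool = False
    ambiguity_reason: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.S_w)


@dataclass
class PositionalSample:
    """Replichore-relative distances (0 = Ori, 1 = Ter) of rearranged-block
    midpoints pooled over a species, one entry per deduplicated block."""

    species_id: str
    distances: list[float]
    event_class: list[str]

    def __post_init__(self) -> None:
        if any(not (0.0 <= d <= 1.0) for d in self.distances):
            raise ValueError("distances must lie in [0, 1]")
        if len(self.distances) != len(self.event_class):
            raise ValueError("distances and event_class must be parallel")


def gc_skew_profile(
    sequence: str, window_bp: int = 1000, genome_id: str = ""
) -> SkewProfile:
    """Windowed and cumulative GC skew of a circular genome sequence.

    Non-overlapping consecutive windows; a trailing partial window is
    dropped.  Windows without G or C contribute S = 0.  The profile is
    ambiguity-flagged via :func:`flag_ambiguous` with default settings.
    """
    L = len(sequence)
    if L < 2 * window_bp:
        raise ValueError(f"sequence length {L} < 2 windows of {window_bp} bp")
    n_win = L // window_bp
    arr = np.frombuffer(sequence[: n_win * window_bp].upper().encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(n_win, window_bp)
    g = (arr == ord("G")).sum(axis=1).astype(float)
    c = (arr == ord("C")).sum(axis=1).astype(float)
    denom = g + c
    S = np.where(denom > 0, (g - c) / np.where(denom > 0, denom, 1.0), 0.0)
    cumS = np.cumsum(S)
    centered = np.cumsum(S - S.mean())
    ori_w = int(np.argmin(centered))
    ter_w = int(np.argmax(centered))
    prof = SkewProfile(
        genome_id=genome_id,
        window_bp=window_bp,
        S_w=S,
        cumS=cumS,
        cum_centered=centered,
        ori_bp=ori_w * window_bp + window_bp // 2,
        ter_bp=ter_w * window_bp + window_bp // 2,
        genome_length_bp=L,
    )
    flag_ambiguous(prof)
    return prof


def flag_ambiguous(
    profile: SkewProfile,
    prominence_frac: float = 0.2,
    min_sep_frac: float = 0.05,
) -> bool:
    """Flag profiles where Ori/Ter cannot be read off unambiguously.

    Ambiguous if a secondary valley (resp. peak) of the centered
    cumulative curve has prominence >= ``prominence_frac`` of the curve
    range and sits >= ``min_sep_frac`` of the genome away from the
    global one — i.e. 'multiple peaks and valleys' — or if the curve
    has no usable range at all.  Sets the profile's flag and reason.
    """
    curve = profile.cum_centered
    rng = float(curve.max() - curve.min())
    if rng <= 0:
        profile.ambiguous = True
        profile.ambiguity_reason = "flat cumulative skew; no extrema"
        return True
    n = profile.n_windows
    min_sep_windows = max(1, int(min_sep_frac * n))
    reasons = []
    for label, signed, global_idx in (
        ("valley", -curve, int(np.argmin(curve))),
        ("peak", curve, int(np.argmax(curve))),
    ):
        # the centered curve is periodic (it returns to zero), so find
        # extrema on a tiled copy to avoid boundary artifacts and keep
        # one full-context copy of each circular peak
        tiled, _ = find_peaks(np.tile(signed, 2), prominence=prominence_frac * rng)
        prominent = sorted({p % n for p in tiled if n // 2 <= p < n + n // 2})
        rivals = [
            p for p in prominent if _circ_dist(p, global_idx, n) >= min_sep_windows
        ]
        if rivals:
            reasons.append(f"secondary {label} of comparable prominence")
        # a global extremum not even detectable as a prominent feature
        # (e.g. an unskewed random walk) offers no support for an Ori/Ter call
        if len(prominent) == 0:
            reasons.append(f"global {label} lacks prominence")
    profile.ambiguous = bool(reasons)
    profile.ambiguity_reason = "; ".join(dict.fromkeys(reasons))
    return profile.ambiguous


def _circ_dist(a: int, b: int, n: int) -> int:
    d = abs(a - b)
    return min(d, n - d)


def relative_position(midpoint_bp: float, profile: SkewProfile) -> float:
    """Replichore-relative distance of a genomic position: 0 at Ori, 1 at Ter.

    The position is assigned to the Ori->Ter arc (replichore) that
    contains it and scaled by that arc's length.
    """
    if profile.ambiguous:
        raise ValueError(
            f"genome {profile.genome_id!r}: Ori/Ter ambiguous ({profile.ambiguity_reason})"
        )
    L = profile.genome_length_bp
    if not (1 <= midpoint_bp <= L):
        raise ValueError(f"midpoint {midpoint_bp} outside [1, {L}]")
    ori, ter = profile.ori_bp, profile.ter_bp
    arc1 = (ter - ori) % L  # replichore 1: Ori -> Ter in increasing coordinates
    if arc1 == 0:
        raise ValueError("Ori and Ter coincide")
    offset = (midpoint_bp - ori) % L
    if offset <= arc1:
        return offset / arc1
    return ((ori - midpoint_bp) % L) / (L - arc1)


def test_positional_bias(sample: PositionalSample) -> dict:
    """Wilcoxon signed-rank test of the distances against the neutral 0.5.

    Two-sided; ``direction`` reports whether the sample skews toward
    Ori (median < 0.5) or Ter.
    """
    if len(sample.distances) == 0:
        raise ValueError("no distances to test")
    res = stats_kernel.wilcoxon_signed_rank(sample.distances, mu=0.5)
    median = float(np.median(sample.distances))
    return {
        "n": len(sample.distances),
        "median_d": median,
        "W_statistic": res.statistic,
        "p_value": res.p_value,
        "direction": "Ori" if median < 0.5 else "Ter",
        "method": res.method,
    }
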