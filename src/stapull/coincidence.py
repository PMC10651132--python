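"""Two-color coincidence detection with chance correction.

An aggregate carrying both dye colors appears as a pair of puncta, one per
registered channel, whose centers of mass lie within the matching radius
(2 px by default). Random overlap of unrelated single-color puncta also
produces such pairs; that chance rate is estimated per field of view by
matching one channel against the other flipped horizontally and vertically —
a transformation that preserves the spot density and spatial statistics while
destroying true colocalization — and subtracted.

Matching is one-to-one and greedy by ascending distance (so every
mutual-nearest pair is accepted and no unmatched cross-channel pair closer
than an accepted pair is skipped), which prevents one bright spot from being
counted against several neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detection import Spot, SpotSet


@dataclass
class MatchParams:
    radius_px: float = 2.0

    def __post_init__(self) -> None:
        if not self.radius_px > 0:
            raise ValueError("radius_px must be positive")


@dataclass
class Match:
    index_a: int
    index_b: int
    spot_a: Spot
    spot_b: Spot
    distance_px: float


def match_spots(
    set_a: SpotSet, set_b: SpotSet, params: MatchParams | None = None
) -> list[Match]:
    """One-to-one greedy matching of cross-channel spot pairs within radius.

    Candidate pairs within ``radius_px`` are sorted by ascending distance
    (ties broken by spot indices for determinism) and accepted while both
    endpoints are unused.
    """
    params = params or MatchParams()
    if set_a.image_shape != set_b.image_shape:
        raise ValueError("spot sets come from images of different shapes")
    if len(set_a) == 0 or len(set_b) == 0:
        return []
    coords_a = set_a.coordinates()
    coords_b = set_b.coordinates()
    tree_b = cKDTree(coords_b)
    candidates: list[tuple[float, int, int]] = []
    for i, neighbors in enumerate(tree_b.query_ball_point(coords_a, params.radius_px)):
        for j in neighbors:
            d = float(np.linalg.norm(coords_a[i] - coords_b[j]))
            candidates.append((d, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[Match] = []
    for d, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append(Match(i, j, set_a.spots[i], set_b.spots[j], d))
    return matches


def flip_spotset(spot_set: SpotSet) -> SpotSet:
    """Flip centroids horizontally and vertically: (x, y) -> (W-1-x, H-1-y).

    Operating on coordinates is equivalent to flipping the image but avoids
    resampling artifacts. The image center is a fixed point of the flip, so a
    spot exactly at the center stays matched to itself — a documented edge
    case that is negligible for sparse fields.
    """
    h, w = spot_set.image_shape
    flipped = [
        replace(s, x=(w - 1) - s.x, y=(h - 1) - s.y) for s in spot_set.spots
    ]
    return SpotSet(
        flipped,
        spot_set.image_shape,
        spot_set.pixel_size_um,
        channel=spot_set.channel + "_flipped",
        fov=spot_set.fov,
    )


def chance_coincidence(
    set_a: SpotSet, set_b: SpotSet, params: MatchParams | None = None
) -> int:
    """Chance-coincidence count from the flipped-channel control."""
    return len(match_spots(set_a, flip_spotset(set_b), params))


@dataclass
class CoincidenceResult:
    """Per-FOV coincidence summary; densities in events/µm²."""

    matches: list[Match]
    n_coincident: int
    n_chance: int
    n_ch1: int
    n_ch2: int
    area_um2: float
    corrected_density: float  # (n_coincident - n_chance) / area; signed
    total_density: float
    fov: str = ""

    def matches_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fov": self.fov,
                "x1": [m.spot_a.x for m in self.matches],
                "y1": [m.spot_a.y for m in self.matches],
                "x2": [m.spot_b.x for m in self.matches],
                "y2": [m.spot_b.y for m in self.matches],
                "distance_px": [m.distance_px for m in self.matches],
            }
        )


def fov_result(
    set_a: SpotSet,
    set_b: SpotSet,
    params: MatchParams | None = None,
    coincident_multiplicity: int = 1,
) -> CoincidenceResult:
    """Coincidence counts and per-area densities for one field of view.

    ``corrected_density`` is the chance-corrected coincident density and may
    be negative for a single FOV (retained signed so sample averages stay
    unbiased). ``total_density`` counts total protein detections as
    ``n_ch1 + n_ch2 - coincident_multiplicity * n_coincident`` — each
    coincident event counted once by default.
    """
    area = set_a.area_um2
    if not area > 0:
        raise ValueError("zero imaged area")
    matches = match_spots(set_a, set_b, params)
    n_c = len(matches)
    n_chance = chance_coincidence(set_a, set_b, params)
    total = len(set_a) + len(set_b) - coincident_multiplicity * n_c
    return CoincidenceResult(
        matches=matches,
        n_coincident=n_c,
        n_chance=n_chance,
        n_ch1=len(set_a),
        n_ch2=len(set_b),
        area_um2=area,
        corrected_density=(n_c - n_chance) / area,
        total_density=total / area,
        fov=set_a.fov,
    )


@dataclass
class SampleSummary:
    """Sample-level aggregation over FOVs.

    ``fraction_oligomeric`` is the chance-corrected pooled proportion of
    total detections that were coincident,
    ``max(Σ(n_c - n_chance), 0) / Σ(n_ch1 + n_ch2 - n_c)``; ``clamped`` flags
    a negative pooled numerator. ``fraction_oligomeric_raw`` keeps the
    uncorrected coincident count in the numerator.
    """

    results: list[CoincidenceResult]
    mean_corrected_density: float
    sd_corrected_density: float
    mean_total_density: float
    sd_total_density: float
    fraction_oligomeric: float
    fraction_oligomeric_raw: float
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "n_fov": len(self.results),
            "mean_corrected_density_per_um2": self.mean_corrected_density,
            "sd_corrected_density_per_um2": self.sd_corrected_density,
            "mean_corrected_density_1e-4_per_um2": self.mean_corrected_density * 1e4,
            "mean_total_density_per_um2": self.mean_total_density,
            "sd_total_density_per_um2": self.sd_total_density,
            "mean_total_density_1e-4_per_um2": self.mean_total_density * 1e4,
            "fraction_oligomeric": self.fraction_oligomeric,
            "clamped": self.clamped,
        }


def summarize_sample(results: list[CoincidenceResult]) -> SampleSummary:
    """Mean/SD densities over FOVs and the pooled oligomeric fraction."""
    if not results:
        raise ValueError("no FOV results to summarize")
    corr = np.array([r.corrected_density for r in results])
    tot = np.array([r.total_density for r in results])
    sum_c = sum(r.n_coincident for r in results)
    sum_chance = sum(r.n_chance for r in results)
    sum_total = sum(r.n_ch1 + r.n_ch2 - r.n_coincident for r in results)
    corrected_num = sum_c - sum_chance
    clamped = corrected_num < 0
    frac = max(corrected_num, 0) / sum_total if sum_total > 0 else 0.0
    frac_raw = sum_c / sum_total if sum_total > 0 else 0.0
    return SampleSummary(
        results=results,
        mean_corrected_density=float(corr.mean()),
        sd_corrected_density=float(corr.std(ddof=1)) if len(corr) > 1 else 0.0,
        mean_total_density=float(tot.mean()),
        sd_total_density=float(tot.std(ddof=1)) if len(tot) > 1 else 0.0,
        fraction_oligomeric=float(frac),
        fraction_oligomeric_raw=float(frac_raw),
        clamped=bool(clamped),
    )
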