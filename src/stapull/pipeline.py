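"""End-to-end chains: project -> detect -> coincide -> summarize -> limits.

These helpers wire the stage modules together the way a full acquisition is
analyzed: per-FOV two-channel stacks are max-projected, channel 2 is
optionally resampled through a bead-derived registration transform, spots
are detected per channel, coincidence is chance-corrected per FOV, and FOV
results pool into sample summaries or calibration-series detection limits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coincidence import (
    CoincidenceResult,
    MatchParams,
    SampleSummary,
    fov_result,
    summarize_sample,
)
from .detection import DetectionParams, detect_spots
from .imaging import Image2D, ImageStack, RegistrationTransform, apply_registration, max_project
from .quantify import (
    DetectionLimits,
    fit_calibration,
    limit_of_blank,
    limit_of_detection,
)


def stapull_fov(
    stack1: ImageStack,
    stack2: ImageStack,
    det_params: DetectionParams | None = None,
    match_params: MatchParams | None = None,
    transform: RegistrationTransform | None = None,
    fov: str = "",
) -> CoincidenceResult:
    """Run the two-color coincidence analysis on one field of view."""
    img1 = max_project(stack1)
    img2 = max_project(stack2)
    if transform is not None:
        img2 = apply_registration(img2, transform)
    set1 = detect_spots(img1, det_params, channel="ch1", fov=fov)
    set2 = detect_spots(img2, det_params, channel="ch2", fov=fov)
    return fov_result(set1, set2, match_params)


def stapull_sample(
    fovs: list[tuple[ImageStack, ImageStack]],
    det_params: DetectionParams | None = None,
    match_params: MatchParams | None = None,
    transform: RegistrationTransform | None = None,
) -> SampleSummary:
    """Coincidence summary over a list of per-FOV stack pairs."""
    results = [
        stapull_fov(s1, s2, det_params, match_params, transform, fov=str(i))
        for i, (s1, s2) in enumerate(fovs)
    ]
    return summarize_sample(results)


def calibration_counts(
    series: list[tuple[float, object, ImageStack, ImageStack]],
    det_params: DetectionParams | None = None,
    match_params: MatchParams | None = None,
    fovs_per_replicate: int = 1,
) -> pd.DataFrame:
    """Chance-corrected coincident counts per replicate of a dilution series.

    ``series`` is the output of
    :func:`stapull.simulate.simulate_calibration_series` (or any list of
    (concentration, truth, stack1, stack2)); consecutive groups of
    ``fovs_per_replicate`` scenes at the same concentration pool into one
    replicate count.
    """
    rows = []
    for conc, _, s1, s2 in series:
        r = stapull_fov(s1, s2, det_params, match_params)
        rows.append((conc, r.n_coincident - r.n_chance))
    df = pd.DataFrame(rows, columns=["concentration", "counts"])
    if fovs_per_replicate > 1:
        df["replicate"] = df.groupby("concentration").cumcount() // fovs_per_replicate
        df = (
            df.groupby(["concentration", "replicate"], as_index=False)["counts"]
            .sum()
            .drop(columns="replicate")
        )
    return df


def detection_limits_from_counts(
    counts: pd.DataFrame, units: str = ""
) -> DetectionLimits:
    """LoB/LoD from a replicate count table with a zero-concentration blank.

    ``counts`` has columns ``concentration`` and ``counts``; concentration 0
    rows are the blanks, the smallest nonzero concentration supplies the SD
    for the LoD, and the calibration curve is fit to mean counts over all
    concentrations (blank included).
    """
    blanks = counts.loc[counts.concentration == 0, "counts"].to_numpy()
    if blanks.size < 2:
        raise ValueError("need >=2 blank (zero-concentration) replicates")
    lob = limit_of_blank(blanks)
    means = counts.groupby("concentration", as_index=False)["counts"].mean()
    curve = fit_calibration(means.concentration, means.counts)
    nonzero = sorted(c for c in counts.concentration.unique() if c > 0)
    if not nonzero:
        raise ValueError("series has no nonzero concentration")
    lowest = counts.loc[counts.concentration == nonzero[0], "counts"].to_numpy()
    return limit_of_detection(lob, lowest, curve, units=units)


def brute_force_lod(
    replicate_counts: pd.DataFrame, lob: float, min_fraction: float = 0.95
) -> float:
    """Empirical LoD: smallest concentration whose replicate counts exceed
    the LoB in at least ``min_fraction`` of replicates.

    Intended as an independent check of the formula-based LoD on densely
    replicated synthetic series; raises if no concentration qualifies.
    """
    for conc, grp in replicate_counts[replicate_counts.concentration > 0].groupby(
        "concentration"
    ):
        frac = float((grp.counts > lob).mean())
        if frac >= min_fraction:
            return float(conc)
    raise ValueError("no concentration exceeds the LoB reliably")
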