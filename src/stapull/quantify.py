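"""Detection-limit statistics and oligomer-concentration estimation.

Assay sensitivity is characterized the standard clinical-chemistry way:

* limit of blank, ``LoB = mean_blank + 1.645 * SD_blank`` — the highest count
  expected when no analyte is present;
* limit of detection, ``LoD = LoB + 1.645 * SD_lowest_concentration`` — the
  lowest count reliably distinguishable from blank, converted to a
  concentration through a second-order polynomial calibration curve fit to
  mean counts vs. concentration.

Concentrations enter as monomer equivalents (the starting monomer molarity),
which overestimates particle molarity; the oligomer (particle) concentration
is approximated as

    conc_olig = conc_mon * fraction_oligomeric / mean_monomer_incorporation

where the mean monomer incorporation — an intensity proxy for monomer units
per aggregate — is the average coincident-event intensity normalized by the
average single-molecule (non-coincident) intensity.

Sample (n-1) standard deviations are used throughout; replicate counts are
small (typically triplicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import Spot

Z_95 = 1.645  # one-sided 95th Gaussian percentile


@dataclass
class CalibrationCurve:
    """counts = c0 + c1*conc + c2*conc**2, valid on the fitted range."""

    coefficients: tuple[float, float, float]  # ascending order
    conc_range: tuple[float, float]
    residuals: np.ndarray

    def predict(self, conc):
        c0, c1, c2 = self.coefficients
        conc = np.asarray(conc, dtype=float)
        return c0 + c1 * conc + c2 * conc**2

    def invert(self, counts: float) -> float:
        """Concentration on the increasing branch within the fitted range."""
        c0, c1, c2 = self.coefficients
        lo, hi = self.conc_range
        span = hi - lo
        if abs(c2) < 1e-12 * max(abs(c1), 1.0):
            if c1 == 0:
                raise ValueError("degenerate flat calibration curve")
            roots = [(counts - c0) / c1]
        else:
            disc = c1**2 - 4 * c2 * (c0 - counts)
            if disc < 0:
                raise ValueError("no real root: counts outside the curve's range")
            sq = np.sqrt(disc)
            roots = [(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)]
        tol = 1e-9 * max(span, 1.0)
        ok = [
            r
            for r in roots
            if lo - tol <= r <= hi + tol and (c1 + 2 * c2 * r) > 0
        ]
        # both quadratic roots can coincide numerically; deduplicate
        uniq: list[float] = []
        for r in ok:
            if not any(abs(r - u) <= tol for u in uniq):
                uniq.append(r)
        if len(uniq) != 1:
            raise ValueError(
                f"{len(uniq)} admissible roots on the increasing branch in range"
            )
        return float(uniq[0])


@dataclass
class DetectionLimits:
    lob_counts: float
    lod_counts: float
    lod_concentration: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.lod_counts < self.lob_counts:
            raise ValueError("LoD counts cannot fall below LoB counts")

    def to_dict(self) -> dict:
        return {
            "lob_counts": self.lob_counts,
            "lod_counts": self.lod_counts,
            "lod_concentration": self.lod_concentration,
            "units": self.units,
        }


def limit_of_blank(blank_counts) -> float:
    """LoB = mean + 1.645 * sample SD of blank replicate counts."""
    blanks = np.asarray(blank_counts, dtype=float)
    if blanks.size < 2:
        raise ValueError("need at least 2 blank replicates")
    return float(blanks.mean() + Z_95 * blanks.std(ddof=1))


def fit_calibration(concs, mean_counts) -> CalibrationCurve:
    """Least-squares second-order polynomial of mean counts vs concentration."""
    concs = np.asarray(concs, dtype=float)
    counts = np.asarray(mean_counts, dtype=float)
    if len(np.unique(concs)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    coeffs = np.polynomial.polynomial.polyfit(concs, counts, deg=2)
    c0, c1, c2 = (float(c) for c in coeffs)
    fitted = c0 + c1 * concs + c2 * concs**2
    return CalibrationCurve(
        coefficients=(c0, c1, c2),
        conc_range=(float(concs.min()), float(concs.max())),
        residuals=counts - fitted,
    )


def limit_of_detection(
    lob: float, lowest_conc_counts, curve: CalibrationCurve, units: str = ""
) -> DetectionLimits:
    """LoD = LoB + 1.645 * SD(lowest-concentration counts), as a concentration.

    The count-scale LoD is converted through the calibration curve on its
    monotone-increasing branch.
    """
    counts = np.asarray(lowest_conc_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 replicates at the lowest concentration")
    lod_counts = float(lob + Z_95 * counts.std(ddof=1))
    return DetectionLimits(
        lob_counts=float(lob),
        lod_counts=lod_counts,
        lod_concentration=curve.invert(lod_counts),
        units=units,
    )


def mean_monomer_incorporation(
    coincident: list[tuple[Spot, Spot]], noncoincident: list[Spot]
) -> float:
    """Average coincident-event intensity over average single-molecule intensity.

    Each coincident event contributes the sum of its two channel intensities;
    the normalizer is the mean integrated intensity of non-coincident
    (single-label) spots.
    """
    if not coincident or not noncoincident:
        raise ValueError("need both coincident and noncoincident spots")
    pair_sums = np.array(
        [a.integrated_intensity + b.integrated_intensity for a, b in coincident]
    )
    mono = np.array([s.integrated_intensity for s in noncoincident])
    denom = mono.mean()
    if denom <= 0:
        raise ValueError("noncoincident mean intensity must be positive")
    return float(pair_sums.mean() / denom)


def oligomer_concentration(
    conc_mon: float, fraction_oligomeric: float, incorporation: float
) -> float:
    """conc_mon * fraction_oligomeric / incorporation, in conc_mon's units."""
    if not incorporation > 0:
        raise ValueError("mean monomer incorporation must be positive")
    return conc_mon * fraction_oligomeric / incorporation


def fold_above_baseline(sample_density: float, baseline_density: float) -> float:
    """Aggregate density as a fold increase above the buffer baseline."""
    if not baseline_density > 0:
        raise ValueError("baseline density must be positive")
    return sample_density / baseline_density
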