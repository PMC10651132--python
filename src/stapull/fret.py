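"""Two-color confocal burst analysis: coincidence, corrections, FRET, sizing.

Photon streams from the donor and acceptor detectors are binned (100 µs by
default, the expected confocal transit time) and analyzed bin-wise. A
coincident burst requires at least 8 counts per bin in *each* channel. Raw
counts are corrected for autofluorescence and donor→acceptor cross-talk,

    I_D = D - A_D
    I_A = A - A_A - C * D

and each burst yields a FRET efficiency E = I_A / (I_A + I_D) and an
approximate oligomer size 2 * (I_D + I_A) / I_monomer, where the monomer
brightness is the mean corrected donor intensity of non-coincident donor
bursts and the factor 2 accounts for the two dye colors each labeling about
half the monomer units.

Sizes are classed small (< 5-mers), medium (5 to 150 monomer units) or
large (> 150). Medium-oligomer FRET histograms are fit globally with two
Gaussian components — centers and widths shared across datasets, amplitudes
free per dataset — and per-population event rates are the analytic component
integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

COINCIDENCE_THRESHOLD_COUNTS = 8
SMALL_MAX_UNITS = 5.0
MEDIUM_MAX_UNITS = 150.0


@dataclass
class PhotonTrace:
    """Per-bin donor/acceptor photon counts."""

    donor_counts: np.ndarray
    acceptor_counts: np.ndarray
    bin_width_s: float = 1e-4

    def __post_init__(self) -> None:
        self.donor_counts = np.asarray(self.donor_counts)
        self.acceptor_counts = np.asarray(self.acceptor_counts)
        if self.donor_counts.shape != self.acceptor_counts.shape:
            raise ValueError("channel count arrays must have equal length")
        if np.any(self.donor_counts < 0) or np.any(self.acceptor_counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not self.bin_width_s > 0:
            raise ValueError("bin_width_s must be positive")

    @property
    def n_bins(self) -> int:
        return len(self.donor_counts)

    @property
    def duration_s(self) -> float:
        return self.n_bins * self.bin_width_s

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"donor": self.donor_counts, "acceptor": self.acceptor_counts}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, bin_width_s: float = 1e-4) -> "PhotonTrace":
        df = pd.read_csv(path)
        return cls(
            df["donor"].to_numpy(), df["acceptor"].to_numpy(), bin_width_s=bin_width_s
        )


@dataclass
class CorrectionConstants:
    """Instrument constants: autofluorescence per bin and donor cross-talk."""

    A_D: float = 0.0
    A_A: float = 0.0
    C: float = 0.0

    def __post_init__(self) -> None:
        if self.A_D < 0 or self.A_A < 0:
            raise ValueError("autofluorescence must be >= 0")
        if not 0.0 <= self.C < 1.0:
            raise ValueError("cross-talk C must lie in [0, 1)")


def find_coincident_bins(
    trace: PhotonTrace, threshold: int = COINCIDENCE_THRESHOLD_COUNTS
) -> np.ndarray:
    """Bins with at least ``threshold`` counts in each channel."""
    return np.flatnonzero(
        (trace.donor_counts >= threshold) & (trace.acceptor_counts >= threshold)
    )


def correct_intensities(D, A, k: CorrectionConstants):
    """Autofluorescence- and cross-talk–corrected channel intensities.

    Values may come out negative from noise; they are retained (downstream
    consumers flag them) rather than clipped.
    """
    D = np.asarray(D, dtype=float)
    A = np.asarray(A, dtype=float)
    return D - k.A_D, A - k.A_A - k.C * D


def fret_efficiency(I_D, I_A):
    """E = I_A / (I_A + I_D); unclamped, caller flags out-of-[0,1] values."""
    I_D = np.asarray(I_D, dtype=float)
    I_A = np.asarray(I_A, dtype=float)
    total = I_A + I_D
    if np.any(total == 0):
        raise ValueError("zero total intensity")
    return I_A / total


def monomer_brightness(
    trace: PhotonTrace,
    k: CorrectionConstants,
    threshold: int = COINCIDENCE_THRESHOLD_COUNTS,
) -> float:
    """Mean corrected donor intensity of non-coincident donor bursts.

    Non-coincident donor bursts have donor counts at or above threshold and
    acceptor counts below it — single-dye (donor-only) species.
    """
    idx = np.flatnonzero(
        (trace.donor_counts >= threshold) & (trace.acceptor_counts < threshold)
    )
    if idx.size == 0:
        raise ValueError("no noncoincident donor bursts")
    I_D, _ = correct_intensities(
        trace.donor_counts[idx], trace.acceptor_counts[idx], k
    )
    return float(np.mean(I_D))


def approximate_size(I_D, I_A, I_monomer: float):
    """Approximate oligomer size in monomer units: 2 (I_D + I_A) / I_monomer."""
    if not I_monomer > 0:
        raise ValueError("monomer brightness must be positive")
    return 2.0 * (np.asarray(I_D, dtype=float) + np.asarray(I_A, dtype=float)) / I_monomer


def classify_size(size: float) -> str:
    """small: < 5-mers; medium: 5 to 150 monomer units; large: > 150."""
    if size < 0:
        raise ValueError("size must be >= 0")
    if size < SMALL_MAX_UNITS:
        return "small"
    if size <= MEDIUM_MAX_UNITS:
        return "medium"
    return "large"


def analyze_trace(
    trace: PhotonTrace,
    k: CorrectionConstants,
    threshold: int = COINCIDENCE_THRESHOLD_COUNTS,
    I_monomer: float | None = None,
) -> pd.DataFrame:
    """Burst table for one trace: bin, D, A, I_D, I_A, E, size, size_class.

    When ``I_monomer`` is None it is estimated from the trace's own
    non-coincident donor bursts. ``flag_E`` marks efficiencies outside [0, 1]
    (kept in the table, excluded from histograms downstream).
    """
    bins = find_coincident_bins(trace, threshold)
    if I_monomer is None:
        I_monomer = monomer_brightness(trace, k, threshold)
    D = trace.donor_counts[bins].astype(float)
    A = trace.acceptor_counts[bins].astype(float)
    I_D, I_A = correct_intensities(D, A, k)
    total = I_D + I_A
    E = np.where(total != 0, I_A / np.where(total != 0, total, 1.0), np.nan)
    size = approximate_size(I_D, I_A, I_monomer)
    return pd.DataFrame(
        {
            "bin": bins,
            "D": D,
            "A": A,
            "I_D": I_D,
            "I_A": I_A,
            "E": E,
            "size": size,
            "size_class": [
                classify_size(s) if s >= 0 else "small" for s in size
            ],
            "flag_E": ~((E >= 0) & (E <= 1)),
        }
    )


def fret_histogram(
    E_values, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of in-range FRET efficiencies on [0, 1]; returns (centers, counts)."""
    E = np.asarray(E_values, dtype=float)
    E = E[(E >= 0) & (E <= 1) & np.isfinite(E)]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    counts, _ = np.histogram(E, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, counts.astype(float)


@dataclass
class FretPopulationFit:
    """Global two-Gaussian fit of FRET histograms.

    Component A is the lower-FRET population. Centers and widths are shared
    across datasets; amplitudes are per-dataset. ``areas`` are the analytic
    Gaussian integrals amp * sigma * sqrt(2*pi) (event-rate proxies) and
    ``weights`` their per-dataset normalized fractions (A, B).
    """

    center_a: float
    center_b: float
    sigma_a: float
    sigma_b: float
    amplitudes: np.ndarray  # (n_datasets, 2)
    areas: np.ndarray  # (n_datasets, 2)
    weights: np.ndarray  # (n_datasets, 2)
    redchi: float

    def to_dict(self) -> dict:
        return {
            "center_a": self.center_a,
            "center_b": self.center_b,
            "sigma_a": self.sigma_a,
            "sigma_b": self.sigma_b,
            "amplitudes": self.amplitudes.tolist(),
            "areas": self.areas.tolist(),
            "weights": self.weights.tolist(),
            "redchi": self.redchi,
        }


def _gauss(x, amp, cen, sig):
    return amp * np.exp(-((x - cen) ** 2) / (2 * sig**2))


def global_two_gaussian_fit(
    histograms: list[tuple[np.ndarray, np.ndarray]],
    init_centers: tuple[float, float] | None = None,
    min_separation: float = 0.02,
) -> FretPopulationFit:
    """Fit all histograms jointly with two shared-shape Gaussian components.

    ``histograms`` is a list of (bin_centers, counts) pairs on a common
    support. Initialization places the centers at the 25th/75th percentiles
    of the pooled distribution unless given. Raises if the input is
    degenerate (fewer than two nonzero bins anywhere, or all-zero) or if the
    fitted components collapse within ``min_separation``.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    for x, y in histograms:
        if np.count_nonzero(y) < 2:
            raise ValueError("each histogram needs at least 2 nonzero bins")
    if init_centers is None:
        pooled_x = np.concatenate([np.asarray(x) for x, _ in histograms])
        pooled_w = np.concatenate([np.asarray(y) for _, y in histograms])
        order = np.argsort(pooled_x)
        cdf = np.cumsum(pooled_w[order])
        cdf = cdf / cdf[-1]
        xs = pooled_x[order]
        init_centers = (
            float(np.interp(0.25, cdf, xs)),
            float(np.interp(0.75, cdf, xs)),
        )
    c1 = min(init_centers)
    c2 = max(init_centers)
    if c2 - c1 < 0.1:
        c1, c2 = max(c1 - 0.05, 0.0), min(c2 + 0.05, 1.0)

    params = Parameters()
    params.add("cen_a", value=c1, min=0.0, max=1.0)
    params.add("cen_b", value=c2, min=0.0, max=1.0)
    params.add("sig_a", value=0.05, min=1e-3, max=0.5)
    params.add("sig_b", value=0.05, min=1e-3, max=0.5)
    for i, (_, y) in enumerate(histograms):
        peak = float(np.max(y))
        params.add(f"amp_a_{i}", value=peak / 2, min=0.0)
        params.add(f"amp_b_{i}", value=peak / 2, min=0.0)

    def residual(p):
        res = []
        for i, (x, y) in enumerate(histograms):
            model = _gauss(x, p[f"amp_a_{i}"], p["cen_a"], p["sig_a"]) + _gauss(
                x, p[f"amp_b_{i}"], p["cen_b"], p["sig_b"]
            )
            res.append(np.asarray(y) - model)
        return np.concatenate(res)

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"global fit did not converge: {out.message}")
    p = out.params
    cen_a, cen_b = float(p["cen_a"]), float(p["cen_b"])
    sig_a, sig_b = float(p["sig_a"]), float(p["sig_b"])
    if cen_a > cen_b:  # enforce A = lower-FRET component
        cen_a, cen_b = cen_b, cen_a
        sig_a, sig_b = sig_b, sig_a
        swap = True
    else:
        swap = False
    n = len(histograms)
    amps = np.empty((n, 2))
    for i in range(n):
        a = float(p[f"amp_a_{i}"])
        b = float(p[f"amp_b_{i}"])
        amps[i] = (b, a) if swap else (a, b)
    if abs(cen_b - cen_a) < min_separation:
        raise RuntimeError("degenerate fit: components overlap within tolerance")
    areas = amps * np.array([sig_a, sig_b]) * np.sqrt(2 * np.pi)
    totals = areas.sum(axis=1, keepdims=True)
    weights = np.where(totals > 0, areas / np.where(totals > 0, totals, 1.0), np.nan)
    return FretPopulationFit(
        center_a=cen_a,
        center_b=cen_b,
        sigma_a=sig_a,
        sigma_b=sig_b,
        amplitudes=amps,
        areas=areas,
        weights=weights,
        redchi=float(out.redchi),
    )
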