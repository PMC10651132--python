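"""Ground-truthed synthetic TIRF scenes and confocal photon traces.

The generator emulates the statistical structure the two-color pulldown assay
assumes: sparse surface-bound molecules, monomers carrying a single detection
antibody and oligomers carrying several, each antibody label falling in one of
two spectral channels with probability ``color_split`` (0.5 for a 1:1 dye
mix). Images are rendered as sums of isotropic Gaussian PSFs with Poisson shot
noise, Gaussian read noise and a camera offset; the second channel can be
rendered with a sub-pixel inter-channel shift to exercise registration.

Photon traces for burst analysis are bin-wise: bursts occupy single 100-µs
bins, with donor/acceptor Poisson means chosen so that the standard
autofluorescence and cross-talk corrections are exact inverses in
expectation.

All randomness flows through one ``numpy`` Generator seeded from the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import Image2D, ImageStack


@dataclass
class SceneSpec:
    """Parameters of one simulated two-channel field of view."""

    fov_shape_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.1
    n_frames: int = 5
    frame_rate_hz: float = 20.0
    monomer_density_per_um2: float = 0.05
    oligomer_density_per_um2: float = 0.01
    # (name, params): "fixed" {"n": k} or "geometric" {"mean": m}; sizes >= 2
    oligomer_size_distribution: tuple[str, dict] = ("geometric", {"mean": 30.0})
    label_model: str = "bernoulli"  # or "poisson"
    labels_per_monomer_unit: float = 0.5  # Bernoulli p or Poisson mean
    color_split: float = 0.5
    psf_sigma_px: float = 1.3
    photons_per_label: float = 1500.0  # per frame
    camera_offset: float = 100.0
    read_noise_sd: float = 2.0
    inter_channel_shift_px: tuple[float, float] = (0.0, 0.0)  # (dx, dy)
    seed: int = 0

    def validate(self) -> None:
        if self.monomer_density_per_um2 < 0 or self.oligomer_density_per_um2 < 0:
            raise ValueError("densities must be >= 0")
        if not 0.0 <= self.color_split <= 1.0:
            raise ValueError("color_split must lie in [0, 1]")
        if not self.psf_sigma_px > 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.label_model not in ("bernoulli", "poisson"):
            raise ValueError("label_model must be 'bernoulli' or 'poisson'")
        name, _ = self.oligomer_size_distribution
        if name not in ("fixed", "geometric"):
            raise ValueError("oligomer size distribution must be 'fixed' or 'geometric'")


@dataclass
class SceneTruth:
    """Per-molecule ground truth for one scene."""

    table: pd.DataFrame  # x_px, y_px, species, n_units, n_labels_ch1, n_labels_ch2

    @property
    def n_molecules(self) -> int:
        return len(self.table)

    def visible(self) -> pd.DataFrame:
        t = self.table
        return t[(t.n_labels_ch1 + t.n_labels_ch2) > 0]

    def two_color_fraction(self) -> float:
        """Ground-truth oligomeric fraction on the detection scale.

        A molecule is a two-color (coincident) event when it carries labels in
        both channels; the denominator counts each molecule once per labeled
        channel, less the coincident — mirroring how detections are pooled.
        """
        t = self.table
        in1 = (t.n_labels_ch1 > 0).sum()
        in2 = (t.n_labels_ch2 > 0).sum()
        both = ((t.n_labels_ch1 > 0) & (t.n_labels_ch2 > 0)).sum()
        total = in1 + in2 - both
        return float(both / total) if total else 0.0


def _draw_sizes(rng: np.random.Generator, n: int, dist: tuple[str, dict]) -> np.ndarray:
    name, params = dist
    if name == "fixed":
        k = int(params["n"])
        if k < 2:
            raise ValueError("oligomer sizes must be >= 2")
        return np.full(n, k, dtype=int)
    # shifted geometric with the requested mean, support {2, 3, ...}
    mean = float(params["mean"])
    if mean <= 2:
        raise ValueError("geometric oligomer size mean must exceed 2")
    p = 1.0 / (mean - 1.0)
    return rng.geometric(p, size=n) + 1


def _render(
    positions: np.ndarray,
    photons: np.ndarray,
    shape: tuple[int, int],
    sigma: float,
) -> np.ndarray:
    """Expected-photon image: sum of unit-integral Gaussians times photons."""
    img = np.zeros(shape, dtype=float)
    half = max(int(np.ceil(4 * sigma)), 2)
    for (x, y), ph in zip(positions, photons):
        if ph <= 0:
            continue
        r0 = max(int(np.floor(y)) - half, 0)
        r1 = min(int(np.ceil(y)) + half + 1, shape[0])
        c0 = max(int(np.floor(x)) - half, 0)
        c1 = min(int(np.ceil(x)) + half + 1, shape[1])
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        g = np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
        img[r0:r1, c0:c1] += ph * g / (2 * np.pi * sigma**2)
    return img


def _camera(
    expected: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> np.ndarray:
    frames = rng.poisson(expected[None].repeat(spec.n_frames, axis=0)).astype(float)
    frames += rng.normal(0.0, spec.read_noise_sd, size=frames.shape)
    frames += spec.camera_offset
    return np.clip(frames, 0, None)


def simulate_scene(
    spec: SceneSpec,
) -> tuple[SceneTruth, ImageStack, ImageStack]:
    """Render one two-channel scene and return it with its ground truth.

    Molecules are placed uniformly at random. Monomers carry exactly one
    label; each oligomer unit acquires labels under the configured labeling
    model; every label is assigned to channel 1 with probability
    ``color_split``. Channel-2 emitter coordinates are shifted by
    ``inter_channel_shift_px`` before rendering.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.fov_shape_px
    area_um2 = h * w * spec.pixel_size_um**2

    n_mono = rng.poisson(spec.monomer_density_per_um2 * area_um2)
    n_olig = rng.poisson(spec.oligomer_density_per_um2 * area_um2)
    n = n_mono + n_olig

    x = rng.uniform(0, w - 1, size=n)
    y = rng.uniform(0, h - 1, size=n)
    species = np.array(["monomer"] * n_mono + ["oligomer"] * n_olig)
    n_units = np.ones(n, dtype=int)
    if n_olig:
        n_units[n_mono:] = _draw_sizes(rng, n_olig, spec.oligomer_size_distribution)

    labels = np.zeros(n, dtype=int)
    labels[:n_mono] = 1  # monomers: exactly one label total
    if n_olig:
        units = n_units[n_mono:]
        if spec.label_model == "bernoulli":
            labels[n_mono:] = rng.binomial(units, spec.labels_per_monomer_unit)
        else:
            labels[n_mono:] = rng.poisson(units * spec.labels_per_monomer_unit)
    labels_ch1 = rng.binomial(labels, spec.color_split)
    labels_ch2 = labels - labels_ch1

    truth = SceneTruth(
        pd.DataFrame(
            {
                "x_px": x,
                "y_px": y,
                "species": species,
                "n_units": n_units,
                "n_labels_ch1": labels_ch1,
                "n_labels_ch2": labels_ch2,
            }
        )
    )

    pos = np.column_stack([x, y])
    dx, dy = spec.inter_channel_shift_px
    exp1 = _render(pos, labels_ch1 * spec.photons_per_label, (h, w), spec.psf_sigma_px)
    exp2 = _render(
        pos + [dx, dy], labels_ch2 * spec.photons_per_label, (h, w), spec.psf_sigma_px
    )
    stack1 = ImageStack(_camera(exp1, spec, rng), spec.pixel_size_um, spec.frame_rate_hz)
    stack2 = ImageStack(_camera(exp2, spec, rng), spec.pixel_size_um, spec.frame_rate_hz)
    return truth, stack1, stack2


def simulate_bead_field(
    shape: tuple[int, int] = (256, 256),
    n_beads: int = 30,
    shift_px: tuple[float, float] = (0.0, 0.0),
    pixel_size_um: float = 0.1,
    photons: float = 20000.0,
    psf_sigma_px: float = 1.3,
    offset: float = 100.0,
    read_noise_sd: float = 2.0,
    seed: int = 0,
) -> tuple[Image2D, Image2D]:
    """Two-channel fiducial bead images; channel B shifted by ``shift_px``.

    Beads are multi-color microspheres visible in both channels, so the same
    positions render in both images (plus the inter-channel shift).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    margin = 12
    pos = np.column_stack(
        [rng.uniform(margin, w - 1 - margin, n_beads), rng.uniform(margin, h - 1 - margin, n_beads)]
    )
    ph = np.full(n_beads, photons)
    a = _render(pos, ph, shape, psf_sigma_px)
    b = _render(pos - [shift_px[0], shift_px[1]], ph, shape, psf_sigma_px)
    a = rng.poisson(a) + rng.normal(0, read_noise_sd, shape) + offset
    b = rng.poisson(b) + rng.normal(0, read_noise_sd, shape) + offset
    return (
        Image2D(np.clip(a, 0, None), pixel_size_um),
        Image2D(np.clip(b, 0, None), pixel_size_um),
    )


def simulate_calibration_series(
    base_spec: SceneSpec,
    concentrations: list[float],
    scenes_per_conc: int = 3,
) -> list[tuple[float, SceneTruth, ImageStack, ImageStack]]:
    """Replicate scenes across a concentration series.

    ``base_spec.oligomer_density_per_um2`` is the surface density at unit
    concentration; the oligomer density of each scene scales linearly with
    concentration (surface capture far from saturation). The nonspecific
    monomer background density is held constant, so blank scenes
    (concentration 0) still carry background puncta. Replicates get
    independent seeds derived from the base seed.
    """
    if len(concentrations) == 0:
        raise ValueError("empty concentration series")
    seeds = np.random.SeedSequence(base_spec.seed).generate_state(
        len(concentrations) * scenes_per_conc
    )
    out = []
    i = 0
    for conc in concentrations:
        for _ in range(scenes_per_conc):
            spec = replace(
                base_spec,
                oligomer_density_per_um2=base_spec.oligomer_density_per_um2 * conc,
                seed=int(seeds[i] % (2**31)),
            )
            truth, s1, s2 = simulate_scene(spec)
            out.append((conc, truth, s1, s2))
            i += 1
    return out


# ---------------------------------------------------------------------------
# Photon traces for burst analysis


@dataclass
class TraceSpec:
    """Parameters of one simulated two-channel photon trace."""

    duration_s: float = 10.0
    bin_width_s: float = 1e-4
    burst_rate_per_s: float = 10.0
    size_units: int = 20
    true_E: float = 0.5
    photons_per_unit: float = 20.0
    autofluorescence_donor: float = 1.0  # counts / bin
    autofluorescence_acceptor: float = 0.5
    crosstalk: float = 0.05  # donor -> acceptor fraction
    seed: int = 0

    def validate(self) -> None:
        if not self.bin_width_s > 0:
            raise ValueError("bin_width_s must be positive")
        if not 0.0 <= self.true_E <= 1.0:
            raise ValueError("true_E must lie in [0, 1]")
        if not 0.0 <= self.crosstalk < 1.0:
            raise ValueError("crosstalk must lie in [0, 1)")
        if self.autofluorescence_donor < 0 or self.autofluorescence_acceptor < 0:
            raise ValueError("autofluorescence rates must be >= 0")


def simulate_photon_trace(spec: TraceSpec):
    """Simulate binned donor/acceptor photon counts with known bursts.

    Background bins draw Poisson counts from the autofluorescence rates (the
    acceptor channel additionally sees cross-talk from donor
    autofluorescence). A burst of ``size_units`` monomer units emits
    ``n = size_units * photons_per_unit`` signal photons split between the
    channels by the true FRET efficiency; the acceptor mean additionally
    carries cross-talk proportional to the donor *mean*, so the standard
    corrections recover the signal intensities exactly in expectation.

    Returns ``(PhotonTrace, burst_truth)`` where ``burst_truth`` is a
    DataFrame with columns bin, size_units, true_E.
    """
    from .fret import PhotonTrace  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_bins = int(round(spec.duration_s / spec.bin_width_s))
    a_d = spec.autofluorescence_donor
    a_a = spec.autofluorescence_acceptor
    c = spec.crosstalk

    lam_d = np.full(n_bins, a_d)
    lam_a = np.full(n_bins, a_a + c * a_d)

    n_bursts = rng.poisson(spec.burst_rate_per_s * spec.duration_s)
    n_bursts = min(n_bursts, n_bins)
    burst_bins = rng.choice(n_bins, size=n_bursts, replace=False)
    n_photons = spec.size_units * spec.photons_per_unit
    sig_d = (1.0 - spec.true_E) * n_photons
    sig_a = spec.true_E * n_photons
    lam_d[burst_bins] += sig_d
    lam_a[burst_bins] += sig_a + c * sig_d

    donor = rng.poisson(lam_d)
    acceptor = rng.poisson(lam_a)
    truth = pd.DataFrame(
        {
            "bin": np.sort(burst_bins),
            "size_units": spec.size_units,
            "true_E": spec.true_E,
        }
    )
    return PhotonTrace(donor, acceptor, spec.bin_width_s), truth
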