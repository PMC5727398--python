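"""Architecture measurement pipeline for MT density data.

Operators that recover, from rendered (or real, suitably preprocessed)
density grids, the quantities that characterize MT architecture:

* :func:`classify_pf_number` - protofilament count from the rotational power
  spectrum of transverse sections;
* :func:`measure_moire` - axial period of the projected moire fringe
  pattern, or a lower bound when no repeat fits in the field of view;
* :func:`measure_axial_repeat` - tubulin dimer repeat from the axial
  layer-line position of the Fourier transform;
* :func:`call_lattice_type` - A/B lattice call from the axial register of
  kinesin-decoration rows on adjacent PFs;
* :func:`estimate_skew` - signed PF skew from the rotation of the wall
  pattern along the axis;
* :func:`summarize` / :func:`compare_repeats` - per-condition tabulation and
  group statistics.

All sub-pixel peak localisation is done on the continuous Fourier transform
(coarse scan + bounded scalar optimisation), which for clean periodic
signals is limited only by spectral leakage, not by the FFT bin width.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .grid import DensityGrid
from .lattice import LatticeSpec

__all__ = [
    "MeasurementError",
    "LowerBound",
    "ArchitectureCall",
    "ConditionSummary",
    "TTestResult",
    "classify_pf_number",
    "measure_moire",
    "measure_axial_repeat",
    "call_lattice_type",
    "estimate_skew",
    "summarize",
    "compare_repeats",
]

logger = logging.getLogger(__name__)

PF_BAND = (9, 17)  #: plausible PF numbers searched for the symmetry harmonic
DIMER_BAND_NM = (7.5, 9.0)  #: layer-line search window for the dimer repeat
MONOMER_BAND_NM = (3.6, 4.7)  #: search window for the monomer repeat
CONFIDENCE_THRESHOLD = 1.5  #: top/second harmonic power ratio for a PF call


class MeasurementError(ValueError):
    """Raised when a measurement cannot be made from the given data."""


@dataclass(frozen=True)
class LowerBound:
    """Sentinel for a moire repeat longer than the field of view ("> box")."""

    box_nm: float

    def __str__(self) -> str:
        return f">{self.box_nm:.0f}"

    def __float__(self) -> float:
        return self.box_nm


@dataclass
class ArchitectureCall:
    """Per-MT measurement result."""

    pf_number: int | None = None
    pf_confidence: float = 0.0
    moire_nm: float | LowerBound | None = None
    axial_repeat_nm: float | None = None
    lattice_type: str = "undetermined"
    skew_deg_est: float | None = None


# ---------------------------------------------------------------------------
# spectral helpers
# ---------------------------------------------------------------------------


def _dtft_power(signal: np.ndarray, zpos: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    phases = np.exp(-2j * np.pi * np.outer(freqs, zpos))
    return np.abs(phases @ signal) ** 2


def _refine_peak_freq(
    signals: list[np.ndarray],
    zpos: np.ndarray,
    band_nm: tuple[float, float],
    min_quality: float = 0.02,
) -> float:
    """Sub-bin peak of the summed windowed DTFT power within a period band.

    Returns the peak frequency (cycles/nm).  The peak quality is the
    fraction of windowed signal power concentrated at the peak frequency
    (~1/3 for a pure sinusoid, ~1/n for white noise); below ``min_quality``,
    or for a peak pinned to a band edge, :class:`MeasurementError` is
    raised (featureless input, or the true repeat lies outside the band).
    """
    from scipy.fft import next_fast_len

    n = len(zpos)
    dz = float(zpos[1] - zpos[0])
    window = np.hanning(n)
    sigs = np.asarray([(s - s.mean()) * window for s in signals])
    total = float(np.sum(sigs**2)) * n
    if total <= 0:
        raise MeasurementError("signal has no contrast")
    # coarse stage: 4x zero-padded FFT power summed over signals
    npad = next_fast_len(4 * n)
    freqs = np.fft.rfftfreq(npad, d=dz)
    power = np.sum(np.abs(np.fft.rfft(sigs, n=npad, axis=1)) ** 2, axis=0)
    f_lo, f_hi = 1.0 / band_nm[1], 1.0 / band_nm[0]
    band = np.where((freqs >= f_lo) & (freqs <= f_hi))[0]
    if len(band) < 3:
        raise MeasurementError("field of view too short for the requested band")
    k = band[int(np.argmax(power[band]))]
    if k in (band[0], band[-1]):
        raise MeasurementError(
            f"no layer-line peak inside the {band_nm[0]}-{band_nm[1]} nm band"
        )
    if power[k] / total < min_quality:
        raise MeasurementError("layer-line peak not distinct above background")

    def neg_power(f: float) -> float:
        return -float(np.sum(_dtft_power(sigs.T, zpos, np.array([f]))))

    res = optimize.minimize_scalar(
        neg_power, bounds=(freqs[k - 1], freqs[k + 1]), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# transverse-section machinery
# ---------------------------------------------------------------------------


def _section_center(img: np.ndarray) -> tuple[float, float]:
    """Centroid of positive intensity (robust to zero-mean noise)."""
    w = np.clip(img, 0.0, None)
    total = w.sum()
    if total <= 0:
        return (img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0
    iy, ix = np.indices(img.shape)
    return float((w * iy).sum() / total), float((w * ix).sum() / total)


def _radial_profile(
    img: np.ndarray, center: tuple[float, float], pixel_nm: float
) -> tuple[np.ndarray, np.ndarray]:
    iy, ix = np.indices(img.shape)
    r = np.hypot(iy - center[0], ix - center[1]) * pixel_nm
    nbins = int(r.max() / pixel_nm)
    idx = np.minimum((r / pixel_nm).astype(int), nbins - 1)
    sums = np.bincount(idx.ravel(), weights=img.ravel(), minlength=nbins)
    counts = np.bincount(idx.ravel(), minlength=nbins)
    profile = sums / np.maximum(counts, 1)
    radii = (np.arange(nbins) + 0.5) * pixel_nm
    return radii, profile


def _peak_radius(radii: np.ndarray, profile: np.ndarray, r_min_nm: float = 3.0,
                 r_max_nm: float | None = None) -> float:
    """Sub-bin radius of the strongest ring in a radial profile."""
    mask = radii >= r_min_nm
    if r_max_nm is not None:
        mask &= radii <= r_max_nm
    if not mask.any():
        raise MeasurementError("no radii in search range")
    sel = np.where(mask)[0]
    k = sel[int(np.argmax(profile[sel]))]
    if 0 < k < len(radii) - 1:
        y0, y1, y2 = profile[k - 1], profile[k], profile[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return float(radii[k] + delta * (radii[1] - radii[0]))


def _angular_profile(
    img: np.ndarray,
    center: tuple[float, float],
    radius_nm: float,
    pixel_nm: float,
    n_theta: int = 720,
    radial_halfwidth_nm: float = 1.2,
    n_radii: int = 5,
) -> np.ndarray:
    """Intensity around an annulus, averaged over a small radial band."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    radii = np.linspace(
        radius_nm - radial_halfwidth_nm, radius_nm + radial_halfwidth_nm, n_radii
    )
    rr, tt = np.meshgrid(radii, theta, indexing="ij")
    ys = center[0] + rr * np.sin(tt) / pixel_nm
    xs = center[1] + rr * np.cos(tt) / pixel_nm
    vals = ndimage.map_coordinates(
        img, np.stack([ys.ravel(), xs.ravel()]), order=1, mode="nearest"
    ).reshape(rr.shape)
    return vals.mean(axis=0)


def _wall_geometry(sections: list[DensityGrid]) -> tuple[tuple[float, float], float]:
    """Common centre and wall radius from the averaged section."""
    mean_img = np.mean([s.values for s in sections], axis=0)
    pixel = sections[0].pixel_nm
    center = _section_center(mean_img)
    radii, profile = _radial_profile(mean_img, center, pixel)
    r_wall = _peak_radius(radii, profile)
    return center, r_wall


def classify_pf_number(
    sections: list[DensityGrid],
    band: tuple[int, int] = PF_BAND,
    confidence_threshold: float = CONFIDENCE_THRESHOLD,
) -> tuple[int | None, float]:
    """PF number from the rotational power spectrum of transverse sections.

    Each section is resampled onto an annulus at the wall radius; the power
    of angular harmonics, summed over sections, is searched over the
    plausible band of PF numbers (restricting the band also resolves
    integer-multiple harmonic ambiguity).  The confidence is the power ratio
    of the winning harmonic to the runner-up; below the threshold the call
    is ``None`` (undetermined) rather than an error.
    """
    if not sections:
        raise ValueError("at least one section is required")
    if any(s.ndim != 2 for s in sections):
        raise ValueError("sections must be 2D grids")
    try:
        center, r_wall = _wall_geometry(sections)
    except MeasurementError:
        return None, 0.0
    n_theta = 720
    power = np.zeros(n_theta // 2 + 1)
    for s in sections:
        prof = _angular_profile(s.values, center, r_wall, s.pixel_nm, n_theta)
        power += np.abs(np.fft.rfft(prof - prof.mean())) ** 2
    lo, hi = band
    band_power = power[lo : hi + 1]
    order = np.argsort(band_power)[::-1]
    top, second = band_power[order[0]], band_power[order[1]]
    confidence = float(top / second) if second > 0 else float("inf")
    n_pf = int(lo + order[0])
    if confidence < confidence_threshold:
        logger.info(
            "PF classification undetermined: confidence %.2f < %.2f",
            confidence, confidence_threshold,
        )
        return None, confidence
    logger.info("PF number %d (confidence %.2f)", n_pf, confidence)
    return n_pf, confidence


# ---------------------------------------------------------------------------
# moire repeat
# ---------------------------------------------------------------------------


def _normalized_axial_autocorr(img: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of a 2D image along axis 0 (all lags >= 0).

    The numerator is computed per column by FFT and summed over columns;
    the normalization uses the actual overlap energies, so edge effects do
    not masquerade as decorrelation.
    """
    from scipy.fft import irfft, next_fast_len, rfft

    nz = img.shape[0]
    x = img - img.mean()
    npad = next_fast_len(2 * nz)
    spec = rfft(x, n=npad, axis=0)
    num = irfft((spec * spec.conj()).sum(axis=1).real, n=npad)[:nz]
    t = (x**2).sum(axis=1)
    c = np.cumsum(t)
    a_energy = c[::-1]  # sum over z < nz - lag
    b_energy = c[-1] - np.concatenate([[0.0], c[:-1]])  # sum over z >= lag
    den = np.sqrt(a_energy * b_energy)
    den[den == 0] = np.inf
    return num / den


def measure_moire(
    projection: DensityGrid,
    smooth_sigma_nm: float = 4.5,
    peak_level: float = 0.4,
    min_prominence: float = 0.2,
    max_overlap_loss: float = 0.85,
) -> float | LowerBound:
    """Moire repeat (nm) of a 2D projection, or a lower bound.

    The moire fringes are the low-frequency part of the projection: the
    smoothed tube is a bundle of continuous helical PF centre-lines, for
    which rotation by one PF spacing is an exact symmetry, so the
    low-passed fringe pattern repeats axially with exactly the moire
    period L = w/tan|theta| (the discrete subunit lattice itself does not
    recur at L, which is why the raw autocorrelation is not used).  The
    subunit periodicity is removed with an axial Gaussian low-pass, the
    static (z-invariant) tube profile is subtracted per column, and the
    period is the first prominent peak of the normalized axial
    autocorrelation of the remaining fringe signal, localized to sub-pixel
    precision by three-point parabolic interpolation.

    When no peak appears within the field of view - straight PFs, or a
    repeat longer than the box - the box length is returned as a
    :class:`LowerBound`, the ">1000"-style entry of architecture tables.
    """
    if projection.ndim != 2 or projection.axes != "zy":
        raise ValueError("measure_moire expects a 2D axial projection (axes 'zy')")
    img = projection.values.astype(np.float64)
    if not img.any():
        raise MeasurementError("empty image")
    pixel = projection.pixel_nm
    nz = img.shape[0]
    box_nm = nz * pixel

    sigma_px = smooth_sigma_nm / pixel
    smooth = ndimage.gaussian_filter(img, sigma=(sigma_px, 1.0))
    trim = int(math.ceil(3 * sigma_px))
    if nz - 2 * trim < 20:
        return LowerBound(box_nm)
    smooth = smooth[trim : nz - trim]
    fringe = smooth - smooth.mean(axis=0, keepdims=True)

    corr = _normalized_axial_autocorr(fringe)
    max_lag = int(max_overlap_loss * len(fringe))
    c = corr[:max_lag]
    if len(c) < 5:
        return LowerBound(box_nm)

    # candidate peaks: local maxima that are high and prominent above the
    # preceding decay (rules out the lag-0 shoulder and noise ripple); the
    # period is the earliest candidate comparable to the strongest one
    # (later candidates are its multiples, earlier ones sub-period bumps)
    running_min = np.minimum.accumulate(c)
    candidates = [
        k
        for k in range(1, len(c) - 1)
        if c[k] >= c[k - 1]
        and c[k] >= c[k + 1]
        and c[k] >= peak_level
        and c[k] - running_min[k] >= min_prominence
    ]
    if not candidates:
        logger.info("no moire repeat within %.0f nm box", box_nm)
        return LowerBound(box_nm)
    c_best = max(c[k] for k in candidates)
    k_best = next(k for k in candidates if c[k] >= c_best - 0.1)
    y0, y1, y2 = c[k_best - 1], c[k_best], c[k_best + 1]
    denom = y0 - 2 * y1 + y2
    delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5)) if denom != 0 else 0.0
    moire = (k_best + delta) * pixel
    logger.info("moire repeat %.1f nm (corr %.3f)", moire, y1)
    return float(moire)


# ---------------------------------------------------------------------------
# axial (layer-line) repeat
# ---------------------------------------------------------------------------


def measure_axial_repeat(
    image: DensityGrid, band_nm: tuple[float, float] = DIMER_BAND_NM
) -> float:
    """Tubulin dimer repeat (nm) from the axial layer-line position.

    The layer line near 1/8.3 nm^-1 in the axial power spectrum comes from
    dimer-level contrast (kinesin decoration, which marks one site per
    dimer, is the standard way to make it strong).  The peak is located on
    the continuous windowed Fourier transform, so the precision at high SNR
    is far below the FFT bin width; a uniform or featureless image raises
    :class:`MeasurementError`.

    For a 2D projection the per-column spectral power is summed.  Note
    that the fixed-frame projection of a *supertwisted* MT has its layer
    line displaced by about dx/L (the lateral rise over the moire repeat)
    because the fringe pattern hands over between PFs as it rotates; for
    skewed MTs pass the 3D volume instead, where the decoration rows are
    followed along each PF and the repeat is read without that bias.
    """
    if image.ndim == 3:
        rows, zpos, _ = _decoration_row_signals(image)
        freq = _refine_peak_freq(rows, zpos, band_nm, min_quality=0.005)
        return 1.0 / freq
    if image.ndim != 2:
        raise ValueError("measure_axial_repeat expects a 2D image or 3D volume")
    img = image.values.astype(np.float64)
    if np.allclose(img, img.ravel()[0]):
        raise MeasurementError("image has no axial contrast")
    zpos = np.arange(img.shape[0]) * image.pixel_nm
    freq = _refine_peak_freq(list(img.T), zpos, band_nm, min_quality=0.005)
    return 1.0 / freq


# ---------------------------------------------------------------------------
# skew estimation
# ---------------------------------------------------------------------------


def _trimmed(vol: DensityGrid, trim_nm: float) -> DensityGrid:
    """Volume with axial margins removed (padding and ragged lattice ends
    would otherwise bias per-section pattern phases)."""
    t = int(round(trim_nm / vol.pixel_nm))
    if vol.shape[0] - 2 * t < 8:
        return vol
    return DensityGrid(vol.values[t : vol.shape[0] - t], vol.pixel_nm, "zyx")


def _harmonic_phase_series(
    vol: DensityGrid,
    n_pf: int,
    center: tuple[float, float],
    radius_nm: float,
    thickness_nm: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phase and magnitude of the N-th angular harmonic per transverse slab."""
    from .synth import transverse_sections

    secs = transverse_sections(vol, thickness_nm, thickness_nm)
    phases, mags, zs = [], [], []
    for k, sec in enumerate(secs):
        prof = _angular_profile(sec.values, center, radius_nm, sec.pixel_nm)
        coef = np.fft.rfft(prof - prof.mean())[n_pf]
        phases.append(np.angle(coef))
        mags.append(np.abs(coef))
        zs.append((k + 0.5) * thickness_nm)
    return np.array(zs), np.unwrap(np.array(phases)), np.array(mags)


def estimate_skew(
    vol: DensityGrid,
    section_thickness_nm: float = 4.0,
    end_trim_nm: float = 8.0,
) -> float:
    """Signed PF skew (degrees) from the rotation of the wall pattern.

    Tracks the phase of the N-fold angular harmonic of the wall annulus
    along z and converts the fitted rotation rate dphi/dz into the skew via
    theta = arctan(R * dphi/dz).  Negative = left-handed supertwist.  The
    fit is weighted by harmonic magnitude and the volume ends are trimmed,
    since partially filled end slabs carry distorted pattern phases.
    """
    if vol.ndim != 3:
        raise ValueError("estimate_skew requires a 3D volume")
    from .synth import transverse_sections

    secs = transverse_sections(vol, section_thickness_nm, section_thickness_nm)
    if len(secs) < 10:
        raise ValueError(
            f"need >= 10 sections for a skew fit, got {len(secs)}; "
            "use a longer volume or thinner sections"
        )
    n_pf, conf = classify_pf_number(secs)
    if n_pf is None:
        raise MeasurementError("PF tracking failed: symmetry order undetermined")
    core = _trimmed(vol, end_trim_nm)
    core_secs = transverse_sections(core, section_thickness_nm,
                                    section_thickness_nm)
    center, r_wall = _wall_geometry(core_secs)
    zs, psi, mags = _harmonic_phase_series(
        core, n_pf, center, r_wall, section_thickness_nm
    )
    slope = np.polyfit(zs, psi, 1, w=mags)[0]  # d(psi)/dz = -N * dphi/dz
    dphi_dz = -slope / n_pf
    theta = math.degrees(math.atan(r_wall * dphi_dz))
    logger.info("skew estimate %.3f deg (N=%d, R=%.2f nm)", theta, n_pf, r_wall)
    return theta


# ---------------------------------------------------------------------------
# lattice-type calling
# ---------------------------------------------------------------------------


def _circular_distance(x: float, targets: list[float], period: float) -> float:
    d = [(abs(x - t) % period) for t in targets]
    return min(min(di, period - di) for di in d)


def _decoration_row_signals(
    vol: DensityGrid, decoration_min_fraction: float = 0.05
) -> tuple[list[np.ndarray], np.ndarray, int]:
    """Per-PF decoration-row intensity traces, following the supertwist.

    Locates the decoration shell (a secondary radial ring outside the wall),
    reads the PF azimuths from the N-fold harmonic phase at mid-height, and
    samples the shell along each PF's drifting azimuth.  Returns
    ``(rows, zpos_nm, n_pf)``.  Raises :class:`MeasurementError` when the
    symmetry order cannot be determined or no decoration shell exists.
    """
    if vol.ndim != 3:
        raise ValueError("a 3D volume is required")
    from .synth import transverse_sections

    secs = transverse_sections(vol, 4.0, 4.0)
    if len(secs) < 3:
        raise ValueError("volume too short for row tracing")
    n_pf, conf = classify_pf_number(secs)
    if n_pf is None:
        raise MeasurementError("symmetry order undetermined")
    center, r_wall = _wall_geometry(secs)

    # decoration shell: a secondary ring (local maximum after a dip) outside
    # the wall -- a raw threshold would be fooled by the wall blobs' tails
    mean_img = np.mean([s.values for s in secs], axis=0)
    radii, rprof = _radial_profile(mean_img, center, vol.pixel_nm)
    wall_peak = rprof[np.argmin(np.abs(radii - r_wall))]
    shell = np.where((radii > r_wall + 2.0) & (radii < r_wall + 7.0))[0]
    r_dec = None
    for k in shell:
        if (
            0 < k < len(rprof) - 1
            and rprof[k] >= rprof[k - 1]
            and rprof[k] >= rprof[k + 1]
            and rprof[k] > decoration_min_fraction * wall_peak
        ):
            r_dec = _peak_radius(radii, rprof, r_min_nm=radii[k] - 1.0,
                                 r_max_nm=radii[k] + 1.0)
            break
    if r_dec is None:
        raise MeasurementError("no decoration shell detected")

    theta = math.radians(estimate_skew(vol))
    nz = vol.shape[0]
    z_mid = (nz - 1) / 2.0 * vol.pixel_nm

    # decoration-row azimuths at mid-height from the N-fold harmonic phase
    mid = secs[len(secs) // 2]
    prof = _angular_profile(mid.values, center, r_dec, vol.pixel_nm)
    coef = np.fft.rfft(prof - prof.mean())[n_pf]
    phi0 = -np.angle(coef) / n_pf

    zpx = np.arange(nz)
    zpos = zpx * vol.pixel_nm
    drift = (zpos - z_mid) * math.tan(theta) / r_wall
    dr_offsets = np.array([-0.7, 0.0, 0.7])
    dphi_offsets = np.array([-0.06, 0.0, 0.06])

    rows = []
    for j in range(n_pf):
        phi = phi0 + 2 * math.pi * j / n_pf + drift
        samples = []
        for dr in dr_offsets:
            for dphi in dphi_offsets:
                y = center[0] + (r_dec + dr) * np.sin(phi + dphi) / vol.pixel_nm
                x = center[1] + (r_dec + dr) * np.cos(phi + dphi) / vol.pixel_nm
                samples.append(
                    ndimage.map_coordinates(
                        vol.values, np.stack([zpx.astype(float), y, x]),
                        order=1, mode="nearest",
                    )
                )
        rows.append(np.mean(samples, axis=0))
    return rows, zpos, n_pf


def call_lattice_type(
    vol: DensityGrid,
    start: int = 3,
    decoration_min_fraction: float = 0.05,
) -> str:
    """A/B-lattice call from the kinesin-decoration register of a 3D volume.

    Decoration rows (one motor per dimer, radius ~4 nm outside the wall)
    are sampled along each PF, following the supertwist; the axial phase
    offset between azimuthally adjacent rows is compared against the
    B-lattice expectation (the lateral rise, ~S*a/N for an S-start lattice)
    and the A-lattice expectation (the same plus one monomer rise, i.e.
    half a dimer out of register).  The call is the majority over
    interfaces: "B" with at most one A interface (the canonical single
    seam), "A" with at most one B interface, "mixed" otherwise, and
    "undetermined" for undecorated input.
    """
    if vol.ndim != 3:
        raise ValueError("call_lattice_type requires a 3D volume")
    try:
        rows, zpos, n_pf = _decoration_row_signals(vol, decoration_min_fraction)
    except MeasurementError as err:
        logger.info("lattice type undetermined: %s", err)
        return "undetermined"

    try:
        d_rep = 1.0 / _refine_peak_freq(rows, zpos, DIMER_BAND_NM)
    except MeasurementError:
        logger.info("no dimer periodicity in decoration rows: undetermined")
        return "undetermined"
    window = np.hanning(len(zpos))
    zeta = []
    for row in rows:
        coef = np.sum((row - row.mean()) * window * np.exp(-2j * np.pi * zpos / d_rep))
        zeta.append((-np.angle(coef) / (2 * math.pi) * d_rep) % d_rep)

    a_rep = d_rep / 2.0
    dx_b = start * a_rep / n_pf  # B-lattice lateral rise for an S-start tube
    b_targets = [dx_b, d_rep - dx_b]
    a_targets = [(dx_b + a_rep) % d_rep, (d_rep - dx_b - a_rep) % d_rep]
    n_a = 0
    for j in range(n_pf):
        delta = (zeta[(j + 1) % n_pf] - zeta[j]) % d_rep
        is_a = _circular_distance(delta, a_targets, d_rep) < _circular_distance(
            delta, b_targets, d_rep
        )
        n_a += int(is_a)
        logger.debug("interface %d: offset %.2f nm -> %s", j, delta, "A" if is_a else "B")
    logger.info("lattice-type interfaces: %d A / %d B", n_a, n_pf - n_a)
    if n_a <= 1:
        return "B"
    if n_a >= n_pf - 1:
        return "A"
    return "mixed"


# ---------------------------------------------------------------------------
# summaries and statistics
# ---------------------------------------------------------------------------


@dataclass
class ConditionSummary:
    """Per-condition tabulation of architecture calls.

    ``table`` has one row per (condition, PF number) with MT count, integer
    percentage and the moire-repeat range; ``repeat_stats`` maps condition
    to the mean and s.d. of the axial repeat over measurement groups.
    """

    table: pd.DataFrame
    repeat_stats: dict[str, dict[str, float]]

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "table": self.table.to_dict(orient="records"),
                "repeat_stats": self.repeat_stats,
            },
            indent=1,
        )


def _format_moire(value: float | LowerBound) -> str:
    if isinstance(value, LowerBound):
        return str(value)
    return f"{value:.0f}"


def _moire_range(values: list) -> str:
    present = [v for v in values if v is not None]
    if not present:
        return ""
    keyed = sorted(present, key=lambda v: (isinstance(v, LowerBound), float(v)))
    lo, hi = keyed[0], keyed[-1]
    if lo is hi or _format_moire(lo) == _format_moire(hi):
        return _format_moire(lo)
    return f"{_format_moire(lo)}-{_format_moire(hi)}"


def summarize(
    calls: list[tuple[str, ArchitectureCall]], n_groups: int = 3
) -> ConditionSummary:
    """Tabulate architecture calls per condition.

    Percentages are rounded to integer percent per condition (they sum to
    100 within rounding).  Axial-repeat statistics follow the measurement
    grouping convention: values are assigned round-robin to ``n_groups``
    groups and the mean and s.d. are taken over group means.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    rows = []
    conditions: dict[str, list[ArchitectureCall]] = {}
    for cond, call in calls:
        conditions.setdefault(cond, []).append(call)
    for cond, items in conditions.items():
        total = len(items)
        by_pf: dict[object, list[ArchitectureCall]] = {}
        for c in items:
            key = c.pf_number if c.pf_number is not None else "undetermined"
            by_pf.setdefault(key, []).append(c)
        for key in sorted(by_pf, key=str):
            group = by_pf[key]
            rows.append(
                {
                    "condition": cond,
                    "pf_number": key,
                    "mt_count": len(group),
                    "percent": round(100.0 * len(group) / total),
                    "moire_range_nm": _moire_range([c.moire_nm for c in group]),
                }
            )
    repeat_stats = {}
    for cond, items in conditions.items():
        vals = [c.axial_repeat_nm for c in items if c.axial_repeat_nm is not None]
        if not vals:
            continue
        k = min(n_groups, len(vals))
        groups = [np.mean(vals[g::k]) for g in range(k)]
        repeat_stats[cond] = {
            "mean_nm": float(np.mean(groups)),
            "sd_nm": float(np.std(groups, ddof=1)) if k > 1 else 0.0,
            "n": len(vals),
            "n_groups": k,
        }
    return ConditionSummary(table=pd.DataFrame(rows), repeat_stats=repeat_stats)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def compare_repeats(groups_a: list[float], groups_b: list[float]) -> TTestResult:
    """Welch two-sample t-test on group-mean repeat measurements.

    Degenerate zero-variance inputs are resolved by convention: equal means
    give p = 1, unequal means give the p -> 0 limit with the ``degenerate``
    flag set.
    """
    a = np.asarray(groups_a, dtype=float)
    b = np.asarray(groups_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(len(a) + len(b) - 2), p=1.0,
                               degenerate=True)
        return TTestResult(
            t=math.copysign(math.inf, a.mean() - b.mean()),
            df=float(len(a) + len(b) - 2), p=0.0, degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
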