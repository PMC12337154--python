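"""Quantitative readouts of image degradation.

The point-spread-function (PSF) of a focused two-way system is analyzed
in three arrival-time regions: the isochronous volume (the bow-tie
shaped region whose two-way travel time matches the target's — the PSF
proper), the preceding region (earlier arrivals, where reverberation
clutter from shallow multiples accumulates) and the trailing region
(later arrivals, where distortions of the ballistic pulse appear).

Further readouts: RMS arrival-time aberration between a transcranial and
a homogeneous recording of the same target; contrast-to-noise ratio of
anechoic lesions; receive-aperture spatial coherence against the Van
Cittert-Zernike triangle; laterally averaged reverberation-vs-depth
curves; PSF-to-clutter ratio; and transmitted-pulse coda envelopes used
to compare fine and homogenized bone microstructure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate, hilbert

from .imaging import BModeImage, ImageGrid
from .solver import C_REF, ChannelData, TransducerArray

__all__ = [
    "PSFRegionMasks",
    "CoherenceCurve",
    "DepthCurve",
    "psf_region_masks",
    "region_mean_db",
    "rms_arrival_time_shift",
    "cnr",
    "spatial_coherence",
    "theoretical_vcz_curve",
    "lag_one_coherence",
    "reverberation_depth_curve",
    "psf_to_clutter_ratio",
    "coda_envelope",
]


@dataclass
class PSFRegionMasks:
    """Preceding / isochronous / trailing partition of an image window."""

    preceding: np.ndarray
    isochronous: np.ndarray
    trailing: np.ndarray
    target: tuple[float, float]  # (lateral, depth) m
    pulse_length: float          # spatial pulse length (m)

    def __post_init__(self) -> None:
        overlap = (self.preceding & self.isochronous) | \
                  (self.preceding & self.trailing) | \
                  (self.isochronous & self.trailing)
        if overlap.any():
            raise ValueError("region masks overlap")

    @property
    def union(self) -> np.ndarray:
        return self.preceding | self.isochronous | self.trailing


@dataclass
class CoherenceCurve:
    """Receive-aperture correlation coefficient vs inter-element lag."""

    lags: np.ndarray
    values: np.ndarray
    depth_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.values[0], 1.0):
            raise ValueError("coherence at lag 0 must be 1")

    @property
    def lag_one(self) -> float:
        return float(self.values[1])


@dataclass
class DepthCurve:
    """Laterally averaged image magnitude (dB) per depth sample."""

    depth: np.ndarray
    db: np.ndarray


def psf_region_masks(
    grid: ImageGrid,
    target: tuple[float, float],
    aperture: float,
    pulse_length: float,
    c0: float = C_REF,
) -> PSFRegionMasks:
    """Partition an image window around a point target by arrival time.

    The isochronous volume collects pixels whose two-way arrival time is
    within +/- one pulse transit (``pulse_length / c0``) of the target's,
    laterally bounded by the geometric bow-tie spanned by lines from the
    aperture edges through the focus.  Pixels with earlier arrivals form
    the preceding region, later arrivals the trailing region; same-time
    pixels outside the bow-tie are assigned to the preceding (shallower)
    or trailing (deeper) region, so the three masks partition the window.
    """
    if pulse_length <= 0:
        raise ValueError("pulse_length must be positive")
    tx, tz = target
    zg, xg = grid.z, grid.x
    if not (zg[0] <= tz <= zg[-1] and xg[0] <= tx <= xg[-1]):
        raise ValueError("target outside the image grid")
    # two-way arrival relative to the target's, on the beam axis model:
    # focused transmit arrives ~ z/c0, receive from the aperture center
    dz = zg[:, None] - tz
    dt_arrival = 2.0 * dz / c0  # (nz, 1)
    band = np.abs(dt_arrival) <= pulse_length / c0
    band = np.broadcast_to(band, (len(zg), len(xg)))
    # bow-tie: |x - tx| <= (aperture/2) * |z - tz| / tz, plus the focal
    # waist of one pulse length around the target
    half_width = 0.5 * aperture * np.abs(dz) / tz + pulse_length
    bowtie = np.abs(xg[None, :] - tx) <= half_width
    iso = band & bowtie
    earlier = np.broadcast_to(dt_arrival < 0, iso.shape)
    preceding = ~iso & earlier
    trailing = ~iso & ~earlier
    return PSFRegionMasks(preceding, iso, trailing, (tx, tz), pulse_length)


def region_mean_db(bmode: BModeImage, mask: np.ndarray,
                   domain: str = "db") -> float:
    """Mean image magnitude over a mask.

    ``domain='db'`` averages the log-compressed pixel values (the
    convention used for region tables); ``domain='linear'`` averages the
    linear envelope and converts the mean to dB.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if domain == "db":
        return float(np.mean(bmode.db[mask]))
    if domain == "linear":
        lin = np.mean(10.0 ** (bmode.db[mask] / 20.0))
        return float(20.0 * np.log10(lin))
    raise ValueError(f"unknown averaging domain {domain!r}")


def rms_arrival_time_shift(
    cd_a: ChannelData,
    cd_b: ChannelData,
    window: tuple[float, float] | None = None,
    min_correlation: float = 0.3,
) -> float:
    """RMS per-element arrival-time shift between two recordings, in ns.

    Each element's traces are cross-correlated over ``window`` (s); the
    correlation peak is refined by parabolic sub-sample interpolation.
    The mean shift (a bulk delay, not aberration) is removed before
    taking the RMS.  Elements whose normalized correlation peak falls
    below ``min_correlation`` are excluded.
    """
    if cd_a.traces.shape != cd_b.traces.shape or cd_a.dt != cd_b.dt:
        raise ValueError("recordings must share geometry and sampling")
    dt = cd_a.dt
    a, b = cd_a.traces, cd_b.traces
    if window is not None:
        t = cd_a.times
        sel = (t >= window[0]) & (t <= window[1])
        if sel.sum() < 8:
            raise ValueError("window too short")
        a, b = a[:, sel], b[:, sel]
    shifts = []
    for e in range(a.shape[0]):
        xa, xb = a[e] - a[e].mean(), b[e] - b[e].mean()
        denom = np.sqrt((xa**2).sum() * (xb**2).sum())
        if denom == 0:
            continue
        cc = correlate(xa, xb, mode="full") / denom
        k = int(np.argmax(cc))
        if cc[k] < min_correlation:
            continue
        if 0 < k < len(cc) - 1:
            y0, y1, y2 = cc[k - 1], cc[k], cc[k + 1]
            denom2 = y0 - 2 * y1 + y2
            frac = 0.5 * (y0 - y2) / denom2 if denom2 != 0 else 0.0
        else:
            frac = 0.0
        shifts.append((k - (len(xa) - 1) + frac) * dt)
    if not shifts:
        raise ValueError("no element produced a usable correlation peak")
    shifts = np.asarray(shifts)
    shifts -= shifts.mean()
    return float(np.sqrt(np.mean(shifts**2)) * 1e9)


def cnr(image: np.ndarray, lesion_mask: np.ndarray,
        background_mask: np.ndarray) -> float:
    """Contrast-to-noise ratio on linear envelope data.

    (mean inside lesion - mean background) / std background.  Anechoic
    lesions give negative values; report the magnitude alongside when
    comparing detectability.
    """
    lesion_mask = np.asarray(lesion_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not lesion_mask.any() or not background_mask.any():
        raise ValueError("masks must be non-empty")
    if (lesion_mask & background_mask).any():
        raise ValueError("lesion and background masks overlap")
    mu_l = image[lesion_mask].mean()
    mu_b = image[background_mask].mean()
    sd_b = image[background_mask].std()
    if sd_b == 0:
        raise ValueError("zero background variance")
    return float((mu_l - mu_b) / sd_b)


def _receive_aligned(cd: ChannelData, array: TransducerArray,
                     beam_x: float, depths: np.ndarray, c0: float) -> np.ndarray:
    """Element x depth matrix of receive-focused (delayed) RF samples."""
    tc = cd.t_pulse_center or 0.0
    if cd.focus is not None and cd.t_focal is not None:
        fx, fz = cd.focus
        t_tx = cd.t_focal + np.sign(depths - fz) * np.hypot(depths - fz, beam_x - fx) / c0
    else:
        t_tx = tc + depths / c0
    out = np.empty((cd.n_elements, len(depths)))
    t_axis0, dt = cd.t0, cd.dt
    n_t = cd.traces.shape[1]
    for e in range(cd.n_elements):
        rx = np.hypot(depths, beam_x - cd.element_x[e]) / c0
        s = (t_tx + rx - t_axis0) / dt
        k = np.floor(s).astype(int)
        w = s - k
        valid = (k >= 0) & (k < n_t - 1)
        k = np.clip(k, 0, n_t - 2)
        vals = (1 - w) * cd.traces[e, k] + w * cd.traces[e, k + 1]
        out[e] = np.where(valid, vals, 0.0)
    return out


def spatial_coherence(
    cd: ChannelData,
    array: TransducerArray,
    depth_window: tuple[float, float],
    beam_x: float | np.ndarray = 0.0,
    c0: float = C_REF,
    max_lag: int | None = None,
    receive_focus: bool = True,
) -> CoherenceCurve:
    """Receive-aperture spatial coherence of focused RF.

    For each inter-element lag m the normalized zero-mean correlation of
    receive-delayed RF between elements (i, i+m), computed over the depth
    window and averaged over all pairs (and over ``beam_x`` positions
    when several are given).  Invariant to per-channel amplitude scaling.
    ``receive_focus=False`` skips the per-element geometric delays and
    correlates the raw traces over the window's two-way time span
    (appropriate when the data are already aligned).
    """
    z0, z1 = depth_window
    lam = c0 / cd.f0 if cd.f0 else c0 / 2.5e6
    if z1 - z0 < 2 * lam:
        raise ValueError("depth window shorter than two wavelengths")
    if cd.n_elements < 2:
        raise ValueError("need at least two elements")
    n = cd.n_elements
    max_lag = max_lag or n - 1
    depths = np.arange(z0, z1, lam / 8.0)
    beams = np.atleast_1d(np.asarray(beam_x, dtype=float))
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for bx in beams:
        if receive_focus:
            rf = _receive_aligned(cd, array, bx, depths, c0)
        else:
            tc = cd.t_pulse_center or 0.0
            t = cd.times
            sel = (t >= tc + 2 * z0 / c0) & (t <= tc + 2 * z1 / c0)
            rf = np.asarray(cd.traces[:, sel], dtype=float)
        rf = rf - rf.mean(axis=1, keepdims=True)
        norms = np.sqrt((rf**2).sum(axis=1))
        norms[norms == 0] = np.inf
        rfn = rf / norms[:, None]
        for m in range(0, max_lag + 1):
            c = (rfn[: n - m] * rfn[m:]).sum(axis=1)
            sums[m] += c.sum()
            counts[m] += len(c)
    values = sums / np.maximum(counts, 1)
    values[0] = 1.0
    return CoherenceCurve(np.arange(max_lag + 1), values, depth_window)


def theoretical_vcz_curve(n_elements: int) -> CoherenceCurve:
    """Van Cittert-Zernike prediction for focused speckle.

    For an unapodized discrete aperture of N elements insonifying a
    random sub-resolution scatterer distribution, the coherence at lag m
    is the triangle 1 - m/N.
    """
    if n_elements < 2:
        raise ValueError("need at least two elements")
    m = np.arange(n_elements)
    return CoherenceCurve(m, 1.0 - m / n_elements)


def lag_one_coherence(cd: ChannelData, array: TransducerArray,
                      depth_window: tuple[float, float],
                      beam_x=0.0, c0: float = C_REF) -> float:
    """Correlation between adjacent receive elements (clutter-sensitive)."""
    return spatial_coherence(cd, array, depth_window, beam_x, c0, max_lag=1).lag_one


def reverberation_depth_curve(bmode: BModeImage) -> DepthCurve:
    """Laterally averaged envelope vs depth, in dB re the image reference."""
    if bmode.envelope is None:
        env = 10.0 ** (bmode.db / 20.0) * bmode.reference
    else:
        env = bmode.envelope
    lat_mean = env.mean(axis=1)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(lat_mean / bmode.reference)
    return DepthCurve(bmode.grid.z, db)


def psf_to_clutter_ratio(bmode: BModeImage, masks: PSFRegionMasks) -> float:
    """Isochronous-region mean over preceding-region (clutter) mean, dB.

    Computed on the linear envelope; the preceding region serves as the
    target-free clutter reference.
    """
    if not masks.preceding.any():
        raise ValueError("empty clutter (preceding) mask")
    env = bmode.envelope if bmode.envelope is not None else \
        10.0 ** (bmode.db / 20.0) * bmode.reference
    psf = env[masks.isochronous].mean()
    clutter = env[masks.preceding].mean()
    return float(20.0 * np.log10(psf / clutter))


def coda_envelope(plane_recording: np.ndarray, dt: float):
    """Plane-averaged envelope of a transmitted pulse and its coda.

    ``plane_recording`` is (receivers, time) pressure sampled along a
    plane beyond the bone.  Returns ``(t, envelope)`` where the envelope
    is the per-receiver analytic-signal magnitude averaged across the
    plane; the ballistic pulse appears as the first lobe and the
    reverberant coda trails it.
    """
    plane_recording = np.asarray(plane_recording, dtype=float)
    env = np.abs(hilbert(plane_recording, axis=1)).mean(axis=0)
    return dt * np.arange(plane_recording.shape[1]), env
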