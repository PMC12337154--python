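"""Transmit focusing, delay-and-sum beamforming and B-mode formation.

The receive chain mirrors a conventional clinical pipeline: geometric
transmit delays realize a fixed focus; receive beamforming is dynamic
delay-and-sum with linear interpolation between samples and no
apodization (transmit or receive); envelope detection is the magnitude
of the analytic signal along depth; display is 20 log10 compression
normalized either to the image's own maximum or to a linked reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import hilbert

from .solver import C_REF, ChannelData, Pulse, TransducerArray

logger = logging.getLogger(__name__)

__all__ = [
    "ImageGrid",
    "RFImage",
    "BModeImage",
    "FocusSequence",
    "tx_focus_delays",
    "das_beamform",
    "envelope_bmode",
    "bandpass_component",
    "multi_focus_bmode",
]


@dataclass
class ImageGrid:
    """Pixel centers of the beamforming grid."""

    z: np.ndarray  # depth coordinates (m)
    x: np.ndarray  # lateral coordinates (m)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.z.ndim != 1 or self.x.ndim != 1:
            raise ValueError("grid axes must be 1D")

    @classmethod
    def regular(cls, z_range: tuple[float, float], x_range: tuple[float, float],
                pitch: float) -> "ImageGrid":
        return cls(np.arange(z_range[0], z_range[1], pitch),
                   np.arange(x_range[0], x_range[1] + pitch / 2, pitch))

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.z), len(self.x))


@dataclass
class RFImage:
    """Beamformed, pre-envelope samples on an (depth x lateral) grid."""

    data: np.ndarray
    grid: ImageGrid
    c0: float = C_REF

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.grid.shape:
            raise ValueError("data shape does not match grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RF image contains non-finite values")


@dataclass
class BModeImage:
    """Envelope-detected, log-compressed image in dB.

    ``reference`` is the linear envelope value mapped to 0 dB — the
    image's own maximum in self-normalized mode, or the maximum of a
    linked reference image (e.g. the skull-free point-spread function)
    in cross-normalized mode.  ``db`` is unclipped; ``display()`` applies
    the dynamic-range floor for rendering only, metrics always use the
    unclipped values.
    """

    db: np.ndarray
    grid: ImageGrid
    reference: float
    dynamic_range: float = 60.0
    envelope: np.ndarray | None = None

    def display(self) -> np.ndarray:
        return np.maximum(self.db, -self.dynamic_range)

    @property
    def self_normalized(self) -> bool:
        return bool(np.isclose(np.nanmax(self.db), 0.0))


@dataclass
class FocusSequence:
    """Laterally swept transmit foci at a constant focal depth."""

    foci: list[tuple[float, float]]  # (lateral, depth), sorted by lateral

    def __post_init__(self) -> None:
        lats = [f[0] for f in self.foci]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("foci must be sorted by strictly increasing lateral position")

    @classmethod
    def lateral_sweep(cls, n_foci: int, spacing: float, depth: float,
                      center: float = 0.0) -> "FocusSequence":
        lats = (np.arange(n_foci) - (n_foci - 1) / 2.0) * spacing + center
        return cls([(float(x), float(depth)) for x in lats])

    def strip_edges(self, x_axis: np.ndarray) -> list[tuple[float, float]]:
        """Lateral strip boundaries tiling [x0, x1] without gaps/overlap."""
        lats = [f[0] for f in self.foci]
        mids = [(a + b) / 2 for a, b in zip(lats, lats[1:])]
        edges = [x_axis[0] - 1e-12] + mids + [x_axis[-1] + 1e-12]
        return list(zip(edges[:-1], edges[1:]))


def tx_focus_delays(array: TransducerArray, focus: tuple[float, float],
                    c0: float = C_REF) -> np.ndarray:
    """Per-element transmit delays focusing at ``focus`` = (lateral, depth).

    The farthest element fires first (zero delay); delays are
    (max path - element path) / c0, all non-negative.
    """
    fx, fz = focus
    if not fz > 0:
        raise ValueError("focus must lie in front of the array")
    paths = np.hypot(array.positions - fx, fz)
    return (paths.max() - paths) / c0


@njit(cache=True)
def _das_kernel(traces, dt, t0, elem_x, zg, xg, t_tx, c0, out):
    n_el, n_t = traces.shape
    nz = zg.shape[0]
    nx = xg.shape[0]
    for iz in range(nz):
        z = zg[iz]
        for ix in range(nx):
            x = xg[ix]
            acc = 0.0
            for e in range(n_el):
                dxe = x - elem_x[e]
                t = t_tx[iz, ix] + np.sqrt(dxe * dxe + z * z) / c0
                s = (t - t0) / dt
                k = int(np.floor(s))
                if 0 <= k < n_t - 1:
                    w = s - k
                    acc += (1.0 - w) * traces[e, k] + w * traces[e, k + 1]
            out[iz, ix] = acc


def das_beamform(cd: ChannelData, array: TransducerArray, grid: ImageGrid,
                 c0: float = C_REF) -> RFImage:
    """Dynamic-receive delay-and-sum beamforming.

    Each pixel sums the element traces sampled (with linear
    interpolation) at the transmit-delay-adjusted two-way travel time.
    The transmit arrival at a pixel uses the virtual-source model of the
    focused beam: the wavefront passes the focus at the focal convergence
    time and propagates spherically from it, converging before and
    diverging after.  For an unfocused (plane) transmit the arrival is
    simply depth / c0 after the pulse center leaves the array.

    Samples requested beyond the trace length contribute zero.
    """
    zg, xg = grid.z, grid.x
    tc = cd.t_pulse_center if cd.t_pulse_center is not None else 0.0
    if cd.focus is not None:
        fx, fz = cd.focus
        t_f = cd.t_focal
        dist = np.hypot(zg[:, None] - fz, xg[None, :] - fx)
        t_tx = t_f + np.sign(zg[:, None] - fz) * dist / c0
    else:
        t_tx = np.broadcast_to(tc + zg[:, None] / c0, (len(zg), len(xg))).copy()
    if cd.element_x is None:
        raise ValueError("channel data carries no element positions")
    t_end = cd.t0 + cd.dt * (cd.traces.shape[1] - 1)
    # worst-case sample request occurs on the deepest image row
    rx_deep = np.hypot(zg.max(), xg[:, None] - cd.element_x[None, :]) / c0
    t_need = float((t_tx[-1, :, None] + rx_deep).max())
    if t_need > t_end:
        logger.warning(
            "beamforming grid requests samples up to %.1f us but traces end "
            "at %.1f us; out-of-range samples are zero-filled",
            t_need * 1e6, t_end * 1e6)
    out = np.empty((len(zg), len(xg)))
    _das_kernel(cd.traces.astype(np.float32), cd.dt, cd.t0,
                cd.element_x.astype(np.float64), zg, xg,
                np.ascontiguousarray(t_tx, dtype=np.float64), c0, out)
    return RFImage(out, grid, c0)


def envelope_bmode(rf: RFImage, dynamic_range: float = 60.0,
                   reference: float | None = None) -> BModeImage:
    """Envelope detection (analytic signal along depth) + log compression.

    ``reference = None`` self-normalizes to the image maximum (0 dB at
    the brightest pixel); passing the maximum envelope of a linked image
    cross-normalizes instead.
    """
    env = np.abs(hilbert(rf.data, axis=0))
    if reference is None:
        reference = float(env.max())
        if reference == 0.0:
            raise ValueError("all-zero RF image: normalization undefined")
    if not reference > 0:
        raise ValueError("reference must be positive")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / reference)
    return BModeImage(db, rf.grid, reference, dynamic_range, envelope=env)


def blank_transmit(cd: ChannelData, t_end: float) -> ChannelData:
    """Zero the element traces before ``t_end`` (transmit blanking).

    Receive chains conventionally gate out the transmit event and its
    crosstalk along the array face; applying the same gate to every
    linked recording keeps clutter subtraction consistent.
    """
    out = cd.copy()
    out.traces = out.traces.copy()
    out.traces[:, out.times < t_end] = 0.0
    return out


def bandpass_component(cd: ChannelData, center: float,
                       fractional_bandwidth: float = 0.5) -> ChannelData:
    """Zero-phase band-pass extraction of one harmonic band.

    Implemented as an FFT-domain mask with raised-cosine edges (exactly
    zero phase, > 60 dB stop-band suppression); the pass band is
    ``center * (1 +/- fractional_bandwidth / 2)``.
    """
    fs = 1.0 / cd.dt
    half = 0.5 * fractional_bandwidth * center
    if center + half >= fs / 2:
        raise ValueError("band extends beyond Nyquist")
    n = cd.traces.shape[1]
    freqs = np.fft.rfftfreq(n, cd.dt)
    # raised-cosine transition, narrow but at least a few FFT bins wide
    taper = max(0.05 * center, 3.0 / (n * cd.dt))
    lo, hi = center - half, center + half
    mask = np.zeros_like(freqs)
    inside = (freqs >= lo) & (freqs <= hi)
    mask[inside] = 1.0
    rise = (freqs > lo - taper) & (freqs < lo)
    mask[rise] = 0.5 * (1 + np.cos(np.pi * (lo - freqs[rise]) / taper))
    fall = (freqs > hi) & (freqs < hi + taper)
    mask[fall] = 0.5 * (1 + np.cos(np.pi * (freqs[fall] - hi) / taper))
    out = cd.copy()
    out.traces = np.fft.irfft(np.fft.rfft(cd.traces, axis=1) * mask, n=n, axis=1)
    return out


def multi_focus_bmode(
    run_for_focus,
    sequence: FocusSequence,
    array: TransducerArray,
    grid: ImageGrid,
    c0: float = C_REF,
    dynamic_range: float = 60.0,
    reference: float | None = None,
):
    """Composite B-mode from a laterally swept focus sequence.

    ``run_for_focus(focus) -> ChannelData`` produces one transmit per
    focus (a solver run, or a clutter-subtracted recording).  Each focus'
    beamformed image contributes the lateral strip centered on its focus;
    strips are delimited midway between neighboring foci and tile the
    image without gaps or overlap.

    Returns ``(BModeImage, composite RF image)``.
    """
    zg, xg = grid.z, grid.x
    comp = np.zeros((len(zg), len(xg)))
    filled = np.zeros(len(xg), dtype=bool)
    for focus, (x_lo, x_hi) in zip(sequence.foci, sequence.strip_edges(xg)):
        cd = run_for_focus(focus)
        rf = das_beamform(cd, array, grid, c0)
        cols = (xg > x_lo) & (xg <= x_hi)
        if np.any(cols & filled):
            raise ValueError("overlapping strips in focus sequence")
        comp[:, cols] = rf.data[:, cols]
        filled |= cols
    rf_comp = RFImage(comp, grid, c0)
    return envelope_bmode(rf_comp, dynamic_range, reference), rf_comp
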