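"""Synthetic acoustic surveys with known ground truth.

The simulator emulates the survey regime the analysis is designed for: a
vessel towing a shallow two-element hydrophone pair (5–10 m deep, ~300 m
astern) at 16–20 km/h along a planar trackline, past sperm whales that
perform U-shaped foraging dives while producing usual clicks
(inter-click interval 0.2–2.0 s). Each click arrives at the array twice —
the direct path and a polarity-inverted surface-reflected echo — and the
lag between the two (the slant delay) encodes whale depth through
image-source geometry.

Coordinates are planar: ``x`` along the trackline (m), ``y`` perpendicular
and signed (m), ``z`` depth positive down (m); the sea surface is ``z=0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

__all__ = [
    "SimConfig",
    "DiveParams",
    "TruthWhale",
    "BathymetryGrid",
    "simulate_dive_profile",
    "place_whales",
    "propagate_click",
    "synthesize_clip",
    "make_bathymetry",
    "write_clip_wav",
    "read_clip_wav",
    "write_esri_ascii",
    "read_esri_ascii",
]

#: plausible range of daily-average sound speed in the survey region (m/s)
SOUND_SPEED_RANGE = (1499.0, 1543.0)


@dataclass
class SimConfig:
    """Scenario parameters for a synthetic line-transect survey.

    Defaults reflect the towed-array survey regime: array at 7.5 m depth,
    300 m behind a vessel doing 18 km/h, sound speed 1500 m/s, events
    truncated at 6500 m perpendicular slant range.
    """

    effort_length_km: float = 100.0
    vessel_speed_kmh: float = 18.0
    array_depth_m: float = 7.5
    array_setback_m: float = 300.0
    pair_spacing_m: float = 0.25
    sound_speed_ms: float = 1500.0
    whale_density_per_km2: float = 0.00833
    truncation_m: float = 6500.0
    noise_snr_db: float = 30.0
    sample_rate_hz: int = 96_000
    ici_s: tuple[float, float] = (0.2, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effort_length_km <= 0:
            raise ValueError("effort_length_km must be positive")
        if not (16.0 <= self.vessel_speed_kmh <= 20.0):
            raise ValueError("vessel_speed_kmh outside survey range [16, 20]")
        if not (5.0 <= self.array_depth_m <= 10.0):
            raise ValueError("array_depth_m outside tow range [5, 10]")
        if self.array_setback_m <= 0 or self.pair_spacing_m <= 0:
            raise ValueError("array geometry distances must be positive")
        lo, hi = SOUND_SPEED_RANGE
        if not (lo <= self.sound_speed_ms <= hi):
            raise ValueError(f"sound_speed_ms outside plausible range [{lo}, {hi}]")
        if self.whale_density_per_km2 < 0:
            raise ValueError("whale_density_per_km2 must be non-negative")
        if self.truncation_m <= self.array_depth_m:
            raise ValueError("truncation_m must exceed array_depth_m")
        if self.sample_rate_hz < 96_000:
            raise ValueError("sample_rate_hz must be at least 96 kHz")
        if not (0.2 <= self.ici_s[0] <= self.ici_s[1] <= 2.0):
            raise ValueError("ici_s must lie within the usual-click band [0.2, 2.0] s")


@dataclass
class DiveParams:
    """Piecewise-linear dive: descent, flat bottom phase, ascent."""

    descent_rate_ms: float = 1.2
    bottom_depth_m: float = 800.0
    bottom_duration_s: float = 1200.0
    ascent_rate_ms: float = 1.2
    ici_s: tuple[float, float] = (0.2, 2.0)

    def __post_init__(self) -> None:
        if self.bottom_depth_m < 0:
            raise ValueError("bottom_depth_m must be non-negative")
        if self.bottom_duration_s < 0:
            raise ValueError("bottom_duration_s must be non-negative")
        if self.bottom_depth_m > 0 and (self.descent_rate_ms <= 0 or self.ascent_rate_ms <= 0):
            raise ValueError("descent/ascent rates must be positive for a non-zero dive")


@dataclass
class TruthWhale:
    """Ground-truth whale: position, dive profile, click times."""

    id: int
    perpendicular_distance_m: float = 0.0  # signed; left/right of track
    x_m: float = 0.0  # along-track position
    dive: DiveParams = field(default_factory=DiveParams)
    dive_start_s: float = 0.0
    click_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    # piecewise-linear profile nodes (relative to dive start)
    profile_t_s: np.ndarray = field(default_factory=lambda: np.zeros(1))
    profile_z_m: np.ndarray = field(default_factory=lambda: np.zeros(1))

    @property
    def dive_duration_s(self) -> float:
        return float(self.profile_t_s[-1])

    @property
    def max_depth_m(self) -> float:
        return float(self.profile_z_m.max())

    def depth_at(self, t_s) -> np.ndarray:
        """Depth (m, positive down) at absolute time(s) ``t_s``.

        Outside the dive the whale sits at the surface (silent interval).
        """
        t = np.asarray(t_s, dtype=float) - self.dive_start_s
        return np.interp(t, self.profile_t_s, self.profile_z_m, left=0.0, right=0.0)


def simulate_dive_profile(
    params: DiveParams,
    seed: int | np.random.Generator = 0,
    seafloor_depth_m: float = math.inf,
    whale_id: int = 0,
) -> TruthWhale:
    """Build one U-shaped dive with a usual-click train.

    Clicks are emitted throughout the dive with inter-click intervals
    drawn uniformly from ``params.ici_s``; the whale is silent outside
    the dive. Raises :class:`ValueError` if the commanded bottom depth
    reaches the seafloor.
    """
    if params.bottom_depth_m >= seafloor_depth_m:
        raise ValueError(
            f"bottom depth {params.bottom_depth_m} m >= seafloor {seafloor_depth_m} m"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    bd = params.bottom_depth_m
    if bd == 0:
        t_desc = t_asc = 0.0
    else:
        t_desc = bd / params.descent_rate_ms
        t_asc = bd / params.ascent_rate_ms
    t_nodes = np.array([0.0, t_desc, t_desc + params.bottom_duration_s,
                        t_desc + params.bottom_duration_s + t_asc])
    z_nodes = np.array([0.0, bd, bd, 0.0])
    total = t_nodes[-1]

    lo, hi = params.ici_s
    if total <= 0:
        clicks = np.empty(0)
    else:
        n_max = int(total / lo) + 2
        ici = rng.uniform(lo, hi, n_max)
        clicks = np.cumsum(ici)
        clicks = clicks[clicks < total]

    return TruthWhale(
        id=whale_id,
        dive=params,
        click_times_s=clicks,
        profile_t_s=t_nodes,
        profile_z_m=z_nodes,
    )


def _whale_rng(master_seed: int, whale_id: int) -> np.random.Generator:
    # stable per-whale substream: master seed + whale id spawn key
    return np.random.default_rng(np.random.SeedSequence((master_seed, whale_id)))


def place_whales(
    config: SimConfig,
    seed: int | None = None,
    bathymetry: "BathymetryGrid | None" = None,
    bottom_depth_range_m: tuple[float, float] = (400.0, 1200.0),
    bottom_duration_range_s: tuple[float, float] = (900.0, 1500.0),
    surface_interval_s: float = 540.0,
) -> list[TruthWhale]:
    """Scatter diving whales over the surveyed strip.

    The whale count is Poisson with mean ``density × 2w × L`` and
    perpendicular distances are uniform on ``[-w, w]`` — the standard
    line-transect placement assumption. Dive bottom depths are uniform in
    ``bottom_depth_range_m`` (clipped 100 m above the local seafloor when
    a bathymetry grid is supplied).

    Foraging whales cycle between a dive and a ~9 min silent surface
    interval, so the dive nearest the vessel's closest approach starts at
    a uniformly random phase of that cycle: most whales are mid-click-train
    when the vessel passes, a few are caught silent at the surface.
    """
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(master)
    w_km = config.truncation_m / 1000.0
    mean_count = config.whale_density_per_km2 * 2.0 * w_km * config.effort_length_km
    count = int(rng.poisson(mean_count))

    whales: list[TruthWhale] = []
    for i in range(count):
        sub = _whale_rng(master, i)
        x = sub.uniform(0.0, config.effort_length_km * 1000.0)
        y = sub.uniform(-config.truncation_m, config.truncation_m)
        lo, hi = bottom_depth_range_m
        if bathymetry is not None:
            hi = min(hi, bathymetry.depth_at(x, y) - 100.0)
        bd = sub.uniform(lo, max(lo + 1.0, hi))
        params = DiveParams(
            bottom_depth_m=bd,
            bottom_duration_s=sub.uniform(*bottom_duration_range_s),
            ici_s=config.ici_s,
        )
        whale = simulate_dive_profile(params, sub, whale_id=i)
        whale.x_m = x
        whale.perpendicular_distance_m = y
        v_ms = config.vessel_speed_kmh / 3.6
        t_closest = (x + config.array_setback_m) / v_ms
        cycle = whale.dive_duration_s + surface_interval_s
        whale.dive_start_s = t_closest - sub.uniform(0.0, cycle)
        whales.append(whale)
    return whales


def propagate_click(
    whale_pos,
    hydrophone_pos,
    sound_speed: float,
    pair_spacing_m: float = 0.25,
):
    """Direct, surface-echo, and inter-channel arrival delays of one click.

    ``whale_pos`` and ``hydrophone_pos`` are ``(..., 3)`` arrays of
    ``(x, y, z)`` with z positive down. The surface echo travels to the
    image hydrophone mirrored above the sea surface, so

    ``echo_delay = (‖whale − image‖ − ‖whale − hydrophone‖) / c  ≥ 0``.

    The inter-channel delay is the direct travel time to the reference
    hydrophone minus that to a second hydrophone ``pair_spacing_m``
    further along +x (the array axis), so that a whale dead ahead gives
    ``+spacing/c`` and the conical bearing is ``arccos(c·Δt/spacing)``.

    Returns ``(direct_delay_s, echo_delay_s, inter_channel_delay_s)``.
    """
    if sound_speed <= 0:
        raise ValueError("sound speed must be positive")
    w = np.asarray(whale_pos, dtype=float)
    h = np.asarray(hydrophone_pos, dtype=float)
    if np.any(w[..., 2] < 0):
        raise ValueError("whale depth must be non-negative")
    if np.any(h[..., 2] <= 0):
        raise ValueError("hydrophone must be submerged (depth > 0)")

    h_img = h.copy()
    h_img[..., 2] = -h_img[..., 2]
    h2 = h.copy()
    h2[..., 0] = h2[..., 0] + pair_spacing_m

    direct = np.linalg.norm(w - h, axis=-1)
    image = np.linalg.norm(w - h_img, axis=-1)
    aft = np.linalg.norm(w - h2, axis=-1)
    return direct / sound_speed, (image - direct) / sound_speed, (direct - aft) / sound_speed


def synthesize_clip(
    direct_delay_s: float,
    echo_delay_s: float,
    ipi_s: float | None = None,
    snr_db: float = 30.0,
    fs: int = 96_000,
    seed: int | np.random.Generator = 0,
    *,
    echo_amplitude: float = 0.3,
    ipi_amplitude: float = 0.0,
    inter_channel_delay_s: float = 0.0,
    centre_hz: float = 10_000.0,
    envelope_tau_s: float = 1e-4,
    click_offset_s: float = 0.002,
    duration_s: float | None = None,
):
    """Render a two-channel click clip with its surface echo.

    The click is a Gabor transient (decaying sinusoid at ``centre_hz``,
    within the 5–15 kHz centroid band of sperm whale clicks) placed
    ``click_offset_s`` into the clip; the surface echo is a
    polarity-inverted copy scaled by ``echo_amplitude`` at lag
    ``echo_delay_s``; an optional second pulse of the multi-pulse click
    structure sits at lag ``ipi_s`` with ``ipi_amplitude``. Channel 2 is
    the aft hydrophone, shifted by ``inter_channel_delay_s``. Gaussian
    noise is added so that the click peak is ``snr_db`` above the noise
    RMS (``snr_db = -inf`` gives noise only).

    Returns ``(clip, truth)`` where ``clip`` is an ``(n, 2)`` float array
    and ``truth`` records the construction parameters, including an
    ``echo_merged`` flag when the echo lag is below one sample.
    """
    if fs < 96_000:
        raise ValueError("fs must be at least 96 kHz")
    if echo_delay_s < 0:
        raise ValueError("echo delay must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if duration_s is None:
        duration_s = click_offset_s + 0.0155 + max(echo_delay_s, ipi_s or 0.0) + 0.004
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    def pulse(t0: float, amp: float) -> np.ndarray:
        dt = t - t0
        return amp * np.exp(-0.5 * (dt / envelope_tau_s) ** 2) * np.cos(
            2 * np.pi * centre_hz * dt
        )

    echo_merged = echo_delay_s < 1.0 / fs
    noise_only = np.isneginf(snr_db)
    clip = np.empty((n, 2))
    for ch, ch_shift in enumerate((0.0, inter_channel_delay_s)):
        x = np.zeros(n)
        if not noise_only:
            t0 = click_offset_s + ch_shift
            x += pulse(t0, 1.0)
            if ipi_s is not None and ipi_amplitude > 0:
                x += pulse(t0 + ipi_s, ipi_amplitude)
            # surface reflection: phase-inverted, attenuated
            x -= pulse(t0 + echo_delay_s, echo_amplitude)
            if ipi_s is not None and ipi_amplitude > 0:
                x -= pulse(t0 + ipi_s + echo_delay_s, echo_amplitude * ipi_amplitude)
        sigma = 1.0 if noise_only else 10.0 ** (-snr_db / 20.0)
        clip[:, ch] = x + rng.normal(0.0, sigma, n)

    truth = {
        "direct_delay_s": direct_delay_s,
        "echo_delay_s": echo_delay_s,
        "ipi_s": ipi_s,
        "snr_db": snr_db,
        "fs": fs,
        "echo_amplitude": echo_amplitude,
        "ipi_amplitude": ipi_amplitude,
        "inter_channel_delay_s": inter_channel_delay_s,
        "click_offset_s": click_offset_s,
        "echo_merged": echo_merged,
    }
    return clip, truth


@dataclass
class BathymetryGrid:
    """Regular planar grid of seafloor depth (m, positive down)."""

    depths_m: np.ndarray  # (ny, nx)
    cell_size_m: float
    origin_xy: tuple[float, float]  # lower-left corner (x0, y0)

    def __post_init__(self) -> None:
        self.depths_m = np.atleast_2d(np.asarray(self.depths_m, dtype=float))
        if np.any(self.depths_m <= 0):
            raise ValueError("seafloor depths must be positive")
        if self.cell_size_m <= 0:
            raise ValueError("cell size must be positive")

    def depth_at(self, x, y):
        """Nearest-cell seafloor depth; raises outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ny, nx = self.depths_m.shape
        ix = np.floor((x - self.origin_xy[0]) / self.cell_size_m).astype(int)
        iy = np.floor((y - self.origin_xy[1]) / self.cell_size_m).astype(int)
        if np.any(ix < 0) or np.any(ix >= nx) or np.any(iy < 0) or np.any(iy >= ny):
            raise ValueError("query point outside bathymetry grid")
        out = self.depths_m[iy, ix]
        return float(out) if out.ndim == 0 else out


def make_bathymetry(
    kind: str,
    *,
    x_extent_m: tuple[float, float] = (0.0, 100_000.0),
    y_extent_m: tuple[float, float] = (-7000.0, 7000.0),
    cell_size_m: float = 1000.0,
    depth_m: float = 2000.0,
    depth_range_m: tuple[float, float] = (500.0, 3000.0),
    axis: str = "y",
) -> BathymetryGrid:
    """Build a flat or linearly sloping seafloor covering the survey strip."""
    nx = max(1, int(math.ceil((x_extent_m[1] - x_extent_m[0]) / cell_size_m)))
    ny = max(1, int(math.ceil((y_extent_m[1] - y_extent_m[0]) / cell_size_m)))
    if kind == "flat":
        if depth_m <= 0:
            raise ValueError("depth must be positive")
        depths = np.full((ny, nx), float(depth_m))
    elif kind == "slope":
        if min(depth_range_m) <= 0:
            raise ValueError("depths must be positive")
        if axis == "y":
            ramp = np.linspace(depth_range_m[0], depth_range_m[1], ny)
            depths = np.repeat(ramp[:, None], nx, axis=1)
        else:
            ramp = np.linspace(depth_range_m[0], depth_range_m[1], nx)
            depths = np.repeat(ramp[None, :], ny, axis=0)
    else:
        raise ValueError(f"unknown bathymetry kind: {kind!r}")
    return BathymetryGrid(depths, cell_size_m, (x_extent_m[0], y_extent_m[0]))


# ---------------------------------------------------------------------------
# file I/O: WAV clips and ESRI ASCII bathymetry


def write_clip_wav(path, clip: np.ndarray, fs: int) -> None:
    """Write a two-channel clip as float32 WAV."""
    wavfile.write(path, fs, np.asarray(clip, dtype=np.float32))


def read_clip_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV clip, returning float samples in [-1, 1] and fs."""
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype == np.int16:
        data = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        data = data.astype(float) / 2147483648.0
    else:
        data = data.astype(float)
    return data, int(fs)


def write_esri_ascii(grid: BathymetryGrid, path) -> None:
    """Write the bathymetry grid in ESRI ASCII raster format."""
    ny, nx = grid.depths_m.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {grid.origin_xy[0]}\n")
        fh.write(f"yllcorner {grid.origin_xy[1]}\n")
        fh.write(f"cellsize {grid.cell_size_m}\n")
        fh.write("NODATA_value -9999\n")
        # ESRI ASCII stores the top row first
        np.savetxt(fh, grid.depths_m[::-1], fmt="%.3f")


def read_esri_ascii(path) -> BathymetryGrid:
    """Read an ESRI ASCII raster back into a :class:`BathymetryGrid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        depths = np.loadtxt(fh)
    depths = np.atleast_2d(depths)[::-1]
    return BathymetryGrid(
        depths,
        header["cellsize"],
        (header["xllcorner"], header["yllcorner"]),
    )
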