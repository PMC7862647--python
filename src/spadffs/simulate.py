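"""Brownian-dynamics photon-count simulator for the 5x5 SPAD detector.

The generative model:

* ``n_particles`` point emitters diffuse freely (diffusion coefficient ``D``)
  in a periodic box of half-lengths ``box`` (um), positions updated every
  ``sim_substep`` seconds by Gaussian steps of variance ``2 D dt`` per axis.
* Pixel *i* observes a 3D Gaussian detection volume of lateral 1/e^2 waist
  ``omega0_pixel`` and axial extent ``z0 = S * omega0_pixel``, laterally
  shifted by ``pitch_sample`` (75 nm) per pixel unit: a particle at (x, y, z)
  contributes an expected count rate

      brightness * exp(-2((x - p dx_i)^2 + (y - p dy_i)^2)/omega0^2)
                 * exp(-2 z^2 / z0^2)

* Photon shot noise is Poissonian per bin and pixel; uncorrelated dark
  counts are added at ``dcr`` Hz per pixel (``hot_pixel_dcr`` for the hot
  pixel, index 1 by default).
* After-pulsing: every detected count spawns, with probability
  ``p_afterpulse``, one extra count in the same pixel at a delay drawn from
  a power-law density proportional to delta^(-ap_exponent) truncated to
  ``ap_delay_range``; after-pulses can themselves after-pulse (geometric
  cascade).  The resulting dark-trace ACF decays as tau^(-B) with the same
  exponent, which is how the after-pulse fit model is made self-consistent.

Identical ``seed`` and configuration give a bit-identical trace.  The
position/emission loop is JIT-compiled with numba and skips the detection
profile for particles far outside the focal region (relative contribution
below e^-16), which dominates the cost in the default box.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from numba import njit

from .errors import InvalidInputError
from .spadio import N_PIXELS, IntensityTrace, PixelGrid


@dataclass
class FfsSimConfig:
    """Full generative description of a synthetic SPAD-FFS measurement.

    Defaults emulate the small-dye free-diffusion study conditions:
    D = 30.6 um^2/s, a 141 nm single-pixel waist with structural parameter
    S = 5, 50 particles in a 3 x 3 x 6 um periodic box, 50 kHz molecular
    brightness, 0.5 us bins, a moderate dark count rate with one hot pixel,
    and weak power-law after-pulsing with exponent 1.103.
    """

    D: float = 30.6  # um^2/s
    n_particles: int = 50
    box: tuple[float, float, float] = (1.5, 1.5, 3.0)  # half-lengths, um
    omega0_pixel: float = 0.141  # um, lateral 1/e^2 waist of one pixel
    S: float = 5.0  # structural parameter z0/omega0
    pitch_sample: float = 0.075  # um per pixel unit in sample space
    brightness: float = 5e4  # Hz per particle at the volume centre
    duration: float = 10.0  # s
    bin_width: float = 5e-7  # s
    sim_substep: float | None = None  # s; defaults to bin_width
    dcr: float = 200.0  # Hz per pixel
    hot_pixel_dcr: float = 2.5e4  # Hz
    hot_pixel_index: int = 1
    p_afterpulse: float = 0.02
    ap_exponent: float = 1.103  # B
    ap_delay_range: tuple[float, float] = (1e-6, 1e-2)  # s
    omega_exc: float | None = 0.30  # um; excitation-envelope waist (None: flat)
    seed: int = 1
    init_positions: np.ndarray | None = None  # (n_particles, 3) um, else uniform

    def validate(self) -> None:
        ss = self.sim_substep or self.bin_width
        if min(self.D, 0.0) < 0 or self.n_particles < 0:
            raise InvalidInputError("D and n_particles must be non-negative")
        for name in ("omega0_pixel", "S", "pitch_sample", "duration", "bin_width"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")
        if any(b <= 0 for b in self.box):
            raise InvalidInputError("box half-lengths must be positive")
        if ss > self.bin_width:
            raise InvalidInputError("sim_substep must not exceed bin_width")
        if not (0.0 <= self.p_afterpulse < 1.0):
            raise InvalidInputError("p_afterpulse must be in [0, 1)")
        dmin, dmax = self.ap_delay_range
        if not (0 < dmin < dmax):
            raise InvalidInputError("ap_delay_range must satisfy 0 < min < max")
        if self.p_afterpulse > 0 and dmin < self.bin_width:
            raise InvalidInputError(
                "ap delay minimum must be >= bin_width when after-pulsing is on"
            )
        if self.brightness < 0 or self.dcr < 0 or self.hot_pixel_dcr < 0:
            raise InvalidInputError("rates must be non-negative")
        if min(self.box[0], self.box[1]) < 5.0 * self.omega0_pixel:
            warnings.warn(
                "box is small relative to the detection volume (< 10x omega0 "
                "across); boundary artefacts may appear", stacklevel=2,
            )
        if 2.0 * self.D * ss > (self.omega0_pixel / 10.0) ** 2:
            warnings.warn(
                "sim_substep is coarse: RMS step exceeds omega0/10; the ACF "
                "is slightly low-pass filtered at the shortest lags",
                stacklevel=2,
            )

    @property
    def substep(self) -> float:
        return self.sim_substep or self.bin_width

    @property
    def tau_D(self) -> float:
        """Nominal single-pixel diffusion time omega0^2 / (4 D)."""
        return self.omega0_pixel**2 / (4.0 * self.D) if self.D > 0 else math.inf

    def as_metadata(self) -> dict:
        md = asdict(self)
        md["sim_substep"] = self.substep
        if md["init_positions"] is not None:
            md["init_positions"] = np.asarray(md["init_positions"]).tolist()
        return md


@njit(cache=True, fastmath=True)
def _sim_chunk(
    pos,  # (n_particles, 3), updated in place
    n_bins,
    substeps_per_bin,
    sigma_step,
    steps,  # (n_bins * substeps_per_bin, n_particles, 3) float32 N(0,1) draws
    bx, by, bz,
    inv_w2,  # 2 / omega0^2
    inv_z2,  # 2 / z0^2
    delta,  # pitch in sample space, um
    eps_sub,  # expected counts per particle per substep at the volume centre
    dxs, dys,  # per-pixel offset indices 0..4 (= dx + 2, dy + 2)
    eff,  # per-pixel relative detection efficiency
    r2cut, z2cut,
    lam,  # (n_bins, 25) output, incremented
):
    n_p = pos.shape[0]
    k1 = math.exp(-inv_w2 * delta * delta)
    k2 = math.exp(-inv_w2 * 4.0 * delta * delta)
    fx = np.empty(5)
    fy = np.empty(5)
    s_idx = 0
    for b in range(n_bins):
        for _s in range(substeps_per_bin):
            for p in range(n_p):
                x = pos[p, 0]
                y = pos[p, 1]
                z = pos[p, 2]
                if sigma_step > 0.0:
                    x += sigma_step * steps[s_idx, p, 0]
                    y += sigma_step * steps[s_idx, p, 1]
                    z += sigma_step * steps[s_idx, p, 2]
                    if x >= bx:
                        x -= 2.0 * bx
                    elif x < -bx:
                        x += 2.0 * bx
                    if y >= by:
                        y -= 2.0 * by
                    elif y < -by:
                        y += 2.0 * by
                    if z >= bz:
                        z -= 2.0 * bz
                    elif z < -bz:
                        z += 2.0 * bz
                    pos[p, 0] = x
                    pos[p, 1] = y
                    pos[p, 2] = z
                if x * x + y * y > r2cut or z * z > z2cut:
                    continue
                # fall through to photon emission below
                gx = math.exp(-inv_w2 * x * x)
                gy = math.exp(-inv_w2 * y * y)
                cx = math.exp(2.0 * inv_w2 * delta * x)
                cy = math.exp(2.0 * inv_w2 * delta * y)
                icx = 1.0 / cx
                icy = 1.0 / cy
                fx[0] = gx * k2 * icx * icx
                fx[1] = gx * k1 * icx
                fx[2] = gx
                fx[3] = gx * k1 * cx
                fx[4] = gx * k2 * cx * cx
                fy[0] = gy * k2 * icy * icy
                fy[1] = gy * k1 * icy
                fy[2] = gy
                fy[3] = gy * k1 * cy
                fy[4] = gy * k2 * cy * cy
                base = eps_sub * math.exp(-inv_z2 * z * z)
                for i in range(25):
                    lam[b, i] += base * eff[i] * fx[dxs[i]] * fy[dys[i]]
            s_idx += 1


def _sample_ap_delays(n, B, dmin, dmax, rng):
    """Inverse-CDF sampling from f(delta) ~ delta^(-B) on [dmin, dmax]."""
    u = rng.random(n)
    if abs(B - 1.0) < 1e-12:
        return dmin * (dmax / dmin) ** u
    e = 1.0 - B
    return (dmin**e + u * (dmax**e - dmin**e)) ** (1.0 / e)


def add_afterpulses(counts, bin_width, p, B, delay_range, rng) -> int:
    """In-place after-pulse cascade on a counts array; returns counts added.

    Each detected count spawns, with probability ``p``, one extra count in
    the same pixel after a power-law-distributed delay; spawned counts are
    themselves eligible, giving a geometric cascade.
    """
    if p <= 0:
        return 0
    dmin, dmax = delay_range
    n_bins = counts.shape[0]
    generation = counts
    total_added = 0
    while True:
        rows, cols = np.nonzero(generation)
        if len(rows) == 0:
            break
        n_ap = rng.binomial(generation[rows, cols].astype(np.int64), p)
        keep = n_ap > 0
        if not np.any(keep):
            break
        rows, cols, n_ap = rows[keep], cols[keep], n_ap[keep]
        src_bins = np.repeat(rows, n_ap)
        src_pix = np.repeat(cols, n_ap)
        delays = _sample_ap_delays(len(src_bins), B, dmin, dmax, rng)
        tgt = src_bins + np.maximum((delays / bin_width).astype(np.int64), 1)
        ok = tgt < n_bins
        tgt, src_pix = tgt[ok], src_pix[ok]
        generation = np.zeros_like(counts)
        np.add.at(generation, (tgt, src_pix), 1)
        info = np.iinfo(counts.dtype) if counts.dtype.kind == "u" else None
        if info is not None:
            headroom = info.max - counts[tgt, src_pix]
            # saturate rather than wrap (overflow is astronomically unlikely)
            generation[tgt, src_pix] = np.minimum(generation[tgt, src_pix], headroom)
        counts += generation
        total_added += int(generation.sum())
    return total_added


def simulate_ffs(config: FfsSimConfig, counts_dtype=np.uint16) -> IntensityTrace:
    """Generate a synthetic SPAD-FFS measurement from the full photon model."""
    config.validate()
    # SFC64: fast, high-quality bit generator; seeding fixes the trace exactly
    rng = np.random.Generator(np.random.SFC64(config.seed))
    grid = PixelGrid(pitch_sample=config.pitch_sample)

    substep = config.substep
    spb = int(round(config.bin_width / substep))
    if abs(spb * substep - config.bin_width) > 1e-12 * config.bin_width:
        raise InvalidInputError("bin_width must be an integer multiple of sim_substep")
    n_bins = int(round(config.duration / config.bin_width))

    bx, by, bz = config.box
    if config.init_positions is not None:
        pos = np.array(config.init_positions, dtype=np.float64)
        if pos.shape != (config.n_particles, 3):
            raise InvalidInputError("init_positions must have shape (n_particles, 3)")
    else:
        pos = np.empty((config.n_particles, 3))
        pos[:, 0] = rng.uniform(-bx, bx, config.n_particles)
        pos[:, 1] = rng.uniform(-by, by, config.n_particles)
        pos[:, 2] = rng.uniform(-bz, bz, config.n_particles)

    w = config.omega0_pixel
    z0 = config.S * w
    inv_w2 = 2.0 / (w * w)
    inv_z2 = 2.0 / (z0 * z0)
    sigma_step = math.sqrt(2.0 * config.D * substep)
    eps_sub = config.brightness * substep
    off = grid.pixel_offsets
    dxs = (off[:, 0] + 2).astype(np.int64)
    dys = (off[:, 1] + 2).astype(np.int64)
    eff = pixel_efficiencies(config)
    # detection negligible (< e^-16 of peak) beyond these bounds
    r2cut = (math.sqrt(8.0) * w + 2.0 * math.sqrt(2.0) * config.pitch_sample) ** 2
    z2cut = 8.0 * z0 * z0

    dark = np.full(N_PIXELS, config.dcr * config.bin_width)
    if 0 <= config.hot_pixel_index < N_PIXELS:
        dark[config.hot_pixel_index] = config.hot_pixel_dcr * config.bin_width

    counts = np.empty((n_bins, N_PIXELS), dtype=counts_dtype)
    # chunk so the pregenerated step array stays below ~200 MB
    denom = max(spb * max(config.n_particles, 1) * 3, 1)
    chunk_bins = int(max(1, min(n_bins, 5e7 // denom)))
    info = np.iinfo(counts_dtype)
    no_steps = np.zeros((0, max(config.n_particles, 1), 3), dtype=np.float32)
    for start in range(0, n_bins, chunk_bins):
        nb = min(chunk_bins, n_bins - start)
        lam = np.zeros((nb, N_PIXELS))
        if config.n_particles:
            if sigma_step > 0.0:
                steps = rng.standard_normal(
                    (nb * spb, config.n_particles, 3), dtype=np.float32
                )
            else:
                steps = no_steps
            _sim_chunk(
                pos, nb, spb, sigma_step, steps, bx, by, bz, inv_w2, inv_z2,
                config.pitch_sample, eps_sub, dxs, dys, eff,
                r2cut if config.brightness > 0 else -1.0,
                z2cut if config.brightness > 0 else -1.0,
                lam,
            )
        lam += dark[None, :]
        counts[start : start + nb] = np.minimum(rng.poisson(lam), info.max)

    n_ap = add_afterpulses(
        counts, config.bin_width, config.p_afterpulse, config.ap_exponent,
        config.ap_delay_range, rng,
    )
    md = config.as_metadata()
    md["afterpulse_counts"] = n_ap
    md["kind"] = "simulated_ffs"
    excluded = frozenset({config.hot_pixel_index}) if config.hot_pixel_dcr > config.dcr else frozenset()
    return IntensityTrace(
        counts=counts, bin_width=config.bin_width,
        excluded_pixels=excluded, metadata=md,
    )


def simulate_dark(config: FfsSimConfig, counts_dtype=np.uint8) -> IntensityTrace:
    """Generate a dark (no-signal) reference trace.

    A constant uncorrelated background at ``dcr`` Hz per pixel (with the hot
    pixel at ``hot_pixel_dcr``) plus the after-pulse cascade; after-pulsing
    is the only correlation structure, which is what makes such a trace the
    reference for calibrating the after-pulse power law.
    """
    config.validate()
    rng = np.random.Generator(np.random.SFC64(config.seed))
    n_bins = int(round(config.duration / config.bin_width))
    rates = np.full(N_PIXELS, config.dcr)
    if 0 <= config.hot_pixel_index < N_PIXELS:
        rates[config.hot_pixel_index] = config.hot_pixel_dcr
    counts = np.zeros((n_bins, N_PIXELS), dtype=counts_dtype)
    dmin, dmax = config.ap_delay_range
    n_ap = 0
    for i in range(N_PIXELS):
        n_events = rng.poisson(rates[i] * config.duration)
        if n_events == 0:
            continue
        # event-based: primary bins, then the after-pulse cascade on events
        gen = rng.integers(0, n_bins, n_events)
        all_events = [gen]
        while config.p_afterpulse > 0 and len(gen):
            spawned = gen[rng.random(len(gen)) < config.p_afterpulse]
            if not len(spawned):
                break
            delays = _sample_ap_delays(
                len(spawned), config.ap_exponent, dmin, dmax, rng
            )
            tgt = spawned + np.maximum(
                (delays / config.bin_width).astype(np.int64), 1
            )
            gen = tgt[tgt < n_bins]
            n_ap += len(gen)
            all_events.append(gen)
        bc = np.bincount(np.concatenate(all_events), minlength=n_bins)
        counts[:, i] = np.minimum(bc, np.iinfo(counts_dtype).max)
    md = config.as_metadata()
    md["afterpulse_counts"] = n_ap
    md["kind"] = "simulated_dark"
    excluded = frozenset({config.hot_pixel_index}) if config.hot_pixel_dcr > config.dcr else frozenset()
    return IntensityTrace(
        counts=counts, bin_width=config.bin_width,
        excluded_pixels=excluded, metadata=md,
    )


def pixel_efficiencies(config: FfsSimConfig) -> np.ndarray:
    """Relative photon-collection efficiency of each pixel.

    Pixels away from the optical axis observe a detection volume displaced
    from the centre of the excitation envelope, so their flux is attenuated
    by exp(-2 (delta rho)^2 / omega_exc^2).  This is what gives the
    fingerprint map its Gaussian-like shape; it cancels in every
    fluctuation-normalized correlation.
    """
    grid = PixelGrid(pitch_sample=config.pitch_sample)
    if config.omega_exc is None or not np.isfinite(config.omega_exc):
        return np.ones(N_PIXELS)
    shift = config.pitch_sample * grid.rho
    return np.exp(-2.0 * shift**2 / config.omega_exc**2)


def expected_mean_rates(config: FfsSimConfig) -> np.ndarray:
    """Analytic expected mean count rate per pixel (Hz), after-pulse inflated.

    The particle term is the box-average of the shifted detection profile,
    brightness * c * (pi/2)^(3/2) * omega0^2 * z0 / V_box for every pixel of
    a volume fully inside the box; the after-pulse cascade inflates every
    rate by 1/(1 - p).
    """
    bx, by, bz = config.box
    vbox = 8.0 * bx * by * bz
    w, z0 = config.omega0_pixel, config.S * config.omega0_pixel
    vint = (math.pi / 2.0) ** 1.5 * w * w * z0
    particle = (
        config.brightness * config.n_particles * vint / vbox
        * pixel_efficiencies(config)
    )
    rates = particle + config.dcr
    if 0 <= config.hot_pixel_index < N_PIXELS:
        i = config.hot_pixel_index
        rates[i] = particle[i] + config.hot_pixel_dcr
    return rates / (1.0 - config.p_afterpulse)
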