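"""Synthetic two-colour movie generator with full ground truth.

Emulates the imaging regimes of the analysis pipeline: rod-shaped cells that
filament after damage, a damage-induced expression time course, fast free
diffusion rendered as motion blur, near-static DNA-bound molecules rendered
as diffraction-limited foci, exponential photobleaching with rare return
(blinking) events, a slower-decaying autofluorescence background, and a
camera model with offset, shot noise and read noise.

Coordinates: positions are in nm; pixel (i, j) of an image covers
``[j*px, (j+1)*px) x [i*px, (i+1)*px)`` nm so its centre sits at
``((j+0.5)*px, (i+0.5)*px)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

from .config import ConfigError, SimulationConfig
from .geometry import CellOutline, spherocylinder_volume
from .stack import MovieStack

__all__ = [
    "PlacementError", "SimCell", "MoleculeSet", "GroundTruth",
    "expression_time_course", "volume_growth_factor", "simulate_cells",
    "place_molecules", "draw_bleach_times", "simulate_bleaching",
    "render_frame", "render_brightfield", "generate_rapid_acquisition",
    "generate_timelapse", "simulate_focus_tables", "save_ground_truth",
    "STATE_FREE", "STATE_TIGHT", "STATE_LOOSE", "STATE_DISPERSED",
]

STATE_FREE, STATE_TIGHT, STATE_LOOSE, STATE_DISPERSED = 0, 1, 2, 3
STATE_NAMES = {0: "free", 1: "tight", 2: "loose", 3: "dispersed"}


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one stage; deterministic in (seed, stream)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

@dataclass
class SimCell:
    """Ground-truth geometry of one simulated spherocylindrical cell."""

    cell_id: int
    center_nm: np.ndarray          # (x, y)
    theta: float                   # axis angle, radians
    length_um: float               # end-to-end, includes the caps
    width_um: float
    mask: np.ndarray               # full-field boolean mask
    pixel_size_nm: float
    baseline_length_um: float = 0.0

    @property
    def volume_fl(self) -> float:
        return spherocylinder_volume(self.length_um, self.width_um)

    @property
    def area_um2(self) -> float:
        px_um = self.pixel_size_nm / 1000.0
        return float(self.mask.sum()) * px_um * px_um

    def axis_endpoints_nm(self) -> tuple[np.ndarray, np.ndarray]:
        """End points of the central axis segment (cylindrical part)."""
        half = (self.length_um - self.width_um) / 2.0 * 1000.0
        d = np.array([np.cos(self.theta), np.sin(self.theta)])
        return self.center_nm - half * d, self.center_nm + half * d

    def to_outline(self, frame: int = 0, time_s: float = 0.0) -> CellOutline:
        return CellOutline(
            cell_id=self.cell_id, mask=self.mask,
            pixel_size_nm=self.pixel_size_nm, area_um2=self.area_um2,
            length_um=self.length_um, width_um=self.width_um,
            volume_fl=self.volume_fl, frame=frame, time_s=time_s,
        )


def expression_time_course(config: SimulationConfig, t_min) -> np.ndarray | float:
    """Expected molecules per cell at time ``t_min`` after damage.

    Constant at ``N_baseline`` before ``onset_min``, rising along a smooth
    sigmoid to ``N_plateau`` at ``plateau_min`` and constant thereafter.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_min must be >= 0")
    r = np.clip((t - config.onset_min) / (config.plateau_min - config.onset_min),
                0.0, 1.0)
    s = r * r * r * (r * (6.0 * r - 15.0) + 10.0)   # smootherstep sigmoid
    out = config.N_baseline + (config.N_plateau - config.N_baseline) * s
    return float(out) if np.isscalar(t_min) else out


def volume_growth_factor(config: SimulationConfig, t_min: float) -> float:
    """Filamentation law: exponential volume inflation after onset, capped.

    The rate is set so the cap (default 2.5x) is reached at
    ``filament_ref_min`` (default 120 min).
    """
    if config.filament_volume_cap <= 1.0 or t_min <= config.onset_min:
        return 1.0
    k = np.log(config.filament_volume_cap) / (config.filament_ref_min
                                              - config.onset_min)
    return float(min(config.filament_volume_cap,
                     np.exp(k * (t_min - config.onset_min))))


def _length_for_volume(volume_fl: float, width_um: float) -> float:
    r = width_um / 2.0
    cap_vol = (4.0 / 3.0) * np.pi * r**3
    return width_um + max(0.0, volume_fl - cap_vol) / (np.pi * r * r)


def _segment_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two 2-D segments (0 when they intersect)."""
    def pt_seg(p, a, b):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            return float(np.hypot(*(p - a)))
        t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
        return float(np.hypot(*(p - (a + t * ab))))

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    d1 = cross(q1, q2, p1)
    d2 = cross(q1, q2, p2)
    d3 = cross(p1, p2, q1)
    d4 = cross(p1, p2, q2)
    if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
        return 0.0
    # for non-intersecting 2-D segments the minimum is at an endpoint
    return min(pt_seg(p1, q1, q2), pt_seg(p2, q1, q2),
               pt_seg(q1, p1, p2), pt_seg(q2, p1, p2))


def _rasterize_cell(center_nm, theta, length_um, width_um, shape, px_nm):
    """Boolean mask of pixels whose centre lies within the spherocylinder."""
    half = max(0.0, (length_um - width_um) / 2.0) * 1000.0
    rad = width_um / 2.0 * 1000.0
    d = np.array([np.cos(theta), np.sin(theta)])
    a = center_nm - half * d
    reach = half + rad + 2 * px_nm
    j0 = max(0, int((center_nm[0] - reach) / px_nm))
    j1 = min(shape[1], int((center_nm[0] + reach) / px_nm) + 1)
    i0 = max(0, int((center_nm[1] - reach) / px_nm))
    i1 = min(shape[0], int((center_nm[1] + reach) / px_nm) + 1)
    mask = np.zeros(shape, dtype=bool)
    if j1 <= j0 or i1 <= i0:
        return mask
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    cx = (jj + 0.5) * px_nm - a[0]
    cy = (ii + 0.5) * px_nm - a[1]
    t = np.clip(cx * d[0] + cy * d[1], 0.0, 2 * half)
    dist2 = (cx - t * d[0]) ** 2 + (cy - t * d[1]) ** 2
    mask[i0:i1, j0:j1] = dist2 <= rad * rad
    return mask


def simulate_cells(
    config: SimulationConfig,
    n_cells: int,
    t_min: float = 0.0,
    seed: Optional[int] = None,
    footprint_t_min: Optional[float] = None,
) -> list[SimCell]:
    """Place non-overlapping spherocylindrical cells on the image plane.

    Baseline lengths are drawn from the configured normal distribution and,
    for ``t_min`` past the damage onset, inflated by the filamentation law so
    the mean cell volume follows :func:`volume_growth_factor`.

    ``footprint_t_min`` reserves space for the cell's length at a later time
    point (used by the time-lapse generator so growing cells never collide).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if t_min < 0 or t_min > config.timelapse_duration_min:
        raise ValueError("t_min outside the simulated duration")
    rng = _rng(config.seed if seed is None else seed, 0)
    shape = (config.field_height_px, config.field_width_px)
    px = config.pixel_size_nm
    w = config.cell_width_um

    base_len = rng.normal(config.cell_length_mean_um, config.cell_length_sd_um,
                          size=n_cells)
    base_len = np.clip(base_len, w + 0.2, None)

    def grown(length0: float, t: float) -> float:
        v0 = spherocylinder_volume(length0, w)
        return _length_for_volume(v0 * volume_growth_factor(config, t), w)

    lengths = np.array([grown(l0, t_min) for l0 in base_len])
    foot_t = t_min if footprint_t_min is None else footprint_t_min
    footprint = np.array([grown(l0, foot_t) for l0 in base_len])

    margin_nm = 500.0
    field_nm = (shape[1] * px, shape[0] * px)
    cells: list[SimCell] = []
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(n_cells):
        half_foot = (footprint[i] / 2.0) * 1000.0 + w * 500.0
        lo = half_foot + px
        hix, hiy = field_nm[0] - lo, field_nm[1] - lo
        if hix <= lo or hiy <= lo:
            raise PlacementError(
                f"field {field_nm[0]:.0f}x{field_nm[1]:.0f} nm too small to "
                f"place a cell of length {footprint[i]:.2f} um"
            )
        ok = False
        for _ in range(600):
            center = np.array([rng.uniform(lo, hix), rng.uniform(lo, hiy)])
            theta = rng.uniform(0.0, np.pi)
            halfax = max(0.0, (footprint[i] - w) / 2.0) * 1000.0
            d = np.array([np.cos(theta), np.sin(theta)])
            p1, p2 = center - halfax * d, center + halfax * d
            clear = all(
                _segment_distance(p1, p2, q1, q2) >= w * 1000.0 + margin_nm
                for q1, q2 in placed
            )
            if clear:
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place cell {i + 1}/{n_cells} without overlap in a "
                f"{shape[1]}x{shape[0]} px field; enlarge the field or reduce "
                "n_cells"
            )
        placed.append((p1, p2))
        mask = _rasterize_cell(center, theta, lengths[i], w, shape, px)
        cells.append(SimCell(
            cell_id=i, center_nm=center, theta=theta, length_um=float(lengths[i]),
            width_um=w, mask=mask, pixel_size_nm=px,
            baseline_length_um=float(base_len[i]),
        ))
    return cells


def grow_cell(cell: SimCell, config: SimulationConfig, t_min: float) -> SimCell:
    """Geometry of ``cell`` at time ``t_min`` under the filamentation law."""
    v0 = spherocylinder_volume(cell.baseline_length_um, cell.width_um)
    length = _length_for_volume(v0 * volume_growth_factor(config, t_min),
                                cell.width_um)
    mask = _rasterize_cell(cell.center_nm, cell.theta, length, cell.width_um,
                           cell.mask.shape, cell.pixel_size_nm)
    return SimCell(cell_id=cell.cell_id, center_nm=cell.center_nm,
                   theta=cell.theta, length_um=length, width_um=cell.width_um,
                   mask=mask, pixel_size_nm=cell.pixel_size_nm,
                   baseline_length_um=cell.baseline_length_um)


# ---------------------------------------------------------------------------
# molecules
# ---------------------------------------------------------------------------

@dataclass
class MoleculeSet:
    """Per-molecule ground truth for one acquisition."""

    cell_id: np.ndarray            # (n,)
    state: np.ndarray              # (n,) STATE_* codes
    pos_nm: np.ndarray             # (n, 2) current positions
    bleach_time_s: np.ndarray = None   # (n,) illuminated-time bleach times
    return_times_s: list = field(default_factory=list)  # (mol_idx, t) pairs

    @property
    def n(self) -> int:
        return int(self.cell_id.size)

    def state_names(self) -> np.ndarray:
        return np.array([STATE_NAMES[s] for s in self.state])


def _uniform_in_mask(mask: np.ndarray, n: int, px_nm: float,
                     rng: np.random.Generator) -> np.ndarray:
    ii, jj = np.nonzero(mask)
    idx = rng.integers(0, ii.size, size=n)
    x = (jj[idx] + rng.uniform(0.0, 1.0, n)) * px_nm
    y = (ii[idx] + rng.uniform(0.0, 1.0, n)) * px_nm
    return np.column_stack([x, y])


def replisome_sites_for_cell(cell: SimCell, n_sites: int,
                             rng: np.random.Generator,
                             axial_fractions: Optional[np.ndarray] = None
                             ) -> np.ndarray:
    """Replisome marker positions along the cell axis (nm)."""
    if n_sites == 0:
        return np.zeros((0, 2))
    if axial_fractions is None:
        axial_fractions = rng.uniform(0.1, 0.9, size=n_sites)
    a, b = cell.axis_endpoints_nm()
    return a[None, :] + axial_fractions[:, None] * (b - a)[None, :]


def place_molecules(
    cell: SimCell,
    n: int,
    fractions: tuple[float, float, float],
    replisome_sites: np.ndarray,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> MoleculeSet:
    """Assign binding classes and initial positions for ``n`` molecules.

    ``fractions`` is (tight, loose, dispersed); the remainder is freely
    diffusing.  Tight molecules sit exactly at a replisome site, loose ones
    at a site plus an isotropic Gaussian offset of scale
    ``loose_offset_sigma_nm``, dispersed and free molecules uniformly within
    the cell mask.
    """
    f_t, f_l, f_d = fractions
    if min(f_t, f_l, f_d) < 0 or f_t + f_l + f_d > 1 + 1e-12:
        raise ConfigError("invalid binding-class fractions")
    if len(replisome_sites) == 0 and f_t + f_l > 0:
        raise ConfigError(
            "f_tight + f_loose > 0 requires at least one replisome site"
        )
    probs = np.array([1.0 - f_t - f_l - f_d, f_t, f_l, f_d])
    state = rng.choice(4, size=n, p=probs).astype(np.int8)
    pos = np.zeros((n, 2))
    at_site = np.flatnonzero((state == STATE_TIGHT) | (state == STATE_LOOSE))
    if at_site.size:
        site_idx = rng.integers(0, len(replisome_sites), size=at_site.size)
        pos[at_site] = replisome_sites[site_idx]
        loose = state[at_site] == STATE_LOOSE
        pos[at_site[loose]] += rng.normal(
            0.0, config.loose_offset_sigma_nm, size=(int(loose.sum()), 2))
    in_cell = np.flatnonzero((state == STATE_DISPERSED) | (state == STATE_FREE))
    if in_cell.size:
        pos[in_cell] = _uniform_in_mask(cell.mask, in_cell.size,
                                        config.pixel_size_nm, rng)
    return MoleculeSet(cell_id=np.full(n, cell.cell_id), state=state, pos_nm=pos)


def draw_bleach_times(n: int, tau_bleach_s: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Exponential bleach times (in illuminated seconds)."""
    if not np.isfinite(tau_bleach_s):
        return np.full(n, np.inf)
    return rng.exponential(tau_bleach_s, size=n)


def simulate_bleaching(mols: MoleculeSet, config: SimulationConfig,
                       rng: np.random.Generator,
                       illuminated_s: float) -> MoleculeSet:
    """Draw bleach times and rare post-bleach return events for a movie.

    Each fluorophore bleaches after an exponential amount of illuminated
    time (mean ``tau_bleach_s``); afterwards it may transiently return to
    the bright state at ``return_rate_per_s``, each return lasting a single
    frame.
    """
    mols.bleach_time_s = draw_bleach_times(mols.n, config.tau_bleach_s, rng)
    mols.return_times_s = []
    if config.return_rate_per_s > 0:
        dark = np.maximum(0.0, illuminated_s - mols.bleach_time_s)
        n_ev = rng.poisson(config.return_rate_per_s * dark)
        for m in np.flatnonzero(n_ev):
            ts = rng.uniform(mols.bleach_time_s[m], illuminated_s,
                             size=int(n_ev[m]))
            mols.return_times_s.extend((int(m), float(t)) for t in ts)
    return mols


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_PSF_TRUNCATION_SIGMAS = 4.5    # keeps truncation loss below 0.01%


def _add_gaussians(img: np.ndarray, x_px: np.ndarray, y_px: np.ndarray,
                   flux: np.ndarray, sigma_px: float,
                   chunk: int = 4096) -> None:
    """Accumulate pixel-integrated 2-D Gaussians into ``img`` in place."""
    n = x_px.size
    if n == 0:
        return
    rad = int(np.ceil(_PSF_TRUNCATION_SIGMAS * sigma_px))
    w = 2 * rad + 1
    offs = np.arange(w)
    s = sigma_px * np.sqrt(2.0)
    H, W = img.shape
    for k0 in range(0, n, chunk):
        xs = x_px[k0:k0 + chunk]
        ys = y_px[k0:k0 + chunk]
        fs = flux[k0:k0 + chunk]
        j0 = np.floor(xs).astype(np.int64) - rad
        i0 = np.floor(ys).astype(np.int64) - rad
        cols = j0[:, None] + offs[None, :]
        rows = i0[:, None] + offs[None, :]
        ex = 0.5 * (erf((cols + 1 - xs[:, None]) / s)
                    - erf((cols - xs[:, None]) / s))
        ey = 0.5 * (erf((rows + 1 - ys[:, None]) / s)
                    - erf((rows - ys[:, None]) / s))
        patch = fs[:, None, None] * ey[:, :, None] * ex[:, None, :]
        rr = np.broadcast_to(rows[:, :, None], patch.shape)
        cc = np.broadcast_to(cols[:, None, :], patch.shape)
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        np.add.at(img, (rr[ok], cc[ok]), patch[ok])


def render_frame(
    positions_nm: np.ndarray,
    flux_au: np.ndarray,
    config: SimulationConfig,
    shape: Optional[tuple] = None,
    autofluor_map: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    noise: bool = True,
) -> np.ndarray:
    """Render one camera frame.

    ``flux_au`` is each emitter's integrated intensity for this frame
    (already scaled by exposure and by any partial-frame bleaching).  Shot
    noise is Poisson on the signal (gain 1 a.u. per photon equivalent), the
    camera offset is added afterwards, then Gaussian read noise; the result
    is clipped to the detector bit depth.
    """
    if shape is None:
        shape = (config.field_height_px, config.field_width_px)
    img = np.zeros(shape, dtype=np.float64)
    positions_nm = np.asarray(positions_nm, dtype=float).reshape(-1, 2)
    flux_au = np.asarray(flux_au, dtype=float).reshape(-1)
    _add_gaussians(img, positions_nm[:, 0] / config.pixel_size_nm,
                   positions_nm[:, 1] / config.pixel_size_nm,
                   flux_au, config.psf_sigma_px)
    if autofluor_map is not None:
        img = img + autofluor_map
    if noise:
        if rng is None:
            raise ValueError("rng required when noise=True")
        img = rng.poisson(np.clip(img, 0.0, None)).astype(np.float64)
        img += config.camera_offset_au
        if config.read_noise_sd_au > 0:
            img += rng.normal(0.0, config.read_noise_sd_au, size=shape)
    else:
        img += config.camera_offset_au
    return np.clip(img, 0.0, float(2 ** config.bit_depth - 1))


def render_brightfield(cells: list[SimCell], config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None,
                       noise: bool = True) -> np.ndarray:
    """Soft-edged inverted mask image standing in for bright-field optics."""
    shape = (config.field_height_px, config.field_width_px)
    union = np.zeros(shape, dtype=float)
    for c in cells:
        union[c.mask] = 1.0
    soft = ndimage.gaussian_filter(union, 1.0)
    img = 1000.0 * (1.0 - 0.5 * soft)
    if noise and rng is not None:
        img = img + rng.normal(0.0, 5.0, size=shape)
    return img


def _autofluor_map(cells: list[SimCell], amplitude_au: float) -> np.ndarray:
    shape = cells[0].mask.shape
    m = np.zeros(shape, dtype=float)
    for c in cells:
        m[c.mask] = amplitude_au
    return m


# ---------------------------------------------------------------------------
# acquisitions
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Simulator record of everything the analysis is asked to recover."""

    config: SimulationConfig
    scenario: str
    t_min: float
    cells: list
    replisome_sites: list          # one (k, 2) array per cell
    molecules: Optional[MoleculeSet] = None
    n_molecules_per_cell: Optional[np.ndarray] = None
    bound_trajectories: Optional[np.ndarray] = None   # (frames, n_bound, 2)
    bound_index: Optional[np.ndarray] = None

    def label_mask(self) -> np.ndarray:
        lab = np.zeros(self.cells[0].mask.shape, dtype=np.int32)
        for c in self.cells:
            lab[c.mask] = c.cell_id + 1
        return lab


@dataclass
class RapidAcquisition:
    yfp: MovieStack
    brightfield: MovieStack
    ground_truth: GroundTruth


def _scenario_fractions(config: SimulationConfig, scenario: str,
                        t_min: float) -> tuple[float, float, float]:
    if scenario == "dead":
        return (0.0, 0.0, 0.0)          # everything diffuses freely
    f_t, f_l, f_d = config.f_tight, config.f_loose, config.f_dispersed
    if scenario == "damage" and t_min >= config.coloc_switch_min:
        f_t *= config.coloc_drop_factor
        f_l *= config.coloc_drop_factor
    return (f_t, f_l, f_d)


def generate_rapid_acquisition(
    config: SimulationConfig,
    scenario: str = "damage",
    n_cells: int = 10,
    t_min: float = 120.0,
    seed: Optional[int] = None,
    n_molecules: Optional[int] = None,
    noise: bool = True,
    store_trajectories: bool = False,
) -> RapidAcquisition:
    """Continuous-excitation movie (default 300 x 34 ms frames).

    ``scenario`` is one of ``undamaged`` (baseline expression, no
    filamentation), ``damage`` (expression and filamentation evaluated at
    ``t_min`` after treatment) or ``dead`` (a catalytically dead analogue:
    molecules never bind, so no foci form).  ``n_molecules`` forces an exact
    per-cell copy number instead of a Poisson draw around the expression
    curve.
    """
    if scenario not in ("undamaged", "damage", "dead"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "undamaged":
        t_min = 0.0
    seed = config.seed if seed is None else seed
    rng_place = _rng(seed, 1)
    rng_bleach = _rng(seed, 2)
    rng_motion = _rng(seed, 3)
    rng_noise = _rng(seed, 4)

    cells = simulate_cells(config, n_cells, t_min, seed=seed)
    sites = [replisome_sites_for_cell(c, config.replisome_foci_per_cell,
                                      rng_place) for c in cells]
    fractions = _scenario_fractions(config, scenario, t_min)

    n_expected = expression_time_course(config, t_min)
    sets = []
    counts = np.zeros(n_cells, dtype=int)
    for c in cells:
        n_i = int(n_molecules) if n_molecules is not None else int(
            rng_place.poisson(n_expected))
        counts[c.cell_id] = n_i
        sets.append(place_molecules(c, n_i, fractions, sites[c.cell_id],
                                    rng_place, config))
    mols = MoleculeSet(
        cell_id=np.concatenate([s.cell_id for s in sets]) if sets else np.zeros(0, int),
        state=np.concatenate([s.state for s in sets]) if sets else np.zeros(0, np.int8),
        pos_nm=np.vstack([s.pos_nm for s in sets]) if sets else np.zeros((0, 2)),
    )

    dt = config.frame_interval_rapid_s
    n_frames = config.n_frames_rapid
    total_s = n_frames * dt
    simulate_bleaching(mols, config, rng_bleach, total_s)
    returns_by_frame: dict[int, list[int]] = {}
    for m, t in mols.return_times_s:
        returns_by_frame.setdefault(int(t / dt), []).append(m)

    exposure_scale = (dt * 1000.0) / config.reference_exposure_ms
    flux_full = config.I_single_au * exposure_scale
    bound = np.flatnonzero(mols.state != STATE_FREE)
    free = np.flatnonzero(mols.state == STATE_FREE)
    pos_bound = mols.pos_nm[bound].copy()
    pos_free = mols.pos_nm[free].copy()
    sig_bound = np.sqrt(2.0 * config.D_bound_um2_s * dt) * 1000.0
    sub = config.free_substeps
    sig_free = np.sqrt(2.0 * config.D_free_um2_s * dt / sub) * 1000.0
    field_nm = (config.field_width_px * config.pixel_size_nm,
                config.field_height_px * config.pixel_size_nm)
    auto_base = _autofluor_map(cells, 1.0) if config.autofluor_amplitude_au > 0 \
        else None

    frames = np.empty((n_frames, config.field_height_px, config.field_width_px),
                      dtype=np.float32)
    traj = np.empty((n_frames, bound.size, 2)) if store_trajectories else None
    for f in range(n_frames):
        t0 = f * dt
        alive_frac = np.clip((mols.bleach_time_s - t0) / dt, 0.0, 1.0)
        pos_list, flux_list = [], []
        frac_b = alive_frac[bound]
        lit = frac_b > 0
        if lit.any():
            pos_list.append(pos_bound[lit])
            flux_list.append(flux_full * frac_b[lit])
        for m in returns_by_frame.get(f, ()):
            pos_list.append(mols.pos_nm[m][None, :])
            flux_list.append(np.array([flux_full]))
        frac_f = alive_frac[free]
        litf = np.flatnonzero(frac_f > 0)
        if litf.size:
            p = pos_free[litf]
            for _ in range(sub):
                p = p + rng_motion.normal(0.0, sig_free, size=p.shape)
                np.clip(p[:, 0], 0.0, field_nm[0], out=p[:, 0])
                np.clip(p[:, 1], 0.0, field_nm[1], out=p[:, 1])
                pos_list.append(p.copy())
                flux_list.append(flux_full * frac_f[litf] / sub)
            pos_free[litf] = p
        pos = np.vstack(pos_list) if pos_list else np.zeros((0, 2))
        flux = np.concatenate(flux_list) if flux_list else np.zeros(0)
        auto = None
        if auto_base is not None:
            amp = (config.autofluor_amplitude_au * exposure_scale
                   * np.exp(-(t0 + dt / 2.0) / config.tau_autofluor_s))
            auto = auto_base * amp
        frames[f] = render_frame(pos, flux, config, autofluor_map=auto,
                                 rng=rng_noise, noise=noise)
        if store_trajectories:
            traj[f] = pos_bound
        if bound.size:
            pos_bound = pos_bound + rng_motion.normal(0.0, sig_bound,
                                                      size=pos_bound.shape)

    gt = GroundTruth(config=config, scenario=scenario, t_min=t_min,
                     cells=cells, replisome_sites=sites, molecules=mols,
                     n_molecules_per_cell=counts,
                     bound_trajectories=traj, bound_index=bound)
    stack = MovieStack(data=frames, pixel_size_nm=config.pixel_size_nm,
                       timestamps_s=np.arange(n_frames) * dt,
                       exposure_ms=dt * 1000.0, channel="yfp")
    bf = MovieStack(data=render_brightfield(cells, config, rng_noise, noise),
                    pixel_size_nm=config.pixel_size_nm,
                    timestamps_s=np.array([0.0]),
                    exposure_ms=config.exposure_bf_ms, channel="brightfield")
    return RapidAcquisition(yfp=stack, brightfield=bf, ground_truth=gt)


@dataclass
class Timelapse:
    times_min: np.ndarray
    brightfield: MovieStack
    yfp: MovieStack
    red: MovieStack
    ground_truths: list            # one GroundTruth per time point


def timelapse_times_min(config: SimulationConfig) -> np.ndarray:
    """Acquisition times 0..duration inclusive at the configured interval."""
    n = int(np.floor(config.timelapse_duration_min
                     / config.timelapse_interval_min + 1e-9)) + 1
    return np.arange(n) * config.timelapse_interval_min


def generate_timelapse(
    config: SimulationConfig,
    scenario: str = "damage",
    n_cells: int = 6,
    seed: Optional[int] = None,
    noise: bool = True,
) -> Timelapse:
    """Time-lapse series: bright-field, YFP and red frames per time point.

    Per time point three images are recorded; the red channel is acquired
    ``channel_lag_s`` after the YFP channel.  Cells grow (scenario
    ``damage``) according to the filamentation law; molecule counts follow
    the expression time course.  Photobleaching over the sparse time-lapse
    illumination is negligible and is not applied.
    """
    if scenario not in ("undamaged", "damage"):
        raise ValueError(f"unknown scenario {scenario!r}")
    seed = config.seed if seed is None else seed
    rng_place = _rng(seed, 11)
    rng_noise = _rng(seed, 12)
    times = timelapse_times_min(config)
    t_final = float(times[-1]) if scenario == "damage" else 0.0
    cells0 = simulate_cells(config, n_cells, 0.0, seed=seed,
                            footprint_t_min=t_final)
    site_fracs = [np.sort(rng_place.uniform(0.1, 0.9,
                                            config.replisome_foci_per_cell))
                  for _ in cells0]

    bf_frames, yfp_frames, red_frames, gts = [], [], [], []
    scale_y = config.exposure_yfp_ms / config.reference_exposure_ms
    scale_r = config.exposure_red_ms / config.reference_exposure_ms
    lag_sd = np.sqrt(2.0 * config.D_bound_um2_s * config.channel_lag_s) * 1000.0
    for t in times:
        t_eff = float(t) if scenario == "damage" else 0.0
        cells = [grow_cell(c, config, t_eff) for c in cells0]
        sites = [replisome_sites_for_cell(c, config.replisome_foci_per_cell,
                                          rng_place, axial_fractions=fr)
                 for c, fr in zip(cells, site_fracs)]
        fractions = _scenario_fractions(config, scenario, t_eff)
        n_expected = expression_time_course(config, t_eff)
        sets, counts = [], np.zeros(n_cells, dtype=int)
        for c in cells:
            n_i = int(rng_place.poisson(n_expected))
            counts[c.cell_id] = n_i
            sets.append(place_molecules(c, n_i, fractions, sites[c.cell_id],
                                        rng_place, config))
        mols = MoleculeSet(
            cell_id=np.concatenate([s.cell_id for s in sets]),
            state=np.concatenate([s.state for s in sets]),
            pos_nm=np.vstack([s.pos_nm for s in sets]) if sets else np.zeros((0, 2)),
        )
        bound = mols.state != STATE_FREE
        auto = _autofluor_map(cells, config.autofluor_amplitude_au * scale_y)
        # free molecules: over a 50 ms exposure the smear is effectively
        # uniform across the cell, so spread their flux over the mask
        free_idx = np.flatnonzero(~bound)
        if free_idx.size:
            per_cell_free = np.bincount(mols.cell_id[free_idx],
                                        minlength=n_cells)
            for c in cells:
                npx = int(c.mask.sum())
                if npx and per_cell_free[c.cell_id]:
                    auto[c.mask] += (per_cell_free[c.cell_id]
                                     * config.I_single_au * scale_y / npx)
        yfp = render_frame(mols.pos_nm[bound],
                           np.full(int(bound.sum()),
                                   config.I_single_au * scale_y),
                           config, autofluor_map=auto, rng=rng_noise,
                           noise=noise)
        site_pos = np.vstack(sites) if sites else np.zeros((0, 2))
        site_lagged = site_pos + rng_noise.normal(0.0, lag_sd, site_pos.shape)
        red = render_frame(site_lagged,
                           np.full(len(site_lagged),
                                   config.I_single_red_au * scale_r),
                           config, rng=rng_noise, noise=noise)
        bf = render_brightfield(cells, config, rng_noise, noise)
        bf_frames.append(bf.astype(np.float32))
        yfp_frames.append(yfp.astype(np.float32))
        red_frames.append(red.astype(np.float32))
        gts.append(GroundTruth(config=config, scenario=scenario, t_min=float(t),
                               cells=cells, replisome_sites=sites,
                               molecules=mols, n_molecules_per_cell=counts))
    t_s = times * 60.0
    mk = lambda fr, ts, exp, ch: MovieStack(
        data=np.stack(fr), pixel_size_nm=config.pixel_size_nm,
        timestamps_s=ts, exposure_ms=exp, channel=ch)
    return Timelapse(
        times_min=times,
        brightfield=mk(bf_frames, t_s, config.exposure_bf_ms, "brightfield"),
        yfp=mk(yfp_frames, t_s + 0.1, config.exposure_yfp_ms, "yfp"),
        red=mk(red_frames, t_s + 0.1 + config.channel_lag_s,
               config.exposure_red_ms, "red"),
        ground_truths=gts,
    )


# ---------------------------------------------------------------------------
# focus-table level simulation (for colocalisation statistics)
# ---------------------------------------------------------------------------

def simulate_focus_tables(
    config: SimulationConfig,
    scenario: str = "damage",
    n_cells: int = 20,
    times_min: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Simulate detected-focus tables for both channels, bypassing rendering.

    Channel B carries the replisome marker foci; channel A foci are placed
    tightly at a site (probability ``f_tight``), loosely around one
    (``f_loose``, Gaussian offset ``loose_offset_sigma_nm``) or uniformly in
    the cell.  Both channels receive isotropic localisation noise
    (``localisation_noise_nm``); channel B additionally jitters by the
    Brownian displacement accumulated over ``channel_lag_s``.  Scenarios:
    ``damage`` (tight/loose fractions drop by ``coloc_drop_factor`` at
    ``coloc_switch_min``), ``undamaged``, ``csr`` (both channels uniform) and
    ``replisome_pair`` (both channels mark every site: a doubly labelled
    replisome control).

    Returns (cells, fociA, fociB); the tables have columns
    time_min, cell_id, x_nm, y_nm.
    """
    if scenario not in ("damage", "undamaged", "csr", "replisome_pair"):
        raise ValueError(f"unknown scenario {scenario!r}")
    seed = config.seed if seed is None else seed
    rng = _rng(seed, 21)
    if times_min is None:
        times_min = np.array([0.0])
    times_min = np.asarray(times_min, dtype=float)
    t_final = float(times_min.max()) if scenario == "damage" else 0.0
    cells0 = simulate_cells(config, n_cells, 0.0, seed=seed,
                            footprint_t_min=t_final)
    site_fracs = [rng.uniform(0.1, 0.9, config.replisome_foci_per_cell)
                  for _ in cells0]
    loc = config.localisation_noise_nm
    lag_sd = np.sqrt(2.0 * config.D_bound_um2_s * config.channel_lag_s) * 1000.0
    rows_a, rows_b = [], []
    cells_by_time = []
    for t in times_min:
        t_eff = float(t) if scenario == "damage" else 0.0
        cells = ([grow_cell(c, config, t_eff) for c in cells0]
                 if scenario == "damage" else cells0)
        cells_by_time.append(cells)
        f_t, f_l, _ = _scenario_fractions(config, "damage" if scenario ==
                                          "damage" else "undamaged", t_eff)
        for c, fr in zip(cells, site_fracs):
            sites = replisome_sites_for_cell(c, config.replisome_foci_per_cell,
                                             rng, axial_fractions=fr)
            if scenario == "csr":
                b_pos = _uniform_in_mask(c.mask, len(sites),
                                         config.pixel_size_nm, rng)
            else:
                b_pos = sites + rng.normal(0.0, lag_sd, sites.shape)
            b_obs = b_pos + rng.normal(0.0, loc, b_pos.shape)
            for x, y in b_obs:
                rows_b.append((float(t), c.cell_id, x, y))
            if scenario == "replisome_pair":
                a_pos = sites.copy()
            else:
                n_a = rng.poisson(config.foci_density_per_um2 * c.area_um2)
                a_pos = np.zeros((n_a, 2))
                u = rng.uniform(0.0, 1.0, n_a)
                for k in range(n_a):
                    if scenario != "csr" and u[k] < f_t and len(sites):
                        a_pos[k] = sites[rng.integers(len(sites))]
                    elif scenario != "csr" and u[k] < f_t + f_l and len(sites):
                        a_pos[k] = (sites[rng.integers(len(sites))]
                                    + rng.normal(0.0,
                                                 config.loose_offset_sigma_nm,
                                                 2))
                    else:
                        a_pos[k] = _uniform_in_mask(c.mask, 1,
                                                    config.pixel_size_nm,
                                                    rng)[0]
            a_obs = a_pos + rng.normal(0.0, loc, a_pos.shape)
            for x, y in a_obs:
                rows_a.append((float(t), c.cell_id, x, y))
    cols = ["time_min", "cell_id", "x_nm", "y_nm"]
    return (cells_by_time,
            pd.DataFrame(rows_a, columns=cols),
            pd.DataFrame(rows_b, columns=cols))


# ---------------------------------------------------------------------------
# ground-truth export
# ---------------------------------------------------------------------------

def save_ground_truth(gt: GroundTruth, outdir: str | Path) -> None:
    """Write ground truth as CSV tables plus a label-mask TIFF."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame([{
        "cell_id": c.cell_id, "x_nm": c.center_nm[0], "y_nm": c.center_nm[1],
        "theta_rad": c.theta, "length_um": c.length_um,
        "width_um": c.width_um, "area_um2": c.area_um2,
        "volume_fl": c.volume_fl,
        "n_molecules": (int(gt.n_molecules_per_cell[c.cell_id])
                        if gt.n_molecules_per_cell is not None else -1),
    } for c in gt.cells])
    cells.to_csv(outdir / "cells.csv", index=False)
    sites = [{"cell_id": i, "x_nm": s[0], "y_nm": s[1]}
             for i, arr in enumerate(gt.replisome_sites) for s in arr]
    pd.DataFrame(sites, columns=["cell_id", "x_nm", "y_nm"]).to_csv(
        outdir / "replisome_sites.csv", index=False)
    if gt.molecules is not None:
        m = gt.molecules
        pd.DataFrame({
            "cell_id": m.cell_id, "state": m.state_names(),
            "x_nm": m.pos_nm[:, 0], "y_nm": m.pos_nm[:, 1],
            "bleach_time_s": (m.bleach_time_s if m.bleach_time_s is not None
                              else np.full(m.n, np.nan)),
        }).to_csv(outdir / "molecules.csv", index=False)
    tifffile.imwrite(str(outdir / "label_mask.tif"), gt.label_mask())
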