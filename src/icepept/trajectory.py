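"""Peptide–ice trajectory analyses.

The stack mirrors what one measures on an ice-growth simulation with a
dissolved binder: where the ice front is and how fast it advances, how many
liquid vs ice-like waters surround a hydrophobic probe (solvation census),
when the shell turns icy (binding detection), the disulfide C–S–S–C torsion
and its coupling to shell hydration, hydrogen bonds split by partner phase,
inter-residue distance distributions, and RMSD flexibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .geometry import dihedral_series, min_image, rmsd as _rmsd
from .phase import WaterPhaseLabels
from .synthetic import FrameSet


@dataclass
class FrontSeries:
    """Per-frame ice-front position along z."""

    times: np.ndarray        # ns
    front_z: np.ndarray      # Å

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.front_z = np.asarray(self.front_z, dtype=float)

    @property
    def growth(self) -> np.ndarray:
        """Front displacement relative to frame 0, Å."""
        return self.front_z - self.front_z[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "front_z": self.front_z,
                             "growth": self.growth})


@dataclass
class SolvationCensus:
    """Liquid / ice-like water counts in a probe's solvation shell."""

    times: np.ndarray
    n_liquid: np.ndarray
    n_icelike: np.ndarray
    r_shell: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.n_liquid = np.asarray(self.n_liquid, dtype=int)
        self.n_icelike = np.asarray(self.n_icelike, dtype=int)

    @property
    def n_total(self) -> np.ndarray:
        return self.n_liquid + self.n_icelike

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "n_liquid": self.n_liquid,
                             "n_icelike": self.n_icelike})


@dataclass
class TorsionSeries:
    """Dihedral series with a moving-average smooth; edges are omitted
    (no value is reported where a full window does not fit)."""

    times: np.ndarray
    phi: np.ndarray
    smooth_window: int
    times_smooth: np.ndarray
    phi_smooth: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "phi_deg": self.phi})


# ---------------------------------------------------------------------------
# front tracking


def ice_front_profile(labels: WaterPhaseLabels, positions_z: np.ndarray,
                      box_z: float, bin_width: float = 1.0) -> float:
    """Ice-front z position from the per-bin ice-like fraction.

    Slab geometry with ice at low z.  The binned ice-like fraction profile
    is monotone-smoothed (non-increasing isotonic fit, which leaves an
    already-monotone profile unchanged) and the front is the linearly
    interpolated z where it crosses 0.5, scanning from the ice side.  With
    no crossing the appropriate boundary (0 or box_z) is returned with a
    diagnostic.
    """
    positions_z = np.asarray(positions_z, dtype=float) % box_z
    edges = np.arange(0.0, box_z + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.clip(np.digitize(positions_z, edges) - 1, 0, len(centers) - 1)
    ice = labels.ice_like_mask().astype(float)
    tot = np.bincount(which, minlength=len(centers))
    icecount = np.bincount(which, weights=ice, minlength=len(centers))
    occupied = tot > 0
    frac = np.zeros(len(centers))
    frac[occupied] = icecount[occupied] / tot[occupied]
    # empty bins inherit their lower neighbour so they cannot fake a crossing
    for i in range(len(frac)):
        if not occupied[i]:
            frac[i] = frac[i - 1] if i > 0 else 1.0
    iso = IsotonicRegression(increasing=False)
    smooth = iso.fit_transform(centers, frac)
    above = smooth >= 0.5
    if above.all():
        warnings.warn("profile entirely ice-like; front at box top")
        return float(box_z)
    if not above.any():
        warnings.warn("profile entirely liquid; front at box bottom")
        return 0.0
    i = int(np.argmin(above))      # first bin below 0.5, scanning from ice side
    if i == 0:
        return float(centers[0])
    f0, f1 = smooth[i - 1], smooth[i]
    z0, z1 = centers[i - 1], centers[i]
    if f0 == f1:
        return float(z0)
    return float(z0 + (f0 - 0.5) / (f0 - f1) * (z1 - z0))


def front_series(frames: FrameSet, per_frame_labels: list[WaterPhaseLabels],
                 bin_width: float = 1.0) -> FrontSeries:
    ow = frames.indices("OW")
    zs = [
        ice_front_profile(lab, frames.coordinates[f][ow][:, 2],
                          float(frames.box[2]), bin_width)
        for f, lab in enumerate(per_frame_labels)
    ]
    return FrontSeries(frames.times, np.array(zs))


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, 'valid' mode (edges omitted)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > len(x):
        raise ValueError(f"window {window} larger than series length {len(x)}")
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")


def _valid_slice(n: int, window: int) -> slice:
    lead = (window - 1) // 2
    return slice(lead, lead + n - window + 1)


def growth_rate(front: FrontSeries, smooth_window: int = 5
                ) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed ice-growth rate dz/dt in Å/ns.

    Moving-average smooth of the front series, then a centered finite
    difference.  Returns (times, rate) on the valid (edge-trimmed) range.
    """
    if len(front.times) < 3:
        raise ValueError("growth_rate needs at least 3 frames")
    sm = moving_average(front.front_z, smooth_window)
    t = front.times[_valid_slice(len(front.times), smooth_window)]
    rate = np.gradient(sm, t)
    return t, rate


# ---------------------------------------------------------------------------
# solvation census and binding


def solvation_census(frames: FrameSet, per_frame_labels: list[WaterPhaseLabels],
                     probe_index: int, r_shell: float = 5.4) -> SolvationCensus:
    """Count liquid and ice-like waters within ``r_shell`` of the probe atom.

    Every water in the shell is either ice-like (by the classification's
    ice_like set) or counted as liquid, so the two counts always sum to the
    shell total.
    """
    if r_shell <= 0:
        raise ValueError("r_shell must be positive")
    ow = frames.indices("OW")
    n_liq = np.empty(frames.n_frames, dtype=int)
    n_ice = np.empty(frames.n_frames, dtype=int)
    for f in range(frames.n_frames):
        opos = frames.coordinates[f][ow]
        probe = frames.coordinates[f][probe_index]
        d = np.linalg.norm(min_image(opos - probe, frames.box), axis=1)
        shell = d <= r_shell
        icemask = per_frame_labels[f].ice_like_mask()
        n_ice[f] = int(np.sum(shell & icemask))
        n_liq[f] = int(np.sum(shell & ~icemask))
    return SolvationCensus(frames.times, n_liq, n_ice, r_shell)


def detect_binding(census: SolvationCensus, k_ice: int = 4,
                   dwell: float = 5.0) -> float | None:
    """Earliest time from which n_icelike ≥ k_ice holds continuously for at
    least ``dwell`` ns; None if that never happens."""
    t = census.times
    if len(t) == 0:
        return None
    good = census.n_icelike >= k_ice
    start = None
    for i in range(len(t)):
        if good[i]:
            if start is None:
                start = i
            if t[i] - t[start] >= dwell:
                return float(t[start])
        else:
            start = None
    # a run reaching the end of the series counts if it spans >= dwell
    if start is not None and t[-1] - t[start] >= dwell:
        return float(t[start])
    return None


# ---------------------------------------------------------------------------
# torsion


def torsion_series(frames: FrameSet, atom_quadruple: tuple[int, int, int, int],
                   smooth_window: int = 5000) -> TorsionSeries:
    """Signed dihedral (IUPAC, cis = 0°) of four atoms across all frames,
    with a moving-average smooth whose edges are omitted.

    If the window exceeds the series length, the smoothed series is empty
    (reported with a diagnostic) — matching the convention of dropping the
    unsupported edge spans outright.
    Collinear central atoms in a frame yield NaN for that frame.
    """
    a, b, c, d = atom_quadruple
    if len({a, b, c, d}) != 4:
        raise ValueError("torsion needs four distinct atoms")
    xyz = frames.coordinates
    phi = dihedral_series(xyz[:, a], xyz[:, b], xyz[:, c], xyz[:, d])
    if smooth_window > len(phi):
        warnings.warn("smoothing window exceeds series length; "
                      "smoothed series is empty")
        return TorsionSeries(frames.times, phi, smooth_window,
                             np.empty(0), np.empty(0))
    sm = moving_average(phi, smooth_window)
    ts = frames.times[_valid_slice(len(phi), smooth_window)]
    return TorsionSeries(frames.times, phi, smooth_window, ts, sm)


# ---------------------------------------------------------------------------
# φ–hydration coupling


@dataclass
class PhiHydrationMap:
    """Normalized 2D histogram over (φ, shell water count), total mass 1."""

    phi_edges: np.ndarray
    count_edges: np.ndarray
    mass: np.ndarray        # shape (len(phi_edges)-1, len(count_edges)-1)
    window: tuple[float, float]

    def phi_marginal(self) -> np.ndarray:
        return self.mass.sum(axis=1)


def phi_hydration_map(torsion: TorsionSeries, census: SolvationCensus,
                      window: tuple[float, float] | str = "full",
                      t_bind: float | None = None,
                      phi_bin: float = 10.0, count_bin: int = 1,
                      use_total: bool = True) -> PhiHydrationMap:
    """Joint density of the torsion angle and the shell water count.

    ``window`` is a (t0, t1) span in ns, or a preset: ``"full"`` (whole
    series), ``"pre_binding"`` (start → t_bind) or ``"last5ns"`` (the 5 ns
    immediately before t_bind) — the presets need ``t_bind``.
    ``use_total`` counts all shell waters; set False to count liquid only.
    """
    if isinstance(window, str):
        if window == "full":
            window = (float(torsion.times[0]), float(torsion.times[-1]))
        elif window == "pre_binding":
            if t_bind is None:
                raise ValueError("pre_binding preset needs t_bind")
            window = (float(torsion.times[0]), float(t_bind))
        elif window == "last5ns":
            if t_bind is None:
                raise ValueError("last5ns preset needs t_bind")
            window = (float(t_bind) - 5.0, float(t_bind))
        else:
            raise ValueError(f"unknown window preset {window!r}")
    t0, t1 = window
    if not np.allclose(torsion.times, census.times):
        raise ValueError("torsion and census series are not time-aligned")
    mask = (torsion.times >= t0) & (torsion.times <= t1) & np.isfinite(torsion.phi)
    if not mask.any():
        raise ValueError(f"empty window {window}")
    phi = torsion.phi[mask]
    n = (census.n_total if use_total else census.n_liquid)[mask]
    phi_edges = np.arange(-180.0, 180.0 + phi_bin, phi_bin)
    count_edges = np.arange(-0.5, n.max() + 0.5 + count_bin, count_bin)
    h, _, _ = np.histogram2d(phi, n, bins=(phi_edges, count_edges))
    return PhiHydrationMap(phi_edges, count_edges, h / h.sum(), (t0, t1))


# ---------------------------------------------------------------------------
# hydrogen bonds


def hydrogen_bond_present(donor, hydrogen, acceptor,
                          dist_cutoff: float = 3.5,
                          angle_cutoff: float = 30.0,
                          box=None) -> bool:
    """Geometric criterion: donor–acceptor heavy-atom distance ≤ 3.5 Å and
    H–donor–acceptor angle ≤ 30°."""
    donor, hydrogen, acceptor = (np.asarray(p, float) for p in (donor, hydrogen, acceptor))
    da = min_image(acceptor - donor, box)
    if np.linalg.norm(da) > dist_cutoff:
        return False
    dh = min_image(hydrogen - donor, box)
    cosang = float(np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da)))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) <= angle_cutoff


def hydrogen_bonds(frames: FrameSet, per_frame_labels: list[WaterPhaseLabels],
                   donors: list[tuple[int, int]],
                   dist_cutoff: float = 3.5, angle_cutoff: float = 30.0
                   ) -> pd.DataFrame:
    """Per-frame hydrogen-bond counts from the given donors to water
    oxygens, split by the partner water's phase (ice-like vs not).

    ``donors`` is a list of (donor_heavy_index, hydrogen_index); a donor
    whose hydrogen index is missing/invalid raises an error naming it.
    """
    ow = frames.indices("OW")
    rows = []
    for d_idx, h_idx in donors:
        if h_idx is None or not (0 <= h_idx < frames.n_atoms) \
                or not str(frames.species[h_idx]).startswith(("H", "h")):
            raise ValueError(f"donor atom {d_idx} has no hydrogen (index {h_idx})")
    for f in range(frames.n_frames):
        xyz = frames.coordinates[f]
        icemask = per_frame_labels[f].ice_like_mask()
        for d_idx, h_idx in donors:
            da = min_image(xyz[ow] - xyz[d_idx], frames.box)
            dist = np.linalg.norm(da, axis=1)
            close = np.flatnonzero((dist <= dist_cutoff) & (dist > 1e-6))
            n_ice = n_liq = 0
            dh = min_image(xyz[h_idx] - xyz[d_idx], frames.box)
            for j in close:
                cosang = float(np.dot(dh, da[j]) / (np.linalg.norm(dh) * dist[j]))
                if np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))) <= angle_cutoff:
                    if icemask[j]:
                        n_ice += 1
                    else:
                        n_liq += 1
            rows.append({"frame": f, "time_ns": frames.times[f],
                         "donor": d_idx, "n_to_ice": n_ice, "n_to_liquid": n_liq})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance PDFs and RMSD


def residue_pair_pdf(frames: FrameSet, pair: tuple[int, int],
                     window: tuple[float, float] | None = None,
                     bin_width: float = 0.2
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Probability density of the distance between two atoms over a time
    window.  Returns (bin_edges, density); the density integrates to 1."""
    i, j = pair
    mask = np.ones(frames.n_frames, dtype=bool)
    if window is not None:
        mask = (frames.times >= window[0]) & (frames.times <= window[1])
    if not mask.any():
        raise ValueError(f"empty window {window}")
    d = np.linalg.norm(
        min_image(frames.coordinates[mask, i] - frames.coordinates[mask, j],
                  frames.box), axis=1)
    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    if hi - lo < bin_width:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    return edges, density


def rmsd_series(frames: FrameSet, selection: np.ndarray,
                reference_frame: int = 0, superpose: bool = True) -> np.ndarray:
    """Per-frame RMSD of the selected atoms to a reference frame, optionally
    after optimal (proper-rotation) superposition."""
    selection = np.asarray(selection, dtype=int)
    if superpose and len(selection) < 3:
        raise ValueError("superposed RMSD needs at least 3 atoms")
    ref = frames.coordinates[reference_frame][selection]
    return np.array([
        _rmsd(frames.coordinates[f][selection], ref, superpose_first=superpose)
        for f in range(frames.n_frames)
    ])
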