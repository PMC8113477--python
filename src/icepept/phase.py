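"""CHILL+-style water-phase classification from local l=3 bond order.

Each water oxygen gets a 7-component Steinhardt vector q3 built from the
directions to its four nearest oxygen neighbours.  For every hydrogen-bonded
pair the normalized correlation

    c_ij = Re(Σ_m q3m(i) · q3m(j)*) / (|q3(i)| |q3(j)|)

distinguishes *staggered* relative orientations of the two water tetrahedra
(c near −1, as between the basal-plane neighbours in hexagonal ice) from
*eclipsed* ones (c near −0.1, as along the hexagonal c axis or throughout
clathrate cages).  Counting staggered and eclipsed bonds per molecule yields
the phase label:

====================  ============================
label                 bonds (out of 4)
====================  ============================
CUBIC                 4 staggered
HEX                   3 staggered + 1 eclipsed
CLATH                 4 eclipsed
INT_CLATH             exactly 3 eclipsed
INT_ICE               ≥2 staggered, none of the above
LIQ                   everything else
====================  ============================

Molecules with fewer than four neighbours inside the cutoff are liquid by
fiat (surface/gas safety).  "Ice-like" = {HEX, CUBIC, INT_ICE} by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

LABELS = ("HEX", "CUBIC", "INT_ICE", "CLATH", "INT_CLATH", "LIQ")
DEFAULT_ICE_LIKE = frozenset({"HEX", "CUBIC", "INT_ICE"})


@dataclass(frozen=True)
class PhaseCutoffs:
    """Thresholds of the bond-order classification (all configurable)."""

    neighbor_cutoff: float = 3.5     # Å, hydrogen-bond O–O distance
    staggered_max: float = -0.8      # c_ij <= this → staggered
    eclipsed_min: float = -0.35
    eclipsed_max: float = 0.25
    ice_like: frozenset = DEFAULT_ICE_LIKE


@dataclass
class WaterPhaseLabels:
    """Per-water phase labels plus the underlying bond bookkeeping."""

    labels: np.ndarray          # (N,) str
    n_staggered: np.ndarray     # (N,) int
    n_eclipsed: np.ndarray      # (N,) int
    neighbors: np.ndarray       # (N, 4) int, -1 where absent
    correlations: np.ndarray    # (N, 4) float, NaN where absent
    cutoffs: PhaseCutoffs = field(default_factory=PhaseCutoffs)

    def __len__(self) -> int:
        return len(self.labels)

    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def ice_like_mask(self) -> np.ndarray:
        return np.isin(self.labels, list(self.cutoffs.ice_like))

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label)) if len(self.labels) else float("nan")

    def to_frame(self, frame_index: int = 0) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": frame_index,
            "molecule_id": np.arange(len(self.labels)),
            "label": self.labels,
            "n_staggered": self.n_staggered,
            "n_eclipsed": self.n_eclipsed,
        })


def q3_vector(center: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
    """l=3 Steinhardt vector of one molecule: mean of Y_3m over the unit
    directions from ``center`` to each neighbour (m = −3..3)."""
    center = np.asarray(center, dtype=float)
    neighbors = np.atleast_2d(np.asarray(neighbors, dtype=float))
    if len(neighbors) == 0:
        raise ValueError("q3_vector needs at least one neighbor")
    vec = neighbors - center
    r = np.linalg.norm(vec, axis=1)
    if (r < 1e-12).any():
        raise ValueError("zero-length bond vector")
    theta = np.arccos(np.clip(vec[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(vec[:, 1], vec[:, 0])
    m = np.arange(-3, 4)
    y = sph_harm_y(3, m[None, :], theta[:, None], phi[:, None])
    return y.mean(axis=0)


def bond_correlation(q3_i: np.ndarray, q3_j: np.ndarray) -> float:
    """Normalized real inner product of two q3 vectors, in [−1, 1]."""
    q3_i = np.asarray(q3_i)
    q3_j = np.asarray(q3_j)
    ni = np.linalg.norm(q3_i)
    nj = np.linalg.norm(q3_j)
    if ni < 1e-12 or nj < 1e-12:
        raise ValueError("bond_correlation: zero-norm q3 vector")
    return float(np.real(np.sum(q3_i * np.conj(q3_j))) / (ni * nj))


def _q3_all(pos: np.ndarray, box: np.ndarray | None, cutoff: float):
    """Vectorized q3, 4-nearest-neighbour lists and validity mask."""
    n = len(pos)
    if box is not None:
        pos = np.mod(pos, box)
        tree = cKDTree(pos, boxsize=box)
    else:
        tree = cKDTree(pos)
    k = min(5, n)
    d, idx = tree.query(pos, k=k)
    if k < 5:
        d = np.pad(d, ((0, 0), (0, 5 - k)), constant_values=np.inf)
        idx = np.pad(idx, ((0, 0), (0, 5 - k)), constant_values=0)
    nbr = idx[:, 1:5]
    nd = d[:, 1:5]
    ok = np.isfinite(nd[:, 3]) & (nd[:, 3] <= cutoff)
    vec = pos[nbr] - pos[:, None, :]
    if box is not None:
        vec -= box * np.round(vec / box)
    r = np.linalg.norm(vec, axis=2)
    r = np.where(r < 1e-12, 1.0, r)
    theta = np.arccos(np.clip(vec[:, :, 2] / r, -1.0, 1.0))
    phi = np.arctan2(vec[:, :, 1], vec[:, :, 0])
    m = np.arange(-3, 4)
    y = sph_harm_y(3, m[None, None, :], theta[..., None], phi[..., None])
    q3 = y.mean(axis=1)
    return q3, nbr, ok


def classify_waters(positions: np.ndarray, box: np.ndarray | None = None,
                    cutoffs: PhaseCutoffs = PhaseCutoffs()) -> WaterPhaseLabels:
    """Classify every water oxygen in one frame.

    ``positions`` are oxygen coordinates (N, 3); ``box`` enables periodic
    minimum-image neighbour searches (orthorhombic).  Fewer than four
    molecules in total → everything liquid, with a diagnostic.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 4:
        if n > 0:
            warnings.warn(f"only {n} molecules: all labeled LIQ")
        return WaterPhaseLabels(
            labels=np.full(n, "LIQ", dtype=object),
            n_staggered=np.zeros(n, dtype=int),
            n_eclipsed=np.zeros(n, dtype=int),
            neighbors=np.full((n, 4), -1, dtype=int),
            correlations=np.full((n, 4), np.nan),
            cutoffs=cutoffs,
        )
    q3, nbr, ok = _q3_all(positions, box, cutoffs.neighbor_cutoff)
    norms = np.linalg.norm(q3, axis=1)
    norms = np.where(norms < 1e-12, 1.0, norms)
    cij = np.real(np.sum(q3[:, None, :] * np.conj(q3[nbr]), axis=2))
    cij /= norms[:, None] * norms[nbr]

    stag = (cij <= cutoffs.staggered_max)
    ecl = (cij >= cutoffs.eclipsed_min) & (cij <= cutoffs.eclipsed_max)
    ns = stag.sum(axis=1)
    ne = ecl.sum(axis=1)

    labels = np.full(n, "LIQ", dtype=object)
    labels[ns >= 2] = "INT_ICE"
    labels[ne == 3] = "INT_CLATH"
    labels[ne == 4] = "CLATH"
    labels[(ns == 3) & (ne == 1)] = "HEX"
    labels[ns == 4] = "CUBIC"
    labels[~ok] = "LIQ"

    ns = np.where(ok, ns, 0)
    ne = np.where(ok, ne, 0)
    neighbors = np.where(ok[:, None], nbr, -1)
    correlations = np.where(ok[:, None], cij, np.nan)
    return WaterPhaseLabels(labels, ns, ne, neighbors, correlations, cutoffs)


def classify_frameset(frames, cutoffs: PhaseCutoffs = PhaseCutoffs()
                      ) -> list[WaterPhaseLabels]:
    """Classify the water oxygens of every frame of a FrameSet."""
    ow = frames.indices("OW")
    return [
        classify_waters(frames.coordinates[f][ow], frames.box, cutoffs)
        for f in range(frames.n_frames)
    ]


def clathrate_fraction(labels: WaterPhaseLabels, positions: np.ndarray,
                       around_points: np.ndarray, r: float,
                       box: np.ndarray | None = None) -> float:
    """Fraction of waters within ``r`` of any listed point that are
    clathrate-labeled (CLATH or INT_CLATH).  An empty shell is undefined and
    reported as NaN, not 0."""
    if r <= 0:
        raise ValueError("shell radius must be positive")
    positions = np.asarray(positions, dtype=float)
    around_points = np.atleast_2d(np.asarray(around_points, dtype=float))
    diff = positions[:, None, :] - around_points[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    in_shell = (np.linalg.norm(diff, axis=2) <= r).any(axis=1)
    if not in_shell.any():
        return float("nan")
    shell_labels = labels.labels[in_shell]
    return float(np.mean(np.isin(shell_labels, ["CLATH", "INT_CLATH"])))


def labels_to_csv(per_frame_labels: list[WaterPhaseLabels], path) -> None:
    """Write per-frame, per-molecule labels as tidy CSV."""
    pd.concat(
        [lab.to_frame(f) for f, lab in enumerate(per_frame_labels)],
        ignore_index=True,
    ).to_csv(path, index=False)


def summary_json(per_frame_labels: list[WaterPhaseLabels]) -> list[dict]:
    """Compact per-frame label counts."""
    return [{"frame": f, **lab.counts()} for f, lab in enumerate(per_frame_labels)]
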