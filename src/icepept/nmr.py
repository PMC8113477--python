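"""Cysteine redox classification from Cβ shifts and conformer-ensemble ranking.

The ¹³C Cβ shift of a cysteine is diagnostic of its redox state: disulfide-
bonded (oxidized) cysteines resonate downfield (≳ 38–42 ppm), free thiols
upfield (≲ 28–32 ppm).  When exactly two cysteines of a peptide classify as
oxidized, they are reported as the inferred disulfide pair.

Ensemble ranking mirrors chemical-shift-guided model selection: sort models
by energy, shortlist the k lowest, superpose all shortlist pairs, and pick
the representative that is best in the combined (energy rank + mean-RMSD
rank) sense, ties going to the lower energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geometry import rmsd as _rmsd


class NMRError(ValueError):
    pass


@dataclass
class ShiftTable:
    """Chemical-shift rows: (position, residue, atom, shift_ppm)."""

    frame: pd.DataFrame

    _COLUMNS = ("position", "residue", "atom", "shift_ppm")

    def __post_init__(self):
        missing = set(self._COLUMNS) - set(self.frame.columns)
        if missing:
            raise NMRError(f"shift table missing columns {sorted(missing)}")
        if not np.isfinite(self.frame["shift_ppm"].to_numpy(dtype=float)).all():
            raise NMRError("shifts must be finite")

    @classmethod
    def from_csv(cls, path) -> "ShiftTable":
        return cls(pd.read_csv(path, comment="#"))

    def cys_cbeta(self) -> pd.DataFrame:
        df = self.frame
        return df[(df["residue"] == "C") & (df["atom"] == "CB")]


def load_packaged_shift_table() -> ShiftTable:
    """The packaged Cβ fixture: four measured cysteine values plus flagged
    synthetic filler rows."""
    ref = resources.files("icepept.data").joinpath("cys_cbeta_shifts.csv")
    with resources.as_file(ref) as path:
        return ShiftTable.from_csv(path)


@dataclass(frozen=True)
class RedoxThresholds:
    """Cβ-shift cutoffs: < reduced_max → reduced, > oxidized_min → oxidized,
    in between → indeterminate."""

    reduced_max: float = 32.0
    oxidized_min: float = 35.0


@dataclass
class RedoxReport:
    states: dict[int, str]                  # position -> reduced|oxidized|indeterminate
    shifts: dict[int, float]
    inferred_pair: tuple[int, int] | None


def classify_shift(shift_ppm: float,
                   thresholds: RedoxThresholds = RedoxThresholds()) -> str:
    if shift_ppm < thresholds.reduced_max:
        return "reduced"
    if shift_ppm > thresholds.oxidized_min:
        return "oxidized"
    return "indeterminate"


def classify_cys_redox(shifts: ShiftTable,
                       thresholds: RedoxThresholds = RedoxThresholds()
                       ) -> RedoxReport:
    """Classify every cysteine Cβ shift and infer the disulfide pairing.

    If exactly two cysteines are oxidized they are reported as the inferred
    disulfide pair (a single bridge); otherwise no pairing is inferred.
    """
    cys = shifts.cys_cbeta()
    if cys.empty:
        raise NMRError("no cysteine Cβ rows in the shift table")
    states = {}
    vals = {}
    for _, row in cys.iterrows():
        pos = int(row["position"])
        states[pos] = classify_shift(float(row["shift_ppm"]), thresholds)
        vals[pos] = float(row["shift_ppm"])
    oxidized = sorted(p for p, s in states.items() if s == "oxidized")
    pair = tuple(oxidized) if len(oxidized) == 2 else None
    return RedoxReport(states, vals, pair)


# ---------------------------------------------------------------------------
# conformer ensembles


@dataclass
class ConformerEnsemble:
    """Conformer models with consistent atoms and per-model energies.

    ``atom_labels`` maps each atom row to (residue position, atom name);
    energies are relative, arbitrary units.
    """

    coordinates: np.ndarray                # (M, A, 3)
    atom_labels: list[tuple[int, str]]
    energies: np.ndarray                   # (M,)
    model_ids: list[int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.coordinates.ndim != 3:
            raise NMRError("coordinates must be (models, atoms, 3)")
        if len(self.energies) != self.coordinates.shape[0]:
            raise NMRError("one energy per model required")
        if len(self.atom_labels) != self.coordinates.shape[1]:
            raise NMRError("atom_labels length must match atom count")
        if self.model_ids is None:
            self.model_ids = list(range(len(self.energies)))

    @property
    def n_models(self) -> int:
        return self.coordinates.shape[0]

    def model(self, model_id: int) -> np.ndarray:
        return self.coordinates[self.model_ids.index(model_id)]

    def atom_index(self, position: int, atom: str) -> int:
        for i, (p, a) in enumerate(self.atom_labels):
            if p == position and a == atom:
                return i
        raise NMRError(f"atom {atom} of residue {position} not in ensemble")


@dataclass
class RankingReport:
    """Shortlist ranking: per-model energies, mean pairwise superposed RMSD,
    both component ranks, and the selected representative."""

    table: pd.DataFrame           # model_id, energy, mean_rmsd, ranks, rank_sum
    rmsd_matrix: np.ndarray       # (k, k) superposed RMSD among the shortlist
    representative: int           # model_id

    @property
    def shortlist(self) -> list[int]:
        return list(self.table["model_id"])


def rank_ensemble(ensemble: ConformerEnsemble, k: int = 10) -> RankingReport:
    """Shortlist the k lowest-energy models and pick a representative.

    All shortlist pairs are superposed (proper rotations only) and each
    model is scored by its mean RMSD to the other shortlisted models.  The
    representative minimizes energy rank + mean-RMSD rank; an exact rank-sum
    tie is broken by the lower energy.  The result is a deterministic
    function of (energies, coordinates), invariant to model input order.
    """
    if not 1 <= k <= ensemble.n_models:
        raise NMRError(f"k must be in 1..{ensemble.n_models}, got {k}")
    order = np.lexsort((ensemble.model_ids, ensemble.energies))
    short = order[:k]
    coords = ensemble.coordinates[short]
    energies = ensemble.energies[short]
    ids = [ensemble.model_ids[i] for i in short]

    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = _rmsd(coords[i], coords[j], superpose_first=True)
    mean_rmsd = mat.sum(axis=1) / max(k - 1, 1)

    e_rank = rankdata(energies, method="min")
    r_rank = rankdata(mean_rmsd, method="min")
    rank_sum = e_rank + r_rank
    best = min(range(k), key=lambda i: (rank_sum[i], energies[i], ids[i]))

    table = pd.DataFrame({
        "model_id": ids,
        "energy": energies,
        "mean_rmsd": mean_rmsd,
        "energy_rank": e_rank.astype(int),
        "rmsd_rank": r_rank.astype(int),
        "rank_sum": rank_sum.astype(int),
    })
    return RankingReport(table, mat, int(ids[best]))


def cbeta_distance(ensemble: ConformerEnsemble, model_id: int,
                   position_a: int, position_b: int) -> float:
    """Euclidean Cβ–Cβ distance between two residues in one model.

    Glycine has no Cβ: asking for one raises an error naming the residue.
    """
    for pos in (position_a, position_b):
        labels = [a for p, a in ensemble.atom_labels if p == pos]
        if "CB" not in labels:
            raise NMRError(f"residue {pos} has no Cβ atom (glycine or absent)")
    xyz = ensemble.model(model_id)
    a = xyz[ensemble.atom_index(position_a, "CB")]
    b = xyz[ensemble.atom_index(position_b, "CB")]
    return float(np.linalg.norm(a - b))


def pairwise_distance_range(ensemble: ConformerEnsemble, model_ids: list[int],
                            position_a: int, position_b: int
                            ) -> tuple[float, float]:
    """(min, max) Cβ–Cβ distance over the given models."""
    if not model_ids:
        raise NMRError("empty model list")
    d = [cbeta_distance(ensemble, m, position_a, position_b) for m in model_ids]
    return (float(min(d)), float(max(d)))
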