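"""Ice recrystallization inhibition (IRI) quantification from grain maps.

A splat-assay micrograph, after segmentation, is an integer label map of ice
grains.  Activity is expressed as the mean grain area (MGA) of a sample
relative to a buffer control: an active inhibitor keeps grains small, so
its MGA ratio falls below 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.segmentation import clear_border


class IRIError(ValueError):
    pass


@dataclass
class GrainStats:
    """Per-grain pixel areas of one label map."""

    areas: np.ndarray            # pixel counts per grain
    border_excluded: bool
    scale_um_per_px: float | None = None

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        if (self.areas <= 0).any():
            raise IRIError("grain areas must be positive")

    @property
    def n_grains(self) -> int:
        return len(self.areas)

    @property
    def mean_area(self) -> float:
        return float(self.areas.mean())

    @property
    def areas_um2(self) -> np.ndarray:
        if self.scale_um_per_px is None:
            raise IRIError("no µm/px scale configured")
        return self.areas * self.scale_um_per_px ** 2


def grain_areas(label_map: np.ndarray, exclude_border: bool = True,
                scale_um_per_px: float | None = None) -> GrainStats:
    """Per-grain pixel areas of an integer label map (background = 0).

    Grains touching the image border are partial and bias the mean area
    down, so they are dropped by default.
    """
    label_map = np.asarray(label_map)
    if label_map.size == 0:
        raise IRIError("empty label map")
    if not np.issubdtype(label_map.dtype, np.integer):
        raise IRIError("label map must be integer")
    work = clear_border(label_map) if exclude_border else label_map
    counts = np.bincount(work.ravel())
    areas = counts[1:][counts[1:] > 0]
    if len(areas) == 0:
        if exclude_border and label_map.max() > 0:
            raise IRIError("every grain touches the border; "
                           "nothing left after border exclusion")
        raise IRIError("label map contains no grains")
    return GrainStats(areas, exclude_border, scale_um_per_px)


def mga_ratio(sample: list[GrainStats], control: list[GrainStats]
              ) -> tuple[float, float]:
    """Mean-grain-area ratio of sample to control, with a propagated SD.

    The ratio is (mean of sample replicate MGAs) / (mean of control
    replicate MGAs).  The SD is the standard deviation of the per-replicate
    ratios — replicate-matched when counts agree, otherwise each sample
    replicate against the control mean.
    """
    if not sample or not control:
        raise IRIError("need at least one replicate on each side")
    s = np.array([g.mean_area for g in sample])
    c = np.array([g.mean_area for g in control])
    if c.mean() == 0:
        raise IRIError("control mean grain area is zero")
    ratio = float(s.mean() / c.mean())
    if len(s) == len(c):
        per_rep = s / c
    else:
        per_rep = s / c.mean()
    sd = float(per_rep.std(ddof=1)) if len(per_rep) > 1 else 0.0
    return ratio, sd


def dose_response(rows: pd.DataFrame, activity_threshold: float = 0.8,
                  headline_concentration: float = 1.0) -> pd.DataFrame:
    """Dose–response summary from (concentration, ratio, sd) rows.

    Returns the rows sorted by concentration with a per-concentration
    ``active`` flag, plus ``headline`` marking the reference concentration
    (the customary 1 mg/mL call).  Duplicate concentrations are an error.
    """
    required = {"concentration", "ratio"}
    if not required <= set(rows.columns):
        raise IRIError(f"dose_response needs columns {sorted(required)}")
    conc = rows["concentration"].to_numpy(dtype=float)
    if (conc <= 0).any():
        raise IRIError("concentrations must be positive")
    if len(np.unique(conc)) != len(conc):
        raise IRIError("duplicate concentrations")
    out = rows.sort_values("concentration").reset_index(drop=True).copy()
    out["active"] = out["ratio"] < activity_threshold
    out["headline"] = np.isclose(out["concentration"], headline_concentration)
    return out
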