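"""Phenotype classification and per-day invasion time-series metrics.

Cells around a spheroid fall into three migratory phenotypes:

* ``epithelial`` — still part of the compact spheroid periphery (touching the
  reference surface, rounded);
* ``escaping``  — attached to the periphery but elongated (low sphericity),
  mid-egress;
* ``amoeboid``  — detached, individually migrating, typically rounded.

The per-day population metrics are the ones a drug invasion assay tracks:
relative spheroid volume, cumulative escaped cells normalized to the imaged
hemispheroid surface area (cells/μm², the invasion measure), mean escaped-cell
sphericity, mean escaped-cell distance, and invasion speed (the day-to-day
change in mean escaped-cell distance; population level, no cell tracking).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .morphometry import SpheroidGeometry

__all__ = [
    "classify_phenotype",
    "classify_cells",
    "invasion_density",
    "build_timeseries",
    "DEFAULT_SPHERICITY_THRESHOLD",
]

#: Escaped cells in this assay keep sphericity ≈ 0.8–0.9; attached cells below
#: this are elongated and classified as escaping.
DEFAULT_SPHERICITY_THRESHOLD = 0.8


def classify_phenotype(sphericity: float, distance: float,
                       sphericity_threshold: float = DEFAULT_SPHERICITY_THRESHOLD) -> str:
    """Classify one cell from its sphericity Ψ and distance d to the reference.

    detached (d > 0) → amoeboid; attached and elongated (Ψ below threshold)
    → escaping; attached and compact → epithelial.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance > 0:
        return "amoeboid"
    if sphericity < sphericity_threshold:
        return "escaping"
    return "epithelial"


def classify_cells(metrics: pd.DataFrame,
                   sphericity_threshold: float = DEFAULT_SPHERICITY_THRESHOLD) -> pd.DataFrame:
    """Add a ``phenotype`` column to a per-cell metrics table."""
    out = metrics.copy()
    out["phenotype"] = [
        classify_phenotype(s, d, sphericity_threshold)
        for s, d in zip(out["sphericity"], out["distance"])
    ]
    return out


def invasion_density(escaped_count: int, SA: float) -> float:
    """Escaped cells per μm² of imaged hemispheroid surface."""
    if SA <= 0:
        raise ValueError("surface area must be positive")
    if escaped_count < 0:
        raise ValueError("escaped count must be non-negative")
    return escaped_count / SA


def build_timeseries(per_day_geometry: list[tuple[float, SpheroidGeometry]],
                     per_day_cells: list[tuple[float, pd.DataFrame]],
                     sphericity_threshold: float = DEFAULT_SPHERICITY_THRESHOLD,
                     ) -> pd.DataFrame:
    """Assemble the per-day invasion table from geometry and cell metrics.

    Parameters
    ----------
    per_day_geometry : list of (day, SpheroidGeometry), days sorted ascending.
    per_day_cells : list of (day, per-cell metrics DataFrame) with at least
        ``sphericity`` and ``distance`` columns; same days.

    "Escaped" for counting means detached cells only (d > 0); attached
    elongated cells are reported separately as ``escaping_count``.  The
    cumulative escaped count sums per-day new detections (no tracking), and
    invasion density is that cumulative count over the day's cap surface
    area.  Relative volume is against day 0; if day 0 is absent the column is
    NaN and a warning is raised.
    """
    days = [d for d, _ in per_day_geometry]
    if days != sorted(days):
        raise ValueError("days must be sorted ascending")
    if days != [d for d, _ in per_day_cells]:
        raise ValueError("geometry and cell tables must cover the same days")

    v0 = None
    for day, geom in per_day_geometry:
        if day == 0:
            v0 = geom.V
            break
    if v0 is None:
        warnings.warn("day 0 missing: relative volume is undefined (NaN)", stacklevel=2)

    rows = []
    cumulative = 0
    prev_day = prev_mean_distance = None
    for (day, geom), (_, cells) in zip(per_day_geometry, per_day_cells):
        detached = cells[cells["distance"] > 0]
        escaped = len(detached)
        escaping = int(((cells["distance"] == 0) & (cells["sphericity"] <
                        sphericity_threshold)).sum()) if len(cells) else 0
        cumulative += escaped
        mean_psi = float(detached["sphericity"].mean()) if escaped else np.nan
        mean_dist = float(detached["distance"].mean()) if escaped else np.nan
        if prev_day is not None and np.isfinite(mean_dist) and np.isfinite(prev_mean_distance):
            speed = (mean_dist - prev_mean_distance) / (day - prev_day)
        else:
            speed = np.nan
        rows.append(
            {
                "day": day,
                "V": geom.V,
                "relative_volume": geom.V / v0 if v0 else np.nan,
                "SA": geom.SA,
                "escaped_count": escaped,
                "escaping_count": escaping,
                "cumulative_escaped": cumulative,
                "invasion_density": invasion_density(cumulative, geom.SA),
                "mean_escaped_sphericity": mean_psi,
                "mean_escaped_distance": mean_dist,
                "invasion_speed": speed,
            }
        )
        prev_day, prev_mean_distance = day, mean_dist
    return pd.DataFrame(rows)
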