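"""Neuroanatomical tracing quantifications.

Two ratio metrics summarize circuit-tracing experiments:

- the rabies *convergence index*: monosynaptically labeled input cells in a
  region divided by the number of starter cells, normalized (multiplied) by
  the fraction of starter cells actually located in the target nucleus;
- anterograde *relative synaptic density*: per-ROI synaptophysin-GFP mean
  fluorescence (integrated density / area) referenced to a dark region of the
  same slice and normalized so the densities of all ROIs sum to one.

Both metrics are ratios, hence invariant to global rescaling of counts or
intensities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["convergence_index", "relative_synaptic_density"]


def convergence_index(
    inputs_per_region: dict[str, int] | pd.Series,
    starter_total: int,
    starter_fraction_in_target: float = 1.0,
) -> pd.DataFrame:
    """Starter-normalized rabies input convergence per region.

    ``CI = inputs / starter_total``; the normalized CI multiplies by the
    fraction of starter cells located in the target nucleus, so animals with
    off-target starter populations are downweighted.

    Returns a frame with columns ``inputs``, ``ci``, ``ci_normalized``.
    """
    if starter_total <= 0:
        raise ValueError("starter_total must be > 0")
    if not 0.0 <= starter_fraction_in_target <= 1.0:
        raise ValueError("starter fraction must be in [0, 1]")
    s = pd.Series(inputs_per_region, dtype=float)
    if (s < 0).any():
        raise ValueError("input counts must be non-negative")
    ci = s / starter_total
    return pd.DataFrame(
        {"inputs": s, "ci": ci, "ci_normalized": ci * starter_fraction_in_target}
    )


def relative_synaptic_density(
    rois: pd.DataFrame,
    dark_int_density: float,
    dark_area: float,
) -> pd.DataFrame:
    """Per-ROI relative synaptic density from fluorescence measurements.

    ``rois`` must have columns ``roi``, ``int_density`` (raw integrated
    density) and ``area`` (pixels).  Each ROI's normalized mean
    (``int_density / area``) is divided by the dark-region normalized mean of
    the same slice to give a density; relative densities divide by the summed
    density over ROIs and therefore sum to exactly 1.
    """
    required = {"roi", "int_density", "area"}
    if not required.issubset(rois.columns):
        raise ValueError(f"ROI table missing columns: {sorted(required - set(rois.columns))}")
    if len(rois) < 1:
        raise ValueError("need at least one ROI")
    if (rois["area"] <= 0).any() or dark_area <= 0:
        raise ValueError("areas must be positive")
    dark_mean = dark_int_density / dark_area
    if dark_mean == 0:
        raise ValueError("dark reference mean is zero")
    out = rois.copy()
    out["norm_mean"] = out["int_density"] / out["area"]
    out["density"] = out["norm_mean"] / dark_mean
    total = out["density"].sum()
    if total == 0:
        raise ValueError("all ROI densities are zero")
    out["relative_density"] = out["density"] / total
    return out


def aggregate_relative_density(per_animal: list[pd.DataFrame]) -> pd.Series:
    """Mean relative density per ROI across animals (replicate aggregation)."""
    stacked = pd.concat(per_animal)
    return stacked.groupby("roi")["relative_density"].mean()
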