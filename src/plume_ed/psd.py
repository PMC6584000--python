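"""Seabed particle-size compositions: classing, silt+clay change, ternary.

Surficial sediment samples are expressed as percentage mass in four size
classes: gravel (>2 mm), sand (2000-62.5 um), silt (62.5-4 um) and clay
(<4 um).  The distance-decay analysis uses the combined silt+clay
proportion and its enrichment relative to the pre-dredging baseline; the
ternary view pools silt+clay into one axis against gravel and sand.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SIZE_CLASS_EDGES_UM",
    "SIZE_CLASS_NAMES",
    "classify_fractions",
    "silt_clay_fraction",
    "enrichment_ratio",
    "ternary_coords",
]

#: class boundaries in micrometres, descending: gravel/sand, sand/silt, silt/clay
SIZE_CLASS_EDGES_UM = (2000.0, 62.5, 4.0)
SIZE_CLASS_NAMES = ("gravel", "sand", "silt", "clay")


def classify_fractions(
    masses: np.ndarray, bin_edges_um: np.ndarray
) -> dict[str, float]:
    """Reduce a binned mass distribution to 4-class percentages.

    ``bin_edges_um`` are ``len(masses) + 1`` strictly monotone grain-size
    edges in micrometres (ascending or descending).  Bins straddling a
    class boundary are split pro-rata on log grain size, matching the
    log-spaced binning of laser-diffraction output.  Returns percentages
    summing to 100.
    """
    m = np.asarray(masses, dtype=float)
    edges = np.asarray(bin_edges_um, dtype=float)
    if edges.size != m.size + 1:
        raise ValueError("need len(masses) + 1 bin edges")
    if np.any(m < 0):
        raise ValueError("masses must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    if np.any(edges <= 0):
        raise ValueError("grain-size edges must be positive")
    diffs = np.diff(edges)
    # zero-width (point-mass) bins are allowed; mixed directions are not
    if np.all(diffs <= 0) and np.any(diffs < 0):
        edges = edges[::-1]
        m = m[::-1]
    elif not np.all(diffs >= 0):
        raise ValueError("bin edges must be monotone")

    log_edges = np.log(edges)
    # class intervals ascending in size: clay, silt, sand, gravel
    cuts = np.log(np.array(SIZE_CLASS_EDGES_UM[::-1]))  # (4, 62.5, 2000)
    class_mass = np.zeros(4)  # clay, silt, sand, gravel
    for mass, lo, hi in zip(m, log_edges[:-1], log_edges[1:]):
        width = hi - lo
        bounds = np.concatenate(([lo], np.clip(cuts, lo, hi), [hi]))
        for k in range(4):
            frac = max(0.0, bounds[k + 1] - bounds[k]) / width if width > 0 else 0.0
            class_mass[k] += mass * frac
        if width == 0:  # point mass exactly on an edge -> to the class above
            k = int(np.searchsorted(cuts, lo, side="right"))
            class_mass[k] += mass
    percents = class_mass[::-1] / total * 100.0  # gravel, sand, silt, clay
    return dict(zip(SIZE_CLASS_NAMES, percents))


def _fractions_of(sample: pd.Series | dict) -> np.ndarray:
    fr = np.array([float(sample[k]) for k in SIZE_CLASS_NAMES])
    if np.any(fr < 0):
        raise ValueError("fractions must be non-negative")
    if abs(fr.sum() - 100.0) > 1e-6:
        raise ValueError(f"fractions sum to {fr.sum()}, expected 100")
    return fr


def silt_clay_fraction(sample: pd.Series | dict) -> float:
    """Combined silt+clay proportion of a sample, in [0, 1]."""
    fr = _fractions_of(sample)
    return float((fr[2] + fr[3]) / 100.0)


def enrichment_ratio(after_sample, before_sample) -> float:
    """Silt+clay proportion after dredging over the baseline proportion.

    Samples must come from the same site.  A zero baseline proportion
    leaves the ratio undefined (NaN).
    """
    if after_sample["site_id"] != before_sample["site_id"]:
        raise ValueError(
            "enrichment_ratio requires samples from the same site, got "
            f"{after_sample['site_id']!r} vs {before_sample['site_id']!r}"
        )
    before = silt_clay_fraction(before_sample)
    after = silt_clay_fraction(after_sample)
    if before == 0.0:
        return float("nan")
    return after / before


def ternary_coords(sample) -> tuple[float, float, float]:
    """(gravel, sand, silt+clay) proportions summing to 1."""
    fr = _fractions_of(sample)
    return (fr[0] / 100.0, fr[1] / 100.0, (fr[2] + fr[3]) / 100.0)
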