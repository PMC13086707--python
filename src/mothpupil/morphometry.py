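"""Eye-morphometry utilities and the packaged reference measurement table.

Two small geometric primitives support cross-checking eye measurements:
the interommatidial angle estimated by dividing 180 degrees by the number
of ommatidia counted along a half-meridian arc, and an algebraic (Kasa)
least-squares circle fit used to estimate eye radius from points on the
eye's outer edge.  A packaged CSV carries the per-species, per-sex CT-scan
and stereomicroscope measurements (ommatidia counts, angles, diameters,
radii and clear-zone thickness) used by the correlation cross-check.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .stats import pearson_correlation

__all__ = [
    "interommatidial_angle",
    "fit_circle",
    "load_morphometry_table",
    "stereo_ct_width_correlation",
]


def interommatidial_angle(n_along_arc: int) -> float:
    """180 degrees divided by the ommatidia count along a half-meridian arc."""
    if n_along_arc < 1:
        raise ValueError(f"ommatidia count must be >= 1, got {n_along_arc}")
    return 180.0 / n_along_arc


def fit_circle(points) -> tuple[tuple[float, float], float]:
    """Algebraic (Kasa) least-squares circle through 2-D points.

    Solves the linear system for (2cx, 2cy, r^2 - cx^2 - cy^2); exact on
    noiseless circular points, no initialisation required.  Returns
    ((cx, cy), radius).  Collinear points are rejected.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 3:
        raise ValueError(f"at least 3 points are required, got {len(pts)}")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    rhs = x**2 + y**2
    sol, residuals, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; no unique circle")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx**2 + cy**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit (nonpositive squared radius)")
    return (float(cx), float(cy)), float(np.sqrt(r2))


def load_morphometry_table() -> pd.DataFrame:
    """Packaged per-species/per-sex eye-morphometry measurements.

    Columns: species, sex, n_ommatidia, interommatidial_angle_deg,
    ommatidial_diameter_um, eye_radius_um, CT and stereo dorso-ventral /
    antero-posterior diameters (stereo values are means of 10 individuals,
    with SEMs), clear_zone_um.
    """
    with resources.files("mothpupil.data").joinpath("table1_morphometry.csv").open() as fh:
        return pd.read_csv(fh)


def stereo_ct_width_correlation() -> tuple[float, float]:
    """Pearson r and p between stereomicroscope and CT-scan eye widths.

    Pairs both diameter aspects (dorso-ventral and antero-posterior) across
    all species/sex rows of the packaged table — 12 paired values.
    """
    t = load_morphometry_table()
    ct = np.concatenate([t["ct_dv_diameter_um"], t["ct_ap_diameter_um"]])
    stereo = np.concatenate([t["stereo_dv_diameter_um"], t["stereo_ap_diameter_um"]])
    return pearson_correlation(stereo, ct)
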