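"""Per-location expression statistics and the mean-independent noise metric.

The trio table becomes a cells x locBC UMI count matrix. Cells with too few
integrations or UMIs and locations seen in too few cells are dropped; counts
are normalized by a per-cell factor (total UMIs / number of detected
locations) so that a cell's normalized entries sum exactly to its number of
detected locations. Per-location mean and sample variance are computed over
expressing cells only. Because variance is strongly coupled to the mean,
noise is summarized as the *mean-independent noise* (MIN): the residual of
an ordinary least squares fit of log2(variance) on log2(mean), fitted
separately within each experimental pool. By construction MIN is
uncorrelated with log2 mean within a pool.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm


def trios_to_matrix(trios: pd.DataFrame, cell_pools: pd.Series | None = None) -> pd.DataFrame:
    """Count UMIs per (cell, locBC): one trio row = one UMI."""
    if trios.empty:
        return pd.DataFrame(dtype=np.int64)
    mat = (
        trios.groupby(["cell_barcode", "loc_barcode"])
        .size()
        .unstack(fill_value=0)
        .astype(np.int64)
    )
    mat.index.name = "cell_barcode"
    mat.columns.name = "loc_barcode"
    if cell_pools is not None:
        mat = mat.loc[mat.index.intersection(cell_pools.index)]
    return mat


def apply_qc_filters(
    counts: pd.DataFrame,
    min_locs: int = 5,
    min_umis: int = 10,
    min_cells_per_loc: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """Drop low-quality cells and locations.

    Cells need at least ``min_locs`` detected locations and ``min_umis``
    total UMIs (removal is strictly "less than", so the boundary survives);
    locations need at least ``min_cells_per_loc`` expressing cells. Filter
    order: cells, then locations, then one cell re-check (location removal
    can push a cell below threshold; a single re-check is applied rather
    than iterating to a fixed point). The read-support (>=2 per UMI) filter
    belongs to the trio stage (see :func:`scnoise.parse.collapse_and_filter_trios`).
    """
    report = {
        "n_cells_in": int(counts.shape[0]),
        "n_locs_in": int(counts.shape[1]) if counts.shape[0] else 0,
    }
    out = counts

    def _cell_mask(m):
        return ((m > 0).sum(axis=1) >= min_locs) & (m.sum(axis=1) >= min_umis)

    out = out.loc[_cell_mask(out)]
    loc_keep = (out > 0).sum(axis=0) >= min_cells_per_loc
    out = out.loc[:, loc_keep]
    out = out.loc[_cell_mask(out)]  # single re-check after location removal
    report["n_cells_removed"] = report["n_cells_in"] - int(out.shape[0])
    report["n_locs_removed"] = report["n_locs_in"] - int(out.shape[1])
    report["n_cells_out"] = int(out.shape[0])
    report["n_locs_out"] = int(out.shape[1])
    if out.empty:
        warnings.warn("QC filters removed every cell", stacklevel=2)
    return out, report


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each entry by its cell's normalization factor.

    factor_j = (total UMIs in cell j) / (number of detected locations in
    cell j); normalized count = raw count / factor_j. Algebraic identity,
    asserted: the normalized entries of a cell sum to its number of
    detected locations.
    """
    n_locs = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    if (n_locs == 0).any():
        raise ValueError("cells with zero detected locations; apply QC filters first")
    factors = totals / n_locs
    norm = counts.div(factors, axis=0)
    assert np.allclose(norm.sum(axis=1), n_locs), "normalization identity violated"
    return norm


def location_statistics(
    norm: pd.DataFrame,
    cell_pools: pd.Series | None = None,
    min_expressing: int = 2,
) -> pd.DataFrame:
    """Mean/variance per location over its expressing cells.

    Statistics use only cells with a nonzero raw count for the location
    (normalized > 0 iff raw > 0). Variance is the sample variance (n-1
    denominator). Locations with fewer than ``min_expressing`` expressing
    cells have no defined variance and are excluded with a warning. CV^2 and
    Fano factor are attached as optional diagnostics only.

    ``cell_pools`` maps cells to experimental pool labels; statistics are
    computed within each pool (default: a single pool named "pool1").
    """
    if cell_pools is None:
        cell_pools = pd.Series("pool1", index=norm.index)
    rows = []
    skipped = 0
    for pool, cells in norm.groupby(cell_pools, sort=True).groups.items():
        sub = norm.loc[cells]
        for loc in sub.columns:
            vals = sub[loc].to_numpy()
            vals = vals[vals > 0]
            if len(vals) < min_expressing:
                skipped += 1
                continue
            mean = float(vals.mean())
            var = float(vals.var(ddof=1))
            rows.append(
                {
                    "loc_barcode": loc,
                    "pool": pool,
                    "n_cells": int(len(vals)),
                    "mean": mean,
                    "variance": var,
                    "log2_mean": float(np.log2(mean)),
                    "log2_variance": float(np.log2(var)) if var > 0 else -np.inf,
                    "cv2": var / mean**2,
                    "fano": var / mean,
                }
            )
    if skipped:
        warnings.warn(
            f"{skipped} (location, pool) groups had <{min_expressing} expressing "
            "cells and were excluded",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def mean_independent_noise(
    stats: pd.DataFrame, min_locations: int = 3
) -> tuple[pd.DataFrame, dict]:
    """Attach the MIN column: per-pool residual of log2 variance on log2 mean.

    An OLS line with intercept is fitted independently within each pool over
    locations with positive variance; MIN = observed log2 variance minus the
    fitted value. Zero-variance locations cannot enter the fit (log2
    undefined) and are flagged with ``zero_variance=True`` and MIN NaN.
    Raises for any pool with fewer than ``min_locations`` usable locations.
    Returns the augmented table and per-pool fit parameters.
    """
    out = stats.copy()
    out["zero_variance"] = ~np.isfinite(out["log2_variance"])
    out["min"] = np.nan
    fits: dict = {}
    for pool, idx in out.groupby("pool", sort=True).groups.items():
        sub = out.loc[idx]
        usable = sub.index[~sub["zero_variance"]]
        if len(usable) < min_locations:
            raise ValueError(
                f"pool {pool!r}: only {len(usable)} locations with positive "
                f"variance; need >= {min_locations} for the MIN fit"
            )
        X = sm.add_constant(out.loc[usable, "log2_mean"])
        fit = sm.OLS(out.loc[usable, "log2_variance"], X).fit()
        out.loc[usable, "min"] = fit.resid
        fits[pool] = {
            "intercept": float(fit.params.iloc[0]),
            "slope": float(fit.params.iloc[1]),
            "r_squared": float(fit.rsquared),
            "n": int(len(usable)),
        }
    return out, fits
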