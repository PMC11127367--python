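"""Intrinsic/extrinsic decomposition of reporter expression noise.

Reporters integrated at different locations of the same cell share that
cell's global state: extrinsic fluctuations move them together, intrinsic
fluctuations move them independently. Two complementary views:

* Per-cell coefficient of variation (CV) over a cell's reporters, compared
  with a null built by shuffling cell labels independently within each
  reporter column. Pure extrinsic noise drives the observed CVs to zero;
  pure intrinsic noise makes observed and shuffled distributions coincide.
* The dual-reporter moment estimators. For paired expression vectors C and
  Y over n cells::

      eta_ext = (sum(C_i * Y_i) - n * Cbar * Ybar) / (a * Cbar * Ybar)
          with a = (n - 1)(1 + 1/n) + 1/rho^2

      eta_int = (sum((C_i - Y_i)^2) - n * (Cbar - Ybar)^2) / (2a * Cbar * Ybar)
          with a = (2n^3 - 7n + 6) / (2(n^2 - n))
                   + ((2 - n) / (n^2 - n)) * rho / (1 - rho)
                   + (1 / (2(n^2 - n))) * (2 / (1 - rho))^2

  where rho is the sample correlation Cov[C,Y]/sqrt(Var[C] Var[Y]). Both
  estimators are normalized by Cbar*Ybar, hence dimensionless and invariant
  to rescaling both reporters, and symmetric in C and Y.

All moments use the sample (n-1) convention, matching the quantification
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clones import ClonePartition


class DegenerateEstimateError(ValueError):
    """A dual-reporter estimate is undefined; the message names the quantity."""


@dataclass
class NoiseEstimate:
    """Pairwise dual-reporter decomposition for one IR pair in one clone."""

    clone_id: str | None
    locbc_1: str | None
    locbc_2: str | None
    n: int
    rho: float
    eta_int: float
    eta_ext: float
    eta_int_clipped: float
    eta_ext_clipped: float
    mean_c: float
    mean_y: float


@dataclass
class CellCV:
    cell_id: str
    clone_id: str | None
    n_irs: int
    cv: float


def dual_reporter_noise(
    C, Y, clone_id: str | None = None, locbc_1: str | None = None, locbc_2: str | None = None
) -> NoiseEstimate:
    """Evaluate the dual-reporter estimators on one paired expression vector.

    Raises :class:`DegenerateEstimateError` when the estimate is undefined:
    rho equal to 0 or +/-1, zero variance in either reporter, or a
    nonpositive mean. Raw (possibly negative, finite-sample) estimates are
    returned together with zero-clipped copies.
    """
    C = np.asarray(C, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if C.shape != Y.shape or C.ndim != 1:
        raise ValueError("C and Y must be equal-length 1-D vectors")
    n = len(C)
    if n < 3:
        raise ValueError("need n >= 3 cells")
    cbar, ybar = C.mean(), Y.mean()
    if cbar <= 0 or ybar <= 0:
        raise DegenerateEstimateError("nonpositive mean expression (Cbar or Ybar)")
    var_c, var_y = C.var(ddof=1), Y.var(ddof=1)
    if var_c == 0 or var_y == 0:
        which = "C" if var_c == 0 else "Y"
        raise DegenerateEstimateError(f"zero variance in reporter {which}")
    cov = float(np.cov(C, Y, ddof=1)[0, 1])
    rho = cov / np.sqrt(var_c * var_y)
    if abs(rho) >= 1.0 - 1e-12:
        raise DegenerateEstimateError(f"rho = {rho:.3g} (perfectly correlated reporters)")
    if abs(rho) < 1e-12:
        raise DegenerateEstimateError("rho = 0 (denominator of the a factor)")

    a_ext = (n - 1) * (1 + 1 / n) + 1 / rho**2
    eta_ext = (float(np.sum(C * Y)) - n * cbar * ybar) / (a_ext * cbar * ybar)

    nn = n * n - n
    a_int = (
        (2 * n**3 - 7 * n + 6) / (2 * nn)
        + ((2 - n) / nn) * (rho / (1 - rho))
        + (1 / (2 * nn)) * (2 / (1 - rho)) ** 2
    )
    eta_int = (float(np.sum((C - Y) ** 2)) - n * (cbar - ybar) ** 2) / (
        2 * a_int * cbar * ybar
    )
    return NoiseEstimate(
        clone_id=clone_id,
        locbc_1=locbc_1,
        locbc_2=locbc_2,
        n=n,
        rho=float(rho),
        eta_int=float(eta_int),
        eta_ext=float(eta_ext),
        eta_int_clipped=float(max(eta_int, 0.0)),
        eta_ext_clipped=float(max(eta_ext, 0.0)),
        mean_c=float(cbar),
        mean_y=float(ybar),
    )


def per_cell_cv(
    norm: pd.DataFrame, clone_id: str | None = None, min_irs: int = 2
) -> pd.DataFrame:
    """CV (sample sd / mean) of each cell's observed normalized IR counts.

    Cells with fewer than ``min_irs`` observed reporters are skipped; so are
    cells whose observed mean is zero (CV undefined).
    """
    rows = []
    skipped_zero = 0
    for cell, row in zip(norm.index, norm.to_numpy()):
        vals = row[row > 0]
        if len(vals) < min_irs:
            continue
        m = vals.mean()
        if m == 0:
            skipped_zero += 1
            continue
        rows.append(
            {
                "cell_id": cell,
                "clone_id": clone_id,
                "n_irs": int(len(vals)),
                "cv": float(vals.std(ddof=1) / m),
            }
        )
    if skipped_zero:
        warnings.warn(f"{skipped_zero} cells with zero mean skipped", stacklevel=2)
    return pd.DataFrame(rows, columns=["cell_id", "clone_id", "n_irs", "cv"])


def shuffled_cv_null(
    norm: pd.DataFrame,
    n_shuffles: int = 50,
    seed: int = 0,
    clone_id: str | None = None,
) -> dict:
    """Null CV distribution from shuffling cell labels within each reporter.

    Each shuffle permutes every locBC column independently, destroying
    within-cell coupling while preserving each reporter's marginal
    distribution exactly; per-cell CVs are recomputed and pooled. Returns
    observed and null CVs plus medians and a two-sample KS comparison.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    observed = per_cell_cv(norm, clone_id=clone_id)
    arr = norm.to_numpy()
    null_cvs = []
    for _ in range(n_shuffles):
        shuffled = np.column_stack(
            [rng.permutation(arr[:, j]) for j in range(arr.shape[1])]
        )
        null = per_cell_cv(
            pd.DataFrame(shuffled, index=norm.index, columns=norm.columns)
        )
        null_cvs.append(null["cv"].to_numpy())
    null_cv = np.concatenate(null_cvs) if null_cvs else np.array([])
    obs_cv = observed["cv"].to_numpy()
    if len(obs_cv) and len(null_cv):
        ks = sps.ks_2samp(obs_cv, null_cv)
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat = ks_p = float("nan")
    return {
        "observed": observed,
        "observed_cv": obs_cv,
        "null_cv": null_cv,
        "observed_median": float(np.median(obs_cv)) if len(obs_cv) else float("nan"),
        "null_median": float(np.median(null_cv)) if len(null_cv) else float("nan"),
        "null_q05": float(np.percentile(null_cv, 5)) if len(null_cv) else float("nan"),
        "ks_stat": ks_stat,
        "ks_p": ks_p,
    }


def clone_noise_summary(
    norm: pd.DataFrame,
    partition: ClonePartition | pd.Series,
    clone_locs: dict[str, frozenset[str]] | None = None,
    min_cells: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Dual-reporter decomposition over every IR pair of every multi-IR clone.

    ``partition`` is a :class:`~scnoise.clones.ClonePartition` or a plain
    cell -> clone Series (then ``clone_locs`` gives each clone's locBC set).
    For each unordered pair, cells with both reporters observed (raw > 0)
    enter the estimators. The pooled intrinsic fraction is
    ``sum(eta_int) / sum(eta_int + eta_ext)`` over non-degenerate pairs,
    using the zero-clipped values so the fraction stays in [0, 1]; raw
    values are reported per pair.
    """
    if isinstance(partition, ClonePartition):
        assignments = partition.assignments
        clone_locs = {k: set(v) for k, v in partition.clones.items()}
    else:
        assignments = partition
        if clone_locs is None:
            raise ValueError("clone_locs required with a plain assignment Series")
    rows = []
    n_degenerate = 0
    multi = 0
    for cid in sorted(clone_locs):
        locs = sorted(set(clone_locs[cid]) & set(norm.columns))
        if len(locs) < 2:
            continue
        multi += 1
        cells = assignments.index[assignments == cid]
        cells = norm.index.intersection(cells)
        sub = norm.loc[cells, locs]
        for a, b in combinations(locs, 2):
            both = (sub[a] > 0) & (sub[b] > 0)
            if int(both.sum()) < min_cells:
                continue
            try:
                est = dual_reporter_noise(
                    sub.loc[both, a], sub.loc[both, b], cid, a, b
                )
            except DegenerateEstimateError:
                n_degenerate += 1
                continue
            rows.append(est.__dict__)
    if multi == 0:
        raise ValueError("no clone with >= 2 observed IR locations")
    pairs = pd.DataFrame(rows)
    summary: dict = {"n_pairs": len(pairs), "n_degenerate": n_degenerate}
    if len(pairs):
        tot_int = pairs["eta_int_clipped"].sum()
        tot_ext = pairs["eta_ext_clipped"].sum()
        summary["pooled_intrinsic_fraction"] = (
            float(tot_int / (tot_int + tot_ext)) if tot_int + tot_ext > 0 else float("nan")
        )
        per_clone = pairs.groupby("clone_id").apply(
            lambda g: g["eta_int_clipped"].sum()
            / max(g["eta_int_clipped"].sum() + g["eta_ext_clipped"].sum(), 1e-300),
            include_groups=False,
        )
        summary["per_clone_intrinsic_fraction"] = per_clone.to_dict()
    else:
        summary["pooled_intrinsic_fraction"] = float("nan")
        summary["per_clone_intrinsic_fraction"] = {}
    return pairs, summary
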