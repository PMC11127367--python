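"""Stratified and comparative analyses over cell substates and clones.

Covers four procedures downstream of the core quantification:

* per-stratum (substate or cell-cycle phase) recomputation of location
  mean and mean-independent noise, with minimum-cell filters;
* binomial comparison of phase composition between substates;
* permutation significance for differences of a per-location feature
  between high/low groups;
* classification of extreme (top vs bottom quantile) locations from a
  numeric feature table with leave-one-out cross-validated logistic
  regression;
* the transgene insertion-effect test: clone pseudobulk vs resampled
  control pseudobulk, Fisher's exact test, log2 fold change of the gene's
  pseudobulk proportion, with a shuffled-gene-label null mode.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .quant import location_statistics, mean_independent_noise


def stratified_location_stats(
    norm: pd.DataFrame,
    labels: pd.Series,
    min_cells: int = 15,
    refit_min_per_stratum: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Per-(location, stratum) mean/variance/MIN.

    ``labels`` maps cells to strata (e.g. phases, min_cells=15; or
    substates, min_cells=30). A location is kept only if it has at least
    ``min_cells`` expressing cells in *every* stratum. MIN is refit within
    each stratum by default; with ``refit_min_per_stratum=False`` a single
    fit over all (location, stratum) points is used and residuals are taken
    against that common line.
    """
    labels = labels.loc[labels.index.intersection(norm.index)]
    strata = sorted(labels.unique())
    if not strata:
        raise ValueError("no labeled cells overlap the matrix")
    expressing = {
        s: (norm.loc[labels.index[labels == s]] > 0).sum(axis=0) for s in strata
    }
    keep = norm.columns[
        np.all([expressing[s] >= min_cells for s in strata], axis=0)
    ]
    dropped = int(norm.shape[1] - len(keep))
    sub = norm.loc[labels.index, keep]
    stats = location_statistics(sub, cell_pools=labels)
    stats = stats.rename(columns={"pool": "stratum"})
    if refit_min_per_stratum:
        tmp = stats.rename(columns={"stratum": "pool"})
        tmp, fits = mean_independent_noise(tmp)
        stats = tmp.rename(columns={"pool": "stratum"})
    else:
        tmp = stats.rename(columns={"stratum": "pool"}).copy()
        tmp["pool"] = "all"
        tmp, fits = mean_independent_noise(tmp)
        stats["min"] = tmp["min"].to_numpy()
        stats["zero_variance"] = tmp["zero_variance"].to_numpy()
    fits["n_locations_dropped"] = dropped
    return stats, fits


def substate_proportion_test(labels: pd.DataFrame) -> pd.DataFrame:
    """Compare phase composition between the two substates.

    For each phase, the count of that phase in one substate is tested
    (two-sided binomial) against the other substate's phase fraction as the
    null proportion. ``labels`` needs columns ``substate`` and ``phase``.
    """
    substates = sorted(labels["substate"].unique())
    if len(substates) != 2:
        raise ValueError(f"need exactly 2 substates, got {substates}")
    a, b = substates
    na = int((labels["substate"] == a).sum())
    nb = int((labels["substate"] == b).sum())
    if na == 0 or nb == 0:
        raise ValueError("empty substate")
    rows = []
    for phase in sorted(labels["phase"].unique()):
        ka = int(((labels["substate"] == a) & (labels["phase"] == phase)).sum())
        kb = int(((labels["substate"] == b) & (labels["phase"] == phase)).sum())
        frac_a, frac_b = ka / na, kb / nb
        p0 = min(max(frac_b, 1e-300), 1 - 1e-300)
        pval = sps.binomtest(ka, na, p0, alternative="two-sided").pvalue
        rows.append(
            {
                "phase": phase,
                f"n_{a}": ka,
                f"frac_{a}": frac_a,
                f"n_{b}": kb,
                f"frac_{b}": frac_b,
                "proportion_difference": frac_a - frac_b,
                "pvalue": float(pval),
            }
        )
    return pd.DataFrame(rows)


def label_permutation_test(
    values, groups, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Permutation p-value for a difference of group means.

    ``groups`` is a two-level labeling aligned with ``values``. The
    statistic is mean(group 1) - mean(group 2); the p-value is
    ``(1 + #{|perm stat| >= |observed|}) / (n_perm + 1)``, which is a valid
    (conservative) permutation p-value.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    m1 = groups == levels[0]
    if m1.all() or not m1.any():
        raise ValueError("both groups must be non-empty")
    if np.ptp(values) == 0:
        warnings.warn("constant values; permutation p-value is 1", stacklevel=2)
        return 0.0, 1.0
    obs = values[m1].mean() - values[~m1].mean()
    rng = np.random.default_rng(seed)
    n1 = int(m1.sum())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        stat = perm[:n1].mean() - perm[n1:].mean()
        if abs(stat) >= abs(obs):
            hits += 1
    return float(obs), (1 + hits) / (n_perm + 1)


def classify_extreme_locations(
    features: pd.DataFrame,
    scores: pd.Series,
    quantile: float = 0.20,
    min_per_class: int = 10,
) -> dict:
    """Classify top- vs bottom-quantile locations from numeric features.

    Locations in the top ``quantile`` of ``scores`` (e.g. MIN, or mean) get
    label 1, the bottom quantile label 0; the rest are excluded. Features
    are standardized (zero mean, unit variance) so weights are comparable.
    An unpenalized logistic regression is evaluated by leave-one-out
    cross-validation; per-feature weights and Wald p-values come from a
    statsmodels fit on all retained locations. Perfect separation is
    reported with a flag instead of failing (p-values are then NaN).
    """
    scores = scores.loc[features.index]
    lo = scores.quantile(quantile)
    hi = scores.quantile(1 - quantile)
    sel = scores.index[(scores <= lo) | (scores >= hi)]
    y = (scores.loc[sel] >= hi).astype(int)
    if y.sum() < min_per_class or (len(y) - y.sum()) < min_per_class:
        raise ValueError(f"need >= {min_per_class} locations per class")
    X = features.loc[sel].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd
    yv = y.to_numpy()

    correct = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(len(yv)):
            mask = np.ones(len(yv), dtype=bool)
            mask[i] = False
            clf = LogisticRegression(penalty=None, max_iter=500)
            clf.fit(X[mask], yv[mask])
            correct += int(clf.predict(X[i : i + 1])[0] == yv[i])
        accuracy = correct / len(yv)

        perfect = False
        pvalues = np.full(X.shape[1], np.nan)
        try:
            fit = sm.Logit(yv, sm.add_constant(X)).fit(disp=0, maxiter=200)
            coefs = fit.params[1:]
            pvalues = fit.pvalues[1:]
            if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(coefs) > 50):
                perfect = True
        except Exception:
            perfect = True
            clf = LogisticRegression(penalty=None, max_iter=500)
            clf.fit(X, yv)
            coefs = clf.coef_[0]
    weights = pd.DataFrame(
        {
            "feature": list(features.columns),
            "weight": np.asarray(coefs, dtype=float),
            "pvalue": np.asarray(pvalues, dtype=float),
        }
    )
    weights["significant"] = weights["pvalue"] < 0.05
    return {
        "loocv_accuracy": float(accuracy),
        "weights": weights,
        "n_per_class": (int(len(yv) - yv.sum()), int(yv.sum())),
        "labels": y,
        "perfect_separation": perfect,
    }


def fisher_pseudobulk_test(
    gene_ins: int, rest_ins: int, gene_ctrl: int, rest_ctrl: int
) -> tuple[float, float]:
    """Fisher's exact test and log2FC on a pseudobulk 2x2 table.

    Table: rows (focal gene, all other genes), columns (insertion clone,
    control sample). The log2 fold change compares the gene's share of each
    pseudobulk; zero counts get a 0.5 continuity guard.
    """
    _, p = sps.fisher_exact(
        [[gene_ins, gene_ctrl], [rest_ins, rest_ctrl]], alternative="two-sided"
    )
    tot_ins = gene_ins + rest_ins
    tot_ctrl = gene_ctrl + rest_ctrl
    if tot_ins == 0 or tot_ctrl == 0:
        raise ValueError("zero pseudobulk total")
    g_i = gene_ins if gene_ins > 0 else 0.5
    g_c = gene_ctrl if gene_ctrl > 0 else 0.5
    log2fc = float(np.log2((g_i / tot_ins) / (g_c / tot_ctrl)))
    return log2fc, float(p)


def insertion_effect_test(
    genes: pd.DataFrame,
    cell_clones: pd.Series,
    clone_id: str,
    gene_id: str,
    n_resample: int = 25,
    seed: int = 0,
    fc_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
) -> dict:
    """Does a transgene insertion in ``clone_id`` alter ``gene_id``?

    Pseudobulk (summed counts over cells) of the insertion clone is compared
    with the pseudobulk of an equal-size random cell sample from all other
    clones by Fisher's exact test on the (gene, all other genes) x
    (insertion, control) table. The control draw is repeated ``n_resample``
    times (median p and log2FC reported) to stabilize the single-draw
    design; ``n_resample=1`` gives the single-draw variant. A call is
    significant when p < ``p_cutoff`` and |log2FC| > ``fc_cutoff``.
    """
    if gene_id not in genes.index:
        raise KeyError(f"gene {gene_id!r} absent from the count matrix")
    cells = genes.columns.intersection(cell_clones.index)
    clones = cell_clones.loc[cells]
    ins_cells = cells[clones == clone_id]
    other_cells = cells[clones != clone_id]
    if len(ins_cells) == 0:
        raise ValueError(f"clone {clone_id!r} has no cells")
    if len(other_cells) < len(ins_cells):
        raise ValueError("other clones have fewer cells than the insertion clone")
    ins_pb = genes[ins_cells].sum(axis=1)
    gene_ins = int(ins_pb[gene_id])
    rest_ins = int(ins_pb.sum()) - gene_ins
    rng = np.random.default_rng(seed)
    fcs, ps = [], []
    for _ in range(n_resample):
        ctrl = rng.choice(other_cells.to_numpy(), size=len(ins_cells), replace=False)
        ctrl_pb = genes[list(ctrl)].sum(axis=1)
        gene_ctrl = int(ctrl_pb[gene_id])
        rest_ctrl = int(ctrl_pb.sum()) - gene_ctrl
        fc, p = fisher_pseudobulk_test(gene_ins, rest_ins, gene_ctrl, rest_ctrl)
        fcs.append(fc)
        ps.append(p)
    log2fc = float(np.median(fcs))
    pvalue = float(np.median(ps))
    return {
        "clone_id": clone_id,
        "gene_id": gene_id,
        "n_cells": int(len(ins_cells)),
        "log2fc": log2fc,
        "pvalue": pvalue,
        "significant": bool(pvalue < p_cutoff and abs(log2fc) > fc_cutoff),
        "log2fc_draws": fcs,
        "pvalue_draws": ps,
    }


def insertion_effect_screen(
    genes: pd.DataFrame,
    cell_clones: pd.Series,
    insertions: list[tuple[str, str]],
    shuffle_gene_labels: bool = False,
    n_resample: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the insertion test over many (clone, gene) pairs.

    With ``shuffle_gene_labels=True`` the gene identities of the matrix are
    randomly permuted before testing, so each insertion is evaluated at a
    random gene: the background null of the screen. An intact assignment
    should flag real insertion effects; the shuffled screen should flag
    nothing.
    """
    rng = np.random.default_rng(seed)
    mat = genes
    relabel = {g: g for g in genes.index}
    if shuffle_gene_labels:
        perm = rng.permutation(genes.index.to_numpy())
        relabel = dict(zip(genes.index, perm))
        mat = genes.rename(index=relabel)
    rows = []
    for i, (clone_id, gene_id) in enumerate(insertions):
        res = insertion_effect_test(
            mat,
            cell_clones,
            clone_id,
            gene_id,
            n_resample=n_resample,
            seed=int(rng.integers(2**31)),
        )
        rows.append(
            {
                "clone_id": clone_id,
                "gene_id": gene_id,
                "tested_gene": gene_id,
                "log2fc": res["log2fc"],
                "pvalue": res["pvalue"],
                "significant": res["significant"],
            }
        )
    return pd.DataFrame(rows)
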