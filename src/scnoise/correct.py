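"""Barcode error correction for trio tables.

Two correction stages, matching the two barcode classes:

* Cell barcodes are corrected against a known whitelist: observed
  whitelisted barcodes are ranked by total read abundance, and each
  non-whitelisted barcode is reassigned to the first (most abundant)
  whitelisted barcode within a Hamming radius (default 2). Unmatched
  barcodes are dropped.
* Location barcodes are random 16-mers with no whitelist, so correction is
  greedy by abundance: the most abundant remaining locBC absorbs every
  remaining locBC within a Hamming radius (default 4); the processed group
  is removed and the loop repeats.

Both stages re-collapse the trio table after reassignment. Abundance ties
are broken lexicographically so the output is deterministic.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .parse import collapse_and_filter_trios


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length barcodes."""
    if len(a) != len(b):
        raise ValueError(f"unequal barcode lengths: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _encode(barcodes: Sequence[str]) -> np.ndarray:
    """Pack equal-length barcodes into a (n, L) uint8 matrix."""
    return np.frombuffer("".join(barcodes).encode(), dtype=np.uint8).reshape(
        len(barcodes), -1
    )


def read_whitelist(path) -> set[str]:
    """Read a plain-text whitelist, one barcode per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def _ranked_abundance(reads_by_bc: pd.Series) -> list[str]:
    # descending reads, lexicographic tie-break
    df = reads_by_bc.rename("reads").rename_axis("bc").reset_index()
    df = df.sort_values(["reads", "bc"], ascending=[False, True])
    return df["bc"].tolist()


def correct_cell_barcodes(
    trios: pd.DataFrame, whitelist: Iterable[str], max_dist: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Rank-scan cell-barcode correction against a whitelist.

    Whitelisted barcodes observed in the table are ranked by total read
    abundance; every non-whitelisted barcode is compared down that list and
    reassigned to the first entry within ``max_dist``. Barcodes matching no
    entry are dropped (their reads are accounted in the report).
    """
    whitelist = set(whitelist)
    if not whitelist:
        raise ValueError("whitelist is empty")
    if trios.empty:
        return trios.copy(), {
            "stage": "cell_barcode",
            "n_corrected": 0,
            "n_dropped": 0,
            "reads_recovered_fraction": 0.0,
        }
    reads_by_bc = trios.groupby("cell_barcode")["reads"].sum()
    observed_wl = [bc for bc in reads_by_bc.index if bc in whitelist]
    others = [bc for bc in reads_by_bc.index if bc not in whitelist]

    mapping: dict[str, str] = {bc: bc for bc in observed_wl}
    dropped: set[str] = set()
    if others and observed_wl:
        ranked = _ranked_abundance(reads_by_bc[observed_wl])
        length = len(ranked[0])
        valid = [bc for bc in others if len(bc) == length]
        dropped.update(bc for bc in others if len(bc) != length)
        if valid:
            enc_other = _encode(valid)
            # distance of every non-whitelisted barcode to every ranked entry
            dists = np.empty((len(valid), len(ranked)), dtype=np.int16)
            for r, wbc in enumerate(ranked):
                dists[:, r] = (enc_other != _encode([wbc])).sum(axis=1)
            within = dists <= max_dist
            has_match = within.any(axis=1)
            first = within.argmax(axis=1)  # first rank within radius
            for bc, ok, r in zip(valid, has_match, first):
                if ok:
                    mapping[bc] = ranked[r]
                else:
                    dropped.add(bc)
    else:
        dropped.update(others)

    kept = trios[~trios["cell_barcode"].isin(dropped)].copy()
    kept["cell_barcode"] = kept["cell_barcode"].map(mapping)
    corrected, _ = collapse_and_filter_trios(kept, min_reads=1)
    reads_total = int(trios["reads"].sum())
    reads_dropped = reads_total - int(corrected["reads"].sum())
    n_corrected = sum(1 for k, v in mapping.items() if k != v)
    reads_corrected = int(
        trios.loc[
            trios["cell_barcode"].map(lambda b: mapping.get(b, b) != b), "reads"
        ].sum()
    )
    report = {
        "stage": "cell_barcode",
        "n_corrected": n_corrected,
        "n_dropped": len(dropped),
        "reads_dropped": reads_dropped,
        "reads_recovered_fraction": reads_corrected / reads_total if reads_total else 0.0,
    }
    return corrected, report


def greedy_absorb(
    reads_by_bc: pd.Series, max_dist: int = 4
) -> dict[str, str]:
    """Greedy abundance-ranked absorption; returns barcode -> representative.

    Starting from the most abundant remaining barcode, every remaining
    barcode within ``max_dist`` is corrected to it; the group is removed and
    the loop repeats until no barcodes remain.
    """
    ranked = _ranked_abundance(reads_by_bc)
    if not ranked:
        return {}
    enc = _encode(ranked)
    alive = np.ones(len(ranked), dtype=bool)
    mapping: dict[str, str] = {}
    for i in range(len(ranked)):
        if not alive[i]:
            continue
        alive[i] = False
        mapping[ranked[i]] = ranked[i]
        idx = np.flatnonzero(alive)
        if idx.size:
            d = (enc[idx] != enc[i]).sum(axis=1)
            hit = idx[d <= max_dist]
            for j in hit:
                mapping[ranked[j]] = ranked[i]
            alive[hit] = False
    return mapping


def correct_location_barcodes(
    trios: pd.DataFrame, max_dist: int = 4
) -> tuple[pd.DataFrame, dict]:
    """Greedy abundance-ranked locBC correction (no whitelist exists)."""
    if trios.empty:
        return trios.copy(), {
            "stage": "loc_barcode",
            "n_corrected": 0,
            "n_dropped": 0,
            "reads_recovered_fraction": 0.0,
        }
    reads_by_bc = trios.groupby("loc_barcode")["reads"].sum()
    mapping = greedy_absorb(reads_by_bc, max_dist=max_dist)
    out = trios.copy()
    out["loc_barcode"] = out["loc_barcode"].map(mapping)
    corrected, _ = collapse_and_filter_trios(out, min_reads=1)
    n_corrected = sum(1 for k, v in mapping.items() if k != v)
    reads_total = int(trios["reads"].sum())
    reads_corrected = int(
        trios.loc[trios["loc_barcode"].map(lambda b: mapping[b] != b), "reads"].sum()
    )
    report = {
        "stage": "loc_barcode",
        "n_corrected": n_corrected,
        "n_dropped": 0,
        "reads_recovered_fraction": reads_corrected / reads_total if reads_total else 0.0,
    }
    return corrected, report


def pairwise_distance_histogram(
    barcodes: Sequence[str], sample_pairs: int = 100_000, seed: int = 0
) -> pd.Series:
    """Empirical Hamming-distance distribution over unordered barcode pairs.

    All pairs are enumerated when their number does not exceed
    ``sample_pairs``; otherwise that many random pairs are sampled. Returns
    counts indexed by distance.
    """
    n = len(barcodes)
    if n < 2:
        raise ValueError("need at least 2 barcodes")
    enc = _encode(list(barcodes))
    total = n * (n - 1) // 2
    if total <= sample_pairs:
        d = (pdist(enc, metric="hamming") * enc.shape[1]).round().astype(int)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=sample_pairs)
        j = rng.integers(0, n - 1, size=sample_pairs)
        j = np.where(j >= i, j + 1, j)  # j != i, uniform over ordered pairs
        d = (enc[i] != enc[j]).sum(axis=1)
    return pd.Series(d).value_counts().sort_index().rename("n_pairs")
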