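"""Turn paired reporter-capture reads into a counted trio table.

A *trio* is a (cell barcode, UMI, location barcode) triple: one captured
reporter transcript molecule in one cell. Read1 carries the 16-bp cell
barcode and 12-bp UMI in its first 28 positions; Read2 carries a constant
stretch of the reporter followed by the 16-bp locBC. The constant is located
by best Levenshtein match (cutoff 2 by default) so the locBC position is
robust to sequencing errors, and identical trios are collapsed with their
supporting read count.
"""

from __future__ import annotations

import gzip
from typing import Iterator, Sequence

import edlib
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synth import DEFAULT_CONSTANTS

TRIO_COLUMNS = ["cell_barcode", "umi", "loc_barcode"]


def locate_constant(
    read2: str, constant: str, max_dist: int = 2
) -> tuple[int, int, int] | None:
    """Best (lowest-distance) Levenshtein match of ``constant`` inside ``read2``.

    Returns ``(start, end, distance)`` with ``end`` exclusive, or None when
    the best match exceeds ``max_dist`` (or the read is empty). Ties on
    distance are broken by the leftmost start, for determinism.
    """
    if not read2 or not constant:
        return None
    res = edlib.align(constant, read2, mode="HW", task="locations", k=max_dist)
    if res["editDistance"] < 0:
        return None
    start, end = min(res["locations"], key=lambda t: (t[0] or 0, t[1]))
    return (start or 0), end + 1, res["editDistance"]


def parse_read_pair(
    read1: str,
    read2: str,
    constants: Sequence[str] = DEFAULT_CONSTANTS,
    locbc_len: int = 16,
    max_dist: int = 2,
) -> tuple[tuple[str, str, str] | None, str]:
    """Extract (cell_barcode, umi, loc_barcode) from one read pair.

    Either version of the constant is accepted; the lowest-distance match
    wins. Returns ``(trio, "ok")`` or ``(None, reason)`` with reason one of
    ``no_constant``, ``read_too_short``, ``n_in_barcode``. Rejections are
    data, not errors: callers tally them into a QC report.
    """
    read1 = read1.upper()
    read2 = read2.upper()
    if len(read1) < 28:
        return None, "read_too_short"
    best = None
    for const in constants:
        hit = locate_constant(read2, const, max_dist)
        if hit is not None and (best is None or hit[2] < best[2]):
            best = hit
    if best is None:
        return None, "no_constant"
    _, end, _ = best
    if end + locbc_len > len(read2):
        return None, "read_too_short"
    cell_bc = read1[:16]
    umi = read1[16:28]
    loc_bc = read2[end : end + locbc_len]
    if "N" in cell_bc or "N" in umi or "N" in loc_bc:
        return None, "n_in_barcode"
    return (cell_bc, umi, loc_bc), "ok"


def _open(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(r1_path, r2_path) -> Iterator[tuple[str, str]]:
    """Yield (read1, read2) sequence pairs from two FASTQ files (gzip ok)."""
    with _open(r1_path) as f1, _open(r2_path) as f2:
        for (_, s1, _), (_, s2, _) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            yield s1, s2


def parse_fastq(
    r1_path,
    r2_path,
    constants: Sequence[str] = DEFAULT_CONSTANTS,
    locbc_len: int = 16,
    max_dist: int = 2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Parse paired FASTQ into one row per accepted read, plus QC counts.

    The returned frame has columns cell_barcode, umi, loc_barcode (one row
    per read; feed it to :func:`collapse_and_filter_trios`). The QC series
    counts accepted reads and every rejection reason.
    """
    rows = []
    qc = {"accepted": 0, "no_constant": 0, "read_too_short": 0, "n_in_barcode": 0}
    for s1, s2 in iter_read_pairs(r1_path, r2_path):
        trio, reason = parse_read_pair(s1, s2, constants, locbc_len, max_dist)
        if trio is None:
            qc[reason] += 1
        else:
            qc["accepted"] += 1
            rows.append(trio)
    return pd.DataFrame(rows, columns=TRIO_COLUMNS), pd.Series(qc, name="reads")


def collapse_and_filter_trios(
    trios: pd.DataFrame, min_reads: int = 2
) -> tuple[pd.DataFrame, dict]:
    """Merge identical trios (summing read support) and drop weak ones.

    ``trios`` is either one-row-per-read output of :func:`parse_fastq` or an
    already-collapsed table with a ``reads`` column. Trios supported by fewer
    than ``min_reads`` reads (default 2: singletons are enriched for PCR
    artifacts) are removed. The QC dict reports trio counts and the mean read
    depth per trio before and after filtering.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if trios.empty:
        empty = pd.DataFrame(columns=TRIO_COLUMNS + ["reads"])
        return empty, {
            "n_trios_raw": 0,
            "n_trios_kept": 0,
            "mean_depth_raw": float("nan"),
            "mean_depth_kept": float("nan"),
            "reads_total": 0,
        }
    if "reads" in trios.columns:
        grouped = trios.groupby(TRIO_COLUMNS, sort=True)["reads"].sum()
    else:
        grouped = trios.groupby(TRIO_COLUMNS, sort=True).size().rename("reads")
    collapsed = grouped.reset_index()
    kept = collapsed[collapsed["reads"] >= min_reads].reset_index(drop=True)
    qc = {
        "n_trios_raw": int(len(collapsed)),
        "n_trios_kept": int(len(kept)),
        "mean_depth_raw": float(collapsed["reads"].mean()),
        "mean_depth_kept": float(kept["reads"].mean()) if len(kept) else float("nan"),
        "reads_total": int(collapsed["reads"].sum()),
    }
    return kept, qc


def write_trios(trios: pd.DataFrame, path) -> None:
    trios.to_csv(path, sep="\t", index=False)


def read_trios(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={c: str for c in TRIO_COLUMNS})
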