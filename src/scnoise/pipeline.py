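"""End-to-end driver: paired FASTQ -> corrected trios -> location statistics.

Stage order: parse reads, collapse to raw trios, correct cell barcodes
against the whitelist, correct location barcodes greedily, re-collapse,
apply the UMI read-support threshold (>= 2 supporting reads), build the
cell x locBC matrix, QC-filter, normalize, and compute per-location
mean/variance and MIN. Correction runs before the read-support threshold so
that reads whose only defect is a correctable barcode substitution are
rescued rather than discarded as singletons; the threshold then suppresses
PCR artifacts on the corrected table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import correct, parse, quant
from .synth import DEFAULT_CONSTANTS


@dataclass
class PipelineResult:
    raw_trios: pd.DataFrame  # collapsed, uncorrected, unfiltered
    corrected_trios: pd.DataFrame  # corrected, before the read-support filter
    trios: pd.DataFrame  # corrected and read-filtered
    counts: pd.DataFrame  # QC-filtered cell x locBC UMI matrix
    norm: pd.DataFrame
    stats: pd.DataFrame  # per-location statistics incl. MIN when fitted
    qc: dict = field(default_factory=dict)


def run_pipeline(
    r1_path,
    r2_path,
    whitelist,
    constants: Sequence[str] = DEFAULT_CONSTANTS,
    min_reads: int = 2,
    cell_max_dist: int = 2,
    loc_max_dist: int = 4,
    min_locs: int = 5,
    min_umis: int = 10,
    min_cells_per_loc: int = 5,
    fit_min: bool = True,
) -> PipelineResult:
    """Run the full pipeline on one pool of paired FASTQ files.

    ``whitelist`` is a path or an iterable of barcodes. When the filtered
    matrix has enough locations, MIN is fitted; otherwise the stats table is
    returned without it (qc notes why).
    """
    if isinstance(whitelist, (str, bytes)) or hasattr(whitelist, "__fspath__"):
        whitelist = correct.read_whitelist(whitelist)
    reads_df, parse_qc = parse.parse_fastq(r1_path, r2_path, constants)
    raw, raw_qc = parse.collapse_and_filter_trios(reads_df, min_reads=1)
    cb_trios, cb_report = correct.correct_cell_barcodes(raw, whitelist, cell_max_dist)
    corrected, loc_report = correct.correct_location_barcodes(cb_trios, loc_max_dist)
    trios, trio_qc = parse.collapse_and_filter_trios(corrected, min_reads=min_reads)
    counts = quant.trios_to_matrix(trios)
    counts, qc_report = quant.apply_qc_filters(
        counts, min_locs=min_locs, min_umis=min_umis, min_cells_per_loc=min_cells_per_loc
    )
    qc = {
        "parse": parse_qc.to_dict(),
        "collapse_raw": raw_qc,
        "cell_correction": cb_report,
        "loc_correction": loc_report,
        "trio_filter": trio_qc,
        "matrix_qc": qc_report,
    }
    if counts.empty:
        return PipelineResult(raw, corrected, trios, counts, counts.astype(float), pd.DataFrame(), qc)
    norm = quant.normalize_counts(counts)
    stats = quant.location_statistics(norm)
    if fit_min:
        usable = int((stats["variance"] > 0).sum()) if len(stats) else 0
        if usable >= 3:
            stats, fits = quant.mean_independent_noise(stats)
            qc["min_fits"] = fits
        else:
            qc["min_fits"] = "skipped: fewer than 3 locations with positive variance"
    return PipelineResult(raw, corrected, trios, counts, norm, stats, qc)
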