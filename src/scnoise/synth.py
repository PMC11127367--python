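"""Ground-truthed synthetic reporter-capture data.

This module simulates the data-generating process of a pooled reporter-gene
noise assay: clonal cell populations carrying fixed sets of genomically
integrated reporters (each tagged by a 16-bp location barcode, locBC),
captured by droplet scRNA-seq with 16-bp cell barcodes and 12-bp UMIs.

Generative model for the latent UMI count of location ``k`` in cell ``j``::

    X_jk ~ Poisson(s_j * E_j * I_jk * mu_k)

where ``mu_k`` is the base expression level of the location (log-normal
across locations), ``E_j`` is a unit-mean log-normal extrinsic factor shared
by every reporter in cell ``j`` (scale ``sigma_ext``), ``I_jk`` is a
unit-mean log-normal intrinsic fluctuation drawn independently per
(cell, location) (scale ``sigma_int``), and ``s_j`` is a unit-mean
log-normal per-cell capture efficiency (scale ``capture_scale``).

Unit-mean log-normal with scale ``sigma`` means ``exp(N(-sigma^2/2, sigma))``,
so the closed-form dual-reporter limits hold: for an equal-mean reporter
pair, ``eta_ext -> exp(sigma_ext^2) - 1`` and
``eta_int -> 1/mu + exp(sigma_ext^2 + sigma_int^2) - exp(sigma_ext^2)``.

Observation layers on top of the latent counts: dropout (each observed entry
zeroed independently), PCR read duplication (each UMI emits ``1 + Poisson``
read pairs), and per-base substitution errors in the barcode segments.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])

#: Two versions of the reporter constant sequence preceding the locBC in R2
#: (transcripts are captured either via poly(A) or via the bead capture
#: sequence, which places a slightly different constant in the read).
DEFAULT_CONSTANTS = (
    "TCTAGAGGGCCCGTTTAAACCCGCTGATCAG",
    "TCTAGAGGGCCCGTTTAAACGGCGCGCCTAG",
)

#: Fixed filler appended to R1 after the 28 informative bases; never parsed.
R1_FILLER = "ACTGACTGACTGACTG"

CELL_BC_LEN = 16
UMI_LEN = 12
LOC_BC_LEN = 16


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults describe one pooled experiment: ~100 clones carrying on average
    five integrations each, per-location base expression log-normal around 50
    UMIs, moderate extrinsic/intrinsic fluctuation, droplet-typical dropout,
    and PCR duplication giving a mean trio read depth around 9.5.
    """

    n_clones: int = 100
    #: (offset, poisson_rate): integrations per clone = offset + Poisson(rate)
    integrations_per_clone: tuple[int, float] = (1, 4.0)
    #: int, or (offset, poisson_rate) for a per-clone draw
    cells_per_clone: int | tuple[int, float] = 40
    #: (meanlog, sdlog) of the per-location base expression mu_k
    mu_loc: tuple[float, float] = (float(np.log(50.0)), 1.0)
    sigma_ext: float = 0.45
    sigma_int: float = 0.45
    capture_scale: float = 0.35
    dropout_rate: float = 0.3
    barcode_error_rate: float = 0.005
    pcr_dup_mean: float = 8.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be positive")
        off, rate = self.integrations_per_clone
        if off < 0 or rate < 0:
            raise ValueError("integrations_per_clone offset/rate must be >= 0")
        if off == 0 and rate == 0:
            raise ValueError("integrations_per_clone would always be zero")
        if isinstance(self.cells_per_clone, tuple):
            coff, crate = self.cells_per_clone
            if coff < 0 or crate < 0:
                raise ValueError("cells_per_clone offset/rate must be >= 0")
        elif self.cells_per_clone < 1:
            raise ValueError("cells_per_clone must be positive")
        for name in ("sigma_ext", "sigma_int", "capture_scale", "pcr_dup_mean"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dropout_rate", "barcode_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulationTruth:
    """Everything the simulation knows and the pipeline must rediscover."""

    clone_table: dict[str, tuple[str, ...]]  # clone id -> locBCs
    location_params: pd.Series  # locBC -> base mean mu_k
    cell_table: pd.DataFrame  # index cell barcode; clone_id, extrinsic, capture
    true_counts: pd.DataFrame | None = None  # latent (pre-dropout) cell x locBC

    @property
    def cell_clones(self) -> pd.Series:
        return self.cell_table["clone_id"]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # Keyed streams: every stage is reproducible on its own and the whole
    # simulation is bit-identical for identical configs.
    return np.random.default_rng([int(config.seed), stream])


def random_barcodes(
    rng: np.random.Generator, n: int, length: int, exclude: Iterable[str] = ()
) -> list[str]:
    """Draw ``n`` distinct random barcodes over {A,C,G,T}."""
    seen = set(exclude)
    if n + len(seen) > 4**length:
        raise ValueError(f"cannot draw {n} distinct {length}-mers")
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out) + 16, length))
        for row in block:
            bc = "".join(BASES[row])
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return out


def _unit_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    if sigma == 0:
        return np.ones(size)
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def build_truth(config: SimulationConfig) -> SimulationTruth:
    """Instantiate clones, locations and cells.

    Location barcodes are globally unique (each tags one genomic site, so
    clone locBC sets are disjoint) and cell barcodes are unique across cells.
    """
    config.validate()
    rng = _rng(config, 0)

    off, rate = config.integrations_per_clone
    n_int = off + rng.poisson(rate, size=config.n_clones)
    n_int = np.maximum(n_int, 1)  # every clone carries at least one reporter

    if isinstance(config.cells_per_clone, tuple):
        coff, crate = config.cells_per_clone
        n_cells = np.maximum(coff + rng.poisson(crate, size=config.n_clones), 1)
    else:
        n_cells = np.full(config.n_clones, int(config.cells_per_clone))

    all_locs = random_barcodes(rng, int(n_int.sum()), LOC_BC_LEN)
    all_cells = random_barcodes(rng, int(n_cells.sum()), CELL_BC_LEN)

    meanlog, sdlog = config.mu_loc
    mu = rng.lognormal(mean=meanlog, sigma=sdlog, size=len(all_locs))
    location_params = pd.Series(mu, index=all_locs, name="mu")

    clone_table: dict[str, tuple[str, ...]] = {}
    rows = []
    loc_it = iter(all_locs)
    cell_it = iter(all_cells)
    for c in range(config.n_clones):
        cid = f"clone{c:03d}"
        clone_table[cid] = tuple(itertools.islice(loc_it, int(n_int[c])))
        ext = _unit_lognormal(rng, config.sigma_ext, int(n_cells[c]))
        cap = _unit_lognormal(rng, config.capture_scale, int(n_cells[c]))
        for j in range(int(n_cells[c])):
            rows.append((next(cell_it), cid, ext[j], cap[j]))
    cell_table = pd.DataFrame(
        rows, columns=["cell_barcode", "clone_id", "extrinsic", "capture"]
    ).set_index("cell_barcode")

    return SimulationTruth(clone_table, location_params, cell_table)


def simulate_counts(truth: SimulationTruth, config: SimulationConfig) -> pd.DataFrame:
    """Draw the observed cell x locBC UMI count matrix.

    The latent (pre-dropout) matrix is stored on ``truth.true_counts``;
    entries for locBCs outside a cell's clone are structural zeros.
    """
    rng = _rng(config, 1)
    all_locs = list(truth.location_params.index)
    latent = pd.DataFrame(
        0, index=truth.cell_table.index, columns=all_locs, dtype=np.int64
    )
    mu = truth.location_params
    for cid, locs in truth.clone_table.items():
        cells = truth.cell_table.index[truth.cell_table["clone_id"] == cid]
        if len(cells) == 0 or len(locs) == 0:
            continue
        s = truth.cell_table.loc[cells, "capture"].to_numpy()
        e = truth.cell_table.loc[cells, "extrinsic"].to_numpy()
        intr = _unit_lognormal(rng, config.sigma_int, (len(cells), len(locs)))
        lam = (s * e)[:, None] * intr * mu[list(locs)].to_numpy()[None, :]
        latent.loc[cells, list(locs)] = rng.poisson(lam)

    observed = latent.copy()
    if config.dropout_rate > 0:
        keep = rng.random(latent.shape) >= config.dropout_rate
        observed = observed.where(keep, 0)
    truth.true_counts = latent
    return observed


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply independent per-base substitutions at the given rate."""
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    shifts = rng.integers(1, 4, size=hits.size)
    lut = {b: i for i, b in enumerate(BASES)}
    for pos, sh in zip(hits, shifts):
        chars[pos] = BASES[(lut[chars[pos]] + sh) % 4]
    return "".join(chars)


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def emit_fastq(
    truth: SimulationTruth,
    counts: pd.DataFrame,
    config: SimulationConfig,
    r1_path,
    r2_path,
    truth_path=None,
    constants: Sequence[str] = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Write paired FASTQ for the observed count matrix.

    Each observed UMI yields ``1 + Poisson(pcr_dup_mean)`` read pairs.
    R1 = cellBC(16) + UMI(12) + fixed filler; R2 = constant + locBC(16).
    Substitution errors are injected per base into the barcode segments of
    every read independently. Returns the ground-truth trio table
    (cell_barcode, umi, loc_barcode, clone_id, reads), also written as TSV
    when ``truth_path`` is given.
    """
    rng = _rng(config, 2)
    clone_of = truth.cell_table["clone_id"]
    records = []
    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        ridx = 0
        arr = counts.to_numpy()
        cells = counts.index.to_numpy()
        locs = counts.columns.to_numpy()
        for i in np.flatnonzero(arr.any(axis=1)):
            cell = cells[i]
            nz = np.flatnonzero(arr[i])
            n_umis = int(arr[i, nz].sum())
            umis = random_barcodes(rng, n_umis, UMI_LEN)
            u = 0
            for j in nz:
                loc = locs[j]
                for _ in range(int(arr[i, j])):
                    umi = umis[u]
                    u += 1
                    n_reads = 1 + int(rng.poisson(config.pcr_dup_mean))
                    const = constants[int(rng.integers(len(constants)))]
                    for _ in range(n_reads):
                        r1 = (
                            _mutate(cell + umi, config.barcode_error_rate, rng)
                            + R1_FILLER
                        )
                        r2 = const + _mutate(loc, config.barcode_error_rate, rng)
                        f1.write(f"@r{ridx}\n{r1}\n+\n{'I' * len(r1)}\n")
                        f2.write(f"@r{ridx}\n{r2}\n+\n{'I' * len(r2)}\n")
                        ridx += 1
                    records.append((cell, umi, loc, clone_of[cell], n_reads))
    truth_df = pd.DataFrame(
        records, columns=["cell_barcode", "umi", "loc_barcode", "clone_id", "reads"]
    )
    if truth_path is not None:
        truth_df.to_csv(truth_path, sep="\t", index=False)
    return truth_df


def write_whitelist(truth: SimulationTruth, path, n_decoys: int = 0) -> None:
    """Write the cell-barcode whitelist (true barcodes plus optional decoys)."""
    barcodes = list(truth.cell_table.index)
    if n_decoys:
        rng = np.random.default_rng([hash("whitelist") % (2**31), len(barcodes)])
        barcodes += random_barcodes(rng, n_decoys, CELL_BC_LEN, exclude=barcodes)
    with open(path, "w") as fh:
        fh.write("\n".join(barcodes) + "\n")


DEFAULT_PHASES = ("G1", "S", "G2M")
#: phase proportions conditional on substate: the stem-like substate cycles
#: faster (more S phase), the differentiated substate sits longer in G1
PHASE_PROPS = {
    "stem-like": (0.35, 0.45, 0.20),
    "differentiated": (0.55, 0.25, 0.20),
}


def emit_gene_counts(
    truth: SimulationTruth,
    config: SimulationConfig,
    insertion_spec: tuple[str, str, float] | None = None,
    n_genes: int = 200,
    base_mean: float = 5.0,
    dispersion: float = 10.0,
    stem_fractions: Mapping[str, float] | float | None = None,
    phase_props: Mapping[str, tuple[float, float, float]] = PHASE_PROPS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a gene x cell transcriptome with one optional spiked gene.

    Baseline counts are negative binomial with gene-specific log-normal
    means; ``insertion_spec=(clone_id, gene_id, fold_change)`` multiplies the
    spiked gene's mean by ``fold_change`` in cells of that clone only. Each
    cell gets a substate label ("stem-like"/"differentiated") from its
    clone's stem fraction and a cell-cycle phase conditional on substate.

    Returns ``(genes, labels)``: genes x cells integer counts and a per-cell
    label frame with columns substate, phase.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = _rng(config, 3)
    cells = truth.cell_table.index
    clone_of = truth.cell_table["clone_id"]
    gene_ids = [f"gene{g:04d}" for g in range(n_genes)]
    gene_mu = rng.lognormal(np.log(base_mean), 1.0, size=n_genes)

    mu_mat = np.tile(gene_mu[:, None], (1, len(cells)))
    if insertion_spec is not None:
        clone_id, gene_id, fold = insertion_spec
        if clone_id not in truth.clone_table:
            raise KeyError(f"unknown clone id {clone_id!r}")
        if gene_id not in gene_ids:
            raise KeyError(f"unknown gene id {gene_id!r}")
        if fold <= 0:
            raise ValueError("fold_change must be > 0")
        gi = gene_ids.index(gene_id)
        in_clone = (clone_of == clone_id).to_numpy()
        mu_mat[gi, in_clone] *= fold

    r = float(dispersion)
    p = r / (r + mu_mat)
    genes = pd.DataFrame(
        rng.negative_binomial(r, p), index=gene_ids, columns=cells
    )

    clone_ids = sorted(truth.clone_table)
    if stem_fractions is None:
        fracs = dict(zip(clone_ids, rng.beta(2.0, 2.0, size=len(clone_ids))))
    elif isinstance(stem_fractions, (int, float)):
        fracs = {c: float(stem_fractions) for c in clone_ids}
    else:
        fracs = dict(stem_fractions)
    substate = np.where(
        rng.random(len(cells)) < clone_of.map(fracs).to_numpy(),
        "stem-like",
        "differentiated",
    )
    phases = np.empty(len(cells), dtype=object)
    for state, props in phase_props.items():
        mask = substate == state
        phases[mask] = rng.choice(DEFAULT_PHASES, size=int(mask.sum()), p=props)
    labels = pd.DataFrame({"substate": substate, "phase": phases}, index=cells)
    return genes, labels
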