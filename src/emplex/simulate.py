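"""Synthetic scRNA-seq generator with ordered EMT states and ground truth.

Cells occupy one of ``n_states`` discrete states ordered along an EMT
axis (default ``E -> I1 -> I2 -> M``). Three gene programs are simulated:

* an *epithelial* program whose mean expression falls slowly along the
  state order, so that terminal cells retain a substantial fraction of
  their epithelial expression (hybrid co-expression in late states);
* a *mesenchymal* program whose mean rises strongly along the order;
* a *housekeeping* program with constant mean.

Counts are drawn gene-wise from a negative binomial parameterized by
(mean, dispersion) and then zeroed independently with a dropout
probability — the simplest noise model with the overdispersion and
sparsity the downstream analyses assume. Ligand/receptor genes for toy
signaling pathways are appended with state-specific means, and each cell
receives a time-point label drawn from a time-course mixture over
states. Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emplex.communication import LRDatabase, LRPair
from emplex.errors import ConfigurationError
from emplex.io import CountMatrix, write_counts

__all__ = [
    "LRSpec",
    "SimConfig",
    "SyntheticDataset",
    "generate_emt_dataset",
    "generate_lr_database",
    "write_dataset",
]

DEFAULT_STATE_LABELS = ("E", "I1", "I2", "M")

# state x program negative-binomial means (columns: epithelial,
# mesenchymal, housekeeping). The mesenchymal program rises strongly
# along the EMT order while the epithelial program decays slowly, its
# terminal mean staying >= 40% of the E-state level so that late states
# co-express both programs (hybrid E/M plasticity).
DEFAULT_PROGRAM_MEANS = np.array(
    [
        [8.0, 0.5, 5.0],  # E
        [7.0, 1.5, 5.0],  # I1
        [6.0, 4.0, 5.0],  # I2
        [5.0, 9.0, 5.0],  # M
    ]
)

# time-point x state mixture: early time points are dominated by
# epithelial cells, late ones by mesenchymal cells (rows sum to 1)
DEFAULT_TIMECOURSE_MIX = np.array(
    [
        [0.85, 0.10, 0.05, 0.00],
        [0.40, 0.35, 0.20, 0.05],
        [0.10, 0.30, 0.35, 0.25],
        [0.02, 0.13, 0.35, 0.50],
    ]
)


@dataclass(frozen=True)
class LRSpec:
    """Design of one toy ligand-receptor pathway.

    ``ligand_level`` is the ligand gene's negative-binomial mean in the
    ``sender_state`` (a state label), ``receptor_level`` likewise for the
    receiver; outside those states the genes sit at ``baseline``.
    """

    pathway: str
    sender_state: str
    receiver_state: str
    ligand_level: float
    receptor_level: float
    baseline: float = 0.2
    n_ligand_subunits: int = 1
    n_receptor_subunits: int = 1


def default_lr_design() -> list[LRSpec]:
    """Toy pathways mirroring juxtacrine/paracrine EMT signaling: the
    intermediate state I2 is the strongest Notch-toy and Wnt-toy sender."""
    return [
        LRSpec("NotchToy", "I2", "M", 10.0, 10.0),
        LRSpec("WntToy", "I2", "I1", 8.0, 8.0),
        LRSpec("TgfbToy", "M", "E", 6.0, 6.0),
    ]


def graded_lr_design() -> list[LRSpec]:
    """Pathways whose ligand and receptor means increase with state index
    (use with ``lr_profile='graded'``): later EMT states both send and
    receive more. Levels are kept moderate so the between-state gradient
    stays inside the responsive range of the Hill transform instead of
    saturating it."""
    return [
        LRSpec("NotchToy", "M", "M", 4.0, 4.0),
        LRSpec("WntToy", "M", "M", 3.0, 3.0),
    ]


@dataclass
class SimConfig:
    """Full design of one synthetic EMT dataset.

    Parameters
    ----------
    n_states
        Number of ordered EMT states (default 4, labelled E, I1, I2, M).
    cells_per_state
        Cells simulated in each state.
    program_means
        ``n_states x 3`` matrix of negative-binomial means for the
        epithelial, mesenchymal and housekeeping programs.
    nb_dispersion
        Negative-binomial dispersion (shape) parameter; smaller means
        more overdispersion.
    dropout_prob
        Independent Bernoulli zeroing probability applied after sampling.
    lr_design / lr_profile
        Toy ligand-receptor pathways. With ``lr_profile='spike'`` each
        ligand/receptor gene has its design level in its designated state
        and the baseline elsewhere; with ``'graded'`` the mean rises
        linearly with state index up to the design level.
    timecourse_mix
        Time-point x state fractions (rows sum to 1); each cell's time
        label is drawn conditional on its state.
    """

    n_states: int = 4
    state_labels: tuple[str, ...] = DEFAULT_STATE_LABELS
    cells_per_state: list[int] = field(default_factory=lambda: [100, 100, 100, 100])
    n_epithelial_genes: int = 108
    n_mesenchymal_genes: int = 193
    n_housekeeping_genes: int = 100
    program_means: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROGRAM_MEANS.copy()
    )
    nb_dispersion: float = 5.0
    dropout_prob: float = 0.2
    # fraction of each state's cells caught mid-transition: their means
    # are blended toward a random adjacent state by a weight drawn from
    # transition_blend (kept below 0.5 so the nominal state stays the
    # majority program). Emulates the EMT continuum of real datasets.
    transition_fraction: float = 0.15
    transition_blend: tuple[float, float] = (0.4, 0.5)
    lr_design: list[LRSpec] = field(default_factory=default_lr_design)
    lr_profile: str = "spike"
    timecourse_mix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TIMECOURSE_MIX.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.program_means = np.asarray(self.program_means, dtype=float)
        self.timecourse_mix = np.asarray(self.timecourse_mix, dtype=float)
        if len(self.cells_per_state) != self.n_states:
            raise ConfigurationError(
                "cells_per_state length must equal n_states"
            )
        if len(self.state_labels) != self.n_states:
            raise ConfigurationError("state_labels length must equal n_states")
        if self.program_means.shape != (self.n_states, 3):
            raise ConfigurationError(
                f"program_means must be {self.n_states} x 3, got "
                f"{self.program_means.shape}"
            )
        if (self.program_means < 0).any():
            raise ConfigurationError("program means must be nonnegative")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not (0.0 <= self.dropout_prob <= 1.0):
            raise ConfigurationError("dropout_prob must be in [0, 1]")
        if not (0.0 <= self.transition_fraction < 1.0):
            raise ConfigurationError("transition_fraction must be in [0, 1)")
        lo, hi = self.transition_blend
        if not (0.0 <= lo <= hi <= 0.5):
            raise ConfigurationError(
                "transition_blend must lie within [0, 0.5]"
            )
        if self.timecourse_mix.shape[1] != self.n_states:
            raise ConfigurationError(
                "timecourse_mix must have one column per state"
            )
        if not np.allclose(self.timecourse_mix.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("timecourse_mix rows must sum to 1")
        if self.lr_profile not in {"spike", "graded"}:
            raise ConfigurationError("lr_profile must be 'spike' or 'graded'")
        for spec in self.lr_design:
            for s in (spec.sender_state, spec.receiver_state):
                if s not in self.state_labels:
                    raise ConfigurationError(
                        f"unknown state {s!r} in lr_design for {spec.pathway}"
                    )


@dataclass
class SyntheticDataset:
    """Counts plus full ground truth for one simulated experiment."""

    counts: CountMatrix
    true_state: np.ndarray  # per-cell state index, 0-based along the EMT order
    true_time: np.ndarray  # per-cell time-point label
    true_transition: np.ndarray  # per-cell: was this cell blended mid-transition
    epithelial_genes: list[str]
    mesenchymal_genes: list[str]
    lr_db: LRDatabase
    config: SimConfig


def generate_lr_database(config: SimConfig) -> LRDatabase:
    """Build the toy ligand-receptor database implied by ``lr_design``."""
    if not config.lr_design:
        raise ConfigurationError("lr_design must be nonempty")
    names = [s.pathway for s in config.lr_design]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate pathway names in lr_design")
    entries = []
    for spec in config.lr_design:
        lig = tuple(
            f"{spec.pathway}_L{i + 1}" for i in range(spec.n_ligand_subunits)
        )
        rec = tuple(
            f"{spec.pathway}_R{i + 1}" for i in range(spec.n_receptor_subunits)
        )
        entries.append(LRPair(spec.pathway, lig, rec))
    return LRDatabase(entries)


def _lr_gene_means(config: SimConfig) -> tuple[list[str], np.ndarray]:
    """Names and state-profile means (gene x state) of the L/R genes."""
    names: list[str] = []
    profiles: list[np.ndarray] = []
    idx = {lab: i for i, lab in enumerate(config.state_labels)}
    s_frac = (np.arange(config.n_states) + 1) / config.n_states
    for spec in config.lr_design:
        for kind, n_sub, level, state in (
            ("L", spec.n_ligand_subunits, spec.ligand_level, spec.sender_state),
            ("R", spec.n_receptor_subunits, spec.receptor_level, spec.receiver_state),
        ):
            for i in range(n_sub):
                names.append(f"{spec.pathway}_{kind}{i + 1}")
                if config.lr_profile == "spike":
                    prof = np.full(config.n_states, spec.baseline)
                    prof[idx[state]] = level
                else:
                    # graded: super-linear rise with state index, so the
                    # gradient survives per-cell library-size
                    # normalization (total depth itself grows along the
                    # state order as the mesenchymal program rises)
                    prof = level * s_frac**2
                profiles.append(prof)
    return names, np.array(profiles) if profiles else np.zeros((0, config.n_states))


def generate_emt_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Simulate counts, truth, signatures and the ligand-receptor database.

    Per-gene means are the program mean of the gene's state, scaled by a
    fixed per-gene factor in [0.7, 1.3] (drawn once per gene) so genes
    within a program are not identically distributed; the scaling
    preserves every designed monotone trend. Counts are NB(mean,
    dispersion) with independent dropout.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    gene_names = (
        [f"EGENE_{i + 1}" for i in range(config.n_epithelial_genes)]
        + [f"MGENE_{i + 1}" for i in range(config.n_mesenchymal_genes)]
        + [f"HKGENE_{i + 1}" for i in range(config.n_housekeeping_genes)]
    )
    program_of_gene = np.concatenate(
        [
            np.zeros(config.n_epithelial_genes, dtype=int),
            np.ones(config.n_mesenchymal_genes, dtype=int),
            np.full(config.n_housekeeping_genes, 2, dtype=int),
        ]
    )
    # gene x state mean matrix for the program genes
    means = config.program_means[:, program_of_gene].T
    gene_scale = rng.uniform(0.7, 1.3, size=means.shape[0])
    means = means * gene_scale[:, None]

    lr_names, lr_means = _lr_gene_means(config)
    if lr_names:
        gene_names = gene_names + lr_names
        means = np.vstack([means, lr_means])

    n_cells = int(np.sum(config.cells_per_state))
    true_state = np.repeat(np.arange(config.n_states), config.cells_per_state)
    cell_names = [f"CELL_{i + 1:05d}" for i in range(n_cells)]

    # per-cell mean profiles; a seeded subset of each state's cells is
    # blended toward a random adjacent state (transition cells)
    cell_means = means[:, true_state].astype(float)
    is_transition = np.zeros(n_cells, dtype=bool)
    if config.transition_fraction > 0 and config.n_states > 1:
        for s in range(config.n_states):
            cols = np.flatnonzero(true_state == s)
            n_t = int(round(config.transition_fraction * cols.size))
            if n_t == 0:
                continue
            chosen = rng.choice(cols, size=n_t, replace=False)
            for c in chosen:
                options = [q for q in (s - 1, s + 1) if 0 <= q < config.n_states]
                nb = int(rng.choice(options))
                w = rng.uniform(*config.transition_blend)
                cell_means[:, c] = (1 - w) * means[:, s] + w * means[:, nb]
                is_transition[c] = True

    r = config.nb_dispersion
    p = np.where(cell_means > 0, r / (r + cell_means), 1.0)
    counts = rng.negative_binomial(r, p).astype(np.int64)
    if config.dropout_prob > 0:
        keep = rng.random(counts.shape) >= config.dropout_prob
        counts *= keep

    # time labels drawn conditional on state: P(t | s) ~ mix[t, s]
    n_tp = config.timecourse_mix.shape[0]
    time_labels = np.array([f"t{t}" for t in range(n_tp)])
    cond = config.timecourse_mix / np.maximum(
        config.timecourse_mix.sum(axis=0, keepdims=True), 1e-300
    )
    true_time = np.empty(n_cells, dtype=object)
    for s in range(config.n_states):
        cols = np.flatnonzero(true_state == s)
        true_time[cols] = rng.choice(time_labels, size=cols.size, p=cond[:, s])

    meta = pd.DataFrame(
        {
            "state": [config.state_labels[s] for s in true_state],
            "time_point": true_time,
        },
        index=cell_names,
    )
    cm = CountMatrix(counts, gene_names, cell_names, meta)
    return SyntheticDataset(
        counts=cm,
        true_state=true_state,
        true_time=np.asarray(true_time),
        true_transition=is_transition,
        epithelial_genes=[g for g in gene_names if g.startswith("EGENE_")],
        mesenchymal_genes=[g for g in gene_names if g.startswith("MGENE_")],
        lr_db=(
            generate_lr_database(config) if config.lr_design else LRDatabase([])
        ),
        config=config,
    )


def sample_timecourse(
    config: SimConfig, cells_per_timepoint: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw a time-course cohort: for each time point, state labels are
    sampled i.i.d. from that row of ``timecourse_mix``.

    Returns a frame with ``time_point`` and ``state`` columns, one row
    per cell; useful for testing composition recovery against the
    designed mixtures.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    for t in range(config.timecourse_mix.shape[0]):
        states = rng.choice(
            list(config.state_labels),
            size=cells_per_timepoint,
            p=config.timecourse_mix[t],
        )
        rows.append(pd.DataFrame({"time_point": f"t{t}", "state": states}))
    return pd.concat(rows, ignore_index=True)


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a dataset in the plain-text layout the pipeline reads:
    ``matrix.mtx`` + ``genes.tsv``/``barcodes.tsv``, one-gene-per-line
    signature files, the L-R table, and a truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(ds.counts, out / "matrix.mtx", format="mtx")
    (out / "epithelial_signature.txt").write_text(
        "\n".join(ds.epithelial_genes) + "\n"
    )
    (out / "mesenchymal_signature.txt").write_text(
        "\n".join(ds.mesenchymal_genes) + "\n"
    )
    ds.lr_db.write_tsv(out / "lr_pairs.tsv")
    pd.DataFrame(
        {
            "cell": ds.counts.cell_names,
            "state_index": ds.true_state,
            "state": [ds.config.state_labels[s] for s in ds.true_state],
            "time_point": ds.true_time,
            "transition": ds.true_transition.astype(int),
        }
    ).to_csv(out / "truth.tsv", sep="\t", index=False)
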