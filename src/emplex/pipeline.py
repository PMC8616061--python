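"""End-to-end orchestration: simulate/load -> preprocess -> score ->
cluster & trajectory -> energies -> communication -> report.

``run_full`` executes every stage with explicit seeds and returns a
result bundle (plain dict) that can optionally be written to disk as
TSV/JSON. A failing stage is recorded in ``bundle["errors"]`` while all
upstream outputs are preserved.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from emplex import communication as comm_mod
from emplex import consensus as cons_mod
from emplex import energy as energy_mod
from emplex import stats as stats_mod
from emplex.errors import ConfigurationError
from emplex.io import PreprocessConfig, preprocess, read_counts
from emplex.scoring import (
    GeneSignature,
    ScoringConfig,
    SignatureScores,
    read_signature,
    score_signature,
    summarize_by_cluster,
)
from emplex.simulate import SimConfig, generate_emt_dataset

__all__ = ["RunConfig", "run_full"]


@dataclass
class RunConfig:
    """Every parameter of a full run in one place.

    Exactly one of ``sim`` (synthetic-data design) or ``counts_path``
    (on-disk dataset with signature files and L-R table) must be set.
    """

    sim: SimConfig | None = None
    counts_path: str | None = None
    counts_format: str | None = None
    sig_e_path: str | None = None
    sig_m_path: str | None = None
    lr_db_path: str | None = None

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    top_k: int | None = None  # scoring window; None = all genes

    n_runs: int = 100
    k_min: int = 3
    k_max: int = 8
    delta: float = 0.2
    seed: int = 0

    tau: float = 0.4
    Kh: float = 0.5
    nperm: int = 100
    alpha: float = 0.05
    ttest_mode: str = "consecutive"

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.counts_path is None):
            raise ConfigurationError(
                "set exactly one of 'sim' or 'counts_path'"
            )

    def digest(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, default=default, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_full(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the whole analysis; returns the result bundle.

    Bundle keys: ``counts``, ``expression``, ``scores``,
    ``cluster_summary``, ``membership``, ``trajectory``, ``energies``,
    ``communication``, ``strengths``, ``roles``, ``information_flow``,
    ``report``, ``summary``, ``provenance``, ``errors``.
    """
    bundle: dict = {"errors": {}, "provenance": {
        "config_digest": config.digest(),
        "seed": config.seed,
    }}

    # ---- input stage ----
    if config.sim is not None:
        ds = generate_emt_dataset(config.sim)
        raw = ds.counts
        sig_e = GeneSignature("epithelial", tuple(ds.epithelial_genes))
        sig_m = GeneSignature("mesenchymal", tuple(ds.mesenchymal_genes))
        lr_db = ds.lr_db
        bundle["truth"] = {
            "state_index": ds.true_state,
            "time_point": ds.true_time,
        }
    else:
        raw = read_counts(config.counts_path, config.counts_format)
        sig_e = read_signature(config.sig_e_path, "epithelial")
        sig_m = read_signature(config.sig_m_path, "mesenchymal")
        lr_db = comm_mod.LRDatabase.read_tsv(config.lr_db_path)
    bundle["counts"] = raw

    # ---- preprocessing ----
    try:
        filtered, expr = preprocess(raw, config.preprocess)
        bundle["counts"] = filtered
        bundle["expression"] = expr
    except Exception as exc:
        bundle["errors"]["preprocess"] = str(exc)
        return bundle

    # ---- signature scoring ----
    try:
        cfg = ScoringConfig(top_k=config.top_k)
        s_e = score_signature(expr, sig_e, cfg)
        s_m = score_signature(expr, sig_m, cfg)
        scores = SignatureScores(
            pd.concat([s_e.scores, s_m.scores], axis=1), s_e.config
        )
        bundle["scores"] = scores
    except Exception as exc:
        bundle["errors"]["scoring"] = str(exc)
        return bundle

    # ---- consensus clustering + trajectory ----
    try:
        cons = cons_mod.build_consensus(
            expr, n_runs=config.n_runs, seed=config.seed
        )
        k = cons_mod.select_k(cons, k_min=config.k_min, k_max=config.k_max)
        memb = cons_mod.soft_cluster(
            cons, k, seed=config.seed, delta=config.delta
        )
        summary = summarize_by_cluster(scores, memb.hard_label)
        cluster_scores = summary["mean"].unstack("signature")
        traj = cons_mod.infer_trajectory(memb, cluster_scores)
        bundle["consensus"] = cons
        bundle["membership"] = memb
        bundle["cluster_summary"] = summary
        bundle["trajectory"] = traj
    except Exception as exc:
        bundle["errors"]["clustering"] = str(exc)
        return bundle

    # ---- energies ----
    try:
        diversity = energy_mod.transcriptional_diversity(filtered)
        net = energy_mod.build_gene_network(expr, tau=config.tau)
        dev_energy = energy_mod.single_cell_energy(expr, net)
        emt_energy = energy_mod.emt_circuit_energy(
            expr, sig_e, sig_m, tau=config.tau
        )
        bundle["energies"] = pd.DataFrame(
            {
                "diversity": diversity,
                "energy": dev_energy,
                "emt_energy": emt_energy,
                "cluster": memb.hard_label,
                "pseudotime": traj.pseudotime,
            },
            index=expr.cell_names,
        )
    except Exception as exc:
        bundle["errors"]["energy"] = str(exc)
        return bundle

    # ---- communication ----
    try:
        comm = comm_mod.permutation_significance(
            filtered,
            memb.hard_label,
            lr_db,
            nperm=config.nperm,
            seed=config.seed,
            Kh=config.Kh,
        )
        strengths, roles = comm_mod.interaction_strengths(
            comm, alpha=config.alpha
        )
        bundle["communication"] = comm
        bundle["strengths"] = strengths
        bundle["roles"] = roles
        bundle["information_flow"] = comm_mod.information_flow(
            comm, alpha=config.alpha
        )
    except Exception as exc:
        bundle["errors"]["communication"] = str(exc)

    # ---- report ----
    try:
        energies = bundle["energies"]
        report = stats_mod.trajectory_comparisons(
            energies["emt_energy"].to_numpy(),
            memb.hard_label,
            traj.cluster_order,
            mode=config.ttest_mode,
        )
        mean_energy = [
            float(energies.loc[energies["cluster"] == c, "emt_energy"].mean())
            for c in traj.cluster_order
        ]
        bundle["report"] = report
        bundle["summary"] = {
            "n_cells": expr.n_cells,
            "n_genes": expr.n_genes,
            "k": memb.k,
            "cluster_order": traj.cluster_order,
            "mean_emt_energy_along_trajectory": mean_energy,
            "emt_energy_monotone": bool(
                np.all(np.diff(mean_energy) > 0)
            ),
            "n_transition_cells": int(memb.transition_flag.sum()),
        }
    except Exception as exc:
        bundle["errors"]["report"] = str(exc)

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if "scores" in bundle:
        bundle["scores"].scores.to_csv(out / "scores.tsv", sep="\t")
    if "membership" in bundle:
        memb = bundle["membership"]
        pd.DataFrame(
            memb.H,
            index=memb.cell_names,
            columns=[f"cluster_{i}" for i in range(memb.k)],
        ).to_csv(out / "membership.tsv", sep="\t")
        pd.DataFrame(
            {
                "cluster": memb.hard_label,
                "transition": memb.transition_flag.astype(int),
            },
            index=memb.cell_names,
        ).to_csv(out / "labels.tsv", sep="\t")
    if "trajectory" in bundle:
        traj = bundle["trajectory"]
        (out / "trajectory.json").write_text(
            json.dumps(
                {
                    "start_cluster": traj.start_cluster,
                    "cluster_order": traj.cluster_order,
                    "edge_weights": {
                        f"{a}-{b}": w for (a, b), w in traj.edge_weights.items()
                    },
                },
                indent=2,
            )
        )
    if "energies" in bundle:
        bundle["energies"].to_csv(out / "energies.tsv", sep="\t")
    if "strengths" in bundle:
        bundle["strengths"].to_csv(out / "strengths.tsv", sep="\t")
    if "information_flow" in bundle:
        bundle["information_flow"].to_csv(out / "information_flow.tsv", sep="\t")
    if "report" in bundle:
        bundle["report"].to_csv(out / "report.tsv", sep="\t", index=False)
    if "summary" in bundle:
        (out / "summary.json").write_text(
            json.dumps(bundle["summary"], indent=2)
        )
    (out / "provenance.json").write_text(
        json.dumps(
            {**bundle["provenance"], "errors": bundle["errors"]}, indent=2
        )
    )
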