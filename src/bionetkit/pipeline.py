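"""Declarative pipeline runner.

A run config (YAML or dict) names the inputs, the output directory, a master
seed, and the steps to execute; steps run in the standard order
build -> annotate -> centrality/topology -> cluster -> consensus/bridgeness ->
separation/ora, each writing a TSV whose header comments record the tool
version, seed and parameters so any output can be traced to its run. Steps
never mutate another step's inputs, so a pipeline can be re-run per step.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annot_stats import run_permutation_test, ora
from .centrality import calc_centrality
from .community import cluster, clustering_summary, cluster_layout
from .consensus import bridgeness, cluster_robustness, consensus_matrix
from .graph_core import annotate_vertices, read_annotations, read_graph
from .topology import fit_power_law, perturb_entropy

STEP_ORDER = (
    "centrality",
    "powerlaw",
    "entropy",
    "cluster",
    "summary",
    "layout",
    "consensus",
    "bridgeness",
    "separation",
    "ora",
)


def write_table(df: pd.DataFrame, path: str, meta: dict, index: bool = False) -> None:
    """Write a TSV with '# key: value' metadata header lines."""
    with open(path, "w") as fh:
        fh.write(f"# bionetkit {__version__}\n")
        for key in sorted(meta):
            fh.write(f"# {key}: {meta[key]}\n")
        df.to_csv(fh, sep="\t", index=index)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict) -> list[str]:
    """Execute the configured steps; returns the list of files written."""
    outdir = config.get("outdir", "bionetkit_out")
    steps: Iterable[str] = config.get("steps") or STEP_ORDER
    unknown = [s for s in steps if s not in STEP_ORDER]
    if unknown:
        raise ValueError(f"unknown steps: {unknown}")
    if "network" not in config:
        raise ValueError("config needs a 'network' input path")
    if not os.path.exists(config["network"]):
        raise FileNotFoundError(config["network"])
    ann_path = config.get("annotations")
    if ann_path and not os.path.exists(ann_path):
        raise FileNotFoundError(ann_path)
    needs_ann = {"separation", "ora"} & set(steps)
    if needs_ann and not ann_path:
        raise ValueError(f"steps {sorted(needs_ann)} need an 'annotations' input")

    os.makedirs(outdir, exist_ok=True)
    seed = int(config.get("seed", 0))
    algorithm = config.get("algorithm", "louvain")
    net = read_graph(config["network"])
    attr = config.get("annotation_attr", "annotation")
    if ann_path:
        annotate_vertices(net, read_annotations(ann_path), attr)
    base_meta = {"seed": seed, "network": config["network"], "algorithm": algorithm}
    written: list[str] = []

    def emit(df, name, extra=None, index=False):
        path = os.path.join(outdir, name)
        write_table(df, path, {**base_meta, **(extra or {})}, index=index)
        written.append(path)

    clustering = None
    cm = None
    for step in (s for s in STEP_ORDER if s in steps):
        if step == "centrality":
            emit(calc_centrality(net), "centrality.tsv", index=True)
        elif step == "powerlaw":
            fit = fit_power_law(net.degree())
            emit(
                pd.DataFrame(
                    [{"alpha": fit.alpha, "xmin": fit.xmin, "ks_stat": fit.ks_stat, "n_tail": fit.n_tail}]
                ),
                "powerlaw.tsv",
            )
        elif step == "entropy":
            over = perturb_entropy(net, baseline=2.0, perturbed=14.0)
            under = perturb_entropy(net, baseline=16.0, perturbed=14.0)
            tbl = over.table.rename(columns={"SR": "SR_over"})
            tbl["SR_under"] = under.table["SR"]
            emit(tbl, "entropy.tsv", {"SR0": over.sr0})
        elif step == "cluster":
            clustering = cluster(net, algorithm, seed=seed)
            emit(clustering.to_frame(), "membership.tsv", {"modularity": clustering.modularity})
        elif step == "summary":
            clustering = clustering or cluster(net, algorithm, seed=seed)
            emit(clustering_summary(net, [clustering]), "summary.tsv", index=True)
        elif step == "layout":
            clustering = clustering or cluster(net, algorithm, seed=seed)
            emit(cluster_layout(net, clustering, seed=seed), "layout.tsv")
        elif step == "consensus":
            cm = consensus_matrix(
                net,
                algorithm,
                sample_fraction=float(config.get("sample_fraction", 0.8)),
                reps=int(config.get("reps", 500)),
                seed=seed,
            )
            emit(cm.to_frame(), "consensus.tsv", {"reps": cm.reps, "fraction": cm.sample_fraction}, index=True)
        elif step == "bridgeness":
            clustering = clustering or cluster(net, algorithm, seed=seed)
            if cm is None:
                cm = consensus_matrix(
                    net,
                    algorithm,
                    sample_fraction=float(config.get("sample_fraction", 0.8)),
                    reps=int(config.get("reps", 500)),
                    seed=seed,
                )
            bt = bridgeness(cm, clustering)
            emit(bt, "bridgeness.tsv")
            emit(
                cluster_robustness(cm, clustering).to_frame(),
                "robustness.tsv",
                index=True,
            )
        elif step == "separation":
            emit(
                run_permutation_test(
                    net, attr, n_perm=int(config.get("n_perm", 1000)), seed=seed
                ),
                "separation.tsv",
            )
        elif step == "ora":
            clustering = clustering or cluster(net, algorithm, seed=seed)
            groups = {
                f"cluster_{c}": set(members)
                for c, members in enumerate(clustering.communities(), start=1)
            }
            emit(
                ora(groups, read_annotations(ann_path), set(net.vs["name"])),
                "ora.tsv",
            )
    return written
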