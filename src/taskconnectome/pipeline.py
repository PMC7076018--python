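"""End-to-end pipeline runner over a synthetic cohort, with a run manifest.

Stages: simulate -> intrinsic networks -> activation GLM -> interaction
models -> network densities -> hubs -> overlap. Every stage writes TSV/JSON
artifacts; the manifest records the configuration snapshot, master seed,
SHA-256 hashes of all outputs, package version, and timestamps. A single
master seed fans out into per-stage substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .density import density_permutation_test, network_degree_and_chi2
from .glm import group_icn_activation
from .hubs import (absolute_graph, centralities, edge_class_counts,
                   hub_icn_test, hub_score_classify, kmeans_classify)
from .io import write_matrix, write_partition
from .overlap import NodeSet, association_comparison, overlap_analysis
from .synth import SynthConfig, write_cohort
from .validation import partition_recovery, run_task_cohort

__all__ = ["run_pipeline"]


def _hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: SynthConfig, out_dir, seed: int = 0,
                 n_perm: int = 1000, write_data: bool = False) -> dict:
    """Run every stage on a synthetic cohort; returns the manifest dict.

    ``seed`` drives independent substreams per stage. The reference region
    set for the overlap stage is the set of nodes incident to planted
    interaction edges; association scores are a noisy readout of planted
    edge involvement (both synthetic stand-ins for external inputs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_seeds = [int(s) & 0x7FFFFFFF
                   for s in np.random.SeedSequence(seed).generate_state(8)]
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in dataclasses.asdict(cfg).items()
                           if k != "hrf"},
                "master_seed": seed, "version": __version__,
                "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "stages": {}, "files": {}}

    def _record(stage, path):
        manifest["files"][str(path.name)] = _hash(path)
        manifest["stages"].setdefault(stage, []).append(str(path.name))

    try:
        if write_data:
            write_cohort(cfg, out / "data")
        # intrinsic networks from the resting branch
        rec = partition_recovery(cfg, seed=stage_seeds[0])
        part = rec["partition"]
        p = write_partition(out / "partition.tsv", part)
        _record("icn", p)
        # task branch: GLM activations + interaction difference matrix
        task = run_task_cohort(cfg, seed=stage_seeds[1])
        dm = task["difference_matrix"]
        p = write_matrix(out / "difference_matrix.tsv", dm.values.astype(float),
                         "difference", ids=part.node_ids)
        _record("gppi", p)
        activ = group_icn_activation(task["contrasts"], part)
        p = out / "icn_activation.json"
        p.write_text(json.dumps(activ, indent=1))
        _record("glm", p)
        # network-level densities with rewiring null
        dens = density_permutation_test(dm, part, n_perm=n_perm,
                                        seed=stage_seeds[2])
        p = write_matrix(out / "density_positive.tsv", dens.positive, "density")
        _record("density", p)
        p = write_matrix(out / "density_negative.tsv", dens.negative, "density")
        _record("density", p)
        degree, chi2, df, chi_p = network_degree_and_chi2(dens)
        p = out / "network_degree.json"
        p.write_text(json.dumps({"degree": degree.tolist(), "chi2": chi2,
                                 "df": df, "p": chi_p}, indent=1))
        _record("density", p)
        # hubs
        adj = absolute_graph(dm)
        table = centralities(adj, part)
        hubs = hub_score_classify(table)
        hubs_km = kmeans_classify(table, seed=stage_seeds[3])
        icn_test = hub_icn_test(hubs, part, n_perm=n_perm, seed=stage_seeds[4])
        counts = edge_class_counts(dm, hubs)
        p = out / "hubs.json"
        p.write_text(json.dumps({
            "hub_score": hubs.indices().tolist(),
            "kmeans": hubs_km.indices().tolist(),
            "per_icn": icn_test, "edge_classes": counts}, indent=1))
        _record("hubs", p)
        # overlap against the planted reference set
        rng = np.random.default_rng(stage_seeds[5])
        involved = sorted({n for e in cfg.ppi_edges for n in e[:2]})
        scores = rng.normal(size=cfg.n_nodes)
        result = {}
        if involved and hubs.n_hubs:
            ref = NodeSet(involved, cfg.n_nodes)
            hub_set = NodeSet.from_mask(hubs.is_hub)
            ov = overlap_analysis(hub_set, ref, n_perm=n_perm,
                                  seed=stage_seeds[6])
            scores[involved] += 2.0
            assoc = association_comparison(scores, hubs, part, n_perm=n_perm,
                                           seed=stage_seeds[7])
            result = {"jaccard": ov.jaccard, "jaccard_max": ov.jaccard_max,
                      "jaccard_p": ov.jaccard_p,
                      "odds_ratio": ov.odds_ratio, "ci95": list(ov.ci95),
                      "association": assoc}
        p = out / "overlap.json"
        p.write_text(json.dumps(result, indent=1))
        _record("overlap", p)
    except Exception as err:
        manifest["failed"] = repr(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(
            f"pipeline aborted in stage after {list(manifest['stages'])}: {err}"
        ) from err
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
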