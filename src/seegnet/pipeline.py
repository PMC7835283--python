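"""End-to-end orchestration: config in, artifacts and a run manifest out.

A run executes signal IO → h² coupling → thresholded event graphs → cosine
similarity / dendrograms → signed-rank + B-H statistics (and streamline
counting when imaging inputs are configured), writing every intermediate
artifact to the output directory.  Identical config + seed produces identical
outputs; the manifest records the seed, a hash of the normalised config and
the artifact list so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import agglomerate, cosine_similarity, similarity_distribution
from .coupling import H2Config, event_coupling_matrix
from .graphs import build_event_graph, fit_baseline, to_adjacency
from .signal_io import Phase, read_annotations, read_edf, write_annotations
from .stats import phase_change_table
from .synthetic import default_scenario, generate_seizure_scenario, write_edf
from .tracts import LabelVolume, difference_vs_controls, load_streamlines, tract_count_matrix

_TOP_KEYS = {"edf", "annotations", "scenario", "h2", "graph", "stats",
             "tracts", "output_dir", "seed"}
_SCENARIO_KEYS = {"n_seizures", "baseline_s", "onset_s", "gain", "noise_sd"}
_H2_KEYS = {"n_bins", "min_points_per_bin", "lag_range_ms", "lag_step_samples",
            "bin_mode"}
_GRAPH_KEYS = {"rule", "adjacency_mode"}
_STATS_KEYS = {"q", "k", "collapse"}
_TRACT_KEYS = {"label_volume", "streamlines", "labels", "mode", "control_mean"}


@dataclass
class PipelineConfig:
    output_dir: str = "seegnet_out"
    seed: int = 0
    edf: str | None = None
    annotations: str | None = None
    scenario: dict = field(default_factory=dict)
    h2: H2Config = field(default_factory=H2Config)
    graph_rule: str = "independent"
    adjacency_mode: str = "binary"
    q: float = 0.05
    k: int = 25
    collapse: str = "max"
    tracts: dict = field(default_factory=dict)

    def __post_init__(self):
        has_edf = self.edf is not None
        has_scn = bool(self.scenario)
        if has_edf == has_scn:
            raise ValueError("exactly one of an EDF input or a synthetic "
                             "scenario must be configured")
        if has_edf and self.annotations is None:
            raise ValueError("an EDF input needs an annotations sidecar")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def validate_config(source) -> PipelineConfig:
    """Schema-check a YAML/JSON config file (or dict) and fill defaults."""
    if isinstance(source, dict):
        raw = dict(source)
    else:
        import yaml

        with open(source) as f:
            raw = yaml.safe_load(f) or {}
    _check_keys(raw, _TOP_KEYS, "top level")
    scenario = dict(raw.get("scenario") or {})
    if scenario:
        _check_keys(scenario, _SCENARIO_KEYS, "scenario")
    h2d = dict(raw.get("h2") or {})
    _check_keys(h2d, _H2_KEYS, "h2")
    if "lag_range_ms" in h2d:
        h2d["lag_range_ms"] = tuple(h2d["lag_range_ms"])
    graph = dict(raw.get("graph") or {})
    _check_keys(graph, _GRAPH_KEYS, "graph")
    stats = dict(raw.get("stats") or {})
    _check_keys(stats, _STATS_KEYS, "stats")
    tracts = dict(raw.get("tracts") or {})
    if tracts:
        _check_keys(tracts, _TRACT_KEYS, "tracts")
        for req in ("label_volume", "streamlines"):
            if req not in tracts:
                raise ValueError(f"tracts config needs '{req}'")
    return PipelineConfig(
        output_dir=raw.get("output_dir", "seegnet_out"),
        seed=int(raw.get("seed", 0)),
        edf=raw.get("edf"),
        annotations=raw.get("annotations"),
        scenario=scenario,
        h2=H2Config(**h2d),
        graph_rule=graph.get("rule", "independent"),
        adjacency_mode=graph.get("adjacency_mode", "binary"),
        q=float(stats.get("q", 0.05)),
        k=int(stats.get("k", 25)),
        collapse=stats.get("collapse", "max"),
        tracts=tracts,
    )


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    payload = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()


def _load_inputs(config: PipelineConfig, out: Path, artifacts: list):
    """Either read the configured EDF or synthesise the scenario recordings."""
    if config.edf is not None:
        rec = read_edf(config.edf)
        anns = read_annotations(config.annotations)
        return [(rec, anns)], {}
    scn = config.scenario
    n_seiz = int(scn.get("n_seizures", 2))
    recordings, truths = [], {}
    for s in range(1, n_seiz + 1):
        spec = default_scenario(
            seed=config.seed + s, seizure_id=s,
            baseline_s=float(scn.get("baseline_s", 20.0)),
            onset_s=float(scn.get("onset_s", 45.0)),
            gain=float(scn.get("gain", 0.9)),
            noise_sd=float(scn.get("noise_sd", 0.15)))
        rec, anns, truth = generate_seizure_scenario(spec)
        edf_path = out / f"seizure{s}.edf"
        write_edf(rec, edf_path)
        write_annotations(anns, out / f"seizure{s}_annotations.json")
        artifacts += [edf_path, out / f"seizure{s}_annotations.json"]
        for phase, g in truth.items():
            if g.n_edges:
                p = out / f"seizure{s}_truth_{phase}.graphml"
                g.write_graphml(p)
                artifacts.append(p)
        recordings.append((rec, anns))
        truths[s] = truth
    return recordings, truths


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list = []

    recordings, truths = _load_inputs(config, out, artifacts)

    # --- coupling matrices, one per annotated event -----------------------
    all_cms, control_cms = [], {}
    for rec, anns in recordings:
        for ann in anns:
            cm = event_coupling_matrix(rec, ann, config.h2)
            tag = f"s{ann.seizure_id}_{ann.phase.value}"
            cm.to_csv(out / f"h2_{tag}.csv", fmt="long")
            artifacts.append(out / f"h2_{tag}.csv")
            all_cms.append(cm)
            if ann.phase == Phase.baseline:
                control_cms[ann.seizure_id] = cm

    if not control_cms:
        raise RuntimeError("event_graphs stage: no baseline window found to fit "
                           "the threshold model")

    # --- threshold model from the first seizure's baseline ----------------
    first = min(control_cms)
    thr = fit_baseline(control_cms[first])
    with open(out / "threshold.json", "w") as f:
        json.dump({"mu_b": thr.mu_b, "sigma_b": thr.sigma_b,
                   "t1": thr.t1, "t2": thr.t2}, f, indent=1)
    artifacts.append(out / "threshold.json")

    # --- event graphs and similarity --------------------------------------
    sims = []
    for cm in all_cms:
        tag = f"s{cm.event.seizure_id}_{cm.event.phase.value}"
        g = build_event_graph(cm, thr, rule=config.graph_rule)
        g.to_edge_frame().to_csv(out / f"graph_{tag}.csv", index=False,
                                 float_format="%.6f")
        g.write_graphml(out / f"graph_{tag}.graphml")
        adj = to_adjacency(g, mode=config.adjacency_mode)
        S = cosine_similarity(adj)
        S.event = cm.event
        sims.append(S)
        dend = agglomerate(S)
        dend.to_linkage_frame().to_csv(out / f"dendrogram_{tag}.csv", index=False,
                                       float_format="%.6f")
        (out / f"dendrogram_{tag}.nwk").write_text(dend.to_newick() + "\n")
        artifacts += [out / f"graph_{tag}.csv", out / f"graph_{tag}.graphml",
                      out / f"dendrogram_{tag}.csv", out / f"dendrogram_{tag}.nwk"]

    dist = similarity_distribution(sims, group_by_phase=True)
    dist.to_frame().to_csv(out / "similarity_distribution.csv", index=False,
                           float_format="%.6f")
    artifacts.append(out / "similarity_distribution.csv")

    # --- phase-change statistics ------------------------------------------
    phases_present = {cm.event.phase for cm in all_cms} - {Phase.baseline}
    for phase in sorted(phases_present, key=lambda p: p.value):
        table, _bh, box = phase_change_table(
            all_cms, control_cms, phase, q=config.q, k=config.k,
            collapse=config.collapse)
        table.to_csv(out / f"stats_{phase.value}.csv", index=False,
                     float_format="%.6f")
        box.to_csv(out / f"boxplot_{phase.value}.csv", index=False,
                   float_format="%.6f")
        artifacts += [out / f"stats_{phase.value}.csv",
                      out / f"boxplot_{phase.value}.csv"]

    # --- structural stage (optional) ---------------------------------------
    if config.tracts:
        vol = LabelVolume.from_nifti(config.tracts["label_volume"])
        sls = load_streamlines(config.tracts["streamlines"])
        tcm = tract_count_matrix(sls, vol, labels=config.tracts.get("labels"),
                                 mode=config.tracts.get("mode", "endpoint"))
        tcm.to_csv(out / "tract_counts.csv")
        artifacts.append(out / "tract_counts.csv")
        if config.tracts.get("control_mean"):
            import pandas as pd

            ctrl = pd.read_csv(config.tracts["control_mean"], index_col=0)
            diff = difference_vs_controls(tcm, ctrl.to_numpy())
            pd.DataFrame(diff, index=tcm.labels, columns=tcm.labels).to_csv(
                out / "tract_diff_vs_controls.csv", float_format="%.6f")
            artifacts.append(out / "tract_diff_vs_controls.csv")

    manifest = {
        "package": "seegnet",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "artifacts": sorted(str(p.relative_to(out)) for p in artifacts),
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest
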