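"""End-to-end analysis pipeline: LCC → R(G) → degradation → NR → centralities.

A :class:`RunConfig` captures every knob of a full network analysis plus a
single master seed.  The master seed spawns an independent, named substream
per stage, so adding or reordering stages never perturbs the randomness of
the others, and re-running the manifest written by a previous run
reproduces every result file bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np

from . import centrality as _centrality
from . import degradation as _degradation
from . import entropy as _entropy
from . import noderes as _noderes
from .exceptions import PPIResilError
from .graphio import extract_lcc, read_edge_list

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("ppiresil")

# fixed stage tags: the substream of a stage never depends on other stages
_STAGE_TAGS = {"resilience": 11, "degradation": 12, "node_resilience": 13}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_TAGS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    edge_list: str
    out_dir: str
    seed: int = 0
    step: float = 0.01
    reps: int = 100
    outer_step: float = 0.01
    outer_reps: int = 100
    inner_step: float = 0.02
    inner_reps: int = 10
    fraction: float = 0.10
    method: str = "spearman"
    window_lo: float = 0.05
    window_hi: float = 0.95
    level: float = 0.95

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key not in fields:
                raise PPIResilError(f"unknown config key {key!r}")
            kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | os.PathLike, **overrides) -> "RunConfig":
        """Read a flat ``key = value`` text config; kwargs override the file."""
        d: dict = {}
        casts = {f.name: type(getattr(cls, f.name, "")) for f in dataclasses.fields(cls)}
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key = key.strip()
                value = value.strip()
                if key in ("seed", "reps", "outer_reps", "inner_reps"):
                    d[key] = int(value)
                elif key in ("edge_list", "out_dir", "method"):
                    d[key] = value
                else:
                    d[key] = float(value)
        d.update(overrides)
        return cls.from_dict(d)


def _fingerprint(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all result files.

    Outputs under ``config.out_dir``: ``manifest.json`` (the resolved
    configuration), per-stage tables/JSON, ``summary.json`` with the headline
    numbers, and ``log.jsonl`` with per-stage timing.  Any stage failure is
    re-raised annotated with the stage name and the input fingerprint, and
    the summary on disk is flagged incomplete.
    """
    if not os.path.exists(config.edge_list):
        # fail before touching the output directory: no partial outputs
        raise PPIResilError(
            f"pipeline stage 'load' failed: input path {config.edge_list!r} does not exist"
        )
    os.makedirs(config.out_dir, exist_ok=True)
    out = lambda name: os.path.join(config.out_dir, name)  # noqa: E731
    with open(out("manifest.json"), "wt", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=1)
    log_path = out("log.jsonl")
    log_fh = open(log_path, "wt", encoding="utf-8")
    summary: dict = {"incomplete": True, "config": config.to_dict()}
    state: dict = {}
    fingerprint = None

    def log_stage(stage, seconds, status):
        log_fh.write(json.dumps({"stage": stage, "seconds": round(seconds, 3), "status": status}) + "\n")
        log_fh.flush()

    def write_summary():
        with open(out("summary.json"), "wt", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, default=float)

    stages = [
        ("load", _stage_load),
        ("resilience", _stage_resilience),
        ("degradation", _stage_degradation),
        ("breakpoint", _stage_breakpoint),
        ("node_resilience", _stage_node_resilience),
        ("centralities", _stage_centralities),
        ("correlation", _stage_correlation),
        ("key_nodes", _stage_key_nodes),
    ]
    try:
        for name, fn in stages:
            t0 = time.perf_counter()
            try:
                fn(config, state, summary, out)
                if name == "load":
                    fingerprint = state["fingerprint"]
            except Exception as exc:
                log_stage(name, time.perf_counter() - t0, "error")
                write_summary()
                raise PPIResilError(
                    f"pipeline stage {name!r} failed on input "
                    f"{config.edge_list!r} (sha256 {fingerprint or 'unavailable'}): {exc}"
                ) from exc
            dt = time.perf_counter() - t0
            log_stage(name, dt, "ok")
            logger.info("stage %s done in %.2fs", name, dt)
        summary["incomplete"] = False
        write_summary()
    finally:
        log_fh.close()
    return summary


def _stage_load(config, state, summary, out):
    fingerprint = _fingerprint(config.edge_list)
    g = extract_lcc(read_edge_list(config.edge_list))
    state["g"] = g
    state["fingerprint"] = fingerprint
    summary["input"] = {
        "edge_list": config.edge_list,
        "sha256": fingerprint,
        "lcc_nodes": g.number_of_nodes(),
        "lcc_edges": g.number_of_edges(),
    }


def _stage_resilience(config, state, summary, out):
    res = _entropy.resilience(
        state["g"],
        step=config.step,
        reps=config.reps,
        seed=stage_seed(config.seed, "resilience"),
    )
    res.curve.to_tsv(out("entropy_curve.tsv"))
    res.to_json(out("resilience.json"))
    summary["R"] = res.value


def _stage_degradation(config, state, summary, out):
    traj = _degradation.degradation_trajectory(
        state["g"],
        outer_step=config.outer_step,
        outer_reps=config.outer_reps,
        inner_step=config.inner_step,
        inner_reps=config.inner_reps,
        seed=stage_seed(config.seed, "degradation"),
    )
    traj.to_tsv(out("trajectory.tsv"))
    state["trajectory"] = traj


def _stage_breakpoint(config, state, summary, out):
    fit = _degradation.fit_breakpoint(
        state["trajectory"], window=(config.window_lo, config.window_hi)
    )
    fit.to_json(out("breakpoint.json"))
    summary["breakpoint_percent"] = fit.breakpoint
    summary["breakpoint_no_acceleration"] = fit.no_acceleration


def _stage_node_resilience(config, state, summary, out):
    table = _noderes.node_resilience_all(
        state["g"],
        step=config.step,
        reps=config.reps,
        seed=stage_seed(config.seed, "node_resilience"),
    )
    table = _noderes.detect_outliers(table, level=config.level)
    table.to_tsv(out("node_resilience.tsv"))
    state["nr"] = table
    summary["baseline_R"] = table.baseline_r
    summary["outlier_percent"] = table.outlier_percent


def _stage_centralities(config, state, summary, out):
    cent = _centrality.centralities(state["g"])
    cent.to_tsv(out("centralities.tsv"))
    state["centralities"] = cent


def _stage_correlation(config, state, summary, out):
    report = _centrality.correlate(state["nr"], state["centralities"], method=config.method)
    report.to_json(out("correlations.json"))
    summary["nr_centrality_correlation"] = report.to_dict()


def _stage_key_nodes(config, state, summary, out):
    kcn = _noderes.key_component_nodes(state["nr"], fraction=config.fraction)
    kbn = _centrality.key_bridge_nodes(state["centralities"], fraction=config.fraction)
    report = _centrality.overlap_report(kcn, kbn)
    report.to_json(out("key_nodes.json"))
    summary["overlap_count"] = report.count
    summary["overlap_fraction"] = report.fraction
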