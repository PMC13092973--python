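"""End-to-end pipeline: simulate/ingest -> topology -> composition -> report.

A run is driven by one config (YAML/dict): per-condition particle sources
(packaged simulator configs, config files, or user STAR tables), topology
and composition parameters, and an optional expansion-segment FASTA for
the RNA layer.  One master seed is forked into named per-stage substreams
so adding a stage never perturbs earlier draws; every output carries the
config hash and seed.  Reruns with the same config and seed are
bitwise-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import composition_by_topology, condition_delta, nn_distance_compare, neighbor_occupancy
from .field import CONDITIONS, FieldConfig, ParticleField, load_condition_config
from .rna import species_scan
from .simulate import simulate_field
from .star_io import read_star, write_star
from .templates import FIVE_CLASSES, load_template_library
from .topology import analyze_topology

logger = logging.getLogger(__name__)

DEFAULT_RUN_CONFIG = {
    "fields": {
        "untreated": {"config": "untreated"},
        "treated": {"config": "treated"},
    },
    "topology": {
        "cutoff": 400.0,
        "eps": 3.0,
        "min_samples": 10,
        "sigma_t": 25.0,
        "sigma_theta": 10.0,
        "strict_fraction": 0.75,
    },
    "occupancy": {"cone_deg": 60.0, "max_dist": 400.0},
    "rna": {"fasta": None, "min_loop": 3, "allow_gu": False},
    "precision": 1,  # decimals when printing percentages
}


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _load_field(name: str, source_cfg: dict, master_seed: int) -> ParticleField:
    if "star" in source_cfg and source_cfg["star"]:
        return read_star(source_cfg["star"])
    seed = stage_seed(master_seed, f"simulate:{name}")
    overrides = dict(source_cfg.get("overrides", {}))
    overrides["seed"] = seed
    source = source_cfg.get("config", name)
    if isinstance(source, str) and source in CONDITIONS:
        cfg = load_condition_config(source, **overrides)
    else:
        cfg = FieldConfig.from_dict(_merge(yaml.safe_load(Path(source).read_text()), overrides))
    return simulate_field(cfg)


def run_pipeline(config: dict | None = None, seed: int = 0, outdir=None) -> dict:
    """Execute the full analysis; returns (and optionally writes) the report.

    The report bundles per-condition topology-class abundances, the
    state-by-topology composition table, condition deltas, the
    nearest-neighbor distance comparison, per-state occupancy, the
    collided-dimer fraction, and (if a FASTA is configured) the
    expansion-segment scan.
    """
    config = _merge(DEFAULT_RUN_CONFIG, config or {})
    chash = config_hash(config)
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    header = {
        "package": f"ribotopo {__version__}",
        "seed": int(seed),
        "config_hash": chash,
    }
    report: dict = {"header": header}
    timings: dict[str, float] = {}
    templates = load_template_library()

    def _run_stage(stage, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - stage-named rethrow
            if outdir is not None:
                _write_json(outdir / "report.json", report)
            raise StageError(stage, e) from e
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.2fs", stage, timings[stage])
        return result

    # --- fields -----------------------------------------------------------
    fields: dict[str, ParticleField] = {}
    for name, src in config["fields"].items():
        fields[name] = _run_stage(
            f"field:{name}", lambda name=name, src=src: _load_field(name, src, seed)
        )
        if outdir is not None:
            write_star(
                fields[name],
                outdir / f"particles_{name}.star",
                comment=f"seed={seed} config_hash={chash}",
            )

    # --- topology ---------------------------------------------------------
    topo_cfg = config["topology"]
    results = {}
    assignments = {}
    for name, f in fields.items():
        res = _run_stage(
            f"topology:{name}",
            lambda f=f: analyze_topology(
                f,
                templates,
                cutoff=topo_cfg["cutoff"],
                eps=topo_cfg["eps"],
                min_samples=topo_cfg["min_samples"],
                sigma_t=topo_cfg["sigma_t"],
                sigma_theta=topo_cfg["sigma_theta"],
                strict_fraction=topo_cfg["strict_fraction"],
            ),
        )
        results[name] = res
        assignments[name] = res.classification.particle_class
        if outdir is not None:
            tsv = f.df[["particle_id", "tomogram_id", "condition", "state_label"]].copy()
            tsv["topology_class"] = res.classification.particle_class.to_numpy()
            tsv.to_csv(outdir / f"assignments_{name}.tsv", sep="\t", index=False)

    ndec = int(config["precision"])
    report["topology"] = {}
    for name, res in results.items():
        cls = res.classification
        ab = cls.abundance
        report["topology"][name] = {
            "n_particles": int(len(fields[name])),
            "n_clusters": len(cls.clusters),
            "classified_percent": round(100 * cls.classified_fraction, ndec),
            "collided_percent": round(100 * res.collided_fraction, ndec),
            "class_abundance_percent": {
                row["topology_class"]: round(100 * row["fraction"], ndec)
                for _, row in ab.iterrows()
            },
            "clusters": [
                {
                    "cluster_id": c.cluster_id,
                    "class": c.assigned_class,
                    "n_pairs": c.n_pairs,
                    "is_c2": bool(c.is_c2),
                    "extendability": c.extendability,
                    "medoid_translation": [round(v, 3) for v in c.medoid_t.tolist()],
                    "medoid_quaternion": [round(v, 6) for v in c.medoid_q.tolist()],
                    "abundance": {k: round(100 * v, ndec) for k, v in c.abundance.items()},
                }
                for c in cls.clusters
            ],
        }

    # --- composition ------------------------------------------------------
    merged_df = pd.concat([f.df for f in fields.values()], ignore_index=True)
    merged = ParticleField(merged_df, validate=False)
    merged_assign = pd.concat(
        [assignments[n] for n in fields], ignore_index=True
    )
    table = _run_stage(
        "composition", lambda: composition_by_topology(merged, merged_assign)
    )
    report["composition"] = {
        f"{cond}/{cls}": {
            "n": int(row["n"]),
            **{
                s: round(100 * float(row[s]), ndec)
                for s in table.columns
                if s != "n"
            },
        }
        for (cond, cls), row in table.iterrows()
    }
    if set(fields) >= {"untreated", "treated"}:
        delta = _run_stage("condition_delta", lambda: condition_delta(table))
        report["condition_delta"] = {
            s: {
                "ratio": None if row["undefined"] else round(float(row["ratio"]), 3),
                "difference_percent": round(100 * float(row["difference"]), ndec),
                "undefined": bool(row["undefined"]),
            }
            for s, row in delta.iterrows()
        }
        nn = _run_stage(
            "nn_compare",
            lambda: nn_distance_compare(fields["untreated"], fields["treated"]),
        )
        nn_dict = nn.to_dict()
        if outdir is not None:
            _write_json(outdir / "nn_histograms.json", nn_dict)
        report["nn_compare"] = {
            k: nn_dict[k] for k in ("statistic", "pvalue", "n_a", "n_b", "median_a", "median_b")
        }

    occ_cfg = config["occupancy"]
    report["occupancy"] = {}
    for name, f in fields.items():
        occ = _run_stage(
            f"occupancy:{name}",
            lambda f=f: neighbor_occupancy(
                f, cone_deg=occ_cfg["cone_deg"], max_dist=occ_cfg["max_dist"]
            ),
        )
        report["occupancy"][name] = {
            s: {k: round(float(row[k]), 4) for k in ("entry_only", "exit_only", "both", "neither")}
            for s, row in occ.iterrows()
        }

    # --- RNA --------------------------------------------------------------
    if config["rna"].get("fasta"):
        scan = _run_stage(
            "rna_scan",
            lambda: species_scan(
                config["rna"]["fasta"],
                min_loop=config["rna"]["min_loop"],
                allow_gu=config["rna"]["allow_gu"],
            ),
        )
        if outdir is not None:
            scan.to_csv(outdir / "es_scan.tsv", sep="\t", index=False)
        report["rna_scan"] = scan.drop(columns=["dot_bracket"]).to_dict(orient="records")

    report["timings_s"] = timings
    if outdir is not None:
        _write_json(outdir / "report.json", report)
    return report


def _write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def summarize_report(report: dict) -> str:
    """Human-readable digest of the headline numbers."""
    lines = [f"ribotopo report (seed={report['header']['seed']})"]
    for name, topo in report.get("topology", {}).items():
        lines.append(
            f"  {name}: {topo['classified_percent']:.1f}% in the five topology "
            f"classes, {topo['collided_percent']:.1f}% stalled-collided"
        )
        for cls in FIVE_CLASSES:
            pct = topo["class_abundance_percent"].get(cls)
            if pct is not None:
                lines.append(f"    {cls:16s} {pct:6.1f}%")
    delta = report.get("condition_delta", {})
    if "idle" in delta and delta["idle"]["ratio"] is not None:
        lines.append(f"  idle fold-change treated/untreated: {delta['idle']['ratio']:.2f}")
    nn = report.get("nn_compare")
    if nn:
        lines.append(f"  NN-distance KS: D={nn['statistic']:.3f}, p={nn['pvalue']:.3g}")
    return "\n".join(lines)
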