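"""End-to-end pipeline driver: simulate → envelope → connect → mask →
stats → classify, with a YAML/JSON run configuration and a checksummed
run manifest for reproducibility.

The driver operates on synthetic cohorts (the package's study object);
each stage writes its outputs under the configured output directory and
records their SHA-256 checksums in ``manifest.json``.  Re-running with
an unchanged configuration skips stages whose outputs already match the
recorded checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .bands import COMBINED, BandSpec
from .classify import auc_permutation_p, loo_balanced_cv, pool_features
from .connectome import amplitude_correlation_matrix, combined_map, valid_edge_mask, zscore_connectome
from .envelope import subject_band_envelope
from .io import (
    load_cohort,
    save_cohort,
    save_connectomes,
    save_envelopes,
    write_edge_mask_tsv,
    write_json,
)
from .stats import group_stats
from .synthetic import CohortDesign, simulate_cohort

__all__ = ["RunConfig", "RunManifest", "run_pipeline"]


@dataclass
class RunConfig:
    """Parameters of one reproducible end-to-end run.

    Every stochastic stage has an explicit seed; configs without one are
    refused at validation so no run depends on hidden state.
    """

    design: dict  # CohortDesign keyword arguments (must include "seed")
    bands: list = field(
        default_factory=lambda: [
            ["Delta", 1.0, 4.0],
            ["Theta", 3.0, 8.0],
            ["Alpha", 8.0, 13.0],
            ["Beta", 13.0, 30.0],
            ["LowGamma", 40.0, 60.0],
            ["HighGamma", 60.0, 140.0],
        ]
    )
    pipeline: dict = field(
        default_factory=lambda: {
            "orthogonalize": True,
            "median_window": 5,
            "variance_normalize": True,
        }
    )
    mask_pct: float = 80.0
    stats: dict = field(
        default_factory=lambda: {
            "n_perm": 5000,
            "edge_alpha": 0.05,
            "frac": 0.5,
            "conf": 0.95,
            "n_iter": 5000,
            "seed": None,
        }
    )
    classifier: dict = field(
        default_factory=lambda: {
            "train_per_class": None,  # default: min group size - 2
            "n_iter": 1000,
            "n_perm": 0,  # label permutations for p (0 = skip)
            "cv_iter": 50,
            "C": 1.0,
            "seed": None,
        }
    )
    outdir: str = "envconn_run"

    def validate(self) -> None:
        if "seed" not in self.design or self.design["seed"] is None:
            raise ValueError("config missing design.seed")
        if self.stats.get("seed") is None:
            raise ValueError("config missing stats.seed")
        if self.classifier.get("seed") is None:
            raise ValueError("config missing classifier.seed")
        self.make_design()  # validates design parameters

    def band_specs(self) -> list[BandSpec]:
        return [BandSpec(str(n), float(lo), float(hi)) for n, lo, hi in self.bands]

    def make_design(self) -> CohortDesign:
        kw = dict(self.design)
        kw["effect_edges"] = [tuple(e) for e in kw.get("effect_edges", [])]
        return CohortDesign(bands=self.band_specs(), **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    """Checksummed record of one pipeline run."""

    config_hash: str
    version: str
    seeds: dict
    stages: dict  # stage -> {relative path -> sha256}
    timestamps: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_current(prev: dict | None, stage: str, outdir: Path) -> bool:
    """True if a previous manifest recorded this stage and every output
    file still exists with a matching checksum."""
    if not prev or stage not in prev.get("stages", {}):
        return False
    rec = prev["stages"][stage]
    return all((outdir / rel).exists() and _sha256(outdir / rel) == h for rel, h in rec.items())


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order and return the run manifest.

    Stage order: simulate → envelope → connect → mask → stats →
    classify.  Any stage failure propagates with the stage name in the
    exception message.  Stages whose outputs are unchanged since a
    previous run with the same configuration are skipped.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    (outdir / "stats").mkdir(exist_ok=True)

    manifest_path = outdir / "manifest.json"
    prev = None
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") != config.config_hash():
            prev = None  # config changed: recompute everything

    design = config.make_design()
    stages: dict[str, dict[str, str]] = {}
    timestamps: dict[str, float] = {}

    def record(stage: str, paths: list[Path]) -> None:
        stages[stage] = {str(p.relative_to(outdir)): _sha256(p) for p in paths}
        timestamps[stage] = time.time()

    def run_stage(stage: str, paths: list[Path], fn) -> bool:
        """Returns True if the stage was skipped (outputs current)."""
        if _stage_current(prev, stage, outdir):
            stages[stage] = prev["stages"][stage]
            timestamps[stage] = prev["timestamps"].get(stage, time.time())
            return True
        try:
            fn()
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {stage!r} failed (design seed {design.seed}): {exc}"
            ) from exc
        record(stage, paths)
        return False

    # -- simulate -----------------------------------------------------
    cohort_path = outdir / "cohort.h5"
    truth_path = outdir / "truth.json"

    def do_simulate():
        recs, truth = simulate_cohort(design)
        save_cohort(recs, cohort_path)
        write_json(
            {
                "effect_edges": [list(e) for e in truth.effect_edges],
                "effect_size": truth.effect_size,
                "subject_seeds": truth.subject_seeds,
            },
            truth_path,
        )

    run_stage("simulate", [cohort_path, truth_path], do_simulate)
    recordings = load_cohort(cohort_path)

    # -- envelope -----------------------------------------------------
    env_path = outdir / "envelopes.h5"
    bands = config.band_specs()
    env_sets_by_band: dict[str, list] = {}

    def do_envelope():
        all_sets = []
        for rec in recordings:
            for band in bands:
                es = subject_band_envelope(
                    rec,
                    band,
                    orthogonalize=config.pipeline["orthogonalize"],
                    median_window=config.pipeline["median_window"],
                )
                all_sets.append(es)
        save_envelopes(all_sets, env_path)

    run_stage("envelope", [env_path], do_envelope)
    from .io import load_envelopes

    for es in load_envelopes(env_path):
        name = es.band.name if isinstance(es.band, BandSpec) else str(es.band)
        env_sets_by_band.setdefault(name, []).append(es)

    # -- connect ------------------------------------------------------
    conn_path = outdir / "connectomes.h5"
    band_names = [b.name for b in bands]

    def do_connect():
        conns = []
        by_subject: dict[str, list] = {}
        for name in band_names:
            for es in env_sets_by_band[name]:
                c = zscore_connectome(
                    amplitude_correlation_matrix(
                        es, variance_normalize=config.pipeline["variance_normalize"]
                    )
                )
                conns.append(c)
                by_subject.setdefault(es.subject_id, []).append(c)
        if len(band_names) == 6:
            for sid, six in by_subject.items():
                conns.append(combined_map(six))
        save_connectomes(conns, conn_path)

    run_stage("connect", [conn_path], do_connect)
    from .io import load_connectomes

    conns_by_band: dict[str, list] = {}
    for c in load_connectomes(conn_path):
        conns_by_band.setdefault(c.band, []).append(c)
    map_names = band_names + ([COMBINED] if COMBINED in conns_by_band else [])

    group_of = {r.subject_id: r.group for r in recordings}
    case_ids = [r.subject_id for r in recordings if r.group == "case"]
    ctrl_ids = [r.subject_id for r in recordings if r.group == "control"]

    # -- mask ---------------------------------------------------------
    mask_paths = {
        name: outdir / "masks" / f"{name}.tsv" for name in map_names
    }
    pooled_paths = {
        name: outdir / "masks" / f"{name}_pooled.tsv" for name in map_names
    }

    def do_mask():
        for name in map_names:
            conns = conns_by_band[name]
            cases = [c for c in conns if group_of[c.subject_id] == "case"]
            ctrls = [c for c in conns if group_of[c.subject_id] == "control"]
            union = valid_edge_mask([cases, ctrls], config.mask_pct, band=name)
            pooled = valid_edge_mask([conns], config.mask_pct, band=name)
            write_edge_mask_tsv(union, mask_paths[name], design.node_labels)
            write_edge_mask_tsv(pooled, pooled_paths[name], design.node_labels)

    run_stage("mask", list(mask_paths.values()) + list(pooled_paths.values()), do_mask)
    from .io import read_edge_mask_tsv

    union_masks = {name: read_edge_mask_tsv(p) for name, p in mask_paths.items()}
    pooled_masks = {name: read_edge_mask_tsv(p) for name, p in pooled_paths.items()}

    # -- stats --------------------------------------------------------
    stat_paths = [outdir / "stats" / f"{name}.json" for name in map_names]

    def do_stats():
        st = config.stats
        rng = np.random.default_rng(st["seed"])
        for name in map_names:
            conns = conns_by_band[name]
            ga = [c for c in conns if group_of[c.subject_id] == "case"]
            gb = [c for c in conns if group_of[c.subject_id] == "control"]
            res = group_stats(
                ga,
                gb,
                union_masks[name],
                band=name,
                n_perm=st["n_perm"],
                edge_alpha=st["edge_alpha"],
                frac=st["frac"],
                conf=st["conf"],
                n_iter=st["n_iter"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            write_json(
                {
                    "band": name,
                    "n_valid_edges": union_masks[name].n_edges,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "n_corr_sig": int(np.nansum(res.p_corr < 0.05) // 2),
                    "clusters": {
                        str(s): {
                            "size_edges": c.size_edges,
                            "size_nodes": c.size_nodes,
                            "p": c.p,
                            "edges": c.edges,
                        }
                        for s, c in res.clusters.items()
                    },
                    "n_ci_pos": int((np.triu(res.ci_edges, 1) == 1).sum()),
                    "n_ci_neg": int((np.triu(res.ci_edges, 1) == -1).sum()),
                    "params": res.params,
                },
                outdir / "stats" / f"{name}.json",
            )

    run_stage("stats", stat_paths, do_stats)

    # -- classify -----------------------------------------------------
    report_path = outdir / "classifier_report.json"

    def do_classify():
        cl = config.classifier
        subjects = [r.subject_id for r in recordings]
        labels = [group_of[s] for s in subjects]
        aligned = {
            name: sorted(conns_by_band[name], key=lambda c: subjects.index(c.subject_id))
            for name in map_names
        }
        table = pool_features(aligned, pooled_masks, subjects, labels)
        tpc = cl["train_per_class"]
        if tpc is None:
            tpc = max(2, min(len(case_ids), len(ctrl_ids)) - 2)
        rep = loo_balanced_cv(
            table, train_per_class=tpc, n_iter=cl["n_iter"], C=cl["C"], seed=cl["seed"]
        )
        if cl["n_perm"]:
            rep.p_perm = auc_permutation_p(
                table,
                rep.auc,
                train_per_class=tpc,
                n_perm=cl["n_perm"],
                cv_iter=cl["cv_iter"],
                C=cl["C"],
                seed=cl["seed"],
            )
        write_json(
            {
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
                "auc": rep.auc,
                "p_perm": rep.p_perm,
                "n_iter": rep.n_iter,
                "n_features": len(table.feature_index),
                "train_per_class": tpc,
                "seed": cl["seed"],
            },
            report_path,
        )

    run_stage("classify", [report_path], do_classify)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        seeds={
            "design": design.seed,
            "stats": config.stats["seed"],
            "classifier": config.classifier["seed"],
        },
        stages=stages,
        timestamps=timestamps,
    )
    write_json(manifest.to_dict(), manifest_path)
    return manifest
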