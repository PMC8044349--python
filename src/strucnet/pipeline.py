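"""Pipeline orchestration: simulate -> build -> metrics -> compare -> nbs -> roc.

A :class:`RunConfig` fixes every stage parameter and the master seed; a run
writes, under its output directory, the cohort bundle, per-subject binary
adjacency matrices, the subject-level metric table, study-style comparison
tables, NBS edge lists with component ids and FWER p-values, group
mean-difference matrices, ROC tables, the echoed config, and a run log.
Identical config + seed reproduces the output tree byte-for-byte (the run
log, which carries wall-clock timestamps, is excluded from the
reproducibility hash).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as snio
from .cohort import CohortSpec, generate_cohort, manifest_frame
from .groupstats import compare_groups, compute_metric_table, roc_auc
from .nbs import NBSParams, design_from_manifest, nbs_test
from .tracto import build_connectome

__all__ = ["RunConfig", "RunLog", "run_pipeline", "tree_hash"]

STAGES = ("simulate", "build", "metrics", "compare", "nbs", "roc")


@dataclass
class RunConfig:
    """All pipeline knobs in one serializable object."""

    output_dir: str = "strucnet_run"
    seed: int = 42
    stages: tuple[str, ...] = STAGES
    # cohort
    n_per_group: dict = field(default_factory=lambda: {"AD": 31, "SIVD": 19, "NC": 17})
    n_nodes: int = 90
    n_modules: int = 6
    intra_module_edge_prob: float = 0.4
    inter_module_edge_prob: float = 0.015
    count_mean: float = 30.0
    count_dispersion: float = 2.0
    count_noise_sigma: float = 0.25
    # connectome
    fiber_threshold: int = 3
    # metrics
    n_null: int = 100
    # comparison
    contrasts: tuple = (("AD", "NC"), ("SIVD", "NC"), ("AD", "SIVD"))
    covariates: tuple = ("age", "sex", "education")
    alpha_metrics: float = 0.001
    threshold_on_adjusted: bool = True
    # NBS
    nbs_contrasts: tuple = (("AD", "NC"), ("SIVD", "NC"))
    nbs_tails: tuple = ("decrease", "increase")
    primary_t_threshold: float = 3.0
    n_permutations: int = 5000
    nbs_alpha: float = 0.05

    @classmethod
    def demo(cls, output_dir: str = "strucnet_demo", seed: int = 42) -> "RunConfig":
        """Small configuration for fast, fully deterministic demonstration runs."""
        return cls(
            output_dir=output_dir,
            seed=seed,
            n_per_group={"AD": 8, "SIVD": 8, "NC": 8},
            n_null=20,
            n_permutations=200,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        cfg = cls(**raw)
        cfg.stages = tuple(cfg.stages)
        cfg.contrasts = tuple(tuple(c) for c in cfg.contrasts)
        cfg.nbs_contrasts = tuple(tuple(c) for c in cfg.nbs_contrasts)
        cfg.nbs_tails = tuple(cfg.nbs_tails)
        cfg.covariates = tuple(cfg.covariates)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d.pop("output_dir")  # where the bundle lives, not part of its content
        d["stages"] = list(d["stages"])
        d["contrasts"] = [list(c) for c in d["contrasts"]]
        d["nbs_contrasts"] = [list(c) for c in d["nbs_contrasts"]]
        d["nbs_tails"] = list(d["nbs_tails"])
        d["covariates"] = list(d["covariates"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            n_per_group=dict(self.n_per_group),
            n_nodes=self.n_nodes,
            n_modules=self.n_modules,
            intra_module_edge_prob=self.intra_module_edge_prob,
            inter_module_edge_prob=self.inter_module_edge_prob,
            count_mean=self.count_mean,
            count_dispersion=self.count_dispersion,
            count_noise_sigma=self.count_noise_sigma,
            seed=self.seed,
        )


@dataclass
class RunLog:
    events: list = field(default_factory=list)

    def add(self, stage: str, message: str, **extra) -> None:
        self.events.append(
            {
                "time": _dt.datetime.now(_dt.timezone.utc).isoformat(),
                "stage": stage,
                "message": message,
                **extra,
            }
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"events": self.events}, indent=1), encoding="utf-8"
        )


class StageError(RuntimeError):
    pass


def tree_hash(directory: str | Path, exclude: Sequence[str] = ("run.log.json",)) -> str:
    """SHA-256 over (relative path, content) of every file in the tree,
    excluding the run log by default."""
    directory = Path(directory)
    h = hashlib.sha256()
    for p in sorted(directory.rglob("*")):
        if p.is_file() and p.name not in exclude:
            h.update(str(p.relative_to(directory)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def _echo(cfg: RunConfig) -> dict:
    return {
        "seed": cfg.seed,
        "fiber_threshold": cfg.fiber_threshold,
        "n_null": cfg.n_null,
        "t_thresh": cfg.primary_t_threshold,
        "n_perm": cfg.n_permutations,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the toggled stages; returns a result bundle of in-memory
    objects (subjects, metric table, comparison tables, NBS results)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log = RunLog()
    bundle: dict = {"config": config}
    spec = config.cohort_spec()
    labels = spec.node_labels()
    echo = _echo(config)

    try:
        if "simulate" in config.stages:
            log.add("simulate", "generating cohort", seed=config.seed)
            subjects, truth = generate_cohort(spec)
            snio.write_cohort(
                out / "cohort", subjects, labels, truth, config.fiber_threshold
            )
            bundle["subjects"] = subjects
            bundle["ground_truth"] = truth
            bundle["manifest"] = manifest_frame(subjects)

        if "build" in config.stages:
            if "subjects" not in bundle:
                raise StageError("[build] missing cohort input (enable 'simulate')")
            adj_dir = out / "adjacency"
            adj_dir.mkdir(exist_ok=True)
            for s in bundle["subjects"]:
                conn = build_connectome(s.counts, config.fiber_threshold, labels)
                snio.write_matrix_tsv(
                    adj_dir / f"{s.subject_id}.tsv", conn.adjacency, labels, echo
                )
            log.add("build", "adjacency matrices written",
                    n=len(bundle["subjects"]))

        if "metrics" in config.stages:
            if "subjects" not in bundle:
                raise StageError("[metrics] missing cohort input (enable 'simulate')")
            log.add("metrics", "computing metric table",
                    n_null=config.n_null, seed=config.seed + 1)
            table = compute_metric_table(
                bundle["subjects"],
                fiber_threshold=config.fiber_threshold,
                n_null=config.n_null,
                seed=config.seed + 1,
            )
            bundle["metric_table"] = table
            tout = table.copy()
            with open(out / "metrics.tsv", "w", encoding="utf-8") as fh:
                for k, v in echo.items():
                    fh.write(f"# {k}={v}\n")
                tout.to_csv(fh, sep="\t", float_format="%.6g", lineterminator="\n")

        if "compare" in config.stages:
            if "metric_table" not in bundle:
                raise StageError("[compare] missing metrics input (enable 'metrics')")
            comp = compare_groups(
                bundle["metric_table"],
                bundle["manifest"],
                contrasts=config.contrasts,
                covariates=config.covariates,
                alpha=config.alpha_metrics,
                threshold_on_adjusted=config.threshold_on_adjusted,
            )
            bundle["comparisons"] = comp
            cmp_dir = out / "compare"
            cmp_dir.mkdir(exist_ok=True)
            for (g1, g2), df in comp.items():
                for family in ("global", "nodal"):
                    sub = df[df["family"] == family].drop(columns="family")
                    path = cmp_dir / f"{family}_{g1}_vs_{g2}.tsv"
                    with open(path, "w", encoding="utf-8") as fh:
                        for k, v in echo.items():
                            fh.write(f"# {k}={v}\n")
                        sub.to_csv(fh, sep="\t", float_format="%.6g",
                                   lineterminator="\n")
            log.add("compare", "comparison tables written",
                    contrasts=[list(c) for c in config.contrasts])

        if "nbs" in config.stages:
            if "subjects" not in bundle:
                raise StageError("[nbs] missing cohort input (enable 'simulate')")
            nbs_dir = out / "nbs"
            nbs_dir.mkdir(exist_ok=True)
            manifest = bundle["manifest"]
            stack = np.stack([s.counts for s in bundle["subjects"]])
            bundle["nbs"] = {}
            for ci, contrast in enumerate(config.nbs_contrasts):
                design, rows = design_from_manifest(
                    manifest, contrast, config.covariates
                )
                g1, g2 = contrast
                # group-mean difference matrix (figure-style analogue)
                in1 = manifest["group"].to_numpy() == g1
                in2 = manifest["group"].to_numpy() == g2
                diff = stack[in1].mean(axis=0) - stack[in2].mean(axis=0)
                snio.write_matrix_tsv(
                    nbs_dir / f"diff_{g1}_vs_{g2}.tsv", diff, labels, echo
                )
                for ti, tail in enumerate(config.nbs_tails):
                    params = NBSParams(
                        primary_t_threshold=config.primary_t_threshold,
                        n_permutations=config.n_permutations,
                        alpha=config.nbs_alpha,
                        tail=tail,
                        seed=config.seed + 100 + 10 * ci + ti,
                        fiber_threshold=config.fiber_threshold,
                    )
                    log.add("nbs", f"{g1} vs {g2} ({tail})", seed=params.seed,
                            n_perm=params.n_permutations)
                    res = nbs_test(stack[rows], design, params)
                    bundle["nbs"][(contrast, tail)] = res
                    rows_out = []
                    for k, comp_ in enumerate(res.components):
                        for a, b in comp_.edges:
                            rows_out.append(
                                {
                                    "node_a": labels[a],
                                    "node_b": labels[b],
                                    "component": k,
                                    "component_size": comp_.size,
                                    "p_fwer": comp_.p_value,
                                    "t": res.t_matrix[a, b],
                                }
                            )
                    edf = pd.DataFrame(
                        rows_out,
                        columns=["node_a", "node_b", "component",
                                 "component_size", "p_fwer", "t"],
                    )
                    path = nbs_dir / f"edges_{g1}_vs_{g2}_{tail}.tsv"
                    with open(path, "w", encoding="utf-8") as fh:
                        for k, v in echo.items():
                            fh.write(f"# {k}={v}\n")
                        fh.write(f"# tail={tail}\n")
                        edf.to_csv(fh, sep="\t", index=False,
                                   float_format="%.6g", lineterminator="\n")

        if "roc" in config.stages:
            if "comparisons" not in bundle or "metric_table" not in bundle:
                raise StageError("[roc] missing compare input (enable 'compare')")
            roc_dir = out / "roc"
            roc_dir.mkdir(exist_ok=True)
            manifest = bundle["manifest"].set_index("subject_id")
            table = bundle["metric_table"]
            bundle["roc"] = {}
            for (g1, g2), df in bundle["comparisons"].items():
                nodes = [
                    m for m in df.index
                    if m.startswith("bc_") and bool(df.loc[m, "significant"])
                ]
                rows_out = []
                for m in nodes:
                    sel = manifest["group"].isin([g1, g2])
                    scores = table.loc[sel.to_numpy(), m].to_numpy(float)
                    lab = (manifest.loc[sel, "group"] == g1).to_numpy(int)
                    r = roc_auc(scores, lab)
                    rows_out.append(
                        {"node": m, "auc": r.auc, "flipped": r.flipped,
                         "n_pos": r.n_pos, "n_neg": r.n_neg}
                    )
                    bundle["roc"][((g1, g2), m)] = r
                rdf = pd.DataFrame(
                    rows_out, columns=["node", "auc", "flipped", "n_pos", "n_neg"]
                )
                path = roc_dir / f"roc_{g1}_vs_{g2}.tsv"
                with open(path, "w", encoding="utf-8") as fh:
                    for k, v in echo.items():
                        fh.write(f"# {k}={v}\n")
                    rdf.to_csv(fh, sep="\t", index=False,
                               float_format="%.6g", lineterminator="\n")
            log.add("roc", "ROC tables written")
    except StageError:
        log.write(out / "run.log.json")
        raise
    except Exception as exc:  # tag unexpected errors with the active stage
        log.write(out / "run.log.json")
        raise StageError(f"pipeline failed: {exc}") from exc

    log.add("done", "pipeline complete")
    log.write(out / "run.log.json")
    return bundle
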