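"""End-to-end orchestration with a serializable run configuration.

Two execution modes:

* **matrix mode** — the full pipeline from an expression matrix:
  normalization, sliding-window screen, trajectory analysis, two-group
  differential expression, screen comparison, candidate cascade, and
  (when the inputs are provided) target enrichment and qPCR validation.
* **fixtures mode** — set algebra, classification checks and the
  candidate cascade over the packaged printed result tables, requiring
  no expression matrix at all.

Every stage writes its TSV next to a ``summary.json`` holding the run's
headline counts; identical configurations (and seeds) produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fixtures as fx
from . import io as atio
from .diffexp import DifferentialExpression
from .integration import candidate_filter, set_overlap, short_name
from .model import ValidationError
from .preprocess import quantile_normalize
from .qpcr import RelativeQuantification
from .simulate import TrendSimConfig, generate_cohort
from .trajectory import analyze_trajectories
from .window import SlidingWindowScreen

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters, YAML round-trippable."""

    mode: str = "matrix"  # matrix | fixtures | synthetic
    matrix: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    gmt: str | None = None
    mti: str | None = None
    cq: str | None = None
    out_dir: str = "agetrend_run"
    normalize: bool = True
    window_size: int = 10
    step: int = 1
    r_threshold: float = 0.75
    fc_threshold: float = 1.5
    n_windows: int | None = None
    drop_last: bool = False
    cutoff: float = 50.0
    alpha: float = 0.05
    fc_cut: float = 2.0
    fdr: float = 0.05
    top_k: int = 20
    quantile: float = 0.75
    reference_assay: str = "miR-191"
    seed: int = 0
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _classify_probe(probeset: str) -> str:
    return "miRNA" if probeset.startswith("hsa-") else "snoRNA"


def fixtures_summary(fc_cut: float = 2.0) -> dict:
    """Headline counts recomputed from the packaged printed tables.

    Reruns the screen's classification rule over the correlation table's
    (R, FC) columns, the UP/DOWN rule over the differential table, the
    per-class screen overlap and the two-stage candidate cascade.
    """
    t1 = fx.load_fixture("table1")
    t2 = fx.load_fixture("table2")
    prior = fx.load_prior_aging_set()

    t1_mirna = t1[t1["probeset"].str.startswith("hsa-")]
    inc = t1[t1["pearson_r"] > 0]
    dec = t1[t1["pearson_r"] < 0]

    t2_mirna = t2[t2["probeset"].str.startswith("hsa-")]
    up = t2[t2["fc_elder_young"] > 1]
    down = t2[t2["fc_elder_young"] < 1]

    overlap = set_overlap(t1["probeset"], t2["probeset"])
    mi = overlap.row("miRNA")
    sno = overlap.row("snoRNA")

    trend_table = t1.rename(columns={"type": "sncRNA_class"}).assign(
        trend=np.where(t1["pearson_r"] > 0, "increasing", "decreasing")
    )
    stage1, stage2 = candidate_filter(trend_table, prior, fc_cut=fc_cut)

    return {
        "table1_total": int(len(t1)),
        "table1_mirna": int(len(t1_mirna)),
        "table1_snorna": int(len(t1) - len(t1_mirna)),
        "table1_increasing": int(len(inc)),
        "table1_decreasing": int(len(dec)),
        "table2_total": int(len(t2)),
        "table2_mirna": int(len(t2_mirna)),
        "table2_snorna": int(len(t2) - len(t2_mirna)),
        "table2_up": int(len(up)),
        "table2_down": int(len(down)),
        "mirna_intersection": int(mi["intersection"]),
        "mirna_union": int(mi["union"]),
        "mirna_pct_overlap_of_union": float(round(mi["pct_overlap_of_union"], 1)),
        "snorna_intersection": int(sno["intersection"]),
        "snorna_union": int(sno["union"]),
        "candidates_stage1": int(len(stage1)),
        "candidates_stage2": int(len(stage2)),
        "candidate_names": sorted(short_name(p) for p in stage2),
    }


def run_full(config: RunConfig) -> dict:
    """Run the configured pipeline end to end; returns the summary dict.

    Any stage failure aborts the run with the stage named in the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"mode": config.mode, "seed": config.seed}
    t_start = time.perf_counter()

    if config.mode == "fixtures":
        summary.update(_stage("fixtures", fixtures_summary, config.fc_cut))
        _write_summary(summary, out)
        return summary
    if config.mode not in ("matrix", "synthetic"):
        raise ValidationError(f"unknown mode {config.mode!r}")

    if config.mode == "synthetic":
        sim_cfg = TrendSimConfig(seed=config.seed, **config.sim)
        matrix, metadata, truth = _stage("simulate", generate_cohort, sim_cfg)
        atio.write_table(truth, out / "truth.tsv")
    else:
        if config.matrix is None or config.metadata is None:
            missing = "matrix" if config.matrix is None else "metadata"
            raise ValidationError(f"matrix mode requires the {missing!r} field")
        matrix, metadata, annotation = _stage(
            "read", atio.read_expression, config.matrix, config.metadata,
            config.annotation,
        )
        if annotation is not None:
            from .preprocess import filter_probes

            matrix = _stage("filter", filter_probes, matrix, annotation)

    if config.normalize:
        matrix = _stage("normalize", quantile_normalize, matrix)

    screen = SlidingWindowScreen(
        window_size=config.window_size,
        step=config.step,
        r_threshold=config.r_threshold,
        fc_threshold=config.fc_threshold,
        n_windows=config.n_windows,
        drop_last=config.drop_last,
    )
    _stage("screen", screen.fit, matrix, metadata)
    trend = screen.trend_table_
    atio.write_table(trend, out / "trend_table.tsv")
    n_inc = int((trend["trend"] == "increasing").sum())
    n_dec = int((trend["trend"] == "decreasing").sum())
    summary["n_increasing"] = n_inc
    summary["n_decreasing"] = n_dec

    if n_inc and n_dec:
        pair, crossing = _stage(
            "trajectory",
            analyze_trajectories,
            screen.zscores_,
            trend,
            screen.windows_.mean_ages,
            config.quantile,
        )
        atio.write_table(pair.to_frame(), out / "trajectory.tsv")
        report = {
            "crossing_ages": crossing.crossing_ages,
            "primary_crossing": crossing.primary_crossing,
            "acceleration_interval": crossing.acceleration_interval,
            "flat_slope": crossing.flat_slope,
        }
        (out / "crossing.json").write_text(json.dumps(report, indent=2) + "\n")
        summary["primary_crossing_age"] = crossing.primary_crossing
        summary["acceleration_interval"] = crossing.acceleration_interval

    de = DifferentialExpression(cutoff=config.cutoff, alpha=config.alpha)
    _stage("diffexp", de.fit, matrix, metadata)
    atio.write_table(de.de_table_, out / "de_table.tsv")
    summary["n_up"] = int((de.de_table_["direction"] == "UP").sum())
    summary["n_down"] = int((de.de_table_["direction"] == "DOWN").sum())

    screened = trend.loc[trend["trend"] != "none", "probeset"]
    de_hits = de.de_table_.loc[de.de_table_["direction"] != "none", "probeset"]
    overlap = _stage("compare", set_overlap, screened, de_hits)
    atio.write_table(overlap.table, out / "overlap.tsv")
    summary["screen_de_intersection"] = int(overlap.table["intersection"].sum())
    summary["screen_de_union"] = int(overlap.table["union"].sum())

    prior = fx.load_prior_aging_set()
    stage1, stage2 = _stage(
        "candidates", candidate_filter, trend, prior, config.fc_cut
    )
    (out / "candidates.json").write_text(
        json.dumps({"stage1": stage1, "stage2": stage2}, indent=2) + "\n"
    )
    summary["candidates_stage1"] = len(stage1)
    summary["candidates_stage2"] = len(stage2)

    if config.gmt and config.mti:
        from .integration import enrich, filter_mti

        gmt = atio.read_gmt(config.gmt)
        mti = atio.read_mti(config.mti)
        directions = dict(
            zip(
                trend.loc[trend["trend"] != "none", "probeset"],
                trend.loc[trend["trend"] != "none", "trend"],
            )
        )
        mirna_dirs = {
            p: d for p, d in directions.items() if _classify_probe(p) == "miRNA"
        }
        targets = _stage(
            "targets", filter_mti, mti, mirna_dirs, "strong", fx.load_alias_table()
        )
        for direction, genes in targets.items():
            if not genes:
                continue
            result = _stage(
                "enrich", enrich, genes, gmt, None, config.fdr, config.top_k
            )
            atio.write_table(result, out / f"enrichment_{direction}.tsv")
            summary[f"n_enriched_{direction}"] = int(len(result))

    if config.cq:
        cq = atio.read_cq(config.cq)
        rq = RelativeQuantification(
            reference_assay=config.reference_assay, cutoff=config.cutoff
        )
        _stage("qpcr", rq.fit, cq, metadata)
        atio.write_table(rq.results_, out / "rq_table.tsv")
        summary["rq"] = {
            row["target"]: round(float(row["rq"]), 4)
            for _, row in rq.results_.iterrows()
        }

    summary["elapsed_s"] = round(time.perf_counter() - t_start, 3)
    _write_summary(summary, out)
    return summary


def _stage(name: str, fn, *args):
    t0 = time.perf_counter()
    try:
        result = fn(*args)
    except Exception as exc:
        raise ValidationError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
    return result


def _write_summary(summary: dict, out: Path) -> None:
    clean = {k: v for k, v in summary.items() if k != "elapsed_s"}
    (out / "summary.json").write_text(json.dumps(clean, indent=2, sort_keys=True) + "\n")
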