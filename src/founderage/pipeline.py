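"""End-to-end analysis orchestration.

``run_pipeline`` chains parse → shared core → founder inference → block
partition → sharing counts → family derivations → segment lengths →
age estimation into a single serializable :class:`AnalysisReport`;
``reproduce_study`` runs it on the packaged carrier table and block
inputs.  Stages are logged to standard error with timings; a failure in
any stage aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import fixtures
from .age import (
    GENERATION_YEARS,
    NotEstimableError,
    age_table,
    gamma_age,
)
from .haplotype import (
    CENSORING_CONVENTIONS,
    derive_family_events,
    find_shared_core,
    infer_founder,
    partition_blocks,
    segment_lengths,
)
from .markers import parse_marker_table

logger = logging.getLogger("founderage")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    marker_table: str | None = None  # None -> packaged carrier table
    block_inputs: str | None = None  # None -> packaged per-block inputs
    cm_per_mb: float = 1.0
    mu: float = 1e-8
    generation_years: float = GENERATION_YEARS
    bootstrap: int = 0
    seed: int = 0
    censoring: str = "midpoint"

    def __post_init__(self) -> None:
        for name in ("cm_per_mb", "generation_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu < 0 or self.bootstrap < 0:
            raise ValueError("mu and bootstrap must be non-negative")
        if self.censoring not in CENSORING_CONVENTIONS:
            raise ValueError(f"unknown censoring convention {self.censoring!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class AnalysisReport:
    config: dict
    core: dict
    founder: dict
    blocks: list[dict]
    tail_markers: list[str]
    families: list[dict]
    ages: list[dict]
    gamma: dict
    summary: dict

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        text = json.dumps(self.__dict__, indent=indent, default=_jsonify)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))

    @classmethod
    def from_json_file(cls, path: str | Path) -> "AnalysisReport":
        return cls.from_json(Path(path).read_text())

    def block_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.blocks)

    def age_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ages)

    def to_tsv(self, path: str | Path) -> None:
        """Block table, one row per block in genomic label order."""
        self.block_frame().to_csv(path, sep="\t", index=False)

    def to_text(self) -> str:
        lines = [
            "Founder-mutation haplotype analysis",
            f"  shared core: {self.core['start_rsid']}..{self.core['stop_rsid']}"
            f" ({self.core['n_markers']} markers)",
            f"  families: {len(self.families)}, max recombination events "
            f"{max(f['n_events'] for f in self.families)}",
            "",
            f"{'block':>16} {'n_snps':>6} {'theta':>8} {'shared':>6} "
            f"{'age EM':>7} {'age CHM':>8}",
        ]
        ages = {
            (a["label_rsid"], a["source"]): a["risch_rounded"]
            for a in self.ages
        }
        for b in self.blocks:
            em = ages.get((b["label_rsid"], "EM"), "")
            chm = ages.get((b["label_rsid"], "CHM"), "")
            lines.append(
                f"{b['label_rsid']:>16} {b['n_markers']:>6} "
                f"{b['theta']:>8.5f} {b['shared_chromosomes']:>6} "
                f"{'' if em is None else em:>7} "
                f"{'' if chm is None else chm:>8}"
            )
        s = self.summary
        if s.get("min_generations") is not None:
            lines.append(
                f"\nage range: {s['min_generations']}-{s['max_generations']} "
                f"generations (~{s['min_years']:.0f}-{s['max_years']:.0f} "
                "years)"
            )
            lines.append(
                f"gamma (independent): {self.gamma['independent']['generations']:.1f} "
                f"({self.gamma['independent']['ci_low']:.1f}-"
                f"{self.gamma['independent']['ci_high']:.1f}); "
                f"(correlated): {self.gamma['correlated']['generations']:.1f} "
                f"({self.gamma['correlated']['ci_low']:.1f}-"
                f"{self.gamma['correlated']['ci_high']:.1f})"
            )
        else:
            lines.append("\nno block estimable by the decay formula")
        return "\n".join(lines)


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if obj is pd.NA or (isinstance(obj, float) and pd.isna(obj)):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage(name: str):
    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                logger.error("stage %s: failed after %.2fs", name, dt)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Stage()


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Run the full analysis and return a serializable report.

    Deterministic given ``config.seed`` (used by bootstrap resampling)."""
    with _stage("parse"):
        if config.marker_table is None:
            mm, matrix = fixtures.table1_fixture(cm_per_mb=config.cm_per_mb)
        else:
            mm, matrix = parse_marker_table(
                config.marker_table, cm_per_mb=config.cm_per_mb
            )
        if config.block_inputs is None:
            block_inputs = fixtures.table2_inputs()
        else:
            block_inputs = pd.read_csv(config.block_inputs, sep="\t")

    with _stage("core"):
        core = find_shared_core(matrix, mm)
    with _stage("founder"):
        founder = infer_founder(matrix, mm, core)
    with _stage("blocks"):
        partition = partition_blocks(matrix, mm, founder)
    with _stage("events"):
        derivations = derive_family_events(matrix, founder, mm)
    with _stage("segments"):
        segments = segment_lengths(
            matrix, founder, mm, censoring=config.censoring
        )

    with _stage("ages"):
        # recompute theta and P_D from the carrier table; control-panel
        # frequencies (Fn) come from the block-input table
        fn = block_inputs.set_index("label_rsid")
        rows = []
        for b in partition.blocks:
            row = {
                "label_rsid": b.label_rsid,
                "shared_chromosomes": b.shared_chromosomes,
                "theta": b.theta,
                "fn_em": float("nan"),
                "fn_chm": float("nan"),
            }
            if b.label_rsid in fn.index:
                row["fn_em"] = fn.loc[b.label_rsid, "fn_em"]
                row["fn_chm"] = fn.loc[b.label_rsid, "fn_chm"]
            rows.append(row)
        ages, summary = age_table(
            pd.DataFrame(rows),
            n_chromosomes=matrix.n_chromosomes,
            mu=config.mu,
            bootstrap=config.bootstrap,
            seed=config.seed,
            generation_years=config.generation_years,
        )
        gamma = {}
        for genealogy in ("independent", "correlated"):
            try:
                est = gamma_age(segments, genealogy=genealogy)
                gamma[genealogy] = {
                    "generations": est.generations,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            except NotEstimableError as exc:
                gamma[genealogy] = {"error": str(exc)}

    return AnalysisReport(
        config={
            "cm_per_mb": config.cm_per_mb,
            "mu": config.mu,
            "generation_years": config.generation_years,
            "bootstrap": config.bootstrap,
            "seed": config.seed,
            "censoring": config.censoring,
        },
        core={
            "start_rsid": mm.rsids[core.start],
            "stop_rsid": mm.rsids[core.stop - 1],
            "start_index": core.start,
            "stop_index": core.stop - 1,
            "n_markers": len(core),
        },
        founder={
            "alleles": "".join(founder.alleles),
            "tie_markers": [mm.rsids[i] for i in founder.tie_indices],
        },
        blocks=[
            {
                "label_rsid": b.label_rsid,
                "n_markers": b.n_markers,
                "theta": b.theta,
                "shared_chromosomes": b.shared_chromosomes,
                "is_focal": b.is_focal,
                "is_distal": b.is_distal,
            }
            for b in partition.blocks
        ],
        tail_markers=[mm.rsids[i] for i in partition.tail_indices],
        families=[
            {
                "family_id": d.family_id,
                "n_events": d.n_events,
                "level": d.level,
                "shared_ancestor_group": d.shared_ancestor_group,
                "left_breakpoint": d.left_breakpoint,
                "right_breakpoint": d.right_breakpoint,
                "data_errors": d.data_errors,
            }
            for d in derivations
        ],
        ages=[{k: (None if pd.isna(v) else v) for k, v in row.items()}
              for row in age_table_records(ages)],
        gamma=gamma,
        summary=summary,
    )


def age_table_records(ages: pd.DataFrame) -> list[dict]:
    return ages.to_dict(orient="records")


def reproduce_study(
    seed: int = 0, bootstrap: int = 0, **overrides
) -> AnalysisReport:
    """One-call reproduction of the packaged study analysis."""
    config = PipelineConfig(seed=seed, bootstrap=bootstrap, **overrides)
    return run_pipeline(config)


def render_report(report: AnalysisReport, fmt: str, path: str | Path) -> None:
    """Write a report as ``json``, ``tsv`` (block table) or ``text``."""
    if fmt == "json":
        report.to_json(path)
    elif fmt == "tsv":
        report.to_tsv(path)
    elif fmt == "text":
        Path(path).write_text(report.to_text() + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(name)s %(levelname)s %(message)s",
    )
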