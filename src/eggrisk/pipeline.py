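"""End-to-end run orchestration and report rendering.

``run_pipeline`` wires the stages together — read (or synthesize) the
concentration table, deterministic assessment, Monte Carlo assessment,
group comparisons, compliance screening — and writes machine-readable
CSV/JSON artifacts plus a plain-text report. Every artifact is stamped
with the package version, the master seed, and a hash of the run
configuration, so a rerun with the same seed is byte-identical on the
numeric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .comparison_stats import compare_groups, compliance_screen, summarize
from .data_io import (
    ConcentrationRecord,
    example_reference_path,
    read_concentration_table,
    read_reference_tables,
    records_to_frame,
    substitute_lod,
)
from .deterministic_risk import assess, results_to_frame
from .probabilistic_risk import (
    build_default_specs,
    percentile_threshold_report,
    run_mcs,
)
from .synthetic_data import GeneratorConfig, generate

__all__ = ["RunConfig", "StageFailure", "run_pipeline", "render_cr_matrix", "format_sci"]

log = logging.getLogger("eggrisk")


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run.

    ``data`` is a long-format concentration CSV; when None, a synthetic
    dataset with the default 9-area design is generated from ``seed``.
    ``reference`` defaults to the packaged example parameter file.
    """

    data: str | None = None
    reference: str | None = None
    outdir: str = "eggrisk_out"
    n_iter: int = 10000
    seed: int = 0
    percentile: float = 95.0
    alpha: float = 0.05
    lod_policy: str = "half"
    dist_overrides: dict[str, str] = field(default_factory=dict)
    write_html: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as e:  # located diagnostic, abort with stage name
            raise StageFailure(name, e) from e
        return out

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the artifact dict and writes ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record_stage(name: str, n_in: int, n_out: int) -> None:
        stages.append({"stage": name, "records_in": n_in, "records_out": n_out})
        log.info("stage %s: %d -> %d records", name, n_in, n_out)

    # -- data_io ----------------------------------------------------------
    try:
        if config.data is None:
            records = generate(GeneratorConfig(seed=config.seed))
            write_source = True
        else:
            records = read_concentration_table(config.data)
            write_source = False
        records = substitute_lod(records, config.lod_policy)
        ref_path = config.reference or example_reference_path()
        profiles, toxicity, limits = read_reference_tables(ref_path)
    except Exception as e:
        raise StageFailure("data_io", e) from e
    record_stage("data_io", 0 if config.data is None else len(records), len(records))
    if write_source:
        records_to_frame(records).to_csv(
            outdir / "concentrations.csv", index=False, float_format="%.12g"
        )

    # -- deterministic_risk ------------------------------------------------
    det = _stage("deterministic_risk")(assess, records, profiles, toxicity)
    det_frame = results_to_frame(det)
    record_stage("deterministic_risk", len(records), len(det))
    det_frame.to_csv(outdir / "risk_deterministic.csv", index=False)
    det_frame.to_json(outdir / "risk_deterministic.json", orient="records", indent=2)

    # -- probabilistic_risk ------------------------------------------------
    def _mcs():
        specs = build_default_specs(records, profiles, overrides=config.dist_overrides)
        return run_mcs(specs, profiles, toxicity, n_iter=config.n_iter, seed=config.seed)

    sims = _stage("probabilistic_risk")(_mcs)
    report = percentile_threshold_report(sims)
    record_stage("probabilistic_risk", len(records), len(sims))
    report.to_csv(outdir / "mcs_p95_report.csv", index=False)
    report.to_json(outdir / "mcs_p95_report.json", orient="records", indent=2)

    # -- comparison_stats --------------------------------------------------
    def _compare():
        out = {}
        df = records_to_frame(records)
        for grouping in ("area", "production_system", "mining_class"):
            if df[grouping].nunique() >= 2:
                out[grouping] = compare_groups(records, grouping, alpha=config.alpha)
        return out

    comparisons = _stage("comparison_stats")(_compare)
    comp_rows = [
        {
            "grouping": grouping,
            "metal": c.metal,
            "F": c.anova_F,
            "p": c.anova_p,
            "significant": c.significant,
            "degenerate": c.degenerate,
        }
        for grouping, results in comparisons.items()
        for c in results
    ]
    comp_frame = pd.DataFrame(comp_rows)
    record_stage("comparison_stats", len(records), len(comp_rows))
    comp_frame.to_csv(outdir / "comparisons.csv", index=False)

    compliance = _stage("comparison_stats")(compliance_screen, records, limits)
    compliance.to_csv(outdir / "compliance.csv", index=False)

    # -- report ------------------------------------------------------------
    cr_matrix = render_cr_matrix(report)
    meta = {
        "version": __version__,
        "seed": config.seed,
        "n_iter": config.n_iter,
        "config_hash": config.config_hash(),
        "stages": stages,
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    text = _render_text_report(meta, summarize(records), det_frame, report, cr_matrix, comp_frame, compliance)
    (outdir / "report.txt").write_text(text)
    if config.write_html:
        (outdir / "report.html").write_text("<pre>\n" + text + "\n</pre>\n")

    return {
        "records": records,
        "deterministic": det,
        "simulation": sims,
        "p95_report": report,
        "comparisons": comparisons,
        "compliance": compliance,
        "cr_matrix": cr_matrix,
        "meta": meta,
    }


def format_sci(x: float, sig: int = 2) -> str:
    """Scientific notation with ``sig`` significant digits, e.g. 5.9×10−5."""
    if x == 0:
        return "0"
    s = f"{x:.{sig - 1}e}"
    mantissa, exp = s.split("e")
    e = int(exp)
    sign = "−" if e < 0 else ""
    return f"{mantissa}×10{sign}{abs(e)}"


def render_cr_matrix(p95_report: pd.DataFrame) -> pd.DataFrame:
    """Areas × (metal, group) matrix of p95 carcinogenic risks, rendered in
    2-significant-figure scientific notation; cells at or above 1e-4 are
    wrapped in ``**`` to mark potential health risks."""
    if p95_report.empty:
        return pd.DataFrame()
    sub = p95_report[p95_report["metric"].str.startswith("CR_")]
    if sub.empty:
        return pd.DataFrame()
    sub = sub.assign(metal=sub["metric"].str.replace("CR_", "", regex=False))

    def cell(v: float) -> str:
        s = format_sci(v)
        return f"**{s}**" if v >= 1e-4 else s

    wide = sub.pivot_table(
        index="area", columns=["metal", "group"], values="p95", aggfunc="first", sort=True
    )
    return wide.map(cell)


def _render_text_report(meta, summary, det_frame, p95_report, cr_matrix, comp_frame, compliance) -> str:
    parts = [
        f"eggrisk v{meta['version']}  seed={meta['seed']}  n_iter={meta['n_iter']}  "
        f"config={meta['config_hash']}",
        "",
        "== Concentration summary (per area x metal) ==",
        summary.to_string(index=False),
        "",
        "== Deterministic risk (HI / TCR rows) ==",
        det_frame[det_frame["metric"].isin(["HI", "TCR"])].to_string(index=False),
        "",
        "== Monte Carlo p95 decision table ==",
        p95_report.to_string(index=False),
        "",
        "== Carcinogenic risk matrix (p95, ** marks >= 1e-4) ==",
        cr_matrix.to_string() if not cr_matrix.empty else "(no carcinogen results)",
        "",
        "== Group comparisons ==",
        comp_frame.to_string(index=False) if not comp_frame.empty else "(single group)",
        "",
        "== Compliance screening ==",
        compliance.to_string(index=False),
        "",
    ]
    return "\n".join(parts)
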