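"""Configuration-driven orchestration of the discovery pipeline.

One YAML document enables and parameterizes the stages, which run in the
method's natural order: index (occurrence statistics) -> digest (in
silico proteolysis panel) -> rsm (hydrolysis optimization) -> score
(candidate ranking) -> kinetics (inhibition mode and Ki) -> ic50.  Each
stage writes machine-readable output into the output directory and the
consolidated ``report.json`` records per-stage summaries with provenance
(input digests, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .digest import default_rules, enzyme_panel, load_rules
from .kinetics import KineticSeries, classify, fit_ic50, fit_series
from .proteome import default_ace_reference, load_fasta, load_reference, occurrence_profile
from .rsm import BBDExperiment, DEFAULT_CODING, FactorCoding, anova, find_optimum, fit_quadratic
from .scoring import load_candidates, score_candidates, select_top

__all__ = ["PipelineConfig", "load_config", "run"]

log = logging.getLogger("acepep")

STAGES = ("index", "digest", "rsm", "score", "kinetics", "ic50")

_KNOWN_KEYS = {
    "top": {"seed", "outdir", "stages", *STAGES},
    "index": {"fasta", "reference"},
    "digest": {"fasta", "rules", "reference"},
    "rsm": {"design", "coding"},
    "score": {"candidates", "weights", "top", "normalization"},
    "kinetics": {"data", "method", "tolerance"},
    "ic50": {"data"},
}
_REQUIRED_PATHS = {
    "index": ["fasta"],
    "digest": ["fasta"],
    "rsm": ["design"],
    "score": ["candidates"],
    "kinetics": ["data"],
    "ic50": ["data"],
}


@dataclass
class PipelineConfig:
    """Validated stage toggles and per-stage options."""

    stages: list[str]
    options: dict
    outdir: Path
    seed: int = 0
    source: Path | None = field(default=None, repr=False)


def _reject_unknown(mapping: dict, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline configuration."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    _reject_unknown(doc, _KNOWN_KEYS["top"], str(path))
    stages = doc.get("stages")
    if not stages:
        raise ValueError(f"{path}: 'stages' must list at least one stage")
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"{path}: unknown stage(s) {bad}; valid: {list(STAGES)}")
    options = {}
    for stage in stages:
        opts = doc.get(stage) or {}
        _reject_unknown(opts, _KNOWN_KEYS[stage], f"{path}: stage {stage!r}")
        for key in _REQUIRED_PATHS[stage]:
            if key not in opts:
                raise ValueError(f"{path}: stage {stage!r} requires {key!r}")
        for key in ("fasta", "reference", "rules", "design", "candidates", "data"):
            if key in opts:
                p = (path.parent / opts[key]).resolve()
                if not p.exists():
                    raise FileNotFoundError(f"{path}: stage {stage!r}: no such file {p}")
                opts[key] = p
        options[stage] = opts
    return PipelineConfig(
        stages=list(stages),
        options=options,
        outdir=(path.parent / doc.get("outdir", "acepep_out")).resolve(),
        seed=int(doc.get("seed", 0)),
        source=path,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _stage_index(opts, outdir: Path) -> dict:
    proteins = load_fasta(opts["fasta"])
    ref = load_reference(opts["reference"]) if "reference" in opts else default_ace_reference()
    profiles = [occurrence_profile(p, ref) for p in proteins]
    rows = [
        {"protein_id": pr.protein_id, **pr.per_activity_a, "sigma_A": pr.sigma_a}
        for pr in profiles
    ]
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "occurrence.tsv", sep="\t", index=False)
    (outdir / "occurrence.json").write_text(
        json.dumps(rows, indent=2), encoding="utf-8"
    )
    return {
        "n_proteins": len(proteins),
        "n_reference_fragments": len(ref),
        "sigma_A": {r["protein_id"]: r["sigma_A"] for r in rows},
    }


def _stage_digest(opts, outdir: Path) -> dict:
    proteins = load_fasta(opts["fasta"])
    rules = load_rules(opts["rules"]) if "rules" in opts else default_rules()
    ref = load_reference(opts["reference"]) if "reference" in opts else default_ace_reference()
    detail, summary = enzyme_panel(proteins, rules, ref)
    detail.to_csv(outdir / "digest_detail.tsv", sep="\t", index=False)
    summary.to_csv(outdir / "digest_summary.tsv", sep="\t", index=False)
    return {
        "enzymes": [r.name for r in rules],
        "mean_dht": summary.drop_duplicates("enzyme").set_index("enzyme")["mean_dht"].to_dict(),
    }


def _stage_rsm(opts, outdir: Path) -> dict:
    table = pd.read_csv(opts["design"])
    coding = (
        FactorCoding({k: tuple(v) for k, v in opts["coding"].items()})
        if "coding" in opts
        else DEFAULT_CODING
    )
    design = BBDExperiment.from_natural(table, coding)
    fit = fit_quadratic(design)
    report = anova(fit)
    optimum = find_optimum(fit, coding)
    (outdir / "anova.txt").write_text(str(report) + "\n", encoding="utf-8")
    payload = {
        "coefficients": fit.coefficients,
        "anova": report.table.reset_index().to_dict(orient="records"),
        "diagnostics": report.diagnostics,
        "optimum": {
            "coded": optimum.coded.tolist(),
            "natural": optimum.natural,
            "predicted": optimum.predicted,
            "interior": optimum.interior,
            "warning": optimum.warning,
        },
    }
    (outdir / "rsm.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return {
        "r_squared": report.diagnostics["r_squared"],
        "optimum_natural": optimum.natural,
        "predicted_response": optimum.predicted,
    }


def _stage_score(opts, outdir: Path) -> dict:
    table = load_candidates(opts["candidates"])
    card = score_candidates(
        table,
        weights=tuple(opts.get("weights", (0.40, 0.30, 0.30))),
        normalization=opts.get("normalization", "ratio_to_max"),
    )
    card.to_csv(outdir / "scorecard.csv", index=False)
    top = select_top(card, int(opts.get("top", min(7, len(card)))))
    return {
        "n_candidates": len(card),
        "top": top[["rank", "sequence", "total"]].to_dict(orient="records"),
    }


def _load_kinetic_series(path) -> list[KineticSeries]:
    table = pd.read_csv(path)
    required = {"inhibitor_conc", "substrate_conc", "rate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        KineticSeries(
            inhibitor_conc=float(conc),
            substrate_conc=g["substrate_conc"].to_numpy(),
            rates=g["rate"].to_numpy(),
        )
        for conc, g in table.groupby("inhibitor_conc", sort=True)
    ]


def _stage_kinetics(opts, outdir: Path) -> dict:
    series = _load_kinetic_series(opts["data"])
    method = opts.get("method", "nls")
    fits = [fit_series(s, method=method) for s in series]
    verdict = classify(fits, tolerance=float(opts.get("tolerance", 0.10)))
    payload = {
        "method": method,
        "fits": [
            {
                "inhibitor_conc": f.inhibitor_conc,
                "vmax": f.vmax,
                "km": f.km,
                "se_vmax": f.se_vmax,
                "se_km": f.se_km,
                "lb_slope": f.slope,
                "lb_y_intercept": f.y_intercept,
                "lb_x_intercept": f.x_intercept,
                "r_squared": f.r_squared,
            }
            for f in fits
        ],
        "mode": verdict.mode,
        "ki": verdict.ki,
        "evidence": verdict.evidence,
        "diagnostic": verdict.diagnostic,
    }
    (outdir / "kinetics.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return {"mode": verdict.mode, "ki": verdict.ki}


def _stage_ic50(opts, outdir: Path) -> dict:
    table = pd.read_csv(opts["data"])
    missing = {"conc", "inhibition"} - set(table.columns)
    if missing:
        raise ValueError(f"{opts['data']}: missing column(s) {sorted(missing)}")
    dr = fit_ic50(table["conc"].to_numpy(), table["inhibition"].to_numpy())
    payload = {
        "ic50": dr.ic50,
        "hill": dr.hill,
        "bottom": dr.bottom,
        "top": dr.top,
        "ic50_within_span": dr.in_span,
        "warning": dr.warning,
    }
    (outdir / "ic50.json").write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return {"ic50": dr.ic50, "hill": dr.hill}


_RUNNERS = {
    "index": _stage_index,
    "digest": _stage_digest,
    "rsm": _stage_rsm,
    "score": _stage_score,
    "kinetics": _stage_kinetics,
    "ic50": _stage_ic50,
}


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write ``report.json``.

    A stage failure aborts the run with a stage-named diagnostic; outputs
    of completed stages are retained.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    inputs = {}
    for stage in config.stages:
        for key, value in config.options[stage].items():
            if isinstance(value, Path):
                inputs[f"{stage}:{key}"] = _sha256(value)
    report = {
        "version": __version__,
        "seed": config.seed,
        "stages": config.stages,
        "inputs_sha256": inputs,
        "results": {},
    }
    np.random.seed(config.seed % 2**31)  # legacy consumers; stages are deterministic
    for stage in config.stages:
        log.info("stage %s: starting", stage)
        try:
            report["results"][stage] = _RUNNERS[stage](config.options[stage], config.outdir)
        except Exception as exc:
            (config.outdir / "report.json").write_text(
                json.dumps(report, indent=2, default=float), encoding="utf-8"
            )
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done", stage)
    (config.outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=float), encoding="utf-8"
    )
    return report
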