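"""End-to-end orchestration: simulate/load -> search -> null -> rank -> report.

One YAML (or dict) configuration drives a full reproducible run.  All
stages share a single :class:`~mimoscan.search.MatchParams` object, so the
forward search and the reversed-peptide null can never diverge; inputs are
validated before any stage executes, and a machine-readable manifest
(inputs, digests, parameters, null summary, seed) is written next to the
reports.

Config keys::

    seed: 1                       # overrides simulate.seed when present
    out_dir: run/
    params: {mode: exact, min_exact_window: 5, max_mismatches: 0}
    simulate: {...SimConfig/PanelSpec fields...}      # either this ...
    inputs: {panels: p.tsv, proteome: db.fasta,       # ... or this
             hits: hits.tsv, null: null.json}         # optional externals
    null_model: {min_matches_threshold: 4, include_panels: [...]}
    rank: {weight_by_copies: false, control_panels: [], two_sided_fisher: false}

Externally produced hits require an externally produced null (same search
engine for both sides); mixing the built-in matcher with imported tables
is refused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .io import (
    read_external_matches,
    read_panels,
    read_proteome,
    write_panels,
    write_proteome,
    write_report,
)
from .null_model import estimate_null, read_null, write_null
from .search import (
    MatchParams,
    hits_from_external,
    search_panels,
    write_hits_tsv,
)
from .significance import rank_candidates
from .simulate import PanelSpec, SimConfig, generate, write_truth

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, dict):
            raise PipelineError(f"config {config} is not a mapping")
        return loaded
    return dict(config)


def _sim_config(block: Mapping, seed: int | None) -> SimConfig:
    block = dict(block)
    panel_blocks = block.pop("panels", None)
    if seed is not None:
        block["seed"] = seed
    if panel_blocks is not None:
        block["panels"] = tuple(
            PanelSpec(**{**pb, "peptide_length": tuple(pb.get("peptide_length", (7, 12)))})
            for pb in panel_blocks
        )
    if "decoy_lengths" in block:
        block["decoy_lengths"] = tuple(block["decoy_lengths"])
    return SimConfig(**block)


def run_all(config, out_dir: str | Path | None = None, seed: int | None = None) -> dict:
    """Execute the full pipeline; returns paths, manifest and results.

    Fail-fast: the configuration and every referenced input file are
    validated before the first stage runs.
    """
    started = time.time()
    cfg = _load_config(config)
    seed = seed if seed is not None else cfg.get("seed")
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "mimoscan_run"))
    params = MatchParams(**cfg.get("params", {}))
    sim_block = cfg.get("simulate")
    inputs_block = cfg.get("inputs", {})
    # "null" is a YAML keyword, so the canonical key is "null_model"; the
    # bare spelling (quoted or not) is accepted as well
    null_block = dict(
        cfg.get("null_model") or cfg.get("null") or cfg.get(None) or {}
    )
    rank_block = dict(cfg.get("rank", {}))

    if sim_block is None and not inputs_block:
        raise PipelineError("config needs either a 'simulate' block or 'inputs'")
    external_hits = inputs_block.get("hits")
    external_null = inputs_block.get("null")
    if bool(external_hits) != bool(external_null):
        raise PipelineError(
            "external hits and external null must be supplied together "
            "(both sides of the analysis must come from one search engine)"
        )
    # fail-fast input validation
    for key in ("panels", "proteome", "hits", "null"):
        path = inputs_block.get(key)
        if path is not None and not Path(path).exists():
            raise PipelineError(f"input {key} file not found: {path}")
    if sim_block is not None and inputs_block.get("panels"):
        raise PipelineError("provide either a simulate block or input panels, not both")

    out.mkdir(parents=True, exist_ok=True)
    input_files: dict[str, Path] = {}
    truth_path = None
    if sim_block is not None:
        sim_cfg = _sim_config(sim_block, seed)
        proteins, panels, truth = generate(sim_cfg)
        panels_path = out / "panels.tsv"
        proteome_path = out / "proteome.fasta"
        truth_path = out / "truth.json"
        write_panels(panels, panels_path)
        write_proteome(proteins, proteome_path)
        write_truth(truth, truth_path)
        if inputs_block.get("proteome"):
            proteome_path = Path(inputs_block["proteome"])
    else:
        panels_path = Path(inputs_block["panels"])
        proteome_path = Path(inputs_block["proteome"])
    input_files["panels"] = panels_path
    input_files["proteome"] = proteome_path

    panels = read_panels(panels_path)
    proteome = read_proteome(proteome_path)

    hits_path = out / "hits.tsv"
    if external_hits:
        rows = read_external_matches(external_hits)
        hits = hits_from_external(rows, panels, proteome)
        input_files["hits"] = Path(external_hits)
        null = read_null(external_null)
        input_files["null"] = Path(external_null)
        if null.params != params:
            raise PipelineError(
                "external null was produced with different MatchParams than "
                "this run requests"
            )
        write_hits_tsv(hits, hits_path)
        null_path = out / "null.json"
        write_null(null, null_path)
    else:
        hits = search_panels(panels, proteome, params)
        write_hits_tsv(hits, hits_path)
        null = estimate_null(
            panels,
            proteome,
            params,
            min_matches_threshold=null_block.get("min_matches_threshold", 4),
            include_panels=null_block.get("include_panels"),
        )
        null_path = out / "null.json"
        write_null(null, null_path)

    results = rank_candidates(
        hits,
        panels,
        proteome,
        null,
        params=params,
        weight_by_copies=rank_block.get("weight_by_copies", False),
        control_panels=rank_block.get("control_panels", ()),
        two_sided_fisher=rank_block.get("two_sided_fisher", False),
    )
    report_path = out / "candidates.tsv"
    report_json = write_report(results, report_path)

    manifest = {
        "tool": "mimoscan",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "params": dataclasses.asdict(params),
        "inputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in input_files.items()},
        "null": {
            "f_mean": null.f_mean,
            "f_sd": null.f_sd,
            "n_peptides_used": null.n_peptides_used,
            "n_proteins_used": len(null.proteins_used),
            "min_matches_threshold": null.min_matches_threshold,
        },
        "outputs": {
            "hits": str(hits_path),
            "null": str(null_path),
            "candidates_tsv": str(report_path),
            "candidates_json": str(report_json),
            **({"truth": str(truth_path)} if truth_path else {}),
        },
        "runtime_seconds": round(time.time() - started, 3),
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
        fh.write("\n")
    logger.info("run complete: %d candidates -> %s", len(results), report_path)
    return {
        "out_dir": out,
        "results": results,
        "null": null,
        "hits": hits,
        "panels": panels,
        "proteome": proteome,
        "manifest": manifest,
        "paths": {
            "hits": hits_path,
            "null": null_path,
            "candidates_tsv": report_path,
            "candidates_json": report_json,
            "manifest": manifest_path,
            **({"truth": truth_path} if truth_path else {}),
        },
    }
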