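"""End-to-end orchestration: screen -> RIP-chip -> sites -> prioritization.

The run configuration is a TOML file with a ``[pipeline]`` table of analysis
parameters (see :mod:`mirscreen.config`) and an ``[inputs]`` table naming the
input files.  Stages whose inputs are absent are skipped, so partial bundles
(e.g. RIP-chip only) still run.  Every run writes its intermediate TSVs plus a
``manifest.json`` recording the package version, parameters and input
checksums.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, io, prioritize, ripchip, screen, seeds
from .config import PipelineConfig, config_dict, load_config
from .types import MatureMiRNA, SiteAnnotation, TargetRecord, ValidationError


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_run_config(path: str | Path) -> tuple[PipelineConfig, dict[str, Any]]:
    """Split a run TOML into validated parameters and the raw inputs table."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cfg = load_config(overrides=data.get("pipeline", {}))
    inputs = data.get("inputs", {})
    base = Path(path).parent
    for key, val in inputs.items():
        if key.endswith(("_counts", "_samples", "_expr", "_fasta", "_regions")) or key == "crispr":
            paths = val if isinstance(val, list) else [val]
            for p in paths:
                resolved = (base / p).resolve() if not Path(p).is_absolute() else Path(p)
                if not resolved.exists():
                    raise ValidationError(f"input file for {key!r} not found: {p}")
    return cfg, inputs


def run_pipeline(config_path: str | Path, outdir: str | Path) -> dict[str, Any]:
    """Run all configured stages, persist outputs, and write a manifest.

    Returns the manifest dictionary.
    """
    config_path = Path(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg, inputs = load_run_config(config_path)
    base = config_path.parent

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else (base / q).resolve()

    manifest: dict[str, Any] = {
        "version": __version__,
        "parameters": config_dict(cfg),
        "inputs": {},
        "outputs": [],
    }
    for key, val in inputs.items():
        if isinstance(val, list):
            manifest["inputs"][key] = [
                {"path": str(p), "sha256": _sha256(resolve(p))}
                if resolve(p).exists()
                else {"path": str(p)}
                for p in val
            ]
        elif isinstance(val, str) and resolve(val).exists():
            manifest["inputs"][key] = {"path": val, "sha256": _sha256(resolve(val))}
        else:
            manifest["inputs"][key] = val

    # --- screen stage -----------------------------------------------------
    if "screen_counts" in inputs:
        pool = str(inputs.get("pool", "mirzip")).lower()
        if pool not in screen.POOL_TARGET_TOTALS:
            raise ValidationError(f"unknown pool type {pool!r}")
        target_total = (
            cfg.target_total_mirzip if pool == "mirzip" else cfg.target_total_pcdh
        )
        sc = io.read_counts(
            resolve(inputs["screen_counts"]),
            resolve(inputs["screen_samples"]),
            controls=inputs.get("controls", ()),
        )
        calls, slopes, excluded = screen.analyze_screen(
            sc, target_total=target_total, min_reads=cfg.min_reads, iqr_k=cfg.iqr_k
        )
        screen.hit_table(calls).to_csv(outdir / "hits.tsv", sep="\t", index=False)
        pd.DataFrame({"excluded_construct": excluded}).to_csv(
            outdir / "excluded.tsv", sep="\t", index=False
        )
        manifest["outputs"] += ["hits.tsv", "excluded.tsv"]
        manifest["screen"] = {
            "pool": pool,
            "n_excluded": len(excluded),
            "n_hits": sum(c.direction != "none" for c in calls),
        }

    # --- RIP-chip stage ---------------------------------------------------
    targets: list[TargetRecord] = []
    if "rip_expr" in inputs:
        expr_paths = inputs["rip_expr"]
        sheet_paths = inputs["rip_samples"]
        if isinstance(expr_paths, str):
            expr_paths, sheet_paths = [expr_paths], [sheet_paths]
        experiments = {}
        for expr_p, sheet_p in zip(expr_paths, sheet_paths):
            exp = io.read_rip_experiment(resolve(expr_p), resolve(sheet_p))
            experiments[exp.cell_line] = exp
        shared, tables = ripchip.identify_targets(
            experiments,
            min_ratio=cfg.min_ratio,
            min_fc=cfg.min_fc,
            lower_percentile=cfg.percentile,
            collapse=cfg.probe_collapse,
        )
        for cell_line, exp in experiments.items():
            probes = ripchip.presence_filter(exp, lower_percentile=cfg.percentile)
            ratios = ripchip.ip_t_ratios(exp, probes, collapse=cfg.probe_collapse)
            ripchip.write_rnk(
                ripchip.ranked_list(ratios), outdir / f"ranked_{cell_line}.rnk"
            )
            manifest["outputs"].append(f"ranked_{cell_line}.rnk")
        targets = [
            TargetRecord(
                gene=g,
                ratio_fc={
                    cl: float(tbl.loc[g, "fc"]) for cl, tbl in tables.items() if g in tbl.index
                },
            )
            for g in sorted(shared)
        ]
        io.write_target_table(targets, outdir / "targets.tsv")
        manifest["outputs"].append("targets.tsv")
        manifest["ripchip"] = {
            "n_targets_shared": len(shared),
            "n_targets_per_line": {cl: int(len(t)) for cl, t in tables.items()},
        }

    # --- seed-site stage --------------------------------------------------
    if "transcripts_fasta" in inputs and "mirna" in inputs:
        mirna = MatureMiRNA(
            inputs.get("mirna_name", "miRNA"), str(inputs["mirna"])
        )
        motifs = seeds.derive_motifs(mirna)
        transcripts = io.read_regions(
            resolve(inputs["transcripts_fasta"]), resolve(inputs["transcripts_regions"])
        )
        rows = []
        hits_by_tid: dict[str, list] = {}
        for t in transcripts:
            hits = seeds.annotate_transcript(t, motifs)
            hits_by_tid[t.transcript_id.upper()] = hits
            for h in hits:
                rows.append(
                    {
                        "transcript_id": h.transcript_id,
                        "region": h.region,
                        "site_class": h.site_class,
                        "orf_position": h.position,
                    }
                )
        pd.DataFrame(
            rows, columns=["transcript_id", "region", "site_class", "orf_position"]
        ).to_csv(outdir / "sites.tsv", sep="\t", index=False)
        manifest["outputs"].append("sites.tsv")
        # attach sites to targets where the transcript is named after the gene
        for t in targets:
            for h in hits_by_tid.get(t.gene.upper(), []):
                t.sites.append(
                    SiteAnnotation(
                        region=h.region, site_class=h.site_class, position=h.position
                    )
                )
        manifest["sites"] = {"n_sites": len(rows)}

    # --- prioritization stage ---------------------------------------------
    if "crispr" in inputs and targets:
        crispr = io.read_crispr_table(resolve(inputs["crispr"]))
        result = prioritize.prioritize(
            targets, crispr, p_max=cfg.p_max, fc_cutoff=cfg.fc_cutoff
        )
        io.write_target_table(result["candidates"], outdir / "candidates.tsv")
        manifest["outputs"].append("candidates.tsv")
        manifest["prioritization"] = {
            "n_with_crispr": len(result["joined"]) - len(result["absent"]),
            "n_significant": len(result["significant"]),
            "n_candidates": len(result["candidates"]),
        }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
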