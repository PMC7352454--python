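"""Readers and writers for the tabular and sequence formats the pipeline uses.

All tables are tab-delimited UTF-8 with a header row; missing values are empty
cells.  FASTA handling goes through Biopython.  Every reader validates against
the container invariants in :mod:`mirscreen.types` and raises
:class:`~mirscreen.types.ValidationError` naming the offending row or column.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    CrisprGeneRecord,
    RipExperiment,
    RipSampleKey,
    SampleKey,
    ScreenCounts,
    SiteAnnotation,
    TargetRecord,
    TranscriptRegions,
    ValidationError,
)

# Site-class abbreviations as printed in target tables.
_SITE_ABBREV = {"8m": "8mer", "7m8": "7mer-m8", "7mA1": "7mer-A1"}


# ---------------------------------------------------------------------------
# Screen counts
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> dict[str, SampleKey]:
    """Read a screen sample sheet (sample, cell_line, infection, day, pcr_rep)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "cell_line": str})
    required = {"sample", "cell_line", "infection", "day", "pcr_rep"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
    out: dict[str, SampleKey] = {}
    for _, row in df.iterrows():
        name = str(row["sample"])
        if name in out:
            raise ValidationError(f"duplicate sample name in sheet: {name!r}")
        out[name] = SampleKey(
            cell_line=str(row["cell_line"]),
            infection=int(row["infection"]),
            day=int(row["day"]),
            pcr_rep=int(row["pcr_rep"]),
        )
    return out


def read_counts(
    path: str | Path,
    samples: dict[str, SampleKey] | str | Path,
    controls: Sequence[str] = (),
    construct_column: str = "construct",
) -> ScreenCounts:
    """Read a construct x sample count TSV against a sample sheet.

    The TSV must carry ``construct_column`` plus one column per sample in the
    sheet; unknown sample columns are rejected.
    """
    if not isinstance(samples, dict):
        samples = read_sample_sheet(samples)
    df = pd.read_csv(path, sep="\t")
    if construct_column not in df.columns:
        raise ValidationError(
            f"count table lacks construct column {construct_column!r}"
        )
    df = df.set_index(construct_column).rename_axis(None)
    absent = [s for s in samples if s not in df.columns]
    if absent:
        raise ValidationError(f"sample sheet columns absent from count table: {absent}")
    extra = [c for c in df.columns if c not in samples]
    if extra:
        raise ValidationError(f"count table columns not in sample sheet: {extra}")
    return ScreenCounts(counts=df[list(samples)], samples=samples, controls=tuple(controls))


def write_counts(sc: ScreenCounts, path: str | Path, construct_column: str = "construct") -> None:
    sc.counts.rename_axis(construct_column).to_csv(path, sep="\t")


def write_sample_sheet(samples: dict[str, SampleKey], path: str | Path) -> None:
    rows = [
        {
            "sample": name,
            "cell_line": k.cell_line,
            "infection": k.infection,
            "day": k.day,
            "pcr_rep": k.pcr_rep,
        }
        for name, k in samples.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RIP-chip expression
# ---------------------------------------------------------------------------


def read_rip_sample_sheet(path: str | Path) -> dict[str, RipSampleKey]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "cell_line", "condition", "fraction", "duplicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"RIP sample sheet missing columns: {sorted(missing)}")
    out: dict[str, RipSampleKey] = {}
    for _, row in df.iterrows():
        name = str(row["sample"])
        if name in out:
            raise ValidationError(f"duplicate sample name in sheet: {name!r}")
        out[name] = RipSampleKey(
            cell_line=str(row["cell_line"]),
            condition=str(row["condition"]),
            fraction=str(row["fraction"]),
            duplicate=int(row["duplicate"]),
        )
    return out


def read_rip_experiment(
    expr_path: str | Path,
    samples: dict[str, RipSampleKey] | str | Path,
    probe_column: str = "probe",
    gene_column: str = "gene",
    present_suffix: str = "_present",
) -> RipExperiment:
    """Read a probe x sample expression TSV with paired presence-flag columns.

    For every sample column ``S`` the table must carry ``S_present`` holding
    0/1 detection flags.
    """
    if not isinstance(samples, dict):
        samples = read_rip_sample_sheet(samples)
    df = pd.read_csv(expr_path, sep="\t")
    for col in (probe_column, gene_column):
        if col not in df.columns:
            raise ValidationError(f"expression table lacks column {col!r}")
    df = df.set_index(probe_column).rename_axis(None)
    value_cols = [s for s in samples]
    absent = [s for s in value_cols if s not in df.columns]
    if absent:
        raise ValidationError(f"expression table lacks sample columns: {absent}")
    flag_cols = {s: s + present_suffix for s in value_cols}
    missing_flags = [f for f in flag_cols.values() if f not in df.columns]
    if missing_flags:
        raise ValidationError(f"expression table lacks presence columns: {missing_flags}")
    values = df[value_cols].astype(float)
    present = df[list(flag_cols.values())].astype(bool)
    present.columns = value_cols
    probe_gene = df[gene_column].astype(str).to_dict()
    return RipExperiment(values=values, present=present, samples=samples, probe_gene=probe_gene)


def write_rip_experiment(
    exp: RipExperiment, expr_path: str | Path, present_suffix: str = "_present"
) -> None:
    df = exp.values.copy()
    for col in exp.values.columns:
        df[col + present_suffix] = exp.present[col].astype(int)
    df.insert(0, "gene", [exp.probe_gene[p] for p in df.index])
    df.rename_axis("probe").to_csv(expr_path, sep="\t")


def write_rip_sample_sheet(samples: dict[str, RipSampleKey], path: str | Path) -> None:
    rows = [
        {
            "sample": name,
            "cell_line": k.cell_line,
            "condition": k.condition,
            "fraction": k.fraction,
            "duplicate": k.duplicate,
        }
        for name, k in samples.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcript sequences and regions
# ---------------------------------------------------------------------------


def read_regions(fasta: str | Path, regions: str | Path) -> list[TranscriptRegions]:
    """Read transcript sequences (FASTA) plus a region table.

    The region TSV needs columns ``transcript_id``, ``cds_start`` and
    ``cds_end`` (0-based half-open on the spliced transcript).
    """
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    df = pd.read_csv(regions, sep="\t")
    required = {"transcript_id", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"region table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        tid = str(row["transcript_id"])
        if tid not in seqs:
            raise ValidationError(f"region table row {tid!r} has no FASTA record")
        out.append(
            TranscriptRegions(
                transcript_id=tid,
                sequence=seqs[tid],
                cds_start=int(row["cds_start"]),
                cds_end=int(row["cds_end"]),
            )
        )
    return out


def write_regions(
    transcripts: Iterable[TranscriptRegions], fasta: str | Path, regions: str | Path
) -> None:
    transcripts = list(transcripts)
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(fasta), "fasta")
    pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "cds_start": [t.cds_start for t in transcripts],
            "cds_end": [t.cds_end for t in transcripts],
        }
    ).to_csv(regions, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CRISPR gene table
# ---------------------------------------------------------------------------


def read_crispr_table(
    path: str | Path,
    gene_column: str = "gene",
    fc_column: str = "fc",
    p_column: str = "p_adj",
) -> list[CrisprGeneRecord]:
    """Read a gene-level CRISPR screen table (e.g. DESeq2/CRISPRAnalyzeR output)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in (gene_column, fc_column):
        if col not in df.columns:
            raise ValidationError(f"CRISPR table lacks column {col!r}")
    out = []
    for _, row in df.iterrows():
        p = row.get(p_column)
        p = None if p is None or (isinstance(p, float) and math.isnan(p)) else float(p)
        out.append(CrisprGeneRecord(gene=str(row[gene_column]), fc=float(row[fc_column]), p_adj=p))
    return out


# ---------------------------------------------------------------------------
# Packaged target-gene fixture
# ---------------------------------------------------------------------------


def _parse_sites(cell: object, region: str) -> list[SiteAnnotation]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    out = []
    for token in str(cell).split("/"):
        token = token.strip()
        if token not in _SITE_ABBREV:
            raise ValidationError(f"unknown site-class abbreviation {token!r}")
        out.append(SiteAnnotation(region=region, site_class=_SITE_ABBREV[token]))
    return out


def read_target_table(path: str | Path) -> list[TargetRecord]:
    """Read a target-gene table with per-cell-line IP/T ratio fold changes.

    Expected columns: ``gene``, optional ``transcript_id``, one
    ``ratio_fc_<cell line>`` per cell line, optional ``crispr_fc``/``crispr_p``
    and optional ``sites_cds``/``sites_utr5``/``sites_utr3`` cells holding
    "/"-separated site-class abbreviations (8m, 7m8, 7mA1).
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "gene" not in df.columns:
        raise ValidationError("target table lacks 'gene' column")
    fc_cols = {c[len("ratio_fc_") :]: c for c in df.columns if c.startswith("ratio_fc_")}
    records = []
    for _, row in df.iterrows():
        ratio_fc = {
            cl: float(row[col]) for cl, col in fc_cols.items() if not pd.isna(row[col])
        }
        sites: list[SiteAnnotation] = []
        for col, region in (("sites_utr5", "5UTR"), ("sites_cds", "CDS"), ("sites_utr3", "3UTR")):
            if col in df.columns:
                sites.extend(_parse_sites(row[col], region))
        crispr = None
        if "crispr_fc" in df.columns and not pd.isna(row["crispr_fc"]):
            p = None
            if "crispr_p" in df.columns and not pd.isna(row["crispr_p"]):
                p = float(row["crispr_p"])
            crispr = CrisprGeneRecord(gene=str(row["gene"]), fc=float(row["crispr_fc"]), p_adj=p)
        tid = row.get("transcript_id")
        tid = None if pd.isna(tid) or tid in ("", "N/A") else str(tid)
        records.append(
            TargetRecord(
                gene=str(row["gene"]),
                ratio_fc=ratio_fc,
                sites=sites,
                crispr=crispr,
                transcript_id=tid,
            )
        )
    return records


def read_mir26b_target_fixture() -> list[TargetRecord]:
    """The packaged table of 47 miR-26b-5p target genes found in both BL lines.

    Each record carries the fold change of the Ago2-IP/total ratio (miR-26b
    overexpression over empty vector) in DG75 and ST486, the gene's Brunello
    CRISPR dropout fold change and adjusted p where the gene was in that
    screen, and its annotated seed-match sites.
    """
    ref = resources.files("mirscreen.data").joinpath("mir26b_targets.tsv")
    with resources.as_file(ref) as path:
        records = read_target_table(path)
    if len(records) != 47:
        raise ValidationError(
            f"target fixture corrupt: expected 47 genes, found {len(records)}"
        )
    return records


def write_target_table(records: Iterable[TargetRecord], path: str | Path) -> None:
    """Write target records to TSV (inverse of :func:`read_target_table`)."""
    inv = {v: k for k, v in _SITE_ABBREV.items()}
    records = list(records)
    cell_lines: list[str] = []
    for r in records:
        for cl in r.ratio_fc:
            if cl not in cell_lines:
                cell_lines.append(cl)
    rows = []
    for r in records:
        row: dict[str, object] = {"gene": r.gene, "transcript_id": r.transcript_id or ""}
        for cl in cell_lines:
            row[f"ratio_fc_{cl}"] = r.ratio_fc.get(cl, "")
        row["crispr_fc"] = r.crispr.fc if r.crispr else ""
        row["crispr_p"] = (
            r.crispr.p_adj if r.crispr and r.crispr.p_adj is not None else ""
        )
        for col, region in (("sites_cds", "CDS"), ("sites_utr3", "3UTR"), ("sites_utr5", "5UTR")):
            abbrevs = [inv[s.site_class] for s in r.sites if s.region == region]
            row[col] = "/".join(abbrevs)
        row["priority"] = r.priority if r.priority is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
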