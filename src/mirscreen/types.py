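"""Core domain containers shared by all pipeline stages.

Tabular data is held in :class:`pandas.DataFrame` objects; the thin dataclass
wrappers here exist to bundle the matrices with their sample metadata and to
enforce the structural invariants each analysis stage relies on (matched
dimensions, non-negative counts, matched IP/T fractions, region partitions).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd


class ValidationError(ValueError):
    """Raised when an input table or container violates a structural invariant."""


# ---------------------------------------------------------------------------
# Pooled-screen containers
# ---------------------------------------------------------------------------

#: Column names required in a screen sample sheet.
SAMPLE_SHEET_COLUMNS = ("sample", "cell_line", "infection", "day", "pcr_rep")


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one sequenced screen sample.

    Parameters
    ----------
    cell_line:
        Cell-line label (e.g. ``"ST486"``, ``"DG75"``).
    infection:
        Independent-infection replicate index, 1-based.
    day:
        Days post infection at collection.
    pcr_rep:
        PCR replicate index, 1-based.
    """

    cell_line: str
    infection: int
    day: int
    pcr_rep: int

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError(f"day must be >= 0, got {self.day}")
        if self.infection < 1 or self.pcr_rep < 1:
            raise ValidationError(
                f"replicate indices must be >= 1, got infection={self.infection} "
                f"pcr_rep={self.pcr_rep}"
            )


@dataclass
class ScreenCounts:
    """Construct-by-sample barcode read counts for one pooled screen.

    ``counts`` rows are constructs, columns are sample names; ``samples`` maps
    each column to its :class:`SampleKey`.  ``controls`` flags the negative
    control constructs that by design do not affect cell growth.
    """

    counts: pd.DataFrame
    samples: Mapping[str, SampleKey]
    controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.controls = tuple(self.controls)
        missing = [c for c in self.counts.columns if c not in self.samples]
        if missing:
            raise ValidationError(f"sample columns without metadata: {missing}")
        extra = [s for s in self.samples if s not in self.counts.columns]
        if extra:
            raise ValidationError(f"sample sheet rows without count columns: {extra}")
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.columns[(self.counts < 0).any(axis=0)].tolist()
            raise ValidationError(f"negative counts in samples: {bad}")
        keys = list(self.samples.values())
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate sample keys: {dupes}")
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate construct IDs: {dupes}")
        unknown_controls = set(self.controls) - set(self.counts.index)
        if unknown_controls:
            raise ValidationError(
                f"controls not among constructs: {sorted(unknown_controls)}"
            )

    @property
    def constructs(self) -> list[str]:
        return list(self.counts.index)

    def sample_table(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample name."""
        rows = {
            name: {
                "cell_line": k.cell_line,
                "infection": k.infection,
                "day": k.day,
                "pcr_rep": k.pcr_rep,
            }
            for name, k in self.samples.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index").loc[
            list(self.counts.columns)
        ]


# ---------------------------------------------------------------------------
# RIP-chip containers
# ---------------------------------------------------------------------------

RIP_SAMPLE_COLUMNS = ("sample", "cell_line", "condition", "fraction", "duplicate")

CONDITIONS = ("miR", "EV")
FRACTIONS = ("T", "IP")


@dataclass(frozen=True, order=True)
class RipSampleKey:
    """Identity of one expression sample: total or Ago2-IP fraction."""

    cell_line: str
    condition: str  # "miR" (miRNA overexpression) or "EV" (empty vector)
    fraction: str  # "T" (total RNA) or "IP" (Ago2 immunoprecipitate)
    duplicate: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}")
        if self.fraction not in FRACTIONS:
            raise ValidationError(f"fraction must be one of {FRACTIONS}")
        if self.duplicate < 1:
            raise ValidationError("duplicate index must be >= 1")


@dataclass
class RipExperiment:
    """Probe-by-sample expression for one cell line's RIP-chip experiment.

    ``values`` holds processed intensities (positive where detected),
    ``present`` the array detection flags, and ``probe_gene`` the probe-to-gene
    mapping used when collapsing probe-level ratios to gene level.
    """

    values: pd.DataFrame
    present: pd.DataFrame
    samples: Mapping[str, RipSampleKey]
    probe_gene: Mapping[str, str]

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.present.columns) or not self.values.index.equals(
            self.present.index
        ):
            raise ValidationError("values and present matrices must be aligned")
        missing = [c for c in self.values.columns if c not in self.samples]
        if missing:
            raise ValidationError(f"sample columns without metadata: {missing}")
        unmapped = [p for p in self.values.index if p not in self.probe_gene]
        if unmapped:
            raise ValidationError(f"probes without gene mapping: {unmapped[:5]}")
        # every IP sample needs its matching T sample
        keys = set(self.samples.values())
        for key in keys:
            if key.fraction == "IP":
                mate = RipSampleKey(key.cell_line, key.condition, "T", key.duplicate)
                if mate not in keys:
                    raise ValidationError(f"IP sample {key} lacks a matching T sample")
        vals = self.values.to_numpy()
        flags = self.present.to_numpy().astype(bool)
        if (vals[flags] <= 0).any():
            raise ValidationError("present probes must have positive expression")

    def columns_for(
        self, condition: str | None = None, fraction: str | None = None
    ) -> list[str]:
        """Sample names matching the given condition and/or fraction."""
        out = []
        for name, key in self.samples.items():
            if condition is not None and key.condition != condition:
                continue
            if fraction is not None and key.fraction != fraction:
                continue
            out.append(name)
        return out

    @property
    def cell_line(self) -> str:
        lines = {k.cell_line for k in self.samples.values()}
        if len(lines) != 1:
            raise ValidationError(f"experiment spans multiple cell lines: {sorted(lines)}")
        return next(iter(lines))


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

_RNA_OK = re.compile(r"^[ACGU]+$")
_DNA_OK = re.compile(r"^[ACGTN]+$")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: name plus 5'->3' sequence.

    The sequence is stored uppercase RNA; ``T`` on input is accepted and mapped
    to ``U``.  The seed (positions 2-8, 1-based) is derived, never stored.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 8:
            raise ValidationError(
                f"mature miRNA {self.name!r} must be >= 8 nt, got {len(seq)}"
            )
        if not _RNA_OK.match(seq):
            raise ValidationError(f"invalid RNA characters in {self.name!r}")

    @property
    def seed(self) -> str:
        """Seed region: nucleotides 2-8 (1-based) of the mature strand."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class TranscriptRegions:
    """A transcript sequence partitioned into 5'UTR / CDS / 3'UTR.

    Coordinates are 0-based half-open: the 5'UTR is ``[0, cds_start)``, the CDS
    ``[cds_start, cds_end)`` and the 3'UTR ``[cds_end, len)``.  Sequences are
    stored uppercase DNA.
    """

    transcript_id: str
    sequence: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if not _DNA_OK.match(seq):
            raise ValidationError(
                f"invalid sequence characters in transcript {self.transcript_id!r}"
            )
        if not (0 <= self.cds_start <= self.cds_end <= len(seq)):
            raise ValidationError(
                f"transcript {self.transcript_id!r}: CDS [{self.cds_start}, "
                f"{self.cds_end}) outside sequence of length {len(seq)}"
            )

    @property
    def utr5(self) -> str:
        return self.sequence[: self.cds_start]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def utr3(self) -> str:
        return self.sequence[self.cds_end :]

    def region_of(self, position: int) -> str:
        """Region name ('5UTR', 'CDS' or '3UTR') containing a 0-based position."""
        if not 0 <= position < len(self.sequence):
            raise ValidationError(
                f"position {position} outside transcript {self.transcript_id!r}"
            )
        if position < self.cds_start:
            return "5UTR"
        if position < self.cds_end:
            return "CDS"
        return "3UTR"


# ---------------------------------------------------------------------------
# CRISPR screen and target records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrisprGeneRecord:
    """Gene-level result from a CRISPR dropout screen.

    ``fc`` is the signed fold change reported by the screen analysis (negative
    for depleted sgRNAs); ``p_adj`` the adjusted p-value, ``None`` when the
    screen did not report one.
    """

    gene: str
    fc: float
    p_adj: float | None = None

    def __post_init__(self) -> None:
        if self.p_adj is not None and not (0.0 <= self.p_adj <= 1.0):
            raise ValidationError(
                f"adjusted p for {self.gene!r} outside [0, 1]: {self.p_adj}"
            )


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated seed-match site on a target transcript."""

    region: str  # "5UTR", "CDS" or "3UTR"
    site_class: str  # "8mer", "7mer-m8" or "7mer-A1"
    position: int | None = None  # 1-based relative to ORF start; None if unknown


@dataclass
class TargetRecord:
    """One putative miRNA target gene with its supporting evidence.

    ``ratio_fc`` maps cell line -> fold change of the IP/T ratio (miRNA
    overexpression over empty vector).  ``sites`` lists annotated seed-match
    sites; ``crispr`` carries the gene's dropout-screen record when the gene
    was present in that screen; ``priority`` is filled by the prioritization
    stage (1 = strongest candidate).
    """

    gene: str
    ratio_fc: dict[str, float] = field(default_factory=dict)
    sites: list[SiteAnnotation] = field(default_factory=list)
    crispr: CrisprGeneRecord | None = None
    priority: int | None = None
    transcript_id: str | None = None


def as_frame(records: Iterable[TargetRecord], cell_lines: Sequence[str] | None = None) -> pd.DataFrame:
    """Flatten target records into a DataFrame (one row per gene)."""
    records = list(records)
    if cell_lines is None:
        seen: list[str] = []
        for r in records:
            for cl in r.ratio_fc:
                if cl not in seen:
                    seen.append(cl)
        cell_lines = seen
    rows = []
    for r in records:
        row: dict[str, object] = {"gene": r.gene, "transcript_id": r.transcript_id}
        for cl in cell_lines:
            row[f"ratio_fc_{cl}"] = r.ratio_fc.get(cl)
        row["crispr_fc"] = r.crispr.fc if r.crispr else None
        row["crispr_p_adj"] = r.crispr.p_adj if r.crispr else None
        row["sites"] = ";".join(
            f"{s.region}:{s.site_class}" + (f"@{s.position}" if s.position is not None else "")
            for s in r.sites
        )
        row["priority"] = r.priority
        rows.append(row)
    return pd.DataFrame(rows)
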