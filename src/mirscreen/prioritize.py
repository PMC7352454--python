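"""Prioritize miRNA target genes by essentiality in a CRISPR dropout screen.

Candidate targets from the RIP-chip stage are joined to a gene-level CRISPR
screen table; genes significantly depleted from the knockout pool
(fc < 0, p_adj below a strict cutoff) are growth-relevant targets, and the
most strongly depleted of those (fc below a fold-change cutoff) are ranked as
top candidates.
"""

from __future__ import annotations

from .types import CrisprGeneRecord, TargetRecord, ValidationError

DEFAULT_P_MAX = 0.001
DEFAULT_FC_CUTOFF = -5.0


def _norm(gene: str) -> str:
    return gene.strip().upper()


def join_crispr(
    targets: list[TargetRecord], crispr: list[CrisprGeneRecord]
) -> tuple[list[TargetRecord], list[str]]:
    """Attach CRISPR records to targets by gene symbol (case-insensitive).

    Returns the annotated targets (input order preserved; new objects) and the
    list of target genes absent from the CRISPR table.
    """
    table: dict[str, CrisprGeneRecord] = {}
    for rec in crispr:
        key = _norm(rec.gene)
        if key in table:
            raise ValidationError(f"duplicate gene in CRISPR table: {rec.gene!r}")
        table[key] = rec
    joined = []
    absent = []
    for t in targets:
        rec = table.get(_norm(t.gene))
        if rec is None:
            absent.append(t.gene)
        joined.append(
            TargetRecord(
                gene=t.gene,
                ratio_fc=dict(t.ratio_fc),
                sites=list(t.sites),
                crispr=rec,
                priority=t.priority,
                transcript_id=t.transcript_id,
            )
        )
    return joined, absent


def significant_depleted(
    records: list[TargetRecord], p_max: float = DEFAULT_P_MAX
) -> list[TargetRecord]:
    """Targets significantly depleted in the CRISPR screen.

    Keeps records with CRISPR data, negative fold change and adjusted
    p strictly below ``p_max``.
    """
    out = []
    for t in records:
        c = t.crispr
        if c is None or c.p_adj is None:
            continue
        if c.fc < 0 and c.p_adj < p_max:
            out.append(t)
    return out


def top_candidates(
    records: list[TargetRecord], fc_cutoff: float = DEFAULT_FC_CUTOFF
) -> list[TargetRecord]:
    """Rank the most strongly depleted targets.

    Keeps records with CRISPR fold change strictly below ``fc_cutoff`` and
    returns them sorted ascending by fold change (strongest depletion first),
    with ``priority`` set to 1, 2, ...
    """
    selected = [t for t in records if t.crispr is not None and t.crispr.fc < fc_cutoff]
    selected.sort(key=lambda t: (t.crispr.fc, _norm(t.gene)))  # type: ignore[union-attr]
    ranked = []
    for rank, t in enumerate(selected, start=1):
        ranked.append(
            TargetRecord(
                gene=t.gene,
                ratio_fc=dict(t.ratio_fc),
                sites=list(t.sites),
                crispr=t.crispr,
                priority=rank,
                transcript_id=t.transcript_id,
            )
        )
    return ranked


def prioritize(
    targets: list[TargetRecord],
    crispr: list[CrisprGeneRecord],
    p_max: float = DEFAULT_P_MAX,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
) -> dict[str, object]:
    """Full chain: join, filter to significant depletion, rank top candidates.

    Returns a dict with keys ``joined``, ``absent``, ``significant`` and
    ``candidates``.
    """
    joined, absent = join_crispr(targets, crispr)
    significant = significant_depleted(joined, p_max=p_max)
    candidates = top_candidates(significant, fc_cutoff=fc_cutoff)
    return {
        "joined": joined,
        "absent": absent,
        "significant": significant,
        "candidates": candidates,
    }
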