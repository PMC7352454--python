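"""Canonical miRNA seed-match motifs and transcript site annotation.

The three canonical site classes on a target mRNA (5'->3' DNA):

* ``8mer``    — perfect Watson-Crick match to miRNA positions 2-8 plus an
  ``A`` opposite position 1,
* ``7mer-m8`` — match to positions 2-8,
* ``7mer-A1`` — match to positions 2-7 plus the position-1 ``A``.

The 8mer motif therefore contains both 7mer motifs; a locus matching the 8mer
is reported once, as an 8mer (class precedence 8mer > 7mer-m8 > 7mer-A1).
Scanning is on the sense strand only, with positions reported 1-based relative
to the ORF start (negative upstream of it).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .types import MatureMiRNA, TranscriptRegions, ValidationError

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class SiteMotifs:
    """Target-site motifs derived from one mature miRNA (5'->3' DNA)."""

    mirna: MatureMiRNA
    seed: str  # miRNA positions 2-8, RNA
    m8mer: str
    m7m8: str
    m7A1: str


@dataclass(frozen=True)
class SiteHit:
    """One seed-match site on a transcript."""

    transcript_id: str
    region: str  # "5UTR", "CDS" or "3UTR"
    site_class: str
    position: int  # 1-based relative to ORF start; negative in the 5'UTR


def _revcomp_dna(rna: str) -> str:
    return str(Seq(rna.replace("U", "T")).reverse_complement())


def derive_motifs(mirna: MatureMiRNA) -> SiteMotifs:
    """Build the 8mer / 7mer-m8 / 7mer-A1 motifs for a mature miRNA.

    The 7mer-m8 is the reverse complement of miRNA positions 2-8; the 8mer
    appends the invariant ``A`` opposite position 1; the 7mer-A1 is the
    reverse complement of positions 2-7 plus that ``A``.
    """
    seed = mirna.seed  # positions 2-8
    m7m8 = _revcomp_dna(seed)
    m8mer = m7m8 + "A"
    m7A1 = _revcomp_dna(mirna.sequence[1:7]) + "A"
    assert m8mer == m7m8 + "A" and m7A1 == m8mer[1:]
    return SiteMotifs(mirna=mirna, seed=seed, m8mer=m8mer, m7m8=m7m8, m7A1=m7A1)


def _find_all(sequence: str, motif: str) -> list[int]:
    """All (overlapping) 0-based occurrences of motif; N never matches."""
    hits = []
    start = sequence.find(motif)
    while start != -1:
        hits.append(start)
        start = sequence.find(motif, start + 1)
    return hits


def scan_sequence(sequence: str, motifs: SiteMotifs) -> list[tuple[str, int]]:
    """All seed-match sites in a DNA sequence, as (class, 0-based start).

    8mer occurrences take precedence: the 7mer-m8 and 7mer-A1 matches they
    contain are not reported separately.  Otherwise overlapping sites are all
    reported.  ``N`` matches nothing; other characters outside {A,C,G,T,N}
    are rejected.
    """
    seq = sequence.upper().replace("U", "T")
    if any(c not in "ACGTN" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGTN"})
        raise ValidationError(f"invalid sequence characters: {bad}")
    eight = _find_all(seq, motifs.m8mer)
    hits = [("8mer", s) for s in eight]
    covered = set(eight)
    # inside an 8mer at s, the 7mer-m8 starts at s and the 7mer-A1 at s + 1
    hits += [
        ("7mer-m8", s) for s in _find_all(seq, motifs.m7m8) if s not in covered
    ]
    hits += [
        ("7mer-A1", s)
        for s in _find_all(seq, motifs.m7A1)
        if (s - 1) not in covered
    ]
    return sorted(hits, key=lambda h: (h[1], SITE_CLASSES.index(h[0])))


def orf_relative(position: int, cds_start: int) -> int:
    """Convert a 0-based transcript offset to a 1-based ORF-relative position.

    The first CDS nucleotide is +1; the nucleotide immediately upstream is -1
    (there is no position 0).
    """
    return position - cds_start + 1 if position >= cds_start else position - cds_start


def annotate_transcript(t: TranscriptRegions, motifs: SiteMotifs) -> list[SiteHit]:
    """Seed-match sites on a transcript with region and ORF-relative position.

    The full sequence is scanned once, so sites spanning a region boundary are
    found and assigned to the region containing their first nucleotide.
    """
    out = []
    for site_class, start in scan_sequence(t.sequence, motifs):
        out.append(
            SiteHit(
                transcript_id=t.transcript_id,
                region=t.region_of(start),
                site_class=site_class,
                position=orf_relative(start, t.cds_start),
            )
        )
    return out


def percent_identity(a: str, b: str) -> float:
    """Ungapped positional identity of two equal-length sequences, in percent.

    Case-insensitive, with U and T equivalent.
    """
    if len(a) != len(b):
        raise ValidationError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "ungapped identity requires equal lengths"
        )
    if not a:
        raise ValidationError("sequences must be non-empty")
    x = a.upper().replace("U", "T")
    y = b.upper().replace("U", "T")
    matches = sum(1 for p, q in zip(x, y) if p == q)
    return 100.0 * matches / len(x)
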