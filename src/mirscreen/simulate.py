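"""Synthetic data generators with ground truth for every pipeline stage.

Three generators emulate the data each analysis stage consumes:

* :func:`simulate_screen` — pooled-screen barcode counts across time points,
  infections and PCR replicates.  Construct abundance follows exponential
  growth with a per-day relative fitness (1 for neutral constructs and
  controls, ``fitness_effect`` for dropouts, its reciprocal for enriched
  constructs); sequencing is compositional, so reads per sample are drawn
  from a multinomial at fixed depth, with optional gamma overdispersion on
  the abundances.
* :func:`simulate_ripchip` — paired total/Ago2-IP expression in duplicate for
  multiple cell lines, with planted IP enrichment for true targets under
  miRNA overexpression and a baseline RISC occupancy for everything else.
* :func:`simulate_transcripts` — transcripts with 5'UTR/CDS/3'UTR structure
  and seed-match sites planted at recorded positions, with spurious motif
  occurrences scrubbed from the background (opt-out).

All generators are deterministic under a fixed seed and return truth tables
sufficient to score the downstream stage without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seeds as seeds_mod
from .types import (
    MatureMiRNA,
    RipExperiment,
    RipSampleKey,
    SampleKey,
    ScreenCounts,
    TranscriptRegions,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Pooled screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimParams:
    """Design of a simulated pooled screen.

    Defaults follow the screen design this package analyses: a pool of ~60
    constructs with two negative controls, duplicate infections of one cell
    line, collection at days 5/7/15/25/40, duplicate PCRs and 50,000 reads
    per sample.  ``fitness_effect`` is the per-day relative growth multiplier
    of dropout constructs (enriched constructs grow at its reciprocal).
    """

    n_constructs: int = 60
    n_controls: int = 2
    n_dropout: int = 6
    n_enriched: int = 3
    fitness_effect: float = 0.85
    days: tuple[int, ...] = (5, 7, 15, 25, 40)
    depth: int = 50_000
    dispersion: float = 0.05
    infections: int = 2
    pcr_reps: int = 2
    cell_line: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dropout + self.n_enriched + self.n_controls > self.n_constructs:
            raise ValidationError("hit + control constructs exceed pool size")
        if self.fitness_effect <= 0:
            raise ValidationError("fitness_effect must be positive")
        if self.depth <= 0 or self.pcr_reps < 1 or self.infections < 1:
            raise ValidationError("depth and replicate counts must be positive")
        if len(self.days) < 2:
            raise ValidationError("need at least two time points")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")


def simulate_screen(params: ScreenSimParams) -> tuple[ScreenCounts, pd.DataFrame]:
    """Simulate barcode counts for a pooled dropout/enrichment screen.

    Returns the counts plus a truth table (construct, class, fitness) where
    class is one of control / neutral / dropout / enriched.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_constructs
    names = [f"ctrl-{i + 1}" for i in range(params.n_controls)] + [
        f"construct-{i + 1}" for i in range(n - params.n_controls)
    ]
    classes = ["control"] * params.n_controls + ["neutral"] * (n - params.n_controls)
    # plant hits among the non-control constructs
    hit_idx = params.n_controls + np.arange(params.n_dropout + params.n_enriched)
    fitness = np.ones(n)
    for j, idx in enumerate(hit_idx):
        if j < params.n_dropout:
            classes[idx] = "dropout"
            fitness[idx] = params.fitness_effect
        else:
            classes[idx] = "enriched"
            fitness[idx] = 1.0 / params.fitness_effect
    day0 = min(params.days)
    counts: dict[str, np.ndarray] = {}
    samples: dict[str, SampleKey] = {}
    for infection in range(1, params.infections + 1):
        for day in params.days:
            abundance = fitness ** (day - day0)
            for rep in range(1, params.pcr_reps + 1):
                w = abundance.copy()
                if params.dispersion > 0:
                    shape = 1.0 / params.dispersion
                    w = w * rng.gamma(shape, scale=1.0 / shape, size=n)
                name = f"{params.cell_line}_i{infection}_d{day}_r{rep}"
                counts[name] = rng.multinomial(params.depth, w / w.sum())
                samples[name] = SampleKey(
                    cell_line=params.cell_line, infection=infection, day=day, pcr_rep=rep
                )
    sc = ScreenCounts(
        counts=pd.DataFrame(counts, index=names),
        samples=samples,
        controls=tuple(names[: params.n_controls]),
    )
    truth = pd.DataFrame({"construct": names, "class": classes, "fitness": fitness})
    return sc, truth


# ---------------------------------------------------------------------------
# RIP-chip
# ---------------------------------------------------------------------------


@dataclass
class RipSimParams:
    """Design of a simulated Ago2-RIP-chip experiment.

    ``enrichment_fc`` multiplies the IP signal of true targets under miRNA
    overexpression; all transcripts carry a baseline RISC occupancy drawn
    uniformly from ``baseline_range``.  ``noise_sigma`` is the log-normal
    scale of the multiplicative noise on the IP signal (the IP and total
    fractions come from the same lysate, so this is the dispersion of the
    IP/T ratio itself).  True targets are drawn from the well-expressed range
    of the intensity distribution; a separate fraction of low-expressed
    background probes exercises the presence/percentile filter.
    """

    n_probes: int = 1000
    n_true_targets: int = 100
    enrichment_fc: float = 4.0
    noise_sigma: float = 0.25
    duplicates: int = 2
    cell_lines: tuple[str, ...] = ("SIM1", "SIM2")
    baseline_range: tuple[float, float] = (1.0, 2.0)
    expr_mu: float = 8.0
    expr_sigma: float = 1.2
    detection_floor_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_targets > self.n_probes:
            raise ValidationError("n_true_targets exceeds n_probes")
        if self.enrichment_fc < 1:
            raise ValidationError("enrichment_fc must be >= 1")
        if self.noise_sigma < 0 or self.duplicates < 1:
            raise ValidationError("invalid noise_sigma or duplicates")


def simulate_ripchip(
    params: RipSimParams,
) -> tuple[dict[str, RipExperiment], pd.DataFrame]:
    """Simulate paired total/IP expression per cell line, with planted targets.

    Returns ({cell line: experiment}, truth) where truth lists every gene with
    an ``is_target`` flag.  Probes map 1:1 to genes.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_probes
    genes = [f"GENE{i + 1}" for i in range(n)]
    probes = [f"P{i + 1}" for i in range(n)]
    is_target = np.zeros(n, dtype=bool)
    is_target[: params.n_true_targets] = True
    floor = float(np.exp(params.expr_mu - params.detection_floor_sd * params.expr_sigma))
    experiments: dict[str, RipExperiment] = {}
    for cell_line in params.cell_lines:
        # baseline expression: targets drawn from the well-expressed range
        log_t = rng.normal(params.expr_mu, params.expr_sigma, size=n)
        log_t[is_target] = rng.normal(
            params.expr_mu + params.expr_sigma, 0.8 * params.expr_sigma,
            size=params.n_true_targets,
        )
        t_base = np.exp(log_t)
        occupancy = rng.uniform(*params.baseline_range, size=n)
        values: dict[str, np.ndarray] = {}
        samples: dict[str, RipSampleKey] = {}
        for condition in ("miR", "EV"):
            enrich = np.where(
                is_target & (condition == "miR"), params.enrichment_fc, 1.0
            )
            for dup in range(1, params.duplicates + 1):
                t_vals = t_base * rng.lognormal(0.0, 0.1, size=n)
                ip_vals = (
                    t_vals
                    * occupancy
                    * enrich
                    * rng.lognormal(0.0, params.noise_sigma, size=n)
                )
                for fraction, vals in (("T", t_vals), ("IP", ip_vals)):
                    name = f"{cell_line}_{condition}_{fraction}_{dup}"
                    values[name] = vals
                    samples[name] = RipSampleKey(
                        cell_line=cell_line,
                        condition=condition,
                        fraction=fraction,
                        duplicate=dup,
                    )
        frame = pd.DataFrame(values, index=probes)
        present = frame >= floor
        experiments[cell_line] = RipExperiment(
            values=frame,
            present=present,
            samples=samples,
            probe_gene=dict(zip(probes, genes)),
        )
    truth = pd.DataFrame({"gene": genes, "probe": probes, "is_target": is_target})
    return experiments, truth


# ---------------------------------------------------------------------------
# Transcripts with planted seed sites
# ---------------------------------------------------------------------------

_MOTIF_LEN = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7}


@dataclass
class TranscriptSimParams:
    """Design of a simulated transcript set with planted seed-match sites.

    ``planted`` lists (region, site class) pairs inserted into *each*
    transcript.  With ``scrub_spurious`` on (default), background positions
    that happen to spell a seed-match motif are redrawn so the planted truth
    is the complete site list.
    """

    mirna: MatureMiRNA
    n_transcripts: int = 10
    length_range: tuple[int, int] = (600, 1200)
    utr5_frac: float = 0.15
    cds_frac: float = 0.50
    planted: list[tuple[str, str]] = field(default_factory=list)
    gc: float = 0.45
    scrub_spurious: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for region, site_class in self.planted:
            if region not in ("5UTR", "CDS", "3UTR"):
                raise ValidationError(f"unknown region {region!r}")
            if site_class not in _MOTIF_LEN:
                raise ValidationError(f"unknown site class {site_class!r}")
        if not 0 < self.gc < 1:
            raise ValidationError("gc must be in (0, 1)")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 30:
            raise ValidationError("invalid length range")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def simulate_transcripts(
    params: TranscriptSimParams,
) -> tuple[list[TranscriptRegions], pd.DataFrame]:
    """Simulate transcripts with seed-match sites planted at known positions.

    Returns the transcripts and a truth table (transcript_id, region,
    site_class, start [0-based], orf_position [1-based, negative in the
    5'UTR]).
    """
    rng = np.random.default_rng(params.seed)
    motifs = seeds_mod.derive_motifs(params.mirna)
    motif_seq = {
        "8mer": motifs.m8mer,
        "7mer-m8": motifs.m7m8,
        "7mer-A1": motifs.m7A1,
    }
    transcripts = []
    truth_rows = []
    for i in range(params.n_transcripts):
        tid = f"TX{i + 1}"
        length = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
        cds_start = int(round(params.utr5_frac * length))
        cds_end = cds_start + int(round(params.cds_frac * length))
        region_span = {
            "5UTR": (0, cds_start),
            "CDS": (cds_start, cds_end),
            "3UTR": (cds_end, length),
        }
        seq = _random_sequence(rng, length, params.gc)
        # choose non-overlapping planted loci
        placements: list[tuple[int, int, str]] = []  # (start, end, class)
        for region, site_class in params.planted:
            lo, hi = region_span[region]
            width = _MOTIF_LEN[site_class]
            if hi - lo < width:
                raise ValidationError(
                    f"region {region} of {tid} too short for a {site_class} site"
                )
            for _ in range(1000):
                start = int(rng.integers(lo, hi - width + 1))
                # keep planted loci >= 8 nt apart so no motif window can span
                # two of them, guaranteeing the spurious-site scrub terminates
                if all(start + width + 8 <= s or start >= e + 8 for s, e, _ in placements):
                    break
            else:
                raise ValidationError(f"cannot place planted sites in {tid}")
            placements.append((start, start + width, site_class))
            seq[start : start + width] = list(motif_seq[site_class])
            truth_rows.append(
                {
                    "transcript_id": tid,
                    "region": region,
                    "site_class": site_class,
                    "start": start,
                    "orf_position": seeds_mod.orf_relative(start, cds_start),
                }
            )
        planted_cover = np.zeros(length, dtype=bool)
        for s, e, _ in placements:
            planted_cover[s:e] = True
        expected = {(c, s) for s, _, c in placements}
        if params.scrub_spurious:
            for _ in range(200):
                observed = set(seeds_mod.scan_sequence("".join(seq), motifs))
                spurious = observed - expected
                if not spurious and expected <= observed:
                    break
                for site_class, start in spurious:
                    span = np.arange(start, start + _MOTIF_LEN[site_class])
                    redraw = span[~planted_cover[span]]
                    seq[redraw] = _random_sequence(rng, len(redraw), params.gc)
            else:  # pragma: no cover - would need adversarial composition
                raise ValidationError(f"could not scrub spurious sites in {tid}")
        transcripts.append(
            TranscriptRegions(
                transcript_id=tid,
                sequence="".join(seq),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "region", "site_class", "start", "orf_position"],
    )
    return transcripts, truth
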