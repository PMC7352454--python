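"""Ago2-RIP-chip target identification from paired total/IP expression.

Transcripts bound by miRNA-loaded RISC are enriched in the Ago2
immunoprecipitate (IP) relative to total RNA (T).  The analysis keeps probes
reliably detected in the total fractions, computes IP/T ratios per duplicate,
collapses probes to genes, and calls a gene a candidate miRNA target when its
IP/T ratio under miRNA overexpression is at least ``min_ratio`` and at least
``min_fc``-fold higher than under the empty-vector control.  Genes passing in
every assayed cell line form the high-confidence overlap set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .types import RipExperiment, ValidationError

DEFAULT_PERCENTILE = 25.0
DEFAULT_MIN_RATIO = 2.0
DEFAULT_MIN_FC = 2.0

#: Duplicate IP/T ratios are "consistent" when they sit on the same side of 1
#: or differ by less than this factor.
CONSISTENCY_FOLD = 2.0


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------


def presence_filter(
    exp: RipExperiment, lower_percentile: float = DEFAULT_PERCENTILE
) -> list[str]:
    """Probes detected in every total fraction at usable expression levels.

    A probe is kept when it is flagged present in *all* total-fraction samples
    and, in every total sample, its expression is at or above that sample's
    ``lower_percentile``-th percentile (computed over the sample's present
    probes).
    """
    t_cols = exp.columns_for(fraction="T")
    if not t_cols:
        raise ValidationError("experiment has no total-fraction samples")
    keep = exp.present[t_cols].all(axis=1)
    for col in t_cols:
        vals = exp.values[col]
        floor = np.percentile(vals[exp.present[col]].to_numpy(), lower_percentile)
        keep &= vals >= floor
    return exp.values.index[keep].tolist()


# ---------------------------------------------------------------------------
# IP/T ratios
# ---------------------------------------------------------------------------


def _duplicate_ratios(exp: RipExperiment, probes: list[str]) -> pd.DataFrame:
    """Long-format probe-level IP/T ratios per (condition, duplicate)."""
    rows = []
    pairs = sorted(
        {(k.condition, k.duplicate) for k in exp.samples.values() if k.fraction == "IP"}
    )
    t_pairs = {
        (k.condition, k.duplicate) for k in exp.samples.values() if k.fraction == "T"
    }
    dangling = t_pairs - set(pairs)
    if dangling:
        raise ValidationError(f"total samples without a matched IP fraction: {sorted(dangling)}")
    for condition, duplicate in pairs:
        ip_col = [
            n
            for n, k in exp.samples.items()
            if k.condition == condition and k.duplicate == duplicate and k.fraction == "IP"
        ]
        t_col = [
            n
            for n, k in exp.samples.items()
            if k.condition == condition and k.duplicate == duplicate and k.fraction == "T"
        ]
        if len(ip_col) != 1 or len(t_col) != 1:
            raise ValidationError(
                f"condition {condition} duplicate {duplicate} lacks a unique IP/T pair"
            )
        ip = exp.values.loc[probes, ip_col[0]]
        t = exp.values.loc[probes, t_col[0]]
        present = exp.present.loc[probes, ip_col[0]] & exp.present.loc[probes, t_col[0]]
        rows.append(
            pd.DataFrame(
                {
                    "probe": probes,
                    "condition": condition,
                    "duplicate": duplicate,
                    "ratio": (ip / t).to_numpy(),
                    "detected": present.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _consistent(ratios: np.ndarray) -> bool:
    """Duplicate-consistency rule: same side of 1, or within CONSISTENCY_FOLD."""
    if len(ratios) < 2:
        return True
    same_side = (ratios >= 1.0).all() or (ratios <= 1.0).all()
    within_fold = ratios.max() / ratios.min() <= CONSISTENCY_FOLD
    return bool(same_side or within_fold)


def ip_t_ratios(
    exp: RipExperiment,
    probes: list[str],
    collapse: str = "max",
) -> pd.DataFrame:
    """Gene-level IP/T ratios per condition, averaged over duplicates.

    Probes must be detected in both duplicates of each fraction and show
    consistent duplicate ratios (same side of 1 or within 2-fold) in every
    condition; inconsistent probes are dropped.  Probe ratios are averaged
    over duplicates, then collapsed per gene (default: the maximum across a
    gene's probes — a target need only be captured by its best probe).

    Returns a frame indexed by gene with one ``ratio_<condition>`` column per
    condition.
    """
    if collapse not in ("max", "mean"):
        raise ValidationError(f"unknown collapse rule {collapse!r}")
    long = _duplicate_ratios(exp, probes)
    # consistency: detected in all duplicate pairs and ratios agree, per condition
    ok_probes = set(probes)
    for (probe, _), grp in long.groupby(["probe", "condition"], sort=False):
        if not grp["detected"].all() or not _consistent(grp["ratio"].to_numpy()):
            ok_probes.discard(probe)
    long = long[long["probe"].isin(ok_probes)]
    if long.empty:
        return pd.DataFrame(columns=["gene"]).set_index("gene")
    probe_means = (
        long.groupby(["probe", "condition"], sort=False)["ratio"].mean().unstack()
    )
    probe_means["gene"] = [exp.probe_gene[p] for p in probe_means.index]
    agg = probe_means.groupby("gene").agg(collapse)
    agg.columns = [f"ratio_{c}" for c in agg.columns]
    return agg


# ---------------------------------------------------------------------------
# Target calling
# ---------------------------------------------------------------------------


def enriched_genes(
    ratios: pd.DataFrame, condition: str, min_ratio: float = DEFAULT_MIN_RATIO
) -> set[str]:
    """Genes whose IP/T ratio in ``condition`` is >= ``min_ratio``."""
    col = f"ratio_{condition}"
    if col not in ratios.columns:
        raise ValidationError(f"no ratios for condition {condition!r}")
    vals = ratios[col].dropna()
    return set(vals.index[vals >= min_ratio])


def differential_enrichment(
    ratios: pd.DataFrame,
    min_fc: float = DEFAULT_MIN_FC,
    min_ratio: float = DEFAULT_MIN_RATIO,
    treatment: str = "miR",
    control: str = "EV",
) -> pd.DataFrame:
    """Genes preferentially RISC-loaded under miRNA overexpression.

    Keeps genes with ratio(treatment) >= ``min_ratio`` and
    ratio(treatment)/ratio(control) >= ``min_fc``.  Returns a frame with the
    two condition ratios and the fold change, sorted by fold change
    descending.
    """
    t_col, c_col = f"ratio_{treatment}", f"ratio_{control}"
    for col in (t_col, c_col):
        if col not in ratios.columns:
            raise ValidationError(f"no ratios for condition column {col!r}")
    df = ratios[[t_col, c_col]].dropna()
    df = df.assign(fc=df[t_col] / df[c_col])
    hits = df[(df[t_col] >= min_ratio) & (df["fc"] >= min_fc)]
    return hits.sort_values("fc", ascending=False)


def overlap_targets(per_cell_line: dict[str, set[str]]) -> tuple[set[str], dict[str, set[str]]]:
    """Intersection of per-cell-line target sets plus the exclusive remainders.

    Returns (shared targets, {cell line: targets found only in that line}).
    """
    if len(per_cell_line) < 2:
        raise ValidationError("need target sets from >= 2 cell lines")
    sets = list(per_cell_line.values())
    shared = set.intersection(*sets)
    only = {cl: s - shared for cl, s in per_cell_line.items()}
    return shared, only


def ranked_list(ratios: pd.DataFrame, treatment: str = "miR", control: str = "EV") -> pd.Series:
    """Genes ranked by IP/T fold change (treatment over control), descending.

    Suitable for export as a GSEA preranked (.rnk) list.
    """
    t_col, c_col = f"ratio_{treatment}", f"ratio_{control}"
    df = ratios[[t_col, c_col]].dropna()
    score = (df[t_col] / df[c_col]).sort_values(ascending=False)
    score.name = "score"
    return score


def write_rnk(score: pd.Series, path) -> None:
    """Write a ranked gene list in the two-column GSEA preranked dialect."""
    score.to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------


def chisq_enrichment(
    hits_in_category: int, hits_total: int, background_fraction: float
) -> tuple[float, float, bool]:
    """Goodness-of-fit chi-squared test for category enrichment among hits.

    Compares the observed split (in category, not in category) of
    ``hits_total`` genes against the expectation under ``background_fraction``.
    Returns (chi2, upper-tail p on 1 df, low_expected flag); the flag is set
    when any expected cell is below 1, where the chi-squared approximation is
    unreliable.
    """
    if hits_total <= 0:
        raise ValidationError("hits_total must be positive")
    if not 0.0 < background_fraction < 1.0:
        raise ValidationError("background_fraction must be in (0, 1)")
    if not 0 <= hits_in_category <= hits_total:
        raise ValidationError("hits_in_category must be within [0, hits_total]")
    observed = np.array([hits_in_category, hits_total - hits_in_category], dtype=float)
    expected = hits_total * np.array(
        [background_fraction, 1.0 - background_fraction], dtype=float
    )
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p, bool((expected < 1.0).any())


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def identify_targets(
    experiments: dict[str, RipExperiment],
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_fc: float = DEFAULT_MIN_FC,
    lower_percentile: float = DEFAULT_PERCENTILE,
    collapse: str = "max",
) -> tuple[set[str], dict[str, pd.DataFrame]]:
    """Run the RIP-chip pipeline per cell line and intersect the target sets.

    ``experiments`` maps cell line -> :class:`RipExperiment`.  Returns the
    shared target set and, per cell line, the differential-enrichment table.
    """
    tables = {}
    per_line_sets = {}
    for cell_line, exp in experiments.items():
        probes = presence_filter(exp, lower_percentile=lower_percentile)
        ratios = ip_t_ratios(exp, probes, collapse=collapse)
        hits = differential_enrichment(ratios, min_fc=min_fc, min_ratio=min_ratio)
        tables[cell_line] = hits
        per_line_sets[cell_line] = set(hits.index)
    if len(experiments) >= 2:
        shared, _ = overlap_targets(per_line_sets)
    else:
        shared = next(iter(per_line_sets.values()), set())
    return shared, tables
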