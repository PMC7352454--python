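"""Hit calling for pooled construct screens from barcode counts over time.

The pipeline mirrors how pooled lentiviral dropout/enrichment screens are
quantified: per-sample totals are scaled to a fixed sequencing depth, PCR
replicates are averaged, poorly represented constructs are removed, per-day
fold changes against the first time point are transformed onto a signed scale
("adapted" fold change, 0 = no change), a trend-line slope through the origin
is fitted per construct and infection, and constructs whose slopes fall
outside Tukey-style interquartile bounds in *both* independent infections of a
cell line are called depleted or enriched.

The adapted fold change maps fc >= 1 to fc - 1 and fc < 1 to 1 - 1/fc, so a
halving and a doubling sit symmetrically at -1 and +1; depletion therefore
produces negative slopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import SampleKey, ScreenCounts, ValidationError

#: Fixed totals the two pool types are scaled to, reflecting the estimated
#: number of cells per PCR reaction (inhibition pool: 50,000; overexpression
#: pool: 20,000).
POOL_TARGET_TOTALS = {"mirzip": 50_000.0, "pcdh": 20_000.0}

#: Constructs averaging fewer reads than this at the first time point are
#: excluded from analysis.
DEFAULT_MIN_READS = 50.0

#: IQR multiplier for the outlier bounds (Q1 - k*IQR, Q3 + k*IQR).
DEFAULT_IQR_K = 1.0

#: Pseudocount applied to zero counts after the baseline so that fold changes
#: stay finite; baseline zeros cannot occur after the low-abundance filter.
ZERO_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# Count preprocessing
# ---------------------------------------------------------------------------


def normalize_totals(sc: ScreenCounts, target_total: float) -> ScreenCounts:
    """Scale every sample column so its total equals ``target_total``.

    Scaling is proportional and floating point; no rounding is applied.
    """
    if target_total <= 0:
        raise ValidationError(f"target_total must be positive, got {target_total}")
    totals = sc.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total reads: {zero}")
    scaled = sc.counts * (target_total / totals)
    return ScreenCounts(counts=scaled, samples=dict(sc.samples), controls=sc.controls)


def average_pcr_replicates(sc: ScreenCounts) -> ScreenCounts:
    """Average counts across PCR replicates of each (cell line, infection, day).

    The result has one column per condition, labelled
    ``<cell_line>_i<infection>_d<day>``, with ``pcr_rep`` collapsed to 1.
    """
    groups: dict[tuple[str, int, int], list[str]] = {}
    for name, key in sc.samples.items():
        groups.setdefault((key.cell_line, key.infection, key.day), []).append(name)
    cols = {}
    keys = {}
    for (cell_line, infection, day), names in sorted(groups.items()):
        label = f"{cell_line}_i{infection}_d{day}"
        cols[label] = sc.counts[names].mean(axis=1)
        keys[label] = SampleKey(cell_line=cell_line, infection=infection, day=day, pcr_rep=1)
    return ScreenCounts(counts=pd.DataFrame(cols), samples=keys, controls=sc.controls)


def filter_low_abundance(
    sc: ScreenCounts, min_reads: float = DEFAULT_MIN_READS
) -> tuple[ScreenCounts, list[str]]:
    """Drop constructs under-represented at the first time point.

    A construct is excluded from the whole pool when its (PCR-averaged,
    depth-normalized) count at the earliest day is strictly below ``min_reads``
    in *any* infection of any cell line.  Returns the filtered counts and the
    list of excluded constructs.
    """
    first_day = min(k.day for k in sc.samples.values())
    baseline_cols = [n for n, k in sc.samples.items() if k.day == first_day]
    below = (sc.counts[baseline_cols] < min_reads).any(axis=1)
    excluded = sc.counts.index[below].tolist()
    kept = ScreenCounts(
        counts=sc.counts.loc[~below],
        samples=dict(sc.samples),
        controls=tuple(c for c in sc.controls if c not in excluded),
    )
    return kept, excluded


# ---------------------------------------------------------------------------
# Fold changes and slopes
# ---------------------------------------------------------------------------


def fold_changes(sc: ScreenCounts, baseline_day: int | None = None) -> pd.DataFrame:
    """Per-construct fold change versus the baseline day, per infection.

    Returns a long-format frame with columns ``construct``, ``cell_line``,
    ``infection``, ``day``, ``fc``.  Zero counts after the baseline receive a
    ``ZERO_PSEUDOCOUNT`` so the fold change stays positive and finite.
    """
    if baseline_day is None:
        baseline_day = min(k.day for k in sc.samples.values())
    infections = sorted({(k.cell_line, k.infection) for k in sc.samples.values()})
    rows = []
    for cell_line, infection in infections:
        cols = {
            k.day: n
            for n, k in sc.samples.items()
            if k.cell_line == cell_line and k.infection == infection
        }
        if baseline_day not in cols:
            raise ValidationError(
                f"no baseline day {baseline_day} sample for {cell_line} infection {infection}"
            )
        base = sc.counts[cols[baseline_day]]
        if (base <= 0).any():
            bad = base.index[base <= 0].tolist()
            raise ValidationError(
                f"zero baseline counts for constructs {bad} in {cell_line} "
                f"infection {infection}; filter low-abundance constructs first"
            )
        for day in sorted(cols):
            vals = sc.counts[cols[day]].to_numpy(dtype=float).copy()
            vals[vals == 0] = ZERO_PSEUDOCOUNT
            fc = vals / base.to_numpy(dtype=float)
            for construct, f in zip(sc.counts.index, fc):
                rows.append(
                    {
                        "construct": construct,
                        "cell_line": cell_line,
                        "infection": infection,
                        "day": day,
                        "fc": f,
                    }
                )
    return pd.DataFrame(rows)


def adapt_fold_change(fc: float | np.ndarray) -> float | np.ndarray:
    """Signed fold-change score: 0 at fc = 1, fc - 1 above, 1 - 1/fc below.

    Antisymmetric under inversion: ``adapt(f) == -adapt(1/f)``.
    """
    arr = np.asarray(fc, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("fold changes must be positive")
    out = np.where(arr >= 1.0, arr - 1.0, 1.0 - 1.0 / arr)
    return float(out) if np.isscalar(fc) or out.ndim == 0 else out


def fit_slope(days: np.ndarray, scores: np.ndarray) -> float:
    """Zero-intercept least-squares slope of score against day offset.

    ``days`` are offsets from the baseline day (baseline = 0); the closed form
    is sum(x*y) / sum(x^2), the minimizer of sum((y - b*x)^2).
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValidationError("need matching day/score arrays of length >= 2")
    denom = float(np.sum(x * x))
    if denom == 0:
        raise ValidationError("all day offsets are zero; cannot fit a slope")
    return float(np.sum(x * y) / denom)


@dataclass(frozen=True)
class SlopeResult:
    """Fitted abundance trend for one construct in one infection."""

    construct: str
    cell_line: str
    infection: int
    slope: float
    n_points: int


def construct_slopes(
    sc: ScreenCounts, baseline_day: int | None = None
) -> list[SlopeResult]:
    """Slopes of adapted fold change versus day for every construct/infection.

    The baseline point (offset 0, score 0) is part of every fit, matching the
    trend line being forced through the origin.
    """
    if baseline_day is None:
        baseline_day = min(k.day for k in sc.samples.values())
    fc = fold_changes(sc, baseline_day)
    fc["score"] = adapt_fold_change(fc["fc"].to_numpy())
    fc["offset"] = fc["day"] - baseline_day
    out = []
    for (construct, cell_line, infection), grp in fc.groupby(
        ["construct", "cell_line", "infection"], sort=True
    ):
        x = grp["offset"].to_numpy(dtype=float)
        y = grp["score"].to_numpy(dtype=float)
        out.append(
            SlopeResult(
                construct=str(construct),
                cell_line=str(cell_line),
                infection=int(infection),
                slope=fit_slope(x, y),
                n_points=int(len(x)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# IQR outlier calling
# ---------------------------------------------------------------------------


def iqr_bounds(slopes: np.ndarray, k: float = DEFAULT_IQR_K) -> tuple[float, float]:
    """Tukey-style outlier bounds (Q1 - k*IQR, Q3 + k*IQR) over a slope set.

    Quartiles use linear interpolation between order statistics.
    """
    arr = np.asarray(slopes, dtype=float)
    if arr.size < 4:
        raise ValidationError(f"need >= 4 slopes for IQR bounds, got {arr.size}")
    q1, q3 = np.percentile(arr, [25, 75], method="linear")
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


@dataclass(frozen=True)
class HitCall:
    """Consolidated verdict for one construct in one cell line.

    ``per_infection`` maps infection index -> "below" / "within" / "above";
    ``bounds`` maps infection index -> (lower, upper).  ``direction`` is
    "depleted" when every infection is below its lower bound, "enriched" when
    every infection is above its upper bound, "none" otherwise.
    """

    construct: str
    cell_line: str
    direction: str
    per_infection: dict[int, str]
    bounds: dict[int, tuple[float, float]]
    slopes: dict[int, float]


def call_hits(slopes: list[SlopeResult], k: float = DEFAULT_IQR_K) -> list[HitCall]:
    """Call depleted/enriched constructs from per-infection slope populations.

    Bounds are computed per (cell line, infection) over all that infection's
    construct slopes.  Verdicts use strict inequalities; a slope exactly at a
    bound is "within".  A construct is a hit in a cell line only when both
    (all) infections agree on the out-of-bounds direction.
    """
    df = pd.DataFrame(
        {
            "construct": [s.construct for s in slopes],
            "cell_line": [s.cell_line for s in slopes],
            "infection": [s.infection for s in slopes],
            "slope": [s.slope for s in slopes],
        }
    )
    calls: list[HitCall] = []
    for cell_line, cl_grp in df.groupby("cell_line", sort=True):
        sets = {
            int(inf): set(g["construct"]) for inf, g in cl_grp.groupby("infection")
        }
        first = next(iter(sets.values()))
        if any(s != first for s in sets.values()):
            raise ValidationError(
                f"infections of {cell_line} cover different construct sets"
            )
        bounds = {}
        verdicts: dict[str, dict[int, str]] = {}
        slope_map: dict[str, dict[int, float]] = {}
        for infection, grp in cl_grp.groupby("infection", sort=True):
            infection = int(infection)
            lo, hi = iqr_bounds(grp["slope"].to_numpy(), k=k)
            bounds[infection] = (lo, hi)
            for _, row in grp.iterrows():
                s = float(row["slope"])
                verdict = "below" if s < lo else "above" if s > hi else "within"
                verdicts.setdefault(str(row["construct"]), {})[infection] = verdict
                slope_map.setdefault(str(row["construct"]), {})[infection] = s
        for construct in sorted(first):
            per_inf = verdicts[construct]
            vs = set(per_inf.values())
            if vs == {"below"}:
                direction = "depleted"
            elif vs == {"above"}:
                direction = "enriched"
            else:
                direction = "none"
            calls.append(
                HitCall(
                    construct=construct,
                    cell_line=str(cell_line),
                    direction=direction,
                    per_infection=per_inf,
                    bounds=bounds,
                    slopes=slope_map[construct],
                )
            )
    return calls


# ---------------------------------------------------------------------------
# End-to-end convenience
# ---------------------------------------------------------------------------


def analyze_screen(
    sc: ScreenCounts,
    target_total: float,
    min_reads: float = DEFAULT_MIN_READS,
    iqr_k: float = DEFAULT_IQR_K,
    baseline_day: int | None = None,
) -> tuple[list[HitCall], list[SlopeResult], list[str]]:
    """Full screen pipeline: normalize, average, filter, fit, call.

    Returns (hit calls, slopes, excluded constructs).
    """
    normalized = normalize_totals(sc, target_total)
    averaged = average_pcr_replicates(normalized)
    kept, excluded = filter_low_abundance(averaged, min_reads=min_reads)
    slopes = construct_slopes(kept, baseline_day=baseline_day)
    return call_hits(slopes, k=iqr_k), slopes, excluded


def hit_table(calls: list[HitCall]) -> pd.DataFrame:
    """Flatten hit calls to a TSV-ready table, one row per construct/cell line."""
    rows = []
    for c in calls:
        row: dict[str, object] = {
            "construct": c.construct,
            "cell_line": c.cell_line,
            "direction": c.direction,
        }
        for inf in sorted(c.slopes):
            row[f"slope_inf{inf}"] = c.slopes[inf]
            row[f"lower_inf{inf}"] = c.bounds[inf][0]
            row[f"upper_inf{inf}"] = c.bounds[inf][1]
            row[f"verdict_inf{inf}"] = c.per_infection[inf]
        rows.append(row)
    return pd.DataFrame(rows)
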