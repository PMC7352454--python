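import numpy as np
import pandas as pd
import pytest

from mirscreen.types import (
    RipExperiment,
    RipSampleKey,
    SampleKey,
    ScreenCounts,
)


def make_screen_counts(counts, days, infections=1, pcr_reps=1, cell_line="CL", controls=()):
    """Build a ScreenCounts from a dict {construct: per-sample counts}.

    Sample order is (infection, day, pcr_rep) sorted; counts values must match
    that length.
    """
    samples = {}
    for inf in range(1, infections + 1):
        for day in days:
            for rep in range(1, pcr_reps + 1):
                name = f"{cell_line}_i{inf}_d{day}_r{rep}"
                samples[name] = SampleKey(cell_line, inf, day, rep)
    df = pd.DataFrame(counts, index=list(samples)).T
    return ScreenCounts(counts=df, samples=samples, controls=controls)


def make_rip_experiment(values, present=None, cell_line="CL", probe_gene=None):
    """Build a RipExperiment from {(condition, fraction, dup): per-probe values}.

    ``values`` maps sample tuples to lists aligned with probe order P1..Pn.
    """
    n = len(next(iter(values.values())))
    probes = [f"P{i + 1}" for i in range(n)]
    cols = {}
    samples = {}
    for (condition, fraction, dup), vals in values.items():
        name = f"{cell_line}_{condition}_{fraction}_{dup}"
        cols[name] = vals
        samples[name] = RipSampleKey(cell_line, condition, fraction, dup)
    frame = pd.DataFrame(cols, index=probes, dtype=float)
    if present is None:
        pres = pd.DataFrame(True, index=probes, columns=frame.columns)
    else:
        pres = pd.DataFrame(
            {f"{cell_line}_{c}_{f}_{d}": v for (c, f, d), v in present.items()},
            index=probes,
        )[list(frame.columns)]
    if probe_gene is None:
        probe_gene = {p: p.replace("P", "G") for p in probes}
    return RipExperiment(values=frame, present=pres, samples=samples, probe_gene=probe_gene)


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)
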