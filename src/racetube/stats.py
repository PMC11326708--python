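"""Summary statistics over selections of period estimates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SelectionError
from .periods import PeriodEstimate


@dataclass
class PeriodSummary:
    """Mean, SD and SEM of a selection of periods from one method."""

    n: int
    mean_h: float
    sd_h: float
    sem_h: float
    method: str
    selection: tuple[str, ...] = ()


def summarize(
    periods: list[PeriodEstimate],
    population_sd: bool = False,
    selection: tuple[str, ...] = (),
) -> PeriodSummary:
    """Mean, standard deviation, and standard error of selected periods.

    The selection must be non-empty, single-method, and free of failed
    estimates.  The SD uses the sample convention (ddof=1) by default, with
    SEM = SD / sqrt(n); a single estimate yields SD = SEM = 0.
    ``population_sd=True`` switches to ddof=0.
    """
    if not periods:
        raise SelectionError("empty period selection")
    methods = {p.method for p in periods}
    if len(methods) > 1:
        raise SelectionError(f"mixed methods in selection: {sorted(methods)}")
    bad = [p for p in periods if not p.ok]
    if bad:
        raise SelectionError(f"selection contains {len(bad)} failed estimate(s)")
    values = np.array([p.period_h for p in periods], dtype=float)
    n = len(values)
    ddof = 0 if population_sd else 1
    sd = float(values.std(ddof=ddof)) if n > ddof else 0.0
    return PeriodSummary(
        n=n,
        mean_h=float(values.mean()),
        sd_h=sd,
        sem_h=sd / np.sqrt(n),
        method=methods.pop(),
        selection=selection,
    )
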