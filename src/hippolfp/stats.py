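"""Session summaries, group comparisons, and the behavioral discrimination
index.

Group comparisons are thin wrappers over standard tests: Mann-Whitney U for
single session-level quantities, and per-bin two-sample t tests with
Holm-Sidak step-down correction for multi-bin curves (e.g. the 16 theta-phase
bins of a gamma-modulation profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats as spstats

from .errors import InsufficientDataError, ParameterError


@dataclass(frozen=True)
class InteractionTimes:
    """Object-interaction times: moved (t_moved_s) vs unmoved (t_unmoved_s)."""
    t_moved_s: float
    t_unmoved_s: float

    def __post_init__(self):
        if self.t_moved_s < 0 or self.t_unmoved_s < 0:
            raise ParameterError("interaction times must be non-negative")


def discrimination_index(times: InteractionTimes) -> float:
    """DI = (Tmo - Tuo) / (Tmo + Tuo), in [-1, 1]; normalized preference for
    the displaced object."""
    total = times.t_moved_s + times.t_unmoved_s
    if total == 0:
        raise InsufficientDataError("both interaction times are zero")
    return (times.t_moved_s - times.t_unmoved_s) / total


@dataclass(frozen=True)
class SessionSummary:
    session_id: str
    group: str
    swr_incidence_hz: float
    n_swr: int
    mean_peak_power_sd: float
    median_peak_power_sd: float
    median_peak_freq_hz: float
    mean_cycles_per_event: float
    mean_duration_ms: float
    pct_singlets: float
    pct_doublets: float
    pct_triplets: float
    spw_ripple_r: float
    band_relative_power: dict = field(default_factory=dict)
    band_mi: dict = field(default_factory=dict)

    def __post_init__(self):
        # singlet/doublet/triplet percentages partition 100% unless chains
        # longer than 3 events exist (those are counted separately)
        total = self.pct_singlets + self.pct_doublets + self.pct_triplets
        if total > 100.0 + 0.1 or min(self.pct_singlets, self.pct_doublets,
                                      self.pct_triplets) < 0:
            raise ParameterError("burst percentages must lie in [0, 100]")

    def as_dict(self) -> dict:
        return asdict(self)


def burst_percentages(groups: list) -> tuple:
    """Percent of SWR events occurring as singlets, doublets, triplets.

    Percentages are of events (not groups), so they partition 100% when no
    chain exceeds three events.
    """
    n_events = sum(len(g.members) for g in groups)
    if n_events == 0:
        raise InsufficientDataError("no events to classify")
    counts = {1: 0, 2: 0, 3: 0}
    for g in groups:
        k = len(g.members)
        if k in counts:
            counts[k] += k
    return tuple(100.0 * counts[k] / n_events for k in (1, 2, 3))


def summarize_session(session_id: str, group: str, swrs: list,
                      burst_groups: list, immobility: list,
                      band_powers: dict | None = None,
                      band_mis: dict | None = None) -> SessionSummary:
    """Aggregate per-session SWR features into one summary record."""
    from .events import swr_incidence, spw_ripple_correlation

    missing = [name for name, val in
               [("swrs", swrs), ("burst_groups", burst_groups),
                ("immobility", immobility)] if not val]
    if missing:
        raise InsufficientDataError(f"missing inputs: {', '.join(missing)}")
    power = np.array([e.ripple.peak_power_sd for e in swrs])
    freqs = np.array([e.ripple.peak_freq_hz for e in swrs])
    cycles = np.array([e.ripple.n_cycles for e in swrs], dtype=float)
    durs = np.array([e.ripple.duration_ms for e in swrs])
    singles, doubles, triples = burst_percentages(burst_groups)
    return SessionSummary(
        session_id=session_id, group=group,
        swr_incidence_hz=swr_incidence(swrs, immobility),
        n_swr=len(swrs),
        mean_peak_power_sd=float(power.mean()),
        median_peak_power_sd=float(np.median(power)),
        median_peak_freq_hz=float(np.nanmedian(freqs)),
        mean_cycles_per_event=float(np.nanmean(np.where(cycles < 0, np.nan, cycles))),
        mean_duration_ms=float(durs.mean()),
        pct_singlets=singles, pct_doublets=doubles, pct_triplets=triples,
        spw_ripple_r=spw_ripple_correlation(swrs) if len(swrs) >= 3 else np.nan,
        band_relative_power=dict(band_powers or {}),
        band_mi=dict(band_mis or {}),
    )


def _extract(summaries: list, fld):
    vals = []
    for s in summaries:
        v = getattr(s, fld) if hasattr(s, fld) else s[fld]
        vals.append(v)
    return np.asarray(vals, dtype=float)


def holm_sidak(pvalues: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Holm-Sidak step-down decisions for a family of p-values."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        level = 1.0 - (1.0 - alpha) ** (1.0 / (m - rank))
        if p[idx] <= level:
            reject[idx] = True
        else:
            break  # step-down stops at the first non-rejection
    return reject


def compare_groups(summaries_a: list, summaries_b: list, fld: str,
                   method: str = "mann_whitney", alpha: float = 0.05):
    """Two-sided group comparison of one summary field.

    ``mann_whitney`` expects a scalar field and returns
    ``(statistic, p, None)``.  ``multi_t_holm_sidak`` expects a vector field
    (one value per bin) and returns per-bin ``(t, p, reject)`` arrays with
    Holm-Sidak corrected decisions.
    """
    if len(summaries_a) < 3 or len(summaries_b) < 3:
        raise InsufficientDataError("need at least 3 sessions per group")
    a = _extract(summaries_a, fld)
    b = _extract(summaries_b, fld)
    if method == "mann_whitney":
        if a.ndim != 1:
            raise ParameterError("mann_whitney requires a scalar field")
        res = spstats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue), None
    if method == "multi_t_holm_sidak":
        a = np.atleast_2d(a)
        b = np.atleast_2d(b)
        t, p = spstats.ttest_ind(a, b, axis=0)
        return np.asarray(t), np.asarray(p), holm_sidak(np.asarray(p), alpha)
    raise ParameterError(f"unknown method {method!r}")
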