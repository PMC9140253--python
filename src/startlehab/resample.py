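"""Fish-level bootstrap of the SRH parameters.

Single fish are too noisy to fit the exponential habituation model
stably, so population-level uncertainty is obtained by resampling whole
fish: each bootstrap replicate draws fish with replacement (the 20-stimulus
curve of a fish is the resampling unit — stimuli within a fish are
dependent), computes the resampled group-mean habituation curve, and fits
the exponential once per replicate.  The spread of the fitted parameters
across replicates (SD) is the bootstrap standard error.

Changes in a parameter between test times are summarised from paired
replicate differences: when two bootstrap runs share their replicate index
matrix (same seed, same fish count — fish identity persists across test
times), replicate ``b`` resamples the same fish at both times and the
difference distribution is formed replicate-wise.  Otherwise the SEs are
combined independently.

Replicates whose decay constant hits its cap (flat resampled curve, no
habituation) are retained and counted, and summaries are also reported over
identified-only replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import load_defaults
from .habituation import SRHFit, fit_exponential, mean_curve

__all__ = ["BootstrapResult", "ParameterDelta", "bootstrap_fits",
           "bootstrap_scalar_mean", "parameter_deltas", "PARAMETERS"]

PARAMETERS = ("amplitude", "decay_constant", "offset")


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap distribution of the three SRH parameters for one cell."""

    group: str
    test_time: str
    n_boot: int
    n_fish: int
    seed: int
    fits: list                    # one SRHFit per replicate
    indices: np.ndarray           # (n_boot, n_fish) resampled fish indices
    means: dict                   # parameter -> bootstrap mean
    ses: dict                     # parameter -> bootstrap SE (SD over replicates)
    n_capped: int                 # replicates with non-identified tau
    means_identified: dict = field(default_factory=dict)
    ses_identified: dict = field(default_factory=dict)
    single_fish_warning: bool = False

    def parameter_values(self, parameter: str) -> np.ndarray:
        if parameter not in PARAMETERS:
            raise KeyError(f"unknown parameter {parameter!r}")
        return np.array([getattr(f, parameter) for f in self.fits])


@dataclass(frozen=True)
class ParameterDelta:
    """Between-time change of one SRH parameter (``to_time - from_time``)."""

    parameter: str
    from_time: str
    to_time: str
    mean_change: float
    se_change: float
    paired: bool


def _summary(values: np.ndarray) -> tuple[float, float]:
    if np.ptp(values) == 0.0:  # identical replicates: SE exactly zero
        return float(values[0]), 0.0
    if len(values) < 2:
        return float(values.mean()), 0.0
    return float(values.mean()), float(values.std(ddof=1))


def bootstrap_fits(traces, n_boot: int | None = None, seed: int = 0,
                   tau_cap: float | None = None) -> BootstrapResult:
    """Fish-level bootstrap of the exponential fit for one group x time cell.

    Each of the ``n_boot`` replicates resamples the fish with replacement
    (same count), fits the exponential to the resampled mean curve, and the
    per-parameter mean and SE (SD across replicates) are reported.
    Deterministic given ``seed``.
    """
    if n_boot is None:
        n_boot = int(load_defaults()["bootstrap"]["n_boot"])
    if n_boot < 2:
        raise ValueError(f"n_boot must be at least 2, got {n_boot}")
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    for t in traces:
        np.asarray(t.distances)  # validated by StartleTrace construction
    n_fish = len(traces)

    rng = np.random.default_rng(seed)
    indices = rng.integers(0, n_fish, size=(n_boot, n_fish))
    stack = np.array([t.distances for t in traces])  # (n_fish, 20)

    fits: list[SRHFit] = []
    for b in range(n_boot):
        resampled_mean = stack[indices[b]].mean(axis=0)
        fits.append(fit_exponential(resampled_mean, tau_cap=tau_cap))

    means, ses, means_id, ses_id = {}, {}, {}, {}
    identified = np.array([f.identified for f in fits])
    for p in PARAMETERS:
        values = np.array([getattr(f, p) for f in fits])
        means[p], ses[p] = _summary(values)
        if identified.any():
            means_id[p], ses_id[p] = _summary(values[identified])
    first = traces[0]
    return BootstrapResult(
        group=getattr(first, "group", ""), test_time=getattr(first, "test_time", ""),
        n_boot=n_boot, n_fish=n_fish, seed=seed, fits=fits, indices=indices,
        means=means, ses=ses, n_capped=int((~identified).sum()),
        means_identified=means_id, ses_identified=ses_id,
        single_fish_warning=(n_fish == 1))


def bootstrap_scalar_mean(values, n_boot: int = 500, seed: int = 0):
    """Bootstrap mean and SE of a scalar per-fish statistic.

    Same resampling machinery applied to a scalar (e.g. TDT20): for large
    ``n_boot`` the SE approaches the classical sd/sqrt(n).
    """
    values = np.asarray(values, dtype=float)
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    replicate_means = values[idx].mean(axis=1)
    return float(replicate_means.mean()), float(replicate_means.std(ddof=1))


def parameter_deltas(results, comparisons=None) -> list[ParameterDelta]:
    """Between-time changes of each SRH parameter for one group.

    ``results`` maps test-time label -> BootstrapResult (or is an iterable
    of results carrying their ``test_time``).  By default every pair among
    the (baseline, 5min, 24h) times present is tabulated; pass explicit
    ``comparisons`` as ``[(from_time, to_time), ...]`` to override.
    """
    if not isinstance(results, dict):
        results = {r.test_time: r for r in results}
    if len(results) < 2:
        raise ValueError("need bootstrap results at >= 2 test times")
    n_boots = {r.n_boot for r in results.values()}
    if len(n_boots) != 1:
        raise ValueError(f"mismatched n_boot across results: {sorted(n_boots)}")

    if comparisons is None:
        present = [t for t in ("baseline", "5min", "24h") if t in results]
        if len(present) < 2:
            present = list(results)[:2]
        comparisons = [(present[i], present[j])
                       for i in range(len(present))
                       for j in range(i + 1, len(present))]

    deltas = []
    for t_from, t_to in comparisons:
        r0, r1 = results[t_from], results[t_to]
        paired = (r0.indices.shape == r1.indices.shape
                  and np.array_equal(r0.indices, r1.indices))
        for p in PARAMETERS:
            v0, v1 = r0.parameter_values(p), r1.parameter_values(p)
            if paired:
                mean, se = _summary(v1 - v0)
            else:
                mean = float(v1.mean() - v0.mean())
                se = float(np.hypot(r0.ses[p], r1.ses[p]))
            deltas.append(ParameterDelta(parameter=p, from_time=t_from,
                                         to_time=t_to, mean_change=mean,
                                         se_change=se, paired=paired))
    return deltas
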