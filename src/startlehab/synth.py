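"""Synthetic startle-trace cohorts with known habituation structure.

The assay records, for every fish and test time, the distance travelled in
each of the 20 consecutive 500-ms vibratory stimulus windows.  The raw
tracking exports behind the published analysis are not deposited, so this
module generates cohorts with the statistical structure the analysis
assumes:

* the noiseless per-stimulus response of a fish follows the first-order
  exponential habituation model ``d(n) = C + (A - C) * exp(-(n-1)/tau)``;
* each fish carries a multiplicative scale drawn once from a mean-one
  lognormal and reused at every test time, so fish identity induces the
  within-subject correlation the repeated-measures design relies on;
* small additive Gaussian noise perturbs each stimulus window, floored at
  zero (distance cannot be negative).

Default generative parameters (see ``data/defaults.yaml``) are calibrated
so that group-level mean TDT20 per test time matches the published anchors
of the assay, with between-fish heterogeneity sized to reproduce the
published standard errors.  Movements during inter-stimulus intervals are
not part of the quantification and are not generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import GROUPS, N_STIMULI, TEST_TIMES, load_defaults

__all__ = [
    "StartleTrace",
    "CellParams",
    "GenerativeParams",
    "CohortConfig",
    "habituation_values",
    "simulate_trace",
    "simulate_cohort",
    "write_tracking_table",
    "read_tracking_table",
    "default_generative_params",
]

_TRACKING_COLUMNS = ["fish_id", "group", "session", "test_time",
                     "stimulus_index", "distance_mm"]


@dataclass(frozen=True)
class StartleTrace:
    """Startle responses of one fish at one test time.

    ``distances`` holds the 20 per-stimulus distances travelled (mm within
    each 500-ms stimulus window).
    """

    fish_id: str
    group: str
    session: int
    test_time: str
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (N_STIMULI,):
            raise ValueError(
                f"trace {self.fish_id}/{self.test_time}: expected "
                f"{N_STIMULI} distances, got {d.shape}")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError(
                f"trace {self.fish_id}/{self.test_time}: distances must be "
                "finite and nonnegative")
        object.__setattr__(self, "distances", d)


@dataclass(frozen=True)
class CellParams:
    """Generative habituation parameters of one group x test-time cell."""

    A: float      # amplitude, mm
    C: float      # offset (steady state), mm
    tau: float    # decay constant, stimuli

    def __post_init__(self) -> None:
        if self.A < 0 or self.C < 0:
            raise ValueError("A and C must be nonnegative")
        if not self.tau > 0:
            raise ValueError(f"tau must be positive, got {self.tau}")


@dataclass(frozen=True)
class GenerativeParams:
    """Per-cell habituation parameters plus the two noise scales."""

    cells: dict                 # (group, test_time) -> CellParams
    fish_sd: float = 0.5        # sd of log fish scale (lognormal, mean 1)
    sigma: float = 0.02         # within-fish additive noise sd, mm

    def cell(self, group: str, test_time: str) -> CellParams:
        return self.cells[(group, test_time)]


@dataclass(frozen=True)
class CohortConfig:
    n_fish_per_group_per_session: int = 24
    n_sessions: int = 3
    params: GenerativeParams = field(default_factory=lambda: default_generative_params())
    seed: int = 0
    groups: tuple = GROUPS
    test_times: tuple = TEST_TIMES

    def __post_init__(self) -> None:
        if self.n_fish_per_group_per_session <= 0 or self.n_sessions <= 0:
            raise ValueError("cohort counts must be positive")

    @property
    def n_fish_per_group(self) -> int:
        return self.n_fish_per_group_per_session * self.n_sessions


def default_generative_params() -> GenerativeParams:
    """The packaged calibrated generative table."""
    cfg = load_defaults()["params"]
    cells = {}
    for group in GROUPS:
        for tt, p in cfg[group].items():
            cells[(group, tt)] = CellParams(A=p["A"], C=p["C"], tau=p["tau"])
    return GenerativeParams(cells=cells, fish_sd=cfg["fish_sd"], sigma=cfg["sigma"])


def habituation_values(A: float, C: float, tau: float,
                       n_stimuli: int = N_STIMULI) -> np.ndarray:
    """Noiseless habituation curve ``C + (A - C) exp(-(n-1)/tau)``, n=1..20."""
    if not tau > 0:
        raise ValueError(f"tau must be positive, got {tau}")
    n = np.arange(n_stimuli, dtype=float)
    return C + (A - C) * np.exp(-n / tau)


def simulate_trace(params: CellParams, fish_scale: float, rng: np.random.Generator,
                   sigma: float = 0.0, *, fish_id: str = "fish", group: str = "control",
                   session: int = 1, test_time: str = "baseline") -> StartleTrace:
    """Simulate one 20-stimulus trace.

    Distance at stimulus n is ``max(0, fish_scale * [C + (A-C) e^{-(n-1)/tau}]
    + eps_n)`` with iid Gaussian ``eps_n``; reproducible given ``rng`` state.
    """
    curve = fish_scale * habituation_values(params.A, params.C, params.tau)
    noise = rng.normal(0.0, sigma, size=N_STIMULI) if sigma > 0 else 0.0
    return StartleTrace(fish_id=fish_id, group=group, session=session,
                        test_time=test_time,
                        distances=np.maximum(0.0, curve + noise))


def simulate_cohort(config: CohortConfig) -> list[StartleTrace]:
    """Simulate a full cohort: every fish tested at every test time.

    The per-fish scale is drawn once (lognormal with mean 1, i.e.
    ``exp(N(-fish_sd^2/2, fish_sd^2))``) and reused across test times, so a
    vigorous fish is vigorous at every session — the within-subject
    correlation of the repeated-measures design.  The whole cohort is a
    deterministic function of ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    p = config.params
    traces: list[StartleTrace] = []
    for group in config.groups:
        for session in range(1, config.n_sessions + 1):
            for i in range(config.n_fish_per_group_per_session):
                fish_id = f"{group[:4]}-s{session}-f{i + 1:02d}"
                scale = float(np.exp(rng.normal(-p.fish_sd ** 2 / 2, p.fish_sd)))
                for tt in config.test_times:
                    traces.append(simulate_trace(
                        p.cell(group, tt), scale, rng, sigma=p.sigma,
                        fish_id=fish_id, group=group, session=session,
                        test_time=tt))
    return traces


# ---------------------------------------------------------------------------
# tracking-table dialect (long format, one row per stimulus)


def traces_to_frame(traces) -> pd.DataFrame:
    """Long-format DataFrame view of a trace collection."""
    records = []
    for t in traces:
        for k in range(N_STIMULI):
            records.append((t.fish_id, t.group, t.session, t.test_time,
                            k + 1, t.distances[k]))
    return pd.DataFrame.from_records(records, columns=_TRACKING_COLUMNS)


def write_tracking_table(traces, destination) -> None:
    """Write traces as the comma-delimited long-format tracking table."""
    traces = list(traces)
    keys = {(t.fish_id, t.test_time) for t in traces}
    if len(keys) != len(traces):
        raise ValueError("duplicate (fish_id, test_time) pairs in cohort")
    traces_to_frame(traces).to_csv(destination, index=False)


def read_tracking_table(source) -> list[StartleTrace]:
    """Read a tracking table, validating structure row by row.

    Rejects malformed rows, duplicate (fish, time, stimulus) keys and
    stimulus indices outside 1..20, reporting the offending data row number;
    rejects fish-time records that do not hold exactly 20 stimuli.
    """
    frame = pd.read_csv(source)
    missing = [c for c in _TRACKING_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"tracking table is missing columns: {missing}")

    idx = frame["stimulus_index"]
    bad = ~(idx.between(1, N_STIMULI) & (idx == idx.astype(int)))
    if bad.any():
        row = int(frame.index[bad][0]) + 2  # 1-based incl. header
        raise ValueError(f"row {row}: stimulus_index must be an integer in "
                         f"1..{N_STIMULI}, got {idx[bad].iloc[0]!r}")
    dist = pd.to_numeric(frame["distance_mm"], errors="coerce")
    bad = dist.isna() | (dist < 0) | np.isinf(dist)
    if bad.any():
        row = int(frame.index[bad][0]) + 2
        raise ValueError(f"row {row}: distance_mm must be a nonnegative "
                         f"finite number, got {frame['distance_mm'][bad].iloc[0]!r}")
    dup = frame.duplicated(subset=["fish_id", "test_time", "stimulus_index"])
    if dup.any():
        row = int(frame.index[dup][0]) + 2
        raise ValueError(f"row {row}: duplicate (fish_id, test_time, "
                         "stimulus_index) key")

    traces = []
    for (fish, tt), g in frame.groupby(["fish_id", "test_time"], sort=False):
        if len(g) != N_STIMULI:
            raise ValueError(
                f"incomplete record for fish {fish!r} at test time {tt!r}: "
                f"{len(g)} stimuli, expected {N_STIMULI}")
        g = g.sort_values("stimulus_index")
        traces.append(StartleTrace(
            fish_id=str(fish), group=str(g["group"].iloc[0]),
            session=int(g["session"].iloc[0]), test_time=str(tt),
            distances=g["distance_mm"].to_numpy(dtype=float)))
    return traces
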