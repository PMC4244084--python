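"""Residence-time kinetics of inhibitor-bound peptides.

A peptide is bound in a frame when it forms strictly more than `threshold`
(default 5) residue contacts with the inhibitor.  Short unbound excursions
of duration strictly less than t0 (default 1 ns) that are flanked by bound
frames are bridged before computing the survival correlation

    S(t) = < Σ_j [ peptide j bound continuously on [t0, t0 + t] ] >_origins

averaged over all time origins of one run, then (separately) across runs.
S(0) is the mean number of simultaneously complexed peptides; S is reported
in absolute peptide counts, with S/S(0) alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contacts import ContactConfig, ContactRecord, chain_pair_contact_count, residue_contacts
from .errors import EmptyResultError, ValidationError
from .model import SystemModel, Trajectory

__all__ = [
    "BoundSeries",
    "KineticsConfig",
    "SurvivalCurve",
    "ResidenceEstimate",
    "bound_series",
    "bound_series_from_records",
    "bridge_excursions",
    "survival_correlation",
    "average_survival_curves",
    "mean_residence_time",
]


@dataclass(frozen=True)
class KineticsConfig:
    threshold: int = 5            # bound iff contacts > threshold
    t0: float = 1.0               # ns; bridge unbound gaps strictly shorter
    origin_stride: int = 1        # use every origin_stride-th frame as origin
    max_lag: float | None = None  # ns; default = half the trajectory length

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ValidationError("t0 must be >= 0")
        if self.origin_stride < 1:
            raise ValidationError("origin stride must be >= 1")


@dataclass
class BoundSeries:
    """Binary bound/unbound indicator for one peptide over a run."""

    chain_id: str
    times: np.ndarray
    b: np.ndarray                 # uint8, 0/1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.b = np.asarray(self.b, dtype=np.uint8)
        if self.times.shape != self.b.shape:
            raise ValidationError("times and indicator must have equal length")
        if not np.isin(self.b, (0, 1)).all():
            raise ValidationError("indicator values must be 0/1")

    @property
    def dt(self) -> float:
        d = np.diff(self.times)
        if d.size == 0:
            raise ValidationError("series too short for a frame spacing")
        if not np.allclose(d, d[0], rtol=1e-3, atol=1e-9):
            raise ValidationError("series is not uniformly spaced")
        return float(d[0])


@dataclass
class SurvivalCurve:
    lags: np.ndarray              # ns
    S: np.ndarray                 # mean number of peptides still bound
    n_origins: np.ndarray         # time origins per lag
    n_peptides: int

    @property
    def S_normalized(self) -> np.ndarray:
        if self.S[0] == 0:
            return np.zeros_like(self.S)
        return self.S / self.S[0]


@dataclass
class ResidenceEstimate:
    tau: float                    # ns
    method: str                   # "exp_fit" | "integral"
    lower_bound: bool = False     # integral did not reach decay below 5% S(0)


def bound_series_from_records(records: list[ContactRecord], model: SystemModel,
                              threshold: int = 5) -> list[BoundSeries]:
    inh = model.inhibitor_chain_ids
    if not inh:
        raise ValidationError("model has no inhibitor entity")
    times = np.array([r.time for r in records])
    out = []
    for p in model.peptide_chain_ids:
        b = np.fromiter(
            (chain_pair_contact_count(r, [p], inh) > threshold for r in records),
            dtype=np.uint8, count=len(records),
        )
        out.append(BoundSeries(p, times, b))
    return out


def bound_series(traj: Trajectory, contact_config: ContactConfig | None = None,
                 config: KineticsConfig | None = None) -> list[BoundSeries]:
    contact_config = contact_config or ContactConfig()
    config = config or KineticsConfig()
    records = [residue_contacts(f, traj.model, contact_config) for f in traj.frames]
    return bound_series_from_records(records, traj.model, config.threshold)


def bridge_excursions(series: BoundSeries, t0: float = 1.0) -> BoundSeries:
    """Fill interior unbound gaps of duration strictly less than t0 (ns).

    A gap of g consecutive 0-frames at spacing dt lasts g*dt; it is bridged
    only when g*dt < t0 and it is flanked by bound frames on both sides.
    Leading and trailing zero runs are never touched.
    """
    b = series.b.copy()
    if t0 <= 0 or b.size < 3:
        return BoundSeries(series.chain_id, series.times.copy(), b)
    dt = series.dt
    i = 0
    n = b.size
    while i < n:
        if b[i] == 1:
            i += 1
            continue
        j = i
        while j < n and b[j] == 0:
            j += 1
        gap = (j - i) * dt
        if i > 0 and j < n and gap < t0 - 1e-12:
            b[i:j] = 1
        i = j
    return BoundSeries(series.chain_id, series.times.copy(), b)


def _maximal_runs(b: np.ndarray) -> np.ndarray:
    """Lengths of the maximal runs of 1s in a 0/1 array."""
    padded = np.concatenate(([0], b.astype(np.int8), [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def _run_lengths(b: np.ndarray) -> np.ndarray:
    """L[t] = number of consecutive 1s starting at t (0 where b[t] = 0)."""
    n = b.size
    L = np.zeros(n, dtype=np.int64)
    run = 0
    for t in range(n - 1, -1, -1):
        run = run + 1 if b[t] else 0
        L[t] = run
    return L


def survival_correlation(series: list[BoundSeries],
                         config: KineticsConfig | None = None) -> SurvivalCurve:
    """Survival correlation S(lag) for one run (bridging applied here)."""
    config = config or KineticsConfig()
    if not series:
        raise ValidationError("need at least one bound series")
    times = series[0].times
    n = times.size
    for s in series[1:]:
        if s.times.shape != times.shape or not np.allclose(s.times, times):
            raise ValidationError("bound series are not aligned in time")
    dt = series[0].dt if n > 1 else 1.0
    if config.max_lag is None:
        max_lag_frames = (n - 1) // 2
    else:
        max_lag_frames = int(round(config.max_lag / dt))
        if max_lag_frames >= n:
            raise ValidationError("max lag exceeds the trajectory length")
    lags = np.arange(max_lag_frames + 1)

    bridged = [bridge_excursions(s, config.t0) for s in series]
    stride = config.origin_stride
    S = np.zeros(max_lag_frames + 1)
    n_origins = np.array([len(range(0, n - k, stride)) for k in lags],
                         dtype=np.int64)
    if stride == 1:
        # An origin t contributes at lag k iff the bound run starting at t
        # has length > k; such an origin automatically satisfies t + k < n,
        # so a maximal run of length R contributes max(R - k, 0) origins.
        totals = np.zeros(max_lag_frames + 1)
        for s in bridged:
            runs = _maximal_runs(s.b)
            if runs.size:
                totals += np.clip(runs[:, None] - lags[None, :], 0, None).sum(axis=0)
        S = totals / n_origins
    else:
        Ls = [_run_lengths(s.b) for s in bridged]
        for k in lags:
            origins = np.arange(0, n - k, stride)
            S[k] = sum(int((L[origins] > k).sum()) for L in Ls) / origins.size
    return SurvivalCurve(lags * dt, S, n_origins, n_peptides=len(series))


def average_survival_curves(curves: list[SurvivalCurve]) -> SurvivalCurve:
    """Unweighted mean of per-run survival curves (identical lag grids)."""
    if not curves:
        raise ValidationError("need at least one curve")
    ref = curves[0]
    for c in curves[1:]:
        if c.lags.shape != ref.lags.shape or not np.allclose(c.lags, ref.lags):
            raise ValidationError("curves have mismatched lag grids")
    S = np.mean([c.S for c in curves], axis=0)
    n_origins = np.sum([c.n_origins for c in curves], axis=0)
    return SurvivalCurve(ref.lags.copy(), S, n_origins,
                         n_peptides=max(c.n_peptides for c in curves))


def mean_residence_time(curve: SurvivalCurve, method: str = "exp_fit",
                        floor: float = 0.05) -> ResidenceEstimate:
    """Mean residence time (ns) from a survival curve.

    exp_fit: linear least squares on ln[S/S(0)] over lags where
    S > floor*S(0); tau = -1/slope.  integral: trapezoidal integral of
    S/S(0); flagged as a lower bound when S never decays below floor*S(0).
    """
    if curve.S[0] <= 0:
        raise EmptyResultError("S(0) = 0: no bound peptides to analyze")
    s_norm = curve.S / curve.S[0]
    if method == "exp_fit":
        keep = curve.S > floor * curve.S[0]
        if keep.sum() < 2:
            raise EmptyResultError("survival curve too short for an exponential fit")
        x = curve.lags[keep]
        y = np.log(s_norm[keep])
        slope = np.polyfit(x, y, 1)[0]
        if slope >= 0:
            return ResidenceEstimate(np.inf, "exp_fit", lower_bound=True)
        return ResidenceEstimate(-1.0 / slope, "exp_fit")
    if method == "integral":
        tau = float(np.trapezoid(s_norm, curve.lags))
        lower = bool(s_norm[-1] > floor)
        return ResidenceEstimate(tau, "integral", lower_bound=lower)
    raise ValidationError(f"unknown method {method!r}")
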