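"""Gibbs-energy machinery: histogram projections, WHAM, reweighting, convergence, TST.

All energies are kcal·mol⁻¹ and every emitted profile is anchored so that its
minimum finite value is exactly zero.  Empty bins carry ``inf`` and zero mass,
never a fake zero of energy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, KB_SI, PLANCK_SI, beta
from .errors import NumericalError, ValidationError
from .series import CVSeries

__all__ = [
    "FreeEnergyProfile",
    "UmbrellaWindow",
    "WhamSolution",
    "ConvergenceReport",
    "direct_projection",
    "equilibration_discard",
    "wham_solve",
    "conformation_weights",
    "reweighted_projection",
    "pool_windows",
    "convergence_check",
    "profile_deviation",
    "tst_convert",
]


@dataclass
class FreeEnergyProfile:
    """Binned ΔG over one or two coordinates."""

    edges: list[np.ndarray]
    delta_g: np.ndarray
    mass: np.ndarray
    temperature: float
    axis_labels: list[str]
    counts: np.ndarray | None = None
    reference_index: tuple = ()

    def __post_init__(self) -> None:
        finite = self.delta_g[np.isfinite(self.delta_g)]
        if finite.size == 0:
            raise ValidationError("profile has no occupied bins")
        if abs(float(np.min(finite))) > 1e-12:
            raise ValidationError("profile is not anchored at zero")

    @property
    def centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.delta_g)

    def value_at(self, *coords: float) -> float:
        """ΔG of the bin containing the given point (nearest bin center)."""
        idx = []
        for c, centers in zip(coords, self.centers):
            idx.append(int(np.argmin(np.abs(centers - c))))
        return float(self.delta_g[tuple(idx)])


@dataclass
class UmbrellaWindow:
    """A biased CV series plus its harmonic restraint.

    The first series column (or ``biased_label``) is the restrained
    coordinate; extra columns are auxiliary CVs carried along for reweighted
    projections.  ``force_constant == 0`` encodes a null bias.
    """

    center: float
    force_constant: float
    series: CVSeries
    biased_label: str | None = None

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValidationError("force_constant must be >= 0")
        if len(self.series) == 0:
            raise ValidationError("empty window series")
        if self.biased_label is None:
            self.biased_label = self.series.labels[0]

    @property
    def x(self) -> np.ndarray:
        return self.series.column(self.biased_label)

    @property
    def temperature(self) -> float:
        return self.series.temperature

    def bias_energy(self, x) -> np.ndarray:
        return 0.5 * self.force_constant * (np.asarray(x, dtype=float) - self.center) ** 2


@dataclass
class WhamSolution:
    """Converged WHAM state: window offsets F_j and per-sample weights p_i."""

    f: np.ndarray
    sample_weights: np.ndarray
    iterations: int
    converged: bool
    tolerance: float
    edges: np.ndarray
    temperature: float
    connected: bool = True
    n_samples_per_window: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ConvergenceReport:
    """Cumulative-block PMFs and their successive max deviations."""

    scheme: str
    fractions: list[float]
    profiles: list[FreeEnergyProfile]
    deviations: list[float]
    tolerance: float
    converged: bool


def _resolve_bins(n_bins, n_samples: int) -> int:
    if n_bins in (None, "auto"):
        return max(1, math.ceil(math.sqrt(n_samples)))
    n = int(n_bins)
    if n <= 0:
        raise ValidationError("n_bins must be positive")
    return n


def _anchored(delta_g: np.ndarray) -> tuple[np.ndarray, tuple]:
    finite = np.isfinite(delta_g)
    if not np.any(finite):
        raise NumericalError("no occupied bins to anchor")
    ref_flat = int(np.nanargmin(np.where(finite, delta_g, np.inf)))
    ref = np.unravel_index(ref_flat, delta_g.shape)
    out = delta_g - delta_g[ref]
    out[~finite] = np.inf
    return out, ref


def direct_projection(
    series: CVSeries,
    axes: list[str] | str | None = None,
    n_bins="auto",
    temperature: float | None = None,
    bin_range=None,
) -> FreeEnergyProfile:
    """Histogram ΔG projection: ΔG_i = −kBT·ln(k_i/k₀).

    ``k_i`` is the occupation of bin i and ``k₀`` that of the most occupied
    bin, so the modal bin is the zero of energy.  ``axes`` selects one or two
    named columns; ``n_bins='auto'`` uses ⌈√N⌉ bins per axis.
    """
    if isinstance(axes, str):
        axes = [axes]
    if axes is None:
        axes = [series.labels[0]]
    if not 1 <= len(axes) <= 2:
        raise ValidationError("projection supports 1 or 2 axes")
    if len(series) == 0:
        raise ValidationError("empty series")
    temperature = series.temperature if temperature is None else temperature
    data = np.column_stack([series.column(a) for a in axes])
    nb = _resolve_bins(n_bins, len(series))
    counts, edges = np.histogramdd(data, bins=[nb] * len(axes), range=bin_range)
    k0 = counts.max()
    with np.errstate(divide="ignore"):
        delta_g = -KB_KCAL * temperature * np.log(counts / k0)
    delta_g, ref = _anchored(delta_g)
    return FreeEnergyProfile(
        edges=[np.asarray(e) for e in edges],
        delta_g=delta_g if len(axes) > 1 else delta_g.ravel(),
        mass=(counts / counts.sum()) if len(axes) > 1 else (counts / counts.sum()).ravel(),
        counts=counts if len(axes) > 1 else counts.ravel(),
        temperature=temperature,
        axis_labels=list(axes),
        reference_index=ref,
    )


def equilibration_discard(window: UmbrellaWindow, t_eq: float = 2.0) -> UmbrellaWindow:
    """Drop frames with time < ``t_eq`` ps (default 2 ps) from a window."""
    if t_eq < 0:
        raise ValidationError("t_eq must be >= 0")
    if t_eq == 0:
        return window
    keep = window.series.times >= t_eq
    if not np.any(keep):
        raise ValidationError(
            f"equilibration discard of {t_eq} ps leaves window at {window.center} empty"
        )
    return UmbrellaWindow(
        center=window.center,
        force_constant=window.force_constant,
        series=window.series.select(keep),
        biased_label=window.biased_label,
    )


def _common_edges(windows: list[UmbrellaWindow], n_bins: int, bin_range=None) -> np.ndarray:
    xs = np.concatenate([w.x for w in windows])
    if bin_range is None:
        lo, hi = float(xs.min()), float(xs.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
    else:
        lo, hi = bin_range
    return np.linspace(lo, hi, n_bins + 1)


def _connected(hist: np.ndarray) -> bool:
    """True when windows form one component through shared occupied bins."""
    n_win = hist.shape[0]
    occupied = hist > 0
    seen = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        overlaps = np.flatnonzero((occupied & occupied[i]).any(axis=1))
        for j in overlaps:
            if j not in seen:
                seen.add(int(j))
                frontier.append(int(j))
    return len(seen) == n_win


def wham_solve(
    windows: list[UmbrellaWindow],
    n_bins: int = 200,
    tolerance: float = 1e-7,
    max_iter: int = 100000,
    bin_range=None,
    temperature: float | None = None,
) -> tuple[WhamSolution, FreeEnergyProfile]:
    """Self-consistent binned WHAM over harmonically biased windows.

    Iterates
    ``P(x_k) ∝ Σ_j h_jk / Σ_j N_j·exp(−β(U_j(x_k) − F_j))`` and
    ``F_j = −kBT·ln Σ_k P(x_k)·exp(−β·U_j(x_k))`` until the largest change in
    any F_j falls below ``tolerance`` (kcal·mol⁻¹).  F of the first window is
    the gauge (fixed to 0).  Returns the solution — including globally
    normalized per-sample weights p_i — and the PMF over the biased
    coordinate, anchored at zero.
    """
    if not windows:
        raise ValidationError("need at least one window")
    temperature = windows[0].temperature if temperature is None else temperature
    b = beta(temperature)
    kt = KB_KCAL * temperature

    edges = _common_edges(windows, n_bins, bin_range)
    centers = 0.5 * (edges[1:] + edges[:-1])
    hist = np.stack([np.histogram(w.x, bins=edges)[0] for w in windows]).astype(float)
    n_j = hist.sum(axis=1)
    if np.any(n_j == 0):
        warnings.warn("some windows have no samples inside the binning range", stacklevel=2)
    total = hist.sum(axis=0)

    connected = _connected(hist)
    if not connected:
        warnings.warn("window histograms have disconnected support", stacklevel=2)

    bias = np.stack([w.bias_energy(centers) for w in windows])  # (n_win, n_bins)
    f = np.zeros(len(windows))
    converged = False
    it = 0
    occupied = total > 0
    for it in range(1, max_iter + 1):
        denom = (n_j[:, None] * np.exp(-b * (bias - f[:, None]))).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied, total / denom, 0.0)
        p = p / p.sum()
        with np.errstate(divide="ignore"):
            f_new = -kt * np.log((p[None, :] * np.exp(-b * bias)).sum(axis=1))
        f_new = f_new - f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tolerance:
            converged = True
            break

    denom = (n_j[:, None] * np.exp(-b * (bias - f[:, None]))).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(occupied, total / denom, 0.0)
    p = p / p.sum()
    with np.errstate(divide="ignore"):
        delta_g = -kt * np.log(p)
    delta_g, ref = _anchored(delta_g)

    solution = WhamSolution(
        f=f, sample_weights=np.array([]), iterations=it, converged=converged,
        tolerance=tolerance, edges=edges, temperature=temperature,
        connected=connected, n_samples_per_window=n_j,
    )
    solution.sample_weights = conformation_weights(windows, solution)
    profile = FreeEnergyProfile(
        edges=[edges], delta_g=delta_g, mass=p, counts=total,
        temperature=temperature, axis_labels=[windows[0].biased_label],
        reference_index=ref,
    )
    return solution, profile


def conformation_weights(windows: list[UmbrellaWindow], solution: WhamSolution) -> np.ndarray:
    """Globally normalized per-sample weights p_i from a converged WHAM solution.

    ``p_i ∝ 1 / Σ_j N_j·exp(−β(U_ij^bias − F_j))`` with the bias evaluated at
    the sample's bin center, consistently with the binned histogram solution,
    so that accumulating p_i per bin reproduces the WHAM density identically.
    """
    if len(windows) != solution.f.size:
        raise ValidationError("window list does not match the WHAM solution")
    if not solution.converged:
        warnings.warn("computing weights from an unconverged WHAM solution", stacklevel=2)
    b = beta(solution.temperature)
    edges = solution.edges
    centers = 0.5 * (edges[1:] + edges[:-1])
    bias = np.stack([w.bias_energy(centers) for w in windows])
    n_j = solution.n_samples_per_window
    denom_bin = (n_j[:, None] * np.exp(-b * (bias - solution.f[:, None]))).sum(axis=0)

    weights = []
    for w in windows:
        x = w.x
        k = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, centers.size - 1)
        denom = denom_bin[k].copy()
        # samples outside the binning range have no bin center: evaluate the
        # bias at the sample position itself instead of clamping to an edge bin
        outside = (x < edges[0]) | (x > edges[-1])
        if np.any(outside):
            bias_out = np.stack([win.bias_energy(x[outside]) for win in windows])
            denom[outside] = (n_j[:, None] * np.exp(
                -b * (bias_out - solution.f[:, None]))).sum(axis=0)
        weights.append(1.0 / denom)
    out = np.concatenate(weights)
    out /= out.sum()
    if np.any(out <= 0):
        raise NumericalError("nonpositive conformation weight")
    return out


def pool_windows(windows: list[UmbrellaWindow]) -> CVSeries:
    """Concatenate window series (sample order matches conformation_weights)."""
    values = np.concatenate([w.series.values for w in windows], axis=0)
    labels = windows[0].series.labels
    for w in windows[1:]:
        if w.series.labels != labels:
            raise ValidationError("windows carry different CV columns")
    n = values.shape[0]
    return CVSeries(times=np.arange(1, n + 1, dtype=float), values=values,
                    labels=list(labels), temperature=windows[0].temperature)


def reweighted_projection(
    series: CVSeries,
    weights: np.ndarray | None,
    axes: list[str] | str | None = None,
    n_bins="auto",
    temperature: float | None = None,
    bin_range=None,
) -> FreeEnergyProfile:
    """ΔG = −kBT·ln p with p the accumulated per-sample probability in each bin.

    With uniform (or ``None``) weights this reduces exactly to
    :func:`direct_projection`.  Bins accumulating zero probability are
    flagged empty (``inf``).
    """
    if isinstance(axes, str):
        axes = [axes]
    if axes is None:
        axes = [series.labels[0]]
    if not 1 <= len(axes) <= 2:
        raise ValidationError("projection supports 1 or 2 axes")
    n = len(series)
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n,):
        raise ValidationError(f"{weights.size} weights for {n} samples")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValidationError("weights must be normalized to 1")
    temperature = series.temperature if temperature is None else temperature

    data = np.column_stack([series.column(a) for a in axes])
    nb = _resolve_bins(n_bins, n)
    mass, edges = np.histogramdd(data, bins=[nb] * len(axes), range=bin_range, weights=weights)
    with np.errstate(divide="ignore"):
        delta_g = -KB_KCAL * temperature * np.log(mass / mass.max())
    delta_g, ref = _anchored(delta_g)
    return FreeEnergyProfile(
        edges=[np.asarray(e) for e in edges],
        delta_g=delta_g if len(axes) > 1 else delta_g.ravel(),
        mass=mass if len(axes) > 1 else mass.ravel(),
        temperature=temperature,
        axis_labels=list(axes),
        reference_index=ref,
    )


def profile_deviation(p1: FreeEnergyProfile, p2: FreeEnergyProfile) -> float:
    """Max |ΔG₁ − ΔG₂| over bins occupied in both profiles."""
    both = p1.occupied & p2.occupied
    if not np.any(both):
        raise NumericalError("profiles share no occupied bins")
    return float(np.max(np.abs(p1.delta_g[both] - p2.delta_g[both])))


def convergence_check(
    windows: list[UmbrellaWindow],
    scheme: str = "direct",
    n_blocks: int = 5,
    tolerance: float = 1.0,
    n_bins: int = 200,
    bin_range=None,
    wham_tolerance: float = 1e-6,
) -> ConvergenceReport:
    """Cumulative time-block PMFs in direct or reverse order.

    Recomputes the PMF on the first 1/n, 2/n, … of every window (last
    fractions for ``scheme='reverse'``), and reports the max-norm deviation
    between successive PMFs over co-occupied bins; the set is converged when
    every successive deviation stays below ``tolerance`` (default
    1 kcal·mol⁻¹), i.e. the cumulative PMFs have stabilized over the series.
    """
    if scheme not in ("direct", "reverse"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    if n_blocks < 2:
        raise ValidationError("n_blocks must be >= 2")
    if bin_range is None:
        xs = np.concatenate([w.x for w in windows])
        bin_range = (float(xs.min()), float(xs.max()))

    profiles: list[FreeEnergyProfile] = []
    fractions: list[float] = []
    for blk in range(1, n_blocks + 1):
        frac = blk / n_blocks
        truncated = []
        for w in windows:
            n = len(w.series)
            m = max(1, int(round(frac * n)))
            sl = slice(0, m) if scheme == "direct" else slice(n - m, n)
            truncated.append(UmbrellaWindow(
                center=w.center, force_constant=w.force_constant,
                series=w.series.select(sl), biased_label=w.biased_label,
            ))
        _, profile = wham_solve(truncated, n_bins=n_bins, bin_range=bin_range,
                                tolerance=wham_tolerance)
        profiles.append(profile)
        fractions.append(frac)

    deviations = [profile_deviation(profiles[i], profiles[i + 1])
                  for i in range(len(profiles) - 1)]
    return ConvergenceReport(
        scheme=scheme, fractions=fractions, profiles=profiles,
        deviations=deviations, tolerance=tolerance,
        converged=bool(deviations and max(deviations) < tolerance),
    )


def tst_convert(value: float, direction: str, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Eyring conversion k = (kB·T/h)·exp(−ΔG‡/RT) between barrier and rate.

    ``barrier_to_rate`` takes kcal·mol⁻¹ and returns s⁻¹; ``rate_to_barrier``
    inverts it.  The round trip is the identity.
    """
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    prefactor = KB_SI * temperature / PLANCK_SI
    rt = KB_KCAL * temperature
    if direction == "barrier_to_rate":
        return prefactor * math.exp(-value / rt)
    if direction == "rate_to_barrier":
        if value <= 0:
            raise ValidationError("rate must be positive")
        return -rt * math.log(value / prefactor)
    raise ValidationError(f"unknown direction {direction!r}")
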