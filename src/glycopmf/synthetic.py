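"""Synthetic biased-dynamics generators with analytically known ground truth.

Everything downstream (WHAM, projections, puckering, clustering) is testable
against these generators: overdamped Langevin sampling on analytic potentials
whose PMF is the potential itself, ideal ring geometries at canonical pucker
vertices, and Gaussian-mixture active-site distance series with known basin
occupancies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .errors import NumericalError, ValidationError
from .puckering import RingGeometry, canonical_table, displacements_from_pucker
from .series import CVSeries

__all__ = [
    "PotentialSpec",
    "BiasSpec",
    "simulate_langevin",
    "generate_umbrella_set",
    "generate_ring_conformer",
    "generate_active_site_series",
]

#: edge length (Å) of the reference hexagon used for ring generation
_RING_EDGE = 1.52


@dataclass
class PotentialSpec:
    """Analytic 1D potential (or separable 2D pair) with a known PMF.

    Supported forms
    ---------------
    harmonic
        U(x) = κ/2 · (x − x0)², params ``stiffness`` (kcal·mol⁻¹·Å⁻²) and
        ``center`` (Å).
    double_well
        U(x) = ΔU‡ · ((x/b)² − 1)², params ``barrier`` (kcal·mol⁻¹) and
        ``half_separation`` b (Å); U(±b) = 0 and U(0) = ΔU‡.
    tabulated_1d
        Cubic-spline interpolation of params ``x`` / ``u`` arrays.
    separable_2d
        params ``x`` and ``y`` hold two 1D PotentialSpec components.
    """

    form: str
    params: dict = field(default_factory=dict)
    domain: tuple[float, float] = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if self.form not in ("harmonic", "double_well", "tabulated_1d", "separable_2d"):
            raise ValidationError(f"unknown potential form {self.form!r}")
        lo, hi = self.domain
        if not lo < hi:
            raise ValidationError(f"empty domain {self.domain}")
        if self.form == "tabulated_1d":
            x = np.asarray(self.params["x"], dtype=float)
            u = np.asarray(self.params["u"], dtype=float)
            if not (np.all(np.isfinite(x)) and np.all(np.isfinite(u))):
                raise ValidationError("tabulated potential contains non-finite values")
            if x.size < 4 or np.any(np.diff(x) <= 0):
                raise ValidationError("tabulated grid must be increasing with >= 4 points")
            self._spline = CubicSpline(x, u)
            self._spline_d = self._spline.derivative()

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            return 0.5 * self.params.get("stiffness", 1.0) * (x - self.params.get("center", 0.0)) ** 2
        if self.form == "double_well":
            b = self.params.get("half_separation", 1.0)
            return self.params.get("barrier", 5.0) * ((x / b) ** 2 - 1.0) ** 2
        if self.form == "tabulated_1d":
            return self._spline(x)
        raise ValidationError("energy(x) is defined for 1D forms only")

    def force(self, x):
        """−dU/dx."""
        x = np.asarray(x, dtype=float)
        if self.form == "harmonic":
            return -self.params.get("stiffness", 1.0) * (x - self.params.get("center", 0.0))
        if self.form == "double_well":
            b = self.params.get("half_separation", 1.0)
            du = self.params.get("barrier", 5.0)
            return -4.0 * du * x * ((x / b) ** 2 - 1.0) / b**2
        if self.form == "tabulated_1d":
            return -self._spline_d(x)
        raise ValidationError("force(x) is defined for 1D forms only")

    def pmf(self, x):
        """Exact PMF of overdamped sampling: the potential itself (1D)."""
        return self.energy(x)

    def boltzmann_pmf(self, edges: np.ndarray, temperature: float) -> np.ndarray:
        """Bin-averaged reference PMF −kBT·ln ∫_bin exp(−βU) dx, min-anchored at 0."""
        beta = 1.0 / (KB_KCAL * temperature)
        out = np.empty(len(edges) - 1)
        for i in range(len(edges) - 1):
            grid = np.linspace(edges[i], edges[i + 1], 64)
            w = np.trapezoid(np.exp(-beta * self.energy(grid)), grid)
            out[i] = -math.log(w) / beta if w > 0 else np.inf
        return out - np.min(out)


@dataclass
class BiasSpec:
    """Harmonic bias: absent, fixed, or with a center moving linearly in time."""

    kind: str = "none"
    center: float = 0.0
    force_constant: float = 0.0
    # moving_harmonic schedule
    center_start: float = 0.0
    center_end: float = 0.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "fixed_harmonic", "moving_harmonic"):
            raise ValidationError(f"unknown bias kind {self.kind!r}")
        if self.force_constant < 0:
            raise ValidationError("force_constant must be >= 0")
        if self.kind == "moving_harmonic" and self.duration <= 0:
            raise ValidationError("moving_harmonic needs a positive schedule duration")

    def center_at(self, t: float) -> float:
        if self.kind != "moving_harmonic":
            return self.center
        frac = min(max(t / self.duration, 0.0), 1.0)
        return self.center_start + frac * (self.center_end - self.center_start)

    def energy(self, x: float, t: float = 0.0) -> float:
        if self.kind == "none":
            return 0.0
        return 0.5 * self.force_constant * (x - self.center_at(t)) ** 2

    def force(self, x: float, t: float = 0.0) -> float:
        if self.kind == "none":
            return 0.0
        return -self.force_constant * (x - self.center_at(t))


def _reflect(x: float, lo: float, hi: float) -> float:
    # reflecting walls; loop guards against multi-crossing at large steps
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        if x > hi:
            x = 2.0 * hi - x
    return x


def simulate_langevin(
    potential: PotentialSpec,
    bias: BiasSpec | None = None,
    n_steps: int = 10000,
    dt: float = 2e-4,
    temperature: float = DEFAULT_TEMPERATURE,
    friction: float = 1.0,
    x0: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    label: str = "x",
) -> CVSeries:
    """Overdamped (Brownian) Langevin sampling of ``potential`` + ``bias``.

    First-order Euler–Maruyama update
    ``x ← x + (dt/γ)·F(x) + sqrt(2·kBT·dt/γ)·N(0,1)`` with reflecting walls at
    the potential-domain edges.  Deterministic for a fixed seed.  The
    stationary distribution is Boltzmann in the total potential up to O(dt)
    discretisation bias, so keep ``dt·κ_max/γ`` well below 1.
    """
    if bias is None:
        bias = BiasSpec()
    if dt <= 0:
        raise ValidationError("dt must be positive")
    if friction <= 0:
        raise ValidationError("friction must be positive")
    if n_steps <= 0:
        raise ValidationError("n_steps must be positive")
    if temperature < 0:
        raise ValidationError("temperature must be nonnegative")
    lo, hi = potential.domain
    if not lo <= x0 <= hi:
        raise ValidationError(f"x0={x0} outside potential domain {potential.domain}")

    rng = np.random.default_rng(seed)
    mobility = dt / friction
    sigma = math.sqrt(2.0 * KB_KCAL * temperature * dt / friction)
    noise = rng.standard_normal(n_steps) if sigma > 0 else np.zeros(n_steps)

    x = float(x0)
    xs = np.empty(n_steps)
    t = 0.0
    for i in range(n_steps):
        f = float(potential.force(x)) + bias.force(x, t)
        if not math.isfinite(f):
            raise NumericalError(f"non-finite force at x={x}")
        x = _reflect(x + mobility * f + sigma * noise[i], lo, hi)
        t += dt
        xs[i] = x

    times = dt * np.arange(1, n_steps + 1)
    # CVSeries requires T > 0; clamp the stored metadata in the T -> 0 limit
    return CVSeries(times=times, values=xs, labels=[label],
                    temperature=temperature if temperature > 0 else 5e-324)


def generate_umbrella_set(
    potential: PotentialSpec,
    centers,
    force_constant: float = 150.0,
    steps_per_window: int = 10000,
    temperature: float = DEFAULT_TEMPERATURE,
    seed: int = 0,
    dt: float = 2e-4,
    friction: float = 1.0,
    label: str = "x",
):
    """One harmonically biased window per center, every window deterministically seeded.

    Default ``force_constant`` of 150 kcal·mol⁻¹·Å⁻² sits inside the
    conventional 100–200 range used with 0.10 Å window spacing.  Warns when
    the center spacing exceeds twice the biased-sampling width
    ``sqrt(kBT/force_constant)``, since neighboring histograms then risk
    losing overlap.  Returns a list of :class:`glycopmf.free_energy.UmbrellaWindow`.
    """
    from .free_energy import UmbrellaWindow  # deferred: avoids a cycle

    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValidationError("centers must be nonempty")
    if np.any(np.diff(centers) <= 0):
        raise ValidationError("centers must be sorted and distinct")
    if force_constant < 0:
        raise ValidationError("force_constant must be nonnegative")
    spacing = np.max(np.diff(centers)) if centers.size > 1 else 0.0
    width = math.sqrt(KB_KCAL * temperature / force_constant) if force_constant > 0 else math.inf
    if spacing > 2.0 * width:
        warnings.warn(
            f"window spacing {spacing:.3f} Å exceeds 2·sqrt(kBT/k) = {2*width:.3f} Å; "
            "neighboring windows may not overlap",
            stacklevel=2,
        )

    child_seeds = np.random.SeedSequence(seed).spawn(centers.size)
    windows = []
    lo, hi = potential.domain
    for center, child in zip(centers, child_seeds):
        if force_constant > 0:
            bias = BiasSpec(kind="fixed_harmonic", center=float(center),
                            force_constant=force_constant)
        else:
            bias = BiasSpec(kind="none")
        series = simulate_langevin(
            potential, bias, n_steps=steps_per_window, dt=dt,
            temperature=temperature, friction=friction,
            x0=min(max(float(center), lo), hi), seed=child, label=label,
        )
        windows.append(UmbrellaWindow(center=float(center),
                                      force_constant=force_constant,
                                      series=series))
    return windows


def generate_ring_conformer(
    label: str,
    Q: float = 0.57,
    seed: int = 0,
    noise: float = 0.0,
    frame_id: int = 0,
) -> RingGeometry:
    """Ideal six-ring geometry whose Cremer–Pople coordinates hit a canonical vertex.

    The out-of-plane displacements are obtained by inverting the puckering
    decomposition at the canonical (phi, theta) of ``label`` and are applied
    to a regular hexagon with 1.52 Å edges, traversed so that the analysis
    convention recovers the same vertex.  ``noise`` adds isotropic Gaussian
    jitter (Å) to every atom.
    """
    if Q < 0:
        raise ValidationError("Q must be nonnegative")
    if noise < 0:
        raise ValidationError("noise must be nonnegative")
    if label == "planar":
        z = np.zeros(6)
    else:
        table = canonical_table()
        if label not in table:
            raise ValidationError(
                f"unknown conformer label {label!r}; expected 'planar' or one of {sorted(table)}"
            )
        phi, theta = table[label]
        q2 = Q * math.sin(math.radians(theta))
        q3 = Q * math.cos(math.radians(theta))
        z = displacements_from_pucker(q2, phi, q3)
    # clockwise traversal puts the mean-plane normal along +z for this ordering
    ang = -2.0 * np.pi * np.arange(6) / 6.0
    coords = np.column_stack([_RING_EDGE * np.cos(ang), _RING_EDGE * np.sin(ang), z])
    if noise > 0:
        rng = np.random.default_rng(seed)
        coords = coords + noise * rng.standard_normal(coords.shape)
    return RingGeometry(coords=coords, frame_id=frame_id)


def generate_active_site_series(
    basins,
    n_frames: int,
    seed: int = 0,
    labels: list[str] | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    frame_spacing: float = 1.0,
) -> CVSeries:
    """Gaussian-mixture sampler over named active-site distances.

    ``basins`` is a list of ``(mean, covariance, weight)`` with positive
    weights summing to 1 and positive-definite covariances (pass a scalar or
    diagonal for uncorrelated coordinates; exact zero covariance pins frames
    to the mean).  Negative draws are rejected and resampled because
    distances are physically nonnegative.
    """
    if n_frames <= 0:
        raise ValidationError("n_frames must be positive")
    if not basins:
        raise ValidationError("at least one basin required")
    means, covs, weights = [], [], []
    for mean, cov, weight in basins:
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        if np.any(mean <= 0):
            raise ValidationError("basin distance means must be positive")
        dim = mean.size
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 0:
            cov = np.eye(dim) * float(cov)
        elif cov.ndim == 1:
            cov = np.diag(cov)
        if cov.shape != (dim, dim):
            raise ValidationError(f"covariance shape {cov.shape} does not match dim {dim}")
        if np.any(np.diag(cov) < 0) or not np.allclose(cov, cov.T):
            raise ValidationError("covariance must be symmetric nonnegative")
        if np.any(cov) and np.min(np.linalg.eigvalsh(cov)) < -1e-12:
            raise ValidationError("degenerate (non-PSD) covariance")
        means.append(mean)
        covs.append(cov)
        weights.append(float(weight))
    if any(w <= 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
        raise ValidationError("weights must be positive and sum to 1")
    dims = {m.size for m in means}
    if len(dims) != 1:
        raise ValidationError("all basins must share dimensionality")
    dim = dims.pop()
    if labels is None:
        default = ["d_acid", "d_nuc", "d_glyc", "d_hb_Asp300",
                   "d_Glu233_WAT", "d_glyc_WAT"]
        labels = default[:dim] if dim <= len(default) else [f"d{i}" for i in range(dim)]
    if len(labels) != dim:
        raise ValidationError(f"{len(labels)} labels for {dim} coordinates")

    rng = np.random.default_rng(seed)
    which = rng.choice(len(basins), size=n_frames, p=weights)
    values = np.empty((n_frames, dim))
    for b in range(len(basins)):
        idx = np.flatnonzero(which == b)
        if idx.size == 0:
            continue
        if not np.any(covs[b]):
            values[idx] = means[b]
            continue
        draws = rng.multivariate_normal(means[b], covs[b], size=idx.size,
                                        method="cholesky" if np.all(np.linalg.eigvalsh(covs[b]) > 0) else "svd")
        bad = np.flatnonzero(np.any(draws <= 0, axis=1))
        guard = 0
        while bad.size:
            draws[bad] = rng.multivariate_normal(means[b], covs[b], size=bad.size)
            bad = bad[np.any(draws[bad] <= 0, axis=1)]
            guard += 1
            if guard > 1000:
                raise NumericalError("rejection sampling failed; basin mass is mostly negative")
        values[idx] = draws
    times = frame_spacing * np.arange(1, n_frames + 1)
    return CVSeries(times=times, values=values, labels=list(labels),
                    temperature=temperature)
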